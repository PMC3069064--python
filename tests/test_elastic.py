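"""Elastic forces: closed forms, gradient consistency, gate state machine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ciliasim import elastic
from ciliasim.elastic import (DegenerateSegmentError, ElasticParams,
                              bending_force, gate_update, link_force,
                              stretching_force, total_energy,
                              total_force_density)
from ciliasim.geometry import GateState, LagrangianBoundary, LinkElement

PARAMS = ElasticParams()


def chain(points, diameter=200e-9, r0=75e-9):
    X = np.asarray(points, dtype=float)
    n = len(X)
    return LagrangianBoundary(
        boundary_id="test", X=X,
        rest_segment_lengths=np.full(n - 1, r0),
        local_diameters=np.full(n, diameter),
        anchored=np.zeros(n, dtype=bool))


class TestStretching:
    def test_rest_chain_has_zero_force(self):
        b = chain([[0, 0], [0, 75e-9], [0, 150e-9]])
        np.testing.assert_allclose(stretching_force(b, PARAMS), 0.0)

    def test_single_segment_closed_form_tension(self):
        # strain 1e-3 on a 200 nm rod: T = E * pi d^2/4 * eps ~ 7.2e-8 N
        eps = 1e-3
        b = chain([[0, 0], [0, 75e-9 * (1 + eps)]])
        F = stretching_force(b, PARAMS)
        expected = PARAMS.youngs_modulus * np.pi * (200e-9) ** 2 / 4 * eps
        assert F[0, 1] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(7.2e-8, rel=0.01)
        np.testing.assert_allclose(F[0], -F[1])

    def test_interior_point_of_uniform_stretch_feels_no_net_force(self):
        s = 80e-9
        b = chain([[0, 0], [0, s], [0, 2 * s]])
        F = stretching_force(b, PARAMS)
        np.testing.assert_allclose(F[1], 0.0, atol=1e-20)

    def test_coincident_points_raise(self):
        b = chain([[0, 0], [0, 0]])
        with pytest.raises(DegenerateSegmentError):
            stretching_force(b, PARAMS)


class TestBending:
    def test_straight_triad_has_zero_bending_force(self):
        b = chain([[0, 0], [0, 75e-9], [0, 150e-9]])
        np.testing.assert_allclose(bending_force(b, PARAMS), 0.0, atol=1e-25)

    def test_triad_forces_sum_to_zero(self):
        rng = np.random.default_rng(7)
        X = np.array([[0, 0], [5e-9, 75e-9], [-3e-9, 150e-9]])
        F = bending_force(chain(X), PARAMS)
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-14 * np.abs(F).max())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_force_is_negative_energy_gradient(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        X = np.column_stack([rng.normal(0, 3e-9, n), np.arange(n) * 75e-9])
        b = chain(X)
        F = bending_force(b, PARAMS) + stretching_force(b, PARAMS)
        eps = 1e-13

        def energy():
            return (elastic.bending_energy(b, PARAMS)
                    + elastic.stretching_energy(b, PARAMS))

        for i in rng.integers(0, n, 4):
            for d in (0, 1):
                orig = b.X[i, d]
                b.X[i, d] = orig + eps
                ep = energy()
                b.X[i, d] = orig - eps
                em = energy()
                b.X[i, d] = orig
                fd = -(ep - em) / (2 * eps)
                assert fd == pytest.approx(F[i, d], rel=5e-4, abs=1e-16)


class TestLinkForce:
    def _pair(self, extension):
        a = chain([[0, 0], [0, 75e-9]])
        b_ = chain([[170e-9 + extension, 0], [170e-9 + extension, 75e-9]])
        link = LinkElement("top_connector", ((0, 0), (1, 0)), 170e-9, 5e-4)
        return [a, b_], link

    def test_hookes_law_signed(self):
        rows, link = self._pair(10e-9)
        Fa, Fb, T = link_force(link, rows)
        assert T == pytest.approx(5e-12)          # 10 nm at 5e-4 N/m = 5 pN
        rows, link = self._pair(-10e-9)
        _, _, T = link_force(link, rows)
        assert T == pytest.approx(-5e-12)         # symmetric in compression

    def test_zero_extension_zero_force(self):
        rows, link = self._pair(0.0)
        Fa, Fb, T = link_force(link, rows)
        assert T == 0.0
        np.testing.assert_allclose(Fa, 0.0)

    def test_forces_equal_and_opposite(self):
        rows, link = self._pair(25e-9)
        Fa, Fb, _ = link_force(link, rows)
        np.testing.assert_allclose(Fa, -Fb)


class TestGate:
    def _link(self, **gate_kw):
        link = LinkElement("upper_tip_link", ((0, 0), (1, 0)), 170e-9, 5e-4,
                           gate=GateState(**gate_kw))
        return link

    def test_below_threshold_stays_closed(self):
        link = self._link()
        gate_update(link, 0.99 * link.gate.threshold, t=0.0)
        assert not link.gate.is_open

    def test_at_threshold_opens_and_ramps_to_5nm(self):
        link = self._link(elongation_time=1e-6)
        gate_update(link, link.gate.threshold, t=0.0)
        assert link.gate.is_open
        assert link.gate.rest_increment(0.5e-6) == pytest.approx(2.5e-9)
        assert link.gate.rest_increment(2e-6) == pytest.approx(5e-9)
        assert link.current_rest_length(2e-6) == pytest.approx(175e-9)

    def test_compression_never_opens(self):
        link = self._link()
        gate_update(link, -10 * link.gate.threshold, t=0.0)
        assert not link.gate.is_open

    def test_latch_holds_when_tension_drops(self):
        link = self._link()
        gate_update(link, link.gate.threshold, t=0.0)
        gate_update(link, 0.0, t=1e-3)
        assert link.gate.is_open

    def test_optional_reclosure(self):
        link = self._link(reclose_enabled=True, reclose_fraction=0.5)
        gate_update(link, link.gate.threshold, t=0.0)
        gate_update(link, 0.1 * link.gate.threshold, t=1e-3)
        assert not link.gate.is_open

    @given(st.lists(st.floats(0, 2), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_open_state_monotone_in_running_max_tension(self, fractions):
        link = self._link()
        thr = link.gate.threshold
        opened = []
        for i, f in enumerate(fractions):
            gate_update(link, f * thr, t=i * 1e-5)
            opened.append(link.gate.is_open)
        # open iff the running max has reached the threshold; never re-closes
        expect = np.maximum.accumulate(np.asarray(fractions)) >= 1.0
        assert opened == list(expect)


class TestTotalForce:
    def test_rest_bundle_is_force_free(self, bundle):
        rows, links = bundle
        F, tensions = total_force_density(rows, links, PARAMS)
        for f in F:
            np.testing.assert_allclose(f, 0.0, atol=1e-16)
        np.testing.assert_allclose(tensions, 0.0, atol=1e-16)

    def test_internal_forces_conserve_momentum(self, bundle):
        rows, links = bundle
        rng = np.random.default_rng(3)
        for r in rows:
            r.X = r.X + rng.normal(0, 2e-9, r.X.shape)
        F, _ = total_force_density(rows, links, PARAMS)
        total = np.sum([f.sum(axis=0) for f in F], axis=0)
        scale = max(np.abs(np.concatenate(F)).max(), 1e-30)
        np.testing.assert_allclose(total / scale, 0.0, atol=1e-10)

    def test_energy_nonnegative_and_zero_at_rest(self, bundle):
        rows, links = bundle
        assert total_energy(rows, links, PARAMS) == pytest.approx(0.0, abs=1e-25)
        rng = np.random.default_rng(5)
        for r in rows:
            r.X = r.X + rng.normal(0, 1e-9, r.X.shape)
        assert total_energy(rows, links, PARAMS) > 0
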