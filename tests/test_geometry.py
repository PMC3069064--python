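"""Bundle construction: row chains, taper, link attachment, invariants."""

import numpy as np
import pytest
from dataclasses import replace

from ciliasim.geometry import (BundleConfig, ConfigurationError, attach_links,
                               build_bundle, build_rows, geometry_table,
                               taper_profile)
from ciliasim.elastic import link_extension


class TestBundleConfig:
    def test_tallest_row_height_is_gap_minus_clearance(self, default_config):
        assert default_config.tallest_height == pytest.approx(4.5e-6)

    def test_widened_gap_clearance(self):
        cfg = replace(BundleConfig(), gap_height=10e-6, tm_clearance=5.5e-6)
        cfg.validate()
        assert cfg.tallest_height == pytest.approx(4.5e-6)
        assert cfg.tm_clearance == pytest.approx(5.5e-6)

    @pytest.mark.parametrize("bad", [
        dict(gap_height=0.4e-6),                      # clearance exceeds gap
        dict(row_height_ratios=(1.0, 0.35, 0.65)),    # not strictly ordered
        dict(shaft_diameter=-1e-9),
        dict(inter_row_spacing=200e-9),               # wider than the tip link
    ])
    def test_invalid_configs_name_the_violation(self, bad):
        with pytest.raises(ConfigurationError):
            replace(BundleConfig(), **bad).validate()

    def test_yaml_round_trip(self, tmp_path, default_config):
        path = tmp_path / "bundle.yaml"
        default_config.to_yaml(path)
        assert BundleConfig.from_yaml(path) == default_config


class TestRows:
    def test_point_counts_follow_heights(self, bundle):
        rows, _ = bundle
        # 4.5 um / 75 nm = 60 segments -> 61 points; ratios 0.65/0.35 likewise
        assert [r.n_points for r in rows] == [61, 40, 22]

    def test_rest_segments_equal_r0(self, bundle, default_config):
        rows, _ = bundle
        for r in rows:
            np.testing.assert_allclose(
                r.rest_segment_lengths, default_config.lagrangian_spacing)
            seg = np.linalg.norm(np.diff(r.X, axis=0), axis=1)
            np.testing.assert_allclose(seg, default_config.lagrangian_spacing)

    def test_rows_centered_and_inside_domain(self, bundle, default_config):
        rows, _ = bundle
        cfg = default_config
        xs = [r.X[0, 0] for r in rows]
        assert xs[1] == pytest.approx(cfg.domain_length / 2)
        assert xs[0] < xs[1] < xs[2]          # tallest on the left
        for r in rows:
            assert np.all(r.X[:, 0] > 0) and np.all(r.X[:, 0] < cfg.domain_length)
            assert np.all(r.X[:, 1] >= 0) and np.all(r.X[:, 1] < cfg.gap_height)

    def test_base_points_anchored(self, bundle):
        rows, _ = bundle
        for r in rows:
            assert r.anchored[:2].all() and not r.anchored[2:].any()

    def test_taper_only_on_lower_third(self, bundle, default_config):
        rows, _ = bundle
        cfg = default_config
        for r in rows:
            frac = r.X[:, 1] / r.X[-1, 1]
            shaft = frac >= cfg.base_fraction
            np.testing.assert_allclose(r.local_diameters[shaft], cfg.shaft_diameter)
            assert r.local_diameters[0] == pytest.approx(cfg.base_diameter)

    def test_rebuild_is_deterministic(self, default_config):
        a, _ = build_bundle(default_config)
        b, _ = build_bundle(default_config)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.X, rb.X)
            np.testing.assert_array_equal(ra.local_diameters, rb.local_diameters)


class TestTaperProfile:
    def test_endpoints_and_midpoint(self, default_config):
        cfg = default_config
        assert taper_profile(0.0, cfg) == pytest.approx(cfg.base_diameter)
        assert taper_profile(0.5, cfg) == pytest.approx(cfg.shaft_diameter)
        assert taper_profile(1.0, cfg) == pytest.approx(cfg.shaft_diameter)
        mid = 0.5 * (cfg.base_diameter + cfg.shaft_diameter)
        assert taper_profile(1.0 / 6.0, cfg) == pytest.approx(mid)

    def test_out_of_range_raises(self, default_config):
        with pytest.raises(ValueError):
            taper_profile(-0.1, default_config)
        with pytest.raises(ValueError):
            taper_profile(1.1, default_config)


class TestLinks:
    def test_two_gated_tip_links_six_ungated_connectors(self, bundle):
        _, links = bundle
        gated = [l for l in links if l.gate is not None]
        connectors = [l for l in links if l.kind == "top_connector"]
        assert len(gated) == 2 and len(connectors) == 6
        assert {l.kind for l in gated} == {"upper_tip_link", "lower_tip_link"}

    def test_upper_tip_link_joins_tallest_and_middle(self, bundle):
        rows, links = bundle
        upper = next(l for l in links if l.kind == "upper_tip_link")
        lower = next(l for l in links if l.kind == "lower_tip_link")
        assert {rows[e[0]].boundary_id for e in upper.endpoints} == {"tallest", "middle"}
        assert {rows[e[0]].boundary_id for e in lower.endpoints} == {"middle", "shortest"}

    def test_rest_extension_is_zero(self, bundle):
        rows, links = bundle
        for l in links:
            assert abs(link_extension(l, rows)) < 1e-15

    def test_tip_link_rest_length_170nm(self, bundle):
        rows, links = bundle
        for l in links:
            if l.gate is not None:
                assert l.rest_length == pytest.approx(170e-9)

    def test_connectors_horizontal_on_top_tenth(self, bundle, default_config):
        rows, links = bundle
        for l in links:
            if l.kind != "top_connector":
                continue
            (bi, pi), (bj, pj) = l.endpoints
            assert rows[bi].X[pi, 1] == pytest.approx(rows[bj].X[pj, 1])
            shorter = rows[max(bi, bj)]
            assert rows[bj].X[pj, 1] >= 0.9 * shorter.X[-1, 1] - 1e-12

    def test_impossible_attachment_raises(self, default_config):
        cfg = replace(default_config, tip_link_rise_points=5)
        rows = build_rows(cfg)
        with pytest.raises(ConfigurationError):
            attach_links(rows, cfg)


def test_geometry_table_lists_every_point(bundle):
    rows, _ = bundle
    tab = geometry_table(rows)
    assert len(tab) == sum(r.n_points for r in rows)
    assert set(tab.columns) >= {"boundary_id", "point", "x", "y", "diameter"}
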