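"""Shared fixtures: bundle geometry and cached quarter-resolution runs.

The scenario runs are expensive (a few minutes each), so they are session
scoped and shared between the behavioral tests and the acceptance suite.
"""

import pytest

from ciliasim.geometry import BundleConfig, build_bundle
from ciliasim.scenario import make_scenario
from ciliasim.simulation import Simulation


@pytest.fixture(scope="session")
def default_config():
    return BundleConfig()


@pytest.fixture()
def bundle(default_config):
    return build_bundle(default_config)


def _run(name, **overrides):
    sc = make_scenario(name, **overrides)
    return Simulation(sc).run()


@pytest.fixture(scope="session")
def normal_run():
    """Normal scenario: 5 um gap, orbital 200 Hz drive.

    Half resolution (h = 156 nm) is the coarsest grid that resolves the
    0.5 um clearance between the tallest row and the tectorial membrane,
    which controls the tip-link phasing; 3 cycles with 2 discarded keeps the
    run inside the suite's time budget.
    """
    return _run("normal", gate_trigger="disabled", resolution="half",
                n_cycles=3)


@pytest.fixture(scope="session")
def widened_gap_run():
    """Tectorial membrane moved 5 um further from the lamina."""
    return _run("widened_gap", gate_trigger="disabled", resolution="half",
                n_cycles=3)


@pytest.fixture(scope="session")
def horizontal_only_run():
    """Same as normal but with the vertical drive component removed."""
    return _run("horizontal_only", gate_trigger="disabled", resolution="half",
                n_cycles=3)


@pytest.fixture(scope="session")
def gating_run():
    """Normal scenario with auto-armed gate thresholds so that a
    gating-spring elongation event occurs during the analyzed cycles."""
    return _run("normal", gate_trigger="auto")
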