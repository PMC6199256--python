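import numpy as np
import pytest

from spinecalc import (
    ModelConfig,
    ScenarioConfig,
    SpineParams,
    build_compartment_grid,
    run_scenario,
)

# The scan lists of the ER-length experiments (µm).
PULSE_SCAN = (0.5, 0.7, 0.75, 0.8, 1.0, 1.5)
NMDAR_SCAN = (0.3, 0.35, 0.4, 0.45, 0.5)


@pytest.fixture(scope="session")
def cfg():
    return ModelConfig()


@pytest.fixture(scope="session")
def default_params():
    return SpineParams()


@pytest.fixture(scope="session")
def default_grid(default_params):
    return build_compartment_grid(default_params)


# ---------------------------------------------------------------------------
# Shared heavy scenario runs (computed once per session)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def no_spine_er_run(cfg):
    """1 ms pulse into a spine without spine ER, 100 ms."""
    sc = ScenarioConfig(er_composition="none", release="pulse1ms",
                        spine_er_lengths=(0.0,), duration=0.1)
    return run_scenario(sc, cfg).runs[0]


@pytest.fixture(scope="session")
def ryr_15_run(cfg):
    """RyR-carrying ER of length 1.5 µm, 1 ms pulse."""
    sc = ScenarioConfig(er_composition="RyR", release="pulse1ms",
                        spine_er_lengths=(1.5,))
    return run_scenario(sc, cfg).runs[0]


@pytest.fixture(scope="session")
def passive_15_run(cfg):
    """Matched purely passive ER of length 1.5 µm, 1 ms pulse."""
    sc = ScenarioConfig(er_composition="passive", release="pulse1ms",
                        spine_er_lengths=(1.5,))
    return run_scenario(sc, cfg).runs[0]


@pytest.fixture(scope="session")
def pulse_scan_runs(cfg):
    """RyR-only ER-length scan under the 1 ms pulse."""
    sc = ScenarioConfig(er_composition="RyR", release="pulse1ms",
                        spine_er_lengths=PULSE_SCAN)
    res = run_scenario(sc, cfg)
    return {r.spine_er_length: r for r in res.runs}


@pytest.fixture(scope="session")
def nmdar_scan_runs(cfg):
    """RyR-only ER-length scan under the 150 ms NMDAR release."""
    sc = ScenarioConfig(er_composition="RyR", release="nmdar150ms",
                        spine_er_lengths=NMDAR_SCAN)
    res = run_scenario(sc, cfg)
    return {r.spine_er_length: r for r in res.runs}


def roi_free_amount_above_baseline(run):
    """Peak free Ca²⁺ (mol) above baseline in the dendritic ROI."""
    grid = run.result.grid
    roi = grid.roi_indices("dendrite_roi")
    v = float(grid.cyt_vol[roi].sum())
    tr = run.result.traces["dendrite_roi"]
    return float((tr - tr[0]).max() * v * 1e-21)
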