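import numpy as np
import pytest

from drmmrm import Design, Scenario, run_study, scenario_grid, simulate_trial, summarize


@pytest.fixture(scope="session")
def design():
    return Design()


@pytest.fixture(scope="session")
def small_trial(design):
    """One 4-dose trial replicate used by several estimator tests."""
    sc = Scenario(ed50_true=8.0, timecourse="direct", n_reps=10, seed=7)
    return simulate_trial(sc, design, 0)


@pytest.fixture(scope="session")
def tiny_design():
    """A 3-visit, 2-subjects-per-arm design for brute-force oracles."""
    return Design(visit_weeks=(2, 4, 6), n_per_arm=2)


@pytest.fixture(scope="session")
def mmrm_audit(design):
    """MMRM-only run of the full 4-dose grid at 100 replicates.

    The scaled unbiasedness audit: 21 scenarios x 100 reps, enough for
    the recomputed +/-2 SD band check over the 84-cell grid.
    """
    scens = scenario_grid(n_reps=100, master_seed=20260921)
    raw = run_study(scens, design, methods=("MMRM",))
    return summarize(raw, design), 100


@pytest.fixture(scope="session")
def scaled_grid(design):
    """All three methods on the full 4-dose grid at 50 replicates.

    Shared by the RMSE-ordering and bias-bound checks; kept at 50 reps
    so the whole grid (3,150 method fits) stays desk scale.
    """
    scens = scenario_grid(n_reps=50, master_seed=917)
    raw = run_study(scens, design)
    return summarize(raw, design), raw, 50
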