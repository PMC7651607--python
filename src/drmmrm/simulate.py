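"""Trial-data simulator.

Simulates log-scale change from baseline in UACR directly at the nine
post-baseline visits:

    y_{i,t} = effect(dose_i, week_t) + eta_i + eps_{i,t}

with a subject-level random intercept ``eta_i ~ N(0, omega^2)`` and
AR(1) residuals ``eps_i ~ N(0, sigma^2 R(rho))``, where ``R`` has
entries ``rho^|i-j|`` over visit positions (so the closely spaced
week-14/15/16 visits correlate as strongly as the 2-week-spaced ones).
The marginal per-visit variance omega^2 + sigma^2 is what drives both
the n=39 power computation and the sqrt(2 (omega^2+sigma^2) / n) ~ 0.14
theoretical precision of an end-of-study arm contrast.

Placebo response is exactly zero on the change scale: all reported
quantities are placebo-adjusted, so a common placebo drift would cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Design, Scenario
from .truth import TruthParams, true_effect

__all__ = [
    "TRIAL_COLUMNS",
    "ar1_correlation",
    "simulate_trial",
    "export_absolute_scale",
    "rederive_changes",
    "write_trial",
    "read_trial",
]

TRIAL_COLUMNS = [
    "subject",
    "arm",
    "dose",
    "visit",
    "week",
    "duacr",
    "scenario",
    "rep",
]


def ar1_correlation(rho: float, m: int) -> np.ndarray:
    """m x m first-order autoregressive correlation matrix rho^|i-j|."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    if m < 1:
        raise ValueError("m must be at least 1")
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _rep_rng(scenario: Scenario, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(rep,))
    )


def simulate_trial(scenario: Scenario, design: Design, rep: int) -> pd.DataFrame:
    """Simulate one complete, balanced trial replicate.

    Returns a long-format table with one row per subject x post-baseline
    visit, columns :data:`TRIAL_COLUMNS`.  Deterministic given
    ``(scenario.seed, rep)``.
    """
    if rep < 0 or rep >= scenario.n_reps:
        raise ValueError("rep must lie in [0, scenario.n_reps)")
    design = design.with_active_doses(scenario.doses)
    params = TruthParams(ed50=scenario.ed50_true, timecourse=scenario.timecourse)
    weeks = np.asarray(design.visit_weeks, dtype=float)
    m = design.n_visits
    n = design.n_per_arm
    rng = _rep_rng(scenario, rep)

    chol = np.linalg.cholesky(design.sigma**2 * ar1_correlation(design.rho, m))
    frames = []
    subj0 = 0
    for label, dose in design.arms:
        mu = np.array([true_effect(params, dose, w) for w in weeks])
        eta = rng.normal(0.0, design.omega, size=n)
        eps = rng.standard_normal((n, m)) @ chol.T
        y = mu[None, :] + eta[:, None] + eps
        frames.append(
            pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(subj0, subj0 + n), m),
                    "arm": label,
                    "dose": dose,
                    "visit": np.tile(np.arange(1, m + 1), n),
                    "week": np.tile(weeks, n),
                    "duacr": y.ravel(),
                }
            )
        )
        subj0 += n
    out = pd.concat(frames, ignore_index=True)
    out["scenario"] = scenario.label
    out["rep"] = rep
    return out


def export_absolute_scale(
    trial: pd.DataFrame, design: Design, seed: int = 0
) -> pd.DataFrame:
    """Emit absolute log-UACR rows including synthetic baseline visits.

    Each subject gets a latent baseline ``b_i ~ N(baseline_mean,
    omega^2)`` observed at the baseline weeks with centred residual
    noise, so the mean of the baseline rows is exactly ``b_i`` and
    subtracting it from the post-baseline rows recovers the simulated
    change-from-baseline panel bit-for-bit.
    """
    subjects = trial[["subject", "arm", "dose"]].drop_duplicates("subject")
    n_sub = len(subjects)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(n_sub,)))
    b = rng.normal(design.baseline_mean, design.omega, size=n_sub)
    b_map = dict(zip(subjects["subject"], b))

    base_rows = []
    kb = len(design.baseline_weeks)
    for (_, row), bi in zip(subjects.iterrows(), b):
        noise = rng.normal(0.0, design.sigma, size=kb)
        noise -= noise.mean()  # keep the baseline mean exactly b_i
        for w, e in zip(design.baseline_weeks, noise):
            base_rows.append(
                {
                    "subject": row["subject"],
                    "arm": row["arm"],
                    "dose": row["dose"],
                    "week": float(w),
                    "log_uacr": bi + e,
                }
            )
    base = pd.DataFrame(base_rows)
    post = trial[["subject", "arm", "dose", "week", "duacr"]].copy()
    post["log_uacr"] = post["duacr"] + post["subject"].map(b_map)
    post = post.drop(columns="duacr")
    out = pd.concat([base, post], ignore_index=True)
    return out.sort_values(["subject", "week"], kind="stable").reset_index(drop=True)


def rederive_changes(absolute: pd.DataFrame, design: Design) -> pd.DataFrame:
    """Recover change-from-mean-baseline rows from an absolute-scale table."""
    is_base = absolute["week"].isin(design.baseline_weeks)
    base_mean = absolute[is_base].groupby("subject")["log_uacr"].mean()
    post = absolute[~is_base].copy()
    post["duacr"] = post["log_uacr"] - post["subject"].map(base_mean)
    return post.drop(columns="log_uacr").reset_index(drop=True)


def write_trial(trial: pd.DataFrame, path) -> None:
    """Write a trial table to CSV with full float precision."""
    trial.to_csv(path, index=False, float_format="%.17g")


def read_trial(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trial`; validates schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c not in ("scenario", "rep")]
    if missing:
        raise ValueError(f"trial CSV missing required columns: {missing}")
    return df
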