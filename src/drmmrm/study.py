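"""Monte-Carlo study engine: simulate, fit, aggregate.

``run_study`` loops scenarios x replicates, simulates each trial, fits
the requested methods and collects the per-replicate placebo-adjusted
estimates plus ED50/Emax parameters.  ``summarize`` condenses the raw
records into the study's operating characteristics: per-cell bias,
relative bias, SD and RMSE of the last-visit effect, and median /
2.5th / 97.5th percentile summaries of ED50 and end-of-study Emax
(medians because boundary ED50 estimates make means meaningless).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .design import ARM_CONFIGS, Design, Scenario
from .estimators import fit_dreos, fit_drmmrm, fit_mmrm
from .metrics import relative_bias_pct, rmse, unbiasedness_band_pct
from .simulate import simulate_trial
from .truth import TruthParams, true_effect

__all__ = [
    "METHODS",
    "StudySummary",
    "run_study",
    "summarize",
    "band_exceedance_count",
]

METHODS: dict[str, Callable] = {
    "MMRM": fit_mmrm,
    "DR-EOS": fit_dreos,
    "DR-MMRM": fit_drmmrm,
}


@dataclass
class StudySummary:
    """Aggregated operating characteristics of a study run."""

    estimates: pd.DataFrame  # per (arm_config, timecourse, ed50_true, dose, method)
    dose_response: pd.DataFrame  # ED50/Emax percentile summaries
    failures: pd.DataFrame  # convergence failure counts per scenario x method
    n_reps: int


def _fit_one(method: str, trial: pd.DataFrame):
    return METHODS[method](trial)


def run_study(
    scenarios: Sequence[Scenario],
    design: Design,
    methods: Sequence[str] = ("MMRM", "DR-EOS", "DR-MMRM"),
    n_reps: int | None = None,
    checkpoint_dir: str | Path | None = None,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Run the simulation study; returns the raw per-replicate records.

    One row per (scenario, rep, method, dose, week) with the estimate,
    SE, convergence flag and — for the dose-response methods — the
    fitted ED50 and end-of-study Emax.  Deterministic given the scenario
    seeds.  With ``checkpoint_dir`` each scenario's records are written
    to ``<label>.csv`` once finished and reloaded instead of recomputed
    on a rerun, making interrupted runs resumable.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)

    frames = []
    for sc in scenarios:
        reps = n_reps if n_reps is not None else sc.n_reps
        path = ckpt / f"{sc.label}.csv" if ckpt is not None else None
        if path is not None and path.exists():
            frames.append(pd.read_csv(path, float_precision="round_trip"))
            if progress:
                progress(f"{sc.label}: loaded checkpoint")
            continue
        rows = []
        for rep in range(reps):
            trial = simulate_trial(sc, design, rep)
            for method in methods:
                fit = _fit_one(method, trial)
                ed50 = fit.dose_response.ed50_hat if fit.dose_response else np.nan
                emax = (
                    float(fit.dose_response.emax_hat[-1])
                    if fit.dose_response
                    else np.nan
                )
                at_bound = (
                    fit.dose_response.at_bound_ed50 if fit.dose_response else False
                )
                if fit.estimates.empty:
                    rows.append(
                        dict(
                            arm_config=sc.arm_config,
                            timecourse=sc.timecourse,
                            ed50_true=sc.ed50_true,
                            rep=rep,
                            method=method,
                            dose=np.nan,
                            week=np.nan,
                            estimate=np.nan,
                            se=np.nan,
                            ed50_hat=ed50,
                            emax_hat=emax,
                            ed50_at_bound=at_bound,
                            converged=fit.converged,
                        )
                    )
                    continue
                for r in fit.estimates.itertuples(index=False):
                    rows.append(
                        dict(
                            arm_config=sc.arm_config,
                            timecourse=sc.timecourse,
                            ed50_true=sc.ed50_true,
                            rep=rep,
                            method=method,
                            dose=r.dose,
                            week=r.week,
                            estimate=r.estimate,
                            se=r.se,
                            ed50_hat=ed50,
                            emax_hat=emax,
                            ed50_at_bound=at_bound,
                            converged=fit.converged,
                        )
                    )
        frame = pd.DataFrame(rows)
        frames.append(frame)
        if path is not None:
            frame.to_csv(path, index=False, float_format="%.17g")
        if progress:
            progress(f"{sc.label}: {reps} replicates done")
    return pd.concat(frames, ignore_index=True)


def _truth_last_visit(timecourse: str, ed50: float, dose: float, week: float) -> float:
    params = TruthParams(ed50=ed50, timecourse=timecourse)
    return true_effect(params, dose, week)


def summarize(raw: pd.DataFrame, design: Design) -> StudySummary:
    """Aggregate raw study records into operating characteristics."""
    last_week = float(np.nanmax(raw["week"]))
    conv = raw[raw["converged"].astype(bool)]
    last = conv[(conv["week"] == last_week)]

    keys = ["arm_config", "timecourse", "ed50_true", "dose", "method"]
    rows = []
    for key, grp in last.groupby(keys, sort=True):
        cfg, tc, ed50, dose, method = key
        truth = _truth_last_visit(tc, ed50, dose, last_week)
        est = grp["estimate"].to_numpy()
        mean = float(est.mean())
        sd = float(est.std(ddof=1)) if len(est) > 1 else 0.0
        bias = mean - truth
        rows.append(
            dict(
                arm_config=cfg,
                timecourse=tc,
                ed50_true=ed50,
                dose=dose,
                method=method,
                n_reps_used=len(est),
                mean_estimate=mean,
                truth=truth,
                sd=sd,
                bias=bias,
                relative_bias_pct=relative_bias_pct(bias),
                rmse=rmse(sd, bias),
                mean_se=float(grp["se"].mean()),
            )
        )
    est_df = pd.DataFrame(rows)

    dr = conv[conv["method"].isin(["DR-EOS", "DR-MMRM"])]
    dr_last = dr[dr["week"] == last_week]
    dr_rows = []
    pkeys = ["arm_config", "timecourse", "ed50_true", "method"]
    for key, grp in dr_last.groupby(pkeys, sort=True):
        one = grp.drop_duplicates(subset=["rep"])
        q = one[["ed50_hat", "emax_hat"]].quantile([0.025, 0.5, 0.975])
        dr_rows.append(
            dict(
                zip(pkeys, key),
                n_reps_used=len(one),
                ed50_median=q.loc[0.5, "ed50_hat"],
                ed50_p2_5=q.loc[0.025, "ed50_hat"],
                ed50_p97_5=q.loc[0.975, "ed50_hat"],
                emax_median=q.loc[0.5, "emax_hat"],
                emax_p2_5=q.loc[0.025, "emax_hat"],
                emax_p97_5=q.loc[0.975, "emax_hat"],
                n_at_bound=int(one["ed50_at_bound"].sum()),
            )
        )
    dr_df = pd.DataFrame(dr_rows)

    fail_rows = []
    for key, grp in raw.groupby(["arm_config", "timecourse", "ed50_true", "method"]):
        one = grp.drop_duplicates(subset=["rep"])
        fail_rows.append(
            dict(
                zip(pkeys, key),
                n_reps=len(one),
                n_failed=int((~one["converged"].astype(bool)).sum()),
            )
        )
    fail_df = pd.DataFrame(fail_rows)

    n_reps = int(raw.groupby(["arm_config", "timecourse", "ed50_true"])["rep"].nunique().max())
    return StudySummary(
        estimates=est_df, dose_response=dr_df, failures=fail_df, n_reps=n_reps
    )


def band_exceedance_count(
    summary: StudySummary,
    method: str,
    design: Design,
    arm_config: str = "4dose",
    n_reps: int | None = None,
) -> tuple[int, int]:
    """Count grid cells whose |relative bias| exceeds the +/-2 SD band.

    The grid must be complete: 3 time-courses x 7 ED50 x n_doses cells
    (84 for the 4-dose configuration, 63 for 3-dose).  The band is
    recomputed for the replicate count actually used, since it is a
    standard-error-of-the-mean quantity scaling as 1/sqrt(reps).
    """
    df = summary.estimates
    sub = df[(df["method"] == method) & (df["arm_config"] == arm_config)]
    n_doses = len(ARM_CONFIGS[arm_config])
    expected = 3 * 7 * n_doses
    if len(sub) != expected:
        raise ValueError(
            f"incomplete grid for {method}/{arm_config}: "
            f"{len(sub)} cells, expected {expected}"
        )
    reps = n_reps if n_reps is not None else summary.n_reps
    band = unbiasedness_band_pct(reps, design.omega, design.sigma, design.n_per_arm)
    count = int((sub["relative_bias_pct"].abs() > band).sum())
    return count, expected
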