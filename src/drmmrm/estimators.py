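"""The three analysis methods compared in the simulation study.

* ``fit_mmrm`` — conventional MMRM: a saturated arm x visit cell-means
  model with AR(1) residual covariance.  One free mean parameter per
  cell, no dose-response assumption.
* ``fit_dreos`` — dose-response at end-of-study: a three-parameter Emax
  model (placebo, Emax, ED50) fitted by bounded nonlinear least squares
  to the last-visit data only.
* ``fit_drmmrm`` — dose-response MMRM: per-visit placebo and drug-effect
  parameters tied together by an Emax dose-response with a single ED50
  shared across visits, AR(1) residual covariance.

DR-MMRM is fitted once per active dose arm using the reference-dose
reparameterization

    y = Plc_t + E_dose,t * [d / (ED50 + d)] * [(ED50 + dose_m) / dose_m]

which collapses to ``y = Plc_t + E_dose,t`` when ``d = dose_m``, so the
placebo-adjusted effect of arm ``dose_m`` at each visit — and its
standard error — is read directly off the fit.  All parameterizations of
one trial share the same likelihood optimum, so ED50 (and the
back-calculated Emax) agree across them; estimates for each arm are kept
only from its own parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .gls import (
    GroupedPanel,
    SingularDesignError,
    ar1_inverse,
    fit_ar1_gls,
    _solve,
)

__all__ = [
    "ED50_BOUNDS",
    "ED50_STARTS",
    "DoseResponseParams",
    "MethodFit",
    "DrmmrmParamFit",
    "fit_mmrm",
    "fit_dreos",
    "fit_drmmrm_single",
    "fit_drmmrm",
    "fits_to_frame",
]

#: ED50 search bounds (mg), log-uniform; estimates this close (relative)
#: to a bound are flagged ``at_bound``.
ED50_BOUNDS = (0.01, 1.0e4)
AT_BOUND_RTOL = 1e-3
#: Multi-start initial values for the ED50 search (mg).
ED50_STARTS = (1.0, 10.0, 30.0, 100.0, 300.0)

_Z95 = 1.959963984540054
_Z_BOUND = float(np.arctanh(0.999))


@dataclass
class DoseResponseParams:
    """Dose-response parameters from an Emax-informed method."""

    ed50_hat: float
    emax_hat: np.ndarray  # per visit for DR-MMRM; length-1 for DR-EOS
    plc_hat: np.ndarray
    ed50_se: float = np.nan
    at_bound_ed50: bool = False
    at_bound_emax: bool = False


@dataclass
class MethodFit:
    """Per-method fit of one trial."""

    method: str
    estimates: pd.DataFrame
    dose_response: DoseResponseParams | None
    converged: bool
    param_converged: dict[float, bool] = field(default_factory=dict)
    details: dict = field(default_factory=dict)


@dataclass
class DrmmrmParamFit:
    """One DR-MMRM parameterization (reference dose ``dose_m``)."""

    dose_m: float
    plc: np.ndarray
    e_dose: np.ndarray
    se_e_dose: np.ndarray
    ed50_hat: float
    ed50_se: float
    rho_hat: float
    sigma_hat: float
    loglik: float
    converged: bool
    at_bound: bool


def _arm_arrays(trial: pd.DataFrame):
    """Pivot a long trial table to per-arm response matrices.

    Returns (doses sorted ascending with placebo first, weeks,
    list of (n_a, m) response matrices).
    """
    wide = trial.pivot_table(
        index=["dose", "subject"], columns="week", values="duacr"
    ).sort_index()
    weeks = np.asarray(wide.columns, dtype=float)
    doses = np.array(sorted(trial["dose"].unique()))
    Y_groups = [wide.loc[d].to_numpy() for d in doses]
    if any(np.isnan(Y).any() for Y in Y_groups):
        raise ValueError("trial panel is incomplete (missing visits)")
    return doses, weeks, Y_groups


def _ci(est: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return est - _Z95 * se, est + _Z95 * se


# ---------------------------------------------------------------------------
# Conventional MMRM
# ---------------------------------------------------------------------------

def fit_mmrm(trial: pd.DataFrame, criterion: str = "reml") -> MethodFit:
    """Saturated cell-means MMRM with AR(1) residual covariance.

    On balanced complete data the cell-mean estimates equal the raw
    per-arm per-visit sample means whatever the working correlation; the
    AR(1) fit supplies the standard errors.  The placebo-adjusted effect
    at (dose, visit) is the cell-mean difference versus placebo.
    """
    doses, weeks, Y_groups = _arm_arrays(trial)
    G, m = len(doses), len(weeks)
    X = np.zeros((G, m, G * m))
    for a in range(G):
        X[a, :, a * m : (a + 1) * m] = np.eye(m)
    panel = GroupedPanel.from_group_data(X, Y_groups)
    fit = fit_ar1_gls(panel, criterion=criterion)

    rows = []
    cov = fit.beta_cov
    for a, d in enumerate(doses):
        if d == 0:
            continue
        for t in range(m):
            ia, i0 = a * m + t, t
            est = fit.beta[ia] - fit.beta[i0]
            var = cov[ia, ia] + cov[i0, i0] - 2 * cov[ia, i0]
            rows.append((d, weeks[t], est, np.sqrt(max(var, 0.0))))
    df = pd.DataFrame(rows, columns=["dose", "week", "estimate", "se"])
    df["ci_low"], df["ci_high"] = _ci(df["estimate"], df["se"])
    return MethodFit(
        method="MMRM",
        estimates=df,
        dose_response=None,
        converged=fit.converged,
        details={"gls": fit},
    )


# ---------------------------------------------------------------------------
# Dose-response at end-of-study (Emax NLS on last-visit data)
# ---------------------------------------------------------------------------

def _emax_frac(dose: np.ndarray, ed50: float) -> np.ndarray:
    return dose / (ed50 + dose)


def fit_dreos(trial: pd.DataFrame) -> MethodFit:
    """Emax dose-response fitted to last-visit data by bounded NLS.

    Model: ``y_i = Plc + Emax * d_i / (ED50 + d_i) + e_i`` on the
    end-of-study visit only.  ED50 is searched on the log scale within
    :data:`ED50_BOUNDS` from multiple starting values; the best
    residual sum of squares is kept.  Standard errors of the
    placebo-adjusted effects come from the delta method on the NLS
    parameter covariance.
    """
    last_week = trial["week"].max()
    sub = trial[trial["week"] == last_week]
    y = sub["duacr"].to_numpy(dtype=float)
    d = sub["dose"].to_numpy(dtype=float)
    doses = np.array(sorted(np.unique(d)))
    if (doses > 0).sum() < 2:
        raise ValueError("DR-EOS needs at least two active dose arms")

    plc0 = float(y[d == 0].mean())
    top = doses[-1]
    top_eff = float(y[d == top].mean()) - plc0
    lb, ub = np.log(ED50_BOUNDS[0]), np.log(ED50_BOUNDS[1])

    def resid(theta):
        plc, emax, led50 = theta
        return plc + emax * _emax_frac(d, np.exp(led50)) - y

    best = None
    any_success = False
    for e0 in ED50_STARTS:
        emax0 = top_eff * (e0 + top) / top
        try:
            res = optimize.least_squares(
                resid,
                x0=[plc0, emax0, np.log(e0)],
                bounds=([-np.inf, -np.inf, lb], [np.inf, np.inf, ub]),
                method="trf",
            )
        except Exception:
            continue
        any_success = any_success or res.success
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        df = pd.DataFrame(columns=["dose", "week", "estimate", "se", "ci_low", "ci_high"])
        return MethodFit("DR-EOS", df, None, converged=False)

    plc, emax, led50 = best.x
    ed50 = float(np.exp(led50))
    dof = max(len(y) - 3, 1)
    sigma2 = 2.0 * best.cost / dof
    JtJ = best.jac.T @ best.jac
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(JtJ)

    rows = []
    for dd in doses[doses > 0]:
        frac = _emax_frac(dd, ed50)
        est = emax * frac
        g = np.array([0.0, frac, -emax * dd * ed50 / (ed50 + dd) ** 2])
        se = float(np.sqrt(max(g @ cov @ g, 0.0)))
        rows.append((dd, last_week, est, se))
    df = pd.DataFrame(rows, columns=["dose", "week", "estimate", "se"])
    df["ci_low"], df["ci_high"] = _ci(df["estimate"], df["se"])
    at_bound = bool(
        min(abs(ed50 - b) / b for b in ED50_BOUNDS) < AT_BOUND_RTOL
    )
    params = DoseResponseParams(
        ed50_hat=ed50,
        emax_hat=np.array([emax]),
        plc_hat=np.array([plc]),
        ed50_se=float(np.sqrt(max(cov[2, 2], 0.0))) * ed50,
        at_bound_ed50=at_bound,
    )
    return MethodFit(
        "DR-EOS", df, params, converged=any_success,
        details={"rss": 2.0 * best.cost, "sigma_hat": float(np.sqrt(sigma2))},
    )


# ---------------------------------------------------------------------------
# DR-MMRM
# ---------------------------------------------------------------------------

def _lag1_autocorr(Y_groups) -> float:
    """Pooled lag-1 autocorrelation of within-arm-mean residuals.

    Cheap moment estimate of the marginal serial correlation, used only
    to warm-start the working-correlation search.
    """
    num = den = 0.0
    for Y in Y_groups:
        R = Y - Y.mean(axis=0, keepdims=True)
        num += float((R[:, 1:] * R[:, :-1]).sum())
        den += float((R * R).sum())
    return num / den if den > 0 else 0.0


def _drmmrm_design(doses: np.ndarray, m: int, ed50: float, dose_m: float) -> np.ndarray:
    """(G, m, 2m) design blocks [I | c_a I] for the reference-dose model."""
    c = _emax_frac(doses, ed50) * (ed50 + dose_m) / dose_m
    G = len(doses)
    eye = np.eye(m)
    X = np.zeros((G, m, 2 * m))
    X[:, :, :m] = eye
    X[:, :, m:] = c[:, None, None] * eye
    return X


def fit_drmmrm_single(
    trial: pd.DataFrame, dose_m: float, criterion: str = "ml"
) -> DrmmrmParamFit:
    """Fit the DR-MMRM reference-dose parameterization for one arm.

    Outer bounded optimization over (log ED50, arctanh rho); at each
    point the per-visit placebo and drug-effect parameters are solved in
    closed form by GLS and the scale is profiled out.  Standard errors
    of the per-visit effects come from the joint curvature including the
    ED50 direction (Gauss-Newton information), so ED50 uncertainty is
    propagated; the ED50 SE itself is a numeric profiled-curvature
    convenience output.

    The criterion is plain maximum likelihood: a restricted likelihood
    is not parameterization-invariant for a nonlinear mean (its
    ``log |X' V^-1 X|`` term changes under the ED50-dependent column
    rescaling of the reference-dose form), which would let the
    reference-dose parameterizations of one trial disagree.  Profiled ML
    depends only on the column span, so all parameterizations share one
    optimum exactly — and ML is what nonlinear GLS software fits anyway.
    """
    doses, weeks, Y_groups = _arm_arrays(trial)
    if dose_m not in doses or dose_m <= 0:
        raise ValueError("dose_m must be one of the trial's active doses")
    m = len(weeks)
    base = GroupedPanel.from_group_data(
        np.zeros((len(doses), m, 2 * m)), Y_groups
    )
    lb, ub = np.log(ED50_BOUNDS[0]), np.log(ED50_BOUNDS[1])
    z0 = np.arctanh(np.clip(_lag1_autocorr(Y_groups), -0.9, 0.9))

    def nll(u):
        led50, z = u
        base.X = _drmmrm_design(doses, m, float(np.exp(led50)), dose_m)
        try:
            _, _, ll, _ = _solve(base, float(np.tanh(z)), criterion)
        except SingularDesignError:
            return 1e10
        return -ll

    best = None
    for e0 in ED50_STARTS:
        res = optimize.minimize(
            nll,
            x0=[np.log(e0), z0],
            method="L-BFGS-B",
            bounds=[(lb, ub), (-_Z_BOUND, _Z_BOUND)],
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    converged = bool(best.success) and best.fun < 1e9
    led50, z = best.x
    ed50 = float(np.exp(led50))
    rho = float(np.tanh(z))
    base.X = _drmmrm_design(doses, m, ed50, dose_m)
    beta, sigma2, ll, A = _solve(base, rho, criterion)
    plc, e_dose = beta[:m].copy(), beta[m:].copy()

    # Joint Gauss-Newton covariance over (Plc, E_dose, log ED50):
    # d c_a / d log ED50 = ed50 * d_a (d_a - dose_m) / (dose_m (ed50+d_a)^2)
    dc = ed50 * doses * (doses - dose_m) / (dose_m * (ed50 + doses) ** 2)
    G = len(doses)
    J = np.zeros((G, m, 2 * m + 1))
    J[:, :, : 2 * m] = base.X
    J[:, :, -1] = dc[:, None] * e_dose[None, :]
    Rinv = ar1_inverse(rho, m)
    JtR = np.einsum("gmi,mn->gin", J, Rinv)
    info = np.einsum("g,gin,gnj->ij", base.counts, JtR, J)
    try:
        cov_full = sigma2 * np.linalg.inv(info)
        se_e = np.sqrt(np.clip(np.diag(cov_full)[m : 2 * m], 0.0, None))
    except np.linalg.LinAlgError:
        cov_cond = sigma2 * np.linalg.inv(A)
        se_e = np.sqrt(np.clip(np.diag(cov_cond)[m:], 0.0, None))

    # profiled curvature in (log ED50, z) for an ED50 SE
    ed50_se = np.nan
    try:
        h = 1e-4
        u0 = np.array([led50, z])
        H = np.zeros((2, 2))
        f0 = nll(u0)
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h
                ej = np.eye(2)[j] * h
                H[i, j] = H[j, i] = (
                    nll(u0 + ei + ej) - nll(u0 + ei - ej)
                    - nll(u0 - ei + ej) + nll(u0 - ei - ej)
                ) / (4 * h * h)
        covu = np.linalg.inv(H)
        if covu[0, 0] > 0:
            ed50_se = float(ed50 * np.sqrt(covu[0, 0]))
    except np.linalg.LinAlgError:
        pass

    at_bound = bool(min(abs(ed50 - b) / b for b in ED50_BOUNDS) < AT_BOUND_RTOL)
    return DrmmrmParamFit(
        dose_m=dose_m,
        plc=plc,
        e_dose=e_dose,
        se_e_dose=se_e,
        ed50_hat=ed50,
        ed50_se=ed50_se,
        rho_hat=rho,
        sigma_hat=float(np.sqrt(sigma2)),
        loglik=ll,
        converged=converged,
        at_bound=at_bound,
    )


def fit_drmmrm(trial: pd.DataFrame, criterion: str = "ml") -> MethodFit:
    """Full DR-MMRM fit: one parameterization per active dose arm.

    Each arm's placebo-adjusted per-visit effect and SE are taken from
    the parameterization where that arm is the reference dose.  ED50
    (and back-calculated per-visit Emax) are read from the
    best-likelihood converged parameterization — all parameterizations
    share the optimum, so this is a tie-break, not a choice.  The fit is
    a complete failure only if every parameterization fails.
    """
    doses = np.array(sorted(trial["dose"].unique()))
    active = doses[doses > 0]
    if len(active) < 3:
        raise ValueError("DR-MMRM needs at least three active dose arms")
    weeks = np.sort(trial["week"].unique())

    fits: dict[float, DrmmrmParamFit] = {}
    for d in active:
        fits[d] = fit_drmmrm_single(trial, float(d), criterion=criterion)
    converged_fits = [f for f in fits.values() if f.converged]
    param_flags = {d: f.converged for d, f in fits.items()}
    if not converged_fits:
        df = pd.DataFrame(columns=["dose", "week", "estimate", "se", "ci_low", "ci_high"])
        return MethodFit("DR-MMRM", df, None, converged=False,
                         param_converged=param_flags)

    rows = []
    for d in active:
        f = fits[d]
        if not f.converged:
            continue
        for t, w in enumerate(weeks):
            rows.append((d, w, f.e_dose[t], f.se_e_dose[t]))
    df = pd.DataFrame(rows, columns=["dose", "week", "estimate", "se"])
    df["ci_low"], df["ci_high"] = _ci(df["estimate"], df["se"])

    ref = max(converged_fits, key=lambda f: f.loglik)
    emax = ref.e_dose * (ref.ed50_hat + ref.dose_m) / ref.dose_m
    params = DoseResponseParams(
        ed50_hat=ref.ed50_hat,
        emax_hat=emax,
        plc_hat=ref.plc,
        ed50_se=ref.ed50_se,
        at_bound_ed50=ref.at_bound,
    )
    return MethodFit(
        "DR-MMRM", df, params, converged=True,
        param_converged=param_flags,
        details={"parameterizations": fits, "rho_hat": ref.rho_hat,
                 "sigma_hat": ref.sigma_hat},
    )


def fits_to_frame(fits: list[MethodFit], scenario: str = "", rep: int = 0) -> pd.DataFrame:
    """Tidy CSV-ready table of per-fit estimates across methods."""
    frames = []
    for f in fits:
        df = f.estimates.copy()
        df.insert(0, "method", f.method)
        df["ed50_hat"] = f.dose_response.ed50_hat if f.dose_response else np.nan
        df["emax_hat"] = (
            float(f.dose_response.emax_hat[-1]) if f.dose_response else np.nan
        )
        df["converged"] = f.converged
        df["scenario"] = scenario
        df["rep"] = rep
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
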