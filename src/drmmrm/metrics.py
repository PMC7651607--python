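"""Operating-characteristic metrics for the simulation study.

Bias is measured on the log scale at the last visit against the true
placebo-adjusted effect; relative bias expresses it as a percentage of
the maximal effect (a 40% UACR reduction, |log 0.6|).  RMSE combines
Monte-Carlo spread and bias as sqrt(sd^2 + bias^2).  The theoretical
RMSE of an unbiased end-of-study arm contrast is
sqrt(omega^2 + sigma^2) / sqrt(n) * sqrt(2) (~0.14 log(mg/g) for the
reference design), and the "gray band" of expected relative-bias
variation for an unbiased method is +/-2 SD of its Monte-Carlo mean
(~1.7% at 1000 replicates).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .design import Design
from .truth import MAX_EFFECT_LOG

__all__ = [
    "rmse",
    "theoretical_rmse",
    "relative_bias_pct",
    "unbiasedness_band_pct",
    "empirical_power",
]


def rmse(sd: float, bias: float) -> float:
    """Root mean squared error: sqrt(sd^2 + bias^2)."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return float(np.hypot(sd, bias))


def theoretical_rmse(omega: float, sigma: float, n: int) -> float:
    """Expected RMSE of an unbiased two-arm end-of-study contrast.

    sqrt(omega^2 + sigma^2) / sqrt(n) * sqrt(2); ~0.141 log(mg/g) at the
    reference design (omega=0.3716, sigma=0.50, n=39).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.sqrt(omega**2 + sigma**2) / np.sqrt(n) * np.sqrt(2.0))


def relative_bias_pct(bias_log: float) -> float:
    """Bias as a signed percentage of the maximal effect |log 0.6|."""
    return float(100.0 * bias_log / abs(MAX_EFFECT_LOG))


def unbiasedness_band_pct(
    n_reps: int, omega: float = 0.3716, sigma: float = 0.50, n: int = 39
) -> float:
    """Half-width (%) of the +/-2 SD band for an unbiased method's
    Monte-Carlo mean relative bias.

    100 * 2 * theoretical_rmse / sqrt(n_reps) / |log 0.6|; ~1.7% at
    1000 replicates of the reference design, scaling as 1/sqrt(reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    return float(
        100.0
        * 2.0
        * theoretical_rmse(omega, sigma, n)
        / np.sqrt(n_reps)
        / abs(MAX_EFFECT_LOG)
    )


def empirical_power(
    design: Design,
    effect: float,
    n_reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo power of the end-of-study two-sample t-test.

    Simulates per-subject last-visit change-from-baseline values for the
    top dose arm (mean ``effect``) and placebo (mean 0), each with SD
    sqrt(omega^2 + sigma^2) and n_per_arm subjects, and reports the
    fraction of two-sided pooled t-tests rejecting at ``alpha``.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    n = design.n_per_arm
    sd = float(np.sqrt(design.omega**2 + design.sigma**2))
    rng = np.random.default_rng(seed)
    x = rng.normal(effect, sd, size=(n_reps, n))
    y = rng.normal(0.0, sd, size=(n_reps, n))
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    sp = np.sqrt(((n - 1) * vx + (n - 1) * vy) / (2 * n - 2))
    tstat = (x.mean(axis=1) - y.mean(axis=1)) / (sp * np.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1 - alpha / 2, 2 * n - 2)
    return float(np.mean(np.abs(tstat) > tcrit))
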