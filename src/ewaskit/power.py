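"""Study power: closed-form RNA-seq power and a methylation simulation.

RNA-seq power uses the standard normal approximation on the log scale
for a two-group comparison where per-gene counts at sequencing depth
``depth`` carry technical (1/depth) plus biological (cv**2) variance:

    sd    = sqrt((1/depth + cv**2) * (1/n1 + 1/n2))
    power = Phi(|ln effect| / sd - z_{1 - alpha/2})

The methylation side has no closed form here; ``methylation_power_sim``
estimates two-group power by simulating beta values with a mean shift
and running the EWAS regression (status only, no covariates) on each
replicate.  It is a simulation stand-in, not equivalent to
reference-tissue bootstrap power tools.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["rnaseq_power", "methylation_power_sim"]


def rnaseq_power(
    effect,
    depth: float = 25.0,
    n1: int = 16,
    n2: int = 16,
    cv: float = 0.4,
    alpha: float = 1e-4,
):
    """Two-group RNA-seq detection power for a fold change ``effect``.

    ``effect`` may be a scalar or array of fold changes (> 0); the result
    is symmetric in effect <-> 1/effect.  ``alpha`` is the two-sided
    type-I error.  An effect of exactly 1 returns ~alpha/2 (the one-sided
    rejection probability under the null), not an error.
    """
    effect = np.asarray(effect, dtype=float)
    if np.any(effect <= 0):
        raise ValueError("effect (fold change) must be > 0")
    if depth <= 0 or cv < 0 or not 0 < alpha < 1 or n1 < 2 or n2 < 2:
        raise ValueError("invalid power specification")
    sd = np.sqrt((1.0 / depth + cv**2) * (1.0 / n1 + 1.0 / n2))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    power = stats.norm.cdf(np.abs(np.log(effect)) / sd - z)
    return float(power) if power.ndim == 0 else power


def methylation_power_sim(
    n_per_group: int,
    delta_beta: float,
    noise_sd: float,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
    base_beta: float = 0.5,
) -> tuple[float, float]:
    """Monte-Carlo power of the two-group EWAS regression at one CpG.

    Simulates ``n_reps`` replicates of two groups of beta values with a
    case mean shift of ``delta_beta``, tests the status coefficient of
    the no-covariate regression, and returns (power, binomial SE).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a usable estimate")
    rng = np.random.default_rng(seed)
    mean_ctrl, mean_case = base_beta, base_beta + delta_beta
    if not 0.0 < mean_case < 1.0:
        warnings.warn("delta_beta pushes the case mean outside (0, 1); clamping")
        mean_case = np.clip(mean_case, 1e-4, 1 - 1e-4)
    n = n_per_group
    ctrl = np.clip(rng.normal(mean_ctrl, noise_sd, size=(n_reps, n)), 0.0, 1.0)
    case = np.clip(rng.normal(mean_case, noise_sd, size=(n_reps, n)), 0.0, 1.0)
    # status-only OLS == pooled-variance two-sample t-test
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    sp2 = (case.var(axis=1, ddof=1) + ctrl.var(axis=1, ddof=1)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * 2.0 / n)
    p = 2.0 * stats.t.sf(np.abs(t), 2 * n - 2)
    power = float(np.mean(p < alpha))
    se = float(np.sqrt(power * (1.0 - power) / n_reps))
    return power, se
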