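"""Methylation QC filtering, batch adjustment and probe-type normalization.

The stage mirrors standard EPIC-array preprocessing:

1. drop poor-quality samples (successful-probe fraction below a threshold,
   where a probe call is successful when its detection p < 0.01);
2. drop probes failing detection, known non-CpG / multi-mapping /
   smoking-associated probes (supplied as id blocklists), and probes with
   a bead count < 3 in at least 5% of samples;
3. location-scale empirical-Bayes batch adjustment (ComBat-style) applied
   to beta values directly;
4. Infinium II rescaling onto the Infinium I distribution via a
   second-order polynomial fitted to type I/II probe pairs within 50 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "QcReport",
    "filter_samples",
    "filter_probes",
    "combat_adjust",
    "BatchAdjuster",
    "ProbeTypeFit",
    "ProbeTypeNormalizer",
    "fit_probe_type_polynomial",
    "apply_probe_type_normalization",
]

#: A probe call is successful when its detection p-value is below this.
DETECTION_P_MAX = 0.01


@dataclass
class QcReport:
    """Bookkeeping for QC removals; counts reconcile with matrix shapes."""

    samples_removed: list = field(default_factory=list)  # (sample_id, reason)
    probes_removed: dict = field(default_factory=dict)   # rule -> count
    probes_retained: int = 0

    def total_removed(self) -> int:
        return sum(self.probes_removed.values())


def filter_samples(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    min_success_ratio: float = 0.9,
) -> tuple[pd.DataFrame, QcReport]:
    """Drop samples whose successful-probe fraction is below the threshold.

    The default threshold (0.9) is the conventional ">=90% of calls
    succeed" rule; the permissive published wording ("successful probe
    ratio > 0.1") is available by passing 0.1.
    """
    if beta.shape != detection_p.shape or list(beta.columns) != list(detection_p.columns):
        raise ValueError("detection_p is not congruent with beta")
    success = (detection_p.to_numpy() < DETECTION_P_MAX).mean(axis=0)
    keep = success >= min_success_ratio
    report = QcReport(
        samples_removed=[
            (s, f"successful-probe fraction {f:.3f} < {min_success_ratio}")
            for s, f, k in zip(beta.columns, success, keep) if not k
        ],
        probes_retained=beta.shape[0],
    )
    if not keep.any():
        raise ValueError("all samples failed QC")
    return beta.loc[:, keep], report


def filter_probes(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    bead_counts: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    blocklists: dict[str, set] | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Remove failing probes; attribute each removal to its first rule.

    Rules, in order: detection p > 0.01 in any retained sample; non-CpG
    ids; multi-mapping ids; bead count < 3 in >= 5% of samples; known
    smoking-associated ids.  Blocklists are id sets keyed by
    ``non_cpg`` / ``multi_mapping`` / ``smoking``.
    """
    for name, mat in (("detection_p", detection_p), ("bead_counts", bead_counts)):
        if mat.shape != beta.shape or list(mat.index) != list(beta.index):
            raise ValueError(f"{name} is not congruent with beta")
    blocklists = blocklists or {}
    ids = beta.index.to_numpy()
    known = set(ids)
    for rule, blocked in blocklists.items():
        stray = set(blocked) - known
        if stray:
            warnings.warn(f"{len(stray)} ids in '{rule}' blocklist not present in the matrix")

    removed = np.zeros(len(ids), dtype=bool)
    report = QcReport()

    def apply_rule(rule: str, mask: np.ndarray) -> None:
        new = mask & ~removed
        report.probes_removed[rule] = int(new.sum())
        removed[new] = True

    apply_rule("detection_p", (detection_p.to_numpy() > DETECTION_P_MAX).any(axis=1))
    apply_rule("non_cpg", np.isin(ids, list(blocklists.get("non_cpg", ()))))
    apply_rule("multi_mapping", np.isin(ids, list(blocklists.get("multi_mapping", ()))))
    apply_rule("bead_count", (bead_counts.to_numpy() < 3).mean(axis=1) >= 0.05)
    apply_rule("smoking", np.isin(ids, list(blocklists.get("smoking", ()))))

    report.probes_retained = int((~removed).sum())
    return beta.loc[~removed], report


# ---------------------------------------------------------------------------
# ComBat-style batch adjustment
# ---------------------------------------------------------------------------

class BatchAdjuster(BaseEstimator, TransformerMixin):
    """Location-scale parametric empirical-Bayes batch adjustment.

    Per probe: standardize against the grand mean and pooled variance,
    estimate per-batch location (gamma) and scale (delta^2) on the
    standardized data, shrink both toward batch-level parametric priors
    (normal prior for gamma, inverse-gamma for delta^2, solved by the
    usual fixed-point iteration), then back-transform.  Applied to beta
    values directly and clamped back into [0, 1] unless ``clip=False``.

    With a single batch there is nothing to adjust and the input is
    returned unchanged.  Batches with fewer than two samples raise,
    since their scale is not estimable.
    """

    def __init__(self, clip: bool = True, max_iter: int = 100, conv: float = 1e-4):
        self.clip = clip
        self.max_iter = max_iter
        self.conv = conv

    def fit_transform(self, X: pd.DataFrame, y=None, *, batch=None) -> pd.DataFrame:
        if batch is None:
            raise ValueError("batch labels are required")
        batch = np.asarray(batch)
        if len(batch) != X.shape[1]:
            raise ValueError("one batch label per sample is required")
        levels, inverse = np.unique(batch, return_inverse=True)
        sizes = np.bincount(inverse)
        if (sizes < 2).any():
            small = levels[sizes < 2]
            raise ValueError(f"batches with < 2 samples (scale not estimable): {list(small)}")
        if len(levels) == 1:
            self.batch_levels_ = levels
            return X.copy()

        data = X.to_numpy(dtype=float)
        n_probes, n = data.shape
        batch_means = np.stack([data[:, inverse == i].mean(axis=1) for i in range(len(levels))], axis=1)
        grand = batch_means @ (sizes / n)
        resid = data - batch_means[:, inverse]
        var_pooled = (resid**2).mean(axis=1)
        var_pooled = np.maximum(var_pooled, 1e-12)
        sd = np.sqrt(var_pooled)
        z = (data - grand[:, None]) / sd[:, None]

        adjusted = np.empty_like(z)
        self.gamma_star_, self.delta_star_ = {}, {}
        for i, level in enumerate(levels):
            zi = z[:, inverse == i]
            n_i = sizes[i]
            gamma_hat = zi.mean(axis=1)
            delta_hat = zi.var(axis=1, ddof=1)
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
            s2 = max(s2, 1e-12)
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
            for _ in range(self.max_iter):
                g_new = (n_i * tau2 * gamma_hat + delta_star * gamma_bar) / (n_i * tau2 + delta_star)
                ss = ((zi - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * ss + b_prior) / (n_i / 2.0 + a_prior - 1.0)
                change = max(
                    np.max(np.abs(g_new - gamma_star) / (np.abs(gamma_star) + 1e-30)),
                    np.max(np.abs(d_new - delta_star) / (np.abs(delta_star) + 1e-30)),
                )
                gamma_star, delta_star = g_new, d_new
                if change < self.conv:
                    break
            adjusted[:, inverse == i] = (zi - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
            self.gamma_star_[level] = gamma_star
            self.delta_star_[level] = delta_star

        out = adjusted * sd[:, None] + grand[:, None]
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        self.batch_levels_ = levels
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    # ComBat is transductive: fitting and transforming are one step.
    def fit(self, X, y=None, *, batch=None):
        self.adjusted_ = self.fit_transform(X, batch=batch)
        return self

    def transform(self, X):
        return self.adjusted_


def combat_adjust(beta: pd.DataFrame, batches, clip: bool = True) -> pd.DataFrame:
    """Empirical-Bayes batch adjustment of a beta matrix (see BatchAdjuster)."""
    return BatchAdjuster(clip=clip).fit_transform(beta, batch=batches)


# ---------------------------------------------------------------------------
# Infinium I/II probe-type normalization
# ---------------------------------------------------------------------------

@dataclass
class ProbeTypeFit:
    """Second-order polynomial mapping Type II betas onto the Type I scale."""

    c0: float
    c1: float
    c2: float
    n_pairs: int
    max_pair_distance: int = 50

    def __call__(self, b: np.ndarray) -> np.ndarray:
        return np.clip(self.c0 + self.c1 * b + self.c2 * b**2, 0.0, 1.0)


def _pair_probes(annotation: pd.DataFrame, max_distance: int) -> list[tuple[str, str]]:
    """Greedy nearest-first pairing of Type II probes to Type I probes.

    Each Type I probe is used at most once; candidate pairs are processed
    by increasing distance, ties broken by lower Type I then Type II
    coordinate so pairing is deterministic.
    """
    candidates = []
    for chrom, grp in annotation.groupby("chrom"):
        one = grp[grp["design_type"] == "I"]
        two = grp[grp["design_type"] == "II"]
        if len(one) == 0 or len(two) == 0:
            continue
        pos1 = one["pos"].to_numpy()
        order = np.argsort(pos1, kind="stable")
        pos1 = pos1[order]
        ids1 = one["probe_id"].to_numpy()[order]
        for pid2, p2 in zip(two["probe_id"], two["pos"]):
            lo = np.searchsorted(pos1, p2 - max_distance, side="left")
            hi = np.searchsorted(pos1, p2 + max_distance, side="right")
            for k in range(lo, hi):
                candidates.append((abs(int(pos1[k]) - int(p2)), int(pos1[k]), int(p2), ids1[k], pid2))
    candidates.sort()
    used1: set[str] = set()
    used2: set[str] = set()
    pairs = []
    for _, _, _, id1, id2 in candidates:
        if id1 in used1 or id2 in used2:
            continue
        used1.add(id1)
        used2.add(id2)
        pairs.append((id1, id2))
    return pairs


class ProbeTypeNormalizer(BaseEstimator, TransformerMixin):
    """Rescale Infinium II betas onto the Infinium I distribution.

    ``fit`` pairs each Type II probe with the nearest unused Type I probe
    on the same chromosome within ``max_pair_distance`` bp and
    least-squares fits mean Type I beta (response) on mean Type II beta
    and its square.  ``transform`` applies the fitted polynomial to every
    Type II value, clamped into [0, 1]; Type I values are untouched.
    """

    def __init__(self, max_pair_distance: int = 50):
        self.max_pair_distance = max_pair_distance

    def fit(self, beta: pd.DataFrame, annotation: pd.DataFrame):
        ann = annotation[annotation["probe_id"].isin(beta.index)]
        pairs = _pair_probes(ann, self.max_pair_distance)
        if len(pairs) < 3:
            raise ValueError(
                f"only {len(pairs)} Type I/II pairs within {self.max_pair_distance} bp; "
                "need >= 3 (enlarge the simulation or skip probe-type normalization)"
            )
        means = beta.mean(axis=1)
        y = np.array([means[a] for a, _ in pairs])   # Type I (response)
        x = np.array([means[b] for _, b in pairs])   # Type II (predictor)
        X = np.column_stack([np.ones_like(x), x, x**2])
        c, *_ = np.linalg.lstsq(X, y, rcond=None)
        self.fit_ = ProbeTypeFit(float(c[0]), float(c[1]), float(c[2]),
                                 n_pairs=len(pairs), max_pair_distance=self.max_pair_distance)
        self.pairs_ = pairs
        return self

    def transform(self, beta: pd.DataFrame, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
        if annotation is None:
            raise ValueError("annotation is required to identify Type II probes")
        return apply_probe_type_normalization(beta, annotation, self.fit_)


def fit_probe_type_polynomial(beta: pd.DataFrame, annotation: pd.DataFrame,
                              max_pair_distance: int = 50) -> ProbeTypeFit:
    """Fit the Type II -> Type I second-order polynomial (see ProbeTypeNormalizer)."""
    return ProbeTypeNormalizer(max_pair_distance).fit(beta, annotation).fit_


def apply_probe_type_normalization(beta: pd.DataFrame, annotation: pd.DataFrame,
                                   fit: ProbeTypeFit) -> pd.DataFrame:
    """Apply a fitted probe-type polynomial to every Type II beta value."""
    type2_ids = set(annotation.loc[annotation["design_type"] == "II", "probe_id"])
    out = beta.copy()
    mask = beta.index.isin(type2_ids)
    out.loc[mask] = fit(beta.loc[mask].to_numpy())
    return out
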