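"""Per-CpG case-control association (EWAS) with an empirical P-P threshold.

Each CpG's beta value is modeled by ordinary least squares:

    beta ~ b0 + b1*status + b2*age + b3*PC1 + b4*PC2

with status coded case=1/control=0 and the PCs computed from the analysis
beta matrix itself to absorb unmeasured structure (e.g. admixture).  The
two-sided t-test on b1 (residual df = n - 5) gives the per-probe p;
Benjamini-Hochberg adjustment gives q.  Beyond the q < 0.4 reporting
rule, an empirical significance threshold is read from the P-P plot of
-log10 p order statistics: a line is fitted where the data must be
null-consistent (theoretical -log10 p in (0, 3)) and the departure point
beyond 3 is located.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "compute_pcs",
    "fit_cpg_regressions",
    "bh_fdr",
    "empirical_threshold",
    "rank_dmcs",
    "PpThreshold",
    "CpGAssociation",
]


def compute_pcs(beta: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Top-k sample scores from the SVD of the probe-centered beta matrix.

    Rows (probes) are centered; sample scores are the right singular
    vectors scaled by their singular values.  Sign convention: the
    largest-|loading| probe of each component has a positive loading.
    """
    n = beta.shape[1]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    X = beta.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(U[np.argmax(np.abs(U[:, :k]), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    scores = (s[:k] * Vt[:k].T) * flip
    return pd.DataFrame(scores, index=beta.columns, columns=[f"PC{i+1}" for i in range(k)])


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-preserving)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


def fit_cpg_regressions(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of every probe's beta on {status, age, PCs} with intercept.

    Returns one row per probe: raw group means, their difference
    (case - control), the adjusted status coefficient, p and BH q.
    A singular design yields NA rows with a counted warning rather than
    an exception.
    """
    samples = list(sheet["sample_id"])
    if list(beta.columns) != samples:
        beta = beta[samples]
    status = (sheet["group"] == "case").to_numpy(dtype=float)
    if status.sum() == 0 or status.sum() == len(status):
        raise ValueError("both groups must be present")
    cols = [np.ones(len(status)), status, sheet["age"].to_numpy(dtype=float)]
    if pcs is not None:
        cols.extend(pcs.to_numpy(dtype=float).T)
    X = np.column_stack(cols)
    n, q_dim = X.shape
    if n < 6:
        raise ValueError("at least 6 samples are required")
    Y = beta.to_numpy(dtype=float)

    case_mean = Y[:, status == 1].mean(axis=1)
    ctrl_mean = Y[:, status == 0].mean(axis=1)

    n_failed = 0
    if np.linalg.matrix_rank(X) < q_dim:
        warnings.warn("singular design matrix; regression coefficients set to NA")
        coef = np.full(Y.shape[0], np.nan)
        p = np.full(Y.shape[0], np.nan)
        n_failed = Y.shape[0]
    else:
        xtx_inv = np.linalg.inv(X.T @ X)
        B = Y @ X @ xtx_inv                     # probes x q_dim
        resid = Y - B @ X.T
        df = n - q_dim
        sigma2 = (resid**2).sum(axis=1) / df
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, B[:, 1] / se, np.nan)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        coef = B[:, 1]
        n_failed = int(np.isnan(p).sum())

    out = pd.DataFrame({
        "probe_id": beta.index,
        "control_mean_beta": ctrl_mean,
        "case_mean_beta": case_mean,
        "difference": case_mean - ctrl_mean,
        "coefficient": coef,
        "p": p,
        "q": bh_fdr(p),
    })
    if annotation is not None:
        ann = annotation.set_index("probe_id")
        keep = [c for c in ("nearest_gene", "chrom", "pos", "island_relation", "location_class") if c in ann.columns]
        out = out.join(ann[keep], on="probe_id")
    out.attrs["n_failed"] = n_failed
    return out


@dataclass
class PpThreshold:
    """Empirical significance threshold read from a P-P plot.

    ``slope``/``intercept`` describe the line fitted to order statistics
    with theoretical -log10 p in (0, 3).  ``departure`` is the smallest
    theoretical -log10 p >= 3 at which the empirical values exceed the
    extrapolated line by more than ``delta`` for ``window`` consecutive
    order statistics (None when the data never depart);
    ``empirical_at_departure`` is the observed -log10 p there, i.e. the
    cutoff one would quote as "-log10 p greater than this is signal".
    """

    slope: float
    intercept: float
    departure: float | None
    empirical_at_departure: float | None
    delta: float
    window: int


def empirical_threshold(p, delta: float = 0.5, window: int = 5) -> PpThreshold:
    """Locate where observed -log10 p order statistics leave the null line."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    m = p.size
    if m < 100:
        raise ValueError("need at least 100 p-values for a stable P-P threshold")
    p = np.sort(p)
    ranks = np.arange(1, m + 1)
    theo = -np.log10(ranks / (m + 1))            # decreasing; index 0 most extreme
    emp = -np.log10(np.maximum(p, 1e-300))
    fit_mask = (theo > 0) & (theo < 3)
    slope, intercept = np.polyfit(theo[fit_mask], emp[fit_mask], 1)
    gap = emp - (intercept + slope * theo)

    departure = empirical = None
    candidates = np.where(theo >= 3)[0]
    for idx in candidates[::-1]:                 # smallest theoretical first
        lo = idx - window + 1
        if lo < 0:                               # sustained run not assessable
            continue
        if np.all(gap[lo:idx + 1] > delta):
            departure = float(theo[idx])
            empirical = float(emp[idx])
            break
    return PpThreshold(float(slope), float(intercept), departure, empirical,
                       delta=delta, window=window)


def rank_dmcs(results: pd.DataFrame, q_max: float = 0.4) -> pd.DataFrame:
    """Filter to q < q_max and rank by |difference| (ties by ascending p)."""
    keep = results[results["q"] < q_max].copy()
    keep["_absdiff"] = keep["difference"].abs()
    keep = keep.sort_values(["_absdiff", "p"], ascending=[False, True], kind="stable")
    return keep.drop(columns="_absdiff").reset_index(drop=True)


class CpGAssociation(BaseEstimator):
    """EWAS scan as an estimator.

    ``fit(beta, sheet)`` computes methylation PCs, runs the per-CpG OLS,
    adjusts p-values, locates the empirical P-P threshold (when at least
    100 probes were tested) and ranks DMCs at ``q < q_max``.

    Fitted attributes: ``pcs_``, ``results_``, ``dmcs_``, ``threshold_``,
    ``n_failed_``.
    """

    def __init__(self, n_pcs: int = 2, q_max: float = 0.4,
                 pp_delta: float = 0.5, pp_window: int = 5):
        self.n_pcs = n_pcs
        self.q_max = q_max
        self.pp_delta = pp_delta
        self.pp_window = pp_window

    def fit(self, beta: pd.DataFrame, sheet: pd.DataFrame,
            annotation: pd.DataFrame | None = None):
        beta = beta[list(sheet["sample_id"])]
        self.pcs_ = compute_pcs(beta, k=self.n_pcs) if self.n_pcs else None
        self.results_ = fit_cpg_regressions(beta, sheet, self.pcs_, annotation)
        self.n_failed_ = self.results_.attrs["n_failed"]
        pvals = self.results_["p"].dropna()
        self.threshold_ = (
            empirical_threshold(pvals, self.pp_delta, self.pp_window)
            if len(pvals) >= 100 else None
        )
        self.dmcs_ = rank_dmcs(self.results_, self.q_max)
        return self
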