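"""Cis expression-quantitative-trait-methylation (eQTM) analysis.

Pairs CpGs with transcripts whose gene body lies within a cis window
(default 100 kb, inclusive at both boundaries), then regresses
TMM-normalized expression on PC-residualized methylation with age as a
covariate:

    expression ~ b0 + b1 * beta_residual + b2 * age

The reported coefficient is b1: the change in normalized expression per
unit change in the methylation residual.  Expression is on the natural
(library-size- and factor-scaled count) scale by default, which is what
gives eQTM coefficients their characteristic large magnitudes; a
log2-CPM mode is available.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = ["residualize_methylation", "map_pairs", "fit_eqtm", "EqtmAnalysis"]


def residualize_methylation(beta: pd.DataFrame, pcs: pd.DataFrame) -> pd.DataFrame:
    """Regress the first PCs out of every probe's beta values.

    Per probe, OLS of beta on {intercept, PC1..PCk}; returns the residual
    matrix (probes x samples), exactly orthogonal to the PCs.
    """
    if list(beta.columns) != list(pcs.index):
        raise ValueError("beta columns and PC rows refer to different samples")
    X = np.column_stack([np.ones(len(pcs)), pcs.to_numpy()])
    Y = beta.to_numpy()
    # residual = Y (I - X (X'X)^-1 X')
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ coef).T
    return pd.DataFrame(resid, index=beta.index, columns=beta.columns)


def map_pairs(
    probes: pd.DataFrame, transcripts: pd.DataFrame, window: int = 100_000
) -> pd.DataFrame:
    """All (probe, transcript) pairs with the probe within ``window`` bp.

    A probe pairs with a transcript iff its position lies in
    ``[start - window, end + window]`` (1-based, inclusive at both ends).
    Implemented as a sorted sweep with an active-interval heap, O((n+m) log m + k).

    Returns columns ``probe_id, gene, distance`` where distance is the bp
    distance to the nearest transcript boundary (0 inside the body).
    """
    rows: list[tuple[str, str, int]] = []
    tx_by_chrom = dict(tuple(transcripts.groupby("chrom"))) if len(transcripts) else {}
    for chrom, pr in probes.groupby("chrom"):
        tx = tx_by_chrom.get(chrom)
        if tx is None:
            continue
        order = np.argsort(tx["start"].to_numpy(), kind="stable")
        starts = tx["start"].to_numpy()[order]
        ends = tx["end"].to_numpy()[order]
        genes = tx["gene"].to_numpy()[order]
        p_order = np.argsort(pr["pos"].to_numpy(), kind="stable")
        positions = pr["pos"].to_numpy()[p_order]
        ids = pr["probe_id"].to_numpy()[p_order]
        active: list[tuple[int, int]] = []  # (end + window, tx index)
        j = 0
        for pos, pid in zip(positions, ids):
            while j < len(starts) and starts[j] - window <= pos:
                heapq.heappush(active, (ends[j] + window, j))
                j += 1
            while active and active[0][0] < pos:
                heapq.heappop(active)
            for _, k in active:
                if pos < starts[k]:
                    dist = int(starts[k] - pos)
                elif pos > ends[k]:
                    dist = int(pos - ends[k])
                else:
                    dist = 0
                rows.append((pid, genes[k], dist))
    out = pd.DataFrame(rows, columns=["probe_id", "gene", "distance"])
    return out.sort_values(["probe_id", "gene"], kind="stable").reset_index(drop=True)


def fit_eqtm(
    pairs: pd.DataFrame,
    residuals: pd.DataFrame,
    expression: pd.DataFrame,
    sheet: pd.DataFrame,
    probes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-pair OLS of expression on {intercept, beta residual, age}.

    ``residuals`` are PC-residualized betas (probes x samples) and
    ``expression`` is the normalized expression matrix (genes x samples)
    on whatever scale the caller chose.  Returns one row per testable
    pair with the methylation coefficient and its two-sided t-test p
    (df = n - 3); pairs with a zero-variance residual get NA and are
    counted in ``result.attrs['n_failed']``.
    """
    if list(residuals.columns) != list(sheet["sample_id"]):
        raise ValueError("residual columns do not match the sample sheet")
    if list(expression.columns) != list(sheet["sample_id"]):
        raise ValueError("expression columns do not match the sample sheet")
    age = sheet["age"].to_numpy(dtype=float)
    n = len(age)
    df = n - 3

    pairs = pairs[pairs["probe_id"].isin(residuals.index)
                  & pairs["gene"].isin(expression.index)]
    probe_pos = {pid: i for i, pid in enumerate(residuals.index)}
    gene_pos = {g: i for i, g in enumerate(expression.index)}
    R = residuals.to_numpy(dtype=float)[[probe_pos[p] for p in pairs["probe_id"]]]
    Y = expression.to_numpy(dtype=float)[[gene_pos[g] for g in pairs["gene"]]]

    # batched normal equations for X = [1, residual, age] per pair
    k = R.shape[0]
    XtX = np.empty((k, 3, 3))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = R.sum(axis=1)
    XtX[:, 0, 2] = XtX[:, 2, 0] = age.sum()
    XtX[:, 1, 1] = (R**2).sum(axis=1)
    XtX[:, 1, 2] = XtX[:, 2, 1] = R @ age
    XtX[:, 2, 2] = (age**2).sum()
    XtY = np.stack([Y.sum(axis=1), (R * Y).sum(axis=1), Y @ age], axis=1)

    degenerate = R.var(axis=1) < 1e-16
    coef = np.full((k, 3), np.nan)
    p = np.full(k, np.nan)
    ok = ~degenerate
    if ok.any():
        inv = np.linalg.inv(XtX[ok])
        coef[ok] = np.einsum("kij,kj->ki", inv, XtY[ok])
        rss = (Y[ok] ** 2).sum(axis=1) - np.einsum("ki,ki->k", coef[ok], XtY[ok])
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(np.maximum(sigma2 * inv[:, 1, 1], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, coef[ok, 1] / se, np.nan)
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    n_failed = int(degenerate.sum())

    out = pd.DataFrame({
        "probe_id": pairs["probe_id"].to_numpy(),
        "transcript_gene": pairs["gene"].to_numpy(),
        "coefficient": coef[:, 1],
        "p": p,
    })
    if probes is not None:
        ann = probes.set_index("probe_id")[["nearest_gene", "chrom", "pos"]]
        out = out.join(ann, on="probe_id")
        out = out.rename(columns={"nearest_gene": "cpg_gene", "pos": "position"})
        out = out[["cpg_gene", "probe_id", "chrom", "position", "transcript_gene", "coefficient", "p"]]
    out = out.sort_values("p", kind="stable", na_position="last").reset_index(drop=True)
    out.attrs["n_failed"] = n_failed
    return out


@dataclass
class _EqtmInputs:
    residuals: pd.DataFrame
    expression: pd.DataFrame


class EqtmAnalysis(BaseEstimator):
    """Cis eQTM scan as an estimator.

    Parameters
    ----------
    window : int
        Cis window in bp around the transcript body (inclusive).
    n_pcs : int
        Methylation PCs regressed out of beta values before testing.
    log_expression : bool
        Use log2 CPM instead of natural-scale normalized counts.
    adjust_p : bool
        Add a BH-adjusted ``q`` column (off by default; the natural output
        reports raw p only).
    """

    def __init__(self, window: int = 100_000, n_pcs: int = 2,
                 log_expression: bool = False, adjust_p: bool = False):
        self.window = window
        self.n_pcs = n_pcs
        self.log_expression = log_expression
        self.adjust_p = adjust_p

    def fit(self, beta: pd.DataFrame, counts: pd.DataFrame, sheet: pd.DataFrame,
            probes: pd.DataFrame, transcripts: pd.DataFrame,
            pcs: pd.DataFrame | None = None):
        from .dge import log_cpm, normalized_counts, tmm_factors
        from .ewas import bh_fdr, compute_pcs

        common = [s for s in sheet["sample_id"] if s in beta.columns and s in counts.columns]
        sheet = sheet[sheet["sample_id"].isin(common)].reset_index(drop=True)
        beta = beta[common]
        counts = counts[common]
        if pcs is None:
            pcs = compute_pcs(beta, k=self.n_pcs)
        residuals = residualize_methylation(beta, pcs)
        factors = tmm_factors(counts)
        expression = log_cpm(counts, factors) if self.log_expression else normalized_counts(counts, factors)
        pairs = map_pairs(probes[probes["probe_id"].isin(beta.index)],
                          transcripts[transcripts["gene"].isin(counts.index)],
                          window=self.window)
        results = fit_eqtm(pairs, residuals, expression, sheet, probes=probes)
        if self.adjust_p:
            results["q"] = bh_fdr(results["p"].to_numpy())
        self.pairs_ = pairs
        self.results_ = results
        self.n_failed_ = results.attrs["n_failed"]
        return self
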