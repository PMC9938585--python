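"""Synthetic case-control methylation + expression study generator.

Emulates the data structure the analysis pipeline assumes: an EPIC-style
beta-value matrix with detection-p and bead-count companions, a transcript
count matrix, probe/transcript annotation on a small synthetic genome, and
a sample sheet with group, age, batch and smoking covariates.  Planted
effects (case-control beta shifts, group log-fold changes, cis
methylation-expression couplings) are recorded in a :class:`TruthTable`
so downstream stages can be scored for recovery.

Statistical structure
---------------------
* Baseline probe means follow a two-component Beta mixture with modes near
  0.1 and 0.85 (the familiar bimodality of methylation arrays); per-sample
  values add logit-normal noise and logit-scale batch effects.
* Infinium II probes are distorted by a fixed, invertible quadratic map so
  probe-type normalization has a recoverable target.
* Counts are negative binomial with dispersion cv**2 around log-normally
  distributed gene abundances; library sizes vary up to two-fold.
* eQTM links couple a transcript's per-sample mean linearly to that
  sample's beta value at a probe within the cis window (100 kb).

All randomness flows from ``SimConfig.seed`` through per-stage
``numpy.random.SeedSequence`` children, so every output is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimulatedStudy",
    "simulate_annotation",
    "simulate_methylation",
    "simulate_counts",
    "simulate_study",
    "TYPE2_DISTORTION",
]

#: Fixed quadratic measurement distortion applied to Infinium II betas:
#: ``b' = 0.05 + 0.85*b + 0.10*b**2`` (monotone and onto [0.05, 1] on [0, 1]).
TYPE2_DISTORTION = (0.05, 0.85, 0.10)

LOCATION_CLASSES = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "ExonBnd", "3UTR", "IGR")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

# Marginal frequencies for probe genomic-location classes.  Body/intergenic
# dominated, as on real arrays.
DEFAULT_LOCATION_FREQS = {
    "TSS200": 0.05, "TSS1500": 0.07, "5UTR": 0.06, "1stExon": 0.04,
    "Body": 0.35, "ExonBnd": 0.03, "3UTR": 0.10, "IGR": 0.30,
}
DEFAULT_ISLAND_FREQS = {
    "Island": 0.20, "N_Shore": 0.08, "S_Shore": 0.08,
    "N_Shelf": 0.045, "S_Shelf": 0.045, "OpenSea": 0.55,
}


@dataclass
class SimConfig:
    """Parameters of a simulated study.

    Defaults are desk-scale but keep the reference study's design: 16 cases
    vs 18 controls, ~19 planted DMCs with case-control beta differences in
    0.03-0.09, ~5% of transcripts differentially expressed with |log2FC| in
    0.26-1.18, negative-binomial counts with biological CV 0.4, and cis
    links of which about half are negative.
    """

    n_cases: int = 16
    n_controls: int = 18
    n_cpgs: int = 5000
    n_transcripts: int = 2000
    n_dmc: int = 19
    delta_range: tuple[float, float] = (0.03, 0.09)
    n_deg: int = 100
    lfc_range: tuple[float, float] = (0.26, 1.18)
    n_links: int = 25
    frac_negative_links: float = 0.5
    n_batches: int = 2
    batch_sd_logit: float = 0.15
    type2_fraction: float = 0.84
    mean_library_size: float = 2e5
    cv: float = 0.4
    age_range: tuple[float, float] = (30.0, 70.0)
    seed: int = 0

    # Stand-ins the reference study does not parameterize; exposed so the
    # study conditions are explicit rather than buried in code.
    noise_sd_logit: float = 0.10        # per-sample logit-beta noise
    n_latent_factors: int = 2           # admixture-like sample structure
    latent_sd_logit: float = 0.08       # per-probe loading sd of the factors
    frac_detection_fail: float = 0.002  # detection p > 0.01 events
    frac_low_bead: float = 0.002        # bead count < 3 events
    frac_positive_dmc: float = 0.5      # sign split of planted beta shifts
    link_slope_range: tuple[float, float] = (6.0, 15.0)  # |slope| per unit beta
    n_chromosomes: int = 4
    chrom_length: int = 5_000_000
    frac_probes_near_transcript: float = 0.9
    frac_probe_pairs: float = 0.05      # probes placed < 50 bp from a neighbor
    location_class_freqs: dict | None = None
    island_relation_freqs: dict | None = None
    dmc_location_weight: dict | None = None  # e.g. {"ExonBnd": 5.0}

    def __post_init__(self) -> None:
        counts = {
            "n_cases": self.n_cases, "n_controls": self.n_controls,
            "n_cpgs": self.n_cpgs, "n_transcripts": self.n_transcripts,
            "n_dmc": self.n_dmc, "n_deg": self.n_deg, "n_links": self.n_links,
            "n_batches": self.n_batches,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_dmc > self.n_cpgs:
            raise ValueError("n_dmc cannot exceed n_cpgs")
        if self.n_deg > self.n_transcripts:
            raise ValueError("n_deg cannot exceed n_transcripts")
        if not 0.0 <= self.frac_negative_links <= 1.0:
            raise ValueError("frac_negative_links must be in [0, 1]")
        lo, hi = self.delta_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("delta_range must lie within (0, 1)")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if not 0.0 <= self.type2_fraction <= 1.0:
            raise ValueError("type2_fraction must be in [0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def _rng(self, stage: int) -> np.random.Generator:
        """Stage-scoped generator so stages are independently reproducible."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class TruthTable:
    """Planted effects, resolvable against the emitted annotation.

    ``dmc``:   probe_id, delta_beta (signed shift added to case betas)
    ``deg``:   gene, log2fc (case relative to control)
    ``links``: probe_id, gene, sign, slope (expression units per unit beta)
    """

    dmc: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["probe_id", "delta_beta"]))
    deg: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene", "log2fc"]))
    links: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["probe_id", "gene", "sign", "slope"]))
    notes: dict = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated study produces."""

    config: SimConfig
    probes: pd.DataFrame
    transcripts: pd.DataFrame
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    beads: pd.DataFrame
    counts: pd.DataFrame
    sheet: pd.DataFrame
    truth: TruthTable


def _freqs_to_arrays(freqs: dict | None, default: dict, vocabulary: tuple) -> tuple[np.ndarray, np.ndarray]:
    table = dict(default if freqs is None else freqs)
    unknown = set(table) - set(vocabulary)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    labels = np.array([c for c in vocabulary if table.get(c, 0) > 0])
    probs = np.array([table[c] for c in labels], dtype=float)
    return labels, probs / probs.sum()


def simulate_annotation(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place probes and transcripts on a small synthetic genome.

    Returns (probe annotation, transcript annotation).  Transcripts are laid
    out first; a configurable fraction of probes is then dropped within the
    cis window (100 kb) of a random transcript so that eQTM pairing is
    non-empty.  Coordinates are 1-based and inclusive.
    """
    rng = config._rng(0)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    n_tx = config.n_transcripts
    tx_chrom = rng.choice(chroms, size=n_tx)
    tx_len = rng.integers(2_000, 80_000, size=n_tx)
    tx_start = np.empty(n_tx, dtype=np.int64)
    for i in range(n_tx):
        tx_start[i] = rng.integers(1, max(2, config.chrom_length - tx_len[i]))
    transcripts = pd.DataFrame({
        "gene": [f"G{i + 1:05d}" for i in range(n_tx)],
        "chrom": tx_chrom,
        "start": tx_start,
        "end": tx_start + tx_len,
        "strand": rng.choice(["+", "-"], size=n_tx),
    })

    n = config.n_cpgs
    loc_labels, loc_p = _freqs_to_arrays(config.location_class_freqs, DEFAULT_LOCATION_FREQS, LOCATION_CLASSES)
    isl_labels, isl_p = _freqs_to_arrays(config.island_relation_freqs, DEFAULT_ISLAND_FREQS, ISLAND_RELATIONS)

    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    near = rng.random(n) < config.frac_probes_near_transcript
    if n_tx == 0:
        near[:] = False
    for i in range(n):
        if near[i]:
            j = rng.integers(0, n_tx)
            lo = max(1, int(tx_start[j]) - 100_000)
            hi = min(config.chrom_length, int(tx_start[j] + tx_len[j]) + 100_000)
            chrom[i] = tx_chrom[j]
            pos[i] = rng.integers(lo, hi + 1)
        else:
            chrom[i] = rng.choice(chroms)
            pos[i] = rng.integers(1, config.chrom_length + 1)

    # Arrays place many probes in tight clusters (islands); emulate by
    # relocating a fraction right next to the preceding probe (< 50 bp) so
    # Type I/II neighbor pairs exist for probe-type normalization.
    if n > 1 and config.frac_probe_pairs > 0:
        paired = np.where(rng.random(n - 1) < config.frac_probe_pairs)[0] + 1
        for i in paired:
            chrom[i] = chrom[i - 1]
            pos[i] = min(int(pos[i - 1]) + int(rng.integers(5, 50)), config.chrom_length)

    design = np.where(rng.random(n) < config.type2_fraction, "II", "I")
    probes = pd.DataFrame({
        "probe_id": [f"cg{i + 1:07d}" for i in range(n)],
        "chrom": chrom,
        "pos": pos,
        "design_type": design,
        "island_relation": rng.choice(isl_labels, size=n, p=isl_p) if n else np.array([], dtype=object),
        "location_class": rng.choice(loc_labels, size=n, p=loc_p) if n else np.array([], dtype=object),
    })
    probes["nearest_gene"] = _nearest_gene(probes, transcripts)
    return probes, transcripts


def _nearest_gene(probes: pd.DataFrame, transcripts: pd.DataFrame) -> np.ndarray:
    """Nearest transcript's gene on the same chromosome ('' if none)."""
    out = np.full(len(probes), "", dtype=object)
    if len(transcripts) == 0 or len(probes) == 0:
        return out
    for chrom, tx in transcripts.groupby("chrom"):
        mask = (probes["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        mid = ((tx["start"] + tx["end"]) // 2).to_numpy()
        order = np.argsort(mid)
        mid_sorted = mid[order]
        genes = tx["gene"].to_numpy()[order]
        p = probes.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(mid_sorted, p)
        idx_lo = np.clip(idx - 1, 0, len(mid_sorted) - 1)
        idx_hi = np.clip(idx, 0, len(mid_sorted) - 1)
        pick = np.where(np.abs(mid_sorted[idx_hi] - p) < np.abs(p - mid_sorted[idx_lo]), idx_hi, idx_lo)
        out[mask] = genes[pick]
    return out


def _position_clusters(probes: pd.DataFrame, max_gap: int = 500) -> np.ndarray:
    """Group probes into regional clusters: same chromosome, gaps <= max_gap."""
    order = np.lexsort((probes["pos"].to_numpy(), probes["chrom"].to_numpy()))
    chrom = probes["chrom"].to_numpy()[order]
    pos = probes["pos"].to_numpy()[order]
    new = np.ones(len(order), dtype=bool)
    if len(order) > 1:
        new[1:] = (chrom[1:] != chrom[:-1]) | (np.diff(pos) > max_gap)
    ids_sorted = np.cumsum(new) - 1
    out = np.empty(len(order), dtype=np.int64)
    out[order] = ids_sorted
    return out


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x / (1.0 - x))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    config: SimConfig, probes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate beta, detection-p and bead-count matrices plus sample sheet.

    Case samples receive a shift of signed magnitude drawn from
    ``delta_range`` at ``n_dmc`` probes (recorded in the truth table);
    batch effects act on the logit scale; Infinium II probes are distorted
    by :data:`TYPE2_DISTORTION` last, as a measurement artifact.
    """
    if len(probes) == 0:
        raise ValueError("probes must be non-empty")
    rng = config._rng(1)
    n_probes = len(probes)
    n = config.n_cases + config.n_controls

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    group = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    age = np.round(rng.uniform(*config.age_range, size=n), 1)
    batch_idx = rng.permutation(np.arange(n) % max(1, config.n_batches))
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "group": group,
        "age": age,
        "batch": [f"B{b + 1}" for b in batch_idx],
        "smoker": rng.random(n) < 0.15,
    })

    # Baseline bimodal probe means (modes ~0.1 and ~0.85).  Methylation is
    # regionally correlated, so probes within 500 bp share a latent regional
    # level with a small probe-specific logit jitter; this is also what lets
    # probe-type normalization learn from Type I/II neighbor pairs.
    cluster = _position_clusters(probes, max_gap=500)
    n_clusters = int(cluster.max()) + 1
    low = rng.random(n_clusters) < 0.45
    cluster_mu = np.where(low, rng.beta(3.0, 19.0, size=n_clusters),
                          rng.beta(18.0, 4.0, size=n_clusters))
    cluster_mu = np.clip(cluster_mu, 1e-3, 1 - 1e-3)
    mu = _expit(_logit(cluster_mu[cluster]) + rng.normal(0.0, 0.2, size=n_probes))
    mu = np.clip(mu, 1e-3, 1 - 1e-3)

    # Planted DMCs, optionally biased toward a genomic-location class.
    weights = np.ones(n_probes)
    if config.dmc_location_weight:
        for cls, w in config.dmc_location_weight.items():
            weights[probes["location_class"].to_numpy() == cls] = w
    dmc_idx = rng.choice(n_probes, size=config.n_dmc, replace=False, p=weights / weights.sum())
    delta = rng.uniform(*config.delta_range, size=config.n_dmc)
    sign = np.where(rng.random(config.n_dmc) < config.frac_positive_dmc, 1.0, -1.0)
    delta *= sign

    mean = np.tile(mu[:, None], (1, n))
    mean[dmc_idx[:, None], np.where(group == "case")[0][None, :]] += delta[:, None]
    n_clamped = int(np.sum((mean < 1e-4) | (mean > 1 - 1e-4)))
    mean = np.clip(mean, 1e-4, 1 - 1e-4)

    gamma = rng.normal(0.0, config.batch_sd_logit, size=(n_probes, max(1, config.n_batches)))
    eta = _logit(mean) + gamma[:, batch_idx] + rng.normal(0.0, config.noise_sd_logit, size=(n_probes, n))
    # Admixture-like background structure: latent per-sample factors with
    # probe-specific loadings, independent of disease status -- the variance
    # the downstream PC adjustment exists to absorb.
    if config.n_latent_factors > 0 and config.latent_sd_logit > 0:
        loadings = rng.normal(0.0, config.latent_sd_logit, size=(n_probes, config.n_latent_factors))
        factors = rng.normal(0.0, 1.0, size=(config.n_latent_factors, n))
        eta += loadings @ factors
    beta = _expit(eta)

    # Infinium II measurement distortion (applied last, invertible).
    c0, c1, c2 = TYPE2_DISTORTION
    type2 = (probes["design_type"].to_numpy() == "II")
    beta[type2] = c0 + c1 * beta[type2] + c2 * beta[type2] ** 2
    beta = np.clip(beta, 0.0, 1.0)

    detp = rng.uniform(0.0, 0.009, size=beta.shape)
    fail = rng.random(beta.shape) < config.frac_detection_fail
    detp[fail] = rng.uniform(0.02, 0.8, size=int(fail.sum()))

    beads = 3 + rng.poisson(9.0, size=beta.shape)
    lowb = rng.random(beta.shape) < config.frac_low_bead
    beads[lowb] = rng.integers(1, 3, size=int(lowb.sum()))

    probe_ids = probes["probe_id"].to_numpy()
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
    detp_df = pd.DataFrame(detp, index=probe_ids, columns=sample_ids)
    beads_df = pd.DataFrame(beads, index=probe_ids, columns=sample_ids)

    truth = TruthTable(
        dmc=pd.DataFrame({"probe_id": probe_ids[dmc_idx], "delta_beta": delta}),
        notes={"clamped_means": n_clamped},
    )
    return beta_df, detp_df, beads_df, sheet, truth


def simulate_counts(
    config: SimConfig,
    transcripts: pd.DataFrame,
    sheet: pd.DataFrame,
    beta: pd.DataFrame,
    truth: TruthTable,
    probes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate the transcript count matrix and extend the truth table.

    Per-gene abundances are log-normal; counts are negative binomial with
    dispersion ``cv**2``.  ``n_deg`` genes receive a group log2 fold change
    and ``n_links`` (probe, gene) pairs within 100 kb couple the gene's
    per-sample mean linearly to that sample's beta value; planted-DMC
    probes are preferred as link anchors when they are in range.
    """
    if list(beta.columns) != list(sheet["sample_id"]):
        raise ValueError("sample sheet is not consistent with beta columns")
    rng = config._rng(2)
    n_tx = len(transcripts)
    n = len(sheet)
    is_case = (sheet["group"] == "case").to_numpy()

    abundance = np.exp(rng.normal(np.log(50.0), 1.2, size=n_tx))
    abundance /= abundance.sum() if n_tx else 1.0
    lib = config.mean_library_size * 2.0 ** rng.uniform(-0.5, 0.5, size=n)

    mean = abundance[:, None] * lib[None, :]

    deg_idx = rng.choice(n_tx, size=config.n_deg, replace=False) if config.n_deg else np.array([], dtype=int)
    lfc = rng.uniform(*config.lfc_range, size=config.n_deg)
    lfc *= np.where(rng.random(config.n_deg) < 0.5, 1.0, -1.0)
    mean[np.ix_(deg_idx, is_case)] *= 2.0 ** lfc[:, None]

    link_rows = []
    if config.n_links:
        if probes is None:
            raise ValueError("probe annotation is required to plant eQTM links")
        from .eqtm import map_pairs  # cis pairing logic lives with the eQTM stage

        pairs = map_pairs(probes, transcripts, window=100_000)
        pairs = pairs[pairs["probe_id"].isin(beta.index)]
        if len(pairs) == 0:
            raise ValueError(
                f"requested {config.n_links} links but no probe lies within "
                "100 kb of any transcript"
            )
        dmc_ids = set(truth.dmc["probe_id"]) if truth is not None else set()
        pairs = pairs.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
        preferred = pairs[pairs["probe_id"].isin(dmc_ids)]
        rest = pairs[~pairs["probe_id"].isin(dmc_ids)]
        ordered = pd.concat([preferred, rest], ignore_index=True)
        seen_genes: set[str] = set()
        chosen = []
        for _, row in ordered.iterrows():
            if row["gene"] in seen_genes:
                continue
            seen_genes.add(row["gene"])
            chosen.append(row)
            if len(chosen) == config.n_links:
                break
        if len(chosen) < config.n_links:
            raise ValueError(
                f"requested {config.n_links} links but only {len(chosen)} "
                "distinct genes have a probe within 100 kb"
            )
        neg = rng.random(config.n_links) < config.frac_negative_links
        slope_mag = rng.uniform(*config.link_slope_range, size=config.n_links)
        gene_pos = {g: i for i, g in enumerate(transcripts["gene"])}
        for k, row in enumerate(chosen):
            s = -slope_mag[k] if neg[k] else slope_mag[k]
            b = beta.loc[row["probe_id"]].to_numpy()
            factor = np.clip(1.0 + s * (b - b.mean()), 0.05, None)
            mean[gene_pos[row["gene"]]] *= factor
            link_rows.append((row["probe_id"], row["gene"], "-" if neg[k] else "+", s))

    r = np.inf if config.cv == 0 else 1.0 / config.cv**2
    if np.isinf(r):
        counts = rng.poisson(mean)
    else:
        counts = rng.negative_binomial(r, r / (r + mean))

    counts_df = pd.DataFrame(counts, index=transcripts["gene"].to_numpy(), columns=beta.columns)
    notes = dict(truth.notes) if truth is not None else {}
    notes["library_sizes"] = lib.tolist()
    out = TruthTable(
        dmc=truth.dmc.copy() if truth is not None else TruthTable().dmc,
        deg=pd.DataFrame({"gene": transcripts["gene"].to_numpy()[deg_idx], "log2fc": lfc}),
        links=pd.DataFrame(link_rows, columns=["probe_id", "gene", "sign", "slope"]),
        notes=notes,
    )
    return counts_df, out


def simulate_blocklists(config: SimConfig, probes: pd.DataFrame,
                        frac: float = 0.01) -> dict[str, set]:
    """Disjoint non-CpG / multi-mapping / smoking-associated probe id sets.

    Real studies take these from the array manifest and the literature;
    here a small seeded fraction of probes is assigned to each rule so QC
    filtering has realistic inputs.
    """
    rng = config._rng(3)
    ids = probes["probe_id"].to_numpy()
    k = int(round(frac * len(ids)))
    chosen = rng.choice(len(ids), size=min(3 * k, len(ids)), replace=False)
    return {
        "non_cpg": set(ids[chosen[:k]]),
        "multi_mapping": set(ids[chosen[k:2 * k]]),
        "smoking": set(ids[chosen[2 * k:3 * k]]),
    }


def simulate_study(config: SimConfig | None = None, **overrides) -> SimulatedStudy:
    """Run all three generator stages with one config."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    probes, transcripts = simulate_annotation(config)
    beta, detp, beads, sheet, truth = simulate_methylation(config, probes)
    counts, truth = simulate_counts(config, transcripts, sheet, beta, truth, probes=probes)
    return SimulatedStudy(config, probes, transcripts, beta, detp, beads, counts, sheet, truth)
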