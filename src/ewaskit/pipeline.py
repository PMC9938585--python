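"""End-to-end orchestration: simulate -> preprocess -> EWAS -> DGE -> eQTM -> enrich.

``run_all`` drives every stage on one simulated study, writes each
stage's tables under an output directory, and returns a run report with
per-stage record counts, the seed and thresholds used, and
truth-recovery summaries scored against the simulator's planted effects.
Outputs are deterministic given the configuration (seed included).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .dge import NBDifferentialExpression
from .enrich import location_enrichment
from .eqtm import EqtmAnalysis
from .ewas import CpGAssociation
from .preprocess import BatchAdjuster, ProbeTypeNormalizer, filter_probes, filter_samples
from .simulate import SimConfig, simulate_blocklists, simulate_study

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, stage by stage."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "ewaskit_run"
    min_success_ratio: float = 0.9
    n_pcs: int = 2
    q_max_ewas: float = 0.4
    q_max_dge: float = 0.4
    window: int = 100_000
    top_n: int = 100
    trim_m: float = 0.30
    trim_a: float = 0.05
    min_cpm: float = 1.0
    prior_df: float = 10.0
    eqtm_top_cpgs: int = 100
    skip_probe_type: bool = False
    verbosity: int = 1

    def __post_init__(self) -> None:
        for name in ("min_success_ratio", "q_max_ewas", "q_max_dge"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.window < 0 or self.top_n < 1 or self.n_pcs < 0:
            raise ValueError("window must be >= 0, top_n >= 1, n_pcs >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in (raw.pop("sim", {}) or {}).items()})
        return cls(sim=sim, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.sim.seed
    meta = {"seed": seed, "version": __version__}
    log = print if config.verbosity else (lambda *a, **k: None)
    report: dict = {"seed": seed, "version": __version__}

    # --- simulate -------------------------------------------------------
    study = simulate_study(config.sim)
    blocklists = simulate_blocklists(config.sim, study.probes)
    io.write_matrix(study.beta, out / "beta.tsv", "beta", meta)
    io.write_matrix(study.detection_p, out / "detection_p.tsv", "detection_p", meta)
    io.write_matrix(study.beads, out / "beads.tsv", "beads", meta)
    io.write_matrix(study.counts, out / "counts.tsv", "counts", meta)
    io.write_sample_sheet(study.sheet, out / "samples.csv", meta)
    io.write_table(study.probes, out / "probe_annotation.tsv", meta)
    io.write_probe_bed(study.probes, out / "probes.bed")
    io.write_table(study.transcripts, out / "transcript_annotation.tsv", meta)
    io.write_table(study.truth.dmc, out / "truth_dmc.tsv", meta)
    io.write_table(study.truth.deg, out / "truth_deg.tsv", meta)
    io.write_table(study.truth.links, out / "truth_links.tsv", meta)
    for rule, ids in blocklists.items():
        io.write_blocklist(ids, out / f"blocklist_{rule}.txt")
    config.to_yaml(out / "config.yaml")
    report["simulate"] = {
        "n_cpgs": len(study.probes), "n_transcripts": len(study.transcripts),
        "n_samples": len(study.sheet), "clamped_means": study.truth.notes.get("clamped_means", 0),
    }
    log(f"[simulate] {len(study.probes)} CpGs, {len(study.transcripts)} transcripts, "
        f"{len(study.sheet)} samples (seed {seed})")

    # --- preprocess -----------------------------------------------------
    beta, sample_report = filter_samples(study.beta, study.detection_p, config.min_success_ratio)
    kept_samples = list(beta.columns)
    detp = study.detection_p[kept_samples]
    beads = study.beads[kept_samples]
    sheet = study.sheet[study.sheet["sample_id"].isin(kept_samples)].reset_index(drop=True)
    beta, probe_report = filter_probes(beta, detp, beads, study.probes, blocklists)
    probe_report.samples_removed = sample_report.samples_removed

    batches = sheet.set_index("sample_id").loc[kept_samples, "batch"].to_numpy()
    beta = BatchAdjuster().fit_transform(beta, batch=batches)
    if not config.skip_probe_type:
        normalizer = ProbeTypeNormalizer().fit(beta, study.probes)
        beta = normalizer.transform(beta, study.probes)
        report["probe_type_fit"] = dataclasses.asdict(normalizer.fit_)
    io.write_matrix(beta, out / "beta_preprocessed.tsv", "beta", meta)
    io.write_report({
        "samples_removed": len(probe_report.samples_removed),
        **{f"probes_removed_{k}": v for k, v in probe_report.probes_removed.items()},
        "probes_retained": probe_report.probes_retained,
    }, out / "qc_report.txt", meta)
    report["preprocess"] = {
        "samples_removed": len(probe_report.samples_removed),
        "probes_removed": dict(probe_report.probes_removed),
        "probes_retained": probe_report.probes_retained,
    }
    log(f"[preprocess] retained {probe_report.probes_retained} probes, "
        f"{len(kept_samples)} samples")

    # --- EWAS -----------------------------------------------------------
    ewas = CpGAssociation(n_pcs=config.n_pcs, q_max=config.q_max_ewas)
    ewas.fit(beta, sheet, annotation=study.probes)
    io.write_table(ewas.results_, out / "ewas_results.tsv", meta)
    io.write_table(ewas.dmcs_, out / "ewas_dmcs.tsv", meta)
    pvals = np.sort(ewas.results_["p"].dropna().to_numpy())
    if pvals.size:
        io.write_table(pd.DataFrame({
            "theoretical_neglog10": -np.log10(np.arange(1, pvals.size + 1) / (pvals.size + 1)),
            "empirical_neglog10": -np.log10(np.maximum(pvals, 1e-300)),
        }), out / "pp_plot.tsv", meta)
    pp = ewas.threshold_
    report["ewas"] = {
        "n_tested": len(ewas.results_), "n_dmc": len(ewas.dmcs_),
        "q_max": config.q_max_ewas, "n_failed": ewas.n_failed_,
        "pp_departure": None if pp is None else pp.departure,
    }
    log(f"[ewas] {len(ewas.results_)} CpGs tested, {len(ewas.dmcs_)} DMCs at "
        f"q<{config.q_max_ewas}")

    # --- DGE ------------------------------------------------------------
    dge = NBDifferentialExpression(trim_m=config.trim_m, trim_a=config.trim_a,
                                   min_cpm=config.min_cpm, prior_df=config.prior_df,
                                   q_max=config.q_max_dge)
    dge.fit(study.counts, sheet, annotation=study.transcripts)
    io.write_table(dge.results_, out / "dge_results.tsv", meta)
    io.write_table(dge.degs_, out / "dge_degs.tsv", meta)
    report["dge"] = {
        "n_tested": len(dge.results_), "n_deg": len(dge.degs_),
        "q_max": config.q_max_dge, "n_unconverged": dge.results_.attrs["n_unconverged"],
    }
    log(f"[dge] {len(dge.results_)} transcripts tested, {len(dge.degs_)} DE at "
        f"q<{config.q_max_dge}")

    # --- eQTM -----------------------------------------------------------
    top_cpg_ids = ewas.results_.sort_values("p").head(config.eqtm_top_cpgs)["probe_id"]
    eqtm_beta = beta.loc[beta.index.intersection(top_cpg_ids)]
    eqtm_genes = dge.degs_["gene"] if len(dge.degs_) else dge.results_["gene"]
    eqtm_counts = study.counts.loc[study.counts.index.intersection(eqtm_genes)]
    eqtm = EqtmAnalysis(window=config.window, n_pcs=config.n_pcs)
    if len(eqtm_counts):
        eqtm.fit(eqtm_beta, eqtm_counts, sheet, study.probes, study.transcripts,
                 pcs=ewas.pcs_.loc[eqtm_beta.columns] if ewas.pcs_ is not None else None)
        io.write_table(eqtm.results_, out / "eqtm_results.tsv", meta)
        report["eqtm"] = {"n_pairs": len(eqtm.results_), "window": config.window}
        log(f"[eqtm] {len(eqtm.results_)} cis pairs tested")
    else:
        report["eqtm"] = {"n_pairs": 0, "window": config.window}

    # --- enrichment -----------------------------------------------------
    top = ewas.results_.sort_values("p").head(config.top_n)
    enrichment = location_enrichment(top, study.probes)
    io.write_table(enrichment, out / "enrichment.tsv", meta)
    report["enrich"] = {"top_n": config.top_n, "n_classes": len(enrichment)}

    # --- truth recovery -------------------------------------------------
    report["recovery"] = _truth_recovery(study, ewas, dge, eqtm if len(eqtm_counts) else None)
    io.write_report(_flatten(report), out / "run_report.txt", meta)
    log(f"[done] report written to {out / 'run_report.txt'}")
    return report


def _truth_recovery(study, ewas, dge, eqtm) -> dict:
    """Score each stage against the simulator's planted truth."""
    out: dict = {}
    truth = study.truth
    res = ewas.results_.dropna(subset=["p"]).sort_values("p").reset_index(drop=True)
    planted = set(truth.dmc["probe_id"])
    if planted and len(res):
        rank = {pid: i for i, pid in enumerate(res["probe_id"])}
        pct = [rank[p] / len(res) for p in planted if p in rank]
        out["dmc_median_rank_pct"] = float(np.median(pct)) if pct else None
        top = set(res.head(max(len(planted), 1))["probe_id"])
        out["dmc_in_top_k"] = len(planted & top)
    dres = dge.results_.dropna(subset=["p"]).sort_values("p").reset_index(drop=True)
    planted_genes = set(truth.deg["gene"])
    if planted_genes and len(dres):
        top = set(dres.head(len(planted_genes))["gene"])
        out["deg_in_top_k"] = len(planted_genes & top)
        est = dres.set_index("gene")["logFC"]
        tr = truth.deg.set_index("gene")["log2fc"]
        common = est.index.intersection(tr.index)
        if len(common):
            out["deg_sign_agreement"] = float((np.sign(est[common]) == np.sign(tr[common])).mean())
    if eqtm is not None and len(truth.links):
        er = eqtm.results_.set_index(["probe_id", "transcript_gene"])
        hits = signs = 0
        for _, row in truth.links.iterrows():
            key = (row["probe_id"], row["gene"])
            if key in er.index:
                hits += 1
                coef = er.loc[key, "coefficient"]
                coef = coef.iloc[0] if isinstance(coef, pd.Series) else coef
                if np.isfinite(coef) and (coef > 0) == (row["sign"] == "+"):
                    signs += 1
        out["links_tested"] = hits
        out["link_sign_agreement"] = signs / hits if hits else None
    return out


def _flatten(report: dict, prefix: str = "") -> dict:
    flat = {}
    for key, value in report.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, prefix=f"{name}."))
        else:
            flat[name] = value
    return flat
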