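# ewaskit

Integrated analysis of case–control DNA methylation (Illumina EPIC-style
beta values) and RNA-seq gene expression, as used in epigenome-wide
association studies (EWAS) of sorted immune-cell populations — for
example classical monocytes in autoimmune disease. The package covers
the full path from raw matrices to integrated results:

1. **QC filtering** — drop samples by successful-probe fraction
   (detection p < 0.01), drop probes failing detection, known
   non-CpG / multi-mapping / smoking-associated probes, and probes with
   bead count < 3 in ≥ 5% of samples;
2. **batch adjustment** — per-probe location–scale parametric
   empirical-Bayes correction (ComBat-style) on beta values;
3. **probe-type normalization** — Infinium II betas rescaled onto the
   Infinium I distribution via a second-order polynomial fitted to
   Type I/II probe pairs within 50 bp;
4. **EWAS** — per-CpG ordinary least squares
   `β ~ b₀ + b₁·status + b₂·age + b₃·PC1 + b₄·PC2`,
   with Benjamini–Hochberg FDR and an empirical significance threshold
   read from the P–P plot of −log₁₀ p order statistics;
5. **differential expression** — TMM normalization and a per-gene
   quasi-likelihood negative-binomial log-linear model
   (`log μ = offset + b₀ + b₁·status`, dispersion = CV², moderated
   F-type test);
6. **eQTM** — cis pairing of CpGs to transcripts within 100 kb and
   per-pair OLS `expression ~ b₀ + b₁·β-residual + b₂·age`, where the
   β-residuals have the first two methylation PCs regressed out;
7. **enrichment** — odds-ratio enrichment of top DMCs across genomic
   location classes (TSS200 … exon boundary … intergenic) against the
   distribution of all tested CpGs, with Woolf CIs and Fisher exact p;
8. **power** — closed-form two-group RNA-seq power
   `Φ(|ln FC| / √((1/depth + cv²)(1/n₁ + 1/n₂)) − z₁₋α/₂)` and a
   simulation-based methylation power estimate.

A first-class, fully seeded synthetic-data generator
(`ewaskit.simulate`) emulates the data structure this design assumes —
bimodal regional methylation with admixture-like latent structure and
batch effects, Infinium II distortion, negative-binomial counts with
biological CV 0.4, and planted case–control effects (Δβ 0.03–0.09,
|log₂FC| 0.26–1.18, signed cis couplings) recorded in a truth table so
every stage can be scored for recovery.

## Worked example

Closed-form RNA-seq power at the design point of a 16-vs-18 monocyte
study (depth 25, CV 0.4, α = 10⁻⁴, equal n = 16):

```console
$ ewaskit power rnaseq
effect  power
1.5     0.0924
2       0.6891
2.5     0.9716
```

So such a study detects a 2.5-fold change with ~97% probability, a
2-fold change with ~69%, but only ~9% of 1.5-fold changes — it is
powered for large expression shifts and essentially blind to subtle
ones.

The full pipeline on the default simulated study (5,000 CpGs, 2,000
transcripts, 16 cases vs 18 controls, seed 0):

```console
$ ewaskit run-all --out-dir run0
[simulate] 5000 CpGs, 2000 transcripts, 34 samples (seed 0)
[preprocess] retained 4524 probes, 34 samples
[ewas] 4524 CpGs tested, 52 DMCs at q<0.4
[dge] 1999 transcripts tested, 153 DE at q<0.4
[eqtm] 189 cis pairs tested
[done] report written to run0/run_report.txt
```

The run report scores each stage against the planted truth; for this
seed, 18 of 19 planted DMCs rank inside the top 19 probes by p-value
(median rank percentile 0.2%), 69 of 100 planted DEGs are inside the
top 100 with 98% sign agreement, and all 22 testable planted eQTM links
are recovered with the correct coefficient sign. Per-stage tables
(`ewas_results.tsv`, `dge_results.tsv`, `eqtm_results.tsv`,
`enrichment.tsv`, `pp_plot.tsv`, …) land next to the report.

As a library, the stages are scikit-learn-style estimators:

```python
import ewaskit as ek

study = ek.simulate_study(ek.SimConfig(seed=0))
ewas = ek.CpGAssociation(n_pcs=2, q_max=0.4).fit(study.beta, study.sheet,
                                                 annotation=study.probes)
ewas.dmcs_          # ranked DMC table (|difference| descending)
ewas.threshold_     # empirical P-P significance threshold
```

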