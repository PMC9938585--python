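# Methods

This note documents the statistical models, the synthetic-data
generator's assumptions, and the numerically consequential design
choices. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## Study design being modeled

A two-group (case/control) study of a sorted cell population measuring
(i) genome-wide DNA methylation as beta values — per-CpG proportions
methylated in [0, 1] from a two-chemistry (Infinium I/II) array — and
(ii) transcript counts from RNA-seq on overlapping samples. Default
group sizes are 16 cases vs 18 controls; EWAS recovery checks also use
the 12 vs 12 layout of a typical methylation arm. Covariates are age,
array batch, and smoking status (smoking enters as a probe blocklist,
not a model term).

## Preprocessing

**Sample QC.** A probe call succeeds when its detection p < 0.01. A
sample is kept when its successful-probe fraction is at least
`min_success_ratio` (default 0.9). The permissive threshold 0.1 that
sometimes appears in study descriptions is expressible through the same
parameter; both behaviors are tested.

**Probe QC.** Probes are removed, in order, when (1) detection p > 0.01
in any retained sample — strictly greater, so p = 0.01 survives; (2)
they appear on the non-CpG or (3) multi-mapping blocklists; (4) bead
count < 3 in ≥ 5% of samples; (5) they appear on the
smoking-association blocklist. The QC report attributes each removal to
the first rule that fired, so removal counts always reconcile with the
matrix shape. Blocklists are plain id files, never hard-coded.

**Batch adjustment.** Standard parametric empirical-Bayes
location–scale adjustment applied to beta values directly (as such
studies typically run it), clamped back into [0, 1]: standardize each
probe by the batch-weighted grand mean and pooled residual variance,
estimate per-batch per-probe location (γ̂) and scale (δ̂²), shrink via a
normal prior on γ and an inverse-gamma prior on δ² solved by the usual
fixed-point iteration, and back-transform. The implementation matches
Bioconductor's reference implementation to < 1e−3 on a shared fixture
(tested via Rscript). Two consequences worth knowing:

* a single batch is special-cased to the identity — the EB scale
  posterior is not exactly 1 even with one batch;
* the adjustment is *not* exactly idempotent: shrinkage leaves residual
  batch differences of order (1 − shrinkage weight)·γ̂, so a second pass
  still moves values slightly (measured ≈ 1e−2 on simulator data, an
  order of magnitude below the planted batch effect). Exact idempotency
  would require unshrunk location/scale removal.

**Probe-type normalization.** Each Infinium II probe is paired with the
nearest unused Infinium I probe on the same chromosome within 50 bp
(nearest-first greedy; ties go to the lower coordinate, making pairing
deterministic). Mean Type I beta is regressed on mean Type II beta and
its square; the fitted polynomial, clamped into [0, 1], replaces every
Type II value. Fitting the *Type I* value on the *Type II* value means
the polynomial approximates the inverse of the Type II compression,
i.e. Type II is rescaled onto the Type I distribution. At least 3 pairs
are required; fewer is an error suggesting a larger simulation or the
skip flag.

## EWAS

Per CpG, ordinary least squares of beta on {intercept, status
(case = 1), age, PC1, PC2}, where the PCs are the top-2 sample scores of
the SVD of the probe-centered analysis matrix (computed *after* all
preprocessing). The status coefficient's two-sided t-test with
residual df = n − 5 gives p; Benjamini–Hochberg step-up gives q. Group
means and their difference (case − control) are reported raw, matching
how such tables present "control β / case β / difference"; the
coefficient equals the difference exactly when covariates are
group-balanced. Although study write-ups sometimes call disease status
"the random effect", the displayed model is an OLS mean model and a
~24-sample study cannot identify a random disease effect; all terms are
fixed here. A singular design produces counted NA rows, not a crash.

**Empirical P–P threshold.** Sorted p-values are plotted as empirical
−log₁₀ p against theoretical quantiles −log₁₀(i/(m+1)). A line is
fitted where the data must be null-consistent (theoretical in (0, 3))
and extrapolated; the departure is the smallest theoretical value ≥ 3
at which the empirical values exceed the line by more than `delta`
(default 0.5) for `window` (default 5) consecutive order statistics,
with the run assessed toward the extreme. Both the theoretical
coordinate and the observed −log₁₀ p at departure are reported. The
theoretical coordinate is **not invariant to the number of tests**: 19
genome-scale signals among ~8×10⁵ tests depart near 4 (tested with a
clean uniform null plus the reported signal p-values), but the same 19
signals among 10⁴ tests occupy ranks beyond the 10⁻³ quantile and pin
the detected departure at the 3.0 floor. Scaled-down simulations should
therefore not expect the full-scale threshold value.

**DMC ranking.** Results with q below `q_max` (default 0.4 — a
deliberately permissive systems-level screen), sorted by |difference|
descending with ties by ascending p.

## Differential expression

**TMM.** The reference sample is the one whose 75th-percentile count
fraction is closest to the mean. Per sample, M (log2 ratio) and A (mean
log2 abundance) values over genes positive in both it and the reference
are doubly trimmed (30% on M, 5% on A, rank-based) and combined by a
precision-weighted mean using delta-method variances; factors are
rescaled to geometric mean 1. This matches edgeR's calcNormFactors to
~1e−10 on shared fixtures (tested via Rscript).

**QL-NB model.** This is a deliberately compact re-implementation of the
quasi-likelihood negative-binomial approach, validated by calibration
and parameter recovery rather than numerical identity to any external
package. Genes pass a CPM > 1 in ≥ min(group sizes) samples filter.
Per-gene NB dispersion is estimated by method of moments on
depth-adjusted counts and shrunk toward the median with a prior weight
of 10 pseudo-genes: φ* = (10·φ_med + df·φ̂)/(10 + df). Gene-wise GLMs
(log link, offset log effective library, design {intercept, group}) are
fitted by IRLS vectorized across all genes. The test compares the
deviance drop of the group coefficient against a shrunken residual
quasi-dispersion, F = Δdev / s̃², with df1 = 1 and df2 = residual df +
prior df. Measured on 20,000 simulated null genes this is slightly
conservative (type-I ≈ 0.0007 at α = 0.001, ≈ 0.042 at α = 0.05) — the
usual price of moderated quasi-likelihood denominators at small n — and
recovers a planted log₂FC of 0.6 at 16 vs 18 with |bias| < 0.01.
logFC is log2, case over control; logCPM is the per-gene mean of
log2((count + 0.5)/(effective library + 1)·10⁶).

## eQTM

CpGs pair with transcripts on the same chromosome whose body expanded
by the cis window (default 100 kb) contains the probe position —
1-based coordinates, inclusive at both boundaries, so a probe exactly
100,000 bp upstream of the start is paired. Methylation enters as the
residual of beta on {intercept, PC1, PC2}; expression enters as
TMM-normalized counts on the natural scale (counts rescaled to a common
effective library), which is what gives coefficients their
characteristic large magnitudes — multiplying expression by c multiplies
coefficients by c (tested). Per pair, OLS of expression on {intercept,
beta residual, age} with a two-sided t-test (df = n − 3) on the
methylation term. Raw p-values are reported without multiplicity
adjustment by default (BH behind a flag), and the pipeline restricts
candidate pairs to top-ranked CpGs and transcripts surviving the DGE
screen, both cutoffs exposed.

## Location enrichment

For each genomic-location class, a 2×2 table compares the top-N DMCs
(default N = 100, ranked by ascending p; rank-by-|difference| behind a
flag) against the general distribution of all tested CpGs — the
background deliberately *includes* the top set, with an
exclusive-background flag. The odds ratio uses the reported cells with
a Haldane–Anscombe 0.5 correction when any cell is empty, and a Woolf
95% CI (log OR ± 1.96·√Σ1/cell). The exact p-value is computed under
the sampling model actually in force — the top set drawn without
replacement from the universe — i.e. Fisher's exact test on the
disjoint top-vs-remainder table, which equals the hypergeometric tail
sum (tested against an enumeration oracle).

## Power

RNA-seq power uses the standard normal approximation on the log scale,
sd = √((1/depth + cv²)(1/n₁ + 1/n₂)), power = Φ(|ln FC|/sd − z₁₋α/₂),
two-sided α. At depth 25, CV 0.4, α = 10⁻⁴ and *equal* group sizes
n = 16 this yields 9.2%/68.9%/97.2% for FC 1.5/2.0/2.5 — the 16/16
layout, not 16/18, is what reproduces the conventionally quoted triple,
a quirk worth knowing when comparing with single-n power tools; with
n₁ = 16, n₂ = 18 the values shift by well under a point. The
methylation side is a labelled simulation stand-in (two-group normal
betas with a mean shift, tested by the status-only EWAS regression),
not equivalent to reference-tissue bootstrap power tools: it confirms,
for example, that 12 per group with Δβ = 0.06 against realistic noise
has low power.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, at desk
scale (defaults: 5,000 CpGs, 2,000 transcripts on 4 × 5 Mb synthetic
chromosomes, library size 2×10⁵), with every stage seeded through
independent `SeedSequence` children so outputs are bit-reproducible.

* **Methylation.** Baseline probe means come from a two-component Beta
  mixture (modes ≈ 0.1 and 0.85); probes within 500 bp share a latent
  regional level (methylation is regionally correlated — this is also
  what makes probe-type normalization learnable from 50 bp neighbor
  pairs, of which a configurable fraction is planted). Per-sample
  values add logit-normal noise (sd 0.10, giving within-group beta
  noise ≈ 0.02, the scale at which reported Δβ of 0.03–0.09 attain
  genome-scale significance at n ≈ 24), logit-scale batch effects
  (default 2 sample-level batches, sd 0.15), and two admixture-like
  latent factors with per-probe loadings (sd 0.08) — independent of
  status, these are the variance the PC adjustment exists to absorb,
  and without them the planted disease axis itself becomes PC1 and the
  adjustment destroys the signal. `n_dmc` probes (default 19) get a
  case-only shift with |Δβ| uniform in (0.03, 0.09), sign split 50/50.
  Infinium II probes are distorted last by the fixed invertible map
  b′ = 0.05 + 0.85·b + 0.10·b², emulating Type II compression. Small
  seeded fractions of detection-p failures and low bead counts feed the
  QC rules.
* **Counts.** Gene abundances are log-normal; library sizes vary up to
  2× around the mean; counts are negative binomial with dispersion
  cv² = 0.16. Defaults plant 100 DEGs (5% of transcripts, matching the
  reported discovery fraction) with |log₂FC| uniform in (0.26, 1.18),
  the reported top-table range. `n_links` (default 25) cis couplings
  multiply a transcript's per-sample mean by 1 + s·(βᵢⱼ − β̄ᵢ) with
  |s| ∈ (6, 15) and negative sign for a configurable fraction (default
  one half); planted-DMC probes are preferred as anchors when in
  range, since that is where eQTM signal arises in a real study.
  Batch assignment differs from the unusual "array × random CpG subset"
  batch definition some studies describe: sample-level batches are the
  general, reconstructible case.
* **Not modeled.** Sex chromosomes, SNP-affected probes, cell-type
  mixtures (the motivating data are sorted cells), chromosome-scale
  manifests, genuine technical dye chemistry. Passing recovery tests
  here demonstrates the pipeline's statistical correctness under the
  assumed structure, not robustness to artifacts the generator omits.

## Numerical and degenerate-case choices

* All matrix regressions (EWAS, eQTM, NB-IRLS) are vectorized
  normal-equation / batched solves; EWAS p-values agree with a
  statsmodels OLS oracle to 1e−8 on small instances.
* PCs use an SVD with a deterministic sign convention (the largest-|·|
  probe loading of each component is positive).
* IRLS clamps linear predictors to ±30 and counts non-converged genes;
  those genes report NA.
* Beta outputs are clamped to [0, 1] after batch adjustment and
  probe-type normalization; clamp events during simulation are counted
  in the truth table's notes.
* Tables use "NA" for missing values; coordinates are 1-based inclusive
  internally and in TSV outputs, with BED export converting to 0-based
  half-open.
* The log-CPM scale-invariance to joint count/library doubling is
  asymptotic: the +0.5/+1 pseudo-counts do not scale, so the identity
  holds to ~1e−3 only for well-expressed genes.

## Known limitations

* The QL-NB test is intentionally simplified; it does not reproduce any
  external package's p-values, only their operating characteristics
  (calibration band, ranking power).
* The empirical P–P departure is pinned to its 3.0 floor whenever the
  signal count is large relative to the test count (see above); it is a
  genome-scale diagnostic and should be read only at genome scale.
* eQTM results are correlational; coupling direction in the generator
  is methylation → expression, and reverse causation is deliberately
  not modeled.
* Enrichment treats each probe as belonging to a single location class;
  arrays that annotate probes to several classes would need the
  universe defined per class.
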