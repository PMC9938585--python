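"""QC filtering, ComBat-style batch adjustment, probe-type normalization."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ewaskit import (
    BatchAdjuster,
    ProbeTypeNormalizer,
    SimConfig,
    apply_probe_type_normalization,
    combat_adjust,
    filter_probes,
    filter_samples,
    fit_probe_type_polynomial,
    simulate_annotation,
    simulate_methylation,
)
from ewaskit.preprocess import ProbeTypeFit


def _beta(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=probes, columns=samples)


# --- sample filtering -------------------------------------------------------

def test_sample_with_all_failed_detections_is_removed():
    beta = _beta(np.full((10, 3), 0.5))
    detp = _beta(np.full((10, 3), 0.001))
    detp.iloc[:, 1] = 0.5
    kept, report = filter_samples(beta, detp)
    assert list(kept.columns) == ["s0", "s2"]
    assert report.samples_removed[0][0] == "s1"


def test_sample_at_95_percent_success_passes_default_threshold():
    detp = _beta(np.full((100, 2), 0.001))
    detp.iloc[:5, 0] = 0.5            # 95% success in s0
    kept, _ = filter_samples(_beta(np.full((100, 2), 0.5)), detp, min_success_ratio=0.9)
    assert "s0" in kept.columns


def test_literal_published_threshold_keeps_15_percent_success():
    detp = _beta(np.full((100, 2), 0.001))
    detp.iloc[:85, 0] = 0.5           # 15% success in s0
    kept, _ = filter_samples(_beta(np.full((100, 2), 0.5)), detp, min_success_ratio=0.1)
    assert "s0" in kept.columns
    kept, _ = filter_samples(_beta(np.full((100, 2), 0.5)), detp, min_success_ratio=0.9)
    assert "s0" not in kept.columns


def test_all_samples_failing_is_a_hard_error():
    with pytest.raises(ValueError):
        filter_samples(_beta(np.full((5, 2), 0.5)), _beta(np.full((5, 2), 0.9)))


# --- probe filtering --------------------------------------------------------

def test_bead_count_rule_fires_at_exactly_five_percent():
    beta = _beta(np.full((2, 20), 0.5))
    detp = _beta(np.full((2, 20), 0.001))
    beads = _beta(np.full((2, 20), 10))
    beads.iloc[0, 0] = 2              # 1/20 samples = 5% -> removed
    kept, report = filter_probes(beta, detp, beads)
    assert "p0" not in kept.index and "p1" in kept.index
    assert report.probes_removed["bead_count"] == 1


def test_detection_p_rule_is_strictly_greater_than():
    beta = _beta(np.full((1, 4), 0.5))
    detp = _beta(np.full((1, 4), 0.01))  # exactly at the boundary
    beads = _beta(np.full((1, 4), 10))
    kept, _ = filter_probes(beta, detp, beads)
    assert len(kept) == 1


def test_probe_filters_match_one_rule_at_a_time_oracle(rng):
    n, m = 1000, 20
    beta = _beta(rng.uniform(0, 1, (n, m)))
    detp = _beta(np.where(rng.random((n, m)) < 0.01, 0.5, 0.001))
    beads = _beta(np.where(rng.random((n, m)) < 0.01, 2, 10))
    ids = beta.index.to_numpy()
    blocklists = {
        "non_cpg": set(rng.choice(ids, 30, replace=False)),
        "multi_mapping": set(rng.choice(ids, 30, replace=False)),
        "smoking": set(rng.choice(ids, 30, replace=False)),
    }
    kept, report = filter_probes(beta, detp, beads, blocklists=blocklists)

    # independent one-rule-at-a-time oracle
    expected = []
    for i, pid in enumerate(ids):
        if (detp.iloc[i] > 0.01).any():
            continue
        if pid in blocklists["non_cpg"] or pid in blocklists["multi_mapping"]:
            continue
        if (beads.iloc[i] < 3).mean() >= 0.05:
            continue
        if pid in blocklists["smoking"]:
            continue
        expected.append(pid)
    assert list(kept.index) == expected
    assert report.probes_retained + report.total_removed() == n


def test_unknown_blocklist_ids_warn_but_do_not_fail():
    beta = _beta(np.full((3, 4), 0.5))
    detp = _beta(np.full((3, 4), 0.001))
    beads = _beta(np.full((3, 4), 10))
    with pytest.warns(UserWarning, match="blocklist"):
        kept, _ = filter_probes(beta, detp, beads, blocklists={"smoking": {"cg_missing"}})
    assert len(kept) == 3


# --- batch adjustment -------------------------------------------------------

def test_single_batch_is_an_exact_identity(rng):
    beta = _beta(rng.uniform(0.05, 0.95, (50, 8)))
    out = combat_adjust(beta, ["A"] * 8)
    assert np.max(np.abs(out.to_numpy() - beta.to_numpy())) < 1e-10


def test_batch_of_one_sample_is_rejected(rng):
    beta = _beta(rng.uniform(0, 1, (10, 5)))
    with pytest.raises(ValueError, match="< 2 samples"):
        combat_adjust(beta, ["A", "A", "A", "A", "B"])


def test_planted_additive_batch_shift_is_removed(rng):
    # per-sample noise low enough that the batch-mean sampling noise
    # (sd*sqrt(2/n) ~ 0.0016) sits below the 0.005 recovery bound
    base = rng.uniform(0.2, 0.7, (800, 1)) + rng.normal(0, 0.005, (800, 40))
    shifted = base.copy()
    shifted[:, 20:] += 0.05
    out = combat_adjust(_beta(shifted), ["A"] * 20 + ["B"] * 20, clip=False).to_numpy()
    gap = np.abs(out[:, :20].mean(1) - out[:, 20:].mean(1))
    assert (gap < 0.005).mean() >= 0.99


def test_adjustment_is_nearly_idempotent_on_simulated_batches():
    """A second pass moves values by far less than the planted batch effect.

    Exact idempotency is impossible with empirical-Bayes shrinkage: the
    shrunk location estimates leave residual batch differences of order
    (1 - shrinkage factor) times the batch effect, which a second pass
    partially removes again.
    """
    config = SimConfig(seed=3, n_cpgs=1500, n_transcripts=300, n_dmc=0,
                       n_deg=0, n_links=0)
    probes, _ = simulate_annotation(config)
    beta, _, _, sheet, _ = simulate_methylation(config, probes)
    batches = sheet["batch"].to_numpy()
    once = combat_adjust(beta, batches)
    twice = combat_adjust(once, batches)
    second_pass = np.max(np.abs(twice.to_numpy() - once.to_numpy()))
    planted = np.max(np.abs(beta.to_numpy() - once.to_numpy()))
    assert second_pass < 0.02
    assert second_pass < 0.2 * planted


def test_batch_adjustment_reduces_between_batch_variance():
    config = SimConfig(seed=5, n_cpgs=1000, n_transcripts=200, n_dmc=0,
                       n_deg=0, n_links=0, batch_sd_logit=0.3)
    probes, _ = simulate_annotation(config)
    beta, _, _, sheet, _ = simulate_methylation(config, probes)
    batches = sheet["batch"].to_numpy()
    adjusted = combat_adjust(beta, batches)

    def median_f(mat):
        groups = [mat[:, batches == b] for b in np.unique(batches)]
        f, _ = stats.f_oneway(*groups, axis=1)
        return np.median(f)

    assert median_f(adjusted.to_numpy()) < median_f(beta.to_numpy())


def test_matches_reference_bioconductor_combat(rng, tmp_path):
    """Dual route: the same small matrix through sva::ComBat."""
    X = np.clip(rng.normal(0.5, 0.12, (60, 12))
                + np.r_[np.zeros(6), 0.06 * np.ones(6)][None, :], 0.01, 0.99)
    beta = _beta(X)
    batch = ["A"] * 6 + ["B"] * 6
    beta.to_csv(tmp_path / "in.tsv", sep="\t")
    (tmp_path / "batch.txt").write_text("\n".join(batch) + "\n")
    (tmp_path / "combat.R").write_text(
        'suppressMessages(library(sva))\n'
        'x <- as.matrix(read.table("in.tsv", sep="\\t", header=TRUE, row.names=1))\n'
        'batch <- readLines("batch.txt")\n'
        'out <- ComBat(dat=x, batch=batch, par.prior=TRUE, prior.plots=FALSE)\n'
        'write.table(out, "ref.tsv", sep="\\t", quote=FALSE)\n'
    )
    subprocess.run(["Rscript", "combat.R"], cwd=tmp_path, check=True,
                   capture_output=True)
    ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)
    mine = combat_adjust(beta, batch, clip=False)
    assert np.max(np.abs(mine.to_numpy() - ref.to_numpy())) < 1e-3


# --- probe-type normalization ----------------------------------------------

def _paired_annotation(n_pairs, spacing=1000):
    rows = []
    for i in range(n_pairs):
        rows.append((f"one{i}", "chr1", i * spacing + 10, "I"))
        rows.append((f"two{i}", "chr1", i * spacing + 30, "II"))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "design_type"])


def test_identical_pairs_fit_the_identity_map(rng):
    ann = _paired_annotation(20)
    means = rng.uniform(0.1, 0.9, 20)
    values = np.repeat(means, 2)[:, None] * np.ones((1, 4))
    beta = pd.DataFrame(values, index=ann["probe_id"], columns=list("abcd"))
    fit = fit_probe_type_polynomial(beta, ann)
    assert fit.n_pairs == 20
    assert np.allclose([fit.c0, fit.c1, fit.c2], [0.0, 1.0, 0.0], atol=1e-6)


def test_linear_distortion_is_inverted_exactly(rng):
    ann = _paired_annotation(30)
    true = rng.uniform(0.1, 0.9, 30)
    distorted = 0.05 + 0.85 * true
    values = np.empty((60, 3))
    values[0::2] = true[:, None]
    values[1::2] = distorted[:, None]
    beta = pd.DataFrame(values, index=ann["probe_id"], columns=list("xyz"))
    fit = fit_probe_type_polynomial(beta, ann)
    recovered = fit(distorted)
    assert np.max(np.abs(recovered - true)) < 1e-3


def test_normalization_shrinks_type_gap_on_simulator_output():
    config = SimConfig(seed=7, n_cpgs=4000, n_transcripts=500, n_dmc=0,
                       n_deg=0, n_links=0, n_batches=1, frac_probe_pairs=0.08)
    probes, _ = simulate_annotation(config)
    beta, *_ = simulate_methylation(config, probes)
    norm = ProbeTypeNormalizer().fit(beta, probes)
    normalized = norm.transform(beta, probes)
    means = beta.mean(axis=1)
    means_post = normalized.mean(axis=1)
    gap_pre = np.mean([abs(means[a] - means[b]) for a, b in norm.pairs_])
    gap_post = np.mean([abs(means_post[a] - means_post[b]) for a, b in norm.pairs_])
    assert gap_post < gap_pre


def test_too_few_pairs_is_an_error(rng):
    ann = _paired_annotation(2)
    beta = pd.DataFrame(rng.uniform(0, 1, (4, 3)), index=ann["probe_id"],
                        columns=list("abc"))
    with pytest.raises(ValueError, match="pairs"):
        fit_probe_type_polynomial(beta, ann)


@pytest.mark.parametrize("fit,b,expected", [
    (ProbeTypeFit(0.0, 1.0, 0.0, 5), 0.37, 0.37),          # identity map
    (ProbeTypeFit(0.1, 0.8, 0.1, 5), 0.5, 0.525),          # hand arithmetic
    (ProbeTypeFit(0.2, 1.0, 0.0, 5), 1.0, 1.0),            # clamped at 1
])
def test_polynomial_application_values(fit, b, expected):
    ann = pd.DataFrame({"probe_id": ["p0"], "chrom": ["chr1"], "pos": [10],
                        "design_type": ["II"]})
    beta = pd.DataFrame([[b]], index=["p0"], columns=["s0"])
    out = apply_probe_type_normalization(beta, ann, fit)
    assert out.iloc[0, 0] == pytest.approx(expected, abs=1e-12)


def test_type_one_probes_are_untouched():
    ann = pd.DataFrame({"probe_id": ["p0", "p1"], "chrom": ["chr1"] * 2,
                        "pos": [10, 500], "design_type": ["I", "II"]})
    beta = pd.DataFrame([[0.4], [0.4]], index=["p0", "p1"], columns=["s0"])
    out = apply_probe_type_normalization(beta, ann, ProbeTypeFit(0.1, 0.8, 0.1, 5))
    assert out.loc["p0", "s0"] == 0.4
    assert out.loc["p1", "s0"] == pytest.approx(0.436)
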