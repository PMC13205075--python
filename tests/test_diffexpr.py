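"""Differential-expression statistics: size factors, dispersion, Wald test,
classification, BH, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from cernascreen import diffexpr, synthetic
from cernascreen.errors import ConsistencyError, FormatError
from cernascreen.types import DERecord, ExpressionMatrix, SimulationConfig

from conftest import SMALL_SIM


def _matrix(counts: dict, groups: list[str], cls: str = "mRNA") -> ExpressionMatrix:
    df = pd.DataFrame(counts)
    return ExpressionMatrix(
        counts=df,
        rna_class=pd.Series([cls] * len(df), index=df.index),
        group=pd.Series(groups, index=df.columns),
    )


# ---------------------------------------------------------------------------
# size factors


def test_size_factors_proportional_samples():
    m = _matrix({"a": [10, 20, 30], "b": [20, 40, 60]}, ["control", "cold"])
    f = diffexpr.size_factors(m)
    assert f["a"] == pytest.approx(1 / np.sqrt(2))
    assert f["b"] == pytest.approx(np.sqrt(2))


def test_size_factors_identical_samples_are_one():
    m = _matrix({"a": [5, 7, 9], "b": [5, 7, 9], "c": [5, 7, 9]},
                ["control", "control", "cold"])
    assert np.allclose(diffexpr.size_factors(m), 1.0)


def test_size_factors_match_direct_formula(small_experiment):
    matrix, *_ = small_experiment
    f = diffexpr.size_factors(matrix)
    # brute-force median-of-ratios straight from the definition
    counts = matrix.counts.to_numpy(dtype=float)
    eligible = counts[(counts > 0).all(axis=1)]
    geomean = np.exp(np.mean(np.log(eligible), axis=1))
    raw = np.median(eligible / geomean[:, None], axis=0)
    expected = raw / np.exp(np.mean(np.log(raw)))
    assert np.allclose(f.to_numpy(), expected)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


def test_size_factors_error_without_reference():
    m = _matrix({"a": [0, 3], "b": [4, 0]}, ["control", "cold"])
    with pytest.raises(FormatError, match="pseudo-reference"):
        diffexpr.size_factors(m)


# ---------------------------------------------------------------------------
# dispersion


def test_dispersion_poisson_like_floors_at_zero():
    # within-group variance equal to the mean -> alpha floored
    m = _matrix(
        {"c1": [8], "c2": [12], "h1": [8], "h2": [12]},
        ["control", "control", "cold", "cold"],
    )
    # identical columns sums? size factors: single feature excluded... use 2 features
    m = _matrix(
        {"c1": [8, 100], "c2": [12, 100], "h1": [8, 100], "h2": [12, 100]},
        ["control", "control", "cold", "cold"],
    )
    f = pd.Series(1.0, index=m.counts.columns)
    alpha = diffexpr.estimate_dispersion(m, f)
    # feature 0: m=10, pooled s2=8 -> (8-10)/100 < 0 -> floored
    assert alpha.iloc[0] == pytest.approx(1e-8)


def test_dispersion_method_of_moments_arithmetic():
    m = _matrix(
        {"c1": [4, 100], "c2": [16, 100], "h1": [4, 100], "h2": [16, 100]},
        ["control", "control", "cold", "cold"],
    )
    f = pd.Series(1.0, index=m.counts.columns)
    alpha = diffexpr.estimate_dispersion(m, f)
    # grand mean 10, pooled within-group variance (72+72)/2 = 72
    assert alpha.iloc[0] == pytest.approx((72 - 10) / 100)


def test_dispersion_all_zero_feature_flagged_nan():
    m = _matrix(
        {"c1": [0, 10], "c2": [0, 12], "h1": [0, 9], "h2": [0, 11]},
        ["control", "control", "cold", "cold"],
    )
    f = pd.Series(1.0, index=m.counts.columns)
    alpha = diffexpr.estimate_dispersion(m, f)
    assert np.isnan(alpha.iloc[0])
    records = diffexpr.nb_wald_test(m, f, alpha)
    assert [r.feature_id for r in records] == [m.feature_ids[1]]


def test_moderate_dispersion_pulls_toward_common():
    alpha = pd.Series([0.0, 0.2, np.nan])
    out = diffexpr.moderate_dispersion(alpha, residual_df=4, prior_df=4)
    assert out.iloc[0] == pytest.approx(0.05)  # (4*0 + 4*0.1)/8
    assert out.iloc[1] == pytest.approx(0.15)
    assert np.isnan(out.iloc[2])


# ---------------------------------------------------------------------------
# Wald test


def test_wald_identical_group_means_null():
    m = _matrix(
        {"c1": [10, 50], "c2": [20, 70], "h1": [10, 50], "h2": [20, 70]},
        ["control", "control", "cold", "cold"],
    )
    f = pd.Series(1.0, index=m.counts.columns)
    alpha = pd.Series(0.1, index=m.counts.index)
    records = diffexpr.nb_wald_test(m, f, alpha)
    for r in records:
        assert r.log10_fc == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)


def test_wald_label_swap_antisymmetry(small_experiment):
    matrix, *_ = small_experiment
    f = diffexpr.size_factors(matrix)
    alpha = diffexpr.estimate_dispersion(matrix, f)
    fwd = diffexpr.nb_wald_test(matrix, f, alpha)
    swapped = ExpressionMatrix(
        counts=matrix.counts,
        rna_class=matrix.rna_class,
        group=matrix.group.map({"cold": "control", "control": "cold"}),
    )
    rev = diffexpr.nb_wald_test(swapped, f, alpha)
    for a, b in zip(fwd, rev):
        assert a.log10_fc == pytest.approx(-b.log10_fc)
        assert a.p == pytest.approx(b.p)


def test_wald_invariant_to_sample_rescaling(small_experiment):
    """Doubling one sample's counts changes (almost) nothing once size
    factors are recomputed. Under the geometric-mean-1 convention all
    normalized counts pick up a common factor 2^(1/n_samples), so the
    invariance is exact up to the pseudocount's influence."""
    matrix, *_ = small_experiment
    scaled_counts = matrix.counts.copy()
    scaled_counts.iloc[:, 0] = scaled_counts.iloc[:, 0] * 2
    scaled = ExpressionMatrix(
        counts=scaled_counts, rna_class=matrix.rna_class, group=matrix.group
    )
    f0, f1 = diffexpr.size_factors(matrix), diffexpr.size_factors(scaled)
    a0 = diffexpr.estimate_dispersion(matrix, f0)
    a1 = diffexpr.estimate_dispersion(scaled, f1)
    # exact: normalized counts scale by the common factor 2^(1/6)
    n0 = diffexpr.normalized_counts(matrix, f0)
    n1 = diffexpr.normalized_counts(scaled, f1)
    assert np.allclose(n1, n0 * 2 ** (1 / 6))
    r0 = diffexpr.nb_wald_test(matrix, f0, a0)
    r1 = diffexpr.nb_wald_test(scaled, f1, a1)
    # where counts dominate the pseudocount the test statistics are stable
    group_min = np.minimum(
        n0[matrix.samples_in_group("cold")].mean(axis=1),
        n0[matrix.samples_in_group("control")].mean(axis=1),
    )
    checked = 0
    for a, b in zip(r0, r1):
        if group_min.loc[a.feature_id] < 20:
            continue
        checked += 1
        assert a.log10_fc == pytest.approx(b.log10_fc, abs=5e-3)
        assert np.isclose(a.p, b.p, rtol=0.1, atol=1e-4) or (a.p < 1e-6 and b.p < 1e-6)
    assert checked > 50


# ---------------------------------------------------------------------------
# classification


def _record(cls, lfc, p):
    return DERecord(feature_id="x", rna_class=cls, base_mean=1.0,
                    log10_fc=lfc, se_log=1.0, p=p)


@pytest.mark.parametrize(
    "cls,lfc,p,expected",
    [
        ("mRNA", 0.68, 0.01, "up"),       # FOXO1-magnitude fold change
        ("mRNA", -0.77, 0.01, "down"),    # PPAR-gamma-magnitude fold change
        ("miRNA", 0.9, 0.03, "ns"),       # miRNA cutoff is 0.01, not 0.05
        ("mRNA", 0.6, 0.04, "up"),        # boundary |log10 FC| = 0.6 inclusive
        ("mRNA", -0.6, 0.04, "down"),
        ("mRNA", 0.59, 0.001, "ns"),      # below the fold-change bound
        ("mRNA", 2.0, 0.05, "ns"),        # p must be strictly below the cutoff
        ("circRNA", 1.0, 0.005, "up"),
        ("lncRNA", -1.0, 0.04, "down"),
    ],
)
def test_classification_thresholds(cls, lfc, p, expected):
    [r] = diffexpr.classify_features([_record(cls, lfc, p)])
    assert r.status == expected


def test_classification_unknown_class_rejected():
    with pytest.raises(FormatError, match="cutoff"):
        diffexpr.classify_features([_record("tRNA", 1.0, 0.001)])


# ---------------------------------------------------------------------------
# BH


def test_bh_step_up_hand_computed():
    assert np.allclose(diffexpr.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert diffexpr.bh_adjust([0.2])[0] == pytest.approx(0.2)


def test_bh_matches_statsmodels():
    rng = np.random.default_rng(0)
    for _ in range(5):
        p = rng.uniform(1e-6, 1.0, size=40)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(diffexpr.bh_adjust(p), expected)


@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
def test_bh_dominates_raw_and_preserves_ranks(p):
    adj = diffexpr.bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_rejects_out_of_range():
    for bad in ([0.0, 0.5], [0.5, 1.5]):
        with pytest.raises(FormatError):
            diffexpr.bh_adjust(bad)


# ---------------------------------------------------------------------------
# PCA


def test_pca_variance_fractions_sum_to_one(small_experiment):
    matrix, *_ = small_experiment
    f = diffexpr.size_factors(matrix)
    _, var_frac = diffexpr.pca(matrix, f)
    assert np.sum(var_frac) == pytest.approx(1.0, abs=1e-9)


def test_pca_duplicated_samples_identical_scores():
    m = _matrix(
        {"c1": [10, 50, 3], "c2": [10, 50, 3], "h1": [30, 20, 9], "h2": [28, 22, 10]},
        ["control", "control", "cold", "cold"],
    )
    f = pd.Series(1.0, index=m.counts.columns)
    scores, _ = diffexpr.pca(m, f)
    assert np.allclose(scores.loc["c1"], scores.loc["c2"])


def test_pca_separates_planted_groups(small_experiment):
    matrix, *_ = small_experiment
    f = diffexpr.size_factors(matrix)
    scores, _ = diffexpr.pca(matrix, f)
    pc1 = scores["PC1"]
    cold = pc1[matrix.samples_in_group("cold")]
    control = pc1[matrix.samples_in_group("control")]
    assert cold.min() > control.max() or control.min() > cold.max()


def test_pca_constant_matrix_rejected():
    m = _matrix(
        {"c1": [5, 5], "c2": [5, 5], "h1": [5, 5]},
        ["control", "control", "cold"],
    )
    f = pd.Series(1.0, index=m.counts.columns)
    with pytest.raises(FormatError, match="constant"):
        diffexpr.pca(m, f)


def test_pca_needs_three_samples():
    m = _matrix({"c1": [5, 1], "h1": [9, 2]}, ["control", "cold"])
    with pytest.raises(ConsistencyError, match=">= 3"):
        diffexpr.pca(m, pd.Series(1.0, index=m.counts.columns))


# ---------------------------------------------------------------------------
# type-I calibration (reduced-size null; the acceptance test runs the full one)


def test_null_type_one_rate_reasonable():
    cfg = SimulationConfig(
        n_mrna=5000, n_lncrna=0, n_mirna=0, n_circrna=0,
        n_de_per_class={"mRNA": 0, "lncRNA": 0, "miRNA": 0, "circRNA": 0},
        n_triads=0, dispersion=0.1, seed=21,
    )
    matrix, *_ = synthetic.simulate_experiment(cfg, with_sequences=False, with_terms=False)
    f = diffexpr.size_factors(matrix)
    alpha = diffexpr.estimate_dispersion(matrix, f)
    alpha = diffexpr.moderate_dispersion(alpha, diffexpr.pooled_residual_df(matrix))
    p = np.array([r.p for r in diffexpr.nb_wald_test(matrix, f, alpha)])
    assert 0.02 <= (p < 0.05).mean() <= 0.09
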