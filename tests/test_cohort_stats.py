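import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dysphonia.cohort_stats import (
    cohens_d,
    cohens_d_from_summary,
    compare_groups,
    correlate,
    disease_burden,
    group_report,
    normality_gate,
)


def test_normality_gate_accepts_gaussian_samples():
    ok = 0
    for seed in range(20):
        x = np.random.default_rng(seed).normal(0, 1, 100)
        ok += normality_gate(x) == "normal"
    assert ok >= 18


def test_normality_gate_rejects_zero_inflated_counts():
    rng = np.random.default_rng(1)
    x = np.where(rng.uniform(size=56) < 0.85, 0.0, rng.poisson(4, 56).astype(float))
    assert normality_gate(x) == "non_normal"


def test_normality_gate_constant_sample_no_crash():
    assert normality_gate(np.zeros(10)) == "non_normal"


def test_normality_gate_needs_five():
    with pytest.raises(ValueError):
        normality_gate(np.array([1.0, 2.0]))


def test_identical_groups_large_p_zero_d(rng):
    x = rng.normal(0, 1, 28)
    row = compare_groups(x, x.copy())
    assert row.p_value > 0.5
    assert row.cohens_d == 0.0


def test_separated_groups_significant():
    sig = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        row = compare_groups(r.normal(0, 1, 28), r.normal(2, 1, 28))
        sig += row.p_value < 0.001
    assert sig >= 9


def test_skewed_data_routed_to_mann_whitney(rng):
    a = rng.exponential(1.0, 40) ** 3
    b = rng.exponential(1.5, 40) ** 3
    assert compare_groups(a, b).test == "mann_whitney"


def test_cohens_d_equal_means_zero():
    assert cohens_d(1.0, 1.0, 10, 1.0, 2.0, 10) == 0.0


def test_cohens_d_undefined_for_two_constants():
    with pytest.raises(ValueError):
        cohens_d(1.0, 0.0, 10, 2.0, 0.0, 10)


@given(
    m1=st.floats(-5, 5), m2=st.floats(-5, 5),
    s1=st.floats(0.1, 3), s2=st.floats(0.1, 3),
)
def test_cohens_d_antisymmetric_and_scale_invariant(m1, m2, s1, s2):
    d = cohens_d(m1, s1, 12, m2, s2, 15)
    assert cohens_d(m2, s2, 15, m1, s1, 12) == pytest.approx(-d, rel=1e-9, abs=1e-12)
    c = 3.7
    assert cohens_d(c * m1, c * s1, 12, c * m2, c * s2, 15) == pytest.approx(
        d, rel=1e-9, abs=1e-12
    )


def test_correlate_identity_is_one(rng):
    x = rng.normal(0, 1, 30)
    r, p, _ = correlate(x, x)
    assert r == pytest.approx(1.0)


def test_correlate_independent_small(rng):
    hits = 0
    for seed in range(20):
        r_ = np.random.default_rng(seed)
        r, _, _ = correlate(r_.normal(0, 1, 28), r_.normal(0, 1, 28))
        hits += abs(r) < 0.4
    assert hits >= 18


def test_correlate_monotone_nonlinear_spearman_one(rng):
    x = rng.exponential(1.0, 30) ** 2  # skewed -> gated to Spearman
    y = np.log1p(x) ** 3
    r, _, method = correlate(x, y)
    assert method == "spearman"
    assert r == pytest.approx(1.0)


def test_correlate_zero_variance_undefined():
    with pytest.raises(ValueError):
        correlate(np.ones(10), np.arange(10.0))


def test_disease_burden_values():
    assert disease_burden(40.0, 35.5) == 0.0
    assert disease_burden(40.0, 42.0) == pytest.approx(260.0)


@given(age=st.floats(20, 60), cag=st.floats(36, 50), dcag=st.floats(0.1, 3))
def test_disease_burden_monotone_in_cag(age, cag, dcag):
    assert disease_burden(age, cag + dcag) > disease_burden(age, cag)


def test_group_report_has_row_per_measure():
    from dysphonia.synth import sample_feature_table
    from dysphonia.wald import MEASURES

    params_a = {m: (0.0, 1.0) for m in MEASURES}
    params_b = {m: (0.5, 1.0) for m in MEASURES}
    tab = sample_feature_table({"a": params_a, "b": params_b}, n_per_group=15, seed=3)
    report = group_report(tab, tab["group"], "b", "a")
    assert set(report["measure"]) == set(MEASURES)
    assert {"test", "p", "cohens_d", "bonferroni_k", "significant"} <= set(report.columns)
    # Bonferroni divisor equals the number of measures in the dimension
    assert (report.loc[report.measure == "NVB", "bonferroni_k"] == 3).all()
    assert (report.loc[report.measure == "HNR", "bonferroni_k"] == 2).all()


def test_equal_n_pooled_sd_reduces_to_rms():
    m1, s1, m2, s2, n = 3.0, 1.2, 1.0, 0.8, 28
    d = cohens_d(m1, s1, n, m2, s2, n)
    assert d == pytest.approx((m1 - m2) / np.sqrt((s1**2 + s2**2) / 2))


def test_printed_summary_effect_sizes_reproduced():
    """The five effect sizes recomputable from printed cohort summaries."""
    cases = {
        "HNR": ((19.0, 4.1, 28), (22.3, 4.0, 28), -0.81),
        "NVB": ((1.11, 2.04, 28), (0.04, 0.19, 28), 0.74),
        "Shimmer": ((3.69, 1.25, 28), (3.18, 1.42, 28), 0.38),
        "FOVB": ((12.4, 6.8, 28), (13.9, 4.4, 28), -0.26),
        "ATRI": ((4.60, 3.39, 28), (4.74, 2.27, 28), -0.05),
    }
    for name, (g1, g2, expected) in cases.items():
        assert cohens_d_from_summary(g1, g2) == pytest.approx(expected, abs=0.005), name
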