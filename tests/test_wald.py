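import numpy as np
import pandas as pd
import pytest

from dysphonia.synth import sample_feature_table
from dysphonia.wald import (
    DIMENSIONS,
    MEASURES,
    affected_summary,
    classify_subject,
    classify_table,
    fit_dimension_model,
)


def _gaussian_table(n=20, seed=0, shift=None):
    """Control at baseline, patient shifted on the given measures."""
    shift = shift or {}
    control = {m: (0.0, 1.0) for m in MEASURES}
    patient = {m: (shift.get(m, 0.0), 1.0) for m in MEASURES}
    return sample_feature_table(
        {"control": control, "patient": patient}, n_per_group=n, seed=seed
    )


def test_fitted_means_close_to_truth():
    tab = _gaussian_table(n=20, seed=1, shift={"DPB": 5.0})
    model = fit_dimension_model(tab, tab["group"])
    g = model.per_measure["DPB"]
    assert g.control_mean == pytest.approx(0.0, abs=0.5)
    assert g.patient_mean == pytest.approx(5.0, abs=0.5)
    assert g.orientation == 1


def test_identical_groups_measure_excluded():
    tab = _gaussian_table(n=10, seed=2)
    tab["MPT"] = 1.0  # identical constant in both groups
    model = fit_dimension_model(tab, tab["group"])
    assert model.per_measure["MPT"].orientation == 0
    assert "MPT" not in model.usable_measures()


def test_constant_control_feature_gets_sd_floor():
    tab = _gaussian_table(n=10, seed=3, shift={"DVA": 2.0})
    tab.loc[tab.group == "control", "DVA"] = 0.0
    model = fit_dimension_model(tab, tab["group"])
    assert model.per_measure["DVA"].control_sd > 0
    profile = classify_subject(model, {m: 0.0 for m in MEASURES})
    assert isinstance(profile.n_affected, int)


def test_subject_at_control_mean_unaffected():
    tab = _gaussian_table(n=30, seed=4, shift={m: 3.0 for m in MEASURES})
    model = fit_dimension_model(tab, tab["group"])
    profile = classify_subject(model, {m: 0.0 for m in MEASURES})
    assert profile.n_affected == 0


def test_single_shifted_measure_flags_its_dimension_only():
    tab = _gaussian_table(n=30, seed=5, shift={m: 3.0 for m in MEASURES})
    model = fit_dimension_model(tab, tab["group"])
    features = {m: 0.0 for m in MEASURES}
    features["DPB"] = 5.0  # far on the pathological side
    profile = classify_subject(model, features)
    assert profile.affected["aperiodicity"]
    assert profile.n_affected == 1


def _exact_moment_table(shift):
    """Groups whose sample means/SDs are exact (symmetric +-1 pattern)."""
    base = np.array([-1.0, 1.0] * 25)
    rows = []
    for i, v in enumerate(base):
        rows.append({"subject": f"c{i}", "group": "control", "HNR": v})
    for i, v in enumerate(base):
        rows.append({"subject": f"p{i}", "group": "patient", "HNR": shift + v})
    return pd.DataFrame(rows)


DIM_HNR = {"increased_noise": ("HNR",)}


def test_equal_variance_boundary_is_midpoint():
    tab = _exact_moment_table(shift=4.0)
    model = fit_dimension_model(tab, tab["group"], dim_map=DIM_HNR)
    g = model.per_measure["HNR"]
    mid = 0.5 * (g.control_mean + g.patient_mean)
    assert mid == pytest.approx(2.0)
    assert not classify_subject(model, {"HNR": mid - 0.02}).affected["increased_noise"]
    assert classify_subject(model, {"HNR": mid + 0.02}).affected["increased_noise"]


def test_one_sided_guard_protects_exceptionally_good_values():
    tab = _exact_moment_table(shift=-3.0)  # patients lower
    model = fit_dimension_model(tab, tab["group"], dim_map=DIM_HNR)
    # exceptionally *high* HNR lies on the healthy side and is never flagged
    assert not classify_subject(model, {"HNR": +6.0}).affected["increased_noise"]


def test_missing_measure_abstains():
    tab = _gaussian_table(n=20, seed=8, shift={m: 3.0 for m in MEASURES})
    model = fit_dimension_model(tab, tab["group"])
    features = {m: 0.0 for m in MEASURES}
    del features["MPT"]
    features["FOVB"] = np.nan
    profile = classify_subject(model, features)
    assert profile.affected["airflow_insufficiency"] is False


def test_summary_percentages_and_histogram():
    tab = _gaussian_table(n=20, seed=9, shift={m: 3.0 for m in MEASURES})
    model = fit_dimension_model(tab, tab["group"])
    profiles = classify_table(model, tab)
    labels = dict(zip(tab["subject"], tab["group"]))
    summary = affected_summary(profiles, labels)
    pct = summary["percent_affected"]
    assert ((pct >= 0) & (pct <= 100)).all().all()
    hist = summary["n_affected_hist"]
    assert hist["control"].sum() == 20
    assert hist["patient"].sum() == 20


def test_all_unaffected_gives_zero_percent():
    tab = _gaussian_table(n=10, seed=10, shift={m: 3.0 for m in MEASURES})
    model = fit_dimension_model(tab, tab["group"])
    profiles = [
        classify_subject(model, {m: 0.0 for m in MEASURES}, subject=f"s{i}")
        for i in range(5)
    ]
    summary = affected_summary(profiles)
    assert (summary["percent_affected"] == 0).all().all()


def test_three_sd_shift_discriminates_groups():
    """One dimension shifted by 3 SD: >=80 % of patients and <=20 % of
    controls flagged on that dimension, over 10 seeds at n=20."""
    hits_p, hits_c = [], []
    for seed in range(10):
        tab = _gaussian_table(n=20, seed=100 + seed, shift={"NVB": 3.0, "DPB": 3.0, "DVA": 3.0})
        model = fit_dimension_model(tab, tab["group"])
        profiles = classify_table(model, tab)
        flags = {p.subject: p.affected["aperiodicity"] for p in profiles}
        groups = dict(zip(tab["subject"], tab["group"]))
        p = np.mean([f for s, f in flags.items() if groups[s] == "patient"])
        c = np.mean([f for s, f in flags.items() if groups[s] == "control"])
        hits_p.append(p)
        hits_c.append(c)
    assert np.mean(hits_p) >= 0.8
    assert np.mean(hits_c) <= 0.2


def test_group_missing_raises():
    tab = _gaussian_table(n=10, seed=11)
    with pytest.raises(ValueError):
        fit_dimension_model(tab, np.array(["control"] * len(tab)))
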