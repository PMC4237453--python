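import numpy as np
import pytest

from dysphonia.synth import (
    BreakEvent,
    CohortSpec,
    ParamDist,
    SynthSpec,
    sample_feature_table,
    synth_cohort,
    synth_vowel,
)

FS = 44100.0


def test_overlapping_events_rejected():
    with pytest.raises(ValueError, match="overlap"):
        SynthSpec(
            break_events=(
                BreakEvent("vocal_arrest", 1.0, 0.5),
                BreakEvent("pitch_drop", 1.2, 0.3),
            )
        )


def test_event_outside_duration_rejected():
    with pytest.raises(ValueError):
        SynthSpec(duration_s=2.0, break_events=(BreakEvent("vocal_arrest", 1.9, 0.5),))


def test_unperturbed_source_has_constant_cycle_lengths():
    spec = SynthSpec(
        duration_s=1.0, jitter_pct=0.0, shimmer_pct=0.0, hnr_db=60.0,
        f0_wander_st=0.0,
    )
    _, truth = synth_vowel(spec, FS, seed=0)
    assert np.ptp(truth.periods) < 1.0 / FS


def test_arrest_zeroes_harmonic_component():
    spec = SynthSpec(
        duration_s=4.0, break_events=(BreakEvent("vocal_arrest", 2.0, 0.2),)
    )
    _, truth = synth_vowel(spec, FS, seed=1)
    # skip the resonator ring-out after the event onset (~100 ms at the
    # narrowest default bandwidth), then the source is exactly zero
    a, b = int(2.10 * FS), int(2.19 * FS)
    assert np.sqrt(np.mean(truth.harmonic[a:b] ** 2)) < 1e-3 * np.sqrt(
        np.mean(truth.harmonic**2)
    )


def test_hnr_calibration_matches_component_powers():
    """Oracle: compare harmonic and noise powers stored separately."""
    for target in (12.0, 20.0, 28.0):
        spec = SynthSpec(duration_s=2.0, hnr_db=target)
        _, truth = synth_vowel(spec, FS, seed=2)
        assert truth.achieved_hnr_db == pytest.approx(target, abs=0.1)


def test_determinism_bit_identical():
    spec = SynthSpec(duration_s=1.5)
    rec1, _ = synth_vowel(spec, FS, seed=7)
    rec2, _ = synth_vowel(spec, FS, seed=7)
    assert np.array_equal(rec1.samples, rec2.samples)
    rec3, _ = synth_vowel(spec, FS, seed=8)
    assert not np.array_equal(rec1.samples, rec3.samples)


def _tiny_cohort(seed, rate_b=1.5):
    dists = {
        "duration_s": ParamDist(2.5, 0.1),
        "f0_hz": ParamDist(125.0, 10.0, low=100, high=150),
        "hnr_db": ParamDist(22.0, 2.0, low=12, high=31),
    }
    return CohortSpec(
        n_per_group=3,
        group_param_distributions={"A": dict(dists), "B": dict(dists)},
        break_rate={"A": 0.0, "B": rate_b},
        seed=seed,
    )


def test_cohort_determinism_and_group_breaks():
    recs1, truth1 = synth_cohort(_tiny_cohort(5), FS)
    recs2, truth2 = synth_cohort(_tiny_cohort(5), FS)
    for (_, _, r1), (_, _, r2) in zip(recs1, recs2):
        assert np.array_equal(r1.samples, r2.samples)
    # breaks only where the rate is non-zero
    assert truth1.loc[truth1.group == "A", "n_breaks"].sum() == 0


def test_cohort_degenerate_sd_rejected():
    with pytest.raises(ValueError):
        CohortSpec(
            n_per_group=3,
            group_param_distributions={"A": {"f0_hz": ParamDist(120.0, -1.0)}},
        )


def test_cohort_injected_hnr_means_recovered():
    """Law of large numbers on the stated sampling distributions."""
    dists_a = {"duration_s": ParamDist(1.5, 0.05), "hnr_db": ParamDist(19.0, 2.0)}
    dists_b = {"duration_s": ParamDist(1.5, 0.05), "hnr_db": ParamDist(22.0, 2.0)}
    cohort = CohortSpec(
        n_per_group=20,
        group_param_distributions={"A": dists_a, "B": dists_b},
        seed=3,
    )
    _, truth = synth_cohort(cohort, 16000.0)
    means = truth.groupby("group")["hnr_db"].mean()
    assert means["A"] == pytest.approx(19.0, abs=2.0)
    assert means["B"] == pytest.approx(22.0, abs=2.0)


def test_feature_table_sd_zero_is_constant():
    tab = sample_feature_table({"g": {"HNR": (20.0, 0.0)}}, n_per_group=5, seed=0)
    assert (tab["HNR"] == 20.0).all()


def test_feature_table_large_shift_separates_perfectly():
    tab = sample_feature_table(
        {"a": {"X": (0.0, 1.0)}, "b": {"X": (5.0, 1.0)}}, n_per_group=30, seed=1
    )
    a = tab.loc[tab.group == "a", "X"]
    b = tab.loc[tab.group == "b", "X"]
    assert a.max() < b.min()


def test_feature_table_exchangeable_groups_give_uniform_p():
    """Identical group parameters: two-sample t-test p is ~uniform."""
    from scipy import stats as st

    ps = []
    for seed in range(120):
        tab = sample_feature_table(
            {"a": {"X": (0.0, 1.0)}, "b": {"X": (0.0, 1.0)}}, n_per_group=10, seed=seed
        )
        a = tab.loc[tab.group == "a", "X"]
        b = tab.loc[tab.group == "b", "X"]
        ps.append(st.ttest_ind(a, b).pvalue)
    frac = np.mean(np.asarray(ps) < 0.05)
    assert 0.0 <= frac <= 0.13  # nominal level 0.05


def test_feature_table_negative_sd_rejected():
    with pytest.raises(ValueError):
        sample_feature_table({"g": {"X": (0.0, -1.0)}}, n_per_group=3)


def test_arrest_energy_localised_to_event_window():
    """Outside the event window the waveform is unchanged."""
    base = SynthSpec(duration_s=3.0, jitter_pct=0.0, shimmer_pct=0.0, hnr_db=60.0)
    with_ev = SynthSpec(
        duration_s=3.0,
        jitter_pct=0.0,
        shimmer_pct=0.0,
        hnr_db=60.0,
        break_events=(BreakEvent("vocal_arrest", 1.5, 0.2),),
    )
    _, t0 = synth_vowel(base, FS, seed=9)
    _, t1 = synth_vowel(with_ev, FS, seed=9)
    n = int(1.4 * FS)
    # identical harmonic component before the event
    assert np.allclose(t0.harmonic[:n] / t0.harmonic[:n].std(),
                       t1.harmonic[:n] / t1.harmonic[:n].std(), atol=1e-6)
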