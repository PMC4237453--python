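import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dysphonia.audio_io import VoiceRecording
from dysphonia.perturbation import (
    InsufficientDataError,
    dfa,
    f0_sd_semitones,
    hnr_db,
    jitter_local,
    rpde,
    shimmer_local,
)
from dysphonia.pitch import PitchParams, PitchTrack, track_pitch
from dysphonia.synth import SynthSpec, synth_vowel

FS = 44100.0


def _track_from_f0(f0_values):
    f0 = np.asarray(f0_values, dtype=float)
    return PitchTrack(
        times=np.arange(len(f0)) * 0.01,
        f0=f0,
        voicing_strength=np.full(len(f0), 0.9),
        label=np.asarray(["voiced"] * len(f0), dtype=object),
        params=PitchParams(),
    )


def test_f0_sd_constant_is_zero():
    assert f0_sd_semitones(_track_from_f0([140.0] * 50)) == pytest.approx(0.0, abs=1e-9)


def test_f0_sd_one_semitone_alternation_is_half():
    # alternating between two values one semitone apart: SD of {0,1} = 0.5
    track = _track_from_f0([100.0, 105.946] * 25)
    assert f0_sd_semitones(track) == pytest.approx(0.5, abs=1e-3)


@given(ratio=st.floats(0.5, 2.0))
def test_f0_sd_transposition_invariant(ratio):
    base = np.array([100.0, 101.0, 99.5, 100.5] * 10)
    a = f0_sd_semitones(_track_from_f0(base))
    b = f0_sd_semitones(_track_from_f0(base * ratio))
    assert a == pytest.approx(b, rel=1e-9)


def test_f0_sd_needs_two_voiced_frames():
    with pytest.raises(InsufficientDataError):
        f0_sd_semitones(_track_from_f0([140.0]))


def test_jitter_constant_periods_zero():
    assert jitter_local(np.full(50, 0.01)) == 0.0


def test_jitter_alternating_arithmetic():
    periods = np.array([0.0100, 0.0102] * 25)
    assert jitter_local(periods) == pytest.approx(100 * 0.0002 / 0.0101, rel=1e-6)


def test_shimmer_alternating_arithmetic():
    amps = np.array([1.00, 1.06] * 25)
    assert shimmer_local(amps) == pytest.approx(100 * 0.06 / 1.03, rel=1e-6)


@given(scale=st.floats(0.1, 10.0))
def test_jitter_scale_invariant(scale):
    periods = np.array([0.010, 0.0103, 0.0099, 0.0101] * 10)
    assert jitter_local(periods) == pytest.approx(
        jitter_local(periods * scale), rel=1e-9
    )


def test_perturbation_needs_three_cycles():
    with pytest.raises(InsufficientDataError):
        jitter_local(np.array([0.01, 0.0101]))


def test_hnr_mixture_oracle():
    """Known harmonic/noise mixture powers recovered within 1 dB."""
    for target in (20.0, 15.0):
        spec = SynthSpec(duration_s=2.5, jitter_pct=0.1, shimmer_pct=0.5, hnr_db=target)
        rec, _ = synth_vowel(spec, FS, seed=21)
        assert hnr_db(track_pitch(rec)) == pytest.approx(target, abs=1.0)


def test_hnr_monotone_in_noise():
    vals = []
    for target in (28.0, 22.0, 16.0, 10.0):
        spec = SynthSpec(duration_s=2.0, jitter_pct=0.1, shimmer_pct=0.5, hnr_db=target)
        rec, _ = synth_vowel(spec, FS, seed=22)
        vals.append(hnr_db(track_pitch(rec)))
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_hnr_gain_invariant(perturbed_vowel):
    rec, _ = perturbed_vowel
    h1 = hnr_db(track_pitch(rec))
    h2 = hnr_db(track_pitch(VoiceRecording(0.2 * rec.samples, rec.sample_rate)))
    assert h1 == pytest.approx(h2, abs=1e-6)


def test_rpde_periodic_low_noise_high(rng):
    spec = SynthSpec(duration_s=2.0, jitter_pct=0.0, shimmer_pct=0.0, hnr_db=60.0,
                     f0_wander_st=0.0, drift_extent_pct=0.0)
    rec, _ = synth_vowel(spec, FS, seed=23)
    assert rpde(rec) <= 0.15
    noise = VoiceRecording(0.3 * rng.standard_normal(int(2 * FS)), FS)
    assert rpde(noise) >= 0.5


def test_dfa_white_noise_exponent(rng):
    noise = VoiceRecording(0.3 * rng.standard_normal(int(2 * FS)), FS)
    assert dfa(noise, return_alpha=True) == pytest.approx(0.5, abs=0.1)


def test_dfa_output_in_unit_interval(perturbed_vowel):
    rec, _ = perturbed_vowel
    assert 0.0 < dfa(rec) < 1.0


def test_dfa_constant_signal_is_error():
    with pytest.raises(InsufficientDataError):
        dfa(VoiceRecording(np.zeros(int(2 * FS)) + 0.1, FS))


def test_rpde_dfa_monotone_in_added_noise(rng):
    """Both nonlinear measures are non-decreasing as noise is added."""
    spec = SynthSpec(duration_s=2.0, jitter_pct=0.2, shimmer_pct=1.0, hnr_db=60.0,
                     f0_wander_st=0.0, drift_extent_pct=0.0)
    rec, _ = synth_vowel(spec, FS, seed=24)
    noise = rng.standard_normal(len(rec.samples))
    noise *= rec.samples.std() / noise.std()
    rpde_vals, dfa_vals = [], []
    for level in (0.0, 0.05, 0.1, 0.2, 0.4):
        noisy = VoiceRecording(rec.samples + level * noise, rec.sample_rate)
        rpde_vals.append(rpde(noisy))
        dfa_vals.append(dfa(noisy))
    assert all(b >= a - 1e-6 for a, b in zip(rpde_vals, rpde_vals[1:]))
    assert all(b >= a - 1e-6 for a, b in zip(dfa_vals, dfa_vals[1:]))


def test_measures_bit_reproducible(perturbed_vowel):
    rec, _ = perturbed_vowel
    t1, t2 = track_pitch(rec), track_pitch(rec)
    assert hnr_db(t1) == hnr_db(t2)
    assert rpde(rec) == rpde(rec)
    assert dfa(rec) == dfa(rec)
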