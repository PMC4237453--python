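import numpy as np
import pytest

from dysphonia.phonation import (
    BreakRules,
    VoiceBreakEvent,
    degree_pitch_breaks,
    degree_vocal_arrests,
    detect_voice_breaks,
    first_voice_break_time,
    maximum_phonation_time,
)
from dysphonia.pitch import PitchParams, PitchTrack, PulseSequence


def _pulse_seq(times, spans=None):
    times = np.asarray(times, dtype=float)
    seq = PulseSequence(
        pulse_times=times,
        span_ids=np.zeros(len(times), dtype=int) if spans is None else np.asarray(spans),
    )
    seq.amplitudes = np.ones(len(times) - 1)
    return seq


def _track(labels, hop=0.01):
    n = len(labels)
    return PitchTrack(
        times=np.arange(n) * hop + 0.02,
        f0=np.where(np.asarray(labels) == "voiced", 120.0, np.nan),
        voicing_strength=np.where(np.asarray(labels) == "voiced", 0.9, 0.1),
        label=np.asarray(labels, dtype=object),
        params=PitchParams(),
    )


RULES = BreakRules()
FLOOR = 75.0  # gap threshold 16.7 ms


def test_mpt_is_trimmed_duration(clean_vowel):
    rec, truth = clean_vowel
    import dysphonia as dp

    trimmed, _, _ = dp.trim_to_phonation(rec)
    assert maximum_phonation_time(trimmed) == pytest.approx(
        truth.spec.duration_s, abs=0.05
    )


def test_mpt_includes_internal_breaks(breaks_analysis, vowel_with_breaks):
    _, truth = vowel_with_breaks
    assert breaks_analysis["features"]["MPT"] == pytest.approx(
        truth.spec.duration_s, abs=0.06
    )


def test_no_gaps_no_breaks():
    times = np.arange(0, 3.0, 0.008)
    nvb, events = detect_voice_breaks(_pulse_seq(times), RULES, FLOOR, 3.0)
    assert nvb == 0 and events == []


def test_qualifying_gap_counted_once():
    t = list(np.arange(0, 2.0, 0.008)) + list(np.arange(2.2, 5.0, 0.008))
    nvb, events = detect_voice_breaks(_pulse_seq(t), RULES, FLOOR, 5.0)
    assert nvb == 1
    assert events[0].onset_s == pytest.approx(2.0, abs=0.02)


def test_gap_without_modal_lead_not_counted():
    # first voiced run lasts only 0.1 s before the gap
    t = list(np.arange(0, 0.1, 0.008)) + list(np.arange(0.4, 3.0, 0.008))
    nvb, _ = detect_voice_breaks(_pulse_seq(t), RULES, FLOOR, 3.0)
    assert nvb == 0


def test_gap_in_terminal_guard_not_counted():
    t = list(np.arange(0, 2.5, 0.008)) + list(np.arange(2.75, 2.95, 0.008))
    nvb, _ = detect_voice_breaks(_pulse_seq(t), RULES, FLOOR, 3.0)
    assert nvb == 0


def test_empty_pulse_sequence_is_an_error():
    seq = PulseSequence(pulse_times=np.array([1.0]), span_ids=np.array([0]))
    seq.amplitudes = np.array([])
    nvb, _ = detect_voice_breaks(seq, RULES, FLOOR, 3.0)
    assert nvb == 0  # single pulse: no gaps
    with pytest.raises(ValueError):
        empty = PulseSequence(pulse_times=np.array([]), span_ids=np.array([]))
        empty.amplitudes = np.array([])
        detect_voice_breaks(empty, RULES, FLOOR, 3.0)


def test_fovb_equals_mpt_without_breaks():
    assert first_voice_break_time([], 14.0) == 14.0


def test_fovb_is_earliest_break():
    events = [
        VoiceBreakEvent(7.4, 0.1, "arrest"),
        VoiceBreakEvent(3.1, 0.2, "pitch_related"),
    ]
    assert first_voice_break_time(events, 14.0) == 3.1


def test_dpb_arithmetic():
    labels = ["voiced"] * 90 + ["unvoiced"] * 10 + ["silent"] * 20
    assert degree_pitch_breaks(_track(labels)) == pytest.approx(10.0)


def test_dpb_fully_voiced_zero(clean_analysis):
    assert clean_analysis["features"]["DPB"] == 0.0


def test_dpb_all_silent_is_error():
    with pytest.raises(ValueError):
        degree_pitch_breaks(_track(["silent"] * 10))


def test_dva_arithmetic():
    # 0.4 s of silent frames in an 8 s span -> 5 %
    labels = ["voiced"] * 100 + ["silent"] * 40 + ["voiced"] * 100
    assert degree_vocal_arrests(_track(labels), 8.0) == pytest.approx(5.0)


def test_dva_zero_without_silences(clean_analysis):
    assert clean_analysis["features"]["DVA"] == 0.0


def test_dva_tracks_injected_arrest(breaks_analysis, vowel_with_breaks):
    _, truth = vowel_with_breaks
    dva = breaks_analysis["features"]["DVA"]
    expected = 100.0 * 0.2 / truth.spec.duration_s
    assert dva == pytest.approx(expected, abs=1.0)


def test_nvb_invariant_to_gain(vowel_with_breaks):
    import dysphonia as dp
    from dysphonia.audio_io import VoiceRecording

    rec, _ = vowel_with_breaks
    res1 = dp.analyze_recording(rec)
    res2 = dp.analyze_recording(
        VoiceRecording(0.3 * rec.samples, rec.sample_rate)
    )
    assert res1["features"]["NVB"] == res2["features"]["NVB"]


def test_fovb_never_exceeds_mpt(breaks_analysis):
    f = breaks_analysis["features"]
    assert f["FOVB"] <= f["MPT"] + 1e-9
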