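"""Airflow-insufficiency and aperiodicity measures.

Five measures defined on the trimmed phonation span: maximum phonation time
(MPT), time to the first voice break (FOVB), number of voice breaks (NVB),
degree of pitch breaks (DPB) and degree of vocal arrests (DVA).

A voice break is an inter-pulse gap longer than ``gap_factor`` divided by
the pitch floor.  A gap is only *counted* when at least ``modal_lead_s`` of
continuous modal phonation precedes it and its onset lies at least
``terminal_guard_s`` before the end of phonation — gaps at the very start
or in the final struggle of the breath are not breaks of sustained
phonation.  A counted break whose interior is silent is classified as a
vocal arrest; otherwise it is pitch-related (e.g. an F0 drop below the
analysis floor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import VoiceRecording, frame_rms
from .pitch import SILENT, PitchTrack, PulseSequence

__all__ = [
    "BreakRules",
    "VoiceBreakEvent",
    "maximum_phonation_time",
    "detect_voice_breaks",
    "first_voice_break_time",
    "degree_pitch_breaks",
    "degree_vocal_arrests",
    "MIN_ANALYSABLE_S",
]

#: Shortest phonation for which the break gating rules are meaningful
#: (modal lead + terminal guard).
MIN_ANALYSABLE_S = 1.25


@dataclass(frozen=True)
class BreakRules:
    """Gating rules for counting voice breaks."""

    gap_factor: float = 1.25  # threshold = gap_factor / floor_hz
    modal_lead_s: float = 0.25  # continuous phonation required before a break
    terminal_guard_s: float = 1.0  # breaks this close to the end are ignored

    def __post_init__(self) -> None:
        if min(self.gap_factor, self.modal_lead_s, self.terminal_guard_s) <= 0:
            raise ValueError("all break rules must be positive")

    def gap_threshold_s(self, floor_hz: float) -> float:
        return self.gap_factor / floor_hz


@dataclass(frozen=True)
class VoiceBreakEvent:
    """One detected voice break."""

    onset_s: float
    duration_s: float
    kind: str  # "pitch_related" | "arrest"


def maximum_phonation_time(trimmed: VoiceRecording) -> float:
    """Duration of the trimmed phonation span, voice breaks included."""
    return trimmed.duration_s


def detect_voice_breaks(
    pulses: PulseSequence,
    rules: BreakRules,
    floor_hz: float,
    span_s: float,
    rec: VoiceRecording | None = None,
    silence_rms_ratio: float = 0.05,
) -> tuple[int, list[VoiceBreakEvent]]:
    """Count qualifying voice breaks among inter-pulse gaps.

    Parameters
    ----------
    pulses
        Pulse sequence over the trimmed span.
    rules, floor_hz
        Gating rules; the gap threshold is ``rules.gap_factor / floor_hz``.
    span_s
        Duration of the trimmed phonation span (for the terminal guard).
    rec
        The trimmed recording; if given, counted gaps whose interior RMS is
        below ``silence_rms_ratio`` of the loud-frame RMS are classified as
        arrests, the rest as pitch-related.

    Returns ``(NVB, events)``.
    """
    times = pulses.pulse_times
    if times.size == 0:
        raise ValueError("voice breaks are undefined for an empty pulse sequence")
    threshold = rules.gap_threshold_s(floor_hz)
    gaps = np.diff(times)
    median_t = float(np.median(gaps[gaps <= threshold])) if (gaps <= threshold).any() else 1.0 / floor_hz

    loud_rms = None
    if rec is not None:
        _, rms = frame_rms(rec.samples, rec.sample_rate)
        if rms.size:
            loud_rms = float(np.percentile(rms, 95))

    events: list[VoiceBreakEvent] = []
    run_start = times[0]  # start of the current continuous phonation run
    for i, gap in enumerate(gaps):
        if gap <= threshold:
            continue
        onset = times[i] + median_t  # end of the last complete cycle
        duration = gap - median_t
        lead = times[i] - run_start
        run_start = times[i + 1]
        if lead < rules.modal_lead_s:
            continue
        if onset > span_s - rules.terminal_guard_s:
            continue
        kind = "pitch_related"
        if rec is not None and loud_rms:
            a = int(onset * rec.sample_rate)
            b = int((onset + duration) * rec.sample_rate)
            seg = rec.samples[a:b]
            if seg.size and np.sqrt(np.mean(seg**2)) < silence_rms_ratio * loud_rms:
                kind = "arrest"
        events.append(VoiceBreakEvent(onset, max(duration, 0.0), kind))
    return len(events), events


def first_voice_break_time(events: list[VoiceBreakEvent], mpt: float) -> float:
    """Onset of the earliest qualifying break; equals MPT when none exists."""
    if not events:
        return mpt
    return min(ev.onset_s for ev in events)


def degree_pitch_breaks(track: PitchTrack) -> float:
    """Percentage of non-silent pitch frames marked unvoiced."""
    not_silent = track.label != SILENT
    n = int(not_silent.sum())
    if n == 0:
        raise ValueError("degree of pitch breaks undefined: all frames silent")
    unvoiced = int((track.label[not_silent] == "unvoiced").sum())
    return 100.0 * unvoiced / n


def degree_vocal_arrests(track: PitchTrack, span_s: float) -> float:
    """Percentage of the phonation span occupied by silent periods."""
    if span_s <= 0:
        raise ValueError("span duration must be positive")
    silent_s = float((track.label == SILENT).sum()) * track.hop_s
    return float(np.clip(100.0 * silent_s / span_s, 0.0, 100.0))
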