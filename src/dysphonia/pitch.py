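"""Autocorrelation pitch tracking and glottal pulse extraction.

The tracker follows the classic short-term autocorrelation design: per
analysis frame the windowed, mean-removed autocorrelation is normalised by
the window's own autocorrelation, and the strongest normalised peak within
the admissible lag range gives the F0 candidate and its *voicing strength*.
A frame is labelled ``silent`` when its RMS falls below a fraction of the
loud-frame RMS, ``voiced`` when the voicing strength reaches the voicing
threshold (default 0.45), and ``unvoiced`` otherwise.  Isolated octave
errors are corrected against the local median track; a genuine pitch drop
sustained over several frames is left untouched.

Glottal pulses are then located in two passes.  A waveform peak is picked
per predicted cycle inside each voiced span, giving one approximate pulse
per cycle.  Each pulse is then refined on the *linear-prediction residual*
(glottal inverse filtering): an all-pole LPC fit removes the vocal-tract
resonances, leaving the residual dominated by one excitation impulse per
cycle, whose energy centroid gives a sub-sample pulse instant and whose
magnitude gives the per-cycle source amplitude.  This makes the cycle
period and amplitude sequences — the substrate of jitter, shimmer and
voice-break analysis — robust to formant ring-down carrying over between
cycles.  When the residual shows no impulse structure (e.g. a pure tone),
the waveform-peak estimates are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio_io import VoiceRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PitchParams",
    "PitchTrack",
    "PulseSequence",
    "track_pitch",
    "extract_pulses",
    "UnvoicedRecordingError",
]

SILENT, UNVOICED, VOICED = "silent", "unvoiced", "voiced"


class UnvoicedRecordingError(ValueError):
    """The recording contains no voiced frames."""


@dataclass(frozen=True)
class PitchParams:
    """Configuration of the pitch tracker.

    ``floor_hz``/``ceiling_hz`` bound the admissible F0 search range; the
    floor also defines the voice-break gap threshold (1.25/floor) used by
    the aperiodicity measures.  The frame should span at least two cycles
    of the lowest admissible F0.
    """

    floor_hz: float = 75.0
    ceiling_hz: float = 500.0
    frame_s: float = 0.04
    hop_s: float = 0.01
    voicing_threshold: float = 0.45
    silence_rms_ratio: float = 0.05  # of the 95th-percentile frame RMS

    def __post_init__(self) -> None:
        if not 0 < self.floor_hz < self.ceiling_hz:
            raise ValueError("need 0 < floor_hz < ceiling_hz")
        if self.frame_s < 2.0 / self.floor_hz:
            logger.warning(
                "frame_s=%.3fs is below two cycles at the %g Hz floor",
                self.frame_s,
                self.floor_hz,
            )


@dataclass
class PitchTrack:
    """Frame-wise F0 estimate with voicing labels."""

    times: np.ndarray  # frame centres, seconds
    f0: np.ndarray  # Hz; NaN where not voiced
    voicing_strength: np.ndarray  # normalised autocorrelation peak, [0, 1]
    label: np.ndarray  # str array: silent | unvoiced | voiced
    params: PitchParams
    #: best-candidate F0 per frame regardless of the voicing decision
    #: (NaN where no candidate); used to judge continuity across
    #: sub-threshold frames
    raw_f0: np.ndarray | None = None

    @property
    def voiced(self) -> np.ndarray:
        return self.label == VOICED

    @property
    def hop_s(self) -> float:
        return self.params.hop_s

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "f0_hz": self.f0,
                "voicing_strength": self.voicing_strength,
                "label": self.label,
            }
        )


@dataclass
class PulseSequence:
    """Glottal pulse instants with cycle periods and amplitudes.

    ``periods`` are successive differences of ``pulse_times``; a period that
    bridges two voiced spans is a candidate voice break, not a vocal cycle,
    and is excluded from the perturbation measures via ``within_span``.
    ``amplitudes`` hold the peak-to-peak waveform extent of each cycle
    (NaN for cross-span entries).
    """

    pulse_times: np.ndarray
    span_ids: np.ndarray  # voiced-span index per pulse

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse_times must be strictly increasing")

    amplitudes: np.ndarray = None  # set in extract_pulses

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.pulse_times)

    @property
    def within_span(self) -> np.ndarray:
        """Mask over ``periods``: True where both pulses share a span."""
        return self.span_ids[1:] == self.span_ids[:-1]

    @property
    def cycle_periods(self) -> np.ndarray:
        return self.periods[self.within_span]

    @property
    def cycle_amplitudes(self) -> np.ndarray:
        amps = self.amplitudes[self.within_span]
        return amps[np.isfinite(amps)]


def _frame_signal(x: np.ndarray, n_frame: int, hop: int) -> np.ndarray:
    n_frames = 1 + max(0, (len(x) - n_frame) // hop)
    idx = np.arange(n_frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def track_pitch(rec: VoiceRecording, params: PitchParams | None = None) -> PitchTrack:
    """Estimate F0, voicing strength and frame labels.

    Raises ``ValueError`` if the recording is shorter than one frame.
    """
    if params is None:
        params = PitchParams()
    fs = rec.sample_rate
    n_frame = int(round(params.frame_s * fs))
    hop = max(int(round(params.hop_s * fs)), 1)
    x = rec.samples
    if len(x) < n_frame:
        raise ValueError("recording shorter than one analysis frame")

    frames = _frame_signal(x, n_frame, hop)
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop + n_frame / 2) / fs

    rms = np.sqrt(np.mean(frames**2, axis=1))
    loud = np.percentile(rms, 95) if n_frames else 0.0
    silent = rms <= params.silence_rms_ratio * loud

    window = np.hanning(n_frame)
    nfft = int(2 ** np.ceil(np.log2(2 * n_frame)))
    # autocorrelation of the window itself, for lag normalisation
    wspec = np.fft.rfft(window, nfft)
    r_w = np.fft.irfft(wspec * np.conj(wspec))[:n_frame]
    r_w /= r_w[0]

    fr = frames - frames.mean(axis=1, keepdims=True)
    fr = fr * window
    spec = np.fft.rfft(fr, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), axis=1)[:, :n_frame]
    ac0 = ac[:, 0].copy()
    ac0[ac0 <= 0] = np.inf
    r = ac / ac0[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = r / np.where(r_w > 0.1, r_w, np.nan)[None, :]

    lag_min = max(int(np.floor(fs / params.ceiling_hz)), 2)
    lag_floor = int(np.ceil(fs / params.floor_hz))
    # candidates are searched down to half the pitch floor so that a genuine
    # half-F0 drop is recognised as strong periodicity *below* the floor
    # (and hence labelled unvoiced) instead of leaving weak in-range
    # artefacts near the lag boundary
    lag_max = min(2 * lag_floor, n_frame - 2)
    if min(lag_floor, lag_max) <= lag_min:
        raise ValueError("frame too short for the configured pitch floor")

    f0 = np.full(n_frames, np.nan)
    strength = np.zeros(n_frames)
    cand_f0 = [[] for _ in range(n_frames)]
    cand_str = [[] for _ in range(n_frames)]
    band = r[:, lag_min : lag_max + 1]
    # local maxima in the searched lag band
    interior = (band[:, 1:-1] > band[:, :-2]) & (band[:, 1:-1] >= band[:, 2:])
    octave_cost = 0.05  # per octave of lag, discourages subharmonic capture
    for i in range(n_frames):
        if silent[i]:
            continue
        peaks = np.flatnonzero(interior[i]) + 1 + lag_min
        peaks = peaks[np.isfinite(r[i, peaks])]
        if peaks.size == 0:
            continue
        vals = np.minimum(r[i, peaks], 1.0)
        scores = vals - octave_cost * np.log2(peaks / lag_min)
        # the sub-floor zone exists only to recognise genuine F0 drops; its
        # long-lag correlations are noisier (less window support), so a
        # sub-floor candidate must beat the in-range best by a clear margin
        in_range = peaks <= lag_floor
        if in_range.any() and (~in_range).any():
            if scores[~in_range].max() < scores[in_range].max() + 0.1:
                peaks, scores = peaks[in_range], scores[in_range]
        order = np.argsort(scores)[::-1][:4]
        for k in order:
            lag = peaks[k]
            y0, y1, y2 = r[i, lag - 1], r[i, lag], r[i, lag + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            delta = np.clip(delta, -0.5, 0.5)
            lag_ref = lag + delta
            s = float(min(max(y1, 0.0), 1.0))
            cand_f0[i].append(fs / lag_ref)
            cand_str[i].append(s)
        strength[i] = cand_str[i][0]
        f0[i] = cand_f0[i][0]

    raw_f0 = f0.copy()
    label = np.full(n_frames, UNVOICED, dtype=object)
    label[silent] = SILENT
    voiced = (
        (~silent)
        & (strength >= params.voicing_threshold)
        & np.isfinite(f0)
        & (f0 >= params.floor_hz)
        & (f0 <= params.ceiling_hz)
    )
    label[voiced] = VOICED
    f0[~voiced] = np.nan

    _fix_octave_errors(f0, cand_f0, cand_str, voiced)
    _repair_isolated_unvoiced(
        f0, strength, label, cand_f0, cand_str, params
    )
    return PitchTrack(
        times, f0, strength, np.asarray(label, dtype=object), params, raw_f0
    )


def _fix_octave_errors(f0, cand_f0, cand_str, voiced) -> None:
    """Replace isolated octave jumps with a neighbour-consistent candidate.

    Uses a running median over 5 voiced frames; a frame deviating by more
    than ~half an octave is swapped to an alternative candidate close to the
    median, if one exists with comparable strength.  A drop sustained over
    at least 3 frames moves the median with it and therefore survives.
    """
    idx = np.flatnonzero(voiced)
    if idx.size < 5:
        return
    vf0 = f0[idx]
    for j, i in enumerate(idx):
        lo, hi = max(0, j - 2), min(len(idx), j + 3)
        med = np.median(vf0[lo:hi])
        if med <= 0 or not np.isfinite(med):
            continue
        if abs(np.log2(f0[i] / med)) > 0.4:
            best = None
            for fc, sc in zip(cand_f0[i], cand_str[i]):
                if abs(np.log2(fc / med)) < 0.2 and sc >= 0.7 * cand_str[i][0]:
                    best = fc
                    break
            if best is not None:
                f0[i] = best


def _repair_isolated_unvoiced(f0, strength, label, cand_f0, cand_str, params) -> None:
    """Re-voice single unvoiced frames flanked by consistent voiced frames.

    An occasional subharmonic capture on one frame would otherwise split a
    voiced span and fabricate a ~2-period pulse gap, which the voice-break
    detector could count as a break.  Only frames with an alternative
    candidate matching the flanking F0 at full voicing strength are
    repaired, so genuine break onsets (several frames long) are untouched.
    """
    n = len(f0)
    i = 1
    while i < n - 1:
        if label[i] != UNVOICED:
            i += 1
            continue
        j = i
        while j < n and label[j] == UNVOICED:
            j += 1
        run = j - i
        if run > 2 or i == 0 or j >= n or label[i - 1] != VOICED or label[j] != VOICED:
            i = j
            continue
        if not np.isfinite(f0[i - 1]) or not np.isfinite(f0[j]):
            i = j
            continue
        if abs(np.log2(f0[i - 1] / f0[j])) > 0.2:
            i = j
            continue
        med = 0.5 * (f0[i - 1] + f0[j])
        for k in range(i, j):
            for fc, sc in zip(cand_f0[k], cand_str[k]):
                if (
                    abs(np.log2(fc / med)) < 0.2
                    and sc >= params.voicing_threshold
                    and params.floor_hz <= fc <= params.ceiling_hz
                ):
                    f0[k] = fc
                    strength[k] = sc
                    label[k] = VOICED
                    break
        i = j


def _voiced_spans(track: PitchTrack) -> list[tuple[int, int]]:
    """Maximal runs of voiced frames, as (first, last) frame indices.

    Spans whose pulse trains turn out to be continuous are unified later at
    the pulse level (see ``_unify_continuous_spans``): strong jitter
    produces genuine subharmonic frames below the voicing threshold
    without interrupting the pulse train.
    """
    v = track.voiced
    spans = []
    start = None
    for i, flag in enumerate(v):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            spans.append((start, i - 1))
            start = None
    if start is not None:
        spans.append((start, len(v) - 1))
    return spans


def _refine_peak(x: np.ndarray, i: int) -> float:
    """Parabolic sub-sample refinement of a peak at sample index i."""
    if i <= 0 or i >= len(x) - 1:
        return float(i)
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-30:
        return float(i)
    return i + float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def _lpc_coefficients(x: np.ndarray, order: int) -> np.ndarray | None:
    """Forward-prediction coefficients by the autocorrelation method."""
    from scipy import linalg as sla

    w = x * np.hamming(len(x))
    nfft = int(2 ** np.ceil(np.log2(len(w) + order + 1)))
    spec = np.fft.rfft(w, nfft)
    r = np.fft.irfft(spec * np.conj(spec))[: order + 1]
    if r[0] <= 0:
        return None
    try:
        return sla.solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except (np.linalg.LinAlgError, ValueError):
        return None


def _lpc_residual(x: np.ndarray, fs: float, order: int | None = None) -> np.ndarray:
    """Linear-prediction residual (inverse-filtered signal)."""
    from scipy import signal as sps

    if order is None:
        order = int(2 + fs / 2000.0)
    a = _lpc_coefficients(x, order)
    if a is None:
        return np.zeros_like(x)
    return sps.lfilter(np.concatenate([[1.0], -a]), [1.0], x)


def extract_pulses(rec: VoiceRecording, track: PitchTrack) -> PulseSequence:
    """Locate glottal pulses: one excitation instant per vocal cycle.

    Within each voiced span the search is seeded at the strongest waveform
    peak and walks outward, looking for the next peak inside a window of
    0.7–1.4 predicted periods; pulses are then refined on the LPC residual
    when it carries impulse structure.  Raises
    :class:`UnvoicedRecordingError` when the track has no voiced frames.
    """
    if not track.voiced.any():
        raise UnvoicedRecordingError("no voiced frames in recording")
    x = rec.samples
    fs = rec.sample_rate
    all_times: list[float] = []
    all_spans: list[int] = []

    for span_id, (fa, fb) in enumerate(_voiced_spans(track)):
        # bound the search at the hop edge of the outermost voiced frames:
        # extending by the full frame width would let the walk encroach
        # into adjacent break regions, which stay loud during pitch drops
        t_lo = track.times[fa] - track.params.hop_s / 2
        t_hi = track.times[fb] + track.params.hop_s / 2
        i_lo = max(int(t_lo * fs), 0)
        i_hi = min(int(t_hi * fs), len(x))
        if i_hi - i_lo < 8:
            continue
        ft = track.times[fa : fb + 1]
        ff = track.f0[fa : fb + 1]
        good = np.isfinite(ff)
        if good.sum() == 0:
            continue

        def period_at(t: float) -> float:
            f = np.interp(t, ft[good], ff[good])
            return 1.0 / max(f, 1e-6)

        seg = x[i_lo:i_hi]
        seed = i_lo + int(np.argmax(seg))
        seed_t = _refine_peak(x, seed) / fs

        span_times = [seed_t]
        seed_peak = float(x[seed])
        # walk right then left; stop when the peak amplitude collapses
        # (the span edge reaches into an arrest or the fade-out)
        for direction in (+1, -1):
            t = seed_t
            recent = [seed_peak]
            while True:
                T = period_at(t)
                if direction > 0:
                    w0, w1 = t + 0.7 * T, t + 1.4 * T
                else:
                    w0, w1 = t - 1.4 * T, t - 0.7 * T
                j0, j1 = int(np.floor(w0 * fs)), int(np.ceil(w1 * fs))
                j0 = max(j0, i_lo)
                j1 = min(j1, i_hi)
                if j1 - j0 < 3:
                    break
                k = j0 + int(np.argmax(x[j0:j1]))
                if x[k] < 0.15 * np.median(recent):
                    break
                t_new = _refine_peak(x, k) / fs
                if direction > 0 and t_new <= t + 0.25 * T:
                    break
                if direction < 0 and t_new >= t - 0.25 * T:
                    break
                span_times.append(t_new)
                recent.append(float(x[k]))
                if len(recent) > 5:
                    recent.pop(0)
                t = t_new

        span_times = sorted(span_times)
        all_times.extend(span_times)
        all_spans.extend([span_id] * len(span_times))

    if not all_times:
        raise UnvoicedRecordingError("no pulses could be located")

    order = np.argsort(all_times)
    times = np.asarray(all_times)[order]
    spans = np.asarray(all_spans)[order]
    # drop duplicates closer than a quarter of the shortest admissible period
    min_gap = 0.25 / track.params.ceiling_hz
    keep = np.concatenate([[True], np.diff(times) > min_gap])
    times, spans = times[keep], spans[keep]

    refined = _refine_on_residual(x, fs, track, times)
    if refined is not None:
        times, residual = refined
        order = np.argsort(times)
        times, spans = times[order], spans[order]
        keep = np.concatenate([[True], np.diff(times) > min_gap])
        times, spans = times[keep], spans[keep]
        spans = _unify_continuous_spans(times, spans, track.params.floor_hz)
        times, spans = _fill_pulse_holes(residual, fs, times, spans)
        amps = _cleaned_cycle_amplitudes(x, fs, times)
        amps[spans[:-1] != spans[1:]] = np.nan
    else:
        amps = np.full(len(times) - 1, np.nan)
        for i in range(len(times) - 1):
            if spans[i] != spans[i + 1]:
                continue
            a = int(times[i] * fs)
            b = int(times[i + 1] * fs)
            if b > a:
                cyc = x[a:b]
                amps[i] = float(cyc.max() - cyc.min())

    seq = PulseSequence(pulse_times=times, span_ids=spans)
    seq.amplitudes = amps
    return seq


def _refine_on_residual(
    x: np.ndarray, fs: float, track: PitchTrack, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Refine pulse instants on the LPC residual.

    The energy centroid of the excitation impulse gives a sub-sample pulse
    time.  Returns ``(refined_times, residual)``, or ``None`` when the
    residual shows no impulse structure (the excitation is not pulse-like,
    e.g. a pure tone), in which case the caller keeps the waveform-peak
    estimates.
    """
    e = _lpc_residual(x, fs)
    ae = np.abs(e)
    med = np.median(ae)
    if med <= 0 or np.percentile(ae, 99.9) < 10.0 * med:
        return None
    voiced = track.voiced
    if voiced.sum() < 2:
        return None
    vt = track.times[voiced]
    vf = track.f0[voiced]
    new_times = np.empty_like(times)
    n = len(e)
    for i, t in enumerate(times):
        period = 1.0 / max(float(np.interp(t, vt, vf)), 1e-6)
        half = max(int(0.45 * period * fs), 4)
        c = int(round(t * fs))
        j0, j1 = max(c - half, 0), min(c + half + 1, n)
        if j1 - j0 < 5:
            new_times[i] = t
            continue
        k = j0 + int(np.argmax(ae[j0:j1]))
        a0, a1 = max(k - 4, 0), min(k + 5, n)
        w = e[a0:a1] ** 2
        total = w.sum()
        centroid = (a0 + (np.arange(a1 - a0) * w).sum() / total) if total > 0 else k
        new_times[i] = centroid / fs
    return new_times, e


def _unify_continuous_spans(
    times: np.ndarray, spans: np.ndarray, floor_hz: float
) -> np.ndarray:
    """Merge span labels across sub-threshold pulse gaps.

    A cross-span pulse gap shorter than the voice-break threshold
    (1.25/floor) can never be counted as a break, so the pulse train is
    effectively continuous there — typically frames pushed under the
    voicing threshold by jitter-induced subharmonics.  Unifying the span
    ids lets those cycles re-enter the perturbation statistics (and lets
    hole-filling recover any pulse lost in the gap).  Genuine break gaps
    exceed the threshold and are never unified.
    """
    limit = 0.95 * 1.25 / floor_hz
    new = spans.copy()
    for i in range(len(times) - 1):
        if new[i + 1] != new[i] and (times[i + 1] - times[i]) < limit:
            new[new == new[i + 1]] = new[i]
    return new


def _fill_pulse_holes(
    e: np.ndarray, fs: float, times: np.ndarray, spans: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Recover single pulses lost inside a voiced span.

    A within-span gap of roughly two local periods usually means one
    excitation impulse was skipped (or two refined pulses collapsed onto
    one impulse); the residual is re-scanned around the gap midpoint and a
    pulse re-inserted when a plausible impulse is present.
    """
    ae = np.abs(e)
    med_impulse = np.median(
        [ae[int(t * fs)] for t in times if 0 <= int(t * fs) < len(ae)]
    )
    out_t = list(times)
    out_s = list(spans)
    periods = np.diff(times)
    ins_t, ins_s = [], []
    for i, gap in enumerate(periods):
        if spans[i] != spans[i + 1]:
            continue
        lo, hi = max(i - 3, 0), min(i + 4, len(periods))
        neigh = [periods[j] for j in range(lo, hi) if j != i and spans[j] == spans[j + 1]]
        if len(neigh) < 2:
            continue
        t_loc = float(np.median(neigh))
        if not 1.6 * t_loc < gap < 2.5 * t_loc:
            continue
        mid = times[i] + gap / 2
        half = int(0.35 * t_loc * fs)
        c = int(mid * fs)
        j0, j1 = max(c - half, 0), min(c + half, len(ae))
        if j1 - j0 < 3:
            continue
        k = j0 + int(np.argmax(ae[j0:j1]))
        if ae[k] < 0.25 * med_impulse:
            continue
        ins_t.append(k / fs)
        ins_s.append(spans[i])
    if ins_t:
        out_t.extend(ins_t)
        out_s.extend(ins_s)
        order = np.argsort(out_t)
        return np.asarray(out_t)[order], np.asarray(out_s)[order]
    return times, spans


def _cleaned_cycle_amplitudes(
    x: np.ndarray, fs: float, times: np.ndarray, order: int | None = None
) -> np.ndarray:
    """Per-cycle amplitude with the previous cycle's ring-down removed.

    The vocal-tract resonances decay autonomously between excitations, so
    the carry-over from the previous cycle is the free (zero-input)
    evolution of the all-pole LPC model seeded with the samples just before
    the pulse.  Subtracting it leaves the current cycle's own response,
    whose RMS is proportional to the source pulse amplitude.
    """
    from scipy import signal as sps

    if order is None:
        order = int(2 + fs / 2000.0)
    a = _lpc_coefficients(x, order)
    amps = np.full(len(times) - 1, np.nan)
    if a is None:
        return amps
    b_ar = np.concatenate([[1.0], -a])
    n = len(x)
    for i in range(len(times) - 1):
        s0 = int(np.floor(times[i] * fs)) - 2
        s1 = int(times[i + 1] * fs) - 2
        if s0 - order < 0 or s1 > n or s1 - s0 < 4:
            continue
        past = x[s0 - order : s0]
        zi = sps.lfiltic([1.0], b_ar, past[::-1])
        free, _ = sps.lfilter([1.0], b_ar, np.zeros(s1 - s0), zi=zi)
        amps[i] = float(np.sqrt(np.mean((x[s0:s1] - free) ** 2)))
    return amps
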