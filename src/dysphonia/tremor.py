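"""Vocal tremor indices and articulation-stability indices.

FTRI and ATRI quantify slow (1.5–15 Hz) modulation of the F0 contour and
of the per-cycle amplitude contour respectively: each is the amplitude of
the strongest in-band sinusoidal component of the contour, expressed as a
percentage of the contour mean — i.e. the modulation extent of the most
intense low-frequency tremor component.

MFCC and delta-MFCC stability summarise how much the short-term vocal-tract
spectrum wanders during the sustained vowel: the mean over coefficients
1–12 of each mel-frequency cepstral coefficient's standard deviation across
frames (the delta variant on the regression slopes, scaled by 10).  The 0th
coefficient is excluded, which makes both indices insensitive to overall
gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import dct, rfft

from .audio_io import VoiceRecording
from .perturbation import InsufficientDataError
from .pitch import PitchTrack, PulseSequence

__all__ = [
    "TremorParams",
    "MfccParams",
    "ftri",
    "atri",
    "mfcc_stability",
]


@dataclass(frozen=True)
class TremorParams:
    """Tremor search band and contour resampling rate."""

    band_lo_hz: float = 1.5
    band_hi_hz: float = 15.0
    contour_rate_hz: float = 100.0
    max_gap_s: float = 0.100  # unvoiced gaps longer than this split the contour
    min_segment_s: float = 1.0  # shortest contour segment analysed

    def __post_init__(self) -> None:
        if not 0 < self.band_lo_hz < self.band_hi_hz < self.contour_rate_hz / 2:
            raise ValueError("need 0 < band_lo < band_hi < contour_rate/2")


@dataclass(frozen=True)
class MfccParams:
    """Mel-cepstral analysis configuration (coefficients 1..n_coeffs)."""

    n_coeffs: int = 12
    frame_s: float = 0.025
    hop_s: float = 0.010
    n_mels: int = 26
    fmax_hz: float = 8000.0
    analysis_fs: float = 16000.0
    delta_window: int = 2  # frames each side for the regression slope
    delta_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.n_coeffs < 1:
            raise ValueError("n_coeffs must be at least 1")


def _contour_segments(
    t: np.ndarray, v: np.ndarray, params: TremorParams
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a sampled contour at gaps longer than max_gap_s."""
    if t.size == 0:
        return []
    cut = np.flatnonzero(np.diff(t) > params.max_gap_s)
    pieces = np.split(np.arange(t.size), cut + 1)
    return [(t[idx], v[idx]) for idx in pieces if idx.size >= 2]


def _tremor_index(
    t: np.ndarray, contour: np.ndarray, params: TremorParams
) -> float:
    """Modulation-extent index of one contour: % of mean at strongest in-band bin."""
    segments = _contour_segments(t, contour, params)
    results, weights = [], []
    for ts, vs in segments:
        dur = ts[-1] - ts[0]
        if dur < params.min_segment_s:
            continue
        n = int(dur * params.contour_rate_hz)
        grid = ts[0] + np.arange(n) / params.contour_rate_hz
        u = np.interp(grid, ts, vs)
        mean = u.mean()
        if mean <= 0:
            continue
        spec = np.abs(rfft(u - mean))
        freqs = np.arange(spec.size) * params.contour_rate_hz / n
        band = (freqs >= params.band_lo_hz) & (freqs <= params.band_hi_hz)
        if not band.any():
            continue
        amp = 2.0 * spec[band].max() / n  # amplitude of the strongest sinusoid
        results.append(100.0 * amp / mean)
        weights.append(dur)
    if not results:
        raise InsufficientDataError("no contour segment long enough for tremor")
    return float(np.average(results, weights=weights))


def ftri(track: PitchTrack, params: TremorParams | None = None) -> float:
    """Frequency tremor intensity index, percent.

    Interpolates the voiced F0 contour onto a uniform grid (gaps longer
    than ``max_gap_s`` split the analysis) and measures the strongest
    1.5–15 Hz modulation component relative to the mean F0.
    """
    if params is None:
        params = TremorParams()
    voiced = track.voiced
    if voiced.sum() < 2:
        raise InsufficientDataError("FTRI needs voiced frames")
    return _tremor_index(track.times[voiced], track.f0[voiced], params)


def atri(pulses: PulseSequence, params: TremorParams | None = None) -> float:
    """Amplitude tremor intensity index, percent.

    As :func:`ftri`, on the per-cycle amplitude contour.  Invariant to
    global gain by construction (ratio to the mean amplitude).
    """
    if params is None:
        params = TremorParams()
    amps = pulses.amplitudes
    ok = np.isfinite(amps)
    if ok.sum() < 2:
        raise InsufficientDataError("ATRI needs cycle amplitudes")
    mid = 0.5 * (pulses.pulse_times[:-1] + pulses.pulse_times[1:])
    return _tremor_index(mid[ok], amps[ok], params)


# ---------------------------------------------------------------------------
# mel-cepstral stability
# ---------------------------------------------------------------------------


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int, n_fft: int, fs: float, fmax: float) -> np.ndarray:
    edges = _mel_to_hz(np.linspace(0.0, _hz_to_mel(fmax), n_mels + 2))
    bins = np.floor((n_fft + 1) * edges / fs).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for i in range(n_mels):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        if mid > lo:
            fb[i, lo:mid] = (np.arange(lo, mid) - lo) / (mid - lo)
        if hi > mid:
            fb[i, mid:hi] = (hi - np.arange(mid, hi)) / (hi - mid)
    return fb


def _mfcc_frames(x: np.ndarray, fs: float, params: MfccParams) -> np.ndarray:
    n_frame = int(round(params.frame_s * fs))
    hop = int(round(params.hop_s * fs))
    n_frames = 1 + max(0, (len(x) - n_frame) // hop)
    if n_frames < 1:
        raise InsufficientDataError("signal shorter than one MFCC frame")
    idx = np.arange(n_frame)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    # silent frames (vocal arrests, pauses) carry no articulatory
    # information and would dominate the coefficient variance
    rms = np.sqrt(np.mean(frames**2, axis=1))
    loud = np.percentile(rms, 95)
    if loud > 0:
        frames = frames[rms > 0.05 * loud]
    frames = frames * np.hanning(n_frame)
    n_fft = int(2 ** np.ceil(np.log2(n_frame)))
    power = np.abs(np.fft.rfft(frames, n_fft, axis=1)) ** 2
    fb = _mel_filterbank(params.n_mels, n_fft, fs, min(params.fmax_hz, fs / 2))
    energy = power @ fb.T
    log_e = np.log(np.maximum(energy, 1e-30))
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)
    return coeffs[:, 1 : params.n_coeffs + 1]  # drop the gain coefficient


def _delta(coeffs: np.ndarray, window: int) -> np.ndarray:
    n = coeffs.shape[0]
    pad = np.pad(coeffs, ((window, window), (0, 0)), mode="edge")
    num = sum(
        k * (pad[window + k : window + k + n] - pad[window - k : window - k + n])
        for k in range(1, window + 1)
    )
    denom = 2.0 * sum(k * k for k in range(1, window + 1))
    return num / denom


def mfcc_stability(
    rec: VoiceRecording, params: MfccParams | None = None
) -> tuple[float, float]:
    """Articulation-stability indices (MFCC, delta-MFCC).

    Returns ``(mfcc, dmfcc)``: the mean over coefficients 1–12 of each
    coefficient's SD across frames, and the same on the delta coefficients
    multiplied by ``delta_scale``.
    """
    if params is None:
        params = MfccParams()
    fs = rec.sample_rate
    x = rec.samples
    if fs != params.analysis_fs:
        g = np.gcd(int(fs), int(params.analysis_fs))
        x = sps.resample_poly(x, int(params.analysis_fs) // g, int(fs) // g)
        fs = params.analysis_fs
    coeffs = _mfcc_frames(x, fs, params)
    if coeffs.shape[0] < 10:
        raise InsufficientDataError("MFCC stability needs at least 10 frames")
    mfcc = float(np.mean(np.std(coeffs, axis=0)))
    deltas = _delta(coeffs, params.delta_window)
    dmfcc = float(params.delta_scale * np.mean(np.std(deltas, axis=0)))
    return mfcc, dmfcc
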