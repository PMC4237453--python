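"""Irregular-vibration, perturbation and noise measures.

Covers six measures: pitch variability on the semitone scale (F0 SD),
cycle-to-cycle frequency and amplitude perturbation (jitter, shimmer),
harmonics-to-noise ratio (HNR), recurrence period density entropy (RPDE)
and detrended fluctuation analysis (DFA).

Jitter and shimmer use the *local* definition: the mean absolute
cycle-to-cycle difference relative to the mean, in percent.  Both are
computed per continuous voiced span and averaged with span weights, so a
voice break never contributes an artefactual "cycle".  Cycles whose period
or amplitude is implausible relative to the span median (tracking slips,
onset/offset transients) are excluded, following the usual practice of
perturbation analysis software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .audio_io import VoiceRecording
from .pitch import PitchTrack, PulseSequence

__all__ = [
    "NonlinearParams",
    "f0_sd_semitones",
    "jitter_local",
    "shimmer_local",
    "jitter_of_pulses",
    "shimmer_of_pulses",
    "hnr_db",
    "rpde",
    "dfa",
    "InsufficientDataError",
]

#: Periods deviating more than this fraction from the span median are
#: treated as tracking errors and excluded from jitter.
PERIOD_GATE = 0.20
#: Same for cycle amplitudes in shimmer (onset/offset transients).
AMPLITUDE_GATE = 0.40


class InsufficientDataError(ValueError):
    """Not enough voiced material for the requested measure."""


@dataclass(frozen=True)
class NonlinearParams:
    """Configuration of the nonlinear measures (RPDE, DFA).

    RPDE embeds the signal (dimension ``rpde_embed_dim``, delay estimated
    from the first autocorrelation zero crossing unless given) and
    normalises the entropy of the first-return-time distribution by
    ``ln(rpde_tmax)``.  DFA fits the log-log slope of detrended fluctuation
    over ``dfa_n_scales`` log-spaced window lengths between
    ``dfa_scale_min_s`` and ``dfa_scale_max_s``.
    """

    rpde_embed_dim: int = 4
    rpde_delay: int | None = None  # samples at the analysis rate; None = auto
    rpde_radius: float = 0.12  # fraction of signal SD
    rpde_tmax_s: float | None = None  # None = 3 periods at 75 Hz
    rpde_fs: float = 11025.0  # analysis rate the signal is decimated to
    dfa_scale_min_s: float = 0.001
    dfa_scale_max_s: float = 0.100
    dfa_n_scales: int = 10
    dfa_norm: str = "logistic"  # or "none" to return the raw exponent

    def __post_init__(self) -> None:
        if self.rpde_embed_dim < 2:
            raise ValueError("rpde_embed_dim must be at least 2")
        if self.dfa_n_scales < 4:
            raise ValueError("dfa needs at least 4 scales")
        if self.dfa_norm not in ("logistic", "none"):
            raise ValueError("dfa_norm must be 'logistic' or 'none'")


# ---------------------------------------------------------------------------
# pitch variability
# ---------------------------------------------------------------------------


def f0_sd_semitones(track: PitchTrack) -> float:
    """Standard deviation of voiced F0 on the semitone scale.

    The semitone transform ``12*log2(F0)`` makes the measure independent of
    the speaker's register (any fixed reference frequency cancels in the
    standard deviation), hence gender-independent.
    """
    f0 = track.f0[track.voiced]
    if f0.size < 2:
        raise InsufficientDataError("need at least 2 voiced frames for F0 SD")
    return float(np.std(12.0 * np.log2(f0)))


# ---------------------------------------------------------------------------
# jitter / shimmer
# ---------------------------------------------------------------------------


def _local_perturbation(values: np.ndarray, gate: float) -> float:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise InsufficientDataError("need at least 3 cycles")
    med = np.median(values)
    if med <= 0:
        raise InsufficientDataError("non-positive cycle statistics")
    ok = np.abs(values / med - 1.0) <= gate
    pair = ok[1:] & ok[:-1]
    if pair.sum() < 2:
        raise InsufficientDataError("too few plausible cycle pairs")
    diffs = np.abs(np.diff(values))[pair]
    return 100.0 * float(np.mean(diffs)) / float(np.mean(values[ok]))


def jitter_local(periods: np.ndarray) -> float:
    """Local jitter: 100 * mean|T[i+1]-T[i]| / mean T, in percent."""
    return _local_perturbation(periods, PERIOD_GATE)


def shimmer_local(amplitudes: np.ndarray) -> float:
    """Local shimmer: 100 * mean|A[i+1]-A[i]| / mean A, in percent."""
    return _local_perturbation(amplitudes, AMPLITUDE_GATE)


#: Cycles dropped at each end of a voiced span before computing the local
#: statistic: onset/offset transients are not steady-state perturbation.
#: Amplitudes need a deeper trim (the onset ramp passes the plausibility
#: gate for several cycles); periods only suffer at the outermost pulse.
EDGE_CYCLES_PERIOD = 1
EDGE_CYCLES_AMPLITUDE = 3


def _per_span(
    seq: PulseSequence, values: np.ndarray, gate: float, edge: int
) -> float:
    """Weighted average of the local statistic over voiced spans."""
    results = []
    weights = []
    within = seq.within_span
    for span in np.unique(seq.span_ids):
        mask = within & (seq.span_ids[:-1] == span)
        v = values[mask]
        if edge and v.size >= 2 * edge + 5:
            v = v[edge:-edge]
        v = v[np.isfinite(v)]
        if v.size < 3:
            continue
        try:
            results.append(_local_perturbation(v, gate))
        except InsufficientDataError:
            continue
        weights.append(v.size)
    if not results:
        raise InsufficientDataError("no voiced span has enough cycles")
    return float(np.average(results, weights=weights))


def jitter_of_pulses(seq: PulseSequence) -> float:
    """Jitter aggregated over voiced spans of a pulse sequence."""
    return _per_span(seq, seq.periods, PERIOD_GATE, EDGE_CYCLES_PERIOD)


def shimmer_of_pulses(seq: PulseSequence) -> float:
    """Shimmer aggregated over voiced spans of a pulse sequence."""
    return _per_span(seq, seq.amplitudes, AMPLITUDE_GATE, EDGE_CYCLES_AMPLITUDE)


# ---------------------------------------------------------------------------
# harmonics-to-noise ratio
# ---------------------------------------------------------------------------


def hnr_db(track: PitchTrack) -> float:
    """Mean harmonics-to-noise ratio over voiced frames, in dB.

    Per frame the normalised autocorrelation strength ``r`` at the F0 lag
    estimates the harmonic fraction of the frame's power, so the frame HNR
    is ``10*log10(r/(1-r))``.  Per-frame strengths are winsorised at their
    10th/90th percentiles before averaging: the log-ratio transform has a
    heavy right tail for nearly periodic frames, and the plain mean would
    be dominated by a handful of frames where the strength estimate
    saturates.
    """
    r = track.voicing_strength[track.voiced]
    if r.size == 0:
        raise InsufficientDataError("no voiced frames for HNR")
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    if r.size >= 10:
        r = np.clip(r, np.percentile(r, 10), np.percentile(r, 90))
    return float(np.mean(10.0 * np.log10(r / (1.0 - r))))


# ---------------------------------------------------------------------------
# recurrence period density entropy
# ---------------------------------------------------------------------------


def _first_ac_zero(x: np.ndarray, max_lag: int) -> int:
    x = x - x.mean()
    ac = np.correlate(x[: 4 * max_lag], x[: 4 * max_lag], "full")
    ac = ac[len(ac) // 2 :]
    below = np.flatnonzero(ac[: max_lag + 1] <= 0)
    return int(below[0]) if below.size else max_lag // 2


def rpde(rec: VoiceRecording, params: NonlinearParams | None = None) -> float:
    """Recurrence period density entropy, in [0, 1].

    The signal is time-delay embedded and, for a strided set of reference
    points, the first return time into an epsilon-ball around the reference
    (after first leaving it) is collected.  The normalised entropy of the
    return-time density is 0 for a perfectly periodic signal (all returns
    at one period) and approaches 1 as the return times spread out.
    """
    if params is None:
        params = NonlinearParams()
    fs = rec.sample_rate
    dec = max(int(round(fs / params.rpde_fs)), 1)
    x = sps.decimate(rec.samples, dec, zero_phase=True) if dec > 1 else rec.samples
    fs_a = fs / dec
    if len(x) < fs_a:
        raise InsufficientDataError("RPDE needs at least 1 s of signal")
    x = (x - x.mean()) / (x.std() + 1e-30)

    tmax_s = params.rpde_tmax_s if params.rpde_tmax_s is not None else 3.0 / 75.0
    tmax = int(round(tmax_s * fs_a))
    delay = params.rpde_delay
    if delay is None:
        delay = max(_first_ac_zero(x, int(fs_a / 75.0)), 1)
    m = params.rpde_embed_dim
    n_vec = len(x) - (m - 1) * delay
    if n_vec <= tmax + 1:
        raise InsufficientDataError("signal too short for RPDE embedding")
    emb = np.stack([x[i * delay : i * delay + n_vec] for i in range(m)], axis=1)
    eps = params.rpde_radius * np.sqrt(m)  # x has unit SD per coordinate

    stride = max(n_vec // 3000, 1)
    refs = np.arange(0, n_vec - tmax - 1, stride)
    counts = np.zeros(tmax + 1)
    for i in refs:
        d2 = np.sum((emb[i + 1 : i + tmax + 1] - emb[i]) ** 2, axis=1)
        inside = d2 <= eps * eps
        out = np.flatnonzero(~inside)
        if out.size == 0:
            continue
        back = np.flatnonzero(inside[out[0] :])
        if back.size == 0:
            continue
        counts[out[0] + back[0] + 1] += 1
    total = counts.sum()
    if total == 0:
        raise InsufficientDataError(
            "no recurrences found; epsilon radius may be too small"
        )
    p = counts / total
    nz = p[p > 0]
    h = -float(np.sum(nz * np.log(nz)))
    return h / np.log(tmax)


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------


def dfa(
    rec: VoiceRecording,
    params: NonlinearParams | None = None,
    return_alpha: bool = False,
) -> float:
    """Detrended fluctuation analysis scaling exponent, normalised to (0,1).

    The mean-removed signal is integrated; in non-overlapping windows of
    each scale a least-squares line is removed and the RMS residual F(L)
    recorded; the scaling exponent ``alpha`` is the slope of log F(L) vs
    log L.  White noise gives ``alpha = 0.5``; turbulent aspiration noise
    in voice gives larger exponents.  The default output maps ``alpha``
    through the logistic function; ``return_alpha=True`` (or
    ``dfa_norm='none'``) returns the raw exponent.
    """
    if params is None:
        params = NonlinearParams()
    x = np.asarray(rec.samples, dtype=float)
    fs = rec.sample_rate
    if len(x) < fs:
        raise InsufficientDataError("DFA needs at least 1 s of signal")
    if np.ptp(x) == 0:
        raise InsufficientDataError("constant signal has no fluctuation")
    y = np.cumsum(x - x.mean())
    scales = np.unique(
        np.round(
            np.geomspace(
                max(params.dfa_scale_min_s * fs, 4),
                min(params.dfa_scale_max_s * fs, len(x) // 4),
                params.dfa_n_scales,
            )
        ).astype(int)
    )
    if scales.size < 4:
        raise InsufficientDataError("too few usable DFA scales")
    fluct = np.empty(scales.size)
    for k, L in enumerate(scales):
        n_win = len(y) // L
        seg = y[: n_win * L].reshape(n_win, L)
        t = np.arange(L)
        t_mean = t.mean()
        t_c = t - t_mean
        denom = np.sum(t_c**2)
        slope = seg @ t_c / denom
        inter = seg.mean(axis=1)
        resid = seg - (inter[:, None] + slope[:, None] * t_c[None, :])
        fluct[k] = np.sqrt(np.mean(resid**2))
    alpha, _ = np.polyfit(np.log(scales), np.log(fluct + 1e-300), 1)
    if return_alpha or params.dfa_norm == "none":
        return float(alpha)
    return float(1.0 / (1.0 + np.exp(-alpha)))
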