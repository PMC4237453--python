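"""Synthetic sustained-vowel generator with known ground truth.

No recordings are distributed with this package, so every analysis stage is
validated by parameter recovery on synthetic phonation.  The generator is a
source-filter model: a glottal pulse train whose cycle lengths carry jitter
and slow F0 tremor, and whose per-cycle amplitudes carry shimmer and
amplitude tremor, is passed through a cascade of second-order formant
resonators (default: adult /a/) and mixed with Gaussian aspiration noise at
a gain calibrated to the requested harmonics-to-noise ratio.  Voice-break
events override the source locally: a *pitch drop* multiplies the
instantaneous F0 by ``drop_ratio`` (default one half) with continuous phase,
a *vocal arrest* silences the source entirely.

Calibration notes
-----------------
Jitter and shimmer are injected as i.i.d. Gaussian perturbations of cycle
period and amplitude.  The local jitter statistic is
``100 * mean|dT| / mean T``; for i.i.d. Gaussian period noise with relative
standard deviation s, ``E|T[i+1]-T[i]| = 2 s T0 / sqrt(pi)``, so the noise
scale is set to ``jitter_pct * sqrt(pi) / 200`` (likewise for shimmer) and
the *injected* percentage equals the expected value of the measured local
statistic.  The harmonic and noise components are returned separately in
the ground truth so HNR calibration can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .audio_io import VoiceRecording

__all__ = [
    "BreakEvent",
    "SynthSpec",
    "GroundTruth",
    "CohortSpec",
    "ParamDist",
    "DEFAULT_FORMANTS",
    "synth_vowel",
    "synth_cohort",
    "sample_feature_table",
]

#: Default formant targets (centre Hz, bandwidth Hz) for an adult /a/.
DEFAULT_FORMANTS: tuple[tuple[float, float], ...] = (
    (700.0, 60.0),
    (1220.0, 70.0),
    (2600.0, 110.0),
)

#: Aspiration noise attenuation inside a vocal arrest (breath level; the
#: source is zero there, and phonation noise stops with phonation).
ARREST_NOISE_GAIN = 0.1


@dataclass(frozen=True)
class BreakEvent:
    """One voice-break event injected into a synthetic vowel."""

    kind: str  # "pitch_drop" | "vocal_arrest"
    onset_s: float
    duration_s: float
    drop_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("pitch_drop", "vocal_arrest"):
            raise ValueError(f"unknown break kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("break duration must be positive")
        if self.kind == "pitch_drop" and not 0.0 < self.drop_ratio <= 1.0:
            raise ValueError("drop_ratio must lie in (0, 1]")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class SynthSpec:
    """Ground-truth parameters of one synthetic sustained vowel.

    Defaults describe a clean modal phonation; pathology is added by raising
    jitter/shimmer, lowering ``hnr_db``, enabling tremor, or appending
    break events.
    """

    duration_s: float = 5.0
    f0_hz: float = 130.0
    jitter_pct: float = 0.5
    shimmer_pct: float = 3.0
    hnr_db: float = 22.0
    tremor_rate_hz: float = 4.0
    tremor_f0_extent_pct: float = 0.0
    tremor_amp_extent_pct: float = 0.0
    #: slow involuntary pitch drift (RMS, semitones): real sustained
    #: phonation wanders by ~0.3 st even in healthy speakers
    f0_wander_st: float = 0.25
    #: slow articulatory drift: depth of the formant-frequency excursion (%)
    drift_extent_pct: float = 2.0
    #: bandwidth of the wander/drift processes (Hz, below the tremor band)
    wander_rate_hz: float = 1.0
    break_events: tuple[BreakEvent, ...] = ()
    formants: tuple[tuple[float, float], ...] = DEFAULT_FORMANTS
    fade_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("jitter/shimmer must be non-negative")
        events = tuple(sorted(self.break_events, key=lambda e: e.onset_s))
        for ev in events:
            if ev.onset_s < 0 or ev.offset_s > self.duration_s:
                raise ValueError("break event outside [0, duration_s]")
        for a, b in zip(events, events[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError("break events overlap")
        object.__setattr__(self, "break_events", events)


@dataclass
class GroundTruth:
    """Everything injected into a synthetic vowel, for recovery tests."""

    spec: SynthSpec
    sample_rate: float
    seed: int
    pulse_times: np.ndarray  # glottal closure instants, seconds
    periods: np.ndarray  # cycle lengths, seconds
    amplitudes: np.ndarray  # per-pulse source amplitudes
    harmonic: np.ndarray  # formant-filtered source, before noise
    noise: np.ndarray  # additive noise component actually mixed in
    achieved_hnr_db: float  # harmonic/noise power over voiced, non-event span

    def as_row(self) -> dict:
        s = self.spec
        return {
            "duration_s": s.duration_s,
            "f0_hz": s.f0_hz,
            "jitter_pct": s.jitter_pct,
            "shimmer_pct": s.shimmer_pct,
            "hnr_db": s.hnr_db,
            "tremor_rate_hz": s.tremor_rate_hz,
            "tremor_f0_extent_pct": s.tremor_f0_extent_pct,
            "tremor_amp_extent_pct": s.tremor_amp_extent_pct,
            "f0_wander_st": s.f0_wander_st,
            "drift_extent_pct": s.drift_extent_pct,
            "n_breaks": len(s.break_events),
            "n_arrests": sum(e.kind == "vocal_arrest" for e in s.break_events),
            "n_pitch_drops": sum(e.kind == "pitch_drop" for e in s.break_events),
            "achieved_hnr_db": self.achieved_hnr_db,
            "seed": self.seed,
        }


def _resonator_sos(freq: float, bw: float, fs: float) -> np.ndarray:
    """Second-order all-pole resonator section (unit gain at resonance)."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * freq / fs
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    # normalise so the peak gain is ~1 regardless of bandwidth
    gain = (1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2.0 * theta) + r * r)
    return np.array([[gain, 0.0, 0.0] + a])


def _event_at(events: tuple[BreakEvent, ...], t: float) -> BreakEvent | None:
    for ev in events:
        if ev.onset_s <= t < ev.offset_s:
            return ev
    return None


def _slow_noise(rng: np.random.Generator, duration_s: float, rate_hz: float):
    """Unit-RMS low-passed noise process sampled at 100 Hz; returns an
    interpolator ``f(t)``.  Models slow involuntary drift (pitch wander,
    articulatory drift) below the tremor band."""
    grid_fs = 100.0
    n = max(int(duration_s * grid_fs) + 2, 16)
    z = rng.standard_normal(n)
    sos = sps.butter(2, min(rate_hz / (grid_fs / 2), 0.99), output="sos")
    z = sps.sosfiltfilt(sos, z)
    rms = np.sqrt(np.mean(z**2))
    if rms > 0:
        z = z / rms
    t_grid = np.arange(n) / grid_fs
    return lambda t: np.interp(t, t_grid, z)


def synth_vowel(
    spec: SynthSpec, sample_rate: float = 44100.0, seed: int = 0
) -> tuple[VoiceRecording, GroundTruth]:
    """Synthesize one sustained vowel with the given ground truth.

    Deterministic for fixed ``(spec, sample_rate, seed)``.

    Raises
    ------
    ValueError
        For an invalid spec (overlapping events are rejected at spec
        construction) or a sample rate below 8 kHz.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be at least 8 kHz")
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * sample_rate))
    fs = float(sample_rate)

    jitter_scale = spec.jitter_pct * np.sqrt(np.pi) / 200.0
    shimmer_scale = spec.shimmer_pct * np.sqrt(np.pi) / 200.0

    wander = (
        _slow_noise(rng, spec.duration_s, spec.wander_rate_hz)
        if spec.f0_wander_st > 0
        else None
    )
    drift = (
        _slow_noise(rng, spec.duration_s, spec.wander_rate_hz)
        if spec.drift_extent_pct > 0
        else None
    )

    # --- glottal cycle sequence ------------------------------------------
    pulse_times: list[float] = []
    periods: list[float] = []
    amplitudes: list[float] = []
    source = np.zeros(n)
    t = 1.0 / spec.f0_hz  # first pulse after one nominal cycle
    while t < spec.duration_s:
        f0_inst = spec.f0_hz
        if wander is not None:
            f0_inst *= 2.0 ** (spec.f0_wander_st * float(wander(t)) / 12.0)
        if spec.tremor_f0_extent_pct > 0:
            f0_inst *= 1.0 + spec.tremor_f0_extent_pct / 100.0 * np.sin(
                2.0 * np.pi * spec.tremor_rate_hz * t
            )
        ev = _event_at(spec.break_events, t)
        if ev is not None and ev.kind == "pitch_drop":
            f0_inst *= ev.drop_ratio
        period = (1.0 / f0_inst) * (1.0 + jitter_scale * rng.standard_normal())
        period = max(period, 0.25 / spec.f0_hz)

        amp = 1.0 + shimmer_scale * rng.standard_normal()
        if spec.tremor_amp_extent_pct > 0:
            amp *= 1.0 + spec.tremor_amp_extent_pct / 100.0 * np.sin(
                2.0 * np.pi * spec.tremor_rate_hz * t
            )
        amp = max(amp, 0.05)

        arrested = ev is not None and ev.kind == "vocal_arrest"
        if not arrested:
            # linear-interpolated impulse keeps sub-sample pulse timing
            idx = t * fs
            i0 = int(np.floor(idx))
            frac = idx - i0
            if i0 + 1 < n:
                source[i0] += amp * (1.0 - frac)
                source[i0 + 1] += amp * frac
            pulse_times.append(t)
            periods.append(period)
            amplitudes.append(amp)
        t += period

    if not pulse_times:
        raise ValueError("no glottal pulses generated (harmonic power is zero)")

    # --- formant filtering ------------------------------------------------
    harmonic = source
    for freq, bw in spec.formants:
        harmonic = sps.sosfilt(_resonator_sos(freq, bw, fs), harmonic)
    if drift is not None:
        # slow articulatory drift: crossfade with a copy filtered through
        # slightly shifted formants, driven by a sub-tremor-rate process
        shifted = source
        for freq, bw in spec.formants:
            shifted = sps.sosfilt(
                _resonator_sos(freq * (1.0 + spec.drift_extent_pct / 100.0), bw, fs),
                shifted,
            )
        tgrid_d = np.arange(n) / fs
        m = 0.5 + 0.5 * np.tanh(drift(tgrid_d))
        harmonic = (1.0 - m) * harmonic + m * shifted

    # onset/offset ramp applied to the harmonic part
    n_fade = int(round(spec.fade_ms / 1000.0 * fs))
    if n_fade > 0 and 2 * n_fade < n:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        harmonic[:n_fade] *= ramp
        harmonic[-n_fade:] *= ramp[::-1]

    # --- noise calibrated to the target HNR ------------------------------
    # Aspiration noise originates at the glottis and is shaped by the same
    # vocal tract; it is filtered through the formant resonators with
    # widened bandwidths so its autocorrelation at pitch lags is negligible
    # and the injected HNR stays well defined for autocorrelation analysis.
    tgrid = np.arange(n) / fs
    in_event = np.zeros(n, dtype=bool)
    for ev in spec.break_events:
        in_event |= (tgrid >= ev.onset_s) & (tgrid < ev.offset_s)
    guard = n_fade if n_fade > 0 else 0
    steady = ~in_event
    if guard:
        steady[:guard] = False
        steady[-guard:] = False
    if not steady.any():
        steady = ~in_event
    p_harm = float(np.mean(harmonic[steady] ** 2))
    if p_harm <= 0:
        raise ValueError("target HNR unreachable: harmonic power is zero")
    noise = rng.standard_normal(n)
    for freq, bw in spec.formants:
        noise = sps.sosfilt(_resonator_sos(freq, 4.0 * bw, fs), noise)
    noise_rms = float(np.sqrt(np.mean(noise[steady] ** 2)))
    noise_sigma = np.sqrt(p_harm / 10.0 ** (spec.hnr_db / 10.0))
    noise *= noise_sigma / noise_rms
    arrest = np.zeros(n, dtype=bool)
    for ev in spec.break_events:
        if ev.kind == "vocal_arrest":
            arrest |= (tgrid >= ev.onset_s) & (tgrid < ev.offset_s)
    noise[arrest] *= ARREST_NOISE_GAIN

    mix = harmonic + noise
    peak = np.max(np.abs(mix))
    if peak > 0:
        scale = 0.8 / peak
        mix = mix * scale
        harmonic = harmonic * scale
        noise = noise * scale

    p_noise = float(np.mean(noise[steady] ** 2))
    achieved = 10.0 * np.log10(np.mean(harmonic[steady] ** 2) / p_noise)

    rec = VoiceRecording(mix, fs, source_path=f"synth(seed={seed})")
    truth = GroundTruth(
        spec=spec,
        sample_rate=fs,
        seed=seed,
        pulse_times=np.asarray(pulse_times),
        periods=np.asarray(periods),
        amplitudes=np.asarray(amplitudes),
        harmonic=harmonic,
        noise=noise,
        achieved_hnr_db=achieved,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamDist:
    """Truncated-Gaussian sampling distribution for one SynthSpec field."""

    mean: float
    sd: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("distribution SD must be non-negative")

    def draw(self, rng: np.random.Generator) -> float:
        x = rng.normal(self.mean, self.sd)
        if self.low is not None:
            x = max(x, self.low)
        if self.high is not None:
            x = min(x, self.high)
        return x


@dataclass(frozen=True)
class CohortSpec:
    """Two-group synthetic cohort description.

    ``group_param_distributions`` maps group name -> {SynthSpec field ->
    ParamDist}.  ``break_rate`` (expected break events per recording,
    Poisson) and ``arrest_fraction`` control event injection per group.
    """

    n_per_group: int
    group_param_distributions: dict
    break_rate: dict | None = None
    arrest_fraction: dict | None = None
    min_break_events: dict | None = None  # per-group floor on event count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        for dists in self.group_param_distributions.values():
            for d in dists.values():
                if d.sd < 0:
                    raise ValueError("degenerate distribution: SD < 0")


def _draw_events(
    rng: np.random.Generator,
    duration_s: float,
    rate: float,
    arrest_fraction: float,
    f0_hz: float,
    min_events: int = 0,
) -> tuple[BreakEvent, ...]:
    """Draw non-overlapping break events, kept clear of the span edges.

    Events are placed at least 0.6 s after onset and 1.3 s before the end,
    at least 0.5 s apart, so each injected event satisfies the counting
    rules (modal lead and terminal guard) by construction.
    """
    n_events = max(rng.poisson(rate), min_events)
    if n_events == 0:
        return ()
    lo, hi = 0.6, duration_s - 1.3 - 0.3
    if hi <= lo:
        return ()
    events = []
    onsets: list[float] = []
    for _ in range(n_events):
        for _attempt in range(20):
            onset = rng.uniform(lo, hi)
            dur = rng.uniform(0.05, 0.30)
            if all(abs(onset - o) > dur + 0.5 for o in onsets):
                onsets.append(onset)
                kind = (
                    "vocal_arrest"
                    if rng.uniform() < arrest_fraction
                    else "pitch_drop"
                )
                events.append(BreakEvent(kind, onset, dur, drop_ratio=0.5))
                break
    return tuple(events)


def synth_cohort(
    cohort: CohortSpec, sample_rate: float = 44100.0
) -> tuple[list[tuple[str, str, VoiceRecording]], "pd.DataFrame"]:
    """Generate one recording per synthetic subject.

    Returns ``(recordings, truth_table)`` where ``recordings`` is a list of
    ``(subject_id, group, VoiceRecording)`` and the table holds one row of
    injected parameters per subject.  Reproducible for a fixed cohort seed.
    """
    import pandas as pd

    rng = np.random.default_rng(cohort.seed)
    recordings = []
    rows = []
    for group, dists in cohort.group_param_distributions.items():
        rate = (cohort.break_rate or {}).get(group, 0.0)
        arrest_frac = (cohort.arrest_fraction or {}).get(group, 0.5)
        min_evts = (cohort.min_break_events or {}).get(group, 0)
        for i in range(cohort.n_per_group):
            kwargs = {name: d.draw(rng) for name, d in dists.items()}
            spec = SynthSpec(**kwargs)
            if rate > 0 or min_evts > 0:
                events = _draw_events(
                    rng, spec.duration_s, rate, arrest_frac, spec.f0_hz, min_evts
                )
                spec = replace(spec, break_events=events)
            subject_seed = int(rng.integers(0, 2**31 - 1))
            rec, truth = synth_vowel(spec, sample_rate, seed=subject_seed)
            sid = f"{group}{i:03d}"
            recordings.append((sid, group, rec))
            row = {"subject": sid, "group": group}
            row.update(truth.as_row())
            rows.append(row)
    return recordings, pd.DataFrame(rows)


def sample_feature_table(
    group_params: dict,
    n_per_group: int,
    seed: int = 0,
) -> "pd.DataFrame":
    """Draw a labelled feature table directly, without audio.

    ``group_params`` maps group name -> {feature name -> (mean, sd)}; each
    feature is sampled independently Gaussian.  Used to exercise the
    decision and classification stages against known class-conditional
    distributions.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for group, feats in group_params.items():
        for mean, sd in feats.values():
            if sd < 0:
                raise ValueError("feature SD must be non-negative")
        for i in range(n_per_group):
            row = {"subject": f"{group}{i:03d}", "group": group}
            for name, (mean, sd) in feats.items():
                row[name] = rng.normal(mean, sd) if sd > 0 else mean
            rows.append(row)
    return pd.DataFrame(rows)
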