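"""Reading, writing and trimming of sustained-phonation recordings.

A :class:`VoiceRecording` is the package's in-memory audio container: a mono
float array in [-1, 1] plus its sample rate.  :func:`trim_to_phonation`
isolates the phonation span from surrounding silence so that duration-based
measures (maximum phonation time, time to first voice break, degree of vocal
arrest) are defined on the vowel itself, while *internal* silences — vocal
arrests, which are part of the pathology — are preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "VoiceRecording",
    "AudioFormatError",
    "NoPhonationError",
    "read_wav",
    "write_wav",
    "trim_to_phonation",
    "frame_rms",
]

#: Default silence threshold for trimming, as a fraction of the peak frame RMS.
DEFAULT_SILENCE_RATIO = 0.03

#: Frame length used for RMS-based silence detection (seconds).
RMS_FRAME_S = 0.010


class AudioFormatError(ValueError):
    """The file is not a readable PCM WAV or contains no audio."""


class NoPhonationError(ValueError):
    """No frame of the recording exceeds the phonation threshold."""


@dataclass(frozen=True)
class VoiceRecording:
    """Mono audio signal with provenance.

    Parameters
    ----------
    samples
        Amplitude sequence, dimensionless, expected in [-1, 1].
    sample_rate
        Sampling frequency in Hz.
    source_path
        Optional provenance string (file path or synthesis tag).
    """

    samples: np.ndarray
    sample_rate: float
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("VoiceRecording is mono: samples must be 1-D")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def time_axis(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def read_wav(path: str) -> VoiceRecording:
    """Read a PCM WAV file into a :class:`VoiceRecording`.

    Integer PCM is scaled to [-1, 1] by the full-scale value of its bit
    depth; float WAV is taken as-is.  Stereo input is averaged to mono with
    a logged warning.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # chunk warnings from odd encoders
            rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise AudioFormatError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path!r} contains no audio samples")
    if data.ndim == 2:
        logger.warning("%s is multi-channel; averaging to mono", path)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return VoiceRecording(samples, float(rate), source_path=str(path))


def write_wav(path: str, rec: VoiceRecording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, int(rec.sample_rate), pcm)


def frame_rms(samples: np.ndarray, sample_rate: float,
              frame_s: float = RMS_FRAME_S) -> tuple[np.ndarray, np.ndarray]:
    """RMS per non-overlapping frame; returns (frame centre times, rms)."""
    n = max(int(round(frame_s * sample_rate)), 1)
    n_frames = len(samples) // n
    if n_frames == 0:
        return np.array([]), np.array([])
    trimmed = samples[: n_frames * n].reshape(n_frames, n)
    rms = np.sqrt(np.mean(trimmed**2, axis=1))
    times = (np.arange(n_frames) + 0.5) * n / sample_rate
    return times, rms


def trim_to_phonation(
    rec: VoiceRecording,
    silence_ratio: float = DEFAULT_SILENCE_RATIO,
) -> tuple[VoiceRecording, float, float]:
    """Cut leading and trailing silence around the phonation span.

    The span runs from the first to the last 10-ms frame whose RMS exceeds
    ``silence_ratio`` times the peak frame RMS.  Internal silences are kept:
    only the boundaries move.

    Returns
    -------
    (trimmed recording, onset seconds, offset seconds)
        Onset/offset are relative to the start of ``rec``.

    Raises
    ------
    NoPhonationError
        If no frame exceeds the threshold.
    """
    if not 0.0 < silence_ratio < 1.0:
        raise ValueError("silence_ratio must be in (0, 1)")
    n = max(int(round(RMS_FRAME_S * rec.sample_rate)), 1)
    _, rms = frame_rms(rec.samples, rec.sample_rate)
    if rms.size == 0 or rms.max() <= 0:
        raise NoPhonationError("no phonation detected")
    above = np.flatnonzero(rms > silence_ratio * rms.max())
    if above.size == 0:
        raise NoPhonationError("no phonation detected")
    start = above[0] * n
    stop = min((above[-1] + 1) * n, len(rec.samples))
    trimmed = VoiceRecording(
        rec.samples[start:stop], rec.sample_rate, source_path=rec.source_path
    )
    return trimmed, start / rec.sample_rate, stop / rec.sample_rate
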