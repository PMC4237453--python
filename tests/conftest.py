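import numpy as np
import pytest
from hypothesis import settings

from dysphonia.synth import BreakEvent, SynthSpec, synth_vowel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

FS = 44100.0


@pytest.fixture(scope="session")
def clean_vowel():
    """A clean modal vowel: low jitter/shimmer, high HNR, no events."""
    spec = SynthSpec(
        duration_s=3.0, f0_hz=130.0, jitter_pct=0.1, shimmer_pct=0.5, hnr_db=30.0
    )
    return synth_vowel(spec, FS, seed=11)


@pytest.fixture(scope="session")
def perturbed_vowel():
    """A typical healthy vowel with moderate perturbation and noise."""
    spec = SynthSpec(
        duration_s=3.0, f0_hz=128.0, jitter_pct=0.6, shimmer_pct=3.0, hnr_db=22.0
    )
    return synth_vowel(spec, FS, seed=12)


@pytest.fixture(scope="session")
def vowel_with_breaks():
    """A vowel with one mid-phonation arrest and one pitch drop."""
    spec = SynthSpec(
        duration_s=5.0,
        f0_hz=120.0,
        jitter_pct=0.5,
        shimmer_pct=2.5,
        hnr_db=24.0,
        break_events=(
            BreakEvent("vocal_arrest", 2.0, 0.2),
            BreakEvent("pitch_drop", 3.2, 0.15, 0.5),
        ),
    )
    return synth_vowel(spec, FS, seed=13)


@pytest.fixture(scope="session")
def clean_analysis(clean_vowel):
    import dysphonia as dp

    rec, _ = clean_vowel
    return dp.analyze_recording(rec)


@pytest.fixture(scope="session")
def breaks_analysis(vowel_with_breaks):
    import dysphonia as dp

    rec, _ = vowel_with_breaks
    return dp.analyze_recording(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
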