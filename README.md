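# dysphonia

Acoustic analysis of sustained vowel phonation for objective dysphonia
assessment: fifteen measures across seven phonatory dimensions,
subject-level decision-theoretic classification of affected dimensions,
cohort statistics with effect sizes, and an SVM feature-combination search —
plus a synthetic pathological-vowel generator with full ground truth, so
every stage is validated by parameter recovery without any clinical
recordings.

The package targets speech scientists and clinical researchers who analyse
sustained /a/ phonations (e.g. in neurodegenerative disease cohorts such as
premanifest Huntington disease) and want a reproducible, scriptable pipeline
from WAV file to cohort report.

## The measures

| dimension | measures |
| --- | --- |
| airflow insufficiency | MPT (s), FOVB (s) |
| aperiodicity | NVB (−), DPB (%), DVA (%) |
| irregular vibration | F0 SD (st), RPDE (−) |
| signal perturbation | jitter (%), shimmer (%) |
| increased noise | HNR (dB), DFA (−) |
| vocal tremor | FTRI (%), ATRI (%) |
| articulation deficiency | MFCC (−), ΔMFCC (−) |

Voicing and F0 come from a windowed-autocorrelation tracker (voicing
threshold 0.45 on the normalised autocorrelation peak). Glottal pulses are
located per predicted cycle and refined on the LPC residual. A voice break
is an inter-pulse gap longer than 1.25/(pitch floor), counted only after at
least 250 ms of continuous phonation and not within the final second.
Jitter and shimmer are the local cycle-to-cycle statistics
`100·mean|x[i+1]−x[i]|/mean x` on periods and cycle amplitudes; per-frame
HNR is `10·log10(r/(1−r))` at the F0 lag; RPDE is the normalised entropy of
the state-space first-return-time density; DFA is the logistic-mapped
detrended-fluctuation exponent; FTRI/ATRI are the strongest 1.5–15 Hz
modulation components of the F0/amplitude contours as a percentage of the
contour mean; the MFCC indices are mean standard deviations of mel-cepstral
coefficients 1–12 (Δ variant ×10).

Per-dimension decisions use the minimum-error likelihood-ratio rule between
class-conditional Gaussians with a one-sided guard (only the pathological
tail can be flagged); a dimension is affected when any of its measures votes
pathological. Group comparisons follow a Kolmogorov–Smirnov normality gate
into t-test or Mann–Whitney U, with per-dimension Bonferroni adjustment and
pooled-SD Cohen's d. Discrimination uses an RBF-kernel SVM with repeated
stratified 75/25 splits and an exhaustive ranked search over feature
subsets.

## Worked example

```sh
python examples/analyze_single_vowel.py
```

synthesizes a six-second /a/ with moderate noise (HNR 19 dB), one 180 ms
vocal arrest and one half-octave pitch drop, and prints:

```
measure      value  unit
MPT          6.000  s
FOVB         2.208  s
NVB          2.000  count
DPB          2.573  %
DVA          2.333  %
F0_SD        0.858  st
RPDE         0.657  -
Jitter       0.801  %
Shimmer      6.236  %
HNR         13.819  dB
DFA          0.523  -
FTRI         0.892  %
ATRI         1.537  %
MFCC         0.339  -
dMFCC        1.011  -
```

Both injected break events are found (NVB = 2) and the first one sets
FOVB ≈ 2.2 s; the arrest contributes the 2.3 % silent fraction (DVA), the
pitch drop most of the 2.6 % unvoiced fraction (DPB). The measured HNR sits
below the injected 19 dB because jitter and breaks also reduce waveform
periodicity — the autocorrelation HNR reads *total* aperiodicity.

Other examples: `examples/cohort_analysis.py` (full two-group pipeline with
effect sizes, affected-dimension percentages and the SVM marker search),
`examples/synthesize_cohort.py` (write a cohort of WAVs with ground truth),
`examples/effect_sizes_from_summary.py` (Cohen's d from published summary
tables), `examples/marker_search.py` (combination ranking on a feature
table).

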