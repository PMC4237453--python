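# Methods

## Scope and model

The package measures phonatory function from sustained vowel phonation.
The working model is the classical source–filter view of voicing: a
quasi-periodic glottal pulse train (the source) excites the vocal-tract
resonances (the filter), with aspiration noise added at the glottis.
Dysphonia appears as perturbations of this process — cycle-length and
cycle-amplitude variability (jitter, shimmer), additive turbulent noise
(HNR, DFA, RPDE), slow modulations (tremor), interruptions of voicing
(pitch breaks and vocal arrests) and instability of the vocal-tract
configuration (MFCC indices). The fifteen measures partition into seven
clinically interpretable dimensions (airflow, aperiodicity, irregular
vibration, perturbation, noise, tremor, articulation; 2/3/2/2/2/2/2
measures).

## Pitch tracking and pulse extraction

F0 and voicing are estimated per 40 ms Hann-windowed frame (10 ms hop) from
the mean-removed autocorrelation normalised by the window's own
autocorrelation. Candidate lags span 1/ceiling (500 Hz) down to *half* the
pitch floor (75 Hz): the sub-floor zone exists so that a genuine half-F0
pitch drop is recognised as strong out-of-range periodicity and labelled
unvoiced, rather than leaving weak in-range artefacts near the lag
boundary. Because the long-lag correlations have less window support, a
sub-floor candidate must beat the best in-range candidate by a clear margin
(0.1). A small per-octave lag cost (0.05) discourages subharmonic capture;
isolated one-to-two-frame subharmonic slips flanked by consistent voiced
frames are re-voiced from the candidate list, while genuine break onsets
(several frames, no full-strength candidate) are untouched. Frames below
5 % of the loud-frame RMS are silent; frames with peak strength below the
0.45 voicing threshold, or best F0 outside [floor, ceiling], are unvoiced.

Glottal pulses are picked one waveform maximum per predicted cycle within
each voiced span (the walk stops when the peak amplitude collapses, so span
edges do not leak into arrests), then refined on the linear-prediction
residual: an all-pole LPC fit (order 2 + fs/2000) removes the resonances,
leaving one excitation impulse per cycle whose energy centroid gives a
sub-sample pulse instant. Strong jitter generates genuine subharmonic
frames that fall below the voicing threshold without interrupting the
pulse train; span labels are therefore unified across any cross-span pulse
gap *shorter than the voice-break threshold* — such a gap can never be
counted as a break, so unification is always safe, and it keeps the most
perturbed cycles inside the perturbation statistics. Single pulses lost
inside a span (gaps of ~2 local periods) are recovered by re-scanning the
residual. Per-cycle
amplitudes subtract the previous cycle's ring-down — the free (zero-input)
evolution of the LPC model seeded with pre-pulse samples — before taking
the cycle RMS; without this, formant ring-down carry-over inflates shimmer
roughly two-fold at the default /a/ bandwidths. When the residual carries
no impulse structure (a pure tone), waveform peaks and cycle peak-to-peak
amplitudes are used instead.

## Measure definitions and numerical choices

* **MPT** — duration of the trimmed phonation span (first to last 10 ms
  frame above 3 % of peak RMS); internal breaks included.
* **Voice breaks** — inter-pulse gap > 1.25/floor (16.7 ms at 75 Hz),
  counted only with ≥ 250 ms of continuous preceding phonation and onset
  ≥ 1 s before the span end; a counted gap with silent interior is an
  *arrest*, otherwise *pitch-related*. FOVB is the earliest qualifying
  onset, equal to MPT when no break exists (the convention implied by
  control cohorts whose FOVB range equals their MPT range). Break onsets
  are estimated as last-pulse-time + one local period; they are defined up
  to one vocal cycle.
* **DPB** — unvoiced share of non-silent frames (%); **DVA** — silent share
  of the whole trimmed span (%; the terminal-guard region is *included* in
  the denominator).
* **F0 SD** — SD of 12·log2(F0) over voiced frames; the reference cancels,
  making the value register-independent.
* **Jitter / shimmer** — local statistics `100·mean|Δ|/mean` on cycle
  periods / amplitudes, per continuous voiced span, averaged with
  cycle-count weights. Edge cycles are dropped per span — one for periods,
  three for amplitudes, since the onset ramp passes the amplitude gate for
  several cycles while periods only suffer at the outermost pulse — and
  cycles
  whose period (amplitude) deviates more than 20 % (40 %) from the span
  median are excluded as tracking slips — the usual plausibility gating of
  perturbation analysers.
* **HNR** — mean over voiced frames of `10·log10(r/(1−r))`, with per-frame
  strengths winsorised at their 10th/90th percentiles first: the log-ratio
  transform has a heavy right tail near r = 1, and the plain mean would be
  dominated by frames where the strength estimate saturates.
* **RPDE** — the signal is decimated to ~11 kHz, unit-normalised and
  embedded (dimension 4, delay = first autocorrelation zero); for a strided
  set of reference points the first return into an ε-ball (ε = 0.12 signal
  SD per coordinate) after first leaving it is collected, up to
  T_max = 3 periods at the floor; the entropy of the return-time density is
  normalised by ln T_max.
* **DFA** — integrated mean-removed signal, least-squares line detrended in
  non-overlapping windows at 10 log-spaced scales between 1 and 100 ms;
  α is the log–log slope, reported through the logistic map 1/(1+e^−α)
  (white noise: α = 0.5). Configurable (`dfa_norm="none"` returns α).
* **FTRI / ATRI** — the voiced F0 contour (pulse-amplitude contour for
  ATRI) is resampled at 100 Hz; unvoiced gaps ≤ 100 ms are interpolated,
  longer gaps split the analysis (segments ≥ 1 s). The index is the
  amplitude of the strongest 1.5–15 Hz spectral component expressed as a
  percentage of the contour mean, i.e. the modulation *extent* of the most
  intense tremor component. The denominator choice (contour mean rather
  than summed spectral magnitude) is deliberate: it makes a constant
  contour read ≈ 0, makes an injected sinusoidal modulation of x % read
  ≈ x %, and matches the magnitudes of the clinical tremor-index family
  this measure descends from.
* **MFCC / ΔMFCC** — 25 ms/10 ms frames at 16 kHz, 26-band mel filterbank
  to 8 kHz, DCT-II; coefficients 1–12 (the gain coefficient is excluded, so
  both indices are level-invariant). Silent frames are excluded from the
  statistics: silence carries no articulatory information and its
  log-energy floor would dominate the variance. MFCC is the mean of the 12
  per-coefficient SDs across frames; ΔMFCC the same on ±2-frame regression
  slopes, ×10.

## Decision rule, statistics, classification

Per measure, class-conditional Gaussians are fitted by group sample
mean/SD (SD floored at 10⁻⁶ of the pooled range, so an all-zero control
measure cannot divide by zero). A measure votes pathological when the
likelihood ratio favours the patient class (equal priors — the
minimum-error rule) *and* the value lies on the pathological side of the
control mean; the one-sided guard prevents flagging exceptionally good
voices. A dimension is affected when any of its measures votes; measures
with identical group means carry no orientation and abstain. Because
dimensions aggregate by "any vote", a measure fitted on nearly identical
groups contributes noise votes near the boundary — at cohort level this is
absorbed by the percentage summaries, but single-subject profiles should be
read with the group separation in mind.

Group comparison: one-sample Kolmogorov–Smirnov against a Gaussian with
sample moments (Lilliefors correction available) applied to the pooled
two-group sample routes each measure to Student's t or Mann–Whitney U
(two-sided); correlations route to Pearson or Spearman the same way.
Bonferroni divisors equal the number of measures within the same phonatory
dimension. Cohen's d uses the pooled SD.

The SVM stage draws, per repeat, a stratified random 75/25 split (the
split is computed from the raw group labels, so relabelling which class is
"positive" exchanges sensitivity and specificity exactly), standardises on
the training subset only, selects C and the RBF γ by an inner stratified
cross-validation on the training subset, and scores patient recall
(sensitivity) and control recall (specificity) on the test subset.
`search_combinations` evaluates all subsets up to the size cap and ranks by
mean of sensitivity and specificity, ties to smaller subsets then
lexicographic order. "Repeated random splits" rather than rotated folds is
deliberate: it is the scheme the validation protocol describes.

## The synthetic generator

`synth_vowel` builds a vowel from first principles so that every injected
quantity is recoverable:

* cycle-by-cycle source construction: period = 1/F0(t) × (1 + jitter
  noise), amplitude = 1 + shimmer noise, with i.i.d. Gaussian noise scaled
  by √π/200 per injected percent so the *expected local statistic equals
  the injected value*; impulses are split across two samples to preserve
  sub-sample timing;
* slow processes: sinusoidal F0/amplitude tremor at the given rate and
  extents; slow F0 wander (default 0.25 st RMS, ~1 Hz bandwidth) and slow
  articulatory drift (crossfade towards resonators shifted by the drift
  extent, default 2 %) — without these, synthetic vowels are unnaturally
  steady (F0 SD ~0.05 st instead of the ~0.3 st real sustained phonation
  shows) and the spectral-stability measures become artifactually pure
  noise proxies;
* vocal tract: cascade of three second-order resonators, default adult /a/
  (700/1220/2600 Hz, bandwidths 60/70/110 Hz), configurable;
* aspiration noise: Gaussian noise shaped through the same resonators with
  4× bandwidths (so its autocorrelation at pitch lags is negligible and the
  injected HNR stays well defined for autocorrelation analysis), calibrated
  on the voiced non-event span to the target HNR, attenuated ×0.1 inside
  arrests (phonation noise stops with phonation; only breath remains);
* break events: a pitch drop multiplies instantaneous F0 by `drop_ratio`
  (default ½) with continuous phase; an arrest zeroes the source. Events
  must not overlap and must lie within the phonation.

`synth_cohort` samples per-subject parameters from truncated-Gaussian
per-group distributions and places break events clear of the span edges so
injected events qualify under the counting rules by construction.
`sample_feature_table` draws labelled feature vectors directly for testing
the decision and classification stages without audio.

What the generator does **not** emulate: irregular (non-Gaussian,
correlated) perturbation processes, diplophonia/subharmonic regimes,
coloured breath noise beyond the resonator shaping, room acoustics,
recording-chain nonlinearity, and articulatory gestures beyond slow drift.
Passing recovery suites therefore demonstrates correctness of the analysis
chain on the modelled phenomena, not clinical validity on real voices.

## Validation design and known cross-talk

Parameter-recovery suites vary one parameter on an otherwise clean carrier
(near-noiseless HNR 40 dB for the jitter and shimmer sweeps; jitter 0.1 %,
shimmer 0.5 % for the HNR sweep): recovery is only well defined where the
parameter under test dominates its estimator. The measures are *not*
independent on real or synthetic voices, and two cross-talks are intrinsic
rather than implementation artefacts:

* the autocorrelation HNR reads total aperiodicity — cycle-length jitter
  above ~0.4 % depresses it by several dB regardless of the additive-noise
  level (the joint-recovery suite therefore runs at jitter 0.1–0.3 %);
* additive noise inflates measured shimmer (and, mildly, jitter) through
  per-cycle amplitude estimation noise; at 25 dB HNR the shimmer floor is
  roughly 1 %.

The end-to-end cohort checks use a scaled-down design: 8 subjects per
group, ~5 s vowels, and a group contrast placed at the outer ends of the
individually observed clinical ranges (HNR 18 vs 24 dB; break rate 2.0 vs
0 per phonation, predominantly pitch drops) so that the qualitative group
pattern — more breaks, more unvoiced frames, higher DFA, lower HNR in the
patient group — is statistically detectable at that size. The
winning-marker-combination check runs on feature-space cohorts (28 per
group, all fifteen measures at realistic control spreads, group shifts only
on DPB, DVA, HNR and DFA): on audio cohorts every noise-sensitive measure
moves together with the injected noise, so which of the collinear measures
tops the ranking is not identifiable — a property of the construction, not
of the search.

## Degenerate inputs and failure handling

All-silent audio raises a "no phonation" error at trimming; unvoiced
recordings raise at pulse extraction; measures with insufficient material
(fewer than 3 cycles, fewer than 2 voiced frames, no contour segment long
enough) raise typed errors which `analyze_recording` converts to NaN plus a
recorded reason — a cohort run never silently drops a subject (failures are
quarantined and reported). Constant signals are rejected by DFA; an
ε-radius too small for any recurrence is reported as such by RPDE.
Deterministic behaviour: all synthesis randomness flows from explicit
integer seeds; analysis is deterministic given the input and configuration,
and every feature row carries a hash of the full analysis configuration.
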