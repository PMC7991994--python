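# Methods

`bulbarvoice` implements a voice-based screening analysis for bulbar
involvement in ALS: phonatory features are measured from sustained-vowel
recordings, preprocessed by an aging correction and PCA, and fed to a
suite of supervised classifiers evaluated under repeated cross-validation.
Because the clinical recordings that motivated this design are not
publicly available, the package ships a synthetic-voice generator whose
ground truth is known exactly; every stage is validated against that
truth or against closed-form oracles.

## Signal model and synthesis

A sustained phonation is modelled as a glottal pulse train. Cycle *i* has
period `T_i = T̄(1 + ε_i)` with `ε_i ~ N(0, j)` (jitter fraction `j`) and
amplitude `1 + δ_i` with `δ_i ~ N(0, s)` (shimmer fraction `s`). Each
cycle contributes a raised-cosine flow pulse of fixed width `0.6 T̄`; a
smooth pulse rather than an impulse keeps peak-to-peak amplitude
extraction well conditioned after resonator filtering. Vowel identity is
imposed by a cascade of three second-order all-pole resonators (e.g.
/a/ ≈ 700, 1100, 2600 Hz, bandwidths 80/90/120 Hz); it is irrelevant to
the phonatory features but makes fixtures spectrally realistic. White
Gaussian noise is added with variance `P_h / 10^(HNR/10)` where `P_h` is
the AC power of the harmonic part, so the injected harmonics-to-noise
ratio is exact by construction. The realized per-cycle periods and
amplitudes are retained on every recording as ground truth.

For i.i.d. Gaussian perturbation the expected relative perturbation
measure has the closed form

    E|X_i − X_{i−1}| / mean = 2·frac/√π    (×100 %),

used throughout as the analytic oracle: injected `j = 0.02` must be
recovered as jitter(relative) ≈ 2.257 %.

### Cohort defaults

Default cohorts mirror the population structure this analysis targets:
18 controls (C), 14 ALS with bulbar involvement (B), 31 ALS without
(NB); five Spanish vowels per subject; 3 s utterances at 44.1 kHz.
Demographics: C ages ~N(45.2, 12.2²) years, B ~N(56.8, 12.3²), NB
~N(58.3, 11.7²); male fractions 9/18, 3/14, 23/31. F0 is sex-dependent
(males ~N(120, 15²) Hz, females ~N(210, 25²) Hz). Group voice effects
are calibration choices made once — the reference data report them only
graphically — reproducing the assumed ordering with the bulbar group
clearly separated and the non-bulbar group intermediate with inflated
variance:

| group | jitter frac | shimmer frac | HNR (dB) |
|-------|-------------|--------------|----------|
| C     | 0.006 ± 0.0015 | 0.030 ± 0.008 | 22 ± 2 |
| B     | 0.022 ± 0.007  | 0.095 ± 0.030 | 12 ± 3 |
| NB    | 0.012 ± 0.006  | 0.055 ± 0.025 | 17 ± 4 |

Linear aging (`+5·10⁻⁵`/yr jitter, `+3·10⁻⁴`/yr shimmer, `−0.05` dB/yr
HNR, centered at 50 years) is injected into all groups alike so the
aging correction has a known target. Per-utterance wobble (lognormal
SD 0.15 on the perturbation fractions, ±0.8 dB HNR, ±2 % F0) makes the
five vowels of a subject similar but not identical.

A `latent_feature_table` path samples per-cycle period/amplitude tables
from the same distributions and runs them through the actual perturbation
formulas, bypassing waveform synthesis; it is used for large statistical
checks (n = 200 aging correction, type-I error) where re-analyzing
hundreds of waveforms would add extraction noise but no information.

### What the generator does not emulate

Real dysarthric voice has tremor, diplophonia, voice breaks, breath
noise with 1/f structure, vowel-dependent articulation deficits and
room/microphone coloration; the generator has none of these. Passing
tests therefore demonstrate that the measurement and evaluation chain is
correct and unbiased on signals satisfying its assumptions — not that
the published clinical accuracies transfer to real recordings.

## Feature extraction

Fifteen features per utterance: jitter(absolute, relative, rap, ppq5),
shimmer(relative, dB, apq3, apq5, apq11), pitch(mean, SD, min, max),
HNR(mean, SD).

**Trimming.** The analyzed span is where short-time RMS (10 ms frames,
5 ms hop) exceeds 10 % of the maximum frame RMS — an automatic stand-in
for manual oscillogram boundary marking.

**Pitch.** Frame-based autocorrelation: local mean removed, Hann window
(3 floor-periods long), FFT autocorrelation normalized by lag 0 and
divided by the window's own autocorrelation. Without that correction a
perfectly periodic frame scores only r ≈ 0.72 at one quarter of the
window length, capping measurable HNR near 4 dB, so the correction is on
by default. The candidate period is the smallest lag among near-maximal
local peaks (within 0.02 of the frame maximum) — for a pure tone every
multiple of the period scores ≈ 1 and the shortest is the fundamental;
the search extends above the pitch ceiling (to ~1200 Hz) so a tone whose
fundamental lies outside [floor, ceiling] is recognized and marked
unvoiced rather than accepted at a sub-harmonic. Frames below the
silence threshold (0.1 × global peak) or without a peak ≥ 0.45 are
unvoiced. Sex-specific settings: floor/ceiling 60/300 Hz and 12.5 ms
steps for males, 100/500 Hz and 7.5 ms for females. Pitch statistics use
voiced frames only; SD uses the n−1 denominator (undefined for a single
voiced frame).

**Cycles.** Marks are placed on the dominant waveform peak inside each
F0-guided search window (±30 % of the local period), walking outward
from the strongest peak. Periods are refined to sub-sample precision by
cross-correlating each cycle's waveform with its predecessor (template
half-width 0.35 T, shift bound 0.2 T, parabolic interpolation); on
synthetic trains with known truth the RMS period error is well under 2
samples. Peak-to-peak amplitude of cycle *i* is max − min inside a
window centered on its own mark, extending 40 % into each neighboring
period — centering matters: a window spanning mark-to-mark captures
`max(a_i, a_{i+1})` and halves measured shimmer.

**Jitter/shimmer.** A period outside [2, 25] ms is out of range; a
consecutive pair with period ratio above 1.3 is excluded and each
excluded term lowers the effective N by one; fewer than two effective
cycles (or an empty quotient window set) yields the distinguished value
"undefined", represented as NaN and propagated, never silently replaced.
ppq5/apq3/apq5/apq11 windows must lie entirely inside the sequence and
contain only in-range periods; asymmetric truncated windows are not
used. Mean period/amplitude normalizers are taken over in-range cycles.

**HNR.** 75 ms windows (4.5 periods of a fixed 60 Hz floor regardless of
sex), 10 ms steps, silence threshold 0.1. The corrected autocorrelation's
second local maximum r(τ) gives `HNR = 10·log₁₀(r/(1−r))`; r is clamped
below 1 by 10⁻¹² (capping at ~+120 dB). Frames that are silent or lack
an admissible peak are skipped; HNR(mean)/HNR(SD) summarize retained
frames.

All features are invariant to positive rescaling of the waveform, since
every threshold is relative and jitter is lag-based.

## Preprocessing

Fixed order: impute shimmer(apq11) → aging correction → standardization
→ PCA → keep the first 8 PCs. An undefined apq11 cell is replaced by the
subject's mean over the other vowels (the only imputation anywhere); a
subject with all five undefined is an error, since no rule covers it.
Aging slopes are ordinary least squares of each feature on age using
control rows only; `slope × age` is subtracted from every row of every
group. Standardization is (x − mean)/SD with the n−1 denominator. PCA is
the thin SVD of the standardized matrix divided by √(n−1), so singular
values are component SDs and variance bookkeeping is exact (Σ s_i² =
total feature variance to 1e−10). Loading signs are fixed by making each
loading's largest-magnitude entry positive. Rows are utterances by
default (the apq11 rule references vowels of one subject); a
subject-averaged mode exists behind a switch. Rows containing undefined
values other than imputed apq11 are dropped before the SVD with a logged
warning.

## Classifier evaluation

Six models on the 8 PC scores, for C vs B, C vs NB, B vs NB and
C vs ALS (= B ∪ NB): random forest (500 trees; mtry tuned once per
classification problem by out-of-bag accuracy over {2, 5, 8} — one tuned
value per comparison, reused across folds, which is also what keeps a
0.5 s/fit forest inside the evaluation budget), Gaussian naive Bayes,
unpenalized logistic regression (binomial, logit link), LDA, a neural
network with one hidden layer of 3 tanh units (SGD backpropagation with
adaptive learning rate, ≤500 epochs, early stop on a training-loss
plateau), and a linear-kernel C-SVM with C tuned over
{10⁻⁴, 5·10⁻⁴, 10⁻³, 10⁻², 0.1, 1} by 3-fold CV inside the training
fold. SVM probabilities come from a logistic (Platt) map fitted on the
training fold's decision values — the restrictive threshold needs
probabilities and the margin itself has no probability scale.

Evaluation: 10 trials × 10-fold CV. Each trial permutes rows with a
seeded RNG and splits them into 10 contiguous chunks; each chunk is the
test set while the rest, after upsampling the minority class with
replacement to equal counts, trains every model. All models share folds,
resamples and fold seeds, so per-fold metrics are paired. Probabilities
are computed once per fold and thresholded at 0.50 and 0.95 (positive
iff p ≥ threshold). Accuracy/sensitivity/specificity are averaged over
the 100 fold evaluations; a fold with an empty positive class has
undefined sensitivity and is excluded from that aggregate with a logged
count. Pairwise model differences use paired t tests on the 100 fold
accuracies, Bonferroni-corrected across the 15 model pairs within one
(comparison, threshold) cell; a zero-variance difference vector reports
p = 1 with a degenerate flag.

### Speaker leakage and the null cohort

Utterance-level folds place five utterances of the same voice on both
sides of a split. Subjects are tight clusters in PC space, so
classifiers can score far above chance by memorizing voices even when
group labels carry no information: on a subject-structured cohort with
no group effect we measure 60–80 % "accuracy" (and spurious model
differences), exactly the leakage expected from splitting utterances
rather than speakers. Two consequences:

* a subject-grouped CV mode (`CVScheme(subject_grouped=True)`) is
  provided — subjects never straddle a fold — and restores chance-level
  accuracy on structured null data; it is off by default for fidelity to
  the published procedure, whose utterance-level results should be read
  with this caveat;
* type-I checks use an exchangeable null: every group draws from the
  control distribution, sex ratios are equalized (the default ratios
  differ by group and F0 is sex-dependent, which would otherwise leave a
  real pitch signal), and voice latents are redrawn per utterance so
  rows carry no speaker identity.

On the exchangeable null the smooth/global models (naive Bayes,
logistic regression, LDA, the small network, the linear SVM) all sit
within a few points of 50 % at the 50 % threshold, and the near-balanced
C-vs-B cell shows no significant model pair. The random forest, however,
scores 62–66 % on the *imbalanced* null comparisons (B vs NB at 14:31,
C vs ALS at 18:45) — and its pairwise contrasts against the other models
are genuinely significant there. This is a property of the procedure,
not an implementation defect: upsampling with replacement duplicates
minority rows without adding new feature-space coverage, so a local
(nearest-neighbor-like) classifier predicts whichever class is locally
denser; on label-free data its accuracy tends to p² + (1−p)² and above.
A control experiment with pure i.i.d. Gaussian features and 90/225
labels reproduces it exactly (forest ≈ 66 %, logistic ≈ 50 %). Chance-
level accuracy for *every* model on an imbalanced null is therefore not
attainable under duplication-upsampling; the corresponding suite checks
document this rather than hide it. The practical reading: forest
accuracies reported under this protocol carry an optimistic bias on
imbalanced comparisons that the other five models do not share.

## Numerical choices and edge cases

* "Undefined" is NaN end to end; CSV serializes it as an empty cell.
* Autocorrelation peaks are refined by parabolic interpolation; the
  harmonicity r is clamped to [1e−12, 1 − 1e−12].
* Fold chunks use `array_split` semantics (sizes differ by at most one).
* A training fold containing a single class raises instead of being
  silently redrawn.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; identical seeds give byte-identical
  feature tables and metrics grids.
* Problem sizes used by the shipped analyses: the default 63-subject ×
  5-vowel cohort for the end-to-end run, 5 × ~300 cycles per point for
  analytic recovery, n = 200 control rows for the aging check.

## Known limitations

* The pitch tracker is a single-candidate-per-frame autocorrelation
  method; it is validated by property tests on synthetic material, not
  bit-compatible with any external implementation, and has no dynamic
  programming path (sustained vowels are near-stationary).
* Measured jitter/shimmer on formant-filtered noisy material carries a
  noise floor (resonator ringing and additive noise inflate small
  perturbations); analytic recovery is asserted on clean trains.
* The published clinical accuracies are not reproducible here by
  construction: the synthetic cohort shows the same qualitative pattern
  (near-ceiling C vs B, intermediate C vs NB / C vs ALS, a clear drop
  for B vs NB, sensitivity collapse at the 95 % threshold) but its
  effect sizes are calibration choices, not measurements.
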