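# Methods

## Problem and model

Infants prenatally exposed to opioids are observed for withdrawal signs
(NOWS); pharmacological treatment is triggered by repeated high scores on
the Finnegan scale (FNAST ≥ 8 twice consecutively, or ≥ 12 once). The
package asks whether frame-level cry acoustics, summarized per utterance and
per infant, predict treatment. The classifier is a *stacked* model: four
random forests — one per (analyzer profile × utterance-duration stratum)
feature table — each produce a class probability for a held-out infant, and
the stacked prediction is their unweighted mean. Feature selection (ensemble
Boruta) and classification both run inside every leave-one-out fold, so
every reported performance number is computed on data never touched by
selection or training for that infant.

## Synthetic cohort generator

The generator emulates the *structure* of a clinical cry study, not the
sound of real infants. Utterances are source–filter synthesized: a glottal
impulse train (with 5% shimmer and 0.5% slow jitter) follows a
piecewise-linear f0 contour (default base 450 Hz, rise–fall shape), filtered
through second-order resonators at F1 = 1100 Hz and F2 = 3300 Hz (a short
neonatal vocal tract); per utterance, hyperphonation (f0 jumps to 1400 Hz,
probability 0.08) and fricative replacement of a sub-segment by 2.5–8 kHz
band noise (probability 0.10) may occur; Gaussian background noise is added
at 30 dB SNR and persists through the silence gaps so that segmentation
thresholds face a realistic noise floor. Recordings are bouts of 4–12
utterances of 150–900 ms separated by 100–400 ms gaps at 22 050 Hz (infant
cry energy lies below ~11 kHz). The cohort defaults to 19 NOWS / 7
opioid-exposed-no-NOWS / 39 unexposed infants; labels are subgroup
membership (treated = NOWS), with an optional FNAST simulator that applies
the treatment rule to scores drawn around a latent severity.

Group differences are standardized shifts per feature family
(`effect_map`). The defaults —
hyperphonation 1.2, f0 0.8, first formant 0.9, energy 0.8, fricative 0.7,
utterance count 1.0 — are free parameters chosen once to produce strong but
imperfect separation at n = 65, consistent with a classifier that is
accurate but not perfect; no published effect sizes exist for these
quantities. In audio mode the shifts act on synthesis parameters
(hyperphonation/fricative probabilities, f0 base, F1 center, utterance
count); energy/entropy/novelty differences arise only indirectly there, and
are directly injectable only in `feature_table` mode, where informative
columns are unit-variance Gaussians with the NOWS mean shifted by the
mapped value and the two control subgroups share one distribution.

What passing tests on this generator do **not** show: robustness to real
recording conditions (adult speech, handling noise, device variation),
inspiratory sounds, or the true covariance structure of cry acoustics —
informative features are conditionally independent here, which real
formant/pitch measures are not.

## Acoustic front end

Frames are 12.5 ms with a 6.25 ms hop and Hann taper; spectra are
zero-padded to 1024 points. Two profiles emulate analyzer multiplicity:

* **cepstral** — f0 from the real cepstrum: within the 150–2500 Hz
  quefrency band, the earliest local peak within 70% of the band maximum is
  taken (the global maximum often sits on a rahmonic at a multiple of the
  period, which would halve or third the pitch). Voicing requires the band
  maximum to exceed 7.5× the median absolute cepstrum level — calibrated on
  synthetic voiced/noise frames, whose statistics separate cleanly (noise
  95th percentile ≈ 7.3, voiced 5th percentile ≈ 8).
* **spectral** — f0 from the autocorrelation computed as the inverse
  transform of the power spectrum; earliest near-maximal peak (85%), voiced
  when the normalized peak is ≥ 0.35.

Formants: the frame is resampled to 10 kHz, pre-emphasized (0.97), and fit
with an **order-6** autocorrelation-method LPC; F1/F2 are the two lowest
local maxima of the all-pole envelope in (200, 5000) Hz. Two deliberate
departures from textbook adult-speech practice: the classical order-12 fit
locks poles onto individual harmonics at cry pitch (f0 300–600 Hz leaves
only ~11 harmonic samples of the envelope below 5 kHz), producing formant
errors of hundreds of Hz, and pole-bandwidth classification admits spurious
broad resonances; the low-order envelope-peak approach recovers synthetic
F1/F2 to better than 100/150 Hz. Band energies use a 2500 Hz split, floored
at −120 dB. Spectral entropy pools the unpadded power spectrum into 32
equal bands before normalizing — the raw periodogram of white noise has an
expected normalized entropy of only ≈ 0.91 (exponential bin statistics),
whereas the banded estimate reads ≈ 0.97 for noise and < 0.2 for tones. The
fricative score is a logistic in the high-band energy ratio (midpoint 0.5)
and zero-crossing rate (midpoint 0.3), slope 8 on each, monotone in both.
Spectral novelty correlates a 16-frame Gaussian-tapered checkerboard kernel
with the cosine self-similarity matrix of magnitude spectra. The amplitude
envelope is per-frame RMS; its modulation frequency is the dominant
non-DC peak of the envelope spectrum, reported missing when the peak is
below 5× the median or the envelope is constant (relative SD < 1%).

## Segmentation and summarization

Utterances are maximal runs of frames whose total energy exceeds the
recording's 10th-percentile energy by 15 dB, merged across gaps < 50 ms,
dropped when shorter than 50 ms, and required to be ≥ 30% voiced (a proxy
for the expiratory phase — inspiratory sounds are mostly unvoiced and
short). These four constants are not clinically derived; they were chosen
to recover synthesis ground truth (≥ 90% of true utterances at IoU > 0.5)
and are all configurable. Strata split at 500 ms (short strictly below).
Utterance summaries are per-feature means over non-missing frames plus
missing-rates; infant rows are unweighted means of utterance means (not
duration-weighted), mean missing-rates, and the utterance count. Whether
counts should be normalized by recording duration is left as a
configuration decision; raw counts are used.

## Filters, selection, classification

Pre-selection filters run once on the full tables, in order: missingness
(> 60%, strict), near-zero variance (dominant/second value ratio ≥ 19 with
< 10% distinct values — the common preprocessing convention), and greedy
correlation pruning (|r| > 0.75 strict, pairwise-complete Pearson; the
member of the worst pair with the larger mean absolute correlation is
removed, ties to the earlier column). Filtering before cross-validation
mirrors the staged data-reduction design but carries a mild leakage risk;
`filters.within_folds` is reserved for moving it inside folds.

Boruta appends a permuted shadow copy of every active feature (minimum 5
shadows), fits a forest, scores a hit when a real feature's importance
exceeds the best shadow's, and applies a two-sided Binomial(n, ½) test to
cumulative hits with Bonferroni correction over features at α = 0.01;
rejected features leave the model, undecided features at the iteration cap
stay tentative, and tentative counts as not selected. The ensemble repeats
this with derived seeds; retention requires selection in strictly more than
`retain_threshold` runs (default 5 of 100). Importance defaults to mean
impurity decrease from a hand-bagged CART forest (bootstrap + sqrt feature
subsampling) — statistically a standard random-forest importance, but
without per-tree estimator-cloning overhead, which dominates runtime at
n ≈ 64; permutation importance (mean accuracy decrease) is available via
`importance="permutation"` at ~10× the cost. Final classifiers are
scikit-learn probability forests (10 000 trees by default, mtry =
floor(√p), minimum node size 10 mapped to `min_samples_split`); missing
values are median-imputed from the training fold.

When a fold's retained set is empty, the model is skipped and stacking
averages the rest; when all four are skipped, the fold emits 0.5. The
fallback is deliberately *not* the training prevalence: under leave-one-out,
prevalence anti-correlates with the held-out label (removing a positive
infant lowers it), which drives null-cohort AUC toward 0. Relatedly,
fitting forests on uninformative tables *without* selection shows the known
pessimistic pooled-LOOCV bias (mean AUC ≈ 0.39 at 19/46 imbalance); along
the procedure-faithful path — selection inside folds — null cohorts are
calibrated at AUC ≈ 0.5 because uninformative models are rejected and the
folds abstain.

## Evaluation

AUC is the Mann–Whitney concordant-pair fraction (ties ½) with a DeLong
rank-based CI; the binary cutpoint minimizes the Euclidean distance to the
(sensitivity 1, specificity 1) corner, ties resolving to the lower
threshold. Proportion CIs are exact Clopper–Pearson (the printed intervals
for 17/19 and 38/40 match this choice at two decimals); Cohen's κ uses the
asymptotic standard error se = √(p₀(1−p₀)/n)/(1−pₑ). Ratios with zero
denominators are reported missing. Subgroup sensitivity analyses re-evaluate
the stored stacked probabilities after excluding one control subgroup,
without refitting. Group comparisons use Welch's t (Satterthwaite df) with
pooled-SD Cohen's d for numeric covariates and Pearson χ² (Yates-corrected
for 2×2) for categorical ones.

## Problem sizes and numerical choices

The full-fidelity configuration (100 Boruta runs per fold per table, 10 000
trees) is the package default for `validate_config`. Tests and
`scripts/acceptance.py` use scaled settings chosen as a deliberate
trade-off — 2–5 ensemble runs with retention > 0–1, Boruta iteration cap
13–20, 20–30 trees inside selection, 60–300-tree final forests, and
feature-table cohorts of 24–65 infants — after verifying that halving or
doubling the final forest moves the LOOCV AUC by well under 0.05. Seeds fan
out from a single master via SHA-256 (`derive_seed`), so every pipeline
output is bit-reproducible; pipeline manifests record checksums of all CSV
and JSON outputs.

## Known limitations

* Synthetic audio is not perceptually realistic; no ingressive cries, no
  vocal-tract physics, no recording-channel variation.
* The two analyzer profiles share an implementation skeleton and therefore
  correlate more strongly than two independent commercial/research
  analyzers would; stacking gains are correspondingly modest.
* Formant estimation assumes at most ~2 strong resonances below 5 kHz
  (LPC order 6); vowels with a prominent F3 would need a higher order.
* Probabilities are not calibrated (by design, matching the modeling
  procedure); only their ranking and the chosen cutpoint are interpreted.
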