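# Methods

## The phase-variability metric

For two network time-courses `x` and `y`, each instantaneous phase is the
angle of the discrete analytic signal, `φ = angle(x + i·H[x])` with `H`
the Hilbert transform (`scipy.signal.hilbert`). The metric is the sample
variance (denominator T−1) of the phase difference after wrapping to the
half-open interval (−π, π]:

```
VAR(x, y) = Var_t[ wrap(φ_x(t) − φ_y(t)) ]
```

Two estimator caveats, both surfaced as options:

* **Wrapping inflation.** When the mean phase difference sits near ±π,
  wrapping splits a tight distribution across the branch cut and the
  ordinary variance is inflated. The default keeps the ordinary variance
  (it is the literal recipe); `estimator="circular"` returns the
  circular variance 1 − R, which is bounded in [0, 1] and immune to the
  branch cut.
* **Edge effects.** The discrete analytic signal is unreliable near the
  series ends, so ⌈5% T⌉ frames are trimmed from each end before the
  variance (or the phase-locking value) is taken; `trim_frac=0` restores
  the full-series computation.

Interpretation anchors: `VAR = 0` for phase-locked pairs (including a
constant offset), and `VAR → π²/3 ≈ 3.29` when the wrapped difference is
uniform on the circle. The comparison metrics are the Pearson
correlation (FC) and the phase-locking value `|mean exp(i·Δφ)|` (PS; the
standard instantaneous-phase synchrony estimator — the label "phase
synchrony" alone does not pin down a formula, so the PLV was adopted).

Pairwise features are ordered by the row-major upper triangle over the
component order (MVN, OVN, LVN, DMN, CBN, SMN, AN, ECN, RFPN, LFPN);
this canonical order fixes feature identity everywhere, including weight
reports. The full predictor vector appends verbal, performance and full
IQ, sex (male = 1), age, and mean framewise displacement: 45 + 6 = 51
predictors. (The formula-implied count is 51; a published table reports
"50" features for the same model — the discrepancy is noted, not
resolved, and this implementation follows the formula.)

## Preprocessing

* **Band-pass**: second-order Butterworth, 0.01–0.1 Hz, applied
  forward-backward (`sosfiltfilt`). Zero-phase filtering is essential
  here: a causal filter's phase lag would bias the instantaneous-phase
  estimates downstream. Measured response: gain 0.99 at 0.05 Hz, < 0.06
  at 0.2 Hz and at 0.005 Hz (TR = 2 s). By default the pipeline filters
  component time-courses before phase estimation; this is configurable.
* **Framewise displacement**: Power-style — the sum of absolute
  frame-to-frame differentials of the six rigid-body parameters, with
  rotations converted to arc length on a 50 mm sphere (radius
  configurable, degrees flag available). FD of the first frame is 0.
  Subjects with mean FD strictly above 0.5 mm are excluded; a subject at
  exactly the threshold is retained ("larger than" is read strictly).

## Time-course extraction

Each frame of a 4D volume is regressed on a template map over the brain
mask (slope of an ordinary least-squares fit with intercept); stacking
the per-frame betas gives the network time-course. The intercept absorbs
any global per-frame offset.

A structural property worth knowing: with the intercept, the effective
regressor is the *centered* map, and two disjoint nonnegative maps are
negatively correlated once centered. The per-map mode therefore carries
bounded cross-talk between sources even for non-overlapping templates
(r ≈ 0.94 against ground truth for 10 disjoint blobs mixing strongly
correlated sources). `joint=True` fits all maps plus the intercept in
one multiple regression per frame and separates the sources exactly in
the noiseless case; the two modes coincide only for maps that are
mutually orthogonal and zero-mean within the mask. The per-map mode
remains the default for fidelity to the published recipe; exact-recovery
guarantees are stated for the joint mode.

## Diagnostic model and evaluation

* Linear SVM (`sklearn.svm.SVC(kernel="linear")`, an SMO-type solver;
  any exact solver of the same convex objective reaches the same
  hyperplane), `C = 1` by default.
* Features are z-scored with training-fold statistics only — no
  test-fold leakage — and weights are reported in standardized units so
  their magnitudes are comparable across predictors. Positive weight =
  predictor elevated in patients (label 1).
* **LOOCV**: n single-subject holdouts; pooled confusion counts give
  accuracy = (TN+TP)/(TN+FN+TP+FP), sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP); AUC from the pooled held-out decision
  scores (equal to the normalized Mann–Whitney U, ties counting ½).
* **Repeated k-fold**: each repeat draws a fresh seeded *stratified*
  partition (stratification is a choice; the source recipe does not
  state it), fits k fold models, pools their held-out confusion counts
  into one performance estimate, and records the mean of the k fold
  weight vectors. The top-10 frequency report counts, per repeat, which
  features fall in the top 10 by absolute weight (ties broken by
  canonical feature order). All randomness flows from one master seed.

## The synthetic cohort generator

The generator emulates a two-group resting-state study (patients vs
controls) at the emulated study's scale: T = 235 frames (240 acquired
minus 5 discarded) at TR = 2 s, 10 components, group sizes defaulting to
100/140. Network i of one subject is

```
x_i(t) = cos(2π·f·t·TR + ε_i(t)) + η(t),      f = 0.05 Hz
```

with Gaussian observation noise η (SD 0.2, i.e. 20% of the carrier
amplitude) and phase noise ε built from two parts:

* an independent per-component term (circular SD 0.05 rad), and
* for **every** unordered pair (i, j), an antisymmetric coupling term:
  a shared process ζ_ij(t) added to phase i and subtracted from phase j.
  The phase difference of pair (i, j) carries 4·Var(ζ_ij) while only
  1·Var(ζ_ij) leaks into the other pairs sharing a component.

Each subject's pair-noise variance is the group-level value plus
additive between-subject heterogeneity (SD 0.01 rad² in variance units).
Both design choices are deliberate and load-bearing:

1. *Pair-level coupling noise* makes a planted group difference a
   property of specific pairs. A per-component dispersion cannot do
   this: raising σ on a component elevates every pair containing it by
   σ², and the affected pair-variances become near-linear combinations
   of one another, so a weight-based ranking cannot attribute the effect
   to the intended pairs.
2. *Additive heterogeneity* keeps the between-subject spread of a pair's
   variability from scaling with its mean. For variance-type features
   both the group difference and the sampling spread otherwise scale
   together, which makes every leakage pair exactly as discriminable
   (in standardized units) as a planted pair — defeating pattern
   recovery regardless of effect size.

The planted effect raises the coupling dispersion of the `effect_pairs`
(default AN-RFPN, CBN-SMN, DMN-LFPN; component-disjoint so no planted
pair rides another's leakage) to 0.3 rad in patients versus 0.05 rad in
controls; all other pairs sit at 0.1 rad in both groups. Under these
defaults a 60+60 cohort yields repeated 10-fold accuracy ≈ 0.95–1.0 and
all planted pairs in the per-repeat top-10 ranking, while the null
configuration (`as_null()`: no planted pairs, identical phenotype
distributions) classifies at chance.

Phenotypes are drawn from the emulated cohort's group moments: sex
Bernoulli (male fraction 88/100 vs 81/140), age N(12.1, 2.05²) vs
N(11.44, 1.86²), and three IQ scores with patient/control means of
111.44/120.46 (verbal), 99.03/111.29 (performance), 106.36/118.02
(full). The inclusion criterion IQ > 80 is enforced with a truncated
normal whose location is solved (Brent's method) so the *truncated* mean
equals the target moment — naive truncation would shift the patient
full-IQ mean by ≈ +0.7. Mean FD is gamma-distributed (shape 4) with
group means 0.20/0.15 mm, a plausible pediatric motion contrast (the
emulated study reports no FD moments). Motion traces are random walks
over the six rigid-body parameters with optional translation spikes of
known magnitude. All generators are pure functions of (config, seed),
with independent substreams per purpose, group and subject.

### What the generator does not emulate

Hemodynamic response shape, 1/f and physiological noise spectra,
scanner drift and slice-timing effects, spatially structured noise,
inter-subject anatomical variability, realistic (BrainMap-derived) ICN
geometry, and any correlation between phenotypes and the imaging signal
beyond the planted group effect. Passing tests therefore demonstrate
the correctness and statistical calibration of the pipeline — not that
the published real-data accuracies are reproducible, which would require
the original consortium data and external preprocessing.

## Problem sizes used in tests and the acceptance script

Planted-effect checks use 60+60 subjects with 50 repeats of 10-fold CV;
null calibration uses 20 cohorts of 50+50 with LOOCV and one 10-fold
partition each, asserting the across-seed mean accuracy within the
single-run 95% binomial interval of 0.5 (a literal every-seed-in-interval
check would fail ~64% of the time even for a perfectly calibrated null);
the uniform-limit check uses 100,000 draws; extraction recovery uses 10
blobs on a 16³ grid. These sizes give comfortably powered checks at
desk scale.

## Known limitations

* The per-map extraction cross-talk described above is inherent to the
  literal recipe; use `joint=True` when templates overlap or exact
  separation matters.
* The ordinary variance of wrapped differences is discontinuous in
  distribution when the mean difference approaches ±π (use the circular
  estimator there).
* With white phase noise, band-pass filtering before phase estimation
  attenuates phase-noise power outside 0.01–0.1 Hz, so absolute VAR
  values are smaller than the generating dispersions; group contrasts
  and orderings are preserved.
* WEKA-style internal normalization versus explicit z-scoring changes
  weight magnitudes (not signs or rankings here); this implementation
  standardizes explicitly on training folds.
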