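# Methods

## Problem setting

A virtual marker tracked on the right-ventricle epicardium of an exposed
beating heart yields an (x, y) pixel trajectory per video (200 frames/s,
5 s, i.e. 1000 samples per axis).  Each patient is recorded 3–4 times
before and 3–4 times after pulmonary valve replacement.  The analysis
treats "before surgery" as the *unhealthy* class and "after surgery" as
the *healthy* class, trains classifiers on frequency-domain features of
the trajectories, and uses them to call the phase of held-out patients.

## Synthetic cohort model

No public recordings exist, so the generator emulates the study
population.  Marker motion per axis is

x(t) = b + r·t + Σₕ Aₕ sin(2π h f₀ t + φₕ) + ε(t),  ε ~ N(0, σ²) i.i.d.,

with H = 3 harmonics decaying geometrically (ratio 0.4), fundamental f₀
drawn per patient uniformly from 1–2 Hz (60–120 bpm, a plausible
intraoperative range) and held identical across the two phases
(anesthesia is given once; heart rate is controlled).  Phases φₕ are
uniform, drift r defaults to 0, and baselines default to 0 px
(coordinates relative to the marker's rest position — a real tracker
export carries an arbitrary absolute offset, which would affect only the
raw-signal band-power feature and is exercised separately in tests).

Class profiles (defaults, chosen once):

| parameter | unhealthy (before) | healthy (after) |
|---|---|---|
| first-harmonic amplitude A₁ (px, per axis) | U[5, 10] | U[2.5, 5] |
| noise σ (px) | U[0.5, 1.0] | U[0.04, 0.08] |

The dilated, fatigued pre-operative ventricle moves with larger
excursions but far less coherently; after a successful repair the motion
is smaller and cleaner.  These two ranges make (a) kinematic energy and
perimeter decrease after surgery and (b) the per-class SNR ranges
disjoint (unhealthy ≈ 12–25 dB, healthy ≈ 26–39 dB), so SNR alone ranks
the classes almost perfectly.  Real intraoperative SNR values are not
published; the *direction* of the contrast is a modelling choice and is
configurable.  Each video of a patient-phase re-uses the phase's
parameters with a ±10% amplitude jitter and a fresh noise realization.

Cohort composition reproduces the study totals deterministically:
12 patients with per-phase video counts (4,4,4,4,4,4,4,3,3,3,3,3) =
43 + 43 = 86 recordings.  Held-out patients: the *favorable* patient
draws its before phase from the unhealthy profile and its after phase
from the healthy profile; the *unfavorable* patient re-uses its own
before-surgery parameters for the after phase scaled ×1.5 in both
amplitude and noise — every kinematic parameter increases while the SNR
stays in the unhealthy range, which is exactly the signature the
decision surface must catch.

Seeding: one master seed; each recording's stream is
`SeedSequence([master, patient_index, phase_index, video_index])`, and
parameter draws use fixed tag constants in place of the video index, so
any recording regenerates independently.

**What passing tests show — and don't.**  The generator reproduces the
statistical *structure* the analysis assumes (periodic multi-harmonic
motion, class-separable SNR/energy, grouped patients), not real cardiac
mechanics: there is no systole/diastole asymmetry, no respiration or
occlusion artifacts, no tracking drop-outs, and the class gap is by
construction clean.  Perfect cross-validated accuracy on this cohort is
a structural analog of the published performance, not a reproduction of
it, and says nothing about accuracy on real hearts.

## Kinematics

Velocity and acceleration use second-order central differences (one-
sided at the ends); no smoothing is applied before differentiation, so
high noise inflates velocity-based parameters by design (this is part of
the unhealthy signature).  Definitions: max contraction velocity =
max |v|; force = max |a| under unit mass, a proxy for instantaneous
force that preserves ordering; energy = ½ Σ v² Δt over the whole
recording (no per-cycle segmentation — at constant heart rate a
fixed-duration integral preserves before/after comparisons); perimeter =
Σ of consecutive-sample chord lengths.  On a sampled circle these
converge to Rω, Rω² and 2πR with O((ωΔt)²) bias; note that an open
polygon over N samples spans (N−1)/N of the circle, so closed-form
checks sample one full period inclusive of both endpoints.  Phase
summaries are mean ± SEM (SEM = sd(ddof=1)/√n, 0 for n = 1).

## Spectral features

All metrics share a modified periodogram of the mean-removed signal
under a Kaiser window with β = 38, whose sidelobes (≈ −350 dB) are far
below double-precision round-off, so leakage cannot masquerade as
signal.  The window's main-lobe half-width (~12.2 DFT bins for β = 38)
is computed numerically from the zero-padded window transform and caches
per (length, β).

* **Fundamental**: the largest PSD bin outside the residual DC lobe
  (the DC lobe is found by walking up from bin 0 while the PSD
  decreases); its power is the PSD integrated over ± one main-lobe
  half-width.
* **SNR**: fundamental power over noise power; DC, fundamental and the
  lobes of harmonics 2–6 are excluded, and the excluded lobes are
  back-filled with the median noise density so the noise estimate spans
  the full band.
* **SINAD**: same numerator; the denominator keeps harmonic distortion
  (only DC and the fundamental lobe are removed, the latter median-
  filled).  The harmonics enter the SNR denominator only through their
  above-median excess, which makes SINAD ≤ SNR an identity rather than
  a statistical tendency.
* **SFDR**: fundamental-lobe power over the largest remaining lobe
  (spur search includes harmonics).
* **3 dB bandwidth**: first half-power crossings on either side of the
  global PSD peak, linearly interpolated; a flat spectrum returns the
  full band with a warning.
* **99% occupied bandwidth**: frequencies where the cumulative power
  crosses 0.5% and 99.5% of the total, linearly interpolated.
* **Spectral entropy**: normalized Shannon entropy of the PSD, one
  scalar per recording (the classifier consumes one number per video; a
  time-varying entropy series is a known alternative reading).
* **Band power**: plain mean square of the *raw* signal, DC included —
  the only offset-sensitive feature; everything else is computed on the
  mean-removed trace.

Numerical guards: dB values are clipped to ±300 dB (noiseless inputs
yield a zero noise estimate and cap with a warning); harmonics beyond
Nyquist are ignored, not folded; signals shorter than 64 samples are
rejected; constant traces raise a degenerate-signal error naming the
axis.

## Classification

Features are **never standardized** — distances act on the raw feature
scales.  Both models are sklearn-style estimators:

* **KNN**: weighted vote among the k nearest training rows under
  euclidean / cityblock / chebyshev / minkowski(p) distance with equal,
  1/d or 1/d² weights.  Distance ties break toward the lowest training
  row index (stable sort); a query coinciding with training rows is
  decided by those rows alone; tied votes resolve to *unhealthy*.  The
  ROC score is the weighted healthy-vote fraction (hard 0/1 votes would
  make the k = 1 ROC degenerate).
* **SVM**: soft-margin dual with box constraint C and Gaussian kernel
  exp(−‖u−v‖²/s²), solved by libsvm (tolerance 1e-6, iteration cap 10⁶,
  cap hit ⇒ convergence error with the offending hyperparameters).  The
  decision function is kept as explicit support rows / dual coefficients
  / bias, so JSON-serialized models evaluate without refitting; the
  signed decision value is the ROC score, positive toward *healthy*,
  with 0 resolving to *unhealthy*.

Cross-validation partitions *patients* into k = 10 folds (seeded
shuffle, sizes differing by ≤ 1 patient); the error pools misclassified
recordings over all folds.  Hyperparameter optimization is seeded random
search, 100 iterations, KNN over k ∈ {1..20} (log-uniform) × 4 metrics ×
3 weightings (minkowski exponent log-uniform in [1, 10]), SVM over C and
s log-uniform in [10⁻³, 10³]; the best point is the first iteration
attaining the minimum cross-validated error, and the full trace
(candidate, error, running best) is retained.  Random search was chosen
because the reference procedure specifies only an iteration budget and
an error-minimization target; the trace format leaves room for a
model-based searcher.  Non-converging SVM candidates score error 1 and
can never become the best point.

Evaluation pools out-of-fold predictions: confusion matrix ordered
(unhealthy, healthy), per-class TPR/FNR from row-normalized diagonals,
ROC by threshold sweep over pooled healthy-scores, AUC by trapezoid.
Whether published confusion matrices are cross-validated or
resubstitution is ambiguous in this setting; this package always reports
the cross-validated form.

## Decision surfaces and held-out calls

The optimized hyperparameters are refit on the (SNR_x, SNR_y)
restriction of the training table (the pair is configurable).  A surface
is the model's prediction at every cell center of a resolution²
grid over the training range ± 10% margin.  Held-out recordings are
featurized, projected to the pair and predicted; the phase-level call is
the majority vote with ties to *unhealthy*; degenerate recordings are
flagged and excluded from the vote with a warning.

## Statistics

* Sample size: n = z²p(1−p)/(D/2)².  D is the *full* confidence-interval
  amplitude, so its half-width enters the denominator — the only reading
  under which a 1/3500 prevalence at 95% confidence and D = 2% gives the
  published bound of 10.97 patients.
* Mann–Whitney: two-sided; exact when min(n₁, n₂) ≤ 8 with no ties
  (enumeration is trivial there and covers the study's 3–4 videos per
  phase), otherwise normal approximation with tie and continuity
  corrections.
* KS normality: one-sample test against N(mean, sd) with parameters
  estimated from the same sample; the resulting conservatism (Lilliefors
  caveat) is recorded in the result's method tag instead of silently
  substituting a different test.

## Problem sizes and determinism

Default analyses use the 86-recording cohort (1000 samples per axis),
100 optimization iterations × 10 folds, and 100-seed medians for
estimator checks; the full test suite and the acceptance script each run
in well under a minute on one CPU.  Every stochastic operation takes an
explicit seed, and all cohort randomness derives from the single master
seed via the documented counter scheme.

## Known limitations

* The kinematic formulas implement the one-line definitions of the
  published parameters; the original per-cycle normalizations are not
  public, so absolute values are proxies that preserve ordering.
* Band power is offset-sensitive by definition; pipelines consuming
  absolute tracker coordinates should be aware that this one feature
  encodes marker placement as well as motion.
* The spectral-entropy scalar (vs. a time-resolved series) and the
  raw-vs-detrended choices per metric are explicit but are judgment
  calls where the reference analysis is underspecified.
* The synthetic class gap is clean by construction; performance numbers
  on it characterize the pipeline's correctness, not clinical accuracy.
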