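# epikin — epicardial kinematics and intraoperative outcome classification

During open-chest surgery the right ventricle (RV) is essentially
unmonitored: no routine intraoperative imaging quantifies its mechanics.
Contactless video-kinematic evaluation fills this gap by filming the
exposed beating heart at high frame rate (200 fps, ~5 s clips), tracking
a virtual marker on the RV epicardium, and summarizing the resulting
(x, y) pixel trajectory.  `epikin` implements the full downstream
analysis for cohorts of patients recorded **before** and **after**
pulmonary valve replacement (e.g. Tetralogy of Fallot repairs):

1. **Kinematics** — per recording: maximum contraction velocity
   (px/s), peak acceleration "force" (px/s²), kinetic energy
   ½∑v²Δt (px²/s), and path-length perimeter (px); phase aggregates as
   mean ± SEM.
2. **Spectral predictors** — seven frequency-domain features per
   coordinate axis (14 per video) from a Kaiser(β = 38) modified
   periodogram of the near-sinusoidal motion: band power, 3 dB
   bandwidth, 99% occupied bandwidth, SFDR, SINAD, SNR and normalized
   spectral entropy.
3. **Classification** — unstandardized features feed k-nearest-neighbor
   and Gaussian-kernel SVM classifiers labelling each video *unhealthy*
   (before surgery) or *healthy* (after surgery).  Hyperparameters are
   chosen by 100 iterations of seeded random search minimizing the
   **patient-grouped** 10-fold cross-validated error (folds partition
   patients, never recordings, so no patient leaks across folds).
   Evaluation reports pooled confusion matrices, per-class TPR/FNR, ROC
   and trapezoidal AUC.
4. **Decision surfaces** — the optimized classifiers are refit on the
   (SNR_x, SNR_y) plane; every point of a Cartesian grid is classified,
   and a held-out patient's videos are called per phase by majority
   vote (ties resolve conservatively to *unhealthy*).
5. **Study statistics** — the prevalence sample-size bound
   n = z²p(1−p)/(D/2)², Kolmogorov–Smirnov normality checks and
   Mann–Whitney before/after comparisons (exact by enumeration for
   small tie-free groups).

Because intraoperative recordings are not publicly available, the
package ships a first-class **synthetic cohort generator**: harmonic
heart-rate motion (fundamental 1–2 Hz, three decaying harmonics) plus
white tracking noise, with class profiles in which surgery reduces
motion amplitude and, especially, noise — so energy and perimeter drop
and spectral SNR rises after a successful repair.  Every stage of the
pipeline is therefore runnable and testable end to end with no data
download.

## Worked example

```python
import epikin as ek

cohort = ek.simulate_cohort(ek.CohortConfig(seed=0))     # 12 patients, 43 + 43 videos
table = ek.build_feature_table(cohort)                   # 86 x 14 feature matrix
X = table.loc[:, list(ek.FEATURE_COLUMNS)].to_numpy(float)
y = table["label"].to_numpy(dtype=object)
groups = table["patient_id"].to_numpy()

best, trace = ek.optimize("knn", X, y, groups, n_iter=100, k=10, seed=0)
print("best KNN:", trace.best_params, f"(cv error {trace.best_error:.3f})")
report = ek.evaluate(best, X, y, groups, k=10, seed=0)
print("TPR unhealthy: {:.1%}  TPR healthy: {:.1%}  AUC: {:.2f}".format(
    report.tpr["unhealthy"], report.tpr["healthy"], report.auc))

model2d = ek.fit_2d(best, table, y)                      # (snr_x, snr_y) plane
before, after = ek.simulate_heldout_patient("unfavorable", seed=0)
calls, majority = ek.classify_patient(model2d, before + after)
print("held-out unfavorable patient:", majority)
```

prints

```
best KNN: {'n_neighbors': 7, 'metric': 'chebyshev', 'weighting': 'equal'} (cv error 0.000)
TPR unhealthy: 100.0%  TPR healthy: 100.0%  AUC: 1.00
held-out unfavorable patient: {'after': 'unhealthy', 'before': 'unhealthy'}
```

The optimized model separates the two surgical phases perfectly on the
synthetic cohort (the class contrast is built into the generator; see
`docs/methods.md` for what this does and does not demonstrate), and the
unfavorable held-out patient — whose kinematic parameters *increase*
after surgery — is correctly kept in the unhealthy region of the SNR
decision surface in both phases, flagging the poor outcome before chest
closure.

The same pipeline is available from the shell:

```bash
epikin simulate --n-patients 12 --seed 0 --out-dir cohort/
epikin features --in cohort/manifest.json --out features.csv
epikin train --features features.csv --model svm --iters 100 --seed 0 --out svm.json
epikin evaluate --model svm.json --features features.csv --report report.json
epikin surface --model svm.json --features features.csv --resolution 200 --out surface.csv
epikin stats samplesize --prevalence 1/3500
```

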