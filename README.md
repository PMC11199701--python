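# kinemetrix

Interpretable kinematics from 2D video-pose landmarks: extract validated gait
and finger-tapping features from pose-estimator time series, classify high-
vs low-severity parkinsonian motor state under leave-one-subject-out
cross-validation, and produce stability / SHAP / MDS interpretation reports.
A landmark-level synthetic cohort simulator makes every stage testable
without any patient data.

## Pipeline

1. **kinematics_io** — landmark CSV + JSON sidecar readers/writers, cohort
   manifest, severity dichotomization (MDS-UPDRS III > threshold → high;
   sample-median or fixed threshold of 32).
2. **preprocessing** — 5-point rolling Gaussian smoothing (σ = 0.5),
   validity rules (standing: lower leg ≤ 2× upper leg; facing: wrist–hip
   offsets of opposite sign; flicker: rapid shoulder-distance zero crossings;
   hand: exactly one raised hand), 0.333 s invalid-window dilation, and
   segmentation into 3–8 s artifact-free segments.
3. **relations** — 13 body + 4 hand relational time series (angles,
   distances, signed displacements), per-frame normalization by body/palm
   length, per-second forward-difference derivatives.
4. **feature_extraction** — 8 temporal + 5 spectral metrics per value and
   derivative channel (338 body / 104 hand features), left/right folding into
   min/max features, and the combined bi-modality table (cartesian pairing
   within subject × medication state).
5. **modeling** — repeated (×16) leave-one-subject-out CV with per-fold
   standardization, inner subject-grouped LASSO alpha selection, seven
   classifiers (LDA, LR, SVM, RF, AdaBoost, KNN, GNB), pooled per-repeat
   accuracy/ROC/AUC.
6. **interpretation** — selection-frequency stability (≥ 50 % of CV
   iterations), group statistics, closed-form linear SHAP, classical
   (Torgerson) MDS and a silhouette separability score.
7. **synthetic_data** — deterministic cohorts of schematic walkers and
   tapping hands with severity effects injected at the landmark level plus
   tracking artifacts (dropout, flicker, crouch, both-hands-raised).

Feature names follow `<relation>.<side|min|max>.<value|deriv>.<metric>`
(side segment absent for unsided relations), with `body.`/`hand.` prefixes in
the combined table.

## CLI

```sh
kinemetrix simulate  -c examples/pipeline.yaml          # cohort on disk
kinemetrix extract   -c examples/pipeline.yaml OUT/cohort
kinemetrix train     -c examples/pipeline.yaml OUT/features/features_combined.csv
kinemetrix interpret -c examples/pipeline.yaml OUT/cv_report.json \
                     OUT/features/features_combined.csv
```

All stages are restartable from their on-disk artifacts; reruns with the same
config and seed are byte-identical. See `examples/pipeline.yaml` for the full
config schema (unknown keys are rejected).

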