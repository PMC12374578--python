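"""Differential features and classification on a synthetic two-class cohort.

Generates a cohort with ten planted two-fold features (the kind of effect
size that separates tumour subtypes on relative intensities), then runs the
volcano gate, PCA, and the class-weighted boosted-tree classifier with
stratified split and 5-fold cross-validation.
"""

import numpy as np

import segscan as ss

cohort = ss.generate_cohort(
    n_per_class=30, n_features=200,
    planted=[(i, 2.0) for i in range(10)],
    seed=0,
)
print(f"cohort: {len(cohort.labels)} samples x {cohort.values.shape[1]} "
      f"features, classes {cohort.classes}")

vol = ss.volcano(cohort, "case", "control")
planted = set(cohort.values.columns[:10])
found = set(vol.significant_features)
print(f"volcano (p<0.05, FC>1.5 or <2/3): {vol.n_significant} significant, "
      f"{len(planted & found)}/10 planted features recovered")

scores, evr = ss.unsupervised(cohort, "pca", n_components=2)
print(f"PCA: first two components explain {100*evr[:2].sum():.0f}% of variance")

report = ss.train_classifier(cohort, seed=0, with_ci=True)
folds = ss.crossvalidate(cohort, folds=5, seed=0)
lo, hi = report.auc_test_ci
print(f"XGBoost (class-weighted, stratified 80:20 split):")
print(f"  train AUC {report.auc_train:.3f}, held-out AUC {report.auc_test:.3f} "
      f"(95% bootstrap CI {lo:.3f}-{hi:.3f})")
print(f"  5-fold AUCs: {', '.join(f'{a:.3f}' for a in folds)}")
print(f"  median per-sample confidence on the test set: "
      f"{float(np.median(report.confidence)):.3f}")

# An AUC near 1 with tight fold-to-fold spread indicates the planted
# metabolic signature is learned robustly rather than memorized; the
# per-sample confidence is the predicted class probability reported to the
# operator for each specimen.
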