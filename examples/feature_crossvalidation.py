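"""Cross-validate the pixel classifiers on a small synthetic cohort.

An 80-subject cohort is standardized and background-normalized; logistic
regression, k-nearest neighbours and gradient boosted trees are each
evaluated by fourfold cross-validation (flip-augmented training folds) for
the low-uptake and dot-shape features.
"""
import numpy as np

from datspect import feature_ml, phantom, preprocess

cohort = phantom.generate_cohort(80, seed=5)
prep = [preprocess.preprocess_volume(r.volume, r.subject_id) for r in cohort]
maxn = [preprocess.normalize_max(f, p) for f, p in prep]
mask = preprocess.build_group_striatal_mask(preprocess.augment_flip(maxn))
images = [preprocess.normalize_background(f, mask) for f, p in prep]

for feature in ("low", "dot"):
    y = np.array([getattr(r.labels, feature) for r in cohort], dtype=int)
    print(f"\nfeature: {feature}  (prevalence {y.mean():.2f})")
    for method in ("lr", "knn", "gbt"):
        spec = feature_ml.ClassifierSpec(method=method, seed=0,
                                         hyperparameters={"n_estimators": 60}
                                         if method == "gbt" else {})
        rep, _ = feature_ml.crossvalidate_fourfold(images, y, spec, seed=2)
        print(f"  {method:>3}: AUC {rep.auc:.3f}  recall {rep.recall:.2f}  "
              f"precision {rep.precision:.2f}  F1 {rep.f1_score:.2f}  "
              f"accuracy {rep.accuracy:.2f}")
# AUC is the pooled out-of-fold probability's Mann-Whitney statistic; the
# other metrics use a 0.5 probability threshold.
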