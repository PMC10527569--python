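"""Cross-validated multiclass metric panel for several classifiers.

Evaluates a few roster classifiers on the same synthetic 7-class table with
10-fold stratified cross-validation and prints one table row per classifier:
accuracy, macro sensitivity/precision, F1, Fowlkes-Mallows, MCC and kappa.
"""

from dermfusion import FeatureFixtureSpec, crossval_classify, make_feature_dataset

mat, _ = make_feature_dataset(FeatureFixtureSpec(n_samples=210, n_classes=7,
                                                 class_separation=2.5, seed=3))

print(f"{'classifier':>14} {'acc':>6} {'sens':>6} {'prec':>6} {'f1':>6} "
      f"{'fm':>6} {'mcc':>6} {'kappa':>6}")
for name in ("fine_knn", "weighted_knn", "quadratic_svm", "fine_tree", "bagged_tree"):
    rep = crossval_classify(mat, name, folds=10, seed=7)
    print(f"{name:>14} {rep.accuracy:>6.3f} {rep.sensitivity:>6.3f} "
          f"{rep.precision:>6.3f} {rep.f1:>6.3f} {rep.fowlkes_mallows:>6.3f} "
          f"{rep.mcc:>6.3f} {rep.kappa:>6.3f}")

print("\nMCC and kappa are chance-corrected: 0 means no better than guessing,")
print("1 means a perfectly diagonal confusion matrix.")
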