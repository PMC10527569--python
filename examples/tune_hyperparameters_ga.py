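"""GA hyperparameter tuning of a degree-2 polynomial SVM.

Replaces manual hyperparameter assignment: declares a log-scale search space
over (C, gamma), scores each candidate by stratified hold-out accuracy, and
evolves for a few generations.  The best-so-far trace is monotone thanks to
elitism.
"""

from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from dermfusion import (
    FeatureFixtureSpec,
    ParamSpec,
    SearchSpace,
    evolve,
    init_population,
    make_feature_dataset,
)

mat, _ = make_feature_dataset(FeatureFixtureSpec(n_samples=210, n_classes=7,
                                                 class_separation=3.0, seed=1))
x_tr, x_val, y_tr, y_val = train_test_split(mat.values, mat.labels, test_size=0.3,
                                            stratify=mat.labels, random_state=7)


def fitness(params):
    clf = SVC(kernel="poly", degree=2, C=params["C"], gamma=params["gamma"])
    clf.fit(x_tr, y_tr)
    return clf.score(x_val, y_val)


space = SearchSpace(params=(
    ParamSpec(name="C", kind="log", low=1e-2, high=1e2),
    ParamSpec(name="gamma", kind="log", low=1e-3, high=1e1),
))
best, trace = evolve(init_population(space, 12, seed=7), space, fitness,
                     generations=10, seed=7)

print(f"best hold-out accuracy: {best.fitness:.3f}")
print(f"best C:                 {best.values['C']:.4g}")
print(f"best gamma:             {best.values['gamma']:.4g}")
print(f"trace: {[round(float(v), 3) for v in trace]}")
print("\nThe trace never decreases: elitism carries the best configuration forward.")
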