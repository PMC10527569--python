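"""End-to-end orchestration: enhance -> augment -> extract -> fuse ->
GA-tune -> select -> evaluate, from a single seeded config.

The pipeline runs either from synthetic lesion images (exercising the
enhancement and extraction stages) or directly from synthetic multi-source
feature tables (the default, exercising fusion, tuning, selection and
evaluation).  Every stage draws its seed from the global config seed, so
two runs with the same config produce identical reports apart from
timings.

Train/test hygiene: flip augmentation, when enabled, is applied only inside
training folds — flip variants of a test image never enter the training
set.  Evaluating on augmented copies of training data would leak
near-duplicates across the split and inflate every metric.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .alo import FitnessSpec, run_alo_md
from .enhancement import HazeParams, MorphParams, enhance_image
from .features import ExtractorSpec, FeatureMatrix, augment_flips, extract_features
from .fusion import FusionResult, fuse_select, serial_fuse
from .ga import ParamSpec, SearchSpace, evolve, init_population
from .metrics import EvalReport, compute_metrics, confusion, crossval_classify, make_classifier
from .synthetic import (
    FeatureFixtureSpec,
    ImageFixtureSpec,
    make_feature_dataset,
    make_hazy_images,
    split_multisource,
)

__all__ = ["RunConfig", "RunReport", "default_run_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Stage toggles and parameters for one pipeline run."""

    seed: int = 7
    # --- image stage (optional) ---
    use_images: bool = False
    image_spec: ImageFixtureSpec | None = None
    enhance_enabled: bool = True
    haze: HazeParams = field(default_factory=HazeParams)
    morph: MorphParams | None = None
    augment_enabled: bool = False
    extractors: tuple[ExtractorSpec, ...] = (
        ExtractorSpec(name="toyA", embed_dim=16),
        ExtractorSpec(name="toyB", embed_dim=16),
        ExtractorSpec(name="toyC", embed_dim=16),
    )
    # --- feature-table stage (default source) ---
    feature_specs: tuple[FeatureFixtureSpec, ...] = ()
    # --- fusion ---
    fusion_threshold: float = 0.5
    knn_k: int = 1
    folds: int = 10
    # --- GA hyperparameter tuning ---
    ga_enabled: bool = True
    ga_pop: int = 10
    ga_generations: int = 8
    # --- ALO-MD selection ---
    alo_enabled: bool = True
    n_ants: int = 20
    n_antlions: int = 20
    iterations: int = 40
    alpha: float = 0.99
    md_enabled: bool = True
    # --- evaluation ---
    classifier_name: str = "fine_knn"


def default_run_config(seed: int = 7) -> RunConfig:
    """Default study conditions: three complementary synthetic feature sources.

    Each source carries 2 informative columns (paired with their redundant
    copies) and 12 noise columns over 7 classes; the sources use different
    seeds, so each one resolves a different grouping of the classes and only
    their fusion separates all seven — the situation multi-backbone fusion
    is meant for.
    """
    specs = tuple(
        FeatureFixtureSpec(
            n_samples=210,
            n_classes=7,
            n_informative=2,
            n_noise=12,
            n_redundant=2,
            class_separation=6.0,
            layout="paired",
            seed=seed + 101 * (i + 1),
        )
        for i in range(3)
    )
    return RunConfig(seed=seed, feature_specs=specs)


@dataclass
class RunReport:
    """Machine-readable outcome of one pipeline run."""

    timings: dict
    feature_counts: dict
    fusion: dict
    ga: dict | None
    selection: dict | None
    eval_individual: list[dict]
    eval_fused: dict
    eval_selected: dict | None
    seed: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def _eval_to_dict(report: EvalReport, name: str) -> dict:
    out = report.to_dict()
    out["name"] = name
    return out


def _augmented_crossval(
    variants: list[FeatureMatrix], classifier_name: str, folds: int, seed: int
) -> EvalReport:
    """CV where flip variants join only the training folds.

    ``variants[0]`` holds the original samples; the remaining matrices hold
    one flip variant each, row-aligned with the originals.  Folds are formed
    over originals; each training fold is the union of its originals and all
    their variants, while test folds contain originals only.
    """
    orig = variants[0]
    y = orig.labels
    classes, counts = np.unique(y, return_counts=True)
    n_folds = max(2, min(folds, int(counts.min())))
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    t0 = time.perf_counter()
    for train_idx, test_idx in splitter.split(orig.values, y):
        train_x = np.vstack([v.values[train_idx] for v in variants])
        train_y = np.concatenate([y[train_idx]] * len(variants))
        clf = make_classifier(classifier_name)
        clf.fit(train_x, train_y)
        pred[test_idx] = clf.predict(orig.values[test_idx])
    elapsed = time.perf_counter() - t0
    cm = confusion(y, pred, class_names=classes.tolist())
    return compute_metrics(cm, elapsed_time=elapsed)


def _image_sources(config: RunConfig):
    """Generate (and optionally enhance/augment) images, then extract features.

    Returns one list of per-variant FeatureMatrix objects per extractor;
    without augmentation each list has a single entry (the originals).
    """
    spec = config.image_spec or ImageFixtureSpec(seed=config.seed, images_per_class=10)
    imageset = make_hazy_images(spec)
    images, labels = imageset.hazy, imageset.labels
    if config.enhance_enabled:
        images = [enhance_image(img, config.haze, config.morph) for img in images]
    variant_lists = [images]
    if config.augment_enabled:
        quads, _ = augment_flips(images, labels)
        variant_lists = [quads[v::4] for v in range(4)]
    sources = []
    for ext in config.extractors:
        sources.append([
            extract_features(variant, ext, labels=labels) for variant in variant_lists
        ])
    return sources


def _feature_sources(config: RunConfig):
    specs = config.feature_specs or default_run_config(config.seed).feature_specs
    sources = []
    for spec in specs:
        mat, _ = make_feature_dataset(spec)
        sources.append([mat])
    return sources


def _ga_stage(config: RunConfig, data: FeatureMatrix) -> dict:
    """Tune a degree-2 polynomial SVM (C, gamma) by stratified hold-out accuracy."""
    x, y = data.values, data.labels
    x_tr, x_val, y_tr, y_val = train_test_split(
        x, y, test_size=0.3, stratify=y, random_state=config.seed
    )

    def fitness(params: dict) -> float:
        clf = SVC(kernel="poly", degree=2, C=params["C"], gamma=params["gamma"])
        clf.fit(x_tr, y_tr)
        return float(clf.score(x_val, y_val))

    space = SearchSpace(params=(
        ParamSpec(name="C", kind="log", low=1e-2, high=1e2),
        ParamSpec(name="gamma", kind="log", low=1e-3, high=1e1),
    ))
    pop = init_population(space, config.ga_pop, config.seed)
    best, trace = evolve(
        pop, space, fitness,
        generations=config.ga_generations, seed=config.seed,
    )
    return {
        "classifier": "quadratic_svm",
        "best_params": best.values,
        "best_holdout_accuracy": best.fitness,
        "trace": [float(v) for v in trace],
    }


def run_pipeline(config: RunConfig | None = None) -> RunReport:
    """Execute the enabled stages in order and return the comparative report.

    The report contrasts each individual feature source, the serially fused
    set, and the ALO-selected subset under the same cross-validated
    classifier — the experiment design the method is built around, at
    synthetic-fixture scale.
    """
    if config is None:
        config = default_run_config()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.use_images:
        sources = _image_sources(config)
    else:
        sources = _feature_sources(config)
    timings["data"] = time.perf_counter() - t0

    n_variants = len(sources[0])

    def evaluate(variant_sets: list[FeatureMatrix], name: str) -> dict:
        if len(variant_sets) == 1:
            rep = crossval_classify(
                variant_sets[0], config.classifier_name, config.folds, config.seed
            )
        else:
            rep = _augmented_crossval(
                variant_sets, config.classifier_name, config.folds, config.seed
            )
        return _eval_to_dict(rep, name)

    # --- fusion (on original, non-augmented rows) ---
    t0 = time.perf_counter()
    originals = [src[0] for src in sources]
    fusion: FusionResult = fuse_select(
        originals,
        threshold=config.fusion_threshold,
        k=config.knn_k,
        folds=config.folds,
        seed=config.seed,
    )
    timings["fusion"] = time.perf_counter() - t0

    # --- GA hyperparameter tuning ---
    ga_report = None
    if config.ga_enabled:
        t0 = time.perf_counter()
        ga_report = _ga_stage(config, fusion.chosen_set)
        timings["ga"] = time.perf_counter() - t0

    # --- ALO-MD wrapper selection on the fusion-chosen set ---
    selection = None
    selected_cols: list[int] | None = None
    if config.alo_enabled:
        t0 = time.perf_counter()
        fitness_spec = FitnessSpec(
            alpha=config.alpha, k=config.knn_k, folds=config.folds, seed=config.seed
        )
        mask, trace = run_alo_md(
            fusion.chosen_set,
            fitness_spec,
            n_ants=config.n_ants,
            n_antlions=config.n_antlions,
            S=config.iterations,
            seed=config.seed,
            md_enabled=config.md_enabled,
        )
        selected_cols = [fusion.chosen_columns[i] for i in mask.indices]
        selection = {
            "bits": mask.bits.astype(int).tolist(),
            "n_selected": mask.n_selected,
            "selected_fused_columns": selected_cols,
            "trace": [float(v) for v in trace],
            "md_enabled": config.md_enabled,
        }
        timings["selection"] = time.perf_counter() - t0

    # --- comparative evaluation ---
    t0 = time.perf_counter()
    eval_individual = []
    for idx, src in enumerate(sources):
        eval_individual.append(evaluate(src, f"source_{idx}"))
    fused_variants = [
        serial_fuse([src[v] for src in sources]) for v in range(n_variants)
    ]
    eval_fused = evaluate(fused_variants, "fused")
    eval_selected = None
    if selected_cols is not None:
        selected_variants = [fv.select_columns(selected_cols) for fv in fused_variants]
        eval_selected = evaluate(selected_variants, "selected")
    timings["evaluation"] = time.perf_counter() - t0

    feature_counts = {
        "individual": [src[0].n_features for src in sources],
        "fused": fusion.fused.n_features,
        "chosen_fusion_set": fusion.chosen_set.n_features,
        "selected": len(selected_cols) if selected_cols is not None else None,
    }
    return RunReport(
        timings=timings,
        feature_counts=feature_counts,
        fusion=fusion.summary(),
        ga=ga_report,
        selection=selection,
        eval_individual=eval_individual,
        eval_fused=eval_fused,
        eval_selected=eval_selected,
        seed=config.seed,
    )
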