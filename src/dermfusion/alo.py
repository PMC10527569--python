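"""Antlion optimization with a mean-deviation restart (ALO-MD) for wrapper
feature selection.

Ants (candidate solutions) random-walk inside per-dimension intervals that
shrink as iterations progress and are recentered on antlions chosen by a
fitness-proportional roulette wheel; each ant's move averages a walk guided
by its roulette antlion with a walk guided by the elite (best-so-far)
antlion.  An antlion that is beaten by its ant is replaced by it, and the
elite is updated whenever any antlion improves on it.

Positions live in the unit box [0, 1]^d and are decoded to feature subsets
by thresholding at 0.5.  The wrapper fitness (to be *minimized*) combines
the cross-validated 1-NN error with a small subset-size penalty:

    score = alpha * (1 - cv_accuracy) + (1 - alpha) * n_selected / d

The mean-deviation (MD) mechanism adds a diversification step: after each
iteration, ants whose score is worse than the population mean plus the mean
absolute deviation are re-seeded uniformly inside the current elite-centered
interval and re-scored.  The elite itself is never touched, so elitism is
preserved.  The mechanism can be disabled (``md_enabled=False``) for
ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix
from .fusion import knn_fitness

__all__ = [
    "SelectionMask",
    "FitnessSpec",
    "AntlionState",
    "random_walk",
    "normalize_walk",
    "shrink_bounds",
    "shift_bounds",
    "roulette_select",
    "elitism_combine",
    "catch_and_rebuild",
    "binarize",
    "selection_fitness",
    "exhaustive_best_score",
    "run_alo_md",
]


@dataclass(frozen=True)
class SelectionMask:
    """Binary feature-subset mask decoded from a continuous position."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass(frozen=True)
class FitnessSpec:
    """Wrapper-fitness configuration.

    alpha weights classification error against subset size; with the default
    0.99 accuracy dominates and sparsity only breaks near-ties.  The
    classifier is a Euclidean k-NN evaluated with seeded stratified
    cross-validation, so the fitness is deterministic.
    """

    alpha: float = 0.99
    k: int = 1
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass
class AntlionState:
    """Populations, elite and adaptive bounds at one iteration (for inspection)."""

    ants: np.ndarray
    antlions: np.ndarray
    ant_scores: np.ndarray
    antlion_scores: np.ndarray
    elite: np.ndarray
    elite_score: float
    as_vec: np.ndarray
    bs_vec: np.ndarray
    s: int
    S: int
    ratio_I: float


def _as_rng(seed_or_rng):
    # anything exposing .random(n) (a Generator or a test stub) passes through
    if hasattr(seed_or_rng, "random"):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_walk(S: int, seed) -> np.ndarray:
    """Cumulative +/-1 random walk of length S+1 starting at 0.

    Each step is +1 when a uniform draw exceeds 0.5 and -1 otherwise.
    """
    if S < 1:
        raise ValueError(f"S must be >= 1, got {S}")
    rng = _as_rng(seed)
    steps = np.where(rng.random(S) > 0.5, 1.0, -1.0)
    return np.concatenate([[0.0], np.cumsum(steps)])


def normalize_walk(walk: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Min-max rescale a raw walk into the interval [lo, hi].

    A constant walk maps to the interval midpoint; a degenerate interval
    (lo == hi) gives a constant output at that value.
    """
    walk = np.asarray(walk, dtype=np.float64)
    if hi < lo:
        raise ValueError("interval upper bound below lower bound")
    wmin, wmax = walk.min(), walk.max()
    if wmax == wmin or hi == lo:
        return np.full_like(walk, (lo + hi) / 2.0)
    return (walk - wmin) * (hi - lo) / (wmax - wmin) + lo


def _u_exponent(s: int, S: int) -> int:
    """Exploitation exponent schedule: 2/4/5/6 past 10/50/75/90% of the run."""
    f = s / S
    if f > 0.9:
        return 6
    if f > 0.75:
        return 5
    if f > 0.5:
        return 4
    if f > 0.1:
        return 2
    return 1


def shrink_bounds(a, b, s: int, S: int):
    """Adaptively shrink the walk interval: as = a/I, bs = b/I, I = 10^u * s/S.

    The shrink ratio I is floored at 1 (no expansion; s = 0 means no
    shrink), so interval width is non-increasing over iterations.
    """
    if s < 0 or S < 1 or s > S:
        raise ValueError(f"need 0 <= s <= S with S >= 1, got s={s}, S={S}")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ratio = 1.0 if s == 0 else max(1.0, 10.0 ** _u_exponent(s, S) * s / S)
    return a / ratio, b / ratio, ratio


def shift_bounds(as_vec, bs_vec, antlion_pos):
    """Recenter the shrunk interval on an antlion, clipped to the unit box.

    Width is preserved (up to clipping) and the center moves to the antlion
    position.
    """
    as_vec = np.asarray(as_vec, dtype=np.float64)
    bs_vec = np.asarray(bs_vec, dtype=np.float64)
    pos = np.asarray(antlion_pos, dtype=np.float64)
    half = (bs_vec - as_vec) / 2.0
    lo = np.clip(pos - half, 0.0, 1.0)
    hi = np.clip(pos + half, 0.0, 1.0)
    return lo, hi


def roulette_select(fitnesses, rng) -> int:
    """Fitness-proportional roulette selection (higher fitness, higher odds).

    Weights are min-shifted fitnesses plus a tiny epsilon, so all-equal
    fitnesses give a uniform draw.
    """
    f = np.asarray(fitnesses, dtype=np.float64)
    if f.size == 0:
        raise ValueError("roulette_select needs at least one fitness")
    rng = _as_rng(rng)
    w = f - f.min() + 1e-12
    cum = np.cumsum(w)
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right").clip(0, f.size - 1))


def elitism_combine(walk_roulette_pos, walk_elite_pos) -> np.ndarray:
    """Elementwise midpoint of the roulette-guided and elite-guided walks."""
    pa = np.asarray(walk_roulette_pos, dtype=np.float64)
    pf = np.asarray(walk_elite_pos, dtype=np.float64)
    if pa.shape != pf.shape:
        raise ValueError("walk positions must have the same dimension")
    return (pa + pf) / 2.0


def catch_and_rebuild(state: AntlionState, ant_idx: int, antlion_idx: int) -> AntlionState:
    """Replace an antlion by its ant iff the ant scores strictly better.

    Scores are minimized.  The elite is updated only if the (possibly
    replaced) antlion beats it, so the elite never worsens.  Ties keep the
    incumbent antlion.
    """
    ant_score = state.ant_scores[ant_idx]
    if ant_score < state.antlion_scores[antlion_idx]:
        state.antlions[antlion_idx] = state.ants[ant_idx]
        state.antlion_scores[antlion_idx] = ant_score
        if ant_score < state.elite_score:
            state.elite = state.ants[ant_idx].copy()
            state.elite_score = float(ant_score)
    return state


def binarize(position) -> SelectionMask:
    """Threshold a continuous position at 0.5; rescue an empty mask.

    If no coordinate exceeds 0.5 the single largest coordinate (first one on
    ties) is switched on, so every returned mask selects at least one
    feature.
    """
    pos = np.asarray(position, dtype=np.float64)
    bits = pos > 0.5
    if not bits.any():
        bits = np.zeros_like(bits)
        bits[int(np.argmax(pos))] = True
    return SelectionMask(bits=bits)


def selection_fitness(mask: SelectionMask, data: FeatureMatrix, spec: FitnessSpec) -> float:
    """Wrapper score (lower is better): weighted CV error plus subset-size share."""
    d = data.n_features
    if mask.bits.shape != (d,):
        raise ValueError("mask length must match the number of features")
    if mask.n_selected == 0:
        return 1.0  # worst possible: full error and full subset penalty
    acc = knn_fitness(data.select_columns(mask.indices), spec.k, spec.folds, spec.seed)
    return spec.alpha * (1.0 - acc) + (1.0 - spec.alpha) * mask.n_selected / d


def exhaustive_best_score(data: FeatureMatrix, spec: FitnessSpec) -> float:
    """Brute-force optimum of the wrapper score over all non-empty subsets.

    Only feasible for small d; used as an independent oracle for the
    optimizer.
    """
    d = data.n_features
    if d > 20:
        raise ValueError("exhaustive search is limited to d <= 20")
    best = np.inf
    for code in range(1, 2**d):
        bits = np.array([(code >> i) & 1 for i in range(d)], dtype=bool)
        score = selection_fitness(SelectionMask(bits=bits), data, spec)
        best = min(best, score)
    return float(best)


def _walk_position(d: int, s: int, S: int, lo: np.ndarray, hi: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Position at step s of fresh per-dimension walks rescaled into [lo, hi]."""
    steps = np.where(rng.random((d, S)) > 0.5, 1.0, -1.0)
    walks = np.concatenate([np.zeros((d, 1)), np.cumsum(steps, axis=1)], axis=1)
    wmin = walks.min(axis=1)
    wmax = walks.max(axis=1)
    span = wmax - wmin
    width = hi - lo
    pos = np.where(
        span > 0,
        (walks[:, s] - wmin) * width / np.where(span > 0, span, 1.0) + lo,
        (lo + hi) / 2.0,
    )
    return pos


def run_alo_md(
    data: FeatureMatrix,
    spec: FitnessSpec = FitnessSpec(),
    n_ants: int = 20,
    n_antlions: int = 20,
    S: int = 50,
    seed: int = 0,
    md_enabled: bool = True,
):
    """Run the full ALO-MD loop and return ``(SelectionMask, trace)``.

    The trace holds the elite score after initialization and after each of
    the S iterations; it is non-increasing by construction.  Runs are fully
    reproducible given the seed.  Fitness evaluations are memoized per mask,
    which changes nothing numerically (the wrapper score is deterministic).
    """
    d = data.n_features
    if d < 2:
        raise ValueError("feature selection needs at least 2 features")
    if S < 1 or n_ants < 1 or n_antlions < 1:
        raise ValueError("population sizes and iteration count must be >= 1")
    rng = np.random.default_rng(seed)
    cache: dict[bytes, float] = {}

    def score(pos: np.ndarray) -> float:
        bits = binarize(pos).bits
        key = np.packbits(bits).tobytes()
        if key not in cache:
            cache[key] = selection_fitness(SelectionMask(bits=bits), data, spec)
        return cache[key]

    ants = rng.random((n_ants, d))
    antlions = rng.random((n_antlions, d))
    ant_scores = np.array([score(p) for p in ants])
    antlion_scores = np.array([score(p) for p in antlions])

    # Seed the antlion population with any stronger initial ants before
    # picking the elite, so no good starting point is lost.
    order = np.argsort(np.concatenate([antlion_scores, ant_scores]))[:n_antlions]
    pool = np.vstack([antlions, ants])
    pool_scores = np.concatenate([antlion_scores, ant_scores])
    antlions = pool[order].copy()
    antlion_scores = pool_scores[order].copy()

    elite_idx = int(np.argmin(antlion_scores))
    elite = antlions[elite_idx].copy()
    elite_score = float(antlion_scores[elite_idx])
    trace = [elite_score]

    a = np.zeros(d)
    b = np.ones(d)
    for s in range(1, S + 1):
        as_vec, bs_vec, _ = shrink_bounds(a, b, s, S)
        lo_e, hi_e = shift_bounds(as_vec, bs_vec, elite)
        chosen_lions = np.empty(n_ants, dtype=int)
        for i in range(n_ants):
            j = roulette_select(-antlion_scores, rng)
            chosen_lions[i] = j
            lo_a, hi_a = shift_bounds(as_vec, bs_vec, antlions[j])
            pa = _walk_position(d, s, S, lo_a, hi_a, rng)
            pf = _walk_position(d, s, S, lo_e, hi_e, rng)
            ants[i] = np.clip(elitism_combine(pa, pf), 0.0, 1.0)
        ant_scores = np.array([score(p) for p in ants])

        if md_enabled and n_ants > 1:
            mu = ant_scores.mean()
            mad = np.abs(ant_scores - mu).mean()
            bad = np.flatnonzero(ant_scores > mu + mad)
            for i in bad:
                ants[i] = rng.uniform(lo_e, hi_e)
                ant_scores[i] = score(ants[i])

        state = AntlionState(
            ants=ants, antlions=antlions,
            ant_scores=ant_scores, antlion_scores=antlion_scores,
            elite=elite, elite_score=elite_score,
            as_vec=as_vec, bs_vec=bs_vec, s=s, S=S, ratio_I=0.0,
        )
        for i in range(n_ants):
            state = catch_and_rebuild(state, i, int(chosen_lions[i]))
        antlions, antlion_scores = state.antlions, state.antlion_scores
        elite, elite_score = state.elite, state.elite_score
        trace.append(elite_score)

    return binarize(elite), np.asarray(trace)
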