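import numpy as np
import pytest

from dermfusion import (
    FitnessSpec,
    SelectionMask,
    binarize,
    catch_and_rebuild,
    elitism_combine,
    exhaustive_best_score,
    normalize_walk,
    random_walk,
    roulette_select,
    run_alo_md,
    selection_fitness,
    shift_bounds,
    shrink_bounds,
)
from dermfusion.alo import AntlionState


class _StubRng:
    """Feeds a predetermined uniform sequence to the walk generator."""

    def __init__(self, draws):
        self.draws = np.asarray(draws, dtype=float)

    def random(self, n=None):
        if n is None:
            out, self.draws = self.draws[0], self.draws[1:]
            return out
        out, self.draws = self.draws[:n], self.draws[n:]
        return out


class TestRandomWalk:
    def test_single_step_up(self):
        assert np.array_equal(random_walk(1, _StubRng([0.7])), [0.0, 1.0])

    def test_prescribed_sequence(self):
        walk = random_walk(4, _StubRng([0.6, 0.2, 0.9, 0.1]))
        assert np.array_equal(walk, [0.0, 1.0, 0.0, 1.0, 0.0])

    def test_unit_steps_and_zero_start(self):
        walk = random_walk(50, seed=3)
        assert walk[0] == 0.0
        assert np.all(np.abs(np.diff(walk)) == 1.0)

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            random_walk(0, seed=0)


class TestNormalizeWalk:
    def test_min_max_rescale(self):
        assert np.allclose(normalize_walk(np.array([0, 1, 2]), 0.0, 1.0), [0, 0.5, 1])

    def test_constant_walk_maps_to_midpoint(self):
        out = normalize_walk(np.zeros(5), 0.2, 0.8)
        assert np.allclose(out, 0.5)

    def test_degenerate_interval_gives_constant(self):
        out = normalize_walk(np.array([0, 1, 2]), 0.4, 0.4)
        assert np.allclose(out, 0.4)

    def test_output_within_interval(self, rng):
        walk = np.cumsum(rng.choice([-1.0, 1.0], 30))
        out = normalize_walk(walk, 0.0, 1.0)
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)


class TestBounds:
    def test_shrink_ratio_examples(self):
        _, _, ratio = shrink_bounds(0.0, 1.0, s=60, S=100)
        assert ratio == pytest.approx(6000.0)
        _, _, ratio = shrink_bounds(0.0, 1.0, s=100, S=100)
        assert ratio == pytest.approx(1e6)

    def test_no_shrink_at_start(self):
        lo, hi, ratio = shrink_bounds(0.0, 1.0, s=0, S=50)
        assert ratio == 1.0 and lo == 0.0 and hi == 1.0

    def test_width_non_increasing_over_iterations(self):
        widths = []
        for s in range(1, 101):
            lo, hi, _ = shrink_bounds(0.0, 1.0, s, 100)
            widths.append(hi - lo)
        assert np.all(np.diff(widths) <= 1e-15)

    def test_shift_recenters_on_antlion(self):
        lo, hi = shift_bounds(-0.1, 0.1, 0.5)
        assert lo == pytest.approx(0.4) and hi == pytest.approx(0.6)

    def test_shift_clips_at_unit_box(self):
        lo, hi = shift_bounds(-0.2, 0.2, 0.0)
        assert lo == 0.0 and hi == pytest.approx(0.2)

    def test_zero_width_bounds_collapse_to_antlion(self):
        lo, hi = shift_bounds(0.0, 0.0, 0.3)
        assert lo == hi == pytest.approx(0.3)


class TestRoulette:
    def test_single_candidate(self):
        assert roulette_select([0.7], np.random.default_rng(0)) == 0

    def test_dominant_fitness_dominates_selection(self):
        rng = np.random.default_rng(1)
        picks = [roulette_select([1.0, 0.0, 0.0, 0.0], rng) for _ in range(10_000)]
        assert np.mean(np.array(picks) == 0) >= 0.95

    def test_equal_fitness_uniform(self):
        rng = np.random.default_rng(2)
        picks = np.array([roulette_select([0.3] * 4, rng) for _ in range(10_000)])
        for idx in range(4):
            assert abs(np.mean(picks == idx) - 0.25) < 0.02


class TestElitismCombine:
    @pytest.mark.parametrize(
        "pa, pf, expected",
        [
            ([0, 1], [1, 0], [0.5, 0.5]),
            ([0.2, 0.8], [0.2, 0.8], [0.2, 0.8]),
            ([0.2, 0.4, 0.6], [0.4, 0.2, 0.0], [0.3, 0.3, 0.3]),
        ],
    )
    def test_midpoint(self, pa, pf, expected):
        assert np.allclose(elitism_combine(pa, pf), expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            elitism_combine([0.1], [0.1, 0.2])


def _state(ant_score, antlion_score, elite_score):
    return AntlionState(
        ants=np.array([[0.9, 0.9]]),
        antlions=np.array([[0.1, 0.1]]),
        ant_scores=np.array([ant_score]),
        antlion_scores=np.array([antlion_score]),
        elite=np.array([0.5, 0.5]),
        elite_score=elite_score,
        as_vec=np.zeros(2), bs_vec=np.ones(2), s=1, S=10, ratio_I=1.0,
    )


class TestCatchAndRebuild:
    def test_worse_ant_leaves_state_unchanged(self):
        state = catch_and_rebuild(_state(0.5, 0.2, 0.1), 0, 0)
        assert np.allclose(state.antlions[0], [0.1, 0.1])
        assert state.elite_score == 0.1

    def test_ant_better_than_antlion_and_elite(self):
        state = catch_and_rebuild(_state(0.05, 0.2, 0.1), 0, 0)
        assert np.allclose(state.antlions[0], [0.9, 0.9])
        assert state.elite_score == 0.05
        assert np.allclose(state.elite, [0.9, 0.9])

    def test_ant_between_antlion_and_elite(self):
        state = catch_and_rebuild(_state(0.15, 0.2, 0.1), 0, 0)
        assert np.allclose(state.antlions[0], [0.9, 0.9])
        assert state.elite_score == 0.1  # elite kept

    def test_tie_keeps_incumbent(self):
        state = catch_and_rebuild(_state(0.2, 0.2, 0.1), 0, 0)
        assert np.allclose(state.antlions[0], [0.1, 0.1])


class TestBinarize:
    @pytest.mark.parametrize(
        "position, expected",
        [
            ([0.9, 0.1, 0.6], [1, 0, 1]),
            ([0.5, 0.5], [1, 0]),  # empty mask rescued at first maximum
            ([1.0, 1.0, 1.0], [1, 1, 1]),
        ],
    )
    def test_thresholding(self, position, expected):
        assert np.array_equal(binarize(position).bits.astype(int), expected)

    def test_never_empty(self, rng):
        for _ in range(20):
            mask = binarize(rng.random(6) * 0.5)
            assert mask.n_selected >= 1


class TestSelectionFitness:
    def test_perfectly_separable_informative_mask_scores_zero(self, separable_small):
        mat, truth = separable_small
        bits = np.zeros(mat.n_features, dtype=bool)
        bits[truth.informative] = True
        score = selection_fitness(SelectionMask(bits=bits), mat, FitnessSpec(alpha=1.0))
        assert score == 0.0

    def test_noise_mask_near_chance(self, separable_small):
        mat, truth = separable_small
        bits = np.zeros(mat.n_features, dtype=bool)
        bits[truth.noise] = True
        scores = [
            selection_fitness(SelectionMask(bits=bits), mat,
                              FitnessSpec(alpha=1.0, seed=seed))
            for seed in range(20)
        ]
        # 4 balanced classes: chance error is 0.75
        assert abs(np.mean(scores) - 0.75) < 0.15

    def test_size_penalty_breaks_accuracy_ties(self, separable_small):
        mat, truth = separable_small
        full = SelectionMask(bits=np.ones(mat.n_features, dtype=bool))
        half_bits = np.zeros(mat.n_features, dtype=bool)
        half_bits[truth.informative] = True
        half = SelectionMask(bits=half_bits)
        spec = FitnessSpec(alpha=0.99)
        s_full = selection_fitness(full, mat, spec)
        s_half = selection_fitness(half, mat, spec)
        assert s_half < s_full

    def test_empty_mask_scores_worst(self, separable_small):
        mat, _ = separable_small
        empty = SelectionMask(bits=np.zeros(mat.n_features, dtype=bool))
        assert selection_fitness(empty, mat, FitnessSpec()) == 1.0


class TestRunAloMd:
    def test_matches_exhaustive_optimum_on_small_problem(self, separable_small):
        mat, _ = separable_small
        spec = FitnessSpec(alpha=0.99, folds=10, seed=11)
        best = exhaustive_best_score(mat, spec)
        hits = 0
        for seed in range(5):
            _, trace = run_alo_md(mat, spec, n_ants=20, n_antlions=20, S=50, seed=seed)
            hits += trace[-1] == pytest.approx(best, abs=1e-12)
        assert hits >= 4

    def test_single_iteration_returns_initial_best(self, separable_small):
        mat, _ = separable_small
        spec = FitnessSpec(seed=11)
        _, trace = run_alo_md(mat, spec, n_ants=5, n_antlions=5, S=1, seed=0)
        assert len(trace) == 2
        assert trace[1] <= trace[0]

    def test_trace_monotone_and_seed_deterministic(self, separable_small):
        mat, _ = separable_small
        spec = FitnessSpec(seed=11)
        mask_a, trace_a = run_alo_md(mat, spec, n_ants=8, n_antlions=8, S=10, seed=4)
        mask_b, trace_b = run_alo_md(mat, spec, n_ants=8, n_antlions=8, S=10, seed=4)
        assert np.array_equal(trace_a, trace_b)
        assert np.array_equal(mask_a.bits, mask_b.bits)
        assert np.all(np.diff(trace_a) <= 0)

    def test_md_toggle_changes_nothing_about_elitism(self, separable_small):
        mat, _ = separable_small
        spec = FitnessSpec(seed=11)
        for md in (True, False):
            _, trace = run_alo_md(mat, spec, n_ants=6, n_antlions=6, S=8,
                                  seed=2, md_enabled=md)
            assert np.all(np.diff(trace) <= 0)

    def test_invalid_populations_rejected(self, separable_small):
        mat, _ = separable_small
        with pytest.raises(ValueError):
            run_alo_md(mat, FitnessSpec(), n_ants=0, n_antlions=5, S=5, seed=0)
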