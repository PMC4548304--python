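import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msa_outliers import (
    MsaOutliersError,
    full_matrix,
    gap_mask,
    mbed_means,
    mean_scores,
    pair_affine,
    pair_cumulative,
    pair_linear,
)
from msa_outliers.gapdist import GapMask, default_seed_count

from oracles import reference_gap_distance

PAIR_FUNCS = {"linear": pair_linear, "affine": pair_affine,
              "cumulative": pair_cumulative}


def make_mask(rows):
    return GapMask(mask=np.array(rows, dtype=np.uint8),
                   ids=tuple(f"s{i}" for i in range(len(rows))))


mask_pair = st.integers(1, 60).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
    )
)


class TestPairMetrics:
    @pytest.mark.parametrize("metric,a,b,expected", [
        ("linear", [0, 0, 1], [0, 1, 0], 2),
        ("linear", [1, 1, 1, 1], [0, 0, 0, 0], 4),
        ("linear", [0, 1, 0, 1], [0, 1, 0, 1], 0),
        ("affine", [0, 0, 1, 1, 0], [0, 0, 0, 0, 0], 4),   # open 3 + extend 1
        ("affine", [1, 0, 1, 0], [0, 0, 0, 0], 6),         # two openings
        ("affine", [1, 1, 0], [1, 1, 0], 0),
        ("cumulative", [0, 1, 1, 1, 0], [0, 0, 0, 0, 0], 6),  # 1+2+3
        ("cumulative", [1, 0, 1], [0, 0, 0], 2),              # two runs of 1
        ("cumulative", [1, 0], [1, 0], 0),
    ])
    def test_worked_examples(self, metric, a, b, expected):
        assert PAIR_FUNCS[metric](a, b) == expected

    @pytest.mark.parametrize("metric", list(PAIR_FUNCS))
    def test_length_mismatch_is_an_error(self, metric):
        with pytest.raises(MsaOutliersError):
            PAIR_FUNCS[metric]([0, 1], [0, 1, 0])

    @pytest.mark.parametrize("metric", list(PAIR_FUNCS))
    @given(pair=mask_pair)
    def test_matches_reference_walk(self, metric, pair):
        a, b = pair
        assert PAIR_FUNCS[metric](a, b) == reference_gap_distance(a, b, metric)

    @given(pair=mask_pair)
    def test_metric_algebra(self, pair):
        a, b = pair
        lin = pair_linear(a, b)
        aff = pair_affine(a, b)
        cum = pair_cumulative(a, b)
        assert lin <= aff <= 3 * lin
        assert cum >= lin
        disagree = [x != y for x, y in zip(a, b)]
        if not any(d1 and d2 for d1, d2 in zip(disagree, disagree[1:])):
            assert cum == lin

    @pytest.mark.parametrize("metric", list(PAIR_FUNCS))
    @given(pair=mask_pair)
    def test_symmetry(self, metric, pair):
        a, b = pair
        assert PAIR_FUNCS[metric](a, b) == PAIR_FUNCS[metric](b, a)

    def test_cumulative_run_closed_form(self):
        """A disagreement run of length k contributes k(k+1)/2."""
        for k in range(1, 51):
            a = [0] + [1] * k + [0]
            b = [0] * (k + 2)
            assert pair_cumulative(a, b) == k * (k + 1) // 2


class TestFullMatrix:
    def test_identical_rows_give_zero_matrix(self):
        dm = full_matrix(make_mask([[0, 1, 0]] * 3), "affine")
        np.testing.assert_array_equal(dm.values, np.zeros((3, 3)))

    def test_two_row_linear_example(self):
        dm = full_matrix(make_mask([[0, 1], [1, 0]]), "linear")
        np.testing.assert_array_equal(dm.values, [[0, 2], [2, 0]])

    @pytest.mark.parametrize("metric", list(PAIR_FUNCS))
    def test_symmetric_zero_diagonal_and_eval_count(self, metric, rng):
        n, length = 17, 40
        mask = make_mask(rng.integers(0, 2, size=(n, length)))
        dm = full_matrix(mask, metric)
        np.testing.assert_array_equal(dm.values, dm.values.T)
        np.testing.assert_array_equal(np.diag(dm.values), np.zeros(n))
        assert dm.n_pair_evals == n * (n - 1) // 2

    def test_matches_pair_functions_entrywise(self, rng):
        mask = make_mask(rng.integers(0, 2, size=(6, 25)))
        dm = full_matrix(mask, "cumulative")
        for i in range(6):
            for j in range(6):
                assert dm.values[i, j] == pair_cumulative(mask.mask[i], mask.mask[j])

    def test_unknown_metric_is_an_error(self):
        with pytest.raises(MsaOutliersError, match="unknown metric"):
            full_matrix(make_mask([[0, 1], [1, 0]]), "euclidean")


class TestMeanScores:
    def test_two_sequences(self):
        dm = full_matrix(make_mask([[0, 1, 1], [1, 0, 0]]), "linear")
        np.testing.assert_allclose(mean_scores(dm).scores, [3.0, 3.0])

    def test_row_means_exclude_diagonal(self):
        # distances 1, 2, 3 between the three pairs
        dm = full_matrix(make_mask([[0, 0, 1, 1, 0, 0],
                                    [0, 0, 1, 0, 0, 0],
                                    [1, 1, 1, 0, 0, 0]]), "linear")
        np.testing.assert_allclose(sorted(mean_scores(dm).scores), [1.5, 2.0, 2.5])

    def test_zero_matrix_gives_zero_scores(self):
        dm = full_matrix(make_mask([[1, 0]] * 4), "linear")
        np.testing.assert_array_equal(mean_scores(dm).scores, np.zeros(4))


class TestMbed:
    def test_all_seeds_reduces_to_full_mode_means(self, rng):
        mask = make_mask(rng.integers(0, 2, size=(30, 50)))
        expected = mean_scores(full_matrix(mask, "linear")).scores
        got = mbed_means(mask, "linear", n_seeds=30, rng_seed=9).scores
        np.testing.assert_allclose(got, expected)

    def test_deterministic_under_fixed_seed(self, rng):
        mask = make_mask(rng.integers(0, 2, size=(40, 30)))
        a = mbed_means(mask, "affine", n_seeds=6, rng_seed=123).scores
        b = mbed_means(mask, "affine", n_seeds=6, rng_seed=123).scores
        np.testing.assert_array_equal(a, b)

    def test_seed_count_bounds_are_errors(self, rng):
        mask = make_mask(rng.integers(0, 2, size=(5, 10)))
        for bad in (0, 1, 6):
            with pytest.raises(MsaOutliersError):
                mbed_means(mask, "linear", n_seeds=bad)

    def test_seed_self_distance_excluded(self):
        # Two seeds among three rows: each seed's mean must be its distance
        # to the other seed and the non-seed, not deflated by its own zero.
        mask = make_mask([[0, 0], [1, 1], [0, 1]])
        full = full_matrix(mask, "linear").values
        scores = mbed_means(mask, "linear", n_seeds=3, rng_seed=0).scores
        np.testing.assert_allclose(scores, full.sum(axis=1) / 2)

    def test_default_seed_count(self):
        assert default_seed_count(4) == 4          # capped at N
        assert default_seed_count(20) == 5         # floor of 5
        assert default_seed_count(500) == 9        # ceil(log2 500)
        assert default_seed_count(100000) == 17


def test_gap_mask_examples(tiny_alignment):
    mask = gap_mask(tiny_alignment)
    np.testing.assert_array_equal(mask.mask[0], [0, 0, 0, 1, 1, 0, 0, 0, 0])
    np.testing.assert_array_equal(mask.mask[4], [1, 1, 0, 0, 0, 0, 0, 1, 1])
    assert mask.ids == tiny_alignment.ids
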