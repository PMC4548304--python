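import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msa_outliers import (
    MsaOutliersError,
    ScoreVector,
    ZeroSpreadError,
    bootstrap_stats,
    classify,
    iqr_stats,
    normalise,
)
from msa_outliers.outlier import NormalisationStats


def vector(values, kind="distance"):
    return ScoreVector(scores=np.asarray(values, dtype=float),
                       ids=tuple(f"s{i}" for i in range(len(values))), kind=kind)


class TestBootstrapStats:
    def test_constant_vector_gives_zero_sd(self):
        stats = bootstrap_stats(vector([5, 5, 5, 5]), replicates=50, rng_seed=1)
        assert stats.est_mean == 5.0
        assert stats.est_sd == 0.0

    def test_identity_resampler_reproduces_plain_mean_and_sd(self):
        x = np.array([1.0, 4.0, 4.0, 9.0, 12.0])
        stats = bootstrap_stats(
            vector(x), replicates=1, rng_seed=0,
            index_sampler=lambda rng, b, n: np.tile(np.arange(n), (b, 1)))
        assert stats.est_mean == pytest.approx(x.mean())
        assert stats.est_sd == pytest.approx(x.std(ddof=1))

    def test_deterministic_under_fixed_seed(self):
        v = vector([1, 3, 3, 7, 9, 11])
        a = bootstrap_stats(v, replicates=200, rng_seed=77)
        b = bootstrap_stats(v, replicates=200, rng_seed=77)
        assert (a.est_mean, a.est_sd) == (b.est_mean, b.est_sd)

    def test_rejects_degenerate_input(self):
        with pytest.raises(MsaOutliersError):
            bootstrap_stats(vector([1.0]))
        with pytest.raises(MsaOutliersError):
            bootstrap_stats(vector([1.0, 2.0]), replicates=0)


class TestIqrStats:
    def test_worked_quartiles(self):
        stats = iqr_stats(vector([1, 2, 3, 4, 5]))
        assert (stats.q1, stats.q3, stats.iqr) == (2.0, 4.0, 2.0)

    def test_unsorted_input_gives_same_quartiles(self):
        assert iqr_stats(vector([5, 1, 4, 2, 3])).iqr == 2.0

    def test_zero_range_advises_bootstrap(self):
        with pytest.raises(ZeroSpreadError, match="bootstrap"):
            iqr_stats(vector([3, 3, 3, 3, 3]))

    def test_q3_never_below_q1(self, rng):
        for _ in range(20):
            x = rng.gamma(2.0, 1.0, size=30)
            stats = iqr_stats(vector(x))
            assert stats.q3 >= stats.q1

    def test_too_few_scores_is_an_error(self):
        with pytest.raises(MsaOutliersError):
            iqr_stats(vector([1, 2, 3]))


class TestNormalise:
    def test_bootstrap_z_scores(self):
        stats = NormalisationStats(method="bootstrap", est_mean=10.0, est_sd=2.0,
                                   replicates=1, rng_seed=0)
        z = normalise(vector([10, 14, 6]), stats)
        np.testing.assert_allclose(z, [0.0, 2.0, -2.0])

    def test_iqr_scores_signed_by_tail(self):
        stats = NormalisationStats(method="iqr", q1=2.0, q3=4.0, iqr=2.0)
        z = normalise(vector([3, 8, 1]), stats)
        # inside the quartiles -> 0; above Q3 -> 2; below Q1 -> 0.5 on the
        # lower tail, carried as a negative sign
        np.testing.assert_allclose(z, [0.0, 2.0, -0.5])

    def test_inside_quartiles_is_exactly_zero(self, rng):
        stats = NormalisationStats(method="iqr", q1=1.0, q3=3.0, iqr=2.0)
        x = rng.uniform(1.001, 2.999, size=50)
        np.testing.assert_array_equal(normalise(vector(x), stats), np.zeros(50))

    def test_zero_sd_is_an_error(self):
        stats = NormalisationStats(method="bootstrap", est_mean=1.0, est_sd=0.0,
                                   replicates=1, rng_seed=0)
        with pytest.raises(ZeroSpreadError, match="inspect"):
            normalise(vector([1, 1, 1]), stats)

    def test_iqr_scores_scale_invariant(self, rng):
        x = rng.gamma(4.0, 2.0, size=40)
        z1 = normalise(vector(x), iqr_stats(vector(x)))
        z2 = normalise(vector(7.5 * x), iqr_stats(vector(7.5 * x)))
        np.testing.assert_allclose(z1, z2)

    def test_bootstrap_z_scale_invariant_with_shared_draws(self, rng):
        x = rng.gamma(4.0, 2.0, size=40)
        z1 = normalise(vector(x), bootstrap_stats(vector(x), 500, rng_seed=3))
        z2 = normalise(vector(3 * x), bootstrap_stats(vector(3 * x), 500, rng_seed=3))
        np.testing.assert_allclose(z1, z2)


class TestClassify:
    def test_upper_tail_flags(self):
        report = classify(np.array([0.1, 2.5, 1.9]), threshold=2.0, tail="upper")
        np.testing.assert_array_equal(report.flags, [False, True, False])

    def test_huge_threshold_flags_nothing(self, rng):
        z = rng.normal(scale=100, size=200)
        assert classify(z, threshold=1e6, tail="both").n_flagged == 0

    def test_similarity_kind_flags_lowest_total(self):
        z = np.array([0.5, 0.4, -2.6])  # lowest similarity is most suspicious
        report = classify(z, threshold=2.0, tail="upper", kind="similarity")
        np.testing.assert_array_equal(report.flags, [False, False, True])

    def test_lower_and_both_tails(self):
        z = np.array([-3.0, 0.0, 3.0])
        np.testing.assert_array_equal(
            classify(z, 2.0, tail="lower").flags, [True, False, False])
        np.testing.assert_array_equal(
            classify(z, 2.0, tail="both").flags, [True, False, True])

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    def test_flagged_sets_nested_in_threshold(self, t1, t2):
        z = np.linspace(-4, 6, 23)
        lo, hi = sorted((t1, t2))
        flags_hi = classify(z, hi, tail="both").flags
        flags_lo = classify(z, lo, tail="both").flags
        assert not np.any(flags_hi & ~flags_lo)

    def test_negative_threshold_rejected(self):
        with pytest.raises(MsaOutliersError):
            classify(np.zeros(3), threshold=-1.0)


def test_flag_rate_stays_low_on_outlier_free_unimodal_scores(rng):
    """At T=2 an outlier-free, unimodal score vector flags < 10 percent."""
    rates = []
    for seed in range(10):
        x = np.random.default_rng(seed).gamma(20.0, 1.0, size=400)
        v = vector(x)
        z = normalise(v, bootstrap_stats(v, 500, rng_seed=seed))
        rates.append(classify(z, 2.0).n_flagged / 400)
    assert np.mean(rates) < 0.10
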