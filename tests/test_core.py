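import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tlsea.core import (
    BackgroundFit,
    BackgroundSamples,
    InitialScoreVector,
    OPool,
    TwoLayerSEA,
    ZPool,
    build_z_pool,
    fit_background,
    initial_score,
    load_model,
    original_score,
    p_o,
    p_z,
    sample_background_initial_scores,
    sample_background_original_scores,
    save_model,
    z_threshold,
    z_transform,
)
from tlsea.io import RunConfig
from tlsea.similarity import SimilarityMatrix

from _oracles import (
    initial_scores_bf,
    original_score_bf,
    tail_p_bf,
    z_scores_bf,
)


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix(
        [f"r{i}" for i in range(values.shape[0])],
        [f"c{i}" for i in range(values.shape[1])],
        values,
    )


def _normal_samples(k, a, b, n_lengths, reps, rng, lo=1, hi=10_000):
    """Background samples drawn straight from the generative moment model."""
    ms = rng.choice(np.arange(lo, hi + 1), size=n_lengths, replace=False)
    lengths = np.repeat(ms, reps)
    values = rng.normal(k * lengths, a * lengths.astype(float) ** b)
    return BackgroundSamples(lengths, values, 0.15)


class TestInitialScore:
    def test_strictly_above_threshold_summed(self):
        ivec = initial_score(_matrix([[0.2], [0.1], [0.3]]), 0.15)
        assert ivec.scores[0] == pytest.approx(0.5)
        assert ivec.m == 3

    def test_all_below_threshold_gives_zero(self):
        ivec = initial_score(_matrix([[0.15], [0.01]]), 0.15)
        assert ivec.scores[0] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        values = rng.random((50, 20))
        ivec = initial_score(_matrix(values), 0.15)
        np.testing.assert_allclose(
            ivec.scores, initial_scores_bf(values.tolist(), 0.15), rtol=1e-12
        )

    def test_invariant_scores_bounded_by_m(self):
        with pytest.raises(ValueError, match=r"\[0, m\]"):
            InitialScoreVector("p", 2, np.array([2.5]))


class TestBackgroundSampling:
    config = RunConfig(n_lengths=10, reps_per_length=20, length_range=(1, 40), seed=0)

    def test_sample_count_contract(self, random_matrix):
        samples = sample_background_initial_scores(random_matrix, self.config, 1)
        assert samples.size == 200

    def test_all_zero_matrix_gives_zero_samples(self):
        M = _matrix(np.zeros((30, 5)))
        samples = sample_background_initial_scores(M, self.config, 1)
        assert np.all(samples.scores == 0)

    def test_fixed_seed_reproducible(self, random_matrix):
        s1 = sample_background_initial_scores(random_matrix, self.config, 42)
        s2 = sample_background_initial_scores(random_matrix, self.config, 42)
        np.testing.assert_array_equal(s1.scores, s2.scores)
        np.testing.assert_array_equal(s1.lengths, s2.lengths)

    def test_lengths_distinct_when_range_allows(self, random_matrix):
        cfg = RunConfig(n_lengths=30, reps_per_length=5, length_range=(1, 100), seed=0)
        samples = sample_background_initial_scores(random_matrix, cfg, 3)
        assert len(np.unique(samples.lengths)) == 30

    def test_lengths_beyond_row_count_sampled_with_replacement(self, random_matrix):
        cfg = RunConfig(n_lengths=5, reps_per_length=10, length_range=(100, 500), seed=0)
        samples = sample_background_initial_scores(random_matrix, cfg, 3)
        # scores can exceed the 60-row no-replacement maximum only via reuse
        assert samples.size == 50
        assert np.all(samples.scores >= 0)


class TestFitBackground:
    def test_parameter_recovery_from_generating_model(self, rng):
        k, a, b = 0.0088, 0.0088, 0.9950
        samples = _normal_samples(k, a, b, 200, 500, rng)
        fit = fit_background(samples)
        assert fit.k_hat == pytest.approx(k, rel=0.10)
        assert fit.a_hat == pytest.approx(a, rel=0.10)
        assert fit.b_hat == pytest.approx(b, rel=0.10)

    def test_exact_linear_means_recovered(self, rng):
        # samples equal to 2m plus tiny jitter -> k ~= 2 by closed-form LS
        lengths = np.repeat([10, 50], 100)
        values = 2.0 * lengths + rng.normal(0, 1e-9, lengths.size)
        fit = fit_background(BackgroundSamples(lengths, values, 0.15))
        assert fit.k_hat == pytest.approx(2.0, rel=1e-6)

    def test_single_length_is_error(self, rng):
        samples = BackgroundSamples(np.full(50, 7), rng.random(50), 0.15)
        with pytest.raises(ValueError, match="2 distinct lengths"):
            fit_background(samples)

    def test_degenerate_background_is_error(self):
        lengths = np.repeat([5, 10], 20)
        samples = BackgroundSamples(lengths, np.zeros(40), 0.15)
        with pytest.raises(ValueError, match="degenerate background"):
            fit_background(samples)


class TestZTransform:
    fit = BackgroundFit(0.5, 0.2, 0.9, np.array([5, 10]), np.array([2.5, 5.0]),
                        np.array([0.8, 1.5]))

    def test_centering(self):
        ivec = InitialScoreVector("p", 10, np.array([self.fit.k_hat * 10]))
        assert z_transform(ivec, self.fit)[0] == pytest.approx(0.0)

    def test_scaling(self):
        m = 10
        target = self.fit.k_hat * m + self.fit.a_hat * m**self.fit.b_hat
        ivec = InitialScoreVector("p", m, np.array([target]))
        assert z_transform(ivec, self.fit)[0] == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        scores = rng.uniform(0, 12, 20)
        ivec = InitialScoreVector("p", 12, scores)
        np.testing.assert_allclose(
            z_transform(ivec, self.fit),
            z_scores_bf(scores.tolist(), 12, self.fit.k_hat, self.fit.a_hat, self.fit.b_hat),
            rtol=1e-12,
        )

    def test_zero_scale_is_error(self):
        degenerate = BackgroundFit(0.5, 0.0, 1.0, np.array([2, 5]),
                                   np.array([1.0, 2.5]), np.array([0.0, 0.0]))
        ivec = InitialScoreVector("p", 5, np.array([1.0]))
        with pytest.raises(ZeroDivisionError):
            z_transform(ivec, degenerate)


class TestZPool:
    def test_pool_standardized_under_generating_model(self, rng):
        samples = _normal_samples(0.0088, 0.0088, 0.995, 100, 300, rng)
        pool = build_z_pool(samples, fit_background(samples))
        assert pool.z_values.mean() == pytest.approx(0.0, abs=0.02)
        assert pool.z_values.std() == pytest.approx(1.0, abs=0.02)

    def test_pool_size_preserved(self, random_matrix):
        cfg = RunConfig(n_lengths=10, reps_per_length=20, length_range=(2, 40), seed=0)
        samples = sample_background_initial_scores(random_matrix, cfg, 1)
        pool = build_z_pool(samples, fit_background(samples))
        assert pool.size == 200


class TestEmpiricalTailProbabilities:
    pool = ZPool(np.array([0.0, 1.0, 2.0, 3.0]))

    def test_direct_count_with_ties_inclusive(self):
        assert p_z(2.0, self.pool) == 0.5

    def test_below_minimum_is_one(self):
        assert p_z(-5.0, self.pool) == 1.0

    def test_beyond_maximum_reported_below_resolution(self):
        assert p_z(10.0, self.pool) == pytest.approx(0.5 / 4)
        assert p_z(10.0, self.pool) < self.pool.resolution

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=50),
           st.floats(-6, 6), st.floats(-6, 6))
    @settings(deadline=None, max_examples=200)
    def test_matches_counting_oracle_and_monotone(self, pool_vals, z1, z2):
        pool = ZPool(np.array(pool_vals))
        assert p_z(z1, pool) == pytest.approx(tail_p_bf(pool_vals, z1), rel=1e-15)
        lo, hi = sorted([z1, z2])
        assert p_z(lo, pool) >= p_z(hi, pool)

    def test_randomized_tail_p_uniform_for_pool_draws(self, rng):
        pool_vals = rng.choice([0.0, 1.0, 2.0], size=5000, p=[0.7, 0.2, 0.1])
        pool = OPool(pool_vals, c=0.0)
        draws = rng.choice([0.0, 1.0, 2.0], size=2000, p=[0.7, 0.2, 0.1])
        p_star = pool.tail_p_randomized(draws, rng)
        assert stats.kstest(p_star, "uniform").pvalue > 0.01


class TestZThreshold:
    def test_counting_example(self):
        pool = ZPool(np.arange(1.0, 101.0))
        assert z_threshold(pool, 0.01) == 100.0

    def test_alpha_one_gives_minimum(self):
        pool = ZPool(np.array([3.0, 1.0, 2.0]))
        assert z_threshold(pool, 1.0) == 1.0

    def test_pool_too_small_is_error(self):
        with pytest.raises(ValueError, match="cannot resolve"):
            z_threshold(ZPool(np.arange(10.0)), 0.01)

    def test_normal_pool_matches_quantile_oracle(self, rng):
        pool = ZPool(rng.standard_normal(1_000_000))
        c = z_threshold(pool, 0.01)
        assert c == pytest.approx(stats.norm.ppf(0.99), abs=0.02)

    def test_threshold_tail_probability_attained(self, rng):
        pool = ZPool(rng.standard_normal(10_000))
        c = z_threshold(pool, 0.05)
        assert p_z(c, pool) <= 0.05
        below = pool.z_values[pool.z_values < c]
        if below.size:
            assert p_z(below.max(), pool) > 0.05


class TestOriginalScore:
    def test_inclusive_sum(self):
        assert original_score(np.array([3.0, 1.0, 5.0]), 2.0) == 8.0

    def test_all_below_threshold_is_zero(self):
        assert original_score(np.array([0.5, -1.0]), 2.0) == 0.0

    def test_matches_loop_oracle(self, rng):
        z = rng.normal(size=100)
        assert original_score(z, 1.3) == pytest.approx(
            original_score_bf(z.tolist(), 1.3), rel=1e-12
        )

    def test_nonfinite_threshold_is_error(self):
        with pytest.raises(ValueError):
            original_score(np.array([1.0]), np.nan)


class TestOriginalScorePool:
    config = RunConfig(n_lengths=10, reps_per_length=20, length_range=(2, 40), seed=0)

    def _fit(self, M_r):
        samples = sample_background_initial_scores(M_r, self.config, 11)
        return fit_background(samples)

    def test_pool_size_contract(self, random_matrix):
        fit = self._fit(random_matrix)
        pool = sample_background_original_scores(
            random_matrix, fit, 2.0, 20, self.config, 5
        )
        assert pool.size == 200

    def test_fixed_seed_reproducible(self, random_matrix):
        fit = self._fit(random_matrix)
        p1 = sample_background_original_scores(random_matrix, fit, 2.0, 20, self.config, 5)
        p2 = sample_background_original_scores(random_matrix, fit, 2.0, 20, self.config, 5)
        np.testing.assert_array_equal(p1.o_values, p2.o_values)

    def test_column_count_mismatch_is_error(self, random_matrix):
        fit = self._fit(random_matrix)
        with pytest.raises(ValueError, match="n_pheno"):
            sample_background_original_scores(random_matrix, fit, 2.0, 7, self.config, 5)

    def test_all_zero_background_errors_upstream(self):
        M = _matrix(np.zeros((30, 5)))
        with pytest.raises(ValueError, match="degenerate background"):
            self._fit(M)


class TestPO:
    pool = OPool(np.array([0.0, 5.0, 10.0, 20.0]), c=2.0)

    def test_zero_score_with_nonnegative_pool_is_one(self):
        assert p_o(0.0, self.pool) == 1.0

    def test_direct_count(self):
        assert p_o(10.0, self.pool) == 0.5

    def test_beyond_maximum_below_resolution(self):
        assert p_o(100.0, self.pool) == pytest.approx(0.5 / 4)


class TestTwoLayerSEA:
    def test_planted_protein_ranks_first(self, planted_universe):
        model = TwoLayerSEA(
            n_lengths=60, reps_per_length=150, length_range=(5, 60), random_state=2
        )
        result = model.fit(planted_universe["M_r"]).score_proteins(
            planted_universe["M"], planted_universe["ligand_sets"]
        )
        table = {p.protein_id: p for p in result.proteins}
        assert table["PLANT"].rank == 1
        assert all(
            table["PLANT"].p_o < p.p_o for p in result.proteins if p.protein_id != "PLANT"
        )

    def test_empty_ligand_sets_give_empty_result(self, planted_universe):
        model = TwoLayerSEA(
            n_lengths=20, reps_per_length=30, length_range=(5, 40), random_state=2
        )
        result = model.fit(planted_universe["M_r"]).score_proteins(planted_universe["M"], [])
        assert result.proteins == []

    def test_protein_with_missing_ligand_dropped_not_fatal(self, planted_universe):
        from tlsea.filtering import LigandSet

        model = TwoLayerSEA(
            n_lengths=20, reps_per_length=30, length_range=(5, 40), random_state=2
        )
        model.fit(planted_universe["M_r"])
        sets = planted_universe["ligand_sets"][:2] + [LigandSet("BROKEN", ("GHOST",) * 1)]
        result = model.score_proteins(planted_universe["M"], sets)
        assert len(result.proteins) == 2
        assert result.dropped[0][0] == "BROKEN"

    def test_scoring_before_fit_is_error(self, planted_universe):
        with pytest.raises(RuntimeError, match="not fitted"):
            TwoLayerSEA().score_proteins(
                planted_universe["M"], planted_universe["ligand_sets"]
            )

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        model = TwoLayerSEA(n_lengths=12, alpha_z=0.05, random_state=9)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()

    def test_save_load_round_trip(self, tmp_path, planted_universe):
        model = TwoLayerSEA(
            n_lengths=30, reps_per_length=50, length_range=(5, 40), random_state=4
        )
        model.fit(planted_universe["M_r"])
        save_model(model, tmp_path / "bg.npz")
        loaded = load_model(tmp_path / "bg.npz")
        r1 = model.score_proteins(planted_universe["M"], planted_universe["ligand_sets"])
        r2 = loaded.score_proteins(planted_universe["M"], planted_universe["ligand_sets"])
        for p1, p2 in zip(r1.proteins, r2.proteins):
            assert p1.protein_id == p2.protein_id
            assert p1.p_o == p2.p_o
            np.testing.assert_array_equal(p1.p_z, p2.p_z)

    def test_fresh_pool_flag_changes_pool_not_contract(self, planted_universe):
        fitted = TwoLayerSEA(
            n_lengths=20, reps_per_length=30, length_range=(5, 40),
            reuse_fit_pool=False, random_state=4,
        ).fit(planted_universe["M_r"])
        assert fitted.z_pool_.size == 600
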