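import numpy as np
import pytest
from scipy import stats

from conftest import make_table
from normbench.sampling import (STRATEGIES, SamplingSpec, SizeGrid,
                                beta_bin_weights, derive_seed, draw_sample,
                                enumerate_conditions, quantile_bins,
                                representative_sample, sex_imbalanced_sample,
                                skewed_sample)


class TestQuantileBins:
    def test_exact_division(self):
        bins = quantile_bins(np.random.default_rng(0).normal(size=100), 10)
        assert np.bincount(bins).tolist() == [10] * 10

    def test_remainder_rule(self):
        bins = quantile_bins(np.random.default_rng(1).normal(size=101), 10)
        counts = sorted(np.bincount(bins))
        assert counts == [10] * 9 + [11]

    def test_bins_ordered_by_age(self):
        ages = np.random.default_rng(2).uniform(40, 90, size=73)
        bins = quantile_bins(ages, 10)
        order = np.argsort(ages, kind="stable")
        assert np.all(np.diff(bins[order]) >= 0)

    def test_degenerate_identical_ages_deterministic(self):
        a = quantile_bins(np.full(25, 60.0), 10)
        b = quantile_bins(np.full(25, 60.0), 10)
        assert np.array_equal(a, b)
        assert np.abs(np.diff(np.bincount(a, minlength=10))).max() <= 1

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            quantile_bins(np.arange(5.0), 10)


class TestRepresentative:
    def test_one_per_bin_when_n_equals_bins(self):
        pool = make_table(200, seed=3)
        spec = SamplingSpec("representative", 10, seed=5)
        sample = representative_sample(pool, spec)
        bins = quantile_bins(pool["age"].to_numpy(), 10)
        picked = pool.index.isin(sample.index)
        assert np.bincount(bins[picked], minlength=10).tolist() == [1] * 10

    @pytest.mark.parametrize("n", [10, 50, 101])
    def test_global_sex_balance(self, n):
        pool = make_table(400, seed=4)
        sample = representative_sample(pool, SamplingSpec("representative", n,
                                                          seed=n))
        counts = sample["sex"].value_counts()
        assert abs(counts.get("F", 0) - counts.get("M", 0)) <= 1

    def test_age_distribution_matches_pool(self):
        """n=600 draws from a ~690 pool reproduce the pool age histogram."""
        pool = make_table(692, seed=5)
        edges = np.quantile(pool["age"], np.linspace(0, 1, 11))
        edges[0] -= 1e-9
        expected = np.histogram(pool["age"], bins=edges)[0] / len(pool) * 600
        for seed in range(10):
            sample = representative_sample(
                pool, SamplingSpec("representative", 600, seed=seed))
            observed = np.histogram(sample["age"], bins=edges)[0]
            p = stats.chisquare(observed, expected * observed.sum()
                                / expected.sum()).pvalue
            assert p > 0.01

    def test_pool_exhaustion_rejected(self):
        pool = make_table(20, seed=6)
        with pytest.raises(ValueError):
            representative_sample(pool, SamplingSpec("representative", 21,
                                                     seed=0))


class TestSkewed:
    def test_beta_weight_ratio_closed_form(self):
        """Beta(2,5) pdf is 30 x (1-x)^4: w(0.05)/w(0.95) = 19^3 = 6859."""
        w = beta_bin_weights(10, 2.0, 5.0)
        assert w[0] / w[9] == pytest.approx(6859.0, rel=1e-9)

    def test_beta_mirror_symmetry(self):
        w_left = beta_bin_weights(10, 2.0, 5.0)
        w_right = beta_bin_weights(10, 5.0, 2.0)
        np.testing.assert_allclose(w_left, w_right[::-1], rtol=1e-12)

    def test_skew_direction_of_mean_age(self):
        pool = make_table(600, seed=7)
        pool_mean = pool["age"].mean()
        means = {"left_skewed": [], "right_skewed": []}
        for strategy in means:
            for seed in range(30):
                s = skewed_sample(pool, SamplingSpec(strategy, 150, seed=seed))
                means[strategy].append(s["age"].mean())
        assert np.mean(means["left_skewed"]) < pool_mean
        assert np.mean(means["right_skewed"]) > pool_mean

    def test_sex_balance_maintained(self):
        pool = make_table(500, seed=8)
        s = skewed_sample(pool, SamplingSpec("left_skewed", 100, seed=1))
        counts = s["sex"].value_counts()
        assert abs(counts.get("F", 0) - counts.get("M", 0)) <= 1

    def test_representative_tracks_pool_closer_than_skews(self):
        """Two-sample KS vs the pool is smallest for representative draws."""
        pool = make_table(600, seed=9)
        ks = {}
        for strategy in ("representative", "left_skewed", "right_skewed"):
            fn = representative_sample if strategy == "representative" \
                else skewed_sample
            vals = [stats.ks_2samp(
                fn(pool, SamplingSpec(strategy, 150, seed=s))["age"],
                pool["age"]).statistic for s in range(30)]
            ks[strategy] = np.mean(vals)
        assert ks["representative"] < ks["left_skewed"]
        assert ks["representative"] < ks["right_skewed"]


class TestSexImbalanced:
    @pytest.mark.parametrize("n,ratio,expected_f", [
        (10, (4, 1), 8),
        (11, (1, 10), 1),
        (100, (1, 4), 20),
    ])
    def test_rounded_sex_counts(self, n, ratio, expected_f):
        pool = make_table(600, seed=10)
        s = sex_imbalanced_sample(pool, SamplingSpec("sex_imbalanced", n,
                                                     sex_ratio=ratio, seed=2))
        assert (s["sex"] == "F").sum() == expected_f
        assert len(s) == n

    def test_insufficient_sex_named_in_error(self):
        pool = make_table(60, seed=11)
        pool["sex"] = "M"
        with pytest.raises(ValueError, match="F"):
            sex_imbalanced_sample(pool, SamplingSpec(
                "sex_imbalanced", 20, sex_ratio=(10, 1), seed=0))


class TestConditions:
    def test_default_grid_has_48_sizes(self):
        grid = SizeGrid()
        assert len(grid.sizes) == 48

    def test_single_size_single_strategy_gives_ten_specs(self):
        grid = SizeGrid(sizes=(50,), include_full=False)
        specs = enumerate_conditions(grid, ("representative",), root_seed=1)
        assert len(specs) == 10
        assert {s.iteration for s in specs} == set(range(1, 11))

    def test_full_condition_single_iteration(self):
        grid = SizeGrid(sizes=(10,), iterations_per_size=3)
        specs = enumerate_conditions(grid, ("representative",), root_seed=1,
                                     pool_size=123)
        assert sum(1 for s in specs if s.n == 123) == 1

    def test_seeds_pairwise_distinct(self):
        grid = SizeGrid(sizes=(10, 20, 30), iterations_per_size=10,
                        include_full=False)
        specs = enumerate_conditions(grid, STRATEGIES, root_seed=3)
        seeds = [s.seed for s in specs]
        assert len(seeds) == len(set(seeds))

    def test_seed_derivation_stable(self):
        assert derive_seed(1, "representative", 50, 2) == \
            derive_seed(1, "representative", 50, 2)
        assert derive_seed(1, "representative", 50, 2) != \
            derive_seed(2, "representative", 50, 2)


class TestInvariants:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_no_duplicates_and_subset_of_pool(self, strategy):
        pool = make_table(300, seed=12)
        s = draw_sample(pool, SamplingSpec(strategy, 80, seed=13))
        assert len(s) == 80
        assert s["subject_id"].is_unique
        assert set(s["subject_id"]) <= set(pool["subject_id"])

    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_determinism_under_seed(self, strategy):
        pool = make_table(300, seed=14)
        spec = SamplingSpec(strategy, 60, seed=15)
        a = draw_sample(pool, spec)
        b = draw_sample(pool, spec)
        assert a.equals(b)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SamplingSpec("bogus", 10)
        with pytest.raises(ValueError):
            SamplingSpec("representative", 0)
        with pytest.raises(ValueError):
            SamplingSpec("sex_imbalanced", 10, sex_ratio=(0, 1))
        with pytest.raises(ValueError):
            SizeGrid(sizes=(10, 10))


class TestPersistence:
    def test_sample_ids_round_trip(self, tmp_path):
        pool = make_table(120, seed=20)
        spec = SamplingSpec("representative", 30, iteration=2, seed=77)
        from normbench.sampling import save_sample_ids

        sample = representative_sample(pool, spec)
        path = save_sample_ids(sample, spec, tmp_path)
        assert "representative_n30_i2_s77" in path.name
        ids = path.read_text().split()
        assert ids == sample["subject_id"].tolist()

    def test_conditions_manifest(self, tmp_path):
        from normbench.sampling import write_conditions_manifest

        grid = SizeGrid(sizes=(10, 20), iterations_per_size=2,
                        include_full=False)
        specs = enumerate_conditions(grid, ("representative", "left_skewed"),
                                     root_seed=1)
        manifest = write_conditions_manifest(specs, tmp_path / "manifest.csv")
        assert len(manifest) == 2 * 2 * 2
        assert (tmp_path / "manifest.csv").exists()
        assert manifest["seed"].is_unique
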