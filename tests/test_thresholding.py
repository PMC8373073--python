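"""Threshold rules, CV-based hyperparameter selection, and their oracles."""

import numpy as np
import pytest

from denoiseq import (
    NoiseFloorDesign,
    ValidationError,
    coefficient_of_variation,
    generate_count_matrix,
    optimize_similarity_threshold,
    threshold_from_binned_stats,
    threshold_from_profile_line,
)
from denoiseq.binning import BinnedStats, bin_similarity_values
from denoiseq.count_approach import SimilarityProfile, profile_all_samples
from denoiseq.thresholding import profile_to_binned_stats


def make_binned(lowers, uppers, q1, median=None, counts=None):
    n = len(lowers)
    q1 = np.asarray(q1, dtype=float)
    median = np.asarray(median if median is not None else np.maximum(q1, q1), float)
    median = np.maximum(median, q1)
    return BinnedStats(
        lower=np.asarray(lowers, float),
        upper=np.asarray(uppers, float),
        count=np.asarray(counts if counts is not None else [1] * n),
        q1=q1,
        median=median,
        q3=np.maximum(median, q1) + 0.01,
    )


def brute_force_binned_threshold(binned, c, statistic):
    """Exhaustive scan: lowest bin whose statistic stays > c through the top."""
    stat = binned.q1 if statistic == "Q1" else binned.median
    populated = [i for i in range(binned.n_bins) if binned.count[i] > 0]
    for pos, i in enumerate(populated):
        if all(stat[j] > c for j in populated[pos:]):
            return float(binned.lower[i])
    return float("nan")


class TestLineMethod:
    def step_profile(self):
        abundance = np.array([10.0, 20, 30, 40, 50, 60, 70, 80])
        similarity = np.where(abundance < 50, 0.1, 0.9)
        return SimilarityProfile("s", abundance, similarity)

    def test_step_profile_crossing(self):
        theta = threshold_from_profile_line(self.step_profile(), 0.25, 1)
        assert theta == 50.0

    def test_everywhere_above_gives_lowest_abundance(self):
        profile = SimilarityProfile("s", [5.0, 10, 15], [0.5, 0.6, 0.7])
        assert threshold_from_profile_line(profile, 0.25, 1) == 5.0

    def test_everywhere_below_is_undetermined(self):
        profile = SimilarityProfile("s", [5.0, 10, 15], [0.1, 0.2, 0.1])
        assert np.isnan(threshold_from_profile_line(profile, 0.25, 1))

    def test_smoothing_bridges_single_dip(self):
        abundance = np.arange(1.0, 11)
        similarity = np.array([0.0, 0.0, 0.9, 0.9, 0.2, 0.9, 0.9, 0.9, 0.9, 0.9])
        rough = threshold_from_profile_line(
            SimilarityProfile("s", abundance, similarity), 0.25, 1
        )
        smooth = threshold_from_profile_line(
            SimilarityProfile("s", abundance, similarity), 0.25, 5
        )
        assert rough == 6.0  # dip at 5 postpones the crossing
        assert smooth < rough

    def test_c_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            threshold_from_profile_line(self.step_profile(), 1.5, 1)

    def test_even_smoothing_width_rejected(self):
        with pytest.raises(ValidationError):
            threshold_from_profile_line(self.step_profile(), 0.25, 4)


class TestBinnedMethod:
    def test_first_consistent_crossing(self):
        binned = make_binned([1, 2, 4, 8], [2, 4, 8, 16], q1=[0.0, 0.2, 0.3, 0.4])
        assert threshold_from_binned_stats(binned, 0.25, "Q1") == 4.0

    def test_dip_postpones_crossing(self):
        binned = make_binned([1, 2, 4, 8], [2, 4, 8, 16], q1=[0.3, 0.1, 0.4, 0.5])
        assert threshold_from_binned_stats(binned, 0.25, "Q1") == 4.0

    def test_empty_bins_skipped_in_consistency(self):
        binned = make_binned(
            [1, 2, 4, 8], [2, 4, 8, 16],
            q1=[0.3, np.nan, 0.4, 0.5], counts=[3, 0, 3, 3],
        )
        assert threshold_from_binned_stats(binned, 0.25, "Q1") == 1.0

    def test_never_above_is_undetermined(self):
        binned = make_binned([1, 2], [2, 4], q1=[0.1, 0.2])
        assert np.isnan(threshold_from_binned_stats(binned, 0.25, "Q1"))

    def test_strict_inequality_at_threshold(self):
        binned = make_binned([1, 2], [2, 4], q1=[0.25, 0.25])
        assert np.isnan(threshold_from_binned_stats(binned, 0.25, "Q1"))

    @pytest.mark.parametrize("statistic", ["Q1", "median"])
    def test_oracle_equivalence_randomized(self, rng, statistic):
        for _ in range(100):
            n_bins = int(rng.integers(1, 12))
            lowers = 2.0 ** np.arange(n_bins)
            uppers = 2.0 ** np.arange(1, n_bins + 1)
            counts = rng.integers(0, 5, size=n_bins)
            q1 = np.where(counts > 0, rng.uniform(-1, 1, n_bins), np.nan)
            med = np.where(counts > 0, q1 + rng.uniform(0, 0.3, n_bins), np.nan)
            if not (counts > 0).any():
                counts[0] = 1
                q1[0], med[0] = 0.0, 0.1
            binned = BinnedStats(lowers, uppers, counts, q1, med, med)
            c = float(rng.uniform(-0.5, 0.9))
            got = threshold_from_binned_stats(binned, c, statistic)
            want = brute_force_binned_threshold(binned, c, statistic)
            assert (np.isnan(got) and np.isnan(want)) or got == want


class TestCoefficientOfVariation:
    def test_constant_values(self):
        assert coefficient_of_variation([1, 1, 1, 1]) == 0.0

    def test_population_sd_convention(self):
        assert coefficient_of_variation([5, 15]) == pytest.approx(0.5)

    def test_matches_direct_formula(self):
        values = np.array([2.0, 4.0, 6.0])
        expected = np.sqrt(((values - 4) ** 2).mean()) / 4
        assert coefficient_of_variation(values) == pytest.approx(expected)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            coefficient_of_variation([-1.0, 1.0])


class TestOptimize:
    def test_identical_samples_tie_break_to_smallest_c(self):
        profile = SimilarityProfile(
            "a", np.array([1.0, 2, 4, 8]), np.array([0.1, 0.3, 0.6, 0.9])
        )
        per_sample = {
            "a": profile,
            "b": SimilarityProfile("b", profile.window_abundance,
                                   profile.window_similarity),
        }
        c, thresholds = optimize_similarity_threshold(
            per_sample, [0.2, 0.4, 0.5], method="line_smoothed", smoothing_width=1
        )
        assert c == 0.2
        assert np.array_equal(thresholds.theta, [2.0, 2.0])

    def test_matches_exhaustive_grid_search(self):
        # two samples whose thresholds diverge as c grows
        a = SimilarityProfile("a", np.array([1.0, 2, 4, 8, 16]),
                              np.array([0.1, 0.3, 0.5, 0.7, 0.9]))
        b = SimilarityProfile("b", np.array([1.0, 2, 4, 8, 16]),
                              np.array([0.1, 0.32, 0.4, 0.45, 0.9]))
        grid = [0.2, 0.35, 0.6]
        per_sample = {"a": a, "b": b}

        def theta(profile, c):
            return threshold_from_profile_line(profile, c, 1)

        best = min(
            grid,
            key=lambda c: abs(theta(a, c) - theta(b, c)) / (theta(a, c) + theta(b, c)),
        )
        c_star, _ = optimize_similarity_threshold(
            per_sample, grid, "line_smoothed", smoothing_width=1
        )
        assert c_star == best

    def test_no_eligible_c_is_error(self):
        low = SimilarityProfile("a", np.array([1.0, 2]), np.array([0.0, 0.01]))
        per_sample = {"a": low, "b": SimilarityProfile("b", low.window_abundance,
                                                       low.window_similarity)}
        with pytest.raises(ValidationError, match="eligible"):
            optimize_similarity_threshold(per_sample, [0.5, 0.9], "line_smoothed")

    def test_grouped_optimization_minimizes_within_group_cv(self):
        a = SimilarityProfile("a", np.array([1.0, 2, 4]), np.array([0.1, 0.5, 0.9]))
        b = SimilarityProfile("b", np.array([1.0, 2, 4]), np.array([0.1, 0.5, 0.9]))
        c_ = SimilarityProfile("c", np.array([1.0, 2, 4]), np.array([0.6, 0.7, 0.9]))
        d = SimilarityProfile("d", np.array([1.0, 2, 4]), np.array([0.6, 0.7, 0.9]))
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        c_star, th = optimize_similarity_threshold(
            {"a": a, "b": b, "c": c_, "d": d}, [0.3, 0.55], "line_smoothed",
            groups=groups, smoothing_width=1,
        )
        assert th.metadata["cv"] == 0.0

    def test_theta_monotone_in_c_random_profiles(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            abundance = np.sort(rng.uniform(1, 1000, size=n))
            similarity = rng.uniform(-0.2, 1.0, size=n)
            profile = SimilarityProfile("s", abundance, similarity)
            thetas = []
            for c in np.linspace(0.0, 0.9, 10):
                t = threshold_from_profile_line(profile, float(c), 1)
                thetas.append(np.inf if np.isnan(t) else t)
            assert all(x <= y for x, y in zip(thetas, thetas[1:]))

    def test_noise_floor_recovery_within_factor_two(self):
        design = NoiseFloorDesign(n_genes=3000, n_samples=4, noise_floor=32, seed=3)
        matrix, _ = generate_count_matrix(design)
        profiles = profile_all_samples(matrix)
        _, thresholds = optimize_similarity_threshold(profiles, method="boxplot_median")
        assert np.all(thresholds.theta >= design.noise_floor / 2)
        assert np.all(thresholds.theta <= design.noise_floor * 2)

    def test_all_noise_design_has_no_determined_thresholds(self):
        design = NoiseFloorDesign(n_genes=800, n_samples=3, noise_floor=2**14, seed=4)
        matrix, _ = generate_count_matrix(design)
        profiles = profile_all_samples(matrix)
        with pytest.raises(ValidationError):
            optimize_similarity_threshold(profiles, method="boxplot_median")


class TestBinning:
    def test_log2_bin_membership(self):
        binned = bin_similarity_values(
            np.array([1.0, 2, 3, 4, 7, 8]), np.zeros(6)
        )
        assert np.array_equal(binned.lower, [1, 2, 4, 8])
        assert np.array_equal(binned.upper, [2, 4, 8, 16])
        assert np.array_equal(binned.count, [1, 2, 2, 1])

    def test_single_record(self):
        binned = bin_similarity_values(np.array([5.0]), np.array([0.4]))
        assert binned.n_bins == 1
        assert binned.q1 == binned.median == binned.q3 == pytest.approx(0.4)

    def test_zero_abundance_goes_to_dedicated_lowest_bin(self):
        binned = bin_similarity_values(
            np.array([0.0, 2.0, 5.0]), np.array([0.0, 0.5, 0.6])
        )
        assert binned.lower[0] == 0.0
        assert binned.count[0] == 1

    def test_oracle_bin_membership_and_quartiles(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            abundance = rng.uniform(0.5, 500, size=n)
            similarity = rng.uniform(-1, 1, size=n)
            binned = bin_similarity_values(abundance, similarity)
            for i in range(binned.n_bins):
                members = similarity[
                    (abundance >= binned.lower[i]) & (abundance < binned.upper[i])
                ]
                assert binned.count[i] == members.size
                if members.size:
                    assert binned.q1[i] == pytest.approx(np.percentile(members, 25))
                    assert binned.median[i] == pytest.approx(np.percentile(members, 50))
                    assert binned.q3[i] == pytest.approx(np.percentile(members, 75))

    def test_profile_to_binned_stats_round(self):
        profile = SimilarityProfile(
            "s", np.array([1.5, 3.0, 10.0]), np.array([0.1, 0.5, 0.9])
        )
        binned = profile_to_binned_stats(profile)
        assert binned.count.sum() == 3
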