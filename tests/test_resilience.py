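"""Perturbation operators, deviation metrics and recovery-time logic."""
import numpy as np
import pytest

from macroresilience.distributions import (
    TruncatedParetoSizeDist,
    fit_trunc_pareto,
    sample_trunc_pareto,
    trunc_pareto_cdf,
)
from macroresilience.resilience import (
    BaselineSummary,
    PerturbationSpec,
    RecoveryTrajectory,
    apply_perturbation,
    baseline_deviation,
    bray_curtis,
    calibrate_tolerance,
    hellinger_between,
    recovery_time,
    track_recovery,
)
from macroresilience.size_structure import IbmForest, MSTGrowthParams


def pareto_sample(n, seed, lam=-2.0, m0=0.01, mmax=1.0):
    dist = TruncatedParetoSizeDist(lam, m0, mmax)
    return sample_trunc_pareto(dist, n, np.random.default_rng(seed))


class TestPerturbationSpec:
    def test_intensity_bounds(self):
        with pytest.raises(ValueError):
            PerturbationSpec("remove_small", 1.5, threshold=0.1)
        # rate multipliers above 1 are legitimate for a press
        PerturbationSpec("rate_shift", 2.0, threshold=0.05)

    def test_size_selective_needs_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            PerturbationSpec("remove_large", 0.5)


class TestApplyPerturbation:
    def test_zero_intensity_is_identity(self):
        sizes = pareto_sample(500, 0)
        out = apply_perturbation(sizes, PerturbationSpec("proportional_thinning", 0.0), 1)
        assert np.array_equal(out, sizes)

    def test_remove_large_clears_above_threshold(self):
        sizes = pareto_sample(2000, 1)
        thr = np.quantile(sizes, 0.9)
        out = apply_perturbation(
            sizes, PerturbationSpec("remove_large", 1.0, threshold=thr), 2
        )
        assert out.max() <= thr
        assert out.size < sizes.size

    def test_partial_small_removal_flattens_fitted_exponent(self):
        """Removing 90% of the individuals below the median makes the fitted
        size-spectrum exponent shallower, consistently across seeds."""
        hits = 0
        for s in range(10):
            sizes = pareto_sample(5000, 100 + s)
            base = fit_trunc_pareto(sizes).lam
            thr = np.median(sizes)
            out = apply_perturbation(
                sizes, PerturbationSpec("remove_small", 0.9, threshold=thr), s
            )
            hits += fit_trunc_pareto(out).lam > base
        assert hits >= 9

    def test_complete_truncation_is_self_similar(self):
        """Deleting *every* individual below a cutoff merely re-truncates the
        Pareto: with plug-in endpoints the fitted exponent is unchanged up to
        sampling noise."""
        sizes = pareto_sample(50_000, 3)
        out = apply_perturbation(
            sizes, PerturbationSpec("remove_small", 1.0, threshold=np.median(sizes)), 4
        )
        assert fit_trunc_pareto(out).lam == pytest.approx(
            fit_trunc_pareto(sizes).lam, abs=0.1
        )

    def test_total_removal_rejected(self):
        sizes = pareto_sample(100, 5)
        with pytest.raises(ValueError, match="whole population"):
            apply_perturbation(
                sizes, PerturbationSpec("proportional_thinning", 1.0), 6
            )
        with pytest.raises(ValueError, match="empty"):
            apply_perturbation(np.array([]), PerturbationSpec("proportional_thinning", 0.5), 0)

    def test_rate_shift_scales_below_threshold_only(self):
        base = lambda D: np.full_like(np.asarray(D, dtype=float), 0.5)
        shifted = apply_perturbation(
            base, PerturbationSpec("rate_shift", 2.0, threshold=0.05), 0
        )
        D = np.array([0.01, 0.04, 0.06, 0.5])
        assert shifted(D) == pytest.approx([1.0, 1.0, 0.5, 0.5])

    def test_seeded_determinism(self):
        sizes = pareto_sample(1000, 7)
        spec = PerturbationSpec("proportional_thinning", 0.3)
        assert np.array_equal(
            apply_perturbation(sizes, spec, 11), apply_perturbation(sizes, spec, 11)
        )


class TestDeviationMetrics:
    def test_ks_small_for_matching_sample(self):
        dist = TruncatedParetoSizeDist(-2.0, 0.01, 1.0)
        base = BaselineSummary(
            "trunc_pareto", {"lambda": -2.0, "m0": 0.01, "mmax": 1.0}
        )
        sizes = sample_trunc_pareto(dist, 10_000, np.random.default_rng(0))
        assert baseline_deviation(sizes, base, "ks") < 0.02

    def test_ks_matches_quadrature_oracle(self):
        """Large-sample empirical KS against a lambda = -2 baseline, for data
        from lambda = -1.5, converges to the analytic sup-cdf gap."""
        d1 = TruncatedParetoSizeDist(-1.5, 1.0, 100.0)
        d2 = TruncatedParetoSizeDist(-2.0, 1.0, 100.0)
        grid = np.geomspace(1.0, 100.0, 200_001)
        oracle = np.max(np.abs(trunc_pareto_cdf(grid, d1) - trunc_pareto_cdf(grid, d2)))
        base = BaselineSummary("trunc_pareto", {"lambda": -2.0, "m0": 1.0, "mmax": 100.0})
        sizes = sample_trunc_pareto(d1, 200_000, np.random.default_rng(1))
        assert baseline_deviation(sizes, base, "ks") == pytest.approx(oracle, abs=0.01)

    def test_hellinger_properties(self):
        d1 = TruncatedParetoSizeDist(-2.0, 0.01, 1.0)
        d2 = TruncatedParetoSizeDist(-1.2, 0.01, 1.0)
        assert hellinger_between(d1, d1) == pytest.approx(0.0, abs=1e-12)
        h12, h21 = hellinger_between(d1, d2), hellinger_between(d2, d1)
        assert h12 == pytest.approx(h21)
        assert 0.0 < h12 <= 1.0

    def test_param_distance(self):
        a = BaselineSummary("trunc_pareto", {"lambda": -2.0, "m0": 0.01, "mmax": 1.0})
        b = BaselineSummary("trunc_pareto", {"lambda": -1.0, "m0": 0.01, "mmax": 1.0})
        assert baseline_deviation(a, a, "param_distance") == 0.0
        assert baseline_deviation(b, a, "param_distance") == pytest.approx(1.0)
        # scaling a parameter rescales its contribution
        assert baseline_deviation(
            b, a, "param_distance", param_scale={"lambda": 2.0}
        ) == pytest.approx(0.5)

    def test_param_distance_type_check(self):
        a = BaselineSummary("trunc_pareto", {"lambda": -2.0})
        with pytest.raises(ValueError):
            baseline_deviation(np.array([1.0, 2.0]), a, "param_distance")

    def test_unknown_metric(self):
        a = BaselineSummary("trunc_pareto", {"lambda": -2.0, "m0": 0.01, "mmax": 1.0})
        with pytest.raises(ValueError, match="metric"):
            baseline_deviation(np.array([0.5]), a, "wasserstein")


class TestBrayCurtis:
    def test_identical_is_zero(self):
        assert bray_curtis([0.5, 0.3, 0.2], [0.5, 0.3, 0.2]) == 0.0

    def test_disjoint_is_one(self):
        assert bray_curtis([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_symmetry_and_range(self):
        p, q = [0.7, 0.2, 0.1], [0.2, 0.5, 0.3]
        assert bray_curtis(p, q) == pytest.approx(bray_curtis(q, p))
        assert 0.0 <= bray_curtis(p, q) <= 1.0


def synthetic_traj(devs, dt=1.0):
    n = len(devs)
    base = BaselineSummary("trunc_pareto", {"lambda": -2.0, "m0": 0.01, "mmax": 1.0})
    return RecoveryTrajectory(
        np.arange(1, n + 1) * dt, [base] * n, np.asarray(devs, dtype=float)
    )


class TestRecoveryTime:
    def test_first_persistent_window(self):
        traj = synthetic_traj([0.5, 0.4, 0.05, 0.04, 0.03, 0.02])
        assert recovery_time(traj, 0.1, persistence=3) == 3.0

    def test_transient_dips_do_not_count(self):
        traj = synthetic_traj([0.05, 0.5, 0.05, 0.5, 0.05, 0.04, 0.03])
        assert recovery_time(traj, 0.1, persistence=3) == 5.0
        assert recovery_time(traj, 0.1, persistence=1) == 1.0

    def test_never_recovering_is_none(self):
        traj = synthetic_traj([0.5, 0.6, 0.7, 0.8])
        assert recovery_time(traj, 0.1) is None

    def test_monotone_in_tolerance_and_persistence(self):
        devs = [0.5, 0.3, 0.15, 0.08, 0.04, 0.02, 0.02, 0.02]
        traj = synthetic_traj(devs)
        loose = recovery_time(traj, 0.2, persistence=2)
        tight = recovery_time(traj, 0.05, persistence=2)
        assert loose <= tight
        longer = recovery_time(traj, 0.2, persistence=4)
        assert loose <= longer

    def test_validation(self):
        traj = synthetic_traj([0.1])
        with pytest.raises(ValueError):
            recovery_time(traj, 0.0)
        with pytest.raises(ValueError):
            recovery_time(traj, 0.1, persistence=0)

    def test_trajectory_alignment_enforced(self):
        base = BaselineSummary("trunc_pareto", {"lambda": -2.0})
        with pytest.raises(ValueError):
            RecoveryTrajectory(np.array([1.0, 2.0]), [base], np.array([0.1, 0.2]))


class TestTrackRecovery:
    @staticmethod
    def relaxed_forest(seed, n=800):
        forest = IbmForest(growth=MSTGrowthParams())
        forest.initialize(n, seed)
        forest.run(0.3, seed)
        return forest

    def test_pulse_scenario_structure(self):
        forest = self.relaxed_forest(1)
        base = BaselineSummary(
            "trunc_pareto", fit_trunc_pareto(forest.diameters).to_dict()
        )
        thr = np.quantile(forest.diameters, 0.9)
        traj = track_recovery(
            forest, base, PerturbationSpec("remove_large", 1.0, threshold=thr),
            horizon=1.0, sampling_interval=0.25, seed=1, keep_sizes=True,
        )
        assert traj.times.size == 4
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(np.isfinite(traj.deviation_series))
        assert len(traj.sizes_series) == 4
        # zero-sum refill keeps the population size constant through the pulse
        assert all(s.size == 800 for s in traj.sizes_series)

    def test_press_restores_mortality_after_run(self):
        forest = self.relaxed_forest(2)
        base_mortality = forest.mortality
        base = BaselineSummary(
            "trunc_pareto", fit_trunc_pareto(forest.diameters).to_dict()
        )
        traj = track_recovery(
            forest, base, PerturbationSpec("rate_shift", 2.0, threshold=0.05),
            horizon=0.5, sampling_interval=0.25, seed=2,
        )
        assert forest.mortality is base_mortality
        assert traj.times.size == 2

    def test_horizon_validation(self):
        forest = self.relaxed_forest(3, n=100)
        base = BaselineSummary(
            "trunc_pareto", fit_trunc_pareto(forest.diameters).to_dict()
        )
        with pytest.raises(ValueError, match="horizon"):
            track_recovery(
                forest, base, PerturbationSpec("proportional_thinning", 0.0),
                horizon=0.1, sampling_interval=0.25, seed=3,
            )

    def test_calibrated_tolerance_bounds_null_fluctuation(self):
        baseline_forest = self.relaxed_forest(4)
        base = BaselineSummary(
            "trunc_pareto", fit_trunc_pareto(baseline_forest.diameters).to_dict()
        )
        tol = calibrate_tolerance(
            lambda s: self.relaxed_forest(s),
            base,
            seeds=[11, 12],
            horizon=0.5,
            sampling_interval=0.25,
        )
        assert 0.0 < tol < 0.5
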