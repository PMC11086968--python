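"""Wald statistic, null moments, λ selection, decision rule and BH control."""

import numpy as np
import pytest

from parcurve import (
    DesignPoints,
    KernelConfig,
    SimulationSetting,
    SpectralSolver,
    assemble_grams,
    bh_adjust,
    decide,
    effective_dimension,
    generate,
    null_moments,
    parallelism_test,
    select_lambda,
)
from parcurve import test_statistic as wald_statistic
from parcurve.kernels import _component_matrices
from parcurve.ssanova import rescale_thetas
from parcurve.waldtest import LambdaGridError, NullMoments

from conftest import make_points


class TestStatistic:
    def test_zero_vector(self):
        assert wald_statistic(np.zeros(8)) == 0.0

    def test_known_value(self):
        assert wald_statistic(np.ones(4)) == 1.0

    def test_quadratic_homogeneity(self, rng):
        f = rng.normal(size=30)
        assert wald_statistic(2.5 * f) == pytest.approx(2.5**2 * wald_statistic(f))


class TestDecide:
    def test_at_null_mean(self):
        m = NullMoments(mu=1.0, sigma=0.5, trace_delta=1, trace_delta2=1, sigma2=1)
        z, p, rej = decide(1.0, m, alpha=0.05)
        assert z == 0.0 and p == 1.0 and not rej

    def test_boundary_rejection(self):
        m = NullMoments(mu=0.0, sigma=1.0, trace_delta=1, trace_delta2=1, sigma2=1)
        z, p, rej = decide(1.959964, m, alpha=0.05)
        assert p == pytest.approx(0.05, abs=1e-4)
        assert rej

    def test_bad_alpha(self):
        m = NullMoments(mu=0, sigma=1, trace_delta=1, trace_delta2=1, sigma2=1)
        with pytest.raises(ValueError):
            decide(0.0, m, alpha=1.5)


class TestNullMoments:
    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegative_traces(self, seed):
        pts = make_points(n=12, seed=seed)
        cfg = KernelConfig(m=2, lam=1e-4)
        _, _, K10, K11 = _component_matrices(pts, 2)
        cfg.theta10, cfg.theta11 = rescale_thetas(K10, K11)
        mom = null_moments(assemble_grams(pts, cfg), sigma2=1.0)
        assert mom.mu >= 0 and mom.trace_delta >= 0 and mom.trace_delta2 >= 0
        assert mom.sigma > 0

    def test_moments_match_quadratic_form_simulation(self):
        """Mean/variance of eps' Δ eps / ns match the trace formulas."""
        rng = np.random.default_rng(0)
        pts = make_points(n=100, seed=11)
        solver = SpectralSolver(pts)
        lam = 1e-4
        td, td2 = solver.delta_traces(lam)
        mu_th = td / pts.total_obs
        var_th = 2.0 * td2 / pts.total_obs**2
        w = solver._weights(lam)
        Ts = []
        for _ in range(3000):
            eps = rng.normal(size=(pts.n, pts.s))
            _, ym, _ = solver.transform(eps)
            f = (pts.s / 4.0) * solver.mu * (w * ym)
            Ts.append(float(f @ f) / pts.total_obs)
        Ts = np.asarray(Ts)
        mc_se = Ts.std() / np.sqrt(len(Ts))
        assert abs(Ts.mean() - mu_th) < 3 * mc_se
        assert Ts.var() == pytest.approx(var_th, rel=0.2)


class TestSelectLambda:
    def test_sigma_nl_nonincreasing(self):
        from parcurve.waldtest import _moments_spectral

        for seed in range(5):
            solver = SpectralSolver(make_points(n=60, seed=seed))
            grid = np.logspace(-8, 0, 40)
            sig = [_moments_spectral(solver, lam, 1.0).sigma for lam in grid]
            assert all(a >= b - 1e-15 for a, b in zip(sig, sig[1:]))

    def test_crossing_is_selected(self):
        from parcurve.waldtest import _moments_spectral

        solver = SpectralSolver(make_points(n=60, seed=1))
        grid = np.logspace(-8, 0, 40)
        lam_star = select_lambda(solver, 1.0, grid)
        assert lam_star >= _moments_spectral(solver, lam_star, 1.0).sigma
        below = grid[grid < lam_star]
        for lam in below[-3:]:  # points just below the crossing still fail
            assert lam < _moments_spectral(solver, lam, 1.0).sigma

    def test_single_point_grid(self):
        solver = SpectralSolver(make_points(n=30, seed=2))
        assert select_lambda(solver, 1.0, [0.5]) == 0.5

    def test_no_crossing_raises(self):
        solver = SpectralSolver(make_points(n=30, seed=2))
        with pytest.raises(LambdaGridError):
            select_lambda(solver, 1.0, [1e-12])

    def test_crossing_interior_and_stable_in_n(self):
        """The crossing stays in the grid interior across sample sizes and the
        noise scale moves it monotonely (larger sigma2 -> larger λ*)."""
        grid = np.logspace(-8, 0, 200)
        for n in (100, 400):
            x = (np.arange(n) + 0.5) / n
            pts = DesignPoints(positions=x, subject_groups=np.array([0, 1]),
                               responses=np.zeros((n, 2)))
            solver = SpectralSolver(pts)
            lam1 = select_lambda(solver, 1.0, grid)
            lam2 = select_lambda(solver, 4.0, grid)
            assert grid[0] < lam1 <= lam2 < grid[-1]


class TestEffectiveDimension:
    def test_counting(self):
        assert effective_dimension(np.array([1.0, 0.5, 0.1]), 0.3) == 2
        assert effective_dimension(np.array([1.0, 0.5]), 2.0) == 0

    def test_lambda_power_law(self):
        """tau_lambda ~ lambda^{-1/(2m)} on the Bernoulli kernel spectrum."""
        n = 500
        x = (np.arange(n) + 0.5) / n
        from parcurve import k1_continuous

        mu = np.linalg.eigvalsh(k1_continuous(x[:, None], x[None, :], 2) / n)[::-1]
        lams = np.logspace(-11, -5, 15)
        taus = np.array([effective_dimension(mu, l) for l in lams])
        keep = (taus > 1) & (taus < n / 2)
        slope = np.polyfit(np.log(lams[keep]), np.log(taus[keep]), 1)[0]
        assert slope == pytest.approx(-0.25, abs=0.1)


class TestPipeline:
    def test_deterministic(self, setting1_points):
        r1 = parallelism_test(setting1_points)
        r2 = parallelism_test(setting1_points)
        assert r1 == r2

    def test_rejects_strong_nonparallel_signal(self):
        s = SimulationSetting(setting_id=1, n=300, delta1=1.0, seed=3)
        res = parallelism_test(generate(s))
        assert res.reject and res.p_value < 0.01

    def test_accepts_parallel_signal(self):
        s = SimulationSetting(setting_id=5, n=300, delta4=1.0, seed=4)
        res = parallelism_test(generate(s))
        assert res.p_value > 0.01

    def test_wilks_nuisance_invariance(self, rng):
        """With sigma2 fixed, adding any parallel structure (grand mean, smooth
        position effect, group shift) leaves statistic, moments and p-value
        bit-identical: the null calibration is nuisance-free."""
        n = 120
        x = np.sort(rng.uniform(0, 1, n))
        noise = rng.normal(size=(n, 2))
        groups = np.array([0, 1])
        base = DesignPoints(positions=x, subject_groups=groups, responses=noise)
        nuisance = (1.7 + 2.5 * np.sin(3 * np.pi * x) * (1 - x))[:, None] \
            + np.array([0.0, 0.9])[None, :]
        shifted = DesignPoints(positions=x, subject_groups=groups,
                               responses=noise + nuisance)
        r0 = parallelism_test(base, sigma2=1.0)
        r1 = parallelism_test(shifted, sigma2=1.0)
        assert r0.statistic == pytest.approx(r1.statistic, rel=1e-9)
        assert r0.p_value == pytest.approx(r1.p_value, rel=1e-9)
        assert r0.lambda_star == r1.lambda_star

    def test_null_normality_grows_with_effective_dimension(self):
        """Asymptotic-normality mechanism: at fixed λ with Tr(Δ²) large the standardized
        null statistic is close to N(0,1) (KS at level 0.01)."""
        from scipy.stats import kstest

        n = 400
        x = (np.arange(n) + 0.5) / n
        pts0 = DesignPoints(positions=x, subject_groups=np.array([0, 1]),
                            responses=np.zeros((n, 2)))
        solver = SpectralSolver(pts0)
        lam = 1e-9  # effective dimension ~ 56
        td, td2 = solver.delta_traces(lam)
        mu_th = td / solver.ns
        sd_th = np.sqrt(2 * td2) / solver.ns
        rng = np.random.default_rng(99)
        w = solver._weights(lam)
        zs = []
        for _ in range(1000):
            _, ym, _ = solver.transform(rng.normal(size=(n, 2)))
            f = (2 / 4.0) * solver.mu * (w * ym)
            zs.append((float(f @ f) / solver.ns - mu_th) / sd_th)
        assert kstest(zs, "norm").pvalue > 0.01


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.001, 0.04]), [0.002, 0.04])

    def test_ties_and_bounds(self, rng):
        p = np.full(5, 0.2)
        np.testing.assert_allclose(bh_adjust(p), p)
        q = bh_adjust(rng.uniform(size=40))
        assert np.all(q <= 1.0) and np.all(q >= 0.0)

    def test_dominates_raw_p(self, rng):
        p = rng.uniform(size=25)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
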