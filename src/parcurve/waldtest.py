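"""Wald-type parallelism test with its asymptotic Gaussian null calibration.

The statistic is T = ||f11_hat||^2 / ns for the penalized least-squares
interaction estimate.  Under H0: f11 = 0 (and group-balanced designs) the
nuisance components cancel exactly and T is a quadratic form in the noise
with

    mean  mu    = sigma^2 Tr(Δ) / ns,
    var   sigma_nl^2 = 2 sigma^4 Tr(Δ²) / ns²,      Δ = M^-1 K11_raw^2 M^-1,

free of f00, f10, f01 (the Wilks phenomenon).  The standardized statistic is
compared two-sided against N(0,1).  The smoothing parameter is chosen by the
testing-oriented rule λ* = min{λ on the grid : λ >= sigma_nl(λ)} — the
crossing point of the penalty scale with the null standard deviation, which
balances estimation bias against the statistic's spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .kernels import DesignPoints, GramSet, KernelConfig
from .spectral import SpectralSolver

__all__ = [
    "NullMoments",
    "TestResult",
    "test_statistic",
    "null_moments",
    "decide",
    "select_lambda",
    "effective_dimension",
    "parallelism_test",
    "bh_adjust",
    "DEFAULT_GRID",
]

#: default λ grid: 50 log-spaced points spanning [1e-8, 1].
DEFAULT_GRID = np.logspace(-8, 0, 50)


class LambdaGridError(RuntimeError):
    """The λ* condition never crossed on the supplied grid."""


@dataclass
class NullMoments:
    """Null mean/sd of the statistic plus the underlying trace functionals."""

    mu: float
    sigma: float
    trace_delta: float
    trace_delta2: float
    sigma2: float

    def z(self, statistic: float) -> float:
        return (statistic - self.mu) / self.sigma


@dataclass
class TestResult:
    statistic: float
    z: float
    p_value: float
    lambda_star: float
    alpha: float
    reject: bool
    sigma2_used: float
    moments: NullMoments
    edf: float
    n: int
    s: int


def test_statistic(f11_hat: np.ndarray) -> float:
    """Squared Euclidean norm of the interaction estimate over ns."""
    f = np.asarray(f11_hat, dtype=float).ravel()
    return float(f @ f) / f.size


def _delta_traces_dense(grams: GramSet) -> tuple[float, float]:
    """Tr(Δ), Tr(Δ²) via Cholesky of M (no explicit inverse).

    With G = M^-1 K11_raw we have Δ = G G', so Tr(Δ) = ||G||_F^2 and
    Tr(Δ²) = ||Δ||_F^2.
    """
    Mc = cho_factor(grams.M, lower=True)
    G = cho_solve(Mc, grams.K11_raw)
    tr_delta = float(np.sum(G * G))
    delta = G @ G.T
    tr_delta2 = float(np.sum(delta * delta))
    return tr_delta, tr_delta2


def null_moments(grams: GramSet, sigma2: float) -> NullMoments:
    """Asymptotic null mean and standard deviation of the statistic (dense path)."""
    td, td2 = _delta_traces_dense(grams)
    ns = grams.ns
    return NullMoments(
        mu=sigma2 * td / ns,
        sigma=float(np.sqrt(2.0 * td2)) * sigma2 / ns,
        trace_delta=td,
        trace_delta2=td2,
        sigma2=sigma2,
    )


def _moments_spectral(solver: SpectralSolver, lam: float, sigma2: float) -> NullMoments:
    td, td2 = solver.delta_traces(lam)
    ns = solver.ns
    return NullMoments(
        mu=sigma2 * td / ns,
        sigma=float(np.sqrt(2.0 * td2)) * sigma2 / ns,
        trace_delta=td,
        trace_delta2=td2,
        sigma2=sigma2,
    )


def decide(statistic: float, moments: NullMoments, alpha: float = 0.05):
    """Two-sided normal decision: z, p-value and rejection flag."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    z = moments.z(statistic)
    p = 2.0 * float(norm.sf(abs(z)))
    return z, p, p <= alpha


def select_lambda(solver: SpectralSolver, sigma2: float, grid=None) -> float:
    """Data-adaptive testing λ: smallest grid λ with λ >= sigma_nl(λ).

    sigma_nl(λ) is nonincreasing in λ, so this is the crossing of the penalty
    scale with the null standard deviation of the statistic.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    for lam in grid:
        s_nl = _moments_spectral(solver, lam, sigma2).sigma
        if lam >= s_nl:
            return float(lam)
    raise LambdaGridError(
        "λ never reached sigma_nl on the grid; expand the grid upper bound"
    )


def effective_dimension(eigenvalues: np.ndarray, lam: float) -> int:
    """Number of kernel eigenvalues >= λ (eigenvalues sorted descending)."""
    ev = np.asarray(eigenvalues, dtype=float)
    return int(np.sum(ev >= lam))


def parallelism_test(
    points: DesignPoints,
    alpha: float = 0.05,
    m: int = 2,
    lam: float | None = None,
    sigma2: float | None = None,
    grid=None,
) -> TestResult:
    """Full pipeline: σ̂² (GCV), λ* selection, fit, statistic, decision.

    ``lam`` overrides the data-adaptive λ*; ``sigma2`` overrides the noise
    variance estimate (useful for the exact Wilks-invariance property).
    Deterministic given inputs.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    solver = SpectralSolver(points, m=m)
    yp, ym, comp_sq = solver.transform(points.responses)
    if sigma2 is None:
        sigma2, _ = solver.sigma2_gcv(yp, ym, comp_sq, grid)
    lam_star = float(lam) if lam is not None else select_lambda(solver, sigma2, grid)
    T, _, tr_ia, _, _ = solver.fit(yp, ym, comp_sq, lam_star)
    moments = _moments_spectral(solver, lam_star, sigma2)
    z, p, reject = decide(T, moments, alpha)
    return TestResult(
        statistic=T,
        z=z,
        p_value=p,
        lambda_star=lam_star,
        alpha=alpha,
        reject=reject,
        sigma2_used=sigma2,
        moments=moments,
        edf=solver.ns - tr_ia,
        n=points.n,
        s=points.s,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]
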