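"""Random permutation benchmark for the parallelism hypothesis.

Under H0 the group label carries no information beyond a vertical shift, so
after removing the fitted null model (grand mean, smooth position effect and
group shift) the residuals are exchangeable across subjects within each
position.  The benchmark permutes subject labels independently at every
position, recomputes the Wald statistic on each permuted data set at the
same λ, and reports the add-one Monte-Carlo p-value

    p = (1 + #{T_b >= T_obs}) / (B + 1).

A raw mode (permuting the observations themselves rather than null-model
residuals) is also provided; residual mode is the default since it preserves
the main effects exactly under H0.
"""

from __future__ import annotations

import numpy as np

from .kernels import DesignPoints
from .spectral import SpectralSolver
from .waldtest import DEFAULT_GRID, select_lambda

__all__ = ["permutation_test"]


def _null_model_fit(solver: SpectralSolver, points: DesignPoints, lam: float) -> np.ndarray:
    """Fitted values of the no-interaction model (f00 + f10 + f01) as (n, s)."""
    yp, ym, _ = solver.transform(points.responses)
    w = solver._weights(lam)
    q = solver.q
    qwq = float(q @ (w * q))
    # + branch: intercept + smooth position effect
    dp = float(q @ (w * yp)) / qwq
    cp = w * (yp - q * dp)
    fit_p = q * dp + solver.rho * solver.mu * cp  # S-part + R-part in branch coords
    # - branch: group shift only (the penalized - branch belongs to f11)
    dm = float(q @ (w * ym)) / qwq
    fit_m = q * dm
    return (np.outer(solver.V @ fit_p, solver.u_plus)
            + np.outer(solver.V @ fit_m, solver.u_minus))


def permutation_test(
    points: DesignPoints,
    B: int = 500,
    seed: int | None = 0,
    alpha: float = 0.05,
    m: int = 2,
    lam: float | None = None,
    mode: str = "residual",
    grid=None,
):
    """Within-position permutation test; returns (p_value, reject, T_obs).

    B permutations; deterministic given (seed, B, data).  λ defaults to the
    same data-adaptive λ* as the Wald test (with GCV σ̂²).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if mode not in ("residual", "raw"):
        raise ValueError("mode must be 'residual' or 'raw'")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    solver = SpectralSolver(points, m=m)
    yp, ym, comp_sq = solver.transform(points.responses)
    if lam is None:
        sigma2, _ = solver.sigma2_gcv(yp, ym, comp_sq, grid)
        lam = select_lambda(solver, sigma2, grid)
    T_obs, _, _, _, _ = solver.fit(yp, ym, comp_sq, lam)

    if mode == "residual":
        base = _null_model_fit(solver, points, lam)
        resid = points.responses - base
    else:
        base = np.zeros_like(points.responses)
        resid = points.responses

    n, s = resid.shape
    count = 0
    for _ in range(B):
        perm = rng.permuted(np.broadcast_to(np.arange(s), (n, s)), axis=1)
        permuted = base + np.take_along_axis(resid, perm, axis=1)
        ypb, ymb, csb = solver.transform(permuted)
        T_b, _, _, _, _ = solver.fit(ypb, ymb, csb, lam)
        if T_b >= T_obs:
            count += 1
    p = (1.0 + count) / (B + 1.0)
    return p, p <= alpha, T_obs
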