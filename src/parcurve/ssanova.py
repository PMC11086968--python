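"""Penalized least-squares fitting of the two-way SSANOVA model.

The estimator minimizes, over the unpenalized coefficients d (intercept and
group contrast) and the kernel coefficients c,

    (1/ns) * || y - S d - R c ||^2  +  lam * c' R c,

where R = theta10*K10 + theta11*K11 is the penalized-block kernel matrix on
the raw scale.  With M = R + ns*lam*I the minimizer is the classical
smoothing-spline linear system

    d = (S' M^-1 S)^-1 S' M^-1 y,
    c = M^-1 (I - S (S' M^-1 S)^-1 S' M^-1) y,

and the nonparallel component evaluated at the data points is
f11 = K11_raw c (the constant scale theta11 is deliberately not folded into
the evaluation).  This module is the dense reference implementation; the
spectral fast path for complete balanced designs lives in
``parcurve.spectral`` and is tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .kernels import DesignPoints, GramSet, InvalidDesignError, KernelConfig, assemble_grams

__all__ = [
    "FitResult",
    "rescale_thetas",
    "solve_coefficients",
    "fit_f11",
    "smoother_trace",
    "estimate_sigma2",
    "penalized_fit",
]


class DegenerateKernelError(ValueError):
    """A penalized kernel block has zero trace and cannot be rescaled."""


@dataclass
class FitResult:
    """Penalized least-squares fit at one λ.

    f11_hat is the interaction component evaluated at the ns data points;
    fitted is the full fitted vector S d + R c; sigma2_hat the residual-based
    noise variance; edf the trace of the (symmetric) smoother matrix.
    """

    alpha_hat: np.ndarray
    d_hat: np.ndarray
    f11_hat: np.ndarray
    fitted: np.ndarray
    sigma2_hat: float
    lambda_used: float
    theta_used: tuple[float, float]
    edf: float


def rescale_thetas(K10: np.ndarray, K11: np.ndarray) -> tuple[float, float]:
    """Trace equalization of the two penalized blocks.

    Returns (theta10, theta11) with theta10*tr(K10) = theta11*tr(K11) = 1, so
    both blocks contribute equally to the penalty.  The resulting penalty
    matrix theta10*K10 + theta11*K11 is invariant to the entry scaling of the
    inputs.
    """
    t10 = float(np.trace(K10))
    t11 = float(np.trace(K11))
    if t10 <= 0 or t11 <= 0:
        raise DegenerateKernelError(
            f"penalized kernel block has nonpositive trace (tr K10={t10:g}, tr K11={t11:g})"
        )
    return 1.0 / t10, 1.0 / t11


def solve_coefficients(y: np.ndarray, grams: GramSet) -> tuple[np.ndarray, np.ndarray]:
    """Solve the penalized least-squares system; returns (c, d).

    c (length ns) are the kernel coefficients, d (length 2) the unpenalized
    coefficients.  Raises on a singular S' M^-1 S (degenerate design).
    """
    y = np.asarray(y, dtype=float)
    try:
        Mc = cho_factor(grams.M, lower=True)
    except np.linalg.LinAlgError as e:  # pragma: no cover - jitter makes this rare
        raise np.linalg.LinAlgError(f"M factorization failed at lam={grams.lam:g}: {e}")
    MiS = cho_solve(Mc, grams.S)
    Miy = cho_solve(Mc, y)
    StMiS = grams.S.T @ MiS
    if np.linalg.cond(StMiS) > 1e12:
        raise InvalidDesignError("S' M^-1 S is numerically singular")
    d = np.linalg.solve(StMiS, grams.S.T @ Miy)
    c = Miy - MiS @ d
    return c, d


def fit_f11(y: np.ndarray, grams: GramSet) -> np.ndarray:
    """Closed-form nonparallel component at the data points.

    f11 = K11_raw M^-1 (I - S (S'M^-1 S)^-1 S' M^-1) y.  Exactly zero (to
    rounding) whenever y lies in the span of S.
    """
    c, _ = solve_coefficients(y, grams)
    return grams.K11_raw @ c


def smoother_trace(grams: GramSet) -> float:
    """Trace of I - A(λ) for the symmetric smoother A mapping y to fitted values.

    Since y - fitted = ns*lam * c, we have I - A = ns*lam * M^-1 (I - P) with
    P the M^-1-orthogonal projector onto span(S), and
    tr(I - A) = ns*lam * (tr M^-1 - tr[(S'M^-1S)^-1 (S'M^-2S)]).
    """
    Mc = cho_factor(grams.M, lower=True)
    ns = grams.ns
    L = np.linalg.cholesky(grams.M)
    Linv_diagsum = np.linalg.solve(L, np.eye(ns))
    trMi = float(np.sum(Linv_diagsum**2))
    MiS = cho_solve(Mc, grams.S)
    StMiS = grams.S.T @ MiS
    StM2S = MiS.T @ MiS
    trMiP = float(np.trace(np.linalg.solve(StMiS, StM2S)))
    return ns * grams.lam * (trMi - trMiP)


def estimate_sigma2(y: np.ndarray, grams: GramSet) -> float:
    """Residual-based noise variance y'(I-A)^2 y / tr(I-A) at the GramSet's λ."""
    c, d = solve_coefficients(y, grams)
    resid = grams.ns * grams.lam * c  # y - fitted, exactly
    tr_ia = smoother_trace(grams)
    if tr_ia <= 0:
        raise ValueError(f"tr(I - A) = {tr_ia:g} <= 0: smoother is degenerate at this λ")
    return float(resid @ resid) / tr_ia


def penalized_fit(points: DesignPoints, config: KernelConfig,
                  grams: GramSet | None = None) -> FitResult:
    """Full dense fit: θ rescaling (if unset), coefficient solve, components.

    Convenience wrapper used by tests and the dense code path of the
    region-scan tooling; large simulations go through ``parcurve.spectral``.
    """
    if config.theta10 is None or config.theta11 is None:
        from .kernels import _component_matrices

        _, _, K10r, K11r = _component_matrices(points, config.m)
        config.theta10, config.theta11 = rescale_thetas(K10r, K11r)
    if grams is None:
        grams = assemble_grams(points, config)
    y = points.y
    c, d = solve_coefficients(y, grams)
    f11 = grams.K11_raw @ c
    R = grams.ns * grams.Q
    fitted = grams.S @ d + R @ c
    tr_ia = smoother_trace(grams)
    resid = grams.ns * grams.lam * c
    sigma2 = float(resid @ resid) / tr_ia
    return FitResult(
        alpha_hat=c,
        d_hat=d,
        f11_hat=f11,
        fitted=fitted,
        sigma2_hat=sigma2,
        lambda_used=grams.lam,
        theta_used=(grams.theta10, grams.theta11),
        edf=grams.ns - tr_ia,
    )
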