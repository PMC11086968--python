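"""Bernoulli-polynomial spline kernels and Gram/design matrices.

The model space is the tensor product of an m-th order *homogeneous* (periodic)
Sobolev space on [0,1] and the two-point group space {0,1}.  Both marginal
spaces split under an averaging operator into a mean part and a contrast part,
which induces the four-way functional ANOVA decomposition

    f = f00 + f10(x) + f01(g) + f11(x, g),

where f11 is the *nonparallel* (interaction) component.  The continuous-margin
contrast kernel is built from scaled Bernoulli polynomials k_r(x) = B_r(x)/r!,
periodized to [0,1); the group-margin kernels are constants +-1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DesignPoints",
    "KernelConfig",
    "GramSet",
    "scaled_bernoulli",
    "k1_continuous",
    "group_kernel",
    "assemble_grams",
]

#: Bernoulli polynomial coefficients (highest power first) for supported orders.
_BERNOULLI = {
    1: np.array([1.0, -0.5]),
    2: np.array([1.0, -1.0, 1.0 / 6.0]),
    4: np.array([1.0, -2.0, 1.0, 0.0, -1.0 / 30.0]),
    6: np.array([1.0, -3.0, 2.5, 0.0, -0.5, 0.0, 1.0 / 42.0]),
}

_FACTORIAL = {1: 1.0, 2: 2.0, 4: 24.0, 6: 720.0}

#: Supported spline orders m (kernel uses k_{2m}).
SUPPORTED_ORDERS = (1, 2, 3)


class UnsupportedOrderError(ValueError):
    """Requested Bernoulli order is not one of the closed forms we carry."""


class InvalidDesignError(ValueError):
    """The observation design cannot support the parallelism model."""


def scaled_bernoulli(r: int, x):
    """Scaled Bernoulli polynomial k_r(x) = B_r(frac(x)) / r!.

    The argument is reduced to [0,1) (the kernels live on the circle), so the
    function is periodic with period 1.  Supported orders: 1, 2, 4, 6.
    """
    if r not in _BERNOULLI:
        raise UnsupportedOrderError(
            f"scaled Bernoulli polynomial of order {r} not available; "
            f"supported orders: {sorted(_BERNOULLI)}"
        )
    x = np.asarray(x, dtype=float)
    x = x - np.floor(x)
    return np.polyval(_BERNOULLI[r], x) / _FACTORIAL[r]


def k1_continuous(x, z, m: int = 2):
    """Contrast kernel of the continuous margin: (-1)^(m-1) k_{2m}(z - x).

    Symmetric, positive semi-definite, integrates to zero in each argument;
    its eigenvalues decay like i^(-2m).
    """
    if m not in SUPPORTED_ORDERS:
        raise UnsupportedOrderError(
            f"spline order m={m} not supported; choose one of {SUPPORTED_ORDERS}"
        )
    return (-1.0) ** (m - 1) * scaled_bernoulli(2 * m, np.asarray(z, float) - np.asarray(x, float))


def group_kernel(x2, z2, component: int):
    """Marginal kernels of the binary group variable.

    component 0 (mean part): constant 1/2.
    component 1 (contrast part): 1(x2 == z2) - 1/2, i.e. +1/2 within a group
    and -1/2 across groups.
    """
    x2 = np.asarray(x2)
    z2 = np.asarray(z2)
    if component == 0:
        return np.broadcast_to(np.array(0.5), np.broadcast_shapes(x2.shape, z2.shape)).copy()
    if component == 1:
        return np.where(x2 == z2, 0.5, -0.5)
    raise ValueError("component must be 0 or 1")


@dataclass(frozen=True)
class DesignPoints:
    """Observed curves: shared positions, one response column per subject.

    positions : (n,) array in [0,1], shared by all subjects.
    subject_groups : (s,) array of 0/1 group labels, one per subject.
    responses : (n, s) array, column j = subject j's curve.

    The flattened observation vector follows subject-major order
    (index i + n*(j-1)), matching ``responses.ravel(order='F')``.
    """

    positions: np.ndarray
    subject_groups: np.ndarray
    responses: np.ndarray

    def __post_init__(self):
        pos = np.atleast_1d(np.asarray(self.positions, dtype=float))
        grp = np.atleast_1d(np.asarray(self.subject_groups))
        resp = np.asarray(self.responses, dtype=float)
        if resp.ndim != 2 or resp.shape != (pos.size, grp.size):
            raise InvalidDesignError(
                f"responses must be (n positions x s subjects) = {(pos.size, grp.size)}, "
                f"got {resp.shape}; incomplete grids are rejected"
            )
        if pos.size < 2:
            raise InvalidDesignError("need at least two positions")
        if np.any(pos < 0.0) or np.any(pos > 1.0):
            raise InvalidDesignError("positions must lie in [0,1]; rescale upstream")
        if not np.all(np.isin(grp, (0, 1))):
            raise InvalidDesignError(f"group labels must be 0/1, got {np.unique(grp)}")
        if grp.size < 2 or not (np.any(grp == 0) and np.any(grp == 1)):
            raise InvalidDesignError("each group needs at least one subject (s >= 2)")
        if not np.all(np.isfinite(resp)):
            raise InvalidDesignError("responses must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "subject_groups", grp.astype(int))
        object.__setattr__(self, "responses", resp)

    @property
    def n(self) -> int:
        return self.positions.size

    @property
    def s(self) -> int:
        return self.subject_groups.size

    @property
    def total_obs(self) -> int:
        return self.n * self.s

    @property
    def y(self) -> np.ndarray:
        """Flattened responses, subject-major."""
        return self.responses.ravel(order="F")

    @property
    def obs_positions(self) -> np.ndarray:
        return np.tile(self.positions, self.s)

    @property
    def obs_groups(self) -> np.ndarray:
        return np.repeat(self.subject_groups, self.n)

    @property
    def balanced(self) -> bool:
        return int(np.sum(self.subject_groups == 0)) == int(np.sum(self.subject_groups == 1))


@dataclass
class KernelConfig:
    """Kernel and penalty hyper-parameters.

    m : spline order (2 = cubic-spline analogue, the default).
    theta00/theta01 : scales of the two unpenalized one-dimensional blocks,
        fixed at 1.
    theta10/theta11 : scales of the penalized blocks; ``None`` until set by
        trace equalization (``parcurve.ssanova.rescale_thetas``).
    lam : smoothing parameter λ of the penalized least-squares objective.
    """

    m: int = 2
    theta00: float = 1.0
    theta01: float = 1.0
    theta10: float | None = None
    theta11: float | None = None
    lam: float | None = None

    def __post_init__(self):
        if self.m not in SUPPORTED_ORDERS:
            raise UnsupportedOrderError(
                f"spline order m={self.m} not supported; choose one of {SUPPORTED_ORDERS}"
            )
        for name in ("theta00", "theta01", "theta10", "theta11", "lam"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class GramSet:
    """All kernel matrices for one design at one (θ, λ).

    K, Q, K10, K11 carry the 1/(ns) entry scaling of the matrix-form
    objective, so Q == theta10*K10 + theta11*K11 entrywise.  M and the
    interaction evaluation matrix K11_raw = ns*K11 are on the raw kernel
    scale: M = theta10*ns*K10 + theta11*ns*K11 + ns*lam*I.
    """

    K: np.ndarray
    Q: np.ndarray
    K10: np.ndarray
    K11: np.ndarray
    S: np.ndarray
    M: np.ndarray
    lam: float
    theta10: float
    theta11: float
    ns: int
    jitter: float = field(default=0.0)

    @property
    def K11_raw(self) -> np.ndarray:
        return self.ns * self.K11


def _component_matrices(points: DesignPoints, m: int):
    """Raw (unscaled) component kernel matrices over the ns observations."""
    x = points.obs_positions
    g = points.obs_groups
    k1 = k1_continuous(x[:, None], x[None, :], m)
    k1 = 0.5 * (k1 + k1.T)  # exact symmetry despite the periodic wrap
    geq = group_kernel(g[:, None], g[None, :], 1)  # +-1/2
    K00 = np.full((points.total_obs,) * 2, 0.5)
    K01 = geq.copy()
    K10 = 0.5 * k1
    K11 = 0.5 * geq * k1
    return K00, K01, K10, K11


def assemble_grams(points: DesignPoints, config: KernelConfig) -> GramSet:
    """Assemble the composite kernel, penalty and design matrices.

    Requires ``config.theta10``, ``config.theta11`` and ``config.lam`` to be
    set.  ``S`` spans the unpenalized subspace: an intercept column and the
    centered group contrast (group - 1/2).
    """
    if config.theta10 is None or config.theta11 is None:
        raise ValueError("theta10/theta11 unset; call rescale_thetas first")
    if config.lam is None:
        raise ValueError("lam unset")
    ns = points.total_obs
    K00r, K01r, K10r, K11r = _component_matrices(points, config.m)

    K = (config.theta00 * K00r + config.theta01 * K01r
         + config.theta10 * K10r + config.theta11 * K11r) / ns
    K10 = K10r / ns
    K11 = K11r / ns
    Q = config.theta10 * K10 + config.theta11 * K11

    contrast = points.obs_groups - 0.5
    S = np.column_stack([np.ones(ns), contrast])
    if np.linalg.matrix_rank(S) < 2:
        raise InvalidDesignError("all subjects in one group: contrast column degenerate")

    M = config.theta10 * K10r + config.theta11 * K11r + ns * config.lam * np.eye(ns)
    jitter = 1e-10 * np.trace(M) / ns
    M[np.diag_indices_from(M)] += jitter

    return GramSet(K=K, Q=Q, K10=K10, K11=K11, S=S, M=M, lam=config.lam,
                   theta10=config.theta10, theta11=config.theta11, ns=ns,
                   jitter=jitter)


def rescale_positions(raw: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine min-max rescale of positions to [0,1]; returns (scaled, (lo, hi))."""
    raw = np.asarray(raw, dtype=float)
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        raise InvalidDesignError("positions are all identical; cannot rescale")
    return (raw - lo) / (hi - lo), (lo, hi)
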