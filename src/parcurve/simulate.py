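"""Synthetic curve-pair generators (Settings 1-7) and the power/size runner.

The seven settings share the base curve 2.5 sin(3πx)(1-x) for the control
group and perturb the case group in different ways:

  1  constant magnitude difference      (2.5+δ1) sin(3πx)(1-x)
  2  frequency difference               2.5 sin((3+δ2)πx)(1-x)
  3  magnitude and frequency            (2.5+δ1) sin((3+δ2)πx)(1-x)
  4  non-constant magnitude             2.5 sin(3πx)(1-x)^(1+δ3)
  5  pure parallel shift (null)         control + δ4·1{case}
  6  as Setting 1, evenly spaced x, AR(1) noise (ρ^|i-i'|) per subject
  7  non-smooth truth with a change point at x = 0.5:
     2.5 sin(2πx)·1{x<0.5} + (1+δ5·1{case})(x-1)·1{x>=0.5}

Positions are iid U(0,1) for Settings 1-5 and evenly spaced (midpoints
(i-1/2)/n) for Settings 6-7; all subjects share the same positions, as in
the observation model Y_ij = f(x_i, g_j) + ε_ij.  Noise is iid N(0, σ²)
(σ = 1 by default) except Setting 6's AR(1).  Each group contains
``subjects_per_group`` independent curves (2 by default — the configuration
under which the published operating characteristics reproduce; see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import DesignPoints
from .waldtest import parallelism_test

__all__ = ["SimulationSetting", "truth_function", "generate", "empirical_power"]

#: settings whose positions are evenly spaced rather than iid uniform
_EVEN_SETTINGS = (6, 7)


@dataclass
class SimulationSetting:
    """One simulation configuration.

    n : positions per curve; delta1..delta5 : nonparallelism knobs (see module
    docstring); rho : AR(1) coefficient (Setting 6 only); sigma : noise sd;
    subjects_per_group : curves per group (total s = 2x that); seed : base
    seed, replicate r uses seed + r.
    """

    setting_id: int
    n: int = 100
    delta1: float = 0.0
    delta2: float = 0.0
    delta3: float = 0.0
    delta4: float = 0.0
    delta5: float = 0.0
    rho: float = 0.5
    sigma: float = 1.0
    subjects_per_group: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.setting_id not in range(1, 8):
            raise ValueError(f"unknown setting id {self.setting_id}")
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.subjects_per_group < 1:
            raise ValueError("subjects_per_group must be >= 1")

    @property
    def design(self) -> str:
        return "uniform" if self.setting_id in _EVEN_SETTINGS else "quasi_uniform"


def truth_function(x, group: int, setting: SimulationSetting):
    """Mean function f(x, group) of the given setting, evaluated exactly."""
    x = np.asarray(x, dtype=float)
    sid = setting.setting_id
    if sid in (1, 2, 3, 4, 6):
        if group == 0:
            return 2.5 * np.sin(3 * np.pi * x) * (1 - x)
        d1 = setting.delta1
        d2 = setting.delta2 if sid in (2, 3) else 0.0
        d3 = setting.delta3 if sid == 4 else 0.0
        return (2.5 + d1) * np.sin((3 + d2) * np.pi * x) * (1 - x) ** (1 + d3)
    if sid == 5:
        base = 2.5 * np.sin(3 * np.pi * x) * (1 - x)
        return base + (setting.delta4 if group == 1 else 0.0)
    if sid == 7:
        left = 2.5 * np.sin(2 * np.pi * x) * (x < 0.5)
        slope = 1.0 + (setting.delta5 if group == 1 else 0.0)
        return left + slope * (x - 1.0) * (x >= 0.5)
    raise ValueError(f"unknown setting id {sid}")


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) vector with marginal variance sigma^2 and corr rho^|lag|."""
    e = np.empty(n)
    z = rng.standard_normal(n)
    e[0] = z[0]
    c = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + c * z[i]
    return sigma * e


def generate(setting: SimulationSetting, rng: np.random.Generator | None = None) -> DesignPoints:
    """Draw one data set for the setting; reproducible from ``setting.seed``."""
    if rng is None:
        rng = np.random.default_rng(setting.seed)
    n = setting.n
    if setting.setting_id in _EVEN_SETTINGS:
        x = (np.arange(n) + 0.5) / n
    else:
        x = rng.uniform(0.0, 1.0, n)
    spg = setting.subjects_per_group
    groups = np.repeat([0, 1], spg)
    Y = np.column_stack([truth_function(x, g, setting) for g in groups])
    if setting.setting_id == 6:
        for j in range(groups.size):
            Y[:, j] += _ar1_noise(rng, n, setting.rho, setting.sigma)
    else:
        Y += rng.normal(0.0, setting.sigma, size=Y.shape)
    return DesignPoints(positions=x, subject_groups=groups, responses=Y)


def empirical_power(
    setting: SimulationSetting,
    reps: int = 200,
    alpha: float = 0.05,
    method: str = "wald",
    m: int = 2,
    permutations: int = 500,
) -> tuple[float, float]:
    """Monte-Carlo rejection rate and its standard error.

    Replicate r uses seed ``setting.seed + r`` (new positions and noise each
    time).  ``method`` is 'wald' (asymptotic calibration) or 'permutation'.
    Any replicate failure propagates with context — no silent skipping.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if method not in ("wald", "permutation"):
        raise ValueError("method must be 'wald' or 'permutation'")
    rejections = 0
    for r in range(reps):
        rng = np.random.default_rng(setting.seed + r)
        try:
            points = generate(setting, rng)
            if method == "wald":
                rejections += parallelism_test(points, alpha=alpha, m=m).reject
            else:
                from .permutation import permutation_test

                _, rej, _ = permutation_test(
                    points, B=permutations, seed=setting.seed + r, alpha=alpha, m=m
                )
                rejections += rej
        except Exception as e:
            raise RuntimeError(
                f"replicate {r} (seed {setting.seed + r}) of setting "
                f"{setting.setting_id} failed: {e}"
            ) from e
    phat = rejections / reps
    return phat, float(np.sqrt(phat * (1.0 - phat) / reps))
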