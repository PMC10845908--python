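"""Gaussian kernel and bandwidth selectors for the local smoother.

Five ways of fixing the kernel bandwidth h are supported, matching the
selector families customarily used with kernel smoothing of a univariate
sample:

* ``fixed``  — a user-supplied constant h;
* ``dpi1``   — two-stage direct plug-in (normal-scale psi_6 -> pilot g_4 ->
  kernel estimate of psi_4 -> AMISE-optimal h);
* ``dpi2``   — one-stage direct plug-in (normal-scale psi_4 plugged straight
  into the AMISE formula, i.e. the normal-reference rule);
* ``bcv``    — biased cross-validation (Scott & Terrell);
* ``ucv``    — unbiased (least-squares) cross-validation.

All selectors are density-type rules applied to the auxiliary x sample only
(they never see y), return strictly positive finite h, and are
scale-equivariant: selector(a*x) = a*selector(x) for a > 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "BandwidthSpec",
    "gaussian_kernel",
    "scaled_kernel",
    "bw_normal_scale",
    "bw_dpi",
    "bw_ucv",
    "bw_bcv",
    "ucv_score",
    "bcv_score",
    "select_bandwidth",
    "default_cv_grid",
]

logger = logging.getLogger(__name__)

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_RK = 1.0 / (2.0 * math.sqrt(math.pi))  # roughness R(K) of the Gaussian kernel


def gaussian_kernel(u):
    """Standard Gaussian kernel K(u) = (2*pi)^(-1/2) exp(-u^2/2)."""
    u = np.asarray(u, dtype=float)
    out = np.exp(-0.5 * u * u) / _SQRT_2PI
    return float(out) if out.ndim == 0 else out


def scaled_kernel(u, h: float):
    """Rescaled kernel K_h(u) = h^-1 K(u/h); integrates to 1 for any h > 0."""
    if h <= 0:
        raise ValueError(f"bandwidth must be positive, got {h}")
    u = np.asarray(u, dtype=float)
    out = gaussian_kernel(u / h) / h
    return float(out) if np.ndim(out) == 0 else out


def _sigma_hat(x: np.ndarray) -> float:
    """Robust scale: min(sample SD, IQR/1.349).  Errors on zero spread."""
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr_scale = (q75 - q25) / 1.349
    sigma = min(sd, iqr_scale) if iqr_scale > 0 else sd
    if not (sigma > 0 and np.isfinite(sigma)):
        raise ValueError("input vector has zero spread; cannot select a bandwidth")
    return sigma


def bw_normal_scale(x) -> float:
    """Normal-scale pilot bandwidth h0 = (4/(3n))^(1/5) * sigma_hat."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return (4.0 / (3.0 * x.size)) ** 0.2 * _sigma_hat(x)


# ---------------------------------------------------------------------------
# Direct plug-in machinery: Gaussian density-derivative functionals psi_r.

def _phi_deriv(r: int, u: np.ndarray) -> np.ndarray:
    """r-th derivative of the standard normal density, r in {4, 6}."""
    phi = np.exp(-0.5 * u * u) / _SQRT_2PI
    if r == 4:
        return (u**4 - 6.0 * u**2 + 3.0) * phi
    if r == 6:
        return (u**6 - 15.0 * u**4 + 45.0 * u**2 - 15.0) * phi
    raise ValueError(f"unsupported derivative order {r}")


def _psi_normal_scale(r: int, sigma: float) -> float:
    """psi_r under a N(0, sigma^2) reference density."""
    half = r // 2
    return (
        (-1) ** half
        * math.factorial(r)
        / ((2.0 * sigma) ** (r + 1) * math.factorial(half) * math.sqrt(math.pi))
    )


def _psi_hat(x: np.ndarray, r: int, g: float) -> float:
    """Kernel estimator psi_hat_r(g) = n^-2 sum_ij phi_g^(r)(x_i - x_j)."""
    d = (x[:, None] - x[None, :]) / g
    return float(np.sum(_phi_deriv(r, d))) / (x.size**2 * g ** (r + 1))


def bw_dpi(x, stages: int = 2) -> float:
    """Direct plug-in bandwidth for a Gaussian kernel.

    ``stages=2``: estimate psi_6 by its normal-scale value, derive the pilot
    g_4 = [-2 phi^(4)(0) / (psi_6 n)]^(1/7), estimate psi_4 with that pilot,
    and plug into h = [R(K) / (psi_4 n)]^(1/5) (second kernel moment
    mu_2(K) = 1 for the Gaussian).  ``stages=1``: plug the normal-scale psi_4
    in directly, which collapses to the normal-reference rule
    (4/(3n))^(1/5) sigma_hat.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations for plug-in selection")
    sigma = _sigma_hat(x)
    n = x.size
    if stages == 1:
        psi4 = _psi_normal_scale(4, sigma)
    elif stages == 2:
        psi6 = _psi_normal_scale(6, sigma)
        g4 = (-2.0 * _phi_deriv(4, np.array(0.0)) / (psi6 * n)) ** (1.0 / 7.0)
        psi4 = _psi_hat(x, 4, float(g4))
    else:
        raise ValueError("stages must be 1 or 2")
    if psi4 <= 0 or not np.isfinite(psi4):
        logger.warning("non-positive psi_4 estimate; falling back to normal-scale rule")
        return bw_normal_scale(x)
    return (_RK / (psi4 * n)) ** 0.2


# ---------------------------------------------------------------------------
# Cross-validation selectors.

def default_cv_grid(x) -> np.ndarray:
    """50 log-spaced candidates in [0.05*sigma_hat*n^(-1/5), 3*sigma_hat]."""
    x = np.asarray(x, dtype=float)
    sigma = _sigma_hat(x)
    lo = 0.05 * sigma * x.size ** (-0.2)
    return np.geomspace(lo, 3.0 * sigma, 50)


def _kk(d: np.ndarray) -> np.ndarray:
    """Kernel self-convolution (K*K): the N(0, 2) density."""
    return np.exp(-0.25 * d * d) / (2.0 * math.sqrt(math.pi))


def _grid_refine(score, grid: np.ndarray, interior_only: bool) -> float:
    vals = np.array([score(h) for h in grid])
    k = int(np.argmin(vals))  # ties -> smallest h (grid is increasing)
    if k == 0 or k == grid.size - 1:
        warnings.warn(
            "cross-validation minimizer on grid boundary; result may be unreliable",
            RuntimeWarning,
        )
        if interior_only:
            k = min(max(k, 1), grid.size - 2)
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if hi <= lo:
        return float(grid[k])
    res = minimize_scalar(score, bounds=(lo, hi), method="bounded")
    return float(res.x) if res.fun <= score(grid[k]) else float(grid[k])


def _prep_cv(x, grid):
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations for cross-validation")
    if np.all(x == x[0]):
        raise ValueError("all observations equal; cannot cross-validate")
    grid = default_cv_grid(x) if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty bandwidth grid")
    if np.any(grid <= 0) or (grid.size > 1 and np.any(np.diff(grid) <= 0)):
        raise ValueError("grid must be strictly positive and increasing")
    iu = np.triu_indices(x.size, k=1)
    diffs = (x[:, None] - x[None, :])[iu]
    return x, grid, diffs


def _make_ucv_score(diffs: np.ndarray, n: int):
    def score(h):
        # off-diagonal sum = 2 * sum over unordered pairs
        d = diffs / h
        s = 2.0 * np.sum(_kk(d) - 2.0 * np.exp(-0.5 * d * d) / _SQRT_2PI)
        return _RK / (n * h) + s / (n * n * h)

    return score


def _make_bcv_score(diffs: np.ndarray, n: int):
    def score(h):
        d2 = (diffs / h) ** 2
        s = 2.0 * np.sum((d2 * d2 - 12.0 * d2 + 12.0) * np.exp(-0.25 * d2))
        return _RK / (n * h) + s / (128.0 * n * n * h * math.sqrt(math.pi))

    return score


def ucv_score(x, h: float) -> float:
    """Evaluate the UCV objective at one bandwidth (see :func:`bw_ucv`)."""
    x = np.asarray(x, dtype=float)
    iu = np.triu_indices(x.size, k=1)
    return _make_ucv_score((x[:, None] - x[None, :])[iu], x.size)(h)


def bcv_score(x, h: float) -> float:
    """Evaluate the BCV objective at one bandwidth (see :func:`bw_bcv`)."""
    x = np.asarray(x, dtype=float)
    iu = np.triu_indices(x.size, k=1)
    return _make_bcv_score((x[:, None] - x[None, :])[iu], x.size)(h)


def bw_ucv(x, grid=None) -> float:
    """Unbiased (least-squares) cross-validation bandwidth.

    Minimizes UCV(h) = R(K)/(nh) + (1/(n^2 h)) sum_{i != j}
    [(K*K)(d_ij) - 2 K(d_ij)], d_ij = (x_i - x_j)/h, by grid search followed
    by bounded scalar refinement around the grid minimizer; ties on the grid
    resolve to the smallest h.
    """
    x, grid, diffs = _prep_cv(x, grid)
    return _grid_refine(_make_ucv_score(diffs, x.size), grid, interior_only=False)


def bw_bcv(x, grid=None) -> float:
    """Biased cross-validation bandwidth (Scott-Terrell, Gaussian kernel).

    Minimizes BCV(h) = R(K)/(nh) + (1/(128 n^2 h sqrt(pi))) sum_{i != j}
    (d^4 - 12 d^2 + 12) exp(-d^2/4), d = (x_i - x_j)/h — the diagonal-removed
    plug-in of the estimated density curvature into the AMISE expansion.
    The minimizer is kept off the grid boundary (with a warning), since the
    BCV score decreases without bound as h grows past the oversmoothed range.
    """
    x, grid, diffs = _prep_cv(x, grid)
    return _grid_refine(_make_bcv_score(diffs, x.size), grid, interior_only=True)


# ---------------------------------------------------------------------------
# Selector specification used across the package.

_METHODS = ("fixed", "dpi1", "dpi2", "bcv", "ucv")


@dataclass
class BandwidthSpec:
    """How the smoothing bandwidth is chosen.

    method : one of fixed | dpi1 | dpi2 | bcv | ucv
        dpi1 is the two-stage direct plug-in, dpi2 the one-stage variant.
    value : required positive bandwidth when method == "fixed".
    grid : optional strictly-increasing positive CV search grid.
    per_bound : select h independently for the lower and upper streams
        (parallel-stream contract); with a fixed h the flag is moot.
    use_population : select h from the full population x rather than the
        sampled x (sample is the default, matching the survey setting).
    """

    method: str = "fixed"
    value: Optional[float] = None
    grid: Optional[np.ndarray] = field(default=None, repr=False)
    per_bound: bool = True
    use_population: bool = False

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown bandwidth method {self.method!r}")
        if self.method == "fixed":
            if self.value is None or self.value <= 0:
                raise ValueError("fixed bandwidth requires value > 0")
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if np.any(g <= 0) or (g.size > 1 and np.any(np.diff(g) <= 0)):
                raise ValueError("grid must be strictly positive and increasing")
            self.grid = g


def select_bandwidth(spec: BandwidthSpec, x) -> float:
    """Resolve a :class:`BandwidthSpec` to a concrete h for one data stream."""
    if spec.method == "fixed":
        return float(spec.value)
    if spec.method == "dpi1":
        return bw_dpi(x, stages=2)
    if spec.method == "dpi2":
        return bw_dpi(x, stages=1)
    if spec.method == "bcv":
        return bw_bcv(x, spec.grid)
    if spec.method == "ucv":
        return bw_ucv(x, spec.grid)
    raise ValueError(f"unknown bandwidth method {spec.method!r}")
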