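"""Local polynomial kernel regression for predicting non-sampled units.

The smoother fits, at each prediction point x0, a weighted least-squares
polynomial of degree p with Gaussian kernel weights K_h(x_i - x0) and
returns its intercept (the design matrix is centered at x0, so the intercept
*is* the fitted value).  It is a linear smoother: the fit equals w' y for a
weight vector w that depends only on the x's, the degree and the bandwidth,
and the weights sum to one because constants are reproduced exactly.
Degree p = 1 (local linear) is the package default and additionally
reproduces any affine trend exactly.

Numerical policy for degenerate configurations:

* the pointwise path solves through a QR factorization of the sqrt-kernel
  scaled design (no explicit stabilizer needed; an exactly singular design
  degrades the degree by one and retries); the vectorized batch path uses
  the degree-1 closed form with a relative ridge
  cfg.ridge * mean(diag(X'WX)) * I, and both renormalize the weights to sum
  exactly to one;
* if every kernel weight underflows (total weight below
  cfg.underflow_guard), the fit falls back to the nearest sample point's
  value; occurrences are counted so simulations can report them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bandwidth import BandwidthSpec, select_bandwidth
from .core import NeutroArray

__all__ = [
    "LocalFitConfig",
    "local_poly_fit",
    "smoother_weights",
    "smoother_weight_matrix",
    "predict_nonsampled",
]

logger = logging.getLogger(__name__)

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class LocalFitConfig:
    """Configuration of one local polynomial fit.

    degree : polynomial degree p >= 0 (1 = local linear, the default).
    bandwidth : kernel scale h > 0 (ignored when a selector chooses h).
    underflow_guard : total-kernel-weight threshold below which the fit
        falls back to the nearest sample value.
    ridge : relative diagonal stabilizer factor for X'WX.
    """

    degree: int = 1
    bandwidth: float = 1.0
    underflow_guard: float = 1e-300
    ridge: float = 1e-10

    def __post_init__(self):
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def _weights_single(xs: np.ndarray, x0: float, p: int, h: float, ridge: float,
                    guard: float) -> tuple[np.ndarray, bool]:
    """Smoother weight vector at one point; returns (w, degenerate_flag).

    Solved through a QR factorization of the sqrt-kernel-scaled design,
    which keeps extreme weight ratios (far extrapolation, tiny h) exact
    where normal equations would lose them to cancellation.  On an exactly
    singular local design the degree is degraded and the fit retried.
    """
    d = xs - x0
    k = np.exp(-0.5 * (d / h) ** 2) / (h * _SQRT_2PI)
    total = k.sum()
    if not (total > guard):
        # all weights underflow: nearest-neighbor fallback
        w = np.zeros_like(xs)
        w[np.argmin(np.abs(d))] = 1.0
        return w, True
    b = np.sqrt(k)
    while p > 0:
        X = np.vander(d, p + 1, increasing=True)  # columns (x_i - x0)^k
        if xs.size == p + 1:
            # square system: the weighted fit interpolates and the kernel
            # weights cancel exactly; solve the Vandermonde system directly
            try:
                w = np.linalg.solve(X.T, np.eye(p + 1)[0])
            except np.linalg.LinAlgError:
                p -= 1
                continue
            if np.all(np.isfinite(w)) and w.sum() > 0:
                return w / w.sum(), False
            p -= 1
            continue
        B = b[:, None] * X
        try:
            Q, R = np.linalg.qr(B)
            # w' = e_1' R^{-1} Q' diag(sqrt k): the linear-smoother covector
            w = np.linalg.solve(R, Q.T * b)[0]
        except np.linalg.LinAlgError:
            p -= 1
            continue
        ws = w.sum()
        if np.all(np.isfinite(w)) and ws > 0:
            return w / ws, False
        p -= 1
    return k / total, False


def smoother_weights(xs, x0: float, cfg: LocalFitConfig) -> np.ndarray:
    """Linear-smoother weights w with local_poly_fit(xs, ys, x0) = w' ys.

    The weights sum to 1 (local polynomials reproduce constants).
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size < 1:
        raise ValueError("need at least one sample point")
    w, degen = _weights_single(
        xs, float(x0), cfg.degree, cfg.bandwidth, cfg.ridge, cfg.underflow_guard
    )
    if degen:
        logger.warning("kernel weights underflowed at x0=%g; nearest-neighbor fallback", x0)
    return w


def local_poly_fit(xs, ys, x0: float, cfg: LocalFitConfig) -> float:
    """Local polynomial estimate m_hat(x0) of the regression function."""
    ys = np.asarray(ys, dtype=float)
    return float(smoother_weights(xs, x0, cfg) @ ys)


def smoother_weight_matrix(xs, x0s, cfg: LocalFitConfig):
    """Weight matrix W (m x n) with row j the smoother weights at x0s[j].

    For degree 1 the rows are computed in closed form from the kernel moment
    sums S_k = sum_i K_i (x_i - x0)^k, with the relative ridge
    r = cfg.ridge * (S_0 + S_2)/2:

        w_i = K_i * ((S_2 + r) - (x_i - x0) S_1) / ((S_0 + r)(S_2 + r) - S_1^2)

    which is exactly e_1'(X'WX + rI)^{-1} X'W for the centered design, so the
    vectorized path agrees with :func:`smoother_weights` to rounding error.
    Rows are renormalized to sum exactly to one, removing the ridge's
    perturbation of the constant-reproduction property.
    Returns ``(W, n_degenerate)`` where the count covers underflow fallbacks
    and rows degraded to degree 0.
    """
    xs = np.asarray(xs, dtype=float)
    x0s = np.asarray(x0s, dtype=float)
    h, r, guard = cfg.bandwidth, cfg.ridge, cfg.underflow_guard
    if cfg.degree != 1:
        rows = []
        n_degen = 0
        for x0 in x0s:
            w, degen = _weights_single(xs, float(x0), cfg.degree, h, r, guard)
            n_degen += degen
            rows.append(w)
        return np.array(rows), n_degen

    D = xs[None, :] - x0s[:, None]
    K = np.exp(-0.5 * (D / h) ** 2) / (h * _SQRT_2PI)
    S0 = K.sum(axis=1)
    KD = K * D
    S1 = KD.sum(axis=1)
    S2 = (KD * D).sum(axis=1)
    reff = r * (S0 + S2) / 2.0  # same relative ridge as the pointwise path
    det = (S0 + reff) * (S2 + reff) - S1 * S1
    ok = S0 > guard
    safe_det = np.where(det > 0, det, 1.0)
    W = K * ((S2 + reff)[:, None] - D * S1[:, None]) / safe_det[:, None]
    rowsum = W.sum(axis=1)
    renorm = (rowsum > 0) & np.isfinite(rowsum)
    W[renorm] /= rowsum[renorm, None]
    # degree-0 fallback where the local-linear system is singular
    bad_det = ok & (~(det > 0) | ~renorm)
    if np.any(bad_det):
        W[bad_det] = K[bad_det] / S0[bad_det, None]
    # nearest-neighbor fallback where every weight underflowed
    n_under = int(np.count_nonzero(~ok))
    if n_under:
        idx = np.argmin(np.abs(D[~ok]), axis=1)
        W[~ok] = 0.0
        W[np.flatnonzero(~ok), idx] = 1.0
        logger.warning("%d prediction points with underflowed kernel weights", n_under)
    return W, n_under + int(np.count_nonzero(bad_det))


def predict_nonsampled(pop, sample, bw: BandwidthSpec, cfg: LocalFitConfig) -> NeutroArray:
    """Predict y at every non-sampled unit, per bound stream independently.

    For each stream, the bandwidth is resolved by ``bw`` (from the sampled x
    by default) and m_hat(x_j) is computed for every j outside the sample,
    ordered by increasing population index.
    """
    preds, _ = predict_nonsampled_counted(pop, sample, bw, cfg)
    return preds


def predict_nonsampled_counted(pop, sample, bw: BandwidthSpec,
                               cfg: LocalFitConfig) -> tuple[NeutroArray, int]:
    """As :func:`predict_nonsampled`, also returning the degenerate-fit count."""
    idx = sample.indices
    N = len(pop.x)
    if not (1 <= idx.size < N):
        raise ValueError("need 1 <= n < N to predict non-sampled units")
    mask = np.zeros(N, dtype=bool)
    mask[idx] = True
    out_idx = np.flatnonzero(~mask)  # increasing population index

    streams = []
    n_degen = 0
    h_shared = None
    for stream in ("lower", "upper"):
        xs = pop.x.stream(stream)[idx]
        ys = pop.y.stream(stream)[idx]
        if h_shared is not None:
            h = h_shared
        else:
            x_src = pop.x.stream(stream) if bw.use_population else xs
            h = select_bandwidth(bw, x_src)
            if not bw.per_bound:
                h_shared = h  # reuse the lower-stream h for the upper stream
        scfg = LocalFitConfig(cfg.degree, h, cfg.underflow_guard, cfg.ridge)
        W, d = smoother_weight_matrix(xs, pop.x.stream(stream)[out_idx], scfg)
        n_degen += d
        streams.append(W @ ys)
    return NeutroArray(streams[0], streams[1]), n_degen
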