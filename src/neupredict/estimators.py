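"""Finite-population mean estimators for interval-valued survey data.

The mean of a finite population decomposes exactly as

    Ybar = f * ybar_s + (1 - f) * ybar_sbar,        f = n / N,

where ybar_s is the observed sample mean and ybar_sbar the mean of the
non-sampled units.  The model-based predictive estimator keeps the first
term and replaces the unknown second term with the mean of local polynomial
kernel predictions m_hat(x_j) at the non-sampled auxiliary values (x must
be known for every unit).  Because the smoother is linear in y, the
estimator can equivalently be written as sum_i omega_i y_i over the sample,
with

    omega_i = (1/N) * (1 + sum_{j not in s} w_j[i]),   sum_i omega_i = 1,

weights that depend on how many non-sampled units lie near each sampled x —
and never on design inclusion probabilities (inference is conditional on
the realized sample, the model-based stance).

Two classical comparators are provided, each per bound stream:

* ratio:      ybar_s * Xbar / xbar_s            (exact when y = c x)
* regression: ybar_s + b_hat (Xbar - xbar_s)    (exact when y affine in x)

with Xbar the known full-population mean of x and b_hat the within-sample
OLS slope.  Every estimator is computed independently on the lower and
upper streams and returned as an interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .bandwidth import BandwidthSpec, select_bandwidth
from .core import NeutroScalar
from .populations import NeutroPopulation
from .smoothing import LocalFitConfig, smoother_weight_matrix

__all__ = [
    "EstimateInterval",
    "ybar_mb",
    "mb_weights",
    "ybar_ratio",
    "ybar_reg",
    "ESTIMATORS",
]


@dataclass
class EstimateInterval:
    """An interval point estimate of the population mean plus provenance."""

    value: NeutroScalar
    estimator_name: str
    n: int
    f: float
    bandwidth_used: Optional[NeutroScalar] = None

    def __post_init__(self):
        if not (0.0 < self.f <= 1.0):
            raise ValueError("sampling fraction f must be in (0, 1]")


def _stream_data(pop: NeutroPopulation, sample, stream: str):
    idx = sample.indices
    x = pop.x.stream(stream)
    y = pop.y.stream(stream)
    return x, y, x[idx], y[idx]


def _mb_streams(pop: NeutroPopulation, sample, bw: BandwidthSpec,
                cfg: LocalFitConfig) -> tuple[list[float], list[float], int]:
    """Per-stream model-based estimates, bandwidths used, degenerate count."""
    idx = sample.indices
    n, N = idx.size, pop.N
    f = n / N
    if n == N:
        vals = [float(np.mean(pop.y.stream(s)[idx])) for s in ("lower", "upper")]
        return vals, [float("nan")] * 2, 0
    mask = np.zeros(N, dtype=bool)
    mask[idx] = True
    out_idx = np.flatnonzero(~mask)
    vals, hs, n_degen = [], [], 0
    h_shared = None
    for stream in ("lower", "upper"):
        x = pop.x.stream(stream)
        xs, ys = x[idx], pop.y.stream(stream)[idx]
        if h_shared is not None:
            h = h_shared
        else:
            x_src = x if bw.use_population else xs
            h = select_bandwidth(bw, x_src)
            if not bw.per_bound:
                h_shared = h
        scfg = LocalFitConfig(cfg.degree, h, cfg.underflow_guard, cfg.ridge)
        W, d = smoother_weight_matrix(xs, x[out_idx], scfg)
        n_degen += d
        mhat = W @ ys
        vals.append(f * float(np.mean(ys)) + (1.0 - f) * float(np.mean(mhat)))
        hs.append(h)
    return vals, hs, n_degen


def ybar_mb(
    pop: NeutroPopulation,
    sample,
    bw: BandwidthSpec,
    cfg: LocalFitConfig | None = None,
) -> EstimateInterval:
    """Model-based predictive estimator f*ybar_s + (1-f)*mean(m_hat)."""
    cfg = cfg or LocalFitConfig()
    if sample.n < 1:
        raise ValueError("empty sample")
    vals, hs, _ = _mb_streams(pop, sample, bw, cfg)
    return EstimateInterval(
        NeutroScalar(vals[0], vals[1]), "mb", sample.n, sample.n / pop.N,
        bandwidth_used=NeutroScalar(hs[0], hs[1]),
    )


def mb_weights(
    pop: NeutroPopulation,
    sample,
    bw: BandwidthSpec,
    cfg: LocalFitConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample weights (omega_lower, omega_upper) with ybar_mb = omega' y_s.

    omega_i = (1/N)(1 + sum_{j not in s} w_j[i]); each stream's weights sum
    to 1 exactly because every smoother-weight row sums to 1.
    """
    cfg = cfg or LocalFitConfig()
    idx = sample.indices
    N = pop.N
    n = idx.size
    if n == N:
        w = np.full(n, 1.0 / N)
        return w, w.copy()
    mask = np.zeros(N, dtype=bool)
    mask[idx] = True
    out_idx = np.flatnonzero(~mask)
    out = []
    for stream in ("lower", "upper"):
        x = pop.x.stream(stream)
        xs = x[idx]
        x_src = x if bw.use_population else xs
        h = select_bandwidth(bw, x_src)
        scfg = LocalFitConfig(cfg.degree, h, cfg.underflow_guard, cfg.ridge)
        W, _ = smoother_weight_matrix(xs, x[out_idx], scfg)
        out.append((1.0 + W.sum(axis=0)) / N)
    return out[0], out[1]


def ybar_ratio(pop: NeutroPopulation, sample) -> EstimateInterval:
    """Classical ratio estimator ybar_s * Xbar / xbar_s, per stream."""
    vals = []
    for stream in ("lower", "upper"):
        x, _, xs, ys = _stream_data(pop, sample, stream)
        xbar_s = float(np.mean(xs))
        if xbar_s == 0.0:
            raise ZeroDivisionError("sample mean of x is zero; ratio undefined")
        vals.append(float(np.mean(ys)) * float(np.mean(x)) / xbar_s)
    return EstimateInterval(
        NeutroScalar(vals[0], vals[1]), "ratio", sample.n, sample.n / pop.N
    )


def ybar_reg(pop: NeutroPopulation, sample) -> EstimateInterval:
    """Classical regression estimator ybar_s + b_hat (Xbar - xbar_s)."""
    vals = []
    for stream in ("lower", "upper"):
        x, _, xs, ys = _stream_data(pop, sample, stream)
        xbar_s = float(np.mean(xs))
        dx = xs - xbar_s
        sxx = float(dx @ dx)
        if sxx == 0.0:
            raise ValueError("sample x is constant; regression slope undefined")
        b = float(dx @ (ys - np.mean(ys))) / sxx
        vals.append(float(np.mean(ys)) + b * (float(np.mean(x)) - xbar_s))
    return EstimateInterval(
        NeutroScalar(vals[0], vals[1]), "reg", sample.n, sample.n / pop.N
    )


ESTIMATORS = {"mb": ybar_mb, "ratio": ybar_ratio, "reg": ybar_reg}
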