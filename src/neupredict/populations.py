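"""Simulated interval-valued finite populations.

Three benchmark superpopulation models relate the study variable y to an
auxiliary x drawn uniformly on (0, 1), with additive standard-normal errors:

* Sine :  y = sin(2*pi*x) + e           (smooth, strongly nonlinear)
* Bump :  y = 1 + 2(x - 0.5) + exp(-200 (x - 0.5)^2) + e
          (linear trend with a narrow Gaussian bump at x = 0.5)
* Jump :  y = 1 + 2(x - 0.5) 1{x <= 0.65} + 0.65 1{x > 0.65} + e
          (discontinuous; the boundary x = 0.65 belongs to the left branch)

Each bound stream of the interval data is an *independent* realization of
the same model: x_L, x_U are two independent uniform samples and e_L, e_U
two independent error vectors (no per-unit min/max ordering is applied).
``crisp=True`` shares one realization between the streams, producing
degenerate intervals for classical-statistics regression tests.

A weather-like fixture emulates a year of daily temperatures (Fahrenheit)
in a subtropical-highland city: a sinusoidal seasonal signal peaking in
mid-April plus noise for x (year 1), and a strong linear response y
(year 2) on top of it.  All its parameters are synthetic and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NeutroArray

__all__ = [
    "NeutroPopulation",
    "gen_sine",
    "gen_bump",
    "gen_jump",
    "gen_weather_like",
    "GENERATORS",
]


@dataclass
class NeutroPopulation:
    """A finite population of N units with interval-valued x and y."""

    x: NeutroArray
    y: NeutroArray
    N: int
    name: str = ""
    seed: int | None = None

    def __post_init__(self):
        if len(self.x) != self.N or len(self.y) != self.N:
            raise ValueError("x and y must both have length N")
        if self.N < 2:
            raise ValueError("population needs N >= 2 units")


def _mean_sine(x):
    return np.sin(2.0 * np.pi * x)


def _mean_bump(x):
    return 1.0 + 2.0 * (x - 0.5) + np.exp(-200.0 * (x - 0.5) ** 2)


def _mean_jump(x):
    left = x <= 0.65
    return 1.0 + np.where(left, 2.0 * (x - 0.5), 0.65)


def _gen_uniform_pop(mean_fn, name: str, N: int, seed: int, crisp: bool) -> NeutroPopulation:
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    x_l = rng.uniform(0.0, 1.0, N)
    e_l = rng.standard_normal(N)
    if crisp:
        x_u, e_u = x_l, e_l
    else:
        x_u = rng.uniform(0.0, 1.0, N)
        e_u = rng.standard_normal(N)
    y_l = mean_fn(x_l) + e_l
    y_u = mean_fn(x_u) + e_u
    return NeutroPopulation(
        NeutroArray(x_l, x_u), NeutroArray(y_l, y_u), N, name=name, seed=seed
    )


def gen_sine(N: int = 1000, seed: int = 0, crisp: bool = False) -> NeutroPopulation:
    """Sine population: y = sin(2*pi*x) + e, x ~ U(0,1), e ~ N(0,1)."""
    return _gen_uniform_pop(_mean_sine, "sine", N, seed, crisp)


def gen_bump(N: int = 1000, seed: int = 0, crisp: bool = False) -> NeutroPopulation:
    """Bump population: y = 1 + 2(x-0.5) + exp(-200(x-0.5)^2) + e."""
    return _gen_uniform_pop(_mean_bump, "bump", N, seed, crisp)


def gen_jump(N: int = 1000, seed: int = 0, crisp: bool = False) -> NeutroPopulation:
    """Jump population: y = 1 + 2(x-0.5)1{x<=0.65} + 0.65*1{x>0.65} + e."""
    return _gen_uniform_pop(_mean_jump, "jump", N, seed, crisp)


def gen_weather_like(
    N: int = 365,
    seed: int = 0,
    crisp: bool = False,
    base_temp: float = 70.0,
    amplitude: float = 25.0,
    peak_day: int = 105,
    x_noise_sd: float = 5.0,
    intercept: float = 4.0,
    slope: float = 0.95,
    y_noise_sd: float = 3.0,
) -> NeutroPopulation:
    """Synthetic year of daily temperatures with a strong linear x-y relation.

    Day t = 1..N:  x_t = base + amplitude * sin(2*pi*(t - peak_day)/365)
    + N(0, x_noise_sd) in degrees Fahrenheit (first-year stream), and
    y_t = intercept + slope * x_t + N(0, y_noise_sd) (second year).  The two
    bound streams are two such correlated realizations sharing the seasonal
    signal.  Purely synthetic fixture; not real station data.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(1, N + 1, dtype=float)
    season = base_temp + amplitude * np.sin(2.0 * np.pi * (t - peak_day + 91.25) / 365.0)
    x_l = season + rng.normal(0.0, x_noise_sd, N)
    y_l = intercept + slope * x_l + rng.normal(0.0, y_noise_sd, N)
    if crisp:
        x_u, y_u = x_l, y_l
    else:
        x_u = season + rng.normal(0.0, x_noise_sd, N)
        y_u = intercept + slope * x_u + rng.normal(0.0, y_noise_sd, N)
    return NeutroPopulation(
        NeutroArray(x_l, x_u), NeutroArray(y_l, y_u), N, name="weather", seed=seed
    )


GENERATORS = {
    "sine": gen_sine,
    "bump": gen_bump,
    "jump": gen_jump,
    "weather": gen_weather_like,
}
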