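"""Interval-valued (neutrosophic) data containers.

A neutrosophic observation records a lower and an upper determination of a
quantity, ``[x_L, x_U]``, instead of a single crisp value.  Throughout this
package the two bounds are treated as two *parallel crisp data streams*:
every statistic is computed once on the lower stream and once on the upper
stream, and the pair is reported in that fixed order.  The bounds are never
combined by interval arithmetic, and no element-wise ordering
``lower_i <= upper_i`` is imposed by default — computed output intervals
(e.g. Monte-Carlo mean squared errors per stream) legitimately violate it.
Crisp data are the degenerate special case ``lower == upper``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

__all__ = ["NeutroArray", "NeutroScalar", "make_neutro", "apply_parallel"]


@dataclass(frozen=True)
class NeutroScalar:
    """An interval-valued scalar ``[lower, upper]`` (bounds may be unordered)."""

    lower: float
    upper: float

    def __iter__(self):
        yield self.lower
        yield self.upper

    def as_tuple(self) -> tuple[float, float]:
        return (self.lower, self.upper)


class NeutroArray:
    """An interval-valued variable over population units.

    Parameters
    ----------
    lower, upper : array_like of float, same length >= 1
        The two bound streams.  All entries must be finite.
    strict : bool
        If True, additionally require ``lower_i <= upper_i`` element-wise
        (useful for user-supplied measurement intervals; never required for
        computed outputs).
    """

    __slots__ = ("lower", "upper")

    def __init__(self, lower, upper, strict: bool = False):
        lo = np.asarray(lower, dtype=float)
        up = np.asarray(upper, dtype=float)
        if lo.ndim != 1 or up.ndim != 1:
            raise ValueError("bounds must be one-dimensional vectors")
        if lo.shape != up.shape:
            raise ValueError(
                f"bound length mismatch: lower has {lo.size}, upper has {up.size}"
            )
        if lo.size < 1:
            raise ValueError("bounds must have length >= 1")
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(up))):
            raise ValueError("bounds must be finite")
        if strict and np.any(lo > up):
            bad = int(np.argmax(lo > up))
            raise ValueError(
                f"strict mode: lower > upper at index {bad} "
                f"({lo[bad]} > {up[bad]})"
            )
        self.lower = lo
        self.upper = up

    def __len__(self) -> int:
        return self.lower.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"NeutroArray(n={len(self)})"

    @property
    def is_degenerate(self) -> bool:
        """True when lower == upper everywhere (crisp data)."""
        return bool(np.array_equal(self.lower, self.upper))

    def stream(self, which: str) -> np.ndarray:
        """Return one bound stream, ``which`` in {'lower', 'upper'}."""
        if which == "lower":
            return self.lower
        if which == "upper":
            return self.upper
        raise ValueError(f"unknown stream {which!r}")


def make_neutro(lower, upper, strict: bool = False) -> NeutroArray:
    """Build a :class:`NeutroArray` from two equal-length finite vectors."""
    return NeutroArray(lower, upper, strict=strict)


NeutroInput = Union[NeutroArray, NeutroScalar]


def apply_parallel(fn: Callable, *inputs: NeutroInput):
    """Apply a crisp computation independently to the two bound streams.

    ``fn`` receives the lower components of every input and then, in a
    separate call, the upper components; there is no cross-bound mixing.
    Returns a :class:`NeutroScalar` when ``fn`` yields a scalar and a
    :class:`NeutroArray` when it yields a vector.
    """
    if not inputs:
        raise ValueError("apply_parallel needs at least one interval input")
    lows = [a.lower for a in inputs]
    ups = [a.upper for a in inputs]
    res_lo = fn(*lows)
    res_up = fn(*ups)
    lo_arr = np.asarray(res_lo, dtype=float)
    up_arr = np.asarray(res_up, dtype=float)
    if lo_arr.shape != up_arr.shape:
        raise ValueError("fn returned differently shaped results per stream")
    if lo_arr.ndim == 0:
        return NeutroScalar(float(lo_arr), float(up_arr))
    return NeutroArray(lo_arr, up_arr)
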