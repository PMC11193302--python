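"""Grünwald-Letnikov fractional-order differentiation of spectra.

The v-th order derivative of a discretely sampled signal f (step h = 1 band,
i.e. 1 nm after resampling) is the weighted backward sum

    d^v f(x) ~ sum_{m=0}^{M} c_m f(x - m),   c_m = (-1)^m binom(v, m),

with the generalized binomial coefficient binom(v, m) = Γ(v+1)/(m! Γ(v-m+1)).
The weights are generated with the numerically stable multiplicative
recurrence c_0 = 1, c_m = c_{m-1} (m - 1 - v) / m, which reduces to the
familiar stencils [1, -1] at v = 1 and [1, -2, 1] at v = 2 and to the
identity at v = 0.

At the start of each contiguous segment the sum is truncated to the
available history (finite lower terminal); no padding is used, so the first
few bands of each segment are order-dependent "warm-up" values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .spectra import SpectraSet, Spectrum, SpectraError

__all__ = [
    "GLWeights",
    "FODStack",
    "DEFAULT_ORDERS",
    "gl_weights",
    "gl_derivative",
    "gl_derivative_set",
    "fod_stack",
]

#: Orders 0.0, 0.2, ..., 2.0 - the standard scan.
DEFAULT_ORDERS: tuple[float, ...] = tuple(round(0.2 * i, 1) for i in range(11))


def _check_order(v: float) -> float:
    v = float(v)
    if not (0.0 <= v <= 2.0):
        raise ValueError(f"fractional order must lie in [0, 2], got {v}")
    return v


@dataclass(frozen=True)
class GLWeights:
    """Fractional order and its truncated G-L coefficient sequence c_0..c_M."""

    order: float
    weights: np.ndarray

    def __len__(self) -> int:
        return self.weights.size


def gl_weights(v: float, m: int) -> GLWeights:
    """G-L weights c_0..c_m for order ``v`` via the multiplicative recurrence."""
    v = _check_order(v)
    m = int(m)
    if m < 0:
        raise ValueError(f"truncation length must be non-negative, got {m}")
    w = np.empty(m + 1)
    w[0] = 1.0
    for k in range(1, m + 1):
        w[k] = w[k - 1] * (k - 1 - v) / k
    return GLWeights(v, w)


def _gl_block(block: np.ndarray, v: float) -> np.ndarray:
    """Apply the truncated G-L sum along axis 1 of a contiguous block."""
    n_bands = block.shape[1]
    w = gl_weights(v, n_bands - 1).weights
    # Lower-triangular Toeplitz: T[k, j] = c_{k-j}; out[:, k] = sum_j T[k, j] f_j
    T = np.tril(toeplitz(w))
    return block @ T.T


def gl_derivative(sp: Spectrum, v: float) -> Spectrum:
    """Fractional derivative of one spectrum, per contiguous segment."""
    v = _check_order(v)
    if sp.wavelengths.size == 0:
        raise SpectraError("empty spectrum")
    if v == 0.0:
        return Spectrum(sp.wavelengths, sp.reflectance.copy())
    out = np.empty_like(sp.reflectance)
    for seg in sp.segments:
        out[seg] = _gl_block(sp.reflectance[None, seg], v)[0]
    return Spectrum(sp.wavelengths, out)


def gl_derivative_set(s: SpectraSet, v: float) -> SpectraSet:
    """Fractional derivative of every sample in a SpectraSet."""
    v = _check_order(v)
    if v == 0.0:
        return s.with_values(s.values.copy())
    out = np.empty_like(s.values)
    for seg in s.segments:
        out[:, seg] = _gl_block(s.values[:, seg], v)
    return s.with_values(out)


@dataclass(frozen=True)
class FODStack:
    """Per-order differentiated copies of one SpectraSet."""

    orders: tuple[float, ...]
    sets: dict[float, SpectraSet]

    def __getitem__(self, order: float) -> SpectraSet:
        key = round(float(order), 6)
        try:
            return self.sets[key]
        except KeyError:
            raise KeyError(f"order {order} not in stack {self.orders}") from None

    def __iter__(self):
        return iter(self.orders)

    def __len__(self) -> int:
        return len(self.orders)


def fod_stack(s: SpectraSet, orders=DEFAULT_ORDERS) -> FODStack:
    """Differentiate ``s`` at each order (default 0.0-2.0 in steps of 0.2).

    Order 0.0 is a verbatim copy of the input.
    """
    keys = tuple(round(_check_order(v), 6) for v in orders)
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate orders")
    return FODStack(keys, {v: gl_derivative_set(s, v) for v in keys})
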