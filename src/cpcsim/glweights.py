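"""Grünwald–Letnikov weight sequences for the NSFD scheme.

Three weight families enter the discretisation of the hybrid
Caputo-proportional-constant operator:

``varpi``
    ϖ₀ = 1, ϖᵢ = (1 − θ/i)·ϖᵢ₋₁ — the GL binomial coefficients of order
    θ−1, i.e. the (all-positive) quadrature weights of the
    Riemann–Liouville integral of order 1−θ.
``kappa``
    κ₁ = θ, κᵢ₊₁ = κᵢ·(i−θ)/(i+1) — the alternating-sign-free form of
    (−1)^{i−1}·C(θ, i), the GL weights of the Caputo derivative of
    order θ.
``r``
    rᵢ = i^{−θ}/Γ(1−θ) — the initial-value correction weights.

For a variable order θ(t), θ is replaced by θ(tᵢ) per index inside the
recurrences, which therefore chain values of different orders; with a
constant order function the constant-order tables are reproduced
bit-for-bit.

Both ϖ and κ satisfy the ordering inequalities
0 < κᵢ₊₁ < κᵢ < … < κ₁ = θ < 1 and 0 < rᵢ₊₁ < rᵢ < … < r₁ = 1/Γ(1−θ)
for θ ∈ (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "OrderSpec",
    "GLWeightTable",
    "OrderDomainError",
    "varpi_weights",
    "kappa_weights",
    "r_weights",
    "gl_weight_table",
]

#: A constant fractional order, or one value of θ(tᵢ) per grid index i=0…N.
OrderSpec = Union[float, Sequence[float], np.ndarray]


class OrderDomainError(ValueError):
    """Raised when a fractional order lies outside its admissible range."""


def _order_values(order: OrderSpec, N: int, *, closed_top: bool) -> np.ndarray:
    """Expand an order spec into per-index values θ₀…θ_N and validate range."""
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    if np.isscalar(order):
        theta = np.full(N + 1, float(order))
    else:
        theta = np.asarray(order, dtype=float)
        if theta.shape != (N + 1,):
            raise OrderDomainError(
                f"variable-order spec must provide N+1={N + 1} values, got shape {theta.shape}"
            )
    hi_ok = theta <= 1.0 if closed_top else theta < 1.0
    if not np.all((theta > 0.0) & hi_ok):
        rng = "(0, 1]" if closed_top else "(0, 1)"
        raise OrderDomainError(f"fractional order values must lie in {rng}")
    return theta


def varpi_weights(order: OrderSpec, N: int) -> np.ndarray:
    """Weights ϖ₀…ϖ_N via ϖᵢ = (1 − θ(tᵢ)/i)·ϖᵢ₋₁, ϖ₀ = 1.

    Equal to (−1)ⁱ·C(θ−1, i) for constant θ; all values lie in [0, 1]
    and decay like i^{−θ}. θ = 1 gives the classical-derivative limit
    (1, 0, 0, …).
    """
    theta = _order_values(order, N, closed_top=True)
    w = np.empty(N + 1)
    w[0] = 1.0
    if N >= 1:
        i = np.arange(1, N + 1, dtype=float)
        w[1:] = np.cumprod(1.0 - theta[1:] / i)
    return w


def kappa_weights(order: OrderSpec, N: int) -> np.ndarray:
    """Weights κ₁…κ_N via κ₁ = θ(t₁), κᵢ = κᵢ₋₁·((i−1) − θ(tᵢ))/i.

    Equal to (−1)^{i−1}·C(θ, i) for constant θ; strictly positive and
    strictly decreasing for θ ∈ (0, 1).
    """
    theta = _order_values(order, N, closed_top=True)
    if N == 0:
        return np.empty(0)
    k = np.empty(N)
    k[0] = theta[1]
    if N >= 2:
        i = np.arange(2, N + 1, dtype=float)
        k[1:] = theta[1] * np.cumprod(((i - 1.0) - theta[2:]) / i)
    return k


def r_weights(order: OrderSpec, N: int) -> np.ndarray:
    """Weights r₁…r_N with rᵢ = i^{−θ(tᵢ)}/Γ(1 − θ(tᵢ)).

    Undefined at θ = 1 (pole of Γ(0)); the classical limit bypasses the
    r-term instead.
    """
    theta = _order_values(order, N, closed_top=False)
    if N == 0:
        return np.empty(0)
    i = np.arange(1, N + 1, dtype=float)
    th = theta[1:]
    return i ** (-th) / _gamma(1.0 - th)


@dataclass(frozen=True)
class GLWeightTable:
    """Bundled weight sequences for one solve.

    ``varpi`` has length N+1 (indices 0…N); ``kappa`` and ``rvals`` have
    length N (indices 1…N). ``padded_kappa``/``padded_rvals`` prepend a
    zero at index 0 so all three sequences share the grid indexing used
    by the history dot products.
    """

    order: OrderSpec
    N: int
    varpi: np.ndarray
    kappa: np.ndarray
    rvals: np.ndarray
    _padded: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def padded_kappa(self) -> np.ndarray:
        if "kappa" not in self._padded:
            self._padded["kappa"] = np.concatenate([[0.0], self.kappa])
        return self._padded["kappa"]

    @property
    def padded_rvals(self) -> np.ndarray:
        if "rvals" not in self._padded:
            self._padded["rvals"] = np.concatenate([[0.0], self.rvals])
        return self._padded["rvals"]


def gl_weight_table(order: OrderSpec, N: int) -> GLWeightTable:
    """Build all three weight sequences for a length-N solve.

    For the classical order θ = 1 the r-sequence is stored as zeros: the
    scheme's r-term is algebraically absent in that limit and Γ(0) has a
    pole, so no finite weight exists.
    """
    theta = _order_values(order, N, closed_top=True)
    varpi = varpi_weights(order, N)
    kappa = kappa_weights(order, N)
    if np.any(theta == 1.0):
        if not np.all(theta == 1.0):
            raise OrderDomainError("mixed classical (θ=1) and fractional orders are not supported")
        rvals = np.zeros(N)
    else:
        rvals = r_weights(order, N)
    return GLWeightTable(order=order, N=N, varpi=varpi, kappa=kappa, rvals=rvals)
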