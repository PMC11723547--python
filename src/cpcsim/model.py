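"""Five-compartment breast-cancer progression model.

Compartments
------------
X : patients hospitalized with stage 1-2 disease
B : patients with stage 3A/3B disease
C : patients diagnosed at stage 4
R : disease-free individuals following chemotherapy
E : patients experiencing chemotherapy-induced cardiotoxicity

The deterministic drift is a linear (affine) vector field::

    dX/dt = ω1 − (γ1+μ2)·X
    dB/dt = ω2 + μ2·X + α1·R − (γ2+μ1+ϕ1+σ1)·B
    dC/dt = ω3 + μ1·B + α2·R − (γ3+ϕ2+σ2)·C
    dR/dt = γ1·X + γ2·B + γ3·C − (α1+α2+ϕ3)·R
    dE/dt = ϕ3·R + ϕ2·C + ϕ1·B − σ3·E

Parameters are published under a different symbol set (Λ, β, ψ, μ) than
the model equations use (ω, μ, α, σ); :func:`map_table1` performs the
canonical reconciliation, driven by a configurable name table rather than
hard-coded constants.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParameters",
    "StateVector",
    "TABLE1_VALUES",
    "TABLE1_NAME_MAP",
    "drift",
    "drift_matrix",
    "map_table1",
    "table1_parameters",
    "x_equilibrium",
    "InvalidInputError",
    "ConfigurationError",
    "DegenerateParameterError",
]

COMPARTMENTS = ("X", "B", "C", "R", "E")


class InvalidInputError(ValueError):
    """Raised when a state or parameter value is non-finite or negative."""


class ConfigurationError(KeyError):
    """Raised when a parameter table is missing a required entry."""


class DegenerateParameterError(ValueError):
    """Raised when a closed-form expression is undefined for the parameters."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the compartmental model.

    All fields are finite and non-negative. Inflows ``omega*`` carry units
    of persons per unit time; every other field is a first-order rate
    (per unit time).
    """

    omega1: float  # recruitment into X
    omega2: float  # recruitment into B
    omega3: float  # recruitment into C
    gamma1: float  # X -> R transfer
    gamma2: float  # B -> R transfer
    gamma3: float  # C -> R transfer
    mu1: float     # B -> C stage progression
    mu2: float     # X -> B stage progression
    alpha1: float  # R -> B relapse
    alpha2: float  # R -> C relapse
    phi1: float    # B -> E chemotherapy cardiotoxicity
    phi2: float    # C -> E chemotherapy cardiotoxicity
    phi3: float    # R -> E chemotherapy cardiotoxicity
    sigma1: float  # mortality of B
    sigma2: float  # mortality of C
    sigma3: float  # mortality of E

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise InvalidInputError(f"parameter {f.name} is not finite: {v!r}")
            if v < 0:
                raise InvalidInputError(f"parameter {f.name} is negative: {v!r}")

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class StateVector:
    """Compartment populations at one instant (real-valued, mean-field)."""

    X: float
    B: float
    C: float
    R: float
    E: float

    def __post_init__(self) -> None:
        for name in COMPARTMENTS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"state component {name} is not finite: {v!r}")

    def to_array(self) -> np.ndarray:
        return np.array([self.X, self.B, self.C, self.R, self.E], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise InvalidInputError(f"state array must have shape (5,), got {arr.shape}")
        return cls(*arr.tolist())


#: Published parameter table: description-level names and printed values.
TABLE1_VALUES: dict[str, float] = {
    "Lambda1": 14000.0,
    "Lambda2": 80.0,
    "Lambda3": 80.0,
    "phi1": 0.03,
    "phi2": 0.4,
    "phi3": 0.01,
    "beta1": 0.01,
    "beta2": 0.01,
    "gamma1": 0.03,
    "gamma2": 0.03,
    "gamma3": 0.03,
    "mu1": 0.0256,
    "mu2": 0.0256,
    "mu3": 0.0256,
    "psi1": 0.03,
    "psi2": 0.3,
}

#: Canonical reconciliation: published symbol -> model field.
#: Λi are the inflows; β1 is the B->C progression and β2 the X->B progression;
#: the published μ1..μ3 are the stage-3/stage-4/cardiotoxic mortalities
#: (model σ1..σ3); ψ1, ψ2 are the relapse rates out of R.
TABLE1_NAME_MAP: dict[str, str] = {
    "Lambda1": "omega1",
    "Lambda2": "omega2",
    "Lambda3": "omega3",
    "phi1": "phi1",
    "phi2": "phi2",
    "phi3": "phi3",
    "beta1": "mu1",
    "beta2": "mu2",
    "gamma1": "gamma1",
    "gamma2": "gamma2",
    "gamma3": "gamma3",
    "mu1": "sigma1",
    "mu2": "sigma2",
    "mu3": "sigma3",
    "psi1": "alpha1",
    "psi2": "alpha2",
}


def map_table1(
    table: Mapping[str, float],
    name_map: Mapping[str, str] = TABLE1_NAME_MAP,
) -> ModelParameters:
    """Translate a published parameter table into :class:`ModelParameters`.

    Parameters
    ----------
    table
        Published-symbol -> value mapping; must provide every key of
        ``name_map`` (the 16 published entries by default).
    name_map
        Published-symbol -> model-field mapping; replaceable so the
        reconciliation is data, not code.

    Raises
    ------
    ConfigurationError
        If any required entry is missing from ``table``.
    """
    kwargs: dict[str, float] = {}
    for src, dst in name_map.items():
        if src not in table:
            raise ConfigurationError(f"parameter table is missing entry {src!r}")
        kwargs[dst] = float(table[src])
    return ModelParameters(**kwargs)


def table1_parameters() -> ModelParameters:
    """The published baseline parameter set, canonically mapped."""
    return map_table1(TABLE1_VALUES)


def _state_array(state: StateVector | np.ndarray) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.to_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (5,):
        raise InvalidInputError(f"state must have 5 components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("state contains non-finite components")
    return arr


def drift(state: StateVector | np.ndarray, params: ModelParameters) -> np.ndarray:
    """Deterministic right-hand side, one rate per compartment.

    Affine in the state for fixed parameters; returns a length-5 array in
    persons per unit time, ordered (X, B, C, R, E).
    """
    X, B, C, R, E = _state_array(state)
    p = params
    return np.array(
        [
            p.omega1 - (p.gamma1 + p.mu2) * X,
            p.omega2 + p.mu2 * X + p.alpha1 * R - (p.gamma2 + p.mu1 + p.phi1 + p.sigma1) * B,
            p.omega3 + p.mu1 * B + p.alpha2 * R - (p.gamma3 + p.phi2 + p.sigma2) * C,
            p.gamma1 * X + p.gamma2 * B + p.gamma3 * C - (p.alpha1 + p.alpha2 + p.phi3) * R,
            p.phi3 * R + p.phi2 * C + p.phi1 * B - p.sigma3 * E,
        ]
    )


def drift_matrix(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Affine decomposition of the drift: drift(x) = A·x + c.

    Returns the 5×5 rate matrix A and the inflow vector c, so implicit
    time-stepping reduces to one linear solve per step.
    """
    p = params
    A = np.array(
        [
            [-(p.gamma1 + p.mu2), 0.0, 0.0, 0.0, 0.0],
            [p.mu2, -(p.gamma2 + p.mu1 + p.phi1 + p.sigma1), 0.0, p.alpha1, 0.0],
            [0.0, p.mu1, -(p.gamma3 + p.phi2 + p.sigma2), p.alpha2, 0.0],
            [p.gamma1, p.gamma2, p.gamma3, -(p.alpha1 + p.alpha2 + p.phi3), 0.0],
            [0.0, p.phi1, p.phi2, p.phi3, -p.sigma3],
        ]
    )
    c = np.array([p.omega1, p.omega2, p.omega3, 0.0, 0.0])
    return A, c


def x_equilibrium(params: ModelParameters) -> float:
    """Steady state of the decoupled X equation, ω1/(γ1+μ2).

    The X compartment obeys dX/dt = ω1 − (γ1+μ2)X independently of the
    rest of the system, so its long-run level is available in closed form:
    X(t) = X* + (X0 − X*)·exp(−(γ1+μ2)t) with X* = ω1/(γ1+μ2).
    """
    denom = params.gamma1 + params.mu2
    if denom == 0:
        raise DegenerateParameterError("gamma1 + mu2 must be positive for an X equilibrium")
    return params.omega1 / denom
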