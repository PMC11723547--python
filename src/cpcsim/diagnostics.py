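"""Analytic certificates: Lipschitz matrix, contraction factor, Lyapunov bound.

These quantities accompany the fixed-point (deterministic phases) and
stopping-time (stochastic phase) well-posedness arguments for the model.
They are computable scalars/matrices, reported as diagnostics; the
formal proofs themselves are not re-derived here.

Two deliberate verbatim choices, flagged because they differ from the
drift equations: the Lipschitz matrix's (1,1) entry is γ1+μ1 (the drift
suggests γ1+μ2) and its row-4 diagonal is α1+α2+σ3 (the drift has
α1+α2+ϕ3). Both are kept exactly as published for the certificate; the
dynamics always use the drift equations.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.special import gamma as _gamma

from .cpc import CPCKernelConfig
from .model import ModelParameters
from .stochastic import StochasticConfig

__all__ = [
    "lipschitz_matrix",
    "contraction_factor",
    "lyapunov_bound",
    "diagnostics_report",
]


def lipschitz_matrix(params: ModelParameters) -> np.ndarray:
    """Componentwise Lipschitz bound Θ of the drift operator (5×5, entrywise ≥ 0)."""
    p = params
    return np.array(
        [
            [p.gamma1 + p.mu1, 0.0, 0.0, 0.0, 0.0],
            [p.mu2, p.gamma2 + p.mu1 + p.phi1 + p.sigma1, 0.0, p.alpha1, 0.0],
            [0.0, p.mu1, p.gamma3 + p.phi2 + p.sigma2, p.alpha2, 0.0],
            [p.gamma1, p.gamma2, p.gamma3, p.alpha1 + p.alpha2 + p.sigma3, 0.0],
            [0.0, p.phi1, p.phi2, p.phi3, p.sigma3],
        ]
    )


def contraction_factor(
    theta_matrix: np.ndarray,
    theta: float,
    lam: float = 1.0,
    Q: float = 1.0,
    psi_max: float = 1.0,
    phi_max: float = 1.0,
    include_gamma: bool = True,
) -> float:
    """Spectral radius of the scaled Lipschitz matrix.

    Returns ρ( λ^{1−θ}·Ψmax·Φmax·g(θ)/|V0(θ)| · Θ ) where g(θ) = |Γ(θ−1)|
    when ``include_gamma`` (Γ(θ−1) is negative for θ ∈ (0,1); its absolute
    value is used so the certificate is a non-negative scale factor) and
    g = 1 otherwise. The unique-solution certificate holds when the
    returned value is below one. Ψmax and Φmax are bound constants not
    pinned down analytically; they default to 1 and are configurable.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError(f"contraction factor requires theta in (0, 1), got {theta}")
    V0 = CPCKernelConfig(theta=theta, Q=Q, lam=lam).V0(theta)
    if V0 == 0.0:
        raise ValueError("V0(theta) vanished; prefactor undefined")
    g = abs(_gamma(theta - 1.0)) if include_gamma else 1.0
    prefactor = lam ** (1.0 - theta) * psi_max * phi_max * g / abs(V0)
    eigvals = np.linalg.eigvals(np.asarray(theta_matrix, dtype=float))
    return float(prefactor * np.max(np.abs(eigvals)))


def lyapunov_bound(
    params: ModelParameters,
    noise: StochasticConfig | Sequence[float],
    five_noise_terms: bool = False,
) -> float:
    """State-independent Itô–Lyapunov drift bound V̄ ≥ 0.

    Sum of all sixteen rate parameters plus half the summed squared noise
    intensities. As published the noise sum covers the first four
    channels only; ``five_noise_terms`` switches to the symmetric
    five-term variant.
    """
    sigmas = noise.sigmas if isinstance(noise, StochasticConfig) else tuple(noise)
    p = params
    rate_sum = (
        p.omega1 + p.omega2 + p.omega3
        + p.gamma1 + p.gamma2 + p.gamma3
        + p.mu1 + p.mu2
        + p.phi1 + p.phi2 + p.phi3
        + p.sigma1 + p.sigma2 + p.sigma3
        + p.alpha1 + p.alpha2
    )
    n_terms = 5 if five_noise_terms else 4
    noise_sum = sum(s**2 for s in sigmas[:n_terms]) / 2.0
    return rate_sum + noise_sum


def diagnostics_report(
    params: ModelParameters,
    theta: float,
    noise: Optional[StochasticConfig] = None,
    lam: float = 1.0,
    Q: float = 1.0,
    psi_max: float = 1.0,
    phi_max: float = 1.0,
) -> dict:
    """Assemble the certificate quantities into a JSON-serialisable block."""
    theta_matrix = lipschitz_matrix(params)
    rho = contraction_factor(theta_matrix, theta, lam=lam, Q=Q, psi_max=psi_max, phi_max=phi_max)
    report = {
        "lipschitz_matrix": theta_matrix.tolist(),
        "spectral_radius_unscaled": float(np.max(np.abs(np.linalg.eigvals(theta_matrix)))),
        "contraction_factor": rho,
        "contraction_certificate_holds": bool(rho < 1.0),
        "theta": theta,
        "psi_max": psi_max,
        "phi_max": phi_max,
        "note": (
            "gamma factor uses |Gamma(theta-1)|; Psi_max/Phi_max are "
            "user-configurable bound constants (default 1)"
        ),
    }
    if noise is not None:
        report["lyapunov_bound"] = lyapunov_bound(params, noise)
    if not math.isfinite(rho):
        report["contraction_certificate_holds"] = False
    return report
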