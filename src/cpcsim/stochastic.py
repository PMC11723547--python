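"""Stochastic phase: fBm-driven SDE system via corrected Euler–Maruyama.

In the final regime each compartment x carries multiplicative noise
ς·x·dM^{H*} driven by an independent fractional Brownian motion with
Hurst index H* > 0.5 (positively correlated increments). The update is

    x_{n+1} = x_n + f_n·Π(Δt) + ς·x_n·ΔB_n + c_n,

with a Hurst-dependent correction c_n:

``unscaled``  c = 0.5·x_n·Π(Δt)^{2H*}        (default)
``sigma-squared``  c = 0.5·ς²·x_n·Π(Δt)^{2H*}     (Itô-type correction)
``off``            c = 0

With the sigma-squared correction, zero noise reduces the step exactly
to explicit Euler; the unscaled correction has no ς factor, so it
contributes a deterministic exponential inflation regardless of noise.

fBm increments are generated with exact covariance: Davies–Harte
circulant embedding (FFT, O(n log n)) by default, with the Hosking
recursion (O(n²)) as fallback and independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .cpc import DivergenceError, Trajectory, denominator, _grid
from .model import ModelParameters, StateVector, drift

__all__ = [
    "StochasticConfig",
    "FBMIncrements",
    "fbm_increments",
    "em_step",
    "solve_stochastic",
    "solve_stochastic_ensemble",
]

CORRECTION_MODES = ("unscaled", "sigma-squared", "off")


@dataclass(frozen=True)
class StochasticConfig:
    """Noise intensities, Hurst index and reproducibility settings.

    ``hurst`` must exceed 0.5 for model runs (the correction term of the
    scheme is stated under that condition); H = 0.5 classical Brownian
    motion remains reachable through :func:`fbm_increments` directly for
    oracle comparisons.
    """

    sigmas: tuple[float, float, float, float, float] = (0.1, 0.1, 0.1, 0.1, 0.1)
    hurst: float = 0.7
    seed: int = 0
    correction: str = "unscaled"
    clip_at_zero: bool = False

    def __post_init__(self) -> None:
        if len(self.sigmas) != 5:
            raise ValueError("exactly five noise intensities are required")
        if any(s < 0 for s in self.sigmas):
            raise ValueError("noise intensities must be non-negative")
        if not 0.5 < self.hurst < 1.0:
            raise ValueError(f"Hurst index must lie in (0.5, 1), got {self.hurst}")
        if self.correction not in CORRECTION_MODES:
            raise ValueError(
                f"correction must be one of {CORRECTION_MODES}, got {self.correction!r}"
            )


@dataclass(frozen=True)
class FBMIncrements:
    """A realised fractional-Gaussian-noise sequence for one driver."""

    hurst: float
    dt: float
    increments: np.ndarray  # length n; stationary Gaussian, var = dt^{2H}


def _fgn_autocovariance(H: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-step fGn: γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})."""
    k = np.abs(lags).astype(float)
    return 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def _fgn_davies_harte(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-step fGn sample of length n by circulant embedding (exact covariance)."""
    gamma = _fgn_autocovariance(H, np.arange(n + 1))
    # First row of the 2n circulant: γ(0)…γ(n), γ(n−1)…γ(1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = 2 * n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        raise FloatingPointError("circulant embedding produced negative eigenvalues")
    lam = np.clip(lam, 0.0, None)

    # Hermitian-symmetric spectral noise; 2n normal draws in a fixed order.
    z = rng.standard_normal(m)
    w = np.empty(m, dtype=complex)
    w[0] = math.sqrt(lam[0] / m) * z[0]
    w[n] = math.sqrt(lam[n] / m) * z[1]
    a = z[2 : n + 1]
    b = z[n + 1 : 2 * n]
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (a + 1j * b)
    w[n + 1 :] = np.conj(w[1:n][::-1])
    return np.fft.fft(w)[:n].real


def _fgn_hosking(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-step fGn by the Hosking recursion (O(n²); exact covariance)."""
    gamma = _fgn_autocovariance(H, np.arange(n))
    out = np.empty(n)
    z = rng.standard_normal(n)
    out[0] = z[0]
    phi = np.empty(n)
    prev = np.empty(n)
    sigma2 = 1.0
    for i in range(1, n):
        if i == 1:
            phi[0] = gamma[1]
        else:
            kappa = (gamma[i] - prev[: i - 1] @ gamma[1:i][::-1]) / sigma2
            phi[: i - 1] = prev[: i - 1] - kappa * prev[: i - 1][::-1]
            phi[i - 1] = kappa
        sigma2 *= 1.0 - phi[i - 1] ** 2
        out[i] = phi[:i] @ out[:i][::-1] + math.sqrt(sigma2) * z[i]
        prev[:i] = phi[:i]
    return out


def fbm_increments(
    H: float,
    n: int,
    dt: float,
    seed: Union[int, np.random.SeedSequence, np.random.Generator],
    method: str = "davies-harte",
) -> FBMIncrements:
    """Generate n increments of fractional Brownian motion over steps dt.

    The increments are stationary Gaussian with mean 0, variance dt^{2H}
    and lag-k correlation ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); the
    generation is exact in covariance, not approximate. Reproducible from
    ``seed``.
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst index must lie in (0, 1), got {H}")
    if n < 1:
        raise ValueError(f"need at least one increment, got n={n}")
    if dt <= 0:
        raise ValueError(f"step must be positive, got dt={dt}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "davies-harte":
        try:
            unit = _fgn_davies_harte(H, n, rng)
        except FloatingPointError:
            unit = _fgn_hosking(H, n, rng)
    elif method == "hosking":
        unit = _fgn_hosking(H, n, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FBMIncrements(hurst=H, dt=dt, increments=dt**H * unit)


def em_step(
    x_n: Union[float, np.ndarray],
    f_n: Union[float, np.ndarray],
    sigma: Union[float, np.ndarray],
    dB_n: Union[float, np.ndarray],
    pi: float,
    hurst: float,
    correction: str = "unscaled",
) -> Union[float, np.ndarray]:
    """One corrected Euler–Maruyama step (componentwise)."""
    x_n = np.asarray(x_n, dtype=float)
    out = x_n + np.asarray(f_n, dtype=float) * pi + np.asarray(sigma, dtype=float) * x_n * dB_n
    if correction == "unscaled":
        out = out + 0.5 * x_n * pi ** (2.0 * hurst)
    elif correction == "sigma-squared":
        out = out + 0.5 * np.asarray(sigma, dtype=float) ** 2 * x_n * pi ** (2.0 * hurst)
    elif correction != "off":
        raise ValueError(f"unknown correction mode {correction!r}")
    return out


def solve_stochastic(
    params: ModelParameters,
    config: StochasticConfig,
    y2: StateVector | np.ndarray,
    t_start: float,
    t_end: float,
    dt: float,
    denominator_kind: str = "plain",
) -> Trajectory:
    """Simulate the SDE phase with five independent fBm drivers.

    One driver per compartment, seeded by splitting ``config.seed``
    (no cross-correlation). The path is fully determined by
    (seed, config). With all ς = 0 and the sigma-squared or off
    correction, the trajectory coincides with deterministic explicit
    Euler on the same grid.
    """
    times = _grid(t_start, t_end, dt)
    n_steps = len(times) - 1
    pi = denominator(dt, denominator_kind)
    y2 = y2.to_array() if isinstance(y2, StateVector) else np.asarray(y2, dtype=float)
    sigmas = np.asarray(config.sigmas, dtype=float)

    children = np.random.SeedSequence(config.seed).spawn(5)
    dB = np.column_stack(
        [fbm_increments(config.hurst, n_steps, dt, np.random.default_rng(s)).increments
         for s in children]
    )

    states = np.empty((n_steps + 1, 5))
    states[0] = y2
    for n in range(n_steps):
        f_n = drift(states[n], params)
        nxt = em_step(states[n], f_n, sigmas, dB[n], pi, config.hurst, config.correction)
        if config.clip_at_zero:
            nxt = np.maximum(nxt, 0.0)
        if not np.all(np.isfinite(nxt)):
            bad = int(np.flatnonzero(~np.isfinite(nxt))[0])
            raise DivergenceError(
                f"non-finite state in component {Trajectory.COLUMNS[bad]} "
                f"at step {n + 1} (t={times[n + 1]:.6g})",
                step=n + 1,
            )
        states[n + 1] = nxt
    return Trajectory(times, states, np.full(n_steps + 1, "stochastic", dtype=object))


def solve_stochastic_ensemble(
    params: ModelParameters,
    config: StochasticConfig,
    y2: StateVector | np.ndarray,
    t_start: float,
    t_end: float,
    dt: float,
    n_paths: int,
    denominator_kind: str = "plain",
    out_dir=None,
):
    """Monte-Carlo ensemble of the stochastic phase.

    Path k uses seed ``config.seed + k``. Returns (list of trajectories,
    summary DataFrame with per-compartment mean and standard deviation at
    each grid point). With ``out_dir`` set, writes one CSV per path plus
    ``ensemble_summary.csv``.
    """
    import dataclasses as _dc
    from pathlib import Path as _Path

    import pandas as pd

    if n_paths < 1:
        raise ValueError("need at least one path")
    trajectories = [
        solve_stochastic(params, _dc.replace(config, seed=config.seed + k),
                         y2, t_start, t_end, dt, denominator_kind)
        for k in range(n_paths)
    ]
    stack = np.stack([tr.states for tr in trajectories])  # (paths, time, 5)
    summary = pd.DataFrame({"t": trajectories[0].times})
    for j, comp in enumerate(Trajectory.COLUMNS):
        summary[f"{comp}_mean"] = stack[:, :, j].mean(axis=0)
        summary[f"{comp}_std"] = stack[:, :, j].std(axis=0, ddof=1 if n_paths > 1 else 0)
    if out_dir is not None:
        out_dir = _Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for k, tr in enumerate(trajectories):
            tr.to_csv(out_dir / f"path_{k:04d}.csv")
        summary.to_csv(out_dir / "ensemble_summary.csv", index=False)
    return trajectories, summary
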