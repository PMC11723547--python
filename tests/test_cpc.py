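"""CPC NSFD solver: classical limit, relaxation stability, exact-solution oracle."""

import math

import mpmath as mp
import numpy as np
import pytest

from cpcsim import (
    CPCKernelConfig,
    DivergenceError,
    Trajectory,
    cpc_step,
    denominator,
    gl_weight_table,
    solve_constant_order,
    solve_variable_order,
    table1_parameters,
    x_equilibrium,
)
from cpcsim.cpc import cpc_step_implicit
from cpcsim.glweights import OrderDomainError


def scalar_relaxation(theta, nu, x0, t_end, dt, implicit=False):
    """Drive the scalar test problem D^θ_CPC x = ν·x with the package's stepper."""
    n = round(t_end / dt)
    table = gl_weight_table(theta, n)
    kern = CPCKernelConfig(theta=theta)
    x = np.empty(n + 1)
    x[0] = x0
    for m in range(n):
        if implicit:
            x[m + 1] = cpc_step_implicit(x[: m + 1], table, kern, dt, nu, 0.0)
        else:
            x[m + 1] = cpc_step(x[: m + 1], table, kern, dt, nu * x[m])
    return x


def cpc_relaxation_exact(theta, nu, x0, t):
    """Exact solution of the scalar CPC relaxation via Laplace inversion.

    From the transform pair of the hybrid operator (Q = 1):
    X(s) = V0·s^{θ−1}·x0 / (V1·s^{θ−1} + V0·s^θ − ν), inverted numerically
    with the Talbot contour. Independent of the time-stepping code.
    """
    V0, V1 = theta, 1.0 - theta
    F = lambda s: V0 * s ** (theta - 1) * x0 / (V1 * s ** (theta - 1) + V0 * s**theta - nu)
    return float(mp.invertlaplace(F, t, method="talbot"))


class TestDenominator:
    def test_plain_is_identity_below_one(self):
        assert denominator(0.01, "plain") == 0.01

    def test_expm1_closed_form(self):
        assert denominator(0.01, "expm1") == pytest.approx(1 - math.exp(-0.01), rel=1e-14)

    def test_plain_rejects_large_step(self):
        with pytest.raises(ValueError):
            denominator(1.0, "plain")

    @pytest.mark.parametrize("kind", ["plain", "expm1"])
    def test_first_order_contract(self, kind):
        """Π(Δt) = Δt + O(Δt²): the relative deviation vanishes with Δt."""
        devs = [abs(denominator(dt, kind) - dt) / dt for dt in (1e-2, 1e-4, 1e-6)]
        assert devs[0] < 1e-2 and devs[1] < 1e-4 and devs[2] < 1e-6


class TestClassicalLimit:
    def test_bitwise_euler_equivalence(self):
        """θ=1, Q=1 (V0=1, V1=0), Π=Δt: the scheme is explicit Euler bit-for-bit."""
        x = scalar_relaxation(1.0, -1.0, 1.0, 1.0, 0.01)
        e = np.empty_like(x)
        e[0] = 1.0
        for i in range(len(e) - 1):
            e[i + 1] = e[i] + 0.01 * (-1.0 * e[i])
        np.testing.assert_array_equal(x, e)

    def test_first_order_convergence_to_exponential(self):
        errs = [
            abs(scalar_relaxation(1.0, -1.0, 1.0, 1.0, dt)[-1] - math.exp(-1.0))
            for dt in (0.01, 0.005, 0.0025)
        ]
        orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert all(abs(o - 1.0) <= 0.15 for o in orders)

    def test_x_compartment_converges_to_equilibrium(self, params, y0):
        """Classical integration drives X monotonically to ω1/(γ1+μ2)."""
        kern = CPCKernelConfig(theta=1.0)
        tr = solve_constant_order(params, kern, y0, 0.0, 200.0, 0.05)
        X = tr.component("X")
        assert np.all(np.diff(X) > 0)  # monotone approach from below
        assert X[-1] == pytest.approx(x_equilibrium(params), rel=1e-3)


class TestScalarRelaxation:
    @pytest.mark.parametrize("theta", [0.5, 0.9, 0.99])
    @pytest.mark.parametrize("implicit", [False, True])
    def test_positive_and_nonincreasing(self, theta, implicit):
        x = scalar_relaxation(theta, -1.0, 1.0, 5.0, 0.01, implicit=implicit)
        assert np.all(x > 0)
        assert np.all(np.diff(x) <= 0)

    @pytest.mark.parametrize("theta", [0.5, 0.9])
    def test_matches_laplace_inversion_oracle(self, theta):
        """Both drift modes land on the exact transform solution at t=1."""
        exact = cpc_relaxation_exact(theta, -1.0, 1.0, 1.0)
        for implicit in (False, True):
            approx = scalar_relaxation(theta, -1.0, 1.0, 1.0, 0.005, implicit=implicit)[-1]
            assert approx == pytest.approx(exact, abs=5e-3)

    def test_explicit_error_shrinks_with_step(self):
        exact = cpc_relaxation_exact(0.5, -1.0, 1.0, 1.0)
        errs = [
            abs(scalar_relaxation(0.5, -1.0, 1.0, 1.0, dt)[-1] - exact)
            for dt in (0.02, 0.01, 0.005)
        ]
        assert errs[0] > errs[1] > errs[2]


class TestCpcStep:
    def test_one_step_hand_expansion(self):
        """At n=0 the update depends only on x₀, f₀, ϖ₁, κ₁, r₁."""
        theta, dt, x0, f0 = 0.5, 0.01, 2.0, -3.0
        table = gl_weight_table(theta, 2)
        kern = CPCKernelConfig(theta=theta)
        got = cpc_step(np.array([x0]), table, kern, dt, f0)
        V0, V1 = theta, 1 - theta
        a = V1 * dt ** (1 - theta)
        b = V0 * dt ** (-theta)
        varpi1 = 1 - theta
        kappa1 = theta
        r1 = 1.0 / math.gamma(1 - theta)
        expected = (f0 - a * varpi1 * x0 + b * (kappa1 * x0 + r1 * x0)) / (a + b)
        assert got == pytest.approx(expected, rel=1e-14)

    def test_pivot_positive_across_orders(self):
        for theta in np.linspace(0.01, 1.0, 25):
            k = CPCKernelConfig(theta=float(theta))
            pi = 0.01
            assert k.V1(theta) * pi ** (1 - theta) + k.V0(theta) * pi**-theta > 0

    def test_kernel_classical_values(self):
        k = CPCKernelConfig(theta=1.0, Q=1.0)
        assert k.V0(1.0) == 1.0 and k.V1(1.0) == 0.0

    def test_variable_config_requires_theta_override(self):
        kern = CPCKernelConfig(theta=lambda t: 0.5)
        with pytest.raises(ValueError):
            cpc_step(np.array([1.0]), gl_weight_table(0.5, 2), kern, 0.01, 0.0)


class TestSystemSolvers:
    def test_history_restart_reproduces_continuation(self, params, y0):
        """Re-feeding the stored history at step k continues the original run."""
        kern = CPCKernelConfig(theta=0.9)
        tr = solve_constant_order(params, kern, y0, 0.0, 2.0, 0.01)
        k = 120
        n_total = len(tr.times) - 1
        table = gl_weight_table(0.9, n_total)
        states = np.empty_like(tr.states)
        states[: k + 1] = tr.states[: k + 1]
        from cpcsim.model import drift

        for n in range(k, n_total):
            states[n + 1] = cpc_step(states[: n + 1], table, kern, 0.01,
                                     drift(states[n], params))
        np.testing.assert_array_equal(states, tr.states)

    def test_variable_constant_reduction_matches_exactly(self, params, y0):
        """θ(t) ≡ θ reproduces the constant-order solve (matched drift mode)."""
        for mode in ("explicit", "implicit"):
            tc = solve_constant_order(params, CPCKernelConfig(theta=0.9), y0,
                                      0.0, 3.0, 0.01, drift_mode=mode)
            tv = solve_variable_order(params, CPCKernelConfig(theta=lambda t: 0.9), y0,
                                      0.0, 3.0, 0.01, drift_mode=mode)
            assert np.max(np.abs(tc.states - tv.states)) <= 1e-12 * np.max(np.abs(tc.states))

    def test_small_variable_order_completes_implicitly(self, params, y0):
        """θ(t) = 0.01 − 0.001·cos(t) stays finite under the implicit drift."""
        kern = CPCKernelConfig(theta=lambda t: 0.01 - 0.001 * math.cos(t))
        tr = solve_variable_order(params, kern, y0, 30.0, 33.0, 0.01)
        assert np.all(np.isfinite(tr.states))

    def test_small_variable_order_explicit_diverges(self, params, y0):
        """Documented stiffness: explicit drift is unstable at θ(t) ≈ 0.01."""
        kern = CPCKernelConfig(theta=lambda t: 0.01 - 0.001 * math.cos(t))
        with pytest.raises(DivergenceError):
            with np.errstate(all="ignore"):
                solve_variable_order(params, kern, y0, 30.0, 40.0, 0.01,
                                     drift_mode="explicit")

    def test_order_function_out_of_domain_names_time(self, params, y0):
        kern = CPCKernelConfig(theta=lambda t: 1.5 if t > 1.0 else 0.5)
        with pytest.raises(OrderDomainError, match="t ="):
            solve_variable_order(params, kern, y0, 0.0, 2.0, 0.01)

    def test_deterministic_repeatability(self, params, y0):
        kern = CPCKernelConfig(theta=0.95)
        a = solve_constant_order(params, kern, y0, 0.0, 2.0, 0.01)
        b = solve_constant_order(params, kern, y0, 0.0, 2.0, 0.01)
        np.testing.assert_array_equal(a.states, b.states)


class TestTrajectory:
    def test_csv_round_trip(self, params, y0, tmp_path):
        import pandas as pd

        tr = solve_constant_order(params, CPCKernelConfig(theta=1.0), y0, 0.0, 1.0, 0.1)
        path = tmp_path / "traj.csv"
        tr.to_csv(path)
        df = pd.read_csv(path)
        np.testing.assert_allclose(df[list(Trajectory.COLUMNS)].to_numpy(), tr.states,
                                   rtol=1e-15)
        assert list(df["regime"].unique()) == ["cpc-constant"]

    def test_concatenate_rejects_discontinuity(self):
        t1 = Trajectory([0.0, 1.0], np.ones((2, 5)), ["a", "a"])
        t2 = Trajectory([1.0, 2.0], 2 * np.ones((2, 5)), ["b", "b"])
        with pytest.raises(ValueError, match="continuity"):
            Trajectory.concatenate([t1, t2])
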