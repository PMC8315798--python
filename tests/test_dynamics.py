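"""Transfer function, gain modulation, drift, fixed point, and FIC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurogain import GainModulation, ModelParameters, make_connectome, SyntheticSpec
from neurogain.connectome import StructuralConnectome
from neurogain.dynamics import (
    apply_fic,
    drift,
    modulate_gain,
    solve_fixed_point,
    synaptic_jacobian,
    transfer_rate,
)

P = ModelParameters()


class TestTransferRate:
    def test_removable_singularity_limit(self):
        # at a*I = b the rate equals 1/d (6.25 Hz for excitatory constants)
        I = P.b_E / P.a_E
        assert transfer_rate(I, P.a_E, P.b_E, P.d_E) == pytest.approx(1 / P.d_E, abs=1e-9)

    def test_continuity_around_singularity(self):
        I0 = P.b_E / P.a_E
        for eps in (-1e-9, 1e-9):
            r = transfer_rate(I0 + eps, P.a_E, P.b_E, P.d_E)
            assert abs(r - 1 / P.d_E) < 1e-6

    def test_asymptotically_linear(self):
        I = 100.0
        u = P.a_E * I - P.b_E
        assert transfer_rate(I, P.a_E, P.b_E, P.d_E) / u == pytest.approx(1.0, rel=1e-12)

    def test_background_current_rate(self):
        # high-precision scalar evaluation at the background current
        assert transfer_rate(0.382, P.a_E, P.b_E, P.d_E) == pytest.approx(
            3.5268949118680327, rel=1e-12
        )

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            transfer_rate(np.nan, P.a_E, P.b_E, P.d_E)

    @given(st.floats(-0.5, 2.0), st.floats(-0.5, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_positive_and_increasing(self, i1, i2):
        r1 = transfer_rate(i1, P.a_E, P.b_E, P.d_E)
        r2 = transfer_rate(i2, P.a_E, P.b_E, P.d_E)
        assert r1 > 0 and r2 > 0
        if i1 + 1e-9 < i2:
            assert r1 < r2


class TestModulateGain:
    def test_zero_h_returns_baseline_bitwise(self):
        mod = GainModulation(h=np.zeros(4), delta_E=0.02, delta_I=0.01)
        aE, aI = modulate_gain(P, mod)
        assert np.all(aE == P.a_E) and np.all(aI == P.a_I)

    def test_zero_delta_returns_baseline_bitwise(self):
        mod = GainModulation(h=np.linspace(0, 1, 4))
        aE, aI = modulate_gain(P, mod)
        assert np.all(aE == P.a_E) and np.all(aI == P.a_I)

    def test_full_weight_scaling(self):
        mod = GainModulation(h=np.ones(3), delta_E=0.03)
        aE, _ = modulate_gain(P, mod)
        assert aE == pytest.approx(1.03 * 310.0)

    def test_negative_gain_rejected(self):
        mod = GainModulation(h=np.ones(2), delta_E=-1.5)
        with pytest.raises(ValueError):
            modulate_gain(P, mod)


class TestDrift:
    def test_matches_scalar_loop(self, rng):
        """Vectorized drift equals an independent hand-coded scalar loop."""
        spec = SyntheticSpec(n_nodes=5, seed=3)
        sc = make_connectome(spec)
        p = ModelParameters(G=0.7)
        S_E = rng.uniform(0, 1, 5)
        S_I = rng.uniform(0, 1, 5)
        dE, dI = drift(S_E, S_I, sc, p)

        def phi(I, a, b, d):
            u = a * I - b
            return u / (1 - np.exp(-d * u))

        for i in range(5):
            lr = sum(sc.C[i, j] * S_E[j] for j in range(5))
            I_E = p.W_E * p.Ib + p.w_EE * S_E[i] + p.G * p.J * lr - p.w_EI * S_I[i]
            I_I = p.W_I * p.Ib + p.w_IE * S_E[i] - S_I[i]
            expect_E = -S_E[i] / p.tau_E + (1 - S_E[i]) * p.gamma_kin * phi(I_E, p.a_E, p.b_E, p.d_E)
            expect_I = -S_I[i] / p.tau_I + phi(I_I, p.a_I, p.b_I, p.d_I)
            assert dE[i] == pytest.approx(expect_E, rel=1e-12)
            assert dI[i] == pytest.approx(expect_I, rel=1e-12)

    def test_zero_at_fixed_point(self, sc10, params, fic10, steady10):
        dE, dI = drift(steady10.S_E, steady10.S_I, sc10, params, w_EI=fic10)
        assert np.max(np.abs(np.concatenate([dE, dI]))) < 1e-10

    def test_gating_cannot_exceed_one(self, sc10, params, fic10):
        S_E = np.ones(10)
        S_I = np.full(10, 0.05)
        dE, _ = drift(S_E, S_I, sc10, params, w_EI=fic10)
        assert np.all(dE < 0)

    def test_dimension_mismatch(self, sc10, params):
        with pytest.raises(ValueError):
            drift(np.zeros(3), np.zeros(3), sc10, params)


class TestFixedPoint:
    def test_explicit_zero_gains_bit_identical(self, sc10, params, fic10, steady10):
        gains = GainModulation(h=np.zeros(10), delta_E=0.0, delta_I=0.0)
        ss = solve_fixed_point(sc10, params, gains, w_EI=fic10)
        assert np.array_equal(ss.S_E, steady10.S_E)
        assert np.array_equal(ss.S_I, steady10.S_I)

    def test_isolated_node_fic_rate(self):
        """With G = 0 and FIC-tuned inhibition, each node fires at 3 Hz."""
        spec = SyntheticSpec(n_nodes=5, seed=2)
        sc = make_connectome(spec)
        p = ModelParameters(G=0.0)
        w = apply_fic(sc, p)
        ss = solve_fixed_point(sc, p, w_EI=w)
        assert np.allclose(ss.r_E, 3.0, atol=1e-8)

    def test_agrees_with_forward_integration(self, sc10, params, fic10, steady10):
        """Long noise-free integration lands on the solver's fixed point."""
        from neurogain import simulate_sde

        p = params.replace(sigma=0.0)
        # start integration slightly off the fixed point
        init = solve_fixed_point(sc10, p, w_EI=fic10)
        bold, se = simulate_sde(
            sc10, p, T=120.0, seed=0, w_EI=fic10, burn=100.0, sample_dt=1.0
        )
        assert np.max(np.abs(se[-1] - steady10.S_E)) < 1e-6

    def test_residual_below_tolerance(self, sc30, params, fic30, steady30):
        dE, dI = drift(steady30.S_E, steady30.S_I, sc30, params, w_EI=fic30)
        assert np.max(np.abs(np.concatenate([dE, dI]))) < 1e-10
        assert steady30.stable

    def test_nonconvergence_raises(self, sc10, params):
        # iteration budget too small to converge from a distant start
        with pytest.raises(RuntimeError, match="fixed point not found"):
            solve_fixed_point(
                sc10, params, init=(np.full(10, 0.99), np.zeros(10)), max_iter=1
            )


class TestFIC:
    def test_rates_pinned_at_target(self, sc30, params, fic30, steady30):
        assert np.allclose(steady30.r_E, 3.0, atol=1e-6)

    def test_symmetric_nodes_equal_weights(self):
        """Two identical, symmetrically coupled nodes get identical w_EI."""
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        sc = StructuralConnectome.from_weights(C + 1e-12)
        w = apply_fic(sc, ModelParameters(G=0.3))
        assert w[0] == pytest.approx(w[1], rel=1e-12)

    def test_matches_iterative_tuning(self, params):
        """Analytic FIC equals a slow adjust-and-resolve tuning loop."""
        spec = SyntheticSpec(n_nodes=20, seed=4)
        sc = make_connectome(spec)
        w_analytic = apply_fic(sc, params)
        w = np.full(20, 1.0)
        for _ in range(200):
            ss = solve_fixed_point(sc, params, w_EI=w)
            err = ss.r_E - 3.0
            if np.max(np.abs(err)) < 1e-9:
                break
            w *= 1 + 0.02 * err
        assert np.allclose(w, w_analytic, atol=1e-6)

    def test_jacobian_matches_finite_differences(self, sc10, params, fic10, steady10):
        J = synaptic_jacobian(steady10.S_E, steady10.S_I, sc10, params, w_EI=fic10)
        z0 = np.concatenate([steady10.S_E, steady10.S_I])
        eps = 1e-7

        def F(z):
            dE, dI = drift(z[:10], z[10:], sc10, params, w_EI=fic10)
            return np.concatenate([dE, dI])

        J_fd = np.empty((20, 20))
        for k in range(20):
            e = np.zeros(20)
            e[k] = eps
            J_fd[:, k] = (F(z0 + e) - F(z0 - e)) / (2 * eps)
        assert np.allclose(J, J_fd, rtol=1e-5, atol=1e-5)
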