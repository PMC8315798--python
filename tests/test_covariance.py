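"""Linearization, Lyapunov covariance, BOLD propagation, analytic GSR."""

import numpy as np
import pytest

from neurogain import (
    GainModulation,
    HemodynamicParameters,
    ModelParameters,
    bold_covariance,
    build_jacobian,
    gsr_covariance,
    model_bold_covariance,
    solve_state_covariance,
)
from neurogain.covariance import build_bold_gradient, build_noise_covariance
from neurogain.dynamics import drift as syn_drift
from neurogain.hemodynamics import HemodynamicState, bold_partials, hemo_drift, hemo_steady_state

HP = HemodynamicParameters()


def combined_drift(z, sc, params, w_EI, hp):
    """Full 6N drift in node-major ordering, for finite differencing."""
    n = sc.n_nodes
    Z = z.reshape(n, 6)
    S_E, S_I = Z[:, 0], Z[:, 1]
    dE, dI = syn_drift(S_E, S_I, sc, params, w_EI=w_EI)
    hstate = HemodynamicState(x=Z[:, 2], f=Z[:, 3], v=Z[:, 4], q=Z[:, 5])
    dh = hemo_drift(hstate, S_E, hp)
    out = np.empty_like(Z)
    out[:, 0], out[:, 1] = dE, dI
    out[:, 2], out[:, 3], out[:, 4], out[:, 5] = dh.x, dh.f, dh.v, dh.q
    return out.ravel()


class TestJacobian:
    def test_matches_finite_differences(self, sc10, params, fic10, steady10):
        hss = hemo_steady_state(steady10.S_E, HP)
        A = build_jacobian(steady10, hss, sc10, params, hp=HP, w_EI=fic10)
        z0 = np.stack(
            [steady10.S_E, steady10.S_I, hss.x, hss.f, hss.v, hss.q], axis=1
        ).ravel()
        eps = 1e-6
        A_fd = np.empty_like(A)
        for k in range(z0.size):
            e = np.zeros_like(z0)
            e[k] = eps
            A_fd[:, k] = (
                combined_drift(z0 + e, sc10, params, fic10, HP)
                - combined_drift(z0 - e, sc10, params, fic10, HP)
            ) / (2 * eps)
        scale = np.max(np.abs(A))
        assert np.max(np.abs(A - A_fd)) / scale < 1e-6

    def test_hurwitz_at_operating_point(self, sc10, params, fic10, steady10):
        hss = hemo_steady_state(steady10.S_E, HP)
        A = build_jacobian(steady10, hss, sc10, params, hp=HP, w_EI=fic10)
        assert np.max(np.linalg.eigvals(A).real) < 0

    def test_hemodynamics_blind_to_inhibition(self, sc10, params, fic10, steady10):
        """x, f, v, q rows have zero partials with respect to S_I."""
        hss = hemo_steady_state(steady10.S_E, HP)
        A = build_jacobian(steady10, hss, sc10, params, hp=HP, w_EI=fic10)
        n = sc10.n_nodes
        si_cols = [6 * i + 1 for i in range(n)]
        hemo_rows = [6 * i + k for i in range(n) for k in (2, 3, 4, 5)]
        assert np.all(A[np.ix_(hemo_rows, si_cols)] == 0)


class TestLyapunov:
    def test_scalar_ou_closed_form(self):
        theta, sigma = 1.7, 0.3
        P = solve_state_covariance(np.array([[-theta]]), np.array([[sigma**2]]))
        assert P[0, 0] == pytest.approx(sigma**2 / (2 * theta), rel=1e-12)

    def test_diagonal_system_diagonal_covariance(self, rng):
        a = -rng.uniform(0.5, 2.0, 6)
        q = rng.uniform(0.1, 1.0, 6)
        P = solve_state_covariance(np.diag(a), np.diag(q))
        assert np.allclose(P, np.diag(np.diag(P)), atol=1e-12)
        assert np.allclose(np.diag(P), q / (-2 * a), rtol=1e-12)

    def test_residual_on_random_stable_systems(self, rng):
        for _ in range(5):
            B = rng.standard_normal((12, 12))
            A = B - (np.max(np.linalg.eigvals(B).real) + 1.0) * np.eye(12)
            L = rng.standard_normal((12, 12)) * 0.3
            Q = L @ L.T
            P = solve_state_covariance(A, Q)
            resid = np.max(np.abs(A @ P + P @ A.T + Q))
            assert resid < 1e-8 * np.max(np.abs(Q))
            assert np.min(np.linalg.eigvalsh(P)) > -1e-10

    def test_matches_linear_sde_ensemble(self, rng):
        """Stationary covariance agrees with a simulated linear SDE."""
        m = 6
        B = rng.standard_normal((m, m))
        A = B - (np.max(np.linalg.eigvals(B).real) + 1.0) * np.eye(m)
        sig = 0.5
        Q = sig**2 * np.eye(m)
        P = solve_state_covariance(A, Q)
        # many parallel paths, Euler-Maruyama
        n_paths, dt, n_steps = 4000, 2e-3, 4000
        X = np.zeros((m, n_paths))
        for _ in range(n_steps):
            X += dt * (A @ X) + sig * np.sqrt(dt) * rng.standard_normal((m, n_paths))
        S = np.cov(X)
        assert np.max(np.abs(S - P)) < 0.15 * np.max(np.abs(P))

    def test_unstable_system_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            solve_state_covariance(np.array([[0.1]]), np.array([[1.0]]))


class TestBoldCovariance:
    def test_zero_gradient_gives_zero(self, rng):
        P = np.eye(12)
        assert np.all(bold_covariance(P, np.zeros((2, 12))) == 0)

    def test_single_node_scalar_expansion(self, rng):
        """P_BOLD = kv^2 Pvv + 2 kv kq Pvq + kq^2 Pqq for one node."""
        L = rng.standard_normal((6, 6))
        P = L @ L.T
        hss = hemo_steady_state(0.16, HP)
        K = build_bold_gradient(hss, HP)
        kv, kq = (float(a[0]) for a in bold_partials(hss.v, hss.q, HP))
        expect = kv**2 * P[4, 4] + 2 * kv * kq * P[4, 5] + kq**2 * P[5, 5]
        assert bold_covariance(P, K)[0, 0] == pytest.approx(expect, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            bold_covariance(np.eye(12), np.zeros((2, 10)))

    def test_noise_covariance_layout(self):
        Q = build_noise_covariance(3, 0.2)
        d = np.diag(Q)
        assert np.allclose(d[[0, 1, 6, 7, 12, 13]], 0.04)
        assert np.allclose(d[[2, 3, 4, 5, 8, 9, 10, 11, 14, 15, 16, 17]], 0.0)


class TestGSR:
    def test_row_sums_zero(self, rng):
        L = rng.standard_normal((8, 8))
        C = L @ L.T
        out = gsr_covariance(C)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-12)

    def test_identity_two_by_two(self):
        out = gsr_covariance(np.eye(2))
        assert np.allclose(out, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-15)

    def test_matches_time_domain_regression(self, rng):
        """Covariance-domain GSR equals regressing out the mean signal."""
        Y = rng.standard_normal((5000, 6)) @ rng.standard_normal((6, 6))
        C = np.cov(Y.T)
        x = Y.sum(axis=1)
        xc = x - x.mean()
        beta = (Y - Y.mean(0)).T @ xc / (xc @ xc)
        resid = Y - Y.mean(0) - np.outer(xc, beta)
        C_resid = resid.T @ resid / (Y.shape[0] - 1)
        assert np.max(np.abs(gsr_covariance(C) - C_resid)) < 1e-10

    def test_idempotent(self, rng):
        L = rng.standard_normal((7, 7))
        C = L @ L.T
        once = gsr_covariance(C)
        twice = gsr_covariance(once + 1e-18 * np.eye(7)) if once.sum() != 0 else once
        # the global signal of residuals is exactly zero; re-applying with a
        # vanishing ridge to dodge the degenerate-total check changes nothing
        assert np.allclose(once, twice, atol=1e-9)

    def test_degenerate_total_rejected(self):
        C = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValueError):
            gsr_covariance(C)


class TestSigmaInvariance:
    def test_correlations_independent_of_noise_scale(self, sc10, params, fic10, steady10):
        from neurogain.metrics import cov_to_fc

        fcs = []
        for sig in (0.02, 0.005):
            p = params.replace(sigma=sig)
            res = model_bold_covariance(steady10, sc10, p, w_EI=fic10)
            fcs.append(cov_to_fc(res.P_BOLD))
        assert np.max(np.abs(fcs[0] - fcs[1])) < 1e-12
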