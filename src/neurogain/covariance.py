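"""Semi-analytic BOLD covariance via linearization around the fixed point.

The full per-node state is six-dimensional — two synaptic gating variables
(S_E, S_I) and four hemodynamic variables (x, f, v, q). Linearizing the
coupled drift around the stable operating point gives a 6N x 6N Jacobian
A; with white noise of covariance Q_N entering the gating equations, the
stationary state covariance P solves the continuous Lyapunov equation

    A P + P A^T + Q_N = 0,

and the BOLD covariance follows by propagating through the linearized
observation map, P_BOLD = K P K^T, where K holds the partial derivatives
of the BOLD readout (nonzero only in the v and q columns).

Global signal regression (GSR) is applied analytically on the covariance:
with the global signal defined as the sum of regional signals, the
covariance of regression residuals is

    Cov(e_i, e_j) = C_ij - (sum_k C_ik)(sum_l C_jl) / sum_mn C_mn,

whose rows sum identically to zero.

State ordering convention: node-major, i.e. node i occupies rows
6*i .. 6*i+5 in the order (S_E, S_I, x, f, v, q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .connectome import StructuralConnectome
from .dynamics import SteadyState, synaptic_jacobian
from .hemodynamics import HemodynamicState, bold_partials, hemo_steady_state
from .parameters import GainModulation, HemodynamicParameters, ModelParameters

__all__ = [
    "CovarianceResult",
    "build_jacobian",
    "build_noise_covariance",
    "build_bold_gradient",
    "solve_state_covariance",
    "bold_covariance",
    "gsr_covariance",
    "model_bold_covariance",
]

N_STATE = 6  # per-node state dimension


def _node_major_permutation(n: int) -> np.ndarray:
    """Map from variable-major [S_E(:), S_I(:), x(:), f(:), v(:), q(:)] to
    node-major [node0(S_E,S_I,x,f,v,q), node1(...), ...] indexing."""
    idx = np.empty(N_STATE * n, dtype=int)
    for i in range(n):
        for k in range(N_STATE):
            idx[N_STATE * i + k] = k * n + i
    return idx


def build_jacobian(
    ss: SteadyState,
    hemo_ss: HemodynamicState,
    sc: StructuralConnectome,
    params: ModelParameters,
    gains: GainModulation | None = None,
    hp: HemodynamicParameters | None = None,
    w_EI=None,
) -> np.ndarray:
    """Analytic 6N x 6N Jacobian of the coupled drift at the fixed point."""
    if not ss.stable:
        raise ValueError("fixed point is unstable; covariance undefined")
    if hp is None:
        hp = HemodynamicParameters()
    n = sc.n_nodes
    A = np.zeros((N_STATE * n, N_STATE * n))

    # synaptic block (2N x 2N, variable-major within itself)
    J_syn = synaptic_jacobian(ss.S_E, ss.S_I, sc, params, gains, w_EI)
    A[: 2 * n, : 2 * n] = J_syn

    f, v, q = hemo_ss.f, hemo_ss.v, hemo_ss.q
    al, tau = hp.alpha, hp.tau_h
    c = 1.0 - hp.rho
    sl = slice
    iSE, ix, if_, iv, iq = (
        sl(0, n),
        sl(2 * n, 3 * n),
        sl(3 * n, 4 * n),
        sl(4 * n, 5 * n),
        sl(5 * n, 6 * n),
    )
    eye = np.eye(n)
    # dx/dt = S_E - kappa*x - gamma_h*(f-1)
    A[ix, iSE] = eye
    A[ix, ix] = -hp.kappa * eye
    A[ix, if_] = -hp.gamma_h * eye
    # df/dt = x
    A[if_, ix] = eye
    # tau*dv/dt = f - v**(1/alpha)
    A[iv, if_] = eye / tau
    A[iv, iv] = np.diag(-(1.0 / al) * v ** (1.0 / al - 1.0) / tau)
    # tau*dq/dt = f*(1-c**(1/f))/rho - q*v**((1-al)/al)
    dm_df = (1.0 - c ** (1.0 / f) * (1.0 - np.log(c) / f)) / hp.rho
    A[iq, if_] = np.diag(dm_df / tau)
    A[iq, iv] = np.diag(-q * ((1.0 - al) / al) * v ** ((1.0 - al) / al - 1.0) / tau)
    A[iq, iq] = np.diag(-(v ** ((1.0 - al) / al)) / tau)

    perm = _node_major_permutation(n)
    return A[np.ix_(perm, perm)]


def build_noise_covariance(n: int, sigma: float) -> np.ndarray:
    """Diagonal noise covariance: sigma^2 on the gating rows, zero elsewhere."""
    Q = np.zeros(N_STATE * n)
    Q[0::N_STATE] = sigma**2  # S_E rows
    Q[1::N_STATE] = sigma**2  # S_I rows
    return np.diag(Q)


def build_bold_gradient(hemo_ss: HemodynamicState, hp: HemodynamicParameters) -> np.ndarray:
    """N x 6N matrix K of BOLD partial derivatives at the hemodynamic fixed point."""
    n = hemo_ss.v.size
    dy_dv, dy_dq = bold_partials(hemo_ss.v, hemo_ss.q, hp)
    K = np.zeros((n, N_STATE * n))
    for i in range(n):
        K[i, N_STATE * i + 4] = dy_dv[i]
        K[i, N_STATE * i + 5] = dy_dq[i]
    return K


def solve_state_covariance(A: np.ndarray, Q_N: np.ndarray) -> np.ndarray:
    """Stationary covariance from the continuous Lyapunov equation.

    Requires A Hurwitz (all eigenvalues in the open left half-plane).
    """
    eig = np.linalg.eigvals(A)
    if np.max(eig.real) >= 0:
        raise ValueError("system unstable; reduce G or delta")
    P = solve_continuous_lyapunov(A, -np.asarray(Q_N, dtype=float))
    P = (P + P.T) / 2.0
    resid = np.max(np.abs(A @ P + P @ A.T + Q_N))
    scale = max(np.max(np.abs(Q_N)), 1e-300)
    if resid > 1e-8 * scale:
        raise RuntimeError(f"Lyapunov residual too large: {resid:.3e}")
    return P


def bold_covariance(P: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Propagate the state covariance through the linearized BOLD readout."""
    P = np.asarray(P, dtype=float)
    K = np.asarray(K, dtype=float)
    if K.shape[1] != P.shape[0]:
        raise ValueError("K columns must match P dimension")
    PB = K @ P @ K.T
    return (PB + PB.T) / 2.0


def gsr_covariance(P_BOLD: np.ndarray) -> np.ndarray:
    """Analytic global signal regression on a covariance matrix.

    Output rows (and columns) sum to zero; applying the map twice equals
    applying it once.
    """
    C = np.asarray(P_BOLD, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    rows = C.sum(axis=1)
    total = rows.sum()
    if total == 0:
        raise ValueError("total covariance is zero; global signal degenerate")
    out = C - np.outer(rows, rows) / total
    return (out + out.T) / 2.0


@dataclass
class CovarianceResult:
    """Bundle of the linearized-covariance pipeline outputs."""

    A: np.ndarray
    Q_N: np.ndarray
    P: np.ndarray
    K: np.ndarray
    P_BOLD: np.ndarray


def model_bold_covariance(
    ss: SteadyState,
    sc: StructuralConnectome,
    params: ModelParameters,
    gains: GainModulation | None = None,
    hp: HemodynamicParameters | None = None,
    w_EI=None,
) -> CovarianceResult:
    """Fixed point -> Jacobian -> Lyapunov -> BOLD covariance, in one call."""
    if hp is None:
        hp = HemodynamicParameters()
    hemo_ss = hemo_steady_state(ss.S_E, hp)
    A = build_jacobian(ss, hemo_ss, sc, params, gains, hp, w_EI)
    Q_N = build_noise_covariance(sc.n_nodes, params.sigma)
    P = solve_state_covariance(A, Q_N)
    K = build_bold_gradient(hemo_ss, hp)
    P_BOLD = bold_covariance(P, K)
    return CovarianceResult(A=A, Q_N=Q_N, P=P, K=K, P_BOLD=P_BOLD)
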