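"""Coupled excitatory-inhibitory mean-field dynamics on a connectome.

Each node holds one excitatory (E) and one inhibitory (I) population with
synaptic gating variables S_E, S_I. Currents combine background drive,
local recurrence, long-range excitation routed through the connectome, and
local inhibitory feedback:

    I_E = W_E*Ib + w_EE*S_E + G*J*(C @ S_E) - w_EI*S_I
    I_I = W_I*Ib + w_IE*S_E - S_I

Currents map to population rates through the soft-rectifying transfer
function phi(I) = (a*I - b)/(1 - exp(-d*(a*I - b))), and gating evolves as

    dS_E/dt = -S_E/tau_E + (1 - S_E)*gamma*r_E   (+ noise)
    dS_I/dt = -S_I/tau_I + r_I                    (+ noise)

Neural gain modulation rescales the slope parameter a per node and cell
type in proportion to a receptor-density proxy map. Feedback inhibition
control (FIC) tunes the per-node inhibitory weight w_EI so that baseline
excitatory rates sit at a common 3 Hz target before any gain modulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .connectome import StructuralConnectome
from .parameters import GainModulation, ModelParameters

__all__ = [
    "transfer_rate",
    "transfer_rate_slope",
    "modulate_gain",
    "synaptic_currents",
    "drift",
    "SteadyState",
    "solve_fixed_point",
    "synaptic_jacobian",
    "apply_fic",
    "FIC_RATE_TARGET",
]

FIC_RATE_TARGET = 3.0  # Hz; baseline excitatory rate enforced by FIC

# |d*(a*I-b)| below which the removable singularity of phi is evaluated by
# Taylor series; the quartic term keeps the switch transparent to 1e-16.
_SERIES_CUTOFF = 1e-4


def _phi_of_u(u: np.ndarray, d: float) -> np.ndarray:
    """phi expressed in the shifted variable u = a*I - b."""
    u = np.asarray(u, dtype=float)
    x = d * u
    small = np.abs(x) < _SERIES_CUTOFF
    xs = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):
        direct = u / (1.0 - np.exp(-xs))
    series = (1.0 + x / 2.0 + x**2 / 12.0 - x**4 / 720.0) / d
    return np.where(small, series, direct)


def _dphi_du(u: np.ndarray, d: float) -> np.ndarray:
    """Derivative of phi with respect to u = a*I - b."""
    u = np.asarray(u, dtype=float)
    x = d * u
    small = np.abs(x) < _SERIES_CUTOFF
    xs = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):
        e = np.exp(-xs)
        direct = (1.0 - e - xs * e) / (1.0 - e) ** 2
    series = 0.5 + x / 6.0 - x**3 / 180.0
    return np.where(small, series, direct)


def transfer_rate(current, a: float, b: float, d: float):
    """Population firing rate (Hz) for synaptic current (nA).

    Continuous at the removable singularity a*I = b, where the rate equals
    1/d; strictly positive and strictly increasing in the current.
    """
    if a <= 0 or d <= 0:
        raise ValueError("transfer-function constants a and d must be positive")
    current = np.asarray(current, dtype=float)
    if not np.all(np.isfinite(current)):
        raise ValueError("current must be finite")
    out = _phi_of_u(a * current - b, d)
    return out if out.ndim else float(out)


def transfer_rate_slope(current, a: float, b: float, d: float):
    """d(rate)/d(current): the chain rule a * phi'(u) at u = a*I - b."""
    current = np.asarray(current, dtype=float)
    out = a * _dphi_du(a * current - b, d)
    return out if out.ndim else float(out)


def modulate_gain(
    params: ModelParameters, mod: GainModulation
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node gain constants (a_E, a_I) under receptor-weighted modulation.

    a_i^p = (1 + h_i * delta_p) * a0^p. With delta_E = delta_I = 0 the
    returned arrays equal the baseline constants exactly (bitwise).
    """
    a_E = (1.0 + mod.h * mod.delta_E) * params.a_E
    a_I = (1.0 + mod.h * mod.delta_I) * params.a_I
    if np.any(a_E <= 0) or np.any(a_I <= 0):
        raise ValueError("gain modulation drove a gain constant non-positive")
    return a_E, a_I


def _resolve_wEI(params: ModelParameters, w_EI, n: int) -> np.ndarray:
    w = params.w_EI if w_EI is None else w_EI
    w = np.broadcast_to(np.asarray(w, dtype=float), (n,)).copy()
    return w


def synaptic_currents(
    S_E: np.ndarray,
    S_I: np.ndarray,
    sc: StructuralConnectome,
    params: ModelParameters,
    gains: GainModulation | None = None,
    w_EI=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Excitatory and inhibitory input currents (nA) at the given gating state."""
    S_E = np.asarray(S_E, dtype=float)
    S_I = np.asarray(S_I, dtype=float)
    n = sc.n_nodes
    if S_E.shape != (n,) or S_I.shape != (n,):
        raise ValueError("gating vectors must have one entry per node")
    w = _resolve_wEI(params, w_EI, n)
    I_E = params.W_E * params.Ib + params.w_EE * S_E + params.G * params.J * (sc.C @ S_E) - w * S_I
    I_I = params.W_I * params.Ib + params.w_IE * S_E - S_I
    return I_E, I_I


def drift(
    S_E: np.ndarray,
    S_I: np.ndarray,
    sc: StructuralConnectome,
    params: ModelParameters,
    gains: GainModulation | None = None,
    w_EI=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free time derivatives (dS_E/dt, dS_I/dt) of the gating variables."""
    n = sc.n_nodes
    if gains is None:
        gains = GainModulation.none(n)
    a_E, a_I = modulate_gain(params, gains)
    I_E, I_I = synaptic_currents(S_E, S_I, sc, params, gains, w_EI)
    r_E = _phi_of_u(a_E * I_E - params.b_E, params.d_E)
    r_I = _phi_of_u(a_I * I_I - params.b_I, params.d_I)
    dS_E = -S_E / params.tau_E + (1.0 - S_E) * params.gamma_kin * r_E
    dS_I = -S_I / params.tau_I + r_I
    return dS_E, dS_I


@dataclass
class SteadyState:
    """Noise-free fixed point of the synaptic system.

    Gating fractions, firing rates and currents per node, plus a stability
    flag derived from the spectrum of the synaptic Jacobian.
    """

    S_E: np.ndarray
    S_I: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray
    I_E: np.ndarray
    I_I: np.ndarray
    stable: bool


def synaptic_jacobian(
    S_E: np.ndarray,
    S_I: np.ndarray,
    sc: StructuralConnectome,
    params: ModelParameters,
    gains: GainModulation | None = None,
    w_EI=None,
) -> np.ndarray:
    """Analytic 2N x 2N Jacobian of the gating drift, state order (S_E, S_I)."""
    n = sc.n_nodes
    if gains is None:
        gains = GainModulation.none(n)
    a_E, a_I = modulate_gain(params, gains)
    w = _resolve_wEI(params, w_EI, n)
    I_E, I_I = synaptic_currents(S_E, S_I, sc, params, gains, w_EI)
    r_E = _phi_of_u(a_E * I_E - params.b_E, params.d_E)
    r_I = _phi_of_u(a_I * I_I - params.b_I, params.d_I)
    # d(rate)/d(current) with per-node gain constants
    sl_E = a_E * _dphi_du(a_E * I_E - params.b_E, params.d_E)
    sl_I = a_I * _dphi_du(a_I * I_I - params.b_I, params.d_I)

    g = params.gamma_kin
    pref = (1.0 - S_E) * g  # multiplies d r_E/d(state)
    dIE_dSE = params.w_EE * np.eye(n) + params.G * params.J * sc.C
    J_EE = -np.eye(n) / params.tau_E - np.diag(g * r_E) + pref[:, None] * sl_E[:, None] * dIE_dSE
    J_EI = np.diag(pref * sl_E * (-w))
    J_IE = np.diag(sl_I * params.w_IE)
    J_II = -np.eye(n) / params.tau_I + np.diag(sl_I * (-1.0))
    return np.block([[J_EE, J_EI], [J_IE, J_II]])


def solve_fixed_point(
    sc: StructuralConnectome,
    params: ModelParameters,
    gains: GainModulation | None = None,
    w_EI=None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> SteadyState:
    """Solve for the noise-free fixed point by damped Newton iteration.

    Falls back to damped fixed-point iteration if a Newton step cannot
    reduce the residual. Raises if the residual never drops below ``tol``.
    """
    n = sc.n_nodes
    if gains is None:
        gains = GainModulation.none(n)
    if init is None:
        S_E = np.full(n, 0.1)
        S_I = np.full(n, 0.1)
    else:
        S_E = np.array(init[0], dtype=float)
        S_I = np.array(init[1], dtype=float)

    def residual(z):
        dE, dI = drift(z[:n], z[n:], sc, params, gains, w_EI)
        return np.concatenate([dE, dI])

    def newton(z, iters):
        """Damped Newton; returns (z, converged)."""
        F = residual(z)
        for _ in range(iters):
            err = np.max(np.abs(F))
            if err < tol:
                return z, True
            if not np.isfinite(err) or err > 1e9:
                return z, False
            J = synaptic_jacobian(z[:n], z[n:], sc, params, gains, w_EI)
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                return z, False
            if not np.all(np.isfinite(step)):
                return z, False
            lam, moved = 1.0, False
            for _ in range(25):
                z_new = z + lam * step
                F_new = residual(z_new)
                if np.max(np.abs(F_new)) < err:
                    z, F, moved = z_new, F_new, True
                    break
                lam *= 0.5
            if not moved:
                return z, False
        return z, bool(np.max(np.abs(F)) < tol)

    def relax(z, steps):
        """Noise-free forward relaxation toward the attractor.

        Explicit Euler with a step well below the fastest (inhibitory)
        time constant; the gating bounds are enforced as in the SDE.
        """
        eta = 0.2 * min(params.tau_E, params.tau_I)
        for _ in range(steps):
            F = residual(z)
            if not np.all(np.isfinite(F)):
                raise RuntimeError("fixed point not found: relaxation diverged")
            z = z + eta * F
            z[:n] = np.clip(z[:n], 0.0, 1.0)
            z[n:] = np.maximum(z[n:], 0.0)
            if np.max(np.abs(F)) < 1e-7:
                break
        return z

    z = np.concatenate([S_E, S_I])
    z, ok = newton(z, min(max_iter, 100))
    if not ok:
        # the fixed point may have moved to a different branch (e.g. a
        # high-activity state near a bifurcation): follow the dynamics,
        # then polish with Newton
        z = relax(z, max_iter)
        z, ok = newton(z, min(max_iter, 100))
    if not ok:
        raise RuntimeError("fixed point not found")
    F = residual(z)

    S_E, S_I = z[:n], z[n:]
    a_E, a_I = modulate_gain(params, gains)
    I_E, I_I = synaptic_currents(S_E, S_I, sc, params, gains, w_EI)
    r_E = _phi_of_u(a_E * I_E - params.b_E, params.d_E)
    r_I = _phi_of_u(a_I * I_I - params.b_I, params.d_I)
    J = synaptic_jacobian(S_E, S_I, sc, params, gains, w_EI)
    stable = bool(np.max(np.linalg.eigvals(J).real) < 0)
    return SteadyState(S_E=S_E, S_I=S_I, r_E=r_E, r_I=r_I, I_E=I_E, I_I=I_I, stable=stable)


def _invert_transfer(rate: float, a: float, b: float, d: float) -> float:
    """Current at which phi equals ``rate`` (phi is strictly increasing)."""
    f = lambda u: float(_phi_of_u(u, d)) - rate
    lo, hi = -1e3, 1e3
    u = brentq(f, lo, hi, xtol=1e-14)
    return (u + b) / a


def apply_fic(
    sc: StructuralConnectome,
    params: ModelParameters,
    rate_target: float = FIC_RATE_TARGET,
) -> np.ndarray:
    """Feedback inhibition control: per-node w_EI pinning baseline E rates.

    Computed analytically on the unmodulated model (FIC precedes any gain
    modulation): invert the E transfer function at the target rate, place
    the excitatory gating at its rate-consistent value, solve each node's
    inhibitory fixed point, and read off the w_EI that balances the
    excitatory current budget.
    """
    n = sc.n_nodes
    # target excitatory operating point, identical across nodes
    I_E_star = _invert_transfer(rate_target, params.a_E, params.b_E, params.d_E)
    g, tau = params.gamma_kin, params.tau_E
    S_E_star = g * rate_target * tau / (1.0 + g * rate_target * tau)

    # inhibitory fixed point: S_I = tau_I * phi_I(I_I(S_I)); the drive is
    # uniform because S_E* is uniform, so one scalar root serves all nodes
    drive = params.W_I * params.Ib + params.w_IE * S_E_star

    def si_residual(s):
        u = params.a_I * (drive - s) - params.b_I
        return s - params.tau_I * float(_phi_of_u(u, params.d_I))

    S_I_star = brentq(si_residual, 0.0, 10.0, xtol=1e-15)

    S_E_vec = np.full(n, S_E_star)
    long_range = params.G * params.J * (sc.C @ S_E_vec)
    w_EI = (params.W_E * params.Ib + params.w_EE * S_E_star + long_range - I_E_star) / S_I_star
    if np.any(w_EI <= 0):
        raise ValueError("FIC produced non-positive inhibitory feedback weight")
    return w_EI
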