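"""Balloon-Windkessel hemodynamic model and BOLD observation equation.

Excitatory synaptic gating drives a per-node vasodilatory cascade: signal
x, blood inflow f, venous volume v, and deoxyhemoglobin content q:

    dx/dt = S_E - kappa*x - gamma_h*(f - 1)
    df/dt = x
    tau_h*dv/dt = f - v**(1/alpha)
    tau_h*dq/dt = (f/rho)*(1 - (1-rho)**(1/f)) - q*v**((1-alpha)/alpha)

with the BOLD readout y = V0*[k1*(1-q) + k2*(1-q/v) + k3*(1-v)]. The
x-equation is driven by the raw gating variable, so the resting operating
point carries a (harmless) nonzero baseline BOLD offset; every downstream
statistic is a correlation and is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import HemodynamicParameters

__all__ = ["HemodynamicState", "hemo_drift", "hemo_steady_state", "bold_signal"]


@dataclass
class HemodynamicState:
    """Per-node hemodynamic variables (x, f, v, q), all dimensionless."""

    x: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))


def hemo_drift(
    state: HemodynamicState, s_E: np.ndarray, hp: HemodynamicParameters
) -> HemodynamicState:
    """Time derivatives of (x, f, v, q) under excitatory drive s_E."""
    x, f, v, q = state.x, state.f, state.v, state.q
    if np.any(f <= 0) or np.any(v <= 0):
        raise ValueError("blood inflow and volume must stay positive")
    s_E = np.atleast_1d(np.asarray(s_E, dtype=float))
    dx = s_E - hp.kappa * x - hp.gamma_h * (f - 1.0)
    df = x
    dv = (f - v ** (1.0 / hp.alpha)) / hp.tau_h
    extraction = (1.0 - (1.0 - hp.rho) ** (1.0 / f)) / hp.rho
    dq = (f * extraction - q * v ** ((1.0 - hp.alpha) / hp.alpha)) / hp.tau_h
    return HemodynamicState(x=dx, f=df, v=dv, q=dq)


def hemo_steady_state(s_E, hp: HemodynamicParameters) -> HemodynamicState:
    """Closed-form hemodynamic fixed point under constant drive s_E >= 0.

    x = 0; f = 1 + s_E/gamma_h; v = f**alpha; and q balances oxygen
    extraction against washout, q = f**alpha * (1-(1-rho)**(1/f))/rho.
    """
    s_E = np.atleast_1d(np.asarray(s_E, dtype=float))
    if np.any(s_E < 0):
        raise ValueError("drive must be non-negative")
    f = 1.0 + s_E / hp.gamma_h
    v = f**hp.alpha
    q = f**hp.alpha * (1.0 - (1.0 - hp.rho) ** (1.0 / f)) / hp.rho
    return HemodynamicState(x=np.zeros_like(f), f=f, v=v, q=q)


def bold_signal(v, q, hp: HemodynamicParameters):
    """BOLD amplitude from venous volume and deoxyhemoglobin content."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v == 0):
        raise ValueError("blood volume must be nonzero")
    y = hp.V0 * (hp.k1 * (1.0 - q) + hp.k2 * (1.0 - q / v) + hp.k3 * (1.0 - v))
    return y if y.ndim else float(y)


def bold_partials(v, q, hp: HemodynamicParameters) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivatives (dy/dv, dy/dq) of the BOLD readout."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    dy_dv = hp.V0 * (hp.k2 * q / v**2 - hp.k3)
    dy_dq = hp.V0 * (-hp.k1 - hp.k2 / v)
    return dy_dv, dy_dq
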