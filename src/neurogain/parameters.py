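"""Model parameters for the two-population mean-field network and hemodynamics.

All synaptic and hemodynamic constants default to the values used by the
reduced Wong-Wang excitatory/inhibitory mean-field lineage of whole-brain
models at 3 T field strength. Units follow the conventions of that
literature: currents in nA, rates in Hz, times in s, gain in nC^-1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "HemodynamicParameters",
    "GainModulation",
    "load_config",
]


@dataclass
class ModelParameters:
    """Synaptic parameters of the coupled E/I mean-field network.

    Attributes
    ----------
    Ib : float
        Constant background input current (nA).
    J : float
        Effective NMDA conductance scaling long-range input (nA).
    gamma_kin : float
        Kinetic rate constant of excitatory gating (dimensionless).
    W_E, W_I : float
        Scaling of the background current onto E and I populations.
    w_EE : float
        Local recurrent excitatory-to-excitatory weight (nA).
    w_EI : float
        Baseline inhibitory-to-excitatory weight (nA); overridden per node
        by feedback inhibition control.
    w_IE : float
        Local excitatory-to-inhibitory weight (nA).
    tau_E, tau_I : float
        Synaptic gating time constants (s).
    a_E, b_E, d_E, a_I, b_I, d_I : float
        Transfer-function constants (gain nC^-1, threshold Hz, shape s).
    G : float
        Global long-range coupling (dimensionless).
    sigma : float
        Standard deviation of the white input noise (nA).
    """

    Ib: float = 0.382
    J: float = 0.15
    gamma_kin: float = 0.641
    W_E: float = 1.0
    W_I: float = 0.7
    w_EE: float = 0.21
    w_EI: float = 1.0
    w_IE: float = 0.15
    tau_E: float = 0.1
    tau_I: float = 0.01
    a_E: float = 310.0
    b_E: float = 125.0
    d_E: float = 0.16
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    G: float = 0.5
    sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("synaptic time constants must be positive")
        for name in ("a_E", "d_E", "a_I", "d_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.G < 0:
            raise ValueError("G must be non-negative")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass
class HemodynamicParameters:
    """Balloon-Windkessel hemodynamic constants (3 T defaults).

    rho: resting oxygen extraction fraction; tau_h: hemodynamic transit
    time (s); kappa: rate of vasodilatory signal decay (s^-1); gamma_h:
    rate of flow-dependent elimination (s^-1); alpha: Grubb's exponent;
    V0: resting blood volume fraction; k1..k3: field-strength constants.
    """

    rho: float = 0.34
    tau_h: float = 0.98
    kappa: float = 0.65
    gamma_h: float = 0.41
    alpha: float = 0.32
    V0: float = 0.02
    k1: float = 3.72
    k2: float = 0.53
    k3: float = 0.53

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("tau_h", "kappa", "gamma_h", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kwargs) -> "HemodynamicParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GainModulation:
    """Regional neural gain modulation weighted by a receptor-density proxy map.

    The gain constant of population p in region i becomes
    ``a_i^p = (1 + h_i * delta_p) * a0^p`` where ``h`` is a per-region
    weight in [0, 1] (e.g. a linearized receptor-gene expression map) and
    ``delta_E``, ``delta_I`` set the modulation strength per cell type.
    ``delta_E = delta_I = 0`` reproduces the unmodulated model exactly.
    """

    h: np.ndarray
    delta_E: float = 0.0
    delta_I: float = 0.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h.ndim != 1:
            raise ValueError("h must be a 1-D vector")
        if not np.all(np.isfinite(self.h)):
            raise ValueError("h must be finite")
        if np.any(self.h < 0) or np.any(self.h > 1):
            raise ValueError("h must lie in [0, 1]")

    @classmethod
    def none(cls, n: int) -> "GainModulation":
        """No-op modulation for an n-node network."""
        return cls(h=np.zeros(n), delta_E=0.0, delta_I=0.0)

    def replace(self, **kwargs) -> "GainModulation":
        return dataclasses.replace(self, **kwargs)


_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)}
_HEMO_KEYS = {f.name for f in dataclasses.fields(HemodynamicParameters)}


def load_config(path: str | Path) -> tuple[ModelParameters, HemodynamicParameters]:
    """Read parameter overrides from a YAML or JSON mapping.

    Keys must match the dataclass field names exactly; unknown keys are
    rejected to guard against silent typos.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(data) - _PARAM_KEYS - _HEMO_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = ModelParameters(**{k: v for k, v in data.items() if k in _PARAM_KEYS})
    hemo = HemodynamicParameters(**{k: v for k, v in data.items() if k in _HEMO_KEYS})
    return params, hemo
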