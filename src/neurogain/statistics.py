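"""Map-to-scalar statistics for surrogate null testing.

The central statistic is the model-empirical loading obtained when a
candidate brain map (empirical receptor expression or one of its
surrogates) drives the gain modulation at fixed (delta_E, delta_I). The
baseline model (FIC weights, fixed point, GBC) is computed once and
shared across all candidate maps.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .connectome import StructuralConnectome
from .covariance import gsr_covariance, model_bold_covariance
from .dynamics import apply_fic, solve_fixed_point
from .metrics import BrainMap, cov_to_fc, delta_gbc, gbc, loading
from .parameters import GainModulation, HemodynamicParameters, ModelParameters

__all__ = ["loading_statistic"]


def loading_statistic(
    sc: StructuralConnectome,
    params: ModelParameters,
    empirical_dgbc: BrainMap,
    delta_E: float,
    delta_I: float,
    gsr: bool = True,
    hp: HemodynamicParameters | None = None,
) -> Callable[[BrainMap], float]:
    """Build map -> loading of the induced model change-in-GBC on a target.

    Candidate maps already in [0, 1] (e.g. CDF-linearized expression maps
    and their value-preserving surrogates) are used as-is; anything else
    is min-max rescaled to [0, 1] before weighting gain.
    """
    w = apply_fic(sc, params)
    base_ss = solve_fixed_point(sc, params, w_EI=w)
    cov = model_bold_covariance(base_ss, sc, params, hp=hp, w_EI=w).P_BOLD
    if gsr:
        cov = gsr_covariance(cov)
    base_gbc = gbc(cov_to_fc(cov), sc.labels)
    target = empirical_dgbc.align_to(sc.labels)

    def statistic(map_: BrainMap) -> float:
        m = map_.align_to(sc.labels)
        vals = m.values
        if vals.min() >= 0 and vals.max() <= 1:
            h = vals
        else:
            span = np.ptp(vals)
            h = np.zeros_like(vals) if span == 0 else (vals - vals.min()) / span
        gains = GainModulation(h=h, delta_E=delta_E, delta_I=delta_I)
        ss = solve_fixed_point(sc, params, gains, w_EI=w)
        c = model_bold_covariance(ss, sc, params, gains, hp, w).P_BOLD
        if gsr:
            c = gsr_covariance(c)
        dmap = delta_gbc(gbc(cov_to_fc(c), sc.labels), base_gbc)
        return loading(dmap, target)

    return statistic
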