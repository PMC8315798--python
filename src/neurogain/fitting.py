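"""Grid-search calibration of global coupling and gain-modulation strength.

Two sequential searches mirror the study workflow. First the global
coupling G is calibrated by maximizing the Spearman rank correlation
between model and target FC over the upper-triangular elements, with
feedback inhibition control re-run at every G (the tuned inhibitory
weights depend on long-range input). Second, with G and the FIC weights
frozen at their baseline values, the two gain-modulation strengths
(delta_E, delta_I) are swept on an 11 x 11 grid and scored by the loading
of the model change-in-GBC map onto an empirical target map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import StructuralConnectome
from .covariance import gsr_covariance, model_bold_covariance
from .dynamics import apply_fic, solve_fixed_point
from .metrics import BrainMap, cov_to_fc, delta_gbc, ei_ratio, gbc, loading, spearman
from .parameters import GainModulation, HemodynamicParameters, ModelParameters

__all__ = [
    "GridSearchResult",
    "default_G_grid",
    "default_gain_grid",
    "calibrate_G",
    "sweep_gain",
    "fit_subject",
    "fit_subjects",
]


def default_G_grid() -> np.ndarray:
    """Coupling grid [0.01, 0.85] in steps of 0.01 (85 points)."""
    return np.round(np.arange(1, 86) * 0.01, 10)


def default_gain_grid() -> np.ndarray:
    """Gain-modulation grid [0, 0.03] in steps of 0.003 (11 points per axis)."""
    return np.round(np.arange(0, 11) * 0.003, 10)


@dataclass
class GridSearchResult:
    """Objective surface over a parameter grid with its maximizer.

    ``surface`` is 1-D for the coupling search and 2-D (delta_E on axis 0,
    delta_I on axis 1) for the gain sweep; unstable grid points are
    recorded as NaN. ``extras`` carries sweep by-products (model change
    maps, relative E/I ratios) keyed by name.
    """

    grids: tuple[np.ndarray, ...]
    surface: np.ndarray
    argmax_index: tuple[int, ...]
    argmax_params: tuple[float, ...]
    objective: float
    extras: dict = field(default_factory=dict)


def _fc_from_model(ss, sc, params, gains, hp, w_EI, gsr: bool) -> np.ndarray:
    cov = model_bold_covariance(ss, sc, params, gains, hp, w_EI).P_BOLD
    if gsr:
        cov = gsr_covariance(cov)
    return cov_to_fc(cov)


def calibrate_G(
    sc: StructuralConnectome,
    params: ModelParameters,
    target_fc: np.ndarray,
    grid: np.ndarray | None = None,
    gsr: bool = True,
    hp: HemodynamicParameters | None = None,
) -> GridSearchResult:
    """1-D grid search over global coupling, scored by FC rank correlation.

    FIC is recomputed at each candidate G. Grid points where the fixed
    point is unstable (or FIC fails) are recorded as NaN and skipped.
    """
    grid = default_G_grid() if grid is None else np.asarray(grid, dtype=float)
    target_fc = np.asarray(target_fc, dtype=float)
    iu = np.triu_indices(sc.n_nodes, k=1)
    surface = np.full(grid.size, np.nan)
    for k, G in enumerate(grid):
        p = params.replace(G=float(G))
        try:
            w = apply_fic(sc, p)
            ss = solve_fixed_point(sc, p, w_EI=w)
            if not ss.stable:
                continue
            fc = _fc_from_model(ss, sc, p, None, hp, w, gsr)
        except (ValueError, RuntimeError):
            continue
        surface[k] = spearman(fc[iu], target_fc[iu])
    if np.all(np.isnan(surface)):
        raise RuntimeError("no stable grid point in the coupling search")
    k_best = int(np.nanargmax(surface))
    return GridSearchResult(
        grids=(grid,),
        surface=surface,
        argmax_index=(k_best,),
        argmax_params=(float(grid[k_best]),),
        objective=float(surface[k_best]),
    )


def _sweep_model_maps(
    sc: StructuralConnectome,
    params: ModelParameters,
    h: BrainMap,
    grid: np.ndarray,
    gsr: bool,
    hp: HemodynamicParameters | None,
) -> tuple[list[list[BrainMap | None]], np.ndarray, np.ndarray]:
    """Model change-in-GBC map and relative E/I ratio at every grid cell.

    The baseline (FIC weights, fixed point, GBC map) is computed once from
    the unmodulated model and frozen; cells where the perturbed system is
    unstable yield None / NaN.
    """
    h_al = h.align_to(sc.labels)
    w = apply_fic(sc, params)
    baseline_ss = solve_fixed_point(sc, params, w_EI=w)
    baseline_gbc = gbc(_fc_from_model(baseline_ss, sc, params, None, hp, w, gsr), sc.labels)
    m = grid.size
    maps: list[list[BrainMap | None]] = [[None] * m for _ in range(m)]
    ei = np.full((m, m), np.nan)
    for i, dE in enumerate(grid):
        for j, dI in enumerate(grid):
            gains = GainModulation(h=h_al.values, delta_E=float(dE), delta_I=float(dI))
            try:
                ss = solve_fixed_point(sc, params, gains, w_EI=w)
                if not ss.stable:
                    continue
                g_map = gbc(_fc_from_model(ss, sc, params, gains, hp, w, gsr), sc.labels)
            except (ValueError, RuntimeError):
                continue
            maps[i][j] = delta_gbc(g_map, baseline_gbc)
            ei[i, j] = ei_ratio(ss, baseline_ss)
    return maps, ei, baseline_gbc.values


def _argmax_lex(surface: np.ndarray, grid: np.ndarray) -> tuple[int, int]:
    """Maximizing cell; ties broken by smallest (delta_I, delta_E)."""
    best = np.nanmax(surface)
    cand = np.argwhere(surface == best)
    order = sorted((int(j), int(i)) for i, j in cand)  # (delta_I, delta_E)
    j, i = order[0]
    return i, j


def sweep_gain(
    sc: StructuralConnectome,
    params: ModelParameters,
    h: BrainMap,
    empirical_dgbc: BrainMap,
    grid: np.ndarray | None = None,
    gsr: bool = True,
    hp: HemodynamicParameters | None = None,
    _precomputed=None,
) -> GridSearchResult:
    """2-D grid search over (delta_E, delta_I), scored by map loading."""
    grid = default_gain_grid() if grid is None else np.asarray(grid, dtype=float)
    if _precomputed is None:
        maps, ei, baseline = _sweep_model_maps(sc, params, h, grid, gsr, hp)
    else:
        maps, ei, baseline = _precomputed
    target = empirical_dgbc.align_to(sc.labels)
    m = grid.size
    surface = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(m):
            if maps[i][j] is not None:
                surface[i, j] = loading(maps[i][j], target)
    if np.all(np.isnan(surface)):
        raise RuntimeError("no stable grid cell in the gain sweep")
    i, j = _argmax_lex(surface, grid)
    return GridSearchResult(
        grids=(grid, grid),
        surface=surface,
        argmax_index=(i, j),
        argmax_params=(float(grid[i]), float(grid[j])),
        objective=float(surface[i, j]),
        extras={"model_maps": maps, "ei_ratio": ei, "baseline_gbc": baseline},
    )


def fit_subject(
    sc: StructuralConnectome,
    params: ModelParameters,
    h: BrainMap,
    subject_dgbc: BrainMap,
    grid: np.ndarray | None = None,
    gsr: bool = True,
    hp: HemodynamicParameters | None = None,
) -> tuple[GridSearchResult, BrainMap]:
    """Per-subject gain sweep; returns the result and the best model map."""
    res = sweep_gain(sc, params, h, subject_dgbc, grid, gsr, hp)
    i, j = res.argmax_index
    return res, res.extras["model_maps"][i][j]


def fit_subjects(
    sc: StructuralConnectome,
    params: ModelParameters,
    h: BrainMap,
    subject_dgbc_maps: list[BrainMap],
    grid: np.ndarray | None = None,
    gsr: bool = True,
    hp: HemodynamicParameters | None = None,
) -> list[tuple[GridSearchResult, BrainMap]]:
    """Fit every subject on a shared model-map grid.

    The model change maps do not depend on the target, so they are
    computed once and re-scored per subject.
    """
    grid = default_gain_grid() if grid is None else np.asarray(grid, dtype=float)
    pre = _sweep_model_maps(sc, params, h, grid, gsr, hp)
    out = []
    for target in subject_dgbc_maps:
        res = sweep_gain(sc, params, h, target, grid, gsr, hp, _precomputed=pre)
        i, j = res.argmax_index
        out.append((res, res.extras["model_maps"][i][j]))
    return out
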