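"""Synthetic fixtures and stochastic oracles.

Emulates, at desk scale, the three classes of empirical input the analysis
pipeline consumes: (i) a distance-decay structural connectome on a 2-D
cortical sheet, (ii) spatially autocorrelated receptor-expression maps
linearized to [0, 1] through the normal CDF, and (iii) a subject cohort of
change-in-GBC maps sharing a group pattern with low-rank individual
variation and behavioral score changes linearly coupled to the maps.

Also provides the forward Euler-Maruyama integrator of the full nonlinear
synaptic + hemodynamic system, which serves as the stochastic oracle for
the linearized covariance route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import norm

from .connectome import StructuralConnectome
from .dynamics import SteadyState, solve_fixed_point
from .hemodynamics import hemo_steady_state
from .metrics import BrainMap
from .parameters import GainModulation, HemodynamicParameters, ModelParameters

__all__ = [
    "SyntheticSpec",
    "make_connectome",
    "make_expression_map",
    "make_cohort",
    "simulate_sde",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Geometry is a square 2-D sheet of side ``sheet_size`` mm; connection
    weights decay exponentially with distance over ``decay_length`` mm with
    lognormal jitter, mirroring tractography-derived connectomes.
    Expression maps are Gaussian fields with correlation length
    ``expr_length`` mm. The cohort mirrors the pharmacological study
    design: 24 subjects, five behavioral scales, individual change maps
    dominated by a shared group pattern.
    """

    n_nodes: int = 30
    sheet_size: float = 100.0
    decay_length: float = 30.0
    expr_length: float = 30.0
    weight_jitter: float = 0.5
    cohort_size: int = 24
    n_scales: int = 5
    group_strength: float = 1.0
    group_spread: float = 0.3
    individual_rank: int = 2
    individual_strength: float = 0.3
    noise_sd: float = 0.1
    score_noise_sd: float = 0.1
    seed: int = 0


def make_connectome(spec: SyntheticSpec) -> StructuralConnectome:
    """Distance-decay connectome on a random 2-D sheet (seeded).

    Weights w_ij = exp(-D_ij/lambda) * lognormal jitter, symmetrized,
    diagonal zeroed, rows normalized to unit sum.
    """
    if spec.n_nodes < 5:
        raise ValueError("need at least 5 nodes")
    rng = np.random.default_rng(spec.seed)
    pos = rng.uniform(0.0, spec.sheet_size, size=(spec.n_nodes, 2))
    D = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    W = np.exp(-D / spec.decay_length)
    W *= rng.lognormal(mean=0.0, sigma=spec.weight_jitter, size=W.shape)
    W = (W + W.T) / 2.0
    return StructuralConnectome.from_weights(W, D=D)


def make_expression_map(spec: SyntheticSpec, D: np.ndarray, seed: int | None = None) -> BrainMap:
    """Spatially autocorrelated expression map linearized to (0, 1).

    Draws a Gaussian field with covariance exp(-D/lambda_expr), z-scores
    it, and maps through the standard-normal CDF so values are bounded and
    approximately uniform — the same linearization used for receptor-gene
    maps before they weight gain modulation.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    cov = np.exp(-D / spec.expr_length)
    # jitter for numerical PSD before factorization
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    z = L @ rng.standard_normal(n)
    z = (z - z.mean()) / z.std()
    h = norm.cdf(z)
    return BrainMap(values=h, labels=[f"parcel{i:03d}" for i in range(n)])


def make_cohort(
    spec: SyntheticSpec, group_map: BrainMap, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Subject change-map ensemble plus linearly coupled score changes.

    Subject s's map is c_s * group + sum_k b_sk u_k + noise, with the
    group-pattern strengths c_s ~ N(group_strength, group_spread), a fixed
    low-rank basis {u_k} of smooth random maps, and i.i.d. Gaussian noise.
    Score changes are scores = maps @ A.T + eps for a known 5 x N coupling
    A whose first row follows the group pattern. Returns
    (maps [M x N], scores [M x 5], truth dict with c, basis, A).
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    g = np.asarray(group_map.values, dtype=float)
    n = g.size
    M = spec.cohort_size
    c = rng.normal(spec.group_strength, spec.group_spread, size=M)
    basis = rng.standard_normal((spec.individual_rank, n)) if spec.individual_rank else np.zeros((0, n))
    if spec.individual_rank:
        # orthogonalize the individual basis against the group pattern
        gn = g / np.linalg.norm(g)
        basis = basis - np.outer(basis @ gn, gn)
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    b = rng.normal(0.0, spec.individual_strength, size=(M, spec.individual_rank))
    maps = np.outer(c, g) + b @ basis + rng.normal(0.0, spec.noise_sd, size=(M, n))

    A = np.zeros((spec.n_scales, n))
    A[0] = g / np.linalg.norm(g)
    if spec.n_scales > 1:
        mix = rng.normal(0.0, 0.3, size=(spec.n_scales - 1,))
        A[1:] = np.outer(1.0 + mix, A[0]) + 0.2 * rng.standard_normal((spec.n_scales - 1, n)) / np.sqrt(n)
    scores = maps @ A.T + rng.normal(0.0, spec.score_noise_sd, size=(M, spec.n_scales))
    truth = {"c": c, "basis": basis, "A": A}
    return maps, scores, truth


@njit(cache=True)
def _phi_scalar(I, a, b, d):
    u = a * I - b
    x = d * u
    if abs(x) < 1e-4:
        return (1.0 + x / 2.0 + x * x / 12.0 - x**4 / 720.0) / d
    return u / (1.0 - np.exp(-x))


@njit(cache=True)
def _integrate(
    C, G, J, Ib, W_E, W_I, w_EE, w_IE, w_EI,
    gamma_kin, tau_E, tau_I, a_E_vec, b_E, d_E, a_I_vec, b_I, d_I, sigma,
    rho, tau_h, kappa, gamma_h, alpha, V0, k1, k2, k3,
    S_E, S_I, x, f, v, q,
    dt, n_steps, burn_steps, sample_every, seed,
):
    np.random.seed(seed)
    n = C.shape[0]
    sq = sigma * np.sqrt(dt)
    n_samples = (n_steps - burn_steps) // sample_every
    bold = np.empty((n_samples, n))
    se_out = np.empty((n_samples, n))
    isample = 0
    inv_alpha = 1.0 / alpha
    ex_alpha = (1.0 - alpha) / alpha
    for step in range(n_steps):
        lr = C @ S_E
        for i in range(n):
            I_E = W_E * Ib + w_EE * S_E[i] + G * J * lr[i] - w_EI[i] * S_I[i]
            I_I = W_I * Ib + w_IE * S_E[i] - S_I[i]
            r_E = _phi_scalar(I_E, a_E_vec[i], b_E, d_E)
            r_I = _phi_scalar(I_I, a_I_vec[i], b_I, d_I)
            dSE = (-S_E[i] / tau_E + (1.0 - S_E[i]) * gamma_kin * r_E) * dt
            dSI = (-S_I[i] / tau_I + r_I) * dt
            if sigma > 0.0:
                dSE += sq * np.random.normal()
                dSI += sq * np.random.normal()
            # hemodynamics driven by the pre-update excitatory gating
            dx = (S_E[i] - kappa * x[i] - gamma_h * (f[i] - 1.0)) * dt
            df = x[i] * dt
            dv = (f[i] - v[i] ** inv_alpha) / tau_h * dt
            extraction = (1.0 - (1.0 - rho) ** (1.0 / f[i])) / rho
            dq = (f[i] * extraction - q[i] * v[i] ** ex_alpha) / tau_h * dt
            S_E[i] = min(max(S_E[i] + dSE, 0.0), 1.0)
            S_I[i] = max(S_I[i] + dSI, 0.0)
            x[i] += dx
            f[i] += df
            v[i] += dv
            q[i] += dq
            if f[i] <= 0.0 or v[i] <= 0.0 or q[i] <= 0.0:
                return bold, se_out, isample, step
        if step >= burn_steps and (step - burn_steps) % sample_every == 0 and isample < n_samples:
            for i in range(n):
                bold[isample, i] = V0 * (
                    k1 * (1.0 - q[i]) + k2 * (1.0 - q[i] / v[i]) + k3 * (1.0 - v[i])
                )
                se_out[isample, i] = S_E[i]
            isample += 1
    return bold, se_out, isample, -1


def simulate_sde(
    sc: StructuralConnectome,
    params: ModelParameters,
    gains: GainModulation | None = None,
    hp: HemodynamicParameters | None = None,
    T: float = 1000.0,
    dt: float = 1e-3,
    seed: int = 0,
    burn: float = 20.0,
    sample_dt: float = 1.0,
    w_EI=None,
    init: SteadyState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama forward integration of the full nonlinear system.

    Gating noise follows dS += sigma*sqrt(dt)*N(0,1) per node and
    population; S_E is clamped to [0, 1] and S_I at 0, mirroring the
    structural asymmetry of the gating equations. Integration starts at
    the deterministic fixed point; ``burn`` seconds are discarded.

    Returns (bold, s_E): arrays of shape [n_samples x N] sampled every
    ``sample_dt`` seconds.
    """
    if dt > 1e-3:
        raise ValueError("dt must be at most 1 ms")
    n = sc.n_nodes
    if gains is None:
        gains = GainModulation.none(n)
    if hp is None:
        hp = HemodynamicParameters()
    from .dynamics import modulate_gain, _resolve_wEI

    ss = init if init is not None else solve_fixed_point(sc, params, gains, w_EI=w_EI)
    if not ss.stable:
        raise ValueError("operating point unstable; simulation would diverge")
    hss = hemo_steady_state(ss.S_E, hp)
    a_E_vec, a_I_vec = modulate_gain(params, gains)
    a_E_vec = np.broadcast_to(a_E_vec, (n,)).astype(float).copy()
    a_I_vec = np.broadcast_to(a_I_vec, (n,)).astype(float).copy()
    w = _resolve_wEI(params, w_EI, n)

    n_steps = int(round(T / dt))
    burn_steps = int(round(burn / dt))
    sample_every = max(int(round(sample_dt / dt)), 1)

    bold, se, got, blew_up_at = _integrate(
        np.ascontiguousarray(sc.C), params.G, params.J, params.Ib,
        params.W_E, params.W_I, params.w_EE, params.w_IE, w,
        params.gamma_kin, params.tau_E, params.tau_I,
        a_E_vec, params.b_E, params.d_E, a_I_vec, params.b_I, params.d_I,
        params.sigma,
        hp.rho, hp.tau_h, hp.kappa, hp.gamma_h, hp.alpha, hp.V0, hp.k1, hp.k2, hp.k3,
        ss.S_E.copy(), ss.S_I.copy(), hss.x.copy(), hss.f.copy(), hss.v.copy(), hss.q.copy(),
        dt, n_steps, burn_steps, sample_every, seed,
    )
    if blew_up_at >= 0:
        raise RuntimeError(f"numerical blow-up at step {blew_up_at} (t={blew_up_at * dt:.3f} s)")
    return bold[:got], se[:got]
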