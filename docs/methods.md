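# Methods

## Model

Each cortical parcel is a two-population (E/I) mean-field microcircuit of
the reduced Wong–Wang type. Excitatory gating S_E relaxes with time
constant τ_E = 0.1 s and grows with rate γ·r_E·(1 − S_E) (γ = 0.641);
inhibitory gating relaxes with τ_I = 0.01 s and grows linearly with r_I —
so S_I has no saturation factor and its fixed point may mathematically
exceed 1, which we allow. Rates follow the soft-rectifying transfer
function φ(I) = (aI − b)/(1 − e^{−d(aI − b)}), evaluated through a fourth
order Taylor series within |d(aI − b)| < 1e−4 of its removable
singularity (where φ = 1/d) so the function and its derivative are smooth
to machine precision.

Standard parameter values (nA, Hz, s): I_b = 0.382, J = 0.15, W_E = 1,
W_I = 0.7, a_E = 310 nC⁻¹, b_E = 125, d_E = 0.16, a_I = 615 nC⁻¹,
b_I = 177, d_I = 0.087. Three constants are not part of that canonical
set and default to the predecessor-model lineage values: w_EE = 0.21 nA
(1.4·J), w_IE = J = 0.15 nA, and noise σ = 0.01 nA. All are
configurable; note that BOLD correlations are exactly invariant to a
uniform σ (covariance scales by σ²), so σ affects none of the
correlation-based statistics.

The connectome C is loaded from delimited text, its diagonal zeroed
(local recurrence is explicit in the equations) and rows normalized to
unit sum at load time — never silently re-applied afterwards.

## Feedback inhibition control

FIC pins each node's baseline excitatory rate at 3 Hz by tuning the local
inhibitory-to-excitatory weight w_EI, before (never after) gain
modulation. We compute it analytically: invert φ_E at 3 Hz for the
operating current; set S_E* = γrτ_E/(1 + γrτ_E); solve the scalar
inhibitory fixed point S_I = τ_I·φ_I(I_I(S_I)) by bracketed root finding;
and read w_EI off the excitatory current budget. A unit test confirms
this equals the classical iterative adjust-and-resolve tuning to 1e−6.

## Fixed points and stability

The fixed point of the 2N gating system is found by damped Newton
iteration (analytic Jacobian, backtracking line search, drift tolerance
1e−12, initialized at S = 0.1). Near the edge of stability, moderate
gain modulation can annihilate the low-activity fixed point in a
saddle-node and leave a stable high-rate branch; when Newton fails we
therefore relax along the noise-free drift (explicit Euler at one fifth
of the fastest time constant, gating clamped to its physical range) until
the attractor's basin is reached, then Newton-polish. Stability is read
from the spectrum of the synaptic Jacobian; the hemodynamic subsystem is
feed-forward from S_E and unconditionally stable near its operating
point, so the full 6N spectrum adds no constraints there.

## Hemodynamics and BOLD covariance

The Balloon–Windkessel cascade (ρ = 0.34, α = 0.32, V₀ = 0.02,
γ_h = 0.41 s⁻¹, κ = 0.65 s⁻¹, k₁ = 3.72, k₂ = k₃ = 0.53 at 3 T) is
driven by the raw gating variable S_E, so the resting state carries a
constant nonzero BOLD offset; all downstream statistics are correlations
and are unaffected. The transit time τ_h, which the canonical 3 T
constant set leaves to its hemodynamic-model source, defaults to 0.98 s.
The hemodynamic fixed point is closed-form: x = 0, f = 1 + S_E/γ_h,
v = f^α, q = f^α(1 − (1−ρ)^{1/f})/ρ.

The coupled 6N system (per-node state order S_E, S_I, x, f, v, q,
node-major blocks) is linearized analytically at the fixed point. Noise
covariance is diagonal with σ² on both gating rows and zeros on
hemodynamic rows. The stationary covariance solves the continuous
Lyapunov equation by a direct Bartels–Stewart solve (no iterative
fallback); residuals above 1e−8·‖Q‖ are an error. BOLD covariance is
K·P·Kᵀ with K the observation gradient (nonzero only in v, q columns);
the adjoint is the real transpose since everything is real.

Global signal regression is performed analytically on covariance
matrices: Cov(ε_i,ε_j) = C_ij − (Σ_k C_ik)(Σ_l C_jl)/Σ_mn C_mn. Row sums
of the output vanish identically and the map is idempotent.

## Connectivity statistics

FC is the correlation matrix of P_BOLD; GBC is the row mean of
off-diagonal Fisher-Z values, with |r| clipped at 1 − 1e−12 before
atanh. Change maps are perturbed-minus-baseline GBC. Loading of a model
map m on an empirical target e is ⟨m,e⟩/⟨e,e⟩ — deliberately sensitive to
magnitude as well as topography, and linear in m. The relative E/I ratio
is (mean r_E′/mean r_I′)/(mean r_E/mean r_I).

## Grid searches

Coupling is calibrated on a grid over G (default 0.01–0.85, step 0.01),
re-running FIC at every G, scoring the Spearman rank correlation of
upper-triangular FC elements against the target; unstable grid points are
recorded as missing. Gain modulation is swept on an 11 × 11 grid over
(δ_E, δ_I) ∈ [0, 0.03] step 0.003 with G and the FIC weights frozen at
their baseline values; ties at the argmax break toward the smallest
(δ_I, δ_E) lexicographically (deterministic, parsimonious). GSR parity
is a flag (default on): when the empirical target was GSR-processed, GSR
is applied to the model covariance too. Subject-level fits reuse one
shared grid of model change maps, since those do not depend on the
target.

Because loading is linear in the model map and the model's change-map
magnitude grows essentially monotonically with δ_E over this grid, the
loading argmax against a target the model itself generated sits at the
grid boundary rather than at the generating cell (whose loading is
exactly 1 by construction); self-consistency is therefore verified
through the loading-equals-one identity, not argmax recovery. Against
empirical targets, whose topography the model cannot reproduce exactly,
the magnitude-topography trade-off is precisely what the statistic is
designed to arbitrate.

## Surrogate maps and null tests

Spatial autocorrelation is operationalized by a variogram: half the mean
squared value difference per inter-parcel distance bin (default 25
uniform bins; empty bins dropped with a warning). Surrogates randomize a
map's topography while preserving its autocorrelation and exact value
multiset: permute (seeded); smooth over each node's k nearest neighbors
with an exponentially decaying kernel whose bandwidth is the k-th
neighbor distance, for candidate k from 5% to 50% of N in 5% steps;
affinely match the smoothed variogram to the empirical one over bins
(the regression slope rescales the map, the intercept enters as added
white noise — the nugget); keep the best k; and finally substitute
empirical values by rank. Null tests report the plain proportion of
null samples at least as extreme as the observed statistic (one-sided
greater); the conservative (r+1)/(n+1) form is available by flag.
Surrogate evaluations that fail are excluded with a warning below a 5%
failure rate and are an error above it.

## Linear decomposition

PCA uses the spatial covariance C = XᵀX/(M−1) of column-centered map
ensembles; eigenvector signs are fixed so each component's
largest-magnitude element is positive. Per-component significance
compares the observed variance fraction against the 95th percentile of a
null in which every map is independently permuted across parcels (1000
permutations by default; both the 5th and 95th null percentiles are
returned, since either tail can serve as the reference line).
Zero-variance components at the rank boundary are never flagged. The
subspace variance fraction is trace(PᵀCP)/trace(C) for an orthonormal
basis P. Experiential regression maps hold, per parcel and behavioral
scale, the OLS slope (and intercept) of subjects' score change on that
parcel's GBC change.

## Synthetic study conditions

The generator emulates the empirical inputs at desk scale. Connectomes:
n nodes placed uniformly on a 100 mm square sheet, weights
exp(−D/30 mm) with lognormal jitter (σ_log = 0.5), symmetrized,
row-normalized — reproducing the distance decay of tractography-derived
connectomes but not their degree-distribution details. Expression maps:
Gaussian fields with covariance exp(−D/30 mm), z-scored and mapped
through the standard normal CDF to (0, 1), mirroring how receptor-gene
maps are linearized before weighting gain. Cohorts: 24 subjects by
default, each subject's change map c_s·group + low-rank individual terms
(rank 2, orthogonalized against the group pattern) + i.i.d. noise, with
c_s ~ N(1, 0.3); five behavioral scale changes are linear in the maps
through a known coupling matrix whose first row follows the group
pattern, plus noise. All draws are seeded and bit-reproducible.

The stochastic oracle integrates the full nonlinear system by
Euler–Maruyama at dt = 1 ms (noise σ√dt per gating variable per step;
S_E clamped to [0, 1], S_I at 0, mirroring the structural asymmetry of
the gating equations), with hemodynamics co-integrated explicitly and
BOLD sampled at 1 s after a 20 s burn-in. The inner loop is
numba-compiled. Validation runs use a 10-node network and 20,000 s of
simulated time: long enough that the analytic correlations match the
sampled ones to a few hundredths, but with a Monte-Carlo floor of about
0.03 on individual correlations — which is why agreement is asserted at
|Δr| < 0.1 and why differences between small noise amplitudes are not
resolvable at this length. Parameter-recovery and surrogate-null
experiments use 30-node networks; variogram-matching quality is assessed
at 100 nodes, where bins hold enough pairs for stable semivariances.

## Known limitations

- Linearized covariance assumes small fluctuations around a stable fixed
  point; near bifurcations, or for strong modulation, the nonlinear
  system's correlations deviate and only the stochastic oracle is
  trustworthy.
- Synthetic cohorts share one global group pattern and white
  individual noise; real between-subject structure (site, motion,
  physiology) is richer, so passing recovery tests bounds algorithmic
  correctness, not empirical power.
- The surrogate generator preserves the variogram approximately (kernel
  smoothing of a permutation), not exactly; its match is quantified per
  surrogate and the approximation is part of the null definition.
- Sliding-window FC dynamics, dense (vertex-level) maps, and subcortical
  structures are out of scope.
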