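# Methods

## Model

The package simulates post-burn contraction of a 1D dermal cross-section
`x ∈ [−L, L]` (cm) over `t ∈ [0, 365]` days.  Six fields are coupled:
signaling molecules `c`, fibroblasts `N`, myofibroblasts `M`, collagen
`ρ`, displacement velocity `v`, and effective Eulerian strain `ε`; the
displacement `u` is integrated alongside.  All conserved species satisfy

    ∂w/∂t + ∂(w v)/∂x = −∂J_w/∂x + R_w ,

with fluxes only for the cells and signaling molecules (Fickian
diffusion `D_c` for `c`; density-dependent diffusion `D_F (N+M)` plus
chemotaxis `χ_F w ∂c/∂x` for `N` and `M`; collagen does not diffuse).
The reaction terms implement: Michaelis–Menten signaling secretion by
(myo)fibroblasts with ratio `η^I`; proteolytic clearance of `c` and `ρ`
by an MMP pool in instantaneous balance `g = [N+η^II M]ρ/(1+a_c^II c)`;
signaling-enhanced, crowding-limited logistic proliferation with
exponent `1+q`; differentiation `k_F c N`; apoptosis `δ_N`, `δ_M`;
collagen secretion `k_ρ` with up to `k_ρ^max`-fold signaling
enhancement.  The momentum balance is viscoelastic with a
collagen-dependent stiffness `E√ρ` and the myofibroblast traction
`ξMρ/(R²+ρ²)`, saturating in collagen around `ρ = R`.  The strain
evolution carries the morphoelastic source `−ζ g_c ε` with
`g_c = [N+η^II M]c/(1+a_c^II c)`: while signaling molecules are present,
elastic strain is continuously converted into permanent deformation.

Two parameters are never free: `q` and `k_ρ` are derived so that the
homeostatic state `(c,N,M,ρ) = (0, N̄, 0, ρ̄)` is an exact root of every
reaction term,

    q  = [ln δ_N − ln(r_F (1 − κ_F N̄))] / ln N̄ ,        k_ρ = δ_ρ ρ̄² .

They are implemented as read-only properties, so any perturbation of
their inputs (sensitivity sweep, heterogeneous sampling) keeps the
equilibrium identities pointwise.

Two stability constraints are validated before every run:
`k_c ≤ δ_c ρ̄ a_c^I` (net signaling secretion cannot outrun MMP
clearance at homeostasis — otherwise the healthy tissue ignites
spontaneous, unbounded inflammation) and `μ ≥ √(ρ̄E)/π` (viscous damping
of the elastic system).

### Initial and boundary conditions

Wounded fields start from plateaus joined by monotone half-sine ramps of
width `s` (default 1.5 cm) placed just inside the wound edge `±L_w`:
healthy values for `|x| ≥ L_w`, wound values `Ñ = 2×10³` cells/cm³,
`c̃ = 10⁻⁸` g/cm³ for `|x| ≤ L_w − s`.  Collagen also receives the wound
profile with `ρ̃ = 0.2·0.1125` g/cm³ — a burn destroys dermal collagen,
and the initial wound collagen is an independent parameter of the
sensitivity analysis; `wounded_collagen=False` restores a uniform `ρ̄`
start.  `M`, `u`, `v`, `ε` start at zero.  At the outer boundary,
`c = 0`, `N = N̄`, `M = 0`, `v = 0` (Dirichlet); collagen, strain, and
displacement carry no boundary conditions.  Production runs use the half
domain `[−L, 0]` with symmetry at the wound center: `v = 0` and natural
zero flux for `c`, `N`, `M`.  Dirichlet values for `c, N, M` are imposed
at the outer boundary only; a full-domain run agrees with the mirrored
half-domain run to discretization tolerance (tested).

## Numerics

Linear (P1) Galerkin finite elements on a mesh whose nodes move with the
material velocity, so convective terms vanish from the discrete material
derivative and the initial wound-edge node remains a material marker.
Mass matrices are lumped (monotonicity).  Time integration is backward
Euler; the update `x_i ← x_i + Δt v_i`, `u_i ← u_i + Δt v_i` uses the
new velocity.  Each step solves one monolithic linear system for all six
fields (blocked by field, nodes contiguous) with nonlinear coefficients
frozen at the current Picard iterate; production terms that are
non-Lipschitz in their own unknown (`N^{1+q}`, `M^{1+q}`) enter as
iterate-evaluated loads, losses and cross-couplings (`k_F c N`, the
`E√ρ ε` stress, `(ε−1)∂v/∂x`) implicitly.  The system is Jacobi
row-equilibrated and solved with a sparse direct factorization.

Defaults (all overridable in `NumericsConfig`): 400 elements on the half
domain with power-law grading factor 3 toward the wound edge; Δt = 0.05
day for t < 5 (fast early kinetics), 0.25 day after; daily output, so
day-index summaries have integer-day resolution.  Picard iterates to a
relative update norm of 1e-7 per field (measured against the field's
running magnitude with a small floor, so fields that decay to numerical
zero cannot stall the test), at most 60 iterations, with damping 0.5
switched on when the residual stagnates and automatic step-halving (≤4
levels) if the iteration still fails — needed only for parameter sets
sitting close to the `k_c` stability bound, where the kinetics are
nearly neutral.  At the exact equilibrium the solver converges in one
iteration and preserves the state and mesh to machine precision
(tested).  Summaries change by <0.2 % under mesh doubling and time-step
halving; the solver was additionally cross-checked against an
independent explicit Lagrangian finite-difference integration of the
same equations (fields agree to <1 % at day 20) and, for the linear
diffusion limit, against a nonuniform-grid finite-difference oracle.

## Observables

RSA(t) = 100 · (current wound length) / (initial wound length), with the
wound length measured between the material points initially at `±L_w`
(on the half domain, `|x_edge(t)|/L_w`, the center being pinned by
symmetry).  The total strain energy is `E_ε(t) = ∫_{−L}^{L} ½E√ρ ε² dx`,
evaluated with the trapezoidal rule on the moving mesh; a half-domain
run reports the symmetric full-domain value (the half-domain integral
without the ½).  The five summaries take the earliest day on ties.

## Sensitivity analysis

Thirty parameters plus the wound half-length are varied one at a time by
0, ±5, ±10, ±15, ±20, ±25 % around the means (341 runs).  For each
output `r` and level `j`, z-scores are computed across parameters with
the sample (n−1) standard deviation; `S_i^r = Σ_j |z_ij^r|`, and the
total score is the rounded sum over the five outputs.  The degenerate
0 % column (all runs identical) contributes `z = 0`, the only finite
value consistent with summing over every level; a flag restricts the sum
to the ±25 % columns for the alternative reading.  When `ρ̄` is varied,
`ρ̃` stays at 20 % of the mean 0.1125 (it is an independent parameter).
The sweep is embarrassingly parallel and cached per parameter-hash so
interrupted sweeps resume.  `scripts/table1_sweep.py` runs it at
production resolution (hours); the test suite exercises the bookkeeping
at reduced resolution.

## Age-group Monte Carlo

Spatial heterogeneity of skin uses a normalized truncated Karhunen–Loève
sine expansion `û(X) = Σ_{j≤n} Ẑ_j √(2/n) sin((2j−1)πX/(2|Ω|))` with iid
standard-normal `Ẑ_j` (n = 60 by default, resolving wavelengths well
below the graded element size; `û(0) = 0` exactly, zero mean, unit
domain-averaged variance — tested by Monte Carlo).  A heterogeneous
parameter with arithmetic mean μ and sd σ becomes the lognormal field
`exp(M + S û(X))` with `M = ln(μ/√(1+σ²/μ²))`, `S = √(ln(1+σ²/μ²))`.
The default heterogeneous subset is {E, μ, ξ, δ_N, δ_M, ρ̄} with
σ = 10 % of the mean — large enough to spread outcomes, small enough to
keep every realization inside the stability bounds (violating draws are
resampled, at most 10 times).  Whether fields are drawn independently
per parameter (default) or shared is a switch.  Derived parameters
follow pointwise.

Four age groups (0–15, 16–40, 41–70, 71+) are configured in an editable
YAML table; group 2 is the adult mean set.  The other groups apply
multiplicative aging factors (documented in the file) plus an
exponential 2 %/yr collagen decline evaluated at a per-group "collagen
age".  Two deliberate design choices, made because compounding the full
decline to ages beyond ~55 drives `ρ̄` below `k_c/(δ_c a_c^I)` — past
the model's own stability bound: the collagen age saturates at 52, and
`k_c` is held at its adult value, so the older groups sit progressively
closer to the bound.  That shrinking margin slows signaling clearance
and is the mechanism by which the shipped configuration produces the
intended aging phenotype: deterministic group-mean runs give maximum
contraction that deepens and arrives later from group 2 to group 4,
while the child group contracts slightly less and much earlier than the
adult group (tested).

Cohorts draw per-sample seeds deterministically from (base seed, group,
index), so results are bit-identical for any worker count (tested).
Reporting uses Gaussian-kernel KDEs with Silverman bandwidth (refused
for zero-variance samples), right-continuous ECDFs, t-based confidence
intervals for the mean, and the equal-sample two-group statistic
`t = (X̄_A − Ȳ_B)/s_p`, `s_p = √((s_a²+s_b²)/n_b)`, rejected when `|t|`
exceeds the upper α/2 quantile with `2(n_b−1)` degrees of freedom
(α = 0.001 by default; 3.293 for n_b = 1950).

## What the generator does and does not emulate

The synthetic cohorts emulate patient-to-patient and within-skin
variability as smooth lognormal fields over an otherwise identical 1D
wound geometry.  They do not emulate: wound-shape and depth variation,
growth and mobility forces (relevant for children), excess slack skin
(relevant for the elderly), re-differentiation of myofibroblasts, or
measurement noise in clinical scar assessment.  Passing cohort tests
therefore demonstrates the statistical machinery and the model's
qualitative age response, not clinical calibration; the aging
multipliers are plausibility-constrained defaults, not fitted values.

## Known limitations and conventions

* The model is strictly 1D; "surface area" is an interval length.
* Unit conventions follow the field's standard (cm, day, g, cells, N)
  with no conversion layer.  Two printed-unit ambiguities are noted:
  `χ_F` is stored as 2×10⁻³ cm⁵/(g day) (at that magnitude chemotaxis is
  dynamically negligible), and `ζ` as 4×10² cm⁶/(cells g day).
* Strain-energy values are reported in model units (N/cm) under the
  full-domain convention above; no rescaling is applied.
* The strain reaches `|ε| ≈ 0.5` at peak contraction, at the edge of the
  small-strain regime the effective-strain formulation assumes.
* Solver undershoots of `c`, `N`, `M` below zero are clipped before
  kinetics evaluation (logged if beyond roundoff); with mass lumping
  they stay at roundoff level in practice.
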