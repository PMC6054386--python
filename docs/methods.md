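# Methods

`capiflow` quantifies a structural error of clinical perfusion imaging: the
classic one-compartment (1C) estimators — deconvolution and maximum slope —
assume that each analyzed region is an isolated compartment with its own
arterial supply, but at voxel resolution capillary tissue is a *coupled*
system in which every voxel feeds its neighbours. The package builds a
continuous reference model of capillary flow, defines two ground-truth
notions of voxelwise perfusion, and measures how far the traditional
estimators drift from them as a function of voxel size.

## The continuous reference model

**Flow.** Blood flow through the capillary slab is modelled as steady
incompressible Darcy flow, `q = -(k/μ)∇p`, with a point-like arterial
source and venous sink and no-flow outer boundaries. The carrying quantity
is the *surface flux* `q` [mm³ s⁻¹ mm⁻²] — flow per unit cross-sectional
area — which, unlike perfusion, is discretization independent. The elliptic
pressure equation is discretized with the two-point flux approximation
(TPFA) on the structured grid and solved by sparse direct factorization;
the pressure gauge is pinned at the sink cell (fluxes are gauge invariant).
The resulting face fluxes satisfy the discrete divergence identity
`div q = Q` to the 1e-10 relative solver tolerance, and the flux field
depends only on the source geometry and strength, not on `k/μ`.

**Tracer.** Indicator dilution follows the linear advection equation
`φ ∂c/∂t + ∇·(c q) = c_a Q_so + c Q_si` with zero initial concentration:
tracer enters dissolved in the arterial inflow at the gamma-variate
concentration `c_a(t) = D₀ tᵅ e^(−t/β)` (α = 3, β = 1.5 s, D₀ = 1, peak at
4.5 s) and leaves at the local concentration of the sink cell. The
equation is integrated with explicit Euler time stepping and donor-cell
(first-order) upwinding. The scheme is monotone under the CFL condition,
hence positivity-preserving and bounded by the AIF peak, and conserves
tracer mass to round-off (the mass-balance bookkeeping in
`ConcentrationMovie` verifies this at every output step). Its first-order
numerical diffusion plays the role of the small physical dispersion the
model otherwise neglects. The solver step is chosen as the largest value
that satisfies the CFL bound with a 0.8 safety factor *and* divides the
0.1 s output step exactly, so output samples fall on solver steps; halving
the step changes the tissue curves by < 0.05% in max norm.

## Two ground truths for voxelwise perfusion

**Local perfusion `P_v`** is the total volume rate entering a control
volume across its boundary divided by the control volume:
`P_v = (1/|Ω_i|) ∫_{S_in} |q·n| dA`. It is well defined for any block size
(`local_perfusion_pv(..., block=b)` recomputes it per b×b block boundary)
but it is *not* scale invariant: serially coupled volumes count the same
flow repeatedly, so halving the control volume doubles `P_v` in a serial
channel — exactly — and on the default phantom the voxelwise mean at full
resolution is ~6350 ml/min/100ml against the true 50. Only at the
whole-domain scale does `P_v` reduce to the target mean perfusion.

**Streamline (global) perfusion `P_s`** assigns to each point the perfusion
of the thin flow tube around its streamline, with tube radius chosen so
that the tube carries constant flow: `P_s = (∫₀ˡ r(u)² du)⁻¹` with
`r² = 1/|q|` along the arterial-to-venous streamline. Equivalently
`P_s = φ/T` with `T` the advective transit time — the central volume
theorem specialized to one flow tube — so `P_s` is constant along each
streamline and independent of discretization. Note the squared radius: the
integrand `1/|q|` is what makes the expression dimensionally a perfusion
and reproduces the central-volume identity; the implementation asserts
`P_s·T = φ` per streamline to 1e-9.

Streamlines are traced with FACT (one constant flow vector per cell, taken
as the average of the face fluxes; straight segment to the cell-exit face,
then switch vectors). Two details matter at this grid scale:

* **No-flow walls.** The outer wall is itself a streamline of the exact
  field, but the cell-averaged vector in a wall cell carries a spurious
  outward component, which would let about a quarter of the back-traces
  (toward the source, along the walls) leave the domain. Whenever a trace
  in a wall cell points outward across a boundary face that carries no
  flux, the outward component is projected out and the trace slides along
  the wall. Boundary faces that genuinely carry flux (user-supplied
  fields) remain crossable.
* **Termination.** A trace ends on *entering* the source or sink cell
  (these represent the arterial and venous compartments, not capillary
  tissue), on leaving the domain, when the speed falls below 1e-6 of the
  field maximum (stagnant corners), or at 50 domain lengths of arc.

With per-cell-center seeding, 4094 of the 4094 non-source/sink cells of
the default phantom yield complete arterial-to-venous streamlines, and the
map mean is 49.95 ml/min/100ml — within 0.1% of the injected mean
perfusion, and stable under block averaging to < 1% at every scale.

## The voxel as an upstream-coupled compartment

Restricted to one voxel, the semi-discrete transport system *is* a
one-compartment model: `(φc_i)' = P_v (c_in − c_i)` with the local
arterial input `c_in` the flux-weighted average of the upstream neighbour
concentrations. `local_convolution_curve` integrates this exactly (an
exponential-integrator step that is closed-form for piecewise-linear
input) and reproduces the simulated tissue curve to 0.02% of peak.

Unrolling the recursion upstream expresses each voxel's response to the
*global* AIF as `H_i = J_i ∗ (P₀/P δ + Σ_j P_j/P H_j)` — its own
exponential kernel convolved with the flux-weighted mix of all upstream
responses (the δ term is convolved symbolically). Because voxel rate
constants `κ = P_v/φ` reach hundreds per second near the source, the
recursion runs on an internal time grid fine enough that `κ·dt ≤ 0.2` for
every ancestor (the response of the chain decays within a few seconds, so
a 30 s window suffices) and is then restricted to the output grid. The
result integrates to φ (areas multiply under convolution, each kernel has
unit area) and matches the threshold-free deconvolution of the simulated
curve to ~1% of peak — demonstrating that what deconvolution recovers at a
voxel is this upstream-mixture response, not the local kernel.

## Traditional estimators

* **bSVD**: the convolution `C = I ∗ c_a` is discretized with the
  rectangle rule on the uniform grid, embedded in a block-circulant matrix
  (zero-padded to twice the curve length) for delay insensitivity, and
  inverted by truncated SVD; perfusion is `max_t I`. The truncation
  threshold (default 0.10·σ_max, the customary choice) matters even on
  noise-free data: the compartment kernel's jump at t = 0 lives in the
  small singular values, so the recovered maximum falls as the threshold
  grows (on a pure single-compartment curve: exact at threshold 0, −25% at
  0.10, −32% at 0.20; on the phantom's voxel curves the fine-scale mean
  moves from ~106 to ~68 ml/min/100ml across thresholds 0.05–0.20). The
  threshold is exposed in `DeconvolutionSettings`; results quoted below
  use 0.10.
* **Maximum slope**: `max_t C'(t) / max_t c_a(t)`, with a forward finite
  difference on the 0.1 s grid and no smoothing (the synthetic curves are
  noise free). Exact when venous outflow vanishes.
* **CBV**: the blood volume fraction (≡ porosity) as the area ratio
  `∫C dt / ∫c_a dt`, trapezoidal, requiring washout-complete curves. The
  area identity `∫c_i dt = ∫c_a dt` holds per cell in the coupled system,
  which is why CBV — unlike perfusion — is recovered to < 1% at every
  scale.

## The discretization study

One full-resolution simulation (90 s, output at 0.1 s) is block-averaged
into b×b blocks for b ∈ {1, 2, 4, 8, 16, 32, 64} (voxel sizes 0.047–3 mm).
At each scale the movie is reconstructed voxelwise (the bSVD operator is
factorized once and reused across scales), the `P_s` map is block-averaged
(NaN-aware over the two flagged source/sink cells), `P_v` is recomputed
per block boundary, and errors are reported as the mean voxelwise relative
error `RE(a,b) = 100·|a−b|/b`. Flow is also reported surface-normalized:
`F/S` with `F = P·V_block` and `S` the in-plane block perimeter times slab
thickness (out-of-plane faces carry no flow in the 2D+time model); this
normalization remains scale dependent because `V/S` grows with block size.

Representative results (defaults, threshold 0.10): whole-ROI estimates
54.3 (bSVD) and 49.8 (MS) ml/min/100ml against a true 50; at 1.5 mm
voxels, mean RE vs `P_s` of 41% (bSVD) and 50% (MS); at full resolution
94% and 122%; CBV error < 1e-5% at every scale. The known direction of
each trend — overestimation versus `P_s` growing as voxels shrink,
underestimation versus `P_v`, scale-independent `P_s`, strictly shrinking
`P_v` — is asserted by the test suite.

## What the phantom does and does not emulate

The generator reproduces the study conditions: a homogeneous 2D+time
porous slab (3 mm field of view, slab thickness equal to the side length
so clinical volume units apply), uniform isotropic permeability
(5e-6 mm²), viscosity 5e-6 kPa·s, porosity 0.05, corner source/sink and a
noise-free gamma-variate bolus. It does not emulate heterogeneous or
anisotropic microvasculature, tracer extravasation or multi-compartment
exchange, physical dispersion beyond the scheme's numerical diffusion,
acquisition noise, or 3D geometry. Passing tests therefore demonstrate the
discretization mechanism itself under clean conditions, not the magnitude
of the error in any particular clinical acquisition; the real-data adapter
applies the same estimators to measured concentration arrays but performs
no signal conversion, motion correction or segmentation.

## Numerical choices and degenerate inputs

* Pressure solve: direct sparse LU (grids here are ≤ 64²); residual
  checked against 1e-10 relative, unbalanced source fields rejected.
* Transport: explicit donor-cell update; CFL violation and non-positive
  porosity raise before stepping; the sink extraction rate is included in
  the CFL bound.
* Face fluxes below 1e-12 of the maximum are dropped when building the
  upstream graph, so round-off at stagnation faces cannot create cycles;
  a genuine cycle raises.
* Zero-length FACT steps (face bouncing at stagnation points) terminate a
  trace after two consecutive occurrences.
* Incomplete streamlines are flagged (NaN in maps) and excluded from
  averages; `global_perfusion_ps` refuses them.
* The 2 mm vs 3 mm field-of-view ambiguity in the study conditions is
  resolved in favour of L = 3 mm (the scale at which the whole-ROI voxel
  size is quoted); L is a config parameter.
* The simulated horizon (90 s) was chosen so the bolus washes out
  (residual < 1e-12 of injected); the CBV area ratio and the per-cell area
  identity depend on it.

## Known limitations

* Maximum-slope error at the 1.5 mm scale comes out near 50% here;
  published figures for comparable setups quote lower values (~20%), and
  the difference is insensitive to every implementation choice we varied
  (derivative stencil, time integrator, slope search window, error
  aggregation), so it likely reflects an unreported detail of the slope
  estimator in that work. The bSVD error at the same scale (~41%) and all
  other headline quantities reproduce closely.
* FACT with one vector per cell is first-order; streamline positions carry
  O(h) error. This cancels in the `P_s` integrals (the map mean is 0.1%
  off the injected mean) but individual corner streamlines are the least
  accurate.
* The recursive impulse response is exact for the semi-discrete system,
  not for the continuous PDE; it inherits the grid's numerical diffusion.
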