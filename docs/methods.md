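# Methods

This note documents the model, the discretization, the defaults, and the
places where the implementation had to make choices the underlying
formulation leaves open.

## Geometry of the unit

The simulated domain is the cubic pore of edge 2r (default 200 µm) framed
by four fiber caps. A cap is the circular segment of sagitta Δ whose chord
spans a full cube edge, so the fiber diameter is D = (r² + Δ²)/Δ; Δ = 0 is
a flat-wall sentinel (D = ∞), Δ = r the inscribed fiber (D = 2r). Both
indicator points of a face pair share one Δ (fabrication constraint), so a
design is the pair (Δ_Y, Δ_Z).

Axis convention: flow runs along +x. The primary (cultured) pair bulges
from the top/bottom faces with axes across the flow — circles in (x, z)
with chord along x — forming the converging–diverging bumps whose
downstream velocity drop motivates the design problem. The secondary pair
runs **along** the flow: circles in the (y, z) cross-section with chord
along z, invariant in x, acting as rails that set the free cross-section.
This convention is fixed by the published narrowest-section areas: for
D1 = 520 µm / D2 = 340 µm it yields a minimum cross-section of
2.3555×10⁻⁸ m² against the printed 2.357×10⁻⁸ m² (0.06%); no
both-pairs-across convention can produce segment-shaped cross-sections at
all.

A consequence worth knowing: the reference design D1 = D2 = 200 µm
(Δ = r on both pairs) closes the pore completely at its throat — the two
tangent primary caps cover the entire mid cross-section. Such occluded
units are flagged, and a culture run on them falls back to a quiescent,
diffusion-fed mode (`occlusion="static"`); `occlusion="error"` restores
strict failure. The fallback is what makes occluded candidates comparable
(and properly penalized — no perfusion, no shear stimulation) inside a
design campaign.

Voxelization is uniform Cartesian (a voxel is solid if its center lies in
a cap), replacing body-fitted octree meshing; the solid volume converges
first-order in the voxel spacing to the analytic cap volume (tested). The
attachment angle α is reported as the tangent-chord angle asin(2r/D1) —
a descriptive output only.

## Flow

Steady incompressible creeping flow with spatially varying viscosity:
μ = 0.001 + ε_c·(1 − 0.001) Pa·s, i.e. culture medium where cell-free and
packed-cell bulk at ε_c = 1. The biomass shell is part of the fluid domain
and is penalized only through this viscosity. At the operating point
(200 µm, 3 mm/s, water-like medium) Re ≈ 0.6, so the convective term is
omitted entirely; quadratic inertial corrections at Re < 1 are below the
discretization error of the grids used.

Discretization: staggered (MAC) finite volumes. Plug inflow is imposed on
the open (cell-free fluid) inlet voxels — biomass voxels touching the
inlet plane are penalized, not force-fed. The outlet holds zero gauge
pressure (ghost value at the outlet face); all solid surfaces and lateral
walls are no-slip, with per-face slip available for benchmark
configurations (plane channels). The coupled velocity–pressure saddle
system is solved by GMRES with a block upper-triangular preconditioner:
ILU factorizations of the three momentum blocks and of the SIMPLE-type
Schur approximation Gᵀ·diag(A)⁻¹·G. Mass conservation is enforced to a
relative continuity defect below 1e-6 (typically 1e-12); the solver errors
rather than returning an unconverged field. Preconditioner factorizations
are reused across re-solves while the viscosity drifts by less than 2% of
its full range — this only changes iteration counts, never the assembled
system. Validation: plane-Poiseuille wall shear within 0.8% at 16 cells
across the gap (0.05% at 64), square-duct profile within 0.1% of the
Fourier-series solution at 48–64 cells per edge.

Shear stress is reported as τ = μ·√(2 e:e) per voxel, with the velocity
gradient taken one-sided at walls so that wall-adjacent voxels report the
shear their attached cell layer experiences. Limitation: with a 2-voxel
biomass shell, the gradient across the shell multiplied by the penalized
viscosity overestimates the interfacial stress, so biomass shear
statistics at 16³–32³ are upper bounds (order 1 Pa where a resolved
calculation would give tenths of a pascal). Only ordering properties of τ
are asserted; reported shear means are diagnostics, not validated
quantities.

## Transport

One fluid-phase glucose field c_gf is evolved; the cell-phase
concentration is slaved through the linear interfacial partition
c_gc = K_eq·c_gf inside biomass voxels. This makes the transient capacity
of a biomass voxel θ = ε_f + K_eq·ε_c and its effective diffusivity
D_gf + K_eq·D_gc, and turns the two-phase balance into a single equation.
Advection uses the local (penalized) velocity also inside the biomass —
the formulation's "penetration rate" reading. Lactate is a fluid-phase
scalar (capacity 1, diffusivity D_lf) with zero inlet concentration.

Discretization: cell-centered finite volumes, harmonic-mean face
diffusivities, first-order upwind advection on the staggered face fluxes
(which are discretely divergence-free, so the conservative and advective
forms coincide). Implicit Euler in time; the Michaelis–Menten sink is
linearized about the previous concentration but kept implicit in the new
value, which preserves positivity at 1-hour steps even at cell Péclet
numbers of order 10–60. Negative concentrations (roundoff-level) are
clipped and accounted; the run aborts if clipped mass ever exceeds 0.1% of
throughput. The lactate source in each step is exactly twice the glucose
sink actually applied in that step, so the cumulative stoichiometric
budget holds to solver precision by construction (the 1% test tolerance is
slack). Linear systems are solved by ILU-preconditioned BiCGStab with a
lazily refreshed preconditioner; nearly-closed compartments (occluded
units) make the near-steady diffusion system almost singular, and the
solver falls back to a direct sparse solve there.

## Biomass dynamics

ε_c lives on the fixed monolayer shell: the d_c = 13 µm layer over the
cultured caps (the intrinsic cell mass density ρ_cb cancels from the
balance and is not tracked). Each step applies, in order: growth by the
exact exponential update ε_c·exp((r_g − r_d)Δt) with the crowding-dependent
rate evaluated at the midpoint (second-order in Δt; exact for constant
rate — halving Δt from the 1-hour default changes 12-hour outcomes by
well under 1%); the pH viability gate (literal mode removes the population
in voxels below pH 6.8; a "freeze" mode merely halts growth there); the
per-voxel bound ε_c ≤ 1; and the monolayer cap.

The monolayer cap is applied per attachment column (per "cell/attachment
area"): along each column normal to a cultured face, the cell count
Σ ε_c·V_vox/V_cell may not exceed σ_max·A_col, with σ_max defaulting to one
cell footprint per d_c² (≈ 5.9×10⁹ cells/m²) and V_cell the volume of a
sphere of diameter d_c (the ε_c ↔ cell-count conversion; both are
config-overridable). Cell migration D_c defaults to 0 (quantitatively
negligible at monolayer scale) and the death rate r_d to 0 — no literature
value exists; population loss then occurs only through the pH gate.

K_c, the growth-law saturation coefficient, also has no literature value.
The default makes the half-saturation concentration K_c·ρ_cell·ε_c equal
to half the default inlet glucose (2.25 kg/m³) at ε_c = 1, i.e.
K_c = 2.25/182 (dimensionless; the product K_c·ρ_cell·ε_c is a
concentration). This is flagged as a non-literature default; growth
time-scales shift with it, orderings between designs do not.

## Coupling loop and operating conditions

Per 1-hour step: viscosity from ε_c → steady flow re-solve (quasi-steady
coupling; `flow_update_interval` can stretch this when the viscosity
drifts slowly) → shear field → glucose → lactate → pH gate → biomass.
Defaults follow the studied operating point: inlet velocity 3 mm/s, inlet
glucose 4.5 kg/m³ (4.5×10⁻³ g/cm³; sweep values 0.059, 1.54, 3.02, 4.5),
seeding density 5×10⁷ cells/cm³ (sweep 2, 5, 10 ×10⁷), Δt = 1 h. Problem
sizes: culture runs use a 32³ unit over a 120 h horizon by default (the
dt-independence and budget tests use 16³ and 12–48 h); design campaigns
default to 16³ candidates. These horizons are the package's desk-scale
study conditions; a 30-day horizon is a configuration change, not a code
change.

CE is averaged over the shell volume (the monolayer habitat); a
zero-duration run has CE = 0 identically, and runs are bit-deterministic
for fixed configuration.

## Design search

Candidates are drawn uniformly and independently per face pair from
[0, 100] µm with a seeded generator; evaluation is plain generate-and-test
(no surrogate, no gradients), with per-candidate failures logged and
excluded. Ties in CE break toward larger attachment area, then lower
index. The ratio report bins CE against |Δ_Y/Δ_Z|, flagging the favorable
[0, 1] band and the > 5.5 risk band; Δ_Z = 0 candidates land in a separate
unbounded band.

## What the synthetic conditions do and do not show

The generator-free inputs here are the parametric designs and the
operating conditions themselves; no external data enters. Passing tests
show internal consistency (conservation, stoichiometry, analytic flow
limits, growth oracles) and the *direction* of the geometric effect
(improved unit vs. reference unit, CE ordering). They do not validate
absolute growth magnitudes: K_c and r_d are not literature-pinned, the
coarse-grid shear in the shell is an overestimate, and negative culture
efficiencies cannot occur at these conditions because the only loss
mechanism (pH < 6.8) requires lactate concentrations (> 14.8 kg/m³)
unreachable at the studied inlet glucose levels and horizons. Oxygen
metabolism is outside the model by design.

## Known limitations

* Staircase (voxel) walls: wall shear and throat areas converge only
  first-order; 32³ is a screening resolution, not a reference one.
* The biomass shell is geometrically fixed; growth changes ε_c and the
  penalizing viscosity but not the shell shape (no moving boundary, no
  scaffold degradation).
* Single-field momentum with viscosity penalization, not a Brinkman drag
  model; the contract is the penalization-consistency property (velocity
  inside packed biomass suppressed > 95%), which is tested.
* First-order upwind advection is diffusive at coarse grids; it buys
  unconditional positivity at the default step sizes.
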