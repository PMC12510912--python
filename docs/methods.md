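# Methods

`grom` implements geometry reduced-order modeling (GROM) for linear elliptic
PDE models on subject-specific brain geometries: precomputed full-order
solutions on other subjects' geometries are transported onto a target
geometry through image-registration deformation fields, stacked into a
snapshot matrix, compressed by proper orthogonal decomposition (POD), and
used as a Galerkin basis for cheap forward solves on the target.  This note
records the models, the synthetic study conditions, the numerical choices
and the known limitations.

## The offline/online split

**Offline.** For subjects i = 1..M with meshes Ω_i^h, solve the full-order
problem a_i(u_i, v) = f_i(v) once per subject.  For a new target geometry,
compute deformations φ_i: Ω_i → Ω_target (from image registration or, on
the synthetic cohort, in closed form), morph each subject mesh by moving its
nodes through φ_i (Lagrange nodal values ride along), and read the morphed
solution off at the target space's dof coordinates — FE interpolation where
a target dof lies inside a morphed cell, Gaussian-weighted nearest-neighbour
extrapolation in the thin uncovered boundary band.  Stack the mapped
solutions û_i (treating an n-field solution as a single vector of
D̃ = n·D coefficients) into X ∈ R^{D̃×M} and take the SVD; the first d left
singular vectors U form the POD basis — the rank-d minimizer of
‖X − UUᵀX‖_F, with squared reconstruction error Σ_{i>d} σ_i².

**Online.** Assemble the full operators A, F on the target once, project
A_rb = UᵀAU, F_rb = UᵀF, solve the d×d dense system directly, and lift
u = U u_rb.  The reduced solve is orders of magnitude cheaper than the full
sparse solve; the projection cost is the assembly-time overhead reported by
the timing tables (wall-clock figures are recorded, never asserted — they
are hardware-dependent).

The POD inner product is the plain Euclidean one on coefficient vectors,
matching the Frobenius-norm optimality statement; a lumped-mass-weighted
variant (`pod(..., mass_weighted=True)`) is available but off by default.
Per-field rescaling of the snapshot rows is likewise off by default: the
stacked fields enter with their native magnitudes.

In every experiment the target's own solution is excluded from its snapshot
set (leave-one-out), emulating an unseen subject; the only exception is the
snapshot-inclusion exactness test, which verifies that a symmetric coercive
Galerkin projection reproduces the full solution when it lies in the basis.

## Forward models

Both models are steady, linear and symmetric; assembly is in mm–s–Pa units
(SI table values converted at load: 1 m² = 1e6 mm², 1 mmHg = 133.322 Pa,
1 ml/min = 1000/60 mm³/s).

**Two-compartment tracer transport (model A, P2 elements).**
Concentrations c_e (extracellular space, ECS) and c_p (perivascular space,
PVS) obey

    −∇·(n_e D_e ∇c_e) = π_ep (c_p − c_e)
    −∇·(n_p D_p ∇c_p) = −π_ep (c_p − c_e) − π_pb c_p

with Robin exchange on both boundary surfaces α ∈ {pial, ventricle}:
−n_a D_a ∇c_a·n = k_a (c_a − c_CSF^α).  Defaults (low-clearance variant):
n_e = 0.2, n_p = 0.02, D_e = 1.3e−4 mm²/s, D_p = 3.9e−4 mm²/s,
π_ep = 2.9e−2 s⁻¹, π_pb = 2.0e−8 s⁻¹, k_e = 1.0e−5 mm/s, k_p = 3.7e−4 mm/s.
The CSF concentration is the idealized post-injection profile

    c_CSF^α(t) = (a_α / φ) · (e^{−t/τ2} − e^{−t/τ1}),

a_pial = 0.52 mm²/s, a_ventricle = 0.2 mm²/s, φ = 0.2, τ1 = 4.43e4 s,
τ2 = 8.5e4 s, evaluated at its peak t* = ln(τ2/τ1)/(1/τ1 − 1/τ2) ≈ 16.7 h.
The published rendering of this formula is typographically corrupted; the
difference-of-exponentials form above is the reconstruction whose peak time
reproduces the published 16.7 h to three significant figures (alternative
readings peak elsewhere or are monotone), and the closed-form peak is
cross-checked against numerical maximization in the tests.

**Steady 7-network MPET (model B, P1 elements).**  Pressures
p_i, i ∈ {a, c, v, pa, pc, pv, e} obey

    −∇·(κ_i/μ_i ∇p_i) = Σ_j ω_ij (p_j − p_i)

with the tabulated permeabilities κ_i and symmetric exchange coefficients
ω_ij on the graph {a–c, c–v, c–pc, pa–e, pv–e, pa–pc, pc–pv, pc–e}.  The
source prints the exchange term with the opposite (anti-dissipative) sign;
the dissipative convention above — fluid flows down pressure gradients, the
standard MPET form — is implemented.  Boundary conditions: arterial Neumann
influx Q_in = B_in/|∂Ω_pial| on the pial surface, capillary Neumann efflux
−Q_prod/|∂Ω_ventricle| (choroid-plexus production, Q_prod = 0.33 ml/min),
Robin anchors β1((p_DS+p_CSF)/2 − p_v), β2(p_CSF − p_pa) and
β3((p_DS+p_CSF)/2 − p_pv) on the pial surface (β1 = β2 = 1e−3, β3 = 1e−7,
p_DS = 8.4 mmHg), homogeneous Neumann otherwise.  The elastic terms of full
MPET are deliberately dropped (steady pre-infusion regime).

Three quantities are **not tabulated** by the parameter sources and are
config-exposed modeling choices here: the viscosities
(μ_blood = 2.67e−3 Pa·s for a/c/v, μ_CSF = 7.0e−4 Pa·s for the CSF-filled
networks), the CSF reference pressure p_CSF = 10 mmHg, and the 2D arterial
inflow B_in = 20 mm²/s.  B_in was fixed once from the volume-averaged
exchange balance (B_in/|Ω|)/ω_ac ≈ 10 mmHg on the ~1.0e4 mm² reference
slice, i.e. so the prescribed inflow produces arterial-to-capillary drops
of order 10 mmHg; all three must be overridden for any quantitative claim.
With the tabulated κ_c and ω's, the capillary compartment develops a
boundary layer of width √(K_c/Σω) ≈ 0.2 mm at the ventricular surface that
the default 1.5 mm meshes do not resolve; full and reduced solutions share
the same discretization, so reduction errors are still meaningful, but
absolute capillary pressures near the ventricle are mesh-limited.

## Synthetic cohort

Real T1 MRI and the associated segmentation/meshing pipeline are out of
scope; the synthetic cohort reproduces the *structure* of the clinical
dataset the method targets — 2D annular "brain slices" with a healthy-like
majority and an iNPH-like subgroup whose single distinguishing feature is
ventriculomegaly:

* outer (pial) boundary: R(θ) = R0(1 + Σ_{k=3..8} a_k cos(kθ + ψ_k)),
  R0 ~ U(55, 65) mm, a_k ~ U(0, 0.04), ψ_k ~ U(0, 2π) — gentle folds with
  Σ|a_k| < 0.3 keeping the curve star-shaped;
* ventricle: ellipse with semi-axes U(6, 10) mm (healthy-like) or
  U(14, 22) mm (iNPH-like), centre ~ U(−3, 3)² mm.  The centre scatter is a
  modeling choice standing in for residual rigid-alignment variability
  after image normalization;
* images: 192×192 voxels at 1 mm (single-slice NIfTI).  The field of view
  is sized so the full R0 sampling range fits with a ≥5-voxel margin;
* intensity: 0 outside the parenchyma and in the ventricle,
  0.4 + 0.6·ρ inside, where ρ ∈ [0,1] is the normalized annular depth
  coordinate, with a one-voxel anti-aliased boundary band.  The radial ramp
  emulates the internal contrast that makes T1 registration work away from
  edges;
* meshes: structured conforming triangulations in (θ, ρ) coordinates at
  target size h (default 1.5 mm, ~5e3 vertices, ~7e4 P2×2 dofs / ~3.5e4
  P1×7 dofs).  The reference 3D pipeline runs at ~1e5 nodes and ~1e6 dofs;
  the desk scale here is a deliberate reduction chosen so the complete
  two-model, 40-subject evaluation runs in minutes on one CPU, not a
  calibrated match.

Because geometries are analytic, the inter-subject correspondence is known
in closed form: the map preserves the polar angle about the ventricle
centre and the annular coordinate ρ, translating ventricle centres onto
each other, and extends continuously outside the annulus (radial scaling
inside the ventricle, radial offset outside the pial curve).  Its Jacobian
is positive throughout the annulus, forward/backward composition returns
interior points to < 0.2 mm, and it doubles as registration ground truth.

**What the synthetic cohort does not emulate:** 3D anatomy, cortical fold
geometry at realistic depth/frequency, white/gray subdomains, intensity
noise and bias fields, and segmentation error.  Tests passing here show the
pipeline's mathematics is right at study scale; they do not certify
accuracy on clinical MRI.

## Registration

The in-repo registration is multi-resolution diffusion-regularized demons
on the intensity SSD metric: 3 levels (4×, 2×, 1× downsampling), 100
iterations per level, per-iteration force field smoothed with σ_update =
1.0 voxel, accumulated field with σ_total = 1.5 voxel, update step capped
at 0.5 voxel, optional centre-of-mass initialization — standard demons
practice, fully deterministic.  `register(moving, fixed)` returns the
*point map* from moving space into fixed space sampled on the moving grid
(identity-plus-displacement, world mm), the convention needed to morph a
subject mesh onto a target; externally computed warps in the same NIfTI
convention plug in via `imaging.load_field`.

Accuracy is gated on what an intensity metric can observe.  The synthetic
intensity depends on ρ alone, so image matching determines displacement
only along ∇I; the along-isocontour component — which carries the
ventricle-centre translation of the analytic ground truth — is a gauge
invisible to any intensity-driven method.  On seeded default pairs the
demons estimate carries ρ correctly to ~1e−3 and its ∇I-projected error is
0.2–0.8 mm (< 1 voxel), while the full-vector difference to the analytic
map is 1.5–3.5 mm of pure isocontour sliding; the quality gates are
therefore (i) observable-component mean error < 1 voxel, (ii)
post-registration SSD ≤ 25% of the initial SSD, (iii) det J > 0 on every
annulus voxel, with the full-vector figure and the forward/backward
inverse-consistency residual reported as diagnostics.  The experiment
drivers default to the analytic backend precisely to separate
transfer/reduction behaviour from registration error — a separation
impossible with real data.

## Numerical choices

* **FE kernel**: P1/P2 Lagrange triangles, field-major dof blocks (all dofs
  of field 1, then field 2, …) so snapshot stacking is well defined;
  deterministic dof order (vertices in node order, then edge midpoints in
  lexicographic edge order).  Quadrature exact to degree 2·order (3-point
  and 6-point symmetric rules; 3-point Gauss on facets).  Exchange is
  assembled in the pairwise form Σ_{f<g} w_fg (u_f − u_g, v_f − v_g), which
  makes symmetry, positive semidefiniteness and zero cross-field row sums
  structural rather than incidental.
* **Sparse solves** via SuperLU with a verified relative residual < 1e−10;
  a preconditioned-CG path exists for cross-checks.  Reduced systems are
  solved densely (LAPACK) with residual < 1e−12.
* **Point location** uses a uniform-grid spatial hash over cell bounding
  boxes (bin ≥ the largest cell bbox, so a containing cell is always in the
  query point's bin) with a brute-force all-cells oracle for verification;
  the barycentric inside test uses a tolerance of 1e−9 and is
  orientation-agnostic, so cells inverted by an imperfect registration
  still participate (inversions are counted and reported, never silently
  dropped).
* **Transfer extrapolation**: k = 8 nearest source dofs, weights
  exp(−d²/2σ²) renormalized to sum to one, σ = 1.0 × the local source mesh
  size at the nearest dof.  Normalization makes constants exact and every
  extrapolated value a convex combination of source values; transfer fails
  loudly if the nearest source dof is further than 10σ (grossly mismatched
  geometries).  P2 transfer morphs vertex nodes and regenerates edge-midpoint
  dofs from the morphed vertices (straight-edge cells).
* **Pulled-back (modified-operator) assembly**: gradients composed with
  J^{−T}, volume measures scaled by |det J|, boundary measures by the
  tangential stretch |Jτ| — the change-of-variables-correct reading of the
  "modified differential operators" identity, validated against direct
  assembly on an affinely mapped mesh to 1e−10 (exact for affine maps) and
  by a residual-decreases-under-refinement trend for smooth nonlinear maps.
  The published notation leaves the transpose/inverse placement ambiguous;
  the affine oracle pins it down.
* **SVD sign fix**: each basis column is scaled so its largest-magnitude
  entry is positive (ties broken by lowest index), making bases
  bit-reproducible across runs.  The Eckart–Young check uses the squared
  Frobenius identity ‖X − U_dU_dᵀX‖_F² = Σ_{i>d} σ_i²; the unsquared form
  sometimes quoted is not the correct theorem statement.
* **L2 errors** are true function-space norms √(eᵀMe) with the consistent
  per-field mass matrix (for P2 these differ from coefficient-vector
  norms); multi-field norms are root-sum-square unless per-field values are
  requested.
* **Degenerate inputs**: meshes with zero-area cells, non-symmetric or
  negative exchange matrices, disconnected MPET coupling graphs, zero-norm
  reference fields, and deformations with non-positive Jacobians at
  quadrature points are rejected with specific errors.

## Evaluation protocol and problem sizes

The default evaluation cohort is 28 healthy-like + 12 iNPH-like subjects
(master seed 1), h ≈ 1.5 mm, analytic deformation backend.  Designated
targets are the first subject of each group.  For each model and target the
39 remaining solutions are mapped leave-one-out; reported quantities are
per-field relative L2 errors of the d = 30 reduced solutions (pooled over
fields, models and the two targets) and the combined two-compartment error
at the untruncated basis d = 39, plus subgroup mapping-error tables
(full / healthy-only / iNPH-only), normalized singular-value spectra and
per-d timing breakdowns.  The complete evaluation runs in roughly five
minutes on a single CPU.

On this cohort the d = 30 pooled median error is well under 10% and the
untruncated two-compartment error under 2%; the iNPH-target arterial
compartment is the consistent outlier (its pure-Neumann pial influx makes
the pressure profile most geometry-sensitive), mirroring which parts of
such models are intrinsically hard to transfer between geometries.

## Limitations

* 2D study scale; contracts are dimension-agnostic but the implementation
  is 2D (`ImageGrid`/`DeformationField` validate 2D shapes).
* Mapped snapshots do not satisfy the target boundary conditions exactly
  (the drift is measurable via `transfer.boundary_condition_drift`), so
  POD spectra decay more slowly than for conforming snapshot sets.
* The demons stand-in is asymmetric and first-order; it is a vehicle for
  the pipeline, not a contribution — real applications should supply
  externally computed diffeomorphic warps through the NIfTI interface.
* Direct dense SVD only; at D̃ ~ 1e6 and M ~ 1e2+ a randomized SVD would be
  the natural replacement.
* Time-dependent problems and the elastic terms of full MPET are out of
  scope.
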