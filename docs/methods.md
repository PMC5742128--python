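# Methods

This note documents the models, numerical choices and limitations behind
`vestim`, in the order the pipeline runs them.

## Mesh representation and voxel conversion

A `LabeledTetMesh` stores vertices (meters), positively oriented
tetrahedra, and one tissue region label per tetrahedron from an open string
vocabulary.  Structural invariants — positive volumes, conforming faces
(every interior face shared by exactly two tets), geometric coincidence of
combinatorially distinct boundary faces — are checked by `validate()`.

Labeled voxel volumes are converted with the uniform Freudenthal/Kuhn
6-tetrahedra split along the main cell diagonal.  Because the split is
identical in every cell, shared faces between neighboring cells match
without any parity alternation, the result is conforming by construction,
and per-label volume is conserved exactly.  The mesh resolution is set
globally by the voxel size; there is no graded or adaptive refinement
(deliberately out of scope — a voxel size fine enough for the smallest
feature of interest is the control knob).

Surface geodesics are vertex-graph Dijkstra distances with Euclidean edge
weights.  On staircase (voxelized) surfaces, graph distance overestimates
smooth geodesic length anisotropically by up to ~√2 per edge; patch
selection only needs ordering, so this is acceptable, but quantitative
checks against geodesic maxima must use slender fixtures where the
ambiguity radius (the cap radius) is small against the distance itself.

## Phantom anatomy

The phantom emulates the *topology* of labeled inner-ear datasets at a
geometrically scaled-up, voxel-resolvable size: a bone sphere (5 cm
diameter) inside a saline shell (1 cm), containing an endolymph space, two
ampullary nerve branches — a stimulation target and a non-target neighbor —
each a straight tube capped by a sensory-epithelium disc opening into an
ampulla-like fluid capsule, and an IAC tube both nerves join.  Default
voxel size is 1.5 mm; nerve radii 2.5 mm.

Three geometric choices matter and are intentional:

* **No mirror symmetry.**  Branch axes are tilted out of any common plane;
  a perfectly symmetric phantom would place the fiber bundle on the null
  plane of the canal-tangent dipole, a degeneracy real anatomy never has.
* **Adjacent ampullae.**  The neighbor's epithelium sits ~7 mm from the
  monopolar electrode position — inside the target's own monopolar
  recruitment band.  Non-target endings within reach of the stimulating
  electrode are precisely the anatomical situation that makes selective
  vestibular stimulation hard; placing the neighbor out of reach would
  trivialize the selectivity question.
* **Fluid spaces merge.**  Both ampullae open into one endolymph label, as
  the membranous labyrinth's compartments communicate.

What the phantom does *not* emulate: real cross-sectional shapes,
three-canal geometry, utricle/saccule/cochlea compartments, tissue-property
heterogeneity, and the μm-scale of real electrodes (see Electrodes below).
Passing tests on the phantom therefore demonstrates the correctness and
robustness of the *workflow machinery* and the qualitative physics of
electrode configurations, not quantitative amplitudes for human anatomy.

## Fiber-orientation fields

Per nerve region, P1 (linear tetrahedral) finite elements discretize:

1. *Distance surrogate*: Δϕ = 0, ϕ = 0 on Γ_s, −∇ϕ·n = 1 on the remaining
   boundary.  By the maximum principle ϕ ≤ 0, and the boundary minimum
   approximates the most distant surface point; the target surface Γ_t is
   the geodesic patch around it (default radius: 2× the tube-radius
   estimate √(area(Γ_s)/π)).
2. *Orientation solve*: Δϕ = 0 with Robin coupling −∇ϕ·n = α(ϕ − ϕ_e),
   (α, ϕ_e) = (α_s, 0) on Γ_s, (α_t, 1) on Γ_t, natural elsewhere.
   Defaults α_s = α_t = 100; larger values steepen the entrance/exit angle
   of the field at the coupling surfaces (asserted as a monotone property
   on a curved-tube fixture).  The Robin/stiffness system is symmetric
   positive definite; values stay in [0, 1] up to discretization.

The orientation field is the per-tet normed P1 gradient; tets with
vanishing gradients (below 10⁻¹²) inherit the averaged direction of their
face neighbors.  For tube-like nerves without an epithelium reference (the
IAC, the facial-nerve case), the start surface is found automatically: a
seeded random boundary triangle acts as a temporary Γ_s, whose distance
solve locates one tube end, around which the definitive start patch is
grown.

## Fiber synthesis

Seeds are drawn area-uniformly on Γ_s (area-weighted triangle choice +
uniform barycentric sampling), nudged a fraction of a step inward, and
integrated along F with fixed-step RK4 (step = ¼ mean tet edge; F is
piecewise constant per tet, located by tet walking with a KD-tree
fallback).  A trace is accepted only if its exit face belongs to Γ_t;
otherwise the seed is resampled.  On voxel staircase walls the discrete
field can point slightly outward, so a fraction of traces graze out
laterally near the end and are resampled — with the geodesic-patch target
the acceptance rate on the tube fixture stays near 0.9.  Everything is
deterministic per seed.

Fiber types: seeds below the configurable `central_fraction` (default 0.5)
quantile of geodesic distance from the epithelium center are "central",
drawing types from {irregular 0.5, dimorphic 0.5}; peripheral seeds draw
from {regular 0.5, dimorphic 0.5}.  Note the quantile is over patch
*vertices*, so the central zone covers roughly a quarter of the patch area
on a disc.  These zone probabilities and the internodal distances
(regular 350 μm, irregular 250 μm, dimorphic 300 μm; fiber diameter =
spacing/100) are representative configurable defaults, not measured human
values.  Nodes of Ranvier sit at arc lengths offset + kΔ ≤ fiber length.

## Electrodes and waveforms

Electrodes are spheres (or sphere arrays) inserted by relabeling the tets
whose centroid falls inside the shape; original labels are kept so
`deactivate_electrode` restores them exactly (an involution on labels).
Electrically the relabeled region is a 10⁶ S/m volume source — the same
effect as a meshed metal body, without boundary-conforming tet surgery.
Two preconditions guard validity: the local tet size (6V)^⅓ must not
exceed ⅓ of the electrode diameter, and a new electrode may not share even
a single vertex with an existing one — in a P1 discretization one shared
vertex short-circuits two highly conductive regions.

`standard_configurations` builds the four canonical arrangements at an
ampulla — monopolar (distant return), and transverse-parallel, axial
(canal-tangent) and transverse-perpendicular dipoles centered on the
monopolar position — with defaults of 200 μm spheres, 750 μm epithelium
offset and 1 mm separation, appropriate for real-sized anatomy.  The
default phantom scenario scales these to its mm resolution (4.5 mm
spheres, 6.5 mm offset, 8 mm separation), keeping the proportions: active
sphere clear of the epithelium, dipole gap > 2 voxels.

The reference stimulus is a cathodic-first symmetric biphasic pulse,
200 μs phases and 30 μs interphase gap (charge-balanced, 430 μs support);
both polarity and timing are configurable.

## Volume-conductor solve

P1 FEM for −∇·(σ∇ϕ) = I_s.  Nerve regions get σ = σ_t I + (σ_l − σ_t)FFᵀ
(eigenvalues {σ_l, σ_t, σ_t}, principal axis F); anisotropic regions
without an orientation field fall back to the isotropic mean, which is
also the default for the cochlear nerve and the epithelium discs.  The
unit current is distributed uniformly over the active region
(I_s = I/V_a); the reference (ϕ = 0) is the reference-electrode vertex set
(bipolar) or the outer saline surface (monopolar), enforced by row/column
elimination, which keeps the reduced system symmetric positive definite.

Solvers: sparse LU below 10⁴ unknowns; above that, conjugate gradients on
the symmetrically Jacobi-scaled system (rtol 10⁻¹⁰) — the scaling handles
the 10⁶ S/m electrode contrast, converging in a few hundred iterations
where incomplete-factorization preconditioners stall.  Diagnostics report
the residual and the current balance (reaction current at the reference vs
injected current; conserved to ≲10⁻⁶ on the analytic fixture, asserted to
2 %).

Potentials at arbitrary points (the nodes of Ranvier) use barycentric P1
interpolation with KD-tree candidate search; time dependence is pure
scaling by amplitude·w(t).

## Neuron model and thresholds

Internodes are treated as perfect insulators, reducing each myelinated
fiber to its node chain:

C_m A dV/dt = G_a Δ²(V + V_e) − A·i_ion(V),  sealed ends,

with A = π·(0.7D)·1.5 μm nodal area, G_a = π(0.7D)²σ_i/(4Δx) axial
conductance (axoplasm resistivity 0.547 Ω·m), C_m = 0.025 F/m².  The
default `active_cable` kinetics are the CRRSS mammalian node (fast sodium
m²h, g_Na = 14450 S/m², E_Na = +115 mV rel., leak 1280 S/m², 37 °C,
rest −80 mV).  Spike criterion: any node's absolute membrane potential
crossing 0 mV.  Numerics: semi-implicit Euler (exact exponential gate
updates, implicit tridiagonal voltage solve), dt = 2 μs, simulated over
the stimulus support plus a 1 ms tail with early exit once a subthreshold
response has decayed below 1 mV; halving dt moves thresholds by < 2 %.
The time loop is JIT-compiled when numba is available (a pure-Python path
gives identical results).

The `linear_sdc` variant spikes when the peak positive second-difference
drive reaches a fixed voltage (default 20 mV); its closed-form threshold
θ/max_t,n[w·Δ²u] is the independent oracle for the search.

Thresholds: bracket by doubling from a 1 μA floor, bisect to 1 % relative
tolerance; no spike up to 10⁶× the floor (1 A) flags the fiber
non-excitable (+∞).  The ceiling is generous because the scaled-up phantom
needs bipolar amplitudes of hundreds of mA — amplitudes scale with linear
anatomy size.  Because extracellular coupling is linear, scaling all node
potentials by k scales thresholds by 1/k exactly; this, strength–duration
monotonicity, and grid-scan agreement are asserted in tests.  An optional
per-fiber Gaussian threshold jitter (seeded, off by default) approximates
the recruitment-curve softening that spontaneous discharge variability
produces; no stochastic firing model is attempted.

## Evaluation

Recruitment(a) = (#thresholds ≤ a)/N, a right-continuous step function;
non-excitable fibers stay in the denominator.  The 80 % amplitude is the
⌈0.8N⌉-th order statistic (not interpolated, matching the step
definition).  The ROC sweeps the union of all finite thresholds, takes
TPR = target recruitment and FPR = max over non-target recruitments,
completes the staircase with (0,0) and (1,1), and integrates
trapezoidally — reproducing the definitional limits 1, 0 and 0.5 exactly.
Charge per pulse is amplitude·Σ|wᵢ|Tᵢ per polarity.  The energy figure is
E = amplitude²·∫w²dt·R_access with R_access the lumped access resistance
implied by the unit solution (mean unit potential over active-electrode
vertices minus reference mean); this convention is a package choice —
alternative definitions can be computed from the same unit solution.

## Pipeline determinism and artifact sizes

`run_scenario` derives every random stream from one seed via named
substreams (CRC-keyed `numpy` generators), so reruns agree bit-for-bit up
to iterative-solver tolerance (thresholds asserted to 10⁻⁶ relative).
Stage artifacts (VTU mesh, fiber and threshold CSVs, JSON reports) are
persisted and individually reloadable.  Default problem sizes — 1.5 mm
voxels (~3·10⁵ tets, ~6·10⁴ vertices) and 50 fibers per branch — were
chosen so a full four-configuration scenario completes in minutes on one
core; fiber counts and resolution scale up freely (the reference fiber
count for production runs is 400 per branch, exercised in the tests on the
tube fixture).

## Known limitations

* Purely resistive tissues; no reactive impedance component.
* No efferent fibers, no branching/bifurcating trajectories.
* Electrode insertion by relabeling cannot represent insulating carriers
  or realistic array bodies.
* Node kinetics and morphometry are representative mammalian defaults, not
  human-fitted values; absolute thresholds on the phantom are not
  predictions for human subjects.
* Voxel staircase boundaries perturb near-wall orientation vectors and
  surface geodesics; conclusions drawn at scales near the voxel size
  should be checked under refinement.
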