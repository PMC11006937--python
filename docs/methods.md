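# Methods

## Scope and model

`craniofea` implements comparative cranial finite-element analysis of the
kind used to compare skull strength across taxa: a small-strain,
linear-elastic solver over four-noded tetrahedral meshes (tet4, the
constant-strain tetrahedron), plus the loading protocols and summary
statistics that make stress fields comparable between crania of different
size and musculature.

Assumptions inherited from the comparative protocol:

* materials are isotropic, homogeneous and linearly elastic; bone and
  teeth carry separate constants (defaults: bone E = 20.49 GPa, ν = 0.40;
  teeth E = 60.40 GPa, ν = 0.31, both derived from extant archosaur
  tissue);
* sutures, contact, kinesis and large deformation are not modelled;
* loads are static point loads; constraints are homogeneous (zero
  prescribed displacement) per axis.

Units are mm / N / MPa: stress fields come out in MPa directly and strain
energy in N·mm. Moduli quoted in GPa are converted (×1000) at config load.

## Element and solver

The element stiffness is `Ke = V · BᵀDB`, with `B` the constant 6×12
strain-displacement matrix from the linear shape-function gradients and
`D` the isotropic constitutive matrix in Voigt order (xx, yy, zz, xy, yz,
zx; engineering shear). Constraints are imposed by exact elimination of
the constrained degrees of freedom — never by penalty, which would leak
spurious stress into exactly the trimmed peak statistics this pipeline
compares. The reduced system is solved with sparse LU by default; a dense
direct path and conjugate gradients (relative residual 1e-10) exist for
cross-checking. Reactions are recovered as `K u − f` at constrained DOFs
and balance the applied loads per axis; strain energy is `U = ½ fᵀu` over
the applied loads (reaction work vanishes at homogeneous constraints).

Stress is constant per element. The "element-nodal" von Mises export
mirrors commercial solvers' reports by replicating each element's value at
its four corners (a multiset of 4·n_elements values); a unique-node
averaged field is provided for contour export only. Since the averaging
scheme of commercial element-nodal reports is not standardised, this
replication is recorded as an approximation.

Degenerate (zero-volume) tets are a validation failure, not silently
dropped — dropping would change the assembled stiffness. Element
orientation is normalised to positive volume on construction and read.

## Loading protocols

**Scaled bending.** Dorsal (+Z) loads perpendicular to the palate, split
equally over the chosen palate node set(s), at the anterior, mid or
posterior bite position, bilaterally or unilaterally on the left. Loads
scale with cranial surface area, `F_i = 100 N · A_i / A_min`, so the
smallest model carries 100 N and every model the same load per unit area —
removing size from the comparison (stress scales with area). All boundary
faces count toward the surface area by default; internal cavity walls are
not distinguished.

**Muscle-driven biting.** Each jaw adductor muscle's contraction force is
divided across exactly eight nodes of its origin set, each nodal force
directed from the node toward a single insertion point (lines of action
are inputs, inherited from volumetric muscle reconstruction; when origin
directions fan out the vector resultant is below the scalar force, which
is the physical behaviour of a distributed attachment). The bite point is
a vertical-axis (Z) constraint at one node (unilateral) or one per side
(bilateral); its Z reaction is the bite force readout.

**Constraints common to all protocols.** Four nodes per quadrate articular
patch and three occipital-condyle nodes, fixed in all axes.

**Node selection.** Within any landmark set, the k members nearest the set
centroid are selected, ties broken by node index. The choice is invented
for determinism (no selection rule is standard); any fixed rule works
because the statistics are trimmed.

**Extrinsic scenarios.** Head-pull (−Y at the beak tip), head-shake (+X)
and head-twist (±Z torsion couple on the left/right beak-tip groups). The
twist couple carries half the nominal force per side so that the magnitude
sum over all applied loads equals the nominal force, keeping the
`total_applied_force` bookkeeping identical across scenario kinds.
Extrinsic magnitudes are config inputs (100 N default here); no published
per-taxon values are asserted.

**Rhamphotheca overlay.** Beak-region elements are re-labelled to a
keratin material; geometry is untouched. Keratin constants are a required
input with no asserted default; the analysis configuration uses E = 1 GPa,
ν = 0.30 — a soft keratin roughly 20× more compliant than bone, within the
range reported for avian beak keratin.

## Summary statistics

Point loads and point constraints on tet4 meshes create artificially high
local stresses, so the top 5% of the element-nodal von Mises multiset is
excluded before comparison: the `floor(0.05·n)` largest values are removed
(deterministic and conservative — never more than the stated fraction).
Mean, quartiles (linear interpolation between order statistics) and the
peak (maximum retained value) are computed on the trimmed multiset;
computing quartiles on the trimmed rather than raw multiset is a recorded
choice made for internal consistency.

Strain energy from area-scaled loading is made size-comparable by volume
correction: for geometrically similar models under area-scaled loads the
stress field is scale-invariant, so `U ∝ V` and
`U_corrected = U · (v_ref / V)` brings all models to a common reference
volume (the smallest model's, by default). This factor is validated by the
similarity property (corrected energies equal across scales to ~1e-13 in
the test family) rather than asserted from a formula.

## Synthetic geometry

The toy skull is a tapered box, not an anatomical cranium: the pipeline's
contracts are geometric and statistical, so what matters is that the
generator furnishes every landmark a scenario needs — palate bite points
at three positions on both sides, ≥4-node quadrate patches, a ≥3-node
occipital patch, ≥8-node muscle-origin patches (dorsotemporal and lateral
on each side), and beak-tip sets — on a bilaterally symmetric mesh.
Default dimensions 60 × 30 × 24 mm with 50% rostral taper at a 6 × 10 × 4
cell resolution (1440 elements, 385 nodes): the coarsest grid that
furnishes every set, solving in ~0.1 s so full suites stay interactive.

Cells are split into six tets each (Kuhn subdivision). Left-half cells use
the x-mirrored subdivision, which remains face-compatible and makes the
tessellation — not just the point set — mirror-symmetric, so symmetric
load cases yield element-for-element mirror-symmetric stress fields.
Optional seeded jitter perturbs interior nodes to exercise asymmetric
meshes; it is off in every study configuration.

What the toy skull does *not* emulate: real cranial topology (fenestrae,
pneumatic chambers, sutured elements), realistic muscle lines of action,
or element-size heterogeneity. Passing tests therefore demonstrate the
correctness of the solver, protocols and statistics — not the biological
conclusions one would draw from segmented crania.

The beam generator provides the analytic validation geometry. The
cantilever oracle uses a 10 × 1 × 1 mm beam at refinements 24×3×3, 48×6×6
and 64×8×8 cells: tip deflection converges monotonically from below (tet4
is stiff in bending) to within 10% of `PL³/3EI` at the finest level. The
oracle material uses bone stiffness with ν = 0, since beam theory carries
no Poisson effect and ν > 0 adds clamped-end stiffening that is a modelling
difference, not a solver error.

## Numerical choices

* Trim count `floor(0.05·n)`; ties at the cut removed by count, making the
  result order-independent.
* Solver residual guard at 1e-6 relative; non-finite solutions and
  factorisation failures raise a singular-system error.
* Similarity tolerances: trimmed statistics 1e-6 relative, corrected
  energies 1e-5 relative (observed agreement is ~1e-13; the tolerances
  allow for solver roundoff on ill-conditioned meshes).
* Rigid-motion invariance of area/volume at 1e-9 relative; INP round-trip
  coordinates at 1e-12.
* Unilateral always means the left side.

## Known limitations

* tet4 elements are stiff in bending; absolute stress levels on coarse
  meshes are under-converged even where comparative ratios are exact.
  Comparative conclusions should rest on identical-resolution families.
* The element-nodal multiset weights elements by count, not volume; on
  strongly graded meshes the mean is element-size biased (the trimming
  protocol exists precisely because of such mesh artefacts).
* The INP dialect covers `*NODE`, `*ELEMENT TYPE=C3D4`, `*NSET`, `*ELSET`
  only; other keywords are ignored, other element types rejected.
* Muscle wrapping, distributed insertions and force regression from
  skeletal proxies are out of scope; forces and insertions are inputs.
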