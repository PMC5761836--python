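# Methods

## Problem and model

`devfea` analyses the mechanics of a small skeletal structure — the
motivating case is the paired upper pharyngeal jaw (UPJ) of larval
cichlid fish — loaded by its musculature and braced against the
neurocranium, across a series of developmental stages. The structure is a
labeled tetrahedral mesh; muscles are defined by attachment node sets, a
physiological cross-sectional area (PCSA) and a specific tension; the
contact with the neurocranium is a fixed node set.

The mechanical model is linear-static elasticity on 4-node
constant-strain tetrahedra (TET4): assemble the global stiffness `K` from
per-element `K_e = V Bᵀ D B`, build the nodal load vector `P` from the
distributed muscle forces, and solve `K d = P` with the contact nodes
fixed. Assumptions: linear isotropic materials, negligibly small
displacements, time-invariant loads, no muscle activation dynamics and no
contact mechanics — forces are applied, the fixed patch absorbs whatever
reaction equilibrium requires.

TET4 elements are over-stiff in bending. Every quantity the package
reports is either a load-resultant (independent of stiffness), a
dimensionless ratio, or compared across stages within the same
discretisation, so this bias does not affect the comparative conclusions;
absolute stress magnitudes should be read with that caveat.

## Muscle loads

* Pull direction: unit vector from the insertion-node centroid to the
  origin centroid (or explicit origin point). Centroids are unweighted
  node means; an area-weighted alternative was considered and rejected as
  the default because the node-mean definition is the simpler convention
  and the two differ only for strongly non-uniform surface meshes.
* Magnitude: PCSA (mm²) × specific tension (default 2.5 N·mm⁻², the
  literature value for pharyngeal musculature), with the PCSA averaged
  across a left/right pair so both sides carry equal force.
* Distribution: the total force is divided *equally* among the insertion
  nodes (100 μN over 200 nodes → 0.5 μN per node). This is deliberate
  model fidelity, not the finite-element-consistent load of a uniform
  traction; the closed-form bar validations therefore use the
  facet-area-consistent loading (`fem.area_consistent_load`), under which
  the linear-field solutions are exact.

## Orientation angles

Canonical frame: +x lateral-right, +y rostral, +z dorsal; left-side
structures use −x as outward-lateral. With `l, r, d` the outward-lateral,
rostral, dorsal components of a pull direction:

* RCA = atan2(|d|, |l|): 0° lateral → 90° dorsal
* MLA = atan2(d, r): 0° rostral, 90° dorsal, 180° caudal; ventral-pointing
  vectors get negative MLA (the range extends below 0° rather than being
  reflected)
* DVA = atan2(r, |l|): +90° rostral, 0° lateral, −90° caudal

Because RCA and DVA use the outward-lateral magnitude, mirrored left and
right muscles report identical triples and pair averaging is a plain
component-wise mean.

## Two-step stage analysis

1. **Full contraction**: all muscles at full force simultaneously. Reports
   the force transferred to the neurocranium (the negated reaction
   resultant over the contact set), the bite force, and the von Mises
   hotspot.
2. **Sliding removal**: part of the contact reaction lies along the
   anterior–posterior (rostro-caudal, ±y) axis — the jaw would slide along
   the neurocranium rather than compress it. One muscle pair is rescaled
   so the net AP reaction vanishes. Because the solution is linear in the
   pair's scale `s`, two solves (all-but-pair, pair-alone) give the zeroing
   scale in closed form, `s* = −AP_rest / AP_pair`. The literal reduction
   factor `X = (F_total − F_old)/F_old`, evaluated on AP force components,
   is computed alongside; algebraically `s* = −X`, and the reported
   `discrepancy = |s* + X|` verifies the two routes agree (≈ solver
   tolerance). `X` is flagged infeasible outside [0, 1]. When the pair
   opposes the rest of the musculature along AP — the physically intended
   configuration — `s*` lands in [0, 1] and the operation is a genuine
   reduction. Both numbers are reported rather than asserting a single
   interpretation, because the verbal goal (no AP sliding) and the printed
   formula admit either reading.
3. The compressive force **normal to the neurocranium** is evaluated on
   the reduced case, as the negated contact reaction projected onto the
   area-weighted mean outward facet normal of the contact patch. The
   global-dorsal projection is reported beside it; the two coincide for a
   flat dorsal patch and differ for curved ones, and neither is privileged.

**Bite force** is the magnitude of the vector resultant of the unreduced
biting-muscle loads (default: levator externus 4 + levator posterior,
both sides), these being taken as fully transmitted to the jaw during
biting. No lever-arm moment balance is attempted — no lever geometry is
part of the model. Bite force and von Mises stress are assessed without
the sliding reduction, since biting benefits from shear and does not
require static compression.

**Hotspot**: maximum per-element von Mises over elements *not* within one
node-ring of the contact or any insertion set. This replaces manual,
case-by-case screening of load-application artefacts with a reproducible
exclusion rule. One ring (expand the seed node sets once through element
adjacency, then drop every element touching the expanded set) removes
roughly two element layers around each patch.

**Percent change** between stages is the later/earlier ratio × 100
(a rise from 0.1 N to 0.337 N reports as 337%). Both this and the
(later−earlier)/earlier reading exist in the literature; the ratio
convention is used consistently and stated here because the two are easy
to conflate.

## Solver numerics

* Constraints by row/column elimination (reduced system), so reactions
  `(K d − P)` at fixed freedoms are exact; prescribed nonzero
  displacements are supported for patch-test style driving.
* Direct sparse LU up to 300k free DOFs, Jacobi-preconditioned CG at
  1e-10 relative tolerance beyond. Every solve verifies the reduced
  residual ≤ 1e-8 relative and raises otherwise.
* Stress is constant per element; principal values/directions from a
  symmetric eigensolve, sorted descending. Nodal smoothing is not used in
  any metric.
* Degenerate inputs (inverted elements, empty insertion sets, coincident
  centroids, a pair with no AP component, a zero-area contact patch) raise
  with specific messages rather than producing numbers.

## Materials and units

Units are mm / N / MPa package-wide (N·mm⁻² ≡ MPa, so no conversions
enter the assembly). Defaults: bone E = 3670 MPa (the low end of the
published 3.67–8.40 GPa range for fish bone, appropriate for larval,
fully ossified but young structures), tooth E = 70000 MPa (young teeth),
ν = 0.3 for both; all overridable per region tag in configuration.

## Synthetic phantoms

No scan data is distributed, so all testing runs on generated phantoms:

* **Bar**: structured box of Kuhn-subdivided cells (six tets per cell
  sharing the main diagonal — conforming across cells) with end-face node
  sets. Used for δ = FL/(EA), σ = F/A, patch tests, and the single-node
  vs distributed loading comparison.
* **Jaw phantom**: two box lobes (default 0.4 × 0.6 × 0.4 mm) joined by a
  thinner midline bridge (0.2 × 0.2 × 0.15 mm, dorsal surface flush with
  the lobe tops). The left half is the exact reflection of the right half
  across x = 0 (midplane nodes shared), so bilateral symmetry holds
  element-by-element and symmetric loads provably produce mirror fields.
  The dorsal bridge surface is the fixed `contact_neurocranium` patch;
  every muscle load must therefore cross the small bridge cross-section,
  which makes the bridge the engineered stress concentration — the
  phantom analogue of the inter-lobe attachment zone where real UPJ
  stress localises. Tooth-cap elements (region 2) sit on the ventral
  lobe faces. Three bilateral muscles insert on the lateral, caudal and
  dorso-caudal lobe surfaces with explicit dorsally-placed origin points;
  the adductor pair pulls slightly rostral and the retractor strongly
  caudal, so the retractor is a meaningful reduction pair with
  `s* ∈ [0, 1]`. Placeholder PCSAs (0.012–0.020 mm²) put per-muscle
  forces at 0.03–0.05 N, the magnitude range plausible for larval jaws.
  Default resolution: 3 element layers through the bridge (~9.5k
  elements, ~6.5k DOFs) — large enough for non-trivial fields, small
  enough that a full two-step stage runs in about a second.
* **Growth series**: stage k scales coordinates and origin points by the
  cumulative per-axis factors (default isotropic 1.26 per stage, i.e.
  volume doubling) and PCSA by the transverse product fx·fy (the
  cross-section plane of the predominantly dorsally pulling muscles).
  Isotropic growth provably preserves all angles; dorsal-dominant
  anisotropic growth rotates every muscle monotonically toward 90° MLA,
  emulating the dorsal reorientation trend seen during cranial growth.

What the phantoms do **not** emulate: realistic jaw curvature and
cartilage, muscle wrapping, spatially varying bone properties, contact
compliance at the basipharyngeal joint, or measured PCSAs. Passing tests
demonstrate the correctness of the mechanics and bookkeeping, not
agreement with any measured specimen.

## Known limitations

* TET4 stiffness over-estimation (above); no higher-order elements.
* Equal-split nodal loading is not traction-consistent (intentional).
* The reduction operates on one muscle pair; simultaneous multi-pair
  optimisation is out of scope.
* Stage chronology is taken from the configuration order; labels with
  leading numbers are additionally checked for monotonicity.
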