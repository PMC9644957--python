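# Methods

## Scope and intent

The package compares bite-induced stress fields between a robust and a
gracile longirostrine skull morphotype. The original comparison was made on
CT-based reconstructions of two fossil specimens in a commercial FE package;
here both the geometry and the solver are replaced by fully specified,
testable components. The scientific claims carried over are *relative* —
regional stress ratios, shifts between bite points, ordering of morphotypes —
never absolute stress magnitudes, which depend on mesh, element formulation
and muscle-reconstruction choices that are not recoverable.

## Parametric skull geometry

Each morphotype is a solid of revolution-like body: an elliptical
cross-section whose half-width `a(x)` and half-height `b(x)` are constant
over the posterior cranium, blend smoothly (cubic smoothstep over the
anterior 20% of the cranium) down to the rostrum-base dimensions, and then
taper along the rostrum as

    s(t) = tip + (1 − tip) · (1 − t)^p,   t ∈ [0, 1],

with `tip = 0.18` (a blunt snout tip that keeps anterior elements
non-degenerate) and `p` the morphotype's `taper_exponent`. Orbits are lateral
voids only: cells outside the mapped-coordinate line |η| > 0.5 and inside a
circle in the x–z plane are removed, leaving a median septum so the solid
stays connected. There is no internal braincase cavity; the palate is the
ventral plate of the cranium. Named regions are geometric proxies for the
osteological ones: `nasal` = dorsal half of the posterior half of the
rostrum, `rostrum` = the rest of the snout, `orbital` = cranium elements
within 1.3 orbit radii of the orbit centre, `palate` = ventral cranial plate,
`posterior_cranium` = remainder.

Meshing is a graded structured grid mapped square-to-ellipse per
cross-section (the mapping sends the square boundary exactly onto the
ellipse), split into six tetrahedra per hexahedron (Kuhn subdivision). Cells
in the left half use the mirrored subdivision so the triangulation — not just
the node cloud — is bilaterally symmetric; the shared faces on the symmetry
plane conform because that plane is pointwise fixed under the mirror.
Anteroposterior grid spacing shrinks with the taper so edge aspect ratios
stay bounded (default bound 8; violations are reported, never silently
accepted). Mesh volume is checked against the analytic volume of the
parametric solid (quadrature of the map Jacobian, independent of the mesh);
at default granularity both presets agree within 1.3%.

### Preset parameters

| parameter | robust | gracile | basis |
|---|---|---|---|
| total skull length (mm) | 401 | 335 | published estimate / preserved length |
| preserved length (mm) | 185 | 335 | published (robust anterior rostrum broken) |
| rostrum fraction | 0.62 | 0.55 | longer rostrum relative to cranium in the robust form |
| rostrum base H×W (mm) | 42×34 | 30×26 | robust vs slender snout contrast |
| taper exponent | 1.0 | 1.3 | gracile snout thins faster |
| cranium H×W (mm) | 80×72 | 82×74 | similar posterior skulls, gracile slightly larger cranial share |
| orbit diameter (mm) | 52 | 62 | gracile has the larger orbit |
| target edge length (mm) | 6 | 6 | desk-scale default (≥ 20k elements each) |

Only the lengths in the first two rows are published numbers; the
cross-sectional dimensions encode the printed *proportional* contrasts
(exact orbit and snout sections of the fossils are not tabulated) and were
fixed once, before any stress field was computed.

## Muscle model

Muscle dimensions are consumed from the packaged transcription of the
published table (not recomputed from 3D muscle solids, which would require
the fossil geometry). `F_max = (V/(L/3)) · P` with `P = 0.3 MPa`; no
intermediate rounding, and presentation rounds half away from zero — the
published per-muscle forces demand this (0.3 × 108.33 = 32.5 prints as 33).
The printed totals (158 N and 291 N) include the jaw-opening depressor; a
flag excludes depressors for sensitivity work.

Node counts per attachment area follow the published protocol (50 mAMIps,
30 mAMEpr, 35 shared mAMEsu/mAMEme origins; 115 combined coronoid insertion
= 30+35+50; 50/25/40 for mAMIpt/mAMP/mDM), interpreted as totals over both
sides by analogy with the bite-node counting; selection is deterministic
farthest-point subsampling on the right side, mirrored exactly to the left.
Per-node magnitude divides by the number of nodes actually loaded, so the
summed applied magnitude equals ΣF_max exactly.

Because the mandible is not meshed, insertion patches are geometric proxies
on the ventral/lateral cranial margin that anchor the pull directions; by
default only origin nodes are loaded (force on the cranium pointing toward
the mandible, as in the source protocol), with `load_insertions=True` giving
the self-equilibrated couple variant.

## Finite-element solver

Linear (constant-strain) tetrahedra, single-point stress evaluation;
homogeneous isotropic bone (E = 15,000 MPa, ν = 0.29) everywhere — no
sutures, no cartilage, matching the akinetic-skull assumption. Constraints
are imposed by freedom elimination, so reaction forces are recovered exactly
and global equilibrium holds to solver precision (verified ≤ 1e-6 relative).
Direct sparse factorisation (SuperLU) by default; diagonal-preconditioned
conjugate gradients (tolerance 1e-10) as a fallback for large meshes.
Verification: exact patch test on a perturbed box, 6 rigid-body modes before
constraints, dense-solve oracle agreement ≤ 1e-8 on small meshes, axial-bar
and cantilever convergence (extreme-fibre bending stress within 10% of
M·c/I at 6 element layers through the depth, error decreasing under
refinement — constant-strain tets are stiff in bending, so layer counts
below ~4 are not trustworthy for bending-dominated questions).

Regional summaries are volume-weighted statistics of per-element von Mises
stress; elements touching loaded or fixed nodes are excluded (counted
separately) to keep constraint-singularity artefacts out of the regional
means.

## Load cases

Each bite case fixes (zero degrees of freedom) ten nodes per basicranium
side — a compact occipital-condyle proxy — plus 20 bite nodes (5 per tooth ×
2 adjacent teeth × 2 sides) at one tooth-row position, with the full
seven-muscle loading applied bilaterally. The robust morphotype is simulated
on its *preserved* extent: the mesh is truncated to 185/401 of total length
(its broken anterior rostrum carried neither loads nor constraints), its two
cases sit at the most posterior and the foremost preserved teeth, and the
foremost case is treated as the analogue of the gracile mid-tooth-row bite.
The gracile morphotype runs posterior, mid and anterior-tip cases — five
simulations in all.

## Comparison layer

Figure-level claims are operationalised as region-statistic inequalities:

1. gracile rostral severity — volume-weighted rostrum+nasal mean von Mises,
   averaged over the shared bite positions — exceeds robust;
2. gracile nasal shift index, (mean_mid − mean_posterior)/mean_posterior,
   exceeds robust;
3. the gracile nasal mean is maximal at the mid bite among its three cases.

All three hold at default granularity and one refinement level up (0.8×
edge length). No significance claims are attached: these are directions with
supporting numbers, as in the source analysis.

The truncation control removes the gracile rostrum anterior to the robust
preserved-length share and re-solves the posterior bite: the
posterior-cranium regional mean changes by ~1.7%, confirming the missing
snout tip does not distort the comparison.

## What a green contrast does and does not establish

The synthetic skulls emulate: the published lengths, the proportional
robusticity contrasts, bilateral symmetry, seven bilateral muscle groups with
the published force magnitudes and node counts, and the published constraint
protocol. They do not emulate: real cranial bone arrangement (individual
bones, sutures, fenestrae other than the orbit), the true orbit/naris
geometry, tooth sockets, the mandible, or bone heterogeneity. A green
verdict therefore establishes that the published *relative* findings follow
from the stated proportional geometry and loading protocol under linear
elasticity — not that the absolute stress values of the fossils are
reproduced.

## Known limitation: lever vs FEA tip-bite consistency

The source study reports close agreement (59 N vs 56 N) between the FE
reaction "at a single node" at the gracile snout tip and the lever-equation
estimate. In this package's stated world the check fails by two orders of
magnitude: with fully fixed basicranium and tooth constraints, load divides
by path stiffness, and the bending compliance of a ~180 mm slender elastic
rostrum (section moments of a few mm⁴ near the tip) shunts almost all muscle
torque to the nearby basicranium, leaving ~1 N vertical reaction at the tip
constraint. The check is implemented exactly as stated (summed vertical
bite-node reaction within a factor of two of the lever estimate) and left
failing rather than relaxed; the posterior-bite cases, where the load path
is stiff, transmit an order of magnitude more force, consistent with the
mechanism.

## Numerical and interface choices

- Consistent mm–N–MPa unit system; +x anterior, y = 0 symmetry plane,
  +z dorsal.
- All randomness flows through one seeded generator; every selection in mesh
  and load-case construction is deterministic, so identical config + seed
  gives byte-identical tables.
- Rounding: full precision internally, half-away-from-zero at presentation.
- Config is YAML validated field-by-field with errors naming the offending
  key; a config hash and the seed are embedded in all outputs.
- Mesh/field exchange: legacy-VTK ASCII unstructured grids (volume, node
  sets, regions, displacements, stress tensors, and a display copy of von
  Mises clamped to 0–3 MPa) and ASCII STL surfaces. These writers/readers
  are minimal in-package implementations because no installed library
  provides the formats.
- In-lever lengths are not published: lever fixtures carry the printed
  mechanical advantages, and the back-of-tooth-row out-levers are algebraic
  back-solves from the printed forces (marked `implied` in the fixture),
  recorded as arithmetic, not anatomy.
- The dentition fixture transcribes the printed table verbatim, including
  one row whose printed diameter (2.8 mm) is inconsistent with its printed
  aspect ratio (0.5) and with the printed mean diameter (2.7); the
  corresponding acceptance checks fail against the printed values and are
  left red rather than "corrected".
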