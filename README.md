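# ichthyofea

Comparative cranial feeding biomechanics for two longirostrine ichthyosaur
morphotypes — a robust-snouted *Stenopterygius*-like form and a
gracile-snouted *Hauffiopteryx*-like form — built as a fully synthetic,
desk-scale pipeline: no CT data is needed, because the skulls are parametric
tetrahedral solids that encode the published proportional contrasts.

## Who this is for

Functional morphologists and palaeobiologists who want a reproducible,
scriptable version of the classic comparative cranial finite-element
workflow: dry-skull muscle-force estimation, bilateral bite-point load cases,
linear-elastic von Mises stress fields, jaw lever mechanics, and
morphotype-contrast statistics — with every stage unit-tested and seedable.

## The models

**Muscle forces (dry-skull estimate).** For each of the seven jaw muscles
(mAMEpr, mAMEsu, mAMEme, mAMIps, mAMIpt, mAMP, mDM), with reconstructed
volume *V* (mm³) and length *L* (mm):

    F_max = (V / (L/3)) · P

where *L*/3 is the muscle-fibre length and *P* = 0.3 MPa (300 kPa) the
standard specific muscle stress. Forces are distributed over attachment node
sets with the "two nodes" method (each loaded node pulls toward its paired
node on the opposing attachment).

**Finite elements.** Self-contained small-deformation linear-elastic solver
on 4-node (constant-strain) tetrahedra; homogeneous isotropic bone
(E = 15,000 MPa, ν = 0.29); constraints (20 bite nodes per case, 10 nodes per
basicranium side) eliminated from the system so reactions are exact; von
Mises stress per element; volume-weighted regional summaries.

**Bite force (jaw lever).** Mechanical advantage A = in-lever / out-lever,
and bite force F = F_total · A at each tooth-row position.

## Worked example

```python
from ichthyofea import muscles, levers

ms = muscles.default_muscles("M1399")          # gracile specimen fixture
total = muscles.total_muscle_force(ms)          # 291.12 N (prints as 291)
lever = levers.lever_from_fixture("M1399")      # mechanical advantage 0.191
print(round(levers.bite_force(total, lever.advantage_tip)))   # 56
```

The full comparative run (about 15 s on one CPU):

```bash
ichthyofea all --out results/run --seed 0
```

prints the three contrast verdicts, all of which hold in this synthetic
world and are stable one mesh-refinement level up:

```
PASS  gracile rostral (rostrum+nasal) mean von Mises exceeds robust
PASS  gracile posterior-to-mid nasal shift index exceeds robust
PASS  gracile nasal mean is maximal at the mid-tooth-row bite
```

Meaning: the slender-snouted morphotype concentrates markedly more stress in
its rostrum and nasal region, and is far more sensitive to where along the
tooth row it bites (nasal shift index ≈ 22 vs ≈ 7.5 for the robust form) —
the biomechanical signature of dietary niche partitioning between the two.

The numbered scripts under `analysis/` run the same stages as a narrative
sequence (tables → meshes → bite simulations → contrasts → truncation
control), each writing its outputs under `results/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged specimen fixtures and the library code, the
headline published quantities: two per-muscle maximum forces, both
seven-muscle force totals, and both tip-of-tooth-row bite forces, writing
them as JSON keyed by target id.

## Layout

```
src/ichthyofea/   library: skull (parametric meshing), muscles, fem,
                  levers, dentition, compare, io, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite incl. acceptance criteria
scripts/          acceptance.py
docs/methods.md   model assumptions, parameters, numerical choices, limits
```
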