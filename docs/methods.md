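# Methods

This note documents the model, the optimizer, every frozen numerical
choice, what the synthetic fixtures do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Assembly model

A cyclic (Cn) complex is built from a single rigid subunit and four
parameters `[α, β, γ, x]`:

1. the subunit is centered on its Cα centroid;
2. rotated by the Euler angles (α, β, γ) — **intrinsic ZYZ, right-handed**,
   about the centroid;
3. translated to `(x, 0, 0)` (x = ring radius, Å);
4. replicated by rotations of `2πk/n, k = 0..n−1` about the z axis.

The symmetry axis is therefore always z through the origin and the first
copy sits on +x. Any fixed Euler convention spans SO(3), so the choice
does not affect what can be represented; it is frozen so parameter vectors
are reproducible across versions. Whether the original rotation center is
the centroid or the file origin is not determinable from the protocol's
outputs; the centroid is used because it makes `x` directly interpretable
as the ring radius. Angles are radians internally; the CLI accepts
degrees. Blind-dock mode appends a 6-dof global pose (ZYZ rotation about
the assembly centroid + translation) applied after moving the assembled
ring to the map center, for 10 parameters total.

Only Cn symmetry is implemented; subunits are rigid throughout.

## Scores and constraints

**Steric energy (E_phys).** 9-6 Lennard-Jones over inter-subunit Cα
pairs: `4ε[(σ/r)⁹ − (σ/r)⁶]`, σ = 4.7 Å, ε = 1 kcal/mol, truncated (not
shifted) at 12 Å; the ≈ −0.0136 kcal/mol discontinuity at the cutoff is
accepted, as usual for coarse scoring. *All* copy pairs contribute, not
only adjacent ones: in closed rings non-adjacent copies can clash.
E_phys < 0 simultaneously excludes clashes and requires contact.
As a viability constraint the strict inequality is realized as the upper
bound −1e−6 kcal/mol, so a completely separated assembly (E_phys = 0)
does not count as viable.

**Distance restraints.** Each restraint is an interval
`[t − e, t + e]` (default e = 2 Å) on the Euclidean distance between a
named atom (Cα or Cβ) of residue a on copy 0 and residue b on copy 1.
Adjacent interfaces are equivalent under Cn, so the 0–1 interface
represents them all. The viability bounds apply to the *observed*
distance — bounds on the fixed target value would constrain nothing.

**E_data** (legacy baseline only): `sqrt(Σ(oᵢ − tᵢ)²)`. The weighted-sum
reference mode minimizes `w·E_phys + (1−w)·E_data` with w = 0.2. No
viability protocol ever aggregates scores this way.

**Diversity.** `diversity(x) = sqrt(Σᵢ ‖x − Xᵢ‖²)/n` over the n search
units' means. Computed in the normalized unit box (angles/2π, radius/x_max)
— in physical units the Euclidean metric would add radians to Ångströms.

**PPV.** `TP/(TP+FP)` of restraint satisfaction, where a restraint is
"satisfied" iff the observed distance lies in its own `[l, u]` interval
(no extra slack — the same criterion as viability). Undefined (reported
as such) when a model satisfies nothing.

**Crosslink objective.** For each profiled residue, the Cβ–Cβ distance
between the two copies of that residue; the objective is the magnitude
|R| of the Pearson correlation against the fractional-crosslinking values.
Physically the correlation should be negative (more crosslinked ↔ closer),
and the signed value is always reported alongside, but the magnitude is
maximized so the search is agnostic to the sign convention of the input
profile.

## The optimizer (mViE)

A population of (1+1)-CMA-ES local search units under per-constraint
viability boundaries, recombined by Differential Evolution, driven by a
fixed-cycle scheduler. All search happens in the normalized unit box.

Frozen defaults (all configurable via `MvieSettings`):

| parameter | default | role |
|---|---|---|
| n_units | 20 | population of local search units |
| success target | 2/11 | 1/5th-rule target success rate |
| success smoothing c_p | 1/12 | success-rate low-pass |
| step damping d | 1 + dim/2 | σ adaptation rate |
| rank-one learning rate | 2/(dim² + 6) | Cholesky-factor update |
| initial σ | 0.25 | quarter of the unit box |
| DE variant | rand/1/bin, F = 0.7, CR = 0.9 | global recombination |
| scheduler | 10 local generations : 1 DE sweep | exploitation/exploration cycle |
| boundary schedule | linear to 0 at 50% of budget | viability tightening |

Mechanics:

- **Sampling**: `y = m + σ·A·z`; out-of-box proposals are resampled up to
  10 times, then clipped, so budget accounting stays exact.
- **Selection** is lexicographic: fewer boundary-violated constraints →
  smaller total boundary violation → better objective (only when both are
  viable) → incumbent. No weighted aggregation anywhere.
- **Boundaries** start at the per-constraint maximum violation of the
  initial population (every starting unit is viable w.r.t. the starting
  boundaries) and are tightened each generation to the minimum of
  (previous value, worst current unit, linear schedule hitting zero at
  half budget); they never increase.
- **Archive**: every evaluated candidate satisfying the *final* bounds
  (violation ≤ 1e−9) is archived; `best` is the archive's best by
  objective, or the least-violating candidate flagged infeasible if the
  archive stays empty.
- **Determinism**: one master seed; per-unit and DE streams are derived
  sub-streams, so runs are bit-reproducible regardless of scheduling.
- Every evaluated parameter vector — local step, DE trial, initial mean —
  counts once against the budget; whether the problem also has an
  objective does not change the count.

When the constraint list is empty the machinery reduces to a memetic
unconstrained optimizer (used by the weighted-sum baseline).

## Density maps

Maps are simulated from the Cα trace as sums of unit-weight isotropic
Gaussians with **FWHM = nominal resolution** (σ = res/2.3548), truncated
at 3σ, on a grid padding the bounding box by 3σ. Default voxel is
resolution/3 (15 Å → 5 Å). Cα-only unit weights match the resolution of
the scoring model. The ccc is the Pearson correlation over voxels where
either map exceeds 1e−6 of its own maximum — without the floor, empty
space dominates and inflates correlations. An optional 6-neighbor
discrete Laplacian (zero-gradient borders) sharpens boundary information
for low-resolution fitting.

Rigid fitting is a deterministic multistart local search (identity first,
then octahedral-group orientations; Powell polishing; translation
initialized by aligning the Cα centroid to the map's center of mass) —
not an FFT-exhaustive search. Adequacy is demonstrated by self-fit and
ground-truth-recovery tests rather than claimed generally. For ranking
many centroids that share the canonical symmetry frame with the map, a
cheaper fit (ring-phase scan about z, up/down flip, short polish) is the
default; the full 6-dof fit is available via `fit="full"`.

In the density-as-objective protocol the alignment frame is refreshed
every 1000 evaluations by re-fitting the best viable model so far;
between refreshes candidates are scored in the current frame.

I/O: MRC/CCP4 mode-2 via gemmi (the map origin is stored in MRC header
words 50–52), and the SITUS ASCII dialect (7-number header, x-fastest
values) parsed directly.

## Post-processing

**Clustering**: agglomerative **complete linkage** on fixed-frame Cα-RMSD,
cut at 1 Å. Complete linkage is the only standard linkage whose clusters
provably keep all pairwise RMSDs below the cut, which is the stated
contract of the cluster report; the contract is re-verified post hoc on
every run. The fixed common frame (no superposition) is deliberate: all
candidates are generated in the same symmetry frame, and superposing
before clustering would merge genuinely different radii and orientations.
At desk scale at most 400 archived candidates (best by objective,
deduplicated on rounded parameters) enter the pairwise RMSD computation.

**Reference comparison** uses optimal (Kabsch) superposition, minimized
over the n cyclic chain relabelings; subunit copies are interchangeable,
so a relabeled model is the same structure. Reflection matching exists
but is off by default — a mirror image is *not* the same structure. Both
the fixed-frame and superposed comparisons are exposed, since either
convention is defensible for benchmarking.

**Audit**. Restraint pools carry truth labels; mixtures take the full
5-restraint true pool and add 1–4 wrong restraints. Because contradictory
restraints usually make full viability unsatisfiable, the audited model
set is the archive plus the final search-unit incumbents: once the
boundaries reach zero, the lexicographic comparator makes each unit
minimize the *number* of violated restraints, so incumbents are exactly
the "maximize restraints satisfied" models the audit needs. A
interval-widening ladder (δ ∈ {0, 1, 2, 4} Å) is kept as a fallback for
the degenerate case where that pool satisfies nothing. An earlier design
that widened the intervals before searching was discarded: diversity
maximization inside the widened region scatters models away from every
original interval.

Known property: when wrong restraints are as numerous as true ones and
happen to be mutually consistent, a distorted geometry can satisfy more
restraints than the native one, and the audit's precision drops. The
audit is reliable in the regime it is designed for — wrong restraints in
the minority.

## Synthetic fixtures

The generator provides everything the protocols consume, determined
entirely by seeds:

- **Toy subunits**: Cα traces with pseudo-Cβ atoms (1.5 Å along a fixed
  local direction — full side chains would add nothing to a Cα/Cβ scoring
  model). `helix` is an ideal α-helix trace (rise 1.5 Å, 100°/residue,
  radius 2.3 Å; consecutive Cα ≈ 3.8 Å); `compact-random` is a
  self-avoiding 3.8 Å-step chain biased toward its centroid, all pairs
  ≥ 3.8 Å — a stand-in for a globular domain.
- **Ground-truth rings**: random orientation, radius = smallest x (0.25 Å
  line search) with E_phys < 0 and no Cα pair closer than 3.0 Å: contact
  without clash, like a native interface.
- **True restraints**: sampled from interfacial Cα pairs < 8 Å, target =
  true distance — the truth satisfies them exactly.
- **Wrong restraints**: plausible-looking targets (6 ± 2 Å) assigned to
  pairs whose true distance exceeds the interval by ≥ 5 Å, so no 2 Å
  interval can be accidentally right.
- **Crosslink profiles**: logistic in the inter-subunit Cβ distance
  (midpoint 12 Å, scale 3 Å) plus Gaussian noise (default sd 0.05),
  clamped to [0, 1] — the monotone distance–crosslinking relation of
  disulfide scanning data.

Fixture geometry per protocol: restraint-driven protocols use the helix
toy; density-driven protocols (blind dock, ccc objective) use the
globular toy. Measured reason: at 15 Å the helix ring's mirror image
renders a density within 2e−5 ccc of the true one, so a density-only
objective cannot distinguish enantiomers — an identifiability property of
that fixture, not of the method. Real globular subunits (and the
compact-random toy, mirror ccc ≈ 0.9997) do not have this degeneracy.

What the fixtures do **not** emulate: side-chain packing, flexibility,
experimental map noise and anisotropy, B-factor variation, restraint
ambiguity from homologous sites. Passing recovery tests therefore shows
the search and scoring machinery works under the stated geometric
assumptions, not that predictions on real complexes reach the same
accuracy.

## Problem sizes used

Recovery and audit experiments in the test suite and acceptance script
use 20–24-residue subunits, C2–C5 rings, budgets of 3,000–20,000
evaluations and 2–5 independent runs — the package's chosen desk-scale
conditions. The production-scale settings from the protocol definitions
(20,000 evaluations for restraint-driven assembly, 100,000 for blind
docking) remain the defaults of the corresponding functions.

## Limitations

- Cyclic symmetry only; no dihedral/helical/icosahedral assemblies, no
  heteromeric complexes, no subunit flexibility.
- Cα/Cβ-level scoring only: no electrostatics, solvation or statistical
  potentials; models need external refinement for atomic detail.
- Map fitting is local multistart, not exhaustive; pathological maps with
  many distant false optima could defeat it.
- The Pearson crosslink objective assumes an approximately monotone,
  quasi-linear fraction–distance relation over the profiled residues;
  saturated profiles (all residues far from the interface) weaken it.
- The blind-dock translation box defaults to ±¼ of the map extent around
  the map center; complexes far off-center need a wider box.
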