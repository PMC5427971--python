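# viasm — viability-evolution assembly prediction

`viasm` predicts the architecture of cyclic (Cn) macromolecular complexes
by integrative modeling: it combines an atomic structure of one subunit
with heterogeneous experimental restraints — inter-subunit residue–residue
distances (e.g. from crosslinking mass spectrometry), low-resolution
density maps (cryo-EM), or fractional-crosslinking profiles (disulfide
scanning) — and searches for assemblies consistent with *all* of them.

It is written for structural bioinformaticians who have a subunit model
and sparse, noisy connectivity data, and want candidate assemblies plus an
audit of which restraints the models actually support.

## The method

A Cn assembly is parametrized by four numbers per complex: three Euler
angles (α, β, γ) orienting one subunit and the ring radius *x*; the other
n−1 copies follow by rotations of 2πk/n about the symmetry axis. Scores:

- **E_phys** — coarse steric energy, a 9-6 Lennard-Jones sum over
  inter-subunit Cα pairs: `E = Σ 4ε[(σ/r)⁹ − (σ/r)⁶]` with σ = 4.7 Å,
  ε = 1 kcal/mol, truncated at 12 Å. Negative values mean contact without
  clashes.
- **distance restraints** — each restraint *i* is an interval
  `[tᵢ − e, tᵢ + e]` on the observed distance *oᵢ* between two residues on
  adjacent subunit copies (default error e = 2 Å).
- **ccc** — Pearson cross-correlation between a model's simulated density
  (Gaussian kernel, FWHM = nominal resolution) and a reference map.
- **diversity** — `sqrt(Σᵢ ‖x − Xᵢ‖²)/n` of a candidate against the
  *n* search units, in normalized parameter coordinates.

The key design decision is **not** to sum these into one weighted fitness.
Instead the optimizer (memetic Viability Evolution) treats every restraint
and `E_phys < 0` as an independent *viability constraint*: a population of
(1+1)-CMA-ES local search units, periodically recombined by Differential
Evolution, survives only inside per-constraint viability boundaries that
tighten over the run until only fully consistent ("viable") models remain.
Once viable, units maximize an objective — solution diversity, map
cross-correlation, or a crosslink correlation, depending on the protocol.
Viable models are clustered (complete-linkage, 1 Å Cα-RMSD), and cluster
centroids are fitted into the reference map and ranked by ccc.

Protocols: `diversity` (restraint-driven assembly), `energy` (minimize
E_phys under restraints), `ccc_objective` (density-driven assembly under
restraints), `blind_dock` (density-only, 10 parameters: 4 assembly + 6
global pose), `crosslink` (homodimer interface from fractional
crosslinking), `audit` (precision of restraint satisfaction against truth
labels), and a legacy weighted-sum baseline.

## Worked example

Everything below is generated synthetically — no downloads. We build a
known C5 ring from a toy helix subunit, derive 3 true distance restraints
(±2 Å) and a 15 Å map from it, then ask the protocol to re-assemble the
complex from the subunit + restraints alone, using the map only for
ranking:

```python
from viasm import synthetic, density, protocols, postprocess

# toy ground truth: C5 ring of a 20-residue helix
subunit = synthetic.make_toy_subunit(synthetic.ToySpec(20, "helix", 0))
truth, params = synthetic.make_reference_assembly(subunit, 5, seed=1)
constraints = synthetic.derive_constraints(truth, 3, tolerance=2.0, seed=1)
density_map = density.simulate_map(truth, resolution=15.0)

result = protocols.protocol_diversity(
    subunit, 5, constraints, density_map, budget=10_000, seed=0
)
print(f"viable models archived: {len(result.run.archive)}")
print(f"clusters (1 Å complete linkage): {len(result.clusters)}")
for rank, (idx, model, _pose, ccc) in enumerate(result.ranked.top(3), 1):
    rmsd = postprocess.compare_to_reference(model, truth, 5)
    print(f"rank {rank}: ccc = {ccc:.4f}, Cα-RMSD to truth = {rmsd:.2f} Å")
```

Output:

```
viable models archived: 174
clusters (1 Å complete linkage): 8
rank 1: ccc = 0.9999, Cα-RMSD to truth = 1.12 Å
rank 2: ccc = 0.9983, Cα-RMSD to truth = 1.02 Å
rank 3: ccc = 0.9965, Cα-RMSD to truth = 1.93 Å
```

Of 10,000 sampled candidates, 174 satisfied all three restraint intervals
and `E_phys < 0` exactly; they fall into 8 structurally distinct clusters,
and the map ranks the near-native ones on top — about 1 Å from the true
assembly, i.e. recovered to well within the restraint error.

The same machinery is available from the shell:

```sh
viasm-fixtures --seed 1 --symmetry 5 --out-prefix toy    # emit toy inputs
viasm assemble --mode diversity --subunit toy_subunit.pdb \
      --symmetry 5 --constraints toy_constraints.txt --map toy_map.mrc
viasm dock --subunit toy_subunit.pdb --symmetry 5 --map toy_map.mrc
```

## Layout

- `viasm.structio` — PDB I/O (gemmi-backed), fixed-frame and superposed RMSD
- `viasm.assembly` — Cn assembly construction, global poses, search bounds
- `viasm.scoring` — E_phys, E_data, diversity, PPV, Pearson, crosslink objective
- `viasm.density` — map simulation, ccc, Laplacian filter, rigid fitting, MRC/SITUS I/O
- `viasm.mvie` — the viability-evolution optimizer
- `viasm.postprocess` — clustering, ccc ranking, restraint audits, reference comparison
- `viasm.protocols` — the experiment modes wired end to end
- `viasm.synthetic` — deterministic toy fixtures (subunits, rings, restraints, profiles)

See `docs/methods.md` for the model, the optimizer internals, all frozen
defaults and known limitations.
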