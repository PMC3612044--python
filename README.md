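# latticefold

Simplified (HP-style) protein lattice models on **square and triangular
lattices of arbitrary dimension**, with a lattice-agnostic move set and
two reference folding optimizers.

In lattice models a protein conformation is a self-avoiding walk on a
lattice, residues reduced to hydrophobic (H) and polar (P) types, and the
energy is the HP potential

    E = −(number of H–H contacts),

where a contact is a pair of residues at backbone separation ≥ 2 on
adjacent lattice vertices. Classically these models live on the 2-D
square or 3-D cubic lattice (coordination numbers 4 and 6); the Cα
neighbourhood of real globular proteins admits coordination numbers up to
about 20, which this package reaches by generalizing both lattice
families parametrically: the n-dimensional square lattice (c = 2n) and
the n-dimensional triangular lattice (c = n(n+1); n = 3 gives FCC with
c = 12, and n = 4, c = 20, is the largest triangular lattice inside the
admissible range). Everything downstream — adjacency, hop distances,
potentials, Monte Carlo moves (end, kink-jump, crankshaft, reptation,
pivot, pull), chain-growth and simulated-annealing optimizers — is
written against the lattice's *main directions* `D` only, so the same
code runs unchanged on any (kind, dimension) pair.

Audience: anyone doing computational experiments on coarse-grained
protein (or heteropolymer) models — conformation-space exploration,
move-set studies, folding heuristics — who wants the lattice to be a
parameter instead of a hard-coded special case.

## Worked example

Fold the bundled 24-residue benchmark (the first half of Harvard
instance 9) on the planar triangular lattice with the chain-growth
optimizer, look-ahead = commit = 3, ten seeded restarts:

```python
from latticefold import get_benchmark, make_lattice, chain_growth, CgConfig

entry = get_benchmark("HI 9/2")
print("sequence:", entry.sequence)
lat = make_lattice("triangular", 2)
res = chain_growth(entry.sequence, lat, CgConfig(runs=10, seed=1))
print("best HP potential:", res.best_potential)
print("first five residues:", res.best_model.coords[:5].tolist())
```

prints

```
sequence: PPHPHPPPPHPHPHPHPHHHHHHP
best HP potential: -12
first five residues: [[0, 0], [-1, 0], [-1, 1], [0, 1], [-1, 2]]
```

The potential −12 means the best of the ten growth runs packed twelve
H–H contacts; coordinates are integer lattice coordinates (multiply by
the basis matrix for Cartesian positions). The same model can then be
handed to the annealing optimizer, which perturbs conformations with the
six-move set under Metropolis acceptance:

```python
from latticefold import SimulatedAnnealingOptimizer, SaConfig, foldit
res2 = foldit(res.best_model, SimulatedAnnealingOptimizer(SaConfig(seed=1)))
```

There is also a CLI:

```
latticefold fold --bench "HI 4" --lattice triangular --dim 3 --optimizer cg --runs 10 --seed 1
latticefold lattice-info --lattice triangular --dim 3
latticefold movestats --bench "HI 9/2" --lattice square --dim 2 --out stats.csv
```

`lattice-info` prints, e.g., coordination number 12 and the FCC basis for
the triangular lattice in three dimensions.

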