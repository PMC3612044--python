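# Methods

## Model

`latticefold` implements simplified (HP-style) protein models on
parametric Bravais lattices. A lattice is specified by a *kind* and a
*dimension* n:

* **square** — basis `B = I`, main directions `D = {±e_i}`, coordination
  number `c = 2n` (4 in the plane, 6 for the cube). These lattices carry
  the parity constraint: residues at odd backbone separation can never be
  lattice neighbours.
* **triangular** — basis built iteratively so every primitive vector has
  unit length and every pair meets at 60° (Gram matrix with unit diagonal
  and 1/2 off-diagonal); `D = {±e_i} ∪ {±(e_i − e_j), i < j}`,
  `c = n(n+1)` (6 in the plane, 12 for FCC). No parity constraint.

All edges have length 1 by convention; adjacency of integer coordinate
vectors p, q is equivalent to `q − p ∈ D` and to `‖B(q − p)‖ = 1`. Main
directions are kept lexicographically sorted so every enumeration and
random draw is reproducible.

A survey of Cα neighbourhoods in globular proteins motivates an
*admissible range* of coordination numbers, roughly 3–4 up to 19–20; the
toolkit exposes the radial neighbour profile `N(r)` (counts of points
inside spheres of growing radius) to perform that census on any
coordinate set. The averaged profile restricts probe centres to points
within a configurable fraction of the gyration radius (default 0.5) so
the probing spheres stay inside the molecule. Within the admissible
range, the largest triangular dimension is 4 (`c = 20`); square lattices
stay admissible up to n = 10.

### Hop distance

The potential needs a lattice metric. Square lattices use the Manhattan
distance in lattice coordinates. The planar triangular lattice has the
closed form: for Δ = q − p, the hop distance is the sum of the two
smallest of `|Δ₁|, |Δ₂|, |Δ₁ + Δ₂|`; the test suite validates it against
an independent breadth-first search, which is also the authority in
higher dimensions. For triangular lattices with n ≥ 3 an exact BFS is
used up to a configurable cutoff (default 6 — contact potentials only
ever ask about small distances); beyond it the ceiling of the Euclidean
distance is returned and flagged approximate.

### Conformations and rigid motions

A conformation is an ordered list of integer lattice coordinates bound to
a sequence (absolute encoding, residue 0 at the origin for all builders).
The differential encoding (successive steps) is derived on demand;
translation leaves it unchanged. The relative encoding is deliberately
out of scope. Self-avoidance checking is linear in N via a hash of
occupied vertices.

Rotations follow the linear hypothesis: an n-dimensional rotation acts in
the 2-plane spanned by a source and a destination main direction and
fixes the orthogonal (n−2)-subspace. When the two directions are
antiparallel the plane is ambiguous; we take the half-turn in the plane
of the source and the lowest-index main direction not parallel to it, for
determinism. Rotated branches may leave the lattice on triangular
lattices; coordinates are accepted when within 1e−6 of integers (far
below half the lattice spacing) and rejected otherwise.

## Potentials

The HP potential counts H–H contacts — pairs of H residues at backbone
separation ≥ 2 on adjacent vertices — each contributing −1. Two
implementations coexist deliberately: a direct quadratic pair loop (the
transparent textbook transcription) and an O(N·c) occupancy-map evaluator
used by the optimizers; their equivalence is asserted on hundreds of
random conformations.

The generalized potential is `Σ_{j≥i+2} g(d_hop(i,j)) · C(s_i, s_j)` with
a symmetric coefficient table `C` and a distance factor `g` that vanishes
beyond a small cutoff (default: contacts only, `g(1) = 1`). The HP table
reduces it exactly to the HP potential. A CSV-table constructor supports
20-letter alphabets; no published coefficient values are bundled.

## Move set

Six move types, all defined through adjacency only, hence
lattice-agnostic: end, kink-jump (corner), crankshaft, slithering snake
(reptation), pivot and pull. Chain-breaking moves are excluded. Every
applied move must yield a *different* self-avoiding walk; destinations
equal to the current placement count as infeasible. Parameter sampling is
uniform over legal values, with no selection heuristics.

The pull move's step constant ν — the least number of hops the pulled
chain advances — is derived from the lattice: the minimum hop distance
over non-cancelling sums of two main directions. It is 2 for square
lattices (destination diagonal to the target, a free intermediate vertex
required and filled by the first pulled residue) and 1 for triangular
ones (some pairs of main directions are mutually adjacent). Subsequent
residues are pulled into the position vacated two steps earlier until one
is already adjacent to its predecessor (the semi-local property) or the
chain ends. The destination must keep the bond to the anchor (non-pulled)
neighbour; for a terminal target there is no anchor constraint.
The crankshaft generalization lets the new pair reuse one of the two old
vertices in a swapped role: only the pair as a whole must differ.

Attempt frequencies (try rates) are configurable; the defaults are snake
0.05, pivot 0.10, end 0.10, kink-jump 0.15, crankshaft 0.10, pull 0.50.
Only the reptation share is a published figure; the pull share follows
the replica-exchange literature's preference for pull-dominated move
sets, and the split is documented as a convention, not a canonical value.
Per-type counters yield the hit rate h (feasible applications over tries)
and the improvement fraction σ (share of all best-so-far improvements).

## Optimizers

Both optimizers sit behind a strategy-pattern interface: a
`ProteinModel.foldit()` call dispatches to whatever optimizer object is
attached, so the same model can be driven by different algorithms.

**Chain growth** (`CgOptimizer` role). Starting from the origin, all
self-avoiding placements of the next k residues are enumerated
(depth-first with incremental contact counting), scored with the HP
potential of the aggregate; among minimum-potential chunks the most
compact ones are kept (smallest mean Euclidean distance of the chunk's
vertices to the centroid of the placed aggregate, tolerance 1e−9), and
one is drawn uniformly with the run's seeded generator; its first l steps
are committed. Defaults k = l = 3. Dead ends abort the run rather than
backtracking; restarts are the mechanism for coverage, and the best over
`runs` independent seeded runs is reported. The random draw among
equally good chunks is what distinguishes runs; with a purely
deterministic tie-break every restart would retrace the same walk.
Partial aggregates are scored with the pure HP potential.

**Simulated annealing** (`SaSimpleOptimizer` role). Moves are drawn by
try rate and accepted by the Metropolis rule (always when ΔE ≤ 0, else
with probability `exp(−ΔE/(k_B T))`, k_B = 1) along an exponential
schedule `T ← αT` from T0 down to Tf. A cooling cycle is a *session*; as
long as a session improves the best-known conformation (is *fruitful*), a
new session starts from that best conformation (safety cap 50 sessions).
The first session starts from a straight chain. During the first half of
the first session's cooling-step indices an optional warmup potential is
used for acceptance: C(H,H) = −1 as in HP plus a uniform −0.25 for every
other pair at contact, driving early compaction; the reported best is
always scored with the pure HP potential. Numeric defaults — T0 = 2.0,
Tf = 0.15, α = 0.97, 20·N steps per temperature — are calibrated so a
48-residue chain on the 2-D square lattice finishes in about two
sessions; they are package conventions (the published description leaves
the values unrecoverable) and all configurable. "First half of the
temperature range" is interpreted on the cooling-step index, which is
well defined for exponential schedules.

**Combined search** (`latticefold.search.figure_potential_search`). The
protocol used to reproduce benchmark conformation potentials: seeded
chain-growth restarts followed by annealing sessions started from the
chain-growth optimum (warmup off — the start is already compact). On
low-coordination lattices the build-up heuristic alone stalls a few
contacts short of the figure-level minima and the annealing supplement
recovers them; on the 5-D triangular lattice chain growth alone
suffices. Problem sizes used by `scripts/acceptance.py`: 10 chain-growth
restarts (100 on FCC, where the candidate space per step is largest) and
one annealing invocation per lattice.

## Benchmark fixture

The bundled table carries the ten 48-residue Harvard instances (24 H
each), the 24-residue first half of the ninth (12 H), and four longer
sequences (90/135/164/200 residues). The distributed run-length notation
for these sequences is glyph-ambiguous in parts; entries whose notation
under-expands were reconstructed deterministically — missing residues
distributed round-robin over the ambiguous run-length tokens — so that
every entry meets its published (length, #H) pair exactly, which the
loader re-validates on every load and refuses to ship otherwise.
Reconstructed entries are flagged in their note field; HI 1–4 are
verbatim literature transcriptions. HI 9/2 is reconstructed first (a
single residue is ambiguous) and HI 9 is constrained to share its first
24 residues.

## What the synthetic inputs do and do not show

All conformational inputs are generated by the package itself (random
walks, straight chains, chain-growth builds); the only empirical anchors
are the published benchmark compositions and figure-level potentials.
Passing tests therefore demonstrate the correctness of the lattice
machinery, the move set and the optimizers on those benchmarks — not
that the HP model predicts real protein structure, and not that the
reconstructed benchmark rows are glyph-for-glyph the historical
sequences (their composition is exact; their residue order is a
documented reconstruction). The radial-profile utility is exercised on
synthetic point clouds; no curated structure data is bundled.

## Numerical choices and limitations

* Integrality tolerance for rotated branches: 1e−6, nearest-integer
  rounding.
* Random-walk builder: uniform feasible steps, single-step backtracking,
  full restart after 100·N failed extensions.
* Hop-distance BFS cutoff 6 (exact region); ceiling-of-Euclidean
  approximation beyond, flagged.
* Honeycomb/hexagonal lattices are out of scope (not a Bravais lattice in
  this framework); so are relative encodings, chain-breaking moves,
  detailed-balance-weighted pulls, and published 20-letter coefficient
  values.
* The optimizers are sequential; runtimes grow as `c^k` per chain-growth
  step and with N·c per annealing move, which in practice confines
  comfortable use to the admissible coordination range.
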