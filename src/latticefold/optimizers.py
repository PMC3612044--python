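"""Reference folding optimizers: chain growth and simulated annealing.

Both operate behind a strategy-pattern interface: an optimizer object holds
its parameters and is attached to a :class:`~latticefold.conformation.ProteinModel`,
whose ``foldit()`` dispatches to it.  Both are lattice-agnostic — the only
lattice knowledge they use is the main-direction list and the adjacency
services of the model's lattice — and bit-reproducible given their seed.

Chain growth builds the walk incrementally: an exhaustive enumeration of
the self-avoiding placements of the next ``k`` residues (the *look-ahead*)
is scored with the HP potential, the minimum-potential chunks are filtered
to the most compact ones (closest to the centroid of the aggregate built so
far), one is drawn at random, and its first ``l`` steps are committed.
Dead ends abort the run; the best conformation over independent runs is
reported.

Simulated annealing perturbs a conformation with the generalized move set
under Metropolis acceptance along an exponentially cooled temperature
schedule.  Cooling cycles (*sessions*) repeat as long as they improve the
best-known conformation (*fruitful* sessions); the first half of the first
session may score with a compaction-biased warmup potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .conformation import ProteinModel, linear_build
from .lattice import Lattice, to_cartesian
from .moves import DEFAULT_TRY_RATES, MoveStats, TryRates, random_move
from .potential import hp_potential

__all__ = [
    "CgConfig",
    "SaConfig",
    "OptimizerResult",
    "metropolis_accept",
    "chain_growth",
    "simulated_annealing",
    "ChainGrowthOptimizer",
    "SimulatedAnnealingOptimizer",
    "foldit",
]


@dataclass(frozen=True)
class CgConfig:
    """Chain-growth parameters: look-ahead ``k``, commit length ``l`` (both
    default 3), independent restarts and master seed."""

    look_ahead: int = 3
    commit: int = 3
    runs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.look_ahead < 1:
            raise ValueError("look_ahead must be >= 1")
        if not 1 <= self.commit <= self.look_ahead:
            raise ValueError("commit must satisfy 1 <= l <= k")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass(frozen=True)
class SaConfig:
    """Simulated-annealing parameters.

    ``steps_per_T`` of ``None`` means 20 moves per residue per temperature.
    The numeric defaults are calibrated so a short 2-D square-lattice chain
    finishes in about two sessions; they are conventions, not canonical
    values, and are all configurable.
    """

    T0: float = 2.0
    Tf: float = 0.15
    alpha: float = 0.97
    steps_per_T: Optional[int] = None
    kB: float = 1.0
    try_rates: TryRates = DEFAULT_TRY_RATES
    warmup: bool = True
    warmup_coefficient: float = -0.25
    seed: int = 0
    max_sessions: int = 50

    def __post_init__(self):
        if self.T0 <= 0 or self.Tf <= 0 or self.Tf >= self.T0:
            raise ValueError("temperatures must satisfy 0 < Tf < T0")
        if not 0 < self.alpha < 1:
            raise ValueError("cooling factor alpha must lie in (0, 1)")


@dataclass
class OptimizerResult:
    """Outcome bundle: best conformation (HP-scored), run/session counts,
    move statistics (annealing only) and a (step, potential) trace."""

    best_model: Optional[ProteinModel]
    best_potential: float
    sessions_or_runs: int
    fruitful_sessions: int = 0
    move_stats: Optional[MoveStats] = None
    trace: list = field(default_factory=list)
    succeeded: bool = True


def metropolis_accept(
    delta_E: float, T: float, kB: float, rng: np.random.Generator
) -> bool:
    """Accept always when the energy does not increase; otherwise with the
    Boltzmann probability ``exp(-delta_E / (kB T))``."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_E <= 0:
        return True
    return rng.random() < math.exp(-delta_E / (kB * T))


# ---------------------------------------------------------------------------
# chain growth


def _enumerate_chunks(lattice, seq, coords, occ, start, depth):
    """DFS over all self-avoiding placements of residues
    ``start .. start+depth-1``, with incremental H-H contact deltas.

    Yields (delta_potential, steps, vertices) triples for complete chunks.
    ``occ`` maps occupied vertices to residue indices of the aggregate.
    """
    dirs = lattice._dir_tuples
    results = []
    chunk_occ = {}
    steps = []
    verts = []

    def place(level, tail, delta):
        if level == depth:
            results.append((delta, tuple(steps), tuple(verts)))
            return
        res_idx = start + level
        is_h = seq[res_idx] == "H"
        for d in dirs:
            v = tuple(a + b for a, b in zip(tail, d))
            if v in occ or v in chunk_occ:
                continue
            dpot = 0
            if is_h:
                for d2 in dirs:
                    w = tuple(a + b for a, b in zip(v, d2))
                    j = occ.get(w)
                    if j is None:
                        j = chunk_occ.get(w)
                    if j is not None and j <= res_idx - 2 and seq[j] == "H":
                        dpot -= 1
            chunk_occ[v] = res_idx
            steps.append(d)
            verts.append(v)
            place(level + 1, v, delta + dpot)
            del chunk_occ[v]
            steps.pop()
            verts.pop()

    place(0, tuple(int(x) for x in coords[-1]), 0)
    return results


def _chunk_compactness(lattice, verts, centroid_cart):
    pts = np.array([to_cartesian(lattice, v) for v in verts])
    return float(np.mean(np.linalg.norm(pts - centroid_cart[None, :], axis=1)))


def _cg_single_run(sequence, lattice: Lattice, cfg: CgConfig, rng):
    n = len(sequence)
    origin = tuple(0 for _ in range(lattice.dim))
    coords = [origin]
    occ = {origin: 0}
    potential = 0
    while len(coords) < n:
        start = len(coords)
        depth = min(cfg.look_ahead, n - start)
        chunks = _enumerate_chunks(lattice, sequence, coords, occ, start, depth)
        if not chunks:
            return None  # dead end: abort the run
        best_pot = min(c[0] for c in chunks)
        pool = [c for c in chunks if c[0] == best_pot]
        if len(pool) > 1:
            cart = np.array([to_cartesian(lattice, v) for v in coords])
            centroid = cart.mean(axis=0)
            scored = [
                (_chunk_compactness(lattice, c[2], centroid), c) for c in pool
            ]
            best_compact = min(s for s, _ in scored)
            pool = [c for s, c in scored if s <= best_compact + 1e-9]
        pool.sort(key=lambda c: c[1])
        delta, steps, verts = pool[int(rng.integers(len(pool)))]
        commit = min(cfg.commit, depth)
        for v in verts[:commit]:
            res_idx = len(coords)
            if sequence[res_idx] == "H":
                for d in lattice.main_dirs:
                    w = tuple(int(a + b) for a, b in zip(v, d))
                    j = occ.get(w)
                    if j is not None and j <= res_idx - 2 and sequence[j] == "H":
                        potential -= 1
            coords.append(v)
            occ[v] = res_idx
    model = ProteinModel(
        sequence=sequence, lattice=lattice, coords=np.array(coords, dtype=np.int64)
    )
    return model, potential


def chain_growth(sequence: str, lattice: Lattice, config: CgConfig) -> OptimizerResult:
    """Best conformation over ``config.runs`` independent chain-growth runs."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.runs)
    best_model = None
    best_pot = math.inf
    trace = []
    for run, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        out = _cg_single_run(sequence, lattice, config, rng)
        if out is None:
            trace.append((run, None))
            continue
        model, pot = out
        trace.append((run, pot))
        if pot < best_pot:
            best_pot = pot
            best_model = model
    if best_model is None:
        return OptimizerResult(
            best_model=None,
            best_potential=math.inf,
            sessions_or_runs=config.runs,
            trace=trace,
            succeeded=False,
        )
    return OptimizerResult(
        best_model=best_model,
        best_potential=best_pot,
        sessions_or_runs=config.runs,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# simulated annealing


def _contact_counts(coords, sequence, lattice, occ):
    """(H-H contacts, other contacts) over non-bonded adjacent pairs."""
    dirs = lattice._dir_tuples
    hh = other = 0
    for i in range(len(sequence)):
        p = tuple(int(x) for x in coords[i])
        for d in dirs:
            j = occ.get(tuple(a + b for a, b in zip(p, d)))
            if j is None or j <= i + 1:
                continue
            if sequence[i] == "H" and sequence[j] == "H":
                hh += 1
            else:
                other += 1
    return hh, other


def _energy(hh, other, warmup_active, warmup_coeff):
    if warmup_active:
        return -float(hh) + warmup_coeff * other
    return -float(hh)


def simulated_annealing(
    sequence: str, lattice: Lattice, config: SaConfig, initial=None
) -> OptimizerResult:
    """Session-repeating simulated annealing over the generalized move set.

    The first session starts from a straight chain (or ``initial``
    coordinates); each later session restarts from the best conformation so
    far and runs while sessions stay fruitful (capped at
    ``config.max_sessions``).  The reported best is always scored with the
    pure HP potential, also during the warmup phase.
    """
    rng = np.random.default_rng(config.seed)
    n = len(sequence)
    steps_per_t = config.steps_per_T if config.steps_per_T is not None else 20 * n
    temps = []
    t = config.T0
    while t >= config.Tf:
        temps.append(t)
        t *= config.alpha
    warmup_end = len(temps) // 2  # first half of the cooling-step indices

    if initial is not None:
        current = ProteinModel(
            sequence=sequence, lattice=lattice, coords=np.asarray(initial)
        )
    else:
        current = linear_build(lattice, sequence)
    occ = {tuple(int(x) for x in current.coords[i]): i for i in range(n)}
    hh, other = _contact_counts(current.coords, sequence, lattice, occ)
    best_hp = -float(hh)
    best_coords = current.coords.copy()
    stats = MoveStats()
    trace = []
    fruitful_sessions = 0
    sessions = 0
    step_counter = 0
    for session in range(config.max_sessions):
        sessions += 1
        session_improved = False
        if session > 0:
            current = ProteinModel(
                sequence=sequence, lattice=lattice, coords=best_coords.copy()
            )
            occ = {tuple(int(x) for x in current.coords[i]): i for i in range(n)}
            hh, other = _contact_counts(current.coords, sequence, lattice, occ)
        for t_index, temp in enumerate(temps):
            warmup_active = (
                config.warmup and session == 0 and t_index < warmup_end
            )
            for _ in range(steps_per_t):
                step_counter += 1
                outcome = random_move(current, config.try_rates, stats, rng)
                if not outcome.applied:
                    continue
                new_occ = {
                    tuple(int(x) for x in outcome.new_coords[i]): i for i in range(n)
                }
                new_hh, new_other = _contact_counts(
                    outcome.new_coords, sequence, lattice, new_occ
                )
                delta = _energy(
                    new_hh, new_other, warmup_active, config.warmup_coefficient
                ) - _energy(hh, other, warmup_active, config.warmup_coefficient)
                if metropolis_accept(delta, temp, config.kB, rng):
                    current = ProteinModel(
                        sequence=sequence, lattice=lattice, coords=outcome.new_coords
                    )
                    occ, hh, other = new_occ, new_hh, new_other
                    if -float(hh) < best_hp:
                        best_hp = -float(hh)
                        best_coords = current.coords.copy()
                        stats.record_improvement(outcome.move_type)
                        session_improved = True
            trace.append((step_counter, best_hp))
        if session_improved:
            fruitful_sessions += 1
        else:
            break
    best_model = ProteinModel(sequence=sequence, lattice=lattice, coords=best_coords)
    assert hp_potential(best_model) == best_hp
    return OptimizerResult(
        best_model=best_model,
        best_potential=best_hp,
        sessions_or_runs=sessions,
        fruitful_sessions=fruitful_sessions,
        move_stats=stats,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# strategy pattern


class ChainGrowthOptimizer:
    """Strategy wrapper around :func:`chain_growth` (CgOptimizer role)."""

    def __init__(self, config: CgConfig | None = None, **kwargs):
        self.config = config if config is not None else CgConfig(**kwargs)

    def optimize(self, model: ProteinModel) -> OptimizerResult:
        return chain_growth(model.sequence, model.lattice, self.config)


class SimulatedAnnealingOptimizer:
    """Strategy wrapper around :func:`simulated_annealing`."""

    def __init__(self, config: SaConfig | None = None, **kwargs):
        self.config = config if config is not None else SaConfig(**kwargs)

    def optimize(self, model: ProteinModel) -> OptimizerResult:
        return simulated_annealing(model.sequence, model.lattice, self.config)


def foldit(protein_model: ProteinModel, optimizer=None) -> OptimizerResult:
    """Run the attached (or given) optimizer on the model; the model itself
    is left untouched and can be re-bound to a different optimizer later."""
    return protein_model.foldit(optimizer)
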