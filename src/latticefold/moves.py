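"""Generalized Monte Carlo moves for lattice conformations.

Six move types, each defined purely through lattice adjacency so the same
code serves square and triangular lattices in any dimension:

* ``end``        — relocate a terminal residue to a free neighbour of its
                   adjacent residue (single-residue end move);
* ``kinkjump``   — relocate an interior residue to a free vertex adjacent
                   to both its backbone neighbours (corner move);
* ``crankshaft`` — relocate two middle residues of a four-residue window to
                   a feasible free adjacent pair;
* ``snake``      — reptation: a terminus steps onto a free neighbour and
                   every other residue shifts one position along the
                   backbone path;
* ``pivot``      — rotate a whole branch about a pivot residue, mapping the
                   branch's first step direction onto a chosen main
                   direction;
* ``pull``       — semi-local pull: the target residue steps to a free
                   vertex ``nu`` hops away (nu = 2 on square lattices,
                   1 on triangular ones) that keeps the anchor bond, and
                   downstream residues are pulled into vacated positions
                   until the chain reconnects.

Chain-breaking moves are deliberately absent.  Every applied move returns a
self-avoiding walk that differs from the input; a destination equal to the
current placement counts as infeasible.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .conformation import (
    ProteinModel,
    is_self_avoiding,
    plane_rotation,
    rotate,
    snap_to_lattice,
)
from .lattice import Lattice, hop_distance

__all__ = [
    "MOVE_TYPES",
    "MoveOutcome",
    "MoveStats",
    "TryRates",
    "DEFAULT_TRY_RATES",
    "end_move",
    "kink_jump",
    "crankshaft",
    "slithering_snake",
    "pivot_move",
    "pull_move",
    "random_move",
    "pull_step_constant",
]

MOVE_TYPES = ("end", "kinkjump", "crankshaft", "snake", "pivot", "pull")


@dataclass
class MoveOutcome:
    """Result of one attempted move.

    When ``applied`` the candidate ``new_coords`` is self-avoiding, differs
    from the input, and ``displaced_count >= 1`` residues changed position.
    """

    applied: bool
    move_type: str
    new_coords: Optional[np.ndarray] = None
    displaced_count: int = 0


@dataclass
class MoveStats:
    """Per-move-type counters of tries, feasible applications ('hits') and
    solution-improving applications.

    Hit rate ``h = hits / tries``; improvement fraction
    ``sigma = improvements(type) / total improvements``.
    """

    tries: dict = field(default_factory=lambda: {t: 0 for t in MOVE_TYPES})
    hits: dict = field(default_factory=lambda: {t: 0 for t in MOVE_TYPES})
    improvements: dict = field(default_factory=lambda: {t: 0 for t in MOVE_TYPES})

    def record_try(self, move_type: str, applied: bool) -> None:
        self.tries[move_type] += 1
        if applied:
            self.hits[move_type] += 1

    def record_improvement(self, move_type: str) -> None:
        self.improvements[move_type] += 1

    def hit_rate(self, move_type: str) -> float:
        t = self.tries[move_type]
        return self.hits[move_type] / t if t else float("nan")

    def sigma(self, move_type: str) -> float:
        total = sum(self.improvements.values())
        return self.improvements[move_type] / total if total else float("nan")

    def to_csv(self, path=None) -> str:
        """Stats table (move_type, tries, hits, improvements, h, sigma)."""
        buf = _io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["move_type", "tries", "hits", "improvements", "h", "sigma"])
        for t in MOVE_TYPES:
            writer.writerow(
                [t, self.tries[t], self.hits[t], self.improvements[t],
                 self.hit_rate(t), self.sigma(t)]
            )
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class TryRates:
    """Probability of attempting each move type; must sum to 1."""

    rates: dict

    def __post_init__(self):
        r = {t: float(self.rates.get(t, 0.0)) for t in MOVE_TYPES}
        if any(v < 0 for v in r.values()):
            raise ValueError("try rates must be non-negative")
        total = sum(r.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"try rates must sum to 1, got {total}")
        object.__setattr__(self, "rates", r)

    def sample(self, rng: np.random.Generator) -> str:
        u = rng.random()
        acc = 0.0
        for t in MOVE_TYPES:
            acc += self.rates[t]
            if u < acc:
                return t
        return MOVE_TYPES[-1]


#: Default attempt distribution.  Only the reptation share (5%) is a
#: published figure; the pull-move share follows the replica-exchange
#: literature's preference for pull-dominated sets, and the remainder is a
#: documented, configurable convention.
DEFAULT_TRY_RATES = TryRates(
    rates={
        "snake": 0.05,
        "pivot": 0.10,
        "end": 0.10,
        "kinkjump": 0.15,
        "crankshaft": 0.10,
        "pull": 0.50,
    }
)


def _occupancy(model: ProteinModel) -> dict:
    return {tuple(int(x) for x in model.coords[i]): i for i in range(len(model))}


def _tup(row) -> tuple:
    return tuple(int(x) for x in row)


def _neighbors(lat: Lattice, p: tuple) -> list[tuple]:
    return [tuple(a + b for a, b in zip(p, d)) for d in lat._dir_tuples]


def _count_displaced(old: np.ndarray, new: np.ndarray) -> int:
    return int(np.any(old != new, axis=1).sum())


def _finish(model, move_type, new_coords) -> MoveOutcome:
    new_coords = np.asarray(new_coords, dtype=np.int64)
    disp = _count_displaced(model.coords, new_coords)
    if disp == 0:
        return MoveOutcome(False, move_type)
    return MoveOutcome(True, move_type, new_coords, disp)


def end_move(
    model: ProteinModel, terminus: Literal["first", "last"], rng: np.random.Generator
) -> MoveOutcome:
    """Relocate a terminal residue onto a free neighbour of its adjacent residue."""
    n = len(model)
    if n < 2:
        return MoveOutcome(False, "end")
    idx = 0 if terminus == "first" else n - 1
    nb = 1 if terminus == "first" else n - 2
    occ = _occupancy(model)
    cur = _tup(model.coords[idx])
    cands = [
        v
        for v in _neighbors(model.lattice, _tup(model.coords[nb]))
        if v != cur and (v not in occ or occ[v] == idx)
    ]
    if not cands:
        return MoveOutcome(False, "end")
    new = model.coords.copy()
    new[idx] = cands[int(rng.integers(len(cands)))]
    return _finish(model, "end", new)


def kink_jump(model: ProteinModel, index: int, rng: np.random.Generator) -> MoveOutcome:
    """Relocate residue ``index`` to a free vertex adjacent to both neighbours."""
    n = len(model)
    if not 1 <= index <= n - 2:
        raise IndexError(f"kink-jump index must be in [1, {n - 2}], got {index}")
    occ = _occupancy(model)
    lat = model.lattice
    cur = _tup(model.coords[index])
    left = set(_neighbors(lat, _tup(model.coords[index - 1])))
    right = set(_neighbors(lat, _tup(model.coords[index + 1])))
    cands = sorted(
        v
        for v in left & right
        if v != cur and (v not in occ or occ[v] == index)
    )
    if not cands:
        return MoveOutcome(False, "kinkjump")
    new = model.coords.copy()
    new[index] = cands[int(rng.integers(len(cands)))]
    return _finish(model, "kinkjump", new)


def crankshaft(model: ProteinModel, index: int, rng: np.random.Generator) -> MoveOutcome:
    """Relocate the two middle residues of the window ``index .. index+3``.

    The new pair (u', v') must be free, with u' adjacent to the window's
    first vertex, v' adjacent to its last, and u' adjacent to v'; the pair
    as a whole must differ from the current placement (one of the two old
    vertices may be reused in a swapped role).
    """
    n = len(model)
    if not 0 <= index <= n - 4:
        raise IndexError(f"crankshaft index must be in [0, {n - 4}], got {index}")
    lat = model.lattice
    occ = _occupancy(model)
    moved = {index + 1, index + 2}
    old_pair = (_tup(model.coords[index + 1]), _tup(model.coords[index + 2]))

    def free(v):
        return v not in occ or occ[v] in moved

    us = [v for v in _neighbors(lat, _tup(model.coords[index])) if free(v)]
    vs = [v for v in _neighbors(lat, _tup(model.coords[index + 3])) if free(v)]
    vset = set(vs)
    cands = []
    for u in us:
        for w in _neighbors(lat, u):
            if w in vset and w != u and (u, w) != old_pair:
                cands.append((u, w))
    if not cands:
        return MoveOutcome(False, "crankshaft")
    cands.sort()
    u, w = cands[int(rng.integers(len(cands)))]
    new = model.coords.copy()
    new[index + 1] = u
    new[index + 2] = w
    return _finish(model, "crankshaft", new)


def slithering_snake(
    model: ProteinModel, terminus: Literal["first", "last"], rng: np.random.Generator
) -> MoveOutcome:
    """Reptation: the target end steps to a free neighbour and the whole
    chain shifts one position along the backbone path."""
    n = len(model)
    if n < 2:
        return MoveOutcome(False, "snake")
    occ = _occupancy(model)
    head = 0 if terminus == "first" else n - 1
    cands = [v for v in _neighbors(model.lattice, _tup(model.coords[head])) if v not in occ]
    if not cands:
        return MoveOutcome(False, "snake")
    q = cands[int(rng.integers(len(cands)))]
    new = np.empty_like(model.coords)
    if terminus == "first":
        new[0] = q
        new[1:] = model.coords[:-1]
    else:
        new[n - 1] = q
        new[:-1] = model.coords[1:]
    return _finish(model, "snake", new)


def pivot_move(
    model: ProteinModel,
    pivot_index: int,
    branch: Literal["forward", "backward"],
    dst_dir,
    rng: np.random.Generator,
) -> MoveOutcome:
    """Rotate one branch about the pivot so its first step maps onto ``dst_dir``.

    Rejected when the rotation is the identity (no-op), when the mapped
    branch leaves the lattice (non-integer coordinates after the
    lattice-frame conjugation), or when any rotated residue clashes with the
    fixed branch.
    """
    n = len(model)
    if not 0 <= pivot_index < n:
        raise IndexError(f"pivot index {pivot_index} out of range")
    lat = model.lattice
    dst = _tup(np.asarray(dst_dir, dtype=np.int64))
    if not lat.contains_direction(dst):
        raise ValueError(f"{dst} is not a main direction")
    if branch == "forward":
        if pivot_index >= n - 1:
            return MoveOutcome(False, "pivot")
        src = _tup(model.coords[pivot_index + 1] - model.coords[pivot_index])
    elif branch == "backward":
        if pivot_index == 0:
            return MoveOutcome(False, "pivot")
        src = _tup(model.coords[pivot_index - 1] - model.coords[pivot_index])
    else:
        raise ValueError("branch must be 'forward' or 'backward'")
    if src == dst:
        return MoveOutcome(False, "pivot")
    rot = plane_rotation(lat, src, dst)
    cand = rotate(model, pivot_index, branch, rot)
    snapped = snap_to_lattice(cand)
    if snapped is None:
        return MoveOutcome(False, "pivot")
    trial = ProteinModel(sequence=model.sequence, lattice=lat, coords=snapped)
    if not is_self_avoiding(trial):
        return MoveOutcome(False, "pivot")
    return _finish(model, "pivot", snapped)


_PULL_STEP_CACHE: dict = {}


def pull_step_constant(lattice: Lattice) -> int:
    """Topology constant ``nu``: the least number of hops a pulled residue
    can advance, derived from the main directions.

    It is the minimum hop distance over non-cancelling sums of two main
    directions: 1 when some pair of main directions is mutually adjacent
    (triangular family), else 2 (square family).
    """
    key = (lattice.kind, lattice.dim)
    if key in _PULL_STEP_CACHE:
        return _PULL_STEP_CACHE[key]
    dirs = list(lattice._dir_tuples)
    best = None
    origin = tuple(0 for _ in range(lattice.dim))
    for d1 in dirs:
        for d2 in dirs:
            s = tuple(a + b for a, b in zip(d1, d2))
            if s == origin:
                continue
            h = hop_distance(lattice, origin, s)
            best = h if best is None else min(best, h)
            if best == 1:
                _PULL_STEP_CACHE[key] = 1
                return 1
    _PULL_STEP_CACHE[key] = int(best)
    return int(best)


def _hop_is_nu(lat: Lattice, p: tuple, t: tuple, nu: int) -> bool:
    d = tuple(a - b for a, b in zip(t, p))
    if nu == 1:
        return lat.contains_direction(d)
    return not lat.contains_direction(d) and hop_distance(lat, p, t) == nu


def _pull_candidates(model: ProteinModel, index: int, branch: str) -> list[tuple]:
    """Legal destination vertices for a pull on ``index`` along ``branch``."""
    n = len(model)
    lat = model.lattice
    occ = _occupancy(model)
    p = _tup(model.coords[index])
    nu = pull_step_constant(lat)
    anchor = index - 1 if branch == "forward" else index + 1
    if 0 <= anchor < n:
        pool = _neighbors(lat, _tup(model.coords[anchor]))
    elif nu == 1:
        pool = _neighbors(lat, p)
    else:
        dirs = list(lat._dir_tuples)
        pool = sorted(
            {
                tuple(x + y + z for x, y, z in zip(p, d1, d2))
                for d1 in dirs
                for d2 in dirs
            }
        )
    out = []
    for t in pool:
        if t in occ or t == p:
            continue
        if not _hop_is_nu(lat, p, t, nu):
            continue
        if nu == 2 and not _free_intermediates(model, occ, p, t):
            continue
        out.append(t)
    return sorted(set(out))


def _free_intermediates(model, occ, p: tuple, t: tuple) -> list[tuple]:
    lat = model.lattice
    return sorted(
        v
        for v in _neighbors(lat, p)
        if v not in occ and lat.contains_direction(tuple(a - b for a, b in zip(t, v)))
    )


def pull_move(
    model: ProteinModel,
    index: int,
    branch: Literal["forward", "backward"],
    dst_vertex,
    rng: np.random.Generator,
) -> MoveOutcome:
    """Pull the ``branch`` side of the chain after moving residue ``index``.

    ``dst_vertex`` must be free, ``nu`` hops from the residue's current
    vertex and adjacent to the anchor neighbour (the residue on the
    non-pulled side, when it exists).  On square lattices (nu = 2) a free
    intermediate vertex adjacent to both endpoints must exist; it receives
    the first pulled residue.  Each subsequent branch residue that is no
    longer adjacent to its predecessor is pulled into the position vacated
    two steps earlier; the pull stops at the first residue already adjacent
    (semi-local property) or at the chain end.
    """
    n = len(model)
    if not 0 <= index < n:
        raise IndexError(f"pull index {index} out of range")
    if branch == "forward":
        pulled = list(range(index + 1, n))
        anchor = index - 1
    elif branch == "backward":
        pulled = list(range(index - 1, -1, -1))
        anchor = index + 1
    else:
        raise ValueError("branch must be 'forward' or 'backward'")
    if not pulled:
        return MoveOutcome(False, "pull")
    lat = model.lattice
    occ = _occupancy(model)
    p = _tup(model.coords[index])
    t = _tup(np.asarray(dst_vertex, dtype=np.int64))
    nu = pull_step_constant(lat)
    if t in occ or t == p:
        return MoveOutcome(False, "pull")
    if not _hop_is_nu(lat, p, t, nu):
        return MoveOutcome(False, "pull")
    if 0 <= anchor < n and not lat.contains_direction(
        tuple(a - b for a, b in zip(t, _tup(model.coords[anchor])))
    ):
        return MoveOutcome(False, "pull")
    slots: list[tuple] = []
    if nu == 2:
        inter = _free_intermediates(model, occ, p, t)
        if not inter:
            return MoveOutcome(False, "pull")
        slots.append(inter[int(rng.integers(len(inter)))])
    slots.append(p)
    slots.extend(_tup(model.coords[r]) for r in pulled[:-1])

    new = model.coords.copy()
    new[index] = t
    prev = t
    for k, r in enumerate(pulled):
        cur = _tup(model.coords[r])
        if lat.contains_direction(tuple(a - b for a, b in zip(cur, prev))):
            break
        new[r] = slots[k]
        prev = slots[k]
    trial = ProteinModel(sequence=model.sequence, lattice=lat, coords=new)
    if not is_self_avoiding(trial):
        return MoveOutcome(False, "pull")
    return _finish(model, "pull", new)


def random_move(
    model: ProteinModel,
    try_rates: TryRates,
    stats: MoveStats,
    rng: np.random.Generator,
) -> MoveOutcome:
    """Sample a move type by its try rate, sample its free parameters
    uniformly among legal values, attempt it, and update the counters.

    Tries are always counted; hits on application; improvement events are
    the caller's responsibility (it knows the potential)."""
    n = len(model)
    mtype = try_rates.sample(rng)
    outcome = MoveOutcome(False, mtype)
    if mtype == "end":
        outcome = end_move(model, ("first", "last")[int(rng.integers(2))], rng)
    elif mtype == "snake":
        outcome = slithering_snake(model, ("first", "last")[int(rng.integers(2))], rng)
    elif mtype == "kinkjump":
        if n >= 3:
            outcome = kink_jump(model, int(rng.integers(1, n - 1)), rng)
    elif mtype == "crankshaft":
        if n >= 4:
            outcome = crankshaft(model, int(rng.integers(0, n - 3)), rng)
    elif mtype == "pivot":
        idx = int(rng.integers(n))
        branches = [b for b, ok in (("forward", idx < n - 1), ("backward", idx > 0)) if ok]
        if branches:
            br = branches[int(rng.integers(len(branches)))]
            dirs = model.lattice.main_dirs
            outcome = pivot_move(model, idx, br, dirs[int(rng.integers(len(dirs)))], rng)
    elif mtype == "pull":
        idx = int(rng.integers(n))
        branches = [b for b, ok in (("forward", idx < n - 1), ("backward", idx > 0)) if ok]
        if branches:
            br = branches[int(rng.integers(len(branches)))]
            cands = _pull_candidates(model, idx, br)
            if cands:
                outcome = pull_move(model, idx, br, cands[int(rng.integers(len(cands)))], rng)
    stats.record_try(mtype, outcome.applied)
    return outcome
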