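"""Conformations as self-avoiding walks on a lattice.

A protein conformation binds an {H,P} (or richer) sequence to an ordered
list of integer lattice coordinates, one per residue (*absolute encoding*).
The *differential encoding* — the list of successive steps, each a main
direction for a valid walk — is derived on demand.  Rigid motions
(translations by integer vectors, rotations mapping one main direction onto
another under the linear hypothesis) and the standard walk builders live
here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .lattice import Lattice, to_cartesian

__all__ = [
    "ProteinModel",
    "Rotation",
    "to_differential",
    "from_differential",
    "is_self_avoiding",
    "translate",
    "plane_rotation",
    "rotate",
    "snap_to_lattice",
    "random_walk_build",
    "linear_build",
    "radial_neighbor_profile",
    "mean_radial_profile",
]

INTEGRALITY_TOL = 1e-6


@dataclass
class ProteinModel:
    """A sequence bound to a lattice and an absolute-encoding coordinate list.

    ``coords`` has shape (N, dim) with residue ``i`` at ``coords[i]``
    (0-based).  Builders anchor residue 0 at the origin; translations may
    relax that.  An optimizer may be attached for the strategy-pattern
    ``foldit`` entry point.
    """

    sequence: str
    lattice: Lattice
    coords: np.ndarray
    optimizer: object | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64)
        n = len(self.sequence)
        if n < 1:
            raise ValueError("sequence must contain at least one residue")
        if self.coords.shape != (n, self.lattice.dim):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"(len(sequence), dim) = ({n}, {self.lattice.dim})"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def copy(self) -> "ProteinModel":
        return replace(self, coords=self.coords.copy())

    def foldit(self, optimizer=None):
        """Run the attached (or given) optimizer on this model.

        Strategy-pattern hook: the model merely dispatches; the optimizer
        holds every algorithmic parameter.  Raises ``ValueError`` when no
        optimizer is attached.
        """
        if optimizer is not None:
            self.optimizer = optimizer
        if self.optimizer is None:
            raise ValueError("no optimizer attached to this model")
        return self.optimizer.optimize(self)


@dataclass(frozen=True)
class Rotation:
    """A rigid rotation mapping main direction ``src`` onto ``dst``.

    ``matrix`` is expressed in lattice coordinates (``B^-1 R_cart B``); its
    Cartesian conjugate is orthogonal with determinant +1.  Applying the
    matrix to ``src`` yields ``dst`` exactly (up to floating noise).
    """

    matrix: np.ndarray
    src: tuple
    dst: tuple

    def apply(self, vec) -> np.ndarray:
        return self.matrix @ np.asarray(vec, dtype=float)


def to_differential(model: ProteinModel) -> np.ndarray:
    """Step vectors ``coords[i+1] - coords[i]``; shape (N-1, dim)."""
    return np.diff(model.coords, axis=0)


def from_differential(
    lattice: Lattice, sequence: str, steps: Iterable
) -> ProteinModel:
    """Rebuild an origin-anchored model from its step list.

    Self-avoidance is *not* validated here; pair with
    :func:`is_self_avoiding`.
    """
    steps = np.asarray(list(steps), dtype=np.int64)
    n = len(sequence)
    if steps.size and steps.shape != (n - 1, lattice.dim):
        raise ValueError(
            f"expected {n - 1} steps of dimension {lattice.dim}, got {steps.shape}"
        )
    coords = np.zeros((n, lattice.dim), dtype=np.int64)
    if n > 1:
        coords[1:] = np.cumsum(steps, axis=0)
    return ProteinModel(sequence=sequence, lattice=lattice, coords=coords)


def is_self_avoiding(model: ProteinModel) -> bool:
    """True iff every step is a main direction and no vertex repeats.

    Linear in N: occupancy is tracked with a hash set keyed on coordinate
    tuples.
    """
    lat = model.lattice
    seen = set()
    prev = None
    for row in model.coords:
        v = tuple(int(x) for x in row)
        if v in seen:
            return False
        if prev is not None and not lat.contains_direction(
            tuple(a - b for a, b in zip(v, prev))
        ):
            return False
        seen.add(v)
        prev = v
    return True


def translate(model: ProteinModel, t) -> ProteinModel:
    """Shift every residue by the integer vector ``t`` (new model)."""
    t = np.asarray(t, dtype=np.int64)
    if t.shape != (model.lattice.dim,):
        raise ValueError(f"translation vector must have dimension {model.lattice.dim}")
    return replace(model, coords=model.coords + t[None, :])


def _pi_rotation_plane(lattice: Lattice, u_hat: np.ndarray) -> np.ndarray:
    """Second plane axis for a half-turn: lowest-index main direction not
    parallel to ``u_hat``, orthogonalised against it."""
    for d in lattice.main_dirs:
        w = to_cartesian(lattice, d)
        w = w - (w @ u_hat) * u_hat
        norm = np.linalg.norm(w)
        if norm > 1e-9:
            return w / norm
    raise ValueError("lattice has no direction independent of the rotation axis")


def plane_rotation(lattice: Lattice, u, v) -> Rotation:
    """Rotation taking main direction ``u`` onto ``v`` about their normal subspace.

    The rotation acts in the Cartesian plane spanned by ``B u`` and ``B v``
    and is the identity on the orthogonal complement (the n-dimensional
    "linear hypothesis").  When ``B u = -B v`` the plane is ambiguous; the
    half-turn is taken in the plane of ``u`` and the lowest-index main
    direction not parallel to it, for determinism.  Note that for
    triangular lattices ``R v`` need not equal ``-u``.
    """
    u = np.asarray(u, dtype=np.int64)
    v = np.asarray(v, dtype=np.int64)
    for w in (u, v):
        if not lattice.contains_direction(tuple(int(x) for x in w)):
            raise ValueError(f"{tuple(w)} is not a main direction of this lattice")
    u_hat = to_cartesian(lattice, u)
    v_hat = to_cartesian(lattice, v)
    n = lattice.dim
    c = float(u_hat @ v_hat)
    if np.allclose(u_hat, v_hat, atol=1e-12):
        r_cart = np.eye(n)
    elif c < -1 + 1e-12:
        b = _pi_rotation_plane(lattice, u_hat)
        r_cart = (
            np.eye(n)
            - 2.0 * np.outer(u_hat, u_hat)
            - 2.0 * np.outer(b, b)
        )
    else:
        w = v_hat - c * u_hat
        s = np.linalg.norm(w)
        b = w / s
        a = u_hat
        r_cart = (
            np.eye(n)
            + (c - 1.0) * (np.outer(a, a) + np.outer(b, b))
            + s * (np.outer(b, a) - np.outer(a, b))
        )
    matrix = lattice._basis_inv @ r_cart @ lattice.basis
    return Rotation(matrix=matrix, src=tuple(int(x) for x in u), dst=tuple(int(x) for x in v))


def rotate(
    model: ProteinModel,
    pivot_index: int,
    branch: Literal["forward", "backward"],
    rotation: Rotation,
) -> np.ndarray:
    """Candidate coordinates after rotating one branch about a pivot residue.

    The chosen branch (residues after or before ``pivot_index``) is mapped by
    ``p -> pivot + R (p - pivot)`` in lattice coordinates.  The returned
    float array may contain non-integer entries (the rotation need not map
    lattice vertices onto lattice vertices for triangular lattices); use
    :func:`snap_to_lattice` to validate and round.
    """
    n = len(model)
    if not 0 <= pivot_index < n:
        raise IndexError(f"pivot index {pivot_index} out of range for N={n}")
    if branch not in ("forward", "backward"):
        raise ValueError("branch must be 'forward' or 'backward'")
    coords = model.coords.astype(float)
    pivot = coords[pivot_index]
    sel = slice(pivot_index + 1, n) if branch == "forward" else slice(0, pivot_index)
    moved = (rotation.matrix @ (coords[sel] - pivot).T).T + pivot
    out = coords.copy()
    out[sel] = moved
    return out


def snap_to_lattice(arr: np.ndarray, tol: float = INTEGRALITY_TOL) -> np.ndarray | None:
    """Round near-integer coordinates; None when any entry deviates beyond tol."""
    rounded = np.rint(arr)
    if np.max(np.abs(arr - rounded)) > tol:
        return None
    return rounded.astype(np.int64)


def random_walk_build(
    lattice: Lattice, sequence: str, rng_seed: int | np.random.Generator = 0
) -> ProteinModel:
    """Grow an origin-anchored self-avoiding walk by uniform feasible steps.

    On a dead end the walk backtracks one step (bounded retries) and after
    ``100 * N`` failed extensions restarts from scratch with the advanced RNG
    state.  Deterministic for a given seed.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = len(sequence)
    dirs = lattice._dir_tuples
    budget = 100 * n
    for _restart in range(1000):
        coords = [tuple(0 for _ in range(lattice.dim))]
        occupied = {coords[0]}
        failures = 0
        while len(coords) < n:
            cur = coords[-1]
            free = [
                tuple(a + b for a, b in zip(cur, d))
                for d in dirs
            ]
            free = [w for w in free if w not in occupied]
            if free:
                nxt = free[rng.integers(len(free))]
                coords.append(nxt)
                occupied.add(nxt)
                continue
            failures += 1
            if failures > budget:
                break
            if len(coords) > 1:  # backtrack one step and retry
                occupied.discard(coords.pop())
        if len(coords) == n:
            return ProteinModel(
                sequence=sequence,
                lattice=lattice,
                coords=np.array(coords, dtype=np.int64),
            )
    raise RuntimeError("random walk construction exhausted its retry budget")


def linear_build(lattice: Lattice, sequence: str) -> ProteinModel:
    """Straight chain along the first (lexicographic) main direction."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    d0 = lattice.main_dirs[0]
    n = len(sequence)
    coords = np.arange(n, dtype=np.int64)[:, None] * d0[None, :]
    return ProteinModel(sequence=sequence, lattice=lattice, coords=coords)


def radial_neighbor_profile(
    points: Sequence, center, radii: Sequence[float]
) -> list[int]:
    """Counts of points within each radius of a centre (cumulative profile).

    Emulates the neighbourhood census of alpha carbons in real structures:
    for each radius ``r`` (ascending, in the coordinate units, typically
    Angstrom) the number of points at Euclidean distance <= r from
    ``center`` is returned, excluding points coincident with the centre.
    """
    radii = list(radii)
    if not radii:
        raise ValueError("radii must be non-empty")
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    pts = np.asarray(points, dtype=float)
    ctr = np.asarray(center, dtype=float)
    d = np.linalg.norm(pts - ctr[None, :], axis=1)
    d = d[d > 1e-12]
    return [int(np.sum(d <= r)) for r in radii]


def mean_radial_profile(
    points: Sequence,
    radii: Sequence[float],
    gyration_fraction: float = 0.5,
) -> list[float]:
    """Average neighbour profile over centres near the centroid.

    Centres are the points within ``gyration_fraction`` times the gyration
    radius of the centroid, so every probing sphere stays inside the
    molecule; the fraction is an explicit parameter (default 0.5).
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    mask = np.linalg.norm(pts - centroid[None, :], axis=1) <= gyration_fraction * rg
    centers = pts[mask]
    if len(centers) == 0:
        centers = pts[[int(np.argmin(np.linalg.norm(pts - centroid, axis=1)))]]
    profiles = np.array([radial_neighbor_profile(pts, c, radii) for c in centers])
    return [float(x) for x in profiles.mean(axis=0)]
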