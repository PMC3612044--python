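"""Contact potentials for lattice conformations.

The classic HP potential counts hydrophobic contacts: pairs of H residues
that are not backbone neighbours but sit on adjacent lattice vertices, each
contributing -1.  The generalized pairwise potential sums
``g(d_hop(i, j)) * C(s_i, s_j)`` over all residue pairs at backbone
separation >= 2, with a symmetric coefficient table ``C`` and a
hop-distance factor ``g`` that vanishes beyond a small cutoff (the HP
default has ``g(1) = 1`` only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformation import ProteinModel
from .lattice import hop_distance

__all__ = [
    "PotentialModel",
    "HP_POTENTIAL",
    "warmup_potential_model",
    "hp_potential",
    "hp_potential_pairwise",
    "generic_potential",
    "count_contacts",
]


@dataclass(frozen=True)
class PotentialModel:
    """Pair coefficients ``C(a, b)`` plus a hop-distance factor ``g(d)``.

    ``coefficients`` maps unordered residue-type pairs to reals; it is
    symmetrised on construction.  ``distance_factor`` maps hop distances to
    weights and is zero beyond ``max(distance_factor)``.
    """

    coefficients: dict = field(default_factory=dict)
    distance_factor: dict = field(default_factory=lambda: {1: 1.0})

    def __post_init__(self):
        sym = {}
        for (a, b), val in self.coefficients.items():
            key = (a, b) if a <= b else (b, a)
            if key in sym and sym[key] != val:
                raise ValueError(f"conflicting coefficients for pair {key}")
            sym[key] = float(val)
        object.__setattr__(self, "coefficients", sym)
        object.__setattr__(
            self, "distance_factor", {int(d): float(g) for d, g in self.distance_factor.items()}
        )

    @property
    def cutoff(self) -> int:
        return max(self.distance_factor, default=0)

    def coefficient(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        try:
            return self.coefficients[key]
        except KeyError:
            raise KeyError(f"no coefficient for residue pair {key}") from None

    def g(self, d: int) -> float:
        return self.distance_factor.get(int(d), 0.0)

    @classmethod
    def from_table(cls, types, matrix, distance_factor=None) -> "PotentialModel":
        """Build from a square coefficient table (rows/cols in ``types``)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(types), len(types)):
            raise ValueError("coefficient matrix must be square over the residue types")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("coefficient matrix must be symmetric")
        coeffs = {
            (a, b): float(matrix[i, j])
            for i, a in enumerate(types)
            for j, b in enumerate(types)
            if a <= b
        }
        return cls(coefficients=coeffs, distance_factor=distance_factor or {1: 1.0})


#: The classic HP potential: C(H,H) = -1, every other pair 0, contacts only.
HP_POTENTIAL = PotentialModel(
    coefficients={("H", "H"): -1.0, ("H", "P"): 0.0, ("P", "P"): 0.0}
)


def warmup_potential_model(other_pair: float = -0.25) -> PotentialModel:
    """Compaction-biased potential: C(H,H) = -1 plus a uniform weak
    attraction for every other pair at contact (used early in annealing to
    drive chains towards globular shapes)."""
    return PotentialModel(
        coefficients={
            ("H", "H"): -1.0,
            ("H", "P"): float(other_pair),
            ("P", "P"): float(other_pair),
        }
    )


def _check_hp(model: ProteinModel) -> None:
    bad = set(model.sequence) - {"H", "P"}
    if bad:
        raise ValueError(f"HP potential requires residues in {{H,P}}; found {sorted(bad)}")


def hp_potential(model: ProteinModel) -> int:
    """(-1) times the number of H-H contacts (backbone separation >= 2).

    Lattice-agnostic and O(N c): an occupancy map from coordinate tuples to
    residue indices lets each H residue inspect only its ``c`` neighbour
    vertices; every contact is seen from both ends, hence the halving.
    """
    _check_hp(model)
    return -count_contacts(model, "H", "H")


def hp_potential_pairwise(model: ProteinModel) -> int:
    """Direct pair-loop evaluation of the HP potential.

    Quadratic transcription of the textbook algorithm: for every H pair at
    backbone separation >= 2, test whether the coordinate difference is a
    main direction.  Kept as the slow reference implementation; the
    occupancy-map route must agree with it everywhere.
    """
    _check_hp(model)
    coords = model.coords
    seq = model.sequence
    lat = model.lattice
    n = len(seq)
    pot = 0
    for i in range(n - 2):
        if seq[i] != "H":
            continue
        for j in range(i + 2, n):
            if seq[j] != "H":
                continue
            d = tuple(int(x) for x in coords[j] - coords[i])
            if lat.contains_direction(d):
                pot -= 1
    return pot


def count_contacts(model: ProteinModel, type_a: str, type_b: str) -> int:
    """Unordered non-bonded adjacent pairs with the given type combination."""
    coords = model.coords
    seq = model.sequence
    lat = model.lattice
    occ = {tuple(int(x) for x in coords[i]): i for i in range(len(seq))}
    dirs = lat._dir_tuples
    count = 0
    for i, res in enumerate(seq):
        if res != type_a and res != type_b:
            continue
        p = tuple(int(x) for x in coords[i])
        for d in dirs:
            j = occ.get(tuple(a + b for a, b in zip(p, d)))
            if j is None or abs(j - i) < 2:
                continue
            if (seq[i], seq[j]) in ((type_a, type_b), (type_b, type_a)):
                count += 1
    return count // 2


def generic_potential(model: ProteinModel, potential_model: PotentialModel) -> float:
    """Pairwise contact potential: sum of g(hop(i,j)) * C(s_i, s_j), j >= i+2.

    With the HP coefficient table this reduces exactly to
    :func:`hp_potential`.  Hop distances are only evaluated when they can be
    at most the distance-factor cutoff (cheap Euclidean prefilter), so the
    default contact potentials never trigger deep lattice searches.
    """
    coords = model.coords
    seq = model.sequence
    lat = model.lattice
    pm = potential_model
    cutoff = pm.cutoff
    if cutoff == 0 or len(seq) <= 2:
        return 0.0
    total = 0.0
    n = len(seq)
    gram = lat._gram
    for i in range(n - 2):
        for j in range(i + 2, n):
            d = (coords[j] - coords[i]).astype(float)
            # hops * edge_length >= euclidean distance, so this prunes safely
            if d @ gram @ d > cutoff * cutoff + 1e-9:
                continue
            g = pm.g(hop_distance(lat, coords[i], coords[j], cutoff=cutoff + 1))
            if g != 0.0:
                total += g * pm.coefficient(seq[i], seq[j])
    return total
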