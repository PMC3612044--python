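"""Sequence parsing, benchmark fixtures, serialization and 3-D projection.

HP sequences arrive either expanded ("PHHP...") or in run-length notation
("PH4P2"; the underscore and caret spellings "H_4_" / "H^4" are accepted
too).  The bundled benchmark table carries the standard HP test set —
the ten 48-residue Harvard instances, the 24-residue first half of the
ninth, and four longer sequences — and every entry is validated against
its declared length and hydrophobic count at load time.

Conformations are serialized as JSON::

    {"lattice": {"kind": ..., "dim": ...}, "sequence": ..., "coords": [[...], ...]}
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .conformation import ProteinModel, Rotation, is_self_avoiding, to_cartesian
from .lattice import make_lattice

__all__ = [
    "BenchmarkEntry",
    "expand_hp_string",
    "compress_hp_string",
    "load_benchmarks",
    "get_benchmark",
    "read_hp_sequence",
    "read_conformation",
    "write_conformation",
    "project_3d",
    "read_xyz_table",
    "read_pdb_ca",
]

_TOKEN = re.compile(r"\s*([HP])(?:_([0-9]+)_|\^([0-9]+)|([0-9]+))?\s*")


def expand_hp_string(compressed: str) -> str:
    """Expand run-length HP notation ("H4P" -> "HHHHP").

    Accepted per-token syntaxes: ``H4``, ``H_4_``, ``H^4``; a bare letter
    counts once.  Malformed tokens and non-positive counts raise
    ``ValueError``.
    """
    out = []
    pos = 0
    s = compressed
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.end() == pos:
            raise ValueError(f"malformed HP token at position {pos}: {s[pos:pos+8]!r}")
        pos = m.end()
        count_str = m.group(2) or m.group(3) or m.group(4)
        count = int(count_str) if count_str is not None else 1
        if count < 1:
            raise ValueError(f"repeat count must be positive, got {count}")
        out.append(m.group(1) * count)
    return "".join(out)


def compress_hp_string(sequence: str) -> str:
    """Canonical run-length form: maximal runs, counts > 1 written as digits."""
    if not re.fullmatch(r"[HP]*", sequence):
        raise ValueError("sequence must be over the alphabet {H, P}")
    out = []
    for m in re.finditer(r"(.)\1*", sequence):
        run = m.group(0)
        out.append(run[0] + (str(len(run)) if len(run) > 1 else ""))
    return "".join(out)


@dataclass(frozen=True)
class BenchmarkEntry:
    """One benchmark sequence with its declared length and H count."""

    id: str
    compressed: str
    sequence: str
    length: int
    n_hydrophobic: int
    note: str

    def validate(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != declared {self.length}"
            )
        if self.sequence.count("H") != self.n_hydrophobic:
            raise ValueError(
                f"{self.id}: H count {self.sequence.count('H')} != declared "
                f"{self.n_hydrophobic}"
            )
        if set(self.sequence) - {"H", "P"}:
            raise ValueError(f"{self.id}: sequence not over {{H, P}}")


def load_benchmarks() -> list[BenchmarkEntry]:
    """Bundled benchmark table, validated entry by entry.

    Entries failing their declared (length, #H) invariant are refused
    (ValueError) rather than returned.
    """
    text = (
        resources.files("latticefold").joinpath("data/benchmarks.tsv").read_text()
    )
    entries = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        ident, seq, length, n_h, note = ln.split("\t")
        entry = BenchmarkEntry(
            id=ident,
            compressed=compress_hp_string(seq),
            sequence=seq,
            length=int(length),
            n_hydrophobic=int(n_h),
            note=note,
        )
        entry.validate()
        entries.append(entry)
    return entries


def get_benchmark(ident: str) -> BenchmarkEntry:
    """Single benchmark entry by id (e.g. ``"HI 4"``; spaces optional)."""
    wanted = ident.replace(" ", "").upper()
    for entry in load_benchmarks():
        if entry.id.replace(" ", "").upper() == wanted:
            return entry
    raise KeyError(f"no benchmark entry named {ident!r}")


def read_hp_sequence(path) -> str:
    """HP sequence from plain text or FASTA-like file (headers ignored);
    run-length notation is expanded."""
    body = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            body.append(line)
    return expand_hp_string("".join(body))


def write_conformation(model: ProteinModel, path) -> None:
    payload = {
        "lattice": {"kind": model.lattice.kind, "dim": model.lattice.dim},
        "sequence": model.sequence,
        "coords": [[int(x) for x in row] for row in model.coords],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_conformation(path) -> ProteinModel:
    """Load a conformation JSON file.

    Schema violations and dimension mismatches raise ``ValueError``; a
    stored walk that is not self-avoiding is returned with a warning.
    """
    with open(path) as fh:
        payload = json.load(fh)
    try:
        lat_spec = payload["lattice"]
        lattice = make_lattice(lat_spec["kind"], int(lat_spec["dim"]))
        sequence = payload["sequence"]
        coords = np.array(payload["coords"], dtype=np.int64)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed conformation file {path}: {exc}") from exc
    if coords.ndim != 2 or coords.shape != (len(sequence), lattice.dim):
        raise ValueError(
            f"coordinate table shape {coords.shape} does not match sequence "
            f"length {len(sequence)} and lattice dimension {lattice.dim}"
        )
    model = ProteinModel(sequence=sequence, lattice=lattice, coords=coords)
    if not is_self_avoiding(model):
        warnings.warn(
            f"conformation in {path} is not a self-avoiding walk", stacklevel=2
        )
    return model


def project_3d(
    model: ProteinModel,
    axes: Sequence[int] = (0, 1, 2),
    pre_rotation: Optional[Rotation] = None,
) -> np.ndarray:
    """Orthogonal 3-D projection of a conformation in dimension >= 3.

    Returns the Cartesian residue coordinates, optionally rotated first,
    restricted to the three chosen axes.  Distinct residues may project to
    coincident points (superpositions are legitimate).
    """
    if model.lattice.dim < 3:
        raise ValueError("3-D projection requires a lattice of dimension >= 3")
    axes = tuple(int(a) for a in axes)
    if len(axes) != 3 or len(set(axes)) != 3:
        raise ValueError("axes must be three distinct indices")
    if any(a < 0 or a >= model.lattice.dim for a in axes):
        raise ValueError(f"axes out of range for dimension {model.lattice.dim}")
    coords = model.coords.astype(float)
    if pre_rotation is not None:
        coords = (pre_rotation.matrix @ coords.T).T
    cart = np.array([to_cartesian(model.lattice, p) for p in coords])
    return cart[:, axes]


def read_xyz_table(path) -> np.ndarray:
    """Whitespace-separated x y z coordinate table (one point per line)."""
    pts = np.loadtxt(path, dtype=float, ndmin=2)
    if pts.shape[1] != 3:
        raise ValueError("coordinate table must have three columns")
    return pts


def read_pdb_ca(path) -> np.ndarray:
    """Alpha-carbon coordinates (Angstrom) from a PDB file via Biopython."""
    from Bio.PDB import PDBParser  # deferred: optional dependency

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("prot", path)
    coords = [
        atom.coord
        for atom in structure.get_atoms()
        if atom.get_name() == "CA"
    ]
    if not coords:
        raise ValueError(f"no CA atoms found in {path}")
    return np.array(coords, dtype=float)
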