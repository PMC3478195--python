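"""Structure data model, PDB I/O and rigid-transform algebra.

A protein subunit is represented as an ordered sequence of heavy atoms
(the file order of the selected chains), grouped into residues.  All
coordinates are in Angstrom.  Rigid transforms are proper rotations plus
translations; they compose, invert and act on structures exactly
(isometry to machine precision).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ProteinStructure",
    "RigidTransform",
    "PDBFormatError",
    "EmptySelectionError",
    "read_pdb",
    "write_pdb",
    "apply_transform",
    "compose",
    "invert",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed as PDB."""


class EmptySelectionError(ValueError):
    """Raised when chain/record filtering leaves no atoms."""


@dataclass
class Atom:
    """One heavy atom of a subunit.

    ``ace_type`` is ``None`` until a typing map assigns an index in
    ``0..17``; untyped atoms are ignored by the contact-energy score.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    chain_id: str
    coords: np.ndarray
    ace_type: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.ace_type is not None and not (0 <= int(self.ace_type) <= 17):
            raise ValueError(f"ace_type must be in 0..17, got {self.ace_type}")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, author residue number, insertion code) identity triple."""
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass
class ProteinStructure:
    """An ordered atom sequence with residue grouping.

    Atom order is the file order restricted to the selected chains; each
    atom belongs to exactly one residue span (residues are contiguous in
    the sequence).
    """

    atoms: list[Atom]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a ProteinStructure needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in atom-sequence order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def ace_types(self) -> np.ndarray:
        """(n,) int array of ACE type indices, -1 where untyped."""
        return np.array(
            [-1 if a.ace_type is None else a.ace_type for a in self.atoms], dtype=int
        )

    def residue_spans(self) -> dict[tuple[str, int, str], tuple[int, int]]:
        """Map residue identity -> half-open atom index span [start, stop)."""
        spans: dict[tuple[str, int, str], tuple[int, int]] = {}
        for i, atom in enumerate(self.atoms):
            rid = atom.residue_id
            if rid in spans:
                start, stop = spans[rid]
                if stop != i:
                    raise ValueError(f"residue {rid} is not contiguous in the sequence")
                spans[rid] = (start, i + 1)
            else:
                spans[rid] = (i, i + 1)
        return spans

    def residue_ids(self) -> list[tuple[str, int, str]]:
        """Residue identities in first-appearance order."""
        seen: list[tuple[str, int, str]] = []
        for atom in self.atoms:
            if not seen or seen[-1] != atom.residue_id:
                seen.append(atom.residue_id)
        return seen

    def residue_index_per_atom(self) -> list[tuple[str, int, str]]:
        """Residue identity of each atom, in atom order."""
        return [a.residue_id for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "ProteinStructure":
        """Copy of the structure with replaced coordinates (metadata kept)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        new_atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return ProteinStructure(new_atoms, label=self.label)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation matrix must have determinant +1")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an (n, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Transform equal to applying ``t2`` first, then ``t1``."""
    return RigidTransform(t1.rotation @ t2.rotation,
                          t1.rotation @ t2.translation + t1.translation)


def invert(t: RigidTransform) -> RigidTransform:
    Rinv = t.rotation.T
    return RigidTransform(Rinv, -Rinv @ t.translation)


def apply_transform(structure: ProteinStructure, t: RigidTransform) -> ProteinStructure:
    """Return a copy of ``structure`` with every coordinate moved by ``t``."""
    return structure.with_coords(t.apply(structure.coords))


# ---------------------------------------------------------------------------
# PDB I/O


def _select_chains(chains: str | Sequence[str] | None) -> set[str] | None:
    if chains is None:
        return None
    if isinstance(chains, str):
        return set(chains.replace(",", ""))
    return set(chains)


def read_pdb(
    path: str | Path,
    chains: str | Sequence[str] | None = None,
    keep_hydrogens: bool = False,
    label: str | None = None,
) -> ProteinStructure:
    """Read ATOM records from a PDB file into a ProteinStructure.

    Only the first MODEL is used; HETATM records and waters are excluded;
    for alternate locations the highest-occupancy copy is kept (ties go to
    altloc 'A').  Hydrogens are dropped unless ``keep_hydrogens`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path} as PDB: {exc}") from exc
    if len(st) == 0:
        raise EmptySelectionError(f"{path}: no coordinate model found")
    wanted = _select_chains(chains)

    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        if wanted is not None and chain.name not in wanted:
            continue
        for res in chain:
            if res.het_flag == "H" or res.name in _WATER_NAMES:
                continue
            # pick one atom per name: highest occupancy, ties by altloc letter
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                if not keep_hydrogens and at.element.name in ("H", "D"):
                    continue
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif (at.occ, _altloc_rank(at.altloc)) > (prev.occ, _altloc_rank(prev.altloc)):
                    best[at.name] = at
            for name in order:
                at = best[name]
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=name,
                        element=at.element.name.upper(),
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        insertion_code=(res.seqid.icode or " ").strip() or " ",
                        chain_id=chain.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    if not atoms:
        raise EmptySelectionError(
            f"{path}: no atoms left after chain/record selection (chains={chains!r})"
        )
    return ProteinStructure(atoms, label=label if label is not None else path.stem)


def _altloc_rank(altloc: str) -> int:
    # higher rank wins; '' (no altloc) beats everything, then 'A' > 'B' > ...
    if not altloc or altloc == "\x00":
        return 1000
    return 255 - ord(altloc[0])


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"
    return f" {name:<3}"


def write_pdb(
    structure: ProteinStructure,
    path: str | Path,
    transform: RigidTransform | None = None,
) -> None:
    """Write the structure as PDB ATOM records (optionally transformed).

    Round trip through :func:`read_pdb` reproduces coordinates to the PDB
    precision of 1e-3 A and all residue/chain identities exactly.
    """
    coords = structure.coords if transform is None else transform.apply(structure.coords)
    lines: list[str] = []
    prev_chain: str | None = None
    serial = 0
    for atom, xyz in zip(structure.atoms, coords):
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        serial += 1
        lines.append(
            "ATOM  {serial:>5} {name}{alt}{res:>3} {chain}{seq:>4}{icode}   "
            "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2}".format(
                serial=serial % 100000,
                name=_format_atom_name(atom.name, atom.element),
                alt=" ",
                res=atom.residue_name,
                chain=atom.chain_id,
                seq=atom.residue_seq,
                icode=atom.insertion_code if atom.insertion_code.strip() else " ",
                x=xyz[0],
                y=xyz[1],
                z=xyz[2],
                occ=1.0,
                b=0.0,
                el=atom.element,
            )
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
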