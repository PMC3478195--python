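"""Atomic Contact Energy (ACE) parameterization and scoring.

ACE is a statistical desolvation score over 18 heavy-atom types: for a
pair of subunits it sums a pre-computed contact energy ``T[i, j]`` over
every cross-subunit atom pair within a distance cutoff ``d`` (6 A by
default).  A more negative sum means a more favorable desolvation change
on binding.

The entries of ``T`` are log-likelihood values derived from observed vs
expected contact counts in known structures:

    T[i, j] = -ln[ (N_ij / C_ij) / ((N_i0 / C_i0) * (N_j0 / C_j0)) ]

with type 0 denoting solvent, ``N`` observed and ``C`` expected counts.
The package ships an editable plain-text parameter file (a synthetic
default; see ``data/ace_table_synthetic.txt``) and can rebuild the table
from user-supplied counts via :func:`build_table`.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy.spatial import cKDTree

from .core_model import Atom, ProteinStructure

__all__ = [
    "N_ACE_TYPES",
    "ScoringParams",
    "AceTable",
    "contact_energy",
    "build_table",
    "load_table",
    "save_table",
    "default_table",
    "assign_ace_types",
    "find_contacts",
    "ace_score",
]

N_ACE_TYPES = 18


@dataclass(frozen=True)
class ScoringParams:
    """All tunable parameters of the docking pipeline.

    Defaults are the published operating point; tests and desk-scale
    runs coarsen ``epsilon`` and ``rotation_step``.
    """

    contact_cutoff: float = 6.0          # d, A: ACE contact distance
    interface_cutoff: float = 4.5        # A: predicted-interface residue rule
    fragment_ace_threshold: float = 400.0  # stage-2 fragment filter
    gap_penalty: float = 1.0             # alignment space penalty (added cost)
    alignment_score_cap: float = 0.0     # x: emit segments scoring <= x
    window_length: int = 15              # sliding-window length, columns
    window_surface_min: int = 10         # >= 2/3 of 15 surface atoms per side
    epsilon: float = 0.1                 # grid pitch = epsilon * d
    rotation_step: float = 1.0           # degrees about the anchor axis
    clash_theta: float = 0.17            # clash tolerance fraction
    grid_spacing: float = 1.0            # A, surface/clash lattice pitch
    protein_point_radius: float = 2.0    # A, lattice point is protein if <= this
    surface_atom_radius: float = 1.5     # A, atom is surface if <= this of a surface point
    vdw_margin: float = 1.0              # A, actual-interface margin over vdW sum
    top_n_poses: int = 10

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "interface_cutoff", "gap_penalty",
                     "grid_spacing", "protein_point_radius", "surface_atom_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        if not (0 <= self.clash_theta < 1):
            raise ValueError("clash_theta must be in [0, 1)")
        if self.rotation_step <= 0 or abs(360.0 / self.rotation_step - round(360.0 / self.rotation_step)) > 1e-9:
            raise ValueError("rotation_step must divide 360")
        if self.window_length < 1 or self.window_surface_min < 0:
            raise ValueError("window parameters must be positive")


@dataclass
class AceTable:
    """18x18 symmetric contact-energy matrix plus an atom-typing map.

    ``typing_map`` sends ``(residue_name, atom_name)`` to a type index in
    ``0..17``.  Raw observed/expected counts may optionally be attached
    (``pair_counts[i][j] = (N_ij, C_ij)``, ``solvent_counts[i] = (N_i0, C_i0)``).
    """

    T: np.ndarray
    typing_map: dict[tuple[str, str], int] = field(default_factory=dict)
    type_names: tuple[str, ...] = tuple(f"T{i}" for i in range(N_ACE_TYPES))

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (N_ACE_TYPES, N_ACE_TYPES):
            raise ValueError(f"T must be {N_ACE_TYPES}x{N_ACE_TYPES}")
        if not np.allclose(self.T, self.T.T, atol=1e-12):
            raise ValueError("contact-energy matrix must be symmetric")
        if len(self.type_names) != N_ACE_TYPES:
            raise ValueError("need exactly 18 type names")

    def lookup(self, res_name: str, atom_name: str) -> int | None:
        return self.typing_map.get((res_name.upper(), atom_name.upper()))


def contact_energy(
    n_ij: float, c_ij: float, n_i0: float, c_i0: float, n_j0: float, c_j0: float
) -> float:
    """Contact energy of a type pair from observed/expected contact counts.

    Returns ``-ln[(N_ij/C_ij) / ((N_i0/C_i0)(N_j0/C_j0))]``; symmetric
    under exchange of the i- and j-labelled count blocks.  More observed
    i-j contacts (larger ``N_ij``) give a more favorable (lower) energy.
    """
    for name, value in (("N_ij", n_ij), ("C_ij", c_ij), ("N_i0", n_i0),
                        ("C_i0", c_i0), ("N_j0", n_j0), ("C_j0", c_j0)):
        if value <= 0:
            raise ValueError(f"count {name} must be strictly positive, got {value}")
    return -math.log((n_ij / c_ij) / ((n_i0 / c_i0) * (n_j0 / c_j0)))


def build_table(
    pair_counts: dict[tuple[int, int], tuple[float, float]],
    solvent_counts: dict[int, tuple[float, float]],
    typing_map: dict[tuple[str, str], int] | None = None,
    type_names: Iterable[str] | None = None,
) -> AceTable:
    """Build the full 18x18 table from contact counts.

    ``pair_counts`` must cover every unordered type pair (i <= j) with
    ``(N_ij, C_ij)``; ``solvent_counts`` every type with ``(N_i0, C_i0)``.
    """
    for i in range(N_ACE_TYPES):
        if i not in solvent_counts:
            raise ValueError(f"missing solvent counts for type {i}")
    T = np.zeros((N_ACE_TYPES, N_ACE_TYPES))
    for i in range(N_ACE_TYPES):
        for j in range(i, N_ACE_TYPES):
            key = (i, j) if (i, j) in pair_counts else (j, i)
            if key not in pair_counts:
                raise ValueError(f"missing pair counts for types ({i}, {j})")
            n_ij, c_ij = pair_counts[key]
            n_i0, c_i0 = solvent_counts[i]
            n_j0, c_j0 = solvent_counts[j]
            T[i, j] = T[j, i] = contact_energy(n_ij, c_ij, n_i0, c_i0, n_j0, c_j0)
    names = tuple(type_names) if type_names is not None else tuple(f"T{i}" for i in range(N_ACE_TYPES))
    return AceTable(T, typing_map=dict(typing_map or {}), type_names=names)


# ---------------------------------------------------------------------------
# Parameter file format: '#' comments; 'TYPES' line with 18 names;
# 'ENERGY i j value' for the upper triangle; 'MAP resname atomname type'.


def save_table(table: AceTable, path: str | Path) -> None:
    lines = ["# ACE parameter file", "TYPES " + " ".join(table.type_names)]
    for i in range(N_ACE_TYPES):
        for j in range(i, N_ACE_TYPES):
            lines.append(f"ENERGY {i} {j} {float(table.T[i, j])!r}")
    for (res, name), t in sorted(table.typing_map.items()):
        lines.append(f"MAP {res} {name} {t}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_table(path: str | Path) -> AceTable:
    """Load a plain-text ACE parameter file; the upper triangle is
    mirrored so the stored matrix is exactly symmetric."""
    path = Path(path)
    T = np.full((N_ACE_TYPES, N_ACE_TYPES), np.nan)
    typing_map: dict[tuple[str, str], int] = {}
    type_names: tuple[str, ...] | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        tag = fields[0].upper()
        if tag == "TYPES":
            if len(fields) != N_ACE_TYPES + 1:
                raise ValueError(f"{path}:{lineno}: TYPES needs {N_ACE_TYPES} names")
            type_names = tuple(fields[1:])
        elif tag == "ENERGY":
            i, j, value = int(fields[1]), int(fields[2]), float(fields[3])
            if not (np.isnan(T[i, j]) or T[i, j] == value):
                raise ValueError(f"{path}:{lineno}: conflicting value for pair ({i},{j})")
            T[i, j] = T[j, i] = value
        elif tag == "MAP":
            typing_map[(fields[1].upper(), fields[2].upper())] = int(fields[3])
        else:
            raise ValueError(f"{path}:{lineno}: unknown record {tag!r}")
    if np.isnan(T).any():
        missing = np.argwhere(np.isnan(np.triu(T) + np.tril(np.full_like(T, 0))))
        raise ValueError(f"{path}: incomplete energy table")
    kwargs = {"type_names": type_names} if type_names else {}
    return AceTable(T, typing_map=typing_map, **kwargs)


def default_table() -> AceTable:
    """The shipped (synthetic) default parameter set."""
    ref = importlib.resources.files("acedock.data") / "ace_table_synthetic.txt"
    with importlib.resources.as_file(ref) as p:
        return load_table(p)


def assign_ace_types(
    structure: ProteinStructure,
    table: AceTable,
    unknown_policy: Literal["skip", "error"] = "skip",
) -> ProteinStructure:
    """Return a copy of the structure with ``ace_type`` set from the map.

    Atoms absent from the typing map are left untyped under policy
    ``"skip"`` (they then contribute nothing to any score) or raise under
    ``"error"``.
    """
    new_atoms: list[Atom] = []
    for atom in structure.atoms:
        t = table.lookup(atom.residue_name, atom.name)
        if t is None and unknown_policy == "error":
            raise KeyError(
                f"no ACE type for atom {atom.residue_name}/{atom.name} "
                f"(chain {atom.chain_id} residue {atom.residue_seq})"
            )
        new_atoms.append(replace(atom, ace_type=t))
    return ProteinStructure(new_atoms, label=structure.label)


def find_contacts(
    coords1: np.ndarray, coords2: np.ndarray, cutoff: float
) -> list[tuple[int, int, float]]:
    """All cross pairs within ``cutoff`` (inclusive), as (i, j, distance).

    Uses a k-d tree; agrees exactly with the quadratic double loop.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    c1 = np.atleast_2d(np.asarray(coords1, dtype=float))
    c2 = np.atleast_2d(np.asarray(coords2, dtype=float))
    if c1.size == 0 or c2.size == 0:
        return []
    tree = cKDTree(c2)
    out: list[tuple[int, int, float]] = []
    for i, neighbors in enumerate(tree.query_ball_point(c1, cutoff)):
        for j in sorted(neighbors):
            out.append((i, j, float(np.linalg.norm(c1[i] - c2[j]))))
    return out


def ace_score(
    s1: ProteinStructure | np.ndarray,
    s2: ProteinStructure | np.ndarray,
    table: AceTable,
    cutoff: float | None = None,
    types1: np.ndarray | None = None,
    types2: np.ndarray | None = None,
) -> float:
    """ACE of a two-subunit configuration.

    Sums ``T[type(s), type(t)]`` over every cross-subunit atom pair within
    ``cutoff`` (6 A when unspecified); untyped atoms are skipped.  The
    value is symmetric in the two subunits and invariant under any joint
    rigid motion.
    """
    if cutoff is None:
        cutoff = ScoringParams().contact_cutoff
    if isinstance(s1, ProteinStructure):
        c1, t1 = s1.coords, s1.ace_types
    else:
        c1, t1 = np.asarray(s1, dtype=float), np.asarray(types1, dtype=int)
    if isinstance(s2, ProteinStructure):
        c2, t2 = s2.coords, s2.ace_types
    else:
        c2, t2 = np.asarray(s2, dtype=float), np.asarray(types2, dtype=int)
    keep1 = t1 >= 0
    keep2 = t2 >= 0
    if not keep1.any() or not keep2.any():
        return 0.0
    c1, t1 = c1[keep1], t1[keep1]
    c2, t2 = c2[keep2], t2[keep2]
    total = 0.0
    tree = cKDTree(c2)
    for i, neighbors in enumerate(tree.query_ball_point(c1, cutoff)):
        if neighbors:
            total += float(table.T[t1[i], t2[neighbors]].sum())
    return total
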