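"""Seeded toy complexes with a planted, analytically known binding site.

The generator builds a "peg and pocket" pair of pseudo-protein subunits:

* subunit A is a straight rod of 4-atom pseudo-residues (N/CA/C/O
  naming) whose last four residues — the *peg* — carry one contact-energy
  type;
* subunit B is a *pocket*: a helical lining of atoms around the peg's
  docked position, a floor below its tip, and a sparse outer shell of
  bulk residues.

Under the accompanying toy contact table the peg-lining pairs are
strongly favorable while peg-bulk and rod-lining pairs are penalized, so
the planted docked pose is the unique energy optimum at the test grid
resolution.  The construction aligns the planted pose exactly with the
pose-enumeration grid: the peg's first anchor atom sits on a d-ball
lattice point of its partner atom, the second anchor on the
corresponding sphere-cap pole, and the rod's collinearity makes the
axis-rotation degree of freedom irrelevant.  Every planted complex
verifies its own invariants (clash-free, surface-labelled interface,
favorable fragment energy) at construction time.

Atom contact-energy types are set directly on the atoms, bypassing the
residue/atom-name typing map, so algorithm tests are independent of any
shipped parameter table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .ace_energy import AceTable, N_ACE_TYPES, ScoringParams, ace_score
from .binding_interface import InterfaceSet, predicted_interface
from .core_model import (Atom, ProteinStructure, RigidTransform,
                         apply_transform, invert, write_pdb)
from .pose_enumeration import Pose
from .surface_grid import clash_check, surface_atoms

__all__ = [
    "TEST_PARAMS",
    "PlantedComplex",
    "make_toy_ace_table",
    "make_planted_complex",
    "make_decoy_pose",
    "write_fixture",
]

# coarse "test mode" resolution: 3 A translation grid, 60 degree rotations
TEST_PARAMS = ScoringParams(epsilon=0.5, rotation_step=60.0)

_ATOM_NAMES = ("N", "CA", "C", "O")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}
# pseudo-residue names encode the toy contact type so fixtures written to
# PDB can be re-typed from the sidecar table's typing map
_TYPE_RESNAMES = {0: "PEG", 1: "LIN", 2: "ROD", 3: "BLK"}
_SPACING = 1.8          # A between consecutive rod/lining atoms along z
_LINING_RADIUS = 2.5    # A, lateral distance of pocket lining from the peg axis
_BULK_RADIUS = 7.0      # A, outer shell distance from the axis
_FRAG_ATOMS = 16        # peg / lining run length (4 pseudo-residues)

PEG_TYPE, LINING_TYPE, ROD_BULK_TYPE, POCKET_BULK_TYPE = 0, 1, 2, 3


@dataclass
class PlantedComplex:
    """A toy two-subunit complex with known ground truth."""

    subunit_a: ProteinStructure       # mobile subunit, displaced input frame
    subunit_b: ProteinStructure       # fixed subunit (pocket)
    native_transform: RigidTransform  # maps subunit_a onto the planted pose
    planted_interface: InterfaceSet
    table: AceTable
    seed: int
    params: ScoringParams = field(default_factory=lambda: TEST_PARAMS)

    @property
    def docked_a(self) -> ProteinStructure:
        return apply_transform(self.subunit_a, self.native_transform)


def make_toy_ace_table(
    favorable_pairs: list[tuple[int, int]],
    favorable_value: float = -10.0,
    background_value: float = 1.0,
) -> AceTable:
    """Symmetric 18x18 table: ``background_value`` everywhere except the
    listed type pairs, which get ``favorable_value``."""
    if not favorable_value < 0 < background_value:
        raise ValueError("need favorable_value < 0 < background_value")
    T = np.full((N_ACE_TYPES, N_ACE_TYPES), float(background_value))
    for i, j in favorable_pairs:
        T[i, j] = T[j, i] = favorable_value
    return AceTable(T)


def _pseudo_residues(
    positions: np.ndarray, chain: str, types: list[int], start_seq: int = 1
) -> list[Atom]:
    """Wrap a (4k, 3) position array into k 4-atom pseudo-residues."""
    atoms = []
    for t, pos in enumerate(positions):
        name = _ATOM_NAMES[t % 4]
        atoms.append(
            Atom(
                serial=t + 1,
                name=name,
                element=_ELEMENTS[name],
                residue_name=_TYPE_RESNAMES[types[t]],
                residue_seq=start_seq + t // 4,
                insertion_code=" ",
                chain_id=chain,
                coords=pos,
                ace_type=types[t],
            )
        )
    return atoms


def make_planted_complex(
    seed: int,
    n_residues_a: int = 6,
    n_residues_b: int = 8,
    pocket_depth: float = 4.0,
    favorable_types: list[tuple[int, int]] | None = None,
    params: ScoringParams | None = None,
) -> PlantedComplex:
    """Build a peg-and-pocket complex whose interface is known exactly.

    ``pocket_depth`` is the drop from the deepest peg anchor to the
    pocket-floor atom (A); it must leave room for the peg tip yet keep
    the floor within contact range, hence 3-6 A.  The seed varies the
    lining helix phase, the bulk shell and subunit A's initial placement;
    anchor-critical coordinates are exact by construction.
    """
    if n_residues_a < 4 or n_residues_b < 4:
        raise ValueError("both subunits need at least 4 residues")
    if not (3.0 <= pocket_depth <= 6.0):
        raise ValueError(
            f"pocket_depth {pocket_depth} A is infeasible: the floor must sit "
            "3-6 A below the deepest anchor (deeper than the contact range "
            "or shallower than the peg tip)"
        )
    if params is None:
        params = TEST_PARAMS
    rng = np.random.default_rng(seed)
    pitch = params.epsilon * params.contact_cutoff   # d-ball lattice pitch
    delta = _SPACING

    # --- subunit A: straight rod along -z, peg = last 16 atoms ------------
    na = 4 * n_residues_a
    t0 = na - _FRAG_ATOMS                  # first peg atom index
    z = (t0 - np.arange(na)) * delta       # peg starts exactly at z = 0
    coords_a_docked = np.column_stack([np.zeros(na), np.zeros(na), z])
    types_a = [ROD_BULK_TYPE] * t0 + [PEG_TYPE] * _FRAG_ATOMS

    # anchors the pipeline will discover: peg atoms 0 and 14 of the run
    anchor_i = np.array([0.0, 0.0, 0.0])             # docked a_i
    anchor_j = np.array([0.0, 0.0, -14 * delta])     # docked a_j

    # --- subunit B: lining helix + floor + bulk shell ---------------------
    # run atom 0 (b_i') is offset from the docked a_i by exactly one lattice
    # pitch in x and -z, so the planted a_i position is a d-ball grid point
    # of b_i'; the -z drop keeps the pocket rim out of 4.5 A range of the
    # rod residue just above the peg.
    phase_step = 2.4 + rng.uniform(-0.15, 0.15)
    run = [np.array([pitch, 0.0, -pitch])]
    # the lining sits one atom spacing deeper than the matching peg atoms;
    # with its 2.5 A radius this puts the peg's in-register placement at the
    # contact-count optimum (any 3 A lattice shift loses contacts) while
    # keeping the pocket rim > 4.5 A from the rod residue above the peg
    for k in range(1, 14):
        psi = k * phase_step
        run.append(np.array([_LINING_RADIUS * math.cos(psi),
                             _LINING_RADIUS * math.sin(psi),
                             -(k + 1) * delta]))
    # run atom 14 (b_j') on the peg axis: the sphere-cap pole for the
    # planted a_i lands exactly on the docked a_j.
    floor_z = -14 * delta - pocket_depth
    run.append(np.array([0.0, 0.0, floor_z]))
    run.append(np.array([0.0, 0.0, floor_z - 1.5]))
    types_b = [LINING_TYPE] * _FRAG_ATOMS

    n_bulk = 4 * (n_residues_b - 4)
    bulk = []
    for w in range(n_bulk):
        phi = w * 2.4 + rng.uniform(-0.2, 0.2)
        zb = -(14 * delta + 2.0) * (w / max(1, n_bulk - 1)) + rng.uniform(-0.3, 0.3)
        bulk.append(np.array([_BULK_RADIUS * math.cos(phi),
                              _BULK_RADIUS * math.sin(phi),
                              zb]))
    types_b = types_b + [POCKET_BULK_TYPE] * n_bulk
    coords_b = np.array(run + bulk)

    # The surface lattice is phase-sensitive: an isolated atom sitting near
    # a lattice cell center can end up marginally farther than the atom
    # labeling radius from every surface lattice point.  Translate the whole
    # docked complex by a sub-lattice offset (seeded search) until every
    # peg and pocket-run atom is surface-labelled; the shift moves A and B
    # together, so no docking-relevant geometry changes.
    shift = _surface_phase_shift(coords_a_docked, range(t0, na), coords_b,
                                 range(_FRAG_ATOMS), rng, params)
    coords_a_docked = coords_a_docked + shift
    coords_b = coords_b + shift
    anchor_i = anchor_i + shift
    anchor_j = anchor_j + shift

    # --- toy energies: peg-lining favorable, misplacement penalized ------
    favorable = favorable_types if favorable_types is not None else [(PEG_TYPE, LINING_TYPE)]
    table = make_toy_ace_table(favorable)
    table.T[PEG_TYPE, POCKET_BULK_TYPE] = table.T[POCKET_BULK_TYPE, PEG_TYPE] = 6.0
    table.T[ROD_BULK_TYPE, LINING_TYPE] = table.T[LINING_TYPE, ROD_BULK_TYPE] = 6.0
    table.typing_map = {
        (res, atom): t
        for t, res in _TYPE_RESNAMES.items()
        for atom in _ATOM_NAMES
    }

    # --- displaced input frame for A --------------------------------------
    g_rot = Rotation.random(random_state=np.random.RandomState(seed + 1)).as_matrix()
    g_tr = rng.uniform(-10, 10, 3) + np.array([60.0, 0.0, 0.0])
    g = RigidTransform(g_rot, g_tr)
    coords_a_input = g.apply(coords_a_docked)
    native = invert(g)

    subunit_a = ProteinStructure(
        _pseudo_residues(coords_a_input, "A", types_a), label=f"peg-{seed}"
    )
    subunit_b = ProteinStructure(
        _pseudo_residues(coords_b, "B", types_b), label=f"pocket-{seed}"
    )

    docked_a = apply_transform(subunit_a, native)
    planted = predicted_interface(docked_a, subunit_b, params.interface_cutoff)
    cx = PlantedComplex(subunit_a, subunit_b, native, planted, table, seed, params)
    _self_check(cx, docked_a, anchor_i, anchor_j, t0)
    return cx


def _surface_phase_shift(
    coords_a: np.ndarray,
    critical_a: "range",
    coords_b: np.ndarray,
    critical_b: "range",
    rng: np.random.Generator,
    params: ScoringParams,
    max_tries: int = 60,
) -> np.ndarray:
    """A global translation making every critical atom a surface atom."""
    for trial in range(max_tries):
        shift = np.zeros(3) if trial == 0 else rng.uniform(0.0, 1.0, 3)
        ok_a = surface_atoms(coords_a + shift, params=params)
        ok_b = surface_atoms(coords_b + shift, params=params)
        if all(ok_a[i] for i in critical_a) and all(ok_b[i] for i in critical_b):
            return shift
    raise RuntimeError(
        "could not find a lattice phase exposing every planted-interface atom"
    )


def _self_check(cx: PlantedComplex, docked_a: ProteinStructure,
                anchor_i: np.ndarray, anchor_j: np.ndarray, t0: int) -> None:
    """Verify the planted complex satisfies its advertised invariants."""
    params = cx.params
    # the planted pose is clash-free
    report = clash_check(docked_a, cx.subunit_b, params)
    if report.clash:
        raise RuntimeError(f"planted pose clashes: {report}")
    # every planted-interface atom region is on the surface
    surf_a = surface_atoms(docked_a, params=params)
    surf_b = surface_atoms(cx.subunit_b, params=params)
    if not surf_a[t0: t0 + _FRAG_ATOMS].all():
        raise RuntimeError("planted peg atoms are not all surface atoms")
    if not surf_b[:_FRAG_ATOMS].all():
        raise RuntimeError("pocket run atoms are not all surface atoms")
    # the planted interface is exactly peg residues vs pocket-run residues
    frag_res = {a.residue_id for a in docked_a.atoms[t0:]}
    run_res = {a.residue_id for a in cx.subunit_b.atoms[:_FRAG_ATOMS]}
    if cx.planted_interface.residues_a != frozenset(frag_res):
        raise RuntimeError("planted interface does not cover exactly the peg residues")
    if cx.planted_interface.residues_b != frozenset(run_res):
        raise RuntimeError("planted interface does not cover exactly the pocket run")
    # anchors land exactly on the enumeration grid
    ai = docked_a.coords[t0]
    aj = docked_a.coords[t0 + 14]
    if not (np.allclose(ai, anchor_i, atol=1e-9) and np.allclose(aj, anchor_j, atol=1e-6)):
        raise RuntimeError("anchor atoms drifted off their planted positions")
    # the peg-pocket fragment energy is favorable (well under any threshold)
    frag_ace = ace_score(
        docked_a.coords[t0:], cx.subunit_b.coords[:_FRAG_ATOMS], cx.table,
        params.contact_cutoff,
        types1=docked_a.ace_types[t0:], types2=cx.subunit_b.ace_types[:_FRAG_ATOMS],
    )
    if frag_ace >= 0:
        raise RuntimeError(f"planted fragment energy {frag_ace} is not favorable")


def make_decoy_pose(
    cx: PlantedComplex,
    seed: int,
    translation_mag: float = 0.0,
    rotation_mag_deg: float = 0.0,
) -> Pose:
    """Perturb the native pose by a random rotation (degrees, about the
    planted-interface centroid) and a random translation (A).

    Magnitude 0 returns the native pose.  For perturbations beyond the
    contact range the decoy's energy is verified to be no better than the
    native energy (the check runs per instance).
    """
    if translation_mag < 0 or rotation_mag_deg < 0:
        raise ValueError("perturbation magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    docked = cx.docked_a
    center = docked.coords.mean(axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(rotation_mag_deg) * axis).as_matrix()
    shift = rng.normal(size=3)
    shift = shift / np.linalg.norm(shift) * translation_mag
    perturb = RigidTransform(R, center - R @ center + shift)
    from .core_model import compose  # local import to avoid top-level cycle noise
    transform = compose(perturb, cx.native_transform)

    posed = transform.apply(cx.subunit_a.coords)
    energy = ace_score(posed, cx.subunit_b.coords, cx.table,
                       cx.params.contact_cutoff,
                       types1=cx.subunit_a.ace_types, types2=cx.subunit_b.ace_types)
    native_energy = ace_score(docked.coords, cx.subunit_b.coords, cx.table,
                              cx.params.contact_cutoff,
                              types1=cx.subunit_a.ace_types,
                              types2=cx.subunit_b.ace_types)
    if translation_mag > 4 * cx.params.contact_cutoff and energy < native_energy:
        raise RuntimeError("far decoy unexpectedly scores better than the native pose")
    clash = clash_check(posed, cx.subunit_b, cx.params).clash
    return Pose(transform=transform, ace=None if clash else energy,
                clash=clash, anchors=None, grid_index=())


def write_fixture(cx: PlantedComplex, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture as two PDB files plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subunit_a": out_dir / "subunit_A.pdb",
        "subunit_b": out_dir / "subunit_B.pdb",
        "native_complex": out_dir / "native_complex.pdb",
        "table": out_dir / "ace_toy_table.txt",
        "meta": out_dir / "fixture.json",
    }
    write_pdb(cx.subunit_a, paths["subunit_a"])
    write_pdb(cx.subunit_b, paths["subunit_b"])
    native = ProteinStructure(cx.docked_a.atoms + cx.subunit_b.atoms,
                              label=f"native-{cx.seed}")
    write_pdb(native, paths["native_complex"])
    from .ace_energy import save_table
    save_table(cx.table, paths["table"])
    meta = {
        "seed": cx.seed,
        "native_rotation": cx.native_transform.rotation.tolist(),
        "native_translation": cx.native_transform.translation.tolist(),
        "planted_interface": sorted(
            [list(map(list, pair)) for pair in cx.planted_interface.residue_pairs]
        ),
    }
    paths["meta"].write_text(json.dumps(meta, indent=2) + "\n")
    return paths
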