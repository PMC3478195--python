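"""Interface extraction and evaluation statistics.

Two notions of interface are used.  The *predicted* interface of a pose
is the set of cross-subunit residue pairs connected by an atom pair
within 4.5 A.  The *actual* interface of an experimental complex is the
set of residue pairs with an atom pair closer than the sum of the two
atoms' van der Waals radii plus a 1 A margin.

Prediction quality is summarized by accuracy (fraction of predicted
interface residues that are actual), coverage (fraction of actual
interface residues recovered), their harmonic mean F on the 0-1 scale,
the success criterion accuracy >= 50%, the interface C-alpha RMSD after
least-squares superposition (iRMSD), and the fraction of native residue
contacts reproduced by the pose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .ace_energy import find_contacts
from .core_model import ProteinStructure

__all__ = [
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "InterfaceSet",
    "EvalResult",
    "predicted_interface",
    "predicted_interface_from_arrays",
    "actual_interface",
    "accuracy_coverage",
    "f_score",
    "success_rate",
    "evaluate_prediction",
    "irmsd",
    "native_contact_fraction",
]

ResidueId = tuple[str, int, str]

# element-based van der Waals radii (A); editable fallback for odd elements
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_VDW_RADIUS = 1.70


@dataclass(frozen=True)
class InterfaceSet:
    """Cross-subunit residue pairs forming an interface."""

    residue_pairs: frozenset[tuple[ResidueId, ResidueId]]

    @property
    def residues_a(self) -> frozenset[ResidueId]:
        return frozenset(p[0] for p in self.residue_pairs)

    @property
    def residues_b(self) -> frozenset[ResidueId]:
        return frozenset(p[1] for p in self.residue_pairs)

    @property
    def residues_pooled(self) -> frozenset[tuple[str, ResidueId]]:
        """Residues from both subunits, tagged by side so they never collide."""
        return frozenset(("A", r) for r in self.residues_a) | frozenset(
            ("B", r) for r in self.residues_b
        )

    def __len__(self) -> int:
        return len(self.residue_pairs)


@dataclass
class EvalResult:
    """Per-case evaluation of a predicted interface."""

    accuracy: float           # %
    coverage: float           # %
    f: float                  # 0..1
    success: bool             # accuracy >= 50
    predicted_size: int       # M, residues
    correct: int              # correctly predicted residues
    actual_size: int          # Int_n
    pred_empty: bool = False


def predicted_interface_from_arrays(
    coords_a: np.ndarray,
    rids_a: Sequence[ResidueId],
    coords_b: np.ndarray,
    rids_b: Sequence[ResidueId],
    cutoff: float = 4.5,
) -> InterfaceSet:
    pairs: set[tuple[ResidueId, ResidueId]] = set()
    for i, j, _ in find_contacts(coords_a, coords_b, cutoff):
        pairs.add((rids_a[i], rids_b[j]))
    return InterfaceSet(frozenset(pairs))


def predicted_interface(
    a_posed: ProteinStructure, b: ProteinStructure, cutoff: float = 4.5
) -> InterfaceSet:
    """Residue pairs with some cross atom pair within ``cutoff`` (inclusive)."""
    return predicted_interface_from_arrays(
        a_posed.coords, a_posed.residue_index_per_atom(),
        b.coords, b.residue_index_per_atom(), cutoff,
    )


def actual_interface(
    native_a: ProteinStructure,
    native_b: ProteinStructure,
    vdw_radii: dict[str, float] | None = None,
    margin: float = 1.0,
    fallback_radius: float | None = DEFAULT_VDW_RADIUS,
) -> InterfaceSet:
    """Residue pairs of the experimental complex whose atoms interact.

    Two atoms interact when their distance is strictly less than the sum
    of their van der Waals radii plus ``margin``.
    """
    radii = VDW_RADII if vdw_radii is None else vdw_radii

    def radius(element: str) -> float:
        r = radii.get(element.upper())
        if r is None:
            if fallback_radius is None:
                raise KeyError(f"no van der Waals radius for element {element!r}")
            return fallback_radius
        return r

    ra = np.array([radius(at.element) for at in native_a.atoms])
    rb = np.array([radius(at.element) for at in native_b.atoms])
    rids_a = native_a.residue_index_per_atom()
    rids_b = native_b.residue_index_per_atom()
    max_reach = ra.max() + rb.max() + margin
    pairs: set[tuple[ResidueId, ResidueId]] = set()
    for i, j, dist in find_contacts(native_a.coords, native_b.coords, max_reach):
        if dist < ra[i] + rb[j] + margin:
            pairs.add((rids_a[i], rids_b[j]))
    return InterfaceSet(frozenset(pairs))


def accuracy_coverage(
    predicted: Iterable, actual: Iterable
) -> tuple[float, float]:
    """(accuracy %, coverage %) of a predicted residue set vs the actual set.

    Accuracy is 0 (flagged via EvalResult.pred_empty in the wrapper) when
    the prediction is empty; an empty actual set leaves coverage
    undefined and raises.
    """
    pred = set(predicted)
    act = set(actual)
    if not act:
        raise ValueError("coverage is undefined for an empty actual interface")
    correct = len(pred & act)
    accuracy = 100.0 * correct / len(pred) if pred else 0.0
    coverage = 100.0 * correct / len(act)
    return accuracy, coverage


def f_score(accuracy: float, coverage: float) -> float:
    """Harmonic mean of accuracy and coverage (inputs in %, result 0-1)."""
    if accuracy < 0 or coverage < 0:
        raise ValueError("accuracy and coverage must be non-negative")
    if accuracy + coverage == 0:
        return 0.0
    return (2 * accuracy * coverage / (accuracy + coverage)) / 100.0


def success_rate(results: Sequence["EvalResult | float"]) -> float:
    """Percentage of cases with accuracy >= 50% (boundary inclusive)."""
    if len(results) == 0:
        raise ValueError("success rate needs at least one case")
    accs = [r.accuracy if isinstance(r, EvalResult) else float(r) for r in results]
    return 100.0 * sum(a >= 50.0 for a in accs) / len(accs)


def evaluate_prediction(
    predicted: InterfaceSet, actual: InterfaceSet, mode: str = "pooled"
) -> EvalResult:
    """Accuracy/coverage/F/success of one prediction.

    ``mode='pooled'`` scores the union of both subunits' interface
    residues (side-tagged); ``mode='a'`` / ``mode='b'`` score one subunit.
    """
    if mode == "pooled":
        pred, act = predicted.residues_pooled, actual.residues_pooled
    elif mode == "a":
        pred, act = predicted.residues_a, actual.residues_a
    elif mode == "b":
        pred, act = predicted.residues_b, actual.residues_b
    else:
        raise ValueError(f"unknown mode {mode!r}")
    acc, cov = accuracy_coverage(pred, act)
    return EvalResult(
        accuracy=acc,
        coverage=cov,
        f=f_score(acc, cov),
        success=acc >= 50.0,
        predicted_size=len(pred),
        correct=len(pred & set(act)),
        actual_size=len(act),
        pred_empty=not pred,
    )


def _kabsch_rmsd(moving: np.ndarray, target: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of ``moving`` onto ``target``."""
    mu_m = moving.mean(axis=0)
    mu_t = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - mu_t, moving - mu_m)
    moved = rot.apply(moving - mu_m) + mu_t
    return float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))


def _ca_coords(structure: ProteinStructure, residues: set[ResidueId]) -> dict[ResidueId, np.ndarray]:
    out: dict[ResidueId, np.ndarray] = {}
    for atom in structure.atoms:
        if atom.name == "CA" and atom.residue_id in residues:
            out.setdefault(atom.residue_id, atom.coords)
    return out


def irmsd(
    predicted_a: ProteinStructure,
    predicted_b: ProteinStructure,
    native_a: ProteinStructure,
    native_b: ProteinStructure,
    interface: InterfaceSet | None = None,
) -> float:
    """Interface C-alpha RMSD of a predicted complex against the native.

    The interface residues are the native (actual) interface unless
    given; their C-alpha atoms from both subunits are superposed by
    least squares (Kabsch) and the residual RMSD returned.  Invariant
    under any joint rigid motion of the prediction; 0 on the native
    complex itself.
    """
    if interface is None:
        interface = actual_interface(native_a, native_b)
    res_a = set(interface.residues_a)
    res_b = set(interface.residues_b)
    pred_ca = {("A",) + r: c for r, c in _ca_coords(predicted_a, res_a).items()}
    pred_ca.update({("B",) + r: c for r, c in _ca_coords(predicted_b, res_b).items()})
    nat_ca = {("A",) + r: c for r, c in _ca_coords(native_a, res_a).items()}
    nat_ca.update({("B",) + r: c for r, c in _ca_coords(native_b, res_b).items()})
    keys = sorted(set(pred_ca) & set(nat_ca))
    if len(keys) < 3:
        raise ValueError(
            f"iRMSD needs at least 3 interface C-alpha atoms present in both "
            f"complexes, found {len(keys)}"
        )
    moving = np.array([pred_ca[k] for k in keys])
    target = np.array([nat_ca[k] for k in keys])
    return _kabsch_rmsd(moving, target)


def _residue_contacts(
    a: ProteinStructure, b: ProteinStructure, cutoff: float
) -> set[tuple[ResidueId, ResidueId]]:
    """Residue pairs whose minimum heavy-atom cross distance is < cutoff."""
    rids_a = a.residue_index_per_atom()
    rids_b = b.residue_index_per_atom()
    pairs: set[tuple[ResidueId, ResidueId]] = set()
    for i, j, dist in find_contacts(a.coords, b.coords, cutoff):
        if dist < cutoff:
            pairs.add((rids_a[i], rids_b[j]))
    return pairs


def native_contact_fraction(
    predicted_a: ProteinStructure,
    predicted_b: ProteinStructure,
    native_a: ProteinStructure,
    native_b: ProteinStructure,
    cutoff: float = 4.5,
) -> float:
    """Percentage of native residue contacts (< cutoff) present in the pose."""
    native = _residue_contacts(native_a, native_b, cutoff)
    if not native:
        raise ValueError("the native complex has no residue contacts at this cutoff")
    predicted = _residue_contacts(predicted_a, predicted_b, cutoff)
    return 100.0 * len(native & predicted) / len(native)
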