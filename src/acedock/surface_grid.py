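"""Grid-based surface-atom labeling and the shared-interior clash test.

A 1-Angstrom lattice is laid over the structure; lattice points within
2 A of any atom are "protein" points, and a protein point with all six
axis neighbors also protein is "interior", otherwise "surface".  An atom
is a surface atom iff it lies within 1.5 A of some surface lattice point.

Two posed subunits clash when the number of lattice points interior to
both exceeds ``theta * min(X_A, X_B)`` where ``X_A``, ``X_B`` are the
subunits' own interior-point counts on a shared lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .ace_energy import ScoringParams
from .core_model import ProteinStructure

__all__ = [
    "EMPTY",
    "SURFACE",
    "INTERIOR",
    "LabeledGrid",
    "ClashReport",
    "build_labeled_grid",
    "surface_atoms",
    "clash_check",
]

EMPTY, SURFACE, INTERIOR = 0, 1, 2
_LABEL_NAMES = {EMPTY: "empty", SURFACE: "surface", INTERIOR: "interior"}


@dataclass
class LabeledGrid:
    """Axis-aligned lattice with per-point labels empty/surface/interior."""

    origin: np.ndarray          # coordinates of lattice index (0,0,0)
    spacing: float
    labels: np.ndarray          # (nx, ny, nz) int array of label codes

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    def points(self, label: int | None = None) -> np.ndarray:
        """(k, 3) coordinates of all lattice points, or of one label class."""
        idx = np.argwhere(np.ones(self.labels.shape, bool) if label is None
                          else self.labels == label)
        return self.origin + idx * self.spacing


@dataclass(frozen=True)
class ClashReport:
    shared_interior: int     # X
    interior_a: int          # X_A
    interior_b: int          # X_B
    theta: float
    clash: bool


def _grid_geometry(coords: np.ndarray, params: ScoringParams) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Lattice origin and dims covering the atoms plus a safety margin.

    The origin is the componentwise floor of the minimum coordinate minus
    the margin, so the lattice phase is a pure function of the input
    coordinates (reproducible, and invariant under whole-Angstrom
    translations of the structure).
    """
    margin = params.protein_point_radius + params.grid_spacing
    lo = np.floor(coords.min(axis=0)) - margin
    hi = coords.max(axis=0) + margin
    dims = tuple(int(np.floor((hi[k] - lo[k]) / params.grid_spacing)) + 1 for k in range(3))
    return lo, dims


_STENCILS: dict[tuple[int, float], np.ndarray] = {}


def _stencil(reach: int, max_sq: float) -> np.ndarray:
    """Index offsets within ``reach`` whose squared norm is <= max_sq."""
    key = (reach, round(max_sq, 9))
    if key not in _STENCILS:
        span = np.arange(-reach, reach + 1)
        offs = np.stack(np.meshgrid(span, span, span, indexing="ij"), axis=-1).reshape(-1, 3)
        _STENCILS[key] = offs[(offs ** 2).sum(axis=1) <= max_sq]
    return _STENCILS[key]


def _occupancy(coords: np.ndarray, origin: np.ndarray, dims: tuple[int, int, int],
               params: ScoringParams) -> np.ndarray:
    """Boolean protein-point mask: lattice points within the protein radius
    (inclusive) of any atom."""
    spacing = params.grid_spacing
    r = params.protein_point_radius
    mask = np.zeros(dims, dtype=bool)
    tree = cKDTree(coords)
    # only lattice points near some atom can be protein: enumerate candidates
    # from per-atom index ranges rather than scanning the full box
    reach = int(np.ceil(r / spacing)) + 1
    idx_atoms = np.rint((coords - origin) / spacing).astype(int)
    offs = _stencil(reach, (r / spacing + np.sqrt(3.0)) ** 2)
    cand = (idx_atoms[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    ok = ((cand >= 0) & (cand < np.array(dims))).all(axis=1)
    cand = cand[ok]
    if cand.size == 0:
        return mask
    lin = np.unique(np.ravel_multi_index(cand.T, dims))
    cand_idx = np.column_stack(np.unravel_index(lin, dims))
    pts = origin + cand_idx * spacing
    dist, _ = tree.query(pts, k=1)
    hit = dist <= r + 1e-12
    mask[cand_idx[hit, 0], cand_idx[hit, 1], cand_idx[hit, 2]] = True
    return mask


def _interior_mask(protein: np.ndarray) -> np.ndarray:
    """Protein points whose six axis neighbors are all protein.

    Out-of-box neighbors count as empty, so box-edge protein points are
    surface; the build margin guarantees the box edge is never reached.
    """
    padded = np.pad(protein, 1, constant_values=False)
    inner = padded[1:-1, 1:-1, 1:-1]
    interior = inner.copy()
    for axis in range(3):
        interior &= np.roll(padded, 1, axis=axis)[1:-1, 1:-1, 1:-1]
        interior &= np.roll(padded, -1, axis=axis)[1:-1, 1:-1, 1:-1]
    return interior & protein


def build_labeled_grid(
    coords: np.ndarray | ProteinStructure, params: ScoringParams | None = None
) -> LabeledGrid:
    """Label a lattice around the atoms as empty / surface / interior."""
    if params is None:
        params = ScoringParams()
    if isinstance(coords, ProteinStructure):
        coords = coords.coords
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("cannot build a grid around zero atoms")
    origin, dims = _grid_geometry(coords, params)
    protein = _occupancy(coords, origin, dims, params)
    interior = _interior_mask(protein)
    labels = np.zeros(dims, dtype=np.int8)
    labels[protein] = SURFACE
    labels[interior] = INTERIOR
    return LabeledGrid(origin=origin, spacing=params.grid_spacing, labels=labels)


def surface_atoms(
    structure: ProteinStructure | np.ndarray,
    grid: LabeledGrid | None = None,
    params: ScoringParams | None = None,
) -> np.ndarray:
    """Per-atom surface mask: True where the atom is a surface atom.

    An atom is surface iff it is within ``surface_atom_radius`` of a
    surface lattice point (inclusive); otherwise interior.  When ``grid``
    is omitted it is built from the structure.
    """
    if params is None:
        params = ScoringParams()
    coords = structure.coords if isinstance(structure, ProteinStructure) else np.atleast_2d(structure)
    if grid is None:
        grid = build_labeled_grid(coords, params)
    else:
        lo = np.floor(coords.min(axis=0)) - (params.protein_point_radius + params.grid_spacing)
        if not np.allclose(lo, grid.origin):
            raise ValueError("grid was not built from this structure (origin mismatch)")
    surf_pts = grid.points(SURFACE)
    if surf_pts.size == 0:
        return np.zeros(len(coords), dtype=bool)
    tree = cKDTree(surf_pts)
    dist, _ = tree.query(coords, k=1)
    return dist <= params.surface_atom_radius + 1e-12


def clash_check(
    coords_a: np.ndarray | ProteinStructure,
    coords_b: np.ndarray | ProteinStructure,
    params: ScoringParams | None = None,
    _b_cache: dict | None = None,
) -> ClashReport:
    """Shared-interior clash test on one lattice covering both subunits.

    Interior labels are computed per subunit as if the partner were
    absent; the report is symmetric in (A, B).  ``_b_cache`` may be a
    dict reused across calls with identical B coordinates to memoize B's
    interior mask per lattice geometry (pure optimization — results are
    identical with or without it).
    """
    if params is None:
        params = ScoringParams()
    ca = coords_a.coords if isinstance(coords_a, ProteinStructure) else np.atleast_2d(coords_a)
    cb = coords_b.coords if isinstance(coords_b, ProteinStructure) else np.atleast_2d(coords_b)
    if ca.size == 0 or cb.size == 0:
        raise ValueError("clash_check needs two non-empty atom sets")
    # quick reject: bounding boxes too far apart to share any interior point
    gap = 2 * params.protein_point_radius + 2 * params.grid_spacing
    if (ca.min(0) - cb.max(0) > gap).any() or (cb.min(0) - ca.max(0) > gap).any():
        xa = int(_interior_only(ca, params, None).sum())
        xb = int(_interior_only(cb, params, _b_cache).sum())
        return ClashReport(0, xa, xb, params.clash_theta, False)
    both = np.vstack([ca, cb])
    origin, dims = _grid_geometry(both, params)
    int_a = _interior_from_geometry(ca, origin, dims, params, None)
    int_b = _interior_from_geometry(cb, origin, dims, params, _b_cache)
    x = int((int_a & int_b).sum())
    xa = int(int_a.sum())
    xb = int(int_b.sum())
    clash = x > params.clash_theta * min(xa, xb)
    return ClashReport(x, xa, xb, params.clash_theta, clash)


def _interior_from_geometry(coords, origin, dims, params, cache) -> np.ndarray:
    if cache is not None:
        key = (tuple(np.round(origin, 9)), dims)
        hit = cache.get(key)
        if hit is not None:
            return hit
    mask = _interior_mask(_occupancy(coords, origin, dims, params))
    if cache is not None:
        cache[key] = mask
    return mask


def _interior_only(coords, params, cache) -> np.ndarray:
    origin, dims = _grid_geometry(coords, params)
    return _interior_from_geometry(coords, origin, dims, params, cache)


def label_names(mask: np.ndarray) -> list[str]:
    """Human-readable surface/interior strings for a boolean surface mask."""
    return ["surface" if m else "interior" for m in mask]
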