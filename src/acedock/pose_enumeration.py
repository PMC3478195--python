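"""Rigid-pose enumeration from anchor interaction pairs.

Given two interaction pairs (a_i, b_i') and (a_j, b_j') — atom a_i of the
mobile subunit A presumed to touch atom b_i' of the fixed subunit B, and
likewise a_j / b_j' — every compatible rigid placement of A is generated
on a discrete grid:

1. candidate positions for a_i: a lattice of pitch ``epsilon * d`` over
   the d-ball of b_i' (d = contact cutoff, 6 A);
2. candidate positions for a_j: a grid over the cap of the sphere of
   radius |a_i - a_j| about the placed a_i that lies inside the d-ball of
   b_j';
3. the remaining degree of freedom: rotations about the a_i - a_j axis in
   fixed angular steps.

Each pose is checked for steric clash on the full structures; clash-free
poses are scored with the contact energy over a selectable atom set
(fragment atoms during candidate filtering, the full structures for the
final ranking).  Enumeration order is deterministic (lexicographic grid
indices), so ties in energy resolve reproducibly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .ace_energy import AceTable, ScoringParams, ace_score
from .binding_interface import InterfaceSet, predicted_interface_from_arrays
from .core_model import ProteinStructure, RigidTransform, compose
from .fragment_candidates import FragmentPair, local_alignments, window_filter
from .surface_grid import clash_check, surface_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorPair",
    "Pose",
    "DockResult",
    "dball_grid",
    "sphere_cap_grid",
    "anchor_transform",
    "axis_rotations",
    "enumerate_poses",
    "filter_fragment_pairs",
    "dock",
]


@dataclass(frozen=True)
class AnchorPair:
    """Two interaction pairs: atoms a_i, a_j on A vs b_i', b_j' on B."""

    a_i: int
    a_j: int
    b_i: int
    b_j: int

    def __post_init__(self) -> None:
        if self.a_i == self.a_j:
            raise ValueError("the two A-side anchor atoms must be distinct")


@dataclass
class Pose:
    """One enumerated rigid placement of subunit A."""

    transform: RigidTransform
    ace: float | None            # None when the pose clashes
    clash: bool
    anchors: AnchorPair | None
    grid_index: tuple[int, ...]  # (dball idx, cap idx, rotation idx[, combo idx])


@dataclass
class DockResult:
    """Outcome of the full docking pipeline."""

    ok: bool
    reason: str = ""
    poses: list[Pose] = field(default_factory=list)   # top-N, ACE ascending
    k_fragment_pairs: int = 0
    n_segments: int = 0
    n_enumerated: int = 0
    n_clashed: int = 0
    interface: InterfaceSet | None = None

    @property
    def best(self) -> Pose | None:
        return self.poses[0] if self.poses else None


# ---------------------------------------------------------------------------
# grid primitives


def dball_grid(center: np.ndarray, d: float, step: float) -> np.ndarray:
    """Lattice of pitch ``step`` anchored at ``center``, clipped to the
    closed ball of radius ``d``; contains the center; lexicographic order
    of the (i, j, k) lattice offsets."""
    if not (0 < step <= 2 * d):
        raise ValueError("need 0 < step <= 2d")
    center = np.asarray(center, dtype=float)
    reach = int(math.floor(d / step + 1e-12))
    pts = []
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            for k in range(-reach, reach + 1):
                if (i * i + j * j + k * k) * step * step <= d * d + 1e-9:
                    pts.append(center + step * np.array([i, j, k]))
    return np.array(pts)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``u``."""
    w = np.cross(u, np.array([1.0, 0.0, 0.0]))
    if np.linalg.norm(w) < 1e-8:
        w = np.cross(u, np.array([0.0, 1.0, 0.0]))
    return w / np.linalg.norm(w)


def sphere_cap_grid(
    p: np.ndarray, r: float, c: np.ndarray, d: float, step: float
) -> np.ndarray:
    """Grid over the cap of the sphere (center p, radius r) inside the
    closed d-ball of c.

    The cap is parameterized from its pole (the sphere point nearest c)
    in rings of polar angle with arc spacing ~``step``; each ring carries
    enough azimuthal samples for ~``step`` arc spacing.  Returns an empty
    array when sphere and ball are disjoint.
    """
    if r <= 0 or step <= 0:
        raise ValueError("need positive radius and step")
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    h = float(np.linalg.norm(c - p))
    if h < 1e-12:
        if r > d + 1e-9:
            return np.empty((0, 3))
        u = np.array([0.0, 0.0, 1.0])
        phi_max = math.pi
    else:
        if abs(h - r) > d + 1e-9:
            return np.empty((0, 3))
        u = (c - p) / h
        cos_phi_max = (h * h + r * r - d * d) / (2 * r * h)
        phi_max = math.acos(min(1.0, max(-1.0, cos_phi_max)))
    e1 = _perpendicular(u)
    e2 = np.cross(u, e1)
    dphi = step / r
    n_rings = int(math.floor(phi_max / dphi + 1e-9))
    pts = []
    for k in range(n_rings + 1):
        phi = k * dphi
        if phi < 1e-12:
            pts.append(p + r * u)  # the cap pole
            continue
        ring_r = r * math.sin(phi)
        n_az = max(1, int(math.ceil(2 * math.pi * ring_r / step)))
        for m in range(n_az):
            a = 2 * math.pi * m / n_az
            pts.append(p + r * (math.cos(phi) * u
                                + math.sin(phi) * (math.cos(a) * e1 + math.sin(a) * e2)))
    return np.array(pts)


def anchor_transform(
    a_i: np.ndarray, a_j: np.ndarray, p: np.ndarray, q: np.ndarray
) -> RigidTransform:
    """The rigid transform taking a_i to p exactly and a_j to q, using the
    minimal-angle rotation of direction (a_j - a_i) onto (q - p).

    Requires |p - q| to match |a_i - a_j| to 1e-6 (guaranteed for cap
    grid points).  The antiparallel case rotates 180 degrees about a
    deterministic perpendicular axis.
    """
    a_i = np.asarray(a_i, float)
    a_j = np.asarray(a_j, float)
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    v1 = a_j - a_i
    v2 = q - p
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if abs(n1 - n2) > 1e-6:
        raise ValueError(f"anchor distance mismatch: |a_i-a_j|={n1:.6f} vs |p-q|={n2:.6f}")
    u1 = v1 / n1
    u2 = v2 / n2
    axis = np.cross(u1, u2)
    s = np.linalg.norm(axis)
    cth = float(np.dot(u1, u2))
    if s < 1e-12:
        if cth > 0:
            R = np.eye(3)
        else:
            w = _perpendicular(u1)
            R = Rotation.from_rotvec(math.pi * w).as_matrix()
    else:
        angle = math.atan2(s, cth)
        R = Rotation.from_rotvec(angle * axis / s).as_matrix()
    return RigidTransform(R, p - R @ a_i)


def axis_rotations(
    base: RigidTransform, p: np.ndarray, u: np.ndarray, step_deg: float
) -> list[RigidTransform]:
    """The 360/step rotations about the line through ``p`` with direction
    ``u``, each composed after ``base``; index 0 is ``base`` itself."""
    u = np.asarray(u, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-9:
        raise ValueError("axis direction must be a unit vector")
    n = round(360.0 / step_deg)
    if abs(n * step_deg - 360.0) > 1e-9:
        raise ValueError("step must divide 360 degrees")
    p = np.asarray(p, dtype=float)
    out = []
    for k in range(n):
        ang = math.radians(k * step_deg)
        R = Rotation.from_rotvec(ang * u).as_matrix()
        rot = RigidTransform(R, p - R @ p)
        out.append(compose(rot, base))
    return out


# ---------------------------------------------------------------------------
# pose enumeration


class _Scorer:
    """Contact-energy scorer with the fixed subunit's tree precomputed."""

    def __init__(self, coords_b: np.ndarray, types_b: np.ndarray,
                 table: AceTable, cutoff: float):
        keep = types_b >= 0
        self.coords_b = coords_b[keep]
        self.types_b = types_b[keep]
        self.table = table.T
        self.cutoff = cutoff
        self.tree = cKDTree(self.coords_b) if len(self.coords_b) else None

    def score(self, coords_a: np.ndarray, types_a: np.ndarray) -> float:
        if self.tree is None:
            return 0.0
        keep = types_a >= 0
        coords_a = coords_a[keep]
        types_a = types_a[keep]
        total = 0.0
        for i, nb in enumerate(self.tree.query_ball_point(coords_a, self.cutoff)):
            if nb:
                total += float(self.table[types_a[i], self.types_b[nb]].sum())
        return total


def enumerate_poses(
    a: ProteinStructure,
    b: ProteinStructure,
    anchors: AnchorPair,
    params: ScoringParams | None = None,
    table: AceTable | None = None,
    score_span_a: tuple[int, int] | None = None,
    score_span_b: tuple[int, int] | None = None,
    _b_clash_cache: dict | None = None,
) -> Iterator[Pose]:
    """Iterate every grid pose for one anchor combination.

    Yields a :class:`Pose` for every point of the product
    d-ball grid x sphere-cap grid x axis rotations, in that lexicographic
    order; clashing poses carry ``ace=None``.  ``score_span_*`` restrict
    scoring to inclusive atom-index spans (fragment scoring); the clash
    test always uses the full structures.  Degenerate anchors (A-side
    atoms closer than twice the grid pitch) yield nothing.
    """
    if params is None:
        params = ScoringParams()
    if table is None:
        raise ValueError("an AceTable is required to score poses")
    coords_a = a.coords
    coords_b = b.coords
    types_a = a.ace_types
    types_b = b.ace_types
    d = params.contact_cutoff
    step = params.epsilon * d
    pos_ai = coords_a[anchors.a_i]
    pos_aj = coords_a[anchors.a_j]
    r = float(np.linalg.norm(pos_ai - pos_aj))
    if r < 2 * step:
        logger.warning(
            "skipping degenerate anchors: |a_i-a_j|=%.3f A < 2*grid pitch %.3f A", r, 2 * step
        )
        return
    sel_a = slice(None) if score_span_a is None else slice(score_span_a[0], score_span_a[1] + 1)
    sel_b = slice(None) if score_span_b is None else slice(score_span_b[0], score_span_b[1] + 1)
    scorer = _Scorer(coords_b[sel_b], types_b[sel_b], table, d)
    sc_types_a = types_a[sel_a]
    b_cache = _b_clash_cache if _b_clash_cache is not None else {}

    ball = dball_grid(coords_b[anchors.b_i], d, step)
    for ib, P in enumerate(ball):
        cap = sphere_cap_grid(P, r, coords_b[anchors.b_j], d, step)
        for ic, Q in enumerate(cap):
            base = anchor_transform(pos_ai, pos_aj, P, Q)
            u = (Q - P) / np.linalg.norm(Q - P)
            for k, t in enumerate(axis_rotations(base, P, u, params.rotation_step)):
                posed = t.apply(coords_a)
                report = clash_check(posed, coords_b, params, _b_cache=b_cache)
                if report.clash:
                    yield Pose(t, None, True, anchors, (ib, ic, k))
                else:
                    energy = scorer.score(posed[sel_a], sc_types_a)
                    yield Pose(t, energy, False, anchors, (ib, ic, k))


def filter_fragment_pairs(
    a: ProteinStructure,
    b: ProteinStructure,
    pairs: Sequence[FragmentPair],
    params: ScoringParams | None = None,
    table: AceTable | None = None,
) -> list[tuple[FragmentPair, Pose]]:
    """Keep fragment pairs that admit a clash-free pose whose fragment
    contact energy is below the threshold; attach each pair's best pose.

    Anchors are the fragment endpoints paired in alignment order.  Input
    order is preserved.
    """
    if params is None:
        params = ScoringParams()
    kept: list[tuple[FragmentPair, Pose]] = []
    cache: dict = {}
    for pair in pairs:
        a0, a1, b0, b1 = pair.anchor_atoms
        try:
            anchors = AnchorPair(a0, a1, b0, b1)
        except ValueError:
            continue
        best: Pose | None = None
        for pose in enumerate_poses(
            a, b, anchors, params, table,
            score_span_a=pair.span_a, score_span_b=pair.span_b,
            _b_clash_cache=cache,
        ):
            if pose.clash:
                continue
            if best is None or pose.ace < best.ace:
                best = pose
        if best is not None and best.ace < params.fragment_ace_threshold:
            kept.append((pair, best))
    return kept


def dock(
    a: ProteinStructure,
    b: ProteinStructure,
    table: AceTable,
    params: ScoringParams | None = None,
) -> DockResult:
    """Full binding-site prediction pipeline.

    Surface labeling -> local alignment -> surface window filter ->
    fragment-pair threshold filter (k surviving pairs) -> enumeration of
    every anchor combination from the 2k fragment endpoints, scoring the
    full structures -> clash-free poses ranked by contact energy
    (ascending, ties by lexicographic grid index) -> interface residues
    of the best pose at the interface cutoff.  Deterministic throughout.
    """
    if params is None:
        params = ScoringParams()
    surf_a = surface_atoms(a, params=params)
    surf_b = surface_atoms(b, params=params)
    segments = local_alignments(a, b, table, params)
    pairs: list[FragmentPair] = []
    for seg in segments:
        pairs.extend(window_filter(seg, surf_a, surf_b, params))
    if not pairs:
        return DockResult(ok=False, reason="no fragment pair passed the alignment/surface filters",
                          n_segments=len(segments))
    survivors = filter_fragment_pairs(a, b, pairs, params, table)
    k = len(survivors)
    if k == 0:
        return DockResult(ok=False, reason="no fragment pair beat the contact-energy threshold",
                          n_segments=len(segments))

    # 2k endpoint interaction pairs; every unordered combination of two
    interaction_pairs: list[tuple[int, int]] = []
    for pair, _ in survivors:
        a0, a1, b0, b1 = pair.anchor_atoms
        for ip in ((a0, b0), (a1, b1)):
            if ip not in interaction_pairs:
                interaction_pairs.append(ip)

    clash_cache: dict = {}
    ranked: list[tuple[float, tuple[int, ...], Pose]] = []
    n_enum = 0
    n_clash = 0
    for combo_idx, ((ai, bi), (aj, bj)) in enumerate(itertools.combinations(interaction_pairs, 2)):
        if ai == aj:
            continue
        anchors = AnchorPair(ai, aj, bi, bj)
        for pose in enumerate_poses(a, b, anchors, params, table,
                                    _b_clash_cache=clash_cache):
            n_enum += 1
            if pose.clash:
                n_clash += 1
                continue
            pose.grid_index = (combo_idx,) + tuple(pose.grid_index)
            ranked.append((pose.ace, pose.grid_index, pose))
    if not ranked:
        return DockResult(ok=False, reason="every enumerated pose clashed",
                          k_fragment_pairs=k, n_segments=len(segments),
                          n_enumerated=n_enum, n_clashed=n_clash)
    ranked.sort(key=lambda item: (item[0], item[1]))
    top = [pose for _, _, pose in ranked[: params.top_n_poses]]
    best = top[0]
    posed_a = best.transform.apply(a.coords)
    interface = predicted_interface_from_arrays(
        posed_a, a.residue_index_per_atom(), b.coords, b.residue_index_per_atom(),
        cutoff=params.interface_cutoff,
    )
    return DockResult(ok=True, poses=top, k_fragment_pairs=k,
                      n_segments=len(segments), n_enumerated=n_enum,
                      n_clashed=n_clash, interface=interface)
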