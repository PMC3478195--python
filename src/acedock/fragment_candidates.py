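"""Candidate binding-site fragments via local alignment of atom sequences.

Stage 1 of the search treats each subunit as a linear sequence of typed
atoms and runs a minimizing Smith-Waterman local alignment where a match
column costs the contact energy ``T[type_a, type_b]`` (favorable pairs
are negative) and aligning an atom against a space costs the gap
penalty.  Segments are extracted best-first (most negative total first),
masking consumed rows/columns after each extraction, until the best
remaining score exceeds the cap ``x`` (0 by default).

Each emitted segment is then scanned with a sliding window of 15
alignment columns; a window qualifies when at least 10 of its atoms on
BOTH sides are surface atoms, in which case the window's atoms become a
fragment pair and its columns are removed before the scan continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ace_energy import AceTable, ScoringParams
from .core_model import ProteinStructure

__all__ = ["AlignedSegment", "FragmentPair", "local_alignments", "window_filter"]

Column = tuple[int | None, int | None]


@dataclass
class AlignedSegment:
    """One local aligned segment: columns pairing atom indices (or gaps)."""

    columns: list[Column]
    score: float
    span_a: tuple[int, int]   # inclusive atom-index span on A
    span_b: tuple[int, int]   # inclusive atom-index span on B

    def recompute_score(self, types_a: np.ndarray, types_b: np.ndarray,
                        table: AceTable, gap_penalty: float) -> float:
        total = 0.0
        for ia, ib in self.columns:
            if ia is None or ib is None:
                total += gap_penalty
            else:
                total += float(table.T[types_a[ia], types_b[ib]])
        return total


@dataclass
class FragmentPair:
    """A window of an aligned segment kept as a potential binding site."""

    span_a: tuple[int, int]   # inclusive atom-index span on A
    span_b: tuple[int, int]
    columns: list[Column]
    n_surface_a: int
    n_surface_b: int

    @property
    def anchor_atoms(self) -> tuple[int, int, int, int]:
        """(a_start, a_end, b_start, b_end) endpoint atom indices."""
        return (self.span_a[0], self.span_a[1], self.span_b[0], self.span_b[1])


def _sequence_types(s: ProteinStructure | np.ndarray) -> np.ndarray:
    types = s.ace_types if isinstance(s, ProteinStructure) else np.asarray(s, dtype=int)
    if (types < 0).any():
        raise ValueError("local alignment requires every atom to carry an ACE type")
    return types


def _dp_pass(
    types_a: np.ndarray,
    types_b: np.ndarray,
    table: np.ndarray,
    gap: float,
    masked_a: np.ndarray,
    masked_b: np.ndarray,
) -> np.ndarray:
    """One minimizing local-alignment matrix with masked rows/columns.

    H[p, q] = min(0, H[p-1, q-1] + T, H[p-1, q] + gap, H[p, q-1] + gap);
    masked positions are pinned to 0 so no path passes through them.
    O(n*m) python loop — adequate for atom sequences up to a few thousand.
    """
    n, m = len(types_a), len(types_b)
    H = np.zeros((n + 1, m + 1))
    S = table[np.ix_(types_a, types_b)]
    for p in range(1, n + 1):
        if masked_a[p - 1]:
            continue
        Hp, Hp1 = H[p], H[p - 1]
        row_s = S[p - 1]
        acc = 0.0
        for q in range(1, m + 1):
            if masked_b[q - 1]:
                acc = 0.0
                continue
            acc = min(0.0, Hp1[q - 1] + row_s[q - 1], Hp1[q] + gap, acc + gap)
            Hp[q] = acc
    return H


def _traceback(H, types_a, types_b, table, gap, p, q) -> list[Column]:
    cols: list[Column] = []
    while H[p, q] < 0:
        here = H[p, q]
        diag = H[p - 1, q - 1] + table[types_a[p - 1], types_b[q - 1]]
        if p > 0 and q > 0 and here == diag:
            cols.append((p - 1, q - 1))
            p, q = p - 1, q - 1
        elif p > 0 and here == H[p - 1, q] + gap:
            cols.append((p - 1, None))
            p -= 1
        elif q > 0 and here == H[p, q - 1] + gap:
            cols.append((None, q - 1))
            q -= 1
        else:  # pragma: no cover - defensive; the DP guarantees a predecessor
            raise AssertionError("traceback found no consistent predecessor")
    cols.reverse()
    return cols


def local_alignments(
    a: ProteinStructure | np.ndarray,
    b: ProteinStructure | np.ndarray,
    table: AceTable,
    params: ScoringParams | None = None,
) -> list[AlignedSegment]:
    """All non-overlapping local segments with score <= the cap.

    Extraction is best-first: the globally minimal segment is emitted,
    its A-rows and B-columns are masked, and the matrix is recomputed
    until the best remaining score exceeds ``params.alignment_score_cap``.
    Ties break on the lexicographically smallest (end_a, end_b) cell.
    """
    if params is None:
        params = ScoringParams()
    if params.gap_penalty <= 0:
        raise ValueError("gap penalty must be positive")
    types_a = _sequence_types(a)
    types_b = _sequence_types(b)
    T = table.T
    gap = params.gap_penalty
    cap = params.alignment_score_cap
    masked_a = np.zeros(len(types_a), dtype=bool)
    masked_b = np.zeros(len(types_b), dtype=bool)

    segments: list[AlignedSegment] = []
    while True:
        H = _dp_pass(types_a, types_b, T, gap, masked_a, masked_b)
        best = H.min()
        if best > cap or best >= 0:
            break
        # smallest (end_p, end_q) among minima
        p, q = map(int, np.argwhere(H == best)[0])
        cols = _traceback(H, types_a, types_b, T, gap, p, q)
        a_idx = [ia for ia, _ in cols if ia is not None]
        b_idx = [ib for _, ib in cols if ib is not None]
        seg = AlignedSegment(
            columns=cols,
            score=float(best),
            span_a=(min(a_idx), max(a_idx)),
            span_b=(min(b_idx), max(b_idx)),
        )
        segments.append(seg)
        masked_a[seg.span_a[0]: seg.span_a[1] + 1] = True
        masked_b[seg.span_b[0]: seg.span_b[1] + 1] = True
    return segments


def window_filter(
    segment: AlignedSegment,
    surface_a: np.ndarray,
    surface_b: np.ndarray,
    params: ScoringParams | None = None,
) -> list[FragmentPair]:
    """Surface filtering of one aligned segment with an extract-and-continue
    sliding window.

    The window unit is the alignment column (gap columns count toward the
    window length but contribute no surface atom).  A qualifying window —
    at least ``window_surface_min`` surface atoms on each side — is
    emitted as a :class:`FragmentPair` and its columns removed; the scan
    then resumes at the same position on the remaining columns.  A
    non-qualifying window advances by one column.
    """
    if params is None:
        params = ScoringParams()
    w = params.window_length
    need = params.window_surface_min
    cols = list(segment.columns)
    out: list[FragmentPair] = []
    i = 0
    while i + w <= len(cols):
        window = cols[i: i + w]
        a_idx = [ia for ia, _ in window if ia is not None]
        b_idx = [ib for _, ib in window if ib is not None]
        n_surf_a = int(sum(bool(surface_a[ia]) for ia in a_idx))
        n_surf_b = int(sum(bool(surface_b[ib]) for ib in b_idx))
        if n_surf_a >= need and n_surf_b >= need and len(a_idx) >= 2 and len(b_idx) >= 2:
            out.append(
                FragmentPair(
                    span_a=(min(a_idx), max(a_idx)),
                    span_b=(min(b_idx), max(b_idx)),
                    columns=window,
                    n_surface_a=n_surf_a,
                    n_surface_b=n_surf_b,
                )
            )
            del cols[i: i + w]
        else:
            i += 1
    return out
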