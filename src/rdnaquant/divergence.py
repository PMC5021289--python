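"""Pairwise divergence of assembled 45S units: p-distance and JC69.

Units are aligned globally (Needleman-Wunsch) under the shared cost model
(match +1, mismatch -2, gap -3 per base).  The p-distance is computed over
*overlapping* columns only — columns with a base in both sequences; gap
columns never enter the numerator or denominator.  The Jukes-Cantor
correction d = -(3/4) ln(1 - 4p/3) is defined for p < 0.75.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import encode, nw_matrix
from .formats_io import FastaRecord, FormatError, RegionAnnotation

__all__ = [
    "DivergenceResult",
    "align_units",
    "jukes_cantor",
    "p_distance_from_alignment",
    "divergence_pair",
    "pairwise_matrix",
]

_MISMATCH_COST = 2
_GAP_COST = 3


@dataclass(frozen=True)
class DivergenceResult:
    pair: tuple[str, str]
    overlapping_positions: int
    mismatches: int
    p_distance: float
    jc_distance: float


def align_units(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global alignment of two units; returns the two gapped strings.

    Tie-breaking is deterministic: at equal score prefer a substitution
    column over a gap, then a gap in ``seq_a`` over a gap in ``seq_b``.
    """
    if not seq_a or not seq_b:
        raise FormatError("cannot align empty sequences")
    a = encode(seq_a)
    b = encode(seq_b)
    H = nw_matrix(a, b, _MISMATCH_COST, _GAP_COST)
    i, j = len(seq_a), len(seq_b)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0:
            s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else -_MISMATCH_COST
            if H[i - 1, j - 1] + s == h:
                out_a.append(seq_a[i - 1])
                out_b.append(seq_b[j - 1])
                i -= 1
                j -= 1
                continue
        if j > 0 and H[i, j - 1] - _GAP_COST == h:  # gap in a
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
            continue
        out_a.append(seq_a[i - 1])
        out_b.append("-")
        i -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def jukes_cantor(p_distance: float) -> float:
    """JC69 correction, d = -(3/4) ln(1 - 4p/3); requires p in [0, 0.75)."""
    if not 0.0 <= p_distance < 0.75:
        raise FormatError(
            f"Jukes-Cantor distance undefined for p = {p_distance} "
            "(saturation at p >= 0.75)"
        )
    return -0.75 * math.log1p(-4.0 * p_distance / 3.0)


def p_distance_from_alignment(aligned_a: str, aligned_b: str) -> tuple[int, int, float]:
    """(overlapping columns, mismatches, p) over both-base columns."""
    if len(aligned_a) != len(aligned_b):
        raise FormatError("aligned sequences differ in length")
    overlap = mism = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        overlap += 1
        if x != y or x not in "ACGT":
            mism += 1
    p = mism / overlap if overlap else 0.0
    return overlap, mism, p


def divergence_pair(a: FastaRecord, b: FastaRecord) -> DivergenceResult:
    aa, bb = align_units(a.sequence, b.sequence)
    overlap, mism, p = p_distance_from_alignment(aa, bb)
    return DivergenceResult(
        pair=(a.id, b.id), overlapping_positions=overlap, mismatches=mism,
        p_distance=p, jc_distance=jukes_cantor(p),
    )


def pairwise_matrix(
    units: list[FastaRecord],
    annotation: RegionAnnotation | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs JC distances, overall and per subregion.

    Returns ``(matrix, long)`` where ``matrix`` is the symmetric JC
    distance matrix (zero diagonal) and ``long`` has one row per pair and
    region ("overall" plus each annotated subregion).  Per-region columns
    are selected by the position of the *first* sequence of the pair —
    a deterministic convention, since the two units need not agree on
    coordinates.
    """
    if len(units) < 2:
        raise FormatError("need at least two units")
    ids = [u.id for u in units]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate unit ids")
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    rows = []
    for ua, ub in itertools.combinations(units, 2):
        aa, bb = align_units(ua.sequence, ub.sequence)
        overlap, mism, p = p_distance_from_alignment(aa, bb)
        jc = jukes_cantor(p)
        mat.loc[ua.id, ub.id] = jc
        mat.loc[ub.id, ua.id] = jc
        rows.append({
            "a": ua.id, "b": ub.id, "region": "overall",
            "overlapping_positions": overlap, "mismatches": mism,
            "p_distance": p, "jc_distance": jc,
        })
        if annotation is not None:
            # map alignment columns to a-coordinates
            a_pos = np.cumsum([c != "-" for c in aa]) - 1
            is_overlap = np.array(
                [x != "-" and y != "-" for x, y in zip(aa, bb)]
            )
            is_mism = np.array([
                x != "-" and y != "-" and (x != y or x not in "ACGT")
                for x, y in zip(aa, bb)
            ])
            in_a = np.array([c != "-" for c in aa])
            for r in annotation.regions:
                sel = in_a & (a_pos >= r.start) & (a_pos < r.end)
                ov = int((is_overlap & sel).sum())
                mm = int((is_mism & sel).sum())
                pr = mm / ov if ov else 0.0
                rows.append({
                    "a": ua.id, "b": ub.id, "region": r.label,
                    "overlapping_positions": ov, "mismatches": mm,
                    "p_distance": pr,
                    "jc_distance": jukes_cantor(pr) if pr < 0.75 else math.nan,
                })
    return mat, pd.DataFrame(rows)
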