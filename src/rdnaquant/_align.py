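"""Dynamic-programming alignment kernels (internal).

Semi-global alignment of a read against the rDNA unit under the cost model
used throughout the pipeline: match +1, mismatch -2, inserted read base -3,
deleted reference base -3.  "Semi-global" means the alignment may start and
end anywhere on the reference, and read bases overhanging a reference end
are soft-clipped (unaligned, zero cost — they only reduce the aligned read
fraction).  Bases outside {A,C,G,T} (N, IUPAC ambiguity codes) never match.

The hot kernel is a plain scalar DP jitted with numba; traceback is done in
Python from the filled score matrix.  A brute-force oracle equivalent lives
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encode", "sg_matrix", "sg_traceback", "nw_matrix"]

_CODE = np.full(256, 4, np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode DNA to int8 codes: A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def sg_matrix(r, u, mismatch_cost, ins_cost, del_cost):  # pragma: no cover
    """Fill the semi-global score matrix H of shape (n+1, m+1).

    H[i][0] = H[0][j] = 0 (free start anywhere on the reference; free
    soft-clip of the read prefix at the reference start).  Optimal ends are
    taken over the last row (read fully aligned) and last column (read
    suffix clipped at the reference end).
    """
    n = r.shape[0]
    m = u.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    for i in range(1, n + 1):
        ri = r[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, m + 1):
            uj = u[j - 1]
            s = 1 if (ri == uj and ri < 4) else -mismatch_cost
            v = prev[j - 1] + s
            w = prev[j] - ins_cost
            if w > v:
                v = w
            w = row[j - 1] - del_cost
            if w > v:
                v = w
            row[j] = v
    return H


@njit(cache=True)
def sg_score(r, u, mismatch_cost, ins_cost, del_cost):  # pragma: no cover
    """Best semi-global score only (rolling rows, no traceback)."""
    n = r.shape[0]
    m = u.shape[0]
    prev = np.zeros(m + 1, np.int32)
    row = np.zeros(m + 1, np.int32)
    best = np.int32(0)
    for i in range(n):
        ri = r[i]
        row[0] = 0
        for j in range(1, m + 1):
            uj = u[j - 1]
            s = 1 if (ri == uj and ri < 4) else -mismatch_cost
            v = prev[j - 1] + s
            w = prev[j] - ins_cost
            if w > v:
                v = w
            w = row[j - 1] - del_cost
            if w > v:
                v = w
            row[j] = v
        if row[m] > best:
            best = row[m]
        prev, row = row, prev
    for j in range(m + 1):
        if prev[j] > best:
            best = prev[j]
    return best


@njit(cache=True)
def nw_matrix(a, b, mismatch_cost, gap_cost):  # pragma: no cover
    """Global (Needleman-Wunsch) score matrix, linear gap penalty."""
    n = a.shape[0]
    m = b.shape[0]
    H = np.empty((n + 1, m + 1), np.int32)
    for j in range(m + 1):
        H[0, j] = -gap_cost * j
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = H[i]
        prev = H[i - 1]
        row[0] = -gap_cost * i
        for j in range(1, m + 1):
            bj = b[j - 1]
            s = 1 if (ai == bj and ai < 4) else -mismatch_cost
            v = prev[j - 1] + s
            w = prev[j] - gap_cost
            if w > v:
                v = w
            w = row[j - 1] - gap_cost
            if w > v:
                v = w
            row[j] = v
    return H


def sg_traceback(H, r, u, end_i, end_j, mismatch_cost, ins_cost, del_cost):
    """Walk one optimal path back from an end cell.

    Returns ``(ref_start, ops)`` where ops is a list of (op, length) runs
    with op in {'S', '=', 'X', 'I', 'D'} in read order.  Predecessor
    preference at score ties is diagonal > up (I) > left (D), which keeps
    traceback deterministic.
    """
    n = len(r)
    ops: list[str] = []
    if end_i < n:  # read suffix clipped at the reference end
        ops.append("S" * (n - end_i))
    i, j = end_i, end_j
    while True:
        if i == 0:
            break
        if j == 0:
            ops.append("S" * i)  # read prefix clipped at the reference start
            i = 0
            break
        h = H[i, j]
        ri, uj = r[i - 1], u[j - 1]
        s = 1 if (ri == uj and ri < 4) else -mismatch_cost
        if H[i - 1, j - 1] + s == h:
            ops.append("=" if s == 1 else "X")
            i -= 1
            j -= 1
        elif H[i - 1, j] - ins_cost == h:
            ops.append("I")
            i -= 1
        elif H[i, j - 1] - del_cost == h:
            ops.append("D")
            j -= 1
        else:
            # start of the alignment in the reference interior (H==0 is not
            # reachable otherwise: every interior cell has a predecessor)
            break
    ref_start = j
    cols = "".join(reversed(ops))
    runs: list[tuple[str, int]] = []
    for c in cols:
        if runs and runs[-1][0] == c:
            runs[-1] = (c, runs[-1][1] + 1)
        else:
            runs.append((c, 1))
    return ref_start, runs
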