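"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain, loop-based Python with
no shared code with the package internals: these are the references the
fast implementations are checked against.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq))


def _matrix(read: str, ref: str, mm: int, ins: int, dl: int):
    n, m = len(read), len(ref)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        a = read[i - 1]
        for j in range(1, m + 1):
            b = ref[j - 1]
            s = 1 if (a == b and a in "ACGT") else -mm
            best = H[i - 1][j - 1] + s
            v = H[i - 1][j] - ins
            if v > best:
                best = v
            v = H[i][j - 1] - dl
            if v > best:
                best = v
            H[i][j] = best
    return H


def _trace(H, read, ref, ei, ej, mm, ins, dl):
    """One optimal path back from (ei, ej); diag > up > left preference."""
    n = len(read)
    cols = []
    if ei < n:
        cols.append(("S", n - ei))
    i, j = ei, ej
    while i > 0:
        if j == 0:
            cols.append(("S", i))
            break
        a, b = read[i - 1], ref[j - 1]
        s = 1 if (a == b and a in "ACGT") else -mm
        if H[i - 1][j - 1] + s == H[i][j]:
            cols.append(("=" if s == 1 else "X", 1))
            i, j = i - 1, j - 1
        elif H[i - 1][j] - ins == H[i][j]:
            cols.append(("I", 1))
            i -= 1
        else:
            cols.append(("D", 1))
            j -= 1
    return j, list(reversed(cols))


def oracle_align(read: str, ref: str, mm: int = 2, ins: int = 3, dl: int = 3):
    """Exhaustive semi-global DP over both strands.

    Returns dict with score, strand, ref_start, aligned_read_fraction and
    similarity of the tie-broken best alignment (leftmost ref_start, then
    + strand, then smallest reference end).
    """
    n = len(read)
    best_score = None
    per_strand = []
    for strand, seq in (("+", read), ("-", rc(read))):
        H = _matrix(seq, ref, mm, ins, dl)
        m = len(ref)
        score = max(max(H[n]), max(H[i][m] for i in range(n + 1)))
        per_strand.append((strand, seq, H, score))
        if best_score is None or score > best_score:
            best_score = score
    if best_score <= 0:
        return {"score": 0, "strand": "+", "ref_start": 0,
                "aligned_read_fraction": 0.0, "similarity": 0.0}
    chosen = None
    for order, (strand, seq, H, score) in enumerate(per_strand):
        if score != best_score:
            continue
        m = len(ref)
        ends = [(n, j) for j in range(m + 1) if H[n][j] == score]
        ends += [(i, m) for i in range(n) if H[i][m] == score]
        for ei, ej in ends:
            ref_start, colruns = _trace(H, seq, ref, ei, ej, mm, ins, dl)
            matches = sum(l for op, l in colruns if op == "=")
            mismatches = sum(l for op, l in colruns if op == "X")
            insb = sum(l for op, l in colruns if op == "I")
            delb = sum(l for op, l in colruns if op == "D")
            clip = sum(l for op, l in colruns if op == "S")
            ref_end = ref_start + matches + mismatches + delb
            key = (ref_start, order, ref_end)
            cand = {
                "score": score, "strand": strand, "ref_start": ref_start,
                "aligned_read_fraction": (n - clip) / n,
                "similarity": (matches / (matches + mismatches + insb + delb)
                               if matches + mismatches + insb + delb else 0.0),
            }
            if chosen is None or key < chosen[0]:
                chosen = (key, cand)
    return chosen[1]


def oracle_accept(read: str, ref: str, lf: float = 0.8, sf: float = 0.8,
                  **kw) -> bool:
    a = oracle_align(read, ref, **kw)
    return a["aligned_read_fraction"] >= lf and a["similarity"] >= sf


def oracle_nw_score(a: str, b: str, mm: int = 2, gap: int = 3) -> int:
    """Plain global alignment score (independent of the package kernels)."""
    n, m = len(a), len(b)
    prev = [-gap * j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [-gap * i] + [0] * m
        for j in range(1, m + 1):
            s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else -mm
            cur[j] = max(prev[j - 1] + s, prev[j] - gap, cur[j - 1] - gap)
        prev = cur
    return prev[m]
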