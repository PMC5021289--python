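"""Read QC, read-to-unit mapping, pileups, consensus and region coverage.

The mapping model follows the CLC-style parameterisation the pipeline is
built around: mismatch cost 2, insertion cost 3, deletion cost 3 (match
+1), and a read is accepted when at least 80% of its bases are aligned
(length fraction) and at least 80% of the aligned columns are matches
(similarity fraction).  Alignment is semi-global against a single unit:
read bases overhanging a reference end are soft-clipped for free, so
junction-spanning reads keep their in-unit piece and lose the rest.

``map_reads`` is exact in its accept/reject decisions.  In the default
``auto`` mode it combines three stages:

1. a gapless candidate search (pigeonhole seeding over 8 read parts) that
   handles near-perfect and junction-clipped reads; when the best gapless
   candidate's penalty (3*mismatches + clipped bases) is within
   ``floor(0.2*L)``, *any* optimal alignment necessarily passes both 0.8
   acceptance fractions, so the accept decision is exact;
2. a certified rejection screen: a read admitting any acceptable alignment
   has an infix (HW) edit distance to the unit of at most
   ``0.25*L + 0.75*floor(0.2*L)``; reads beyond that bound on both strands
   cannot be accepted and are dropped without a full DP;
3. the full dynamic program (``align_read``) for everything else.

``mode="exact"`` sends every read through the full DP.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._align import encode, sg_matrix, sg_score, sg_traceback
from .formats_io import (
    FastaRecord,
    FastqRecord,
    FormatError,
    RegionAnnotation,
    RdnaUnitReference,
    revcomp,
)

__all__ = [
    "QcParams",
    "QcReport",
    "trim_read",
    "apply_qc",
    "MappingParams",
    "AlignmentResult",
    "align_read",
    "accept_mapping",
    "map_reads",
    "MappingSummary",
    "extract_consensus",
    "region_coverage",
]

# Phred -> error probability lookup
_PERR = 10.0 ** (-np.arange(128) / 10.0)


@dataclass(frozen=True)
class QcParams:
    """Quality/length trimming settings (error-probability limit 0.05,
    minimum kept length 90 nt, drop reads containing N)."""

    quality_limit: float = 0.05
    min_len: int = 90
    drop_n: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.quality_limit < 1.0:
            raise FormatError("quality_limit must be in (0, 1)")
        if self.min_len < 1:
            raise FormatError("min_len must be >= 1")


@dataclass
class QcReport:
    kept: int = 0
    too_short: int = 0
    contains_n: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.too_short + self.contains_n


@dataclass(frozen=True)
class TrimResult:
    read: FastqRecord | None
    reason: str | None  # None | "too_short" | "contains_N"
    start: int
    end: int


def trim_read(read: FastqRecord, params: QcParams = QcParams()) -> TrimResult:
    """Two-sided running-sum (modified-Mott) quality trimming.

    Each base contributes ``quality_limit - 10**(-Q/10)``; the kept segment
    is the maximal-scoring contiguous stretch of these contributions
    (longest such stretch on ties, then leftmost).  After trimming the read
    is rejected if shorter than ``min_len`` or, with ``drop_n``, if it
    still contains an N.
    """
    n = len(read)
    # fast path: every base already below the error limit => nothing trims
    if n and _PERR[min(min(read.quals), 127)] < params.quality_limit:
        if n < params.min_len:
            return TrimResult(None, "too_short", 0, n)
        if params.drop_n and "N" in read.sequence:
            return TrimResult(None, "contains_N", 0, n)
        return TrimResult(read, None, 0, n)
    q = np.asarray(read.quals, dtype=np.int64)
    w = params.quality_limit - _PERR[np.clip(q, 0, 127)]
    S = np.concatenate(([0.0], np.cumsum(w)))
    amin = np.minimum.accumulate(S)
    first_idx = np.minimum.accumulate(
        np.where(S == amin, np.arange(n + 1), n + 1)
    )
    vals = S[1:] - amin[:-1]
    best = float(vals.max()) if n else 0.0
    if n == 0 or best <= 0.0:
        start = end = 0
    else:
        ends = np.flatnonzero(vals >= best - 1e-12) + 1
        starts = first_idx[ends - 1]
        lengths = ends - starts
        k = int(np.argmax(lengths))  # first occurrence on ties -> leftmost
        start, end = int(starts[k]), int(ends[k])
    if end - start < params.min_len:
        return TrimResult(None, "too_short", start, end)
    seq = read.sequence[start:end]
    if params.drop_n and "N" in seq:
        return TrimResult(None, "contains_N", start, end)
    if start == 0 and end == n:
        return TrimResult(read, None, start, end)
    return TrimResult(
        FastqRecord(id=read.id, sequence=seq, quals=read.quals[start:end]),
        None, start, end,
    )


def apply_qc(
    reads: Iterable[FastqRecord],
    params: QcParams = QcParams(),
    report: QcReport | None = None,
):
    """Generator applying :func:`trim_read`; tallies into ``report``."""
    for read in reads:
        res = trim_read(read, params)
        if res.read is None:
            if report is not None:
                if res.reason == "too_short":
                    report.too_short += 1
                else:
                    report.contains_n += 1
            continue
        if report is not None:
            report.kept += 1
        yield res.read


# ---------------------------------------------------------------------------
# Alignment


@dataclass(frozen=True)
class MappingParams:
    match_score: int = 1
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.8
    similarity_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.match_score != 1:
            raise FormatError("match score is fixed at +1 in this cost model")
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise FormatError("costs must be positive")
        for f in (self.length_fraction, self.similarity_fraction):
            if not 0.0 < f <= 1.0:
                raise FormatError("acceptance fractions must be in (0, 1]")


@dataclass(frozen=True)
class AlignmentResult:
    """Best semi-global placement of one read on the unit."""

    read_id: str
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    ops: str  # run-length string over {S,=,X,I,D}, e.g. "3S96=1X"
    aligned_read_fraction: float
    similarity: float
    score: int

    def op_runs(self) -> list[tuple[str, int]]:
        runs: list[tuple[str, int]] = []
        num = ""
        for c in self.ops:
            if c.isdigit():
                num += c
            else:
                runs.append((c, int(num)))
                num = ""
        return runs


def _runs_to_str(runs: list[tuple[str, int]]) -> str:
    return "".join(f"{ln}{op}" for op, ln in runs)


def _stats_from_runs(runs, read_len, params):
    matches = mism = ins = dels = clip = 0
    for op, ln in runs:
        if op == "=":
            matches += ln
        elif op == "X":
            mism += ln
        elif op == "I":
            ins += ln
        elif op == "D":
            dels += ln
        else:
            clip += ln
    cols = matches + mism + ins + dels
    aligned = read_len - clip
    score = (params.match_score * matches - params.mismatch_cost * mism
             - params.insertion_cost * ins - params.deletion_cost * dels)
    fraction = aligned / read_len if read_len else 0.0
    similarity = matches / cols if cols else 0.0
    ref_span = matches + mism + dels
    return score, fraction, similarity, ref_span


def _paths_from_matrix(H, senc, uenc, score, params):
    """All optimal paths (ref_start, runs) for one strand at ``score``."""
    n, m = len(senc), len(uenc)
    ends: list[tuple[int, int]] = [
        (n, int(j)) for j in np.flatnonzero(H[n, :] == score)
    ]
    ends += [
        (int(i), m) for i in np.flatnonzero(H[:n, m] == score)
    ]
    paths = []
    for end_i, end_j in ends:
        ref_start, runs = sg_traceback(
            H, senc, uenc, end_i, end_j,
            params.mismatch_cost, params.insertion_cost, params.deletion_cost,
        )
        paths.append((ref_start, runs))
    return paths


def align_read(
    read: FastqRecord | str,
    unit_seq: str,
    params: MappingParams = MappingParams(),
) -> AlignmentResult:
    """Best-scoring semi-global alignment of a read against the unit.

    Both strands are evaluated; score ties are broken by leftmost
    ``ref_start``, then the + strand, then smallest reference end.
    """
    if isinstance(read, FastqRecord):
        read_id, seq = read.id, read.sequence
    else:
        read_id, seq = "", read
    if not seq or not unit_seq:
        raise FormatError("empty read or reference")
    uenc = encode(unit_seq)
    n = len(seq)

    candidates = []  # (ref_start, strand_order, ref_end, strand, runs)
    best_score = None
    strand_results = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        H = sg_matrix(encode(s), uenc, params.mismatch_cost,
                      params.insertion_cost, params.deletion_cost)
        score = int(max(H[n, :].max(), H[:, len(unit_seq)].max()))
        strand_results.append((strand, s, H, score))
    if max(score for *_, score in strand_results) <= 0:
        # nothing aligns at a positive score: report the read as unaligned
        # (soft-clipped in full) rather than enumerating zero-score paths
        return AlignmentResult(
            read_id=read_id, ref_start=0, ref_end=0, strand="+",
            ops=f"{n}S", aligned_read_fraction=0.0, similarity=0.0, score=0,
        )
    best_score = max(score for *_, score in strand_results)
    for order, (strand, s, H, score) in enumerate(strand_results):
        if score != best_score:
            continue
        for ref_start, runs in _paths_from_matrix(H, encode(s), uenc, score, params):
            _, _, _, ref_span = _stats_from_runs(runs, n, params)
            candidates.append(
                (ref_start, order, ref_start + ref_span, strand, runs)
            )
    ref_start, _, ref_end, strand, runs = min(candidates)
    score, fraction, similarity, _ = _stats_from_runs(runs, n, params)
    return AlignmentResult(
        read_id=read_id, ref_start=ref_start, ref_end=ref_end, strand=strand,
        ops=_runs_to_str(runs), aligned_read_fraction=fraction,
        similarity=similarity, score=score,
    )


def accept_mapping(aln: AlignmentResult, params: MappingParams = MappingParams()) -> bool:
    """Acceptance rule: length fraction >= 0.8 AND similarity >= 0.8."""
    return (aln.aligned_read_fraction >= params.length_fraction
            and aln.similarity >= params.similarity_fraction)


# ---------------------------------------------------------------------------
# Fast paths (mode="auto")

# Gapless fast path: accept outright when some gapless (possibly
# end-clipped) candidate has penalty 3*mismatches + clipped_bases
# <= floor(0.2*L).  Any such candidate forces the optimal alignment's
# penalty under the 2/3/3 cost model to the same bound, hence its clip
# C* <= 0.2L (length fraction passes) and its non-match columns
# X*+I*+D* <= 0.2L/3, giving similarity >= 1 - (0.2L/3)/(0.8L) = 11/12
# (similarity passes) — so the accept decision is exact.  Candidate
# enumeration by 8-part pigeonhole (11-mer seeds) is complete for <= 4
# mismatches, which covers every candidate with penalty <= 0.2L apart
# from opportunistically skipped ones that fall through to the DP.
_FAST_MAX_MISM = 4
_FAST_MIN_LEN = 88  # 8 parts of >= 11 nt each
_N_PARTS = 8
_SEED_K = 11
_MAX_DIAGS = 64


def _screen_k(read_len: int, params: MappingParams) -> int:
    """Certified infix-edit-distance bound for possibly-acceptable reads.

    A read with an alignment passing both acceptance fractions has an
    HW (infix) edit distance to the unit of at most
    ``(1 - lf*sf)/ (1 - sf) ...`` — derived for the default 0.8/0.8 case as
    ``0.25*(L - C) + C`` maximised over clip ``C <= floor((1-lf)*L)``.
    """
    lf, sf = params.length_fraction, params.similarity_fraction
    eps = 1e-9  # guard against float error shrinking the (upper) bound
    cmax = math.floor((1.0 - lf) * read_len + eps)
    # errors within the aligned part: X+I+D <= (1-sf)/sf * aligned bases
    r = (1.0 - sf) / sf
    worst = max(r * read_len, r * (read_len - cmax) + cmax)
    return math.floor(worst + eps)


def _fast_pen_max(read_len: int) -> int:
    """Gapless fast-path penalty budget, floor(0.2 * L)."""
    return math.floor(0.2 * read_len + 1e-9)


def _score_min(read_len: int, params: MappingParams) -> int:
    """Lower bound on the score of any acceptable alignment.

    score = M - 2X - 3(I+D) >= 4M - 3*cols >= (4*sf - 3)*cols with
    cols >= ceil(lf*L); positive only for sf > 0.75.  Rounded down so the
    bound stays sound under float error.
    """
    lf, sf = params.length_fraction, params.similarity_fraction
    if sf <= 0.75:
        return 0
    cols_min = math.ceil(lf * read_len - 1e-9)
    return math.floor((4.0 * sf - 3.0) * cols_min + 1e-9)


@dataclass(frozen=True)
class _GaplessHit:
    penalty: int
    ref_start: int
    strand: str
    read_a: int  # aligned read interval [a, b)
    read_b: int
    codes: np.ndarray  # encoded oriented read
    mism: np.ndarray  # boolean over [a, b)


def _seed_index(unit: str) -> dict[str, list[int]]:
    """All occurrences of every ``_SEED_K``-mer of the unit."""
    idx: dict[str, list[int]] = {}
    for p in range(len(unit) - _SEED_K + 1):
        idx.setdefault(unit[p:p + _SEED_K], []).append(p)
    return idx


def _best_gapless(seq, rc, senc, rcenc, unit, uenc, index, pen_max):
    """Best gapless (possibly end-clipped) placement within the fast budget.

    Each of the 8 contiguous read parts is seeded by its leading 11-mer;
    a placement with <= 4 mismatches and end clipping within the budget
    leaves at least one part untouched and in-bounds, so every qualifying
    diagonal is enumerated.  Returns None when no candidate fits the
    budget or the read seeds too many diagonals to stay cheap.
    """
    L = len(seq)
    m = len(unit)
    bounds = [round(L * t / _N_PARTS) for t in range(_N_PARTS + 1)]
    best = None
    best_key = None
    for order, (strand, s, e) in enumerate((("+", seq, senc), ("-", rc, rcenc))):
        diags = set()
        for t in range(_N_PARTS):
            off = bounds[t]
            hits = index.get(s[off:off + _SEED_K])
            if hits:
                for p in hits:
                    diags.add(p - off)
                if len(diags) > _MAX_DIAGS:
                    return None
        for d in sorted(diags):
            a = max(0, -d)
            b = min(L, m - d)
            clip = L - (b - a)
            if clip > pen_max:
                continue
            useg = uenc[d + a:d + b]
            sseg = e[a:b]
            mism = (useg != sseg) | (sseg > 3) | (useg > 3)
            x = int(mism.sum())
            pen = 3 * x + clip
            if x > _FAST_MAX_MISM or pen > pen_max:
                continue
            key = (pen, d + a, order)
            if best_key is None or key < best_key:
                best_key = key
                best = _GaplessHit(
                    penalty=pen, ref_start=d + a, strand=strand,
                    read_a=a, read_b=b, codes=e, mism=mism,
                )
    return best


def _gapless_alignment_result(hit: _GaplessHit, read_id: str, L: int,
                              params: MappingParams) -> AlignmentResult:
    runs: list[tuple[str, int]] = []
    if hit.read_a:
        runs.append(("S", hit.read_a))
    run_op = None
    run_len = 0
    for is_x in hit.mism:
        op = "X" if is_x else "="
        if op == run_op:
            run_len += 1
        else:
            if run_op is not None:
                runs.append((run_op, run_len))
            run_op, run_len = op, 1
    if run_op is not None:
        runs.append((run_op, run_len))
    if L - hit.read_b:
        runs.append(("S", L - hit.read_b))
    score, fraction, similarity, ref_span = _stats_from_runs(runs, L, params)
    return AlignmentResult(
        read_id=read_id, ref_start=hit.ref_start,
        ref_end=hit.ref_start + ref_span, strand=hit.strand,
        ops=_runs_to_str(runs), aligned_read_fraction=fraction,
        similarity=similarity, score=score,
    )


# ---------------------------------------------------------------------------
# Mapping summary / pileup

_ROW_DEL = 4


@dataclass
class MappingSummary:
    """Counts of mapped reads plus the per-position pileup over the unit.

    ``counts`` rows are A, C, G, T, deletion; ``insertions`` maps the
    reference position *preceding* an insertion to a Counter of inserted
    sequences.  Coverage at a position is the sum over all five rows
    (a read deleting a base still covers it).
    """

    unit_id: str
    unit_len: int
    total_reads: int = 0
    mapped_reads: int = 0
    counts: np.ndarray = field(default_factory=lambda: np.zeros((5, 0), np.int64))
    insertions: dict[int, Counter] = field(default_factory=dict)
    alignments: list[AlignmentResult] | None = None

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def genome_proportion_percent(self) -> float:
        if self.total_reads == 0:
            raise FormatError("no reads mapped: total_reads == 0")
        return 100.0 * self.mapped_reads / self.total_reads

    def pileup_table(self):
        import pandas as pd

        return pd.DataFrame({
            "pos": np.arange(self.unit_len),
            "depth": self.coverage,
            "A": self.counts[0], "C": self.counts[1],
            "G": self.counts[2], "T": self.counts[3],
            "del": self.counts[4],
        })


def _add_gapless(counts: np.ndarray, hit: _GaplessHit) -> None:
    codes = hit.codes[hit.read_a:hit.read_b]
    pos = np.arange(hit.ref_start, hit.ref_start + codes.shape[0])
    valid = codes < 4
    np.add.at(counts, (codes[valid], pos[valid]), 1)


def _add_alignment(counts, insertions, aln: AlignmentResult, oriented: str) -> None:
    oenc = encode(oriented)
    i = 0
    j = aln.ref_start
    for op, ln in aln.op_runs():
        if op in "=X":
            codes = oenc[i:i + ln]
            pos = np.arange(j, j + ln)
            valid = codes < 4
            np.add.at(counts, (codes[valid], pos[valid]), 1)
            i += ln
            j += ln
        elif op == "D":
            counts[_ROW_DEL, j:j + ln] += 1
            j += ln
        elif op == "I":
            if j > 0:
                ins_seq = oriented[i:i + ln]
                insertions.setdefault(j - 1, Counter())[ins_seq] += 1
            i += ln
        else:  # S
            i += ln


def map_reads(
    reads: Iterable[FastqRecord],
    reference: RdnaUnitReference | FastaRecord | str,
    params: MappingParams = MappingParams(),
    mode: str = "auto",
    keep_alignments: bool = False,
) -> MappingSummary:
    """Map a (QC'd) read stream against the unit and build the pileup.

    ``total_reads`` counts every read consumed; ``mapped_reads`` counts
    those whose best alignment passes the acceptance fractions.  Each read
    contributes at most once, at its best placement.
    """
    if isinstance(reference, RdnaUnitReference):
        unit = reference.sequence
        unit_id = reference.unit.id
    elif isinstance(reference, FastaRecord):
        unit, unit_id = reference.sequence, reference.id
    else:
        unit, unit_id = reference, "unit"
    if not unit:
        raise FormatError("empty reference unit")
    if mode not in ("auto", "exact"):
        raise FormatError(f"unknown mapping mode {mode!r}")
    unit = unit.upper()
    uenc = encode(unit)
    m = len(unit)
    counts = np.zeros((5, m), np.int64)
    insertions: dict[int, Counter] = {}
    alignments: list[AlignmentResult] | None = [] if keep_alignments else None

    # the gapless fast path's proof assumes the default cost model and the
    # 0.8/0.8 acceptance fractions; any other settings go through the DP
    default_fast = (
        mode == "auto"
        and params.length_fraction == 0.8
        and params.similarity_fraction == 0.8
        and (params.mismatch_cost, params.insertion_cost,
             params.deletion_cost) == (2, 3, 3)
    )
    index = _seed_index(unit) if default_fast else None
    total = mapped = 0
    k_cache: dict[int, tuple[int, int, int]] = {}
    for read in reads:
        total += 1
        seq = read.sequence
        L = len(seq)
        if L == 0:
            continue
        lims = k_cache.get(L)
        if lims is None:
            lims = (_screen_k(L, params), _fast_pen_max(L), _score_min(L, params))
            k_cache[L] = lims
        screen_k, pen_max, s_min = lims
        rc = revcomp(seq)
        if default_fast and L >= _FAST_MIN_LEN and "N" not in seq:
            senc = encode(seq)
            rcenc = encode(rc)
            hit = _best_gapless(seq, rc, senc, rcenc, unit, uenc, index, pen_max)
            if hit is not None:
                mapped += 1
                _add_gapless(counts, hit)
                if alignments is not None:
                    alignments.append(
                        _gapless_alignment_result(hit, read.id, L, params)
                    )
                continue
        if mode == "auto":
            if (
                edlib.align(seq, unit, mode="HW", task="distance",
                            k=screen_k)["editDistance"] == -1
                and edlib.align(rc, unit, mode="HW", task="distance",
                                k=screen_k)["editDistance"] == -1
            ):
                continue  # no acceptable alignment can exist
            if s_min > 0:
                best = max(
                    int(sg_score(encode(seq), uenc, params.mismatch_cost,
                                 params.insertion_cost, params.deletion_cost)),
                    int(sg_score(encode(rc), uenc, params.mismatch_cost,
                                 params.insertion_cost, params.deletion_cost)),
                )
                if best < s_min:
                    continue  # every acceptable alignment scores >= s_min
        aln = align_read(read, unit, params)
        if accept_mapping(aln, params):
            mapped += 1
            oriented = seq if aln.strand == "+" else rc
            _add_alignment(counts, insertions, aln, oriented)
            if alignments is not None:
                alignments.append(aln)
    return MappingSummary(
        unit_id=unit_id, unit_len=m, total_reads=total, mapped_reads=mapped,
        counts=counts, insertions=insertions, alignments=alignments,
    )


# ---------------------------------------------------------------------------
# Consensus and coverage


def extract_consensus(summary: MappingSummary, unit_seq: str | None = None) -> FastaRecord:
    """Majority-rule consensus over the pileup.

    Per position: the most frequent base among A/C/G/T (alphabetical first
    on ties); positions with zero coverage emit N; a deletion observed in a
    strict majority of covering reads removes the position; an insertion
    sequence observed in a strict majority of reads covering the preceding
    position is included after it.
    """
    counts = summary.counts
    cov = summary.coverage
    winners = counts[:4].argmax(axis=0)  # first max -> alphabetical order
    letters = "ACGT"
    out: list[str] = []
    for p in range(summary.unit_len):
        c = cov[p]
        if c == 0:
            out.append("N")
        elif 2 * counts[_ROW_DEL, p] > c:
            pass  # deleted
        else:
            out.append(letters[winners[p]])
        ins = summary.insertions.get(p)
        if ins and c > 0:
            seq, cnt = ins.most_common(1)[0]
            if 2 * cnt > c:
                out.append(seq)
    return FastaRecord(id=f"{summary.unit_id}_consensus", sequence="".join(out))


def region_coverage(summary: MappingSummary, annotation: RegionAnnotation):
    """Per-region mean depth and ratio to the median region depth.

    Regions whose mean depth exceeds 10x the median of the per-region
    means are flagged as coverage anomalies (the signature of
    subregion-related sequences, e.g. dispersed ITS2 copies, outside the
    rDNA unit).
    """
    import pandas as pd

    annotation.validate_length(summary.unit_len)
    cov = summary.coverage
    rows = []
    for r in annotation.regions:
        rows.append({
            "label": r.label,
            "start": r.start,
            "end": r.end,
            "mean_depth": float(cov[r.start:r.end].mean()),
        })
    med = float(np.median([row["mean_depth"] for row in rows]))
    for row in rows:
        if med > 0:
            row["ratio_to_median"] = row["mean_depth"] / med
        else:
            row["ratio_to_median"] = math.inf if row["mean_depth"] > 0 else 0.0
        row["anomaly"] = row["ratio_to_median"] > 10.0
    return pd.DataFrame(rows)
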