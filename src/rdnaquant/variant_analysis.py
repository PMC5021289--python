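"""Pileup-based variant detection and intragenomic heterogeneity summaries.

Variants are called from the mapping pileup with deterministic post
filters — minimum coverage 100, minimum supporting-read count 10, minimum
allele frequency 10% ("high-frequency" variants, i.e. carried by on the
order of a hundred of a ~thousand-copy family).  Runs of adjacent
substitutions with concordant frequencies merge into multi-nucleotide
variants (MNV); insertions and deletions are called but pooled into one
"indel" category and, by default, excluded from the SNP tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._align import encode
from .formats_io import FormatError, RegionAnnotation
from .read_processing import MappingSummary

__all__ = [
    "VariantFilters",
    "VariantCall",
    "call_variants",
    "merge_mnv",
    "assign_regions",
    "HeterogeneityReport",
    "summarize_heterogeneity",
    "heterogeneity_ratio",
    "calls_table",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class VariantFilters:
    min_coverage: int = 100
    min_count: int = 10
    min_frequency: float = 0.10
    drop_indels_from_snp_set: bool = True

    def __post_init__(self) -> None:
        if not self.min_coverage >= self.min_count >= 1:
            raise FormatError("need min_coverage >= min_count >= 1")
        if not 0.0 < self.min_frequency <= 1.0:
            raise FormatError("min_frequency must be in (0, 1]")


@dataclass(frozen=True)
class VariantCall:
    unit_pos: int
    kind: str  # SNV | MNV | INS | DEL
    ref_allele: str
    alt_allele: str
    count: int
    coverage: int
    frequency: float
    region_label: str = ""


def call_variants(
    summary: MappingSummary,
    unit_seq: str,
    filters: VariantFilters = VariantFilters(),
) -> list[VariantCall]:
    """Emit every allele passing the coverage/count/frequency filters.

    Substitution alleles are reported per position (one call per
    qualifying allele at multi-allelic positions); deletions are reported
    at each deleted reference position; insertions are keyed to the
    preceding reference position.  Consecutive substitutions are merged
    into MNVs by :func:`merge_mnv`, not here.
    """
    unit_seq = unit_seq.upper()
    if len(unit_seq) != summary.unit_len:
        raise FormatError("unit sequence length does not match pileup")
    cov = summary.coverage
    refcode = encode(unit_seq)
    calls: list[VariantCall] = []

    eligible = cov >= filters.min_coverage
    counts = summary.counts
    # frequency is compared as count/coverage (matching the reported value)
    # so that exact-boundary alleles, e.g. 20/200 at a 10% threshold, pass
    safe_cov = np.maximum(cov, 1)
    for b in range(4):
        alt_mask = (
            eligible
            & (refcode != b)
            & (counts[b] >= filters.min_count)
            & (counts[b] / safe_cov >= filters.min_frequency)
        )
        for pos in np.flatnonzero(alt_mask):
            pos = int(pos)
            calls.append(VariantCall(
                unit_pos=pos, kind="SNV",
                ref_allele=unit_seq[pos], alt_allele=_BASES[b],
                count=int(counts[b, pos]), coverage=int(cov[pos]),
                frequency=float(counts[b, pos] / cov[pos]),
            ))
    del_mask = (
        eligible
        & (counts[4] >= filters.min_count)
        & (counts[4] / safe_cov >= filters.min_frequency)
    )
    for pos in np.flatnonzero(del_mask):
        pos = int(pos)
        calls.append(VariantCall(
            unit_pos=pos, kind="DEL",
            ref_allele=unit_seq[pos], alt_allele="",
            count=int(counts[4, pos]), coverage=int(cov[pos]),
            frequency=float(counts[4, pos] / cov[pos]),
        ))
    for pos, ins in sorted(summary.insertions.items()):
        c = int(cov[pos]) if 0 <= pos < summary.unit_len else 0
        if c < filters.min_coverage:
            continue
        for seq, cnt in sorted(ins.items()):
            if cnt >= filters.min_count and cnt / c >= filters.min_frequency:
                calls.append(VariantCall(
                    unit_pos=int(pos), kind="INS",
                    ref_allele="", alt_allele=seq,
                    count=int(cnt), coverage=c, frequency=float(cnt / c),
                ))
    calls.sort(key=lambda v: (v.unit_pos, v.kind, v.alt_allele))
    return calls


def merge_mnv(calls: list[VariantCall], freq_tol: float = 0.05) -> list[VariantCall]:
    """Merge runs of adjacent substitutions into MNVs.

    A run is >= 2 SNV calls at consecutive positions whose frequencies
    agree pairwise within ``freq_tol`` — the pileup-level surrogate for
    read-backed phasing.  Runs break at positions carrying more than one
    qualifying substitution allele.  The merged MNV takes count = min of
    the member counts and frequency = that count over the max coverage.
    """
    snvs_by_pos: dict[int, list[VariantCall]] = {}
    for c in calls:
        if c.kind == "SNV":
            snvs_by_pos.setdefault(c.unit_pos, []).append(c)
    mergeable = {p: cs[0] for p, cs in snvs_by_pos.items() if len(cs) == 1}

    merged_positions: set[int] = set()
    out: list[VariantCall] = []
    positions = sorted(mergeable)
    i = 0
    while i < len(positions):
        run = [mergeable[positions[i]]]
        j = i + 1
        while (
            j < len(positions)
            and positions[j] == positions[j - 1] + 1
            and abs(mergeable[positions[j]].frequency - run[-1].frequency)
            <= freq_tol
        ):
            run.append(mergeable[positions[j]])
            j += 1
        if len(run) >= 2:
            count = min(c.count for c in run)
            coverage = max(c.coverage for c in run)
            out.append(VariantCall(
                unit_pos=run[0].unit_pos, kind="MNV",
                ref_allele="".join(c.ref_allele for c in run),
                alt_allele="".join(c.alt_allele for c in run),
                count=count, coverage=coverage,
                frequency=count / coverage,
            ))
            merged_positions.update(c.unit_pos for c in run)
        i = j
    for c in calls:
        if c.kind == "SNV" and c.unit_pos in merged_positions and len(
            snvs_by_pos[c.unit_pos]
        ) == 1:
            continue
        out.append(c)
    out.sort(key=lambda v: (v.unit_pos, v.kind, v.alt_allele))
    return out


def assign_regions(
    calls: list[VariantCall], annotation: RegionAnnotation
) -> list[VariantCall]:
    """Label each call by the subregion containing its start position.

    MNVs spanning a boundary are labelled by their start.  Positions
    outside every annotated interval get ``unannotated`` (counted, never
    dropped).
    """
    out = []
    for c in calls:
        label = annotation.label_for(c.unit_pos)
        out.append(replace(c, region_label=label if label else "unannotated"))
    return out


@dataclass
class HeterogeneityReport:
    """Totals by variant kind and by subregion for one species/sample."""

    species: str
    totals: dict[str, int]  # keys: SNV, MNV, indel
    snp_totals: dict[str, int]  # indels excluded (when configured)
    per_region: pd.DataFrame  # region x kind counts
    positions: pd.DataFrame  # one row per call, for plotting

    @property
    def total_calls(self) -> int:
        return sum(self.totals.values())

    @property
    def total_snp_calls(self) -> int:
        return sum(self.snp_totals.values())


def summarize_heterogeneity(
    calls: list[VariantCall],
    annotation: RegionAnnotation | None = None,
    species: str = "",
    drop_indels_from_snp_set: bool = True,
) -> HeterogeneityReport:
    """Tally calls by kind (indels pooled) and by subregion."""
    if annotation is not None and calls and not calls[0].region_label:
        calls = assign_regions(calls, annotation)

    def kind_key(c: VariantCall) -> str:
        return "indel" if c.kind in ("INS", "DEL") else c.kind

    totals = {"SNV": 0, "MNV": 0, "indel": 0}
    for c in calls:
        totals[kind_key(c)] += 1
    snp_totals = dict(totals)
    if drop_indels_from_snp_set:
        snp_totals.pop("indel")

    labels = ([r.label for r in annotation.regions] if annotation else [])
    labels = labels + ["unannotated"]
    per_region = pd.DataFrame(
        0, index=labels, columns=["SNV", "MNV", "indel"], dtype=int
    )
    for c in calls:
        label = c.region_label or "unannotated"
        if label not in per_region.index:
            per_region.loc[label] = 0
        per_region.loc[label, kind_key(c)] += 1
    positions = pd.DataFrame([
        {
            "pos": c.unit_pos, "kind": c.kind, "ref": c.ref_allele,
            "alt": c.alt_allele, "count": c.count, "coverage": c.coverage,
            "frequency": c.frequency, "region": c.region_label or "unannotated",
        }
        for c in calls
    ], columns=["pos", "kind", "ref", "alt", "count", "coverage",
                "frequency", "region"])
    return HeterogeneityReport(
        species=species, totals=totals, snp_totals=snp_totals,
        per_region=per_region, positions=positions,
    )


def heterogeneity_ratio(
    report_a: HeterogeneityReport, report_b: HeterogeneityReport
) -> dict[str, float]:
    """Fold difference in high-frequency variant load, a over b.

    Returned per kind and overall (and for the indel-free SNP set); a zero
    denominator yields ``inf`` so the caller sees the degenerate case.
    """
    def ratio(a: int, b: int) -> float:
        if b == 0:
            return math.inf if a > 0 else math.nan
        return a / b

    out = {
        kind: ratio(report_a.totals[kind], report_b.totals[kind])
        for kind in report_a.totals
    }
    out["overall"] = ratio(report_a.total_calls, report_b.total_calls)
    out["snp_overall"] = ratio(report_a.total_snp_calls, report_b.total_snp_calls)
    return out


def calls_table(calls: list[VariantCall]) -> pd.DataFrame:
    """Calls as a table (position, type, alleles, count, coverage,
    frequency, region) — 1-based positions for the report."""
    return pd.DataFrame([
        {
            "position": c.unit_pos + 1,
            "type": c.kind,
            "ref": c.ref_allele,
            "alt": c.alt_allele,
            "count": c.count,
            "coverage": c.coverage,
            "frequency": round(c.frequency, 4),
            "region": c.region_label or "unannotated",
        }
        for c in calls
    ], columns=["position", "type", "ref", "alt", "count", "coverage",
                "frequency", "region"])
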