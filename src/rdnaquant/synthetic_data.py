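"""Synthetic tandem-array genomes, reads and qPCR data with known truth.

The generator emulates the study design this pipeline targets: a nuclear
genome carrying a single 45S rDNA locus, i.e. a random background plus a
head-to-tail tandem array of a known number of rDNA units.  Intragenomic
heterogeneity is injected as variants (SNV/MNV/insertion/deletion), each
present in a stated fraction of the array copies, so that downstream
pileup frequencies have an exact expected value.  Reads are unpaired,
uniformly sampled, with i.i.d. substitution errors and occasional N calls,
mirroring the unpaired Illumina archives the real analysis consumes.

Everything is deterministic under a fixed seed, down to the byte.
"""

from __future__ import annotations

import math
from collections.abc import Iterator
from dataclasses import dataclass

import numpy as np

from .formats_io import (
    CANONICAL_REGION_LABELS,
    FastaRecord,
    FastqRecord,
    FormatError,
    Region,
    RegionAnnotation,
    RdnaUnitReference,
    write_tsv,
)

__all__ = [
    "VariantSpec",
    "SyntheticTruth",
    "ReadSimParams",
    "random_unit",
    "default_regions",
    "default_reference",
    "build_rdna_genome",
    "simulate_reads",
    "reads_for_depth",
    "simulate_qpcr",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: internal chunk size for read simulation; fixed so that output is
#: byte-identical regardless of how the stream is consumed.
_CHUNK = 8192


@dataclass(frozen=True)
class VariantSpec:
    """One intragenomic variant present in a fraction of the array copies.

    ``unit_pos`` is 0-based on the reference unit.  For insertions the
    ``ref_allele`` is empty and ``alt_allele`` is inserted *after*
    ``unit_pos`` (the pileup convention of keying insertions to the
    preceding reference position).  For deletions ``ref_allele`` is the
    deleted stretch and ``alt_allele`` is empty.
    """

    unit_pos: int
    kind: str  # SNV | MNV | INS | DEL
    ref_allele: str
    alt_allele: str
    copy_fraction: float

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "MNV", "INS", "DEL"):
            raise FormatError(f"unknown variant kind {self.kind!r}")
        if self.kind == "SNV" and not (len(self.ref_allele) == len(self.alt_allele) == 1):
            raise FormatError("SNV requires single-base ref and alt alleles")
        if self.kind == "MNV" and not (
            len(self.ref_allele) == len(self.alt_allele) >= 2
        ):
            raise FormatError("MNV requires equal-length alleles of >= 2 nt")
        if self.kind == "INS" and (self.ref_allele or not self.alt_allele):
            raise FormatError("INS requires empty ref and non-empty alt")
        if self.kind == "DEL" and (self.alt_allele or not self.ref_allele):
            raise FormatError("DEL requires non-empty ref and empty alt")
        if not 0.0 < self.copy_fraction <= 1.0:
            raise FormatError("copy_fraction must be in (0, 1]")

    def n_copies(self, copies: int) -> int:
        n = round(self.copy_fraction * copies)
        if n < 1:
            raise FormatError(
                f"copy_fraction {self.copy_fraction} x {copies} copies "
                "rounds to zero carriers"
            )
        return n

    def check_against(self, unit_seq: str) -> None:
        if self.unit_pos < 0 or self.unit_pos >= len(unit_seq):
            raise FormatError(f"variant position {self.unit_pos} outside unit")
        if self.kind != "INS":
            ref = unit_seq[self.unit_pos:self.unit_pos + len(self.ref_allele)]
            if ref != self.ref_allele:
                raise FormatError(
                    f"ref allele {self.ref_allele!r} at {self.unit_pos} "
                    f"disagrees with unit sequence {ref!r}"
                )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated genome."""

    background_len: int
    unit_seq: str
    copies: int
    variants: tuple[VariantSpec, ...]
    genome_len: int
    array_len: int
    true_gp_percent: float

    def realized_fraction(self, v: VariantSpec) -> float:
        """Exact carrier fraction after integer rounding of carriers."""
        return v.n_copies(self.copies) / self.copies


@dataclass(frozen=True)
class ReadSimParams:
    """Read simulation settings.

    Defaults describe an unpaired short-read run of the kind deposited for
    the species this pipeline was designed around: 100 nt reads, 0.5%
    per-base substitution error, high quality (Q37) for correct calls,
    marginal quality (Q12) for miscalls, and a small rate of N calls
    emitted at Q2.  ``rc_fraction`` > 0 emits that fraction of reads as
    reverse complements (off by default: forward-only reads force the
    mapper, not the simulator, to prove strand handling).
    """

    n_reads: int
    seed: int
    read_len: int = 100
    error_rate: float = 0.005
    q_correct: int = 37
    q_error: int = 12
    n_rate: float = 0.001
    rc_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("error_rate", "n_rate", "rc_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise FormatError(f"{name} must be in [0, 1], got {p}")
        if self.n_reads < 0 or self.read_len < 1:
            raise FormatError("n_reads must be >= 0 and read_len >= 1")


def random_unit(length: int = 6000, seed: int = 7) -> FastaRecord:
    """A uniformly random DNA unit to stand in for a 45S rDNA repeat."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode()
    return FastaRecord(id=f"unit{length}", sequence=seq)


def default_regions(unit_id: str, unit_len: int) -> RegionAnnotation:
    """Proportional 18S-ITS1-5.8S-ITS2-26S intervals covering the unit.

    Proportions follow a typical compact plant unit (long 18S and 26S,
    short spacers and 5.8S).
    """
    weights = (0.30, 0.05, 0.027, 0.055, 0.568)  # sums to 1
    bounds = [0]
    for w in weights[:-1]:
        bounds.append(bounds[-1] + int(round(w * unit_len)))
    bounds.append(unit_len)
    regions = [
        Region(label, bounds[i], bounds[i + 1])
        for i, label in enumerate(CANONICAL_REGION_LABELS)
    ]
    return RegionAnnotation(unit_id=unit_id, regions=regions)


def default_reference(length: int = 6000, seed: int = 7) -> RdnaUnitReference:
    unit = random_unit(length, seed)
    return RdnaUnitReference(unit=unit, regions=default_regions(unit.id, length))


def _apply_variants(unit_seq: str, variants: list[VariantSpec]) -> str:
    """Apply variants (descending position, so coordinates stay valid)."""
    s = unit_seq
    for v in sorted(variants, key=lambda v: v.unit_pos, reverse=True):
        if v.kind == "INS":
            p = v.unit_pos + 1
            s = s[:p] + v.alt_allele + s[p:]
        else:
            p = v.unit_pos
            s = s[:p] + v.alt_allele + s[p + len(v.ref_allele):]
    return s


def build_rdna_genome(
    background_len: int,
    unit_seq: str,
    copies: int,
    variants: list[VariantSpec] | None = None,
    seed: int = 0,
) -> tuple[FastaRecord, SyntheticTruth]:
    """Assemble background + tandem array and return it with its truth.

    Each variant is applied to exactly ``round(copy_fraction x copies)``
    array copies; carriers are the first so-many copies of an independent
    seed-shuffled copy order per variant, so realized fractions are exact
    and reproducible.
    """
    variants = list(variants or [])
    if copies < 0:
        raise FormatError("copies must be >= 0")
    for v in variants:
        v.check_against(unit_seq)
    ivals = sorted(
        (v.unit_pos, v.unit_pos + max(len(v.ref_allele), 1)) for v in variants
    )
    for a, b in zip(ivals, ivals[1:]):
        if b[0] < a[1]:
            raise FormatError("overlapping variants are not supported")

    rng = np.random.default_rng(seed)
    background = rng.choice(_BASES, size=background_len).tobytes().decode()

    carriers: list[set[int]] = []
    for v in variants:
        order = rng.permutation(copies)
        carriers.append(set(order[: v.n_copies(copies)].tolist()))

    copy_seqs = []
    for c in range(copies):
        mine = [v for v, who in zip(variants, carriers) if c in who]
        copy_seqs.append(_apply_variants(unit_seq, mine) if mine else unit_seq)

    array = "".join(copy_seqs)
    genome_seq = background + array
    genome_len = len(genome_seq)
    gp = 100.0 * len(array) / genome_len if genome_len else 0.0
    truth = SyntheticTruth(
        background_len=background_len,
        unit_seq=unit_seq,
        copies=copies,
        variants=tuple(variants),
        genome_len=genome_len,
        array_len=len(array),
        true_gp_percent=gp,
    )
    return FastaRecord(id="synthetic_genome", sequence=genome_seq), truth


def reads_for_depth(genome_len: int, depth: float, read_len: int = 100) -> int:
    """Number of reads giving a target mean genome-wide depth."""
    return int(round(depth * genome_len / read_len))


def simulate_reads(genome: FastaRecord, params: ReadSimParams) -> Iterator[FastqRecord]:
    """Stream uniformly sampled error-bearing reads from a genome.

    Start positions are uniform over ``[0, L - read_len]``; substitution
    errors are i.i.d. at ``error_rate`` (always changing the base); each
    base is independently replaced by N (quality 2) at ``n_rate``.
    Deterministic under a fixed seed.
    """
    L = len(genome.sequence)
    if params.read_len > L:
        raise FormatError(f"read_len {params.read_len} exceeds genome length {L}")
    rng = np.random.default_rng(params.seed)
    g = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    code = np.full(256, 4, np.uint8)
    for i, b in enumerate(_BASES):
        code[b] = i
    gcode = code[g]

    rl = params.read_len
    emitted = 0
    comp = np.array([3, 2, 1, 0, 4], np.uint8)  # A<->T, C<->G, N->N
    base_with_n = np.frombuffer(b"ACGTN", dtype=np.uint8)
    while emitted < params.n_reads:
        n = min(_CHUNK, params.n_reads - emitted)
        starts = rng.integers(0, L - rl + 1, size=n)
        mat = gcode[starts[:, None] + np.arange(rl)[None, :]]
        err = rng.random((n, rl)) < params.error_rate
        # substitution errors always change the base (uniform over the 3 others)
        shift = rng.integers(1, 4, size=(n, rl), dtype=np.uint8)
        mat = np.where(err & (mat < 4), (mat + shift) % 4, mat)
        nmask = rng.random((n, rl)) < params.n_rate
        mat = np.where(nmask, np.uint8(4), mat)
        quals = np.where(err, np.uint8(params.q_error), np.uint8(params.q_correct))
        quals = np.where(nmask, np.uint8(2), quals)
        if params.rc_fraction > 0:
            flip = rng.random(n) < params.rc_fraction
        else:
            flip = np.zeros(n, dtype=bool)
        for i in range(n):
            row, q = mat[i], quals[i]
            if flip[i]:
                row = comp[row[::-1]]
                q = q[::-1]
            yield FastqRecord(
                id=f"r{emitted + i:08d}",
                sequence=base_with_n[row].tobytes().decode(),
                quals=tuple(q.tolist()),
            )
        emitted += n


def simulate_qpcr(
    copies_per_1c: float,
    genome_mb: float,
    ref_copies_per_1c: float,
    ref_genome_mb: float,
    ct_ref: float,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> float:
    """Threshold cycle consistent with a target copy number.

    Inverts the relative-quantification estimator (perfect doubling per
    cycle): with ``noise_sd=0`` the copy-number module recovers
    ``copies_per_1c`` exactly from the returned ct.  Gaussian ct noise is
    added when ``noise_sd > 0``.
    """
    for name, v in (
        ("copies_per_1c", copies_per_1c),
        ("genome_mb", genome_mb),
        ("ref_copies_per_1c", ref_copies_per_1c),
        ("ref_genome_mb", ref_genome_mb),
        ("ct_ref", ct_ref),
    ):
        if not v > 0:
            raise FormatError(f"{name} must be positive")
    ct = ct_ref - math.log2(
        copies_per_1c * ref_genome_mb / (ref_copies_per_1c * genome_mb)
    )
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        ct += float(rng.normal(0.0, noise_sd))
    return ct


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    """Truth record as TSV: one summary line + one line per variant."""
    rows = [{
        "record": "genome",
        "unit_pos": "",
        "kind": "",
        "ref_allele": "",
        "alt_allele": "",
        "copy_fraction": "",
        "background_len": truth.background_len,
        "copies": truth.copies,
        "genome_len": truth.genome_len,
        "array_len": truth.array_len,
        "true_gp_percent": truth.true_gp_percent,
    }]
    for v in truth.variants:
        rows.append({
            "record": "variant",
            "unit_pos": v.unit_pos,
            "kind": v.kind,
            "ref_allele": v.ref_allele,
            "alt_allele": v.alt_allele,
            "copy_fraction": v.copy_fraction,
            "background_len": "",
            "copies": "",
            "genome_len": "",
            "array_len": "",
            "true_gp_percent": "",
        })
    write_tsv(rows, path)
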