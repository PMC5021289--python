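"""Readers/writers for the standard formats the pipeline touches.

All coordinates in this package are 0-based, half-open.  Conversion to
1-based happens only when a human-facing report is rendered.

FASTA/FASTQ parsing and writing are delegated to Biopython's ``SeqIO``;
this module wraps them in small domain records and adds the validation
the rest of the pipeline relies on (uppercasing, U->T normalisation,
per-record sanity checks).  FASTQ is Phred+33 only — the modern Illumina
dialect used by the sequence read archives this pipeline targets.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FastaRecord",
    "FastqRecord",
    "Region",
    "RegionAnnotation",
    "RdnaUnitReference",
    "GenomeProfile",
    "FormatError",
    "PG_TO_MB",
    "CANONICAL_REGION_LABELS",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_regions",
    "write_regions",
    "read_tsv",
    "write_tsv",
]

#: Standard conversion between picograms of DNA and megabases (1 pg = 978 Mb).
PG_TO_MB = 978.0

#: Subregions of one 45S rDNA unit, in transcription order.
CANONICAL_REGION_LABELS = ("18S", "ITS1", "5.8S", "ITS2", "26S")

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


class FormatError(ValueError):
    """Raised for malformed input files or invalid domain records."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class FastaRecord:
    """A named DNA sequence (reference unit, genome, consensus...)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise FormatError(f"record {self.id!r}: whitespace in sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FastqRecord:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    sequence: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.quals)} quality values"
            )
        if self.quals and min(self.quals) < 0:
            raise FormatError(f"record {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)


class Region(NamedTuple):
    label: str
    start: int
    end: int


@dataclass
class RegionAnnotation:
    """Ordered 18S/ITS1/5.8S/ITS2/26S subregion intervals on one unit.

    Intervals are 0-based half-open, non-overlapping and sorted; labels are
    unique.  The annotation does not have to cover the whole unit (IGS-less
    units usually are fully covered, but gaps are tolerated and reported as
    ``unannotated`` downstream).
    """

    unit_id: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        regs = [Region(str(l), int(s), int(e)) for l, s, e in self.regions]
        regs.sort(key=lambda r: r.start)
        labels = [r.label for r in regs]
        if len(set(labels)) != len(labels):
            raise FormatError(f"duplicate region labels: {labels}")
        for r in regs:
            if r.label not in CANONICAL_REGION_LABELS:
                raise FormatError(
                    f"region label {r.label!r} not one of "
                    f"{CANONICAL_REGION_LABELS}"
                )
            if r.start < 0 or r.end <= r.start:
                raise FormatError(f"invalid interval for region {r!r}")
        for a, b in zip(regs, regs[1:]):
            if b.start < a.end:
                raise FormatError(f"overlapping regions: {a!r} and {b!r}")
        self.regions = regs

    def validate_length(self, unit_len: int) -> None:
        for r in self.regions:
            if r.end > unit_len:
                raise FormatError(
                    f"region {r!r} extends past unit end ({unit_len} bp)"
                )

    def label_for(self, pos: int) -> str | None:
        for r in self.regions:
            if r.start <= pos < r.end:
                return r.label
        return None

    @property
    def span(self) -> int:
        return sum(r.end - r.start for r in self.regions)


@dataclass(frozen=True)
class RdnaUnitReference:
    """The 45S unit reference: sequence plus subregion annotation.

    This is the coordinate frame shared by mapping, pileups, variant calls
    and coverage summaries.
    """

    unit: FastaRecord
    regions: RegionAnnotation | None = None

    def __post_init__(self) -> None:
        if self.regions is not None:
            self.regions.validate_length(len(self.unit))

    @property
    def sequence(self) -> str:
        return self.unit.sequence

    def __len__(self) -> int:
        return len(self.unit)


@dataclass(frozen=True)
class GenomeProfile:
    """Haploid (1C) genome size of a species, in pg and/or Mb."""

    species: str
    c1_mb: float
    c1_pg: float | None = None

    def __post_init__(self) -> None:
        if not self.c1_mb > 0:
            raise FormatError(f"{self.species}: 1C size must be positive")
        if self.c1_pg is not None:
            expected = self.c1_pg * PG_TO_MB
            if not math.isclose(self.c1_mb, expected, rel_tol=0.01):
                raise FormatError(
                    f"{self.species}: 1C of {self.c1_mb} Mb inconsistent with "
                    f"{self.c1_pg} pg (= {expected:.1f} Mb)"
                )

    @classmethod
    def from_pg(cls, species: str, c1_pg: float) -> "GenomeProfile":
        return cls(species=species, c1_mb=c1_pg * PG_TO_MB, c1_pg=c1_pg)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a (multi-)FASTA file into normalised records.

    Sequences are uppercased and U is replaced by T.  IUPAC ambiguity codes
    are kept (alignment treats them as mismatches).
    """
    records: list[FastaRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            seq = _normalise(str(rec.seq))
            if not seq:
                raise FormatError(f"{path}: record {i} ({rec.id!r}) is empty")
            records.append(FastaRecord(id=rec.id, sequence=seq))
    except ValueError as exc:  # Biopython parse failure
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path,
                width: int = 80) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream a Phred+33 FASTQ file (constant memory in number of reads)."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield FastqRecord(
                id=rec.id,
                sequence=_normalise(str(rec.seq)),
                quals=tuple(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")


# ---------------------------------------------------------------------------
# Region annotation (BED-like TSV: unit_id, label, start, end)


def read_regions(path: str | Path) -> RegionAnnotation:
    """Read a BED-like subregion table (unit_id, label, start, end).

    Coordinates are 0-based half-open.  Input order is irrelevant; regions
    come back sorted.  Overlaps and malformed intervals raise
    :class:`FormatError` naming the offending region.
    """
    rows: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{ln}: expected 4 tab-separated fields, "
                    f"got {len(parts)}"
                )
            unit_id, label, start, end = parts
            try:
                rows.append((unit_id, label, int(start), int(end)))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
    if not rows:
        raise FormatError(f"{path}: no regions found")
    unit_ids = {r[0] for r in rows}
    if len(unit_ids) != 1:
        raise FormatError(f"{path}: multiple unit ids {sorted(unit_ids)}")
    return RegionAnnotation(
        unit_id=rows[0][0],
        regions=[Region(label, s, e) for _, label, s, e in rows],
    )


def write_regions(annotation: RegionAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in annotation.regions:
            fh.write(f"{annotation.unit_id}\t{r.label}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# Tabular reports


def write_tsv(table, path: str | Path) -> None:
    """Write a rectangular table as UTF-8 TSV with one header line.

    ``table`` may be a pandas DataFrame or a list of dicts with identical
    keys (ragged rows raise).  Floats are rendered with up to 6 significant
    digits; column order is preserved (deterministic).
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        rows = list(table)
        if rows:
            keys = list(rows[0].keys())
            for i, row in enumerate(rows):
                if list(row.keys()) != keys:
                    raise FormatError(f"ragged row {i}: {list(row.keys())} != {keys}")
            df = pd.DataFrame(rows, columns=keys)
        else:
            raise FormatError("cannot infer header from an empty row list; "
                              "pass a DataFrame with columns instead")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g",
              encoding="utf-8")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
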