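"""rDNA copy-number estimators: genome proportion (NGS) and qPCR (ΔCt).

The NGS path is a three-step chain: (i) genome proportion GP% =
100 x mapped/total reads against the 26S (or whole-unit) reference;
(ii) GP in Mb = GP x 1C genome size; (iii) copies = GP(Mb) / reference
length (Mb), with ~0.003 Mb for a 26S gene and 0.0112 Mb for a whole
11.2 kb unit.  Full precision is carried between the steps; rounding (GP
and GP-Mb to 2 decimals, copies to the nearest 50) happens only at report
time — the printed-table values are reproducible only that way.

The qPCR path is relative quantification against a calibrator species of
known copy number (classically *Arabidopsis thaliana*, 570 copies/1C,
1C = 157 Mb), assuming perfect doubling per cycle:

    copies = 2**(ct_ref - ct_sample) * ref_copies * (1C_sample / 1C_ref)

The default exponent is ``ct_ref - ct_sample`` (more copies amplify
earlier, i.e. lower ct); ``printed_exponent=True`` flips the sign for
compatibility with sources quoting the opposite convention.
"""

from __future__ import annotations

import importlib.resources
import math
import statistics
from dataclasses import dataclass

import pandas as pd

from .formats_io import FormatError
from .read_processing import MappingSummary

__all__ = [
    "REF_26S_MB",
    "WHOLE_UNIT_MB",
    "ARABIDOPSIS_REFERENCE",
    "genome_proportion",
    "gp_megabases",
    "copies_from_gp",
    "round_copies",
    "CopyEstimate",
    "estimate_from_mapping",
    "QpcrSample",
    "QpcrEstimate",
    "qpcr_copies",
    "CopySummary",
    "copy_summary",
    "load_published_ngs_table",
    "load_published_qpcr_table",
]

#: Approximate length of a plant 26S rRNA gene, in Mb.
REF_26S_MB = 0.003
#: Length of a whole 11.2 kb 45S unit, in Mb.
WHOLE_UNIT_MB = 0.0112


def genome_proportion(mapped_reads: int, total_reads: int) -> float:
    """GP% = 100 x mapped/total, at full precision."""
    if total_reads <= 0:
        raise FormatError("total_reads must be positive")
    if not 0 <= mapped_reads <= total_reads:
        raise FormatError("mapped_reads must be in [0, total_reads]")
    return 100.0 * mapped_reads / total_reads


def gp_megabases(gp_percent: float, genome_mb: float) -> float:
    """GP expressed in Mb of the haploid genome."""
    if gp_percent < 0 or genome_mb < 0:
        raise FormatError("gp_percent and genome_mb must be >= 0")
    return gp_percent / 100.0 * genome_mb


def copies_from_gp(gp_mb: float, ref_len_mb: float = REF_26S_MB) -> float:
    """Copy number = GP(Mb) / reference element length (Mb), unrounded."""
    if ref_len_mb <= 0:
        raise FormatError("ref_len_mb must be positive")
    if gp_mb < 0:
        raise FormatError("gp_mb must be >= 0")
    return gp_mb / ref_len_mb


def round_copies(copies: float, step: int = 50) -> int:
    """Display rounding of a copy estimate to the nearest ``step``."""
    return int(round(copies / step)) * step


@dataclass(frozen=True)
class CopyEstimate:
    """One species' copy-number estimate from the GP chain."""

    species: str
    gp_percent: float
    gp_mb: float
    ref_len_mb: float
    copies: float
    genome_mb: float | None = None
    total_reads: int | None = None
    mapped_reads: int | None = None

    @property
    def copies_display(self) -> int:
        return round_copies(self.copies)


def estimate_from_mapping(
    summary: MappingSummary,
    genome_mb: float,
    ref_len_mb: float = REF_26S_MB,
    species: str = "",
) -> CopyEstimate:
    """Run the full GP chain on a mapping summary."""
    gp = genome_proportion(summary.mapped_reads, summary.total_reads)
    gpmb = gp_megabases(gp, genome_mb)
    return CopyEstimate(
        species=species, gp_percent=gp, gp_mb=gpmb, ref_len_mb=ref_len_mb,
        copies=copies_from_gp(gpmb, ref_len_mb), genome_mb=genome_mb,
        total_reads=summary.total_reads, mapped_reads=summary.mapped_reads,
    )


@dataclass(frozen=True)
class QpcrSample:
    """Mean threshold cycle of >= 3 technical replicates for one species."""

    species: str
    ct: float
    c1_mb: float
    ct_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise FormatError(f"{self.species}: ct must be positive")
        if not self.c1_mb > 0:
            raise FormatError(f"{self.species}: missing/invalid 1C genome size")


#: Conventional calibrator: *A. thaliana*, 570 rDNA copies per 1C, 157 Mb.
ARABIDOPSIS_REFERENCE = QpcrSample(species="Arabidopsis thaliana",
                                   ct=14.0, c1_mb=157.0)


@dataclass(frozen=True)
class QpcrEstimate:
    species: str
    copies: float
    sd: float


def qpcr_copies(
    sample: QpcrSample,
    reference: QpcrSample = ARABIDOPSIS_REFERENCE,
    ref_copies: float = 570.0,
    printed_exponent: bool = False,
) -> QpcrEstimate:
    """Relative-quantification copy number per 1C.

    ``printed_exponent=True`` uses 2**(ct_sample - ct_reference) instead of
    the default physically consistent 2**(ct_reference - ct_sample).
    The reported SD propagates the replicate ct SDs of both samples
    through the exponential (sd = copies * ln2 * sqrt(sd_s^2 + sd_r^2)).
    """
    delta = (sample.ct - reference.ct) if printed_exponent else (reference.ct - sample.ct)
    copies = 2.0 ** delta * ref_copies * (sample.c1_mb / reference.c1_mb)
    sd = copies * math.log(2.0) * math.hypot(sample.ct_sd, reference.ct_sd)
    return QpcrEstimate(species=sample.species, copies=copies, sd=sd)


@dataclass(frozen=True)
class CopySummary:
    n: int
    median: float
    mean: float
    sd: float
    min: float
    max: float
    sd_defined: bool


def copy_summary(values) -> CopySummary:
    """Median / mean / sample SD / range of a panel of copy numbers.

    The median is the middle order statistic for odd n (mean of the two
    central values for even n); the SD uses n-1 degrees of freedom and is
    reported as 0 (flagged undefined) for a single value.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise FormatError("copy_summary requires at least one value")
    sd_defined = len(vals) > 1
    return CopySummary(
        n=len(vals),
        median=float(statistics.median(vals)),
        mean=float(statistics.fmean(vals)),
        sd=float(statistics.stdev(vals)) if sd_defined else 0.0,
        min=min(vals),
        max=max(vals),
        sd_defined=sd_defined,
    )


def _data_path(name: str):
    return importlib.resources.files("rdnaquant") / "data" / name


def load_published_ngs_table() -> pd.DataFrame:
    """Published NGS copy-number table (genome size, read counts, GP)."""
    with importlib.resources.as_file(_data_path("ngs_copy_table.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_published_qpcr_table() -> pd.DataFrame:
    """Published qPCR copy-number panel for 25 liverwort/moss species."""
    with importlib.resources.as_file(_data_path("qpcr_copy_number.tsv")) as p:
        return pd.read_csv(p, sep="\t")
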