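"""End-to-end orchestration: simulate -> qc -> map -> copynum -> variants.

A :class:`PipelineConfig` gathers every tunable with defaults equal to the
workflow's canonical parameter set (trim limit 0.05, min length 90,
mismatch/insertion/deletion costs 2/3/3, acceptance fractions 0.8/0.8,
variant filters 100/10/10%, 26S reference length 0.003 Mb).  Each stage
writes TSV outputs plus a manifest entry recording the config hash and
input checksums, so a rerun with an unchanged config resumes from the
existing outputs and a changed config recomputes exactly the stages it
invalidates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic_data
from .copy_number import CopyEstimate, estimate_from_mapping, round_copies
from .formats_io import (
    FormatError,
    RdnaUnitReference,
    read_fasta,
    read_fastq,
    read_regions,
    write_fasta,
    write_fastq,
    write_regions,
    write_tsv,
)
from .read_processing import (
    MappingParams,
    MappingSummary,
    QcParams,
    QcReport,
    apply_qc,
    extract_consensus,
    map_reads,
    region_coverage,
)
from .variant_analysis import (
    VariantFilters,
    assign_regions,
    call_variants,
    calls_table,
    merge_mnv,
    summarize_heterogeneity,
)

__all__ = ["PipelineConfig", "run_pipeline", "render_table2"]

log = logging.getLogger("rdnaquant")


@dataclass
class PipelineConfig:
    """Flat configuration for the end-to-end run.

    When ``reads`` is None a synthetic dataset is generated first (the
    ``sim_*`` block defines it and ``seed`` drives all randomness).
    """

    outdir: str = "rdnaquant_run"
    seed: int = 1

    # inputs (all optional for a synthetic run)
    reads: str | None = None
    reference: str | None = None
    regions: str | None = None
    genome_mb: float | None = None
    species: str = "synthetic"

    qc: QcParams = field(default_factory=QcParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    filters: VariantFilters = field(default_factory=VariantFilters)
    ref_len_mb: float = 0.003
    ref_len_from_unit: bool = False
    mapping_mode: str = "auto"

    # display conventions
    gp_decimals: int = 2
    copies_step: int = 50

    # synthetic-data block
    sim_unit_len: int = 6000
    sim_copies: int = 10
    sim_background_len: int = 100_000
    sim_depth: float = 50.0
    sim_read_len: int = 100
    sim_error_rate: float = 0.005
    sim_n_rate: float = 0.001
    sim_rc_fraction: float = 0.0

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key=value config file; CLI overrides win over the file."""
        values: dict = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{ln}: expected key=value")
                key, val = (x.strip() for x in line.split("=", 1))
                values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls._from_flat(values)

    @classmethod
    def _from_flat(cls, values: dict) -> "PipelineConfig":
        nested = {
            "qc": (QcParams, {"quality_limit": float, "min_len": int,
                              "drop_n": _as_bool}),
            "mapping": (MappingParams, {
                "match_score": int, "mismatch_cost": int,
                "insertion_cost": int, "deletion_cost": int,
                "length_fraction": float, "similarity_fraction": float}),
            "filters": (VariantFilters, {
                "min_coverage": int, "min_count": int,
                "min_frequency": float, "drop_indels_from_snp_set": _as_bool}),
        }
        kwargs: dict = {}
        grouped: dict[str, dict] = {k: {} for k in nested}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in values.items():
            matched = False
            for group, (_, types) in nested.items():
                if key in types:
                    grouped[group][key] = types[key](val)
                    matched = True
                    break
            if matched:
                continue
            if key not in fields:
                raise FormatError(f"unknown config key {key!r}")
            f = fields[key]
            if isinstance(val, str):
                val = _coerce(val, f)
            kwargs[key] = val
        for group, (klass, _) in nested.items():
            if grouped[group]:
                kwargs[group] = klass(**grouped[group])
        return cls(**kwargs)


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).lower() in ("1", "true", "yes", "on")


def _coerce(val: str, f: dataclasses.Field):
    t = str(f.type)
    if val.lower() in ("none", ""):
        return None
    if "bool" in t:
        return _as_bool(val)
    if "int" in t:
        return int(val)
    if "float" in t:
        return float(val)
    return val


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}}
        if path.exists():
            try:
                self.data = json.loads(path.read_text())
            except json.JSONDecodeError:
                pass

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        return (
            rec is not None
            and rec.get("key") == key
            and all(Path(o).exists() for o in rec.get("outputs", []))
            and [str(o) for o in outputs] == rec.get("outputs")
        )

    def record(self, stage: str, key: str, outputs: list[Path],
               inputs: dict[str, str], params: dict) -> None:
        self.data["stages"][stage] = {
            "key": key,
            "outputs": [str(o) for o in outputs],
            "input_checksums": inputs,
            "params": params,
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the report directory.

    Deterministic under a fixed seed.  Any stage error aborts with the
    stage name and the offending input's checksum in the message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    ckey = config.config_hash()
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("map", _stage_map),
        ("copynum", _stage_copynum),
        ("variants", _stage_variants),
        ("report", _stage_report),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            skipped = fn(config, out, manifest, ckey, state)
        except Exception as exc:
            checksums = manifest.data["stages"].get(name, {}).get(
                "input_checksums", {})
            raise RuntimeError(
                f"stage {name!r} failed ({checksums}): {exc}"
            ) from exc
        log.info("stage %-8s %s in %.2fs", name,
                 "resumed" if skipped else "done", time.perf_counter() - t0)
    return out


def _load_reference(config: PipelineConfig, out: Path) -> RdnaUnitReference:
    if config.reference:
        unit = read_fasta(config.reference)[0]
    else:
        unit = read_fasta(out / "unit.fasta")[0]
    regions = None
    regions_path = config.regions or (out / "regions.tsv")
    if Path(regions_path).exists():
        regions = read_regions(regions_path)
    return RdnaUnitReference(unit=unit, regions=regions)


def _stage_simulate(config, out, manifest, ckey, state) -> bool:
    if config.reads is not None:
        state["reads_path"] = Path(config.reads)
        return True
    outputs = [out / n for n in
               ("unit.fasta", "regions.tsv", "genome.fasta",
                "reads.fastq", "truth.tsv")]
    state["reads_path"] = out / "reads.fastq"
    if manifest.fresh("simulate", ckey, outputs):
        return True
    ref = (RdnaUnitReference(unit=read_fasta(config.reference)[0])
           if config.reference
           else synthetic_data.default_reference(config.sim_unit_len,
                                                 seed=config.seed + 1))
    genome, truth = synthetic_data.build_rdna_genome(
        config.sim_background_len, ref.sequence, config.sim_copies,
        seed=config.seed + 2,
    )
    n_reads = synthetic_data.reads_for_depth(
        truth.genome_len, config.sim_depth, config.sim_read_len)
    params = synthetic_data.ReadSimParams(
        n_reads=n_reads, seed=config.seed + 3, read_len=config.sim_read_len,
        error_rate=config.sim_error_rate, n_rate=config.sim_n_rate,
        rc_fraction=config.sim_rc_fraction,
    )
    write_fasta([ref.unit], out / "unit.fasta")
    if ref.regions is not None:
        write_regions(ref.regions, out / "regions.tsv")
    write_fasta([genome], out / "genome.fasta")
    write_fastq(synthetic_data.simulate_reads(genome, params),
                out / "reads.fastq")
    synthetic_data.write_truth_tsv(truth, out / "truth.tsv")
    state["truth"] = truth
    manifest.record("simulate", ckey, outputs, {},
                    {"n_reads": n_reads, "seed": config.seed})
    return False


def _stage_qc(config, out, manifest, ckey, state) -> bool:
    reads_path = state["reads_path"]
    outputs = [out / "reads.qc.fastq", out / "qc_report.tsv"]
    state["qc_reads_path"] = outputs[0]
    inputs = {"reads": _sha256(reads_path)}
    key = ckey + inputs["reads"]
    if manifest.fresh("qc", key, outputs):
        return True
    report = QcReport()
    write_fastq(
        apply_qc(read_fastq(reads_path), config.qc, report), outputs[0])
    write_tsv([{
        "kept": report.kept,
        "too_short": report.too_short,
        "contains_N": report.contains_n,
        "total": report.total,
    }], outputs[1])
    manifest.record("qc", key, outputs, inputs,
                    dataclasses.asdict(config.qc))
    return False


def _stage_map(config, out, manifest, ckey, state) -> bool:
    reads_path = state["qc_reads_path"]
    outputs = [out / n for n in
               ("pileup.tsv", "mapping_summary.tsv", "consensus.fasta",
                "region_coverage.tsv")]
    inputs = {"reads": _sha256(reads_path)}
    key = ckey + inputs["reads"]
    reference = _load_reference(config, out)
    state["reference"] = reference
    if manifest.fresh("map", key, outputs):
        state["summary"] = _reload_summary(out, reference)
        return True
    summary = map_reads(read_fastq(reads_path), reference,
                        config.mapping, mode=config.mapping_mode)
    state["summary"] = summary
    write_tsv(summary.pileup_table(), outputs[0])
    write_tsv([{
        "unit_id": summary.unit_id,
        "unit_len": summary.unit_len,
        "total_reads": summary.total_reads,
        "mapped_reads": summary.mapped_reads,
    }], outputs[1])
    write_fasta([extract_consensus(summary)], outputs[2])
    if reference.regions is not None:
        write_tsv(region_coverage(summary, reference.regions), outputs[3])
    else:
        write_tsv(pd.DataFrame(columns=["label", "start", "end", "mean_depth",
                                        "ratio_to_median", "anomaly"]),
                  outputs[3])
    # insertion evidence is kept in-memory for the variants stage and
    # serialised alongside for resumed runs
    ins_rows = [
        {"pos": pos, "inserted": seq, "count": cnt}
        for pos, ctr in sorted(summary.insertions.items())
        for seq, cnt in sorted(ctr.items())
    ]
    write_tsv(pd.DataFrame(ins_rows, columns=["pos", "inserted", "count"]),
              out / "insertions.tsv")
    manifest.record("map", key, outputs, inputs,
                    dataclasses.asdict(config.mapping))
    return False


def _reload_summary(out: Path, reference: RdnaUnitReference) -> MappingSummary:
    import numpy as np

    pileup = pd.read_csv(out / "pileup.tsv", sep="\t")
    meta = pd.read_csv(out / "mapping_summary.tsv", sep="\t").iloc[0]
    counts = np.zeros((5, len(pileup)), dtype=np.int64)
    for i, col in enumerate(["A", "C", "G", "T", "del"]):
        counts[i] = pileup[col].to_numpy()
    insertions: dict = {}
    ins_path = out / "insertions.tsv"
    if ins_path.exists():
        from collections import Counter

        df = pd.read_csv(ins_path, sep="\t")
        for _, row in df.iterrows():
            insertions.setdefault(int(row["pos"]), Counter())[
                str(row["inserted"])] += int(row["count"])
    return MappingSummary(
        unit_id=str(meta["unit_id"]), unit_len=int(meta["unit_len"]),
        total_reads=int(meta["total_reads"]),
        mapped_reads=int(meta["mapped_reads"]),
        counts=counts, insertions=insertions,
    )


def _genome_mb(config: PipelineConfig, out: Path) -> float:
    if config.genome_mb is not None:
        return config.genome_mb
    truth_path = out / "truth.tsv"
    if truth_path.exists():
        df = pd.read_csv(truth_path, sep="\t")
        genome_len = df.loc[df["record"] == "genome", "genome_len"].iloc[0]
        return float(genome_len) / 1e6
    raise FormatError("genome_mb is required when no synthetic truth exists")


def _stage_copynum(config, out, manifest, ckey, state) -> bool:
    outputs = [out / "copy_estimate.tsv"]
    key = ckey + str(state["summary"].mapped_reads)
    if manifest.fresh("copynum", key, outputs):
        return True
    genome_mb = _genome_mb(config, out)
    ref_len_mb = (len(state["reference"]) / 1e6 if config.ref_len_from_unit
                  else config.ref_len_mb)
    est = estimate_from_mapping(state["summary"], genome_mb,
                                ref_len_mb, species=config.species)
    state["estimate"] = est
    write_tsv(render_table2([est], gp_decimals=config.gp_decimals,
                            copies_step=config.copies_step), outputs[0])
    manifest.record("copynum", key, outputs, {},
                    {"genome_mb": genome_mb, "ref_len_mb": ref_len_mb})
    return False


def _stage_variants(config, out, manifest, ckey, state) -> bool:
    outputs = [out / "variants.tsv", out / "heterogeneity_summary.tsv"]
    key = ckey + str(state["summary"].mapped_reads)
    if manifest.fresh("variants", key, outputs):
        return True
    summary = state["summary"]
    reference = state["reference"]
    calls = merge_mnv(call_variants(summary, reference.sequence,
                                    config.filters))
    if reference.regions is not None:
        calls = assign_regions(calls, reference.regions)
    het = summarize_heterogeneity(
        calls, reference.regions, species=config.species,
        drop_indels_from_snp_set=config.filters.drop_indels_from_snp_set)
    write_tsv(calls_table(calls), outputs[0])
    per_region = het.per_region.reset_index(names="region")
    write_tsv(per_region, outputs[1])
    state["heterogeneity"] = het
    manifest.record("variants", key, outputs, {},
                    dataclasses.asdict(config.filters))
    return False


def _stage_report(config, out, manifest, ckey, state) -> bool:
    outputs = [out / "report.tsv"]
    if manifest.fresh("report", ckey, outputs) and "estimate" not in state:
        return True
    est = state.get("estimate")
    if est is None:
        df = pd.read_csv(out / "copy_estimate.tsv", sep="\t")
        df.to_csv(outputs[0], sep="\t", index=False)
    else:
        write_tsv(render_table2([est], gp_decimals=config.gp_decimals,
                                copies_step=config.copies_step), outputs[0])
    manifest.record("report", ckey, outputs, {}, {})
    return False


def render_table2(
    estimates: list[CopyEstimate],
    gp_decimals: int = 2,
    copies_step: int = 50,
) -> pd.DataFrame:
    """Copy-number report table: species, genome size, read counts, GP%,
    GP(Mb) and copies, with display rounding (GP to 2 decimals, copies to
    the nearest 50)."""
    rows = []
    for e in estimates:
        rows.append({
            "species": e.species,
            "genome_mb": e.genome_mb if e.genome_mb is not None else "",
            "total_reads": e.total_reads if e.total_reads is not None else "",
            "mapped_reads": e.mapped_reads if e.mapped_reads is not None else "",
            "gp_percent": round(e.gp_percent, gp_decimals),
            "gp_mb": round(e.gp_mb, gp_decimals),
            "copies": round_copies(e.copies, copies_step),
            # full-precision value alongside the display-rounded one, so
            # small synthetic runs stay interpretable
            "copies_exact": e.copies,
        })
    return pd.DataFrame(rows, columns=["species", "genome_mb", "total_reads",
                                       "mapped_reads", "gp_percent", "gp_mb",
                                       "copies", "copies_exact"])


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
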