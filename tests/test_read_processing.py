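from __future__ import annotations

import numpy as np
import pytest

import helpers
from rdnaquant.formats_io import FastqRecord, revcomp
from rdnaquant.read_processing import (
    MappingParams,
    QcParams,
    QcReport,
    accept_mapping,
    align_read,
    apply_qc,
    extract_consensus,
    map_reads,
    region_coverage,
    trim_read,
)
from rdnaquant.synthetic_data import (
    ReadSimParams,
    build_rdna_genome,
    random_unit,
    simulate_reads,
)


def _read(seq, q=40, id="r"):
    return FastqRecord(id=id, sequence=seq, quals=(q,) * len(seq))


class TestTrimming:
    def test_high_quality_read_untouched(self):
        res = trim_read(_read("ACGT" * 25, q=40))
        assert res.read is not None and res.read.sequence == "ACGT" * 25
        assert (res.start, res.end) == (0, 100)

    def test_all_q2_read_fully_trimmed(self):
        """Q2 means p_err ~ 0.63 >> 0.05, so the running sum never rises:
        the kept segment is empty and the read is rejected too_short."""
        res = trim_read(_read("ACGT" * 25, q=2))
        assert res.read is None and res.reason == "too_short"
        assert res.end - res.start == 0

    def test_read_with_n_rejected(self):
        seq = "ACGT" * 29 + "NACG"
        res = trim_read(_read(seq, q=40))
        assert res.read is None and res.reason == "contains_N"

    def test_low_quality_tail_trimmed(self):
        quals = (40,) * 95 + (2,) * 15
        read = FastqRecord(id="r", sequence="A" * 110, quals=quals)
        res = trim_read(read)
        assert res.read is not None
        assert (res.start, res.end) == (0, 95)

    def test_trimmed_below_min_len_rejected(self):
        quals = (40,) * 80 + (2,) * 40
        read = FastqRecord(id="r", sequence="A" * 120, quals=quals)
        res = trim_read(read)
        assert res.read is None and res.reason == "too_short"
        assert res.end - res.start == 80

    def test_apply_qc_tallies(self):
        reads = [
            _read("A" * 100, q=40, id="keep"),
            _read("A" * 50, q=40, id="short"),
            _read("A" * 99 + "N", q=40, id="withn"),
        ]
        rep = QcReport()
        kept = list(apply_qc(reads, QcParams(), rep))
        assert [r.id for r in kept] == ["keep"]
        assert (rep.kept, rep.too_short, rep.contains_n) == (1, 1, 1)


class TestAlignRead:
    def test_exact_substring(self, unit600):
        unit = unit600.sequence
        aln = align_read(unit[100:200], unit)
        assert (aln.score, aln.similarity, aln.aligned_read_fraction) == (100, 1.0, 1.0)
        assert (aln.ref_start, aln.ref_end, aln.strand) == (100, 200, "+")
        assert aln.ops == "100="

    def test_reverse_complement_maps_minus(self, unit600):
        unit = unit600.sequence
        aln = align_read(revcomp(unit[250:330]), unit)
        assert aln.strand == "-" and aln.similarity == 1.0
        assert (aln.ref_start, aln.ref_end) == (250, 330)

    def test_overhang_is_clipped_not_penalised(self, unit600):
        unit = unit600.sequence
        read = unit[570:] + "ACGTACGTAC"  # 30 nt in-unit + 10 nt overhang
        aln = align_read(read, unit)
        assert aln.score == 30
        assert aln.aligned_read_fraction == pytest.approx(0.75)
        assert aln.ops.endswith("S")

    def test_deletion_and_insertion_ops(self, unit600):
        unit = unit600.sequence
        read_del = unit[100:150] + unit[153:203]  # 3 bp deletion
        aln = align_read(read_del, unit)
        assert aln.score == 100 - 3 * 3
        assert "3D" in aln.ops
        read_ins = unit[300:350] + "TTT" + unit[350:400]
        aln = align_read(read_ins, unit)
        assert aln.score == 100 - 3 * 3
        assert "3I" in aln.ops

    def test_scores_match_exhaustive_dp_oracle(self, rng):
        """200 random 60 nt reads at ~5% error vs a 500 nt unit score
        identically to the brute-force full-matrix DP."""
        unit = random_unit(500, seed=77).sequence
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in range(200):
            kind = i % 4
            if kind == 0:
                read = "".join(rng.choice(list("ACGT"), 60))
            else:
                s = int(rng.integers(0, 440))
                read = list(unit[s:s + 60])
                for p in rng.choice(60, size=int(rng.integers(0, 6)),
                                    replace=False):
                    read[p] = flip[read[p]]
                read = "".join(read)
                if kind == 2:
                    read = helpers.rc(read)
                if kind == 3:
                    p = int(rng.integers(5, 55))
                    read = read[:p] + read[p + 1:]  # 1 bp deletion
            got = align_read(read, unit)
            want = helpers.oracle_align(read, unit)
            assert got.score == want["score"], read
            assert accept_mapping(got) == (
                want["aligned_read_fraction"] >= 0.8
                and want["similarity"] >= 0.8), read


class TestAcceptMapping:
    @pytest.mark.parametrize("fraction,similarity,expected", [
        (1.0, 1.0, True),
        (1.0, 0.75, False),   # 25 mismatches in a 100 nt full alignment
        (0.79, 0.95, False),  # boundary is >=
        (0.8, 0.8, True),
    ])
    def test_thresholds(self, fraction, similarity, expected):
        from rdnaquant.read_processing import AlignmentResult

        aln = AlignmentResult(read_id="r", ref_start=0, ref_end=10,
                              strand="+", ops="10=",
                              aligned_read_fraction=fraction,
                              similarity=similarity, score=10)
        assert accept_mapping(aln) is expected


class TestMapReads:
    def test_single_unit_genome_maps_every_read(self, unit600):
        genome, _ = build_rdna_genome(0, unit600.sequence, 1, seed=1)
        reads = list(simulate_reads(genome, ReadSimParams(
            n_reads=300, seed=2, read_len=90, error_rate=0.0, n_rate=0.0)))
        summary = map_reads(reads, unit600)
        assert summary.mapped_reads == summary.total_reads == 300
        assert summary.counts[:4].sum() == 300 * 90

    def test_background_only_reads_never_map(self, unit600):
        genome, _ = build_rdna_genome(5000, unit600.sequence, 0, seed=3)
        reads = list(simulate_reads(genome, ReadSimParams(
            n_reads=400, seed=4, read_len=90, error_rate=0.0, n_rate=0.0)))
        summary = map_reads(reads, unit600)
        assert summary.mapped_reads == 0

    def test_auto_mode_equals_exact_mode(self, unit600):
        """Fast paths (gapless candidates, rejection screens) must not
        change decisions or the pileup relative to the full DP."""
        unit = unit600.sequence
        genome, _ = build_rdna_genome(2000, unit, 3, seed=5)
        reads = list(simulate_reads(genome, ReadSimParams(
            n_reads=400, seed=6, read_len=100, error_rate=0.01, n_rate=0.0)))
        auto = map_reads(reads, unit600, mode="auto")
        exact = map_reads(reads, unit600, mode="exact")
        assert auto.mapped_reads == exact.mapped_reads
        assert np.array_equal(auto.counts, exact.counts)

    def test_strand_invariance(self, unit600):
        genome, _ = build_rdna_genome(1000, unit600.sequence, 2, seed=7)
        reads = list(simulate_reads(genome, ReadSimParams(
            n_reads=300, seed=8, read_len=100, error_rate=0.005, n_rate=0.0)))
        flipped = [FastqRecord(id=r.id, sequence=revcomp(r.sequence),
                               quals=r.quals[::-1]) for r in reads]
        a = map_reads(reads, unit600)
        b = map_reads(flipped, unit600)
        assert a.mapped_reads == b.mapped_reads
        assert np.array_equal(a.counts, b.counts)

    def test_acceptance_fraction_monotonicity(self, unit600):
        genome, _ = build_rdna_genome(3000, unit600.sequence, 2, seed=9)
        reads = list(simulate_reads(genome, ReadSimParams(
            n_reads=300, seed=10, read_len=100, error_rate=0.02, n_rate=0.0)))
        mapped = []
        for frac in (0.7, 0.8, 0.9, 1.0):
            p = MappingParams(length_fraction=frac, similarity_fraction=frac)
            mapped.append(map_reads(reads, unit600, p).mapped_reads)
        assert mapped == sorted(mapped, reverse=True)

    def test_score_consistent_with_ops(self, unit600):
        """Invariant: score == matches - 2*mismatches - 3*ins - 3*del."""
        genome, _ = build_rdna_genome(500, unit600.sequence, 2, seed=11)
        reads = list(simulate_reads(genome, ReadSimParams(
            n_reads=100, seed=12, read_len=100, error_rate=0.02, n_rate=0.0)))
        summary = map_reads(reads, unit600, keep_alignments=True)
        for aln in summary.alignments:
            tallies = {op: 0 for op in "=XIDS"}
            for op, ln in aln.op_runs():
                tallies[op] += ln
            assert aln.score == (tallies["="] - 2 * tallies["X"]
                                 - 3 * tallies["I"] - 3 * tallies["D"])
            assert sum(tallies[o] for o in "=XIS") == 100

    def test_pileup_allele_counts_sum_to_depth(self, unit600):
        genome, _ = build_rdna_genome(500, unit600.sequence, 2, seed=13)
        reads = list(simulate_reads(genome, ReadSimParams(
            n_reads=200, seed=14, read_len=100, error_rate=0.01, n_rate=0.0)))
        summary = map_reads(reads, unit600)
        assert np.array_equal(summary.coverage, summary.counts.sum(axis=0))
        assert summary.coverage.sum() > 0


class TestConsensus:
    def test_agreeing_reads_reproduce_reference(self, unit600):
        # 3 tandem copies so junction reads also cover the unit edges
        genome, _ = build_rdna_genome(0, unit600.sequence, 3, seed=1)
        reads = list(simulate_reads(genome, ReadSimParams(
            n_reads=1200, seed=2, read_len=100, error_rate=0.0, n_rate=0.0)))
        summary = map_reads(reads, unit600)
        consensus = extract_consensus(summary)
        assert consensus.sequence == unit600.sequence

    def test_majority_and_tie_rules(self):
        from rdnaquant.read_processing import MappingSummary

        counts = np.zeros((5, 3), dtype=np.int64)
        counts[3, 0] = 60  # T
        counts[1, 0] = 40  # C -> T wins
        counts[0, 1] = 50  # A
        counts[2, 1] = 50  # G -> alphabetical tie -> A
        # position 2: uncovered -> N
        summary = MappingSummary(unit_id="u", unit_len=3, counts=counts)
        assert extract_consensus(summary).sequence == "TAN"

    def test_majority_deletion_removes_position(self):
        from rdnaquant.read_processing import MappingSummary

        counts = np.zeros((5, 3), dtype=np.int64)
        counts[0, :] = 10
        counts[4, 1] = 30  # deletion majority at position 1
        counts[0, 1] = 10
        summary = MappingSummary(unit_id="u", unit_len=3, counts=counts)
        assert extract_consensus(summary).sequence == "AA"


class TestRegionCoverage:
    def test_uniform_reads_have_balanced_ratios(self, ref6k):
        genome, _ = build_rdna_genome(0, ref6k.sequence, 4, seed=3)
        reads = list(simulate_reads(genome, ReadSimParams(
            n_reads=2000, seed=4, read_len=100, error_rate=0.0, n_rate=0.0)))
        summary = map_reads(reads, ref6k)
        table = region_coverage(summary, ref6k.regions)
        assert not table["anomaly"].any()
        assert ((table["ratio_to_median"] > 0.5)
                & (table["ratio_to_median"] < 2.0)).all()

    def test_dispersed_its2_copies_flagged(self, ref6k):
        """A genome carrying extra dispersed copies of the ITS2 subsequence
        only shows >10x relative ITS2 coverage, the signature reported for
        subregion-related sequences outside the rDNA unit."""
        its2 = next(r for r in ref6k.regions.regions if r.label == "ITS2")
        its2_seq = ref6k.sequence[its2.start:its2.end]
        genome, _ = build_rdna_genome(20_000, ref6k.sequence, 1, seed=5)
        spiked = genome.sequence + its2_seq * 12
        from rdnaquant.formats_io import FastaRecord

        reads = list(simulate_reads(
            FastaRecord(id="g", sequence=spiked),
            ReadSimParams(n_reads=4000, seed=6, read_len=100,
                          error_rate=0.0, n_rate=0.0)))
        summary = map_reads(reads, ref6k)
        table = region_coverage(summary, ref6k.regions).set_index("label")
        assert table.loc["ITS2", "anomaly"]
        assert table.loc["ITS2", "ratio_to_median"] > 10

    def test_empty_pileup_no_flags(self, ref6k):
        summary = map_reads([], ref6k)
        table = region_coverage(summary, ref6k.regions)
        assert (table["mean_depth"] == 0).all()
        assert not table["anomaly"].any()
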