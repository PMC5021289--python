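from __future__ import annotations

import numpy as np
import pytest

from rdnaquant.formats_io import Region, RegionAnnotation
from rdnaquant.read_processing import MappingSummary, apply_qc, map_reads
from rdnaquant.synthetic_data import (
    ReadSimParams,
    VariantSpec,
    build_rdna_genome,
    random_unit,
    reads_for_depth,
    simulate_reads,
)
from rdnaquant.variant_analysis import (
    VariantCall,
    VariantFilters,
    assign_regions,
    call_variants,
    heterogeneity_ratio,
    merge_mnv,
    summarize_heterogeneity,
)

FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _summary_with(unit_seq, pos_counts):
    """Build a synthetic pileup: {pos: (ref_count, alt_base, alt_count)}."""
    from rdnaquant._align import encode

    m = len(unit_seq)
    counts = np.zeros((5, m), dtype=np.int64)
    refcode = encode(unit_seq)
    counts[refcode, np.arange(m)] = 200  # baseline ref coverage
    for pos, (refn, alt, altn) in pos_counts.items():
        counts[refcode[pos], pos] = refn
        if alt == "del":
            counts[4, pos] = altn
        else:
            counts["ACGT".index(alt), pos] = altn
    return MappingSummary(unit_id="u", unit_len=m, total_reads=0,
                          mapped_reads=0, counts=counts)


class TestCallVariants:
    def test_filter_thresholds(self):
        unit = random_unit(300, seed=1).sequence
        alt = {p: FLIP[unit[p]] for p in (50, 100, 150)}
        summary = _summary_with(unit, {
            50: (160, alt[50], 40),    # 20% of 200 -> called
            100: (190, alt[100], 10),  # 5% -> fails frequency
            150: (30, alt[150], 20),   # coverage 50 -> fails coverage
        })
        calls = call_variants(summary, unit)
        assert [(c.unit_pos, c.alt_allele, c.frequency) for c in calls] == [
            (50, alt[50], pytest.approx(0.2))]

    def test_exact_frequency_boundary_passes(self):
        unit = random_unit(100, seed=2).sequence
        alt = FLIP[unit[40]]
        summary = _summary_with(unit, {40: (180, alt, 20)})  # exactly 10%
        calls = call_variants(summary, unit)
        assert len(calls) == 1 and calls[0].count == 20

    def test_multiallelic_position_yields_multiple_calls(self):
        unit = random_unit(100, seed=3).sequence
        ref = unit[60]
        others = [b for b in "ACGT" if b != ref]
        from rdnaquant._align import encode

        counts = np.zeros((5, 100), dtype=np.int64)
        counts[encode(unit), np.arange(100)] = 300
        counts["ACGT".index(others[0]), 60] = 60
        counts["ACGT".index(others[1]), 60] = 45
        counts[encode(unit)[60], 60] = 195
        summary = MappingSummary(unit_id="u", unit_len=100, counts=counts)
        calls = call_variants(summary, unit)
        assert sorted(c.alt_allele for c in calls) == sorted(others[:2])

    def test_deletion_allele_called(self):
        unit = random_unit(100, seed=4).sequence
        summary = _summary_with(unit, {70: (150, "del", 50)})
        calls = call_variants(summary, unit)
        assert [(c.kind, c.alt_allele) for c in calls] == [("DEL", "")]

    def test_filter_monotonicity(self):
        """Raising any threshold never increases the number of calls."""
        unit = random_unit(400, seed=5).sequence
        rng = np.random.default_rng(6)
        pos_counts = {}
        for p in rng.choice(400, size=40, replace=False):
            altn = int(rng.integers(5, 80))
            pos_counts[int(p)] = (200 - altn, FLIP[unit[p]], altn)
        summary = _summary_with(unit, pos_counts)
        base = len(call_variants(summary, unit, VariantFilters()))
        for f in (VariantFilters(min_coverage=150),
                  VariantFilters(min_count=20),
                  VariantFilters(min_frequency=0.2)):
            assert len(call_variants(summary, unit, f)) <= base


class TestMergeMnv:
    def _snv(self, pos, ref="A", alt="C", count=40, cov=200):
        return VariantCall(unit_pos=pos, kind="SNV", ref_allele=ref,
                           alt_allele=alt, count=count, coverage=cov,
                           frequency=count / cov)

    def test_adjacent_similar_frequencies_merge(self):
        calls = [self._snv(10, count=40), self._snv(11, count=42)]
        merged = merge_mnv(calls)
        assert len(merged) == 1
        mnv = merged[0]
        assert (mnv.kind, mnv.unit_pos, len(mnv.alt_allele)) == ("MNV", 10, 2)
        assert mnv.count == 40 and mnv.frequency == pytest.approx(0.2)

    def test_non_consecutive_stay_snv(self):
        merged = merge_mnv([self._snv(10), self._snv(12)])
        assert [c.kind for c in merged] == ["SNV", "SNV"]

    def test_discordant_frequencies_stay_snv(self):
        merged = merge_mnv([self._snv(10, count=40), self._snv(11, count=80)])
        assert [c.kind for c in merged] == ["SNV", "SNV"]

    def test_three_way_run_merges_once(self):
        merged = merge_mnv([self._snv(5), self._snv(6), self._snv(7)])
        assert len(merged) == 1 and len(merged[0].alt_allele) == 3

    def test_synthetic_mnv_recovered_at_depth(self):
        """An injected 2 nt MNV at copy fraction 0.25 comes back as one MNV
        with frequency within +-0.05 of the truth at ~300x."""
        unit = random_unit(1000, seed=7)
        pos = 500
        ref2 = unit.sequence[pos:pos + 2]
        alt2 = FLIP[ref2[0]] + FLIP[ref2[1]]
        v = VariantSpec(unit_pos=pos, kind="MNV", ref_allele=ref2,
                        alt_allele=alt2, copy_fraction=0.25)
        genome, _ = build_rdna_genome(0, unit.sequence, 20, [v], seed=8)
        n = reads_for_depth(len(genome.sequence), 16.0, 100)  # ~300x pileup
        reads = apply_qc(simulate_reads(genome, ReadSimParams(
            n_reads=n, seed=9)))
        summary = map_reads(reads, unit)
        calls = merge_mnv(call_variants(summary, unit.sequence))
        mnvs = [c for c in calls if c.kind == "MNV"]
        assert len(mnvs) == 1
        assert mnvs[0].unit_pos == pos and mnvs[0].alt_allele == alt2
        assert abs(mnvs[0].frequency - 0.25) <= 0.05


class TestRegions:
    ANN = RegionAnnotation(unit_id="u", regions=[
        Region("18S", 0, 100), Region("ITS1", 100, 150),
        Region("5.8S", 150, 180), Region("ITS2", 180, 230),
        Region("26S", 230, 400)])

    def _call(self, pos, kind="SNV", alt="C"):
        return VariantCall(unit_pos=pos, kind=kind, ref_allele="A",
                           alt_allele=alt, count=30, coverage=200,
                           frequency=0.15)

    def test_interval_labels(self):
        calls = assign_regions([self._call(120), self._call(150),
                                self._call(149)], self.ANN)
        assert [c.region_label for c in calls] == ["ITS1", "5.8S", "ITS1"]

    def test_mnv_labelled_by_start(self):
        mnv = VariantCall(unit_pos=179, kind="MNV", ref_allele="AA",
                          alt_allele="CC", count=30, coverage=200,
                          frequency=0.15)
        assert assign_regions([mnv], self.ANN)[0].region_label == "5.8S"

    def test_unannotated_positions_kept(self):
        short = RegionAnnotation(unit_id="u",
                                 regions=[Region("18S", 0, 100)])
        calls = assign_regions([self._call(250)], short)
        assert calls[0].region_label == "unannotated"


class TestSummaries:
    def test_empty(self):
        rep = summarize_heterogeneity([], TestRegions.ANN)
        assert rep.totals == {"SNV": 0, "MNV": 0, "indel": 0}
        assert rep.total_calls == 0

    def test_kind_pooling(self):
        calls = []
        mk = TestRegions()._call
        calls += [mk(10), mk(20), mk(30)]
        calls.append(VariantCall(unit_pos=40, kind="MNV", ref_allele="AA",
                                 alt_allele="CC", count=30, coverage=200,
                                 frequency=0.15))
        calls += [VariantCall(unit_pos=p, kind="DEL", ref_allele="A",
                              alt_allele="", count=30, coverage=200,
                              frequency=0.15) for p in (50, 60)]
        calls.append(VariantCall(unit_pos=70, kind="INS", ref_allele="",
                                 alt_allele="TT", count=30, coverage=200,
                                 frequency=0.15))
        rep = summarize_heterogeneity(calls, TestRegions.ANN)
        assert rep.totals == {"SNV": 3, "MNV": 1, "indel": 3}
        assert rep.snp_totals == {"SNV": 3, "MNV": 1}

    def test_region_totals_sum_to_overall(self):
        mk = TestRegions()._call
        calls = [mk(10), mk(120), mk(160), mk(200), mk(300), mk(399)]
        rep = summarize_heterogeneity(calls, TestRegions.ANN)
        assert int(rep.per_region.to_numpy().sum()) == rep.total_calls


class TestHeterogeneityRatio:
    def _report(self, n_snv):
        mk = TestRegions()._call
        return summarize_heterogeneity([mk(i * 3) for i in range(n_snv)],
                                       TestRegions.ANN)

    def test_three_fold(self):
        r = heterogeneity_ratio(self._report(150), self._report(50))
        assert r["overall"] == pytest.approx(3.0)

    def test_identical_reports(self):
        r = heterogeneity_ratio(self._report(40), self._report(40))
        assert r["overall"] == pytest.approx(1.0)

    def test_zero_denominator_flagged_infinite(self):
        r = heterogeneity_ratio(self._report(5), self._report(0))
        assert r["overall"] == np.inf
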