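"""Coverage building, junction extraction, UTR modeling, intron refinement."""

from collections import Counter

import numpy as np
import pytest

from conftest import make_annotation, make_gene
from lmseq.annotation_refine import (
    CoverageTrack,
    apply_utr_calls,
    build_coverage,
    extract_junctions,
    model_utrs,
    refine_gene_models,
    utr_summary_table,
)
from lmseq.models import AlignedRead, LmseqError
from lmseq.validation import validate_intron_recovery, validate_utr_recovery


def read(blocks, read_id="r", contig="chr1", unique=True, primary=True):
    blocks = tuple(tuple(b) for b in blocks)
    length = sum(e - s for s, e in blocks)
    return AlignedRead(read_id=read_id, contig=contig, blocks=blocks,
                       read_length=length, is_unique=unique, is_primary=primary)


class TestBuildCoverage:
    def test_no_reads_gives_zero_track(self):
        track = build_coverage([], {"chr1": 100})
        assert track["chr1"].sum() == 0

    def test_single_read_covers_its_bases_once(self):
        track = build_coverage([read([(10, 60)])], {"chr1": 100})
        assert track["chr1"][10:60].tolist() == [1] * 50
        assert track["chr1"].sum() == 50

    def test_splice_skip_contributes_nothing(self):
        track = build_coverage([read([(0, 20), (120, 150)])], {"chr1": 200})
        assert track["chr1"][20:120].sum() == 0
        assert track["chr1"].sum() == 50

    def test_nonunique_and_secondary_excluded(self):
        reads = [read([(0, 50)], unique=False), read([(0, 50)], primary=False)]
        assert build_coverage(reads, {"chr1": 100})["chr1"].sum() == 0

    def test_block_outside_contig_raises(self):
        with pytest.raises(LmseqError):
            build_coverage([read([(90, 120)])], {"chr1": 100})

    def test_fuzzed_equality_with_per_base_loop(self):
        rng = np.random.default_rng(21)
        reads = []
        for i in range(500):
            start = int(rng.integers(0, 900))
            if rng.random() < 0.3:
                gap = int(rng.integers(10, 50))
                blocks = [(start, start + 20), (start + 20 + gap, start + 50 + gap)]
            else:
                blocks = [(start, start + int(rng.integers(10, 60)))]
            reads.append(read(blocks, read_id=f"r{i}",
                              unique=rng.random() > 0.1,
                              primary=rng.random() > 0.1))
        track = build_coverage(reads, {"chr1": 1000})
        expected = np.zeros(1000, dtype=int)
        for r in reads:
            if r.is_primary and r.is_unique:
                for s, e in r.blocks:
                    for pos in range(s, e):
                        expected[pos] += 1
        assert np.array_equal(track["chr1"], expected)


class TestExtractJunctions:
    def test_unspliced_reads_give_no_junctions(self):
        assert extract_junctions([read([(0, 50)])]) == []

    def test_shared_junction_aggregates_support(self):
        reads = [read([(0, 20), (120, 150)], read_id=f"r{i}") for i in range(3)]
        [junction] = extract_junctions(reads)
        assert (junction.donor_end, junction.acceptor_start) == (20, 120)
        assert junction.support == 3

    def test_fuzzed_multiset_matches_gap_enumeration(self):
        rng = np.random.default_rng(22)
        reads = []
        for i in range(400):
            start = int(rng.integers(0, 5000))
            n_blocks = int(rng.integers(1, 4))
            blocks, cursor = [], start
            for _ in range(n_blocks):
                blocks.append((cursor, cursor + int(rng.integers(5, 40))))
                cursor = blocks[-1][1] + int(rng.integers(30, 200))
            reads.append(read(blocks, read_id=f"r{i}",
                              unique=rng.random() > 0.1))
        got = Counter({(j.contig, j.donor_end, j.acceptor_start): j.support
                       for j in extract_junctions(reads)})
        want: Counter = Counter()
        for r in reads:
            if r.is_unique and r.is_primary and len(r.blocks) > 1:
                for i in range(len(r.blocks) - 1):
                    want[(r.contig, r.blocks[i][1], r.blocks[i + 1][0])] += 1
        assert got == want


def flat_coverage(intervals, length=10_000, depth=10):
    arr = np.zeros(length, dtype=np.int32)
    for s, e in intervals:
        arr[s:e] = depth
    return CoverageTrack({"chr1": arr})


class TestModelUtrs:
    def test_zero_coverage_gives_no_calls(self):
        genes = [make_gene(exons=[(1000, 2000)])]
        calls, summary = model_utrs(make_annotation(genes), flat_coverage([]))
        assert calls == []
        assert summary.none == summary.n_genes == 1
        table = utr_summary_table(summary)
        assert table.loc[table.category == "no UTR found", "percent"].item() == 100.0

    def test_true_utr_recovered_from_uniform_coverage(self):
        # gene CDS [1000,2000); transcript truly extends 120 bases 3'
        gene = make_gene(exons=[(1000, 2000)])
        cov = flat_coverage([(1000, 2120)])
        calls, _ = model_utrs(make_annotation([gene]), cov)
        call = {c.side: c for c in calls}["3'"]
        assert call.interval[0] == 2000
        assert abs(call.interval[1] - 2120) <= 10
        assert call.mean_coverage == pytest.approx(10.0)

    def test_minus_strand_swaps_sides(self):
        gene = make_gene(strand="-", exons=[(1000, 2000)])
        cov = flat_coverage([(880, 2000)])
        calls, _ = model_utrs(make_annotation([gene]), cov)
        [call] = calls
        assert call.side == "3'"  # left extension is 3' on the minus strand
        assert call.interval == (880, 1000)

    def test_extension_stops_at_neighbor_gene(self):
        gene_a = make_gene("gA", exons=[(1000, 2000)])
        gene_b = make_gene("gB", exons=[(2050, 3000)])
        cov = flat_coverage([(1000, 3000)])  # continuous coverage across both
        calls, _ = model_utrs(make_annotation([gene_a, gene_b]), cov)
        call3 = [c for c in calls if c.gene_id == "gA" and c.side == "3'"][0]
        assert call3.length <= 50
        assert call3.interval[1] <= 2050

    def test_gap_tolerance_boundary(self):
        gene = make_gene(exons=[(1000, 2000)])
        ann = make_annotation([gene])
        # an 8-base hole inside the extension is crossed...
        cov = flat_coverage([(2000, 2050), (2058, 2100)])
        calls, _ = model_utrs(ann, cov, max_gap=10)
        assert calls[0].interval == (2000, 2100)
        # ...an 11-base hole is not
        cov = flat_coverage([(2000, 2050), (2061, 2100)])
        calls, _ = model_utrs(ann, cov, max_gap=10)
        assert calls[0].interval == (2000, 2050)

    def test_max_extent_caps_the_walk(self):
        gene = make_gene(exons=[(1000, 2000)])
        cov = flat_coverage([(0, 10_000)])
        calls, _ = model_utrs(make_annotation([gene]), cov, max_extent=300)
        for call in calls:
            assert call.length <= 300

    def test_apply_calls_extends_exons_and_validates(self):
        gene = make_gene(exons=[(1000, 2000)])
        cov = flat_coverage([(900, 2120)])
        ann = make_annotation([gene])
        calls, _ = model_utrs(ann, cov)
        refined = apply_utr_calls(ann, calls)
        out = refined.by_id()["g1"]
        assert out.utr5 is not None and out.utr3 is not None
        assert out.exons[0][0] == out.utr5[0]
        assert out.exons[-1][1] == out.utr3[1]

    def test_simulated_recovery_rate(self):
        """>= 90% of true UTR termini restored within 10 bases at ~20x."""
        metrics = validate_utr_recovery(seed=2, n_genes=30,
                                        reads_per_sample=24_000)
        assert metrics["recovered_frac"] >= 0.9


class TestRefineGeneModels:
    def setup_method(self):
        self.gene = make_gene(
            exons=[(1000, 1100), (1200, 1400), (1500, 1700)],
            cds=(1000, 1700),
        )
        self.ann = make_annotation([self.gene])

    def _junctions(self, reads):
        return extract_junctions(reads)

    def test_exact_junctions_confirm_and_leave_annotation_fixed(self):
        reads = [read([(1050, 1100), (1200, 1250)], read_id="a"),
                 read([(1350, 1400), (1500, 1550)], read_id="b")]
        refined, report = refine_gene_models(self.ann, self._junctions(reads))
        assert refined.by_id()["g1"].exons == self.gene.exons
        assert report.confirmed == 2
        assert report.adjusted == report.novel_internal == report.outside == 0

    def test_shifted_intron_replaced_when_supported(self):
        # annotated intron [1100,1200); reads say [1105,1200)
        reads = [read([(1050, 1105), (1200, 1250)], read_id=f"r{i}")
                 for i in range(5)]
        refined, report = refine_gene_models(self.ann, self._junctions(reads))
        assert (1105, 1200) in refined.by_id()["g1"].introns
        assert report.adjusted == 1

    def test_low_support_junction_not_applied(self):
        reads = [read([(1050, 1105), (1200, 1250)], read_id="solo")]
        refined, report = refine_gene_models(self.ann, self._junctions(reads),
                                             min_support=2)
        assert refined.by_id()["g1"].exons == self.gene.exons
        assert report.unsupported == 1

    def test_junction_inside_exon_splits_it(self):
        reads = [read([(1240, 1260), (1320, 1340)], read_id=f"r{i}")
                 for i in range(3)]
        refined, report = refine_gene_models(self.ann, self._junctions(reads))
        assert (1260, 1320) in refined.by_id()["g1"].introns
        assert report.novel_internal == 1
        refined.validate()

    def test_intergenic_junction_reported_as_candidate_only(self):
        reads = [read([(5000, 5050), (5200, 5250)], read_id=f"r{i}")
                 for i in range(3)]
        refined, report = refine_gene_models(self.ann, self._junctions(reads))
        assert refined.by_id()["g1"].exons == self.gene.exons
        assert report.outside == 1
        assert [(j.donor_end, j.acceptor_start) for j in report.candidates] == [
            (5050, 5200)
        ]

    def test_adjustment_creating_empty_exon_rejected(self):
        # junction [1000,1300) would erase the first exon entirely
        reads = [read([(950, 1000), (1300, 1350)], read_id=f"r{i}")
                 for i in range(4)]
        refined, report = refine_gene_models(self.ann, self._junctions(reads))
        assert refined.by_id()["g1"].exons == self.gene.exons
        assert report.rejected == 1

    def test_corrupted_introns_restored_exactly(self):
        metrics = validate_intron_recovery(seed=3, n_corrupt=8)
        assert metrics["restored"] == metrics["n_corrupted"] == 8
        assert metrics["false_introns"] == 0
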