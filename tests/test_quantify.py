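"""Both-ends counting, region classification, 3'-window counts, CPM."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_annotation, make_gene
from lmseq.models import AlignedRead, LmseqError
from lmseq.quantify import (
    CountMatrix,
    classify_regions,
    count_3prime_window,
    count_features,
    normalize,
    three_prime_window_blocks,
)
from lmseq.synthetic_data import strip_annotation_utrs
from lmseq.validation import _count_reference, make_counting_instance


def read(blocks, read_id="r", contig="chr1", length=None, unique=True,
         primary=True):
    blocks = tuple(tuple(b) for b in blocks)
    if length is None:
        length = sum(e - s for s, e in blocks)
    return AlignedRead(read_id=read_id, contig=contig, blocks=blocks,
                       read_length=length, is_unique=unique, is_primary=primary)


@pytest.fixture
def two_gene_annotation():
    gene_a = make_gene("gA", exons=[(1000, 1400), (1500, 2000)], cds=(1000, 2000))
    gene_b = make_gene("gB", exons=[(3000, 4000)])
    return make_annotation([gene_a, gene_b])


class TestCountFeatures:
    def test_short_read_excluded_by_length_filter(self, two_gene_annotation):
        counts, stats = count_features(
            [read([(1100, 1134)])], two_gene_annotation
        )
        assert counts.sum() == 0
        assert stats.skipped_short == 1
        # one base longer and it counts
        counts, _ = count_features([read([(1100, 1135)])], two_gene_annotation)
        assert counts["gA"] == 1

    def test_boundary_straddling_read_not_counted(self, two_gene_annotation):
        # start in gA's exon, end in intergenic space
        counts, stats = count_features(
            [read([(1950, 2050)])], two_gene_annotation
        )
        assert counts.sum() == 0
        assert stats.uncounted == 1

    def test_spliced_read_with_both_ends_in_exons_counts(self, two_gene_annotation):
        counts, _ = count_features(
            [read([(1350, 1400), (1500, 1550)])], two_gene_annotation
        )
        assert counts["gA"] == 1

    def test_ends_in_different_genes_is_ambiguous(self):
        gene_a = make_gene("gA", exons=[(1000, 2000)])
        gene_b = make_gene("gB", exons=[(2100, 3000)])
        ann = make_annotation([gene_a, gene_b])
        counts, stats = count_features(
            [read([(1950, 2000), (2100, 2150)])], ann
        )
        assert counts.sum() == 0
        assert stats.ambiguous + stats.uncounted == 1

    def test_nonunique_and_secondary_skipped(self, two_gene_annotation):
        reads = [read([(1100, 1200)], unique=False),
                 read([(1100, 1200)], primary=False)]
        counts, stats = count_features(reads, two_gene_annotation)
        assert counts.sum() == 0
        assert stats.skipped_nonunique == 2

    def test_fuzzed_equality_with_nested_loop_reference(self):
        annotation, reads = make_counting_instance(seed=4, n_genes=20,
                                                   n_reads=3000)
        got, _ = count_features(reads, annotation)
        want = _count_reference(reads, annotation)
        pd.testing.assert_series_equal(got.sort_index(), want.sort_index())

    def test_removing_utrs_never_increases_counts(self, sim_small):
        _, _, truth, sample = sim_small
        with_utrs, _ = count_features(sample.alignments, truth.annotation)
        without, _ = count_features(
            sample.alignments, strip_annotation_utrs(truth.annotation)
        )
        assert (without <= with_utrs).all()
        assert without.sum() < with_utrs.sum()  # 3'-UTR reads are lost


class TestClassifyRegions:
    def test_read_fully_in_intron_is_intronic(self, two_gene_annotation):
        tally = classify_regions([read([(1420, 1480)])], two_gene_annotation)
        assert tally.reads_intronic == 1

    def test_majority_rule_favours_exon(self, two_gene_annotation):
        # 30 exonic bases, 20 intronic -> exonic
        tally = classify_regions([read([(1370, 1420)])], two_gene_annotation)
        assert tally.reads_exonic == 1
        # 10 exonic, 40 intronic -> intronic
        tally = classify_regions([read([(1390, 1440)])], two_gene_annotation)
        assert tally.reads_intronic == 1

    def test_fuzzed_equality_with_base_labeling_oracle(self, two_gene_annotation):
        rng = np.random.default_rng(31)
        reads = []
        for i in range(800):
            start = int(rng.integers(0, 4500))
            length = int(rng.integers(35, 80))
            if rng.random() < 0.2:
                gap = int(rng.integers(50, 400))
                half = length // 2
                blocks = [(start, start + half),
                          (start + half + gap, start + length + gap)]
            else:
                blocks = [(start, start + length)]
            reads.append(read(blocks, read_id=f"r{i}"))
        got = classify_regions(reads, two_gene_annotation).as_dict()
        want = _region_reference(reads, two_gene_annotation)
        assert got == want

    def test_categories_partition_counted_reads(self, sim_small):
        _, _, truth, sample = sim_small
        tally = classify_regions(sample.alignments, truth.annotation)
        eligible = sum(
            1 for a in sample.alignments
            if a.is_primary and a.is_unique and a.read_length >= 35
        )
        assert (tally.reads_exonic + tally.reads_intronic
                + tally.reads_intergenic + tally.reads_ambiguous) == eligible


def _region_reference(reads, annotation, min_read_len=35):
    """Per-base labeling oracle: scan every gene for every aligned base."""
    out = {"reads_exonic": 0, "reads_intronic": 0, "reads_intergenic": 0,
           "reads_ambiguous": 0, "reads_skipped_short": 0}
    for r in reads:
        if not (r.is_primary and r.is_unique):
            continue
        if r.read_length < min_read_len:
            out["reads_skipped_short"] += 1
            continue
        labels = []  # per base: (gene_id or None, region)
        for s, e in r.blocks:
            for pos in range(s, e):
                label = (None, "intergenic")
                for gene in annotation.genes:
                    if gene.contig != r.contig:
                        continue
                    if gene.start <= pos < gene.end:
                        region = "intron"
                        for xs, xe in gene.exons:
                            if xs <= pos < xe:
                                region = "exon"
                                break
                        label = (gene.gene_id, region)
                        break
                labels.append(label)
        per_gene = {}
        for gene_id, _ in labels:
            if gene_id is not None:
                per_gene[gene_id] = per_gene.get(gene_id, 0) + 1
        if len(per_gene) >= 2 and max(per_gene.values()) * 2 <= len(labels):
            out["reads_ambiguous"] += 1
            continue
        tallies = {"exon": 0, "intron": 0, "intergenic": 0}
        for _, region in labels:
            tallies[region] += 1
        best = max(["intergenic", "intron", "exon"], key=lambda k: (tallies[k],
                   {"exon": 3, "intron": 2, "intergenic": 1}[k]))
        out[{"exon": "reads_exonic", "intron": "reads_intronic",
             "intergenic": "reads_intergenic"}[best]] += 1
    return out


class TestThreePrimeWindow:
    def test_plus_strand_single_exon_arithmetic(self):
        gene = make_gene(exons=[(0, 1000)])
        assert three_prime_window_blocks(gene) == [(600, 900)]

    def test_minus_strand_window_sits_left(self):
        gene = make_gene(strand="-", exons=[(0, 1000)])
        assert three_prime_window_blocks(gene) == [(100, 400)]

    def test_short_transcript_clips_and_degenerates(self):
        gene = make_gene(exons=[(0, 250)])
        assert three_prime_window_blocks(gene) == [(0, 150)]
        tiny = make_gene(exons=[(0, 90)])
        assert three_prime_window_blocks(tiny) == []
        counts, _ = count_3prime_window(
            [read([(10, 60)])], make_annotation([tiny])
        )
        assert counts["g1"] == 0

    def test_window_projects_through_introns(self):
        gene = make_gene(exons=[(0, 500), (700, 1200)], cds=(0, 1200))
        # transcript length 1000; window [600, 900) in transcript coords
        # falls entirely in the second exon: genomic [800, 1100)
        assert three_prime_window_blocks(gene) == [(800, 1100)]
        gene2 = make_gene(exons=[(0, 800), (1000, 1200)], cds=(0, 1200))
        # window spans the intron: [600,800) + [1000,1100)
        assert three_prime_window_blocks(gene2) == [(600, 800), (1000, 1100)]

    def test_counting_requires_both_ends_in_window(self):
        gene = make_gene(exons=[(0, 1000)])
        ann = make_annotation([gene])
        inside = read([(650, 700)])
        straddling = read([(580, 630)])
        counts, stats = count_3prime_window([inside, straddling], ann)
        assert counts["g1"] == 1
        assert stats.uncounted == 1

    def test_invariant_under_5prime_elongation(self):
        gene = make_gene(exons=[(500, 1500)])
        longer = make_gene(exons=[(100, 1500)])  # 400 extra 5' bases
        assert three_prime_window_blocks(gene) == three_prime_window_blocks(longer)
        minus = make_gene(strand="-", exons=[(500, 1500)])
        minus_longer = make_gene(strand="-", exons=[(500, 1900)])
        assert (three_prime_window_blocks(minus)
                == three_prime_window_blocks(minus_longer))


class TestNormalize:
    def test_single_gene_full_mass_gives_one_million(self):
        m = CountMatrix.from_columns({"s1": pd.Series({"g1": 123})})
        assert normalize(m).loc["g1", "s1"] == pytest.approx(1e6)

    def test_scale_invariance_and_column_sums(self):
        counts = pd.DataFrame({"s1": [10, 30, 60], "s2": [5, 5, 0]},
                              index=["g1", "g2", "g3"])
        m = CountMatrix.from_columns({c: counts[c] for c in counts})
        norm = normalize(m)
        doubled = CountMatrix.from_columns({c: counts[c] * 2 for c in counts})
        pd.testing.assert_frame_equal(norm, normalize(doubled))
        assert norm.sum(axis=0).round(6).eq(1e6).all()

    def test_zero_total_raises(self):
        m = CountMatrix.from_columns({"s1": pd.Series({"g1": 0})})
        with pytest.raises(LmseqError):
            normalize(m)

    def test_tsv_round_trip(self, tmp_path):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]}, index=["g1", "g2"])
        counts.index.name = "gene_id"
        m = CountMatrix.from_columns({c: counts[c] for c in counts})
        path = tmp_path / "counts.tsv"
        m.write(str(path))
        back = CountMatrix.read(str(path))
        pd.testing.assert_frame_equal(back.counts, m.counts)
        assert back.total_counted.tolist() == m.total_counted.tolist()
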