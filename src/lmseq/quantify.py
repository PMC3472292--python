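"""Gene-level read counting with the stringent both-ends rule.

A read is counted for a gene only when it is > 34 bases long, primary and
uniquely mapped, and **both** of its terminal aligned bases fall inside the
gene's exonic footprint (CDS plus annotated UTRs).  Internal blocks are
unconstrained, so spliced reads over a gene's introns count normally.  The
rule deliberately drops reads straddling a feature boundary — the price
paid is that genes with unannotated 3' UTRs lose reads, which is exactly
why UTR modeling precedes counting in the pipeline.

``count_3prime_window`` restricts counting to reads falling 100–400 bases
from the transcript 3' end (strand-aware, projected through the exon
chain), which makes counts insensitive to transcript length and to the 5'
loss introduced by linear RNA amplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import AlignedRead, GeneModel, GenomeAnnotation, Interval, LmseqError

DEFAULT_MIN_READ_LEN = 35  # "> 34 bases"
DEFAULT_WINDOW = (100, 400)


@dataclass
class CountingStats:
    """Where the reads of one sample went during counting."""

    counted: int = 0
    ambiguous: int = 0
    uncounted: int = 0
    skipped_short: int = 0
    skipped_nonunique: int = 0


@dataclass
class RegionTally:
    """Region classification of one sample's counted primary alignments."""

    reads_exonic: int = 0
    reads_intronic: int = 0
    reads_intergenic: int = 0
    reads_ambiguous: int = 0
    reads_skipped_short: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_exonic": self.reads_exonic,
            "reads_intronic": self.reads_intronic,
            "reads_intergenic": self.reads_intergenic,
            "reads_ambiguous": self.reads_ambiguous,
            "reads_skipped_short": self.reads_skipped_short,
        }


@dataclass
class CountMatrix:
    """Gene x sample raw counts plus per-sample counted-read totals.

    ``total_counted`` is defined as the column sum of the matrix, so the
    normalization below is self-contained ("counts per million counted
    reads").
    """

    counts: pd.DataFrame
    total_counted: pd.Series

    @classmethod
    def from_columns(cls, columns: dict[str, pd.Series]) -> "CountMatrix":
        counts = pd.DataFrame(columns).fillna(0).astype(int)
        counts.index.name = "gene_id"
        return cls(counts=counts, total_counted=counts.sum(axis=0))

    def normalize(self) -> pd.DataFrame:
        return normalize(self)

    def write(self, path: str) -> None:
        from .io_formats import write_counts

        write_counts(self.counts, self.total_counted, path)

    @classmethod
    def read(cls, path: str) -> "CountMatrix":
        from .io_formats import read_counts

        counts, totals = read_counts(path)
        return cls(counts=counts.astype(int), total_counted=totals.astype(int))


def _exon_trees(annotation: GenomeAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in annotation.contigs}
    for gene in annotation.genes:
        for s, e in gene.exons:
            trees[gene.contig][s:e] = gene.gene_id
    return trees


def _span_trees(annotation: GenomeAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in annotation.contigs}
    for gene in annotation.genes:
        trees[gene.contig][gene.start:gene.end] = gene.gene_id
    return trees


def _genes_at(trees: dict[str, IntervalTree], contig: str, pos: int) -> set[str]:
    tree = trees.get(contig)
    if tree is None:
        return set()
    return {iv.data for iv in tree[pos]}


def count_features(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
) -> tuple[pd.Series, CountingStats]:
    """Both-ends gene counts for one sample.

    Returns a Series over all annotated genes (zero-filled) and the
    bookkeeping of ambiguous/uncounted/skipped reads.
    """
    trees = _exon_trees(annotation)
    counts = {g.gene_id: 0 for g in annotation.genes}
    stats = CountingStats()
    for read in reads:
        if not (read.is_primary and read.is_unique):
            stats.skipped_nonunique += 1
            continue
        if read.read_length < min_read_len:
            stats.skipped_short += 1
            continue
        first = read.blocks[0][0]
        last = read.blocks[-1][1] - 1
        hits = _genes_at(trees, read.contig, first) & _genes_at(
            trees, read.contig, last
        )
        if len(hits) == 1:
            counts[hits.pop()] += 1
            stats.counted += 1
        elif len(hits) > 1:
            stats.ambiguous += 1
        else:
            stats.uncounted += 1
    series = pd.Series(counts, name="count")
    series.index.name = "gene_id"
    return series, stats


def classify_regions(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
) -> RegionTally:
    """Assign each primary unique alignment to exon/intron/intergenic.

    The category is decided by the majority of aligned bases, with ties
    broken exon > intron > intergenic.  A read whose genic bases are split
    across two or more genes with no gene holding a strict majority of its
    aligned bases is ambiguous.
    """
    exon_trees = _exon_trees(annotation)
    span_trees = _span_trees(annotation)
    tally = RegionTally()
    for read in reads:
        if not (read.is_primary and read.is_unique):
            continue
        if read.read_length < min_read_len:
            tally.reads_skipped_short += 1
            continue
        total = read.aligned_length
        exon_by_gene: dict[str, int] = {}
        genic_by_gene: dict[str, int] = {}
        for s, e in read.blocks:
            for iv in exon_trees[read.contig].overlap(s, e):
                n = min(e, iv.end) - max(s, iv.begin)
                exon_by_gene[iv.data] = exon_by_gene.get(iv.data, 0) + n
            for iv in span_trees[read.contig].overlap(s, e):
                n = min(e, iv.end) - max(s, iv.begin)
                genic_by_gene[iv.data] = genic_by_gene.get(iv.data, 0) + n
        if len(genic_by_gene) >= 2 and max(genic_by_gene.values()) * 2 <= total:
            tally.reads_ambiguous += 1
            continue
        exon_bases = sum(exon_by_gene.values())
        genic_bases = sum(genic_by_gene.values())
        intron_bases = genic_bases - exon_bases
        intergenic_bases = total - genic_bases
        best = max(
            [(exon_bases, 3, "exon"), (intron_bases, 2, "intron"),
             (intergenic_bases, 1, "intergenic")],
        )[2]
        if best == "exon":
            tally.reads_exonic += 1
        elif best == "intron":
            tally.reads_intronic += 1
        else:
            tally.reads_intergenic += 1
    return tally


def three_prime_window_blocks(
    gene: GeneModel, window: tuple[int, int] = DEFAULT_WINDOW
) -> list[Interval]:
    """Genomic blocks of the transcript interval [window) from the 3' end.

    Distances are measured on the spliced transcript; transcripts shorter
    than the far edge use [near, length), and transcripts of at most
    ``near`` bases have an empty window.
    """
    near, far = window
    L = gene.transcript_length
    lo = max(0, L - far)
    hi = L - near
    if hi <= lo:
        return []
    return gene.transcript_to_genomic(lo, hi)


def count_3prime_window(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    window: tuple[int, int] = DEFAULT_WINDOW,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
) -> tuple[pd.Series, CountingStats]:
    """Both-ends counts restricted to each gene's 3'-end window."""
    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in annotation.contigs}
    for gene in annotation.genes:
        for s, e in three_prime_window_blocks(gene, window):
            trees[gene.contig][s:e] = gene.gene_id
    counts = {g.gene_id: 0 for g in annotation.genes}
    stats = CountingStats()
    for read in reads:
        if not (read.is_primary and read.is_unique):
            stats.skipped_nonunique += 1
            continue
        if read.read_length < min_read_len:
            stats.skipped_short += 1
            continue
        first = read.blocks[0][0]
        last = read.blocks[-1][1] - 1
        hits = _genes_at(trees, read.contig, first) & _genes_at(
            trees, read.contig, last
        )
        if len(hits) == 1:
            counts[hits.pop()] += 1
            stats.counted += 1
        elif len(hits) > 1:
            stats.ambiguous += 1
        else:
            stats.uncounted += 1
    series = pd.Series(counts, name="count")
    series.index.name = "gene_id"
    return series, stats


def normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million counted reads: counts / total_counted * 1e6."""
    totals = matrix.total_counted.astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise LmseqError(f"cannot normalize samples with zero counted reads: {bad}")
    return matrix.counts.div(totals, axis=1) * 1e6
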