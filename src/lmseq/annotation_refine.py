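"""Coverage- and junction-based refinement of gene annotations.

Two kinds of evidence are distilled from mapped reads:

* per-base read coverage, used to model 5'/3' UTRs by walking outward from
  each gene's annotated terminus while coverage stays above a threshold
  (short gaps tolerated when flanked by covered runs);
* splice junctions (block gaps of spliced reads), used to confirm annotated
  introns, shift mis-placed intron boundaries, and split exons that hide an
  unannotated intron.  Junctions outside all genes are reported as
  candidates only — novel gene calling stays a manual step.

UTRs are modeled on genomic coordinates; a UTR that itself contains an
intron is recovered as its genomic extent (a documented simplification).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .models import AlignedRead, GeneModel, GenomeAnnotation, Interval, LmseqError

DEFAULT_MIN_COV = 2
DEFAULT_MAX_GAP = 10
DEFAULT_MAX_EXTENT = 2000
DEFAULT_MIN_SUPPORT = 2


@dataclass
class CoverageTrack:
    """Per-contig, per-base count of overlapping read match blocks."""

    contigs: dict[str, np.ndarray]

    @property
    def total_bases(self) -> int:
        return int(sum(arr.sum() for arr in self.contigs.values()))

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.contigs[contig]


@dataclass(frozen=True)
class SpliceJunction:
    """A donor/acceptor pair; the interval [donor_end, acceptor_start) is the intron."""

    contig: str
    donor_end: int
    acceptor_start: int
    support: int

    @property
    def interval(self) -> Interval:
        return (self.donor_end, self.acceptor_start)


@dataclass(frozen=True)
class UtrCall:
    gene_id: str
    side: str  # "5'" or "3'"
    interval: Interval
    mean_coverage: float

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class UtrSummary:
    """Per-gene UTR status counts mirroring the four reporting categories."""

    n_genes: int = 0
    both: int = 0
    only5: int = 0
    only3: int = 0
    none: int = 0
    median_utr5: float = float("nan")
    median_utr3: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "n_genes": self.n_genes, "both": self.both, "only5": self.only5,
            "only3": self.only3, "none": self.none,
            "median_utr5": self.median_utr5, "median_utr3": self.median_utr3,
        }


@dataclass
class RefinementReport:
    confirmed: int = 0
    adjusted: int = 0
    novel_internal: int = 0
    outside: int = 0
    rejected: int = 0
    unsupported: int = 0
    candidates: list[SpliceJunction] = field(default_factory=list)


def build_coverage(
    reads: Iterable[AlignedRead], contigs: dict[str, int]
) -> CoverageTrack:
    """Accumulate match-block coverage from primary, unique alignments.

    Splice skips contribute nothing; multi-mapped and secondary alignments
    are ignored so the track matches what the counting stage would see.
    """
    arrays = {name: np.zeros(length, dtype=np.int32) for name, length in contigs.items()}
    for read in reads:
        if not (read.is_primary and read.is_unique):
            continue
        if read.contig not in arrays:
            raise LmseqError(f"read {read.read_id}: unknown contig {read.contig}")
        arr = arrays[read.contig]
        for start, end in read.blocks:
            if start < 0 or end > len(arr):
                raise LmseqError(
                    f"read {read.read_id}: block [{start},{end}) outside contig"
                )
            arr[start:end] += 1
    return CoverageTrack(arrays)


def extract_junctions(reads: Iterable[AlignedRead]) -> list[SpliceJunction]:
    """Aggregate block gaps of spliced reads into supported junctions."""
    support: dict[tuple[str, int, int], int] = {}
    for read in reads:
        if not (read.is_primary and read.is_unique) or len(read.blocks) < 2:
            continue
        for left, right in zip(read.blocks, read.blocks[1:]):
            key = (read.contig, left[1], right[0])
            support[key] = support.get(key, 0) + 1
    return [
        SpliceJunction(contig, donor, acceptor, count)
        for (contig, donor, acceptor), count in sorted(support.items())
    ]


def _neighbor_limits(annotation: GenomeAnnotation) -> dict[str, tuple[int, int]]:
    """For each gene: furthest allowed extension (left_limit, right_limit)."""
    limits: dict[str, tuple[int, int]] = {}
    for contig, length in annotation.contigs.items():
        genes = annotation.genes_on(contig)
        for i, gene in enumerate(genes):
            left = genes[i - 1].end if i > 0 else 0
            right = genes[i + 1].start if i + 1 < len(genes) else length
            limits[gene.gene_id] = (left, right)
    return limits


def _walk(cov: np.ndarray, start: int, step: int, limit: int,
          min_cov: int, max_gap: int) -> Optional[int]:
    """Walk from ``start`` in direction ``step`` while coverage holds up.

    ``limit`` is the first disallowed position.  Returns the furthest
    position with coverage >= min_cov (gaps <= max_gap bases are crossed
    only when covered bases follow), or None if no covered base was found.
    """
    pos = start
    last_good: Optional[int] = None
    gap = 0
    while pos != limit and 0 <= pos < len(cov):
        if cov[pos] >= min_cov:
            last_good = pos
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
        pos += step
    return last_good


def model_utrs(
    annotation: GenomeAnnotation,
    coverage: CoverageTrack,
    min_cov: int = DEFAULT_MIN_COV,
    max_gap: int = DEFAULT_MAX_GAP,
    max_extent: int = DEFAULT_MAX_EXTENT,
) -> tuple[list[UtrCall], UtrSummary]:
    """Model UTRs by extending each gene terminus through covered bases.

    For each gene and side, the walk starts just outside the annotated exon
    footprint and continues while coverage >= ``min_cov``, tolerating at
    most ``max_gap`` consecutive sub-threshold bases (included only when
    flanked by covered runs), stopping at ``max_extent`` or the nearest
    neighbouring gene.  A side yields a call when the extension is >= 1 base.
    """
    limits = _neighbor_limits(annotation)
    calls: list[UtrCall] = []
    summary = UtrSummary(n_genes=len(annotation.genes))
    lengths5: list[int] = []
    lengths3: list[int] = []
    for gene in annotation.genes:
        cov = coverage[gene.contig]
        left_limit, right_limit = limits[gene.gene_id]
        side_for = {"left": "5'" if gene.strand == "+" else "3'",
                    "right": "3'" if gene.strand == "+" else "5'"}
        found: dict[str, UtrCall] = {}
        # leftward walk from the left terminus
        start = gene.start - 1
        limit = max(left_limit, gene.start - max_extent) - 1
        hit = _walk(cov, start, -1, limit, min_cov, max_gap)
        if hit is not None:
            interval = (hit, gene.start)
            mean_cov = float(cov[interval[0]:interval[1]].mean())
            found[side_for["left"]] = UtrCall(gene.gene_id, side_for["left"],
                                              interval, mean_cov)
        # rightward walk from the right terminus
        start = gene.end
        limit = min(right_limit, gene.end + max_extent)
        hit = _walk(cov, start, +1, limit, min_cov, max_gap)
        if hit is not None:
            interval = (gene.end, hit + 1)
            mean_cov = float(cov[interval[0]:interval[1]].mean())
            found[side_for["right"]] = UtrCall(gene.gene_id, side_for["right"],
                                               interval, mean_cov)
        has5, has3 = "5'" in found, "3'" in found
        if has5 and has3:
            summary.both += 1
        elif has5:
            summary.only5 += 1
        elif has3:
            summary.only3 += 1
        else:
            summary.none += 1
        for call in found.values():
            calls.append(call)
            (lengths5 if call.side == "5'" else lengths3).append(call.length)
    if lengths5:
        summary.median_utr5 = float(np.median(lengths5))
    if lengths3:
        summary.median_utr3 = float(np.median(lengths3))
    return calls, summary


def apply_utr_calls(
    annotation: GenomeAnnotation, calls: Iterable[UtrCall]
) -> GenomeAnnotation:
    """Extend gene models with modeled UTRs (terminal exons grow outward)."""
    by_gene: dict[str, dict[str, UtrCall]] = {}
    for call in calls:
        by_gene.setdefault(call.gene_id, {})[call.side] = call
    genes: list[GeneModel] = []
    for gene in annotation.genes:
        sides = by_gene.get(gene.gene_id)
        if not sides:
            genes.append(gene)
            continue
        exons = list(gene.exons)
        utr5, utr3 = gene.utr5, gene.utr3
        for side, call in sides.items():
            s, e = call.interval
            if e == gene.start:  # left extension
                exons[0] = (s, exons[0][1])
            elif s == gene.end:  # right extension
                exons[-1] = (exons[-1][0], e)
            else:
                raise LmseqError(f"UTR call for {gene.gene_id} does not abut the gene")
            if side == "5'":
                utr5 = (s, e)
            else:
                utr3 = (s, e)
        refined = replace(gene, exons=tuple(exons), utr5=utr5, utr3=utr3)
        refined.validate()
        genes.append(refined)
    out = GenomeAnnotation(contigs=dict(annotation.contigs), genes=genes)
    out.validate()
    return out


def utr_summary_table(summary: UtrSummary) -> pd.DataFrame:
    """The four-category UTR summary as a small table with percentages."""
    n = max(summary.n_genes, 1)
    rows = [
        ("both UTRs found", summary.both),
        ("only 5' UTR found", summary.only5),
        ("only 3' UTR found", summary.only3),
        ("no UTR found", summary.none),
    ]
    return pd.DataFrame(
        [(cat, count, 100.0 * count / n) for cat, count in rows],
        columns=["category", "n_genes", "percent"],
    )


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def refine_gene_models(
    annotation: GenomeAnnotation,
    junctions: Iterable[SpliceJunction],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> tuple[GenomeAnnotation, RefinementReport]:
    """Confirm, adjust or add introns from splice-junction evidence.

    Per gene: a junction identical to an annotated intron confirms it; a
    junction with support >= ``min_support`` overlapping an intron replaces
    that intron; a junction fully inside an exon splits it.  Any change that
    would produce an empty exon is rejected and the gene left unchanged.
    Junctions outside all gene spans become candidates for manual curation.
    """
    report = RefinementReport()
    by_contig: dict[str, list[SpliceJunction]] = {}
    for j in junctions:
        by_contig.setdefault(j.contig, []).append(j)

    genes_out: list[GeneModel] = []
    claimed: set[tuple[str, int, int]] = set()
    for gene in annotation.sorted_genes():
        gene_junctions = [
            j for j in by_contig.get(gene.contig, [])
            if gene.start <= j.donor_end and j.acceptor_start <= gene.end
        ]
        introns = list(gene.introns)
        for j in gene_junctions:
            claimed.add((j.contig, j.donor_end, j.acceptor_start))
            if j.interval in introns:
                report.confirmed += 1
                continue
            if j.support < min_support:
                report.unsupported += 1
                continue
            overlapping = [i for i in introns if _overlaps(i, j.interval)]
            if overlapping:
                candidate = [i for i in introns if i not in overlapping[:1]]
                candidate.append(j.interval)
                candidate.sort()
                if _intron_chain_valid(gene.span, candidate):
                    introns = candidate
                    report.adjusted += 1
                else:
                    report.rejected += 1
            else:
                # fully inside an exon (no intron overlap, inside the span)
                candidate = sorted(introns + [j.interval])
                if _intron_chain_valid(gene.span, candidate):
                    introns = candidate
                    report.novel_internal += 1
                else:
                    report.rejected += 1
        refined = gene.with_introns(tuple(sorted(introns)))
        try:
            refined.validate()
        except ValueError:
            # e.g. a new intron swallowed a CDS endpoint
            report.rejected += 1
            refined = gene
        genes_out.append(refined)

    for contig, js in sorted(by_contig.items()):
        for j in js:
            if (j.contig, j.donor_end, j.acceptor_start) not in claimed:
                report.outside += 1
                report.candidates.append(j)
    out = GenomeAnnotation(contigs=dict(annotation.contigs), genes=genes_out)
    out.validate()
    return out, report


def _intron_chain_valid(span: Interval, introns: list[Interval]) -> bool:
    """All resulting exons must have length >= 1 and introns must not touch."""
    start, end = span
    cursor = start
    for a, b in introns:
        if a - cursor < 1 or b <= a:
            return False
        cursor = b
    return end - cursor >= 1


def junction_table(junctions: Iterable[SpliceJunction]) -> pd.DataFrame:
    return pd.DataFrame(
        [(j.contig, j.donor_end, j.acceptor_start, j.support) for j in junctions],
        columns=["contig", "donor_end", "acceptor_start", "support"],
    )
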