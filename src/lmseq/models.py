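"""Core domain types shared by all pipeline stages.

All coordinates are 0-based half-open genomic intervals on the internal
side; conversion to/from the 1-based closed GFF convention happens only in
:mod:`lmseq.io_formats`.  The data model is unstranded at the read level
(oligo-dT primed and twice-amplified libraries carry no usable strand
information); gene strand is used only to decide which end of a gene is
its 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

Interval = tuple[int, int]


class LmseqError(Exception):
    """Base class for all package errors."""


class ParseError(LmseqError):
    """A structured error while reading an input file."""


class ConfigError(LmseqError):
    """Invalid configuration or inconsistent inputs."""


def _check_sorted_disjoint(intervals: tuple[Interval, ...], what: str) -> None:
    prev_end = None
    for start, end in intervals:
        if end <= start:
            raise ValueError(f"{what}: empty or inverted interval [{start},{end})")
        if prev_end is not None and start < prev_end:
            raise ValueError(f"{what}: intervals overlap or are unsorted at [{start},{end})")
        prev_end = end


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene model.

    ``exons`` span the full mRNA footprint (UTRs included where annotated);
    ``cds`` is the genomic span of the coding sequence.  ``utr5``/``utr3``
    are genomic intervals abutting the CDS on the strand-appropriate side.
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: tuple[Interval, ...]
    cds: Interval
    utr5: Optional[Interval] = None
    utr3: Optional[Interval] = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons, as genomic intervals."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has no exons")
        _check_sorted_disjoint(self.exons, self.gene_id)
        cs, ce = self.cds
        if ce <= cs:
            raise ValueError(f"{self.gene_id}: empty CDS")
        # CDS endpoints must land inside exons (the CDS span may bridge introns)
        if not (self._in_exon(cs) and self._in_exon(ce - 1)):
            raise ValueError(f"{self.gene_id}: CDS endpoints outside exons")
        five_left = self.strand == "+"
        if self.utr5 is not None:
            s, e = self.utr5
            ok = (e == cs) if five_left else (s == ce)
            if not ok:
                raise ValueError(f"{self.gene_id}: 5' UTR does not abut the CDS")
        if self.utr3 is not None:
            s, e = self.utr3
            ok = (s == ce) if five_left else (e == cs)
            if not ok:
                raise ValueError(f"{self.gene_id}: 3' UTR does not abut the CDS")

    def _in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def strip_utrs(self) -> "GeneModel":
        """Copy of this gene with exons clipped to the CDS span, UTRs removed."""
        cs, ce = self.cds
        clipped = tuple(
            (max(s, cs), min(e, ce)) for s, e in self.exons if e > cs and s < ce
        )
        return replace(self, exons=clipped, utr5=None, utr3=None)

    def with_introns(self, introns: tuple[Interval, ...]) -> "GeneModel":
        """Copy with the same span but a new intron chain (exons rebuilt)."""
        start, end = self.span
        exons = []
        cursor = start
        for a, b in sorted(introns):
            exons.append((cursor, a))
            cursor = b
        exons.append((cursor, end))
        return replace(self, exons=tuple(exons))

    def transcript_to_genomic(self, tstart: int, tend: int) -> list[Interval]:
        """Project a transcript-coordinate interval to genomic blocks.

        Transcript coordinate 0 is the 5' end of the mRNA, so for '-' strand
        genes the projection walks the exon chain from right to left.
        Returns genomic intervals sorted by start.
        """
        if not (0 <= tstart < tend <= self.transcript_length):
            raise ValueError(
                f"{self.gene_id}: transcript interval [{tstart},{tend}) out of range"
            )
        blocks: list[Interval] = []
        cursor = 0  # transcript offset consumed so far
        exon_iter = self.exons if self.strand == "+" else reversed(self.exons)
        for s, e in exon_iter:
            length = e - s
            lo = max(tstart, cursor)
            hi = min(tend, cursor + length)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + (lo - cursor), s + (hi - cursor)))
                else:
                    blocks.append((e - (hi - cursor), e - (lo - cursor)))
            cursor += length
            if cursor >= tend:
                break
        return sorted(blocks)


@dataclass
class GenomeAnnotation:
    """A genome's contigs plus its single-transcript gene models."""

    contigs: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for gene in self.genes:
            if gene.gene_id in seen:
                raise ValueError(f"duplicate gene id {gene.gene_id}")
            seen.add(gene.gene_id)
            if gene.contig not in self.contigs:
                raise ValueError(f"{gene.gene_id}: unknown contig {gene.contig}")
            gene.validate()
            if gene.start < 0 or gene.end > self.contigs[gene.contig]:
                raise ValueError(f"{gene.gene_id}: exons outside contig bounds")

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def genes_on(self, contig: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes if g.contig == contig), key=lambda g: g.start
        )

    def sorted_genes(self) -> list[GeneModel]:
        return sorted(self.genes, key=lambda g: (g.contig, g.start, g.gene_id))


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read as ordered genomic match blocks.

    Gaps between consecutive blocks are splice skips (CIGAR N); insertions
    and soft clips consume read bases only and are represented implicitly by
    ``read_length`` exceeding the summed block length.
    """

    read_id: str
    contig: str
    blocks: tuple[Interval, ...]
    read_length: int
    is_unique: bool = True
    is_primary: bool = True

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def validate(self) -> None:
        if self.read_length <= 0:
            raise ValueError(f"{self.read_id}: non-positive read length")
        _check_sorted_disjoint(self.blocks, self.read_id)


@dataclass(frozen=True)
class ReadRecord:
    """A raw sequencing read with Sanger-scale phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)
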