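"""Readers and writers for GFF3, SAM, FASTA, FASTQ and TSV count tables.

One fixed coordinate convention: everything in memory is 0-based half-open;
the 1-based closed GFF convention is converted exactly at the file boundary
(``start - 1`` on read, ``start + 1`` on write).  SAM parsing is delegated
to :mod:`pysam`; the block decomposition (M/D extend a block, N splits it,
I/S consume read bases only) is done here so the contract is explicit.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Iterator, Optional

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AlignedRead,
    GeneModel,
    GenomeAnnotation,
    Interval,
    ParseError,
    ReadRecord,
)

# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    The gene -> mRNA -> exon/CDS/UTR hierarchy is resolved through Parent
    attributes.  Genes are treated as single-transcript: when several mRNAs
    are attached to one gene the first (by coordinate, then ID) is used and
    a warning is emitted.  Contig lengths come from ``##sequence-region``
    directives when present, otherwise from the rightmost feature end.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    contigs: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 3:
            contigs[parts[1]] = int(parts[3]) if len(parts) > 3 else int(parts[2])

    # orphan check: every sub-feature must reach a gene through Parent links
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise ParseError(
                    f"feature references missing Parent {parent_id!r}: {feat}"
                )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = sorted(
            db.children(gene, featuretype="mRNA"), key=lambda f: (f.start, f.id)
        )
        if not mrnas:
            raise ParseError(f"gene {gene.id} has no mRNA child")
        if len(mrnas) > 1:
            warnings.warn(
                f"gene {gene.id} has {len(mrnas)} mRNA isoforms; using {mrnas[0].id}",
                stacklevel=2,
            )
        mrna = mrnas[0]

        def _intervals(ftype: str) -> list[Interval]:
            return sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype=ftype)
            )

        exons = _intervals("exon")
        cds_parts = _intervals("CDS")
        if not exons:
            raise ParseError(f"mRNA {mrna.id} has no exon children")
        if not cds_parts:
            raise ParseError(f"mRNA {mrna.id} has no CDS children")
        cds = (cds_parts[0][0], cds_parts[-1][1])
        utr5_parts = _intervals("five_prime_UTR")
        utr3_parts = _intervals("three_prime_UTR")
        utr5 = (utr5_parts[0][0], utr5_parts[-1][1]) if utr5_parts else None
        utr3 = (utr3_parts[0][0], utr3_parts[-1][1]) if utr3_parts else None
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
        )
        contigs.setdefault(gene.seqid, 0)
        contigs[gene.seqid] = max(contigs[gene.seqid], gene.end)
    annotation = GenomeAnnotation(contigs=contigs, genes=genes)
    annotation.validate()
    return annotation


def write_gff(annotation: GenomeAnnotation, path: str) -> None:
    """Write a deterministic GFF3 (sorted by contig, start, gene_id)."""

    def line(contig, source, ftype, start, end, strand, attrs) -> str:
        return "\t".join(
            [contig, source, ftype, str(start + 1), str(end), ".", strand, ".", attrs]
        )

    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for contig in sorted(annotation.contigs):
            out.write(f"##sequence-region {contig} 1 {annotation.contigs[contig]}\n")
        for gene in annotation.sorted_genes():
            gid = gene.gene_id
            mid = f"{gid}.t1"
            rows = [
                line(gene.contig, "lmseq", "gene", gene.start, gene.end, gene.strand,
                     f"ID={gid}"),
                line(gene.contig, "lmseq", "mRNA", gene.start, gene.end, gene.strand,
                     f"ID={mid};Parent={gid}"),
            ]
            for i, (s, e) in enumerate(gene.exons, start=1):
                rows.append(
                    line(gene.contig, "lmseq", "exon", s, e, gene.strand,
                         f"ID={mid}.exon{i};Parent={mid}")
                )
            cs, ce = gene.cds
            for i, (s, e) in enumerate(gene.exons, start=1):
                lo, hi = max(s, cs), min(e, ce)
                if lo < hi:
                    rows.append(
                        line(gene.contig, "lmseq", "CDS", lo, hi, gene.strand,
                             f"ID={mid}.cds{i};Parent={mid}")
                    )
            if gene.utr5 is not None:
                rows.append(
                    line(gene.contig, "lmseq", "five_prime_UTR", gene.utr5[0],
                         gene.utr5[1], gene.strand, f"ID={mid}.utr5;Parent={mid}")
                )
            if gene.utr3 is not None:
                rows.append(
                    line(gene.contig, "lmseq", "three_prime_UTR", gene.utr3[0],
                         gene.utr3[1], gene.strand, f"ID={mid}.utr3;Parent={mid}")
                )
            out.write("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# SAM

_QUERY_OPS = {0, 1, 4, 7, 8}  # M, I, S, =, X consume read bases
_ALLOWED_OPS = {0, 1, 2, 3, 4, 7, 8}  # M I D N S = X
_OP_NAMES = "MIDNSHP=X"


def blocks_from_cigartuples(
    cigartuples: Iterable[tuple[int, int]], pos: int, read_id: str = "?"
) -> tuple[tuple[Interval, ...], int]:
    """Decompose CIGAR operations into genomic match blocks.

    M/D (and =/X) extend the current block on the reference, N closes the
    block and opens a new one after the skip, I/S consume read bases only.
    Returns ``(blocks, read_length)``.
    """
    blocks: list[Interval] = []
    ref = pos
    block_start: Optional[int] = None
    read_len = 0
    for op, n in cigartuples:
        if op not in _ALLOWED_OPS:
            name = _OP_NAMES[op] if op < len(_OP_NAMES) else str(op)
            raise ParseError(f"read {read_id}: unsupported CIGAR op {name!r}")
        if op in (0, 7, 8):  # M, =, X
            if block_start is None:
                block_start = ref
            ref += n
            read_len += n
        elif op == 2:  # D
            if block_start is None:
                block_start = ref
            ref += n
        elif op == 3:  # N
            if block_start is not None:
                blocks.append((block_start, ref))
                block_start = None
            ref += n
        else:  # I, S
            read_len += n
    if block_start is not None:
        blocks.append((block_start, ref))
    return tuple(blocks), read_len


def read_sam(path: str) -> Iterator[AlignedRead]:
    """Stream mapped reads from a text SAM file as :class:`AlignedRead`.

    A read is unique when its NH tag is 1, or — if NH is absent — when
    MAPQ > 3 (older splice mappers encode multi-mapping in MAPQ).
    Secondary/supplementary alignments are flagged non-primary.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            blocks, read_len = blocks_from_cigartuples(
                seg.cigartuples or [], seg.reference_start, seg.query_name
            )
            if seg.has_tag("NH"):
                unique = seg.get_tag("NH") == 1
            else:
                unique = seg.mapping_quality > 3
            yield AlignedRead(
                read_id=seg.query_name,
                contig=seg.reference_name,
                blocks=blocks,
                read_length=read_len,
                is_unique=unique,
                is_primary=not (seg.is_secondary or seg.is_supplementary),
            )


def read_sam_contigs(path: str) -> dict[str, int]:
    """Contig name -> length map from the SAM header."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        return dict(zip(sam.references, sam.lengths))


def write_sam(
    path: str,
    alignments: Iterable[AlignedRead],
    records: Iterable[ReadRecord],
    contigs: dict[str, int],
) -> None:
    """Write paired alignments/records as a text SAM file (flag 0, NH:i:1)."""
    names = sorted(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": contigs[n]} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for aln, rec in zip(alignments, records):
            if aln.read_id != rec.read_id:
                raise ValueError("alignment/record streams out of sync")
            seg = pysam.AlignedSegment()
            seg.query_name = aln.read_id
            seg.query_sequence = rec.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rec.qualities)
            )
            seg.flag = 0
            seg.reference_id = tid[aln.contig]
            seg.reference_start = aln.blocks[0][0]
            seg.mapping_quality = 50
            cigar: list[tuple[int, int]] = []
            prev_end = None
            for s, e in aln.blocks:
                if prev_end is not None:
                    cigar.append((3, s - prev_end))
                cigar.append((0, e - s))
                prev_end = e
            seg.cigartuples = cigar
            seg.set_tag("NH", 1)
            out.write(seg)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str) -> Iterator[ReadRecord]:
    """Stream a Sanger-encoded (+33) FASTQ file."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield ReadRecord(
                read_id=rec.description or rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ParseError(f"{path}: {exc}") from exc


def write_fastq(records: Iterable[ReadRecord], path: str) -> None:
    with open(path, "w") as out:
        for rec in records:
            quals = "".join(chr(q + 33) for q in rec.qualities)
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{quals}\n")


# ---------------------------------------------------------------------------
# TSV count tables

TOTALS_ROW = "_total_counted"


def write_counts(counts: pd.DataFrame, totals: pd.Series, path: str) -> None:
    """Write a gene x sample table with a trailing per-sample totals row."""
    table = counts.copy()
    table.loc[TOTALS_ROW] = totals
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str) -> tuple[pd.DataFrame, pd.Series]:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    if TOTALS_ROW not in table.index:
        raise ParseError(f"{path}: missing {TOTALS_ROW} row")
    totals = table.loc[TOTALS_ROW]
    counts = table.drop(index=TOTALS_ROW)
    return counts, totals
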