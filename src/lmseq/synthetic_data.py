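"""Synthetic genomes, annotations and RNA-seq samples with known truth.

The generator emulates the two library types of a laser-microdissection
fruiting-body study:

* ``uniform`` samples — total-mycelium-like libraries whose reads start
  uniformly along the spliced transcript;
* ``three_prime`` samples — LM-like libraries made from two rounds of
  linear (T7) RNA amplification, whose reads cluster towards the 3' end.
  The 3' bias is modeled as a truncated exponential of the read 3'-end
  distance from the transcript 3' end (scale ``bias_decay``), a stand-in
  for the unknown functional form of the amplification's 5' loss.

Genes carry known UTR extents and GT..AG introns; reads are emitted with
their true spliced alignment (the mapping stage is bypassed), so every
downstream stage can be scored against ground truth.  Two biological
replicates per condition is the default, matching the study design.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .models import (
    AlignedRead,
    ConfigError,
    GeneModel,
    GenomeAnnotation,
    ReadRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    Lengths are in bases.  ``bias_decay`` is the exponential scale of the
    read 3'-end distance from the transcript 3' end for ``three_prime``
    samples.  Expression levels are log-normal(``expr_mu``, ``expr_sigma``)
    per gene; a fraction ``de_fraction`` of genes changes ``de_fold_change``-
    fold (direction random) in conditions after the first.
    """

    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 120_000
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (1, 4)
    cds_exon_length: tuple[int, int] = (150, 500)
    intron_length: tuple[int, int] = (50, 120)
    utr5_length: tuple[int, int] = (50, 260)
    utr3_length: tuple[int, int] = (100, 420)
    intergenic_gap_min: int = 500
    n_conditions: int = 2
    replicates_per_condition: int = 2
    reads_per_sample: int = 50_000
    read_length: int = 50
    bias_mode: str = "uniform"
    bias_decay: float = 150.0
    expr_mu: float = 1.0
    expr_sigma: float = 1.0
    de_fraction: float = 0.1
    de_fold_change: float = 16.0
    de_direction: str = "both"  # "both", "up" or "down" (relative to cond 1)
    noise: str = "poisson"  # or "nb"
    nb_dispersion: float = 0.05
    quality_baseline: int = 38
    quality_slope: float = 0.1  # phred lost per base towards the read 3' end
    n_rate: float = 0.002

    def validate(self) -> None:
        for name in ("exons_per_gene", "cds_exon_length", "intron_length",
                     "utr5_length", "utr3_length"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must be a positive (lo, hi) range")
        if self.intron_length[0] < 5:
            raise ConfigError("introns shorter than 5 bases cannot carry splice motifs")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must be in [0, 1]")
        if self.bias_mode not in ("uniform", "three_prime"):
            raise ConfigError(f"unknown bias_mode {self.bias_mode!r}")
        if self.noise not in ("poisson", "nb"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        if self.de_direction not in ("both", "up", "down"):
            raise ConfigError(f"unknown de_direction {self.de_direction!r}")
        for name in ("n_contigs", "contig_length", "n_genes", "intergenic_gap_min",
                     "n_conditions", "replicates_per_condition", "reads_per_sample",
                     "read_length"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of one simulated genome."""

    annotation: GenomeAnnotation
    true_expression: pd.DataFrame  # genes x conditions
    de_genes: dict[str, tuple[int, float]]  # gene_id -> (direction, fold)


@dataclass
class SimulatedSample:
    """All reads of one sample, with their true alignments and origins."""

    name: str
    records: list[ReadRecord]
    alignments: list[AlignedRead]
    origins: list[tuple[str, str, int]]  # (read_id, gene_id, transcript offset)
    n_truncated: int = 0


def _sample_gene(rng: np.random.Generator, config: SimConfig, gene_id: str,
                 contig: str, start: int) -> GeneModel:
    n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    cds_lens = rng.integers(
        config.cds_exon_length[0], config.cds_exon_length[1] + 1, n_ex
    )
    intron_lens = rng.integers(
        config.intron_length[0], config.intron_length[1] + 1, max(n_ex - 1, 0)
    )
    u5 = int(rng.integers(config.utr5_length[0], config.utr5_length[1] + 1))
    u3 = int(rng.integers(config.utr3_length[0], config.utr3_length[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    left_utr, right_utr = (u5, u3) if strand == "+" else (u3, u5)

    exons = []
    cursor = start
    for i in range(n_ex):
        length = int(cds_lens[i])
        if i == 0:
            length += left_utr
        if i == n_ex - 1:
            length += right_utr
        exons.append((cursor, cursor + length))
        cursor += length
        if i < n_ex - 1:
            cursor += int(intron_lens[i])
    end = exons[-1][1]
    cds = (start + left_utr, end - right_utr)
    utr5 = (start, start + left_utr) if strand == "+" else (end - right_utr, end)
    utr3 = (end - right_utr, end) if strand == "+" else (start, start + left_utr)
    gene = GeneModel(gene_id=gene_id, contig=contig, strand=strand,
                     exons=tuple(exons), cds=cds, utr5=utr5, utr3=utr3)
    gene.validate()
    return gene


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate a random genome plus fully-known annotation and expression.

    Genes are laid out left to right with at least ``intergenic_gap_min``
    bases between neighbours, introns get canonical GT..AG (strand-aware)
    boundaries, and the whole construction is deterministic under
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    contig_names = [f"ctg{i + 1:02d}" for i in range(config.n_contigs)]
    cursors = {name: config.intergenic_gap_min for name in contig_names}

    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        contig = contig_names[i % config.n_contigs]
        gap_extra = int(rng.integers(0, 201))
        start = cursors[contig] + gap_extra
        gene = _sample_gene(rng, config, f"g{i + 1:04d}", contig, start)
        if gene.end + config.intergenic_gap_min > config.contig_length:
            raise ConfigError(
                f"gene {gene.gene_id} does not fit on {contig}; increase "
                "contig_length or reduce n_genes"
            )
        genes.append(gene)
        cursors[contig] = gene.end + config.intergenic_gap_min

    # random sequence, then stamp canonical splice motifs over each intron
    genome: dict[str, str] = {}
    arrays = {
        name: _BASES[rng.integers(0, 4, config.contig_length)].copy()
        for name in contig_names
    }
    for gene in genes:
        arr = arrays[gene.contig]
        donor, acceptor = (b"GT", b"AG") if gene.strand == "+" else (b"CT", b"AC")
        for a, b in gene.introns:
            arr[a:a + 2] = np.frombuffer(donor, dtype=np.uint8)
            arr[b - 2:b] = np.frombuffer(acceptor, dtype=np.uint8)
    for name in contig_names:
        genome[name] = arrays[name].tobytes().decode("ascii")

    annotation = GenomeAnnotation(
        contigs={name: config.contig_length for name in contig_names}, genes=genes
    )
    annotation.validate()

    gene_ids = [g.gene_id for g in genes]
    base = rng.lognormal(config.expr_mu, config.expr_sigma, config.n_genes)
    expr = np.tile(base[:, None], (1, max(config.n_conditions, 1)))
    de_genes: dict[str, tuple[int, float]] = {}
    n_de = int(round(config.de_fraction * config.n_genes))
    if n_de and config.n_conditions > 1:
        de_idx = rng.choice(config.n_genes, n_de, replace=False)
        if config.de_direction == "both":
            directions = rng.choice([-1, 1], n_de)
        else:
            directions = np.full(n_de, 1 if config.de_direction == "up" else -1)
        for idx, direction in zip(de_idx, directions):
            fold = config.de_fold_change ** int(direction)
            expr[idx, 1:] *= fold
            de_genes[gene_ids[idx]] = (int(direction), config.de_fold_change)
    true_expression = pd.DataFrame(
        expr,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"cond{c + 1}" for c in range(max(config.n_conditions, 1))],
    )
    return genome, SimTruth(annotation, true_expression, de_genes)


def _draw_counts(rng: np.random.Generator, expected: np.ndarray,
                 config: SimConfig) -> np.ndarray:
    if config.noise == "poisson":
        return rng.poisson(expected)
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, expected * config.nb_dispersion)
    return rng.poisson(lam)


def simulate_sample(
    genome: dict[str, str],
    truth: SimTruth,
    condition: int,
    replicate: int,
    config: SimConfig,
    bias_mode: Optional[str] = None,
) -> SimulatedSample:
    """Draw one sample's reads (FASTQ-ready records plus true alignments).

    Reads per gene are proportional to true expression with Poisson or
    negative-binomial noise; read starts on the spliced transcript are
    uniform or 3'-biased depending on ``bias_mode``; spliced reads project
    through the exon chain into multi-block alignments.  Deterministic for
    a fixed ``(config.seed, condition, replicate)``.
    """
    bias = bias_mode if bias_mode is not None else config.bias_mode
    if bias not in ("uniform", "three_prime"):
        raise ConfigError(f"unknown bias_mode {bias!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2, condition, replicate])
    )
    name = f"c{condition + 1}r{replicate + 1}"
    expr = truth.true_expression.iloc[:, condition].to_numpy(dtype=float)
    probs = expr / expr.sum()
    counts = _draw_counts(rng, config.reads_per_sample * probs, config)

    records: list[ReadRecord] = []
    alignments: list[AlignedRead] = []
    origins: list[tuple[str, str, int]] = []
    n_truncated = 0
    serial = 0
    max_q = 40
    for gene, n_reads in zip(truth.annotation.genes, counts):
        if n_reads == 0:
            continue
        L = gene.transcript_length
        R = min(config.read_length, L)
        if R < config.read_length:
            n_truncated += int(n_reads)
        span = L - R  # largest valid start offset
        if span == 0:
            starts = np.zeros(n_reads, dtype=int)
        elif bias == "uniform":
            starts = rng.integers(0, span + 1, n_reads)
        else:
            # 3'-end distance d ~ Exp(bias_decay) truncated to [0, span]
            trunc_mass = 1.0 - np.exp(-span / config.bias_decay)
            d = -config.bias_decay * np.log(1.0 - rng.random(n_reads) * trunc_mass)
            d = np.clip(np.floor(d).astype(int), 0, span)
            starts = span - d
        qual_template = np.clip(
            np.round(config.quality_baseline
                     - config.quality_slope * np.arange(R)).astype(int),
            2, max_q,
        )
        contig_seq = genome[gene.contig]
        for start in starts:
            start = int(start)
            blocks = gene.transcript_to_genomic(start, start + R)
            seq = "".join(contig_seq[s:e] for s, e in blocks)
            if config.n_rate > 0:
                mask = rng.random(R) < config.n_rate
                if mask.any():
                    chars = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
                    chars[mask] = ord("N")
                    seq = chars.tobytes().decode("ascii")
            read_id = f"{name}.r{serial:07d}|{gene.gene_id}|{start}"
            records.append(ReadRecord(read_id, seq, tuple(int(q) for q in qual_template)))
            alignments.append(
                AlignedRead(
                    read_id=read_id,
                    contig=gene.contig,
                    blocks=tuple(blocks),
                    read_length=R,
                    is_unique=True,
                    is_primary=True,
                )
            )
            origins.append((read_id, gene.gene_id, start))
            serial += 1
    return SimulatedSample(name, records, alignments, origins, n_truncated)


def strip_annotation_utrs(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """UTR-less copy of an annotation (the input for UTR-recovery runs)."""
    return GenomeAnnotation(
        contigs=dict(annotation.contigs),
        genes=[g.strip_utrs() for g in annotation.genes],
    )


def simulate_dataset(
    config: SimConfig,
    outdir: str,
    bias_modes: Optional[Sequence[str]] = None,
) -> SimTruth:
    """Write a complete simulated study to ``outdir``.

    Emits the genome FASTA, the truth annotation with and without UTRs,
    expression/DE truth tables, and one FASTQ + SAM pair per sample.
    ``bias_modes`` gives one mode per condition (default: ``config.bias_mode``
    everywhere).
    """
    os.makedirs(outdir, exist_ok=True)
    genome, truth = simulate_genome(config)
    if bias_modes is None:
        bias_modes = [config.bias_mode] * config.n_conditions
    if len(bias_modes) != config.n_conditions:
        raise ConfigError("bias_modes must name one mode per condition")

    io_formats.write_fasta(genome, os.path.join(outdir, "genome.fasta"))
    io_formats.write_gff(truth.annotation, os.path.join(outdir, "annotation.gff3"))
    io_formats.write_gff(
        strip_annotation_utrs(truth.annotation),
        os.path.join(outdir, "annotation_noutr.gff3"),
    )
    truth.true_expression.to_csv(
        os.path.join(outdir, "true_expression.tsv"), sep="\t"
    )
    de_table = pd.DataFrame(
        [(g, d, f) for g, (d, f) in sorted(truth.de_genes.items())],
        columns=["gene_id", "direction", "fold"],
    )
    de_table.to_csv(os.path.join(outdir, "de_genes.tsv"), sep="\t", index=False)

    for condition in range(config.n_conditions):
        for replicate in range(config.replicates_per_condition):
            sample = simulate_sample(
                genome, truth, condition, replicate, config, bias_modes[condition]
            )
            io_formats.write_fastq(
                sample.records, os.path.join(outdir, f"{sample.name}.fastq")
            )
            io_formats.write_sam(
                os.path.join(outdir, f"{sample.name}.sam"),
                sample.alignments,
                sample.records,
                truth.annotation.contigs,
            )
    return truth
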