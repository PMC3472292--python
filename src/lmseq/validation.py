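"""Ground-truth validation scenarios.

Each function here builds a synthetic dataset with known truth (or an
exhaustive input enumeration), runs one pipeline stage through its public
interface, and returns recovery/agreement metrics.  Where a stage is
checked against a reference implementation, that reference is written
independently and naively (per-character loops, nested scans) so the two
code paths share nothing but the rule they both implement.

The scenario sizes are chosen to give stable metrics on a single CPU in
seconds to a couple of minutes; the methods documentation lists them.
"""

from __future__ import annotations

import itertools
import os
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotation_refine import (
    apply_utr_calls,
    build_coverage,
    extract_junctions,
    model_utrs,
    refine_gene_models,
)
from .diffexpr import (
    BayesResult,
    ClassicalResult,
    EXCLUDED,
    assign_group,
    consensus_call,
    differential_expression,
)
from .models import AlignedRead, ReadRecord
from .pipeline import ComparisonSpec, PipelineConfig, SampleSpec, run_pipeline
from .quantify import CountMatrix, count_3prime_window, count_features
from .read_cleaning import clean_read
from .reporting import fit_expression_mixture
from .synthetic_data import (
    SimConfig,
    simulate_dataset,
    simulate_genome,
    simulate_sample,
    strip_annotation_utrs,
)

# ---------------------------------------------------------------------------
# read cleaning vs a naive per-character reference


def _clean_reference(seq: str, quals: tuple[int, ...], min_q: int,
                     min_len_keep: int) -> Optional[tuple[str, tuple[int, ...]]]:
    """Character-level restatement of the cleaning rule (reference only)."""
    for ch in seq:
        if ch == "N":
            return None
    keep = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        if quals[i] >= min_q:
            break
        keep = i
    if keep < min_len_keep:
        return None
    return seq[:keep], quals[:keep]


def fuzz_reads(n_reads: int, seed: int) -> list[ReadRecord]:
    """Random reads biased towards the cleaning rule's edge cases."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    reads = []
    for i in range(n_reads):
        length = int(rng.integers(1, 81))
        seq = "".join(rng.choice(alphabet, length))
        if rng.random() < 0.1:
            pos = int(rng.integers(0, length))
            seq = seq[:pos] + "N" + seq[pos + 1:]
        # qualities concentrated around the threshold to probe boundaries
        quals = rng.choice([0, 5, 8, 9, 10, 11, 20, 30, 40], length).astype(int)
        reads.append(ReadRecord(f"fz{i}", seq, tuple(int(q) for q in quals)))
    return reads


def validate_cleaning(n_reads: int = 10_000, seed: int = 0,
                      min_q: int = 10, min_len_keep: int = 21) -> dict:
    """Fraction of fuzzed reads where cleaning matches the naive reference."""
    agree = 0
    for read in fuzz_reads(n_reads, seed):
        got = clean_read(read, min_q=min_q, min_len_keep=min_len_keep)
        want = _clean_reference(read.sequence, read.qualities, min_q, min_len_keep)
        if got is None and want is None:
            agree += 1
        elif got is not None and want is not None:
            if got.sequence == want[0] and got.qualities == want[1]:
                agree += 1
    return {"agreement": agree / n_reads, "n": n_reads}


# ---------------------------------------------------------------------------
# both-ends counting vs a nested-loop reference


def _count_reference(reads, annotation, min_read_len=35) -> pd.Series:
    """Nested loop over reads x genes applying the both-ends rule literally."""
    counts = {g.gene_id: 0 for g in annotation.genes}
    for read in reads:
        if not read.is_primary or not read.is_unique:
            continue
        if read.read_length < min_read_len:
            continue
        p1 = read.blocks[0][0]
        p2 = read.blocks[-1][1] - 1
        hits = []
        for gene in annotation.genes:
            if gene.contig != read.contig:
                continue
            in1 = any(s <= p1 < e for s, e in gene.exons)
            in2 = any(s <= p2 < e for s, e in gene.exons)
            if in1 and in2:
                hits.append(gene.gene_id)
        if len(hits) == 1:
            counts[hits[0]] += 1
    series = pd.Series(counts, name="count")
    series.index.name = "gene_id"
    return series


def make_counting_instance(seed: int, n_genes: int = 50,
                           n_reads: int = 10_000):
    """A synthetic genome plus a read mix of real, boundary-straddling,
    spliced and sub-length reads for exercising the counting rule."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_contigs=2,
                    contig_length=200_000, reads_per_sample=int(n_reads * 0.7),
                    exons_per_gene=(1, 3), n_rate=0.0)
    genome, truth = simulate_genome(cfg)
    reads = list(simulate_sample(genome, truth, 0, 0, cfg).alignments)
    contigs = list(truth.annotation.contigs)
    n_random = n_reads - len(reads)
    for i in range(n_random):
        contig = contigs[int(rng.integers(0, len(contigs)))]
        length = int(rng.integers(20, 81))
        start = int(rng.integers(0, cfg.contig_length - length - 300))
        if rng.random() < 0.2:
            split = int(rng.integers(1, length))
            gap = int(rng.integers(50, 200))
            blocks = ((start, start + split),
                      (start + split + gap, start + gap + length))
        else:
            blocks = ((start, start + length),)
        reads.append(
            AlignedRead(
                read_id=f"rand{i}", contig=contig, blocks=blocks,
                read_length=length,
                is_unique=rng.random() > 0.05,
                is_primary=rng.random() > 0.05,
            )
        )
    return truth.annotation, reads


def validate_counting(seed: int = 0, n_genes: int = 50,
                      n_reads: int = 10_000) -> dict:
    """Gene-by-gene agreement of count_features with the nested-loop rule."""
    annotation, reads = make_counting_instance(seed, n_genes, n_reads)
    got, _ = count_features(reads, annotation)
    want = _count_reference(reads, annotation)
    agree = int((got.sort_index() == want.sort_index()).sum())
    return {"agreement": agree / len(want), "genes_checked": len(want),
            "n": n_reads}


# ---------------------------------------------------------------------------
# classical groups and consensus vs independent rule evaluators


def _group_reference(ratios) -> object:
    """Literal restatement of the four printed group criteria."""
    if len(ratios) == 0:
        return EXCLUDED
    n = len(ratios)
    mean = sum(ratios) / n
    sd = (sum((r - mean) ** 2 for r in ratios) / (n - 1)) ** 0.5 if n > 1 else 0.0
    if mean > 0:
        cv = sd / mean
    else:
        cv = 0.0 if sd == 0 else float("inf")

    def crit4():
        return all(r >= 4 for r in ratios) or all(r <= 0.25 for r in ratios)

    def crit3():
        return (mean >= 4 or mean <= 0.25) and cv < 0.5

    def crit2():
        return all(r >= 2 for r in ratios) or all(r <= 0.5 for r in ratios)

    def crit1():
        return (mean >= 2 or mean <= 0.5) and cv < 0.5

    for group, crit in ((4, crit4), (3, crit3), (2, crit2), (1, crit1)):
        if crit():
            return group
    return 0


def fuzz_ratio_vectors(n_vectors: int, seed: int) -> list[tuple[float, ...]]:
    rng = np.random.default_rng(seed)
    boundary = [0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
    vectors = []
    for _ in range(n_vectors):
        k = int(rng.integers(1, 5))
        vals = []
        for _ in range(k):
            if rng.random() < 0.3:
                vals.append(float(rng.choice(boundary)))
            else:
                vals.append(float(rng.lognormal(0.0, 1.5)))
        vectors.append(tuple(vals))
    return vectors


def validate_groups(n_vectors: int = 10_000, seed: int = 0) -> dict:
    vectors = fuzz_ratio_vectors(n_vectors, seed)
    agree = sum(
        1 for v in vectors if assign_group(v) == _group_reference(v)
    )
    return {"agreement": agree / n_vectors, "n": n_vectors}


def validate_consensus_table(p_min: float = 0.999) -> dict:
    """Exhaustive qualitative truth table for the consensus caller."""
    ratio_levels = [10.0, 5.0, 1.0, 0.2, 0.1]
    groups = [0, 1, 4, EXCLUDED]
    p_levels = [1.0, 0.9995, 0.99]
    checked = agree = 0
    for threshold_set, T in (("fourfold", 4.0), ("eightfold", 8.0)):
        for c_ratio, b_ratio, group, p in itertools.product(
            ratio_levels, [*ratio_levels, None], groups, p_levels
        ):
            classical = ClassicalResult(
                "g", ("A", "B"), (c_ratio,), c_ratio, 0.0, 0.0, group
            )
            bayes = (
                BayesResult("g", b_ratio, (b_ratio * 0.8, b_ratio * 1.2), p)
                if b_ratio is not None
                else None
            )
            got = consensus_call(
                classical if group != EXCLUDED else None, bayes,
                threshold_set, p_min,
            ).call
            # independently derived expectation
            if bayes is None or group in (0, EXCLUDED) or p < p_min:
                want = 0
            elif c_ratio > T and b_ratio > T:
                want = 1
            elif c_ratio < 1.0 / T and b_ratio < 1.0 / T:
                want = -1
            else:
                want = 0
            checked += 1
            agree += got == want
    return {"agreement": agree / checked, "n": checked}


# ---------------------------------------------------------------------------
# UTR terminus recovery


def validate_utr_recovery(seed: int = 0, n_genes: int = 100,
                          reads_per_sample: int = 80_000,
                          tolerance: int = 10) -> dict:
    """Strip true UTRs, rebuild them from uniform coverage, score termini.

    Expression spread is kept narrow (sigma 0.3) so all genes carry the
    well-covered transcripts the walk needs; neighbour gaps are >= 500.
    """
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_contigs=4,
                    contig_length=200_000, reads_per_sample=reads_per_sample,
                    expr_sigma=0.3, de_fraction=0.0, n_rate=0.0)
    genome, truth = simulate_genome(cfg)
    sample = simulate_sample(genome, truth, 0, 0, cfg, bias_mode="uniform")
    stripped = strip_annotation_utrs(truth.annotation)
    coverage = build_coverage(sample.alignments, truth.annotation.contigs)
    calls, _ = model_utrs(stripped, coverage)
    by_id = truth.annotation.by_id()
    n_termini = 2 * n_genes  # every simulated gene has both UTRs
    recovered = 0
    for call in calls:
        gene = by_id[call.gene_id]
        true_iv = gene.utr5 if call.side == "5'" else gene.utr3
        if true_iv is None:
            continue
        if call.interval[0] < gene.cds[0]:  # left-side extension
            err = abs(call.interval[0] - true_iv[0])
        else:
            err = abs(call.interval[1] - true_iv[1])
        recovered += err <= tolerance
    return {"recovered_frac": recovered / n_termini, "n": n_termini}


# ---------------------------------------------------------------------------
# intron restoration


def validate_intron_recovery(seed: int = 0, n_corrupt: int = 20) -> dict:
    """Corrupt intron boundaries, restore them from splice junctions.

    Only introns with >= 2 supporting spliced reads are corrupted (shifts of
    3-9 bases, alternating donor/acceptor side).  Success means every
    corrupted intron is restored exactly and no gene gains an intron absent
    from the truth.
    """
    cfg = SimConfig(seed=seed, n_genes=40, n_contigs=2, contig_length=200_000,
                    exons_per_gene=(2, 4), reads_per_sample=60_000,
                    expr_sigma=0.5, de_fraction=0.0, n_rate=0.0)
    genome, truth = simulate_genome(cfg)
    sample = simulate_sample(genome, truth, 0, 0, cfg, bias_mode="uniform")
    junctions = extract_junctions(sample.alignments)
    support = {(j.contig, j.donor_end, j.acceptor_start): j.support
               for j in junctions}

    eligible = []  # (gene_id, intron index) with junction support >= 2
    for gene in truth.annotation.sorted_genes():
        for idx, intron in enumerate(gene.introns):
            if support.get((gene.contig, intron[0], intron[1]), 0) >= 2:
                eligible.append((gene.gene_id, idx))
    chosen = eligible[:n_corrupt]

    by_id = truth.annotation.by_id()
    corrupted_genes = {}
    for i, (gene_id, idx) in enumerate(chosen):
        gene = corrupted_genes.get(gene_id, by_id[gene_id])
        introns = list(gene.introns)
        a, b = introns[idx]
        shift = 3 + (i % 7)
        introns[idx] = (a + shift, b) if i % 2 == 0 else (a, b - shift)
        corrupted_genes[gene_id] = gene.with_introns(tuple(introns))
    corrupted = truth.annotation.__class__(
        contigs=dict(truth.annotation.contigs),
        genes=[corrupted_genes.get(g.gene_id, g) for g in truth.annotation.genes],
    )

    refined, report = refine_gene_models(corrupted, junctions, min_support=2)
    refined_by_id = refined.by_id()
    restored = sum(
        1 for gene_id, idx in chosen
        if refined_by_id[gene_id].introns[idx] == by_id[gene_id].introns[idx]
    )
    false_introns = sum(
        1 for gene in refined.genes
        for intron in gene.introns
        if intron not in by_id[gene.gene_id].introns
    )
    return {
        "restored": restored,
        "n_corrupted": len(chosen),
        "false_introns": false_introns,
        "novel_internal": report.novel_internal,
    }


# ---------------------------------------------------------------------------
# differential-expression recovery


def validate_de_recovery(seed: int = 0, n_genes: int = 200,
                         reads_per_sample: int = 200_000,
                         n_draws: int = 10_000) -> dict:
    """Two conditions x two replicates, 10% true 16-fold changes.

    Changes point downward in the second condition, mirroring the
    predominant down-regulation seen in microdissected samples; this also
    keeps the fold observable under total-count normalization (10% of
    genes rising 16-fold would double a sample's total and compress every
    normalized ratio to about half its nominal value).  Consensus calling
    uses the eightfold threshold set; reports sensitivity on the true
    changers and the false-positive rate on null genes.
    """
    cfg = SimConfig(seed=seed, n_genes=n_genes, n_contigs=4,
                    contig_length=250_000, reads_per_sample=reads_per_sample,
                    expr_sigma=0.6, de_fraction=0.1, de_fold_change=16.0,
                    de_direction="down", n_conditions=2, n_rate=0.0)
    genome, truth = simulate_genome(cfg)
    columns = {}
    for condition in range(2):
        for replicate in range(2):
            sample = simulate_sample(genome, truth, condition, replicate, cfg)
            columns[sample.name], _ = count_features(
                sample.alignments, truth.annotation
            )
    matrix = CountMatrix.from_columns(columns)
    table = differential_expression(
        matrix.counts, matrix.total_counted, ("cond2", "cond1"),
        ["c2r1", "c2r2"], ["c1r1", "c1r2"], "eightfold",
        n_draws=n_draws, seed=seed,
    )
    de_true = truth.de_genes
    tp = sum(1 for g, (direction, _) in de_true.items()
             if table.loc[g, "consensus"] == direction)
    fp = sum(1 for g in table.index
             if g not in de_true and table.loc[g, "consensus"] != 0)
    n_null = len(table.index) - len(de_true)
    return {
        "sensitivity": tp / len(de_true) if de_true else float("nan"),
        "fpr": fp / n_null,
        "n_de": len(de_true),
        "n_null": n_null,
    }


# ---------------------------------------------------------------------------
# 3'-window robustness under amplification bias


def validate_three_prime_robustness(seed: int = 0) -> dict:
    """LM-like sample: window counts vs full-length counts against truth.

    Full-length counting runs on the UTR-less annotation (the situation
    before UTR modeling, where 3'-clustered reads fall outside features);
    window counting runs on the annotation refined from a uniform sample.
    Length independence is scored on a constant-expression genome with
    mRNAs longer than the window's far edge, using the complete annotation
    (the counting operation's stated precondition).
    """
    cfg = SimConfig(seed=seed, n_genes=150, n_contigs=4, contig_length=250_000,
                    reads_per_sample=120_000, expr_sigma=1.0, de_fraction=0.0,
                    utr3_length=(50, 500), bias_decay=150.0, n_rate=0.0)
    genome, truth = simulate_genome(cfg)
    uniform = simulate_sample(genome, truth, 0, 0, cfg, bias_mode="uniform")
    stripped = strip_annotation_utrs(truth.annotation)
    coverage = build_coverage(uniform.alignments, truth.annotation.contigs)
    calls, _ = model_utrs(stripped, coverage)
    refined = apply_utr_calls(stripped, calls)
    lm = simulate_sample(genome, truth, 0, 1, cfg, bias_mode="three_prime")
    full, _ = count_features(lm.alignments, stripped)
    window, _ = count_3prime_window(lm.alignments, refined)
    expr = truth.true_expression["cond1"]
    rho_full = float(spearmanr(full, expr).statistic)
    rho_window = float(spearmanr(window, expr).statistic)

    cfg2 = SimConfig(seed=seed + 1, n_genes=150, n_contigs=4,
                     contig_length=400_000, reads_per_sample=120_000,
                     expr_sigma=0.0, de_fraction=0.0,
                     cds_exon_length=(400, 800), utr3_length=(100, 400),
                     bias_decay=150.0, n_rate=0.0)
    genome2, truth2 = simulate_genome(cfg2)
    lm2 = simulate_sample(genome2, truth2, 0, 1, cfg2, bias_mode="three_prime")
    window2, _ = count_3prime_window(lm2.alignments, truth2.annotation)
    lengths = np.array([g.transcript_length for g in truth2.annotation.genes])
    rho_length = float(spearmanr(window2, lengths).statistic)
    return {
        "rho_window": rho_window,
        "rho_full": rho_full,
        "rho_length_abs": abs(rho_length),
        "n": cfg.n_genes,
    }


# ---------------------------------------------------------------------------
# expression-mixture recovery


def validate_mixture_recovery(seed: int = 0, n: int = 5000,
                              means=(-2.0, 5.0), sd: float = 1.0) -> dict:
    rng = np.random.default_rng(seed)
    half = n // 2
    data = np.concatenate([
        rng.normal(means[0], sd, half), rng.normal(means[1], sd, n - half)
    ])
    fit = fit_expression_mixture(data, k_max=3, seed=seed)
    return {
        "n_components": fit.n_components,
        "mean_low": fit.means[0],
        "mean_high": fit.means[-1],
        "n": n,
    }


# ---------------------------------------------------------------------------
# end-to-end determinism


def pipeline_fixture_config(datadir: str, seed: int = 0) -> PipelineConfig:
    """Simulate a small two-condition study and describe it to the pipeline."""
    cfg = SimConfig(seed=seed, n_genes=20, n_contigs=2, contig_length=120_000,
                    reads_per_sample=6000, n_conditions=2,
                    replicates_per_condition=2, de_fraction=0.1)
    simulate_dataset(cfg, datadir, bias_modes=["uniform", "three_prime"])
    samples = [
        SampleSpec(name=f"c{c}r{r}", condition=f"cond{c}",
                   sam=os.path.join(datadir, f"c{c}r{r}.sam"),
                   fastq=os.path.join(datadir, f"c{c}r{r}.fastq"))
        for c in (1, 2) for r in (1, 2)
    ]
    comparisons = [ComparisonSpec(name="c2_vs_c1", condition_a="cond2",
                                  condition_b="cond1", threshold_set="eightfold")]
    return PipelineConfig(
        annotation=os.path.join(datadir, "annotation_noutr.gff3"),
        samples=samples, comparisons=comparisons, seed=seed,
        n_draws=2000, top_n=10,
    )


def validate_pipeline_determinism(workdir: str, seed: int = 0) -> dict:
    config = pipeline_fixture_config(os.path.join(workdir, "data"), seed=seed)
    m1 = run_pipeline(config, os.path.join(workdir, "run1"))
    m2 = run_pipeline(config, os.path.join(workdir, "run2"))
    identical = m1["outputs"] == m2["outputs"]
    return {"identical": int(identical), "n_outputs": len(m1["outputs"])}
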