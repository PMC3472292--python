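"""End-to-end pipeline: clean -> ingest SAM -> refine annotation ->
count -> differential expression -> reports, with a deterministic manifest.

Evidence for annotation refinement (coverage, junctions) is pooled across
all samples — sampling several growth conditions raises the number of
expressed genes and therefore the number of genes with usable evidence.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation_refine import (
    apply_utr_calls,
    build_coverage,
    extract_junctions,
    junction_table,
    model_utrs,
    refine_gene_models,
    utr_summary_table,
)
from .diffexpr import differential_expression, ma_table
from .io_formats import read_gff, read_sam, read_sam_contigs, write_gff
from .models import ConfigError
from .quantify import (
    CountMatrix,
    classify_regions,
    count_3prime_window,
    count_features,
)
from .read_cleaning import clean_fastq
from .reporting import expression_distribution, top_n_sets


@dataclass
class SampleSpec:
    name: str
    condition: str
    sam: str
    fastq: Optional[str] = None


@dataclass
class ComparisonSpec:
    name: str
    condition_a: str
    condition_b: str
    threshold_set: str = "fourfold"


@dataclass
class PipelineConfig:
    annotation: str
    samples: list[SampleSpec]
    comparisons: list[ComparisonSpec] = field(default_factory=list)
    seed: int = 0
    min_q: int = 10
    min_len_keep: int = 21
    min_cov: int = 2
    max_gap: int = 10
    max_extent: int = 2000
    min_support: int = 2
    min_read_len: int = 35
    window: tuple[int, int] = (100, 400)
    p_min: float = 0.999
    n_draws: int = 10_000
    top_n: int = 500
    k_max: int = 3

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(**s) for s in raw.pop("samples")]
        comparisons = [ComparisonSpec(**c) for c in raw.pop("comparisons", [])]
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(samples=samples, comparisons=comparisons, **raw)

    def condition_columns(self) -> dict[str, list[str]]:
        cols: dict[str, list[str]] = {}
        for s in self.samples:
            cols.setdefault(s.condition, []).append(s.name)
        return cols


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute every stage and write all artifacts plus a manifest.

    Returns the manifest dict (parameters, per-output sha256 checksums).
    Deterministic for a fixed config and seed.
    """
    os.makedirs(outdir, exist_ok=True)
    outputs: list[str] = []

    def path_for(name: str) -> str:
        outputs.append(name)
        return os.path.join(outdir, name)

    names = [s.name for s in config.samples]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate sample names")
    for sample in config.samples:
        if not os.path.exists(sample.sam):
            raise ConfigError(f"sample {sample.name}: missing SAM file {sample.sam}")

    # 1. cleaning (when raw FASTQ is provided)
    cleaning_rows = []
    for sample in config.samples:
        if sample.fastq is None:
            continue
        report = clean_fastq(
            sample.fastq,
            path_for(f"{sample.name}.clean.fastq"),
            min_q=config.min_q,
            min_len_keep=config.min_len_keep,
        )
        cleaning_rows.append({"sample": sample.name, **report.as_dict()})
    if cleaning_rows:
        pd.DataFrame(cleaning_rows).to_csv(
            path_for("cleaning_report.tsv"), sep="\t", index=False
        )

    # 2. ingest annotation and alignments
    annotation = read_gff(config.annotation)
    contigs = read_sam_contigs(config.samples[0].sam)
    for contig, length in contigs.items():
        annotation.contigs.setdefault(contig, length)
    reads_by_sample = {s.name: list(read_sam(s.sam)) for s in config.samples}
    all_reads = [r for reads in reads_by_sample.values() for r in reads]

    # 3. refinement: junctions first, then UTRs on the junction-refined models
    junctions = extract_junctions(all_reads)
    junction_table(junctions).to_csv(path_for("junctions.tsv"), sep="\t", index=False)
    refined, refine_report = refine_gene_models(
        annotation, junctions, min_support=config.min_support
    )
    coverage = build_coverage(all_reads, refined.contigs)
    utr_calls, utr_summary = model_utrs(
        refined,
        coverage,
        min_cov=config.min_cov,
        max_gap=config.max_gap,
        max_extent=config.max_extent,
    )
    refined = apply_utr_calls(refined, utr_calls)
    write_gff(refined, path_for("annotation_refined.gff3"))
    utr_summary_table(utr_summary).to_csv(
        path_for("utr_summary.tsv"), sep="\t", index=False
    )

    # 4. quantification
    full_cols, window_cols, region_rows = {}, {}, []
    for sample in config.samples:
        reads = reads_by_sample[sample.name]
        full_cols[sample.name], _ = count_features(
            reads, refined, min_read_len=config.min_read_len
        )
        window_cols[sample.name], _ = count_3prime_window(
            reads, refined, window=config.window, min_read_len=config.min_read_len
        )
        tally = classify_regions(reads, refined, min_read_len=config.min_read_len)
        region_rows.append({"sample": sample.name, **tally.as_dict()})
    counts = CountMatrix.from_columns(full_cols)
    counts3p = CountMatrix.from_columns(window_cols)
    counts.write(path_for("counts.tsv"))
    counts3p.write(path_for("counts_3prime.tsv"))
    pd.DataFrame(region_rows).to_csv(path_for("regions.tsv"), sep="\t", index=False)
    norm = counts.normalize()
    norm.to_csv(path_for("counts_normalized.tsv"), sep="\t")

    # 5. differential expression
    cond_cols = config.condition_columns()
    for comp in config.comparisons:
        for cond in (comp.condition_a, comp.condition_b):
            if cond not in cond_cols:
                raise ConfigError(f"comparison {comp.name}: unknown condition {cond}")
        table = differential_expression(
            counts.counts,
            counts.total_counted,
            (comp.condition_a, comp.condition_b),
            cond_cols[comp.condition_a],
            cond_cols[comp.condition_b],
            comp.threshold_set,
            p_min=config.p_min,
            n_draws=config.n_draws,
            seed=config.seed,
        )
        table.to_csv(path_for(f"de_{comp.name}.tsv"), sep="\t")
        ma = ma_table(norm, cond_cols[comp.condition_a], cond_cols[comp.condition_b])
        ma.to_csv(path_for(f"ma_{comp.name}.tsv"), sep="\t")

    # 6. reports
    norm3p = counts3p.normalize()
    _, venn = top_n_sets(norm3p, cond_cols, n=min(config.top_n, len(norm3p)))
    venn.to_csv(path_for("top_venn.tsv"), sep="\t", index=False)
    mixture_rows = []
    level_cols = {}
    for sample in config.samples:
        coverage_s = build_coverage(reads_by_sample[sample.name], refined.contigs)
        if coverage_s.total_bases == 0:
            continue
        levels, fit = expression_distribution(
            coverage_s, refined, k_max=config.k_max, seed=config.seed
        )
        level_cols[sample.name] = levels
        frame = fit.as_frame()
        frame.insert(0, "sample", sample.name)
        mixture_rows.append(frame)
    if level_cols:
        pd.DataFrame(level_cols).to_csv(path_for("expression_levels.tsv"), sep="\t")
    if mixture_rows:
        pd.concat(mixture_rows, ignore_index=True).to_csv(
            path_for("mixture_fits.tsv"), sep="\t", index=False
        )

    manifest = {
        "lmseq_version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_q": config.min_q,
            "min_len_keep": config.min_len_keep,
            "min_cov": config.min_cov,
            "max_gap": config.max_gap,
            "max_extent": config.max_extent,
            "min_support": config.min_support,
            "min_read_len": config.min_read_len,
            "window": list(config.window),
            "p_min": config.p_min,
            "n_draws": config.n_draws,
            "top_n": config.top_n,
            "k_max": config.k_max,
        },
        "refinement": {
            "confirmed": refine_report.confirmed,
            "adjusted": refine_report.adjusted,
            "novel_internal": refine_report.novel_internal,
            "outside": refine_report.outside,
            "rejected": refine_report.rejected,
        },
        "outputs": {name: _sha256(os.path.join(outdir, name)) for name in sorted(outputs)},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
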