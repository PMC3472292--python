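"""Summary artifacts: top-N gene sets with overlaps, and the decomposition
of the expression-level distribution into Gaussian components.

The top-N analysis averages normalized 3'-window counts across the
replicates of each condition and takes the N highest genes per condition
(ties broken lexicographically by gene id), then counts every Venn cell of
the resulting sets.  The expression-level analysis computes, per gene, the
average per-base coverage of its mRNA scaled to coverage per kilobase per
million counted bases, log2-transforms the positive levels, and fits 1-D
Gaussian mixtures by expectation-maximization, choosing the component
count by BIC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .annotation_refine import CoverageTrack
from .models import GenomeAnnotation, LmseqError

DEFAULT_TOP_N = 500
DEFAULT_K_MAX = 3


def top_n_sets(
    norm_matrix: pd.DataFrame,
    condition_columns: dict[str, Sequence[str]],
    n: int = DEFAULT_TOP_N,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Highest-expressed gene sets per condition plus the Venn cell table.

    ``condition_columns`` maps each condition name to its replicate columns
    in ``norm_matrix``.  Returns ``(sets, venn)`` where ``venn`` has one
    row per non-empty membership pattern with its gene count.
    """
    conditions = list(condition_columns)
    sets: dict[str, set[str]] = {}
    for cond in conditions:
        avg = norm_matrix[list(condition_columns[cond])].mean(axis=1)
        if len(avg) < n:
            import warnings

            warnings.warn(
                f"condition {cond}: only {len(avg)} genes for top-{n}", stacklevel=2
            )
        ranked = sorted(avg.items(), key=lambda kv: (-kv[1], kv[0]))
        sets[cond] = {gene for gene, _ in ranked[:n]}

    union = set().union(*sets.values()) if sets else set()
    cells: dict[tuple[bool, ...], int] = {}
    for gene in union:
        pattern = tuple(gene in sets[c] for c in conditions)
        cells[pattern] = cells.get(pattern, 0) + 1
    rows = []
    for pattern in sorted(cells, reverse=True):
        row = {c: int(flag) for c, flag in zip(conditions, pattern)}
        row["n_genes"] = cells[pattern]
        rows.append(row)
    venn = pd.DataFrame(rows, columns=conditions + ["n_genes"])
    return sets, venn


def expression_levels(
    coverage: CoverageTrack, annotation: GenomeAnnotation
) -> pd.Series:
    """Per-gene mean mRNA coverage per kilobase per million counted bases.

    level = mean per-base coverage over the gene's exons x 1e9 / total
    aligned bases in the sample.
    """
    total = coverage.total_bases
    if total <= 0:
        raise LmseqError("coverage track is empty; cannot compute levels")
    levels = {}
    for gene in annotation.genes:
        arr = coverage[gene.contig]
        covered = sum(int(arr[s:e].sum()) for s, e in gene.exons)
        mean_cov = covered / gene.transcript_length
        levels[gene.gene_id] = mean_cov * 1e9 / total
    series = pd.Series(levels, name="level")
    series.index.name = "gene_id"
    return series


@dataclass
class MixtureFit:
    """A 1-D Gaussian mixture selected by BIC."""

    n_components: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    variances: tuple[float, ...]
    bic: dict[int, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": range(1, self.n_components + 1),
                "weight": self.weights,
                "mean": self.means,
                "variance": self.variances,
            }
        )


def fit_expression_mixture(
    log2_levels: Sequence[float],
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of 1..k_max Gaussian components to log2 expression levels.

    Components are 1-D Gaussians; the component count is chosen by BIC
    among fits whose smallest weight is at least 1/n (a k whose best fit
    leaves a component effectively empty is not considered).
    """
    x = np.asarray(log2_levels, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise LmseqError(f"refusing to fit a mixture to {len(x)} genes (< 10)")
    fits: dict[int, GaussianMixture] = {}
    bic: dict[int, float] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            n_init=3,
            random_state=seed,
            reg_covar=1e-6,
        )
        gm.fit(x)
        if gm.weights_.min() < 1.0 / len(x):
            continue
        fits[k] = gm
        bic[k] = float(gm.bic(x))
    if not bic:
        raise LmseqError("no admissible mixture fit")
    best_k = min(bic, key=lambda k: (bic[k], k))
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        n_components=best_k,
        weights=tuple(float(w) for w in gm.weights_[order]),
        means=tuple(float(m) for m in gm.means_.ravel()[order]),
        variances=tuple(float(v) for v in gm.covariances_.ravel()[order]),
        bic=bic,
    )


def expression_distribution(
    coverage: CoverageTrack,
    annotation: GenomeAnnotation,
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
) -> tuple[pd.Series, MixtureFit]:
    """Levels plus mixture fit; genes with zero coverage are excluded from
    the log2 set."""
    levels = expression_levels(coverage, annotation)
    positive = levels[levels > 0]
    fit = fit_expression_mixture(np.log2(positive.to_numpy()), k_max=k_max, seed=seed)
    return levels, fit
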