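"""Replicate-ratio classification, a Bayesian count-ratio model, and the
two-threshold consensus caller.

The "classical analysis" computes, per gene and comparison, the normalized
count ratio of each replicate pair, their mean, standard deviation and
coefficient of variance (CV = sd / mean), and sorts genes into stringency
groups::

    group 4 : every replicate ratio >= 4, or every ratio <= 0.25
    group 3 : mean ratio >= 4 or <= 0.25, and CV < 0.5
    group 2 : every replicate ratio >= 2, or every ratio <= 0.5
    group 1 : mean ratio >= 2 or <= 0.5, and CV < 0.5
    group 0 : everything else

A gene satisfying several criteria gets the highest group.  The "all
replicates" criteria require directional consistency (all up or all down).
Genes with no computable ratio (denominator zero in every pair) are
excluded from the analysis.

The Bayesian model is a gamma-Poisson rate-ratio: per condition the read
rate gets a Jeffreys Gamma(sum(k) + 1/2, sum(totals)) posterior with the
per-sample counted-read totals as exposure; Monte-Carlo draws of the rate
ratio give the posterior mean, an equal-tailed 95% credible interval, and
p_diff = max(P(ratio > 1), P(ratio < 1)).  It stands in for external
count-ratio programs that report Bayesian credible intervals, without
reproducing any particular program's model.

A gene is called up (+1) or down (-1) only when both methods put the mean
ratio beyond the comparison's fold threshold (4x for like-vs-like
comparisons, 8x for microdissected-vs-total comparisons) in the same
direction, p_diff is indistinguishable from 1, and the gene sits in
classical groups 1-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import ConfigError

THRESHOLDS = {"fourfold": 4.0, "eightfold": 8.0}
DEFAULT_P_MIN = 0.999
EXCLUDED = "excluded"
LOG2_ZERO_DENOM = 20.0
LOG2_ZERO_NUM = -20.0


@dataclass
class ClassicalResult:
    gene_id: str
    comparison: tuple[str, str]
    replicate_ratios: tuple[float, ...]
    mean_ratio: float
    sd: float
    cv: float
    group: object  # 0..4 or EXCLUDED


@dataclass
class BayesResult:
    gene_id: str
    posterior_mean_ratio: float
    credible_interval: tuple[float, float]
    p_diff: float


@dataclass
class ConsensusCall:
    gene_id: str
    comparison: tuple[str, str]
    call: int  # -1, 0, +1
    threshold_set: str


def assign_group(ratios: Sequence[float]) -> object:
    """Sort one gene's replicate ratios into groups 0-4 (or excluded)."""
    if len(ratios) == 0:
        return EXCLUDED
    r = np.asarray(ratios, dtype=float)
    mean = float(r.mean())
    sd = float(r.std(ddof=1)) if len(r) > 1 else 0.0
    if mean > 0:
        cv = sd / mean
    else:
        cv = 0.0 if sd == 0 else float("inf")
    if (r >= 4).all() or (r <= 0.25).all():
        return 4
    if (mean >= 4 or mean <= 0.25) and cv < 0.5:
        return 3
    if (r >= 2).all() or (r <= 0.5).all():
        return 2
    if (mean >= 2 or mean <= 0.5) and cv < 0.5:
        return 1
    return 0


def classical_analysis(
    norm_matrix: pd.DataFrame,
    comparison: tuple[str, str],
    cols_a: Sequence[str],
    cols_b: Sequence[str],
) -> list[ClassicalResult]:
    """Replicate-ratio classification of every gene for one comparison.

    ``cols_a``/``cols_b`` name the replicate columns of the two conditions
    in ``norm_matrix`` (normalized counts).  Replicate i of A pairs with
    replicate i of B; with unequal replicate numbers all pairwise ratios
    are used.  A ratio is defined only where the denominator is positive.
    """
    for col in list(cols_a) + list(cols_b):
        if col not in norm_matrix.columns:
            raise ConfigError(f"comparison references unknown sample column {col!r}")
    if len(cols_a) == len(cols_b):
        pairs = list(zip(cols_a, cols_b))
    else:
        pairs = [(a, b) for a in cols_a for b in cols_b]
    results: list[ClassicalResult] = []
    for gene_id, row in norm_matrix.iterrows():
        ratios = tuple(
            float(row[a]) / float(row[b]) for a, b in pairs if float(row[b]) > 0
        )
        if not ratios:
            results.append(
                ClassicalResult(gene_id, comparison, (), float("nan"),
                                float("nan"), float("nan"), EXCLUDED)
            )
            continue
        r = np.asarray(ratios)
        mean = float(r.mean())
        sd = float(r.std(ddof=1)) if len(r) > 1 else 0.0
        if mean > 0:
            cv = sd / mean
        else:
            cv = 0.0 if sd == 0 else float("inf")
        results.append(
            ClassicalResult(gene_id, comparison, ratios, mean, sd, cv,
                            assign_group(ratios))
        )
    return results


def bayes_ratio(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    totals_a: Sequence[int],
    totals_b: Sequence[int],
    n_draws: int = 10_000,
    seed: int = 0,
    gene_id: str = "",
) -> Optional[BayesResult]:
    """Posterior of the per-read rate ratio of one gene between conditions.

    Replicates are pooled: the condition rate has a
    Gamma(sum(k) + 1/2, sum(totals)) posterior (Jeffreys prior, totals as
    exposure).  Returns None when both conditions have zero counts.
    """
    ka, kb = int(np.sum(counts_a)), int(np.sum(counts_b))
    ta, tb = float(np.sum(totals_a)), float(np.sum(totals_b))
    if ta <= 0 or tb <= 0:
        raise ConfigError("sample totals must be positive")
    if ka == 0 and kb == 0:
        return None
    rng = np.random.default_rng(seed)
    lam_a = rng.gamma(ka + 0.5, 1.0 / ta, n_draws)
    lam_b = rng.gamma(kb + 0.5, 1.0 / tb, n_draws)
    ratio = lam_a / lam_b
    p_up = float(np.mean(ratio > 1.0))
    lo, hi = np.quantile(ratio, [0.025, 0.975])
    return BayesResult(
        gene_id=gene_id,
        posterior_mean_ratio=float(ratio.mean()),
        credible_interval=(float(lo), float(hi)),
        p_diff=max(p_up, 1.0 - p_up),
    )


def consensus_call(
    classical: Optional[ClassicalResult],
    bayes: Optional[BayesResult],
    threshold_set: str,
    p_min: float = DEFAULT_P_MIN,
) -> ConsensusCall:
    """Combine both methods into an up/down/unchanged verdict.

    +1 requires mean ratios from both methods above the fold threshold,
    p_diff >= ``p_min`` and classical group 1-4; -1 mirrors this below the
    inverse threshold.  A missing or excluded component yields 0.
    """
    if threshold_set not in THRESHOLDS:
        raise ConfigError(f"unknown threshold_set {threshold_set!r}")
    T = THRESHOLDS[threshold_set]
    gene_id = classical.gene_id if classical else (bayes.gene_id if bayes else "")
    comparison = classical.comparison if classical else ("", "")
    call = 0
    if (
        classical is not None
        and bayes is not None
        and classical.group in (1, 2, 3, 4)
        and bayes.p_diff >= p_min
    ):
        if classical.mean_ratio > T and bayes.posterior_mean_ratio > T:
            call = 1
        elif classical.mean_ratio < 1.0 / T and bayes.posterior_mean_ratio < 1.0 / T:
            call = -1
    return ConsensusCall(gene_id, comparison, call, threshold_set)


def ma_log2_ratio(a: float, b: float) -> float:
    """log2(a/b) with the zero-count conventions of the MA plots.

    A zero denominator maps to +20, a zero numerator to -20; genes with
    zero on both sides have no defined ratio (NaN).
    """
    if a == 0 and b == 0:
        return float("nan")
    if b == 0:
        return LOG2_ZERO_DENOM
    if a == 0:
        return LOG2_ZERO_NUM
    return math.log2(a / b)


def ma_table(
    norm_matrix: pd.DataFrame,
    cols_a: Sequence[str],
    cols_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene (A, M) values: average count and log2 ratio of means."""
    mean_a = norm_matrix[list(cols_a)].mean(axis=1)
    mean_b = norm_matrix[list(cols_b)].mean(axis=1)
    m = [ma_log2_ratio(a, b) for a, b in zip(mean_a, mean_b)]
    out = pd.DataFrame(
        {"A": norm_matrix[list(cols_a) + list(cols_b)].mean(axis=1), "M": m},
        index=norm_matrix.index,
    )
    return out


def differential_expression(
    counts: pd.DataFrame,
    totals: pd.Series,
    comparison: tuple[str, str],
    cols_a: Sequence[str],
    cols_b: Sequence[str],
    threshold_set: str,
    p_min: float = DEFAULT_P_MIN,
    n_draws: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-gene DE table for one comparison (classical + Bayes + consensus)."""
    norm = counts.div(totals.astype(float), axis=1) * 1e6
    classical = classical_analysis(norm, comparison, cols_a, cols_b)
    tot_a = [int(totals[c]) for c in cols_a]
    tot_b = [int(totals[c]) for c in cols_b]
    rows = []
    child = np.random.SeedSequence(seed).spawn(len(classical))
    for cres, seq in zip(classical, child):
        gene_id = cres.gene_id
        bres = bayes_ratio(
            counts.loc[gene_id, list(cols_a)].to_numpy(),
            counts.loc[gene_id, list(cols_b)].to_numpy(),
            tot_a,
            tot_b,
            n_draws=n_draws,
            seed=seq,
            gene_id=gene_id,
        )
        verdict = consensus_call(
            cres if cres.group != EXCLUDED else None, bres, threshold_set, p_min
        )
        rows.append(
            {
                "gene_id": gene_id,
                "ratios": ";".join(f"{r:.6g}" for r in cres.replicate_ratios),
                "mean_ratio": cres.mean_ratio,
                "sd": cres.sd,
                "cv": cres.cv,
                "group": cres.group,
                "bayes_mean_ratio": bres.posterior_mean_ratio if bres else float("nan"),
                "ci_low": bres.credible_interval[0] if bres else float("nan"),
                "ci_high": bres.credible_interval[1] if bres else float("nan"),
                "p_diff": bres.p_diff if bres else float("nan"),
                "consensus": verdict.call,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
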