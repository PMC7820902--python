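"""Relevance scores, minimum-strategy integration, and rank aggregation.

Per-omics relevance scores are W = D @ S: the diffusion matrix spreads each
sample's (column-normalized) mutation or differential-expression signal over
the network, so a gene scores highly when it is proximal to that sample's
altered genes. The two omics are integrated elementwise; the minimum ("double
high") strategy keeps a gene only as high as its weaker evidence channel,
suppressing single-omics outliers. Per-sample scores become within-sample
ranks (rank 1 = highest score) and the cohort ranking is the ascending sum of
per-sample ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .network import DiffusionMatrix
from .omics import OmicsScoreMatrix


@dataclass(frozen=True)
class RelevanceScoreMatrix:
    """Gene x sample diffused scores, or their elementwise integration."""

    matrix: np.ndarray = field(repr=False)
    gene_order: tuple[str, ...]
    samples: tuple[str, ...]
    source: str  # {mutation, expression, integrated}
    strategy: str | None = None  # {min, mean, max} when integrated


@dataclass(frozen=True)
class GeneRanking:
    """Ordered gene list (best first) with the per-gene aggregate score.

    ``scores`` aligns with ``genes``. For aggregated rankings the score is the
    sum of per-sample ranks (lower is better); for metric baselines it is the
    metric value (higher is better). Ties are always broken lexicographically.
    """

    genes: tuple[str, ...]
    scores: tuple[float, ...]
    score_kind: str  # {rank_sum, metric}
    rank_matrix: np.ndarray | None = field(default=None, repr=False)
    rank_matrix_genes: tuple[str, ...] | None = field(default=None, repr=False)
    samples: tuple[str, ...] | None = None

    @classmethod
    def from_metric(cls, values: Mapping[str, float], higher_is_better: bool) -> "GeneRanking":
        sign = -1.0 if higher_is_better else 1.0
        ordered = sorted(values, key=lambda g: (sign * values[g], g))
        return cls(
            genes=tuple(ordered),
            scores=tuple(values[g] for g in ordered),
            score_kind="metric" if higher_is_better else "rank_sum",
        )

    def top(self, n: int) -> tuple[str, ...]:
        return self.genes[:n]

    def __len__(self) -> int:
        return len(self.genes)


def relevance_scores(d: DiffusionMatrix, s: OmicsScoreMatrix) -> RelevanceScoreMatrix:
    """W = D @ S. Gene orders must be identical; no silent realignment."""
    if tuple(d.gene_order) != tuple(s.gene_order):
        raise ValueError("gene order of the diffusion matrix and score matrix differ")
    if not s.normalized:
        raise ValueError("score matrix must be column-normalized before diffusion")
    return RelevanceScoreMatrix(
        matrix=d.matrix @ s.matrix,
        gene_order=tuple(d.gene_order),
        samples=tuple(s.samples),
        source=s.kind,
    )


def integrate(
    wm: RelevanceScoreMatrix, we: RelevanceScoreMatrix, strategy: str = "min"
) -> RelevanceScoreMatrix:
    """Combine mutation and expression relevance scores elementwise."""
    if tuple(wm.gene_order) != tuple(we.gene_order):
        raise ValueError("gene orders differ between the two relevance matrices")
    if tuple(wm.samples) != tuple(we.samples):
        only_m = set(wm.samples) - set(we.samples)
        only_e = set(we.samples) - set(wm.samples)
        raise ValueError(
            f"sample sets differ: {sorted(only_m)} only in mutation, "
            f"{sorted(only_e)} only in expression"
        )
    ops = {"min": np.minimum, "max": np.maximum, "mean": lambda a, b: 0.5 * (a + b)}
    if strategy not in ops:
        raise ValueError(f"unknown integration strategy {strategy!r}")
    return RelevanceScoreMatrix(
        matrix=ops[strategy](wm.matrix, we.matrix),
        gene_order=tuple(wm.gene_order),
        samples=tuple(wm.samples),
        source="integrated",
        strategy=strategy,
    )


def per_sample_ranks(w: RelevanceScoreMatrix) -> np.ndarray:
    """Within-sample ranks: rank 1 = largest score; ties get average ranks."""
    if w.matrix.size == 0:
        raise ValueError("empty relevance matrix")
    return scipy.stats.rankdata(-w.matrix, axis=0, method="average")


def aggregate_ranks(
    rank_matrix: np.ndarray,
    gene_order: Sequence[str],
    samples: Sequence[str] | None = None,
) -> GeneRanking:
    """Sum per-sample ranks into the population-level ranking (ascending)."""
    if rank_matrix.ndim != 2 or rank_matrix.shape[1] < 1:
        raise ValueError("rank matrix must have at least one sample column")
    agg = rank_matrix.sum(axis=1)
    order = sorted(range(len(gene_order)), key=lambda i: (agg[i], gene_order[i]))
    return GeneRanking(
        genes=tuple(gene_order[i] for i in order),
        scores=tuple(float(agg[i]) for i in order),
        score_kind="rank_sum",
        rank_matrix=rank_matrix,
        rank_matrix_genes=tuple(gene_order),
        samples=tuple(samples) if samples is not None else None,
    )


def rank_integrated(w: RelevanceScoreMatrix) -> GeneRanking:
    """Convenience: per-sample ranks of W followed by rank-sum aggregation."""
    return aggregate_ranks(per_sample_ranks(w), w.gene_order, w.samples)


def frequency_baseline(sm: OmicsScoreMatrix) -> GeneRanking:
    """Rank genes by the fraction of samples in which they are mutated."""
    if sm.normalized:
        raise ValueError("frequency baseline needs the unnormalized mutation matrix")
    freq = (sm.matrix > 0).mean(axis=1)
    return GeneRanking.from_metric(
        {g: float(freq[i]) for i, g in enumerate(sm.gene_order)}, higher_is_better=True
    )


def min_source_proportions(
    wm: RelevanceScoreMatrix,
    we: RelevanceScoreMatrix,
    w_min: RelevanceScoreMatrix,
    top_genes: Sequence[str],
) -> tuple[float, float]:
    """Which omics supplies the min-score, over (gene, sample) cells of ``top_genes``.

    Returns the (mutation fraction, expression fraction); exact ties count in
    both, so the pair may sum to more than 1.
    """
    if w_min.strategy != "min":
        raise ValueError("w_min must come from the min integration strategy")
    index = {g: i for i, g in enumerate(w_min.gene_order)}
    missing = [g for g in top_genes if g not in index]
    if missing:
        raise ValueError(f"genes not in the ranking universe: {missing}")
    rows = [index[g] for g in top_genes]
    from_mut = (w_min.matrix[rows] == wm.matrix[rows]).mean()
    from_expr = (w_min.matrix[rows] == we.matrix[rows]).mean()
    return float(from_mut), float(from_expr)
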