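"""Benchmarking a gene ranking against a gold-standard cancer-gene set.

Metrics are computed over the top N genes (N = 50 by default): precision at
each cutoff i, recall against the T gold genes, the F1 harmonic mean, and the
partial AUC

    AUC_n = (1 / (n * T)) * sum_{i=1..n} T_i,

where T_i is the number of gold ("positive") genes ranked above the i-th
highest-ranked non-gold ("negative") gene. Partial AUC is informative when
positives are vastly outnumbered by negatives, as known cancer genes are. The
robustness protocol reruns the whole ranking on random sample subsets of
increasing size and summarizes metric stability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .ranking import GeneRanking

logger = logging.getLogger(__name__)


def load_gold_standard(path: str | Path) -> frozenset[str]:
    """Read a gold-standard gene list: one symbol per line, '#' comments skipped."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip()
        if sym and not sym.startswith("#"):
            genes.add(sym)
    if not genes:
        raise ValueError(f"{path}: gold-standard list is empty")
    return frozenset(genes)


@dataclass(frozen=True)
class EvaluationResult:
    """Precision/recall/F1 curves over cutoffs 1..N plus the partial AUC."""

    cutoffs: tuple[int, ...]
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    partial_auc: float
    n_top: int
    gold_size: int

    @property
    def precision_at_top(self) -> float:
        return self.precision[-1]

    @property
    def f1_at_top(self) -> float:
        return self.f1[-1]

    @property
    def mean_precision(self) -> float:
        """P = mean(p_i) over i = 1..N, the robustness summary statistic."""
        return float(np.mean(self.precision))


def _restricted_gold(ranking: GeneRanking, gold: Iterable[str], restrict: bool) -> frozenset[str]:
    gold = frozenset(gold)
    if restrict:
        gold = gold & frozenset(ranking.genes)
    return gold


def precision_recall_f1(
    ranking: GeneRanking,
    gold: Iterable[str],
    n_top: int = 50,
    restrict_gold_to_universe: bool = True,
) -> EvaluationResult:
    """Precision, recall and F1 at every cutoff i = 1..n_top.

    ``restrict_gold_to_universe`` counts only gold genes present in the
    ranking's gene universe toward T (recall's denominator), since genes
    absent from the network can never be recovered.
    """
    gold = _restricted_gold(ranking, gold, restrict_gold_to_universe)
    if not gold:
        raise ValueError("gold-standard set is empty (after restriction to the ranking universe)")
    if n_top > len(ranking):
        raise ValueError(f"cutoff {n_top} exceeds ranking length {len(ranking)}")
    t = len(gold)
    hits = 0
    prec, rec, f1s = [], [], []
    for i, gene in enumerate(ranking.genes[:n_top], start=1):
        if gene in gold:
            hits += 1
        p = hits / i
        r = hits / t
        f1s.append(0.0 if (p + r) == 0 else 2 * p * r / (p + r))
        prec.append(p)
        rec.append(r)
    try:
        pauc = partial_auc(ranking, gold, n_top, restrict_gold_to_universe=False)
    except ValueError:
        # tiny rankings can lack n_top negatives; the curves are still defined
        pauc = float("nan")
    return EvaluationResult(
        cutoffs=tuple(range(1, n_top + 1)),
        precision=tuple(prec),
        recall=tuple(rec),
        f1=tuple(f1s),
        partial_auc=pauc,
        n_top=n_top,
        gold_size=t,
    )


def partial_auc(
    ranking: GeneRanking,
    gold: Iterable[str],
    n_top: int = 50,
    restrict_gold_to_universe: bool = True,
) -> float:
    """AUC_n: positives ranked above each of the top n negatives, / (n * T)."""
    gold = _restricted_gold(ranking, gold, restrict_gold_to_universe)
    if not gold:
        raise ValueError("gold-standard set is empty (after restriction to the ranking universe)")
    t = len(gold)
    t_i_sum = 0
    n_neg_seen = 0
    positives_above = 0
    for gene in ranking.genes:
        if gene in gold:
            positives_above += 1
        else:
            n_neg_seen += 1
            t_i_sum += positives_above
            if n_neg_seen == n_top:
                break
    if n_neg_seen < n_top:
        raise ValueError(
            f"ranking contains only {n_neg_seen} negatives, need {n_top} for the partial AUC"
        )
    return t_i_sum / (n_top * t)


@dataclass(frozen=True)
class RobustnessResult:
    """Mean and SD of P = mean(p_i), F1 and partial AUC per subset size."""

    sizes: tuple[int, ...]
    repeats: int
    seed: int
    mean_precision: dict[int, tuple[float, float]] = field(repr=False)
    f1: dict[int, tuple[float, float]] = field(repr=False)
    partial_auc: dict[int, tuple[float, float]] = field(repr=False)
    n_missing: dict[int, int] = field(repr=False)


def subsample_size_grid(n_samples: int) -> list[int]:
    """Subset sizes 10, 25, 50, 100, ..., 50 * ceil(N/50) capped at the cohort size."""
    sizes = [10, 25] + [50 * k for k in range(1, math.ceil(n_samples / 50) + 1)]
    return sorted({min(s, n_samples) for s in sizes if s <= n_samples} | {n_samples})


def robustness_subsample(
    rank_fn: Callable[[Sequence[str]], GeneRanking],
    cohort_samples: Sequence[str],
    gold: Iterable[str],
    sizes: Sequence[int],
    repeats: int = 10,
    seed: int = 0,
    n_top: int = 50,
) -> RobustnessResult:
    """Rerun the ranking pipeline on random sample subsets and summarize stability.

    ``rank_fn`` maps a subset of sample ids to a population-level ranking (the
    pipeline module provides a ready-made closure over a cohort). Subsets are
    drawn without replacement; the RNG for each draw is seeded by
    (master seed, size, repeat) so adding sizes never perturbs earlier draws.
    A repeat whose pipeline fails (e.g. no network-mapped mutation in the
    subset) is recorded as missing.
    """
    if repeats < 2:
        raise ValueError("need at least 2 repeats to report an SD")
    cohort = list(cohort_samples)
    for s in sizes:
        if s > len(cohort):
            raise ValueError(f"subset size {s} exceeds cohort size {len(cohort)}")
    gold = frozenset(gold)
    mean_p, f1_d, pauc_d, missing = {}, {}, {}, {}
    for size in sizes:
        vals_p, vals_f1, vals_auc = [], [], []
        n_miss = 0
        for rep in range(repeats):
            rng = np.random.default_rng([seed, size, rep])
            subset = [cohort[i] for i in rng.choice(len(cohort), size=size, replace=False)]
            try:
                ranking = rank_fn(subset)
                res = precision_recall_f1(ranking, gold, n_top)
            except ValueError as exc:
                logger.warning("size %d repeat %d skipped: %s", size, rep, exc)
                n_miss += 1
                continue
            vals_p.append(res.mean_precision)
            vals_f1.append(res.f1_at_top)
            vals_auc.append(res.partial_auc)
        if not vals_p:
            raise ValueError(f"all {repeats} repeats failed at size {size}")
        mean_p[size] = (float(np.mean(vals_p)), float(np.std(vals_p)))
        f1_d[size] = (float(np.mean(vals_f1)), float(np.std(vals_f1)))
        pauc_d[size] = (float(np.mean(vals_auc)), float(np.std(vals_auc)))
        missing[size] = n_miss
    return RobustnessResult(
        sizes=tuple(sizes),
        repeats=repeats,
        seed=seed,
        mean_precision=mean_p,
        f1=f1_d,
        partial_auc=pauc_d,
        n_missing=missing,
    )
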