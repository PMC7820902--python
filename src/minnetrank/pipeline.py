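"""End-to-end orchestration: diffuse -> score -> integrate -> rank -> evaluate -> stratify.

The library functions here stitch the per-module operations together. The
integrated analysis runs on the intersection of samples having both mutation
and expression data; single-omics rankings use their full cohorts. A run is
fully determined by its :class:`RunConfig` and master seed; stage-specific
seeds are fanned out from the master seed so stages stay independent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    load_gold_standard,
    precision_recall_f1,
    robustness_subsample,
    subsample_size_grid,
)
from .network import (
    DiffusionMatrix,
    InteractionNetwork,
    compute_diffusion,
    load_network,
    normalize_adjacency,
)
from .omics import (
    OmicsScoreMatrix,
    VariantRecord,
    build_mutation_scores,
    column_normalize,
    compute_alfc,
    read_maf,
)
from .ranking import (
    GeneRanking,
    integrate,
    min_source_proportions,
    rank_integrated,
    relevance_scores,
)
from .simulate import read_expression, read_pairing
from .stratify import load_survival, stratify
from .weighting import WeightScheme, assign_variant_weights

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a full run; defaults follow the published study settings."""

    network: str = ""
    maf: str = ""
    tumor_expr: str = ""
    normal_expr: str = ""
    pairing: str | None = None
    gold: str | None = None
    survival: str | None = None
    out_dir: str = "minnetrank_out"

    beta: float = 0.48
    weight_scheme: str = "uniform"
    prdsm_threshold: float = 0.308
    sift_transform: str = "as_stated"
    strategy: str = "min"
    pseudocount: float = 0.5
    top_n: int = 50
    robustness_sizes: list[int] = field(default_factory=list)
    robustness_repeats: int = 10
    stratify_top_k: int = 7
    sd_threshold: float = 5.0
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")
        if self.strategy not in ("min", "mean", "max", "mutation", "expression"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def scheme(self) -> WeightScheme:
        return WeightScheme(
            name=self.weight_scheme,
            prdsm_threshold=self.prdsm_threshold,
            sift_transform=self.sift_transform,
        )


def build_diffusion(net: InteractionNetwork, beta: float = 0.48) -> DiffusionMatrix:
    return compute_diffusion(normalize_adjacency(net), beta)


@dataclass(frozen=True)
class CohortScores:
    """Relevance score matrices of one cohort run, plus the derived ranking."""

    ranking: GeneRanking
    wm: object | None = None
    we: object | None = None
    w: object | None = None


def rank_cohort(
    net: InteractionNetwork,
    diffusion: DiffusionMatrix,
    variants: Sequence[VariantRecord],
    tumor_expr: pd.DataFrame,
    normal_expr: pd.DataFrame,
    pairing: Mapping[str, str] | None = None,
    scheme: WeightScheme | None = None,
    strategy: str = "min",
    samples: Sequence[str] | None = None,
    pseudocount: float = 0.5,
) -> CohortScores:
    """Full single-cohort ranking.

    ``strategy`` selects min/mean/max integration, or the single-omics
    variants ``"mutation"`` / ``"expression"``. For integrated strategies the
    sample universe defaults to the intersection of the mutation and tumor
    expression cohorts (in expression column order).
    """
    scheme = scheme or WeightScheme()
    weighted = assign_variant_weights(variants, scheme)
    # cohort membership is defined by having mutation data at all, not by
    # surviving the weighting scheme (a sample whose variants are all dropped
    # keeps an all-zero column, which is a reported condition downstream)
    mut_samples = {v.sample for v in variants}
    expr_samples = list(tumor_expr.columns)

    if strategy == "mutation":
        use = list(samples) if samples is not None else sorted(mut_samples)
        in_use = set(use)
        sm = build_mutation_scores(
            [v for v in weighted if v.sample in in_use], net, use,
            cap_at_one=scheme.name == "uniform",
        )
        wm = relevance_scores(diffusion, column_normalize(sm))
        return CohortScores(ranking=rank_integrated(wm), wm=wm)
    if strategy == "expression":
        use = list(samples) if samples is not None else expr_samples
        se = compute_alfc(tumor_expr[use], normal_expr, net, pairing, pseudocount)
        we = relevance_scores(diffusion, column_normalize(se))
        return CohortScores(ranking=rank_integrated(we), we=we)

    if samples is not None:
        use = list(samples)
    else:
        use = [s for s in expr_samples if s in mut_samples]
    if not use:
        raise ValueError("no samples with both mutation and expression data")
    in_use = set(use)
    sm = build_mutation_scores(
        [v for v in weighted if v.sample in in_use], net, use,
        cap_at_one=scheme.name == "uniform",
    )
    se = compute_alfc(tumor_expr[use], normal_expr, net, pairing, pseudocount)
    wm = relevance_scores(diffusion, column_normalize(sm))
    we = relevance_scores(diffusion, column_normalize(se))
    w = integrate(wm, we, strategy)
    return CohortScores(ranking=rank_integrated(w), wm=wm, we=we, w=w)


def write_ranking(ranking: GeneRanking, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgene\taggregate_score\n")
        for i, (g, s) in enumerate(zip(ranking.genes, ranking.scores), start=1):
            fh.write(f"{i}\t{g}\t{s:.10g}\n")


def read_ranking(path: str | Path) -> GeneRanking:
    df = pd.read_csv(path, sep="\t")
    return GeneRanking(
        genes=tuple(df["gene"].astype(str)),
        scores=tuple(df["aggregate_score"].astype(float)),
        score_kind="rank_sum",
    )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the configured end-to-end run and write its artifacts.

    Writes ``ranking.tsv``, ``top_genes.tsv``, optional ``evaluation.json``,
    ``robustness.json``, ``stratification.tsv``/``stratification.json``, and a
    ``manifest.json`` echoing the config, input hashes, and package version.
    Returns the in-memory results keyed by artifact name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load inputs"
    try:
        net = load_network(config.network)
        variants = read_maf(config.maf)
        tumor = read_expression(config.tumor_expr)
        normal = read_expression(config.normal_expr)
        pairing = read_pairing(config.pairing) if config.pairing else None

        stage = "diffusion"
        diffusion = build_diffusion(net, config.beta)

        stage = "ranking"
        seeds = np.random.SeedSequence(config.seed).generate_state(4) >> 1
        scores = rank_cohort(
            net, diffusion, variants, tumor, normal, pairing,
            scheme=config.scheme(), strategy=config.strategy,
            pseudocount=config.pseudocount,
        )
        write_ranking(scores.ranking, out / "ranking.tsv")
        results: dict[str, object] = {"ranking": scores.ranking}

        top = scores.ranking.top(config.top_n)
        (out / "top_genes.tsv").write_text("".join(f"{g}\n" for g in top))
        if scores.w is not None:
            mut_prop, expr_prop = min_source_proportions(scores.wm, scores.we, scores.w, top)
            results["min_source_proportions"] = (mut_prop, expr_prop)

        if config.gold:
            stage = "evaluation"
            gold = load_gold_standard(config.gold)
            ev = precision_recall_f1(scores.ranking, gold, config.top_n)
            results["evaluation"] = ev
            (out / "evaluation.json").write_text(json.dumps({
                "precision_at_top": ev.precision_at_top,
                "mean_precision": ev.mean_precision,
                "f1_at_top": ev.f1_at_top,
                "partial_auc": ev.partial_auc,
                "n_top": ev.n_top,
                "gold_size": ev.gold_size,
            }, indent=2))

            if config.robustness_sizes:
                stage = "robustness"
                cohort = list(scores.ranking.samples or [])
                sizes = [s for s in config.robustness_sizes if s <= len(cohort)]
                if sizes:
                    def rank_fn(subset: Sequence[str]) -> GeneRanking:
                        return rank_cohort(
                            net, diffusion, variants, tumor, normal, pairing,
                            scheme=config.scheme(), strategy=config.strategy,
                            samples=subset, pseudocount=config.pseudocount,
                        ).ranking

                    rob = robustness_subsample(
                        rank_fn, cohort, gold, sizes,
                        repeats=config.robustness_repeats, seed=int(seeds[1]),
                        n_top=config.top_n,
                    )
                    results["robustness"] = rob
                    (out / "robustness.json").write_text(json.dumps({
                        "sizes": list(rob.sizes),
                        "repeats": rob.repeats,
                        "mean_precision": {str(k): v for k, v in rob.mean_precision.items()},
                        "f1": {str(k): v for k, v in rob.f1.items()},
                        "partial_auc": {str(k): v for k, v in rob.partial_auc.items()},
                    }, indent=2))

        if config.survival:
            stage = "stratification"
            surv = load_survival(config.survival)
            strat = stratify(
                scores.ranking, tumor, surv,
                top_k=config.stratify_top_k, sd_threshold=config.sd_threshold,
                seed=int(seeds[2]),
            )
            results["stratification"] = strat
            with open(out / "stratification.tsv", "w") as fh:
                fh.write("sample\tgroup\n")
                for s in sorted(strat.labels):
                    fh.write(f"{s}\t{strat.labels[s]}\n")
            (out / "stratification.json").write_text(json.dumps({
                "biomarkers": list(strat.biomarkers),
                "statistic": strat.statistic,
                "p_value": strat.p_value,
                "degenerate": strat.degenerate,
            }, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            key: _sha256(p)
            for key, p in (
                ("network", config.network), ("maf", config.maf),
                ("tumor_expr", config.tumor_expr), ("normal_expr", config.normal_expr),
                ("pairing", config.pairing), ("gold", config.gold),
                ("survival", config.survival),
            )
            if p
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
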