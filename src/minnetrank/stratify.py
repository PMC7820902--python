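"""Survival risk stratification from top-ranked biomarker genes.

Walking the population-level ranking best-first, the first ``top_k`` genes
whose tumor-expression standard deviation exceeds a threshold are kept as
biomarkers (low-variance genes carry little stratification signal; the
threshold is on the scale of the supplied expression matrix). Patients are
clustered into two groups by k-means on the z-scored biomarker expression,
and the groups are compared by the two-sample log-rank test. "High risk" is
the group with the worse survival curve (smaller restricted mean survival
time), not a cluster index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from sklearn.cluster import KMeans

from .ranking import GeneRanking

logger = logging.getLogger(__name__)


def load_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival table TSV with columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in ("sample", "time", "event") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing survival columns {missing}")
    if (df["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")
    return df[["sample", "time", "event"]].astype({"sample": str, "time": float, "event": int})


@dataclass(frozen=True)
class StratificationResult:
    biomarkers: tuple[str, ...]
    labels: dict[str, str]  # sample -> {"high_risk", "low_risk"}
    statistic: float | None
    p_value: float | None
    degenerate: bool
    seed: int | None = None


def select_biomarkers(
    ranking: GeneRanking,
    tumor_expr: pd.DataFrame,
    top_k: int = 7,
    sd_threshold: float = 5.0,
) -> tuple[str, ...]:
    """Top ``top_k`` ranked genes with expression SD above ``sd_threshold``."""
    chosen: list[str] = []
    for gene in ranking.genes:
        if gene not in tumor_expr.index:
            continue
        if tumor_expr.loc[gene].std(ddof=1) > sd_threshold:
            chosen.append(gene)
            if len(chosen) == top_k:
                return tuple(chosen)
    raise ValueError(
        f"only {len(chosen)} gene(s) pass SD > {sd_threshold}; {top_k} biomarkers requested"
    )


def cluster_patients(
    biomarker_expr: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    restarts: int = 25,
) -> pd.Series:
    """K-means cluster samples on z-scored biomarker expression (genes x samples).

    Features are standardized per gene so high-variance biomarkers do not
    dominate by scale. Best of ``restarts`` initializations by inertia;
    deterministic under a fixed seed. Returns a sample -> cluster-id Series.
    """
    if biomarker_expr.shape[1] < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-means, got {biomarker_expr.shape[1]}")
    x = biomarker_expr.T.to_numpy(dtype=float)  # samples x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x)
    if len(np.unique(labels)) < k:
        logger.warning("k-means produced fewer than %d non-empty clusters", k)
    return pd.Series(labels, index=biomarker_expr.columns, name="cluster")


def logrank_compare(
    cluster_labels: Mapping[str, int] | pd.Series,
    survival: pd.DataFrame,
    biomarkers: Sequence[str] = (),
    seed: int | None = None,
) -> StratificationResult:
    """Two-group log-rank test; the worse-surviving group is labeled high_risk.

    Group risk is decided by the restricted mean survival time up to the last
    time both groups still have follow-up; ties go to the group with more
    events. A grouping that leaves one side empty is flagged degenerate and
    carries no p-value.
    """
    labels = pd.Series(dict(cluster_labels))
    surv = survival.set_index("sample").loc[labels.index.intersection(survival["sample"])]
    labels = labels.loc[surv.index]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        return StratificationResult(
            biomarkers=tuple(biomarkers), labels={}, statistic=None, p_value=None,
            degenerate=True, seed=seed,
        )
    g0, g1 = (surv[labels == g] for g in groups)
    res = logrank_test(g0["time"], g1["time"], event_observed_A=g0["event"], event_observed_B=g1["event"])

    horizon = min(g0["time"].max(), g1["time"].max())
    rmst = []
    for g in (g0, g1):
        kmf = KaplanMeierFitter().fit(g["time"], g["event"])
        rmst.append(restricted_mean_survival_time(kmf, t=horizon))
    if rmst[0] != rmst[1]:
        high_idx = int(np.argmin(rmst))
    else:
        high_idx = int(np.argmax([g0["event"].sum(), g1["event"].sum()]))
    name = {groups[high_idx]: "high_risk", groups[1 - high_idx]: "low_risk"}
    return StratificationResult(
        biomarkers=tuple(biomarkers),
        labels={s: name[c] for s, c in labels.items()},
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        degenerate=False,
        seed=seed,
    )


def stratify(
    ranking: GeneRanking,
    tumor_expr: pd.DataFrame,
    survival: pd.DataFrame,
    top_k: int = 7,
    sd_threshold: float = 5.0,
    seed: int = 0,
    restarts: int = 25,
) -> StratificationResult:
    """Select biomarkers, cluster patients into two groups, and log-rank test."""
    biomarkers = select_biomarkers(ranking, tumor_expr, top_k, sd_threshold)
    shared = [s for s in tumor_expr.columns if s in set(survival["sample"])]
    clusters = cluster_patients(tumor_expr.loc[list(biomarkers), shared], seed=seed, restarts=restarts)
    return logrank_compare(clusters, survival, biomarkers=biomarkers, seed=seed)
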