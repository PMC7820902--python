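"""Gene x sample omics score matrices: mutation status and differential expression.

Both omics channels are represented the same way — a non-negative gene x sample
matrix aligned to the network's gene order — so that the diffusion matrix can
multiply either one. Mutation scores are per-variant weights summed per
(gene, sample); with uniform weights and capping this reduces to the classic
0/1 mutation-status matrix. Expression scores are the absolute log2 fold-change
(ALFC) between tumor and matched (or cohort-average) normal expression, which
captures up- and down-regulation symmetrically. Columns are normalized to unit
sum before diffusion so both channels live on a common per-sample scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

VARIANT_CLASSES = (
    "missense",
    "stop_gain",
    "stop_loss",
    "frameshift",
    "nonframeshift",
    "synonymous",
    "other",
)

#: Standard MAF Variant_Classification terms -> controlled vocabulary.
MAF_CLASS_MAP: dict[str, str] = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "stop_gain",
    "Nonstop_Mutation": "stop_loss",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "nonframeshift",
    "In_Frame_Ins": "nonframeshift",
    "Silent": "synonymous",
}


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call, optionally carrying a deleteriousness score.

    ``score`` holds the external predictor value appropriate to the class
    (SIFT for missense, PrDSM for synonymous, PredCID for frameshift);
    ``weight`` is filled in by a weighting scheme.
    """

    sample: str
    gene: str
    variant_class: str
    score: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"variant score must lie in [0, 1], got {self.score}")


def read_maf(path: str | Path) -> list[VariantRecord]:
    """Read a MAF-lite TSV into variant records.

    Requires columns ``Tumor_Sample_Barcode``, ``Hugo_Symbol``,
    ``Variant_Classification``; an optional ``Weight_Score`` column carries the
    external deleteriousness score. Classification terms already in the
    controlled vocabulary are accepted as-is; standard MAF terms are mapped;
    anything else becomes ``other``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing MAF columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        raw_class = getattr(row, "Variant_Classification")
        vclass = raw_class if raw_class in VARIANT_CLASSES else MAF_CLASS_MAP.get(raw_class, "other")
        score = None
        if "Weight_Score" in df.columns:
            raw = getattr(row, "Weight_Score")
            if raw is not None and not pd.isna(raw) and str(raw) != "":
                score = float(raw)
        records.append(
            VariantRecord(
                sample=getattr(row, "Tumor_Sample_Barcode"),
                gene=getattr(row, "Hugo_Symbol"),
                variant_class=vclass,
                score=score,
            )
        )
    return records


@dataclass(frozen=True)
class OmicsScoreMatrix:
    """Non-negative gene x sample scores aligned to a network's gene order."""

    matrix: np.ndarray = field(repr=False)
    gene_order: tuple[str, ...]
    samples: tuple[str, ...]
    kind: str  # {mutation, expression}
    normalized: bool = False
    zero_sample_ids: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.gene_order), columns=list(self.samples))


def build_mutation_scores(
    variants: Sequence[VariantRecord],
    net: InteractionNetwork,
    samples: Sequence[str],
    cap_at_one: bool = False,
) -> OmicsScoreMatrix:
    """Sum per-variant weights into the gene x sample mutation score matrix S^M.

    Variants must already carry weights (see the weighting module). Genes not
    in the network are dropped (count logged); variants for samples outside
    ``samples`` are skipped with a warning. ``cap_at_one`` clips entries at 1,
    which under the uniform scheme reproduces the 0/1 mutation-status matrix.
    """
    if not samples:
        raise ValueError("sample list is empty")
    idx = net.gene_index()
    sidx = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((net.n_genes, len(samples)))
    n_outside = 0
    n_unknown_sample = 0
    for v in variants:
        if v.weight is None:
            raise ValueError(f"variant {v.gene}/{v.sample} has no weight; run a weighting scheme first")
        if v.gene not in idx:
            n_outside += 1
            continue
        if v.sample not in sidx:
            n_unknown_sample += 1
            continue
        mat[idx[v.gene], sidx[v.sample]] += v.weight
    if n_outside:
        logger.info("dropped %d variant(s) in genes outside the network", n_outside)
    if n_unknown_sample:
        logger.warning("skipped %d variant(s) referencing unknown samples", n_unknown_sample)
    if cap_at_one:
        np.clip(mat, 0.0, 1.0, out=mat)
    return OmicsScoreMatrix(
        matrix=mat, gene_order=net.genes, samples=tuple(samples), kind="mutation"
    )


def compute_alfc(
    tumor_expr: pd.DataFrame,
    normal_expr: pd.DataFrame,
    net: InteractionNetwork,
    pairing: Mapping[str, str] | None = None,
    pseudocount: float = 0.5,
) -> OmicsScoreMatrix:
    """Absolute log2 fold-change scores S^E, aligned to the network genes.

    Expression frames are genes x samples with non-negative values. Tumor
    samples listed in ``pairing`` are compared to their matched normal; the
    rest fall back to the mean expression over all normal samples. A
    pseudocount is added to numerator and denominator so zero expression is
    well defined.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if normal_expr.shape[1] == 0:
        raise ValueError("no normal samples: ALFC needs at least one normal column")
    if tumor_expr.shape[1] == 0:
        raise ValueError("no tumor samples")
    if (tumor_expr.values < 0).any() or (normal_expr.values < 0).any():
        raise ValueError("expression values must be non-negative")
    pairing = dict(pairing or {})
    for t, nrm in pairing.items():
        if nrm not in normal_expr.columns:
            raise ValueError(f"paired normal sample {nrm!r} (for tumor {t!r}) not in normal matrix")

    shared = [g for g in net.genes if g in tumor_expr.index and g in normal_expr.index]
    n_dropped = len(set(tumor_expr.index) - set(net.genes))
    if n_dropped:
        logger.info("dropped %d expression gene(s) outside the network", n_dropped)
    samples = tuple(tumor_expr.columns)
    mat = np.zeros((net.n_genes, len(samples)))
    idx = net.gene_index()
    rows = [idx[g] for g in shared]
    tumor = tumor_expr.loc[shared]
    normal_mean = normal_expr.loc[shared].mean(axis=1).to_numpy()
    for j, s in enumerate(samples):
        t_vals = tumor[s].to_numpy()
        if s in pairing:
            n_vals = normal_expr.loc[shared, pairing[s]].to_numpy()
        else:
            n_vals = normal_mean
        mat[rows, j] = np.abs(np.log2((t_vals + pseudocount) / (n_vals + pseudocount)))
    return OmicsScoreMatrix(
        matrix=mat, gene_order=net.genes, samples=samples, kind="expression"
    )


def column_normalize(scores: OmicsScoreMatrix) -> OmicsScoreMatrix:
    """Divide each sample column by its sum; all-zero columns are left zero and reported."""
    if scores.normalized:
        raise ValueError("matrix is already normalized")
    col_sums = scores.matrix.sum(axis=0)
    zero = col_sums == 0
    zero_ids = tuple(s for s, z in zip(scores.samples, zero) if z)
    if zero_ids:
        logger.warning("%d sample(s) have all-zero %s scores: %s",
                       len(zero_ids), scores.kind, ", ".join(zero_ids[:10]))
    safe = np.where(zero, 1.0, col_sums)
    return replace(
        scores,
        matrix=scores.matrix / safe,
        normalized=True,
        zero_sample_ids=zero_ids,
    )
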