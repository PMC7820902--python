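"""Variant-type weighting schemes for the mutation score matrix.

The uniform scheme gives every non-synonymous variant weight 1 (the classic
binary mutation status). The weighted schemes replace selected classes with
external per-variant deleteriousness predictions, all on a [0, 1] scale:

* ``sift``              — missense weighted by SIFT; truncating/in-frame
                          indels and stop variants keep weight 1; synonymous
                          dropped.
* ``sift_prdsm``        — additionally keeps synonymous variants, weighted by
                          PrDSM.
* ``sift_prdsm_filtered`` — synonymous kept only when PrDSM exceeds the
                          deleteriousness threshold (default 0.308).
* ``sift_predcid``      — like ``sift`` but frameshift variants weighted by
                          PredCID.

SIFT is used as stated (low = deleterious in SIFT's own convention, yet the
raw score is the published weight); a ``one_minus`` transform is available for
users who prefer the deleteriousness orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .omics import VariantRecord

logger = logging.getLogger(__name__)

SCHEME_NAMES = ("uniform", "sift", "sift_prdsm", "sift_prdsm_filtered", "sift_predcid")

#: variant classes that keep weight 1 under every score-based scheme
_UNIT_WEIGHT_CLASSES = {"stop_gain", "stop_loss", "nonframeshift", "other"}


@dataclass(frozen=True)
class WeightScheme:
    name: str = "uniform"
    prdsm_threshold: float = 0.308
    sift_transform: str = "as_stated"  # or "one_minus"
    missing_score_policy: str = "warn"  # or "error"

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown weight scheme {self.name!r}")
        if self.sift_transform not in ("as_stated", "one_minus"):
            raise ValueError(f"unknown sift transform {self.sift_transform!r}")
        if self.missing_score_policy not in ("warn", "error"):
            raise ValueError(f"unknown missing-score policy {self.missing_score_policy!r}")


def _scored_weight(v: VariantRecord, scheme: WeightScheme, transform: bool = False) -> float:
    if v.score is None:
        if scheme.missing_score_policy == "error":
            raise ValueError(
                f"variant {v.gene}/{v.sample} ({v.variant_class}) lacks the score "
                f"required by scheme {scheme.name!r}"
            )
        logger.warning(
            "missing score for %s variant in %s/%s; defaulting weight to 1",
            v.variant_class, v.gene, v.sample,
        )
        return 1.0
    if transform and scheme.sift_transform == "one_minus":
        return 1.0 - v.score
    return v.score


def assign_variant_weights(
    variants: Sequence[VariantRecord], scheme: WeightScheme
) -> list[VariantRecord]:
    """Return variants with weights set; variants a scheme excludes are dropped."""
    out: list[VariantRecord] = []
    for v in variants:
        if v.variant_class == "synonymous":
            if scheme.name == "sift_prdsm":
                out.append(replace(v, weight=_scored_weight(v, scheme)))
            elif scheme.name == "sift_prdsm_filtered":
                w = _scored_weight(v, scheme)
                if w > scheme.prdsm_threshold:
                    out.append(replace(v, weight=w))
            # uniform / sift / sift_predcid drop synonymous variants
            continue
        if scheme.name == "uniform":
            out.append(replace(v, weight=1.0))
        elif v.variant_class == "missense":
            out.append(replace(v, weight=_scored_weight(v, scheme, transform=True)))
        elif v.variant_class == "frameshift" and scheme.name == "sift_predcid":
            out.append(replace(v, weight=_scored_weight(v, scheme)))
        else:
            # stop_gain, stop_loss, nonframeshift, other, and frameshift
            # under non-PredCID schemes keep weight 1
            out.append(replace(v, weight=1.0))
    return out
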