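"""Voxel-wise and lesion-wise accuracy of a predicted segmentation
against a reference (manual) segmentation.

Voxel agreement is the Dice similarity coefficient (DSC),
2|A∩B| / (|A| + |B|). Detection is counted per lesion (connected
component): a reference lesion is a true positive if it shares at least
``min_match_voxels`` voxels (default 1) with any predicted lesion, a
false negative otherwise; a predicted lesion with no reference overlap
is a false positive. All three rates use the reference lesion count as
denominator, so TPR + FNR = 1 and the FPR may exceed 1 — it is a ratio
of spurious lesions to true lesions, not a classical specificity-style
rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locations import AnatomyMasks, ClassificationParams, classify_lesions
from .mask import BinaryMask3D, LesionLabelMap

__all__ = ["MatchResult", "DetectionRates", "dice", "match_lesions", "detection_rates", "rates_by_location"]

LOCATION_ORDER = ["periventricular", "juxtacortical", "infratentorial", "deep", "other"]


def dice(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """Dice similarity coefficient in [0, 1].

    Two empty masks agree perfectly on absence and score 1.
    """
    a.check_compatible(b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


@dataclass
class MatchResult:
    """Lesion-wise assignment between reference and predicted label maps."""

    tp_ref_ids: list[int]
    fn_ref_ids: list[int]
    fp_pred_ids: list[int]
    n_ref: int
    overlap_table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["ref_id", "pred_id", "n_shared"])
    )

    @property
    def n_tp(self) -> int:
        return len(self.tp_ref_ids)

    @property
    def n_fn(self) -> int:
        return len(self.fn_ref_ids)

    @property
    def n_fp(self) -> int:
        return len(self.fp_pred_ids)


@dataclass(frozen=True)
class DetectionRates:
    tpr: float
    fpr: float
    fnr: float
    n_ref: int


def match_lesions(
    reference: LesionLabelMap,
    predicted: LesionLabelMap,
    min_match_voxels: int = 1,
) -> MatchResult:
    """Match lesions by voxel overlap.

    Many-to-one matches are allowed in both directions: one predicted
    blob spanning two reference lesions detects both, and several
    predicted blobs may hit one reference lesion. TP/FN are counted per
    reference lesion, FP per predicted lesion.
    """
    reference.check_compatible(predicted)
    both = (reference.labels > 0) & (predicted.labels > 0)
    ref_ids = set(reference.lesion_ids)
    pred_ids = set(predicted.lesion_ids)

    if both.any():
        pairs = np.stack([reference.labels[both], predicted.labels[both]], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        table = pd.DataFrame(
            {"ref_id": uniq[:, 0], "pred_id": uniq[:, 1], "n_shared": counts}
        )
    else:
        table = pd.DataFrame(columns=["ref_id", "pred_id", "n_shared"])

    matched = table[table["n_shared"] >= min_match_voxels]
    tp = sorted(ref_ids & set(matched["ref_id"].tolist()))
    fn = sorted(ref_ids - set(tp))
    # FP requires zero shared voxels regardless of min_match_voxels:
    # a predicted lesion touching a reference lesion is not spurious.
    overlapping_pred = set(table["pred_id"].tolist())
    fp = sorted(pred_ids - overlapping_pred)
    return MatchResult(tp, fn, fp, n_ref=len(ref_ids), overlap_table=table)


def detection_rates(m: MatchResult) -> DetectionRates:
    """Lesion-wise TPR/FPR/FNR with the reference count as denominator."""
    if m.n_ref == 0:
        warnings.warn("no reference lesions; detection rates are undefined")
        return DetectionRates(np.nan, np.nan, np.nan, 0)
    return DetectionRates(
        tpr=m.n_tp / m.n_ref,
        fpr=m.n_fp / m.n_ref,
        fnr=m.n_fn / m.n_ref,
        n_ref=m.n_ref,
    )


def rates_by_location(
    m: MatchResult,
    reference: LesionLabelMap,
    predicted: LesionLabelMap,
    anatomy: AnatomyMasks,
    params: ClassificationParams = ClassificationParams(),
) -> pd.DataFrame:
    """Distribution of TP / FN / FP lesions over anatomical locations.

    TP and FN use the reference records' locations (classifying them if
    needed); FP lesions are classified on the fly with the same rules.
    Shares within each nonempty category sum to 1.
    """
    ref = reference
    if any(r.location == "unclassified" for r in ref.records):
        ref = classify_lesions(ref, anatomy, params)
    pred = classify_lesions(predicted, anatomy, params)

    def shares(ids, labelmap):
        locs = [labelmap.record(i).location for i in ids]
        s = pd.Series(locs, dtype=object).value_counts()
        return (s / s.sum()) if len(locs) else s

    out = pd.DataFrame(
        {
            "tp_share": shares(m.tp_ref_ids, ref),
            "fn_share": shares(m.fn_ref_ids, ref),
            "fp_share": shares(m.fp_pred_ids, pred),
        }
    ).reindex([l for l in LOCATION_ORDER])
    out = out.fillna(0.0)
    out.index.name = "location"
    return out
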