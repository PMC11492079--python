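"""Probability-map thresholding and grid-search threshold optimization.

Lesion-probability maps (as produced by LST-style segmenters) are
binarized at a threshold, labelled with 26-connectivity and filtered to
a minimum cluster size. The optimization grid sweeps thresholds from
0.1 to 0.9 in steps of 0.05 (17 candidates) and returns the one
maximizing the mean DSC over the supplied cases — one case reproduces
scanner-specific tuning, several cases a combined (shared) threshold.

Subject selection for tuning follows the median-lesion-volume rule: the
single subject nearest the cohort median, or the k=3 subjects nearest
the median for combined tuning; selected subjects are excluded from
performance evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .accuracy import dice
from .mask import BinaryMask3D, LesionLabelMap, connected_components, filter_min_cluster

__all__ = [
    "ProbabilityMap",
    "ThresholdResult",
    "binarize_probability",
    "optimize_threshold",
    "threshold_grid",
    "select_median_subject",
    "select_k_nearest_median",
]


@dataclass(frozen=True)
class ProbabilityMap:
    """A 3D grid of lesion probabilities in [0, 1] with mm spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"probability map must be 3D, got shape {data.shape}")
        if data.size and (data.min() < -1e-6 or data.max() > 1 + 1e-6):
            raise ValueError(
                f"probabilities outside [0,1]: range [{data.min()}, {data.max()}]"
            )
        object.__setattr__(self, "data", data)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ThresholdResult:
    threshold: float
    grid: list[float]
    dsc_per_threshold: pd.DataFrame  # columns: threshold, mean_dsc
    n_subjects_used: int


def binarize_probability(
    p: ProbabilityMap, threshold: float, min_cluster: int = 5
) -> LesionLabelMap:
    """Threshold (strictly above), label with 26-connectivity, filter clusters."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    mask = BinaryMask3D(p.data > threshold, p.spacing, p.affine)
    return filter_min_cluster(connected_components(mask, 26), min_cluster)


def threshold_grid(lo: float = 0.1, hi: float = 0.9, step: float = 0.05) -> list[float]:
    """Inclusive candidate grid built by integer arithmetic (no FP drift)."""
    lo_i, hi_i, step_i = round(lo * 100), round(hi * 100), round(step * 100)
    if step_i <= 0 or hi_i < lo_i:
        raise ValueError("invalid grid specification")
    return [round(i / 100.0, 2) for i in range(lo_i, hi_i + 1, step_i)]


def optimize_threshold(
    cases: Sequence[tuple[ProbabilityMap, BinaryMask3D]],
    grid_lo: float = 0.1,
    grid_hi: float = 0.9,
    grid_step: float = 0.05,
    min_cluster: int = 5,
    aggregate: str = "mean",
) -> ThresholdResult:
    """Exhaustive grid search for the DSC-optimal binarization threshold.

    ``aggregate`` pools per-case DSC across subjects: "mean" (default,
    unweighted), "median" or "min". Ties are broken toward the lowest
    threshold (the more sensitive setting).
    """
    cases = list(cases)
    if not cases:
        raise ValueError("at least one (probability map, reference) case is required")
    aggfun = {"mean": np.mean, "median": np.median, "min": np.min}.get(aggregate)
    if aggfun is None:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    grid = threshold_grid(grid_lo, grid_hi, grid_step)
    rows = []
    for t in grid:
        dscs = [
            dice(binarize_probability(p, t, min_cluster).as_binary(), ref)
            for p, ref in cases
        ]
        rows.append((t, float(aggfun(dscs))))
    table = pd.DataFrame(rows, columns=["threshold", "mean_dsc"])
    best = int(np.argmax(table["mean_dsc"].to_numpy()))  # argmax → first/lowest on ties
    return ThresholdResult(
        threshold=grid[best],
        grid=grid,
        dsc_per_threshold=table,
        n_subjects_used=len(cases),
    )


def _rank_by_median_distance(volumes: Mapping[str, float]) -> list[str]:
    if not volumes:
        raise ValueError("volumes must be non-empty")
    med = float(np.median(list(volumes.values())))
    return sorted(volumes, key=lambda s: (abs(volumes[s] - med), volumes[s], str(s)))


def select_median_subject(volumes: Mapping[str, float]) -> str:
    """Subject whose reference lesion volume is nearest the sample median.

    For even n the median is the mean of the middle two values. Distance
    ties go to the smaller volume, then the lexicographically smaller id.
    """
    return _rank_by_median_distance(volumes)[0]


def select_k_nearest_median(volumes: Mapping[str, float], k: int = 3) -> list[str]:
    """The k subjects nearest the median volume; also the exclusion list —
    subjects used for tuning are not used for performance evaluation."""
    if k > len(volumes):
        raise ValueError(f"k={k} exceeds number of subjects ({len(volumes)})")
    return _rank_by_median_distance(volumes)[:k]
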