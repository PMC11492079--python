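"""Synthetic phantom study generator.

Generates every input the evaluation pipeline consumes, with known
ground truth, emulating a scan-rescan multi-scanner study design
(default: 30 subjects x 3 scanners x 2 runs):

* a brain-like anatomy phantom (ellipsoidal brain, two interior
  ventricles, an outer cortical shell, an inferior infratentorial blob,
  and cerebral white matter as the remainder);
* spheroid lesions planted so each unambiguously satisfies one of the
  four anatomical typing rules, every lesion at least 5 voxels;
* perturbed "automated" segmentations per scanner and run, with
  per-lesion detection failures, boundary jitter, a multiplicative
  per-scanner volume bias and additive run-level noise, plus Poisson
  false-positive blobs;
* probability maps constructed so the DSC-optimal binarization
  threshold sits at a chosen grid point;
* long-format measurement tables drawn from a known variance-component
  model (subject + scanner + residual).

Seeds are split hierarchically (study -> subject -> scanner -> run) so
adding subjects never reshuffles existing ones. No MR intensities are
simulated — only masks, probability maps and summary measurements.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .locations import AnatomyMasks, ClassificationParams, classify_lesions
from .mask import (
    BinaryMask3D,
    LesionLabelMap,
    LesionRecord,
    connected_components,
    dilate,
)
from .threshold import ProbabilityMap, threshold_grid

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "make_anatomy",
    "plant_lesions",
    "perturb_segmentation",
    "make_probability_map",
    "simulate_measurement_table",
    "DEFAULT_LESION_COUNTS",
]

#: Default planted lesion counts per anatomical class, roughly matching
#: the location mix of an MS cohort (periventricular-dominant).
DEFAULT_LESION_COUNTS = {
    "periventricular": 5,
    "juxtacortical": 3,
    "infratentorial": 2,
    "deep": 6,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling parameters of one subject's phantom."""

    shape: tuple[int, int, int] = (48, 56, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    n_lesions_per_class: dict = field(default_factory=lambda: dict(DEFAULT_LESION_COUNTS))
    lesion_radius_mm: tuple[float, float] = (1.6, 2.6)

    def __post_init__(self):
        if any(s < 32 for s in self.shape):
            raise ValueError(f"shape must be at least 32 voxels per axis, got {self.shape}")
        if any(c < 0 for c in self.n_lesions_per_class.values()):
            raise ValueError("lesion counts must be non-negative")
        lo, hi = self.lesion_radius_mm
        if lo < 1.0:
            # a sphere under ~1 voxel radius cannot guarantee >= 5 voxels
            raise ValueError("lesion_radius_mm lower bound must be >= 1.0 mm")
        if hi < lo:
            raise ValueError("lesion_radius_mm range is inverted")


@dataclass(frozen=True)
class PerturbationSpec:
    """Noise model standing in for scanner / segmentation-tool differences.

    p_detect
        Per-location detection probability (scalar or mapping by class);
        undetected lesions become false negatives.
    fp_rate
        Expected number of spurious blobs per segmentation (Poisson).
    boundary_jitter_mm
        SD of the zero-mean random boundary shift applied per lesion.
    volume_bias
        Multiplicative per-scanner volume factor (mapping scanner -> factor);
        realised as a deterministic boundary shift.
    run_noise_sd
        SD (mm) of the run-level boundary shift shared by all lesions of
        one (scanner, run) segmentation.
    """

    p_detect: float | dict = 0.85
    fp_rate: float = 2.0
    boundary_jitter_mm: float = 0.3
    volume_bias: dict = field(default_factory=lambda: {"GE": 0.9, "Sola": 1.0, "Vida": 1.1})
    run_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        probs = (
            self.p_detect.values() if isinstance(self.p_detect, dict) else [self.p_detect]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("detection probabilities must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_anatomy(spec: PhantomSpec) -> AnatomyMasks:
    """Deterministic brain-like anatomy phantom.

    Brain = ellipsoid filling ~80 % of the grid; cortex = its outer
    shell (~3 mm); ventricles = two interior ellipsoids; infratentorial
    = an inferior blob (brainstem + cerebellum, split along the
    left-right axis); cerebral WM = the remainder.
    """
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    semi = (0.42 * nx, 0.44 * ny, 0.42 * nz)

    brain = _ellipsoid(spec.shape, (cx, cy, cz), semi)
    shell_vox = tuple(max(1, round(3.0 / s)) for s in spec.spacing)
    inner = _ellipsoid(
        spec.shape, (cx, cy, cz), tuple(a - v for a, v in zip(semi, shell_vox))
    )
    cortex = brain & ~inner

    vent_semi = (0.055 * nx, 0.16 * ny, 0.05 * nz)
    off = 0.10 * nx
    ventricles = _ellipsoid(spec.shape, (cx - off, cy, cz + 0.06 * nz), vent_semi) | _ellipsoid(
        spec.shape, (cx + off, cy, cz + 0.06 * nz), vent_semi
    )

    # inferior-posterior blob for brainstem + cerebellum, clipped to the
    # brain interior and kept clear of the cortex shell
    infra = _ellipsoid(
        spec.shape,
        (cx, cy - 0.22 * ny, cz - 0.26 * nz),
        (0.22 * nx, 0.18 * ny, 0.16 * nz),
    )
    infra = infra & inner & ~ventricles
    half = np.zeros(spec.shape, dtype=bool)
    half[: nx // 2] = True
    brainstem = infra & half
    cerebellum = infra & ~half

    cerebral_wm = inner & ~ventricles & ~infra
    if not (ventricles.any() and cortex.any() and brainstem.any() and cerebellum.any()):
        raise ValueError(f"shape {spec.shape} too small to host all structures")

    mk = lambda d: BinaryMask3D(d, spec.spacing)
    return AnatomyMasks(mk(ventricles), mk(cortex), mk(brainstem), mk(cerebellum), mk(cerebral_wm))


def _distance_to(region: np.ndarray, spacing) -> np.ndarray:
    """Physical distance (mm) from each voxel to the nearest region voxel."""
    if not region.any():
        return np.full(region.shape, np.inf)
    return ndimage.distance_transform_edt(~region, sampling=spacing)


def _rasterize_sphere(shape, center, radius_mm, spacing) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, s in zip(grids, center, spacing):
        acc = acc + ((g - c) * s) ** 2
    return acc <= radius_mm**2


def plant_lesions(
    anatomy: AnatomyMasks,
    spec: PhantomSpec,
    params: ClassificationParams = ClassificationParams(),
    max_retries: int = 200,
) -> tuple[LesionLabelMap, pd.DataFrame]:
    """Plant spheroid lesions that unambiguously satisfy their class rule.

    Periventricular lesions touch the dilated ventricle mask;
    juxtacortical lesions overlap cortex by at least 5 voxels while
    avoiding the dilated ventricles; infratentorial lesions sit inside
    brainstem/cerebellum; deep lesions sit inside the eroded cerebral WM
    only. Rejection sampling keeps a 2-voxel gap between lesions so
    connected components never merge. Returns the reference label map
    and a truth table (lesion_id, location, n_voxels, volume_ml).
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = anatomy.shape, anatomy.spacing
    r_lo, r_hi = spec.lesion_radius_mm
    gap_mm = 2.0 * max(spacing)

    dvent = dilate(anatomy.ventricles, params.pv_dilation_mm).data
    infra = anatomy.brainstem.data | anatomy.cerebellum.data
    brain = (
        anatomy.cortex.data | anatomy.cerebral_wm.data | anatomy.ventricles.data | infra
    )

    d_brain_edge = _distance_to(~brain, spacing)      # depth inside the brain
    d_dvent = _distance_to(dvent, spacing)            # distance to dilated ventricles
    d_cortex_in = _distance_to(~anatomy.cortex.data, spacing)  # depth inside cortex
    d_infra_in = _distance_to(~(infra & ~anatomy.cortex.data & ~dvent), spacing)
    from .mask import erode as _erode

    ewm = _erode(anatomy.cerebral_wm, params.wm_erosion_mm).data
    d_deep_in = _distance_to(~(ewm & ~dvent & ~anatomy.cortex.data & ~infra), spacing)

    def eligible_centers(location: str, r: float) -> np.ndarray:
        if location == "periventricular":
            # sphere must reach the dilated ventricles but stay in-brain
            ok = (d_dvent <= r - 0.5 * max(spacing)) & (d_brain_edge > r)
        elif location == "juxtacortical":
            # a 1.5 mm sub-sphere fully inside cortex guarantees >= 5
            # overlapping voxels at ~1 mm spacing
            ok = (d_cortex_in > min(r, 1.5)) & (d_brain_edge > min(r, 2.0)) & (d_dvent > r + 1.0)
        elif location == "infratentorial":
            ok = d_infra_in > r
        elif location == "deep":
            ok = d_deep_in > r
        else:
            raise ValueError(f"unknown location {location!r}")
        return np.argwhere(ok)

    labels = np.zeros(shape, dtype=np.int32)
    blocked = np.zeros(shape, dtype=bool)
    vox_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    records, truth_rows = [], []
    lesion_id = 0

    for location in ("periventricular", "juxtacortical", "infratentorial", "deep"):
        n_wanted = int(spec.n_lesions_per_class.get(location, 0))
        for _ in range(n_wanted):
            placed = False
            for _attempt in range(max_retries):
                r = float(rng.uniform(r_lo, r_hi))
                cand = eligible_centers(location, r)
                if len(cand) == 0:
                    continue
                c = cand[rng.integers(len(cand))]
                sphere = _rasterize_sphere(shape, c, r, spacing)
                if sphere.sum() < 5 or (sphere & blocked).any():
                    continue
                lesion_id += 1
                labels[sphere] = lesion_id
                blocked |= _rasterize_sphere(shape, c, r + gap_mm, spacing)
                n_vox = int(sphere.sum())
                records.append(LesionRecord(lesion_id, n_vox, n_vox * vox_ml, location))
                truth_rows.append(
                    dict(lesion_id=lesion_id, location=location, n_voxels=n_vox,
                         volume_ml=n_vox * vox_ml)
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {location} lesion after {max_retries} tries; "
                    "reduce the requested counts or enlarge the phantom"
                )

    labelmap = LesionLabelMap(labels, spacing, records)
    # construction check: the typing rules must recover the planted classes
    recovered = classify_lesions(labelmap, anatomy, params)
    for rec, tru in zip(recovered.records, records):
        if rec.location != tru.location:
            raise RuntimeError(
                f"planted {tru.location} lesion {tru.lesion_id} classified as "
                f"{rec.location}; phantom geometry violated"
            )
    return labelmap, pd.DataFrame(truth_rows)


def _shift_boundary(lesion: np.ndarray, dr_mm: float, spacing) -> np.ndarray:
    """Dilate (dr > 0) or erode (dr < 0) one lesion by a physical distance."""
    if dr_mm > 0:
        return ndimage.distance_transform_edt(~lesion, sampling=spacing) <= dr_mm
    if dr_mm < 0:
        return ndimage.distance_transform_edt(lesion, sampling=spacing) > -dr_mm
    return lesion.copy()


def _child_rng(seed: int, *keys) -> np.random.Generator:
    # stable across processes (unlike builtin hash of strings)
    stable = tuple(zlib.crc32(repr(k).encode()) for k in keys)
    ss = np.random.SeedSequence(seed, spawn_key=stable)
    return np.random.default_rng(ss)


def perturb_segmentation(
    reference: LesionLabelMap,
    anatomy: AnatomyMasks,
    spec: PerturbationSpec,
    scanner: str,
    run: int,
) -> BinaryMask3D:
    """One simulated automated segmentation for a given (scanner, run).

    Each reference lesion is kept with its detection probability; kept
    lesions get a boundary shift composed of the scanner's volume bias
    (converted to an equivalent-radius change), a shared run-level
    offset, and an independent per-lesion jitter. Poisson false-positive
    blobs are planted inside the brain, off-lesion. Deterministic given
    (seed, scanner, run).
    """
    rng = _child_rng(spec.seed, str(scanner), int(run))
    shape, spacing = reference.shape, reference.spacing
    out = np.zeros(shape, dtype=bool)

    bias = spec.volume_bias.get(scanner, 1.0) if isinstance(spec.volume_bias, dict) else float(spec.volume_bias)
    run_shift = rng.normal(0.0, spec.run_noise_sd) if spec.run_noise_sd > 0 else 0.0

    for rec in reference.records:
        p = (
            spec.p_detect.get(rec.location, 1.0)
            if isinstance(spec.p_detect, dict)
            else spec.p_detect
        )
        detected = rng.random() < p
        if not detected:
            continue
        lesion = reference.lesion_mask(rec.lesion_id)
        # equivalent-sphere radius change realising the volume bias
        r_eff = (3.0 * rec.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        dr = r_eff * (bias ** (1.0 / 3.0) - 1.0) + run_shift
        if spec.boundary_jitter_mm > 0:
            dr += rng.normal(0.0, spec.boundary_jitter_mm)
        out |= _shift_boundary(lesion, dr, spacing)

    n_fp = rng.poisson(spec.fp_rate) if spec.fp_rate > 0 else 0
    if n_fp:
        brain = (
            anatomy.cortex.data
            | anatomy.cerebral_wm.data
            | anatomy.ventricles.data
            | anatomy.brainstem.data
            | anatomy.cerebellum.data
        )
        d_brain_edge = _distance_to(~brain, spacing)
        d_ref = _distance_to(reference.labels > 0, spacing)
        for _ in range(n_fp):
            r = float(rng.uniform(1.2, 2.0))
            ok = (d_brain_edge > r) & (d_ref > r + 2.0 * max(spacing)) & ~out
            cand = np.argwhere(ok)
            if len(cand) == 0:
                warnings.warn("no room for a false-positive blob; skipping")
                continue
            c = cand[rng.integers(len(cand))]
            out |= _rasterize_sphere(shape, c, r, spacing)

    return BinaryMask3D(out, spacing)


def make_probability_map(
    reference: LesionLabelMap,
    true_threshold: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin: float = 0.02,
    anatomy: AnatomyMasks | None = None,
) -> ProbabilityMap:
    """A probability map whose grid-search DSC optimum is a chosen point.

    Reference lesion voxels receive values just above the planted
    threshold; decoy blobs (at least 5 voxels, off-lesion) receive
    values just below it, so any lower grid threshold admits false
    positives and any higher one loses the lesions. Noise is bounded
    uniform and must stay below the separation margin.
    """
    if not 0 < true_threshold < 1:
        raise ValueError("true_threshold must be in (0, 1)")
    if noise_sd >= margin:
        raise ValueError(
            f"noise_sd {noise_sd} too large for the separation margin {margin}"
        )
    rng = np.random.default_rng(seed)
    grid = np.asarray(threshold_grid())
    g_star = float(grid[np.argmin(np.abs(grid - true_threshold))])

    shape, spacing = reference.shape, reference.spacing
    data = np.zeros(shape, dtype=float)
    lesion = reference.labels > 0
    data[lesion] = g_star + 2.0 * margin

    # decoy blobs below the optimum: only useful when a lower grid
    # threshold exists to admit them
    if g_star > grid[0]:
        d_ref = _distance_to(lesion, spacing)
        interior = np.ones(shape, dtype=bool)
        if anatomy is not None:
            interior = (
                anatomy.cortex.data
                | anatomy.cerebral_wm.data
                | anatomy.ventricles.data
                | anatomy.brainstem.data
                | anatomy.cerebellum.data
            )
        for _ in range(3):
            ok = (d_ref > 4.0) & interior
            cand = np.argwhere(ok)
            if len(cand) == 0:
                break
            c = cand[rng.integers(len(cand))]
            blob = _rasterize_sphere(shape, c, 1.6, spacing) & ~lesion
            data[blob] = g_star - margin
            d_ref = np.minimum(d_ref, _distance_to(blob, spacing))

    if noise_sd > 0:
        noise = rng.uniform(-noise_sd, noise_sd, size=shape)
        data = np.where(data > 0, data + noise, data)
    return ProbabilityMap(np.clip(data, 0.0, 1.0), spacing)


def simulate_measurement_table(
    n_subjects: int = 30,
    scanners: int | list = 3,
    runs: int = 2,
    mu: float = 6.0,
    sigma2_subject: float = 4.0,
    sigma2_scanner: float = 0.25,
    sigma2_error: float = 0.04,
    seed: int = 0,
    metric: str = "volume_ml",
    lognormal: bool = False,
) -> pd.DataFrame:
    """Long-format measurement table from a known variance-component model.

    value(s, c, r) = mu + subject(s) + scanner(c) + error(s, c, r), all
    effects Gaussian with the stated variances. Defaults emulate the
    study's cohort scale (30 subjects, mean lesion volume ~6 ml).
    Negative values are truncated at zero with a warning reporting the
    rate. With ``lognormal`` the same effects act multiplicatively on
    the log scale (right-skewed volumes).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if min(sigma2_subject, sigma2_scanner, sigma2_error) < 0:
        raise ValueError("variances must be non-negative")
    scanner_ids = (
        [f"scanner{i+1}" for i in range(scanners)] if isinstance(scanners, int) else list(scanners)
    )
    rng = np.random.default_rng(seed)
    subj_eff = rng.normal(0, np.sqrt(sigma2_subject), n_subjects)
    scan_eff = rng.normal(0, np.sqrt(sigma2_scanner), len(scanner_ids))
    rows = []
    for i in range(n_subjects):
        for j, sc in enumerate(scanner_ids):
            for r in range(1, runs + 1):
                eps = rng.normal(0, np.sqrt(sigma2_error))
                if lognormal:
                    v = float(np.exp(np.log(mu) + subj_eff[i] + scan_eff[j] + eps))
                else:
                    v = mu + subj_eff[i] + scan_eff[j] + eps
                rows.append((f"sub{i+1:03d}", sc, r, metric, v))
    df = pd.DataFrame(rows, columns=["subject", "scanner", "run", "metric", "value"])
    neg = df["value"] < 0
    if neg.any():
        warnings.warn(f"truncated {neg.mean():.2%} of simulated values at zero")
        df.loc[neg, "value"] = 0.0
    return df
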