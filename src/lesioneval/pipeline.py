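"""Study orchestration: accuracy evaluation per subject/scanner/method,
measurement extraction across runs, and the full reliability bundle.

A study is described by a manifest table with one row per
(subject, scanner, run, method) holding file paths to the reference
mask, the predicted mask (or probability map) and the subject's anatomy
masks. Subjects flagged as used for threshold/network optimization are
excluded from evaluation. The pipeline has no hidden state: every
number it reports equals composing the module-level operations by hand
on the same inputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reliability as rel
from .accuracy import detection_rates, dice, match_lesions, rates_by_location
from .locations import AnatomyMasks, ClassificationParams, classify_lesions
from .mask import BinaryMask3D, connected_components, filter_min_cluster, read_mask

log = logging.getLogger("lesioneval")

MANIFEST_COLUMNS = [
    "subject", "scanner", "run", "method",
    "reference_path", "predicted_path", "anatomy_path", "excluded",
]

ANATOMY_STRUCTURES = ["ventricles", "cortex", "brainstem", "cerebellum", "cerebral_wm"]

#: Default anatomical label values in a combined multi-label NIfTI.
DEFAULT_ANATOMY_LABELS = {
    "ventricles": 1, "cortex": 2, "brainstem": 3, "cerebellum": 4, "cerebral_wm": 5,
}


@dataclass
class StudyConfig:
    """All tunables of a study run, with the evaluation defaults baked in."""

    min_cluster_voxels: int = 5
    connectivity: int = 26
    binarize_threshold: float = 0.0
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    min_match_voxels: int = 1
    cluster_size_sweep: tuple = (5, 10, 20)
    anatomy_labels: dict = field(default_factory=lambda: dict(DEFAULT_ANATOMY_LABELS))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cls_params = ClassificationParams(**raw.pop("classification", {}))
        return cls(classification=cls_params, **raw)

    def config_hash(self) -> str:
        payload = {**asdict(self)}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "excluded"]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if "excluded" not in df.columns:
        df["excluded"] = False
    df["excluded"] = df["excluded"].astype(bool)
    return df


def load_anatomy(path, labels: dict | None = None) -> AnatomyMasks:
    """Read anatomy from one multi-label NIfTI using a label->structure map."""
    import nibabel as nib

    labels = labels or DEFAULT_ANATOMY_LABELS
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    data = np.rint(data).astype(int)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    masks = {
        name: BinaryMask3D(data == lab, spacing, img.affine)
        for name, lab in labels.items()
    }
    return AnatomyMasks(**{k: masks[k] for k in ANATOMY_STRUCTURES})


def write_anatomy(anatomy: AnatomyMasks, path, labels: dict | None = None) -> None:
    import nibabel as nib

    labels = labels or DEFAULT_ANATOMY_LABELS
    data = np.zeros(anatomy.shape, dtype=np.int16)
    # later labels overwrite earlier ones where structures touch
    for name in ANATOMY_STRUCTURES:
        data[getattr(anatomy, name).data] = labels[name]
    affine = np.diag([*anatomy.spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(anatomy.spacing)
    nib.save(img, str(path))


def _labelled(mask: BinaryMask3D, config: StudyConfig, min_cluster=None):
    lm = connected_components(mask, config.connectivity)
    return filter_min_cluster(lm, min_cluster or config.min_cluster_voxels)


def evaluate_case(
    reference: BinaryMask3D,
    predicted: BinaryMask3D,
    anatomy: AnatomyMasks,
    config: StudyConfig = StudyConfig(),
) -> dict:
    """Per-case accuracy: DSC, lesion counts, detection rates, locations."""
    ref_lm = classify_lesions(_labelled(reference, config), anatomy, config.classification)
    pred_lm = _labelled(predicted, config)
    m = match_lesions(ref_lm, pred_lm, config.min_match_voxels)
    rates = detection_rates(m)
    loc = rates_by_location(m, ref_lm, pred_lm, anatomy, config.classification)
    return {
        "dsc": dice(ref_lm.as_binary(), pred_lm.as_binary()),
        "n_ref": m.n_ref,
        "n_tp": m.n_tp,
        "n_fp": m.n_fp,
        "n_fn": m.n_fn,
        "tpr": rates.tpr,
        "fpr": rates.fpr,
        "fnr": rates.fnr,
        "location_table": loc,
    }


def run_accuracy_study(manifest: pd.DataFrame, config: StudyConfig = StudyConfig()) -> dict:
    """Accuracy over all run-1 manifest rows of non-excluded subjects.

    Returns per-case rows, a mean +/- sd summary per scanner x method,
    and a list of per-row errors (the run continues past failures).
    """
    rows, errors = [], []
    eval_rows = manifest[(manifest["run"] == 1) & (~manifest["excluded"])]
    for _, row in eval_rows.iterrows():
        try:
            reference = read_mask(row["reference_path"], config.binarize_threshold)
            predicted = read_mask(row["predicted_path"], config.binarize_threshold)
            anatomy = load_anatomy(row["anatomy_path"], config.anatomy_labels)
            res = evaluate_case(reference, predicted, anatomy, config)
            res.pop("location_table")
            rows.append({"subject": row["subject"], "scanner": row["scanner"],
                         "method": row["method"], **res})
        except Exception as exc:  # collected, reported, run continues
            log.error("case failed: %s/%s/%s: %s", row["subject"], row["scanner"], row["method"], exc)
            errors.append({"subject": row["subject"], "scanner": row["scanner"],
                           "method": row["method"], "error": str(exc)})
    per_case = pd.DataFrame(rows)
    summary = (
        per_case.groupby(["scanner", "method"])
        .agg(dsc_mean=("dsc", "mean"), dsc_sd=("dsc", "std"),
             tpr_mean=("tpr", "mean"), fpr_mean=("fpr", "mean"), fnr_mean=("fnr", "mean"),
             n_cases=("dsc", "size"))
        .reset_index()
        if len(per_case)
        else pd.DataFrame()
    )
    return {"per_case": per_case, "summary": summary, "errors": errors,
            "n_evaluated": len(per_case), "n_excluded": int(manifest["excluded"].sum()),
            "config_hash": config.config_hash()}


def measurement_table_from_manifest(
    manifest: pd.DataFrame, config: StudyConfig = StudyConfig(), min_cluster: int | None = None
) -> pd.DataFrame:
    """Extract lesion volume (ml) and count per manifest row from the masks."""
    rows = []
    for _, row in manifest[~manifest["excluded"]].iterrows():
        predicted = read_mask(row["predicted_path"], config.binarize_threshold)
        lm = _labelled(predicted, config, min_cluster)
        for metric, value in (("volume_ml", lm.total_volume_ml), ("count", float(lm.n_lesions))):
            rows.append((row["subject"], row["scanner"], int(row["run"]), metric, value))
    return pd.DataFrame(rows, columns=rel.REQUIRED_COLUMNS)


def run_reliability_study(
    table: pd.DataFrame,
    config: StudyConfig = StudyConfig(),
    manifest: pd.DataFrame | None = None,
) -> dict:
    """The full reliability bundle on a long-format measurement table.

    Per metric: ICC-AA per scanner (runs 1-2), ICC-C per scanner pair
    (run 1), within-/between-scanner SEM & SDC, the omnibus test across
    scanners (RM-ANOVA for volume, Friedman for count) and Bonferroni
    post hocs. When a manifest is supplied, the volume ICCs are repeated
    at the configured minimum-cluster sweep (default 5/10/20 voxels).
    """
    scanners = sorted(table["scanner"].unique())
    out: dict = {"metrics": {}, "config_hash": config.config_hash()}
    for metric, sub in table.groupby("metric"):
        rel.check_balanced(sub)
        run1 = sub[sub["run"] == 1]
        entry: dict = {}
        entry["icc_aa"] = {
            sc: rel.icc_absolute_agreement(sub[sub["scanner"] == sc]) for sc in scanners
        }
        entry["icc_c"] = {
            f"{a}|{b}": rel.icc_consistency(run1[run1["scanner"].isin([a, b])])
            for a, b in itertools.combinations(scanners, 2)
        }
        vc_w = rel.variance_components_within(sub)
        vc_b = rel.variance_components_between(run1)
        entry["variance_components"] = {"within": vc_w, "between": vc_b}
        entry["sem_sdc"] = {"within": rel.sem_sdc(vc_w), "between": rel.sem_sdc(vc_b)}
        if metric == "count":
            # Friedman needs >= 3 conditions; with two scanners the
            # Bonferroni "post hoc" Wilcoxon IS the omnibus comparison
            entry["omnibus"] = rel.friedman(run1) if len(scanners) >= 3 else None
            entry["posthoc"] = rel.posthoc_pairwise(run1, method="wilcoxon")
        else:
            entry["omnibus"] = rel.rm_anova(run1)
            entry["posthoc"] = rel.posthoc_pairwise(run1, method="paired_t")
        out["metrics"][metric] = entry

    if manifest is not None:
        sweep = {}
        for mc in config.cluster_size_sweep:
            t = measurement_table_from_manifest(manifest, config, min_cluster=mc)
            vol = t[t["metric"] == "volume_ml"]
            sweep[int(mc)] = {
                sc: rel.icc_absolute_agreement(vol[vol["scanner"] == sc]) for sc in scanners
            }
        out["cluster_size_sweep"] = sweep
    return out


def report_to_tables(bundle: dict) -> dict[str, pd.DataFrame]:
    """Flatten a reliability bundle into CSV-ready tables."""
    icc_rows, sem_rows = [], []
    for metric, entry in bundle["metrics"].items():
        for sc, r in entry["icc_aa"].items():
            icc_rows.append((metric, "ICC-AA", sc, r.icc, r.ci_low, r.ci_high))
        for pair, r in entry["icc_c"].items():
            icc_rows.append((metric, "ICC-C", pair, r.icc, r.ci_low, r.ci_high))
        for design, rep in entry["sem_sdc"].items():
            sem_rows.append((metric, design, rep.sem_pct, rep.sdc_pct, rep.sem_abs, rep.sdc_abs))
    return {
        "icc": pd.DataFrame(icc_rows, columns=["metric", "form", "condition", "icc", "ci_low", "ci_high"]),
        "sem_sdc": pd.DataFrame(sem_rows, columns=["metric", "design", "sem_pct", "sdc_pct", "sem_abs", "sdc_abs"]),
    }
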