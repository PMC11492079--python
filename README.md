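# lesioneval

Evaluation machinery for automated white-matter lesion segmentation in
multiple sclerosis (MS), built for scan–rescan, multi-scanner studies.
It answers two questions clinicians and method developers keep asking of
tools such as LST-LPA or CNN-based lesion segmenters:

1. **How accurate is a segmentation** against a manual reference — voxel
   overlap, lesion-wise detection, and where in the brain the hits and
   misses fall?
2. **How repeatable and reproducible are its outputs** — if the same
   patient is scanned twice on the same scanner, or once on each of
   three scanners, how much do lesion volume and count move for reasons
   that have nothing to do with disease?

The package is aimed at imaging scientists evaluating segmentation
pipelines; it consumes binary lesion masks and lesion-probability maps
(NIfTI) plus long-format measurement tables (CSV), and ships a synthetic
3D phantom generator so the whole pipeline is testable without any
patient data.

## What it computes

**Lesion extraction.** Connected components under 26-connectivity
(faces, edges, corners), with a minimum cluster size of 5 voxels
(sweepable to 10/20). Each lesion is typed by anatomical rules applied
in fixed precedence: *periventricular* (touches the lateral ventricles
dilated by a 1 mm spherical kernel) → *juxtacortical* (≥ 5 voxels in
cortex) → *infratentorial* (touches brainstem/cerebellum) → *deep*
(inside cerebral WM eroded by 2 mm; residual "other" merged into deep).
All kernels are physical (mm), converted per axis by the voxel spacing.

**Accuracy.** Dice similarity coefficient
`DSC = 2|A∩B| / (|A|+|B|)`; lesion-wise TPR/FNR/FPR with the manual
lesion count as denominator (so TPR + FNR = 1 and FPR may exceed 1), and
the distribution of TP/FN/FP lesions over the four locations.

**Threshold optimization.** For probability-map segmenters: exhaustive
grid search over thresholds 0.10–0.90 in steps of 0.05, maximizing mean
DSC over the tuning subjects; subject selection by the
median-lesion-volume rule (1 subject for scanner-specific tuning, the 3
nearest the median for a combined threshold), with tuning subjects
excluded from evaluation.

**Reliability.** ICC(2,1) absolute agreement for run 1 vs run 2 within a
scanner, ICC(3,1) consistency for run-1 values of each scanner pair,
both with F-based 95 % CIs; moment (EMS) variance components; the
standard error of measurement and smallest detectable change,

    SEM_within  = √σ̂²_error            SEM_between = √(σ̂²_scanner + σ̂²_error)
    SDC         = 1.96 · √2 · SEM

reported in absolute units and as % of the mean measurement; plus
repeated-measures ANOVA (volumes), Friedman (counts) and
Bonferroni-corrected pairwise post hocs.

## Worked example

```python
import numpy as np
from lesioneval.synthetic import (PhantomSpec, PerturbationSpec,
                                  make_anatomy, plant_lesions,
                                  perturb_segmentation,
                                  simulate_measurement_table)
from lesioneval import (connected_components, filter_min_cluster, dice,
                        match_lesions, detection_rates, classify_lesions,
                        location_counts, icc_absolute_agreement,
                        variance_components_within,
                        variance_components_between, sem_sdc)

spec = PhantomSpec(seed=3)
anatomy = make_anatomy(spec)
reference, truth = plant_lesions(anatomy, spec)
print(location_counts(classify_lesions(reference, anatomy)))
# {'periventricular': 5, 'juxtacortical': 3, 'infratentorial': 2, 'deep': 6}

pred = perturb_segmentation(reference, anatomy, PerturbationSpec(seed=3), "GE", 1)
pred_lm = filter_min_cluster(connected_components(pred), 5)
print(round(dice(reference.as_binary(), pred_lm.as_binary()), 3))   # 0.961
r = detection_rates(match_lesions(reference, pred_lm))
print(round(r.tpr, 2), round(r.fpr, 2))                             # 0.88 0.06

df = simulate_measurement_table(n_subjects=30, seed=5)
print(round(icc_absolute_agreement(df[df.scanner == "scanner1"]).icc, 3))  # 0.99
sem_w = sem_sdc(variance_components_within(df))
sem_b = sem_sdc(variance_components_between(df[df.run == 1]))
print(round(sem_w.sem_pct, 2), round(sem_b.sem_pct, 2))             # 3.69 7.88
```

The phantom's 16 planted lesions are recovered in their planted
anatomical classes; the perturbed "GE run 1" segmentation overlaps the
reference at DSC 0.961, detects 14 of the 16 reference lesions
(TPR 0.88) with 0.06 spurious lesions per true lesion; and on the
simulated 30-subject
cohort the within-scanner agreement is near-perfect (ICC 0.99) while the
between-scanner SEM (7.88 % of the mean volume) is roughly double the
within-scanner SEM (3.69 %) — the scanner, not the rescan, dominates the
measurement noise.

A CLI mirrors the library: `lesioneval simulate-study`,
`optimize-threshold`, `evaluate-accuracy`, `evaluate-reliability`,
`report`.

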