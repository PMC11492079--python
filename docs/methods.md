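# Methods

## Scope and data model

The package evaluates automated MS lesion segmentations; it does not
segment. Everything upstream of a binary mask or probability map —
acquisition, bias-field correction, registration, brain extraction,
anatomical segmentation, and the segmentation algorithms themselves —
is out of scope: masks arrive already resampled to a common voxel grid,
and anatomy masks (lateral ventricles, cortex, brainstem, cerebellum,
cerebral white matter) are inputs.

All spatial computation happens on the voxel grid in index space, with
physical voxel spacing (mm) used only to convert kernel radii and
volumes. The NIfTI affine is carried through I/O untouched and never
enters a metric; masks combined in any operation must share shape and
spacing, which is checked and raised on mismatch.

## Lesion extraction and typing

Lesions are connected components under 26-connectivity, filtered to a
minimum cluster size of 5 voxels (inclusive boundary; 10 and 20 used
for sensitivity sweeps). Component labelling is made deterministic by
relabelling in lexicographic order of each component's minimum (i,j,k)
voxel, so repeated runs are bit-identical.

Binarization of stored volumes and probability maps uses strictly
`value > threshold`. The convention matters at the default 0.5
threshold, where a voxel at exactly 0.5 must land on one side
reproducibly; strict inequality excludes it.

Spherical structuring elements are specified by an inclusive physical
radius: offset (a,b,c) belongs to the kernel iff
√((a·dx)² + (b·dy)² + (c·dz)²) ≤ r. On a 1×1×1.2 mm grid a "1 mm"
kernel therefore has 5 elements (centre + 4 in-plane face neighbours),
which is the intended behaviour of a millimetre-specified kernel on an
anisotropic grid.

Typing applies four rules in fixed precedence — periventricular
(≥ 1 voxel overlap with ventricles dilated 1 mm), juxtacortical
(≥ 5 voxels in cortex), infratentorial (≥ 1 voxel in
brainstem ∪ cerebellum), deep (≥ 1 voxel in cerebral WM eroded 2 mm) —
with the residual "other" class merged into deep by default (a flag
keeps it separate). The deep-WM rule uses the *cerebral* WM mask:
cerebellar WM would already be captured by the infratentorial rule.
Overlap thresholds for rules 1, 3 and 4 are 1 voxel; only the
juxtacortical rule carries a 5-voxel requirement.

## Accuracy metrics

DSC is 2|A∩B|/(|A|+|B|), defined as 1 when both masks are empty
(perfect agreement on absence). Lesion-wise matching uses a ≥ 1-voxel
overlap criterion (configurable via `min_match_voxels`); many-to-one
matches are allowed in both directions, TP/FN counted per reference
lesion and FP per predicted lesion. All three rates are normalized by
the reference lesion count, so TPR + FNR = 1 and FPR is a ratio of
spurious to true lesions that can exceed 1 — deliberately not a
classical false-positive rate, because there is no meaningful negative
count. With an empty reference the rates are undefined and returned as
missing with a warning. Location breakdowns classify predicted FP
lesions on the fly with the same typing rules.

## Threshold optimization

The candidate grid 0.10–0.90 (step 0.05, both endpoints, 17 values) is
built by integer arithmetic and rounded to two decimals to avoid
floating-point drift. The selected threshold maximizes the unweighted
mean DSC over the supplied cases (median and min aggregation available);
ties break toward the lowest threshold, the more sensitive setting — a
deterministic rule is required and the lower threshold is the
clinically safer default for lesion detection. Cluster filtering is
applied after thresholding, before DSC.

Tuning-subject selection: the subject nearest the cohort median lesion
volume (even n: mean of the middle two); distance ties go to the
smaller volume, then the lexicographically smaller id. The k-nearest
variant (k = 3) doubles as the exclusion list — tuning subjects are
dropped from evaluation.

## Reliability statistics

Within-scanner agreement uses ICC(2,1): two-way random effects, single
measurement, absolute agreement,
(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)), which penalizes a
systematic run-1/run-2 offset. Between-scanner consistency uses
ICC(3,1), (MSR − MSE) / (MSR + (k−1)MSE), invariant to per-scanner
offsets, computed on run-1 values of each scanner pair. Confidence
intervals are the standard F-based forms (Satterthwaite degrees of
freedom for the agreement form). Single-measurement versions are used
throughout because each value is one scan, not an average. Designs with
no between-subject variance make the ICC undefined; it is returned
missing with a warning rather than forced to a number.

Variance components are method-of-moments (EMS) estimates, truncated at
zero, chosen over REML for exact testability against hand-computed
ANOVA sums. Within-scanner, the scan–rescan residual is estimated from
run differences pooled over subject × scanner cells:
σ̂²_error = mean(d²)/2. Between-scanner, a two-way subject × scanner
ANOVA on run-1 values gives σ̂²_scanner = (MSC − MSE)/n,
σ̂²_subject = (MSR − MSE)/k, σ̂²_error = MSE.

SEM_within = √σ̂²_error; SEM_between = √(σ̂²_scanner + σ̂²_error) — the
between-scanner SEM must carry the residual noise floor in addition to
the scanner effect (component selection is exposed, so scanner-only is
one argument away). SDC = 1.96·√2·SEM; both SDCs are derived from their
SEM so the ratio is bit-exact. Percentages are of the grand mean of the
values entering the respective decomposition, per metric.

The omnibus test across scanners is a one-way repeated-measures ANOVA
for volumes (F = MS_scanner/MS_residual, p deliberately uncorrected for
sphericity and flagged as such) and a tie-corrected Friedman test for
counts (≥ 3 conditions; two-scanner studies fall back to the pairwise
Wilcoxon, which is then the comparison itself). Post hoc pairwise
paired t or Wilcoxon tests are Bonferroni-corrected by multiplication,
capped at 1; zero-variance pairs return missing with a warning.

## Synthetic phantom study

The generator emulates the study design the pipeline targets: 30
subjects scanned twice on each of three scanners. Defaults, chosen once
to be realistic for an MS cohort:

| parameter | default | rationale |
|---|---|---|
| grid | 48×56×48 voxels, 1 mm isotropic (0.98×0.98×1.2 mm variant) | smallest grid hosting all structures; keeps a full study cheap |
| lesions per class | PV 5, JC 3, INF 2, deep 6 | periventricular/deep-dominant mix typical of MS |
| lesion radius | 1.6–2.6 mm | every rasterized lesion ≥ 5 voxels with margin |
| p_detect | 0.85 | lesion-wise TPR in the range reported for tuned tools |
| fp_rate | Poisson(2) | a few spurious blobs per scan |
| boundary jitter | 0.3 mm SD | sub-voxel contour disagreement |
| volume bias | GE 0.9, Sola 1.0, Vida 1.1 | ±10 % multiplicative scanner effect |
| run noise | 0.1 mm SD | repositioning-scale rescan noise |
| measurement model | μ=6 ml, σ²_subject=4, σ²_scanner=0.25, σ²_error=0.04 | cohort mean volume ≈ 6 ml, subject spread dominant, scanner ≫ rescan noise |

Anatomy is a brain ellipsoid with a ~3 mm cortical shell, two interior
ventricular ellipsoids, an inferior infratentorial blob split into
brainstem and cerebellum, and cerebral WM as the remainder. Lesions are
spheres placed by rejection sampling on eligibility maps built from
exact Euclidean distance transforms, so each lesion satisfies its class
rule unambiguously (PV lesions reach the dilated ventricles, JC lesions
bury a 1.5 mm sub-sphere in cortex, INF/deep lesions sit wholly inside
their region), with a 2-voxel gap so components never merge; planting
verifies itself by running the classifier and fails loudly on
violation.

Perturbed segmentations drop each lesion with probability 1 − p_detect,
shift kept boundaries by the scanner bias expressed as an
equivalent-sphere radius change plus run-level and per-lesion Gaussian
jitters (via distance transforms, so shifts are metric), and add
Poisson false-positive blobs inside the brain, off-lesion. Probability
maps place lesion voxels just above the target grid point and decoy
blobs just below it, so the grid-search optimum is the planted point by
construction; bounded uniform noise must stay below the separation
margin or construction refuses. Seeds split hierarchically
(study → subject → scanner → run, via CRC-stable spawn keys), so adding
subjects never reshuffles existing ones.

What the phantom does *not* emulate: MR intensities, partial volume,
registration error, spatially correlated segmentation failure modes,
and the right-skew of real lesion-volume distributions (a log-normal
option exists; the Gaussian default truncates negatives at zero and
warns with the rate). Passing tests therefore demonstrate the
*evaluation machinery* is correct — not that any segmentation tool
would achieve these numbers on patients.

## Numerical choices and degenerate inputs

- Component labels, grid thresholds and subject selection all carry
  deterministic tie-breaks (documented above) so outputs are
  bit-reproducible; the pipeline logs a config hash.
- Negative moment estimates truncate at 0; ICC intervals collapse to
  [1, 1] when the residual mean square is 0.
- Unbalanced designs are rejected with the list of missing cells rather
  than silently dropped.
- Empty masks: 0 components; empty-vs-empty DSC is 1; detection rates
  on an empty reference are missing-with-warning.

## Known limitations

- Sphericity corrections (Mauchly, Greenhouse–Geisser) are not
  computed; RM-ANOVA p-values are labelled accordingly.
- REML variance components and bootstrap CIs for SEM/SDC are not
  implemented; moment estimates are noisy for the scanner component
  when only three scanners exist (its sampling distribution is
  ~χ²₂-scaled, so single-study scanner-variance estimates can collapse
  to zero even when the true component is positive).
- Masks are compared strictly in voxel space; cross-space evaluation
  requires prior resampling by the caller.

## Simulation sizes used by the test suite and acceptance script

Oracle-equivalence checks run 100 randomized small instances per
operation (7³ grids, 4–10 subjects); variance-component recovery uses
1000 replicates of the 30-subject cohort; phantom-based checks use the
default 48×56×48 grid with 16 lesions, 50 seeds for the classification
construction oracle and 17 planted grid points for threshold recovery.
These sizes give Monte-Carlo error comfortably below the asserted
tolerances while keeping a full run in tens of seconds.
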