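# Methods

## Scope and model

The package quantifies whole-body tumour burden from ⁶⁸Ga-PSMA PET/CT SUV
volumes and asks two questions: how did the burden change under therapy
(response classification), and do two measurement pipelines agree well
enough to be interchanged (agreement statistics). The computational content
is threshold segmentation, additive aggregation, interval classification
and paired-difference statistics; scanner physics (attenuation, scatter,
reconstruction) and image registration between timepoints are out of scope,
as is automatic detection of new lesions or of reference-organ position —
both are expert inputs in clinical practice and are expert inputs here.

## Volumes and geometry

A volume is a 3-D array of SUV values with per-axis voxel spacing in mm,
axis-aligned; world orientation is not modelled. The centre of voxel
(i, j, k) sits at ((i+0.5)·dx, (j+0.5)·dy, (k+0.5)·dz) from the volume
corner, and *every* region-membership decision — reference sphere,
reference cylinder, phantom lesion — is the voxel-centre-inside-shape rule
on that grid. One rule everywhere makes phantom ground truth and
segmentation output commensurable: a noise-free phantom lesion is recovered
at exactly its generated voxel count.

SUV conversion, when starting from activity concentration, uses the
body-weight convention: SUVbw = concentration [Bq/mL] × weight [g] /
injected dose [Bq] decay-corrected to acquisition start with the ⁶⁸Ga
half-life of 67.71 min. SUVbw is the community default; no uptake-time
harmonization between timepoints is attempted, matching how such cohorts
are read clinically.

## Segmentation

* Liver reference: 3 cm **diameter** sphere (the conventional PERCIST-style
  liver ROI size; a 3 cm radius would approach the whole organ), threshold
  1.5·mean + 2·SD. Aortic blood pool (used when liver metastases preclude a
  clean liver ROI): 1 cm diameter, 2 cm z-extent cylinder, threshold
  2·mean + 2·SD. SD is the sample SD (ddof = 1), consistent with the
  agreement module. ROIs smaller than 10 voxels are refused — their SD is
  too unstable to set a threshold.
* Threshold comparison is inclusive (SUV ≥ threshold): boundary voxels
  count as lesion. Components are 26-connected, the common choice for PET
  hot-spot segmentation; minimum component size defaults to 1 voxel and is
  configurable because real analyses drop single-voxel noise specks.
* Lesions are ordered by descending SUVmax, ties by ascending centroid
  (lexicographic), so outputs are deterministic. The hottest lesion is the
  SUVmax maximiser with ties to the lowest id.
* Physiological uptake (salivary glands, coeliac ganglia, renal
  collecting system …) is handled by a user-supplied boolean exclusion
  mask, the algorithmic counterpart of the manual lesion veto performed by
  readers.

## Biomarkers and response

PSMA-TV sums lesion volumes; TL-PSMA sums volume × SUVmean per lesion
(dimensionally cm³·SUV, conventionally reported in cm³ since SUV is
dimensionless). Sums use compensated summation so aggregation is
order-independent to float precision.

Change is stored as the ratio follow-up/baseline × 100 %; signed change for
reporting is ratio − 100. The ratio is undefined (NA downstream) when the
baseline is zero or missing. Cut-points: BR 50/125, the imaging schemes
70/130, with ≤/≥ on the PR/PD side and strict inequalities for SD, so each
defined ratio maps to exactly one category; ratios are compared at full
float precision.

Decisions that were genuinely open:

* **PSA-negative disease is NA, not CR.** The CR row of the BR scheme
  ("PSA negative") is read as PSA falling to undetectable *under therapy*;
  patients whose disease never expressed PSA cannot be assessed
  biochemically at all.
* **New-lesion status is an input flag.** PERCIST's new-lesion rule
  overrides the SUVmax ratio (PD even when uptake fell, and even when the
  baseline ratio is unavailable).
* **NA patients are excluded pairwise, not listwise**, from cross-scheme
  agreement counts; a disagreement is "relevant" when exactly one scheme of
  the pair calls PD, the distinction that changes clinical management.

## Agreement statistics

Relative difference per pair is (A − B)/((A + B)/2) × 100 — the symmetric
Bland–Altman ratio variant; percent-of-A is available as a sensitivity
option. Bias is the mean relative difference, limits of agreement
bias ± 1.96·SD, repeatability coefficient RC = 1.96 × SD, all with sample
SD. Outliers are pairs outside the limits computed from *all* pairs; no
iterative exclusion, so one outlier in ~21 pairs is the expected 95 %
behaviour, not a flaw.

Wilcoxon signed-rank drops zero differences, uses midranks for ties, and
the exact null for ≤ 25 tie-free pairs (normal approximation with
continuity correction otherwise). Spearman and Shapiro–Wilk delegate to
scipy; a constant vector makes rank correlation undefined and is an error.

The sample-size computation treats the between-method comparison as a
paired t test: power(n) = P(|T′| > t_{1−α/2, n−1}) with noncentrality
d_z·√n, scanned upward from n = 2. At d_z = 0.7, α = 0.05, power 0.80 this
gives n = 19 (and 34 at d_z = 0.5). A Wilcoxon-based variant (inflating n
by the asymptotic relative efficiency) was considered and not made the
default; the t-test reading is the standard G*Power-style computation for
a paired design.

## Synthetic data

`generate_phantom` emulates the relevant structure of a PSMA PET scan:
low uniform background (SUV 0.5), a liver-like sphere with Gaussian voxel
statistics (defaults mean 5, SD 0.5 — typical hepatic PSMA uptake), and
lesions painted at peak SUV with analytic shapes. Default grid 64³ at 4 mm
isotropic voxels keeps whole-pipeline tests fast while leaving reference
ROIs well-sampled (the 3 cm sphere covers ≈ 220 voxels). PSF blur is a
Gaussian in mm applied before i.i.d. Gaussian voxel noise — the simplest
degradation that stresses threshold segmentation; values are clipped at 0
to respect the SUV domain. The ground truth always reports the
pre-degradation analytic voxel count, which is the quantity a perfect
segmentation should recover. An axis-aligned "box" shape exists purely so
exact-volume tests are integer arithmetic.

`generate_paired_measurements` draws true burdens log-normal (defaults:
median 40 cm³, log-SD 1.2, matching the right-skewed, orders-of-magnitude
spread of metastatic burden) and derives method B from method A so the
pair's relative difference is *exactly* the sampled Gaussian deviate
(B = A·(200 − d)/(200 + d)); bias and SD are therefore recovered by the
agreement module up to sampling error, which the tests check at n = 10⁴
within three standard errors. The default relative-difference SD of 20 %
produces RC ≈ 39 %, the order observed between real software pairs.

What the phantoms do **not** model: anatomy beyond one liver sphere,
partial-volume spill-in/out beyond Gaussian blur, reconstruction artefacts,
correlated noise, respiratory motion. Passing tests therefore demonstrate
correctness of the *computational* chain, not clinical segmentation
accuracy on patient scans.

## Validation data

`psmaquant.datasets` embeds the per-patient response categories of a
published 21-patient CRPC chemotherapy cohort assessed with two software
tools, plus the raw percentage changes of the six patients whose
biochemical and volume-based classifications disagreed relevantly.
Re-deriving those six patients' categories from their printed changes, and
re-counting the cohort's category tallies and disagreement counts, are
regression tests that the classification and cross-tabulation logic matches
real clinical usage. Overall-survival columns are carried as pass-through
metadata only.

## Problem sizes and determinism

Tests run phantoms at 24³–48³ voxels and Monte-Carlo checks at 10⁴ pairs;
property tests (hypothesis) are derandomised. All randomness flows through
`numpy.random.default_rng` seeded per spec, so identical specs give
bit-identical volumes and tables.

## Known limitations

* Reference-ROI statistics assume the ROI is placed in homogeneous normal
  tissue; no guard exists against a user placing it over a lesion.
* Lesions are not tracked across timepoints; biomarker change is
  whole-body, so a vanished lesion plus an equal-volume new one cancels.
* The repeatability coefficient presumes approximately Gaussian relative
  differences; with heavy outlier contamination it overstates the 95 %
  band of the clean component.
* TL-PSMA inherits threshold sensitivity twice (through both volume and
  SUVmean), so it is more threshold-dependent than PSMA-TV.
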