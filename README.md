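# psmaquant

Whole-body tumour-burden quantification for PSMA PET/CT, for nuclear-medicine
researchers who need the full chain from SUV volume to therapy-response call
— and who need to know whether two software tools measuring the same scans
would have called it the same way.

## What it computes

**Segmentation.** The lesion threshold comes from a normal-tissue reference
region: a 3 cm sphere in healthy liver (threshold = 1.5·mean + 2·SD of its
voxels) or, when liver metastases preclude that, a 1 cm × 2 cm(z) cylinder in
the descending thoracic aorta (threshold = 2·mean + 2·SD). All voxels with
SUV ≥ threshold, outside an optional physiological-uptake exclusion mask,
are grouped into 26-connected components; each component is a lesion with
volume, SUVmean and SUVmax.

**Biomarkers.** Per patient and timepoint,

    PSMA-TV = Σ_lesions V_i        [cm³]
    TL-PSMA = Σ_lesions V_i · SUVmean_i

and the hottest lesion's SUVmax. Change between scans is expressed as
ratio = X_follow-up / X_baseline × 100 %.

**Response classification** under four schemes — biochemical response from
serum PSA (PR ≤ 50 %, PD ≥ 125 %), adapted PERCIST from the hottest lesion's
SUVmax (PR ≤ 70 %, PD ≥ 130 % or any new lesion), and ΔPSMA-TV / ΔTL-PSMA
(PR ≤ 70 %, PD ≥ 130 %) — with cross-scheme disagreement counts
("relevant" = PD versus non-PD).

**Agreement statistics.** Bland–Altman analysis on per-pair *relative*
differences d = (A − B)/((A + B)/2) × 100, limits of agreement
bias ± 1.96·SD, repeatability coefficient RC = 1.96 × SD(d), Spearman/
Wilcoxon/Shapiro–Wilk wrappers, and the sample size of a two-sided paired
t test via the noncentral t distribution.

**Synthetic phantoms.** A generator for SUV volumes with a liver-like
reference sphere and lesions of exactly known voxel volume (plus Gaussian
PSF blur and noise), and a paired-measurement generator with a prescribed
relative-difference distribution — so every stage is testable with known
ground truth.

## Worked example

A one-command synthetic study — 21 patients measured by two "methods" whose
relative differences are Gaussian with SD 20 % — followed by the power
analysis:

```
$ psmaquant demo --out-dir demo --seed 1
demo study of 21 patients -> demo (bias 0.57%, RC 40.18%)
$ psmaquant power --dz 0.7 --alpha 0.05 --power 0.8
n = 19
```

The demo writes `pairs.csv` and `agreement.json`:

```json
{
  "n_pairs": 21,
  "bias_pct": 0.5687370570356243,
  "rc_pct": 40.17540316315781,
  "loa_low_pct": -39.606666106122184,
  "loa_high_pct": 40.74414022019344,
  "n_outliers": 1
}
```

Bias ≈ 0.6 % means neither method systematically over-reads the other; the
repeatability coefficient ≈ 40 % says 95 % of between-method differences are
expected within ±40 % of the pair mean (the generator's truth is
1.96 × 20 % = 39.2 %); one of 21 pairs falls outside the limits of
agreement, as expected at the 95 % level. `n = 19` is the smallest cohort
at which a paired t test with effect size d_z = 0.7 reaches 80 % power at
α = 0.05.

The imaging path is available as subcommands (`phantom`, `segment`,
`biomarkers`, `classify`, `agree`) or through the library:

```python
import psmaquant as pq

vol, truth = pq.generate_phantom(pq.PhantomSpec(
    liver_center_mm=(128, 128, 128),
    lesions=(pq.LesionSpec.sphere((60, 60, 200), radius_mm=12, peak_suv=15),),
))
ref = pq.liver_reference(vol, (128, 128, 128))       # threshold 1.5·mean + 2·SD
lesions = pq.segment_lesions(vol, ref.threshold_suv)
study = pq.aggregate(lesions, patient_id="p1", timepoint="baseline")
```

`psmaquant.datasets` ships the response-category table of a published
21-patient CRPC chemotherapy cohort assessed with two software tools, used
throughout the tests as a real-data check of the classification and
agreement logic.

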