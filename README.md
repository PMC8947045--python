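# vncamarrow

Volumetric analysis of vertebral bone marrow in dual-energy CT **virtual
non-calcium (VNCa)** images.

VNCa reconstructions suppress the calcium-specific portion of X-ray
attenuation, virtually removing trabecular bone and unmasking the marrow
signal that conventional CT hides.  Because marrow-replacing disease
(metastasis, myeloma) *raises* marrow VNCa attenuation, an exam can be
screened by comparing its marrow attenuation distribution against an age-
and sex-matched reference range.  `vncamarrow` provides the full automated
pipeline for building and applying such references, for radiologists and
imaging scientists working with spectral CT:

- **Marrow VOI extraction** from a vertebra label map: prune excess
  vertebrae above 17 (5 lumbar + 12 thoracic, counted from the bottom),
  erode all margins by 3 mm in physical millimetres to exclude cortical
  bone, transfer the mask to each VNCa channel.
- **Attenuation histogramming** at a fixed 5 HU bin width with a
  −1000 HU lower cutoff (sub-cutoff values arise from calcium suppression
  of dense calcifications, not marrow), unit-mass normalization, and the
  histogram-intersection similarity
  `overlap(h1, h2) = Σᵢ min(h1ᵢ, h2ᵢ) = 1 − ½‖h1 − h2‖₁`.
- **Reference tables** of marrow attenuation (median, quartiles, 95th
  percentile, mode bin) stratified by sex × age band (21–40, 41–60,
  61–80, >80 years) × calcium-suppression level (low/medium/maximum,
  vendor indices 76/50/25), including a packaged 24-cell table from a
  500-exam cohort with healthy trabecular bone; intra-individual
  consistency grading (overlap > 0.80 "good", > 0.90 "excellent") and
  classification of new exams against the matched 95th percentile.
- **A synthetic phantom cohort generator**: stacked vertebral bodies
  with cortical shells whose marrow attenuation is drawn from a
  two-component normal mixture calibrated to any reference cell's
  quantiles, with calcified inclusions, lesion shifts and repeat exams —
  so the whole pipeline is testable without clinical data.

## Worked example

Calibrate the packaged (female, 41–60 years, maximum suppression)
reference cell, simulate one 17-vertebra exam, run the VOI pipeline on
it, and classify the result:

```python
from vncamarrow import (compute_histogram, extract_marrow_voi,
                        histogram_statistics, transfer_mask, classify_exam,
                        packaged_reference, ExamRecord)
from vncamarrow.phantom import PhantomSpec, calibrate_distribution, generate_phantom

table = packaged_reference()
entry = table.get("female", "41-60", "maximum")       # median -382.5, P95 -212.5
params = calibrate_distribution((entry.q1, entry.median, entry.q3, entry.p95))

spec = PhantomSpec(n_vertebrae=17, marrow={"maximum": params}, seed=5)
label_map, volumes, truth = generate_phantom(spec)

voi = extract_marrow_voi(label_map, margin=3.0)       # prune to 17, erode 3 mm
values, vol_mm3 = transfer_mask(voi, volumes["maximum"])
hist = compute_histogram(values, volume_mm3=vol_mm3)
print(len(voi.labels_retained), voi.voxel_count)      # 17 137088
print(histogram_statistics(hist))
# HistogramSummary(median=-382.5, q1=-467.5, q3=-317.5, p95=-212.5, mode=-357.5)

exam = ExamRecord("P001", "female", 52, "2021-03-01", {"maximum": hist}, 17)
print(classify_exam(exam, table, "maximum"))
# ClassificationResult(category='within-reference', margin_hu=-170.0,
#                      statistic='median', statistic_hu=-382.5, reference_p95=-212.5)
```

The simulated exam's binned quantiles land exactly on the calibration
targets (the VOI holds ~1.4 × 10⁵ marrow voxels, so sampling error is far
below the 5 HU bin), and its median sits 170 HU below the matched
reference P95 — a physiological exam.  Raising the marrow attenuation
above −212.5 HU (e.g. with a lesion shift) flips the category to
`above-95th-percentile`.

The same workflow is available from the shell:

```bash
vncamarrow simulate --out cohort/ --seed 1          # phantom cohort + manifest
vncamarrow run --manifest cohort/manifest.csv --out results/
vncamarrow overlap results/<exam1>/hist_maximum.csv results/<exam2>/hist_maximum.csv
vncamarrow compare --exam results/<exam>/exam.json --level maximum
```

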