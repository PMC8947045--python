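# Methods

## Problem and pipeline

Virtual non-calcium (VNCa) reconstructions from dual-energy CT suppress
the calcium-specific portion of X-ray attenuation, unmasking the bone
marrow inside trabecular bone.  Marrow-replacing disease (e.g. metastasis,
myeloma) raises marrow VNCa attenuation, so an exam can be screened by
comparing its marrow attenuation distribution against an age- and
sex-matched reference range.  `vncamarrow` implements the volumetric,
fully automated evaluation behind such a reference:

1. **VOI extraction** (`voi`).  Input is an integer vertebra label map
   co-registered with the VNCa volumes (segmentation itself is out of
   scope; any segmenter that produces one label per vertebra works).
   Excess vertebrae above 17 — 5 lumbar + 12 thoracic — are discarded,
   counted from the bottom, to avoid inconsistent inclusion of a partially
   imaged cervical spine.  All margins are then narrowed by 3 mm to
   exclude the bordering cortical bone, and the resulting marrow mask is
   transferred to each VNCa channel.
2. **Histogramming** (`histogram`).  Marrow attenuation is binned at 5 HU
   on a grid anchored at multiples of 5 (bin centers end in .5).  Values
   below −1000 HU are excluded from the mass (they arise from calcium
   suppression of densely calcified structures, not marrow) but their
   count is reported.  Histograms are normalized to unit mass; similarity
   between two exams is the histogram intersection Σᵢ min(h1ᵢ, h2ᵢ),
   which equals 1 − ½‖h1 − h2‖₁.
3. **Reference statistics** (`reference`).  Exams are stratified by sex ×
   age band (21–40, 41–60, 61–80, >80 years; age at exam, truncated; 80
   belongs to 61–80) × calcium-suppression level (low/medium/maximum,
   vendor indices 76/50/25).  Per stratum, exam histograms are averaged
   with equal weight and summarized by bin-center quantiles (median, Q1,
   Q3, P95) and the mode bin.  A packaged 24-cell reference table from a
   500-exam cohort of individuals with healthy trabecular bone ships as a
   versioned CSV.
4. **Phantom simulation** (`phantom`).  A synthetic cohort generator
   stands in for clinical data; see below.
5. **Batch orchestration** (`pipeline`, `cli`).  Manifest-driven batch
   processing with per-exam skip-and-log failure handling, cohort
   summaries, and lossless CSV/JSON reports.

## Key numerical choices

**Erosion in physical millimetres.**  The default erosion keeps exactly
the voxels whose Euclidean distance to the nearest background voxel —
measured in mm with the anisotropic voxel spacing — strictly exceeds the
margin, computed with a Euclidean distance transform.  On anisotropic
grids this differs from iterating a voxel structuring element, where
"3 mm" through-plane can mean 1.5 slices rounded either way; the physical
definition is the default because the margin is a physical statement,
and a `voxel` structuring-element mode (per-axis radius
`round(margin/spacing)`) is available for strict emulation of grid-based
erosion.  The outside of the grid counts as background, so a mask touching
the grid border still loses its margin there.  Exact distance ties at the
margin are excluded (strict inequality), enforced with a 10⁻⁶ mm guard so
the decision cannot flip on floating-point rounding inside the transform.
Per-vertebra erosion before the union is the default: each vertebra loses
its own cortical border even where two bodies abut.

**Ordering "from the bottom".**  Vertebra order is the per-label centroid
coordinate along the inferior→superior axis declared by the image header
(never guessed), which is robust to tilted spines.  Labels need not be
anatomically named; only count and vertical order matter.  Exams with
fewer than 17 vertebrae are processed as-is.

**Quantiles without interpolation.**  Quantile q is reported as the
center of the first bin whose cumulative mass reaches ≥ q, and the mode
is the maximal bin (ties toward lower HU).  This keeps every reported
statistic on the 5 HU bin-center grid of the reference table.  Against
direct sorted-sample quantiles the discrepancy is bounded by one bin.

**Normalization.**  "Standard volume" normalization is implemented as
unit total mass; any constant standard volume is a scalar relabeling of
the ordinate that cancels in overlap and quantiles, so the physical VOI
volume is kept as metadata only.  Overlap refuses un-normalized input
rather than silently renormalizing.

**Strict boundaries.**  Consistency grades use strict inequalities
(overlap > 0.90 "excellent", > 0.80 "good"); classification against the
reference P95 is strict ("above" only when the exam statistic exceeds
P95).  The exam-side statistic defaults to the histogram median; the
exam's own P95 is exposed as an alternative.  "Below reference support"
(far below the reference body, beyond Q1 − 1.5·IQR) is flagged separately
— attenuation that low is physiologically implausible marrow and usually
indicates a processing or calibration problem.

## The phantom generator

The generator emulates the imaging substrate the pipeline consumes, not
anatomy: axis-aligned vertebral bodies (default 30 × 30 × 20 mm) stacked
along the inferior→superior axis with uniform gaps, each with a 1 mm
cortical shell around a marrow interior.  Defaults use a 1 mm isotropic
grid for test speed; a 2 mm slice / 1 mm increment anisotropic preset
mirrors typical reconstructions.  Every body axis must exceed
2 × (shell + 3 mm) so a non-empty marrow VOI survives erosion — this is
validated at construction.

**Marrow attenuation model.**  Marrow voxels are i.i.d. draws from a
two-component normal mixture in HU — the smallest family that can match
four target quantiles with skew.  `calibrate_distribution` fits the
mixture's (Q1, median, Q3, P95) to a reference cell by deterministic
least squares: residuals are model-minus-target quantiles in HU, with a
weak (0.05-weighted) regularizer pinning the two log-scales and the
mixture weight near their moment-based starting values, because four
constraints under-determine five parameters.  The fit runs in two stages
— plain mixture quantiles first, then refined against the *cutoff-
truncated* quantiles (conditioned on X ≥ −1000 HU), which are what the
measured histograms realize once sub-cutoff mass is excluded.  Ignoring
the truncation biases Q1 by several HU in the most-suppressed strata,
where up to ~1 % of mixture mass falls below −1000 HU.  Fits with any
residual above 2 HU (under half a bin) are rejected with diagnostics.

**Physiological floor.**  Marrow draws are truncated (resampled) at
−1000 HU: in real VNCa data sub-cutoff values come from densely calcified
structures, which the generator models explicitly as calcified islands
(single marrow voxels set to a configurable value < −1000 HU, default
−1500) and as the cortical shell (−1200 HU on the VNCa channels).  So a
phantom with zero islands contains no marrow voxel below the cutoff, and
the excluded count measures exactly the simulated calcifications.

**Cohorts and repeat exams.**  `generate_cohort` calibrates each
stratum's distributions once from a reference table, draws patient ages
uniformly within the band, and gives each patient's repeat exams fresh
sampling noise with the same parameters (optionally plus an additive
N(0, σ) HU drift per follow-up; default 0 — no inter-exam change model is
imposed).  Exam dates are spaced by a typical 185-day follow-up interval.
With `render_volumes=False` the generator skips rasterization and samples
the marrow values directly (default count: the geometry's marrow voxel
count); this is statistically identical for every histogram-level
statistic, because the rendered path computes histograms from the same
i.i.d. draws, and it is what cohort-scale runs use.  Rendered volumes are
exercised end-to-end in the pipeline tests.

**What the phantoms do not emulate** — and hence what passing tests do
not show about clinical data: realistic vertebra shape, partial-volume
mixing at the cortical interface, spatial correlation of marrow texture,
contrast-enhancement and scanner effects, segmentation errors beyond
vertebra miscounts, and any physiological inter-exam change beyond an
additive shift.  Results on phantoms validate the *pipeline arithmetic*
(geometry, binning, overlap, stratification), not VNCa physics.

## Problem sizes used in the shipped checks

Cohort-scale checks run with 5 exams per stratum cell and 10⁵ marrow
voxels per exam (the reference-recovery bound of ±5 HU, one bin, is met
with margin at this size), repeat-exam consistency with 10 independent
seeds, and erosion-oracle comparisons with ≥ 50 random masks up to 32³
voxels at three anisotropic spacings.  All randomness flows from explicit
seeds; identical spec + seed reproduces volumes bit-identically.

## Known limitations

- The mixture family is a modeling choice; the underlying cohort reports
  only binned summaries, so any family matching the four quantiles is
  admissible.  Skewness/tail behavior between the matched quantiles is
  not constrained by data.
- Group summaries are computed from the equal-weight average histogram,
  not pooled voxels, so prolific patients do not dominate; building from
  pooled voxels would weight by marrow volume instead.
- Intra-individual consistency is computed per suppression level and
  pooled across levels by the median over all consecutive-pair values;
  per-exam medians are an alternative pooling that is not the default.
- Ages 18–20 are excluded from reference building rather than merged into
  the 21–40 band.
- The voxel-structuring erosion mode approximates the margin by whole
  voxels per axis and is provided for emulation only; reported results
  should state the mode used.
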