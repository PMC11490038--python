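# Methods

## Model and pipeline

The quantification treats a field as an ordered z-series of registered
green/red intensity rasters, surface first (index 0) to substrate (last
index), with a 0.71 µm section step. Processing is strictly per pixel and
per section:

1. **Classification.** VIABLE iff green > g_thr and red < r_thr;
   NONVIABLE iff red > r_thr (the red-dominant rule takes precedence, so
   orange double-high pixels are non-viable); otherwise BACKGROUND.
   Thresholds default to 100/100 on the 0–255 scale. Inequalities are
   strict as stated by the underlying classification rule, so a pixel at
   exactly 100 in a channel satisfies neither the "high" nor the "low"
   test: green > 100 with red exactly 100 is background. Data deeper than
   8 bits are linearly rescaled (full scale → 255) before thresholding,
   because the thresholds are defined on the 8-bit scale.
2. **Epithelial exclusion.** Connected components (8-neighbour by
   default) are built per section from NONVIABLE pixels — nuclei are
   compact red areas *inside* the counted non-viable population — and
   flagged when area > 200 px AND solidity > 0.70 AND mean red ≥ 180.
   The 180 criterion is read as the red-channel mean, the quantitative
   form of "high red value". Flagged pixels become background; viability
   before and after exclusion is stored per section, and exclusion can
   only raise BV since it removes only non-viable pixels.
3. **Scoring.** BV% = 100·viable/(viable+non-viable) per section;
   sections below the 250 µm² aggregate-area gate are excluded from all
   means (a field with no passing section is excluded, a sample with no
   passing field is flagged missing). Field BV is the mean over included
   sections, sample BV the unweighted mean over fields.
4. **Thickness and layers** (biofilm experiment only). MFT = (n_slices −
   topmost) · z_step, where topmost is the shallowest section whose
   largest bacterial (viable ∪ non-viable) connected component reaches
   the cluster gate; the gate defaults to the pixel equivalent of the
   250 µm² area gate, the only cluster-size constant the analysis
   defines, and is configurable. The MFT span splits at MFT/2; an odd
   section count sends the middle section to the upper layer. Layer BV is
   the mean of included-section BVs (a pixel-pooled alternative is
   available via `layer_bv_mode`). Saliva samples are scored on the
   per-channel maximum-intensity projection only — the standard CLSM
   overall-view operator, monotone with per-slice classification — with
   no thickness or layers.
5. **Statistics.** Descriptives are mean ± sample SD (n−1) and median
   (IQR, linear-interpolation quartiles). Shapiro–Wilk screens for
   normality but only for reporting: the pipeline is nonparametric
   throughout. Wilcoxon tests are two-sided; the exact null is enumerated
   when there are no ties (and no zero differences, paired) and n ≤ 29,
   otherwise the normal approximation with continuity correction and
   mid-ranks is used, and the method is recorded in each result. Paired
   tests drop zero differences; an all-zero difference vector is reported
   as degenerate with p = 1. Intra-gel comparisons are the nine pairs
   shown per product (baseline vs each post time; five-minute vs each
   later time) against 0.05/5 = 0.01 — the five baseline-vs-post tests
   being the Bonferroni family behind the published threshold — and
   inter-gel comparisons are unpaired tests per timepoint against 0.05/6,
   displayed truncated to 0.008. Family sizes are configuration-exposed.
   A paired inter-gel mode (crossover pairing) exists behind a flag, off
   by default, since the published analysis used independent-samples
   tests.

## Solidity convention

Solidity is area divided by the pixel count of the filled convex hull,
where the hull is taken over the corners of the member pixels' unit
squares and a lattice pixel counts when it overlaps the hull with positive
area. A single pixel and any solid rectangle score exactly 1.0; a 2×3
block missing a corner scores 5/6. This differs from
`skimage.regionprops`, whose hull rasterisation gives 1.0 for that shape;
the stricter convention penalises ragged boundaries slightly and is
verified in the tests against an independent polygon-clipping oracle.
The hull is only evaluated for components that already pass the cheaper
area and brightness tests.

## Harmonised layer mode

The default layer split halves each field's own MFT. An optional
harmonised mode first computes, per (gel × timepoint) group, the median of
the per-field MFTs, takes the minimum over groups as a common span length,
and splits that span (measured from the top of each field's MFT span) at
its midpoint, so layer comparisons cover the same depth range in every
sample. Both modes are reported; the mode and the resulting span are
recorded in the run log.

## Synthetic data

`generate_stack` paints, per section, bacterial aggregates as
Gaussian-profiled disks of radius 1–4 px — far below the 200 px nucleus
criterion — grown into a few clusters by tangential accretion (each blob
attaches flush against a cluster member), plus scattered singletons.
Blobs never share pixels, so no pixel carries both stains, but touching
blobs merge into aggregates large enough for the thickness gate; blob
classes (viable/non-viable) are assigned against a per-section pixel-area
quota, so the realised viable fraction tracks the requested one to within
about half a blob (~0.5 percentage points). Non-viable bacteria are
painted with red peaks of 130–170, below the 180 nucleus criterion, so
merged bacterial components can never be mistaken for nuclei; planted
nuclei are bright (200–240) compact ellipses larger than 200 px kept
clear of bacterial pixels. Intensity profiles stay above the
classification threshold across the whole disk, a detector noise floor
(σ = 4) and background offset are added, and the ground truth records
per-section suprathreshold pixel counts, nucleus masks and the true
thickness. The default frame is a deliberately scaled-down 160×160 px
field at 1 µm/pixel — it preserves every structure the pipeline gates on
(aggregates above 250 µm², nuclei above 200 px) at a small pixel budget —
and the default thickness is drawn uniformly from the observed 11–19 µm
median range, rounded to whole 0.71 µm sections.

What the generator does **not** emulate: optical point-spread blur,
spectral bleed-through, photobleaching, depth-dependent attenuation, and
the skewed, zero-inflated BV distributions of real post-antiseptic
samples. Passing recovery tests therefore shows the measurement chain is
correct on well-separated two-channel signal, not that classification is
robust to real acquisition artefacts.

`generate_trial` draws subject-level BV as mu + sd·(√ρ·z_subject +
√(1−ρ)·ε), clamped to [0, 100], with the subject effect shared across all
of a subject's cells (both gels, all timepoints — the crossover reading of
a persistent subject effect) and ρ defaulting to 0.5. Defaults for the
per-(gel, timepoint) means/SDs are the published summary tables. The
clamping produces realistic point masses at 0 for low-viability cells
(which the rank tests then handle via mid-ranks). A known limitation:
normal draws parameterised by the published means/SDs carry the small
*real* between-gel differences those tables show, so simulated trials
occasionally find significant inter-gel differences that the single
observed trial did not; the published data were heavily skewed (medians
near zero), which means and SDs alone cannot reproduce.

## Numerical choices

- Area gate comparisons allow a 1e-9 µm² slack for float safety; the
  default pixel size is √(250/4750) ≈ 0.22942 µm so the 250 µm² gate is
  exactly 4 750 pixels.
- Quantile convention: linear interpolation between order statistics
  (recorded in output metadata).
- Display: p-values at four significant figures, scientific notation
  below 1e-4; the inter-gel threshold is truncated (floored) to three
  decimals for display while comparisons use full precision.
- Degenerate inputs: empty sections yield undefined BV and are excluded;
  MFT is 0 when no section reaches the cluster gate, in which case both
  layers are empty and layer BVs undefined.
- Determinism: all generators take explicit seeds; pipeline CSVs are
  byte-identical across reruns on identical inputs.

## Problem sizes used in the tests

The test suite and acceptance checks run on scaled-down inputs chosen as
the smallest sizes that exercise every gate: 128–160 px frames, 7–10 µm
synthetic biofilms, 2-subject end-to-end manifests, 200-replicate trial
simulations and 250-replicate null simulations at the study's n = 29.
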