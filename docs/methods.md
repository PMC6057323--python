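# Methods

`nucleograde` quantifies nuclear atypia in H&E-stained cervical biopsy
microscopy: it segments nuclei, measures 63 textural and morphological
features per nucleus, averages them into one 63-feature vector per
patient, and screens each feature for differences between low-grade and
high-grade CIN patient groups.  This note records the model choices,
conventions, and their rationale.

## Segmentation chain

Hematoxylin stains chromatin darkly, so nuclei appear as dark blobs on
a lighter eosin background.  The chain is:

1. **Grayscale conversion** with the ITU-R BT.601 luminance weights
   (0.2989, 0.5870, 0.1140), rounded half-up — the convention of the
   common numerical environments for `rgb2gray`.
2. **Smoothing** — Gaussian blur, `smoothing_sigma = 2.0` px by
   default.  An alternative `smoothing="log"` mode feeds the (negated,
   rescaled) Laplacian-of-Gaussian response to the edge detector
   instead; a band-pass "smoothing" stage admits both readings, and the
   Gaussian is the default because the Canny detector expects a
   smoothed intensity image.
3. **Canny edge detection**.  Hysteresis thresholds may be given as
   fractions of the maximum gradient magnitude; by default the high
   threshold is chosen by Otsu's method on the gradient magnitudes and
   the low threshold is 0.4 × high.  Because Otsu will happily split a
   pure-noise gradient distribution, an image whose Otsu threshold
   falls below 4× the median gradient magnitude is declared edge-free
   (object edges in this material are tens of times the noise
   gradients; measured ratios are ≈1 for edge-free scenes vs ≈20 for
   scenes with nuclei).
4. **Contour completion**: morphological closing with a disk of radius
   3 whose hole-filling step runs *between* the dilation and erosion
   halves (dilate → fill → erode).  A plain closing-then-fill cannot
   retain a bridge across a gap in a one-pixel-wide contour — the
   erosion probes reach the open regions on either side of the arc — 
   whereas the interleaved form bridges gaps up to twice the radius and
   then restores the outline.
5. **Size filter**: 8-connected components below `min_area = 500` px
   are discarded (the preset threshold for ~1728×1296 images at 400×
   magnification; it is a parameter).  Components touching the image
   border are also discarded because their truncated morphology would
   bias size and shape features.
6. **Logical AND** of the surviving mask with the grayscale image,
   then 8-connected labeling.  Regions are reported in (row0, col0)
   bounding-box order.

Touching nuclei are not split (no watershed); clumps that survive the
chain are treated as single regions.

## Feature definitions (63 per nucleus)

All point statistics are computed over in-mask pixels only; background
zeros inside the bounding box never enter a histogram, pair, run, code
or Tamura summary.  The wavelet transform needs a rectangular grid, so
it alone operates on the zero-background bounding-box crop.  All
entropies use the natural logarithm with 0·log 0 ≡ 0.

* **Histogram (4)** — mean, standard deviation, skewness, kurtosis with
  population (1/N) denominators over the raw 256 gray values; kurtosis
  is the non-excess form (Gaussian ≈ 3).  A constant nucleus has SD 0
  and undefined (missing) skewness/kurtosis.
* **Co-occurrence (13)** — gray levels quantized into 16 equal-width
  bins of [0, 255] (fixed binning, not per-nucleus min–max, so contrast
  information stays comparable across nuclei).  Pairs are counted at
  inter-pixel distance 1 in the four directions 0°/45°/90°/135°, only
  when both pixels are in-mask; directional matrices are symmetrized,
  summed, and normalized to a single matrix, from which the 13 Haralick
  features are evaluated with levels indexed 1..16.  Conventions for
  degenerate terms: correlation ≡ 0 when a marginal SD vanishes, the
  first information measure of correlation ≡ 0 when both marginal
  entropies vanish.  Sum variance is taken about the sum entropy (the
  classical Haralick form); difference variance is the variance of the
  |i−j| distribution.
* **Run length (5)** — runs of equal quantized level traced along the
  same four directions, broken at the mask boundary; SRE, LRE, GLNU,
  RLNU and RP (with P = in-mask pixel count) are computed per direction
  and averaged.
* **Wavelet (24)** — two-level Daubechies-2 decomposition with
  symmetric boundary extension; for each level-2 detail matrix
  (horizontal, diagonal, vertical): mean, median, max, min, range,
  sample (n−1) standard deviation, median absolute deviation about the
  median, mean absolute deviation about the mean.  The sample-SD
  convention here deliberately differs from the population SD of the
  histogram family; each follows the convention its formula family
  prints.  Crops smaller than 8×8 are flagged undefined.
* **Tamura (6)** — window scales k = 0..5; A_k is the mean over a
  2^k×2^k window (for k ≥ 1 spanning rows i−h..i+h−1 with h = 2^(k−1);
  k = 0 is the pixel itself), with reflective padding for windows and
  offsets that leave the crop.  E_k is the larger of the horizontal and
  vertical |A_k(·+d) − A_k(·−d)| differences with d = 2^(k−1) (d = 1 at
  k = 0).  S_best = 2^k for the maximizing k, ties resolved toward the
  smallest k (so a constant region has S_best ≡ 1).  Coarseness 1 is
  the in-mask mean of S_best; coarseness 2–4 are the 3-bin equal-width
  histogram of S_best over [1, 32] as percentages (they sum to 100);
  contrast is σ/(a₄)^{1/4} with σ, a₄ the in-mask population SD and
  kurtosis (defined 0 when σ = 0); roughness = coarseness 1 + contrast.
* **LBP (2)** — 8 circular neighbours at radius 1, bilinear sampling,
  for in-mask pixels whose sampling positions all lie inside the crop;
  code = Σ s(g_p − g_c)·2^p with s(x) = 1 for x ≥ 0, so a flat
  neighbourhood codes to 255.  The bilinear comparison is evaluated on
  centred differences (neighbour minus centre) so exact ties are exact,
  not floating-point noise.  Features are the mean and population SD of
  the code distribution.
* **Morphology (9)** — area; perimeter as the chain length of the
  8-connected outer contour (axial steps 1, diagonal √2), via
  Moore-neighbour tracing with a repeated-state stopping rule;
  equivalent diameter √(4A/π); convex area from the convex hull of
  pixel centres rasterized by centre inclusion (so digitally convex
  shapes reach solidity 1); major/minor axis lengths and eccentricity
  from the ellipse with identical normalized second central moments,
  including the +1/12 per-pixel variance correction (a 1-px line has a
  nonzero minor axis); solidity = area/convex area; extent =
  area/bounding-box area.

Feature order is fixed: histogram (1–4), co-occurrence (5–17),
run-length (18–22), wavelet H/D/V (23–46), Tamura (47–52), LBP (53–54),
morphology (55–63); column names are the lower-snake-case feature
names.

**Missing-value policy.** Any family-level degeneracy (constant region,
no valid pair, undersized crop, no qualifying LBP pixel) yields missing
(NaN) entries for that family, never aborts a batch.  Patient averaging
skips missing nucleus values; a patient-level entry is missing only
when every nucleus missed the feature, in which case that patient drops
out of that feature's comparison only (pairwise deletion).

## Cohort aggregation and screening

Patients are represented by the arithmetic mean of their nuclei's
feature vectors, pooled at nucleus level across all the patient's
images (not image-level means of means).  The screen then tests each of
the 63 features between the low (0) and high (1) groups:

* **Wilcoxon rank-sum** (the two groups are independent patients, so
  the unpaired rank-sum form applies, not the signed-rank form),
  two-sided; exact enumeration of the null distribution when the
  combined sample is ≤ 25 with no ties, otherwise the normal
  approximation with mid-ranks, tie correction and continuity
  correction.  Two identical constant samples give p = 1.
* **Point-biserial correlation** = Pearson correlation of the feature
  against the 0/1 label; positive r means higher values in high grade.
  Zero-variance features give r = 0.
* **Benjamini–Hochberg step-up FDR** over m = 63 tests (m is
  configurable; `bh_fdr` also accepts an explicit m larger than the
  supplied list for adjusting a published subset of a wider screen).
* Per-group mean and standard error (sample SD/√n) complete the
  report row; rows are sorted alphabetically by feature name.

## Synthetic cohort generator

The generator emulates the acquisition structure of the clinical
material: 22 patients per group, 4–5 non-overlapping fields per patient
(alternating), darkly stained non-overlapping nuclei on a lighter noisy
background.  Default frame is 512×512 with 8 nuclei per field — a
reduced-scale stand-in for 1728×1296 clinical fields chosen so a full
two-group cohort (≈200 images, ≈1600 nuclei) runs in about a minute on
one CPU.

Each nucleus is a star-convex region: an ellipse (area-preserving
semi-axes r√a and r/√a, random orientation) whose boundary radius is
modulated by random cosine harmonics 3–6 with a single irregularity
amplitude, so boundary irregularity is one controllable scalar and
masks stay single-component.  The interior is filled with a Gaussian
random field (white noise smoothed with a Gaussian kernel of the given
correlation length, normalized to unit variance and scaled to the
nucleus's intensity SD) on top of its mean intensity, blended into the
background over a ≈2-px smoothed boundary.  Placement is by dart
throwing with whole-configuration restarts, guaranteeing ≥4 px
clearance between conservative nucleus envelopes.

The two presets encode the directions reported for advancing CIN
grade — `high_like` has strictly larger mean radius (22 vs 18 px),
boundary irregularity (0.18 vs 0.08), texture correlation length (6 vs
3 px) and intensity inhomogeneity (SD 18 vs 10), and is slightly darker
(hyperchromasia).  The minimum base radius of 14 px keeps every planted
nucleus above the 500-px size filter.  One seed stream is split
hierarchically (cohort → patient → image → nucleus), so identical
specs and seeds reproduce bit-identical cohorts.

What the generator does *not* emulate: H&E colour (scenes are
grayscale; the pipeline's colour conversion is exercised separately),
epithelium architecture, touching/overlapping nuclei, staining
gradients, and out-of-focus blur.  Passing tests therefore demonstrate
that the pipeline recovers planted geometry, texture and group effects
under idealized optics — not that it matches expert segmentation of
real slides, which requires expert review.

A note on solidity: with the standard definition (area/convex area),
more irregular boundaries *lower* solidity, so the generator's
high-grade preset produces lower measured solidity; the published
screening table reports the opposite sign alongside prose describing
"higher border irregularities".  The standard definition is
implemented and the sign of the solidity effect is treated as an
empirical outcome, not asserted.

## Evaluation runs

`nucleograde.evaluation` packages the seeded end-to-end checks used by
`scripts/acceptance.py` and the validation tests:

* **Segmentation recovery** — fields of five well-separated planted
  nuclei (planted area ≥ twice the size threshold) plus two
  sub-threshold distractor disks (area ≈ 314 px): planted count must be
  recovered exactly, distractors rejected, matched centroid error ≤ 3
  px.
* **Coarseness response** — 20 single-nucleus scenes per correlation
  length (2, 4, 8 px): mean measured Tamura coarseness must increase
  strictly.
* **Planted-effect recovery** — the default 22 vs 22 cohort: the size
  features (area, equivalent diameter, minor axis length) must come out
  FDR-significant with positive point-biserial correlation.
* **Type-I calibration** — 200 replicate null cohorts (both groups
  drawn from `low_like`) at reduced scene scale (one 128×128 image with
  a single nucleus per patient, so hundreds of replicates fit in
  minutes): the pooled fraction of raw p < 0.05 over 200×63 tests must
  lie in the 99% binomial band around 5%.  Features from one cohort
  are correlated, so the binomial band is approximate for the pooled
  rate; measured rates across seeds fall near 4.8–5.2%.

## Known limitations

* The Canny "no-edges" guard (Otsu < 4× median gradient) is a
  heuristic tuned to noisy-background microscopy; extremely crowded
  fields could in principle raise the median gradient enough to
  suppress detection.
* The 500-px size filter and the generator's 14-px minimum radius are
  coupled; segmenting much smaller magnifications requires adjusting
  `min_area`.
* BH adjusted p-values are monotone but not idempotent under
  re-application; the report carries full precision, and printed ties
  at limited precision may legitimately adjust differently.
* Exact Wilcoxon enumeration is limited to combined samples of ≤ 25
  without ties; beyond that the continuity-corrected normal
  approximation is used, which is very slightly conservative near the
  5% level at n = 22 + 22.
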