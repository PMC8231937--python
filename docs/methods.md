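# Methods

## The measurement model

A *tumor map* is a whole cryosection imaged separately per stain with a
monochrome camera, stitched from adjacent fields of view, and analyzed per
region of interest (ROI). The package treats each channel as an 8-bit
intensity grid at a physical resolution of 0.75 μm/px (configurable), and
every lesion-level quantity as a functional of ROI pixel sets:

- intensity histograms are exact per-level pixel fractions (percent of ROI
  pixels), so the histogram-weighted mean equals the direct pixel mean by
  construction (verified to 1e-9 in tests);
- cellularity is the area fraction of the thresholded, particle-filtered
  Hoechst mask within the ROI;
- vascular density is the mean Euclidean distance from ROI pixels to the
  nearest CD31-positive pixel **anywhere in the section**. Restricting the
  search to the ROI would make values undefined for any lesion whose
  vasculature sits just outside its outline; biologically, such a lesion is
  well-supplied. ROIs with no internal vessel are still flagged
  (`no_vessel_in_roi`), and sections with no vessel at all yield NaN with
  `no_vessel_in_section` — flagged-and-excluded, never imputed.

Distances come from an exact Euclidean distance transform; a torus-wrapped
variant (3×3 tiling) exists for comparisons against boundary-free
point-process theory.

## Heterogeneity statistics

Kruskal–Wallis with mid-ranks and tie correction
(`C = 1 − Σ(t³−t)/(N³−N)`) is applied to per-lesion pixel intensities and,
separately, to per-lesion vascular densities grouped by organ; both entry
points share one implementation. The all-tied pooled sample (C = 0) is
defined as H = 0, p = 1 with a degeneracy flag rather than an error. The
chi-square approximation is used throughout; group sizes in this workflow
are large, so no exact permutation test is provided.

Whole-lesion pixel samples run to 10⁵–10⁷ values, where any rank test
rejects at machine-level p-values. A seeded uniform subsample without
replacement (default 10 000 pixels per lesion, configurable up to
full-sample) bounds both runtime and this degeneracy; subsampling is
recorded in every stats table header. Tests are reported per section
without multiple-testing correction, and the output says so explicitly.

Boxplot summaries use type-7 (linear interpolation) quartiles and Tukey
1.5·IQR whiskers; report figures draw boxes from the summary table itself,
so figure quartiles equal table values exactly. Spearman correlation
(mid-ranked ties, t-approximation p-value) relates vascular density to
marker expression across lesions and requires ≥ 3 lesions with defined
density.

## The synthetic section generator

The generator emulates the statistical structure of metastasis-bearing
sections, not their appearance:

- **Lesions** are non-overlapping disks with per-channel mean intensities
  (inter-metastatic heterogeneity) and an optional radial modulation
  `A·(1 − 2r/R)` (intra-tumoral gradient; its disk average is −A/3, which
  the ground-truth table accounts for by recording *spatial* noiseless
  means). Lesion shape is deliberately simple: none of the implemented
  statistics depends on boundary geometry.
- **Nuclei** are filled disks (radius uniform on {2, 3, 4} px, i.e.
  ~3–6 μm at 0.75 μm/px) at Poisson-placed centers, dense inside lesions
  (default 110 per 100×100 px ≈ 25% area coverage, matching packed tumor
  tissue) and sparser outside (default 30 ≈ 8%). The ground-truth nuclei
  area fraction is computed from the rendered mask, so recovery checks are
  exact at zero noise.
- **Vessels** are disk cross-sections at homogeneous spatial Poisson
  centers with region-specific rate λ (per px²), standing in for
  organ-dependent vascular density. A point process is used instead of
  branched networks because it keeps the analytic nearest-distance law
  `E[d] = 1/(2√λ)` available as an independent check of the entire
  distance-measurement chain.
- **Rendering convention**: a disk of radius *r* covers pixels *strictly*
  closer than *r* to its center, so `object_radius = 1` is a single pixel.
  This keeps radius-1 vessel fields point-like and the Poisson distance law
  applicable without a finite-size correction.
- **Noise and quantization**: additive Gaussian noise (one sd for all
  channels), clipped to [0, 255] and rounded. No camera model is claimed;
  this is the simplest noise under which mean recovery is unbiased to
  within quantization.

What the generator does **not** emulate: spectral overlap/unmixing,
autofluorescence gradients, staining batch effects, irregular lesion
shapes, vessel branching, marker released from destroyed tumor cells into
normal tissue (only a flat per-channel background mean is exposed), or 3-D
structure. Passing recovery tests therefore validates the measurement
chain — masking, ROI bookkeeping, histogramming, distance transforms, rank
tests — not the biology of real sections, where manual ROI screening
remains essential.

## Segmentation choices

- 8-connectivity everywhere; Otsu as the default auto-threshold. The
  recorded `threshold_used` under auto is Otsu's value + 1 so the mask
  convention "intensity ≥ threshold" coincides with Otsu's foreground.
- Defaults: `min_object_px = 4` for CD31 (rejects single-pixel noise),
  `min_lesion_px = 500`, `closing_radius = 10 px`; all exposed in config
  and echoed into output headers.
- Automatic lesion proposal (close → fill holes → size-filter) is a
  reviewable stand-in for expert screening, not a reproduction of it. On
  zero-noise synthetic sections it recovers the lesion count exactly and
  each proposal matches its true lesion with IoU ≥ 0.8 **provided** lesions
  are dense (nuclei density ≳ 350 per 100×100 px ≈ 50–60% coverage) and the
  background nuclei spacing exceeds twice the closing radius; below that,
  boundaries blur and manual override should be used. Exact pixelwise
  recovery of a disk boundary from a point-process nuclei mask is not
  achievable by morphological closing, which is why the criterion is
  count + IoU rather than pixel identity.
- Manual ROI masks override automatic labels wherever nonzero; label −1
  marks artifacts, which are excluded from every area normalization and
  statistic (stored as 65535 in 16-bit label TIFFs, documented in the CSV
  sidecar).
- In the pipeline, a constant channel under auto-threshold (e.g. a
  vessel-free, noise-free CD31 image) degrades to an empty mask with a
  warning instead of aborting the section; calling the library functions
  directly still raises, so interactive users are told to supply a
  threshold.

## Alignment

Channels of one section are co-registered by integer-pixel translation
only: they come from one physical section re-imaged per stain, so
translation dominates and subpixel/rotational registration is out of
scope. The correlation objective is the Pearson correlation between the
moving channel's central crop (margin = `max_shift`, default 20 px) and
the same-size reference window, evaluated for all shifts via fast
normalized cross-correlation. Ties and zero-variance images resolve
deterministically to (0, 0) with a flag; a maximum on the search boundary
is flagged as possibly truncated. The test oracle is an independent
exhaustive shift loop.

## Numerical and reproducibility choices

- All randomness flows from explicit seeds through `numpy` generators in a
  fixed draw order (lesions → nuclei → vessels → per-channel noise in
  sorted channel order), making channels and ground truth bit-identical
  across reruns.
- Stage manifests record the config snapshot, package version, wall times,
  warnings and SHA-256 of every emitted file; rerunning a config
  reproduces table bytes exactly (figures may differ in PNG metadata
  only).
- Validation problem sizes (e.g. 1024² Poisson fields, 2000 null
  replicates for the type-I error, 100 seeds for the homogeneous-section
  non-rejection rate, 360×400 px six-lesion recovery sections) were chosen
  so each check is statistically decisive — binomial/Monte-Carlo standard
  errors well inside the tolerance being asserted — while the whole suite
  runs in seconds.
- Parameter-recovery checks measure lesions under ground-truth ROI labels,
  the file-based equivalent of the manually outlined ROIs this workflow
  assumes; automatic proposals are validated separately because their
  boundary ring would otherwise confound marker-mean recovery.

## Known limitations

- Montage stitching is plain block concatenation; overlap-and-blend
  stitching is intentionally absent.
- Heat-map cutpoints default to equal thirds of the intensity range; they
  are a display/communication device, configurable and always echoed in
  output, not a validated staining score.
- Vascular "density" is a distance statistic; no skeletonization,
  branching, or vessel-maturity metrics are computed.
- No spatial autocorrelation / hotspot statistics; lesions are treated as
  exchangeable sampling units within a section.
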