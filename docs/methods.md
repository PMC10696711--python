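# Methods

`neolus` re-creates, end to end, a texture-based classification pipeline
for the six most common neonatal lung pathologies seen on point-of-care
lung ultrasound (LUS): Normal, TTN (transient tachypnea of the newborn),
PTX (pneumothorax), RDS (respiratory distress syndrome), CLD (chronic
lung disease) and CON (consolidation).  Clinical LUS images of this kind
are restricted by ethics and hospital data-sharing policy, so the
package pairs the analysis pipeline with a synthetic phantom generator
that renders the diagnostic morphologies the pipeline is meant to read.

## The pipeline

1. **Preprocessing.**  Overlay artifacts (patient info burned into fixed
   x–y positions of a video) are removed ROI-wise: pixels above half the
   ROI maximum, plus their 8-connected neighbours, are replaced by the
   ROI median (lower median of the original ROI values, for integer
   stability).  Every frame is then resampled (bilinear) to 520×420 and
   a 10-pixel border is trimmed, giving the canonical 500×400 raster.
   The size pairs are read as rows×columns.

2. **Dual-tree complex wavelet transform (DTCWT).**  Five decomposition
   levels; per level a real low-pass raster `M_j` and six oriented
   complex subbands `D_j^g`, `g ∈ {±15°, ±45°, ±75°}`.  Level 1 uses the
   near-symmetric biorthogonal 5/7 pair (exact rational taps, rescaled
   to DC gain √2 so all levels share one normalization); levels ≥ 2 use
   the standard 14-tap quarter-shift orthonormal pair, tree B the
   time-reverse of tree A.  The tabulated quarter-shift coefficients
   carry eight printed decimals, so at import they are projected
   (least-squares) onto the exact constraints Σh = √2 and Σ(−1)ⁿh = 0;
   without the projection a constant image leaks ~1e−6 of its amplitude
   into the subbands, with it the leak is at machine precision.
   Boundary handling is symmetric extension; odd-sized rasters are
   padded by one symmetric row/column before each split.  `M_j` is the
   average of the four tree combinations' scaling rasters — plain
   dual-tree implementations expose only the final low-pass, but the
   feature set needs a low-pass raster *per level* (e.g. the global mean
   of `M_2` is a known strong discriminator: coalescent-B-line classes
   brighten the deep low-pass bands).

   Oriented subbands are consumed as complex magnitudes.  Magnitude is
   the near-shift-invariant quantity of the transform, and means or
   co-occurrence statistics are only meaningful on non-negative rasters;
   whether the original analysis used magnitude, real part or both is
   not documented, so this is a deliberate, flagged choice.

3. **Texture features.**  Every sub-image raster is split into a top
   half (pleural-line content) and bottom half (A-line/B-line content);
   low-pass rasters additionally contribute a full-extent region.  Per
   region: 5 statistical features, 5 GLCM features × 6 offsets
   {(0,1),(1,0),(0,2),(2,0),(1,1),(2,2)} on an 8-level equal-width
   quantization, 11 GLRLM run-length features × 4 directions
   {0°,45°,90°,135°} on the same quantization, and the 10-bin
   rotation-invariant uniform LBP histogram (8 neighbours, 3×3
   neighbourhood, neighbour ≥ centre).  With 5 levels this yields
   (35 rasters × 2 regions + 5 low-pass full regions) × 89 = 6675 image
   features, plus the three clinical covariates.  Notable numerical
   conventions:

   * The SD in the statistical family is the population standard
     deviation.  The source formula as printed divides the root of the
     squared-deviation sum by `m·n`, which is dimensionally inconsistent
     with the skewness/kurtosis that must be scaled by SD³ and SD⁴; the
     population SD restores the standard moment definitions.
     Zero-variance regions return skewness = kurtosis = 0 and a
     degenerate flag.
   * Intensity entropy treats the sum-normalized region as a
     distribution (0·log₂0 := 0); a 256-bin histogram entropy is
     available via `FeatureConfig(entropy_mode="hist256")`.
   * GLCM correlation normalizes by the mean and population variance of
     the quantized region itself (not the GLCM marginals); the textbook
     marginal form is available via `glcm_correlation="marginal"`.
     Zero-variance regions return correlation 0.
   * GLCM/GLRLM features are emitted per offset/direction; averaging
     across them is a config option (`average_directions=True`).
   * GLRLM reuses the 8-level GLCM quantization.

4. **Selection and classification.**  Each image feature is discretized
   into 10 quantile bins computed on the training rows, and a chi-square
   test of independence against the class labels gives its p-value; the
   15 smallest p-values win (ties broken by original column order).
   Quantile binning was chosen because it is scale-invariant — the
   feature families differ by orders of magnitude — and how continuous
   features entered the original chi-square test is not documented.
   Clinical covariates never enter the ranking and always pass.  The
   classifier is a pooled-covariance LDA on features standardized with
   training statistics, ridge `1e−6·trace(Σ)/d` on the covariance
   diagonal (folds can have nearly as many features as samples), priors
   equal (balanced design) or proportional to class counts (imbalanced
   design).  Ties in the discriminant scores resolve to the first class
   in class order.

5. **Evaluation.**  Leave-one-out CV (per-image performance) and
   leave-one-subject-out CV (per-subject performance: all images of one
   subject held out together).  Ranking, selection, standardization and
   LDA are refit inside every fold.  The LOO driver computes each fold's
   quantile edges from one pre-sorted copy of the matrix (deleting a row
   of a sorted column is an index shift); the test suite asserts bit
   equality with the naive per-fold recomputation.  The feature-count
   sweep re-ranks per fold, consistent with the in-fold selection
   policy.  Confusion matrices are reported as counts and row
   percentages (two decimals); overall accuracy is `100·trace/total` and
   weighted F1 averages per-class F1 by true-label count.

## The phantom generator

The generator renders what a sonographer reads, not acoustic physics:

* **Pleural line** — bright horizontal band near the top; `normal`
  (thin), `thick`, or `irregular` (thick, undulating depth and patchy
  brightness).
* **A-lines** — equidistant horizontal echoes below the pleura with
  geometrically decaying brightness (aerated lung, reverberation).
* **B-lines** — vertical bright bands from the pleural line to the
  image bottom; `separate` (a few narrow lines), `coalescent` (one wide
  band), or `mixed`.
* **Consolidation** — elliptical hypoechoic blob (interior intensities
  compressed toward the background) with a bright, angularly irregular
  rim.
* **Double lung point** — A-line texture on one lateral half, B-line
  texture on the other (the TTN hallmark).
* **Speckle** — multiplicative Rayleigh field, lightly blurred
  (σ = 1.2 px) and mean-normalized; the minimal standard surrogate for
  ultrasound speckle.

Default class specs follow the standard morphology-by-pathology grid:
Normal (A-lines, thin pleura), TTN (separate B-lines + double lung
point), PTX (enhanced, brighter A-line pattern, no B-lines), RDS (thick
irregular pleura, coalescent B-lines, small consolidation), CLD (thick
irregular pleura, mixed B-lines), CON (large consolidation, thick
pleura).  Clinical covariates are drawn per class: CLD GA∈[24,28] wk
and DOL∈[28,90] d; RDS GA∈[24,32] wk, DOL∈[0,7] d; TTN GA∈[34,41] wk,
DOL∈[0,3] d; Normal/PTX/CON GA∈[24,41] wk uniform.  CGATS = GA + DOL/7.
This reproduces the clinical logic that covariates separate CLD from
RDS but say nothing about Normal vs PTX.  Canvas is 520×420 so phantoms
flow through the same preprocessing as real frames.  Subjects jitter
the class spec (geometry ±10 %, brightness ±8 %, pleural depth ±4 px);
frames within a video share the subject spec with a ±2 px translation
and fresh speckle.

No quantitative intensity statistics are available for the real
morphologies, so phantom realism is calibrated only to their qualitative
descriptions.  The phantoms are deliberately constructed to be
separable: the end-to-end experiments demonstrate that the pipeline
recovers class structure through the full preprocessing → DTCWT →
texture → selection → LDA chain, not that clinical-grade accuracy is
attainable — real LUS exhibits probe/depth variation, shadowing, rib
artifacts and far messier within-class heterogeneity, none of which the
generator emulates.  Passing phantom thresholds therefore validates the
machinery, not clinical performance.

## Study designs and problem sizes

The balanced design is 4 subjects per class × 6 lung regions × 5 frames
= 720 images from 24 subjects; the imbalanced clinical design
(185/180/305/105/245/530 images per class, 1550 total from 42 subjects)
exists in the package only through its reported confusion tables, from
which the metric arithmetic is recomputed.  The end-to-end experiments
in the acceptance script use the full 720-image balanced design with
k = 15 and equal priors.  The label-shuffled chance control is the mean
LOO accuracy over 3 independent label permutations: frames within a
video are nearly identical, so the effective sample size of a single
permutation is closer to the 144 videos than the 720 frames and one
draw has an accuracy SD of ~2.5 points; averaging three brings the
control's precision in line with the ±4-point band it is checked
against.

## Known limitations

* No inverse transform; the decomposition is analysis-only.
* The DTCWT is validated by structural and property tests (constant
  annihilation, orientation selectivity, energy ≈ conservation,
  shift-variance below the critically-sampled DWT baseline), not
  against an external reference implementation.
* The ±15°/±75° orientation sign convention is internal; only the ±45°
  pair is pinned by a directional fixture.
* Lung sliding and all temporal/video features are out of scope, as is
  curvilinear probe geometry.
* The chi-square binning scheme and feature standardization are
  documented deviations wherever the original analysis left them
  unspecified; both are config-exposed.
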