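# Methods

## The processing model

The package treats apoptosis quantification as a five-stage measurement on a
calibrated single-channel z-stack I(z, y, x):

1. **Per-slice rank filtering.** For radius r, each output pixel is the mean
   or median over the (2r+1)×(2r+1) Chebyshev neighbourhood with
   replicate-edge padding.  The default is the median with r = 1: the median
   of one extreme value and eight background values is a background value, so
   every isolated aberrant-high pixel is removed, while straight object edges
   are fixed points of the filter.  The square neighbourhood matches the
   8-neighbours-plus-centre definition exactly at r = 1; for r ≥ 2 it
   diverges from disc-shaped kernels used by some interactive tools (a
   documented, deliberate simplification — the protocol itself only uses
   r = 1).  All filter arithmetic is floating point; quantization happens
   only on explicit save.
2. **Z-projection.** Per-pixel mean, max or sum over z.  Max is the default:
   the tissue is a monolayer, so each (y, x) column contains at most one
   object, and max projection preserves the full object–background contrast
   where averaging dilutes signal that occupies a few slices.
   The identities max ≥ average (pointwise) and sum = n·average are tested.
3. **Thresholding.** Foreground is *strictly* greater than T (configurable
   to ≥).  T may be algorithmic, manual (from a CSV table, the headless
   equivalent of interactive determination), or a consensus.
4. **Particle analysis.** 8-connected components (4 available) are measured
   and filtered by equivalent-circle diameter (default) or area, then
   reduced to the count and total-area readouts.
5. **Group statistics.** Per-group mean/SD/min/max/median and two-sided
   Mann–Whitney/Wilcoxon rank-sum tests on either readout; ordinary least
   squares for threshold-series concordance.

## Threshold algorithms

All four algorithms operate on an equal-width histogram of the (optionally
ROI-masked) image over its [min, max] range, 256 bins by default, mirroring
the 8-bit convention such algorithms were defined for while supporting
arbitrary dynamic range.  Bin-index results are mapped back to intensity as
the selected bin's **lower edge**, consistent with the strictly-greater
foreground rule.

* **Otsu** maximizes the between-class variance ω₀ω₁(μ₀−μ₁)².  Because the
  histogram counts are integers, the comparison is done in exact rational
  arithmetic ((S₀N₁−S₁N₀)²/(N₀N₁) with integer class sums), which makes the
  documented tie rule — lowest optimizing bin — exact rather than dependent
  on floating-point summation order.
* **Moments** (Tsai's moment-preserving selection) matches the first three
  histogram moments with a two-level distribution and places T at the first
  bin where the cumulative fraction reaches the background fraction p₀
  (`cumsum ≥ p₀` with a 1e-12 tolerance; the ≥ convention is what makes the
  symmetric two-spike case resolve to the lower spike).
* **IsoData** iterates T ← (mean below + mean above)/2 from the overall mean
  to a fixed point (tolerance 1e-9, cap 10 000 iterations).  The fixed point
  depends on the starting value; starting at the overall mean is the
  package's pinned convention and the oracle tests verify both the
  fixed-point property and agreement with an independent iteration.
* **Intermode** smooths the histogram with a replicate-padded 3-bin moving
  average until exactly two local maxima remain (cap 10 000 passes) and
  returns the intensity at the midpoint of the two mode indices.

A degenerate histogram (constant source, or a single occupied bin) is
flagged and refused by every algorithm rather than silently producing a
cutoff.

**Consensus thresholds.** When one unique value must binarize a whole
experiment, the package uses the median of per-group medians of the
per-image thresholds.  Taking group medians first makes the consensus
invariant to group headcount — duplicating every image of one group leaves
the value unchanged — which a global median does not guarantee.  An optional
consensus fraction applies the rule to only the first k% of images (sorted
by image id), for workflows that decide the unique value early.

## Particle measurement conventions

Coordinates are 0-based with x = column, y = row; bounding boxes are
half-open.  Area is the pixel count times pixel_size².  The perimeter is
scikit-image's weighted line-integral estimator of digital boundary length;
it was chosen over chain-code boundary following because it is substantially
less biased on small convex objects (a rasterized disc of radius 20 px
scores circularity 0.91 with this estimator versus ≈0.87 with √2-weighted
chain codes).  Circularity 4πA/P² is clamped at 1 from above only; digital
discs legitimately score below 1.  Single-pixel objects, whose estimated
perimeter is 0, are assigned circularity 1.

The physical size limit is interpreted as a minimum equivalent-circle
**diameter** (strictly greater than the limit), because such limits are
stated as lengths comparable to a nucleus diameter; a minimum-**area** mode
(µm²) is provided as well since classic particle analyzers filter on area.
Filtering happens after measurement, so recorded particle tables can be
re-filtered without re-segmentation.

One ROI polygon per image is enforced (rasterized at pixel centres, even-odd
rule, boundary included); quantifying two zones of one field means listing
the image twice in the manifest.

## Statistics

Rank-sum tests use exact enumeration when both groups have ≤ 10 observations
and no ties, otherwise the normal approximation with tie and continuity
corrections (delegated to scipy; validated in the tests against an
independent dynamic-programming enumeration of the null distribution).
Group SD uses the n−1 denominator and is reported as 0 for singleton groups.
P-values are two-sided and uncorrected.  Concordance between two threshold
series is OLS of y on x with R² the squared Pearson correlation and p from
the slope t-test.

## The synthetic scene generator

Scenes emulate a stained monolayer epithelium imaged as a z-stack.  Defaults
(the generator's study conditions): 512×512 px × 8 slices at 0.5 µm/px,
16-bit range, background level 200, signal level 1800, Gaussian background
noise SD 30 — a bright-staining regime in which mid-level thresholds sit far
(≈27 SD) above background, so defect behaviour rather than shot noise
dominates, as in the stainings the protocol targets.  Objects occupy a
contiguous central band of ~40% of the slices (monolayer with limited
folding).

* **Nuclear (TUNEL-like) scenes** place `n_cells` soft-edged spots (logistic
  edge, softness 0.7 px) of diameter 3.5 µm.  With `cluster_strength = 0`
  centres are drawn uniformly with enforced pairwise separation
  ≥ 2·radius + 3 px, so every half-maximum mask is separated by at least one
  background pixel and the true count is recoverable exactly.
* **Cytosolic (cleaved-caspase-like) scenes** place whole-cell discs of
  diameter 7 µm at `round(event_rate · field_area/1000)` centres drawn from
  a Thomas-like parent–offspring process: parents uniform, offspring
  displaced by an isotropic Gaussian whose SD shrinks from 2 object
  diameters to 0.4 diameters as `cluster_strength` goes 0 → 1, so adjacent
  events overlap and merge after binarization.

**Ground truth is frozen before noise and defects**: each object's truth
mask is the half-maximum set of its own noiseless profile, the true area is
the union area (overlaps counted once), and the true count is the number of
placed objects.  Binarizing the noiseless scene at the mid-level between
background and signal therefore recovers the truth, and any later
degradation is attributable to noise, defects, or processing.

**Defect injection** adds (a) isolated hot pixels at 97% of the dynamic
range, each with all 8 in-plane neighbours untouched, placed ≥ 3 px
(Chebyshev) from bright regions and from each other, at a deterministic
count of `round(rate · kilo-voxels)`; and (b) 3×3 hot patches (`round(rate)`
per image) whose equivalent diameter (1.7 µm at 0.5 µm/px, eroding to a 5-px
cross ≈ 1.26 µm after the median filter) stays below a 2 µm size limit.
Inventories of all injected coordinates are returned for auditing.

What the generator does **not** emulate: optics (PSF blur, depth
attenuation), photobleaching, tissue folding, intensity heterogeneity within
objects, and autofluorescence gradients.  Passing tests therefore show that
the pipeline implements the protocol's logic correctly and that its
qualitative claims (median-vs-mean behaviour, size-limit efficacy,
count-readout attenuation) hold under controlled geometry — not that any
fixed threshold choice is optimal for a particular microscope or stain.

## Problem sizes and numerical choices

Tests and the acceptance script use the default 512×512×8 scenes for
filter/defect/recovery checks (10–20 scenes each) and 320×320×6 scenes for
the cytosolic density sweep (5 densities × 20 replicates, plus a 2×-density
two-group comparison at n = 20/group), the package's chosen balance between
statistical stability and seconds-scale runs.  All randomness flows from a
single seed through `numpy` SeedSequence spawning, and reruns are
byte-identical, including written TIFFs and CSVs.  Degenerate inputs (empty
masks, constant images, single-bin histograms, empty groups, inverted filter
bounds, self-intersecting polygons) raise explicit errors rather than
propagating NaNs.

## Known limitations

* Disc-kernel rank filters (r ≥ 2) of interactive tools are not reproduced;
  only the square-neighbourhood definition is implemented.
* The remaining histogram algorithms found in interactive menus (Huang, Li,
  Triangle, …) are out of scope; the four implemented ones cover the
  validated and the cautionary cases.
* No watershed splitting of merged clusters: the package's position is that
  the area readout, not post-hoc splitting, is the robust response to
  cytosolic cluster merging.
* `.lif` and other proprietary containers are not read; convert to
  multi-page TIFF/OME-TIFF with µm calibration (or pass `--calibration`).
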