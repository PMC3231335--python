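# Methods

## Problem setting and model

`bloomsat` maps the reproductively active population of a mass-flowering
canopy tree species from two single-date, 4-band (blue/green/red/NIR)
reflectance images at ~2.4 m ground sample distance. The core physical
assumption is linear mixing: the reflectance of a pixel is a convex
combination of "endmember" spectra (flowering crown, vegetation, soil,
water, man-made), so a crown smaller than a few pixels appears as a compact
cluster of pixels whose flower abundance F decays from the crown core to its
edge. Detection is per-date and purely spectral; change analysis is purely
geometric on the resulting centroid sets and assumes crowns do not move
between dates (matched centroids are the same tree).

## Pipeline stages and their tunables

| parameter | default | meaning |
|---|---|---|
| `nu` | 0.1 | one-class SVM outlier budget, dimensionless in (0, 1] |
| `gamma` (`gamma_date2`) | 0.1 | RBF kernel width, in 1/reflectance²; scene-dependent, overridable per date |
| `train_quantile` | 0.001 | fraction of scene pixels (brightest in green+red) used to train the one-class SVM |
| `fraction_pure` | 0.80 | Region A purity threshold on flower abundance F |
| `fraction_mixed_low` | 0.25 | lower F bound of Region B |
| `angle_max` | 0.05 rad | spectral-angle ceiling for Region B |
| `n_classes` | 25 | ISODATA spectral class count |
| `merge_radius` | 5.0 m | centroid buffer-merge radius (≈ one crown diameter) |
| `match_tolerance` | 5.0 m | cross-date centroid matching distance |

**Training-pixel selection.** Candidate flowering pixels are picked
automatically as the top `train_quantile` of a flower-likeness index — the
summed green and red reflectance, where a yellow floral display outshines
every background class. The default of 0.1 % reflects the expected pure
flowering-pixel budget of a crown-scale scene (tens of crowns of 2–4 pixel
diameter contribute a few pure pixels each); a much larger quantile would
drag background pixels into the one-class training set and bias the derived
endmember. The pipeline additionally floors the training size at ⌈1/ν⌉ so
the dual box constraint stays feasible on small scenes.

**One-class SVM.** The dual quadratic program (RBF kernel) is solved by
libsvm via scikit-learn with a 1e-9 convergence tolerance; dual coefficients
are rescaled to the normalization 0 ≤ α ≤ 1/(νl), Σα = 1 and the bias is the
mean kernel expansion over unbounded support vectors — the standard,
numerically stable choice. Spectra enter in native reflectance units without
standardization, because the kernel width γ is specified on that scale.
Tests cross-check the fit against an independent dense-QP solve (SLSQP on
the full kernel matrix) on small instances.

**Unmixing.** Fully constrained least squares (sum-to-one and
non-negativity) is solved per pixel by non-negative least squares on a
system augmented with a heavily weighted (1e5) sum-to-one row, followed by
exact renormalization; this pins Σ F to 1 at the 1e-9 level while moving the
solution negligibly. Non-negativity and sum-to-one are defaults, not
hard-wired: both can be disabled, in which case the equality constraint is
handled by null-space elimination. A rank check on the (sum-to-one
augmented) mixing matrix rejects degenerate endmember sets. With 4 bands the
library may carry at most 5 endmembers.

**Region rule.** The F = 0.80 boundary is assigned to Region B and the
F = 0.25 boundary to background, making the rule total and non-overlapping
(half-open intervals). Region A is fraction-only by default; a configuration
flag (`angle_applies_to_pure`) additionally imposes the angle ceiling on
Region A for users who want a stricter purity rule. Zero-reflectance pixels
(possible after noise clipping) are labeled background with angle π rather
than raising.

**ISODATA.** Implemented as Lloyd iterations with empty-class dropping
(warned, so the final class count may fall below 25) and a deterministic,
data-driven initialization: seeds at evenly spaced quantiles — endpoints
included — of the pixel projections onto the first principal axis. Including
the endpoints guarantees that extreme spectra (the bright flowering pixels)
seed their own class instead of being absorbed into a background class.
Split/merge variance thresholds are deliberately not applied. A spectral
class is flower-positive when the majority of its pixels carry a Region A/B
label; the flower raster is the union of such classes.

**Centroids and merging.** 8-connected components (diagonal adjacency is
physically contiguous at 2–4 pixel crown diameters) become centroids at the
unweighted mean of member pixel centers. Buffer merging takes the transitive
closure of the "within `merge_radius`" relation via union-find and collapses
each group to its pixel-count-weighted mean; the pass repeats to a fixed
point so the post-merge minimum spacing provably exceeds the radius. A
manual quality-control inspection of merged centroids is replaced by the
audit log attached to each `CrownSet`, which records every grouping for
human review.

**Change detection.** Greedy nearest-pair matching (globally closest
unmatched pair first, ties broken by id order) under `match_tolerance`. At
realistic crown spacings (inter-crown distance well above the tolerance)
this agrees with the exhaustive maximum-cardinality / minimum-distance
matching, which the tests verify by brute force on small instances. The
tolerance reuses the 5.0 m crown-scale reasoning of the merge radius; it is
configurable and is the package's own choice of default.

## Synthetic scene generator

The generator emulates the study conditions the pipeline is designed for: a
256×256-pixel, 4-band reflectance scene at 2.4 m resolution, a blocky
background mosaic (85 % vegetation, 6 % water, 6 % soil, 3 % built, in
8-pixel patches), and by default 50 flowering crowns of 2.4–4.8 m radius
(2–4 pixel diameters) with peak flower fraction 0.9–1.0, at least 12 m
apart, plus additive i.i.d. Gaussian noise of sd 0.01 reflectance units per
band, clipped to [0, 1] (clipping affects ≪ 1 % of samples at the default
noise). Crown abundance tapers linearly from the peak at the centroid to
zero at the crown radius. Crown centers are snapped to pixel centers: at
2.4 m resolution sub-pixel centroid placement is unidentifiable, and
snapping gives the generator an exact pure-pixel contract (a noiseless crown
with peak fraction 1 contains one pixel exactly equal to the flower
endmember). Two-date pairs share the background mosaic and crown layout;
each crown is flagged present on both dates, date 1 only, or date 2 only,
and noise is drawn independently per date.

What the generator does *not* emulate: sensor point-spread, atmospheric and
illumination effects, georegistration error between dates, crown overlap and
liana loads, within-crown spectral variability, and partial flowering.
Passing end-to-end tests therefore demonstrates the correctness and internal
consistency of the algorithm chain under the linear-mixing model — not
detection accuracy on real imagery, where endmember variability and
registration error dominate. Inputs are assumed to be surface reflectance;
radiometric calibration (per-band gain/offset) is accepted as a pre-step
hook but no atmospheric correction is performed.

## Numerical choices and degenerate inputs

- Decision values of margin support vectors straddle zero at the solver
  tolerance; the test suite counts training outliers as f < −1e-8.
- Spectral angle clamps the cosine to [−1, 1] before arccos; zero-norm
  vectors raise in the scalar API and are mapped to background in rasters.
- ISODATA stops when the assignment change rate drops below 1e-4 or after
  100 iterations; with `n_classes=1` it returns the trivial single class.
- Empty flower rasters, empty crown sets and background-only scenes are
  valid zero-crown outcomes throughout the pipeline, not errors; failed
  stages abort with the stage name and retain partial outputs.
- Crown placement is rejection sampling with an explicit retry budget;
  infeasibly dense requests fail loudly rather than silently under-placing.

## Problem sizes

Default test and reproduction runs use 256×256-pixel scenes (65,536 pixels,
the scale at which 50–100 non-overlapping crowns fit comfortably at 12 m
separation); unit tests use 48–160-pixel scenes. A full single-date
detection on the default scene takes ~10 s on one CPU, dominated by the
per-pixel constrained unmixing and the ISODATA iterations.

## Known limitations

- The per-scene kernel width γ must be supplied (default 0.1); no automated
  ν/γ search is included.
- Greedy matching is not guaranteed optimal when inter-crown spacing
  approaches the matching tolerance.
- The packaged aerial-photo comparison supports only the simple pooled
  match-rate percentage; the analogous second-date rate is computable with
  `match_rate(table, date=2)` but the table's second-date bookkeeping mixes
  trees that skipped the reference-year flowering, so that rate should be
  interpreted with care.
- One-class training assumes the flower display is the brightest green+red
  feature; scenes with brighter non-flower targets (specular roofs, sand)
  would need a user-supplied training mask.
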