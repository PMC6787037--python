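# Methods

This note documents the models, conventions and design choices behind
`nanotube-quant`: what each pipeline computes, which parameters matter and
why their defaults are what they are, what the synthetic scenes do and do not
emulate, and the numerical corner cases.

## Calibration and coordinates

Every raster carries a mandatory physical pixel size (µm per pixel edge);
all thresholds stated in µm or µm² are converted to pixels at this
calibration (`area_px = area_um2 / s²`). Calibration is always user-supplied:
TIFF resolution metadata, when present and in disagreement by more than 1 %,
triggers a warning and is ignored — silently trusting writer-dependent
metadata is a reproducibility hazard. Coordinates are row-major, origin at
the top-left, 0-based; bounding boxes are half-open. Intensities enter the
analysis only through thresholding; no flat-field or illumination correction
is applied (acquisition settings are assumed constant within a run, which is
how screening batches are acquired).

The synthetic fixtures default to 0.5 µm/px, a plausible wide-field 40×
sampling; nothing in the package depends on that particular value, and every
physical threshold rescales automatically.

## Background models

The manual "adjust and select" intensity step of interactive image analysis
is replaced by an explicit `BackgroundModel` with four reproducible rules:

| method | threshold | default use |
|---|---|---|
| `percentile` | max of per-image percentiles of donor-free controls (param 99.9) | donor channels |
| `mean_plus_k_sd` | µ + k·σ of pooled control pixels (k = 5) | alternative for very clean backgrounds |
| `otsu` | Otsu's threshold on pooled pixels | cell/recipient channels (on the image itself) |
| `manual` | user value | exact reproduction of a previous run |

Using the *maximum* of per-image percentiles guarantees that on every control
the supra-threshold fraction is at most (100−p)/100 up to ties. Segmentation
takes pixels strictly above the threshold, labels components (8-connectivity
by default, so 1-px diagonal protrusion necks stay attached to their body),
optionally fills internal holes, and applies inclusive area bounds. Holes in
cell masks are filled before morphology so that internal dark spots are not
misreported as protrusion residue. The "≥ 100 µm²" cell/recipient gate is
inclusive, reading "100 µm² or larger" literally.

## Protrusion pipeline

Opening with *n* erosion passes followed by *n* dilation passes of a square
element removes structures thinner than ≈ 2·*n*+1 px (3×3 element) while
restoring the convex cell body; the residue (original minus opened mask) is
the candidate protrusion set. Defaults: 3×3 square, 7 passes, capturing
structures up to ≈ 7 µm wide at 0.5 µm/px. Passes are a pixel-space
parameter; `MorphologyConfig.captured_width_um` reports the implied physical
capture width so users at other calibrations can rescale.

A 2×2 element is also offered. An even element has no centre pixel, so a
fixed anchor rule is applied — erosion over {p, p+(0,1), p+(1,0), p+(1,1)}
and the adjoint dilation — making the composition a mathematically true
opening (anti-extensive, idempotent). This pins down behaviour that
interactive packages leave to an undocumented anchor convention. As a belt
and braces, `open_mask` intersects its output with the input mask, so the
residue is never negative regardless of configuration.

Residue components are screened with four inclusive bounds (defaults:
area ≥ 20 µm², longest axis ≥ 10 µm, circularity ≤ 0.6, box-area ratio
≥ 1.9). The longest-axis bound is a *length* in µm. The box-area criterion is
interpreted as the dimensionless ratio of axis-aligned bounding-box area to
object area — a pure number near 1.9 cannot be an absolute area, and this
ratio selects elongated or bent shapes, which is the evident intent of a TNT
screen; the filter can be disabled (`min_box_area_ratio=None`) if a
different reading is wanted. One caveat of the ratio: a perfectly
axis-aligned straight ribbon has ratio ≈ 1 and is rejected; real TNTs are
curved and arbitrarily oriented, where the ratio is large.

A cell is positive iff at least one surviving protrusion overlaps or is
8-adjacent to the opened body. Cells whose body vanishes entirely under
erosion ("degenerate": everywhere thinner than the capture width) are never
classified positive — calling a fully-eroded cell "all protrusion" would be a
false positive by construction — and are excluded from percentage
denominators but reported in a separate count. A group with zero valid cells
reports a missing percentage, never 0 %.

## Morphometry conventions

Pixels are treated as unit squares centred on their integer coordinates,
consistently in two places:

* **Feret (caliper) length** = maximum pixel-centre distance + 1 px. The
  caliper maximum is computed exactly over convex-hull vertices (not sampled
  at a finite set of orientations); collinear regions fall back to all-pairs.
  The +1 px term accounts for the two half-pixel margins at the extreme
  pixels, so a 1×n line measures n px and a w×h rectangle measures
  √(w²+h²) px within √2−1 ≈ 0.41 px.
* **Equivalent-ellipse moments** carry the +1/12 per-pixel variance of a unit
  square, so a solid rectangle's aspect ratio is exactly w/h and a 1-px-wide
  line has a finite aspect ratio.

Circularity = area / (π/4 · Feret²); a rasterized disk of radius r measures
≈ (2r/(2r+1))² ≈ 0.98 at r = 50, converging to 1 from below. Rasterization
can push circularity slightly above 1 for tiny compact shapes; the reported
value is clipped to [0, 1.05] while filters always compare the raw value
(transparency over cosmetic clipping). Single-pixel regions have a defined
area but undefined length/circularity/aspect; they are flagged and excluded
from summaries.

"Length" of a protrusion defaults to the Feret diameter, which is the natural
measure for separated, straightish protrusions; `traced_length_um` offers a
skeleton-geodesic alternative (longest shortest path along the 8-connected
skeleton) for strongly curved TNTs. Summaries report arithmetic mean and
sample SD (n−1), with no outlier removal.

Cut lines (polylines, default 1 px wide) remove their pixels from a cell
mask and re-label the pieces, the largest piece being the body — supporting
the manual separate-and-measure workflow for individual protrusions.

## Transfer pipeline

Donor components are defined on the *full* donor channel and then related to
each ROI, so a physical punctum spanning two touching recipients is handled
symmetrically (boundary-excluded from both) instead of double-counted.
Exclusion precedence is fixed and auditable: (1) any component intersecting
the ROI's inner boundary band (ROI minus its erosion by `boundary_width`,
default 1 px, 8-neighbourhood) is excluded entirely and counted as a
boundary exclusion — edge signal typically reflects donor/recipient cell
overlap; (2) a remaining component larger than `punctum_max_area` (default
25 µm²) is excluded as oversize. The size cap is applied after ROI clipping;
since accepted components are fully interior, clipping is the identity for
them.

`punctum_min_area` (default 1 µm²) discards components below an
organelle-plausible size *at detection*, before either exclusion step. This
noise floor is required by the percentile background model: a 99.9th
percentile threshold by construction leaves ~0.1 % of background pixels
supra-threshold, and without a minimum size nearly every ROI would contain a
1-px speck. Applying it at detection keeps the boundary/oversize counts
about real objects. The floor is configurable to 0.

## Synthetic scenes

`SceneSpec` → `generate_scene` produces a three-channel field (cell, donor,
recipient) plus exact per-object ground truth. Defaults emulate the
co-culture screening conditions: ~40 macrophage bodies (ellipses,
150–600 µm², aspect ≤ 1.8) and ~12 fibroblasts (300–1500 µm²) per ~1 mm²
field — matching the seeding density of 75k + 50k cells per 6-well well —
protrusion prevalence 0.4, ribbons 2 µm wide with length N(45, 15) µm
truncated at 15 µm (the scale of measured TNT-like protrusions), puncta
2–20 µm², background N(200, 20) on a 16-bit scale with foreground +3000,
optional Poisson noise. Objects are rejection-placed with a 2-px minimum
separation so components never merge under 8-connectivity; impossible
geometry raises `SceneGeometryError` naming the first offending object.

Ribbons attach radially at a random boundary point, their root embedded
1.5 px into the body to guarantee attachment. The default band is a
quadratic Bézier with sagitta 8 % of the chord — TNTs curve, and an exactly
axis-aligned straight ribbon is a rasterization corner case rather than a
biological one — bounded so the Feret length stays ≥ 0.9 × arc length,
keeping the Feret-vs-traced-length ambiguity immaterial. Straight bands
(`protrusion_bend = 0`) are rasterized by exact rectangle inclusion
(pixel centre within the chord × width box), giving analytic area and length
for the self-consistency tests.

Puncta are rasterized disks: interior puncta are placed clear of the
boundary band, edge puncta centred on the ROI's outermost pixel ring
(guaranteeing boundary exclusion), oversize blobs (default 40 µm²) fully
interior. Counts can be drawn (positive fraction + 1 + Poisson) or specified
exactly per recipient. `generate_control` emits the matching donor-free
background image.

What the generator does **not** emulate: point-spread-function blur,
illumination gradients and stitching seams, touching/overlapping cells of
the same channel, out-of-focus light, and 3-D structure. Passing tests on
these scenes therefore demonstrate the correctness of the *algorithmic*
chain (thresholding → morphology → descriptors → counting) under realistic
geometry and noise, not robustness to every optical artifact of real
micrographs; on real data the background model choice and the cell-overlap
rate are the dominant extra error sources.

## Numerical choices and degenerate inputs

* Area bounds are compared in pixels with a 1e-9 guard so exact-boundary
  objects ("100 µm² or larger") are kept at either calibration.
* Filter comparisons carry the same epsilon; ties are inclusive.
* Empty masks are legal everywhere: opening an empty mask, segmenting a
  blank image, or classifying zero ROIs returns empty results or a missing
  (NaN) summary, never an exception.
* Scene generation, noise and all sampled geometry derive from one
  `numpy.random.default_rng(seed)` (PCG64), so scenes are bit-identical
  across platforms for a given seed.
* Problem sizes in the test suite (scene fields of 768–2304 px, 100-cell
  classification batches, 200-raster morphology oracles) were chosen as the
  smallest sizes at which every property is exercised away from its boundary
  conditions.

## Known limitations

* Touching cells are not split (no watershed); overlapping-cell signal is
  excluded rather than resolved, mirroring the screening workflow's own
  exclusion rule.
* The protrusion capture width is set in pixels (passes); analyses at other
  magnifications must rescale passes, and the config surfaces the implied
  physical width to make that explicit.
* Box-area ratio rejects protrusions that are both perfectly straight and
  axis-aligned; disable the filter if that matters for a given dataset.
* 3-D structure (Z-stacks, substrate detachment of true TNTs) is out of
  scope; the pipelines classify *TNT-like protrusions* from single 2-D
  frames.
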