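# Methods

This note records the models, conventions and design choices behind
`rootgrain`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Scale model

All physical traits derive from the scanner resolution:
`mm_per_px = 25.4 / dpi`. The reference acquisition setting is 1200 dpi
(0.02117 mm/px, 47.24 px/mm). Tests and examples that only assert
scale-free orderings (growth-pattern contrasts) run the generator at
300 dpi to keep canvases small; single-root recovery is validated at the
full 1200 dpi.

## Annotation tiling

Two modes split a polygon annotation document across an s × s tile grid
(default s = 2048):

- **faithful** reproduces the historical splitting loop: every vertex is
  shifted by the tile origin, vertices strictly outside `[0, s]` in either
  coordinate are deleted (so boundary values 0 and s survive), and shapes
  left with ≤ 2 vertices are dropped. Border-crossing polygons are thereby
  distorted — the price of bit-level reproducibility of historical tile sets.
- **clip** (default for new data) intersects each polygon with the tile
  square using exact polygon geometry; a polygon may split into several
  parts, each emitted under the parent label. Clipped parts partition the
  original area exactly (verified in tests by area conservation).

Edge tiles are padded to s × s with a constant background value; the
alternative (discarding partial tiles) would lose annotated roots near the
scan border. Tile outputs are named `<stem>_r<row>_c<col>`. Unknown JSON
fields are passed through untouched and key order is preserved, so a
read–write round trip changes nothing but float formatting.

## Largest-connected-domain selection

Each predicted instance mask is reduced to one connected component.
Default criterion is **area** (foreground pixel count), which directly
encodes the stated goal of keeping the largest connected domain; a
**contour_length** criterion (boundary pixel count) is retained because a
per-contour point-count comparison is what the original selection loop
computes, and the two can disagree (a long thin fragment can out-score a
compact blob on boundary length). Connectivity defaults to 8 so thin
diagonal roots stay connected. Ties break deterministically toward the
component whose first pixel comes earliest in row-major order. Empty masks
are reported (and dropped by the batch wrapper) rather than crashing a run.

## Skeletonization

**Thinning.** The default method is K3M: per iteration, border pixels are
marked via a 3×3 neighbourhood weight lookup (weights 1,2,4,…,128 clockwise
from north), then five sequential phases delete marked pixels with 3, 3–4,
3–5, 3–6 and 3–7 "sticking" neighbours according to per-phase lookup sets;
iterations repeat to a fixpoint. A final pass sequentially deletes
remaining 8-simple pixels (Hilditch crossing number 1) that have at least
two neighbours, leaving a strictly unit-width, 8-connected skeleton with
the same component and hole structure as the input — endpoints are never
eaten. The same final pass backs the `fallback` method (scikit-image
thinning), which serves as an independent cross-check in the tests. All
scans are row-major, so results are bit-stable.

**Spur pruning.** "Noise reduction" is implemented as iterative spur
pruning: any branch running from an endpoint to a junction in fewer than
`min_branch_px` pixels (default 10 px ≈ 0.21 mm at 1200 dpi) is a
candidate; the shortest candidate is removed, junction residue is
dissolved by the unit-width pass, and the scan repeats. Removing one spur
per round keeps the junction classification consistent and makes the
result independent of arbitrary endpoint order. Branches ending at another
endpoint (the main path) are never candidates.

**Polyline ordering.** The skeleton is ordered as the longest geodesic
between two endpoints (Dijkstra with axial weight 1 and diagonal weight
√2); residual side branches are ignored, because downstream fitting treats
each root as a single curve. Corner pixels that a geodesic would cut
diagonally are reinstated so the full curve is traversed. A skeleton with
no endpoints (a closed loop, e.g. from a mask hole) is reported as cyclic;
a single-endpoint skeleton (loop with a tail) falls back to the farthest
reachable node.

## Trait measurement

**Length.** The documented primitive convention is chain-code length
(axial step 1 px, diagonal step √2 px). That estimator is exact on axial
and diagonal lines but biased up to ~8 % high for intermediate
orientations, so the pipeline default resamples the polyline every 7 px
and sums chords, which is unbiased to O((K·s)²) and exact on straight
lines. Root length is reported **tip-to-tip**: the polyline length plus
the Euclidean distance transform (EDT) value at each skeleton tip, minus
1 px. On the axial ridge a thinning algorithm leaves inside a rounded root
end, the EDT equals the remaining distance to the tip, so this correction
is insensitive to how far thinning retracted or overshot the tip.

**Diameter.** Local diameter at a skeleton pixel is `2·EDT − 1` px
(pixel-centre convention: a width-1 line measures exactly 1 px). The
average/max/min statistics run over the polyline with its tip regions
trimmed back to the point of locally maximal inscribed-disk radius;
without the trim, the declining EDT inside the rounded ends biases the
average low and drives the minimum toward d/2. These traits are
re-implementations of the usual skeleton-based measurements, not bit-exact
emulations of any particular GUI tool.

**Areas.** Projected area is the foreground pixel count × `mm_per_px²`;
cylindrical surface models the root as a cylinder of the average diameter,
`π · d̄ · L`. Both are reported since conventions differ between tools.

**Curvature.** The polyline is rotated about its centroid so its principal
axis is horizontal (keeping y(x) single-valued for near-vertical roots;
the angle is recorded in the fit), then least-squares fitted with
`y = a x² + b x + c`. Curvature follows the standard plane-curve formula
`K = |y''| / (1 + y'²)^{3/2}` with `y' = 2ax + b`, `y'' = 2a`, and
`ρ = 1/K`. One summary value is reported per root; the default evaluation
point is the **arc-length midpoint** (the rotated x of the polyline's
middle point) — for asymmetric segments this, not the x-domain midpoint,
corresponds to a well-defined point on the curve. `vertex` (K = |2a|) and
`mean_abs` (the closed-form domain mean of |K|,
`[t/√(1+t²)]` evaluated at the domain ends over the domain width, with
`t = y'`) are selectable. Straight roots (a = 0) report K = 0 with an
infinite radius and a `straight` flag rather than an error. The −ln K
transform (natural log by default; base selectable) maps the small
curvatures of long roots onto a convenient trend scale: K falling ⇒
−ln K rising. K is rotation- and translation-invariant by construction
(tested to 1e−6 relative under random rigid motions).

Model validity: a single quadratic represents bends up to roughly a
subtended angle of ~45°; beyond that the fit underestimates curvature.
This bounds the conditions under which pointwise curvature recovery is
asserted (below).

## Architecture accounting

`netarch` counts without instantiating networks. Conventions (validated by
reproducing the published per-variant table exactly for n/s/m/l/x):

- **Layers** enumerate the flattened module tree — every container and leaf
  once, a single shared activation instance once per model, plus the two
  top-level containers.
- **Parameters** sum conv kernels, biases where present, batch-norm
  affine pairs, and the 16 fixed weights of the distribution-focal
  decoding conv (gradient-free, hence gradients = parameters − 16).
- **FLOPs** are twice the multiply-accumulate count at a recorded input
  size (640 × 640 default): convolutions count
  `out_elements · (c_in/groups · k² + bias)`, batch norm counts 4 × numel,
  and pooling / nearest upsampling / concatenation / activations count 0.
  Conv FLOPs scale exactly quadratically with input size.

Class count is 2 (primary root, lateral root); this, not the 80-class
configuration, reproduces the published per-variant numbers.

**Improved variant.** The improved n model extends the backbone past the
SPPF block with two stride-2 stages (Conv + C2f each) to stride 128 and
runs a full top-down/bottom-up fusion neck over five pyramid levels, with
detect/segment heads at strides 8–128. The widths and repeats of the two
added stages and their fusion blocks are not derivable from the family's
scaling rules; they are fixed constants of this module (stage widths 352
and 160, fusion width 256, two bottleneck repeats in the two top-down
fusion blocks feeding the new levels), chosen so the flattened layer count
(431) is reproduced exactly and parameters/FLOPs agree with the published
accounting to 0.1 % / 0.7 % (10.46 M vs 10.45 M; 13.7 G vs 13.8 G). No
configuration in the natural design family reproduces both printed values
at full precision, so the residual is reported rather than hidden.

**Training-target filter.** Ground-truth boxes with non-positive width or
height are always excluded; the historical aspect-ratio limit
(max(w/h, h/w) < 100) is optional and off by default, so elongated root
boxes remain available for training. Training itself, inference, and
detection-quality metrics are out of scope — they require the original
annotated scans and GPU training.

## Synthetic generator

The generator's purpose is geometric ground truth, not photorealism: soil
is a speckle background, roots are parametric medial curves (straight,
circular arc — curvature exactly 1/R — or quadratic) dilated by stamping
disks of the local radius every quarter pixel. `length_mm` means tip-to-tip
visible length: the medial curve spans `length − diameter` and rounded caps
complete it, so mask area ≈ L·d. The stamping radius is d/2 + 0.5 px to
compensate the strict-inequality disk rasterization, making the measured
cross-section unbiased. Default scene presets: root lengths 5–16 mm,
diameters 0.4–1.0 mm, a curved/straight pattern mix, optional deliberate
overlaps (overlapping roots keep separate instance masks; the composite
image resolves occlusion in favour of the later-drawn root).

**Growth patterns.** Two presets emulate the observed contrast between
curved- and straight-growing roots. Curved roots start at 3 mm and add
2.5 mm/day (per-root multiplier U(0.75, 1.25)) along an arc whose radius
relaxes from 10 mm by 2 mm/day: the total bend L/R keeps increasing (the
root visibly bends further) while the fitted K = 1/R falls, so −ln K rises
day over day. Straight roots add 0.8 mm/day (multiplier U(0.9, 1.1)) at an
effectively straight 220 mm radius; their measured K sits at or below the
resolution floor, so their −ln K trend is flat/undefined. The wider
multiplier spread gives the curved population its larger length dispersion.
These presets support ordering assertions only (faster, more dispersed,
rising transformed curvature) — no quantitative growth magnitudes are
claimed.

**What passing tests show.** Closed-loop recovery (generator →
largest-component → thinning → traits) is asserted on 50 seeded roots at
1200 dpi: length within 2 %, average diameter within 5 %, curvature within
10 %, using straight roots and constant-curvature arcs with subtended
angle ≤ 0.8 rad — constant-K curves are the only ones for which "the"
curvature of a root is well defined, and the bound keeps the quadratic
model inside its validity domain. Real scans add occlusion, root hairs,
blur and annotation noise that the generator does not emulate; passing
these tests validates the measurement chain, not detector performance on
real imagery.

## Degenerate inputs and determinism

Empty masks, single-pixel skeletons, collinear or identical fit points,
cyclic skeletons and non-binary mask files all raise typed, descriptive
errors; the batch wrapper converts per-instance failures into `failed`
rows and continues. Every pixel iteration is row-major and every random
draw flows from a single integer seed, so identical configuration + seed
yields byte-identical outputs.
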