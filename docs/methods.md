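# Methods

This note records the model underlying `stalkfield`, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where the design was genuinely open.

## Pipeline model and assumptions

The method assumes a plot of young (elongation-stage) maize scanned by
terrestrial LiDAR into a dense, registered point cloud in meters, z up.
Its central premise is that although canopies interleave, each plant's
stalk is laterally isolated at ground level, so a *thin* vertical slice of
the cloud shows stalks as narrow, tall, bottom-rooted bars that can be
detected in 2D and used to anchor a bottom-up 3D region growth.

Stages and their contracts:

1. **Ground filter.** A grid of per-cell minimum elevations (cell 0.25 m)
   approximates the terrain; all points within 0.1 m elevation of their
   cell minimum are removed.  0.25 m is chosen below the 0.5 m row spacing
   so every cell sees true ground between rows; the threshold is read as an
   elevation-only cut (the simplest reading of a "global threshold").
   Out-of-extent points snap to the nearest cell.  The cut necessarily
   removes each plant's lowest centimeters — see "Height bias" below.
2. **Slicing and depth images.** The filtered cloud is rotated about the
   vertical axis through its x–y centroid by k·360°/32, k = 0…31, and tiled
   into windows of 1.024 m × 1.024 m (x, z) by 0.016 m (viewing depth y),
   stride = size (a partition; every point falls in exactly one window per
   direction).  With 0.004 m pixels the field is an exact 256 × 256 raster.
   Pixel intensity encodes the *nearest* point's depth,
   1 − (y_min − y0)/depth, floored at 1/255 so zero means empty; nearest-
   surface encoding keeps a foreground stalk bright against background
   rows.  The 0.016 m test depth is below any within-row plant gap, which
   is what makes stalks appear isolated regardless of planting density.
3. **Stem detection.** The reference backend is deterministic geometry:
   occupied pixels are closed once with a 3 × 3 structuring element
   (surface sampling near the pixel pitch leaves pinhole gaps in a truly
   solid bar; a single closing bridges them without inventing mass beyond
   one pixel), 8-connected into components, and each component is reduced
   to its *column-support core* — the columns holding at least half the
   peak per-column pixel count.  This core step is essential: leaf bases
   are 8-connected to the stalk, and even a one-pixel stub would otherwise
   widen the box and sink the fill score for every true stem.  A core is
   accepted if width ≤ 0.05 m, height ≥ 0.05 m, height/width ≥ 2, and its
   foot lies in the bottom quarter of the image's occupied height;
   confidence = 0.5·min(1, (h/w)/4) + 0.5·(core pixels)/(h·w) ∈ [0, 1], an
   invented but monotone quality score under which clean stalk bars score
   near 1.  An anchor-based learned detector can replace the baseline
   behind the same `detect()` contract; its anchor scheme (areas 1², 7²,
   14², 59² px × ratios 0.13, 0.51, 0.84, 1.3, 8 = 20 anchors per location;
   foreground above 0.7 IoU or max-IoU, background below 0.3, the 0.5 band
   ignored; SGD at lr 0.01, momentum 0.9, weight decay 5e-4, stop when both
   loss terms < 0.01) is implemented, but training requires the optional
   `torch` dependency and raises a capability error without it.
4. **Mapping and fusion.** Detections with confidence strictly above 0.9
   are mapped through their window to the 3D box [x-box] × [y slab] ×
   [z-box]; the world points inside are the stem's seed points.  Across
   directions, seed centroids within 0.1 m in x–y (single-linkage) are one
   maize — 0.1 m is half the within-row spacing, the largest radius that
   cannot merge adjacent plants on the nominal grid.  The best-confidence
   detection is kept per plant; two quantities are pooled over the cluster
   because a single 16 mm slab misreads them: the stalk diameter (median of
   member estimates; a slab through the stalk edge can read 5 mm for a
   25 mm stalk) and the seed point set (union of member points within
   0.05 m of the centroid — the stalk column seen from all directions).
   Without the pooled point set, path distances from a tall plant's top to
   its own low sliver seed occasionally exceed the scaled distance to a
   thicker neighbor, which costs the plant its upper half.
5. **Comparative-shortest-path growth.** Points are joined into a
   symmetric k-nearest-neighbor graph (k = 10, Euclidean weights, edges
   capped at 0.05 m — below the 0.2 m plant spacing so plants cannot
   short-circuit through air).  For each stem, D_v is the multi-source
   Dijkstra distance from its seed set; each point takes the stem
   minimizing DvN = D_v / d^(2/3) (ties to the lowest stem id).  The 2/3
   exponent is fixed by the method but exposed for sensitivity tests; the
   diameter stands in for the trunk DBH of the forestry original (maize
   has no breast-height diameter).  Estimated diameters are floored at
   5 mm to avoid division blow-up.  Unreachable points keep label 0; an
   optional Euclidean fallback can claim them instead (off by default —
   isolated returns are more often noise than plant).
6. **Evaluation and traits.** Predicted and reference plants are matched
   greedily by descending point overlap, one-to-one; a pair is a true
   positive when the overlap covers ≥ 50 % of the reference plant.  r, p
   and F are reported to two decimals (half-up).  The automatic height of
   a plant is the vertical extent (max z − min z) of its segmented points;
   the reference height is the same measure on the labeled points *before*
   the ground cut, mirroring manual practice where the operator keeps the
   stem base.  `plant_height` also offers a ground-model-normalized
   maximum-elevation variant that is insensitive to the basal cut.
   Heights of matched plants are regressed (ordinary least squares,
   auto ~ ref); R² and fit RMSE are reported, with the mean bias
   (auto − ref) kept separate because the cut-induced component is
   systematic.

## Height bias

The 0.1 m ground cut removes each plant's base down to 0.1 m above the
local *furrow* minimum.  Because maize is planted on ridge tops, the cut
into the plant itself is 0.1 m minus the local ridge height — a few
centimeters — so extent-based automatic heights underestimate reference
heights by a small, strictly negative margin (−0.038 m on the default
synthetic sites) that is bounded above by the threshold itself.

## Synthetic fields: what they emulate, and what not

`synth_field` generates labeled clouds matching the published site
layouts.  Presets (plants, grid, area, density, heights):

| preset   | plants | grid    | area m² | plants/m² | heights m   |
|----------|-------:|---------|--------:|----------:|-------------|
| sparse   | 62     | 10 × 23 | 23.0    | 2.70      | 0.13–0.49   |
| moderate | 71     | 7 × 16  | 11.2    | 6.34      | 0.29–0.69   |
| dense    | 88     | 7 × 14  | 9.8     | 8.98      | 0.14–0.73   |
| training | 337    | 20 × 50 | 100.0   | 3.37      | 0.09–0.68   |

Plants occupy a seeded random subset of the 0.5 m × 0.2 m grid with
±15 mm jitter; heights are uniform over the preset range (only min/max
are published).  Each plant is a stalk cylinder to 0.6·height (diameter
uniform 10–30 mm — no published stalk statistics exist, so this is a
visible knob), a near-vertical rolled-whorl leaf tapering from the stalk
top to the full height (the newest leaf of elongation-stage maize points
straight up; it is what keeps the top of even a 0.13 m seedling attached
to a detectable vertical bar), and 5–9 strap leaves on alternating ranks,
modeled as tapered ribbons along quadratic Bézier arcs — the simplest
geometry producing leaf–leaf interleaving between neighbors.  Ground is a
ridge-and-furrow surface (ridges under the rows, amplitude 0.03 m, plus
low-frequency micro-topography), with plants based on ridge tops.  The
ridge scale matters doubly: it keeps furrow-referenced cell minima low
enough that the 0.1 m cut leaves short plants detectable, and it makes the
cut-induced height underestimation land in the few-centimeter range rather
than at the full threshold.

Sampling: surfaces at 5 mm target spacing (ground 15 mm), Gaussian noise
of 2 mm per coordinate, 15 % uniform dropout standing in for occlusion.
These are the package's desk-scale choices; a full-resolution TLS scan is
denser.  Not emulated: ray-cast occlusion and shadowing, beam divergence
and footprint, intensity/reflectance, registration artifacts, senescent or
broken leaves, weeds.  Passing tests on these synthetics therefore
demonstrate the pipeline's geometric correctness and its behavior under
the published field layouts — not robustness to every artifact of real
scans, where the learned detector backend is the intended upgrade path.

## Numerical choices

- Depth-image occupancy floors intensity at 1/255 so "occupied" survives
  8-bit export; rasterization is permutation-invariant (per-pixel minimum).
- Windows at the far boundary include points exactly on the top edge, so
  slicing is an exact partition.
- Coincident points get a 1e-12 m edge weight floor in the graph.
- Fusion tie-breaks: confidence, then seed size, then direction index,
  then centroid; output sorted by centroid — the stage is deterministic
  and permutation-invariant.
- LAS I/O uses a 1e-6 m coordinate scale (auto-coarsened only if an extent
  would overflow int32), preserving the 1 µm round-trip contract; labels
  ride in `point_source_id` (PLY: an extra `plant_label` property; XYZ: a
  4th column).
- `prf` rounds half-up to 2 decimals, matching printed report precision;
  F is computed from unrounded r and p.
- Windows with fewer than 10 points are skipped during detection: a
  detectable bar needs ≥ 13 rows at ≥ 80 % fill, so nothing reachable by
  the confidence gate is lost.

## Known limitations

- The geometric baseline assumes near-vertical stalks; lodged plants or
  strongly leaning stems would need the learned backend.
- A leaf hanging vertically in an otherwise empty window can in principle
  pass the geometric filters and seed a false plant; the bottom-quarter
  rule suppresses this only when real stems share the window.
- Plants whose every point lies within the ground threshold (height
  < ~0.13 m on flat ground) vanish before detection and cannot be
  recovered; they are also absent from the evaluation reference.
- Single-linkage fusion could chain across plants if stems were closer
  than 0.1 m; the nominal grid prevents this, irregular planting may not.
- `transport_distances` materializes an (n_seeds × n_points) matrix;
  `segment` avoids this by folding per-seed rows into running minima, but
  very large clouds still pay one Dijkstra per seed.
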