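# stalkfield

Individual maize segmentation from terrestrial LiDAR (TLS) point clouds.

Plot-scale TLS captures a young maize field as millions of unlabeled 3D
points.  Extracting per-plant traits (height above all) requires assigning
every point to an individual plant, which is hard because neighboring
canopies interleave while the one reliably isolated organ — the stalk — is
short and thin.  `stalkfield` implements a detect-then-grow pipeline for
this problem, aimed at field-phenotyping researchers:

1. **Ground filtering** — per 0.25 m cell, the lowest elevation is recorded
   and every point within a global 0.1 m threshold of its cell minimum is
   removed.
2. **Multi-directional slicing** — the cloud is viewed from 32 azimuths
   (360°/32 apart) and tiled into 3D windows of 1.024 m × 1.024 m field and
   0.016 m depth; each window is compressed into a 256 × 256 depth image
   (0.004 m pixels, nearest surface brightest).
3. **Stem detection** — stalks appear on these thin slices as narrow,
   tall, bottom-rooted bars.  The default backend is a deterministic
   geometric detector (connected components filtered by width ≤ 0.05 m,
   height ≥ 0.05 m, aspect ≥ 2, foot in the bottom quarter of the occupied
   height, scored by elongation and fill).  The anchor-based learned
   detector contract (20 anchors/location = 4 areas × 5 ratios, 0.7/0.3
   foreground/background IoU gates) is provided for drop-in use; training
   it requires the optional `torch` dependency.
4. **2D→3D mapping and fusion** — detections with confidence > 0.9 are
   mapped back through their slice window to 3D *seed points*; across the
   32 directions, seeds within 0.1 m (x–y) are the same plant and the
   best-confidence detection is kept.
5. **Region growing** — every remaining point joins the stem minimizing the
   diameter-scaled graph distance

   DvN = D_v / d^(2/3),

   where D_v is the multi-source shortest-path distance along a k-nearest-
   neighbor graph (k = 10, edges capped at 0.05 m) and d is the estimated
   stalk diameter — so thicker stalks reach further, growing each plant
   from the bottom up.
6. **Evaluation** — predicted plants are matched to reference labels
   (greedy by overlap, ≥ 50 % coverage ⇒ true positive), giving
   r = TP/(TP+FN), p = TP/(TP+FP), F = 2rp/(r+p), plus a least-squares
   regression of automatic on reference plant heights (R², RMSE, bias).

Because no public TLS maize dataset accompanies the method, the package
ships a first-class synthetic-field generator (`stalkfield.synth_field`)
that reproduces the published site layouts: 0.5 m × 0.2 m planting grid,
site presets with 62/71/88/337 plants at 2.69–8.96 plants/m², plant heights
0.09–0.73 m, ridged ground with micro-topography, and elongation-stage
plant morphology (stalk + vertical whorl leaf + arcing strap leaves).

## Worked example

```python
from stalkfield import FieldSpec, PipelineConfig, generate_field, run_pipeline

cloud, truths = generate_field(FieldSpec.preset("sparse", rng_seed=1))
seg, report, _ = run_pipeline(cloud, PipelineConfig())
print(len(seg.seeds), report.counts)
print(report.r, report.p, report.f)
print(round(report.r2, 3), round(report.rmse, 3), round(report.mean_bias, 3))
```

prints

```
62 ConfusionCounts(tp=62, fp=0, fn=0)
1.0 1.0 1.0
0.999 0.003 -0.038
```

All 62 plants of the sparse site (2.69 plants/m², heights 0.13–0.49 m) are
detected and recovered (recall, precision and F-score 1.00); automatic
heights track the reference heights with R² = 0.999 and RMSE 3 mm, and sit
38 mm *below* them on average — the systematic underestimation induced by
the 0.1 m ground cut, which removes each plant's lowest few centimeters.

The same flow from a shell:

```
stalkfield simulate --preset sparse --seed 1 --out field.ply --truth truth.csv
stalkfield run --in field.ply --out results/
```

Other subcommands (`convert`, `ground`, `trainset`, `detect`, `fuse`,
`segment`, `evaluate`) expose the individual stages; see
`stalkfield --help` and `docs/methods.md` for the model details and
parameter rationale.

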