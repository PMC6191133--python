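# Methods

## Problem and model

A hive-frame photograph contains a hexagonal lattice of comb cells.
Capped brood and capped honey form contiguous textured patches; uncapped
cells appear as dark circular lumens surrounded by bright wax walls.
Because only the uncapped class has reliable, camera-independent
contrast, the pipeline detects uncapped cells automatically and leaves
the brood/honey distinction to the operator, who draws wide polygons
around capped regions and marks the four inner-frame corners. The capped
area of a polygon is its shoelace area minus one disc per detected
uncapped centre inside it, clamped at zero:

```
capped = max(0, area(P) − n_inside · π · r_eff²),
r_eff  = CELL_INFLATE · RADIUS_FRACTION · median_NN_spacing
```

## Detection

Detection runs on the CIELAB L* channel (sRGB, D65; L* in [0, 100]).
The gradient variant of the circular Hough transform is implemented
directly on numpy/scipy/scikit-image primitives:

1. L* is rescaled to the 8-bit range so gradient thresholds keep their
   conventional meaning; Canny edges are extracted with hysteresis
   thresholds (edge_threshold / 2, edge_threshold).
2. Every edge pixel votes into a full-resolution centre accumulator
   along its (smoothed Sobel) gradient direction, both ways, at 1 px
   radius steps over [min_radius, max_radius].
3. Local accumulator maxima with at least `accumulator_threshold` votes
   are accepted greedily, strongest first, subject to a minimum
   centre-to-centre distance; ties break in raster order so detection
   is fully deterministic. Accepted peaks are refined to sub-pixel
   positions by the vote-weighted centroid of the 3×3 accumulator
   neighbourhood, which removes most of the integer-bin quantisation
   error in centre estimates.
4. Each circle's radius is the modal distance from its centre to the
   nearby edge pixels.

### Parameters

| symbol | meaning | default |
|---|---|---|
| `EDGE_THRESHOLD` | Canny high threshold, 8-bit gradient units | 200 |
| `ACC_THRESHOLD` | minimum centre votes (sensitivity) | 20 |
| `THRESHOLD_INC` | sensitivity adjustment step | 2 |
| `CELL_INFLATE` | inflation factor on the subtraction radius | 1.0 |
| `RADIUS_FRACTION` | spacing → base-radius factor | 0.5 |
| `EXPECTED_PITCH` | pitch prior, px | image width / 80 |
| `MIN_RADIUS`, `MAX_RADIUS` | candidate radius bounds, px | 0.25 / 0.75 × pitch |
| `MIN_DIST` | minimum centre separation, px | 0.6 × pitch |

The operator loop is: run detection, inspect, lower or raise the
sensitivity by `THRESHOLD_INC` (lower threshold ⇒ more detections),
repeat. `step_sensitivity` implements one such step and clamps the
threshold at 1 with a warning.

On a hexagonal lattice the nearest-neighbour spacing of cell centres is
the *pitch*, i.e. one full cell diameter. Using it directly as a
subtraction radius would make each disc cover ~3.6 cells' worth of
area, so the default `RADIUS_FRACTION = 0.5` converts spacing to a
radius; setting it to 1.0 restores the raw-spacing-as-radius reading.
Both the fraction and `CELL_INFLATE` are exposed independently, and the
practical calibration is to choose `CELL_INFLATE` so that one
subtracted disc matches the true lumen footprint of the local comb
(for a known lumen radius ρ and pitch p: `CELL_INFLATE = ρ / (p/2)`).

## Quantification choices

- Disc membership is by centre only; discs are not clipped at polygon
  borders. This keeps the subtraction closed-form at the cost of a
  small bias for uncapped cells straddling a region edge.
- Over-subtraction clamps at zero and logs the raw value rather than
  raising: a clamp signals either mis-calibrated inflation or an
  annotation that is almost entirely uncapped.
- Physical scaling uses the area ratio to the inner-frame
  quadrilateral; the photograph is assumed perpendicular to the lens,
  so no homography rectification is applied (a documented extension
  point). The physical inner-frame area (e.g. 880 cm² in the examples)
  is a required input, not a built-in constant.
- Polygons with the same label are summed (with per-polygon clamping);
  overlapping polygons of *different* labels are accepted but warned
  about, since the overlap is double-counted.

## Statistics

`exact_signed_rank_test` implements the paired Wilcoxon signed-rank
test in its exact small-sample form: zero differences are dropped,
absolute differences are ranked with midranks for ties, V is the sum of
ranks of positive differences, and the null distribution is built by
enumerating all 2ⁿ sign assignments of the realised rank multiset
(n ≤ 25). The one-sided p is the smaller inclusive tail; the two-sided
p doubles it, capped at 1. For six pairs all shifted the same way this
gives V = 21 and p = 2/64 = 0.03125 — the regime where a normal
approximation would be meaningless.

The two frame-mass estimators are linear maps from measured surfaces to
grams; their constants (honey g/cm², brood g/cm², empty drawn-frame g)
are per-apiary reference values the user must supply.
`agreement_report` summarises between-method agreement with the Pearson
product-moment r and its t-transform p-value.

## Synthetic scenes

The generator emulates what the detector must tolerate in field photos:
a flat-top hexagonal lattice (row offset pitch/2, row spacing
pitch·√3/2, so every nearest-neighbour distance equals the pitch),
dark lumens (L* 20) with bright walls (L* 70), capped regions filled
with low-pass Gaussian texture (mean L* 55, sd 6), a linear
illumination gradient (10 L* peak-to-peak) and pixel noise (sd 2.5 L*).
Per-cell centre jitter (sd 0.35 px, ~2% of the 18 px pitch) models the
regularity of natural comb. A single `default_rng(seed)` stream drives
jitter, texture and noise, so a seed reproduces the raster bit for bit.
Greyscale rendering is replicated into three sRGB channels through the
exact inverse of the neutral-grey L* mapping; colour realism is out of
scope because detection consumes only L*.

The canonical test scene is 1200 × 800 px at pitch 18: a brood slab
with an emerged (uncapped) band inside it, a honey block with an
uncapped patch, and a free uncapped band (~795 uncapped cells). This
size keeps a full generate–detect–quantify pass at ~1.5 s, so the whole
suite runs in well under a minute while still exercising ~800-cell
statistics.

What the generator does *not* emulate: perspective distortion, bees and
debris occluding cells, specular flash highlights, partially-capped
cells, pollen, and comb-wall irregularity beyond Gaussian jitter.
Passing tests therefore demonstrate the correctness of the machinery
and its noise/lighting tolerance, not field-grade robustness on
arbitrary photographs — on real data the operator's sensitivity loop
and inflation calibration remain essential.

## Numerical notes and known limitations

- The median nearest-neighbour spacing is a *minimum* over ~6
  neighbours and is therefore biased low under centre jitter: at jitter
  sd 1 px on an 18 px lattice the median drops ~9% below the pitch even
  for perfectly localised centres; at the realistic 0.35 px default the
  total bias (jitter + residual localisation error) stays near −3%.
  Since the effective radius is calibrated through `CELL_INFLATE`, this
  bias folds into the operator's calibration rather than the final
  areas.
- Spacing and the effective radius are recomputed on every detection
  pass (not frozen after the first), so sensitivity adjustments always
  see a consistent radius.
- With fewer than two detections the spacing and effective radius are
  reported as unavailable (`None`) and nothing is subtracted; this is a
  flagged condition, not an error.
- Detection contains no randomness; all stochastic behaviour lives in
  the scene generator behind an explicit seed.
- The exact signed-rank enumeration is capped at n = 25 (2²⁵ sign
  vectors); larger samples need the standard large-sample test, which
  is out of scope here.
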