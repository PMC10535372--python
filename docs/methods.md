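# Methods

## Problem setting

A rhino-laryngoscope placed in front of the epiglottis during drug-induced
sleep endoscopy records the airway opening behind the epiglottic
cartilage.  When the epiglottis collapses toward the posterior pharyngeal
wall, that opening — the airway field of view (AE-region) — shrinks; its
pixel area ω = |A| is the airflow-path proxy.  The pipeline converts a
frame sequence plus per-frame epiglottis bounding boxes into a per-frame
obstruction-ratio series O ∈ [0, 100] % at 0.1% granularity.

The detector is a pluggable interface (a text file of boxes): any trained
localizer, manual annotation, or the synthetic ground truth can supply it.
Training or running a neural detector is out of scope here.

## Color quantization

Median cut, generalized to arbitrary palette sizes rather than powers of
two: repeatedly split the box with the largest single-channel range at the
pixel-count median along that channel, until `q` boxes exist or no box
spans more than one value.  Each pixel maps to the rounded mean color of
its box.  Determinism is pinned down by explicit tie-breaks: box selection
ties go to the larger pixel count, then the lower box position; channel
ties to the lower channel index.  These conventions are design choices —
the classic algorithm does not prescribe them — and the independent oracle
in the test suite implements the same stated rules from scratch.

Quantization operates on the unique-color histogram (counts as weights),
which is mathematically identical to operating on the raw pixel list and
keeps 640×480 frames fast even under sensor noise.

Regions are 8-connected components of equal palette index; boundary edges
use the 4-neighbor criterion (a set pixel with any 4-neighbor outside the
mask, the raster border counting as outside).  This standard pairing keeps
region outlines closed.

## Region-puzzle merging

Both anatomical regions are grown by the same committed merge loop, seeded
differently:

* **EP-region**: brightest region (max R+G+B of the palette color) in a
  `u×u` window at the detector-box center; only regions lying fully inside
  the box are admissible; weight ≡ 0.  If the seed itself spills outside
  the box it is returned alone as the EP-region.
  Default `u = round(H_B/2)`, floored at 8 px (the box height `H_B`
  bounds the sensible range `H_B/4 … H_B/2`).
* **AE-region**: darkest admissible region in an `h×h` window centered at
  `(x_ρ, Y_e/2)`, where ρ is the EP-region's lowest pixel (maximum row,
  ties to the smallest column) and `Y_e` the top edge of the EP-region in
  ρ's column.  Admissible regions lie entirely above the top edge
  (max row ≤ Y_e).  Default `h = max(4, round(Y_e/4))`.  The weight
  `w_j = ȳ_j − Y_e/2` (region centroid row) makes pieces nearer the
  epiglottis easier to merge.  No admissible seed means the airway is
  completely obstructed in that frame: ω = 0, a valid outcome.

Loop semantics, per iteration: (1) a target completely surrounded by a
single admissible region absorbs it directly; (2) every admissible
4-neighbor `R_j` is scored `P_j = |edge(R_j ∪ T)| − w_j` and all `R_j`
with `P_j ≤ P = |edge(T)|` are merged in one sweep (descending shared
border, ties by id), holes filled; (3) the sweep is kept only if the new
edge count strictly decreased, otherwise the algorithm stops with the
previous target.  Iterations are bounded by the region count.

The candidate edge is computed exactly on the union mask.  The jigsaw
intuition — a merge is good when it smooths the outline — is often phrased
as an XOR of the two edge sets; on inter-pixel (crack) boundaries the two
are identical, on pixel edges XOR is only an approximation, so the union
edge is used.  A standalone `puzzle_candidate` helper exposes the literal
set-XOR form for auditing.

Two readings of the weight are defensible (`ȳ_j − Y_e/2` vs
`(ȳ_j − Y_e)/2`; centroid row vs topmost row); both preserve the intended
monotonicity.  The literal centroid form is the default and the
alternatives are switchable via `RPAConfig`.

## Periods, anomalies, ratios

Periods are maximal runs of frames with a detected epiglottis; a frame
without a detection ends the period (scope slip), and re-detection starts
the next.  Within a period the endoscope is assumed stationary, so the
period's maximum airway area is the unobstructed reference.

Post-processing order: operator-marked interference intervals are excluded
first, then the neighbor rule (a frame with ω > 0 whose two neighbors both
saw no epiglottis or complete obstruction is abnormal; sequence endpoints
use their single neighbor), then the backward-difference rule (frame n is
abnormal when ω′_n and ω′_{n+1} sign-alternate and both exceed ε; default
ε = 30 000 px for 640×480 frames).  Only then is each period's maximum
taken — over frames neither abnormal nor excluded — and the ratio computed
as `O = 100·(max − ω)/max`, rounded half-up to one decimal.  Complete
obstruction reports O = 100.0; abnormal, excluded and no-epiglottis frames
carry no ratio; a period whose maximum is zero yields no ratios and a
warning.  The spike rule may fire on a one-frame complete-obstruction dip
surrounded by open-airway frames; such a frame is treated as abnormal (no
ratio) rather than O = 100, since a physical collapse-and-release inside
1/15 s is implausible relative to a segmentation dropout.

The triple-pattern phrasing of the spike rule is ambiguous in places; the
single-frame sign-alternating reading is implemented, and the raw ω′
series is exported (`diffs.csv`) so alternative rules can be audited.

The legacy three-degree bands (0–49 / 50–75 / 76–100%) are kept only as a
reporting annotation for comparison tables.

## Synthetic phantoms

The generator emulates the structure of a DISE frame, not its photometry:
a mid-tone pharyngeal wall with endoscope vignetting and smooth mucosal
mottling, a bright convex epiglottis ellipse in the lower half, and a dark
airway blob above the epiglottis top edge with lumen depth shading.  The
blob is rendered by taking exactly the scheduled number of pixels in
increasing elliptical-norm order, so the ground-truth area is exact by
construction.  The area schedule composes a baseline (default 18 000 px at
640×480), sinusoidal breathing (±15% over 60 frames ≈ 2 s at 30 fps),
and occlusion episodes with a given depth; scope-slip intervals shift the
scene and remove the epiglottis.  Sensor noise is Gaussian, σ = 4 gray
levels by default — mild enough to survive q = 6 quantization, as real
capture noise does.  Everything is deterministic for a fixed seed, and
ground truth (boxes, masks as run-length encodings, areas, periods, true
ratio schedule) serializes to JSON.

What passing on phantoms does and does not show: recovery is demonstrated
for single-connected-lumen scenes with clean color separation between
lumen, cartilage and wall.  Real frames add specular reflections, folds,
vocal-cord structure and tonsil intrusions; on such content the merge loop
faces admissible-but-wrong pieces that the phantom cannot produce.  In
particular, the known sensitivity of real AE-region curves to large
quantization numbers (fragmented, erratic areas at q ≥ 9) does not emerge
on contract phantoms — fragmented lumen pieces are concentric or
cavity-filling and are healed by the direct-merge and outline-smoothing
rules — so the q-sweep test asserts q-stability on contract scenes rather
than the erraticness ordering seen on clinical material.  The multi-lobe
airway option is an out-of-contract stress scene.

## Numerical and interface choices

* Rounding of ratios and averages is decimal half-up to one decimal,
  matching a 0.1% reporting precision.
* Pixels equidistant between palette representatives cannot occur (box
  membership, not nearest-color, assigns pixels), so assignment is always
  unambiguous.
* Seed windows clip at raster borders; a window with no admissible region
  pixels yields the no-seed outcome (an error for the EP stage, complete
  obstruction for the AE stage).
* `Y_e < 4` leaves no room for an airway window and reports ω = 0.
* Detection files: `frame x y w h conf` (1-based frames, 0-based integer
  pixels, confidence to 4 decimals); the normalized center dialect is
  converted on load.  Default confidence threshold 0.25; ties broken by
  larger box area.
* Frame input: a directory of numbered PNG/JPEG frames is the first-class
  path; video containers are handed to imageio when a backend is present.
* Desk-scale problem sizes in the test suite: recovery runs on a 100-frame
  noise-free 640×480 phantom; merge-oracle equivalence on 200 random
  16×16 maps with ≤ 6 regions; anomaly calibration on 1000 randomized
  traces; smaller rasters (≈ 200×160) stand in where noise makes full
  frames expensive.

## Known limitations

* Only the epiglottic site is quantified; other obstruction levels
  (velum, oropharynx, tongue base) need their own anchors.
* Tonsil interference must be marked by the operator; it is not detected.
* The reference maximum is retrospective over the whole period, so ratios
  early in a period depend on later frames.
* Box-center seeding assumes the detector box is roughly centered on the
  cartilage; grossly wrong boxes produce wrong seeds, not errors.
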