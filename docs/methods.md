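# Methods

This note documents the models, conventions and numerical choices
behind `mielapse`, and what the synthetic benchmarks do and do not
establish.

## Motion-informed enhancement

Time-lapse recording (one frame every 30 s) is too sparse for optical
flow or video background models, but with a stationary camera the
background is nearly constant between neighbouring frames. The
enhancement therefore uses pure three-frame differencing. Each frame
is converted to grayscale with BT.601 luma weights (0.299, 0.587,
0.114) and blurred with a 5 × 5 Gaussian; the motion likelihood of the
centre frame is the sum of absolute differences to its two neighbours,
clamped to [0, 255] on export. The enhanced image keeps the original
green channel bitwise (vegetation appearance), averages the original
red and blue channels into the blue channel (flower hues remain
distinguishable), and writes the motion likelihood into the red
channel. Identities the implementation maintains and the tests assert:
a static triple produces an all-zero red channel; the map is invariant
to time reversal of the triple; the blue mix is symmetric under
swapping the input red and blue channels; the un-clamped likelihood is
bounded by 510.

Choices left open by the construction, and how they were fixed:

* **Grayscale convention** — BT.601 luma, the dominant toolkit default,
  so externally produced detections remain comparable.
* **Gaussian σ** — 1.1 for the 5 × 5 kernel, the standard
  kernel-size-derived value 0.3·((k−1)/2 − 1) + 0.8; configurable.
* **Order of operations** — grayscale then blur (one-channel blur; for
  these linear operations the order only matters at rounding level).
* **Borders** — reflective padding, so frame edges do not register as
  motion.
* **Rounding** — all arithmetic in floating point with a single
  round-half-away-from-zero at the final 8-bit export, avoiding
  double-rounding drift.
* **Values above 255** — clamped, not rescaled: the output must remain
  a standard 8-bit RGB image, and a clamp preserves the meaning of
  mid-range intensities.
* **Run boundaries** — triples are formed only inside consecutive runs
  (successive timestamps ≤ 90 s apart by default, three nominal
  intervals); the first/last frame of a run either produces no output
  ("skip", the default) or is enhanced against a duplicated terminal
  frame ("pad", making the missing-side difference zero).

## Baseline blob detector

The package's detector stage is pluggable; CNN detectors are consumed
through a CSV adapter. The built-in baseline is a deliberately simple
classical detector over the enhanced red channel only: binarise at an
intensity threshold (default 130), optionally open with a small disk,
label 8-connected components (8-connectivity keeps thin diagonal blobs
whole), keep components with area in [4, 5000] px, and report each
component's bounding box with confidence = mean motion intensity / 255
(giving ranking-based metrics something meaningful to rank). Output
order is deterministic (ymin, then xmin). Because it sees only the
motion channel, the baseline is also the instrument for measuring what
the motion channel alone contributes (see the control below).

The default threshold sits between the single-difference response of a
"ghost" (the insect's position in a neighbouring frame, amplitude ≈ the
insect–background luma contrast) and the double response at the true
position (≈ twice that contrast), which is what makes a plain
threshold usable at all in this regime.

## Evaluation protocol

Matching is per frame, greedy in descending confidence (ties by ymin,
then xmin), one-to-one, and accepts a pair only when IoU is strictly
greater than the threshold; the default threshold is 0.25 because tiny
boxes make annotation geometry uncertain. Greedy matching is the
de-facto standard of detection benchmarks; on adversarial geometries
it can undercount true positives relative to the optimal assignment,
and the tests assert exactly that one-sided bound (greedy TP ≤
exhaustive optimum) on small random instances. Precision, recall and
F1 use the convention that a metric with zero denominator is 0, which
keeps macro averages total over insect-free sites. Macro averages are
unweighted means of per-site metrics; micro averages recompute the
metrics from pooled TP/FP/FN. Average precision integrates the
precision–recall curve under all-point (monotone-envelope)
interpolation. Boxes are 0-based half-open pixel rectangles
throughout; YOLO-normalised labels convert by rounding each corner
symmetrically, which bounds the round-trip error at one pixel per
edge.

Frames dropped by the "skip" endpoint policy have no enhanced image
and are excluded from evaluation of the baseline; with 200-frame runs
this affects at most two frames per site.

## Two-minute duplicate filter

Detections are scanned in time order per camera; one is suppressed iff
a previously *retained* detection within the preceding 120 s (inclusive)
has a box centre within 25 px (a full-HD default; scale by image
width). Anchoring the window on retained detections means a
continuously present object re-enters the count once per window — the
worked chain of 11 same-position detections at 30 s spacing retains
exactly those at 0 s, 150 s and 300 s. The filter is idempotent. Its
suppression is monotone in the window and distance parameters when
detection positions are either coincident up to jitter (the duplicate
chains it targets) or mutually separated by more than twice the
tolerance; for arbitrary scattered geometry monotonicity can fail —
removing an early anchor can free later detections — which is a known
property of anchor-based suppression, not an implementation artifact.

## Synthetic scenes

The generator emulates the structure of greenhouse pollinator
recordings: a static green-dominant texture (smoothed Gaussian noise
around RGB (70, 160, 60)) with elliptical pink/orange/red flowers;
dark insect ellipses (default RGB (25, 20, 15), 6–20 px across at the
default quarter-scale 480 × 270 resolution) performing seeded random
walks with 15–40 px steps and a configurable per-frame visibility
probability; timestamps at 30 s intervals. Two nuisance factors of
real recordings are modelled: a global per-frame brightness jitter
(automatic exposure, default σ = 2 %) and a ±1 px rigid sway of the
flower layer (wind). Multi-site benchmarks draw per-site insect
prevalence uniformly from 1–15 % of frames, spanning the range
observed across real camera sites, with independent child seeds per
site. Every painted insect pixel lies inside its annotation box, and
all outputs are pure functions of configuration and seed.

Quarter-scale frames keep a full 7-site × 200-frame benchmark at
roughly a minute of CPU while preserving the small-object regime; the
acceptance script and tests use those sizes.

What passing on these scenes shows: the pipeline's plumbing,
geometry, matching and aggregation are correct, and the motion channel
carries recoverable signal exactly where colour does not. What it does
not show: performance on real imagery — real scenes have plant growth,
focus drift, occlusion, specular highlights and non-rigid motion that
the generator deliberately omits, and a thresholded blob detector is
not a stand-in for a trained CNN's absolute scores.

## Controls and headline comparison

The motion-free control replaces the red channel with the centre
frame's own luma (green/blue mappings unchanged). With insect colour
drawn near the vegetation's luma distribution, the blob detector on
control frames sees no separable signal (the whole scene exceeds any
usable threshold and is rejected by the area band), while on
motion-enhanced frames it still recovers a large fraction of insects —
the package-level analogue of motion enhancement improving detection,
asserted as a strict micro-F1 inequality rather than any absolute
value.

## Published-table reproductions

Aggregation arithmetic is checked against the published site-level
summaries of the public benchmark (embedded in
`mielapse.benchmark_data`): macro rows recomputed from the per-site
motion-image metrics, bookkeeping totals (6356 insects in 102,649
images, 6.2 % ratio; 2814/2525 training-source counts; 3067/4729/2461
final-split totals), and the 2160 frames/day capture capacity. The
published macro rows are means of unrounded per-site values, so
recomputing them from the 3-decimal printed rows carries up to half a
final-digit unit of quantisation; comparisons use a 1e-3 tolerance
accordingly.

## Known limitations

* The blob baseline has no learned appearance model; its absolute
  scores are meaningful only on the synthetic scenes.
* Greedy confidence-order matching can differ from optimal assignment
  in dense clusters of boxes.
* The duplicate filter cannot distinguish a persistent false positive
  from a genuinely stationary insect; both are counted once per window.
* EXIF metadata, video input and multi-class taxonomies are out of
  scope; timestamps come from filename patterns.
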