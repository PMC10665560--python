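# Methods

This note documents the models and procedures implemented in `spinetrack`,
the parameters that matter, the numerical choices at the edges, and what the
synthetic-data experiments do and do not demonstrate.

## Coordinates and types

Boxes are axis-aligned rectangles in continuous pixel coordinates, origin at
the image's top-left, x rightward, y downward, with half-open semantics:
`area = (x_max − x_min)·(y_max − y_min)` and no ±1 pixel adjustments anywhere.
This makes every overlap quantity exact arithmetic. Slice indices are
0-based. A 3D spine track is an inclusive z-interval `[z1, z2]` with one box
per covered slice, a coordinate-wise mean box, and an aggregate confidence.

## Overlap metrics

* `iou_2d` — intersection over union.
* `iom_xy_2d` — intersection over the *smaller* area. Symmetric, always
  ≥ IoU, equal to 1 whenever one box contains the other. This tolerance to
  tight-but-offset boxes is why it is the pipeline's primary 2D score; its
  known failure mode (a huge box swallowing a small ground truth scores 1) is
  removed up front by the 2000 px² area cap on detections.
* `iom_z` — interval overlap over the shorter interval. The default
  `slice_count` convention counts slices (`len = z2 − z1 + 1`), which is well
  defined for single-slice spines. A `literal` mode keeps the raw endpoint
  arithmetic (`len = z2 − z1`) for compatibility; its 0/0 case for two
  single-slice intervals is defined as 1 when they coincide and 0 otherwise.
* `mean_box` — coordinate-wise mean over the track's slice count. Dividing by
  the number of boxes (rather than `z2 − z1`, which is zero for a single-slice
  track) is the only reading under which the average is defined for all
  tracks.
* `iom_3d` — the F-beta combination `(1+β²)xy/(β²x + y)` of
  `x = IoM_xy(mean boxes)` and `y = IoM_z`, with β = 0.5, i.e.
  `5xy/(x + 4y)`, weighting the xy component more; defined 0 at x = y = 0.
  It equals 1 iff both components equal 1.

Matching at a threshold (default 0.5, boundary counts as a hit) supports two
semantics. The **existential** default counts a detection as TP when *some*
ground truth reaches the threshold and a ground truth as FN when *no*
detection does; this is simple and order-free but can count two detections of
one spine as two TPs. The **one_to_one** alternative pairs greedily by
descending score with each side used at most once (ties break by lower
detection index, then lower ground-truth index). `f1_score(0, 0, 0)` returns
0 with a logged warning rather than NaN: an empty-vs-empty comparison is
reported, not scored. The 2D evaluator applies the same machinery per slice
with `iom_xy_2d` and sums counts over slices; its threshold defaults to 0.5
by analogy with the 3D definitions.

## Post-processing

Raw per-slice detections pass three rules, in the order confidence → area →
duplicates (cheap filters first; duplicates resolved only among plausible
boxes). All three inequalities are strict: keep confidence **>** 0.5, remove
area **>** 2000 px², suppress when pairwise IoM **>** 0.5 (greedy by
descending confidence, ties by input order). Each rule only removes boxes,
so the composite is idempotent and its output pairwise-satisfies the IoM cap.
The area rule applies to detections only, not to ground-truth boxes.

## Tracking

The tracker sweeps slices top to bottom, scoring open tracks against the
current slice's detections by `iom_xy_2d` of the track's *last observed* box
(the simplest stateful choice during a gap), accepting pairs greedily while
the score strictly exceeds 0.5. An unmatched track increments a miss counter
and is closed when the counter reaches `max_consecutive_misses` (default 2:
survive one missed slice, stop after the second consecutive miss); unmatched
detections open new tracks, with ids assigned in order of first appearance
and left-to-right by `x_min` within a slice for determinism. Single-slice
tracks are retained.

On finalization the z-interval spans the first to last actual detection;
interior gap slices get linearly interpolated boxes (the minimal continuous
completion; `interpolate_gaps=False` carries the previous box instead, and
interpolated slices are flagged in the track CSV). Track confidence is the
maximum member confidence — a track is as credible as its best detection.

## Consensus ground truth

Each annotator's per-slice boxes are tracked into 3D exactly like detections
(confidence 1), so annotator tracks and model tracks live in the same space.
Tracks from different annotators are joined by single-linkage when their
combined 3D IoM reaches 0.5; within a connected component each annotator may
keep only one track (the one best linked to the other annotators' members;
the rest split out as singletons), so support = number of distinct
annotators. The cluster representative takes the rounded mean of member
z-endpoints and, on each slice of that interval, the coordinate-wise mean of
member boxes (a member without a box on that slice contributes its nearest
endpoint box). Thresholding support at k gives the fused ground truths;
because the clusters are fixed and only the support filter changes, the
k-level sets are nested by construction. Fusion operates on 3D tracks;
per-slice 2D fusion is available by presenting depth-1 stacks. No
annotator-skill weighting is attempted.

## Detector support

The spine detector is a pluggable callable (image → detections) addressed by
name. The bundled `reference` detector is a classical baseline: Gaussian
smoothing (σ 1.5 px), background subtraction (σ 25 px), fixed threshold
(25 gray levels), connected components, then shape filters (area within
[20, 2000] px², major/minor axis ratio ≤ 3.5 to reject dendritic shafts);
confidence is the component's peak intensity / 255. Its parameters were tuned
on the simulator's default regime and it is a test vehicle and baseline, not
a detection claim.

Training-side geometry for region-proposal networks is provided as pure
functions. The anchor generator places, at every stride-grid center, one box
per (scale, ratio) with base side scale·stride, width base·√ratio, height
base/√ratio, unclipped — the convention of the underlying detection
framework; the count obeys
`|ratios|·|scales|·Σ_s ⌊W/s⌋·⌊H/s⌋`, which for the default 512² configuration
(scale 8; strides 4, 8, 16, 32, 64; ratios 0.5, 1, 2) is 65,472. A published
figure of 50,700 anchors for these same parameters is not reproducible from
any closed form we could derive (nor from 12 anchors per location as
elsewhere stated); the discrepancy is documented here rather than resolved.
Label assignment implements the narrow rule — only each ground truth's
argmax-IoU anchor is positive, and only if that IoU ≥ 0.7; anchors below 0.3
against all ground truths are negative; everything else is ignored — with the
broader standard rule (any anchor ≥ 0.7 positive; argmax positive
unconditionally) behind a flag. Augmentation draws one of the 8 dihedral
orientations uniformly (boxes transformed exactly, areas preserved), then
adds Gaussian noise (σ 5 gray levels) and Gaussian blur (σ 1 px) each with
probability 0.5; the magnitudes are exposed because no canonical values
exist. The combined loss is the arithmetic
`(L_obj + 2·L_regr)_RPN + (L_obj + 2·L_regr)_BoxC + 3·10⁻⁶·L_regu`; the
component losses themselves (cross-entropy, smooth-L1) are out of scope, as
is all network training.

## Synthetic stacks

The generator emulates the main dataset's statistics: 512×512 px slices at
0.1 µm/px, 0.5 µm z-steps, depth sampled uniformly from 5–68 slices, spine
areas uniform in 100–700 px² with a 1300 px² hard max, 15 spines and 2
dendrites per stack, background noise σ 8 gray levels, intensities clipped
at 255 so dendrite cores and bright spine heads saturate. Dendrites are
smooth sinusoidal curves drawn as Gaussian-profile tubes (width 8 px),
constant across depth. Spines are rasterized ellipses (axis ratio 0.6–1.6,
random orientation) offset from the shaft, blurred by 1 px, visible over a
contiguous z-extent of 2–7 slices with intensity peaking at the central slice
(floor 0.4 of peak so the spine never vanishes mid-extent). Ground truth is
the tight bounding box of each spine's pre-blur mask per slice, shaft pixels
excluded, and the sampled target area is exposed on each track as
`target_area_px` for fidelity checks.

By default spines keep ≥ 2 px clearance from the shaft and pairwise-disjoint
boxes (margin 3 px). This is deliberate: it defines the regime in which
detection and tracking are well posed, so that exact recovery (feeding
ground-truth boxes through post-processing and tracking must return
F1³ᴰ = 1) is a meaningful invariant. An `attached` mode lets spines touch the
shaft to reproduce the known hard case. The generator does **not** model a
realistic PSF, photobleaching, motion, overlapping spines, axons or other
confusers — so a high F1³ᴰ here validates the *pipeline machinery*, not
detection performance on real tissue.

Simulated annotators perturb the ground truth: whole spines dropped with a
configured probability, z-endpoints jittered, box corners jittered per slice
with Gaussian σ, spurious boxes added per slice at a Poisson rate. All draws
are unit variates scaled by the σ parameters, so runs with the same seed and
different σ perturb the same underlying sample — which makes degradation
curves across σ levels directly comparable (common random numbers).

## Numerical and degenerate-input choices

* Scores exactly at a *match* threshold count as hits (≥); *filter* and
  *suppression* thresholds are strict (>), following their respective
  definitions ("greater than", "exceeding", "more than").
* Greedy procedures break ties deterministically (input order, then lower
  index), so identical inputs always yield identical tracks and ids.
* All randomness flows from explicit seeds (`PipelineConfig.random_seed`,
  `SimulationParams.seed`, `PerturbationParams.seed`).
* Degenerate denominators are defined, not NaN: `f_beta(0,0) = 0`,
  `f1_score(0,0,0) = 0` with a warning, literal `iom_z` 0/0 as described.
* Consensus z-endpoint rounding uses round-half-up for determinism across
  platforms.

## Problem sizes used in the bundled experiments

The test suite and the acceptance script exercise full-default stacks (512²,
sampled depth) for the 20-stack tracking-recovery experiment, and smaller
stacks (192–256 px, 10–12 slices, 5–8 spines) for the 50-panel consensus and
10-seed degradation experiments, chosen so the complete suite runs in well
under a minute while keeping hundreds of spines per experiment.

## Known limitations

* The existential TP definition can reward duplicate detections of one spine;
  use `matching_mode="one_to_one"` when that matters.
* The classical reference detector misses dim off-center slices of small
  spines; it exists to exercise the pipeline, and any trained 2D detector can
  be registered in its place.
* The simulator's separated-spine default sidesteps the hardest real-world
  failure modes (overlapping spines, spines directly above/below the shaft);
  `attached=True` restores one of them.
* No image registration across time points, no cross-session spine identity,
  no precision–recall sweeps or COCO-style mAP.
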