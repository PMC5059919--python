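# Methods

This note documents the model, the synthetic benchmark, and the numerical
and design choices behind `henstrack`, in the spirit of a methods section
a maintainer can audit.

## State, coordinates and geometry

The tracker state is an oriented rectangle `T{w, h, a, c}` in continuous
image coordinates: origin at the top-left, x right, y down; centers may be
fractional. The angle `a` (degrees, between the rectangle's width axis and
the image x-axis) is stored normalized to `[-90, 90)`; a rectangle is
invariant under `a → a + 180`, and the `±90` boundary is equivalent to a
width/height swap. The sign of `a` is defined operationally by the
candidate-rotation mapping (counterclockwise direction = the `i = 2`
branch); no separate on-screen claim is made. The box size is fixed for
the whole track: only center and angle move (scale adaptation is out of
scope).

Initialization accepts either a rotated box or a marked contour; a contour
is reduced to its minimum-area enclosing oriented rectangle (computed on
the convex hull via shapely's rotated-rectangle routine, the
rotating-calipers equivalent, and verified in tests against a brute-force
angle sweep). Overlap rate — used both as the regression target and as the
evaluation metric — is the exact polygon-clipping IoU of the two oriented
rectangles (shapely), cross-checked against an independent rasterization
oracle to 1e-3.

Boxes may extend past the frame; patch extraction pads by edge
replication, since a hen can brush the pen wall.

## Descriptor

Each candidate region is rectified (inverse-rotated) to an axis-aligned
`w×h` patch by bilinear sampling, then resized to the fixed 16×16 window
with a Gaussian anti-aliasing prefilter before the bilinear down-sample —
without the prefilter, aliasing makes the descriptor jump under sub-pixel
motion and sensor noise, which destabilizes both scoring and the
appearance-change gate. Color input is converted to luminance (Rec.601)
first.

The HOG layout is fixed by the tracker design: 4×4-px cells, 2×2-cell
blocks at 1-cell stride, 9 orientation bins — (16/4−1)² blocks × 4 cells ×
9 bins = 324 values. Choices the design leaves open were resolved to the
simplest standard variants: unsigned orientations (0–180°), hard bin
assignment (no trilinear interpolation), centered-difference gradients
`[-1, 0, 1]` with edge replication, and plain L2 block normalization,
which also makes the cosine-based change measure well behaved. The
implementation is vectorized over candidate batches (the per-frame hot
path evaluates 36 regions per alternation).

## Sub-models and fusion

All three sub-models use an RBF kernel with the standard
`1/(n_features · var(X))` bandwidth; C = 1 for the classifier and
regressor, ε = 0.1, ν = 0.1 — library defaults, all configurable. A
bandwidth sweep on the synthetic scenes showed no benefit to narrower
kernels. Binary labels are stored as {+1, 0} but trained as {+1, −1}: with
{+1, 0} the negative terms of the binary decision sum would vanish.
Decision-function intercepts are included in the raw scores; per-batch
min–max normalization makes that choice score-invariant. A degenerate
batch (min = max, e.g. a single candidate) normalizes to 0.5. Ties in the
fused argmax go to the earliest candidate, which is ordered
smallest-|rotation| first in the angle step and row-major in the shift
step, so a tie keeps the least-motion candidate.

## Search

Per frame, starting from the previous result: an angle step scores the
2h+1 = 11 rotation candidates (h = 5 steps of k = 3°), then a shift step
scores the M×N = 5×5 grid of same-size boxes spanning the best-angle box
expanded m = 1.2×; the steps alternate until two successive quasi-tracking
areas coincide (center within 0.5 px and angle within 0.5°) or 10
alternations are reached. Each alternation costs M·N + 2h + 1 = 36 region
evaluations; the joint search it replaces would cost (M·N)(2h+1) = 275.
Both counters are logged per frame.

Two grid variants are implemented. The literal 0-indexed grid places
offsets at `-(m-1)/2·W + (m-1)/M·W·i`, i = 0…M−1 — spanning −0.10 W to
+0.06 W with no zero-displacement candidate. Measured on the synthetic
scenes, its nonzero mean offset (−0.02·W per axis per step) integrates
over repeated alternations into a systematic drag: tracked boxes settle
3–14 px behind/above the target on every seed, and the drag pushes the box
toward oncoming distractors during crossings. The tracker therefore
defaults to the symmetric variant — same M×N count and ±(m−1)/2 span,
offsets centered with a zero candidate — which removes the drag, lets the
coincidence test terminate exactly, and halves runtime; the literal grid
remains available (`SearchConfig(symmetric_grid=False)`) and is used by
the geometry-level contract tests. When the literal grid is active the
coincidence tolerance is floored just above the smallest move the grid can
make, since "no more movement" is otherwise unreachable.

## Online update

After localization, the change measure `d = 1 − max_j cos(x_cur, x_j)`
against the FIFO history (capacity 100) of per-frame result descriptors
gates the update: re-sample and retrain only when `d < 0.05`. This is a
conservative rule — the model refuses to learn from results that no longer
resemble any accepted appearance (occlusion, drift). On the synthetic
scenes a well-aligned box yields d ≈ 0.04–0.07 and an occluded or
mislocalized one 0.1–0.4, so updates fire mainly when tracking is clean;
both threshold and comparison direction are configurable. On update, the
result patch enters the 40-slot positive queues (binary, regression,
one-class) FIFO with the 10 initial samples immortal — the anchor against
long-occlusion drift — and the negative sets are redrawn (50 binary in the
`(d₂, d₃)` annulus; 20 regression, labeled by the same overlap-ratio
target, since no separate label rule exists for regression negatives).
Whether the regression/one-class queues also reserve 10 initial samples is
not specified anywhere; they use the same queue mechanics as the binary
queue. Likewise the 50 initial positives are FIFO-capped into the 40-queue
(earliest 10 reserved), the reading adopted for "the queue of 40 positive
samples".

There is no re-detection: a fully lost target stays lost, which matches
the method's acknowledged limitation under long occlusion.

## Synthetic scenes

Real pen footage is proprietary, so the benchmark emulates it: a textured
ellipse (the hen) over a cluttered static background, with similar
distractor ellipses for the occlusion scenarios. Textures are band-limited
noise rendered in each ellipse's local frame, so they translate and rotate
rigidly with the body and give the descriptor orientation structure; plain
discs would defeat gradient features. Ground truth per frame is the
minimum outer rectangle of the target ellipse (the 2A×2B rectangle at the
ellipse's angle). Frames are 8-bit grayscale with per-frame Gaussian
sensor noise (σ = 4 intensity levels).

Scene scale is derived from the physical setup the scenes emulate: an
overhead camera at ~2.2 m over a ~1.2 × 1.5 m pen maps a laying hen to
roughly 90–160 px at VGA-class resolution. The default target is an
88 × 58 px ellipse box in a 320 × 240 px frame — scaled down for cheap
simulation but preserving the regime the sampling rules assume: the fixed
positive radius d₁ = √20 ≈ 4.5 px must be small relative to the box (at
4.5 px offset a 88 px box still overlaps its reference by ≈ 0.93; a much
smaller box would push the regression annulus into territory where the
overlap target is already far below 1 and the regressor's maximum moves
off-center). Boxes with diagonal < 2√20 px are rejected outright since the
distance rules then invert.

Five trajectory presets mirror the usual evaluation taxonomy: `linear`
(constant-velocity walk, 3 px/frame), `direction_change` (smooth 55° and
−80° turns), `crossing_occlusion` (one distractor crosses in front,
covering >30 % of the target at peak), `preen_jitter` (in-place ±20° angle
and ±15 % axis-ratio oscillation — a stand-in for unquantified preening
motion), and `multi_occlusion` (three crossing distractors). All rendering
and sampling is driven by one seed; identical seeds give bit-identical
frames and byte-identical tracker output.

## Evaluation

Per-frame overlap rates are averaged arithmetically, lost frames (OR = 0)
included; scenario tags from the generator (or a user CSV) stratify the
report. Tracks round-trip through a fixed-format CSV
(`frame,cx,cy,w,h,a_deg`, six decimal places) so repeated runs are
byte-comparable.

## What passing tests do and do not show

The synthetic scenes exercise the mechanics the tracker claims: rotation
and displacement search, occlusion-gated updating, recovery after a
crossing, fixed evaluation budget, determinism. They do not model
illumination change, non-rigid gait deformation beyond angle/axis jitter,
motion blur, or hens entering/leaving the frame — results on real pen
video will be worse than on these scenes, and the benchmark numbers (mean
overlap per scenario ≈ 0.6–0.8 across texture seeds at the default
settings) characterize the implementation, not field performance. The localization scatter of the
method is roughly 10 % of the box size, set by the 16×16 window
normalization; overlap rates in the high-0.7s are therefore its natural
operating point regardless of image scale.
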