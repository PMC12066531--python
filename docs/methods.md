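# Methods

## Problem setting

A potato precision planter lifts seed tubers on a chain of seed scoops. A
fixed camera above the seed-clearing position views the two scoop columns
top-down in a 640×480 window; objects enter at the top and leave at the
bottom at roughly constant speed. The computation consumes the *detection
stream* of that view — per frame, a class (scoop or tuber), a confidence
score and a box — and produces counted totals per side and per class and a
classification of every scoop cast as missed (0 tubers), qualified (1) or
replanted (≥ 2). Detector training and inference are outside this package;
any detector emitting the documented CSV dialect can feed it.

## Tracking

Association is tracking-by-detection with the two-stage confidence split of
ByteTrack. Motion is a linear-Gaussian constant-velocity model on the state
(cx, cy, a, h, v·): process and measurement standard deviations scale with
box height (weights 1/20 position, 1/160 velocity — the published values for
this model family). Stage 1 assigns detections with score ≥ `tau_high` (0.5)
to all live tracks (active *and* lost) by Hungarian assignment on IoU cost,
accepting pairs with cost ≤ 0.8; stage 2 offers the remaining detections
with score in [`tau_low`, `tau_high`) = [0.1, 0.5) to the unmatched tracks
at cost ≤ 0.5. Unmatched high-confidence detections with score ≥ 0.6 seed
new tracks (active immediately, as in the reference scheme's first-frame
behavior); unmatched tracks become lost and are removed after 30 unseen
frames. Association never crosses classes. While a track is lost, its
aspect/height velocities are zeroed before prediction so extrapolation
cannot drive the height negative. All thresholds live in `TrackerConfig`.

Assignment ties are resolved by the deterministic behavior of
`scipy.optimize.linear_sum_assignment`; for a fixed input the output is
reproducible, which is the property that matters.

## Counting

Two zero-thickness horizontal ordinates are placed mid-window: the entry
line at 0.45·H and the counting line at 0.60·H, with the left/right split at
0.5·W (all configurable). The crossing predicate for consecutive centers of
one id is `prev_y < line_y ≤ curr_y` — downward motion only; line
"thickness" is irrelevant once crossing is a sign-change test. Per id, entry
must precede counting: on an entry crossing the id joins its side's list
(unless already counted); on a counting crossing it is counted only if
present in that side's list and absent from the global `list_sum`, which it
then joins permanently. Consequences, all property-tested: tallies are
monotone; a counted id can never be re-counted; an id born between the lines
(mid-scene id switch) counts nothing; left and right bookkeeping are
independent. A target jumping past both lines in one frame step triggers
entry then count within the same update, preserving semantics under dropped
frames. Side membership is evaluated at each crossing from the current
center-x with strict `< split_x` = left; an id that drifts across the split
between the lines is *not* counted (its entry-list membership is on the
other side) — the conservative reading of per-side bookkeeping.

## Metering

The counter's event log is reduced to casts per side: each tuber count event
is attributed to the nearest scoop count event within a window of frames
(ties to the earlier scoop); unattributable tubers are dropped rather than
guessed. The default window is half the median inter-scoop frame gap,
estimated from the scoop events themselves, so it adapts to chain speed.
Counting accuracy against a manual count is `100·(1 − |alg − manual| /
manual)`, rounded to one decimal; the absolute-deviation form penalizes
over-counting and under-counting symmetrically and coincides with the plain
ratio whenever the algorithm undercounts. Aggregate accuracy over several
videos pools the counts first (Σalg vs Σmanual), then applies the same
formula.

## LAMP pruning

For a layer flattened and sorted ascending by |W|, the score of index u is
W[u]² / Σ_{v≥u} W[v]². Implementation notes: ties in |W| are broken by
original flat index (stable sort), making the total order and hence the
masks reproducible; weights are divided by the layer's maximum magnitude
before squaring — exact in real arithmetic because the score is a ratio, and
immune to float64 underflow of tiny weights' squares; an all-zero layer
raises rather than inventing a denominator. The global mask removes
⌈target·N⌉ weights in ascending score order, never a layer's maximum-score
weight, so every layer keeps ≥ 1 connection and the achieved sparsity lies
in [target, target + 1/N]. The structured variant groups by output channel,
scoring a channel by the sum of its element scores — the minimal extension
of the element-wise score to channel granularity — and a compute-speedup
target s maps to sparsity 1 − 1/s as a documented alias. Fine-tuning after
pruning requires training and is out of scope.

## Block operators

`conv2d` is a direct dense cross-correlation (stride-view + einsum) intended
as a numerical oracle on small tensors, not a performance path. RepConv's
train form is BN(conv3×3(x)) + BN(conv1×1(x)) + BN(x), the identity branch
present only when cin = cout and stride 1 (the standard composition for this
block; the source design leaves it open). Fusion folds each BN
(w′ = w·γ/√(σ²+ε), b′ = β − μ·γ/√(σ²+ε)), zero-pads the 1×1 kernel to the
3×3 center, writes the identity as a per-channel Dirac kernel, and sums —
equivalence to the train form is property-tested to < 1e-6 over random
blocks. PConv convolves the first c_p = round(r·ch) channels (default
r = 1/4, the published FasterNet ratio) and passes the rest through
bit-identically; FasterBlock is x + pw2(ReLU(pw1(pconv(x)))) with ReLU as
the default rectifier (configurable); C3-Faster is the usual two-branch C3
layout with FasterBlocks in the main branch. Parameter accounting: conv
k²·cin·cout (+cout if biased), BN 2·cout.

## Detection metrics

Greedy matching per frame and class: detections in descending score order
claim the unmatched truth box of highest IoU ≥ threshold. AP integrates the
monotone precision envelope over all recall points (the continuous form of
the P-R integral, as the YOLO-ecosystem evaluators compute it); mAP averages
classes, and the 0.5:0.95 variant also averages the ten IoU thresholds.
Conventions at the degenerate corners: P = 1 with no predictions, R = 1 with
no truths; classes absent from the ground truth are excluded from mAP. A TN
field exists in `MatchOutcome` for completeness but no metric uses it —
"correctly detected background" is not an event in box detection.

## Scene simulator

The generator is the test bed for everything above. Geometry and kinematics:
two scoop columns at x = 192 and 448, scoops 64×48 px spaced 96 px moving
down at 4 px/frame (≈ 0.8 s per scoop at 30 fps, and ~18 frames between the
two counting lines), tubers 22×22 px riding inside their scoop (side by side
when a scoop carries two), loads drawn from {0: 0.1, 1: 0.8, 2: 0.1}. After
passing the counting line a tuber is cast free and descends faster than the
chain, so casting is observable without simulating physics. None of these
values is printed by any source; they were fixed once as plausible for this
capture geometry and are all configurable. Detector noise: per-frame miss
probability 0.05, multi-frame detection gaps (probability 0.01/frame, 3–6
frames — these break tracker identities), Gaussian corner jitter (σ = 1 px),
and scores drawn U(0.6, 0.95) with probability 0.85, else U(0.15, 0.45), so
the low-confidence recovery path is actually exercised. All randomness flows
from one seeded generator; a fixed config reproduces identical output.

What the simulator does *not* emulate: appearance (talc coating, lighting),
occlusion between scoop and tuber, class confusion, false-positive
detections, perspective and lens distortion, variable chain speed. Passing
tests therefore demonstrate the correctness of the association, counting and
metering *logic* under realistic detection degradation — not field
performance of any particular detector.

Test problem sizes: end-to-end exactness runs 20 scoops per side noiselessly;
the stochastic regression guard runs 20 seeded scenes of 20 scoops per side
at miss probability 0.2 and requires mean counting accuracy ≥ 95 %. These
sizes give a few hundred frames and ~80 counted objects per scene, enough
that an id switch between the lines would be visible in the tallies.

## Degenerate inputs and numerical choices

Boxes with non-positive area are rejected at construction, so IoU never
divides by zero. A singular innovation covariance raises instead of
producing NaN gains. The crossing predicate's boundary convention (a center
exactly on the line counts as crossed only from strictly above) is arbitrary
but fixed and tested. Accuracy with a zero manual count is an error, not
infinity. RepConv fusion tolerance 1e-6 reflects float64 round-off through
two BN foldings and a kernel sum on O(10)-magnitude values, with margin.

## Limitations

The tuber-to-scoop attribution window is an interpretation — the source
method counts "changes in the number of categories" without operationalizing
attribution — and is isolated in `pair_casts`. Absolute parameter counts of
a full pruned detector depend on architecture widths this package does not
model; only the block-level arithmetic and the relative-reduction formula
are provided. The CLI's `lamp`/`fuse` subcommands exchange `.npz` archives
produced at run time; no trained weights ship with the package.
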