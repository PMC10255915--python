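# Methods

## The model

`tsml` implements a two-stream video behavior classifier with deep
mutual learning inside each stream and late score fusion across streams.

**Two streams.** A clip contributes two views: an *appearance* input
(the RGB center frame of the clip, shape H×W×3) and a *motion* input
(a stack of F dense optical-flow fields computed from the F+1
consecutive frames centered on the same point, shape H×W×2F — x and y
displacement planes per field). The spatial stream classifies the
appearance input, the temporal stream the motion input. The two streams
are trained independently; they interact only at prediction time.

**Mutual learning.** Each stream holds two peer "student" classifiers
with independent parameters (same or different architectures). For a
labeled batch, student *k* minimizes

    L_k = CE(p_k, y) + D_KL(p_peer ‖ p_k)

where `p_k` is its softmax posterior, CE is cross-entropy in nats, and
the peer's posterior enters as a constant (no gradient flows into the
peer through the coupling term). The stream loss is the convex
combination

    L_stream = (1 − α) · L_1 + α · L_2,   α ∈ [0, 1].

Because the peers are detached, the combined update decomposes exactly:
student 1 receives a 2(1 − α)-weighted gradient of L_1 and student 2 a
2α-weighted gradient of L_2. The factor 2 normalizes the per-student
step size: the optimized objective is 2·L_stream, which at the default
α = 0.5 is the classic collaborative objective L_1 + L_2, so each
mutual student trains at exactly the rate of an independently trained
network — mutual and single configurations are comparable at equal
epoch budgets instead of the mutual one running at half the effective
learning rate. Two consequences worth knowing:

* at α ∈ {0, 1} one student receives no gradient at all and its
  parameters stay frozen — α is a training-loss weight only, never an
  inference-time choice;
* with the KL weight at 0, mutual training is two decoupled
  cross-entropy trainings, bitwise identical to independent training of
  each student (the test suite asserts this to the last bit).

**KL direction.** The literature and the source equations admit both
orientations of the coupling term. The default is D_KL(peer ‖ self) —
the gradient `p_self − p_peer` in logit space, the standard deep mutual
learning form; `kl_direction="self_to_peer"` selects the reverse mode.
The two differ (KL is asymmetric) but both pull the posteriors together.

**Late fusion.** The fused posterior is the convex combination
`w_rgb · p_rgb + (1 − w_rgb) · p_flow` with default `w_rgb = 0.5`
(equal trust in appearance and motion); the predicted class is the
argmax, ties broken toward the lowest class index so evaluation is
deterministic and order-independent. With two students per stream,
student *k* of the spatial stream is fused with student *k* of the
temporal stream (`by_index`); `best_of` instead picks, per stream, the
student with the higher single-stream accuracy.

## Training recipe

Gradient descent with classical momentum, fixed throughout training:

| parameter      | default | note                                   |
|----------------|---------|----------------------------------------|
| momentum       | 0.9     |                                        |
| batch size     | 16      |                                        |
| learning rate  | 0.001   | no schedule, no early stopping         |
| α              | 0.5     | equal weight on the two students       |
| epochs         | 500     | desk-scale runs shorten this, nothing else |

Batch losses reduce by the mean over samples, so loss magnitudes (and
the fixed learning rate) are batch-size invariant. Shuffling is drawn
from a named substream of the run seed keyed by (modality, epoch), so
single and mutual runs see identical batch orders, and every run is
bitwise reproducible on CPU. The default update scheme computes both
students' gradients from the same pre-update forward passes
(`simultaneous`); `alternating` refreshes student 1's posterior before
updating student 2, the original mutual-learning recipe. Probabilities
are clamped to [1e-12, 1] inside logarithms so degenerate one-hot
posteriors yield finite losses; training aborts with context if a loss
becomes non-finite.

## Backbones

The registry holds small CPU-trainable convolutional classifiers written
against the package's own NumPy layer framework (NHWC tensors,
same-padding 3×3 convolutions evaluated as nine shifted GEMMs,
hand-written backward passes):

* `tiny` — three conv blocks (8/16/32 channels, each ReLU + 2×2 stride-2
  max pool), global average pooling, linear head. At 64×64 RGB input:
  6,230 parameters, ≈3.2 M MACs per forward pass.
* `tiny_wide` — the same with doubled widths (16/32/64).
* `tiny_deep` — a fourth block (8/16/32/64).

The family gives genuinely different architectures for the
same-backbone versus different-backbone mutual-learning experiments
while keeping a full benchmark run in CPU-minutes. Initialization is
He-scaled Gaussian drawn from a substream of (seed, architecture,
interface), so the same spec and seed always produce bitwise-identical
parameters and the two students of a pair always differ. New
architectures can be added via `register_backbone`.

Parameter counts are exact sums over parameter arrays. FLOP counts are
multiply-accumulate counts of one forward pass (the convention under
which a same-padding conv costs H·W·k²·C_in·C_out MACs and a linear
layer D_in·D_out); pooling, ReLU and normalization-free layers count 0,
and an unrecognized layer object is excluded with a warning.

## Video input pipeline

Clips are frame directories (PNG/JPEG, with an optional `_meta.json`
recording fps) or video containers where a decoding plugin is
available. The manifest CSV (`path,label,split,num_frames,fps`)
persists class order as order of first appearance — that ordering *is*
the label-index mapping.

The train/test split shuffles each class independently with a seeded
substream and assigns round-half-up(fraction × n) clips to train. With
the usual 80/20 convention this rounding reproduces published per-class
train/test totals exactly, which is why it was chosen over floor or
banker's rounding.

Optical flow is computed between consecutive grayscale frames with
scikit-image's iterative Lucas–Kanade solver by default (`ilk`;
`tvl1` available where fidelity matters more than speed), returning
forward displacements in pixels/frame. The flow stack for a sample uses
the F+1 consecutive frames centered in the clip, and the RGB frame is
the center frame of that same window, so appearance and motion describe
the same moment. Displacements are clipped to ±`flow_clip` (20 px) and
stored scaled to [−1, 1]; flow can be cached per clip (compressed
`.npz` + JSON sidecar keyed by method, depth and frame count; any
mismatch triggers a recompute, never a stale read).

**Input standardization.** Network inputs are standardized with fixed
nominal constants at array-assembly time: RGB as (x − 0.45)/0.25, flow
as displacement in pixels divided by `flow_scale` (default 1.0 px, i.e.
raw pixel units). With a fixed learning rate and no normalization
layers in the backbones, input scale directly sets gradient scale;
mapping typical signal amplitudes to order one makes the fixed recipe
effective for both streams. The per-sample stacks keep their documented
units ([0, 1] intensities, [−1, 1] clipped flow); standardization is a
property of batch assembly, not of the stored data.

## The synthetic benchmark

The generator emulates the *structure* of a farm-animal behavior-clip
dataset — K classes, equal clip counts, a few seconds per clip at fixed
fps, one foreground subject — without any claim to photorealism. Each
class is a (texture family, motion law) signature: textures are
procedural (stripes, checkerboard, dot lattice, smooth blobs) evaluated
in object coordinates with per-clip random phase and orientation;
motion laws are static, reflecting linear drift (1.2–1.8 px/frame),
oscillation (amplitude 6–8 px, period 10–14 frames), random-walk jitter
(step σ 1.4–2.0 px), and in-place rotation (0.18–0.26 rad/frame).
Nuisance variation — object placement, radius (12–15 px), color tint,
background pattern, pixel noise, trajectory jitter — is drawn per clip
from named substreams of the root seed, so every pixel is a pure
function of the configuration.

The default six classes are deliberately confounded:
walking/investigating share the stripe texture (appearance cannot
separate them), eating/fighting share the checkerboard, and
investigating/eating share the oscillation law (motion cannot separate
those). An appearance-only classifier therefore has an accuracy ceiling
of 4/6 on this design and a motion-only classifier of 5/6, while the
joint signature identifies every class — fusion has headroom by
construction, which is the phenomenon the two-stream experiments
measure. Default conditions: 6 classes × 60 clips, 32 frames at 8 fps,
64×64 px.

What the generator does *not* emulate: real video statistics (camera
noise, compression, lighting drift), multiple interacting animals,
occlusion, class imbalance, annotation noise, or any visual resemblance
to pigs. Passing benchmarks here show the method's machinery —
complementary streams, peer coupling, fusion arithmetic — behaves as
designed, not that any particular accuracy transfers to real footage.

## Benchmark problem sizes

The standard comparison (`run_benchmark`) trains, per seed, the mutual
two-stream model and the single-network-per-stream baseline for 30
epochs on the default benchmark with `tiny` backbones and flow depth
F = 5, and repeats over three seeds. Thirty epochs of 18 batches is
enough for both phenomena of interest to be measurable — the fused
accuracy exceeding the single-stream mean, and the peer KL falling as
students converge — while a full three-seed comparison finishes in
roughly ten CPU-minutes. F = 5 rather than a deeper stack reflects the
benchmark's 8 fps clips, where each motion law completes its
characteristic cycle well within five flow fields.

## Numerical choices and degenerate inputs

* Softmax is max-subtracted; non-finite logits are rejected.
* log-clamping at 1e-12 (losses finite on one-hot posteriors; clamps on
  the true-class probability are logged).
* Argmax ties → lowest class index.
* The first convolution of a network skips its input-gradient
  computation (inputs need no gradient), a pure speed optimization that
  does not change any parameter update.
* Max-pool gradients route to the window argmax (first index on exact
  ties).
* Empty test sets, channel mismatches, unknown backbone names, α or
  fusion weights outside [0, 1], and non-splittable classes (< 2 clips)
  all raise typed errors early.

## Known limitations

* The backbone registry contains only the tiny family; large ImageNet
  architectures are out of scope for a CPU-only NumPy framework.
* Video container decoding requires an imageio plugin; frame
  directories are the always-available path.
* The flow solver struggles with displacements larger than its search
  scale (~5 px between consecutive frames at 64×64); the generator's
  motion laws stay within that regime, and larger real-world motions
  would need the pyramidal `tvl1` path or higher fps.
* `best_of` student pairing selects on the evaluation data itself; for
  honest model selection use a validation split for the choice.
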