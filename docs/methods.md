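# Methods

`handtrack` estimates and tracks articulated multi-instance hand poses in
video following the detect-then-track paradigm, with one distinctive
ingredient: pose prediction for each hand crop is *conditioned* on the
same track's heatmap estimate from an earlier frame. This note records
the model, its assumptions, the synthetic study conditions, and the
numerical and design choices a maintainer would want spelled out.

## Model

### Frame-wise estimation

Each detected hand is processed top-down: the bounding box is expanded
to 2.2x its area (each side stretched by sqrt(2.2), aspect preserved),
resampled to a fixed crop (64x64 by default for the `tiny` backbone),
and passed through a convolutional network that outputs J = 21 response
channels on an H'xW' grid (32x32 by default). Ground-truth channels are
unnormalized Gaussians (sigma 2.0 grid px by default) centered on each
annotated joint's grid cell, so the peak value is exactly 1.0 at that
cell; a joint decodes back to the argmax cell center mapped through the
crop affine, with the channel maximum as its confidence. The training
loss is the mean squared error over the cells of annotated ("masked-in")
channels only; the mask operates at joint level, and masked-out channels
are excluded from the denominator so the loss scale does not depend on
annotation completeness.

The backbone is a small encoder-decoder: a stride-2 conv produces the
early feature map v (8 channels), two further stride-2 convs and a
stride-1 conv form a bottleneck whose receptive field spans most of the
crop — necessary to tell fingers apart, since their local appearance is
identical — and two nearest-upsample+conv stages with skip connections
decode back to the heatmap grid. The final response conv is initialized
near zero so the output maps start flat; with a conventional init the
large random responses drive an irrecoverable dead-ReLU collapse of the
decoder in the first few optimizer steps. A `small` variant doubles the
input resolution and widens the channels. Optimizer defaults are Adam,
lr 1e-3, batch 16, 30 epochs, with random rotations (±30°) and
horizontal flips as augmentation; a flip mirrors x and swaps the
handedness label, and the per-finger joint ordering means no joint index
permutation is required.

### Conditional prediction

For video, the estimate for a track at frame t is

    H_t = M_fus(P(I_t); M_att(v_t; H_{t-delta}))

where H_{t-delta} is the track's stored heatmap stack from delta frames
earlier (delta = 3 by default), M_att re-weights that prior in the
context of the current image features, and M_fus merges the weighted
prior with the frame-wise estimate H'_t. Both heads are three stride-1
3x3 conv layers (16 channels) with ReLUs between; at stride 1 a
transposed convolution is an ordinary convolution, so the final
up-projection is implemented as a plain conv. The feature map v is the
first conv block's activations, brought onto the heatmap grid by exact
integer-factor average pooling (identity for the default tiny sizes) —
chosen over fractional bilinear resizing so the hand-written backward
pass is exact.

Ablation switches reproduce the reduced variants: `use_feature_map=False`
(NC) feeds the attention head the prior alone; `use_attention=False`
(NA) bypasses attention and concatenates the raw prior *and* the feature
map directly into the fusion input; both off (NC-NA) fuses only the two
heatmaps. The four variants have strictly distinct parameter counts,
all smaller than the full model.

When a track has no stored estimate before t, the prior is an all-zeros
stack — always the case at frame one. If frame t-delta is missing, the
nearest stored frame is used: t-delta+1 .. t-1 are scanned first
(nearest the intended gap), then backwards from t-delta-1 to the track's
first occurrence.

**Curriculum.** Training the conditional head on ground-truth priors
alone teaches it to copy the prior; it then propagates its own errors at
inference, where priors are its previous outputs. The finetuning
curriculum therefore draws a *predicted* prior (the model's stored fused
output at the prior frame, recomputed each epoch) with probability
p = 0.10 x epoch, and the encoded ground-truth heatmap otherwise, using
only predictions from epoch 10 onward. Training past saturation matters:
in our benchmark, a conditional model stopped at p = 0.5 scores *below*
the baseline on tracking MOTA, while the same model trained to
saturation scores far above it. Augmentation is disabled during
conditional finetuning so the prior stays geometrically consistent with
the crop.

**Inference.** The prior belonging to a new detection is unknown, so
every detection is paired with every live track's prior plus the zeros
prior, and the candidate whose mean over joints of per-channel maxima
("average confidence") is highest wins; ties break to the lowest prior
index. Including the zeros prior whenever candidates are formed (not
just at frame one) lets hands entering the scene escape a bad prior; it
is switchable (`include_zero_prior`). The fused output H_t is what the
track stores for future priors.

### Association

Frame-to-frame matching scores every (track, detection) pair with one of
three similarities — box IoU, negative mean keypoint L2 distance over
jointly annotated joints, or negative Euclidean distance between
128-dimensional pose embeddings — followed by greedy descending-score
one-to-one assignment (Hungarian assignment is available behind a flag;
on diagonal-dominant matrices the two coincide). Default gates: IoU >=
0.2; keypoint distance <= 0.5x the track box diagonal; embedding
distance <= m/2. Unmatched detections open new ids; ids are never
reused; a track unseen for `max_age` frames (1 by default — matching
only t-1 to t) expires.

The embedder normalizes keypoints to [0, 1] within the pose's box
(C = 3 channels appends the annotation state: 0 unannotated, 1
annotated, or the predicted confidence), applies two graph-conv layers
(32, 64 channels) over the symmetric-normalized skeleton adjacency with
self-loops, mean-pools over joints and maps linearly to 128 dimensions.
It is trained with the contrastive loss in its literal printed form,
L = 1/2 (y d + (1-y) max(0, (m-d)^2)) with d the *squared* embedding
distance and margin m = 1 — whose negative branch drives d toward m
rather than beyond it; the textbook hinge form is available as mode
`standard`. Pairs are sampled per batch item as: positive (same track,
adjacent frames) with probability 0.5, negative from the same video 0.4,
negative from a different video 0.1; infeasible draws (e.g. cross-video
pairs in a one-clip dataset) are redrawn and counted. Pair
classification — and the tracker's gate — thresholds the *Euclidean*
embedding distance at m/2: under the printed loss positives concentrate
near 0 and negatives near d = m (squared), so the Euclidean rule at m/2
separates them where a squared-distance rule at m/2 would not.
Training defaults: batch 32, lr 1e-3, 60 epochs (20 in the desk-scale
benchmark), 100 batches per epoch.

## Evaluation protocol

A joint is *correct* when its distance to the annotated ground-truth
joint is at most sigma x norm(gt box), sigma = 0.2, with norm the larger
box side (a diagonal option exists). PCK is the fraction of annotated
joints correct. Per frame, predictions are matched to ground-truth
poses one-to-one by highest PCK; zero-PCK pairs never match.

**mAP** follows the keypoint-AP convention of pose-tracking benchmarks:
per joint, predicted keypoints are ranked dataset-wide by confidence; a
keypoint is a true positive iff its pose was matched and the joint is
correct; every joint of an unmatched predicted pose is a false
positive; matched joints whose ground-truth counterpart is unannotated
are ignored. AP is the area under the interpolated precision-recall
curve; mAP averages the 21 joints (joints never annotated in the ground
truth are excluded from the mean).

**MOTA** is counted at joint level:
MOTA = 1 - sum(FN + FP + IDSW) / sum(G), printed x100, range
(-inf, 100]. An annotated joint of an unmatched ground-truth pose, or a
mislocalized matched joint, is a FN; predicted joints of unmatched poses
and mislocalized matched joints are FPs (a mislocalized joint therefore
counts once on each side); when a ground-truth track's matched predicted
id differs from its previous one, IDSW increments once per annotated
joint of that pose, so per-joint MOTA columns stay consistent. G counts
annotated ground-truth joints; occluded joints are annotated and count.
**MOTP** — no canonical joint-level formula exists, so ours is declared:
100 x mean over correct matched joints of (1 - d/threshold). Precision,
recall and F1 are computed over joint-level TP/FP/FN. The whole
accounting is verified exactly (FN/FP/IDSW) against an independent,
deliberately loop-based reference implementation on randomized
scenarios.

## Synthetic study conditions

The generator renders planar 21-joint skeletons (wrist + five 4-joint
chains; per-finger flexion angles curl successive segments) as filled
capsules in glove-like colors (skin, white latex, green, blue, with
per-hand jitter) over a smooth noise background. Per clip the hand
count is drawn from a categorical over 1..7 with mean 2.92 and median 3,
capped at 7, emulating a crowded surgical field. Wrists follow bounded
random walks (2 px/frame default) around disjoint home cells — so hands
do not cover one another unless trajectories are scripted to cross —
with slow orientation drift; flexion angles follow bounded random walks
(0.06 rad/frame). With probability `occlusion_prob` per hand, an opaque
"instrument" rectangle oscillates across the hand's cell; joints under
an occluder (or under a hand drawn later, in scripted crossings) are
annotated `occluded` but keep true coordinates, and off-image joints are
`unannotated`. Boxes tightly pad the annotated joints. All randomness
flows from one per-clip generator, so clips are bit-reproducible; frames
are written as PNG, annotations in the package's JSON dialect.

What the generator does *not* emulate: photometric realism, motion blur,
3D articulation and foreshortening, camera motion, and detector noise
(boxes are ground truth unless a detection file is supplied). Passing
benchmarks here show the machinery is correct and the conditional
mechanism helps under temporal coherence and occlusion; they do not
predict absolute accuracy on real surgical video.

## Benchmark sizes and defaults

The packaged benchmark (`run_benchmark`) uses 30 clips of 16 frames
reduced to 10 frames per clip, occlusion probability 0.3, 24/6
train/val split, baseline trained 8 epochs (augmentation off, since
train and val come from the same generator), conditional model
finetuned 12 epochs at lr 5e-4 from the baseline weights; these sizes
are chosen so a full run completes in minutes on one CPU core while
leaving the directional comparisons stable across seeds. Evaluation
reports mean per-pose PCK@0.2 (ground-truth boxes; the conditional model
scored with true priors and with zeros priors), and mAP/MOTA from the
full tracking pipeline with IoU matching, where the conditional model
selects priors from its own tracks. The embedding benchmark
(`run_gcn_benchmark`) trains on 20 clips (hand count 2-4, 12 frames) for
20 epochs and reports held-out pair accuracy on 200 fixed pairs.

## Degenerate inputs and tie-breaks

Heatmap argmax ties break to the lowest row-major cell, so an all-zero
channel decodes to cell (0, 0) with confidence 0. Poses sharing no
jointly annotated joint get similarity -inf (never matched). A
zero-area box cannot be normalized and raises. Empty detection lists,
empty clips and empty datasets are valid inputs everywhere and produce
empty outputs rather than errors. Checkpoints are single `.npz` files
with a versioned JSON header; configs serialize into every run manifest
with a content hash, and all artifacts (JSON with sorted keys, CSV) are
byte-stable for a given seed.

## Known limitations

- The conditional gain depends on temporal coherence; at very large
  delta or fast motion the prior misleads more than it guides.
- Candidate selection is per-detection argmax: two detections may pick
  the same prior, and a confidently wrong prior can win when the model
  was not trained to curriculum saturation.
- The embedder sees single poses (no temporal stack); hands that adopt
  near-identical normalized configurations are genuinely ambiguous.
- Desk-scale backbones saturate well below what a deep pretrained
  network would reach on real footage; absolute numbers from the
  synthetic benchmark are not comparable to published real-data scores.
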