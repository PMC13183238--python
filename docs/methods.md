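# Methods

This note documents the models, procedures and design choices behind the
package, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic experiments can and cannot show.

## Detector architecture

The detector is a three-scale anchor-free one-stage network. The backbone
is a stem convolution followed by four stride-2 stages; each stage carries
a fusion block, and the deepest stage ends in an SPPF layer (three chained
stride-1 5×5 max pools). The neck is the usual top-down path (2× nearest
upsampling + concatenation + fusion block) followed by a bottom-up path
(stride-2 3×3 convolution + concatenation + fusion block). The head is
decoupled per level: a box branch emitting 4×16 distribution logits
(16-bin discretization of the distance from the cell center to each box
edge, in stride units, decoded by softmax expectation) and a class branch
emitting independent per-class logits. At nano widths (16/32/64/128/256)
and a 640×640 input the pyramid features are 64×80×80, 128×40×40 and
256×20×20 with strides 8/16/32.

Every convolution is followed by batch normalization and SiLU except the
two head output projections, which carry biases and no normalization. The
class-output bias starts at −4.6 (a ~1% positive prior over the dense
grid) and the box-output bias tilts the initial distance distributions
toward small offsets; both choices stabilize the first epochs, when almost
every cell is background.

## Kernel-team fusion

The KTF block is a CSP-style wrapper around a multi-kernel "team": an
entry 1×1 convolution projects to the block width; a `work_fraction`
(default 0.5) of the channels feeds the team and the rest bypass it as a
shortcut; team output and shortcut are concatenated and fused by a final
1×1 convolution, also SiLU-activated. Within the team, channels are
partitioned across kernel sizes 1/3/5/7 (all same-padded, dense within
each group), each branch is convolved and activated, branches are stacked
along channels and fused by a 1×1 convolution.

Partition rules: even division, remainder channels to the smallest kernels
first (keeping the expensive large-kernel branches at or below the even
share); when the work width cannot give every kernel its minimum of 8
channels, the largest kernels are dropped one at a time; below 8 channels
altogether a single degenerate group with the smallest non-1×1 kernel
(3×3, the strongest single kernel in the ablation grid) takes everything.
Which split half feeds the team is not dictated by anything structural; the
work half is taken from the upper channel range, mirroring the ordering of
the CSP blocks this design descends from. KTF blocks never downsample;
stride-2 convolutions between stages do.

The KT variant replaces the fusion blocks of backbone stages 2–4 and all
four neck fusion blocks with KTF; the first backbone fusion block stays a
C2f in both variants. With these placements the profiler reports 6.958
GFLOPs and 2.41 M parameters versus 8.744 GFLOPs and 3.16 M for the
all-C2f baseline at 640×640 — comfortably inside the ≤8.5 GFLOPs budget
the multi-kernel design is meant to respect.

## Profiling convention

FLOPs are counted symbolically per primitive convolution as
2·k²·C_in·C_out·H_out·W_out (two operations per multiply-accumulate) plus
C_out·H_out·W_out for biased layers; upsampling, concatenation, pooling,
normalization and activations count zero. Parameters count convolution
weights, biases where present, and the two affine terms per batch-norm
channel. This is the convention under which the published nano baseline
totals 8.7 GFLOPs and ~3.16 M parameters, which the profiler reproduces;
budget comparisons use an 80-class head because the published figures do
(a 4-class head profiles at 8.09 GFLOPs for the same baseline). Parameter
storage is reported as raw counts, not megabytes, since file sizes depend
on serialization dtype.

## Slide-weighted classification loss

The slide weight is implemented exactly as its piecewise definition:
weight 1 for x ≤ μ−0.1, the constant e^(1−μ) on the open interval
(μ−0.1, μ), and e^(1−x) for x ≥ μ. The function is continuous at μ and
deliberately discontinuous at μ−0.1 (jump of e^(1−μ)−1); no smoothing is
applied. Its range is [1, e].

In training, x is the IoU between a positive cell's decoded box and its
assigned ground truth, treated as a constant for the weight (the weight
does not backpropagate into the box branch). Negative (background) samples
keep weight 1 — weighting is a statement about the difficulty of
*localized* samples, and applying it to the background sea would rescale
the entire loss; this choice is documented rather than assumed. μ is the
mean IoU of the training set: a running exponential average (momentum
0.98) over assigned-sample IoUs, snapshotted once per epoch when
`slide_mu: auto`; a fixed value can be set instead. The per-epoch μ values
are written to the training log.

## Target assignment and box loss

Assignment is center-cell: each ground truth becomes exactly one positive
sample, at the cell containing its center on the pyramid level selected by
object size (max dimension ≤96 px → stride 8, ≤192 → stride 16, else
stride 32). When two objects land on the same cell the smaller one keeps
it (larger objects are assigned first and overwritten). The box loss is
1−IoU on the decoded box plus a distribution-focal cross-entropy on the two
bins bracketing each target distance; total loss is
(cls + 5·(1−IoU) + dfl) / max(n_pos, 1). This is a simplification relative
to task-aligned multi-cell assignment with CIoU: with one positive per
object the slide weight's "sample" is unambiguous, the gradient paths stay
small enough for a numpy engine, and the loss-swap comparison (BCE vs
slide) is not confounded by assignment dynamics. The cost is recall
pressure in extremely dense scenes where several objects share a cell.

## Numpy network engine

No GPU tensor framework is used anywhere; `ktyolo.nn` implements the
needed layers with explicit forward/backward pairs: im2col + BLAS matmul
convolution (with a zero-copy fast path for 1×1/stride-1), exact
batch-norm backward through the batch statistics, SiLU, stride-1 max
pooling with argmax routing (gradient ties broken toward the first maximal
offset), nearest upsampling, and SGD with momentum 0.937 and weight decay
0.0005 applied to convolution weights only (not to normalization
parameters or biases). All computation is float32; every layer is verified
against numeric differentiation, and the composite blocks against
straight-line loop-based reference implementations, in the test suite.
Training is fully deterministic given the master seed, which fans out to
weight initialization, batch order, augmentation and scene generation.

## Training protocol

SGD with momentum 0.937, weight decay 5e-4, initial learning rate 0.01 at
batch size 16, decaying linearly to 1% of its initial value over the epoch
budget (the published protocol fixes the optimizer and initial rate; the
schedule shape is this package's choice and is configurable). Early
stopping monitors validation mAP50 and halts after 50 consecutive
non-improving epochs (improvement = strictly greater by ≥1e-6) within a
500-epoch budget; the best checkpoint is retained. Augmentation is
horizontal flip only, keeping ablation comparisons interpretable.
Inference uses a 0.01 score floor and per-class NMS at IoU 0.7, both
configurable.

## Evaluation stack

AP integrates the precision–recall curve over all score cutoffs after
applying the monotone precision envelope (the continuous variant of the
area-under-curve definition); a 101-point interpolation is available for
cross-tool comparison. Ties in score keep insertion order. mAP50:95
averages over IoU thresholds 0.50–0.95 in steps of 0.05. Matching is
greedy one-to-one in descending score with the highest-IoU unmatched
ground truth at or above the threshold. Classes with zero ground truths in
an evaluation subset are excluded from that subset's mean rather than
scored zero — relevant for drinking at night, which the generator never
produces. Stratified evaluation (day/night, summer/winter) runs one
trained model over all strata; no per-stratum retraining.

## Synthetic scenes: what they emulate and what they don't

The generator renders ellipsoidal sheep proxies on a textured pen
background: standing = tall bright ellipse; lying = flat wide ellipse
whose fleece color is blended toward the floor (more strongly on the
bright "summer" floor, reproducing the low-contrast failure mode of lying
detection in summer); eating = ellipse abutting a feed-trough strip along
the top edge; drinking = ellipse abutting a water-dispenser patch on a
side edge. Class frequencies default to the observed training-set
imbalance (50.3 / 15.9 / 31.5 / 2.3 percent); instance counts are uniform
on [5, 36] per image with 36 as a hard density ceiling; proxy size shrinks
as the square root of instance count (dense pens are filmed wider) so the
ceiling remains placeable under the occlusion cap, which bounds pairwise
box IoU at 0.3 by default via rejection sampling. Night scenes (30% by
default) get a global gain reduction, pedestal and sensor noise, and never
contain drinking instances. Everything is deterministic given the seed.

What passing tests on these scenes establish: the blocks propagate and
train, the losses order difficulty as designed, the metric stack is exact,
dense occluded multi-scale detection with realistic imbalance is learnable
end to end, and the class-geometry cues (aspect ratio, edge context) are
separable. What they do not establish: detection accuracy on real barn
footage — real fleece texture, perspective, lighting, motion blur and
animal articulation are absent, so absolute mAP values here do not
transfer, and published real-data accuracies are deliberately not targets.

## Desk-scale study sizes

The end-to-end checks train a reduced model (widths 8/16/24/48/96, one
bottleneck per stage, KTF fusion) on 200 synthetic 128×128 scenes with
3–10 instances each, validating on 50 held-out scenes, for up to 30 epochs
at batch 16 — about two minutes per run on one CPU, three seeds per
classification loss. Rare-class (drinking) AP is measured on a larger
day-only held-out set of 150 scenes: drinking is ~2% of instances and
absent at night, so the 50-scene set carries only a couple of drinking
boxes, too few for a stable class AP. The ablation runners expose the
kernel-subset grid ([1], [3], [5], [7], [3,5], [1,3,5], [1,3,5,7]) and the
{BCE, slide} × {C2f, KTF} cross at the same scale.

## Known limitations

- At desk scale the rare drinking class (~2% of instances, a few dozen
  training boxes) is barely learned by either classification loss: its
  held-out AP stays near zero across seeds, so the slide-vs-BCE comparison
  on that class is noise-dominated. The slide mechanism rewards hard
  (low-IoU) samples, and the synthetic drinking instances are rare but
  geometrically easy, giving the reweighting little purchase; demonstrating
  a rare-class advantage needs either more data or a proxy whose rare class
  is also hard to localize.
- Center-cell assignment saturates in scenes where many objects share a
  grid cell; multi-positive assignment would lift the recall ceiling.
- The numpy engine is single-threaded BLAS-bound; it is meant for
  reduced-scale studies and correctness work, not full-resolution training.
- Slide weighting is applied to positives only; whether background samples
  should also be weighted is an open modeling question, documented above.
- The 16-bin distance discretization caps regressable distances at 15
  strides per side, which bounds detectable object size per level; the
  level-selection thresholds are chosen to respect this.
- CVAT parsing supports the "for images 1.1" dialect only.
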