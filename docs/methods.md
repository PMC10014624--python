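# Methods

## Problem and model

The package classifies fixed-length 200-bp DNA fragments in two layers:
enhancer vs non-enhancer, then strong vs weak enhancer.  Both layers share
one pipeline: encode, extract features with a dense convolutional
backbone, (optionally) reweight features with attention, classify with a
softmax head, and aggregate five cross-validation models by soft voting.

### Encoding

Each sequence becomes a 7×200 binary matrix: rows 0–3 are the one-hot
indicators in A, C, G, T order; rows 4–6 are the nucleotide chemical
properties x (purine: A/G), y (amino: A/C), z (weak hydrogen bonding:
A/T), so A=(1,1,1), C=(0,1,0), G=(1,0,0), T=(0,0,1).  The NCP rows are a
linear function of the one-hot rows (x=A+G, y=A+C, z=A+T), which the test
suite asserts; the fusion is still useful because convolution over the
7-row height axis mixes the two codes locally.  The row order (one-hot
above NCP) is a fixed convention of this package; it is weakly material
because 3×3 kernels span adjacent rows.  The matrix enters the network as
ONE grey-image channel of height 7 and width 200, not as 7 channels of a
1-D signal.  Ambiguity codes (N etc.) are rejected at ingest rather than
imputed, because the encoding is defined only on A/C/G/T and silent
imputation would corrupt the feature matrix.

### Backbone

A densely connected convolutional network, modified in two ways: the stem
convolution is removed (the raw 7×200 grid enters dense block 1 as a
1-channel image) and an extra batch-normalization layer sits between each
dense block and the following transition.  Each dense block has L=3
layers; layer l applies H = BN → ReLU → 3×3 same-padded convolution to the
channel-wise concatenation of the block input and all previous layer
outputs, adding k (growth rate) channels; the block emits the full
concatenation, c_in + L·k channels.  Transitions are a 1×1 convolution
compressing channels to floor(c·θ) followed by 2×2 stride-2 average
pooling.  Pooling uses ceiling division with edge windows averaging only
the cells that exist: floor division would annihilate the height-7 axis
before block 4 (7→3→1→0), whereas ceiling keeps 7→4→2→1 while the width
shrinks 200→100→50→25.  Channel bookkeeping follows the closed form
c_{b+1} = floor((c_b + L·k)·θ); with defaults the per-block trace is
1→37→18→54→27→63→31→67.

Batch normalization is the standard x̃ = (x−μ)/√(σ²+ε), y = γx̃+β with
per-channel batch statistics in train mode and running statistics
(momentum 0.1) in eval mode.  Train mode requires more than one value per
channel; a batch of one sample is accepted when the spatial extent
provides additional values, otherwise rejected.

### Attention

Layer-1 models insert an attention stage after the last block's batch
norm.  Channel attention: global average-pool and global max-pool each
give a C-vector; both pass through ONE shared two-layer MLP with
bottleneck C/r and are summed; a sigmoid gives per-channel weights in
(0,1) that rescale whole channels.  The shared MLP follows the original
convolutional-block-attention design; sharing is assumed where the
arrangement is ambiguous.  Spatial attention: the channel-wise mean and
max maps (each 1×H×W) are concatenated and convolved with a single 7×7
same-padded kernel; a sigmoid gives per-position weights that rescale
whole positions.  Both are pure scalings — relative magnitudes within a
channel (channel branch) or within a position (spatial branch) are
preserved, which the tests assert.

The two branches run in PARALLEL on the same input F and their outputs
are combined position-wise.  The default combination is the literal
product of the two weighted maps, (M_c⊙F)⊙(M_s⊙F); the alternative
reading F⊙M_c⊙M_s is available as `attention_combine: joint_mask`.  The
classic serial arrangement (spatial after channel) and single-branch
variants exist for the ablation registry.  Layer-2 models set
`use_attention: false` — the smaller strong/weak dataset overfits the
full model.

### Head and ensemble

The final map (67 channels at 1×25 under defaults) is adaptively
average-pooled to a 1×4 grid, flattened, passed through dropout (0.3) and
one hidden layer of 64 ReLU units, and a 2-way softmax.  Training is
mini-batch Adam (lr 1e-3, batch 64) minimizing cross-entropy; the
parameter snapshot with the best validation accuracy is kept, and
training stops early after `patience` epochs without improvement (best
validation selection is an assumption; no stopping criterion is inherent
to the protocol).  Five stratified folds (four parts train / one
validates) each yield a model; the test set is scored by all five and the
positive-class probabilities averaged — soft voting — with the 0.5 tie
broken toward the positive class (documented, deterministic).  A hard
majority vote is available (`vote: hard`).  The stability protocol
re-runs everything for n cycles, reseeding both fold assignment and
initialization with base_seed+c, and summarizes each metric as
mean ± population standard deviation (divisor N; this convention, not
N−1, reproduces published mean±STD tables of this protocol family).

### Metrics

Sn, Sp and Acc are reported as percentages; on balanced test sets
Acc=(Sn+Sp)/2 exactly.  MCC uses the square-rooted denominator
√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) — it is the φ (Pearson) correlation of
the binary label vectors, asserted against an independent oracle — with a
zero denominator mapping to 0 by convention.  Empty-class rates are NaN,
never a silent 0.  AUC is the trapezoidal area with rank-average tie
handling, computed on the soft-voted probabilities (computing it on the
ensemble output, not per fold, is a package decision where the protocol
is ambiguous).  Full precision is kept internally; display rounds
half-even.

## Numerical core

The network runs on a small reverse-mode automatic-differentiation engine
written for this package on NumPy: convolution is lowered to batched
GEMM via per-offset column gathering, pooling/attention/batch-norm carry
closed-form gradients, and gradient correctness is validated against
central finite differences (h=1e-6, float64) on a miniature model in the
test suite.  Default parameters and activations are float32; `dtype` is
configurable.  Global max-pool gradients route to the first argmax on
ties.  Model seeds fix initialization and dropout; fold seeds fix
shuffling — two runs with identical seeds and configs are bitwise
reproducible on the same platform.

## Synthetic benchmark

The generator emulates the structure of the real two-layer benchmark —
balanced classes of 200-bp sequences with disjoint train/test ids — with
i.i.d. background bases at a configurable G+C fraction and a planted
motif: each positive carries the motif at a uniform random position with
probability `implant_rate`.  Defaults: 400+400 train and 100+100 test per
class, the Sp1-like GC-box `GGGCGGGGC`, implant rate 0.9, GC 0.5.  The
motif is strong enough to be learned quickly by a small receptive field
and the 0.9 rate caps achievable accuracy near 95%, so success is
non-trivial.  A JSON manifest records implant positions for white-box
tests.  What passing proves: the encode→train→vote→score pipeline can
extract a genuine, localized sequence signal and does not hallucinate one
when `implant_rate=0`.  What it does not prove: performance on real
enhancers, whose signal is distributed, context-dependent and far from
i.i.d. (no dinucleotide structure, CpG effects, or conservation are
modelled).

## Problem sizes and defaults

Desk-scale verification uses the default synthetic fixture (800 train /
200 test) with 12 training epochs per fold for the learnability check and
4 epochs for the null check (chance-level accuracy is independent of
training length).  The null check keeps the same 400+400 training fixture
but evaluates on a 1000+1000 held-out sample: under the null any
classifier's population accuracy is exactly 50%, so observed deviation is
pure evaluation-sample noise and the larger sample (~1.1% std) resolves
chance behaviour sharply where 100+100 (~3.5% std) cannot.  Full-scale
runs on a real benchmark use
`reproduce --full` (10 cycles, 30-epoch budget with early stopping).
Hyperparameters the protocol leaves open are fixed as: growth rate k=12,
compression θ=0.5, attention reduction r=4, head 64, dropout 0.3,
Adam lr 1e-3, batch 64 — all surfaced in `NetworkConfig`/`TrainConfig`
and the YAML config.

## Known limitations

* The exact filter counts of the reference protocol are unpublished;
  headline benchmark numbers therefore constrain but do not pin this
  architecture, and matching them requires the external benchmark data
  and `reproduce --full`.
* Batch-norm eval statistics come from the final training epoch's running
  averages; very short runs may leave them poorly converged.
* The CPU implementation is practical for the benchmark scale
  (seconds per epoch) but not for genome-wide scanning.
* Layer 2 is trained on curated strong/weak labels; cascading layer 1's
  predictions into layer 2 at inference is supported by running the two
  models in sequence but is not a calibrated joint model.
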