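# Methods

## The model

`falcnn` implements a feedback-attention ladder CNN (FAL-CNN): a VGG-style
feedforward encoder whose per-level activations are folded back through a
U-Net-style decoder that emits *multi-channel spatial attention logits*, one
stack per scale-group.  On the next feedforward pass those logits, squashed
through a sigmoid, multiplicatively gate the features entering each
scale-group — the Feedback Attention Module (FAM):

    x_l  <-  x_l ⊙ σ(a_l)

where `x_l` are the features entering scale-group `l` (the raw RGB input for
`l = 0`) and `a_l` the decoder logits shaped exactly like them.  A feedback
*iteration* is one decoder run followed by one gated encoder re-pass.  The
first pass always runs ungated; with N = 0 iterations the decoder is never
executed and the model degenerates to the plain feedforward encoder plus the
extra fully connected reduction layer.

The C-dimensional embedding of every pass (the output of the second C-wide
FC layer, after its ReLU) is stored in the Feature Embedding Store (FES), a
tensor of shape `B × C × (N+1)`: slot 0 holds the initial pass, slot k the
pass after feedback iteration k.  A fully connected layer reduces the
flattened store to `B × C`, and a final FC + softmax yields the class
probabilities.  Masks produced by the decoder run on pass k−1 gate pass k;
the decoder is not run again after the final encoder pass.

The encoder is described declaratively by `ModelSpec`: an ordered list of
scale-groups `(n_convs, channels)`, each a run of 3×3/stride-1 convolutions
with ReLU followed by 2×2 max pooling.  The `vgg19` preset reproduces the
canonical 5-group, 19-layer configuration (FAM insertion sites fall at
pre-insertion layer indices 0, 5, 10, 19 and 28); the `mini` preset
(3 groups of 8/16/32 channels, C = 64) is the CPU-scale configuration all
tests and benchmarks run on.  Every scale-group, including the first,
receives a FAM.

The decoder starts from the pooled deepest encoder output, and per level
applies bilinear 2× upsampling, concatenation with the same-level encoder
activation (the forward "skip" of the ladder), a 3×3 merge convolution with
ReLU, and a 3×3 head convolution producing the attention logits for that
level's FAM site.  The gating form is the pure product `x ⊙ σ(a)`; the gate
is bounded in (0, 1), which keeps repeated iterations stable.  A residual
form `x ⊙ (1 + σ(a))` would also be possible but is not implemented.

### Numerical substrate

The network, its reverse-mode differentiation and SGD-with-momentum training
are implemented directly over numpy (`falcnn.autodiff`): im2col convolution,
argmax-routed max-pool backward, an exact-adjoint bilinear upsampler, and a
softmax cross-entropy loss.  Everything is float32 and single-threaded, so
model builds, forward passes, training runs, splits and saccade traces are
bitwise reproducible from their seeds; no separate "deterministic mode" is
needed.  Weights use He-normal initialisation seeded per build; the final
classification layer's weights are scaled down by 100× so training starts
from a near-uniform softmax (initial loss ≈ log K) — with arbitrary
confident initial logits, short training runs were seed-fragile.  An
exactly-zero head would block first-step gradient flow to the decoder, so a
small random init is used instead.

Inference with fewer feedback iterations than the model was configured for
leaves the unused FES slots at zero (the reduction FC is dimensioned for
N+1 slots); requesting more iterations than configured is an error.

## Attention maps, contours, centre of attention

Per FAM site, the channel dimension of the attention logits is averaged
into a single `H_l × W_l` map, min-max normalised to [0, 1] (a flat map
becomes all zeros and is flagged), and bilinearly interpolated to the input
resolution.  Because interpolation can place all output samples slightly
off the peak, the result is renormalised once more so the maximum is
exactly 1 for non-flat inputs.  The *attention region* at fraction t is the
pixel set `{heatmap ≥ t}` (the map is normalised, so t is a fraction of the
maximum); contours are traced by marching squares at the same iso-level,
with (row, col), 0-based, pixel-centre coordinates.  The *centre of
attention* (CoA) is the unweighted centroid of the union of all
suprathreshold pixels at t = 0.8; when the region is split into several
components the union centroid is still used (deterministic and robust),
with a largest-component alternative behind a flag.  A flat map falls back
to the argmax pixel.  Aggregate maps (grouped by level and iteration) are
per-pixel means renormalised to [0, 1], rendered with the perceptually
uniform viridis colour map.

## Saccades

A parent image (canonically 448×448 px) is sampled by a crop of half its
side.  Cycle 0 classifies the central crop.  In attention mode, the CoA of
the deepest FAM level's heatmap from the last feedback iteration, mapped to
parent coordinates (crop origin + CoA, rounded to the nearest pixel),
becomes the next crop centre; in random-walk mode the centre moves by
independent uniform integer offsets in ±half-crop per axis (±112 px at
canonical size), drawn from a seeded generator.  Crop centres are always
clamped so the crop lies fully inside the parent ([112, 336] per axis at
canonical size); a CoA pointing outside the frame is clamped rather than
terminating the run.  The default run length is 8 saccades (9 recorded
cycles); more than 10 triggers a warning.  Traces record per-cycle crop
centres, CoAs, predicted classes and probability vectors.

## Synthetic data

The generator emulates the structure of a histopathology patch corpus
without any real data.  Each of up to 9 classes is a coloured Gaussian
background scattered with Poisson-placed nucleus-like discs; base colour,
disc colour, density and radius distribution carry the class identity, so
class is a *local texture* property, as in tissue patches.  Datasets are
laid out as `class_<k>/<parent>_<i>.png` plus a `manifest.csv`, with patches
grouped under synthetic parent ("slide") identifiers so parent-grouped
cross-validation is exercisable.  For saccade experiments, parents are a
neutral grey texture containing one compact cluster of class discs at a
known, off-centre position; the rendered cluster's pixel-mass centroid is
returned as ground truth.  Object-localisation training images place the
cluster at random positions so the class signal is spatially localised.

What the generator does *not* emulate: stain variability, nuclear
morphology, tissue boundaries, scanner artefacts, or inter-class ambiguity.
Passing the synthetic benchmarks therefore demonstrates that the
architecture, training loop, attention extraction and saccade mechanics
work as specified — not that the model reaches any particular accuracy on
real histopathology.

## Training protocol and statistics

Training uses SGD with momentum 0.9 and cross-entropy loss; the learning
rate decays by 0.7 every 30 epochs (`lr(e) = lr0 · 0.7^⌊e/30⌋`, reference
lr0 = 3·10⁻⁴ over 200 epochs).  The desk-scale runs in this package keep
the schedule shape but use lr0 = 0.01 and far fewer epochs (30 for the
64-px texture classifier, 4 for the 224-px object model) — problem sizes
chosen so the whole pipeline runs in minutes on one CPU core.  Per-channel
input standardization constants are computed from the training set and
stored with the model.

Evaluation follows the grouped protocol: parents are assigned whole to one
of five folds (greedy balancing by patch count on a seeded shuffle), so
test patches always come from parents unseen in training.  Per fold, the
test set is partitioned uniformly at random (seeded) into six subgroups;
subgroup accuracies across five folds give 30 points, summarised as mean ±
1.96·sd/√n (normal-approximation 95% CI).  Distribution comparisons use the
Wilcoxon rank-sum test (scipy's normal-approximation `ranksums`; two-sided
default, one-sided available).  A prediction is *uncertain-class* when its
top-two class probabilities satisfy (P_A − P_B)/P_A < 0.25 (strict).

Agreement tables group records by expert label and report per-class
agreement rates with Wald binomial 95% CIs: p̂ ± 1.96·√(p̂(1−p̂)/n), as
percentages, clipped to [0, 100] and rounded half-up to 2 dp from the
unrounded p̂ (this form, rather than Wilson or Clopper–Pearson, reproduces
the reference per-class bounds exactly).  The overall row is computed as
100·k/n from the summed counts; for the reference 313/400 evaluation this
gives 78.25% (CI 74.21–82.29) — the per-class source table prints 76.90%
(72.81–81.00) for the same counts, an internal inconsistency; this package
reports the directly computed value.  Classes with zero records report a
0% rate and no CI.

## Known limitations

* The vgg19 preset builds and runs but is far too slow to train in numpy at
  scale; no pretrained weights are shipped (a loading hook accepts encoder
  weights by parameter name).
* Convolutions are fixed at 3×3/stride 1/pad 1 and pooling at 2×2, matching
  the VGG family; other geometries are out of scope.
* The subgroup bootstrap is unstratified (uniform at patch level), so very
  small test sets can give noisy per-subgroup accuracies.
* Saccade evaluation assumes square parents with a crop of half the parent
  side.
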