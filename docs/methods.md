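# Methods

## Problem and model

The package targets plant species identification from leaf images when only
a handful of labeled images per species exist — the regime where a softmax
classifier overfits and, worse, cannot say anything at all about species it
was never trained on.  The approach is metric learning with a convolutional
Siamese network (CSN): two copies of one embedding CNN share a single weight
vector *w*, each maps an image *x* to a feature vector *F_w(x)*, and the
network's output is the Euclidean distance

    D_w(x1, x2) = || F_w(x1) − F_w(x2) ||₂ .

Training minimizes the margin-based contrastive loss on labeled image pairs
(y = 1 for same species, 0 otherwise):

    L(d, y) = (y/2) d² + ((1 − y)/2) max(0, m − d)² ,   d = D_w(x1, x2),

which pulls same-species pairs together and pushes different-species pairs
apart until their distance exceeds the margin *m*.  Negatives beyond the
margin contribute nothing; the hinge is squared, so the y = 0 branch meets
zero at d = m with zero slope.

Classification needs no class-specific parameters.  For each candidate
species *i* a small reference set *C_i* of images is stored, and a query *q*
is scored by its mean learned distance

    S̄_i(q) = (1/|C_i|) Σ_{x ∈ C_i} D_w(q, x) ,    C* = argmin_i S̄_i(q).

Top-k accuracy accepts the k species with the smallest mean distance.
Because the metric is independent of the class count, species unseen in
training participate simply by supplying a few reference images.

## Embedding architecture

Inputs are single-channel grayscale images in [0, 1] (224×224 by default;
the input size is configurable and everything downstream adapts).  The
trunk is:

| stage | layer |
|---|---|
| 1 | conv 32 filters 11×11 (valid, stride 1) + ReLU + maxpool 2×2/2 |
| 2 | conv 64 filters 8×8 + ReLU + maxpool 2×2/2 |
| 3 | conv 128 filters 5×5 + ReLU |
| 4 | global average pooling → 128-vector |
| 5 | fully connected 1024 + ReLU  (the embedding *F_w(x)*) |

A softmax head over the species is attached only for the baseline
classifier.  With a 32-class head the network holds 504,864 trainable
parameters (472,064 without it); global average pooling makes the count
independent of the input resolution.  The smallest square input the full
stack accepts is 44×44.

Pooling geometry (2×2, stride 2), valid convolutions with stride 1, He
initialization (seeded, zero biases), and [0, 1] pixel scaling are the
package's choices where the architecture leaves them open; they follow the
classical Siamese verification networks this design descends from.  The
embedding used by the distance is the 1024-unit FC output after ReLU — a
class-count-free vector, which is what the reference-set classifier
requires — so embeddings are non-negative by construction.

The two twins are deliberately *one* network object: weight sharing holds
by identity rather than by synchronization, and a pair batch is pushed
through the trunk as a single stack of 2·B images, so one backward pass
updates the shared weights exactly once per step.

The numeric core (valid convolution, max pooling, dense layers, softmax
cross-entropy, Adam) is a compact numpy implementation inside the package
(`leafsiam.nn`).  Convolutions lower to a single GEMM over an im2col patch
matrix; gradients of every layer are covered by finite-difference tests.
All computation is deterministic given the seeds.

## Training protocol

Pair batches follow a two-stage draw: a Bernoulli(p_same = 0.3) decides
same- vs different-species, then images are drawn uniformly from the chosen
class(es), with replacement across batch entries.  A positive pair's class
is drawn among classes holding at least two images — necessary because the
smallest experiments keep only one validation image per species.  During
training each image passes, behind a single Bernoulli(0.5) gate, through a
composed affine transform: rotation (integer degrees in [0, 360]), optional
horizontal/vertical flips, ±10 % isotropic zoom, and integer shifts of up
to ±10 px; bilinear interpolation, background-value fill.  Validation draws
the same kind of batches but never augments, predicts "same species" when
d ≤ tol (tol = 0.5), and reports the fraction of agreement with the labels.
The weights with the best validation pair accuracy are restored at the end
(the same rule is applied to the baseline, for symmetry of treatment).

Reference defaults: margin m = 1.0, Adam with lr = 1e-5, β₁ = 0.9,
β₂ = 0.999, 500 epochs for the CSN and 2000 for the CNN, pair batches of
32, ⌈|T|/batch⌉ batches per epoch (so an epoch sees roughly one training
set's worth of images), validation every epoch over 10 batches.  The margin
is chosen by `margin_sweep`: one CSN per candidate, identical seeds and
data, argmax of final validation pair accuracy, ties toward the smaller
margin.

The batch size (32), the validation period (every epoch) and the validation
budget (10 batches) are free parameters the protocol leaves open; the
defaults keep small-dataset epochs cheap while giving a dense history.

### Scaled-down profile

End-to-end runs on one CPU use the `test` profile: 30 epochs (CSN) and 40
epochs (CNN) at Adam lr = 1e-3, on 64×64 synthetic images.  The larger step
size is what makes a 30-epoch budget meaningful for ~0.5 M weights; at the
reference lr = 1e-5 such a short run barely leaves initialization.  All
similarity-scale parameters (margin 1.0, p_same 0.3, tol 0.5) keep their
reference values, since the loss itself pins the distance scale these
thresholds live on.

## Data protocol

`make_split` first removes a fixed test pool P (10 images per species by
default, drawn without replacement); the remainder splits 80/20 into
training and validation pools T and V.  An experiment E_i subsamples i
images per species — round(0.8·i) from T, the rest from V — while P never
changes, so every dataset size is scored on identical held-out images.
Subsets for different i are drawn independently from the same seeded pools.
Membership is canonicalized by file path before the seeded shuffle, so
splits are independent of directory listing order, and leak-freedom across
P/T/V is asserted by tests.

The loader converts to grayscale, resizes, scales to [0, 1], and can invert
intensities so white-background scans become bright-leaf-on-dark — the
convention the synthetic generator and the augmentation fill value share.

## Synthetic leaves

The generator defines the study conditions for every end-to-end test: by
default 10 species × 24–30 images at 64×64.  A species is a prototype of
six shape parameters — blade aspect ratio, serration frequency and
amplitude, petiole length, lobe count, base intensity — rejection-sampled
to keep at least 0.35 separation in normalized parameter space.  An image
modulates an ellipse in polar coordinates with the serration sinusoid and a
lobe term, attaches a petiole, applies a uniform random in-plane rotation,
jitters every continuous parameter by 6 % of its range, and adds σ = 0.03
Gaussian intensity noise (clipped to [0, 1]).

What this emulates: consistent within-species shape with moderate
variation, arbitrary leaf orientation, intensity noise.  What it does not:
natural texture and venation, lighting gradients, occlusion, background
clutter, or the Same-Specimen-Picture Bias of real collections — so passing
tests demonstrate that the pipeline learns and transfers a shape metric
under controlled conditions, not field-level accuracy.  Raw-pixel
nearest-centroid sits clearly above chance but well below 100 % on this
data, which is the intended difficulty window.

## Numerical choices and degenerate cases

* Distance gradients divide by d; a 1e-12 floor avoids the singularity at
  d = 0 (where coincident pairs contribute zero gradient anyway).
* Ranking ties break toward the lexicographically smaller species label,
  making predictions deterministic.
* Reference-set embeddings are cached per weight state (Eq.-style
  evaluation would otherwise re-embed |C_i| images per query).
* Max pooling drops partial windows and routes gradients to the first
  maximal element of a window.
* A non-finite loss aborts training with a diagnostic rather than
  continuing silently.
* Zero training epochs is a no-op returning unchanged weights and an empty
  history.

## Known limitations

* Grayscale only; no color pathway, by design.
* The numpy core targets clarity and CPU-scale experiments, not GPU
  throughput; the reference 500/2000-epoch protocol at 224×224 is expensive
  in this implementation.
* `retrain_with_novel` rebuilds the softmax head from scratch (keeping the
  trunk), so the baseline's transfer numbers depend on the retraining
  budget — which is precisely the comparison the Siamese route avoids.
* The pair sampler samples with replacement, so a batch can repeat pairs;
  statistics over batches remain Bernoulli(p_same) per entry.
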