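# Methods

## The pipeline and its assumptions

`mitopipe` treats mitosis detection as segment-then-classify: a U-Net finds
nucleus pixels, each connected component becomes a fixed-size candidate
patch, a convolutional backbone turns patches into feature vectors, and a
deep belief network (DBN) classifies each candidate as mitotic or
non-mitotic. The DBN's hyperparameters are not hand-set; they are chosen by
a chaotic butterfly optimization algorithm (CBOA) minimising the
cross-validated classification error on the training split. The pipeline
assumes two-class candidates, one dominant nucleus per classification
sample, and tiles small enough to process whole (no whole-slide tiling or
pyramid I/O).

All networks are NumPy implementations with hand-written backward passes
(`_nn.py`): at the tile and patch sizes used here (64×64 tiles, 32×32
patches, ≤16 channels) CPU matrix products are entirely adequate, and a
single code path keeps every stage bit-reproducible from one integer seed.

## Synthetic data generator

The generator emulates the visual contrast that makes mitotic figures
recognisable in H&E stains, and only that contrast:

- background: Gaussian colour noise around an eosin-pink mean (236, 205, 221);
- non-mitotic nuclei: smooth ellipses (radius 5–9 px, aspect 0.65–1) around
  a hematoxylin purple (130, 95, 168);
- mitotic nuclei: darker (62, 40, 92), doubled interior texture noise, and a
  boundary modulated by a seeded harmonic series (orders 2–5, amplitude
  capped at 0.45·irregularity so the radius stays positive and the centroid
  stays inside the footprint).

Placement rejects candidates overlapping existing nuclei by more than 5% of
their area and raises an explicit error after 200 failed tries.
Classification samples are single-nucleus 64×64 tiles, 75 per class by
default, mirroring the balanced 150-sample benchmark composition;
segmentation uses multi-nucleus tiles (2 mitotic + 4 non-mitotic) from the
same renderer. What the generator does **not** model: stain variability and
deconvolution physics, touching/overlapping nucleus clusters, apoptotic and
other mimics, tissue texture, imaging artefacts. Passing tests therefore
demonstrate that the machinery is correct and that the pipeline can exploit
real class contrast; they do not predict accuracy on clinical slides, where
class contrast is far weaker.

## Segmentation

Same padding on all 3×3 convolutions keeps output resolution equal to input
resolution at every stage, which is the consistent reading of an
encoder–decoder that "recovers" spatial resolution; input dimensions must be
divisible by 2^depth. The head is a 1×1 convolution to 2 classes with
per-pixel softmax; masks threshold the nucleus channel at 0.5. Training uses
per-pixel cross-entropy with Adam (lr 3·10⁻³, batch 5, 8 epochs over 50
tiles by default — loss plateaus there on generator data). The desk-scale
default is depth 2 with 8 base channels; the classic 64-channel schedule is
a config choice away and is what the channel-doubling tests inspect.
Candidate extraction takes one component per connected region ≥ 30 px
(8-connectivity), crops a patch centred on the centroid (row-major, 0-based,
half-open windows), edge-padding near borders.

## Feature backbone

A depthwise-separable convolution computes a per-channel k×k spatial filter
followed by a 1×1 pointwise mix (8 768 parameters for 64→128 channels at
k=3, versus 73 728 for a standard convolution). The full variant reproduces
the Extreme-Inception census — 36 convolution layers in 14 blocks (2 entry
convs; three 2-conv entry blocks; eight 3-conv middle blocks; a 2-conv exit
block; two final convs), with linear residual connections on blocks 2–13 —
counting a separable layer as one convolution and excluding 1×1 residual
projections from the census. The `tiny` variant is a 4-block analogue
(residuals on the two middle blocks) used for training and testing at
32×32. The custom head is three 3×3 convolutions (batch-norm after each,
16 channels) each followed by 2×2 max-pooling, then flatten — giving the
256-dimensional feature vector for 32×32 inputs — then dropout (rate 0.5)
and a 1-unit sigmoid. Features are tapped at the flatten; dropout is active
only in training and batch norm uses running statistics at inference, so
extraction is deterministic. The backbone trains from scratch on the
synthetic training split (binary cross-entropy, Adam lr 2·10⁻³, 10 epochs);
a hook loads externally supplied weight files but nothing is downloaded.

## DBN

Real-valued features are min–max scaled per dimension to [0, 1] and treated
as visible activation probabilities, keeping the binary-unit energy model
unchanged. CD-1 samples hidden states as Bernoulli draws and reconstructs
visibles as mean-field probabilities — the lowest-variance common variant.
Weights start at N(0, 0.01²), biases at zero. Exact partition-function and
log-likelihood routines (enumeration, refused above n+m = 20) serve as
test oracles for the conditionals and for CD-1's likelihood ascent.
Pretraining is greedy and layer-wise (each layer consumes the previous
layer's hidden probabilities; defaults ε = 0.1, 50 epochs, batch 32 — small
ε leaves hidden activations nearly input-independent, which starves the
supervised stage). Fine-tuning appends a 2-class softmax and backpropagates
through the sigmoid stack with Adam-style adaptive steps (100 epochs, batch
32): adaptive scaling is what keeps fine-tuning effective across the three
orders of magnitude of learning rate that the hyperparameter search
explores; plain SGD stalls on the plateau where hidden activations are
nearly constant. Standalone default architecture: hidden widths (256, 128).

## CBOA

Original-BOA parameter roles are used: c is the sensory modality (initial
0.01), a the power exponent. Schedules: a(t) = a_s − (a_s − a_f)·
sin(π·μ·t / (2·T_max)) with defaults a_s = 0.1, a_f = 0.3, μ = 1 (a sin²
variant sits behind `a_schedule="sin2"`), and c ← c + 0.025/(c·T_max),
strictly increasing; the additive-product reading of the c update diverges
immediately and is rejected. Moves use s², with s a fresh uniform draw
(plain BOA) or a logistic-map iterate x ← 4x(1−x) (CBOA; canonical choice
in the chaotic-metaheuristic literature), one independent stream per
butterfly obtained by warming the shared initial state 0.7 a
butterfly-specific number of steps; initial states at the map's fixed
points are rejected. A butterfly moves globally with probability 0.8
(original-BOA convention), otherwise locally along the difference of two
distinct random peers. Stimulus intensity for minimisation is
I = 1/(1 + fitness), so better solutions emit stronger fragrance; the
intensity map is pluggable. Acceptance is greedy per butterfly with ties
keeping the incumbent, which makes the best-so-far trace exactly monotone.
Positions are clipped to the search box after every move.

The tuning adapter decodes a 5-vector — log₁₀ RBM learning rate ∈ [−4, −1],
hidden widths ∈ [16, 512] and [8, 256] (nearest integer), pretraining
epochs ∈ [5, 50], log₁₀ fine-tune learning rate ∈ [−4, −1] — and scores it
by stratified k-fold cross-validation (error pooled over folds, percent
scale). Fine-tune epochs are fixed at 40 inside the search (enough for the
adaptive optimiser at any decoded rate); identical positions are cached.

## Evaluation conventions

Mitotic is the positive class; per-class rows treat each class in turn as
positive, which makes per-class "accuracy" equal that class's recall, and
the Average row the unweighted macro mean (balanced accuracy). F-score is
the harmonic and G-measure the geometric mean of precision and recall, so
F ≤ G ≤ arithmetic mean holds row-wise. MCC is the standard binary formula
and is identical for both class orientations. Metrics are computed
unrounded and rounded half-up to 2 decimals only for reporting. Degenerate
denominators yield 0 with a `degenerate` flag rather than an error, so
sweeps never crash. `reconstruct_cm_from_rates` inverts a printed
precision/recall quadruple back to the unique integer confusion matrix at a
given n by exhaustive search, and is the bridge by which the metric suite
is validated against published two-decimal tables.

## Pipeline scale and determinism

Desk-scale problem sizes, chosen to keep a full run in the low minutes on
one CPU: 75 + 75 classification tiles of 64×64; 50 training + 10 held-out
segmentation tiles; depth-2/8-channel U-Net; tiny backbone; CBOA with 6
butterflies × 5 iterations and 3-fold cross-validated fitness. The master
seed is fanned out to per-stage seeds via a seed sequence; every random
draw flows from those, so reruns are bit-identical, which the tests assert
on the serialised report.

## Known limitations

- Synthetic contrast is generous; expected accuracies do not transfer to
  clinical material (see generator section).
- The BOA fragrance scale (c ≪ 1) makes early moves small; at 5 iterations
  the search behaves closer to seeded random sampling with local refinement
  than to a converged swarm. With the adaptive fine-tuner most of the
  search box classifies well, so this costs little here.
- The candidate stage assumes one dominant nucleus per classification tile
  and picks the largest component; clustered nuclei would need instance
  separation (out of scope).
- RBMs are binary–binary only; no persistent CD or Gaussian visible units.
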