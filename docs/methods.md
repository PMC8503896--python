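# Methods

This note documents the models, conventions and design choices behind
`annoloop`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The segmentation network

The model is a symmetric encoder–decoder ("U-net") operating on RGB
patches, implemented in numpy with explicit forward/backward passes:

- **Encoder** — five levels; each level applies two 3×3 same-padded
  convolutions, each followed by batch normalization and ReLU; 2×2 max
  pooling between levels.
- **Decoder** — mirrored levels with learned 2×2 stride-2 transposed-conv
  upsampling, concatenation of the encoder skip at the same resolution,
  then the same double-convolution block.
- **Head** — a 1×1 convolution to two class logits (positive /
  non-positive), softmax over classes at inference.
- **Channel ladder** — (5, 8, 16, 30, 62). The ladder approximately
  doubles per level but is width-tuned: it was fixed once, by a
  configuration search over per-level widths, upsampling mode and
  normalization, to pin the network capacity at exactly **113,306
  trainable parameters** (conv weights and biases plus batch-norm affine
  parameters; running statistics are buffers, not parameters). The search
  and its outcome are frozen as the package default — the ladder is not a
  tuning knob.
- An auxiliary 1×1 RGB **reconstruction head** shares the decoder output
  and exists only for autoencoder pretraining; it is excluded from the
  parameter count, which refers to the segmentation network proper.

A closed-form per-layer parameter sum serves as an independent oracle in
the tests; the built network must agree with it on a grid of toy
configurations (depths 1–3, widths 2–8, both norm and both upsampling
modes).

### Training stages

1. **Autoencoder pretraining** (unsupervised): minimize mean-squared
   reconstruction error of the input patch through the shared body and the
   reconstruction head. Initializes features from tissue appearance before
   any labels exist.
2. **Supervised fine-tuning** on 3-class masks: per-pixel cross entropy
   where *unknown* is an ignore label. The loss is averaged over labelled
   pixels only, so unknown pixels — and entirely unannotated patches —
   contribute exactly zero gradient (asserted as a property test).
   Training is gated: at least 3 annotated patches are required (an
   annotated patch has ≥1 non-unknown pixel).

Optimization uses Adam (lr 1e-3 pretraining, 2e-3 fine-tuning, batch
size 4). These are conservative defaults chosen for stable convergence of
a ~1e5-parameter network on small patch sets; they are exposed as
arguments and recorded in training logs, not hidden. All randomness
(initialization, shuffling) flows from explicit integer seeds; identical
seeds and data give bit-identical weights. Inputs are scaled to [0, 1];
convolution weights use He-normal initialization.

Prediction is fully convolutional: any input whose sides are divisible by
2^(depth−1) is accepted; probability maps are deterministic given weights
(batch norm uses running statistics in eval mode). Binarization thresholds
at 0.5 by default with ties mapping to positive.

## Patch and mask conventions

- Coordinates are 0-based, row-major, half-open; patches default to
  256×256 with stride = patch size (a partition). Overlapping strides are
  supported for inference; overlapping predictions are averaged and padded
  pixels dropped on reassembly.
- Non-multiple tile sizes are reflect-padded, with a validity mask
  flagging synthetic pixels.
- Annotation masks hold exactly three labels — unknown (default),
  negative, positive — persisted as indexed PNGs with a fixed palette;
  encode/decode round-trips bit-exactly (tested exhaustively on 2×2
  masks). Overlays render positive turquoise, negative fuchsia, model
  suggestions white.

## Synthetic scenes

The generator emulates the three structure scales the engine targets,
with full ground truth:

| kind       | shape model                            | size (px)        | default density (/Mpx) |
|------------|----------------------------------------|------------------|------------------------|
| nuclei     | random ellipses                        | radii 4–12       | 300                    |
| tubules    | elliptical rings with bright lumens    | outer radii 20–60| 12                     |
| epithelium | radial-harmonic blobs (irregular)      | base radii 40–90 | 5                      |

Placement is a homogeneous Poisson process (intensity = density per
megapixel); overlaps resolve by draw order (later wins); surviving
instances are relabelled into consecutive 4-connected regions of ≥10 px.
Colours default to a two-tone purple/pink (hematoxylin/eosin-like) palette
with per-instance jitter (±14) and Gaussian texture noise (amplitude
`noise` × 64 grey levels, default `noise` = 0.08); the palette is
configurable, as the engine itself is stain-agnostic. Replicate counts are
checked against the Poisson expectation (mean within 3 SE, dispersion
within χ² bounds over 20 replicates at 512×512).

What the scenes deliberately do **not** model: chromatin texture, stain
variation and bleed-through, scanner artifacts, out-of-focus regions,
touching-structure ambiguity at scale. Passing tests on these scenes
demonstrate that the machinery (training, selection, review, accounting)
is correct and that the workflow converges on colour-separable imagery;
they do not certify segmentation accuracy on real tissue.

## Embedding and diverse selection

Patch features are the channel-wise global average of the deepest encoder
(bottleneck) activations — 62 dimensions for the reference network. The
2-D layout uses UMAP (seeded, `n_neighbors` clamped to n−1 for small
sets; default 15, `min_dist` 0.1) or PCA as a cheap deterministic
alternative; the simulation loop defaults to PCA since the layout only
drives dispersion sampling. The interactive "click dispersed patches"
behaviour is automated as greedy farthest-point (max-min) selection, whose
min-pairwise-distance is within a factor 2 of optimal (classical
guarantee, verified against brute force for n ≤ 10). The first pick is
the point farthest from the layout centroid, making the selection
deterministic for every seed.

## Superpixels

SLIC-style k-means in (signal, position) space, via scikit-image, with
connectivity enforcement and consecutive relabelling. Two signal modes:

- **intensity** — the RGB image (SLIC's internal CIELAB conversion);
- **dl_features** — the model's full-resolution decoder activations,
  channel-standardized. SLIC is scale-invariant in the signal, so the
  feature-vs-spatial balance is governed entirely by compactness; the
  per-mode defaults are 10.0 (8-bit colour convention) and 0.3
  (standardized features).

Boundary adherence is quantified as **boundary recall**: the fraction of
ground-truth boundary pixels within a tolerance (default 2 px) of any
superpixel boundary; an empty ground-truth boundary returns an explicit
undefined marker (`None`), not zero. On *clean* synthetic scenes colour
superpixels are near-oracle — the colour signal is the ground-truth
definition — so learned features cannot beat them there. The regime where
learned features matter (and where the suite asserts they win, 5/5 seeded
scenes, sign-test p = 1/32) is heavy texture noise (`noise` = 0.45), where
the fine-tuned model denoises through spatial context while colour
clustering degrades. This mirrors real tissue, where raw colour is
ambiguous.

## The simulated session

`simulate_session` drives the full loop against a scene's ground truth.
Per round: select dispersed unconfirmed patches on the embedding →
oracle annotates them fully from ground truth → fine-tune on *all*
confirmed masks → predict and review a batch of unconfirmed patches.
Accepted and corrected masks are confirmed annotations and feed the next
round's training — this is what moves the session from manual-heavy to
review-heavy. The final round reviews every remaining patch, so coverage
is always complete. The default schedule is 3 rounds × 3 manual patches,
8 fine-tuning epochs per round, 2 pretraining epochs.

**Oracle.** A suggestion with pixel f-score ≥ `accept_threshold`
(default 0.9) is accepted unchanged at one click-cost; otherwise each
erroneous pixel is flipped to ground truth independently with probability
`correction_fidelity` (default 1.0), at a cost proportional to the number
of ground-truth structures intersecting the error set. A threshold above
1 never accepts; fidelity 1 corrections reproduce ground truth exactly —
together they form the perfect-oracle invariant used in the tests.

**Cost model** (configurable seconds): manual annotation 7 s per
structure — chosen to match the implied manual rate of the reference
nuclei task (~8.4 structures/min); accept 1 s per patch; correction 3 s
per erroneous structure (editing is faster than drawing). Training is
charged to the clock at a deterministic 0.5 s per patch-epoch and excluded
from human time (the annotator is dismissed during training). The
deterministic training charge — rather than measured wall time — is what
makes logs, reports and output files bit-reproducible per seed; real wall
time is still accumulated on the model object for diagnostics. The exact
identity human + training = total seconds is asserted on every session.

**Accounting.** M_t extrapolates the manual subset's rate to the task's
total structure count (8-connected components ≥10 px — the package's
counting convention); θ_t = ⌊M_t/QA_t⌋, the floor being the unique simple
rounding rule consistent with all three reference worked examples. Both
masks empty defines pixel f-score as 1.0 (perfect agreement on absence).
The efficiency curve bins completed structures (annotated, accepted or
corrected) per human-minute; Σ(rate × width) equals total structures by
construction.

## Problem sizes

The suite trains three-level width-4 networks on 64 px patches of 256²
scenes (seconds per session), and one full-scale check runs the reference
five-level network on a 1024² scene of ~300 nuclei — the package's
standard demonstration size, also used by `scripts/acceptance.py`.

## Known limitations

- No real-tissue validation data ships with the package; all quantitative
  claims are about the synthetic benchmark.
- The numpy network trains on CPU at small scale; it is not a route to
  training on whole-slide cohorts.
- The oracle's cost constants are explicit configuration, not measured
  human timings; θ_t values from simulation characterize the cost model
  as much as the workflow, and should be read comparatively (early vs
  late phase, manual vs assisted), not as field measurements.
- Pyramidal whole-slide formats are out of scope; inputs are RGB tiles.
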