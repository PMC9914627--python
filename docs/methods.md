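# Methods

## Model family and assumptions

The package implements one configurable encoder-decoder graph family for
binary segmentation. A variant is described declaratively (`ArchConfig`):
its skip topology (`unet`, `unet3plus`, `unet3plus_pruned`), encoder widths
(strictly increasing, at least three levels), attention flag, and a
`ConventionSet` of block-level choices. The forward contract is strict:
inputs are (N, C, H, W) with H and W divisible by 2^(N_levels−1); outputs
are sigmoid probabilities of the same spatial size, strictly inside (0, 1).

The pruned topology follows the per-level rule: decoder *i* > 1 fuses the
same-level encoder (conv branch), the next-deeper decoder (bilinear
upsample branch) and, when it exists, the encoder two levels shallower
(max-pool branch); decoder 1 fuses its encoder plus the decoders at levels
2..N−2. The bottleneck encoder output serves directly as "decoder N" —
there is no decoder block at level N, and construction as well as a test
assert this. With N = 5 the wiring is exactly

| decoder | sources |
|---|---|
| 1 | en1, de2, de3 |
| 2 | en2, de3 |
| 3 | en1, en3, de4 |
| 4 | en2, en4, de5 |

For the top decoder's source range two readings were possible (decoders
2..N−2, or also N−1); the literal index bound N−2 is adopted, so decoder 1
sees de2 and de3 at N = 5.

Each decoder branch projects its rescaled source to a common branch width
(default: the first encoder width) with a 3×3 conv; branches are
concatenated and fused by a 3×3 conv + batch norm, then CBAM when
attention is enabled, then ReLU — attention before the activation, since
the fused block is defined as attention applied to the conv+BN output.
CBAM uses reduction 16 and a 7×7 spatial kernel (the attention module's
customary defaults; the hidden width clamps to ≥1 with a logged warning
when the channel count is not divisible by the reduction). The perceptron
carries no biases; the spatial conv carries one.

## Conventions and calibration

A topology does not determine a parameter count; the remaining freedom is
captured in `ConventionSet` and resolved by calibration
(`prunet.calibration`). The documented finite space (48 candidates) is the
product of: conv biases on/off; batch norm in the projection branches
on/off; classic-decoder upsampling bilinear vs learned 2×2 transposed
conv; fusion output width = branch width × number of branches vs fixed
branch width; and a channel-reduction conv (none / 2×2 / 3×3) after the
classic decoder's upsampling. Branch upsampling in the full-scale family
is always bilinear — that is part of the architecture's own description,
not a free choice. Calibration minimises the summed absolute deviation (in
millions, at the two-decimal reporting precision) from the four published
full-width counts and reports the three small-width counts as a held-out
check under the same set; ties keep the earliest candidate in the
documented order.

The best-fit set — biases off, branch batch norm off, bilinear
upsampling, per-branch fusion width, no reduction conv — is the repo
default. Its counts are 31.38 / 26.96 / 21.65 / 21.67 M at widths 64..1024
against published 32.92 / 25.71 / 21.00 / 21.02 M, and 0.49 / 0.42 / 0.34 M
at widths 8..128 against 0.60 / 0.40 / 0.33 M. No candidate set does
better than a total fitted residual of 4.09 M, and the published figures
are mutually inconsistent under any uniform convention: conv-dominated
counts scale by ≈1/64 between the two width regimes, which the published
UNet pair violates (32.92/64 ≈ 0.51 ≠ 0.60) while the published full-scale
and pruned pairs satisfy it. The near-zero small-width residuals
(+0.02/+0.01 M) support the chosen conventions; the residual table is part
of every calibration result rather than a footnote. A consequence worth
stating plainly: the headline "36% / 18% fewer parameters" reductions hold
for the published counts themselves but not for any architecture this
convention space can assemble (the best-fit set yields 31% / 20%).

## Attention operators

Channel gate: Mc = σ(MLP(avgpool F) + MLP(maxpool F)) with one shared
two-layer perceptron C → max(C/r, 1) → C realised as 1×1 convs. Spatial
gate: Ms = σ(conv_k[mean_c F′; max_c F′]) with same padding. Composition:
F″ = Ms ⊗ (Mc ⊗ F). Correctness is established against loop-based dense
oracles (independent code in the tests) to 1e−6 over 100 random seeds in
float64, plus limiting cases (zero weights → 0.5 gates, saturating
weights → identity) and structural symmetries (channel gate invariant to
pixel permutation; spatial gate invariant to channel permutation).

## Metrics and loss

Pixel metrics come from exact confusion counts; overlap metrics from set
sizes. Conventions: binarization uses ≥ threshold; 0/0 ratio metrics
return 0 with a logged warning; two empty masks count as perfect overlap
(JS = DC = 1). F1 from counts and DC from overlaps are algebraically
identical for a single binarized pair (both 2TP/(2TP+FP+FN)) — asserted
on random pairs. Because published fold tables can nevertheless show
F1 ≠ DC, aggregation is always reported in two scopes: the arithmetic mean
of per-image metrics and the metrics of pooled pixel counts; the two
differ whenever image sizes or prevalences differ, and no attempt is made
to guess which scope an external table used.

The training loss is the soft Dice loss on probabilities (differentiable),
with smoothing ε = 1.0 by default — a common stabiliser for small or
empty foregrounds; batches average per-sample losses.

## Synthetic data

The generator emulates the statistical character of three modalities at a
configurable size (multiples of 16, matching the five-level divisibility
constraint): `skin_like` — one large irregular bright lesion (perturbed
ellipse whose polar radius is modulated by random Fourier harmonics 2–5,
roughness 0.25) on a smoothly textured background, foreground brighter by
≥0.15 mean intensity in ≥95% of samples; `breast_like` — a smaller,
darker, low-contrast lesion under multiplicative speckle (σ = 0.18);
`lung_like` — exactly two smooth bright regions confined to the left and
right halves, guaranteeing two connected components. Intensities are
replicated to three channels with a mild tint so every profile feeds the
same RGB-input network. Each sample derives from a per-sample child of one
seed sequence: datasets are pure functions of (profile, n, size, seed).

What the generator does *not* emulate: anatomical context, acquisition
artefacts, hair/probe occlusions, inter-annotator mask noise, or
multi-lesion and empty-mask images. Passing the desk-scale benchmark
therefore shows the implementation trains and generalises on a task of
this geometry — not clinical-grade performance. A global Otsu threshold
already reaches mean Dice ≈ 0.8 on the bright-lesion profile, which is
deliberate: the profile is meant to be learnable at desk scale, and the
trained network's held-out Dice (≥ 0.97 at the reference seeds) clearly
exceeds that baseline.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e−8) at learning rate 2e−4 with L2 weight decay
1e−4 folded into the gradient; batch size 8 (unstated in the protocol
source; configurable); 200 epochs by default with explicit desk-scale
overrides recorded in the run manifest; augmentation applied per sample
with probability 0.5 from {horizontal flip, vertical flip, right-angle
rotations}. "Iterations" is read as epochs — 200 gradient steps could not
traverse the reference datasets. Weight init is He-normal from a seed
sequence split so that enabling attention leaves every backbone weight
bitwise unchanged. k-fold splitting permutes indices once per (n, k, seed)
and partitions into folds differing by at most one in size; per-fold model
and shuffling seeds derive from the base seed and fold number. Training
aborts with a named error if the loss becomes non-finite. Everything is
NumPy, so runs are bit-reproducible; the `deterministic` flag is retained
in the manifest for provenance.

Desk-scale problem sizes used by the test suite: the learnability
benchmark trains the widths-8..128 pruned+CBAM model for 30 epochs on 60
bright-lesion samples at 64×64 and evaluates 20 held-out samples
(reference seeds 7/11/12/13); the pipeline smoke test cross-validates
k = 5 at a 5-epoch budget on 50 samples. Both finish in a few minutes on
one CPU.

## Numerical core

A minimal reverse-mode autograd on NumPy arrays (`prunet.nn`): convolution
via im2col and BLAS matmul (asymmetric same-padding supports even
kernels), batch norm with running statistics, max pooling by reshape with
argmax scatter, bilinear upsampling as two cached 1-D interpolation
matrices (half-pixel-centre convention), channel/global reductions for the
attention gates, and Adam. Backward closures receive the output gradient
as an argument so the graph is a pure child→parent DAG — no reference
cycles, which keeps per-step memory flat and lets intermediate buffers free
by reference counting. Gradients of every op are verified against central
finite differences in float64. Default arithmetic is float32;
`set_default_dtype` switches to float64 for oracle-grade comparisons.

## Known limitations

Single-class (binary) segmentation only; stride-1 convolutions with
max-pool downsampling (no strided or dilated convs); no deep supervision
or classification-guided module; no learning-rate schedules, early
stopping or mixed precision; CPU-oriented throughput (desk-scale inputs,
batch ≈ 8 at 64–256 px). The published parameter counts cannot all be
reproduced by any uniform convention set, as quantified above; parameter
ratios and orderings, not absolute published counts, are the reliable
comparison surface.
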