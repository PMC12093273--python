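# Methods

## Problem and pipeline

Whole-brain fluorescence microscopy of retrogradely labeled neurons (e.g.
fMOST at 0.35 × 0.35 × 2 µm/voxel) produces terabyte-scale volumes in which
each labeled neuron appears as a bright, roughly spherical soma a few
micrometers across. The goal is a brain-wide census: find every soma, assign
it to an atlas region, and report per-region counts normalized by the
whole-brain total.

somamapper implements this as four stages:

1. **Preprocessing** (`blocking`). The raw anisotropic volume is resampled to
   an isotropic grid by cubic interpolation (production default 0.35 µm),
   min–max normalized to [0, 1], and partitioned into non-overlapping
   sub-blocks (production default 512³ voxels; edge blocks are zero-padded so
   all blocks share one shape). Each block is reduced to a 2D maximum
   intensity projection (MIP) along the depth axis.
2. **Gating** (`classifier`). A small residual 2D network labels each MIP as
   soma-containing or background, so the expensive 3D stage only runs on the
   minority of blocks that need it.
3. **Segmentation** (`segmenter`, `infer`). A 3D encoder–decoder with
   shifted-window self-attention at its bottleneck produces per-voxel soma
   probabilities, binarized at 0.5. Large volumes are processed as
   overlapping sliding-window patches whose probability maps are averaged
   where they overlap.
4. **Detection and mapping** (`detect`, `atlas`, `metrics`). Connected
   components of the binary mask (default 26-connectivity) are the detected
   somata; each component's geometric center is its coordinate. Detections
   are carried into atlas space by a precomputed affine (registration
   estimation is an external tool's job), assigned to the region labeled at
   their containing voxel, and tabulated as counts and whole-brain fractions.

## Network architectures

**Classifier.** Stem 3×3 convolution lifting 1 → `stem_channels`, then four
stages; each stage is a 3×3 convolution followed by a stride-2 3×3
convolution, with an additive shortcut whose skip path is a 1×1 stride-2
projection. Downsampling is entirely by strided convolution; there is no max
pooling. Every convolution except the head is followed by batch
normalization and ReLU. Global average pooling, a fully connected layer and
a softmax over two classes finish the network. Default widths
(16, 32, 64, 128) with stem 16; inputs are resized to a fixed square
resolution (default 512, divisible by 2⁴) and assumed globally normalized to
[0, 1] — no per-image renormalization, since an all-background MIP carrying
only faint speckle must not be stretched to look like a bright soma.

**Segmenter.** Constant channel width K (default 16). Encoder: stem conv
(1 → K); stage 1 = one conv block + stride-2 conv (→ 1/2); stages 2 and 3 =
two conv blocks + stride-2 conv each (→ 1/4 → 1/8); stage 4 = four conv
blocks at 1/8. At the bottleneck, L (default 1) attention blocks, each two
sub-layers: window-partitioned multi-head self-attention over non-overlapping
ΔH×ΔW×ΔD windows, then the same with features cyclically shifted by half a
window (attention-masked so positions wrapped across the volume edge do not
attend to each other). Each sub-layer is layer norm → attention → residual →
layer norm → feed-forward (ratio 4) → residual, with a learned
relative-position bias per head (configurable off). The cyclic shift is
suppressed along any axis whose window already spans the full feature
extent, where shifting is provably a no-op. Decoder: two conv blocks, then
three 2× upsampling stages (transposed conv, kernel 2 stride 2), each
concatenating the encoder feature at the matching resolution (1/4, 1/2,
1/1 — the encoder's 1/4-scale feature is transient in the stage bookkeeping
but is the natural middle skip tap) followed by a conv block; 1-channel 1×1
head with sigmoid.

Both networks run on a small reverse-mode autodiff engine (`somamapper.nn`)
written on numpy: broadcasting arithmetic, matmul, N-dimensional strided
convolution (sliding-window view + einsum; the input gradient is the
stride-dilated correlation with the flipped kernel), batch/layer norm,
window/shift tensor ops, and SGD/Adam. All gradients are validated against
central finite differences in the test suite. Checkpoints are saved as
`.npz` weight archives with a JSON config sidecar.

## Training procedures

- Classifier: SGD, default lr 1e-4, batch 8, ≤ 100 epochs, cross-entropy on
  the softmax output. After each epoch the validation AUC (rank-based
  Mann–Whitney formulation) is computed; training stops after 10 epochs
  without improvement (> 1e-4 over the running best) and the best-AUC
  weights are kept. On AUC ties the later weights win: the ranking is
  identical but longer-trained probabilities are better calibrated for the
  fixed 0.5 decision threshold.
- Segmenter: Adam, default lr 1e-4 multiplied by 0.9 every 10 epochs, batch
  1, ≤ 200 epochs × 80 iterations, soft Dice loss
  `1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1e-5. Augmentation per iteration:
  a random crop (default 128³, applied jointly to image and label) and
  left-right / up-down flips, each with probability 0.5. Validation Dice
  (binarized at 0.5) is monitored with patience 30; best-Dice weights kept.

### Smoke-scale study conditions

CPU-scale runs (tests and `scripts/acceptance.py`) use deliberately tiny
conditions chosen once: 32³–64³ phantoms; classifier with stem 8, widths
(8, 16, 32, 64), 64×64 inputs, lr 0.05, ≤ 20 epochs on 40–52 MIPs;
segmenter with K = 8, window 2³, 2 heads, crop 32, lr 3e-3,
6 iterations/epoch, ≤ 30 epochs on 6 training blocks. The larger learning
rates are what make networks this narrow converge within tens of epochs;
the production defaults above remain the full-scale settings. Under these
conditions the tiny segmenter reaches held-out phantom Dice ≳ 0.95 and the
classifier perfect validation AUC.

## Phantom generator

The generator emulates the regimes that make real whole-brain data hard:
densely placed somata of varying radius (default 3–6 voxels) and brightness
(default 0.4–1.0), soma-mimicking background speckles (radius below the
smallest true soma, present in the image but never in the mask), a
multiplicative illumination ramp along x, and additive Gaussian sensor
noise, all clipped to [0, 1]. Somata are hard balls (mask support
‖p − c‖ ≤ r at integer voxel centers) with a 1-voxel cosine intensity
rolloff from full peak at r−1 to half peak at r, so the ground-truth mask
stays binary while edges are soft. A configurable fraction of somata is
placed as touching pairs at center distance 1.2·(r₁+r₂)/2 to exercise the
known closely-adjacent-somata failure mode; all other somata are placed
with a ≥ 2-voxel mask gap (rejection sampling with a retry budget; an
overcrowded spec raises rather than degrading silently). One RNG stream per
seed, drawn in documented order, makes samples bit-reproducible.

What the phantom does **not** model: optics (no PSF convolution), neurites,
vasculature, tissue autofluorescence texture, stitching seams, or
anisotropic blur. Passing phantom tests therefore demonstrates the
correctness of the pipeline's mechanics and the trainability of the
networks, not field performance on real fMOST data.

## Matching and metrics

Detected and ground-truth centroids are matched one-to-one using candidate
pairs within a Euclidean threshold (default 10 px — the average soma radius;
"below the threshold" is read inclusively, so a pair at exactly 10.0
matches). Among feasible matchings the implementation maximizes the number
of pairs and then minimizes the total distance, solved as a rectangular
assignment problem. A global ascending-distance greedy rule was considered
and rejected: on ~8% of random small instances greedy disagrees with the
optimal assignment in cardinality or total distance, whereas the assignment
formulation is exactly reproducible by exhaustive enumeration (the test
oracle) and reduces to per-point nearest matching in the conflict-free case
typical of well-separated somata.

Detection precision/recall follow, by default, the *as-printed* convention
of the source formulas — precision = N_TP/N_GT, recall = N_TP/N_detected —
which swaps the conventional roles of the two names. Both conventions are
exposed (`convention="as_printed" | "conventional"`); F1 is the harmonic
mean and identical under either. Other conventions: Dice of two empty masks
is 1.0 (empty vs non-empty is 0.0); an average matched distance over zero
matches raises rather than returning 0 or ∞; AUC with a single class
raises; ties in AUC scores count 1/2 via midranks.

## Numerical and design choices

- Partition edges: zero padding (keeps block shapes uniform for the
  networks); `reassemble` crops pads and is bit-exact.
- Patch stitching: overlap resolution by averaging probabilities — unlike
  last-write-wins it is invariant to patch enumeration order.
- Binarization threshold 0.5 on the sigmoid/softmax outputs.
- Resampling: `scipy.ndimage.zoom` cubic splines, output dimension
  `round(dim × voxel/target)`, results clipped to the input range to remove
  interpolation overshoot.
- Block-boundary consolidation: per-block masks are re-embedded in the
  global frame and connected components recomputed, so a soma straddling a
  block face yields one detection, not two.
- Atlas lookup: floor(physical / voxel_size); points on the max face or on
  label 0 are reported unassigned, and counts + unassigned always conserve
  the input size. Hemisphere flags use a configurable midline plane.
- Early-stopping "no improvement" means less than 1e-4 gain over the
  running best for both networks.

## Known limitations

- No splitting of merged adjacent somata (a touching pair segments into one
  component by design of the 26-connectivity default); watershed-style
  post-processing is out of scope.
- The numpy engine is single-threaded BLAS-bound and intended for the
  tiny-to-moderate configurations above, not for 512³ production blocks.
- Registration (rigid/affine/landmark) must be estimated externally; only
  its exported point transform is consumed.
- Phantom defaults for soma density and SNR are plausible but uncalibrated
  against any quantitative measurement of real data.
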