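# Methods

## Problem

Pork marbling — the visible intramuscular fat (IMF) on the cut surface
of the longissimus dorsi (LD) muscle — is a meat-quality trait used in
breeding programs. Quantifying it from smartphone images requires a
pixel-wise segmentation of marbling, which is hard because the targets
are thin (down to 2 px flecks), sparse (typically 0.5–3.5 % of the
image), multi-scale (single flecks to multi-thousand-pixel stripes) and
low-contrast against the pink lean. `marblingnet` implements a
patch-based training framework around a shallow encoder–decoder network
with a multi-scale context extractor, plus the downstream trait
quantification (marbling ratio, per-piece statistics, regression
against IMF content and visual score).

## Pipeline

1. **Preprocessing.** Images are smoothed with an edge-preserving
   mean-shift filter (spatial radius 5 px, color radius 10 intensity
   units) to suppress specular reflections on the wet meat surface
   while keeping marbling edges. The filter iteratively replaces each
   pixel's color by the mean of the spatial neighbours within the color
   radius — the Comaniciu–Meer range-mean iteration with a fixed
   spatial window. It is implemented in numpy in
   `data_io.mean_shift_filter`; the contract (dimension preservation,
   fixed point on constant images, within-region variance reduction) is
   property-tested.
2. **Patch slicing.** Training images (canonically 400 × 800) are cut
   into non-overlapping s × s tiles left-to-right, top-to-bottom:
   128 / 32 / 8 / 2 patches at s = 50 / 100 / 200 / 400. The default
   full-scale patch size is 200, the best-performing setting of the
   patch-size sweep. Validation/inference always runs on whole images —
   never patched, never augmented.
3. **Augmentation** (online, per epoch, per sample, identical geometric
   transform on image and mask; masks nearest-neighbour): horizontal
   flip (p = 0.5), counterclockwise 90° rotation (p = 0.5, square tiles
   only), free rotation ±180° (p = 0.2), then shift ±0.0625 of the side
   and scale 1 ± 0.2 (p = 0.2; the source protocol lists the magnitudes
   but not this probability, so the free-rotation value is reused).
   Exposed borders are filled with black/label 0, matching the black
   acquisition board.
4. **Network.** Input patches are bilinearly up-sampled ×2, then pass a
   four-block encoder (the first ten VGG-16 convolutions: 2+2+3+3 convs
   of widths 64/128/256/512, each 3×3 conv + BN + ReLU, 2×2 stride-2
   max pooling after the first three blocks), giving a feature pyramid
   of sides 400/200/100/50 for a 200×200 patch. At the encoder top a
   dense atrous convolution (DAC) block — four cascaded branches with
   dilation stacks (1), (3), (1,3), (1,3,5), i.e. receptive fields
   3/7/9/19, each branch but the first closed by a 1×1 conv, residual
   sum with the input — is followed by residual multi-kernel pooling
   (RMP): max pools with 2/3/5/6 windows, squeezed to 1 channel,
   resized back and concatenated (+4 channels). The decoder mirrors
   U-Net: 2×2 transposed-conv up-sampling (a bilinear+conv option
   exists), concatenation of the matching encoder feature, two 3×3
   conv+BN+ReLU, and a final 1×1 conv to two classes. With the context
   module off and up-sampling off the model reduces to a VGG-16 U-Net,
   spanning the ablation grid. The full-width model has ≈ 28 M
   parameters.
5. **Loss.** The composite CE-LS loss `L = L_ce + λ·L_ls` (λ = 1, the
   best-performing weight). `L_ce` is mean pixel-wise cross-entropy.
   `L_ls` is the Lovász–Softmax loss: for each class c the error vector
   m_i = 1 − p_i(c) if y_i = c else p_i(c) is sorted in decreasing
   order and dotted with the discrete gradient of the Jaccard loss over
   sorted prefix sets; the class losses are averaged over both classes,
   classes absent from the target included (with m_i = p_i(c)). For
   hard predictions this equals the mean per-class Jaccard loss; for
   soft ones it is the Lovász extension — the tightest convex
   surrogate — verified in the tests against an exact threshold-integral
   oracle. Soft-dice and focal losses are provided for comparison.
   Pixels of a mini-batch are flattened jointly before the sort, which
   stabilizes the sorted-gradient estimate at batch size 4; sorting
   ties break by original index; log probabilities are clamped at
   1e−12. The loss is computed at the up-sampled (×2) resolution
   against nearest-neighbour-up-sampled masks; predictions are returned
   at native resolution by bilinearly down-sampling the softmax
   probabilities and arg-maxing (ties → background).
6. **Optimization.** Adam (β = 0.9/0.999, no weight decay), batch 4,
   poly learning-rate decay lr = base_lr·(1 − epoch/num_epoch)^power
   with power 1, stepped per epoch; full-scale defaults base_lr = 1e−4
   and 400 epochs. Early stopping monitors whole-image validation
   marbling IoU (micro-aggregated); the checkpoint with the best
   validation IoU is kept. Five-fold cross-validation splits the index
   into folds differing by at most one record (173 records → 35/35/35/
   34/34) after a seeded shuffle.
7. **Metrics.** IoU, precision, recall and F1 of the marbling class
   from pixel totals pooled over the whole validation set (micro
   aggregation), not per-image averages. Both-empty IoU is defined as
   1.0 with a warning. The recall denominator is TP + FN (the printed
   formula in the source duplicates the precision denominator; the
   prose definition is followed).
8. **Traits.** Connected components of the predicted mask
   (8-connectivity by default — diagonally touching flecks count as one
   piece) give per-piece pixel counts and proportions *of the whole
   image*; the marbling *ratio* divides marbling pixels by muscle
   pixels (muscle = lean + marbling, delimited from the black board by
   a max-channel threshold of 40/255 plus hole filling). Ordinary least
   squares relates the ratio to reference IMF content and marbling
   score.

## Numerical backend

The network, its layers and the training loop run on a small
reverse-mode automatic-differentiation engine over numpy float32 arrays
(`marblingnet.autograd`): im2col convolution (with dilation), 2×2
stride-2 transposed convolution, stride-=-window max pooling with -inf
edge padding, batch normalization with running statistics, separable
bilinear resizing, concatenation and cropping. Every operation's
gradient is finite-difference tested. Inference runs with the tape
disabled. Forward passes are deterministic for fixed weights;
initialization is He-normal from a seeded generator (ImageNet-pretrained
encoder weights can be loaded from a local `.npz` but are not bundled).

## Synthetic data

The generator (`marblingnet.synthetic`) emulates the structure of the
real dataset: a near-black board, one smooth star-convex pink lean blob
covering ≥ 50 % of the frame with low-frequency multiplicative texture,
and marbling drawn as tiny elliptical flecks (2–32 px, log-uniform) and
smoothed random-walk stripes (width 1–4 px) rendered creamy-white with
soft edges and low-but-positive contrast to the lean. Two rendering
conventions keep those properties exact: the marbling alpha map uses an
absolute scale (a blurred isolated pixel peaks at 0.32 and is clipped
to full opacity), so even a 2-px fleck is white-ish rather than being
washed out by normalization against larger pieces; and the lean texture
amplitude (±18 % multiplicative) is capped so the brightest lean stays
below marbling brightness in every channel. The realized
marbling proportion is constrained to the requested range (default
0.5–3.5 % of the image, sampled right-skewed, echoing the published
distribution in which ~90 % of images fall below 3.5 %). A few pure
white specular spots are painted on the lean as reflection noise and
never enter the ground-truth mask. Synthetic IMF is linear in the
marbling ratio, `imf = 60·ratio + 1 + N(0, 0.45)` percent by default —
slope and noise chosen so that IMF spans a realistic 1–5 % with a
correlation strength comparable to real spectroscopy references — and
the synthetic score is a monotone binning of the ratio onto the 1–10
scale.

What the generator does *not* model: camera optics, illumination
gradients, JPEG artifacts, muscle-fiber texture anisotropy, connective
tissue, or annotation noise. Passing the scaled-down training tests
therefore demonstrates that the pipeline can learn thin/sparse
low-contrast targets end-to-end, not that it reaches the published
accuracy on real images.

## Scaled-down protocol

The published full-scale protocol (five folds × 400 epochs at width 64
on 173 images) is GPU-scale. The package's CPU test protocol, fixed as
its own study condition, is: width-reduced network (encoder
6/12/24/48, decoder 24/12/6 — roughly a tenth of the full widths), 40
synthetic 100 × 200 training images and 10 held out, patch size 50,
up-sampling ×2, batch 4, CE-LS loss, Adam with base_lr 2e−3 and poly
decay (the full protocol's 1e−4 over 400 epochs, rescaled for a
schedule some fifty times shorter), trained for the full 8 epochs with
the best held-out-IoU checkpoint kept (at this schedule length early
stopping has nothing to guard against, so its patience equals the
epoch budget; the full-scale default is patience 30). The patch-free comparison arm
disables patching and input up-sampling (the ablation baseline row)
under the same budget. The acceptance suite requires held-out IoU
≥ 0.5 for at least 4 of 5 seeds and that the patch-based arm's mean
IoU is at least the patch-free arm's.

## Design choices where the source was open

- **Loss grid.** The source does not say on which grid the loss lives;
  it is computed at the up-sampled resolution (nearest-up-sampled
  masks), keeping the surrogate aligned with what the decoder produces.
- **DAC branch composition.** The branch prose ("increases from 1 to 1,
  3, 5") is ambiguous; the published receptive-field sequence 3/7/9/19
  is treated as normative, realized as dilation stacks (1), (3), (1,3),
  (1,3,5).
- **Early stopping.** Named but unparameterized in the source; patience
  30 epochs, min-delta 0 at full scale (3 at test scale).
- **Decay granularity.** Poly decay is stepped per epoch, as the
  formula is written in epochs.
- **Skip connections** concatenate (not add), per the U-Net strategy.
- **Fold sizes.** A fixed 35/138 split cannot hold for all five folds
  of 173; the first n mod k folds receive the extra record.
- **Muscle denominator.** Whether the muscle area includes marbling
  pixels is unstated; it does here (lean + marbling), so the ratio is
  bounded by 1 and insensitive to segmentation of the lean/fat border.
- **Augmented-count bookkeeping.** The source's "92,736 patches"
  estimate is not derivable from the stated probabilities and is
  treated as descriptive; augmentation is online and effectively
  unbounded.

## Degenerate inputs and conventions

Images are row-major, origin top-left, 0-based half-open coordinate
ranges. Masks are palette PNGs: foreground RGB (128, 0, 0), background
(0, 0, 0); palette matching is exact with an optional per-channel
tolerance for compressed masks. Inputs whose up-sampled sides are not
divisible by 8 are reflection-padded internally and cropped back. Tied
class scores predict background. Empty-union IoU is 1.0 (flagged);
zero-denominator precision/recall/F1 are 0.0 (flagged). Marbling pixels
outside the muscle mask are clipped with a warning. Exact
reproducibility holds for fixed seeds on a given BLAS; across BLAS
builds, float32 reductions may reorder and flip individual argmax ties.

## Known limitations

- The numpy backend is single-threaded GEMM-bound; full-width training
  at the published scale is impractical on CPU (a forward pass at
  200 × 200 takes seconds). The architecture is exact, so weights
  trained elsewhere can be loaded from `.npz`.
- The mean-shift filter omits the pyramid (coarse-to-fine) stage of
  pyramidal implementations; for the 400 × 800 working resolution the
  single-scale filter meets the same contract.
- Free rotation and shift/scale change the foreground pixel count near
  borders (and scaling changes it quadratically); flips and 90°
  rotations are exactly count-preserving.
- The synthetic IMF model is linear by construction; the regression
  tests validate recovery, not biological linearity.
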