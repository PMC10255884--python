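# marblingnet

Segmentation and quantification of **pork marbling** — the visible
intramuscular fat (IMF) on the cut surface of the longissimus dorsi
(LD) muscle — from ordinary RGB images, for meat-quality phenotyping in
pig breeding.

Marbling is a hard segmentation target: flecks down to 2 px, stripes a
few pixels wide, 0.5–3.5 % of the image, low contrast against the pink
lean. `marblingnet` implements a patch-based training framework around
a shallow encoder–decoder network with a multi-scale context extractor:

- **Patch-based training with input up-sampling**: training images are
  sliced into non-overlapping s×s patches (a 400×800 image gives
  128/32/8/2 patches at s = 50/100/200/400) and each patch is
  bilinearly up-sampled ×2 before entering the network; inference runs
  on whole images.
- **Marbling-Net**: a VGG-16-backboned U-Net (first ten convolutional
  layers as the encoder, widths 64/128/256/512) with a context
  extractor at the encoder top — a dense atrous convolution (DAC)
  block whose four cascaded branches realize receptive fields
  3/7/9/19, then residual multi-kernel pooling (RMP) with 2/3/5/6
  windows — and a skip-connected decoder.
- **CE-LS loss**: `L = L_ce + λ·L_ls` with λ = 1, where `L_ls` is the
  Lovász–Softmax loss — the Lovász extension of the per-class Jaccard
  loss `ΔJ_c` evaluated on the sorted error vector
  `m_i(c) = 1 − p_i(c)` if `y_i = c` else `p_i(c)` — which directly
  optimizes IoU and counters the extreme foreground/background
  imbalance.
- **Protocol**: Adam, batch 4, poly decay
  `lr = base_lr·(1 − epoch/num_epoch)^power` (base 1e−4, power 1),
  early stopping on validation marbling IoU, five-fold
  cross-validation; micro-aggregated IoU / precision / recall / F1.
- **Traits**: marbling ratio (marbling ÷ muscle pixels), per-piece
  connected-component statistics, and OLS regression of the ratio
  against IMF content and visual marbling score.

The whole stack — including the network and its training — runs on a
small numpy autodiff engine shipped with the package, so everything is
testable on one CPU. A seeded synthetic generator reproduces the
statistical structure of real LD images (board/lean/marbling, piece
size spectrum, specular noise) for end-to-end tests without any
download.

## Worked example

```python
import numpy as np
from marblingnet import MarblingSegmenter, SyntheticParams, generate_dataset
from marblingnet.traits import regress, trait_report, muscle_mask

params = SyntheticParams.for_size(100, 200)
ds = generate_dataset(50, params=params, seed=7)
images = [s.image for s in ds.samples]
masks = [s.mask for s in ds.samples]

seg = MarblingSegmenter(seed=0)            # width-reduced CPU defaults
seg.fit(images[:40], masks[:40], validation_data=(images[40:], masks[40:]))
print(f"held-out marbling IoU: {seg.score(images[40:], masks[40:]):.3f}")

pred = seg.predict(images[40:41])[0]
rep = trait_report("img_0040", pred, muscle_mask(images[40]))
print(f"predicted marbling ratio: {rep.marbling_ratio:.4f}  "
      f"pieces: {len(rep.piece_counts)}  largest piece: {max(rep.piece_counts)} px")

fit = regress(ds.ratios, ds.imf)
print(f"IMF ~ ratio: slope {fit.slope:.1f}, intercept {fit.intercept:.2f}, "
      f"R^2 {fit.r_squared:.3f} (n={fit.n})")
```

Output (a few minutes on one CPU):

```
held-out marbling IoU: 0.948
predicted marbling ratio: 0.0288  pieces: 8  largest piece: 207 px
IMF ~ ratio: slope 53.7, intercept 1.18, R^2 0.549 (n=50)
```

The segmenter recovers 95 % IoU against the synthetic ground truth;
the predicted mask of one held-out image carries 2.88 % marbling over
the muscle surface in 8 pieces; and the regression of synthetic IMF on
the marbling ratio recovers a slope near the generating value of 60
(the moderate R² at n = 50 reflects the injected measurement noise).

`MarblingSegmenter` is a scikit-learn style estimator
(`get_params`/`set_params`/`clone` work); the underlying modules
(`data_io`, `patching`, `network`, `losses`, `training`, `evaluation`,
`traits`, `synthetic`) are importable directly, and a thin CLI covers
the shell workflow:

```bash
marbling synth --n 100 --out data/ --seed 7 --size 400x800
marbling train --config cfg.yaml --fold 0
marbling predict --checkpoint runs/fold0/best.npz --images data/ --out preds/
marbling eval --predictions preds/ --references data/
marbling traits --masks preds/ --images data/ --out traits.csv
marbling regress --traits-csv traits.csv --reference-csv data/index.csv
```

See `docs/methods.md` for the model, its assumptions, the synthetic
generator, and every numerical convention.

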