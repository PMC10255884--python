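"""The Marbling-Net: a shallow VGG-16-backboned encoder–decoder with a
multi-scale context extractor, for two-class marbling segmentation.

Architecture
------------
The input patch is first up-sampled x2 with bilinear interpolation to
enlarge thin marbling detail, then passed through four encoder blocks
(the first ten convolutional layers of VGG-16: 2+2+3+3 convs of widths
64/128/256/512, each conv 3x3 + BN + ReLU, with 2x2 stride-2 max
pooling after the first three blocks).  A context extractor — a dense
atrous convolution (DAC) block whose four cascaded branches realize
receptive fields 3/7/9/19, followed by a residual multi-kernel pooling
(RMP) block with 2/3/5/6 windows — sits at the encoder top.  The
decoder mirrors U-Net: each stage up-samples x2 (2x2 transposed
convolution by default), concatenates the matching encoder feature and
applies two 3x3 conv+BN+ReLU; a final 1x1 convolution emits per-pixel
class scores at the up-sampled resolution.

With the context module disabled and ``upsample_factor=1`` the model
reduces to a VGG-16-backboned U-Net, which is the ablation baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor

__all__ = ["ModelConfig", "MarblingNet", "DacBlock", "RmpBlock",
           "receptive_field", "predict_image", "predict_proba",
           "save_checkpoint", "load_checkpoint"]


def receptive_field(stack: Sequence[tuple[int, int]]) -> int:
    """Receptive field of a cascade of dilated convolutions.

    ``stack`` is a list of (kernel, dilation) pairs; the result is
    ``1 + sum (kernel-1) * dilation``.  An empty stack is the identity
    (receptive field 1).
    """
    rf = 1
    for kernel, dilation in stack:
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError(f"kernel must be odd and positive, got {kernel}")
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        rf += (kernel - 1) * dilation
    return rf


@dataclass
class ModelConfig:
    """Hyperparameters of the Marbling-Net, including ablation toggles.

    ``encoder`` lists (conv count, output channels) per block; the
    default is the first ten convolutional layers of VGG-16.  The
    ablation grid of the original study is spanned by
    ``upsample_factor`` (2 = full model, 1 = no input up-sampling) and
    ``use_context_module``.
    """
    upsample_factor: int = 2
    encoder: list[tuple[int, int]] = field(
        default_factory=lambda: [(2, 64), (2, 128), (3, 256), (3, 512)])
    use_context_module: bool = True
    rmp_pool_sizes: list[int] = field(default_factory=lambda: [2, 3, 5, 6])
    dac_branch_rates: list[tuple[int, ...]] = field(
        default_factory=lambda: [(1,), (3,), (1, 3), (1, 3, 5)])
    decoder_channels: list[int] = field(default_factory=lambda: [256, 128, 64])
    num_classes: int = 2
    decoder_upsample: str = "deconv"  # or "bilinear"
    pretrained_encoder: str | None = None  # path to an .npz of encoder weights
    seed: int = 0

    def __post_init__(self):
        if self.upsample_factor not in (1, 2):
            raise ValueError("upsample_factor must be 1 or 2")
        if len(self.encoder) != len(self.decoder_channels) + 1:
            raise ValueError("encoder block count must equal decoder stage count + 1")
        if self.decoder_upsample not in ("deconv", "bilinear"):
            raise ValueError("decoder_upsample must be 'deconv' or 'bilinear'")

    @classmethod
    def scaled(cls, base_width: int = 4, **kwargs) -> "ModelConfig":
        """A width-reduced configuration (encoder w/2w/4w/8w) for CPU use."""
        w = base_width
        kwargs.setdefault("encoder", [(2, w), (2, 2 * w), (3, 4 * w), (3, 8 * w)])
        kwargs.setdefault("decoder_channels", [4 * w, 2 * w, w])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder"] = [list(b) for b in self.encoder]
        d["dac_branch_rates"] = [list(r) for r in self.dac_branch_rates]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder"] = [tuple(b) for b in d["encoder"]]
        d["dac_branch_rates"] = [tuple(r) for r in d["dac_branch_rates"]]
        return cls(**d)


class DacBlock(nn.Module):
    """Dense atrous convolution block (cascade mode, residual sum).

    Four parallel branches of stacked 3x3 atrous convolutions with
    dilation-rate stacks (1), (3), (1,3) and (1,3,5), giving receptive
    fields 3, 7, 9 and 19; every branch except the first ends in a 1x1
    convolution.  The output is the input plus the four branch outputs,
    so zero-weight branches reduce the block to the identity.
    """

    def __init__(self, ch: int, branch_rates: Sequence[tuple[int, ...]],
                 rng: np.random.Generator):
        super().__init__()
        self.branches = []
        for i, rates in enumerate(branch_rates):
            layers: list[nn.Module] = []
            for r in rates:
                layers += [nn.Conv2d(ch, ch, 3, dilation=r, rng=rng), nn.ReLU()]
            if i > 0:
                layers += [nn.Conv2d(ch, ch, 1, rng=rng), nn.ReLU()]
            self.branches.append(nn.Sequential(*layers))

    def forward(self, x: Tensor) -> Tensor:
        out = x
        for branch in self.branches:
            out = out + branch(x)
        return out


class RmpBlock(nn.Module):
    """Residual multi-kernel pooling block.

    Max-pools the input with windows 2/3/5/6 (stride = window), squeezes
    each pooled map to one channel with a 1x1 convolution, up-samples it
    back bilinearly and concatenates all four maps onto the input:
    C channels in, C + 4 out, spatial size unchanged.
    """

    def __init__(self, ch: int, pool_sizes: Sequence[int], rng: np.random.Generator):
        super().__init__()
        self.pool_sizes = list(pool_sizes)
        self.squeezes = [nn.Conv2d(ch, 1, 1, rng=rng) for _ in self.pool_sizes]

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[2:]
        if min(h, w) < max(self.pool_sizes):
            raise ValueError(f"spatial side {min(h, w)} smaller than the largest "
                             f"pooling window {max(self.pool_sizes)}")
        maps = [x]
        for k, squeeze in zip(self.pool_sizes, self.squeezes):
            y = ag.max_pool(x, k)
            y = squeeze(y)
            maps.append(ag.bilinear_resize(y, (h, w)))
        return ag.concat(maps, axis=1)


class _DecoderStage(nn.Module):
    """x2 up-sampling, skip concatenation, then two 3x3 conv+BN+ReLU."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, mode: str,
                 rng: np.random.Generator):
        super().__init__()
        self.mode = mode
        if mode == "deconv":
            self.up = nn.ConvTranspose2x2(in_ch, out_ch, rng=rng)
        else:
            self.up = nn.Conv2d(in_ch, out_ch, 3, rng=rng)
        self.convs = nn.Sequential(nn.conv_bn_relu(out_ch + skip_ch, out_ch, rng),
                                   nn.conv_bn_relu(out_ch, out_ch, rng))

    def forward_with_skip(self, x: Tensor, skip: Tensor) -> Tensor:
        if self.mode == "deconv":
            x = self.up(x)
        else:
            x = ag.bilinear_resize(x, (x.data.shape[2] * 2, x.data.shape[3] * 2))
            x = self.up(x)
        return self.convs(ag.concat([x, skip], axis=1))


class MarblingNet(nn.Module):
    """Encoder–decoder segmentation network for pork marbling.

    ``forward`` maps a float32 (N, 3, h, w) batch in [0, 1] to
    (N, num_classes, h*f, w*f) class scores, f the up-sample factor.
    Sides whose up-sampled size is not divisible by 8 (three pooling
    stages) are reflection-padded internally and the scores cropped
    back.
    """

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        in_ch = 3
        self.enc_blocks = []
        for n_conv, out_ch in cfg.encoder:
            layers = []
            for _ in range(n_conv):
                layers.append(nn.conv_bn_relu(in_ch, out_ch, rng))
                in_ch = out_ch
            self.enc_blocks.append(nn.Sequential(*layers))
        top_ch = cfg.encoder[-1][1]
        if cfg.use_context_module:
            self.dac = DacBlock(top_ch, cfg.dac_branch_rates, rng)
            self.rmp = RmpBlock(top_ch, cfg.rmp_pool_sizes, rng)
            top_ch += len(cfg.rmp_pool_sizes)
        self.dec_stages = []
        skip_chs = [ch for _, ch in cfg.encoder[-2::-1]]  # 256, 128, 64
        in_ch = top_ch
        for out_ch, skip_ch in zip(cfg.decoder_channels, skip_chs):
            self.dec_stages.append(
                _DecoderStage(in_ch, skip_ch, out_ch, cfg.decoder_upsample, rng))
            in_ch = out_ch
        self.head = nn.Conv2d(in_ch, cfg.num_classes, 1, rng=rng)
        if cfg.pretrained_encoder:
            self._load_encoder_weights(cfg.pretrained_encoder)

    def _load_encoder_weights(self, path: str) -> None:
        with np.load(path) as npz:
            state = {k: npz[k] for k in npz.files}
        for i, block in enumerate(self.enc_blocks):
            for name, p in block.named_parameters(f"enc_blocks.{i}."):
                if name in state:
                    if p.data.shape != state[name].shape:
                        raise ValueError(f"pretrained weight {name} has shape "
                                         f"{state[name].shape}, expected {p.data.shape}")
                    p.data = state[name].astype(np.float32)

    # ------------------------------------------------------------------
    def forward(self, x, return_features: bool = False):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        f = self.cfg.upsample_factor
        n, c, h, w = x.data.shape
        hu, wu = h * f, w * f
        if f > 1:
            x = ag.bilinear_resize(x, (hu, wu))
        ph, pw = (-hu) % 8, (-wu) % 8
        if ph or pw:  # reflection-pad the (gradient-free) input
            x = Tensor(np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)),
                              mode="reflect"))
        feats = []
        for i, block in enumerate(self.enc_blocks):
            if i > 0:
                x = ag.max_pool(x, 2)
            x = block(x)
            feats.append(x)
        if self.cfg.use_context_module:
            x = self.dac(x)
            x = self.rmp(x)
            feats[-1] = x
        for stage, skip in zip(self.dec_stages, feats[-2::-1]):
            x = stage.forward_with_skip(x, skip)
        logits = self.head(x)
        if ph or pw:
            logits = ag.crop2d(logits, 0, 0, hu, wu)
        if return_features:
            return logits, feats
        return logits


def predict_proba(model: MarblingNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel marbling probability map at the image's own resolution.

    The whole image (H, W, 3 uint8) is run through the network without
    patching; softmax probabilities at the up-sampled resolution are
    bilinearly resized back to (H, W).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    x = (img.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]
    was_training = model.training
    model.eval()
    try:
        with ag.no_grad():
            logits = model.forward(x)
            z = logits.data[0].astype(np.float64)
            z -= z.max(axis=0, keepdims=True)
            e = np.exp(z)
            probs = e / e.sum(axis=0, keepdims=True)
            probs = ag.bilinear_resize(Tensor(probs[None]), img.shape[:2]).data[0]
    finally:
        model.train(was_training)
    return probs


def predict_image(model: MarblingNet, image: np.ndarray) -> np.ndarray:
    """Segment a whole image into a {0,1} marbling mask (ties -> background)."""
    probs = predict_proba(model, image)
    return (probs[1] > probs[0]).astype(np.uint8)


def save_checkpoint(model: MarblingNet, path) -> None:
    """Persist weights and the embedded ModelConfig to an .npz file."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> MarblingNet:
    with np.load(path) as npz:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(npz["__config__"].tobytes()).decode()))
        state = {k: npz[k] for k in npz.files if k != "__config__"}
    model = MarblingNet(cfg)
    model.load_state_dict(state)
    return model
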