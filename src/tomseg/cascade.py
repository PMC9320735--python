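"""The two-stage hard-pixel cascade.

Stage 1 is a small depthwise-separable network that segments the RGB image at
low cost.  Its per-pixel confidence (the maximum class probability, "Premax")
splits pixels into easy (confidence > t1) and hard (<= t1).  Stage 2 then
receives three inputs - the full RGB image, the RGB image with easy pixels
zeroed, and the mean-centered depth map with easy pixels zeroed - so the
expensive network and the depth signal are spent only on the ambiguous
regions (typically thin stems, branches and suckers, and crossings where a
far stem mimics a sucker).  Stage 2's output is the final segmentation;
stage 1's output exists only to locate hard pixels.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .blocks import (ArchVariantFlags, DEFAULT_FLAGS, ClassifyHead, ConvNorm,
                     DSConvBlock, Bottleneck, PyramidPooling, Upsampler,
                     make_feature_block)
from .io import RGBDSample, center_depth
from .nn import Module, Tensor

__all__ = [
    "CascadeConfig", "Stage1", "Stage2", "CascadeNet", "build_stage1",
    "build_stage2", "build_variant", "premax", "hard_mask", "mask_easy",
    "save_checkpoint", "load_checkpoint",
]

#: depth is fed in meters so its dynamic range matches [0,1]-scaled RGB
DEPTH_SCALE = 1.0 / 1000.0


@dataclasses.dataclass
class CascadeConfig:
    t1: float = 0.7                 # stage-1 confidence threshold
    fusion_ratio: tuple = (12, 16, 4)  # channels of I1 : I2 : I3
    input_size: tuple = (480, 640)

    def __post_init__(self):
        if not 0 < self.t1 < 1:
            raise ValueError(f"t1 must lie in (0, 1), got {self.t1}")


# ---------------------------------------------------------------------------
# gating primitives

def premax(prob: np.ndarray) -> np.ndarray:
    """Per-pixel confidence: maximum over the class axis of a (..., 4, H, W)
    probability map."""
    return np.asarray(prob).max(axis=-3)


def hard_mask(conf: np.ndarray, t1: float) -> np.ndarray:
    """Boolean mask of hard pixels: confidence <= t1 (ties count as hard)."""
    if not 0 < t1 < 1:
        raise ValueError(f"t1 must lie in (0, 1), got {t1}")
    return np.asarray(conf) <= t1


def mask_easy(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero easy pixels (mask False) across all channels; keep hard pixels."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[-2:] != mask.shape and image.shape[:2] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image.shape}")
    if image.ndim == 2:
        return np.where(mask, image, 0)
    if image.shape[:2] == mask.shape:          # HWC layout
        return np.where(mask[..., None], image, 0)
    return np.where(mask[None], image, 0)      # CHW layout


# ---------------------------------------------------------------------------
# stages

def _pad_to_multiple(x: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad (C,H,W) or (N,C,H,W) on the bottom/right to a multiple of m."""
    H, W = x.shape[-2:]
    ph, pw = (-H) % m, (-W) % m
    if ph or pw:
        pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
        x = np.pad(x, pad)
    return x, (H, W)


class Stage1(Module):
    """Small full-resolution gate network (downsample x4, upsample back)."""

    def __init__(self, flags: ArchVariantFlags = DEFAULT_FLAGS, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        b, a = flags.conv_bias, flags.norm_affine
        ns = flags.dsconv_norm
        if flags.stage1_first == "conv":
            self.entry = ConvNorm(3, 32, 3, stride=2, bias=b, affine=a, rng=rng)
        else:
            self.entry = DSConvBlock(3, 32, stride=2, bias=b, affine=a,
                                     norm_style=ns, rng=rng)
        self.ds1 = DSConvBlock(32, 64, stride=2, bias=b, affine=a,
                               norm_style=ns, rng=rng)
        self.ds2 = DSConvBlock(64, 96, bias=b, affine=a, norm_style=ns, rng=rng)
        self.ds3 = DSConvBlock(96, 32, bias=b, affine=a, norm_style=ns, rng=rng)
        self.head = ConvNorm(32, 4, 1, bias=flags.head_bias,
                             norm=flags.stage1_head_norm, affine=a,
                             act=None, rng=rng)
        self.up = Upsampler(4, 4, flags=flags, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """RGB (N,3,H,W) in [0,1] -> class logits (N,4,H,W)."""
        x = self.entry(x)
        x = self.ds3(self.ds2(self.ds1(x)))
        return self.up(self.head(x))


class Stage2(Module):
    """Main network: three gated inputs, 1/8-resolution trunk, feature blocks,
    pyramid pooling, two-resolution skip fusion and the classify head."""

    def __init__(self, flags: ArchVariantFlags = DEFAULT_FLAGS, *,
                 third_input_channels: int = 1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        b, a = flags.conv_bias, flags.norm_affine
        self.flags = flags
        sn = flags.stem_norm
        self.i1 = ConvNorm(3, 12, 3, bias=b, norm=sn, affine=a, rng=rng)
        self.i2 = ConvNorm(3, 16, 3, bias=b, norm=sn, affine=a, rng=rng)
        self.i3 = ConvNorm(third_input_channels, 4, 3, bias=b, norm=sn,
                           affine=a, rng=rng)
        trunk = []
        for i, (ci, co) in enumerate(((32, 32), (32, 64), (64, 64))):
            plain = flags.trunk_style == "conv" or (
                flags.trunk_style == "dsconv_last2" and i == 0)
            if plain:
                trunk.append(ConvNorm(ci, co, 3, stride=2, bias=b, affine=a,
                                      rng=rng))
            else:
                trunk.append(DSConvBlock(ci, co, stride=2, bias=b, affine=a,
                                         norm_style=flags.dsconv_norm, rng=rng))
        self.trunk = trunk  # trunk[1] output is the C1 skip (1/4 resolution)
        self.bottlenecks = [Bottleneck(t, ci, co, bias=b, affine=a, rng=rng)
                            for t, ci, co in flags.chain()]
        self.fs1 = make_feature_block("s1", flags=flags, rng=rng)
        self.fs2 = make_feature_block("s2", flags=flags, rng=rng)
        self.fd = make_feature_block("d", flags=flags, rng=rng)
        self.ppm = PyramidPooling(flags.ppm_tap, flags.ppm_out(), flags=flags,
                                  rng=rng)
        fus = flags.skip_fusion
        if fus == "project_low":
            self.fuse_proj = ConvNorm(96, 64, 1, bias=b, affine=a, act=None,
                                      rng=rng)
        elif fus == "project_high":
            self.fuse_proj = ConvNorm(64, 96, 1, bias=b, affine=a, act=None,
                                      rng=rng)
        elif fus in ("fast_scnn", "fast_scnn_bias"):
            b1 = True if fus == "fast_scnn_bias" else b
            self.fuse_dw = ConvNorm(96, 96, 3, groups=96, bias=b, affine=a,
                                    rng=rng)
            self.fuse_low = ConvNorm(96, 96, 1, bias=b1, affine=a, act=None,
                                     rng=rng)
            self.fuse_high = ConvNorm(64, 96, 1, bias=b1, affine=a, act=None,
                                      rng=rng)
        self.classify = ClassifyHead(flags.fusion_width(), flags=flags, rng=rng)

    def _fuse(self, c1: Tensor, c2: Tensor) -> Tensor:
        """Merge the 1/4-resolution skip (c1, 64ch) with the trunk (c2)."""
        flags = self.flags
        H, W = c1.data.shape[2:]
        if flags.final_upsample == "x8_from_eighth":
            c1 = nn.adaptive_avg_pool(c1, c2.data.shape[2:])
        else:
            c2 = nn.resize_bilinear(c2, (H, W))
        fus = flags.skip_fusion
        if fus == "project_low":
            return nn.relu(nn.add(self.fuse_proj(c2), c1))
        if fus == "project_high":
            return nn.relu(nn.add(self.fuse_proj(c1), c2))
        if fus == "ppm64_add":
            return nn.relu(nn.add(c1, c2))
        if fus == "concatenate":
            return nn.concat([c1, c2], axis=1)
        low = self.fuse_low(self.fuse_dw(c2))
        return nn.relu(nn.add(low, self.fuse_high(c1)))

    def forward(self, rgb: Tensor, masked_rgb: Tensor,
                masked_third: Tensor) -> Tensor:
        x = nn.concat([self.i1(rgb), self.i2(masked_rgb),
                       self.i3(masked_third)], axis=1)
        x = self.trunk[0](x)
        c1 = self.trunk[1](x)
        x = self.trunk[2](c1)
        for blk in self.bottlenecks:
            x = blk(x)
        x = self.fd(self.fs2(self.fs1(x)))
        x = self.ppm(x)
        x = self._fuse(c1, x)
        logits = self.classify(x)
        H, W = rgb.data.shape[2:]
        if logits.data.shape[2:] != (H, W):
            logits = nn.resize_bilinear(logits, (H, W))
        return logits


class CascadeNet(Module):
    """Full model: stage 1 + gating + stage 2, or the single-stage ablation.

    ``variant`` is one of ``proposed`` (depth in the third input), ``v2``
    (two stages, masked RGB instead of depth) and ``v1`` (stage-2 structure
    alone on plain RGB, no gating).
    """

    def __init__(self, variant: str = "proposed",
                 flags: ArchVariantFlags = DEFAULT_FLAGS,
                 config: CascadeConfig | None = None, seed: int = 0):
        super().__init__()
        if variant not in ("proposed", "v1", "v2"):
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.flags = flags
        self.config = config or CascadeConfig()
        rng = np.random.default_rng(seed)
        self.stage1 = None if variant == "v1" else Stage1(flags, rng=rng)
        self.stage2 = Stage2(flags,
                             third_input_channels=1 if variant == "proposed" else 3,
                             rng=rng)
        self.seed_dropout(seed)

    def seed_dropout(self, seed: int):
        self.stage2.classify.drop.reseed(seed + 1)

    # -- input preparation -------------------------------------------------
    @staticmethod
    def _prep_rgb(rgb: np.ndarray) -> np.ndarray:
        """(H,W,3) uint8 -> (3,H,W) float32 in [0,1]."""
        return (rgb.astype(np.float32) / 255.0).transpose(2, 0, 1)

    @staticmethod
    def _prep_depth(depth: np.ndarray) -> np.ndarray:
        """Integer-mm depth -> centered, meter-scaled (1,H,W) float32."""
        return (center_depth(depth) * DEPTH_SCALE)[None]

    def stage1_proba(self, rgb_chw: np.ndarray) -> np.ndarray:
        """Stage-1 probability map (4,H,W) for a single prepared RGB image."""
        x, size = _pad_to_multiple(rgb_chw[None], 4)
        logits = self.stage1(Tensor(x)).data[0]
        return nn.softmax(logits[None], axis=1)[0][:, :size[0], :size[1]]

    def stage2_logits(self, rgb, masked_rgb, masked_third) -> Tensor:
        xs = [np.asarray(v, dtype=np.float32) for v in (rgb, masked_rgb, masked_third)]
        padded = []
        for v in xs:
            p, size = _pad_to_multiple(v[None] if v.ndim == 3 else v, 8)
            padded.append(Tensor(p))
        out = self.stage2(*padded)
        H, W = size
        if out.data.shape[2:] != (H, W):
            out = nn.resize_bilinear(out, out.data.shape[2:])  # no-op guard
        return out, size

    # -- end-to-end inference ---------------------------------------------
    def predict(self, sample: RGBDSample, t1: float | None = None):
        """Segment one RGB-D sample; returns (label_map, diagnostics)."""
        if sample.rgb.shape[:2] != sample.depth.shape:
            raise ValueError("rgb and depth shapes disagree")
        t1 = self.config.t1 if t1 is None else t1
        rgb = self._prep_rgb(sample.rgb)
        if self.variant == "v1":
            logits, size = self.stage2_logits(rgb, rgb, rgb)
            prob = nn.softmax(logits.data, axis=1)[0][:, :size[0], :size[1]]
            return prob.argmax(axis=0).astype(np.int64), {
                "probabilities": prob}
        prob1 = self.stage1_proba(rgb)
        conf = prob1.max(axis=0)
        hard = hard_mask(conf, t1)
        masked_rgb = mask_easy(rgb, hard)
        if self.variant == "proposed":
            third = mask_easy(self._prep_depth(sample.depth), hard)
        else:
            third = masked_rgb
        logits, size = self.stage2_logits(rgb, masked_rgb, third)
        prob = nn.softmax(logits.data, axis=1)[0][:, :size[0], :size[1]]
        label = prob.argmax(axis=0).astype(np.int64)
        diagnostics = {
            "stage1_probabilities": prob1,
            "confidence": conf,
            "hard_mask": hard,
            "hard_pixel_count": int(hard.sum()),
            "probabilities": prob,
        }
        return label, diagnostics


def build_stage1(flags: ArchVariantFlags = DEFAULT_FLAGS, seed: int = 0) -> Stage1:
    return Stage1(flags, rng=np.random.default_rng(seed))


def build_stage2(flags: ArchVariantFlags = DEFAULT_FLAGS, *,
                 third_input_channels: int = 1, seed: int = 0) -> Stage2:
    if third_input_channels not in (1, 3):
        raise ValueError(
            "third input takes 1 depth channel (proposed) or 3 RGB channels "
            "(Version 2, the depth-free alternative)")
    return Stage2(flags, third_input_channels=third_input_channels,
                  rng=np.random.default_rng(seed))


def build_variant(which: str, flags: ArchVariantFlags = DEFAULT_FLAGS,
                  config: CascadeConfig | None = None, seed: int = 0) -> CascadeNet:
    return CascadeNet(which, flags, config, seed=seed)


# ---------------------------------------------------------------------------
# checkpoints (single .npz; flags/config embedded as JSON)

def save_checkpoint(path, net: CascadeNet, extra: dict | None = None) -> None:
    meta = {
        "variant": net.variant,
        "flags": dataclasses.asdict(net.flags),
        "config": dataclasses.asdict(net.config),
        "extra": extra or {},
    }
    arrays = {f"state/{k}": v for k, v in net.state_dict().items()}
    arrays["meta"] = np.asarray(json.dumps(meta))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[CascadeNet, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        state = {k[len("state/"):]: data[k] for k in data.files
                 if k.startswith("state/")}
    cfg = meta["config"]
    cfg["fusion_ratio"] = tuple(cfg["fusion_ratio"])
    cfg["input_size"] = tuple(cfg["input_size"])
    net = CascadeNet(meta["variant"], ArchVariantFlags(**meta["flags"]),
                     CascadeConfig(**cfg))
    net.load_state_dict(state)
    net.eval()
    return net, meta.get("extra", {})
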