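"""Network building blocks and the architecture-variant arbitration.

The published description of the cascade network leaves several structural
choices ambiguous (bias/normalization placement, the exact meaning of the
grouped "DSConv" rows inside the feature blocks, the bottleneck channel
chain, how the two-resolution skip connection is fused, where the pyramid
pooling module taps the trunk, and one group count that does not divide its
channel count).  :class:`ArchVariantFlags` enumerates every such reading;
:func:`resolve_variant` arbitrates among them against the published trainable
parameter totals of the full network and its RGB-only ablation, which pin the
combination down exactly.  :data:`DEFAULT_FLAGS` is the frozen result.

Closed-form counts (:func:`count_variant`) mirror the builders layer by layer
and are cross-checked in the test suite against brute-force enumeration of
trainable entries in the constructed networks.
"""
from __future__ import annotations

import dataclasses
import itertools
from functools import lru_cache

import numpy as np

from . import nn
from .nn import Module, Sequential

__all__ = [
    "ArchVariantFlags", "BlockSpec", "DEFAULT_FLAGS", "FLAG_SPACE", "ParamCount",
    "ConvNorm", "make_dsconv", "make_bottleneck", "make_feature_block",
    "make_ppm", "make_classify", "make_upsampler", "count_params",
    "count_variant", "resolve_variant", "ResolutionReport",
]

PPM_BINS = (1, 2, 3, 6)


@dataclasses.dataclass(frozen=True)
class BlockSpec:
    """One table row: operator, kernel, stride, groups, dilation, channels."""
    operator: str
    c_in: int
    c_out: int
    kernel: int = 3
    stride: int = 1
    groups: int = 1
    dilation: int = 1
    expansion: int | None = None    # bottlenecks only

    def __post_init__(self):
        if self.kernel not in (1, 3, 5, 7):
            raise ValueError(f"kernel must be one of 1/3/5/7, got {self.kernel}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")
        if self.c_in % self.groups or self.c_out % self.groups:
            raise ValueError(
                f"groups={self.groups} must divide c_in={self.c_in} "
                f"and c_out={self.c_out}")


@dataclasses.dataclass(frozen=True)
class ArchVariantFlags:
    """One resolution of every structural ambiguity in the printed tables."""
    conv_bias: bool = False              # bias on convs that feed a norm layer
    norm_affine: bool = True             # learnable scale/shift in batch norm
    stage1_first: str = "conv"           # {"conv", "dsconv"} entry layer
    dsconv_norm: str = "pointwise_only"  # {"both", "pointwise_only"}
    trunk_style: str = "conv"            # {"conv", "dsconv_last2", "dsconv_all"}
    feature_pointwise: str = "grouped_only"  # {"none", "all", "grouped_only"}
    feature_branch_norm: bool = False    # norm inside feature-block branches
    s1_third_branch_groups: int = 16     # {16, 32}; printed 26 does not divide 64
    bottleneck_chain: str = "collapsed"  # {"collapsed", "as_printed"}
    skip_fusion: str = "project_low"     # {"project_low", "project_high",
    #                                       "concatenate", "fast_scnn",
    #                                       "fast_scnn_bias", "ppm64_add"}
    ppm_tap: int = 256                   # {96, 256} trunk width entering the PPM
    ppm_level_projection: bool = False   # 1x1 conv per pyramid level
    ppm_reduce_kernel: int = 1           # {1, 3}
    stem_norm: bool = False              # norm after the three input convs
    head_bias: bool = False              # bias on the final 1x1 class convs
    stage1_head_norm: bool = False
    classify_head_norm: bool = False
    upsample_style: str = "bilinear"     # {"bilinear", "deconv"}
    dilation_mapping: str = "offset_by_one"  # {"offset_by_one", "literal"}
    final_upsample: str = "x4_from_quarter"  # {"x4_from_quarter", "x8_from_eighth"}

    def fusion_width(self) -> int:
        """Channel count entering the classify block."""
        return {"project_low": 64, "project_high": 96, "concatenate": 160,
                "fast_scnn": 96, "fast_scnn_bias": 96, "ppm64_add": 64}[self.skip_fusion]

    def ppm_out(self) -> int:
        return 64 if self.skip_fusion == "ppm64_add" else 96

    def feature_dilations(self) -> tuple[int, int, int]:
        # printed dilation column reads 0/1/2; rate 0 is undefined
        return (1, 2, 3) if self.dilation_mapping == "offset_by_one" else (1, 1, 2)

    def chain(self):
        if self.bottleneck_chain == "collapsed":
            return ((6, 64, 64), (5, 64, 64), (4, 64, 64))
        return ((6, 64, 64), (5, 64, 96), (4, 96, 96))

    def fs1_channels(self) -> int:
        return self.chain()[-1][2]

    def fs1_groups(self):
        c = self.fs1_channels()
        return (c, 32, self.s1_third_branch_groups)


#: arbitration outcome, frozen as the package default (see resolve_variant)
DEFAULT_FLAGS = ArchVariantFlags()

FLAG_SPACE: dict[str, tuple] = {
    "conv_bias": (False, True),
    "norm_affine": (True, False),
    "stage1_first": ("conv", "dsconv"),
    "dsconv_norm": ("pointwise_only", "both"),
    "trunk_style": ("conv", "dsconv_last2", "dsconv_all"),
    "feature_pointwise": ("none", "all", "grouped_only"),
    "feature_branch_norm": (False, True),
    "s1_third_branch_groups": (16, 32),
    "bottleneck_chain": ("collapsed", "as_printed"),
    "skip_fusion": ("project_low", "project_high", "concatenate",
                    "fast_scnn", "fast_scnn_bias", "ppm64_add"),
    "ppm_tap": (96, 256),
    "ppm_level_projection": (False, True),
    "ppm_reduce_kernel": (1, 3),
    "stem_norm": (False, True),
    "head_bias": (False, True),
    "stage1_head_norm": (False, True),
    "classify_head_norm": (False, True),
    "upsample_style": ("bilinear", "deconv"),
}


# ---------------------------------------------------------------------------
# composite layers

class ConvNorm(Module):
    """Convolution + optional batch norm + optional rectification."""

    def __init__(self, c_in, c_out, k, *, stride=1, dilation=1, groups=1,
                 bias=False, norm=True, affine=True, act="relu", rng=None):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, k, stride=stride, dilation=dilation,
                              groups=groups, bias=bias, rng=rng)
        self.norm = nn.BatchNorm2d(c_out, affine=affine) if norm else None
        self.act = {"relu": nn.ReLU(), "relu6": nn.ReLU6(), None: None}[act]

    def forward(self, x):
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        if self.act is not None:
            x = self.act(x)
        return x


class DSConvBlock(Module):
    """Depthwise k x k followed by pointwise 1 x 1, each rectified."""

    def __init__(self, c_in, c_out, k=3, *, stride=1, bias=False, affine=True,
                 norm_style="both", rng=None):
        super().__init__()
        dw_norm = norm_style == "both"
        self.depthwise = ConvNorm(c_in, c_in, k, stride=stride, groups=c_in,
                                  bias=bias, norm=dw_norm, affine=affine, rng=rng)
        self.pointwise = ConvNorm(c_in, c_out, 1, bias=bias, norm=True,
                                  affine=affine, rng=rng)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


def make_dsconv(c_in, c_out, k=3, *, stride=1, bias=False, affine=True,
                norm_style="both", rng=None) -> DSConvBlock:
    """Standalone depthwise-separable convolution block."""
    return DSConvBlock(c_in, c_out, k, stride=stride, bias=bias, affine=affine,
                       norm_style=norm_style, rng=rng)


class Bottleneck(Module):
    """Inverted residual block: 1x1 expand, depthwise 3x3, 1x1 project.

    The identity skip is active iff stride == 1 and c_in == c_out; the
    rectification inside is the clipped (relu6) variant, the projection is
    linear, following the mobile-architecture convention.
    """

    def __init__(self, t, c_in, c_out, stride=1, *, bias=False, affine=True,
                 rng=None):
        super().__init__()
        if t < 1:
            raise ValueError("expansion factor t must be >= 1")
        mid = t * c_in
        self.expand = ConvNorm(c_in, mid, 1, bias=bias, affine=affine,
                               act="relu6", rng=rng)
        self.depthwise = ConvNorm(mid, mid, 3, stride=stride, groups=mid,
                                  bias=bias, affine=affine, act="relu6", rng=rng)
        self.project = ConvNorm(mid, c_out, 1, bias=bias, affine=affine,
                                act=None, rng=rng)
        self.residual = stride == 1 and c_in == c_out

    def forward(self, x):
        y = self.project(self.depthwise(self.expand(x)))
        return nn.add(y, x) if self.residual else y


def make_bottleneck(t, c_in, c_out, stride=1, *, flags=DEFAULT_FLAGS, rng=None):
    return Bottleneck(t, c_in, c_out, stride, bias=flags.conv_bias,
                      affine=flags.norm_affine, rng=rng)


class FeatureBlock(Module):
    """Three parallel grouped convolutions (k = 3, 5, 7), summed, then mixed.

    Per the frozen reading a branch whose group count is strictly smaller
    than its channel count carries a pointwise 1x1 mixing conv ("grouped_only"
    placement); a pure depthwise branch does not.  ``c_out=None`` omits the
    final 1x1 (used when the pyramid pooling module performs the reduction).
    """

    def __init__(self, c_in, c_out, groups, *, dilations=(1, 1, 1),
                 flags=DEFAULT_FLAGS, rng=None):
        super().__init__()
        bias, affine = flags.conv_bias, flags.norm_affine
        bnorm = flags.feature_branch_norm
        self.branches = []
        for k, g, d in zip((3, 5, 7), groups, dilations):
            if c_in % g:
                raise ValueError(f"groups {g} does not divide {c_in} channels")
            layers = [ConvNorm(c_in, c_in, k, groups=g, dilation=d, bias=bias,
                               norm=bnorm, affine=affine, rng=rng)]
            want_pw = (flags.feature_pointwise == "all"
                       or (flags.feature_pointwise == "grouped_only" and g < c_in))
            if want_pw:
                layers.append(ConvNorm(c_in, c_in, 1, bias=bias, norm=bnorm,
                                       affine=affine, rng=rng))
            self.branches.append(Sequential(*layers))
        self.mix = None if c_out is None else \
            ConvNorm(c_in, c_out, 1, bias=bias, affine=affine, rng=rng)

    def forward(self, x):
        y = self.branches[0](x)
        for b in self.branches[1:]:
            y = nn.add(y, b(x))
        return self.mix(y) if self.mix is not None else y


def make_feature_block(which: str, *, flags=DEFAULT_FLAGS, rng=None) -> FeatureBlock:
    """Construct Feature_s1 / Feature_s2 / Feature_d per the variant flags."""
    if which == "s1":
        return FeatureBlock(flags.fs1_channels(), 128, flags.fs1_groups(),
                            flags=flags, rng=rng)
    if which == "s2":
        return FeatureBlock(128, 256, (128, 64, 32), flags=flags, rng=rng)
    if which == "d":
        c_out = None if flags.ppm_tap == 256 else 96
        return FeatureBlock(256, c_out, (256, 128, 64),
                            dilations=flags.feature_dilations(),
                            flags=flags, rng=rng)
    raise ValueError(f"unknown feature block {which!r}")


class PyramidPooling(Module):
    """Multi-scale global context: pool at bins (1,2,3,6), optionally project
    each level, upsample back, concatenate with the trunk, reduce to c_out."""

    def __init__(self, c_in, c_out, *, flags=DEFAULT_FLAGS, rng=None):
        super().__init__()
        bias, affine = flags.conv_bias, flags.norm_affine
        self.bins = PPM_BINS
        self.level_projs = []
        level_c = c_in
        if flags.ppm_level_projection:
            level_c = c_in // 4
            self.level_projs = [ConvNorm(c_in, level_c, 1, bias=bias,
                                         affine=affine, rng=rng)
                                for _ in self.bins]
        cat = c_in + len(self.bins) * level_c
        self.reduce = ConvNorm(cat, c_out, flags.ppm_reduce_kernel, bias=bias,
                               affine=affine, rng=rng)

    def forward(self, x):
        H, W = x.data.shape[2:]
        if H < max(self.bins) or W < max(self.bins):
            raise RuntimeError(
                f"pyramid pooling input {H}x{W} smaller than largest bin "
                f"{max(self.bins)}")
        feats = [x]
        for i, b in enumerate(self.bins):
            lvl = nn.adaptive_avg_pool(x, (b, b))
            if self.level_projs:
                lvl = self.level_projs[i](lvl)
            feats.append(nn.resize_bilinear(lvl, (H, W)))
        return self.reduce(nn.concat(feats, axis=1))


def make_ppm(c_in=None, c_out=None, *, flags=DEFAULT_FLAGS, rng=None):
    return PyramidPooling(flags.ppm_tap if c_in is None else c_in,
                          flags.ppm_out() if c_out is None else c_out,
                          flags=flags, rng=rng)


class Upsampler(Module):
    """x``factor`` upsampling: bilinear (parameter-free) or learned deconv."""

    def __init__(self, channels, factor, *, flags=DEFAULT_FLAGS, rng=None):
        super().__init__()
        if flags.upsample_style == "deconv":
            self.up = nn.ConvTranspose2d(channels, channels, factor,
                                         bias=flags.conv_bias, rng=rng)
        else:
            self.up = nn.UpsampleBilinear(factor)

    def forward(self, x):
        return self.up(x)


def make_upsampler(channels, factor, *, flags=DEFAULT_FLAGS, rng=None):
    return Upsampler(channels, factor, flags=flags, rng=rng)


class ClassifyHead(Module):
    """Two depthwise-separable convs, x4 upsample, dropout 0.1, 1x1 to 4."""

    def __init__(self, c_in, *, flags=DEFAULT_FLAGS, rng=None, dropout_seed=0):
        super().__init__()
        bias, affine = flags.conv_bias, flags.norm_affine
        self.ds1 = DSConvBlock(c_in, 64, bias=bias, affine=affine,
                               norm_style=flags.dsconv_norm, rng=rng)
        self.ds2 = DSConvBlock(64, 32, bias=bias, affine=affine,
                               norm_style=flags.dsconv_norm, rng=rng)
        self.up = Upsampler(32, 4, flags=flags, rng=rng)
        self.drop = nn.Dropout(0.1, seed=dropout_seed)
        self.head = ConvNorm(32, 4, 1, bias=flags.head_bias,
                             norm=flags.classify_head_norm,
                             affine=flags.norm_affine, act=None, rng=rng)

    def forward(self, x):
        x = self.up(self.ds2(self.ds1(x)))
        return self.head(self.drop(x))


def make_classify(c_in=None, *, flags=DEFAULT_FLAGS, rng=None):
    return ClassifyHead(flags.fusion_width() if c_in is None else c_in,
                        flags=flags, rng=rng)


# ---------------------------------------------------------------------------
# parameter counting

@dataclasses.dataclass
class ParamCount:
    total: int
    breakdown: list[tuple[str, int]]


def count_params(module: Module) -> ParamCount:
    """Brute-force count of trainable entries, broken down per child module."""
    breakdown = []
    counted = set()
    for name, child in module.children():
        n = child.num_parameters()
        breakdown.append((name, n))
        counted.update(id(p) for p in child.parameters())
    own = sum(p.data.size for _, p in module.named_parameters()
              if id(p) not in counted)
    if own:
        breakdown.append(("(own)", int(own)))
    total = int(sum(n for _, n in breakdown))
    assert total == module.num_parameters()
    return ParamCount(total=total, breakdown=breakdown)


# --- closed-form (must mirror the builders exactly) ------------------------

def _cf_conv(cin, cout, k, groups=1, bias=False, norm=True, affine=True):
    n = k * k * (cin // groups) * cout
    if bias:
        n += cout
    if norm and affine:
        n += 2 * cout
    return n


def _cf_dsconv(cin, cout, bias, affine, norm_style, k=3):
    return (_cf_conv(cin, cin, k, groups=cin, bias=bias,
                     norm=norm_style == "both", affine=affine)
            + _cf_conv(cin, cout, 1, bias=bias, affine=affine))


def _cf_bottleneck(t, cin, cout, bias, affine):
    mid = t * cin
    return (_cf_conv(cin, mid, 1, bias=bias, affine=affine)
            + _cf_conv(mid, mid, 3, groups=mid, bias=bias, affine=affine)
            + _cf_conv(mid, cout, 1, bias=bias, affine=affine))


def _cf_upsampler(ch, factor, flags):
    if flags.upsample_style == "deconv":
        return factor * factor * ch * ch + (ch if flags.conv_bias else 0)
    return 0


@lru_cache(maxsize=None)
def _cf_stage1(flags: ArchVariantFlags) -> int:
    b, a = flags.conv_bias, flags.norm_affine
    if flags.stage1_first == "conv":
        n = _cf_conv(3, 32, 3, bias=b, affine=a)
    else:
        n = _cf_dsconv(3, 32, b, a, flags.dsconv_norm)
    for ci, co in ((32, 64), (64, 96), (96, 32)):
        n += _cf_dsconv(ci, co, b, a, flags.dsconv_norm)
    n += _cf_conv(32, 4, 1, bias=flags.head_bias, norm=flags.stage1_head_norm,
                  affine=a)
    n += _cf_upsampler(4, 4, flags)
    return n


@lru_cache(maxsize=None)
def _cf_feature_block(cin, cout, groups, dilations, flags) -> int:
    b, a = flags.conv_bias, flags.norm_affine
    bn = flags.feature_branch_norm
    n = 0
    for k, g in zip((3, 5, 7), groups):
        n += _cf_conv(cin, cin, k, groups=g, bias=b, norm=bn, affine=a)
        if flags.feature_pointwise == "all" or (
                flags.feature_pointwise == "grouped_only" and g < cin):
            n += _cf_conv(cin, cin, 1, bias=b, norm=bn, affine=a)
    if cout is not None:
        n += _cf_conv(cin, cout, 1, bias=b, affine=a)
    return n


@lru_cache(maxsize=None)
def _cf_ppm(flags) -> int:
    b, a = flags.conv_bias, flags.norm_affine
    cin, cout = flags.ppm_tap, flags.ppm_out()
    n = 0
    level_c = cin
    if flags.ppm_level_projection:
        level_c = cin // 4
        n += 4 * _cf_conv(cin, level_c, 1, bias=b, affine=a)
    n += _cf_conv(cin + 4 * level_c, cout, flags.ppm_reduce_kernel,
                  bias=b, affine=a)
    return n


@lru_cache(maxsize=None)
def _cf_fusion(flags) -> int:
    b, a = flags.conv_bias, flags.norm_affine
    fus = flags.skip_fusion
    if fus == "project_low":
        return _cf_conv(96, 64, 1, bias=b, affine=a)
    if fus == "project_high":
        return _cf_conv(64, 96, 1, bias=b, affine=a)
    if fus in ("concatenate", "ppm64_add"):
        return 0
    n = _cf_conv(96, 96, 3, groups=96, bias=b, affine=a)
    bias_1x1 = True if fus == "fast_scnn_bias" else b
    n += _cf_conv(96, 96, 1, bias=bias_1x1, affine=a)
    n += _cf_conv(64, 96, 1, bias=bias_1x1, affine=a)
    return n


@lru_cache(maxsize=None)
def _cf_classify(flags) -> int:
    b, a = flags.conv_bias, flags.norm_affine
    n = _cf_dsconv(flags.fusion_width(), 64, b, a, flags.dsconv_norm)
    n += _cf_dsconv(64, 32, b, a, flags.dsconv_norm)
    n += _cf_upsampler(32, 4, flags)
    n += _cf_conv(32, 4, 1, bias=flags.head_bias,
                  norm=flags.classify_head_norm, affine=a)
    return n


@lru_cache(maxsize=None)
def _cf_stage2_shared(flags) -> int:
    """Stage-2 params excluding the third input conv (the depth/RGB branch)."""
    b, a = flags.conv_bias, flags.norm_affine
    n = _cf_conv(3, 12, 3, bias=b, norm=flags.stem_norm, affine=a)
    n += _cf_conv(3, 16, 3, bias=b, norm=flags.stem_norm, affine=a)
    for i, (ci, co) in enumerate(((32, 32), (32, 64), (64, 64))):
        plain = flags.trunk_style == "conv" or (
            flags.trunk_style == "dsconv_last2" and i == 0)
        if plain:
            n += _cf_conv(ci, co, 3, bias=b, affine=a)
        else:
            n += _cf_dsconv(ci, co, b, a, flags.dsconv_norm)
    for t, ci, co in flags.chain():
        n += _cf_bottleneck(t, ci, co, b, a)
    n += _cf_feature_block(flags.fs1_channels(), 128, flags.fs1_groups(),
                           (1, 1, 1), flags)
    n += _cf_feature_block(128, 256, (128, 64, 32), (1, 1, 1), flags)
    fd_out = None if flags.ppm_tap == 256 else 96
    n += _cf_feature_block(256, fd_out, (256, 128, 64),
                           flags.feature_dilations(), flags)
    n += _cf_ppm(flags)
    n += _cf_fusion(flags)
    n += _cf_classify(flags)
    return n


def count_variant(flags: ArchVariantFlags, variant: str = "proposed") -> int:
    """Closed-form trainable-parameter total for a network variant."""
    b, a = flags.conv_bias, flags.norm_affine
    depth_ch = 1 if variant == "proposed" else 3
    i3 = _cf_conv(depth_ch, 4, 3, bias=b, norm=flags.stem_norm, affine=a)
    stage2 = _cf_stage2_shared(flags) + i3
    if variant == "v1":
        return stage2
    if variant in ("proposed", "v2"):
        return _cf_stage1(flags) + stage2
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# arbitration

@dataclasses.dataclass
class ResolutionReport:
    matches: list[ArchVariantFlags]
    nearest: list[tuple[int, ArchVariantFlags, dict[str, int]]]
    targets: dict[str, int]

    @property
    def resolved(self) -> bool:
        return bool(self.matches)


def resolve_variant(targets: dict[str, int] | None = None,
                    space: dict[str, tuple] | None = None) -> ResolutionReport:
    """Enumerate the flag space; keep combinations matching every target count.

    ``targets`` maps variant name ("proposed", "v1", "v2") to the published
    trainable-parameter total.  If nothing matches, the report carries the
    nearest candidates with per-variant deltas instead of failing silently.
    """
    if targets is None:
        targets = {"proposed": 680_760, "v2": 680_832}
    if not targets:
        raise ValueError("targets must not be empty")
    space = dict(space or FLAG_SPACE)
    keys = list(space)
    matches, nearest = [], []
    for values in itertools.product(*space.values()):
        flags = ArchVariantFlags(**dict(zip(keys, values)))
        deltas = {v: count_variant(flags, v) - n for v, n in targets.items()}
        err = sum(abs(d) for d in deltas.values())
        if err == 0:
            matches.append(flags)
        else:
            nearest.append((err, flags, deltas))
            if len(nearest) > 2000:
                nearest.sort(key=lambda r: r[0])
                del nearest[10:]
    nearest.sort(key=lambda r: r[0])
    return ResolutionReport(matches=matches, nearest=nearest[:10],
                            targets=dict(targets))
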