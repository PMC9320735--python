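"""RGB-D dataset I/O: lossless 24-bit depth codec, depth centering, the PNG
directory layout (rgb/, depth/, labels/), the label palette and dataset splits.

Depth maps hold integer millimeters.  On disk, depth is either a raw 16-bit
single-channel PNG or a 24-bit RGB-encoded PNG where a distance ``d`` is stored
base-256 across the channels::

    d = R + 256 * G + 65536 * B

which is a bijection on [0, 2**24); the encoded PNG is the canonical output
dialect, the 16-bit form is accepted on read (auto-detected by channel count).
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image

N_CLASSES = 4
#: visualization palette; class semantics live in the index map, not the colors
PALETTE = np.array(
    [(0, 0, 0),        # 0 other
     (138, 43, 226),   # 1 stem (violet)
     (255, 105, 180),  # 2 branch (pink)
     (0, 255, 0)],     # 3 sucker (green)
    dtype=np.uint8)

MAX_DEPTH = 2 ** 24


@dataclasses.dataclass
class RGBDSample:
    """One RGB-D frame: 8-bit color, integer-mm depth, optional class labels."""
    rgb: np.ndarray                 # (H, W, 3) uint8
    depth: np.ndarray               # (H, W) integer millimeters
    label: np.ndarray | None = None  # (H, W) values in {0,1,2,3}
    identifier: str = ""

    def __post_init__(self):
        h, w = self.depth.shape
        if self.rgb.shape != (h, w, 3):
            raise ValueError(
                f"rgb shape {self.rgb.shape} does not match depth {self.depth.shape}")
        if self.label is not None and self.label.shape != (h, w):
            raise ValueError(
                f"label shape {self.label.shape} does not match depth {self.depth.shape}")
        if self.label is not None:
            validate_label(self.label)

    @property
    def shape(self):
        return self.depth.shape


def validate_label(label: np.ndarray) -> None:
    bad = np.setdiff1d(np.unique(label), np.arange(N_CLASSES))
    if bad.size:
        raise ValueError(f"label contains values outside 0..3: {bad.tolist()}")


# ---------------------------------------------------------------------------
# depth codec

def encode_depth(depth: np.ndarray) -> np.ndarray:
    """Encode integer-mm depth into an (H, W, 3) uint8 image, base 256.

    Raises ValueError naming the first offending pixel if any value is
    negative or >= 2**24.
    """
    d = np.asarray(depth)
    bad = (d < 0) | (d >= MAX_DEPTH)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"depth value {int(d[i, j])} at pixel ({i}, {j}) outside [0, 2^24)")
    d = d.astype(np.uint32)
    out = np.empty(d.shape + (3,), dtype=np.uint8)
    out[..., 0] = d & 0xFF
    out[..., 1] = (d >> 8) & 0xFF
    out[..., 2] = (d >> 16) & 0xFF
    return out


def decode_depth(img: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`encode_depth`; accepts (H, W, 3) uint8."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"encoded depth must be (H, W, 3); got {img.shape}")
    r, g, b = (img[..., k].astype(np.uint32) for k in range(3))
    return (r + (g << 8) + (b << 16)).astype(np.int64)


def center_depth(depth: np.ndarray) -> np.ndarray:
    """Subtract the grand mean: per-pixel distance relative to the image mean.

    The result is invariant to a constant camera offset (translation along the
    optical axis) and has zero mean by construction.
    """
    d = np.asarray(depth, dtype=np.float64)
    if d.size == 0:
        raise ValueError("cannot center an empty depth grid")
    return (d - d.mean()).astype(np.float32)


# ---------------------------------------------------------------------------
# palette

def label_to_color(label: np.ndarray) -> np.ndarray:
    validate_label(label)
    return PALETTE[np.asarray(label, dtype=np.intp)]


def color_to_label(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.uint8)
    label = np.full(img.shape[:2], -1, dtype=np.int64)
    for cls, color in enumerate(PALETTE):
        label[np.all(img == color, axis=-1)] = cls
    if (label < 0).any():
        raise ValueError("image contains colors outside the label palette")
    return label


# ---------------------------------------------------------------------------
# dataset layout

def _read_png(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im)


def load_sample(root: str | Path, identifier: str, *,
                require_label: bool = True) -> RGBDSample:
    """Load ``<root>/{rgb,depth,labels}/<identifier>.png`` into a sample.

    Depth PNGs are auto-detected: a single-channel image is raw millimeters,
    a 3-channel image is decoded with the 24-bit codec.
    """
    root = Path(root)
    rgb_path = root / "rgb" / f"{identifier}.png"
    depth_path = root / "depth" / f"{identifier}.png"
    label_path = root / "labels" / f"{identifier}.png"
    for p in ([rgb_path, depth_path] + ([label_path] if require_label else [])):
        if not p.exists():
            raise FileNotFoundError(p)
    rgb = _read_png(rgb_path)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError(f"{rgb_path} is not an RGB image")
    rgb = rgb[..., :3].astype(np.uint8)
    draw = _read_png(depth_path)
    depth = decode_depth(draw) if draw.ndim == 3 else draw.astype(np.int64)
    label = None
    if label_path.exists():
        label = _read_png(label_path).astype(np.int64)
        validate_label(label)
    return RGBDSample(rgb=rgb, depth=depth, label=label, identifier=identifier)


def save_sample(root: str | Path, sample: RGBDSample, *,
                encoded_depth: bool = True) -> None:
    """Write a sample in the dataset layout (encoded 24-bit depth by default)."""
    root = Path(root)
    for sub in ("rgb", "depth", "labels"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    name = f"{sample.identifier}.png"
    Image.fromarray(sample.rgb).save(root / "rgb" / name)
    if encoded_depth:
        Image.fromarray(encode_depth(sample.depth)).save(root / "depth" / name)
    else:
        arr = sample.depth
        if (arr < 0).any() or (arr >= 2 ** 16).any():
            raise ValueError("raw 16-bit dialect requires depth in [0, 65536)")
        Image.fromarray(arr.astype(np.uint16)).save(root / "depth" / name)
    if sample.label is not None:
        Image.fromarray(sample.label.astype(np.uint8)).save(root / "labels" / name)


def list_identifiers(root: str | Path) -> list[str]:
    return sorted(p.stem for p in (Path(root) / "rgb").glob("*.png"))


def split_dataset(samples: list, seed: int,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)):
    """Seeded uniform shuffle into train/val/test (80/10/10 by default)."""
    if len(samples) < 10:
        raise ValueError(f"need at least 10 samples to split, got {len(samples)}")
    n = len(samples)
    order = np.random.default_rng(seed).permutation(n)
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    pick = lambda idx: [samples[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)
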