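"""Seeded synthetic tomato RGB-D scenes.

The generator emulates the statistical structure of greenhouse tomato imagery
for a camera roughly half a meter from the plants: thin elongated strokes
(stems near-vertical, branches diagonal from stem nodes, short suckers rising
in the stem-branch axil), a strong class imbalance (suckers a few percent of
pixels), and two depth layers.  When a far plant is enabled it is drawn first
and occluded by the near plant, so a far stem can cross behind a near
stem-branch junction - the configuration that makes a far stem look like a
sucker in a plain RGB view and that depth input is meant to disambiguate.

Rendering is deliberately non-photorealistic: flat class-dependent colors with
additive Gaussian noise and hard (non-anti-aliased) class boundaries, so that
every pixel has an unambiguous ground-truth label.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line

from .io import RGBDSample

__all__ = ["SceneParams", "generate_scene", "generate_dataset",
           "generate_counting_fixture"]

# flat rendering colors per (class, layer); arbitrary but well separated
_COLORS = {
    "background": (42, 58, 36),
    "stem": (118, 84, 48),
    "branch": (62, 142, 58),
    "sucker": (150, 205, 92),
}
_FAR_SHADE = 0.72  # far-plant colors are darkened by this factor


@dataclasses.dataclass
class SceneParams:
    height: int = 480
    width: int = 640
    n_stems: int = 2
    sucker_probability: float = 0.7
    include_far_plant: bool = True
    near_depth_mm: int = 500
    far_depth_mm: int = 800
    background_depth_mm: int = 1500
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not (self.near_depth_mm < self.far_depth_mm < self.background_depth_mm):
            raise ValueError("depth layers must satisfy near < far < background")
        if self.height < 48 or self.width < 48:
            raise ValueError("canvas too small to place a stem (need >= 48 px)")


def _stroke(mask: np.ndarray, p0, p1, width: int) -> None:
    """Rasterize a hard-edged thick line segment into a boolean mask."""
    h, w = mask.shape
    r0, c0 = int(np.clip(p0[0], 0, h - 1)), int(np.clip(p0[1], 0, w - 1))
    r1, c1 = int(np.clip(p1[0], 0, h - 1)), int(np.clip(p1[1], 0, w - 1))
    rr, cc = _draw_line(r0, c0, r1, c1)
    thin = np.zeros_like(mask)
    thin[rr, cc] = True
    radius = max((width - 1) // 2, 0)
    if radius:
        yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
        footprint = yy ** 2 + xx ** 2 <= radius ** 2
        thin = ndimage.binary_dilation(thin, structure=footprint)
    mask |= thin


def _draw_plant(shape, rng: np.random.Generator, n_stems: int,
                sucker_probability: float):
    """Rasterize one plant; returns per-class boolean masks (stem, branch, sucker)."""
    H, W = shape
    stem = np.zeros(shape, bool)
    branch = np.zeros(shape, bool)
    sucker = np.zeros(shape, bool)
    scale = min(H, W)
    for _ in range(n_stems):
        base_c = rng.uniform(0.15, 0.85) * W
        drift = rng.uniform(-0.12, 0.12) * W
        width_stem = rng.integers(8, 15)
        # near-vertical polyline bottom -> top through 3 control points
        rows = np.array([H - 1, H // 2, 0])
        cols = np.array([base_c, base_c + drift / 2, base_c + drift])
        for (r0, c0), (r1, c1) in zip(zip(rows[:-1], cols[:-1]),
                                      zip(rows[1:], cols[1:])):
            _stroke(stem, (r0, c0), (r1, c1), width_stem)
        # nodes along the stem spawn branches; suckers sit in the axil
        for frac in rng.uniform(0.25, 0.85, size=rng.integers(2, 4)):
            node_r = frac * (H - 1)
            node_c = np.interp(node_r, rows[::-1], cols[::-1])
            side = rng.choice((-1.0, 1.0))
            b_angle = np.deg2rad(rng.uniform(35, 65))  # from vertical
            b_len = rng.uniform(0.25, 0.45) * scale
            b_end = (node_r - b_len * np.cos(b_angle),
                     node_c + side * b_len * np.sin(b_angle))
            _stroke(branch, (node_r, node_c), b_end,
                    int(rng.integers(5, 11)))
            if rng.random() < sucker_probability:
                # axillary shoot: between the upward stem and the branch
                s_angle = b_angle * rng.uniform(0.35, 0.6)
                s_len = rng.uniform(20, 60)
                s_end = (node_r - s_len * np.cos(s_angle),
                         node_c + side * s_len * np.sin(s_angle))
                _stroke(sucker, (node_r, node_c), s_end,
                        int(rng.integers(4, 9)))
    return stem, branch, sucker


def _compose_labels(plant_masks):
    """Paint (stem, branch, sucker) mask triples back-to-front into a LabelMap."""
    H, W = plant_masks[0][0].shape
    label = np.zeros((H, W), dtype=np.int64)
    for stem, branch, sucker in plant_masks:  # far first, near last (occludes)
        label[stem] = 1
        label[branch] = 2
        label[sucker] = 3
    return label


def _prune_orphan_suckers(label: np.ndarray) -> np.ndarray:
    """Relabel sucker components that lost stem or branch contact to class 0.

    Occlusion by the near plant can strip a far sucker of its axil; a sucker
    only counts as such when it touches both a stem and a branch (within a
    2-px dilation), so orphans become unlabeled plant matter.
    """
    comp, n = ndimage.label(label == 3, structure=np.ones((3, 3), int))
    if not n:
        return label
    footprint = np.ones((5, 5), bool)  # 2-px dilation
    for i in range(1, n + 1):
        grown = ndimage.binary_dilation(comp == i, structure=footprint)
        if not ((label[grown] == 1).any() and (label[grown] == 2).any()):
            label[comp == i] = 0
    return label


def generate_scene(params: SceneParams) -> RGBDSample:
    """Render one synthetic RGB-D scene; deterministic under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    H, W = params.height, params.width
    plants = []
    if params.include_far_plant:
        plants.append(_draw_plant((H, W), rng, max(params.n_stems - 1, 1),
                                  params.sucker_probability))
    plants.append(_draw_plant((H, W), rng, params.n_stems,
                              params.sucker_probability))
    label = _compose_labels(plants)
    label = _prune_orphan_suckers(label)

    # depth: background everywhere, then the far layer, then the near layer
    depth = np.full((H, W), float(params.background_depth_mm))
    layer_depths = ([params.far_depth_mm] if params.include_far_plant else []) \
        + [params.near_depth_mm]
    layer_id = np.zeros((H, W), dtype=np.int8)  # 0 bg, 1 far, 2(or 1) near
    for idx, ((stem, branch, sucker), d) in enumerate(zip(plants, layer_depths), 1):
        cover = stem | branch | sucker
        depth[cover] = d
        layer_id[cover] = idx if params.include_far_plant else 2
    depth += rng.normal(0.0, params.noise_sd, size=(H, W))
    depth = np.clip(np.rint(depth), 0, 2 ** 24 - 1).astype(np.int64)

    rgb = np.empty((H, W, 3), dtype=np.float64)
    rgb[:] = _COLORS["background"]
    for cls, name in ((1, "stem"), (2, "branch"), (3, "sucker")):
        rgb[label == cls] = _COLORS[name]
    far_px = layer_id == 1 if params.include_far_plant else np.zeros((H, W), bool)
    rgb[far_px] *= _FAR_SHADE
    rgb += rng.normal(0.0, 6.0, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    return RGBDSample(rgb=rgb, depth=depth, label=label,
                      identifier=f"scene_{params.seed:08d}")


def generate_dataset(n: int, params: SceneParams) -> list[RGBDSample]:
    """n scenes with per-scene seeds derived from ``params.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = np.random.default_rng(params.seed).integers(0, 2 ** 31 - 1, size=n)
    out = []
    for i, s in enumerate(seeds):
        p = dataclasses.replace(params, seed=int(s))
        sample = generate_scene(p)
        sample.identifier = f"scene_{i:04d}_{int(s):08d}"
        out.append(sample)
    return out


def generate_counting_fixture() -> tuple[np.ndarray, np.ndarray]:
    """Deterministic worked example for the sucker-counting procedure.

    Returns ``(prediction, ground_truth)`` label maps.  The ground truth holds
    two sucker regions (areas 192 and 200 px).  The prediction holds three:
    one overlapping the first true sucker (192 px), one spurious but large
    region (200 px), and one spurious small region (100 px) that the area
    filter at t = 160 removes.  Exactly one true sucker is therefore detected.
    """
    H, W = 120, 160
    truth = np.zeros((H, W), dtype=np.int64)
    pred = np.zeros((H, W), dtype=np.int64)
    truth[20:36, 20:32] = 3    # sucker A, 16 x 12 = 192 px
    truth[70:90, 100:110] = 3  # sucker B, 20 x 10 = 200 px
    pred[24:40, 22:34] = 3     # overlaps A
    pred[70:90, 40:50] = 3     # large spurious region, 200 px
    pred[100:110, 10:20] = 3   # small spurious region, 100 px < 160
    return pred, truth
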