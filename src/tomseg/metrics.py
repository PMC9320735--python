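"""Evaluation: per-class IOU and the four-step correct-sucker count.

The sucker count follows the detection-oriented procedure: binarize the
sucker class in prediction and ground truth, drop predicted connected
components smaller than an area threshold (t = 160 px by default - regions
below it are noise, and a real sucker must be large enough for a robot to
grasp), split the ground truth into components, and score a true sucker as
detected when its component overlaps the filtered prediction in at least one
pixel (the elementwise sum of the two binary masks reaches 2).
"""
from __future__ import annotations

import dataclasses

import numpy as np
from skimage import measure

from .io import N_CLASSES

__all__ = [
    "EvalConfig", "SuckerCountResult", "class_iou", "sucker_binary",
    "filter_noise_regions", "count_correct_suckers", "evaluate_dataset",
    "measure_throughput",
]


@dataclasses.dataclass
class EvalConfig:
    noise_area_threshold: int = 160
    connectivity: int = 8          # pixel adjacency: 8 (default) or 4

    def __post_init__(self):
        if self.noise_area_threshold < 0:
            raise ValueError("area threshold must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _skimage_connectivity(self) -> int:
        return 2 if self.connectivity == 8 else 1


@dataclasses.dataclass
class SuckerCountResult:
    n_ground_truth_suckers: int
    n_prediction_regions_after_filter: int
    n_correct: int
    overlap_flags: list[bool]      # per ground-truth component


def _check_shapes(pred, truth):
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")


def class_iou(pred: np.ndarray, truth: np.ndarray,
              n_classes: int = N_CLASSES):
    """Per-class intersection-over-union and their mean.

    Classes absent from both maps have an undefined IOU (0/0) and are
    excluded from the mean; their entry is NaN.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_shapes(pred, truth)
    per_class = np.full(n_classes, np.nan)
    for c in range(n_classes):
        p, t = pred == c, truth == c
        union = np.logical_or(p, t).sum()
        if union:
            per_class[c] = np.logical_and(p, t).sum() / union
    mean = float(np.nanmean(per_class)) if not np.isnan(per_class).all() else np.nan
    return per_class, mean


def sucker_binary(label: np.ndarray) -> np.ndarray:
    """0/1 mask of the sucker class (class 3)."""
    return (np.asarray(label) == 3).astype(np.uint8)


def filter_noise_regions(mask: np.ndarray,
                         config: EvalConfig = EvalConfig()) -> np.ndarray:
    """Remove connected components with area strictly below the threshold."""
    mask = np.asarray(mask).astype(bool)
    comp = measure.label(mask, connectivity=config._skimage_connectivity)
    out = np.zeros_like(mask, dtype=np.uint8)
    for region in measure.regionprops(comp):
        if region.area >= config.noise_area_threshold:
            out[comp == region.label] = 1
    return out


def count_correct_suckers(pred: np.ndarray, truth: np.ndarray,
                          config: EvalConfig = EvalConfig()) -> SuckerCountResult:
    """Four-step count of correctly detected suckers (see module docstring).

    Ground-truth components are trusted as annotated and are not
    noise-filtered; only the prediction is.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_shapes(pred, truth)
    conn = config._skimage_connectivity
    pred_mask = filter_noise_regions(sucker_binary(pred), config)
    n_pred_regions = int(measure.label(pred_mask, connectivity=conn).max())
    truth_comp = measure.label(sucker_binary(truth), connectivity=conn)
    flags = []
    for i in range(1, truth_comp.max() + 1):
        g = (truth_comp == i).astype(np.uint8)
        flags.append(bool((g + pred_mask).max() == 2))
    return SuckerCountResult(
        n_ground_truth_suckers=int(truth_comp.max()),
        n_prediction_regions_after_filter=n_pred_regions,
        n_correct=int(sum(flags)),
        overlap_flags=flags,
    )


def evaluate_dataset(net, samples, config: EvalConfig = EvalConfig()) -> dict:
    """Dataset-level report: mean IOU, sucker detection %, per-image breakdown.

    Mean IOU aggregates summed intersections over summed unions per class
    across the set, then averages over the classes that occur; a per-image
    mean is also reported.  Detection % is per sucker: 100 x detected / total.
    If the set holds no ground-truth suckers the detection rate is undefined
    and reported as None (never as 0).
    """
    inter = np.zeros(N_CLASSES)
    union = np.zeros(N_CLASSES)
    n_correct = n_truth = 0
    per_image = []
    for sample in samples:
        if sample.label is None:
            raise ValueError(f"sample {sample.identifier!r} has no label")
        pred, _ = net.predict(sample)
        truth = sample.label
        per_class, mean_iou = class_iou(pred, truth)
        for c in range(N_CLASSES):
            p, t = pred == c, truth == c
            inter[c] += np.logical_and(p, t).sum()
            union[c] += np.logical_or(p, t).sum()
        counts = count_correct_suckers(pred, truth, config)
        n_correct += counts.n_correct
        n_truth += counts.n_ground_truth_suckers
        per_image.append({
            "identifier": sample.identifier,
            "per_class_iou": [None if np.isnan(v) else float(v)
                              for v in per_class],
            "mean_iou": None if np.isnan(mean_iou) else float(mean_iou),
            "n_ground_truth_suckers": counts.n_ground_truth_suckers,
            "n_correct": counts.n_correct,
        })
    defined = union > 0
    agg_per_class = np.full(N_CLASSES, np.nan)
    agg_per_class[defined] = inter[defined] / union[defined]
    fg = defined.copy()
    fg[0] = False
    report = {
        "per_class_iou": [None if np.isnan(v) else float(v)
                          for v in agg_per_class],
        "mean_iou": float(np.nanmean(agg_per_class)),
        "mean_iou_foreground": (float(np.nanmean(agg_per_class[1:]))
                                if fg.any() else None),
        "sucker_detection_pct": (100.0 * n_correct / n_truth
                                 if n_truth else None),
        "n_ground_truth_suckers": n_truth,
        "n_correct": n_correct,
        "per_image": per_image,
    }
    return report


def measure_throughput(net, n_frames: int = 10, *, shape=(120, 160),
                       warmup: int = 2, seed: int = 0) -> float:
    """Wall-clock frames per second of end-to-end prediction (informational;
    hardware-dependent).  Warm-up frames are excluded from the timed window."""
    import time

    from .io import RGBDSample
    rng = np.random.default_rng(seed)
    H, W = shape
    sample = RGBDSample(
        rgb=rng.integers(0, 256, size=(H, W, 3), dtype=np.uint8),
        depth=rng.integers(400, 1600, size=(H, W)).astype(np.int64),
        identifier="throughput")
    for _ in range(warmup):
        net.predict(sample)
    t0 = time.perf_counter()
    for _ in range(n_frames):
        net.predict(sample)
    return n_frames / (time.perf_counter() - t0)
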