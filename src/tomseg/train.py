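"""Augmentation and the two-phase training protocol.

The cascade is trained in two passes over the data: first stage 1 alone is
optimized against its own output (it must learn to locate hard pixels), then
stage 1 is frozen and stage 2 is optimized against the final output, with the
hard-pixel gating recomputed on the fly from the frozen stage 1 each batch.
Optimization is plain SGD with momentum 0.9 and a geometric learning-rate
decay: after k optimizer steps the rate is ``initial_lr * 0.997 ** k``.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from skimage import filters as _filters
from skimage import transform as _transform

from .blocks import DEFAULT_FLAGS
from .cascade import CascadeNet, hard_mask, mask_easy, save_checkpoint
from .io import RGBDSample, list_identifiers, load_sample, split_dataset
from .metrics import evaluate_dataset
from .nn import SGD, Tensor, softmax, softmax_cross_entropy

__all__ = ["TrainConfig", "augment", "hflip", "scale_crop", "pixel_loss",
           "train_phase", "fit"]


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 12
    epochs: int = 40
    initial_lr: float = 0.025
    lr_decay_per_iteration: float = 0.997
    t1: float = 0.7
    momentum: float = 0.9
    seed: int = 0
    phase: str = "stage1"          # {"stage1", "stage2"}
    augment: bool = True
    class_weights: tuple | None = None  # hook; None = unweighted

    def lr_at(self, iteration: int) -> float:
        """Learning rate after ``iteration`` optimizer steps (closed form)."""
        return self.initial_lr * self.lr_decay_per_iteration ** iteration


# ---------------------------------------------------------------------------
# augmentation

def hflip(sample: RGBDSample) -> RGBDSample:
    """Mirror rgb, depth and label about the vertical axis (an involution)."""
    return RGBDSample(
        rgb=np.ascontiguousarray(sample.rgb[:, ::-1]),
        depth=np.ascontiguousarray(sample.depth[:, ::-1]),
        label=None if sample.label is None
        else np.ascontiguousarray(sample.label[:, ::-1]),
        identifier=sample.identifier)


def scale_crop(sample: RGBDSample, factor: float, r0: int, c0: int) -> RGBDSample:
    """Upscale by ``factor`` >= 1 and crop back to the original size at (r0, c0).

    rgb is interpolated bilinearly; depth and label use nearest-neighbor so
    their integer values survive.  factor 1.0 with the zero offset is the
    identity.
    """
    H, W = sample.depth.shape
    Hs, Ws = round(H * factor), round(W * factor)

    def _resize(arr, order):
        out = _transform.resize(arr.astype(np.float32), (Hs, Ws), order=order,
                                preserve_range=True, anti_aliasing=False)
        return out[r0:r0 + H, c0:c0 + W]

    rgb = np.clip(np.rint(_resize(sample.rgb, 1)), 0, 255).astype(np.uint8)
    depth = _resize(sample.depth, 0).astype(sample.depth.dtype)
    label = None if sample.label is None \
        else _resize(sample.label, 0).astype(sample.label.dtype)
    return RGBDSample(rgb=rgb, depth=depth, label=label,
                      identifier=sample.identifier)


def augment(sample: RGBDSample, rng: np.random.Generator) -> RGBDSample:
    """Randomized copy of a sample; each op applied independently with p=0.5.

    Spatial ops (horizontal flip; upscale by 1.0-2.0 then random crop back)
    act identically on rgb, depth and label.  Photometric ops (Gaussian blur
    sigma 0.5-1.5, per-channel noise +-10/255, brightness +-20%) act on rgb
    only - they do not move objects, so the depth map stays valid.
    """
    if rng.random() < 0.5:
        sample = hflip(sample)
    if rng.random() < 0.5:
        f = rng.uniform(1.0, 2.0)
        H, W = sample.depth.shape
        Hs, Ws = round(H * f), round(W * f)
        sample = scale_crop(sample, f, rng.integers(0, Hs - H + 1),
                            rng.integers(0, Ws - W + 1))
    rgb = sample.rgb.astype(np.float32)
    if rng.random() < 0.5:
        rgb = _filters.gaussian(rgb, sigma=rng.uniform(0.5, 1.5),
                                channel_axis=-1, preserve_range=True)
    if rng.random() < 0.5:
        rgb = rgb + rng.uniform(-10.0, 10.0, size=3)
    if rng.random() < 0.5:
        rgb = rgb * rng.uniform(0.8, 1.2)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return RGBDSample(rgb=rgb, depth=sample.depth, label=sample.label,
                      identifier=sample.identifier)


# ---------------------------------------------------------------------------
# losses

def pixel_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean per-pixel negative log-likelihood of the target class.

    ``pred`` is a probability map (4,H,W) or (N,4,H,W); zero iff the
    prediction is one-hot correct everywhere.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target)
    if pred.ndim == 3:
        pred, target = pred[None], target[None]
    n_classes = pred.shape[1]
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError(f"target class outside 0..{n_classes - 1}")
    N, _, H, W = pred.shape
    idx = (np.arange(N)[:, None, None], target,
           np.arange(H)[None, :, None], np.arange(W)[None, None, :])
    p = np.clip(pred[idx], 1e-12, None)
    return float(-np.log(p).mean())


# ---------------------------------------------------------------------------
# training loops

def _phase_batch_loss(net: CascadeNet, batch: list[RGBDSample], phase: str,
                      t1: float):
    """Forward one batch through the phase-relevant path; return loss node."""
    rgb = np.stack([net._prep_rgb(s.rgb) for s in batch])
    target = np.stack([s.label for s in batch])
    H, W = rgb.shape[2:]
    if H % 8 or W % 8:
        raise ValueError(
            f"training images must have sides divisible by 8, got {H}x{W}")
    if phase == "stage1":
        logits = net.stage1(Tensor(rgb))
        return softmax_cross_entropy(logits, target)
    if net.variant == "v1":
        x = Tensor(rgb)
        return softmax_cross_entropy(net.stage2(x, x, x), target)
    # gate the whole batch with one frozen stage-1 forward
    prob1 = softmax(net.stage1(Tensor(rgb)).data, axis=1)
    hard = hard_mask(prob1.max(axis=1), t1)          # (N,H,W)
    masked_rgb = rgb * hard[:, None]
    if net.variant == "proposed":
        third = np.stack([net._prep_depth(s.depth) for s in batch])
        third *= hard[:, None]
    else:
        third = masked_rgb
    logits = net.stage2(Tensor(rgb), Tensor(masked_rgb), Tensor(third))
    return softmax_cross_entropy(logits, target)


def _training_mean_iou(net: CascadeNet, samples) -> float:
    was_training = net.training
    net.eval()
    iou = evaluate_dataset(net, samples)["mean_iou"]
    net.train(was_training)
    return iou


def train_phase(net: CascadeNet, samples: list[RGBDSample],
                config: TrainConfig, *, max_iterations: int | None = None,
                stop_mean_iou: float | None = None,
                check_every: int = 25,
                epoch_callback=None) -> list[dict]:
    """Run one optimization phase; returns the per-iteration history.

    Phase ``stage1`` optimizes only stage-1 parameters against the stage-1
    output; phase ``stage2`` requires a completed stage-1 phase, freezes
    stage 1 entirely (parameters, statistics, mode) and optimizes only
    stage-2 parameters against the final output.  Optional early stopping
    checks the training-set mean IOU of the phase-relevant output every
    ``check_every`` iterations.
    """
    if config.phase not in ("stage1", "stage2"):
        raise ValueError(f"unknown phase {config.phase!r}")
    if net.variant == "v1" and config.phase == "stage1":
        raise ValueError("variant v1 has no stage 1; train it with phase stage2")
    if config.phase == "stage2" and net.variant != "v1" \
            and not getattr(net, "stage1_trained", False):
        raise ValueError("phase stage2 requires a completed stage-1 phase "
                         "(train phase stage1 first)")
    rng = np.random.default_rng(config.seed)
    net.seed_dropout(config.seed)

    def set_modes():
        if config.phase == "stage1":
            net.stage1.train()
            net.stage2.eval()
        else:
            net.stage2.train()
            if net.stage1 is not None:
                net.stage1.eval()

    set_modes()
    params = list((net.stage1 if config.phase == "stage1"
                   else net.stage2).parameters())
    opt = SGD(params, lr=config.initial_lr, momentum=config.momentum)
    n = len(samples)
    iters_per_epoch = max(1, -(-n // config.batch_size))
    total = config.epochs * iters_per_epoch
    if max_iterations is not None:
        total = min(total, max_iterations)
    history = []
    for k in range(total):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        batch = [augment(samples[i], rng) if config.augment else samples[i]
                 for i in idx]
        opt.lr = config.lr_at(k)
        opt.zero_grad()
        loss = _phase_batch_loss(net, batch, config.phase, config.t1)
        loss.backward()
        opt.step()
        history.append({"iteration": k, "phase": config.phase,
                        "loss": float(loss.data), "lr": opt.lr})
        if stop_mean_iou is not None and (k + 1) % check_every == 0:
            if _training_mean_iou(net, samples) >= stop_mean_iou:
                break
            set_modes()
        if epoch_callback is not None and (k + 1) % iters_per_epoch == 0:
            epoch_callback(net, (k + 1) // iters_per_epoch)
            set_modes()
    if config.phase == "stage1":
        net.stage1_trained = True
    net.eval()
    return history


def fit(dataset_root, config: TrainConfig, *, variant: str = "proposed",
        flags=DEFAULT_FLAGS, checkpoint_path=None,
        max_iterations_per_phase: int | None = None):
    """Full protocol: load, split 80/10/10, train both phases from random
    initialization, select the best stage-2 state by validation mean IOU.

    Returns ``(net, history, report)`` where ``report`` is the validation
    evaluation of the selected state.
    """
    identifiers = list_identifiers(dataset_root)
    if not identifiers:
        raise ValueError(f"no samples found under {dataset_root}")
    samples = [load_sample(dataset_root, i) for i in identifiers]
    train_set, val_set, _ = split_dataset(samples, config.seed)
    net = CascadeNet(variant, flags, seed=config.seed)
    net.config.t1 = config.t1
    history = []
    if variant != "v1":
        cfg1 = dataclasses.replace(config, phase="stage1")
        history += train_phase(net, train_set, cfg1,
                               max_iterations=max_iterations_per_phase)
    cfg2 = dataclasses.replace(config, phase="stage2")
    # validate once per epoch; keep the best state by validation mean IOU
    best = {"iou": -1.0, "state": None}

    def keep_best(model, _epoch):
        model.eval()
        val_iou = evaluate_dataset(model, val_set)["mean_iou"] if val_set else 0.0
        if val_iou > best["iou"]:
            best.update(iou=val_iou,
                        state={k: v.copy() for k, v in model.state_dict().items()})

    history += train_phase(net, train_set, cfg2,
                           max_iterations=max_iterations_per_phase,
                           epoch_callback=keep_best)
    keep_best(net, -1)
    if best["state"] is not None:
        net.load_state_dict(best["state"])
    net.eval()
    report = evaluate_dataset(net, val_set) if val_set else None
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, net, extra={
            "config": dataclasses.asdict(config),
            "stage1_trained": bool(getattr(net, "stage1_trained", False)),
            "validation_mean_iou": best["iou"],
        })
    return net, history, report
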