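# tomseg

Two-stage RGB-D cascade semantic segmentation for **tomato sucker
detection** — finding the axillary shoots that growers prune away — aimed at
plant-phenotyping and agricultural-robotics work where the pruning point
must first be localized in the image.

Every pixel of a 480×640 RGB-D frame is classified as background (0), stem
(1), branch (2) or sucker (3). A small **stage-1** network segments the RGB
image and scores each pixel's confidence as the maximum class probability
(*Premax*); pixels with confidence ≤ t₁ = 0.7 are *hard*. **Stage 2** — the
network that produces the final output — then sees three inputs fused at a
12:16:4 channel ratio: the RGB image, the RGB image with easy pixels zeroed,
and the mean-centered depth map with easy pixels zeroed,

    D_ij = d_ij − (Σ_ij d_ij) / (n·m),

so depth information is spent only on the ambiguous regions (thin stems,
branches, suckers, and crossings where a far stem mimics a sucker), and the
prediction is exactly invariant to a constant camera offset. The assembled
network has **680,760** trainable parameters; the depth-free Version-2
ablation has **680,832** (+72: its third input convolution reads 3 RGB
channels instead of 1 depth channel).

Sucker detection is scored by a four-step connected-component procedure:
binarize the sucker class in prediction and ground truth, drop predicted
components smaller than t = 160 px, split the ground truth into components,
and count a sucker as detected when its component overlaps the filtered
prediction in at least one pixel.

The networks, including training, run on a NumPy reverse-mode autodiff
engine inside the package (`tomseg.nn`) — there is no deep-learning
framework dependency. Because the original farm dataset is not public, the
package ships a seeded synthetic-scene generator (`tomseg.synth`) that
reproduces the data's structure: thin elongated plant organs, suckers inside
stem–branch axils, class imbalance, and two depth layers with the
crossing-stem ambiguity. See `docs/methods.md` for the model, the
architecture-ambiguity arbitration, and what synthetic results do and do not
show.

## Worked example

```sh
tomseg synth --n 30 --seed 1 --out scenes --small
tomseg train --data scenes --out model.npz --seed 1 \
             --epochs 25 --batch-size 6
tomseg eval --weights model.npz --data scenes --area-threshold 20 \
            --report report.json
tomseg count-params --variant proposed | tail -3
```

The `synth` step writes 30 synthetic 120×160 RGB-D scenes in the dataset
layout (`rgb/`, `depth/` as 24-bit encoded PNG, `labels/`). `train` runs the
two-phase protocol (stage 1 first, then stage 2 with stage 1 frozen; SGD,
batch 12 by default, lr 0.025 decaying ×0.997 per step) on an 80/10/10
split and keeps the best validation checkpoint. A run of the commands above
prints, at the end of training and evaluation:

```
validation mean IOU: 0.7046
checkpoint written to model.npz
mean IOU 0.7313; sucker detection 84.7%
```

i.e. after this short run (25 epochs on 24 training scenes) the cascade
overlaps ground truth by 73% IOU averaged over the four classes (per class:
0.94 background, 0.77 stem, 0.61 branch, 0.61 sucker — the thin classes are
hardest), and 94 of the 111 ground-truth suckers in the set are recovered by
the counting procedure (the area threshold is scaled to the small canvas;
160 px is the 480×640 default). `count-params` ends with

```
    stage1     14432
    stage2    666328
     total    680760
```

— the published anchor that `resolve-variant` uses to arbitrate the
architecture's ambiguities.

Single-image inference:

```sh
tomseg predict --weights model.npz --rgb scenes/rgb/scene_0000_*.png \
       --depth scenes/depth/scene_0000_*.png --out pred.png \
       --dump-diagnostics diag/
```

writes the label map, a color overlay (violet stems, pink branches, green
suckers), and the stage-1 diagnostics (hard-pixel mask, stage-1 labels).

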