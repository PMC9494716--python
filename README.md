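# cellseg

Label-efficient segmentation and counting of mixed cell images.

Counting red blood cells (RBCs) and macrophages in bright-field
microscopy normally requires either a cell analyzer or a semantic
segmentation network trained on thousands of hand-annotated masks.
`cellseg` implements the alternative: **generate the training labels
automatically** on single-kind cell images with classical image
processing, pretrain a U-Net on those free labels, then fine-tune on a
small manually labeled mixed-cell set, and count cells per class from
the predicted masks.  It is aimed at researchers who can culture or
isolate each cell type separately but cannot afford large-scale pixel
annotation of mixed samples.

The package contains:

- `cellseg.autolabel` — the classical pipeline: Gaussian filtering →
  adaptive Gaussian-weighted thresholding → Moore-neighbor border
  following with small-area removal → optional morphological opening
  (erosion `dst(x,y) = min src(x+x',y+y')`, then dilation with `max`)
  to separate adhesive cells and drop debris → contour filling;
- `cellseg.unet` — a size-configurable U-Net (encoder/decoder with skip
  connections, nearest-neighbor upsampling, optional VGG16-style
  encoder preset) implemented in pure numpy with analytic backprop, so
  a tiny variant trains on one CPU core;
- `cellseg.train` — the combined loss `L = H − log J` (pixel-wise
  cross-entropy plus a soft Jaccard term), rotation/scale/gray-value
  augmentation, Adam (β₁ = 0.9, β₂ = 0.999, lr 1e-3, batch 4), and the
  fine-tuning loop at half the learning rate;
- `cellseg.metrics` — confusion matrix, Jaccard/Dice, and

      mIoU  = mean_i  p_ii / (Σ_j p_ij + Σ_j p_ji − p_ii)
      FWIoU = Σ_i (Σ_j p_ij / Σ p) · IoU_i

- `cellseg.count` — per-class connected-component counting with a
  minimum-area false-positive filter and count-accuracy reporting;
- `cellseg.synth` — a seeded generator of synthetic single-kind and
  mixed scenes with ground-truth masks and true counts (small
  near-circular RBCs, ~2.5× larger macrophages, adhesive macrophage
  pairs, debris fibers, noise, illumination gradients);
- `cellseg.protocol` — the desk-scale replication of the three training
  regimes U-Base / U-Single / U-Transfer.

## Worked example

Generate mixed scenes, auto-label a single-kind set, and run the
scaled transfer protocol end to end (one seed, a couple of CPU
minutes):

```pycon
>>> import cellseg as cs
>>> cfg = cs.SynthConfig.small()                      # 64x64 scenes
>>> sc = cs.generate_scene(cfg, "macrophage", cs.scene_rng(2, "macrophage", 0))
>>> sc.true_counts
{1: 0, 2: 1}
>>> label = cs.autolabel_image(sc.image, cs.preset_for_kind(cfg, "macrophage"),
...                            class_value=2)
>>> round(cs.jaccard(label == 2, sc.mask == 2), 3)
0.993
>>> res = cs.run_protocol(seed=1)
>>> {k: round(v, 3) for k, v in res["transfer"].items() if k != "n_images"}
{'miou': 0.961, 'fwiou': 0.984, 'dice': 0.972}
>>> res["counts"]["accuracy_pct"]
{1: 100.57803468208093, 2: 100.0}
```

Reading the numbers: the auto-generated label overlaps the generator's
ground truth at IoU 0.993 on a single-kind macrophage scene;
after pretraining on 200 auto-labeled single-kind images and
fine-tuning on just 10 labeled mixed images, the network reaches
mIoU 0.961 / FWIoU 0.984 / Dice 0.972 on 30 held-out mixed scenes, and
the component counter recovers 174/173 RBCs (100.6%) and 47/47
macrophages (100.0%).

The same steps are available as a CLI for directory-based workflows:

```sh
cellseg synth --kind all --n 20 --size 256 --seed 7 --out data/
cellseg autolabel --in data/rbc/images --class 1 --out data/rbc/autolabels
cellseg train --phase single --data data --kind rbc --masks-dir autolabels --out runs/single
cellseg finetune --from runs/single/model.npz --data data --kind mixed --out runs/transfer
cellseg predict --model runs/transfer/model.npz --in data/mixed/images/0000.png --out pred.png
cellseg count --mask pred.png --out report.json
cellseg eval --pred preds/ --true data/mixed/masks --classes 3 --out metrics.csv
```

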