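# osteoseg

A leak-free 2D semantic-segmentation toolkit for volumetric micro-CT-style
bone scans. It covers the full workflow on plain CPUs with no deep-learning
framework dependency:

- **volume_io** — scans and masks as TIFF slice-stack folders; per-scan
  normalization statistics (z-score / min-max).
- **dataset** — scan-level train/validation splitting (no slice leakage),
  ordered k-fold partitioning, per-tile random patch sampling with overlap
  control, and flip/rot90/brightness/contrast augmentation.
- **models** — architecture registry (a built-in NumPy `tiny_unet` that is
  always available; U-Net/UNet++/DeepLabV3+/SegFormer pass through to
  `segmentation_models_pytorch` when installed) plus FLOPs/parameter
  profiling.
- **fitting** — Jaccard-loss training with Adam, single-cycle cosine
  annealing, micro-aggregated epoch IoU, best-checkpoint saving with
  embedded metadata, versioned CSV logs, and a deterministic mode.
- **prediction** — chunked sliding-window inference with overlap-aware
  probability averaging and confidence-thresholded background reassignment.
- **evaluation** — class-wise/mean IoU, IoU→Dice conversion, and k-fold
  cross-validation orchestration.
- **ranking** — min-max-normalized performance–efficiency weighted scoring
  of model configurations with a weight-sensitivity sweep.
- **phantom** — a synthetic long-bone phantom generator (paired scan/mask
  volumes with packed-bone, dim, composite, 8-bit, drill-hole and
  growth-plate difficulty modes) so everything is testable offline.

Classes are `0 = background`, `1 = bone`, `2 = pores` throughout.

## Test

```sh
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which checks the published
worked values (Dice conversions, patch bookkeeping, split/fold contracts,
ranking formula, augmentation frequencies) and an end-to-end CPU
learnability bar (~3 min: a tiny U-Net trained 5 epochs on 4 phantoms must
reach held-out foreground mIoU ≥ 0.85).

## CLI

```sh
# generate a synthetic dataset
osteoseg simulate --n 6 --shape 16,64,64 --out data/ --hard-modes easy,dim

# train (scan-level split; repeat --pair up to 20 times)
osteoseg fit --pair data/phantom_0000_easy data/phantom_0000_easy_mask \
             --pair data/phantom_0001_dim data/phantom_0001_dim_mask \
             --epochs 5 --patch-size 64 --out run/

# predict with confidence thresholding
osteoseg predict --scan data/phantom_0000_easy --weights run/best.npz \
                 --chunk-size 64 --threshold 0.5 --out pred/

# evaluate
osteoseg iou --reference data/phantom_0000_easy_mask --prediction pred/

# rank model configurations from a metrics CSV
osteoseg rank --metrics metrics.csv --miou-weight 0.85 --sweep 1.0,0.85,0.7
```

Every run echoes the toolkit version string and the resolved configuration;
exit codes are 0 (success), 2 (usage), 3 (data error), 4 (runtime failure).

## Notes

- Checkpoints are `.npz` bundles of weights plus a JSON metadata block
  (architecture, normalization mode, patch size, hyperparameters, version);
  prediction refuses checkpoints with incomplete metadata.
- Training defaults include one cross-entropy warmup epoch before the
  Jaccard objective takes over (`FitConfig.ce_warmup_epochs`, set 0 to
  disable): pure region losses started from random initialization on small
  CPU budgets can permanently entrench early confident errors.
- Deterministic mode guarantees bitwise-identical reruns on the same
  machine; cross-platform bitwise identity is not promised.
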