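# Methods

## Problem and approach

`nsseg` implements Noisy Student self-training for binary lesion
segmentation. The setting: a small set of images with expert masks, a much
larger pool of unlabeled images, and the goal of a per-pixel foreground
classifier that beats what the labeled set alone supports.

Three models are trained in sequence:

1. **Teacher** — trained on labeled data only.
2. **Student** — the teacher predicts a probability map for every unlabeled
   image; maps are thresholded at 0.5 into pseudo-masks; masks with fewer
   than 100 foreground pixels (defined at 256×256, rescaled quadratically
   to the working resolution) are screened out as low-confidence. The
   student trains on all n labeled images plus n×m sampled pseudo-labeled
   ones, under *input noise* (augmentations) and *model noise* (spatial
   dropout p=0.5), so it must reproduce labels made on clean images from
   noised ones.
3. **Student\*** — the best student (by validation mIoU) regenerates the
   pseudo-labels and a second student is trained the same way.

Validation and testing only ever use real labels; a pseudo- or unlabeled
record reaching an evaluation path raises `ValidationPurityError`.

## Loss and metrics

Training minimizes the soft dice loss with smoothing λ (default 1):

    L = 1 − (2·Σ p·y + λ) / (Σ p + Σ y + λ)

summed per image, averaged over the batch. Evaluation uses pixel-wise
confusion counts per image: IoU = TP/(TP+FP+FN), Dice = 2TP/(2TP+FP+FN),
precision, recall. Conventions chosen for degenerate synthetic cases and
documented because they matter:

- all four metrics return 1 when their denominator is zero (both-empty);
- aggregates are arithmetic means of per-image values, never pooled counts;
- "fraction of images with IoU over τ" uses strict inequality; τ=0.8 and
  the clinical-usefulness threshold τ=0.786 are both reported;
- binarization maps p ≥ threshold to foreground.

Confidence intervals are nonparametric percentile bootstraps of the mean
(default 10,000 resamples, seeded). Test-time augmentation evaluates R
seeded perturbation runs (flips, shifts, brightness/contrast, hue shift,
histogram equalization, rotation; geometric ops transform the mask too so
pairs stay aligned) and averages each metric over runs.

## Network

`CompactSegNet` is an encoder–decoder written directly in numpy with
explicit backward passes: per stage a same-padded 3×3 convolution,
instance normalization, ReLU, and 2×2 max-pooling; channel widths double
per stage (capped at 8× the base width); an optional multi-rate dilated
context block (parallel 3×3 convolutions at rates 1/2/4, summed) sits at
the bottleneck; the decoder mirrors with nearest-neighbour upsampling and
optional concatenated skip connections; one spatial-dropout layer before a
1×1 logistic classifier provides the model noise. Weights are He-normal
from the spec seed, so identical specs give bitwise-identical models.

Two deliberate deviations from the heavyweight reference architectures:

- **Scale.** The default (depth 3, base 8, ≈40k parameters at 64 px) is
  sized for desk-scale CPU experiments, not for dermoscopy benchmarks.
  Heavier backbones can be registered through `segmodel.register_builder`.
- **Instance normalization.** Large pretrained backbones carry batch
  normalization internally; a small net trained from scratch without any
  normalization is initialization-sensitive (training can stall in the
  constant-prediction basin of the dice loss). Instance norm keeps
  evaluation deterministic (no running statistics, identical train/eval
  behaviour) and removes that sensitivity.

## Optimization

SGD with momentum and weight decay, cosine-annealed learning rate
lr(e) = lr0·½(1+cos(π·e/E)), batch size 10, dice loss, per-sample
augmentation re-drawn every epoch, early stopping on validation mIoU with
patience 15, and the returned checkpoint is the best-validation one, not
the last. The recipe record (`TrainConfig`) defaults to the study values
lr0=0.002, momentum β=0.54 (taken verbatim, not "corrected"), weight decay
0.01 — appropriate for large pretrained encoders trained for 60–90 epochs
on thousands of images. The compact from-scratch network needs a larger
step: `ConvSegmenter` defaults to lr0=0.1, and the synthetic benchmark
sets lr0=0.1 explicitly. This was calibrated once for trainability (the
net reaches mIoU ≈ 0.84 across seeds at 64 px within 20 epochs; at 0.002
the loss is flat) and not revisited.

Every random draw — weight init, shuffling, augmentation parameters,
dropout masks, pseudo-label subsampling, bootstrap — comes from a child
seed derived as SHA-256(master seed, stage, purpose), so any stage is
independently reproducible and two runs with the same config are
byte-identical, including pseudo-label PNGs and metric JSON.

## Augmentation engine

Ops act jointly on (image, mask). Photometric ops (brightness, contrast,
saturation multiplicative factors in [0.8, 1.2]; hue shift ±0.05 of the
hue circle; Gaussian blur σ ∈ [0, 1.5] px; coarse dropout of 1–8 black
rectangles, 2–10% of the side each; histogram equalization) never touch
the mask — coarse dropout models an occluder, so it does not punch holes
in the label. Geometric ops (flips p=0.5; rotation uniform in ±180°;
shifts ±10%; elastic transform σ=8 px / α=30 px; 5×5 grid distortion
±30%; radial optical distortion k ∈ [−0.3, 0.3]) sample one inverse
coordinate map and apply it to the image bilinearly and to the mask with
nearest-neighbour interpolation, so the pair cannot desynchronize;
out-of-frame samples fill by reflection. Firing probabilities: flips,
blur, and the single "modern" op of a set fire at 0.5, the remaining
photometric ops and rotation always fire. The named sets are exactly
`none`, `simple`, and `simple+{coarse_dropout,elastic,grid,optical}`; the
TTA op list is a separate builder (`tta_set()`).

## Synthetic data generator

Each sample is one darker, irregular lesion on a skin-toned background
with an exact mask. The boundary is a radial-Fourier star
r(θ) = r0·(1 + A·Σ_{j≤k} a_j cos(jθ+φ_j)) with Σa_j = 1, k=6 harmonics and
amplitude A=0.25 by default; since the enclosed area is analytically
r0²π(1 + A²Σa_j²/2), r0 is solved so the foreground fraction lands in the
configured range (default 5–40% of the image), with a small iterative
correction for rasterization. The image is a sampled skin tone, the lesion
tone shifted so the mean intensity gap equals a sampled contrast delta
(default 0.15–0.45), a 2-px Gaussian-smoothed boundary, 0–5 dark
anti-aliased hair-like polylines drawn on the image only (occluders never
enter the mask), and i.i.d. Gaussian noise (σ=0.03). Parameter validation
enforces contrast > 2σ_noise so lesions stay statistically detectable.

What the generator does *not* emulate: ruler/gel artifacts, multi-lesion
images, color calibration differences, camera vignetting, and the
long-tailed difficulty distribution of real dermoscopy. Passing the
synthetic benchmark therefore demonstrates that the pipeline's mechanics
(pseudo-labeling, screening, composition, noise, selection, metrics) are
correct and that self-training helps when pseudo-labels are imperfect but
mostly right — it does not certify clinical-grade accuracy on real data.

## Benchmark and problem sizes

The bundled benchmark generates 330 samples at 64×64: 30 labeled train,
240 unlabeled (the same 1:8 imbalance direction as the study), 20
validation, 40 test; ratio m=4, 20 epochs per stage. A full three-stage
run takes ≈3 minutes on one CPU core. At seed 11 the teacher reaches test
mIoU ≈ 0.845 and the student ≈ 0.855 — the direction of the self-training
effect, at desk scale. `scripts/acceptance.py` re-runs this benchmark from
scratch at a caller-chosen seed and adds TTA evaluation and bootstrap CIs.

## Numerical and design notes

- Images load as float64 in [0,1] (bilinear resize to the target size);
  masks resize by nearest-neighbour index sampling (floor((i+0.5)·in/out))
  and binarize at >127, so antialiased mask files stay strictly binary.
- Evaluation happens at the working resolution (256 default, 64 in the
  benchmark), not the original file resolution.
- The pseudo-label subset of size n×m is a seeded uniform sample without
  replacement; ranking by mean foreground confidence is available as
  `selection="confidence"`.
- The screening threshold is strict (< min_pixels rejects).
- Early stopping reads "validation IoU no longer improves"; the best
  checkpoint is restored afterwards.
- The final short batch of an epoch is kept, not dropped.
- Teacher and student share one architecture spec by default; the teacher
  trains with the same augmentation set as the student.
- Checkpoints are single-file .npz archives embedding weights, the model
  spec, the stage tag, and the training seed.

## Known limitations

- No third self-training iteration (the pipeline stops at student*).
- No boundary metrics (Hausdorff, ASSD) and no significance testing
  between models.
- The numpy network is single-threaded per op; expect minutes, not
  seconds, for benchmark-scale training, and do not expect it to scale to
  256×256 datasets of thousands of images.
- The CLI covers run/generate/pseudolabel/evaluate; ratio sweeps and
  report tables are a few lines of Python over `run_selftrain` /
  `MetricsReport`.
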