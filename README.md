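# cmapaug

Colormap-based intensity augmentation for cross-modality domain
generalization in medical image segmentation.

## The problem

A segmentation network trained on one imaging modality (say, abdominal MRI)
usually fails outright on another (CT): the physics behind each modality
assigns tissues entirely different intensities, and intensity is exactly the
cue a convolutional network latches onto first. *Domain generalization*
asks for a model trained on source-modality data only — the target modality
stays completely unseen until test time.

This package implements a simple, GPU-free intensity augmentation that
attacks the problem at the data level, inside a complete training/evaluation
harness for single-organ (liver-style) segmentation:

* **CmapAug** — every training slice is mapped from grayscale to RGB through
  a colormap lookup table drawn uniformly from a curated pool of 32
  matplotlib colormaps (probability 1, a fresh draw per image per epoch).
  Validation and test images are all rendered with one fixed map,
  `gnuplot2`. Because the color assigned to a tissue keeps changing during
  training, the network is pushed to rely on image *structure* rather than
  absolute intensity.
* **ExAug** — an extensive stack of 14 stochastic transforms τ¹…τ¹⁴ applied
  in a fixed order, each with probability *p* and magnitude *m*
  (crop-resize, rotation, affine scale/translation, optical distortion,
  elastic deformation, a one-of group of sharpen/blur/noise/motion-blur, a
  global intensity shift, and a one-of group of brightness/gamma/color
  jitter). The augmented pair is
  (x̂, ŷ) = τ¹⁴(τ¹³(… τ¹(x, y))), with geometric members warping image and
  mask identically and intensity members leaving the mask untouched.
* A 5-stage **2D U-Net** (two 3×3 zero-padded convolutions + batch norm +
  ReLU per stage, feature widths doubling from `base_width`), trained with
  the soft dice loss and Adam, written in pure NumPy with hand-derived
  backpropagation so the whole pipeline runs anywhere Python runs.
* **Evaluation** — per-slice 2D Dice for epoch validation and model
  selection; per-patient-volume 3D Dice (%) and symmetric Hausdorff
  distance (voxels) for testing.
* **Synthetic phantoms** — paired contrast-inverted "modalities" with shared
  per-patient anatomy (ellipsoidal organ plus distractor blobs, bias fields,
  texture, noise), so the full cross-modality experiment runs at desk scale
  without any clinical data download.

The colormap pool is derived from the standard matplotlib catalogue in two
steps: drop maps that lose gray-level information through many-to-one color
coding (all qualitative maps, `flag`, `prism`), then drop maps that barely
recolor the image (all diverging and sequential maps, `twilight`,
`twilight_shifted`, `cividis`, `binary`, `gist_yarg`, `gist_gray`, `gray`).
Exactly 32 maps survive.

## Worked example

Select the colormap package:

```text
$ cmapaug select-colormaps
# 32 colormaps, eval map: gnuplot2
viridis              perceptually-uniform-sequential
plasma               perceptually-uniform-sequential
inferno              perceptually-uniform-sequential
magma                perceptually-uniform-sequential
bone                 sequential2
...
```

Generate a paired-modality phantom cohort and run the two key strategies of
the ablation (desk-scale profile: 8 source + 8 target patients, 32×64×64
volumes, width-8 U-Net, 30 epochs, batch 12):

```python
from cmapaug import default_phantom_spec, generate_dataset
from cmapaug.pipeline import desk_experiment_config, train_strategy, test_strategy
import numpy as np

src, tgt = generate_dataset(default_phantom_spec(seed=0), "phantoms/")
for name in ("baseline", "exaug+cmapaug"):
    cfg = desk_experiment_config(src, {"modality_b": tgt}, strategy=name, seed=0)
    model, history = train_strategy(cfg)
    records = test_strategy(model, name, tgt, source_domain="modality_a",
                            target_domain="modality_b", image_size=64)
    print(name, f"val {max(history.val_dice):.1f}",
          f"target {np.mean([r.dice_3d for r in records]):.1f}")
```

Output from this exact run:

```text
baseline val 98.9 target 0.0
exaug+cmapaug val 93.6 target 26.0
```

Read: the unaugmented model is essentially perfect on its own modality
(validation Dice 98.9%) and collapses to Dice 0 on the contrast-inverted
unseen modality; combining colormap and extensive augmentation recovers a
substantial part of that gap (Dice 26 vs 0) under identical seeds, split
and architecture. At this miniature scale the size of the recovery varies
with the training seed (see `docs/methods.md`); the baseline collapse does
not.

The same experiment is scriptable from the shell: `cmapaug simulate`,
`cmapaug train --config exp.yaml`, `cmapaug evaluate`, `cmapaug ablation`,
and `cmapaug preview-augment` for visual inspection of augmented slices.

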