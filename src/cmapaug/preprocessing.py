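"""Fixed preprocessing pipeline: outlier clipping, normalization, resizing.

Every volume passes through the same three steps before training or
evaluation: (1) CT volumes only — intensities beyond the upper bound of the
12-bit Hounsfield scale are acquisition artifacts and are replaced by the
volume's in-range maximum; (2) per-volume min-max normalization to [0, 1];
(3) per-slice resize to a common grid (256x256 at clinical scale), bilinear
for images and nearest-neighbor for masks.  The pipeline is idempotent on
already-processed data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "GrayVolume", "MaskVolume", "HOUNSFIELD_RANGE",
    "clip_hounsfield_outliers", "minmax_normalize", "resize_slices",
    "preprocess_pair",
]

#: 12-bit CT convention; only the upper bound triggers replacement.
HOUNSFIELD_RANGE = (-1024.0, 3071.0)


@dataclass(frozen=True)
class GrayVolume:
    """A D x H x W stack of grayscale slices with patient identity."""

    voxels: np.ndarray
    patient_id: str
    modality_tag: str = ""
    spacing: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        if voxels.ndim != 3:
            raise ValueError(f"volume must be 3D (D, H, W), got {voxels.shape}")
        object.__setattr__(self, "voxels", voxels)

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]

    def is_ct(self) -> bool:
        return self.modality_tag.upper().startswith("CT")


@dataclass(frozen=True)
class MaskVolume:
    """A binary D x H x W organ mask paired with a gray volume."""

    voxels: np.ndarray
    patient_id: str

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels)
        if voxels.ndim != 3:
            raise ValueError(f"mask must be 3D (D, H, W), got {voxels.shape}")
        labels = np.unique(voxels)
        if not np.isin(labels, (0, 1)).all():
            raise ValueError(f"mask labels must be within {{0, 1}}, got {labels}")
        object.__setattr__(self, "voxels", voxels.astype(np.uint8))

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]


def clip_hounsfield_outliers(
    vol: GrayVolume, hu_range: tuple[float, float] = HOUNSFIELD_RANGE
) -> GrayVolume:
    """Replace intensities exceeding the Hounsfield upper bound.

    Values above ``hu_range[1]`` become the volume's maximum value within the
    range; everything at or below the bound is untouched.
    """
    _, hi = hu_range
    voxels = np.asarray(vol.voxels)
    in_range = voxels <= hi
    if not in_range.any():
        raise ValueError(
            f"volume {vol.patient_id!r} has no intensity within the "
            f"Hounsfield range (max allowed {hi})"
        )
    ceiling = voxels[in_range].max()
    return replace(vol, voxels=np.where(in_range, voxels, ceiling))


def minmax_normalize(vol: GrayVolume) -> GrayVolume:
    """Map the volume linearly onto [0, 1] using volume-level extrema.

    Constant volumes map to all zeros.
    """
    voxels = np.asarray(vol.voxels, dtype=np.float64)
    if not np.isfinite(voxels).all():
        raise ValueError(f"volume {vol.patient_id!r} contains non-finite values")
    lo, hi = voxels.min(), voxels.max()
    if hi == lo:
        return replace(vol, voxels=np.zeros_like(voxels, dtype=np.float32))
    return replace(vol, voxels=((voxels - lo) / (hi - lo)).astype(np.float32))


def resize_slices(
    vol: GrayVolume, mask: MaskVolume, target: int = 256
) -> tuple[GrayVolume, MaskVolume]:
    """Resize every slice to ``target x target``.

    Bilinear interpolation for the image, nearest-neighbor for the mask, so
    the mask stays binary and the pair keeps spatial correspondence.
    """
    if vol.depth == 0:
        raise ValueError("cannot resize an empty volume")
    if vol.voxels.shape != mask.voxels.shape:
        raise ValueError("volume and mask shapes differ")
    if vol.voxels.shape[1:] == (target, target):
        return vol, mask
    shape = (vol.depth, target, target)
    img = _sk_resize(vol.voxels.astype(np.float32), shape, order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    msk = _sk_resize(mask.voxels.astype(np.float32), shape, order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return (replace(vol, voxels=img.astype(np.float32)),
            replace(mask, voxels=(msk > 0.5).astype(np.uint8)))


def preprocess_pair(
    vol: GrayVolume, mask: MaskVolume, target: int = 256,
    apply_hounsfield_clip: bool | None = None,
) -> tuple[GrayVolume, MaskVolume]:
    """Run the fixed pipeline: clip (CT only) -> normalize -> resize.

    ``apply_hounsfield_clip=None`` decides from the modality tag.
    """
    if apply_hounsfield_clip is None:
        apply_hounsfield_clip = vol.is_ct()
    if apply_hounsfield_clip:
        vol = clip_hounsfield_outliers(vol)
    vol = minmax_normalize(vol)
    return resize_slices(vol, mask, target=target)
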