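"""Dataset readers and writers.

Two on-disk layouts are supported:

* NIfTI pairs — ``<patient>.nii[.gz]`` image plus a mask NIfTI; float
  voxels round-trip bit-exactly (float32).
* Slice directories — a directory with ``image/`` and ``mask/`` subfolders of
  per-slice PNG files, matched by natural-sorted filename order (the layout
  of public abdominal challenge exports).

A dataset manifest is a CSV with columns ``patient_id, image_path,
mask_path, modality_tag, split``; one row per patient volume.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .preprocessing import GrayVolume, MaskVolume

__all__ = [
    "MissingMaskError", "SliceCountMismatchError", "UnreadableFileError",
    "read_volume", "write_volume_nifti", "write_volume_png_dir",
    "read_manifest", "write_manifest", "load_patient",
]

MANIFEST_COLUMNS = ("patient_id", "image_path", "mask_path", "modality_tag", "split")


class MissingMaskError(FileNotFoundError):
    """The ground-truth mask for a volume could not be located."""


class SliceCountMismatchError(ValueError):
    """Image and mask disagree in slice count or slice shape."""


class UnreadableFileError(OSError):
    """A file exists but could not be parsed as image data."""


def _natural_key(path: Path):
    return [int(tok) if tok.isdigit() else tok.lower()
            for tok in re.split(r"(\d+)", path.name)]


def _read_png_stack(directory: Path) -> np.ndarray:
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() == ".png"),
        key=_natural_key,
    )
    if not files:
        raise UnreadableFileError(f"no PNG slices in {directory}")
    slices = []
    for f in files:
        try:
            arr = np.asarray(iio.imread(f))
        except Exception as exc:  # pillow raises various types
            raise UnreadableFileError(f"cannot read {f}: {exc}") from exc
        if arr.ndim == 3:  # RGB(A) export of a gray slice
            arr = arr[..., 0]
        slices.append(arr)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise SliceCountMismatchError(f"inconsistent slice shapes in {directory}: {shapes}")
    return np.stack(slices)


def _load_nifti(path: Path) -> np.ndarray:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise UnreadableFileError(f"cannot read {path}: {exc}") from exc
    # store/read in (D, H, W); nibabel uses Fortran-style (X, Y, Z)
    return np.asarray(img.dataobj).transpose(2, 1, 0)


def read_volume(
    image_path: str | Path,
    mask_path: str | Path | None = None,
    *,
    patient_id: str | None = None,
    modality_tag: str = "",
) -> tuple[GrayVolume, MaskVolume]:
    """Read one patient volume with its binary mask.

    ``image_path`` is either a NIfTI file (then ``mask_path`` must name the
    mask NIfTI) or a slice directory.  For a directory, the mask defaults to
    its ``mask/`` subfolder with images under ``image/``.  Masks are
    binarized by a nonzero test; slices are ordered by natural filename sort.
    """
    image_path = Path(image_path)
    if patient_id is None:
        patient_id = image_path.name.split(".")[0]

    if image_path.is_dir():
        img_dir = image_path / "image" if (image_path / "image").is_dir() else image_path
        if mask_path is None:
            mask_path = image_path / "mask"
        mask_dir = Path(mask_path)
        if not mask_dir.is_dir():
            raise MissingMaskError(f"mask directory {mask_dir} not found")
        voxels = _read_png_stack(img_dir)
        mask_vox = _read_png_stack(mask_dir)
    else:
        if mask_path is None or not Path(mask_path).exists():
            raise MissingMaskError(f"mask for {image_path} not found: {mask_path}")
        voxels = _load_nifti(image_path)
        mask_vox = _load_nifti(Path(mask_path))

    if voxels.shape != mask_vox.shape:
        raise SliceCountMismatchError(
            f"{patient_id}: image {voxels.shape} vs mask {mask_vox.shape}"
        )
    return (
        GrayVolume(voxels=voxels, patient_id=patient_id, modality_tag=modality_tag),
        MaskVolume(voxels=(mask_vox != 0).astype(np.uint8), patient_id=patient_id),
    )


def write_volume_nifti(
    vol: GrayVolume, mask: MaskVolume, image_path: str | Path,
    mask_path: str | Path,
) -> None:
    """Write an image/mask pair as float32/uint8 NIfTI files."""
    spacing = vol.spacing or (1.0, 1.0, 1.0)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img_xyz = np.asarray(vol.voxels, dtype=np.float32).transpose(2, 1, 0)
    msk_xyz = np.asarray(mask.voxels, dtype=np.uint8).transpose(2, 1, 0)
    for arr, path in ((img_xyz, image_path), (msk_xyz, mask_path)):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_volume_png_dir(
    vol: GrayVolume, mask: MaskVolume, directory: str | Path
) -> None:
    """Write a pair as 8-bit PNG slice folders (``image/`` and ``mask/``)."""
    directory = Path(directory)
    voxels = np.asarray(vol.voxels, dtype=np.float64)
    if voxels.size and (voxels.min() < 0 or voxels.max() > 1):
        raise ValueError("PNG export expects voxels normalized to [0, 1]")
    (directory / "image").mkdir(parents=True, exist_ok=True)
    (directory / "mask").mkdir(parents=True, exist_ok=True)
    for i in range(vol.depth):
        img8 = np.rint(voxels[i] * 255).astype(np.uint8)
        iio.imwrite(directory / "image" / f"slice_{i:04d}.png", img8)
        iio.imwrite(directory / "mask" / f"slice_{i:04d}.png",
                    (mask.voxels[i] * 255).astype(np.uint8))


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(df)[list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def load_patient(row, base_dir: str | Path | None = None
                 ) -> tuple[GrayVolume, MaskVolume]:
    """Load the volume a manifest row points to (paths may be relative to
    the manifest's directory, passed as ``base_dir``)."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    image_path = Path(row["image_path"])
    mask_path = Path(row["mask_path"])
    if not image_path.is_absolute():
        image_path = base / image_path
    if not mask_path.is_absolute():
        mask_path = base / mask_path
    return read_volume(
        image_path, mask_path,
        patient_id=row["patient_id"],
        modality_tag=row.get("modality_tag", "") or "",
    )
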