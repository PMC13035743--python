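"""Synthetic cross-modality phantom volumes.

Generates paired "modalities" that share anatomy but differ in appearance,
emulating the structure of a cross-modality liver benchmark at desk scale:
each patient is an ellipsoidal body containing one large target organ
(the segmentation target) and a few small distractor blobs.  A modality
profile renders the tissue-class map into intensities through its own
transfer function, adds a smooth low-order polynomial bias field and
Gaussian noise.  The default pair is contrast-inverted — organ bright in
modality A, dark in modality B — the strongest appearance shift between
real modalities (e.g. a structure that is bright on one sequence and
extremely dark on another).

Everything is deterministic in ``(seed, patient_index)``; source and target
datasets use disjoint patient indices so the two domains contain different
anatomies, as separate patient cohorts would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .io import write_manifest, write_volume_nifti
from .preprocessing import GrayVolume, MaskVolume

__all__ = [
    "ModalityProfile", "PhantomSpec", "default_phantom_spec",
    "generate_patient", "generate_dataset",
]


@dataclass(frozen=True)
class ModalityProfile:
    """Appearance of one imaging modality on the [0, 1] intensity scale.

    ``intensities`` maps each tissue class to its mean intensity — a scalar,
    or a ``(lo, hi)`` range sampled once per structure (per patient for the
    organ, per blob for distractors).  Ranges let tissue classes overlap in
    intensity, as real parenchyma and lesions do, so that no single gray
    value identifies a class and structure must disambiguate.  On top of the
    class means the renderer adds a smooth low-order polynomial bias field
    (``bias_amplitude``), spatially correlated within-tissue texture
    (``texture_sd``, Gaussian-smoothed) and white Gaussian noise
    (``noise_sd``).
    """

    intensities: Mapping[str, float | tuple[float, float]]
    noise_sd: float = 0.03
    bias_amplitude: float = 0.15
    texture_sd: float = 0.06

    def __post_init__(self) -> None:
        required = {"air", "body", "organ", "distractor"}
        if set(self.intensities) != required:
            raise ValueError(f"profile must define intensities for {sorted(required)}")
        object.__setattr__(self, "intensities",
                           MappingProxyType(dict(self.intensities)))


def _default_profiles() -> dict[str, ModalityProfile]:
    return {
        # bright organ on darker parenchyma; distractor blobs span a range
        # that overlaps the organ, so intensity alone cannot separate them
        "modality_a": ModalityProfile(
            {"air": 0.05, "body": 0.35, "organ": (0.65, 0.80),
             "distractor": (0.50, 0.90)}),
        # contrast-inverted: dark organ on a brighter background
        "modality_b": ModalityProfile(
            {"air": 0.05, "body": 0.65, "organ": (0.15, 0.30),
             "distractor": (0.10, 0.50)}),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance settings for the phantom cohort.

    Ellipsoid semi-axes and radii are in normalized coordinates (half the
    volume extent along each axis equals 1).  The organ must occupy between
    1% and 40% of the volume; anatomies violating this are re-drawn.
    """

    shape: tuple[int, int, int] = (32, 64, 64)
    organ_semi_axes: tuple[tuple[float, float], ...] = (
        (0.50, 0.65), (0.42, 0.56), (0.42, 0.56))
    organ_center_jitter: float = 0.12
    body_semi_axes: tuple[float, float, float] = (0.95, 0.88, 0.88)
    distractor_count: tuple[int, int] = (2, 4)
    distractor_radius: tuple[float, float] = (0.10, 0.20)
    profiles: Mapping[str, ModalityProfile] = field(
        default_factory=_default_profiles)
    n_patients: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 4:
            raise ValueError("shape must be 3D with sides >= 4")
        object.__setattr__(self, "profiles",
                           MappingProxyType(dict(self.profiles)))


def default_phantom_spec(seed: int = 0, n_patients: int = 8) -> PhantomSpec:
    """The shipped desk-scale cohort: 32x64x64 volumes, 8 patients per
    domain, contrast-inverted modality pair."""
    return PhantomSpec(seed=seed, n_patients=n_patients)


def _normalized_grid(shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grid, center, semi_axes) -> np.ndarray:
    zz, yy, xx = grid
    return (((zz - center[0]) / semi_axes[0]) ** 2
            + ((yy - center[1]) / semi_axes[1]) ** 2
            + ((xx - center[2]) / semi_axes[2]) ** 2) <= 1.0


def _bias_field(grid, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    zz, yy, xx = grid
    terms = [zz, yy, xx, zz * zz, yy * yy, xx * xx, zz * yy, zz * xx, yy * xx]
    coeffs = rng.normal(size=len(terms))
    fld = sum(c * t for c, t in zip(coeffs, terms))
    fld -= fld.mean()
    peak = np.abs(fld).max()
    return amplitude * fld / peak if peak > 0 else fld


def _draw_anatomy(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Tissue-label map: 0 air, 1 body, 2 organ, 3+j the j-th distractor."""
    grid = _normalized_grid(spec.shape)
    classes = np.zeros(spec.shape, dtype=np.uint8)
    classes[_ellipsoid(grid, (0.0, 0.0, 0.0), spec.body_semi_axes)] = 1

    center = rng.uniform(-spec.organ_center_jitter, spec.organ_center_jitter, 3)
    axes = [rng.uniform(lo, hi) for lo, hi in spec.organ_semi_axes]
    organ = _ellipsoid(grid, center, axes) & (classes == 1)

    n_distract = int(rng.integers(spec.distractor_count[0],
                                  spec.distractor_count[1] + 1))
    for j in range(n_distract):
        for _try in range(20):
            c = rng.uniform(-0.6, 0.6, 3)
            r = rng.uniform(*spec.distractor_radius)
            blob = _ellipsoid(grid, c, (r, r, r))
            if (blob & (classes == 1) & ~organ).any():
                classes[blob & (classes == 1)] = 3 + j
                break
    classes[organ] = 2
    return classes


def generate_patient(
    spec: PhantomSpec, patient_index: int
) -> tuple[dict[str, GrayVolume], MaskVolume]:
    """Render one patient in every modality of the spec.

    The anatomy (and hence the mask) is shared across modalities; each
    modality adds its own transfer function, bias field and noise.
    Deterministic in ``(spec.seed, patient_index)``.
    """
    for attempt in range(10):
        rng = np.random.default_rng([spec.seed, patient_index, attempt])
        classes = _draw_anatomy(spec, rng)
        fraction = np.count_nonzero(classes == 2) / classes.size
        if 0.01 < fraction < 0.4:
            break
    else:
        raise ValueError(
            f"patient {patient_index}: no valid organ geometry in 10 attempts"
        )

    grid = _normalized_grid(spec.shape)
    mask = MaskVolume(voxels=(classes == 2).astype(np.uint8),
                      patient_id=f"p{patient_index:03d}")
    n_labels = int(classes.max()) + 1
    volumes: dict[str, GrayVolume] = {}
    for k, (name, profile) in enumerate(spec.profiles.items()):
        mod_rng = np.random.default_rng([spec.seed, patient_index, 100 + k])

        def _mean(value) -> float:
            if isinstance(value, tuple):
                return float(mod_rng.uniform(*value))
            return float(value)

        lookup = np.empty(n_labels)
        lookup[0] = _mean(profile.intensities["air"])
        lookup[1] = _mean(profile.intensities["body"])
        lookup[2] = _mean(profile.intensities["organ"])
        for label in range(3, n_labels):  # one draw per distractor blob
            lookup[label] = _mean(profile.intensities["distractor"])
        voxels = lookup[classes]
        voxels = voxels + _bias_field(grid, profile.bias_amplitude, mod_rng)
        if profile.texture_sd > 0:
            from scipy.ndimage import gaussian_filter

            texture = gaussian_filter(
                mod_rng.normal(0.0, 1.0, spec.shape), sigma=2.0)
            peak = np.abs(texture).max()
            if peak > 0:
                voxels = voxels + profile.texture_sd * texture / texture.std()
        voxels = voxels + mod_rng.normal(0.0, profile.noise_sd, spec.shape)
        volumes[name] = GrayVolume(
            voxels=np.clip(voxels, 0.0, 1.0).astype(np.float32),
            patient_id=mask.patient_id,
            modality_tag=name,
        )
    return volumes, mask


_TARGET_INDEX_OFFSET = 100  # target-domain patients use a disjoint id range


def generate_dataset(
    spec: PhantomSpec,
    out_dir: str | Path,
    source_modality: str = "modality_a",
    target_modality: str = "modality_b",
) -> tuple[Path, Path]:
    """Write a source and a target dataset plus manifest CSVs.

    Source patients are rendered in ``source_modality`` and target patients
    — different anatomies, disjoint patient ids — in ``target_modality``,
    ``spec.n_patients`` each.  Volumes go to NIfTI files with paths stored
    relative to ``out_dir``; returns the two manifest paths.
    """
    if spec.n_patients < 8:
        raise ValueError("need n_patients >= 8 for a patient-level split")
    out_dir = Path(out_dir)
    manifests = {}
    for role, modality, offset in (
        ("source", source_modality, 0),
        ("target", target_modality, _TARGET_INDEX_OFFSET),
    ):
        rows = []
        for i in range(spec.n_patients):
            index = offset + i
            volumes, mask = generate_patient(spec, index)
            vol = volumes[modality]
            pid = f"{role[:3]}{i:02d}"
            img_rel = f"{role}/{pid}_img.nii.gz"
            msk_rel = f"{role}/{pid}_mask.nii.gz"
            write_volume_nifti(
                GrayVolume(vol.voxels, patient_id=pid, modality_tag=modality),
                MaskVolume(mask.voxels, patient_id=pid),
                out_dir / img_rel, out_dir / msk_rel,
            )
            rows.append({
                "patient_id": pid, "image_path": img_rel,
                "mask_path": msk_rel, "modality_tag": modality,
                "split": role,
            })
        manifest_path = out_dir / f"{role}_manifest.csv"
        write_manifest(pd.DataFrame(rows), manifest_path)
        manifests[role] = manifest_path
    return manifests["source"], manifests["target"]
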