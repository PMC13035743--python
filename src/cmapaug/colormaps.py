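"""Grayscale-to-RGB colormap lookup-table transforms.

The core augmentation idea: map each normalized gray value through a 256-entry
RGB lookup table (LUT) so a segmentation network trains entirely in RGB space,
seeing the same anatomy under a different color rendering for every image.  A
curated package of 32 matplotlib colormaps is used as the training pool; one
fixed member (``gnuplot2``) renders every validation and test image so model
selection and testing happen under a single, reproducible coloring.

The training pool is derived from the standard matplotlib catalogue in two
steps: drop maps that destroy gray-level information (many-to-one color
assignment: all qualitative maps, plus ``flag`` and ``prism``), then drop maps
whose rendering stays too close to the gray diagonal to perturb intensities
meaningfully (all diverging and sequential maps, ``twilight``,
``twilight_shifted``, ``cividis``, ``binary``, ``gist_yarg``, ``gist_gray``,
``gray``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from matplotlib import colormaps as _mpl_colormaps

__all__ = [
    "CATEGORY_TABLE",
    "Colormap",
    "ColormapPackage",
    "RGBSlice",
    "NormalizationError",
    "ConfigurationError",
    "get_colormap",
    "standard_catalogue",
    "apply_colormap",
    "is_injective",
    "change_magnitude",
    "select_package",
    "default_package",
    "draw_training_map",
    "save_package",
    "load_package",
]

LUT_SIZE = 256

#: Canonical category assignment of the standard matplotlib colormap
#: catalogue (the grouping of the matplotlib colormap reference).  Shipped as
#: data so the selection procedure is insulated from catalogue drift across
#: plotting-library versions.
CATEGORY_TABLE: dict[str, tuple[str, ...]] = {
    "perceptually-uniform-sequential": (
        "viridis", "plasma", "inferno", "magma", "cividis",
    ),
    "sequential": (
        "Greys", "Purples", "Blues", "Greens", "Oranges", "Reds",
        "YlOrBr", "YlOrRd", "OrRd", "PuRd", "RdPu", "BuPu", "GnBu",
        "PuBu", "YlGnBu", "PuBuGn", "BuGn", "YlGn",
    ),
    "sequential2": (
        "binary", "gist_yarg", "gist_gray", "gray", "bone", "pink",
        "spring", "summer", "autumn", "winter", "cool", "Wistia",
        "hot", "afmhot", "gist_heat", "copper",
    ),
    "diverging": (
        "PiYG", "PRGn", "BrBG", "PuOr", "RdGy", "RdBu", "RdYlBu",
        "RdYlGn", "Spectral", "coolwarm", "bwr", "seismic",
    ),
    "cyclic": ("twilight", "twilight_shifted", "hsv"),
    "qualitative": (
        "Pastel1", "Pastel2", "Paired", "Accent", "Dark2", "Set1",
        "Set2", "Set3", "tab10", "tab20", "tab20b", "tab20c",
    ),
    "miscellaneous": (
        "flag", "prism", "ocean", "gist_earth", "terrain", "gist_stern",
        "gnuplot", "gnuplot2", "CMRmap", "cubehelix", "brg",
        "gist_rainbow", "rainbow", "jet", "turbo", "nipy_spectral",
        "gist_ncar",
    ),
}

EVAL_MAP_NAME = "gnuplot2"

# Step-1 exclusions: many-to-one color coding loses gray-level information.
_INFO_LOSS_NAMES = frozenset({"flag", "prism"})
# Step-2 exclusions: renderings too close to a gray ramp to change intensities.
_MINOR_CHANGE_NAMES = frozenset(
    {"twilight", "twilight_shifted", "cividis", "binary", "gist_yarg",
     "gist_gray", "gray"}
)
_EXCLUDED_CATEGORIES_STEP1 = frozenset({"qualitative"})
_EXCLUDED_CATEGORIES_STEP2 = frozenset({"diverging", "sequential"})


class NormalizationError(ValueError):
    """Raised when image data is not normalized to the [0, 1] range."""


class ConfigurationError(ValueError):
    """Raised when a colormap package or catalogue is unusable."""


@dataclass(frozen=True)
class Colormap:
    """A named 256-entry RGB lookup table with its catalogue category."""

    name: str
    lut: np.ndarray
    category: str

    def __post_init__(self) -> None:
        lut = np.asarray(self.lut, dtype=np.float64)
        if lut.shape != (LUT_SIZE, 3):
            raise ValueError(f"LUT must be ({LUT_SIZE}, 3), got {lut.shape}")
        if lut.min() < 0.0 or lut.max() > 1.0:
            raise ValueError("LUT channel values must lie in [0, 1]")
        object.__setattr__(self, "lut", lut)


@dataclass(frozen=True)
class RGBSlice:
    """An RGB rendering of a gray slice, tagged with the colormap applied."""

    pixels: np.ndarray
    provenance: str

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.pixels, dtype=dtype)


def _category_of(name: str) -> str:
    for category, names in CATEGORY_TABLE.items():
        if name in names:
            return category
    raise KeyError(f"colormap {name!r} is not in the standard catalogue")


def get_colormap(name: str) -> Colormap:
    """Build a :class:`Colormap` from the matplotlib registry."""
    mpl_map = _mpl_colormaps[name]
    lut = np.asarray(mpl_map(np.arange(LUT_SIZE) / (LUT_SIZE - 1)))[:, :3]
    return Colormap(name=name, lut=lut, category=_category_of(name))


def standard_catalogue() -> list[Colormap]:
    """The full standard plotting catalogue with category annotations."""
    return [get_colormap(n) for names in CATEGORY_TABLE.values() for n in names]


def apply_colormap(slice_: np.ndarray, cmap: Colormap) -> RGBSlice:
    """Map a gray slice through a colormap LUT, pixel by pixel.

    Each gray value ``g`` in [0, 1] is assigned the LUT entry at index
    ``round(g * 255)``; no interpolation or neighborhood information is
    involved, so the operation commutes with any spatial permutation.
    Masks are never colormapped — only the image passes through here.

    Parameters
    ----------
    slice_
        2D gray image with values in [0, 1].
    cmap
        Lookup table to apply.

    Returns
    -------
    RGBSlice
        H×W×3 rendering, channels in [0, 1], tagged with ``cmap.name``.
    """
    gray = np.asarray(slice_, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError(f"expected a 2D gray slice, got shape {gray.shape}")
    if gray.size and (gray.min() < 0.0 or gray.max() > 1.0):
        raise NormalizationError(
            "gray values outside [0, 1]; min-max normalize before colormapping"
        )
    idx = np.clip(np.rint(gray * (LUT_SIZE - 1)).astype(np.intp), 0, LUT_SIZE - 1)
    return RGBSlice(pixels=cmap.lut[idx], provenance=cmap.name)


def is_injective(cmap: Colormap, max_collision_span: int = 4) -> bool:
    """Whether the LUT preserves gray-level information at 8-bit precision.

    Entries are quantized to 8 bits per channel (the stored precision of the
    source images).  Adjacent gray levels on a slow color ramp may then share
    a quantized color; that costs at most a couple of bits of gray precision
    and loses no structure.  Information is genuinely destroyed only when two
    *distant* gray levels receive the same color — the many-to-one coding of
    periodic or piecewise-constant maps.  The LUT is therefore judged
    injective iff no two gray levels more than ``max_collision_span`` indices
    apart share an 8-bit color.
    """
    quantized = np.rint(cmap.lut * 255.0).astype(np.int64)
    seen: dict[tuple[int, int, int], int] = {}
    for i, triple in enumerate(map(tuple, quantized)):
        first = seen.setdefault(triple, i)
        if i - first > max_collision_span:
            return False
    return True


def change_magnitude(cmap: Colormap) -> float:
    """Mean Euclidean RGB distance of the LUT from the gray diagonal.

    Zero for the identity gray ramp; larger for maps that recolor the image
    more aggressively.  Depends only on the LUT, never on image content.
    Advisory score for the "minor changes" screening step, whose published
    outcome is the fixed exclusion list applied by :func:`select_package`.
    """
    gray_diagonal = np.repeat(
        (np.arange(LUT_SIZE) / (LUT_SIZE - 1))[:, None], 3, axis=1
    )
    return float(np.mean(np.linalg.norm(cmap.lut - gray_diagonal, axis=1)))


def select_package(catalogue: Iterable[Colormap]) -> ColormapPackage:
    """Run the two-step screening over a catalogue and return the package.

    Step 1 removes information-losing maps (all qualitative maps, ``flag``,
    ``prism``); step 2 removes maps that barely change the image (all
    diverging and sequential maps, the near-gray cyclic and sequential2
    entries and ``cividis``).  Catalogue order is preserved.  On the standard
    catalogue the survivors are exactly the 32-map training pool.
    """
    survivors = []
    for cmap in catalogue:
        if cmap.category in _EXCLUDED_CATEGORIES_STEP1 or cmap.name in _INFO_LOSS_NAMES:
            continue
        if cmap.category in _EXCLUDED_CATEGORIES_STEP2 or cmap.name in _MINOR_CHANGE_NAMES:
            continue
        survivors.append(cmap.name)
    if not survivors:
        raise ConfigurationError("no colormaps survive the selection procedure")
    eval_map = EVAL_MAP_NAME if EVAL_MAP_NAME in survivors else survivors[0]
    return ColormapPackage(members=tuple(survivors), eval_map=eval_map)


@dataclass(frozen=True)
class ColormapPackage:
    """An ordered training pool of colormap names plus the fixed eval map.

    ``eval_map`` renders every validation and test image; training images are
    rendered with uniform random draws from ``members`` (probability 1 — every
    training image is colormapped).
    """

    members: tuple[str, ...]
    eval_map: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigurationError("colormap package has no members")
        if len(set(self.members)) != len(self.members):
            raise ConfigurationError("duplicate colormap names in package")
        if self.eval_map not in self.members:
            raise ConfigurationError(
                f"eval map {self.eval_map!r} is not a package member"
            )

    def __len__(self) -> int:
        return len(self.members)

    def colormap(self, name: str) -> Colormap:
        if name not in self.members:
            raise KeyError(f"{name!r} is not in the package")
        return get_colormap(name)

    @property
    def eval_colormap(self) -> Colormap:
        return get_colormap(self.eval_map)

    def content_hash(self) -> str:
        import hashlib

        text = "\n".join(self.members) + f"\neval:{self.eval_map}"
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def default_package() -> ColormapPackage:
    """The canonical 32-member training pool with ``gnuplot2`` for eval."""
    return select_package(standard_catalogue())


def draw_training_map(
    pkg: ColormapPackage, rng: np.random.Generator
) -> Colormap:
    """Uniformly draw one training colormap from the package."""
    if len(pkg) == 0:  # pragma: no cover - ColormapPackage forbids this
        raise ConfigurationError("cannot draw from an empty package")
    name = pkg.members[int(rng.integers(len(pkg)))]
    return get_colormap(name)


def save_package(pkg: ColormapPackage, path: str | Path) -> None:
    """Serialize a package as one name per line with an ``# eval:`` header."""
    lines = [f"# eval: {pkg.eval_map}"] + list(pkg.members)
    Path(path).write_text("\n".join(lines) + "\n")


def load_package(path: str | Path) -> ColormapPackage:
    eval_map = None
    members: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("eval:"):
                eval_map = body.split(":", 1)[1].strip()
            continue
        members.append(line)
    if eval_map is None:
        raise ConfigurationError(f"{path}: missing '# eval:' header")
    return ColormapPackage(members=tuple(members), eval_map=eval_map)
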