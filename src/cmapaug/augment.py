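"""Stacked stochastic augmentation strategies.

An augmentation strategy is an ordered stack of stochastic transforms.  Each
transform carries a firing probability ``p`` and a magnitude ``m`` (a scalar
or a uniform sampling range); when applied, the stack composes sequentially,
so the augmented pair is the n-fold composition of the member transforms on
the input image/mask pair.  Geometric members warp image and mask with
identical sampled parameters; intensity members modify the image only.

The shipped ``exaug`` configuration is the 14-transform extensive stack
(crop/rotate/affine/distortion/elastic, a one-of group of quality transforms,
a global intensity perturbation, and a one-of group of brightness/gamma/color
jitter); ``bigaug`` is a second, stronger-magnitude stack built from the same
machinery.  Combining a stack with colormap augmentation colorizes the
grayscale slice first (a random training map) and then runs the stack in RGB
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from . import transforms as T
from .colormaps import ColormapPackage, apply_colormap, draw_training_map

__all__ = [
    "TransformSpec", "OneOfGroup", "AugmentationStrategy",
    "STRATEGY_NAMES", "builtin_strategy", "make_exaug_stack",
    "make_bigaug_stack", "apply_transform", "apply_stack",
    "augment_training_sample", "load_strategy_file", "save_strategy_file",
    "flatten_stack",
]

_GEOMETRIC_NAMES = frozenset({
    "centercrop_resize", "rotation", "affine_scale", "affine_translate",
    "optical_distortion", "elastic",
})
_INTENSITY_NAMES = frozenset({
    "sharpen", "gaussian_blur", "gaussian_noise", "motion_blur",
    "intensity_shift", "brightness_contrast", "gamma", "color_jitter",
})

#: The baseline plus the eight ablation strategies.  The style-transfer
#: slots keep the table structure but are not runnable here (they require
#: pre-trained style prediction/transfer networks and an external painting
#: dataset).
STRATEGY_NAMES = (
    "baseline",
    "bigaug", "exaug", "styleaug", "cmapaug",
    "bigaug+styleaug", "exaug+styleaug",
    "bigaug+cmapaug", "exaug+cmapaug",
)


@dataclass(frozen=True)
class TransformSpec:
    """One stochastic transform: a name, firing probability and magnitudes.

    ``params`` maps parameter names to either a fixed scalar or a
    ``(lo, hi)`` uniform sampling range.
    """

    name: str
    probability: float
    params: tuple[tuple[str, float | tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        if self.name not in _GEOMETRIC_NAMES | _INTENSITY_NAMES:
            raise ValueError(f"unknown transform {self.name!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        for key, value in self.params:
            if isinstance(value, tuple) and value[0] > value[1]:
                raise ValueError(f"{self.name}.{key}: range min exceeds max")

    @property
    def kind(self) -> str:
        return "geometric" if self.name in _GEOMETRIC_NAMES else "intensity"

    def param_dict(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class OneOfGroup:
    """A group that fires with its own probability and then selects exactly
    one member, weighting the selection by the members' probabilities."""

    probability: float
    members: tuple[TransformSpec, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("one-of group needs at least one member")
        if sum(m.probability for m in self.members) <= 0:
            raise ValueError("one-of member probabilities must not all be zero")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([m.probability for m in self.members], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class AugmentationStrategy:
    """An ordered transform stack plus the colormap-augmentation switch."""

    name: str
    stack: tuple[TransformSpec | OneOfGroup, ...] = ()
    use_colormap: bool = False

    def requires_color(self) -> bool:
        return self.use_colormap or any(
            m.name == "color_jitter" for m in flatten_stack(self.stack)
        )


def flatten_stack(
    stack: Sequence[TransformSpec | OneOfGroup],
) -> list[TransformSpec]:
    """All member TransformSpecs in application/table order."""
    out: list[TransformSpec] = []
    for item in stack:
        if isinstance(item, OneOfGroup):
            out.extend(item.members)
        else:
            out.append(item)
    return out


# ----------------------------------------------------------------- sampling

def _sample(value, rng: np.random.Generator) -> float:
    if isinstance(value, tuple):
        return float(rng.uniform(value[0], value[1]))
    return float(value)


def _execute(spec: TransformSpec, image, mask, rng):
    p = {k: _sample(v, rng) for k, v in spec.params}
    name = spec.name
    if name == "centercrop_resize":
        return T.center_crop_resize(image, mask, p["size"])
    if name == "rotation":
        return T.rotate(image, mask, p["angle"])
    if name == "affine_scale":
        return T.affine_scale(image, mask, p["scale"])
    if name == "affine_translate":
        px = spec.param_dict()["px"]
        return T.affine_translate(image, mask, _sample(px, rng), p["px"])
    if name == "optical_distortion":
        return T.optical_distortion(image, mask, p["distort_limit"],
                                    p.get("shift_limit", 0.0))
    if name == "elastic":
        return T.elastic(image, mask, p["alpha"], p["sigma"],
                         p["alpha_affine"], rng)
    if name == "sharpen":
        return T.sharpen(image, p["alpha"]), mask
    if name == "gaussian_blur":
        return T.gaussian_blur(image, p["sigma"]), mask
    if name == "gaussian_noise":
        return T.gaussian_noise(image, p["var"], rng), mask
    if name == "motion_blur":
        ksize = int(round(p["ksize"]))
        return T.motion_blur(image, ksize if ksize % 2 else ksize + 1, rng), mask
    if name == "intensity_shift":
        return T.intensity_shift(image, p["shift"]), mask
    if name == "brightness_contrast":
        return T.brightness_contrast(image, p["brightness"], p["contrast"]), mask
    if name == "gamma":
        # tabulated percent-style range (100 = identity)
        return T.gamma(image, p["gamma"] / 100.0), mask
    if name == "color_jitter":
        return T.color_jitter(image, p["brightness"], p["contrast"],
                              p["saturation"], p["hue"]), mask
    raise AssertionError(f"unhandled transform {name!r}")


def apply_transform(spec, image, mask, rng: np.random.Generator, *,
                    force: bool = False, trace: list | None = None):
    """Apply one transform (or one-of group) with its firing probability.

    With probability ``1 - p`` the inputs are returned untouched (the same
    arrays, bit-identical).  ``force=True`` skips the probability draw; the
    transform fires unconditionally.  ``trace``, if given, collects the names
    of transforms that actually fired.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} spatial shapes differ"
        )
    if isinstance(spec, OneOfGroup):
        if not force and rng.random() >= spec.probability:
            return image, mask
        member = spec.members[int(rng.choice(len(spec.members), p=spec.weights))]
        if trace is not None:
            trace.append(member.name)
        return _execute(member, image, mask, rng)
    if not force and rng.random() >= spec.probability:
        return image, mask
    if trace is not None:
        trace.append(spec.name)
    return _execute(spec, image, mask, rng)


def apply_stack(strategy: AugmentationStrategy | Sequence, image, mask,
                rng: np.random.Generator, *, trace: list | None = None):
    """Compose the strategy's transforms sequentially in stack order."""
    stack = strategy.stack if isinstance(strategy, AugmentationStrategy) else strategy
    for item in stack:
        image, mask = apply_transform(item, image, mask, rng, trace=trace)
    return image, mask


def augment_training_sample(strategy: AugmentationStrategy,
                            pkg: ColormapPackage | None, image, mask,
                            rng: np.random.Generator, *,
                            trace: list | None = None):
    """Augment one grayscale training slice under a strategy.

    Colormap-augmented strategies colorize first — a uniform random training
    map, applied to every image (probability 1) — and then run the stack in
    RGB space.  Stacks containing color transforms but no colormap operate on
    the grayscale slice replicated to three channels.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("training samples enter as 2D grayscale slices")
    if strategy.use_colormap:
        if pkg is None:
            raise ValueError(f"strategy {strategy.name!r} needs a colormap package")
        cmap = draw_training_map(pkg, rng)
        if trace is not None:
            trace.append(f"colormap:{cmap.name}")
        image = apply_colormap(image, cmap).pixels
    elif strategy.requires_color():
        image = np.repeat(image[..., None], 3, axis=-1)
    return apply_stack(strategy, image, mask, rng, trace=trace)


# ------------------------------------------------------------ configuration

def _format_value(value) -> str:
    if isinstance(value, tuple):
        return f"{value[0]:g}..{value[1]:g}"
    return f"{value:g}"


def _parse_value(text: str):
    if ".." in text:
        lo, hi = text.split("..")
        return (float(lo), float(hi))
    return float(text)


def _parse_line(line: str) -> tuple[str, float, tuple]:
    tokens = line.split()
    name = tokens[0]
    prob = None
    params = []
    for token in tokens[1:]:
        key, _, value = token.partition("=")
        if key == "p":
            prob = float(value)
        else:
            params.append((key, _parse_value(value)))
    if prob is None:
        raise ValueError(f"transform line without p=: {line!r}")
    return name, prob, tuple(params)


def load_strategy_file(path: str | Path, name: str | None = None,
                       use_colormap: bool | None = None) -> AugmentationStrategy:
    """Parse a plain-text strategy file into an :class:`AugmentationStrategy`.

    Format: one transform per line as ``name p=<prob> key=value ...`` where a
    value is a scalar or a ``lo..hi`` range; a ``oneof p=<prob>`` line opens a
    group whose members are the following indented lines.  ``# strategy:``
    and ``# use_colormap:`` headers set defaults that the keyword arguments
    override.
    """
    file_name, file_cmap = None, False
    stack: list[TransformSpec | OneOfGroup] = []
    pending: tuple[float, list[TransformSpec]] | None = None

    def close_pending():
        nonlocal pending
        if pending is not None:
            stack.append(OneOfGroup(pending[0], tuple(pending[1])))
            pending = None

    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        stripped = raw.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.startswith("strategy:"):
                file_name = body.split(":", 1)[1].strip()
            elif body.startswith("use_colormap:"):
                file_cmap = body.split(":", 1)[1].strip().lower() == "true"
            continue
        indented = raw[0].isspace()
        tname, prob, params = _parse_line(stripped)
        if tname == "oneof":
            close_pending()
            pending = (prob, [])
        elif indented and pending is not None:
            pending[1].append(TransformSpec(tname, prob, params))
        else:
            close_pending()
            stack.append(TransformSpec(tname, prob, params))
    close_pending()
    return AugmentationStrategy(
        name=name or file_name or Path(path).stem,
        stack=tuple(stack),
        use_colormap=file_cmap if use_colormap is None else use_colormap,
    )


def save_strategy_file(strategy: AugmentationStrategy, path: str | Path) -> None:
    lines = [f"# strategy: {strategy.name}",
             f"# use_colormap: {str(strategy.use_colormap).lower()}"]
    for item in strategy.stack:
        if isinstance(item, OneOfGroup):
            lines.append(f"oneof p={item.probability:g}")
            for member in item.members:
                parts = [f"    {member.name}", f"p={member.probability:g}"]
                parts += [f"{k}={_format_value(v)}" for k, v in member.params]
                lines.append(" ".join(parts))
        else:
            parts = [item.name, f"p={item.probability:g}"]
            parts += [f"{k}={_format_value(v)}" for k, v in item.params]
            lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def _load_builtin(stem: str, **kwargs) -> AugmentationStrategy:
    ref = resources.files("cmapaug.data").joinpath(f"{stem}.cfg")
    with resources.as_file(ref) as path:
        return load_strategy_file(path, **kwargs)


def make_exaug_stack() -> AugmentationStrategy:
    """The shipped 14-transform extensive augmentation stack."""
    return _load_builtin("exaug")


def make_bigaug_stack() -> AugmentationStrategy:
    """The shipped benchmark stack: three families (quality, appearance,
    spatial), fewer members with stronger magnitudes."""
    return _load_builtin("bigaug")


def builtin_strategy(name: str) -> AugmentationStrategy:
    """Resolve one of the named ablation strategies."""
    if name not in STRATEGY_NAMES:
        raise KeyError(f"unknown strategy {name!r}; choose from {STRATEGY_NAMES}")
    if "styleaug" in name:
        raise NotImplementedError(
            f"strategy {name!r} requires pre-trained style prediction and "
            "transfer networks plus an external painting dataset; it is a "
            "named placeholder in this package"
        )
    if name == "baseline":
        return AugmentationStrategy("baseline", (), use_colormap=False)
    if name == "cmapaug":
        return AugmentationStrategy("cmapaug", (), use_colormap=True)
    base, _, _ = name.partition("+")
    use_cmap = name.endswith("+cmapaug")
    return _load_builtin(base, name=name, use_colormap=use_cmap)
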