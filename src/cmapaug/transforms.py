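"""Low-level image transform primitives for the augmentation stacks.

All functions operate on float images in [0, 1], shaped (H, W) for grayscale
or (H, W, 3) for RGB, and on binary masks shaped (H, W).  Geometric
primitives take ``(image, mask)`` and warp both with the identical sampled
parameters — bilinear interpolation for the image, nearest-neighbor for the
mask so it stays binary.  Intensity primitives touch the image only and clip
the result back to [0, 1].
"""

from __future__ import annotations

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "center_crop_resize", "rotate", "affine_scale", "affine_translate",
    "optical_distortion", "elastic", "sharpen", "gaussian_blur",
    "gaussian_noise", "motion_blur", "intensity_shift",
    "brightness_contrast", "gamma", "color_jitter",
]

_REFERENCE_SIDE = 256  # side length the tabulated pixel magnitudes refer to


def _per_channel(image: np.ndarray, fn) -> np.ndarray:
    if image.ndim == 2:
        return fn(image)
    return np.stack([fn(image[..., c]) for c in range(image.shape[-1])], axis=-1)


def _clip01(image: np.ndarray) -> np.ndarray:
    return np.clip(image, 0.0, 1.0)


def _warp_affine(image, mask, matrix, offset):
    """Apply ``input = matrix @ output + offset`` to image (linear) and mask
    (nearest)."""
    warped = _per_channel(
        image,
        lambda ch: ndimage.affine_transform(
            ch, matrix, offset=offset, order=1, mode="constant", cval=0.0
        ),
    )
    warped_mask = ndimage.affine_transform(
        mask.astype(np.float32), matrix, offset=offset, order=0,
        mode="constant", cval=0.0,
    )
    return _clip01(warped), (warped_mask > 0.5).astype(mask.dtype)


def _warp_coords(image, mask, coords):
    warped = _per_channel(
        image,
        lambda ch: ndimage.map_coordinates(
            ch, coords, order=1, mode="constant", cval=0.0
        ),
    )
    warped_mask = ndimage.map_coordinates(
        mask.astype(np.float32), coords, order=0, mode="constant", cval=0.0
    )
    return _clip01(warped), (warped_mask > 0.5).astype(mask.dtype)


# ---------------------------------------------------------------- geometric

def center_crop_resize(image, mask, size: float, out: int | None = None):
    """Crop a centered square and resize back to the original grid.

    ``size`` is the crop side on a 256-pixel reference grid; for other image
    sizes the crop side scales proportionally so the magnitude keeps the same
    relative meaning.  The output always has the input's spatial shape (the
    tabulated 256x256 output coincides with it for 256x256 inputs).
    """
    h, w = mask.shape
    side = int(round(size * min(h, w) / _REFERENCE_SIDE))
    side = max(2, min(side, min(h, w)))
    top, left = (h - side) // 2, (w - side) // 2
    img_c = image[top:top + side, left:left + side]
    mask_c = mask[top:top + side, left:left + side]
    out_shape = (h, w)
    img_r = _sk_resize(
        img_c, out_shape + img_c.shape[2:], order=1, mode="constant",
        cval=0.0, anti_aliasing=False, preserve_range=True,
    )
    mask_r = _sk_resize(
        mask_c.astype(np.float32), out_shape, order=0, mode="constant",
        cval=0.0, anti_aliasing=False, preserve_range=True,
    )
    return _clip01(img_r), (mask_r > 0.5).astype(mask.dtype)


def rotate(image, mask, angle: float):
    """Rotate by ``angle`` degrees around the image center."""
    h, w = mask.shape
    theta = np.deg2rad(angle)
    # rounding kills ~1e-16 trig noise that would push edge coordinates
    # infinitesimally out of bounds (constant mode blanks those pixels)
    rot = np.round(np.array([[np.cos(theta), -np.sin(theta)],
                             [np.sin(theta), np.cos(theta)]]), 12)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - rot @ center
    return _warp_affine(image, mask, rot, offset)


def affine_scale(image, mask, scale: float):
    """Zoom by ``scale`` (>1 enlarges) around the image center."""
    h, w = mask.shape
    matrix = np.eye(2) / scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - matrix @ center
    return _warp_affine(image, mask, matrix, offset)


def affine_translate(image, mask, px_row: float, px_col: float):
    """Shift content by (+px_row, +px_col) pixels toward increasing indices."""
    offset = np.array([-px_row, -px_col])
    return _warp_affine(image, mask, np.eye(2), offset)


def optical_distortion(image, mask, distort: float, shift: float = 0.0):
    """Radial (barrel/pincushion) distortion with coefficient ``distort``.

    Output position at normalized radius r samples the input at
    ``r * (1 + distort * r^2)``, optionally shifted by ``shift`` (fraction of
    the image side) — zero in the shipped configuration.
    """
    h, w = mask.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    u, v = (yy - cy) / cy, (xx - cx) / cx
    r2 = u * u + v * v
    factor = 1.0 + distort * r2
    coords = np.stack([cy + u * factor * cy + shift * h,
                       cx + v * factor * cx + shift * w])
    return _warp_coords(image, mask, coords)


def elastic(image, mask, alpha: float, sigma: float, alpha_affine: float,
            rng: np.random.Generator):
    """Elastic deformation: smoothed random displacement plus a small affine.

    The displacement field is uniform noise in [-1, 1] per axis, Gaussian
    smoothed with ``sigma`` and scaled by ``alpha`` pixels.  The affine part
    perturbs three reference points by up to ``alpha_affine`` pixels and maps
    the image through the exactly fitted affine transform.
    """
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # affine part from three perturbed reference points
    d = min(h, w) / 3.0
    src = np.array([[h / 2, w / 2], [h / 2 + d, w / 2], [h / 2, w / 2 + d]])
    dst = src + rng.uniform(-abs(alpha_affine), abs(alpha_affine), src.shape)
    # solve dst -> src (inverse map) as an exact affine fit
    a_mat = np.hstack([dst, np.ones((3, 1))])
    sol = np.linalg.solve(a_mat, src)  # (3, 2): rows = linear part + offset
    lin, off = sol[:2].T, sol[2]
    base_y = lin[0, 0] * yy + lin[0, 1] * xx + off[0]
    base_x = lin[1, 0] * yy + lin[1, 1] * xx + off[1]

    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma) * alpha
    coords = np.stack([base_y + dy, base_x + dx])
    return _warp_coords(image, mask, coords)


# ---------------------------------------------------------------- intensity

def sharpen(image, alpha: float):
    """Unsharp-mask blend: emphasize detail by ``alpha`` of the residual."""
    blurred = _per_channel(image, lambda ch: ndimage.gaussian_filter(ch, 1.0))
    return _clip01(image + alpha * (image - blurred))


def gaussian_blur(image, sigma: float):
    return _clip01(_per_channel(image, lambda ch: ndimage.gaussian_filter(ch, sigma)))


def gaussian_noise(image, var: float, rng: np.random.Generator):
    """Additive Gaussian noise with variance ``var`` on the [0, 1] scale."""
    return _clip01(image + rng.normal(0.0, np.sqrt(var), image.shape))


def motion_blur(image, ksize: int, rng: np.random.Generator):
    """Convolve with a random-direction line kernel of odd size ``ksize``."""
    ksize = int(ksize) | 1
    angle = rng.uniform(0.0, np.pi)
    kernel = np.zeros((ksize, ksize))
    c = (ksize - 1) / 2.0
    for t in np.linspace(-c, c, 2 * ksize + 1):
        r = int(round(c + t * np.sin(angle)))
        col = int(round(c + t * np.cos(angle)))
        kernel[r, col] = 1.0
    kernel /= kernel.sum()
    return _clip01(_per_channel(
        image, lambda ch: ndimage.convolve(ch, kernel, mode="nearest")))


def intensity_shift(image, shift: float):
    """Global additive offset, sampled once per image."""
    return _clip01(image + shift)


def brightness_contrast(image, brightness: float, contrast: float):
    """Brightness offset plus contrast scaling around the image mean."""
    out = image + brightness
    if contrast:
        out = image.mean() + (out - image.mean()) * (1.0 + contrast)
    return _clip01(out)


def gamma(image, gamma_value: float):
    """Power-law intensity remap; ``gamma_value`` = 1 is the identity."""
    return _clip01(np.power(np.clip(image, 0.0, 1.0), gamma_value))


def color_jitter(image, brightness: float, contrast: float,
                 saturation: float, hue: float):
    """Jitter brightness/contrast/saturation by multiplicative factors and
    rotate hue by a fraction of the full color circle.

    Requires a 3-channel image; grayscale inputs must be replicated to RGB by
    the caller.  Factors of 1 and hue 0 are the identity.  The four steps are
    applied in the fixed order brightness, contrast, saturation, hue.
    """
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("color_jitter requires an (H, W, 3) image")
    out = _clip01(image * brightness)
    gray_mean = out.mean()
    out = _clip01(gray_mean + (out - gray_mean) * contrast)
    luma = (0.299 * out[..., 0] + 0.587 * out[..., 1] + 0.114 * out[..., 2])
    out = _clip01(luma[..., None] + (out - luma[..., None]) * saturation)
    if hue:
        hsv = rgb_to_hsv(out)
        hsv[..., 0] = np.mod(hsv[..., 0] + hue, 1.0)
        out = _clip01(hsv_to_rgb(hsv))
    return out
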