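"""Patch tiling, whole-image downsampling, and the 8-fold augmentation policy.

Conventions: bilinear interpolation everywhere; tiling is a non-overlapping
row-major floor grid with right/bottom remainders discarded; rotation/shear
use reflect padding and keep the original size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import AffineTransform, warp

__all__ = ["TilingSpec", "AugmentPolicy", "tile", "downsample_global", "augment",
           "tile_count"]


@dataclass
class TilingSpec:
    """Resize target (width, height), patch side, and global input side."""

    resize_to: tuple[int, int] | None = (1120, 672)
    patch_side: int = 224
    global_input_side: int = 224

    def __post_init__(self):
        if self.patch_side < 1 or self.global_input_side < 1:
            raise ValueError("patch and global sides must be positive")
        if self.resize_to is not None:
            w, h = self.resize_to
            if self.patch_side > w or self.patch_side > h:
                raise ValueError("patch side exceeds the resized dimensions")


@dataclass
class AugmentPolicy:
    """Random rotation, flips, and shear; n_outputs independent draws."""

    n_outputs: int = 8
    rotation_range: tuple[float, float] = (0.0, 360.0)
    flip_horizontal: bool = True
    flip_vertical: bool = True
    shear_range: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")
        if self.shear_range < 0:
            raise ValueError("shear_range must be non-negative")


def _bilinear_resize(image: np.ndarray, width: int, height: int) -> np.ndarray:
    """Center-aligned bilinear resize (output pixel centers sample the input).

    With this convention an exact factor-2 downscale averages 2x2 blocks.
    """
    if image.shape[0] == height and image.shape[1] == width:
        return image
    img = image.astype(float)
    h, w = img.shape[:2]
    rows = (np.arange(height) + 0.5) * h / height - 0.5
    cols = (np.arange(width) + 0.5) * w / width - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    if img.ndim == 2:
        out = ndimage.map_coordinates(img, [rr, cc], order=1, mode="nearest")
    else:
        out = np.stack(
            [ndimage.map_coordinates(img[..., c], [rr, cc], order=1, mode="nearest")
             for c in range(img.shape[2])], axis=-1)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(image.dtype)
    return out


def tile_count(width: int, height: int, side: int) -> int:
    """Patches on the non-overlapping floor grid: floor(W/s) * floor(H/s)."""
    return (width // side) * (height // side)


def tile(image: np.ndarray, spec: TilingSpec | None = None) -> list[np.ndarray]:
    """Row-major non-overlapping patches of ``patch_side`` after resizing."""
    spec = spec or TilingSpec()
    img = np.asarray(image)
    if spec.resize_to is not None:
        img = _bilinear_resize(img, spec.resize_to[0], spec.resize_to[1])
    h, w = img.shape[:2]
    s = spec.patch_side
    if h < s or w < s:
        raise ValueError(f"image {w}x{h} smaller than one {s}x{s} patch")
    patches = []
    for gy in range(h // s):
        for gx in range(w // s):
            patches.append(img[gy * s : (gy + 1) * s, gx * s : (gx + 1) * s].copy())
    return patches


def downsample_global(image: np.ndarray, spec: TilingSpec | None = None) -> np.ndarray:
    """Bilinear resize to a square of ``global_input_side``."""
    spec = spec or TilingSpec()
    img = np.asarray(image)
    side = spec.global_input_side
    if img.shape[0] == side and img.shape[1] == side:
        return img.copy()
    return _bilinear_resize(img, side, side)


def _warp_affine(image: np.ndarray, rotation_deg: float, shear_deg: float) -> np.ndarray:
    if rotation_deg == 0.0 and shear_deg == 0.0:
        return image.copy()
    h, w = image.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tform = (AffineTransform(translation=-center)
             + AffineTransform(rotation=np.deg2rad(rotation_deg),
                               shear=np.deg2rad(shear_deg))
             + AffineTransform(translation=center))
    out = warp(image.astype(float), tform.inverse, mode="reflect", order=1,
               preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(image.dtype)
    return out


def augment(image: np.ndarray, policy: AugmentPolicy | None = None) -> list[np.ndarray]:
    """``n_outputs`` independently sampled transformed copies of the image.

    Each output draws: rotation uniform over ``rotation_range``, each enabled
    flip with probability 0.5, shear uniform over +-``shear_range``.
    Deterministic under the policy seed; output size is preserved.
    """
    policy = policy or AugmentPolicy()
    rng = np.random.default_rng(policy.seed)
    img = np.asarray(image)
    outputs = []
    lo, hi = policy.rotation_range
    for _ in range(policy.n_outputs):
        rot = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        flip_h = policy.flip_horizontal and rng.random() < 0.5
        flip_v = policy.flip_vertical and rng.random() < 0.5
        shear = (float(rng.uniform(-policy.shear_range, policy.shear_range))
                 if policy.shear_range > 0 else 0.0)
        out = img
        if flip_h:
            out = out[:, ::-1]
        if flip_v:
            out = out[::-1, :]
        outputs.append(_warp_affine(out, rot, shear))
    return outputs
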