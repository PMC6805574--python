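"""Statistical stain color normalization in the logarithmic lab opponent space.

Imposes the per-channel mean/std of a reference image on an input image.  The
fixed RGB<->LMS and log-LMS<->lab matrices are the canonical Reinhard/Ruderman
color-transfer constants; 1/255 is added before the log to guard log(0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["ColorStats", "compute_stats", "normalize", "rgb_to_lab", "lab_to_rgb",
           "STD_FLOOR"]

STD_FLOOR = 1e-8
_LOG_GUARD = 1.0 / 255.0

RGB2LMS = np.array([
    [0.3811, 0.5783, 0.0402],
    [0.1967, 0.7244, 0.0782],
    [0.0241, 0.1288, 0.8444],
])
LMS2RGB = np.linalg.inv(RGB2LMS)

_D = np.diag([1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)])
_A = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]])
LOGLMS2LAB = _D @ _A
LAB2LOGLMS = np.linalg.inv(LOGLMS2LAB)


@dataclass
class ColorStats:
    """Per-channel mean and (floored) standard deviation in lab space."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.std = np.maximum(np.asarray(self.std, dtype=float).ravel(), STD_FLOOR)
        if self.mean.shape != (3,) or self.std.shape != (3,):
            raise ValueError("stats must be 3-vectors")

    def to_yaml(self) -> str:
        return yaml.safe_dump({"mean": self.mean.tolist(), "std": self.std.tolist()})

    @classmethod
    def from_yaml(cls, text: str) -> "ColorStats":
        d = yaml.safe_load(text)
        return cls(np.asarray(d["mean"]), np.asarray(d["std"]))


def _check_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("expected a non-empty (H, W, 3) RGB image")
    return img


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """(H, W, 3) RGB in [0, 255] (or [0, 1] floats) -> lab opponent space."""
    img = _check_rgb(image).astype(float)
    if np.issubdtype(np.asarray(image).dtype, np.integer) or img.max() > 1.0:
        img = img / 255.0
    lms = img @ RGB2LMS.T
    log_lms = np.log10(np.maximum(lms, 0.0) + _LOG_GUARD)
    return log_lms @ LOGLMS2LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse transform; returns a clipped uint8 RGB image."""
    log_lms = np.asarray(lab, dtype=float) @ LAB2LOGLMS.T
    lms = np.power(10.0, log_lms) - _LOG_GUARD
    rgb = lms @ LMS2RGB.T
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def compute_stats(image: np.ndarray) -> ColorStats:
    """Per-channel lab mean/std of an RGB image (std floored, never fails)."""
    lab = rgb_to_lab(image).reshape(-1, 3)
    return ColorStats(lab.mean(axis=0), lab.std(axis=0))


def normalize(image: np.ndarray, reference: ColorStats,
              return_stats: bool = False):
    """Recentre/rescale each lab channel to match the reference statistics.

    Returns a uint8 RGB image; with ``return_stats`` also returns the
    pre-clipping lab statistics of the output (useful because the final
    clip to valid RGB can perturb the realized statistics).
    """
    img = _check_rgb(image)
    lab = rgb_to_lab(img)
    src = compute_stats(img)
    out_lab = (lab - src.mean) * (reference.std / src.std) + reference.mean
    out = lab_to_rgb(out_lab)
    if return_stats:
        flat = out_lab.reshape(-1, 3)
        return out, ColorStats(flat.mean(axis=0), flat.std(axis=0))
    return out
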