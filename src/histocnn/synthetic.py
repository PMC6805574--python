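"""Synthetic histology-like cohorts and small deterministic feature fixtures.

Images are textured blob fields on a pink base palette: dark nucleus-like
blobs whose density and radius differ between the two classes in proportion
to a single separability scalar.  A per-patient parameter offset makes
patient-level and image-level metrics differ, and an optional per-image
color cast (an affine shift in the stain-normalization lab space) exercises
the normalization stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from skimage import measure

from .data import ImageRecord, Manifest, save_manifest
from .stain import lab_to_rgb, rgb_to_lab

__all__ = ["CohortSpec", "generate_cohort", "make_feature_fixture",
           "count_dark_blobs", "CLASS_NAMES"]

CLASS_NAMES = ("benign", "malignant")

_BASE_RGB = np.array([225.0, 178.0, 205.0])       # pink-ish HE-like base
_NUCLEUS_RGB = np.array([96.0, 60.0, 138.0])      # dark purple blobs
_BASE_BLOBS = 16.0
_DENSITY_GAIN = 0.25         # relative blob-count gain per separability unit
_RADIUS_GAIN = 0.04
_BASE_RADIUS = 2.6
_PATIENT_SD = 1.2            # per-patient blob-count offset
_IMAGE_SD = 1.2              # per-image blob-count noise
_CAST_SCALE = np.array([0.06, 0.04, 0.04])  # lab-channel cast magnitudes


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-class cohort with patient grouping."""

    n_patients: int
    images_per_patient: int
    image_size: tuple[int, int] = (96, 96)  # (width, height)
    class_balance: float = 0.5
    separability: float = 1.0
    stain_variation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.images_per_patient < 1:
            raise ValueError("n_patients and images_per_patient must be positive")
        if min(self.image_size) < 16:
            raise ValueError("image dimensions must be at least 16 px")
        if not 0 <= self.class_balance <= 1:
            raise ValueError("class_balance must lie in [0, 1]")
        if self.separability < 0 or self.stain_variation < 0:
            raise ValueError("separability and stain_variation must be >= 0")

    def to_yaml(self) -> str:
        d = {"n_patients": self.n_patients,
             "images_per_patient": self.images_per_patient,
             "image_size": list(self.image_size),
             "class_balance": self.class_balance,
             "separability": self.separability,
             "stain_variation": self.stain_variation,
             "seed": self.seed}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        d = yaml.safe_load(text)
        d["image_size"] = tuple(d["image_size"])
        return cls(**d)


def _render_image(rng: np.random.Generator, width: int, height: int,
                  n_blobs: int, radius: float) -> np.ndarray:
    img = np.clip(
        _BASE_RGB[None, None, :] + rng.normal(0.0, 4.0, (height, width, 3)),
        0, 255,
    )
    sigma = radius / 1.6
    for _ in range(n_blobs):
        cx = rng.uniform(radius, width - radius)
        cy = rng.uniform(radius, height - radius)
        r_win = int(np.ceil(3 * radius))
        x0, x1 = max(0, int(cx) - r_win), min(width, int(cx) + r_win + 1)
        y0, y1 = max(0, int(cy) - r_win), min(height, int(cy) + r_win + 1)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        alpha = np.minimum(np.exp(-d2 / (2 * sigma**2)) * 1.4, 0.95)
        win = img[y0:y1, x0:x1]
        img[y0:y1, x0:x1] = win * (1 - alpha[..., None]) + _NUCLEUS_RGB * alpha[..., None]
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _apply_cast(image: np.ndarray, rng: np.random.Generator,
                magnitude: float) -> np.ndarray:
    lab = rgb_to_lab(image)
    lab = lab + rng.normal(0.0, magnitude, 3) * _CAST_SCALE
    return lab_to_rgb(lab)


def generate_cohort(spec: CohortSpec, out_dir) -> Manifest:
    """Write the cohort PNGs plus a manifest CSV; reproducible from the seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    width, height = spec.image_size

    n_malignant = int(np.floor(spec.n_patients * spec.class_balance + 0.5))
    labels = np.array([1] * n_malignant + [0] * (spec.n_patients - n_malignant))
    rng.shuffle(labels)

    records: list[ImageRecord] = []
    for p in range(spec.n_patients):
        is_mal = int(labels[p])
        patient_id = f"patient{p:03d}"
        density_off = rng.normal(0.0, _PATIENT_SD)
        radius_off = rng.normal(0.0, 0.2)
        for j in range(spec.images_per_patient):
            mean_count = _BASE_BLOBS * (1.0 + _DENSITY_GAIN * spec.separability * is_mal)
            n_blobs = max(1, int(np.floor(
                mean_count + density_off + rng.normal(0.0, _IMAGE_SD) + 0.5)))
            radius = max(1.8, _BASE_RADIUS * (1.0 + _RADIUS_GAIN * spec.separability
                                              * is_mal) + radius_off)
            img = _render_image(rng, width, height, n_blobs, radius)
            if spec.stain_variation > 0:
                img = _apply_cast(img, rng, spec.stain_variation)
            name = f"{patient_id}_img{j:02d}.png"
            Image.fromarray(img).save(out_dir / name)
            records.append(ImageRecord(str(out_dir / name), patient_id,
                                       CLASS_NAMES[is_mal]))
    manifest = Manifest(records, list(CLASS_NAMES))
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def count_dark_blobs(image: np.ndarray, threshold: float = 150.0,
                     min_area: int = 4) -> int:
    """Connected-component count of dark blobs (the independent oracle)."""
    gray = np.asarray(image, dtype=float).mean(axis=2)
    labelled = measure.label(gray < threshold)
    regions = measure.regionprops(labelled)
    return sum(1 for r in regions if r.area >= min_area)


def make_feature_fixture(height: int, width: int, channels: int,
                         pattern: str = "zeros", value: float = 1.0,
                         seed: int = 0) -> np.ndarray:
    """Deterministic (H, W, C) activation grid for SE/pruning unit tests.

    Patterns: ``constant`` (every cell = ``value``), ``ramp`` (1..H*W in
    row-major order, repeated per channel), ``zeros``, ``random`` (seeded
    standard normal).
    """
    if min(height, width, channels) < 1:
        raise ValueError("dimensions must be positive")
    if pattern == "zeros":
        return np.zeros((height, width, channels))
    if pattern == "constant":
        return np.full((height, width, channels), float(value))
    if pattern == "ramp":
        ramp = np.arange(1, height * width + 1, dtype=float).reshape(height, width)
        return np.repeat(ramp[:, :, None], channels, axis=2)
    if pattern == "random":
        return np.random.default_rng(seed).standard_normal((height, width, channels))
    raise ValueError(f"unknown pattern {pattern!r}")
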