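"""Cohort manifests, patient-aware splitting, bagging folds and data plans.

The manifest is a CSV with header ``path,patient_id,label,split``; unknown
extra columns survive a load/save round trip.  Train/test splitting operates
on whole patients; fold assignment inside the training pool is image-level
random sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageRecord",
    "Manifest",
    "FoldPlan",
    "DataPlan",
    "SchemaError",
    "load_manifest",
    "save_manifest",
    "patient_split",
    "bagging_partition",
    "build_data_plan",
    "iter_patch_entries",
    "read_class_magnification_tree",
]

REQUIRED_COLUMNS = ("path", "patient_id", "label", "split")
SPLIT_VALUES = ("train", "val", "test", "unassigned")


class SchemaError(ValueError):
    """A manifest violates the CSV schema or a record invariant."""


@dataclass
class ImageRecord:
    path: str
    patient_id: str
    label: str
    split: str = "unassigned"


@dataclass
class Manifest:
    """Ordered image records plus the ordered class-name set."""

    records: list[ImageRecord]
    class_names: list[str]
    extras: pd.DataFrame | None = None  # extra CSV columns, aligned by row

    def __post_init__(self):
        if len(self.class_names) < 2:
            raise SchemaError("class_names must contain at least 2 entries")
        paths = [r.path for r in self.records]
        if len(set(paths)) != len(paths):
            raise SchemaError("duplicate paths in manifest")
        for r in self.records:
            if not r.patient_id:
                raise SchemaError(f"empty patient_id for {r.path}")
            if r.label not in self.class_names:
                raise SchemaError(f"unknown label {r.label!r} for {r.path}")
            if r.split not in SPLIT_VALUES:
                raise SchemaError(f"invalid split {r.split!r} for {r.path}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "Manifest":
        extras = self.extras.iloc[list(indices)].reset_index(drop=True) \
            if self.extras is not None else None
        return Manifest([self.records[i] for i in indices],
                        list(self.class_names), extras)

    def with_split(self, split_of_patient: dict[str, str]) -> "Manifest":
        recs = [ImageRecord(r.path, r.patient_id, r.label,
                            split_of_patient.get(r.patient_id, r.split))
                for r in self.records]
        extras = self.extras.copy() if self.extras is not None else None
        return Manifest(recs, list(self.class_names), extras)

    def split_records(self, split: str) -> list[ImageRecord]:
        return [r for r in self.records if r.split == split]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"path": [r.path for r in self.records],
             "patient_id": [r.patient_id for r in self.records],
             "label": [r.label for r in self.records],
             "split": [r.split for r in self.records]}
        )
        if self.extras is not None:
            for col in self.extras.columns:
                df[col] = self.extras[col].to_numpy()
        return df


def load_manifest(csv_path, class_names: Sequence[str] | None = None) -> Manifest:
    """Read a manifest CSV; missing required columns raise SchemaError."""
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"manifest is missing required column {col!r}")
    records = [ImageRecord(p, pid, lab, sp or "unassigned")
               for p, pid, lab, sp in zip(df["path"], df["patient_id"],
                                          df["label"], df["split"])]
    if class_names is None:
        class_names = sorted({r.label for r in records})
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    extras = df[extra_cols].reset_index(drop=True) if extra_cols else None
    return Manifest(records, list(class_names), extras)


def save_manifest(manifest: Manifest, csv_path) -> None:
    manifest.to_dataframe().to_csv(csv_path, index=False)


def patient_split(manifest: Manifest, train_fraction: float, seed: int = 0
                  ) -> Manifest:
    """Tag records train/test by whole patients (rounding toward train)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    patients = manifest.patient_ids
    if len(patients) < 2:
        raise ValueError("patient-level split needs at least 2 patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(np.ceil(train_fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    assignment = {}
    for rank, idx in enumerate(order):
        assignment[patients[idx]] = "train" if rank < n_train else "test"
    return manifest.with_split(assignment)


@dataclass
class FoldPlan:
    """Assignment of training-pool record indices to n_folds disjoint folds."""

    n_folds: int
    assignments: np.ndarray  # record index -> fold index
    seed: int

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=int)
        sizes = self.fold_sizes()
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_folds)

    def val_indices(self, model_index: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == model_index)

    def train_indices(self, model_index: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != model_index)

    def pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train, validation) index pairs, one per model."""
        return [(self.train_indices(i), self.val_indices(i))
                for i in range(self.n_folds)]

    def to_json(self) -> str:
        return json.dumps({"n_folds": self.n_folds, "seed": self.seed,
                           "assignments": self.assignments.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(d["n_folds"], np.asarray(d["assignments"]), d["seed"])


def bagging_partition(training_pool: Manifest | int, n_folds: int = 5,
                      seed: int = 0) -> FoldPlan:
    """Split the training pool into n_folds near-equal disjoint random folds.

    Each model i trains on the union of the other folds and validates on
    fold i.  When the pool is not divisible, earlier folds take the extra
    records.  Accepts a manifest or a bare pool size.
    """
    n = training_pool if isinstance(training_pool, int) else len(training_pool)
    if n < n_folds:
        raise ValueError(f"pool of {n} records cannot form {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    base, extra = divmod(n, n_folds)
    start = 0
    for f in range(n_folds):
        size = base + (1 if f < extra else 0)
        assignments[order[start : start + size]] = f
        start += size
    return FoldPlan(n_folds, assignments, seed)


@dataclass
class DataPlan:
    """Augmentation/tiling counting: images = base x augment, patches = x per-image."""

    base_count: int
    augment_factor: int = 8
    patches_per_image: int = 15

    def __post_init__(self):
        if min(self.base_count, self.augment_factor, self.patches_per_image) < 1:
            raise ValueError("data-plan counts must be positive integers")

    @property
    def image_count(self) -> int:
        return self.base_count * self.augment_factor

    @property
    def patch_count(self) -> int:
        return self.image_count * self.patches_per_image


def build_data_plan(base_count: int, augment_factor: int = 8,
                    patches_per_image: int = 15) -> DataPlan:
    return DataPlan(base_count, augment_factor, patches_per_image)


def iter_patch_entries(records: Iterable[ImageRecord], plan: DataPlan
                       ) -> Iterator[tuple[str, int, int]]:
    """Lazily enumerate (path, augmentation index, patch index) entries.

    Sizes training manifests without materializing any pixels.
    """
    for rec in records:
        for a in range(plan.augment_factor):
            for p in range(plan.patches_per_image):
                yield rec.path, a, p


def read_class_magnification_tree(root, class_names: Sequence[str] | None = None
                                  ) -> Manifest:
    """Convenience adapter for a <class>/<magnification>/<image> layout.

    The file stem is used as the patient identifier; magnification is kept
    as an extra column.  Filename grammar beyond that is not parsed.
    """
    root = Path(root)
    rows = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for mag_dir in sorted(p for p in class_dir.iterdir() if p.is_dir()):
            for img in sorted(mag_dir.glob("*")):
                if img.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"}:
                    rows.append((str(img), img.stem, class_dir.name, mag_dir.name))
    if not rows:
        raise SchemaError(f"no images found under {root}")
    records = [ImageRecord(p, pid, lab) for p, pid, lab, _ in rows]
    names = list(class_names) if class_names else sorted({r[2] for r in rows})
    extras = pd.DataFrame({"magnification": [r[3] for r in rows]})
    return Manifest(records, names, extras)
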