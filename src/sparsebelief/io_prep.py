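"""Volume loading, masking/flattening, and multimodal dataset assembly.

Inputs are assumed already spatially preprocessed (segmented, template-
normalized, smoothed); this module only reads volumes, flattens masked
voxels into feature vectors in fixed C-order, and rescales features into
[0, 1] — the range required downstream, where RBM visible units are
interpreted as Bernoulli activation probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from ._utils import ValidationError

__all__ = [
    "LabeledDataset",
    "MinMaxNormalizer",
    "load_volume",
    "mask_and_flatten",
    "nonzero_union_mask",
    "build_dataset",
    "save_dataset",
    "load_dataset",
]

RESERVED_COLUMNS = ("subject_id", "label")


@dataclass
class LabeledDataset:
    """Aligned per-modality feature matrices with class labels.

    Every modality matrix has one row per subject, in the same order as
    ``subject_ids`` and ``labels``.  Labels are integer codes indexing
    ``class_names``.
    """

    modalities: Dict[str, np.ndarray]
    labels: np.ndarray
    class_names: List[str]
    subject_ids: List[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.subject_ids)
        if self.labels.shape != (n,):
            raise ValidationError("labels must align with subject_ids")
        for name, M in self.modalities.items():
            if M.shape[0] != n:
                raise ValidationError(
                    f"modality '{name}' has {M.shape[0]} rows, expected {n}"
                )
        present = np.unique(self.labels)
        if present.size and (present.min() < 0 or present.max() >= len(self.class_names)):
            raise ValidationError("labels must index class_names")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def modality_names(self) -> List[str]:
        return list(self.modalities.keys())

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        """Row-subset (or reorder) every aligned field at once."""
        rows = np.asarray(rows)
        return LabeledDataset(
            modalities={k: M[rows] for k, M in self.modalities.items()},
            labels=self.labels[rows],
            class_names=list(self.class_names),
            subject_ids=[self.subject_ids[i] for i in rows],
            meta=dict(self.meta),
        )


class MinMaxNormalizer:
    """Per-column min-max rescaling to [0, 1], fit on training rows only.

    Constant columns map to 0 (avoids divide-by-zero); transform clips
    out-of-range values — e.g. test subjects outside the training range —
    back into [0, 1].  Applying the transform twice equals applying once.
    """

    def __init__(self):
        self.lo = None
        self.span = None

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=np.float64)
        self.lo = X.min(axis=0)
        span = X.max(axis=0) - self.lo
        self.span = np.where(span > 0, span, np.inf)  # constant columns -> 0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise ValidationError("normalizer is not fitted")
        X = np.asarray(X, dtype=np.float64)
        return np.clip((X - self.lo) / self.span, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def load_volume(path):
    """Read a NIfTI volume; returns (voxel array, affine). No resampling."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return data, img.affine


def mask_and_flatten(volume: np.ndarray, mask="nonzero") -> np.ndarray:
    """Flatten the masked voxels of a 3-D volume in C-order.

    ``mask`` is a boolean array of the same shape, or the string "nonzero"
    to select the volume's own nonzero voxels.  For a train-consistent mask
    across subjects use :func:`nonzero_union_mask` on the training volumes.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if isinstance(mask, str):
        if mask != "nonzero":
            raise ValidationError(f"unknown mask mode: {mask!r}")
        mask = volume != 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != volume.shape:
            raise ValidationError(
                f"mask shape {mask.shape} != volume shape {volume.shape}"
            )
    if not mask.any():
        warnings.warn("mask selects no voxels; returning empty feature vector")
    return volume.ravel(order="C")[mask.ravel(order="C")]


def nonzero_union_mask(volumes: Sequence[np.ndarray]) -> np.ndarray:
    """Boolean union of nonzero voxels across a set of (training) volumes."""
    volumes = list(volumes)
    if not volumes:
        raise ValidationError("need at least one volume")
    mask = np.zeros(np.shape(volumes[0]), dtype=bool)
    for v in volumes:
        if np.shape(v) != mask.shape:
            raise ValidationError("all volumes must share one shape")
        mask |= np.asarray(v) != 0
    return mask


def build_dataset(manifest, normalization: str = "minmax") -> LabeledDataset:
    """Assemble a LabeledDataset from a CSV manifest of volume paths.

    The manifest needs columns ``subject_id``, ``label``, plus one path
    column per modality.  Voxels are masked to the nonzero union across the
    manifest's subjects (per modality) and flattened in C-order.  With
    ``normalization="minmax"`` each feature column is rescaled to [0, 1]
    over the manifest's rows; inside cross-validation the evaluation
    harness instead fits normalization on training folds only.
    """
    if normalization not in ("minmax", "none"):
        raise ValidationError(f"unknown normalization: {normalization!r}")
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    for col in RESERVED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"manifest missing required column '{col}'")
    modality_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not modality_cols:
        raise ValidationError("manifest has no modality path columns")
    ids = df["subject_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate subject_id values: {dupes}")

    class_names = sorted(df["label"].astype(str).unique())
    code = {c: i for i, c in enumerate(class_names)}
    labels = np.array([code[str(l)] for l in df["label"]], dtype=np.int64)

    missing = [
        (i, str(p))
        for col in modality_cols
        for i, p in enumerate(df[col])
        if not (manifest.parent / str(p)).exists() and not Path(str(p)).exists()
    ]
    if missing:
        raise IOError(f"manifest references missing files (row, path): {missing}")

    modalities = {}
    for col in modality_cols:
        vols = []
        for p in df[col]:
            p = Path(str(p))
            if not p.exists():
                p = manifest.parent / p
            vols.append(load_volume(p)[0])
        mask = nonzero_union_mask(vols)
        X = np.stack([mask_and_flatten(v, mask) for v in vols])
        if normalization == "minmax":
            X = MinMaxNormalizer().fit_transform(X)
        modalities[col] = X

    return LabeledDataset(
        modalities=modalities,
        labels=labels,
        class_names=class_names,
        subject_ids=ids,
        meta={"normalization": normalization, "flatten_order": "C"},
    )


def save_dataset(dataset: LabeledDataset, out_dir) -> Path:
    """Serialize to a directory: one .npy per modality + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, M in dataset.modalities.items():
        np.save(out_dir / f"{name}.npy", M)
    sidecar = {
        "modalities": dataset.modality_names,
        "labels": dataset.labels.tolist(),
        "class_names": dataset.class_names,
        "subject_ids": dataset.subject_ids,
        "meta": dataset.meta,
    }
    (out_dir / "dataset.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def load_dataset(in_dir) -> LabeledDataset:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "dataset.json").read_text())
    modalities = {
        name: np.load(in_dir / f"{name}.npy") for name in sidecar["modalities"]
    }
    return LabeledDataset(
        modalities=modalities,
        labels=np.asarray(sidecar["labels"], dtype=np.int64),
        class_names=sidecar["class_names"],
        subject_ids=sidecar["subject_ids"],
        meta=sidecar.get("meta", {}),
    )
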