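"""Synthetic multimodal datasets and toy volumes with known structure.

Real studies of this kind use access-controlled multimodal neuroimages
(amyloid-PET uptake maps plus gray- and white-matter segmentations), so a
fully testable stand-in is needed.  The generator draws class-conditional
feature vectors from a Gaussian-latent low-rank-plus-noise model:

    x = μ_class + B z + ε,   z ~ N(0, I_r),  ε ~ N(0, σ² I)

then squashes them through a logistic map into [0, 1], matching the
downstream treatment of features as Bernoulli activation probabilities
(real inputs are nonnegative normalized intensities).  Class means are
separated by ``separation`` within-class standard deviations along a
random unit direction.  Modalities share labels but draw independent
mixing matrices, emulating PET/GM/WM carrying partially redundant signal.

Toy NIfTI volumes with a spherical "atrophy" region exercise the I/O path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ._utils import ValidationError, sigmoid, substream
from .io_prep import LabeledDataset

__all__ = [
    "SyntheticSpec",
    "generate_multimodal_dataset",
    "generate_toy_volumes",
    "generate_lowrank_matrix",
]

# marginal sd of each feature's latent (low-rank) component on the
# pre-squash scale; with the default noise this keeps pre-squash values in
# the near-linear band of the logistic so separation survives squashing
LATENT_SD = 0.2


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of one synthetic multimodal dataset.

    separation is the distance between class mean vectors in units of the
    (per-feature) within-class standard deviation; latent_rank controls the
    rank of the class-conditional covariance; noise_sd the isotropic noise.
    """

    n_per_class: int = 60
    n_modalities: int = 3
    dims: int = 50
    separation: float = 4.0
    latent_rank: int = 5
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 2:
            raise ValidationError("n_per_class must be >= 2")
        if self.n_modalities < 1:
            raise ValidationError("n_modalities must be >= 1")
        if self.latent_rank < 1 or self.dims < self.latent_rank:
            raise ValidationError("need dims >= latent_rank >= 1")
        if self.separation < 0 or self.noise_sd < 0:
            raise ValidationError("separation and noise_sd must be nonnegative")


def generate_multimodal_dataset(spec: SyntheticSpec, n_classes: int = 2) -> LabeledDataset:
    """Draw a balanced labeled dataset of ``n_classes`` × n_per_class subjects.

    Per modality, classes are placed symmetrically along one random unit
    direction at spacing separation·sd_within, where sd_within is the
    per-feature within-class standard deviation sqrt(LATENT_SD² + noise_sd²).
    Latent draws are split deterministically per modality and class from the
    master seed, so a run with separation=0 uses the *same* latent draws for
    every class and the class-conditional distributions coincide exactly.
    """
    if n_classes < 2:
        raise ValidationError("n_classes must be >= 2")
    sd_within = float(np.hypot(LATENT_SD, spec.noise_sd))
    modalities = {}
    labels = np.repeat(np.arange(n_classes), spec.n_per_class)
    for m in range(spec.n_modalities):
        rng_struct = substream(spec.seed, "modality", m)
        B = rng_struct.normal(0.0, LATENT_SD / np.sqrt(spec.latent_rank),
                              size=(spec.dims, spec.latent_rank))
        u = rng_struct.normal(size=spec.dims)
        u /= np.linalg.norm(u)
        blocks = []
        for c in range(n_classes):
            rng_c = substream(spec.seed, "modality", m, "class", c)
            offset = (c - (n_classes - 1) / 2.0) * spec.separation * sd_within
            Z = rng_c.normal(size=(spec.n_per_class, spec.latent_rank))
            E = rng_c.normal(0.0, spec.noise_sd, size=(spec.n_per_class, spec.dims))
            blocks.append(offset * u + Z @ B.T + E)
        modalities[f"mod{m}"] = sigmoid(np.vstack(blocks))
    return LabeledDataset(
        modalities=modalities,
        labels=labels,
        class_names=[f"class{c}" for c in range(n_classes)],
        subject_ids=[f"S{i:04d}" for i in range(n_classes * spec.n_per_class)],
        meta={"synthetic": True, "spec": spec.__dict__ | {}},
    )


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def generate_toy_volumes(n_per_class: int, shape=(12, 12, 12), seed: int = 0,
                         out_dir=".", n_classes: int = 2,
                         modalities=("pet", "gm", "wm"),
                         attenuation: float = 0.5, noise_sd: float = 0.02):
    """Write toy NIfTI volumes plus a CSV manifest; returns the manifest path.

    Every subject gets one smooth positive base pattern per modality; in
    classes other than class 0 the intensity inside a fixed central sphere
    is multiplied by ``attenuation`` (synthetic "atrophy").  attenuation=1
    is the null case with identical voxelwise class means.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        if not out_dir.is_dir():
            raise OSError("not a directory")
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    shape = tuple(int(s) for s in shape)
    center = tuple(s // 2 for s in shape)
    radius = max(1, min(shape) // 4)
    sphere = _sphere_mask(shape, center, radius)
    affine = np.eye(4)

    rows = []
    base_rng = substream(seed, "toyvol_base")
    base = {m: 0.5 + 0.3 * sigmoid(base_rng.normal(size=shape)) for m in modalities}
    for c in range(n_classes):
        for i in range(n_per_class):
            sid = f"sub{c}{i:03d}"
            row = {"subject_id": sid, "label": f"class{c}"}
            for m in modalities:
                rng = substream(seed, "toyvol", c, i, m)
                vol = base[m] + rng.normal(0.0, noise_sd, size=shape)
                if c > 0:
                    vol = np.where(sphere, vol * attenuation, vol)
                fname = f"{sid}_{m}.nii.gz"
                nib.save(nib.Nifti1Image(vol.astype(np.float64), affine),
                         str(out_dir / fname))
                row[m] = fname
            rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def generate_lowrank_matrix(n: int, p: int, rank: int, seed: int = 0) -> np.ndarray:
    """Centered matrix of exact numerical rank ``rank`` (a PCA fixture)."""
    if not (1 <= rank <= min(n, p)):
        raise ValidationError(f"rank={rank} out of range [1, {min(n, p)}]")
    rng = substream(seed, "lowrank")
    A = rng.normal(size=(n, rank))
    A = A - A.mean(axis=0)  # centered factors => centered product, rank preserved
    return A @ rng.normal(size=(rank, p))
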