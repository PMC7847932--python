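"""End-to-end orchestration: normalization → PCA → SR-DBNs → ELM.

The fitted pipeline mirrors the four-stage design: per-modality min-max
normalization and snapshot PCA reduce the voxel features; one SR-DBN per
modality learns a deep sparse code; the codes are concatenated across
modalities and classified by a single ELM.  Variants: ``no_sparsity``
zeroes the sparsity weight λ (plain DBN) and ``pca_elm`` skips the DBN
stage entirely, feeding PCA scores to the ELM.

Bundles serialize to a single self-describing file — a JSON header
followed by raw C-order array bytes — chosen over archive formats because
it is byte-deterministic: saving the same bundle twice yields identical
files, which makes reproducibility auditable by checksum.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from ._utils import ValidationError, sigmoid, substream
from . import elm as elm_mod
from . import fast_pca
from . import srdbn
from .io_prep import LabeledDataset, MinMaxNormalizer
from .srrbm import RBMParams, SRTrainConfig

__all__ = [
    "PipelineConfig",
    "PipelineBundle",
    "fit_pipeline",
    "predict_pipeline",
    "save_bundle",
    "load_bundle",
]

FORMAT_MAGIC = b"SBNBUNDLE"
FORMAT_VERSION = 1


class BundleFormatError(IOError):
    """Raised on corrupt or version-incompatible bundle files."""


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob that affects pipeline results.

    pca_threshold/pca_max_k: cumulative explained-variance target and the
    component cap (defaults 0.90 and 20, the selection rule of the original
    study).  dbn_hidden: hidden layer width; 0 means "match the PCA output
    dimension".  finetune: "supervised" or "off".  elm_L: hidden node
    count; 0 means 10x the ELM input width, capped at 1000.
    """

    variant: str = "full"
    pca_threshold: float = 0.90
    pca_max_k: int = 20
    dbn_hidden: int = 0
    dbn_layers: int = 3
    train: SRTrainConfig = field(default_factory=SRTrainConfig)
    finetune: str = "supervised"
    finetune_lr: float = 2.0
    finetune_epochs: int = 2000
    elm_L: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("full", "no_sparsity", "pca_elm"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.finetune not in ("supervised", "off"):
            raise ValidationError(f"finetune must be 'supervised' or 'off', got {self.finetune!r}")

    def with_variant(self, variant: str) -> "PipelineConfig":
        if variant == "no_sparsity":
            return replace(self, variant=variant, train=replace(self.train, lam=0.0))
        return replace(self, variant=variant)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = SRTrainConfig(**d["train"])
        return cls(**d)


@dataclass
class PipelineBundle:
    config: PipelineConfig
    modality_names: list
    class_names: list
    normalizers: dict          # modality -> MinMaxNormalizer
    pca_models: dict           # modality -> PCAModel
    dbn_models: dict           # modality -> DBNModel (absent for pca_elm)
    elm_model: "elm_mod.ELMModel"
    train_accuracy: float = float("nan")


def _resolve_elm_L(config: PipelineConfig, feat_dim: int) -> int:
    return config.elm_L if config.elm_L > 0 else min(10 * feat_dim, 1000)


def _modality_features(bundle: PipelineBundle, dataset_mods: dict) -> np.ndarray:
    feats = []
    for name in bundle.modality_names:
        if name not in dataset_mods:
            raise ValidationError(f"dataset lacks modality {name!r} expected by the bundle")
        Z = bundle.normalizers[name].transform(dataset_mods[name])
        S = _unit_scale(fast_pca.transform(bundle.pca_models[name], Z), bundle.pca_models[name])
        if bundle.config.variant != "pca_elm":
            S = srdbn.extract_features(bundle.dbn_models[name], S)
        feats.append(S)
    return np.hstack(feats)


def _unit_scale(S: np.ndarray, pca_model) -> np.ndarray:
    """Whiten PCA scores by their training variance, then squash to [0,1].

    DBN visible units (and the study's inputs) live in [0,1]; PCA scores do
    not, so each score is divided by its component's training standard
    deviation (a fitted PCA parameter — no test-fold statistics involved)
    and mapped through a logistic.  Scores then span the informative middle
    band of the sigmoid instead of piling up near 0.5.
    """
    sd = np.sqrt(np.maximum(pca_model.explained_variance, 1e-30))
    return sigmoid(S / sd)


def fit_pipeline(train: LabeledDataset, config: PipelineConfig,
                 seed_offset: int = 0) -> PipelineBundle:
    """Fit every stage on the training rows only.

    Stage order per modality: min-max normalization → snapshot PCA with
    variance-threshold component selection → SR-DBN pretraining (+ optional
    supervised fine-tuning); then the per-modality codes are concatenated
    and a single ELM is fitted on them.  ``seed_offset`` lets a CV harness
    decorrelate repeats while staying reproducible.
    """
    if train.n_subjects == 0:
        raise ValidationError("training dataset is empty")
    seed = (config.seed + seed_offset) & 0x7FFFFFFF

    normalizers, pca_models, dbn_models, feats = {}, {}, {}, []
    for m_idx, name in enumerate(train.modality_names):
        try:
            X = train.modalities[name]
            norm = MinMaxNormalizer().fit(X)
            Z = norm.transform(X)
            k_max = min(config.pca_max_k, Z.shape[0] - 1, Z.shape[1])
            pca = fast_pca.fit_fast_pca(Z, k_max)
            k = fast_pca.select_k_for_variance(pca.explained_variance_ratio,
                                               config.pca_threshold)
            pca = fast_pca.PCAModel(
                mean=pca.mean,
                components=pca.components[:k],
                explained_variance=pca.explained_variance[:k],
                explained_variance_ratio=pca.explained_variance_ratio[:k],
            )
            S = _unit_scale(fast_pca.transform(pca, Z), pca)
            normalizers[name], pca_models[name] = norm, pca

            if config.variant != "pca_elm":
                hidden = config.dbn_hidden if config.dbn_hidden > 0 else S.shape[1]
                dbn_seed = int(substream(seed, "dbn", m_idx).integers(2 ** 31))
                model = srdbn.build_dbn(S.shape[1], hidden, config.dbn_layers, seed=dbn_seed,
                                        weight_init_sd=config.train.weight_init_sd)
                model = srdbn.pretrain(model, S, replace(config.train, seed=dbn_seed))
                if config.finetune == "supervised":
                    model = srdbn.finetune(model, S, train.labels, lr=config.finetune_lr,
                                           epochs=config.finetune_epochs, seed=dbn_seed)
                dbn_models[name] = model
                S = srdbn.extract_features(model, S)
            feats.append(S)
        except Exception as exc:
            raise RuntimeError(f"stage failure in modality {name!r}: {exc}") from exc

    F = np.hstack(feats)
    elm_seed = int(substream(seed, "elm").integers(2 ** 31))
    model = elm_mod.init_elm(F.shape[1], _resolve_elm_L(config, F.shape[1]), elm_seed)
    model = elm_mod.fit_elm(model, F, train.labels, class_names=train.class_names)

    bundle = PipelineBundle(
        config=config,
        modality_names=train.modality_names,
        class_names=list(train.class_names),
        normalizers=normalizers,
        pca_models=pca_models,
        dbn_models=dbn_models,
        elm_model=model,
    )
    pred, _ = elm_mod.predict(model, F)
    bundle.train_accuracy = float(np.mean(pred == train.labels))
    return bundle


def predict_pipeline(bundle: PipelineBundle, data, positive_class: int | None = None):
    """Apply the frozen pipeline; never refits any stage.

    ``data`` is a LabeledDataset or a dict of modality matrices.  Returns
    (predicted class codes, score matrix[, positive-class score]).
    """
    mods = data.modalities if isinstance(data, LabeledDataset) else dict(data)
    F = _modality_features(bundle, mods)
    return elm_mod.predict(bundle.elm_model, F, positive_class=positive_class)


# ---------------------------------------------------------------------------
# deterministic single-file persistence


def _flatten_bundle(bundle: PipelineBundle):
    """Split a bundle into (json-safe meta, {key: ndarray})."""
    arrays = {}
    meta = {
        "config": bundle.config.to_dict(),
        "modality_names": bundle.modality_names,
        "class_names": bundle.class_names,
        "train_accuracy": bundle.train_accuracy,
        "dbn": {},
        "elm": {"L": bundle.elm_model.L, "seed": bundle.elm_model.seed,
                "class_names": bundle.elm_model.class_names},
    }
    for name in bundle.modality_names:
        norm = bundle.normalizers[name]
        arrays[f"norm/{name}/lo"] = norm.lo
        arrays[f"norm/{name}/span"] = norm.span
        pca = bundle.pca_models[name]
        arrays[f"pca/{name}/mean"] = pca.mean
        arrays[f"pca/{name}/components"] = pca.components
        arrays[f"pca/{name}/ev"] = pca.explained_variance
        arrays[f"pca/{name}/evr"] = pca.explained_variance_ratio
        if name in bundle.dbn_models:
            dbn = bundle.dbn_models[name]
            meta["dbn"][name] = {
                "layer_sizes": dbn.layer_sizes,
                "finetuned": dbn.finetuned,
                "pretrained": dbn.pretrained,
                "has_head": dbn.head_W is not None,
            }
            for t, layer in enumerate(dbn.layers):
                arrays[f"dbn/{name}/{t}/W"] = layer.W
                arrays[f"dbn/{name}/{t}/c"] = layer.c_vis
                arrays[f"dbn/{name}/{t}/b"] = layer.b_hid
            if dbn.head_W is not None:
                arrays[f"dbn/{name}/head_W"] = dbn.head_W
                arrays[f"dbn/{name}/head_b"] = dbn.head_b
    arrays["elm/A"] = bundle.elm_model.A
    arrays["elm/d"] = bundle.elm_model.d_bias
    if bundle.elm_model.beta is not None:
        arrays["elm/beta"] = bundle.elm_model.beta
    return meta, arrays


def save_bundle(bundle: PipelineBundle, path) -> Path:
    """Write a bundle; identical bundles produce byte-identical files."""
    meta, arrays = _flatten_bundle(bundle)
    index = []
    blobs = []
    offset = 0
    for key in sorted(arrays):
        a = np.ascontiguousarray(np.asarray(arrays[key], dtype=np.float64))
        raw = a.tobytes(order="C")
        index.append({"key": key, "shape": list(a.shape), "offset": offset,
                      "nbytes": len(raw)})
        blobs.append(raw)
        offset += len(raw)
    header = json.dumps({"version": FORMAT_VERSION, "meta": meta, "index": index},
                        sort_keys=True).encode("utf-8")
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(FORMAT_MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        for raw in blobs:
            fh.write(raw)
    return path


def load_bundle(path) -> PipelineBundle:
    path = Path(path)
    raw = path.read_bytes()
    if raw[: len(FORMAT_MAGIC)] != FORMAT_MAGIC:
        raise BundleFormatError(f"{path} is not a pipeline bundle (bad magic)")
    try:
        (hlen,) = struct.unpack_from("<Q", raw, len(FORMAT_MAGIC))
        header = json.loads(raw[len(FORMAT_MAGIC) + 8: len(FORMAT_MAGIC) + 8 + hlen])
    except Exception as exc:
        raise BundleFormatError(f"corrupt bundle header in {path}: {exc}") from exc
    if header["version"] != FORMAT_VERSION:
        raise BundleFormatError(
            f"bundle version {header['version']} incompatible with reader version {FORMAT_VERSION}"
        )
    body = raw[len(FORMAT_MAGIC) + 8 + hlen:]
    arrays = {}
    for ent in header["index"]:
        chunk = body[ent["offset"]: ent["offset"] + ent["nbytes"]]
        if len(chunk) != ent["nbytes"]:
            raise BundleFormatError(f"truncated bundle {path}: missing bytes for {ent['key']}")
        arrays[ent["key"]] = np.frombuffer(chunk, dtype=np.float64).reshape(ent["shape"]).copy()

    meta = header["meta"]
    config = PipelineConfig.from_dict(meta["config"])
    normalizers, pca_models, dbn_models = {}, {}, {}
    for name in meta["modality_names"]:
        norm = MinMaxNormalizer()
        norm.lo = arrays[f"norm/{name}/lo"]
        norm.span = arrays[f"norm/{name}/span"]
        normalizers[name] = norm
        pca_models[name] = fast_pca.PCAModel(
            mean=arrays[f"pca/{name}/mean"],
            components=arrays[f"pca/{name}/components"],
            explained_variance=arrays[f"pca/{name}/ev"],
            explained_variance_ratio=arrays[f"pca/{name}/evr"],
        )
        if name in meta["dbn"]:
            info = meta["dbn"][name]
            layers = [
                RBMParams(arrays[f"dbn/{name}/{t}/W"], arrays[f"dbn/{name}/{t}/c"],
                          arrays[f"dbn/{name}/{t}/b"])
                for t in range(len(info["layer_sizes"]) - 1)
            ]
            dbn = srdbn.DBNModel(layers=layers, layer_sizes=info["layer_sizes"],
                                 pretrained=info["pretrained"], finetuned=info["finetuned"])
            if info["has_head"]:
                dbn.head_W = arrays[f"dbn/{name}/head_W"]
                dbn.head_b = arrays[f"dbn/{name}/head_b"]
            dbn_models[name] = dbn

    model = elm_mod.ELMModel(
        A=arrays["elm/A"], d_bias=arrays["elm/d"], L=int(meta["elm"]["L"]),
        seed=int(meta["elm"]["seed"]),
        beta=arrays.get("elm/beta"),
        class_names=meta["elm"]["class_names"],
    )
    return PipelineBundle(
        config=config,
        modality_names=meta["modality_names"],
        class_names=meta["class_names"],
        normalizers=normalizers,
        pca_models=pca_models,
        dbn_models=dbn_models,
        elm_model=model,
        train_accuracy=meta["train_accuracy"],
    )
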