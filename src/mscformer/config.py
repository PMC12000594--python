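"""Experiment configuration, manifests, checkpoints, and feature export.

A run is described by one YAML file with three sections (``data``, ``model``,
``train``); unknown keys are rejected with field paths.  Every run directory
is self-describing: the manifest records the full configuration snapshot,
seeds, a fingerprint of the input container, and the artifact paths, so a
stored manifest plus the input container reproduces the report exactly.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import __version__
from .autograd import Tensor
from .containers import TrialSet, load_trialset
from .model import MSCFormer, NetworkConfig, build_model
from .preprocess import AugmentConfig, apply_standardizer, fit_standardizer
from .train import EvalReport, TrainConfig, run_subject

__all__ = [
    "DataSection",
    "ModelSection",
    "TrainSection",
    "ExperimentConfig",
    "RunManifest",
    "load_experiment_config",
    "run_experiment",
    "save_checkpoint",
    "load_checkpoint",
    "export_features",
    "dataset_fingerprint",
]

_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


class DataSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    train_container: str
    test_container: str
    augment: bool = True
    n_segments: int = 8
    n_augmented: int | None = None
    augment_seed: int = 0


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    channels: int = 22
    samples: int = 1000
    n_classes: int = 4
    f1: int = 16
    kernels: list[int] = [85, 65, 45]
    pool: int = 44
    conv_dropout: float = 0.5
    depth: int = 5
    heads: int = 8
    ff_dim: int = 192
    encoder_dropout: float = 0.25
    classifier_dropout: float = 0.25
    pool_ceil_mode: bool = True
    variant: str = "mscformer"

    @model_validator(mode="after")
    def _check(self):
        if (3 * self.f1) % self.heads != 0:
            raise ValueError(
                f"embed_dim {3 * self.f1} (= 3*f1) is not divisible by "
                f"heads {self.heads}"
            )
        if self.variant not in ("mscformer", "msnet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        return self

    def network_config(self) -> NetworkConfig:
        d = self.model_dump()
        d.pop("variant")
        d["kernels"] = tuple(d["kernels"])
        return NetworkConfig(**d)


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lr: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 288
    epochs: int = 1000
    weight_decay: float = 0.0
    seed: int = 0
    folds: int = 5
    standardizer_scope: str = "global"

    def train_config(self) -> TrainConfig:
        return TrainConfig(**self.model_dump())


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    data: DataSection
    model: ModelSection
    train: TrainSection = TrainSection()


def load_experiment_config(path) -> ExperimentConfig:
    """Parse and validate a YAML config; schema errors name their field path."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    try:
        return ExperimentConfig.model_validate(payload)
    except ValidationError as err:
        locs = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in err.errors()
        )
        raise ValueError(f"invalid experiment config {path!r}: {locs}") from err


def dataset_fingerprint(path) -> str:
    """SHA-256 of the input container bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")

    software_version: str
    config: dict
    seed: int
    train_fingerprint: str
    test_fingerprint: str
    report_path: str
    checkpoint_paths: list[str]
    loss_log_path: str

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def save_checkpoint(model: MSCFormer, path) -> None:
    """Single-file weight bundle + JSON config snapshot (deterministic bytes)."""
    cfg = {"variant": model.variant, "network": model.cfg.to_dict()}
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name, arr in sorted(model.get_weights().items()):
            buf = io.BytesIO()
            np.save(buf, arr, allow_pickle=False)
            info = zipfile.ZipInfo(name.replace("/", "__") + ".npy", date_time=_ZIP_DATE)
            zf.writestr(info, buf.getvalue())
        info = zipfile.ZipInfo("config.json", date_time=_ZIP_DATE)
        zf.writestr(info, json.dumps(cfg, sort_keys=True, indent=1))


def load_checkpoint(path) -> MSCFormer:
    with zipfile.ZipFile(path, "r") as zf:
        cfg = json.loads(zf.read("config.json"))
        weights = {}
        for name in zf.namelist():
            if not name.endswith(".npy"):
                continue
            key = name[: -len(".npy")].replace("__", "/")
            weights[key] = np.load(io.BytesIO(zf.read(name)), allow_pickle=False)
    model = build_model(NetworkConfig.from_dict(cfg["network"]), variant=cfg["variant"])
    model.set_weights(weights)
    return model


def run_experiment(config_path, out_dir) -> tuple[RunManifest, EvalReport]:
    """Execute import -> standardize -> augment -> train -> evaluate.

    Writes the evaluation report, per-epoch loss logs (CSV), the
    best-checkpoint bundle per fold, and the manifest, under ``out_dir``.
    """
    cfg = load_experiment_config(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    for name in ("train_container", "test_container"):
        if not Path(getattr(cfg.data, name)).exists():
            raise FileNotFoundError(
                f"{name} {getattr(cfg.data, name)!r} does not exist"
            )

    train_ts = load_trialset(cfg.data.train_container)
    test_ts = load_trialset(cfg.data.test_container)

    net_cfg = cfg.model.network_config()
    train_cfg = cfg.train.train_config()
    aug_cfg = (
        AugmentConfig(
            n_segments=cfg.data.n_segments,
            n_augmented=cfg.data.n_augmented,
            seed=cfg.data.augment_seed,
        )
        if cfg.data.augment
        else None
    )

    report = run_subject(train_ts, test_ts, net_cfg, train_cfg, aug_cfg,
                         variant=cfg.model.variant)

    report_path = out_dir / "report.json"
    report.save(report_path)

    loss_log_path = out_dir / "loss_log.csv"
    with open(loss_log_path, "w") as fh:
        fh.write("fold,epoch,train_loss,val_loss\n")
        for fr in report.fold_results:
            for e, (tl, vl) in enumerate(zip(fr.train_loss_trace, fr.val_loss_trace)):
                fh.write(f"{fr.fold_index},{e},{tl:.8f},{vl:.8f}\n")

    checkpoint_paths: list[str] = []
    for fr in report.fold_results:
        if fr.best_weights is None:
            continue
        model = build_model(net_cfg, variant=cfg.model.variant)
        model.set_weights(fr.best_weights)
        ckpt = out_dir / f"fold{fr.fold_index}.ckpt"
        save_checkpoint(model, ckpt)
        checkpoint_paths.append(str(ckpt))

    manifest = RunManifest(
        software_version=__version__,
        config=json.loads(cfg.model_dump_json()),
        seed=train_cfg.seed,
        train_fingerprint=dataset_fingerprint(cfg.data.train_container),
        test_fingerprint=dataset_fingerprint(cfg.data.test_container),
        report_path=str(report_path),
        checkpoint_paths=checkpoint_paths,
        loss_log_path=str(loss_log_path),
    )
    manifest.save(out_dir / "manifest.json")
    return manifest, report


_STAGES = ("raw", "conv", "final")


def export_features(
    model: MSCFormer, ts: TrialSet, stage: str = "final"
) -> np.ndarray:
    """Per-trial feature vectors at a pipeline stage.

    ``raw``: flattened input (C*T); ``conv``: fused token map flattened
    (Tp*F2); ``encoder_k`` (k = 1..depth): sequence after encoder layer k,
    flattened; ``final``: the class-token embedding after the full encoder
    (length F2).  Intended for external embedding/plotting (e.g. t-SNE).
    """
    x = np.asarray(ts.signals, dtype=np.float64)
    if stage == "raw":
        return x.reshape(x.shape[0], -1)
    if x.shape[1] != model.cfg.channels:
        raise ValueError(
            f"checkpoint expects {model.cfg.channels} channels, data has {x.shape[1]}"
        )
    rng = np.random.default_rng(0)
    tokens = model.conv_tokens(Tensor(x), train=False, rng=rng)
    if stage == "conv":
        return tokens.data.reshape(x.shape[0], -1)
    if stage.startswith("encoder_"):
        k = int(stage.split("_", 1)[1])
        if not 1 <= k <= model.cfg.depth:
            raise ValueError(
                f"stage {stage!r} out of range; encoder depth is {model.cfg.depth}"
            )
        seq = model.encode(tokens, train=False, rng=rng, n_layers=k)
        return seq.data.reshape(x.shape[0], -1)
    if stage == "final":
        seq = model.encode(tokens, train=False, rng=rng)
        return seq.data[:, 0, :]
    raise ValueError(
        f"unknown stage {stage!r}; expected one of {_STAGES} or 'encoder_k'"
    )
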