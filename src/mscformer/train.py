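"""Subject-specific five-fold cross-validation training protocol.

The original training session is split into five near-equal subsets.  Each
fold holds one subset out for validation and trains on the other four plus
their S&R-augmented copies; standardization statistics are fitted on the
four original subsets and applied to train, validation and test data.  After
every epoch the validation loss is computed without augmentation; the
checkpoint with the lowest validation loss (earliest epoch on ties) is
restored and scored once on the held-out test session.  Subject-level
results average the five fold results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import KFold

from .containers import TrialSet
from .metrics import ConfusionMatrix, accuracy, confusion_from_predictions, kappa
from .model import NetworkConfig, build_model
from .preprocess import (
    AugmentConfig,
    apply_standardizer,
    fit_standardizer,
    segment_reconstruct,
)

__all__ = [
    "TrainConfig",
    "FoldResult",
    "EvalReport",
    "split_five_fold",
    "train_one_fold",
    "run_subject",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and protocol settings (Adam with cross-entropy)."""

    lr: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 288
    epochs: int = 1000
    weight_decay: float = 0.0  # 0 for the 4-class benchmark, 1e-3 for the 2-class one
    seed: int = 0
    folds: int = 5
    standardizer_scope: str = "global"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class FoldResult:
    fold_index: int
    best_epoch: int
    best_val_loss: float
    test_accuracy: float
    test_kappa: float
    confusion: np.ndarray
    probabilities: np.ndarray
    val_loss_trace: list[float] = field(default_factory=list)
    train_loss_trace: list[float] = field(default_factory=list)
    best_weights: dict | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("best_weights", None)
        d["confusion"] = self.confusion.tolist()
        d["probabilities"] = self.probabilities.tolist()
        return d


@dataclass
class EvalReport:
    """Aggregate of the five folds for one subject."""

    subject_id: str
    mean_accuracy: float
    mean_kappa: float
    mean_confusion: np.ndarray
    fold_results: list[FoldResult]
    test_labels: np.ndarray

    @property
    def pooled_probabilities(self) -> np.ndarray:
        """Fold-averaged per-trial class scores (ROC input for binary tasks)."""
        return np.mean([f.probabilities for f in self.fold_results], axis=0)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean_accuracy": self.mean_accuracy,
            "mean_kappa": self.mean_kappa,
            "mean_confusion": self.mean_confusion.tolist(),
            "test_labels": self.test_labels.tolist(),
            "fold_results": [f.to_dict() for f in self.fold_results],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        folds = [
            FoldResult(
                fold_index=f["fold_index"],
                best_epoch=f["best_epoch"],
                best_val_loss=f["best_val_loss"],
                test_accuracy=f["test_accuracy"],
                test_kappa=f["test_kappa"],
                confusion=np.asarray(f["confusion"]),
                probabilities=np.asarray(f["probabilities"]),
                val_loss_trace=list(f.get("val_loss_trace", [])),
                train_loss_trace=list(f.get("train_loss_trace", [])),
            )
            for f in d["fold_results"]
        ]
        return cls(
            subject_id=d["subject_id"],
            mean_accuracy=d["mean_accuracy"],
            mean_kappa=d["mean_kappa"],
            mean_confusion=np.asarray(d["mean_confusion"]),
            fold_results=folds,
            test_labels=np.asarray(d["test_labels"]),
        )

    @classmethod
    def load(cls, path) -> "EvalReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def split_five_fold(train: TrialSet, seed: int, folds: int = 5):
    """Deterministic shuffled partition into ``folds`` near-equal subsets.

    Returns a list of ``(train_subset, val_subset)`` TrialSet pairs; every
    trial is a validation member exactly once.
    """
    if train.n_trials < folds:
        raise ValueError(f"{train.n_trials} trials cannot form {folds} folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pairs = []
    for tr_idx, va_idx in kf.split(np.arange(train.n_trials)):
        pairs.append(
            (train.subset(tr_idx, provenance="train"),
             train.subset(va_idx, provenance="validation"))
        )
    return pairs


class _Adam:
    """Adam with L2 weight decay applied to weights but not biases or norms."""

    def __init__(self, params: dict, cfg: TrainConfig) -> None:
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0
        self.decay = {k: self._decayable(k) for k in params}

    @staticmethod
    def _decayable(name: str) -> bool:
        if name.endswith(".bias"):
            return False
        if ".bn." in name or ".ln1." in name or ".ln2." in name:
            return False
        if name in ("cls_token", "pos_table"):
            return False
        return True

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1 - c.beta1**self.t
        bc2 = 1 - c.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if c.weight_decay and self.decay[k]:
                g = g + c.weight_decay * p.data
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g**2
            p.data -= c.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + 1e-8)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _check_no_leakage(train_subset: TrialSet, val_subset: TrialSet) -> None:
    if any(tag == "validation" for tag in train_subset.provenance):
        raise ValueError(
            "leakage guard: training subset contains validation-tagged trials"
        )
    if any(tag in ("augmented",) for tag in val_subset.provenance):
        raise ValueError("leakage guard: validation subset contains augmented trials")


def _evaluate_loss(model, signals: np.ndarray, labels: np.ndarray) -> float:
    loss = model.loss(signals, labels, train=False)
    return float(loss.data)


def train_one_fold(
    train_subset: TrialSet,
    val_subset: TrialSet,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    aug_cfg: AugmentConfig | None,
    test: TrialSet,
    fold_index: int = 0,
    variant: str = "mscformer",
) -> FoldResult:
    """Train one fold and score the best-validation-loss checkpoint on ``test``.

    Standardization is fitted on the original training subset (global scope
    by default) and applied to train, validation and test signals.
    Augmentation donors come exclusively from ``train_subset``.
    """
    _check_no_leakage(train_subset, val_subset)
    fold_seed = train_cfg.seed + fold_index

    stats = fit_standardizer(train_subset, scope=train_cfg.standardizer_scope)
    train_std = apply_standardizer(stats, train_subset)
    val_std = apply_standardizer(stats, val_subset)
    test_std = apply_standardizer(stats, test)

    if aug_cfg is not None:
        aug_cfg = AugmentConfig(
            n_segments=aug_cfg.n_segments,
            n_augmented=aug_cfg.n_augmented,
            class_conditional=aug_cfg.class_conditional,
            seed=fold_seed if aug_cfg.seed == 0 else aug_cfg.seed,
        )
        augmented = segment_reconstruct(train_std, aug_cfg)
        pool_x = np.concatenate([train_std.signals, augmented.signals])
        pool_y = np.concatenate([train_std.labels, augmented.labels])
    else:
        pool_x, pool_y = train_std.signals, train_std.labels

    model = build_model(net_cfg, variant=variant, seed=fold_seed)
    opt = _Adam(model.params, train_cfg)
    rng = np.random.default_rng(fold_seed + 10_000)

    best_val = np.inf
    best_epoch = -1
    best_weights = model.get_weights()
    val_trace: list[float] = []
    train_trace: list[float] = []

    n_pool = pool_x.shape[0]
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n_pool)
        epoch_losses = []
        for start in range(0, n_pool, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            opt.zero_grad()
            loss = model.loss(pool_x[idx], pool_y[idx], train=True, rng=rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch starting {start} (fold {fold_index})"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        train_trace.append(float(np.mean(epoch_losses)))
        val_loss = _evaluate_loss(model, val_std.signals, val_std.labels)
        val_trace.append(val_loss)
        if val_loss < best_val:  # strict: ties keep the earlier epoch
            best_val = val_loss
            best_epoch = epoch
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    probs = model.forward(test_std.signals, train=False)
    preds = probs.argmax(axis=1)  # argmax ties break toward the lower class index
    cm = confusion_from_predictions(test_std.labels, preds, test.n_classes)
    return FoldResult(
        fold_index=fold_index,
        best_epoch=best_epoch,
        best_val_loss=best_val,
        test_accuracy=accuracy(cm),
        test_kappa=kappa(cm),
        confusion=cm.counts,
        probabilities=probs,
        val_loss_trace=val_trace,
        train_loss_trace=train_trace,
        best_weights=best_weights,
    )


def run_subject(
    train: TrialSet,
    test: TrialSet,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    aug_cfg: AugmentConfig | None = AugmentConfig(),
    variant: str = "mscformer",
) -> EvalReport:
    """Full five-fold protocol for one subject; averages fold test metrics."""
    if (train.n_channels, train.n_samples, train.n_classes) != (
        test.n_channels,
        test.n_samples,
        test.n_classes,
    ):
        raise ValueError(
            "train/test geometry mismatch: "
            f"train (C={train.n_channels}, T={train.n_samples}, M={train.n_classes}) "
            f"vs test (C={test.n_channels}, T={test.n_samples}, M={test.n_classes})"
        )
    folds = split_five_fold(train, seed=train_cfg.seed, folds=train_cfg.folds)
    results = [
        train_one_fold(tr, va, net_cfg, train_cfg, aug_cfg, test,
                       fold_index=i, variant=variant)
        for i, (tr, va) in enumerate(folds)
    ]
    return EvalReport(
        subject_id=train.subject_id,
        mean_accuracy=float(np.mean([r.test_accuracy for r in results])),
        mean_kappa=float(np.mean([r.test_kappa for r in results])),
        mean_confusion=np.mean([r.confusion for r in results], axis=0),
        fold_results=results,
        test_labels=test.labels.copy(),
    )
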