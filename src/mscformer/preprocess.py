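"""Zero-mean standardization and segmentation-and-reconstruction augmentation.

Standardization statistics are always fitted on training trials and applied
unchanged to validation/test trials.  S&R augmentation cuts each trial into
``n_segments`` contiguous time blocks and builds artificial trials by drawing
each block, at its own temporal position, from a random donor trial of the
same class — temporal order is preserved, classes are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialSet

__all__ = [
    "StandardizerStats",
    "AugmentConfig",
    "fit_standardizer",
    "apply_standardizer",
    "segment_boundaries",
    "segment_reconstruct",
]


@dataclass(frozen=True)
class StandardizerStats:
    """Training-set mean/S.D. applied to train and test alike.

    ``scope="global"`` stores one scalar pair over every sample of every
    channel and trial; ``scope="per_channel"`` one pair per channel.
    """

    mu: np.ndarray
    sigma: np.ndarray
    scope: str

    def __post_init__(self) -> None:
        if self.scope not in ("global", "per_channel"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma must be strictly positive")


@dataclass(frozen=True)
class AugmentConfig:
    """S&R configuration: ``n_segments`` blocks, ``n_augmented`` new trials."""

    n_segments: int = 8
    n_augmented: int | None = None  # None -> one per original trial
    class_conditional: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.n_augmented is not None and self.n_augmented < 0:
            raise ValueError("n_augmented must be >= 0")


def fit_standardizer(
    train: TrialSet, scope: str = "global", epsilon: float | None = None
) -> StandardizerStats:
    """Compute mean and population S.D. of all training samples.

    Raises if any fitted sigma is zero (constant signal) unless ``epsilon``
    is given, in which case ``epsilon`` is added to sigma.
    """
    if train.n_trials == 0:
        raise ValueError("cannot fit standardizer on an empty TrialSet")
    x = train.signals
    if scope == "global":
        mu = np.array(x.mean())
        sigma = np.array(x.std())
    elif scope == "per_channel":
        mu = x.mean(axis=(0, 2))
        sigma = x.std(axis=(0, 2))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if np.any(sigma == 0):
        if epsilon is None:
            raise ValueError(
                "zero standard deviation (constant signal); pass epsilon=1e-8 "
                "to enable the documented epsilon override"
            )
        sigma = sigma + epsilon
    return StandardizerStats(mu=mu, sigma=sigma, scope=scope)


def apply_standardizer(stats: StandardizerStats, ts: TrialSet) -> TrialSet:
    """Element-wise ``(x - mu) / sigma``; labels and metadata unchanged."""
    if stats.scope == "global":
        z = (ts.signals - stats.mu) / stats.sigma
    else:
        if len(stats.mu) != ts.n_channels:
            raise ValueError(
                f"per_channel stats have {len(stats.mu)} channels but data has "
                f"{ts.n_channels}"
            )
        z = (ts.signals - stats.mu[None, :, None]) / stats.sigma[None, :, None]
    return ts.with_signals(z)


def segment_boundaries(n_samples: int, n_segments: int) -> list[tuple[int, int]]:
    """Partition ``[0, n_samples)`` into contiguous blocks of near-equal size.

    Sizes differ by at most one; the first ``n_samples % n_segments`` blocks
    get the extra sample.
    """
    if n_segments > n_samples:
        raise ValueError(
            f"n_segments={n_segments} exceeds trial length {n_samples}"
        )
    base, extra = divmod(n_samples, n_segments)
    bounds, start = [], 0
    for k in range(n_segments):
        size = base + (1 if k < extra else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def segment_reconstruct(train: TrialSet, cfg: AugmentConfig) -> TrialSet:
    """Generate artificial trials by recombining same-position segments.

    Each output trial's k-th time segment is the k-th time segment of a donor
    trial drawn uniformly (with replacement) from the donor pool; under
    ``class_conditional`` the pool is restricted to the target class, and the
    output label equals the donor class.  Deterministic under ``cfg.seed``.
    """
    if train.n_trials == 0:
        raise ValueError("cannot augment an empty TrialSet")
    n_aug = train.n_trials if cfg.n_augmented is None else cfg.n_augmented
    bounds = segment_boundaries(train.n_samples, cfg.n_segments)
    rng = np.random.default_rng(cfg.seed)

    if cfg.class_conditional:
        pools = {}
        for c in range(train.n_classes):
            pool = np.flatnonzero(train.labels == c)
            if pool.size == 0:
                raise ValueError(
                    f"class {c} ({train.class_names[c]!r}) has no trials; "
                    "cannot draw class-conditional donors"
                )
            pools[c] = pool
        # balanced round-robin over classes so augmented labels stay balanced
        classes = np.arange(n_aug) % train.n_classes
    else:
        pools = {0: np.arange(train.n_trials)}
        classes = np.zeros(n_aug, dtype=int)

    out = np.empty((n_aug, train.n_channels, train.n_samples), dtype=train.signals.dtype)
    out_labels = np.empty(n_aug, dtype=np.int64)
    for i in range(n_aug):
        c = classes[i]
        pool = pools[c]
        donors = rng.integers(0, pool.size, size=cfg.n_segments)
        for k, (lo, hi) in enumerate(bounds):
            out[i, :, lo:hi] = train.signals[pool[donors[k]], :, lo:hi]
        out_labels[i] = train.labels[pool[donors[0]]] if not cfg.class_conditional else c

    aug = TrialSet(
        signals=out,
        labels=out_labels,
        fs=train.fs,
        channel_names=list(train.channel_names),
        class_names=list(train.class_names),
        subject_id=train.subject_id,
        session_tag=train.session_tag + "+augmented" if train.session_tag else "augmented",
        provenance=["augmented"] * n_aug,
    )
    return aug
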