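"""The MSCFormer network and its MSNet ablation.

Architecture, per trial of shape ``(C, T)``:

* three parallel CNN branches, each: temporal convolution (``F1`` filters,
  kernel ``(1, Kc)``, 'same' padding, kernels 85/65/45 by default) ->
  depthwise spatial convolution (``(C, 1)``, one spatial filter per temporal
  map) -> batch norm -> ELU -> average pooling ``(1, P)`` stride ``P`` ->
  dropout 0.5;
* branch maps transposed and concatenated along features into tokens of
  dimension ``F2 = 3*F1``;
* a class token is prepended, a learnable positional table added, and the
  sequence passes through ``L`` post-norm Transformer encoder layers
  (multi-head self-attention + GELU feed-forward, residual then LayerNorm);
* the final-layer class-token embedding, after dropout 0.25, feeds one fully
  connected softmax layer.

MSNet drops the Transformer entirely: the fused tokens are flattened and fed
to the classifier.  ``count_parameters`` reports, by default, the operator
weight count (convolutions, norms, attention, feed-forward, classifier) —
the accounting convention behind the published model sizes, which leaves out
the class-token and positional embedding tables; pass
``include_embeddings=True`` for the complete trainable count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, concat, softmax_cross_entropy

__all__ = [
    "ConvBranchConfig",
    "NetworkConfig",
    "MSCFormer",
    "MSNet",
    "build_model",
    "count_parameters",
    "pooled_length",
]


@dataclass(frozen=True)
class ConvBranchConfig:
    """One CNN branch: ``f1`` temporal filters of length ``kc``, pool ``pool``."""

    f1: int = 16
    kc: int = 85
    pool: int = 44
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.kc < 1 or self.pool < 1:
            raise ValueError("kernel and pool lengths must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class NetworkConfig:
    """All architecture hyperparameters.

    Defaults are the benchmark 4-class configuration: 22 channels, 1000
    samples, branch kernels (85, 65, 45) sharing ``f1=16`` and ``pool=44``,
    embedding ``embed_dim = 3*f1 = 48``, depth 5, 8 heads, feed-forward width
    192.  For the 2-class bipolar benchmark use ``channels=3, n_classes=2,
    pool=52``.
    """

    channels: int = 22
    samples: int = 1000
    n_classes: int = 4
    f1: int = 16
    kernels: tuple[int, int, int] = (85, 65, 45)
    pool: int = 44
    conv_dropout: float = 0.5
    depth: int = 5
    heads: int = 8
    ff_dim: int = 192
    encoder_dropout: float = 0.25
    classifier_dropout: float = 0.25
    pool_ceil_mode: bool = True

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} (= 3*f1) must be divisible by "
                f"heads {self.heads}"
            )
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def embed_dim(self) -> int:
        return 3 * self.f1

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads

    @property
    def n_tokens(self) -> int:
        return pooled_length(self.samples, self.pool, self.pool_ceil_mode)

    @property
    def branches(self) -> tuple[ConvBranchConfig, ...]:
        return tuple(
            ConvBranchConfig(f1=self.f1, kc=k, pool=self.pool, dropout=self.conv_dropout)
            for k in self.kernels
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernels"] = list(self.kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["kernels"] = tuple(d.get("kernels", (85, 65, 45)))
        return cls(**d)


def pooled_length(samples: int, pool: int, ceil_mode: bool = True) -> int:
    """Token count after average pooling with kernel == stride == ``pool``."""
    if ceil_mode:
        return -(-samples // pool)
    return samples // pool


# --------------------------------------------------------------------------
# parameter initialization
# --------------------------------------------------------------------------


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class _Module:
    """Base: a named dict of parameter Tensors plus non-trainable state."""

    def __init__(self) -> None:
        self.params: dict[str, Tensor] = {}
        self.state: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True, name=name)
        self.params[name] = t
        return t

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.params.items()}
        out.update({f"state/{k}": v.copy() for k, v in self.state.items()})
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = weights[k].copy()
        for k in self.state:
            self.state[k] = weights[f"state/{k}"].copy()


class _BatchNorm:
    """Batch normalization over (batch, channel, time) per feature map."""

    def __init__(self, owner: _Module, prefix: str, n_features: int,
                 momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = owner.add_param(f"{prefix}.gamma", np.ones(n_features))
        self.beta = owner.add_param(f"{prefix}.beta", np.zeros(n_features))
        owner.state[f"{prefix}.running_mean"] = np.zeros(n_features)
        owner.state[f"{prefix}.running_var"] = np.ones(n_features)
        self.owner, self.prefix = owner, prefix
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        # x: (N, F, C, T); normalize each feature map over (N, C, T)
        axes = (0, 2, 3)
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            rm = self.owner.state[f"{self.prefix}.running_mean"]
            rv = self.owner.state[f"{self.prefix}.running_var"]
            n = x.data.size / x.shape[1]
            unbiased = var.data.reshape(-1) * n / max(n - 1, 1)
            rm *= 1 - self.momentum
            rm += self.momentum * mu.data.reshape(-1)
            rv *= 1 - self.momentum
            rv += self.momentum * unbiased
        else:
            mu = Tensor(self.owner.state[f"{self.prefix}.running_mean"].reshape(1, -1, 1, 1))
            var = Tensor(self.owner.state[f"{self.prefix}.running_var"].reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class _LayerNorm:
    def __init__(self, owner: _Module, prefix: str, dim: int, eps: float = 1e-5) -> None:
        self.gamma = owner.add_param(f"{prefix}.gamma", np.ones(dim))
        self.beta = owner.add_param(f"{prefix}.beta", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class _Linear:
    def __init__(self, owner: _Module, prefix: str, d_in: int, d_out: int,
                 rng: np.random.Generator) -> None:
        self.w = owner.add_param(f"{prefix}.weight", _uniform(rng, (d_in, d_out), d_in))
        self.b = owner.add_param(f"{prefix}.bias", _uniform(rng, (d_out,), d_in))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


def _dropout(x: Tensor, p: float, train: bool, rng: np.random.Generator) -> Tensor:
    if not train or p == 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# --------------------------------------------------------------------------
# network modules
# --------------------------------------------------------------------------


class _ConvBranch:
    """temporal conv -> depthwise spatial conv -> BN -> ELU -> avg pool -> dropout."""

    def __init__(self, owner: _Module, prefix: str, cfg: ConvBranchConfig,
                 channels: int, ceil_mode: bool, rng: np.random.Generator) -> None:
        f1, kc = cfg.f1, cfg.kc
        self.cfg = cfg
        self.channels = channels
        self.ceil_mode = ceil_mode
        self.wt = owner.add_param(f"{prefix}.temporal.weight", _uniform(rng, (f1, kc), kc))
        self.bt = owner.add_param(f"{prefix}.temporal.bias", _uniform(rng, (f1,), kc))
        self.ws = owner.add_param(
            f"{prefix}.spatial.weight", _uniform(rng, (f1, channels), channels)
        )
        self.bs = owner.add_param(f"{prefix}.spatial.bias", _uniform(rng, (f1,), channels))
        self.bn = _BatchNorm(owner, f"{prefix}.bn", f1)

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator) -> Tensor:
        # x: (N, C, T) -> (N, F1, Tp)
        if x.shape[1] != self.channels:
            raise ValueError(
                f"input has {x.shape[1]} channels but the spatial kernel was "
                f"built for {self.channels}"
            )
        windows = x.unfold_time(self.cfg.kc)  # (N, C, T, Kc)
        # temporal conv: one filter bank shared across EEG channels
        h = windows @ self.wt.transpose((1, 0))  # (N, C, T, F1)
        h = h + self.bt
        h = h.transpose((0, 3, 1, 2))  # (N, F1, C, T)
        # depthwise spatial conv: weighted sum over channels per temporal map
        ws = self.ws.reshape(1, self.cfg.f1, self.channels, 1)
        h = (h * ws).sum(axis=2, keepdims=True)  # (N, F1, 1, T)
        h = h + self.bs.reshape(1, self.cfg.f1, 1, 1)
        h = self.bn(h, train)
        h = h.elu()
        h = _avg_pool_time(h, self.cfg.pool, self.ceil_mode)  # (N, F1, 1, Tp)
        h = h.reshape(h.shape[0], self.cfg.f1, h.shape[3])
        return _dropout(h, self.cfg.dropout, train, rng)


def _avg_pool_time(x: Tensor, pool: int, ceil_mode: bool) -> Tensor:
    """Average pooling over the last axis, kernel == stride == ``pool``.

    In ceil mode a trailing partial window is averaged over the samples it
    actually contains (count_include_pad off).
    """
    T = x.shape[-1]
    n_full = T // pool
    rem = T - n_full * pool
    lead = x.shape[:-1]
    full = x[..., : n_full * pool].reshape(*lead, n_full, pool).mean(axis=-1)
    if ceil_mode and rem:
        tail = x[..., n_full * pool :].mean(axis=-1, keepdims=True)
        return concat([full, tail], axis=-1)
    return full


class MSCFormer(_Module):
    """Multi-scale CNN + Transformer encoder + class-token softmax classifier."""

    variant = "mscformer"

    def __init__(self, cfg: NetworkConfig, seed: int = 0) -> None:
        super().__init__()
        if cfg.depth < 1:
            raise ValueError(
                "MSCFormer requires depth >= 1; the no-Transformer ablation is "
                "MSNet, a distinct head, not a depth-0 encoder"
            )
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.branches = [
            _ConvBranch(self, f"branch{i}", bc, cfg.channels, cfg.pool_ceil_mode, rng)
            for i, bc in enumerate(cfg.branches)
        ]
        E = cfg.embed_dim
        self.cls_token = self.add_param("cls_token", rng.normal(0.0, 0.02, size=(E,)))
        self.pos_table = self.add_param(
            "pos_table", rng.normal(0.0, 0.02, size=(cfg.n_tokens + 1, E))
        )
        self.layers = []
        for l in range(cfg.depth):
            p = f"encoder{l}"
            layer = {
                "wq": _Linear(self, f"{p}.wq", E, E, rng),
                "wk": _Linear(self, f"{p}.wk", E, E, rng),
                "wv": _Linear(self, f"{p}.wv", E, E, rng),
                "wo": _Linear(self, f"{p}.wo", E, E, rng),
                "ln1": _LayerNorm(self, f"{p}.ln1", E),
                "w1": _Linear(self, f"{p}.ff1", E, cfg.ff_dim, rng),
                "w2": _Linear(self, f"{p}.ff2", cfg.ff_dim, E, rng),
                "ln2": _LayerNorm(self, f"{p}.ln2", E),
            }
            self.layers.append(layer)
        self.classifier = _Linear(self, "classifier", E, cfg.n_classes, rng)

    # -- forward pieces ------------------------------------------------------

    def conv_tokens(self, x: Tensor, train: bool, rng: np.random.Generator) -> Tensor:
        """Fused multi-scale token map: (N, C, T) -> (N, Tp, F2)."""
        maps = [br(x, train, rng) for br in self.branches]  # each (N, F1, Tp)
        tokens = concat(maps, axis=1)  # (N, F2, Tp)
        return tokens.transpose((0, 2, 1))

    def encode(
        self,
        tokens: Tensor,
        train: bool,
        rng: np.random.Generator,
        n_layers: int | None = None,
        use_positions: bool = True,
        use_class_token: bool = True,
    ) -> Tensor:
        """Run the encoder; returns the full sequence after ``n_layers``."""
        cfg = self.cfg
        N, S = tokens.shape[0], tokens.shape[1]
        if use_class_token:
            cls = self.cls_token.reshape(1, 1, cfg.embed_dim) * Tensor(np.ones((N, 1, 1)))
            seq = concat([cls, tokens], axis=1)
            S += 1
        else:
            seq = tokens
        if use_positions:
            seq = seq + self.pos_table[:S].reshape(1, S, cfg.embed_dim)
        depth = cfg.depth if n_layers is None else n_layers
        for layer in self.layers[:depth]:
            seq = self._mha_block(seq, layer, train, rng)
            seq = self._ff_block(seq, layer, train, rng)
        return seq

    def _attention(self, seq: Tensor, layer: dict) -> Tensor:
        cfg = self.cfg
        N, S, E = seq.shape
        h, dk = cfg.heads, cfg.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(N, S, h, dk).transpose((0, 2, 1, 3))  # (N, h, S, dk)

        q, k, v = split(layer["wq"](seq)), split(layer["wk"](seq)), split(layer["wv"](seq))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(dk))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (N, h, S, dk)
        ctx = ctx.transpose((0, 2, 1, 3)).reshape(N, S, E)
        return layer["wo"](ctx)

    def _mha_block(self, seq: Tensor, layer: dict, train: bool,
                   rng: np.random.Generator) -> Tensor:
        out = self._attention(seq, layer)
        out = _dropout(out, self.cfg.encoder_dropout, train, rng)
        return layer["ln1"](seq + out)  # post-norm residual

    def _ff_block(self, seq: Tensor, layer: dict, train: bool,
                  rng: np.random.Generator) -> Tensor:
        h = layer["w1"](seq).gelu()
        h = _dropout(h, self.cfg.encoder_dropout, train, rng)
        h = layer["w2"](h)
        return layer["ln2"](seq + h)

    def logits(self, x: Tensor, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        rng = rng or np.random.default_rng(0)
        tokens = self.conv_tokens(x, train, rng)
        seq = self.encode(tokens, train, rng)
        feat = seq[:, 0, :]  # class-token embedding only
        feat = _dropout(feat, self.cfg.classifier_dropout, train, rng)
        return self.classifier(feat)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities for a batch ``(N, C, T)`` (or one ``(C, T)`` trial)."""
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        out = self.logits(Tensor(x), train=train, rng=rng).softmax(axis=-1).data
        return out[0] if single else out

    def loss(self, x: np.ndarray, y: np.ndarray, train: bool = True,
             rng: np.random.Generator | None = None) -> Tensor:
        return softmax_cross_entropy(self.logits(Tensor(x), train, rng), y)


class MSNet(MSCFormer):
    """Ablation without the Transformer: fused tokens flattened into the classifier."""

    variant = "msnet"

    def __init__(self, cfg: NetworkConfig, seed: int = 0) -> None:
        _Module.__init__(self)
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.branches = [
            _ConvBranch(self, f"branch{i}", bc, cfg.channels, cfg.pool_ceil_mode, rng)
            for i, bc in enumerate(cfg.branches)
        ]
        self.layers = []
        self.classifier = _Linear(
            self, "classifier", cfg.n_tokens * cfg.embed_dim, cfg.n_classes, rng
        )

    def logits(self, x: Tensor, train: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        rng = rng or np.random.default_rng(0)
        tokens = self.conv_tokens(x, train, rng)  # (N, Tp, F2)
        flat = tokens.reshape(tokens.shape[0], tokens.shape[1] * tokens.shape[2])
        flat = _dropout(flat, self.cfg.classifier_dropout, train, rng)
        return self.classifier(flat)


def build_model(cfg: NetworkConfig, variant: str = "mscformer", seed: int = 0) -> MSCFormer:
    if variant == "mscformer":
        return MSCFormer(cfg, seed=seed)
    if variant == "msnet":
        return MSNet(cfg, seed=seed)
    raise ValueError(f"unknown variant {variant!r}")


_EMBEDDING_TABLES = ("cls_token", "pos_table")


def count_parameters(
    cfg: NetworkConfig,
    variant: str = "mscformer",
    include_embeddings: bool = False,
    as_thousands: bool = False,
) -> int | float:
    """Trainable-scalar count of the configured network.

    The default convention counts operator weights only (convolutions, batch
    and layer norms, attention and feed-forward projections, classifier),
    matching the published size accounting for these models;
    ``include_embeddings=True`` adds the class token and positional table.
    ``as_thousands`` reports ``count / 1000`` rounded to one decimal.
    """
    model = build_model(cfg, variant)
    total = 0
    for name, p in model.params.items():
        if not include_embeddings and name in _EMBEDDING_TABLES:
            continue
        total += p.data.size
    return round(total / 1000.0, 1) if as_thousands else total
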