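"""The three sgRNA activity architectures.

* **AttnToMismatchCNN** — off-target specificity classifier. Aligned base-pair
  tokens are embedded, summed elementwise with a positional embedding, passed
  through a stack of transformer blocks (shape-preserving), then treated as a
  1-channel (L, embed_dim) image for two Conv2d + MaxPool stages, flattened
  into fully connected layers, and finished with a log-softmax over the two
  classes (active / inactive).

* **AttnToCrisprCNN** — on-target efficiency regressor. Identical trunk over
  dimer tokens, but extra per-guide biological features (NetExpress score,
  copy number, ...) are concatenated after the CNN flatten and the head is a
  single linear output.

* **SeqCrispr** — on-target regressor with a CNN branch and an LSTM branch in
  parallel over the embedded dimers; their flattened outputs are concatenated
  (with the optional biological features) into the fully connected head.

Transformer blocks are encoder-only by default. ``use_decoder=True`` appends
decoder blocks that self-attend the embedded sequence and cross-attend the
encoder output — there is no separate target sequence in this task, so the
decoder reprocesses the same embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import nn
from .errors import ConfigError
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "AttnToMismatchCNN",
    "AttnToCrisprCNN",
    "SeqCrispr",
    "build_attn_to_mismatch",
    "build_attn_to_crispr",
    "build_seq_crispr",
    "build_model",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Hyperparameters shared by the three architectures.

    ``max_len`` is the token-sequence length the model consumes: the aligned
    pair length (20/27) for the classifier, the dimer count (19/33) for the
    regressors. ``n_extra_features`` appends that many per-sample covariates
    to the fully connected head.
    """

    vocab_size: int = 16
    embed_dim: int = 32
    max_len: int = 20
    n_attention_layers: int = 2
    n_heads: int = 4
    use_decoder: bool = False
    conv_channels: tuple[int, int] = (32, 64)
    conv_kernels: tuple[tuple[int, int], tuple[int, int]] = ((3, 3), (3, 3))
    pool_kernels: tuple[tuple[int, int], tuple[int, int]] = ((2, 2), (2, 2))
    recurrent_hidden: int = 32
    fc_sizes: tuple[int, ...] = (128, 32)
    dropout: float = 0.2
    n_extra_features: int = 0
    positional_mode: str = "learned"
    task: str = "classify"  # or "regress"
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError("embed_dim must be divisible by n_heads")
        if self.task not in ("classify", "regress"):
            raise ConfigError(f"unknown task {self.task!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.n_extra_features < 0:
            raise ConfigError("n_extra_features must be >= 0")
        self.conv_channels = tuple(self.conv_channels)
        self.conv_kernels = tuple(tuple(k) for k in self.conv_kernels)
        self.pool_kernels = tuple(tuple(k) for k in self.pool_kernels)
        self.fc_sizes = tuple(self.fc_sizes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def compact(cls, **overrides) -> "ModelConfig":
        """Desk-scale profile used by the synthetic benchmarks: a quarter-width
        trunk (embed 16, 1 attention layer, conv 8/16, one FC layer) that
        trains in seconds per epoch on one CPU core while remaining ample for
        the planted-signal tasks."""
        base = dict(
            embed_dim=16,
            n_heads=2,
            n_attention_layers=1,
            conv_channels=(8, 16),
            fc_sizes=(64,),
            recurrent_hidden=16,
            dropout=0.1,
        )
        base.update(overrides)
        return cls(**base)


def _cnn_output_size(cfg: ModelConfig) -> int:
    h, w = cfg.max_len, cfg.embed_dim
    for (kh, kw), (ph, pw) in zip(cfg.conv_kernels, cfg.pool_kernels):
        h, w = h - kh + 1, w - kw + 1
        if h <= 0 or w <= 0:
            raise ConfigError(
                f"sequence length {cfg.max_len} too short for conv kernels {cfg.conv_kernels}"
            )
        h, w = h // ph, w // pw
        if h <= 0 or w <= 0:
            raise ConfigError("pooling collapses the feature map to zero size")
    return cfg.conv_channels[-1] * h * w


class _EmbedTransformer(nn.Module):
    """Shared trunk: token + positional embedding, transformer stack."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.embed = nn.Embedding(cfg.vocab_size, cfg.embed_dim, rng)
        self.pos = nn.PositionalEmbedding(cfg.max_len, cfg.embed_dim, rng, cfg.positional_mode)
        ff = 2 * cfg.embed_dim
        self.encoder_layers = [
            nn.TransformerEncoderLayer(cfg.embed_dim, cfg.n_heads, ff, cfg.dropout, rng)
            for _ in range(cfg.n_attention_layers)
        ]
        self.decoder_layers = (
            [
                nn.TransformerDecoderLayer(cfg.embed_dim, cfg.n_heads, ff, cfg.dropout, rng)
                for _ in range(cfg.n_attention_layers)
            ]
            if cfg.use_decoder
            else []
        )

    def forward(self, tokens: np.ndarray) -> Tensor:
        x = self.pos(self.embed(tokens))
        h = x
        for layer in self.encoder_layers:
            h = layer(h)
        if self.decoder_layers:
            d = x
            for layer in self.decoder_layers:
                d = layer(d, memory=h)
            h = d
        return h  # (B, L, E) — same shape as the embedding


class _ConvStack(nn.Module):
    """Two Conv2d + MaxPool stages over the (1, L, E) embedding image."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(1, cfg.conv_channels[0], cfg.conv_kernels[0], rng)
        self.pool1 = nn.MaxPool2d(cfg.pool_kernels[0])
        self.conv2 = nn.Conv2d(cfg.conv_channels[0], cfg.conv_channels[1], cfg.conv_kernels[1], rng)
        self.pool2 = nn.MaxPool2d(cfg.pool_kernels[1])

    def forward(self, x: Tensor) -> Tensor:
        b, length, dim = x.shape
        img = x.reshape(b, 1, length, dim)
        h = self.pool1(self.conv1(img).relu())
        h = self.pool2(self.conv2(h).relu())
        b2, c, hh, ww = h.shape
        return h.reshape(b2, c * hh * ww)


class _FCHead(nn.Module):
    def __init__(self, in_dim: int, cfg: ModelConfig, out_dim: int, rng: np.random.Generator):
        super().__init__()
        sizes = (in_dim,) + cfg.fc_sizes
        self.hidden = [nn.Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.out = nn.Linear(sizes[-1], out_dim, rng)
        self.drop = nn.Dropout(cfg.dropout, np.random.default_rng(rng.integers(2**31)))

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.hidden:
            x = self.drop(layer(x).relu())
        return self.out(x)


class _SequenceModel(nn.Module):
    """Common scaffolding: config storage and extra-feature plumbing."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg

    def _check_inputs(self, tokens: np.ndarray, extra: Optional[np.ndarray]):
        tokens = np.asarray(tokens)
        if tokens.ndim == 1:
            tokens = tokens[None, :]
        if tokens.shape[1] != self.cfg.max_len:
            raise ConfigError(
                f"expected token sequences of length {self.cfg.max_len}, got {tokens.shape[1]}"
            )
        if self.cfg.n_extra_features:
            if extra is None:
                raise ConfigError(
                    f"model expects {self.cfg.n_extra_features} extra features, got none"
                )
            extra = np.asarray(extra, dtype=np.float64)
            if extra.ndim == 1:
                extra = extra[None, :]
            if extra.shape != (tokens.shape[0], self.cfg.n_extra_features):
                raise ConfigError(
                    f"extra features must have shape ({tokens.shape[0]}, "
                    f"{self.cfg.n_extra_features}), got {extra.shape}"
                )
        elif extra is not None and np.asarray(extra).size:
            raise ConfigError("model was built without extra features")
        return tokens, extra


class AttnToMismatchCNN(_SequenceModel):
    """Off-target classifier: embedding -> transformer -> CNN -> FC -> log-softmax."""

    def __init__(self, cfg: ModelConfig):
        if cfg.task != "classify":
            raise ConfigError("AttnToMismatchCNN requires task='classify'")
        super().__init__(cfg)
        rng = np.random.default_rng(cfg.seed)
        self.trunk = _EmbedTransformer(cfg, rng)
        self.cnn = _ConvStack(cfg, rng)
        self.head = _FCHead(_cnn_output_size(cfg) + cfg.n_extra_features, cfg, 2, rng)

    def forward(self, tokens: np.ndarray, extra: Optional[np.ndarray] = None) -> Tensor:
        tokens, extra = self._check_inputs(tokens, extra)
        h = self.cnn(self.trunk(tokens))
        if extra is not None:
            h = nn.concat([h, Tensor(extra)], axis=1)
        return self.head(h).log_softmax(axis=-1)  # (B, 2) log-probabilities


class AttnToCrisprCNN(_SequenceModel):
    """On-target regressor: embedding -> transformer -> CNN -> FC -> linear."""

    def __init__(self, cfg: ModelConfig):
        if cfg.task != "regress":
            raise ConfigError("AttnToCrisprCNN requires task='regress'")
        super().__init__(cfg)
        rng = np.random.default_rng(cfg.seed)
        self.trunk = _EmbedTransformer(cfg, rng)
        self.cnn = _ConvStack(cfg, rng)
        self.head = _FCHead(_cnn_output_size(cfg) + cfg.n_extra_features, cfg, 1, rng)

    def forward(self, tokens: np.ndarray, extra: Optional[np.ndarray] = None) -> Tensor:
        tokens, extra = self._check_inputs(tokens, extra)
        h = self.cnn(self.trunk(tokens))
        if extra is not None:
            h = nn.concat([h, Tensor(extra)], axis=1)
        return self.head(h).reshape(tokens.shape[0])  # (B,)


class SeqCrispr(_SequenceModel):
    """On-target regressor with parallel CNN and LSTM branches over the embedding."""

    def __init__(self, cfg: ModelConfig):
        if cfg.task != "regress":
            raise ConfigError("SeqCrispr requires task='regress'")
        super().__init__(cfg)
        rng = np.random.default_rng(cfg.seed)
        self.embed = nn.Embedding(cfg.vocab_size, cfg.embed_dim, rng)
        self.cnn = _ConvStack(cfg, rng)
        self.lstm = nn.LSTM(cfg.embed_dim, cfg.recurrent_hidden, rng)
        in_dim = _cnn_output_size(cfg) + cfg.recurrent_hidden + cfg.n_extra_features
        self.head = _FCHead(in_dim, cfg, 1, rng)

    def forward(self, tokens: np.ndarray, extra: Optional[np.ndarray] = None) -> Tensor:
        tokens, extra = self._check_inputs(tokens, extra)
        x = self.embed(tokens)
        parts = [self.cnn(x), self.lstm(x)]
        if extra is not None:
            parts.append(Tensor(extra))
        h = nn.concat(parts, axis=1)
        return self.head(h).reshape(tokens.shape[0])


def build_attn_to_mismatch(cfg: ModelConfig) -> AttnToMismatchCNN:
    return AttnToMismatchCNN(cfg)


def build_attn_to_crispr(cfg: ModelConfig) -> AttnToCrisprCNN:
    return AttnToCrisprCNN(cfg)


def build_seq_crispr(cfg: ModelConfig) -> SeqCrispr:
    return SeqCrispr(cfg)


_REGISTRY = {
    "attn_mismatch": AttnToMismatchCNN,
    "attn_crispr": AttnToCrisprCNN,
    "seqcrispr": SeqCrispr,
}


def build_model(name: str, cfg: ModelConfig) -> _SequenceModel:
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ConfigError(f"unknown model {name!r}; choose from {sorted(_REGISTRY)}")
    return cls(cfg)


def save_model(model: _SequenceModel, path: str | Path, model_name: str | None = None) -> None:
    """Checkpoint = npz of parameter arrays + YAML sidecar with the config."""
    path = Path(path)
    name = model_name or {v: k for k, v in _REGISTRY.items()}[type(model)]
    np.savez(path, **model.state_arrays())
    meta = {"model": name, "config": model.cfg.to_dict()}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_model(path: str | Path) -> _SequenceModel:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    cfg = ModelConfig(**meta["config"])
    model = build_model(meta["model"], cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_arrays({k: data[k] for k in data.files})
    return model.eval()
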