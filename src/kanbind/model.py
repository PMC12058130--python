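"""Assembly of the hybrid binding-site network and its ablation variants.

The full model embeds each sequence as a (T, k) matrix of k-mer vectors and
runs two parallel encoders over it: three multi-scale 1-D convolution
blocks (concatenated) and a bidirectional LSTM.  The two feature vectors
are linearly projected to a common width, fused (additively when the
residual connection is on, by concatenation+projection when off),
layer-normalized, dropped out, and classified by a Kolmogorov-Arnold head
(or an MLP of the same widths) producing one sigmoid logit.

Every ablation variant — single conv blocks, widened channels, trainable
instead of pretrained embeddings, no residual, MLP head, no BiLSTM — is a
:class:`ModelConfig`, not a code fork.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .embedding import kmer_vocabulary, make_fallback_table, table_to_matrix, token_count, TokenizerSpec
from .io_formats import EmbeddingTable
from .kan import KAN, SplineGrid
from .nn.tensor import Tensor, relu, concat

__all__ = [
    "ConvLayerSpec",
    "ConvBlockSpec",
    "ModelConfig",
    "default_conv_block",
    "build_model",
    "parameter_count",
    "trace_conv_shapes",
    "ablation_variant_configs",
    "ABLATION_VARIANT_NAMES",
    "BindingSiteNetwork",
]

#: Block structure as (out_channels, kernel) pairs.  The two-layer blocks
#: admit two kernel/channel pairings; the default pairs kernels (11,9)
#: with block 2 and (1,8) with block 3, the "alternate" preset (11,1)
#: and (9,8).
_BLOCK_PRESETS = {
    "default": {
        1: ((160, 9), (160, 1), (160, 5), (256, 8)),
        2: ((128, 11), (256, 9)),
        3: ((180, 1), (256, 8)),
    },
    "alternate": {
        1: ((160, 9), (160, 1), (160, 5), (256, 8)),
        2: ((128, 11), (256, 1)),
        3: ((180, 9), (256, 8)),
    },
}


@dataclass(frozen=True)
class ConvLayerSpec:
    """One valid (stride-1, unpadded) conv layer followed by ReLU + max-pool."""

    in_channels: int
    out_channels: int
    kernel: int
    pool: int = 2

    def __post_init__(self):
        if min(self.in_channels, self.out_channels, self.kernel, self.pool) < 1:
            raise ValueError("conv layer sizes must be positive")


@dataclass(frozen=True)
class ConvBlockSpec:
    name: str
    layers: tuple[ConvLayerSpec, ...]
    channel_multiplier: int = 1

    def __post_init__(self):
        if not self.layers:
            raise ValueError(f"{self.name}: block needs at least one layer")
        for a, b in zip(self.layers[:-1], self.layers[1:]):
            if a.out_channels != b.in_channels:
                raise ValueError(f"{self.name}: channel chain broken "
                                 f"({a.out_channels} -> {b.in_channels})")


def default_conv_block(block_id: int, in_channels: int,
                       channel_multiplier: int = 1, pool: int = 2,
                       reading: str = "default") -> ConvBlockSpec:
    """The published structure of ConvBlock1/2/3 (channels optionally widened)."""
    try:
        pairs = _BLOCK_PRESETS[reading][block_id]
    except KeyError:
        raise ValueError(f"unknown block {block_id} or reading {reading!r}") from None
    layers = []
    c_in = in_channels
    for c_out, kernel in pairs:
        c_out *= channel_multiplier
        layers.append(ConvLayerSpec(c_in, c_out, kernel, pool))
        c_in = c_out
    return ConvBlockSpec(name=f"ConvBlock{block_id}", layers=tuple(layers),
                         channel_multiplier=channel_multiplier)


@dataclass(frozen=True)
class ModelConfig:
    """Complete architectural description; every ablation is a field setting."""

    conv_blocks: tuple[int, ...] = (1, 2, 3)
    channel_multiplier: int = 1
    pool_width: int = 2
    conv_reading: str = "default"
    use_bilstm: bool = True
    bilstm_hidden: int = 128
    bilstm_combine: str = "concat"
    bilstm_peephole: bool = True
    residual: bool = True
    head: str = "kan"
    fusion_dim: int = 128
    kan_hidden: int = 32
    kan_grid_size: int = 5
    kan_degree: int = 3
    kan_use_base: bool = True
    dropout_rate: float = 0.3
    norm: str = "layer_norm"
    kmer_size: int = 3
    stride: int = 1
    embedding_dim: int = 100
    embedding_mode: str = "pretrained"  # 'pretrained' (frozen) | 'trainable'
    sequence_length: int = 200

    def __post_init__(self):
        if not self.conv_blocks:
            raise ValueError("at least one conv block must be enabled")
        if self.head not in ("kan", "mlp"):
            raise ValueError(f"head must be 'kan' or 'mlp', got {self.head!r}")
        if self.norm not in ("layer_norm", "none"):
            raise ValueError(f"norm must be 'layer_norm' or 'none'")
        if self.embedding_mode not in ("pretrained", "trainable"):
            raise ValueError("embedding_mode must be 'pretrained' or 'trainable'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def tokens_per_sequence(self) -> int:
        return token_count(self.sequence_length,
                           TokenizerSpec(self.kmer_size, self.stride))

    def block_specs(self) -> list[ConvBlockSpec]:
        return [default_conv_block(b, self.embedding_dim,
                                   self.channel_multiplier, self.pool_width,
                                   self.conv_reading)
                for b in self.conv_blocks]


def trace_conv_shapes(spec: ConvBlockSpec, length: int) -> list[dict]:
    """Symbolic length trace through a block; errors name the failing layer.

    Each entry records the length before the layer, after the valid
    convolution (L - K + 1) and after pooling (floor division).
    """
    trace = []
    L = length
    for i, layer in enumerate(spec.layers):
        l_conv = L - layer.kernel + 1
        if l_conv < 1:
            raise ValueError(
                f"{spec.name} layer {i} (kernel {layer.kernel}): input length "
                f"{L} too short")
        l_pool = l_conv // layer.pool
        if l_pool < 1:
            raise ValueError(
                f"{spec.name} layer {i} (pool {layer.pool}): pooled length 0")
        trace.append({"layer": i, "in": L, "conv": l_conv, "pool": l_pool,
                      "channels": layer.out_channels})
        L = l_pool
    return trace


def _block_output_dim(spec: ConvBlockSpec, length: int) -> int:
    trace = trace_conv_shapes(spec, length)
    return trace[-1]["pool"] * trace[-1]["channels"]


class _ConvBlock(nn.Module):
    def __init__(self, spec: ConvBlockSpec, rng, dtype):
        super().__init__()
        self.spec = spec
        self.convs = [nn.Conv1d(l.in_channels, l.out_channels, l.kernel, rng, dtype)
                      for l in spec.layers]
        self.pools = [nn.MaxPool1d(l.pool) for l in spec.layers]

    def forward(self, x: Tensor) -> Tensor:
        for conv, pool in zip(self.convs, self.pools):
            x = pool(relu(conv(x)))
        return x


class BindingSiteNetwork(nn.Module):
    """End-to-end differentiable network: token indices -> binding logit."""

    def __init__(self, config: ModelConfig, embedding_matrix: np.ndarray,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.config = config
        T = config.tokens_per_sequence
        k = config.embedding_dim
        if embedding_matrix.shape[1] != k:
            raise ValueError(
                f"embedding matrix dim {embedding_matrix.shape[1]} != {k}")
        self.embedding = nn.Embedding(embedding_matrix.astype(dtype),
                                      trainable=config.embedding_mode == "trainable")
        self.blocks = [_ConvBlock(s, rng, dtype) for s in config.block_specs()]
        cnn_dim = sum(_block_output_dim(s, T) for s in config.block_specs())
        self.cnn_dim = cnn_dim
        D = config.fusion_dim
        if config.use_bilstm:
            self.bilstm = nn.BiLSTM(k, config.bilstm_hidden, rng,
                                    combine=config.bilstm_combine,
                                    peephole=config.bilstm_peephole, dtype=dtype)
            lstm_dim = (2 * config.bilstm_hidden
                        if config.bilstm_combine == "concat"
                        else config.bilstm_hidden)
            if config.residual:
                self.proj_cnn = nn.Linear(cnn_dim, D, rng, dtype)
                self.proj_lstm = nn.Linear(lstm_dim, D, rng, dtype)
            else:
                self.proj_cat = nn.Linear(cnn_dim + lstm_dim, D, rng, dtype)
        else:
            self.proj_cnn = nn.Linear(cnn_dim, D, rng, dtype)
        if config.norm == "layer_norm":
            # gain 0.5 keeps the normalized fused features (~N(0, 0.25))
            # almost entirely inside the spline grid's [-1, 1] domain
            self.norm = nn.LayerNorm(D, dtype, gain=0.5)
        else:
            self.norm = None
        self.dropout = nn.Dropout(config.dropout_rate,
                                  seed=int(rng.integers(2 ** 31)))
        grid = SplineGrid(intervals=config.kan_grid_size,
                          degree=config.kan_degree)
        widths = [D, config.kan_hidden, 1]
        if config.head == "kan":
            self.head = KAN(widths, rng, grid=grid,
                            use_base=config.kan_use_base, dtype=dtype)
        else:
            self.head = _MLPHead(widths, rng, dtype)

    def forward(self, idx: np.ndarray) -> Tensor:
        emb = self.embedding(idx)                      # (N, T, k): channels last
        feats = [self._flatten(block(emb)) for block in self.blocks]
        cnn = concat(feats, axis=1) if len(feats) > 1 else feats[0]
        if self.config.use_bilstm:
            lstm_feat = self.bilstm(emb)
            if self.config.residual:
                fused = self.proj_cnn(cnn) + self.proj_lstm(lstm_feat)
            else:
                fused = self.proj_cat(concat([cnn, lstm_feat], axis=1))
        else:
            fused = self.proj_cnn(cnn)
        if self.norm is not None:
            fused = self.norm(fused)
        fused = self.dropout(fused)
        logit = self.head(fused)                       # (N, 1)
        return logit.reshape(-1)

    @staticmethod
    def _flatten(x: Tensor) -> Tensor:
        n, L, c = x.shape
        return x.reshape(n, L * c)

    def predict_proba(self, idx: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Sigmoid binding probabilities in eval mode, batched."""
        was_training = self.training
        self.eval()
        try:
            out = []
            for start in range(0, idx.shape[0], batch_size):
                logits = self.forward(idx[start:start + batch_size]).data
                out.append(1.0 / (1.0 + np.exp(-logits.astype(np.float64))))
            return np.concatenate(out)
        finally:
            self.train(was_training)


class _MLPHead(nn.Module):
    """ReLU MLP of the same widths as the KAN head (the head ablation)."""

    def __init__(self, widths: list[int], rng, dtype):
        super().__init__()
        self.linears = [nn.Linear(a, b, rng, dtype)
                        for a, b in zip(widths[:-1], widths[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for lin in self.linears[:-1]:
            x = relu(lin(x))
        return self.linears[-1](x)


def build_model(config: ModelConfig, seed: int,
                table: EmbeddingTable | None = None,
                dtype=np.float32) -> BindingSiteNetwork:
    """Build a network from its config, reproducibly under ``seed``.

    ``table`` supplies pretrained k-mer vectors; when absent, or when the
    config asks for trainable embeddings, a seeded random fallback table
    over the full k-mer vocabulary is used instead.
    """
    rng = np.random.default_rng(seed)
    vocab = kmer_vocabulary(config.kmer_size)
    if table is None or config.embedding_mode == "trainable":
        table = make_fallback_table(config.kmer_size, config.embedding_dim,
                                    seed=seed)
    matrix = table_to_matrix(table, vocab, dtype=dtype)
    return BindingSiteNetwork(config, matrix, rng, dtype=dtype)


def parameter_count(model: nn.Module) -> int:
    """Total trainable scalar parameters (frozen tables contribute zero)."""
    return model.num_parameters()


def save_checkpoint(model: BindingSiteNetwork, path: str | Path,
                    extra: dict | None = None) -> None:
    """Self-describing checkpoint: config + all weights (incl. frozen table)."""
    meta = {"config": asdict(model.config), "extra": extra or {}}
    np.savez_compressed(
        path,
        __meta__=np.array(json.dumps(meta)),
        __embedding__=model.embedding.weight.data,
        **{f"param:{k}": v for k, v in model.state_dict().items()})


def load_checkpoint(path: str | Path) -> tuple[BindingSiteNetwork, dict]:
    """Rebuild a network from a checkpoint; returns (model, extra metadata)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg = meta["config"]
        cfg["conv_blocks"] = tuple(cfg["conv_blocks"])
        config = ModelConfig(**cfg)
        model = build_model(config, seed=0)
        model.embedding.weight.data = z["__embedding__"].copy()
        state = {k[len("param:"):]: z[k] for k in z.files
                 if k.startswith("param:")}
        model.load_state_dict(state)
    model.eval()
    return model, meta["extra"]


# -- ablation matrix ----------------------------------------------------------

ABLATION_VARIANT_NAMES = (
    "C-KAN(dna2vec)(ConvBlock3)",
    "C-KAN(dna2vec)(ConvBlock1)",
    "C-KAN(dna2vec)(ConvBlock2)",
    "C-KAN(dna2vec)(ConvBlock2)-kernel*2",
    "C-KAN(dna2vec)(ConvBlock2)-kernel*3",
    "C-KAN(dna2vec)C(ConvBlock1/2/3)",
    "C-KAN(Non-dna2vec)C(ConvBlock1/2/3)",
    "CB-KAN(dna2vec)C(ConvBlock1/2/3)(Non-Residual)",
    "CBR-MLP(dna2vec)C(ConvBlock1/2/3)(Residual)",
    "CBR-KAN(dna2vec)C(ConvBlock1/2/3)(Residual)",
)


def ablation_variant_configs(base: ModelConfig | None = None) -> dict[str, ModelConfig]:
    """The full ablation matrix as config settings on a shared base.

    'dna2vec' rows use whatever pretrained (frozen) embedding table the run
    supplies; the 'Non-dna2vec' row trains its embedding from random
    initialization instead.
    """
    b = base if base is not None else ModelConfig()
    c_kan = replace(b, use_bilstm=False, residual=False)
    return {
        "C-KAN(dna2vec)(ConvBlock3)": replace(c_kan, conv_blocks=(3,)),
        "C-KAN(dna2vec)(ConvBlock1)": replace(c_kan, conv_blocks=(1,)),
        "C-KAN(dna2vec)(ConvBlock2)": replace(c_kan, conv_blocks=(2,)),
        "C-KAN(dna2vec)(ConvBlock2)-kernel*2":
            replace(c_kan, conv_blocks=(2,), channel_multiplier=2),
        "C-KAN(dna2vec)(ConvBlock2)-kernel*3":
            replace(c_kan, conv_blocks=(2,), channel_multiplier=3),
        "C-KAN(dna2vec)C(ConvBlock1/2/3)": c_kan,
        "C-KAN(Non-dna2vec)C(ConvBlock1/2/3)":
            replace(c_kan, embedding_mode="trainable"),
        "CB-KAN(dna2vec)C(ConvBlock1/2/3)(Non-Residual)":
            replace(b, residual=False),
        "CBR-MLP(dna2vec)C(ConvBlock1/2/3)(Residual)":
            replace(b, head="mlp"),
        "CBR-KAN(dna2vec)C(ConvBlock1/2/3)(Residual)": b,
    }
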