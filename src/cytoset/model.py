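"""Permutation-invariant set transformer for cytometry samples.

The encoder is a stack of Pre-LN self-attention blocks over cells — no
positional encoding, since a sample is an unordered set — so its output is
permutation-equivariant.  The decoder pools the encoded cells through
iterative cross-attention: a single task-specific learnable query token
attends over all cell latents in each of its blocks, and the token's final
state feeds a feed-forward prediction head.  The prediction is therefore
permutation-invariant, and the softmax cross-attention weights (one per
cell, per head, per layer) provide per-cell importance for interpretation.

Three heteroscedastic pretraining heads map each cell latent to a mean and
a strictly positive variance for every vocabulary marker slot (expression,
percentile, density), parameterised as log-variance with a positive floor.
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Parameter, Tensor, collect_parameters, layer_norm, softmax
from .core import CytometrySample, MarkerVocabulary
from .embedding import LearnableMaskBank, Projection, embed_sample

__all__ = ["ModelConfig", "EncoderOutput", "PretrainHeadOutput", "AttentionMap",
           "CytoTransformer"]

VARIANCE_FLOOR = 1e-6


@dataclass
class ModelConfig:
    hidden_size: int = 128
    encoder_layers: int = 4     # 0 = decoder-only (pool raw cell embeddings)
    decoder_layers: int = 4
    heads: int = 4
    feedforward_multiplier: int = 4
    dropout: float = 0.0
    projection_depth: int = 1

    def __post_init__(self):
        if self.hidden_size % self.heads != 0:
            raise ValueError("hidden_size must be divisible by heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class EncoderOutput:
    latent: Tensor  # n x h, order-aligned with the input cells

    @property
    def n_cells(self) -> int:
        return self.latent.shape[0]


@dataclass
class PretrainHeadOutput:
    expr_mean: Tensor
    expr_var: Tensor
    pct_mean: Tensor
    pct_var: Tensor
    dens_mean: Tensor
    dens_var: Tensor
    clamped_entries: int = 0  # variance outputs lifted to the floor


@dataclass
class AttentionMap:
    """Cross-attention of the prediction token over cells.

    ``weights`` has shape (decoder_layers, heads, n); every (layer, head)
    row sums to one.  ``per_layer_mean`` averages over heads and therefore
    also sums to one per layer.
    """

    weights: np.ndarray

    @property
    def per_layer_mean(self) -> np.ndarray:
        return self.weights.mean(axis=1)

    @property
    def n_layers(self) -> int:
        return self.weights.shape[0]


def _check_finite(x: Tensor, where: str) -> Tensor:
    if not np.all(np.isfinite(x.data)):
        raise FloatingPointError(f"non-finite activations in {where}")
    return x


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 scale: float | None = None):
        scale = scale if scale is not None else (2.0 / (in_dim + out_dim)) ** 0.5
        self.w = Parameter(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.b = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm:
    def __init__(self, dim: int):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias)


class MultiHeadAttention:
    """Scaled dot-product attention; query and key/value sets may differ."""

    def __init__(self, hidden: int, heads: int, rng: np.random.Generator):
        self.hidden, self.heads = hidden, heads
        self.head_dim = hidden // heads
        self.wq = Linear(hidden, hidden, rng)
        self.wk = Linear(hidden, hidden, rng)
        self.wv = Linear(hidden, hidden, rng)
        self.wo = Linear(hidden, hidden, rng)
        self.last_weights: np.ndarray | None = None  # (heads, n_q, n_kv), post-softmax

    def _split(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        return x.reshape(n, self.heads, self.head_dim).transpose(1, 0, 2)

    def __call__(self, query: Tensor, keyvalue: Tensor) -> Tensor:
        q = self._split(self.wq(query))          # (H, n_q, d)
        k = self._split(self.wk(keyvalue))       # (H, n, d)
        v = self._split(self.wv(keyvalue))
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)          # (H, n_q, n)
        self.last_weights = attn.data.copy()
        ctx = attn @ v                           # (H, n_q, d)
        n_q = query.shape[0]
        merged = ctx.transpose(1, 0, 2).reshape(n_q, self.hidden)
        return self.wo(merged)


class FeedForward:
    def __init__(self, hidden: int, multiplier: int, rng: np.random.Generator):
        self.fc1 = Linear(hidden, hidden * multiplier, rng)
        self.fc2 = Linear(hidden * multiplier, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class EncoderBlock:
    """Pre-LN: x + Attn(LN(x)) then x + FFN(LN(x))."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.ln1 = LayerNorm(cfg.hidden_size)
        self.attn = MultiHeadAttention(cfg.hidden_size, cfg.heads, rng)
        self.ln2 = LayerNorm(cfg.hidden_size)
        self.ffn = FeedForward(cfg.hidden_size, cfg.feedforward_multiplier, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h)
        x = x + self.ffn(self.ln2(x))
        return x


class DecoderBlock:
    """Cross-attention + feed-forward, Pre-LN.  With a single query token,
    query self-attention would be vacuous and is omitted."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.ln_q = LayerNorm(cfg.hidden_size)
        self.attn = MultiHeadAttention(cfg.hidden_size, cfg.heads, rng)
        self.ln2 = LayerNorm(cfg.hidden_size)
        self.ffn = FeedForward(cfg.hidden_size, cfg.feedforward_multiplier, rng)

    def __call__(self, q: Tensor, memory: Tensor) -> Tensor:
        q = q + self.attn(self.ln_q(q), memory)
        q = q + self.ffn(self.ln2(q))
        return q


class PretrainHead:
    """Position-wise head emitting a mean and a log-variance per vocab slot."""

    def __init__(self, hidden: int, vocab_size: int, rng: np.random.Generator):
        self.fc = Linear(hidden, hidden, rng)
        self.mean = Linear(hidden, vocab_size, rng)
        self.logvar = Linear(hidden, vocab_size, rng)

    def __call__(self, z: Tensor) -> tuple[Tensor, Tensor, int]:
        h = self.fc(z).gelu()
        mean = self.mean(h)
        raw_var = self.logvar(h).exp()
        clamped = int(np.count_nonzero(raw_var.data < VARIANCE_FLOOR))
        return mean, raw_var.clip_min(VARIANCE_FLOOR), clamped


class CytoTransformer:
    """Full encoder-decoder model over a fixed marker vocabulary.

    ``n_outputs`` sets the downstream head width: the number of classes
    for classification, 1 for regression.
    """

    def __init__(self, vocabulary: MarkerVocabulary, config: ModelConfig,
                 n_outputs: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.vocabulary = vocabulary
        self.config = config
        self.n_outputs = n_outputs
        self.seed = seed
        h = config.hidden_size
        self.mask_bank = LearnableMaskBank(vocabulary)
        self.projection = Projection(2 * vocabulary.size, h, rng,
                                     depth=config.projection_depth)
        self.encoder_blocks = [EncoderBlock(config, rng) for _ in range(config.encoder_layers)]
        self.encoder_norm = LayerNorm(h)
        self.heads = {
            "expression": PretrainHead(h, vocabulary.size, rng),
            "percentile": PretrainHead(h, vocabulary.size, rng),
            "density": PretrainHead(h, vocabulary.size, rng),
        }
        self.query_token = Parameter(rng.normal(0.0, 0.02, size=(1, h)))
        self.decoder_blocks = [DecoderBlock(config, rng) for _ in range(config.decoder_layers)]
        self.decoder_norm = LayerNorm(h)
        self.task_head = Linear(h, n_outputs, rng)
        # fixed affine standardisation of cell latents entering the decoder,
        # set from corpus statistics at the start of downstream training
        # (identity until then); conditions the pooling optimisation
        self.latent_mu = np.zeros(h)
        self.latent_sd = np.ones(h)

    # -- forward passes ----------------------------------------------------
    def embed(self, sample: CytometrySample, per_cell_mask=None) -> Tensor:
        aug = embed_sample(sample, self.vocabulary, self.mask_bank, per_cell_mask)
        return self.projection(aug)

    def encode_cells(self, cells: Tensor) -> EncoderOutput:
        x = cells
        for i, block in enumerate(self.encoder_blocks):
            x = _check_finite(block(x), f"encoder block {i}")
        if self.encoder_blocks:
            x = self.encoder_norm(x)
        return EncoderOutput(latent=x)

    def encode(self, sample: CytometrySample, per_cell_mask=None) -> EncoderOutput:
        return self.encode_cells(self.embed(sample, per_cell_mask))

    def pretrain_heads(self, latent: EncoderOutput) -> PretrainHeadOutput:
        em, ev, c1 = self.heads["expression"](latent.latent)
        pm, pv, c2 = self.heads["percentile"](latent.latent)
        dm, dv, c3 = self.heads["density"](latent.latent)
        return PretrainHeadOutput(em, ev, pm, pv, dm, dv, clamped_entries=c1 + c2 + c3)

    def decode_predict(self, latent: EncoderOutput) -> tuple[Tensor, AttentionMap]:
        """Pool cells into a prediction via iterative cross-attention.

        Returns raw scores (logits for classification, a scalar for
        regression) and the per-layer, per-head attention over cells.
        """
        memory = (latent.latent - Tensor(self.latent_mu)) * Tensor(1.0 / self.latent_sd)
        q = self.query_token
        weights = []
        for i, block in enumerate(self.decoder_blocks):
            q = _check_finite(block(q, memory), f"decoder block {i}")
            weights.append(block.attn.last_weights[:, 0, :])  # (heads, n)
        q = self.decoder_norm(q)
        scores = self.task_head(q).reshape(self.n_outputs)
        return scores, AttentionMap(np.stack(weights, axis=0))

    def forward(self, sample: CytometrySample, per_cell_mask=None) -> tuple[Tensor, AttentionMap]:
        return self.decode_predict(self.encode(sample, per_cell_mask))

    # -- parameter groups --------------------------------------------------
    def encoder_parameters(self) -> list[Parameter]:
        """Embedding (mask bank + projection) and encoder stack parameters."""
        return collect_parameters([self.mask_bank, self.projection,
                                   self.encoder_blocks, self.encoder_norm])

    def pretrain_parameters(self) -> list[Parameter]:
        return self.encoder_parameters() + collect_parameters(list(self.heads.values()))

    def decoder_parameters(self) -> list[Parameter]:
        return collect_parameters([self.query_token, self.decoder_blocks,
                                   self.decoder_norm, self.task_head])

    def parameters(self) -> list[Parameter]:
        return self.pretrain_parameters() + self.decoder_parameters()

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "format_version": 1,
            "vocabulary": list(self.vocabulary.markers),
            "config": asdict(self.config),
            "n_outputs": self.n_outputs,
            "seed": self.seed,
        }
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        arrays["latent_mu"] = self.latent_mu
        arrays["latent_sd"] = self.latent_sd
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=1))
            import io as _io
            buf = _io.BytesIO()
            np.savez(buf, **arrays)
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "CytoTransformer":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            import io as _io
            z = np.load(_io.BytesIO(zf.read("params.npz")))
            model = cls(MarkerVocabulary(meta["vocabulary"]),
                        ModelConfig(**meta["config"]),
                        n_outputs=meta["n_outputs"], seed=meta["seed"])
            for i, p in enumerate(model.parameters()):
                arr = z[f"param_{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError("checkpoint does not match model architecture")
                p.data = arr.astype(np.float64)
            model.latent_mu = z["latent_mu"].astype(np.float64)
            model.latent_sd = z["latent_sd"].astype(np.float64)
        return model
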