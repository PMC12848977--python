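"""Decoder-only transformer over SELFIES tokens.

GPT-2-style pre-norm blocks (multi-head causal self-attention + 4x-expanded
feed-forward), learned absolute positional embeddings, and a logit space
padded to a power of two (default 512): ids at or beyond the vocabulary size
are unused slots hard-masked to -inf, as is [PAD], so they carry exactly zero
probability mass.  Two attention masks keep the model honest: a look-ahead
mask (no attending to future positions) and a padding mask (pad positions are
invisible as keys, so their content cannot influence chemical positions).

Sampling is autoregressive multinomial sampling with three control-token
rules: [PAD] and [SOS] are never admissible continuations, and [EOS] is
masked until at least one atom token has been emitted, so every sample
derives a non-empty molecule — which, through the SELFIES grammar, makes
generation 100% valid by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import codec
from .autograd import Parameter, Tensor
from .codec import Vocabulary

__all__ = [
    "ModelConfig",
    "GenerationSettings",
    "CausalLM",
    "count_core_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "CheckpointError",
]

NEG_INF = np.float32(-1e9)  # additive-mask -inf surrogate, exact zeros after softmax

PRESETS = {
    "M": (24, 1024, 16),
    "L": (36, 1280, 20),
    "XL": (48, 1600, 25),
    "tiny": (2, 64, 4),
}


class CheckpointError(RuntimeError):
    """Checkpoint/vocabulary incompatibility."""


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int
    d_model: int
    n_heads: int
    padded_vocab: int = 512
    max_len: int = 82
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    @classmethod
    def from_preset(cls, name: str, padded_vocab: int = 512,
                    max_len: int = 82) -> "ModelConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        n_layers, d_model, n_heads = PRESETS[name]
        return cls(n_layers=n_layers, d_model=d_model, n_heads=n_heads,
                   padded_vocab=padded_vocab, max_len=max_len, preset=name)


@dataclass(frozen=True)
class GenerationSettings:
    batch_size: int = 256
    temperature: float = 1.0
    seed: int = 0
    max_new_tokens: int | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def count_core_parameters(config: ModelConfig) -> int:
    """Weights of the attention and feed-forward projections: 12*d_model^2 per block.

    Per block: four d x d attention projections (Q, K, V, output) plus the
    d x 4d and 4d x d feed-forward matrices.  Embeddings, biases, norms and
    the output head are excluded; ``CausalLM.count_total_parameters`` adds them.
    """
    return 12 * config.d_model ** 2 * config.n_layers


class CausalLM:
    """The SELFIES-token causal language model."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary, seed: int = 0):
        if vocab.padded_size != config.padded_vocab:
            raise ValueError("vocabulary padded_size differs from config.padded_vocab")
        self.config = config
        self.vocab = vocab
        self.params: dict[str, Parameter] = {}
        self._init_params(seed)
        # Class mask over the padded logit space: [PAD] and unused slots -> -inf.
        mask = np.zeros(config.padded_vocab, dtype=np.float32)
        mask[vocab.pad_id] = NEG_INF
        mask[len(vocab):] = NEG_INF
        self.class_mask = mask
        self._atom_token = np.array(
            [vocab.is_atom_token(i) for i in range(len(vocab))]
            + [False] * (config.padded_vocab - len(vocab)))

    # -- parameters ----------------------------------------------------------

    def _init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        c = self.config
        std = 0.02
        res_std = std / np.sqrt(2 * c.n_layers)

        def P(name, arr):
            self.params[name] = Parameter(arr.astype(np.float32))

        P("tok_emb", rng.normal(0, std, (c.padded_vocab, c.d_model)))
        P("pos_emb", rng.normal(0, std, (c.max_len, c.d_model)))
        for i in range(c.n_layers):
            for nm in ("q", "k", "v"):
                P(f"b{i}.W{nm}", rng.normal(0, std, (c.d_model, c.d_model)))
                P(f"b{i}.b{nm}", np.zeros(c.d_model))
            P(f"b{i}.Wo", rng.normal(0, res_std, (c.d_model, c.d_model)))
            P(f"b{i}.bo", np.zeros(c.d_model))
            P(f"b{i}.Wfc", rng.normal(0, std, (c.d_model, 4 * c.d_model)))
            P(f"b{i}.bfc", np.zeros(4 * c.d_model))
            P(f"b{i}.Wproj", rng.normal(0, res_std, (4 * c.d_model, c.d_model)))
            P(f"b{i}.bproj", np.zeros(c.d_model))
            P(f"b{i}.ln1_g", np.ones(c.d_model))
            P(f"b{i}.ln1_b", np.zeros(c.d_model))
            P(f"b{i}.ln2_g", np.ones(c.d_model))
            P(f"b{i}.ln2_b", np.zeros(c.d_model))
        P("lnf_g", np.ones(c.d_model))
        P("lnf_b", np.zeros(c.d_model))
        P("Whead", rng.normal(0, std, (c.d_model, c.padded_vocab)))
        P("bhead", np.zeros(c.padded_vocab))

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def core_parameter_arrays(self) -> list[np.ndarray]:
        """The projection matrices counted by :func:`count_core_parameters`."""
        out = []
        for i in range(self.config.n_layers):
            for nm in ("Wq", "Wk", "Wv", "Wo", "Wfc", "Wproj"):
                out.append(self.params[f"b{i}.{nm}"].data)
        return out

    def count_total_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward -------------------------------------------------------------

    def forward(self, ids: np.ndarray,
                lengths: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
        """Run the transformer; returns (raw logits (B,T,V), final hidden (B,T,d)).

        ``lengths`` gives the true (unpadded) length of each row; positions at
        or beyond it are invisible as attention keys.  When omitted, pad
        positions are inferred as ``ids == pad_id``.
        """
        ids = np.atleast_2d(np.asarray(ids, dtype=np.int64))
        B, T = ids.shape
        c = self.config
        if T > c.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {c.max_len}")
        if lengths is None:
            key_visible = ids != self.vocab.pad_id
        else:
            key_visible = np.arange(T)[None, :] < np.asarray(lengths)[:, None]
        pad_mask = np.where(key_visible, 0.0, NEG_INF).astype(np.float32)
        causal = np.triu(np.full((T, T), NEG_INF, dtype=np.float32), k=1)
        att_mask = causal[None, None, :, :] + pad_mask[:, None, None, :]

        p = self.params
        x = p["tok_emb"].gather_rows(ids) + p["pos_emb"].gather_rows(np.arange(T))
        H, hd = c.n_heads, c.d_model // c.n_heads
        for i in range(c.n_layers):
            h = x.layer_norm(p[f"b{i}.ln1_g"], p[f"b{i}.ln1_b"])

            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, T, H, hd).transpose(0, 2, 1, 3)

            q = heads(h @ p[f"b{i}.Wq"] + p[f"b{i}.bq"])
            k = heads(h @ p[f"b{i}.Wk"] + p[f"b{i}.bk"])
            v = heads(h @ p[f"b{i}.Wv"] + p[f"b{i}.bv"])
            att = (q @ k.transpose(0, 1, 3, 2)) * np.float32(1.0 / np.sqrt(hd))
            att = att.softmax(mask=att_mask)
            y = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, c.d_model)
            x = x + (y @ p[f"b{i}.Wo"] + p[f"b{i}.bo"])
            h = x.layer_norm(p[f"b{i}.ln2_g"], p[f"b{i}.ln2_b"])
            x = x + ((h @ p[f"b{i}.Wfc"] + p[f"b{i}.bfc"]).gelu()
                     @ p[f"b{i}.Wproj"] + p[f"b{i}.bproj"])
        hidden = x.layer_norm(p["lnf_g"], p["lnf_b"])
        logits = hidden @ p["Whead"] + p["bhead"]
        return logits, hidden

    def masked_log_probs(self, ids: np.ndarray,
                         lengths: np.ndarray | None = None) -> Tensor:
        """Log next-token distributions (B,T,V) with control-slot masking applied."""
        logits, _ = self.forward(ids, lengths)
        return logits.log_softmax(mask=self.class_mask)

    def next_token_distribution(self, prefix: Sequence[int],
                                lengths: np.ndarray | None = None) -> np.ndarray:
        """Probability vector over the padded vocabulary after ``prefix``.

        [PAD] and unused padded slots carry exactly zero mass; the vector sums
        to 1.  The prefix must start with [SOS] and leave room for one more
        token.
        """
        prefix = np.asarray(prefix)
        row = prefix if prefix.ndim == 1 else prefix[0]
        if row.size == 0 or int(row[0]) != self.vocab.sos_id:
            raise ValueError("prefix must be non-empty and start with [SOS]")
        if row.size > self.config.max_len - 1:
            raise ValueError(
                f"prefix length {row.size} exceeds max_len-1 = {self.config.max_len - 1}")
        logp = self.masked_log_probs(prefix, lengths)
        probs = np.exp(logp.data[..., -1, :])
        return probs[0] if probs.ndim == 2 and prefix.ndim == 1 else probs

    # -- sampling ------------------------------------------------------------

    def _forward_cached(self, ids_new: np.ndarray, pos_start: int,
                        caches: list[dict]) -> np.ndarray:
        """Incremental no-grad forward with per-layer key/value caches.

        Mirrors :meth:`forward` exactly but in plain NumPy, processing only
        ``ids_new`` (B, t) and attending to all cached positions.  Sampled
        sequences contain no [PAD] before termination, so no padding mask is
        needed here.
        """
        p = {k: t.data for k, t in self.params.items()}
        c = self.config
        B, t_new = ids_new.shape
        H, hd = c.n_heads, c.d_model // c.n_heads

        def ln(x, g, b):
            mu = x.mean(axis=-1, keepdims=True)
            var = x.var(axis=-1, keepdims=True)
            return (x - mu) / np.sqrt(var + 1e-5) * g + b

        def gelu(x):
            cst = np.float32(np.sqrt(2.0 / np.pi))
            return 0.5 * x * (1.0 + np.tanh(cst * (x + 0.044715 * x ** 3)))

        x = p["tok_emb"][ids_new] + p["pos_emb"][pos_start:pos_start + t_new]
        if t_new > 1:
            causal = np.triu(np.full((t_new, t_new), NEG_INF, dtype=np.float32), k=1)
            mask = np.concatenate(
                [np.zeros((t_new, pos_start), dtype=np.float32), causal], axis=1)
        else:
            mask = None
        for i, cache in enumerate(caches):
            h = ln(x, p[f"b{i}.ln1_g"], p[f"b{i}.ln1_b"])

            def heads(t):
                return t.reshape(B, t_new, H, hd).transpose(0, 2, 1, 3)

            q = heads(h @ p[f"b{i}.Wq"] + p[f"b{i}.bq"])
            k = heads(h @ p[f"b{i}.Wk"] + p[f"b{i}.bk"])
            v = heads(h @ p[f"b{i}.Wv"] + p[f"b{i}.bv"])
            cache["k"] = k if cache["k"] is None else np.concatenate(
                [cache["k"], k], axis=2)
            cache["v"] = v if cache["v"] is None else np.concatenate(
                [cache["v"], v], axis=2)
            att = q @ cache["k"].swapaxes(2, 3) * np.float32(1.0 / np.sqrt(hd))
            if mask is not None:
                att = att + mask[None, None]
            att = att - att.max(axis=-1, keepdims=True)
            att = np.exp(att)
            att /= att.sum(axis=-1, keepdims=True)
            y = (att @ cache["v"]).transpose(0, 2, 1, 3).reshape(B, t_new, c.d_model)
            x = x + y @ p[f"b{i}.Wo"] + p[f"b{i}.bo"]
            h = ln(x, p[f"b{i}.ln2_g"], p[f"b{i}.ln2_b"])
            x = x + gelu(h @ p[f"b{i}.Wfc"] + p[f"b{i}.bfc"]) @ p[f"b{i}.Wproj"] \
                + p[f"b{i}.bproj"]
        hidden = ln(x, p["lnf_g"], p["lnf_b"])
        return hidden @ p["Whead"] + p["bhead"]

    def sample_ids(self, batch_size: int, seed: int, temperature: float = 1.0,
                   max_new_tokens: int | None = None,
                   prefix_tokens: Sequence[str] | None = None) -> np.ndarray:
        """Autoregressively sample ``batch_size`` sequences; returns (B, L) ids.

        Sequences start with [SOS] (plus the optional priming prefix), end at
        [EOS] or at the length cap, and are right-padded with [PAD].  A fixed
        seed reproduces the identical batch.
        """
        c, vocab = self.config, self.vocab
        rng = np.random.default_rng(seed)
        start = [vocab.sos_id]
        if prefix_tokens:
            for t in prefix_tokens:
                if t not in vocab.token_to_id:
                    raise codec.VocabularyError(f"prefix token {t!r} not in vocabulary")
                start.append(vocab.token_to_id[t])
        if len(start) >= c.max_len:
            raise ValueError("priming prefix leaves no room for generation")
        limit = c.max_len - len(start)
        if max_new_tokens is not None:
            limit = min(limit, max_new_tokens)

        seqs = np.tile(np.array(start, dtype=np.int64), (batch_size, 1))
        has_atom = np.full(batch_size, any(
            vocab.is_atom_token(i) for i in start[1:]), dtype=bool)
        alive = np.ones(batch_size, dtype=bool)
        atom_ids = np.where(self._atom_token)[0]
        caches = [{"k": None, "v": None} for _ in range(c.n_layers)]
        logits = self._forward_cached(seqs, 0, caches)

        for _ in range(limit):
            z = logits[:, -1, :] / np.float32(max(temperature, 1e-8))
            z = z + self.class_mask
            z[:, vocab.sos_id] = NEG_INF
            z[~has_atom, :] = np.where(
                self._atom_token[None, :], z[~has_atom, :], NEG_INF)
            z = z - z.max(axis=-1, keepdims=True)
            probs = np.exp(z)
            probs /= probs.sum(axis=-1, keepdims=True)
            cdf = np.cumsum(probs, axis=-1)
            u = rng.random((batch_size, 1))
            nxt = (cdf < u).sum(axis=-1).astype(np.int64)
            nxt[~alive] = vocab.pad_id
            has_atom |= alive & np.isin(nxt, atom_ids)
            seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
            alive &= nxt != vocab.eos_id
            if not alive.any():
                break
            logits = self._forward_cached(nxt[:, None], seqs.shape[1] - 1, caches)
        return seqs

    def sample_batch(self, settings: GenerationSettings,
                     prefix_tokens: Sequence[str] | None = None) -> list[str]:
        """Sample a batch and decode to SMILES; 100% valid by construction."""
        ids = self.sample_ids(settings.batch_size, seed=settings.seed,
                              temperature=settings.temperature,
                              max_new_tokens=settings.max_new_tokens,
                              prefix_tokens=prefix_tokens)
        return [codec.decode_ids(row, self.vocab) for row in ids]


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(model: CausalLM, path, iteration: int = 0) -> None:
    """Write weights (npz blob) plus a plain-text sidecar (config, vocab hash)."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             **{k: p.data for k, p in model.params.items()})
    meta = {
        "config": asdict(model.config),
        "vocab_sha256": model.vocab.sha256,
        "iteration": iteration,
        "format": "smolgen-checkpoint-v1",
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_checkpoint(path, vocab: Vocabulary) -> tuple[CausalLM, int]:
    """Restore a model; refuses checkpoints written against another vocabulary."""
    path = str(path)
    with open(_sidecar(path)) as fh:
        meta = json.load(fh)
    cfg = ModelConfig(**meta["config"])
    if cfg.padded_vocab != vocab.padded_size:
        raise CheckpointError(
            f"checkpoint padded_vocab {cfg.padded_vocab} != vocabulary "
            f"padded_size {vocab.padded_size}")
    if meta["vocab_sha256"] != vocab.sha256:
        raise CheckpointError("checkpoint was written against a different vocabulary")
    model = CausalLM(cfg, vocab)
    blob = np.load(path if path.endswith(".npz") else path + ".npz")
    for k in model.params:
        model.params[k].data = blob[k].astype(np.float32)
    return model, int(meta["iteration"])


def _sidecar(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".meta.json"
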