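"""Transformer encoder over SMILES tokens with masked-language-model pretraining.

The encoder is a standard pre-norm transformer: learned token and position
embeddings, multi-head scaled-dot-product self-attention with a padding
mask, GELU feed-forward blocks, and a final layer norm. Pretraining follows
the RoBERTa recipe: a fraction of non-special positions is selected
(default 15%), of which 80% become ``[MASK]``, 10% a random token and 10%
stay unchanged; cross-entropy is computed at the selected positions only.

A molecule embedding is the hidden state at the leading CLS position by
default; masked mean pooling over real tokens is the alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor
from .tokenizer import TokenVocab, encode_batch

__all__ = [
    "EncoderConfig",
    "MaskingPolicy",
    "TransformerEncoder",
    "mask_tokens",
    "pretrain",
    "embed",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters. Hidden size 768 is the published default;
    tests use much smaller encoders — the size is configuration, never baked in."""

    n_layers: int = 4
    n_heads: int = 8
    hidden_size: int = 768
    ffn_size: int | None = None  # defaults to 4 * hidden_size
    max_len: int = 128
    vocab_size: int = 512
    dropout: float = 0.1

    def __post_init__(self):
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        for name in ("n_layers", "n_heads", "hidden_size", "max_len", "vocab_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ffn(self) -> int:
        return self.ffn_size or 4 * self.hidden_size


@dataclass
class MaskingPolicy:
    """RoBERTa-style corruption: rate of selection and mask/random/keep split."""

    mask_rate: float = 0.15
    mask_proportion: float = 0.8
    random_proportion: float = 0.1
    keep_proportion: float = 0.1
    seed: int = 0

    def __post_init__(self):
        total = self.mask_proportion + self.random_proportion + self.keep_proportion
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mask/random/keep proportions must sum to 1, got {total}")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must lie in [0, 1]")


class _EncoderLayer(nn.Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator, drop_rng: np.random.Generator):
        super().__init__()
        H = config.hidden_size
        self.n_heads = config.n_heads
        self.head_dim = H // config.n_heads
        self.ln1 = nn.LayerNorm(H)
        self.q = nn.Linear(H, H, rng)
        self.k = nn.Linear(H, H, rng)
        self.v = nn.Linear(H, H, rng)
        self.proj = nn.Linear(H, H, rng)
        self.ln2 = nn.LayerNorm(H)
        self.ff1 = nn.Linear(H, config.ffn, rng)
        self.ff2 = nn.Linear(config.ffn, H, rng)
        self.drop = nn.Dropout(config.dropout, drop_rng)

    def forward(self, x: Tensor, neg_mask: np.ndarray) -> Tensor:
        B, T, H = x.shape
        nh, hd = self.n_heads, self.head_dim
        h = self.ln1(x)
        split = lambda t: t.reshape(B, T, nh, hd).transpose(0, 2, 1, 3).reshape(B * nh, T, hd)
        q, k, v = split(self.q(h)), split(self.k(h)), split(self.v(h))
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(hd))
        scores = scores + Tensor(neg_mask)  # -inf-like on padded keys
        attn = scores.softmax(-1)
        ctx = (attn @ v).reshape(B, nh, T, hd).transpose(0, 2, 1, 3).reshape(B, T, H)
        x = x + self.drop(self.proj(ctx))
        h = self.ln2(x)
        x = x + self.drop(self.ff2(self.ff1(h).relu()))
        return x


class TransformerEncoder(nn.Module):
    """Maps (ids, attention_mask) to hidden states (B, T, H)."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)
        H = config.hidden_size
        self.tok_emb = nn.Embedding(config.vocab_size, H, rng)
        self.pos_emb = nn.Embedding(config.max_len, H, rng)
        self.emb_ln = nn.LayerNorm(H)
        self.emb_drop = nn.Dropout(config.dropout, self.drop_rng)
        for i in range(config.n_layers):
            setattr(self, f"block{i}", _EncoderLayer(config, rng, self.drop_rng))
        self.final_ln = nn.LayerNorm(H)

    def forward(self, ids: np.ndarray, attention_mask: np.ndarray) -> Tensor:
        ids = np.asarray(ids)
        attention_mask = np.asarray(attention_mask)
        B, T = ids.shape
        if T > self.config.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.config.max_len}")
        x = self.tok_emb(ids) + self.pos_emb(np.arange(T)[None, :].repeat(B, axis=0))
        x = self.emb_drop(self.emb_ln(x))
        # additive key mask, broadcast over heads: (B*nh, 1, T)
        neg = np.where(attention_mask[:, None, :] > 0, 0.0, -1e9).astype(np.float32)
        neg = np.repeat(neg, self.config.n_heads, axis=0)
        for i in range(self.config.n_layers):
            x = getattr(self, f"block{i}")(x, neg)
        return self.final_ln(x)

    def pool(self, hidden: Tensor, attention_mask: np.ndarray, pooling: str = "cls") -> Tensor:
        if pooling == "cls":
            return hidden[:, 0, :]
        if pooling == "mean":
            m = np.asarray(attention_mask, dtype=np.float32)[:, :, None]
            return (hidden * Tensor(m)).sum(axis=1) / Tensor(m.sum(axis=1))
        raise ValueError(f"unknown pooling {pooling!r}")


def mask_tokens(
    ids: np.ndarray,
    special_mask: np.ndarray,
    policy: MaskingPolicy,
    vocab: TokenVocab,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt token ids for MLM; returns (corrupted ids, target selector).

    `special_mask` is 1 at positions that must never be corrupted (PAD, CLS,
    SEP). Each remaining position is selected independently with
    ``policy.mask_rate``; selected positions get ``[MASK]`` / a random
    non-special token / the original at the policy proportions. The target
    selector is a boolean array marking selected positions; originals are
    recoverable from the input `ids`.
    """
    rng = rng or np.random.default_rng(policy.seed)
    ids = np.asarray(ids)
    eligible = np.asarray(special_mask) == 0
    selected = eligible & (rng.random(ids.shape) < policy.mask_rate)
    corrupted = ids.copy()
    u = rng.random(ids.shape)
    to_mask = selected & (u < policy.mask_proportion)
    to_random = selected & (u >= policy.mask_proportion) & (u < policy.mask_proportion + policy.random_proportion)
    corrupted[to_mask] = vocab.mask_id
    n_special = len(vocab.special_ids)
    if to_random.any():
        corrupted[to_random] = rng.integers(n_special, vocab.vocab_size, size=int(to_random.sum()))
    return corrupted, selected


def special_positions(ids: np.ndarray, vocab: TokenVocab) -> np.ndarray:
    """1 where the token is PAD/CLS/SEP/MASK/UNK-reserved, else 0."""
    return np.isin(np.asarray(ids), list(vocab.special_ids)).astype(np.int64)


def pretrain(
    corpus: list[str],
    vocab: TokenVocab,
    config: EncoderConfig,
    policy: MaskingPolicy | None = None,
    *,
    epochs: int = 3,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    seed: int = 0,
    max_len: int | None = None,
) -> tuple[TransformerEncoder, "nn.Linear", dict]:
    """MLM-pretrain an encoder on a SMILES corpus.

    Returns the encoder, the MLM output head, and a history dict with the
    per-epoch mean loss and masked-token accuracy. Loss is cross-entropy at
    masked positions only.
    """
    if vocab.vocab_size > config.vocab_size:
        raise ValueError(
            f"vocabulary ({vocab.vocab_size} tokens) exceeds encoder vocab_size {config.vocab_size}"
        )
    policy = policy or MaskingPolicy(seed=seed)
    max_len = max_len or config.max_len
    ids, attn = encode_batch(corpus, vocab, max_len)
    specials = special_positions(ids, vocab)

    encoder = TransformerEncoder(config, seed=seed)
    rng = np.random.default_rng(seed + 17)
    head = nn.Linear(config.hidden_size, config.vocab_size, rng)
    params = encoder.parameters() + head.parameters()
    opt = nn.AdamW(params, lr=learning_rate)
    mask_rng = np.random.default_rng(policy.seed + 29)

    n = len(corpus)
    history = {"loss": [], "masked_accuracy": []}
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, correct, total = [], 0, 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            bids, battn, bspec = ids[idx], attn[idx], specials[idx]
            corrupted, selected = mask_tokens(bids, bspec, policy, vocab, mask_rng)
            if not selected.any():
                continue
            hidden = encoder(corrupted, battn)
            rows, cols = np.nonzero(selected)
            picked = hidden[rows, cols]  # (M, H)
            logits = head(picked)
            targets = bids[rows, cols]
            loss = nn.softmax_cross_entropy(logits, targets)
            encoder.zero_grad()
            head.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == targets).sum())
            total += len(targets)
        history["loss"].append(float(np.mean(losses)))
        history["masked_accuracy"].append(correct / max(total, 1))
    return encoder, head, history


def masked_token_baseline(corpus: list[str], vocab: TokenVocab, max_len: int = 128) -> float:
    """Majority-class accuracy over the corpus token distribution: the score a
    predictor gets by always guessing the most frequent non-special token."""
    ids, _ = encode_batch(corpus, vocab, max_len)
    flat = ids[~np.isin(ids, list(vocab.special_ids))]
    counts = np.bincount(flat, minlength=vocab.vocab_size)
    return counts.max() / counts.sum()


def embed(
    smiles: list[str],
    encoder: TransformerEncoder,
    vocab: TokenVocab,
    pooling: str = "cls",
    max_len: int | None = None,
) -> np.ndarray:
    """One pooled H-dimensional vector per molecule (inference mode)."""
    max_len = max_len or encoder.config.max_len
    ids, attn = encode_batch(smiles, vocab, max_len)
    was_training = encoder.training
    encoder.eval()
    hidden = encoder(ids, attn)
    out = encoder.pool(hidden, attn, pooling).data.copy()
    encoder.train(was_training)
    return out


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(path: str | Path, encoder: TransformerEncoder, vocab: TokenVocab, head: nn.Linear | None = None):
    """Single .npz archive: weights + EncoderConfig JSON + vocabulary hash."""
    meta = {"config": asdict(encoder.config), "vocab_hash": vocab.content_hash()}
    arrays = {f"enc.{k}": v for k, v in encoder.state_dict().items()}
    if head is not None:
        arrays.update({f"head.{k}": v for k, v in head.state_dict().items()})
    with open(path, "wb") as fh:  # keep the exact path (savez would append .npz)
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path, vocab: TokenVocab | None = None) -> tuple[TransformerEncoder, EncoderConfig]:
    with np.load(path) as payload:
        meta = json.loads(bytes(payload["__meta__"]).decode())
        config = EncoderConfig(**meta["config"])
        if vocab is not None and vocab.content_hash() != meta["vocab_hash"]:
            raise ValueError("vocabulary hash mismatch: checkpoint was trained with a different vocab")
        encoder = TransformerEncoder(config, seed=0)
        state = {k[len("enc."):]: payload[k] for k in payload.files if k.startswith("enc.")}
        encoder.load_state_dict(state)
    return encoder, config
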