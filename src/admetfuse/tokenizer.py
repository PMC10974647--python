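"""Byte-pair-encoding tokenizer for SMILES strings.

BPE treats each SMILES as a sequence of single characters and greedily
merges the most frequent adjacent pair into a new token until the target
vocabulary size is reached. Unseen strings are still encodable: any
character outside the learned alphabet maps to ``[UNK]`` and everything
else decomposes into learned sub-strings. Multi-character atoms such as
``Cl`` are not special-cased; frequent ones are learned as merges.

Determinism: pair-frequency ties are broken by lexicographic order of the
pair, so retraining on the same corpus yields a byte-identical vocabulary.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TokenVocab", "TokenSequence", "train_bpe", "encode", "decode", "encode_batch"]

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK)


@dataclass
class TokenVocab:
    """Learned merges plus the token-to-id table.

    Ids are dense ``0..vocab_size-1`` with the five special tokens occupying
    the reserved low ids 0-4 in the order PAD, UNK, CLS, SEP, MASK.
    """

    merges: list[tuple[str, str]]
    token_to_id: dict[str, int]
    id_to_token: dict[int, str] = field(init=False, repr=False)

    def __post_init__(self):
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}
        self._ranks = {pair: i for i, pair in enumerate(self.merges)}

    @property
    def vocab_size(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(range(len(SPECIAL_TOKENS)))

    def content_hash(self) -> str:
        """Stable hash of merges+tokens, stored in checkpoints to detect mismatch."""
        import hashlib

        payload = json.dumps({"merges": self.merges, "tokens": self.token_to_id}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path: str | Path):
        payload = {
            "merges": [list(p) for p in self.merges],
            "token_to_id": self.token_to_id,
            "special_tokens": list(SPECIAL_TOKENS),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocab":
        payload = json.loads(Path(path).read_text())
        return cls(
            merges=[tuple(p) for p in payload["merges"]],
            token_to_id={k: int(v) for k, v in payload["token_to_id"].items()},
        )


@dataclass
class TokenSequence:
    """Encoded SMILES: padded ids plus the attention mask (1 = real token)."""

    ids: np.ndarray
    attention_mask: np.ndarray
    text: str

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.attention_mask = np.asarray(self.attention_mask, dtype=np.int64)


def _pair_counts(seq: list[str]) -> Counter:
    return Counter(zip(seq, seq[1:]))


def _merge_sequence(seq: list[str], pair: tuple[str, str], merged: str) -> list[str]:
    out = []
    i = 0
    n = len(seq)
    a, b = pair
    while i < n:
        if i < n - 1 and seq[i] == a and seq[i + 1] == b:
            out.append(merged)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def train_bpe(corpus: list[str], vocab_size: int = 512, min_frequency: int = 2) -> TokenVocab:
    """Learn a BPE vocabulary from a SMILES corpus.

    Merging stops when `vocab_size` tokens exist or no adjacent pair occurs
    at least `min_frequency` times. Ties on frequency go to the
    lexicographically smallest pair.
    """
    corpus = [s for s in corpus if s]
    if not corpus:
        raise ValueError("cannot train BPE on an empty corpus")
    base = sorted(set("".join(corpus)))
    n_floor = len(SPECIAL_TOKENS) + len(base)
    if vocab_size < n_floor:
        raise ValueError(f"vocab_size={vocab_size} below base alphabet + specials ({n_floor})")

    token_to_id = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
    for ch in base:
        token_to_id[ch] = len(token_to_id)

    seqs = [list(s) for s in corpus]
    counts: Counter = Counter()
    occurs: dict[tuple[str, str], set[int]] = {}
    for idx, seq in enumerate(seqs):
        for pair, c in _pair_counts(seq).items():
            counts[pair] += c
            occurs.setdefault(pair, set()).add(idx)

    merges: list[tuple[str, str]] = []
    while len(token_to_id) < vocab_size and counts:
        # max count, ties to the lexicographically smallest pair
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if counts[best] < min_frequency:
            break
        merged = best[0] + best[1]
        merges.append(best)
        token_to_id[merged] = len(token_to_id)
        for idx in list(occurs.get(best, ())):
            seq = seqs[idx]
            before = _pair_counts(seq)
            new_seq = _merge_sequence(seq, best, merged)
            after = _pair_counts(new_seq)
            seqs[idx] = new_seq
            for pair, c in (before - after).items():
                counts[pair] -= c
                if counts[pair] <= 0:
                    del counts[pair]
                    occurs.pop(pair, None)
            for pair, c in (after - before).items():
                counts[pair] += c
                occurs.setdefault(pair, set()).add(idx)
            for pair in before:
                if pair in occurs and pair not in after:
                    occurs[pair].discard(idx)

    return TokenVocab(merges=merges, token_to_id=token_to_id)


def _bpe_split(text: str, vocab: TokenVocab) -> list[str]:
    seq = list(text)
    ranks = vocab._ranks
    while len(seq) > 1:
        best_rank = None
        best_pair = None
        for pair in zip(seq, seq[1:]):
            r = ranks.get(pair)
            if r is not None and (best_rank is None or r < best_rank):
                best_rank = r
                best_pair = pair
        if best_pair is None:
            break
        seq = _merge_sequence(seq, best_pair, best_pair[0] + best_pair[1])
    return seq


def encode(smiles: str, vocab: TokenVocab, max_len: int = 128) -> TokenSequence:
    """Encode one SMILES: CLS + BPE tokens + SEP, tail-truncated, tail-padded.

    Over-length strings are truncated keeping the SEP terminator; characters
    absent from the training alphabet become UNK.
    """
    if max_len < 3:
        raise ValueError("max_len must be at least 3 (CLS + one token + SEP)")
    pieces = _bpe_split(smiles, vocab)
    ids = [vocab.token_to_id.get(tok, vocab.unk_id) for tok in pieces]
    ids = [vocab.cls_id] + ids[: max_len - 2] + [vocab.sep_id]
    mask = [1] * len(ids)
    pad = max_len - len(ids)
    ids = ids + [vocab.pad_id] * pad
    mask = mask + [0] * pad
    return TokenSequence(ids=np.array(ids), attention_mask=np.array(mask), text=smiles)


def decode(seq: TokenSequence | np.ndarray, vocab: TokenVocab) -> str:
    """Invert `encode` up to truncation: specials dropped, tokens concatenated."""
    ids = seq.ids if isinstance(seq, TokenSequence) else np.asarray(seq)
    specials = vocab.special_ids
    return "".join(vocab.id_to_token[int(i)] for i in ids if int(i) not in specials)


def encode_batch(smiles: list[str], vocab: TokenVocab, max_len: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Encode many SMILES into stacked (ids, attention_mask) int64 arrays."""
    seqs = [encode(s, vocab, max_len) for s in smiles]
    return np.stack([s.ids for s in seqs]), np.stack([s.attention_mask for s in seqs])
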