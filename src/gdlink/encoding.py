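"""BPE tokenization with character-offset alignment, and contextual encoders.

The tokenizer is a plain byte-pair-encoding learner: whitespace
pre-tokenization, character-level start symbols, greedy merges by pair
frequency. It caps the vocabulary and decomposes out-of-vocabulary words
into subword pieces instead of dropping them. Every token carries its
half-open character offsets into the original text, which is what lets
character-offset annotations meet subword models.

Two encoder kinds sit behind one contract (``encode(TokenizedDocument) ->
EncodedDocument``): a tiny trainable transformer meant for CPU-scale
training, and an adapter slot for externally supplied pretrained encoders.
All downstream modules are written and tested against the tiny encoder.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from pydantic import BaseModel

from gdlink import nn

UNK = "<unk>"


class AlignmentError(ValueError):
    """A character span cannot be mapped onto any token."""


@dataclass
class TokenizedDocument:
    """Subword tokens plus per-token character intervals (0-based half-open)."""

    doc_id: str
    tokens: list[str]
    offsets: list[tuple[int, int]]
    token_ids: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.tokens)


@dataclass
class EncodedDocument:
    """Per-token contextual vectors; ``embeddings`` is an autodiff Tensor (n, H)."""

    doc_id: str
    embeddings: nn.Tensor

    @property
    def hidden(self) -> int:
        return self.embeddings.shape[1]


class BPETokenizer:
    """Byte-pair-encoding tokenizer with offset tracking.

    Merges are learned greedily by pair frequency over a whitespace
    pre-tokenized corpus; ties break lexicographically so training is
    deterministic. Unknown characters map to a dedicated ``<unk>`` id but
    keep their offsets, so alignment never loses text.
    """

    def __init__(self, merges: list[tuple[str, str]] | None = None,
                 vocab: list[str] | None = None) -> None:
        self.merges: list[tuple[str, str]] = merges or []
        self.vocab: list[str] = vocab or [UNK]
        self._ids = {tok: i for i, tok in enumerate(self.vocab)}
        self._ranks = {pair: i for i, pair in enumerate(self.merges)}

    # -- training ----------------------------------------------------------
    @classmethod
    def train(cls, texts: list[str], vocab_size: int = 400) -> "BPETokenizer":
        words: Counter[tuple[str, ...]] = Counter()
        chars: set[str] = set()
        for text in texts:
            for w in text.split():
                words[tuple(w)] += 1
                chars.update(w)
        vocab = [UNK] + sorted(chars)
        merges: list[tuple[str, str]] = []
        seqs = dict(words)
        while len(vocab) < vocab_size:
            pairs: Counter[tuple[str, str]] = Counter()
            for seq, cnt in seqs.items():
                for a, b in zip(seq, seq[1:]):
                    pairs[(a, b)] += cnt
            if not pairs:
                break
            best_count = max(pairs.values())
            if best_count < 2:
                break
            best = min(p for p, c in pairs.items() if c == best_count)
            merges.append(best)
            vocab.append(best[0] + best[1])
            merged = {}
            for seq, cnt in seqs.items():
                out: list[str] = []
                i = 0
                while i < len(seq):
                    if i + 1 < len(seq) and (seq[i], seq[i + 1]) == best:
                        out.append(seq[i] + seq[i + 1])
                        i += 2
                    else:
                        out.append(seq[i])
                        i += 1
                merged[tuple(out)] = merged.get(tuple(out), 0) + cnt
            seqs = merged
        return cls(merges=merges, vocab=vocab)

    # -- tokenization ------------------------------------------------------
    def _encode_word(self, word: str) -> list[tuple[str, int, int]]:
        pieces = [(c, i, i + 1) for i, c in enumerate(word)]
        while len(pieces) > 1:
            best_rank, best_i = None, None
            for i in range(len(pieces) - 1):
                r = self._ranks.get((pieces[i][0], pieces[i + 1][0]))
                if r is not None and (best_rank is None or r < best_rank):
                    best_rank, best_i = r, i
            if best_i is None:
                break
            a, b = pieces[best_i], pieces[best_i + 1]
            pieces[best_i : best_i + 2] = [(a[0] + b[0], a[1], b[2])]
        return pieces

    def tokenize(self, text: str, doc_id: str = "<doc>") -> TokenizedDocument:
        tokens: list[str] = []
        offsets: list[tuple[int, int]] = []
        pos = 0
        for word in text.split():
            start = text.index(word, pos)
            for piece, rel_s, rel_e in self._encode_word(word):
                tokens.append(piece if piece in self._ids else UNK)
                offsets.append((start + rel_s, start + rel_e))
            pos = start + len(word)
        ids = [self._ids.get(t, 0) for t in tokens]
        return TokenizedDocument(doc_id=doc_id, tokens=tokens, offsets=offsets, token_ids=ids)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"vocab": self.vocab, "merges": [list(m) for m in self.merges]},
            indent=0, sort_keys=True,
        ))

    @classmethod
    def load(cls, path: str | Path) -> "BPETokenizer":
        obj = json.loads(Path(path).read_text())
        return cls(merges=[tuple(m) for m in obj["merges"]], vocab=obj["vocab"])

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)


def align_span(span: tuple[int, int], tok: TokenizedDocument) -> tuple[int, int]:
    """Minimal token interval [i, j) whose character coverage contains ``span``.

    Mention boundaries that split a subword snap outward to the covering
    piece. A span that overlaps no token at all (whitespace-only) raises
    :class:`AlignmentError`.
    """
    s, e = span
    idx = [k for k, (ts, te) in enumerate(tok.offsets) if ts < e and te > s]
    if not idx:
        raise AlignmentError(f"span [{s}, {e}) overlaps no token in {tok.doc_id!r}")
    return (idx[0], idx[-1] + 1)


class EncoderSpec(BaseModel):
    """Shape of a contextual encoder; ``kind`` selects the implementation."""

    kind: str = "tiny-trainable"  # or "pretrained-adapter"
    hidden: int = 64
    layers: int = 2
    heads: int = 2
    vocab_size: int = 400
    max_len: int = 512


class ContextualEncoder(Protocol):
    spec: EncoderSpec

    def encode(self, tok: TokenizedDocument) -> EncodedDocument: ...


class TinyEncoder(nn.Module):
    """A small trainable transformer encoder (token + position embeddings,
    pre-norm blocks, final layer norm). Trains in minutes on one CPU.

    Documents longer than ``spec.max_len`` are processed with a sliding
    window (stride = half window) and overlapping token vectors are
    mean-merged, so long inputs degrade gracefully instead of crashing.
    """

    def __init__(self, spec: EncoderSpec, seed: int = 0) -> None:
        if spec.kind != "tiny-trainable":
            raise ValueError(f"TinyEncoder cannot implement kind {spec.kind!r}")
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        self.tok_emb = nn.Embedding(rng, spec.vocab_size, spec.hidden)
        self.pos_emb = nn.Embedding(rng, spec.max_len, spec.hidden)
        self.blocks = [nn.TransformerBlock(rng, spec.hidden, spec.heads)
                       for _ in range(spec.layers)]
        self.ln = nn.LayerNorm(spec.hidden)

    def _forward(self, ids: np.ndarray) -> nn.Tensor:
        x = self.tok_emb(ids) + self.pos_emb(np.arange(len(ids)))
        for blk in self.blocks:
            x = blk(x)
        return self.ln(x)

    def encode(self, tok: TokenizedDocument) -> EncodedDocument:
        ids = np.asarray(tok.token_ids, dtype=np.intp)
        n, L = len(ids), self.spec.max_len
        if n == 0:
            return EncodedDocument(tok.doc_id, nn.Tensor(np.zeros((0, self.spec.hidden))))
        if n <= L:
            return EncodedDocument(tok.doc_id, self._forward(ids))
        # Sliding window, stride L//2, mean-merge of overlapping vectors.
        stride = L // 2
        rows: list[list[nn.Tensor]] = [[] for _ in range(n)]
        start = 0
        while start < n:
            chunk = self._forward(ids[start : start + L])
            for k in range(chunk.shape[0]):
                rows[start + k].append(chunk[k : k + 1])
            if start + L >= n:
                break
            start += stride
        merged = []
        for parts in rows:
            acc = parts[0]
            for p in parts[1:]:
                acc = acc + p
            merged.append(acc * (1.0 / len(parts)))
        return EncodedDocument(tok.doc_id, nn.concat(merged, axis=0))


class PretrainedAdapter:
    """Adapter slot for an externally supplied contextual encoder.

    The callable must map a token-id list to an (n, H) array. No pretrained
    weights ship with this package; users plug in their own model here.
    """

    def __init__(self, spec: EncoderSpec, fn: Callable[[list[int]], np.ndarray]) -> None:
        self.spec = spec
        self._fn = fn

    def encode(self, tok: TokenizedDocument) -> EncodedDocument:
        out = np.asarray(self._fn(tok.token_ids), dtype=np.float64)
        if out.shape != (tok.n, self.spec.hidden):
            raise ValueError(f"adapter returned shape {out.shape}, expected {(tok.n, self.spec.hidden)}")
        return EncodedDocument(tok.doc_id, nn.Tensor(out))


def save_checkpoint(path: str | Path, encoder: TinyEncoder, extra: dict[str, list[np.ndarray]] | None = None) -> None:
    """One .npz checkpoint with an embedded JSON EncoderSpec header."""
    arrays = {f"enc_{i}": a for i, a in enumerate(encoder.state_arrays())}
    for name, arrs in (extra or {}).items():
        for i, a in enumerate(arrs):
            arrays[f"{name}_{i}"] = a
    np.savez(path, spec=json.dumps(encoder.spec.model_dump(), sort_keys=True), **arrays)


def load_checkpoint(path: str | Path, seed: int = 0) -> tuple[TinyEncoder, dict[str, list[np.ndarray]]]:
    data = np.load(path, allow_pickle=False)
    spec = EncoderSpec(**json.loads(str(data["spec"])))
    enc = TinyEncoder(spec, seed=seed)
    enc_keys = sorted((k for k in data.files if k.startswith("enc_")),
                      key=lambda k: int(k.split("_")[1]))
    enc.load_state_arrays([data[k] for k in enc_keys])
    pieces: dict[str, list[tuple[int, np.ndarray]]] = {}
    for k in data.files:
        if k == "spec" or k.startswith("enc_"):
            continue
        name, i = k.rsplit("_", 1)
        pieces.setdefault(name, []).append((int(i), data[k]))
    extra = {name: [a for _, a in sorted(items)] for name, items in pieces.items()}
    return enc, extra
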