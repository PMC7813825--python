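"""Vocabulary construction and CBOW word-embedding pretraining.

The classifier's embedding layer is initialized from vectors pretrained on the
full-text corpus with the continuous-bag-of-words objective: predict a target
word from the mean of its neighbouring context vectors.  Training uses
negative sampling (k noise words drawn from the unigram^0.75 distribution),
the standard efficient approximation to the softmax, with a linearly decaying
learning rate.  The trainer is a self-contained numpy implementation, batched
over (target, context) examples and fully deterministic under a seed.

Conventional word2vec defaults (dimension 100, window 5, min_count 2,
10 epochs) apply; the special tokens of the blanked instances receive trained
vectors by appending tokenized annotated sentences to the pretraining stream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .instances import PAD, SPECIAL_TOKENS, UNK


class VocabularyError(ValueError):
    pass


class EmbeddingFormatError(ValueError):
    pass


@dataclass
class Vocabulary:
    """Bijective token↔index mapping with reserved special tokens.

    PAD is index 0 and UNK index 1; the remaining special tokens occupy the
    following fixed indices, then corpus tokens ordered by descending
    frequency (ties alphabetical).
    """

    token_to_index: dict[str, int]
    index_to_token: list[str]
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.index_to_token[0] != PAD:
            raise VocabularyError("PAD must have index 0")
        for tok in SPECIAL_TOKENS:
            if tok not in self.token_to_index:
                raise VocabularyError(f"special token {tok} missing")
        if len(self.token_to_index) != len(self.index_to_token):
            raise VocabularyError("token_to_index and index_to_token are not bijective")
        for i, tok in enumerate(self.index_to_token):
            if self.token_to_index[tok] != i:
                raise VocabularyError("token_to_index and index_to_token disagree")

    def __len__(self) -> int:
        return len(self.index_to_token)

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, self.token_to_index[UNK])

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.index(t) for t in tokens], dtype=np.int64)


def build_vocab(corpus: Iterable[Sequence[str]], min_count: int = 2) -> Vocabulary:
    """Vocabulary over token streams; tokens rarer than ``min_count`` map to UNK."""
    counts: Counter[str] = Counter()
    n_streams = 0
    for stream in corpus:
        n_streams += 1
        counts.update(stream)
    if n_streams == 0 or not counts:
        raise VocabularyError("empty corpus")
    index_to_token = list(SPECIAL_TOKENS)
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count and t not in SPECIAL_TOKENS),
        key=lambda t: (-counts[t], t),
    )
    index_to_token.extend(kept)
    return Vocabulary(
        token_to_index={t: i for i, t in enumerate(index_to_token)},
        index_to_token=index_to_token,
        counts=dict(counts),
    )


@dataclass
class EmbeddingMatrix:
    """V × d real matrix of token vectors; the PAD row is pinned to zero."""

    weights: np.ndarray
    vocab: Vocabulary

    def __post_init__(self) -> None:
        if self.weights.shape[0] != len(self.vocab):
            raise ValueError("row count must equal vocabulary size")
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite embedding values")
        if np.any(self.weights[self.vocab.token_to_index[PAD]] != 0):
            raise ValueError("PAD row must be all-zero")

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def vector(self, token: str) -> np.ndarray:
        return self.weights[self.vocab.index(token)]


def _cbow_examples(
    corpus: Sequence[Sequence[str]], vocab: Vocabulary, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(targets, padded context index matrix, context counts) over the corpus."""
    targets, contexts = [], []
    for stream in corpus:
        idx = [vocab.index(t) for t in stream]
        for pos, center in enumerate(idx):
            ctx = idx[max(0, pos - window):pos] + idx[pos + 1:pos + 1 + window]
            if ctx:
                targets.append(center)
                contexts.append(ctx)
    if not targets:
        raise VocabularyError("corpus yields no CBOW examples")
    width = max(len(c) for c in contexts)
    mat = np.zeros((len(contexts), width), dtype=np.int64)  # 0 = PAD, masked below
    mask = np.zeros((len(contexts), width), dtype=np.float32)
    for i, ctx in enumerate(contexts):
        mat[i, : len(ctx)] = ctx
        mask[i, : len(ctx)] = 1.0
    return np.array(targets, dtype=np.int64), mat, mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_cbow(
    corpus: Sequence[Sequence[str]],
    vocab: Vocabulary,
    window: int = 5,
    dim: int = 100,
    epochs: int = 10,
    seed: int = 0,
    negatives: int = 5,
    lr: float = 0.025,
    batch_size: int = 64,
    loss_history: list[float] | None = None,
) -> EmbeddingMatrix:
    """Pretrain CBOW vectors with negative sampling; deterministic under seed."""
    if dim <= 0 or window <= 0:
        raise ValueError("dim and window must be positive")
    targets, ctx_mat, ctx_mask = _cbow_examples(corpus, vocab, window)
    V = len(vocab)
    rng = np.random.default_rng(seed)
    w_in = ((rng.random((V, dim), dtype=np.float32) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((V, dim), dtype=np.float32)
    pad_idx = vocab.token_to_index[PAD]
    w_in[pad_idx] = 0.0

    # unigram^0.75 noise distribution over non-special corpus tokens
    freq = np.zeros(V, dtype=np.float64)
    for tok, c in vocab.counts.items():
        freq[vocab.index(tok)] += c
    freq[pad_idx] = 0.0
    noise = freq ** 0.75
    noise /= noise.sum()

    n = len(targets)
    total_steps = max(1, epochs * ((n + batch_size - 1) // batch_size))
    step = 0
    for _epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_batches = 0.0, 0
        for lo in range(0, n, batch_size):
            sel = order[lo:lo + batch_size]
            B = len(sel)
            cur_lr = lr * max(1e-4, 1.0 - step / total_steps)
            step += 1
            ctx = ctx_mat[sel]
            msk = ctx_mask[sel]
            denom = msk.sum(axis=1, keepdims=True)
            h = (w_in[ctx] * msk[..., None]).sum(axis=1) / denom  # B×d context mean

            pos = targets[sel]
            neg = rng.choice(V, size=(B, negatives), p=noise)
            samples = np.concatenate([pos[:, None], neg], axis=1)  # B×(1+k)
            labels = np.zeros((B, 1 + negatives), dtype=np.float32)
            labels[:, 0] = 1.0
            out_vecs = w_out[samples]                       # B×(1+k)×d
            scores = np.einsum("bkd,bd->bk", out_vecs, h)
            probs = _sigmoid(scores)
            eps = 1e-7
            epoch_loss += float(-(labels * np.log(probs + eps) + (1 - labels) * np.log(1 - probs + eps)).sum() / B)
            epoch_batches += 1
            g = (probs - labels).astype(np.float32)         # B×(1+k)
            grad_h = np.einsum("bk,bkd->bd", g, out_vecs)
            grad_out = np.einsum("bk,bd->bkd", g, h)
            np.add.at(w_out, samples, -cur_lr * grad_out)
            grad_ctx = (grad_h[:, None, :] * (msk / denom)[..., None]).astype(np.float32)
            np.add.at(w_in, ctx, -cur_lr * grad_ctx)
            w_in[pad_idx] = 0.0
        if loss_history is not None:
            loss_history.append(epoch_loss / max(1, epoch_batches))
    w_in[pad_idx] = 0.0
    return EmbeddingMatrix(weights=w_in, vocab=vocab)


def export_embeddings(matrix: EmbeddingMatrix, path: str | Path) -> None:
    """Write the word2vec text format: header ``V d``, then token + d floats."""
    path = Path(path)
    V, d = matrix.weights.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{V} {d}\n")
        for tok, row in zip(matrix.vocab.index_to_token, matrix.weights):
            if any(ch.isspace() for ch in tok):
                raise EmbeddingFormatError(f"token {tok!r} contains whitespace")
            fh.write(tok + " " + " ".join(repr(float(x)) for x in row) + "\n")


def import_embeddings(path: str | Path) -> EmbeddingMatrix:
    """Read the word2vec text format written by :func:`export_embeddings`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError("header must be 'V d'")
        V, d = (int(x) for x in header)
        tokens, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise EmbeddingFormatError(f"line {lineno}: expected {d} values, got {len(parts) - 1}")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(tokens) != V:
        raise EmbeddingFormatError(f"header promises {V} rows, file has {len(tokens)}")
    counts = {t: 1 for t in tokens if t not in SPECIAL_TOKENS}
    vocab = Vocabulary(
        token_to_index={t: i for i, t in enumerate(tokens)},
        index_to_token=tokens,
        counts=counts,
    )
    return EmbeddingMatrix(weights=np.array(rows, dtype=np.float32), vocab=vocab)
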