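"""Static unigram word embeddings (skip-gram with negative sampling).

Embeddings are learned exclusively on training-split sentences, are never
fine-tuned on the class label downstream, and out-of-vocabulary tokens map to
a fixed all-zeros vector so that tune/test-only words contribute nothing to
the recurrent input.  The trainer is a vectorised numpy implementation of
skip-gram with negative sampling: dynamic context windows, a unigram^0.75
noise distribution and a linearly decaying SGD learning rate, run
single-threaded so results are bit-reproducible given the seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["EmbeddingModel", "train_embeddings", "save_word2vec_text",
           "load_word2vec_text"]


@dataclass
class EmbeddingModel:
    vocab: dict[str, int]          # token -> row of matrix
    matrix: np.ndarray             # V x d
    dim: int
    min_count: int
    window: int
    seed: int

    def lookup(self, token: str) -> np.ndarray:
        """Row vector for ``token``; the zero UNK vector when out of vocab."""
        idx = self.vocab.get(token)
        if idx is None:
            return np.zeros(self.dim)
        return self.matrix[idx].astype(float)

    def __contains__(self, token: str) -> bool:
        return token in self.vocab


def _build_vocab(sentences: Sequence[Sequence[str]],
                 min_count: int) -> tuple[dict[str, int], np.ndarray]:
    freq = Counter(tok for sent in sentences for tok in sent)
    if not freq:
        raise ValueError("cannot train embeddings on an empty corpus")
    kept = sorted((t for t, c in freq.items() if c >= min_count),
                  key=lambda t: (-freq[t], t))
    if not kept:
        raise ValueError(
            f"no token reaches min_count={min_count}; vocabulary is empty")
    vocab = {t: i for i, t in enumerate(kept)}
    counts = np.array([freq[t] for t in kept], dtype=float)
    return vocab, counts


def train_embeddings(train_documents, dim: int = 100, window: int = 5,
                     min_count: int = 5, epochs: int = 5, seed: int = 0,
                     negatives: int = 5, lr: float = 0.025) -> EmbeddingModel:
    """Fit skip-gram-with-negative-sampling vectors on training documents.

    ``train_documents`` may be Document objects (their ``sentences`` are
    used) or plain token-list sentences.
    """
    if dim < 2:
        raise ValueError("embedding dimension must be at least 2")
    sentences = _as_sentences(train_documents)
    if not sentences:
        raise ValueError("cannot train embeddings on an empty corpus")
    for sent in sentences:
        for tok in sent:
            if " " in tok:
                raise ValueError(f"multi-word token {tok!r}: unigrams only")

    vocab, counts = _build_vocab(sentences, min_count)
    V = len(vocab)
    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))

    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    encoded = [np.array([vocab[t] for t in sent if t in vocab], dtype=np.int64)
               for sent in sentences]
    encoded = [s for s in encoded if len(s) >= 2]
    if not encoded:
        return EmbeddingModel(vocab, w_in, dim, min_count, window, seed)

    total_steps = epochs * sum(len(s) for s in encoded)
    step = 0
    min_lr = 1e-4
    for _ in range(epochs):
        order = rng.permutation(len(encoded))
        for si in order:
            sent = encoded[si]
            centers, contexts = _pairs(sent, window, rng)
            if len(centers) == 0:
                step += len(sent)
                continue
            cur_lr = max(min_lr, lr * (1.0 - step / total_steps))
            _sgns_update(w_in, w_out, centers, contexts, noise_cdf,
                         negatives, cur_lr, rng)
            step += len(sent)
    return EmbeddingModel(vocab, w_in, dim, min_count, window, seed)


def _as_sentences(docs) -> list[list[str]]:
    sentences: list[list[str]] = []
    for d in docs:
        if hasattr(d, "sentences"):
            sentences.extend(d.sentences)
        else:
            sentences.append(list(d))
    return sentences


def _pairs(sent: np.ndarray, window: int,
           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) index pairs with per-center dynamic window size."""
    n = len(sent)
    spans = rng.integers(1, window + 1, size=n)
    centers, contexts = [], []
    for i in range(n):
        b = spans[i]
        lo, hi = max(0, i - b), min(n, i + b + 1)
        for j in range(lo, hi):
            if j != i:
                centers.append(sent[i])
                contexts.append(sent[j])
    return np.array(centers, dtype=np.int64), np.array(contexts, dtype=np.int64)


def _sgns_update(w_in: np.ndarray, w_out: np.ndarray, centers: np.ndarray,
                 contexts: np.ndarray, noise_cdf: np.ndarray, k: int,
                 lr: float, rng: np.random.Generator) -> None:
    n = len(centers)
    vi = w_in[centers]                                   # n x d
    # positive examples
    vo = w_out[contexts]
    g_pos = _expit(np.sum(vi * vo, axis=1)) - 1.0        # n
    grad_in = g_pos[:, None] * vo
    np.add.at(w_out, contexts, -lr * g_pos[:, None] * vi)
    # negative examples
    neg = np.searchsorted(noise_cdf, rng.random((n, k)))  # n x k
    vn = w_out[neg]                                       # n x k x d
    g_neg = _expit(np.einsum("nd,nkd->nk", vi, vn))       # n x k
    grad_in += np.einsum("nk,nkd->nd", g_neg, vn)
    np.add.at(w_out.reshape(-1), _flat_idx(neg, w_out.shape[1]),
              (-lr * g_neg[:, :, None] * vi[:, None, :]).reshape(-1))
    np.add.at(w_in, centers, -lr * grad_in)


def _flat_idx(idx: np.ndarray, d: int) -> np.ndarray:
    base = (idx * d)[:, :, None] + np.arange(d)[None, None, :]
    return base.reshape(-1)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ------------------------------------------------------------------------ IO
def save_word2vec_text(model: EmbeddingModel, path: str | Path) -> None:
    """Plain-text word2vec format: header "V d", then token + d floats."""
    tokens = sorted(model.vocab, key=model.vocab.get)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(tokens)} {model.dim}\n")
        for t in tokens:
            row = " ".join(repr(float(x)) for x in model.matrix[model.vocab[t]])
            fh.write(f"{t} {row}\n")


def load_word2vec_text(path: str | Path, min_count: int = 0, window: int = 0,
                       seed: int = -1) -> EmbeddingModel:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        v, d = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        matrix = np.zeros((v, d))
        for i in range(v):
            parts = fh.readline().rstrip("\n").split(" ")
            vocab[parts[0]] = i
            matrix[i] = [float(x) for x in parts[1:d + 1]]
    return EmbeddingModel(vocab, matrix, d, min_count, window, seed)
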