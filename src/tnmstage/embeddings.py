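"""Word embeddings via skip-gram with negative sampling.

A compact, deterministic word2vec trainer: skip-gram objective, negative
sampling (k = 5), dynamic context windows, unigram^0.75 noise distribution
and linearly decaying learning rate — trained single-threaded with a seeded
generator so identical corpora and seeds give identical vectors.  Defaults
follow the staging pipeline's configuration: vector length 100, window
width 5, minimum token count 2.

Training is mini-batched: all (center, context) pairs of an epoch are
drawn, shuffled and processed in vectorized numpy batches, which keeps
corpora of a few hundred thousand tokens in the tens of seconds on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass
class EmbeddingModel:
    vocabulary: dict[str, int]
    vectors: np.ndarray  # (V, d)
    training_params: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.vocabulary[token]]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "embedding_vectors.npy", self.vectors)
        tokens = sorted(self.vocabulary, key=self.vocabulary.get)
        (directory / "embedding_vocab.txt").write_text(
            "\n".join(tokens) + "\n", encoding="utf-8"
        )
        (directory / "embedding_params.json").write_text(
            json.dumps(self.training_params, indent=2), encoding="utf-8"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingModel":
        directory = Path(directory)
        vectors = np.load(directory / "embedding_vectors.npy")
        tokens = (directory / "embedding_vocab.txt").read_text(encoding="utf-8").split()
        params = json.loads((directory / "embedding_params.json").read_text(encoding="utf-8"))
        return cls({t: i for i, t in enumerate(tokens)}, vectors, params)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(
    token_streams: Iterable[Sequence[str]],
    d: int = 100,
    window: int = 5,
    seed: int = 0,
    min_count: int = 2,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.025,
    batch_size: int = 1024,
) -> EmbeddingModel:
    """Train skip-gram embeddings over tokenized sentences.

    Raises ``ValueError`` if the corpus is empty after min-count filtering.
    """
    sentences = [list(s) for s in token_streams]
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab_tokens = sorted(
        (t for t, c in counts.items() if c >= min_count), key=lambda t: (-counts[t], t)
    )
    if not vocab_tokens:
        raise ValueError("corpus is empty after min-count filtering; nothing to train on")
    vocab = {t: i for i, t in enumerate(vocab_tokens)}
    V = len(vocab)
    encoded = [[vocab[t] for t in sent if t in vocab] for sent in sentences]
    encoded = [s for s in encoded if len(s) >= 2]

    rng = np.random.default_rng(seed)
    W = (rng.random((V, d)) - 0.5) / d  # input vectors (the embeddings)
    C = np.zeros((V, d))  # output (context) vectors

    freq = np.array([counts[t] for t in vocab_tokens], dtype=float)
    noise = freq**0.75
    noise /= noise.sum()

    # pairs are regenerated per epoch with fresh dynamic windows
    n_epoch_pairs = sum(len(s) * window for s in encoded)  # upper-bound estimate
    total_steps = max(1, epochs * max(1, n_epoch_pairs // batch_size))
    step = 0
    for _epoch in range(epochs):
        centers: list[int] = []
        contexts: list[int] = []
        for sent in encoded:
            L = len(sent)
            widths = rng.integers(1, window + 1, size=L)
            for i, (c, b) in enumerate(zip(sent, widths)):
                for j in range(max(0, i - b), min(L, i + b + 1)):
                    if j != i:
                        centers.append(c)
                        contexts.append(sent[j])
        order = rng.permutation(len(centers))
        centers_a = np.asarray(centers)[order]
        contexts_a = np.asarray(contexts)[order]
        for start in range(0, len(centers_a), batch_size):
            alpha = max(lr * (1 - step / total_steps), lr * 0.01)
            step += 1
            c_idx = centers_a[start : start + batch_size]
            o_idx = contexts_a[start : start + batch_size]
            B = len(c_idx)
            neg_idx = rng.choice(V, size=(B, negative), p=noise)
            v = W[c_idx]  # (B, d)
            u_pos = C[o_idx]  # (B, d)
            u_neg = C[neg_idx]  # (B, k, d)
            g_pos = _sigmoid(np.sum(v * u_pos, axis=1)) - 1.0  # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))  # (B, k)
            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            grad_u_pos = g_pos[:, None] * v
            grad_u_neg = g_neg[..., None] * v[:, None, :]
            np.add.at(W, c_idx, -alpha * grad_v)
            np.add.at(C, o_idx, -alpha * grad_u_pos)
            np.add.at(C, neg_idx.ravel(), -alpha * grad_u_neg.reshape(-1, d))
    return EmbeddingModel(
        vocabulary=vocab,
        vectors=W,
        training_params={
            "algorithm": "skip-gram",
            "d": d,
            "window": window,
            "seed": int(seed),
            "min_count": min_count,
            "epochs": epochs,
            "negative": negative,
            "lr": lr,
        },
    )
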