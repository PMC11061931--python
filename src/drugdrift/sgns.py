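"""Incremental skip-gram with negative sampling (SGNS).

A single model is trained in one chronological pass over the corpus: the
vocabulary is extended as new words appear, previously learned vectors are
retained and trained further on each new chunk of documents, and the
caller copies out the input vectors whenever a snapshot is due.

Design notes
------------
* Pairs are generated with a fixed symmetric context window (no random
  window shrinking) so that runs are bitwise reproducible.
* Negatives are drawn from the unigram distribution raised to 3/4, the
  standard smoothing for SGNS, recomputed from cumulative counts at the
  start of each chunk.
* Updates are applied sequentially pair by pair (classic word2vec style)
  in a numba kernel; the learning rate decays linearly within each chunk
  and restarts at the next one.  Single-threaded and seeded, so training
  is deterministic.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numba
import numpy as np

__all__ = ["IncrementalSGNS"]

_NEG_TABLE_POWER = 0.75


@numba.njit(fastmath=True)
def _sgd_pairs(vec_in, vec_out, centers, contexts, negs, lr_start, lr_end):  # pragma: no cover
    n = centers.shape[0]
    k = negs.shape[1]
    d = vec_in.shape[1]
    gv = np.zeros(d, dtype=np.float32)
    for i in range(n):
        lr = np.float32(lr_start + (lr_end - lr_start) * (i / n))
        c = centers[i]
        gv[:] = 0.0
        for j in range(k + 1):
            if j == 0:
                t = contexts[i]
                label = np.float32(1.0)
            else:
                t = negs[i, j - 1]
                label = np.float32(0.0)
            s = np.float32(0.0)
            for m in range(d):
                s += vec_in[c, m] * vec_out[t, m]
            if s >= 0.0:
                p = 1.0 / (1.0 + np.exp(-s))
            else:
                e = np.exp(s)
                p = e / (1.0 + e)
            g = np.float32((p - label) * lr)
            for m in range(d):
                gv[m] += g * vec_out[t, m]
                vec_out[t, m] -= g * vec_in[c, m]
        for m in range(d):
            vec_in[c, m] -= gv[m]


class IncrementalSGNS:
    """Continuously trainable skip-gram negative-sampling embeddings.

    Parameters
    ----------
    dimension : length of the embedding vectors.
    window : symmetric context window in tokens.
    negative : negative samples per (center, context) pair.
    alpha, min_alpha : initial and final per-chunk learning rate.
    seed : RNG seed; all sampling (shuffling, negatives) derives from it.
    """

    def __init__(
        self,
        dimension: int = 50,
        window: int = 5,
        negative: int = 5,
        alpha: float = 0.025,
        min_alpha: float = 1e-4,
        seed: int = 0,
    ) -> None:
        if dimension < 1 or window < 1 or negative < 1:
            raise ValueError("dimension, window and negative must be positive")
        self.dimension = dimension
        self.window = window
        self.negative = negative
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self.word2idx: dict[str, int] = {}
        self.words: list[str] = []
        self.counts = np.zeros(0, dtype=np.int64)
        self.vec_in = np.zeros((0, dimension), dtype=np.float32)
        self.vec_out = np.zeros((0, dimension), dtype=np.float32)

    # -- vocabulary ---------------------------------------------------------

    @property
    def vocab_size(self) -> int:
        return len(self.words)

    def cumulative_count(self, word: str) -> int:
        idx = self.word2idx.get(word)
        return 0 if idx is None else int(self.counts[idx])

    def _grow_vocab(self, docs: Sequence[Sequence[str]]) -> None:
        new_words: list[str] = []
        add_counts: dict[int, int] = {}
        for doc in docs:
            for tok in doc:
                idx = self.word2idx.get(tok)
                if idx is None:
                    idx = len(self.words) + len(new_words)
                    self.word2idx[tok] = idx
                    new_words.append(tok)
                add_counts[idx] = add_counts.get(idx, 0) + 1
        if new_words:
            n_new = len(new_words)
            self.words.extend(new_words)
            # word2vec-style init: small uniform inputs, zero outputs
            init = (self._rng.random((n_new, self.dimension), dtype=np.float32) - 0.5)
            init /= self.dimension
            self.vec_in = np.concatenate([self.vec_in, init])
            self.vec_out = np.concatenate(
                [self.vec_out, np.zeros((n_new, self.dimension), dtype=np.float32)]
            )
            self.counts = np.concatenate([self.counts, np.zeros(n_new, dtype=np.int64)])
        if add_counts:
            idxs = np.fromiter(add_counts.keys(), dtype=np.int64, count=len(add_counts))
            vals = np.fromiter(add_counts.values(), dtype=np.int64, count=len(add_counts))
            self.counts[idxs] += vals

    # -- training -----------------------------------------------------------

    def _pairs(self, docs: Sequence[Sequence[str]]) -> tuple[np.ndarray, np.ndarray]:
        centers: list[np.ndarray] = []
        contexts: list[np.ndarray] = []
        w = self.window
        for doc in docs:
            ids = np.fromiter((self.word2idx[t] for t in doc), dtype=np.int64, count=len(doc))
            n = len(ids)
            for off in range(1, w + 1):
                if off >= n:
                    break
                centers.append(ids[:-off])
                contexts.append(ids[off:])
        if not centers:
            empty = np.zeros(0, dtype=np.int64)
            return empty, empty
        c = np.concatenate(centers)
        o = np.concatenate(contexts)
        # each unordered co-occurrence trains both directions
        return np.concatenate([c, o]), np.concatenate([o, c])

    def train_chunk(self, docs: Iterable[Sequence[str]], epochs: int) -> int:
        """Extend the vocabulary with ``docs`` and run ``epochs`` passes over them.

        Returns the number of (center, context) training pairs per epoch.
        """
        docs = [list(d) for d in docs]
        if not docs:
            return 0
        self._grow_vocab(docs)
        centers, contexts = self._pairs(docs)
        n_pairs = len(centers)
        if n_pairs == 0:
            return 0

        noise = self.counts.astype(np.float64) ** _NEG_TABLE_POWER
        noise_cdf = np.cumsum(noise / noise.sum())
        noise_cdf[-1] = 1.0

        span = self.alpha - self.min_alpha
        for epoch in range(epochs):
            order = self._rng.permutation(n_pairs)
            negs = np.searchsorted(
                noise_cdf, self._rng.random((n_pairs, self.negative))
            ).astype(np.int64)
            _sgd_pairs(
                self.vec_in,
                self.vec_out,
                centers[order],
                contexts[order],
                negs,
                self.alpha - span * (epoch / epochs),
                self.alpha - span * ((epoch + 1) / epochs),
            )
        return n_pairs

    # -- export -------------------------------------------------------------

    def qualifying_words(self, min_count: int) -> list[str]:
        """Words whose cumulative corpus frequency has reached ``min_count``."""
        mask = self.counts >= min_count
        return [self.words[i] for i in np.flatnonzero(mask)]

    def vector(self, word: str) -> np.ndarray:
        return self.vec_in[self.word2idx[word]]
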