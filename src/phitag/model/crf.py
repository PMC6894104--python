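"""Linear-chain conditional random field: likelihood, gradients, decoding.

The CRF scores a tag path ``y`` for a sentence of length ``T`` as

    score(y) = start[y_0] + sum_t emis[t, y_t]
               + sum_t trans[y_{t-1}, y_t] + stop[y_{T-1}]

and normalizes over all ``K^T`` paths with the forward algorithm in log
space.  Gradients come from forward-backward marginals, so training never
enumerates paths.  Decoding runs the Viterbi recursion backwards over the
sentence so that ties can be broken front-to-first for the
lexicographically smallest optimal tag-index path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _logsumexp(a: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
            ).squeeze(axis)


@dataclass
class TransitionMatrix:
    """(K+2)x(K+2) score matrix: K tags plus virtual start/stop states.

    Row/column ``K`` is the start state, ``K+1`` the stop state; only the
    tag->tag block, the start row and the stop column carry meaning.
    """

    matrix: np.ndarray

    n_tags: int = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        k2 = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != k2 or k2 < 3:
            raise ValueError("transition matrix must be (K+2)x(K+2)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("transition matrix has non-finite entries")
        self.n_tags = k2 - 2

    @classmethod
    def zeros(cls, n_tags: int) -> "TransitionMatrix":
        return cls(np.zeros((n_tags + 2, n_tags + 2)))

    @property
    def trans(self) -> np.ndarray:
        return self.matrix[:self.n_tags, :self.n_tags]

    @property
    def start(self) -> np.ndarray:
        return self.matrix[self.n_tags, :self.n_tags]

    @property
    def stop(self) -> np.ndarray:
        return self.matrix[:self.n_tags, self.n_tags + 1]


def _check(emissions: np.ndarray, tm: TransitionMatrix,
           tags: np.ndarray | None = None) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[1] != tm.n_tags:
        raise ValueError(
            f"emissions must be (T, {tm.n_tags}), got {emissions.shape}")
    if tags is not None:
        tags = np.asarray(tags)
        if tags.shape != (emissions.shape[0],):
            raise ValueError("tags length must equal T")
        if tags.size and (tags.min() < 0 or tags.max() >= tm.n_tags):
            raise IndexError("tag index out of range")
    return emissions


def path_score(emissions: np.ndarray, tm: TransitionMatrix,
               tags: np.ndarray) -> float:
    emissions = _check(emissions, tm, tags)
    tags = np.asarray(tags)
    if tags.size == 0:
        return 0.0
    s = tm.start[tags[0]] + emissions[np.arange(len(tags)), tags].sum()
    s += tm.trans[tags[:-1], tags[1:]].sum() + tm.stop[tags[-1]]
    return float(s)


def log_partition(emissions: np.ndarray, tm: TransitionMatrix) -> float:
    emissions = _check(emissions, tm)
    if emissions.shape[0] == 0:
        return 0.0
    alpha = tm.start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = _logsumexp(alpha[:, None] + tm.trans, axis=0) + emissions[t]
    return float(_logsumexp(alpha + tm.stop))


def crf_log_likelihood(emissions: np.ndarray, tm: TransitionMatrix,
                       tags: np.ndarray) -> float:
    """log P(tags | emissions); always <= 0."""
    return path_score(emissions, tm, tags) - log_partition(emissions, tm)


def crf_gradients(emissions: np.ndarray, tm: TransitionMatrix,
                  tags: np.ndarray
                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood and its gradients wrt emissions and transitions.

    Returns ``(ll, d_emissions, d_matrix)`` where ``d_matrix`` has the
    same (K+2)x(K+2) layout as the transition matrix.  Gradients are of
    the log-likelihood (ascend to maximize).
    """
    emissions = _check(emissions, tm, tags)
    T, K = emissions.shape
    d_emis = np.zeros_like(emissions)
    d_mat = np.zeros_like(tm.matrix)
    if T == 0:
        return 0.0, d_emis, d_mat
    tags = np.asarray(tags)
    trans = tm.trans

    # forward / backward messages in log space
    alpha = np.empty((T, K))
    alpha[0] = tm.start + emissions[0]
    for t in range(1, T):
        alpha[t] = _logsumexp(alpha[t - 1][:, None] + trans, axis=0) \
            + emissions[t]
    beta = np.empty((T, K))
    beta[T - 1] = tm.stop
    for t in range(T - 2, -1, -1):
        beta[t] = _logsumexp(trans + (emissions[t + 1] + beta[t + 1])[None, :],
                             axis=1)
    log_z = float(_logsumexp(alpha[T - 1] + beta[T - 1]))

    # unary marginals
    gamma = np.exp(alpha + beta - log_z)
    d_emis = -gamma
    d_emis[np.arange(T), tags] += 1.0

    # pairwise marginals -> transition block
    d_trans = np.zeros((K, K))
    for t in range(1, T):
        xi = np.exp(alpha[t - 1][:, None] + trans
                    + (emissions[t] + beta[t])[None, :] - log_z)
        d_trans -= xi
        d_trans[tags[t - 1], tags[t]] += 1.0
    d_mat[:K, :K] = d_trans
    d_mat[K, :K] = -gamma[0]
    d_mat[K, tags[0]] += 1.0
    d_mat[:K, K + 1] = -gamma[T - 1]
    d_mat[tags[T - 1], K + 1] += 1.0

    ll = path_score(emissions, tm, tags) - log_z
    return ll, d_emis, d_mat


def viterbi_decode(emissions: np.ndarray, tm: TransitionMatrix
                   ) -> tuple[list[int], float]:
    """Best-scoring tag path and its score.

    The max-score recursion runs from the end of the sentence, so the
    path is then built front-to-back choosing at every step the smallest
    tag index among optimal continuations -- the lexicographically
    smallest optimal path under exact ties.
    """
    emissions = _check(emissions, tm)
    T, K = emissions.shape
    if T == 0:
        return [], 0.0
    # best[t, j] = max score of the suffix starting at t in state j
    best = np.empty((T, K))
    best[T - 1] = emissions[T - 1] + tm.stop
    for t in range(T - 2, -1, -1):
        best[t] = emissions[t] + np.max(tm.trans + best[t + 1][None, :],
                                        axis=1)
    totals = tm.start + best[0]
    score = float(np.max(totals))
    path = [int(np.argmax(totals))]  # argmax takes the smallest index on ties
    for t in range(1, T):
        cont = tm.trans[path[-1]] + best[t]
        path.append(int(np.argmax(cont)))
    return path, score
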