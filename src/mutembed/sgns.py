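"""Skip-gram with negative sampling (SGNS), implemented from scratch.

The model learns one d-dimensional input vector u_i (a row of the
embedding lookup matrix U) and one output vector v_j (a row of V) per
vocabulary entity.  The full-softmax skip-gram objective

    J(U, V) = (1/N) sum_i sum_{j in C_i} log softmax(u_i^T V)_j

is expensive for large vocabularies, so training optimizes the negative
sampling surrogate: for an observed (center i, context j) pair and a
fixed-size set D_i of noise entities,

    loss(i, j, D_i) = -log sigma(u_i^T v_j) - sum_{l in D_i} log(1 - sigma(u_i^T v_l))

with noise entities drawn from the unigram distribution raised to the
3/4 power.  Positives are pushed up, sampled non-contexts pushed down.

Training is plain sequential SGD with a linearly decaying learning rate,
single-threaded and bit-reproducible under a fixed seed.  The exact
softmax objective is retained as a small-vocabulary testing oracle.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .containers import GeneVectorTable, MutationProfileSet
from .contexts import pairs_array, sample_profile_contexts, window_corpus_contexts
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters of the SGNS trainer.

    dim: embedding dimension (300 gives gene vectors comparable to
        literature-trained word vectors, enabling pre-initialization).
    negatives_per_pair: |D_i|, the fixed number of noise draws per
        observed pair.
    epochs: full passes over the pair stream.
    lr_initial/lr_final: linear learning-rate decay endpoints.
    min_count: entities observed fewer times are dropped from the vocabulary.
    """

    dim: int = 300
    negatives_per_pair: int = 5
    epochs: int = 5
    lr_initial: float = 0.025
    lr_final: float = 1e-4
    seed: int = 0
    min_count: int = 1

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ConfigurationError("dim must be >= 1")
        if self.negatives_per_pair < 1:
            raise ConfigurationError("negatives_per_pair must be >= 1")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if not (self.lr_initial >= self.lr_final > 0):
            raise ConfigurationError("need lr_initial >= lr_final > 0")
        if self.min_count < 1:
            raise ConfigurationError("min_count must be >= 1")


@dataclass
class EmbeddingModel:
    """Vocabulary plus the two trained weight matrices."""

    vocab: list[str]
    U: np.ndarray  # |E| x d input/embedding lookup matrix
    V: np.ndarray  # |E| x d output matrix
    counts: np.ndarray | None = field(default=None)

    @property
    def d(self) -> int:
        return int(self.U.shape[1])

    def vectors(self) -> GeneVectorTable:
        """The learned representations (rows of U)."""
        return GeneVectorTable(list(self.vocab), self.U.copy())


def build_vocab(
    source: MutationProfileSet | Iterable[Sequence[str]],
    min_count: int = 1,
) -> tuple[list[str], np.ndarray]:
    """Count entities and build the training vocabulary.

    Accepts a mutation-profile set (counting per-sample occurrence) or an
    iterable of token lists (counting token occurrences).  Entities below
    ``min_count`` are dropped; order is count-descending with
    lexicographic tie-break, so the vocabulary is stable across runs.
    """
    if min_count < 1:
        raise ConfigurationError("min_count must be >= 1")
    if isinstance(source, MutationProfileSet):
        counts = source.gene_counts()
    else:
        counts = Counter()
        for sentence in source:
            counts.update(tok.upper() for tok in sentence)
    kept = [(tok, c) for tok, c in counts.items() if c >= min_count]
    if not kept:
        raise ConfigurationError("empty vocabulary after applying min_count")
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    vocab = [tok for tok, _ in kept]
    return vocab, np.array([c for _, c in kept], dtype=np.float64)


def noise_distribution(counts: np.ndarray, power: float = 0.75) -> np.ndarray:
    """Unigram^power noise distribution for negative sampling."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    w = counts**power
    return w / w.sum()


def _neg_log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """-log(sigma(x)) = log(1 + exp(-x)), overflow-safe."""
    return np.logaddexp(0.0, -np.asarray(x, dtype=np.float64))


def sgns_loss_grad(
    u_i: np.ndarray,
    v_j: np.ndarray,
    v_negs: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and exact gradients for one (center, context, negatives) triple.

    Returns ``(loss, grad_u, grad_v_pos, grad_v_negs)`` where the loss is
    -log sigma(u.v_j) - sum_l log(1 - sigma(u.v_l)).
    """
    u_i = np.asarray(u_i, dtype=np.float64)
    v_j = np.asarray(v_j, dtype=np.float64)
    v_negs = np.atleast_2d(np.asarray(v_negs, dtype=np.float64))
    dot_pos = float(u_i @ v_j)
    dots_neg = v_negs @ u_i
    loss = float(_neg_log_sigmoid(dot_pos) + _neg_log_sigmoid(-dots_neg).sum())
    with np.errstate(over="ignore"):  # exp overflow saturates sigma to 0
        sig_pos = 1.0 / (1.0 + np.exp(-dot_pos))
        sig_neg = 1.0 / (1.0 + np.exp(-dots_neg))
    grad_v_pos = (sig_pos - 1.0) * u_i
    grad_v_negs = sig_neg[:, None] * u_i[None, :]
    grad_u = (sig_pos - 1.0) * v_j + sig_neg @ v_negs
    return loss, grad_u, grad_v_pos, grad_v_negs


def init_matrices(
    n_vocab: int, dim: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """word2vec-style init: U ~ uniform(-0.5/d, 0.5/d), V = 0."""
    U = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n_vocab, dim))
    V = np.zeros((n_vocab, dim))
    return U, V


def init_from_pretrained(model: EmbeddingModel, table: GeneVectorTable) -> int:
    """Overwrite rows of the lookup matrix U with pre-trained vectors.

    Tokens are matched case-insensitively; rows without a match keep
    their random initialization and V is untouched.  Returns the number
    of rows initialized.  Idempotent.
    """
    if table.d != model.d:
        raise ConfigurationError(
            f"pre-trained dimension {table.d} != model dimension {model.d}"
        )
    by_upper = {tok.upper(): i for i, tok in enumerate(table.vocab)}
    n = 0
    for row, tok in enumerate(model.vocab):
        src = by_upper.get(tok.upper())
        if src is not None:
            model.U[row] = table.matrix[src]
            n += 1
    return n


def _draw_negatives(
    rng: np.random.Generator,
    positives: np.ndarray,
    n_vocab: int,
    k: int,
    noise: np.ndarray,
) -> np.ndarray:
    """k i.i.d. noise draws per pair, re-drawing any that hit the positive."""
    cumulative = np.cumsum(noise)
    cumulative[-1] = 1.0
    negs = np.searchsorted(cumulative, rng.random((positives.size, k)), side="right")
    bad = negs == positives[:, None]
    while bad.any():
        negs[bad] = np.searchsorted(cumulative, rng.random(int(bad.sum())), side="right")
        bad = negs == positives[:, None]
    return negs.astype(np.int64)


def train_sgns(
    pairs: np.ndarray | Iterable[tuple[int, int]],
    vocab: Sequence[str],
    config: TrainConfig | None = None,
    noise: np.ndarray | None = None,
    init_table: GeneVectorTable | None = None,
    counts: np.ndarray | None = None,
) -> EmbeddingModel:
    """SGD training over a fixed stream of (center, context) pairs.

    The pair stream is traversed in order once per epoch; the learning
    rate decays linearly from ``lr_initial`` to ``lr_final`` over all
    updates.  With a fixed seed and pair order the result is
    bit-identical across runs.
    """
    config = config or TrainConfig()
    pairs = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs)
    pairs = pairs.reshape(-1, 2).astype(np.int64)
    n_vocab = len(vocab)
    if pairs.size and (pairs.min() < 0 or pairs.max() >= n_vocab):
        raise ValueError("pair indices outside the vocabulary")
    if noise is None:
        if counts is not None:
            noise = noise_distribution(counts)
        else:
            noise = np.full(n_vocab, 1.0 / n_vocab)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != (n_vocab,):
        raise ConfigurationError("noise distribution size != vocabulary size")

    rng = np.random.default_rng(config.seed)
    U, V = init_matrices(n_vocab, config.dim, rng)
    if init_table is not None:
        n_init = init_from_pretrained(EmbeddingModel(list(vocab), U, V), init_table)
        logger.info("initialized %d/%d rows from pre-trained vectors", n_init, n_vocab)

    n_pairs = pairs.shape[0]
    total_updates = max(1, config.epochs * n_pairs)
    k = config.negatives_per_pair
    update = 0
    for epoch in range(config.epochs):
        if n_pairs == 0:
            break
        negs = _draw_negatives(rng, pairs[:, 1], n_vocab, k, noise)
        rows = np.empty(k + 1, dtype=np.int64)
        # divergence surfaces as the explicit finiteness check below,
        # not as floating-point warnings mid-loop
        err = np.errstate(over="ignore", invalid="ignore")
        err.__enter__()
        for idx in range(n_pairs):
            lr = config.lr_initial + (config.lr_final - config.lr_initial) * (
                update / total_updates
            )
            i, j = pairs[idx, 0], pairs[idx, 1]
            rows[0] = j
            rows[1:] = negs[idx]
            u = U[i]
            Vr = V[rows]
            sig = 1.0 / (1.0 + np.exp(-(Vr @ u)))
            g = -sig
            g[0] += 1.0  # labels: positive first, then k negatives
            grad_u = g @ Vr
            gl = lr * g
            # sequential row updates: exact even when a negative repeats
            for t in range(k + 1):
                V[rows[t]] += gl[t] * u
            U[i] += lr * grad_u
            update += 1
        err.__exit__(None, None, None)
        if not (np.isfinite(U).all() and np.isfinite(V).all()):
            raise FloatingPointError(
                f"non-finite parameters after epoch {epoch + 1}; "
                "the learning rate is likely too high"
            )
        logger.debug("epoch %d/%d done (%d updates)", epoch + 1, config.epochs, update)
    return EmbeddingModel(list(vocab), U, V, counts=counts)


def mean_sgns_loss(
    model: EmbeddingModel,
    pairs: np.ndarray,
    noise: np.ndarray,
    negatives_per_pair: int = 5,
    seed: int = 0,
) -> float:
    """Mean negative-sampling loss of a pair sample (held-out diagnostics)."""
    pairs = np.asarray(pairs).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    negs = _draw_negatives(rng, pairs[:, 1], len(model.vocab), negatives_per_pair, noise)
    total = 0.0
    for idx in range(pairs.shape[0]):
        i, j = pairs[idx]
        loss, *_ = sgns_loss_grad(model.U[i], model.V[j], model.V[negs[idx]])
        total += loss
    return total / max(1, pairs.shape[0])


def softmax_objective(model: EmbeddingModel, pairs: Iterable[tuple[int, int]]) -> float:
    """Exact full-softmax skip-gram objective (mean log-likelihood, <= 0).

    Enumerates the normalizer over the whole vocabulary; intended as a
    testing oracle for small vocabularies, not for production training.
    """
    pairs = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs)
    pairs = pairs.reshape(-1, 2).astype(np.int64)
    if pairs.shape[0] == 0:
        raise ValueError("no pairs to score")
    scores = model.U[pairs[:, 0]] @ model.V.T  # (n_pairs, |E|)
    log_z = logsumexp(scores, axis=1)
    log_p = scores[np.arange(pairs.shape[0]), pairs[:, 1]] - log_z
    return float(log_p.mean())


class SkipGramEmbedder(BaseEstimator):
    """Scikit-learn style estimator wrapping the SGNS trainer.

    ``fit`` accepts either a :class:`MutationProfileSet` (contexts drawn
    by repeated fixed-size random subsets of each sample) or a list of
    tokenized sentences (conventional positional windows), so the same
    estimator trains mutation embeddings and corpus word vectors.

    Parameters mirror :class:`TrainConfig` plus the context-construction
    knobs; ``pretrained`` optionally seeds the lookup matrix from an
    existing :class:`GeneVectorTable` (matched case-insensitively).

    Attributes (after fit): ``vocab_``, ``counts_``, ``model_``,
    ``embedding_`` (a GeneVectorTable of the learned vectors) and
    ``n_pretrained_`` (rows initialized from ``pretrained``).
    """

    def __init__(
        self,
        dim: int = 300,
        negatives_per_pair: int = 5,
        epochs: int = 5,
        lr_initial: float = 0.025,
        lr_final: float = 1e-4,
        min_count: int = 1,
        draws_per_sample: int = 10,
        draw_size: int = 10,
        window: int = 5,
        noise_power: float = 0.75,
        pretrained: GeneVectorTable | None = None,
        seed: int = 0,
    ) -> None:
        self.dim = dim
        self.negatives_per_pair = negatives_per_pair
        self.epochs = epochs
        self.lr_initial = lr_initial
        self.lr_final = lr_final
        self.min_count = min_count
        self.draws_per_sample = draws_per_sample
        self.draw_size = draw_size
        self.window = window
        self.noise_power = noise_power
        self.pretrained = pretrained
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(
            dim=self.dim,
            negatives_per_pair=self.negatives_per_pair,
            epochs=self.epochs,
            lr_initial=self.lr_initial,
            lr_final=self.lr_final,
            seed=self.seed,
            min_count=self.min_count,
        )

    def fit(self, X: MutationProfileSet | list[Sequence[str]], y=None) -> "SkipGramEmbedder":
        config = self._config()
        self.vocab_, self.counts_ = build_vocab(X, min_count=self.min_count)
        if isinstance(X, MutationProfileSet):
            ctx = sample_profile_contexts(
                X,
                self.vocab_,
                draws_per_sample=self.draws_per_sample,
                draw_size=self.draw_size,
                seed=self.seed,
            )
            pairs = pairs_array(ctx)
        else:
            pairs = np.array(
                list(window_corpus_contexts(X, self.vocab_, window=self.window)),
                dtype=np.int64,
            ).reshape(-1, 2)
        noise = noise_distribution(self.counts_, power=self.noise_power)
        self.model_ = train_sgns(
            pairs,
            self.vocab_,
            config=config,
            noise=noise,
            init_table=self.pretrained,
            counts=self.counts_,
        )
        if self.pretrained is None:
            self.n_pretrained_ = 0
        else:
            known = {t.upper() for t in self.pretrained.vocab}
            self.n_pretrained_ = sum(tok.upper() in known for tok in self.vocab_)
        self.embedding_ = self.model_.vectors()
        return self

    def transform(self, tokens: Sequence[str]) -> np.ndarray:
        """Look up learned vectors for ``tokens`` (upper-cased)."""
        if not hasattr(self, "embedding_"):
            raise ConfigurationError("estimator is not fitted")
        return np.vstack([self.embedding_.vector(t.upper()) for t in tokens])

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return self.embedding_.matrix
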