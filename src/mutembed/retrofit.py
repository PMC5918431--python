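"""Graph retrofitting of embedding vectors.

Post-processes trained vectors so that genes adjacent in a
protein-interaction network end up close in embedding space, on the
assumption that interacting proteins participate in the same cellular
processes and their mutations have similar downstream effects.

The retrofitted vectors Q minimize the convex quadratic

    J(Q, Q~) = sum_i [ alpha_i ||q_i - q~_i||^2
                       + sum_{j in S_i} beta_ij ||q_i - q_j||^2 ]

where q~_i is the trained vector, S_i the one-hop network neighbours of
gene i restricted to the embedding vocabulary, alpha_i = 1 and
beta_ij = |S_i|^-1 (the center's degree, so every gene distributes unit
weight over its neighbourhood).  Minimization is by in-place coordinate
descent: each update replaces q_i with the weighted mean

    q_i <- (alpha_i q~_i + sum_{j in S_i} beta_ij q_j) / (alpha_i + sum_j beta_ij)

which for the default weights is the midpoint of q~_i and the current
neighbour mean.  Genes with no in-vocabulary neighbour keep q_i = q~_i
exactly.

A subtlety worth knowing: with the degree-based weights the update map
is *not* coordinate descent on J itself — it is exact coordinate
descent on the degree-weighted energy

    G(Q) = sum_i c_i alpha_i ||q_i - q~_i||^2
           + sum_{unordered edges {i,j}} w_ij ||q_i - q_j||^2

with c_i = |S_i| and w_ij = 1 (for a constant beta, c_i = 1 and
w_ij = beta).  G decreases monotonically every sweep and the iteration
converges to its minimizer; J itself is guaranteed lower than its
starting value but can fluctuate by small amounts between sweeps on the
way (it converges to the stationary point of the update map, which is
the minimizer of G, not of J).  :func:`retrofit_energy` evaluates G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GeneVectorTable, InteractionGraph
from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


def build_neighbor_sets(
    graph: InteractionGraph, vocab: Sequence[str]
) -> dict[str, set[str]]:
    """One-hop neighbour sets S_i, intersected with the vocabulary.

    Genes absent from the graph get an empty set; graph nodes outside the
    vocabulary are dropped (degrees are computed after intersection).
    """
    in_vocab = set(vocab)
    return {g: graph.neighbors(g) & in_vocab for g in vocab}


def _validate_neighbors(
    neighbor_sets: Mapping[str, set[str]], table: GeneVectorTable
) -> None:
    for g, neigh in neighbor_sets.items():
        if g in neigh:
            raise ValidationError(f"gene {g!r} listed as its own neighbour")
        missing = neigh - set(table.vocab)
        if missing:
            raise ValidationError(
                f"neighbours of {g!r} outside the vector vocabulary: "
                f"{sorted(missing)[:5]}"
            )


@dataclass
class RetrofitProblem:
    """Trained vectors plus the similarity structure to retrofit them to."""

    q_tilde: GeneVectorTable
    neighbor_sets: dict[str, set[str]]
    alpha: float = 1.0
    beta: float | None = None  # None -> 1/|S_i| per center

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError("alpha must be > 0")
        self.neighbor_sets = {
            g: set(self.neighbor_sets.get(g, set())) for g in self.q_tilde.vocab
        }
        _validate_neighbors(self.neighbor_sets, self.q_tilde)


def retrofit_objective(
    Q: np.ndarray,
    Q_tilde: np.ndarray,
    neighbor_sets: Mapping[str, set[str]],
    vocab: Sequence[str],
    alpha: float = 1.0,
    beta: float | None = None,
) -> float:
    """Evaluate J(Q, Q~) directly from its definition."""
    index = {g: i for i, g in enumerate(vocab)}
    total = 0.0
    for g in vocab:
        i = index[g]
        total += alpha * float(np.sum((Q[i] - Q_tilde[i]) ** 2))
        neigh = neighbor_sets.get(g, set())
        if not neigh:
            continue
        b = beta if beta is not None else 1.0 / len(neigh)
        for h in neigh:
            total += b * float(np.sum((Q[i] - Q[index[h]]) ** 2))
    return total


def retrofit_energy(
    Q: np.ndarray,
    Q_tilde: np.ndarray,
    neighbor_sets: Mapping[str, set[str]],
    vocab: Sequence[str],
    alpha: float = 1.0,
    beta: float | None = None,
) -> float:
    """The descent energy G of the retrofitting iteration (see module docs).

    Non-increasing across sweeps of :func:`retrofit_vectors`; its
    minimizer is the iteration's fixed point.
    """
    index = {g: i for i, g in enumerate(vocab)}
    total = 0.0
    seen: set[frozenset[str]] = set()
    for g in vocab:
        i = index[g]
        neigh = neighbor_sets.get(g, set())
        c_i = (len(neigh) if beta is None else 1.0) or 0.0
        total += c_i * alpha * float(np.sum((Q[i] - Q_tilde[i]) ** 2))
        if beta is None and not neigh:
            # isolated gene: anchor weight 1, not 0 (it never moves anyway)
            total += alpha * float(np.sum((Q[i] - Q_tilde[i]) ** 2))
        for h in neigh:
            edge = frozenset((g, h))
            if edge in seen:
                continue
            seen.add(edge)
            w = 1.0 if beta is None else beta
            total += w * float(np.sum((Q[i] - Q[index[h]]) ** 2))
    return total


def retrofit_vectors(
    problem: RetrofitProblem,
    iterations: int = 10,
    tol: float = 1e-6,
    on_sweep=None,
) -> GeneVectorTable:
    """Minimize the retrofitting energy by in-place coordinate updates.

    Runs at most ``iterations`` sweeps over the vocabulary (in vocabulary
    order, updating in place), stopping early when no vector moves more
    than ``tol`` in max-norm during a sweep.  Each coordinate update is
    the exact minimizer of the descent energy G in q_i with the rest
    held fixed, so G is non-increasing sweep to sweep.  ``on_sweep``,
    if given, is called with a copy of Q after every sweep.
    """
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    table = problem.q_tilde
    vocab = table.vocab
    index = {g: i for i, g in enumerate(vocab)}
    Q_tilde = table.matrix
    Q = Q_tilde.copy()
    neigh_idx = {
        index[g]: np.array(sorted(index[h] for h in problem.neighbor_sets[g]), dtype=np.int64)
        for g in vocab
    }
    active = [i for i in range(len(vocab)) if neigh_idx[i].size > 0]
    alpha = problem.alpha
    for sweep in range(iterations):
        max_change = 0.0
        for i in active:
            nbrs = neigh_idx[i]
            b = problem.beta if problem.beta is not None else 1.0 / nbrs.size
            new = (alpha * Q_tilde[i] + b * Q[nbrs].sum(axis=0)) / (alpha + b * nbrs.size)
            max_change = max(max_change, float(np.abs(new - Q[i]).max()))
            Q[i] = new
        if on_sweep is not None:
            on_sweep(Q.copy())
        if max_change < tol:
            logger.debug("retrofit converged after %d sweeps", sweep + 1)
            break
    return GeneVectorTable(list(vocab), Q)


class GraphRetrofitter(BaseEstimator, TransformerMixin):
    """Transformer: pull each gene vector toward its PPI neighbours.

    ``fit`` intersects the interaction graph with the vector vocabulary
    (storing ``neighbor_sets_``); ``transform`` returns the retrofitted
    :class:`GeneVectorTable`.  With no graph (or an empty one) the
    transform is the identity.
    """

    def __init__(
        self,
        graph: InteractionGraph | None = None,
        iterations: int = 10,
        tol: float = 1e-6,
        alpha: float = 1.0,
        beta: float | None = None,
    ) -> None:
        self.graph = graph
        self.iterations = iterations
        self.tol = tol
        self.alpha = alpha
        self.beta = beta

    def fit(self, X: GeneVectorTable, y=None) -> "GraphRetrofitter":
        graph = self.graph if self.graph is not None else InteractionGraph()
        self.neighbor_sets_ = build_neighbor_sets(graph, X.vocab)
        return self

    def transform(self, X: GeneVectorTable) -> GeneVectorTable:
        if not hasattr(self, "neighbor_sets_"):
            raise ConfigurationError("retrofitter is not fitted")
        problem = RetrofitProblem(
            q_tilde=X,
            neighbor_sets={g: self.neighbor_sets_.get(g, set()) & set(X.vocab) for g in X.vocab},
            alpha=self.alpha,
            beta=self.beta,
        )
        return retrofit_vectors(problem, iterations=self.iterations, tol=self.tol)
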