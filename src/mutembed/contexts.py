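"""Context construction for skip-gram training.

Mutation profiles have no word order: every gene mutated in the same
sample is context for every other.  Sliding a positional window over an
unordered set would be arbitrary, so contexts are built by drawing small
random subsets of each sample and treating each drawn subset as mutual
context (all ordered pairs).  Because the same fixed-size draw is applied
to every sample regardless of its mutation burden, hypermutated (noisy)
samples contribute proportionally less per mutation while sparse samples
are used in full on every draw.

For pre-training on text, the conventional positional window applies.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Sequence

import numpy as np

from .containers import MutationProfileSet

logger = logging.getLogger(__name__)

#: A context set: distinct vocabulary indices drawn from one sample.
ContextSet = np.ndarray

#: A (center, context) index pair.
TrainingPair = tuple[int, int]


def sample_profile_contexts(
    profiles: MutationProfileSet,
    vocab: Sequence[str],
    draws_per_sample: int = 10,
    draw_size: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[ContextSet]:
    """Draw fixed-size random gene subsets from each sample.

    Each sample with at least two in-vocabulary genes contributes exactly
    ``draws_per_sample`` draws of ``min(draw_size, n_genes)`` distinct
    genes (sampling without replacement within a draw; draws are
    independent repetitions).  Samples with fewer than two usable genes
    are skipped with a warning — no co-occurrence pair can be formed.
    """
    if draws_per_sample < 1:
        raise ValueError("draws_per_sample must be >= 1")
    if draw_size < 2:
        raise ValueError("draw_size must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    index = {tok: i for i, tok in enumerate(vocab)}
    out: list[ContextSet] = []
    n_skipped = 0
    for sample_id, genes in profiles:
        # sorted for determinism: set iteration order is not reproducible
        idx = np.array(sorted(index[g] for g in genes if g in index), dtype=np.int64)
        if idx.size < 2:
            n_skipped += 1
            continue
        size = min(draw_size, idx.size)
        for _ in range(draws_per_sample):
            out.append(rng.choice(idx, size=size, replace=False))
    if n_skipped:
        logger.warning(
            "skipped %d samples with < 2 in-vocabulary genes", n_skipped
        )
    return out


def contexts_to_pairs(sets: Iterable[ContextSet]) -> Iterator[TrainingPair]:
    """Expand each context set of size s into all s*(s-1) ordered pairs."""
    for ctx in sets:
        for i in range(len(ctx)):
            for j in range(len(ctx)):
                if i != j:
                    yield int(ctx[i]), int(ctx[j])


def pairs_array(sets: Iterable[ContextSet]) -> np.ndarray:
    """Vectorized ``contexts_to_pairs``: an (n_pairs, 2) int64 array."""
    chunks = []
    for ctx in sets:
        s = len(ctx)
        if s < 2:
            continue
        centers = np.repeat(ctx, s - 1)
        # for each center position, all other members in order
        mask = ~np.eye(s, dtype=bool)
        contexts = np.broadcast_to(ctx, (s, s))[mask]
        chunks.append(np.column_stack([centers, contexts]))
    if not chunks:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(chunks).astype(np.int64)


def window_corpus_contexts(
    sentences: Iterable[Sequence[str]],
    vocab: Sequence[str],
    window: int = 5,
    seed: int | None = None,
) -> Iterator[TrainingPair]:
    """Positional-window pairs for tokenized sentences.

    For each position t, emits (token_t, token_{t+j}) for 0 < |j| <= window
    within the sentence; out-of-vocabulary tokens are skipped both as
    centers and as contexts.  The window is fixed (no shrinking), so the
    enumeration is deterministic; ``seed`` is accepted for interface
    symmetry and unused.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    del seed
    index = {tok: i for i, tok in enumerate(vocab)}
    for sentence in sentences:
        ids = [index.get(tok.upper()) for tok in sentence]
        n = len(ids)
        for t, center in enumerate(ids):
            if center is None:
                continue
            lo, hi = max(0, t - window), min(n, t + window + 1)
            for s in range(lo, hi):
                if s == t or ids[s] is None:
                    continue
                yield center, ids[s]
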