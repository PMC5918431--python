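"""Domain containers shared across the pipeline.

Gene symbols are normalized to upper case everywhere: mutation profiles,
interaction networks and literature-derived vectors are joined by gene
name, which requires a single canonical casing.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: Allowed driver/passenger annotation values.
VALID_LABELS = frozenset({"known_driver", "predicted_driver", "predicted_passenger"})

#: Labels counted as "driver" when extracting unannotated candidates.
DRIVER_LABELS = frozenset({"known_driver", "predicted_driver"})


@dataclass
class MutationProfileSet:
    """Ordered collection of per-sample mutated-gene sets.

    Each element of ``samples`` is a ``(sample_id, genes)`` pair where
    ``genes`` is the set of gene symbols carrying a somatic mutation in
    that sample.  This is the training corpus: genes co-occurring in a
    sample play the role words co-occurring in a sentence play in text.
    """

    samples: list[tuple[str, set[str]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        normalized: list[tuple[str, set[str]]] = []
        for sample_id, genes in self.samples:
            if sample_id in seen:
                raise ValidationError(f"duplicate sample id: {sample_id!r}")
            seen.add(sample_id)
            genes = {g.upper() for g in genes}
            if not genes:
                raise ValidationError(f"sample {sample_id!r} has an empty gene set")
            normalized.append((sample_id, genes))
        self.samples = normalized

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[tuple[str, set[str]]]:
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.samples]

    def gene_counts(self) -> Counter[str]:
        """Number of samples each gene is mutated in."""
        counts: Counter[str] = Counter()
        for _, genes in self.samples:
            counts.update(genes)
        return counts


@dataclass
class GeneVectorTable:
    """An ordered vocabulary with one d-dimensional real vector per token."""

    vocab: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.vocab = list(self.vocab)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValidationError("vector matrix must be 2-dimensional")
        if len(self.vocab) != self.matrix.shape[0]:
            raise ValidationError(
                f"vocab size {len(self.vocab)} != matrix rows {self.matrix.shape[0]}"
            )
        if self.matrix.shape[1] < 1:
            raise ValidationError("embedding dimension must be >= 1")
        if len(set(self.vocab)) != len(self.vocab):
            raise ValidationError("duplicate tokens in vocabulary")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("non-finite entries in vector matrix")
        self._index = {tok: i for i, tok in enumerate(self.vocab)}

    @property
    def d(self) -> int:
        return int(self.matrix.shape[1])

    def __len__(self) -> int:
        return len(self.vocab)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index(self, token: str) -> int:
        return self._index[token]

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self._index[token]]

    def subset(self, tokens: Iterable[str]) -> "GeneVectorTable":
        """Table restricted to ``tokens``, in the given order."""
        tokens = list(tokens)
        missing = [t for t in tokens if t not in self._index]
        if missing:
            raise ValidationError(f"tokens absent from table: {missing[:5]}")
        rows = [self._index[t] for t in tokens]
        return GeneVectorTable(tokens, self.matrix[rows].copy())


class InteractionGraph:
    """Undirected protein-interaction network over gene symbols.

    Self-loops are dropped and reversed duplicates collapse to a single
    edge; only the topology matters (one-hop neighbourhoods feed the
    retrofitting step).
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._g = nx.Graph()
        for a, b in edges:
            a, b = a.upper(), b.upper()
            if a == b:
                continue
            self._g.add_edge(a, b)

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self._g.edges}

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self._g:
            return set()
        return set(self._g.neighbors(gene))

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def __len__(self) -> int:
        return self._g.number_of_nodes()


@dataclass
class LabelTable:
    """Gene -> driver/passenger annotation."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for gene, label in self.mapping.items():
            if label not in VALID_LABELS:
                raise ValidationError(
                    f"unknown label {label!r} for gene {gene!r}; "
                    f"expected one of {sorted(VALID_LABELS)}"
                )
            normalized[gene.upper()] = label
        self.mapping = normalized

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, gene: str) -> bool:
        return gene in self.mapping

    def get(self, gene: str, default: str | None = None) -> str | None:
        return self.mapping.get(gene, default)

    def genes_with(self, labels: str | Iterable[str]) -> set[str]:
        if isinstance(labels, str):
            labels = {labels}
        labels = set(labels)
        return {g for g, l in self.mapping.items() if l in labels}

    def is_driver(self, gene: str) -> bool:
        return self.mapping.get(gene) in DRIVER_LABELS


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) for over-representation analysis."""

    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized = {}
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            normalized[name] = {g.upper() for g in genes}
        self.sets = normalized

    def __len__(self) -> int:
        return len(self.sets)

    def items(self) -> Iterable[tuple[str, set[str]]]:
        return self.sets.items()


@dataclass
class Partition:
    """Assignment of items to disjoint blocks (clusters or classes)."""

    assignment: Mapping[object, int]

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)
        if not self.assignment:
            raise ValidationError("partition over an empty item set")

    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable[object]]) -> "Partition":
        assignment: dict[object, int] = {}
        for b, items in enumerate(blocks):
            for item in items:
                if item in assignment:
                    raise ValidationError(f"item {item!r} assigned to two blocks")
                assignment[item] = b
        return cls(assignment)

    @property
    def items(self) -> set[object]:
        return set(self.assignment)

    def blocks(self) -> dict[int, set[object]]:
        out: dict[int, set[object]] = {}
        for item, b in self.assignment.items():
            out.setdefault(b, set()).add(item)
        return out

    def block_sizes(self) -> np.ndarray:
        return np.array(sorted(Counter(self.assignment.values()).values()))

    def __len__(self) -> int:
        return len(self.assignment)
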