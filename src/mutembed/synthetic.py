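"""Synthetic cohorts, interaction networks and text corpora.

Real inputs to the pipeline are a tumour mutation cohort, a curated
protein-interaction network and a biomedical text corpus; none can ship
with the package, so this module generates structurally analogous data
with planted ground truth:

* **Cohort** — each sample expresses each planted "driver module" (a set
  of co-operating driver genes) with a fixed penetrance, carrying each
  module gene with probability 0.9 when it does, plus a heavy-tailed
  count of uniformly chosen passenger genes (Pareto tail, alpha = 2:
  most samples carry a handful of passengers, a few carry very many —
  mimicking the spread between near-silent and hypermutated tumours).
* **PPI graph** — a stochastic block model whose blocks are the driver
  modules: dense within a module, sparse elsewhere.
* **Corpus** — sentences mixing driver genes with "driver-context"
  filler words (the vocabulary of therapeutic/oncogenic discussion) and
  passenger genes with neutral laboratory vocabulary, so literature
  pre-training places driver genes near each other before cohort
  training starts.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import InteractionGraph, LabelTable, MutationProfileSet
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

DRIVER_FILLERS = [
    "CRITICAL", "DRUG", "THERAPY", "ONCOGENIC", "TARGETED", "RESISTANCE",
    "PROGNOSIS", "TUMORIGENESIS", "PATHWAY", "INHIBITOR",
]
NEUTRAL_FILLERS = [
    "CELL", "PROTEIN", "ASSAY", "SAMPLE", "EXPRESSION", "SEQUENCE",
    "ANALYSIS", "CULTURE", "BUFFER", "CONTROL",
]


@dataclass
class CohortSpec:
    """Parameters of a synthetic tumour cohort.

    ``driver_modules`` are disjoint sets of co-mutated driver genes;
    ``module_penetrance`` is the probability a sample expresses a given
    module; ``passenger_rate`` scales the Pareto-tailed passenger count
    per sample.
    """

    n_samples: int = 400
    n_genes: int = 500
    driver_modules: list[set[str]] = field(default_factory=list)
    module_penetrance: float = 0.5
    passenger_rate: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValidationError("n_samples and n_genes must be >= 1")
        if not 0.0 <= self.module_penetrance <= 1.0:
            raise ValidationError("module_penetrance must lie in [0, 1]")
        if self.passenger_rate < 0:
            raise ValidationError("passenger_rate must be >= 0")
        self.driver_modules = [
            {g.upper() for g in module} for module in self.driver_modules
        ]
        all_drivers: set[str] = set()
        for module in self.driver_modules:
            if module & all_drivers:
                raise ValidationError("driver modules must be disjoint")
            all_drivers |= module
        if len(all_drivers) > self.n_genes:
            raise ValidationError("driver modules exceed the gene universe")

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_samples: int = 400,
        n_genes: int = 500,
        n_modules: int = 2,
        module_size: int = 20,
        module_penetrance: float = 0.5,
        passenger_rate: float = 3.0,
    ) -> "CohortSpec":
        """Canonical planted cohort: 2 disjoint 20-gene driver modules."""
        modules = [
            {f"M{m + 1}G{i:03d}" for i in range(module_size)}
            for m in range(n_modules)
        ]
        return cls(
            n_samples=n_samples,
            n_genes=n_genes,
            driver_modules=modules,
            module_penetrance=module_penetrance,
            passenger_rate=passenger_rate,
            seed=seed,
        )

    @property
    def driver_genes(self) -> list[str]:
        return sorted(g for module in self.driver_modules for g in module)

    @property
    def passenger_genes(self) -> list[str]:
        n_pass = self.n_genes - len(self.driver_genes)
        return [f"P{i:04d}" for i in range(n_pass)]


def simulate_cohort(spec: CohortSpec) -> tuple[MutationProfileSet, LabelTable]:
    """Generate a mutation cohort plus ground-truth labels.

    Returns the profiles and a label table marking module genes
    ``known_driver`` and all remaining genes ``predicted_passenger``.
    A sample that would otherwise be empty (no module expressed, zero
    passengers drawn) receives one uniform passenger so every profile is
    non-empty.
    """
    rng = np.random.default_rng(spec.seed)
    passengers = spec.passenger_genes
    modules = [sorted(m) for m in spec.driver_modules]
    samples: list[tuple[str, set[str]]] = []
    for s in range(spec.n_samples):
        genes: set[str] = set()
        for module in modules:
            if rng.random() < spec.module_penetrance:
                mask = rng.random(len(module)) < 0.9
                genes.update(g for g, keep in zip(module, mask) if keep)
        if passengers and spec.passenger_rate > 0:
            # Pareto(alpha=2, x_m=1): heavy tail, finite mean 2
            count = int(round(spec.passenger_rate * (1.0 + rng.pareto(2.0))))
            count = min(count, len(passengers))
            if count > 0:
                genes.update(rng.choice(passengers, size=count, replace=False))
        if not genes:
            pool = passengers if passengers else sorted(set(spec.driver_genes))
            genes.add(str(rng.choice(pool)))
        samples.append((f"S{s:04d}", genes))
    labels = LabelTable(
        {g: "known_driver" for g in spec.driver_genes}
        | {g: "predicted_passenger" for g in passengers}
    )
    return MutationProfileSet(samples), labels


def simulate_ppi(
    modules: list[set[str]],
    other_genes: list[str] | None = None,
    intra_p: float = 0.8,
    inter_p: float = 0.005,
    seed: int = 0,
) -> InteractionGraph:
    """Stochastic block model over the gene universe.

    Gene pairs within the same module are connected with probability
    ``intra_p``; all other pairs (cross-module and any involving
    ``other_genes``) with probability ``inter_p``.
    """
    if not (0.0 <= inter_p <= intra_p <= 1.0):
        raise ValidationError("need 0 <= inter_p <= intra_p <= 1")
    rng = np.random.default_rng(seed)
    block: dict[str, int] = {}
    genes: list[str] = []
    for m, module in enumerate(modules):
        for g in sorted(module):
            block[g] = m
            genes.append(g)
    for g in sorted(other_genes or []):
        block[g] = -1
        genes.append(g)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    blocks = np.array([block[g] for g in genes])
    same = (blocks[iu] == blocks[ju]) & (blocks[iu] >= 0)
    probs = np.where(same, intra_p, inter_p)
    keep = rng.random(iu.size) < probs
    edges = [(genes[i], genes[j]) for i, j in zip(iu[keep], ju[keep])]
    return InteractionGraph(edges)


def simulate_corpus(
    labels: LabelTable,
    n_sentences: int = 1000,
    vocab_extra: list[str] | None = None,
    seed: int = 0,
    genes_per_sentence: int = 3,
    fillers_per_sentence: int = 5,
    fidelity: float = 0.85,
) -> list[list[str]]:
    """Sentences carrying the driver/passenger contextual signal.

    Half the sentences are driver-themed (driver genes + driver-context
    fillers), half passenger-themed; each gene slot draws from the
    theme's pool with probability ``fidelity``, otherwise from the other
    pool, so driver genes co-occur with each other far more often than
    with passengers.  ``vocab_extra`` appends extra neutral filler
    tokens.
    """
    if n_sentences < 1:
        raise ValidationError("n_sentences must be >= 1")
    drivers = sorted(labels.genes_with({"known_driver", "predicted_driver"}))
    passengers = sorted(labels.genes_with("predicted_passenger"))
    if not drivers or not passengers:
        raise ValidationError("corpus simulation needs both driver and passenger genes")
    neutral = NEUTRAL_FILLERS + [t.upper() for t in (vocab_extra or [])]
    rng = np.random.default_rng(seed)
    sentences: list[list[str]] = []
    for s in range(n_sentences):
        driver_theme = s % 2 == 0
        pool, alt = (drivers, passengers) if driver_theme else (passengers, drivers)
        fillers = DRIVER_FILLERS if driver_theme else neutral
        tokens: list[str] = []
        for _ in range(genes_per_sentence):
            src = pool if rng.random() < fidelity else alt
            tokens.append(str(rng.choice(src)))
        tokens.extend(str(rng.choice(fillers)) for _ in range(fillers_per_sentence))
        perm = rng.permutation(len(tokens))
        sentences.append([tokens[i] for i in perm])
    return sentences
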