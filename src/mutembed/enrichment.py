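"""Driver enrichment of clusters and gene-set over-representation.

After k-means clustering of the full mutation-embedding space, the
cluster containing the most driver-labelled genes is scored with the
hypergeometric upper tail: drawing the cluster's n genes from the N
embedded genes, of which K carry the driver label, what is
P(X >= k observed drivers)?  Cluster members without a driver
annotation are the candidate drivers the method proposes.  Gene-set
(pathway) over-representation of a cluster uses the one-sided Fisher
exact test with Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import DRIVER_LABELS, GeneSetCollection, LabelTable, Partition
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    """Counts and p-value of one cluster-vs-population enrichment test."""

    population_size: int  # N: all embedded genes
    population_successes: int  # K: labelled genes among them
    cluster_size: int  # n: genes in the cluster
    cluster_successes: int  # k: labelled genes in the cluster
    p_value: float

    def __post_init__(self) -> None:
        N, K, n, k = (
            self.population_size,
            self.population_successes,
            self.cluster_size,
            self.cluster_successes,
        )
        if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
            raise ValidationError(
                f"inconsistent contingency counts N={N} K={K} n={n} k={k}"
            )


def hypergeom_sf(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in n draws without replacement from a population
    of N containing K successes.  Evaluated in log space by scipy for
    numerical stability at the extreme tails enrichment tests live in.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValidationError(f"invalid hypergeometric parameters N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def most_enriched_cluster(
    partition: Partition,
    labels: LabelTable,
    label_class: str | Iterable[str] = "known_driver",
) -> tuple[int, ContingencyResult]:
    """Select the cluster holding the most genes of ``label_class``.

    Ties break toward the smaller hypergeometric p-value, then the lower
    cluster id.  The test population N is the full set of clustered
    (embedded) genes; K is how many of them carry the label.
    """
    if isinstance(label_class, str):
        label_class = {label_class}
    labelled = labels.genes_with(label_class) & partition.items
    if not labelled:
        raise ValidationError(f"no genes with labels {sorted(label_class)} in the partition")
    N = len(partition)
    K = len(labelled)
    best: tuple[int, float, int] | None = None  # (-count, p, cluster_id)
    best_result: ContingencyResult | None = None
    blocks = partition.blocks()
    for cluster_id in sorted(blocks):
        members = blocks[cluster_id]
        k = len(members & labelled)
        p = hypergeom_sf(N, K, len(members), k)
        key = (-k, p, cluster_id)
        if best is None or key < best:
            best = key
            best_result = ContingencyResult(N, K, len(members), k, p)
    assert best is not None and best_result is not None
    return best[2], best_result


def extract_candidates(cluster_genes: Iterable[str], labels: LabelTable) -> list[str]:
    """Cluster members with no driver annotation, lexicographically sorted."""
    return sorted(
        g for g in cluster_genes if labels.get(g) not in DRIVER_LABELS
    )


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher exact test on [[a, b], [c, d]].

    Identical to the hypergeometric upper tail with N = a+b+c+d,
    K = a+b, n = a+c, k = a.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValidationError("contingency cells must be non-negative")
    return hypergeom_sf(a + b + c + d, a + b, a + c, a)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def geneset_enrichment(
    cluster_genes: Iterable[str],
    sets: GeneSetCollection,
    background: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of each gene set within a cluster.

    For each set: a one-sided Fisher test on (cluster ∩ set,
    cluster \\ set, background-minus-cluster ∩ set, rest), BH-adjusted
    across sets, sorted by adjusted then raw p.  ``overlap`` is
    "members-in-cluster/set-size-in-background".
    """
    cluster = {g.upper() for g in cluster_genes}
    bg = {g.upper() for g in background}
    if not bg:
        raise ValidationError("empty background")
    if not cluster <= bg:
        raise ValidationError("cluster genes must be contained in the background")
    rows = []
    for name, members in sorted(sets.items()):
        members_bg = members & bg
        a = len(cluster & members_bg)
        b = len(cluster - members_bg)
        c = len(members_bg - cluster)
        d = len(bg) - a - b - c
        rows.append(
            {
                "set": name,
                "p_value": fisher_exact_greater(a, b, c, d),
                "overlap": f"{a}/{len(members_bg)}",
                "cluster_hits": a,
                "set_size": len(members_bg),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(
            ["adjusted_p", "p_value", "set"], kind="mergesort"
        ).reset_index(drop=True)
        table = table[["set", "p_value", "adjusted_p", "overlap", "cluster_hits", "set_size"]]
    return table
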