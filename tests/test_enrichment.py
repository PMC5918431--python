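import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from mutembed.containers import GeneSetCollection, LabelTable, Partition
from mutembed.enrichment import (
    bh_adjust,
    extract_candidates,
    fisher_exact_greater,
    geneset_enrichment,
    hypergeom_sf,
    most_enriched_cluster,
)
from mutembed.exceptions import ValidationError


def _sf_oracle(N, K, n, k):
    """Exhaustive enumeration of the upper tail from binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, min(K, n) + 1)
    ) / total


class TestHypergeomSf:
    def test_k_zero_is_one(self):
        assert hypergeom_sf(100, 10, 5, 0) == 1.0

    def test_small_case_enumeration(self):
        # N=10, K=4, n=3, k=2: [C(4,2)C(6,1)+C(4,3)C(6,0)]/C(10,3) = 40/120
        assert hypergeom_sf(10, 4, 3, 2) == pytest.approx(40 / 120, abs=1e-14)

    def test_matches_enumeration_spot_checks(self, rng):
        for _ in range(200):
            N = int(rng.integers(1, 15))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_sf(N, K, n, k) == pytest.approx(
                _sf_oracle(N, K, n, k), rel=1e-12, abs=1e-300
            )

    def test_monotone_non_increasing_in_k(self):
        vals = [hypergeom_sf(50, 10, 8, k) for k in range(9)]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_bound_violations_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_sf(10, 11, 3, 1)
        with pytest.raises(ValidationError):
            hypergeom_sf(10, 4, 3, 4)


class TestMostEnrichedCluster:
    def _labels(self, drivers, passengers):
        return LabelTable(
            {g: "known_driver" for g in drivers}
            | {g: "predicted_passenger" for g in passengers}
        )

    def test_cluster_with_most_drivers_selected(self):
        drivers = [f"D{i}" for i in range(7)]
        passengers = [f"P{i}" for i in range(13)]
        labels = self._labels(drivers, passengers)
        part = Partition.from_blocks(
            [passengers[:5], drivers[:5] + passengers[5:7], drivers[5:] + passengers[7:]]
        )
        cluster_id, res = most_enriched_cluster(part, labels, "known_driver")
        assert cluster_id == 1
        assert res.cluster_successes == 5
        assert res.population_size == 20 and res.population_successes == 7

    def test_tie_broken_by_smaller_p(self):
        drivers = [f"D{i}" for i in range(10)]
        passengers = [f"P{i}" for i in range(50)]
        labels = self._labels(drivers, passengers)
        part = Partition.from_blocks(
            [drivers[:5] + passengers[:45], drivers[5:] + passengers[45:]]
        )
        cluster_id, res = most_enriched_cluster(part, labels, "known_driver")
        assert cluster_id == 1  # same driver count, smaller cluster => smaller p
        assert res.p_value == pytest.approx(hypergeom_sf(60, 10, 10, 5))

    def test_all_drivers_in_minimal_cluster(self):
        drivers = ["D0", "D1", "D2"]
        passengers = [f"P{i}" for i in range(9)]
        labels = self._labels(drivers, passengers)
        part = Partition.from_blocks([drivers, passengers])
        _, res = most_enriched_cluster(part, labels, "known_driver")
        assert res.p_value == pytest.approx(1 / math.comb(12, 3))

    def test_no_labelled_genes_rejected(self):
        labels = self._labels([], ["P0", "P1"])
        part = Partition.from_blocks([["P0"], ["P1"]])
        with pytest.raises(ValidationError):
            most_enriched_cluster(part, labels, "known_driver")


class TestExtractCandidates:
    def test_unlabelled_members_returned_sorted(self):
        labels = LabelTable({"TP53": "known_driver"})
        assert extract_candidates({"TP53", "XYZ", "ABC"}, labels) == ["ABC", "XYZ"]

    def test_all_drivers_gives_empty(self):
        labels = LabelTable({"A": "known_driver", "B": "predicted_driver"})
        assert extract_candidates({"A", "B"}, labels) == []

    def test_cluster_partitions_into_label_groups(self):
        labels = LabelTable(
            {"A": "known_driver", "B": "predicted_driver", "C": "predicted_passenger"}
        )
        cluster = {"A", "B", "C", "D"}
        candidates = extract_candidates(cluster, labels)
        n_known = sum(1 for g in cluster if labels.get(g) == "known_driver")
        n_pred = sum(1 for g in cluster if labels.get(g) == "predicted_driver")
        assert len(candidates) == len(cluster) - n_known - n_pred
        assert candidates == ["C", "D"]


class TestFisher:
    def test_two_by_two_hand_value(self):
        # table [[2,0],[0,2]]: P(X>=2) with N=4, K=2, n=2 -> 1/C(4,2) = 1/6
        assert fisher_exact_greater(2, 0, 0, 2) == pytest.approx(1 / 6)

    def test_a_zero_gives_one(self):
        assert fisher_exact_greater(0, 5, 3, 7) == 1.0

    def test_matches_scipy_greater_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            ours = fisher_exact_greater(a, b, c, d)
            _, scipy_p = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert ours == pytest.approx(scipy_p, rel=1e-9, abs=1e-12)

    def test_equals_hypergeom_mapping(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, 4))
            assert fisher_exact_greater(a, b, c, d) == hypergeom_sf(
                a + b + c + d, a + b, a + c, a
            )


def _bh_oracle(p):
    """Hand step-up: adj_(i) = min_{j>=i} p_(j) m / j, in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_three_values_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_adjusted_ge_raw_and_capped(self, rng):
        p = rng.random(30)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_matches_hand_oracle(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 15)))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(list(p)), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestGenesetEnrichment:
    def test_matching_set_most_significant(self):
        cluster = {f"G{i}" for i in range(5)}
        background = [f"G{i}" for i in range(50)]
        sets = GeneSetCollection(
            {
                "match": set(cluster),
                "random": {f"G{i}" for i in range(10, 20)},
                "partial": {"G0", "G10", "G11"},
            }
        )
        table = geneset_enrichment(cluster, sets, background)
        assert table.iloc[0]["set"] == "match"
        assert table.iloc[0]["overlap"] == "5/5"

    def test_disjoint_set_p_one(self):
        cluster = {"G0", "G1"}
        sets = GeneSetCollection({"far": {"G8", "G9"}})
        table = geneset_enrichment(cluster, sets, [f"G{i}" for i in range(10)])
        assert table.iloc[0]["p_value"] == 1.0

    def test_adjustment_is_bh_of_raw(self, rng):
        background = [f"G{i}" for i in range(40)]
        cluster = set(background[:8])
        sets = GeneSetCollection(
            {f"s{j}": set(rng.choice(background, size=6, replace=False)) for j in range(3)}
        )
        table = geneset_enrichment(cluster, sets, background)
        np.testing.assert_allclose(
            table["adjusted_p"], bh_adjust(table["p_value"].to_numpy()), atol=1e-12
        )

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            geneset_enrichment(set(), GeneSetCollection({"s": {"A"}}), [])

    def test_cluster_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            geneset_enrichment({"A"}, GeneSetCollection({"s": {"A"}}), ["B"])
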