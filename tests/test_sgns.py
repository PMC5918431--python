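import math

import numpy as np
import pytest

from mutembed.containers import GeneVectorTable, MutationProfileSet
from mutembed.contexts import pairs_array, sample_profile_contexts
from mutembed.exceptions import ConfigurationError
from mutembed.sgns import (
    EmbeddingModel,
    SkipGramEmbedder,
    TrainConfig,
    build_vocab,
    init_from_pretrained,
    init_matrices,
    noise_distribution,
    sgns_loss_grad,
    softmax_objective,
    train_sgns,
)


class TestBuildVocab:
    def test_min_count_filters(self):
        profiles = MutationProfileSet(
            [("s1", {"A", "B"}), ("s2", {"A"}), ("s3", {"A", "B"}), ("s4", {"A"})]
        )
        vocab, counts = build_vocab(profiles, min_count=3)
        assert vocab == ["A"] and counts.tolist() == [4]

    def test_min_count_one_keeps_all(self):
        vocab, _ = build_vocab([["a", "b", "a"]], min_count=1)
        assert set(vocab) == {"A", "B"}

    def test_order_count_desc_then_lexicographic(self):
        vocab, counts = build_vocab([["b", "a", "c", "c"]])
        assert vocab == ["C", "A", "B"]
        assert counts.tolist() == [2, 1, 1]

    def test_empty_vocab_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            build_vocab([["a"]], min_count=5)


class TestNoiseDistribution:
    def test_three_quarters_power(self):
        p = noise_distribution(np.array([4.0, 1.0]))
        expected = 4**0.75 / (4**0.75 + 1)
        assert p[0] == pytest.approx(expected, abs=1e-12)
        assert p[0] == pytest.approx(0.7388, abs=1e-4)

    def test_power_zero_is_uniform(self):
        p = noise_distribution(np.array([10.0, 1.0, 5.0]), power=0.0)
        np.testing.assert_allclose(p, 1 / 3)

    def test_equal_counts_uniform_any_power(self):
        p = noise_distribution(np.full(7, 13.0))
        np.testing.assert_allclose(p, 1 / 7)

    def test_sums_to_one(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 1000, size=rng.integers(2, 50))
            assert abs(noise_distribution(counts).sum() - 1.0) < 1e-12


class TestLossGrad:
    def test_zero_dots_one_negative(self):
        u = np.zeros(4)
        loss, *_ = sgns_loss_grad(u, np.zeros(4), np.zeros((1, 4)))
        assert loss == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_strong_positive_no_negative_loss_vanishes(self):
        u = np.ones(3) * 20
        loss, *_ = sgns_loss_grad(u, np.ones(3), np.zeros((0, 3)))
        assert 0 <= loss < 1e-8

    def test_overflow_safe(self):
        u = np.full(2, 500.0)
        loss, gu, *_ = sgns_loss_grad(u, -np.ones(2), np.ones((2, 2)))
        assert np.isfinite(loss) and np.all(np.isfinite(gu))

    def test_gradients_match_central_finite_differences(self, rng):
        """Analytic gradients agree with a finite-difference oracle."""
        eps = 1e-6
        for _ in range(100):
            d = int(rng.integers(2, 8))
            n_neg = int(rng.integers(1, 5))
            u = rng.normal(scale=0.8, size=d)
            v = rng.normal(scale=0.8, size=d)
            negs = rng.normal(scale=0.8, size=(n_neg, d))
            loss, gu, gv, gn = sgns_loss_grad(u, v, negs)

            def f(uu=None, vv=None, nn=None):
                return sgns_loss_grad(
                    u if uu is None else uu,
                    v if vv is None else vv,
                    negs if nn is None else nn,
                )[0]

            for t in range(d):
                e = np.zeros(d)
                e[t] = eps
                assert (f(uu=u + e) - f(uu=u - e)) / (2 * eps) == pytest.approx(
                    gu[t], abs=1e-5
                )
                assert (f(vv=v + e) - f(vv=v - e)) / (2 * eps) == pytest.approx(
                    gv[t], abs=1e-5
                )
            for l in range(n_neg):
                e = np.zeros((n_neg, d))
                e[l, 0] = eps
                assert (f(nn=negs + e) - f(nn=negs - e)) / (2 * eps) == pytest.approx(
                    gn[l, 0], abs=1e-5
                )


class TestSoftmaxObjective:
    def test_zero_parameters_give_uniform(self):
        model = EmbeddingModel(["A", "B"], np.zeros((2, 3)), np.zeros((2, 3)))
        assert softmax_objective(model, [(0, 1)]) == pytest.approx(math.log(0.5))

    def test_matches_hand_enumeration(self, rng):
        U = rng.normal(size=(3, 4))
        V = rng.normal(size=(3, 4))
        model = EmbeddingModel(["A", "B", "C"], U, V)
        pairs = [(0, 1), (1, 2), (2, 0), (0, 2)]
        # independent oracle: explicit softmax sums
        total = 0.0
        for i, j in pairs:
            z = sum(math.exp(float(U[i] @ V[k])) for k in range(3))
            total += math.log(math.exp(float(U[i] @ V[j])) / z)
        assert softmax_objective(model, pairs) == pytest.approx(total / 4, abs=1e-12)

    def test_monotone_in_observed_score(self):
        U = np.zeros((2, 2))
        V = np.zeros((2, 2))
        model = EmbeddingModel(["A", "B"], U, V)
        base = softmax_objective(model, [(0, 1)])
        model.V[1, 0] = 1.0
        model.U[0, 0] = 1.0
        assert softmax_objective(model, [(0, 1)]) > base


class TestInitFromPretrained:
    def _model(self, d=4):
        rng = np.random.default_rng(0)
        U, V = init_matrices(2, d, rng)
        return EmbeddingModel(["TP53", "KRAS"], U, V)

    def test_partial_overwrite(self):
        model = self._model()
        before = model.U.copy()
        table = GeneVectorTable(["TP53"], np.ones((1, 4)))
        assert init_from_pretrained(model, table) == 1
        np.testing.assert_array_equal(model.U[0], np.ones(4))
        np.testing.assert_array_equal(model.U[1], before[1])
        assert np.all(model.V == 0)

    def test_case_insensitive_match(self):
        model = self._model()
        table = GeneVectorTable(["tp53"], np.full((1, 4), 2.0))
        assert init_from_pretrained(model, table) == 1
        np.testing.assert_array_equal(model.U[0], np.full(4, 2.0))

    def test_empty_table_no_change(self):
        model = self._model()
        before = model.U.copy()
        table = GeneVectorTable([], np.empty((0, 4)))
        assert init_from_pretrained(model, table) == 0
        np.testing.assert_array_equal(model.U, before)

    def test_idempotent(self):
        model = self._model()
        table = GeneVectorTable(["KRAS"], np.full((1, 4), 3.0))
        init_from_pretrained(model, table)
        once = model.U.copy()
        init_from_pretrained(model, table)
        np.testing.assert_array_equal(model.U, once)

    def test_dimension_mismatch(self):
        model = self._model(d=4)
        table = GeneVectorTable(["TP53"], np.ones((1, 3)))
        with pytest.raises(ConfigurationError):
            init_from_pretrained(model, table)


def _two_module_cohort(seed=0, n_samples=120, module_size=10):
    rng = np.random.default_rng(seed)
    m1 = [f"A{i:02d}" for i in range(module_size)]
    m2 = [f"B{i:02d}" for i in range(module_size)]
    samples = []
    for s in range(n_samples):
        module = m1 if s % 2 == 0 else m2
        genes = {g for g in module if rng.random() < 0.9}
        if len(genes) < 2:
            genes = set(module[:2])
        samples.append((f"s{s}", genes))
    return MutationProfileSet(samples), m1, m2


class TestTrainSgns:
    def _pairs_and_vocab(self, profiles, seed=0):
        vocab, counts = build_vocab(profiles)
        sets = sample_profile_contexts(profiles, vocab, seed=seed)
        return pairs_array(sets), vocab, counts

    def test_zero_epochs_returns_initialization(self, tiny_profiles):
        pairs, vocab, counts = self._pairs_and_vocab(tiny_profiles)
        config = TrainConfig(dim=8, epochs=0, seed=5)
        model = train_sgns(pairs, vocab, config=config, counts=counts)
        U0, V0 = init_matrices(len(vocab), 8, np.random.default_rng(5))
        np.testing.assert_array_equal(model.U, U0)
        np.testing.assert_array_equal(model.V, V0)

    def test_deterministic_bit_identical(self, tiny_profiles):
        pairs, vocab, counts = self._pairs_and_vocab(tiny_profiles)
        config = TrainConfig(dim=8, epochs=2, seed=9)
        a = train_sgns(pairs, vocab, config=config, counts=counts)
        b = train_sgns(pairs, vocab, config=config, counts=counts)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)

    def test_training_increases_softmax_objective(self, tiny_profiles):
        """SGNS is a consistent surrogate: the exact softmax objective improves."""
        pairs, vocab, counts = self._pairs_and_vocab(tiny_profiles)
        config = TrainConfig(dim=16, epochs=10, negatives_per_pair=5, seed=1)
        before = train_sgns(pairs, vocab, config=TrainConfig(dim=16, epochs=0, seed=1), counts=counts)
        after = train_sgns(pairs, vocab, config=config, counts=counts)
        assert softmax_objective(after, pairs) > softmax_objective(before, pairs)

    def test_planted_modules_separate(self):
        profiles, m1, m2 = _two_module_cohort()
        pairs, vocab, counts = self._pairs_and_vocab(profiles)
        config = TrainConfig(dim=32, epochs=5, seed=2)
        model = train_sgns(pairs, vocab, config=config, counts=counts)
        table = model.vectors()
        X = table.matrix / np.linalg.norm(table.matrix, axis=1, keepdims=True)
        idx = {g: i for i, g in enumerate(vocab)}
        within, between = [], []
        for a in m1:
            for b in m1:
                if a < b:
                    within.append(float(X[idx[a]] @ X[idx[b]]))
            for b in m2:
                between.append(float(X[idx[a]] @ X[idx[b]]))
        assert np.mean(within) > np.mean(between)

    def test_nan_aborts_with_diagnostic(self, tiny_profiles):
        pairs, vocab, counts = self._pairs_and_vocab(tiny_profiles)
        config = TrainConfig(dim=8, epochs=50, lr_initial=200.0, lr_final=100.0, seed=0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            train_sgns(pairs, vocab, config=config, counts=counts)


class TestSkipGramEmbedder:
    def test_sklearn_params_roundtrip(self):
        est = SkipGramEmbedder(dim=12, epochs=1)
        params = est.get_params()
        assert params["dim"] == 12
        est.set_params(epochs=3)
        assert est.epochs == 3

    def test_fit_profiles_exposes_embedding(self, tiny_profiles):
        est = SkipGramEmbedder(dim=8, epochs=1, seed=0)
        est.fit(tiny_profiles)
        assert len(est.vocab_) == len(est.embedding_)
        assert est.embedding_.d == 8

    def test_fit_corpus(self):
        sentences = [["tp53", "drug"], ["kras", "cell"], ["tp53", "kras"]] * 5
        est = SkipGramEmbedder(dim=6, epochs=1, window=2, seed=0)
        est.fit(sentences)
        assert "TP53" in est.embedding_
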