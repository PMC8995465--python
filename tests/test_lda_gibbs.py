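import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import chisquare

from litscape.lda_gibbs import (
    LdaConfig,
    LdaModel,
    fit,
    fold_in,
    log_joint,
    matched_tv_distance,
    perplexity,
    select_k,
    token_streams,
    top_terms,
)
from litscape.synthetic_data import aligned_true_phi
from litscape.text_prep import BowCorpus, Vocabulary


def _corpus(docs, terms):
    vocab = Vocabulary(terms=list(terms), min_df=1, stopwords=frozenset())
    return BowCorpus(
        docs=docs, doc_ids=[f"d{i}" for i in range(len(docs))], vocab=vocab
    )


MICRO_CONFIG = LdaConfig(K=2, alpha=0.5, beta=0.5, n_iterations=30, burn_in=20, seed=0)


def _enumerate_posterior(corpus, config):
    """Exact posterior over all K^N assignment vectors via the collapsed joint."""
    n = token_streams(corpus)[0].shape[0]
    zs = list(itertools.product(range(config.K), repeat=n))
    logps = np.array([log_joint(corpus, z, config) for z in zs])
    p = np.exp(logps - logps.max())
    return zs, p / p.sum()


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"K": 1},
            {"alpha": -0.1},
            {"beta": 0.0},
            {"n_iterations": 10, "burn_in": 10},
            {"sample_every": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            LdaConfig(**kwargs)

    def test_alpha_defaults_to_50_over_k(self):
        assert LdaConfig(K=50).resolved_alpha == pytest.approx(1.0)
        assert LdaConfig(K=10, alpha=0.3).resolved_alpha == 0.3


class TestFit:
    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit(_corpus([], []), MICRO_CONFIG)

    def test_disjoint_vocabularies_recovered(self):
        # two documents over disjoint 5-word vocabularies -> each topic's
        # mass concentrates on one planted word set
        doc1 = {i: 10 for i in range(5)}
        doc2 = {i: 10 for i in range(5, 10)}
        corpus = _corpus([doc1, doc2], [f"t{i}" for i in range(10)])
        config = LdaConfig(
            K=2, alpha=0.1, beta=0.01, n_iterations=200, burn_in=100, seed=3
        )
        model = fit(corpus, config)
        mass_first = model.phi[:, :5].sum(axis=1)
        # one topic owns the first word set, the other the second
        k1 = int(np.argmax(mass_first))
        assert mass_first[k1] >= 0.95
        assert model.phi[1 - k1, 5:].sum() >= 0.95

    def test_single_repeated_word_document(self):
        corpus = _corpus([{0: 20}], ["only"])
        with pytest.warns(UserWarning):  # V < K
            model = fit(corpus, MICRO_CONFIG)
        assert model.theta.sum(axis=1) == pytest.approx(1.0)
        # with a single vocabulary word every topic's phi is that word
        assert model.phi[:, 0] == pytest.approx(1.0)

    def test_row_stochastic_and_counts_conserved(self, clean_bow):
        config = LdaConfig(
            K=5, alpha=0.1, beta=0.01, n_iterations=60, burn_in=30, seed=1
        )
        model = fit(clean_bow, config)
        np.testing.assert_allclose(model.phi.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.theta.sum(axis=1), 1.0, atol=1e-9)
        assert model.n_kw.sum() == clean_bow.n_tokens
        assert model.n_dk.sum() == clean_bow.n_tokens

    def test_seed_determinism(self, micro_corpus):
        m1 = fit(micro_corpus, MICRO_CONFIG)
        m2 = fit(micro_corpus, MICRO_CONFIG)
        assert np.array_equal(m1.z, m2.z)
        np.testing.assert_array_equal(m1.phi, m2.phi)
        m3 = fit(micro_corpus, replace(MICRO_CONFIG, seed=99))
        assert not np.array_equal(m1.phi, m3.phi)

    def test_sampled_assignments_match_enumeration(self, micro_corpus):
        """Gibbs chain endpoints follow the exact collapsed posterior."""
        zs, p = _enumerate_posterior(micro_corpus, MICRO_CONFIG)
        idx = {z: i for i, z in enumerate(zs)}
        n = 4000
        counts = np.zeros(len(zs))
        for seed in range(n):
            model = fit(micro_corpus, replace(MICRO_CONFIG, seed=seed))
            counts[idx[tuple(model.z.tolist())]] += 1
        _, pval = chisquare(counts, p * n)
        assert pval > 0.01


class TestLogJoint:
    def test_enumeration_normalizes(self, micro_corpus):
        _, p = _enumerate_posterior(micro_corpus, MICRO_CONFIG)
        assert p.sum() == pytest.approx(1.0)

    def test_label_swap_symmetry(self, micro_corpus):
        z = [0, 1, 1, 0]
        swapped = [1 - k for k in z]
        a = log_joint(micro_corpus, z, MICRO_CONFIG)
        b = log_joint(micro_corpus, swapped, MICRO_CONFIG)
        assert a == pytest.approx(b)

    def test_length_mismatch_rejected(self, micro_corpus):
        with pytest.raises(ValueError):
            log_joint(micro_corpus, [0, 1], MICRO_CONFIG)


class TestPerplexity:
    def test_uniform_phi_gives_v(self, clean_bow):
        K, V, D = 3, len(clean_bow.vocab), len(clean_bow)
        model = LdaModel(
            phi=np.full((K, V), 1.0 / V),
            theta=np.full((D, K), 1.0 / K),
            z=np.zeros(1, dtype=np.int32),
            n_kw=np.zeros((K, V)),
            n_dk=np.zeros((D, K)),
            config=LdaConfig(K=K),
        )
        assert perplexity(model, clean_bow) == pytest.approx(V, rel=1e-9)

    def test_single_word_vocabulary_gives_one(self):
        corpus = _corpus([{0: 5}], ["only"])
        model = LdaModel(
            phi=np.ones((2, 1)),
            theta=np.full((1, 2), 0.5),
            z=np.zeros(1, dtype=np.int32),
            n_kw=np.zeros((2, 1)),
            n_dk=np.zeros((1, 2)),
            config=LdaConfig(K=2),
        )
        assert perplexity(model, corpus) == pytest.approx(1.0)

    def test_fitted_beats_uniform(self, clean_bow):
        config = LdaConfig(
            K=5, alpha=0.1, beta=0.01, n_iterations=120, burn_in=60, seed=2
        )
        model = fit(clean_bow, config)
        assert perplexity(model, clean_bow) < len(clean_bow.vocab)

    def test_zero_probability_advises_beta(self, micro_corpus):
        model = LdaModel(
            phi=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            theta=np.array([[1.0, 0.0], [1.0, 0.0]]),
            z=np.zeros(1, dtype=np.int32),
            n_kw=np.zeros((2, 3)),
            n_dk=np.zeros((2, 2)),
            config=LdaConfig(K=2),
        )
        with pytest.raises(ValueError, match="beta > 0"):
            perplexity(model, micro_corpus)


class TestSelectK:
    CONFIG = LdaConfig(
        K=5, alpha=0.1, beta=0.01, n_iterations=150, burn_in=75, seed=11
    )

    def test_single_candidate(self, clean_bow):
        table = select_k(clean_bow, [3], self.CONFIG)
        assert list(table["K"]) == [3]
        assert table["heldout_perplexity"].iloc[0] > 1

    def test_true_k_beats_underfit(self, clean_bow):
        table = select_k(clean_bow, [2, 5], self.CONFIG)
        pp = dict(zip(table["K"], table["heldout_perplexity"]))
        assert pp[5] <= pp[2]

    def test_deterministic(self, clean_bow):
        t1 = select_k(clean_bow, [3], self.CONFIG)
        t2 = select_k(clean_bow, [3], self.CONFIG)
        assert t1.equals(t2)

    def test_too_small_corpus(self, micro_corpus):
        single = _corpus([{0: 1}], ["a"])
        with pytest.raises(ValueError):
            select_k(single, [2], self.CONFIG)


class TestTopTerms:
    @pytest.fixture(scope="class")
    def model(self, clean_bow):
        config = LdaConfig(
            K=4, alpha=0.1, beta=0.01, n_iterations=40, burn_in=20, seed=4
        )
        return fit(clean_bow, config)

    def test_zero_and_full(self, model):
        assert top_terms(model, 0, 0) == []
        full = top_terms(model, 0, model.V)
        assert len(full) == model.V
        assert sum(p for _, p in full) == pytest.approx(1.0)

    def test_matches_brute_force_sort(self, model):
        got = top_terms(model, 1, 10)
        pairs = sorted(
            zip(model.terms, model.phi[1]), key=lambda tp: (-tp[1], tp[0])
        )
        assert got == [(t, pytest.approx(p)) for t, p in pairs[:10]]

    def test_out_of_range(self, model):
        with pytest.raises(ValueError):
            top_terms(model, model.K, 3)


class TestRecovery:
    def test_planted_topics_recovered(self, clean_corpus_pair, clean_bow):
        _, truth = clean_corpus_pair
        config = LdaConfig(
            K=5, alpha=0.1, beta=0.01, n_iterations=400, burn_in=200, seed=7
        )
        model = fit(clean_bow, config)
        phi_true = aligned_true_phi(truth, clean_bow.vocab)
        assert matched_tv_distance(phi_true, model.phi) < 0.1

    def test_tv_distance_identity_and_permutation(self, rng):
        phi = rng.dirichlet(np.ones(6), size=3)
        assert matched_tv_distance(phi, phi) == pytest.approx(0.0)
        assert matched_tv_distance(phi, phi[::-1]) == pytest.approx(0.0)


def test_fold_in_rows_stochastic(clean_bow):
    config = LdaConfig(K=4, alpha=0.1, beta=0.01, n_iterations=40, burn_in=20, seed=9)
    model = fit(clean_bow, config)
    theta = fold_in(model, clean_bow, n_sweeps=10, seed=1)
    np.testing.assert_allclose(theta.sum(axis=1), 1.0, atol=1e-9)
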