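"""LDA engine: derived matrices, determinism, separability, top terms."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from genetopics import (
    ConfigurationError,
    LdaConfig,
    fit_from_assignments,
    fit_lda,
    top_terms,
    topic_proportions,
    word_count_matrix,
)


def _fit(words, zs, k, vocab_size):
    return fit_from_assignments(
        [np.asarray(w) for w in words],
        [np.asarray(z) for z in zs],
        k,
        vocab_size,
    )


def _two_vocab_tdm(n_docs=20, doc_len=30, vocab_half=20, seed=0):
    """Documents use vocabulary A xor vocabulary B."""
    rng = np.random.default_rng(seed)
    vocab = 2 * vocab_half
    tdm = np.zeros((vocab, n_docs), dtype=np.int64)
    for d in range(n_docs):
        lo = 0 if d % 2 == 0 else vocab_half
        for w in rng.integers(lo, lo + vocab_half, size=doc_len):
            tdm[w, d] += 1
    return sp.csr_matrix(tdm)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            LdaConfig(k=1)
        with pytest.raises(ConfigurationError):
            LdaConfig(k=3, alpha=0.0)
        with pytest.raises(ConfigurationError):
            LdaConfig(k=3, eta=float("nan"))
        with pytest.raises(ConfigurationError):
            LdaConfig(k=3, iterations=10, burn_in=10)

    def test_default_alpha_is_50_over_k(self):
        assert LdaConfig(k=25).effective_alpha == 2.0


class TestDerivedMatrices:
    def test_worked_example_100_tokens_40_60(self):
        """100-token document, 40 tokens in topic 0 and 60 in topic 1,
        gives proportions exactly 0.4 / 0.6 / 0 elsewhere."""
        zs = [0] * 40 + [1] * 60
        fit = _fit([list(range(100))], [zs], k=4, vocab_size=100)
        assert np.array_equal(
            fit.topic_proportion_matrix[0], [0.4, 0.6, 0.0, 0.0]
        )
        assert np.array_equal(fit.word_count_matrix[0], [40, 60, 0, 0])

    def test_word_count_rows(self):
        fit = _fit([[5, 6, 7]], [[0, 0, 1]], k=2, vocab_size=10)
        assert np.array_equal(word_count_matrix(fit)[0], [2, 1])

    def test_single_topic_document(self):
        fit = _fit([[1, 2, 3]], [[1, 1, 1]], k=3, vocab_size=5)
        assert np.array_equal(topic_proportions(fit)[0], [0, 1, 0])

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(3)
        words = [rng.integers(0, 30, size=n) for n in (5, 17, 9)]
        zs = [rng.integers(0, 4, size=len(w)) for w in words]
        fit = _fit(words, zs, k=4, vocab_size=30)
        for d, (w, z) in enumerate(zip(words, zs)):
            for j in range(4):
                assert fit.word_count_matrix[d, j] == int(np.sum(z == j))
        twc = np.zeros((4, 30), dtype=int)
        for w, z in zip(words, zs):
            for wi, zi in zip(w, z):
                twc[zi, wi] += 1
        assert np.array_equal(fit.topic_word_counts, twc)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.data())
    def test_proportion_rows_always_sum_to_one(self, data):
        k = data.draw(st.integers(2, 5))
        n_docs = data.draw(st.integers(1, 6))
        words, zs = [], []
        for _ in range(n_docs):
            n = data.draw(st.integers(1, 20))
            words.append(data.draw(
                st.lists(st.integers(0, 9), min_size=n, max_size=n)))
            zs.append(data.draw(
                st.lists(st.integers(0, k - 1), min_size=n, max_size=n)))
        fit = _fit(words, zs, k=k, vocab_size=10)
        sums = fit.topic_proportion_matrix.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert fit.topic_word_counts.sum() == fit.word_count_matrix.sum()

    def test_permuting_documents_permutes_rows(self):
        rng = np.random.default_rng(5)
        words = [rng.integers(0, 12, size=n) for n in (4, 7, 3, 9)]
        zs = [rng.integers(0, 3, size=len(w)) for w in words]
        fit = _fit(words, zs, k=3, vocab_size=12)
        perm = [2, 0, 3, 1]
        fit_p = _fit([words[i] for i in perm], [zs[i] for i in perm],
                     k=3, vocab_size=12)
        assert np.array_equal(
            fit_p.topic_proportion_matrix, fit.topic_proportion_matrix[perm]
        )
        assert np.array_equal(fit_p.topic_word_counts, fit.topic_word_counts)


class TestFitLda:
    def test_disjoint_vocabularies_separate(self):
        tdm = _two_vocab_tdm()
        fit = fit_lda(tdm, LdaConfig(k=2, alpha=0.5, iterations=400,
                                     burn_in=200, seed=9))
        dominant = fit.topic_proportion_matrix.max(axis=1)
        assert np.all(dominant > 0.9)

    def test_single_token_corpus_degenerate(self):
        tdm = sp.csr_matrix(np.array([[1]]))
        fit = fit_lda(tdm, LdaConfig(k=2, iterations=20, burn_in=10, seed=0))
        row = fit.topic_proportion_matrix[0]
        assert sorted(row) == [0.0, 1.0]

    def test_seed_reproducibility(self):
        tdm = _two_vocab_tdm(seed=2)
        cfg = LdaConfig(k=3, iterations=60, burn_in=30, seed=123)
        a = fit_lda(tdm, cfg)
        b = fit_lda(tdm, cfg)
        for za, zb in zip(a.assignments, b.assignments):
            assert np.array_equal(za, zb)

    def test_argmax_mode_runs_and_conserves(self):
        tdm = _two_vocab_tdm(seed=4)
        cfg = LdaConfig(k=2, iterations=60, burn_in=30, seed=1,
                        assignment_mode="argmax")
        fit = fit_lda(tdm, cfg)
        assert fit.word_count_matrix.sum() == tdm.sum()

    def test_k_exceeding_token_count_warns_and_conserves(self, caplog):
        tdm = sp.csr_matrix(np.array([[1], [1]]))  # 2 tokens
        fit = fit_lda(tdm, LdaConfig(k=3, iterations=10, burn_in=5, seed=0))
        assert any("exceeds the corpus token count" in r.message
                   for r in caplog.records)
        assert fit.word_count_matrix.sum() == 2

    def test_planted_topics_recovered_by_top_terms(self):
        """Corpus drawn from 4 well-separated topics: greedy matching of
        fitted to true topics reaches mean top-20-term Jaccard >= 0.5."""
        rng = np.random.default_rng(8)
        k, vocab = 4, 400
        truth = rng.dirichlet(np.full(vocab, 0.02), size=k)
        tdm = np.zeros((vocab, 160), dtype=np.int64)
        for d in range(160):
            mix = np.full(k, 0.05 / 3)
            mix[d % k] = 0.95
            topics = rng.choice(k, size=60, p=mix)
            for t in range(k):
                n = int(np.sum(topics == t))
                if n:
                    for w in rng.choice(vocab, size=n, p=truth[t]):
                        tdm[w, d] += 1
        fit = fit_lda(sp.csr_matrix(tdm),
                      LdaConfig(k=k, iterations=300, burn_in=150, seed=3))
        vocab_names = [f"w{i}" for i in range(vocab)]
        true_top = [
            set(np.argsort(-truth[t])[:20].tolist()) for t in range(k)
        ]
        fitted_top = [
            {vocab_names.index(w) for w in
             top_terms(fit, t, 20, vocab_names)}
            for t in range(k)
        ]
        pairs = sorted(
            ((len(a & b) / len(a | b), i, j)
             for i, a in enumerate(fitted_top)
             for j, b in enumerate(true_top)),
            reverse=True,
        )
        used_i, used_j, scores = set(), set(), []
        for jac, i, j in pairs:
            if i not in used_i and j not in used_j:
                used_i.add(i)
                used_j.add(j)
                scores.append(jac)
        assert np.mean(scores) >= 0.5


class TestTopTerms:
    def test_tie_break_by_stem_string(self):
        fit = _fit([[0, 0, 0, 0, 0, 1, 1, 1, 2, 2, 2]],
                   [[0] * 11], k=2, vocab_size=3)
        assert top_terms(fit, 0, 3, ["a", "c", "b"]) == ["a", "b", "c"]

    def test_truncates_to_nonzero_stems(self):
        fit = _fit([[0, 1]], [[0, 0]], k=2, vocab_size=5)
        assert len(top_terms(fit, 0, 10, list("abcde"))) == 2
        assert top_terms(fit, 1, 10, list("abcde")) == []

    def test_surface_mapping_applied(self):
        fit = _fit([[0, 0, 1]], [[0, 0, 0]], k=2, vocab_size=2)
        out = top_terms(fit, 0, 2, ["activ", "bind"],
                        {"activ": "activity", "bind": "binding"})
        assert out == ["activity", "binding"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(12)
        words = rng.integers(0, 25, size=200)
        zs = rng.integers(0, 3, size=200)
        fit = _fit([words], [zs], k=3, vocab_size=25)
        vocab = [f"s{i:02d}" for i in range(25)]
        for t in range(3):
            counts = fit.topic_word_counts[t]
            oracle = [
                vocab[i]
                for i in sorted(range(25), key=lambda i: (-counts[i], vocab[i]))
                if counts[i] > 0
            ][:10]
            assert top_terms(fit, t, 10, vocab) == oracle
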