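"""Gene-topic matrix and the binomial specificity test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

from genetopics import (
    ConfigurationError,
    Corpus,
    GeneTopicMatrix,
    WorkingGeneSet,
    enrichment_test,
    fit_from_assignments,
    gene_topic_matrix,
    score_distributions,
)


def _fit_with_props(props):
    """Build a fit whose topic proportions equal ``props`` exactly."""
    props = np.asarray(props, dtype=float)
    n_docs, k = props.shape
    words, zs = [], []
    for row in props:
        counts = np.round(row * 10).astype(int)  # rows in tenths
        z = np.repeat(np.arange(k), counts)
        zs.append(z)
        words.append(np.zeros(len(z), dtype=int))
    return fit_from_assignments(words, zs, k=k, n_vocab=1)


def _corpus(doc_gene_pairs):
    docs = [d for d, _ in doc_gene_pairs]
    return Corpus(
        documents=docs,
        doc_genes={d: set(gs) for d, gs in doc_gene_pairs},
        texts={d: "x" for d in docs},
        tokens=[np.zeros(1, dtype=int) for _ in docs],
        vocab=["x"],
        stem_to_surface={"x": "x"},
    )


def _gtm(input_scores, random_scores):
    scores = np.vstack([input_scores, random_scores]).astype(float)
    n_i = len(input_scores)
    genes = [f"I{i}" for i in range(n_i)] + [
        f"R{i}" for i in range(len(random_scores))
    ]
    ws = WorkingGeneSet(
        input_genes=genes[:n_i], random_genes=genes[n_i:],
    )
    return GeneTopicMatrix(genes=genes, n_input=n_i, scores=scores), ws


class TestGeneTopicMatrix:
    def test_max_reduction(self):
        fit = _fit_with_props([[0.4, 0.6], [0.9, 0.1]])
        corpus = _corpus([("d0", ["G1"]), ("d1", ["G1"])])
        ws = WorkingGeneSet(input_genes=["G1"], random_genes=[])
        gtm = gene_topic_matrix(fit, corpus, ws)
        assert np.allclose(gtm.scores[0], [0.9, 0.6])

    def test_single_document_gene(self):
        fit = _fit_with_props([[0.3, 0.7]])
        corpus = _corpus([("d0", ["G1"])])
        ws = WorkingGeneSet(input_genes=["G1"], random_genes=[])
        gtm = gene_topic_matrix(fit, corpus, ws)
        assert np.allclose(gtm.scores[0], [0.3, 0.7])

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(21)
        k, n_docs = 4, 30
        counts = np.array([
            rng.multinomial(10, rng.dirichlet(np.ones(k)))
            for _ in range(n_docs)
        ])
        fit = _fit_with_props(counts / 10)  # exact tenths
        genes = [f"G{i}" for i in range(8)]
        membership = [
            (f"d{d}", [g for g in genes if rng.random() < 0.35] or [genes[0]])
            for d in range(n_docs)
        ]
        corpus = _corpus(membership)
        ws = WorkingGeneSet(input_genes=genes[:5], random_genes=genes[5:])
        gtm = gene_topic_matrix(fit, corpus, ws)
        props_fit = fit.topic_proportion_matrix
        for gi, g in enumerate(gtm.genes):
            for j in range(k):
                expected = max(
                    props_fit[d, j]
                    for d, (doc, gs) in enumerate(membership)
                    if g in gs
                )
                assert gtm.scores[gi, j] == pytest.approx(expected, abs=1e-12)

    def test_gene_with_no_surviving_docs_moved_to_excluded(self, caplog):
        fit = _fit_with_props([[1.0, 0.0]])
        corpus = _corpus([("d0", ["G1"])])  # G2's documents all dropped
        ws = WorkingGeneSet(input_genes=["G1", "G2"], random_genes=[])
        gtm = gene_topic_matrix(fit, corpus, ws)
        assert ws.excluded_genes == {"G2"}
        assert gtm.genes == ["G1"]
        assert any("all dropped" in r.message for r in caplog.records)


class TestEnrichment:
    def test_zero_high_input_genes_gives_p_one(self):
        gtm, ws = _gtm(np.zeros((6, 2)), np.full((6, 2), 0.9))
        for r in enrichment_test(gtm, ws):
            assert r.n_input_high == 0
            assert r.p_raw == 1.0
            assert not r.significant

    def test_binomial_against_direct_summation(self):
        """n=10, x=8, 1 of 10 random genes high: smoothed null 2/12."""
        inp = np.zeros((10, 1))
        inp[:8, 0] = 0.8
        rnd = np.zeros((10, 1))
        rnd[0, 0] = 0.7
        gtm, ws = _gtm(inp, rnd)
        (r,) = enrichment_test(gtm, ws)
        p0 = 2.0 / 12.0
        oracle = sum(
            comb(10, i, exact=True) * p0**i * (1 - p0) ** (10 - i)
            for i in range(8, 11)
        )
        assert r.null_p == pytest.approx(p0, abs=1e-15)
        assert r.p_raw == pytest.approx(oracle, abs=1e-12)

    def test_everything_high_is_not_significant(self):
        gtm, ws = _gtm(np.full((8, 1), 0.9), np.full((8, 1), 0.9))
        (r,) = enrichment_test(gtm, ws)
        assert not r.significant
        assert r.p_raw > 0.4

    def test_member_genes_are_high_scoring_input_genes(self):
        inp = np.array([[0.9], [0.51], [0.5], [0.1]])
        rnd = np.zeros((4, 1))
        gtm, ws = _gtm(inp, rnd)
        (r,) = enrichment_test(gtm, ws, threshold=0.5)
        assert r.member_genes == {"I0", "I1"}  # strict > 0.5

    def test_raw_smoothing_uses_unsmoothed_null(self):
        inp = np.full((5, 1), 0.9)
        rnd = np.zeros((5, 1))
        gtm, ws = _gtm(inp, rnd)
        (r,) = enrichment_test(gtm, ws, smoothing="raw")
        assert r.null_p == 0.0
        assert r.p_raw == pytest.approx(0.0, abs=1e-300)

    def test_bonferroni_scales_with_k(self):
        inp = np.hstack([np.full((6, 1), 0.9), np.zeros((6, 3))])
        rnd = np.zeros((6, 4))
        gtm, ws = _gtm(inp, rnd)
        results = enrichment_test(gtm, ws)
        assert results[0].p_bonferroni == pytest.approx(
            min(1.0, results[0].p_raw * 4)
        )
        for r in results:
            assert r.p_raw <= r.p_bonferroni <= 1.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n=st.integers(2, 40),
        x=st.integers(0, 40),
        rhigh=st.integers(0, 15),
        nrand=st.integers(1, 15),
    )
    def test_p_raw_monotone_decreasing_in_x(self, n, x, rhigh, nrand):
        from genetopics.scoring import _binomial_p

        x = min(x, n)
        rhigh = min(rhigh, nrand)
        p0 = (rhigh + 1) / (nrand + 2)
        if x < n:
            assert _binomial_p(x + 1, n, p0) <= _binomial_p(x, n, p0) + 1e-12

    def test_alternative_tests_order_planted_topic_first(self):
        rng = np.random.default_rng(2)
        inp = np.clip(rng.normal(0.7, 0.1, size=(12, 2)), 0, 1)
        inp[:, 1] = rng.uniform(0, 0.3, size=12)
        rnd = rng.uniform(0, 0.3, size=(12, 2))
        gtm, ws = _gtm(inp, rnd)
        for test in ("ks", "wilcoxon"):
            res = enrichment_test(gtm, ws, test=test)
            assert res[0].p_raw < res[1].p_raw

    def test_invalid_parameters_rejected(self):
        gtm, ws = _gtm(np.zeros((3, 1)), np.zeros((3, 1)))
        with pytest.raises(ConfigurationError):
            enrichment_test(gtm, ws, threshold=0.0)
        with pytest.raises(ConfigurationError):
            enrichment_test(gtm, ws, smoothing="bogus")


class TestCalibration:
    def test_false_positive_rate_bounded_on_null_corpora(self):
        """With the input genes themselves drawn at random (no planted
        structure), at most 10% of 200 simulated corpora may yield any
        significant topic at corrected 0.05."""
        from genetopics import (
            FixtureSpec, LdaConfig, assemble_corpus, build_working_set,
            fit_lda, generate_fixture, preprocess, term_document_matrix,
        )

        false_positive = 0
        n_runs = 200
        for seed in range(n_runs):
            fx = generate_fixture(FixtureSpec(
                n_topics_true=4, vocab_size=120, n_gene_groups=0,
                genes_per_group=0, n_background_genes=20, docs_per_gene=3,
                doc_length_mean=20, seed=seed,
            ))
            ws = build_working_set(fx.input_genes, fx.index, seed=seed)
            corpus = preprocess(assemble_corpus(ws, fx.index, n_docs=3))
            fit = fit_lda(
                term_document_matrix(corpus),
                LdaConfig(k=4, iterations=120, burn_in=60, seed=seed),
            )
            gtm = gene_topic_matrix(fit, corpus, ws)
            results = enrichment_test(gtm, ws)
            false_positive += any(r.significant for r in results)
        assert false_positive / n_runs <= 0.10


class TestScoreDistributions:
    def test_lengths_and_permutation(self):
        rng = np.random.default_rng(9)
        inp = rng.uniform(size=(7, 3))
        rnd = rng.uniform(size=(5, 3))
        gtm, ws = _gtm(inp, rnd)
        a, b = score_distributions(gtm, ws, topic=1)
        assert len(a) == 7 and len(b) == 5
        assert sorted(np.concatenate([a, b])) == pytest.approx(
            sorted(gtm.scores[:, 1])
        )

    def test_planted_topic_separates_means(self, small_planted):
        fx, options, report = small_planted
        assert report.topics, "planted fixture should yield significant topics"
        # scores of the planted topic separate input from random genes
        top = report.topics[0]
        member_scores = [m.score for m in top.members]
        assert np.mean(member_scores) > 0.5
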