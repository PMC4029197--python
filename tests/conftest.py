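"""Shared fixtures: tiny in-memory indexes and a small planted run.

Everything is generated programmatically; no data files ship with the
tests.
"""

from __future__ import annotations

import pytest

from genetopics import (
    DocRecord,
    FixtureSpec,
    GeneDocIndex,
    GeneDocLink,
    PipelineOptions,
    generate_fixture,
    run_pipeline,
)


def make_index(links, docs):
    """Build a GeneDocIndex from (gene, doc_id, relevancy) and
    (doc_id, year, title, abstract) tuples."""
    return GeneDocIndex(
        links=[GeneDocLink(g.upper(), d, r) for g, d, r in links],
        docs={d: DocRecord(d, y, t, a) for d, y, t, a in docs},
    )


@pytest.fixture
def tiny_index():
    """Three genes, five documents, mixed years and relevancies."""
    docs = [
        ("d1", 1990, "Old glycolysis study", "Enzyme kinetics in yeast."),
        ("d2", 2000, "Insulin signaling", "Receptor binding and glucose uptake."),
        ("d3", 2005, "Beta cell function", "Insulin secretion in islets."),
        ("d4", 2010, "Lipid metabolism", "Cholesterol transport pathways."),
        ("d5", 2015, "Glucose transport", "GLUT4 translocation in muscle."),
    ]
    links = [
        ("INS", "d1", 0.9),
        ("INS", "d2", 0.8),
        ("INS", "d3", 0.7),
        ("GCK", "d2", 0.6),
        ("GCK", "d5", 0.6),
        ("LDLR", "d4", 1.0),
    ]
    return make_index(links, docs)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted fixture plus one pipeline run at the true k."""
    spec = FixtureSpec(
        n_topics_true=3,
        vocab_size=300,
        n_gene_groups=2,
        genes_per_group=8,
        n_background_genes=16,
        docs_per_gene=5,
        doc_length_mean=40,
        purity=0.85,
        seed=7,
    )
    fx = generate_fixture(spec)
    options = PipelineOptions(seed=7, grid=(3,), iterations=400, burn_in=200)
    report = run_pipeline(fx.input_genes, fx.index, options)
    return fx, options, report
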