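"""Choose the number of topics by scanning a grid.

Fits one LDA model per grid point, counts topics significant for the
input genes, and stops once the count no longer increases; the selected
k is the evaluated point with the most significant topics.
"""

from genetopics import (
    FixtureSpec,
    LdaConfig,
    assemble_corpus,
    build_working_set,
    generate_fixture,
    preprocess,
    search_topic_number,
)

fx = generate_fixture(FixtureSpec(
    n_topics_true=4, vocab_size=400, n_gene_groups=3, genes_per_group=8,
    n_background_genes=24, docs_per_gene=5, doc_length_mean=35,
    purity=0.85, seed=7,
))

ws = build_working_set(fx.input_genes, fx.index, seed=7)
corpus = preprocess(assemble_corpus(ws, fx.index, n_docs=5))
print(f"corpus: {len(corpus.documents)} documents, "
      f"{len(corpus.vocab)} stems, {corpus.total_tokens()} tokens")

trace = search_topic_number(
    corpus, ws, grid=[4, 8, 12, 16],
    base_config=LdaConfig(k=4, iterations=500, burn_in=250, seed=7),
)

for ev in trace.evaluated:
    marker = "  <- selected" if ev.k == trace.selected_k else ""
    print(f"k={ev.k:>3}: {ev.n_significant} significant topics{marker}")
print(f"stopped because of {trace.stop_reason}; "
      f"the earliest maximum wins ties.")
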