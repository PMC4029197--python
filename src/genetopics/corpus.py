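"""Corpus construction around a working gene set.

The working gene set G_w is the union of the input genes G_i and an
equal-sized random gene set G_r drawn (seeded, without replacement) from a
background population. G_r embeds known noise in the corpus: topics driven
by it, or equally by it and G_i, are not specific to the input and are
discarded later by the enrichment test.

For every gene in G_w, up to ``n_docs`` documents are sampled from the
index (default 50, balancing computation against over-representation of
well-studied genes); titles and abstracts are concatenated, documents
shared between genes are kept once with back-links to all selecting genes,
and the text is preprocessed: lowercase, strip punctuation characters,
tokenize on whitespace, drop stopwords, Porter-stem. Hyphens and slashes
are deleted rather than replaced (fusing e.g. "enoyl-CoA" to "enoylcoa")
and numeric tokens are retained. Both the stemmed vocabulary and a
stem -> most-frequent-surface-form map are kept so reports remain readable.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError
from .index import GeneDocIndex, canonical_gene, sample_documents
from .stem import stem

logger = logging.getLogger(__name__)

_PUNCT_RE = re.compile(r"[^a-z0-9\s]")


@dataclass
class WorkingGeneSet:
    """Input genes G_i, random comparison genes G_r, and excluded genes.

    All symbols are canonical (uppercase); ``display`` maps them back to
    the surface forms used in reports. ``excluded_genes`` are input genes
    with no usable documents; they carry no literature signal and are not
    counted in enrichment denominators.
    """

    input_genes: list[str]
    random_genes: list[str]
    excluded_genes: set[str] = field(default_factory=set)
    display: dict[str, str] = field(default_factory=dict)

    @property
    def working_genes(self) -> list[str]:
        return self.input_genes + self.random_genes


@dataclass
class Corpus:
    """Deduplicated documents with gene back-links and (after
    :func:`preprocess`) stemmed token streams.

    ``tokens[i]`` is an integer array indexing ``vocab`` for document
    ``documents[i]``; ``stem_to_surface`` maps each stem to its most
    frequent pre-stemming surface form.
    """

    documents: list[str]
    doc_genes: dict[str, set[str]]
    texts: dict[str, str]
    tokens: list[np.ndarray] | None = None
    vocab: list[str] | None = None
    stem_to_surface: dict[str, str] | None = None

    @property
    def is_preprocessed(self) -> bool:
        return self.tokens is not None

    def total_tokens(self) -> int:
        if self.tokens is None:
            raise ConfigurationError("corpus is not preprocessed")
        return int(sum(len(t) for t in self.tokens))


def load_stopwords(path: str | Path | None = None) -> set[str]:
    """Load a stopword list (one word per line, '#' comments allowed).

    Without a path, the packaged default English list is used.
    """
    if path is None:
        text = (
            resources.files("genetopics.data")
            .joinpath("stopwords_en.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return words


def read_gene_list(path: str | Path) -> list[str]:
    """Read an input gene list: one symbol per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    if not genes:
        raise ConfigurationError(f"{path}: no gene symbols found")
    return genes


def build_working_set(
    input_genes: list[str],
    index: GeneDocIndex,
    background: set[str] | None = None,
    seed: int = 0,
) -> WorkingGeneSet:
    """Draw G_r and assemble the working gene set G_w = G_i + G_r.

    Input genes with no documents in the index are moved to
    ``excluded_genes``. The random genes are drawn uniformly without
    replacement, seeded, from ``background`` (default: every gene in the
    index) excluding the input genes. When the eligible pool is smaller
    than the usable input set the draw is capped at the pool size with a
    warning; an empty pool is a configuration error.
    """
    display: dict[str, str] = {}
    seen: set[str] = set()
    canon_input: list[str] = []
    for g in input_genes:
        c = canonical_gene(g)
        if not c or any(ch.isspace() for ch in c):
            raise ConfigurationError(f"invalid gene symbol {g!r}")
        if c not in seen:
            seen.add(c)
            canon_input.append(c)
            display[c] = g.strip()

    usable = [g for g in canon_input if index.gene_links(g)]
    excluded = set(canon_input) - set(usable)
    if excluded:
        logger.warning(
            "excluding %d input genes with no documents: %s",
            len(excluded), ", ".join(sorted(excluded)),
        )
    if not usable:
        raise ConfigurationError("every input gene lacks documents in the index")

    if background is None:
        pool_set = set(index.background)
    else:
        pool_set = {canonical_gene(g) for g in background}
        outside = pool_set - set(index.background)
        if outside:
            logger.warning(
                "ignoring %d background genes absent from the index", len(outside)
            )
            pool_set -= outside
    pool = sorted(pool_set - set(canon_input))
    if not pool:
        raise ConfigurationError(
            "no background genes available outside the input gene set"
        )
    draw = min(len(usable), len(pool))
    if draw < len(usable):
        logger.warning(
            "background pool (%d genes) smaller than input set (%d); "
            "drawing %d random genes", len(pool), len(usable), draw,
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=draw, replace=False)
    random_genes = [pool[i] for i in chosen]
    for g in random_genes:
        display.setdefault(g, index.display.get(g, g))
    return WorkingGeneSet(
        input_genes=usable,
        random_genes=random_genes,
        excluded_genes=excluded,
        display=display,
    )


def assemble_corpus(
    ws: WorkingGeneSet,
    index: GeneDocIndex,
    n_docs: int = 50,
    sample_mode: str = "top",
    seed: int = 0,
) -> Corpus:
    """Sample documents for every working gene and deduplicate them.

    A document selected by several genes appears once, with every
    selecting gene recorded in ``doc_genes``. Document text is the title
    concatenated with the abstract.
    """
    documents: list[str] = []
    doc_genes: dict[str, set[str]] = {}
    texts: dict[str, str] = {}
    for gene in ws.working_genes:
        ids = sample_documents(index, gene, n_docs, mode=sample_mode, seed=seed)
        if not ids:
            raise ConfigurationError(f"gene {gene} has no documents to sample")
        for doc_id in ids:
            if doc_id not in doc_genes:
                doc_genes[doc_id] = set()
                documents.append(doc_id)
                texts[doc_id] = index.docs[doc_id].text
            doc_genes[doc_id].add(gene)
    return Corpus(documents=documents, doc_genes=doc_genes, texts=texts)


def tokenize(text: str, stopwords: set[str]) -> list[str]:
    """Lowercase, strip punctuation, split, drop stopwords (pre-stemming)."""
    lowered = _PUNCT_RE.sub("", text.lower())
    return [t for t in lowered.split() if t and t not in stopwords]


def preprocess(corpus: Corpus, stopwords: set[str] | None = None) -> Corpus:
    """Tokenize and Porter-stem every document of the corpus.

    Documents reduced to zero tokens are dropped with a warning and
    removed from the gene back-links. Numeric tokens are retained. The
    surface form recorded for each stem is the most frequent one, ties
    broken by the lexicographically smallest.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    stem_cache: dict[str, str] = {}
    surface_counts: dict[str, Counter] = {}
    doc_stems: list[list[str]] = []
    kept_docs: list[str] = []
    dropped = 0
    for doc_id in corpus.documents:
        words = tokenize(corpus.texts[doc_id], stopwords)
        stems = []
        for w in words:
            s = stem_cache.get(w)
            if s is None:
                s = stem_cache[w] = stem(w)
            if not s:
                continue
            stems.append(s)
            surface_counts.setdefault(s, Counter())[w] += 1
        if not stems:
            dropped += 1
            continue
        kept_docs.append(doc_id)
        doc_stems.append(stems)
    if dropped:
        logger.warning("dropped %d documents with no tokens after preprocessing", dropped)
    if not kept_docs:
        raise ConfigurationError("preprocessing removed every document")

    vocab = sorted({s for stems in doc_stems for s in stems})
    vindex = {s: i for i, s in enumerate(vocab)}
    tokens = [
        np.array([vindex[s] for s in stems], dtype=np.int32) for stems in doc_stems
    ]
    stem_to_surface = {
        s: min(
            (w for w, c in counts.items() if c == max(counts.values()))
        )
        for s, counts in surface_counts.items()
        if s in vindex
    }
    doc_genes = {d: set(corpus.doc_genes[d]) for d in kept_docs}
    logger.info(
        "preprocessed corpus: %d documents, vocabulary of %d stems",
        len(kept_docs), len(vocab),
    )
    return Corpus(
        documents=kept_docs,
        doc_genes=doc_genes,
        texts=corpus.texts,
        tokens=tokens,
        vocab=vocab,
        stem_to_surface=stem_to_surface,
    )


def term_document_matrix(corpus: Corpus) -> sp.csr_matrix:
    """Sparse terms x documents count matrix over the stemmed vocabulary."""
    if not corpus.is_preprocessed:
        raise ConfigurationError("corpus must be preprocessed first")
    n_terms = len(corpus.vocab)
    n_docs = len(corpus.documents)
    rows, cols, vals = [], [], []
    for j, tok in enumerate(corpus.tokens):
        counts = np.bincount(tok, minlength=n_terms)
        nz = np.nonzero(counts)[0]
        rows.extend(nz.tolist())
        cols.extend([j] * len(nz))
        vals.extend(counts[nz].tolist())
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_terms, n_docs), dtype=np.int64
    )
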