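"""Topic-number selection and end-to-end pipeline orchestration.

The number of topics k is not known a priori. The method scans a fixed
increasing grid (default [5, 10, 15, 20, 25, 30, 40, 50, 75, 100]), fits
one model per grid point and counts the topics deemed significant for the
input gene set. The scan stops as soon as that count stops increasing
(default rule ``no-increase``: current <= previous; ``strict-decline``
stops only on current < previous) or the grid is exhausted; the selected
k is the evaluated grid point with the maximal count, the smallest on
ties (fewer topics are easier to interpret). Each grid point gets its own
RNG seed derived by hashing (base seed, k), so appending grid points
never perturbs earlier fits.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Callable

from .corpus import (
    Corpus,
    WorkingGeneSet,
    assemble_corpus,
    build_working_set,
    load_stopwords,
    preprocess,
    read_gene_list,
    term_document_matrix,
)
from .errors import ConfigurationError, GeneTopicsError
from .index import GeneDocIndex, filter_index
from .lda import LdaConfig, TopicModelFit, fit_lda
from .scoring import (
    GeneTopicMatrix,
    TopicEnrichmentResult,
    enrichment_test,
    gene_topic_matrix,
)

logger = logging.getLogger(__name__)

DEFAULT_GRID = (5, 10, 15, 20, 25, 30, 40, 50, 75, 100)


def derive_seed(base_seed: int, k: int) -> int:
    """Stable per-grid-point seed (< 2**31) from the base seed and k."""
    digest = hashlib.blake2b(
        f"{base_seed}:{k}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


@dataclass
class SearchEval:
    """One evaluated grid point."""

    k: int
    seed: int
    n_significant: int
    fit: TopicModelFit
    gtm: GeneTopicMatrix
    results: list[TopicEnrichmentResult]


@dataclass
class SearchTrace:
    """The evaluated prefix of the grid and the selected model."""

    grid: list[int]
    evaluated: list[SearchEval]
    selected_k: int
    stop_reason: str  # "plateau", "decline" or "grid_exhausted"

    @property
    def selected(self) -> SearchEval:
        for ev in self.evaluated:
            if ev.k == self.selected_k:
                return ev
        raise ConfigurationError("selected k missing from evaluated points")


def search_topic_number(
    corpus: Corpus,
    ws: WorkingGeneSet,
    grid: list[int] | tuple[int, ...] = DEFAULT_GRID,
    base_config: LdaConfig | None = None,
    threshold: float = 0.5,
    alpha_level: float = 0.05,
    stop_rule: str = "no-increase",
    smoothing: str = "laplace",
    test: str = "binomial",
    evaluator: Callable[[int, int], SearchEval] | None = None,
) -> SearchTrace:
    """Scan the topic-number grid and apply the stopping rule.

    ``evaluator(k, seed)`` may be injected (e.g. for unit tests of the
    stopping rule); by default each grid point fits LDA on the corpus,
    scores genes and runs the enrichment test. Grid points with k not
    below the corpus token count are skipped with a warning.
    """
    grid = list(grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigurationError(
            f"grid must be non-empty and strictly increasing, got {grid}"
        )
    if stop_rule not in ("no-increase", "strict-decline"):
        raise ConfigurationError(f"unknown stop rule {stop_rule!r}")

    if evaluator is None:
        tdm = term_document_matrix(corpus)
        n_tokens = int(tdm.sum())
        base = base_config if base_config is not None else LdaConfig(k=grid[0])

        def evaluator(k: int, seed: int) -> SearchEval:
            config = LdaConfig(
                k=k,
                alpha=base.alpha,
                eta=base.eta,
                iterations=base.iterations,
                burn_in=base.burn_in,
                seed=seed,
                assignment_mode=base.assignment_mode,
            )
            fit = fit_lda(tdm, config)
            gtm = gene_topic_matrix(fit, corpus, ws)
            results = enrichment_test(
                gtm, ws, threshold=threshold, alpha_level=alpha_level,
                smoothing=smoothing, test=test,
            )
            n_sig = sum(r.significant for r in results)
            return SearchEval(k, seed, n_sig, fit, gtm, results)

        token_limit = n_tokens
    else:
        token_limit = None

    evaluated: list[SearchEval] = []
    stop_reason = "grid_exhausted"
    for k in grid:
        if token_limit is not None and k >= token_limit:
            logger.warning(
                "skipping grid point k=%d (corpus has only %d tokens)",
                k, token_limit,
            )
            continue
        ev = evaluator(k, derive_seed(
            base_config.seed if base_config is not None else 0, k
        ))
        evaluated.append(ev)
        logger.info("k=%d: %d significant topics", k, ev.n_significant)
        if len(evaluated) >= 2:
            prev = evaluated[-2].n_significant
            cur = ev.n_significant
            if cur < prev:
                stop_reason = "decline"
                break
            if cur == prev and stop_rule == "no-increase":
                stop_reason = "plateau"
                break
    if not evaluated:
        raise ConfigurationError("no grid point could be evaluated")
    best = max(range(len(evaluated)), key=lambda i: (evaluated[i].n_significant, -i))
    selected_k = evaluated[best].k
    return SearchTrace(
        grid=grid,
        evaluated=evaluated,
        selected_k=selected_k,
        stop_reason=stop_reason,
    )


@dataclass
class PipelineOptions:
    """All tunable parameters of an end-to-end run (see docs/methods.md)."""

    docs_per_gene: int = 50
    min_year: int = 1996
    min_relevancy: float = 0.0
    sample_mode: str = "top"
    grid: tuple[int, ...] = DEFAULT_GRID
    threshold: float = 0.5
    alpha_level: float = 0.05
    stop_rule: str = "no-increase"
    smoothing: str = "laplace"
    test: str = "binomial"
    top_terms: int = 20
    alpha: float | None = None
    eta: float = 0.1
    iterations: int = 1000
    burn_in: int = 500
    seed: int = 0
    stopwords: str | None = None  # path; None = packaged default list

    def manifest(self) -> dict:
        return {
            "docs_per_gene": self.docs_per_gene,
            "min_year": self.min_year,
            "min_relevancy": self.min_relevancy,
            "sample_mode": self.sample_mode,
            "grid": list(self.grid),
            "threshold": self.threshold,
            "alpha_level": self.alpha_level,
            "stop_rule": self.stop_rule,
            "smoothing": self.smoothing,
            "test": self.test,
            "top_terms": self.top_terms,
            "alpha": self.alpha,
            "eta": self.eta,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "stopwords": self.stopwords,
        }


def run_pipeline(
    genes,
    index: GeneDocIndex,
    options: PipelineOptions | None = None,
    background: set[str] | None = None,
    out_dir=None,
):
    """Run the whole workflow: filter -> G_w -> corpus -> search -> report.

    ``genes`` is a path to a gene list file or a list of symbols. Returns
    the :class:`~genetopics.report.GeneTopicsReport`; when ``out_dir`` is
    given the report files and the run manifest are written there.
    Failures carry the pipeline stage in their message.
    """
    from . import report as report_mod
    from importlib.metadata import version as pkg_version

    options = options or PipelineOptions()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GeneTopicsError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    if isinstance(genes, (str,)) or hasattr(genes, "__fspath__"):
        gene_list = stage("read-genes", read_gene_list, genes)
    else:
        gene_list = list(genes)

    fidx = stage(
        "filter-index", filter_index, index,
        min_year=options.min_year, min_relevancy=options.min_relevancy,
    )
    ws = stage(
        "working-set", build_working_set, gene_list, fidx,
        background=background, seed=options.seed,
    )
    raw_corpus = stage(
        "assemble-corpus", assemble_corpus, ws, fidx,
        n_docs=options.docs_per_gene, sample_mode=options.sample_mode,
        seed=options.seed,
    )
    stopwords = stage("stopwords", load_stopwords, options.stopwords)
    corpus = stage("preprocess", preprocess, raw_corpus, stopwords)
    base_config = LdaConfig(
        k=options.grid[0],
        alpha=options.alpha,
        eta=options.eta,
        iterations=options.iterations,
        burn_in=options.burn_in,
        seed=options.seed,
    )
    trace = stage(
        "topic-search", search_topic_number, corpus, ws,
        grid=options.grid, base_config=base_config,
        threshold=options.threshold, alpha_level=options.alpha_level,
        stop_rule=options.stop_rule, smoothing=options.smoothing,
        test=options.test,
    )
    try:
        ver = pkg_version("genetopics")
    except Exception:  # pragma: no cover - not installed
        ver = "unknown"
    manifest = {
        "package_version": ver,
        "options": options.manifest(),
        "n_input_genes_given": len(gene_list),
        "n_input_genes_usable": len(ws.input_genes),
        "n_random_genes": len(ws.random_genes),
        "excluded_genes": sorted(ws.excluded_genes),
        "n_documents": len(corpus.documents),
        "vocabulary_size": len(corpus.vocab),
        "per_k_seeds": {str(ev.k): ev.seed for ev in trace.evaluated},
        "selected_k": trace.selected_k,
        "stop_reason": trace.stop_reason,
    }
    sel = trace.selected
    rep = stage(
        "report", report_mod.build_report, trace, sel.gtm, corpus, sel.fit,
        ws=ws, threshold=options.threshold, top_n=options.top_terms,
        manifest=manifest,
    )
    if out_dir is not None:
        stage("write-report", report_mod.write_report, rep, out_dir)
    return rep
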