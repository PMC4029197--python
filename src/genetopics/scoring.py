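"""Gene-topic scoring and topic specificity testing.

A gene's score for a topic is the **maximum** topic proportion over the
gene's documents. The max (rather than a mean or sum) reflects that genes
are multi-functional and publications typically focus on one biological
aspect: a single strongly on-topic paper suffices to tie the gene to the
topic, whereas averaging drags scores toward the corpus mean.

Thresholding the gene-topic matrix at t (default 0.5) discretizes scores;
a topic is specific to the input genes G_i when the fraction of input
genes above t significantly exceeds the fraction observed among the
embedded random genes G_r, by a one-tailed binomial test. The null
success probability is estimated from G_r; the default "laplace"
smoothing uses (high + 1) / (n + 2) so that a topic where no random gene
scores highly still has a bounded, conservative null rather than an
impossible one. Raw p-values are Bonferroni-corrected by the number of
topics k of the current fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .corpus import Corpus, WorkingGeneSet
from .errors import ConfigurationError
from .lda import TopicModelFit

logger = logging.getLogger(__name__)


@dataclass
class GeneTopicMatrix:
    """Genes x topics relevancy scores in [0, 1] (input genes first)."""

    genes: list[str]
    n_input: int
    scores: np.ndarray  # (len(genes), k)

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def score(self, gene: str, topic: int) -> float:
        return float(self.scores[self.genes.index(gene), topic])


@dataclass
class TopicEnrichmentResult:
    """Binomial specificity test of one topic against the random genes."""

    topic: int
    n_input_high: int
    n_input: int
    n_random_high: int
    n_random: int
    prop_random: float  # raw fraction of random genes above threshold
    null_p: float  # null success probability actually used (may be smoothed)
    p_raw: float
    p_bonferroni: float
    significant: bool
    member_genes: set[str] = field(default_factory=set)


def gene_doc_rows(corpus: Corpus, ws: WorkingGeneSet) -> dict[str, np.ndarray]:
    """Map each working gene to the corpus row indices of its documents."""
    rows: dict[str, list[int]] = {g: [] for g in ws.working_genes}
    for i, doc_id in enumerate(corpus.documents):
        for g in corpus.doc_genes[doc_id]:
            if g in rows:
                rows[g].append(i)
    return {g: np.asarray(r, dtype=np.int64) for g, r in rows.items()}


def gene_topic_matrix(
    fit: TopicModelFit, corpus: Corpus, ws: WorkingGeneSet
) -> GeneTopicMatrix:
    """Max-reduce each gene's document topic proportions into its scores.

    Genes whose documents were all dropped during preprocessing are moved
    to ``ws.excluded_genes`` with a warning (never silently zero-scored).
    """
    props = fit.topic_proportion_matrix
    rows = gene_doc_rows(corpus, ws)
    lost = [g for g in ws.working_genes if rows[g].size == 0]
    if lost:
        logger.warning(
            "excluding %d genes whose documents were all dropped: %s",
            len(lost), ", ".join(sorted(lost)),
        )
        ws.excluded_genes.update(g for g in lost if g in ws.input_genes)
        ws.input_genes = [g for g in ws.input_genes if g not in lost]
        ws.random_genes = [g for g in ws.random_genes if g not in lost]
    genes = ws.working_genes
    if not ws.input_genes:
        raise ConfigurationError("no input genes with surviving documents")
    scores = np.empty((len(genes), fit.k), dtype=np.float64)
    for i, g in enumerate(genes):
        scores[i] = props[rows[g]].max(axis=0)
    return GeneTopicMatrix(genes=genes, n_input=len(ws.input_genes), scores=scores)


def score_distributions(
    gtm: GeneTopicMatrix, ws: WorkingGeneSet, topic: int
) -> tuple[np.ndarray, np.ndarray]:
    """Score vectors (input genes, random genes) for one topic."""
    if not (0 <= topic < gtm.k):
        raise ConfigurationError(f"topic {topic} outside [0, {gtm.k})")
    col = gtm.scores[:, topic]
    return col[: gtm.n_input].copy(), col[gtm.n_input:].copy()


def _binomial_p(x: int, n: int, p0: float) -> float:
    # one-tailed: probability of >= x successes under Binomial(n, p0)
    return float(stats.binom.sf(x - 1, n, p0))


def enrichment_test(
    gtm: GeneTopicMatrix,
    ws: WorkingGeneSet,
    threshold: float = 0.5,
    alpha_level: float = 0.05,
    smoothing: str = "laplace",
    test: str = "binomial",
) -> list[TopicEnrichmentResult]:
    """Test every topic for specificity to the input genes.

    For topic j: x = #{input genes with score > threshold}, against a
    binomial null with success probability estimated from the random
    genes. ``smoothing="laplace"`` (default) uses (high+1)/(n+2);
    ``"raw"`` uses the unsmoothed fraction. ``test`` may also name the
    rejected alternatives "ks" (one-sided Kolmogorov-Smirnov) or
    "wilcoxon" (one-sided rank-sum), kept for comparison; both ignore the
    threshold when computing p but still report the discretized counts.
    Bonferroni multiplies by the number of topics of this fit.
    """
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(f"threshold must be in (0, 1), got {threshold}")
    if not (0.0 < alpha_level < 1.0):
        raise ConfigurationError(f"alpha_level must be in (0, 1), got {alpha_level}")
    if smoothing not in ("laplace", "raw"):
        raise ConfigurationError(f"unknown smoothing {smoothing!r}")
    if test not in ("binomial", "ks", "wilcoxon"):
        raise ConfigurationError(f"unknown test {test!r}")
    n_input = gtm.n_input
    n_random = len(gtm.genes) - n_input
    if n_input == 0:
        raise ConfigurationError("no input genes to test")
    if n_random < 1:
        raise ConfigurationError("need at least one random background gene")
    k = gtm.k
    input_scores = gtm.scores[:n_input]
    random_scores = gtm.scores[n_input:]
    results = []
    for j in range(k):
        x = int(np.sum(input_scores[:, j] > threshold))
        rhigh = int(np.sum(random_scores[:, j] > threshold))
        prop_random = rhigh / n_random
        if smoothing == "laplace":
            p0 = (rhigh + 1) / (n_random + 2)
        else:
            p0 = prop_random
        if test == "binomial":
            p_raw = _binomial_p(x, n_input, p0)
        elif test == "ks":
            p_raw = float(
                stats.ks_2samp(
                    input_scores[:, j], random_scores[:, j], alternative="less"
                ).pvalue
            )
        else:
            p_raw = float(
                stats.mannwhitneyu(
                    input_scores[:, j], random_scores[:, j], alternative="greater"
                ).pvalue
            )
        p_bonf = min(1.0, p_raw * k)
        members = {
            gtm.genes[i] for i in range(n_input) if gtm.scores[i, j] > threshold
        }
        results.append(
            TopicEnrichmentResult(
                topic=j,
                n_input_high=x,
                n_input=n_input,
                n_random_high=rhigh,
                n_random=n_random,
                prop_random=prop_random,
                null_p=p0,
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                significant=p_bonf < alpha_level,
                member_genes=members,
            )
        )
    return results


def write_enrichment_tsv(results: list[TopicEnrichmentResult], path,
                         display: dict[str, str] | None = None) -> None:
    """Per-topic TSV export of the enrichment test."""
    display = display or {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "topic\tp_raw\tp_bonferroni\tsignificant\tn_input_high\t"
            "prop_random\tgenes\n"
        )
        for r in results:
            genes = ",".join(sorted(display.get(g, g) for g in r.member_genes))
            fh.write(
                f"{r.topic}\t{r.p_raw:.6g}\t{r.p_bonferroni:.6g}\t"
                f"{str(r.significant).lower()}\t{r.n_input_high}\t"
                f"{r.prop_random:.6g}\t{genes}\n"
            )
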