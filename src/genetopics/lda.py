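"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The model: each of k topics is a distribution over the stemmed vocabulary
(symmetric Dirichlet prior eta); each document is a mixture over topics
(symmetric Dirichlet prior alpha). Collapsed Gibbs sampling integrates
both sets of distributions out and resamples a topic for every token from

    p(z_i = j | rest)  ∝  (n_dj + alpha) * (n_jw + eta) / (n_j + V * eta)

where n_dj counts tokens of document d currently in topic j, n_jw counts
tokens of word w in topic j, and n_j is topic j's total. The fit exposes
per-token assignments, from which two document-level matrices follow:

* word count matrix   (documents x topics): tokens of d assigned to j;
* topic proportion matrix: each row divided by the document length, so a
  100-token document with 40 tokens in topic 1 and 60 in topic 2 has
  proportions 0.4 and 0.6 (and 0 elsewhere).

Default hyperparameters follow common Gibbs-LDA conventions
(alpha = 50/k, eta = 0.1, 1000 sweeps with 500 burn-in). Assignments are,
by default, the final Gibbs state (a posterior sample); the "argmax" mode
instead takes each token's most frequent topic over the post-burn-in
sweeps. Identical inputs, configuration and seed give identical fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LdaConfig:
    """Sampler configuration; ``alpha=None`` means the 50/k default."""

    k: int
    alpha: float | None = None
    eta: float = 0.1
    iterations: int = 1000
    burn_in: int = 500
    seed: int = 0
    assignment_mode: str = "final"  # or "argmax"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError(f"k must be >= 2, got {self.k}")
        a = self.effective_alpha
        if not (math.isfinite(a) and a > 0):
            raise ConfigurationError(f"alpha must be finite and > 0, got {a}")
        if not (math.isfinite(self.eta) and self.eta > 0):
            raise ConfigurationError(f"eta must be finite and > 0, got {self.eta}")
        if not (self.iterations > self.burn_in >= 0):
            raise ConfigurationError(
                f"need iterations > burn_in >= 0, got "
                f"{self.iterations}/{self.burn_in}"
            )
        if self.assignment_mode not in ("final", "argmax"):
            raise ConfigurationError(
                f"unknown assignment mode {self.assignment_mode!r}"
            )

    @property
    def effective_alpha(self) -> float:
        return 50.0 / self.k if self.alpha is None else self.alpha


@dataclass
class TopicModelFit:
    """A fitted topic model: per-token assignments and derived matrices."""

    config: LdaConfig
    assignments: list[np.ndarray]  # per document, one topic index per token
    topic_word_counts: np.ndarray  # (k, vocab)
    word_count_matrix: np.ndarray  # (documents, k)
    topic_proportion_matrix: np.ndarray  # (documents, k), rows sum to 1
    n_vocab: int = field(default=0)

    @property
    def k(self) -> int:
        return self.config.k


@njit(cache=True)
def _gibbs(doc_of, word_of, n_docs, n_words, k, alpha, eta,
           iterations, burn_in, seed, argmax_mode):  # pragma: no cover - jit
    np.random.seed(seed)
    n = doc_of.shape[0]
    z = np.empty(n, dtype=np.int32)
    ndk = np.zeros((n_docs, k), dtype=np.int64)
    nkw = np.zeros((k, n_words), dtype=np.int64)
    nk = np.zeros(k, dtype=np.int64)
    for i in range(n):
        t = np.random.randint(0, k)
        z[i] = t
        ndk[doc_of[i], t] += 1
        nkw[t, word_of[i]] += 1
        nk[t] += 1
    acc_rows = n if argmax_mode else 1
    acc = np.zeros((acc_rows, k), dtype=np.int64)
    p = np.empty(k, dtype=np.float64)
    veta = n_words * eta
    for it in range(iterations):
        for i in range(n):
            d = doc_of[i]
            w = word_of[i]
            t = z[i]
            ndk[d, t] -= 1
            nkw[t, w] -= 1
            nk[t] -= 1
            total = 0.0
            for j in range(k):
                total += (ndk[d, j] + alpha) * (nkw[j, w] + eta) / (nk[j] + veta)
                p[j] = total
            u = np.random.random() * total
            t = 0
            while t < k - 1 and p[t] < u:
                t += 1
            z[i] = t
            ndk[d, t] += 1
            nkw[t, w] += 1
            nk[t] += 1
        if argmax_mode and it >= burn_in:
            for i in range(n):
                acc[i, z[i]] += 1
    if argmax_mode:
        for i in range(n):
            best = 0
            for j in range(1, k):
                if acc[i, j] > acc[i, best]:
                    best = j
            z[i] = best
    return z


def _expand_tokens(tdm: sp.spmatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a terms x documents count matrix into parallel token arrays.

    Tokens are ordered document by document, ascending term index within a
    document (bag-of-words order is immaterial to the model).
    """
    csc = sp.csc_matrix(tdm)
    doc_of, word_of = [], []
    for d in range(csc.shape[1]):
        start, end = csc.indptr[d], csc.indptr[d + 1]
        terms = csc.indices[start:end]
        counts = csc.data[start:end]
        order = np.argsort(terms, kind="stable")
        words = np.repeat(terms[order], counts[order].astype(np.int64))
        word_of.append(words)
        doc_of.append(np.full(words.shape[0], d, dtype=np.int32))
    doc_of = np.concatenate(doc_of) if doc_of else np.empty(0, np.int32)
    word_of = np.concatenate(word_of).astype(np.int32) if word_of else np.empty(0, np.int32)
    doc_lengths = np.asarray(tdm.sum(axis=0)).ravel().astype(np.int64)
    return doc_of, word_of, doc_lengths


def fit_from_assignments(
    token_words: list[np.ndarray],
    assignments: list[np.ndarray],
    k: int,
    n_vocab: int,
    config: LdaConfig | None = None,
) -> TopicModelFit:
    """Build a :class:`TopicModelFit` from explicit token-topic assignments.

    Used wherever the derived matrices must be checked independently of
    the sampler (and by the sampler itself, on its own final state).
    """
    if config is None:
        config = LdaConfig(k=k)
    n_docs = len(assignments)
    wcm = np.zeros((n_docs, k), dtype=np.int64)
    twc = np.zeros((k, n_vocab), dtype=np.int64)
    for d, (words, zs) in enumerate(zip(token_words, assignments)):
        if len(words) != len(zs):
            raise ConfigurationError(
                f"document {d}: {len(words)} tokens but {len(zs)} assignments"
            )
        if len(zs) == 0:
            raise ConfigurationError(f"document {d} has no tokens")
        if np.any((zs < 0) | (zs >= k)):
            raise ConfigurationError(f"document {d}: assignment outside [0, {k})")
        np.add.at(wcm[d], zs, 1)
        np.add.at(twc, (zs, words), 1)
    lengths = wcm.sum(axis=1, keepdims=True)
    props = wcm / lengths
    return TopicModelFit(
        config=config,
        assignments=[np.asarray(z, dtype=np.int32) for z in assignments],
        topic_word_counts=twc,
        word_count_matrix=wcm,
        topic_proportion_matrix=props,
        n_vocab=n_vocab,
    )


def fit_lda(tdm: sp.spmatrix, config: LdaConfig) -> TopicModelFit:
    """Fit LDA on a terms x documents count matrix by collapsed Gibbs."""
    n_terms, n_docs = tdm.shape
    doc_of, word_of, doc_lengths = _expand_tokens(tdm)
    n_tokens = doc_of.shape[0]
    if n_tokens == 0:
        raise ConfigurationError("term-document matrix is empty")
    if np.any(doc_lengths == 0):
        raise ConfigurationError("every document must contain at least one token")
    if config.k > n_tokens:
        logger.warning(
            "k=%d exceeds the corpus token count %d; surplus topics will "
            "stay empty", config.k, n_tokens,
        )
    if n_terms < config.k:
        logger.warning(
            "vocabulary (%d) smaller than k=%d topics", n_terms, config.k
        )
    z = _gibbs(
        doc_of, word_of, n_docs, n_terms, config.k,
        float(config.effective_alpha), float(config.eta),
        config.iterations, config.burn_in, config.seed,
        config.assignment_mode == "argmax",
    )
    bounds = np.cumsum(doc_lengths)[:-1]
    token_words = np.split(word_of, bounds)
    assignments = np.split(z, bounds)
    return fit_from_assignments(token_words, assignments, config.k, n_terms, config)


def word_count_matrix(fit: TopicModelFit) -> np.ndarray:
    """Documents x topics counts of tokens assigned to each topic."""
    return fit.word_count_matrix


def topic_proportions(fit: TopicModelFit) -> np.ndarray:
    """Documents x topics proportions; each row sums to 1."""
    return fit.topic_proportion_matrix


def top_terms(
    fit: TopicModelFit,
    topic: int,
    n: int,
    vocab: list[str],
    stem_to_surface: dict[str, str] | None = None,
) -> list[str]:
    """Top ``n`` display words of one topic.

    Stems are ranked by the topic's assigned-token counts (descending),
    ties broken by ascending stem string; stems never assigned to the
    topic are omitted. Display words come from ``stem_to_surface``.
    """
    if not (0 <= topic < fit.k):
        raise ConfigurationError(f"topic {topic} outside [0, {fit.k})")
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    counts = fit.topic_word_counts[topic]
    ranked = sorted(
        (i for i in range(len(vocab)) if counts[i] > 0),
        key=lambda i: (-counts[i], vocab[i]),
    )[:n]
    mapping = stem_to_surface or {}
    return [mapping.get(vocab[i], vocab[i]) for i in ranked]
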