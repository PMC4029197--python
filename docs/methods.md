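# Methods

## Model and procedure

The workflow annotates an input gene set G_i by topic-modelling a corpus
built around it.

**Working gene set.** A random gene set G_r of the same size as the
usable input is drawn uniformly without replacement from a background
population (by default, every gene in the index) excluding G_i. G_r is
deliberately *embedded in the corpus*: the topic model sees input and
random genes symmetrically, so any topic that the random genes reach as
easily as the input genes is, by construction, not specific to the
input. Input genes without any indexed document are excluded from G_w
and from every denominator — they carry no literature signal either
way — and are reported in the run manifest. If the eligible background
pool is smaller than the input set, the draw is capped at the pool size
with a warning; the binomial null below is valid for any number of
random genes ≥ 1.

**Corpus.** Per working gene, up to `docs_per_gene` documents (default
50, balancing computation against over-representation of well-studied
genes), ranked by relevancy score with document-id tie-break so that
sampling is deterministic; a seeded random sampling mode exists for
sensitivity checks. Only documents from `min_year` on (default 1996)
and with relevancy ≥ `min_relevancy` (default 0, as relevancy scales
are index-specific) are eligible. Documents selected by several genes
are kept once with back-links to all selecting genes. Text processing:
lowercase → delete punctuation characters (deletion, not replacement,
so hyphenated chemistry like "enoyl-CoA" fuses to "enoylcoa") →
whitespace tokenization → stopword removal (packaged English list,
overridable) → Porter stemming. Numeric tokens are retained ("95", "p450"
are informative biomedical tokens). The stemmed vocabulary drives the
model; each stem maps back to its most frequent surface form (ties:
lexicographically smallest) for display.

**LDA by collapsed Gibbs sampling.** Symmetric priors: document–topic
concentration α (default 50/k) and topic–word concentration η (default
0.1), the common Gibbs-LDA conventions; 1000 sweeps with 500 burn-in.
Per-token topic assignments are taken from the final Gibbs state — a
posterior sample, matching how assignment-exposing LDA implementations
behave — with an alternative `argmax` mode that assigns each token its
modal topic over the post-burn-in sweeps. The word-count matrix
(documents × topics) tallies assignments; the topic-proportion matrix
divides each row by the document's token count, i.e. normalization is
**per document** (each row sums to 1), which is what the 40/60 → 0.4/0.6
example forces. All randomness flows from a single integer seed;
identical inputs and configuration reproduce the fit exactly.

**Gene–topic scores.** S(g,j) = max over g's documents of the document's
proportion for topic j. The max (not mean or sum) reflects that genes
are multi-functional and papers usually address one biological aspect;
averaging compresses scores toward the corpus mean and washes out true
associations.

**Specificity test.** Scores are discretized strictly above a threshold
t (default 0.5, adjustable to focus on stronger or weaker gene–topic
associations). Tests comparing full score distributions (KS, rank-sum —
both available via `test=`) flag topics whose input scores are shifted
upward but still uniformly low; the binomial test on the discretized
counts avoids this. The null success probability is estimated from the
random genes with a Laplace-style pseudocount, (high+1)/(n+2), because
the raw fraction can be exactly 0, which would make any input success
infinitely significant; `smoothing="raw"` restores the unsmoothed
estimator. p = P(X ≥ x) for X ~ Binomial(n_input, p0), computed as a
binomial survival function. Bonferroni correction multiplies by the
topic count k of the current fit; the topic-number scan below is not
corrected for — each grid point is a separate model whose significant
count is itself the selection signal.

**Topic-number search.** Grid default [5, 10, 15, 20, 25, 30, 40, 50,
75, 100]. Evaluation stops at the first grid point whose significant
count does not exceed the previous one (`no-increase`; the stricter
`strict-decline` rule stops only on an actual drop). The selected k
maximizes the significant count, smallest k on ties (fewer topics are
easier to interpret). Per-k seeds are derived by hashing (base seed, k),
so extending the grid never changes earlier fits. Grid points with k at
or above the corpus token count are skipped. A single-point grid
reproduces a plain fixed-k run.

**Report.** Per significant topic: the top 20 display terms (count-ranked,
stem-string tie-break), the input genes scoring above t, and per member
gene the supporting documents — those of the gene's documents whose
proportion for the topic exceeds t, always including the score-attaining
document, since the gene's score is defined by its documents. Topics are
sorted by corrected p-value. The report holds no numbers of its own;
everything is re-derivable from the corpus, fit and score matrix (and a
test asserts this). An empty topic list is a valid result and the
expected one for random input.

## Synthetic fixtures

The generator emulates the structure the method assumes: k_true topics
drawn from a symmetric Dirichlet (concentration 0.05 — sparse,
well-separated word distributions, as topic models assume of real
corpora); planted gene groups whose documents mix `purity` weight on the
group's home topic with the remainder spread uniformly; diffuse
background genes whose documents use the exactly uniform mixture. Tokens
are drawn multinomially from the mixed word distribution. Pseudo-words
are CV-syllable strings over an alphabet avoiding every Porter suffix,
so stemming is the identity on fixtures and end-to-end tests isolate
topic-model behaviour from stemming behaviour. Documents are
gene-private by default; a `shared_docs` switch exercises deduplication.

Defaults describe the standard planted condition used throughout the
tests: 5 true topics, 3 groups × 20 genes, 30 background genes, 20
documents per gene, mean length 60 tokens (a short abstract), purity
0.8, vocabulary 2000.

What fixtures do *not* emulate: real PubMed language (burstiness,
phrases, named entities), gene-symbol ambiguity, correlated topics, or
realistic relevancy-score noise (fixture scores are all 1.0). Passing
recovery tests therefore demonstrates the statistical machinery — not
performance on real literature, which also depends on the quality of the
gene–document index.

Recovery scoring matches significant topics to planted groups greedily,
one-to-one, by member-gene overlap; precision and recall are
micro-averaged over matched pairs, unmatched significant topics count as
false topics, and unmatched groups lower the topic match rate.

## Numerical and design choices

- Gene symbols match case-insensitively; the first surface form seen is
  kept for display.
- Relevancy ties in document sampling break by ascending document id;
  term-count ties in top terms break by ascending stem string; equal
  significant counts in the k-scan select the smaller k. All ties are
  deterministic.
- Duplicate (gene, document) link rows keep the highest relevancy, with
  a logged count; links to unknown documents are dropped, with a logged
  count.
- A document reduced to zero tokens by preprocessing is dropped with a
  warning; a gene whose documents were all dropped is moved to the
  excluded set rather than silently zero-scored.
- `fit_lda` warns (rather than fails) when k exceeds the corpus token
  count — surplus topics simply stay empty, and the degenerate
  one-token corpus yields a one-hot proportion row. The grid scan skips
  such k values instead.
- The Gibbs kernel is compiled with numba; the sampler seeds its own
  generator inside the kernel, so fits are reproducible across processes.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
corpora sized to resolve in seconds to a couple of minutes per stage:
planted recovery uses the standard condition above (≈1800 documents,
≈10^5 tokens) over 10 seeds at the true topic number; null calibration
uses 20 random-input runs at fixed k = 10 (600 documents each);
false-positive calibration uses 200 miniature corpora; the
worked-example and oracle checks are instantaneous.

## Known limitations

- On a corpus with exactly K true themes, the `no-increase` scan can
  overshoot: at k > K the sampler splits a coherent topic's vocabulary
  across fragments, each fragment can still pass the binomial test, so
  the significant count keeps rising and a larger k is selected — where
  per-document proportions dilute below the 0.5 threshold and member
  lists shrink. Real literature corpora have deeper topic hierarchies,
  which is the regime the stopping rule was designed for; for corpora
  with a known or suspected topic count, run with a single-point grid.
- Bonferroni within a fit is conservative; no correction is applied
  across the grid scan (each k is a separate model).
- The bag-of-words assumption ignores phrase structure; topics are
  described by unigram stems.
- The background gene population strongly shapes which topics are
  "specific": a pool sharing the input's broad theme (e.g. all kinases)
  focuses the method on finer contrasts; the full index background
  surfaces the broad theme itself.
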