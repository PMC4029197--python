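"""Synthetic gene-linked corpora with known topic structure.

The generator emulates the statistical structure the workflow assumes:
k true topics, each a Dirichlet-distributed distribution over a
pseudo-word vocabulary; groups of "planted" genes tied to a home topic,
whose documents draw tokens from a mixture putting weight ``purity`` on
the home topic and spreading the remainder uniformly; and diffuse
"background" genes whose documents use the uniform mixture (1/k on every
topic), so no background gene concentrates on any one topic. Because truth (topic-word distributions, gene-topic
membership, per-document mixtures) is known, recovery by the full
pipeline can be scored exactly - without any download.

Pseudo-words are CV-syllable strings over an alphabet chosen so that
Porter stemming is the identity on them, isolating topic-model behaviour
from stemming behaviour in end-to-end tests. Documents are gene-private
by default; ``shared_docs=True`` makes consecutive genes share their
first document to exercise the deduplication path. All years are >= 1996
and relevancy scores are 1.0, so the default index filter keeps
everything.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .index import DocRecord, GeneDocIndex, GeneDocLink, write_index
from .report import GeneTopicsReport
from .stem import stem

_CONSONANTS = "bcdfgjklmnprtvz"
_VOWELS = "aou"


def pseudo_vocabulary(size: int) -> list[str]:
    """First ``size`` stem-stable pseudo-words in a fixed enumeration."""
    syllables = [c + v for c in _CONSONANTS for v in _VOWELS]
    words: list[str] = []
    for n_syll in (2, 3):
        for parts in itertools.product(syllables, repeat=n_syll):
            w = "".join(parts)
            if stem(w) == w:  # defensive; the alphabet avoids all suffixes
                words.append(w)
                if len(words) == size:
                    return words
    raise ConfigurationError(f"cannot enumerate {size} pseudo-words")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture (defaults: a mid-sized planted
    corpus that the full pipeline resolves in seconds)."""

    n_topics_true: int = 5
    vocab_size: int = 2000
    topic_concentration: float = 0.05
    n_gene_groups: int = 3
    genes_per_group: int = 20
    n_background_genes: int = 30
    docs_per_gene: int = 20
    doc_length_mean: int = 60
    purity: float = 0.8
    seed: int = 0
    shared_docs: bool = False

    def __post_init__(self) -> None:
        problems = []
        for name in (
            "n_topics_true", "vocab_size", "n_background_genes",
            "docs_per_gene", "doc_length_mean",
        ):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.n_gene_groups < 0:
            problems.append("n_gene_groups must be >= 0")
        if self.n_gene_groups > 0 and self.genes_per_group < 1:
            problems.append("genes_per_group must be >= 1 when groups exist")
        if self.n_gene_groups > self.n_topics_true:
            problems.append("n_gene_groups must be <= n_topics_true")
        if not (0.0 < self.purity <= 1.0):
            problems.append("purity must be in (0, 1]")
        if self.n_gene_groups > 0 and self.purity <= 1.0 / self.n_topics_true:
            problems.append(
                "purity must exceed 1/n_topics_true for a planted signal"
            )
        if self.topic_concentration <= 0:
            problems.append("topic_concentration must be > 0")
        if problems:
            raise ConfigurationError(
                "invalid fixture spec: " + "; ".join(problems)
            )

    @classmethod
    def from_json(cls, path) -> "FixtureSpec":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class FixtureTruth:
    """Ground truth of a generated fixture."""

    topic_word_dists: np.ndarray  # (n_topics_true, vocab)
    gene_home_topic: dict[str, int | None]  # None for background genes
    doc_mixtures: dict[str, np.ndarray]

    def groups(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, t in self.gene_home_topic.items():
            if t is not None:
                out.setdefault(t, set()).add(g)
        return out


@dataclass
class SyntheticFixture:
    spec: FixtureSpec
    index: GeneDocIndex
    input_genes: list[str]
    truth: FixtureTruth
    token_topics: dict[str, np.ndarray] = field(default_factory=dict)


def _doc_tokens(rng, mixture, topic_word_dists, length):
    """Draw one document's tokens; returns (word ids, per-token topics)."""
    k = mixture.shape[0]
    topics = rng.choice(k, size=length, p=mixture)
    words = np.empty(length, dtype=np.int64)
    for t in range(k):
        mask = topics == t
        cnt = int(mask.sum())
        if cnt:
            words[mask] = rng.choice(
                topic_word_dists.shape[1], size=cnt, p=topic_word_dists[t]
            )
    perm = rng.permutation(length)
    return words[perm], topics[perm]


def generate_fixture(spec: FixtureSpec, out_dir=None) -> SyntheticFixture:
    """Generate a synthetic index, input gene list and ground truth.

    With ``out_dir``, also writes ``links.tsv``, ``docs.tsv``,
    ``genes.txt`` and ``truth.json`` in the standard dialects; a fixed
    seed yields byte-identical files. For a pure-null fixture
    (``n_gene_groups=0``) the input gene list is a seeded random half of
    the background genes.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = pseudo_vocabulary(spec.vocab_size)
    k = spec.n_topics_true
    topic_word_dists = rng.dirichlet(
        np.full(spec.vocab_size, spec.topic_concentration), size=k
    )

    genes: list[tuple[str, int | None]] = []
    for g in range(spec.n_gene_groups):
        for i in range(spec.genes_per_group):
            genes.append((f"T{g + 1}G{i + 1:03d}", g))
    for i in range(spec.n_background_genes):
        genes.append((f"RND{i + 1:03d}", None))

    links: list[GeneDocLink] = []
    docs: dict[str, DocRecord] = {}
    doc_mixtures: dict[str, np.ndarray] = {}
    token_topics: dict[str, np.ndarray] = {}
    counter = 0
    prev_first_doc: str | None = None
    for gene, home in genes:
        first_doc_of_gene = None
        for d in range(spec.docs_per_gene):
            if spec.shared_docs and d == 0 and prev_first_doc is not None:
                # share the previous gene's first document
                links.append(GeneDocLink(gene, prev_first_doc, 1.0))
                first_doc_of_gene = prev_first_doc
                continue
            counter += 1
            doc_id = f"9{counter:08d}"
            if home is None:
                mixture = np.full(k, 1.0 / k)
            else:
                mixture = np.full(k, (1.0 - spec.purity) / k)
                mixture[home] += spec.purity
            length = max(10, int(rng.poisson(spec.doc_length_mean)))
            words, topics = _doc_tokens(rng, mixture, topic_word_dists, length)
            text = [vocab[w] for w in words]
            title = " ".join(text[:6])
            abstract = " ".join(text[6:])
            docs[doc_id] = DocRecord(
                doc_id, 1996 + (counter % 25), title, abstract
            )
            doc_mixtures[doc_id] = mixture
            token_topics[doc_id] = topics
            links.append(GeneDocLink(gene, doc_id, 1.0))
            if first_doc_of_gene is None:
                first_doc_of_gene = doc_id
        prev_first_doc = first_doc_of_gene

    index = GeneDocIndex(links=links, docs=docs)
    truth = FixtureTruth(
        topic_word_dists=topic_word_dists,
        gene_home_topic=dict(genes),
        doc_mixtures=doc_mixtures,
    )
    if spec.n_gene_groups > 0:
        input_genes = [g for g, home in genes if home is not None]
    else:
        bg = [g for g, _ in genes]
        take = max(1, len(bg) // 2)
        chosen = rng.choice(len(bg), size=take, replace=False)
        input_genes = [bg[i] for i in sorted(chosen)]

    fixture = SyntheticFixture(
        spec=spec, index=index, input_genes=input_genes, truth=truth,
        token_topics=token_topics,
    )
    if out_dir is not None:
        write_fixture(fixture, out_dir)
    return fixture


def write_fixture(fixture: SyntheticFixture, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "links": out / "links.tsv",
        "docs": out / "docs.tsv",
        "genes": out / "genes.txt",
        "truth": out / "truth.json",
    }
    write_index(fixture.index, paths["links"], paths["docs"])
    paths["genes"].write_text(
        "\n".join(fixture.input_genes) + "\n", encoding="utf-8"
    )
    truth = fixture.truth
    paths["truth"].write_text(
        json.dumps(
            {
                "topic_word_dists": truth.topic_word_dists.tolist(),
                "gene_home_topic": truth.gene_home_topic,
                "doc_mixtures": {
                    d: m.tolist() for d, m in sorted(truth.doc_mixtures.items())
                },
            },
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    return paths


@dataclass
class RecoveryMetrics:
    """How well a report recovered the planted structure.

    Significant topics are greedily matched one-to-one to true gene
    groups by member-gene overlap (largest overlap first; zero-overlap
    pairs never match). ``topic_match_rate`` is the fraction of planted
    groups matched; precision and recall are micro-averaged over the
    matched pairs only, so partially recovered structure is scored on
    what was recovered; ``false_topic_count`` counts significant topics
    left unmatched.
    """

    topic_match_rate: float
    gene_precision: float
    gene_recall: float
    false_topic_count: int
    matched: list[tuple[int, int]] = field(default_factory=list)  # (topic, group)


def evaluate_recovery(
    report: GeneTopicsReport, truth: FixtureTruth
) -> RecoveryMetrics:
    """Score a report against the fixture truth (see RecoveryMetrics)."""
    groups = truth.groups()
    topic_members = {
        t.topic: {m.gene.upper() for m in t.members} for t in report.topics
    }
    pairs = []
    for topic, members in topic_members.items():
        for gid, group in groups.items():
            ov = len(members & group)
            if ov > 0:
                pairs.append((ov, topic, gid))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_topics: set[int] = set()
    used_groups: set[int] = set()
    matched: list[tuple[int, int]] = []
    for ov, topic, gid in pairs:
        if topic in used_topics or gid in used_groups:
            continue
        used_topics.add(topic)
        used_groups.add(gid)
        matched.append((topic, gid))
    overlap_sum = sum(
        len(topic_members[t] & groups[g]) for t, g in matched
    )
    member_sum = sum(len(topic_members[t]) for t, _ in matched)
    group_sum = sum(len(groups[g]) for _, g in matched)
    n_groups = len(groups)
    return RecoveryMetrics(
        topic_match_rate=(len(matched) / n_groups) if n_groups else float("nan"),
        gene_precision=(overlap_sum / member_sum) if member_sum else 0.0,
        gene_recall=(overlap_sum / group_sum) if group_sum else 0.0,
        false_topic_count=len(topic_members) - len(matched),
        matched=matched,
    )
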