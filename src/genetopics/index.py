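"""Gene-document association index.

The method needs, for every gene, a ranked set of publications mentioning
it. Production systems obtain this from a literature-mining index (or from
resources such as gene2pubmed or GeneRIF); here the contract is a pluggable
pair of TSV tables:

* links:  ``gene<TAB>pmid<TAB>score``  - one row per gene-document pair,
  with a relevancy score normalised to [0, 1];
* docs:   ``pmid<TAB>year<TAB>title<TAB>abstract`` - one row per document.

A MEDLINE-format reader (``load_medline_docs``) maps PMID/DP/TI/AB fields
of PubMed exports onto the same document records.

Gene symbols are matched case-insensitively; the first surface form seen
is kept for display.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError, ParseError

logger = logging.getLogger(__name__)

LINKS_HEADER = ["gene", "pmid", "score"]
DOCS_HEADER = ["pmid", "year", "title", "abstract"]


def canonical_gene(symbol: str) -> str:
    """Canonical (uppercase) form of a gene symbol used for matching."""
    return symbol.strip().upper()


def validate_gene_symbol(symbol: str) -> str:
    s = symbol.strip()
    if not s or any(ch.isspace() for ch in s):
        raise ConfigurationError(f"invalid gene symbol: {symbol!r}")
    return s


@dataclass(frozen=True)
class DocRecord:
    """A document: identifier, publication year, title and abstract."""

    doc_id: str
    year: int
    title: str
    abstract: str

    @property
    def text(self) -> str:
        return (self.title + " " + self.abstract).strip()


@dataclass(frozen=True)
class GeneDocLink:
    """One gene-document association with a relevancy score in [0, 1]."""

    gene: str  # canonical symbol
    doc_id: str
    relevancy: float


@dataclass
class GeneDocIndex:
    """Many-to-many gene<->document links plus the document store.

    ``background`` is the set of canonical gene symbols appearing in at
    least one link; it is the default pool from which the random
    comparison gene set is drawn.
    """

    links: list[GeneDocLink]
    docs: dict[str, DocRecord]
    display: dict[str, str] = field(default_factory=dict)  # canonical -> surface

    def __post_init__(self) -> None:
        self._by_gene: dict[str, list[GeneDocLink]] = {}
        for link in self.links:
            if link.doc_id not in self.docs:
                raise ConfigurationError(
                    f"link references unknown document {link.doc_id!r}"
                )
            self._by_gene.setdefault(link.gene, []).append(link)
        for g in self._by_gene:
            self.display.setdefault(g, g)

    @property
    def background(self) -> frozenset[str]:
        return frozenset(self._by_gene)

    def gene_links(self, gene: str) -> list[GeneDocLink]:
        return list(self._by_gene.get(canonical_gene(gene), []))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneDocIndex):
            return NotImplemented
        return set(self.links) == set(other.links) and self.docs == other.docs


def _read_tsv(path: str | Path, expected_header: list[str]):
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(path, 1, "empty file") from None
        if [h.strip().lower() for h in header] != expected_header:
            raise ParseError(
                path, 1,
                f"expected header {expected_header}, got {header}",
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(expected_header):
                raise ParseError(
                    path, line_no,
                    f"expected {len(expected_header)} fields, got {len(row)}",
                )
            yield line_no, row


def load_docs(path: str | Path) -> dict[str, DocRecord]:
    """Read a document-store TSV into a dict keyed by document id."""
    docs: dict[str, DocRecord] = {}
    for line_no, (doc_id, year, title, abstract) in (
        (n, r) for n, r in _read_tsv(path, DOCS_HEADER)
    ):
        doc_id = doc_id.strip()
        try:
            year_i = int(year)
        except ValueError:
            raise ParseError(path, line_no, f"year is not an integer: {year!r}")
        if year_i <= 0:
            raise ParseError(path, line_no, f"year must be positive: {year_i}")
        rec = DocRecord(doc_id, year_i, title.strip(), abstract.strip())
        if not rec.text:
            raise ParseError(path, line_no, "title and abstract are both empty")
        if doc_id in docs:
            raise ParseError(path, line_no, f"duplicate document id {doc_id!r}")
        docs[doc_id] = rec
    return docs


def load_medline_docs(path: str | Path) -> dict[str, DocRecord]:
    """Read MEDLINE-format records (PMID/DP/TI/AB fields) as documents.

    Records without a PMID, a parseable 4-digit year in DP, or any
    title/abstract text are skipped with a logged count.
    """
    from Bio import Medline

    docs: dict[str, DocRecord] = {}
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for rec in Medline.parse(fh):
            pmid = rec.get("PMID", "").strip()
            dp = rec.get("DP", "")
            title = (rec.get("TI") or "").strip()
            abstract = (rec.get("AB") or "").strip()
            year = None
            for token in dp.replace("-", " ").split():
                if len(token) == 4 and token.isdigit():
                    year = int(token)
                    break
            if not pmid or year is None or not (title + abstract):
                skipped += 1
                continue
            docs[pmid] = DocRecord(pmid, year, title, abstract)
    if skipped:
        logger.warning("skipped %d MEDLINE records lacking PMID/year/text", skipped)
    return docs


def load_index(
    links_path: str | Path,
    docs_path: str | Path,
    medline: bool = False,
) -> GeneDocIndex:
    """Load and validate a gene-document index from its two files.

    Links whose document id is absent from the document store are dropped
    with a logged count; duplicate (gene, document) pairs keep the highest
    relevancy. An index with no usable links is a configuration error.
    """
    docs = load_medline_docs(docs_path) if medline else load_docs(docs_path)

    best: dict[tuple[str, str], GeneDocLink] = {}
    display: dict[str, str] = {}
    dropped = 0
    dupes = 0
    for line_no, (gene, pmid, score) in (
        (n, r) for n, r in _read_tsv(links_path, LINKS_HEADER)
    ):
        surface = gene.strip()
        if not surface or any(ch.isspace() for ch in surface):
            raise ParseError(links_path, line_no, f"invalid gene symbol {gene!r}")
        try:
            rel = float(score)
        except ValueError:
            raise ParseError(links_path, line_no, f"score is not a number: {score!r}")
        if not (0.0 <= rel <= 1.0):
            raise ParseError(
                links_path, line_no, f"relevancy score outside [0, 1]: {rel}"
            )
        doc_id = pmid.strip()
        if doc_id not in docs:
            dropped += 1
            continue
        canon = canonical_gene(surface)
        display.setdefault(canon, surface)
        key = (canon, doc_id)
        if key in best:
            dupes += 1
            if rel <= best[key].relevancy:
                continue
        best[key] = GeneDocLink(canon, doc_id, rel)
    if dropped:
        logger.warning(
            "%s: dropped %d links referencing unknown document ids", links_path, dropped
        )
    if dupes:
        logger.warning(
            "%s: collapsed %d duplicate (gene, document) links", links_path, dupes
        )
    if not best:
        raise ConfigurationError(f"{links_path}: no usable gene-document links")
    links = [best[k] for k in sorted(best)]
    return GeneDocIndex(links=links, docs=docs, display=display)


def filter_index(
    index: GeneDocIndex, min_year: int = 1996, min_relevancy: float = 0.0
) -> GeneDocIndex:
    """Keep links to documents from ``min_year`` on with relevancy >= cutoff.

    The default year cutoff keeps literature published after 1995. The
    background gene set is recomputed from the surviving links; an empty
    result is a configuration error.
    """
    if min_year < 0:
        raise ConfigurationError(f"min_year must be >= 0, got {min_year}")
    if not (0.0 <= min_relevancy <= 1.0):
        raise ConfigurationError(
            f"min_relevancy must be in [0, 1], got {min_relevancy}"
        )
    links = [
        l for l in index.links
        if index.docs[l.doc_id].year >= min_year and l.relevancy >= min_relevancy
    ]
    if not links:
        raise ConfigurationError(
            f"filter (min_year={min_year}, min_relevancy={min_relevancy}) "
            "removed every link"
        )
    return GeneDocIndex(links=links, docs=dict(index.docs), display=dict(index.display))


def sample_documents(
    index: GeneDocIndex,
    gene: str,
    n_docs: int,
    mode: str = "top",
    seed: int = 0,
) -> list[str]:
    """Pick up to ``n_docs`` documents for one gene.

    The default mode is deterministic: the top-n links by relevancy, ties
    broken by ascending document id. ``mode="random"`` draws a seeded
    uniform sample instead (for sensitivity checks). A gene absent from
    the index yields an empty list.
    """
    if n_docs < 1:
        raise ConfigurationError(f"n_docs must be >= 1, got {n_docs}")
    links = index.gene_links(gene)
    if not links:
        return []
    if mode == "top":
        ranked = sorted(links, key=lambda l: (-l.relevancy, l.doc_id))
        return [l.doc_id for l in ranked[:n_docs]]
    if mode == "random":
        import numpy as np

        ids = sorted(l.doc_id for l in links)
        rng = np.random.default_rng(seed)
        take = min(n_docs, len(ids))
        chosen = rng.choice(len(ids), size=take, replace=False)
        return [ids[i] for i in chosen]
    raise ConfigurationError(f"unknown sample mode {mode!r}")


def write_index(index: GeneDocIndex, links_path: str | Path, docs_path: str | Path) -> None:
    """Write an index back to the two TSV files (inverse of load_index)."""
    with open(links_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(LINKS_HEADER)
        for link in sorted(index.links, key=lambda l: (l.gene, l.doc_id)):
            w.writerow([index.display.get(link.gene, link.gene), link.doc_id,
                        repr(link.relevancy)])
    with open(docs_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(DOCS_HEADER)
        for doc_id in sorted(index.docs):
            d = index.docs[doc_id]
            w.writerow([d.doc_id, d.year, d.title, d.abstract])
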