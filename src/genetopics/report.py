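"""Result reporting.

A run's deliverable lists, per significant topic: the top display words,
the input genes scoring above the threshold (with their scores), and the
supporting document ids - every document of the gene whose topic
proportion exceeds the threshold, always including the document that
attains the gene's (max) score. Everything in the report is re-derivable
from the corpus, the fit and the gene-topic matrix; the report holds no
numbers of its own.

Files written: ``report.json`` (full structure), ``topics.tsv`` (one row
per topic), ``members.tsv`` (one row per topic member) and
``manifest.json`` (parameters, seeds, versions, excluded genes). Output
is deterministic: rerunning with an identical manifest reproduces the
files byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus, WorkingGeneSet
from .errors import ConfigurationError
from .lda import TopicModelFit, top_terms
from .scoring import GeneTopicMatrix, gene_doc_rows


@dataclass
class TopicMember:
    gene: str  # display form
    score: float
    supporting_doc_ids: list[str]


@dataclass
class ReportTopic:
    topic: int
    p_raw: float
    p_bonferroni: float
    n_input_high: int
    n_input: int
    prop_random: float
    top_terms: list[str]
    members: list[TopicMember]


@dataclass
class GeneTopicsReport:
    run_manifest: dict
    selected_k: int
    topics: list[ReportTopic] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "run_manifest": self.run_manifest,
            "selected_k": self.selected_k,
            "topics": [asdict(t) for t in self.topics],
        }


def build_report(
    trace,
    gtm: GeneTopicMatrix,
    corpus: Corpus,
    fit: TopicModelFit,
    ws: WorkingGeneSet,
    threshold: float = 0.5,
    top_n: int = 20,
    manifest: dict | None = None,
) -> GeneTopicsReport:
    """Assemble the report for the selected fit's significant topics.

    An empty significant-topic list is a valid outcome (the expected one
    for a random input gene set), not an error. Topics are sorted by
    ascending corrected p-value, ties by topic index; members by
    descending score, ties by gene symbol.
    """
    results = trace.selected.results
    if fit.k != gtm.k:
        raise ConfigurationError("fit and gene-topic matrix disagree on k")
    props = fit.topic_proportion_matrix
    rows = gene_doc_rows(corpus, ws)
    display = ws.display

    topics: list[ReportTopic] = []
    sig = sorted(
        (r for r in results if r.significant),
        key=lambda r: (r.p_bonferroni, r.topic),
    )
    for r in sig:
        members: list[TopicMember] = []
        for gene in sorted(r.member_genes):
            gi = gtm.genes.index(gene)
            score = float(gtm.scores[gi, r.topic])
            doc_rows = rows[gene]
            col = props[doc_rows, r.topic]
            keep = set(np.nonzero(col > threshold)[0].tolist())
            keep.add(int(np.argmax(col)))  # the score-attaining document
            chosen = sorted(keep, key=lambda i: (-col[i], corpus.documents[doc_rows[i]]))
            members.append(
                TopicMember(
                    gene=display.get(gene, gene),
                    score=score,
                    supporting_doc_ids=[
                        corpus.documents[doc_rows[i]] for i in chosen
                    ],
                )
            )
        members.sort(key=lambda m: (-m.score, m.gene))
        topics.append(
            ReportTopic(
                topic=r.topic,
                p_raw=r.p_raw,
                p_bonferroni=r.p_bonferroni,
                n_input_high=r.n_input_high,
                n_input=r.n_input,
                prop_random=r.prop_random,
                top_terms=top_terms(
                    fit, r.topic, top_n, corpus.vocab, corpus.stem_to_surface
                ),
                members=members,
            )
        )
    return GeneTopicsReport(
        run_manifest=manifest or {},
        selected_k=trace.selected_k,
        topics=topics,
    )


def write_report(report: GeneTopicsReport, out_dir) -> dict[str, Path]:
    """Write report.json, topics.tsv, members.tsv and manifest.json."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "report": out / "report.json",
            "topics": out / "topics.tsv",
            "members": out / "members.tsv",
            "manifest": out / "manifest.json",
        }
        paths["report"].write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=False) + "\n",
            encoding="utf-8",
        )
        paths["manifest"].write_text(
            json.dumps(report.run_manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        with open(paths["topics"], "w", encoding="utf-8") as fh:
            fh.write(
                "topic\tp_raw\tp_bonferroni\tn_input_high\tn_input\t"
                "prop_random\ttop_terms\n"
            )
            for t in report.topics:
                fh.write(
                    f"{t.topic}\t{t.p_raw:.6g}\t{t.p_bonferroni:.6g}\t"
                    f"{t.n_input_high}\t{t.n_input}\t{t.prop_random:.6g}\t"
                    f"{','.join(t.top_terms)}\n"
                )
        with open(paths["members"], "w", encoding="utf-8") as fh:
            fh.write("topic\tgene\tscore\tdoc_ids\n")
            for t in report.topics:
                for m in t.members:
                    fh.write(
                        f"{t.topic}\t{m.gene}\t{m.score:.6g}\t"
                        f"{','.join(m.supporting_doc_ids)}\n"
                    )
    except OSError as exc:
        raise ConfigurationError(f"cannot write report to {out}: {exc}") from exc
    return paths


def read_report(path) -> GeneTopicsReport:
    """Load a report.json back into a :class:`GeneTopicsReport`."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    topics = [
        ReportTopic(
            topic=t["topic"],
            p_raw=t["p_raw"],
            p_bonferroni=t["p_bonferroni"],
            n_input_high=t["n_input_high"],
            n_input=t["n_input"],
            prop_random=t["prop_random"],
            top_terms=list(t["top_terms"]),
            members=[
                TopicMember(
                    gene=m["gene"],
                    score=m["score"],
                    supporting_doc_ids=list(m["supporting_doc_ids"]),
                )
                for m in t["members"]
            ],
        )
        for t in data["topics"]
    ]
    return GeneTopicsReport(
        run_manifest=data["run_manifest"],
        selected_k=data["selected_k"],
        topics=topics,
    )
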