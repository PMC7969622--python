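"""Cosine co-occurrence scoring and thresholded gene-interaction networks.

For genes g, h with binary document-incidence vectors, the co-occurrence
score is the cosine similarity

    c(g, h) = n_gh / sqrt(n_g * n_h)

where n_g is the number of abstracts mentioning g and n_gh the number
mentioning both. The score is 0 when the genes are never co-mentioned and
1 when they appear in exactly the same abstracts. Networks connect gene
pairs whose score exceeds a threshold (strictly, by default 0.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .corpus_io import DocumentCorpus
from .gene_ner import TermDocumentMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CosineMatrix",
    "GenePair",
    "cosine_matrix",
    "top_pairs",
    "pair_evidence",
    "build_network",
    "export_network",
    "read_network",
]

NETWORK_FORMATS = ("graphml", "sif", "edge_tsv")


@dataclass
class CosineMatrix:
    """Symmetric gene×gene cosine scores in [0, 1] with joint counts."""

    genes: list[str]
    scores: np.ndarray
    joint_counts: np.ndarray

    def score(self, gene_a: str, gene_b: str) -> float:
        i, j = self.genes.index(gene_a), self.genes.index(gene_b)
        return float(self.scores[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.genes, columns=self.genes)


@dataclass(frozen=True)
class GenePair:
    """An unordered gene pair (stored with gene_a < gene_b) and its evidence."""

    gene_a: str
    gene_b: str
    score: float
    n_joint: int
    evidence_pmids: tuple[str, ...] = ()
    tied_at_cutoff: bool = False

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError(
                f"pair must be canonically ordered gene_a < gene_b, "
                f"got ({self.gene_a}, {self.gene_b})"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def cosine_matrix(tdm: TermDocumentMatrix, use_counts: bool = False) -> CosineMatrix:
    """Cosine similarity of every gene pair from the incidence matrix.

    ``use_counts=True`` scores cosine on mention-count vectors instead of
    binary incidence; the binary form is the default because only there
    does 1 mean "identical abstract sets".
    """
    if len(tdm.genes) < 2:
        raise ValueError("cosine_matrix requires at least 2 genes")
    if np.any(tdm.n_docs_per_gene == 0):
        raise ValueError("term-document matrix contains all-zero gene rows")
    vectors = (tdm.mention_counts if use_counts else tdm.incidence).astype(np.float64)
    gram = vectors @ vectors.T
    norms_sq = np.diag(gram)
    scores = gram / np.sqrt(np.outer(norms_sq, norms_sq))
    np.clip(scores, 0.0, 1.0, out=scores)
    joint = (tdm.incidence.astype(np.int64) @ tdm.incidence.astype(np.int64).T)
    return CosineMatrix(genes=list(tdm.genes), scores=scores, joint_counts=joint)


def _all_pairs(cosmat: CosineMatrix, tdm: TermDocumentMatrix, min_joint: int) -> list[GenePair]:
    docs = np.asarray(tdm.documents)
    pairs: list[GenePair] = []
    for i in range(len(cosmat.genes)):
        for j in range(i + 1, len(cosmat.genes)):
            n_joint = int(cosmat.joint_counts[i, j])
            if n_joint < min_joint:
                continue
            both = (tdm.incidence[i] == 1) & (tdm.incidence[j] == 1)
            a, b = sorted((cosmat.genes[i], cosmat.genes[j]))
            pairs.append(
                GenePair(
                    gene_a=a,
                    gene_b=b,
                    score=float(cosmat.scores[i, j]),
                    n_joint=n_joint,
                    evidence_pmids=tuple(docs[both]),
                )
            )
    return pairs


def top_pairs(
    cosmat: CosineMatrix,
    tdm: TermDocumentMatrix,
    n: int = 60,
    min_joint: int = 1,
) -> list[GenePair]:
    """Rank co-occurring pairs by (score desc, n_joint desc, pair asc).

    All pairs tied with the n-th ranked pair are included and flagged via
    ``tied_at_cutoff`` rather than truncated arbitrarily, so the returned
    list can be longer than ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pairs = _all_pairs(cosmat, tdm, min_joint)
    pairs.sort(key=lambda p: (-p.score, -p.n_joint, p.key))
    if len(pairs) <= n:
        return pairs
    cut_key = (pairs[n - 1].score, pairs[n - 1].n_joint)
    kept = list(pairs[:n])
    extra = [p for p in pairs[n:] if (p.score, p.n_joint) == cut_key]
    if extra:
        logger.info("top_pairs: %d pair(s) tied at the rank-%d cutoff", len(extra), n)
        kept = [
            replace(p, tied_at_cutoff=(p.score, p.n_joint) == cut_key) for p in kept
        ] + [replace(p, tied_at_cutoff=True) for p in extra]
    return kept


def pair_evidence(
    pair: GenePair, tdm: TermDocumentMatrix, corpus: DocumentCorpus
) -> pd.DataFrame:
    """Evidence table for a pair: one row per co-mentioning abstract."""
    for g in (pair.gene_a, pair.gene_b):
        if g not in tdm.genes:
            raise ValueError(f"gene {g} not present in the term-document matrix")
    joint = sorted(tdm.doc_set(pair.gene_a) & tdm.doc_set(pair.gene_b))
    by_pmid = {r.pmid: r for r in corpus}
    rows = []
    for pmid in joint:
        r = by_pmid.get(pmid)
        rows.append(
            {
                "pmid": pmid,
                "journal": r.journal if r else "",
                "impact_factor": r.impact_factor if r else None,
                "year": r.year if r else None,
            }
        )
    return pd.DataFrame(rows, columns=["pmid", "journal", "impact_factor", "year"])


def build_network(
    pairs: Iterable[GenePair],
    threshold: float = 0.1,
    seed_nodes: Sequence[str] = (),
    strict: bool = True,
) -> nx.Graph:
    """Build the interaction network from scored pairs.

    Edges require score > threshold (``strict=False`` uses >=, for
    sensitivity analysis). Seed genes are always present as nodes, isolated
    if nothing passes the threshold. Node categories default to
    "uncategorized"; curation attaches S/R/A labels afterwards.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    net = nx.Graph(threshold=threshold, strict=strict)
    for s in seed_nodes:
        net.add_node(s, category="uncategorized")
    for p in pairs:
        passes = p.score > threshold if strict else p.score >= threshold
        if not passes:
            continue
        for g in p.key:
            if g not in net:
                net.add_node(g, category="uncategorized")
        net.add_edge(
            p.gene_a,
            p.gene_b,
            score=p.score,
            n_joint=p.n_joint,
            n_evidence=len(p.evidence_pmids),
        )
    return net


def export_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> Path:
    """Write a network as GraphML, SIF or an edge TSV.

    GraphML and the edge TSV are lossless for node categories and edge
    attributes; SIF (``geneA<TAB>cooccur<TAB>geneB``) keeps topology only.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(net.edges):
                fh.write(f"{a}\tcooccur\t{b}\n")
            for node in sorted(nx.isolates(net)):
                fh.write(f"{node}\n")
    elif format == "edge_tsv":
        rows = [
            {
                "gene_a": min(a, b),
                "gene_b": max(a, b),
                "score": d.get("score"),
                "n_joint": d.get("n_joint"),
                "n_evidence": d.get("n_evidence"),
            }
            for a, b, d in net.edges(data=True)
        ]
        df = pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "score", "n_joint", "n_evidence"]
        ).sort_values(["gene_a", "gene_b"])
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}; expected {NETWORK_FORMATS}")
    return path


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Re-import a network written by :func:`export_network`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        net = nx.Graph()
        for row in df.itertuples(index=False):
            net.add_edge(
                row.gene_a,
                row.gene_b,
                score=float(row.score),
                n_joint=int(row.n_joint),
                n_evidence=int(row.n_evidence),
            )
        return net
    if format == "sif":
        net = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    net.add_edge(parts[0], parts[2])
                elif parts[0]:
                    net.add_node(parts[0])
        return net
    raise ValueError(f"unknown network format {format!r}; expected {NETWORK_FORMATS}")
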