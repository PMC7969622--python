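"""Dictionary-based gene recognition and the gene×document matrix.

Recognition is deliberately simple and auditable: a text is split into
alphanumeric tokens and a token is a mention iff it equals an approved
HGNC symbol (case-sensitive) or a listed alias. An exclusion list of
ambiguous acronyms (e.g. laboratory measurements that collide with gene
symbols, such as CBF for ciliary beat frequency) suppresses matches at
recognition time without removing the symbol from the dictionary.

The recognized mentions are summarized per corpus into a binary
:class:`TermDocumentMatrix` (gene × abstract incidence), the object that
co-occurrence scoring consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .corpus_io import DocumentCorpus

logger = logging.getLogger(__name__)

__all__ = [
    "GeneDictionary",
    "GeneMention",
    "TermDocumentMatrix",
    "DEFAULT_EXCLUSIONS",
    "load_gene_dictionary",
    "recognize_genes",
    "build_tdm",
    "unique_genes",
]

#: Measurement/assay acronyms that collide with HGNC symbols in the
#: respiratory-toxicology literature; shipped as a conservative default,
#: extensible via the exclusion file.
DEFAULT_EXCLUSIONS: frozenset[str] = frozenset({"CBF", "TEER", "LDH", "PCR"})

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


@dataclass(frozen=True)
class GeneDictionary:
    """HGNC symbol dictionary with aliases and an exclusion list.

    ``exclusion_list`` entries stay in the dictionary but are never
    reported by :func:`recognize_genes` — exclusion is a reporting policy,
    not a dictionary edit, so the same dictionary can be reused with a
    different exclusion file.
    """

    approved_symbols: frozenset[str]
    aliases: Mapping[str, str] = field(default_factory=dict)
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.approved_symbols:
            raise ValueError("gene dictionary must contain at least one symbol")

    def resolve(self, token: str) -> str | None:
        """Map a surface token to its approved symbol, honouring exclusions."""
        if token in self.exclusion_list:
            return None
        symbol = (
            token
            if token in self.approved_symbols
            else self.aliases.get(token)
        )
        if symbol is None or symbol in self.exclusion_list:
            return None
        return symbol


@dataclass(frozen=True)
class GeneMention:
    """One recognized gene occurrence with its character span."""

    symbol: str
    pmid: str
    span: tuple[int, int]
    matched_text: str


def load_gene_dictionary(
    path: str | Path, exclusion_path: str | Path | None = None
) -> GeneDictionary:
    """Load a ``symbol[<TAB>alias]`` TSV and an optional exclusion file.

    Symbols are taken exactly as given (HGNC symbols are already
    case-normalized upstream). The exclusion file holds one token per line;
    blank lines and ``#`` comments are ignored.
    """
    symbols: set[str] = set()
    aliases: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            symbol = parts[0].strip()
            if symbol.lower() == "symbol":  # tolerate a header line
                continue
            if symbol:
                symbols.add(symbol)
            for alias in parts[1:]:
                alias = alias.strip()
                if alias:
                    aliases[alias] = symbol
    if not symbols:
        raise ValueError(f"{path}: empty gene dictionary")

    exclusions: set[str] = set(DEFAULT_EXCLUSIONS)
    if exclusion_path is not None:
        exclusions = set()
        with open(exclusion_path, encoding="utf-8") as fh:
            for line in fh:
                tok = line.strip()
                if tok and not tok.startswith("#"):
                    exclusions.add(tok)
    return GeneDictionary(
        approved_symbols=frozenset(symbols),
        aliases=aliases,
        exclusion_list=frozenset(exclusions),
    )


def recognize_genes(text: str, dictionary: GeneDictionary) -> list[GeneMention]:
    """Find whole-token, case-sensitive gene symbol mentions in ``text``.

    Tokens are maximal alphanumeric runs, so punctuation and hyphens act as
    boundaries ("EGFR-dependent" yields the token "EGFR"). Aliases resolve
    to their approved symbol; excluded tokens and symbols are never
    reported. The ``pmid`` field is filled by :func:`build_tdm`; here it is
    empty.
    """
    if text is None:
        raise ValueError("text must not be None")
    mentions: list[GeneMention] = []
    for m in _TOKEN_RE.finditer(text):
        symbol = dictionary.resolve(m.group())
        if symbol is not None:
            mentions.append(
                GeneMention(
                    symbol=symbol,
                    pmid="",
                    span=(m.start(), m.end()),
                    matched_text=m.group(),
                )
            )
    return mentions


@dataclass
class TermDocumentMatrix:
    """Binary gene × document incidence with optional mention counts.

    Rows (genes) and columns (pmids) are sorted lexicographically so the
    matrix is identical regardless of corpus record order. ``incidence`` is
    0/1; ``mention_counts`` holds the underlying token counts and satisfies
    ``incidence == (mention_counts >= 1)``.
    """

    genes: list[str]
    documents: list[str]
    incidence: np.ndarray
    mention_counts: np.ndarray
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels in term-document matrix")
        if len(set(self.documents)) != len(self.documents):
            raise ValueError("duplicate document labels in term-document matrix")
        if self.incidence.shape != (len(self.genes), len(self.documents)):
            raise ValueError("incidence shape does not match labels")
        if not np.array_equal(self.incidence, (self.mention_counts >= 1).astype(self.incidence.dtype)):
            raise ValueError("incidence must be the binarization of mention_counts")

    @property
    def n_docs_per_gene(self) -> np.ndarray:
        """Documents mentioning each gene (the cosine marginals n_g)."""
        return self.incidence.sum(axis=1)

    def doc_set(self, gene: str) -> frozenset[str]:
        """The set of pmids in which ``gene`` is mentioned."""
        i = self.genes.index(gene)
        return frozenset(
            d for d, v in zip(self.documents, self.incidence[i]) if v
        )

    def to_frame(self, counts: bool = False) -> pd.DataFrame:
        data = self.mention_counts if counts else self.incidence
        return pd.DataFrame(data, index=self.genes, columns=self.documents)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="gene")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermDocumentMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        df.columns = df.columns.astype(str)
        incidence = (df.to_numpy() >= 1).astype(np.int8)
        return cls(
            genes=[str(g) for g in df.index],
            documents=list(df.columns),
            incidence=incidence,
            mention_counts=df.to_numpy().astype(np.int64),
        )


def build_tdm(corpus: DocumentCorpus, dictionary: GeneDictionary) -> TermDocumentMatrix:
    """Scan title+abstract of every record and build the incidence matrix.

    Genes never mentioned anywhere (all-zero rows) are dropped and listed in
    ``dropped_genes``; a gene mentioned several times in one abstract still
    contributes a single incidence (abstract-level co-occurrence).
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a term-document matrix from an empty corpus")
    documents = sorted(corpus.pmids)
    doc_index = {d: j for j, d in enumerate(documents)}
    counts_by_gene: dict[str, np.ndarray] = {}
    for record in corpus:
        j = doc_index[record.pmid]
        for mention in recognize_genes(record.text, dictionary):
            row = counts_by_gene.get(mention.symbol)
            if row is None:
                row = counts_by_gene.setdefault(
                    mention.symbol, np.zeros(len(documents), dtype=np.int64)
                )
            row[j] += 1

    all_genes = sorted(dictionary.approved_symbols)
    mentioned = sorted(counts_by_gene)
    dropped = [g for g in all_genes if g not in counts_by_gene]
    if dropped:
        logger.info(
            "term-document matrix: dropped %d dictionary gene(s) with no mentions",
            len(dropped),
        )
    mention_counts = (
        np.vstack([counts_by_gene[g] for g in mentioned])
        if mentioned
        else np.zeros((0, len(documents)), dtype=np.int64)
    )
    return TermDocumentMatrix(
        genes=mentioned,
        documents=documents,
        incidence=(mention_counts >= 1).astype(np.int8),
        mention_counts=mention_counts,
        dropped_genes=dropped,
    )


def unique_genes(tdm: TermDocumentMatrix) -> tuple[list[str], int]:
    """Sorted symbols with at least one mention, and their count."""
    present = [g for g, n in zip(tdm.genes, tdm.n_docs_per_gene) if n > 0]
    return sorted(present), len(present)
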