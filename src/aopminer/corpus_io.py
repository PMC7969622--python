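"""Reading, writing, merging and filtering of abstract corpora.

The evidence unit of the pipeline is a PubMed-style abstract record
(pmid, title, abstract, journal, year, optional journal impact factor).
A :class:`DocumentCorpus` is an ordered, pmid-unique collection of such
records together with provenance strings (queries and source files).

Three on-disk dialects are supported: JSON-lines (the canonical dialect),
MEDLINE tagged text (import/export via :mod:`Bio.Medline` conventions) and
TSV with a header. Round-tripping through any dialect preserves the corpus
exactly, including record order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import Medline

logger = logging.getLogger(__name__)

__all__ = [
    "AbstractRecord",
    "DocumentCorpus",
    "CorpusParseError",
    "DEFAULT_KEY_TERMS",
    "build_query",
    "read_corpus",
    "write_corpus",
    "merge_corpora",
    "normalize_journal",
    "read_if_table",
    "annotate_impact_factor",
    "filter_by_impact_factor",
    "corpus_summary",
]

#: Oxidative-stress / tobacco-exposure key terms combined with each seed
#: gene when querying the literature for key-event evidence.
DEFAULT_KEY_TERMS: tuple[str, ...] = (
    "smoke",
    "tobacco",
    "acrolein",
    "acetaldehyde",
    "peroxide",
    "H2O2",
    "reactive oxygen species",
)

DIALECTS = ("jsonl", "medline", "tsv")

_FIELDS = ("pmid", "title", "abstract", "journal", "year", "impact_factor")


class CorpusParseError(ValueError):
    """A corpus file could not be parsed under the requested dialect."""


@dataclass(frozen=True)
class AbstractRecord:
    """One literature abstract with journal metadata.

    Parameters
    ----------
    pmid:
        Non-empty document identifier, unique within a corpus.
    title, abstract:
        Free text; both are scanned by gene recognition.
    journal:
        Journal name as printed in the source record.
    year:
        Publication year, if known.
    impact_factor:
        Journal impact factor (non-negative), or ``None`` when not yet
        annotated / not found in the impact-factor table.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    journal: str = ""
    year: int | None = None
    impact_factor: float | None = None

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("AbstractRecord requires a non-empty pmid")
        if self.impact_factor is not None and self.impact_factor < 0:
            raise ValueError(
                f"impact_factor must be non-negative, got {self.impact_factor}"
            )

    @property
    def text(self) -> str:
        """Title and abstract joined for mining."""
        return f"{self.title} {self.abstract}".strip()


@dataclass
class DocumentCorpus:
    """Ordered, pmid-unique collection of abstract records."""

    records: list[AbstractRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pmids = [r.pmid for r in self.records]
        if len(pmids) != len(set(pmids)):
            dupes = sorted({p for p in pmids if pmids.count(p) > 1})
            raise ValueError(f"duplicate pmids in corpus: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AbstractRecord]:
        return iter(self.records)

    @property
    def pmids(self) -> list[str]:
        return [r.pmid for r in self.records]

    def get(self, pmid: str) -> AbstractRecord:
        for r in self.records:
            if r.pmid == pmid:
                return r
        raise KeyError(pmid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DocumentCorpus):
            return NotImplemented
        return self.records == other.records


def build_query(seed_gene: str, key_terms: Sequence[str] = DEFAULT_KEY_TERMS) -> str:
    """Construct the boolean literature query for one seed gene.

    The query has the shape ``SEED AND (t1 OR t2 OR ...)``; multi-word key
    terms are quoted so they are matched as phrases. With no key terms the
    query is the bare seed symbol.
    """
    if not seed_gene or not seed_gene.strip():
        raise ValueError("seed_gene must be non-empty")
    seed = seed_gene.strip()
    terms = [t.strip() for t in key_terms if t.strip()]
    if not terms:
        return seed
    quoted = [f'"{t}"' if re.search(r"\s", t) else t for t in terms]
    return f"{seed} AND ({' OR '.join(quoted)})"


# ---------------------------------------------------------------------------
# dialect readers / writers
# ---------------------------------------------------------------------------


def _record_to_dict(r: AbstractRecord) -> dict:
    return {
        "pmid": r.pmid,
        "title": r.title,
        "abstract": r.abstract,
        "journal": r.journal,
        "year": r.year,
        "impact_factor": r.impact_factor,
    }


def _record_from_dict(d: Mapping, where: str) -> AbstractRecord:
    try:
        year = d.get("year")
        if year is not None and not (isinstance(year, float) and pd.isna(year)):
            year = int(year)
        else:
            year = None
        impf = d.get("impact_factor")
        if impf is None or (isinstance(impf, float) and pd.isna(impf)):
            impf = None
        else:
            impf = float(impf)
        return AbstractRecord(
            pmid=str(d["pmid"]),
            title=str(d.get("title") or ""),
            abstract=str(d.get("abstract") or ""),
            journal=str(d.get("journal") or ""),
            year=year,
            impact_factor=impf,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusParseError(f"malformed record at {where}: {exc}") from exc


def _read_jsonl(path: Path) -> list[AbstractRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(
                    f"{path}: invalid JSON on line {lineno}: {exc}"
                ) from exc
            records.append(_record_from_dict(obj, f"{path}:{lineno}"))
    return records


def _write_jsonl(records: Iterable[AbstractRecord], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(_record_to_dict(r), ensure_ascii=False) + "\n")


def _read_tsv(path: Path) -> list[AbstractRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"pmid": str}, encoding="utf-8")
    except Exception as exc:  # pandas raises several parser error types
        raise CorpusParseError(f"{path}: TSV parse failure: {exc}") from exc
    if "pmid" not in df.columns:
        raise CorpusParseError(f"{path}: TSV corpus requires a 'pmid' column")
    return [
        _record_from_dict(row, f"{path} row {i}")
        for i, row in enumerate(df.to_dict("records"))
    ]


def _write_tsv(records: Iterable[AbstractRecord], path: Path) -> None:
    df = pd.DataFrame([_record_to_dict(r) for r in records], columns=_FIELDS)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def _read_medline(path: Path) -> list[AbstractRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, rec in enumerate(Medline.parse(fh)):
            pmid = rec.get("PMID")
            if not pmid:
                raise CorpusParseError(f"{path}: MEDLINE record {i + 1} lacks PMID")
            year: int | None = None
            dp = rec.get("DP", "")
            m = re.match(r"(\d{4})", dp)
            if m:
                year = int(m.group(1))
            records.append(
                AbstractRecord(
                    pmid=str(pmid),
                    title=rec.get("TI", ""),
                    abstract=rec.get("AB", ""),
                    journal=rec.get("TA", ""),
                    year=year,
                )
            )
    return records


def _write_medline(records: Iterable[AbstractRecord], path: Path) -> None:
    # Tagged MEDLINE layout; the impact factor has no MEDLINE tag and is
    # dropped on export (annotate again after re-import).
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"PMID- {r.pmid}\n")
            if r.title:
                fh.write(f"TI  - {r.title}\n")
            if r.abstract:
                fh.write(f"AB  - {r.abstract}\n")
            if r.journal:
                fh.write(f"TA  - {r.journal}\n")
            if r.year is not None:
                fh.write(f"DP  - {r.year}\n")
            fh.write("\n")


_READERS = {"jsonl": _read_jsonl, "tsv": _read_tsv, "medline": _read_medline}
_WRITERS = {"jsonl": _write_jsonl, "tsv": _write_tsv, "medline": _write_medline}


def read_corpus(path: str | Path, dialect: str = "jsonl") -> DocumentCorpus:
    """Read a corpus file; duplicate pmids collapse to the first occurrence."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    raw = _READERS[dialect](path)
    seen: dict[str, AbstractRecord] = {}
    n_dupes = 0
    for r in raw:
        if r.pmid in seen:
            n_dupes += 1
        else:
            seen[r.pmid] = r
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate pmid record(s)", path, n_dupes)
    return DocumentCorpus(records=list(seen.values()), provenance=[str(path)])


def write_corpus(corpus: DocumentCorpus, path: str | Path, dialect: str = "jsonl") -> Path:
    """Write a corpus; ``read_corpus(write_corpus(c))`` restores the records."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    _WRITERS[dialect](corpus.records, path)
    return path


def merge_corpora(corpora: Sequence[DocumentCorpus]) -> DocumentCorpus:
    """Pool per-seed-gene (or per-source) corpora by pmid union.

    The first occurrence of each pmid wins; provenance strings are
    concatenated in input order.
    """
    if not corpora:
        raise ValueError("merge_corpora requires at least one corpus")
    seen: dict[str, AbstractRecord] = {}
    provenance: list[str] = []
    for c in corpora:
        provenance.extend(c.provenance)
        for r in c.records:
            seen.setdefault(r.pmid, r)
    return DocumentCorpus(records=list(seen.values()), provenance=provenance)


# ---------------------------------------------------------------------------
# impact-factor annotation and filtering
# ---------------------------------------------------------------------------


def normalize_journal(name: str) -> str:
    """Lowercase, trim and collapse internal whitespace (no fuzzy matching)."""
    return re.sub(r"\s+", " ", name.strip().lower())


def read_if_table(path: str | Path) -> dict[str, float]:
    """Read a ``journal<TAB>impact_factor`` TSV into a normalized-name map.

    A first line whose second field is not numeric is treated as a header.
    """
    table: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise CorpusParseError(
                    f"{path}:{lineno}: expected 'journal<TAB>impact_factor'"
                )
            try:
                impf = float(parts[1])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise CorpusParseError(
                    f"{path}:{lineno}: non-numeric impact factor {parts[1]!r}"
                ) from None
            table[normalize_journal(parts[0])] = impf
    return table


def annotate_impact_factor(
    corpus: DocumentCorpus, if_table: Mapping[str, float]
) -> DocumentCorpus:
    """Attach journal impact factors by normalized journal-name lookup.

    Journals absent from the table leave ``impact_factor`` missing; the
    number of unmatched journals is logged, never raised.
    """
    table = {normalize_journal(k): float(v) for k, v in if_table.items()}
    out: list[AbstractRecord] = []
    unmatched: set[str] = set()
    for r in corpus.records:
        impf = table.get(normalize_journal(r.journal))
        if impf is None and r.journal:
            unmatched.add(r.journal)
        out.append(dataclasses.replace(r, impact_factor=impf))
    if unmatched:
        logger.warning(
            "impact-factor annotation: %d journal(s) not found in table", len(unmatched)
        )
    return DocumentCorpus(records=out, provenance=list(corpus.provenance))


def filter_by_impact_factor(
    corpus: DocumentCorpus, threshold: float = 3.0
) -> DocumentCorpus:
    """Keep records whose journal impact factor is >= ``threshold``.

    The comparison is inclusive. Records without an annotated impact factor
    are dropped (restricting evidence to ranked journals) and counted in the
    log and in the returned corpus provenance.
    """
    kept = [r for r in corpus.records if r.impact_factor is not None and r.impact_factor >= threshold]
    n_missing = sum(1 for r in corpus.records if r.impact_factor is None)
    n_low = len(corpus.records) - len(kept) - n_missing
    logger.info(
        "impact-factor filter (>= %.2f): kept %d, dropped %d below threshold, "
        "dropped %d with missing impact factor",
        threshold,
        len(kept),
        n_low,
        n_missing,
    )
    prov = list(corpus.provenance) + [
        f"filter_by_impact_factor(threshold={threshold}): kept={len(kept)} "
        f"dropped_low={n_low} dropped_missing={n_missing}"
    ]
    return DocumentCorpus(records=kept, provenance=prov)


def corpus_summary(
    per_ke_corpora: Mapping[str, DocumentCorpus],
    seed_genes: Mapping[str, Sequence[str]] | None = None,
    unique_gene_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-key-event corpus accounting with a TOTAL row.

    Columns: number of seed genes, abstracts (after per-KE pmid dedup, which
    the corpus invariant guarantees) and unique recognized genes (supplied by
    the caller from the term-document matrix, since recognition lives in
    :mod:`aopminer.gene_ner`). The TOTAL abstract count is the plain sum of
    per-KE counts — one abstract retrieved for two key events counts once in
    each KE corpus, as in per-KE literature accounting.
    """
    rows = []
    for ke, corpus in per_ke_corpora.items():
        rows.append(
            {
                "ke": ke,
                "n_seed_genes": len(seed_genes[ke]) if seed_genes and ke in seed_genes else pd.NA,
                "n_abstracts": len(corpus),
                "n_unique_genes": (
                    unique_gene_counts[ke]
                    if unique_gene_counts and ke in unique_gene_counts
                    else pd.NA
                ),
            }
        )
    df = pd.DataFrame(rows, columns=["ke", "n_seed_genes", "n_abstracts", "n_unique_genes"])
    total = {
        "ke": "TOTAL",
        "n_seed_genes": df["n_seed_genes"].sum() if seed_genes else pd.NA,
        "n_abstracts": int(df["n_abstracts"].sum()),
        "n_unique_genes": (
            df["n_unique_genes"].sum() if unique_gene_counts else pd.NA
        ),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
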