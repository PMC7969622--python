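"""Curation replay and key-event geneset assembly with S/R/A provenance.

The human step of literature curation is externalized as a machine-readable
decision ledger: each decision keeps or discards an abstract (by pmid) or a
gene pair, with a coded reason. Replaying the ledger against the scored
pairs is deterministic, so the curated corpus and the derived R-genes
(genes of surviving pairs, minus the seeds) are fully auditable.

A geneset pools three member categories:

* S-genes — seed genes from the initial manual key-event searches;
* R-genes — relevant genes from curated co-occurring pairs;
* A-genes — additional genes from follow-up manual citation chasing.

A gene reachable through several categories is counted once, with
precedence S > R > A, so category tallies stay disjoint and the total is
the size of the union.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .cooccur_network import GenePair
from .corpus_io import DocumentCorpus, filter_by_impact_factor

logger = logging.getLogger(__name__)

__all__ = [
    "CurationDecision",
    "CurationResult",
    "Geneset",
    "GenesetMember",
    "AccountingRow",
    "AGene",
    "read_decisions",
    "write_decisions",
    "apply_curation",
    "add_a_genes",
    "assemble_geneset",
    "merge_genesets",
    "overlap_report",
    "annotate_pairs",
    "apply_categories",
    "read_gmt",
    "write_gmt",
]

REASON_CODES = ("low_if", "false_acronym", "irrelevant", "non_hgnc", "other")
CATEGORIES = ("S", "R", "A")
_PRECEDENCE = {"S": 0, "R": 1, "A": 2}


@dataclass(frozen=True)
class CurationDecision:
    """One keep/discard verdict on a pair or an abstract.

    ``target`` is a pmid for ``target_type='pmid'`` and ``'GENEA|GENEB'``
    (canonical order) for ``target_type='pair'``.
    """

    target_type: str
    target: str
    verdict: str
    reason: str = ""
    note: str = ""
    source: str = "manual"

    def __post_init__(self) -> None:
        if self.target_type not in ("pair", "pmid"):
            raise ValueError(f"target_type must be 'pair' or 'pmid', got {self.target_type!r}")
        if self.verdict not in ("keep", "discard"):
            raise ValueError(f"verdict must be 'keep' or 'discard', got {self.verdict!r}")
        if self.verdict == "discard" and self.reason not in REASON_CODES:
            raise ValueError(
                f"discard decisions need a reason code in {REASON_CODES}, got {self.reason!r}"
            )

    @property
    def pair_key(self) -> tuple[str, str]:
        if self.target_type != "pair":
            raise ValueError("pair_key only defined for pair decisions")
        a, b = self.target.split("|")
        return tuple(sorted((a, b)))  # type: ignore[return-value]


def read_decisions(path: str | Path) -> list[CurationDecision]:
    """Read a decision ledger from JSON (list of objects) or TSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return [CurationDecision(**d) for d in raw]
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        CurationDecision(
            target_type=row["target_type"],
            target=row["target"],
            verdict=row["verdict"],
            reason=row.get("reason", ""),
            note=row.get("note", ""),
            source=row.get("source", "manual") or "manual",
        )
        for _, row in df.iterrows()
    ]


def write_decisions(decisions: Sequence[CurationDecision], path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([vars(d) for d in decisions], fh, indent=1)
    else:
        pd.DataFrame([vars(d) for d in decisions]).to_csv(path, sep="\t", index=False)
    return path


@dataclass
class CurationResult:
    """Outcome of replaying a decision ledger."""

    kept_pairs: list[GenePair]
    curated_corpus: DocumentCorpus
    r_genes: list[str]
    removals: list[dict] = field(default_factory=list)


def apply_curation(
    pairs: Sequence[GenePair],
    corpus: DocumentCorpus,
    decisions: Sequence[CurationDecision],
    seed_genes: Sequence[str],
    if_threshold: float | None = None,
) -> CurationResult:
    """Replay curation decisions against scored pairs and their corpus.

    Order of operations: (1) optional impact-factor filter on the corpus,
    (2) drop abstracts with a discard verdict, (3) drop pairs with a
    discard verdict, (4) drop pairs whose entire evidence vanished in
    (1)–(2). Kept pairs carry their surviving evidence pmids; scores are
    left as computed on the pre-curation corpus. R-genes are the genes of
    the kept pairs minus the seed genes. A decision referencing an unknown
    pair or pmid is an error listing every offender.
    """
    known_pairs = {p.key for p in pairs}
    known_pmids = set(corpus.pmids)
    offenders = []
    for d in decisions:
        if d.target_type == "pair" and d.pair_key not in known_pairs:
            offenders.append(f"pair {d.target}")
        if d.target_type == "pmid" and d.target not in known_pmids:
            offenders.append(f"pmid {d.target}")
    if offenders:
        raise ValueError(
            "curation decisions reference unknown targets: " + ", ".join(offenders)
        )

    curated = corpus
    if if_threshold is not None:
        curated = filter_by_impact_factor(curated, if_threshold)
    discarded_pmids = {
        d.target: d.reason for d in decisions
        if d.target_type == "pmid" and d.verdict == "discard"
    }
    curated = DocumentCorpus(
        records=[r for r in curated.records if r.pmid not in discarded_pmids],
        provenance=list(curated.provenance) + [f"curation: discarded {len(discarded_pmids)} pmid(s)"],
    )
    surviving_pmids = set(curated.pmids)

    discarded_pairs = {
        d.pair_key: d.reason for d in decisions
        if d.target_type == "pair" and d.verdict == "discard"
    }

    kept: list[GenePair] = []
    removals: list[dict] = []
    for p in pairs:
        if p.key in discarded_pairs:
            removals.append(
                {"pair": p.key, "reason": discarded_pairs[p.key], "stage": "pair_verdict"}
            )
            continue
        evidence = tuple(e for e in p.evidence_pmids if e in surviving_pmids)
        if not evidence:
            removals.append(
                {"pair": p.key, "reason": "no_surviving_evidence", "stage": "evidence"}
            )
            continue
        kept.append(
            GenePair(
                gene_a=p.gene_a,
                gene_b=p.gene_b,
                score=p.score,
                n_joint=len(evidence),
                evidence_pmids=evidence,
            )
        )
    for removal in removals:
        logger.info("curation removed pair %s (%s)", removal["pair"], removal["reason"])

    seeds = set(seed_genes)
    r_genes = sorted({g for p in kept for g in p.key} - seeds)
    return CurationResult(
        kept_pairs=kept, curated_corpus=curated, r_genes=r_genes, removals=removals
    )


@dataclass(frozen=True)
class AGene:
    """An additional gene added from manual citation chasing, with refs."""

    symbol: str
    references: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError(f"A-gene {self.symbol} requires at least one reference")


def add_a_genes(
    genes: Sequence[str], references: Mapping[str, Sequence[str]]
) -> list[AGene]:
    """Create A-gene records; every gene must carry at least one reference."""
    records = []
    for g in genes:
        refs = tuple(references.get(g, ()))
        if not refs:
            raise ValueError(f"A-gene {g} has no supporting reference")
        records.append(AGene(symbol=g, references=refs))
    return records


@dataclass(frozen=True)
class GenesetMember:
    symbol: str
    category: str
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")


@dataclass
class Geneset:
    """A named key-event geneset with per-member category and provenance."""

    name: str
    members: dict[str, GenesetMember] = field(default_factory=dict)

    @property
    def symbols(self) -> list[str]:
        return sorted(self.members)

    def by_category(self, category: str) -> list[str]:
        return sorted(
            s for s, m in self.members.items() if m.category == category
        )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members


@dataclass(frozen=True)
class AccountingRow:
    """One key-event line of the geneset accounting table."""

    ke: str
    n_S: int
    n_R: int
    n_A: int
    n_total: int
    n_seed: int | None = None
    n_abstracts: int | None = None
    n_unique_genes: int | None = None
    n_abstracts_curated: int | None = None


def _dedupe(symbols: Sequence[str], label: str, name: str) -> list[str]:
    seen: list[str] = []
    for s in symbols:
        if s in seen:
            logger.warning("geneset %s: duplicate %s-gene %r collapsed", name, label, s)
        else:
            seen.append(s)
    return seen


def assemble_geneset(
    name: str,
    s_genes: Sequence[str],
    r_genes: Sequence[str],
    a_genes: Sequence[str] | Sequence[AGene],
    provenance: Mapping[str, Sequence[str]] | None = None,
) -> tuple[Geneset, AccountingRow]:
    """Pool S, R and A genes into one geneset with category precedence S>R>A.

    Duplicates within a list are collapsed with a warning; a gene in more
    than one category keeps the highest-precedence label and is counted in
    that category only, so the accounting row always satisfies
    ``n_total == n_S + n_R + n_A`` on the de-overlapped categories.
    """
    a_records = [
        a if isinstance(a, AGene) else AGene(symbol=a, references=("manual",))
        for a in a_genes
    ]
    s_list = _dedupe(list(s_genes), "S", name)
    r_list = _dedupe(list(r_genes), "R", name)
    a_list = _dedupe([a.symbol for a in a_records], "A", name)
    a_refs = {a.symbol: a.references for a in a_records}

    provenance = provenance or {}
    members: dict[str, GenesetMember] = {}
    for category, symbols in (("S", s_list), ("R", r_list), ("A", a_list)):
        for s in symbols:
            if s in members:
                continue  # precedence: earlier (higher) category wins
            prov = tuple(provenance.get(s, ()))
            if category == "A":
                prov = prov + tuple(a_refs.get(s, ()))
            members[s] = GenesetMember(symbol=s, category=category, provenance=prov)

    geneset = Geneset(name=name, members=members)
    row = AccountingRow(
        ke=name,
        n_S=len(geneset.by_category("S")),
        n_R=len(geneset.by_category("R")),
        n_A=len(geneset.by_category("A")),
        n_total=len(geneset),
    )
    return geneset, row


def merge_genesets(g1: Geneset, g2: Geneset, merged_name: str) -> Geneset:
    """Union of two genesets; categories merge with precedence S>R>A and
    provenance is concatenated."""
    members: dict[str, GenesetMember] = dict(g1.members)
    for s, m in g2.members.items():
        if s in members:
            prior = members[s]
            category = min(prior.category, m.category, key=_PRECEDENCE.__getitem__)
            prov = prior.provenance + tuple(
                p for p in m.provenance if p not in prior.provenance
            )
            members[s] = GenesetMember(symbol=s, category=category, provenance=prov)
        else:
            members[s] = m
    return Geneset(name=merged_name, members=members)


def overlap_report(
    geneset: Geneset, reference_lists: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Exact intersection of the geneset with user-supplied reference lists
    (e.g. published COPD or asthma gene lists)."""
    rows = []
    members = set(geneset.members)
    for ref_name, ref_genes in reference_lists.items():
        shared = sorted(members & set(ref_genes))
        rows.append(
            {
                "reference": ref_name,
                "n_reference": len(set(ref_genes)),
                "n_overlap": len(shared),
                "members": ",".join(shared),
            }
        )
    return pd.DataFrame(rows, columns=["reference", "n_reference", "n_overlap", "members"])


def annotate_pairs(
    pairs: Sequence[GenePair],
    annotation_tables: Mapping[str, Mapping[str, Iterable[str]]],
) -> pd.DataFrame:
    """Annotate each pair with the attributes shared by both members.

    ``annotation_tables`` maps a resource name (e.g. a pathway database
    export) to a gene→attributes table. A pair with no shared attribute is
    retained with an empty annotation.
    """
    rows = []
    for p in pairs:
        row: dict = {"gene_a": p.gene_a, "gene_b": p.gene_b, "score": p.score}
        for resource, table in annotation_tables.items():
            shared = sorted(
                set(table.get(p.gene_a, ())) & set(table.get(p.gene_b, ()))
            )
            row[resource] = ";".join(shared)
        rows.append(row)
    return pd.DataFrame(rows)


def apply_categories(net: nx.Graph, geneset: Geneset) -> nx.Graph:
    """Label network nodes with the geneset's S/R/A categories in place."""
    for node in net.nodes:
        member = geneset.members.get(node)
        if member is not None:
            net.nodes[node]["category"] = member.category
    return net


# ---------------------------------------------------------------------------
# GMT serialization
# ---------------------------------------------------------------------------


def _description_for(geneset: Geneset) -> str:
    payload = {
        "categories": {s: m.category for s, m in sorted(geneset.members.items())},
        "provenance": {
            s: list(m.provenance)
            for s, m in sorted(geneset.members.items())
            if m.provenance
        },
    }
    return json.dumps(payload, separators=(",", ":"))


def write_gmt(genesets: Sequence[Geneset], path: str | Path) -> Path:
    """Write genesets as GMT lines ``name<TAB>description<TAB>gene...``.

    Categories and provenance are serialized as compact JSON in the
    description field so the round trip is lossless.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.name, _description_for(gs)] + gs.symbols) + "\n")
    return path


def read_gmt(path: str | Path) -> list[Geneset]:
    """Read a GMT file.

    Files written by :func:`write_gmt` restore categories and provenance
    from the JSON description; foreign GMT files (free-text description)
    load with every member defaulting to category 'S' and no provenance.
    """
    genesets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, description, genes = parts[0], parts[1], parts[2:]
            categories: Mapping[str, str] = {}
            provenance: Mapping[str, Sequence[str]] = {}
            try:
                payload = json.loads(description)
                categories = payload.get("categories", {})
                provenance = payload.get("provenance", {})
            except (json.JSONDecodeError, AttributeError):
                pass  # foreign GMT file: description is free text
            members = {
                g: GenesetMember(
                    symbol=g,
                    category=categories.get(g, "S"),
                    provenance=tuple(provenance.get(g, ())),
                )
                for g in genes
                if g
            }
            genesets.append(Geneset(name=name, members=members))
    return genesets
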