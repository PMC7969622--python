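"""Synthetic corpora and expression data with known ground truth.

Two generators make every pipeline stage testable offline:

* a **block-model abstract corpus**: each document picks one topic block of
  genes; genes of that block are mentioned with probability ``p_in``,
  genes of other blocks with ``p_out`` and genes outside any block with the
  background rate ``q``. Gene symbols are embedded as standalone tokens in
  lowercase filler sentences, so dictionary recognition recovers the
  planted incidence exactly and tests exercise co-occurrence statistics,
  not tokenizer luck. Closed-form expected cosine similarities are
  available for calibration.

* a **two-group expression matrix**: Gaussian noise around per-gene
  baselines on a log-like scale, a mean shift ``delta`` on the geneset
  genes in the treated group, and an optional continuous technical
  confounder loading on a disjoint gene subset — the structure of a
  treated-vs-control transcriptomic validation dataset.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import AbstractRecord, DocumentCorpus
from .validation import ExpressionMatrix

__all__ = [
    "CorpusSimConfig",
    "ExprSimConfig",
    "ConfounderConfig",
    "simulate_corpus",
    "expected_cosine",
    "simulate_expression",
]

DEFAULT_JOURNALS: tuple[tuple[str, float], ...] = (
    ("synthetic journal of high impact", 8.5),
    ("synthetic respiratory journal", 4.2),
    ("synthetic archive of notes", 1.5),
)

_FILLER = (
    "observations in airway epithelium culture after exposure were recorded",
    "the response of mucosal tissue to the stimulus was characterised",
    "expression changes accompanied the treatment in this model",
)


@dataclass(frozen=True)
class CorpusSimConfig:
    """Block-model corpus parameters.

    ``blocks`` partitions a subset of ``genes``; remaining genes are
    background. Probabilities: ``p_in`` mention rate for the document's
    topic block, ``p_out`` for other blocks, ``q`` for background genes.
    """

    genes: tuple[str, ...]
    n_docs: int = 200
    blocks: tuple[tuple[str, ...], ...] = ()
    p_in: float = 0.8
    p_out: float = 0.0
    q: float = 0.3
    key_terms: tuple[str, ...] = ("tobacco", "smoke")
    journals: tuple[tuple[str, float], ...] = DEFAULT_JOURNALS
    seed: int = 0
    adversarial: bool = False

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("require 0 <= p_out <= p_in <= 1")
        if not 0 <= self.q <= 1:
            raise ValueError("q must be in [0, 1]")
        blocked = [g for b in self.blocks for g in b]
        if len(blocked) != len(set(blocked)):
            raise ValueError("blocks must be disjoint")
        unknown = set(blocked) - set(self.genes)
        if unknown:
            raise ValueError(f"block genes not in gene list: {sorted(unknown)}")

    def mention_prob(self, gene: str, topic: int | None) -> float:
        """Probability that ``gene`` is mentioned in a document with the
        given topic block (``None`` when the config has no blocks)."""
        for b, block in enumerate(self.blocks):
            if gene in block:
                return self.p_in if topic == b else self.p_out
        return self.q


def _doc_text(
    mentioned: Sequence[str], key_term: str, filler: str, adversarial: bool
) -> str:
    gene_clause = ", ".join(mentioned) if mentioned else "no candidate gene"
    text = f"Effects of {key_term} on {gene_clause} were investigated; {filler}."
    if adversarial:
        # lowercase homographs and a measurement acronym: recognisable only
        # if the NER policy is broken
        decoys = " ".join(g.lower() for g in mentioned) or "egfr"
        text += f" Decoy terms {decoys} and CBF readings are reported."
    return text


def simulate_corpus(
    config: CorpusSimConfig,
) -> tuple[DocumentCorpus, dict[str, frozenset[str]]]:
    """Draw a corpus from the block model.

    Returns the corpus and the planted ground-truth incidence
    (gene → set of pmids), which :func:`aopminer.gene_ner.build_tdm` must
    reproduce exactly.
    """
    rng = np.random.default_rng(config.seed)
    records: list[AbstractRecord] = []
    truth: dict[str, set[str]] = {g: set() for g in config.genes}
    n_blocks = len(config.blocks)
    for i in range(config.n_docs):
        pmid = f"SIM{i:07d}"
        topic = int(rng.integers(n_blocks)) if n_blocks else None
        mentioned = [
            g for g in config.genes if rng.random() < config.mention_prob(g, topic)
        ]
        for g in mentioned:
            truth[g].add(pmid)
        key_term = config.key_terms[i % len(config.key_terms)] if config.key_terms else "exposure"
        journal, _impf = config.journals[int(rng.integers(len(config.journals)))]
        records.append(
            AbstractRecord(
                pmid=pmid,
                title=f"Synthetic abstract {i} on {key_term}",
                abstract=_doc_text(
                    mentioned, key_term, _FILLER[i % len(_FILLER)], config.adversarial
                ),
                journal=journal,
                year=int(rng.integers(2000, 2022)),
            )
        )
    corpus = DocumentCorpus(
        records=records, provenance=[f"simulate_corpus(seed={config.seed})"]
    )
    return corpus, {g: frozenset(s) for g, s in truth.items()}


def expected_cosine(
    config: CorpusSimConfig,
    gene_a: str,
    gene_b: str,
    monte_carlo: int = 0,
) -> tuple[float, float | None]:
    """Expected cosine similarity of a gene pair under the block model.

    Closed form: with the document topic T uniform over blocks and
    mentions conditionally independent given T,

        E[n_g]  = N * E_T[pi_g(T)]
        E[n_gh] = N * E_T[pi_g(T) * pi_h(T)]
        cos     = E[n_gh] / sqrt(E[n_g] * E[n_h])

    which for two background genes reduces to ``q``. With
    ``monte_carlo=m > 0`` the value is instead estimated from ``m``
    simulated corpora (seeds derived from ``config.seed``) and returned
    with its standard error; the closed-form mode returns ``(value, None)``.
    """
    for g in (gene_a, gene_b):
        if g not in config.genes:
            raise ValueError(f"gene {g} not in config")
    if monte_carlo > 0:
        values = []
        for rep in range(monte_carlo):
            rep_cfg = CorpusSimConfig(
                **{**vars(config), "seed": config.seed + 1 + rep}
            )
            _, truth = simulate_corpus(rep_cfg)
            na, nb = len(truth[gene_a]), len(truth[gene_b])
            nab = len(truth[gene_a] & truth[gene_b])
            values.append(nab / np.sqrt(na * nb) if na and nb else 0.0)
        arr = np.asarray(values)
        se = float(arr.std(ddof=1) / np.sqrt(monte_carlo)) if monte_carlo > 1 else None
        return float(arr.mean()), se

    topics: list[int | None] = (
        list(range(len(config.blocks))) if config.blocks else [None]
    )
    pa = np.array([config.mention_prob(gene_a, t) for t in topics])
    pb = np.array([config.mention_prob(gene_b, t) for t in topics])
    e_a, e_b, e_ab = pa.mean(), pb.mean(), (pa * pb).mean()
    if e_a == 0 or e_b == 0:
        return 0.0, None
    return float(e_ab / np.sqrt(e_a * e_b)), None


@dataclass(frozen=True)
class ConfounderConfig:
    """A continuous technical covariate loading on a gene subset.

    Defaults are chosen so the planted factor structure is identifiable in
    a 20-sample PCA: the confounder's total planted variance sits clearly
    above the sampling-noise eigenvalue edge and clearly apart from the
    treatment factor's variance, so "the confounder's principal component"
    is well defined. Factors with near-equal planted variances mix under
    PCA rotation and have no recoverable axis.
    """

    n_genes: int = 50
    loading: float = 1.5


@dataclass(frozen=True)
class ExprSimConfig:
    """Two-group expression simulation parameters.

    Defaults give the reference validation scenario: 10 treated vs 10
    control samples, a 25-gene geneset shifted by ``delta`` (in units of
    ``noise_sd``-scaled log-like expression) in the treated group, inside a
    200-gene background.
    """

    n_genes: int = 200
    n_samples_per_group: int = 10
    n_geneset_genes: int = 25
    delta: float = 5.0
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    confounder: ConfounderConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.n_geneset_genes > self.n_genes:
            raise ValueError("geneset larger than gene universe")
        if self.confounder is not None and (
            self.n_geneset_genes + self.confounder.n_genes > self.n_genes
        ):
            raise ValueError("geneset and confounder gene subsets must fit disjointly")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def geneset_genes(self) -> list[str]:
        return self.gene_names[: self.n_geneset_genes]

    @property
    def confounder_genes(self) -> list[str]:
        if self.confounder is None:
            return []
        return self.gene_names[self.n_geneset_genes :][: self.confounder.n_genes]


def simulate_expression(
    config: ExprSimConfig,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Simulate the two-group matrix; returns (matrix, treatment labels).

    Metadata carries ``treatment`` (categorical) and, when a confounder is
    configured, its per-sample value as the continuous covariate
    ``confounder``.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names
    n_per = config.n_samples_per_group
    samples = [f"control_{i + 1:02d}" for i in range(n_per)] + [
        f"treated_{i + 1:02d}" for i in range(n_per)
    ]
    labels = np.array(["control"] * n_per + ["treated"] * n_per)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    X = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), 2 * n_per))

    gs_idx = [genes.index(g) for g in config.geneset_genes]
    X[np.ix_(gs_idx, np.where(labels == "treated")[0])] += config.delta

    metadata = pd.DataFrame({"treatment": labels}, index=samples)
    types = {"treatment": "categorical"}
    if config.confounder is not None:
        conf_values = rng.normal(0.0, 1.0, size=2 * n_per)
        conf_idx = [genes.index(g) for g in config.confounder_genes]
        X[conf_idx, :] += config.confounder.loading * conf_values[None, :]
        metadata["confounder"] = conf_values
        types["confounder"] = "continuous"

    expr = ExpressionMatrix(
        values=pd.DataFrame(X, index=genes, columns=samples),
        metadata=metadata,
        covariate_types=types,
    )
    return expr, labels
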