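import numpy as np
import pytest

from aopminer import (
    AbstractRecord,
    DocumentCorpus,
    GeneDictionary,
    build_tdm,
)


@pytest.fixture
def tiny_corpus() -> DocumentCorpus:
    """Three abstracts with known gene mentions and journals."""
    return DocumentCorpus(
        records=[
            AbstractRecord(
                pmid="1001",
                title="EGFR activation by tobacco smoke",
                abstract="EGFR and MUC5AC are induced; TLR4 is not discussed here.",
                journal="Journal of Airway Biology",
                year=2018,
            ),
            AbstractRecord(
                pmid="1002",
                title="MUC5AC regulation",
                abstract="MUC5AC expression after smoke exposure — unicode dash kept.",
                journal="Respiratory Notes",
                year=2020,
            ),
            AbstractRecord(
                pmid="1003",
                title="Oxidative stress signalling",
                abstract="EGFR-dependent signalling via reactive oxygen species.",
                journal="Journal of Airway Biology",
                year=2015,
            ),
        ],
        provenance=["fixture"],
    )


@pytest.fixture
def dictionary() -> GeneDictionary:
    return GeneDictionary(
        approved_symbols=frozenset({"EGFR", "MUC5AC", "TLR4", "NQO1", "CBF"}),
        aliases={"HER1": "EGFR"},
        exclusion_list=frozenset({"CBF"}),
    )


@pytest.fixture
def tiny_tdm(tiny_corpus, dictionary):
    return build_tdm(tiny_corpus, dictionary)


def brute_force_cosine(doc_sets: dict[str, frozenset]) -> dict[tuple[str, str], float]:
    """Independent oracle: cosine from raw document sets."""
    genes = sorted(doc_sets)
    out = {}
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            na, nb = len(doc_sets[a]), len(doc_sets[b])
            nab = len(doc_sets[a] & doc_sets[b])
            out[(a, b)] = nab / np.sqrt(na * nb) if na and nb else 0.0
    return out


def greedy_ward_merges(points: np.ndarray) -> list[set[frozenset[int]]]:
    """Oracle: at each agglomeration step, exhaustively pick the merge that
    minimizes the increase in total within-cluster sum of squares.

    Returns, per step, the partition (as a set of frozensets of point
    indices) after the merge.
    """
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(points))]

    def sse_increase(a: frozenset[int], b: frozenset[int]) -> float:
        mu_a = points[list(a)].mean(axis=0)
        mu_b = points[list(b)].mean(axis=0)
        return len(a) * len(b) / (len(a) + len(b)) * float(np.sum((mu_a - mu_b) ** 2))

    partitions = []
    while len(clusters) > 1:
        best = min(
            (
                (sse_increase(clusters[i], clusters[j]), i, j)
                for i in range(len(clusters))
                for j in range(i + 1, len(clusters))
            ),
            key=lambda t: t[0],
        )
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        partitions.append(set(clusters))
    return partitions


def linkage_merge_partitions(linkage: np.ndarray, n: int) -> list[set[frozenset[int]]]:
    """Partition sequence implied by a SciPy linkage matrix."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    active = set(range(n))
    partitions = []
    for step, row in enumerate(linkage):
        left, right = int(row[0]), int(row[1])
        new = members[left] | members[right]
        members[n + step] = new
        active -= {left, right}
        active.add(n + step)
        partitions.append({members[a] for a in active})
    return partitions
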