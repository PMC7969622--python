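"""Geneset validation against expression data.

The validation recipe: subset a normalized gene×sample expression matrix
to the geneset, Z-score each gene across samples, cluster samples
agglomeratively on Euclidean distances with Ward linkage, and quantify how
well the resulting partition recovers known sample labels (adjusted Rand
index, per-cluster purity). Separately, fit a PCA per geneset and test
each principal component for association with sample covariates — ANOVA
for categorical covariates, Spearman rank correlation for continuous ones
(e.g. technical read-quality fractions such as perc_gene/perc_unmapped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.stats import false_discovery_control
from sklearn.metrics import adjusted_rand_score

from .curation_geneset import Geneset

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClusteringResult",
    "PCAModel",
    "AgreementScores",
    "read_expression",
    "read_metadata",
    "write_metadata",
    "subset_by_geneset",
    "zscore_rows",
    "hierarchical_cluster",
    "cluster_label_agreement",
    "pca_fit",
    "associate_pcs",
]


@dataclass
class ExpressionMatrix:
    """Normalized expression values (genes × samples) plus sample metadata.

    ``covariate_types`` declares each metadata column as ``"categorical"``
    or ``"continuous"``; the association tests depend on this typing.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None
    covariate_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if self.metadata is not None:
            if set(self.metadata.index) != set(self.values.columns):
                raise ValueError("metadata rows must align 1:1 with samples")
            self.metadata = self.metadata.loc[self.values.columns]
            for cov, kind in self.covariate_types.items():
                if kind not in ("categorical", "continuous"):
                    raise ValueError(
                        f"covariate {cov!r} typed {kind!r}; expected categorical/continuous"
                    )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_expression(
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a gene×sample TSV (gene ids in the first column) and optional
    metadata."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    metadata, types = (None, {})
    if metadata_path is not None:
        metadata, types = read_metadata(metadata_path)
    return ExpressionMatrix(values=values, metadata=metadata, covariate_types=types)


def read_metadata(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read sample metadata TSV whose second line is a type row.

    Layout: header ``sample<TAB>cov1<TAB>cov2``, then a row with first
    field ``#type`` giving ``categorical``/``continuous`` per covariate,
    then one row per sample.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.empty or str(raw.iloc[0, 0]) != "#type":
        raise ValueError(f"{path}: expected a '#type' row after the header")
    types = {
        col: str(raw.iloc[0][col]).strip()
        for col in raw.columns[1:]
    }
    body = raw.iloc[1:].set_index(raw.columns[0])
    for cov, kind in types.items():
        if kind == "continuous":
            body[cov] = body[cov].astype(float)
    return body, types


def write_metadata(
    metadata: pd.DataFrame, covariate_types: Mapping[str, str], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        cols = list(metadata.columns)
        fh.write("\t".join(["sample"] + cols) + "\n")
        fh.write("\t".join(["#type"] + [covariate_types[c] for c in cols]) + "\n")
        for sample, row in metadata.iterrows():
            fh.write("\t".join([str(sample)] + [str(v) for v in row]) + "\n")
    return path


def subset_by_geneset(
    expr: ExpressionMatrix, geneset: Geneset | Sequence[str]
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict the matrix to geneset genes; report members not measured."""
    wanted = list(geneset.symbols) if isinstance(geneset, Geneset) else list(geneset)
    present = [g for g in wanted if g in expr.values.index]
    missing = sorted(set(wanted) - set(present))
    if not present:
        raise ValueError("no geneset gene is present in the expression matrix")
    if missing:
        logger.info("subset_by_geneset: %d geneset gene(s) not measured", len(missing))
    sub = ExpressionMatrix(
        values=expr.values.loc[present],
        metadata=expr.metadata,
        covariate_types=dict(expr.covariate_types),
    )
    return sub, missing


def zscore_rows(expr: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Mean-center and scale each gene to unit variance across samples.

    Uses the sample standard deviation (n-1 denominator). Zero-variance
    genes cannot be scaled and are dropped with a warning; if every gene is
    constant the operation fails.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    sd = expr.values.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance; nothing to z-score")
    if (~keep).any():
        logger.warning("zscore_rows: dropped %d zero-variance gene(s)", int((~keep).sum()))
    values = expr.values.loc[keep]
    z = values.sub(values.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(
        values=z, metadata=expr.metadata, covariate_types=dict(expr.covariate_types)
    )


@dataclass
class ClusteringResult:
    """Agglomerative clustering output: SciPy linkage plus item labels."""

    linkage: np.ndarray
    items: list[str]
    axis: str

    def assignments(self, k: int) -> np.ndarray:
        """Cluster labels (1..k) from cutting the dendrogram into k groups."""
        if not 1 <= k <= len(self.items):
            raise ValueError(f"k must be in [1, {len(self.items)}]")
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaf depth equals the root merge height."""
        n = len(self.items)
        heights = {i: 0.0 for i in range(n)}

        def subtree(node: int) -> str:
            if node < n:
                return self.items[node]
            row = self.linkage[node - n]
            left, right, h = int(row[0]), int(row[1]), float(row[2])
            parts = []
            for child in (left, right):
                parts.append(f"{subtree(child)}:{h - heights[child]:.6g}")
            heights[node] = h
            return f"({parts[0]},{parts[1]})"

        root = 2 * n - 2
        return subtree(root) + ";"


def hierarchical_cluster(expr: ExpressionMatrix, axis: str = "samples") -> ClusteringResult:
    """Ward-linkage agglomerative clustering on pairwise Euclidean distances.

    ``axis="samples"`` clusters the columns (the usual validation view);
    ``axis="genes"`` clusters the rows. The linkage is the squared-distance
    Ward update applied to Euclidean distances (the convention of SciPy and
    of R's ``ward.D2``), computed deterministically.
    """
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    points = expr.values.T if axis == "samples" else expr.values
    if points.shape[0] < 2:
        raise ValueError(f"need at least 2 {axis} to cluster")
    linkage = hierarchy.linkage(points.to_numpy(), method="ward", metric="euclidean")
    return ClusteringResult(linkage=linkage, items=list(points.index), axis=axis)


@dataclass(frozen=True)
class AgreementScores:
    """Chance-corrected and per-cluster agreement with reference labels."""

    ari: float
    purity: Mapping[int, float]
    overall_purity: float


def cluster_label_agreement(
    result: ClusteringResult,
    labels: Sequence | Mapping[str, object],
    k: int,
) -> AgreementScores:
    """Compare the k-cluster partition with known labels.

    ``labels`` is either a sequence aligned with ``result.items`` or a
    mapping item→label. ARI is 1 for identical partitions and has
    expectation 0 under random labelling; purity is the modal-label
    fraction per cluster.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(labels, Mapping):
        y = [labels[item] for item in result.items]
    else:
        if len(labels) != len(result.items):
            raise ValueError("labels must align with clustered items")
        y = list(labels)
    assignments = result.assignments(k)
    ari = float(adjusted_rand_score(y, assignments))
    purity: dict[int, float] = {}
    for cluster in sorted(set(assignments)):
        members = [lab for lab, a in zip(y, assignments) if a == cluster]
        counts = pd.Series(members).value_counts()
        purity[int(cluster)] = float(counts.iloc[0] / len(members))
    overall = float(
        sum(p * list(assignments).count(c) for c, p in purity.items()) / len(y)
    )
    return AgreementScores(ari=ari, purity=purity, overall_purity=overall)


@dataclass
class PCAModel:
    """PCA of samples (observations) × genes (variables), fit by SVD."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    mean: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_fit(expr: ExpressionMatrix, n_components: int | None = None) -> PCAModel:
    """Fit a PCA with samples as observations via SVD of the centered matrix.

    Genes are centered across samples; apply :func:`zscore_rows` first to
    reproduce the clustering preprocessing. ``variance_explained`` is each
    component's share of the total variance, so a truncated model sums
    to < 1.
    """
    X = expr.values.T  # samples × genes
    n_samples, n_genes = X.shape
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_rank = min(n_samples - 1, n_genes)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc.to_numpy(), full_matrices=False)
    total_var = float(np.sum(s**2))
    if total_var == 0:
        raise ValueError("expression matrix has zero total variance")
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * s[:n_components], index=X.index, columns=pcs
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=X.columns, columns=pcs)
    variance_explained = (s[:n_components] ** 2) / total_var
    return PCAModel(
        scores=scores, loadings=loadings, variance_explained=variance_explained, mean=mean
    )


def associate_pcs(
    pca: PCAModel,
    metadata: pd.DataFrame,
    covariate_types: Mapping[str, str],
) -> pd.DataFrame:
    """Test every (component, covariate) pair for association.

    Categorical covariates: one-way ANOVA of scores across levels
    (covariates with a single level are skipped with a warning).
    Continuous covariates: Spearman rank correlation. P-values are
    reported raw and Benjamini–Hochberg adjusted across the whole table.
    """
    metadata = metadata.loc[pca.scores.index]
    rows = []
    for cov in metadata.columns:
        kind = covariate_types.get(cov)
        if kind is None:
            raise ValueError(f"covariate {cov!r} has no declared type")
        values = metadata[cov]
        if kind == "categorical":
            levels = values.unique()
            if len(levels) < 2:
                logger.warning("associate_pcs: covariate %r has one level; skipped", cov)
                continue
        for pc in pca.scores.columns:
            scores = pca.scores[pc]
            if kind == "categorical":
                groups = [scores[values == lv].to_numpy() for lv in levels]
                stat, p = stats.f_oneway(*groups)
                test = "anova"
            else:
                rho = stats.spearmanr(scores.to_numpy(), values.to_numpy(dtype=float))
                stat, p = rho.statistic, rho.pvalue
                test = "spearman"
            rows.append(
                {
                    "component": pc,
                    "covariate": cov,
                    "test": test,
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    table = pd.DataFrame(
        rows, columns=["component", "covariate", "test", "statistic", "p_value"]
    )
    if not table.empty:
        pvals = table["p_value"].fillna(1.0).clip(0, 1)
        table["p_adj"] = false_discovery_control(pvals, method="bh")
    else:
        table["p_adj"] = []
    return table
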