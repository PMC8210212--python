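"""Single-cell expression preprocessing for the activity model.

The propagation model needs per-gene values in [0, 1] and, crucially, needs
true zeros (a gene that is off) distinguished from dropout zeros (a gene
whose transcript failed capture).  The pipeline is therefore:

1. consensus-cluster dropout imputation on raw counts,
2. log(1 + x) transform,
3. per-gene truncation at the 0.99 quantile (outlier cells would otherwise
   own the whole dynamic range),
4. per-gene min-max scaling to [0, 1].

Clustering utilities (2-D embedding + k-means) and Rand-index agreement
scores support the imputation-quality comparison workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.cluster import pair_confusion_matrix

STAGES = ("counts", "imputed", "normalized")


@dataclass
class GeneExpressionMatrix:
    """Genes x cells expression values tagged with a processing stage."""

    values: pd.DataFrame  # rows = gene symbols, columns = cell ids
    stage: str = "counts"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dups)!r}")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("expression values must be non-negative")
        if self.stage == "normalized" and arr.size and np.nanmax(arr) > 1 + 1e-12:
            raise ValueError("normalized values must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterLabels:
    """Integer cluster assignment per cell."""

    labels: pd.Series  # index = cell ids, values = int labels
    k: int
    seed: int | None = None
    embedding: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(self.labels):
            raise ValueError("k must be in [1, n_cells]")

    @property
    def cells(self) -> list[str]:
        return list(self.labels.index)


def _consensus_clusterings(
    counts: pd.DataFrame, k_grid: Sequence[int], seed: int
) -> list[np.ndarray]:
    """Cells clustered for each (k, distance) pair of the consensus grid.

    Two cell-cell geometries are used: Euclidean distance on log1p counts,
    and Spearman-style distance (Euclidean on per-cell gene ranks, which is
    monotone in 1 - Spearman correlation after per-cell standardization).
    """
    log = np.log1p(counts.to_numpy(dtype=float)).T  # cells x genes
    ranks = rankdata(log, axis=1)
    ranks = (ranks - ranks.mean(axis=1, keepdims=True)) / np.maximum(
        ranks.std(axis=1, keepdims=True), 1e-12
    )
    out = []
    for features in (log, ranks):
        for k in k_grid:
            km = KMeans(n_clusters=int(k), random_state=seed, n_init=10)
            out.append(km.fit_predict(features))
    return out


def impute_dropouts(
    counts: GeneExpressionMatrix,
    k_grid: Iterable[int] = range(2, 9),
    seed: int = 0,
) -> GeneExpressionMatrix:
    """Replace dropout zeros by consensus within-cluster gene means.

    Cells are clustered once per (k, distance) combination of the grid; a
    zero entry (gene g, cell j) is replaced by the average, over all those
    clusterings, of gene g's mean within the cluster containing j.  Nonzero
    entries are never altered, so a gene that is genuinely off everywhere
    (all cluster means zero) stays at zero.
    """
    if counts.stage != "counts":
        raise ValueError(f"expected stage 'counts', got {counts.stage!r}")
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    n_cells = counts.n_cells
    for k in k_grid:
        if k >= n_cells:
            raise ValueError(f"k={k} must be smaller than the number of cells ({n_cells})")

    arr = counts.values.to_numpy(dtype=float)
    clusterings = _consensus_clusterings(counts.values, k_grid, seed)

    imputed_sum = np.zeros_like(arr)
    for labels in clusterings:
        # genes x clusters means, broadcast back to genes x cells
        means = np.zeros_like(arr)
        for c in np.unique(labels):
            mask = labels == c
            means[:, mask] = arr[:, mask].mean(axis=1, keepdims=True)
        imputed_sum += means
    consensus = imputed_sum / len(clusterings)

    out = np.where(arr == 0, consensus, arr)
    return GeneExpressionMatrix(
        values=pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        stage="imputed",
    )


def quantile_truncate(values: np.ndarray, q: float, per_gene: bool = True) -> np.ndarray:
    """Cap values above the q-quantile (linear-interpolation / type-7 convention).

    With ``per_gene`` the quantile is taken along each row; otherwise over
    the whole array.
    """
    if not 0 < q <= 1:
        raise ValueError("quantile q must be in (0, 1]")
    arr = np.asarray(values, dtype=float)
    cap = np.quantile(arr, q, axis=1, keepdims=True) if per_gene else np.quantile(arr, q)
    return np.minimum(arr, cap)


def normalize_expression(
    m: GeneExpressionMatrix,
    q: float = 0.99,
    per_gene: bool = True,
) -> GeneExpressionMatrix:
    """log1p -> quantile truncation -> min-max scaling to [0, 1].

    The truncation quantile is computed with linear interpolation (the
    sort-based "type 7" convention) either per gene (default) or over the
    whole matrix; values above it are capped.  Constant genes map to
    all-zero rows.
    """
    if not 0 < q <= 1:
        raise ValueError("quantile q must be in (0, 1]")
    arr = m.values.to_numpy(dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("expression values must be non-negative")
    trunc = quantile_truncate(np.log1p(arr), q, per_gene=per_gene)

    if per_gene:
        lo = trunc.min(axis=1, keepdims=True)
        hi = trunc.max(axis=1, keepdims=True)
    else:
        lo, hi = trunc.min(), trunc.max()
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (trunc - lo) / np.where(span > 0, span, 1.0), 0.0)

    return GeneExpressionMatrix(
        values=pd.DataFrame(scaled, index=m.values.index, columns=m.values.columns),
        stage="normalized",
    )


def cluster_cells(
    m,
    k: int,
    seed: int = 0,
    embedding: str | pd.DataFrame = "pca",
) -> ClusterLabels:
    """k-means on a 2-D embedding of the cells.

    ``m`` is any features x cells table (expression matrix, circuit-activity
    matrix, or bare DataFrame).  The default embedding is the first two
    principal components (deterministic); a precomputed cells x 2 table —
    e.g. a t-SNE layout produced elsewhere — is accepted instead.
    """
    df = m.values if hasattr(m, "values") and isinstance(getattr(m, "values"), pd.DataFrame) else m
    cells = list(df.columns)
    if k > len(cells):
        raise ValueError(f"k={k} exceeds the number of cells ({len(cells)})")
    if k < 1:
        raise ValueError("k must be >= 1")

    if isinstance(embedding, pd.DataFrame):
        missing = set(cells) - set(embedding.index)
        if missing:
            raise ValueError(f"embedding missing cells: {sorted(missing)[:5]!r}")
        emb = embedding.loc[cells].to_numpy(dtype=float)
    elif embedding == "pca":
        X = df.to_numpy(dtype=float).T  # cells x features
        n_comp = min(2, X.shape[1], max(1, X.shape[0] - 1))
        emb = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    else:
        raise ValueError(f"unknown embedding {embedding!r}")

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(emb)
    return ClusterLabels(
        labels=pd.Series(labels, index=cells, name="cluster"),
        k=k,
        seed=seed,
        embedding=pd.DataFrame(emb, index=cells, columns=[f"dim{i+1}" for i in range(emb.shape[1])]),
    )


def _aligned(a: ClusterLabels | pd.Series, b: ClusterLabels | pd.Series):
    sa = a.labels if isinstance(a, ClusterLabels) else pd.Series(a)
    sb = b.labels if isinstance(b, ClusterLabels) else pd.Series(b)
    if set(sa.index) != set(sb.index):
        raise ValueError("partitions cover different cell sets")
    sb = sb.loc[sa.index]
    return sa.to_numpy(), sb.to_numpy()


def rand_index(a, b) -> float:
    """Plain Rand index: fraction of cell pairs grouped consistently."""
    xa, xb = _aligned(a, b)
    c = pair_confusion_matrix(xa, xb).astype(float)
    total = c.sum()
    if total == 0:  # single cell: zero pairs, perfect agreement by convention
        return 1.0
    return float((c[0, 0] + c[1, 1]) / total)


def adjusted_rand(a, b) -> float:
    """Chance-corrected Rand index (1 = identical partitions, ~0 = random)."""
    xa, xb = _aligned(a, b)
    return float(adjusted_rand_score(xa, xb))
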