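"""Single-cell TIL profiling: UMI QC, UPM normalization, embedding,
clustering and per-treatment cluster proportions.

Cells are kept when their total UMI count lies in an inclusive window
(default 400-10,000), counts are scaled to UMIs-per-million and
log2(UPM + 1)-transformed, a 2-D t-SNE embedding is computed on an
immune-gene panel, cells are clustered by k-means on the embedding
(default k = 3), and cluster occupancy fractions are compared between
treatment groups.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)


def qc_filter(
    counts: pd.DataFrame, min_total: int = 400, max_total: int = 10000
) -> pd.DataFrame:
    """Keep cells whose total UMI count is within [min_total, max_total]
    (inclusive bounds).  ``counts`` is genes x cells, integer."""
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("UMI counts must be integers")
    totals = counts.sum(axis=0)
    keep = (totals >= min_total) & (totals <= max_total)
    kept = counts.loc[:, keep]
    logger.info("UMI QC [%d, %d]: %d of %d cells kept", min_total, max_total,
                kept.shape[1], counts.shape[1])
    if kept.shape[1] == 0:
        logger.warning("no cells pass UMI QC")
    return kept


def upm_log_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(UPM + 1) where UPM scales each cell's counts to one million."""
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        cell = counts.columns[int(np.argmax(totals <= 0))]
        raise ValueError(f"cell {cell!r} has zero total UMI; run QC first")
    upm = counts.to_numpy(dtype=float) / totals * 1e6
    return pd.DataFrame(np.log2(upm + 1.0), index=counts.index, columns=counts.columns)


def embed_and_cluster(
    normalized: pd.DataFrame,
    gene_panel: "Optional[Sequence[str]]" = None,
    k: int = 3,
    seed: int = 0,
    perplexity: "Optional[float]" = None,
    cluster_on: str = "embedding",
) -> "tuple[pd.DataFrame, pd.Series]":
    """2-D stochastic-neighbor embedding of panel genes plus k-means labels.

    Panel genes absent from the matrix are logged and skipped.  Clustering
    runs on the embedding by default (``cluster_on="panel"`` clusters in
    panel expression space instead).  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_cells = normalized.shape[1]
    if n_cells < k:
        raise ValueError(f"fewer cells ({n_cells}) than clusters ({k})")
    if gene_panel is not None:
        panel = [g for g in gene_panel if g in normalized.index]
        missing = len(list(gene_panel)) - len(panel)
        if missing:
            logger.info("%d panel gene(s) absent from the matrix; skipped", missing)
        if not panel:
            raise ValueError("no panel genes present in the matrix")
        data = normalized.loc[panel]
    else:
        data = normalized
    X = data.to_numpy(dtype=float).T  # cells x genes
    if perplexity is None:
        perplexity = min(30.0, max(5.0, (n_cells - 1) / 3.0))
    tsne = TSNE(
        n_components=2, perplexity=perplexity, init="pca", random_state=seed
    )
    embedding = tsne.fit_transform(X)
    target = embedding if cluster_on == "embedding" else X
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(target)
    emb = pd.DataFrame(embedding, index=normalized.columns, columns=["tsne1", "tsne2"])
    return emb, pd.Series(labels, index=normalized.columns, name="cluster")


def cluster_proportions(labels: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Fraction of each group's cells in each cluster (rows = groups).

    Rows sum to 1; an empty group is an error.
    """
    if not labels.index.equals(groups.index):
        groups = groups.reindex(labels.index)
        if groups.isna().any():
            raise ValueError("labels and groups are not aligned")
    table = pd.crosstab(groups, labels)
    if (table.sum(axis=1) == 0).any():
        empty = table.index[table.sum(axis=1) == 0][0]
        raise ValueError(f"group {empty!r} has no cells")
    props = table.div(table.sum(axis=1), axis=0)
    props.index.name = "group"
    props.columns.name = "cluster"
    return props


class SingleCellClusterer(ClusterMixin, BaseEstimator):
    """QC + UPM-log normalization + embedding + k-means in one estimator.

    ``fit`` expects ``X`` as cells x genes raw UMI counts (scikit-learn
    orientation).  Fitted attributes: ``kept_cells_`` (boolean mask over
    input rows), ``embedding_``, ``labels_`` (per kept cell), and
    ``normalized_`` (genes x kept cells, log2(UPM+1)).
    """

    def __init__(
        self,
        gene_panel: "Optional[Sequence[str]]" = None,
        n_clusters: int = 3,
        min_total: int = 400,
        max_total: int = 10000,
        cluster_on: str = "embedding",
        random_state: int = 0,
    ):
        self.gene_panel = gene_panel
        self.n_clusters = n_clusters
        self.min_total = min_total
        self.max_total = max_total
        self.cluster_on = cluster_on
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            counts = X.T
        else:
            arr = np.asarray(X)
            counts = pd.DataFrame(
                arr.T,
                index=[f"g{j}" for j in range(arr.shape[1])],
                columns=[f"c{i}" for i in range(arr.shape[0])],
            )
        kept = qc_filter(counts, self.min_total, self.max_total)
        self.kept_cells_ = counts.columns.isin(kept.columns)
        self.normalized_ = upm_log_normalize(kept)
        self.embedding_, labels = embed_and_cluster(
            self.normalized_,
            gene_panel=self.gene_panel,
            k=self.n_clusters,
            seed=self.random_state,
            cluster_on=self.cluster_on,
        )
        self.cell_labels_ = labels
        self.labels_ = labels.to_numpy()
        self.n_features_in_ = counts.shape[0]
        return self
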