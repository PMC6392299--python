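"""Weighted co-expression network construction and module detection.

The stage chain: filter lowly expressed genes, raise |Pearson correlation|
to a soft power chosen for approximate scale-free topology, convert the
adjacency to a topological overlap similarity, cluster genes by average
linkage on the overlap dissimilarity (1 - TOM), cut the dendrogram into
color-labeled modules, merge modules with near-identical eigengenes, and
summarize each module by its eigengene (first principal component of the
standardized member expression).

Everything is deterministic: no stage draws random numbers.

The :class:`CoexpressionModuleDetector` estimator wraps the chain with a
scikit-learn fit interface (genes are the clustered objects; ``X`` follows
the sklearn samples-by-features orientation, features being genes).
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: Fixed, ordered color names for deterministic module labeling (largest
#: module first).  The names carry no meaning beyond identity; the list is
#: extended programmatically ("module41", ...) if more modules arise.
MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
    "antiquewhite2", "sienna3", "yellowgreen", "skyblue3", "plum1",
    "orangered4",
)


def module_label(rank: int) -> str:
    """Color label for the module of given size rank (0 = largest)."""
    if rank < len(MODULE_COLORS):
        return MODULE_COLORS[rank]
    return f"module{rank + 1}"


# ---------------------------------------------------------------------------
# gene filtering and correlation

def filter_genes(expr: pd.DataFrame, tpm_threshold: float = 1.0) -> pd.DataFrame:
    """Keep genes whose mean expression across all samples is strictly above
    ``tpm_threshold``; sample set and gene order are preserved."""
    if tpm_threshold < 0:
        raise ValueError("tpm_threshold must be >= 0")
    kept = expr.loc[expr.mean(axis=1) > tpm_threshold]
    logger.info("gene filter (mean > %g): %d of %d genes kept", tpm_threshold, len(kept), len(expr))
    if kept.empty:
        raise ValueError(
            f"no genes pass mean expression > {tpm_threshold}; lower tpm_threshold"
        )
    return kept


def log2_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), the working scale for correlations and eigengenes."""
    return np.log2(expr + 1.0)


def correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation across samples (rows = genes)."""
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        gene = expr.index[int(np.argmax(sd == 0))]
        raise ValueError(f"gene {gene!r} has zero variance; correlation undefined")
    return np.corrcoef(values)


def adjacency(
    expr: pd.DataFrame, beta: int, corr: "Optional[np.ndarray]" = None
) -> np.ndarray:
    """Unsigned weighted adjacency ``a_ij = |cor(i, j)|^beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    if corr is None:
        corr = correlation_matrix(expr)
    adj = np.abs(np.clip(corr, -1.0, 1.0)) ** float(beta)
    np.fill_diagonal(adj, 1.0)
    return adj


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Per-gene network connectivity ``k_i = sum_{j != i} a_ij``."""
    return adj.sum(axis=0) - np.diag(adj)


# ---------------------------------------------------------------------------
# scale-free fit and soft-threshold selection

def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> "tuple[float, float]":
    """Signed scale-free topology fit index of a connectivity distribution.

    Bins k into ``n_bins`` equal-width bins, regresses log10(occupancy
    fraction) on log10(mean k per bin) over non-empty bins, and returns
    ``(fit, slope)`` where fit is the regression R^2 when the slope is
    negative and 0 otherwise.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, frac = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            mean_k.append(k[mask].mean())
            frac.append(mask.mean())
    if len(mean_k) < 3:
        return 0.0, 0.0
    x = np.log10(np.asarray(mean_k))
    y = np.log10(np.asarray(frac))
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = np.sum((y - (slope * x + intercept)) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return (float(r2) if slope < 0 else 0.0), float(slope)


def sample_size_power_floor(n_samples: int) -> int:
    """Minimum advisable unsigned soft power for a given sample count.

    Small sample sizes leave a high noise floor on |Pearson r| (roughly
    1/sqrt(n)), so low powers keep substantial random adjacency between
    unrelated genes and wash out topological-overlap contrast.  The floors
    follow the standard WGCNA guidance for unsigned networks: 9 below 20
    samples, 8 for 20-30, 7 for 30-40, 6 above 40.
    """
    if n_samples < 20:
        return 9
    if n_samples < 30:
        return 8
    if n_samples < 40:
        return 7
    return 6


class SoftThresholdResult(NamedTuple):
    beta: int
    table: pd.DataFrame       # per-power fit, slope, mean/max connectivity
    reached_target: bool


def pick_soft_threshold(
    expr: pd.DataFrame,
    power_grid: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.8,
    corr: "Optional[np.ndarray]" = None,
) -> SoftThresholdResult:
    """Choose the smallest soft power whose connectivity distribution reaches
    the scale-free fit target; fall back to the best-fitting power (with a
    logged warning) when no power reaches it."""
    power_grid = [int(b) for b in power_grid]
    if not power_grid:
        raise ValueError("power_grid must be non-empty")
    if corr is None:
        corr = correlation_matrix(expr)
    rows = []
    for beta in power_grid:
        adj = adjacency(expr, beta, corr=corr)
        k = connectivity(adj)
        fit, slope = scale_free_fit(k)
        rows.append(
            {"power": beta, "fit": fit, "slope": slope,
             "mean_k": float(k.mean()), "max_k": float(k.max())}
        )
    table = pd.DataFrame(rows)
    reaching = table.loc[table["fit"] >= r2_target]
    if len(reaching):
        beta = int(reaching.iloc[0]["power"])
        reached = True
    else:
        beta = int(table.loc[table["fit"].idxmax(), "power"])
        reached = False
        logger.warning(
            "no soft power reaches scale-free fit >= %g; using argmax power %d (fit %.3f)",
            r2_target, beta, table["fit"].max(),
        )
    return SoftThresholdResult(beta=beta, table=table, reached_target=reached)


# ---------------------------------------------------------------------------
# topological overlap

def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of a weighted adjacency matrix.

    ``t_ij = (sum_{u not in {i,j}} a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij)`` with unit diagonal, where connectivity k
    excludes the diagonal.  Shared-neighbor products are taken over all
    third nodes, so two genes are similar when they are directly connected
    or wired to the same neighborhood.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    k = connectivity(adj)
    prod = adj @ adj
    # (A @ A)_ij includes the u = i and u = j terms a_ii*a_ij + a_ij*a_jj;
    # with unit diagonal these contribute 2 * a_ij and are removed.
    shared = prod - 2.0 * adj
    numer = shared + adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


def linkage_from_tom(tom: np.ndarray) -> np.ndarray:
    """Average-linkage dendrogram of the TOM dissimilarity 1 - T."""
    dissim = np.clip(1.0 - tom, 0.0, None)
    np.fill_diagonal(dissim, 0.0)
    condensed = ssd.squareform(dissim, checks=False)
    return sch.linkage(condensed, method="average")


def dendrogram_table(linkage: np.ndarray) -> pd.DataFrame:
    """Merge list (left, right, height, size) view of a linkage matrix."""
    return pd.DataFrame(
        {
            "left": linkage[:, 0].astype(int),
            "right": linkage[:, 1].astype(int),
            "height": linkage[:, 2],
            "size": linkage[:, 3].astype(int),
        }
    )


# ---------------------------------------------------------------------------
# module detection

def cut_modules(
    linkage: np.ndarray,
    gene_ids: Sequence[str],
    min_module_size: int = 30,
    cut_quantile: float = 0.97,
) -> pd.Series:
    """Cut the dendrogram into modules by a recursive per-branch height cut.

    Starting from the root, each branch is cut at ``cut_quantile`` times
    its own root merge height.  When the cut exposes two or more
    sub-branches with at least ``min_module_size`` leaves the branch is
    split and the rule recurses into each large sub-branch (leaves falling
    into small fragments at a split level stay unassigned); otherwise the
    whole branch becomes one module.  Because every branch is judged
    against its own height scale, tight modules hanging at very different
    dissimilarity levels are all resolved — the behavior a single global
    static cut cannot deliver.

    Detected modules are labeled from the fixed color list in decreasing
    size order (ties broken by first gene position).  All other genes are
    labeled "unassigned".
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if not 0 < cut_quantile <= 1:
        raise ValueError("cut_quantile must be in (0, 1]")
    gene_ids = list(gene_ids)
    n_leaf = linkage.shape[0] + 1
    if len(gene_ids) != n_leaf:
        raise ValueError("gene_ids length does not match the dendrogram")
    left = linkage[:, 0].astype(int)
    right = linkage[:, 1].astype(int)
    height = linkage[:, 2]
    size = np.ones(2 * n_leaf - 1, dtype=int)
    for i in range(n_leaf - 1):
        size[n_leaf + i] = size[left[i]] + size[right[i]]

    def node_height(node: int) -> float:
        return float(height[node - n_leaf]) if node >= n_leaf else 0.0

    def node_leaves(node: int) -> "list[int]":
        acc, stack = [], [node]
        while stack:
            x = stack.pop()
            if x < n_leaf:
                acc.append(x)
            else:
                stack.extend((left[x - n_leaf], right[x - n_leaf]))
        return acc

    clusters: list[list[int]] = []
    stack = [2 * n_leaf - 2]
    while stack:
        node = stack.pop()
        if size[node] < min_module_size:
            continue
        if node < n_leaf or node_height(node) == 0:
            clusters.append(node_leaves(node))
            continue
        cut = cut_quantile * node_height(node)
        comps, inner = [], [node]
        while inner:
            x = inner.pop()
            if x < n_leaf or node_height(x) <= cut:
                comps.append(x)
            else:
                inner.extend((left[x - n_leaf], right[x - n_leaf]))
        big = [c for c in comps if size[c] >= min_module_size]
        if len(big) <= 1:
            clusters.append(node_leaves(node))
        else:
            stack.extend(big)

    order = sorted((-len(c), min(c), c) for c in clusters)
    labels = np.full(n_leaf, UNASSIGNED, dtype=object)
    for rank, (_, _, cluster) in enumerate(order):
        labels[cluster] = module_label(rank)
    result = pd.Series(labels, index=gene_ids, name="module")
    if not order:
        logger.warning("branch cut found no branch of size >= %d; all genes unassigned",
                       min_module_size)
    logger.info("branch cut (quantile %.2f): %d modules, %d of %d genes assigned",
                cut_quantile, len(order), int((labels != UNASSIGNED).sum()), n_leaf)
    return result


class EigengeneResult(NamedTuple):
    eigengenes: pd.DataFrame        # modules x samples, unit sample variance
    variance_explained: pd.Series   # per module


def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance gene in module; eigengene undefined")
    return (values - mean) / sd


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> EigengeneResult:
    """First-principal-component eigengene of each named module.

    Member genes are standardized across samples; the eigengene is the
    first right singular vector's sample scores scaled to unit sample
    variance and sign-oriented so that it correlates non-negatively with
    the module's mean standardized expression.  ``variance_explained`` is
    the first squared singular value over the total.
    """
    modules = [m for m in pd.unique(labels) if m != UNASSIGNED]
    if not modules:
        raise ValueError("no named modules; eigengenes undefined")
    rows, ve = [], []
    for module in modules:
        genes = labels.index[labels == module]
        if len(genes) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 genes")
        std = _standardize(expr.loc[genes].to_numpy(dtype=float))
        u, s, vt = np.linalg.svd(std, full_matrices=False)
        scores = vt[0]
        scores = scores / scores.std(ddof=1)
        mean_profile = std.mean(axis=0)
        orient = np.corrcoef(scores, mean_profile)[0, 1] if mean_profile.std() > 0 else 1.0
        if orient < 0:
            scores = -scores
        rows.append(scores)
        ve.append(float(s[0] ** 2 / np.sum(s**2)))
    eigengenes = pd.DataFrame(rows, index=modules, columns=expr.columns)
    return EigengeneResult(eigengenes, pd.Series(ve, index=modules, name="variance_explained"))


def merge_close_modules(
    labels: pd.Series,
    expr: pd.DataFrame,
    merge_dissimilarity: float = 0.05,
) -> pd.Series:
    """Iteratively merge the module pair with the smallest eigengene
    dissimilarity ``1 - cor(E_a, E_b)`` while it is below the threshold.

    The merged module keeps the label of the larger member (ties: earlier
    label in sorted order); eigengenes are recomputed after every merge.
    """
    labels = labels.copy()
    if merge_dissimilarity <= 0:
        return labels
    while True:
        modules = sorted(m for m in pd.unique(labels) if m != UNASSIGNED)
        if len(modules) < 2:
            return labels
        eig = module_eigengenes(expr, labels).eigengenes.loc[modules]
        corr = np.corrcoef(eig.to_numpy())
        dissim = 1.0 - corr
        np.fill_diagonal(dissim, np.inf)
        i, j = np.unravel_index(int(np.argmin(dissim)), dissim.shape)
        if dissim[i, j] >= merge_dissimilarity:
            return labels
        a, b = modules[i], modules[j]
        size_a, size_b = (labels == a).sum(), (labels == b).sum()
        if size_a == size_b:
            keep, drop = sorted((a, b))
        elif size_a > size_b:
            keep, drop = a, b
        else:
            keep, drop = b, a
        logger.info("merging module %s into %s (eigengene dissimilarity %.4f)",
                    drop, keep, dissim[i, j])
        labels[labels == drop] = keep


def _module_eigengene_vector(expr: pd.DataFrame, genes) -> np.ndarray:
    std = _standardize(expr.loc[genes].to_numpy(dtype=float))
    _, _, vt = np.linalg.svd(std, full_matrices=False)
    scores = vt[0]
    mean_profile = std.mean(axis=0)
    if mean_profile.std() > 0 and np.corrcoef(scores, mean_profile)[0, 1] < 0:
        scores = -scores
    return scores


def split_modules(
    labels: pd.Series,
    expr: pd.DataFrame,
    min_module_size: int = 30,
    split_dissimilarity: float = 0.1,
    membership_preference: float = 0.1,
) -> pd.Series:
    """Split modules that carry two distinguishable co-expression factors.

    Each module is bisected by the sign of the second eigenvector of its
    gene-gene |correlation| matrix (the spectral direction that separates a
    two-block structure).  A split is accepted only when (a) both halves
    have at least ``min_module_size`` genes, (b) the halves' eigengenes
    disagree by at least ``split_dissimilarity`` (1 - |cor|), and (c) the
    median gene prefers its own half's eigengene over the other's by at
    least ``membership_preference`` in |correlation| units — i.e. the
    member genes can genuinely tell the halves apart.  Accepted halves are
    re-examined, so three-factor merges resolve too.  Random halves of a
    single-factor module fail (b) and (c) by a wide margin, which makes
    this operation the dual of the eigengene merge.
    """
    labels = labels.copy()
    suffix = 0
    stack = [m for m in pd.unique(labels) if m != UNASSIGNED]
    n = expr.shape[1]
    while stack:
        module = stack.pop()
        genes = list(labels.index[labels == module])
        if len(genes) < 2 * min_module_size:
            continue
        values = expr.loc[genes].to_numpy(dtype=float)
        corr = np.abs(np.corrcoef(values))
        _, vectors = np.linalg.eigh(corr)
        second = vectors[:, -2]
        if second[np.argmax(np.abs(second))] < 0:
            second = -second
        side = second > 0
        g1 = [g for g, s in zip(genes, side) if s]
        g2 = [g for g, s in zip(genes, side) if not s]
        if len(g1) < min_module_size or len(g2) < min_module_size:
            continue
        e1 = _module_eigengene_vector(expr, g1)
        e2 = _module_eigengene_vector(expr, g2)
        dissim = 1.0 - abs(np.corrcoef(e1, e2)[0, 1])
        if dissim < split_dissimilarity:
            continue
        std = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
        k1 = np.abs(std @ ((e1 - e1.mean()) / e1.std()) / n)
        k2 = np.abs(std @ ((e2 - e2.mean()) / e2.std()) / n)
        own = np.where(side, k1, k2)
        other = np.where(side, k2, k1)
        if np.median(own - other) < membership_preference:
            continue
        new_label = f"{module}.{suffix}"
        suffix += 1
        labels[labels.index.isin(g2)] = new_label
        logger.info("split module %s (%d genes) -> %s/%s (eigengene dissim %.3f)",
                    module, len(genes), module, new_label, dissim)
        stack.extend([module, new_label])
    return labels


def assign_by_kme(
    labels: pd.Series,
    expr: pd.DataFrame,
    kme_threshold: float = 0.7,
    min_module_size: int = 30,
) -> pd.Series:
    """Reassign every gene to the module whose eigengene it correlates with
    most (|kME|), or to "unassigned" when no module reaches
    ``kme_threshold``.  Modules shrinking below ``min_module_size`` are
    dissolved.  This rescues branch-cut stragglers and corrects genes
    stranded on the wrong branch."""
    named = [m for m in pd.unique(labels) if m != UNASSIGNED]
    if not named:
        return labels.copy()
    eig = module_eigengenes(expr, labels).eigengenes
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance gene; kME undefined")
    gz = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    e = eig.to_numpy()
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, keepdims=True)
    kme = np.abs(gz @ ez.T / values.shape[1])          # genes x modules
    best = kme.argmax(axis=1)
    best_value = kme.max(axis=1)
    module_names = np.asarray(eig.index, dtype=object)
    new = np.where(best_value >= kme_threshold, module_names[best], UNASSIGNED)
    result = pd.Series(new, index=expr.index, name="module")
    sizes = result.value_counts()
    for module, count in sizes.items():
        if module != UNASSIGNED and count < min_module_size:
            logger.info("dissolving module %s (%d genes after kME reassignment)",
                        module, count)
            result[result == module] = UNASSIGNED
    return result


def relabel_by_size(labels: pd.Series) -> pd.Series:
    """Map module names onto the fixed color list in decreasing size order
    (ties broken by first gene position); "unassigned" is preserved."""
    named = [m for m in pd.unique(labels) if m != UNASSIGNED]
    arr = labels.to_numpy()
    order = sorted((-(arr == m).sum(), int(np.argmax(arr == m)), m) for m in named)
    mapping = {m: module_label(rank) for rank, (_, _, m) in enumerate(order)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping)


def intramodular_connectivity(adj: np.ndarray, labels: pd.Series) -> pd.Series:
    """Per-gene connectivity restricted to the gene's own module (kWithin)."""
    k_within = np.zeros(len(labels))
    arr = labels.to_numpy()
    for module in pd.unique(arr):
        if module == UNASSIGNED:
            continue
        mask = arr == module
        sub = adj[np.ix_(mask, mask)]
        k_within[mask] = sub.sum(axis=0) - np.diag(sub)
    return pd.Series(k_within, index=labels.index, name="kWithin")


# ---------------------------------------------------------------------------
# sklearn estimator facade

class CoexpressionModuleDetector(ClusterMixin, BaseEstimator):
    """Detect co-expressed gene modules from a samples x genes matrix.

    The fitted chain: soft power (scale-free pick bounded below by the
    sample-size floor), unsigned adjacency, topological overlap,
    average-linkage dendrogram, recursive branch cut, then an iterated
    refinement of spectral splitting, eigengene merging and kME
    reassignment.  ``fit`` expects ``X`` in the scikit-learn orientation
    (rows = samples, columns = genes, on the scale correlations should be
    computed on); the fitted attributes describe the genes.

    Attributes
    ----------
    labels_ : ndarray of str, per gene — module color or "unassigned".
    soft_power_ : int, the selected soft-thresholding power.
    scale_free_table_ : DataFrame, per-power scale-free fit diagnostics.
    eigengenes_ : DataFrame (modules x samples).
    variance_explained_ : Series per module.
    dendrogram_ : linkage matrix of the TOM dissimilarity clustering.
    k_within_ : Series, per-gene intramodular connectivity.
    """

    def __init__(
        self,
        power_grid: Sequence[int] = tuple(range(1, 21)),
        scale_free_r2_target: float = 0.8,
        soft_power: "Optional[int]" = None,
        apply_power_floor: bool = True,
        min_module_size: int = 30,
        merge_dissimilarity: float = 0.05,
        cut_quantile: float = 0.97,
        split_dissimilarity: float = 0.1,
        kme_threshold: float = 0.7,
        refine_iterations: int = 3,
    ):
        self.power_grid = power_grid
        self.scale_free_r2_target = scale_free_r2_target
        self.soft_power = soft_power
        self.apply_power_floor = apply_power_floor
        self.min_module_size = min_module_size
        self.merge_dissimilarity = merge_dissimilarity
        self.cut_quantile = cut_quantile
        self.split_dissimilarity = split_dissimilarity
        self.kme_threshold = kme_threshold
        self.refine_iterations = refine_iterations

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            gene_ids = [str(c) for c in X.columns]
            sample_ids = [str(i) for i in X.index]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be 2-D (samples x genes)")
            gene_ids = [f"g{j}" for j in range(values.shape[1])]
            sample_ids = [f"s{i}" for i in range(values.shape[0])]
        expr = pd.DataFrame(values.T, index=gene_ids, columns=sample_ids)

        corr = correlation_matrix(expr)
        if self.soft_power is not None:
            beta = int(self.soft_power)
            self.scale_free_table_ = None
        else:
            result = pick_soft_threshold(
                expr, self.power_grid, self.scale_free_r2_target, corr=corr
            )
            beta = result.beta
            self.scale_free_table_ = result.table
            if self.apply_power_floor:
                floor = sample_size_power_floor(len(sample_ids))
                if beta < floor:
                    logger.info(
                        "raising soft power %d to the sample-size floor %d (n=%d)",
                        beta, floor, len(sample_ids),
                    )
                    beta = floor
        adj = adjacency(expr, beta, corr=corr)
        tom = tom_similarity(adj)
        linkage = linkage_from_tom(tom)
        labels = cut_modules(linkage, gene_ids, self.min_module_size, self.cut_quantile)
        for _ in range(self.refine_iterations):
            if not (labels != UNASSIGNED).any():
                break
            labels = split_modules(
                labels, expr, self.min_module_size, self.split_dissimilarity
            )
            labels = merge_close_modules(labels, expr, self.merge_dissimilarity)
            labels = assign_by_kme(
                labels, expr, self.kme_threshold, self.min_module_size
            )
        if (labels != UNASSIGNED).any():
            labels = relabel_by_size(labels)
            eig = module_eigengenes(expr, labels)
            self.eigengenes_ = eig.eigengenes
            self.variance_explained_ = eig.variance_explained
        else:
            self.eigengenes_ = pd.DataFrame(columns=sample_ids)
            self.variance_explained_ = pd.Series(dtype=float)
        self.soft_power_ = beta
        self.dendrogram_ = linkage
        self.k_within_ = intramodular_connectivity(adj, labels)
        self.module_assignments_ = labels
        self.labels_ = labels.to_numpy()
        self.n_features_in_ = len(gene_ids)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
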