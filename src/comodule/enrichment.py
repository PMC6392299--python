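"""Hypergeometric over-representation of module genes in gene sets.

For each (module, gene set) pair the overlap is scored with the upper-tail
hypergeometric probability P(X >= k) of drawing k or more set members when
n module genes are sampled from a universe of N analyzed genes containing
K set members.  Benjamini-Hochberg adjustment is applied across all gene
sets within each module, matching a per-module top-pathway report.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .network import UNASSIGNED

logger = logging.getLogger(__name__)


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts set members among ``n`` genes drawn without replacement from a
    universe of ``N`` genes of which ``K`` are set members.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= min(n, K) <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: "Sequence[float] | np.ndarray") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        bad = p[(p <= 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValueError(f"p-values must lie in (0, 1]; got {bad}")
    return multipletests(p, method="fdr_bh")[1]


def enrich_modules(
    labels: pd.Series,
    gene_sets: GeneSetCollection,
    universe: "Iterable[str] | None" = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every named module in every gene set.

    ``universe`` defaults to all labeled genes (the filtered genes that
    entered the network).  Gene sets are intersected with the universe
    before testing; sets with empty intersection are skipped with a log
    entry.  BH adjustment runs within each module across sets; per module
    the top set by adjusted p is flagged (ties broken by larger overlap,
    then set name).

    Returns a long table with columns module, gene_set, universe_size,
    set_size, module_size, overlap, p, p_adjusted, significant, is_top.
    """
    universe_set = set(labels.index if universe is None else universe)
    N = len(universe_set)
    if N == 0:
        raise ValueError("empty gene universe")
    trimmed: dict[str, set] = {}
    for name, members in gene_sets.items():
        inter = set(members) & universe_set
        if not inter:
            logger.info("gene set %r has no overlap with the universe; skipped", name)
            continue
        trimmed[name] = inter
    modules = [m for m in pd.unique(labels) if m != UNASSIGNED]
    frames = []
    for module in modules:
        module_genes = set(labels.index[labels == module]) & universe_set
        n = len(module_genes)
        rows = []
        for name in sorted(trimmed):
            members = trimmed[name]
            K = len(members)
            k = len(module_genes & members)
            rows.append(
                {
                    "module": module,
                    "gene_set": name,
                    "universe_size": N,
                    "set_size": K,
                    "module_size": n,
                    "overlap": k,
                    "p": hypergeom_p(k, n, K, N),
                }
            )
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["p_adjusted"] = bh_adjust(df["p"])
        df["significant"] = df["p_adjusted"] < fdr_threshold
        # top set: smallest adjusted p, ties by larger overlap then name
        ranking = df.sort_values(
            ["p_adjusted", "overlap", "gene_set"], ascending=[True, False, True]
        )
        df["is_top"] = df.index == ranking.index[0]
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["module", "gene_set", "universe_size", "set_size",
                     "module_size", "overlap", "p", "p_adjusted",
                     "significant", "is_top"]
        )
    return pd.concat(frames, ignore_index=True)
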