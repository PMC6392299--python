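"""Combination-effect trait encoding, eigengene-trait correlation, and
selection of potentiating modules.

Each of the nine traits assigns every sample a numeric value from its
treatment arm via the shared archetype table, then is mean-centered.
Module eigengenes are correlated against the traits with Pearson r; the
two-sided p-value comes from ``t = r * sqrt((n - 2) / (1 - r^2))`` on
n - 2 degrees of freedom.  A module is "potentiating" when its most
correlated trait (by |r|) is one of the four combination-benefit
archetypes and the correlation passes strict |r| and p thresholds.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .archetypes import ARCHETYPE_PATTERNS, ARMS, POTENTIATING_TRAITS, TRAIT_NAMES


def build_traits(metadata: pd.Series) -> pd.DataFrame:
    """Build the 9 x samples trait matrix from sample -> arm metadata.

    Trait values are assigned at the arm level from the archetype table and
    centered to mean 0 per trait.  All four arms must be present.
    """
    missing = [a for a in ARMS if a not in set(metadata)]
    if missing:
        raise ValueError(f"metadata is missing arm(s): {missing}")
    arm_index = {arm: i for i, arm in enumerate(ARMS)}
    cols = np.array([arm_index[a] for a in metadata], dtype=int)
    values = ARCHETYPE_PATTERNS[:, cols]
    values = values - values.mean(axis=1, keepdims=True)
    return pd.DataFrame(values, index=list(TRAIT_NAMES), columns=metadata.index)


def pearson_p(r: "float | np.ndarray", n: int) -> "float | np.ndarray":
    """Two-sided p-value of a Pearson correlation from the t transform."""
    if n < 4:
        raise ValueError("need at least 4 samples")
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    return 2.0 * stats.t.sf(t, df=n - 2)


def correlate(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Correlate every module eigengene with every trait.

    Returns a long-format table with one row per (module, trait): Pearson
    ``r``, two-sided ``p``, and ``is_top`` marking each module's most
    correlated trait by |r| (ties broken by trait order).
    """
    if list(eigengenes.columns) != list(traits.columns):
        raise ValueError("eigengene and trait sample orders differ")
    n = eigengenes.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for trait correlation")
    e = eigengenes.to_numpy(dtype=float)
    t = traits.to_numpy(dtype=float)
    if (e.std(axis=1) == 0).any():
        module = eigengenes.index[int(np.argmax(e.std(axis=1) == 0))]
        raise ValueError(f"eigengene of module {module!r} is constant; r undefined")
    if (t.std(axis=1) == 0).any():
        trait = traits.index[int(np.argmax(t.std(axis=1) == 0))]
        raise ValueError(f"trait {trait!r} is constant; r undefined")
    ez = (e - e.mean(axis=1, keepdims=True)) / e.std(axis=1, keepdims=True)
    tz = (t - t.mean(axis=1, keepdims=True)) / t.std(axis=1, keepdims=True)
    r = np.clip(ez @ tz.T / n, -1.0, 1.0)   # modules x traits
    p = pearson_p(r, n)
    rows = []
    for i, module in enumerate(eigengenes.index):
        top_j = int(np.argmax(np.abs(r[i])))  # argmax takes first on ties
        for j, trait in enumerate(traits.index):
            rows.append(
                {
                    "module": module,
                    "trait": trait,
                    "r": float(r[i, j]),
                    "p": float(p[i, j]),
                    "is_top": j == top_j,
                }
            )
    return pd.DataFrame(rows)


class PotentiatingSelection(NamedTuple):
    table: pd.DataFrame         # selected modules with top trait, r, p
    r_threshold: float
    p_threshold: float


def select_potentiating(
    correlations: pd.DataFrame,
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
) -> PotentiatingSelection:
    """Select modules whose top trait is a combination-benefit archetype
    with |r| strictly above ``r_threshold`` and p strictly below
    ``p_threshold``.  An empty selection is legal."""
    top = correlations.loc[correlations["is_top"]]
    mask = (
        top["trait"].isin(POTENTIATING_TRAITS)
        & (top["r"].abs() > r_threshold)
        & (top["p"] < p_threshold)
    )
    table = (
        top.loc[mask, ["module", "trait", "r", "p"]]
        .rename(columns={"trait": "top_trait"})
        .reset_index(drop=True)
    )
    return PotentiatingSelection(table=table, r_threshold=r_threshold, p_threshold=p_threshold)
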