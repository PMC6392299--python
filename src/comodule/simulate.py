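"""Synthetic data generators with planted ground truth.

Three generators emulate the study's data types so every downstream stage
is testable without any download:

* :func:`generate_bulk` — a 4-arm bulk expression matrix (TPM-like,
  log-normal) containing co-expressed gene modules whose shared latent
  signal follows one of the nine combination-effect archetypes, plus
  independent background genes and planted gene-set annotations.
* :func:`generate_sc_counts` — droplet-style single-cell UMI counts with
  negative-binomial cluster programs and treatment-dependent cluster
  proportions.
* :func:`generate_growth` — per-mouse tumor axis measurements under
  exponential growth with multiplicative noise and optional dropout tails.

The latent bulk model: for module *m* with archetype pattern *p* the
per-sample signal is ``s = effect_size * p(arm) + N(0, 1)``; a member
gene's log-scale value is ``loading * s + N(0, noise_sd)`` plus a per-gene
baseline, then exponentiated to the TPM scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .archetypes import ARMS, TRAIT_NAMES, pattern_for_samples
from .io import GeneSetCollection, validate_expression


@dataclass
class PlantedModule:
    """Specification of one planted co-expression module."""

    size: int = 60
    archetype: int = 1          # 1..9, indexes TRAIT_NAMES
    effect_size: float = 3.0    # arm shift in latent-signal SD units
    loading_mean: float = 1.0
    loading_sd: float = 0.2
    sign_mix: float = 0.2       # fraction of genes with negative loading

    def validate(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not 1 <= self.archetype <= len(TRAIT_NAMES):
            raise ValueError(f"archetype must be in 1..{len(TRAIT_NAMES)}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.sign_mix <= 1:
            raise ValueError("sign_mix must be in [0, 1]")


def default_planted_modules() -> "list[PlantedModule]":
    """Nine 60-gene modules, one per archetype, at effect size 3."""
    return [PlantedModule(size=60, archetype=a, effect_size=3.0) for a in range(1, 10)]


@dataclass
class SyntheticScenario:
    """Design of one synthetic 4-arm bulk experiment.

    Defaults mirror the study scale: 4 arms x 5 replicates (20 samples),
    nine planted archetype modules of 60 genes at effect size 3, and 1,500
    independent background genes with unit log-scale noise.
    """

    n_background_genes: int = 1500
    planted_modules: "list[PlantedModule]" = field(default_factory=default_planted_modules)
    samples_per_arm: int = 5
    noise_sd: float = 1.0
    baseline_log_mean: float = 2.5   # per-gene log-TPM baseline location
    baseline_log_sd: float = 1.0
    gene_set_decoys: int = 5         # background-only decoy sets for FDR realism
    seed: int = 42

    def validate(self) -> None:
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.samples_per_arm < 2:
            raise ValueError("samples_per_arm must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for m in self.planted_modules:
            m.validate()


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a synthetic dataset."""

    gene_to_module: "dict[str, Optional[str]]"   # None = background
    module_archetype: "dict[str, int]"
    set_to_module: "dict[str, Optional[str]]"    # None = decoy set

    def module_genes(self, module_id: str) -> "set[str]":
        return {g for g, m in self.gene_to_module.items() if m == module_id}


class BulkDataset(NamedTuple):
    expression: pd.DataFrame    # genes x samples, TPM-like
    metadata: pd.Series         # sample id -> arm
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


def _sample_frame(samples_per_arm: int) -> pd.Series:
    ids, arms = [], []
    for arm in ARMS:
        for r in range(1, samples_per_arm + 1):
            ids.append(f"{arm}_{r}")
            arms.append(arm)
    return pd.Series(arms, index=ids, name="arm")


def generate_bulk(scenario: SyntheticScenario) -> BulkDataset:
    """Generate a 4-arm bulk expression dataset with planted modules.

    Deterministic given ``scenario.seed``.  Per planted module one gene set
    is emitted containing half of the module's genes plus an equal number
    of random background decoys; ``gene_set_decoys`` extra sets contain
    background genes only.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    metadata = _sample_frame(scenario.samples_per_arm)
    sample_arms = metadata.to_numpy()
    n_samples = len(metadata)

    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []
    gene_to_module: dict[str, Optional[str]] = {}
    module_archetype: dict[str, int] = {}

    for k, mod in enumerate(scenario.planted_modules, start=1):
        module_id = f"M{k}"
        module_archetype[module_id] = mod.archetype
        pattern = pattern_for_samples(mod.archetype, sample_arms)
        latent = mod.effect_size * pattern + rng.normal(0.0, 1.0, n_samples)
        loadings = np.abs(rng.normal(mod.loading_mean, mod.loading_sd, mod.size))
        signs = np.where(rng.random(mod.size) < mod.sign_mix, -1.0, 1.0)
        loadings *= signs
        noise = rng.normal(0.0, scenario.noise_sd, (mod.size, n_samples))
        blocks.append(np.outer(loadings, latent) + noise)
        for j in range(1, mod.size + 1):
            gid = f"{module_id}_G{j:03d}"
            gene_ids.append(gid)
            gene_to_module[gid] = module_id

    n_bg = scenario.n_background_genes
    if n_bg:
        blocks.append(rng.normal(0.0, scenario.noise_sd, (n_bg, n_samples)))
        for j in range(1, n_bg + 1):
            gid = f"BG_{j:04d}"
            gene_ids.append(gid)
            gene_to_module[gid] = None

    log_signal = np.vstack(blocks) if blocks else np.empty((0, n_samples))
    baselines = rng.normal(scenario.baseline_log_mean, scenario.baseline_log_sd, len(gene_ids))
    tpm = np.exp(log_signal + baselines[:, None])
    expression = pd.DataFrame(tpm, index=gene_ids, columns=metadata.index)
    validate_expression(expression)

    background_ids = [g for g, m in gene_to_module.items() if m is None]
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    set_to_module: dict[str, Optional[str]] = {}
    for module_id, archetype in module_archetype.items():
        mod_genes = sorted(g for g, m in gene_to_module.items() if m == module_id)
        n_half = max(1, len(mod_genes) // 2)
        chosen = list(rng.choice(mod_genes, size=n_half, replace=False))
        if background_ids:
            decoys = list(
                rng.choice(background_ids, size=min(n_half, len(background_ids)), replace=False)
            )
        else:
            decoys = []
        name = f"pathway_{module_id}"
        sets[name] = frozenset(chosen + decoys)
        descriptions[name] = f"planted set for {module_id} ({TRAIT_NAMES[archetype - 1]})"
        set_to_module[name] = module_id
    size_ref = scenario.planted_modules[0].size if scenario.planted_modules else 60
    for d in range(1, scenario.gene_set_decoys + 1):
        if not background_ids:
            break
        name = f"decoy_set_{d}"
        members = rng.choice(background_ids, size=min(size_ref, len(background_ids)), replace=False)
        sets[name] = frozenset(members)
        descriptions[name] = "background decoy set"
        set_to_module[name] = None

    gene_sets = GeneSetCollection(sets=sets, descriptions=descriptions)
    truth = SyntheticTruth(
        gene_to_module=gene_to_module,
        module_archetype=module_archetype,
        set_to_module=set_to_module,
    )
    return BulkDataset(expression, metadata, gene_sets, truth)


class SingleCellDataset(NamedTuple):
    counts: pd.DataFrame        # genes x cells, integer UMI
    cell_groups: pd.Series      # cell id -> group label
    cluster_labels: pd.Series   # cell id -> true cluster (int, 0-based)
    marker_genes: "dict[int, list[str]]"  # cluster -> marker gene ids


def generate_sc_counts(
    n_cells_per_group: "dict[str, int]",
    cluster_proportions_per_group: "dict[str, Sequence[float]]",
    n_genes: int = 300,
    n_markers_per_cluster: int = 25,
    marker_fold: float = 8.0,
    mean_total_umi: float = 2000.0,
    log_total_sd: float = 0.9,
    dispersion: float = 2.0,
    seed: int = 0,
) -> SingleCellDataset:
    """Generate droplet-style UMI counts with planted cluster structure.

    Cells draw a log-normal total-UMI target (some falling outside the
    400-10,000 QC window by design) and gene counts from a gamma-Poisson
    (negative-binomial) program; each cluster elevates its own marker block
    ``marker_fold``-fold.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    groups = list(n_cells_per_group)
    n_clusters = None
    for g in groups:
        props = np.asarray(cluster_proportions_per_group[g], dtype=float)
        if n_clusters is None:
            n_clusters = len(props)
        elif len(props) != n_clusters:
            raise ValueError("all groups must define proportions for the same clusters")
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError(f"cluster proportions for group {g!r} must be >= 0 and sum to 1")
    assert n_clusters is not None
    if n_markers_per_cluster * n_clusters > n_genes:
        raise ValueError("marker blocks exceed the number of genes")

    gene_ids = [f"g{j:04d}" for j in range(1, n_genes + 1)]
    base_rel = rng.lognormal(0.0, 1.0, n_genes)
    marker_genes: dict[int, list[str]] = {}
    profiles = np.tile(base_rel, (n_clusters, 1))
    for c in range(n_clusters):
        lo, hi = c * n_markers_per_cluster, (c + 1) * n_markers_per_cluster
        profiles[c, lo:hi] *= marker_fold
        marker_genes[c] = gene_ids[lo:hi]
    profiles /= profiles.sum(axis=1, keepdims=True)

    cell_ids, cell_groups, cell_clusters, columns = [], [], [], []
    for g in groups:
        n_cells = n_cells_per_group[g]
        props = np.asarray(cluster_proportions_per_group[g], dtype=float)
        clusters = rng.choice(n_clusters, size=n_cells, p=props)
        totals = rng.lognormal(np.log(mean_total_umi), log_total_sd, n_cells)
        for i in range(n_cells):
            mu = totals[i] * profiles[clusters[i]]
            lam = rng.gamma(dispersion, mu / dispersion)
            columns.append(rng.poisson(lam))
            cell_ids.append(f"{g}_cell{i + 1:04d}")
            cell_groups.append(g)
            cell_clusters.append(int(clusters[i]))

    counts = pd.DataFrame(
        np.column_stack(columns).astype(np.int64), index=gene_ids, columns=cell_ids
    )
    return SingleCellDataset(
        counts=counts,
        cell_groups=pd.Series(cell_groups, index=cell_ids, name="group"),
        cluster_labels=pd.Series(cell_clusters, index=cell_ids, name="cluster"),
        marker_genes=marker_genes,
    )


def generate_growth(
    arms: "dict[str, float]",
    n_mice: int = 6,
    days: Sequence[int] = (1, 4, 8, 11, 15, 18, 22),
    initial_volume: float = 100.0,
    noise_sd: float = 0.1,
    dropout_probability: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-mouse tumor axis series under exponential growth.

    ``arms`` maps group name to per-day exponential growth rate.  Volumes
    follow ``V0 * exp(rate * (day - day0))`` with multiplicative log-normal
    noise; with probability ``dropout_probability`` a mouse loses all
    measurements after a uniformly chosen non-initial day (a missing tail,
    to exercise last-observation-carried-forward imputation).  Axes are
    derived from volume assuming a fixed short/long ratio of 0.8 so that
    ``V = L * S^2 / 2`` holds exactly.

    Returns a tidy DataFrame with columns mouse_id, group, day, long_axis,
    short_axis.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    rng = np.random.default_rng(seed)
    days = list(days)
    ratio = 0.8
    rows = []
    for group, rate in arms.items():
        for m in range(1, n_mice + 1):
            mouse = f"{group}_m{m}"
            v0 = initial_volume * rng.lognormal(0.0, noise_sd) if noise_sd else initial_volume
            cutoff = None
            if dropout_probability and rng.random() < dropout_probability:
                cutoff = days[int(rng.integers(1, len(days)))]
            for day in days:
                if cutoff is not None and day >= cutoff:
                    continue
                noise = rng.lognormal(0.0, noise_sd) if noise_sd else 1.0
                volume = v0 * np.exp(rate * (day - days[0])) * noise
                long_axis = (2.0 * volume / ratio**2) ** (1.0 / 3.0)
                rows.append(
                    {
                        "mouse_id": mouse,
                        "group": group,
                        "day": day,
                        "long_axis": long_axis,
                        "short_axis": ratio * long_axis,
                    }
                )
    return pd.DataFrame(rows, columns=["mouse_id", "group", "day", "long_axis", "short_axis"])
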