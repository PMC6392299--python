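# Methods

## Co-expression network and module detection

The analysis operates on a genes × samples matrix of TPM-like values.
Genes are kept when their **mean** expression across all samples strictly
exceeds `tpm_threshold` (default 1.0).  Mean-based filtering was chosen
over per-sample or any-sample rules because it is deterministic under
resampling of arms and insensitive to a single outlier library; the rule
is configurable.  Unless `log_transform` is disabled, all correlation and
eigengene computations run on log₂(x+1): Pearson correlation on raw
log-normal expression is dominated by the right tail, and the log scale is
the standard working scale for correlation networks.  Zero-variance genes
surviving the filter are dropped with a log entry before correlation.

**Adjacency.** `a_ij = |cor(x_i, x_j)|^β` (unsigned network, unit
diagonal).  The unsigned form pairs naturally with the |r|-based trait
selection downstream: a module and its mirrored (down-regulated) genes are
one program.

**Soft power.** For each power in `soft_power_grid` (default 1–20) the
connectivity distribution `k_i = Σ_{j≠i} a_ij` is scored for approximate
scale-free topology: k is binned into 10 equal-width bins, log₁₀(occupancy
fraction) is regressed on log₁₀(mean k), and the fit index is R² when the
slope is negative, else 0.  The selected power is the smallest one
reaching `scale_free_r2_target` (default 0.8) — but never below a
**sample-size floor** (unsigned: 9 below 20 samples, 8 for 20–30, 7 for
30–40, 6 above 40; `apply_power_floor` disables it).  The floor matters
because with few samples the |r| noise floor is ≈ 1/√n, and low powers
leave substantial random adjacency between unrelated genes; on data with a
few large modules the scale-free index can look excellent at powers as low
as 2 (the modular degree tail mimics a power law) while the resulting
network has no usable topological-overlap contrast.  These floors follow
the widely used guidance of the reference WGCNA implementation.

**Topological overlap.**
`t_ij = (Σ_{u∉{i,j}} a_iu·a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`,
`t_ii = 1`, computed by matrix products and verified in the test suite
against a literal triple-loop oracle to 10⁻¹².  Genes are clustered by
average linkage on the dissimilarity 1 − TOM.

**Branch cutting.**  A single global height cut cannot resolve modules
whose mutual attachment heights differ — with nine correlated archetypes
two modules can attach to each other *below* the height at which a third
module's internal structure completes.  The detector therefore cuts
recursively: each branch is cut at `cut_quantile` (default 0.97) of its
own root merge height; if at least two sub-branches of `min_module_size`
(default 30) or more emerge, the rule recurses into them (leaves falling
into small fragments at that level stay unassigned for now); otherwise the
branch becomes one module.  Judging every branch on its own height scale
is the essential property of dynamic branch-cutting algorithms, here in a
deterministic, fully specified form.

**Refinement.**  Three passes are iterated (3 iterations, deterministic):

1. *Split* — each module is bisected by the sign of the second eigenvector
   of its gene–gene |correlation| matrix, the spectral direction that
   separates a two-block structure and is insensitive to the outlier
   chaining that defeats linkage-based bisection.  The split is accepted
   only when both halves have ≥ `min_module_size` genes, the halves'
   eigengenes disagree by ≥ `split_dissimilarity` = 0.1 (1 − |cor|), and
   the median gene prefers its own half's eigengene by ≥ 0.1 in |r| units.
   During method development on the synthetic generator, random halves of
   a single-factor module measured below 0.1 on both statistics while
   genuine two-factor modules measured above 0.11 (typically 0.2–0.5), so
   0.1 sits in the gap; the dual requirement keeps the false-split rate
   low because both statistics must fail simultaneously.
2. *Merge* — the module pair with the smallest eigengene dissimilarity
   1 − cor(E_a, E_b) is merged while below `merge_dissimilarity`
   (default 0.05, the published "dissimilarity correlation threshold"),
   with eigengenes recomputed after each merge and ties broken by label
   order.  Split and merge are deliberately dual: a split must clear 0.1
   so an accepted split can never immediately re-merge at 0.05.
3. *kME reassignment* — every gene moves to the module whose eigengene it
   correlates with most in absolute value, or to "unassigned" below
   `kme_threshold` = 0.7; modules shrinking under the minimum size
   dissolve.  At 20 samples |r| = 0.7 corresponds to p ≈ 6·10⁻⁴, so
   background genes essentially never attach, while genuine members with
   modest loadings are recovered.  This mirrors the module-membership
   (kME) cleanup step of standard co-expression practice.

Modules are finally relabeled onto a fixed, ordered color list by
decreasing size (ties by first gene position), so labeling is
deterministic; color names carry no meaning beyond identity.

**Eigengenes.** Per module, member genes are standardized across samples
(ddof = 1); the eigengene is the first right singular vector's sample
scores scaled to unit sample variance, sign-oriented to correlate
non-negatively with the module's mean standardized expression; variance
explained is s₁²/Σs².

## Traits, selection, enrichment

Trait vectors are assigned per sample from the arm-level archetype table
(README) and centered; centering suffices because Pearson r is
scale-invariant.  The archetype table is the single source of truth shared
with the synthetic generator, so recovery tests cannot drift.  Correlation
p-values are two-sided from the t transform and deliberately not
multiplicity-adjusted at this stage (selection uses raw p < 0.01; FDR
control appears only in enrichment, matching the published procedure).
Selection thresholds are strict inequalities; the figure-legend variant
r > 0.65 of the published |r| > 0.6 rule is available via
`trait_r_threshold`.

Enrichment uses the upper-tail hypergeometric probability P(X ≥ k)
(scipy's stable implementation, verified exhaustively against exact
rational enumeration for N ≤ 30), with the **universe defined as the
filtered genes that entered the network** — the exchangeability population
for module membership — rather than the whole genome.  BH adjustment runs
within each module across gene sets because the report of interest is the
top pathway per module with its own FDR-adjusted p; a global scope is a
one-line change.  Top-set ties break by larger overlap, then name.

## Synthetic data

`generate_bulk` emulates the 4-arm design (default 5 replicates/arm, 20
samples).  For module *m* with archetype pattern *p*: per-sample latent
signal `s = effect_size·p(arm) + N(0,1)`; member gene log-values are
`loading·s + N(0, noise_sd)` with loadings |N(1, 0.2)| and a `sign_mix` =
0.2 fraction negated (so eigengene sign-orientation is exercised);
background genes are pure noise.  A per-gene baseline N(2.5, 1) is added
on the log scale before exponentiation, giving log-normal TPM-like values
with a realistic dynamic range in which background genes mostly pass the
TPM > 1 filter and negative-loading module genes are not systematically
filtered away.  Per planted module one gene set contains a random half of
the module plus an equal number of background decoys; five background-only
decoy sets are added so FDR adjustment has genuine nulls.  Defaults (nine
60-gene modules, archetypes 1–9, effect size 3, 1,500 background genes,
noise SD 1, seed 42) define the package's reference study.

What the generator does **not** emulate: count noise (values are exact
log-normals, not sequencing counts), library-size variation,
batch/covariate structure, and correlated background (real transcriptomes
have pervasive weak co-expression).  Passing recovery tests therefore
demonstrates correctness of the machinery on well-posed module structure,
not performance on real tissue RNA-Seq.

`generate_sc_counts` draws per-cell totals log-normal(log 2000, 0.9) — so
a few percent of cells fall outside the 400–10,000 QC window by design —
and gene counts gamma-Poisson (negative binomial, dispersion 2) from
cluster-specific programs with an 8-fold marker elevation.
`generate_growth` produces exponential tumor growth with multiplicative
log-normal noise, axes derived from volume at a fixed 0.8 short/long
ratio, and optional missing tails to exercise LOCF.

## Single-cell and in vivo conventions

QC bounds 400 and 10,000 total UMIs are treated as inclusive (the source
phrasing "between" does not specify).  Clustering runs by default on the
2-D embedding (k-means, fixed seed, default k = 3) to mirror the visual
cluster definition of such analyses; `cluster_on="panel"` clusters in
panel-expression space instead.  The embedding itself is delegated to
scikit-learn's t-SNE (PCA initialization, seeded).  The immune gene panel
is user-supplied; synthetic fixtures carry their own.

Tumor volume is L·S²/2 with axes auto-swapped (and logged) if reversed.
ΔT/C is computed on group means by default (a per-mouse variant is a
straightforward extension of the volume tables).  Dunnett-style multiple
comparisons are out of scope; the implemented two-group test is the
pooled-variance unpaired t.

## Numerical and testing choices

All pipeline stages are RNG-free, so full-run determinism is exact
(byte-identical outputs), verified by test.  Oracles used in the suite:
triple-loop TOM, exact-rational hypergeometric enumeration, SVD
eigengene check, closed-form archetype correlations (e.g. the most
confusable pair, with-X vs X-dominant-synergy, at r = 1.5/√2.75 ≈ 0.905).
Reference problem sizes were chosen to keep the whole suite under a
minute on one CPU: 2,040 genes × 20 samples for the bulk study, 600 cells
× 250 genes for the single-cell study, N ≤ 30 for the exhaustive
hypergeometric grid.

## Known limitations

- When two archetypes correlate strongly (the with-X / X-dominant-synergy
  pairs at pattern r ≈ 0.90, latent r ≈ 0.70 at effect 3), an unlucky
  noise realization can leave the two planted modules fused below the
  split criterion; across ten generator seeds this affected one pair at
  one seed.  The reference study (seed 42) resolves all nine modules with
  minimum Jaccard 0.84 against truth.
- The static-parameter branch cut plus refinement is a deterministic
  stand-in for the adaptive dynamic-tree-cut family; very small modules
  (< `min_module_size`) are by construction invisible.
- Enrichment assumes user-supplied GMT collections; no annotation database
  is bundled, so results are annotation-version-independent by design.
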