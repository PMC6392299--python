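# comodule

Weighted gene co-expression module detection and combination-effect trait
analysis for four-arm drug-combination transcriptomics.

## The problem

A two-drug combination study profiles bulk tumor transcriptomes under four
arms — vehicle, drug A alone, drug B alone, and the combination.  The
scientific question is which *gene programs* respond to the combination in
a way neither single agent produces: purely combination-specific
induction, additivity of the two single-agent effects, or a single-agent
effect amplified by the partner drug ("drug-dominant synergy").  Genes are
first grouped into co-expression modules from a weighted correlation
network; each module is summarized by its **eigengene** (first principal
component of the standardized member expression); eigengenes are then
correlated against nine **combination-effect traits** — per-sample numeric
encodings of the qualitative cross-arm patterns (vehicle, drug A, drug B,
combo):

| # | trait | encoding |
|---|-------|----------|
| 1 | Treatment | (0, 1, 1, 1) |
| 2 | A-only | (0, 1, 0, 0) |
| 3 | B-only | (0, 0, 1, 0) |
| 4 | with-A | (0, 1, 0, 1) |
| 5 | with-B | (0, 0, 1, 1) |
| 6 | Combo-only | (0, 0, 0, 1) |
| 7 | Additive | (0, 1, 1, 2) |
| 8 | A-dominant-synergy | (0, 1, 0, 2) |
| 9 | B-dominant-synergy | (0, 0, 1, 2) |

A module is a candidate carrier of the combination's **potentiating
effect** when its most correlated trait (by |Pearson r|) is one of traits
6–9 with |r| > 0.6 and p < 0.01 (p from t = r·√((n−2)/(1−r²)) on n−2 df).
Candidate modules are interpreted through hypergeometric
over-representation of their genes in user-supplied pathway collections
(GMT), with Benjamini–Hochberg FDR per module.

The package also implements the two companion analyses of such studies: a
droplet single-cell pipeline (UMI QC at 400–10,000 total counts,
UMIs-per-million log₂ normalization, t-SNE embedding of an immune gene
panel, k-means clusters, per-treatment cluster proportions) and the
in vivo quantification formulas (tumor volume L·S²/2, ΔT/C %, LOCF
imputation, pooled-variance t test).

Because studies of this design rarely deposit raw data, the package ships
a synthetic-data generator that plants co-expression modules with known
archetype, effect size and gene-set annotation, so the entire chain is
testable against ground truth.

## Worked example

```python
from comodule import AnalysisConfig, SyntheticScenario, generate_bulk
from comodule.pipeline import run_pipeline

data = generate_bulk(SyntheticScenario())   # 9 planted modules + 1,500 background genes
summary = run_pipeline(AnalysisConfig(), data.expression, data.metadata,
                       data.gene_sets, out_dir="out")
print(summary["n_modules"], summary["soft_power"])
print(summary["potentiating_modules"])
```

prints

```
9 8
['turquoise', 'pink', 'blue', 'magenta', 'black']
```

i.e. the detector recovers the nine planted modules at soft power 8 and
flags five of them as potentiating — the four modules planted with
archetypes 6–9 (Combo-only, Additive, A-/B-dominant synergy) plus one
planted with the correlated "with-A" pattern.  `out/summary.json` records
each module's top trait with r and p, and `out/enrichment.tsv` shows each
module's planted gene set as its top pathway (BH-adjusted p ≈ 10⁻²⁶ or
smaller).

The same stages are scriptable from the shell:

```bash
comodule simulate --seed 42 --out-dir sim
comodule run-all --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --gmt sim/gene_sets.gmt --out-dir out
comodule sc-profile --counts umi.tsv --groups groups.tsv --k 3 --seed 0 --out-dir sc
comodule growth --series growth.tsv --treated combo --control vehicle --day 22
```

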