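import pytest

from comodule import AnalysisConfig, simulate
from comodule.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_bulk():
    """The default synthetic scenario: 9 archetype modules x 60 genes at
    effect size 3, 1,500 background genes, 5 samples/arm, seed 42."""
    return simulate.generate_bulk(simulate.SyntheticScenario())


@pytest.fixture(scope="session")
def default_run(default_bulk, tmp_path_factory):
    """Full pipeline output on the default scenario (shared across tests)."""
    out = tmp_path_factory.mktemp("default_run")
    summary = run_pipeline(
        AnalysisConfig(),
        default_bulk.expression,
        default_bulk.metadata,
        default_bulk.gene_sets,
        out_dir=out,
    )
    return summary, out


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


@pytest.fixture(scope="session")
def recovered_modules(default_bulk, default_run):
    """Best-matching detected module (by Jaccard) for each planted module."""
    import pandas as pd

    _, out = default_run
    table = pd.read_csv(out / "module_assignments.tsv", sep="\t")
    labels = pd.Series(table["module"].to_numpy(), index=table["gene_id"])
    named = [m for m in labels.unique() if m != "unassigned"]
    match = {}
    for module_id in default_bulk.truth.module_archetype:
        planted = default_bulk.truth.module_genes(module_id)
        scored = [
            (jaccard(labels.index[labels == m], planted), m) for m in named
        ]
        best_j, best_m = max(scored)
        match[module_id] = (best_j, best_m)
    return labels, match
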