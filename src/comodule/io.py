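"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices, sample metadata, eigengene tables and module
assignments travel as UTF-8 TSV with '.' decimal separator; gene sets as
standard GMT (set name, description, tab-separated members).  In memory an
expression matrix is a pandas DataFrame with gene ids on the index and
sample ids on the columns; metadata is a pandas Series mapping sample id to
treatment arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .archetypes import ARMS


def _check_unique(ids, what: str) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id {x!r}")
        seen.add(x)


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate an expression DataFrame (genes x samples, nonnegative, finite)."""
    _check_unique(expr.index, "gene")
    _check_unique(expr.columns, "sample")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric values")
    if not np.all(np.isfinite(values)):
        gi, si = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value at gene {expr.index[gi]!r}, "
            f"sample {expr.columns[si]!r}"
        )
    if (values < 0).any():
        gi, si = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative expression value {values[gi, si]} at gene "
            f"{expr.index[gi]!r}, sample {expr.columns[si]!r}"
        )
    return expr


def read_expression_tsv(path: "str | Path") -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Raises on duplicate gene/sample ids, non-numeric cells and negative
    values, naming the offending position.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "gene")
    _check_unique(raw.columns, "sample")
    try:
        expr = raw.astype(float)
    except ValueError:
        for gene, row in raw.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {cell!r} at gene {gene!r}, "
                        f"sample {sample!r} in {path}"
                    ) from None
        raise
    expr.index.name = None
    expr.columns.name = None
    return validate_expression(expr)


def write_expression_tsv(expr: pd.DataFrame, path: "str | Path") -> None:
    validate_expression(expr).to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path: "str | Path") -> pd.Series:
    """Read sample metadata TSV with columns ``sample_id`` and ``arm``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "arm"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns {sorted(missing)}")
    _check_unique(df["sample_id"], "sample")
    arms = pd.Series(df["arm"].to_numpy(), index=df["sample_id"].to_numpy(), name="arm")
    return validate_metadata(arms)


def validate_metadata(arms: pd.Series) -> pd.Series:
    unknown = sorted(set(arms) - set(ARMS))
    if unknown:
        raise ValueError(f"unknown arm value(s) {unknown}; expected one of {list(ARMS)}")
    return arms


def write_metadata_tsv(arms: pd.Series, path: "str | Path") -> None:
    pd.DataFrame({"sample_id": arms.index, "arm": arms.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways / GO terms) with optional descriptions."""

    sets: "dict[str, frozenset[str]]" = field(default_factory=dict)
    descriptions: "dict[str, str]" = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> "frozenset[str]":
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: "str | Path") -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one member"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_table_tsv(df: pd.DataFrame, path: "str | Path", index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
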