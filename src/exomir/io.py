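"""Plain-text table I/O with schema checking.

Every artifact is a TSV with a header row (expression matrices carry the
feature id in the first column), SIF for networks, JSON for the truth ledger
and run report — all diffable text.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .exprde import ExpressionStudy

FLOAT_FMT = "%.10g"


def require_columns(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing column(s): {missing}")


def check_unique(values, what: str) -> None:
    values = list(values)
    if len(values) != len(set(values)):
        raise SchemaError(f"duplicate {what} ids")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path, columns=None, name: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if columns is not None:
        require_columns(df, columns, name or Path(path).name)
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    check_unique(df.index, "feature")
    check_unique(df.columns, "sample")
    return df


def write_samples(sheet: pd.DataFrame, path) -> None:
    out = sheet.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    require_columns(df, ["sample_id", "group"], Path(path).name)
    check_unique(df["sample_id"], "sample")
    return df.set_index("sample_id")


def read_study(expr_path, samples_path) -> ExpressionStudy:
    return ExpressionStudy(matrix=read_expression(expr_path),
                           sample_sheet=read_samples(samples_path))


def read_gene_list(path) -> set[str]:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_sif(edges, path, relation: str = "targets") -> None:
    """One `source relation target` line per edge, sorted for determinism."""
    lines = [f"{m}\t{relation}\t{g}" for m, g in sorted(edges)]
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_sif(path) -> set[tuple[str, str]]:
    edges = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise SchemaError(f"malformed SIF line: {line!r}")
        edges.add((parts[0], parts[2]))
    return edges
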