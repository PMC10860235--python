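"""Plain-TSV readers and writers for the pipeline's tabular inputs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .expression import validate_matrix


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene × sample TSV: gene ids in the first column, sample-id header."""
    X = pd.read_csv(path, sep="\t", index_col=0)
    X.index = X.index.astype(str)
    validate_matrix(X)
    return X


def write_expression(X: pd.DataFrame, path: str | Path) -> None:
    X.to_csv(path, sep="\t", index_label="gene")


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> sample -> group Series."""
    # keep_default_na: the normoandrogenic group label is literally "NA"
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = {"sample_id", "group"}
    if set(df.columns) != expected:
        raise ValueError(f"labels file must have columns {sorted(expected)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in labels file")
    s = pd.Series(df["group"].values, index=df["sample_id"].values, name="group")
    return s


def write_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index, "group": labels.values}).to_csv(
        path, sep="\t", index=False
    )


def read_drug_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["score"] = df["score"].astype(float)
    return df


def write_drug_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
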