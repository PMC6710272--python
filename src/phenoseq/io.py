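"""Readers and writers for the plain-text formats used at the CLI boundary."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_cell_numbers_csv",
    "write_cell_numbers_csv",
    "read_gmt",
    "read_gene_list",
]


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x spheroids matrix from TSV; first column holds gene ids."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    if matrix.index.duplicated().any():
        raise ValueError(f"duplicate gene identifiers in {path}")
    if matrix.columns.duplicated().any():
        raise ValueError(f"duplicate spheroid identifiers in {path}")
    return matrix


def write_counts_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_cell_numbers_csv(path: str | Path) -> pd.Series:
    """Two-column CSV (spheroid_id, n_cells) -> Series."""
    table = pd.read_csv(path)
    series = table.set_index(table.columns[0])[table.columns[1]].astype(int)
    if (series < 1).any():
        raise ValueError("cell numbers must be >= 1")
    return series


def write_cell_numbers_csv(cells: pd.Series, path: str | Path) -> None:
    cells.rename("n_cells").to_csv(path, index_label="spheroid_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: one tab-separated line per set (name, description, genes...)."""
    gene_sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, genes): {line!r}")
        gene_sets[fields[0]] = [g for g in fields[2:] if g]
    return gene_sets


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
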