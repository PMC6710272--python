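"""Library QC, cell-number estimation and constant-counts-per-cell transform.

Count matrices are pandas DataFrames with genes as the index and spheroid
identifiers as columns.  Downsampling draws without replacement
(multivariate hypergeometric), so downsampled column totals are exact and
the correlation between column totals and cell numbers is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "QCThresholds",
    "CalibrationModel",
    "qc_filter_libraries",
    "fit_size_to_cells",
    "estimate_cell_numbers",
    "min_per_cell_count",
    "suggest_target_per_cell",
    "downsample_per_cell",
    "downsample_library",
    "filter_genes_for_deconvolution",
    "replace_zeros",
]


@dataclass(frozen=True)
class QCThresholds:
    """Library-level filters: strict > on reads and detected genes, strict <
    on mitochondrial fraction."""

    min_reads: int = 200_000
    min_genes_detected: int = 3_000
    max_mito_fraction: float = 0.15
    mito_gene_ids: tuple[str, ...] | None = None
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def _mito_mask(gene_ids: pd.Index, thresholds: QCThresholds) -> np.ndarray:
    if thresholds.mito_gene_ids is not None:
        return gene_ids.isin(thresholds.mito_gene_ids)
    return np.asarray(gene_ids.str.upper().str.startswith(thresholds.mito_prefix.upper()))


def qc_filter_libraries(
    matrix: pd.DataFrame, thresholds: QCThresholds
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep libraries with enough reads and genes and low mito content.

    A spheroid passes iff total counts > min_reads, detected genes
    (count > 0) > min_genes_detected, and mito fraction < max_mito_fraction.
    The report lists each removed spheroid with its first failing criterion
    (checked in that order).
    """
    totals = matrix.sum(axis=0)
    detected = (matrix > 0).sum(axis=0)
    mito = matrix.loc[_mito_mask(matrix.index, thresholds)].sum(axis=0)
    with np.errstate(invalid="ignore"):
        mito_frac = (mito / totals).fillna(0.0)

    removed = []
    keep = []
    for spheroid in matrix.columns:
        if not totals[spheroid] > thresholds.min_reads:
            removed.append((spheroid, "reads"))
        elif not detected[spheroid] > thresholds.min_genes_detected:
            removed.append((spheroid, "genes"))
        elif not mito_frac[spheroid] < thresholds.max_mito_fraction:
            removed.append((spheroid, "mito"))
        else:
            keep.append(spheroid)

    if not keep:
        raise ValueError("QC thresholds removed every library")
    report = pd.DataFrame(removed, columns=["spheroid_id", "reason"])
    return matrix[keep], report


@dataclass(frozen=True)
class CalibrationModel:
    """Size -> cell-number calibration; power (count = a * area**b) or
    linear (count = a * area + b)."""

    model_form: Literal["power", "linear"]
    a: float
    b: float
    fit_residual_sd: float

    def predict(self, area: np.ndarray | float) -> np.ndarray | float:
        area = np.asarray(area, dtype=float)
        if self.model_form == "power":
            pred = self.a * area**self.b
        else:
            pred = self.a * area + self.b
        return pred if pred.ndim else float(pred)


def fit_size_to_cells(
    pairs: pd.DataFrame | Sequence[tuple[float, float]],
    model_form: Literal["power", "linear"] = "power",
) -> CalibrationModel:
    """Fit the area -> nuclei-count relation by least squares.

    The power form regresses log(count) on log(area); the linear form fits
    count = a*area + b directly.  Residual spread is reported on the fitted
    scale (log for power).
    """
    if isinstance(pairs, pd.DataFrame):
        areas = pairs.iloc[:, 0].to_numpy(dtype=float)
        counts = pairs.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        areas, counts = arr[:, 0], arr[:, 1]
    if areas.size < 3:
        raise ValueError("need at least 3 calibration pairs")
    if (areas <= 0).any() or (counts <= 0).any():
        raise ValueError("areas and counts must be positive")
    if np.ptp(areas) == 0:
        raise ValueError("degenerate design: all areas are equal")

    if model_form == "power":
        slope, intercept = np.polyfit(np.log(areas), np.log(counts), 1)
        residuals = np.log(counts) - (intercept + slope * np.log(areas))
        return CalibrationModel("power", a=float(np.exp(intercept)), b=float(slope),
                                fit_residual_sd=float(residuals.std(ddof=2)))
    if model_form == "linear":
        slope, intercept = np.polyfit(areas, counts, 1)
        residuals = counts - (intercept + slope * areas)
        return CalibrationModel("linear", a=float(slope), b=float(intercept),
                                fit_residual_sd=float(residuals.std(ddof=2)))
    raise ValueError(f"unknown model form {model_form!r}")


def estimate_cell_numbers(
    features: pd.DataFrame, model: CalibrationModel,
    area_column: str = "area_px", id_column: str = "spheroid_id",
) -> pd.Series:
    """Predict per-spheroid cell numbers, rounded and floored at 1."""
    if id_column in features.columns:
        ids = features[id_column]
    else:
        ids = features.index
    areas = features[area_column]
    missing = areas.isna()
    if missing.any():
        raise ValueError(
            f"missing area for spheroids: {list(pd.Index(ids)[missing.to_numpy()])}"
        )
    predictions = model.predict(areas.to_numpy(dtype=float))
    n = np.maximum(1, np.round(predictions)).astype(int)
    return pd.Series(n, index=pd.Index(ids, name=id_column), name="n_cells")


def min_per_cell_count(matrix: pd.DataFrame, cells: pd.Series) -> float:
    """Minimum over spheroids of column total / estimated cell number."""
    cells = cells.reindex(matrix.columns)
    if cells.isna().any():
        raise ValueError("every spheroid needs a cell-number estimate")
    return float((matrix.sum(axis=0) / cells).min())


def suggest_target_per_cell(minimal_per_cell: float) -> int:
    """Suggest a round target below the minimum (floor to nearest 100)."""
    return int(math.floor(minimal_per_cell / 100.0) * 100)


def _downsample_column_keyed(
    column: np.ndarray, gene_ids: Sequence[str], target: int,
    seed: int, spheroid_id: str,
) -> np.ndarray:
    """Without-replacement subsample of a count column, keyed per gene.

    Each count unit receives a uniform key from a (seed, spheroid, gene)
    substream and the ``target`` smallest keys are kept, so the result is
    invariant under gene reordering.
    """
    keys = []
    owners = []
    for gi, gene in enumerate(gene_ids):
        c = int(column[gi])
        if c > 0:
            rng = substream(seed, "downsample", spheroid_id, gene)
            keys.append(rng.random(c))
            owners.append(np.full(c, gi, dtype=np.int64))
    keys = np.concatenate(keys) if keys else np.empty(0)
    owners = np.concatenate(owners) if owners else np.empty(0, dtype=np.int64)
    kept = owners[np.argpartition(keys, target - 1)[:target]] if target > 0 else owners[:0]
    return np.bincount(kept, minlength=len(gene_ids))


def downsample_per_cell(
    matrix: pd.DataFrame, cells: pd.Series, target_per_cell: int, seed: int
) -> pd.DataFrame:
    """Downsample each column without replacement to target_per_cell * n_i.

    Fails loudly, naming the spheroid, if a column holds fewer counts than
    its target (choose a target at or below :func:`min_per_cell_count`).
    """
    cells = cells.reindex(matrix.columns)
    if cells.isna().any():
        raise ValueError("every spheroid needs a cell-number estimate")
    counts = matrix.to_numpy(dtype=np.int64)
    out = np.empty_like(counts)
    gene_ids = list(matrix.index)
    for ci, spheroid in enumerate(matrix.columns):
        target = int(target_per_cell) * int(cells[spheroid])
        total = int(counts[:, ci].sum())
        if total < target:
            raise ValueError(
                f"spheroid {spheroid!r} holds {total} counts < target {target}"
            )
        out[:, ci] = _downsample_column_keyed(counts[:, ci], gene_ids, target, seed, str(spheroid))
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def downsample_library(column: np.ndarray | pd.Series, target_total: int, seed: int):
    """Without-replacement subsample of one library to an exact total."""
    values = np.asarray(column, dtype=np.int64)
    total = int(values.sum())
    if total < target_total:
        raise ValueError(f"library holds {total} counts < target {target_total}")
    rng = substream(seed, "library")
    sampled = rng.multivariate_hypergeometric(values, int(target_total))
    if isinstance(column, pd.Series):
        return pd.Series(sampled, index=column.index, name=column.name)
    return sampled


def filter_genes_for_deconvolution(
    original: pd.DataFrame,
    working: pd.DataFrame,
    min_mean: float = 1.0,
    min_count: int = 5,
    min_wells: int = 2,
) -> pd.DataFrame:
    """Keep genes with mean count >= min_mean over the original matrix and
    >= min_count counts in >= min_wells wells of the working matrix."""
    if not original.index.equals(working.index):
        raise ValueError("original and working matrices must share the same genes")
    mean_ok = original.mean(axis=1) >= min_mean
    wells_ok = (working >= min_count).sum(axis=1) >= min_wells
    return working.loc[mean_ok & wells_ok]


def replace_zeros(matrix: pd.DataFrame | np.ndarray, value: float = 0.1):
    """Replace exact zeros with a small positive value (lognormal support)."""
    if value <= 0:
        raise ValueError("replacement value must be > 0")
    if isinstance(matrix, pd.DataFrame):
        return matrix.mask(matrix == 0, value).astype(float)
    out = np.asarray(matrix, dtype=float).copy()
    out[out == 0] = value
    return out
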