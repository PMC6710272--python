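"""Spheroid segmentation and feature extraction for nanowell images.

Two presets share the same segmentation core: the immunofluorescence route
(Gaussian sigma=2, Otsu, 300-800,000 px size filter, mean projection) and
the RNA-FISH route (Gaussian sigma=5, maximum filter radius 12, max
projection, biggest object only, intermodes background threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

__all__ = [
    "WellImage",
    "GridLayout",
    "IntermodesResult",
    "BimodalityError",
    "split_field_into_wells",
    "project_z",
    "segment_spheroids",
    "fish_nuclear_mask",
    "compute_features",
    "intermodes_threshold",
    "fraction_above_threshold",
]

DEFAULT_MIN_AREA = 300
DEFAULT_MAX_AREA = 800_000


class BimodalityError(ValueError):
    """Raised when a pixel histogram cannot be reduced to two modes."""


@dataclass
class WellImage:
    channels: dict[str, np.ndarray]
    well_id: tuple[int, int]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        shapes = {ch: img.shape for ch, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")


@dataclass(frozen=True)
class GridLayout:
    """Chip layout: how many wells one field of view spans and how fields
    are ordered in the scan."""

    wells_per_field: tuple[int, int] = (2, 2)
    chip_wells: tuple[int, int] = (72, 72)
    scan_order: Literal["raster", "serpentine"] = "raster"

    @property
    def field_grid(self) -> tuple[int, int]:
        fr, rem_r = divmod(self.chip_wells[0], self.wells_per_field[0])
        fc, rem_c = divmod(self.chip_wells[1], self.wells_per_field[1])
        if rem_r or rem_c:
            raise ValueError("chip wells must be divisible by wells_per_field")
        return fr, fc

    def field_position(self, scan_index: int) -> tuple[int, int]:
        n_rows, n_cols = self.field_grid
        if not (0 <= scan_index < n_rows * n_cols):
            raise ValueError(f"scan index {scan_index} outside chip ({n_rows}x{n_cols} fields)")
        row, col = divmod(scan_index, n_cols)
        if self.scan_order == "serpentine" and row % 2 == 1:
            col = n_cols - 1 - col
        return row, col


def split_field_into_wells(
    field_image: Mapping[str, np.ndarray] | np.ndarray,
    layout: GridLayout,
    scan_index: int = 0,
) -> list[WellImage]:
    """Cut one field of view into its constituent wells.

    The field is divided into a ``wells_per_field`` grid of equal tiles;
    well coordinates come from the field's position in the chip scan order.
    Tiles partition the field exactly.
    """
    if isinstance(field_image, np.ndarray):
        field_image = {"intensity": field_image}
    wr, wc = layout.wells_per_field
    shape = next(iter(field_image.values())).shape[-2:]
    if shape[0] % wr:
        raise ValueError(f"field height {shape[0]} not divisible by {wr} (row axis)")
    if shape[1] % wc:
        raise ValueError(f"field width {shape[1]} not divisible by {wc} (col axis)")
    tile_h, tile_w = shape[0] // wr, shape[1] // wc

    frow, fcol = layout.field_position(scan_index)
    wells = []
    for dr in range(wr):
        for dc in range(wc):
            sl = (
                slice(dr * tile_h, (dr + 1) * tile_h),
                slice(dc * tile_w, (dc + 1) * tile_w),
            )
            channels = {ch: img[..., sl[0], sl[1]] for ch, img in field_image.items()}
            wells.append(
                WellImage(channels=channels, well_id=(frow * wr + dr, fcol * wc + dc))
            )
    return wells


def project_z(stack: np.ndarray, mode: Literal["mean", "max"]) -> np.ndarray:
    """Project a (z, row, col) stack to 2D by pixelwise mean or max."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must have shape (z, rows, cols) with z >= 1")
    if mode == "mean":
        return stack.mean(axis=0)
    if mode == "max":
        return stack.max(axis=0)
    raise ValueError(f"unknown projection mode {mode!r}; use 'mean' or 'max'")


def _relabel(binary: np.ndarray, min_area: int, max_area: int) -> np.ndarray:
    labels = measure.label(binary, connectivity=2)
    out = np.zeros_like(labels)
    next_label = 1
    for region in measure.regionprops(labels):
        if min_area <= region.area <= max_area:
            out[labels == region.label] = next_label
            next_label += 1
    return out


def segment_spheroids(
    image: np.ndarray,
    sigma: float = 2.0,
    min_area: int = DEFAULT_MIN_AREA,
    max_area: int = DEFAULT_MAX_AREA,
) -> np.ndarray:
    """Gaussian smoothing, Otsu threshold, 8-connected labelling, size filter.

    Objects outside [min_area, max_area] pixels are discarded and the
    remaining labels renumbered consecutively.  A constant image (Otsu
    undefined) yields an empty mask and a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_spheroids expects a single-channel 2D image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite intensities")
    smoothed = filters.gaussian(image, sigma=sigma, preserve_range=True) if sigma > 0 else image
    if np.ptp(smoothed) == 0:
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask")
        return np.zeros(image.shape, dtype=np.int32)
    threshold = filters.threshold_otsu(smoothed)
    return _relabel(smoothed > threshold, min_area, max_area).astype(np.int32)


def fish_nuclear_mask(
    dapi_image: np.ndarray,
    sigma: float = 5.0,
    maxfilter_radius: int = 12,
) -> np.ndarray:
    """Nuclear-counterstain mask: Gaussian sigma=5, maximum filter radius 12,
    Otsu, keep only the biggest object."""
    image = np.asarray(dapi_image, dtype=float)
    if image.ndim != 2:
        raise ValueError("fish_nuclear_mask expects a single-channel 2D image")
    smoothed = filters.gaussian(image, sigma=sigma, preserve_range=True)
    footprint = morphology.disk(maxfilter_radius)
    filtered = ndimage.maximum_filter(smoothed, footprint=footprint)
    if np.ptp(filtered) == 0:
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask")
        return np.zeros(image.shape, dtype=np.int32)
    threshold = filters.threshold_otsu(filtered)
    labels = measure.label(filtered > threshold, connectivity=2)
    if labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(areas)) + 1
    return (labels == biggest).astype(np.int32)


def _perimeter_polygonal(object_mask: np.ndarray, tolerance: float = 1.0) -> float:
    """Length of the simplified outer marching-squares contour of an object.

    Douglas-Peucker simplification (1 px tolerance) removes the staircase
    jaggies that would otherwise overestimate the perimeter of smooth
    boundaries, while polygon corners survive exactly.
    """
    padded = np.pad(object_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    lengths = []
    for contour in contours:
        simplified = measure.approximate_polygon(contour, tolerance=tolerance)
        deltas = np.diff(simplified, axis=0)
        lengths.append(float(np.hypot(deltas[:, 0], deltas[:, 1]).sum()))
    return max(lengths)  # outer boundary; holes produce shorter contours


def compute_features(
    mask: np.ndarray,
    channels: Mapping[str, np.ndarray] | None = None,
    well_id: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-object morphology and per-channel mean intensity.

    Circularity is 4*pi*area / perimeter**2 with a polygonal-contour
    perimeter, capped at 1.0 to absorb discretisation overshoot.
    """
    channels = dict(channels or {})
    for name, img in channels.items():
        if img.shape != mask.shape:
            raise ValueError(f"channel {name!r} shape {img.shape} != mask shape {mask.shape}")

    rows = []
    for region in measure.regionprops(mask):
        object_mask = mask == region.label
        perimeter = _perimeter_polygonal(object_mask)
        circularity = 4.0 * np.pi * region.area / perimeter**2 if perimeter > 0 else np.nan
        row = {
            "well_row": well_id[0] if well_id else -1,
            "well_col": well_id[1] if well_id else -1,
            "object_id": int(region.label),
            "area_px": int(region.area),
            "perimeter_px": perimeter,
            "circularity": min(1.0, circularity),
            "centroid_row": region.centroid[0],
            "centroid_col": region.centroid[1],
        }
        for name, img in channels.items():
            row[f"mean_intensity_{name}"] = float(img[object_mask].mean())
        rows.append(row)

    columns = [
        "well_row",
        "well_col",
        "object_id",
        "area_px",
        "perimeter_px",
        "circularity",
        "centroid_row",
        "centroid_col",
    ] + [f"mean_intensity_{name}" for name in channels]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class IntermodesResult:
    j: float
    k: float
    threshold: float
    smoothing_iterations: int

    def __post_init__(self) -> None:
        if not (self.j < self.k):
            raise ValueError("intermodes requires j < k")
        if not (self.j < self.threshold < self.k):
            raise ValueError("threshold must lie strictly between the modes")


def _count_peaks(hist: np.ndarray) -> np.ndarray:
    """Positions (bin indices, plateau centers) of local histogram maxima.

    Runs of equal values are collapsed so a flat-topped peak counts once.
    """
    change = np.flatnonzero(np.diff(hist) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [hist.size]])
    values = hist[starts]
    padded = np.concatenate([[-np.inf], values, [-np.inf]])
    is_peak = (padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:])
    return ((starts + ends - 1) / 2.0)[is_peak]


def intermodes_threshold(
    pixels: np.ndarray,
    n_bins: int = 256,
    max_iterations: int = 10_000,
) -> IntermodesResult:
    """Classic intermodes auto-threshold.

    The intensity histogram is repeatedly smoothed with a 3-bin mean filter
    until exactly two local maxima j < k remain; the threshold is (j+k)/2.
    Effectively unimodal samples raise :class:`BimodalityError`.
    """
    values = np.asarray(pixels, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise BimodalityError("intensity sample has fewer than 2 distinct values")
    hist, edges = np.histogram(values, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0

    smoothed = hist.astype(float)
    iterations = 0
    while True:
        peaks = _count_peaks(smoothed)
        if peaks.size == 2:
            break
        if peaks.size < 2 or iterations >= max_iterations:
            raise BimodalityError(
                f"histogram not bimodal after {iterations} smoothing iterations "
                f"({peaks.size} modes)"
            )
        smoothed = np.convolve(smoothed, np.ones(3) / 3.0, mode="same")
        iterations += 1

    j, k = np.interp(peaks, np.arange(n_bins), centers)
    return IntermodesResult(j=float(j), k=float(k), threshold=float((j + k) / 2.0),
                            smoothing_iterations=iterations)


def fraction_above_threshold(
    probe_image: np.ndarray,
    mask: np.ndarray,
    threshold: float,
) -> pd.Series:
    """Per object: fraction of masked pixels with intensity above threshold."""
    probe_image = np.asarray(probe_image, dtype=float)
    if probe_image.shape != mask.shape:
        raise ValueError("probe image and mask shapes differ")
    fractions = {}
    for label in np.unique(mask):
        if label == 0:
            continue
        values = probe_image[mask == label]
        fractions[int(label)] = float((values > threshold).mean())
    return pd.Series(fractions, name="fraction_above", dtype=float)
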