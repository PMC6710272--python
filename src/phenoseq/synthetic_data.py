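"""Ground-truth generators for expression matrices, spheroid images and
size-to-cell-number calibration pairs.

Every generator takes an explicit integer seed and is bit-reproducible.
The expression generator draws, for each gene independently, every cell of
every spheroid from one of two lognormal populations sharing a common
log-SD; spheroid-level expression is the sum of its per-cell draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "LnLnParams",
    "SimulationTruth",
    "SpheroidObject",
    "SyntheticImageSpec",
    "simulate_lnln_matrix",
    "simulate_depth_matrix",
    "render_spheroid_image",
    "add_spots",
    "simulate_calibration_pairs",
]

DEBRIS_MAX_AREA = 300


@dataclass(frozen=True)
class LnLnParams:
    """Two-population lognormal mixture parameters.

    ``mu1``/``mu2`` are the log-means of the low and high population, ``F``
    the fraction of cells in the high population, ``sigma`` the shared
    log-SD.  ``mu1 <= mu2`` is the canonical labelling; unordered instances
    are permitted so that label symmetry can be expressed, use
    :meth:`ordered` to canonicalise.
    """

    mu1: float
    mu2: float
    F: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.F <= 1.0):
            raise ValueError(f"F must lie in [0, 1], got {self.F}")
        if not (self.sigma > 0.0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        for name in ("mu1", "mu2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def ordered(self) -> "LnLnParams":
        """Relabel populations so that mu1 <= mu2 (swaps F accordingly)."""
        if self.mu1 <= self.mu2:
            return self
        return LnLnParams(self.mu2, self.mu1, 1.0 - self.F, self.sigma)

    def swapped(self) -> "LnLnParams":
        return LnLnParams(self.mu2, self.mu1, 1.0 - self.F, self.sigma)


@dataclass
class SimulationTruth:
    params: list[LnLnParams]
    cell_numbers: np.ndarray
    seed: int
    per_cell_assignments: list[list[np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.cell_numbers = np.asarray(self.cell_numbers, dtype=int)
        if self.cell_numbers.size < 1:
            raise ValueError("need at least one spheroid")
        if (self.cell_numbers < 1).any():
            raise ValueError("all cell numbers must be >= 1")


def simulate_lnln_matrix(
    params_per_gene: Sequence[LnLnParams],
    cell_numbers: Sequence[int],
    seed: int,
    *,
    return_assignments: bool = False,
) -> tuple[np.ndarray, SimulationTruth]:
    """Simulate a genes x spheroids expression matrix under the LN-LN model.

    Entry (g, i) is the sum over ``cell_numbers[i]`` independent per-cell
    draws; each cell comes from LogNormal(mu2, sigma) with probability F,
    else LogNormal(mu1, sigma).  Assignments are independent across cells
    and across genes.
    """
    params = list(params_per_gene)
    n = np.asarray(cell_numbers, dtype=int)
    if n.size < 1:
        raise ValueError("need at least one spheroid")
    if (n < 1).any():
        raise ValueError("cell numbers must be positive integers")

    total_cells = int(n.sum())
    # reduceat boundaries: cells of spheroid i occupy offsets[i]:offsets[i+1]
    offsets = np.concatenate([[0], np.cumsum(n)[:-1]])
    matrix = np.empty((len(params), n.size), dtype=float)
    assignments: list[list[np.ndarray]] | None = [] if return_assignments else None

    for g, p in enumerate(params):
        rng = substream(seed, "lnln", g)
        high = rng.random(total_cells) < p.F
        log_x = np.where(high, p.mu2, p.mu1) + p.sigma * rng.standard_normal(total_cells)
        matrix[g] = np.add.reduceat(np.exp(log_x), offsets)
        if assignments is not None:
            assignments.append(np.split(high, np.cumsum(n)[:-1]))

    truth = SimulationTruth(params=params, cell_numbers=n, seed=seed,
                            per_cell_assignments=assignments)
    return matrix, truth


def simulate_depth_matrix(
    relative_gene_rates: Sequence[float],
    cell_numbers: Sequence[int],
    per_cell_depth: int,
    seed: int,
) -> np.ndarray:
    """Draw a count matrix whose column totals are exactly depth * n_i.

    Column i is a single multinomial draw of size ``per_cell_depth * n_i``
    over genes with the given rates.
    """
    rates = np.asarray(relative_gene_rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("gene rates must be non-negative")
    if not math.isclose(rates.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("gene rates must sum to 1")
    if per_cell_depth < 1:
        raise ValueError("per_cell_depth must be >= 1")
    n = np.asarray(cell_numbers, dtype=int)
    if (n < 1).any():
        raise ValueError("cell numbers must be positive integers")

    matrix = np.empty((rates.size, n.size), dtype=np.int64)
    for i, ni in enumerate(n):
        rng = substream(seed, "depth", i)
        matrix[:, i] = rng.multinomial(per_cell_depth * int(ni), rates)
    return matrix


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------

ObjectClass = Literal["round", "aberrant", "debris"]


@dataclass(frozen=True)
class SpheroidObject:
    """One object to render: a disk, a star-convex perturbed disk or debris.

    Aberrant shapes use r(theta) = radius * (1 + sum_k a_k sin(k theta + phi_k));
    amplitudes must keep the radius positive.
    """

    center: tuple[float, float]
    radius: float
    intensity: float
    kind: ObjectClass = "round"
    amplitudes: tuple[float, ...] = ()
    phases: tuple[float, ...] = ()

    def max_radius(self) -> float:
        return self.radius * (1.0 + sum(abs(a) for a in self.amplitudes))


@dataclass
class SyntheticImageSpec:
    image_shape: tuple[int, int]
    objects: list[SpheroidObject] = field(default_factory=list)
    noise_sd: float = 0.0
    background: float = 0.0
    channels: tuple[str, ...] = ("intensity",)


def _object_mask(obj: SpheroidObject, shape: tuple[int, int]) -> np.ndarray:
    r0, c0 = obj.center
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - r0
    dc = cc - c0
    dist = np.hypot(dr, dc)
    if obj.kind == "aberrant" and obj.amplitudes:
        theta = np.arctan2(dr, dc)
        boundary = obj.radius * (
            1.0
            + sum(
                a * np.sin(k * theta + (obj.phases[k - 1] if k - 1 < len(obj.phases) else 0.0))
                for k, a in enumerate(obj.amplitudes, start=1)
            )
        )
        if np.any(boundary <= 0):
            raise ValueError("aberrant amplitudes produce non-positive radius")
        return dist <= boundary
    return dist <= obj.radius


def render_spheroid_image(
    spec: SyntheticImageSpec, seed: int
) -> tuple[dict[str, np.ndarray], np.ndarray, pd.DataFrame]:
    """Render objects into (channel images, label mask, ground-truth table).

    Round objects become filled disks, aberrant objects star-convex
    perturbed disks, debris small specks (< 300 px).  Overlapping objects
    are rejected because the label ground truth would be ambiguous.
    """
    shape = tuple(spec.image_shape)
    labels = np.zeros(shape, dtype=np.int32)
    records = []
    for idx, obj in enumerate(spec.objects, start=1):
        rmax = obj.max_radius()
        if not (
            0 <= obj.center[0] - rmax
            and obj.center[0] + rmax < shape[0]
            and 0 <= obj.center[1] - rmax
            and obj.center[1] + rmax < shape[1]
        ):
            raise ValueError(f"object {idx} extends outside the image bounds")
        mask = _object_mask(obj, shape)
        if (labels[mask] != 0).any():
            raise ValueError(f"object {idx} overlaps a previously placed object")
        area = int(mask.sum())
        if obj.kind == "debris" and area >= DEBRIS_MAX_AREA:
            raise ValueError(
                f"debris object {idx} has area {area} >= {DEBRIS_MAX_AREA} px"
            )
        labels[mask] = idx
        records.append(
            {
                "object_id": idx,
                "class": obj.kind,
                "area_px": area,
                "centroid_row": obj.center[0],
                "centroid_col": obj.center[1],
                "radius": obj.radius,
                "intensity": obj.intensity,
            }
        )

    base = np.full(shape, spec.background, dtype=float)
    for idx, obj in enumerate(spec.objects, start=1):
        base[labels == idx] = obj.intensity

    images: dict[str, np.ndarray] = {}
    for channel in spec.channels:
        img = base.copy()
        if spec.noise_sd > 0:
            rng = substream(seed, "image-noise", channel)
            img += rng.normal(0.0, spec.noise_sd, size=shape)
            np.clip(img, 0.0, None, out=img)
        images[channel] = img

    truth = pd.DataFrame.from_records(
        records,
        columns=[
            "object_id",
            "class",
            "area_px",
            "centroid_row",
            "centroid_col",
            "radius",
            "intensity",
        ],
    )
    return images, labels, truth


def add_spots(
    image: np.ndarray,
    mask: np.ndarray,
    fraction: float,
    intensity: float,
    seed: int,
) -> np.ndarray:
    """Paint a random fraction of masked pixels at a fixed high intensity.

    Produces the bimodal within-object pixel distribution used to exercise
    the FISH quantification stage; returns a modified copy.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    out = np.array(image, dtype=float, copy=True)
    coords = np.flatnonzero(mask.ravel())
    n_spots = int(round(fraction * coords.size))
    rng = substream(seed, "spots")
    chosen = rng.choice(coords, size=n_spots, replace=False)
    out.ravel()[chosen] = intensity
    return out


def simulate_calibration_pairs(
    a: float,
    b: float,
    noise_sd: float,
    areas: Sequence[float],
    seed: int,
) -> pd.DataFrame:
    """Generate (area, nuclei_count) pairs from a noisy power law.

    count = round(a * area**b * exp(eps)) with eps ~ Normal(0, noise_sd),
    floored at 1.
    """
    if a <= 0:
        raise ValueError("scale coefficient a must be > 0")
    areas_arr = np.asarray(areas, dtype=float)
    if (areas_arr <= 0).any():
        raise ValueError("areas must be positive")
    rng = substream(seed, "calibration")
    eps = rng.normal(0.0, noise_sd, size=areas_arr.size) if noise_sd > 0 else 0.0
    counts = np.maximum(1, np.round(a * areas_arr**b * np.exp(eps)).astype(int))
    return pd.DataFrame({"area_px": areas_arr, "nuclei_count": counts})
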