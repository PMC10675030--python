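"""Per-plot biophysical observables from RGB and thermal grids.

Grids are plain 2-D arrays (row-major, origin top-left, 0-based); plot
masks are boolean arrays of the same shape.  Sources can be single-band
TIFFs (via :mod:`tifffile`) or whitespace-delimited text matrices; no
georeferencing is performed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "RgbPlotStats",
    "VegetationIndexContext",
    "ComponentTemperatures",
    "DegeneratePixelError",
    "compute_vari",
    "compute_fc",
    "plant_height",
    "calibrate_thermal",
    "vegetation_mask",
    "separate_component_temperatures",
    "read_grid",
    "write_grid",
]


class DegeneratePixelError(ValueError):
    """VARI denominator vanished (G + R − B = 0)."""


@dataclass(frozen=True)
class RgbPlotStats:
    """Mean digital numbers of a plot's RGB pixels."""

    dn_red: float
    dn_green: float
    dn_blue: float

    def __post_init__(self) -> None:
        for v in (self.dn_red, self.dn_green, self.dn_blue):
            if not math.isfinite(v) or v < 0:
                raise ValueError("digital numbers must be finite and >= 0")


@dataclass(frozen=True)
class VegetationIndexContext:
    """VARI of the target plus bare-soil and pure-vegetation references."""

    vari_i: float
    vari_soil: float
    vari_veg: float

    def __post_init__(self) -> None:
        if self.vari_veg == self.vari_soil:
            raise ValueError("vegetation and soil references must differ")


@dataclass(frozen=True)
class ComponentTemperatures:
    """Mean canopy and soil temperatures of a plot with pixel counts.

    A temperature is ``None`` when its pixel class is empty; the caller
    decides the fallback (e.g. single-source residual ETa).
    """

    t_canopy: float | None
    t_soil: float | None
    n_canopy_px: int
    n_soil_px: int


def compute_vari(dn_red, dn_green, dn_blue):
    """Visible Atmospherically Resistant Index (G − R) / (G + R − B).

    Scalars raise :class:`DegeneratePixelError` on a zero denominator;
    array inputs return NaN at degenerate pixels instead.
    """
    r = np.asarray(dn_red, dtype=float)
    g = np.asarray(dn_green, dtype=float)
    b = np.asarray(dn_blue, dtype=float)
    denom = g + r - b
    if r.ndim == 0:
        if denom == 0:
            raise DegeneratePixelError("VARI denominator G + R - B is zero")
        return float((g - r) / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom == 0, np.nan, (g - r) / denom)
    return out


def compute_fc(context: VegetationIndexContext) -> float:
    """Fractional vegetation cover from VARI, clamped to [0, 1].

    Linear mixing between the bare-soil and pure-vegetation references;
    noisy references can push the raw ratio outside the unit interval, so
    the result is clamped.
    """
    raw = (context.vari_i - context.vari_soil) / (
        context.vari_veg - context.vari_soil
    )
    return float(min(max(raw, 0.0), 1.0))


def plant_height(dsm: np.ndarray, dtm: np.ndarray, mask: np.ndarray) -> float:
    """Mean canopy height (m) over a plot: mean of max(DSM − DTM, 0).

    Negative surface-minus-terrain differences (point-cloud noise) are
    floored at zero before averaging.
    """
    dsm = np.asarray(dsm, dtype=float)
    dtm = np.asarray(dtm, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dsm.shape != dtm.shape or dsm.shape != mask.shape:
        raise ValueError("DSM, DTM and mask must share one shape")
    if not mask.any():
        raise ValueError("empty plot mask")
    diff = np.maximum(dsm - dtm, 0.0)
    return float(diff[mask].mean())


def calibrate_thermal(raw, reference_pairs):
    """Linear radiometric correction from in-scene reference targets.

    ``reference_pairs`` is a sequence of (measured_on_image, ground_truth)
    temperature pairs from hot/cold calibration targets.  Two pairs give
    the exact two-point line; more are fit by least squares.  The map is
    applied to ``raw`` (scalar or array).
    """
    pairs = np.asarray(reference_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2 or pairs.shape[1] != 2:
        raise ValueError("need at least two (measured, truth) reference pairs")
    measured, truth = pairs[:, 0], pairs[:, 1]
    if np.ptp(measured) == 0:
        raise ValueError("reference measured temperatures are identical")
    slope, intercept = np.polyfit(measured, truth, 1)
    out = slope * np.asarray(raw, dtype=float) + intercept
    return float(out) if np.ndim(raw) == 0 else out


def vegetation_mask(vari_grid: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Boolean vegetation mask from a VARI grid.

    Pixels above the threshold are vegetation.  By default the threshold
    is Otsu's on the grid's finite values — a deterministic, training-free
    replacement for a supervised soil/vegetation classifier.
    """
    grid = np.asarray(vari_grid, dtype=float)
    finite = grid[np.isfinite(grid)]
    if finite.size == 0:
        raise ValueError("no finite VARI values to threshold")
    if threshold is None:
        if np.ptp(finite) == 0:
            raise ValueError("constant VARI grid: Otsu threshold undefined")
        threshold = float(threshold_otsu(finite))
    return np.isfinite(grid) & (grid > threshold)


def separate_component_temperatures(
    thermal: np.ndarray, veg_mask: np.ndarray
) -> ComponentTemperatures:
    """Mean canopy and soil temperatures from a thermal grid and a mask."""
    thermal = np.asarray(thermal, dtype=float)
    veg_mask = np.asarray(veg_mask, dtype=bool)
    if thermal.shape != veg_mask.shape:
        raise ValueError("thermal grid and mask must share one shape")
    valid = np.isfinite(thermal)
    canopy = thermal[veg_mask & valid]
    soil = thermal[~veg_mask & valid]
    return ComponentTemperatures(
        t_canopy=float(canopy.mean()) if canopy.size else None,
        t_soil=float(soil.mean()) if soil.size else None,
        n_canopy_px=int(canopy.size),
        n_soil_px=int(soil.size),
    )


def read_grid(path: str | Path) -> np.ndarray:
    """Read a single-band grid from TIFF or a delimited text matrix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    return np.loadtxt(path, dtype=float)


def write_grid(path: str | Path, grid: np.ndarray) -> None:
    """Write a single-band grid as TIFF or a delimited text matrix."""
    path = Path(path)
    grid = np.asarray(grid, dtype=float)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, grid)
    else:
        np.savetxt(path, grid)
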