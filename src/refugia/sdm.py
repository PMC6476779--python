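"""Species-distribution-model post-processing: TSS-based thresholding,
binary suitability maps, distributional-shift classification, and
stability maps.

Continuous occurrence-probability rasters (one per time period, e.g.
present / Mid-Holocene / LGM / LIG) are binarized at a single scalar
threshold chosen via the True Skill Statistic, then compared between
successive periods:

    shift = 2 * recent - older   per cell

yielding the four categories colonization (2), stability (1), absence (0)
and extinction (-1).  Stability across many periods is the cell-wise
product of the binary maps.

Raster I/O uses the single-band ESRI ASCII grid dialect with a declared
no-data value; compared grids must share shape and geotransform exactly
(no resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, DataError

CATEGORY_LABELS = {2: "colonization", 1: "stability", 0: "absence", -1: "extinction"}


@dataclass(frozen=True)
class GridSpec:
    """Geotransform of a north-up raster: lower-left corner and cell size."""

    xll: float
    yll: float
    cellsize: float

    def cell_of(self, x: float, y: float, shape: tuple[int, int]) -> tuple[int, int]:
        """(row, col) of the cell containing a point; half-open intervals
        [edge, edge + cellsize).  Row 0 is the northernmost row."""
        nrows, ncols = shape
        col = int(np.floor((x - self.xll) / self.cellsize))
        row_from_south = int(np.floor((y - self.yll) / self.cellsize))
        row = nrows - 1 - row_from_south
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise DataError(f"point ({x}, {y}) outside raster extent")
        return row, col


@dataclass(frozen=True)
class ProbabilityRaster:
    """Occurrence probabilities in [0, 1] with a no-data mask."""

    values: np.ndarray  # float grid; NaN = no-data
    grid: GridSpec
    period: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        valid = np.isfinite(v)
        if valid.any() and ((v[valid] < 0) | (v[valid] > 1)).any():
            raise DataError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def value_at(self, x: float, y: float) -> float:
        r, c = self.grid.cell_of(x, y, self.shape)
        return float(self.values[r, c])


@dataclass(frozen=True)
class BinaryMap:
    """Suitable (1) / unsuitable (0) grid; -1 marks no-data."""

    values: np.ndarray  # int8
    grid: GridSpec
    threshold: float
    period: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ShiftMap:
    """Categorical change grid over {2, 1, 0, -1}; -9 marks no-data."""

    values: np.ndarray  # int8
    grid: GridSpec
    older_period: str = ""
    recent_period: str = ""

    NODATA = -9

    def category_counts(self) -> pd.Series:
        valid = self.values != self.NODATA
        out = {
            label: int((self.values[valid] == code).sum())
            for code, label in CATEGORY_LABELS.items()
        }
        return pd.Series(out)


@dataclass(frozen=True)
class OccurrenceSet:
    """Presence points and replicated pseudo-absence point sets."""

    presences: np.ndarray  # (n, 2) of (x, y)
    absence_replicates: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.absence_replicates) < 1:
            raise DataError("at least one pseudo-absence replicate required")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_ascii_grid(path, period: str = "") -> ProbabilityRaster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required.issubset(header):
        raise DataError(f"ASCII grid header incomplete: has {sorted(header)}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise DataError("ASCII grid data does not match declared shape")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    return ProbabilityRaster(
        values,
        GridSpec(header["xllcorner"], header["yllcorner"], header["cellsize"]),
        period,
    )


def write_ascii_grid(raster, path, nodata: float = -9999.0) -> None:
    values = np.asarray(raster.values, dtype=float).copy()
    values[~np.isfinite(values)] = nodata
    nrows, ncols = values.shape
    g = raster.grid
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {g.xll}\nyllcorner {g.yll}\n"
            f"cellsize {g.cellsize}\nNODATA_value {nodata}\n"
        )
        for row in values:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# TSS and threshold selection


def tss(
    raster: ProbabilityRaster,
    presences: np.ndarray,
    absences: np.ndarray,
    threshold: float,
) -> tuple[float, float, float]:
    """(sensitivity, specificity, TSS) at a threshold.

    A point predicts presence iff its cell's probability is strictly
    greater than the threshold.  Points on no-data cells are dropped; if
    none remain on either side, that's an input error.
    """
    pres = _values_at(raster, presences)
    absn = _values_at(raster, absences)
    pres = pres[np.isfinite(pres)]
    absn = absn[np.isfinite(absn)]
    if len(pres) == 0 or len(absn) == 0:
        raise DataError("all presence or absence points fall on no-data cells")
    sens = float((pres > threshold).mean())
    spec = float((absn <= threshold).mean())
    return sens, spec, sens + spec - 1.0


def _values_at(raster: ProbabilityRaster, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.array([raster.value_at(x, y) for x, y in pts])


DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass(frozen=True)
class ThresholdSelection:
    threshold: float
    grid: np.ndarray
    curves: np.ndarray  # (n_replicates, n_grid) TSS values
    median_curve: np.ndarray
    policy: str


def select_threshold(
    raster: ProbabilityRaster,
    occ: OccurrenceSet,
    grid: np.ndarray | None = None,
    policy: str = "max_tss",
    slope_cutoff: float = 0.02,
) -> ThresholdSelection:
    """Choose a binarization threshold from per-replicate TSS curves.

    ``max_tss``: per-replicate argmax (lowest grid value at the maximum),
    aggregated by the median across pseudo-absence replicates.
    ``lowest_before_steep_slope``: the smallest grid threshold at which
    the median TSS curve's forward difference first falls below
    ``slope_cutoff`` — the rationale behind picking the lowest usable
    threshold rather than the strict TSS maximizer.
    """
    if policy not in ("max_tss", "lowest_before_steep_slope"):
        raise ConfigError(f"unknown threshold policy {policy!r}")
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
    pres = _values_at(raster, occ.presences)
    pres = pres[np.isfinite(pres)]
    curves = np.zeros((len(occ.absence_replicates), len(grid)))
    for r, absent in enumerate(occ.absence_replicates):
        absn = _values_at(raster, absent)
        absn = absn[np.isfinite(absn)]
        if len(pres) == 0 or len(absn) == 0:
            raise DataError("all points on no-data cells")
        sens = (pres[None, :] > grid[:, None]).mean(axis=1)
        spec = (absn[None, :] <= grid[:, None]).mean(axis=1)
        curves[r] = sens + spec - 1.0
    median_curve = np.median(curves, axis=0)
    if policy == "max_tss":
        per_rep = grid[np.argmax(curves, axis=1)]
        chosen = float(np.median(per_rep))
    else:
        diffs = np.diff(median_curve)
        below = np.nonzero(diffs < slope_cutoff)[0]
        chosen = float(grid[below[0]]) if len(below) else float(grid[np.argmax(median_curve)])
    return ThresholdSelection(chosen, grid, curves, median_curve, policy)


# ---------------------------------------------------------------------------
# map algebra


def binarize(raster: ProbabilityRaster, threshold: float) -> BinaryMap:
    """Suitable iff probability strictly exceeds the threshold."""
    if not 0 <= threshold <= 1:
        raise ConfigError("threshold must be in [0, 1]")
    out = np.full(raster.shape, -1, dtype=np.int8)
    valid = np.isfinite(raster.values)
    out[valid] = (raster.values[valid] > threshold).astype(np.int8)
    return BinaryMap(out, raster.grid, threshold, raster.period)


def _check_aligned(a, b) -> None:
    if a.shape != b.shape or a.grid != b.grid:
        raise AlignmentError("rasters are not aligned (shape or geotransform differs)")


def shift_map(older: BinaryMap, recent: BinaryMap) -> ShiftMap:
    """Per-cell 2*recent - older: colonization 2, stability 1, absence 0,
    extinction -1; no-data where either input lacks data."""
    _check_aligned(older, recent)
    out = np.full(older.shape, ShiftMap.NODATA, dtype=np.int8)
    valid = (older.values >= 0) & (recent.values >= 0)
    out[valid] = 2 * recent.values[valid] - older.values[valid]
    return ShiftMap(out, older.grid, older.period, recent.period)


def stability_map(maps: list[BinaryMap]) -> BinaryMap:
    """Cell-wise product: suitable only where every period is suitable."""
    if len(maps) < 2:
        raise ConfigError("stability map needs at least 2 binary maps")
    for m in maps[1:]:
        _check_aligned(maps[0], m)
    stacked = np.stack([m.values for m in maps])
    valid = (stacked >= 0).all(axis=0)
    out = np.full(maps[0].shape, -1, dtype=np.int8)
    out[valid] = stacked[:, valid].prod(axis=0).astype(np.int8)
    return BinaryMap(out, maps[0].grid, maps[0].threshold,
                     "+".join(m.period for m in maps))


__all__ = [
    "CATEGORY_LABELS",
    "GridSpec",
    "ProbabilityRaster",
    "BinaryMap",
    "ShiftMap",
    "OccurrenceSet",
    "read_ascii_grid",
    "write_ascii_grid",
    "tss",
    "ThresholdSelection",
    "select_threshold",
    "binarize",
    "shift_map",
    "stability_map",
    "DEFAULT_THRESHOLD_GRID",
]
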