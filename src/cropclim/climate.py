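"""Half-degree gridded climate normals, area-weighted aggregation and scenario
CO2-concentration lookup."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RESOLUTION",
    "GridError",
    "MissingDataError",
    "ClimateGrid",
    "WeightGrid",
    "ScenarioTrajectory",
    "DEFAULT_CO2_TRAJECTORIES",
    "build_climatology",
    "extract_point",
    "area_weighted_mean",
    "co2_concentration",
    "precip_change_from_relative",
    "read_grid_csv",
    "write_grid_csv",
    "read_grid_netcdf",
]

RESOLUTION = 0.5

VARIABLES = ("annual_mean_temp_C", "annual_total_precip_mm")


class GridError(ValueError):
    pass


class MissingDataError(ValueError):
    """Requested cell holds no data (e.g. ocean mask)."""


def _check_axis(centers: np.ndarray, name: str) -> None:
    if centers.ndim != 1 or centers.size == 0:
        raise GridError(f"{name} axis must be a non-empty 1-D array")
    if centers.size > 1 and not np.allclose(np.diff(centers), RESOLUTION):
        raise GridError(f"{name} axis spacing must be {RESOLUTION} degrees")
    # half-degree cell centers sit at +-0.25 + k*0.5
    frac = np.mod(centers - 0.25, RESOLUTION)
    if not np.all(np.isclose(frac, 0.0) | np.isclose(frac, RESOLUTION)):
        raise GridError(f"{name} centers must follow the +-0.25 + k*0.5 convention")


@dataclass
class ClimateGrid:
    """A half-degree raster of one climate normal; NaN marks masked cells."""

    variable: str
    lats: np.ndarray  # cell centers, ascending
    lons: np.ndarray
    values: np.ndarray  # shape (nlat, nlon)
    period_label: str = ""

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.variable not in VARIABLES:
            raise GridError(f"unknown variable {self.variable!r}")
        _check_axis(self.lats, "lat")
        _check_axis(self.lons, "lon")
        if self.values.shape != (self.lats.size, self.lons.size):
            raise GridError(
                f"values shape {self.values.shape} != ({self.lats.size}, {self.lons.size})"
            )
        finite = self.values[np.isfinite(self.values)]
        if self.variable == "annual_mean_temp_C" and finite.size:
            if finite.min() < -90.0 or finite.max() > 60.0:
                raise GridError("temperatures outside [-90, 60] degC")
        if self.variable == "annual_total_precip_mm" and finite.size and finite.min() < 0:
            raise GridError("negative precipitation")

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Containing cell; points on a boundary resolve to the north-east cell."""
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise GridError(f"coordinates ({lat}, {lon}) out of range")
        south_edge = self.lats[0] - RESOLUTION / 2
        west_edge = self.lons[0] - RESOLUTION / 2
        i = int(np.floor((lat - south_edge) / RESOLUTION + 1e-9))
        j = int(np.floor((lon - west_edge) / RESOLUTION + 1e-9))
        if not (0 <= i < self.lats.size and 0 <= j < self.lons.size):
            raise GridError(f"point ({lat}, {lon}) outside grid extent")
        return i, j


@dataclass
class WeightGrid:
    """Harvested area (ha) per cell; geometry must match the paired ClimateGrid."""

    lats: np.ndarray
    lons: np.ndarray
    harvested_area: np.ndarray

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.harvested_area = np.asarray(self.harvested_area, dtype=float)
        _check_axis(self.lats, "lat")
        _check_axis(self.lons, "lon")
        if self.harvested_area.shape != (self.lats.size, self.lons.size):
            raise GridError("weight shape does not match axes")
        if np.nanmin(self.harvested_area) < 0:
            raise GridError("harvested areas must be non-negative")


@dataclass(frozen=True)
class ScenarioTrajectory:
    """Tabulated CO2 concentration trajectory for one emission scenario."""

    scenario: str
    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("need at least two points for interpolation")
        years = [y for y, _ in self.points]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        if any(ppm <= 0 for _, ppm in self.points):
            raise ValueError("concentrations must be positive")


# Approximate concentration anchors per scenario family, used by the synthetic
# generator and the CO2-ppm fallback when a study does not report ppm.
DEFAULT_CO2_TRAJECTORIES: Mapping[str, ScenarioTrajectory] = {
    "RCP2.6": ScenarioTrajectory("RCP2.6", ((2005, 379.0), (2050, 443.0), (2100, 421.0))),
    "RCP4.5": ScenarioTrajectory("RCP4.5", ((2005, 379.0), (2050, 487.0), (2100, 538.0))),
    "RCP6.0": ScenarioTrajectory("RCP6.0", ((2005, 379.0), (2050, 478.0), (2100, 670.0))),
    "RCP8.5": ScenarioTrajectory("RCP8.5", ((2005, 379.0), (2050, 541.0), (2100, 936.0))),
    "A2": ScenarioTrajectory("A2", ((2005, 379.0), (2050, 532.0), (2100, 856.0))),
    "A1B": ScenarioTrajectory("A1B", ((2005, 379.0), (2050, 532.0), (2100, 717.0))),
    "B1": ScenarioTrajectory("B1", ((2005, 379.0), (2050, 488.0), (2100, 538.0))),
}


def build_climatology(
    annual_fields: Sequence[np.ndarray],
    years: Sequence[int],
    window: tuple[int, int],
    lats: np.ndarray,
    lons: np.ndarray,
    variable: str,
) -> ClimateGrid:
    """Average annual fields over a window of years into one climate normal.

    ``annual_fields[k]`` is the annual mean (or total) field for ``years[k]``.
    """
    if len(annual_fields) != len(years):
        raise GridError("one field per year required")
    start, end = window
    if start < min(years) or end > max(years):
        raise GridError(f"window {window} outside series coverage {min(years)}-{max(years)}")
    selected = [np.asarray(f, dtype=float) for f, y in zip(annual_fields, years) if start <= y <= end]
    stack = np.stack(selected, axis=0)
    return ClimateGrid(
        variable=variable,
        lats=lats,
        lons=lons,
        values=stack.mean(axis=0),
        period_label=f"{start}-{end}",
    )


def extract_point(grid: ClimateGrid, lat: float, lon: float) -> float:
    """Value of the half-degree cell containing the point."""
    i, j = grid.cell_index(lat, lon)
    v = grid.values[i, j]
    if not np.isfinite(v):
        raise MissingDataError(f"cell ({grid.lats[i]}, {grid.lons[j]}) holds no data")
    return float(v)


def area_weighted_mean(grid: ClimateGrid, weights: WeightGrid, mask: np.ndarray) -> float:
    """Harvested-area weighted mean of grid values over the masked cells."""
    if weights.harvested_area.shape != grid.values.shape:
        raise GridError("weight geometry does not match grid")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.values.shape:
        raise GridError("mask geometry does not match grid")
    if not mask.any():
        raise GridError("mask selects no cells")
    w = weights.harvested_area[mask]
    v = grid.values[mask]
    if not np.all(np.isfinite(v)):
        raise MissingDataError("mask covers cells with no data")
    total = w.sum()
    if total <= 0:
        raise GridError("total weight over mask is zero")
    return float((w * v).sum() / total)


def co2_concentration(trajectory: ScenarioTrajectory, year: float) -> float:
    """Concentration at a year: exact at tabulated years, linear in between.

    No extrapolation: years outside the tabulated span raise ``ValueError``.
    """
    years = np.array([y for y, _ in trajectory.points], dtype=float)
    ppm = np.array([c for _, c in trajectory.points], dtype=float)
    if year < years[0] or year > years[-1]:
        raise ValueError(f"year {year} outside trajectory span {years[0]}-{years[-1]}")
    return float(np.interp(year, years, ppm))


def precip_change_from_relative(rel_change_pct: float, Pr_base: float) -> float:
    """Absolute precipitation change (mm) from a relative change and a base level."""
    if Pr_base < 0:
        raise ValueError("baseline precipitation must be non-negative")
    return rel_change_pct / 100.0 * Pr_base


# ---------------------------------------------------------------------------
# raster I/O: plain-text CSV fixtures and a CF-style netCDF adapter


def write_grid_csv(grid: ClimateGrid, path) -> Path:
    """Write a raster as CSV: first column lat centers, header row lon centers."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["lat/lon"] + [repr(x) for x in grid.lons.tolist()])
        for i, lat in enumerate(grid.lats.tolist()):
            writer.writerow([repr(lat)] + [repr(v) for v in grid.values[i].tolist()])
    return path


def read_grid_csv(path, variable: str, period_label: str = "") -> ClimateGrid:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    lons = np.array([float(x) for x in rows[0][1:]])
    lats = np.array([float(r[0]) for r in rows[1:]])
    values = np.array([[float(x) if x != "" else np.nan for x in r[1:]] for r in rows[1:]])
    return ClimateGrid(variable=variable, lats=lats, lons=lons, values=values, period_label=period_label)


def read_grid_netcdf(path, var_name: str, variable: str, lat_name: str = "lat", lon_name: str = "lon"):
    """Adapter for CF-style lat/lon netCDF rasters (W5E5/MIRCA-like products).

    Requires an xarray-compatible backend at call time; test fixtures use the
    CSV raster format instead.
    """
    import xarray as xr  # deferred: only needed for real-product ingestion

    ds = xr.open_dataset(path)
    da = ds[var_name]
    lats = np.asarray(da[lat_name].values, dtype=float)
    lons = np.asarray(da[lon_name].values, dtype=float)
    values = np.asarray(da.values, dtype=float)
    if lats[0] > lats[-1]:  # store south-to-north
        lats, values = lats[::-1], values[::-1]
    return ClimateGrid(variable=variable, lats=lats, lons=lons, values=values)
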