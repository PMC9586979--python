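"""Site-level E_c-to-ET ratios against a 1-km gridded ET product.

Canopy transpiration of the dominant vegetation (E_c) is compared with
total evapotranspiration (ET) of the 1-km grid cell containing each site.
ET is read either from the focal cell alone or as the unweighted mean of
the focal cell and its Moore neighborhood (up to 9 cells), excluding
cells flagged as open water and cells beyond the grid edge. The
"potential" scenario inflates the mean ratio by the relative dispersion
of leaf-level WUE_int along salinity gradients (default 32% of the mean),
approximating how much more water the canopy could move if porewater
freshened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ETRaster",
    "RatioResult",
    "extract_et",
    "ec_et_ratio",
    "potential_ratio",
    "summarize_ratios",
    "project_sites",
]


@dataclass
class ETRaster:
    """Annual ET on a regular 1-km grid with an open-water mask.

    ``values`` are mm H2O yr^-1, row-major with the grid origin at the
    north-west corner; ``water_mask`` is True over open water (those
    cells never contribute to a site's ET).
    """

    values: np.ndarray
    water_mask: np.ndarray
    cell_size_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)  # (lat, lon) of NW corner

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("ET grid must be 2-D")
        if self.values.shape != self.water_mask.shape:
            raise ValueError("ET grid and water mask shapes differ")
        if np.any(self.values[~self.water_mask] <= 0):
            raise ValueError("unmasked ET values must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def latlon_to_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """Nearest cell for a point, from the NW origin (1 km ~ 1/111 deg)."""
        deg_per_cell = self.cell_size_km / 111.0
        row = int(round((self.origin[0] - lat) / deg_per_cell))
        col = int(round((lon - self.origin[1]) / deg_per_cell))
        return row, col

    def to_csv(self, values_path, mask_path) -> None:
        np.savetxt(values_path, self.values, fmt="%.6f", delimiter=",")
        np.savetxt(mask_path, self.water_mask.astype(int), fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, values_path, mask_path=None, **kwargs) -> "ETRaster":
        values = np.loadtxt(values_path, delimiter=",", ndmin=2)
        if mask_path is not None and Path(mask_path).exists():
            mask = np.loadtxt(mask_path, delimiter=",", ndmin=2).astype(bool)
        else:
            mask = np.zeros_like(values, dtype=bool)
        return cls(values=values, water_mask=mask, **kwargs)


@dataclass(frozen=True)
class RatioResult:
    """E_c-to-ET comparison for one site."""

    site: str
    ec: float  # mm yr^-1
    et: float  # mm yr^-1
    ratio_pct: float
    neighborhood_cells_used: int

    def __post_init__(self) -> None:
        if self.et <= 0:
            raise ValueError("et must be > 0")
        if self.ratio_pct < 0:
            raise ValueError("ratio_pct must be >= 0")
        if not 1 <= self.neighborhood_cells_used <= 9:
            raise ValueError("cells_used must be in 1..9")


def extract_et(
    raster: ETRaster, site_cell: tuple[int, int], neighborhood: int = 1
) -> tuple[float, int]:
    """ET for a site cell, optionally averaged over its Moore neighborhood.

    ``neighborhood=1`` returns the focal cell's value; ``neighborhood=9``
    averages the focal cell with its up-to-8 neighbors, dropping water-
    masked and out-of-bounds cells. Returns ``(et_mm_yr, cells_used)``.
    Raises ``ValueError`` if the focal cell is out of bounds or over water.
    """
    if neighborhood not in (1, 9):
        raise ValueError("neighborhood must be 1 or 9")
    r, c = site_cell
    nrow, ncol = raster.shape
    if not (0 <= r < nrow and 0 <= c < ncol):
        raise ValueError(f"site cell {site_cell} out of bounds for grid {raster.shape}")
    if raster.water_mask[r, c]:
        raise ValueError(f"no land cell: focal cell {site_cell} is over water")
    if neighborhood == 1:
        return float(raster.values[r, c]), 1
    vals = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and not raster.water_mask[rr, cc]:
                vals.append(raster.values[rr, cc])
    return float(np.mean(vals)), len(vals)


def ec_et_ratio(ec: float, et: float) -> float:
    """Canopy-transpiration share of evapotranspiration, percent."""
    if et <= 0:
        raise ValueError("invalid denominator: et must be > 0")
    if ec < 0:
        raise ValueError("ec must be >= 0")
    return 100.0 * ec / et


def potential_ratio(mean_ratio: float, sd_fraction: float = 0.32) -> float:
    """Low-salinity "potential" ratio: mean inflated by the relative SD.

    The relative dispersion of leaf WUE_int along salinity gradients
    (SD/mean, default 0.32) is rescaled onto E_c and added to the mean,
    i.e. ``mean_ratio * (1 + sd_fraction)``.
    """
    if mean_ratio <= 0:
        raise ValueError("mean_ratio must be > 0")
    if sd_fraction < 0:
        raise ValueError("sd_fraction must be >= 0")
    return mean_ratio * (1.0 + sd_fraction)


def summarize_ratios(results: Iterable[RatioResult | float]) -> tuple[float, float]:
    """Mean and standard error (sd/sqrt(n)) of site E_c/ET ratios, percent."""
    ratios = np.asarray(
        [r.ratio_pct if isinstance(r, RatioResult) else float(r) for r in results],
        dtype=float,
    )
    if ratios.size < 2:
        raise ValueError("need >= 2 ratios for a mean with standard error")
    return float(ratios.mean()), float(ratios.std(ddof=1) / np.sqrt(ratios.size))


def project_sites(
    sites: pd.DataFrame,
    raster: ETRaster,
    neighborhood: int = 1,
    ec_column: str = "ec_mm_yr",
) -> list[RatioResult]:
    """E_c/ET ratios for a site table against a gridded ET product.

    ``sites`` needs a site label, an E_c column (mm yr^-1) and either
    (``row``, ``col``) grid indices or (``lat``, ``lon``) coordinates.
    """
    out = []
    for rec in sites.itertuples():
        if hasattr(rec, "row") and hasattr(rec, "col"):
            cell = (int(rec.row), int(rec.col))
        else:
            cell = raster.latlon_to_cell(float(rec.lat), float(rec.lon))
        et, used = extract_et(raster, cell, neighborhood=neighborhood)
        ec = float(getattr(rec, ec_column))
        out.append(
            RatioResult(
                site=str(rec.site),
                ec=ec,
                et=et,
                ratio_pct=ec_et_ratio(ec, et),
                neighborhood_cells_used=used,
            )
        )
    return out
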