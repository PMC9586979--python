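"""Leaf-level water-use efficiency from gas-exchange measurements.

Two efficiencies are in routine use for mangrove leaves:

* intrinsic water-use efficiency, ``WUE_int = P_n / g_w``
  [umol CO2 (mol H2O)^-1] — net photosynthesis over stomatal conductance;
  for mangroves it rises approximately linearly with porewater salinity.
* instantaneous water-use efficiency, ``WUE_ins = P_n / T_r``
  [mmol CO2 (mol H2O)^-1] — net photosynthesis over leaf transpiration.

With P_n in umol CO2 m^-2 s^-1, g_w in mol H2O m^-2 s^-1 and T_r in
mmol H2O m^-2 s^-1, both ratios land on the stated output units with a
conversion factor of exactly 1 (umol/mmol = mmol/mol); no hidden 10^3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GasExchangeRecord",
    "WUESummary",
    "SalinityResponse",
    "wue_int",
    "wue_ins",
    "summarize",
    "fit_salinity_response",
    "load_gas_exchange",
]

logger = logging.getLogger(__name__)

#: column layout of a leaf gas-exchange CSV
GASEX_COLUMNS = [
    "species",
    "site",
    "salinity_psu",
    "pn_umol_m2_s",
    "gw_mol_m2_s",
    "tr_mmol_m2_s",
    "ci_ul_l",
]


class InvalidRecordError(ValueError):
    """A gas-exchange record violates a precondition (e.g. g_w <= 0)."""


@dataclass(frozen=True)
class GasExchangeRecord:
    """One leaf-level measurement.

    Parameters
    ----------
    species, site
        Free-text labels.
    salinity
        Porewater salinity at the time of measurement, psu.
    p_n
        Net photosynthesis, umol CO2 m^-2 s^-1.
    g_w
        Stomatal conductance to water vapour, mol H2O m^-2 s^-1.
    t_r
        Leaf transpiration, mmol H2O m^-2 s^-1 (optional; required only
        for instantaneous WUE).
    c_i
        Intercellular CO2 concentration, ul l^-1 (optional, carried but
        unused by the WUE math).
    """

    species: str
    site: str
    salinity: float
    p_n: float
    g_w: float
    t_r: float | None = None
    c_i: float | None = None

    def __post_init__(self) -> None:
        if self.salinity < 0 or not math.isfinite(self.salinity):
            raise InvalidRecordError(f"salinity must be finite and >= 0, got {self.salinity}")


@dataclass(frozen=True)
class WUESummary:
    """Distributional summary of a WUE sample (units of the input)."""

    n: int
    mean: float
    median: float
    sd: float
    q1: float
    q3: float
    sd_over_mean: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _as_pn_gw(record_or_pn, g_w=None):
    if g_w is None:
        rec: GasExchangeRecord = record_or_pn
        return rec.p_n, rec.g_w
    return record_or_pn, g_w


def wue_int(record_or_pn, g_w=None):
    """Intrinsic water-use efficiency P_n / g_w, umol CO2 (mol H2O)^-1.

    Accepts either a :class:`GasExchangeRecord` or ``(p_n, g_w)`` scalars
    or arrays. Raises :class:`InvalidRecordError` if any g_w is
    non-positive or non-finite.
    """
    p_n, g = _as_pn_gw(record_or_pn, g_w)
    p_n = np.asarray(p_n, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(~np.isfinite(g)) or np.any(g <= 0):
        raise InvalidRecordError("stomatal conductance g_w must be finite and > 0")
    out = p_n / g
    return float(out) if out.ndim == 0 else out


def wue_ins(record_or_pn, t_r=None):
    """Instantaneous water-use efficiency P_n / T_r, mmol CO2 (mol H2O)^-1.

    Unit chain: P_n [umol CO2] / T_r [mmol H2O] = mmol CO2 / mol H2O with
    factor 1. Raises :class:`InvalidRecordError` when T_r is missing or
    non-positive.
    """
    if t_r is None:
        rec: GasExchangeRecord = record_or_pn
        p_n, t = rec.p_n, rec.t_r
    else:
        p_n, t = record_or_pn, t_r
    if t is None:
        raise InvalidRecordError("record has no leaf transpiration t_r")
    p_n = np.asarray(p_n, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise InvalidRecordError("leaf transpiration t_r must be finite and > 0")
    out = p_n / t
    return float(out) if out.ndim == 0 else out


def summarize(values: Iterable[float]) -> WUESummary:
    """Summarize a WUE sample: mean, median, quartiles, SD and SD/mean.

    Quantiles use linear interpolation between order statistics (the
    type-7 rule; the median of an even-length sample is the mean of the
    two central values). SD is the sample standard deviation (n-1
    denominator); a singleton sample reports SD 0. ``sd_over_mean`` is
    populated when the mean is positive, else NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no data: cannot summarize an empty sample")
    if np.any(~np.isfinite(arr)):
        raise ValueError("non-finite value in sample")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.quantile(arr, [0.25, 0.5, 0.75]))
    som = sd / mean if mean > 0 else float("nan")
    return WUESummary(n=int(arr.size), mean=mean, median=med, sd=sd, q1=q1, q3=q3, sd_over_mean=som)


@dataclass(frozen=True)
class SalinityResponse:
    """OLS fit of WUE_int on salinity (Results-style container).

    slope is in umol CO2 (mol H2O)^-1 psu^-1.
    """

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    se_slope: float
    n: int

    def predict(self, salinity):
        return self.intercept + self.slope * np.asarray(salinity, dtype=float)

    def summary(self) -> str:
        return (
            "WUE_int ~ salinity (OLS)\n"
            f"  n          {self.n}\n"
            f"  slope      {self.slope:.4f} +/- {self.se_slope:.4f} umol mol^-1 psu^-1"
            f"  (p = {self.p_slope:.3g})\n"
            f"  intercept  {self.intercept:.4f} umol mol^-1\n"
            f"  r^2        {self.r_squared:.4f}"
        )


def fit_salinity_response(
    salinity: Sequence[float], wue: Sequence[float] | None = None
) -> SalinityResponse:
    """Fit WUE_int against salinity by ordinary least squares.

    Accepts either a DataFrame with ``salinity_psu``, ``pn_umol_m2_s``
    and ``gw_mol_m2_s`` columns, or two aligned sequences
    ``(salinity, wue_int)``. Requires >= 3 records spanning at least two
    distinct salinities; an all-equal salinity design raises
    ``ValueError`` (singular fit).
    """
    if wue is None:
        df = salinity
        s = df["salinity_psu"].to_numpy(dtype=float)
        w = wue_int(df["pn_umol_m2_s"].to_numpy(), df["gw_mol_m2_s"].to_numpy())
    else:
        s = np.asarray(salinity, dtype=float)
        w = np.asarray(wue, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 records to fit a salinity response")
    if np.unique(s).size < 2:
        raise ValueError("singular fit: all salinities identical")
    res = sm.OLS(w, sm.add_constant(s)).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)
    return SalinityResponse(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=r2 if math.isfinite(r2) else 0.0,
        p_slope=float(res.pvalues[1]),
        se_slope=float(res.bse[1]),
        n=int(s.size),
    )


def load_gas_exchange(path) -> pd.DataFrame:
    """Read a leaf gas-exchange CSV (columns of :data:`GASEX_COLUMNS`).

    Optional columns (t_r, c_i) may be empty. Rows with missing required
    fields are dropped with a logged count.
    """
    df = pd.read_csv(path)
    missing = [c for c in GASEX_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"gas-exchange file lacks required columns: {missing}")
    for c in GASEX_COLUMNS[5:]:
        if c not in df.columns:
            df[c] = np.nan
    n0 = len(df)
    df = df.dropna(subset=GASEX_COLUMNS[2:5])
    if len(df) < n0:
        logger.info("dropped %d incomplete gas-exchange records", n0 - len(df))
    return df[GASEX_COLUMNS].reset_index(drop=True)
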