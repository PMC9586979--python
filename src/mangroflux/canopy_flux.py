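"""Canopy transpiration (E_c) <-> net primary productivity (NPP) scaling.

The bridge between water and carbon at the canopy scale is instantaneous
water-use efficiency: each mm of transpired water (1 mm = 1 L m^-2 =
55.51 mol H2O m^-2) fixes ``WUE_ins`` mmol CO2 per mol H2O, which converts
through the CO2 molar mass and a carbon fraction of 0.273 kg C per kg CO2
into kg C m^-2. The calibrated linear model

    E_c = 384.59 * NPP + 33.56        [mm H2O yr^-1; NPP in kg C m^-2 yr^-1]

projects canopy transpiration onto sites where only productivity is known.
Sap-flow records provide the per-tree analogue: water use scales linearly
with stem diameter (dbh), and the slope (L day^-1 cm^-1) is the tree-level
water-use intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SpeciesWUE",
    "StandComposition",
    "EcNppModel",
    "EcNppFit",
    "UnitConstants",
    "EQ1_MODEL",
    "stand_wue",
    "npp_from_ec",
    "ec_from_npp",
    "fit_ec_npp",
    "fit_sapflow_per_dbh",
    "nee_cross_check",
    "efflux_adjust",
    "load_species_wue",
]


@dataclass(frozen=True)
class SpeciesWUE:
    """Light-saturated leaf WUE_ins for one species, mmol CO2 (mol H2O)^-1."""

    species: str
    wue_ins: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.wue_ins <= 0:
            raise ValueError("wue_ins must be > 0")


@dataclass(frozen=True)
class StandComposition:
    """Species mix of a stand as basal-area fractions (normalized to 1)."""

    entries: tuple[tuple[str, float], ...]

    def __init__(self, entries: Iterable[tuple[str, float]]):
        entries = tuple((str(s), float(f)) for s, f in entries)
        if not entries:
            raise ValueError("empty stand composition")
        if any(f < 0 for _, f in entries):
            raise ValueError("basal-area fractions must be >= 0")
        total = sum(f for _, f in entries)
        if total <= 0:
            raise ValueError("basal-area fractions sum to zero")
        object.__setattr__(self, "entries", tuple((s, f / total) for s, f in entries))


@dataclass(frozen=True)
class EcNppModel:
    """Linear canopy-transpiration model E_c = slope * NPP + intercept."""

    slope: float  # mm H2O yr^-1 per (kg C m^-2 yr^-1)
    intercept: float  # mm H2O yr^-1

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")

    def predict(self, npp):
        return self.slope * np.asarray(npp, dtype=float) + self.intercept


#: the calibrated model with its published coefficients
EQ1_MODEL = EcNppModel(slope=384.59, intercept=33.56)


@dataclass(frozen=True)
class EcNppFit:
    """OLS calibration of E_c on NPP with fit diagnostics."""

    model: EcNppModel
    r_squared: float
    p_slope: float
    se_slope: float
    n: int

    def predict(self, npp):
        return self.model.predict(npp)

    def summary(self) -> str:
        return (
            "E_c ~ NPP (OLS)\n"
            f"  n          {self.n}\n"
            f"  slope      {self.model.slope:.4f} +/- {self.se_slope:.4f} mm yr^-1 per kg C m^-2 yr^-1"
            f"  (p = {self.p_slope:.3g})\n"
            f"  intercept  {self.model.intercept:.4f} mm yr^-1\n"
            f"  r^2        {self.r_squared:.4f}"
        )


@dataclass(frozen=True)
class UnitConstants:
    """Molar/mass constants of the water-to-carbon unit chain.

    ``c_fraction`` is kept at the conventional rounded 0.273 kg C per kg
    CO2 (not 12.011/44.01) so that published arithmetic reproduces
    exactly. 1 mm of water over 1 m^2 is 1 L, i.e. 1000/18.015 = 55.51
    mol H2O.
    """

    molar_mass_h2o: float = 18.015  # g mol^-1
    molar_mass_co2: float = 44.01  # g mol^-1
    c_fraction: float = 0.273  # kg C per kg CO2
    mm_to_mol_h2o_per_m2: float = 55.51  # mol H2O m^-2 per mm

    def __post_init__(self) -> None:
        if abs(self.mm_to_mol_h2o_per_m2 - 1000.0 / self.molar_mass_h2o) > 0.01:
            raise ValueError("mm_to_mol_h2o_per_m2 inconsistent with molar_mass_h2o")


DEFAULT_CONSTANTS = UnitConstants()


def stand_wue(comp: StandComposition, table: Sequence[SpeciesWUE]) -> float:
    """Basal-area-weighted stand WUE_ins, mmol CO2 (mol H2O)^-1."""
    lookup = {t.species: t.wue_ins for t in table}
    missing = [s for s, _ in comp.entries if s not in lookup]
    if missing:
        raise KeyError(f"species missing from WUE table: {missing}")
    return float(sum(f * lookup[s] for s, f in comp.entries))


def npp_from_ec(ec, wue: float, constants: UnitConstants = DEFAULT_CONSTANTS):
    """Convert canopy transpiration to NPP through the WUE_ins unit chain.

    NPP [kg C m^-2 yr^-1] = ec [mm] * 55.51 [mol H2O mm^-1 m^-2]
    * (wue/1000) [mol CO2 / mol H2O] * 44.01 [g CO2 mol^-1] * 0.273 / 1000.
    """
    ec_arr = np.asarray(ec, dtype=float)
    if np.any(ec_arr < 0):
        raise ValueError("canopy transpiration must be >= 0")
    out = (
        ec_arr
        * constants.mm_to_mol_h2o_per_m2
        * (wue / 1000.0)
        * constants.molar_mass_co2
        * constants.c_fraction
        / 1000.0
    )
    return float(out) if out.ndim == 0 else out


def ec_from_npp(npp, model: EcNppModel = EQ1_MODEL):
    """Canopy transpiration (mm H2O yr^-1) from NPP via the linear model."""
    npp_arr = np.asarray(npp, dtype=float)
    if np.any(npp_arr < 0):
        raise ValueError("NPP must be >= 0")
    out = model.predict(npp_arr)
    return float(out) if out.ndim == 0 else out


def fit_ec_npp(pairs: Iterable[tuple[float, float]]) -> EcNppFit:
    """Calibrate the E_c ~ NPP line by OLS on (npp, ec) pairs.

    Requires >= 3 pairs with at least two distinct NPP values.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (npp, ec) pairs")
    npp, ec = arr[:, 0], arr[:, 1]
    if np.unique(npp).size < 2:
        raise ValueError("degenerate fit: all NPP values identical")
    res = sm.OLS(ec, sm.add_constant(npp)).fit()
    model = EcNppModel(slope=float(res.params[1]), intercept=float(res.params[0]))
    return EcNppFit(
        model=model,
        r_squared=float(res.rsquared),
        p_slope=float(res.pvalues[1]),
        se_slope=float(res.bse[1]),
        n=int(arr.shape[0]),
    )


def fit_sapflow_per_dbh(records: Iterable[tuple[float, float]]) -> float:
    """Per-dbh water-use intensity (L day^-1 cm^-1) from sap-flow records.

    OLS slope of individual tree water use on dbh; for exactly two points
    this equals the finite-difference slope. Display convention for
    reporting is two decimals, round-half-even.
    """
    arr = np.asarray(list(records), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (dbh, water_use) records")
    dbh, wu = arr[:, 0], arr[:, 1]
    if np.unique(dbh).size < 2:
        raise ValueError("degenerate fit: all dbh values identical")
    res = sm.OLS(wu, sm.add_constant(dbh)).fit()
    return float(res.params[1])


def nee_cross_check(npp_predicted: float, npp_flux_derived: float) -> tuple[float, float]:
    """Deviation of WUE-chain NPP from a flux-tower-derived NPP.

    Returns (absolute deviation, deviation relative to the predicted
    value), both in the input units.
    """
    if npp_predicted <= 0:
        raise ValueError("npp_predicted must be > 0")
    abs_dev = abs(npp_predicted - npp_flux_derived)
    return abs_dev, abs_dev / npp_predicted


def efflux_adjust(gross_c: float, efflux: float) -> float:
    """Subtract soil/pneumatophore CO2 efflux from a gross carbon flux.

    Both arguments in kg C m^-2 over the caller's accounting period.
    A negative result is returned as-is (the caller decides whether a
    net-heterotrophic period is an error).
    """
    if gross_c < 0 or efflux < 0:
        raise ValueError("carbon fluxes must be >= 0")
    return gross_c - efflux


def load_species_wue(path=None) -> list[SpeciesWUE]:
    """Load a species WUE_ins table (CSV: species, wue_ins_mmol_mol, se).

    Without a path, loads the packaged table of light-saturated values
    for the three dominant neotropical mangroves.
    """
    if path is None:
        path = resources.files("mangroflux.data").joinpath("species_wue.csv")
    df = pd.read_csv(path)
    return [
        SpeciesWUE(species=r.species, wue_ins=float(r.wue_ins_mmol_mol), se=float(r.se))
        for r in df.itertuples()
    ]
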