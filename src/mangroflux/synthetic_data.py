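"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis consumes literature-derived tables (leaf
gas-exchange records, a 71-site NPP table, a 1-km ET grid, sap-flow
records). This module generates stand-ins for all of them so the whole
pipeline runs and is testable offline:

* leaf records — salinity uniform on 10-49 psu; WUE_int linear in
  salinity with Gaussian noise scaled so the realized SD/mean matches a
  target relative dispersion (default 0.32); P_n and g_w consistent with
  the drawn WUE_int, T_r consistent with a configurable WUE_ins.
* site table — two regions (Florida-Caribbean / Asia-Pacific, default
  24/47 of 71 sites) with positive litter/wood/root NPP components whose
  total stays in a plausible 0.2-2.5 kg C m^-2 yr^-1 band.
* ET grid — values ~ Normal(1172, sd) truncated positive, with a
  Boolean open-water mask.
* sap-flow — tree water use linear in dbh with Gaussian noise, floored
  at zero.

One integer seed drives everything through a fixed SeedSequence spawn
order (leaf=0, sites=1, raster=2, sapflow=3), so a manifest of
(config, seed) reproduces every file byte-identically. CSVs are written
with 6-decimal floats.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .et_comparison import ETRaster
from .leaf_gas_exchange import GASEX_COLUMNS

__all__ = [
    "GeneratorConfig",
    "gen_leaf_gas_exchange",
    "gen_site_table",
    "gen_et_raster",
    "gen_sapflow",
    "write_all",
]

_SPECIES = [
    "Avicennia germinans",
    "Laguncularia racemosa",
    "Rhizophora mangle",
    "Avicennia marina",
    "Bruguiera gymnorhiza",
    "Sonneratia alba",
]

# stream indices of the SeedSequence spawn; order is part of the format
_STREAMS = {"leaf": 0, "sites": 1, "raster": 2, "sapflow": 3, "placement": 4}


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating parameters for all synthetic inputs.

    Defaults mirror the study conditions the pipeline assumes: salinity
    10-49 psu, mean WUE_int 67 umol mol^-1 with SD 32% of the mean,
    ET mean 1172 mm yr^-1, and a sap-flow slope of 1.4 L day^-1 cm^-1
    (the mangrove average; 3.5 is the upland-tree value).
    """

    seed: int = 0
    n_sites: int = 71
    n_leaf_records: int = 200
    salinity_range: tuple[float, float] = (10.0, 49.0)
    wue_mean: float = 67.0  # umol CO2 (mol H2O)^-1
    wue_sd_fraction: float = 0.32
    wue_salinity_slope: float = 55.0 / 39.0  # umol mol^-1 psu^-1: ~40 at 10 psu, ~95 at 49
    wue_ins: float = 4.57  # mmol CO2 (mol H2O)^-1, sets T_r from P_n
    et_mean: float = 1172.0  # mm yr^-1
    et_sd: float = 150.0
    water_fraction: float = 0.2
    sapflow_slope: float = 1.4  # L day^-1 cm^-1
    sapflow_noise_sd: float = 2.0  # L day^-1
    region_split: tuple[int, int] = (24, 47)  # Florida-Caribbean : Asia-Pacific

    def __post_init__(self) -> None:
        lo, hi = self.salinity_range
        if not (0 <= lo <= hi <= 90):
            raise ValueError("salinity_range must lie within [0, 90]")
        if self.wue_sd_fraction < 0:
            raise ValueError("wue_sd_fraction must be >= 0")
        if not 0 <= self.water_fraction < 1:
            raise ValueError("water_fraction must be in [0, 1)")
        if self.n_sites <= 0 or self.n_leaf_records <= 0:
            raise ValueError("counts must be > 0")
        for name in ("wue_mean", "wue_ins", "et_mean", "et_sd", "sapflow_slope", "sapflow_noise_sd"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.wue_mean <= 0 or self.wue_ins <= 0 or self.et_mean <= 0:
            raise ValueError("wue_mean, wue_ins and et_mean must be > 0")
        if self.et_sd < 0 or self.sapflow_noise_sd < 0:
            raise ValueError("spread parameters must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for a named stream (fixed spawn order)."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


def _wue_line(config: GeneratorConfig) -> tuple[float, float]:
    """(intercept, slope) of the WUE_int-salinity line, centred on wue_mean."""
    lo, hi = config.salinity_range
    mid = 0.5 * (lo + hi)
    b = config.wue_salinity_slope
    return config.wue_mean - b * mid, b


def gen_leaf_gas_exchange(config: GeneratorConfig) -> pd.DataFrame:
    """Leaf gas-exchange records with WUE_int linear in salinity.

    The residual SD is chosen so that the *total* dispersion (salinity
    trend plus noise) targets ``wue_sd_fraction`` of the mean: with
    salinity uniform on (lo, hi), var_total = b^2 (hi-lo)^2/12 + sigma^2.
    If the trend alone exceeds the target the noise is zero. P_n/g_w
    equals the drawn WUE_int exactly; T_r = P_n / wue_ins.
    """
    rng = config.rng("leaf")
    n = config.n_leaf_records
    lo, hi = config.salinity_range
    a, b = _wue_line(config)
    salinity = rng.uniform(lo, hi, size=n)
    target_var = (config.wue_sd_fraction * config.wue_mean) ** 2
    trend_var = b**2 * (hi - lo) ** 2 / 12.0
    sigma = math.sqrt(max(target_var - trend_var, 0.0))
    wue = a + b * salinity + rng.normal(0.0, sigma, size=n) if sigma > 0 else a + b * salinity
    wue = np.clip(wue, 1.0, None)  # physically positive
    g_w = rng.uniform(0.1, 0.5, size=n)  # mol H2O m^-2 s^-1
    p_n = wue * g_w
    t_r = p_n / config.wue_ins  # mmol H2O m^-2 s^-1
    c_i = rng.uniform(150.0, 350.0, size=n)
    df = pd.DataFrame(
        {
            "species": rng.choice(_SPECIES, size=n),
            "site": [f"site-{i % config.n_sites:03d}" for i in range(n)],
            "salinity_psu": salinity,
            "pn_umol_m2_s": p_n,
            "gw_mol_m2_s": g_w,
            "tr_mmol_m2_s": t_r,
            "ci_ul_l": c_i,
        }
    )
    return df[GASEX_COLUMNS]


def gen_site_table(config: GeneratorConfig) -> pd.DataFrame:
    """Mangrove study sites with NPP components across two regions.

    Regions split proportionally to ``region_split`` (24:47 by default).
    Total NPP is drawn from a truncated Normal(1.0, 0.35) clipped into
    the 0.2-2.5 kg C m^-2 yr^-1 band and partitioned into litter, wood
    and root components with a jittered 40/35/25 mix.
    """
    if config.n_sites < 2:
        raise ValueError("need n_sites >= 2 to cover both regions")
    rng = config.rng("sites")
    n = config.n_sites
    w24, w47 = config.region_split
    n_fc = max(1, round(n * w24 / (w24 + w47)))
    n_ap = n - n_fc
    regions = ["Florida-Caribbean"] * n_fc + ["Asia-Pacific"] * n_ap
    total = np.clip(rng.normal(1.0, 0.35, size=n), 0.2, 2.5)
    mix = rng.dirichlet([40.0, 35.0, 25.0], size=n)
    litter, wood, root = (total * mix[:, k] for k in range(3))
    lat = np.where(
        np.arange(n) < n_fc, rng.uniform(9.0, 27.0, n), rng.uniform(-25.0, 25.0, n)
    )
    lon = np.where(
        np.arange(n) < n_fc, rng.uniform(-88.0, -60.0, n), rng.uniform(95.0, 155.0, n)
    )
    return pd.DataFrame(
        {
            "site": [f"site-{i:03d}" for i in range(n)],
            "region": regions,
            "lat": lat,
            "lon": lon,
            "salinity_psu": rng.uniform(*config.salinity_range, size=n),
            "npp_litter": litter,
            "npp_wood": wood,
            "npp_root": root,
            "npp_total": litter + wood + root,
        }
    )


def gen_et_raster(config: GeneratorConfig, rows: int, cols: int) -> ETRaster:
    """A rows x cols annual-ET grid with an open-water mask.

    Values are Normal(et_mean, et_sd) redrawn until positive (truncation
    by resampling); with et_sd = 0 every land cell is exactly et_mean.
    Approximately ``water_fraction`` of cells are masked as water.
    """
    if rows < 3 or cols < 3:
        raise ValueError("grid must be at least 3x3 for neighborhood extraction")
    rng = config.rng("raster")
    vals = rng.normal(config.et_mean, config.et_sd, size=(rows, cols))
    while np.any(vals <= 0):
        bad = vals <= 0
        vals[bad] = rng.normal(config.et_mean, config.et_sd, size=int(bad.sum()))
    mask = rng.random(size=(rows, cols)) < config.water_fraction
    if mask.all():  # keep at least one land cell
        mask[rows // 2, cols // 2] = False
    return ETRaster(values=vals, water_mask=mask)


def gen_sapflow(
    config: GeneratorConfig, dbh_range: tuple[float, float] = (4.0, 45.0), n: int = 200
) -> pd.DataFrame:
    """Sap-flow records: water use linear in dbh, Gaussian noise, floored at 0."""
    lo, hi = dbh_range
    if lo <= 0 or hi <= lo:
        raise ValueError("dbh_range must be positive and increasing")
    if n < 3:
        raise ValueError("need n >= 3 sap-flow records")
    rng = config.rng("sapflow")
    dbh = rng.uniform(lo, hi, size=n)
    wu = config.sapflow_slope * dbh + rng.normal(0.0, config.sapflow_noise_sd, size=n)
    return pd.DataFrame({"dbh_cm": dbh, "water_use_l_day": np.maximum(wu, 0.0)})


def write_all(config: GeneratorConfig, outdir, raster_shape: tuple[int, int] = (30, 30)) -> dict:
    """Generate every input file into ``outdir`` plus a manifest.

    Writes leaf_gasex.csv, sites.csv, et_raster.csv + et_mask.csv
    (row-major grid, NW origin), sapflow.csv and manifest.json. Floats
    are formatted to 6 decimals so reruns are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6f"
    gen_leaf_gas_exchange(config).to_csv(outdir / "leaf_gasex.csv", index=False, float_format=fmt)
    gen_site_table(config).to_csv(outdir / "sites.csv", index=False, float_format=fmt)
    raster = gen_et_raster(config, *raster_shape)
    raster.to_csv(outdir / "et_raster.csv", outdir / "et_mask.csv")
    gen_sapflow(config).to_csv(outdir / "sapflow.csv", index=False, float_format=fmt)
    manifest = {
        "config": dataclasses.asdict(config),
        "raster_shape": list(raster_shape),
        "files": ["leaf_gasex.csv", "sites.csv", "et_raster.csv", "et_mask.csv", "sapflow.csv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
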