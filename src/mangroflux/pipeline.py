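"""End-to-end pipeline orchestration: generate -> convert -> project -> account -> simulate.

Each stage reads/writes plain CSV under a single output directory and
contributes a summary block (counts, means, checksums) to a JSON run
report. All randomness flows from the single top-level seed, so a report
is reproducible from (config, seed) alone; logging and report capture
never alter numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import canopy_flux, et_comparison, synthetic_data, water_accounting
from .bettina_sim import SimConfig, salinity_sweep

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_inputs", "SCHEMAS"]

logger = logging.getLogger(__name__)

ALL_STAGES = ["gen-data", "convert", "project", "account", "simulate"]

#: per-file schemas: required columns and (min, max, allow_equal_min) ranges
SCHEMAS: dict[str, dict] = {
    "leaf_gasex": {
        "columns": ["species", "site", "salinity_psu", "pn_umol_m2_s", "gw_mol_m2_s"],
        "ranges": {"salinity_psu": (0.0, 90.0, True), "gw_mol_m2_s": (0.0, None, False)},
    },
    "sites": {
        "columns": ["site", "region", "salinity_psu", "npp_litter", "npp_wood", "npp_root", "npp_total"],
        "ranges": {
            "npp_litter": (0.0, None, False),
            "npp_wood": (0.0, None, False),
            "npp_root": (0.0, None, False),
            "npp_total": (0.0, None, False),
            "salinity_psu": (0.0, 90.0, True),
        },
    },
    "sapflow": {
        "columns": ["dbh_cm", "water_use_l_day"],
        "ranges": {"dbh_cm": (0.0, None, False), "water_use_l_day": (0.0, None, True)},
    },
    "ecoregions": {
        "columns": ["name", "ec_et_pct", "ec_et_sd", "n", "et_mm", "area_ha"],
        "ranges": {
            "ec_et_pct": (0.0, 100.0, False),
            "et_mm": (0.0, None, False),
            "area_ha": (0.0, None, True),
        },
    },
}


def validate_inputs(path, schema_name: str) -> list[str]:
    """Check a CSV against a named schema; return a list of violations.

    Column order is irrelevant; extra columns are allowed. An empty list
    means the file is valid. The file is never modified.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read {path}")
    df = pd.read_csv(path)
    schema = SCHEMAS[schema_name]
    violations = []
    for col in schema["columns"]:
        if col not in df.columns:
            violations.append(f"missing column: {col}")
    for col, (lo, hi, eq) in schema["ranges"].items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if lo is not None:
            bad |= (vals < lo) if eq else (vals <= lo)
        if hi is not None:
            bad |= vals > hi
        if bad.any():
            violations.append(f"{col}: {int(bad.sum())} value(s) out of range")
    return violations


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration (stages, seed, paths, per-stage params)."""

    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = tuple(ALL_STAGES)
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    raster_shape: tuple[int, int] = (30, 30)
    neighborhood: int = 1
    sd_fraction: float = 0.32
    ecoregions_path: str | None = None  # None -> packaged table
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    sweep_salinities: tuple[float, ...] = tuple(float(s) for s in range(0, 81, 10))

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {ALL_STAGES}")
        # keep dependency order regardless of listed order
        object.__setattr__(
            self, "stages", tuple(s for s in ALL_STAGES if s in self.stages)
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        raw.pop("schema_version", None)
        for key in ("stages", "raster_shape", "sweep_salinities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    """Per-stage summaries and output checksums of one pipeline run."""

    seed: int
    stages: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"seed": self.seed, "stages": self.stages, "checksums": self.checksums},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    Stage failures abort the run with a stage-attributed error. The
    returned report is identical for identical (config, seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    gencfg = synthetic_data.GeneratorConfig(seed=config.seed, **config.generator)
    for stage in config.stages:
        try:
            _STAGE_FUNCS[stage](config, gencfg, outdir, report)
        except Exception as exc:  # attribute the failure to its stage
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done", stage)
    for f in sorted(outdir.iterdir()):
        if f.suffix in (".csv", ".json"):
            report.checksums[f.name] = _checksum(f)
    return report


def _stage_gen_data(config, gencfg, outdir, report):
    manifest = synthetic_data.write_all(gencfg, outdir, raster_shape=config.raster_shape)
    leaf = pd.read_csv(outdir / "leaf_gasex.csv")
    sites = pd.read_csv(outdir / "sites.csv")
    report.stages["gen-data"] = {
        "n_leaf_records": int(len(leaf)),
        "n_sites": int(len(sites)),
        "files": manifest["files"],
    }


def _stage_convert(config, gencfg, outdir, report):
    sites = pd.read_csv(outdir / "sites.csv")
    sites["ec_mm_yr"] = canopy_flux.ec_from_npp(sites["npp_total"].to_numpy())
    sites.to_csv(outdir / "sites.csv", index=False, float_format="%.6f")
    report.stages["convert"] = {
        "n_sites": int(len(sites)),
        "mean_npp": round(float(sites["npp_total"].mean()), 6),
        "mean_ec_mm_yr": round(float(sites["ec_mm_yr"].mean()), 6),
    }


def _stage_project(config, gencfg, outdir, report):
    sites = pd.read_csv(outdir / "sites.csv")
    raster = et_comparison.ETRaster.from_csv(outdir / "et_raster.csv", outdir / "et_mask.csv")
    rng = gencfg.rng("placement")  # independent stream for site->cell placement
    land = [tuple(rc) for rc in zip(*(~raster.water_mask).nonzero())]
    cells = [land[i] for i in rng.integers(0, len(land), size=len(sites))]
    sites["row"] = [c[0] for c in cells]
    sites["col"] = [c[1] for c in cells]
    results = et_comparison.project_sites(sites, raster, neighborhood=config.neighborhood)
    mean, se = et_comparison.summarize_ratios(results)
    pot = et_comparison.potential_ratio(mean, config.sd_fraction)
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        outdir / "ratios.csv", index=False, float_format="%.6f"
    )
    report.stages["project"] = {
        "n_sites": len(results),
        "mean_ratio_pct": round(mean, 6),
        "se_ratio_pct": round(se, 6),
        "potential_ratio_pct": round(pot, 6),
        "neighborhood": config.neighborhood,
    }


def _stage_account(config, gencfg, outdir, report):
    ecoregions = water_accounting.load_ecoregions(config.ecoregions_path)
    table = water_accounting.build_account(ecoregions)
    table.to_csv(outdir / "water_account.csv")
    report.stages["account"] = {
        "n_ecoregions": len(table.rows),
        "total_avg_gl": round(table.total_avg_gl, 6),
        "total_pot_gl": round(table.total_pot_gl, 6),
    }


def _stage_simulate(config, gencfg, outdir, report):
    simcfg = SimConfig(seed=config.seed, **config.sim)
    sweep = salinity_sweep(config.sweep_salinities, config=simcfg)
    sweep.to_csv(outdir / "salinity_sweep.csv", index=False, float_format="%.6f")
    u = sweep["uptake_l_day"]
    report.stages["simulate"] = {
        "n_salinities": int(len(sweep)),
        "uptake_0psu_l_day": round(float(u.iloc[0]), 6),
        "uptake_final_over_first": round(float(u.iloc[-1] / u.iloc[0]), 6),
    }


_STAGE_FUNCS = {
    "gen-data": _stage_gen_data,
    "convert": _stage_convert,
    "project": _stage_project,
    "account": _stage_account,
    "simulate": _stage_simulate,
}
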