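# mangroflux

Water-use scaling for mangrove forests, from leaf gas exchange to global
water accounting — with an individual-tree growth simulator for the
salinity response.

Mangroves are "blue carbon" ecosystems: they sequester large amounts of
carbon while transpiring a notably small share of the water that leaves
their landscape. This package implements the full analysis chain needed
to quantify that claim for researchers in coastal ecohydrology:

1. **Leaf level** (`leaf_gas_exchange`) — intrinsic and instantaneous
   water-use efficiency from gas-exchange records,

   *WUE*<sub>int</sub> = *P*<sub>n</sub>/*g*<sub>w</sub> [µmol CO₂ (mol H₂O)⁻¹],  
   *WUE*<sub>ins</sub> = *P*<sub>n</sub>/*T*<sub>r</sub> [mmol CO₂ (mol H₂O)⁻¹],

   their distributional summaries, and the OLS response of
   *WUE*<sub>int</sub> to porewater salinity.
2. **Canopy level** (`canopy_flux`) — the unit chain between canopy
   transpiration *E*<sub>c</sub> (mm H₂O yr⁻¹) and net primary
   productivity NPP (kg C m⁻² yr⁻¹) through basal-area-weighted
   *WUE*<sub>ins</sub>, the calibrated linear model

   *E*<sub>c</sub> = 384.59 · NPP + 33.56,

   and sap-flow regressions of tree water use on stem diameter (dbh).
3. **Landscape level** (`et_comparison`) — extraction of 1-km gridded
   annual evapotranspiration (ET) at study sites with a
   Moore-neighborhood rule that excludes open-water cells, site
   *E*<sub>c</sub>/ET ratios, and the low-salinity "potential" ratio
   (mean inflated by the 32% relative dispersion of leaf WUE).
4. **Global accounting** (`water_accounting`) — per-ecoregion water-use
   reductions (Δratio/100 · ET, in mm yr⁻¹, ×10 → kL ha⁻¹ yr⁻¹,
   ×area/10⁶ → GL yr⁻¹), global totals, a mangrove→oil-palm conversion
   scenario, and virtual-water values (USD per mm of transpired water).
5. **Tree level** (`bettina_sim`) — a BETTINA-style individual-based
   model: a tree is four geometric measures (stem radius/height, crown
   and root radius); uptake follows the soil-to-leaf water-potential
   gradient through a root + stem resistance network; growth allocates
   volume toward the binding resource, so allometry adapts to salinity.
6. **Plumbing** (`synthetic_data`, `pipeline`, `cli`) — a seeded
   generator for every input table, an end-to-end pipeline with a JSON
   run report, and a `mangroflux` command-line entry point.

## Worked example

```bash
$ mangroflux account
...
  TOTAL: 34,714 GL yr^-1 (average), 16,161 GL yr^-1 (potential)
```

Reading the packaged seven-ecoregion table (tabulated *E*<sub>c</sub>/ET
ratios, ET and adjacent mangrove area), the account engine compares each
ecoregion with the mangrove reference (43% of ET on average, 57% under
the low-salinity potential scenario, ET 1172 mm yr⁻¹). For tropical
rainforest (70% of 1076 mm ET) the chain gives (0.70 − 0.43) × 1076 =
290.52 mm yr⁻¹ = 2905 kL ha⁻¹ yr⁻¹, and over the 11,233,190 ha of
mangrove adjacent to that ecoregion ≈ 32,632 GL yr⁻¹. Summed over all
seven ecoregions mangroves use ~34.7 TL yr⁻¹ less water than comparable
terrestrial vegetation would (still ~16.2 TL yr⁻¹ under the potential
scenario).

```bash
$ mangroflux scenario --ratios 53,70 --et 1172 --area 18467
additional water use: 21.6 to 58.4 GL/yr over 18467 ha

$ mangroflux simulate-tree --salinity 40 --years 200
BETTINA-style tree @ 40 psu, 200 yr:
  dbh 46.6 cm, height 19.1 m, crown r 5.0 m, root r 5.2 m
  water use 100.6 L/day (potential 145.2 L/day)
```

The scenario prices the conversion of 18,467 ha of mangrove to oil palm
(whose canopies transpire 53–70% of ET): an extra 21.6–58.4 GL of water
per year. The simulated tree at seawater-plus salinity ends shorter and
proportionally thicker-stemmed than a freshwater tree and uses about
half its salinity-free potential; across a 0–80 psu sweep
(`mangroflux salinity-sweep`) final water use declines monotonically, to
~20% of the freshwater value at 70 psu.

In Python, the same computations hang off model/result objects:

```python
from mangroflux import (SimConfig, simulate, build_account,
                        load_ecoregions, fit_sapflow_per_dbh)

table = build_account(load_ecoregions())   # WaterAccountTable
print(table.summary())

traj = simulate(SimConfig(salinity=40))    # Trajectory
traj.plot()                                # water use vs dbh diagnostic

fit_sapflow_per_dbh([(8, 0.76), (24, 9.31)])   # 0.534 L/day per cm dbh
```

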