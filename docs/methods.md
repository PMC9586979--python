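# Methods

This note documents the models, unit conventions, parameter choices and
known limitations of the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Leaf water-use efficiency

Two leaf-level efficiencies are supported. Intrinsic WUE is net
photosynthesis over stomatal conductance, WUE_int = P_n / g_w; with P_n
in µmol CO₂ m⁻² s⁻¹ and g_w in mol H₂O m⁻² s⁻¹ the ratio is in
µmol CO₂ (mol H₂O)⁻¹ directly. Instantaneous WUE is net photosynthesis
over leaf transpiration, WUE_ins = P_n / T_r; with T_r in
mmol H₂O m⁻² s⁻¹ the conversion factor is exactly 1
(µmol/mmol = mmol/mol), a deliberate bookkeeping choice that avoids
silent 10³ errors. Summaries use the sample SD (n−1) and type-7
quantiles (linear interpolation between order statistics) — the most
widely used convention and the numpy default; the even-length median is
the mean of the two central values. The salinity response of WUE_int is
an ordinary least-squares line (statsmodels OLS); a design with a single
distinct salinity is rejected as singular. The relative dispersion
SD/mean of WUE_int can be computed over all leaf records or per site
grouping — both groupings are exposed because the convention behind the
canonical 32% figure is ambiguous.

## Canopy transpiration ↔ productivity

The water-to-carbon chain converts canopy transpiration E_c (mm H₂O
yr⁻¹, where 1 mm = 1 L m⁻² = 55.51 mol H₂O m⁻²) through stand-level
WUE_ins (basal-area-weighted over species) and the CO₂ molar mass into
kg CO₂, then multiplies by a carbon fraction of 0.273 kg C per kg CO₂.
The carbon fraction is kept at the conventional rounded 0.273 — not
12.011/44.01 = 0.2729 — so that published arithmetic reproduces exactly.
The calibrated projection model is the linear E_c = 384.59·NPP + 33.56
(mm yr⁻¹ per kg C m⁻² yr⁻¹). Its original calibration pairs are not
publicly tabulated, so `fit_ec_npp` is validated on synthetic pairs:
noiseless pairs refit to the printed coefficients at 1e-9, and pairs
with ~25 mm residual noise retain r² ≥ 0.955, matching the reported
calibration quality. As a sanity property, the unit chain at
WUE_ins = 4.5 mmol mol⁻¹ yields ≈ 3.0 g C per mm of water, within a
factor 1.5 of the slope-implied 1000/384.59 ≈ 2.6 g C mm⁻¹.

Sap-flow water-use intensity is the OLS slope of individual tree water
use (L day⁻¹) on dbh (cm); a two-point input gives the
finite-difference slope (identical to OLS). Display rounding is two
decimals, round-half-even. The eddy-covariance cross-check is plain
arithmetic: absolute deviation and deviation relative to the predicted
value, plus an efflux subtraction for soil/pneumatophore CO₂. Published
worked values of this validation are mutually inconsistent under any
single operand set (a 0.21 kg C m⁻² deviation described as 17.5% of
predicted does not compose with the 1.2 − x = 0.96 efflux arithmetic),
so the operations implement the stated formulas and the tests assert
only self-consistent operand sets.

## Site ratios against gridded ET

ET is read from a 1-km annual grid (plain CSV grid plus a CSV water
mask; the container is format-agnostic). A site maps to its nearest cell
from the NW origin (row-major). Extraction uses either the focal cell or
the unweighted mean over the Moore neighborhood (up to 9 cells),
excluding out-of-bounds cells and any cell flagged as open water — the
mask is Boolean, so partial water coverage is outside the data model. A
masked focal cell is an error, not a fallback. The E_c/ET ratio is
100·ec/et; site summaries report the equal-weighted mean and standard
error (a region-weighted mean is a caller-side groupby, since the
weighting convention behind published site means is unstated). The
"potential" low-salinity ratio inflates the mean by the relative
dispersion of leaf WUE_int: mean·(1 + sd_fraction), default
sd_fraction = 0.32. Applied to the rounded mean of 43.4% this gives
57.29%, slightly below the 57.4% obtainable from per-site application;
the difference (< 0.15 percentage points) is a documented consequence of
applying the adjustment to the mean.

## Ecoregional and global water accounting

For each ecoregion the reduction chain is exact arithmetic:
(ratio_eco − ratio_mangrove)/100 · ET_eco in mm yr⁻¹, ×10 to
kL ha⁻¹ yr⁻¹, ×area_ha/10⁶ to GL yr⁻¹. The mangrove reference ratios
used in the arithmetic are the rounded 43% and 57% — these, not the
unrounded 43.4/57.4 site means, reproduce the tabulated cells (e.g.
0.27·1076 = 290.52). Negative reductions are meaningful: they mark
ecoregions whose canopies transpire a smaller ET share than mangroves
would under the potential scenario. Totals are sums of unrounded per-row
values; summing display-rounded cells instead differs by ≲ 0.1% (the
tabulated global column uses integer-rounded kL values, e.g.
2905 × 11,233,190 / 10⁶ = 32,632.42 GL, where the unrounded chain gives
32,634.66). The packaged `ecoregions.csv` is a transcription of the
published seven-ecoregion inputs. The mangrove reference also carries
both published dispersion conventions (tabulated SD 2/3 and site-mean
SE 3.0/4.0) without reconciling them; neither enters the arithmetic.
The conversion scenario applies the same chain to a replacement cover's
ratio range over a converted area. Virtual-water value divides an annual
per-hectare service value (USD ha⁻¹ yr⁻¹) by E_c (mm yr⁻¹); the
packaged `services_synthetic.csv` is a synthetic illustration because
per-ecoregion service valuations are not redistributable here.

## Individual-tree growth model

A tree is four measures: stem radius r_s, stem height h, crown radius
r_c, root radius r_r (m). Water uptake is

    Q = (ψ_soil − ψ_leaf − ρ g h) / (R_bg + R_ag),   floored at 0,

with ψ_soil = −71,430 Pa psu⁻¹ × salinity (seawater ≈ −2.5 MPa at
35 psu), fixed leaf potential ψ_leaf = −9.5 MPa, R_bg = b/r_r²
(b = 5.46e13 Pa s m⁻¹, root plate area) and
R_ag = a·(h + r_c + r_r)/r_s² (a = 6.58e9 Pa s m⁻¹, flow-path length
over sapwood cross-section). Biomass is tracked as volume: a stem
cylinder plus thin crown and root plates (effective thickness 0.02 m
each). Growth per timestep is

    dV/dt = min(light gain, water gain) − maintenance · V,

with light gain = 0.0174 m³ yr⁻¹ per m² crown area, water gain =
0.0267 m³ biomass per m³ water taken up, maintenance 0.15 yr⁻¹. The
increment is split by the limitation index w = light/(light + water):
w/2 each to root radius and stem radius (water-limited trees thicken
and root), (1−w)/2 each to height and crown — except that the height
share is damped by a soft mechanical slenderness cap
f_h = 1/(1 + (h/(100·r_s))⁴), with the withheld share thickening the
stem. Without this cap, light-limited trees grow unboundedly tall and
thin, which inverts the salinity response; with it, allometry stays
self-similar and equilibrium size scales with the water-potential
gradient. Geometry updates are exact per compartment (square-root
updates of the quadratic volumes, sequential radius-then-height for the
stem), so total volume changes by exactly the computed increment —
mass conservation holds to machine precision, not just to Euler order.
A negative increment is paid by crown die-back; an exhausted crown
raises a death state.

Dynamics are deterministic explicit Euler with a 0.25-yr default step;
halving the step changes 200-yr outputs by < 1% (verified in the test
suite). The seed only jitters the optional initial state. The default
horizon of 200 years brings trees within < 1% final-decade volume
growth of their asymptotic size. The published description of this
model class gives its mechanism but not its parameter values, so the
constants above are this package's own calibration, chosen once to
satisfy the documented behavioural envelope: final water use strictly
decreasing over 0–80 psu; actual-to-potential transpiration 1 at 0 psu
and non-increasing in salinity; height decreasing and r_s/h increasing
with salinity; the adapted-allometry curve crossing the fixed
40-psu-allometry curve at the reference; and 200-yr water use at 70 psu
within 10–40% of the freshwater tree (the acceptance script computes
≈ 20%, near the ≈ 21% figure this band brackets, but only the band is a
test requirement). Freshwater adults reach ≈ 200 L day⁻¹, consistent
with "theoretically high (> 150 L day⁻¹)" behaviour expected in the
absence of salt limitation. Out of scope: multi-tree competition,
below-ground hydrological redistribution, and species-specific
parameter sets beyond a generic *Avicennia*-like tree.

## Synthetic data

The generator exists so that every pipeline stage is testable without
downloads; its defaults are the study conditions the analysis assumes.
Leaf records: salinity uniform on 10–49 psu; WUE_int = a + b·salinity
with default slope 55/39 µmol mol⁻¹ psu⁻¹ (≈ 40 at 10 psu, ≈ 95 at
49 psu, bracketing the mangrove median of 67 at the mid-range) and
Gaussian residual noise sized so the total SD/mean matches the 0.32
target (residual variance = target variance minus the salinity-trend
variance; zero if the trend alone exceeds the target). P_n/g_w equals
the drawn WUE_int exactly and T_r = P_n/WUE_ins (default
4.57 mmol mol⁻¹). Site table: 71 sites split 24:47 between a
Florida-Caribbean and an Asia-Pacific region; total NPP from a clipped
Normal(1.0, 0.35) within 0.2–2.5 kg C m⁻² yr⁻¹ (the published per-site
distribution is not tabulated, so this band brackets rather than
matches it), partitioned by a jittered 40/35/25 litter/wood/root
Dirichlet mix. ET grid: Normal(1172, 150) mm yr⁻¹ truncated positive by
resampling, with a Bernoulli open-water mask. Sap flow: water use =
slope·dbh + Gaussian noise floored at 0, default slope 1.4 L day⁻¹ cm⁻¹
(mangrove average; 3.5 is the upland comparison). All noise is Gaussian
with physical truncation — the simplest model consistent with
means ± SD/SE reporting.

One integer seed drives every stream through a fixed SeedSequence spawn
order (leaf = 0, sites = 1, raster = 2, sapflow = 3, site placement =
4); CSVs are written with 6-decimal floats, so a manifest of
(config, seed) reproduces every file byte-identically. What passing
tests on these data do **not** show: real leaf records have
non-Gaussian, heteroscedastic errors and species-level structure; real
NPP tables carry gap-filling assumptions; real MOD16 ET has spatial
autocorrelation and multi-year structure that the i.i.d. grid lacks.
Parameter-recovery tests demonstrate that the estimators are correct,
not that the field values are.

## Pipeline and interfaces

The `mangroflux` CLI groups all commands under one entry point; the
pipeline runs gen-data → convert → project → account → simulate in
dependency order regardless of the listed order, writes per-stage
summaries and SHA-256 file checksums to a JSON report, and is
idempotent for a given (config, seed). Input CSVs are validated against
column/range schemas without modification; validation failures exit 1,
stage failures exit 2 with the stage named. GeoTIFF ingestion is not
provided; gridded inputs are plain CSV grids with NW origin, which keeps
the deliverable text-only and the container format-agnostic.
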