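"""Tree growth simulator: hydraulics, allocation, salinity response."""

import math
from dataclasses import replace

import pytest

from mangroflux.bettina_sim import (
    DEFAULT_INITIAL,
    M3_PER_S_TO_L_PER_DAY,
    RHO_G,
    DeathState,
    SimConfig,
    TreeState,
    fixed_allometry_uptake,
    grow_step,
    potential_transpiration,
    salinity_sweep,
    simulate,
    water_uptake,
)

CFG = SimConfig()
ADULT = TreeState(r_stem=0.2, h_stem=15.0, r_crown=4.0, r_root=4.0, age=100.0)


def _hand_uptake(tree: TreeState, cfg: SimConfig, salinity: float) -> float:
    """Independent evaluation of the resistance network, L/day."""
    gradient = -cfg.osmotic_coeff * salinity - cfg.psi_leaf - RHO_G * tree.h_stem
    if gradient <= 0:
        return 0.0
    r_bg = cfg.bg_resistivity / tree.r_root**2
    r_ag = cfg.ag_resistivity * (tree.h_stem + tree.r_crown + tree.r_root) / tree.r_stem**2
    return gradient / (r_bg + r_ag) * M3_PER_S_TO_L_PER_DAY


class TestWaterUptake:
    def test_zero_gradient_cutoff(self):
        # soil potential at ~133 psu equals psi_leaf; beyond, uptake is 0
        cfg = replace(CFG, salinity=90.0, psi_leaf=-90.0 * CFG.osmotic_coeff + 1.0)
        assert water_uptake(ADULT, cfg) == 0.0

    def test_saline_soil_reduces_uptake(self):
        assert water_uptake(ADULT, CFG, salinity=35.0) < water_uptake(ADULT, CFG, salinity=0.0)

    def test_matches_hand_evaluated_resistance_formula(self):
        for s in (0.0, 35.0, 70.0):
            assert water_uptake(ADULT, CFG, salinity=s) == pytest.approx(
                _hand_uptake(ADULT, CFG, s), rel=1e-12
            )

    def test_doubling_stem_radius_quarters_ag_resistance(self):
        thick = replace(ADULT, r_stem=2 * ADULT.r_stem)
        # hand-recompute with R_ag/4
        r_bg = CFG.bg_resistivity / ADULT.r_root**2
        r_ag = CFG.ag_resistivity * (ADULT.h_stem + ADULT.r_crown + ADULT.r_root) / ADULT.r_stem**2
        gradient = -CFG.psi_leaf - RHO_G * ADULT.h_stem
        expected = gradient / (r_bg + r_ag / 4.0) * M3_PER_S_TO_L_PER_DAY
        assert water_uptake(thick, CFG, salinity=0.0) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            TreeState(r_stem=0.0, h_stem=1.0, r_crown=1.0, r_root=1.0)


class TestPotentialTranspiration:
    def test_freshwater_tree_at_its_potential(self):
        cfg = replace(CFG, salinity=0.0)
        assert potential_transpiration(ADULT, cfg) == water_uptake(ADULT, cfg)

    def test_saline_tree_below_potential(self):
        cfg = replace(CFG, salinity=30.0)
        assert water_uptake(ADULT, cfg) < potential_transpiration(ADULT, cfg)

    def test_ratio_non_increasing_over_salinity_grid(self):
        # fixed geometry: ratio actual/potential must fall as salinity rises
        ratios = [
            water_uptake(ADULT, CFG, salinity=s) / potential_transpiration(ADULT, CFG)
            for s in range(0, 81, 10)
        ]
        assert all(b <= a for a, b in zip(ratios, ratios[1:]))
        assert ratios[0] == pytest.approx(1.0)


class TestGrowStep:
    def test_zero_increment_leaves_geometry_unchanged(self):
        # tune light efficiency so light gain exactly cancels maintenance
        v = ADULT.volume(CFG)
        light_eff = CFG.maintenance_coeff * v / (math.pi * ADULT.r_crown**2)
        cfg = replace(CFG, salinity=0.0, light_efficiency=light_eff)
        stepped = grow_step(ADULT, cfg)
        for attr in ("r_stem", "h_stem", "r_crown", "r_root"):
            assert getattr(stepped, attr) == pytest.approx(getattr(ADULT, attr), rel=1e-12)
        assert stepped.age == ADULT.age + cfg.timestep

    def test_water_limited_tree_prioritises_roots_over_crown(self):
        cfg = replace(CFG, salinity=80.0)  # strongly water-limited
        stepped = grow_step(ADULT, cfg)
        dv_root = cfg.root_depth * math.pi * (stepped.r_root**2 - ADULT.r_root**2)
        dv_crown = cfg.crown_depth * math.pi * (stepped.r_crown**2 - ADULT.r_crown**2)
        assert dv_root > dv_crown

    def test_one_step_matches_hand_evaluated_allocation(self):
        cfg = replace(CFG, salinity=35.0)
        tree = TreeState(r_stem=0.05, h_stem=3.0, r_crown=1.0, r_root=1.0)
        # hand-evaluate gains, increment, weights and geometry updates
        light = cfg.light_efficiency * math.pi * tree.r_crown**2
        uptake_m3_yr = _hand_uptake(tree, cfg, 35.0) / 1000.0 * 365.25
        water = cfg.water_efficiency * uptake_m3_yr
        v = (
            math.pi * tree.r_stem**2 * tree.h_stem
            + cfg.crown_depth * math.pi * tree.r_crown**2
            + cfg.root_depth * math.pi * tree.r_root**2
        )
        inc = (min(light, water) - cfg.maintenance_coeff * v) * cfg.timestep
        w = light / (light + water)
        f_h = 1.0 / (1.0 + (tree.h_stem / (cfg.slenderness * tree.r_stem)) ** 4)
        r_root = math.sqrt(tree.r_root**2 + 0.5 * w * inc / (cfg.root_depth * math.pi))
        r_crown = math.sqrt(tree.r_crown**2 + 0.5 * (1 - w) * inc / (cfg.crown_depth * math.pi))
        r_stem = math.sqrt(
            tree.r_stem**2
            + (0.5 * w + 0.5 * (1 - w) * (1 - f_h)) * inc / (math.pi * tree.h_stem)
        )
        h_stem = tree.h_stem + 0.5 * (1 - w) * f_h * inc / (math.pi * r_stem**2)
        stepped = grow_step(tree, cfg)
        assert stepped.r_root == pytest.approx(r_root, rel=1e-12)
        assert stepped.r_crown == pytest.approx(r_crown, rel=1e-12)
        assert stepped.r_stem == pytest.approx(r_stem, rel=1e-12)
        assert stepped.h_stem == pytest.approx(h_stem, rel=1e-12)

    def test_volume_change_equals_increment_exactly(self):
        cfg = replace(CFG, salinity=20.0)
        tree = DEFAULT_INITIAL
        for _ in range(50):
            light = cfg.light_efficiency * math.pi * tree.r_crown**2
            water = cfg.water_efficiency * _hand_uptake(tree, cfg, 20.0) / 1000.0 * 365.25
            inc = (min(light, water) - cfg.maintenance_coeff * tree.volume(cfg)) * cfg.timestep
            stepped = grow_step(tree, cfg)
            assert stepped.volume(cfg) - tree.volume(cfg) == pytest.approx(inc, rel=1e-9)
            tree = stepped

    def test_starvation_raises_death_state(self):
        cfg = replace(CFG, salinity=80.0, maintenance_coeff=50.0)
        tree = DEFAULT_INITIAL
        with pytest.raises(DeathState):
            for _ in range(1000):
                tree = grow_step(tree, cfg)


class TestSimulate:
    def test_zero_years_returns_initial_state_only(self):
        traj = simulate(replace(CFG, years=0.0))
        assert len(traj.records) == 1
        assert traj.records.age.iloc[0] == 0.0

    def test_deterministic_given_config(self):
        cfg = replace(CFG, salinity=40.0, years=20.0)
        a, b = simulate(cfg), simulate(cfg)
        assert a.records.equals(b.records)

    def test_age_strictly_increasing_geometry_non_decreasing(self):
        traj = simulate(replace(CFG, salinity=30.0, years=50.0))
        rec = traj.records
        assert rec.age.is_monotonic_increasing and rec.age.is_unique
        for col in ("r_stem", "h_stem", "r_crown", "r_root"):
            assert (rec[col].diff().dropna() >= -1e-12).all()

    def test_short_sweep_monotone_decreasing_uptake(self):
        df = salinity_sweep([0.0, 30.0, 60.0], config=replace(CFG, years=80.0))
        u = df.uptake_l_day
        assert u.iloc[0] > u.iloc[1] > u.iloc[2]

    def test_timestep_halving_changes_endpoint_under_one_percent(self):
        cfg = replace(CFG, salinity=40.0, years=100.0)
        coarse = simulate(cfg).records.iloc[-1]
        fine = simulate(replace(cfg, timestep=cfg.timestep / 2)).records.iloc[-1]
        assert abs(coarse.uptake_l_day - fine.uptake_l_day) / fine.uptake_l_day < 0.01
        assert abs(coarse.volume - fine.volume) / fine.volume < 0.01


class TestFixedAllometry:
    def test_benchmark_coincides_at_reference_salinity(self):
        cfg = replace(CFG, years=60.0)
        ref_uptake = salinity_sweep([40.0], config=cfg).uptake_l_day.iloc[0]
        fixed = fixed_allometry_uptake(40.0, [40.0], config=cfg).uptake_l_day.iloc[0]
        assert fixed == pytest.approx(ref_uptake, rel=1e-9)
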