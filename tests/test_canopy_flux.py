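"""E_c <-> NPP conversion chain, calibration fits and sap-flow slopes."""

import numpy as np
import pytest

from mangroflux.canopy_flux import (
    EQ1_MODEL,
    EcNppModel,
    SpeciesWUE,
    StandComposition,
    UnitConstants,
    ec_from_npp,
    efflux_adjust,
    fit_ec_npp,
    fit_sapflow_per_dbh,
    load_species_wue,
    nee_cross_check,
    npp_from_ec,
    stand_wue,
)
from mangroflux.synthetic_data import GeneratorConfig, gen_sapflow

THREE_SPECIES = [
    SpeciesWUE("Avicennia germinans", 3.82, 0.3),
    SpeciesWUE("Laguncularia racemosa", 4.57, 0.3),
    SpeciesWUE("Rhizophora mangle", 5.15, 0.4),
]


class TestStandWue:
    def test_single_species(self):
        comp = StandComposition([("Avicennia germinans", 1.0)])
        assert stand_wue(comp, THREE_SPECIES) == pytest.approx(3.82)

    def test_equal_thirds_matches_hand_weighted_mean(self):
        comp = StandComposition([(s.species, 1 / 3) for s in THREE_SPECIES])
        oracle = (3.82 + 4.57 + 5.15) / 3.0  # hand-weighted mean
        assert stand_wue(comp, THREE_SPECIES) == pytest.approx(oracle)

    def test_degenerate_weights_equal_single_species(self):
        comp = StandComposition(
            [("Avicennia germinans", 1.0), ("Laguncularia racemosa", 0.0), ("Rhizophora mangle", 0.0)]
        )
        assert stand_wue(comp, THREE_SPECIES) == pytest.approx(3.82)

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            stand_wue(StandComposition([("Nypa fruticans", 1.0)]), THREE_SPECIES)

    def test_packaged_table_loads(self):
        table = load_species_wue()
        assert {t.species for t in table} == {s.species for s in THREE_SPECIES}


class TestUnitChain:
    def test_zero_transpiration_fixes_no_carbon(self):
        assert npp_from_ec(0.0, 4.57) == 0.0

    def test_hand_unit_chain_oracle(self):
        oracle = 500 * 55.51 * 0.00457 * 44.01 * 0.273 / 1000
        assert npp_from_ec(500.0, 4.57) == pytest.approx(oracle)
        assert oracle == pytest.approx(1.524, abs=1e-3)

    def test_linearity(self):
        assert npp_from_ec(800.0, 4.0) == pytest.approx(2 * npp_from_ec(400.0, 4.0))

    def test_negative_transpiration_rejected(self):
        with pytest.raises(ValueError):
            npp_from_ec(-1.0, 4.57)

    def test_roundtrip_with_inverse(self):
        # npp_from_ec and its inverse built from the same constants compose to identity
        wue = 4.57
        for ec in (1.0, 250.0, 900.0):
            npp = npp_from_ec(ec, wue)
            inv = npp / (55.51 * (wue / 1000) * 44.01 * 0.273 / 1000)
            assert inv == pytest.approx(ec, rel=1e-12)

    def test_carbon_per_mm_same_order_as_calibrated_slope(self):
        # ~3 g C per mm at wue 4.5 vs the calibration's 1000/384.59 ~ 2.6 g C/mm
        g_c_per_mm = npp_from_ec(1.0, 4.5) * 1000
        slope_implied = 1000.0 / EQ1_MODEL.slope
        assert g_c_per_mm / slope_implied < 1.5
        assert slope_implied / g_c_per_mm < 1.5

    def test_constants_self_consistency_enforced(self):
        with pytest.raises(ValueError):
            UnitConstants(mm_to_mol_h2o_per_m2=50.0)


class TestEcNppModel:
    @pytest.mark.parametrize(
        "npp, expected", [(0.0, 33.56), (1.0, 418.15), (0.5, 225.855)]
    )
    def test_calibrated_line_evaluation(self, npp, expected):
        assert ec_from_npp(npp) == pytest.approx(expected)

    def test_noiseless_pairs_refit_exactly(self):
        npp = np.linspace(0.2, 2.0, 12)
        fit = fit_ec_npp(zip(npp, EQ1_MODEL.predict(npp)))
        assert fit.model.slope == pytest.approx(EQ1_MODEL.slope, abs=1e-9)
        assert fit.model.intercept == pytest.approx(EQ1_MODEL.intercept, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_calibration_quality_at_generating_noise(self):
        # small noise mimicking the calibration data quality keeps r^2 >= 0.955
        rng = np.random.default_rng(11)
        npp = rng.uniform(0.2, 2.0, 40)
        ec = EQ1_MODEL.predict(npp) + rng.normal(0, 25.0, npp.size)
        fit = fit_ec_npp(zip(npp, ec))
        assert fit.r_squared >= 0.955
        assert fit.p_slope < 0.001

    def test_two_point_fit_rejected(self):
        with pytest.raises(ValueError):
            fit_ec_npp([(0.5, 200.0), (1.0, 400.0)])

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            EcNppModel(slope=-1.0, intercept=0.0)


class TestSapflowSlope:
    def test_two_point_finite_difference(self):
        slope = fit_sapflow_per_dbh([(8.0, 0.76), (24.0, 9.31)])
        assert slope == pytest.approx((9.31 - 0.76) / (24.0 - 8.0))
        assert round(slope, 2) == 0.53

    @pytest.mark.parametrize("true_slope", [1.4, 3.5])
    def test_noiseless_line_recovery(self, true_slope):
        dbh = np.linspace(5.0, 45.0, 15)
        assert fit_sapflow_per_dbh(zip(dbh, true_slope * dbh)) == pytest.approx(true_slope)

    def test_generator_recovery_within_tolerance(self):
        cfg = GeneratorConfig(seed=5, sapflow_slope=1.4)
        df = gen_sapflow(cfg, n=200)
        slope = fit_sapflow_per_dbh(zip(df.dbh_cm, df.water_use_l_day))
        assert slope == pytest.approx(1.4, abs=0.1)

    def test_identical_dbh_rejected(self):
        with pytest.raises(ValueError):
            fit_sapflow_per_dbh([(10.0, 5.0), (10.0, 7.0)])


class TestValidationArithmetic:
    @pytest.mark.parametrize(
        "pred, obs, expected",
        [((1.0), 1.0, (0.0, 0.0)), (1.2, 0.99, (0.21, 0.175)), (2.0, 1.0, (1.0, 0.5))],
    )
    def test_nee_cross_check(self, pred, obs, expected):
        abs_dev, rel_dev = nee_cross_check(pred, obs)
        assert abs_dev == pytest.approx(expected[0])
        assert rel_dev == pytest.approx(expected[1])

    @pytest.mark.parametrize(
        "gross, efflux, expected", [(2.16, 1.2, 0.96), (1.65, 0.8, 0.85), (1.3, 0.0, 1.3)]
    )
    def test_efflux_adjust(self, gross, efflux, expected):
        assert efflux_adjust(gross, efflux) == pytest.approx(expected)

    def test_efflux_may_exceed_gross(self):
        assert efflux_adjust(0.5, 0.8) == pytest.approx(-0.3)
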