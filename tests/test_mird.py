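"""MIRD quantities: S-values, absorbed fractions, dose conversions."""

import math

import numpy as np
import pytest

import voxdose as vd

# E_mean in joules: 0.937 MeV, so S_self for full absorption in mass m is
# 1e6 * 1.5013e-13 / m Gy/MBq*s = 1.5013e-4 / m mGy/MBq*s
E_MEAN_J = 0.937 * 1.602176634e-13


class TestSValue:
    def test_closed_form_self_s_on_contained_cube(self, water_cube, cube_run):
        """A self-contained uniform organ of mass m: S = 1e6 E_mean / m
        within 5% (surface escape is the only loss)."""
        dosemap, ledger = cube_run
        m = vd.organ_mass(water_cube, "liver")
        s, _ = vd.s_value(dosemap, water_cube, "liver")
        closed = 1e6 * E_MEAN_J / m * 1e3  # mGy/MBq*s
        assert s == pytest.approx(closed, rel=0.05)
        # the shortfall is exactly the escape fraction
        escape = ledger.escaped_mev / ledger.emitted_mev
        assert s == pytest.approx(closed * (1 - escape), rel=0.005)

    def test_self_s_scales_inversely_with_mass(self):
        """Doubling the organ's linear size (8x mass) divides the
        self-S-value by ~8."""
        results = {}
        for side in (16, 32):
            block = vd.water_block_phantom((side,) * 3, density=1.0)
            batch = vd.sample_emissions(block, "liver", 100_000, seed=14)
            dosemap, _ = vd.transport_mc(
                block, batch, options=vd.TransportOptions(radiative="off")
            )
            results[side], _ = vd.s_value(dosemap, block, "liver")
        assert results[16] / results[32] == pytest.approx(8.0, rel=0.05)

    def test_distant_target_gets_exactly_zero(self, physics):
        """A target entirely beyond the CSDA range of every source voxel
        receives S = 0 with radiative losses off."""
        from voxdose.phantom import LABELS

        block = vd.water_block_phantom((40, 8, 8), density=1.0)
        block.labels[:] = LABELS["body"]
        block.labels[:4] = LABELS["liver"]
        block.labels[-4:] = LABELS["kidney"]  # > 10 cm away
        batch = vd.sample_emissions(block, "liver", 20_000, seed=15)
        dosemap, _ = vd.transport_mc(
            block, batch, options=vd.TransportOptions(radiative="off", crop=False)
        )
        s, sig = vd.s_value(dosemap, block, "kidney")
        assert s == 0.0

    def test_empty_target_raises(self, water_cube, cube_run):
        dosemap, _ = cube_run
        with pytest.raises(vd.EmptyOrganError):
            vd.s_value(dosemap, water_cube, "marrow")

    def test_grid_mismatch_raises(self, water_cube, cube_run):
        dosemap, _ = cube_run
        other = vd.water_block_phantom((10, 10, 10))
        with pytest.raises(vd.GridMismatchError):
            vd.s_value(dosemap, other, "liver")


class TestAbsorbedFraction:
    def test_conservation_over_all_organs(self, female_phantom):
        """Sum of organ absorbed fractions + escape + radiative = 1."""
        batch = vd.sample_emissions(female_phantom, "liver", 5000, seed=16)
        dosemap, ledger = vd.transport_mc(female_phantom, batch)
        phi_total = sum(
            vd.absorbed_fraction(ledger, dosemap, female_phantom, organ)
            for organ in female_phantom.organ_names()
        )
        escape = ledger.escaped_mev / ledger.emitted_mev
        rad = ledger.radiative_mev / ledger.emitted_mev
        assert phi_total + escape + rad == pytest.approx(1.0, abs=1e-6)

    def test_self_fraction_near_one_in_infinite_medium(self, water_cube, cube_run):
        dosemap, ledger = cube_run
        phi = vd.absorbed_fraction(ledger, dosemap, water_cube, "liver")
        assert 0.95 < phi <= 1.0


class TestDoseConversion:
    def test_total_dose_reproduces_published_liver_maximum(self):
        """S = 1.2085e-4 mGy/MBq*s at 3 GBq for one 64.1 h half-life
        gives 83.7 Gy — the published female liver maximum, 84 Gy at
        its printed precision."""
        d = vd.total_dose(1.2085e-4, vd.THERAPY_3GBQ)
        assert d == pytest.approx(83.66, abs=0.01)
        assert round(d) == 84

    def test_total_dose_mird_convention(self):
        admin = vd.AdministrationSpec(3000.0, 64.1, "mird")
        assert vd.total_dose(1.2085e-4, admin) == pytest.approx(120.7, abs=0.05)

    def test_zero_activity_zero_dose(self):
        assert vd.total_dose(1.2085e-4, vd.AdministrationSpec(0.0, 64.1)) == 0.0

    def test_convention_ratio_identity(self):
        s = 7.31e-5
        simple = vd.total_dose(s, vd.AdministrationSpec(3000.0, 64.1, "simple"))
        mird = vd.total_dose(s, vd.AdministrationSpec(3000.0, 64.1, "mird"))
        assert mird / simple == pytest.approx(1.0 / math.log(2), rel=1e-12)

    def test_equivalent_dose_rate_hand_value(self):
        rate = vd.equivalent_dose_rate(1.2085e-4, 100.0, w_r=1.0)
        assert rate == pytest.approx(1.2085e-2, rel=1e-12)

    def test_equivalent_equals_absorbed_for_unit_weighting(self):
        s, a = 8.5e-5, 250.0
        assert vd.equivalent_dose_rate(s, a, 1.0) == s * a
        assert vd.equivalent_dose_rate(s, 0.0) == 0.0


class TestDominance:
    def test_reference_row_hand_value(self):
        """Female BMI 20.8: 8.5090e-5 / 6.9404e-7 = 122.6."""
        rec = vd.SValueRecord(
            sex="female", bmi=20.8, source_organ="liver",
            s_values={"liver": 8.5090e-5, "lung": 1.7210e-7,
                      "kidney": 6.9404e-7, "marrow": 3.1386e-8},
        )
        assert rec.dominance_ratio() == pytest.approx(122.6, abs=0.05)

    def test_reference_table_minimum_at_least_100(self):
        table = vd.load_reference_svalues()
        assert table.min_dominance_ratio() >= 100.0

    def test_all_zero_cross_organs_give_infinity(self):
        rec = vd.SValueRecord(
            sex="male", bmi=23.0, source_organ="liver",
            s_values={"liver": 8e-5, "lung": 0.0, "kidney": 0.0, "marrow": 0.0},
        )
        assert rec.dominance_ratio() == math.inf

    def test_self_s_dominates_in_reference_table(self):
        for rec in vd.load_reference_svalues().records:
            cross = [v for k, v in rec.s_values.items() if k != "liver"]
            assert rec.s_values["liver"] > max(cross)
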