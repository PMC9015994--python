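"""MIRD dose assembly, kidney schemes, marrow/blood, glands, voxels."""

import math

import numpy as np
import pytest

from lutedose.dosimetry import (
    BloodKinetics,
    blood_dose,
    compute_dvh,
    extravasation_dose,
    gland_dose,
    kidney_scheme1,
    kidney_scheme2,
    mean_dose,
    red_marrow_dose,
    voxel_dose_rate,
    voxel_tia_and_dvh,
)
from lutedose.kinetics import TimeActivityCurve
from lutedose.nuclide import ICRP107, decay_constant
from lutedose.svalues import IDAC_MALE, SValueRecord, SValueTable


class TestMeanDose:
    def test_single_self_contribution(self, svalue_table):
        rep = mean_dose({"kidney": 1e5}, svalue_table, "kidney", IDAC_MALE)
        assert rep.mean_dose_Gy == pytest.approx(20.4)

    def test_empty_map(self, svalue_table):
        rep = mean_dose({}, svalue_table, "kidney", IDAC_MALE)
        assert rep.mean_dose_mGy == 0.0 and rep.contributions == []

    def test_additivity(self):
        table = SValueTable(
            [
                SValueRecord("kidney", "kidney", 0.2, 400.0, "p"),
                SValueRecord("liver", "kidney", 0.001, None, "p"),
            ]
        )
        rep = mean_dose({"kidney": 1000.0, "liver": 2000.0}, table, "kidney", "p")
        assert rep.mean_dose_mGy == pytest.approx(0.2 * 1000 + 0.001 * 2000)

    def test_unmatched_source_raises(self, svalue_table):
        with pytest.raises(LookupError, match="spleen"):
            mean_dose({"kidney": 1.0, "spleen": 1.0}, svalue_table, "kidney", IDAC_MALE)

    def test_rest_of_body_term_adds_two_percent(self, svalue_table):
        # A remainder-body cross term sized to 2% of the self dose shifts
        # the kidney dose by exactly that amount.
        self_rec = svalue_table.lookup("kidney", "kidney", IDAC_MALE)
        tia_self = 1e5
        self_dose = tia_self * self_rec.value
        tia_rob = 10 * tia_self
        s_cross = 0.02 * self_dose / tia_rob
        table = SValueTable(
            [self_rec, SValueRecord("remainder", "kidney", s_cross, None, IDAC_MALE)]
        )
        rep = mean_dose(
            {"kidney": tia_self, "remainder": tia_rob}, table, "kidney", IDAC_MALE
        )
        assert rep.mean_dose_mGy / self_dose == pytest.approx(1.02)

    def test_report_serialisation(self, svalue_table, tmp_path):
        rep = mean_dose({"kidney": 1e5}, svalue_table, "kidney", IDAC_MALE)
        rep.to_csv(tmp_path / "rep.csv")
        import json

        payload = json.loads(rep.to_json())
        assert payload["mean_dose_mGy"] == pytest.approx(20.4e3)


def _kidney_tacs(conc0=0.8, lam=0.0139, vol_l=150.0, vol_r=140.0,
                 times=(24.0, 72.0, 168.0)):
    left = TimeActivityCurve(
        "kidney left", times, tuple(conc0 * vol_l * math.exp(-lam * t) for t in times)
    )
    right = TimeActivityCurve(
        "kidney right", times, tuple(conc0 * vol_r * math.exp(-lam * t) for t in times)
    )
    return left, right


class TestKidneySchemes:
    LAM = 0.0139
    CONC0 = 0.8
    VOLS = (150.0, 140.0)

    def kidney_svalue(self, svalue_table):
        return svalue_table.lookup("kidney", "kidney", IDAC_MALE)

    def test_scheme1_closed_form(self, svalue_table):
        left, right = _kidney_tacs(self.CONC0, self.LAM, *self.VOLS)
        masses = tuple(v * 1.05 for v in self.VOLS)
        res = kidney_scheme1(left, right, masses, self.kidney_svalue(svalue_table))
        sv = self.kidney_svalue(svalue_table)
        for rep, vol, mass in zip((res.left, res.right), self.VOLS, masses):
            tia = self.CONC0 * vol / self.LAM
            expected = tia * sv.value * sv.ref_mass_g / mass / 1000.0
            assert rep.mean_dose_Gy == pytest.approx(expected, rel=1e-6)

    def test_scheme1_symmetry_for_equal_kidneys(self, svalue_table):
        left, right = _kidney_tacs(vol_l=150.0, vol_r=150.0)
        res = kidney_scheme1(left, right, (157.5, 157.5), self.kidney_svalue(svalue_table))
        assert res.left.mean_dose_Gy == pytest.approx(res.right.mean_dose_Gy)
        assert res.combined_mass_weighted_Gy == pytest.approx(res.left.mean_dose_Gy)

    def test_scheme1_mass_weighted_equals_combined_mass_route(self, svalue_table):
        # Mass-weighted mean of per-kidney doses equals the combined-mass
        # S-value applied to the summed TIA.
        left, right = _kidney_tacs()
        masses = tuple(v * 1.05 for v in self.VOLS)
        sv = self.kidney_svalue(svalue_table)
        res = kidney_scheme1(left, right, masses, sv)
        s_pat = sv.value * sv.ref_mass_g / sum(masses)
        assert res.combined_mass_weighted_Gy == pytest.approx(
            res.total_tia_MBq_h * s_pat / 1000.0, rel=1e-9
        )

    def test_scheme1_followup_linearity(self, svalue_table):
        left, right = _kidney_tacs()
        masses = tuple(v * 1.05 for v in self.VOLS)
        sv = self.kidney_svalue(svalue_table)
        cycle1 = kidney_scheme1(left, right, masses, sv)
        hl = cycle1.effective_halflives_h
        t_follow = (72.0,)
        half = [
            TimeActivityCurve(tac.region, t_follow, (0.5 * tac.a[1],))
            for tac in (left, right)
        ]
        res2 = kidney_scheme1(half[0], half[1], masses, sv,
                              cycle1_halflives_h=hl, cycle=2)
        assert res2.left.mean_dose_Gy == pytest.approx(0.5 * cycle1.left.mean_dose_Gy, rel=1e-6)
        assert any("carried" in a for a in res2.left.assumptions)

    def test_scheme1_followup_requires_halflife(self, svalue_table):
        left = TimeActivityCurve("kidney left", (72.0,), (50.0,))
        with pytest.raises(ValueError, match="cycle1_halflives_h"):
            kidney_scheme1(left, left, (150.0, 150.0),
                           self.kidney_svalue(svalue_table), cycle=2)

    def test_scheme2_dose_rate_factor(self, icrp107):
        # 1 MBq/mL at density 1.05 → 0.0813 Gy/h under LED.
        times = (24.0, 72.0, 168.0)
        conc = TimeActivityCurve("kidney left", times,
                                 tuple(math.exp(-0.01 * t) for t in times))
        res = kidney_scheme2(conc, conc, recovery=1.0, nuclide=icrp107)
        # Back out the fitted initial dose rate: dose = R0/λ.
        r0 = res.left.mean_dose_mGy * 0.01
        assert r0 / 1000.0 == pytest.approx(0.0813, abs=2e-4)

    def test_schemes_agree_within_2pc_on_uniform_kidneys(self, svalue_table, icrp107):
        # Same underlying kinetics through both routes: the only gap is the
        # LED-vs-S-value ratio (1.01 for kidney), well within 2%.
        left, right = _kidney_tacs(self.CONC0, self.LAM, *self.VOLS)
        masses = tuple(v * 1.05 for v in self.VOLS)
        res1 = kidney_scheme1(left, right, masses, self.kidney_svalue(svalue_table))
        conc_l = TimeActivityCurve(
            "kidney left", left.times_h, tuple(a / self.VOLS[0] for a in left.a)
        )
        conc_r = TimeActivityCurve(
            "kidney right", right.times_h, tuple(a / self.VOLS[1] for a in right.a)
        )
        res2 = kidney_scheme2(conc_l, conc_r, recovery=1.0, nuclide=icrp107,
                              volumes_ml=self.VOLS)
        ratio = res1.combined_mass_weighted_Gy / res2.combined_mass_weighted_Gy
        assert abs(ratio - 1.0) < 0.02

    def test_scheme2_zero_concentration(self, icrp107):
        times = (24.0, 72.0, 168.0)
        conc = TimeActivityCurve("kidney left", times,
                                 tuple(math.exp(-0.01 * t) for t in times))
        zero = TimeActivityCurve("kidney right", times, (0.0, 0.0, 0.0))
        res = kidney_scheme2(conc, zero, recovery=1.0, nuclide=icrp107,
                             cycle1_halflives_h=(69.3, 69.3))
        assert res.right.mean_dose_mGy == 0.0


class TestMarrowAndBlood:
    def test_blood_based_self_term(self, svalue_table):
        rm = svalue_table.lookup("red marrow", "red marrow", IDAC_MALE)
        blood = BloodKinetics(tia_conc_blood_MBq_h_per_mL=0.5, rmblr=1.0)
        rep = red_marrow_dose(blood, rm)
        # 0.5 MBq·h/mL × 1394 g → 697 MBq·h × 0.0349 = 24.3 mGy
        assert rep.contributions[0].tia_MBq_h == pytest.approx(697.0)
        assert rep.mean_dose_mGy == pytest.approx(24.3, abs=0.05)

    def test_zero_rmblr_no_cross(self, svalue_table):
        rm = svalue_table.lookup("red marrow", "red marrow", IDAC_MALE)
        rep = red_marrow_dose(BloodKinetics(0.5, rmblr=0.0), rm)
        assert rep.mean_dose_mGy == 0.0

    def test_cross_terms_increase_dose(self, svalue_table):
        rm = svalue_table.lookup("red marrow", "red marrow", IDAC_MALE)
        blood = BloodKinetics(0.5)
        base = red_marrow_dose(blood, rm).mean_dose_mGy
        with_bone = red_marrow_dose(
            blood, rm, image_contributions={"bone": (1000.0, 0.002)}
        )
        assert with_bone.mean_dose_mGy == pytest.approx(base + 2.0)
        assert all("bone" not in a for a in with_bone.assumptions if "omitted" in a)

    def test_blood_dose_self_term(self):
        blood = BloodKinetics(tia_conc_blood_MBq_h_per_mL=2.0)  # 0.002 GBq·h/mL
        assert blood_dose(blood) == pytest.approx(0.1706)

    def test_blood_dose_total_body_term(self):
        blood = BloodKinetics(0.0, tia_total_body_MBq_h=50_000.0, body_mass_kg=70.0)
        assert blood_dose(blood) == pytest.approx(50 * 0.00185 / 70 ** (2 / 3), rel=1e-9)
        assert blood_dose(blood) == pytest.approx(0.00545, abs=5e-5)

    def test_blood_dose_requires_body_mass(self):
        blood = BloodKinetics(0.0, tia_total_body_MBq_h=50_000.0)
        with pytest.raises(ValueError, match="body mass"):
            blood_dose(blood)

    def test_all_zero(self):
        assert blood_dose(BloodKinetics(0.0)) == 0.0


class TestGlandDose:
    def test_lacrimal_led(self, icrp107):
        res = gland_dose(1000.0, 1.4, dataset=icrp107)
        assert res.report.mean_dose_Gy == pytest.approx(60.9, abs=0.05)

    def test_mass_doubling_halves_dose(self, icrp107):
        d1 = gland_dose(1000.0, 1.0, dataset=icrp107).report.mean_dose_Gy
        d2 = gland_dose(1000.0, 2.0, dataset=icrp107).report.mean_dose_Gy
        assert d1 == pytest.approx(2 * d2)

    def test_mass_range_bounds(self, icrp107):
        res = gland_dose(1000.0, (1.0, 1.4, 2.0), dataset=icrp107)
        de = 0.08532 * 1000  # mJ for TIA 1000 MBq·h
        assert res.dose_high_mGy == pytest.approx(de / 0.001, rel=1e-3)
        assert res.dose_low_mGy == pytest.approx(de / 0.002, rel=1e-3)
        assert res.dose_low_mGy < res.report.mean_dose_mGy < res.dose_high_mGy

    def test_with_reference_svalue(self, svalue_table, icrp107):
        sal = svalue_table.lookup(
            "salivary glands (male)", "salivary glands (male)", "OpenDose"
        )
        res = gland_dose(1000.0, 85.0, dataset=icrp107, svalue=sal)
        expected = 1000.0 * sal.value * sal.ref_mass_g / 85.0
        assert res.report.mean_dose_mGy == pytest.approx(expected)

    def test_tac_input(self, icrp107):
        times = (4.0, 24.0, 72.0, 168.0)
        tac = TimeActivityCurve(
            "gland", times, tuple(10 * math.exp(-0.01 * t) for t in times)
        )
        res = gland_dose(tac, 1.4, dataset=icrp107)
        assert res.report.contributions[0].tia_MBq_h == pytest.approx(1000.0, rel=1e-6)


class TestExtravasation:
    def test_worked_example(self, icrp107):
        # 7.4 GBq in 100 cm³, physical decay only → ~1450 Gy ("order of 1400").
        dose = extravasation_dose(7400.0, 100.0, nuclide=icrp107)
        expected = 7400.0 * (159.528 / math.log(2)) * 0.08532e-3 / 0.1 / 1000 * 1e3
        assert dose == pytest.approx(1453.0, abs=1.0)
        assert dose == pytest.approx(expected, rel=1e-3)

    def test_clearance_reduction_ratio(self, icrp107):
        # A 2 h lymphatic clearance half-life cuts the dose by
        # λ_phys/(λ_phys+λ_bio) ≈ 1/80.8.
        no_clear = extravasation_dose(7400.0, 100.0, nuclide=icrp107)
        cleared = extravasation_dose(7400.0, 100.0, clearance_halflife_h=2.0, nuclide=icrp107)
        lam_p = decay_constant(icrp107)
        lam_b = math.log(2) / 2.0
        assert cleared / no_clear == pytest.approx(lam_p / (lam_p + lam_b), rel=1e-12)
        assert no_clear / cleared == pytest.approx(80.8, abs=0.1)

    def test_zero_activity(self, icrp107):
        assert extravasation_dose(0.0, 100.0, nuclide=icrp107) == 0.0

    def test_bad_volume(self, icrp107):
        with pytest.raises(ValueError):
            extravasation_dose(100.0, 0.0, nuclide=icrp107)


class TestVoxelDosimetry:
    def test_uniform_dose_rate(self, icrp107):
        conc = np.ones((4, 4, 4))
        m = voxel_dose_rate(conc, density_g_per_cm3=1.05, dataset=icrp107)
        # 0.0853.../1.05 ≈ 81.25-81.3 mGy/h depending on the rounding of the
        # electron energy column; allow the propagated input rounding.
        assert np.allclose(m.values_mGy_per_h, 81.3, atol=0.1)

    def test_zero_map(self, icrp107):
        m = voxel_dose_rate(np.zeros((3, 3, 3)), dataset=icrp107)
        assert np.all(m.values_mGy_per_h == 0.0)

    def test_shape_mismatch_rejected(self, icrp107):
        with pytest.raises(ValueError, match="shape"):
            voxel_dose_rate(np.ones((3, 3, 3)), np.ones((2, 2, 2)), icrp107)

    def _decaying_maps(self, base, lam=0.02, times=(4.0, 24.0, 72.0, 168.0)):
        return [
            voxel_dose_rate(base * math.exp(-lam * t), 1.0, ICRP107, time_h=t)
            for t in times
        ]

    def test_uniform_phantom_methods_agree(self):
        base = np.full((4, 4, 4), 2.0)
        maps = self._decaying_maps(base)
        mask = np.ones(base.shape, dtype=bool)
        vw = voxel_tia_and_dvh(maps, mask, "voxelwise_fit")
        vm = voxel_tia_and_dvh(maps, mask, "voi_mean_fit")
        assert vw.voi_dose_mGy == pytest.approx(vm.voi_dose_mGy, rel=1e-6)
        assert vw.n_fallback_voxels == 0

    def test_uniform_dvh_is_step(self):
        base = np.full((4, 4, 4), 2.0)
        maps = self._decaying_maps(base)
        mask = np.ones(base.shape, dtype=bool)
        res = voxel_tia_and_dvh(maps, mask, "voxelwise_fit")
        dose = res.voi_dose_mGy
        assert res.dvh.at(0.0) == 1.0
        assert res.dvh.at(dose * 0.99) == pytest.approx(1.0)

    def test_two_compartment_dvh_steps(self):
        # Compartments at dose d1 < d2 with volume fractions f1, f2 give a
        # DVH stepping from 1 to f2 at d1 and to 0 at d2.
        shape = (4, 4, 4)
        base = np.full(shape, 1.0)
        base[:2] = 3.0  # f(hot) = 0.5
        maps = self._decaying_maps(base, lam=0.02)
        mask = np.ones(shape, dtype=bool)
        res = voxel_tia_and_dvh(maps, mask, "voxelwise_fit")
        dmap = res.dose_map_mGy
        d1, d2 = np.unique(np.round(dmap, 6))
        assert d2 == pytest.approx(3 * d1, rel=1e-6)
        assert res.dvh.at(0.5 * d1) == pytest.approx(1.0)
        assert res.dvh.at(0.5 * (d1 + d2)) == pytest.approx(0.5)

    def test_dvh_monotone_non_increasing(self):
        base = np.random.default_rng(3).uniform(0.5, 2.0, (5, 5, 5))
        maps = self._decaying_maps(base)
        res = voxel_tia_and_dvh(maps, np.ones(base.shape, bool), "voxelwise_fit")
        assert np.all(np.diff(res.dvh.volume_fraction) <= 1e-12)
        assert res.dvh.volume_fraction[0] == 1.0

    def test_non_decreasing_voxels_fall_back(self, icrp107):
        shape = (2, 2, 2)
        times = (4.0, 24.0, 72.0)
        maps = []
        for t in times:
            arr = np.full(shape, math.exp(-0.02 * t))
            arr[0, 0, 0] = 1.0  # constant voxel: no washout
            maps.append(voxel_dose_rate(arr, 1.0, icrp107, time_h=t))
        res = voxel_tia_and_dvh(maps, np.ones(shape, bool), "voxelwise_fit")
        assert res.n_fallback_voxels == 1
        # fallback = trapezoid + physical-decay tail for the flat voxel,
        # whose LED dose rate is Δ_e × 1 MBq/mL ≈ 85.3 mGy/h throughout
        lam_phys = decay_constant(icrp107)
        rate = maps[0].values_mGy_per_h[0, 0, 0]
        expected = rate * ((times[-1] - times[0]) + 0.5 * times[0] + 1.0 / lam_phys)
        assert res.dose_map_mGy[0, 0, 0] == pytest.approx(expected, rel=1e-6)

    def test_region_mean_consistent_with_scheme2_rate(self, icrp107):
        # The mean LED dose rate over a uniform VOI equals the region-level
        # concentration route at the same density.
        conc = np.full((3, 3, 3), 1.0)
        m = voxel_dose_rate(conc, 1.05, icrp107)
        assert m.values_mGy_per_h.mean() / 1000 == pytest.approx(0.0813, abs=2e-4)

    def test_dvh_csv(self, tmp_path):
        base = np.full((3, 3, 3), 1.0)
        maps = self._decaying_maps(base)
        res = voxel_tia_and_dvh(maps, np.ones(base.shape, bool))
        res.dvh.to_csv(tmp_path / "dvh.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "dvh.csv")
        assert set(df.columns) == {"dose_mGy", "volume_fraction"}
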