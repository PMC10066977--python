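"""Blood gas carriage: dissociation curves, contents, acid-base, Fick loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from vqshunt import bloodchem as bc
from vqshunt.config import PhysConstants

C = PhysConstants()


class TestODC:
    def test_po2_at_standard_p50_gives_half_saturation(self):
        # definition of standard P50, for any P50st
        for p50st in (20.8, 26.86, 31.2):
            s = bc.odc_saturation(p50st, ph=7.40, pco2=40.0, be=0.0, p50st=p50st)
            assert s == pytest.approx(0.50, abs=1e-3)

    def test_zero_po2_zero_saturation(self):
        assert bc.odc_saturation(0.0) == 0.0

    def test_reference_curve_oracle_values(self):
        # frozen from direct evaluation of the published reference curve
        # S = (x^3+150x)/(x^3+150x+23400): S(26.86)=0.50008, S(150)=0.993160
        assert bc.odc_saturation(26.86) == pytest.approx(0.500079, abs=1e-5)
        assert bc.odc_saturation(150.0) == pytest.approx(0.993160, abs=1e-5)

    def test_negative_po2_rejected(self):
        with pytest.raises(ValueError):
            bc.odc_saturation(-1.0)

    @settings(derandomize=True, max_examples=40)
    @given(po2=st.floats(0.5, 600.0), ph=st.floats(7.0, 7.6),
           p50st=st.floats(20.8, 31.2), be=st.floats(-6.5, 4.9))
    def test_strictly_increasing_in_po2(self, po2, ph, p50st, be):
        s1 = bc.odc_saturation(po2, ph, 40.0, be, p50st)
        s2 = bc.odc_saturation(po2 * 1.01, ph, 40.0, be, p50st)
        assert s2 > s1

    @settings(derandomize=True, max_examples=40)
    @given(so2=st.floats(0.01, 0.995), ph=st.floats(7.0, 7.6),
           p50st=st.floats(20.8, 31.2))
    def test_inverse_round_trips(self, so2, ph, p50st):
        po2 = bc.odc_po2(so2, ph, 40.0, 0.0, p50st)
        back = bc.odc_po2(float(bc.odc_saturation(po2, ph, 40.0, 0.0, p50st)),
                          ph, 40.0, 0.0, p50st)
        assert back == pytest.approx(po2, abs=1e-6)

    def test_raising_p50st_lowers_saturation(self):
        po2 = 60.0
        sats = [float(bc.odc_saturation(po2, 7.40, 40.0, 0.0, p))
                for p in np.linspace(20.8, 31.2, 6)]
        assert all(a > b for a, b in zip(sats, sats[1:]))

    def test_acidemia_right_shifts_curve(self):
        # Bohr effect: lower pH, lower saturation at fixed PO2
        assert bc.odc_saturation(40.0, ph=7.20) < bc.odc_saturation(40.0, ph=7.40)


class TestContents:
    def test_o2_content_zero_cases(self):
        assert bc.o2_content(0.0, 0.0, 0.0) == 0.0

    def test_o2_content_hand_arithmetic(self):
        # 1.34*9.30*0.94 + 0.003*69.0
        assert bc.o2_content(69.0, 0.94, 9.30) == pytest.approx(11.92128, abs=1e-9)

    def test_o2_content_linear_in_hb(self):
        assert bc.o2_content(0.0, 0.9, 20.0) == pytest.approx(
            2 * bc.o2_content(0.0, 0.9, 10.0))

    def test_co2_content_zero_at_zero_pco2(self):
        assert bc.co2_content(0.0, 7.40, 0.97, 15.0) == 0.0

    def test_haldane_direction(self):
        lo = bc.co2_content(40.0, 7.40, 0.70, 15.0)
        hi = bc.co2_content(40.0, 7.40, 1.00, 15.0)
        assert lo > hi

    def test_co2_content_against_published_formulation(self):
        # independent transcription of the whole-blood CO2 content equation
        # (Douglas et al. 1988), evaluated at 37 degC
        pco2, ph, so2, hb = 40.0, 7.40, 0.97, 15.0
        pk = 6.086 + 0.042 * (7.4 - ph) + (38 - 37) * (0.00472 + 0.00139 * (7.4 - ph))
        plasma = 0.0307 * pco2 * (1 + 10 ** (ph - pk))
        blood = 2.226 * plasma * (1 - 0.0289 * hb / ((3.352 - 0.456 * so2) * (8.142 - ph)))
        assert bc.co2_content(pco2, ph, so2, hb) == pytest.approx(blood, rel=1e-9)
        # and the physiologic magnitude: ~47 mL/dL for normal arterial blood
        assert 44.0 < blood < 50.0

    def test_co2_content_increasing_in_pco2(self):
        grid = np.linspace(10, 120, 12)
        c = bc.co2_content(grid, 7.30, 0.9, 12.0)
        assert np.all(np.diff(c) > 0)

    def test_co2_content_inversion_round_trip(self):
        # content -> PCO2 at fixed pH/SO2 recovers the tension to 1e-6 mmHg
        for pco2 in (25.0, 40.0, 80.0):
            c = float(bc.co2_content(pco2, 7.35, 0.92, 11.0))
            sol = brentq(lambda p: float(bc.co2_content(p, 7.35, 0.92, 11.0)) - c,
                         1.0, 200.0, xtol=1e-9)
            assert sol == pytest.approx(pco2, abs=1e-6)


class TestAcidBase:
    def test_normal_point(self):
        assert float(bc.acid_base_ph(40.0, 0.0, 15.0)) == pytest.approx(7.40, abs=0.01)

    def test_monotone_in_pco2_and_be(self):
        assert bc.acid_base_ph(80.0, 0.0, 15.0) < 7.40 < bc.acid_base_ph(20.0, 0.0, 15.0)
        assert bc.acid_base_ph(40.0, 4.9, 15.0) > bc.acid_base_ph(40.0, -6.5, 15.0)

    def test_nonpositive_pco2_rejected(self):
        with pytest.raises(ValueError):
            bc.acid_base_ph(0.0, 0.0, 15.0)

    def test_sweep_spans_viable_ph_window(self):
        # over the sampled BE range and the observable PaCO2 window, pH spans
        # a range compatible with the 7.02-7.56 bedside envelope
        pco2 = np.linspace(23.8, 111.6, 30)[None, :]
        be = np.linspace(-6.5, 4.9, 10)[:, None]
        ph = bc.acid_base_ph(pco2, be, 12.0)
        assert ph.min() < 7.02 and ph.max() > 7.56
        assert 6.7 < ph.min() and ph.max() < 7.9

    def test_base_excess_inverts_ph(self):
        for pco2, be, hb in [(30.0, -5.0, 8.0), (40.0, 0.0, 15.0), (90.0, 4.0, 17.0)]:
            ph = float(bc.acid_base_ph(pco2, be, hb))
            assert float(bc.base_excess(ph, pco2, hb)) == pytest.approx(be, abs=1e-8)


class TestMixedVenous:
    params = bc.BloodParams(hb=9.30, p50st=26.86, be=0.0)

    def test_zero_metabolism_returns_arterial(self):
        art = bc.blood_state_from_contents(11.92, 46.0, self.params)
        metab = bc.MetabolicState(vco2=1e-9, r=0.8, co=5.0)
        ven = bc.mixed_venous(art, metab, self.params)
        assert ven.o2_content == pytest.approx(art.o2_content, abs=1e-9)
        assert ven.po2 == pytest.approx(art.po2, abs=1e-4)

    def test_vo2_derived_from_r(self):
        metab = bc.MetabolicState(vco2=187.0, r=0.74, co=5.25)
        assert metab.vo2 == pytest.approx(252.7027, abs=1e-3)
        assert metab.vo2 * metab.r == pytest.approx(metab.vco2, rel=1e-12)

    def test_fick_arithmetic(self):
        # CvO2 = CaO2 - VO2/(10*CO) = 11.92 - 252.7/52.5
        art = bc.blood_state_from_contents(11.92, 46.0, self.params)
        metab = bc.MetabolicState(vco2=187.0, r=0.74, co=5.25)
        ven = bc.mixed_venous(art, metab, self.params)
        assert ven.o2_content == pytest.approx(11.92 - 252.7027 / 52.5, abs=1e-4)
        # mass conservation to 1e-9 relative
        vo2_back = 10.0 * metab.co * (art.o2_content - ven.o2_content)
        assert vo2_back == pytest.approx(metab.vo2, rel=1e-9)

    def test_infeasible_scenario_raises(self):
        art = bc.blood_state_from_contents(5.0, 46.0, bc.BloodParams(hb=6.0))
        metab = bc.MetabolicState(vco2=223.0, r=0.57, co=4.32)
        with pytest.raises(bc.InfeasibleScenarioError):
            bc.mixed_venous(art, metab, bc.BloodParams(hb=6.0))

    def test_state_from_contents_round_trip(self):
        st_ = bc.blood_state_from_contents(14.0, 50.0, bc.BloodParams(hb=12.0, be=-3.0))
        assert bc.o2_content(st_.po2, st_.so2, 12.0) == pytest.approx(14.0, abs=1e-6)
        assert bc.co2_content(st_.pco2, st_.ph, st_.so2, 12.0) == pytest.approx(50.0, abs=1e-6)


class TestInvariantsValidation:
    def test_blood_params_validation(self):
        with pytest.raises(ValueError):
            bc.BloodParams(hb=0.0)
        with pytest.raises(ValueError):
            bc.BloodParams(hb=12.0, p50st=50.0)

    def test_blood_gas_state_validation(self):
        with pytest.raises(ValueError):
            bc.BloodGasState(po2=50, pco2=40, ph=7.4, so2=1.2,
                             o2_content=10, co2_content=40)
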