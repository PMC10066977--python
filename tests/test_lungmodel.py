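"""Forward lung model: distribution, compartment equilibration, whole lung."""

import numpy as np
import pytest
from scipy import integrate, stats

from vqshunt import bloodchem as bc
from vqshunt import lungmodel as lm
from vqshunt.config import PhysConstants, SolverSettings

C = PhysConstants()


def make_inputs(shunt=0.15, log_sd=1.0, mean_vq=0.6, vco2=200.0, r=0.8,
                co=5.0, hb=11.0, p50st=26.86, be=0.0) -> lm.LungInputs:
    return lm.LungInputs(shunt_frac=shunt, log_sd=log_sd, mean_vq=mean_vq,
                         metab=bc.MetabolicState(vco2=vco2, r=r, co=co),
                         blood=bc.BloodParams(hb=hb, p50st=p50st, be=be))


class TestPerfusionDistribution:
    def test_fractions_normalized(self):
        for mean_vq, log_sd in [(0.21, 0.36), (1.25, 1.83), (0.6, 1.0)]:
            dist = lm.perfusion_distribution(mean_vq, log_sd)
            q = np.array([f for _, f in dist])
            assert q.sum() == pytest.approx(1.0, abs=1e-12)
            assert len(dist) == 20

    def test_matches_lognormal_quadrature(self):
        # bin masses equal numerical quadrature of the log-normal perfusion
        # density over each compartment's bin (renormalized to the grid span)
        mean_vq, log_sd, span, n = 1.0, 0.5, 3.5, 20
        dist = lm.perfusion_distribution(mean_vq, log_sd, n, span)
        rv = stats.lognorm(s=log_sd, scale=mean_vq)
        edges = mean_vq * np.exp(log_sd * np.linspace(-span, span, n + 1))
        masses = np.array([integrate.quad(rv.pdf, lo, hi, limit=200)[0]
                           for lo, hi in zip(edges[:-1], edges[1:])])
        masses /= masses.sum()
        np.testing.assert_allclose([q for _, q in dist], masses, atol=1e-6)

    def test_degenerate_dispersion_concentrates_at_mean(self):
        dist = lm.perfusion_distribution(0.8, 0.001)
        mass_near = sum(q for vq, q in dist if abs(vq / 0.8 - 1) < 0.01)
        assert mass_near > 0.999

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lm.perfusion_distribution(0.0, 0.5)


class TestCompartment:
    venous_params = bc.BloodParams(hb=11.0)
    venous = bc.blood_state_from_contents(10.5, 52.0, venous_params)

    def test_shunt_compartment_transmits_venous_blood(self):
        comp = lm.equilibrate_compartment(0.0, 0.21, self.venous, self.venous_params)
        assert comp.endcap == self.venous
        assert comp.v_frac == 0.0 and comp.vq == 0.0

    def test_infinite_ventilation_limit(self):
        # alveolar gas approaches inspired gas: PAO2 -> 0.21*713 = 149.73
        comp = lm.equilibrate_compartment(1000.0, 0.21, self.venous,
                                          self.venous_params)
        assert comp.pao2 == pytest.approx(0.21 * C.dry_pressure, abs=2.0)
        assert comp.paco2 < 1.0

    @pytest.mark.parametrize("vq", [0.05, 0.5, 1.0, 10.0])
    def test_flux_conservation(self, vq):
        # gas-side flux equals blood-side flux per unit perfusion
        comp = lm.equilibrate_compartment(vq, 0.4, self.venous, self.venous_params)
        pio2 = 0.4 * C.dry_pressure
        gas_o2 = (comp.vai * pio2 - comp.vq * comp.pao2) / C.k_gas
        gas_co2 = (0.0 - comp.vq * comp.paco2) / C.k_gas
        assert abs(gas_o2 - comp.o2_flux) < 1e-8
        assert abs(-gas_co2 - comp.co2_flux) < 1e-8

    def test_n2_closure(self):
        comp = lm.equilibrate_compartment(0.8, 0.35, self.venous, self.venous_params)
        assert comp.pao2 + comp.paco2 + comp.pan2 == pytest.approx(
            C.dry_pressure, abs=1e-6)


class TestRunForward:
    def test_homogeneous_lung_negligible_admixture(self):
        res = lm.run_forward(make_inputs(shunt=0.0, log_sd=0.01, mean_vq=1.0), 0.21)
        assert res.venad < 0.01

    def test_sao2_decreases_with_shunt(self):
        sats = [lm.run_forward(make_inputs(shunt=s), 0.35).sao2
                for s in (0.05, 0.15, 0.25, 0.35)]
        assert all(a > b for a, b in zip(sats, sats[1:]))

    def test_whole_lung_conservation(self):
        # summed compartment fluxes recover VO2 and VCO2 to 0.1%
        inp = make_inputs()
        res = lm.run_forward(inp, 0.35)
        vo2 = sum(c.q_frac * c.o2_flux for c in res.compartments) * inp.metab.co
        vco2 = sum(c.q_frac * c.co2_flux for c in res.compartments) * inp.metab.co
        assert vo2 == pytest.approx(inp.metab.vo2, rel=1e-3)
        assert vco2 == pytest.approx(inp.metab.vco2, rel=1e-3)

    def test_n2_closure_every_compartment(self):
        res = lm.run_forward(make_inputs(), 0.5)
        for comp in res.compartments:
            if comp.vq > 0:
                assert comp.pao2 + comp.paco2 + comp.pan2 == pytest.approx(
                    C.dry_pressure, abs=1e-6)

    def test_venad_at_least_shunt(self):
        # low V/Q flow is non-negative up to the ideal-compartment tolerance
        for shunt in (0.08, 0.2, 0.3):
            for log_sd in (0.4, 1.0, 1.8):
                res = lm.run_forward(make_inputs(shunt=shunt, log_sd=log_sd), 0.4)
                assert res.venad >= shunt - 0.005

    def test_pure_shunt_limit(self):
        # as dispersion vanishes all admixture becomes true shunt (0.5 pp)
        res = lm.run_forward(make_inputs(shunt=0.15, log_sd=0.02, mean_vq=1.0), 0.30)
        assert res.venad == pytest.approx(0.15, abs=0.005)

    def test_discretization_stability(self):
        inp = make_inputs()
        p20 = lm.run_forward(inp, 0.35).pao2
        p40 = lm.run_forward(inp, 0.35,
                             solver=SolverSettings(n_compartments=40)).pao2
        assert abs(p20 - p40) < 1.0

    def test_fio2_bounds_checked(self):
        with pytest.raises(ValueError):
            lm.run_forward(make_inputs(), 0.1)

    def test_infeasible_scenario_raises(self):
        bad = make_inputs(shunt=0.3, hb=6.0, vco2=223.0, r=0.57, co=4.32)
        with pytest.raises((bc.InfeasibleScenarioError, lm.ConvergenceError)):
            lm.run_forward(bad, 0.9)


class TestVenAd:
    def test_no_admixture(self):
        assert lm.venad(13.0, 13.0, 7.0) == 0.0

    def test_total_admixture(self):
        assert lm.venad(13.0, 7.0, 7.0) == 1.0

    def test_degenerate_contents_rejected(self):
        with pytest.raises(bc.InfeasibleScenarioError):
            lm.venad(6.0, 5.0, 7.0)


class TestTitration:
    def test_in_band_on_air_returns_room_air(self):
        inp = make_inputs(shunt=0.10, log_sd=0.6, mean_vq=0.9)
        sa = lm.run_forward(inp, 0.21).sao2
        assert 0.87 <= sa <= 0.98  # scenario chosen to sit in band on air
        assert lm.titrate_fio2(inp) == 0.21

    def test_sao2_monotone_in_fio2(self):
        inp = make_inputs(shunt=0.2, log_sd=1.4, mean_vq=0.4)
        sats = [lm.run_forward(inp, f).sao2 for f in (0.21, 0.4, 0.6, 0.8, 0.99)]
        assert all(b >= a - 1e-9 for a, b in zip(sats, sats[1:]))

    def test_titrated_fio2_lands_in_band(self):
        inp = make_inputs(shunt=0.2, log_sd=1.6, mean_vq=0.3, hb=8.0)
        f = lm.titrate_fio2(inp, target=0.95)
        sa = lm.run_forward(inp, f).sao2
        assert 0.87 <= sa <= 0.98

    def test_unreachable_band_rejected(self):
        # massive shunt: even pure O2 cannot reach SaO2 0.87
        inp = make_inputs(shunt=0.5, log_sd=0.5, mean_vq=0.6, hb=7.0,
                          vco2=223.0, r=0.6, co=4.4)
        with pytest.raises((lm.ScenarioRejected, bc.InfeasibleScenarioError)):
            lm.titrate_fio2(inp)
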