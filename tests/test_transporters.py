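"""Unit and property tests for the membrane flux laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saliduct import (MembraneEnvironment, channel_flux, exchanger_fluxes,
                      nak_atpase_flux, nernst, paracellular_flux, water_flux,
                      buffer_rate, ion_vector)
from saliduct.constants import FARADAY, IDX, KA_BUFFER, RT_F, SPECIES, Z
from saliduct.transporters import ae_flux, ghk_flux, nbc_flux, nhe_flux


def env(inside=None, outside=None, v=0.0, area=1.0):
    inside = inside if inside is not None else ion_vector(25, 120, 40, 10, 5e-5)
    outside = outside if outside is not None else ion_vector(140, 5, 110, 25, 4e-5)
    return MembraneEnvironment(np.asarray(inside, float),
                               np.asarray(outside, float), v=v, area=area)


concs = st.floats(min_value=0.5, max_value=300.0)
volts = st.floats(min_value=-120.0, max_value=120.0)


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst(12.0, 12.0, 1) == pytest.approx(0.0)

    def test_e_fold_ratio_gives_rt_over_f(self):
        assert nernst(1.0, np.e, 1) == pytest.approx(RT_F)

    def test_valence_antisymmetry(self):
        assert nernst(10.0, 100.0, -1) == pytest.approx(
            -nernst(10.0, 100.0, 1))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            nernst(0.0, 10.0, 1)


class TestChannels:
    @pytest.mark.parametrize("species,z", [("Na", 1), ("K", 1), ("Cl", -1)])
    def test_zero_flux_at_nernst_potential(self, species, z):
        e = env()
        i = IDX[species]
        v_eq = nernst(e.inside[i], e.outside[i], z)
        e.v = v_eq
        fx = channel_flux(e, 50.0, species)
        assert fx.fluxes[i] == pytest.approx(0.0, abs=1e-9)

    def test_zero_conductance_zero_flux(self):
        fx = channel_flux(env(v=-60), 0.0, "Na")
        assert np.all(fx.fluxes == 0)

    def test_linearity_in_conductance(self):
        e = env(v=-30)
        f1 = channel_flux(e, 10.0, "K").fluxes
        f2 = channel_flux(e, 20.0, "K").fluxes
        np.testing.assert_allclose(f2, 2 * f1)

    def test_anion_channel_splits_by_permeability_ratio(self):
        e = env(v=-40)
        fx = channel_flux(e, 10.0, "Cl", p_hco3_ratio=0.3)
        alone = channel_flux(e, 3.0, "Cl").fluxes[IDX["Cl"]]
        # HCO3 branch equals a Cl-only channel at 0.3x conductance applied
        # to the HCO3 gradient
        only_b = ghk_flux(3.0, -1.0, e.inside[IDX["HCO3"]],
                          e.outside[IDX["HCO3"]], e.v)
        assert fx.fluxes[IDX["HCO3"]] == pytest.approx(only_b)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            channel_flux(env(), 1.0, "Ca")

    @given(p=st.floats(0.1, 100), c_in=concs, c_out=concs, v=volts)
    @settings(max_examples=200, deadline=None)
    def test_ghk_thermodynamic_sign(self, p, c_in, c_out, v):
        """Passive flux always follows the electrochemical driving force."""
        for z in (1.0, -1.0):
            v_eq = nernst(c_in, c_out, z)
            f = ghk_flux(p, z, c_in, c_out, v)
            drive = v - v_eq          # >0 pushes cation out
            assert np.sign(f) == pytest.approx(np.sign(np.round(
                drive * z, 12)), abs=0) or abs(f) < 1e-9

    def test_ghk_continuous_at_zero_potential(self):
        lo = ghk_flux(5.0, 1.0, 30.0, 100.0, -1e-7)
        hi = ghk_flux(5.0, 1.0, 30.0, 100.0, 1e-7)
        mid = ghk_flux(5.0, 1.0, 30.0, 100.0, 0.0)
        assert lo == pytest.approx(mid, rel=1e-6)
        assert hi == pytest.approx(mid, rel=1e-6)


class TestPump:
    def test_zero_density_zero_flux(self):
        fx = nak_atpase_flux(env(), 0.0)
        assert np.all(fx.fluxes == 0)

    @given(na=concs, k=concs, v=volts)
    @settings(max_examples=100, deadline=None)
    def test_three_two_stoichiometry(self, na, k, v):
        e = env(inside=ion_vector(na, 120, 40, 10, 5e-5),
                outside=ion_vector(140, k, 110, 25, 4e-5), v=v)
        fx = nak_atpase_flux(e, 7.0)
        assert fx.fluxes[IDX["Na"]] == pytest.approx(
            -1.5 * fx.fluxes[IDX["K"]])

    def test_rate_monotone_saturating_in_internal_na(self):
        """Pump rate rises monotonically with [Na+]_C and saturates below
        the density ceiling (checked against direct evaluation over a
        1-100 mM sweep)."""
        nas = np.linspace(1.0, 100.0, 60)
        rates = []
        for na in nas:
            e = env(inside=ion_vector(na, 120, 40, 10, 5e-5))
            rates.append(nak_atpase_flux(e, 9.0).fluxes[IDX["Na"]] / 3.0)
        rates = np.array(rates)
        assert np.all(np.diff(rates) > 0)
        ceiling = 9.0 * (5.0 / 6.5) ** 2      # density * K saturation
        assert np.all(rates < ceiling)
        assert rates[-1] > 0.6 * ceiling


class TestCarriers:
    def test_symmetric_conditions_zero_flux(self):
        same = ion_vector(100, 10, 60, 15, 5e-5)
        e = MembraneEnvironment(same, same.copy(), v=0.0, area=1.0)
        fx = exchanger_fluxes(e, {"nhe": 5.0, "ae": 5.0})
        assert np.all(np.abs(fx.fluxes) < 1e-12)

    def test_ae_one_to_one_stoichiometry(self):
        fx = ae_flux(env(), 8.0)
        assert fx.fluxes[IDX["Cl"]] == pytest.approx(-fx.fluxes[IDX["HCO3"]])

    def test_nhe_direction_follows_na_gradient(self):
        """At a fixed pH gradient the exchanger reverses with the Na+
        gradient, as the product rule Na_o H_i vs Na_i H_o dictates."""
        inside = ion_vector(25, 120, 40, 10, 5e-5)
        fwd = nhe_flux(env(inside=inside,
                           outside=ion_vector(140, 5, 110, 25, 5e-5)), 4.0)
        rev = nhe_flux(env(inside=inside,
                           outside=ion_vector(2, 5, 110, 25, 5e-5)), 4.0)
        assert fwd.fluxes[IDX["Na"]] < 0       # Na enters the cell
        assert rev.fluxes[IDX["Na"]] > 0       # gradient reversed

    @given(na_i=concs, na_o=concs, b_i=concs, b_o=concs, v=volts)
    @settings(max_examples=150, deadline=None)
    def test_nbc_zero_at_electrochemical_equilibrium(self, na_i, na_o,
                                                     b_i, b_o, v):
        """The cotransporter rate vanishes exactly when the combined
        chemical and electrical driving force is zero, and otherwise has
        its sign."""
        e = env(inside=ion_vector(na_i, 120, 40, b_i, 5e-5),
                outside=ion_vector(na_o, 5, 110, b_o, 4e-5), v=v)
        fx = nbc_flux(e, 6.0)
        # net charge -1 moves inward with the cotransport flux
        drive = RT_F * np.log((na_o * b_o ** 2) / (na_i * b_i ** 2)) + v
        inward = -fx.fluxes[IDX["Na"]]
        if abs(drive) < 1e-9:
            assert abs(inward) < 1e-9
        else:
            assert np.sign(inward) == np.sign(drive)

    def test_electroneutral_carriers_carry_zero_current(self):
        fx = exchanger_fluxes(env(v=-50), {"nhe": 7.0, "ae": 3.0})
        assert fx.current == pytest.approx(0.0, abs=1e-9)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            exchanger_fluxes(env(), {"nhe": -1.0})


class TestWaterAndParacellular:
    def test_water_zero_at_equal_osmolarity(self):
        assert water_flux(300.0, 300.0, 1e-3, 100.0) == 0.0

    def test_water_sign_and_area_linearity(self):
        out = water_flux(290.0, 310.0, 1e-3, 100.0)
        assert out > 0                      # water leaves toward higher osm
        assert water_flux(290.0, 310.0, 1e-3, 200.0) == pytest.approx(2 * out)

    def test_paracellular_zero_without_driving_force(self):
        c = ion_vector(140, 5, 110, 25, 4e-5)
        fx = paracellular_flux(c, c.copy(), 0.0,
                               {"Na": 10.0, "K": 10.0, "Cl": 10.0})
        assert np.all(np.abs(fx.fluxes) < 1e-12)

    def test_blocked_species_rejected_and_zero(self):
        c = ion_vector(140, 5, 110, 25, 4e-5)
        with pytest.raises(ValueError):
            paracellular_flux(c, c, 10.0, {"HCO3": 1.0})
        fx = paracellular_flux(c, 0.5 * c, 30.0, {"Na": 5.0})
        assert fx.fluxes[IDX["HCO3"]] == 0.0
        assert fx.fluxes[IDX["H"]] == 0.0


class TestBuffer:
    def test_equilibrium_gives_zero_rate(self):
        co2 = 1.2
        b = 25.0
        h = KA_BUFFER * co2 / b
        conc = ion_vector(140, 5, 110, b, h)
        rates = buffer_rate(conc, 0.1, co2)
        assert np.all(np.abs(rates) < 1e-12)

    def test_h_and_hco3_rates_equal(self):
        conc = ion_vector(140, 5, 110, 10, 1e-4)
        rates = buffer_rate(conc, 0.5, 1.2)
        assert rates[IDX["H"]] == pytest.approx(rates[IDX["HCO3"]])
        assert np.all(rates[:3] == 0)

    def test_perturbed_compartment_relaxes_monotonically(self):
        """A closed compartment displaced from buffer equilibrium returns
        to it; the late-time approach matches the analytic linearised
        exponential rate."""
        from scipy.integrate import solve_ivp
        co2, k = 1.2, 1e-4           # slow hydration so the decay resolves
        b0, h0 = 20.0, 2e-4          # supra-equilibrium product

        def rhs(t, y):
            conc = ion_vector(0, 0, 0, y[0], y[1])
            r = buffer_rate(conc, k, co2)
            return [r[IDX["HCO3"]], r[IDX["H"]]]

        sol = solve_ivp(rhs, (0, 20), [b0, h0], rtol=1e-10, atol=1e-14,
                        dense_output=True, method="LSODA",
                        t_eval=np.linspace(0, 20, 200))
        b_end, h_end = sol.y[:, -1]
        assert h_end * b_end / co2 == pytest.approx(KA_BUFFER, rel=1e-4)
        diffs = np.diff(sol.y[1])
        assert np.all(diffs <= 1e-12)       # monotone approach
        # linearised relaxation rate near equilibrium: k (B + H)/Ka
        lam = k * (b_end + h_end) / KA_BUFFER
        t1, t2 = 4.0, 5.0
        d1 = sol.sol(t1)[1] - h_end
        d2 = sol.sol(t2)[1] - h_end
        assert np.log(d1 / d2) / (t2 - t1) == pytest.approx(lam, rel=0.05)


class TestChargeBookkeeping:
    @given(v=volts, g=st.floats(0.5, 50))
    @settings(max_examples=100, deadline=None)
    def test_current_equals_faraday_weighted_flux_sum(self, v, g):
        """Reported currents always equal F·Σ z·flux recomputed
        independently, for every mechanism."""
        e = env(v=v)
        for fx in (channel_flux(e, g, "Cl", 0.3), nak_atpase_flux(e, g),
                   exchanger_fluxes(e, {"nhe": g, "ae": g, "nbc": g})):
            assert fx.current == pytest.approx(
                FARADAY * float(np.dot(Z, fx.fluxes)), rel=1e-12, abs=1e-9)
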