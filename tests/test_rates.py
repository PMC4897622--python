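"""Rate-equation engine: mass conservation, equilibrium oracle, monotonicity."""

import math

import numpy as np
import pytest

from cartwheel.geometry import InvalidParameterError
from cartwheel.rates import (
    RateMatrix,
    bd_encounter_rate,
    build_ode_system,
    equilibrium_oracle,
    estimate_diffusive_rates,
    integrate,
)
from cartwheel.reactions import EncounterWindow


@pytest.fixture(scope="module")
def rates():
    return estimate_diffusive_rates()


class TestRateMatrix:
    def test_symmetric_nonnegative(self, rates):
        assert np.allclose(rates.k_ij, rates.k_ij.T)
        assert (rates.k_ij >= 0).all()

    def test_shrinking_window_decreases_rates(self):
        ks = [
            estimate_diffusive_rates(window=EncounterWindow(d, a, a)).k_ij[0, 0]
            for d, a in ((3.0, 75.0), (2.0, 50.0), (1.0, 25.0))
        ]
        assert ks[0] > ks[1] > ks[2]

    def test_larger_chains_react_more_slowly(self, rates):
        diag = np.diag(rates.k_ij)
        assert all(diag[i] > diag[i + 1] for i in range(8))

    def test_bd_route_scales_with_first_passage_measurement(self):
        # the BD-measured monomer rate sets the kernel scale; frozen-orientation
        # window estimate is a lower bound of the dynamical rate
        rm_bd = estimate_diffusive_rates(method="bd", bd_events=25, seed=5)
        rm_w = estimate_diffusive_rates()
        assert rm_bd.k_ij[0, 0] > rm_w.k_ij[0, 0]
        ratio = rm_bd.k_ij / rm_bd.k_ij[0, 0]
        ratio_w = rm_w.k_ij / rm_w.k_ij[0, 0]
        assert np.allclose(ratio, ratio_w, rtol=1e-9)  # same size dependence


class TestOdeSystem:
    def test_mass_conserved_to_1e8(self, rates):
        pops = integrate(build_ode_system(rates, -9.2, 5.0))
        assert np.max(np.abs(pops.total_mass - 5.0)) / 5.0 < 1e-8

    def test_all_rates_zero_concentrations_frozen(self):
        rm = RateMatrix(k_ij=np.zeros((9, 9)), kd_um=60.0, c_eff_um=1e5)
        pops = integrate(build_ode_system(rm, 0.0, 5.0), t_end=10.0)
        assert np.allclose(pops.concentrations[-1, 0], 5.0)
        assert np.allclose(pops.concentrations[-1, 1:], 0.0)

    def test_unbreakable_bonds_make_ring_absorbing(self, rates):
        # with k_off = 0 the ring never opens and its mass is monotone
        # nondecreasing; full conversion is not guaranteed (irreversible
        # coagulation jams in non-co-reactive chain sizes), but the ring
        # ends up the dominant state
        rm = RateMatrix(k_ij=rates.k_ij, kd_um=0.0, c_eff_um=rates.c_eff_um)
        system = build_ode_system(rm, 0.0, 50.0)
        assert math.isinf(system.rho) and system.open_fraction == 0.0
        pops = integrate(system, t_end=50.0)
        ring = pops.ring_fraction
        assert np.all(np.diff(ring) > -1e-12)
        assert ring[-1] > 1.0 / 3.0
        assert ring[-1] == max(pops.relative_populations[-1])

    def test_positive_ring_energy_rejected(self, rates):
        with pytest.raises(InvalidParameterError):
            build_ode_system(rates, +1.0, 5.0)

    def test_stabilization_increases_ring_fraction(self, rates):
        f0 = integrate(build_ode_system(rates, 0.0, 5.0)).ring_fraction[-1]
        f92 = integrate(build_ode_system(rates, -9.2, 5.0)).ring_fraction[-1]
        assert f92 > f0

    def test_steady_state_monotone_in_energy_and_concentration(self, rates):
        by_e = [
            equilibrium_oracle(1 / 60.0, e, 5.0, rates.c_eff_um)[9]
            for e in (0.0, -9.2, -13.8)
        ]
        assert by_e[0] < by_e[1] < by_e[2]
        by_c = [
            9 * equilibrium_oracle(1 / 60.0, -9.2, c, rates.c_eff_um)[9] / c
            for c in (1.0, 5.0, 75.0)
        ]
        assert by_c[0] < by_c[1] < by_c[2]


class TestEquilibriumOracle:
    def test_dilute_limit_all_monomer(self):
        c = equilibrium_oracle(1 / 60.0, 0.0, 1e-9)
        assert c[0] / 1e-9 == pytest.approx(1.0, rel=1e-4)

    def test_infinite_stabilization_all_ring(self):
        fracs = [9 * equilibrium_oracle(1 / 60.0, e, 5.0)[9] / 5.0 for e in (-60.0, -120.0)]
        assert fracs[0] < fracs[1]
        assert fracs[1] == pytest.approx(1.0, rel=1e-3)

    @pytest.mark.parametrize(
        "kd,e,c0", [(60.0, 0.0, 75.0), (60.0, -9.2, 5.0), (60.0, -13.8, 5.0), (10.0, -5.0, 20.0)]
    )
    def test_ode_steady_state_matches_oracle(self, kd, e, c0):
        from cartwheel.reactions import AffinityCalibration

        rm = estimate_diffusive_rates(calibration=AffinityCalibration(kd_nn=kd))
        pops = integrate(build_ode_system(rm, e, c0))
        want = equilibrium_oracle(1.0 / kd, e, c0, rm.c_eff_um)
        got = pops.final()
        scale = np.maximum(np.abs(want), 1e-12 * c0)
        assert np.max(np.abs(got - want) / scale) < 1e-6


class TestPopulations:
    def test_relative_populations_sum_to_one(self, rates):
        pops = integrate(build_ode_system(rates, 0.0, 75.0), t_end=1.0)
        assert np.allclose(pops.relative_populations.sum(axis=1), 1.0)

    def test_bulk_75_uM_dimers_trimers_dominate_oligomers(self, rates):
        pops = integrate(build_ode_system(rates, 0.0, 75.0), t_end=1.0)
        p = pops.relative_populations[-1]
        chains = p[1:9]  # oligomer sizes 2..9
        assert set(np.argsort(chains)[-2:]) == {0, 1}  # sizes 2 and 3

    def test_bulk_5_uM_monomers_dominate(self, rates):
        pops = integrate(build_ode_system(rates, 0.0, 5.0), t_end=1.0)
        p = pops.relative_populations[-1]
        assert p[0] > 0.8 and p[0] == max(p)


class TestBdEncounterRate:
    def test_first_passage_rate_is_diffusion_limited_scale(self):
        # the dynamical rate lies between the frozen-orientation window
        # estimate and the full-contact Smoluchowski bound
        k, (lo, hi) = bd_encounter_rate(n_events=25, seed=11)
        rm = estimate_diffusive_rates()
        from cartwheel.species import build_species_tables
        from cartwheel.units import NM3_PER_NS_TO_PER_UM_S

        d1 = build_species_tables()[0].diffusion.d_trans_mean
        smol_contact = 4 * math.pi * (2 * d1) * 8.0 * NM3_PER_NS_TO_PER_UM_S
        assert rm.k_ij[0, 0] < k < smol_contact
        assert lo < k < hi
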