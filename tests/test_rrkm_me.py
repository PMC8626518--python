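"""RRKM k(E), LJ collisions, master equation, and canonical TST."""
import math
from dataclasses import replace

import numpy as np
import pytest

from stabkin import constants as const
from stabkin.eckart_tunneling import EckartBarrier
from stabkin.fixtures import WATER_BATH, FixtureSpec, make_two_pathway_network, \
    make_toy_species
from stabkin.network_kinetics import DEFAULT_T_GRID
from stabkin.rrkm_me import (CollisionModel, boltzmann_average, k_hpl,
                             k_micro, lj_collision_frequency,
                             network_hpl_rates, solve_me, _omega22)
from stabkin.state_counting import EnergyGrid, count_states
from stabkin.thermo_rrho import reaction_free_energy


def _snapped_pair(seed: int, grain: float):
    """Toy well/TS pair with grain-commensurate frequencies (so the grained
    and analytic partition functions agree exactly)."""
    spec = FixtureSpec(seed=seed, n_modes=8)
    well = make_toy_species(spec, "intermediate", label="W", offset=0)
    ts = make_toy_species(spec, "transition_state", label="TS", offset=1)
    snap = lambda fs: tuple(round(f / grain) * grain for f in fs)
    well = replace(well, frequencies=snap(well.frequencies),
                   rotational_constants=())
    ts = replace(ts, frequencies=snap(ts.frequencies), rotational_constants=())
    return well, ts


class TestKMicro:
    def test_zero_below_critical_energy(self):
        grid = EnergyGrid(grain=10.0, e_max=2000.0)
        w = count_states([100.0, 200.0], grid)
        g = count_states([150.0], grid)
        curve = k_micro(1.0, g, w, E0=1000.0)
        assert np.all(curve.k_of_E[: grid.index(1000.0)] == 0.0)

    def test_linearity_in_path_degeneracy(self):
        grid = EnergyGrid(grain=10.0, e_max=2000.0)
        w = count_states([100.0, 200.0], grid)
        g = count_states([150.0], grid)
        k1 = k_micro(1.0, g, w, E0=300.0)
        k2 = k_micro(2.0, g, w, E0=300.0)
        np.testing.assert_allclose(k2.k_of_E, 2.0 * k1.k_of_E)

    def test_hand_evaluated_bin(self):
        # well {100, 200}, TS {150}, E0 = 300 cm^-1, at E = 500 cm^-1:
        # G*(200) = floor(200/150)+1 = 2; well states in [500, 510):
        # (5,0), (3,1), (1,2) -> N = 3/10 per cm^-1; k = 2/(h N)
        grid = EnergyGrid(grain=10.0, e_max=1000.0)
        w = count_states([100.0, 200.0], grid)
        g = count_states([150.0], grid)
        curve = k_micro(1.0, g, w, E0=300.0)
        h_cm = 1.0 / const.SPEED_OF_LIGHT_CM_S
        expected = 2.0 / (h_cm * 0.3)
        assert curve.k_of_E[grid.index(500.0)] == pytest.approx(expected, rel=1e-12)


class TestCollisions:
    def test_combining_rules_water_solute(self):
        # water (2.74 A, 506 K) + furanone solute (5.34 A, 519.88 K)
        sigma12 = 0.5 * (2.74 + 5.34)
        eps12 = math.sqrt(506.0 * 519.88)
        assert sigma12 == pytest.approx(4.04)
        assert eps12 == pytest.approx(512.89, abs=0.01)

    def test_omega22_against_tabulated_values(self):
        # classic reduced-collision-integral table points
        assert _omega22(1.0) == pytest.approx(1.593, abs=0.01)
        assert _omega22(2.0) == pytest.approx(1.176, abs=0.01)
        assert _omega22(10.0) == pytest.approx(0.8242, abs=0.01)

    def test_linear_in_number_density(self):
        z1 = lj_collision_frequency(WATER_BATH, (5.34, 519.88), 100.0, 298.15)
        denser = replace(WATER_BATH, number_density=2 * WATER_BATH.number_density)
        z2 = lj_collision_frequency(denser, (5.34, 519.88), 100.0, 298.15)
        assert z2 == pytest.approx(2.0 * z1, rel=1e-12)

    def test_liquid_water_collision_frequency_magnitude(self):
        # ~1e13 s^-1 in liquid water: collisions vastly outrun reaction
        z = lj_collision_frequency(WATER_BATH, (5.44, 580.79), 99.0, 298.15)
        assert 1e12 < z < 1e15

    def test_nonpositive_temperature_raises(self):
        with pytest.raises(ValueError):
            lj_collision_frequency(WATER_BATH, (5.34, 519.88), 100.0, -1.0)


class TestTwoRouteEquivalence:
    @pytest.mark.parametrize("T", [300.0, 360.0])
    def test_boltzmann_average_matches_tst(self, T):
        grain = 10.0
        well, ts = _snapped_pair(3, grain)
        e0_kcal = 20.0
        e0_cm = e0_kcal * const.KCAL_TO_CM
        grid = EnergyGrid(grain=grain, e_max=e0_cm + 100000.0)
        nw = count_states(well.frequencies, grid)
        gt = count_states(ts.frequencies, grid)
        curve = k_micro(1.0, gt, nw, e0_cm)
        assert boltzmann_average(curve, nw, T) == pytest.approx(
            k_hpl(well, ts, e0_kcal, T), rel=0.01)


class TestMasterEquation:
    @staticmethod
    def _setup(T=320.0, grain=20.0, e0_kcal=15.0):
        well, ts = _snapped_pair(3, grain)
        e0_cm = e0_kcal * const.KCAL_TO_CM
        kt_cm = T / const.CM_TO_K
        grid = EnergyGrid(grain=grain, e_max=e0_cm + 40.0 * kt_cm)
        nw = count_states(well.frequencies, grid)
        gt = count_states(ts.frequencies, grid)
        curve = k_micro(1.0, gt, nw, e0_cm)
        return curve, nw, T

    def test_high_omega_limit_matches_hpl(self):
        curve, nw, T = self._setup()
        khpl = boltzmann_average(curve, nw, T)
        omega = 1e6 * float(curve.k_of_E.max())
        k_me = solve_me([curve], CollisionModel(omega=omega, delta_e_down=200.0),
                        nw, T)[0]
        assert k_me == pytest.approx(khpl, rel=0.005)

    def test_all_zero_micro_rates_give_zero(self):
        curve, nw, T = self._setup()
        dead = replace(curve, k_of_E=np.zeros_like(curve.k_of_E))
        rates = solve_me([dead], CollisionModel(omega=1e12, delta_e_down=200.0),
                         nw, T)
        assert rates == [0.0]

    def test_falloff_bounded_by_hpl_and_monotone_in_omega(self):
        curve, nw, T = self._setup()
        khpl = boltzmann_average(curve, nw, T)
        prev = 0.0
        for omega in (1e9, 1e11, 1e13, 1e15):
            k_me = solve_me([curve],
                            CollisionModel(omega=omega, delta_e_down=200.0),
                            nw, T)[0]
            assert k_me <= khpl * (1 + 1e-6)
            assert k_me >= prev
            prev = k_me

    def test_two_channels_partition_total_loss(self):
        curve, nw, T = self._setup()
        half = replace(curve, k_of_E=0.5 * curve.k_of_E)
        cm = CollisionModel(omega=1e13, delta_e_down=200.0)
        both = solve_me([half, half], cm, nw, T)
        assert both[0] == pytest.approx(both[1], rel=1e-9)
        one = solve_me([curve], cm, nw, T)[0]
        assert sum(both) == pytest.approx(one, rel=1e-6)


class TestCanonicalTst:
    def test_prefactor_limit(self):
        sp = make_toy_species(FixtureSpec(seed=5), "intermediate", label="X")
        k = k_hpl(sp, sp, 0.0, 298.15)
        assert k == pytest.approx(const.KB_OVER_H * 298.15, rel=1e-12)
        assert k == pytest.approx(6.21e12, rel=1e-3)

    def test_rt_ln10_barrier_increment_divides_rate_by_ten(self):
        well, ts = _snapped_pair(9, 10.0)
        k1 = k_hpl(well, ts, 10.0, 298.15)
        k2 = k_hpl(well, ts, 11.364, 298.15)
        assert k1 / k2 == pytest.approx(10.0, rel=5e-3)

    def test_tunneling_raises_rate(self):
        well, ts = _snapped_pair(9, 10.0)
        barrier = EckartBarrier(10.0, 20.0, 1500.0)
        assert k_hpl(well, ts, 10.0, 298.15, tunneling=barrier) > \
            k_hpl(well, ts, 10.0, 298.15)


class TestNetworkRates:
    def test_detailed_balance_across_grid(self, toy_network):
        for T in DEFAULT_T_GRID:
            rs = network_hpl_rates(toy_network, T, level="toy")
            for i in range(1, 5):
                dg = reaction_free_energy(toy_network, rs.labels[i - 1],
                                          rs.labels[i], T, "toy")
                expected = math.exp(-dg / (const.R_KCAL * T))
                assert rs.k[i] / rs.k_rev[i] == pytest.approx(expected, rel=1e-3)

    def test_all_channels_increase_with_temperature(self, toy_network):
        sets = [network_hpl_rates(toy_network, T, level="toy")
                for T in DEFAULT_T_GRID]
        for i in range(1, 5):
            fwd = [rs.k[i] for rs in sets]
            rev = [rs.k_rev[i] for rs in sets]
            assert all(b > a for a, b in zip(fwd, fwd[1:]))
            assert all(b > a for a, b in zip(rev, rev[1:]))
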