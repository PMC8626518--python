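"""Eckart transmission: closed form vs numerical scattering, kappa limits."""
import math

import numpy as np
import pytest

from stabkin import constants as const
from stabkin.eckart_tunneling import (EckartBarrier, kappa, transmission,
                                      tunneling_corrected_sum)
from stabkin.scattering import numerical_transmission
from stabkin.state_counting import EnergyGrid, count_states

FIXTURE_BARRIERS = [
    EckartBarrier(5.0, 5.0, 1200.0),
    EckartBarrier(12.0, 30.0, 1550.0),
    EckartBarrier(19.3, 40.2, 1700.0),
    EckartBarrier(8.0, 3.0, 900.0),
]


class TestTransmission:
    @pytest.mark.parametrize("barrier", FIXTURE_BARRIERS)
    def test_classical_limit(self, barrier):
        assert transmission(barrier, 100.0 * barrier.v_forward) == pytest.approx(
            1.0, abs=1e-6)

    @pytest.mark.parametrize("barrier", FIXTURE_BARRIERS)
    def test_tunneling_below_barrier_is_positive(self, barrier):
        e = max(0.05, barrier.v_forward - barrier.v_reverse + 0.05)
        assert 0.0 < transmission(barrier, e) < 1.0

    def test_below_exothermicity_floor_is_zero(self):
        barrier = EckartBarrier(20.0, 5.0, 1400.0)  # endothermic by 15
        assert transmission(barrier, 10.0) == 0.0

    def test_symmetric_barrier_against_numerov_oracle(self):
        barrier = EckartBarrier(5.0, 5.0, 1200.0)
        closed = transmission(barrier, 2.5)
        numeric = numerical_transmission(barrier, 2.5)
        assert closed == pytest.approx(numeric, rel=1e-4)

    @pytest.mark.parametrize("barrier", FIXTURE_BARRIERS)
    def test_monotone_nondecreasing_in_energy(self, barrier):
        floor = max(0.0, barrier.v_forward - barrier.v_reverse)
        es = np.linspace(floor + 0.01, 3.0 * barrier.v_forward, 200)
        ps = [transmission(barrier, e) for e in es]
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("barrier", FIXTURE_BARRIERS)
    def test_detailed_balance_symmetry(self, barrier):
        # P(E; Vf, Vr) == P(E - (Vf - Vr); Vr, Vf)
        swapped = EckartBarrier(barrier.v_reverse, barrier.v_forward,
                                barrier.nu_imag)
        shift = barrier.v_forward - barrier.v_reverse
        for e in (0.6 * barrier.v_forward, barrier.v_forward,
                  2.0 * barrier.v_forward):
            if e <= max(0.0, shift) or (e - shift) <= 0:
                continue
            assert transmission(barrier, e) == pytest.approx(
                transmission(swapped, e - shift), rel=1e-10)

    def test_oracle_equivalence_random_barriers(self):
        # closed form vs Numerov scattering across seeded random barriers
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(8):
            vf = rng.uniform(3.0, 25.0)
            vr = rng.uniform(3.0, 25.0)
            nu = rng.uniform(800.0, 2000.0)
            barrier = EckartBarrier(vf, vr, nu)
            floor = max(0.0, vf - vr)
            for frac in (0.6, 1.0, 1.5):
                e = floor + frac * (vf - floor + 1.0)
                p_closed = transmission(barrier, e)
                p_num = numerical_transmission(barrier, e)
                if p_num > 1e-12:
                    worst = max(worst, abs(p_closed - p_num) / p_num)
        assert worst < 1e-3


class TestKappa:
    def test_vanishing_curvature_is_classical(self):
        assert kappa(EckartBarrier(10.0, 10.0, 1.0), 300.0) == pytest.approx(
            1.0, abs=1e-3)

    def test_high_temperature_limit(self):
        assert kappa(EckartBarrier(5.0, 5.0, 1200.0), 1e5) == pytest.approx(
            1.0, abs=1e-3)

    def test_wigner_limit_for_thick_symmetric_barrier(self):
        # kappa ~ 1 + u^2/24 at u = h c nu / k T = 0.5
        T = 300.0
        nu = 0.5 * T / const.CM_TO_K
        wigner = 1.0 + 0.5**2 / 24.0
        assert kappa(EckartBarrier(30.0, 30.0, nu), T) == pytest.approx(
            wigner, rel=0.10)

    @pytest.mark.parametrize("barrier", FIXTURE_BARRIERS)
    def test_monotone_nonincreasing_in_temperature(self, barrier):
        ts = np.geomspace(100.0, 2000.0, 12)
        ks = [kappa(barrier, t) for t in ts]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(ks, ks[1:]))

    def test_greater_than_one_at_room_temperature(self):
        assert kappa(EckartBarrier(12.0, 30.0, 1550.0), 298.15) > 1.0


class TestMicrocanonicalSum:
    @staticmethod
    def _step_reference(ts_counts, v1_cm, grid):
        # classical shifted sum through the same center-sampled convolution
        g, n = grid.grain, grid.n_bins
        step = np.array([1.0 if (k + 0.5) * g >= v1_cm else 0.0
                         for k in range(n)])
        return np.convolve(ts_counts.counts[:n], step)[:n]

    def test_reduces_to_shifted_sum_in_classical_limit(self):
        # tiny curvature -> step-function transmission -> exact shifted sum
        grid = EnergyGrid(grain=20.0, e_max=8000.0)
        ts_counts = count_states([400.0, 1000.0], grid)
        barrier = EckartBarrier(10.0, 10.0, 5.0)  # near-classical
        out = tunneling_corrected_sum(ts_counts, barrier, grid)
        expected = self._step_reference(ts_counts, barrier.v1_cm, grid)
        np.testing.assert_allclose(out.W, expected, atol=1e-3)

    def test_enhancement_below_barrier_and_positivity(self):
        grid = EnergyGrid(grain=20.0, e_max=8000.0)
        ts_counts = count_states([500.0], grid)
        barrier = EckartBarrier(10.0, 12.0, 1600.0)
        out = tunneling_corrected_sum(ts_counts, barrier, grid)
        e0_bin = grid.index(barrier.v1_cm)
        assert np.all(out.W >= 0)
        assert out.W[e0_bin - 5] > 0.0  # sub-barrier states contribute

    def test_thermal_average_matches_canonical_kappa(self):
        # Boltzmann ratio of corrected to classical sums equals kappa(T)
        T = 320.0
        grid = EnergyGrid(grain=2.0, e_max=22000.0)
        ts_counts = count_states([300.0, 800.0, 1500.0], grid)
        barrier = EckartBarrier(10.0, 14.0, 1300.0)
        corrected = tunneling_corrected_sum(ts_counts, barrier, grid).W
        classical = self._step_reference(ts_counts, barrier.v1_cm, grid)
        weight = np.exp(-(grid.energies + 0.5 * grid.grain) * const.CM_TO_K / T)
        ratio = np.sum(corrected * weight) / np.sum(classical * weight)
        assert ratio == pytest.approx(kappa(barrier, T), rel=0.01)

    def test_grid_mismatch_raises(self):
        ts_counts = count_states([500.0], EnergyGrid(grain=10.0, e_max=5000.0))
        with pytest.raises(ValueError, match="grid mismatch"):
            tunneling_corrected_sum(ts_counts, EckartBarrier(5.0, 5.0, 1000.0),
                                    EnergyGrid(grain=20.0, e_max=5000.0))
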