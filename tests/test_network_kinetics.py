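"""Steady-state overall rates, half-lives, scans, ranking, ODE oracle."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stabkin.network_kinetics import (RateSet, RateTable, compare_rates,
                                      half_life, ode_reference, overall_rates,
                                      rate_table_from_ratesets,
                                      stability_ranking, temperature_scan)


def _rateset(k, k_rev, T=298.15):
    return RateSet(T=T, k=dict(enumerate(k, 1)), k_rev=dict(enumerate(k_rev, 1)))


positive_rate = st.floats(min_value=1e-20, max_value=1e12,
                          allow_nan=False, allow_infinity=False)


class TestOverallRates:
    def test_unit_rates_telescope(self):
        rs = _rateset([1.0] * 4, [1.0] * 4)
        assert overall_rates(rs) == pytest.approx((1.0, 0.5, 1 / 3, 0.25))

    def test_first_well_rate_is_k1_bit_exact(self):
        k1 = 2.49e-19
        rs = _rateset([k1, 1e4, 8.5e-2, 1e-14], [1e8, 1e-3, 1e2, 1e-2])
        assert overall_rates(rs)[0] == k1  # identical float, not approx

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(positive_rate, min_size=8, max_size=8))
    def test_telescoping_monotonicity(self, vals):
        rs = _rateset(vals[:4], vals[4:])
        obs = overall_rates(rs)
        assert obs[0] == rs.k[1]
        for a, b in zip(obs, obs[1:]):
            assert b <= a

    def test_zero_k1_is_undefined(self):
        rs = _rateset([0.0, 1.0, 1.0, 1.0], [1.0] * 4)
        with pytest.raises(ValueError, match="k1"):
            overall_rates(rs)

    def test_matches_ode_production_slopes_in_separation_regime(self):
        # quasi-steady-state regime: intermediates relax much faster than
        # the entrance step feeds them.  Each composite k_obs treats its
        # target well as a sink, so the chain is truncated at that well
        # before integrating.
        rng = np.random.default_rng(11)
        for _ in range(5):
            k1 = 10.0 ** rng.uniform(-6, -5)
            k = [k1] + list(10.0 ** rng.uniform(0, 2, 3))
            k_rev = list(10.0 ** rng.uniform(1, 3, 3)) + [0.0]
            for m in (2, 3, 4):  # target wells C, D, E
                rs = _rateset(k[:m], k_rev[:m - 1] + [0.0])
                k_obs = overall_rates(rs)[m - 1]
                t0, t1 = 50.0, 60.0  # after relaxation, before A depletion
                traj = ode_reference(rs, [t0, t1])
                slope = (traj[1, m] - traj[0, m]) / (t1 - t0)
                assert slope == pytest.approx(k_obs, rel=0.01)


class TestHalfLife:
    def test_single_channel(self):
        assert half_life([math.log(2.0)]) == pytest.approx(1.0)

    def test_forward_plus_reverse_channels(self):
        # IN2-type well: forward 8.50e-2 plus implied reverse 2.7e-3
        assert half_life([8.50e-2, 2.7e-3]) == pytest.approx(7.90, abs=5e-3)

    @given(st.lists(positive_rate, min_size=1, max_size=5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_doubling_rates_halves_half_life(self, rates):
        assert half_life([2 * r for r in rates]) == pytest.approx(
            half_life(rates) / 2.0, rel=1e-12)

    def test_all_zero_is_infinite(self):
        assert half_life([0.0, 0.0]) == math.inf


class TestCompareRates:
    @pytest.mark.parametrize("a,b,expected", [
        (1.09e-25, 2.49e-19, 4.38e-7),   # entrance channels, furanone vs pyrrolone
        (7.30e7, 2.04e2, 3.58e5),        # second step, thiophenone vs furanone
        (5.13e-32, 6.92e-42, 7.41e9),    # minor pathway, thiophenone vs furanone
    ])
    def test_cross_compound_ratios(self, a, b, expected):
        assert compare_rates(a, b) == pytest.approx(expected, rel=5e-3)

    def test_identity(self):
        assert compare_rates(3.3, 3.3) == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            compare_rates(1.0, 0.0)


class TestOdeReference:
    def test_zero_rates_are_constant(self):
        rs = _rateset([0.0] * 4, [0.0] * 4)
        traj = ode_reference(rs, [0.0, 10.0, 1e6])
        np.testing.assert_allclose(traj[:, 0], 1.0)
        np.testing.assert_allclose(traj[:, 1:], 0.0)

    def test_mass_conservation(self):
        rs = _rateset([1e-3, 1.0, 0.5, 0.1], [10.0, 0.2, 0.05, 0.3])
        traj = ode_reference(rs, np.geomspace(1e-3, 1e4, 20))
        np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-9)

    def test_production_rate_matches_steady_state(self):
        # k1 = 1e-3, k-1 = 10, k2 = 1: Eq.-style k_obs,C = 1/(1/k1 + k-1/(k1 k2))
        rs = _rateset([1e-3, 1.0, 0.0, 0.0], [10.0, 0.0, 0.0, 0.0])
        k_obs_c = 1.0 / (1.0 / 1e-3 + 10.0 / (1e-3 * 1.0))
        traj = ode_reference(rs, [2.0, 3.0])
        slope = (traj[1, 2:].sum() - traj[0, 2:].sum()) / 1.0
        assert slope == pytest.approx(k_obs_c, rel=0.01)


class TestRateTable:
    def test_scan_columns_strictly_increase(self, toy_network):
        table = temperature_scan(toy_network, level="toy")
        for name, arr in table.channels.items():
            assert np.all(np.diff(arr) > 0), name
        for name, arr in table.overall.items():
            assert np.all(np.diff(arr) > 0), name

    def test_single_temperature_grid(self, toy_network):
        table = temperature_scan(toy_network, t_grid=[310.0], level="toy")
        assert table.temperatures.shape == (1,)
        for arr in table.channels.values():
            assert arr.shape == (1,)

    def test_half_life_shorter_than_forward_only_estimate(self, toy_network):
        # exit through forward + reverse channels: implied reverse rate
        # positive means ln2/t1/2 exceeds the forward rate alone
        table = temperature_scan(toy_network, level="toy")
        labels = list(table.half_lives)
        for i, lab in enumerate(labels):
            fwd = table.channels[f"{lab}->{toy_network.pathway_a[i + 2]}"]
            implied_total = math.log(2.0) / table.half_lives[lab]
            assert np.all(implied_total - fwd > 0)


class TestStabilityRanking:
    @staticmethod
    def _table(k_e, k_d=1.0):
        return RateTable(temperatures=np.array([298.15]),
                         overall={"D": np.array([k_d]), "E": np.array([k_e])})

    def test_orders_by_product_formation_rate(self):
        tables = [("first", self._table(1e-30)), ("second", self._table(1e-25)),
                  ("third", self._table(1e-28))]
        assert stability_ranking(tables, 298.15) == ["first", "third", "second"]

    def test_ties_break_by_name(self):
        tables = [("b", self._table(1e-20)), ("a", self._table(1e-20))]
        assert stability_ranking(tables, 298.15) == ["a", "b"]

    def test_penultimate_well_breaks_rate_ties(self):
        tables = [("slowfeed", self._table(1e-20, k_d=1e-5)),
                  ("fastfeed", self._table(1e-20, k_d=1e-2))]
        assert stability_ranking(tables, 298.15) == ["slowfeed", "fastfeed"]
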