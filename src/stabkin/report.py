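"""Headline quantities the package recomputes from its embedded fixtures.

Two groups:

* :func:`scaffold_comparison` — barrier heights, activation parameters and
  cross-compound rate/half-life ratios recomputed from the embedded
  reference tables through the network-model and kinetics operations;
* :func:`pipeline_diagnostics` — oracle agreements and physical-limit
  checks computed by running the full rate pipeline on seeded synthetic
  fixtures (Eckart closed form vs scattering, RRKM thermal average vs
  TST, master equation vs its high-pressure limit, detailed balance).
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from . import constants as const
from .eckart_tunneling import EckartBarrier, transmission
from .fixtures import WATER_BATH, FixtureSpec, make_toy_species, scaffold_network, \
    reference_tables
from .network_kinetics import DEFAULT_T_GRID, compare_rates
from .network_model import barrier_height
from .rrkm_me import (CollisionModel, boltzmann_average, k_hpl, k_micro,
                      lj_collision_frequency, network_hpl_rates, solve_me)
from .scattering import numerical_transmission
from .state_counting import EnergyGrid, count_states
from .thermo_rrho import reaction_free_energy

T_ROOM = "298.15"


def scaffold_comparison() -> dict[str, dict]:
    """Cross-scaffold energetics and kinetics from the embedded tables.

    Energies in kcal/mol; ratios dimensionless; every value is computed
    by the package's own operations on the loaded tables.
    """
    nets = {c: scaffold_network(c) for c in ("pyrrolone", "furanone", "thiophenone")}
    tabs = reference_tables()
    rates, halves = tabs["rates"], tabs["half_lives"]

    def rate(compound, channel):
        return rates[(compound, channel, "A", T_ROOM)]

    out = {
        # pyrrolone second-step isomerization barrier (ZPE-corrected)
        "pyrrolone_step2_barrier_kcal": barrier_height(
            nets["pyrrolone"], "TS2-N", "IN1-N", "E_plus_ZPE", "A"),
        # pyrrolone third-step barrier
        "pyrrolone_step3_barrier_kcal": barrier_height(
            nets["pyrrolone"], "TS3-N", "IN2-N", "E_plus_ZPE", "A"),
        # furanone rate-determining step activation enthalpy
        "furanone_rds_activation_enthalpy_kcal": barrier_height(
            nets["furanone"], "TS4-O", "IN3-O", "H", "A"),
        # entrance-barrier gap between the O and N scaffolds
        "entrance_barrier_gap_o_minus_n_kcal": (
            barrier_height(nets["furanone"], "TS1-O", "R-O", "E_plus_ZPE", "A")
            - barrier_height(nets["pyrrolone"], "TS1-N", "R-N", "E_plus_ZPE", "A")),
        # thiophenone second-step activation free energy
        "thiophenone_step2_activation_g_kcal": barrier_height(
            nets["thiophenone"], "TS2-S", "IN1-S", "G", "A"),
        # thiophenone rate-determining step activation free energy
        "thiophenone_rds_activation_g_kcal": barrier_height(
            nets["thiophenone"], "TS4-S", "IN3-S", "G", "A"),
        # entrance rates: furanone vs pyrrolone (the O scaffold is slower)
        "entrance_rate_ratio_o_over_n": compare_rates(
            rate("furanone", "R-O->IN1-O"), rate("pyrrolone", "R-N->IN1-N")),
        # second step: thiophenone vs furanone
        "step2_rate_ratio_s_over_o": compare_rates(
            rate("thiophenone", "IN1-S->IN2-S"), rate("furanone", "IN1-O->IN2-O")),
        # minor-pathway entrance: thiophenone vs furanone
        "minor_path_rate_ratio_s_over_o": compare_rates(
            rate("thiophenone", "R-S->IN4-S"), rate("furanone", "R-O->IN4-O")),
        # pyrrolone first vs second intermediate half-life
        "halflife_ratio_in1n_over_in2n": compare_rates(
            halves[("pyrrolone", "IN1-N", "A", T_ROOM)],
            halves[("pyrrolone", "IN2-N", "A", T_ROOM)]),
    }
    return {k: float(v) for k, v in out.items()}


def _eckart_oracle_error(rng: np.random.Generator, n_barriers: int = 20) -> float:
    worst = 0.0
    for _ in range(n_barriers):
        vf = float(rng.uniform(3.0, 25.0))
        vr = float(rng.uniform(3.0, 25.0))
        nu = float(rng.uniform(800.0, 2000.0))
        barrier = EckartBarrier(vf, vr, nu)
        floor = max(0.0, vf - vr)
        for frac in (0.7, 1.2):
            e = floor + frac * (vf - floor + 1.0)
            p_num = numerical_transmission(barrier, e)
            if p_num > 1e-12:
                worst = max(worst, abs(transmission(barrier, e) - p_num) / p_num)
    return worst


def _snapped_pair(seed: int, grain: float):
    # moderate frequencies keep the well's ladder quasi-continuous at the
    # barrier energy, which the statistical k(E) treatment assumes
    spec = FixtureSpec(seed=seed, n_modes=10, freq_range=(80.0, 900.0))
    well = make_toy_species(spec, "intermediate", label="W", offset=0)
    ts = make_toy_species(spec, "transition_state", label="TS", offset=1)

    def snap(fs):
        return tuple(round(f / grain) * grain for f in fs)

    return (replace(well, frequencies=snap(well.frequencies),
                    rotational_constants=()),
            replace(ts, frequencies=snap(ts.frequencies),
                    rotational_constants=()))


def pipeline_diagnostics(seed: int = 1) -> dict[str, float]:
    """Oracle agreements and physical-limit checks on seeded fixtures."""
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}

    out["tst_prefactor_298K_s^-1"] = const.KB_OVER_H * 298.15
    out["eckart_oracle_max_rel_err"] = _eckart_oracle_error(rng, 20)

    # two-route equivalence: Boltzmann-averaged RRKM k(E) vs canonical TST
    grain = 10.0
    well, ts = _snapped_pair(seed + 2, grain)
    e0_kcal = 20.0
    e0_cm = e0_kcal * const.KCAL_TO_CM
    grid = EnergyGrid(grain=grain, e_max=e0_cm + 100000.0)
    nw = count_states(well.frequencies, grid)
    gt = count_states(ts.frequencies, grid)
    curve = k_micro(1.0, gt, nw, e0_cm)
    T = 320.0
    out["rrkm_thermal_avg_over_tst"] = (boltzmann_average(curve, nw, T)
                                        / k_hpl(well, ts, e0_kcal, T))

    # master equation vs HPL at the liquid-water collision frequency
    grain_me = 20.0
    well_me, ts_me = _snapped_pair(seed + 2, grain_me)
    e0_me = 15.0 * const.KCAL_TO_CM
    grid_me = EnergyGrid(grain=grain_me, e_max=e0_me + 40.0 * T / const.CM_TO_K)
    nw_me = count_states(well_me.frequencies, grid_me)
    gt_me = count_states(ts_me.frequencies, grid_me)
    curve_me = k_micro(1.0, gt_me, nw_me, e0_me)
    omega = lj_collision_frequency(WATER_BATH, (5.44, 580.79), 99.0, T)
    k_me = solve_me([curve_me], CollisionModel(omega=omega, delta_e_down=200.0),
                    nw_me, T)[0]
    out["liquid_water_collision_freq_s^-1"] = omega
    out["me_over_hpl_at_liquid_omega"] = k_me / boltzmann_average(curve_me, nw_me, T)

    # detailed balance on the synthetic two-pathway network
    from .fixtures import make_two_pathway_network

    net = make_two_pathway_network(FixtureSpec(seed=seed))
    worst_db = 0.0
    for temp in DEFAULT_T_GRID:
        rs = network_hpl_rates(net, temp, level="toy")
        for i in range(1, 5):
            dg = reaction_free_energy(net, rs.labels[i - 1], rs.labels[i],
                                      temp, "toy")
            expected = math.exp(-dg / (const.R_KCAL * temp))
            worst_db = max(worst_db, abs(rs.k[i] / rs.k_rev[i] / expected - 1.0))
    out["detailed_balance_max_rel_dev"] = worst_db
    return out
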