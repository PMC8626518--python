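"""RRKM microcanonical rates, LJ collision frequency, the exponential-down
master equation, and canonical high-pressure-limit (TST) rates.

The microcanonical rate of a unimolecular step is

    k(E) = alpha * G*(E - E0) / (h * N(E)),   E >= E0,

with G* the (tunneling-corrected) sum of states of the activated complex,
N the density of states of the well, E0 the ZPE-corrected critical
energy and alpha the reaction-path degeneracy.  At liquid-phase collision
frequencies the grained master equation collapses onto the
high-pressure limit, where the thermal rate equals canonical TST

    k(T) = alpha * kappa(T) * (kB T / h) * (Q'/Q) * exp(-E0 / kB T).

Both routes are implemented; the suite pins them against each other.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from . import constants as const
from .eckart_tunneling import EckartBarrier, kappa as eckart_kappa
from .network_model import BathModel, ReactionNetwork, Species
from .network_kinetics import RateSet
from .state_counting import EnergyGrid, StateCountTable, count_states
from .thermo_rrho import internal_partition


@dataclass
class MicroRateCurve:
    """k(E) on a grained energy ladder; zero below the critical energy."""

    grid: EnergyGrid
    k_of_E: np.ndarray
    E0: float          # cm^-1
    alpha: float = 1.0


@dataclass(frozen=True)
class CollisionModel:
    """Collision frequency and exponential-down step for the ME."""

    omega: float          # collisions per second per molecule
    delta_e_down: float   # mean energy per down-collision, cm^-1
    bath: BathModel | None = None

    def __post_init__(self) -> None:
        if self.omega <= 0 or self.delta_e_down <= 0:
            raise ValueError("omega and delta_e_down must be positive")


def k_micro(alpha: float, g_star: StateCountTable, n_reactant: StateCountTable,
            E0: float) -> MicroRateCurve:
    """RRKM k(E) = alpha G*(E-E0) / (h N(E)) bin-wise; E0 in cm^-1.

    ``g_star`` is the activated complex's sum-of-states table anchored at
    its own ZPE (the barrier top); ``n_reactant`` the well's table.
    """
    grid = n_reactant.grid
    if g_star.grid.grain != grid.grain:
        raise ValueError("G* and N(E) must share a grain")
    n = grid.n_bins
    w_ts = g_star.W
    w_well = n_reactant.W
    dens = n_reactant.N
    e0_bins = int(round(E0 / grid.grain)) if E0 > 0 else 0
    h_cm = 1.0 / const.SPEED_OF_LIGHT_CM_S  # h in (cm^-1)·s
    k = np.zeros(n)
    g_shift = np.zeros(n)
    if e0_bins < n:
        m = min(n - e0_bins, w_ts.size)
        g_shift[e0_bins:e0_bins + m] = w_ts[:m]
        if e0_bins + m < n:
            g_shift[e0_bins + m:] = w_ts[-1]
    # a well with *no* states at an energy where the TS sum is open is a
    # data inconsistency; isolated empty bins of a sparse direct count at
    # fine grain simply carry no population and contribute k(E) = 0
    bad = (g_shift > 0) & (w_well <= 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"well has no states at bin {i} (E = {i * grid.grain:.0f} cm^-1) "
            "where G* > 0: inconsistent state-count inputs")
    nz = dens > 0
    k[nz] = g_shift[nz] / (h_cm * dens[nz])
    return MicroRateCurve(grid=grid, k_of_E=alpha * k, E0=float(E0), alpha=alpha)


def _omega22(t_star: float) -> float:
    """Reduced collision integral Omega(2,2)*, Neufeld-style analytic fit."""
    if t_star <= 0:
        raise ValueError("reduced temperature must be positive")
    return (1.16145 * t_star ** -0.14874
            + 0.52487 * math.exp(-0.77320 * t_star)
            + 2.16178 * math.exp(-2.43787 * t_star))


def lj_collision_frequency(bath: BathModel, species_lj: tuple[float, float],
                           species_mass: float, T: float) -> float:
    """Lennard-Jones collision rate per solute molecule, s^-1.

    Z = pi sigma12^2 Omega(2,2)*(T*) <v_rel> [M] with the usual combining
    rules sigma12 = (sigma1+sigma2)/2 and eps12 = sqrt(eps1 eps2).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    sigma1, eps1 = species_lj
    sigma12 = 0.5 * (sigma1 + bath.sigma) * 1e-8           # cm
    eps12 = math.sqrt(eps1 * bath.eps_over_k)              # K
    mu = (species_mass * bath.mass / (species_mass + bath.mass)) * const.AMU_KG
    v_rel = math.sqrt(8.0 * const.BOLTZMANN_J_K * T / (math.pi * mu)) * 100.0  # cm/s
    omega22 = _omega22(T / eps12)
    return math.pi * sigma12**2 * omega22 * v_rel * bath.number_density


def boltzmann_average(curve: MicroRateCurve, n_well: StateCountTable,
                      T: float) -> float:
    """Thermal (HPL) rate as the Boltzmann average of k(E) over the well.

    Weights are evaluated at bin centers: binning rounds every state's
    energy down by up to one grain, and the half-grain shift removes the
    resulting first-order bias in the thermal average.
    """
    e = curve.grid.energies + 0.5 * curve.grid.grain
    w = n_well.N * np.exp(-e * const.CM_TO_K / T)
    z = np.sum(w)
    if z <= 0:
        return 0.0
    return float(np.sum(curve.k_of_E * w) / z)


def solve_me(well_curves: list[MicroRateCurve], collision: CollisionModel,
             n_well: StateCountTable, T: float) -> list[float]:
    """Phenomenological thermal rate per exit channel of a single well.

    Energy-grained master equation with the exponential-down transfer
    kernel (up-transitions fixed by detailed balance against the well's
    Boltzmann distribution), solved through the least-negative
    eigenvalue of the full transport-reaction matrix; the eigenvector
    apportions the total loss among channels.
    """
    grid = n_well.grid
    e_full = grid.energies + 0.5 * grid.grain
    kT_cm = T / const.CM_TO_K
    rho_full = np.maximum(n_well.N, 0.0)

    k_tot_full = np.zeros(grid.n_bins)
    for c in well_curves:
        k_tot_full += c.k_of_E
    if not np.any(k_tot_full > 0):
        return [0.0 for _ in well_curves]

    # restrict to bins the well actually populates
    mask = rho_full > 0
    e = e_full[mask]
    boltz = rho_full[mask] * np.exp(-(e - e[0]) / kT_cm)
    boltz /= boltz.sum()
    k_tot = k_tot_full[mask]
    n = e.size

    # exponential-down kernel: down-rates out of column j normalized to
    # omega, up-rates fixed by detailed balance against the Boltzmann
    # distribution (so the collision operator's stationary state is
    # exactly Boltzmann and the high-omega limit is exactly HPL)
    de = e[:, None] - e[None, :]          # de[i, j] = E_i - E_j
    down = np.where(de < 0, np.exp(de / collision.delta_e_down), 0.0)
    col = down.sum(axis=0)
    col[col <= 0] = 1.0
    down /= col                            # column-normalized down part
    with np.errstate(divide="ignore", invalid="ignore"):
        up = down.T * (boltz[:, None] / boltz[None, :])
    up[~np.isfinite(up)] = 0.0
    rate = collision.omega * (down + np.tril(up, -1))
    m = rate - np.diag(rate.sum(axis=0)) - np.diag(k_tot)

    # detailed balance makes D^-1 M D symmetric with D = diag(sqrt(boltz))
    d = np.sqrt(boltz)
    s = m * (d[None, :] / d[:, None])
    s = 0.5 * (s + s.T)
    vals, vecs = eigh(s)
    lead = int(np.argmax(vals))
    g = vecs[:, lead] * d
    if g.sum() < 0:
        g = -g
    g = np.maximum(g, 0.0)
    tot = g.sum()
    if tot <= 0 or not np.isfinite(tot):
        raise ValueError("master-equation eigenvector collapsed; "
                         "conditioning failure (coarsen the grid or raise T)")
    g /= tot
    full = np.zeros(grid.n_bins)
    full[mask] = g
    return [float(np.sum(c.k_of_E * full)) for c in well_curves]


def k_hpl(reactant: Species, ts: Species, E0: float, T: float,
          tunneling: EckartBarrier | None = None, alpha: float = 1.0) -> float:
    """Canonical TST rate constant (s^-1); E0 in kcal/mol (ZPE-corrected).

    k = alpha kappa(T) (kB T/h) (Q'/Q) exp(-E0/kB T) with internal
    (rotational x vibrational x electronic) partition functions; equal
    to the Boltzmann average of k_micro for consistent inputs.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    q_ts = internal_partition(ts, T)
    q_r = internal_partition(reactant, T)
    kap = eckart_kappa(tunneling, T) if tunneling is not None else 1.0
    return (alpha * kap * const.KB_OVER_H * T * (q_ts / q_r)
            * math.exp(-E0 / (const.R_KCAL * T)))


def network_hpl_rates(network: ReactionNetwork, T: float,
                      level: str | None = None,
                      tunneling: str = "canonical") -> RateSet:
    """Forward/reverse HPL rate constants for every step of pathway (a).

    ``tunneling`` is "none" or "canonical" (canonical Eckart kappa applied
    to both directions of each step, as the same barrier governs both).
    """
    if level is None:
        levels = network.levels
        level = levels[0] if levels else ""
    path = network.pathway_a or [s.label for s in network.species.values()
                                 if not s.is_ts]
    steps_by_pair = {}
    for st in network.steps:
        steps_by_pair[(st.from_label, st.to_label)] = (st, False)
        steps_by_pair[(st.to_label, st.from_label)] = (st, True)
    k: dict[int, float] = {}
    k_rev: dict[int, float] = {}
    for i in range(len(path) - 1):
        pair = (path[i], path[i + 1])
        if pair not in steps_by_pair:
            raise KeyError(f"no step connects {pair[0]} and {pair[1]}")
        st, reversed_ = steps_by_pair[pair]
        e_fwd, e_rev = network.step_barriers(st, level)
        if reversed_:
            e_fwd, e_rev = e_rev, e_fwd
            a_f, a_r = st.alpha_rev, st.alpha_fwd
            sp_f, sp_r = network.species[st.to_label], network.species[st.from_label]
        else:
            a_f, a_r = st.alpha_fwd, st.alpha_rev
            sp_f, sp_r = network.species[st.from_label], network.species[st.to_label]
        ts = network.species[st.ts_label]
        barrier = None
        if tunneling == "canonical" and ts.imaginary_frequency:
            barrier = EckartBarrier(max(e_fwd, 1e-10), max(e_rev, 1e-10),
                                    ts.imaginary_frequency)
        k[i + 1] = k_hpl(sp_f, ts, e_fwd, T, tunneling=barrier, alpha=a_f)
        k_rev[i + 1] = k_hpl(sp_r, ts, e_rev, T, tunneling=barrier, alpha=a_r)
    return RateSet(T=T, k=k, k_rev=k_rev, labels=tuple(path))
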