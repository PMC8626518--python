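"""Asymmetric Eckart barrier: transmission probabilities and kappa(T).

The closed-form transmission through the one-dimensional asymmetric Eckart
potential is parameterized by the ZPE-corrected forward/reverse barriers
and the magnitude of the imaginary frequency.  A numerical scattering
solver (Numerov integration through the same potential) serves as an
independent oracle for the closed form; the test suite pins the two
against each other, so no transcribed convention is trusted blindly.

Energies inside this module are in cm^-1 unless noted; the public
``EckartBarrier`` takes kcal/mol, matching the network energy tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from . import constants as const
from .state_counting import EnergyGrid, StateCountTable


@dataclass(frozen=True)
class EckartBarrier:
    """ZPE-corrected barriers (kcal/mol) and imaginary frequency (cm^-1)."""

    v_forward: float
    v_reverse: float
    nu_imag: float

    def __post_init__(self) -> None:
        if self.v_forward <= 0 or self.v_reverse <= 0 or self.nu_imag <= 0:
            raise ValueError("barriers and imaginary frequency must be positive")

    @property
    def v1_cm(self) -> float:
        return self.v_forward * const.KCAL_TO_CM

    @property
    def v2_cm(self) -> float:
        return self.v_reverse * const.KCAL_TO_CM


def _logcosh(x: float) -> float:
    ax = abs(x)
    return ax + math.log1p(math.exp(-2.0 * ax)) - math.log(2.0)


def transmission(barrier: EckartBarrier, E: float) -> float:
    """Transmission probability at total energy E (kcal/mol) above the
    reactant-side ZPE.

    Closed form in the reduced variables alpha_i = 2 pi V_i / (h nu*);
    returns 0 below the exothermicity floor max(0, V1 - V2) where the
    product channel is closed.
    """
    v1, v2 = barrier.v1_cm, barrier.v2_cm
    nu = barrier.nu_imag
    e = E * const.KCAL_TO_CM
    if e <= 0 or e <= v1 - v2:
        return 0.0
    a1 = 2.0 * math.pi * v1 / nu
    a2 = 2.0 * math.pi * v2 / nu
    inv = 1.0 / math.sqrt(a1) + 1.0 / math.sqrt(a2)
    xi = e / v1
    A = 2.0 * math.sqrt(a1 * xi) / inv                      # 2*pi*a
    B = 2.0 * math.sqrt((xi - 1.0) * a1 + a2) / inv          # 2*pi*b
    disc = a1 * a2 - math.pi**2 / 4.0
    lc_apb = _logcosh(A + B)
    num = 1.0 - math.exp(_logcosh(A - B) - lc_apb)
    if disc >= 0.0:
        D = 2.0 * math.sqrt(disc)
        excess = _logcosh(D) - lc_apb
        if excess > 700.0:  # deep tunneling: denominator dominated by cosh(D)
            return min(max(num * math.exp(-excess), 0.0), 1.0)
        den = 1.0 + math.exp(excess)
    else:
        d = 2.0 * math.sqrt(-disc)
        den = 1.0 + math.cos(d) * math.exp(-lc_apb)
    t = num / den
    return min(max(t, 0.0), 1.0)


def kappa(barrier: EckartBarrier, T: float, rel_tol: float = 1e-8) -> float:
    """Canonical tunneling correction factor.

    kappa(T) = exp(V1/kT) / kT * int_0^inf P(E) exp(-E/kT) dE with E from
    the reactant-side ZPE; adaptive quadrature, upper limit 40 kT above
    the barrier top.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    kt_cm = T / const.CM_TO_K
    kt_kcal = kt_cm / const.KCAL_TO_CM
    v1 = barrier.v_forward
    upper = v1 + 40.0 * kt_kcal
    lower = max(0.0, v1 - barrier.v_reverse)

    def integrand(e_kcal: float) -> float:
        # weight relative to the classical step at V1 to avoid overflow
        return transmission(barrier, e_kcal) * math.exp(-(e_kcal - v1) / kt_kcal)

    val, err = quad(integrand, lower, upper, points=[v1],
                    epsrel=rel_tol, epsabs=0.0, limit=200)
    if val <= 0 or (err > 0 and err / val > 1e-4):
        raise RuntimeError(
            f"kappa integral did not converge: value={val:.3e} err={err:.3e}")
    return val / kt_kcal


def tunneling_corrected_sum(ts_counts: StateCountTable, barrier: EckartBarrier,
                            grid: EnergyGrid | None = None) -> StateCountTable:
    """Microcanonical effective sum of states G*(E) with tunneling.

    Each TS rovibrational state with internal energy eps contributes the
    transmission probability evaluated at total energy E - eps (measured
    from the reactant ZPE); with a step-function transmission this reduces
    exactly to the classical shifted sum W_ts(E - E0).
    """
    grid = grid or ts_counts.grid
    if grid.grain != ts_counts.grid.grain:
        raise ValueError("grid mismatch between TS counts and target grid")
    g = grid.grain
    n = grid.n_bins
    counts = np.zeros(n)
    m = min(n, ts_counts.counts.size)
    counts[:m] = ts_counts.counts[:m]
    # P sampled at bin-center total energies from the reactant ZPE; a TS
    # state with internal energy eps_j = j*grain contributes P at offset
    # (i-j) bins, so G_eff is a plain convolution.  Center sampling keeps
    # the thermal average of the corrected sum consistent with kappa(T).
    p = np.array([transmission(barrier, ((k + 0.5) * g) / const.KCAL_TO_CM)
                  for k in range(n)])
    g_eff = np.convolve(counts, p)[:n]
    # store as per-bin increments so W reproduces G_eff (monotone since P is)
    incr = np.maximum(np.diff(np.concatenate([[0.0], g_eff])), 0.0)
    return StateCountTable(grid=grid, counts=incr)
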