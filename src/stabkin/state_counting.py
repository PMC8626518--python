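"""Sums and densities of rovibrational states on a grained energy ladder.

The harmonic vibrational count uses the Beyer–Swinehart direct-count
algorithm: exact within the grain resolution, with states binned by
floor(E/grain) and the zero-point state in bin 0.  Classical external
rotors can be convolved on top; by default external rotations are treated
as adiabatic (not counted).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as const


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform energy ladder above a species' ZPE level (cm^-1)."""

    grain: float = 10.0
    e_max: float = 50000.0

    def __post_init__(self) -> None:
        if self.grain <= 0:
            raise ValueError("grain must be positive")
        if self.e_max < self.grain:
            raise ValueError("e_max must be at least one grain")

    @property
    def n_bins(self) -> int:
        return int(math.ceil(self.e_max / self.grain))

    @property
    def energies(self) -> np.ndarray:
        """Bin-center representative energies (lower edges), cm^-1."""
        return np.arange(self.n_bins) * self.grain

    def index(self, e: float) -> int:
        return int(math.floor(e / self.grain))


@dataclass
class StateCountTable:
    """Cumulative count W(E) and density N(E) (per cm^-1) on one grid.

    ``counts`` holds the number of states in each bin, so
    W[i] = W[i-1] + counts[i] and N[i] = counts[i]/grain.
    """

    grid: EnergyGrid
    counts: np.ndarray

    @property
    def W(self) -> np.ndarray:
        return np.cumsum(self.counts)

    @property
    def N(self) -> np.ndarray:
        return self.counts / self.grid.grain

    def w_at(self, e: float) -> float:
        """W at energy e (cm^-1); 0 below the zero-point level."""
        if e < 0:
            return 0.0
        i = min(self.grid.index(e), self.grid.n_bins - 1)
        return float(self.W[i])


def count_states(frequencies, grid: EnergyGrid) -> StateCountTable:
    """Beyer–Swinehart direct count of harmonic vibrational states.

    W(E) equals the number of non-negative integer occupation vectors n
    with sum(n_i nu_i) <= E, exactly, up to the grain rounding of each
    frequency onto the ladder.
    """
    freqs = [float(f) for f in frequencies]
    if any(f <= 0 for f in freqs):
        raise ValueError("frequencies must be positive")
    if freqs and grid.grain > min(freqs):
        warnings.warn(
            f"grain {grid.grain} cm^-1 exceeds the smallest frequency "
            f"{min(freqs)} cm^-1; resolution loss", stacklevel=2)
    n = grid.n_bins
    t = np.zeros(n, dtype=float)
    t[0] = 1.0  # zero-point state
    for f in freqs:
        r = max(1, int(round(f / grid.grain)))
        for i in range(r, n):
            t[i] += t[i - r]
    return StateCountTable(grid=grid, counts=t)


def _classical_rotor_density(rotational_constants, symmetry_number: int,
                             energies: np.ndarray) -> np.ndarray:
    """Classical rotational density of states rho(E) per cm^-1.

    1-D free rotor: rho = 1/(sigma sqrt(B E)); 2-D (linear): rho = 1/(sigma B);
    3-D asymmetric top: rho = 2 sqrt(E) / (sigma sqrt(B1 B2 B3)).
    """
    B = [float(b) for b in rotational_constants]
    if any(b <= 0 for b in B):
        raise ValueError("rotational constants must be positive")
    sigma = float(symmetry_number)
    e = np.maximum(energies, 1e-300)
    if len(B) == 1:
        return 1.0 / (sigma * np.sqrt(B[0] * e))
    if len(B) == 2:
        return np.full_like(e, 1.0 / (sigma * B[0]))  # linear: rho = 1/(sigma B)
    if len(B) == 3:
        return 2.0 * np.sqrt(e) / (sigma * math.sqrt(B[0] * B[1] * B[2]))
    raise ValueError("1-3 rotational constants required")


def convolve_classical_rotor(table: StateCountTable, rotational_constants,
                             symmetry_number: int = 1) -> StateCountTable:
    """Convolve vibrational counts with a classical rotational density.

    With no rotational constants the input is returned unchanged (identity
    element of the convolution).
    """
    if not rotational_constants:
        if symmetry_number != 1:
            return StateCountTable(table.grid, table.counts / symmetry_number)
        return table
    grid = table.grid
    # bin-integrated rotor counts: integrate rho over each bin analytically
    edges = np.arange(grid.n_bins + 1) * grid.grain
    B = [float(b) for b in rotational_constants]
    if any(b <= 0 for b in B):
        raise ValueError("rotational constants must be positive")
    sigma = float(symmetry_number)
    if len(B) == 1:
        cum = 2.0 * np.sqrt(edges / B[0]) / sigma          # W_rot(E) = 2 sqrt(E/B)/sigma
    elif len(B) == 2:
        cum = edges / (sigma * B[0])
    elif len(B) == 3:
        cum = (4.0 / 3.0) * edges ** 1.5 / (sigma * math.sqrt(B[0] * B[1] * B[2]))
    else:
        raise ValueError("1-3 rotational constants required")
    rot_counts = np.diff(cum)
    conv = np.convolve(table.counts, rot_counts)[: grid.n_bins]
    return StateCountTable(grid=grid, counts=conv)


def brute_force_count(frequencies, e_max: float) -> int:
    """Explicit enumeration oracle: number of occupation vectors with
    sum(n_i nu_i) <= e_max.  Exponential cost; only for tiny systems."""
    freqs = sorted(float(f) for f in frequencies)
    if not freqs:
        return 1 if e_max >= 0 else 0
    if e_max < 0:
        return 0

    def rec(i: int, remaining: float) -> int:
        if i == len(freqs):
            return 1
        total = 0
        n_max = int(math.floor(remaining / freqs[i] + 1e-9))
        for n in range(n_max + 1):
            total += rec(i + 1, remaining - n * freqs[i])
        return total

    return rec(0, float(e_max))
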