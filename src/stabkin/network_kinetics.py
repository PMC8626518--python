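"""Steady-state network kinetics: overall rate constants, half-lives,
temperature scans, cross-compound comparison and stability ranking.

For the sequential scheme A <=> B <=> C <=> D <=> E (reactant, three
intermediates, product) the steady-state approximation gives composite
overall rate constants for the production of each downstream well:

    1/k_obs,B = 1/k1
    1/k_obs,C = 1/k1 + k-1/(k1 k2)
    1/k_obs,D = 1/k_obs,C + k-1 k-2/(k1 k2 k3)
    1/k_obs,E = 1/k_obs,D + k-1 k-2 k-3/(k1 k2 k3 k4)

Each added reciprocal term is nonnegative, so k_obs telescopes
monotonically down the chain.  A matrix-exponential integration of the
full linear system is provided as the numerical oracle.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

INF_HALF_LIFE = math.inf


@dataclass
class RateSet:
    """Forward/reverse rate constants of one sequential chain at one T.

    ``k[i]`` and ``k_rev[i]`` (1-based step index) in s^-1; ``labels``
    names the wells A..E in order (e.g. R, IN1, IN2, IN3, P).
    """

    T: float
    k: dict[int, float]
    k_rev: dict[int, float]
    labels: tuple[str, ...] = ("A", "B", "C", "D", "E")

    @property
    def n_steps(self) -> int:
        return len(self.k)


def overall_rates(rs: RateSet) -> tuple[float, ...]:
    """Steady-state overall production rate constants down the chain.

    Returns one k_obs per downstream well (B, C, D, E for a 4-step
    chain); k_obs,B == k1 identically.  Raises ZeroDivisionError-style
    ValueError when a needed forward rate is zero with a nonzero
    upstream term.
    """
    n = rs.n_steps
    if rs.k.get(1, 0.0) <= 0.0:
        raise ValueError("k1 must be positive for overall rates to be defined")
    out: list[float] = []
    inv = 1.0 / rs.k[1]
    out.append(rs.k[1])  # k_obs,B = k1, bit-exact
    num = 1.0           # running product k-1 ... k-(i-1)
    den = rs.k[1]       # running product k1 ... k(i-1)
    for i in range(2, n + 1):
        num *= rs.k_rev[i - 1]
        if rs.k[i] <= 0.0 and num > 0.0:
            raise ValueError(f"k{i} = 0 with a nonzero upstream term: "
                             f"k_obs undefined for well {i}")
        den *= rs.k[i] if rs.k[i] > 0 else 1.0
        if rs.k[i] > 0:
            inv += num / den
        # each reciprocal adds a nonnegative term, so the sequence is
        # nonincreasing; clamp the one-ulp float rounding of 1/(1/k)
        out.append(min(out[-1], 1.0 / inv))
    return tuple(out)


def half_life(out_rates) -> float:
    """t1/2 = ln2 / sum of all first-order exit rates of the species.

    All exit channels (forward and reverse) are summed; an all-zero set
    returns the infinite-half-life sentinel.
    """
    rates = [float(r) for r in out_rates]
    if any(r < 0 for r in rates):
        raise ValueError("decay rates must be nonnegative")
    total = sum(rates)
    if total == 0.0:
        return INF_HALF_LIFE
    return math.log(2.0) / total


def compare_rates(value_a: float, value_b: float) -> float:
    """Ratio a/b for cross-compound rate or half-life comparison."""
    if value_b == 0:
        raise ZeroDivisionError("comparison denominator is zero")
    return value_a / value_b


@dataclass
class RateTable:
    """k(T) per channel, overall k_obs(T) per well, and half-lives.

    ``channels`` maps channel name -> array over the temperature grid;
    ``overall`` maps well label -> k_obs array; ``half_lives`` maps
    intermediate label -> t1/2 array.
    """

    temperatures: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    overall: dict[str, np.ndarray] = field(default_factory=dict)
    half_lives: dict[str, np.ndarray] = field(default_factory=dict)
    level: str = ""

    def at(self, mapping: str, name: str, T: float) -> float:
        arr = getattr(self, mapping)[name]
        idx = int(np.argmin(np.abs(self.temperatures - T)))
        if abs(self.temperatures[idx] - T) > 1e-6:
            raise KeyError(f"temperature {T} not on the grid")
        return float(arr[idx])


DEFAULT_T_GRID = (298.15, 300.0, 310.0, 320.0, 330.0, 340.0, 350.0, 360.0)


def rate_table_from_ratesets(ratesets: list[RateSet], level: str = "") -> RateTable:
    """Assemble a RateTable from per-temperature RateSets of one chain."""
    ts = np.array([rs.T for rs in ratesets])
    n = ratesets[0].n_steps
    labels = ratesets[0].labels
    table = RateTable(temperatures=ts, level=level)
    for i in range(1, n + 1):
        fwd = np.array([rs.k[i] for rs in ratesets])
        rev = np.array([rs.k_rev[i] for rs in ratesets])
        table.channels[f"{labels[i - 1]}->{labels[i]}"] = fwd
        table.channels[f"{labels[i]}->{labels[i - 1]}"] = rev
    ov = np.array([overall_rates(rs) for rs in ratesets])
    for j in range(n):
        table.overall[labels[j + 1]] = ov[:, j]
    for j in range(1, n):  # intermediates only
        exits = np.array([rs.k[j + 1] + rs.k_rev[j] for rs in ratesets])
        table.half_lives[labels[j]] = np.array(
            [half_life([e]) for e in exits])
    return table


def temperature_scan(network, t_grid=DEFAULT_T_GRID, level: str | None = None,
                     tunneling: str = "canonical") -> RateTable:
    """Compute per-channel HPL rates, overall rates, and half-lives over a
    temperature grid for the wells of pathway (a) of a network.

    Requires full rovibrational species records; delegates the per-step
    rate constants to :func:`stabkin.rrkm_me.network_hpl_rates`.
    """
    from .rrkm_me import network_hpl_rates

    ratesets = [network_hpl_rates(network, float(T), level=level,
                                  tunneling=tunneling)
                for T in t_grid]
    return rate_table_from_ratesets(ratesets, level=level or "")


def stability_ranking(tables: list[tuple[str, RateTable]], T: float) -> list[str]:
    """Rank compounds most chemically resistant first.

    Ascending k_obs for final-product formation (slower product
    formation = more resistant); ties broken by the penultimate well's
    k_obs, then by name.
    """
    keyed = []
    for name, tab in tables:
        wells = list(tab.overall)
        if not wells:
            raise ValueError(f"{name}: table has no overall rates")
        k_e = tab.at("overall", wells[-1], T)
        k_d = tab.at("overall", wells[-2], T) if len(wells) > 1 else 0.0
        keyed.append((k_e, k_d, name))
    return [name for _, _, name in sorted(keyed)]


def ode_reference(rs: RateSet, t_grid) -> np.ndarray:
    """Concentration trajectories of the full linear chain, pure A at t=0.

    Solves dX/dt = M X by matrix exponential; rows = times, columns =
    species A..last.  Mass is conserved to the 1e-9 level by
    construction (column sums of M are zero).
    """
    n = rs.n_steps + 1
    m = np.zeros((n, n))
    for i in range(1, rs.n_steps + 1):
        kf, kr = rs.k[i], rs.k_rev[i]
        a, b = i - 1, i
        m[a, a] -= kf
        m[b, a] += kf
        m[b, b] -= kr
        m[a, b] += kr
    x0 = np.zeros(n)
    x0[0] = 1.0
    return np.vstack([expm(m * float(t)) @ x0 for t in t_grid])
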