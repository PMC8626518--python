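"""Seeded synthetic species/networks and the embedded reference tables.

Two kinds of fixtures:

* deterministic toy species and two-pathway networks (seeded RNG) with
  full rovibrational data, used to exercise the whole rate pipeline;
* the embedded printed tables for the three heterocyclic scaffolds
  (relative energies, rate constants, half-lives), exposed both as parsed
  floats and as stub networks for barrier bookkeeping.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import tables_data as td
from .network_model import (BathModel, ReactionNetwork, ReactionStep,
                            RelativeEnergyTable, Species)

# liquid water at 298.15 K, 0.997 g/cm^3
WATER_BATH = BathModel(name="water", sigma=2.74, eps_over_k=506.0,
                       number_density=3.34e22, mass=18.015)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic synthetic species or network."""

    seed: int = 0
    n_modes: int = 12
    freq_range: tuple[float, float] = (80.0, 3200.0)
    barrier_pattern: tuple[tuple[float, float], ...] = (
        # (E0_fwd, E0_rev) per step of the 4-step chain, kcal/mol —
        # shaped like the scaffold PESs: high entrance barrier, deep
        # second well, rate-determining last step
        (43.0, 13.0), (19.0, 40.0), (36.0, 9.0), (36.0, 55.0),
    )
    topology: str = "two-pathway"


def make_toy_species(spec: FixtureSpec, role: str, label: str | None = None,
                     offset: int = 0) -> Species:
    """Deterministic synthetic stationary point for a given role.

    Transition states receive exactly one imaginary frequency drawn in
    800-2000 cm^-1.  The same (seed, offset, role) always produces the
    same species.
    """
    rng = np.random.default_rng((spec.seed, offset))
    lo, hi = spec.freq_range
    freqs = tuple(float(f) for f in np.sort(rng.uniform(lo, hi, size=spec.n_modes)))
    imag = float(rng.uniform(800.0, 2000.0)) if role == "transition_state" else None
    rots = tuple(float(b) for b in rng.uniform(0.05, 0.4, size=3))
    return Species(label=label or f"{role}-{offset}", role=role,
                   frequencies=freqs, imaginary_frequency=imag,
                   rotational_constants=rots, symmetry_number=1,
                   optical_isomers=1, multiplicity=1, mass=99.0)


_WELL_ROLES = {"R": "reactant", "IN1": "intermediate", "IN2": "intermediate",
               "IN3": "intermediate", "IN4": "intermediate", "P": "product"}
_STEP_DEFS = (("R", "TS1", "IN1"), ("IN1", "TS2", "IN2"),
              ("IN2", "TS3", "IN3"), ("IN3", "TS4", "P"),
              ("R", "TS5", "IN4"), ("IN4", "TS6", "IN3"))


def make_two_pathway_network(spec: FixtureSpec) -> ReactionNetwork:
    """Synthetic two-pathway network with the scaffold PES graph.

    Pathway (a): R -> IN1 -> IN2 -> IN3 -> P; pathway (b): R -> IN4 -> IN3.
    Well energies and TS energies are built from the barrier pattern so
    the E_plus_ZPE table is self-consistent and every TS clears its
    adjacent wells; always passes validate_network.
    """
    if spec.topology != "two-pathway":
        raise ValueError("make_two_pathway_network requires the two-pathway topology")
    # chain well energies from the barrier pattern
    e = {"R": 0.0}
    wells_a = ("R", "IN1", "IN2", "IN3", "P")
    ts_a = ("TS1", "TS2", "TS3", "TS4")
    e_ts: dict[str, float] = {}
    for i, (e0f, e0r) in enumerate(spec.barrier_pattern):
        e_ts[ts_a[i]] = e[wells_a[i]] + e0f
        e[wells_a[i + 1]] = e_ts[ts_a[i]] - e0r
    # pathway b: IN4 between R and IN3, barriers echo the entrance step
    e["IN4"] = e["R"] + spec.barrier_pattern[0][0] - 4.0
    e_ts["TS5"] = max(e["R"], e["IN4"]) + 22.0
    e_ts["TS6"] = max(e["IN4"], e["IN3"]) + 20.0

    species: dict[str, Species] = {}
    for i, (lab, role) in enumerate(_WELL_ROLES.items()):
        species[lab] = make_toy_species(spec, role, label=lab, offset=i)
    for i, lab in enumerate(("TS1", "TS2", "TS3", "TS4", "TS5", "TS6")):
        species[lab] = make_toy_species(spec, "transition_state",
                                        label=lab, offset=10 + i)
    values = {**e, **e_ts}
    table = RelativeEnergyTable(level="toy", kind="E_plus_ZPE",
                                values=values, reference_label="R")
    steps = [ReactionStep(a, ts, b) for a, ts, b in _STEP_DEFS]
    return ReactionNetwork(species=species, steps=steps,
                           pathway_a=list(wells_a),
                           pathway_b=["R", "IN4", "IN3", "P"],
                           energy_tables=[table], bath=WATER_BATH,
                           name=f"toy-{spec.seed}")


# ---------------------------------------------------------------------------
# embedded printed tables

def reference_tables() -> dict:
    """The embedded reference tables parsed to floats.

    Returns a dict with keys ``energies`` ((compound, species, level) ->
    {kind: value}), ``rates`` ((compound, channel, level, T) -> s^-1) and
    ``half_lives`` ((compound, intermediate, level, T) -> s), plus the
    raw printed strings under ``printed``.
    """
    energies = {}
    for compound, spdata in td.RELATIVE_ENERGIES.items():
        for sp, levels in spdata.items():
            for level, row in levels.items():
                energies[(compound, sp, level)] = {
                    "E_plus_ZPE": float(row[0]), "E_thermal": float(row[1]),
                    "H": float(row[2]), "G": float(row[3])}
    rates = {}
    for compound, ldata in td.RATE_CONSTANTS.items():
        x = td.HETEROATOM[compound]
        for level, rows in ldata.items():
            for t, row in rows.items():
                for ch, val in zip(td.CHANNELS, row):
                    name = ch.replace("IN1", f"IN1-{x}").replace(
                        "IN2", f"IN2-{x}").replace("IN3", f"IN3-{x}").replace(
                        "IN4", f"IN4-{x}").replace("R", f"R-{x}").replace(
                        "P", f"P-{x}")
                    rates[(compound, name, level, t)] = float(val)
    half_lives = {}
    for compound, ldata in td.HALF_LIVES.items():
        x = td.HETEROATOM[compound]
        for level, rows in ldata.items():
            for t, row in rows.items():
                for inter, val in zip(td.INTERMEDIATES, row):
                    half_lives[(compound, f"{inter}-{x}", level, t)] = float(val)
    return {"energies": energies, "rates": rates, "half_lives": half_lives,
            "printed": {"energies": td.RELATIVE_ENERGIES,
                        "rates": td.RATE_CONSTANTS,
                        "half_lives": td.HALF_LIVES}}


def tables_checksum() -> str:
    """SHA-256 over a canonical serialization of every printed table row."""
    payload = json.dumps({"energies": td.RELATIVE_ENERGIES,
                          "rates": td.RATE_CONSTANTS,
                          "half_lives": td.HALF_LIVES},
                         sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


def scaffold_network(compound: str) -> ReactionNetwork:
    """Stub network for one scaffold with its printed energy tables.

    Species carry no rovibrational data (the frequencies live in
    supplementary material the user may supply); the network supports
    validation and barrier bookkeeping at all three levels.
    """
    if compound not in td.COMPOUNDS:
        raise KeyError(f"unknown compound {compound!r}; known: {td.COMPOUNDS}")
    x = td.HETEROATOM[compound]
    spdata = td.RELATIVE_ENERGIES[compound]
    species = {}
    for label in spdata:
        base = label.rsplit("-", 1)[0]
        role = _WELL_ROLES.get(base, "transition_state")
        species[label] = Species(label=label, role=role)
    steps = [ReactionStep(f"{a}-{x}", f"{ts}-{x}", f"{b}-{x}")
             for a, ts, b in _STEP_DEFS]
    tables = []
    for level in td.LEVELS:
        for kind_idx, kind in enumerate(("E_plus_ZPE", "E_thermal", "H", "G")):
            values = {sp: float(rows[level][kind_idx])
                      for sp, rows in spdata.items()}
            tables.append(RelativeEnergyTable(level=level, kind=kind,
                                              values=values,
                                              reference_label=f"R-{x}"))
    return ReactionNetwork(
        species=species, steps=steps,
        pathway_a=[f"{w}-{x}" for w in ("R", "IN1", "IN2", "IN3", "P")],
        pathway_b=[f"{w}-{x}" for w in ("R", "IN4", "IN3", "P")],
        energy_tables=tables, bath=WATER_BATH, name=compound)
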