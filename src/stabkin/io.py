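"""Network-definition file reading/writing and table serialization.

Network files are YAML (JSON is a YAML subset and also accepted) with the
schema::

    name: ...
    bath: {name, sigma, eps_over_k, number_density, mass}
    temperatures: {start, stop, points}  |  [explicit grid]
    species:
      - label: R-N
        role: reactant
        energies: {A: {electronic: -285.123, zpe: 0.070, unit: hartree}}
        # or, for stubs:
        relative: {A: {E_plus_ZPE: 0.0, E_thermal: 0.0, H: 0.0, G: 0.0}}
        frequencies: [...]
        imaginary_frequency: 1550.3
        rotational_constants: [...]
        symmetry_number: 1
        optical_isomers: 1
        mass: 99.0
    steps:
      - {from: R-N, ts: TS1-N, to: IN1-N, alpha_fwd: 1, alpha_rev: 1}
    pathways: {a: [...], b: [...]}

Energies may be declared in Hartree or kcal/mol per level block; they are
normalized to kcal/mol on input.  Scientific notation in outputs uses the
ASCII dialect "2.49E-19"; unicode minus signs are normalized on input.
"""
from __future__ import annotations

import csv
from pathlib import Path

import yaml

from .network_kinetics import RateTable
from .network_model import (BathModel, ReactionNetwork, ReactionStep,
                            RelativeEnergyTable, Species, convert_energy,
                            validate_network)

_MINUS_VARIANTS = {"−": "-", "–": "-", "—": "-"}


def normalize_number(text: str) -> float:
    """Parse a printed number, normalizing unicode minus/dash variants
    and doubled exponent markers like '9.53E-E-01'."""
    s = str(text).strip()
    for bad, good in _MINUS_VARIANTS.items():
        s = s.replace(bad, good)
    s = s.replace("E-E-", "E-").replace("e-e-", "e-")
    return float(s)


def parse_freq_block(text: str, dialect: str = "plain") -> tuple[list[float], float | None]:
    """Parse a whitespace-separated frequency block (cm^-1).

    Negative entries mark the imaginary mode (at most one, stored as a
    positive magnitude); returns (positive frequencies sorted, imaginary
    magnitude or None).
    """
    if dialect != "plain":
        raise ValueError(f"unknown frequency dialect {dialect!r}")
    tokens = text.split()
    if not tokens:
        raise ValueError("empty frequency block")
    values = [normalize_number(t) for t in tokens]
    imag = [abs(v) for v in values if v < 0]
    if len(imag) > 1:
        raise ValueError(f"{len(imag)} imaginary modes in block; at most one allowed")
    pos = sorted(v for v in values if v > 0)
    return pos, (imag[0] if imag else None)


def _species_from_record(rec: dict) -> tuple[Species, dict[str, dict[str, float]]]:
    label = rec["label"]
    role = rec["role"]
    freqs = tuple(float(f) for f in rec.get("frequencies", ()))
    relative = rec.get("relative", {})
    energies = rec.get("energies", {})
    abs_e = abs_zpe = None
    if energies:
        # single-level absolute energies; unit declared per block
        level, block = next(iter(energies.items()))
        unit = block.get("unit", "hartree")
        abs_e = convert_energy(float(block["electronic"]), unit, "kcal/mol")
        abs_zpe = convert_energy(float(block.get("zpe", 0.0)), unit, "kcal/mol")
    sp = Species(
        label=label, role=role, frequencies=freqs,
        imaginary_frequency=(float(rec["imaginary_frequency"])
                             if rec.get("imaginary_frequency") else None),
        rotational_constants=tuple(float(b) for b in
                                   rec.get("rotational_constants", ())),
        symmetry_number=int(rec.get("symmetry_number", 1)),
        optical_isomers=int(rec.get("optical_isomers", 1)),
        multiplicity=int(rec.get("multiplicity", 1)),
        electronic_energy=abs_e, zpe=abs_zpe,
        mass=(float(rec["mass"]) if rec.get("mass") else None))
    rel = {lvl: {k: float(v) for k, v in kinds.items()}
           for lvl, kinds in relative.items()}
    return sp, rel


def read_network(path: str | Path) -> ReactionNetwork:
    """Load and validate a network-definition file.

    Raises ValueError naming the offending species/field on schema
    violations, duplicate labels, or invariant violations.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "species" not in data:
        raise ValueError(f"{path}: not a network-definition file (no 'species')")

    species: dict[str, Species] = {}
    relatives: dict[str, dict[str, dict[str, float]]] = {}
    for rec in data["species"]:
        try:
            sp, rel = _species_from_record(rec)
        except KeyError as exc:
            raise ValueError(f"{path}: species record missing field {exc}") from None
        if sp.label in species:
            raise ValueError(f"{path}: duplicate species label {sp.label!r}")
        species[sp.label] = sp
        if rel:
            relatives[sp.label] = rel

    steps = [ReactionStep(from_label=s["from"], ts_label=s["ts"],
                          to_label=s["to"],
                          alpha_fwd=float(s.get("alpha_fwd", 1.0)),
                          alpha_rev=float(s.get("alpha_rev", 1.0)))
             for s in data.get("steps", [])]

    pathways = data.get("pathways", {})
    bath_rec = data.get("bath")
    bath = BathModel(**bath_rec) if bath_rec else None

    temps = data.get("temperatures", [])
    if isinstance(temps, dict):
        import numpy as np

        temps = list(np.linspace(float(temps["start"]), float(temps["stop"]),
                                 int(temps["points"])))
    temps = [float(t) for t in temps]

    # assemble relative-energy tables from per-species blocks
    tables: list[RelativeEnergyTable] = []
    ref = next((l for l, s in species.items() if s.role == "reactant"), None)
    level_kinds: dict[tuple[str, str], dict[str, float]] = {}
    for label, rel in relatives.items():
        for level, kinds in rel.items():
            for kind, value in kinds.items():
                level_kinds.setdefault((level, kind), {})[label] = value
    for (level, kind), values in sorted(level_kinds.items()):
        tables.append(RelativeEnergyTable(level=level, kind=kind,
                                          values=values,
                                          reference_label=ref or ""))

    net = ReactionNetwork(species=species, steps=steps,
                          pathway_a=list(pathways.get("a", [])),
                          pathway_b=list(pathways.get("b", [])),
                          energy_tables=tables, bath=bath,
                          temperatures=temps, name=data.get("name", path.stem))
    violations = validate_network(net)
    if violations:
        msgs = "; ".join(v.message for v in violations)
        raise ValueError(f"{path}: invalid network: {msgs}")
    return net


def write_network(network: ReactionNetwork, path: str | Path) -> None:
    """Serialize a network back to YAML (relative energies, not absolutes).

    Round-trips the decimal strings of relative-energy tables through
    repr, so load -> write -> load is stable.
    """
    recs = []
    for sp in network.species.values():
        rec: dict = {"label": sp.label, "role": sp.role}
        if sp.frequencies:
            rec["frequencies"] = list(sp.frequencies)
        if sp.imaginary_frequency:
            rec["imaginary_frequency"] = sp.imaginary_frequency
        if sp.rotational_constants:
            rec["rotational_constants"] = list(sp.rotational_constants)
        for attr in ("symmetry_number", "optical_isomers", "multiplicity"):
            if getattr(sp, attr) != 1:
                rec[attr] = getattr(sp, attr)
        if sp.mass is not None:
            rec["mass"] = sp.mass
        rel: dict = {}
        for tab in network.energy_tables:
            if sp.label in tab.values:
                rel.setdefault(tab.level, {})[tab.kind] = tab.values[sp.label]
        if rel:
            rec["relative"] = rel
        recs.append(rec)
    data = {
        "name": network.name,
        "species": recs,
        "steps": [{"from": s.from_label, "ts": s.ts_label, "to": s.to_label,
                   "alpha_fwd": s.alpha_fwd, "alpha_rev": s.alpha_rev}
                  for s in network.steps],
        "pathways": {"a": network.pathway_a, "b": network.pathway_b},
    }
    if network.bath:
        b = network.bath
        data["bath"] = {"name": b.name, "sigma": b.sigma,
                        "eps_over_k": b.eps_over_k,
                        "number_density": b.number_density, "mass": b.mass}
    if network.temperatures:
        data["temperatures"] = network.temperatures
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def sci(x: float) -> str:
    """Scientific notation in the table dialect: '2.49E-19'."""
    if x == float("inf"):
        return "INF"
    return f"{x:.2E}"


def write_rate_table(table: RateTable, path: str | Path) -> None:
    """CSV rate table: temperature rows, channel/overall/half-life columns.

    Deterministic byte output for a fixed table (3 significant figures,
    uppercase E notation).
    """
    path = Path(path)
    cols = (list(table.channels) + [f"k_obs({w})" for w in table.overall]
            + [f"t1/2({w})" for w in table.half_lives])
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        if table.level:
            w.writerow([f"# level: {table.level}"])
        w.writerow(["T/K"] + cols)
        for i, t in enumerate(table.temperatures):
            row = [f"{t:g}"]
            row += [sci(table.channels[c][i]) for c in table.channels]
            row += [sci(table.overall[c][i]) for c in table.overall]
            row += [sci(table.half_lives[c][i]) for c in table.half_lives]
            w.writerow(row)
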