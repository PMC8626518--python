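"""Domain types and bookkeeping for multiwell unimolecular reaction networks.

A network is the labelled graph of wells (reactant R, intermediates IN1..IN4,
product P) connected through transition states, together with per-level
relative-energy tables (kcal/mol, relative to the reactant) of the four kinds
``E_plus_ZPE``, ``E_thermal``, ``H`` and ``G``.  Species may be supplied
either as full rovibrational records (needed to compute rates) or as
label-only stubs carrying relative energies (enough for barrier bookkeeping
against printed tables).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import constants as const

ROLES = ("reactant", "intermediate", "product", "transition_state")
ENERGY_KINDS = ("E_plus_ZPE", "E_thermal", "H", "G")


@dataclass(frozen=True)
class Species:
    """A PES stationary point: minimum (well/product) or first-order saddle.

    ``frequencies`` are real harmonic wavenumbers (cm^-1, all positive);
    a transition state additionally carries the magnitude of its single
    imaginary mode.  ``electronic_energy``/``zpe`` are absolute energies in
    kcal/mol when present; stubs leave them ``None`` and rely on the
    network's relative-energy tables.
    """

    label: str
    role: str
    frequencies: tuple[float, ...] = ()
    imaginary_frequency: float | None = None
    rotational_constants: tuple[float, ...] = ()
    symmetry_number: int = 1
    optical_isomers: int = 1
    multiplicity: int = 1
    electronic_energy: float | None = None
    zpe: float | None = None
    mass: float | None = None  # amu; optional, cancels in isomer tables

    @property
    def is_ts(self) -> bool:
        return self.role == "transition_state"

    @property
    def is_stub(self) -> bool:
        return self.electronic_energy is None and not self.frequencies


@dataclass(frozen=True)
class BathModel:
    """Collider (solvent) description for the master equation."""

    name: str
    sigma: float          # collision diameter, Angstrom
    eps_over_k: float     # LJ well depth / k_B, K
    number_density: float  # molecules / cm^3
    mass: float           # amu


@dataclass
class RelativeEnergyTable:
    """One (level, kind) column of a relative-energy table, kcal/mol."""

    level: str
    kind: str
    values: dict[str, float]
    reference_label: str

    def __post_init__(self) -> None:
        if self.kind not in ENERGY_KINDS:
            raise ValueError(f"unknown energy kind {self.kind!r}")

    def __getitem__(self, label: str) -> float:
        return self.values[label]


@dataclass
class ReactionStep:
    """An elementary reversible well -> TS -> well pair.

    ``alpha_fwd``/``alpha_rev`` are reaction-path degeneracies; critical
    energies (ZPE-corrected barriers, kcal/mol) are derived from the
    E_plus_ZPE table unless set explicitly.
    """

    from_label: str
    ts_label: str
    to_label: str
    alpha_fwd: float = 1.0
    alpha_rev: float = 1.0
    critical_energy_forward: float | None = None
    critical_energy_reverse: float | None = None


@dataclass
class ReactionNetwork:
    species: dict[str, Species]
    steps: list[ReactionStep]
    pathway_a: list[str] = field(default_factory=list)
    pathway_b: list[str] = field(default_factory=list)
    energy_tables: list[RelativeEnergyTable] = field(default_factory=list)
    bath: BathModel | None = None
    temperatures: list[float] = field(default_factory=list)
    name: str = ""

    def table(self, kind: str, level: str) -> RelativeEnergyTable:
        for t in self.energy_tables:
            if t.kind == kind and t.level == level:
                return t
        raise KeyError(f"no table of kind {kind!r} at level {level!r}")

    @property
    def levels(self) -> list[str]:
        seen: list[str] = []
        for t in self.energy_tables:
            if t.level not in seen:
                seen.append(t.level)
        return seen

    def step_barriers(self, step: ReactionStep, level: str,
                      kind: str = "E_plus_ZPE") -> tuple[float, float]:
        """ZPE-corrected forward/reverse critical energies for one step."""
        if (step.critical_energy_forward is not None
                and step.critical_energy_reverse is not None):
            return step.critical_energy_forward, step.critical_energy_reverse
        tab = self.table(kind, level)
        e_ts = tab[step.ts_label]
        return e_ts - tab[step.from_label], e_ts - tab[step.to_label]


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Violation:
    code: str
    message: str


def validate_network(network: ReactionNetwork) -> list[Violation]:
    """Check every structural invariant; an empty list means a valid network.

    Violations are data, not exceptions: each one names the offending
    species, step or table.
    """
    out: list[Violation] = []
    labels = set(network.species)

    for sp in network.species.values():
        if sp.role not in ROLES:
            out.append(Violation("bad_role", f"species {sp.label}: unknown role {sp.role!r}"))
        if any(f <= 0 for f in sp.frequencies):
            out.append(Violation("bad_frequency",
                                 f"species {sp.label}: nonpositive frequency"))
        if sp.is_ts:
            if not sp.imaginary_frequency or sp.imaginary_frequency <= 0:
                if not sp.is_stub:
                    out.append(Violation(
                        "missing_imaginary",
                        f"transition state {sp.label}: needs one imaginary frequency > 0"))
        elif sp.imaginary_frequency is not None:
            out.append(Violation("unexpected_imaginary",
                                 f"species {sp.label}: imaginary frequency on a non-TS"))
        if sp.symmetry_number < 1:
            out.append(Violation("bad_symmetry",
                                 f"species {sp.label}: symmetry_number < 1"))

    for i, st in enumerate(network.steps):
        for lab in (st.from_label, st.ts_label, st.to_label):
            if lab not in labels:
                out.append(Violation("unknown_species",
                                     f"step {i}: unknown species {lab!r}"))
        if st.alpha_fwd <= 0 or st.alpha_rev <= 0:
            out.append(Violation("bad_degeneracy",
                                 f"step {i} ({st.ts_label}): degeneracy must be positive"))

    for path_name, path in (("a", network.pathway_a), ("b", network.pathway_b)):
        for lab in path:
            if lab not in labels:
                out.append(Violation("unknown_species",
                                     f"pathway {path_name}: unknown species {lab!r}"))

    for tab in network.energy_tables:
        ref = tab.reference_label
        if ref not in tab.values:
            out.append(Violation("missing_reference",
                                 f"table {tab.level}/{tab.kind}: reference {ref!r} missing"))
        elif tab.values[ref] != 0.0:
            out.append(Violation("nonzero_reference",
                                 f"table {tab.level}/{tab.kind}: reference {ref!r} not 0"))
        missing = labels - set(tab.values)
        for lab in sorted(missing):
            out.append(Violation("missing_entry",
                                 f"table {tab.level}/{tab.kind}: no entry for {lab!r}"))

    # TS must sit above both adjacent wells at E_plus_ZPE (per level)
    for tab in network.energy_tables:
        if tab.kind != "E_plus_ZPE":
            continue
        for i, st in enumerate(network.steps):
            try:
                e_ts = tab[st.ts_label]
                e_lo = max(tab[st.from_label], tab[st.to_label])
            except KeyError:
                continue
            if e_ts < e_lo:
                out.append(Violation(
                    "submerged_ts",
                    f"step {i}: TS {st.ts_label} below an adjacent well "
                    f"at {tab.level}/E_plus_ZPE"))

    # connectivity of the well graph through its steps
    wells = {l for l, s in network.species.items() if not s.is_ts}
    if len(wells) > 1 and network.steps:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(wells)
        for st in network.steps:
            if st.from_label in wells and st.to_label in wells:
                g.add_edge(st.from_label, st.to_label)
        if not nx.is_connected(g):
            out.append(Violation("disconnected", "well graph is not connected"))

    return out


# ---------------------------------------------------------------------------
# energy bookkeeping

def barrier_height(network: ReactionNetwork, upper_label: str, lower_label: str,
                   kind: str = "E_plus_ZPE", level: str | None = None) -> float:
    """Energy difference values[upper] - values[lower] (kcal/mol).

    Antisymmetric by construction; exact to the precision of the loaded
    table (no additional rounding).
    """
    if level is None:
        levels = network.levels
        if len(levels) != 1:
            raise ValueError("level must be given when several are loaded")
        level = levels[0]
    tab = network.table(kind, level)
    try:
        return tab[upper_label] - tab[lower_label]
    except KeyError as exc:
        raise KeyError(f"unknown species {exc.args[0]!r} in table "
                       f"{level}/{kind}") from None


_TO_KCAL = {
    "kcal/mol": 1.0,
    "hartree": const.HARTREE_TO_KCAL,
    "kj/mol": 1.0 / const.KCAL_TO_KJ,
    "cm-1": 1.0 / const.KCAL_TO_CM,
    # 1 K of energy is (1/CM_TO_K) cm^-1
    "k": 1.0 / (const.CM_TO_K * const.KCAL_TO_CM),
}

_ALIASES = {
    "hartree": "hartree", "eh": "hartree", "au": "hartree",
    "kcal/mol": "kcal/mol", "kcal": "kcal/mol",
    "kj/mol": "kj/mol", "kj": "kj/mol",
    "cm-1": "cm-1", "cm^-1": "cm-1", "wavenumber": "cm-1", "cm⁻¹": "cm-1",
    "k": "k", "kelvin": "k",
}


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert among Hartree, kcal/mol, kJ/mol, cm^-1 and K (as energy/k_B)."""
    try:
        f = _ALIASES[from_unit.strip().lower()]
        t = _ALIASES[to_unit.strip().lower()]
    except KeyError as exc:
        raise ValueError(f"unknown energy unit {exc.args[0]!r}") from None
    return value * _TO_KCAL[f] / _TO_KCAL[t]
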