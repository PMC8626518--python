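"""Rigid-rotor harmonic-oscillator partition functions and thermochemistry.

Produces the per-species thermal corrections and the relative
(ΔE+ZPE, ΔE°, ΔH°, ΔG°) tables for a reaction network.  Vibrations are
harmonic and referenced to the zero-point level (the ZPE itself lives in
the electronic+ZPE energies); external rotations are classical; the
electronic factor is the spin multiplicity times the number of optical
isomers.  The translational factor uses the 1 atm ideal-gas standard state
and cancels exactly in every relative isomer table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as const
from .network_model import ReactionNetwork, RelativeEnergyTable, Species


@dataclass(frozen=True)
class ThermoRecord:
    """Partition-function factors and thermal functions at one temperature.

    Energies in kcal/mol, entropy in cal/mol/K.  ``E_thermal`` excludes the
    ZPE (zero-point-referenced vibrations); ``H = E_thermal + RT`` for an
    ideal-gas species.
    """

    T: float
    q_trans: float
    q_rot: float
    q_vib: float
    q_elec: float
    E_thermal: float
    H: float
    S: float
    G: float


def vib_partition(frequencies, T: float) -> float:
    """Harmonic vibrational partition function, zero-point referenced.

    q_vib = prod_i [1 - exp(-h c nu_i / k T)]^-1; the empty product is 1.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        return 1.0
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    x = freqs * const.CM_TO_K / T  # h c nu / k T
    return float(np.prod(1.0 / -np.expm1(-x)))


def _rot_partition(species: Species, T: float) -> tuple[float, float, float]:
    """(q_rot, E_rot, S-less helper) — returns q, thermal energy (kcal/mol),
    and the number of rotational degrees of freedom."""
    B = tuple(b for b in species.rotational_constants if b > 0)
    sigma = species.symmetry_number
    if not B:
        return 1.0, 0.0, 0.0
    kT_cm = T / const.CM_TO_K  # kT in cm^-1
    if len(B) == 1:
        # linear rotor
        q = kT_cm / (sigma * B[0])
        return q, const.R_KCAL * T, 2.0
    if len(B) == 2:
        # treat as symmetric top with two distinct constants -> use geometric mean
        B = (B[0], B[1], math.sqrt(B[0] * B[1]))
    q = (math.sqrt(math.pi) / sigma) * kT_cm ** 1.5 / math.sqrt(B[0] * B[1] * B[2])
    return q, 1.5 * const.R_KCAL * T, 3.0


def _vib_thermal(frequencies, T: float) -> tuple[float, float]:
    """Vibrational thermal energy (kcal/mol) and entropy (cal/mol/K)."""
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        return 0.0, 0.0
    x = freqs * const.CM_TO_K / T
    e = const.R_KCAL * T * float(np.sum(x / np.expm1(x)))
    s = const.R_CAL * float(np.sum(x / np.expm1(x) - np.log(-np.expm1(-x))))
    return e, s


def thermal_corrections(species: Species, T: float) -> ThermoRecord:
    """Standard RRHO thermal functions for one species at temperature T.

    Requires rovibrational data (a stub raises).  A species without a mass
    contributes no translational factor; that choice is only valid for
    relative isomer tables, where translation cancels identically.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if species.is_stub and species.frequencies == () and species.rotational_constants == ():
        # mode-less, rotation-less hypothetical particle is allowed (translation only)
        pass

    R = const.R_KCAL
    # translation (1 atm ideal gas)
    if species.mass is not None:
        m = species.mass * const.AMU_KG
        lam3 = (2.0 * math.pi * m * const.BOLTZMANN_J_K * T / const.PLANCK_J_S**2) ** 1.5
        v = const.BOLTZMANN_J_K * T / const.STANDARD_PRESSURE_PA  # m^3 per molecule
        q_trans = lam3 * v
    else:
        q_trans = 1.0
    e_trans = 1.5 * R * T
    s_trans = const.R_CAL * (math.log(q_trans) + 2.5) if species.mass is not None \
        else const.R_CAL * 1.5  # entropy of the omitted factor is ill-defined; keep E-part only

    q_rot, e_rot, _ = _rot_partition(species, T)
    s_rot = const.R_CAL * (math.log(q_rot) + e_rot / (R * T)) if q_rot != 1.0 else 0.0

    q_vib = vib_partition(species.frequencies, T)
    e_vib, s_vib = _vib_thermal(species.frequencies, T)

    q_elec = float(species.multiplicity * species.optical_isomers)
    s_elec = const.R_CAL * math.log(q_elec)

    e_thermal = e_trans + e_rot + e_vib
    h = e_thermal + R * T
    s = s_trans + s_rot + s_vib + s_elec
    g = h - T * s / 1000.0
    return ThermoRecord(T=T, q_trans=q_trans, q_rot=q_rot, q_vib=q_vib,
                        q_elec=q_elec, E_thermal=e_thermal, H=h, S=s, G=g)


def internal_partition(species: Species, T: float) -> float:
    """q_rot * q_vib * q_elec — the factors that matter for unimolecular TST."""
    q_rot, _, _ = _rot_partition(species, T)
    return q_rot * vib_partition(species.frequencies, T) * \
        species.multiplicity * species.optical_isomers


def reaction_free_energy(network: ReactionNetwork, from_label: str,
                         to_label: str, T: float, level: str) -> float:
    """ΔG_rxn (kcal/mol) of well -> well isomerization at temperature T.

    ZPE-corrected electronic difference from the network's E_plus_ZPE
    table plus the RRHO thermal free-energy difference of the two wells;
    translation cancels for equal-mass isomers.
    """
    tab = network.table("E_plus_ZPE", level)
    d_e0 = tab[to_label] - tab[from_label]
    g_to = thermal_corrections(network.species[to_label], T).G
    g_from = thermal_corrections(network.species[from_label], T).G
    return d_e0 + g_to - g_from


def relative_thermo(network: ReactionNetwork, T: float,
                    level: str) -> list[RelativeEnergyTable]:
    """Per-species ΔE+ZPE, ΔE°, ΔH°, ΔG° vs the reactant (kcal/mol).

    All species must carry absolute electronic+ZPE energies and
    rovibrational data at this level; the reactant row is identically zero.
    """
    ref = next((s for s in network.species.values() if s.role == "reactant"), None)
    if ref is None:
        raise ValueError("network has no reactant")
    stubs = [s.label for s in network.species.values() if s.is_stub]
    if stubs:
        raise ValueError(f"stub species lack rovibrational data: {stubs}")

    tables = {k: RelativeEnergyTable(level=level, kind=k, values={},
                                     reference_label=ref.label)
              for k in ("E_plus_ZPE", "E_thermal", "H", "G")}
    ref_rec = thermal_corrections(ref, T)
    ref_e0 = (ref.electronic_energy or 0.0) + (ref.zpe or 0.0)
    for sp in network.species.values():
        rec = thermal_corrections(sp, T)
        d_e0 = (sp.electronic_energy or 0.0) + (sp.zpe or 0.0) - ref_e0
        tables["E_plus_ZPE"].values[sp.label] = d_e0
        tables["E_thermal"].values[sp.label] = d_e0 + rec.E_thermal - ref_rec.E_thermal
        tables["H"].values[sp.label] = d_e0 + rec.H - ref_rec.H
        tables["G"].values[sp.label] = d_e0 + rec.G - ref_rec.G
    return list(tables.values())
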