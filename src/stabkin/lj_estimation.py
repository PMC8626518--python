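"""Lennard-Jones parameters from critical constants (Tee correlations).

sigma/Angstrom = 2.3647 (Tc/Pc)^(1/3), eps/k = 0.7740 Tc, with Tc in K
and Pc in atm.  Solvent and solute presets used by the shipped networks
are pinned here with their provenance.
"""
from __future__ import annotations

from dataclasses import dataclass

TEE_SIGMA_COEFF = 2.3647
TEE_EPS_COEFF = 0.7740


@dataclass(frozen=True)
class CriticalProperties:
    Tc: float  # K
    Pc: float  # atm

    def __post_init__(self) -> None:
        if self.Tc <= 0 or self.Pc <= 0:
            raise ValueError("critical constants must be positive")


@dataclass(frozen=True)
class LJParameters:
    sigma: float       # Angstrom
    eps_over_k: float  # K

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.eps_over_k <= 0:
            raise ValueError("LJ parameters must be positive")


def tee_parameters(cp: CriticalProperties) -> LJParameters:
    """Forward Tee correlation: critical constants -> LJ parameters."""
    return LJParameters(sigma=TEE_SIGMA_COEFF * (cp.Tc / cp.Pc) ** (1.0 / 3.0),
                        eps_over_k=TEE_EPS_COEFF * cp.Tc)


def invert_tee(lj: LJParameters) -> CriticalProperties:
    """Algebraic inverse of the Tee correlation (consistency checking)."""
    tc = lj.eps_over_k / TEE_EPS_COEFF
    pc = tc / (lj.sigma / TEE_SIGMA_COEFF) ** 3
    return CriticalProperties(Tc=tc, Pc=pc)


# literature / correlation-derived presets used by the shipped networks
_PRESETS: dict[str, LJParameters] = {
    # water collider constants (experimental compilation)
    "water": LJParameters(2.74, 506.0),
    # solute values from the Tee correlation on estimated critical constants
    "3-hydroxyfuran-2(5H)-one": LJParameters(5.34, 519.88),
    "3-hydroxy-1H-pyrrol-2(5H)-one": LJParameters(5.44, 580.79),
    "3-hydroxythiophen-2(5H)-one": LJParameters(5.34, 553.67),
}

_ALIASES = {
    "water": "water",
    "furanone": "3-hydroxyfuran-2(5H)-one",
    "pyrrolone": "3-hydroxy-1H-pyrrol-2(5H)-one",
    "thiophenone": "3-hydroxythiophen-2(5H)-one",
}


def bath_presets(name: str) -> LJParameters:
    """Pinned LJ constants by solvent/solute label; raises on unknown names."""
    key = _ALIASES.get(name.strip().lower(), name)
    try:
        return _PRESETS[key]
    except KeyError:
        raise KeyError(f"unknown LJ preset {name!r}; known: "
                       f"{sorted(set(_ALIASES) | set(_PRESETS))}") from None
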