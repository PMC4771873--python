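"""Equilibrium and flux electrochemistry for monovalent cation channels.

Provides Nernst and Goldman-Hodgkin-Katz (GHK) reversal potentials, the GHK
current equation, and the electrochemical driving force

    dmu = Vm - Erev        (mV)

which is the quantity the flux-gated selectivity filter senses.  Units are
fixed throughout the package: millivolts, milliseconds, picoamperes and
millimolar; all unit conversions are internal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_PERMEABILITIES",
    "DomainError",
    "IonSpecies",
    "BathConditions",
    "DrivingForce",
    "thermal_voltage",
    "nernst_potential",
    "ghk_reversal",
    "ghk_flux",
    "ghk_current",
    "driving_force",
]

GAS_CONSTANT = 8.31446261815324  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: Room-temperature default used by all recordings and simulations.
DEFAULT_TEMPERATURE_K = 294.0

#: Relative permeabilities vs K+.  Only K+ is well constrained; the alkali /
#: organic cation values are package assumptions chosen to reproduce the
#: qualitative selectivity sequence (Tl+ ~ K+ >> Rb+ > NH4+ >> Cs+ > Na+,
#: NMDG+ impermeant), not measured numbers.
DEFAULT_PERMEABILITIES: dict[str, float] = {
    "K": 1.0,
    "Tl": 1.1,
    "Rb": 0.7,
    "NH4": 0.3,
    "Cs": 0.1,
    "Na": 0.01,
    "NMDG": 0.0,
}

# GHK current singularity at Vm = 0 is removable; below this |Vm| (mV) a
# second-order series expansion is used instead of the closed form.
_SERIES_VM_MV = 1e-6


class DomainError(ValueError):
    """Raised when an electrochemical quantity is undefined for the input."""


def thermal_voltage(temperature_k: float) -> float:
    """RT/F in millivolts (~25.3 mV at 294 K)."""
    if temperature_k <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature_k}")
    return 1000.0 * GAS_CONSTANT * temperature_k / FARADAY


@dataclass(frozen=True)
class IonSpecies:
    """A permeant (or impermeant) monovalent cation species."""

    name: str
    valence: int = 1
    rel_permeability: float = 1.0

    def __post_init__(self) -> None:
        if self.valence != 1:
            raise DomainError(
                f"only monovalent cations are modeled (got valence {self.valence} "
                f"for {self.name})"
            )
        if self.rel_permeability < 0:
            raise DomainError(f"rel_permeability must be >= 0 for {self.name}")


@dataclass
class BathConditions:
    """Ion concentrations on both membrane sides plus temperature.

    ``intracellular`` / ``extracellular`` map species name -> concentration in
    mM.  ``permeabilities`` maps species name -> permeability relative to K+
    and falls back to :data:`DEFAULT_PERMEABILITIES` for listed species.
    """

    intracellular: dict[str, float]
    extracellular: dict[str, float]
    temperature_k: float = DEFAULT_TEMPERATURE_K
    permeabilities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise DomainError("temperature must be > 0 K")
        for side_name, side in (
            ("intracellular", self.intracellular),
            ("extracellular", self.extracellular),
        ):
            for name, conc in side.items():
                if conc < 0:
                    raise DomainError(
                        f"negative {side_name} concentration for {name}: {conc}"
                    )
            if not any(
                conc > 0 and self.permeability(name) > 0
                for name, conc in side.items()
            ):
                raise DomainError(
                    f"no permeant species with concentration > 0 on the "
                    f"{side_name} side"
                )

    @property
    def vt(self) -> float:
        """Thermal voltage RT/F in mV."""
        return thermal_voltage(self.temperature_k)

    def permeability(self, species: str) -> float:
        if species in self.permeabilities:
            return self.permeabilities[species]
        return DEFAULT_PERMEABILITIES.get(species, 0.0)

    def species(self) -> list[str]:
        """All species names present on either side, sorted."""
        return sorted(set(self.intracellular) | set(self.extracellular))

    def swapped(self) -> "BathConditions":
        """Conditions with intracellular and extracellular sides exchanged."""
        return BathConditions(
            intracellular=dict(self.extracellular),
            extracellular=dict(self.intracellular),
            temperature_k=self.temperature_k,
            permeabilities=dict(self.permeabilities),
        )

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            "int": dict(self.intracellular),
            "ext": dict(self.extracellular),
            "temperature_K": self.temperature_k,
        }
        if self.permeabilities:
            out["permeabilities"] = dict(self.permeabilities)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "BathConditions":
        return cls(
            intracellular=dict(d["int"]),
            extracellular=dict(d["ext"]),
            temperature_k=float(d.get("temperature_K", DEFAULT_TEMPERATURE_K)),
            permeabilities=dict(d.get("permeabilities", {})),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BathConditions":
        return cls.from_dict(json.loads(Path(path).read_text()))


def symmetric_k(conc_mm: float = 120.0,
                temperature_k: float = DEFAULT_TEMPERATURE_K) -> BathConditions:
    """Symmetrical K+ bath, the reference recording condition."""
    return BathConditions({"K": conc_mm}, {"K": conc_mm}, temperature_k)


@dataclass(frozen=True)
class DrivingForce:
    """Membrane voltage, reversal potential, and their difference (all mV)."""

    vm: float
    erev: float

    @property
    def dmu(self) -> float:
        return self.vm - self.erev


def nernst_potential(species: str | IonSpecies, conditions: BathConditions) -> float:
    """Nernst equilibrium potential (mV) for one species: (RT/zF) ln(c_ext/c_int)."""
    name = species.name if isinstance(species, IonSpecies) else species
    c_int = conditions.intracellular.get(name, 0.0)
    c_ext = conditions.extracellular.get(name, 0.0)
    if c_int <= 0 or c_ext <= 0:
        raise DomainError(
            f"Nernst potential for {name} requires concentration > 0 on both "
            f"sides (int={c_int}, ext={c_ext})"
        )
    return conditions.vt * np.log(c_ext / c_int)


def ghk_reversal(conditions: BathConditions) -> float:
    """Reversal potential (mV) from the GHK voltage equation.

    For monovalent cations, Erev = (RT/F) ln(sum P c_ext / sum P c_int).
    Reduces exactly to the Nernst potential when a single permeant species is
    present.
    """
    num = 0.0
    den = 0.0
    for name in conditions.species():
        p = conditions.permeability(name)
        if p <= 0:
            continue
        num += p * conditions.extracellular.get(name, 0.0)
        den += p * conditions.intracellular.get(name, 0.0)
    if num <= 0 or den <= 0:
        raise DomainError("all permeant concentrations are zero on one side")
    return conditions.vt * np.log(num / den)


def _ghk_phi(u: np.ndarray, c_int: float, c_ext: float) -> np.ndarray:
    """Dimensionless GHK flux factor u (c_int - c_ext e^-u) / (1 - e^-u).

    ``u`` is Vm/(RT/F).  Outward current positive.  The removable singularity
    at u = 0 is handled by a series expansion; large |u| is computed in the
    numerically stable branch.
    """
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    dc = c_int - c_ext

    small = np.abs(u) < (_SERIES_VM_MV / 30.0)  # conservative: vt >= ~5 mV
    # second-order series about u = 0
    us = u[small]
    out[small] = dc + us * (c_ext + dc / 2.0) + us**2 * (c_ext / 2.0 + dc / 12.0)

    pos = (~small) & (u > 0)
    up = u[pos]
    out[pos] = up * (c_int - c_ext * np.exp(-up)) / (1.0 - np.exp(-up))

    neg = (~small) & (u < 0)
    un = u[neg]
    # multiply through by e^u to avoid overflow of e^-u
    out[neg] = un * (c_int * np.exp(un) - c_ext) / (np.exp(un) - 1.0)
    return out


def ghk_flux(
    vm: float | np.ndarray,
    species: str | IonSpecies,
    conditions: BathConditions,
) -> float | np.ndarray:
    """GHK current carried by one species, scaled by its relative permeability.

    Returned in the package's per-channel current unit (pA per unit
    conductance scale); outward current is positive.  At Vm = 0 with symmetric
    concentrations the current is exactly 0 and the function is continuous
    through Vm = 0.
    """
    name = species.name if isinstance(species, IonSpecies) else species
    p = conditions.permeability(name)
    c_int = conditions.intracellular.get(name, 0.0)
    c_ext = conditions.extracellular.get(name, 0.0)
    u = np.asarray(vm, dtype=float) / conditions.vt
    out = p * _ghk_phi(u, c_int, c_ext)
    if np.isscalar(vm) or np.ndim(vm) == 0:
        return float(out)
    return out


def ghk_current(
    vm: float | np.ndarray, conditions: BathConditions
) -> float | np.ndarray:
    """Total GHK current summed over every species in the bath."""
    total = None
    for name in conditions.species():
        term = ghk_flux(vm, name, conditions)
        total = term if total is None else total + term
    return total


def driving_force(vm: float, conditions: BathConditions) -> DrivingForce:
    """Electrochemical driving force dmu = Vm - Erev (GHK reversal)."""
    return DrivingForce(vm=float(vm), erev=ghk_reversal(conditions))
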