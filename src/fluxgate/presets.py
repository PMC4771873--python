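"""Channel preset registry.

Presets bundle the kinetic parameters, bath conditions and (optionally) an
agonist Hill law for one channel/condition combination.  They ship as a
single JSON file (``data/presets.json``); each non-default parameter carries
a provenance note saying which observable it was calibrated to, or that it
is a free assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .electrochem import BathConditions
from .gating import GatingParams

__all__ = [
    "HillModeShift",
    "ChannelPreset",
    "list_presets",
    "get_preset",
    "K2P_RB_PRESETS",
    "FLUX_GATED_SYMK_PRESETS",
]

#: The six flux-gated K2P presets under intracellular-Rb+ conditions whose
#: fitted gating charges average ~2.2 e0.
K2P_RB_PRESETS = [
    "traak_rb",
    "trek1_rb",
    "trek2_rb",
    "talk1_rb",
    "talk2_rb",
    "tresk_rb",
]

FLUX_GATED_SYMK_PRESETS = [
    "traak_wt_symK",
    "trek1_wt_symK",
    "trek2_wt_symK",
    "talk2_wt_symK",
    "task3_wt_symK",
    "tresk_wt_symK",
]


@dataclass(frozen=True)
class HillModeShift:
    """Agonist concentration -> leak-mode fraction, m(c) = m_max c^n/(c^n + EC50^n)."""

    ec50_um: float
    n: float = 1.3
    m_max: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50_um <= 0:
            raise ValueError("EC50 must be > 0")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be > 0")
        if not 0.0 <= self.m_max <= 1.0:
            raise ValueError("m_max must be in [0, 1]")

    def mode_shift(self, concentration_um: float) -> float:
        if concentration_um < 0:
            raise ValueError("concentration must be >= 0")
        if concentration_um == 0:
            return 0.0
        cn = concentration_um**self.n
        return self.m_max * cn / (cn + self.ec50_um**self.n)


@dataclass(frozen=True)
class ChannelPreset:
    name: str
    params: GatingParams
    conditions: BathConditions
    hill: HillModeShift | None = None
    provenance: dict = field(default_factory=dict)


@lru_cache(maxsize=1)
def _registry() -> dict[str, dict]:
    text = (
        resources.files("fluxgate").joinpath("data/presets.json").read_text()
    )
    return json.loads(text)


def list_presets() -> dict[str, dict]:
    """Preset names mapped to their provenance notes."""
    return {name: dict(entry["provenance"]) for name, entry in _registry().items()}


def get_preset(name: str, **param_overrides) -> ChannelPreset:
    """Load a preset by name, optionally overriding kinetic parameters."""
    registry = _registry()
    if name not in registry:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(registry))}"
        )
    entry = registry[name]
    params = GatingParams(**entry["params"]).with_(**param_overrides)
    conditions = BathConditions.from_dict(entry["conditions"])
    hill = None
    if entry.get("hill"):
        h = entry["hill"]
        hill = HillModeShift(ec50_um=h["ec50_uM"], n=h["n"], m_max=h["m_max"])
    return ChannelPreset(
        name=name,
        params=params,
        conditions=conditions,
        hill=hill,
        provenance=dict(entry["provenance"]),
    )
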