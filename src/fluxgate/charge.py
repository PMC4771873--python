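"""Linear-field decomposition of the equivalent gating charge.

The selectivity filter of a K2P channel spans a narrow region over which most
of the transmembrane voltage drops.  If a fraction ``f`` of the membrane field
falls linearly across the filter, then moving an ion from the cavity (outside
the field) to a site at fractional electrical depth ``d`` contributes
``f * d`` elementary charges to the equivalent gating charge.  Loading the
four sites S1-S4 in sequence with the default field fraction 0.8 contributes
[0.8, 0.6, 0.4, 0.2] e0, i.e. 2.0 e0 in total - close to the ~2.2 e0 measured
from Boltzmann fits of K2P tail-current G-V curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FieldModel", "per_site_charge", "total_gating_charge", "evenly_spaced"]

#: Approximate geometric span of the filter (Angstrom).  Metadata only: the
#: decomposition works in electrical distance, not geometric distance.
FILTER_GEOMETRIC_SPAN_A = 12.0


@dataclass(frozen=True)
class FieldModel:
    """Focused-field model of the filter.

    Parameters
    ----------
    field_fraction:
        Fraction of the total membrane voltage drop occurring across the
        filter (default 0.8).
    site_depths:
        Fractional electrical distances of the resting positions of
        successively loaded ions, measured from the cavity side (0) to the
        extracellular end (1).  The first loaded ion is assigned the deepest
        (S1) position; the order does not affect the total.
    """

    field_fraction: float = 0.8
    site_depths: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25)

    def __post_init__(self) -> None:
        if not 0.0 < self.field_fraction <= 1.0:
            raise ValueError(
                f"field_fraction must be in (0, 1], got {self.field_fraction}"
            )
        depths = tuple(float(d) for d in self.site_depths)
        object.__setattr__(self, "site_depths", depths)
        for d in depths:
            if not 0.0 < d <= 1.0:
                raise ValueError(f"site depths must be in (0, 1], got {d}")
        if any(a <= b for a, b in zip(depths, depths[1:])):
            raise ValueError("site depths must be strictly decreasing")

    @property
    def n_sites(self) -> int:
        return len(self.site_depths)


def evenly_spaced(n_sites: int, field_fraction: float = 0.8) -> FieldModel:
    """Field model with ``n_sites`` evenly spaced depths k/n, k = n..1.

    ``n_sites = 4`` reproduces the default S1-S4 geometry (1, 3/4, 1/2, 1/4).
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    depths = tuple((n_sites - k) / n_sites for k in range(n_sites))
    return FieldModel(field_fraction=field_fraction, site_depths=depths)


def per_site_charge(model: FieldModel) -> np.ndarray:
    """Charge contribution (e0) of each successively loaded ion."""
    return model.field_fraction * np.asarray(model.site_depths, dtype=float)


def total_gating_charge(model: FieldModel) -> float:
    """Total equivalent gating charge (e0): the sum of per-site contributions.

    For evenly spaced depths k/n this equals field_fraction * (n + 1) / 2.
    """
    return float(per_site_charge(model).sum())
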