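"""Trajectory statistics: permeation events and per-site filter occupancy.

Works on synthetic per-frame axial ion coordinates that stand in for MD
output.  The pore axis points outward: the cavity lies below the filter, the
extracellular solution above.  The filter spans 1.2 nm, split into four equal
0.3 nm site windows S4 (cavity side) to S1 (extracellular side).

A permeation event is a full, hysteresis-guarded crossing: an ion counts as
having permeated outward only after moving from below the cavity/S4 threshold
to above the S1/extracellular threshold (and symmetrically for inward).
Partial excursions into the filter that return to the same side are never
counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteDefinition",
    "IonTrajectory",
    "SiteOccupancy",
    "PermeationEvents",
    "detect_permeation_events",
    "site_occupancy_fractions",
    "expected_total_occupancy",
    "generate_trajectory",
    "TRAAK_K_OCCUPANCY",
    "TRAAK_RB_OCCUPANCY",
    "TRAAK_PERMEATION_RATE_PER_US",
]

#: Per-site occupancy fractions (S1, S2, S3, S4) of the open TRAAK filter
#: conducting K+ at depolarized voltage, and the corresponding Rb+ profile
#: (S2 suppressed, S4 raised).
TRAAK_K_OCCUPANCY: tuple[float, ...] = (0.58, 0.97, 0.65, 0.46)
TRAAK_RB_OCCUPANCY: tuple[float, ...] = (0.60, 0.30, 0.65, 0.70)

#: Outward permeation rate (events/us) of open TRAAK at depolarized voltage.
TRAAK_PERMEATION_RATE_PER_US = 20.0


@dataclass(frozen=True)
class SiteDefinition:
    """Axial windows (nm) for the filter sites plus hysteresis margins.

    ``edges`` are the five boundaries of the four contiguous site windows,
    cavity side first: S4 = [edges[0], edges[1]), ..., S1 = [edges[3],
    edges[4]).  Below ``edges[0]`` is cavity, at or above ``edges[4]`` is
    extracellular.  Event thresholds sit ``hysteresis`` nm beyond the filter
    on each side.
    """

    edges: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9, 1.2)
    hysteresis: float = 0.05

    def __post_init__(self) -> None:
        if len(self.edges) != 5:
            raise ValueError("edges must contain five boundaries")
        if any(a >= b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if self.hysteresis < 0:
            raise ValueError("hysteresis must be >= 0")

    @property
    def lower_threshold(self) -> float:
        """Full-crossing threshold on the cavity side."""
        return self.edges[0] - self.hysteresis

    @property
    def upper_threshold(self) -> float:
        """Full-crossing threshold on the extracellular side."""
        return self.edges[4] + self.hysteresis

    def site_window(self, site: int) -> tuple[float, float]:
        """Window [lo, hi) for site 1 (S1, extracellular) to 4 (S4)."""
        if site not in (1, 2, 3, 4):
            raise ValueError("site must be 1..4")
        lo = self.edges[4 - site]
        hi = self.edges[5 - site]
        return lo, hi


@dataclass
class IonTrajectory:
    """Per-frame axial ion positions: (n_ions, n_frames) array in nm."""

    frame_interval_ns: float
    positions: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval_ns <= 0:
            raise ValueError("frame interval must be > 0")
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))

    @property
    def n_ions(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_us(self) -> float:
        return self.n_frames * self.frame_interval_ns * 1e-3

    def time_reversed(self) -> "IonTrajectory":
        return IonTrajectory(
            frame_interval_ns=self.frame_interval_ns,
            positions=self.positions[:, ::-1].copy(),
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class SiteOccupancy:
    """Fraction of frames with at least one ion in each site window.

    Sites can be occupied simultaneously, so the fractions need not sum to 1.
    """

    s1: float
    s2: float
    s3: float
    s4: float

    def __post_init__(self) -> None:
        for name in ("s1", "s2", "s3", "s4"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} occupancy must be in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s1, self.s2, self.s3, self.s4])


@dataclass
class PermeationEvents:
    """Counts and frame-resolved times (us) of complete crossings."""

    outward_times_us: np.ndarray
    inward_times_us: np.ndarray

    @property
    def n_outward(self) -> int:
        return len(self.outward_times_us)

    @property
    def n_inward(self) -> int:
        return len(self.inward_times_us)


def detect_permeation_events(
    traj: IonTrajectory, sites: SiteDefinition | None = None
) -> PermeationEvents:
    """Count complete outward and inward filter crossings.

    An outward event is an ion's passage from below the lower (cavity-side)
    threshold to above the upper (extracellular-side) threshold without fully
    returning in between; an event is attributed to the frame at which the
    ion clears the far threshold.  Inward events are symmetric.
    """
    sites = sites or SiteDefinition()
    if traj.n_frames == 0:
        warnings.warn("empty trajectory: zero events", stacklevel=2)
        return PermeationEvents(np.empty(0), np.empty(0))

    lo, hi = sites.lower_threshold, sites.upper_threshold
    out_frames: list[int] = []
    in_frames: list[int] = []
    for ion in range(traj.n_ions):
        x = traj.positions[ion]
        zone = np.zeros(traj.n_frames, dtype=np.int8)
        zone[x < lo] = -1
        zone[x > hi] = 1
        extreme = np.flatnonzero(zone)
        if len(extreme) == 0:
            continue
        z = zone[extreme]
        flips = np.flatnonzero(z[1:] != z[:-1]) + 1
        for k in flips:
            frame = int(extreme[k])
            if z[k] > 0:
                out_frames.append(frame)
            else:
                in_frames.append(frame)

    scale = traj.frame_interval_ns * 1e-3
    return PermeationEvents(
        outward_times_us=np.sort(np.asarray(out_frames, dtype=float)) * scale,
        inward_times_us=np.sort(np.asarray(in_frames, dtype=float)) * scale,
    )


def site_occupancy_fractions(
    traj: IonTrajectory, sites: SiteDefinition | None = None
) -> SiteOccupancy:
    """Fraction of frames with >= 1 ion inside each site window S1-S4."""
    sites = sites or SiteDefinition()
    if traj.n_frames == 0:
        raise ValueError("cannot compute occupancy of an empty trajectory")
    x = traj.positions
    fractions = []
    for site in (1, 2, 3, 4):
        lo, hi = sites.site_window(site)
        occupied = np.any((x >= lo) & (x < hi), axis=0)
        fractions.append(float(occupied.mean()))
    return SiteOccupancy(*fractions)


def expected_total_occupancy(occ: SiteOccupancy) -> float:
    """Mean simultaneous ion count in the filter.

    Expectation of the total count under the per-site indicator
    decomposition: the sum of the four site fractions.
    """
    return float(occ.as_array().sum())


def generate_trajectory(
    rate_per_us: float,
    duration_us: float,
    occupancy_profile: tuple[float, ...] | np.ndarray = TRAAK_K_OCCUPANCY,
    seed: int | None = None,
    frame_interval_ns: float = 1.0,
    sites: SiteDefinition | None = None,
    crossing_frames: int = 8,
) -> IonTrajectory:
    """Synthetic trajectory with Poisson outward crossings and resident ions.

    Complete outward crossings are drawn Poisson(rate * duration); each event
    ion starts parked in the cavity, traverses the filter monotonically over
    ``crossing_frames`` frames, and parks extracellularly.  One resident ion
    per site sits inside its window each frame with probability given by
    ``occupancy_profile`` (order S1, S2, S3, S4) and otherwise excursion-parks
    in the cavity; residents never cross both thresholds, so the detector's
    event count equals the number of drawn crossings exactly.
    """
    if rate_per_us < 0:
        raise ValueError("rate must be >= 0")
    if duration_us <= 0:
        raise ValueError("duration must be > 0")
    profile = np.asarray(occupancy_profile, dtype=float)
    if profile.shape != (4,) or np.any(profile < 0) or np.any(profile > 1):
        raise ValueError("occupancy_profile must be four fractions in [0, 1]")
    sites = sites or SiteDefinition()

    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_us * 1000.0 / frame_interval_ns))
    if n_frames <= crossing_frames + 2:
        raise ValueError("trajectory too short for a complete crossing")

    below = sites.lower_threshold - 0.3
    above = sites.upper_threshold + 0.3
    span = np.linspace(below, above, crossing_frames)

    n_events = int(rng.poisson(rate_per_us * duration_us))
    rows = []
    starts = rng.integers(0, n_frames - crossing_frames, size=n_events)
    for s in np.sort(starts):
        x = np.full(n_frames, below)
        x[s : s + crossing_frames] = span
        x[s + crossing_frames :] = above
        rows.append(x)

    # resident ions reproduce the per-site occupancy profile in expectation
    for site, p in zip((1, 2, 3, 4), profile):
        lo, hi = sites.site_window(site)
        center = 0.5 * (lo + hi)
        inside = rng.random(n_frames) < p
        x = np.where(inside, center, below)
        rows.append(x)

    return IonTrajectory(
        frame_interval_ns=frame_interval_ns,
        positions=np.vstack(rows),
        metadata={
            "rate_per_us": rate_per_us,
            "duration_us": duration_us,
            "n_events_drawn": n_events,
            "occupancy_profile": profile.tolist(),
            "seed": seed,
        },
    )
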