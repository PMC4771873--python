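"""Four-state selectivity-filter kinetic scheme driven by the driving force.

The filter is modeled with four states:

* ``ID`` - ion-depleted inactive (the resting state at negative driving force)
* ``IO`` - ion-occupied inactive (filter loaded with 3-4 ions, not yet open)
* ``AO`` - active, conducting outward
* ``AI`` - active, conducting inward (unstable; decays to ID)

Ion loading (ID <-> IO) equilibrates rapidly according to a Boltzmann
function of the electrochemical driving force dmu = Vm - Erev with slope
RT/zF, where z is the equivalent gating charge.  The conformational opening
step IO -> AO proceeds at a voltage-independent rate and only while the
driving force is outward (dmu > 0): the filter is opened by outward flux.
The active state is a single conducting conformation; ``AO`` vs ``AI`` is a
conduction-direction label controlled by the sign of dmu.  When the driving
force inverts, the active state is relabeled ``AI`` and inactivates to the
structurally distinct ion-depleted state at ``k_inact`` - this produces the
transient inward tail currents and the one-way "check valve" behavior.

Macroscopic current combines a flux-gated component with a mode-shifted
(GHK leak) component:

    I(t) = n_channels * gamma_scale * I_GHK(V) *
           [ (1 - m) * (P_AO + P_AI + po_floor * (P_ID + P_IO)) + m ]

where ``m`` is the fraction of channels shifted into leak mode by agonists.
Simulation is deterministic at the occupancy-probability (ODE) level;
single-channel stochastic gating is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Sequence

import numpy as np
from scipy.linalg import expm, null_space

from .electrochem import BathConditions, ghk_current, ghk_reversal

__all__ = [
    "FilterState",
    "GatingParams",
    "Segment",
    "VoltageProtocol",
    "CurrentTrace",
    "step_family_protocol",
    "loading_equilibrium",
    "rate_matrix",
    "propagate",
    "steady_state",
    "simulate_current",
    "open_fraction",
]

_EXP_CLIP = 40.0  # caps loading rates at k_load0 * e^40; equilibrium ratio
#                   is exact for |dmu - dmu_half| <= 80 * RT/zF


class FilterState(IntEnum):
    ID = 0  # ion-depleted inactive
    IO = 1  # ion-occupied inactive
    AO = 2  # active, outward-conducting
    AI = 3  # active, inward-conducting (unstable)


@dataclass(frozen=True)
class GatingParams:
    """Kinetic and thermodynamic parameters of one channel model.

    Rates are in 1/ms, voltages in mV.  ``z`` is the equivalent gating charge
    (e0) setting the Boltzmann slope RT/zF of ion loading; ``dmu_half`` is the
    driving force at half-maximal loading.  ``k_flip`` is the fast relabeling
    rate between the outward- and inward-conducting active states when the
    driving force changes sign.  ``po_floor`` is the residual conductance of
    the inactive states (the "not entirely impermeable" inactive filter);
    ``mode_shift`` is the fraction of channels in GHK leak mode.
    """

    z: float = 2.2
    dmu_half: float = -15.0
    k_load0: float = 10.0
    k_act: float = 0.23
    k_deact: float = 0.02
    k_inact: float = 0.25
    k_flip: float = 200.0
    po_floor: float = 0.01
    mode_shift: float = 0.0
    n_channels: int = 200
    gamma_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be > 0")
        for name in ("k_load0", "k_act", "k_deact", "k_inact", "k_flip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.mode_shift <= 1.0:
            raise ValueError("mode_shift must be in [0, 1]")
        if not 0.0 <= self.po_floor < 1.0:
            raise ValueError("po_floor must be in [0, 1)")
        if self.n_channels < 0:
            raise ValueError("n_channels must be >= 0")
        if self.gamma_scale <= 0:
            raise ValueError("gamma_scale must be > 0")

    def with_(self, **kwargs) -> "GatingParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Segment:
    """One protocol segment: constant voltage, or a linear ramp if
    ``v_end_mv`` is given."""

    duration_ms: float
    v_start_mv: float
    v_end_mv: float | None = None

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be > 0")

    @property
    def is_ramp(self) -> bool:
        return self.v_end_mv is not None and self.v_end_mv != self.v_start_mv


@dataclass
class VoltageProtocol:
    """Ordered voltage segments sampled at a uniform interval ``dt_ms``."""

    segments: list[Segment]
    dt_ms: float = 0.05

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        self.segments = [
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        ]
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.dt_ms > min(s.duration_ms for s in self.segments):
            raise ValueError("dt must not exceed the shortest segment")

    def n_samples(self) -> int:
        return sum(int(round(s.duration_ms / self.dt_ms)) for s in self.segments)

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples()) * self.dt_ms

    def voltages(self) -> np.ndarray:
        chunks = []
        for s in self.segments:
            n = int(round(s.duration_ms / self.dt_ms))
            if s.is_ramp:
                chunks.append(np.linspace(s.v_start_mv, s.v_end_mv, n))
            else:
                chunks.append(np.full(n, s.v_start_mv))
        return np.concatenate(chunks)

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        segs = []
        for s in self.segments:
            if s.is_ramp:
                segs.append(
                    {"ms": s.duration_ms, "mV_start": s.v_start_mv,
                     "mV_end": s.v_end_mv}
                )
            else:
                segs.append({"ms": s.duration_ms, "mV": s.v_start_mv})
        return {"dt_ms": self.dt_ms, "segments": segs}

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        segs = []
        for s in d["segments"]:
            if "mV" in s:
                segs.append(Segment(s["ms"], s["mV"]))
            else:
                segs.append(Segment(s["ms"], s["mV_start"], s["mV_end"]))
        return cls(segments=segs, dt_ms=float(d["dt_ms"]))


def step_family_protocol(
    step_mv: float,
    hold_mv: float = -80.0,
    hold_ms: float = 50.0,
    step_ms: float = 300.0,
    tail_mv: float = -80.0,
    tail_ms: float = 100.0,
    dt_ms: float = 0.05,
) -> VoltageProtocol:
    """Standard step protocol: hold, 300 ms step, tail at -80 mV."""
    return VoltageProtocol(
        segments=[
            Segment(hold_ms, hold_mv),
            Segment(step_ms, step_mv),
            Segment(tail_ms, tail_mv),
        ],
        dt_ms=dt_ms,
    )


@dataclass
class CurrentTrace:
    """Sampled (time, voltage, current) record, the pipeline's exchange
    currency.  Time in ms (uniform), voltage in mV, current in pA."""

    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if not (len(self.time) == len(self.voltage) == len(self.current)):
            raise ValueError("time, voltage, current must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time must be strictly increasing and uniform")

    @property
    def dt_ms(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def loading_equilibrium(
    dmu: float, params: GatingParams, temperature_k: float = 294.0
) -> float:
    """Probability of the ion-occupied state among the inactive states.

    Boltzmann function of the driving force with slope s = RT/(zF):
    1 / (1 + exp(-(dmu - dmu_half)/s)).
    """
    from .electrochem import thermal_voltage

    s = thermal_voltage(temperature_k) / params.z
    x = (dmu - params.dmu_half) / s
    # expit, written out to keep scipy.special out of the hot path
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def _generator(dmu: float, vt: float, params: GatingParams) -> np.ndarray:
    """4x4 generator matrix Q with Q[i, j] = rate j -> i; columns sum to 0."""
    s = vt / params.z
    x = (dmu - params.dmu_half) / s
    k_on = params.k_load0 * np.exp(min(0.5 * x, _EXP_CLIP))
    k_off = params.k_load0 * np.exp(min(-0.5 * x, _EXP_CLIP))

    ID, IO, AO, AI = FilterState.ID, FilterState.IO, FilterState.AO, FilterState.AI
    q = np.zeros((4, 4))
    q[IO, ID] = k_on
    q[ID, IO] = k_off
    # conformational opening requires outward flux (check valve)
    q[AO, IO] = params.k_act if dmu > 0 else 0.0
    q[IO, AO] = params.k_deact
    # conduction-direction relabeling of the single active conformation
    if dmu >= 0:
        q[AO, AI] = params.k_flip
    else:
        q[AI, AO] = params.k_flip
    # inward-conducting active state inactivates to the ion-depleted state
    q[ID, AI] = params.k_inact
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=0))
    return q


def rate_matrix(
    vm: float, conditions: BathConditions, params: GatingParams
) -> np.ndarray:
    """Generator matrix at membrane voltage ``vm`` under ``conditions``.

    Convention: Q[i, j] is the rate from state j to state i (i != j), columns
    sum to zero, and dp/dt = Q p for a column probability vector p.
    """
    dmu = vm - ghk_reversal(conditions)
    return _generator(dmu, conditions.vt, params)


def _check_state(p: Sequence[float]) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (4,):
        raise ValueError("state vector must have four components")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("state vector must be a normalized probability vector")
    return p


def steady_state(
    vm: float, conditions: BathConditions, params: GatingParams
) -> np.ndarray:
    """Stationary distribution: normalized null vector of the generator."""
    q = rate_matrix(vm, conditions, params)
    ns = null_space(q)
    if ns.shape[1] != 1:
        raise ValueError(
            f"stationary distribution is not unique at vm={vm} mV "
            f"(null space dimension {ns.shape[1]})"
        )
    p = ns[:, 0]
    if p.sum() < 0:
        p = -p
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def propagate(
    initial_state: Sequence[float],
    protocol: VoltageProtocol,
    conditions: BathConditions,
    params: GatingParams,
) -> np.ndarray:
    """State-probability time series under a voltage protocol.

    Piecewise-constant matrix-exponential stepping: within each sample of
    duration ``dt`` the generator is held fixed at that sample's voltage and
    the state advanced by expm(Q dt).  Returns an (n_samples, 4) array whose
    row k is the state at ``times()[k]``; row 0 is the initial state.
    """
    p = _check_state(initial_state)
    v = protocol.voltages()
    n = len(v)
    out = np.empty((n, 4))
    out[0] = p

    erev = ghk_reversal(conditions)
    vt = conditions.vt
    cache: dict[float, np.ndarray] = {}
    for k in range(n - 1):
        vk = v[k]
        t = cache.get(vk)
        if t is None:
            q = _generator(vk - erev, vt, params)
            t = expm(q * protocol.dt_ms)
            cache[vk] = t
        p = t @ p
        if p.min() < 0.0:
            p = np.clip(p, 0.0, None)
            p = p / p.sum()
        out[k + 1] = p
    return out


def open_fraction(states: np.ndarray, params: GatingParams) -> np.ndarray:
    """Conducting fraction mixing flux-gated and leak-mode channels."""
    states = np.atleast_2d(states)
    p_active = states[:, FilterState.AO] + states[:, FilterState.AI]
    p_inactive = states[:, FilterState.ID] + states[:, FilterState.IO]
    m = params.mode_shift
    return (1.0 - m) * (p_active + params.po_floor * p_inactive) + m


def simulate_current(
    protocol: VoltageProtocol,
    conditions: BathConditions,
    params: GatingParams,
    metadata: dict | None = None,
) -> CurrentTrace:
    """Macroscopic current under a voltage protocol.

    The channel population is equilibrated at the first segment's voltage
    (steady-state solve) before the protocol starts.
    """
    v = protocol.voltages()
    p0 = steady_state(protocol.segments[0].v_start_mv, conditions, params)
    states = propagate(p0, protocol, conditions, params)
    po = open_fraction(states, params)

    flux = np.empty_like(v)
    for vu in np.unique(v):
        flux[v == vu] = ghk_current(float(vu), conditions)

    current = params.n_channels * params.gamma_scale * flux * po
    meta = {
        "dt_ms": protocol.dt_ms,
        "conditions": conditions.to_dict(),
        "protocol": protocol.to_dict(),
    }
    if metadata:
        meta.update(metadata)
    return CurrentTrace(
        time=protocol.times(), voltage=v, current=current, metadata=meta
    )
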