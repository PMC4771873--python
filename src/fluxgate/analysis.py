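"""Measurement pipeline for current traces.

Mirrors a patch-clamp workflow: single-exponential time-constant fits,
tail-current extraction, conductance-voltage (G-V) construction from tail
amplitudes, Boltzmann fitting with z = RT/(F * slope), rectification and
tail fold-change statistics, Hill dose-response fits, and the V1/2-vs-Erev
coupling line.

Tail amplitudes are the instantaneous current at the repolarization instant,
obtained by fitting a single exponential to the tail (after a short blanking
window for the capacitive settle) and extrapolating back to the step time.
This definition keeps leak-mode traces well defined: their tails are flat
and the amplitude is simply the ohmic current at the tail voltage.  Because
the Boltzmann model carries a free offset, the constant background current
of the inactive states drops out of the fitted z and V1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.stats import linregress

from .electrochem import BathConditions, ghk_reversal, thermal_voltage
from .gating import CurrentTrace

__all__ = [
    "FitError",
    "ExpFitResult",
    "GVCurve",
    "BoltzmannFitResult",
    "HillFitResult",
    "fit_exponential",
    "extract_tail_amplitude",
    "build_gv",
    "fit_boltzmann",
    "rectification_coefficient",
    "tail_fold_change",
    "fit_hill",
    "v_half_vs_erev",
]

#: Samples discarded at the start of a tail fit (capacitive settle), ms.
TAIL_BLANK_MS = 0.3

#: z bounds for Boltzmann fits, in elementary charges.
Z_BOUNDS = (0.1, 20.0)

#: A fit is flagged saturating when the upper plateau (95% point of the
#: logistic) lies inside the sampled voltage range.
_SATURATION_LOGITS = np.log(0.95 / 0.05)


class FitError(RuntimeError):
    """A nonlinear fit failed to converge or the data cannot constrain it."""


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpFitResult:
    tau_ms: float
    amplitude_pa: float
    baseline_pa: float
    residual_rms: float

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ValueError("tau must be > 0")


def _exp_decay(t, amplitude, tau, baseline):
    return amplitude * np.exp(-t / tau) + baseline


def _fit_exp_arrays(t: np.ndarray, y: np.ndarray) -> ExpFitResult:
    span = float(t[-1] - t[0])
    scale = max(np.max(np.abs(y)), 1e-12)
    if np.ptp(y) < 1e-9 * scale:
        raise FitError("trace is flat over the fit window; tau is undefined")

    baseline0 = float(np.median(y[-max(3, len(y) // 10):]))
    amp0 = float(y[0] - baseline0)
    # time at which the decaying component has dropped to 1/e
    target = baseline0 + amp0 / np.e
    crossing = np.nonzero(
        np.sign(y - target) != np.sign(y[0] - target)
    )[0]
    tau0 = float(t[crossing[0]] - t[0]) if len(crossing) else span / 5.0
    tau0 = min(max(tau0, span / 200.0), span * 5.0)

    model = Model(_exp_decay)
    params = model.make_params(
        amplitude=amp0,
        tau={"value": tau0, "min": span / 1000.0, "max": span * 100.0},
        baseline=baseline0,
    )
    try:
        res = model.fit(y, params, t=t - t[0])
    except Exception as exc:  # lmfit wraps scipy failures
        raise FitError(f"exponential fit failed: {exc}") from exc
    if not res.success:
        raise FitError(f"exponential fit did not converge: {res.message}")
    rms = float(np.sqrt(np.mean(res.residual**2)))
    return ExpFitResult(
        tau_ms=float(res.params["tau"].value),
        amplitude_pa=float(res.params["amplitude"].value),
        baseline_pa=float(res.params["baseline"].value),
        residual_rms=rms,
    )


def fit_exponential(
    trace: CurrentTrace, window: tuple[float, float]
) -> ExpFitResult:
    """Least-squares single-exponential fit A exp(-t/tau) + B over a window.

    ``window`` is (t_start, t_end) in ms; time is re-referenced to the window
    start, so ``amplitude_pa`` is the decaying component at ``t_start``.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window start must precede window end")
    mask = (trace.time >= t0) & (trace.time <= t1)
    if mask.sum() < 10:
        raise ValueError(
            f"fit window contains {int(mask.sum())} samples; need >= 10"
        )
    return _fit_exp_arrays(trace.time[mask], trace.current[mask])


# ---------------------------------------------------------------------------
# tails and G-V curves
# ---------------------------------------------------------------------------


def _segment_runs(trace: CurrentTrace) -> list[tuple[int, int, float]]:
    """Protocol segments as (start, stop, voltage) index triples, stop
    exclusive.

    Uses the protocol carried in the trace metadata when available (this
    keeps segments apart even when adjacent ones share a voltage, e.g. a
    step to the holding potential); otherwise segments are inferred from
    voltage changes.
    """
    proto = trace.metadata.get("protocol") if trace.metadata else None
    if proto and "segments" in proto and "dt_ms" in proto:
        dt = float(proto["dt_ms"])
        runs, start = [], 0
        for seg in proto["segments"]:
            n = int(round(float(seg["ms"]) / dt))
            v = seg.get("mV", seg.get("mV_start"))
            runs.append((start, start + n, float(v)))
            start += n
        if start == len(trace.voltage):
            return runs
    v = trace.voltage
    changes = np.flatnonzero(np.abs(np.diff(v)) > 1e-9) + 1
    bounds = np.concatenate([[0], changes, [len(v)]])
    return [
        (int(a), int(b), float(v[a])) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def extract_tail_amplitude(
    trace: CurrentTrace,
    repolarization_time_ms: float | None = None,
    blank_ms: float = TAIL_BLANK_MS,
) -> float:
    """Instantaneous tail current (pA) at the repolarization instant.

    Fits a single exponential to the tail segment, excluding ``blank_ms``
    after the step, and extrapolates back to the repolarization time.  A flat
    tail (leak mode, or an inactive channel) returns its mean current.
    """
    runs = _segment_runs(trace)
    if repolarization_time_ms is None:
        if len(runs) < 2:
            raise ValueError("trace has no voltage step; cannot locate a tail")
        start, stop, _ = runs[-1]
    else:
        idx = int(np.searchsorted(trace.time, repolarization_time_ms))
        for start, stop, _ in runs:
            if start <= idx < stop:
                break
        else:
            raise ValueError("repolarization time outside the trace")
        start = idx
    t_repol = float(trace.time[start])
    t = trace.time[start:stop]
    y = trace.current[start:stop]
    if t[-1] - t[0] < 5.0:
        raise ValueError(
            f"tail segment of {t[-1] - t[0]:.2f} ms is too short (need >= 5 ms)"
        )
    keep = t >= t_repol + blank_ms
    t, y = t[keep], y[keep]

    scale = max(np.max(np.abs(trace.current)), 1e-12)
    if np.ptp(y) < 1e-6 * scale:
        return float(np.mean(y))
    try:
        fit = _fit_exp_arrays(t, y)
    except FitError:
        return float(np.mean(y))
    # extrapolate the fitted exponential back through the blanking window;
    # the fit's time origin is t[0], which sits (t[0] - t_repol) after the step
    return float(
        fit.amplitude_pa * np.exp((t[0] - t_repol) / fit.tau_ms)
        + fit.baseline_pa
    )


@dataclass
class GVCurve:
    """Normalized tail amplitude versus pre-pulse voltage."""

    prepulse_mv: np.ndarray
    tail_amplitude_pa: np.ndarray
    normalized: np.ndarray
    tail_voltage_mv: float
    saturating: bool = True

    def __post_init__(self) -> None:
        self.prepulse_mv = np.asarray(self.prepulse_mv, dtype=float)
        self.tail_amplitude_pa = np.asarray(self.tail_amplitude_pa, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if not (
            len(self.prepulse_mv)
            == len(self.tail_amplitude_pa)
            == len(self.normalized)
        ):
            raise ValueError("one amplitude per voltage required")


@dataclass(frozen=True)
class BoltzmannFitResult:
    """Boltzmann fit f(x) = amplitude/(1 + exp(-(x - v_half)/slope)) + offset,
    with z = RT/(F * slope)."""

    v_half_mv: float
    z: float
    amplitude: float
    offset: float
    stderr: dict = field(default_factory=dict)
    saturating: bool = True

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be > 0")


def _boltzmann(x, amplitude, v_half, slope, offset):
    return amplitude / (1.0 + np.exp(-(x - v_half) / slope)) + offset


def fit_boltzmann(
    gv: GVCurve | tuple[np.ndarray, np.ndarray],
    temperature_k: float = 294.0,
) -> BoltzmannFitResult:
    """Fit a standard Boltzmann to tail amplitude vs pre-pulse voltage.

    Accepts a :class:`GVCurve` (raw amplitudes are fitted; the free offset
    absorbs any constant background) or an (x, y) pair.  The equivalent
    gating charge is z = RT/(F * slope) with slope in mV.  Fits whose upper
    plateau lies outside the sampled voltage range are flagged
    ``saturating=False``; their z should be treated with caution.
    """
    if isinstance(gv, GVCurve):
        x, y = gv.prepulse_mv, gv.tail_amplitude_pa
    else:
        x, y = np.asarray(gv[0], dtype=float), np.asarray(gv[1], dtype=float)
    if len(x) < 5:
        raise ValueError(f"need >= 5 points for a Boltzmann fit, got {len(x)}")
    order = np.argsort(x)
    x, y = x[order], y[order]

    vt = thermal_voltage(temperature_k)
    slope_min, slope_max = vt / Z_BOUNDS[1], vt / Z_BOUNDS[0]

    amp0 = float(y[-1] - y[0])
    if abs(amp0) < 1e-12 * max(np.max(np.abs(y)), 1e-12):
        raise FitError("G-V has no voltage-dependent component")
    offset0 = float(y[0])
    # analytic guesses: V1/2 at half range, slope from the 20-80% rise span
    yn = (y - y[0]) / amp0
    v_half0 = float(np.interp(0.5, yn, x))
    x20 = float(np.interp(0.2, yn, x))
    x80 = float(np.interp(0.8, yn, x))
    slope0 = min(max((x80 - x20) / (2.0 * np.log(4.0)), slope_min), slope_max)

    model = Model(_boltzmann)
    params = model.make_params(
        amplitude=amp0,
        v_half=v_half0,
        slope={"value": slope0, "min": slope_min, "max": slope_max},
        offset=offset0,
    )
    try:
        res = model.fit(y, params, x=x)
    except Exception as exc:
        raise FitError(f"Boltzmann fit failed: {exc}") from exc
    if not res.success:
        raise FitError(f"Boltzmann fit did not converge: {res.message}")

    slope = float(res.params["slope"].value)
    v_half = float(res.params["v_half"].value)
    saturating = bool(v_half + _SATURATION_LOGITS * slope <= x[-1])
    stderr = {
        name: (float(p.stderr) if p.stderr is not None else float("nan"))
        for name, p in res.params.items()
    }
    stderr["z"] = (
        vt / slope**2 * stderr["slope"] if np.isfinite(stderr["slope"]) else
        float("nan")
    )
    return BoltzmannFitResult(
        v_half_mv=v_half,
        z=vt / slope,
        amplitude=float(res.params["amplitude"].value),
        offset=float(res.params["offset"].value),
        stderr=stderr,
        saturating=saturating,
    )


def build_gv(
    traces: list[CurrentTrace], temperature_k: float = 294.0
) -> GVCurve:
    """G-V curve from a family of step traces with a common tail voltage.

    Tail amplitudes are normalized to the fitted Boltzmann amplitude when the
    fit saturates within the sampled range; otherwise to the observed range,
    and the curve is flagged non-saturating.
    """
    if len(traces) < 5:
        raise ValueError("need >= 5 pre-pulse voltages to build a G-V curve")
    prepulses, amps, tail_vs = [], [], []
    for trace in traces:
        runs = _segment_runs(trace)
        if len(runs) < 3:
            raise ValueError("each trace needs hold, step and tail segments")
        prepulses.append(runs[-2][2])
        tail_vs.append(runs[-1][2])
        amps.append(extract_tail_amplitude(trace))
    if np.ptp(tail_vs) > 1e-9:
        raise ValueError(f"inconsistent tail voltages: {sorted(set(tail_vs))}")

    order = np.argsort(prepulses)
    x = np.asarray(prepulses, dtype=float)[order]
    y = np.asarray(amps, dtype=float)[order]

    saturating = False
    normalized = None
    try:
        fit = fit_boltzmann((x, y), temperature_k)
        if fit.saturating:
            saturating = True
            normalized = (y - fit.offset) / fit.amplitude
    except FitError:
        pass
    if normalized is None:
        span = np.ptp(y)
        if span < 1e-12 * max(np.max(np.abs(y)), 1e-12):
            normalized = np.ones_like(y)  # voltage-independent (leak) family
        else:
            normalized = (y - y[0]) / (y[-1] - y[0])
    return GVCurve(
        prepulse_mv=x,
        tail_amplitude_pa=y,
        normalized=normalized,
        tail_voltage_mv=float(tail_vs[0]),
        saturating=saturating,
    )


# ---------------------------------------------------------------------------
# family statistics
# ---------------------------------------------------------------------------


def _end_of_step_current(trace: CurrentTrace, end_fraction: float = 0.05) -> float:
    """Mean current over the last ``end_fraction`` of the step segment."""
    runs = _segment_runs(trace)
    if len(runs) < 2:
        raise ValueError("trace has no step segment")
    start, stop, _ = runs[-2]
    n = max(int(round((stop - start) * end_fraction)), 1)
    return float(np.mean(trace.current[stop - n : stop]))


def _find_by_prepulse(
    traces: list[CurrentTrace], voltage: float
) -> CurrentTrace:
    for trace in traces:
        runs = _segment_runs(trace)
        if len(runs) >= 2 and abs(runs[-2][2] - voltage) < 1e-6:
            return trace
    raise ValueError(f"no trace with a step to {voltage} mV in the family")


def rectification_coefficient(
    traces: list[CurrentTrace],
    positive_mv: float = 100.0,
    negative_mv: float = -100.0,
) -> float:
    """End-of-step current ratio I(+100 mV) / |I(-100 mV)|.

    Equals 1 for a linear conductance in symmetric K+; large values report
    flux-gated outward rectification.
    """
    i_pos = _end_of_step_current(_find_by_prepulse(traces, positive_mv))
    i_neg = _end_of_step_current(_find_by_prepulse(traces, negative_mv))
    scale = max(abs(i_pos), abs(i_neg))
    if scale == 0.0 or abs(i_neg) < 1e-9 * scale:
        raise ValueError(
            "current at the negative step is below the noise floor; "
            "rectification coefficient is undefined"
        )
    return float(i_pos / abs(i_neg))


def tail_fold_change(
    traces: list[CurrentTrace], depolarized_mv: float = 100.0
) -> float:
    """Tail amplitude after a depolarized pre-pulse relative to the tail
    after a pre-pulse at the holding level."""
    hold_mv = _segment_runs(traces[0])[0][2]
    num = extract_tail_amplitude(_find_by_prepulse(traces, depolarized_mv))
    den = extract_tail_amplitude(_find_by_prepulse(traces, hold_mv))
    scale = max(abs(num), abs(den))
    if scale == 0.0 or abs(den) < 1e-9 * scale:
        raise ValueError("holding-level tail amplitude is ~0; fold change undefined")
    return float(num / den)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillFitResult:
    ec50_um: float
    hill_n: float
    max_fold: float
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ec50_um <= 0:
            raise ValueError("EC50 must be > 0")


def _hill(c, ec50, n, max_fold):
    c = np.asarray(c, dtype=float)
    return 1.0 + (max_fold - 1.0) * c**n / (c**n + ec50**n)


def fit_hill(
    concentrations_um: np.ndarray, fold_activation: np.ndarray
) -> HillFitResult:
    """Standard Hill fit of fold-activation versus agonist concentration.

    The unstimulated level is fixed at fold = 1.  Flat or decreasing dose
    series cannot constrain the fit and raise :class:`FitError`.
    """
    c = np.asarray(concentrations_um, dtype=float)
    y = np.asarray(fold_activation, dtype=float)
    if len(c) < 4:
        raise ValueError(f"need >= 4 concentrations, got {len(c)}")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0 for a Hill fit")
    order = np.argsort(c)
    c, y = c[order], y[order]

    if np.ptp(y) < 1e-9 * max(np.max(np.abs(y)), 1e-12):
        raise FitError("dose-response is flat; EC50 is undefined")
    trend = np.corrcoef(np.log(c), y)[0, 1]
    if not trend > 0:
        raise FitError(
            f"dose-response is not increasing (correlation {trend:.2f}); "
            "Hill fit is not meaningful"
        )

    max0 = float(np.max(y))
    half = 1.0 + (max0 - 1.0) / 2.0
    ec50_0 = float(np.interp(half, y, c))
    model = Model(_hill)
    params = model.make_params(
        ec50={"value": ec50_0, "min": c[0] / 100.0, "max": c[-1] * 100.0},
        n={"value": 1.0, "min": 0.2, "max": 6.0},
        max_fold={"value": max0, "min": 1.0 + 1e-9},
    )
    try:
        res = model.fit(y, params, c=c)
    except Exception as exc:
        raise FitError(f"Hill fit failed: {exc}") from exc
    if not res.success:
        raise FitError(f"Hill fit did not converge: {res.message}")
    stderr = {
        name: (float(p.stderr) if p.stderr is not None else float("nan"))
        for name, p in res.params.items()
    }
    return HillFitResult(
        ec50_um=float(res.params["ec50"].value),
        hill_n=float(res.params["n"].value),
        max_fold=float(res.params["max_fold"].value),
        stderr=stderr,
    )


# ---------------------------------------------------------------------------
# V1/2 vs Erev coupling
# ---------------------------------------------------------------------------


@dataclass
class VhalfErevResult:
    slope: float
    intercept_mv: float
    table: pd.DataFrame


def v_half_vs_erev(
    results: list[tuple[BathConditions, BoltzmannFitResult]],
) -> VhalfErevResult:
    """Least-squares line of fitted V1/2 against the computed Erev.

    A slope of 1 means activation tracks the electrochemical driving force
    rather than the absolute membrane voltage.
    """
    if len(results) < 3:
        raise ValueError("need >= 3 condition sets")
    erev = np.array([ghk_reversal(cond) for cond, _ in results])
    v_half = np.array([fit.v_half_mv for _, fit in results])
    if np.ptp(erev) < 1e-9:
        raise ValueError(
            "all conditions share the same reversal potential; slope undefined"
        )
    fit = linregress(erev, v_half)
    table = pd.DataFrame({"erev_mV": erev, "v_half_mV": v_half})
    return VhalfErevResult(
        slope=float(fit.slope), intercept_mv=float(fit.intercept), table=table
    )
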