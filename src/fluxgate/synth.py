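"""Synthetic trace and dose-response generators.

Everything the analysis pipeline consumes can be generated here: voltage-step
trace families with seeded Gaussian recording noise, agonist dose-response
tables from a preset's Hill mode-shift law, and (via
:mod:`fluxgate.occupancy`) Poisson permeation trajectories.  Generation is
bitwise reproducible for a fixed seed, and noise-free output is exactly the
deterministic simulator output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import (
    CurrentTrace,
    VoltageProtocol,
    open_fraction,
    simulate_current,
    steady_state,
    step_family_protocol,
)
from .electrochem import ghk_current
from .presets import ChannelPreset

__all__ = [
    "NoiseSpec",
    "STANDARD_STEP_VOLTAGES",
    "generate_family",
    "generate_dose_response",
    "make_fixtures",
]

#: Standard step family: -100 to +100 mV in 20 mV increments.
STANDARD_STEP_VOLTAGES: tuple[float, ...] = tuple(np.arange(-100.0, 101.0, 20.0))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian recording noise.

    ``sigma`` is the standard deviation as a fraction of the trace's maximum
    absolute current.  No drift or line-frequency artifacts are emulated.
    """

    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def generate_family(
    preset: ChannelPreset,
    voltages: tuple[float, ...] = STANDARD_STEP_VOLTAGES,
    noise: NoiseSpec | float = 0.0,
    seed: int | None = None,
    hold_mv: float = -80.0,
    hold_ms: float = 50.0,
    step_ms: float = 300.0,
    tail_mv: float = -80.0,
    tail_ms: float = 100.0,
    dt_ms: float = 0.05,
    out_dir: str | Path | None = None,
) -> list[CurrentTrace]:
    """Simulate one trace per step voltage for a preset.

    ``noise`` may be a :class:`NoiseSpec` or a bare sigma (the ``seed``
    argument then supplies the generator seed).  With sigma = 0 the traces
    are exactly the deterministic simulator output.  When ``out_dir`` is
    given, traces are also written as CSV + JSON sidecars.
    """
    if not isinstance(noise, NoiseSpec):
        noise = NoiseSpec(sigma=float(noise), seed=seed)
    rng = np.random.default_rng(noise.seed)

    traces = []
    for v in voltages:
        protocol = step_family_protocol(
            v, hold_mv=hold_mv, hold_ms=hold_ms, step_ms=step_ms,
            tail_mv=tail_mv, tail_ms=tail_ms, dt_ms=dt_ms,
        )
        trace = simulate_current(
            protocol,
            preset.conditions,
            preset.params,
            metadata={
                "preset": preset.name,
                "step_mV": float(v),
                "noise_sigma": noise.sigma,
                "seed": noise.seed,
            },
        )
        if noise.sigma > 0:
            scale = np.max(np.abs(trace.current))
            trace.current = trace.current + rng.normal(
                0.0, noise.sigma * scale, size=len(trace.current)
            )
        traces.append(trace)

    if out_dir is not None:
        from .io import write_trace

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for trace in traces:
            v = trace.metadata["step_mV"]
            tag = f"m{abs(v):03.0f}" if v < 0 else f"p{v:03.0f}"
            write_trace(trace, out_dir / f"{preset.name}_{tag}.csv")
    return traces


def _steady_current(preset: ChannelPreset, vm: float, mode_shift: float) -> float:
    """Steady-state macroscopic current at a fixed voltage and leak fraction."""
    params = preset.params.with_(mode_shift=mode_shift)
    p = steady_state(vm, preset.conditions, params)
    po = float(open_fraction(p, params)[0])
    flux = ghk_current(vm, preset.conditions)
    return params.n_channels * params.gamma_scale * flux * po


def generate_dose_response(
    preset: ChannelPreset,
    concentrations_um,
    noise: NoiseSpec | float = 0.0,
    seed: int | None = None,
    test_mv: float = -80.0,
) -> pd.DataFrame:
    """Fold-activation at ``test_mv`` for each agonist concentration.

    The preset's Hill law maps concentration to the leak-mode fraction m;
    fold-activation is the steady-state current relative to the unstimulated
    channel.  Multiplicative Gaussian noise of the given sigma is applied to
    the fold values.  Returns a DataFrame with columns ``concentration_uM``
    and ``fold_activation``.
    """
    conc = np.asarray(list(concentrations_um), dtype=float)
    if conc.size == 0:
        raise ValueError("need at least one concentration")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    if preset.hill is None:
        raise ValueError(f"preset {preset.name!r} has no agonist Hill law")
    if not isinstance(noise, NoiseSpec):
        noise = NoiseSpec(sigma=float(noise), seed=seed)
    rng = np.random.default_rng(noise.seed)

    i_ref = _steady_current(preset, test_mv, preset.params.mode_shift)
    if i_ref == 0.0:
        raise ValueError(
            f"unstimulated current is zero at {test_mv} mV; fold undefined"
        )
    fold = np.array(
        [
            _steady_current(preset, test_mv, preset.hill.mode_shift(c)) / i_ref
            for c in conc
        ]
    )
    if noise.sigma > 0:
        fold = fold * (1.0 + rng.normal(0.0, noise.sigma, size=fold.shape))
    return pd.DataFrame({"concentration_uM": conc, "fold_activation": fold})


def make_fixtures(out_dir: str | Path, seed: int = 1) -> dict[str, list[str]]:
    """Write a small standard corpus: step families, a dose series, and a
    permeation trajectory.  Returns the files written, grouped by kind."""
    from .io import write_results, write_trajectory
    from .occupancy import TRAAK_PERMEATION_RATE_PER_US, generate_trajectory
    from .presets import get_preset

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"traces": [], "dose": [], "trajectory": []}

    for name in ("traak_wt_symK", "trek1_wt_symK", "twik1_leak", "kv_control"):
        preset = get_preset(name)
        family_dir = out_dir / name
        generate_family(preset, noise=NoiseSpec(0.02, seed), out_dir=family_dir)
        written["traces"].append(str(family_dir))

    aa = get_preset("traak_aa")
    conc = np.geomspace(0.1, 30.0, 7)
    table = generate_dose_response(aa, conc, noise=NoiseSpec(0.05, seed))
    dose_path = out_dir / "traak_aa_dose.csv"
    table.to_csv(dose_path, index=False)
    written["dose"].append(str(dose_path))

    traj = generate_trajectory(
        TRAAK_PERMEATION_RATE_PER_US, duration_us=1.0, seed=seed
    )
    traj_path = out_dir / "traak_trajectory.csv"
    write_trajectory(traj, traj_path)
    written["trajectory"].append(str(traj_path))

    write_results(written, out_dir / "manifest.json")
    return written
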