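# Methods

This note documents the model, its parameters, the numerical choices, what
the synthetic data do and do not emulate, and the design decisions taken
where the underlying science leaves the implementation open.

## Electrochemistry

Reversal potentials come from the GHK voltage equation for monovalent
cations, `Erev = (RT/F) ln(Σ P_s c_ext,s / Σ P_s c_int,s)`, which reduces
exactly to the Nernst potential for a single permeant species. Open-pore
current follows the GHK current equation with outward current positive; the
removable singularity at V = 0 is evaluated by a second-order series below
|V| < 1e-6 mV, and the negative-voltage branch is computed in a
multiplied-through form to avoid overflow of e^(−u). Units are fixed: mV,
ms, pA, mM.

Temperature defaults to 294 K ("room temperature"; RT/F ≈ 25.33 mV).
Relative permeabilities other than K⁺ (Tl⁺ 1.1, Rb⁺ 0.7, NH₄⁺ 0.3, Cs⁺ 0.1,
Na⁺ 0.01, NMDG⁺ 0) are package assumptions chosen to reproduce the
qualitative selectivity sequence of K⁺ channels — they are not measured
values, and none of the calibrated observables depends on them beyond the
sign and rough magnitude of Erev shifts. NMDG⁺ is strictly impermeant and
contributes to no current or reversal. Ion-activity corrections, surface
potentials and divalent block are out of scope.

## Gating-charge decomposition

Assuming a fraction f (default 0.8) of the membrane field drops linearly
across the filter, an ion moving from the cavity (outside the field) to
electrical depth d contributes f·d e₀. With four evenly spaced sites
(d = 1, 3/4, 1/2, 1/4 for S1..S4) the contributions are 0.8, 0.6, 0.4,
0.2 e₀ and total 2.0 e₀; for evenly spaced depths the total has the closed
form f·(n+1)/2. Depths are electrical, not geometric; the ~12 Å geometric
span of the filter is retained as metadata only. Ion–ion repulsion
corrections and non-linear field profiles are deliberately not modeled, and
no correction is applied for the small gap between the 2.0 e₀ arithmetic
and the ~2.2 e₀ experimental average.

## Kinetic scheme

Four states: ion-depleted inactive (ID), ion-occupied inactive (IO), active
outward-conducting (AO), active inward-conducting (AI). The generator
matrix uses the column convention dp/dt = Q p.

Design decisions where no rate law is prescribed by the data:

* **Ion loading (ID↔IO).** Implemented with a symmetric barrier
  (δ = 0.5): forward rate k_load0·e^(+x/2), backward k_load0·e^(−x/2) with
  x = (Δμ − Δμ½)/(RT/zF). This guarantees the Boltzmann equilibrium
  occupancy with slope RT/zF regardless of k_load0. k_load0 = 10/ms makes
  loading fast relative to opening (the ion-translocation step is treated
  as quasi-instantaneous). Rate exponents are clipped at e^±40; the
  equilibrium ratio is exact for |x| ≤ 80.
* **Opening (IO→AO).** Rate k_act, voltage independent, but conditional on
  Δμ > 0: the filter is opened by outward flux. This conditionality is what
  makes the check valve exact — at any voltage below Erev the steady-state
  conducting probability is identically zero (not merely small).
* **AO vs AI.** A single conducting conformation carrying a
  direction-of-conduction label, not two free-energy wells. The label
  follows the sign of Δμ through a fast relabeling rate k_flip = 200/ms
  (settled within ~0.03 ms, well inside the tail blanking window).
* **Inactivation (AI→ID).** The inward-conducting state decays at k_inact
  to the structurally distinct ion-depleted state (rather than back through
  IO); 1/k_inact is the tail time constant. The alternative (deactivation
  through IO) cannot be distinguished from tail decay alone; the AI→ID
  arrow was chosen and k_inact set from the printed tail τ only.
* **Residual conductance.** Inactive states conduct po_floor of the
  open-pore current ("not entirely impermeable" filter). This gives the
  finite inward currents needed for a finite rectification coefficient; its
  physical origin is not modeled.
* **Mode shift.** A fraction m of channels behaves as a pure GHK leak.
  Agonists map to m through a Hill function per preset (EC₅₀, n_H, m_max);
  a Hill law is an assumption consistent with single-site dose-response
  fitting practice.

Consequences used as tests: the steady-state conducting fraction is
A/(1 + e^(−(Δμ−Δμ_eff)/s)) — exactly a Boltzmann with the loading slope s
and midpoint Δμ_eff = Δμ½ − s·ln(1 + k_act/k_deact) — so noise-free G-V
fits recover the preset z; and V½ shifts exactly with Erev because the
scheme depends on voltage only through Δμ. Below Erev the G-V is clamped at
zero by the check valve, so Boltzmann fits should sample pre-pulses at or
above Erev (saturating-fit practice); points below Erev shallow the fitted
z by ~1 %.

## Numerics

Propagation is piecewise-constant matrix-exponential stepping: within each
dt sample the generator is frozen at the sample's voltage and the state
advanced by expm(Q·dt), with the exponential cached per distinct voltage.
Probabilities are conserved to ~1e-14 over 10⁴ steps; tiny negative
round-off is clipped and renormalized. Against an explicit-Euler oracle at
h = 1e-5 ms the propagated states agree to < 1e-6 per state (the residual
is the oracle's own first-order error — it scales as h). Steady states are
nullspace solves; a non-unique stationary distribution raises an error.
Every protocol is preceded by a steady-state solve at its first segment's
voltage (holding-potential equilibration).

Fits use Levenberg–Marquardt nonlinear least squares (lmfit) with analytic
initial guesses: exponential τ from the 1/e crossing; Boltzmann V½ at half
range and slope from the 20–80 % rise span; Hill EC₅₀ from the half-rise
interpolation. Boltzmann slopes are bounded to z ∈ (0.1, 20]. A fit is
flagged non-saturating when the 95 % point of the logistic lies beyond the
sampled voltage range; such z values are reported but flagged (mirroring the
practice of not fitting non-saturating K⁺ G-V curves). Tail amplitudes are
single-exponential fits over the tail segment, excluding a 0.3 ms blanking
window (capacitive settle; the value is a convention), extrapolated back to
the repolarization instant. The amplitude is the instantaneous total
current, not a baseline-subtracted difference: this keeps flat leak-mode
tails well defined (their amplitude is the ohmic step) and the free offset
of the Boltzmann model absorbs the constant inactive-state background.
End-of-step current is the mean of the last 5 % of the step samples.

## Presets and calibration

Preset parameters fall in two classes. Printed observables fix: z per
channel (1.8–2.6 e₀, mean 2.2, for the six K2P presets fitted under
intracellular Rb⁺; 4.6 e₀ for the voltage-gated control), k_act + k_deact
(τ_act = 4 ms), k_inact (τ_tail = 4 ms), the TREK-1 po_floor
(rectification 47), and the TRAAK agonist EC₅₀ (1.2 μM). Everything else
(k_load0, Δμ½, gamma_scale, the other po_floor values, Rb⁺/Cs⁺ overrides,
Hill n_H and m_max) is a free calibration constant documented as an
assumption in each preset's provenance notes. Δμ½ is −15 mV for
symmetric-K⁺ presets (loading saturated above +20 mV, hence
voltage-independent τ_act with CV < 2 %) and +70 mV for Rb⁺ presets (smooth,
saturating G-V inside the −100..+100 mV window). Permeant-ion effects are
encoded purely as preset overrides, not predicted from occupancy. The
twik1_leak preset has m = 1 (pure GHK leak); traak_physK/traak_invK change
only the K⁺ gradient (120/4 and 4/120 mM).

## Synthetic data

The generators emulate: the standard voltage-step family (hold −80 mV for
50 ms, 300 ms steps −100..+100 mV in 20 mV increments, 100 ms tail at
−80 mV, dt = 0.05 ms), ion-condition variants, agonist dose series from the
preset Hill law, additive Gaussian recording noise (σ relative to the trace
maximum; seeded), and permeation trajectories with Poisson-distributed
complete crossings plus per-site resident ions that reproduce a target
occupancy profile in expectation. They do **not** emulate amplifier
filtering, series-resistance or capacitance artifacts, drift, line noise,
single-channel stochasticity, or real MD output (no force fields, no
electric field, no water). Passing tests therefore demonstrate the
self-consistency of model + pipeline (parameter recovery, detector-generator
round trips), not agreement with any real recording.

Trajectory conventions: the filter spans 1.2 nm split into four equal
0.3 nm windows (window positions are a package convention, not data);
occupancy is a per-site binary indicator (≥ 1 ion), so simultaneous
occupancy is allowed and fractions need not sum to 1; the mean filter
occupancy is the sum of the four site fractions (indicator decomposition).
An event requires both hysteresis thresholds (0.05 nm beyond the filter) to
be fully crossed and is attributed to the frame clearing the far threshold.
The double-threshold criterion is validated only against the package's own
generator. Occupancy recovery error scales as 1/√frames; profiles are
recovered to ±0.02 at 10⁵ frames.

## Problem sizes

Default simulations are desk-scale by design: 9 000 samples per trace
(450 ms at dt = 0.05 ms), 11–21 traces per family, 10-replicate noise
ensembles, 10 μs trajectories at 1 ns frames (10⁴ frames) and 20-seed
Poisson ensembles. The full test suite and the acceptance script each run
in well under a minute on a single core.

## Known limitations

* The check valve is exact by construction (the Δμ > 0 gate on opening);
  real channels may leak slightly below Erev in ways po_floor only
  caricatures.
* AI occupancy has no quantitative experimental description; k_flip and the
  AI→ID route are conventions constrained only by the tail τ.
* Rb⁺/Cs⁺ potentiation is parameterized, not mechanistic: the occupancy
  module and the gating module are linked by narrative, not by equations.
* Boltzmann z from non-saturating curves is biased low and only reported
  with a flag; the normalization of such curves (to the observed maximum)
  is a convention.
* Divalent block, state-dependent blockers, mechanosensitive tension terms
  and temperature-dependent gating are out of scope; pressure/pH activation
  appears only as a mode-shift override.
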