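import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluxgate import analysis, get_preset
from fluxgate.electrochem import BathConditions, ghk_reversal, thermal_voltage
from fluxgate.gating import (
    FilterState,
    GatingParams,
    Segment,
    VoltageProtocol,
    loading_equilibrium,
    open_fraction,
    propagate,
    rate_matrix,
    simulate_current,
    steady_state,
    step_family_protocol,
)
from fluxgate.synth import generate_family


class TestLoadingEquilibrium:
    def test_half_loading_at_dmu_half(self):
        params = GatingParams(dmu_half=-15.0)
        assert loading_equilibrium(-15.0, params) == pytest.approx(0.5)

    def test_one_slope_unit_above_midpoint(self):
        # z = 2.2 at 294 K gives s = RT/zF = 11.52 mV; one slope unit up the
        # logistic is 1/(1 + e^-1) ~ 0.731
        params = GatingParams(z=2.2, dmu_half=0.0)
        s = thermal_voltage(294.0) / 2.2
        assert loading_equilibrium(s, params) == pytest.approx(0.731, abs=2e-3)

    def test_saturation_limits(self):
        params = GatingParams(z=2.2, dmu_half=0.0)
        assert loading_equilibrium(-1e4, params) == pytest.approx(0.0, abs=1e-12)
        assert loading_equilibrium(+1e4, params) == pytest.approx(1.0, abs=1e-12)


class TestRateMatrix:
    @given(vm=st.floats(min_value=-150.0, max_value=150.0))
    def test_columns_sum_to_zero(self, vm, symk, traak):
        q = rate_matrix(vm, symk, traak.params)
        np.testing.assert_allclose(q.sum(axis=0), 0.0, atol=1e-12)
        off_diag = q[~np.eye(4, dtype=bool)]
        assert np.all(off_diag >= 0)

    @given(vm=st.floats(min_value=-120.0, max_value=120.0))
    def test_loading_detailed_balance(self, vm, symk, traak):
        q = rate_matrix(vm, symk, traak.params)
        f = loading_equilibrium(vm - ghk_reversal(symk), traak.params,
                                symk.temperature_k)
        ratio = q[FilterState.IO, FilterState.ID] / q[FilterState.ID, FilterState.IO]
        assert ratio == pytest.approx(f / (1.0 - f), rel=1e-9)

    def test_activation_rate_voltage_independent(self, symk, traak):
        q20 = rate_matrix(20.0, symk, traak.params)
        q100 = rate_matrix(100.0, symk, traak.params)
        assert (
            q20[FilterState.AO, FilterState.IO]
            == q100[FilterState.AO, FilterState.IO]
            == traak.params.k_act
        )

    def test_active_state_label_follows_driving_force_sign(self, symk, traak):
        q_pos = rate_matrix(60.0, symk, traak.params)
        assert q_pos[FilterState.AO, FilterState.AI] == traak.params.k_flip
        assert q_pos[FilterState.AI, FilterState.AO] == 0.0
        q_neg = rate_matrix(-60.0, symk, traak.params)
        assert q_neg[FilterState.AI, FilterState.AO] == traak.params.k_flip
        assert q_neg[FilterState.AO, FilterState.AI] == 0.0
        # inactivation drains the inward-conducting state to ion-depleted
        assert q_neg[FilterState.ID, FilterState.AI] == traak.params.k_inact


class TestPropagate:
    def test_requires_normalized_initial_state(self, symk, traak):
        proto = VoltageProtocol([Segment(2.0, -80.0)], dt_ms=0.5)
        with pytest.raises(ValueError):
            propagate([0.5, 0.2, 0.1, 0.1], proto, symk, traak.params)

    def test_probability_conserved(self, symk, traak):
        proto = step_family_protocol(100.0, dt_ms=0.1, hold_ms=10.0,
                                     step_ms=50.0, tail_ms=20.0)
        p0 = steady_state(-80.0, symk, traak.params)
        states = propagate(p0, proto, symk, traak.params)
        np.testing.assert_allclose(states.sum(axis=1), 1.0, atol=1e-9)
        assert states.min() >= 0.0

    def test_long_hold_converges_to_steady_state(self, symk, traak):
        proto = VoltageProtocol([Segment(2000.0, 40.0)], dt_ms=1.0)
        p0 = np.array([1.0, 0.0, 0.0, 0.0])
        states = propagate(p0, proto, symk, traak.params)
        np.testing.assert_allclose(
            states[-1], steady_state(40.0, symk, traak.params), atol=1e-8
        )

    def test_matches_fine_step_euler_oracle(self, symk, traak):
        proto = VoltageProtocol(
            [Segment(5.0, -80.0), Segment(5.0, 60.0)], dt_ms=0.1
        )
        p0 = steady_state(-80.0, symk, traak.params)
        states = propagate(p0, proto, symk, traak.params)

        refine = 10_000  # explicit Euler at h = 1e-5 ms
        v = proto.voltages()
        ref = np.empty_like(states)
        ref[0] = p = p0.copy()
        h = proto.dt_ms / refine
        for k in range(len(v) - 1):
            m = np.eye(4) + h * rate_matrix(v[k], symk, traak.params)
            for _ in range(refine):
                p = m @ p
            ref[k + 1] = p
        assert np.max(np.abs(states - ref)) < 1e-6


class TestSteadyState:
    def test_hyperpolarized_filter_is_ion_depleted(self, symk, traak):
        p = steady_state(-80.0, symk, traak.params)
        assert p[FilterState.ID] > 0.9
        assert p[FilterState.AO] + p[FilterState.AI] < 1e-12

    def test_depolarized_filter_is_mostly_active(self, symk, traak):
        p = steady_state(100.0, symk, traak.params)
        assert p[FilterState.AO] > 0.85

    def test_normalized(self, symk, traak):
        for vm in (-100.0, -5.0, 5.0, 100.0):
            p = steady_state(vm, symk, traak.params)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert p.min() >= 0.0


class TestCheckValve:
    def test_no_steady_inward_current_without_floor(self, symk, traak):
        """At any voltage negative to Erev a flux-gated channel carries zero
        steady-state current (the valve is shut)."""
        params = traak.params.with_(po_floor=0.0)
        for vm in (-120.0, -60.0, -20.0, -1.0):
            p = steady_state(vm, symk, params)
            po = float(open_fraction(p, params)[0])
            assert abs(po) < 1e-12

    def test_transient_inward_tail_requires_depolarized_prepulse(self, symk, traak):
        params = traak.params.with_(po_floor=0.0)
        proto_dep = step_family_protocol(100.0, dt_ms=0.1)
        trace_dep = simulate_current(proto_dep, symk, params)
        proto_hyp = step_family_protocol(-100.0, dt_ms=0.1)
        trace_hyp = simulate_current(proto_hyp, symk, params)
        tail = trace_dep.time >= 350.0
        assert trace_dep.current[tail].min() < -100.0  # large inward tail
        assert np.max(np.abs(trace_hyp.current)) < 1e-9  # never opens


class TestSimulateCurrent:
    def test_zero_channels_zero_trace(self, symk, traak):
        proto = step_family_protocol(60.0, dt_ms=0.1)
        trace = simulate_current(proto, symk, traak.params.with_(n_channels=0))
        assert np.all(trace.current == 0.0)

    def test_leak_mode_is_instantaneous_and_linear(self, leak_family):
        iv = [
            (tr.metadata["step_mV"], analysis._end_of_step_current(tr))
            for tr in leak_family
        ]
        v = np.array([p[0] for p in iv])
        i = np.array([p[1] for p in iv])
        fit = np.polyval(np.polyfit(v, i, 1), v)
        r2 = 1.0 - np.sum((i - fit) ** 2) / np.sum((i - i.mean()) ** 2)
        assert r2 > 0.999
        amps = [analysis.extract_tail_amplitude(tr) for tr in leak_family]
        assert np.ptp(amps) < 1e-9 * abs(np.mean(amps))

    def test_tail_decay_recovers_inactivation_rate(self, symk, traak, traak_family):
        trace = next(
            tr for tr in traak_family if tr.metadata["step_mV"] == 100.0
        )
        fit = analysis.fit_exponential(trace, (350.3, 390.0))
        assert fit.tau_ms == pytest.approx(1.0 / traak.params.k_inact, rel=0.02)

    def test_gv_fit_recovers_preset_gating_charge(self):
        """Noise-free G-V round trip: Boltzmann fit returns the preset z and
        the V1/2 implied by the kinetic scheme to < 1%."""
        base = get_preset("traak_rb")
        cond = BathConditions({"Rb": 120.0}, {"K": 4.0})
        # sample at/above Erev (-77 mV): below it the check valve clamps Po
        # to zero, which deviates from the pure Boltzmann foot by design
        fam = generate_family(
            type(base)(base.name, base.params, cond, base.hill, base.provenance),
            voltages=tuple(np.arange(-70.0, 101.0, 10.0)),
        )
        fit = analysis.fit_boltzmann(analysis.build_gv(fam))
        p = base.params
        s = thermal_voltage(cond.temperature_k) / p.z
        v_half_pred = (
            ghk_reversal(cond) + p.dmu_half - s * np.log(1.0 + p.k_act / p.k_deact)
        )
        assert fit.z == pytest.approx(p.z, rel=0.01)
        assert fit.v_half_mv == pytest.approx(v_half_pred, rel=0.01)


class TestProtocolValidation:
    def test_dt_must_not_exceed_shortest_segment(self):
        with pytest.raises(ValueError):
            VoltageProtocol([Segment(1.0, -80.0), Segment(0.1, 40.0)], dt_ms=0.5)

    def test_durations_positive(self):
        with pytest.raises(ValueError):
            Segment(0.0, -80.0)

    def test_round_trip(self):
        proto = VoltageProtocol(
            [Segment(50.0, -80.0), Segment(100.0, -100.0, 100.0)], dt_ms=0.05
        )
        assert VoltageProtocol.from_dict(proto.to_dict()) == proto

    def test_ramp_voltages(self):
        proto = VoltageProtocol([Segment(10.0, 0.0, 90.0)], dt_ms=1.0)
        v = proto.voltages()
        assert v[0] == 0.0 and v[-1] == 90.0 and len(v) == 10
        assert np.all(np.diff(v) > 0)


class TestGatingParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"z": 0.0},
            {"k_act": -1.0},
            {"mode_shift": 1.5},
            {"po_floor": 1.0},
            {"n_channels": -1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GatingParams(**kwargs)
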