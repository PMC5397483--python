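"""A1 input stage: tuning, adaptation, recovery, non-triplet rules."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from streamseg.a1 import (
    A1Params,
    AdaptationState,
    compute_input_trace,
    distractor_response,
    effective_df,
    recover_during_silence,
    tonotopic_weight,
)
from streamseg.paradigm import (
    ToneEvent,
    apply_distractor,
    apply_pause,
    make_triplet_sequence,
    st_to_hz,
)


class TestTonotopicWeight:
    def test_peak_at_zero_distance(self):
        assert tonotopic_weight(3.0, 3.0, 2.5) == 1.0

    @given(d=st.floats(0.01, 30), w=st.floats(0.5, 10))
    def test_symmetric_and_decreasing(self, d, w):
        assert tonotopic_weight(d, 0.0, w) == pytest.approx(
            tonotopic_weight(-d, 0.0, w)
        )
        assert tonotopic_weight(d, 0.0, w) < tonotopic_weight(d * 0.5, 0.0, w)

    def test_gaussian_profile(self):
        assert tonotopic_weight(5.0, 0.0, 2.5) == pytest.approx(
            math.exp(-25 / (2 * 2.5**2))
        )

    def test_far_distractor_weight_negligible(self, a1_params):
        # 15 st above B at DF 7 -> ~13.5 st effective distance when adapted
        w = tonotopic_weight(22.0, 7.0, a1_params.tuning_width_st)
        assert w < 1e-3


class TestEffectiveDF:
    def test_limits(self, a1_params):
        assert effective_df(0.0, 7.0, a1_params) == pytest.approx(
            a1_params.df_onset_frac * 7.0
        )
        assert effective_df(1e7, 7.0, a1_params) == pytest.approx(7.0)

    def test_exponential_relaxation_at_tau(self, a1_params):
        f = effective_df(a1_params.tau_a1, 1.0, a1_params)
        f0 = a1_params.df_onset_frac
        assert f - f0 == pytest.approx((1 - f0) * (1 - math.exp(-1)))

    @given(t1=st.floats(0, 5000), dt=st.floats(1, 2000))
    def test_monotone_nondecreasing(self, t1, dt):
        p = A1Params()
        assert effective_df(t1 + dt, 7.0, p) >= effective_df(t1, 7.0, p)


class TestRecovery:
    def test_zero_silence_identity(self, a1_params):
        s = AdaptationState(amp_state=1.3, df_state=0.8)
        assert recover_during_silence(s, 0.0, a1_params) == s

    def test_600ms_within_e6_of_onset(self, a1_params):
        s = AdaptationState(amp_state=1.0, df_state=1.0)
        out = recover_during_silence(s, 600.0, a1_params)
        g = a1_params.amp_onset_gain
        assert abs(out.amp_state - g) == pytest.approx((g - 1) * math.exp(-6))
        f0 = a1_params.df_onset_frac
        assert abs(out.df_state - f0) == pytest.approx((1 - f0) * math.exp(-6))

    def test_post_pause_pulse_larger_and_lower_df(self, a1_params, net_params):
        tl = make_triplet_sequence(10, 7.0)
        paused = apply_pause(tl, 300, 7)
        trace = compute_input_trace(paused, a1_params, net_params.dt)
        pre = [p for p in trace.provenance if p["onset_ms"] == 2600][0]
        post = [p for p in trace.provenance if p["onset_ms"] == 3100][0]
        assert post["amp_state"] > pre["amp_state"]
        assert post["df_state"] < pre["df_state"]

    def test_longer_pause_larger_first_pulse(self, a1_params, net_params):
        amps = []
        for pause in (0, 150, 300, 600, 1200):
            tl = make_triplet_sequence(10, 7.0)
            if pause:
                tl = apply_pause(tl, pause, 7)
            trace = compute_input_trace(tl, a1_params, net_params.dt)
            first_post = [
                p for p in trace.provenance if p["onset_ms"] == 2800 + pause
            ][0]
            amps.append(first_post["amp_state"])
        assert all(a < b for a, b in zip(amps, amps[1:]))
        assert amps[-1] <= a1_params.amp_onset_gain


class TestInputTrace:
    def test_nonnegative_and_zero_in_silence(self, a1_params, net_params):
        tl = make_triplet_sequence(6, 7.0)
        trace = compute_input_trace(tl, a1_params, net_params.dt)
        assert np.all(trace.I >= 0)
        gap = trace.I[(trace.t >= 300) & (trace.t < 400)]
        assert np.all(gap == 0.0)

    def test_first_triplet_larger_and_less_differentiated(self, a1_params, net_params):
        trace = compute_input_trace(
            make_triplet_sequence(6, 7.0), a1_params, net_params.dt
        )
        p1 = trace.I[:80].max(axis=0)
        p5 = trace.I[64 * 5 : 64 * 5 + 80].max(axis=0)
        assert np.all(p1 > p5)
        # relative spread across units grows as DF dependence emerges
        spread = lambda p: (p.max() - p.min()) / p.mean()
        assert spread(p1) < spread(p5)

    def test_periodic_steady_state(self, a1_params, net_params):
        trace = compute_input_trace(
            make_triplet_sequence(12, 7.0), a1_params, net_params.dt
        )
        t8 = trace.I[80 * 8 : 80 * 9]
        t9 = trace.I[80 * 9 : 80 * 10]
        peak = trace.I.max()
        assert np.abs(t8 - t9).max() < 0.01 * peak

    def test_static_mode_strictly_periodic(self, a1_params, net_params):
        params = replace(a1_params, adapting=False)
        trace = compute_input_trace(
            make_triplet_sequence(8, 7.0), params, net_params.dt
        )
        one = trace.I[:80]
        for k in range(1, 8):
            assert np.array_equal(trace.I[80 * k : 80 * (k + 1)], one)

    def test_ab_receives_largest_onset_input(self, a1_params, net_params):
        # broad onset responses centered near the midpoint bias the AB unit
        for df in (4.0, 7.0, 10.0):
            trace = compute_input_trace(
                make_triplet_sequence(6, df), a1_params, net_params.dt
            )
            first_tone = trace.I[:20]
            assert first_tone.max(axis=0).argmax() == 1

    def test_steady_state_ordering_reverses_with_df(self, a1_params, net_params):
        static = replace(a1_params, adapting=False)
        amps = {}
        for df in (1.0, 10.0):
            trace = compute_input_trace(
                make_triplet_sequence(2, df), static, net_params.dt
            )
            amps[df] = trace.I[:80].mean(axis=0)
        assert amps[1.0][1] > max(amps[1.0][0], amps[1.0][2])  # AB wins, small DF
        assert amps[10.0][1] < amps[10.0][0]                   # AB loses, large DF

    def test_ab_symmetry_per_tone(self, a1_params):
        # at equal adaptation, an A tone drives unit A exactly as a B tone
        # drives unit B, and both drive the AB unit equally
        from streamseg.a1 import _standard_amps, unit_centers_st

        state = AdaptationState(amp_state=1.4, df_state=0.6)
        centers = unit_centers_st(7.0)
        amps_a = _standard_amps(0.0, centers, state, a1_params, 3.5)
        amps_b = _standard_amps(7.0, centers, state, a1_params, 3.5)
        assert amps_a[0] == pytest.approx(amps_b[2])
        assert amps_a[2] == pytest.approx(amps_b[0])
        assert amps_a[1] == pytest.approx(amps_b[1])

    def test_dt_must_divide_grid(self, a1_params):
        with pytest.raises(ValueError, match="divide|grid"):
            compute_input_trace(make_triplet_sequence(2, 7.0), a1_params, dt=7.0)


class TestNonTripletRules:
    def _state(self):
        return AdaptationState(amp_state=1.1, df_state=0.9)

    def _event(self, freq_hz):
        return ToneEvent(1125, 50, freq_hz, "distractor")

    def test_gated_b2_skips_ab_and_exceeds_adapted_b(self, net_params):
        params = A1Params(gate_non_triplet_from_ab=True)
        tl = apply_distractor(make_triplet_sequence(6, 7.0), "B+2", 3)
        trace = compute_input_trace(tl, params, net_params.dt)
        dis = [p for p in trace.provenance if p["label"] == "distractor"][0]
        assert dis["amps"][1] == 0.0
        prior_b = [p for p in trace.provenance if p["label"] == "B"][2]
        assert dis["amps"][2] > prior_b["amps"][2]

    def test_ungated_midpoint_feeds_ab_most(self, a1_params):
        params = replace(a1_params, gate_non_triplet_from_ab=False)
        ev = self._event(st_to_hz(500.0, 5.0))
        amps = distractor_response(ev, self._state(), params, 500.0, 10.0)
        assert amps.argmax() == 1

    def test_masking_applies_to_a_center_only(self, a1_params):
        params = replace(
            a1_params, masking_factor=0.5, boost_to_unadapted=False,
            gate_non_triplet_from_ab=False,
        )
        unmasked = replace(params, masking_factor=1.0)
        ev = self._event(500.0)
        m = distractor_response(ev, self._state(), params, 500.0, 7.0)
        u = distractor_response(ev, self._state(), unmasked, 500.0, 7.0)
        assert m[0] == pytest.approx(0.5 * u[0])
        assert m[1] == u[1] and m[2] == u[2]

    def test_neutral_flags_reduce_to_standard_rule(self, a1_params):
        from streamseg.a1 import _standard_amps, unit_centers_st

        params = replace(
            a1_params, masking_factor=1.0, boost_to_unadapted=False,
            gate_non_triplet_from_ab=False,
        )
        state = self._state()
        ev = self._event(st_to_hz(500.0, 9.0))
        got = distractor_response(ev, state, params, 500.0, 7.0)
        want = _standard_amps(9.0, unit_centers_st(7.0), state, params, 3.5)
        assert np.allclose(got, want)

    def test_rejects_triplet_labels(self, a1_params):
        with pytest.raises(ValueError, match="non-triplet"):
            distractor_response(
                ToneEvent(0, 100, 500.0, "A"), self._state(), a1_params, 500.0, 7.0
            )

    def test_boost_uses_unadapted_gain(self, a1_params):
        params = replace(a1_params, gate_non_triplet_from_ab=False)
        boosted = distractor_response(
            self._event(500.0), self._state(), params, 500.0, 7.0
        )
        plain = distractor_response(
            self._event(500.0), self._state(),
            replace(params, boost_to_unadapted=False), 500.0, 7.0,
        )
        ratio = params.amp_onset_gain / self._state().amp_state
        assert boosted[2] == pytest.approx(plain[2] * ratio)
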