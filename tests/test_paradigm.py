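"""Stimulus construction: triplet grammar, perturbations, designs, audio."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from streamseg.paradigm import (
    GAP_MS,
    TRIPLET_MS,
    DesignTable,
    apply_deviant,
    apply_distractor,
    apply_pause,
    build_timeline,
    hz_to_st,
    make_triplet_sequence,
    pause_experiment_design,
    perturbation_experiment_design,
    resolve_freq_spec,
    rove_base_frequency,
    rove_ladder_hz,
    st_to_hz,
    synthesize_waveform,
    StimulusTimeline,
)


class TestTripletGrammar:
    @given(
        n=st.integers(1, 30),
        df=st.floats(0.5, 15.0),
        base=st.floats(100.0, 2000.0),
    )
    def test_grammar_and_duration(self, n, df, base):
        tl = make_triplet_sequence(n, df, base)
        assert len(tl.events) == 3 * n
        assert tl.total_ms == 400 * n
        labels = [ev.label for ev in tl.events]
        assert labels == ["A", "B", "A"] * n
        for ev in tl.events:
            assert ev.onset_ms % TRIPLET_MS in (0, 100, 200)
        b = tl.events[1]
        assert b.freq_hz == pytest.approx(base * 2 ** (df / 12))

    @pytest.mark.parametrize(
        "n,expected_ms", [(3, 1200), (6, 2400), (10, 4000)]
    )
    def test_printed_durations(self, n, expected_ms):
        assert make_triplet_sequence(n, 7.0, 420.0).total_ms == expected_ms

    def test_b_frequency_twelve_tet(self):
        tl = make_triplet_sequence(1, 10.0, 420.0)
        assert tl.freq_b == pytest.approx(748.36, abs=0.01)

    @given(s=st.floats(-40, 40), base=st.floats(50, 5000))
    def test_semitone_roundtrip(self, s, base):
        assert hz_to_st(st_to_hz(base, s), base) == pytest.approx(s, abs=1e-9)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_triplets=0, df_st=7, base_freq_hz=420), "n_triplets"),
            (dict(n_triplets=3, df_st=-1, base_freq_hz=420), "df_st"),
            (dict(n_triplets=3, df_st=7, base_freq_hz=0), "base_freq_hz"),
        ],
    )
    def test_rejects_nonpositive_naming_field(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            make_triplet_sequence(**kwargs)


class TestPause:
    def test_shift_and_total(self):
        tl = make_triplet_sequence(10, 7.0)
        paused = apply_pause(tl, 600, after_triplet=7)
        assert paused.total_ms == 4600
        for ev, pev in zip(tl.events, paused.events):
            expected = ev.onset_ms + (600 if ev.onset_ms >= 2800 else 0)
            assert pev.onset_ms == expected

    def test_zero_pause_is_identity(self):
        tl = make_triplet_sequence(5, 4.0)
        assert apply_pause(tl, 0, 2) is tl

    def test_pause_roundtrip_bit_exact(self):
        tl = make_triplet_sequence(10, 7.0)
        paused = apply_pause(tl, 300, 7)
        from dataclasses import replace

        restored = tuple(
            replace(ev, onset_ms=ev.onset_ms - (300 if ev.onset_ms > 2800 else 0))
            for ev in paused.events
        )
        assert restored == tl.events

    def test_test_triplets_shift_exactly(self):
        control = make_triplet_sequence(10, 7.0)
        paused = apply_pause(control, 300, 7)
        ctrl_onsets = [e.onset_ms for e in control.events[21:]]
        test_onsets = [e.onset_ms for e in paused.events[21:]]
        assert test_onsets == [t + 300 for t in ctrl_onsets]

    def test_boundary_outside_sequence_rejected(self):
        tl = make_triplet_sequence(3, 7.0)
        with pytest.raises(ValueError, match="after_triplet"):
            apply_pause(tl, 300, 3)


class TestDistractor:
    def test_margins_25ms(self):
        tl = make_triplet_sequence(6, 7.0)
        out = apply_distractor(tl, "B+2", 3, dur_ms=50)
        d = [e for e in out.events if e.label == "distractor"][0]
        gap_start = 3 * 400 - GAP_MS
        assert d.onset_ms - gap_start == 25
        assert (gap_start + GAP_MS) - d.offset_ms == 25

    def test_adds_one_event_changes_none(self):
        tl = make_triplet_sequence(6, 7.0)
        out = apply_distractor(tl, "A-2", 3)
        assert len(out.events) == len(tl.events) + 1
        assert [e for e in out.events if e.label != "distractor"] == list(tl.events)

    @pytest.mark.parametrize(
        "spec,expected_st",
        [("B+0", 7.0), ("B+2", 9.0), ("A-2", -2.0), ("(A+B)/2", 5.0), ("AB", 5.0)],
    )
    def test_freq_spec_resolution(self, spec, expected_st):
        tl = make_triplet_sequence(6, 10.0, 500.0) if expected_st == 5.0 else \
            make_triplet_sequence(6, 7.0, 500.0)
        freq = resolve_freq_spec(spec, tl.freq_a, tl.freq_b)
        assert hz_to_st(freq, tl.freq_a) == pytest.approx(expected_st, abs=1e-9)

    def test_midpoint_is_geometric_mean(self):
        tl = make_triplet_sequence(1, 10.0, 420.0)
        mid = resolve_freq_spec("(A+B)/2", tl.freq_a, tl.freq_b)
        assert mid == pytest.approx(math.sqrt(tl.freq_a * tl.freq_b))

    def test_too_long_rejected(self):
        tl = make_triplet_sequence(6, 7.0)
        with pytest.raises(ValueError, match="dur_ms"):
            apply_distractor(tl, "B+2", 3, dur_ms=150)


class TestDeviant:
    def test_only_target_b_changes(self):
        tl = make_triplet_sequence(6, 7.0)
        out = apply_deviant(tl, 2.0, 3)
        assert len(out.events) == len(tl.events)
        changed = [
            (old, new) for old, new in zip(tl.events, out.events) if old != new
        ]
        assert len(changed) == 1
        old, new = changed[0]
        assert (old.label, new.label) == ("B", "deviant")
        assert new.onset_ms == old.onset_ms
        assert new.freq_hz == pytest.approx(old.freq_hz * 2 ** (2 / 12))

    def test_zero_offset_relabels_only(self):
        tl = make_triplet_sequence(3, 7.0)
        out = apply_deviant(tl, 0.0, 2)
        dev = [e for e in out.events if e.label == "deviant"][0]
        assert dev.freq_hz == pytest.approx(tl.freq_b)

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError, match="in_triplet"):
            apply_deviant(make_triplet_sequence(3, 7.0), 2.0, 4)


class TestRoving:
    def test_ladder_endpoints_and_count(self):
        ladder = rove_ladder_hz()
        assert len(ladder) == 5
        assert ladder[0] == pytest.approx(420.0)
        assert ladder[-1] == pytest.approx(1060.0)
        steps = np.diff([hz_to_st(f, 420.0) for f in ladder])
        assert np.allclose(steps, steps[0])
        assert steps[0] == pytest.approx(4.0, abs=0.01)

    def test_max_roved_b_frequency_1888(self):
        assert int(st_to_hz(rove_ladder_hz()[-1], 10.0)) == 1888

    def test_draws_in_range_and_deterministic(self):
        vals = {rove_base_frequency(s) for s in range(50)}
        assert all(420.0 <= v <= 1060.0 for v in vals)
        assert len(vals) == 5
        assert rove_base_frequency(7) == rove_base_frequency(7)


class TestDesigns:
    def test_pause_design_counts(self):
        table = pause_experiment_design(repetitions=20)
        assert len(table) == 300
        frame = table.to_frame()
        assert len(frame[["df_st", "n_triplets", "perturbation"]].drop_duplicates()) == 15
        assert len(pause_experiment_design(repetitions=1)) == 15

    def test_pause_design_cells(self):
        frame = pause_experiment_design(1).to_frame()
        cells = set(zip(frame.n_triplets, frame.perturbation))
        assert cells == {
            (3, "none"), (7, "none"), (10, "none"),
            (10, "pause300@7"), (10, "pause600@7"),
        }

    def test_perturbation_design_counts_and_durations(self):
        table = perturbation_experiment_design(
            ["distractor:B+2", "distractor:(A+B)/2", "deviant:+2"], repetitions=4
        )
        assert len(table) == 3 * 5 * 4
        for cond in table.rows:
            tl = build_timeline(cond)
            assert tl.total_ms in (1200, 2400)
            if cond.perturbation.kind != "none":
                assert tl.total_ms == 2400

    def test_empty_cells_warns_controls_only(self):
        with pytest.warns(UserWarning):
            table = perturbation_experiment_design([], repetitions=1)
        assert len(table) == 6

    def test_csv_round_and_seeding(self, tmp_path):
        table = pause_experiment_design(2)
        path = tmp_path / "design.csv"
        table.to_csv(path, master_seed=5)
        import pandas as pd

        frame = pd.read_csv(path)
        assert set(frame.columns) >= {
            "experiment", "df_st", "n_triplets", "perturbation", "repetition",
            "base_freq_hz", "seed",
        }
        frame2 = table.to_frame(master_seed=5)
        assert frame.base_freq_hz.tolist() == frame2.base_freq_hz.tolist()


class TestTimelineSerialization:
    def test_json_roundtrip(self, tmp_path):
        tl = apply_distractor(make_triplet_sequence(6, 7.0, 529.38), "B+2", 3)
        text = tl.to_json()
        back = StimulusTimeline.from_json(text)
        assert back == tl
        path = tmp_path / "tl.json"
        tl.to_json(path)
        assert StimulusTimeline.from_json(str(path)) == tl
        json.loads(text)  # valid JSON document


class TestAudio:
    def test_silence_is_exact_zero_and_tone_support(self):
        tl = make_triplet_sequence(2, 7.0, 500.0)
        wav = synthesize_waveform(tl, sample_rate=44100)
        assert len(wav) == int(round(tl.total_ms * 44.1))
        gap = wav[int(0.3 * 44100) : int(0.4 * 44100)]
        assert np.all(gap == 0.0)
        tone = wav[: 4410]
        assert np.any(tone != 0.0)

    def test_envelope_midpoint_full_scale(self):
        tl = make_triplet_sequence(1, 7.0, 100.0)
        sr = 40000
        wav = synthesize_waveform(tl, sample_rate=sr, level_db=65.0)
        mid = wav[int(0.045 * sr) : int(0.055 * sr)]
        assert np.max(np.abs(mid)) == pytest.approx(0.5, rel=0.01)

    def test_ramp_too_long_rejected(self):
        tl = make_triplet_sequence(1, 7.0)
        with pytest.raises(ValueError, match="ramp"):
            synthesize_waveform(tl, 44100, ramp_ms=60.0)

    def test_wav_formats(self, tmp_path):
        from scipy.io import wavfile

        from streamseg.paradigm import write_wav

        tl = make_triplet_sequence(1, 7.0)
        wav = synthesize_waveform(tl, 8000)
        for fmt, dtype in (("float32", np.float32), ("pcm16", np.int16)):
            p = tmp_path / f"x_{fmt}.wav"
            write_wav(p, wav, 8000, fmt)
            sr, data = wavfile.read(p)
            assert sr == 8000 and data.dtype == dtype
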