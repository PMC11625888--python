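"""ERG feature extraction, group averaging and tabulation."""
import numpy as np
import pandas as pd
import pytest

import oracles
from emmetropy import erg, synthgen
from emmetropy.exceptions import InsufficientDataError, InvalidInputError


def make_trace(voltage, onset=100.0, dt=1.0, **kw):
    voltage = np.asarray(voltage, dtype=float)
    return erg.ErgTrace(
        time_ms=np.arange(voltage.size) * dt,
        voltage_uv=voltage,
        stimulus_onset_ms=onset,
        **kw,
    )


def triangle_trace():
    """Baseline 0, trough -100 uV at 20 ms post-onset, peak +200 uV at 60 ms."""
    v = np.zeros(400)
    onset = 100
    v[onset + 10 : onset + 21] = np.linspace(0, -100, 11)
    v[onset + 21 : onset + 61] = np.linspace(-100, 200, 41)[1:]
    v[onset + 61 : onset + 121] = np.linspace(200, 0, 61)[1:]
    return make_trace(v, onset=float(onset))


class TestExtractFeatures:
    def test_construction_example(self):
        f = erg.extract_features(triangle_trace())
        assert f.a_amplitude == pytest.approx(100.0)
        assert f.b_amplitude == pytest.approx(300.0)
        assert f.a_implicit_time == pytest.approx(20.0)
        assert f.b_implicit_time == pytest.approx(60.0)
        assert f.baseline == pytest.approx(0.0)

    def test_flat_trace_flagged_no_response(self):
        f = erg.extract_features(make_trace(np.zeros(400)))
        assert f.a_amplitude == 0.0 and f.b_amplitude == 0.0
        assert np.isnan(f.a_implicit_time) and np.isnan(f.b_implicit_time)
        assert "no-response" in f.flags

    def test_offset_invariance(self):
        base = erg.extract_features(triangle_trace())
        shifted_trace = triangle_trace()
        shifted_trace.voltage_uv = shifted_trace.voltage_uv + 37.5
        shifted = erg.extract_features(shifted_trace)
        assert shifted.a_amplitude == pytest.approx(base.a_amplitude)
        assert shifted.b_amplitude == pytest.approx(base.b_amplitude)
        assert shifted.baseline == pytest.approx(base.baseline + 37.5)

    def test_time_shift_invariance(self):
        tr = triangle_trace()
        shifted = erg.ErgTrace(
            time_ms=tr.time_ms + 250.0,
            voltage_uv=tr.voltage_uv,
            stimulus_onset_ms=tr.stimulus_onset_ms + 250.0,
        )
        a = erg.extract_features(tr)
        b = erg.extract_features(shifted)
        assert (a.a_amplitude, a.b_amplitude) == (b.a_amplitude, b.b_amplitude)
        assert a.a_implicit_time == b.a_implicit_time
        assert a.b_implicit_time == b.b_implicit_time

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_extrema_oracle(self, seed):
        spec = synthgen.ErgComponentSpec(noise_sd=5.0, seed=seed)
        trace, _ = synthgen.gen_erg_trace(spec)
        feats = erg.extract_features(trace)
        ti, pi = oracles.windowed_extrema(
            trace.time_ms,
            trace.voltage_uv,
            trace.stimulus_onset_ms,
            erg.DEFAULT_A_WINDOW,
            erg.DEFAULT_B_WINDOW_END,
        )
        onset = trace.stimulus_onset_ms
        assert feats.a_implicit_time == pytest.approx(trace.time_ms[ti] - onset)
        assert feats.b_implicit_time == pytest.approx(trace.time_ms[pi] - onset)
        base = trace.voltage_uv[
            (trace.time_ms >= onset - 50) & (trace.time_ms < onset)
        ].mean()
        assert feats.a_amplitude == pytest.approx(base - trace.voltage_uv[ti])
        assert feats.b_amplitude == pytest.approx(
            trace.voltage_uv[pi] - trace.voltage_uv[ti]
        )

    def test_noiseless_recovery_is_exact(self):
        spec = synthgen.ErgComponentSpec(noise_sd=0.0)
        trace, truth = synthgen.gen_erg_trace(spec)
        feats = erg.extract_features(trace)
        assert feats.a_amplitude == pytest.approx(truth["a_amplitude"], abs=1e-9)
        assert feats.b_amplitude == pytest.approx(truth["b_amplitude"], abs=1e-9)
        assert feats.a_implicit_time == truth["a_implicit_time"]
        assert feats.b_implicit_time == truth["b_implicit_time"]

    def test_negative_a_window_start_rejected(self):
        with pytest.raises(InvalidInputError):
            erg.extract_features(triangle_trace(), a_window=(-5.0, 100.0))


class TestGroupAverage:
    def test_identical_traces_have_zero_sem(self):
        traces = [triangle_trace() for _ in range(5)]
        avg = erg.group_average(traces)
        assert np.allclose(avg["mean_uv"], traces[0].voltage_uv)
        assert np.allclose(avg["sem_uv"], 0.0)
        assert avg.attrs["n"] == 5

    def test_two_constant_traces_hand_arithmetic(self):
        # values {+1, -1}: SD = sqrt(2) with n-1 denominator, SEM = SD/sqrt(2) = 1
        traces = [
            make_trace(np.full(200, 1.0)),
            make_trace(np.full(200, -1.0)),
        ]
        avg = erg.group_average(traces)
        assert np.allclose(avg["mean_uv"], 0.0)
        assert np.allclose(avg["sem_uv"], 1.0)

    def test_single_trace_sem_undefined_not_zero(self):
        avg = erg.group_average([triangle_trace()])
        assert avg["sem_uv"].isna().all()
        assert avg.attrs.get("sem_undefined") is True

    def test_grid_mismatch_rejected_without_resampling(self):
        a = make_trace(np.zeros(100))
        b = make_trace(np.zeros(100), dt=2.0)
        with pytest.raises(InvalidInputError):
            erg.group_average([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(InsufficientDataError):
            erg.group_average([])


class TestIntensityResponseTable:
    def features_frame(self, n_eyes=12, intensities=(-0.83, 0.73, 1.87)):
        rows = []
        for e in range(n_eyes):
            for i in intensities:
                rows.append(
                    {
                        "eye_id": f"e{e}",
                        "intensity": i,
                        "a_amplitude": 100.0,
                        "b_amplitude": 300.0,
                        "a_implicit_time": 20.0,
                        "b_implicit_time": 60.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_row_counting(self):
        table = erg.intensity_response_table(self.features_frame())
        assert len(table) == 3 * 12 * 4

    def test_intensities_carried_verbatim(self):
        table = erg.intensity_response_table(self.features_frame())
        assert set(table["intensity"]) == {-0.83, 0.73, 1.87}

    def test_repeats_averaged_per_eye(self):
        df = self.features_frame(n_eyes=1, intensities=(-0.83,))
        reps = pd.concat([df] * 3, ignore_index=True)
        reps["repeat"] = [0, 1, 2]
        reps.loc[2, "a_amplitude"] = 130.0  # mean becomes 110
        table = erg.intensity_response_table(reps)
        a_row = table[table.feature == "a_amplitude"]
        assert len(a_row) == 1
        assert a_row["value"].iloc[0] == pytest.approx(110.0)

    def test_duplicate_keys_rejected(self):
        df = self.features_frame(n_eyes=1, intensities=(0.73,))
        dup = pd.concat([df, df], ignore_index=True)
        with pytest.raises(InvalidInputError):
            erg.intensity_response_table(dup)


def test_trace_csv_round_trip(tmp_path):
    spec = synthgen.ErgComponentSpec(noise_sd=2.0, seed=4)
    traces = [
        synthgen.gen_erg_trace(spec, intensity=1.87, eye_id=f"e{i}")[0]
        for i in range(3)
    ]
    path = tmp_path / "traces.csv"
    erg.write_traces(traces, path)
    back = erg.read_traces(path)
    assert len(back) == 3
    for orig, rt in zip(traces, back):
        assert np.allclose(orig.voltage_uv, rt.voltage_uv)
        assert rt.intensity == 1.87
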