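"""Generator contracts: ground truth, determinism, noise models."""
import numpy as np
import pytest

import oracles
from emmetropy import erg, omr, synthgen, tuning
from emmetropy.exceptions import InvalidSpecError


class TestGenTrajectory:
    def test_locked_fish_noiseless_displacement(self):
        tr = synthgen.gen_trajectory(1.0, 1, 0.5, 30.0, 30.0, 0.0, seed=0)
        assert tr.truth_net_displacement == pytest.approx(15.0)
        assert omr.compute_omi(tr).omi == pytest.approx(15.0)

    def test_zero_gain_constant_angle(self):
        tr = synthgen.gen_trajectory(0.0, -1, 0.5, 30.0, 30.0, 0.0, seed=0)
        assert np.allclose(tr.angle_wrapped, tr.angle_wrapped[0])
        assert tr.truth_net_displacement == 0.0

    def test_noise_stream_reintegration_oracle(self):
        # same seeded noise stream, integrated independently
        tr = synthgen.gen_trajectory(0.6, 1, 0.5, 30.0, 30.0, 0.05, seed=7)
        expected = oracles.reintegrate_trajectory(0.6, 1, 0.5, 30.0, 30.0, 0.05, 7)
        assert tr.truth_net_displacement == pytest.approx(expected, abs=1e-9)
        # and the draw is within 3 SD of the drift-only displacement
        sd = 0.05 * np.sqrt(30.0)
        assert abs(tr.truth_net_displacement - 9.0) < 3 * sd

    def test_wrapped_angles_in_half_open_interval(self):
        tr = synthgen.gen_trajectory(1.0, 1, 2.0, 10.0, 30.0, 0.5, seed=2)
        assert np.all(tr.angle_wrapped > -np.pi)
        assert np.all(tr.angle_wrapped <= np.pi)

    @pytest.mark.parametrize("kw", [{"duration": 0.0}, {"sample_rate": -1.0}])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(InvalidSpecError):
            synthgen.gen_trajectory(1.0, 1, 0.5, **{"duration": 30.0,
                                                    "sample_rate": 30.0, **kw})


class TestGenOmrCohort:
    def test_gain_at_peak_equals_amplitude(self):
        g = synthgen.GroupTuning("g", 1.0, 0.062, 0.3)
        assert tuning.log_gaussian(0.062, g.amplitude, g.peak_frequency,
                                   g.bandwidth) == pytest.approx(1.0)

    def test_trial_counting(self, standard_frequencies):
        spec = synthgen.CohortSpec(
            n_fish_per_group=14,
            groups=(
                synthgen.GroupTuning("a", 1.0, 0.062, 0.3),
                synthgen.GroupTuning("b", 0.7, 0.062, 0.3),
            ),
            noise_sd_omi=0.1,
            seed=0,
        )
        trajectories, truth = synthgen.gen_omr_cohort(spec, standard_frequencies)
        assert len(trajectories) == 2 * 14 * 6 * 4
        assert len(truth) == 2 * 14 * 6
        directions = [t.stim_direction for t in trajectories[:4]]
        assert sorted(directions) == [-1, -1, 1, 1]  # 2 CW + 2 CCW per condition

    def test_seed_determinism_byte_identical_export(self, tmp_path,
                                                    small_cohort_spec):
        paths = []
        for name in ("a.csv", "b.csv"):
            trajectories, _ = synthgen.gen_omr_cohort(
                small_cohort_spec, frequencies=(0.0155, 0.062)
            )
            p = tmp_path / name
            omr.write_trajectories(trajectories, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_empty_frequency_list_rejected(self, small_cohort_spec):
        with pytest.raises(InvalidSpecError):
            synthgen.gen_omr_cohort(small_cohort_spec, frequencies=())

    def test_truth_gains_follow_curve_at_zero_noise(self, standard_frequencies):
        spec = synthgen.CohortSpec(
            n_fish_per_group=2,
            groups=(synthgen.GroupTuning("a", 1.0, 0.062, 0.3),),
            noise_sd_omi=0.0,
            seed=5,
        )
        _, truth = synthgen.gen_omr_cohort(spec, standard_frequencies)
        assert np.allclose(truth["sampled_gain"], truth["true_curve_gain"])


class TestGenErgTrace:
    def test_single_component_minimum_at_kernel_peak(self):
        spec = synthgen.ErgComponentSpec(a_scale=100.0, b_scale=0.0, noise_sd=0.0)
        trace, truth = synthgen.gen_erg_trace(spec)
        k = int(np.argmin(trace.voltage_uv))
        assert trace.voltage_uv[k] == pytest.approx(-100.0)
        assert trace.time_ms[k] - trace.stimulus_onset_ms == pytest.approx(20.0)
        assert truth["a_amplitude"] == pytest.approx(100.0)

    def test_flat_zero_trace(self):
        spec = synthgen.ErgComponentSpec(a_scale=0.0, b_scale=0.0, noise_sd=0.0)
        trace, truth = synthgen.gen_erg_trace(spec)
        assert np.allclose(trace.voltage_uv, 0.0)
        assert truth["a_amplitude"] == 0.0 and truth["b_amplitude"] == 0.0

    def test_extrema_match_dense_grid_of_closed_form(self):
        spec = synthgen.ErgComponentSpec(noise_sd=0.0, sample_interval=1.0)
        trace, truth = synthgen.gen_erg_trace(spec)
        # dense evaluation of the closed-form sum (10x finer grid)
        t = np.arange(0.0, 400.0001, 0.1)
        rel = t - 50.0
        dense = -100.0 * synthgen.gamma_kernel(rel, 20.0, 8.0) + 300.0 * (
            synthgen.gamma_kernel(rel, 60.0, 8.0)
        )
        t_min = t[np.argmin(dense)] - 50.0
        t_max = t[np.argmax(dense)] - 50.0
        assert truth["a_implicit_time"] == pytest.approx(t_min, abs=1.0)
        assert truth["b_implicit_time"] == pytest.approx(t_max, abs=1.0)

    def test_kernel_peak_outside_trace_rejected(self):
        with pytest.raises(InvalidSpecError):
            synthgen.gen_erg_trace(
                synthgen.ErgComponentSpec(b_time_to_peak=500.0), duration_ms=400.0
            )

    def test_kernel_unit_peak(self):
        t = np.linspace(0, 200, 20001)
        k = synthgen.gamma_kernel(t, 60.0, 8.0)
        assert k.max() == pytest.approx(1.0, abs=1e-9)
        assert t[np.argmax(k)] == pytest.approx(60.0, abs=0.02)


class TestGenBscan:
    def test_noiseless_profile_has_four_maxima_at_truth(self):
        image, rows = synthgen.gen_bscan(
            synthgen.EyeGeometrySpec(), noise_sd=0.0
        )
        profile = image.mean(axis=1)
        interior = (profile[1:-1] > profile[:-2]) & (profile[1:-1] > profile[2:])
        maxima = np.flatnonzero(interior) + 1
        assert maxima.size == 4
        assert np.all(np.abs(maxima - rows) <= 0.5)

    def test_ordering_violation_rejected(self):
        with pytest.raises(InvalidSpecError):
            synthgen.EyeGeometrySpec(cornea_pos=100.0, anterior_lens_pos=50.0)

    def test_landmark_generation_jitterless_matches_spec(self):
        lm = synthgen.gen_oct_landmarks(synthgen.EyeGeometrySpec())
        assert lm.as_tuple() == (0.0, 50.0, 550.0, 900.0)


class TestGenLayerImage:
    def test_zero_one_zero_intensities_exact_column_means(self):
        spec = synthgen.LayerImageSpec(
            layer_mean_intensities=(0.0, 1.0, 0.0), noise_sd=0.0
        )
        image, truth = synthgen.gen_layer_image(spec)
        means = image.mean(axis=0)
        lo, hi = truth["ipl_bounds"]
        assert np.allclose(means[lo:hi], 1.0)
        assert np.allclose(means[:lo], 0.0) and np.allclose(means[hi:], 0.0)

    def test_invalid_widths_rejected(self):
        with pytest.raises(InvalidSpecError):
            synthgen.LayerImageSpec(layer_widths_px=(0, 10, 10))


class TestPurity:
    """Identical spec + seed -> identical output, for every generator."""

    def test_trajectory(self):
        a = synthgen.gen_trajectory(0.5, 1, noise_sd=0.1, seed=42)
        b = synthgen.gen_trajectory(0.5, 1, noise_sd=0.1, seed=42)
        assert np.array_equal(a.angle_wrapped, b.angle_wrapped)

    def test_erg(self):
        spec = synthgen.ErgComponentSpec(noise_sd=5.0, seed=9)
        (a, _), (b, _) = synthgen.gen_erg_trace(spec), synthgen.gen_erg_trace(spec)
        assert np.array_equal(a.voltage_uv, b.voltage_uv)

    def test_bscan(self):
        spec = synthgen.EyeGeometrySpec(jitter_sd=2.0, seed=9)
        (a, ra), (b, rb) = synthgen.gen_bscan(spec), synthgen.gen_bscan(spec)
        assert np.array_equal(a, b) and np.array_equal(ra, rb)

    def test_layer_image(self):
        spec = synthgen.LayerImageSpec(noise_sd=0.1, seed=9)
        (a, _), (b, _) = synthgen.gen_layer_image(spec), synthgen.gen_layer_image(spec)
        assert np.array_equal(a, b)

    def test_ct_table(self):
        spec = synthgen.QpcrDesignSpec(
            genes=("ef1a", "g"),
            fold_changes={"wt": {"g": 1.0}, "mut": {"g": 2.0}},
            ct_noise_sd=0.2,
            seed=9,
        )
        (a, _), (b, _) = synthgen.gen_ct_table(spec), synthgen.gen_ct_table(spec)
        assert a.equals(b)
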