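"""Simulation-based validation studies.

Each study runs the full analysis path on freshly generated synthetic data
with known ground truth and summarises how well the pipeline recovers it:
tuning-parameter recovery error, omnibus F-test size and power, ERG
implicit-time accuracy, and OCT landmark-detection reliability.  They are
used by the test suite and the reproduction script, and are available to
users who want to re-check calibration under their own conditions.

Default problem sizes mirror the study conditions the pipeline is meant for
(14 fish per group at six spatial frequencies, normalized-OMI noise SD 0.1,
5 uV ERG noise, 2 um OCT landmark jitter).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import erg, oct, omr, synthgen, tuning

#: Control-group truth used across the studies (normalized amplitude, c/deg,
#: log10-frequency units).
CONTROL_TRUTH = {"amplitude": 1.0, "peak_frequency": 0.062, "bandwidth": 0.3}
REFERENCE_FREQUENCY = 0.0155  # c/deg, the larval normalization condition
OMI_NOISE_SD = 0.1


def _cohort_spec(seed: int, n_fish: int, amplitude_deficit: float = 0.0,
                 noise_sd: float = OMI_NOISE_SD) -> synthgen.CohortSpec:
    groups = (
        synthgen.GroupTuning("control", **CONTROL_TRUTH),
        synthgen.GroupTuning(
            "mutant",
            amplitude=CONTROL_TRUTH["amplitude"] * (1.0 - amplitude_deficit),
            peak_frequency=CONTROL_TRUTH["peak_frequency"],
            bandwidth=CONTROL_TRUTH["bandwidth"],
        ),
    )
    return synthgen.CohortSpec(
        n_fish_per_group=n_fish, groups=groups, noise_sd_omi=noise_sd, seed=seed
    )


def cohort_dataset(spec: synthgen.CohortSpec) -> pd.DataFrame:
    """Generate -> track -> OMI -> average -> normalize, the full OMR path."""
    trajectories, _ = synthgen.gen_omr_cohort(spec)
    results = [omr.compute_omi(t) for t in trajectories]
    ds = omr.build_tuning_dataset(results)
    return omr.normalize_omi(ds, "control", REFERENCE_FREQUENCY)


def fitted_gain_scale_params(ds: pd.DataFrame, group: str) -> dict[str, float]:
    """Fit one group's normalized tuning points; report amplitude on the
    generator's gain scale (undo normalization and the stimulus displacement)."""
    f, y = tuning.dataset_groups(ds)[group]
    fit = tuning.fit_log_gaussian(f, y)
    rad_per_gain = synthgen.OMR_STIM_SPEED * synthgen.OMR_TRIAL_DURATION
    scale = ds.attrs["normalization_reference_mean"] / rad_per_gain
    return {
        "amplitude": fit.amplitude * scale,
        "peak_frequency": fit.peak_frequency,
        "bandwidth": fit.bandwidth,
    }


def tuning_recovery_study(
    n_cohorts: int = 200, n_fish: int = 14, seed: int = 0
) -> dict[str, float]:
    """Median absolute recovery error of amplitude and peak frequency, in %
    of their true values, over repeated control-vs-mutant cohorts."""
    rng = np.random.default_rng(seed)
    amp_err, peak_err = [], []
    truths = {"control": 1.0, "mutant": 0.7}
    for _ in range(n_cohorts):
        spec = _cohort_spec(int(rng.integers(2**31)), n_fish, amplitude_deficit=0.3)
        ds = cohort_dataset(spec)
        for group, true_amp in truths.items():
            est = fitted_gain_scale_params(ds, group)
            amp_err.append(abs(est["amplitude"] - true_amp) / true_amp * 100.0)
            peak_err.append(
                abs(est["peak_frequency"] - CONTROL_TRUTH["peak_frequency"])
                / CONTROL_TRUTH["peak_frequency"]
                * 100.0
            )
    return {
        "median_abs_amplitude_error_pct": float(np.median(amp_err)),
        "median_abs_peak_frequency_error_pct": float(np.median(peak_err)),
        "n_cohorts": n_cohorts,
    }


def omnibus_rejection_rate(
    n_cohorts: int,
    amplitude_deficit: float,
    n_fish: int = 14,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of cohorts whose omnibus F-test rejects at ``alpha``.

    With ``amplitude_deficit`` 0 the groups share one true curve and the
    rate estimates the test's size; with a deficit it estimates power."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_cohorts):
        spec = _cohort_spec(int(rng.integers(2**31)), n_fish, amplitude_deficit)
        ds = cohort_dataset(spec)
        result = tuning.omnibus_f_test(tuning.dataset_groups(ds))
        rejections += result.p_value < alpha
    return {
        "rejection_rate": rejections / n_cohorts,
        "n_cohorts": n_cohorts,
        "alpha": alpha,
        "amplitude_deficit": amplitude_deficit,
    }


def erg_timing_study(
    n_seeds: int = 200, noise_sd: float = 5.0, seed: int = 0
) -> dict[str, float]:
    """Mean signed implicit-time recovery error (ms) over noisy traces with a
    100 uV / 20 ms a-component and a 300 uV / 60 ms b-component."""
    rng = np.random.default_rng(seed)
    a_err, b_err = [], []
    for _ in range(n_seeds):
        spec = synthgen.ErgComponentSpec(
            a_scale=100.0,
            a_time_to_trough=20.0,
            b_scale=300.0,
            b_time_to_peak=60.0,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        trace, truth = synthgen.gen_erg_trace(spec)
        feats = erg.extract_features(trace)
        a_err.append(feats.a_implicit_time - truth["a_implicit_time"])
        b_err.append(feats.b_implicit_time - truth["b_implicit_time"])
    return {
        "mean_a_implicit_time_error_ms": float(np.mean(a_err)),
        "mean_b_implicit_time_error_ms": float(np.mean(b_err)),
        "n_traces": n_seeds,
    }


def oct_detection_study(
    n_eyes: int = 100, jitter_sd: float = 2.0, tol_px: float = 1.0, seed: int = 0
) -> dict[str, float]:
    """Fraction of synthetic B-scans on which all four landmarks are detected
    within ``tol_px`` of their sub-pixel ground truth."""
    rng = np.random.default_rng(seed)
    successes = 0
    offsets = []
    for _ in range(n_eyes):
        spec = synthgen.EyeGeometrySpec(jitter_sd=jitter_sd, seed=int(rng.integers(2**31)))
        image, true_rows = synthgen.gen_bscan(spec)
        try:
            lm = oct.detect_axis_landmarks(image)
        except Exception:
            continue
        err = np.array(lm.as_tuple()) - true_rows
        offsets.extend(err.tolist())
        if np.all(np.abs(err) <= tol_px):
            successes += 1
    return {
        "success_rate": successes / n_eyes,
        "mean_offset_px": float(np.mean(offsets)) if offsets else float("nan"),
        "n_eyes": n_eyes,
    }
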