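"""Seeded synthetic-data generators for every pipeline input modality.

Every generator is a pure function of its spec and seed (all randomness flows
through ``numpy.random.default_rng`` seeded per generator; no global state),
and every generated object travels with its ground truth, sufficient to
compute each downstream expected value without re-deriving it from the data.
With noise parameters set to zero each downstream extraction recovers ground
truth exactly, up to grid resolution.

What the generators emulate
---------------------------
* OMR trajectories: a drift-diffusion view of swim bouts -- angular velocity
  equals tuning gain x stimulus velocity plus white noise in velocity, so
  displacement variance grows linearly with time and is analytically known.
* OMR cohorts: per fish and spatial frequency, the effective gain is the
  group's log-Gaussian tuning curve plus Gaussian noise (drawn once per
  fish x frequency, shared across that condition's four trials: two
  clockwise, two counter-clockwise).
* ERG traces: difference of two gamma-shaped unimodal kernels, each
  normalized to unit peak with its peak time an explicit parameter, so
  feature-recovery tests have closed-form truth.
* OCT B-scans: bright axial Gaussian bands (3 px SD) at the four landmark
  rows on a dark background, with optional additive speckle-like noise;
  sub-pixel landmark truth is the band centre.
* Layer images: piecewise-constant column intensities per retinal layer.
* Ct tables: reference-gene Ct near a fixed base cycle; target-gene Ct
  offset so each group's true ddCt equals -log2(true fold change).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .erg import ErgTrace
from .exceptions import InvalidSpecError
from .layers import LayerProfile  # noqa: F401  (re-exported for callers)
from .oct import OctLandmarks
from .omr import TrialTrajectory
from .tuning import log_gaussian

# Stimulus constants of the optomotor assay.
OMR_STIM_SPEED = 0.5  # rad/s
OMR_TRIAL_DURATION = 30.0  # s
OMR_SAMPLE_RATE = 30.0  # Hz (video frame rate)
OMR_FREQUENCIES = (0.0078, 0.0155, 0.0310, 0.0620, 0.1240, 0.2480)  # c/deg

BSCAN_BAND_SD_PX = 3.0
BSCAN_TOP_PAD_PX = 12.0
QPCR_REFERENCE_BASE_CT = 18.0
QPCR_TARGET_BASE_DELTA_CT = 4.0


def _wrap_to_pi(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - theta, 2.0 * np.pi)


# ---------------------------------------------------------------------------
# OMR


@dataclass(frozen=True)
class GroupTuning:
    """True tuning-curve parameters for one cohort group."""

    label: str
    amplitude: float
    peak_frequency: float  # c/deg
    bandwidth: float  # log10-frequency units

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidSpecError("amplitude must be >= 0")
        if self.peak_frequency <= 0 or self.bandwidth <= 0:
            raise InvalidSpecError("peak frequency and bandwidth must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition spec for a simulated OMR cohort."""

    n_fish_per_group: int
    groups: tuple[GroupTuning, ...]
    noise_sd_omi: float
    seed: int

    def __post_init__(self):
        if self.n_fish_per_group < 1:
            raise InvalidSpecError("n_fish_per_group must be >= 1")
        if not self.groups:
            raise InvalidSpecError("need at least one group")
        if self.noise_sd_omi < 0:
            raise InvalidSpecError("noise_sd_omi must be >= 0")


def gen_trajectory(
    tuning_gain: float,
    stim_direction: int,
    stim_speed: float = OMR_STIM_SPEED,
    duration: float = OMR_TRIAL_DURATION,
    sample_rate: float = OMR_SAMPLE_RATE,
    noise_sd: float = 0.0,
    seed: int | SeedSequence = 0,
    spatial_frequency: float = float("nan"),
    fish_id: str = "fish",
    group: str = "",
    trial_id: str = "t0",
) -> TrialTrajectory:
    """One trial: d(theta)/dt = gain * direction * speed + white velocity noise.

    ``noise_sd`` is the white-noise intensity in rad/sqrt(s): over a step dt
    the angular increment is N(gain*direction*speed*dt, noise_sd^2 * dt), so
    net-displacement variance grows linearly with trial duration.  The raw
    angle is reported wrapped to (-pi, pi]; the unwrapped net displacement is
    stored as ground truth.
    """
    if duration <= 0 or sample_rate <= 0:
        raise InvalidSpecError("duration and sample_rate must be positive")
    if stim_direction not in (-1, 1):
        raise InvalidSpecError("stim_direction must be +1 or -1")
    if noise_sd < 0:
        raise InvalidSpecError("noise_sd must be >= 0")
    n_steps = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate
    time = np.arange(n_steps + 1) * dt
    drift = tuning_gain * stim_direction * stim_speed * dt
    increments = np.full(n_steps, drift)
    if noise_sd > 0:
        rng = default_rng(seed)
        increments = increments + noise_sd * np.sqrt(dt) * rng.standard_normal(n_steps)
    theta = np.concatenate([[0.0], np.cumsum(increments)])
    return TrialTrajectory(
        time=time,
        angle_wrapped=_wrap_to_pi(theta),
        stim_direction=stim_direction,
        stim_speed=stim_speed,
        spatial_frequency=spatial_frequency,
        fish_id=fish_id,
        group=group,
        trial_id=trial_id,
        truth_net_displacement=float(theta[-1] - theta[0]),
    )


def gen_omr_cohort(
    spec: CohortSpec,
    frequencies=OMR_FREQUENCIES,
    trials_per_condition: int = 4,
) -> tuple[list[TrialTrajectory], pd.DataFrame]:
    """Simulate a cohort; returns (trajectories, ground-truth gain table).

    Per fish x frequency, the effective gain is the group's tuning curve at
    that frequency plus N(0, noise_sd_omi), shared across the condition's
    trials (half clockwise, half counter-clockwise).  The truth table holds
    one row per fish x frequency with the curve value and the sampled gain.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise InvalidSpecError("empty frequency list")
    if np.any(freqs <= 0) or np.unique(freqs).size != freqs.size:
        raise InvalidSpecError("frequencies must be positive and distinct")
    if trials_per_condition < 1:
        raise InvalidSpecError("trials_per_condition must be >= 1")
    rng = default_rng(SeedSequence(spec.seed))
    trajectories: list[TrialTrajectory] = []
    truth_rows = []
    for g in spec.groups:
        for i in range(spec.n_fish_per_group):
            fish_id = f"{g.label}_f{i:03d}"
            for f in freqs:
                curve_gain = float(
                    log_gaussian(f, g.amplitude, g.peak_frequency, g.bandwidth)
                )
                gain = curve_gain + (
                    float(rng.normal(0.0, spec.noise_sd_omi))
                    if spec.noise_sd_omi > 0
                    else 0.0
                )
                truth_rows.append(
                    {
                        "fish_id": fish_id,
                        "group": g.label,
                        "spatial_frequency": f,
                        "true_curve_gain": curve_gain,
                        "sampled_gain": gain,
                    }
                )
                for k in range(trials_per_condition):
                    direction = 1 if k % 2 == 0 else -1
                    trajectories.append(
                        gen_trajectory(
                            tuning_gain=gain,
                            stim_direction=direction,
                            spatial_frequency=float(f),
                            fish_id=fish_id,
                            group=g.label,
                            trial_id=f"t{k}",
                        )
                    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["groups"] = {
        g.label: {
            "amplitude": g.amplitude,
            "peak_frequency": g.peak_frequency,
            "bandwidth": g.bandwidth,
        }
        for g in spec.groups
    }
    return trajectories, truth


# ---------------------------------------------------------------------------
# ERG


@dataclass(frozen=True)
class ErgComponentSpec:
    """Ground-truth model of one synthetic ERG trace."""

    a_scale: float = 100.0  # uV
    a_time_to_trough: float = 20.0  # ms (a-kernel peak time)
    b_scale: float = 300.0  # uV
    b_time_to_peak: float = 60.0  # ms (b-kernel peak time)
    kernel_shape: float = 8.0  # gamma shape, > 1
    noise_sd: float = 0.0  # uV
    sample_interval: float = 1.0  # ms
    seed: int = 0

    def __post_init__(self):
        if self.a_scale < 0 or self.b_scale < 0:
            raise InvalidSpecError("component scales must be >= 0")
        if self.a_time_to_trough <= 0 or self.b_time_to_peak <= 0:
            raise InvalidSpecError("component times must be > 0")
        if self.kernel_shape <= 1:
            raise InvalidSpecError("kernel_shape must be > 1")
        if self.sample_interval <= 0:
            raise InvalidSpecError("sample_interval must be > 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


def gamma_kernel(t_ms, peak_ms: float, shape: float):
    """Unimodal gamma-shaped kernel, zero for t <= 0, unit peak at ``peak_ms``."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_ms
    out[pos] = x ** (shape - 1.0) * np.exp((shape - 1.0) * (1.0 - x))
    return out


def gen_erg_trace(
    spec: ErgComponentSpec,
    pre_stimulus_ms: float = 50.0,
    duration_ms: float = 400.0,
    intensity: float = float("nan"),
    eye_id: str = "eye",
    fish_id: str = "fish",
    group: str = "",
    condition: str = "",
) -> tuple[ErgTrace, dict]:
    """Voltage = -a_scale*K_a(t) + b_scale*K_b(t) + noise, t from stimulus onset.

    Ground truth holds the noiseless trace's trough/peak amplitudes (baseline
    to trough; trough to peak) and latencies from onset, evaluated on the
    sample grid (the sum's extrema shift slightly off the component peak
    times when the kernels overlap).
    """
    if not duration_ms > pre_stimulus_ms >= 0:
        raise InvalidSpecError("need duration_ms > pre_stimulus_ms >= 0")
    post = duration_ms - pre_stimulus_ms
    for peak in (spec.a_time_to_trough, spec.b_time_to_peak):
        if peak >= post:
            raise InvalidSpecError(
                f"kernel peak time {peak} ms outside the {post} ms post-stimulus trace"
            )
    n = int(round(duration_ms / spec.sample_interval)) + 1
    t = np.arange(n) * spec.sample_interval
    rel = t - pre_stimulus_ms
    clean = -spec.a_scale * gamma_kernel(
        rel, spec.a_time_to_trough, spec.kernel_shape
    ) + spec.b_scale * gamma_kernel(rel, spec.b_time_to_peak, spec.kernel_shape)
    v = clean
    if spec.noise_sd > 0:
        rng = default_rng(spec.seed)
        v = clean + spec.noise_sd * rng.standard_normal(n)

    if np.all(clean == 0):
        truth = {
            "a_amplitude": 0.0,
            "b_amplitude": 0.0,
            "a_implicit_time": float("nan"),
            "b_implicit_time": float("nan"),
        }
    else:
        trough_idx = int(np.argmin(clean))
        after = clean[trough_idx + 1 :]
        peak_idx = trough_idx + 1 + int(np.argmax(after)) if after.size else trough_idx
        truth = {
            "a_amplitude": float(-clean[trough_idx]),
            "b_amplitude": float(clean[peak_idx] - clean[trough_idx]),
            "a_implicit_time": float(t[trough_idx] - pre_stimulus_ms),
            "b_implicit_time": float(t[peak_idx] - pre_stimulus_ms),
        }
    trace = ErgTrace(
        time_ms=t,
        voltage_uv=v,
        stimulus_onset_ms=pre_stimulus_ms,
        intensity=intensity,
        eye_id=eye_id,
        fish_id=fish_id,
        group=group,
        condition=condition,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# OCT


@dataclass(frozen=True)
class EyeGeometrySpec:
    """True axial landmark positions (um) of one synthetic eye."""

    cornea_pos: float = 0.0
    anterior_lens_pos: float = 50.0
    posterior_lens_pos: float = 550.0
    rpe_pos: float = 900.0
    jitter_sd: float = 0.0  # um, per-landmark positional jitter
    seed: int = 0

    def __post_init__(self):
        if not (
            self.cornea_pos
            < self.anterior_lens_pos
            < self.posterior_lens_pos
            < self.rpe_pos
        ):
            raise InvalidSpecError(
                "need cornea < anterior lens < posterior lens < RPE"
            )
        if self.jitter_sd < 0:
            raise InvalidSpecError("jitter_sd must be >= 0")


def gen_oct_landmarks(
    spec: EyeGeometrySpec, eye_id: str = "eye", fish_id: str = "fish", group: str = ""
) -> OctLandmarks:
    """Jittered landmark positions in um (no image), for biometry-only runs."""
    pos = np.array(
        [
            spec.cornea_pos,
            spec.anterior_lens_pos,
            spec.posterior_lens_pos,
            spec.rpe_pos,
        ]
    )
    if spec.jitter_sd > 0:
        rng = default_rng(spec.seed)
        pos = np.sort(pos + rng.normal(0.0, spec.jitter_sd, size=4))
    return OctLandmarks(*pos.tolist(), eye_id=eye_id, fish_id=fish_id, group=group)


def gen_bscan(
    spec: EyeGeometrySpec,
    px_per_um: float = 0.5,
    width_px: int = 64,
    noise_sd: float = 0.05,
    band_sd_px: float = BSCAN_BAND_SD_PX,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic B-scan: bright Gaussian bands at the four landmark rows.

    Returns (image, true landmark rows in px, top to bottom).  Rows are the
    (jittered) axial positions converted to pixels plus a fixed top pad that
    keeps a cornea at axial position 0 inside the image; the pad cancels in
    every biometry difference.  ``noise_sd`` is additive Gaussian noise
    relative to the unit band amplitude.
    """
    if px_per_um <= 0 or width_px < 1:
        raise InvalidSpecError("px_per_um must be > 0 and width_px >= 1")
    pos_um = np.array(
        [
            spec.cornea_pos,
            spec.anterior_lens_pos,
            spec.posterior_lens_pos,
            spec.rpe_pos,
        ]
    )
    rng = default_rng(spec.seed)
    if spec.jitter_sd > 0:
        pos_um = np.sort(pos_um + rng.normal(0.0, spec.jitter_sd, size=4))
    rows = pos_um * px_per_um + BSCAN_TOP_PAD_PX
    height = int(np.ceil(rows[-1] + BSCAN_TOP_PAD_PX + 4 * band_sd_px))
    r = np.arange(height, dtype=float)
    profile = np.zeros(height)
    for row in rows:
        profile += np.exp(-0.5 * ((r - row) / band_sd_px) ** 2)
    image = np.tile(profile[:, None], (1, width_px))
    if noise_sd > 0:
        image = image + noise_sd * rng.standard_normal(image.shape)
    return image, rows


# ---------------------------------------------------------------------------
# Layer images


@dataclass(frozen=True)
class LayerImageSpec:
    """Synthetic straightened inner-retina section (ACL | IPL | GCL)."""

    layer_mean_intensities: tuple[float, float, float] = (0.5, 1.0, 0.25)
    layer_widths_px: tuple[int, int, int] = (90, 210, 90)
    roi_height_px: int = 150
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(w < 1 for w in self.layer_widths_px):
            raise InvalidSpecError("layer widths must be >= 1 px")
        if self.roi_height_px < 1:
            raise InvalidSpecError("roi_height_px must be >= 1")
        if any(m < 0 for m in self.layer_mean_intensities):
            raise InvalidSpecError("layer intensities must be >= 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


def gen_layer_image(spec: LayerImageSpec) -> tuple[np.ndarray, dict]:
    """Image of height roi_height_px, width = sum of layer widths.

    Ground truth holds the layer means, the 0-based half-open column bounds
    of each layer, and the IPL bounds.
    """
    widths = spec.layer_widths_px
    total = sum(widths)
    if total == 0:
        raise InvalidSpecError("zero total width")
    cols = np.concatenate(
        [np.full(w, m) for w, m in zip(widths, spec.layer_mean_intensities)]
    )
    image = np.tile(cols[None, :], (spec.roi_height_px, 1))
    if spec.noise_sd > 0:
        rng = default_rng(spec.seed)
        image = image + spec.noise_sd * rng.standard_normal(image.shape)
    edges = np.concatenate([[0], np.cumsum(widths)])
    bounds = {
        name: (int(edges[i]), int(edges[i + 1]))
        for i, name in enumerate(("acl", "ipl", "gcl"))
    }
    truth = {
        "layer_means": dict(zip(("acl", "ipl", "gcl"), spec.layer_mean_intensities)),
        "bounds": bounds,
        "ipl_bounds": bounds["ipl"],
        "width_px": int(total),
    }
    return image, truth


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrDesignSpec:
    """Design of a synthetic qPCR experiment with known fold changes.

    ``fold_changes`` maps group -> {gene -> true fold change relative to the
    calibrator group}; the calibrator group's folds must all be 1 so that the
    attached truth is exactly what the 2^-ddCt pipeline recovers at zero
    noise.
    """

    genes: tuple[str, ...]
    fold_changes: dict[str, dict[str, float]] = field(hash=False)
    n_samples_per_group: int = 4
    n_replicates: int = 3
    ct_noise_sd: float = 0.0
    reference_gene: str = "ef1a"
    calibrator_group: str | None = None
    timepoint: str = "t1"
    seed: int = 0

    def __post_init__(self):
        if self.reference_gene not in self.genes:
            raise InvalidSpecError(
                f"reference gene {self.reference_gene!r} missing from genes"
            )
        if self.n_replicates < 1 or self.n_samples_per_group < 1:
            raise InvalidSpecError("need >= 1 replicate and sample per group")
        if self.ct_noise_sd < 0:
            raise InvalidSpecError("ct_noise_sd must be >= 0")
        cal = self.calibrator()
        if cal not in self.fold_changes:
            raise InvalidSpecError(f"calibrator group {cal!r} missing from groups")
        targets = [g for g in self.genes if g != self.reference_gene]
        for group, folds in self.fold_changes.items():
            for gene in targets:
                fc = folds.get(gene)
                if fc is None or fc <= 0:
                    raise InvalidSpecError(
                        f"group {group!r} needs a positive fold change for {gene!r}"
                    )
                if group == cal and fc != 1.0:
                    raise InvalidSpecError("calibrator-group fold changes must be 1")

    def calibrator(self) -> str:
        return (
            self.calibrator_group
            if self.calibrator_group is not None
            else next(iter(self.fold_changes))
        )


def gen_ct_table(spec: QpcrDesignSpec) -> tuple[pd.DataFrame, dict]:
    """Long-format Ct table whose true ddCt per group is -log2(fold change).

    Reference-gene Cts sit at a fixed base cycle; target-gene Cts at base +
    a per-gene offset - log2(fold).  Replicate noise is N(0, ct_noise_sd).
    """
    rng = default_rng(spec.seed)
    targets = [g for g in spec.genes if g != spec.reference_gene]
    rows = []
    for group, folds in spec.fold_changes.items():
        for j in range(spec.n_samples_per_group):
            sample_id = f"{group}_s{j}"
            for gene in spec.genes:
                if gene == spec.reference_gene:
                    base = QPCR_REFERENCE_BASE_CT
                else:
                    base = (
                        QPCR_REFERENCE_BASE_CT
                        + QPCR_TARGET_BASE_DELTA_CT
                        + targets.index(gene)  # separate genes by one cycle
                        - np.log2(folds[gene])
                    )
                for rep in range(spec.n_replicates):
                    ct = base + (
                        float(rng.normal(0.0, spec.ct_noise_sd))
                        if spec.ct_noise_sd > 0
                        else 0.0
                    )
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "group": group,
                            "timepoint": spec.timepoint,
                            "gene": gene,
                            "replicate": rep,
                            "ct": ct,
                        }
                    )
    truth = {
        "fold_changes": {g: dict(f) for g, f in spec.fold_changes.items()},
        "calibrator_group": spec.calibrator(),
        "reference_gene": spec.reference_gene,
    }
    return pd.DataFrame(rows), truth
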