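"""Electroretinogram feature extraction and group averaging.

Feature conventions for the flash ERG: the a-wave is the corneal-negative,
photoreceptor-driven trough after the flash; the b-wave is the subsequent
positive, bipolar-cell-driven peak.  The a-wave amplitude is measured from
baseline down to the trough; the b-wave amplitude from the trough up to the
peak.  Implicit times are latencies from stimulus onset to the respective
extremum.  Search windows and the baseline window are explicit parameters
(defaults sized to typical zebrafish flash-ERG morphology) and the b-wave
search starts strictly after the a-trough sample.

No smoothing is applied before extremum detection by default; an optional
moving-average width can be configured and is recorded in the output flags.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, InvalidInputError

#: Default windows, ms relative to stimulus onset.
DEFAULT_BASELINE_MS = 50.0
DEFAULT_A_WINDOW = (3.0, 100.0)
DEFAULT_B_WINDOW_END = 300.0
#: a-trough must undercut baseline by this many baseline-noise SDs to count.
DETECTION_FLOOR_SDS = 3.0

FEATURE_NAMES = ("a_amplitude", "b_amplitude", "a_implicit_time", "b_implicit_time")

TRACE_COLUMNS = [
    "time_ms",
    "voltage_uv",
    "onset_ms",
    "intensity",
    "eye_id",
    "fish_id",
    "group",
    "condition",
]


@dataclass
class ErgTrace:
    """Voltage time series (uniform grid, ms / microvolt) with stimulus onset."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    stimulus_onset_ms: float
    intensity: float = float("nan")
    eye_id: str = "eye"
    fish_id: str = "fish"
    group: str = ""
    condition: str = ""

    def validate(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        v = np.asarray(self.voltage_uv, dtype=float)
        if t.size < 2 or v.shape != t.shape:
            raise InvalidInputError("trace needs >= 2 samples with matching arrays")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise InvalidInputError("trace must be uniformly sampled")

    @property
    def sample_interval_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass(frozen=True)
class ErgFeatures:
    """Extracted a-/b-wave amplitudes (uV, >= 0) and implicit times (ms)."""

    a_amplitude: float
    b_amplitude: float
    a_implicit_time: float
    b_implicit_time: float
    baseline: float
    flags: tuple[str, ...] = field(default=())


def extract_features(
    trace: ErgTrace,
    a_window: tuple[float, float] = DEFAULT_A_WINDOW,
    b_window_end: float = DEFAULT_B_WINDOW_END,
    baseline_window_ms: float = DEFAULT_BASELINE_MS,
    detection_floor: float | None = None,
    smooth_width: int = 0,
) -> ErgFeatures:
    """Windowed extremum extraction of a-/b-wave features from one trace.

    ``detection_floor`` (uV) separates a real a-trough from noise minima on a
    flat trace; by default it is ``DETECTION_FLOOR_SDS`` times the SD of the
    baseline window.  Extrema take the earliest sample on exact ties.
    """
    trace.validate()
    t = np.asarray(trace.time_ms, dtype=float)
    v = np.asarray(trace.voltage_uv, dtype=float)
    onset = float(trace.stimulus_onset_ms)
    flags: list[str] = []
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        v = np.convolve(v, kernel, mode="same")
        flags.append(f"smoothed(width={smooth_width})")

    if a_window[0] < 0:
        raise InvalidInputError("a_window must start at or after stimulus onset")
    base_mask = (t >= onset - baseline_window_ms) & (t < onset)
    if not base_mask.any():
        raise InvalidInputError("baseline window contains no samples")
    baseline = float(v[base_mask].mean())
    base_sd = float(v[base_mask].std(ddof=1)) if base_mask.sum() > 1 else 0.0
    floor = DETECTION_FLOOR_SDS * base_sd if detection_floor is None else detection_floor

    a_mask = (t >= onset + a_window[0]) & (t <= onset + a_window[1])
    if not a_mask.any():
        raise InvalidInputError("a-wave window contains no samples")
    a_idx_local = int(np.argmin(v[a_mask]))
    a_idx = int(np.flatnonzero(a_mask)[a_idx_local])
    trough_v = float(v[a_idx])
    a_present = (baseline - trough_v) >= max(floor, 0.0) and (baseline - trough_v) > 0

    b_mask = np.zeros_like(a_mask)
    b_mask[a_idx + 1 :] = t[a_idx + 1 :] <= onset + b_window_end
    if not b_mask.any():
        raise InvalidInputError("empty b-wave window after the a-trough")
    b_idx_local = int(np.argmax(v[b_mask]))
    b_idx = int(np.flatnonzero(b_mask)[b_idx_local])
    peak_v = float(v[b_idx])
    b_present = (peak_v - trough_v) >= max(floor, 0.0) and (peak_v - trough_v) > 0

    if not a_present and not b_present:
        flags.append("no-response")
        return ErgFeatures(0.0, 0.0, float("nan"), float("nan"), baseline, tuple(flags))
    if not a_present:
        flags.append("a-wave-absent")
        a_amp, a_time = 0.0, float("nan")
    else:
        a_amp, a_time = baseline - trough_v, float(t[a_idx] - onset)
    if not b_present:
        flags.append("b-wave-absent")
        b_amp, b_time = 0.0, float("nan")
    else:
        b_amp, b_time = peak_v - trough_v, float(t[b_idx] - onset)
    return ErgFeatures(a_amp, b_amp, a_time, b_time, baseline, tuple(flags))


def group_average(traces: list[ErgTrace]) -> pd.DataFrame:
    """Pointwise mean and SEM (SD/sqrt(n), SD with n-1 denominator) of traces.

    All traces must share the time grid and intensity exactly; no resampling.
    A single trace yields an undefined (NaN) SEM, recorded in ``attrs``.
    """
    if not traces:
        raise InsufficientDataError("no traces to average")
    t0 = np.asarray(traces[0].time_ms, dtype=float)
    for tr in traces:
        tr.validate()
        if np.asarray(tr.time_ms).shape != t0.shape or not np.array_equal(
            np.asarray(tr.time_ms, dtype=float), t0
        ):
            raise InvalidInputError("traces do not share a common time grid")
        if not (
            tr.intensity == traces[0].intensity
            or (np.isnan(tr.intensity) and np.isnan(traces[0].intensity))
        ):
            raise InvalidInputError("traces do not share a common intensity")
    stack = np.vstack([np.asarray(tr.voltage_uv, dtype=float) for tr in traces])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.full_like(mean, np.nan)
    out = pd.DataFrame({"time_ms": t0, "mean_uv": mean, "sem_uv": sem})
    out.attrs["n"] = n
    if n == 1:
        out.attrs["sem_undefined"] = True
    return out


def intensity_response_table(features: pd.DataFrame) -> pd.DataFrame:
    """Tidy one-row-per-eye x intensity x feature table for external statistics.

    ``features`` has columns eye_id, intensity, optionally repeat, and the
    four feature columns.  Repeated flashes at the same intensity (the
    low-intensity three-repeat protocol) are averaged per eye before
    tabulation.  Intensity values are carried through verbatim.
    """
    required = {"eye_id", "intensity", *FEATURE_NAMES}
    missing = required - set(features.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    key = ["eye_id", "intensity"] + (["repeat"] if "repeat" in features.columns else [])
    if features.duplicated(subset=key).any():
        raise InvalidInputError("duplicate eye x intensity keys")
    averaged = (
        features.groupby(["eye_id", "intensity"], sort=True)[list(FEATURE_NAMES)]
        .mean()
        .reset_index()
    )
    long = averaged.melt(
        id_vars=["eye_id", "intensity"],
        value_vars=list(FEATURE_NAMES),
        var_name="feature",
        value_name="value",
    )
    return long.sort_values(["eye_id", "intensity", "feature"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV I/O


def traces_to_frame(traces: list[ErgTrace]) -> pd.DataFrame:
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "time_ms": np.asarray(tr.time_ms, dtype=float),
                    "voltage_uv": np.asarray(tr.voltage_uv, dtype=float),
                    "onset_ms": tr.stimulus_onset_ms,
                    "intensity": tr.intensity,
                    "eye_id": tr.eye_id,
                    "fish_id": tr.fish_id,
                    "group": tr.group,
                    "condition": tr.condition,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)[TRACE_COLUMNS]


def frame_to_traces(df: pd.DataFrame) -> list[ErgTrace]:
    out = []
    for (eye, intensity), g in df.groupby(["eye_id", "intensity"], sort=True):
        g = g.sort_values("time_ms")
        out.append(
            ErgTrace(
                time_ms=g["time_ms"].to_numpy(),
                voltage_uv=g["voltage_uv"].to_numpy(),
                stimulus_onset_ms=float(g["onset_ms"].iloc[0]),
                intensity=float(intensity),
                eye_id=str(eye),
                fish_id=str(g["fish_id"].iloc[0]),
                group=str(g["group"].iloc[0]),
                condition=str(g["condition"].iloc[0]),
            )
        )
    return out


def write_traces(traces: list[ErgTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path) -> list[ErgTrace]:
    return frame_to_traces(pd.read_csv(path))
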