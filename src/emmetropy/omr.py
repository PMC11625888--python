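"""Optomotor-response analysis: the optomotor index (OMI), trial averaging and
normalization.

The OMI of a trial is the net angular displacement of the fish over the trial,
signed so that movement in the direction of the rotating grating is positive.
Tracked angular position arrives wrapped to (-pi, pi]; it is unwrapped before
differencing, which is exact as long as the true per-sample rotation stays
below pi (comfortably satisfied at 30 Hz video and zebrafish swim speeds).

Per fish and spatial frequency, the OMIs of the four trials (two clockwise,
two counter-clockwise) are averaged arithmetically; the signed convention makes
the average direction-neutral. The resulting tuning dataset is normalized by
dividing every value by the mean OMI of a designated reference group at a
designated reference spatial frequency, so the reference condition's group mean
is exactly 1 afterwards.

Units: OMI is reported in net signed radians (the tracker's native angular
unit); this convention is recorded in the dataset metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
)

#: Column order of the tidy trajectory CSV schema.
TRAJECTORY_COLUMNS = [
    "time_s",
    "angle_rad",
    "stim_direction",
    "stim_speed",
    "spatial_freq",
    "fish_id",
    "group",
    "trial_id",
]

#: Column order of the tidy tuning-dataset CSV schema.
DATASET_COLUMNS = [
    "fish_id",
    "group",
    "spatial_frequency",
    "omi_mean",
    "omi_normalized",
    "n_trials",
]


@dataclass
class TrialTrajectory:
    """One OMR trial: timestamped angular position plus stimulus metadata.

    ``angle_wrapped`` is in radians in (-pi, pi]; ``stim_direction`` is +1 or
    -1; ``stim_speed`` in rad/s; ``spatial_frequency`` in cycles/degree.
    ``truth_net_displacement`` carries generator ground truth (unwrapped net
    rotation, rad) when the trial is synthetic; it is never used by analysis.
    """

    time: np.ndarray
    angle_wrapped: np.ndarray
    stim_direction: int
    stim_speed: float
    spatial_frequency: float
    fish_id: str = "fish"
    group: str = ""
    trial_id: str = "t0"
    truth_net_displacement: float | None = field(default=None, compare=False)

    def validate(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.angle_wrapped, dtype=float)
        if t.size < 2:
            raise InsufficientDataError(
                f"trial {self.trial_id!r}: need >= 2 samples, got {t.size}"
            )
        if a.shape != t.shape:
            raise InvalidInputError("time and angle arrays differ in length")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError(f"trial {self.trial_id!r}: time not strictly increasing")
        if self.stim_direction not in (-1, 1):
            raise InvalidInputError("stim_direction must be +1 or -1")


@dataclass(frozen=True)
class TrialResult:
    """Signed OMI (rad, positive = with the stimulus) of one trial."""

    omi: float
    spatial_frequency: float
    fish_id: str
    group: str
    trial_id: str = "t0"


def unwrap_angles(angle_wrapped: np.ndarray) -> np.ndarray:
    """Undo (-pi, pi] wrapping: adjacent jumps larger than pi are corrected by 2*pi."""
    return np.unwrap(np.asarray(angle_wrapped, dtype=float))


def compute_omi(traj: TrialTrajectory) -> TrialResult:
    """Net signed angular displacement of a trial, positive with the grating."""
    traj.validate()
    theta = unwrap_angles(traj.angle_wrapped)
    omi = float((theta[-1] - theta[0]) * traj.stim_direction)
    return TrialResult(
        omi=omi,
        spatial_frequency=traj.spatial_frequency,
        fish_id=traj.fish_id,
        group=traj.group,
        trial_id=traj.trial_id,
    )


def average_trials(results: list[TrialResult]) -> dict:
    """Mean signed OMI of one fish x frequency cell; no imputation of missing trials."""
    if not results:
        raise InsufficientDataError("no trial results to average")
    fish = {r.fish_id for r in results}
    freqs = {r.spatial_frequency for r in results}
    if len(fish) != 1 or len(freqs) != 1:
        raise InvalidInputError(
            "average_trials expects results from a single fish and frequency"
        )
    omis = [r.omi for r in results]
    return {
        "fish_id": results[0].fish_id,
        "group": results[0].group,
        "spatial_frequency": results[0].spatial_frequency,
        "omi_mean": float(np.mean(omis)),
        "n_trials": len(omis),
    }


def build_tuning_dataset(results: list[TrialResult]) -> pd.DataFrame:
    """Aggregate trial results into one row per fish x spatial frequency."""
    if not results:
        raise InsufficientDataError("no trial results")
    keyed: dict[tuple, list[TrialResult]] = {}
    for r in results:
        keyed.setdefault((r.fish_id, r.spatial_frequency), []).append(r)
    rows = [average_trials(v) for v in keyed.values()]
    ds = pd.DataFrame(rows).sort_values(["group", "fish_id", "spatial_frequency"])
    ds = ds.reset_index(drop=True)
    ds["omi_normalized"] = np.nan
    ds.attrs["omi_units"] = "net signed radians"
    return ds


def normalize_omi(
    ds: pd.DataFrame, reference_group: str, reference_frequency: float
) -> pd.DataFrame:
    """Divide every OMI by the reference group's mean OMI at the reference frequency.

    After normalization the reference group's mean at the reference frequency is
    exactly 1. The reference is recorded in ``ds.attrs``.
    """
    mask = (ds["group"] == reference_group) & np.isclose(
        ds["spatial_frequency"], reference_frequency, rtol=1e-9, atol=0.0
    )
    if not mask.any():
        raise InvalidInputError(
            f"no rows for reference group {reference_group!r} "
            f"at frequency {reference_frequency}"
        )
    ref_mean = float(ds.loc[mask, "omi_mean"].mean())
    if ref_mean == 0.0:
        raise DegenerateDataError("reference-condition mean OMI is zero")
    out = ds.copy()
    out["omi_normalized"] = out["omi_mean"] / ref_mean
    out.attrs.update(ds.attrs)
    out.attrs["normalization_reference_group"] = reference_group
    out.attrs["normalization_reference_frequency"] = reference_frequency
    out.attrs["normalization_reference_mean"] = ref_mean
    return out


# ---------------------------------------------------------------------------
# CSV I/O


def trajectories_to_frame(trajectories: list[TrialTrajectory]) -> pd.DataFrame:
    """Long-format table of trajectory samples (one row per time sample)."""
    parts = []
    for tr in trajectories:
        parts.append(
            pd.DataFrame(
                {
                    "time_s": np.asarray(tr.time, dtype=float),
                    "angle_rad": np.asarray(tr.angle_wrapped, dtype=float),
                    "stim_direction": tr.stim_direction,
                    "stim_speed": tr.stim_speed,
                    "spatial_freq": tr.spatial_frequency,
                    "fish_id": tr.fish_id,
                    "group": tr.group,
                    "trial_id": tr.trial_id,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)[TRAJECTORY_COLUMNS]


def frame_to_trajectories(df: pd.DataFrame) -> list[TrialTrajectory]:
    out = []
    for (fish, trial, freq), g in df.groupby(
        ["fish_id", "trial_id", "spatial_freq"], sort=True
    ):
        g = g.sort_values("time_s")
        out.append(
            TrialTrajectory(
                time=g["time_s"].to_numpy(),
                angle_wrapped=g["angle_rad"].to_numpy(),
                stim_direction=int(g["stim_direction"].iloc[0]),
                stim_speed=float(g["stim_speed"].iloc[0]),
                spatial_frequency=float(freq),
                fish_id=str(fish),
                group=str(g["group"].iloc[0]),
                trial_id=str(trial),
            )
        )
    return out


def write_trajectories(trajectories: list[TrialTrajectory], path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False)


def read_trajectories(path) -> list[TrialTrajectory]:
    return frame_to_trajectories(pd.read_csv(path))


def write_dataset(ds: pd.DataFrame, path) -> None:
    ds[DATASET_COLUMNS].to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path)
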