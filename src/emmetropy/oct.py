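"""Ocular biometry from OCT axial landmarks and Matthiessen's ratio.

For an aquatic eye the lens does essentially all refracting, so relative
refraction can be indexed by Matthiessen's ratio: retinal radius divided by
lens radius (R/L).  From axial landmark positions along the central optical
axis (corneal apex, anterior and posterior lens surfaces, RPE):

    axial length   = RPE - corneal apex
    lens radius    = (posterior lens - anterior lens) / 2
    retinal radius = axial length - lens radius
    R/L ratio      = retinal radius / lens radius

Retinal radius is taken as axial length minus lens radius (the lens-center to
RPE distance) which coincides with the optical retinal radius when the
cornea-to-lens gap is negligible, the usual small-fish-eye assumption.  An
R/L ratio higher than the control group's indicates relative axial myopia; a
lower ratio a relative hyperopic shift.

Landmark detection on synthetic B-scans averages an axial intensity profile
over a central column band, picks the four most prominent peaks, orders them
by depth, and refines each by parabolic interpolation; it returns pixel
units, and biometry requires explicitly calibrated micrometres.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
)

LANDMARK_NAMES = ("cornea_apex", "anterior_lens", "posterior_lens", "rpe")

#: Peak prominence threshold for landmark detection, as a fraction of the
#: axial profile's dynamic range.
DETECTION_PROMINENCE_FRACTION = 0.1

#: |mean case - control R/L difference| below this is reported as emmetropic.
EMMETROPIA_TOLERANCE = 1e-3


@dataclass(frozen=True)
class OctLandmarks:
    """Axial positions (um, or px from detection) along the central axis."""

    cornea_apex: float
    anterior_lens: float
    posterior_lens: float
    rpe: float
    eye_id: str = "eye"
    fish_id: str = "fish"
    group: str = ""

    def validate(self) -> None:
        if not (self.cornea_apex < self.anterior_lens < self.posterior_lens < self.rpe):
            raise InvalidInputError(
                "landmarks must be ordered cornea < anterior lens < "
                f"posterior lens < RPE, got {self.as_tuple()}"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.cornea_apex, self.anterior_lens, self.posterior_lens, self.rpe)


@dataclass(frozen=True)
class Biometry:
    """Derived axial biometry (um) and the dimensionless R/L ratio."""

    axial_length: float
    lens_radius: float
    retinal_radius: float
    rl_ratio: float


def compute_biometry(lm: OctLandmarks) -> Biometry:
    """Axial length, lens radius, retinal radius and Matthiessen's ratio."""
    if lm.posterior_lens == lm.anterior_lens:
        raise DegenerateDataError("zero lens radius: R/L ratio undefined")
    lm.validate()
    axial = lm.rpe - lm.cornea_apex
    lens_r = (lm.posterior_lens - lm.anterior_lens) / 2.0
    retinal_r = axial - lens_r
    return Biometry(
        axial_length=float(axial),
        lens_radius=float(lens_r),
        retinal_radius=float(retinal_r),
        rl_ratio=float(retinal_r / lens_r),
    )


def _parabolic_refine(profile: np.ndarray, idx: int) -> float:
    """Sub-pixel peak position via a parabola through (idx-1, idx, idx+1)."""
    if idx <= 0 or idx >= profile.size - 1:
        return float(idx)
    y0, y1, y2 = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def detect_axis_landmarks(
    image: np.ndarray,
    axis_column_band: int = 10,
    prominence_fraction: float = DETECTION_PROMINENCE_FRACTION,
    eye_id: str = "eye",
    fish_id: str = "fish",
    group: str = "",
) -> OctLandmarks:
    """Locate the four axial landmarks on a B-scan, in pixel rows.

    The intensity profile is the row-wise mean over ``axis_column_band``
    columns centred on the image's vertical midline; the four most prominent
    peaks, re-sorted by depth, become cornea / anterior lens / posterior lens
    / RPE, each refined to sub-pixel by parabolic interpolation.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError("expected a nonempty 2-D grayscale image")
    if not 1 <= axis_column_band <= img.shape[1]:
        raise InvalidInputError("axis_column_band outside image width")
    mid = img.shape[1] // 2
    half = axis_column_band // 2
    lo = max(0, mid - half)
    profile = img[:, lo : lo + axis_column_band].mean(axis=1)
    span = float(profile.max() - profile.min())
    if span == 0:
        raise InsufficientDataError("flat axial profile: no landmarks found")
    peaks, props = find_peaks(profile, prominence=prominence_fraction * span)
    if peaks.size < 4:
        raise InsufficientDataError(
            f"found {peaks.size} axial peaks, need 4 landmarks"
        )
    top4 = peaks[np.argsort(props["prominences"])[-4:]]
    rows = sorted(_parabolic_refine(profile, int(i)) for i in np.sort(top4))
    return OctLandmarks(*rows, eye_id=eye_id, fish_id=fish_id, group=group)


def relative_refraction(
    case_ratios, control_ratios, tolerance: float = EMMETROPIA_TOLERANCE
) -> dict:
    """Mean R/L difference (case - control) with its refractive direction label.

    Positive difference = relative myopia, negative = relative hyperopia,
    within ``tolerance`` of zero = emmetropic.  Descriptive only; inferential
    statistics are left to external tools on the tidy tables.
    """
    case = np.asarray(case_ratios, dtype=float)
    control = np.asarray(control_ratios, dtype=float)
    if case.size == 0 or control.size == 0:
        raise InsufficientDataError("both ratio lists must be nonempty")
    shift = float(case.mean() - control.mean())
    if abs(shift) <= tolerance:
        label = "emmetropic"
    elif shift > 0:
        label = "relative myopia"
    else:
        label = "relative hyperopia"
    return {
        "mean_shift": shift,
        "label": label,
        "case_mean": float(case.mean()),
        "control_mean": float(control.mean()),
        "n_case": int(case.size),
        "n_control": int(control.size),
    }


# ---------------------------------------------------------------------------
# CSV I/O

LANDMARK_COLUMNS = ["eye_id", "fish_id", "group", *LANDMARK_NAMES]


def landmarks_to_frame(landmarks: list[OctLandmarks]) -> pd.DataFrame:
    rows = [
        {
            "eye_id": lm.eye_id,
            "fish_id": lm.fish_id,
            "group": lm.group,
            **dict(zip(LANDMARK_NAMES, lm.as_tuple())),
        }
        for lm in landmarks
    ]
    return pd.DataFrame(rows)[LANDMARK_COLUMNS]


def frame_to_landmarks(df: pd.DataFrame) -> list[OctLandmarks]:
    return [
        OctLandmarks(
            cornea_apex=float(r["cornea_apex"]),
            anterior_lens=float(r["anterior_lens"]),
            posterior_lens=float(r["posterior_lens"]),
            rpe=float(r["rpe"]),
            eye_id=str(r["eye_id"]),
            fish_id=str(r["fish_id"]),
            group=str(r["group"]),
        )
        for _, r in df.iterrows()
    ]


def biometry_table(landmarks: list[OctLandmarks]) -> pd.DataFrame:
    """One biometry row per eye."""
    rows = []
    for lm in landmarks:
        b = compute_biometry(lm)
        rows.append(
            {
                "eye_id": lm.eye_id,
                "fish_id": lm.fish_id,
                "group": lm.group,
                "axial_length_um": b.axial_length,
                "lens_radius_um": b.lens_radius,
                "retinal_radius_um": b.retinal_radius,
                "rl_ratio": b.rl_ratio,
            }
        )
    return pd.DataFrame(rows)
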