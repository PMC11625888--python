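"""Inner-retinal layer-profile quantification.

Workflow for straightened retinal cross-sections (inner nuclear side on the
left, ganglion-cell side on the right): extract a columnwise mean intensity
profile over a fixed-height horizontal band; rescale the pixel axis so the
IPL width matches the control group's mean IPL width; normalize the profile
to its maximum; then sum normalized intensity over fixed per-layer pixel
windows (amacrine cell layer, inner plexiform layer, ganglion cell layer).

The published window schemes are 1-based inclusive pixel ranges:

    2-day:  ACL 1-90, IPL 91-300, GCL 301-390   (390-px profile)
    4-week: ACL 1-90, IPL 91-330, GCL 331-455   (455-px profile)

Internally windows are converted to 0-based half-open slices.  Resampling
happens before max-normalization, and uses linear interpolation (the minimal
assumption for an image-editor resize); both choices are recorded in output
metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DegenerateDataError, InvalidInputError

#: 1-based inclusive (start, end) windows per scheme, ordered ACL, IPL, GCL.
SCHEMES: dict[str, tuple[tuple[int, int], ...]] = {
    "2-day": ((1, 90), (91, 300), (301, 390)),
    "4-week": ((1, 90), (91, 330), (331, 455)),
}
LAYER_NAMES = ("acl", "ipl", "gcl")
DEFAULT_ROI_HEIGHT_PX = 150


@dataclass
class LayerProfile:
    """Intensity vs pixel position across the inner retina (left = INL side)."""

    intensity: np.ndarray
    ipl_bounds: tuple[float, float] | None = None
    roi_height_px: int = DEFAULT_ROI_HEIGHT_PX
    eye_id: str = "eye"
    group: str = ""
    condition: str = ""
    timepoint: str = ""
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidInputError("profile must be 1-D with >= 2 pixels")
        if self.ipl_bounds is not None:
            lo, hi = self.ipl_bounds
            if not (0 <= lo < hi <= arr.size):
                raise InvalidInputError(f"ipl_bounds {self.ipl_bounds} outside profile")


def extract_profile(
    image: np.ndarray,
    roi_height_px: int = DEFAULT_ROI_HEIGHT_PX,
    ipl_bounds: tuple[float, float] | None = None,
    **labels,
) -> LayerProfile:
    """Columnwise mean over a vertically centred band of ``roi_height_px`` rows."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("expected a 2-D grayscale image")
    if img.shape[1] < 2:
        raise InvalidInputError("image narrower than 2 px")
    if not 1 <= roi_height_px <= img.shape[0]:
        raise InvalidInputError(
            f"roi_height_px {roi_height_px} exceeds image height {img.shape[0]}"
        )
    top = (img.shape[0] - roi_height_px) // 2
    band = img[top : top + roi_height_px, :]
    return LayerProfile(
        intensity=band.mean(axis=0),
        ipl_bounds=ipl_bounds,
        roi_height_px=roi_height_px,
        **labels,
    )


def resample_to_control_ipl(
    profile: LayerProfile, control_mean_ipl_px: float
) -> LayerProfile:
    """Rescale the pixel axis so the IPL width equals the control mean width.

    The whole profile is stretched by factor ``control_mean_ipl_px / ipl
    width`` with linear interpolation; ``ipl_bounds`` are mapped to the new
    scale.  New pixel i samples the old profile at coordinate i / factor.
    """
    profile.validate()
    if profile.ipl_bounds is None:
        raise InvalidInputError("profile has no ipl_bounds; cannot rescale")
    if control_mean_ipl_px < 1:
        raise InvalidInputError("control_mean_ipl_px must be >= 1")
    lo, hi = profile.ipl_bounds
    width = hi - lo
    if width <= 0:
        raise InvalidInputError("zero IPL width")
    factor = control_mean_ipl_px / width
    old = np.asarray(profile.intensity, dtype=float)
    n_new = max(2, int(round(old.size * factor)))
    x_new = np.arange(n_new) / factor
    values = np.interp(x_new, np.arange(old.size), old)
    out = replace(
        profile,
        intensity=values,
        ipl_bounds=(lo * factor, hi * factor),
        metadata={**profile.metadata, "ipl_resample_factor": factor},
    )
    return out


def normalize_profile(profile: LayerProfile) -> LayerProfile:
    """Divide by the profile maximum so the highest value becomes exactly 1."""
    profile.validate()
    arr = np.asarray(profile.intensity, dtype=float)
    peak = float(arr.max())
    if peak <= 0:
        raise DegenerateDataError("profile maximum is not positive; cannot normalize")
    return replace(
        profile,
        intensity=arr / peak,
        normalized=True,
        metadata={
            **profile.metadata,
            "normalization": "max",
            "normalization_order": "resample-then-normalize",
        },
    )


@dataclass(frozen=True)
class LayerSums:
    """Summed normalized intensity per layer (dimensionless)."""

    acl_sum: float
    ipl_sum: float
    gcl_sum: float
    window_scheme: str

    def as_dict(self) -> dict[str, float]:
        return {"acl": self.acl_sum, "ipl": self.ipl_sum, "gcl": self.gcl_sum}


def _windows_to_slices(windows) -> list[slice]:
    """1-based inclusive (start, end) -> 0-based half-open slices."""
    return [slice(start - 1, end) for start, end in windows]


def layer_sums(
    profile: LayerProfile,
    scheme: str = "2-day",
    custom_windows: tuple[tuple[int, int], ...] | None = None,
) -> LayerSums:
    """Sum normalized intensity over the ACL / IPL / GCL pixel windows."""
    profile.validate()
    if not profile.normalized:
        raise InvalidInputError("profile must be max-normalized before summing")
    if custom_windows is not None:
        windows, scheme_name = tuple(custom_windows), "custom"
    else:
        if scheme not in SCHEMES:
            raise InvalidInputError(f"unknown scheme {scheme!r}; have {sorted(SCHEMES)}")
        windows, scheme_name = SCHEMES[scheme], scheme
    arr = np.asarray(profile.intensity, dtype=float)
    expected_len = windows[-1][1]
    if arr.size != expected_len:
        raise InvalidInputError(
            f"profile length {arr.size} does not match scheme {scheme_name!r} "
            f"(expects {expected_len} px)"
        )
    sums = [float(arr[s].sum()) for s in _windows_to_slices(windows)]
    return LayerSums(*sums, window_scheme=scheme_name)


def quantify(
    image: np.ndarray,
    scheme: str,
    control_mean_ipl_px: float | None = None,
    ipl_bounds: tuple[float, float] | None = None,
    roi_height_px: int = DEFAULT_ROI_HEIGHT_PX,
    **labels,
) -> tuple[LayerProfile, LayerSums]:
    """End-to-end: extract, optionally IPL-rescale, normalize, and sum."""
    profile = extract_profile(
        image, roi_height_px=roi_height_px, ipl_bounds=ipl_bounds, **labels
    )
    if control_mean_ipl_px is not None:
        profile = resample_to_control_ipl(profile, control_mean_ipl_px)
    profile = normalize_profile(profile)
    # IPL-rescaling by a non-integer factor can leave the profile a pixel or
    # two away from the fixed ROI width; the ROI is anchored at the left
    # (INL side), so reconcile at the right edge.
    expected_len = SCHEMES[scheme][-1][1] if scheme in SCHEMES else None
    arr = np.asarray(profile.intensity, dtype=float)
    if expected_len is not None and arr.size != expected_len:
        if arr.size > expected_len:
            arr = arr[:expected_len]
        else:
            arr = np.pad(arr, (0, expected_len - arr.size))
        profile = replace(
            profile,
            intensity=arr,
            metadata={**profile.metadata, "roi_length_adjusted_to": expected_len},
        )
    return profile, layer_sums(profile, scheme=scheme)
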