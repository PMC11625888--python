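"""Spatial-frequency tuning: three-parameter log-Gaussian fits and
extra-sum-of-squares F-tests for group comparison.

Model
-----
The tuning function relates response amplitude (normalized OMI) to grating
spatial frequency f (cycles/degree):

    g(f; A, p, sigma) = A * exp(-(log10 f - log10 p)^2 / (2 sigma^2))

with amplitude A (height of the peak, normalized OMI units), peak frequency p
(c/deg) and bandwidth sigma (standard deviation in log10-frequency units; the
base-10 choice only rescales sigma and is recorded in output metadata).
Parameters are estimated by unweighted least squares on per-fish points, with
a multi-start strategy over log-spaced initial peak frequencies because the
objective is multimodal in p.

Group comparison uses extra-sum-of-squares F-tests. The omnibus test compares
a full model in which every group has its own three parameters (k_full = 3G)
with a restricted model fitting one curve to the pooled data (k_restr = 3):

    F = ((RSS_R - RSS_F) / (k_full - k_restr)) / (RSS_F / (N - k_full))

with p from F(k_full - k_restr, N - k_full). Nested tests constrain a single
named parameter to be shared across groups (k_restr = 3G - (G-1)), refitting
the restricted model jointly rather than constraining full-fit estimates
post hoc. For a common dataset this is equivalent to comparing goodness of
fit (r^2) between the models, but is numerically better defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
)

PARAMETERS = ("amplitude", "peak_frequency", "bandwidth")

#: Default bandwidth bounds, log10-frequency units.
SIGMA_BOUNDS = (0.05, 2.0)
#: Peak-frequency bounds extend the tested range by this factor on both sides.
PEAK_RANGE_FACTOR = 4.0
#: Amplitude upper bound as a multiple of the largest observed response.
AMPLITUDE_CEILING_FACTOR = 10.0
DEFAULT_N_STARTS = 8


def log_gaussian(f, amplitude: float, peak_frequency: float, bandwidth: float):
    """Evaluate the log-Gaussian tuning function at frequency ``f`` (c/deg)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise InvalidInputError("spatial frequency must be positive")
    if peak_frequency <= 0:
        raise InvalidInputError("peak frequency must be positive")
    if bandwidth <= 0:
        raise InvalidInputError("bandwidth must be positive")
    z = (np.log10(f) - np.log10(peak_frequency)) / bandwidth
    return amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class LogGaussianFit:
    """Least-squares log-Gaussian fit to (frequency, response) points."""

    amplitude: float
    peak_frequency: float
    bandwidth: float
    rss: float
    n_points: int
    r_squared: float
    flags: tuple[str, ...] = field(default=())

    @property
    def df(self) -> int:
        return self.n_points - 3

    def predict(self, f):
        return log_gaussian(f, self.amplitude, self.peak_frequency, self.bandwidth)

    def params(self) -> dict[str, float]:
        return {
            "amplitude": self.amplitude,
            "peak_frequency": self.peak_frequency,
            "bandwidth": self.bandwidth,
        }


@dataclass(frozen=True)
class ModelComparisonResult:
    """Extra-sum-of-squares F-test between a full and a restricted model."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    rss_full: float
    rss_restricted: float
    comparison_kind: str


def _validate_xy(frequencies, responses):
    f = np.asarray(frequencies, dtype=float)
    y = np.asarray(responses, dtype=float)
    if f.shape != y.shape or f.ndim != 1:
        raise InvalidInputError("frequencies and responses must be 1-D and equal length")
    if f.size < 4:
        raise InsufficientDataError(f"need >= 4 points to fit 3 parameters, got {f.size}")
    if np.unique(f).size < 3:
        raise DegenerateDataError("need >= 3 distinct frequencies")
    if np.any(f <= 0):
        raise InvalidInputError("spatial frequencies must be positive")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("non-finite responses")
    return f, y


def _bounds(f: np.ndarray, y: np.ndarray):
    """(lower, upper) for (A, log10 p, sigma)."""
    ymax = float(np.max(np.abs(y)))
    lo_p = np.log10(f.min() / PEAK_RANGE_FACTOR)
    hi_p = np.log10(f.max() * PEAK_RANGE_FACTOR)
    return (
        np.array([0.0, lo_p, SIGMA_BOUNDS[0]]),
        np.array([AMPLITUDE_CEILING_FACTOR * max(ymax, 1e-12), hi_p, SIGMA_BOUNDS[1]]),
    )


def _start_points(f, y, n_starts):
    """Log-spaced peak starts across the tested range, amplitude from the data."""
    lf = np.log10(f)
    a0 = max(float(np.max(y)), 1e-6)
    starts = []
    for lp in np.linspace(lf.min(), lf.max(), n_starts):
        starts.append(np.array([a0, lp, 0.3]))
    return starts


def _solve(residual_fn, x0, lower, upper):
    x0c = np.clip(x0, lower, upper)
    try:
        res = optimize.least_squares(
            residual_fn, x0c, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12
        )
    except Exception:
        return None
    return res


def _better(cand, best):
    """Tie-break best-of-starts: rss, then smaller sigma, then smaller peak."""
    if best is None:
        return True
    rtol = 1e-10 * max(best[0], 1.0)
    if cand[0] < best[0] - rtol:
        return True
    if cand[0] > best[0] + rtol:
        return False
    if cand[1][2] < best[1][2]:
        return True
    if cand[1][2] > best[1][2]:
        return False
    return cand[1][1] < best[1][1]


def fit_log_gaussian(
    frequencies,
    responses,
    n_starts: int = DEFAULT_N_STARTS,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> LogGaussianFit:
    """Fit A, p, sigma by least squares with multi-start over peak frequency.

    All-zero responses are a degenerate but legal input: amplitude 0 fits
    exactly and p, sigma are unidentifiable; they are reported at nominal
    values with an ``unidentifiable`` flag.
    """
    f, y = _validate_xy(frequencies, responses)
    if np.max(np.abs(y)) == 0.0:
        return LogGaussianFit(
            amplitude=0.0,
            peak_frequency=float(10 ** np.mean(np.log10(f))),
            bandwidth=0.3,
            rss=0.0,
            n_points=f.size,
            r_squared=1.0,
            flags=("unidentifiable",),
        )
    lower, upper = bounds if bounds is not None else _bounds(f, y)
    lf = np.log10(f)

    def residual(x):
        z = (lf - x[1]) / x[2]
        return x[0] * np.exp(-0.5 * z * z) - y

    best = None
    for x0 in _start_points(f, y, n_starts):
        res = _solve(residual, x0, lower, upper)
        if res is None:
            continue
        rss = float(2.0 * res.cost)
        if _better((rss, res.x), best):
            best = (rss, res.x)
    if best is None:
        raise DegenerateDataError("all optimizer starts failed")
    rss, x = best
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else float("nan"))
    return LogGaussianFit(
        amplitude=float(x[0]),
        peak_frequency=float(10 ** x[1]),
        bandwidth=float(x[2]),
        rss=rss,
        n_points=f.size,
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# Model comparison


def _check_groups(groups: dict):
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups to compare")
    clean = {}
    for label, (f, y) in groups.items():
        clean[label] = _validate_xy(f, y)
    return clean


def _extra_ss_f(rss_full, rss_restricted, df_num, df_den, kind) -> ModelComparisonResult:
    if df_num < 1 or df_den < 1:
        raise InsufficientDataError("not enough points for the requested comparison")
    extra = rss_restricted - rss_full
    # Restricted space is a subset of the full space: a tiny negative extra SS
    # can only be optimizer round-off.  A grossly negative one is a real defect.
    if extra < 0:
        if extra < -1e-6 * max(rss_full, 1.0):
            raise RuntimeError(
                "restricted model fit better than full model: optimizer failure "
                f"(RSS_R={rss_restricted}, RSS_F={rss_full})"
            )
        extra = 0.0
    if rss_full == 0.0:
        fstat = float("inf") if extra > 0 else 0.0
        p = 0.0 if extra > 0 else 1.0
    else:
        fstat = (extra / df_num) / (rss_full / df_den)
        p = float(stats.f.sf(fstat, df_num, df_den))
    return ModelComparisonResult(
        f_statistic=float(fstat),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        rss_full=float(rss_full),
        rss_restricted=float(rss_restricted),
        comparison_kind=kind,
    )


def omnibus_f_test(groups: dict, n_starts: int = DEFAULT_N_STARTS) -> ModelComparisonResult:
    """Do the groups share one tuning curve?  Full: 3 parameters per group;
    restricted: one 3-parameter curve fit to the pooled data."""
    clean = _check_groups(groups)
    n_groups = len(clean)
    fits = {k: fit_log_gaussian(f, y, n_starts=n_starts) for k, (f, y) in clean.items()}
    rss_full = sum(fit.rss for fit in fits.values())
    f_all = np.concatenate([f for f, _ in clean.values()])
    y_all = np.concatenate([y for _, y in clean.values()])
    pooled = fit_log_gaussian(f_all, y_all, n_starts=n_starts)
    n_total = f_all.size
    return _extra_ss_f(
        rss_full,
        pooled.rss,
        df_num=3 * n_groups - 3,
        df_den=n_total - 3 * n_groups,
        kind="omnibus",
    )


def _restricted_joint_fit(clean: dict, parameter: str, n_starts: int):
    """Jointly refit all groups with ``parameter`` shared; returns RSS.

    Parametrization: x = [shared, other1_g1, other2_g1, other1_g2, ...] where
    A and sigma live on their natural scale and p as log10 p.
    """
    idx = PARAMETERS.index(parameter)
    labels = list(clean)
    data = [clean[k] for k in labels]
    per_bounds = [_bounds(f, y) for f, y in data]
    # shared-parameter bounds: intersection across groups
    lo_shared = max(b[0][idx] for b in per_bounds)
    hi_shared = min(b[1][idx] for b in per_bounds)
    other_idx = [i for i in range(3) if i != idx]

    lower = [lo_shared]
    upper = [hi_shared]
    for lo, hi in per_bounds:
        lower.extend(lo[other_idx])
        upper.extend(hi[other_idx])
    lower = np.array(lower)
    upper = np.array(upper)

    lfs = [np.log10(f) for f, _ in data]
    ys = [y for _, y in data]

    def residual(x):
        out = []
        for g, (lf, y) in enumerate(zip(lfs, ys)):
            p3 = np.empty(3)
            p3[idx] = x[0]
            p3[other_idx[0]] = x[1 + 2 * g]
            p3[other_idx[1]] = x[2 + 2 * g]
            z = (lf - p3[1]) / p3[2]
            out.append(p3[0] * np.exp(-0.5 * z * z) - y)
        return np.concatenate(out)

    # Starts: seed from independent full fits (shared value = their mean), plus
    # a sweep of shared values across its bounds.
    full_fits = [fit_log_gaussian(f, y, n_starts=n_starts) for f, y in data]
    full_x = []
    for fit in full_fits:
        v = [fit.amplitude, np.log10(fit.peak_frequency), fit.bandwidth]
        full_x.append(np.array(v))
    starts = []
    base = [np.mean([v[idx] for v in full_x])]
    for v in full_x:
        base.extend(v[other_idx])
    starts.append(np.array(base))
    for shared in np.linspace(lo_shared, hi_shared, n_starts):
        s = np.array(base, dtype=float)
        s[0] = shared
        starts.append(s)

    best = None
    for x0 in starts:
        res = _solve(residual, x0, lower, upper)
        if res is None:
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best:
            best = rss
    if best is None:
        raise DegenerateDataError("restricted joint fit failed from every start")
    rss_full = sum(fit.rss for fit in full_fits)
    return best, rss_full


def nested_f_test(
    groups: dict, constrained_parameter: str, n_starts: int = DEFAULT_N_STARTS
) -> ModelComparisonResult:
    """Does the named parameter differ between groups?  The restricted model
    shares that parameter across groups and is refit jointly."""
    if constrained_parameter not in PARAMETERS:
        raise InvalidInputError(
            f"constrained_parameter must be one of {PARAMETERS}, "
            f"got {constrained_parameter!r}"
        )
    clean = _check_groups(groups)
    n_groups = len(clean)
    n_total = sum(f.size for f, _ in clean.values())
    rss_restricted, rss_full = _restricted_joint_fit(
        clean, constrained_parameter, n_starts
    )
    return _extra_ss_f(
        rss_full,
        rss_restricted,
        df_num=n_groups - 1,
        df_den=n_total - 3 * n_groups,
        kind=f"nested({constrained_parameter})",
    )


def dataset_groups(ds, response_column: str = "omi_normalized") -> dict:
    """Split a tidy tuning dataset into {group: (frequencies, responses)}."""
    out = {}
    for label, g in ds.groupby("group", sort=True):
        out[str(label)] = (
            g["spatial_frequency"].to_numpy(dtype=float),
            g[response_column].to_numpy(dtype=float),
        )
    return out
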