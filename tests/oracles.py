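"""Independent oracles used by the test suite and the reproduction script.

Each oracle recomputes an expected value by a different route than the
implementation under test: brute-force loops, dense grid searches with a
simplex polish, closed forms, or direct re-integration of a seeded noise
stream.  None of them call the code paths they check.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# OMR


def unwrap_by_increments(wrapped: np.ndarray) -> np.ndarray:
    """Cumulative sum of wrapped per-sample increments mapped to (-pi, pi]."""
    wrapped = np.asarray(wrapped, dtype=float)
    out = [wrapped[0]]
    for k in range(1, wrapped.size):
        d = wrapped[k] - wrapped[k - 1]
        d = np.pi - (np.pi - d) % (2.0 * np.pi)  # map increment to (-pi, pi]
        out.append(out[-1] + d)
    return np.array(out)


def reintegrate_trajectory(
    tuning_gain, stim_direction, stim_speed, duration, sample_rate, noise_sd, seed
) -> float:
    """Net displacement from independently re-integrating the same seeded
    velocity-noise stream (drift + white noise in velocity)."""
    n_steps = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate
    rng = np.random.default_rng(seed)
    noise = noise_sd * np.sqrt(dt) * rng.standard_normal(n_steps)
    total = 0.0
    for k in range(n_steps):
        total += tuning_gain * stim_direction * stim_speed * dt + noise[k]
    return total


# ---------------------------------------------------------------------------
# Tuning fits


def _model(lf, amplitude, lp, sigma):
    z = (lf - lp) / sigma
    return amplitude * np.exp(-0.5 * z * z)


def _rss(lf, y, amplitude, lp, sigma):
    return float(np.sum((y - _model(lf, amplitude, lp, sigma)) ** 2))


def grid_fit_rss(
    frequencies,
    responses,
    n_grid: int = 60,
    lp_range=None,
    sigma_range=(0.05, 2.0),
    polish: bool = True,
) -> float:
    """Best RSS of the 3-parameter log-Gaussian by dense grid search.

    Grid over (log10 peak, sigma) with the amplitude profiled out in closed
    form (the model is linear in amplitude, clipped at zero), optionally
    followed by a Nelder-Mead polish of all three parameters.
    """
    f = np.asarray(frequencies, dtype=float)
    y = np.asarray(responses, dtype=float)
    lf = np.log10(f)
    if lp_range is None:
        lp_range = (np.log10(f.min() / 4.0), np.log10(f.max() * 4.0))
    lps = np.linspace(*lp_range, n_grid)
    sigmas = np.linspace(*sigma_range, n_grid)
    # vectorized: basis[i, j, k] = exp kernel at (lp_i, sigma_j, point_k)
    z = (lf[None, None, :] - lps[:, None, None]) / sigmas[None, :, None]
    basis = np.exp(-0.5 * z * z)
    denom = np.sum(basis * basis, axis=2)
    amp = np.clip(np.sum(basis * y[None, None, :], axis=2) / denom, 0.0, None)
    rss = np.sum((y[None, None, :] - amp[:, :, None] * basis) ** 2, axis=2)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    best = float(rss[i, j])
    if not polish:
        return best
    x0 = np.array([amp[i, j], lps[i], sigmas[j]])
    res = minimize(
        lambda x: _rss(lf, y, max(x[0], 0.0), x[1], max(x[2], 1e-6)),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000},
    )
    return min(best, float(res.fun))


def restricted_refit_rss(
    groups: dict,
    parameter: str,
    n_shared: int = 160,
    n_grid: int = 60,
    polish: bool = True,
) -> float:
    """Best RSS of the shared-parameter restricted model by grid search.

    For each candidate shared value on a dense grid, the per-group RSS
    minimisation over the remaining two parameters separates across groups
    (grid over the non-shared nonlinear parameters, amplitude profiled in
    closed form where free); a Nelder-Mead polish of the full restricted
    parameter vector finishes the search.
    """
    data = [(np.log10(np.asarray(f, float)), np.asarray(y, float))
            for f, y in groups.values()]
    lf_min = min(lf.min() for lf, _ in data)
    lf_max = max(lf.max() for lf, _ in data)
    lp_range = (lf_min - np.log10(4.0), lf_max + np.log10(4.0))
    sigma_range = (0.05, 2.0)
    amp_hi = [10.0 * max(np.max(np.abs(y)), 1e-12) for _, y in data]

    if parameter == "amplitude":
        shared_grid = np.linspace(0.0, max(amp_hi), n_shared)
    elif parameter == "peak_frequency":
        shared_grid = np.linspace(*lp_range, n_shared)
    elif parameter == "bandwidth":
        shared_grid = np.linspace(*sigma_range, n_shared)
    else:
        raise ValueError(parameter)

    lps = np.linspace(*lp_range, n_grid)
    sigmas = np.linspace(*sigma_range, n_grid)

    def group_min_rss(g, shared):
        lf, y = data[g]
        if parameter == "amplitude":
            z = (lf[None, None, :] - lps[:, None, None]) / sigmas[None, :, None]
            basis = np.exp(-0.5 * z * z)
            rss = np.sum((y[None, None, :] - shared * basis) ** 2, axis=2)
            i, j = np.unravel_index(np.argmin(rss), rss.shape)
            return float(rss[i, j]), (shared, lps[i], sigmas[j])
        if parameter == "peak_frequency":
            z = (lf[None, :] - shared) / sigmas[:, None]
            basis = np.exp(-0.5 * z * z)
        else:  # bandwidth shared
            z = (lf[None, :] - lps[:, None]) / shared
            basis = np.exp(-0.5 * z * z)
        denom = np.sum(basis * basis, axis=1)
        amp = np.clip(np.sum(basis * y[None, :], axis=1) / denom, 0.0, None)
        rss = np.sum((y[None, :] - amp[:, None] * basis) ** 2, axis=1)
        i = int(np.argmin(rss))
        if parameter == "peak_frequency":
            return float(rss[i]), (amp[i], shared, sigmas[i])
        return float(rss[i]), (amp[i], lps[i], shared)

    best_total = np.inf
    best_params = None
    for shared in shared_grid:
        total = 0.0
        params = []
        for g in range(len(data)):
            r, p3 = group_min_rss(g, shared)
            total += r
            params.append(p3)
        if total < best_total:
            best_total = total
            best_params = (shared, params)
    if not polish:
        return best_total

    shared0, per_group = best_params
    pidx = {"amplitude": 0, "peak_frequency": 1, "bandwidth": 2}[parameter]
    other = [i for i in range(3) if i != pidx]
    x0 = [shared0]
    for p3 in per_group:
        x0.extend([p3[other[0]], p3[other[1]]])

    def objective(x):
        total = 0.0
        for g, (lf, y) in enumerate(data):
            p3 = [0.0, 0.0, 0.0]
            p3[pidx] = x[0]
            p3[other[0]] = x[1 + 2 * g]
            p3[other[1]] = x[2 + 2 * g]
            a = max(p3[0], 0.0)
            s = max(p3[2], 1e-6)
            total += _rss(lf, y, a, p3[1], s)
        return total

    res = minimize(
        objective,
        np.array(x0),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000, "maxfev": 50000},
    )
    return min(best_total, float(res.fun))


def extra_ss_f_statistic(rss_full, rss_restricted, df_num, df_den) -> float:
    return ((rss_restricted - rss_full) / df_num) / (rss_full / df_den)


# ---------------------------------------------------------------------------
# ERG


def windowed_extrema(time_ms, voltage, onset, a_window, b_window_end):
    """Brute-force loop: earliest argmin in the a-window, earliest argmax
    strictly after it up to ``onset + b_window_end``."""
    trough_idx, trough_v = None, np.inf
    for k in range(len(time_ms)):
        rel = time_ms[k] - onset
        if a_window[0] <= rel <= a_window[1] and voltage[k] < trough_v:
            trough_idx, trough_v = k, voltage[k]
    peak_idx, peak_v = None, -np.inf
    for k in range(trough_idx + 1, len(time_ms)):
        if time_ms[k] - onset <= b_window_end and voltage[k] > peak_v:
            peak_idx, peak_v = k, voltage[k]
    return trough_idx, peak_idx


# ---------------------------------------------------------------------------
# Images


def column_means(image: np.ndarray, top: int, height: int) -> np.ndarray:
    """Per-column mean over rows [top, top+height) by explicit summation."""
    out = np.zeros(image.shape[1])
    for c in range(image.shape[1]):
        s = 0.0
        for r in range(top, top + height):
            s += image[r, c]
        out[c] = s / height
    return out


def linear_interp_at(values: np.ndarray, x: float) -> float:
    """Piecewise-linear evaluation of samples at integer positions."""
    n = len(values)
    if x <= 0:
        return float(values[0])
    if x >= n - 1:
        return float(values[-1])
    k = int(np.floor(x))
    frac = x - k
    return float(values[k] * (1 - frac) + values[k + 1] * frac)
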