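"""Extracellular field-potential analysis: FV/EPSP measurement, sigmoid
input-output curves, population-spike threshold, and LTP quantification.

The fiber volley (FV) is the first negative deflection after the stimulus
artifact; the field EPSP slope is the linear-regression slope over the
20-80% segment of the EPSP falling phase (initial slope, magnitude in
mV/ms).  Input-output ("synaptic strength") curves relate EPSP slope to FV
amplitude and FV amplitude to stimulus level, each fit with a
three-parameter Boltzmann sigmoid.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import find_peaks

from .simulate import boltzmann


def _baseline(sweep: pd.DataFrame, artifact_time_ms: float) -> float:
    pre = sweep[sweep["time_ms"] < artifact_time_ms - 0.5]["voltage_mv"]
    return float(pre.mean()) if len(pre) else 0.0


def measure_fv(
    sweep: pd.DataFrame,
    artifact_time_ms: float,
    fv_window_ms: tuple[float, float] = (0.5, 3.0),
    noise_k: float = 3.0,
) -> tuple[float, bool]:
    """Fiber-volley amplitude: baseline-to-trough of the first negative
    deflection after the artifact.

    Returns (amplitude mV, flagged); a sweep with no deflection beyond
    ``noise_k`` times the pre-artifact noise returns (0, True).
    """
    base = _baseline(sweep, artifact_time_ms)
    pre = sweep[sweep["time_ms"] < artifact_time_ms - 0.5]["voltage_mv"]
    noise = float(pre.std()) if len(pre) > 1 else 0.0
    a, b = fv_window_ms
    win = sweep[(sweep["time_ms"] >= artifact_time_ms + a)
                & (sweep["time_ms"] <= artifact_time_ms + b)]
    if len(win) == 0:
        return 0.0, True
    trough = float(win["voltage_mv"].min())
    amp = base - trough
    if amp <= noise_k * noise or amp <= 0:
        return 0.0, True
    return amp, False


def measure_epsp_slope(
    sweep: pd.DataFrame,
    artifact_time_ms: float,
    epsp_window_ms: tuple[float, float] = (3.0, 15.0),
    slope_fracs: tuple[float, float] = (0.2, 0.8),
    noise_k: float = 3.0,
) -> tuple[float, bool]:
    """Initial EPSP slope (mV/ms, magnitude) over the 20-80% falling segment.

    The EPSP trough is the first local voltage minimum within
    ``epsp_window_ms`` after the artifact (beyond the FV window) — the
    first, not the deepest, so a later population-spike notch does not
    displace it; the slope is the linear fit over samples whose depth below
    baseline lies between the ``slope_fracs`` fractions of the trough
    depth, on the falling limb only.
    """
    base = _baseline(sweep, artifact_time_ms)
    pre = sweep[sweep["time_ms"] < artifact_time_ms - 0.5]["voltage_mv"]
    noise = float(pre.std()) if len(pre) > 1 else 0.0
    a, b = epsp_window_ms
    win = sweep[(sweep["time_ms"] >= artifact_time_ms + a)
                & (sweep["time_ms"] <= artifact_time_ms + b)]
    if len(win) < 3:
        return 0.0, True
    t = win["time_ms"].to_numpy()
    v = win["voltage_mv"].to_numpy()
    depth_floor = max(noise_k * noise, 0.05 * (base - v.min()))
    troughs, _ = find_peaks(-v, prominence=depth_floor)
    k_tr = int(troughs[0]) if len(troughs) else int(np.argmin(v))
    depth = base - v[k_tr]
    if depth <= noise_k * noise or depth <= 0:
        return 0.0, True
    falling_t, falling_v = t[:k_tr + 1], v[:k_tr + 1]
    frac = (base - falling_v) / depth
    seg = (frac >= slope_fracs[0]) & (frac <= slope_fracs[1])
    if seg.sum() < 2:
        return 0.0, True
    res = stats.linregress(falling_t[seg], falling_v[seg])
    return abs(float(res.slope)), False


def detect_pop_spike(
    sweep: pd.DataFrame,
    artifact_time_ms: float,
    epsp_window_ms: tuple[float, float] = (3.0, 15.0),
    k: float = 4.0,
    smooth_ms: float = 0.4,
    lag_ms: float = 0.25,
    guard_ms: float = 0.75,
    trend_ms: float = 2.0,
    depth_floor_frac: float = 0.05,
) -> bool:
    """Population spike: a fast notch interrupting the EPSP return phase.

    The EPSP return (recovery) phase after the trough rises smoothly; a PS
    superimposes a fast downward notch.  The sweep is boxcar-smoothed over
    ``smooth_ms`` and its lagged-difference slope (lag ``lag_ms``, mV/ms)
    is detrended with a ``trend_ms`` median filter (removing the slow
    recovery slope that would otherwise mask a small notch) and scanned
    after the trough plus a ``guard_ms`` junction guard: a PS is present
    iff the detrended slope dips below ``-k`` times the robust pre-artifact
    slope-noise scale (MAD-based), with a floor of ``depth_floor_frac`` of
    the EPSP depth per ms so noiseless sweeps need a genuine notch.
    """
    t = sweep["time_ms"].to_numpy()
    v = sweep["voltage_mv"].to_numpy()
    if len(v) < 8:
        return False
    dt = t[1] - t[0]
    m = max(1, int(round(smooth_ms / dt)))
    v_sm = uniform_filter1d(v.astype(float), m)
    lag = max(1, int(round(lag_ms / dt)))
    slope = (v_sm[lag:] - v_sm[:-lag]) / (lag * dt)  # mV/ms at t[i]+lag/2
    n_tr = max(1, int(round(trend_ms / dt)))
    if n_tr % 2 == 0:
        n_tr += 1
    slope = slope - median_filter(slope, size=n_tr, mode="nearest")
    t_slope = t[:-lag] + lag * dt / 2.0

    a, b = epsp_window_ms
    win = (t >= artifact_time_ms + a) & (t <= artifact_time_ms + b)
    if not win.any():
        return False
    vw = v[win]
    troughs, _ = find_peaks(-vw, prominence=0.05 * np.ptp(vw))
    k_tr = int(troughs[0]) if len(troughs) else int(np.argmin(vw))
    t_trough = t[win][k_tr]
    base = _baseline(sweep, artifact_time_ms)
    depth = base - vw[k_tr]
    if depth <= 0:
        return False

    region = (t_slope > t_trough + guard_ms) \
        & (t_slope <= artifact_time_ms + b)
    if not region.any():
        return False
    # robust scale from the analysis region itself: the notch is sparse, so
    # the MAD reflects the noise floor, not the notch
    seg = slope[region]
    noise_scale = 1.4826 * np.median(np.abs(seg - np.median(seg)))
    thr = max(k * noise_scale, depth_floor_frac * depth)
    return bool(np.any(seg < -thr))


def measure_sweeps(
    sweeps: pd.DataFrame,
    artifact_time_ms: float = 5.0,
    **kwargs,
) -> pd.DataFrame:
    """Per-level FV amplitude, EPSP slope, ratio, and PS flag.

    ``sweeps`` is long-format (time_ms, voltage_mv, level).
    """
    rows = []
    for level, sw in sweeps.groupby("level"):
        fv, fv_flag = measure_fv(sw, artifact_time_ms)
        sl, ep_flag = measure_epsp_slope(sw, artifact_time_ms)
        ps = detect_pop_spike(sw, artifact_time_ms, **kwargs)
        rows.append({
            "level": level, "fv_amplitude_mv": fv,
            "epsp_slope_mv_per_ms": sl,
            "ratio": sl / fv if fv > 0 else np.nan,
            "pop_spike": ps, "fv_flagged": fv_flag,
            "epsp_flagged": ep_flag,
        })
    return pd.DataFrame(rows).sort_values("level").reset_index(drop=True)


def fit_sigmoid(x, y) -> tuple[np.ndarray, bool]:
    """Least-squares Boltzmann fit; returns (params, converged).

    params = (max_response, half_max_input, slope_factor).  All-equal
    responses give a degenerate fit, flagged not converged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need >= 4 finite points for a sigmoid fit")
    if np.ptp(y) == 0:
        return np.array([y[0], np.median(x), np.ptp(x) / 4 or 1.0]), False
    p0 = [1.1 * y.max(), float(np.median(x)), float(np.ptp(x)) / 4 or 1.0]
    try:
        popt, _ = curve_fit(boltzmann, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return np.array(p0), False
    return popt, True


@dataclasses.dataclass
class StrengthCurve:
    """Input-output curve measurements with fitted sigmoid parameters."""

    measurements: pd.DataFrame
    fv_fit: np.ndarray            # FV vs stimulus level
    fv_fit_converged: bool
    strength_fit: np.ndarray      # EPSP slope vs FV amplitude
    strength_fit_converged: bool
    ps_threshold_epsp_slope: float

    @property
    def max_fv(self) -> float:
        return float(self.fv_fit[0])

    @property
    def half_max_fv(self) -> float:
        return float(self.fv_fit[1])

    @property
    def fv_curve_slope_factor(self) -> float:
        return float(self.fv_fit[2])

    @property
    def fv_curve_max_tangent_slope(self) -> float:
        # steepest tangent of a Boltzmann curve: max / (4 * slope_factor)
        return float(self.fv_fit[0] / (4.0 * self.fv_fit[2]))

    @property
    def max_epsp_slope(self) -> float:
        return float(self.strength_fit[0])

    @property
    def strength_slope_factor(self) -> float:
        return float(self.strength_fit[2])

    @property
    def max_ratio(self) -> float:
        m = self.measurements
        return float(m["ratio"].max())

    def parameters(self) -> dict:
        return {
            "max_fv_mv": self.max_fv,
            "half_max_fv_mv": self.half_max_fv,
            "fv_curve_slope_factor": self.fv_curve_slope_factor,
            "fv_curve_max_tangent_slope": self.fv_curve_max_tangent_slope,
            "max_epsp_slope_mv_per_ms": self.max_epsp_slope,
            "strength_half_max_fv_mv": float(self.strength_fit[1]),
            "strength_slope_factor": self.strength_slope_factor,
            "max_ratio": self.max_ratio,
            "ps_threshold_epsp_slope_mv_per_ms":
                self.ps_threshold_epsp_slope,
        }


def fit_strength_curve(sweeps: pd.DataFrame,
                       artifact_time_ms: float = 5.0) -> StrengthCurve:
    """Measure all sweeps and fit the two input-output sigmoids.

    The FV curve is FV amplitude vs stimulus level; the synaptic strength
    curve is EPSP slope vs FV amplitude.  The population-spike threshold is
    the EPSP slope at the lowest stimulus level where a PS appears (NaN if
    none does).
    """
    meas = measure_sweeps(sweeps, artifact_time_ms)
    fv_fit, fv_ok = fit_sigmoid(meas["level"], meas["fv_amplitude_mv"])
    st_fit, st_ok = fit_sigmoid(meas["fv_amplitude_mv"],
                                meas["epsp_slope_mv_per_ms"])
    with_ps = meas[meas["pop_spike"]]
    ps_slope = float(with_ps.sort_values("level")
                     ["epsp_slope_mv_per_ms"].iloc[0]) \
        if len(with_ps) else float("nan")
    return StrengthCurve(
        measurements=meas,
        fv_fit=fv_fit, fv_fit_converged=fv_ok,
        strength_fit=st_fit, strength_fit_converged=st_ok,
        ps_threshold_epsp_slope=ps_slope,
    )


def quantify_ltp(
    epsp_slopes: np.ndarray,
    times_s: np.ndarray,
    tetanus_time_s: float,
    baseline_min: float = 20.0,
    quantify_min: float = 10.0,
) -> dict:
    """LTP as percent of the pre-tetanus baseline.

    Slopes (sampled at 0.033 Hz) are normalized to the mean over the
    ``baseline_min``-minute pre-tetanus window (x100); the LTP level is the
    mean normalized slope over the final ``quantify_min`` minutes of the
    post period.
    """
    epsp_slopes = np.asarray(epsp_slopes, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    pre = (times_s >= tetanus_time_s - baseline_min * 60.0) \
        & (times_s < tetanus_time_s)
    if not pre.any() or times_s[pre].min() > tetanus_time_s \
            - baseline_min * 60.0 + 60.0:
        raise ValueError(f"need >= {baseline_min} min of pre-tetanus sweeps")
    post_end = times_s.max()
    if post_end < tetanus_time_s + quantify_min * 60.0:
        raise ValueError(f"need >= {quantify_min} min of post-tetanus sweeps")
    base_mean = epsp_slopes[pre].mean()
    normalized = 100.0 * epsp_slopes / base_mean
    # half-open window so 10 min at 0.033 Hz holds exactly 20 sweeps
    last = times_s > post_end - quantify_min * 60.0
    return {
        "normalized_pct": normalized,
        "times_s": times_s,
        "ltp_pct": float(normalized[last].mean()),
        "n_quantified_sweeps": int(last.sum()),
    }
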