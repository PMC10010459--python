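"""Synthetic data generators with machine-readable ground truth.

Every generator in this module emulates one of the raw data streams the
pipeline consumes — GCaMP ROI traces, astrocyte-shaped image stacks,
RBC line-scan kymographs, arteriole lumen series, dual-channel leakiness
stacks, field-potential sweeps, and Y-maze arm-entry sequences — and
returns, alongside the data, the ground truth needed to score the
corresponding analysis module.  All randomness for a call is drawn from a
single ``numpy.random.default_rng(seed)`` so identical seed + parameters
give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# configuration / spec types
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TransientSpec:
    """One injected Ca2+ transient.

    amplitude is the fractional fluorescence change at the transient peak
    (0.5 -> a 50 %dF/F event); rise_tau / decay_tau are the two time
    constants of the product-of-exponentials waveform, in seconds.
    """

    amplitude: float
    rise_tau: float
    decay_tau: float
    onset_time: float

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be > 0")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Common simulation settings.

    noise_sd is additive Gaussian noise in fractional fluorescence units
    (i.e. multiplied by baseline_f0 before being added to the raw trace).
    """

    seed: int = 0
    duration: float = 600.0
    sampling_rate: float = 10.0
    noise_sd: float = 0.02
    baseline_f0: float = 100.0

    def __post_init__(self):
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


# --------------------------------------------------------------------------
# transient waveform
# --------------------------------------------------------------------------

def transient_peak_offset(rise_tau: float, decay_tau: float) -> float:
    """Time from onset to peak of the product-of-exponentials waveform."""
    return rise_tau * math.log((rise_tau + decay_tau) / rise_tau)


def _unit_transient(t: np.ndarray, onset: float, rise_tau: float,
                    decay_tau: float) -> np.ndarray:
    """(1 - exp(-u/rise)) * exp(-u/decay) for u = t - onset, peak-normalized."""
    u = t - onset
    shape = np.where(
        u > 0,
        (1.0 - np.exp(-np.clip(u, 0, None) / rise_tau))
        * np.exp(-np.clip(u, 0, None) / decay_tau),
        0.0,
    )
    u_star = transient_peak_offset(rise_tau, decay_tau)
    peak = (1.0 - math.exp(-u_star / rise_tau)) * math.exp(-u_star / decay_tau)
    return shape / peak


def gen_roi_traces(
    config: SimConfig,
    events_per_roi: Sequence[Sequence[TransientSpec]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw fluorescence traces with injected Ca2+ transients.

    Each trace is ``baseline_f0 * (1 + sum of transients(t)) + noise`` where
    noise is Gaussian with SD ``noise_sd * baseline_f0``.

    Returns
    -------
    traces : DataFrame with a ``time`` column and one ``roi_<k>`` column per
        ROI, raw fluorescence units.
    truth : DataFrame with one row per injected transient: roi_id,
        onset_time, peak_time, amplitude (fractional dF/F, i.e. the value
        the dF/F pipeline should recover divided by 100), rise_tau,
        decay_tau.
    """
    rng = np.random.default_rng(config.seed)
    t = config.time_axis()
    traces = {"time": t}
    truth_rows = []
    for k, specs in enumerate(events_per_roi):
        signal = np.zeros_like(t)
        for spec in specs:
            if not (0 <= spec.onset_time < config.duration):
                raise ValueError(
                    f"onset_time {spec.onset_time} outside trace duration")
            signal += spec.amplitude * _unit_transient(
                t, spec.onset_time, spec.rise_tau, spec.decay_tau)
            truth_rows.append({
                "roi_id": k,
                "onset_time": spec.onset_time,
                "peak_time": spec.onset_time
                + transient_peak_offset(spec.rise_tau, spec.decay_tau),
                "amplitude": spec.amplitude,
                "rise_tau": spec.rise_tau,
                "decay_tau": spec.decay_tau,
            })
        noise = rng.normal(0.0, config.noise_sd * config.baseline_f0,
                           size=t.shape)
        traces[f"roi_{k}"] = config.baseline_f0 * (1.0 + signal) + noise
    truth = pd.DataFrame(
        truth_rows,
        columns=["roi_id", "onset_time", "peak_time", "amplitude",
                 "rise_tau", "decay_tau"],
    )
    return pd.DataFrame(traces), truth


# --------------------------------------------------------------------------
# astrocyte-shaped image stacks
# --------------------------------------------------------------------------

def gen_astro_movie(
    config: SimConfig,
    blobs: Sequence[tuple[tuple[float, float], float, float]],
    shape: tuple[int, int] = (256, 256),
    n_frames: int | None = None,
) -> np.ndarray:
    """Render a 16-bit frame stack of Gaussian-profile astrocyte blobs.

    Each blob is ``(centroid (row, col), pixel_area, peak_intensity)``.
    pixel_area is the footprint above half maximum: for a Gaussian of
    spatial scale sigma that footprint is ``2*pi*sigma^2*ln 2``, so sigma is
    chosen as ``sqrt(area / (2*pi*ln 2))``.  Background level is
    ``baseline_f0`` counts; per-pixel Gaussian noise has SD
    ``noise_sd * baseline_f0``.
    """
    rng = np.random.default_rng(config.seed)
    if n_frames is None:
        n_frames = max(1, config.n_samples)
    h, w = shape
    base = np.full((h, w), config.baseline_f0, dtype=float)
    for (cy, cx), area, peak in blobs:
        if area <= 0:
            raise ValueError("blob area must be positive")
        if area > h * w:
            raise ValueError("blob area exceeds frame")
        if not (0 <= cy < h and 0 <= cx < w):
            raise ValueError("blob centroid outside frame")
        sigma = math.sqrt(area / (2.0 * math.pi * math.log(2.0)))
        yy, xx = np.mgrid[0:h, 0:w]
        base += peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                              / (2.0 * sigma ** 2))
    stack = base[None, :, :] + rng.normal(
        0.0, config.noise_sd * config.baseline_f0, size=(n_frames, h, w))
    return np.clip(stack, 0, 2 ** 16 - 1).astype(np.uint16)


# --------------------------------------------------------------------------
# line-scan kymographs
# --------------------------------------------------------------------------

def kymograph_slope(velocity_mm_s: float, pixel_size_um: float,
                    line_rate_hz: float) -> float:
    """Streak slope in pixels per line for a given RBC velocity."""
    return (velocity_mm_s * 1000.0) / (pixel_size_um * line_rate_hz)


def gen_kymograph(
    velocity_mm_s: float,
    line_rate_hz: float = 2000.0,
    pixel_size_um: float = 0.1,
    n_lines: int = 1000,
    space_extent_um: float = 10.0,
    streak_density: float = 0.1,
    contrast: float = 0.5,
    streak_sigma_um: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Simulate a line-scan kymograph of moving RBC shadows.

    Returns a (space, time) matrix: bright plasma background with dark
    streaks whose space/time slope equals exactly
    ``velocity / (pixel_size * line_rate)`` pixels per line, plus the
    ground-truth metadata (velocity, slope, geometry, seed).  Streaks have
    a Gaussian cross-section of SD ``streak_sigma_um`` (default 1 um,
    the scale of an RBC shadow edge).
    """
    if line_rate_hz <= 0 or pixel_size_um <= 0:
        raise ValueError("line_rate and pixel_size must be > 0")
    rng = np.random.default_rng(seed)
    n_space = int(round(space_extent_um / pixel_size_um))
    slope = kymograph_slope(velocity_mm_s, pixel_size_um, line_rate_hz)
    if abs(slope) > n_space:
        raise ValueError(
            "velocity unresolvable: streak crosses the full spatial extent "
            "in under one line")
    # Seed streaks so coverage is uniform over the scan: each streak is a
    # line x(t) = x0 + slope * (t - t0) clipped to the field.
    n_streaks = max(1, int(round(streak_density * n_lines)))
    t0 = rng.uniform(-n_lines * 0.1, n_lines * 1.1, size=n_streaks)
    x0 = rng.uniform(-n_space * 0.5, n_space * 1.5, size=n_streaks)
    img = np.ones((n_space, n_lines), dtype=float)
    lines = np.arange(n_lines)
    xs = np.arange(n_space)
    sigma_px = streak_sigma_um / pixel_size_um
    for i in range(n_streaks):
        pos = x0[i] + slope * (lines - t0[i])  # spatial position per line
        # Gaussian cross-section around pos; broadcast (space, time)
        img -= contrast * np.exp(-((xs[:, None] - pos[None, :]) ** 2)
                                 / (2.0 * sigma_px ** 2))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    truth = {
        "velocity_mm_s": velocity_mm_s,
        "slope_px_per_line": slope,
        "pixel_size_um": pixel_size_um,
        "line_rate_hz": line_rate_hz,
        "n_lines": n_lines,
        "n_space": n_space,
        "seed": seed,
    }
    return img, truth


# --------------------------------------------------------------------------
# arteriole dilation series
# --------------------------------------------------------------------------

def gen_vessel_series(
    baseline_radius_um: float = 10.0,
    dilation_pct: float = 20.0,
    stim_onset_s: float = 20.0,
    stim_duration_s: float = 10.0,
    rise_s: float = 2.0,
    fall_s: float = 5.0,
    frame_rate_hz: float = 2.0,
    duration_s: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Simulate an arteriole lumen-area series with a plateau dilation.

    The lumen cross-sectional area (um^2, the paper-style volume proxy)
    rises exponentially toward a plateau of ``(1 + dilation_pct/100) *
    baseline`` during stimulation and relaxes exponentially afterwards.
    Noise is multiplicative Gaussian (``noise_sd`` fractional).

    Returns the noisy series and ground truth containing the noiseless
    series, the true peak time and the true max/baseline ratio in percent.
    Negative dilation (constriction) is permitted but flagged.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * frame_rate_hz))) / frame_rate_hz
    base_area = math.pi * baseline_radius_um ** 2
    g = np.zeros_like(t)
    stim_end = stim_onset_s + stim_duration_s
    during = (t >= stim_onset_s) & (t <= stim_end)
    after = t > stim_end
    g[during] = 1.0 - np.exp(-(t[during] - stim_onset_s) / rise_s)
    g_end = 1.0 - math.exp(-stim_duration_s / rise_s)
    g[after] = g_end * np.exp(-(t[after] - stim_end) / fall_s)
    # rescale so the realized maximum hits dilation_pct exactly
    if g.max() > 0:
        g = g / g.max()
    clean = base_area * (1.0 + dilation_pct / 100.0 * g)
    noisy = clean * (1.0 + rng.normal(0.0, noise_sd, size=t.shape))
    truth = {
        "clean_series": clean,
        "time_s": t,
        "baseline_area_um2": base_area,
        "max_dilation_pct": 100.0 + dilation_pct,
        "peak_time_s": float(t[np.argmax(clean)]),
        "stim_onset_s": stim_onset_s,
        "stim_end_s": stim_end,
        "constriction": dilation_pct < 0,
        "seed": seed,
    }
    return noisy, truth


def gen_leakiness_stacks(
    rhodamine_decay_per_min: float = 0.01,
    egfp_decay_per_min: float = 0.0,
    timepoints_min: Sequence[float] = (0, 15, 30, 45, 60),
    base_rhodamine: float = 2000.0,
    base_egfp: float = 1000.0,
    shape: tuple[int, int] = (64, 64),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[dict[float, dict[str, np.ndarray]], dict]:
    """Dual-channel mean-intensity stacks at the leakiness timepoints.

    Each channel decays exponentially at its own per-minute rate; frames
    are uniform fields plus optional Gaussian noise.  Ground truth carries
    the analytic rhodamine/EGFP ratio (normalized to t = 0) per timepoint.
    """
    rng = np.random.default_rng(seed)
    stacks: dict[float, dict[str, np.ndarray]] = {}
    truth_ratio = {}
    for tp in timepoints_min:
        rho = base_rhodamine * math.exp(-rhodamine_decay_per_min * tp)
        egf = base_egfp * math.exp(-egfp_decay_per_min * tp)
        stacks[tp] = {
            "rhodamine": rho + rng.normal(0, noise_sd * rho, size=shape),
            "egfp": egf + rng.normal(0, noise_sd * egf, size=shape),
        }
        truth_ratio[tp] = math.exp(
            -(rhodamine_decay_per_min - egfp_decay_per_min) * tp)
    truth = {"ratio_to_t0": truth_ratio, "seed": seed}
    return stacks, truth


# --------------------------------------------------------------------------
# field-potential sweeps
# --------------------------------------------------------------------------

def boltzmann(x, max_response, half_max_input, slope_factor):
    """Three-parameter sigmoid used for input-output curves."""
    x = np.asarray(x, dtype=float)
    z = np.clip((half_max_input - x) / slope_factor, -500.0, 500.0)
    return max_response / (1.0 + np.exp(z))


def gen_fp_sweeps(
    sigmoid_params: tuple[float, float, float] = (1.5, 0.3, 0.08),
    n_levels: int = 12,
    fv_gain: float = 0.05,
    ps_threshold_level: int = 9,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_rate_hz: float = 20000.0,
    sweep_duration_s: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Simulate extracellular field-potential sweeps over stimulus levels.

    Per level ``i`` (1..n_levels): a stimulus artifact at 5 ms, a fiber
    volley (FV) of amplitude ``fv_gain * i`` mV at ~7 ms, and a field EPSP
    whose initial falling phase is a straight segment with slope (mV/ms)
    given by the Boltzmann sigmoid of the FV amplitude.  Levels at or above
    ``ps_threshold_level`` carry a fast population-spike notch on the EPSP
    return phase.  ``sigmoid_params`` is (max_response mV/ms,
    half_max_input mV on the FV axis, slope_factor mV).

    Returns a long-format DataFrame (time_ms, voltage_mv, level) plus
    ground truth (per-level FV amplitude and EPSP slope, the generating
    parameters, artifact time, and PS levels).
    """
    if n_levels < 4:
        raise ValueError("need >= 4 levels for curve fitting")
    rng = np.random.default_rng(seed)
    n = int(round(sweep_duration_s * sampling_rate_hz))
    t_ms = np.arange(n) / sampling_rate_hz * 1000.0
    artifact_ms, fv_ms, epsp_on_ms = 5.0, 7.0, 9.0
    fall_dur_ms, recover_tau_ms = 3.0, 8.0
    rows = []
    fv_true, slope_true = [], []
    for level in range(1, n_levels + 1):
        v = np.zeros_like(t_ms)
        # biphasic stimulus artifact
        v += 2.0 * np.exp(-((t_ms - artifact_ms) ** 2) / (2 * 0.05 ** 2))
        v -= 2.0 * np.exp(-((t_ms - artifact_ms - 0.15) ** 2) / (2 * 0.05 ** 2))
        fv_amp = fv_gain * level
        v -= fv_amp * np.exp(-((t_ms - fv_ms) ** 2) / (2 * 0.25 ** 2))
        slope = float(boltzmann(fv_amp, *sigmoid_params))  # mV/ms
        depth = slope * fall_dur_ms
        falling = (t_ms >= epsp_on_ms) & (t_ms < epsp_on_ms + fall_dur_ms)
        v[falling] -= slope * (t_ms[falling] - epsp_on_ms)
        trough_ms = epsp_on_ms + fall_dur_ms
        recov = t_ms >= trough_ms
        v[recov] -= depth * np.exp(-(t_ms[recov] - trough_ms) / recover_tau_ms)
        if level >= ps_threshold_level:
            v -= 0.4 * depth * np.exp(
                -((t_ms - (trough_ms + 2.0)) ** 2) / (2 * 0.25 ** 2))
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.shape)
        fv_true.append(fv_amp)
        slope_true.append(slope)
        rows.append(pd.DataFrame({
            "time_ms": t_ms, "voltage_mv": v, "level": level}))
    sweeps = pd.concat(rows, ignore_index=True)
    truth = {
        "sigmoid_params": tuple(sigmoid_params),
        "fv_amplitude_mv": np.array(fv_true),
        "epsp_slope_mv_per_ms": np.array(slope_true),
        "ps_levels": list(range(ps_threshold_level, n_levels + 1)),
        "artifact_time_ms": artifact_ms,
        "fv_gain": fv_gain,
        "seed": seed,
    }
    return sweeps, truth


# --------------------------------------------------------------------------
# Y-maze arm entries
# --------------------------------------------------------------------------

def gen_arm_entries(
    n_entries: int,
    p_perfect_alternation: float,
    seed: int = 0,
) -> tuple[list[str], dict]:
    """Markov arm-entry sequence over {A, B, C}.

    After the first two entries, the next arm differs from both previous
    arms with probability ``p``; otherwise the previous arm is repeated.
    A sliding triad (three consecutive pairwise-distinct entries) requires
    two consecutive "alternate" draws, so the analytic expected alternation
    fraction is ``p**2``; it is returned as ground truth.
    """
    if n_entries < 3:
        raise ValueError("n_entries must be >= 3")
    if not 0.0 <= p_perfect_alternation <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    arms = ["A", "B", "C"]
    p = p_perfect_alternation
    seq = [arms[rng.integers(3)]]
    # second entry: alternate (differ from the first) with probability p
    if rng.random() < p:
        seq.append(rng.permuted([a for a in arms if a != seq[0]])[0])
    else:
        seq.append(seq[0])
    while len(seq) < n_entries:
        if rng.random() < p:
            choices = [a for a in arms if a not in seq[-2:]]
            seq.append(choices[int(rng.integers(len(choices)))])
        else:
            seq.append(seq[-1])
    truth = {"expected_alternation_fraction": p * p, "seed": seed}
    return seq, truth
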