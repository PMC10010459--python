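"""Ca2+ transient detection and kinetics on per-ROI fluorescence traces.

Raw traces are normalized to a pre-stimulus baseline (%dF/F), events are
extracted as supra-threshold excursions where the threshold is the baseline
mean plus a multiple of the baseline SD, and each event is measured for
amplitude, 10-90% rise time and half-decay time.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

EVENT_COLUMNS = [
    "roi_id", "onset_time", "peak_time", "end_time", "amplitude",
    "rise_time", "decay_time", "decay_censored", "window_label",
]


@dataclasses.dataclass
class DffTrace:
    """A %dF/F trace for one ROI."""

    roi_id: int
    sampling_rate: float
    values: np.ndarray
    baseline_window: tuple[float, float]

    def time_axis(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sampling_rate


def compute_dff(
    trace: np.ndarray,
    baseline_window: tuple[float, float],
    sampling_rate: float,
    roi_id: int = 0,
) -> DffTrace:
    """Normalize a raw fluorescence trace to %dF/F.

    F0 is the mean over ``baseline_window`` (seconds); output is
    ``100 * (F - F0) / F0``.  A non-positive F0 indicates a dead ROI and
    raises.
    """
    trace = np.asarray(trace, dtype=float)
    i0 = int(round(baseline_window[0] * sampling_rate))
    i1 = int(round(baseline_window[1] * sampling_rate))
    if i1 - i0 < 2 or i0 < 0 or i1 > len(trace):
        raise ValueError("baseline window must contain >= 2 samples "
                         "inside the trace")
    f0 = trace[i0:i1].mean()
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0 ({f0}); dead ROI?")
    return DffTrace(
        roi_id=roi_id,
        sampling_rate=sampling_rate,
        values=100.0 * (trace - f0) / f0,
        baseline_window=baseline_window,
    )


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float,
                     rising: bool) -> float:
    """First time y crosses `level` (linear interpolation between samples)."""
    if rising:
        idx = np.nonzero(y >= level)[0]
    else:
        idx = np.nonzero(y <= level)[0]
    if len(idx) == 0:
        return np.nan
    i = idx[0]
    if i == 0:
        return t[0]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return t[i]
    frac = (level - y0) / (y1 - y0)
    return t[i - 1] + frac * (t[i] - t[i - 1])


def detect_events(
    dff: DffTrace,
    k_sd: float = 2.0,
    min_separation: float = 1.0,
    min_duration: float = 0.3,
    smooth_s: float = 0.5,
    k_lo: float | None = None,
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Extract threshold-crossing events from a %dF/F trace.

    Detection runs on a lightly smoothed copy of the trace (moving average
    of ``smooth_s`` seconds) so single transients are not fragmented by
    sample noise; kinetics are measured on the raw trace afterwards.  The
    event threshold is ``baseline mean + k_sd * baseline SD`` computed on
    the raw %dF/F over the baseline window.  Detection uses hysteresis: an
    excursion must exceed that threshold, and its span extends until the
    trace returns below the lower bound ``baseline mean + k_lo * SD``
    (default ``k_sd / 2``) — so a transient's slow tail is not fragmented
    into spurious events.  Each excursion lasting at least ``min_duration``
    seconds contributes one event per local peak, with peaks at least
    ``min_separation`` seconds apart and a prominence of at least ``k_sd``
    baseline SDs.  ``windows`` maps labels (baseline / stimulation /
    recovery) to (start, end) seconds; each event is labeled by the window
    containing its peak.
    """
    raw = np.asarray(dff.values, dtype=float)
    if np.all(np.isnan(raw)):
        raise ValueError("all-NaN trace")
    fs = dff.sampling_rate
    n_sm = max(1, int(round(smooth_s * fs)))
    y = uniform_filter1d(raw, n_sm)
    t = dff.time_axis()
    i0 = int(round(dff.baseline_window[0] * fs))
    i1 = int(round(dff.baseline_window[1] * fs))
    # threshold from the raw %dF/F baseline statistics, applied to the
    # smoothed trace (smoothing only suppresses single-sample noise)
    base = raw[i0:i1]
    thr = base.mean() + k_sd * base.std()
    if k_lo is None:
        k_lo = k_sd / 2.0
    thr_lo = base.mean() + k_lo * base.std()

    # hysteresis: spans above the lower bound that contain at least one
    # sample above the event threshold
    above_lo = y > thr_lo
    rows = []
    edges = np.diff(above_lo.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
    if above_lo[0]:
        starts.insert(0, 0)
    if above_lo[-1]:
        ends.append(len(y))
    spans = [(s, e) for s, e in zip(starts, ends) if np.any(y[s:e] > thr)]
    min_dist = max(1, int(round(min_separation * fs)))
    min_len = max(1, int(round(min_duration * fs)))
    prominence = k_sd * base.std()
    for s, e in spans:
        if e - s < min_len:
            continue
        seg = y[s:e]
        # pad with the hysteresis floor so edge peaks are measurable and
        # every event (including a lone one) passes the prominence check
        seg_p = np.concatenate([[thr_lo], seg, [thr_lo]])
        peaks, _ = find_peaks(seg_p, distance=min_dist,
                              prominence=prominence)
        peaks = np.clip(peaks - 1, 0, e - s - 1)
        peaks = peaks[y[s + peaks] > thr]
        for p in peaks:
            pk = s + p
            rows.append({
                "roi_id": dff.roi_id,
                "onset_time": t[s],
                "peak_time": t[pk],
                "end_time": t[e - 1],
                "peak_value": raw[pk],
                "threshold": thr,
            })
    events = pd.DataFrame(
        rows, columns=["roi_id", "onset_time", "peak_time", "end_time",
                       "peak_value", "threshold"])
    if windows:
        def _label(pt):
            for name, (a, b) in windows.items():
                if a <= pt < b:
                    return name
            return "unassigned"
        events["window_label"] = events["peak_time"].map(_label)
    else:
        events["window_label"] = "all"
    return events


def event_kinetics(
    dff: DffTrace,
    peak_time: float,
    onset_time: float | None = None,
    pre_window: float = 1.0,
    rise_fracs: tuple[float, float] = (0.1, 0.9),
    decay_frac: float = 0.5,
) -> dict:
    """Measure amplitude, 10-90% rise time, and half-decay time of an event.

    Amplitude is the peak %dF/F minus the local pre-event baseline (mean of
    ``pre_window`` seconds preceding the onset; 0 if no samples).  Rise time
    is the interpolated interval between the ``rise_fracs`` crossings on the
    ascending limb; decay time the interpolated interval from the peak to
    ``decay_frac`` of the amplitude on the descending limb.  If the trace
    ends before the decay crossing, decay_time is NaN and flagged censored.
    """
    y = np.asarray(dff.values, dtype=float)
    t = dff.time_axis()
    fs = dff.sampling_rate
    pk = int(round(peak_time * fs))
    if not (0 <= pk < len(y)):
        raise ValueError("event peak outside trace")
    if onset_time is None:
        onset_time = max(0.0, peak_time - 5.0)
    on = int(round(onset_time * fs))
    pre0 = max(0, on - int(round(pre_window * fs)))
    local_base = y[pre0:on].mean() if on > pre0 else 0.0

    amplitude = y[pk] - local_base
    lo = local_base + rise_fracs[0] * amplitude
    hi = local_base + rise_fracs[1] * amplitude
    t_lo = _interp_crossing(t[on:pk + 1], y[on:pk + 1], lo, rising=True)
    t_hi = _interp_crossing(t[on:pk + 1], y[on:pk + 1], hi, rising=True)
    rise_time = t_hi - t_lo if np.isfinite(t_lo) and np.isfinite(t_hi) \
        else np.nan

    half = local_base + decay_frac * amplitude
    t_half = _interp_crossing(t[pk:], y[pk:], half, rising=False)
    censored = not np.isfinite(t_half)
    decay_time = np.nan if censored else t_half - t[pk]
    return {
        "amplitude": amplitude,
        "rise_time": rise_time,
        "decay_time": decay_time,
        "decay_censored": censored,
        "local_baseline": local_base,
    }


def measure_events(dff: DffTrace, events: pd.DataFrame,
                   **kinetics_kwargs) -> pd.DataFrame:
    """Attach kinetics to every detected event of one ROI."""
    out = []
    for _, ev in events.iterrows():
        kin = event_kinetics(dff, peak_time=ev["peak_time"],
                             onset_time=ev["onset_time"], **kinetics_kwargs)
        row = dict(ev)
        row.update(kin)
        out.append(row)
    return pd.DataFrame(out)


def transient_frequency(
    events: pd.DataFrame,
    duration: float,
    roi_ids=None,
    per_fov: bool = False,
) -> pd.Series | float:
    """Events per minute per ROI; optionally averaged across a FOV's ROIs.

    ROIs with zero events contribute 0/min when listed in ``roi_ids``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if roi_ids is None:
        roi_ids = sorted(events["roi_id"].unique()) if len(events) else []
    counts = pd.Series(0.0, index=pd.Index(roi_ids, name="roi_id"))
    if len(events):
        got = events.groupby("roi_id").size()
        counts.loc[got.index.intersection(counts.index)] = got
    per_min = counts / duration * 60.0
    return float(per_min.mean()) if per_fov else per_min
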