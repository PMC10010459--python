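"""Binarized-event pairwise correlation statistics for astrocyte networks.

Detected Ca2+ events are rasterized at a fixed bin rate (default 2 Hz over
a 60 s window, i.e. 120 samples per ROI and a 240-sample denominator per
ROI pair), Pearson-correlated pair-by-pair, and weighted by the pair's
event-sample fraction.  Pairs with weighted CC > 0.02 count as coactive;
correlogram edges are displayed for CC in [0.4, 1]; FOVs with a correlated-
ROI density of at most 100 per mm^2 are excluded from summaries.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

WCC_MIN = 0.02          # inclusion threshold on the weighted CC
CC_LINK_RANGE = (0.4, 1.0)  # correlogram display range for unweighted CC
FOV_DENSITY_MIN = 100.0     # correlated ROIs per mm^2, strict ">" gate


@dataclasses.dataclass
class BinaryRaster:
    """Event-occupancy raster: one {0,1} row per ROI."""

    roi_ids: list
    bin_rate: float
    window: tuple[float, float]
    matrix: np.ndarray  # (n_rois, n_bins) of uint8

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def samples_per_roi(self) -> int:
        return self.n_bins

    @property
    def samples_per_pair(self) -> int:
        return 2 * self.n_bins


def binarize_events(
    events: pd.DataFrame,
    roi_ids,
    bin_rate: float = 2.0,
    window: tuple[float, float] = (0.0, 60.0),
    recording_duration: float | None = None,
) -> BinaryRaster:
    """Rasterize event spans into half-open time bins.

    A bin ``[t, t + 1/bin_rate)`` is 1 for an ROI iff any part of one of
    its events' supra-threshold spans (onset_time..end_time) intersects the
    bin.  A 60 s window at 2 Hz therefore yields 120 samples per ROI.
    """
    start, end = window
    if end <= start:
        raise ValueError("empty analysis window")
    if recording_duration is not None and (start < 0
                                           or end > recording_duration):
        raise ValueError("analysis window outside the recording")
    n_bins = int(round((end - start) * bin_rate))
    roi_ids = list(roi_ids)
    mat = np.zeros((len(roi_ids), n_bins), dtype=np.uint8)
    index = {rid: k for k, rid in enumerate(roi_ids)}
    for _, ev in events.iterrows():
        rid = ev["roi_id"]
        if rid not in index:
            continue
        a = max(ev["onset_time"], start)
        b = min(ev["end_time"], end)
        if b < a:
            continue
        # half-open bins: bin j covers [start + j/rate, start + (j+1)/rate)
        j0 = int(np.floor((a - start) * bin_rate))
        j1 = int(np.floor((b - start) * bin_rate))
        j1 = min(j1, n_bins - 1)
        if j0 < n_bins and j1 >= j0:
            mat[index[rid], j0:j1 + 1] = 1
    return BinaryRaster(roi_ids=roi_ids, bin_rate=bin_rate,
                        window=window, matrix=mat)


def pair_cc(raster: BinaryRaster, i, j) -> float:
    """Pearson correlation of two binary event rows.

    Raises for a constant row (undefined correlation); callers exclude and
    log such pairs.
    """
    a = raster.matrix[raster.roi_ids.index(i)].astype(float)
    b = raster.matrix[raster.roi_ids.index(j)].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError(f"constant event row for pair ({i}, {j}); "
                         "correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def weighted_cc(cc: float, raster: BinaryRaster, i, j,
                coincident: bool = False) -> float:
    """Scale a pair's CC by its event-sample fraction.

    Default: the number of detected event samples for the pair is the total
    count of 1-bins across both rows, divided by the per-pair denominator
    (2 x samples-per-ROI; 240 at the default 2 Hz x 60 s).  With
    ``coincident=True`` the count is the number of bins where both rows are
    1 (alternative reading, same denominator).
    """
    ai = raster.matrix[raster.roi_ids.index(i)]
    bj = raster.matrix[raster.roi_ids.index(j)]
    if coincident:
        n_event = int(np.sum((ai == 1) & (bj == 1)))
    else:
        n_event = int(ai.sum() + bj.sum())
    return cc * n_event / raster.samples_per_pair


def pair_table(
    raster: BinaryRaster,
    distances: pd.DataFrame | None = None,
    wcc_min: float = WCC_MIN,
    coincident: bool = False,
) -> pd.DataFrame:
    """Compute cc / weighted cc / inclusion for every ROI pair.

    Pairs with a constant row get NaN cc and are never included.
    ``distances`` (roi_i, roi_j, distance_um) is merged in when given.
    """
    rows = []
    for i, j in itertools.combinations(raster.roi_ids, 2):
        try:
            cc = pair_cc(raster, i, j)
        except ValueError:
            rows.append({"roi_i": i, "roi_j": j, "cc": np.nan,
                         "weighted_cc": np.nan, "included": False})
            continue
        wcc = weighted_cc(cc, raster, i, j, coincident=coincident)
        rows.append({"roi_i": i, "roi_j": j, "cc": cc, "weighted_cc": wcc,
                     "included": bool(wcc > wcc_min)})
    pairs = pd.DataFrame(
        rows, columns=["roi_i", "roi_j", "cc", "weighted_cc", "included"])
    if distances is not None and len(pairs):
        key = ["roi_i", "roi_j"]
        d = distances.copy()
        d[key] = np.sort(d[key].to_numpy(), axis=1)
        pairs[key] = np.sort(pairs[key].to_numpy(), axis=1)
        pairs = pairs.merge(d[key + ["distance_um"]], on=key, how="left")
    return pairs


def network_summary(
    pairs: pd.DataFrame,
    fov_area: float,
    cc_link_range: tuple[float, float] = CC_LINK_RANGE,
    fov_density_min: float = FOV_DENSITY_MIN,
    gate_on_pairs: bool = False,
) -> dict:
    """FOV-level summary of one analysis window.

    coactive_pairs_per_mm2 counts included pairs (weighted CC above
    threshold) per FOV area; mean_pair_distance_um averages distance over
    pairs whose unweighted CC lies in the correlogram display range.  The
    FOV is excluded when the density of correlated ROIs (ROIs participating
    in >= 1 included pair; or included pairs themselves when
    ``gate_on_pairs``) is not strictly greater than ``fov_density_min``.
    """
    if fov_area <= 0:
        raise ValueError("fov_area must be > 0")
    inc = pairs[pairs["included"] == True] if len(pairs) else pairs  # noqa: E712
    n_inc = len(inc)
    correlated_rois = (pd.unique(inc[["roi_i", "roi_j"]].to_numpy().ravel())
                       if n_inc else [])
    density = (n_inc if gate_on_pairs else len(correlated_rois)) / fov_area
    lo, hi = cc_link_range
    if len(pairs) and "distance_um" in pairs:
        in_range = pairs[(pairs["cc"] >= lo) & (pairs["cc"] <= hi)]
        mean_dist = float(in_range["distance_um"].mean()) \
            if len(in_range) else np.nan
    else:
        mean_dist = np.nan
    return {
        "coactive_pairs_per_mm2": n_inc / fov_area,
        "n_included_pairs": n_inc,
        "n_correlated_rois": len(correlated_rois),
        "mean_pair_distance_um": mean_dist,
        "correlated_roi_density_per_mm2": density,
        "fov_included": bool(density > fov_density_min),
    }


def windowed_summaries(
    events: pd.DataFrame,
    roi_ids,
    fov_area: float,
    windows: dict[str, tuple[float, float]],
    distances: pd.DataFrame | None = None,
    bin_rate: float = 2.0,
    **summary_kwargs,
) -> pd.DataFrame:
    """Per-window (baseline / stimulation / recovery) FOV summaries."""
    rows = []
    for name, win in windows.items():
        raster = binarize_events(events, roi_ids, bin_rate=bin_rate,
                                 window=win)
        pairs = pair_table(raster, distances=distances)
        summ = network_summary(pairs, fov_area, **summary_kwargs)
        summ["window"] = name
        rows.append(summ)
    return pd.DataFrame(rows).set_index("window")


def active_roi_density(events: pd.DataFrame, roi_ids, fov_area: float,
                       window: tuple[float, float] | None = None) -> float:
    """ROIs with >= 1 event (peaking) in the window, per mm^2."""
    if fov_area <= 0:
        raise ValueError("fov_area must be > 0")
    ev = events
    if window is not None:
        ev = ev[(ev["peak_time"] >= window[0])
                & (ev["peak_time"] < window[1])]
    active = set(ev["roi_id"]).intersection(roi_ids)
    return len(active) / fov_area


def oscillation_frequency(events: pd.DataFrame,
                          window: tuple[float, float]) -> float:
    """Mean event rate (Hz) per active ROI within a stimulation window."""
    a, b = window
    if b <= a:
        raise ValueError("window length must be > 0")
    ev = events[(events["peak_time"] >= a) & (events["peak_time"] < b)]
    if len(ev) == 0:
        return 0.0
    per_roi = ev.groupby("roi_id").size() / (b - a)
    return float(per_roi.mean())


def export_correlogram(
    pairs: pd.DataFrame,
    rois: pd.DataFrame,
    cc_link_range: tuple[float, float] = CC_LINK_RANGE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge tables for correlogram plotting.

    Node weight is the sum of weighted CCs over the ROI's included
    partners (dot size in the figure); edges carry the unweighted CC and
    are restricted to the display range.
    """
    weights = {rid: 0.0 for rid in rois["roi_id"]}
    inc = pairs[pairs["included"] == True] if len(pairs) else pairs  # noqa: E712
    for _, p in inc.iterrows():
        weights[p["roi_i"]] = weights.get(p["roi_i"], 0.0) + p["weighted_cc"]
        weights[p["roi_j"]] = weights.get(p["roi_j"], 0.0) + p["weighted_cc"]
    nodes = rois[["roi_id", "centroid_x_um", "centroid_y_um"]].copy() \
        if {"centroid_x_um", "centroid_y_um"}.issubset(rois.columns) \
        else rois[["roi_id"]].copy()
    nodes["weight"] = nodes["roi_id"].map(weights)
    lo, hi = cc_link_range
    edges = pairs[(pairs["cc"] >= lo) & (pairs["cc"] <= hi)][
        ["roi_i", "roi_j", "cc"]].reset_index(drop=True) if len(pairs) \
        else pd.DataFrame(columns=["roi_i", "roi_j", "cc"])
    return nodes, edges
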