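"""Binarized-event correlation statistics and FOV summaries."""

import numpy as np
import pandas as pd
import pytest

from astrovasc import network as nw

FOV_180 = 0.0324  # mm^2, a 180 x 180 um field


def _raster_from_rows(rows, bin_rate=2.0, window=(0.0, 60.0)):
    mat = np.asarray(rows, dtype=np.uint8)
    return nw.BinaryRaster(roi_ids=list(range(len(mat))), bin_rate=bin_rate,
                           window=window, matrix=mat)


def _events(rows):
    """Event table with one span per (roi, start, end) triple."""
    return pd.DataFrame(
        [{"roi_id": r, "onset_time": a, "end_time": b,
          "peak_time": (a + b) / 2} for r, a, b in rows],
        columns=["roi_id", "onset_time", "end_time", "peak_time"])


class TestBinarize:
    def test_sample_counts_at_methods_rate(self):
        raster = nw.binarize_events(_events([]), [0], bin_rate=2.0,
                                    window=(0.0, 60.0))
        assert raster.samples_per_roi == 120
        assert raster.samples_per_pair == 240
        assert raster.matrix.sum() == 0

    def test_half_open_binning(self):
        raster = nw.binarize_events(_events([(0, 10.2, 10.7)]), [0],
                                    bin_rate=2.0, window=(0.0, 60.0))
        assert set(np.nonzero(raster.matrix[0])[0]) == {20, 21}

    def test_window_outside_recording_errors(self):
        with pytest.raises(ValueError):
            nw.binarize_events(_events([]), [0], window=(0.0, 60.0),
                               recording_duration=30.0)

    def test_denominator_tracks_rate_and_window(self):
        raster = nw.binarize_events(_events([]), [0], bin_rate=4.0,
                                    window=(0.0, 30.0))
        assert raster.samples_per_pair == 2 * 4 * 30


class TestPairCc:
    def test_identical_rows_unity(self):
        r = _raster_from_rows([[0, 1, 0, 1, 1], [0, 1, 0, 1, 1]])
        assert nw.pair_cc(r, 0, 1) == pytest.approx(1.0)

    def test_complement_rows_minus_one(self):
        a = np.array([0, 1, 0, 1, 1], dtype=np.uint8)
        r = _raster_from_rows([a, 1 - a])
        assert nw.pair_cc(r, 0, 1) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 120).astype(float)
        b = rng.integers(0, 2, 120).astype(float)
        r = _raster_from_rows([a, b])
        manual = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert nw.pair_cc(r, 0, 1) == pytest.approx(manual, abs=1e-12)

    def test_constant_row_raises(self):
        r = _raster_from_rows([[0, 0, 0, 0], [0, 1, 0, 1]])
        with pytest.raises(ValueError):
            nw.pair_cc(r, 0, 1)


class TestWeightedCc:
    def test_printed_denominator_arithmetic(self):
        # cc = 1, 24 event bins across the pair, 240 samples -> wcc = 0.1
        row = np.zeros(120, dtype=np.uint8)
        row[:12] = 1
        r = _raster_from_rows([row, row])
        cc = nw.pair_cc(r, 0, 1)
        assert nw.weighted_cc(cc, r, 0, 1) == pytest.approx(0.1)

    def test_zero_event_bins_zero_wcc(self):
        row = np.zeros(120, dtype=np.uint8)
        row2 = row.copy()
        row2[0] = 1  # keep cc defined for one row only
        r = _raster_from_rows([row2, row2])
        assert nw.weighted_cc(0.0, r, 0, 1) == 0.0

    def test_wcc_never_exceeds_cc_magnitude(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.integers(0, 2, 120).astype(np.uint8)
            b = rng.integers(0, 2, 120).astype(np.uint8)
            r = _raster_from_rows([a, b])
            try:
                cc = nw.pair_cc(r, 0, 1)
            except ValueError:
                continue
            assert abs(nw.weighted_cc(cc, r, 0, 1)) <= abs(cc) + 1e-15

    def test_inclusion_strictly_above_threshold(self):
        def raster_with_n_ones(n):
            row = np.zeros(120, dtype=np.uint8)
            row[:n] = 1
            return _raster_from_rows([row, row])
        # cc = 1 for identical rows; wcc = 2n/240
        below = nw.pair_table(raster_with_n_ones(2))    # wcc = 1/60 < 0.02
        exact = nw.pair_table(raster_with_n_ones(12), wcc_min=0.1)  # = 0.1
        above = nw.pair_table(raster_with_n_ones(3))    # wcc = 0.025
        assert not below["included"].iloc[0]
        assert not exact["included"].iloc[0]  # strict '>'
        assert above["included"].iloc[0]


class TestNetworkSummary:
    def test_one_pair_per_fov_area(self):
        row = np.zeros(120, dtype=np.uint8)
        row[:20] = 1
        pairs = nw.pair_table(_raster_from_rows([row, row]))
        summ = nw.network_summary(pairs, FOV_180)
        assert summ["n_included_pairs"] == 1
        assert summ["coactive_pairs_per_mm2"] == pytest.approx(1 / 0.0324)

    def test_silent_fov_zero_everywhere(self):
        raster = nw.binarize_events(_events([]), [0, 1, 2])
        pairs = nw.pair_table(raster)
        summ = nw.network_summary(pairs, FOV_180)
        assert summ["n_included_pairs"] == 0
        assert summ["coactive_pairs_per_mm2"] == 0.0
        assert not summ["fov_included"]

    def test_density_gate_is_strict(self):
        row = np.zeros(120, dtype=np.uint8)
        row[:20] = 1
        pairs = nw.pair_table(_raster_from_rows([row, row]))
        # 2 correlated ROIs: density exactly 100/mm^2 at area 0.02 -> excluded
        assert not nw.network_summary(pairs, 0.02)["fov_included"]
        assert nw.network_summary(pairs, 0.019)["fov_included"]

    def test_planted_clique_recovered_exactly(self):
        rng = np.random.default_rng(8)
        k, n_other = 4, 5
        clique_row = np.zeros(120, dtype=np.uint8)
        clique_row[rng.choice(120, 15, replace=False)] = 1
        rows = [clique_row.copy() for _ in range(k)]
        for i in range(n_other):
            # independent sparse rows, each active in its own private bins
            r = np.zeros(120, dtype=np.uint8)
            r[100 + i * 4:100 + i * 4 + 2] = 1
            rows.append(r)
        pairs = nw.pair_table(_raster_from_rows(rows))
        included = pairs[pairs["included"]]
        assert len(included) == k * (k - 1) // 2
        assert set(map(tuple, included[["roi_i", "roi_j"]].to_numpy())) == {
            (i, j) for i in range(k) for j in range(i + 1, k)}
        # weighted cc equals hand computation to 1e-12
        for _, p in included.iterrows():
            n_ev = rows[p["roi_i"]].sum() + rows[p["roi_j"]].sum()
            assert p["weighted_cc"] == pytest.approx(
                p["cc"] * n_ev / 240.0, abs=1e-12)


class TestDensitiesAndRates:
    def test_active_roi_density(self):
        events = _events([(0, 5, 6), (1, 8, 9)])
        d = nw.active_roi_density(events, [0, 1, 2, 3], FOV_180)
        assert d == pytest.approx(2 / FOV_180)

    def test_active_density_additivity(self):
        events = _events([(0, 5, 6)])
        d0 = nw.active_roi_density(events, [0, 1], FOV_180)
        events2 = _events([(0, 5, 6), (1, 8, 9)])
        d1 = nw.active_roi_density(events2, [0, 1], FOV_180)
        assert d1 - d0 == pytest.approx(1 / FOV_180)

    def test_oscillation_frequency(self):
        assert nw.oscillation_frequency(_events([]), (0, 10)) == 0.0
        ev2 = _events([(0, 1, 1.5), (0, 5, 5.5)])
        assert nw.oscillation_frequency(ev2, (0, 10)) == pytest.approx(0.2)

    def test_oscillation_matches_counting_oracle(self):
        rng = np.random.default_rng(1)
        rows = [(int(r), float(t), float(t) + 0.3)
                for r, t in zip(rng.integers(0, 4, 50),
                                rng.uniform(0, 60, 50))]
        events = _events(rows)
        win = (10.0, 40.0)
        per_roi = {}
        for r, a, b in rows:
            pk = (a + b) / 2
            if win[0] <= pk < win[1]:
                per_roi[r] = per_roi.get(r, 0) + 1
        oracle = np.mean([c / 30.0 for c in per_roi.values()])
        assert nw.oscillation_frequency(events, win) == pytest.approx(oracle)


class TestCorrelogramExport:
    def test_single_pair_node_weights(self):
        row = np.zeros(120, dtype=np.uint8)
        row[:12] = 1
        pairs = nw.pair_table(_raster_from_rows([row, row]))
        rois = pd.DataFrame({"roi_id": [0, 1, 2]})
        nodes, edges = nw.export_correlogram(pairs[:1], rois)
        w = dict(zip(nodes["roi_id"], nodes["weight"]))
        assert w[0] == pytest.approx(0.1)
        assert w[1] == pytest.approx(0.1)
        assert w[2] == 0.0

    def test_edges_restricted_to_display_range(self):
        pairs = pd.DataFrame({
            "roi_i": [0, 0, 1], "roi_j": [1, 2, 2],
            "cc": [0.9, 0.3, -0.5],
            "weighted_cc": [0.1, 0.05, 0.04],
            "included": [True, True, True]})
        rois = pd.DataFrame({"roi_id": [0, 1, 2]})
        _, edges = nw.export_correlogram(pairs, rois)
        assert len(edges) == 1
        assert edges["cc"].iloc[0] == 0.9

    def test_node_weights_match_row_sums(self):
        rng = np.random.default_rng(6)
        ids = list(range(6))
        rows = []
        for i in ids:
            for j in ids:
                if i < j:
                    rows.append({"roi_i": i, "roi_j": j,
                                 "cc": rng.uniform(-1, 1),
                                 "weighted_cc": rng.uniform(0, 0.2)})
        pairs = pd.DataFrame(rows)
        pairs["included"] = pairs["weighted_cc"] > 0.02
        rois = pd.DataFrame({"roi_id": ids})
        nodes, _ = nw.export_correlogram(pairs, rois)
        for i in ids:
            brute = pairs[((pairs["roi_i"] == i) | (pairs["roi_j"] == i))
                          & pairs["included"]]["weighted_cc"].sum()
            assert nodes.set_index("roi_id")["weight"].loc[i] == \
                pytest.approx(brute)
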