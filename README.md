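# astrovasc

Analysis pipeline for awake two-photon imaging of cortical astrocytes and
microvessels, with companion modules for hippocampal field-potential
recordings and Y-maze behavior. It covers the quantification chain used in
studies of neurovascular coupling under vascular pathology (e.g.
hyperhomocysteinemia models of VCID): astrocyte Ca²⁺ transients and their
network statistics, arteriole dilation responses to whisker stimulation,
capillary red-blood-cell velocimetry, cerebrovessel leakiness, synaptic
strength curves and LTP, and spontaneous alternation scoring.

Because raw imaging and electrophysiology data of this kind are rarely
deposited, the package ships a first-class synthetic-data module
(`astrovasc.simulate`) that generates every input the pipeline consumes
with machine-readable ground truth, so the whole chain is testable end to
end.

## What it computes

- **ROI segmentation** (`segmentation`): astrocyte ROIs from the
  time-averaged movie — local-maximum seeding above `median + s·MAD`,
  seed-relative region growth, and a 600–6000 px footprint filter;
  centroids and pairwise distances in µm.
- **Ca²⁺ events** (`events`): %ΔF/F normalization to a pre-stimulus
  baseline F₀ (`100·(F−F₀)/F₀`), threshold-crossing event detection at
  `baseline mean + k·SD`, and per-event amplitude, 10–90 % rise time and
  half-decay time; transient frequency per ROI and per FOV.
- **Network statistics** (`network`): events binarized at 2 Hz over 60 s
  windows (120 samples per ROI, 240 per pair), Pearson CC per ROI pair,
  the weighted CC `cc · (event samples of the pair) / 240`, coactive-pair
  inclusion at weighted CC > 0.02, correlogram export with the 0.4–1 CC
  display range, and the >100 correlated ROIs/mm² FOV gate.
- **Vessel dynamics** (`vessels`): lumen area per frame (Otsu inside a
  vessel ROI), resting baseline as the mean of the lower fifth percentile
  of the series, maximal dilation as % of that baseline, latency and
  rise/fall slopes, vessel–end-foot peak timing (T2 − T1), rhodamine/EGFP
  leakiness ratios at 0/15/30/45/60 min normalized to the 0-min point, and
  0.5 µm vessel-width histograms with two-sample KS comparison.
- **RBC velocimetry** (`velocimetry`): radon-transform streak-angle
  estimation per 50 ms bin on line-scan kymographs (~2000 Hz over 10 µm),
  750 ms moving-average smoothing, and stimulus-response metrics
  (max change from baseline, time to maximum).
- **Field potentials** (`ephys`): fiber-volley amplitude, EPSP initial
  slope (20–80 % falling phase), population-spike detection, three-
  parameter Boltzmann fits `R(x) = R_max / (1 + e^{(x_half − x)/k})` of the
  FV-vs-stimulus and EPSP-vs-FV curves, EPSP slope at PS threshold, and
  LTP as % of the pre-tetanus baseline over the final 10 min post-tetanus.
- **Behavior** (`behavior`): Y-maze spontaneous alternation,
  `% Alternation = alternations / (entries − 2) × 100` over sliding triads.

## Worked example

```python
import pandas as pd
from astrovasc import simulate as sim, events as ev, network as nw, behavior as bh

# two ROIs with known transients, 2% noise, 10 Hz sampling
cfg = sim.SimConfig(seed=8, duration=120.0, sampling_rate=10.0, noise_sd=0.02)
specs = [
    [sim.TransientSpec(amplitude=0.5, rise_tau=2.0, decay_tau=6.0, onset_time=40.0),
     sim.TransientSpec(amplitude=0.3, rise_tau=1.5, decay_tau=4.0, onset_time=80.0)],
    [sim.TransientSpec(amplitude=0.4, rise_tau=2.0, decay_tau=5.0, onset_time=41.0)],
]
traces, truth = sim.gen_roi_traces(cfg, specs)

tables = []
for k in (0, 1):
    dff = ev.compute_dff(traces[f"roi_{k}"].to_numpy(), (0.0, 30.0), 10.0, roi_id=k)
    tables.append(ev.measure_events(dff, ev.detect_events(dff, k_sd=2.0)))
events = pd.concat(tables, ignore_index=True)
print(events[["roi_id", "peak_time", "amplitude", "rise_time", "decay_time"]].round(2))

raster = nw.binarize_events(events, [0, 1], bin_rate=2.0, window=(30.0, 90.0))
pairs = nw.pair_table(raster)
summary = nw.network_summary(pairs, fov_area=0.0324)  # 180 x 180 um FOV
print(f"coactive pairs per mm^2: {summary['coactive_pairs_per_mm2']:.2f}")

seq, _ = sim.gen_arm_entries(20, 0.8, seed=8)
print("".join(seq), f"-> {bh.percent_alternation(seq):.1f}% alternation")
```

Output:

```
   roi_id  peak_time  amplitude  rise_time  decay_time
0       0       42.9      51.31       1.41        5.47
1       0       81.7      30.23       0.82        4.62
2       1       44.3      37.45       1.15        4.37
coactive pairs per mm^2: 30.86
CCABBCABCABCAABCABCC -> 66.7% alternation
```

The detected amplitudes (51.3, 30.2, 37.4 %ΔF/F) recover the injected
transients (50, 30, 40 %ΔF/F) to within the 2 % sampling noise; the two
co-firing ROIs form one included pair, and one pair in a 0.0324 mm² FOV is
30.86 coactive pairs/mm².

A `click` CLI wraps the same functions: `astrovasc simulate`, `segment`,
`events`, `network`, `vessel`, `velocity`, `ephys`, `behavior` (see
`astrovasc --help`).

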