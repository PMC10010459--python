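# Methods

This note documents the models, estimators, defaults, and numerical choices
behind each module, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Synthetic data (`astrovasc.simulate`)

All generators draw from a single `numpy.random.default_rng(seed)` per
call, so identical seed and parameters give bit-identical output, and every
generator returns the ground truth needed to score the matching analysis
module.

**Ca²⁺ transients.** A transient is the product of exponentials
`(1 − e^{−u/τ_rise}) · e^{−u/τ_decay}` (u = time since onset), peak-
normalized and scaled to the requested fractional amplitude. The product
form was chosen because its two time constants map directly onto the
measured rise and decay times; the peak occurs at
`u* = τ_rise · ln(1 + τ_decay/τ_rise)`, which is returned as ground truth.
Traces are `F₀ · (1 + Σ transients) + N(0, noise_sd · F₀)`. The default
noise (2 % of F₀) is a typical shot-noise-limited two-photon fractional
noise at astrocyte-soma ROI sizes; a Poisson mode is deliberately omitted —
additive Gaussian at these photon counts is indistinguishable in practice.
Default sampling: 10 Hz (the binarization rate downstream is 2 Hz; any
rate ≥ ~5 Hz resolves the simulated kinetics).

**Astrocyte movies.** ROI-scale objects are isotropic Gaussian blobs. The
requested `pixel_area` is the footprint above half maximum, so
`σ = sqrt(area / (2π ln 2))`. Real astrocytes have ramified, anisotropic
morphology; the generator only exercises seeding, growth, and the size
filter, not shape curation.

**Kymographs.** Dark streaks on a bright plasma background with exact
slope `v / (pixel_size · line_rate)` px/line; Gaussian cross-section of
σ = 1 µm, the scale of an RBC shadow edge (sub-pixel-wide streaks produce a
dotted sampling lattice at fast velocities that no real scan shows, and
that biases any angle estimator). Density 0.1 streaks/line. No motion
artifact, no scattering background structure.

**Vessel series.** Lumen cross-sectional area (πr² at the requested
baseline radius) rising exponentially (τ = `rise_s`) toward a plateau of
`1 + dilation/100` during a 10 s stimulation, relaxing exponentially
(τ = `fall_s`) afterwards, with multiplicative Gaussian noise; the
noiseless series, true peak time and true max/baseline ratio are returned.
Negative dilations are allowed and flagged as constriction.

**Field-potential sweeps.** Per stimulus level: a biphasic artifact at
5 ms, a Gaussian fiber volley at 7 ms with amplitude `fv_gain · level`, and
an EPSP whose falling phase is a *straight* segment of slope given by the
Boltzmann sigmoid of the FV amplitude (so the generating slope is exactly
recoverable by a linear fit), followed by exponential recovery. Levels at
or above the PS-threshold level carry a fast Gaussian notch (σ = 0.25 ms,
amplitude 0.4 × EPSP depth) on the recovery phase.

**Arm entries.** After the first two entries, the next arm differs from
both previous arms with probability p, otherwise the previous arm is
repeated. A distinct triad requires two consecutive "alternate" draws, so
the expected alternation fraction is p²; this analytic value is returned
as ground truth and verified by Monte Carlo in the tests.

## ROI segmentation

Seeds are local maxima at least `min_seed_distance` px apart and above
`median + sensitivity·MAD` of the mean image (default sensitivity 8).
Using a robust background spread makes detection invariant to adding a
constant offset. Each seed grows to the 8-connected component above a
*seed-relative* level, `background + growth_frac · (seed − background)`
(default half-maximum); contested pixels go to the nearest seed, ties to
the lower label. The 600–6000 px filter applies to the grown footprint.
Raising the sensitivity can only remove seeds, so the ROI count is
non-increasing in it. The manual morphology curation described for this
kind of data is replaced by an optional eccentricity/solidity filter, off
by default. No motion correction and no activity-based segmentation.

## Ca²⁺ events

%ΔF/F uses the mean over the configured pre-stimulus baseline window as
F₀; a non-positive F₀ raises (dead ROI). Detection: the threshold is
`baseline mean + k·SD` (k = 2 by default) computed on the **raw** %ΔF/F
baseline, applied to a copy smoothed with a 0.5 s moving average (raw
samples at 10 Hz would otherwise fragment a single transient). Events are
supra-threshold excursions with hysteresis — the span extends until the
trace returns below `mean + (k/2)·SD` — lasting at least 0.3 s; within a
span, peaks must be ≥ 1 s apart and have prominence ≥ k·SD. These guards
set the false-event rate on synthetic data to ≪ 1 % of the true count
while keeping sensitivity at 100 % for transients ≥ 5× noise.

Kinetics are measured on the raw trace: amplitude relative to the local
pre-event baseline (1 s before onset; both local and global conventions
are available), rise time between the interpolated 10 % and 90 % crossings
of the ascending limb, decay time from the peak to the interpolated 50 %
crossing; traces ending before the half-decay flag the event censored.
On a linear ramp the rise time is exactly 0.8 of the ramp duration, and on
a pure exponential the decay time is τ·ln 2 — both are asserted to one
sample in the tests. Frequency is events/min per ROI, optionally averaged
over the FOV.

## Network statistics

Events are binarized into half-open bins `[t, t + 1/rate)` at 2 Hz over
60 s windows: 120 samples per ROI, 240 per pair. A bin is 1 iff any part
of an event's supra-threshold span intersects it. The pair statistic is
the Pearson correlation of the two binary rows (the phi coefficient);
constant rows are undefined and the pair is excluded. The weighted CC
multiplies the CC by the pair's event-sample fraction, with "events of the
pair" counted as the total 1-bins across both rows — consistent with the
240-sample denominator; a coincident-bins variant is available behind a
flag. Pairs with weighted CC > 0.02 (strict) count as coactive; distance
summaries average over pairs with CC in the 0.4–1 display range; a FOV is
kept only when the density of ROIs participating in at least one included
pair strictly exceeds 100/mm² (a pair-based gate is available). Baseline /
stimulation / recovery are analyzed as separate 60 s windows whose offsets
are configurable — their exact placement relative to the 10 s air puff is
an acquisition choice, not something the pipeline fixes. Correlogram
export: node weight = Σ weighted CC over included partners, edges carry
the unweighted CC restricted to 0.4–1.

## Vessel dynamics

The per-frame lumen measure is the Otsu-thresholded area within the vessel
ROI (scale-invariant); 2-D frames at 2 Hz are the only data, so area is
the volume proxy and an equivalent-radius mode derives from it. The
resting baseline is the mean of the smallest ⌈0.05 n⌉ values (at least one
sample; n ≥ 20 required) — robust against transient motion-artifact drops.
Maximal dilation is `100 · max(series) / baseline`, so responses read as
% ≥ 100. The raw maximum is upward-biased under noise (the max of ~120
noisy samples sits ~2 SD above the trend); `vessel_response(smooth_s=...)`
optionally pre-smooths with a centered moving average before all
measurements — with a 6.5 s window the mean bias across dilations of
5–40 % at 2 % noise falls below one percentage point, at the cost of ~0.7
points of attenuation on a noiseless 20 % response; the default is
unsmoothed. Kinetics: latency from stimulus onset to the maximum within
the stimulation-plus-30 s window; rise and fall slopes are linear fits
over the 20–80 % amplitude segments flanking the peak, in %-of-baseline/s;
frames > 5 robust SD below baseline are excluded; a peak at the window
edge or a flat response flags the kinetics censored.

End-foot timing reports the signed interval between the end-foot %ΔF/F
peak (T2) and the vessel dilation peak (T1); positive when Ca²⁺ follows
dilation. Leakiness: FOV-mean rhodamine/EGFP per timepoint
(0/15/30/45/60 min), normalized to the 0-min ratio — exactly 1 at t = 0
and invariant to any gain common to both channels. Width histograms use
half-open 0.5 µm bins; distributions are compared with the asymptotic
two-sample KS test (scipy).

## RBC velocimetry

Within each 50 ms bin (≥ 8 lines) the streak angle maximizes the variance
of the radon projection. Numerical choices that matter:

- the block is mean-subtracted and apodized with a 2-D Hann window.
  Without the window, streak segments truncated at block edges bias the
  variance peak by ~0.1°, which at the shallow angles of fast streaks is a
  4–9 % velocity error; with it, worst-bin recovery error over
  0.2–5 mm/s is 1.4 %;
- the objective is symmetrized over the space-flipped block at mirrored
  angles, so mirroring a kymograph negates every velocity exactly;
- a 1° coarse grid over (0°, 180°) is refined by a 0.02° local grid (the
  residual quantization dominates the error budget at 5 mm/s).

Velocity = `cot θ · pixel_size · line_rate`, positive toward increasing
spatial index. Bins with variance contrast (max/mean over the coarse grid)
below 1.5 are flagged low-confidence; angles within 1° of the time axis
are flagged saturated (unresolvably fast). Return-sweep lines of
bidirectional scans are reversed in space unless the input is declared
rectified. The binned trace is smoothed with a centered 750 ms (15-bin)
moving average with edge truncation; response metrics (max change as a
fraction of the pre-stimulus baseline, time to maximum) exclude flagged
bins. No flux counting or per-cell tracking.

## Field potentials

The FV is the baseline-to-trough amplitude of the first negative
deflection 0.5–3 ms after the artifact; deflections within 3× the
pre-artifact noise return 0 with a flag. The EPSP trough is the *first*
local minimum in the 3–15 ms window (the deepest point may be a PS notch),
and the slope is the linear regression over the 20–80 % depth segment of
the falling limb, reported as magnitude in mV/ms. PS detection: the sweep
is smoothed (0.4 ms boxcar), the lagged-difference slope (0.25 ms) is
median-filter detrended (2 ms) to remove the recovery ramp, and a PS is
declared when the detrended slope dips below −4× the robust (MAD) scale of
the analysis region, with a floor of 5 % of the EPSP depth per ms so
noiseless sweeps require a genuine notch. A second-derivative statistic
was rejected: at 20 kHz its noise term scales as √6·σ/Δt² and swamps any
physiological curvature.

Both input-output curves — FV vs stimulus level and EPSP slope vs FV —
are least-squares Boltzmann fits `R_max / (1 + e^{(x_half − x)/k})`,
initialized at 1.1× the observed maximum, the median abscissa, and a
quarter of the abscissa range; non-convergence and all-equal responses are
flagged with raw points still exported. Because the named curve-slope
parameter could mean either the Boltzmann slope factor or the steepest
tangent (`R_max/4k`), both are exported. The PS-threshold EPSP slope is
taken at the lowest level where a PS is detected. LTP: slopes at 0.033 Hz
normalized to the pre-tetanus mean (×100); the LTP level is the mean over
the final 10 min of the post period, a half-open window holding exactly 20
sweeps at 0.033 Hz.

## Behavior

Alternations are counted with an overlapping sliding window of triads
(consistent with the `entries − 2` denominator); consecutive re-entries
are retained. The score is invariant under any relabeling of the three
arms and bounded in [0, 100].

## Problem sizes used in tests and the acceptance script

Event recovery uses 200 traces × 3 transients (120 s at 10 Hz, 2 % noise);
velocimetry uses 500-line kymographs (five 50 ms bins) per velocity;
sigmoid recovery uses 12-level curves with 100 noise replicates; the
alternation and percentile oracles use 1000 random instances. These sizes
give stable statistics for the stated tolerances while keeping the whole
suite fast.

## Limitations

The generators emulate signal structure, not optics: no PSF, no motion
artifacts, no photobleaching, no hemodynamic coupling between modalities.
Passing closed-loop tests therefore demonstrates correctness of the
estimators under the stated signal models, not robustness to every
artifact of real recordings. Group-level inferential statistics are out of
scope by design — the pipeline exports tidy per-unit tables for external
statistical software.
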