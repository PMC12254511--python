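# Methods

## Fluorescence kernel

Fluorescence transients are modeled by the double exponential
h(t) = A·(1 − e^(−t/τr))·e^(−t/τd), t ≥ 0, the standard phenomenological
form for a fast genetically encoded calcium indicator. The indicator is
specified by its measured half-rise (6.6 ms) and post-peak half-decay
(87 ms), not by τr and τd, so `calibrate_kernel` solves for the time
constants numerically: the peak time is analytic
(t* = τr·ln(1 + τd/τr)), each half-time is an exact 1-D root of h, and
alternating bisection on τr (matching half-rise) and τd (matching
half-decay) converges to 0.1% relative tolerance in a few rounds. A is
set so the peak equals 1, making `noise_sd` directly interpretable as
noise relative to a single-spike transient. Calibration failure raises
`KernelCalibrationError` naming the unmet half-time.

## Synthetic fields of view

Each neuron is a pacemaker: inter-spike intervals are gamma-distributed
with mean 1/rate and coefficient of variation `jitter_cv` (default 0.2),
the renewal-process idealization of rhythmic spontaneous firing. Rates
default to uniform 1–5 Hz per neuron, a plausible spontaneous range for
midbrain dopamine neurons; the in-vivo imaging literature for this
preparation does not pin these numbers down, so they are explicit,
documented defaults rather than estimates.

Inter-neuron correlation comes from one mechanism only: each ensemble has
a Poisson process of shared latent events (default 1.0 Hz), and every
member fires one extra spike per event with probability `participation`
(default 0.8), jittered by 20 ms. The default hyperconnected condition
splits the field into two equal ensembles; the control condition has
none. Correlation through shared discrete events (rather than common
Gaussian input) matches the event-driven character of fluorescence data
and yields positively correlated transients, which is what the
positive-edge gating downstream expects.

Rendering convolves each spike train with the kernel at 0.5-ms internal
resolution, bin-averages down to the frame rate (20 fps default,
250 s default duration; upsampling is refused), and adds i.i.d. Gaussian
noise (sd 0.05). ROI centroids are placed uniformly at random in a
250 × 250 µm field, independent of ensemble membership, so any
distance–correlation association in the output is sampling noise. Noise
and centroids draw from a seed stream decoupled from the spike draw;
identical configurations give bit-identical outputs.

What the generator deliberately omits: photobleaching, baseline drift,
movement artifacts, overlapping ROIs, spike-rate adaptation, and any
biophysical (conductance-based) neuron model. Tests passing on this
generator therefore certify the analysis pipeline's correctness on data
satisfying its assumptions, not robustness to those artifacts.

## Traces, events, rasters

Normalization is per neuron (minmax to [0, 1] default; z-score and ΔF/F
with a 10th-percentile baseline available). All downstream network
statistics are rank-based and thus invariant to the choice; constant
traces are flagged, mapped to zeros and retained. Event detection uses a
robust baseline — per-trace median plus `threshold_sd` (default 2.5) ×
1.4826·MAD — because transients skew mean-based baselines; consecutive
supra-threshold frames merge into one event at onset, and a tiny floor on
the robust sd guards noise-free traces against counting convolution
round-off as crossings. Rasters bin event counts into half-open 100-s
intervals with the last partial bin kept (250 s → bins of 100, 100, 50 s).

## Networks

Spearman ρ uses mid-rank ties and Pearson on ranks; p-values default to
the two-sided t approximation t = ρ√((n−2)/(1−ρ²)) with n−2 df, the
behavior of common statistical `corr` routines. Because frames are
autocorrelated (the kernel decay spans several frames), a circular-shift
permutation null is provided as an alternative p-value; it preserves each
trace's autocorrelation while destroying alignment. Gating keeps edges
with p < α (default 0.05, uncorrected; BH optional). The default
`weighted_positive` mode carries ρ as the weight of significant positive
edges — weighted graph measures assume nonnegative weights — with
`binary` and `weighted_signed` modes available since displayed adjacency
matrices are binary while the cited toolbox functions are weighted; both
A and W are always stored. Fields with fewer than four neurons are
excluded (a 4-neuron field is retained). The correlation input is the
full-frame-rate normalized trace, not the 100-s raster: binning serves
raster plotting, and rank correlation of 3 bins would be meaningless.

Degenerate distance-control inputs (constant correlation or distance
vector) report association 0, p 1, flagged degenerate.

## Graph metrics

Normalized degree divides by N (total nodes), not N−1, so the statistic
reads as "connections per neuron in the field"; the N−1 variant is an
option. Weighted clustering uses the Onnela cube-root-product form with
weights rescaled by the network maximum; weighted efficiency maps edge
lengths L = 1/W and runs Dijkstra, with disconnected pairs contributing 0
(the standard convention). Condition comparisons are node-level
two-sample t-tests (pooled variance by default, Welch behind a flag),
reporting means ± SEM (n−1 sd). Treating nodes as the unit of inference
is pseudo-replication with respect to animals; the package reports
node-level statistics because that is the convention it implements, and
per-field aggregates are available from the summary tables for a
conservative reanalysis.

## Electrophysiology

Spike detection: upward crossings of −20 mV with a 2-ms refractory merge
(no criterion is standard for stylized sweeps; this one is robust for the
template used). Half-width is measured at half of (peak − local
baseline), the baseline being the mean of the 10 ms preceding the
threshold crossing, with linear interpolation on both flanks. The
synthetic action potential is a difference-of-exponentials spikelet
(τ_rise = τ_decay/4) time-scaled to a requested half-width.

Challenge resilience divides the 90-s protocol into 30-s baseline, 30-s
hold at −100 mV, and 30-s recovery; spikes during the hold are excluded
and percent change is 100·(f_post − f_pre)/f_pre, undefined (neuron
flagged) when the baseline is silent.

Capacitance: the ramp protocol commands −70 → −80 → −70 mV over
50 + 50 ms. For an RC cell the capacitive current is +Cm·dV/dt on one
limb and −Cm·dV/dt on the other, while leak current depends only on
voltage, so averaging each limb's current over a *voltage-matched*
central band (central 50% of the excursion by default) and subtracting
cancels leak exactly and leaves ΔI = 2·Cm·|dV/dt|. The estimator is
therefore Cm = ΔI/(2·dV/dt). Note the factor 2: applying the bare
formula Cm = ΔI/(dV/dt) to the full rising-minus-falling separation
would return twice the true capacitance of a simulated RC cell — the
convention here is fixed by requiring ground-truth recovery, which the
tests verify to 1% across leak resistances of 100 MΩ, 1 GΩ and ∞.
Voltage-matching the averaging windows (rather than trimming by sample
index) is what makes the leak cancellation exact at finite sampling;
averaging past the access-resistance charging transient keeps a 10-MΩ
series resistance perturbation under 5% (at Rm = 1 GΩ). Sweep input is
CSV (`time,signal[,command]` with a JSON sidecar for protocol
annotations); no binary acquisition formats are read.

## Verification protocol sizes

The study-level checks (in `synconnect.study` and the test suite) use:
hyperconnectivity recovery at the full study conditions (20 neurons,
250 s, 20 fps); null calibration pooled over 50 independent-noise fields
of 15 neurons × 500 frames, compared against the binomial 99% band around
α; the distance control over 20 hyperconnected fields of 30 neurons at
250 s; and resilience power over 10 cohort draws of 10 cells per group.
The distance-control field size (30 neurons, within the 14–46-node range
typical of these fields) is a design choice driven by the null sampling
variability of a rank correlation over N(N−1)/2 pairs: at 20 neurons the
sampling sd of the association (~0.073) leaves substantial null mass
outside |ρ| < 0.1, so a "no association" criterion stated as an absolute
bound needs the larger field to be a sharp test of the generator's
spatial independence rather than of sampling noise.

## Known limitations

- Edge p-values ignore temporal autocorrelation unless the permutation
  option is used; under the default asymptotic p the null edge rate is
  calibrated for exchangeable frames (and verified on white-noise traces).
- The generator's correlation structure is block-like; it does not emulate
  graded spatial falloff, bursting, or cross-condition variance changes.
- Node-level inference pseudo-replicates within fields (above).
- The capacitance estimator assumes a single-compartment RC cell; dendritic
  charge redistribution is outside the model.
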