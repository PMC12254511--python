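"""Synthetic calcium-imaging trace sets and patch-clamp sweeps.

The generator emulates the statistical structure that the downstream
analysis assumes: pacemaker-like dopamine neurons firing jittered-periodic
background spikes, optional neuronal ensembles driven by shared latent
events (the sole source of inter-neuron correlation), fluorescence rendered
by convolving spikes with a calibrated fast-GCaMP kernel, and stylized
current-/voltage-clamp sweeps for the firing, hyperpolarization-challenge
and capacitance-ramp protocols.

Every operation is reproducible from the seed carried in the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "GCaMPKernel",
    "KernelCalibrationError",
    "calibrate_kernel",
    "Ensemble",
    "SimulationConfig",
    "SpikeTrainSet",
    "TraceSet",
    "Sweep",
    "simulate_spikes",
    "render_traces",
    "simulate_traceset",
    "simulate_sweep",
    "default_hyperconnected_ensembles",
    "make_config",
]

# Defaults for the fast GCaMP indicator used in the study conditions:
# half-rise 6.6 ms and half-decay 87 ms.
DEFAULT_HALF_RISE_MS = 6.6
DEFAULT_HALF_DECAY_MS = 87.0


class KernelCalibrationError(RuntimeError):
    """Raised when the kernel time constants cannot be solved for."""


@dataclass(frozen=True)
class GCaMPKernel:
    """Double-exponential fluorescence impulse response.

    h(t) = amplitude * (1 - exp(-t/tau_rise)) * exp(-t/tau_decay), t >= 0

    with ``amplitude`` chosen so the peak equals 1.  Time constants are in
    milliseconds; they are *not* the half-rise/half-decay times themselves
    but are calibrated so the measured half-times match requested values.
    """

    tau_rise: float  # ms
    tau_decay: float  # ms
    amplitude: float = 1.0
    resolution: float = 0.5  # ms, internal sampling step for rendering

    @property
    def t_peak(self) -> float:
        """Time of the kernel maximum (ms), analytic for this family."""
        return self.tau_rise * math.log1p(self.tau_decay / self.tau_rise)

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        out = np.where(
            t >= 0.0,
            self.amplitude
            * (1.0 - np.exp(-np.maximum(t, 0.0) / self.tau_rise))
            * np.exp(-np.maximum(t, 0.0) / self.tau_decay),
            0.0,
        )
        return out

    def support_ms(self, rtol: float = 1e-5) -> float:
        """Duration after which the kernel is below ``rtol`` of its peak."""
        return self.t_peak + self.tau_decay * math.log(1.0 / rtol)

    def sample(self, resolution_ms: float | None = None) -> np.ndarray:
        """Kernel evaluated on a uniform grid covering its support."""
        dt = self.resolution if resolution_ms is None else resolution_ms
        n = int(math.ceil(self.support_ms() / dt)) + 1
        return self.evaluate(np.arange(n) * dt)

    def integral_ms(self) -> float:
        """Analytic integral of h(t) dt in (fluorescence * ms)."""
        # ∫ A (1 - e^{-t/τr}) e^{-t/τd} dt = A [τd - τr τd/(τr+τd)]
        tr, td = self.tau_rise, self.tau_decay
        return self.amplitude * (td - tr * td / (tr + td))

    def measured_half_times(self, grid_ms: float = 0.01) -> tuple[float, float]:
        """Half-rise and post-peak half-decay measured on a dense grid."""
        t = np.arange(0.0, self.support_ms(), grid_ms)
        h = self.evaluate(t)
        peak_idx = int(np.argmax(h))
        half = h[peak_idx] / 2.0
        rise = _interp_crossing(t[: peak_idx + 1], h[: peak_idx + 1], half, rising=True)
        decay_t = _interp_crossing(t[peak_idx:], h[peak_idx:], half, rising=False)
        return rise, decay_t - t[peak_idx]


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    if rising:
        idx = np.nonzero(y >= level)[0]
        if idx.size == 0:
            raise KernelCalibrationError("no rising half-maximum crossing found")
        i = idx[0]
    else:
        idx = np.nonzero(y <= level)[0]
        if idx.size == 0:
            raise KernelCalibrationError("no decaying half-maximum crossing found")
        i = idx[0]
    if i == 0:
        return t[0]
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return t1
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _analytic_half_times(tau_rise: float, tau_decay: float) -> tuple[float, float]:
    """Exact half-rise / half-decay of the unit double exponential."""
    from scipy.optimize import brentq

    t_peak = tau_rise * math.log1p(tau_decay / tau_rise)

    def h(t: float) -> float:
        return (1.0 - math.exp(-t / tau_rise)) * math.exp(-t / tau_decay)

    peak = h(t_peak)
    half = peak / 2.0
    rise = brentq(lambda t: h(t) - half, 1e-12 * tau_rise, t_peak, xtol=1e-12)
    hi = t_peak + 60.0 * tau_decay
    decay = brentq(lambda t: h(t) - half, t_peak, hi, xtol=1e-12)
    return rise, decay - t_peak


def calibrate_kernel(
    half_rise: float = DEFAULT_HALF_RISE_MS,
    half_decay: float = DEFAULT_HALF_DECAY_MS,
    *,
    rtol: float = 1e-3,
    max_rounds: int = 100,
    resolution: float = 0.5,
) -> GCaMPKernel:
    """Solve for double-exponential time constants matching the requested
    half-rise and post-peak half-decay times (both in ms).

    Uses alternating bisection on each half-time to relative tolerance
    ``rtol`` (default 0.1%); the returned kernel is normalized to unit peak.

    Raises
    ------
    KernelCalibrationError
        If either half-time cannot be matched, naming the unmet one.
    """
    if not half_rise > 0:
        raise ValueError("half_rise must be positive")
    if not half_decay > half_rise:
        raise ValueError("half_decay must exceed half_rise")

    # Measured half-rise increases monotonically with tau_rise at fixed
    # tau_decay, and half-decay with tau_decay at fixed tau_rise, so each
    # 1-D solve is a clean bisection; alternate until both match.
    tau_r = half_rise  # starting guesses of the right order
    tau_d = half_decay / math.log(2.0)

    def bisect(fun, lo, hi, target):
        flo, fhi = fun(lo) - target, fun(hi) - target
        grow = 0
        while flo * fhi > 0 and grow < 60:
            lo /= 2.0
            hi *= 2.0
            flo, fhi = fun(lo) - target, fun(hi) - target
            grow += 1
        if flo * fhi > 0:
            return None
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fm = fun(mid) - target
            if abs(fm) <= rtol * 0.1 * target:
                return mid
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
        return 0.5 * (lo + hi)

    for _ in range(max_rounds):
        sol = bisect(lambda tr: _analytic_half_times(tr, tau_d)[0],
                     tau_r / 4, tau_r * 4, half_rise)
        if sol is None:
            raise KernelCalibrationError(
                f"could not match half-rise time {half_rise} ms")
        tau_r = sol
        sol = bisect(lambda td: _analytic_half_times(tau_r, td)[1],
                     tau_d / 4, tau_d * 4, half_decay)
        if sol is None:
            raise KernelCalibrationError(
                f"could not match half-decay time {half_decay} ms")
        tau_d = sol
        hr, hd = _analytic_half_times(tau_r, tau_d)
        if abs(hr - half_rise) <= rtol * half_rise and abs(hd - half_decay) <= rtol * half_decay:
            break
    else:
        hr, hd = _analytic_half_times(tau_r, tau_d)
        if abs(hr - half_rise) > rtol * half_rise:
            raise KernelCalibrationError(
                f"half-rise did not converge: wanted {half_rise} ms, got {hr:.4g} ms")
        raise KernelCalibrationError(
            f"half-decay did not converge: wanted {half_decay} ms, got {hd:.4g} ms")

    t_peak = tau_r * math.log1p(tau_d / tau_r)
    peak = (1.0 - math.exp(-t_peak / tau_r)) * math.exp(-t_peak / tau_d)
    return GCaMPKernel(tau_rise=tau_r, tau_decay=tau_d, amplitude=1.0 / peak,
                       resolution=resolution)


@dataclass(frozen=True)
class Ensemble:
    """A co-active group of neurons sharing latent events.

    members: neuron indices; event_rate: Hz of the shared Poisson event
    process; participation: probability each member fires an extra spike
    per event.
    """

    members: tuple[int, ...]
    event_rate: float  # Hz
    participation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation must lie in [0, 1]")
        if self.event_rate < 0:
            raise ValueError("event_rate must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated field of view (and its seed).

    ``base_rate=None`` draws each neuron's pacemaker rate uniformly from
    1-5 Hz, the plausible spontaneous range for midbrain dopamine neurons;
    a scalar fixes all neurons to that rate.
    """

    seed: int
    n_neurons: int
    duration: float = 250.0  # s
    frame_rate: float = 20.0  # Hz (admissible 20-25)
    base_rate: float | None = None  # Hz; None -> uniform 1-5 per neuron
    jitter_cv: float = 0.2  # CV of inter-spike intervals
    ensemble_spec: tuple[Ensemble, ...] = ()
    kernel: GCaMPKernel | None = None  # None -> default calibrated kernel
    noise_sd: float = 0.05  # fluorescence units (kernel peak = 1)
    field_size: tuple[float, float] = (250.0, 250.0)  # µm
    ensemble_jitter_sd: float = 0.02  # s, spread of member spikes per event
    condition_label: str = "control"
    region_label: str = "SNc"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")
        if self.jitter_cv <= 0:
            raise ValueError("jitter_cv must be positive")
        spec = tuple(self.ensemble_spec)
        object.__setattr__(self, "ensemble_spec", spec)
        for ens in spec:
            if any(m < 0 or m >= self.n_neurons for m in ens.members):
                raise ValueError("ensemble member index out of range")
        active = any(e.participation > 0 and e.event_rate > 0 for e in spec)
        if self.condition_label == "control" and active:
            raise ValueError("control condition must have no active ensembles")
        if self.condition_label == "hyperconnected" and not active:
            raise ValueError("hyperconnected condition needs an active ensemble")


@dataclass
class SpikeTrainSet:
    """Latent ground-truth spike times, one sorted array per neuron (s)."""

    spike_times: list[np.ndarray]
    duration: float
    labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = list(range(len(self.spike_times)))

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.spike_times])


@dataclass
class TraceSet:
    """Neuron-by-frame fluorescence matrix with ROI centroids."""

    traces: np.ndarray  # (n_neurons, n_frames)
    frame_rate: float  # Hz
    centroids: np.ndarray  # (n_neurons, 2) µm
    region_label: str = "SNc"
    condition_label: str = "control"

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (neurons x frames)")
        if np.isnan(self.traces).any():
            raise ValueError("traces contain missing values")
        if self.centroids.shape != (self.traces.shape[0], 2):
            raise ValueError("centroid count must equal trace row count")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class Sweep:
    """A single electrophysiology record with protocol annotations.

    ``signal`` is membrane voltage (mV) in current clamp or membrane
    current (pA) in voltage clamp; ``command`` is the commanded waveform
    (pA or mV) where meaningful.  ``segment_marks`` maps segment names to
    (start_s, end_s) windows.
    """

    time: np.ndarray  # s, uniform
    signal: np.ndarray
    mode: str  # current_clamp | voltage_clamp
    protocol: str
    command: np.ndarray | None = None
    segment_marks: dict[str, tuple[float, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValueError("time and signal must be 1-D and equal length")
        dt = np.diff(self.time)
        if dt.size and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time must be strictly increasing and uniform")
        t0, t1 = self.time[0], self.time[-1]
        # a segment covering the final samples ends one period past t[-1]
        period = float(dt[0]) if dt.size else 0.0
        for name, (a, b) in self.segment_marks.items():
            if a < t0 - 1e-9 or b > t1 + period + 1e-9 or b <= a:
                raise ValueError(f"segment {name!r} outside record")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


def _jittered_periodic_train(rng: np.random.Generator, rate: float,
                             duration: float, cv: float) -> np.ndarray:
    """Gamma-renewal spike train: ISI mean 1/rate, coefficient of variation cv."""
    if rate <= 0:
        return np.empty(0)
    shape = 1.0 / cv**2
    scale = 1.0 / (rate * shape)
    n_guess = int(rate * duration * 1.5) + 20
    t = rng.uniform(0.0, 1.0 / rate)  # random phase
    times = []
    isis = rng.gamma(shape, scale, size=n_guess)
    i = 0
    while t < duration:
        times.append(t)
        if i >= isis.size:
            isis = rng.gamma(shape, scale, size=n_guess)
            i = 0
        t += isis[i]
        i += 1
    return np.asarray(times)


def simulate_spikes(cfg: SimulationConfig) -> SpikeTrainSet:
    """Latent spike trains: jittered-periodic pacemaking plus ensemble events.

    Shared latent events are the sole source of inter-neuron correlation:
    each ensemble's events arrive as a Poisson process and every member
    fires one extra spike per event with its participation probability.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.base_rate is None:
        rates = rng.uniform(1.0, 5.0, size=cfg.n_neurons)
    else:
        rates = np.full(cfg.n_neurons, float(cfg.base_rate))

    trains = [
        _jittered_periodic_train(rng, rates[i], cfg.duration, cfg.jitter_cv)
        for i in range(cfg.n_neurons)
    ]

    for ens in cfg.ensemble_spec:
        n_events = rng.poisson(ens.event_rate * cfg.duration)
        event_times = np.sort(rng.uniform(0.0, cfg.duration, size=n_events))
        for m in ens.members:
            fire = rng.random(n_events) < ens.participation
            extra = event_times[fire] + rng.normal(
                0.0, cfg.ensemble_jitter_sd, size=int(fire.sum()))
            trains[m] = np.concatenate([trains[m], extra])

    out = []
    for t in trains:
        t = np.sort(t[(t >= 0.0) & (t < cfg.duration)])
        # enforce strictly increasing times (duplicates are measure-zero
        # but possible after jitter rounding)
        if t.size > 1:
            keep = np.concatenate([[True], np.diff(t) > 0])
            t = t[keep]
        out.append(t)
    return SpikeTrainSet(spike_times=out, duration=cfg.duration)


def render_traces(spikes: SpikeTrainSet, cfg: SimulationConfig) -> TraceSet:
    """Convolve spikes with the kernel, bin-average to the frame rate,
    add Gaussian noise, and place ROI centroids uniformly at random.

    Centroid placement is independent of ensemble membership, so any
    correlation structure is spatially random by construction.
    """
    kernel = cfg.kernel if cfg.kernel is not None else calibrate_kernel()
    internal_rate_target = 1000.0 / kernel.resolution  # Hz
    oversample = int(round(internal_rate_target / cfg.frame_rate))
    if oversample < 1:
        raise ValueError(
            "frame_rate exceeds the kernel's internal resolution rate; "
            "only downsampling is supported")
    internal_rate = cfg.frame_rate * oversample
    dt_ms = 1000.0 / internal_rate

    n_frames = int(round(cfg.duration * cfg.frame_rate))
    n_internal = n_frames * oversample
    ksamp = kernel.sample(dt_ms)

    traces = np.empty((spikes.n_neurons, n_frames))
    for i, st in enumerate(spikes.spike_times):
        deltas = np.zeros(n_internal)
        if st.size:
            idx = np.minimum((st * internal_rate).astype(int), n_internal - 1)
            np.add.at(deltas, idx, 1.0)
            fine = fftconvolve(deltas, ksamp)[:n_internal]
        else:
            fine = deltas
        traces[i] = fine.reshape(n_frames, oversample).mean(axis=1)

    # Noise and centroids come from a stream decoupled from the spike draw
    # so the same latent activity can be re-rendered reproducibly.
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    if cfg.noise_sd > 0:
        traces = traces + rng.normal(0.0, cfg.noise_sd, size=traces.shape)
    centroids = rng.uniform([0.0, 0.0], list(cfg.field_size),
                            size=(spikes.n_neurons, 2))
    return TraceSet(traces=traces, frame_rate=cfg.frame_rate,
                    centroids=centroids, region_label=cfg.region_label,
                    condition_label=cfg.condition_label)


def simulate_traceset(cfg: SimulationConfig) -> TraceSet:
    """Convenience: simulate spikes then render fluorescence."""
    return render_traces(simulate_spikes(cfg), cfg)


def default_hyperconnected_ensembles(n_neurons: int,
                                     event_rate: float = 1.0,
                                     participation: float = 0.8) -> tuple[Ensemble, ...]:
    """Two ensembles splitting the field in half — the default structure of
    the hyperconnected condition."""
    half = n_neurons // 2
    return (
        Ensemble(members=tuple(range(half)), event_rate=event_rate,
                 participation=participation),
        Ensemble(members=tuple(range(half, n_neurons)), event_rate=event_rate,
                 participation=participation),
    )


def make_config(condition: str, seed: int, n_neurons: int = 20,
                **overrides) -> SimulationConfig:
    """Build a control or hyperconnected configuration with study defaults."""
    if condition == "control":
        spec: tuple[Ensemble, ...] = ()
    elif condition == "hyperconnected":
        spec = default_hyperconnected_ensembles(n_neurons)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return SimulationConfig(seed=seed, n_neurons=n_neurons,
                            ensemble_spec=spec, condition_label=condition,
                            **overrides)


# ---------------------------------------------------------------------------
# Patch-clamp sweep synthesis
# ---------------------------------------------------------------------------

def _ap_template(sample_rate: float, amplitude_mv: float,
                 half_width_ms: float) -> np.ndarray:
    """Biexponential spikelet of given amplitude and half-width.

    Shape g(u) = e^{-u/τd} - e^{-u/τr} with τr = τd/4, time-scaled so the
    width at half of the peak matches ``half_width_ms``.
    """
    # unit shape with tau_d = 1 (arbitrary units), tau_r = 0.25
    tau_d, tau_r = 1.0, 0.25
    u = np.linspace(0.0, 12.0, 4000)
    g = np.exp(-u / tau_d) - np.exp(-u / tau_r)
    peak = g.max()
    half = peak / 2.0
    above = np.nonzero(g >= half)[0]
    unit_hw = u[above[-1]] - u[above[0]]
    scale = (half_width_ms / 1000.0) / unit_hw  # s per unit-u

    dur_s = 12.0 * scale
    n = max(int(round(dur_s * sample_rate)), 3)
    t = np.arange(n) / sample_rate
    uu = t / scale
    g = np.exp(-uu / tau_d) - np.exp(-uu / tau_r)
    return amplitude_mv * g / peak


def _insert_spikes(trace: np.ndarray, times: np.ndarray, template: np.ndarray,
                   sample_rate: float) -> None:
    n = trace.size
    for t in times:
        i0 = int(round(t * sample_rate))
        if i0 >= n:
            continue
        i1 = min(i0 + template.size, n)
        trace[i0:i1] += template[: i1 - i0]


def simulate_sweep(protocol: str, *, seed: int = 0,
                   sample_rate: float = 10_000.0, **params) -> Sweep:
    """Generate a stylized patch-clamp sweep for one of three protocols.

    spontaneous
        30 s (``duration``) of current-clamp pacemaking at ``rate`` Hz with
        templated action potentials on a ``baseline_mv`` resting trace.
    hyperpolarization_challenge
        30 s free firing, 30 s held at −100 mV, 30 s recovery at
        ``rate * recovery_multiplier`` Hz (a multiplier < 1 models impaired
        homeostatic recovery).
    capacitance_ramp
        Voltage-clamp current of an RC cell under a −70→−80→−70 mV command
        (50 ms per limb): I = Cm·dV/dt + (V − v_rest)/Rm, with optional
        series (access) resistance ``rs_mohm`` simulated explicitly.
    """
    rng = np.random.default_rng(seed)

    if protocol == "spontaneous":
        rate = params.pop("rate", 2.0)
        duration = params.pop("duration", 30.0)
        jitter_cv = params.pop("jitter_cv", 0.1)
        baseline = params.pop("baseline_mv", -60.0)
        amp = params.pop("ap_amplitude_mv", 80.0)
        hw = params.pop("ap_half_width_ms", 1.5)
        _reject_unknown(params)
        n = int(round(duration * sample_rate))
        t = np.arange(n) / sample_rate
        v = np.full(n, baseline)
        spikes = _jittered_periodic_train(rng, rate, duration, jitter_cv)
        _insert_spikes(v, spikes, _ap_template(sample_rate, amp, hw), sample_rate)
        return Sweep(time=t, signal=v, mode="current_clamp",
                     protocol="spontaneous",
                     segment_marks={"baseline": (0.0, duration)},
                     meta={"true_spike_times": spikes, "rate": rate})

    if protocol == "hyperpolarization_challenge":
        rate = params.pop("rate", 2.0)
        seg = params.pop("segment_duration", 30.0)
        multiplier = params.pop("recovery_multiplier", 1.0)
        jitter_cv = params.pop("jitter_cv", 0.1)
        baseline = params.pop("baseline_mv", -60.0)
        hold = params.pop("hold_mv", -100.0)
        amp = params.pop("ap_amplitude_mv", 80.0)
        hw = params.pop("ap_half_width_ms", 1.5)
        _reject_unknown(params)
        n = int(round(3 * seg * sample_rate))
        t = np.arange(n) / sample_rate
        v = np.full(n, baseline)
        i_hold0, i_hold1 = int(seg * sample_rate), int(2 * seg * sample_rate)
        v[i_hold0:i_hold1] = hold
        tmpl = _ap_template(sample_rate, amp, hw)
        pre = _jittered_periodic_train(rng, rate, seg, jitter_cv)
        post = _jittered_periodic_train(rng, rate * multiplier, seg, jitter_cv) + 2 * seg
        _insert_spikes(v, pre, tmpl, sample_rate)
        _insert_spikes(v, post, tmpl, sample_rate)
        marks = {"baseline": (0.0, seg), "hyperpolarization": (seg, 2 * seg),
                 "recovery": (2 * seg, 3 * seg)}
        return Sweep(time=t, signal=v, mode="current_clamp",
                     protocol="hyperpolarization_challenge",
                     segment_marks=marks,
                     meta={"pre_spikes": pre, "post_spikes": post,
                           "recovery_multiplier": multiplier})

    if protocol == "capacitance_ramp":
        cm_pf = params.pop("cm_pf", 100.0)
        rm_mohm = params.pop("rm_mohm", math.inf)
        rs_mohm = params.pop("rs_mohm", 0.0)
        v_hold = params.pop("hold_mv", -70.0)
        v_rest = params.pop("v_rest_mv", -70.0)
        dv = params.pop("ramp_dv_mv", -10.0)  # deviation of first limb
        limb_ms = params.pop("limb_ms", 50.0)
        pad_ms = params.pop("pad_ms", 25.0)
        noise_pa = params.pop("noise_pa", 0.0)
        _reject_unknown(params)

        dt = 1.0 / sample_rate
        n_pad = int(round(pad_ms / 1000.0 * sample_rate))
        n_limb = int(round(limb_ms / 1000.0 * sample_rate))
        n = 2 * n_pad + 2 * n_limb
        t = np.arange(n) / sample_rate
        cmd = np.full(n, v_hold)
        a, b, c = n_pad, n_pad + n_limb, n_pad + 2 * n_limb
        cmd[a:b] = v_hold + dv * (np.arange(n_limb) + 1) / n_limb
        cmd[b:c] = v_hold + dv * (n_limb - 1 - np.arange(n_limb)) / n_limb

        cm_F = cm_pf * 1e-12
        gm = 0.0 if math.isinf(rm_mohm) else 1.0 / (rm_mohm * 1e6)
        cmd_V = cmd * 1e-3
        vrest_V = v_rest * 1e-3
        if rs_mohm <= 0:
            dvdt = np.gradient(cmd_V, dt)
            i_A = cm_F * dvdt + (cmd_V - vrest_V) * gm
        else:
            rs = rs_mohm * 1e6
            vm = np.empty(n)
            v0 = cmd_V[0]
            # steady state before the sweep: (Vc - Vm)/Rs = (Vm - Vr) gm
            vm0 = (v0 / rs + vrest_V * gm) / (1.0 / rs + gm)
            vm[0] = vm0
            # exact exponential update per step for the linear RC ODE
            g_tot = 1.0 / rs + gm
            tau = cm_F / g_tot
            decay = math.exp(-dt / tau)
            for k in range(1, n):
                v_inf = (cmd_V[k] / rs + vrest_V * gm) / g_tot
                vm[k] = v_inf + (vm[k - 1] - v_inf) * decay
            i_A = (cmd_V - vm) / rs
        i_pa = i_A * 1e12
        if noise_pa > 0:
            i_pa = i_pa + rng.normal(0.0, noise_pa, size=n)
        marks = {"pre": (0.0, t[a]), "down_limb": (t[a], t[b - 1]),
                 "up_limb": (t[b], t[c - 1])}
        return Sweep(time=t, signal=i_pa, mode="voltage_clamp",
                     protocol="capacitance_ramp", command=cmd,
                     segment_marks=marks,
                     meta={"cm_pf": cm_pf, "rm_mohm": rm_mohm,
                           "rs_mohm": rs_mohm, "ramp_dv_mv": dv,
                           "limb_ms": limb_ms})

    raise ValueError(f"unknown protocol {protocol!r}")


def _reject_unknown(params: dict) -> None:
    if params:
        raise TypeError(f"unknown sweep parameters: {sorted(params)}")
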