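"""Single-neuron electrophysiology statistics.

Spontaneous firing frequency and action-potential half-width from
current-clamp sweeps; resilience to a 30-s hyperpolarization challenge as
the percent change in firing frequency between the baseline and recovery
segments; and membrane capacitance from a voltage-clamp ramp.

The capacitance ramp commands -70 -> -80 -> -70 mV over 50 ms per limb.
The capacitive current reverses sign between limbs while the leak current
is identical at matched voltages, so the rise/fall current separation dI
isolates 2*Cm*dV/dt and the estimator uses Cm = dI / (2*dV/dT).  Averaging
over the central portion of each limb makes the estimate insensitive to
series access resistance, whose charging transient settles early in the
limb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synth import Sweep

__all__ = [
    "SpikeStats",
    "CapacitanceEstimate",
    "detect_spikes",
    "firing_frequency",
    "half_width",
    "challenge_resilience",
    "estimate_capacitance",
]


@dataclass
class SpikeStats:
    """Firing statistics of one current-clamp sweep."""

    spike_times: np.ndarray  # s
    firing_frequency: float  # Hz over the analyzed window
    half_width_ms: float | None = None
    f_pre: float | None = None  # Hz, baseline segment
    f_post: float | None = None  # Hz, recovery segment
    percent_change: float | None = None  # 100*(f_post - f_pre)/f_pre
    flagged: bool = False  # True when percent change is undefined


@dataclass
class CapacitanceEstimate:
    """Membrane capacitance from the voltage-ramp protocol."""

    cm_pf: float
    di_pa: float  # rising-minus-falling current separation
    dv_mv: float  # ramp deviation
    dt_ms: float  # single-limb duration
    central_fraction: float


def detect_spikes(sweep: Sweep, threshold: float = -20.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Spike times as upward crossings of ``threshold`` (mV) separated by
    at least ``refractory_ms``."""
    if sweep.mode != "current_clamp":
        raise ValueError("spike detection requires a current-clamp sweep")
    v = sweep.signal
    above = v > threshold
    crossings = np.nonzero(above & ~np.concatenate([[False], above[:-1]]))[0]
    if crossings.size == 0:
        return np.empty(0)
    times = sweep.time[crossings]
    refr = refractory_ms / 1000.0
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refr:
            kept.append(t)
    return np.asarray(kept)


def firing_frequency(sweep: Sweep, window: tuple[float, float] | None = None,
                     **detect_kwargs) -> float:
    """Spike count / duration (Hz) within ``window`` (default: whole sweep)."""
    spikes = detect_spikes(sweep, **detect_kwargs)
    if window is None:
        window = (sweep.time[0], sweep.time[-1])
    a, b = window
    n = int(np.sum((spikes >= a) & (spikes < b)))
    return n / (b - a)


def _flank_crossing(t: np.ndarray, v: np.ndarray, level: float,
                    peak_idx: int, side: str) -> float | None:
    """Linear-interpolated time where v crosses ``level`` on one flank."""
    if side == "left":
        idx = np.nonzero(v[: peak_idx + 1] < level)[0]
        if idx.size == 0:
            return None
        i = idx[-1]
        if i + 1 > peak_idx:
            return float(t[i])
        t0, t1, v0, v1 = t[i], t[i + 1], v[i], v[i + 1]
    else:
        rel = np.nonzero(v[peak_idx:] < level)[0]
        if rel.size == 0:
            return None
        i = peak_idx + rel[0]
        t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def half_width(sweep: Sweep, spike_time: float, *,
               baseline_window_ms: float = 10.0,
               peak_search_ms: float = 10.0) -> float | None:
    """Action-potential width (ms) at half of (peak - local baseline).

    The local baseline is the mean voltage over ``baseline_window_ms``
    preceding the threshold crossing; flank crossings of the half level
    are located by linear interpolation.  Returns None when the peak does
    not exceed the baseline.
    """
    t, v = sweep.time, sweep.signal
    sr = sweep.sample_rate
    i_cross = int(np.searchsorted(t, spike_time))
    i_cross = min(max(i_cross, 0), t.size - 1)
    i_base0 = max(0, i_cross - int(round(baseline_window_ms / 1000.0 * sr)))
    if i_base0 == i_cross:
        baseline = v[i_cross]
    else:
        baseline = float(v[i_base0:i_cross].mean())
    i_end = min(t.size, i_cross + int(round(peak_search_ms / 1000.0 * sr)) + 1)
    seg = v[i_cross:i_end]
    if seg.size == 0:
        return None
    peak_rel = int(np.argmax(seg))
    peak_idx = i_cross + peak_rel
    peak = v[peak_idx]
    if peak <= baseline:
        return None
    level = baseline + 0.5 * (peak - baseline)
    left = _flank_crossing(t, v, level, peak_idx, "left")
    right = _flank_crossing(t, v, level, peak_idx, "right")
    if left is None or right is None:
        return None
    return (right - left) * 1000.0


def challenge_resilience(sweep: Sweep, **detect_kwargs) -> SpikeStats:
    """Percent change in firing frequency across the hyperpolarization
    challenge: 100 * (f_recovery - f_baseline) / f_baseline.

    Requires segment marks named 'baseline', 'hyperpolarization' and
    'recovery'; spikes inside the hyperpolarized segment are excluded.
    A silent baseline leaves the percent change undefined and flags the
    neuron.
    """
    for name in ("baseline", "hyperpolarization", "recovery"):
        if name not in sweep.segment_marks:
            raise ValueError(f"sweep lacks segment mark {name!r}")
    spikes = detect_spikes(sweep, **detect_kwargs)
    b0, b1 = sweep.segment_marks["baseline"]
    r0, r1 = sweep.segment_marks["recovery"]
    h0, h1 = sweep.segment_marks["hyperpolarization"]
    spikes = spikes[(spikes < h0) | (spikes >= h1)]
    n_pre = int(np.sum((spikes >= b0) & (spikes < b1)))
    n_post = int(np.sum((spikes >= r0) & (spikes < r1)))
    f_pre = n_pre / (b1 - b0)
    f_post = n_post / (r1 - r0)
    if f_pre > 0:
        pct = 100.0 * (f_post - f_pre) / f_pre
        flagged = False
    else:
        pct = None
        flagged = True
    freq = spikes.size / (sweep.time[-1] - sweep.time[0] - (h1 - h0))
    return SpikeStats(spike_times=spikes, firing_frequency=freq,
                      f_pre=f_pre, f_post=f_post, percent_change=pct,
                      flagged=flagged)


def estimate_capacitance(sweep: Sweep, central_fraction: float = 0.5
                         ) -> CapacitanceEstimate:
    """Membrane capacitance from the voltage-clamp ramp.

    Limbs are identified from the sign of the command-voltage slope; the
    current is averaged over the central ``central_fraction`` of each limb
    (leak currents at matched voltages cancel in the subtraction) and
    Cm = dI / (2 * dV/dT) with dI the rising-minus-falling separation.
    """
    if sweep.mode != "voltage_clamp":
        raise ValueError("capacitance estimation requires a voltage-clamp sweep")
    if sweep.command is None:
        raise ValueError("capacitance estimation requires the command waveform")
    if not 0 < central_fraction <= 1:
        raise ValueError("central_fraction must lie in (0, 1]")
    cmd = np.asarray(sweep.command, dtype=float)
    dt = sweep.time[1] - sweep.time[0]
    slope = np.diff(cmd)
    tol = 1e-9
    down = np.nonzero(slope < -tol)[0]
    up = np.nonzero(slope > tol)[0]
    if down.size == 0 or up.size == 0:
        raise ValueError("command waveform has no ramp limbs")

    # central window selected by command voltage so the two limbs are
    # averaged over matched voltages and the leak cancels exactly
    v_ends = [cmd[down[0]], cmd[down[-1] + 1]]
    v_hi, v_lo = max(v_ends), min(v_ends)
    span = v_hi - v_lo
    v_mid = 0.5 * (v_hi + v_lo)
    band = 0.5 * central_fraction * span

    def central(idx: np.ndarray) -> np.ndarray:
        samples = np.arange(idx[0] + 1, idx[-1] + 2)  # samples on the limb
        sel = np.abs(cmd[samples] - v_mid) <= band + 1e-12
        return samples[sel]

    i_down = sweep.signal[central(down)].mean()
    i_up = sweep.signal[central(up)].mean()
    di = float(i_up - i_down)  # pA; capacitive parts are +C dV/dt and -C dV/dt

    dv_mv = float(abs(cmd[down[-1] + 1] - cmd[down[0]]))
    dt_ms = float((down.size) * dt * 1000.0)
    dvdt = (dv_mv * 1e-3) / (dt_ms * 1e-3)  # V/s
    cm_pf = abs(di) / (2.0 * dvdt)  # pA / (V/s) = pF
    return CapacitanceEstimate(cm_pf=cm_pf, di_pa=di, dv_mv=dv_mv,
                               dt_ms=dt_ms, central_fraction=central_fraction)
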