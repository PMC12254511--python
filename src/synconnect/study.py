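"""Study-level verification protocols.

These functions bundle the package's own end-to-end checks at the study
conditions: kernel half-time measurement, the control-vs-hyperconnected
node-degree comparison, null-calibration of the edge rate, the
distance-vs-correlation control, hyperpolarization-resilience cohort
power, and leak-invariance of the capacitance estimator.  They are used
by the verification scripts and tests and are convenient entry points for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ephys import challenge_resilience, estimate_capacitance
from .metrics import compare_conditions, node_degree, GroupComparison
from .network import build_network, distance_control
from .report import group_stats
from .synth import TraceSet, calibrate_kernel, make_config, simulate_sweep, simulate_traceset
from .traces import normalize_traces

__all__ = [
    "measured_kernel_half_times",
    "hyperconnectivity_comparison",
    "null_edge_rate",
    "distance_control_runs",
    "resilience_cohort_comparison",
    "capacitance_leak_sweep",
]


def measured_kernel_half_times(half_rise: float = 6.6, half_decay: float = 87.0,
                               grid_ms: float = 0.01) -> tuple[float, float]:
    """Calibrate the fluorescence kernel and re-measure its half-rise and
    half-decay on a dense grid (the measurement is independent of the
    calibration's internal root solve)."""
    k = calibrate_kernel(half_rise, half_decay)
    return k.measured_half_times(grid_ms=grid_ms)


def hyperconnectivity_comparison(seed: int, n_neurons: int = 20,
                                 duration: float = 250.0,
                                 frame_rate: float = 20.0,
                                 alpha: float = 0.05) -> GroupComparison:
    """Simulate one control and one hyperconnected field at the study
    conditions, run traces -> network -> metrics, and compare node-level
    normalized degree (hyperconnected as group a)."""
    cfg_h = make_config("hyperconnected", seed, n_neurons=n_neurons,
                        duration=duration, frame_rate=frame_rate)
    cfg_c = make_config("control", seed + 1, n_neurons=n_neurons,
                        duration=duration, frame_rate=frame_rate)
    ks = {}
    for label, cfg in (("hyper", cfg_h), ("control", cfg_c)):
        ts = simulate_traceset(cfg)
        net = build_network(normalize_traces(ts), alpha=alpha)
        ks[label] = node_degree(net)[1]
    return compare_conditions(ks["hyper"], ks["control"])


def null_edge_rate(n_fields: int = 50, n_neurons: int = 15,
                   n_frames: int = 500, alpha: float = 0.05,
                   seed: int = 0) -> tuple[float, int]:
    """Empirical p < alpha edge rate over seeded fields of independent
    Gaussian noise traces (two-sided gating so the rate targets alpha).

    Returns (rate, number of pair tests pooled)."""
    root = np.random.SeedSequence(seed)
    edges = trials = 0
    for child in root.spawn(n_fields):
        rng = np.random.default_rng(child)
        x = rng.normal(size=(n_neurons, n_frames))
        ts = TraceSet(traces=x, frame_rate=20.0,
                      centroids=np.zeros((n_neurons, 2)))
        net = build_network(ts, alpha=alpha, mode="weighted_signed")
        iu = np.triu_indices(n_neurons, 1)
        edges += int(net.A[iu].sum())
        trials += iu[0].size
    return edges / trials, trials


def distance_control_runs(n_runs: int = 20, n_neurons: int = 30,
                          duration: float = 250.0, seed: int = 0
                          ) -> list[tuple[float, float]]:
    """Distance-vs-correlation association over seeded hyperconnected
    fields with spatially random ROI placement.

    Returns (association rho, p-value) per run; under the generator's
    spatial independence both should indicate no relationship."""
    out = []
    for r in range(n_runs):
        cfg = make_config("hyperconnected", seed + r, n_neurons=n_neurons,
                          duration=duration)
        ts = simulate_traceset(cfg)
        net = build_network(normalize_traces(ts))
        res = distance_control(net, ts.centroids)
        out.append((res.association_rho, res.p_value))
    return out


def resilience_cohort_comparison(seed: int, n_per_group: int = 10,
                                 impaired_multiplier: float = 0.4,
                                 rate: float = 2.0):
    """Percent-change-in-firing comparison between an impaired cohort
    (recovery rate multiplied by ``impaired_multiplier``) and an intact
    cohort, n cells per group."""
    imp, intact = [], []
    for i in range(n_per_group):
        st = challenge_resilience(simulate_sweep(
            "hyperpolarization_challenge", seed=seed * 10_000 + i,
            rate=rate, recovery_multiplier=impaired_multiplier))
        imp.append(st.percent_change)
        st = challenge_resilience(simulate_sweep(
            "hyperpolarization_challenge", seed=seed * 10_000 + 5000 + i,
            rate=rate, recovery_multiplier=1.0))
        intact.append(st.percent_change)
    return group_stats(imp, intact, test="t_test")


def capacitance_leak_sweep(cm_pf: float = 100.0,
                           rm_mohm: tuple = (100.0, 1000.0, float("inf"))
                           ) -> dict[float, float]:
    """Capacitance estimates across membrane (leak) resistances on the
    -70 -> -80 -> -70 mV, 50 ms + 50 ms ramp; a leak-invariant estimator
    returns the same value for every Rm."""
    return {rm: estimate_capacitance(
        simulate_sweep("capacitance_ramp", cm_pf=cm_pf, rm_mohm=rm)).cm_pf
        for rm in rm_mohm}
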