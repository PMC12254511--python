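"""Readers and writers for trace sets, sweeps, rasters and networks.

Formats: HDF5 (datasets ``traces`` and ``centroids``, attrs ``frame_rate``
and ``condition``) and flat CSV for trace sets; CSV with a
``time,signal[,command]`` header for sweeps; CSV matrices plus
GraphML/GEXF (Gephi-importable) for networks; JSON or YAML key-value
files for configurations.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .network import CorrelationNetwork
from .synth import Sweep, TraceSet
from .traces import Raster

__all__ = [
    "write_traceset_hdf5", "read_traceset_hdf5",
    "write_traceset_csv", "read_traceset_csv",
    "write_sweep_csv", "read_sweep_csv",
    "write_raster_csv", "write_events_csv",
    "write_network_matrices", "network_to_graph",
    "write_network_graphml", "write_network_gexf",
    "load_config_file", "save_config_file",
]


def write_traceset_hdf5(t: TraceSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=t.traces)
        f.create_dataset("centroids", data=t.centroids)
        f.attrs["frame_rate"] = t.frame_rate
        f.attrs["condition"] = t.condition_label
        f.attrs["region"] = t.region_label


def read_traceset_hdf5(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        return TraceSet(
            traces=f["traces"][...],
            centroids=f["centroids"][...],
            frame_rate=float(f.attrs["frame_rate"]),
            condition_label=str(f.attrs.get("condition", "control")),
            region_label=str(f.attrs.get("region", "SNc")),
        )


def write_traceset_csv(t: TraceSet, path) -> None:
    """One row per neuron: x, y centroid then the frame values."""
    n_frames = t.n_frames
    cols = ["x_um", "y_um"] + [f"f{i}" for i in range(n_frames)]
    df = pd.DataFrame(np.hstack([t.centroids, t.traces]), columns=cols)
    df.to_csv(path, index=False)


def read_traceset_csv(path, frame_rate: float = 20.0,
                      condition_label: str = "control",
                      region_label: str = "SNc") -> TraceSet:
    df = pd.read_csv(path)
    centroids = df.iloc[:, :2].to_numpy(dtype=float)
    traces = df.iloc[:, 2:].to_numpy(dtype=float)
    return TraceSet(traces=traces, centroids=centroids, frame_rate=frame_rate,
                    condition_label=condition_label, region_label=region_label)


def write_sweep_csv(s: Sweep, path) -> None:
    data = {"time": s.time, "signal": s.signal}
    if s.command is not None:
        data["command"] = s.command
    pd.DataFrame(data).to_csv(path, index=False)
    meta = {"mode": s.mode, "protocol": s.protocol,
            "segment_marks": {k: list(v) for k, v in s.segment_marks.items()}}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_sweep_csv(path, mode: str | None = None, protocol: str | None = None,
                   segment_marks: dict | None = None) -> Sweep:
    """Read a ``time,signal[,command]`` CSV; protocol annotations come from
    a sidecar ``<path>.json`` when present, else from the arguments."""
    df = pd.read_csv(path)
    sidecar = Path(str(path) + ".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    mode = mode or meta.get("mode", "current_clamp")
    protocol = protocol or meta.get("protocol", "spontaneous")
    marks = segment_marks or {
        k: tuple(v) for k, v in meta.get("segment_marks", {}).items()}
    cmd = df["command"].to_numpy() if "command" in df.columns else None
    return Sweep(time=df["time"].to_numpy(), signal=df["signal"].to_numpy(),
                 mode=mode, protocol=protocol, command=cmd,
                 segment_marks=marks)


def write_raster_csv(r: Raster, path) -> None:
    cols = [f"bin{i}" for i in range(r.n_bins)]
    pd.DataFrame(r.counts, columns=cols).to_csv(path, index_label="neuron")


def write_events_csv(events: list[np.ndarray], path) -> None:
    rows = [(i, t) for i, ev in enumerate(events) for t in ev]
    pd.DataFrame(rows, columns=["neuron", "event_time_s"]).to_csv(path, index=False)


def write_network_matrices(net: CorrelationNetwork, outdir, prefix: str = "network") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, mat in (("rho", net.rho), ("p", net.p), ("A", net.A), ("W", net.W)):
        pd.DataFrame(mat).to_csv(outdir / f"{prefix}_{name}.csv", index=False)


def network_to_graph(net: CorrelationNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(net.n_neurons))
    n = net.n_neurons
    for i in range(n):
        for j in range(i + 1, n):
            if net.A[i, j]:
                g.add_edge(i, j, weight=float(net.W[i, j]),
                           rho=float(net.rho[i, j]), p=float(net.p[i, j]))
    return g


def write_network_graphml(net: CorrelationNetwork, path) -> None:
    nx.write_graphml(network_to_graph(net), path)


def write_network_gexf(net: CorrelationNetwork, path) -> None:
    nx.write_gexf(network_to_graph(net), path)


def load_config_file(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config_file(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg))
    else:
        path.write_text(json.dumps(cfg, indent=1))
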