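"""Persistence: spike tables, LFP movies, synapse tables, run manifests.

Array containers are numpy ``.npz`` files with named datasets plus a JSON
header dataset carrying the generating configuration, format version and
seed, so a round trip restores both data and provenance.  Summary tables
are written as delimited text.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .dynamics import PooledTraces, SpikeEvents
from .lfp import LFPMovie
from .topology import SynapseTable

__all__ = [
    "save_spikes", "load_spikes", "save_movie", "load_movie",
    "save_synapses", "load_synapses", "save_traces", "load_traces",
    "RunManifest", "file_sha256",
]

FORMAT_VERSION = 1


class FormatError(RuntimeError):
    pass


def _header(kind: str, **meta) -> np.ndarray:
    payload = {"format_version": FORMAT_VERSION, "kind": kind, **meta}
    return np.frombuffer(json.dumps(payload, default=str).encode(), dtype=np.uint8)


def _read_header(z, kind: str) -> dict:
    if "header" not in z:
        raise FormatError("missing header dataset")
    try:
        hdr = json.loads(bytes(z["header"].tobytes()).decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as e:
        raise FormatError(f"corrupted header: {e}") from e
    if hdr.get("format_version") != FORMAT_VERSION:
        raise FormatError(f"format version mismatch: {hdr.get('format_version')}")
    if hdr.get("kind") != kind:
        raise FormatError(f"expected kind {kind!r}, found {hdr.get('kind')!r}")
    return hdr


def save_spikes(path, spikes: SpikeEvents, **meta) -> None:
    np.savez_compressed(
        path, header=_header("spikes", duration=spikes.duration,
                             n_neurons=spikes.n_neurons, **meta),
        neuron=spikes.neuron.astype(np.int32), t_ms=spikes.t_ms)


def load_spikes(path) -> SpikeEvents:
    with np.load(path) as z:
        hdr = _read_header(z, "spikes")
        return SpikeEvents(neuron=z["neuron"], t_ms=z["t_ms"],
                           duration=float(hdr["duration"]),
                           n_neurons=int(hdr["n_neurons"]))


def save_movie(path, movie: LFPMovie, **meta) -> None:
    np.savez_compressed(
        path,
        header=_header("lfp-movie", pitch_mm=movie.pitch_mm, fs=movie.fs,
                       t0_ms=movie.t0_ms, meta=movie.meta, **meta),
        data=movie.data, valid=movie.valid_mask())


def load_movie(path) -> LFPMovie:
    with np.load(path) as z:
        hdr = _read_header(z, "lfp-movie")
        return LFPMovie(data=z["data"], pitch_mm=float(hdr["pitch_mm"]),
                        t0_ms=float(hdr["t0_ms"]), fs=float(hdr["fs"]),
                        valid=z["valid"], meta=hdr.get("meta", {}))


def save_traces(path, traces: PooledTraces, **meta) -> None:
    np.savez_compressed(
        path,
        header=_header("pooled-traces", t0_ms=traces.t0_ms,
                       grid_shape=list(traces.grid_shape),
                       pool_size=traces.pool_size, **meta),
        sum_ge=traces.sum_ge, sum_gi=traces.sum_gi, mean_V=traces.mean_V,
        spike_counts=traces.spike_counts)


def load_traces(path) -> PooledTraces:
    with np.load(path) as z:
        hdr = _read_header(z, "pooled-traces")
        return PooledTraces(sum_ge=z["sum_ge"], sum_gi=z["sum_gi"],
                            mean_V=z["mean_V"],
                            spike_counts=z["spike_counts"],
                            t0_ms=float(hdr["t0_ms"]),
                            grid_shape=tuple(hdr["grid_shape"]),
                            pool_size=int(hdr["pool_size"]))


def save_synapses(path, table: SynapseTable, **meta) -> None:
    arrays = dict(targets=table.targets, delay_steps=table.delay_steps)
    if table.vc_draw is not None:
        arrays["vc_draw"] = table.vc_draw
    np.savez_compressed(
        path, header=_header("synapses", Ne=table.Ne, dt=table.dt, **meta),
        **arrays)


def load_synapses(path) -> SynapseTable:
    with np.load(path) as z:
        hdr = _read_header(z, "synapses")
        return SynapseTable(targets=z["targets"],
                            delay_steps=z["delay_steps"],
                            Ne=int(hdr["Ne"]), dt=float(hdr["dt"]),
                            vc_draw=z["vc_draw"] if "vc_draw" in z else None)


# ---------------------------------------------------------------------------


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record for one pipeline invocation."""

    config: dict
    seed: int
    stages: dict = dataclasses.field(default_factory=dict)
    flags: list = dataclasses.field(default_factory=list)
    version: str = "sparsewave-0.1.0"

    def record(self, stage: str, path) -> None:
        self.stages.setdefault(stage, {})[str(Path(path).name)] = \
            file_sha256(path)

    def warn(self, message: str) -> None:
        self.flags.append(message)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(config=raw["config"], seed=raw["seed"],
                   stages=raw.get("stages", {}), flags=raw.get("flags", []),
                   version=raw.get("version", "unknown"))
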