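"""Shared fixtures: small networks and reusable simulation runs.

Heavy objects are session-scoped so the whole suite pays for each
simulation once.
"""

from __future__ import annotations

import numpy as np
import pytest

from sparsewave.config import (ConnectivityConfig, GeometryConfig,
                               NetworkConfig, NeuronParams, SimConfig,
                               substream)
from sparsewave.topology import build_synapse_table, place_neurons


@pytest.fixture(scope="session")
def tiny_geometry() -> GeometryConfig:
    """400 E + 100 I on concentric grids — smallest pool-compatible sheet."""
    return GeometryConfig(L=0.5, Ne=400, Ni=100, dims=2)


@pytest.fixture(scope="session")
def tiny_net(tiny_geometry):
    """Positions + synapse table of a small topographic delayed network."""
    params = NeuronParams()
    conn = ConnectivityConfig(K=40, kind="gaussian", sigma=0.1, vc=0.2)
    rng = substream(7, "topology:test")
    pos = place_neurons(tiny_geometry)
    table = build_synapse_table(tiny_geometry, conn, params, 0.1, rng, pos)
    return pos, table, params, conn


def small_sustained_config() -> NetworkConfig:
    """A ~4.5k-neuron random network that self-sustains (dense synapses).

    Geometry divisible into 10x10 pools so the full LFP pipeline runs.
    """
    return NetworkConfig(
        geometry=GeometryConfig(L=0.4, Ne=3600, Ni=900, dims=2),
        neurons=NeuronParams(),
        connectivity=ConnectivityConfig(K=80, kind="uniform", vc=None),
        sim=SimConfig(duration=1200.0, discard=200.0, Ge=1.0, Gi=12.0,
                      rate_guard=100.0),
        name="test-sustained",
    )


@pytest.fixture(scope="session")
def sustained_run():
    """One spontaneous run of the small self-sustained network."""
    from sparsewave.experiments import run_network
    run = run_network(small_sustained_config(), seed=3, settle_ms=600.0)
    assert run.moments.self_sustained
    assert run.result.spikes.mean_rate(*run.analysis_window) > 1.0
    return run


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
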