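"""Composite experiments: build-and-run helpers, E/I conductance scans,
network-size series, and the phase-aligned gain-modulation experiment.

The gain experiment replays a spontaneous run deterministically (identical
seed and initial state), snapshots the full dynamical state whenever the
target region's generalized phase enters the depolarized or hyperpolarized
phase bin, and branches a short stimulated continuation from each snapshot.
Evoked and baseline responses therefore share history exactly up to
stimulus onset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import spikestats, waves
from .config import (NetworkConfig, connections_for_size, geometry_for_size,
                     substream)
from .dynamics import (Moments, NeuronState, RunResult, bootstrap_moments,
                       init_from_moments, inject_poisson, run_simulation)
from .lfp import LFPMovie, PoolGrid, compute_lfp
from .topology import SynapseTable, build_synapse_table, place_neurons
from .waves import AnalyticField

__all__ = [
    "NetworkRun", "ScanResult", "GainResult",
    "build_network", "run_network", "conductance_scan",
    "phase_aligned_stimulus", "size_series",
]


@dataclass
class NetworkRun:
    """A built network together with one spontaneous run and its LFP."""

    cfg: NetworkConfig
    seed: int
    positions: np.ndarray
    table: SynapseTable
    pools: PoolGrid
    moments: Moments
    result: RunResult
    lfp: LFPMovie
    _field: AnalyticField | None = None

    @property
    def field(self) -> AnalyticField:
        if self._field is None:
            self._field = waves.generalized_phase(self.lfp)
        return self._field

    @property
    def analysis_window(self) -> tuple[float, float]:
        return (self.cfg.sim.discard, self.cfg.sim.duration)


def build_network(cfg: NetworkConfig, seed: int):
    """Positions, synapse table and pool grid for a configuration.

    Topology randomness comes from the 'topology' substream of ``seed``.
    """
    rng = substream(seed, f"topology:{cfg.name}")
    positions = place_neurons(cfg.geometry)
    table = build_synapse_table(cfg.geometry, cfg.connectivity, cfg.neurons,
                                cfg.sim.dt, rng, positions)
    pools = PoolGrid.from_geometry(cfg.geometry)
    return positions, table, pools


def run_network(cfg: NetworkConfig, seed: int, *,
                settle_ms: float = 1000.0,
                checkpoint_steps: list[int] | None = None,
                prebuilt=None) -> NetworkRun:
    """Bootstrap, initialize and run one network; attach the LFP movie.

    The steady state is found once per configuration via a kicked settling
    run and memoized; production runs start from Gaussian draws of those
    moments (V clipped into (Ei, VT)).
    """
    if prebuilt is None:
        positions, table, pools = build_network(cfg, seed)
    else:
        positions, table, pools = prebuilt
    boot_rng = substream(seed, f"bootstrap:{cfg.name}")
    moments = bootstrap_moments(
        cfg.neurons, table, cfg.sim, boot_rng, settle_ms=settle_ms,
        cache_key=(cfg.content_hash(), seed))
    init_rng = substream(seed, f"init:{cfg.name}")
    if moments.self_sustained:
        state = init_from_moments(moments, table.N, cfg.neurons, init_rng)
    else:  # fall back to a kicked start so the run still reports something
        state = NeuronState.resting(table.N, cfg.neurons)
    result = run_simulation(cfg.neurons, table, cfg.sim, state,
                            pool_idx=pools.pool_idx, grid_shape=pools.shape,
                            pool_size=pools.m,
                            checkpoint_steps=checkpoint_steps)
    movie = compute_lfp(result.traces, cfg.neurons, pitch_mm=pools.pitch_mm)
    # analysis excludes the initialization transient
    discard_samples = int(round(cfg.sim.discard * movie.fs / 1000.0))
    valid = movie.valid_mask().copy()
    valid[:discard_samples] = False
    movie.valid = valid
    return NetworkRun(cfg=cfg, seed=seed, positions=positions, table=table,
                      pools=pools, moments=moments, result=result, lfp=movie)


# ---------------------------------------------------------------------------
# Conductance scans


@dataclass
class ScanResult:
    ge_values: np.ndarray
    gi_values: np.ndarray
    mean_rate: np.ndarray          # (n_ge, n_gi)
    mean_cv: np.ndarray
    self_sustained: np.ndarray     # bool
    asynchronous_irregular: np.ndarray
    early_exit: np.ndarray
    wave_fraction: np.ndarray      # NaN where not analyzed
    mean_wavelength: np.ndarray
    spike_phase_index: np.ndarray
    failures: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.ge_values), len(self.gi_values))


def _scan_cell(cfg: NetworkConfig, prebuilt, seed: int, *,
               analyze_waves: bool, n_shuffles: int, time_stride: int):
    """One kicked simulation at a single (Ge, Gi); returns a result record.

    Scan cells start from rest with a brief Poisson kick (rather than a
    per-cell moment bootstrap): cells that cannot self-sustain simply die
    after the kick, which is exactly the classification sought.
    """
    positions, table, pools = prebuilt
    rng = substream(seed, f"kick:{cfg.name}:{cfg.sim.Ge}:{cfg.sim.Gi}")
    state = NeuronState.resting(table.N, cfg.neurons)
    ext = inject_poisson(np.arange(table.N), 2.0, 100, 100.0, 0.0,
                         cfg.sim.Ge, cfg.sim.dt, rng)
    res = run_simulation(cfg.neurons, table, cfg.sim, state,
                         pool_idx=pools.pool_idx, grid_shape=pools.shape,
                         pool_size=pools.m, ext_events=ext)
    window = (cfg.sim.discard, min(cfg.sim.duration,
                                   (res.exit_step + 1) * cfg.sim.dt))
    rec = {"early_exit": res.early_exit, "rate": np.nan, "cv": np.nan,
           "self_sustained": False, "ai": False, "wave_fraction": np.nan,
           "mean_wavelength": np.nan, "spi": np.nan}
    if window[1] <= window[0]:
        return rec
    srng = substream(seed, "scan-sample")
    summary = spikestats.summarize_trains(res.spikes, window, rng=srng)
    label = spikestats.classify_regime(summary, res.spikes,
                                       early_exit=res.early_exit)
    rec.update(rate=summary.mean_rate, cv=summary.mean_cv,
               self_sustained=label.self_sustained,
               ai=label.asynchronous_irregular)
    if analyze_waves and label.self_sustained and not res.early_exit:
        movie = compute_lfp(res.traces, cfg.neurons, pitch_mm=pools.pitch_mm)
        valid = movie.valid_mask().copy()
        valid[:int(round(window[0]))] = False
        movie.valid = valid
        wm = waves.shuffle_significance(
            movie, n_shuffles=n_shuffles, rng=substream(seed, "scan-shuffle"),
            periodic=True, time_stride=time_stride)
        rec["wave_fraction"] = wm.fraction()
        sig = wm.observed[wm.mask]
        rec["mean_wavelength"] = float(sig.mean()) if sig.size else np.nan
        fld = waves.generalized_phase(movie)
        pc = spikestats.spike_phase_coupling(
            res.spikes, fld, pools.pool_idx, t_offset_ms=movie.t0_ms)
        rec["spi"] = pc.index
    return rec


def conductance_scan(base: NetworkConfig, ge_values, gi_values, seed: int, *,
                     analyze_waves: bool = True, n_shuffles: int = 20,
                     time_stride: int = 5,
                     progress=None) -> ScanResult:
    """Grid of simulations over excitatory/inhibitory synaptic weights.

    The network topology is built once (it does not depend on the weights);
    each cell runs an independent kicked simulation whose seed derives from
    the master seed and the cell coordinates, so execution order cannot
    change results.  Per-cell failures are recorded and the scan continues.
    """
    ge_values = np.asarray(list(ge_values), dtype=float)
    gi_values = np.asarray(list(gi_values), dtype=float)
    if ge_values.size == 0 or gi_values.size == 0:
        raise ValueError("value lists must be nonempty")
    prebuilt = build_network(base, seed)
    shape = (ge_values.size, gi_values.size)
    grids = {k: np.full(shape, np.nan) for k in
             ("rate", "cv", "wave_fraction", "mean_wavelength", "spi")}
    flags = {k: np.zeros(shape, dtype=bool) for k in
             ("self_sustained", "ai", "early_exit")}
    failures = []
    for a, ge in enumerate(ge_values):
        for b, gi in enumerate(gi_values):
            cfg = dataclasses.replace(
                base, sim=dataclasses.replace(base.sim, Ge=float(ge),
                                              Gi=float(gi)))
            cell_seed = int(substream(seed, f"cell:{a}:{b}").integers(2 ** 31))
            try:
                rec = _scan_cell(cfg, prebuilt, cell_seed,
                                 analyze_waves=analyze_waves,
                                 n_shuffles=n_shuffles,
                                 time_stride=time_stride)
            except Exception as e:  # record and continue
                failures.append(((a, b), repr(e)))
                continue
            for k in grids:
                key = {"rate": "rate", "cv": "cv",
                       "wave_fraction": "wave_fraction",
                       "mean_wavelength": "mean_wavelength", "spi": "spi"}[k]
                grids[k][a, b] = rec[key]
            for k in flags:
                flags[k][a, b] = rec[{"self_sustained": "self_sustained",
                                      "ai": "ai",
                                      "early_exit": "early_exit"}[k]]
            if progress is not None:
                progress(a, b, rec)
    return ScanResult(ge_values=ge_values, gi_values=gi_values,
                      mean_rate=grids["rate"], mean_cv=grids["cv"],
                      self_sustained=flags["self_sustained"],
                      asynchronous_irregular=flags["ai"],
                      early_exit=flags["early_exit"],
                      wave_fraction=grids["wave_fraction"],
                      mean_wavelength=grids["mean_wavelength"],
                      spike_phase_index=grids["spi"],
                      failures=failures)


def size_series(base: NetworkConfig, sizes_mm, ge_values, gi_values,
                seed: int, **scan_kwargs) -> dict[float, ScanResult]:
    """Conductance scans repeated across network sizes at fixed density.

    The out-degree follows the coverage rule (grows with area up to the
    2 mm saturation size).
    """
    out: dict[float, ScanResult] = {}
    for L in sizes_mm:
        geom = geometry_for_size(float(L), margin=base.geometry.margin
                                 if base.geometry.margin < L / 2 else 0.0)
        conn = dataclasses.replace(base.connectivity,
                                   K=connections_for_size(float(L)))
        cfg = dataclasses.replace(base, geometry=geom, connectivity=conn,
                                  name=f"{base.name}-{L}mm")
        out[float(L)] = conductance_scan(cfg, ge_values, gi_values, seed,
                                         **scan_kwargs)
    return out


# ---------------------------------------------------------------------------
# Phase-aligned stimulation


@dataclass
class GainResult:
    condition: str
    gains: np.ndarray         # per completed trial
    evoked: np.ndarray        # summed spike counts in the response window
    baseline: np.ndarray
    onsets_ms: np.ndarray
    n_requested: int
    n_skipped: int
    depol_bin: int
    hyper_bin: int

    @property
    def mean_gain(self) -> float:
        return float(self.gains.mean()) if self.gains.size else float("nan")


def _region_neurons(run: NetworkRun, half_mm: float = 0.1) -> np.ndarray:
    """Excitatory neurons within a square region at the sheet centre."""
    c = run.cfg.geometry.L / 2.0
    pos = run.positions[:run.cfg.geometry.Ne]
    inside = (np.abs(pos[:, 0] - c) < half_mm) & (np.abs(pos[:, 1] - c) < half_mm)
    return np.flatnonzero(inside)


def _center_pool(run: NetworkRun) -> int:
    ny, nx = run.pools.shape
    return (ny // 2) * nx + nx // 2


def phase_aligned_stimulus(run: NetworkRun, condition: str, *,
                           n_trials: int = 40, stim_rate_hz: float = 20.0,
                           stim_nsyn: int = 100, stim_duration_ms: float = 10.0,
                           window_ms: float = 30.0,
                           stim_weight: float | None = None,
                           min_separation_ms: float = 40.0,
                           nbins: int = 10) -> GainResult:
    """Gain of responses to input arriving at a chosen network phase.

    ``condition`` is ``"depolarized"`` (stimulus onset when the target
    region's GP enters the phase bin where spontaneous spiking is most
    probable), ``"hyperpolarized"`` (least probable bin) or ``"none"``
    (onsets at fixed intervals, phase-blind).  Per trial the spontaneous
    run is replayed bit-identically to the onset, a 10 ms Poisson
    bombardment is applied to every neuron in the 0.2 x 0.2 mm^2 target
    region, and the gain is the summed region spike count in the response
    window divided by the matching count of the undisturbed run.  Trials
    whose condition phase never occurs, or whose baseline window is silent,
    are skipped and reported.
    """
    if condition not in ("depolarized", "hyperpolarized", "none"):
        raise ValueError(f"unknown condition {condition!r}")
    cfg = run.cfg
    dt = cfg.sim.dt
    fld = run.field
    pool = _center_pool(run)
    pool_phi = np.angle(
        fld.Lambda.reshape(-1, fld.Lambda.shape[-1])[pool])

    # spontaneous spike-phase preference of the whole network
    pc = spikestats.spike_phase_coupling(run.result.spikes, fld,
                                         run.pools.pool_idx, nbins=nbins,
                                         t_offset_ms=run.lfp.t0_ms)
    occ, _ = np.histogram(np.angle(fld.Lambda[:, :, fld.valid]).ravel(),
                          bins=pc.bin_edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        prob = np.where(occ > 0, pc.hist / np.maximum(occ, 1), np.nan)
    depol_bin = int(np.nanargmax(prob))
    hyper_bin = int(np.nanargmin(prob))
    edges = pc.bin_edges

    t_ms = run.lfp.t0_ms + np.arange(pool_phi.size) * 1000.0 / fld.fs
    usable = fld.valid & (t_ms >= cfg.sim.discard) & \
        (t_ms <= cfg.sim.duration - window_ms)

    if condition == "none":
        cand = t_ms[usable][:: max(1, usable.sum() // max(n_trials, 1))]
        onsets = cand[:n_trials]
    else:
        b = depol_bin if condition == "depolarized" else hyper_bin
        inbin = (pool_phi >= edges[b]) & (pool_phi < edges[b + 1]) & usable
        entries = np.flatnonzero(inbin & ~np.roll(inbin, 1))
        onsets = []
        last = -np.inf
        for k in entries:
            if t_ms[k] - last >= min_separation_ms:
                onsets.append(t_ms[k])
                last = t_ms[k]
            if len(onsets) == n_trials:
                break
        onsets = np.asarray(onsets)

    region = _region_neurons(run)
    weight = cfg.sim.Ge if stim_weight is None else stim_weight
    onset_steps = sorted(int(round(o / dt)) for o in onsets)

    # deterministic replay capturing state snapshots at the onsets
    init_rng = substream(run.seed, f"init:{cfg.name}")
    if run.moments.self_sustained:
        state0 = init_from_moments(run.moments, run.table.N, cfg.neurons,
                                   init_rng)
    else:
        state0 = NeuronState.resting(run.table.N, cfg.neurons)
    replay = run_simulation(cfg.neurons, run.table, cfg.sim, state0,
                            checkpoint_steps=onset_steps)
    assert len(replay.spikes) == len(run.result.spikes), \
        "replay diverged from the recorded spontaneous run"

    spikes0 = run.result.spikes
    window_steps = int(round(window_ms / dt))
    gains, evoked_l, base_l, used = [], [], [], []
    n_skipped = n_trials - len(onsets)
    for onset, st in zip(sorted(onsets), replay.checkpoints):
        srng = substream(run.seed, f"stim:{condition}:{onset:.1f}")
        ext = inject_poisson(region, stim_rate_hz, stim_nsyn,
                             stim_duration_ms, onset, weight, dt, srng)
        branch = run_simulation(cfg.neurons, run.table, cfg.sim, st,
                                ext_events=ext, n_steps=window_steps,
                                spike_cap_rate=2000.0)
        t1 = onset + window_ms
        ev = branch.spikes
        evoked = int(np.count_nonzero(
            np.isin(ev.neuron, region) & (ev.t_ms >= onset) & (ev.t_ms < t1)))
        base_ev = spikes0.in_window(onset, t1)
        base = int(np.count_nonzero(np.isin(base_ev.neuron, region)))
        if base == 0:
            n_skipped += 1
            continue
        gains.append(evoked / base)
        evoked_l.append(evoked)
        base_l.append(base)
        used.append(onset)
    return GainResult(condition=condition, gains=np.asarray(gains),
                      evoked=np.asarray(evoked_l),
                      baseline=np.asarray(base_l),
                      onsets_ms=np.asarray(used), n_requested=n_trials,
                      n_skipped=n_skipped, depol_bin=depol_bin,
                      hyper_bin=hyper_bin)
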