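"""Forward-Euler integration of the delayed conductance-based LIF network.

The membrane potential of each neuron follows

    Cm dV/dt = GL (EL - V) + ge (Ee - V) + gi (Ei - V) + I_ext

with exponentially decaying synaptic conductances, tau dg/dt = -g.  When V
crosses threshold VT the neuron resets to Vr, holds there for the refractory
period tau_r, and each of its K targets receives a conductance increment
(Ge or Gi according to the presynaptic population) after the connection's
conduction delay.  Delayed deliveries are exact at step resolution: an
increment scheduled for step n is applied at step n through a ring buffer of
per-step accumulators.

Within each step the update order is fixed: due increments are applied,
conductances decay, membrane potentials advance (refractory neurons stay
clamped at Vr), and threshold crossings are registered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import NeuronParams, SimConfig
from .topology import SynapseTable

__all__ = [
    "NeuronState",
    "SpikeEvents",
    "PooledTraces",
    "RunResult",
    "Moments",
    "run_simulation",
    "bootstrap_moments",
    "init_from_moments",
    "inject_poisson",
    "lif_rate_analytic",
]

EXIT_OK = 0
EXIT_RATE_GUARD = 1
EXIT_SPIKE_CAP = 2
EXIT_NAN = -1

_RATE_WINDOW_MS = 100  # sliding window for the early-exit rate guard


@dataclass
class NeuronState:
    """Full dynamical state at one step (plus the pending-event buffer)."""

    V: np.ndarray           # (N,) mV
    ge: np.ndarray          # (N,) nS
    gi: np.ndarray          # (N,) nS
    refr_until: np.ndarray  # (N,) step index until which V is clamped
    step: int = 0           # current global step
    buffer: np.ndarray | None = None  # (n_slots, N, 2) float32 ring

    def copy(self) -> "NeuronState":
        return NeuronState(self.V.copy(), self.ge.copy(), self.gi.copy(),
                           self.refr_until.copy(), self.step,
                           None if self.buffer is None else self.buffer.copy())

    @classmethod
    def resting(cls, N: int, params: NeuronParams) -> "NeuronState":
        return cls(V=np.full(N, params.EL), ge=np.zeros(N), gi=np.zeros(N),
                   refr_until=np.zeros(N, dtype=np.int64))


@dataclass
class SpikeEvents:
    """Columnar, time-sorted spike record."""

    neuron: np.ndarray  # int32
    t_ms: np.ndarray    # float64
    duration: float
    n_neurons: int

    def __len__(self) -> int:
        return self.neuron.size

    def in_window(self, t0: float, t1: float) -> "SpikeEvents":
        m = (self.t_ms >= t0) & (self.t_ms < t1)
        return SpikeEvents(self.neuron[m], self.t_ms[m], self.duration,
                           self.n_neurons)

    def mean_rate(self, t0: float, t1: float) -> float:
        """Population mean firing rate (sp/s) over [t0, t1)."""
        n = np.count_nonzero((self.t_ms >= t0) & (self.t_ms < t1))
        return n / self.n_neurons / ((t1 - t0) * 1e-3)


@dataclass
class PooledTraces:
    """Per-pool summed conductances, mean V and spike counts at 1 kHz.

    Arrays are (n_pools, n_ms); ``grid_shape`` maps pools onto the 2D pool
    grid (row-major) for 2D networks.
    """

    sum_ge: np.ndarray
    sum_gi: np.ndarray
    mean_V: np.ndarray
    spike_counts: np.ndarray
    t0_ms: float
    grid_shape: tuple[int, ...]
    pool_size: int  # neurons per pool

    @property
    def fs(self) -> float:
        return 1000.0


@dataclass
class RunResult:
    spikes: SpikeEvents
    traces: PooledTraces | None
    exit_code: int
    exit_step: int
    checkpoints: list[NeuronState] = field(default_factory=list)
    final_state: NeuronState | None = None

    @property
    def early_exit(self) -> bool:
        return self.exit_code == EXIT_RATE_GUARD

    @property
    def failed(self) -> bool:
        return self.exit_code == EXIT_NAN


@dataclass(frozen=True)
class Moments:
    """Gaussian steady-state summary used to initialize later runs."""

    V_mean: float
    V_sd: float
    ge_mean: float
    ge_sd: float
    gi_mean: float
    gi_sd: float
    rate: float  # population mean rate in the sampled window, sp/s
    self_sustained: bool


# ---------------------------------------------------------------------------
# Kernel


@njit(cache=True)
def _step_range(V, ge, gi, refr_until, buf, start_step, n_steps, local_offset,
                targets, delay_steps, Ne, dt,
                Cm, GL, EL, Ee, Ei, VT, Vr, tau_e, tau_i, tau_r_steps,
                Ge, Gi, I_ext,
                ext_steps, ext_neuron, ext_weight, ext_ptr,
                pool_idx, n_pools, ms_stride,
                trace_ge, trace_gi, trace_V, trace_spk,
                spike_neuron, spike_step,
                guard_count, ms_counts):
    """Advance the network ``n_steps`` steps.  Returns
    (n_spikes, exit_code, exit_step, ext_ptr).

    ``local_offset`` is the number of steps already executed in this run
    (so trace bins stay aligned when the run is split at checkpoints).
    """
    N = V.shape[0]
    K = targets.shape[1]
    n_slots = buf.shape[0]
    decay_e = 1.0 - dt / tau_e
    decay_i = 1.0 - dt / tau_i
    inv_cm = dt / Cm
    n_spk = 0
    max_spk = spike_neuron.shape[0]
    n_ext = ext_steps.shape[0]
    window = ms_counts.shape[0]
    have_traces = n_pools > 0

    for local in range(n_steps):
        s = start_step + local
        slot = s % n_slots
        # external arrivals due at this step
        while ext_ptr < n_ext and ext_steps[ext_ptr] == s:
            ge[ext_neuron[ext_ptr]] += ext_weight[ext_ptr]
            ext_ptr += 1
        ms_bin = (local_offset + local) // ms_stride
        for n in range(N):
            g_e = (ge[n] + buf[slot, n, 0]) * decay_e
            g_i = (gi[n] + buf[slot, n, 1]) * decay_i
            buf[slot, n, 0] = 0.0
            buf[slot, n, 1] = 0.0
            ge[n] = g_e
            gi[n] = g_i
            if s >= refr_until[n]:
                v = V[n]
                v += inv_cm * (GL * (EL - v) + g_e * (Ee - v)
                               + g_i * (Ei - v) + I_ext[n])
                if v >= VT:
                    # spike: reset, clamp for tau_r, schedule K deliveries
                    if n_spk >= max_spk:
                        return n_spk, EXIT_SPIKE_CAP, s, ext_ptr
                    spike_neuron[n_spk] = n
                    spike_step[n_spk] = s
                    n_spk += 1
                    v = Vr
                    refr_until[n] = s + tau_r_steps
                    w = Ge if n < Ne else Gi
                    chan = 0 if n < Ne else 1
                    for j in range(K):
                        dslot = (s + delay_steps[n, j]) % n_slots
                        buf[dslot, targets[n, j], chan] += w
                    if have_traces and pool_idx[n] >= 0:
                        trace_spk[pool_idx[n], ms_bin] += 1.0
                V[n] = v
            if have_traces:
                p = pool_idx[n]
                if p >= 0:
                    trace_ge[p, ms_bin] += g_e
                    trace_gi[p, ms_bin] += g_i
                    trace_V[p, ms_bin] += V[n]

        # once per ms: NaN check and sliding-window rate guard
        if (local_offset + local + 1) % ms_stride == 0:
            ms = (local_offset + local + 1) // ms_stride - 1
            # spike count in the ms that just completed, from the record tail
            cnt = 0
            k = n_spk - 1
            lo = s - ms_stride + 1
            while k >= 0 and spike_step[k] >= lo:
                cnt += 1
                k -= 1
            ms_counts[ms % window] = cnt
            total = 0
            for q in range(window):
                total += ms_counts[q]
            if total > guard_count:
                return n_spk, EXIT_RATE_GUARD, s, ext_ptr
            if math.isnan(V[0]) or math.isnan(V[N // 2]) or math.isnan(V[N - 1]):
                return n_spk, EXIT_NAN, s, ext_ptr
    return n_spk, EXIT_OK, start_step + n_steps - 1, ext_ptr


# ---------------------------------------------------------------------------
# Python wrappers


def _make_buffer(table: SynapseTable, N: int) -> np.ndarray:
    n_slots = int(table.delay_steps.max()) + 1
    return np.zeros((n_slots, N, 2), dtype=np.float32)


def _normalize_traces(trace_ge, trace_gi, trace_V, ms_stride, pool_size):
    trace_ge /= ms_stride
    trace_gi /= ms_stride
    trace_V /= ms_stride * pool_size


def run_simulation(params: NeuronParams, table: SynapseTable, cfg: SimConfig,
                   init: NeuronState, *,
                   pool_idx: np.ndarray | None = None,
                   grid_shape: tuple[int, ...] = (),
                   pool_size: int = 100,
                   ext_events: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                   I_ext: np.ndarray | None = None,
                   checkpoint_steps: list[int] | None = None,
                   n_steps: int | None = None,
                   spike_cap_rate: float = 100.0) -> RunResult:
    """Run the network forward from ``init``.

    ``init.step`` sets the starting step (supports resuming from a saved
    checkpoint); by default the run covers ``cfg.duration``.  Pooled traces
    are recorded at 1 kHz when ``pool_idx`` is given (index -1 excludes a
    neuron from pooling).  ``ext_events`` is a (step, neuron, weight) triple
    of externally scheduled excitatory conductance increments, sorted by
    step.  ``checkpoint_steps`` requests full state snapshots at those
    global steps (taken before the step executes).

    Identical (configuration, seed) inputs yield bit-identical spike output.
    """
    N = table.N
    dt = cfg.dt
    ms_stride = max(1, int(round(1.0 / dt)))
    start = init.step
    if n_steps is None:
        n_steps = int(round(cfg.duration / dt)) - start
    if n_steps <= 0:
        raise ValueError("nothing to simulate")

    state = init.copy()
    if state.buffer is None:
        state.buffer = _make_buffer(table, N)
    if state.buffer.shape[0] <= table.delay_steps.max():
        raise RuntimeError(
            f"event buffer too small: {state.buffer.shape[0]} slots for max "
            f"delay {int(table.delay_steps.max())} steps")

    if pool_idx is None:
        pool_idx_arr = np.full(N, -1, dtype=np.int32)
        n_pools = 0
    else:
        pool_idx_arr = pool_idx.astype(np.int32)
        n_pools = int(pool_idx_arr.max()) + 1

    n_ms = (n_steps + ms_stride - 1) // ms_stride
    trace_ge = np.zeros((max(n_pools, 1), n_ms))
    trace_gi = np.zeros_like(trace_ge)
    trace_V = np.zeros_like(trace_ge)
    trace_spk = np.zeros_like(trace_ge)

    if ext_events is None:
        ext_steps = np.empty(0, dtype=np.int64)
        ext_neuron = np.empty(0, dtype=np.int32)
        ext_weight = np.empty(0, dtype=np.float64)
    else:
        ext_steps, ext_neuron, ext_weight = ext_events
        order = np.argsort(ext_steps, kind="stable")
        ext_steps = np.ascontiguousarray(ext_steps[order], dtype=np.int64)
        ext_neuron = np.ascontiguousarray(ext_neuron[order], dtype=np.int32)
        ext_weight = np.ascontiguousarray(ext_weight[order], dtype=np.float64)
    ext_ptr = int(np.searchsorted(ext_steps, start))

    if I_ext is None:
        I_ext = np.zeros(N)

    duration_s = n_steps * dt * 1e-3
    cap = int(max(1000, spike_cap_rate * N * duration_s))
    spike_neuron = np.empty(cap, dtype=np.int32)
    spike_step = np.empty(cap, dtype=np.int64)

    guard_count = cfg.rate_guard * N * (_RATE_WINDOW_MS * 1e-3)
    ms_counts = np.zeros(_RATE_WINDOW_MS, dtype=np.int64)

    tau_r_steps = max(1, int(round(params.tau_r / dt)))

    checkpoints: list[NeuronState] = []
    cp_steps = sorted(checkpoint_steps or [])
    segments: list[tuple[int, int]] = []
    seg_start = start
    for c in cp_steps:
        if start <= c < start + n_steps:
            segments.append((seg_start, c))
            seg_start = c
    segments.append((seg_start, start + n_steps))

    n_spk_total = 0
    exit_code = EXIT_OK
    exit_step = start + n_steps - 1
    for a, b in segments:
        if a in cp_steps:
            checkpoints.append(state.copy())
        if b <= a:
            continue
        spk_view_n = spike_neuron[n_spk_total:]
        spk_view_s = spike_step[n_spk_total:]
        got, code, stop, ext_ptr = _step_range(
            state.V, state.ge, state.gi, state.refr_until, state.buffer,
            a, b - a, a - start,
            table.targets, table.delay_steps, table.Ne, dt,
            params.Cm, params.GL, params.EL, params.Ee, params.Ei,
            params.VT, params.Vr, params.tau_e, params.tau_i, tau_r_steps,
            cfg.Ge, cfg.Gi, I_ext,
            ext_steps, ext_neuron, ext_weight, ext_ptr,
            pool_idx_arr, n_pools, ms_stride,
            trace_ge, trace_gi, trace_V, trace_spk,
            spk_view_n, spk_view_s,
            guard_count, ms_counts)
        n_spk_total += got
        state.step = stop + 1
        if code != EXIT_OK:
            exit_code, exit_step = code, stop
            break
        exit_step = stop
    if exit_code == EXIT_NAN:
        raise FloatingPointError(
            f"NaN membrane potential at step {exit_step}")

    spikes = SpikeEvents(
        neuron=spike_neuron[:n_spk_total].copy(),
        t_ms=spike_step[:n_spk_total] * dt,
        duration=(start + n_steps) * dt,
        n_neurons=N)

    traces = None
    if n_pools > 0:
        _normalize_traces(trace_ge, trace_gi, trace_V, ms_stride, pool_size)
        traces = PooledTraces(sum_ge=trace_ge, sum_gi=trace_gi,
                              mean_V=trace_V, spike_counts=trace_spk,
                              t0_ms=start * dt, grid_shape=grid_shape,
                              pool_size=pool_size)
    return RunResult(spikes=spikes, traces=traces, exit_code=exit_code,
                     exit_step=exit_step, checkpoints=checkpoints,
                     final_state=state)


# ---------------------------------------------------------------------------
# Initialization


def inject_poisson(neurons: np.ndarray, rate_hz: float, nsyn: int,
                   duration_ms: float, onset_ms: float, weight: float,
                   dt: float, rng: np.random.Generator):
    """Independent Poisson synaptic bombardment of a set of neurons.

    Each neuron receives ``nsyn`` independent trains at ``rate_hz`` over
    [onset, onset+duration); every arrival schedules one excitatory
    conductance increment of ``weight`` nS.  Returns a (step, neuron,
    weight) event triple for :func:`run_simulation`.
    """
    lam = rate_hz * nsyn * duration_ms * 1e-3
    counts = rng.poisson(lam, size=neurons.size)
    total = int(counts.sum())
    if total == 0 or duration_ms <= 0:
        z = np.empty(0)
        return (z.astype(np.int64), z.astype(np.int32), z)
    neuron_col = np.repeat(neurons.astype(np.int32), counts)
    t = onset_ms + rng.random(total) * duration_ms
    steps = np.floor(t / dt).astype(np.int64)
    weights = np.full(total, float(weight))
    return (steps, neuron_col, weights)


def init_from_moments(moments: Moments, N: int, params: NeuronParams,
                      rng: np.random.Generator) -> NeuronState:
    """Independent Gaussian draws of V, ge, gi from steady-state moments.

    Membrane potentials are clipped into the physical range (Ei, VT);
    conductances are clipped at zero.
    """
    eps = 1e-9
    V = rng.normal(moments.V_mean, moments.V_sd, size=N)
    V = np.clip(V, params.Ei + eps, params.VT - eps)
    ge = np.clip(rng.normal(moments.ge_mean, moments.ge_sd, size=N), 0, None)
    gi = np.clip(rng.normal(moments.gi_mean, moments.gi_sd, size=N), 0, None)
    return NeuronState(V=V, ge=ge, gi=gi,
                       refr_until=np.zeros(N, dtype=np.int64))


_MOMENTS_CACHE: dict[tuple, Moments] = {}


def bootstrap_moments(params: NeuronParams, table: SynapseTable,
                      cfg: SimConfig, rng: np.random.Generator, *,
                      kick_rate_hz: float = 2.0, kick_nsyn: int = 100,
                      kick_duration_ms: float = 100.0,
                      settle_ms: float = 2000.0,
                      cache_key: tuple | None = None) -> Moments:
    """Steady-state Gaussian moments of a self-sustained network.

    Starts the network from rest with a brief external Poisson kick, lets it
    settle, and summarizes the final state by population mean and SD of V,
    ge and gi.  If activity dies out (no spikes in the final fifth of the
    settle window, at least 200 ms) the result is flagged not self-sustained
    and carries no usable moments.  Results are memoized per ``cache_key``.
    """
    if cache_key is not None and cache_key in _MOMENTS_CACHE:
        return _MOMENTS_CACHE[cache_key]
    N = table.N
    state = NeuronState.resting(N, params)
    ext = inject_poisson(np.arange(N), kick_rate_hz, kick_nsyn,
                         kick_duration_ms, 0.0, cfg.Ge, cfg.dt, rng)
    total = kick_duration_ms + settle_ms
    res = run_simulation(params, table, cfg, state, ext_events=ext,
                         n_steps=int(round(total / cfg.dt)))
    tail = max(200.0, settle_ms / 5.0)
    tail_rate = res.spikes.mean_rate(total - tail, total)
    alive = (not res.failed) and len(res.spikes.in_window(total - tail, total)) > 0
    st = res.final_state
    m = Moments(
        V_mean=float(st.V.mean()), V_sd=float(st.V.std()),
        ge_mean=float(st.ge.mean()), ge_sd=float(st.ge.std()),
        gi_mean=float(st.gi.mean()), gi_sd=float(st.gi.std()),
        rate=tail_rate,
        self_sustained=bool(alive and not res.early_exit))
    if cache_key is not None:
        _MOMENTS_CACHE[cache_key] = m
    return m


# ---------------------------------------------------------------------------
# Analytic reference


def lif_rate_analytic(params: NeuronParams, I_pA: float) -> float:
    """Steady firing rate (sp/s) of one LIF neuron under DC current.

    With no synaptic input the membrane relaxes toward
    ``V_inf = EL + I/GL`` with time constant ``tau_m``; if ``V_inf > VT``
    the interspike interval is ``tau_r + tau_m ln((V_inf-Vr)/(V_inf-VT))``.
    """
    v_inf = params.EL + I_pA / params.GL
    if v_inf <= params.VT:
        return 0.0
    t_isi = params.tau_r + params.tau_m * math.log(
        (v_inf - params.Vr) / (v_inf - params.VT))
    return 1000.0 / t_isi
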