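"""Integrator correctness: membrane dynamics, delays, refractoriness,
determinism, initialization and external input."""

import numpy as np
import pytest

from sparsewave.config import (ConnectivityConfig, GeometryConfig,
                               NeuronParams, SimConfig, substream)
from sparsewave.dynamics import (Moments, NeuronState, bootstrap_moments,
                                 init_from_moments, inject_poisson,
                                 lif_rate_analytic, run_simulation)
from sparsewave.topology import SynapseTable, build_synapse_table


def chain_table(delays_ms, dt=0.1, Ne=3):
    """3-neuron feed-forward chain 0 -> 1 -> 2 with hand-set delays.

    The terminal neuron's obligatory synapse points back to 0 with a delay
    beyond the simulated horizon, so it never delivers.
    """
    steps = [max(1, round(d / dt)) for d in delays_ms]
    return SynapseTable(
        targets=np.array([[1], [2], [0]], dtype=np.int32),
        delay_steps=np.array([[steps[0]], [steps[1]], [100_000]],
                             dtype=np.int32),
        Ne=Ne, dt=dt)


def isolated_table(n, dt=0.1):
    """n neurons wired in a ring with zero-weight synapses (no interaction)."""
    return SynapseTable(
        targets=np.array([[(i + 1) % n] for i in range(n)], dtype=np.int32),
        delay_steps=np.ones((n, 1), dtype=np.int32), Ne=n, dt=dt)


class TestMembrane:
    def test_rest_is_fixed_point(self):
        p = NeuronParams()
        cfg = SimConfig(duration=100.0, discard=0.0, Ge=0.0, Gi=0.0)
        res = run_simulation(p, isolated_table(5), cfg,
                             NeuronState.resting(5, p))
        assert len(res.spikes) == 0
        assert np.allclose(res.final_state.V, p.EL)

    def test_exponential_decay_to_rest(self):
        p = NeuronParams()
        cfg = SimConfig(duration=60.0, discard=0.0, Ge=0.0, Gi=0.0)
        st = NeuronState.resting(1, p)
        st.V[:] = p.EL + 10.0
        res = run_simulation(p, isolated_table(1), cfg, st)
        t = 60.0
        expect = p.EL + 10.0 * np.exp(-t / p.tau_m)
        # forward Euler: O(dt) per-unit-time error, tiny at dt = 0.1 ms
        assert abs(res.final_state.V[0] - expect) < 0.02

    def test_conductance_impulse_decay(self):
        p = NeuronParams()
        cfg = SimConfig(duration=20.0, discard=0.0, Ge=0.0, Gi=0.0)
        st = NeuronState.resting(1, p)
        st.ge[:] = 5.0
        res = run_simulation(p, isolated_table(1), cfg, st)
        expect = 5.0 * (1 - cfg.dt / p.tau_e) ** 200
        assert np.isclose(res.final_state.ge[0], expect, rtol=1e-10)
        assert abs(expect - 5.0 * np.exp(-20.0 / p.tau_e)) < 0.02

    @pytest.mark.parametrize("I_pA", [120.0, 150.0, 200.0, 300.0])
    def test_fI_curve_matches_analytic(self, I_pA):
        """DC-driven LIF rate agrees with the closed form within 2%."""
        p = NeuronParams()
        cfg = SimConfig(duration=3000.0, discard=0.0, Ge=0.0, Gi=0.0,
                        rate_guard=2000.0)
        st = NeuronState.resting(1, p)
        res = run_simulation(p, isolated_table(1), cfg, st,
                             I_ext=np.array([I_pA]))
        isi = np.diff(res.spikes.t_ms)
        rate = 1000.0 / isi.mean()
        expect = lif_rate_analytic(p, I_pA)
        assert abs(rate - expect) / expect < 0.02

    def test_subthreshold_current_never_fires(self):
        p = NeuronParams()
        assert lif_rate_analytic(p, 99.0) == 0.0  # rheobase = GL*(VT-EL)
        cfg = SimConfig(duration=500.0, discard=0.0, Ge=0.0, Gi=0.0)
        res = run_simulation(p, isolated_table(1), cfg,
                             NeuronState.resting(1, p),
                             I_ext=np.array([99.0]))
        assert len(res.spikes) == 0


def _euler_chain_oracle(p, cfg, delays_ms, I0, T_ms):
    """Plain-python forward-Euler of the 3-neuron chain (independent oracle)."""
    dt = cfg.dt
    n_steps = round(T_ms / dt)
    delay_steps = [max(1, round(d / dt)) for d in delays_ms]
    V = [p.EL] * 3
    ge = [0.0] * 3
    refr = [0] * 3
    pending = {}  # step -> list of target
    spikes = []
    tau_r_steps = max(1, round(p.tau_r / dt))
    for s in range(n_steps):
        for tgt in pending.pop(s, []):
            ge[tgt] += cfg.Ge
        for n in range(3):
            ge[n] *= (1 - dt / p.tau_e)
            if s >= refr[n]:
                V[n] += dt / p.Cm * (p.GL * (p.EL - V[n])
                                     + ge[n] * (p.Ee - V[n])
                                     + (I0 if n == 0 else 0.0))
                if V[n] >= p.VT:
                    spikes.append((n, s))
                    V[n] = p.Vr
                    refr[n] = s + tau_r_steps
                    if n < 2:
                        pending.setdefault(s + delay_steps[n], []).append(n + 1)
    return spikes


class TestChainAndDelays:
    def test_feedforward_chain_exact_spike_times(self):
        """Delayed chain reproduces an independently stepped oracle exactly."""
        p = NeuronParams()
        delays = [3.7, 8.2]
        cfg = SimConfig(duration=300.0, discard=0.0, Ge=30.0, Gi=0.0,
                        rate_guard=1e9)
        table = chain_table(delays)
        st = NeuronState.resting(3, p)
        res = run_simulation(p, table, cfg, st, I_ext=np.array([150.0, 0, 0]))
        got = sorted(zip(res.spikes.neuron.tolist(),
                         np.rint(res.spikes.t_ms / cfg.dt).astype(int)))
        expect = sorted(_euler_chain_oracle(p, cfg, delays, 150.0, 300.0))
        assert got == expect
        assert any(n == 2 for n, _ in got)  # the chain actually propagates

    def test_delivery_lag_matches_delay(self):
        """A postsynaptic conductance jump appears exactly delay steps later."""
        p = NeuronParams()
        cfg = SimConfig(duration=2.0, discard=0.0, Ge=5.0, Gi=0.0)
        table = chain_table([1.0, 1.0])
        st = NeuronState.resting(3, p)
        st.V[0] = p.VT + 1.0  # spikes at step 0
        res = run_simulation(p, table, cfg, st, n_steps=10)
        assert res.final_state.ge[1] == 0.0  # due at step 10: not yet run
        res2 = run_simulation(p, table, cfg, st, n_steps=11)
        assert res2.final_state.ge[1] > 0.0  # applied when step 10 executes

    def test_refractory_floor_on_isi(self, sustained_run):
        ev = sustained_run.result.spikes
        p = sustained_run.cfg.neurons
        order = np.lexsort((ev.t_ms, ev.neuron))
        n, t = ev.neuron[order], ev.t_ms[order]
        same = n[1:] == n[:-1]
        isi = np.diff(t)[same]
        assert isi.min() >= p.tau_r - 1e-9

    def test_event_conservation(self):
        """Every spike schedules exactly K increments (ge bookkeeping)."""
        p = NeuronParams()
        cfg = SimConfig(duration=50.0, discard=0.0, Ge=1.0, Gi=0.0)
        # star: neuron 0 projects to 1..4 with distinct delays
        table = SynapseTable(
            targets=np.array([[1, 2, 3, 4], [0, 2, 3, 4], [0, 1, 3, 4],
                              [0, 1, 2, 4], [0, 1, 2, 3]], dtype=np.int32),
            delay_steps=np.array([[10, 20, 30, 40]] * 5, dtype=np.int32),
            Ne=5, dt=0.1)
        st = NeuronState.resting(5, p)
        st.V[0] = p.VT + 1.0
        res = run_simulation(p, table, cfg, st, n_steps=450)
        n_spikes = len(res.spikes)
        # total conductance injected = K * Ge per spike; integrate analytically
        # instead: each target's ge jumped once by Ge (checked via decay-back)
        assert n_spikes >= 1
        ge = res.final_state.ge
        assert np.count_nonzero(ge[1:] > 0) == 4


class TestDeterminismAndGuards:
    def test_identical_seeds_bit_identical(self, tiny_net):
        pos, table, params, conn = tiny_net
        cfg = SimConfig(duration=300.0, discard=0.0, Ge=3.0, Gi=10.0)
        outs = []
        for _ in range(2):
            st = NeuronState.resting(table.N, params)
            ext = inject_poisson(np.arange(table.N), 5.0, 100, 50.0, 0.0,
                                 cfg.Ge, cfg.dt, substream(4, "det"))
            res = run_simulation(params, table, cfg, st, ext_events=ext)
            outs.append(res.spikes)
        assert np.array_equal(outs[0].neuron, outs[1].neuron)
        assert np.array_equal(outs[0].t_ms, outs[1].t_ms)

    def test_checkpoint_resume_is_exact(self, tiny_net):
        """Splitting a run at checkpoints does not change a single spike."""
        pos, table, params, conn = tiny_net
        cfg = SimConfig(duration=200.0, discard=0.0, Ge=3.0, Gi=10.0,
                        rate_guard=1e9)
        ext = inject_poisson(np.arange(table.N), 5.0, 100, 50.0, 0.0,
                             cfg.Ge, cfg.dt, substream(4, "cp"))
        st = NeuronState.resting(table.N, params)
        whole = run_simulation(params, table, cfg, st, ext_events=ext,
                               spike_cap_rate=500.0)
        split = run_simulation(params, table, cfg, st, ext_events=ext,
                               checkpoint_steps=[500, 1300],
                               spike_cap_rate=500.0)
        assert np.array_equal(whole.spikes.neuron, split.spikes.neuron)
        assert np.array_equal(whole.spikes.t_ms, split.spikes.t_ms)
        # resuming from the snapshot reproduces the tail of the run
        tail = run_simulation(params, table, cfg, split.checkpoints[1],
                              ext_events=ext, spike_cap_rate=500.0)
        ref = whole.spikes.in_window(130.0, 200.0)
        assert np.array_equal(tail.spikes.neuron, ref.neuron)
        assert np.array_equal(tail.spikes.t_ms, ref.t_ms)

    def test_runaway_triggers_early_exit(self):
        p = NeuronParams()
        geom = GeometryConfig(L=0.5, Ne=400, Ni=100, dims=2)
        conn = ConnectivityConfig(K=100, kind="uniform", vc=None)
        table = build_synapse_table(geom, conn, p, 0.1, substream(6, "run"))
        cfg = SimConfig(duration=500.0, discard=0.0, Ge=50.0, Gi=0.0,
                        rate_guard=25.0)
        st = NeuronState.resting(table.N, p)
        st.V[:50] = p.VT + 1.0
        res = run_simulation(p, table, cfg, st)
        assert res.early_exit


class TestInitialization:
    def test_poisson_arrival_statistics(self):
        rng = substream(0, "poisson")
        steps, neurons, w = inject_poisson(np.arange(100), 20.0, 100, 10.0,
                                           5.0, 1.0, 0.1, rng)
        lam = 20.0 * 100 * 0.010  # 20 expected arrivals per neuron
        counts = np.bincount(neurons, minlength=100)
        assert abs(counts.mean() - lam) < 3 * np.sqrt(lam / 100)
        assert steps.min() >= 50 and steps.max() < 150
        empty = inject_poisson(np.arange(10), 20.0, 100, 0.0, 0.0, 1.0, 0.1,
                               rng)
        assert empty[0].size == 0

    def test_init_from_moments_zero_variance(self):
        p = NeuronParams()
        m = Moments(V_mean=-55.0, V_sd=0.0, ge_mean=2.0, ge_sd=0.0,
                    gi_mean=5.0, gi_sd=0.0, rate=5.0, self_sustained=True)
        st = init_from_moments(m, 50, p, substream(0, "m"))
        assert np.all(st.V == -55.0) and np.all(st.ge == 2.0)

    def test_init_from_moments_clipping_and_clt(self):
        p = NeuronParams()
        m = Moments(V_mean=-52.0, V_sd=6.0, ge_mean=1.0, ge_sd=3.0,
                    gi_mean=1.0, gi_sd=3.0, rate=5.0, self_sustained=True)
        n = 100_000
        st = init_from_moments(m, n, p, substream(1, "m"))
        assert st.V.max() < p.VT and st.V.min() > p.Ei
        assert st.ge.min() >= 0 and st.gi.min() >= 0
        # V is CLIPPED (not resampled) into (Ei, VT): compare the sample
        # mean against the clipped-normal expectation within 4 SEM
        from scipy.stats import norm
        a = (p.Ei - m.V_mean) / m.V_sd
        b = (p.VT - m.V_mean) / m.V_sd
        expect = (p.Ei * norm.cdf(a) + p.VT * norm.sf(b)
                  + m.V_mean * (norm.cdf(b) - norm.cdf(a))
                  - m.V_sd * (norm.pdf(b) - norm.pdf(a)))
        assert abs(st.V.mean() - expect) < 4 * m.V_sd / np.sqrt(n)

    def test_dead_network_flagged(self):
        p = NeuronParams()
        geom = GeometryConfig(L=0.5, Ne=64, Ni=16, dims=2)
        conn = ConnectivityConfig(K=5, kind="uniform", vc=None)
        table = build_synapse_table(geom, conn, p, 0.1, substream(8, "dead"))
        cfg = SimConfig(duration=500.0, discard=0.0, Ge=0.01, Gi=10.0)
        m = bootstrap_moments(p, table, cfg, substream(9, "dead"),
                              settle_ms=400.0)
        assert not m.self_sustained

    def test_bootstrap_moments_physical_range(self, sustained_run):
        m = sustained_run.moments
        p = sustained_run.cfg.neurons
        assert m.self_sustained
        assert p.Ei < m.V_mean < p.VT
        assert m.ge_mean >= 0 and m.gi_mean >= 0

    def test_bootstrap_stationarity(self, sustained_run):
        """Restarting from moments gives a stationary rate across halves."""
        ev = sustained_run.result.spikes
        t0, t1 = sustained_run.analysis_window
        mid = (t0 + t1) / 2
        r1 = ev.mean_rate(t0, mid)
        r2 = ev.mean_rate(mid, t1)
        # SEM from 100 ms block rates (population counts are correlated,
        # so a plain count-based SEM would be far too tight)
        blocks = np.array([ev.mean_rate(a, a + 100.0)
                           for a in np.arange(t0, t1, 100.0)])
        sem = blocks.std(ddof=1) / np.sqrt(blocks.size / 2)
        assert abs(r1 - r2) < 5 * sem
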