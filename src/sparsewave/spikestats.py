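"""Spike-train statistics and spike-field coupling.

Rates and interspike-interval CV over a random neuron sample, smoothed
pairwise Pearson correlations, the asynchronous-irregular (A-I)
classification (mean rate in (1, 25) sp/s and mean CV in (0.7, 1.4) for a
self-sustained network), multitaper pairwise spike coherence between pooled
spike trains, and circular spike-phase statistics against the generalized
phase of the LFP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal.windows import dpss

from .dynamics import SpikeEvents
from .waves import AnalyticField

__all__ = [
    "TrainSummary", "RegimeLabel", "CoherenceResult", "PhaseCoupling",
    "summarize_trains", "pairwise_correlation", "classify_regime",
    "bin_trains", "spike_coherence", "spike_phase_coupling",
    "phase_index_resampled", "wave_peak_modulation",
]

RATE_BOUNDS = (1.0, 25.0)   # sp/s, A-I criterion
CV_BOUNDS = (0.7, 1.4)      # A-I criterion
MIN_SPIKES_FOR_CV = 3


@dataclass
class TrainSummary:
    neurons: np.ndarray      # sampled neuron ids
    rate: np.ndarray         # sp/s per sampled neuron
    cv: np.ndarray           # CV per sampled neuron (NaN if ineligible)
    eligible: np.ndarray     # bool, >= 3 spikes
    window: tuple[float, float]

    @property
    def mean_rate(self) -> float:
        return float(self.rate.mean())

    @property
    def mean_cv(self) -> float:
        good = self.cv[self.eligible]
        return float(good.mean()) if good.size else float("nan")


@dataclass
class RegimeLabel:
    self_sustained: bool
    asynchronous_irregular: bool
    mean_rate: float
    mean_cv: float
    mean_correlation: float | None = None


@dataclass
class CoherenceResult:
    freq_hz: np.ndarray
    coherence: np.ndarray
    Sxx: np.ndarray
    Syy: np.ndarray
    Sxy: np.ndarray
    n_epochs: int
    degenerate: bool  # single epoch -> coherence identically 1

    def peak(self) -> tuple[float, float]:
        """(frequency, coherence) at the coherence maximum (DC excluded)."""
        i = int(np.argmax(self.coherence[1:])) + 1
        return float(self.freq_hz[i]), float(self.coherence[i])


@dataclass
class PhaseCoupling:
    hist: np.ndarray         # spike counts per phase bin
    bin_edges: np.ndarray    # nbins+1 edges over (-pi, pi]
    resultant: complex       # r = (1/M) sum exp(i phi_j)
    n_spikes: int
    meta: dict = field(default_factory=dict)

    @property
    def index(self) -> float:
        """Spike-phase index |r| in [0, 1]."""
        return abs(self.resultant)

    @property
    def preferred_phase(self) -> float:
        return float(np.angle(self.resultant))


# ---------------------------------------------------------------------------
# Train statistics


def summarize_trains(events: SpikeEvents, window: tuple[float, float],
                     sample: int = 5000,
                     rng: np.random.Generator | None = None,
                     neurons: np.ndarray | None = None) -> TrainSummary:
    """Per-neuron rate and ISI CV over ``window`` for a random neuron sample.

    CV is defined only for neurons with at least three spikes in the window.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    if neurons is None:
        rng = np.random.default_rng() if rng is None else rng
        n_pick = min(sample, events.n_neurons)
        neurons = rng.choice(events.n_neurons, size=n_pick, replace=False)
    neurons = np.asarray(neurons)
    ev = events.in_window(t0, t1)
    order = np.argsort(ev.neuron, kind="stable")
    by_n, times = ev.neuron[order], ev.t_ms[order]
    starts = np.searchsorted(by_n, neurons)
    stops = np.searchsorted(by_n, neurons, side="right")
    counts = stops - starts
    rate = counts / ((t1 - t0) * 1e-3)
    cv = np.full(neurons.size, np.nan)
    eligible = counts >= MIN_SPIKES_FOR_CV
    for k in np.flatnonzero(eligible):
        isi = np.diff(times[starts[k]:stops[k]])
        mu = isi.mean()
        cv[k] = isi.std() / mu if mu > 0 else np.nan
    return TrainSummary(neurons=neurons, rate=rate, cv=cv, eligible=eligible,
                        window=(t0, t1))


def bin_trains(events: SpikeEvents, neurons: np.ndarray,
               window: tuple[float, float], bin_ms: float = 1.0) -> np.ndarray:
    """(n_neurons, n_bins) spike-count matrix over ``window``."""
    t0, t1 = window
    nb = int(round((t1 - t0) / bin_ms))
    idx = {int(n): i for i, n in enumerate(neurons)}
    out = np.zeros((len(neurons), nb))
    m = (events.t_ms >= t0) & (events.t_ms < t1) & np.isin(events.neuron, neurons)
    rows = np.fromiter((idx[int(n)] for n in events.neuron[m]), dtype=np.int64,
                       count=int(m.sum()))
    cols = ((events.t_ms[m] - t0) / bin_ms).astype(np.int64)
    np.add.at(out, (rows, np.clip(cols, 0, nb - 1)), 1.0)
    return out


def pairwise_correlation(events: SpikeEvents, window: tuple[float, float],
                         n_pairs: int = 1000, smooth_ms: float = 100.0,
                         rng: np.random.Generator | None = None,
                         sample: int = 2000) -> tuple[float, int]:
    """Mean Pearson correlation of smoothed spike trains over random pairs.

    Trains are binned at 1 ms, smoothed with a ``smooth_ms`` boxcar, and
    correlated for ``n_pairs`` randomly selected distinct neuron pairs.
    Pairs containing a zero-variance smoothed train are skipped.  Returns
    ``(mean correlation, pairs used)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    neurons = rng.choice(events.n_neurons, size=min(sample, events.n_neurons),
                         replace=False)
    binned = bin_trains(events, neurons, window)
    sm = ndimage.uniform_filter1d(binned, size=int(round(smooth_ms)), axis=1,
                                  mode="constant")
    sm = sm - sm.mean(axis=1, keepdims=True)
    norms = np.sqrt((sm ** 2).sum(axis=1))
    used = 0
    total = 0.0
    for _ in range(n_pairs):
        i, j = rng.choice(len(neurons), size=2, replace=False)
        if norms[i] == 0 or norms[j] == 0:
            continue
        total += float(sm[i] @ sm[j] / (norms[i] * norms[j]))
        used += 1
    return (total / used if used else float("nan")), used


def classify_regime(summary: TrainSummary, events: SpikeEvents,
                    early_exit: bool = False,
                    mean_correlation: float | None = None) -> RegimeLabel:
    """Asynchronous-irregular classification from the printed criteria.

    Self-sustained requires spiking in the final 200 ms (and no early
    exit); A-I additionally requires the population mean rate in (1, 25)
    sp/s and mean CV in (0.7, 1.4).
    """
    alive = len(events.in_window(events.duration - 200.0,
                                 events.duration + 1e-9)) > 0
    self_sustained = bool(alive and not early_exit)
    r, c = summary.mean_rate, summary.mean_cv
    ai = bool(self_sustained
              and RATE_BOUNDS[0] < r < RATE_BOUNDS[1]
              and not np.isnan(c) and CV_BOUNDS[0] < c < CV_BOUNDS[1])
    return RegimeLabel(self_sustained=self_sustained,
                       asynchronous_irregular=ai,
                       mean_rate=r, mean_cv=c,
                       mean_correlation=mean_correlation)


# ---------------------------------------------------------------------------
# Coherence


def spike_coherence(pool_a: np.ndarray, pool_b: np.ndarray, fs: float = 1000.0,
                    epoch_ms: float = 500.0, step_ms: float = 125.0,
                    half_bw_hz: float = 2.5) -> CoherenceResult:
    """Multitaper coherence between two pooled spike trains.

    ``pool_a``/``pool_b`` are (n_trains, nt) binned count matrices; the
    concurrent trains of each pool are summed into one population train.
    The record is cut into overlapping epochs, each epoch is demeaned and
    tapered with a single Slepian taper (time-half-bandwidth T*W chosen for
    ``half_bw_hz`` smoothing), and auto-/cross-spectra are averaged over
    epochs before forming C = |Sxy| / sqrt(Sxx Syy).
    """
    x = np.asarray(pool_a).sum(axis=0) if np.ndim(pool_a) == 2 else np.asarray(pool_a, float)
    y = np.asarray(pool_b).sum(axis=0) if np.ndim(pool_b) == 2 else np.asarray(pool_b, float)
    if x.shape != y.shape:
        raise ValueError("pool trains must share a time base")
    n = int(round(epoch_ms * fs / 1000.0))
    step = int(round(step_ms * fs / 1000.0))
    if x.size < n:
        raise ValueError("record shorter than one epoch")
    nw = epoch_ms * 1e-3 * half_bw_hz
    taper = dpss(n, nw)
    dt = 1.0 / fs
    T = n * dt
    starts = list(range(0, x.size - n + 1, step))
    Sxx = Syy = 0.0
    Sxy = 0.0
    for s0 in starts:
        xs = x[s0:s0 + n]
        ys = y[s0:s0 + n]
        X = np.fft.rfft((xs - xs.mean()) * taper)
        Y = np.fft.rfft((ys - ys.mean()) * taper)
        Sxx = Sxx + (2 * dt ** 2 / T) * (X * np.conj(X)).real
        Syy = Syy + (2 * dt ** 2 / T) * (Y * np.conj(Y)).real
        Sxy = Sxy + (2 * dt ** 2 / T) * X * np.conj(Y)
    m = len(starts)
    Sxx, Syy, Sxy = Sxx / m, Syy / m, Sxy / m
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.abs(Sxy) / np.sqrt(Sxx * Syy)
    C = np.nan_to_num(np.clip(C, 0.0, 1.0))
    freq = np.fft.rfftfreq(n, d=dt)
    return CoherenceResult(freq_hz=freq, coherence=C, Sxx=Sxx, Syy=Syy,
                           Sxy=Sxy, n_epochs=m, degenerate=(m == 1))


# ---------------------------------------------------------------------------
# Spike-phase coupling


def _phases_at_spikes(events: SpikeEvents, fld: AnalyticField,
                      pool_idx: np.ndarray) -> np.ndarray:
    """GP of each spike's own pool at the nearest 1 ms sample."""
    ny, nx, nt = fld.Lambda.shape
    t0 = 0.0  # field sample k corresponds to t0_ms + k/fs; caller aligns
    p = pool_idx[events.neuron]
    k = np.rint((events.t_ms - t0) * fld.fs / 1000.0).astype(np.int64)
    ok = (p >= 0) & (k >= 0) & (k < nt)
    ok &= fld.valid[np.clip(k, 0, nt - 1)]
    phi = np.angle(fld.Lambda.reshape(ny * nx, nt))
    return phi[p[ok], k[ok]]


def spike_phase_coupling(events: SpikeEvents, fld: AnalyticField,
                         pool_idx: np.ndarray, nbins: int = 10,
                         t_offset_ms: float = 0.0) -> PhaseCoupling:
    """Spike-phase histogram and mean resultant against the pool GP.

    Each spike is scored with the generalized phase of its own pool at the
    nearest field sample; ``t_offset_ms`` shifts spike times into the
    field's time base (pass the field's start time).  The spike-phase index
    is |r| of the resultant r = (1/M) sum_j exp(i phi_j).
    """
    shifted = SpikeEvents(events.neuron, events.t_ms - t_offset_ms,
                          events.duration, events.n_neurons)
    phis = _phases_at_spikes(shifted, fld, pool_idx)
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    hist, _ = np.histogram(phis, bins=edges)
    M = phis.size
    r = complex(np.exp(1j * phis).mean()) if M else 0j
    return PhaseCoupling(hist=hist, bin_edges=edges, resultant=r, n_spikes=M,
                         meta={"undefined": M == 0})


def phase_index_resampled(events: SpikeEvents, fld: AnalyticField,
                          pool_idx: np.ndarray, n_resamples: int = 22,
                          match_count: int | None = None,
                          rng: np.random.Generator | None = None,
                          t_offset_ms: float = 0.0) -> tuple[float, float]:
    """Spike-phase index under repeated spike-count-matched resampling.

    Subsamples the spike set ``n_resamples`` times to ``match_count`` spikes
    (default: half the available spikes) and returns (mean index, SEM).
    """
    rng = np.random.default_rng() if rng is None else rng
    shifted = SpikeEvents(events.neuron, events.t_ms - t_offset_ms,
                          events.duration, events.n_neurons)
    phis = _phases_at_spikes(shifted, fld, pool_idx)
    if phis.size == 0:
        return float("nan"), float("nan")
    if match_count is None:
        match_count = max(1, phis.size // 2)
    match_count = min(match_count, phis.size)
    vals = np.empty(n_resamples)
    for i in range(n_resamples):
        take = rng.choice(phis.size, size=match_count, replace=False)
        vals[i] = np.abs(np.exp(1j * phis[take]).mean())
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_resamples))


def wave_peak_modulation(events: SpikeEvents, fld: AnalyticField,
                         pool_idx: np.ndarray, nbins: int = 10,
                         neurons_per_pool: int = 100,
                         t_offset_ms: float = 0.0) -> float:
    """Percent increase of per-ms spike probability at the wave peak.

    The per-millisecond spiking probability is computed per phase bin
    (spikes in the bin over phase-bin occupancy times neurons per pool) and
    the maximal bin is compared with the occupancy-weighted phase average:
    0% for a phase-uniform histogram, (nbins-1)*100% if all spikes land in
    one of ``nbins`` equally occupied bins.
    """
    shifted = SpikeEvents(events.neuron, events.t_ms - t_offset_ms,
                          events.duration, events.n_neurons)
    spike_phi = _phases_at_spikes(shifted, fld, pool_idx)
    if spike_phi.size == 0:
        return float("nan")
    ny, nx, nt = fld.Lambda.shape
    field_phi = np.angle(fld.Lambda[:, :, fld.valid]).ravel()
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    occ, _ = np.histogram(field_phi, bins=edges)
    spk, _ = np.histogram(spike_phi, bins=edges)
    good = occ > 0
    p_bin = spk[good] / (occ[good] * neurons_per_pool)
    p_avg = spk[good].sum() / (occ[good].sum() * neurons_per_pool)
    return float((p_bin.max() / p_avg - 1.0) * 100.0)
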