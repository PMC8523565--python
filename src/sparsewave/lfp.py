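"""Simulated local field potential from pooled synaptic activity.

The LFP proxy for each non-overlapping pool of 10 x 10 excitatory neurons is
a lagged, weighted difference of the pooled excitatory and inhibitory
synaptic currents,

    lambda(t) = sum_j Ie_j(t - tau) - alpha * sum_j Ii_j(t),

with tau = 6 ms and alpha = 1.65 (values transferred from a multicompartment
forward-model calibration of the point-neuron proxy).  Currents are
reconstructed from the pooled conductances times the driving force between
the pool-mean membrane potential and the synaptic reversal potentials, which
is nearly identical to summing per-neuron currents.  With this sign
convention both terms are positive, so periods of high total conductance map
to positive z-scored LFP (the inhibition-dominated, shunted state) and
low-conductance excitation-dominated periods map to negative values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import GeometryConfig, NeuronParams
from .dynamics import PooledTraces

__all__ = ["PoolGrid", "LFPMovie", "compute_lfp", "lfp_from_currents",
           "smooth_spatial", "zscore"]

DEFAULT_ALPHA = 1.65
DEFAULT_TAU_LAG_MS = 6.0
POOL_SIDE = 10  # neurons per pool edge


@dataclass
class PoolGrid:
    """Mapping of excitatory neurons onto non-overlapping square pools."""

    pool_idx: np.ndarray      # (N,) int32; -1 = excluded (inhibitory/margin)
    shape: tuple[int, int]    # (ny, nx) pools
    pitch_mm: float           # pool centre spacing
    m: int                    # neurons per pool

    @classmethod
    def from_geometry(cls, geometry: GeometryConfig,
                      pool_side: int = POOL_SIDE) -> "PoolGrid":
        """Tile the analysis region (after margin discard) with pools.

        The margin is rounded up to a whole number of pools so the remaining
        region is tiled exactly.
        """
        if geometry.dims != 2:
            raise ValueError("pool grids require a 2D geometry")
        side = int(round(np.sqrt(geometry.Ne)))
        if side % pool_side:
            raise ValueError(
                f"excitatory lattice side {side} not divisible by pool side "
                f"{pool_side}")
        spacing = geometry.L / side
        pools_per_side = side // pool_side
        m_pools = int(np.ceil(geometry.margin / (pool_side * spacing) - 1e-9))
        n_keep = pools_per_side - 2 * m_pools
        if n_keep < 1:
            raise ValueError("margin leaves no analysis region")
        pool_idx = np.full(geometry.N, -1, dtype=np.int32)
        e = np.arange(geometry.Ne)
        row, col = e // side, e % side
        prow, pcol = row // pool_side - m_pools, col // pool_side - m_pools
        ok = (prow >= 0) & (prow < n_keep) & (pcol >= 0) & (pcol < n_keep)
        pool_idx[e[ok]] = prow[ok] * n_keep + pcol[ok]
        return cls(pool_idx=pool_idx, shape=(n_keep, n_keep),
                   pitch_mm=pool_side * spacing, m=pool_side ** 2)

    @property
    def n_pools(self) -> int:
        return int(self.shape[0] * self.shape[1])

    def neurons_in_pool(self, pool: int) -> np.ndarray:
        return np.flatnonzero(self.pool_idx == pool)


@dataclass
class LFPMovie:
    """Scalar field lambda(y, x, t) over the pool grid at 1 kHz."""

    data: np.ndarray          # (ny, nx, nt)
    pitch_mm: float
    t0_ms: float = 0.0
    fs: float = 1000.0
    valid: np.ndarray | None = None  # (nt,) bool; None = all valid
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.data.shape[2]) * 1000.0 / self.fs

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.data.shape[2], dtype=bool)
        return self.valid

    def copy_with(self, data: np.ndarray, **meta) -> "LFPMovie":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return LFPMovie(data=data, pitch_mm=self.pitch_mm, t0_ms=self.t0_ms,
                        fs=self.fs,
                        valid=None if self.valid is None else self.valid.copy(),
                        meta=new_meta)


def lfp_from_currents(Ie_sum: np.ndarray, Ii_sum: np.ndarray,
                      alpha: float = DEFAULT_ALPHA,
                      lag_samples: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Core proxy: lambda(t) = Ie(t - lag) - alpha * Ii(t).

    Operates on arrays whose last axis is time; returns (lambda, valid mask).
    The first ``lag_samples`` outputs have no lagged excitatory term and are
    marked invalid.  Linear in both inputs.
    """
    Ie = np.asarray(Ie_sum, dtype=float)
    Ii = np.asarray(Ii_sum, dtype=float)
    lam = -alpha * Ii
    if lag_samples == 0:
        lam = lam + Ie
    else:
        lam[..., lag_samples:] += Ie[..., :-lag_samples]
    valid = np.ones(lam.shape[-1], dtype=bool)
    valid[:lag_samples] = False
    return lam, valid


def compute_lfp(traces: PooledTraces, params: NeuronParams,
                alpha: float = DEFAULT_ALPHA,
                tau_lag_ms: float = DEFAULT_TAU_LAG_MS,
                pitch_mm: float = 0.0678) -> LFPMovie:
    """LFP movie from pooled conductance/potential traces.

    The pooled excitatory current is the summed excitatory conductance times
    the driving force (Ee - mean V of the pool); likewise for inhibition
    (whose driving force Ei - V is negative, so the -alpha term adds a
    positive contribution).
    """
    if traces.sum_ge is None or traces.mean_V is None:
        raise ValueError("traces must carry pooled conductances and mean V")
    lag = int(round(tau_lag_ms * traces.fs / 1000.0))
    if abs(lag * 1000.0 / traces.fs - tau_lag_ms) > 1e-9:
        raise ValueError("tau_lag must be a multiple of the sampling interval")
    Ie = traces.sum_ge * (params.Ee - traces.mean_V)
    Ii = traces.sum_gi * (params.Ei - traces.mean_V)
    lam, valid = lfp_from_currents(Ie, Ii, alpha, lag)
    ny, nx = traces.grid_shape
    data = lam.reshape(ny, nx, -1)
    return LFPMovie(data=data, pitch_mm=pitch_mm, t0_ms=traces.t0_ms,
                    valid=valid,
                    meta={"alpha": alpha, "tau_lag_ms": tau_lag_ms,
                          "kind": "lfp"})


def smooth_spatial(movie: LFPMovie, sigma_pools: float = 4.0,
                   periodic: bool = True) -> LFPMovie:
    """Framewise 2D Gaussian smoothing, emulating electrode integration.

    ``sigma_pools`` is the kernel SD in pool units (4 pools ~ 272 um at the
    reference pitch).  ``sigma_pools = 0`` is the identity.
    """
    if sigma_pools < 0:
        raise ValueError("sigma_pools must be >= 0")
    if sigma_pools == 0:
        return movie.copy_with(movie.data.copy())
    mode = "wrap" if periodic else "nearest"
    out = ndimage.gaussian_filter(movie.data, sigma=(sigma_pools, sigma_pools, 0),
                                  mode=mode)
    return movie.copy_with(out, smoothing_sigma_pools=sigma_pools)


def zscore(movie: LFPMovie) -> LFPMovie:
    """Per-pool z-score over the valid analysis window.

    Pools with zero variance are left as zeros and flagged in
    ``meta['zero_variance_pools']``.
    """
    valid = movie.valid_mask()
    data = movie.data
    sel = data[..., valid]
    mu = sel.mean(axis=-1, keepdims=True)
    sd = sel.std(axis=-1, keepdims=True)
    flat = sd[..., 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (data - mu) / sd_safe
    out[flat] = 0.0
    return movie.copy_with(out, zscored=True,
                           zero_variance_pools=np.argwhere(flat))
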