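"""Network construction: neuron placement, wiring, and conduction delays.

Excitatory and inhibitory neurons tile the sheet as two concentric square
lattices (or a ring in 1D) with periodic boundaries.  Each neuron sends
exactly K synapses; targets are drawn either uniformly over the whole
network ("random" networks) or from an isotropic Gaussian of SD ``sigma``
centred on the source ("topographic" networks), wrapped onto the torus and
snapped to the nearest lattice site.  Axonal conduction delays grow linearly
with torus distance, ``tau(i,j) = tau_s + d(i,j) / vc(i,j)``, quantized to
the integration step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (ConfigError, ConnectivityConfig, GeometryConfig,
                     NeuronParams)

__all__ = [
    "SynapseTable",
    "place_neurons",
    "torus_distance",
    "sample_targets",
    "build_synapse_table",
    "rewire_uniform",
    "assign_delays",
]


@dataclass
class SynapseTable:
    """Outgoing wiring of the whole network.

    ``targets[i]`` holds the K postsynaptic indices of neuron ``i`` and
    ``delay_steps[i]`` the matching conduction delays in integration steps.
    The presynaptic sign is implicit in the index: sources ``< Ne`` are
    excitatory.  ``vc_draw`` keeps the per-connection conduction velocity
    (m/s) so rewired connections can be re-delayed consistently; it is None
    when delays are disabled.
    """

    targets: np.ndarray      # (N, K) int32
    delay_steps: np.ndarray  # (N, K) int32
    Ne: int
    dt: float
    vc_draw: np.ndarray | None = None  # (N, K) float32, m/s

    @property
    def N(self) -> int:
        return self.targets.shape[0]

    @property
    def K(self) -> int:
        return self.targets.shape[1]

    def is_excitatory(self, i) -> np.ndarray:
        return np.asarray(i) < self.Ne

    def validate(self) -> None:
        """Assert the structural invariants by scan (no self, no duplicates)."""
        n, k = self.targets.shape
        src = np.arange(n)[:, None]
        if np.any(self.targets == src):
            raise AssertionError("self-connection found")
        sorted_t = np.sort(self.targets, axis=1)
        if np.any(sorted_t[:, 1:] == sorted_t[:, :-1]):
            raise AssertionError("duplicate connection found")
        if self.targets.min() < 0 or self.targets.max() >= n:
            raise AssertionError("target index out of range")
        if self.delay_steps.min() < 1:
            raise AssertionError("delay below one integration step")


# ---------------------------------------------------------------------------

def place_neurons(geometry: GeometryConfig) -> np.ndarray:
    """Per-neuron coordinates (mm), excitatory first.

    In 2D both populations sit on cell-centred square lattices of side L
    (spacings ``L/sqrt(Ne)`` and ``L/sqrt(Ni)``), which makes the two grids
    concentric about (L/2, L/2).  In 1D neurons are spread uniformly on a
    ring of length L, returned as an (N, 1) array.
    """
    L = geometry.L
    if geometry.dims == 1:
        pos_e = (np.arange(geometry.Ne) + 0.5) * (L / geometry.Ne)
        pos_i = (np.arange(geometry.Ni) + 0.5) * (L / geometry.Ni)
        return np.concatenate([pos_e, pos_i])[:, None]

    def lattice(n: int) -> np.ndarray:
        side = int(round(np.sqrt(n)))
        ax = (np.arange(side) + 0.5) * (L / side)
        xx, yy = np.meshgrid(ax, ax, indexing="xy")
        return np.column_stack([xx.ravel(), yy.ravel()])

    return np.vstack([lattice(geometry.Ne), lattice(geometry.Ni)])


def torus_distance(p: np.ndarray, q: np.ndarray, L: float) -> np.ndarray:
    """Minimum Euclidean distance under periodic boundaries.

    Works elementwise on broadcastable coordinate arrays whose last axis is
    the spatial dimension (or on scalars in 1D).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = np.abs(p - q)
    d = np.minimum(d, L - d)
    if d.ndim == 0:
        return d
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# Target sampling

def _lattice_side(n: int) -> int:
    return int(round(np.sqrt(n)))


def _snap_to_lattice(xy: np.ndarray, side: int, L: float, offset: int) -> np.ndarray:
    """Nearest cell-centred lattice site index for continuous positions.

    ``offset`` is the index of the population's first neuron (0 for E,
    Ne for I).  Lattice sites are at ((col+0.5)*L/side, (row+0.5)*L/side)
    and indices follow row-major order matching :func:`place_neurons`.
    """
    spacing = L / side
    col = np.floor(xy[..., 0] / spacing).astype(np.int64) % side
    row = np.floor(xy[..., 1] / spacing).astype(np.int64) % side
    return offset + row * side + col


def _fill_distinct(draw_fn, i: int, K: int) -> np.ndarray:
    """Accumulate K distinct candidates != i, resampling rejected draws.

    ``draw_fn(n)`` returns n candidate indices.  Candidates are accepted in
    draw order (equivalent to sequential rejection sampling), so overdrawing
    introduces no selection bias.
    """
    acc = np.empty(0, dtype=np.int64)
    for _ in range(100_000):
        cand = np.asarray(draw_fn(K - acc.size + 8), dtype=np.int64)
        _, first = np.unique(cand, return_index=True)
        cand = cand[np.sort(first)]
        cand = cand[(cand != i) & ~np.isin(cand, acc)]
        acc = np.concatenate([acc, cand[: K - acc.size]])
        if acc.size >= K:
            return acc
    raise ConfigError(
        [f"could not draw {K} distinct targets for neuron {i}; the "
         "displacement law may be degenerate (e.g. sigma far below the "
         "lattice spacing)"])


def _sample_gaussian_targets(i: int, pos_i: np.ndarray, cfg: ConnectivityConfig,
                             geometry: GeometryConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """K distinct targets of neuron i under the Gaussian displacement law."""
    L, K = geometry.L, cfg.K
    Ne, Ni, N = geometry.Ne, geometry.Ni, geometry.N
    side_e, side_i = _lattice_side(Ne), _lattice_side(Ni)

    def draw(n: int) -> np.ndarray:
        disp = rng.normal(0.0, cfg.sigma, size=(n, geometry.dims))
        xy = np.mod(pos_i[None, :] + disp, L)
        pop_e = rng.random(n) < Ne / N
        if geometry.dims == 1:
            idx_e = np.floor(xy[:, 0] / (L / Ne)).astype(np.int64) % Ne
            idx_i = Ne + np.floor(xy[:, 0] / (L / Ni)).astype(np.int64) % Ni
        else:
            idx_e = _snap_to_lattice(xy, side_e, L, 0)
            idx_i = _snap_to_lattice(xy, side_i, L, Ne)
        return np.where(pop_e, idx_e, idx_i)

    return _fill_distinct(draw, i, K)


def _sample_uniform_targets(i: int, K: int, N: int,
                            rng: np.random.Generator) -> np.ndarray:
    """K distinct uniform targets excluding the source."""
    if K > 0.25 * N:
        pool = np.delete(np.arange(N), i)
        return rng.choice(pool, size=K, replace=False)
    return _fill_distinct(lambda n: rng.integers(0, N, size=n), i, K)


def sample_targets(i: int, cfg: ConnectivityConfig, positions: np.ndarray,
                   geometry: GeometryConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """K distinct postsynaptic targets for neuron ``i`` (never ``i`` itself)."""
    N = geometry.N
    if cfg.K >= N - 1:
        raise ConfigError([f"K={cfg.K} must be < N-1={N - 1}"])
    if cfg.kind == "uniform":
        return _sample_uniform_targets(i, cfg.K, N, rng)
    return _sample_gaussian_targets(i, positions[i], cfg, geometry, rng)


def _draw_candidates(rows_pos: np.ndarray, n_each: int,
                     cfg: ConnectivityConfig, geometry: GeometryConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_rows, n_each) candidate targets under the configured law."""
    n_rows = rows_pos.shape[0]
    L, Ne, Ni, N = geometry.L, geometry.Ne, geometry.Ni, geometry.N
    if cfg.kind == "uniform":
        return rng.integers(0, N, size=(n_rows, n_each))
    disp = rng.normal(0.0, cfg.sigma, size=(n_rows, n_each, geometry.dims))
    xy = np.mod(rows_pos[:, None, :] + disp, L)
    pop_e = rng.random((n_rows, n_each)) < Ne / N
    if geometry.dims == 1:
        idx_e = np.floor(xy[..., 0] / (L / Ne)).astype(np.int64) % Ne
        idx_i = Ne + np.floor(xy[..., 0] / (L / Ni)).astype(np.int64) % Ni
    else:
        idx_e = _snap_to_lattice(xy, _lattice_side(Ne), L, 0)
        idx_i = _snap_to_lattice(xy, _lattice_side(Ni), L, Ne)
    return np.where(pop_e, idx_e, idx_i)


def _sample_all_targets(cfg: ConnectivityConfig, positions: np.ndarray,
                        geometry: GeometryConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Whole-network target matrix with vectorized self/duplicate repair.

    All rows are drawn at once; slots holding the source index or a repeat
    within their row are redrawn in vectorized rounds until every row holds
    K distinct non-self targets.  Repair replaces only offending slots, so
    accepted draws are identical to sequential rejection sampling.
    """
    N, K = geometry.N, cfg.K
    if K >= N - 1:
        raise ConfigError([f"K={K} must be < N-1={N - 1}"])
    src = np.arange(N, dtype=np.int64)[:, None]
    targets = _draw_candidates(positions, K, cfg, geometry, rng)
    for _ in range(200):
        order = np.argsort(targets, axis=1, kind="stable")
        sorted_t = np.take_along_axis(targets, order, axis=1)
        dup_sorted = np.zeros_like(targets, dtype=bool)
        dup_sorted[:, 1:] = sorted_t[:, 1:] == sorted_t[:, :-1]
        bad = np.zeros_like(dup_sorted)
        np.put_along_axis(bad, order, dup_sorted, axis=1)
        bad |= targets == src
        n_bad = int(bad.sum())
        if n_bad == 0:
            return targets.astype(np.int32)
        rows_bad, cols_bad = np.nonzero(bad)
        fresh = _draw_candidates(positions[rows_bad], 1, cfg, geometry,
                                 rng)[:, 0]
        targets[rows_bad, cols_bad] = fresh
    # pathological tail: finish the few remaining rows sequentially
    for i in np.unique(np.nonzero((targets == src)
                                  | _row_dup_mask(targets))[0]):
        targets[i] = sample_targets(int(i), cfg, positions, geometry, rng)
    return targets.astype(np.int32)


def _row_dup_mask(targets: np.ndarray) -> np.ndarray:
    order = np.argsort(targets, axis=1, kind="stable")
    sorted_t = np.take_along_axis(targets, order, axis=1)
    dup_sorted = np.zeros_like(targets, dtype=bool)
    dup_sorted[:, 1:] = sorted_t[:, 1:] == sorted_t[:, :-1]
    out = np.zeros_like(dup_sorted)
    np.put_along_axis(out, order, dup_sorted, axis=1)
    return out


# ---------------------------------------------------------------------------
# Delays

def _delay_steps_from_distance(d: np.ndarray, vc: np.ndarray | float,
                               tau_s: float, dt: float) -> np.ndarray:
    delay_ms = tau_s + np.asarray(d) / np.asarray(vc)
    steps = np.rint(delay_ms / dt).astype(np.int32)
    floor = max(1, int(round(tau_s / dt)))
    return np.maximum(steps, floor)


def assign_delays(table: SynapseTable, positions: np.ndarray, tau_s: float,
                  vc: float | tuple[float, float] | None, L: float,
                  rng: np.random.Generator | None = None) -> SynapseTable:
    """Fill conduction delays ``tau = tau_s + d/vc`` (quantized to dt).

    With ``vc = None`` every connection gets the bare synaptic release delay.
    A ``(low, high)`` tuple draws each connection's velocity uniformly.
    """
    n, k = table.targets.shape
    if vc is None:
        floor = max(1, int(round(tau_s / table.dt)))
        table.delay_steps = np.full((n, k), floor, dtype=np.int32)
        table.vc_draw = None
        return table
    if isinstance(vc, tuple):
        if rng is None:
            raise ConfigError(["vc range requires an RNG"])
        vdraw = rng.uniform(vc[0], vc[1], size=(n, k)).astype(np.float32)
    else:
        if vc <= 0:
            raise ConfigError(["vc must be > 0"])
        vdraw = np.full((n, k), float(vc), dtype=np.float32)
    # distances in mm, vc in m/s = mm/ms; chunked to bound peak memory
    table.delay_steps = np.empty((n, k), dtype=np.int32)
    block = max(1, int(2e7 // max(k, 1)))
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        d = torus_distance(positions[lo:hi, None, :],
                           positions[table.targets[lo:hi]], L)
        table.delay_steps[lo:hi] = _delay_steps_from_distance(
            d, vdraw[lo:hi], tau_s, table.dt)
    table.vc_draw = vdraw
    return table


# ---------------------------------------------------------------------------

def build_synapse_table(geometry: GeometryConfig, cfg: ConnectivityConfig,
                        params: NeuronParams, dt: float,
                        rng: np.random.Generator,
                        positions: np.ndarray | None = None) -> SynapseTable:
    """Construct the full wiring for one network.

    Samples K targets per neuron, applies optional uniform rewiring, and
    assigns distance-dependent delays.
    """
    if positions is None:
        positions = place_neurons(geometry)
    N = geometry.N
    targets = _sample_all_targets(cfg, positions, geometry, rng)
    table = SynapseTable(targets=targets,
                         delay_steps=np.ones((N, cfg.K), dtype=np.int32),
                         Ne=geometry.Ne, dt=dt)
    table = assign_delays(table, positions, params.tau_s, cfg.vc, geometry.L, rng)
    if cfg.rewire_fraction > 0:
        table = rewire_uniform(table, cfg.rewire_fraction, positions,
                               params.tau_s, cfg.vc, geometry.L, rng)
    return table


def rewire_uniform(table: SynapseTable, fraction: float,
                   positions: np.ndarray, tau_s: float,
                   vc: float | tuple[float, float] | None, L: float,
                   rng: np.random.Generator) -> SynapseTable:
    """Redraw a fraction of all connections uniformly across the network.

    Exactly ``round(fraction * N * K)`` connection slots, chosen uniformly
    without replacement, get a new uniform target (no self, no duplicate
    within the source's row) and a delay recomputed from the new distance.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(["rewire fraction must lie in [0, 1]"])
    n, k = table.targets.shape
    n_rewire = int(round(fraction * n * k))
    if n_rewire == 0:
        return table
    flat = rng.choice(n * k, size=n_rewire, replace=False)
    rows = flat // k
    cols = flat % k
    order = np.argsort(rows, kind="stable")
    rows, cols = rows[order], cols[order]

    vc_range = vc if isinstance(vc, tuple) else None
    row_starts = np.searchsorted(rows, np.arange(n + 1))
    for i in np.unique(rows):
        sel = cols[row_starts[i]:row_starts[i + 1]]
        keep = np.delete(table.targets[i], sel)
        new = _fill_distinct(lambda m: rng.integers(0, n, size=m), int(i),
                             sel.size + keep.size)
        # _fill_distinct guarantees distinctness among `new`; also exclude
        # the connections this row keeps
        fresh = new[~np.isin(new, keep)]
        while fresh.size < sel.size:
            extra = _fill_distinct(lambda m: rng.integers(0, n, size=m),
                                   int(i), k)
            fresh = np.concatenate(
                [fresh, extra[~np.isin(extra, keep) &
                              ~np.isin(extra, fresh)]])
        fresh = fresh[:sel.size]
        table.targets[i, sel] = fresh
        if vc is not None:
            d = torus_distance(positions[i], positions[fresh], L)
            v = (rng.uniform(vc_range[0], vc_range[1], size=sel.size)
                 if vc_range is not None else float(vc))
            table.delay_steps[i, sel] = _delay_steps_from_distance(
                d, v, tau_s, table.dt)
            if table.vc_draw is not None:
                table.vc_draw[i, sel] = v
    return table
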