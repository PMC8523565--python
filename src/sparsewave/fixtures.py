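"""Ground-truth synthetic signals for validating the analysis stack.

Planar traveling waves with known wavelength, frequency and direction (the
oracle for the phase-gradient pipeline) and cosine-modulated inhomogeneous
Poisson spike trains with a closed-form spike-phase index (the oracle for
circular spike-phase statistics).  Fixtures are emitted in the same
containers the simulator produces, so they flow through the identical
analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SpikeEvents
from .lfp import LFPMovie

__all__ = ["PlanarWaveSpec", "make_planar_wave", "make_modulated_trains",
           "shuffle_movie"]


@dataclass(frozen=True)
class PlanarWaveSpec:
    """A plane wave lambda = A cos(2 pi (f t - (k . x) / wavelength)) + noise."""

    wavelength_mm: float
    freq_hz: float
    direction: tuple[float, float] = (1.0, 0.0)  # unit propagation direction
    amplitude: float = 1.0
    noise_sd: float = 0.0
    shape: tuple[int, int] = (24, 24)     # (ny, nx) pools
    pitch_mm: float = 0.25
    duration_ms: float = 1000.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.wavelength_mm <= 2 * self.pitch_mm:
            raise ValueError("wavelength must exceed 2 x pitch (resolvable)")
        if self.freq_hz >= self.fs / 2:
            raise ValueError("frequency must be below Nyquist")

    @property
    def speed_mps(self) -> float:
        """Ground-truth propagation speed f * wavelength (mm/s -> m/s)."""
        return self.freq_hz * self.wavelength_mm * 1e-3


def make_planar_wave(spec: PlanarWaveSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[LFPMovie, dict]:
    """Planar-wave movie plus its analytic ground truth.

    Returns ``(movie, truth)`` where ``truth`` carries the exact phase
    field, wavelength, speed and the (unit) gradient direction so tests
    never re-derive them.
    """
    rng = np.random.default_rng() if rng is None else rng
    ny, nx = spec.shape
    d = np.asarray(spec.direction, dtype=float)
    d = d / np.linalg.norm(d)
    x = np.arange(nx) * spec.pitch_mm
    y = np.arange(ny) * spec.pitch_mm
    t = np.arange(int(round(spec.duration_ms * spec.fs / 1000.0))) / spec.fs
    proj = d[0] * x[None, :, None] + d[1] * y[:, None, None]  # mm
    phase = 2 * np.pi * (spec.freq_hz * t[None, None, :]
                         - proj / spec.wavelength_mm)
    data = spec.amplitude * np.cos(phase)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    movie = LFPMovie(data=data, pitch_mm=spec.pitch_mm, fs=spec.fs,
                     meta={"kind": "planar-wave-fixture",
                           "wavelength_mm": spec.wavelength_mm,
                           "freq_hz": spec.freq_hz})
    truth = {
        "phi": np.mod(phase + np.pi, 2 * np.pi) - np.pi,
        "wavelength_mm": spec.wavelength_mm,
        "speed_mps": spec.speed_mps,
        "direction": d,
    }
    return movie, truth


def make_modulated_trains(rate_hz: float, depth: float,
                          phase_fn, n_trains: int, duration_ms: float,
                          rng: np.random.Generator,
                          preferred_phase: float = 0.0,
                          dt_ms: float = 1.0) -> tuple[SpikeEvents, np.ndarray]:
    """Inhomogeneous Poisson trains locked to a phase carrier.

    Intensity r(t) = rate * (1 + depth * cos(phi(t) - preferred_phase)),
    sampled by thinning on a ``dt_ms`` grid.  For a sinusoidal modulation
    the population spike-phase resultant has the closed form |r| = depth/2
    with preferred phase ``preferred_phase``.

    ``phase_fn(t_ms)`` returns the carrier phase (rad) at the sample times;
    returns ``(events, phi_samples)`` with the carrier phase at each sample
    so callers can score spikes against the exact carrier.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    n_samples = int(round(duration_ms / dt_ms))
    t_ms = (np.arange(n_samples) + 0.5) * dt_ms
    phi = np.asarray(phase_fn(t_ms), dtype=float)
    lam = rate_hz * 1e-3 * dt_ms * (1 + depth * np.cos(phi - preferred_phase))
    counts = rng.poisson(lam[None, :].repeat(n_trains, axis=0))
    train_idx, sample_idx = np.nonzero(counts)
    reps = counts[train_idx, sample_idx]
    neuron = np.repeat(train_idx, reps).astype(np.int32)
    times = np.repeat(t_ms[sample_idx], reps)
    order = np.argsort(times, kind="stable")
    events = SpikeEvents(neuron=neuron[order], t_ms=times[order],
                         duration=duration_ms, n_neurons=n_trains)
    return events, phi


def shuffle_movie(movie: LFPMovie, axis: str,
                  rng: np.random.Generator) -> LFPMovie:
    """Uniform permutation of pool positions (space) or samples (time).

    The value multiset is preserved exactly; spatial shuffling destroys any
    spatial phase organisation while leaving every pool's temporal
    statistics untouched.
    """
    ny, nx, nt = movie.data.shape
    if axis == "space":
        perm = rng.permutation(ny * nx)
        data = movie.data.reshape(ny * nx, nt)[perm].reshape(ny, nx, nt)
    elif axis == "time":
        perm = rng.permutation(nt)
        data = movie.data[:, :, perm]
    else:
        raise ValueError("axis must be 'space' or 'time'")
    return movie.copy_with(data.copy(), shuffled_axis=axis)
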