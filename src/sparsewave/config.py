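"""Configuration types for network geometry, neurons, connectivity and runs.

All biophysical and structural parameters of the model live here as plain
dataclasses with eager validation.  A handful of named presets capture the
reference network configurations (the "sparse-wave" network and scaled
variants); every field can be overridden from a YAML config file through
:func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryConfig",
    "NeuronParams",
    "ConnectivityConfig",
    "SimConfig",
    "NetworkConfig",
    "ConfigError",
    "geometry_for_size",
    "connections_for_size",
    "PRESETS",
    "get_preset",
    "load_config",
    "substream",
]

REFERENCE_DENSITY = 28125.0  # neurons per mm^2 (cortical layer 2/3 scale)
REFERENCE_K = 3000  # outgoing synapses per cell at full scale
REFERENCE_K_SIZE_MM = 2.0  # network side at/above which K stops growing


class ConfigError(ValueError):
    """A configuration violates one or more invariants.

    ``errors`` lists every violation found, not only the first.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def _check(errors: list[str], ok: bool, msg: str) -> None:
    if not ok:
        errors.append(msg)


@dataclass(frozen=True)
class GeometryConfig:
    """Spatial layout of the neuron sheet.

    Excitatory and inhibitory neurons sit on two concentric square lattices
    (in 2D) of common side ``L`` with periodic boundaries, or uniformly on a
    ring (in 1D).  ``margin`` is the border stripe discarded from analysis.
    """

    L: float  # side length, mm
    Ne: int  # excitatory count (perfect square in 2D)
    Ni: int  # inhibitory count (perfect square in 2D)
    dims: int = 2
    margin: float = 0.0  # mm, excluded from pooled analysis

    def __post_init__(self) -> None:
        errs: list[str] = []
        _check(errs, self.L > 0, f"L must be > 0, got {self.L}")
        _check(errs, self.dims in (1, 2), f"dims must be 1 or 2, got {self.dims}")
        _check(errs, self.Ne > 0 and self.Ni > 0, "Ne and Ni must be positive")
        _check(errs, self.Ne == 4 * self.Ni,
               f"Ne must equal 4*Ni (80/20 split), got Ne={self.Ne}, Ni={self.Ni}")
        if self.dims == 2:
            for name, n in (("Ne", self.Ne), ("Ni", self.Ni)):
                side = math.isqrt(n)
                _check(errs, side * side == n,
                       f"{name}={n} must be a perfect square in 2D")
        _check(errs, 0 <= self.margin < self.L / 2,
               f"margin must lie in [0, L/2), got {self.margin}")
        if errs:
            raise ConfigError(errs)

    @property
    def N(self) -> int:
        return self.Ne + self.Ni

    @property
    def density(self) -> float:
        return self.N / self.L ** self.dims


@dataclass(frozen=True)
class NeuronParams:
    """Conductance-based leaky integrate-and-fire neuron constants."""

    Cm: float = 200.0    # membrane capacitance, pF
    GL: float = 10.0     # leak conductance, nS  (tau_m = Cm/GL = 20 ms)
    EL: float = -60.0    # resting potential, mV
    Ee: float = 0.0      # excitatory reversal potential, mV
    Ei: float = -80.0    # inhibitory reversal potential, mV
    VT: float = -50.0    # spike threshold, mV
    Vr: float = -60.0    # reset potential, mV
    tau_e: float = 10.0  # excitatory synaptic time constant, ms
    tau_i: float = 10.0  # inhibitory synaptic time constant, ms
    tau_r: float = 5.0   # absolute refractory period, ms
    tau_s: float = 0.1   # synaptic release delay, ms

    def __post_init__(self) -> None:
        errs: list[str] = []
        _check(errs, self.Ei <= self.Vr < self.VT < self.Ee,
               "require Ei <= Vr < VT < Ee")
        for name in ("tau_e", "tau_i", "tau_r", "tau_s"):
            _check(errs, getattr(self, name) > 0, f"{name} must be > 0")
        _check(errs, self.Cm > 0 and self.GL > 0, "Cm and GL must be > 0")
        if errs:
            raise ConfigError(errs)

    @property
    def tau_m(self) -> float:
        return self.Cm / self.GL


@dataclass(frozen=True)
class ConnectivityConfig:
    """Wiring rule: out-degree, displacement law and conduction velocity.

    ``vc`` is either a scalar conduction velocity (m/s) or a ``(low, high)``
    range from which each connection draws uniformly.  ``vc = None`` disables
    distance-dependent delays (synaptic release delay only), the control used
    to dissociate topography from delays.
    """

    K: int                       # outgoing synapses per neuron
    kind: str = "gaussian"       # "gaussian" (topographic) | "uniform" (random)
    sigma: float = 0.4           # Gaussian SD of connection distance, mm
    rewire_fraction: float = 0.0
    vc: float | tuple[float, float] | None = 0.2  # m/s

    def __post_init__(self) -> None:
        errs: list[str] = []
        _check(errs, self.K >= 1, f"K must be >= 1, got {self.K}")
        _check(errs, self.kind in ("gaussian", "uniform"),
               f"kind must be 'gaussian' or 'uniform', got {self.kind!r}")
        if self.kind == "gaussian":
            _check(errs, self.sigma > 0, "sigma must be > 0 for gaussian kind")
        _check(errs, 0.0 <= self.rewire_fraction <= 1.0,
               "rewire_fraction must lie in [0, 1]")
        if self.vc is not None:
            if isinstance(self.vc, (tuple, list)):
                lo, hi = self.vc
                _check(errs, 0 < lo <= hi, "vc range requires 0 < low <= high")
                object.__setattr__(self, "vc", (float(lo), float(hi)))
            else:
                _check(errs, self.vc > 0, "vc must be > 0")
        if errs:
            raise ConfigError(errs)

    @property
    def vc_range(self) -> tuple[float, float] | None:
        if self.vc is None:
            return None
        if isinstance(self.vc, tuple):
            return self.vc
        return (float(self.vc), float(self.vc))


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for one simulation run."""

    dt: float = 0.1          # integration step, ms
    duration: float = 1200.0 # total simulated time, ms
    discard: float = 200.0   # initial transient excluded from analysis, ms
    Ge: float = 1.0          # excitatory synaptic weight, nS
    Gi: float = 10.0         # inhibitory synaptic weight, nS
    rate_guard: float = 25.0 # early-exit threshold on population rate, sp/s
    seed: int = 0

    def __post_init__(self) -> None:
        errs: list[str] = []
        _check(errs, self.dt > 0, "dt must be > 0")
        _check(errs, 0 <= self.discard < self.duration,
               "require 0 <= discard < duration")
        _check(errs, self.Ge >= 0 and self.Gi >= 0, "Ge, Gi must be >= 0")
        _check(errs, self.rate_guard > 0, "rate_guard must be > 0")
        if errs:
            raise ConfigError(errs)


@dataclass(frozen=True)
class NetworkConfig:
    """Bundle of everything needed to build and run one network."""

    geometry: GeometryConfig
    neurons: NeuronParams = field(default_factory=NeuronParams)
    connectivity: ConnectivityConfig = field(
        default_factory=lambda: ConnectivityConfig(K=REFERENCE_K))
    sim: SimConfig = field(default_factory=SimConfig)
    name: str = "custom"

    def content_hash(self) -> str:
        """Stable hash of the full configuration (for caching and manifests)."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Size scaling helpers

def geometry_for_size(L: float, density: float = REFERENCE_DENSITY,
                      margin: float = 0.0, dims: int = 2) -> GeometryConfig:
    """Geometry at a given side length holding neuron density fixed.

    Counts are snapped to the nearest admissible split: ``Ni = s**2`` and
    ``Ne = (2s)**2`` so both populations form perfect square lattices and
    Ne = 4*Ni exactly; total count stays within one lattice row of
    ``density * L**dims``.
    """
    target = density * L ** dims
    if dims == 2:
        s = max(1, round(math.sqrt(target / 5.0)))
        return GeometryConfig(L=L, Ne=(2 * s) ** 2, Ni=s ** 2, dims=2,
                              margin=margin)
    ni = max(1, round(target / 5.0))
    return GeometryConfig(L=L, Ne=4 * ni, Ni=ni, dims=1, margin=margin)


def connections_for_size(L: float, sigma: float | None = 0.4,
                         K_ref: int = REFERENCE_K,
                         size_ref: float = REFERENCE_K_SIZE_MM) -> int:
    """Out-degree at network side ``L`` (mm) for kernel width ``sigma``.

    The out-degree maintains the density of connections within the kernel
    footprint: it scales with the area the kernel can reach — the 3-sigma
    disc for a Gaussian kernel (``sigma=None`` means an unbounded/uniform
    footprint, i.e. the whole sheet) clipped to the sheet area — and
    saturates at ``K_ref`` for the reference kernel once L reaches 2 mm
    (99% of the sigma = 0.4 mm kernel mass inside the sheet).
    """
    foot = math.inf if sigma is None else math.pi * (3.0 * sigma) ** 2
    area = min(L ** 2, foot)
    area_ref = min(size_ref ** 2, math.pi * (3.0 * 0.4) ** 2)
    return max(1, min(K_ref, round(K_ref * area / area_ref)))


# ---------------------------------------------------------------------------
# Presets

def _preset_sparse(L: float = 6.0, margin: float = 1.0, *, kind: str = "gaussian",
                   sigma: float = 0.4,
                   vc: float | tuple[float, float] | None = 0.2,
                   Ge: float = 1.0, Gi: float = 10.0,
                   rewire: float = 0.0, name: str = "sparse") -> NetworkConfig:
    k_sigma = sigma if kind == "gaussian" else None
    return NetworkConfig(
        geometry=geometry_for_size(L, margin=margin),
        neurons=NeuronParams(),
        connectivity=ConnectivityConfig(
            K=connections_for_size(L, k_sigma), kind=kind, sigma=sigma,
            rewire_fraction=rewire, vc=vc),
        sim=SimConfig(Ge=Ge, Gi=Gi),
        name=name,
    )


def _build_presets() -> dict[str, NetworkConfig]:
    presets: dict[str, NetworkConfig] = {}
    # Full-scale reference sparse-wave network: 6 mm simulated, outer 1 mm
    # discarded leaving a 4 x 4 mm^2 analysis region, sigma = 400 um,
    # vc = 0.2 m/s, Ge = 1 nS, Gi = 10 nS.
    presets["sparse"] = _preset_sparse()
    presets["random"] = _preset_sparse(kind="uniform", vc=None, name="random")
    # Heterogeneous variant: 10% rewired uniformly, vc drawn from 0.1-0.6 m/s.
    presets["sparse-heterogeneous"] = _preset_sparse(
        vc=(0.1, 0.6), rewire=0.1, name="sparse-heterogeneous")
    # Desk-scale variants at 1 mm (~28k neurons).  All lengths scale with
    # the sheet (sigma = L/10 as in the full-scale analysis region) so the
    # connectivity footprint stays a small fraction of the sheet and
    # spatial structure remains resolvable; inhibition is slightly stronger
    # than the full-scale reference, which at this size yields rates and
    # CVs inside the asynchronous-irregular band.  See docs/methods.md.
    for L, tag in ((1.0, "1mm"), (0.5, "0.5mm")):
        presets[f"sparse-{tag}"] = _preset_sparse(
            L, margin=0.0, sigma=L / 10, Ge=1.0, Gi=14.0,
            name=f"sparse-{tag}")
        presets[f"random-{tag}"] = _preset_sparse(
            L, margin=0.0, kind="uniform", vc=None, Ge=1.0, Gi=14.0,
            name=f"random-{tag}")
    # Dissociation controls at 1 mm.
    presets["topographic-nodelay-1mm"] = _preset_sparse(
        1.0, margin=0.0, sigma=0.1, vc=None, Ge=1.0, Gi=14.0,
        name="topographic-nodelay-1mm")
    presets["random-delay-1mm"] = _preset_sparse(
        1.0, margin=0.0, kind="uniform", vc=0.2, Ge=1.0, Gi=14.0,
        name="random-delay-1mm")
    # Dense-wave contrast network: fewer neurons, denser connectivity and
    # outsized conductances, which couple spikes strongly to the wave.
    dense_geom = geometry_for_size(0.5, margin=0.0)
    presets["dense"] = NetworkConfig(
        geometry=dense_geom,
        neurons=NeuronParams(),
        connectivity=ConnectivityConfig(K=1500, kind="gaussian", sigma=0.2,
                                        vc=0.2),
        sim=SimConfig(Ge=6.0, Gi=60.0),
        name="dense",
    )
    return presets


PRESETS = _build_presets()


def get_preset(name: str, **overrides) -> NetworkConfig:
    """Fetch a named preset, optionally replacing sub-configs."""
    if name not in PRESETS:
        raise ConfigError([f"unknown preset {name!r}; "
                           f"available: {sorted(PRESETS)}"])
    cfg = PRESETS[name]
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# YAML config loading

_SECTION_TYPES = {
    "geometry": GeometryConfig,
    "neurons": NeuronParams,
    "connectivity": ConnectivityConfig,
    "sim": SimConfig,
}


def load_config(path) -> NetworkConfig:
    """Load a validated :class:`NetworkConfig` from a YAML file.

    The file may name a ``preset`` and override any subset of fields in the
    ``geometry``/``neurons``/``connectivity``/``sim`` sections.  Unknown keys
    and every violated invariant are reported together.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError([f"config root must be a mapping, got {type(raw)}"])

    errs: list[str] = []
    preset = raw.pop("preset", None)
    name = raw.pop("name", preset or "custom")
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError([f"unknown preset {preset!r}"])
        base = PRESETS[preset]
        sections = {k: dataclasses.asdict(getattr(base, k))
                    for k in _SECTION_TYPES}
    else:
        sections = {k: {} for k in _SECTION_TYPES}

    for key, val in raw.items():
        if key not in _SECTION_TYPES:
            errs.append(f"unknown section {key!r}")
            continue
        if not isinstance(val, dict):
            errs.append(f"section {key!r} must be a mapping")
            continue
        known = {f.name for f in dataclasses.fields(_SECTION_TYPES[key])}
        for k2 in val:
            if k2 not in known:
                errs.append(f"unknown key {key}.{k2}")
        sections[key].update({k2: v for k2, v in val.items() if k2 in known})
    if errs:
        raise ConfigError(errs)

    if preset is None and not sections["geometry"]:
        raise ConfigError(["config must provide a preset or a geometry section"])

    built = {}
    for key, typ in _SECTION_TYPES.items():
        vals = sections[key]
        if isinstance(vals.get("vc"), list):
            vals["vc"] = tuple(vals["vc"])
        try:
            built[key] = typ(**vals)
        except ConfigError as e:
            errs.extend(f"{key}: {m}" for m in e.errors)
        except TypeError as e:
            errs.append(f"{key}: {e}")
    if errs:
        raise ConfigError(errs)
    return NetworkConfig(name=str(name), **built)


# ---------------------------------------------------------------------------
# Seeding

def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from a master seed.

    Streams are keyed by purpose ("topology", "init", "stimulus", ...) so
    that, e.g., changing the number of wavelength shuffles cannot perturb the
    simulation itself.
    """
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
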