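"""Multi-compartment retinal ganglion cell biophysics.

Five-region cable (soma, axon hillock, sodium-channel band, narrow segment,
distal axon) of 1-um cylindrical compartments carrying five voltage/calcium
gated membrane currents (Na, delayed-rectifier K, A-type K, Ca-activated K,
L-type Ca) plus leak, in the amphibian-RGC kinetics lineage at 22 C (no Q10
scaling).  Extracellular stimulation enters the cable equation through
neighbour differences of the interpolated extracellular potential,
``Ve_i(t) = ve_unit_i * I(t)``.

The rate functions live in one table (``RATE_FUNCTIONS``) so an independent
ODE integration of a single compartment can validate the production
integrator against the very same kinetics.

Units: mV, ms, uA, uS, uF, um, mM; channel densities in mS/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .geometry import ConfigurationError, GeometryError

__all__ = [
    "REGIONS",
    "RATE_FUNCTIONS",
    "GATES",
    "Morphometry",
    "RegionConductances",
    "ChannelParams",
    "CompartmentChain",
    "StimulusWaveform",
    "SampledWaveform",
    "SimResult",
    "IntegrationError",
    "build_cable",
    "make_waveform",
    "simulate",
    "detect_spikes",
    "initiation_site",
    "resting_state",
]

REGIONS = ("soma", "axon_hillock", "socb", "narrow", "distal_axon")

FARADAY = 96485.332  # C/mol
GAS_R = 8.314462  # J/(mol K)


class IntegrationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Channel kinetics (rates in 1/ms, V in mV)
# --------------------------------------------------------------------------


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x / y)) with the removable singularity at x = 0 patched."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, y * (1.0 + x / y / 2.0), safe / -np.expm1(-safe / y))


def _alpha_m(v):
    return 0.6 * _vtrap(v + 30.0, 10.0)


def _beta_m(v):
    return 20.0 * np.exp(-(v + 55.0) / 18.0)


def _alpha_h(v):
    return 0.4 * np.exp(-(v + 50.0) / 20.0)


def _beta_h(v):
    return 6.0 / (1.0 + np.exp(-0.1 * (v + 20.0)))


def _alpha_n(v):
    return 0.02 * _vtrap(v + 40.0, 10.0)


def _beta_n(v):
    return 0.4 * np.exp(-(v + 50.0) / 80.0)


def _alpha_a(v):
    return 0.006 * _vtrap(v + 90.0, 10.0)


def _beta_a(v):
    return 0.1 * np.exp(-(v + 30.0) / 10.0)


def _alpha_ha(v):
    return 0.04 * np.exp(-(v + 70.0) / 20.0)


def _beta_ha(v):
    return 0.6 / (1.0 + np.exp(-0.1 * (v + 40.0)))


def _alpha_c(v):
    return 0.3 * _vtrap(v + 13.0, 10.0)


def _beta_c(v):
    return 10.0 * np.exp(-(v + 38.0) / 18.0)


GATES = ("m", "h", "n", "a", "ha", "c")

#: gate -> (alpha, beta); the single source of kinetics for the integrator
RATE_FUNCTIONS = {
    "m": (_alpha_m, _beta_m),
    "h": (_alpha_h, _beta_h),
    "n": (_alpha_n, _beta_n),
    "a": (_alpha_a, _beta_a),
    "ha": (_alpha_ha, _beta_ha),
    "c": (_alpha_c, _beta_c),
}


def gate_steady_state(v: float | np.ndarray, na_shift_mV: float = 0.0) -> dict[str, np.ndarray]:
    """Steady-state gate values; ``na_shift_mV`` left-shifts Na activation."""
    out = {}
    for g, (fa, fb) in RATE_FUNCTIONS.items():
        vv = np.asarray(v, dtype=float) - na_shift_mV if g == "m" else v
        a, b = fa(vv), fb(vv)
        out[g] = a / (a + b)
    return out


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Morphometry:
    """Region lengths and diameters (um)."""

    lengths_um: dict[str, float] = field(
        default_factory=lambda: {
            "soma": 24.0,
            "axon_hillock": 20.0,
            "socb": 40.0,
            "narrow": 20.0,
            "distal_axon": 2896.0,
        }
    )
    diameters_um: dict[str, float] = field(
        default_factory=lambda: {
            "soma": 24.0,
            "axon_hillock": 2.0,
            "socb": 1.4,
            "narrow": 0.6,
            "distal_axon": 1.0,
        }
    )
    compartment_length_um: float = 1.0
    #: chain order from the soma end; the sodium band sits distal to the
    #: thin segment (its junction is the preferred initiation hotspot)
    region_order: tuple[str, ...] = ("soma", "axon_hillock", "narrow", "socb", "distal_axon")

    def __post_init__(self) -> None:
        if set(self.lengths_um) != set(REGIONS) or set(self.diameters_um) != set(REGIONS):
            raise ConfigurationError(f"regions must be exactly {REGIONS}")
        if sorted(self.region_order) != sorted(REGIONS):
            raise ConfigurationError("region_order must be a permutation of the regions")
        if self.region_order[0] != "soma" or self.region_order[-1] != "distal_axon":
            raise ConfigurationError("chain must run from soma to distal axon")
        if any(d <= 0 for d in self.diameters_um.values()):
            raise ConfigurationError("diameters must be positive")
        if self.compartment_length_um <= 0:
            raise ConfigurationError("compartment length must be positive")
        for r in REGIONS:
            n = self.lengths_um[r] / self.compartment_length_um
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ConfigurationError(
                    f"compartment length must divide region {r} length exactly"
                )

    @property
    def total_length_um(self) -> float:
        return float(sum(self.lengths_um.values()))

    def with_total_length(self, total_um: float) -> "Morphometry":
        """Shrink/grow the distal axon so the total length equals ``total_um``."""
        other = sum(v for r, v in self.lengths_um.items() if r != "distal_axon")
        distal = total_um - other
        if distal < self.compartment_length_um:
            raise ConfigurationError("requested total length too short for the proximal regions")
        lengths = dict(self.lengths_um)
        lengths["distal_axon"] = float(distal)
        return replace(self, lengths_um=lengths)


@dataclass(frozen=True)
class RegionConductances:
    """Maximal conductance densities, mS/cm^2."""

    g_na: float
    g_k: float
    g_ka: float
    g_kca: float
    g_ca: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.g_na, self.g_k, self.g_ka, self.g_kca, self.g_ca)):
            raise ConfigurationError("conductances must be non-negative")


_DEFAULT_GBAR = {
    # sodium-channel band carries the highest Na density by construction;
    # K densities scale with Na so every region holds a quiescent rest
    "soma": RegionConductances(80.0, 18.0, 54.0, 0.065, 1.5),
    "axon_hillock": RegionConductances(150.0, 30.0, 54.0, 0.065, 1.5),
    "socb": RegionConductances(400.0, 80.0, 0.0, 0.065, 1.5),
    "narrow": RegionConductances(100.0, 25.0, 0.0, 0.065, 1.5),
    "distal_axon": RegionConductances(80.0, 20.0, 0.0, 0.065, 1.5),
}

#: per-region leak (mS/cm^2): the dense sodium band needs extra leak to hold
#: a quiescent rest against its window current
_DEFAULT_GLEAK = {
    "soma": 0.1,
    "axon_hillock": 0.1,
    "socb": 1.0,
    "narrow": 0.1,
    "distal_axon": 0.1,
}

#: per-region shift of Na activation (mV): band-type sodium channels
#: activate at lower voltages, which makes the band the initiation site
_DEFAULT_NA_SHIFT = {
    "soma": 0.0,
    "axon_hillock": 0.0,
    "socb": -10.0,
    "narrow": 0.0,
    "distal_axon": 0.0,
}


@dataclass(frozen=True)
class ChannelParams:
    """Membrane and cytoplasm parameters (defaults: 22 C amphibian lineage)."""

    gbar: dict[str, RegionConductances] = field(default_factory=lambda: dict(_DEFAULT_GBAR))
    e_na_mV: float = 35.0
    e_k_mV: float = -75.0
    e_leak_mV: float = -72.0
    g_leak_mS_cm2: float | dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_GLEAK))
    cm_uF_cm2: float = 1.0
    axial_resistivity_ohm_cm: float = 110.0
    ca_out_mM: float = 1.8
    ca_rest_mM: float = 1e-4
    ca_tau_ms: float = 1.5
    ca_shell_depth_um: float | None = None  # None -> d/4 (whole cylinder volume)
    ca_dissoc_mM: float = 1e-3
    temperature_C: float = 22.0
    na_shift_mV: float | dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NA_SHIFT))

    def __post_init__(self) -> None:
        if set(self.gbar) != set(REGIONS):
            raise ConfigurationError(f"gbar must cover exactly regions {REGIONS}")
        socb_na = self.gbar["socb"].g_na
        if any(self.gbar[r].g_na >= socb_na for r in REGIONS if r != "socb"):
            raise ConfigurationError("SOCB sodium density must be strictly greatest")
        if any(v < 0 for v in self.leak_by_region().values()):
            raise ConfigurationError("leak conductance must be non-negative")
        if self.cm_uF_cm2 <= 0 or self.axial_resistivity_ohm_cm <= 0:
            raise ConfigurationError("invalid passive parameters")
        if self.ca_out_mM <= 0 or self.ca_rest_mM <= 0 or self.ca_tau_ms <= 0:
            raise ConfigurationError("invalid calcium pool parameters")

    def leak_by_region(self) -> dict[str, float]:
        if isinstance(self.g_leak_mS_cm2, dict):
            if set(self.g_leak_mS_cm2) != set(REGIONS):
                raise ConfigurationError(f"leak dict must cover exactly regions {REGIONS}")
            return dict(self.g_leak_mS_cm2)
        return {r: float(self.g_leak_mS_cm2) for r in REGIONS}

    def na_shift_by_region(self) -> dict[str, float]:
        if isinstance(self.na_shift_mV, dict):
            if set(self.na_shift_mV) != set(REGIONS):
                raise ConfigurationError(f"na_shift dict must cover exactly regions {REGIONS}")
            return dict(self.na_shift_mV)
        return {r: float(self.na_shift_mV) for r in REGIONS}

    @property
    def nernst_prefactor_mV(self) -> float:
        """RT/2F in mV at the configured temperature."""
        return GAS_R * (273.15 + self.temperature_C) / (2.0 * FARADAY) * 1e3

    def e_ca_mV(self, ca_i_mM: np.ndarray) -> np.ndarray:
        return self.nernst_prefactor_mV * np.log(self.ca_out_mM / np.asarray(ca_i_mM))


# --------------------------------------------------------------------------
# Chain construction
# --------------------------------------------------------------------------


@dataclass
class CompartmentChain:
    """A path-connected chain of cylindrical compartments with state."""

    morphometry: Morphometry
    params: ChannelParams
    region_index: np.ndarray  # (n,) int8 into REGIONS
    centers_um: np.ndarray  # (n, 3)
    length_um: np.ndarray  # (n,)
    diameter_um: np.ndarray  # (n,)
    area_cm2: np.ndarray  # (n,) lateral membrane area
    axial_uS: np.ndarray  # (n-1,) conductance between i and i+1
    rest_V: np.ndarray  # (n,) resting potential
    rest_gates: np.ndarray  # (n, 6)
    rest_ca: np.ndarray  # (n,)

    @property
    def n_compartments(self) -> int:
        return len(self.region_index)

    def region_names(self) -> np.ndarray:
        return np.array(REGIONS)[self.region_index]

    def region_slice(self, region: str) -> slice:
        idx = np.nonzero(self.region_index == REGIONS.index(region))[0]
        return slice(int(idx[0]), int(idx[-1]) + 1)


def _polyline_arclength_points(path: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Points at arc lengths ``s`` along a 3D polyline (extends final segment)."""
    path = np.asarray(path, dtype=float)
    seg = np.diff(path, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    keep = seglen > 0
    seg, seglen = seg[keep], seglen[keep]
    starts = path[:-1][keep]
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
    frac = (s - cum[idx]) / seglen[idx]
    return starts[idx] + frac[:, None] * seg[idx]


_REST_CACHE: dict = {}


def _region_resting_state(params: ChannelParams, region: str) -> tuple[float, float]:
    """(V_rest, Ca_rest) of an isolated patch of the given region type."""
    g = params.gbar[region]
    shift = params.na_shift_by_region()[region]

    def ca_balance(v: float) -> float:
        # fixed point of the pool equation at holding potential v; influx is
        # clipped at zero exactly as in the integrator (pump handles efflux)
        ss = gate_steady_state(v, shift)
        c3 = float(ss["c"]) ** 3
        ca = params.ca_rest_mM
        depth = 1.0  # depth rescales influx only; resting pool is influx-free
        for _ in range(100):
            e_ca = float(params.e_ca_mV(ca))
            i_ca_dens = g.g_ca * c3 * (v - e_ca)  # uA/cm^2
            influx = max(-i_ca_dens / (2.0 * FARADAY * 0.1) / depth, 0.0)
            ca_new = max(params.ca_rest_mM + params.ca_tau_ms * influx, 1e-9)
            if abs(ca_new - ca) < 1e-13:
                return ca_new
            ca = 0.5 * (ca + ca_new)
        return ca

    def net_current(v: float) -> float:
        ss = gate_steady_state(v, shift)
        ca = ca_balance(v)
        kca_act = (ca / params.ca_dissoc_mM) ** 2 / (1 + (ca / params.ca_dissoc_mM) ** 2)
        i = g.g_na * float(ss["m"]) ** 3 * float(ss["h"]) * (v - params.e_na_mV)
        i += (g.g_k * float(ss["n"]) ** 4 + g.g_ka * float(ss["a"]) ** 3 * float(ss["ha"])) * (
            v - params.e_k_mV
        )
        i += g.g_kca * kca_act * (v - params.e_k_mV)
        i += g.g_ca * float(ss["c"]) ** 3 * (v - float(params.e_ca_mV(ca)))
        i += params.leak_by_region()[region] * (v - params.e_leak_mV)
        return i

    from scipy.optimize import brentq

    # stable equilibrium: net current crosses zero upward (outward above rest)
    vs = np.linspace(-90.0, -40.0, 101)
    fs = np.array([net_current(float(v)) for v in vs])
    idx = np.nonzero((fs[:-1] < 0) & (fs[1:] >= 0))[0]
    if len(idx) == 0:  # fall back to leak reversal
        return params.e_leak_mV, ca_balance(params.e_leak_mV)
    i = idx[0]
    v0 = float(brentq(net_current, float(vs[i]), float(vs[i + 1]), xtol=1e-9))
    return v0, ca_balance(v0)


def resting_state(
    params: ChannelParams, region_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-compartment resting (V, gates, Ca) from per-region equilibria."""
    v = np.empty(len(region_index), dtype=float)
    ca = np.empty(len(region_index), dtype=float)
    gates = np.empty((len(region_index), len(GATES)))
    shifts = params.na_shift_by_region()
    for ri, region in enumerate(REGIONS):
        mask = region_index == ri
        if not mask.any():
            continue
        v0, ca0 = _region_resting_state(params, region)
        v[mask] = v0
        ca[mask] = ca0
        ss = gate_steady_state(v0, shifts[region])
        gates[mask] = np.array([float(ss[g]) for g in GATES])
    return v, gates, ca


def build_cable(
    m: Morphometry,
    path_um: np.ndarray,
    params: ChannelParams | None = None,
    *,
    settle_ms: float = 200.0,
    settle_dt_ms: float = 0.01,
) -> CompartmentChain:
    """Lay compartments of fixed length along a 3D path (soma end first).

    The initial state is the per-region channel equilibrium relaxed by
    ``settle_ms`` of field-free integration (cached per parameter set), so a
    freshly built chain is quiescent to well under 0.5 mV.
    """
    params = params or ChannelParams()
    path = np.asarray(path_um, dtype=float)
    if path.ndim != 2 or path.shape[1] != 3 or len(path) < 2:
        raise ConfigurationError("path must be an (n, 3) polyline")
    seglen = np.linalg.norm(np.diff(path, axis=0), axis=1)
    if seglen.sum() + 1e-6 < m.total_length_um:
        raise GeometryError(
            f"path length {seglen.sum():.1f} um shorter than cable ({m.total_length_um:.0f} um)"
        )

    h = m.compartment_length_um
    region_index = []
    for region in m.region_order:
        ri = REGIONS.index(region)
        region_index.extend([ri] * int(round(m.lengths_um[region] / h)))
    region_index = np.asarray(region_index, dtype=np.int8)
    n = len(region_index)
    lengths = np.full(n, h)
    diam_by_region = np.array([m.diameters_um[r] for r in REGIONS])
    diams = diam_by_region[region_index]

    s_centers = (np.arange(n) + 0.5) * h
    centers = _polyline_arclength_points(path, s_centers)

    area_cm2 = np.pi * diams * lengths * 1e-8  # um^2 -> cm^2
    rho = params.axial_resistivity_ohm_cm
    r_half = (rho * (lengths / 2 * 1e-4)) / (np.pi * (diams / 2 * 1e-4) ** 2)  # Ohm
    axial_uS = 1.0 / (r_half[:-1] + r_half[1:]) * 1e6  # S -> uS

    key = (
        tuple(sorted((r, g.g_na, g.g_k, g.g_ka, g.g_kca, g.g_ca) for r, g in params.gbar.items())),
        params.e_na_mV,
        params.e_k_mV,
        params.e_leak_mV,
        tuple(sorted(params.leak_by_region().items())),
        tuple(sorted(params.na_shift_by_region().items())),
        params.cm_uF_cm2,
        params.axial_resistivity_ohm_cm,
        params.ca_tau_ms,
        params.ca_rest_mM,
        params.ca_shell_depth_um,
        settle_ms,
        region_index.tobytes(),
        diams.tobytes(),
    )
    chain = CompartmentChain(
        morphometry=m,
        params=params,
        region_index=region_index,
        centers_um=centers,
        length_um=lengths,
        diameter_um=diams,
        area_cm2=area_cm2,
        axial_uS=axial_uS,
        rest_V=np.zeros(n),
        rest_gates=np.zeros((n, len(GATES))),
        rest_ca=np.zeros(n),
    )
    if key in _REST_CACHE:
        v0, gates0, ca0 = _REST_CACHE[key]
    else:
        v0, gates0, ca0 = resting_state(params, region_index)
        chain.rest_V, chain.rest_gates, chain.rest_ca = v0, gates0, ca0
        if settle_ms > 0:
            wave = SampledWaveform(
                samples_uA=np.zeros(int(round(settle_ms / settle_dt_ms))),
                dt_ms=settle_dt_ms,
                pulse_onsets_ms=np.array([]),
            )
            res = simulate(chain, np.zeros(n), wave, dt_ms=settle_dt_ms, record_every=10**9)
            v0, gates0, ca0 = res.final_V, res.final_gates, res.final_ca
        _REST_CACHE[key] = (v0.copy(), gates0.copy(), ca0.copy())
    chain.rest_V, chain.rest_gates, chain.rest_ca = (v0.copy(), gates0.copy(), ca0.copy())
    return chain


# --------------------------------------------------------------------------
# Stimulus waveform
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusWaveform:
    """Biphasic charge-balanced pulse-train shape (amplitude supplied later)."""

    pulse_width_ms: float = 0.45
    interphase_gap_ms: float = 0.0
    frequency_hz: float = 20.0
    train_duration_ms: float = 250.0
    dt_ms: float = 0.005
    cathodic_first: bool = True
    anodic_width_ms: float | None = None  # None -> symmetric
    anodic_scale: float | None = None

    def __post_init__(self) -> None:
        if self.pulse_width_ms <= 0 or self.dt_ms <= 0:
            raise ConfigurationError("pulse width and dt must be positive")
        aw = self.anodic_width_ms if self.anodic_width_ms is not None else self.pulse_width_ms
        sc = self.anodic_scale if self.anodic_scale is not None else self.pulse_width_ms / aw
        if abs(aw * sc - self.pulse_width_ms) > 1e-9:
            raise ConfigurationError(
                "unbalanced waveform: anodic charge must equal cathodic charge"
            )
        if not self.cathodic_first:
            raise ConfigurationError("waveform must be cathodic-first")
        period = 1e3 / self.frequency_hz
        if self.pulse_duration_ms > period + 1e-9:
            raise ConfigurationError("pulse does not fit in the stimulation period")
        if self.pulse_duration_ms > self.train_duration_ms + 1e-9:
            raise ConfigurationError("pulse does not fit in the train")
        for width in (self.pulse_width_ms, aw, self.interphase_gap_ms):
            k = width / self.dt_ms
            if abs(k - round(k)) > 1e-6:
                raise ConfigurationError("dt must divide every phase width")

    @property
    def pulse_duration_ms(self) -> float:
        aw = self.anodic_width_ms if self.anodic_width_ms is not None else self.pulse_width_ms
        return self.pulse_width_ms + self.interphase_gap_ms + aw

    @property
    def n_pulses(self) -> int:
        period = 1e3 / self.frequency_hz
        return int(np.floor((self.train_duration_ms - self.pulse_duration_ms) / period + 1e-9)) + 1

    @property
    def pulse_onsets_ms(self) -> np.ndarray:
        period = 1e3 / self.frequency_hz
        return np.arange(self.n_pulses) * period


@dataclass(frozen=True)
class SampledWaveform:
    samples_uA: np.ndarray
    dt_ms: float
    pulse_onsets_ms: np.ndarray

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(len(self.samples_uA)) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return len(self.samples_uA) * self.dt_ms

    def charge_nC(self) -> float:
        return float(np.sum(self.samples_uA) * self.dt_ms)


def make_waveform(amplitude_uA: float, spec: StimulusWaveform | None = None) -> SampledWaveform:
    """Sample the biphasic train at ``spec.dt_ms``; cathodic (negative) first."""
    spec = spec or StimulusWaveform()
    dt = spec.dt_ms
    n = int(round(spec.train_duration_ms / dt))
    w = np.zeros(n)
    aw = spec.anodic_width_ms if spec.anodic_width_ms is not None else spec.pulse_width_ms
    sc = spec.anodic_scale if spec.anodic_scale is not None else spec.pulse_width_ms / aw
    n_cath = int(round(spec.pulse_width_ms / dt))
    n_gap = int(round(spec.interphase_gap_ms / dt))
    n_an = int(round(aw / dt))
    for onset in spec.pulse_onsets_ms:
        k = int(round(onset / dt))
        w[k : k + n_cath] = -amplitude_uA
        w[k + n_cath + n_gap : k + n_cath + n_gap + n_an] = amplitude_uA * sc
    return SampledWaveform(samples_uA=w, dt_ms=dt, pulse_onsets_ms=spec.pulse_onsets_ms.copy())


# --------------------------------------------------------------------------
# Integration kernel
# --------------------------------------------------------------------------

_VMIN, _VMAX, _VSTEP = -150.0, 100.0, 0.05


def _gate_tables(dt: float, na_shifts: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-region, per-gate lookup tables of x_inf(V) and exp(-dt/tau(V)).

    ``na_shifts`` holds one Na-activation shift per region (mV); the m-gate
    rates are evaluated at V - shift.
    """
    if na_shifts is None:
        na_shifts = np.zeros(len(REGIONS))
    v = np.arange(_VMIN, _VMAX + _VSTEP, _VSTEP)
    xinf = np.empty((len(na_shifts), len(GATES), len(v)))
    edt = np.empty_like(xinf)
    for ri, shift in enumerate(na_shifts):
        for gi, g in enumerate(GATES):
            fa, fb = RATE_FUNCTIONS[g]
            vv = v - shift if g == "m" else v
            a, b = fa(vv), fb(vv)
            xinf[ri, gi] = a / (a + b)
            edt[ri, gi] = np.exp(-dt * (a + b))
    return xinf, edt


@njit(cache=True, fastmath=True)
def _step_gates(V, gates, region, xinf, edt):
    n = V.shape[0]
    nmax = xinf.shape[2] - 1
    for i in range(n):
        u = (V[i] - _VMIN) / _VSTEP
        if u < 0.0:
            u = 0.0
        if u > nmax - 1e-9:
            u = nmax - 1e-9
        j = int(u)
        f = u - j
        ri = region[i]
        for gi in range(gates.shape[1]):
            xi = xinf[ri, gi, j] * (1 - f) + xinf[ri, gi, j + 1] * f
            ed = edt[ri, gi, j] * (1 - f) + edt[ri, gi, j + 1] * f
            gates[i, gi] = xi + (gates[i, gi] - xi) * ed


@njit(cache=True, fastmath=True)
def _integrate(
    V,
    gates,
    ca,
    region,
    area,
    cap_nF,
    gax,
    gbar_uS,  # (n, 5): na, k, ka, kca, ca
    gleak_uS,
    e_na,
    e_k,
    e_leak,
    ca_out,
    ca_rest,
    ca_tau,
    ca_depth_um,
    ca_dissoc,
    nernst_mV,
    ve_mV_per_uA,
    i_intra_nA,
    wave_uA,
    dt,
    xinf,
    edt,
    theta,
    v_spike,
    window_ends_step,
    require_every_window,
    rec_every,
    rec_idx,
    V_rec,
    ev_comp,
    ev_time,
):
    n = V.shape[0]
    nsteps = wave_uA.shape[0]
    lo = np.zeros(n)
    di = np.empty(n)
    up = np.zeros(n)
    rhs = np.empty(n)
    prevV = V.copy()
    n_ev = 0
    win_i = 0
    win_has_spike = False
    status = 0  # 0 ok, 1 aborted (missed window), 2 numeric failure
    t_fail = -1.0
    rec_row = 0
    ca_fac = 1.0 / (2.0 * FARADAY * 0.1)  # (uA/cm^2) / um -> mM/ms

    for step in range(nsteps):
        _step_gates(V, gates, region, xinf, edt)
        i_uA = wave_uA[step]
        for i in range(n):
            m3h = gates[i, 0] ** 3 * gates[i, 1]
            n4 = gates[i, 2] ** 4
            a3ha = gates[i, 3] ** 3 * gates[i, 4]
            c3 = gates[i, 5] ** 3
            e_ca = nernst_mV * math.log(ca_out / ca[i])
            g_na = gbar_uS[i, 0] * m3h
            g_k = gbar_uS[i, 1] * n4
            g_ka = gbar_uS[i, 2] * a3ha
            ratio = ca[i] / ca_dissoc
            g_kca = gbar_uS[i, 3] * ratio * ratio / (1.0 + ratio * ratio)
            g_ca = gbar_uS[i, 4] * c3

            # calcium pool: explicit influx (clipped at 0), implicit decay
            i_ca_dens = (g_ca * 1e-3 / area[i]) * (V[i] - e_ca)  # uA/cm^2
            influx = -i_ca_dens * ca_fac / ca_depth_um[i]
            if influx < 0.0:
                influx = 0.0
            ca[i] = (ca[i] + dt * (influx + ca_rest / ca_tau)) / (1.0 + dt / ca_tau)
            if ca[i] < 1e-9:
                ca[i] = 1e-9

            g_tot = g_na + g_k + g_ka + g_kca + g_ca + gleak_uS[i]
            g_e = (
                g_na * e_na
                + (g_k + g_ka + g_kca) * e_k
                + g_ca * e_ca
                + gleak_uS[i] * e_leak
            )
            cdt = cap_nF[i] / dt
            di[i] = cdt + theta * g_tot
            # theta-scheme: C/dt V+ + theta(gV+ - ge) = C/dt V - (1-theta)(gV - ge) + I
            rhs[i] = cdt * V[i] + g_e + i_intra_nA[i] - (1.0 - theta) * g_tot * V[i]

        for i in range(n - 1):
            g = gax[i]
            di[i] += theta * g
            di[i + 1] += theta * g
            up[i] = -theta * g
            lo[i + 1] = -theta * g
            ve_diff = (ve_mV_per_uA[i + 1] - ve_mV_per_uA[i]) * i_uA
            rhs[i] += g * ve_diff + (1.0 - theta) * g * (V[i + 1] - V[i])
            rhs[i + 1] += -g * ve_diff + (1.0 - theta) * g * (V[i] - V[i + 1])

        # Thomas solve (in place on di/rhs)
        for i in range(1, n):
            wfac = lo[i] / di[i - 1]
            di[i] -= wfac * up[i - 1]
            rhs[i] -= wfac * rhs[i - 1]
        V[n - 1] = rhs[n - 1] / di[n - 1]
        for i in range(n - 2, -1, -1):
            V[i] = (rhs[i] - up[i] * V[i + 1]) / di[i]

        t_now = (step + 1) * dt
        for i in range(n):
            if not np.isfinite(V[i]):
                return 2, t_now, n_ev, rec_row
            if prevV[i] < v_spike and V[i] >= v_spike:
                if n_ev < ev_comp.shape[0]:
                    ev_comp[n_ev] = i
                    ev_time[n_ev] = t_now
                    n_ev += 1
                win_has_spike = True
            prevV[i] = V[i]

        if rec_every > 0 and (step + 1) % rec_every == 0 and rec_row < V_rec.shape[0]:
            for jj in range(rec_idx.shape[0]):
                V_rec[rec_row, jj] = V[rec_idx[jj]]
            rec_row += 1

        if win_i < window_ends_step.shape[0] and (step + 1) == window_ends_step[win_i]:
            if require_every_window and not win_has_spike:
                return 1, t_now, n_ev, rec_row
            win_has_spike = False
            win_i += 1

    return status, t_fail, n_ev, rec_row


@dataclass
class SimResult:
    """Voltage traces, threshold-crossing events, and final state."""

    t_rec_ms: np.ndarray
    V_rec: np.ndarray  # (n_times, n_recorded)
    recorded_compartments: np.ndarray
    event_compartments: np.ndarray
    event_times_ms: np.ndarray
    final_V: np.ndarray
    final_gates: np.ndarray
    final_ca: np.ndarray
    dt_ms: float
    spike_threshold_mV: float
    aborted_missed_window: bool
    chain: CompartmentChain | None = None
    wave: SampledWaveform | None = None

    def to_frame(self):
        import pandas as pd

        cols = {f"c{int(i)}": self.V_rec[:, j] for j, i in enumerate(self.recorded_compartments)}
        return pd.DataFrame({"t_ms": self.t_rec_ms, **cols})


def simulate(
    chain: CompartmentChain,
    ve_unit_V_per_A: np.ndarray,
    wave: SampledWaveform,
    dt_ms: float | None = None,
    *,
    theta: float = 1.0,
    spike_threshold_mV: float = 0.0,
    record_every: int | None = None,
    record_compartments: Sequence[int] | None = None,
    abort_on_missed_pulse: bool = False,
    pulse_window_ends_ms: np.ndarray | None = None,
    i_intra_nA: np.ndarray | None = None,
    max_events: int = 200_000,
) -> SimResult:
    """Integrate the cable under ``Ve(t) = ve_unit * I(t)``.

    ``theta`` = 1 is backward Euler, 0.5 Crank-Nicolson (gating by
    Rush-Larsen either way).  ``ve_unit_V_per_A`` is the unit-current
    extracellular potential at the compartment centres (V/A); the waveform
    is in uA.  With ``abort_on_missed_pulse`` the integration stops at the
    end of the first pulse window containing no threshold crossing (used by
    the bisection search to cut subthreshold runs short).
    """
    n = chain.n_compartments
    ve_unit_V_per_A = np.ascontiguousarray(ve_unit_V_per_A, dtype=float)
    if ve_unit_V_per_A.shape != (n,):
        raise ConfigurationError("ve_unit length must equal compartment count")
    dt = float(dt_ms if dt_ms is not None else wave.dt_ms)

    # resample the waveform onto dt (piecewise-constant)
    if abs(dt - wave.dt_ms) < 1e-12:
        w = np.ascontiguousarray(wave.samples_uA, dtype=float)
        nsteps = len(w)
    else:
        nsteps = int(round(wave.duration_ms / dt))
        idx = np.minimum(
            np.floor(np.arange(nsteps) * dt / wave.dt_ms + 1e-9).astype(np.int64),
            len(wave.samples_uA) - 1,
        )
        w = np.ascontiguousarray(wave.samples_uA[idx], dtype=float)

    shifts = chain.params.na_shift_by_region()
    xinf, edt = _gate_tables(dt, np.array([shifts[r] for r in REGIONS]))
    gbar_uS = np.empty((n, 5))
    for ri, region in enumerate(REGIONS):
        mask = chain.region_index == ri
        g = chain.params.gbar[region]
        for ci, dens in enumerate((g.g_na, g.g_k, g.g_ka, g.g_kca, g.g_ca)):
            gbar_uS[mask, ci] = dens * 1e3 * chain.area_cm2[mask]  # mS/cm^2 * cm^2 -> uS
    leak = chain.params.leak_by_region()
    gleak_dens = np.array([leak[r] for r in REGIONS])[chain.region_index]
    gleak_uS = gleak_dens * 1e3 * chain.area_cm2
    cap_nF = chain.params.cm_uF_cm2 * chain.area_cm2 * 1e3  # uF/cm^2 * cm^2 -> nF
    depth = (
        np.full(n, float(chain.params.ca_shell_depth_um))
        if chain.params.ca_shell_depth_um
        else chain.diameter_um / 4.0
    )

    if pulse_window_ends_ms is None:
        onsets = wave.pulse_onsets_ms
        ends = np.concatenate([onsets[1:], [wave.duration_ms]]) if len(onsets) else np.array([])
    else:
        ends = np.asarray(pulse_window_ends_ms, dtype=float)
    window_ends_step = np.round(np.asarray(ends) / dt).astype(np.int64)

    if record_every is None:
        record_every = max(1, int(round(0.025 / dt)))
    if record_compartments is None:
        rec_idx = np.arange(0, n, max(1, n // 600), dtype=np.int64)
    else:
        rec_idx = np.asarray(record_compartments, dtype=np.int64)
    n_rec_rows = nsteps // record_every if record_every <= nsteps else 0
    V_rec = np.zeros((n_rec_rows, len(rec_idx)))
    ev_comp = np.full(max_events, -1, dtype=np.int64)
    ev_time = np.zeros(max_events)

    V = chain.rest_V.copy()
    gates = chain.rest_gates.copy()
    ca = chain.rest_ca.copy()
    ve_mV_per_uA = ve_unit_V_per_A * 1e-3  # (V/A) * uA = uV -> mV
    if i_intra_nA is None:
        i_intra = np.zeros(n)
    else:
        i_intra = np.ascontiguousarray(i_intra_nA, dtype=float)
        if i_intra.shape != (n,):
            raise ConfigurationError("i_intra_nA length must equal compartment count")

    status, t_fail, n_ev, rec_rows = _integrate(
        V,
        gates,
        ca,
        chain.region_index.astype(np.int64),
        chain.area_cm2,
        cap_nF,
        chain.axial_uS,
        gbar_uS,
        gleak_uS,
        chain.params.e_na_mV,
        chain.params.e_k_mV,
        chain.params.e_leak_mV,
        chain.params.ca_out_mM,
        chain.params.ca_rest_mM,
        chain.params.ca_tau_ms,
        depth,
        chain.params.ca_dissoc_mM,
        chain.params.nernst_prefactor_mV,
        ve_mV_per_uA,
        i_intra,
        w,
        dt,
        xinf,
        edt,
        theta,
        spike_threshold_mV,
        window_ends_step,
        abort_on_missed_pulse,
        record_every,
        rec_idx,
        V_rec,
        ev_comp,
        ev_time,
    )
    if status == 2:
        raise IntegrationError(f"integration diverged (NaN/Inf) at t = {t_fail:.3f} ms")
    t_rec = (np.arange(rec_rows) + 1) * record_every * dt
    return SimResult(
        t_rec_ms=t_rec,
        V_rec=V_rec[:rec_rows],
        recorded_compartments=rec_idx,
        event_compartments=ev_comp[:n_ev].copy(),
        event_times_ms=ev_time[:n_ev].copy(),
        final_V=V,
        final_gates=gates,
        final_ca=ca,
        dt_ms=dt,
        spike_threshold_mV=spike_threshold_mV,
        aborted_missed_window=(status == 1),
        chain=chain,
        wave=wave,
    )


# --------------------------------------------------------------------------
# Spike analysis
# --------------------------------------------------------------------------


def detect_spikes(
    sim: SimResult,
    pulse_onsets_ms: np.ndarray | None = None,
    *,
    refractory_ms: float = 1.0,
) -> dict:
    """Per-compartment spike times (refractory-merged) and per-pulse flags.

    A pulse window spans [onset, next onset); a pulse "has a spike" iff any
    compartment crosses the detection level upward inside its window.
    """
    comp = sim.event_compartments
    times = sim.event_times_ms
    per_comp: dict[int, np.ndarray] = {}
    for c in np.unique(comp):
        t = np.sort(times[comp == c])
        merged = [t[0]]
        for ti in t[1:]:
            if ti - merged[-1] >= refractory_ms:
                merged.append(ti)
        per_comp[int(c)] = np.array(merged)

    spikes_per_pulse = None
    if pulse_onsets_ms is not None and len(pulse_onsets_ms) > 0:
        onsets = np.asarray(pulse_onsets_ms, dtype=float)
        dur = sim.wave.duration_ms if sim.wave is not None else (
            float(times.max()) + 1.0 if len(times) else float(onsets[-1]) + 1.0
        )
        edges = np.concatenate([onsets, [dur]])
        all_spikes = (
            np.sort(np.concatenate(list(per_comp.values()))) if per_comp else np.array([])
        )
        spikes_per_pulse = np.array(
            [
                int(np.any((all_spikes >= a) & (all_spikes < b)))
                for a, b in zip(edges[:-1], edges[1:])
            ]
        )
    return {"per_compartment": per_comp, "spikes_per_pulse": spikes_per_pulse}


def initiation_site(sim: SimResult) -> dict | None:
    """Region/compartment of the earliest crossing (ties -> smaller index).

    Returns None when no spike occurred (distinct from an error).
    """
    if len(sim.event_times_ms) == 0:
        return None
    t0 = sim.event_times_ms.min()
    cands = sim.event_compartments[sim.event_times_ms == t0]
    comp = int(cands.min())
    chain = sim.chain
    region = REGIONS[chain.region_index[comp]] if chain is not None else None
    return {"compartment": comp, "region": region, "time_ms": float(t0)}
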