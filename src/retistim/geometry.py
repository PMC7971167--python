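"""Parametric patient geometry: eye, retina, electrode array, fibrotic capsule.

The geometry is a layered slab described by smooth height-fields rather than a
whole-eye mesh: the retinal surface is a (possibly undulating) sheet near
z = 0, the retina extends below it with a laterally varying thickness, the
sclera lies underneath, and the electrode array floats in the vitreous above
with an optional fibrotic capsule filling the gap.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "EyeParams",
    "ElectrodeArray",
    "RetinalSurface",
    "FibroticCapsule",
    "PatientGeometry",
    "SynthRanges",
    "GeometryError",
    "ConfigurationError",
    "generate_synthetic_patient",
    "electrode_retina_distances",
]


class GeometryError(ValueError):
    """Raised when a geometric configuration is physically inconsistent."""


class ConfigurationError(ValueError):
    """Raised when user-supplied parameter ranges or settings are invalid."""


# --------------------------------------------------------------------------
# Smooth 2D fields (thickness / surface height / capsule thickness)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicField2D:
    """Smooth scalar field: ``base + sum_k amp_k * cos(kx x + ky y + phase_k)``.

    Wavenumbers are in rad/um.  The gradient is bounded by
    ``sum_k |amp_k| * |k|``, so smoothness constraints can be checked
    analytically.  An empty term list is a constant field.
    """

    base: float
    amplitudes: tuple[float, ...] = ()
    wavenumbers: tuple[tuple[float, float], ...] = ()
    phases: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (len(self.amplitudes) == len(self.wavenumbers) == len(self.phases)):
            raise ConfigurationError("amplitudes, wavenumbers and phases must align")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(np.broadcast(x, y).shape, self.base, dtype=float)
        for a, (kx, ky), p in zip(self.amplitudes, self.wavenumbers, self.phases):
            out += a * np.cos(kx * x + ky * y + p)
        return out

    @property
    def amplitude_sum(self) -> float:
        return float(sum(abs(a) for a in self.amplitudes))

    @property
    def gradient_bound(self) -> float:
        """Upper bound on |grad field| (per um)."""
        return float(
            sum(abs(a) * float(np.hypot(kx, ky)) for a, (kx, ky) in zip(self.amplitudes, self.wavenumbers))
        )

    def bounds(self) -> tuple[float, float]:
        """Conservative (min, max) of the field value."""
        return self.base - self.amplitude_sum, self.base + self.amplitude_sum

    def to_dict(self) -> dict:
        return {
            "base": self.base,
            "amplitudes": list(self.amplitudes),
            "wavenumbers": [list(k) for k in self.wavenumbers],
            "phases": list(self.phases),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HarmonicField2D":
        return cls(
            base=float(d["base"]),
            amplitudes=tuple(float(a) for a in d["amplitudes"]),
            wavenumbers=tuple((float(k[0]), float(k[1])) for k in d["wavenumbers"]),
            phases=tuple(float(p) for p in d["phases"]),
        )


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EyeParams:
    """Global eye dimensions (mm) and implant-case pose (degrees)."""

    axial_length_mm: float = 24.0
    vitreous_diameter_x_mm: float = 22.0
    vitreous_diameter_y_mm: float = 22.0
    vitreous_diameter_z_mm: float = 22.5
    anterior_chamber_depth_mm: float = 3.2
    eoc_angle_coronal_deg: float = 35.0
    eye_side: str = "left"

    def __post_init__(self) -> None:
        lengths = (
            self.axial_length_mm,
            self.vitreous_diameter_x_mm,
            self.vitreous_diameter_y_mm,
            self.vitreous_diameter_z_mm,
            self.anterior_chamber_depth_mm,
        )
        if any(v <= 0 for v in lengths):
            raise ConfigurationError("all eye lengths must be positive")
        if self.anterior_chamber_depth_mm >= self.axial_length_mm:
            raise ConfigurationError("anterior chamber depth must be < axial length")
        if not -180.0 <= self.eoc_angle_coronal_deg <= 180.0:
            raise ConfigurationError("EOC angle must lie in [-180, 180] degrees")
        if self.eye_side not in ("left", "right"):
            raise ConfigurationError("eye_side must be 'left' or 'right'")


_ROW_LETTERS = string.ascii_uppercase


@dataclass(frozen=True)
class ElectrodeArray:
    """Planar electrode grid.

    Rows are lettered (A..), columns numbered (1..).  The long axis (columns)
    is the local u axis, rows run along v.  ``tilt_long_deg`` rotates the
    plane about the long axis (changing the gap across rows);
    ``tilt_short_deg`` rotates about the short axis (changing it across
    columns).  ``standoff_um`` is the gap between the array plane and the
    retinal surface at the array centre, measured along the plane normal.
    """

    rows: int = 6
    cols: int = 10
    electrode_diameter_um: float = 200.0
    pitch_um: float = 575.0
    center_position_mm: tuple[float, float] = (0.0, 0.0)
    tilt_long_deg: float = 0.0
    tilt_short_deg: float = 0.0
    standoff_um: float = 50.0
    metal_thickness_um: float = 20.0
    substrate_thickness_um: float = 60.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("array must have at least one row and column")
        if self.rows > len(_ROW_LETTERS):
            raise ConfigurationError("too many rows for letter labels")
        if not 0 < self.electrode_diameter_um < self.pitch_um:
            raise ConfigurationError("electrode diameter must be in (0, pitch)")

    @property
    def labels(self) -> list[str]:
        """Row-major labels: A1 .. A<cols>, B1 .. (bijective with (row, col))."""
        return [f"{_ROW_LETTERS[r]}{c + 1}" for r in range(self.rows) for c in range(self.cols)]

    def label_to_rowcol(self, label: str) -> tuple[int, int]:
        row = _ROW_LETTERS.index(label[0].upper())
        col = int(label[1:]) - 1
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise KeyError(f"electrode label {label!r} outside {self.rows}x{self.cols} array")
        return row, col

    def local_uv(self, label: str) -> tuple[float, float]:
        """In-plane electrode centre (u along columns, v along rows), um."""
        row, col = self.label_to_rowcol(label)
        u = (col - (self.cols - 1) / 2.0) * self.pitch_um
        v = ((self.rows - 1) / 2.0 - row) * self.pitch_um  # row A on top (+v)
        return u, v

    def normal(self) -> np.ndarray:
        """Unit normal of the tilted array plane, pointing toward the retina (+z)."""
        return _tilt_rotation(self.tilt_long_deg, self.tilt_short_deg) @ np.array([0.0, 0.0, 1.0])

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        rot = _tilt_rotation(self.tilt_long_deg, self.tilt_short_deg)
        return rot @ np.array([1.0, 0.0, 0.0]), rot @ np.array([0.0, 1.0, 0.0])


def _tilt_rotation(tilt_long_deg: float, tilt_short_deg: float) -> np.ndarray:
    """Rotation taking the untilted array frame to the scene frame."""
    a = np.deg2rad(tilt_long_deg)
    b = np.deg2rad(tilt_short_deg)
    rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    return rx @ ry


@dataclass(frozen=True)
class RetinalSurface:
    """Inner-limiting-membrane height and retinal thickness over the footprint.

    ``surface_height_um(x, y)`` is the z coordinate of the inner retinal
    surface (positive = recessed away from the vitreous); ``thickness_um``
    is the retina's local thickness.  Both are smooth harmonic fields with
    analytically bounded gradients.
    """

    thickness_um: HarmonicField2D = field(default_factory=lambda: HarmonicField2D(200.0))
    surface_height_um: HarmonicField2D = field(default_factory=lambda: HarmonicField2D(0.0))
    lateral_extent_mm: float = 8.0
    max_gradient: float = 0.5  # dimensionless (um per um) smoothness cap

    def __post_init__(self) -> None:
        tmin, _ = self.thickness_um.bounds()
        if tmin <= 0:
            raise ConfigurationError("retinal thickness must be positive everywhere")
        for f in (self.thickness_um, self.surface_height_um):
            if f.gradient_bound > self.max_gradient:
                raise ConfigurationError("surface field gradient exceeds smoothness bound")

    def surface_z(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        return self.surface_height_um(x_um, y_um)

    def thickness(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        return self.thickness_um(x_um, y_um)


@dataclass(frozen=True)
class FibroticCapsule:
    """Fibrotic tissue layer between the array plane and the retina."""

    thickness_um: HarmonicField2D = field(default_factory=lambda: HarmonicField2D(0.0))
    lateral_margin_um: float = 100.0

    def __post_init__(self) -> None:
        tmin, _ = self.thickness_um.bounds()
        if tmin < 0:
            raise ConfigurationError("capsule thickness must be non-negative")
        if self.lateral_margin_um < 0:
            raise ConfigurationError("capsule margin must be non-negative")


@dataclass(frozen=True)
class PatientGeometry:
    """Complete synthetic patient scene.

    ``optic_disc_position_mm`` / ``fovea_position_mm`` are retinal-plane
    coordinates in the scene frame (scene origin = array centre).
    """

    eye: EyeParams = field(default_factory=EyeParams)
    array: ElectrodeArray = field(default_factory=ElectrodeArray)
    surface: RetinalSurface = field(default_factory=RetinalSurface)
    capsule: FibroticCapsule = field(default_factory=FibroticCapsule)
    optic_disc_position_mm: tuple[float, float] = (2.3, 0.6)
    fovea_position_mm: tuple[float, float] = (-2.0, 0.0)

    def __post_init__(self) -> None:
        if np.allclose(self.optic_disc_position_mm, self.fovea_position_mm):
            raise ConfigurationError("optic disc and fovea must be distinct")
        half_u = (self.array.cols - 1) / 2 * self.array.pitch_um + self.array.pitch_um
        half_v = (self.array.rows - 1) / 2 * self.array.pitch_um + self.array.pitch_um
        ext = self.surface.lateral_extent_mm * 1e3 / 2
        if half_u > ext or half_v > ext:
            raise ConfigurationError("array footprint exceeds retinal surface extent")

    # -- array pose in scene coordinates -----------------------------------

    def array_center_xyz_um(self) -> np.ndarray:
        """Array-plane centre in scene um, standoff along the plane normal."""
        cx, cy = (np.asarray(self.array.center_position_mm) * 1e3)
        n = self.array.normal()
        # anchor: the point on the retina hit by the normal ray from the centre
        anchor = _normal_ray_hit(self.surface, np.array([cx, cy, 0.0]), n)
        return anchor - self.array.standoff_um * n

    def electrode_positions_um(self) -> dict[str, np.ndarray]:
        """Scene-frame 3D centres (um) of every electrode disc."""
        center = self.array_center_xyz_um()
        eu, ev = self.array.axes()
        out: dict[str, np.ndarray] = {}
        for label in self.array.labels:
            u, v = self.array.local_uv(label)
            out[label] = center + u * eu + v * ev
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["surface"]["thickness_um"] = self.surface.thickness_um.to_dict()
        d["surface"]["surface_height_um"] = self.surface.surface_height_um.to_dict()
        d["capsule"]["thickness_um"] = self.capsule.thickness_um.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PatientGeometry":
        surf = dict(d["surface"])
        surf["thickness_um"] = HarmonicField2D.from_dict(surf["thickness_um"])
        surf["surface_height_um"] = HarmonicField2D.from_dict(surf["surface_height_um"])
        cap = dict(d["capsule"])
        cap["thickness_um"] = HarmonicField2D.from_dict(cap["thickness_um"])
        arr = dict(d["array"])
        arr["center_position_mm"] = tuple(arr["center_position_mm"])
        return cls(
            eye=EyeParams(**d["eye"]),
            array=ElectrodeArray(**arr),
            surface=RetinalSurface(**surf),
            capsule=FibroticCapsule(**cap),
            optic_disc_position_mm=tuple(d["optic_disc_position_mm"]),
            fovea_position_mm=tuple(d["fovea_position_mm"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PatientGeometry":
        return cls.from_dict(json.loads(text))


# --------------------------------------------------------------------------
# Electrode-retina distances
# --------------------------------------------------------------------------


def _normal_ray_hit(
    surface: RetinalSurface, origin: np.ndarray, n: np.ndarray, max_range_um: float = 5e3
) -> np.ndarray:
    """First intersection of the ray origin + t*n with the retinal surface."""

    def f(t: float) -> float:
        p = origin + t * n
        return p[2] - float(surface.surface_z(p[0], p[1]))

    ts = np.linspace(-max_range_um, max_range_um, 2001)
    vals = np.array([f(t) for t in ts])
    sign_change = np.nonzero(np.diff(np.sign(vals)) > 0)[0]
    if len(sign_change) == 0:
        raise GeometryError("normal ray does not intersect the retinal surface")
    i = sign_change[0]
    a, b = ts[i], ts[i + 1]
    for _ in range(60):
        m = 0.5 * (a + b)
        if f(m) < 0:
            a = m
        else:
            b = m
    return origin + 0.5 * (a + b) * n


def electrode_retina_distances(g: PatientGeometry) -> dict[str, float]:
    """Gap (um) from each electrode centre, along the array-plane normal, to
    the inner retinal surface.  Raises :class:`GeometryError` if any electrode
    sits at or below the surface (interpenetration)."""
    n = g.array.normal()
    positions = g.electrode_positions_um()
    labels = list(positions)
    pos = np.stack([positions[k] for k in labels])  # (m, 3)

    def f(t: np.ndarray) -> np.ndarray:
        p = pos + t[:, None] * n[None, :]
        return p[:, 2] - g.surface.surface_z(p[:, 0], p[:, 1])

    m = len(labels)
    if np.any(f(np.zeros(m)) > 1e-9):
        bad = labels[int(np.argmax(f(np.zeros(m))))]
        raise GeometryError(f"electrode {bad} penetrates the retinal surface")
    lo, hi = np.zeros(m), np.full(m, 5e3)
    if np.any(f(hi) < 0):
        raise GeometryError("no retinal surface within range along the array normal")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = f(mid) < 0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    t_hit = 0.5 * (lo + hi)
    return {label: float(t) for label, t in zip(labels, t_hit)}


# --------------------------------------------------------------------------
# Synthetic patient generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthRanges:
    """Sampling ranges for synthetic patients (min, max pairs)."""

    thickness_um: tuple[float, float] = (100.0, 350.0)
    gap_um: tuple[float, float] = (0.0, 300.0)
    tilt_deg: tuple[float, float] = (-2.0, 2.0)
    capsule_um: tuple[float, float] = (0.0, 100.0)
    surface_ripple_um: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        for name in ("thickness_um", "gap_um", "tilt_deg", "capsule_um", "surface_ripple_um"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"range {name}: min > max")


def _sample_field(
    rng: np.random.Generator,
    lo: float,
    hi: float,
    n_modes: int,
    min_wavelength_um: float = 1500.0,
) -> HarmonicField2D:
    """Random smooth field whose values stay inside [lo, hi] by construction."""
    span = hi - lo
    if span == 0 or n_modes == 0:
        return HarmonicField2D(base=float(rng.uniform(lo, hi)))
    amp_total = rng.uniform(0.0, span / 2.0)
    base = rng.uniform(lo + amp_total, hi - amp_total)
    raw = rng.uniform(0.3, 1.0, n_modes)
    amps = amp_total * raw / raw.sum()
    ks = []
    for _ in range(n_modes):
        wavelength = rng.uniform(min_wavelength_um, 4 * min_wavelength_um)
        theta = rng.uniform(0, 2 * np.pi)
        k = 2 * np.pi / wavelength
        ks.append((k * np.cos(theta), k * np.sin(theta)))
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    return HarmonicField2D(
        base=float(base),
        amplitudes=tuple(float(a) for a in amps),
        wavenumbers=tuple(ks),
        phases=tuple(float(p) for p in phases),
    )


def generate_synthetic_patient(
    seed: int,
    ranges: SynthRanges | None = None,
    *,
    n_field_modes: int = 3,
) -> PatientGeometry:
    """Draw a random patient geometry, deterministic per seed.

    The retinal thickness field, surface ripple, array tilt and fibrotic
    capsule are sampled within ``ranges``; the array standoff is then chosen
    such that every electrode-retina gap falls inside ``ranges.gap_um``.
    """
    ranges = ranges or SynthRanges()
    rng = np.random.default_rng(seed)

    thickness = _sample_field(rng, *ranges.thickness_um, n_modes=n_field_modes)
    ripple_amp = rng.uniform(*ranges.surface_ripple_um)
    surface_h = _sample_field(rng, -ripple_amp, ripple_amp, n_modes=n_field_modes)
    surface = RetinalSurface(thickness_um=thickness, surface_height_um=surface_h)

    capsule = FibroticCapsule(
        thickness_um=_sample_field(rng, *ranges.capsule_um, n_modes=max(0, n_field_modes - 1)),
        lateral_margin_um=float(rng.uniform(50.0, 200.0)),
    )

    tilt_long = float(rng.uniform(*ranges.tilt_deg))
    tilt_short = float(rng.uniform(*ranges.tilt_deg))
    eye = EyeParams(
        axial_length_mm=float(rng.uniform(22.0, 26.0)),
        vitreous_diameter_x_mm=float(rng.uniform(20.5, 23.5)),
        vitreous_diameter_y_mm=float(rng.uniform(20.5, 23.5)),
        vitreous_diameter_z_mm=float(rng.uniform(21.0, 24.0)),
        anterior_chamber_depth_mm=float(rng.uniform(2.8, 3.8)),
        eoc_angle_coronal_deg=float(rng.uniform(20.0, 50.0)),
        eye_side="left" if rng.random() < 0.5 else "right",
    )

    gap_lo, gap_hi = ranges.gap_um
    for shrink in (1.0, 0.5, 0.25, 0.1, 0.0):
        # probe well above the surface so the gap variation can be measured
        array = ElectrodeArray(
            tilt_long_deg=tilt_long * shrink,
            tilt_short_deg=tilt_short * shrink,
            standoff_um=gap_hi + 500.0,
        )
        probe = PatientGeometry(eye=eye, array=array, surface=surface, capsule=capsule)
        try:
            d0 = np.array(list(electrode_retina_distances(probe).values()))
        except GeometryError:
            continue
        rel = d0 - probe.array.standoff_um  # gap variation relative to centre standoff
        lo_s = gap_lo - rel.min()
        hi_s = gap_hi - rel.max()
        lo_s = max(lo_s, 0.0)
        if lo_s > hi_s:
            continue
        standoff = float(rng.uniform(lo_s, hi_s))
        # verify; on an undulating surface the shift with standoff is only
        # approximately linear, so nudge until every gap is inside the range
        for _ in range(8):
            array = dataclasses.replace(array, standoff_um=standoff)
            cand = PatientGeometry(eye=eye, array=array, surface=surface, capsule=capsule)
            gaps = np.array(list(electrode_retina_distances(cand).values()))
            under, over = gap_lo - gaps.min(), gaps.max() - gap_hi
            if under <= 1e-6 and over <= 1e-6:
                return cand
            standoff += under if under > 0 else -over
            if standoff < 0:
                break
    raise GeometryError("could not place the array within the requested gap range")
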