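"""RGC population placement and nerve-fiber axon routing.

Somas are spread under an electrode by Lloyd's algorithm (centroidal Voronoi
relaxation clipped to a sampling disk).  Axons follow a modified-polar-spiral
nerve-fiber-bundle model: in polar coordinates ``(r, phi)`` centred on the
optic disc, a bundle launched at angle ``phi0`` evolves as

    phi(r) = phi0 + b(phi0) * (r - r0) ** c(phi0)

with separate coefficient branches for the superior and inferior hemifields
and a power-law/tanh parameterization taken from the published fits; all
coefficients are configuration data so alternative fits can be swapped in.
Bundles never cross the horizontal raphe (the temporal midline through the
fovea).

Frames: scene coordinates are mm on the retinal plane with x pointing
temporal->nasal (the optic disc sits at positive x) and y inferior->superior.
The bundle model works in degrees of a fovea-centred frame whose polar axis
points nasally from the disc centre.  ``mm_per_degree`` converts between the
two (default 0.286 mm/deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .geometry import ConfigurationError, RetinalSurface

__all__ = [
    "JansoniusParams",
    "SomaPlacement",
    "AxonTrajectory",
    "lloyd_disk_sample",
    "jansonius_path",
    "embed_neuron",
    "axon_slope_range",
]


# --------------------------------------------------------------------------
# Lloyd sampling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SomaPlacement:
    """Soma positions (um, scene frame) under one electrode."""

    electrode: str
    points_um: np.ndarray  # (n, 2)
    center_um: tuple[float, float]
    radius_um: float
    seed: int

    def __post_init__(self) -> None:
        d = np.linalg.norm(self.points_um - np.asarray(self.center_um), axis=1)
        if np.any(d > self.radius_um + 1e-6):
            raise ConfigurationError("soma points must lie inside the sampling disk")


def lloyd_disk_sample(
    n: int,
    radius_um: float,
    seed: int,
    iterations: int = 50,
    *,
    center_um: tuple[float, float] = (0.0, 0.0),
    grid_resolution: int = 160,
) -> SomaPlacement:
    """Uniform-coverage points in a disk via discretized Lloyd relaxation.

    A dense grid of disk points is repeatedly assigned to the nearest seed
    and seeds move to their cell centroids (a centroidal Voronoi iteration).
    Deterministic per seed.
    """
    if n < 1 or radius_um <= 0:
        raise ConfigurationError("need n >= 1 and a positive radius")
    rng = np.random.default_rng(seed)
    rr = radius_um * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([rr * np.cos(th), rr * np.sin(th)])

    ax = np.linspace(-radius_um, radius_um, grid_resolution)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    inside = gx**2 + gy**2 <= radius_um**2
    grid = np.column_stack([gx[inside], gy[inside]])

    for _ in range(iterations):
        owner = cKDTree(pts).query(grid)[1]
        sums = np.zeros((n, 2))
        counts = np.zeros(n)
        np.add.at(sums, owner, grid)
        np.add.at(counts, owner, 1.0)
        moved = counts > 0
        pts[moved] = sums[moved] / counts[moved, None]

    # keep strictly inside and pairwise distinct
    norm = np.linalg.norm(pts, axis=1)
    over = norm > radius_um
    pts[over] *= (radius_um / norm[over])[:, None]
    return SomaPlacement(
        electrode="",
        points_um=pts + np.asarray(center_um, dtype=float),
        center_um=tuple(float(c) for c in center_um),
        radius_um=float(radius_um),
        seed=int(seed),
    )


# --------------------------------------------------------------------------
# Nerve-fiber bundle model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class JansoniusParams:
    """Coefficients of the nerve-fiber-bundle spiral model (config data).

    ``beta/c`` branches: b = exp(beta(phi0)) superiorly and -exp(beta(phi0))
    inferiorly, with beta and c given by tanh ramps in phi0 (degrees).
    """

    disc_center_deg: tuple[float, float] = (15.0, 2.0)  # fovea frame, x nasal
    r0_deg: float = 4.0
    mm_per_degree: float = 0.286
    sup_beta_0: float = -1.9
    sup_beta_amp: float = 3.9
    sup_beta_center: float = 121.0
    sup_beta_width: float = 14.0
    sup_c_0: float = 1.9
    sup_c_amp: float = 1.4
    inf_beta_0: float = 0.7
    inf_beta_amp: float = 1.5
    inf_beta_center: float = 90.0
    inf_beta_width: float = 25.0
    inf_c_0: float = 1.0
    inf_c_amp: float = 0.5
    r_step_deg: float = 0.1
    max_r_deg: float = 80.0

    def bc(self, phi0_deg: float) -> tuple[float, float]:
        """(b, c) for a bundle launched at phi0 (deg; >0 superior)."""
        if phi0_deg >= 0:
            beta = self.sup_beta_0 + self.sup_beta_amp * np.tanh(
                -(phi0_deg - self.sup_beta_center) / self.sup_beta_width
            )
            c = self.sup_c_0 + self.sup_c_amp * np.tanh(
                (phi0_deg - self.sup_beta_center) / self.sup_beta_width
            )
            return float(np.exp(beta)), float(c)
        p = -phi0_deg
        beta = self.inf_beta_0 + self.inf_beta_amp * np.tanh(
            -(p - self.inf_beta_center) / self.inf_beta_width
        )
        c = self.inf_c_0 + self.inf_c_amp * np.tanh((p - self.inf_beta_center) / self.inf_beta_width)
        return float(-np.exp(beta)), float(c)

    def mirrored_inferior(self) -> "JansoniusParams":
        """Parameter set whose inferior branch mirrors the superior one."""
        return JansoniusParams(
            disc_center_deg=self.disc_center_deg,
            r0_deg=self.r0_deg,
            mm_per_degree=self.mm_per_degree,
            sup_beta_0=self.sup_beta_0,
            sup_beta_amp=self.sup_beta_amp,
            sup_beta_center=self.sup_beta_center,
            sup_beta_width=self.sup_beta_width,
            sup_c_0=self.sup_c_0,
            sup_c_amp=self.sup_c_amp,
            inf_beta_0=self.sup_beta_0,
            inf_beta_amp=self.sup_beta_amp,
            inf_beta_center=self.sup_beta_center,
            inf_beta_width=self.sup_beta_width,
            inf_c_0=self.sup_c_0,
            inf_c_amp=self.sup_c_amp,
            r_step_deg=self.r_step_deg,
            max_r_deg=self.max_r_deg,
        )


@dataclass
class AxonTrajectory:
    """Retinal-plane axon course from a soma to the optic disc (scene mm)."""

    polyline_mm: np.ndarray  # (k, 2), first point = soma, last at disc edge
    slopes: np.ndarray  # (k-1,) dy/dx per segment, coronal convention
    phi0_deg: float
    degenerate: bool = False
    raphe_flagged: bool = False

    @property
    def arc_length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.polyline_mm, axis=0), axis=1).sum())


def _phi_of_r(phi0: float, r: np.ndarray, params: JansoniusParams) -> np.ndarray:
    b, c = params.bc(phi0)
    return phi0 + b * np.maximum(np.asarray(r) - params.r0_deg, 0.0) ** c


def _solve_phi0(r_p: float, phi_p: float, params: JansoniusParams) -> tuple[float, bool]:
    """Launch angle of the bundle through (r_p, phi_p); (phi0, degenerate)."""
    if abs(phi_p) < 1e-9:
        return 0.0, True  # on the nasal horizontal: the degenerate radial bundle
    sign = 1.0 if phi_p > 0 else -1.0

    def g(phi0: float) -> float:
        return float(_phi_of_r(phi0, np.array([r_p]), params)[0]) - phi_p

    # phi moves away from the raphe monotonically with r, so phi0 lies
    # between 0 and phi_p (superior) / between phi_p and 0 (inferior)
    lo, hi = (1e-9, phi_p) if sign > 0 else (phi_p, -1e-9)
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        # no bundle reaches this point (nasal fan gap): degenerate radial
        return (0.0, True) if abs(glo) < abs(ghi) else (phi_p, True)
    phi0 = float(brentq(g, lo, hi, xtol=1e-10))
    return phi0, False


def jansonius_path(
    start_mm: tuple[float, float],
    eye_side: str = "right",
    params: JansoniusParams | None = None,
    *,
    fovea_mm: tuple[float, float] = (0.0, 0.0),
) -> AxonTrajectory:
    """Axon course from ``start_mm`` (scene frame) to the optic disc.

    The start must lie outside the disc radius.  A start exactly on the
    raphe (temporal horizontal through the fovea) is assigned to the
    superior branch and flagged.  For a left eye the recorded coronal-plane
    slopes flip sign (the scene frame itself is side-agnostic).
    """
    params = params or JansoniusParams()
    if eye_side not in ("left", "right"):
        raise ConfigurationError("eye_side must be 'left' or 'right'")
    mmdeg = params.mm_per_degree
    start_deg = (np.asarray(start_mm, dtype=float) - np.asarray(fovea_mm)) / mmdeg
    disc = np.asarray(params.disc_center_deg, dtype=float)
    rel = start_deg - disc
    r_p = float(np.hypot(*rel))
    if r_p <= params.r0_deg:
        raise ConfigurationError("start lies inside the optic disc")
    # polar angle about the disc, axis pointing nasally (+x), CCW positive
    phi_p = float(np.degrees(np.arctan2(rel[1], rel[0])))

    raphe_flagged = False
    if abs(abs(phi_p) - 180.0) < 1e-9 and start_deg[0] < disc[0]:
        phi_p = 180.0 - 1e-6  # raphe start: assign to the superior branch
        raphe_flagged = True

    phi0, degenerate = _solve_phi0(r_p, phi_p, params)

    rs = np.arange(r_p, params.r0_deg, -params.r_step_deg)
    rs = np.append(rs, params.r0_deg)
    if degenerate:
        phis = np.full_like(rs, phi_p)
    else:
        phis = _phi_of_r(phi0, rs, params)
        # hard raphe guard: clip just short of +-180
        phis = np.clip(phis, -180.0 + 1e-9, 180.0 - 1e-9)
    xy_deg = disc[None, :] + np.column_stack([rs * np.cos(np.radians(phis)), rs * np.sin(np.radians(phis))])
    poly_mm = xy_deg * mmdeg + np.asarray(fovea_mm)

    d = np.diff(poly_mm, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(np.abs(d[:, 0]) > 1e-12, d[:, 1] / d[:, 0], np.inf)
    if eye_side == "left":
        slopes = -slopes
    return AxonTrajectory(
        polyline_mm=poly_mm,
        slopes=slopes,
        phi0_deg=phi0,
        degenerate=degenerate,
        raphe_flagged=raphe_flagged,
    )


def params_for_geometry(g, params: JansoniusParams | None = None) -> JansoniusParams:
    """Bundle parameters whose disc position matches a patient geometry."""
    from dataclasses import replace

    params = params or JansoniusParams()
    disc = np.asarray(g.optic_disc_position_mm) - np.asarray(g.fovea_position_mm)
    return replace(params, disc_center_deg=tuple(disc / params.mm_per_degree))


# --------------------------------------------------------------------------
# 3D embedding
# --------------------------------------------------------------------------


def embed_neuron(
    soma_um: tuple[float, float],
    traj: AxonTrajectory,
    surface: RetinalSurface,
    *,
    soma_depth_um: float = 55.0,
    axon_depth_um: float = 15.0,
    total_length_um: float = 3000.0,
    soma_segment_um: float = 30.0,
    step_um: float = 10.0,
) -> dict:
    """3D cable path (um): soma at depth 55, vertical ascent to 15, 90-degree
    bend, then a surface-contour-following course along the axon trajectory.

    The trajectory is resampled from the soma position toward the disc; if
    it ends before ``total_length_um`` of cable is available the path is
    extended along the final tangent and flagged.

    Returns {"path_um": (k, 3), "extended": bool}.
    """
    if soma_depth_um < axon_depth_um:
        raise ConfigurationError("soma must lie deeper than the axon plane")
    soma = np.asarray(soma_um, dtype=float)
    poly = traj.polyline_mm * 1e3  # -> um

    # arc-length position of the soma's projection on the trajectory
    d2 = np.linalg.norm(poly - soma[None, :], axis=1)
    i0 = int(np.argmin(d2))
    course = np.vstack([soma[None, :], poly[i0 + 1 :]]) if i0 + 1 < len(poly) else soma[None, :]

    # resample the 2D course at uniform steps
    seg = np.diff(course, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    keep = seglen > 1e-9
    seg, seglen = seg[keep], seglen[keep]
    starts = course[:-1][keep]
    if len(seglen) == 0:
        tangent = np.array([1.0, 0.0])
        course2 = soma[None, :]
    else:
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s = np.arange(0.0, cum[-1], step_um)
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
        course2 = starts[idx] + ((s - cum[idx]) / seglen[idx])[:, None] * seg[idx]
        tangent = seg[-1] / seglen[-1]

    z_s = float(surface.surface_z(soma[0], soma[1]))
    first_tan = course2[1] - course2[0] if len(course2) > 1 else tangent
    first_tan = first_tan / max(np.linalg.norm(first_tan), 1e-12)

    pts = []
    # soma segment: horizontal at soma depth, trailing the ascent point
    pts.append([*(soma - soma_segment_um * first_tan), z_s + soma_depth_um])
    pts.append([soma[0], soma[1], z_s + soma_depth_um])
    # vertical ascent to the axon plane (the 90-degree bend sits at its top)
    pts.append([soma[0], soma[1], z_s + axon_depth_um])
    # surface-contour course at the axon depth
    for p in course2[1:]:
        pts.append([p[0], p[1], float(surface.surface_z(p[0], p[1])) + axon_depth_um])
    path = np.asarray(pts)

    arclen = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
    extended = False
    if arclen < total_length_um + step_um:
        need = total_length_um + 2 * step_um - arclen
        last = path[-1]
        ext_xy = last[:2] + np.outer(np.arange(step_um, need + step_um, step_um), tangent)
        ext = np.column_stack(
            [ext_xy, np.full(len(ext_xy), last[2])]
        )
        path = np.vstack([path, ext])
        extended = True
    return {"path_um": path, "extended": extended}


# --------------------------------------------------------------------------
# Slope statistics
# --------------------------------------------------------------------------


def axon_slope_range(
    trajectories: list[AxonTrajectory],
    center_um: tuple[float, float],
    radius_um: float = 500.0,
) -> tuple[float, float] | None:
    """(min, max) coronal-plane slope of trajectory segments inside the disk.

    Returns None when no trajectory passes under the footprint.
    """
    center = np.asarray(center_um, dtype=float) / 1e3  # mm
    r_mm = radius_um / 1e3
    collected = []
    for traj in trajectories:
        mids = 0.5 * (traj.polyline_mm[:-1] + traj.polyline_mm[1:])
        inside = np.linalg.norm(mids - center[None, :], axis=1) <= r_mm
        sl = traj.slopes[inside]
        collected.append(sl[np.isfinite(sl)])
    if not collected:
        return None
    allsl = np.concatenate(collected)
    if len(allsl) == 0:
        return None
    return float(allsl.min()), float(allsl.max())
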