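"""Voxel conductivity grids: tissue labels, bulk conductivities, RPE interface.

The grid is regular and cell-centred.  Each voxel carries one tissue label and
one isotropic conductivity.  Faces between retina and sclera voxels are
treated by the field solver as a thin resistive membrane (contact impedance),
modelling the retinal pigment epithelium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ConfigurationError, GeometryError, PatientGeometry

__all__ = [
    "TissueConductivities",
    "ConductivityGrid",
    "build_conductivity_grid",
    "LABELS",
    "VITREOUS",
    "RETINA",
    "FIBROTIC",
    "SCLERA",
    "METAL",
    "INSULATOR",
]

VITREOUS, RETINA, FIBROTIC, SCLERA, METAL, INSULATOR = range(6)
LABELS = {
    VITREOUS: "vitreous",
    RETINA: "retina",
    FIBROTIC: "fibrotic",
    SCLERA: "sclera",
    METAL: "electrode-metal",
    INSULATOR: "insulator",
}


@dataclass(frozen=True)
class TissueConductivities:
    """Bulk conductivities (S/m) and the RPE contact impedance (Ohm * m^2).

    Defaults are literature-typical stand-ins (the study's own table is not
    public); the fibrotic default is the calibrated value 0.2715 S/m.  All
    values are config-overridable.
    """

    sigma_vitreous: float = 1.28
    sigma_retina: float = 0.10
    sigma_sclera: float = 0.50
    sigma_fibrotic: float = 0.2715
    rpe_contact_impedance: float = 0.5  # Ohm * m^2
    metal_sigma_factor: float = 1e6  # metal = factor * max tissue sigma

    def __post_init__(self) -> None:
        sigmas = (self.sigma_vitreous, self.sigma_retina, self.sigma_sclera, self.sigma_fibrotic)
        if any(s <= 0 for s in sigmas):
            raise ConfigurationError("all conductivities must be positive")
        if self.rpe_contact_impedance < 0:
            raise ConfigurationError("contact impedance must be non-negative")

    @property
    def sigma_metal(self) -> float:
        return self.metal_sigma_factor * max(
            self.sigma_vitreous, self.sigma_retina, self.sigma_sclera, self.sigma_fibrotic
        )

    def by_label(self) -> np.ndarray:
        """Conductivity for each label code (insulator voxels carry 0)."""
        return np.array(
            [
                self.sigma_vitreous,
                self.sigma_retina,
                self.sigma_fibrotic,
                self.sigma_sclera,
                self.sigma_metal,
                0.0,
            ]
        )


@dataclass
class ConductivityGrid:
    """Regular cell-centred grid of tissue labels and conductivities.

    ``labels[i, j, k]`` covers the voxel whose centre is
    ``origin_um + (i + 1/2, j + 1/2, k + 1/2) * spacing_um``.
    ``electrode_id`` is -1 outside metal and the row-major electrode index
    inside.  Contact-impedance faces are derived from the labels by the
    solver (every retina|sclera face).
    """

    origin_um: np.ndarray
    spacing_um: float
    labels: np.ndarray  # uint8 (nx, ny, nz)
    sigma: np.ndarray  # float64 (nx, ny, nz), S/m
    electrode_id: np.ndarray  # int32 (nx, ny, nz)
    electrode_labels: list[str]
    conductivities: TissueConductivities
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def cell_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.spacing_um
        return tuple(
            self.origin_um[a] + (np.arange(self.shape[a]) + 0.5) * h for a in range(3)
        )

    def electrode_cells(self, label: str) -> np.ndarray:
        """(n, 3) voxel indices of one electrode's metal."""
        idx = self.electrode_labels.index(label)
        return np.argwhere(self.electrode_id == idx)

    def voxel_counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.labels == code)) for code, name in LABELS.items()}

    def contains_points(self, pts_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_um, dtype=float))
        lo = self.origin_um + 0.5 * self.spacing_um
        hi = self.origin_um + (np.array(self.shape) - 0.5) * self.spacing_um
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def to_vtk(self, path: str) -> None:
        """Write labels and sigma as a legacy-VTK structured-points file."""
        nx, ny, nz = self.shape
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nretistim conductivity grid\nASCII\n")
            f.write("DATASET STRUCTURED_POINTS\n")
            f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
            o = self.origin_um + 0.5 * self.spacing_um
            f.write(f"ORIGIN {o[0]} {o[1]} {o[2]}\n")
            f.write(f"SPACING {self.spacing_um} {self.spacing_um} {self.spacing_um}\n")
            f.write(f"POINT_DATA {nx * ny * nz}\n")
            f.write("SCALARS label unsigned_char 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, self.labels.ravel(order="F"), fmt="%d")
            f.write("SCALARS sigma double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, self.sigma.ravel(order="F"), fmt="%.6g")


def build_conductivity_grid(
    g: PatientGeometry,
    spacing_um: float,
    extent_mm: float | tuple[float, float],
    conductivities: TissueConductivities | None = None,
    *,
    vitreous_depth_mm: float = 1.0,
    sclera_depth_mm: float = 0.3,
) -> ConductivityGrid:
    """Voxelize a patient geometry onto a regular grid.

    ``extent_mm`` is the lateral (x, y) span, centred on the array;
    the z span reaches ``vitreous_depth_mm`` above the retinal surface
    reference plane and ``sclera_depth_mm`` below the deepest retina.

    Raises a resolution error if ``spacing_um`` exceeds the thinnest retina.
    """
    cond = conductivities or TissueConductivities()
    if spacing_um <= 0:
        raise ConfigurationError("spacing must be positive")
    tmin, _ = g.surface.thickness_um.bounds()
    if spacing_um > tmin:
        raise ConfigurationError(
            f"spacing {spacing_um} um exceeds thinnest retina ({tmin:.1f} um): "
            "the retinal layer would vanish from the grid"
        )
    if np.isscalar(extent_mm):
        ext_x = ext_y = float(extent_mm) * 1e3
    else:
        ext_x, ext_y = (float(v) * 1e3 for v in extent_mm)

    arr = g.array
    cx, cy = np.asarray(arr.center_position_mm) * 1e3
    half_u = ((arr.cols - 1) / 2) * arr.pitch_um + arr.pitch_um / 2
    half_v = ((arr.rows - 1) / 2) * arr.pitch_um + arr.pitch_um / 2
    if ext_x < 2 * half_u or ext_y < 2 * half_v:
        raise ConfigurationError("grid extent does not cover the electrode array")

    h = float(spacing_um)
    nx = int(np.ceil(ext_x / h))
    ny = int(np.ceil(ext_y / h))
    _, tmax = g.surface.thickness_um.bounds()
    _, smax = g.surface.surface_height_um.bounds()
    z_lo = -float(vitreous_depth_mm) * 1e3
    z_hi = smax + tmax + float(sclera_depth_mm) * 1e3
    nz = int(np.ceil((z_hi - z_lo) / h))
    origin = np.array([cx - nx * h / 2, cy - ny * h / 2, z_lo])

    xs = origin[0] + (np.arange(nx) + 0.5) * h
    ys = origin[1] + (np.arange(ny) + 0.5) * h
    zs = origin[2] + (np.arange(nz) + 0.5) * h
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    zsurf = g.surface.surface_z(X, Y)  # (nx, ny)
    thick = g.surface.thickness(X, Y)
    cap_thick = g.capsule.thickness_um(X, Y)

    center = g.array_center_xyz_um()
    eu, ev = arr.axes()
    en = arr.normal()
    rx, ry = X - center[0], Y - center[1]
    # in-plane/normal coordinates of each lateral column at z = 0, then
    # updated per z-slice (linear in z)
    u0 = rx * eu[0] + ry * eu[1] - center[2] * 0  # eu z-contribution added per slice
    v0 = rx * ev[0] + ry * ev[1]
    w0 = rx * en[0] + ry * en[1]

    # electrode grid in (u, v): cols along u, rows along v
    col_c = (np.arange(arr.cols) - (arr.cols - 1) / 2) * arr.pitch_um
    row_c = ((arr.rows - 1) / 2 - np.arange(arr.rows)) * arr.pitch_um
    e_rad = arr.electrode_diameter_um / 2

    labels = np.empty((nx, ny, nz), dtype=np.uint8)
    eid = np.full((nx, ny, nz), -1, dtype=np.int32)
    cap_margin = g.capsule.lateral_margin_um

    for k in range(nz):
        z = zs[k]
        dz = z - center[2]
        u = u0 + dz * eu[2]
        v = v0 + dz * ev[2]
        w = w0 + dz * en[2]

        sl = np.where(z >= zsurf + thick, SCLERA, np.where(z >= zsurf, RETINA, VITREOUS))

        in_foot = (np.abs(u) <= half_u) & (np.abs(v) <= half_v)
        vitre = sl == VITREOUS
        # fibrotic capsule fills the gap under the array plane (w > 0 side)
        fib = vitre & (w > 0) & (w <= cap_thick)
        fib &= (np.abs(u) <= half_u + cap_margin) & (np.abs(v) <= half_v + cap_margin)
        sl = np.where(fib, FIBROTIC, sl)

        # thin layers are preserved at >= one-cell thickness on coarse grids
        metal_t = max(arr.metal_thickness_um, h)
        subst_t = max(arr.substrate_thickness_um, h)
        metal_layer = vitre & in_foot & (w <= 0) & (w > -metal_t)
        subst = vitre & in_foot & (w <= -metal_t) & (w > -(metal_t + subst_t))
        if metal_layer.any():
            ci = np.clip(np.rint(u / arr.pitch_um + (arr.cols - 1) / 2).astype(int), 0, arr.cols - 1)
            ri = np.clip(np.rint((arr.rows - 1) / 2 - v / arr.pitch_um).astype(int), 0, arr.rows - 1)
            du = u - col_c[ci]
            dv = v - row_c[ri]
            in_disc = metal_layer & (du * du + dv * dv <= e_rad * e_rad)
            sl = np.where(in_disc, METAL, np.where(metal_layer, INSULATOR, sl))
            eid[:, :, k] = np.where(in_disc, (ri * arr.cols + ci).astype(np.int32), -1)
        sl = np.where(subst, INSULATOR, sl)
        labels[:, :, k] = sl

    present = {int(i) for i in np.unique(eid) if i >= 0}
    expected = set(range(arr.rows * arr.cols))
    if present != expected:
        missing = sorted(expected - present)
        raise GeometryError(
            f"{len(missing)} electrodes have no metal voxels at spacing {h} um "
            f"(e.g. index {missing[:3]}); refine the grid"
        )
    # electrodes may not intersect retina/sclera (interpenetration guard)
    sigma = cond.by_label()[labels]
    return ConductivityGrid(
        origin_um=origin,
        spacing_um=h,
        labels=labels,
        sigma=sigma,
        electrode_id=eid,
        electrode_labels=list(arr.labels),
        conductivities=cond,
        meta={
            "extent_mm": (ext_x / 1e3, ext_y / 1e3),
            "vitreous_depth_mm": vitreous_depth_mm,
            "sclera_depth_mm": sclera_depth_mm,
        },
    )
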