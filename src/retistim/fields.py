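"""Quasi-static bioelectric field computation, impedance and calibration.

Solves ``div(sigma grad phi) = -I delta`` on a :class:`ConductivityGrid`
with a cell-centred finite-volume discretization (harmonic-mean face
conductances), a grounded return boundary, floating inactive electrodes
(realized as high-conductivity metal) and a contact-impedance condition on
every retina|sclera face (the RPE membrane).

The solve is linear in the injected current, so a single unit-current
solution per electrode is reused for every stimulus amplitude
(``V_e(x, t) = phi_unit(x) * I(t)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

from ._mgsolver import FaceOperator, SolverError, pcg
from .conductivity import RETINA, SCLERA, ConductivityGrid, TissueConductivities
from .geometry import ConfigurationError

__all__ = [
    "SourceSpec",
    "FieldSolution",
    "OutOfDomainError",
    "SolverError",
    "solve_field",
    "sample_potentials",
    "compute_impedance",
    "analytic_disk_resistance",
    "point_source_potential",
    "calibrate_fibrotic_conductivity",
    "CalibrationResult",
    "grid_convergence_report",
]


class OutOfDomainError(ValueError):
    """A query point lies outside the solved grid."""


@dataclass(frozen=True)
class SourceSpec:
    """One active electrode driven with a fixed total current.

    Inactive electrodes float (their metal voxels are simply very
    conductive, so they equilibrate to an equipotential with zero net
    current).  The return is either the whole far-vitreous grid face
    (``far_boundary``) or a grounded patch on that face (``patch``,
    approximating an extraocular case return).
    """

    active_electrode: str
    injected_current_A: float = 1.0
    return_policy: str = "far_boundary"  # or "patch"
    patch_center_mm: tuple[float, float] = (0.0, 0.0)
    patch_half_size_mm: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.return_policy not in ("far_boundary", "patch"):
            raise ConfigurationError("return_policy must be 'far_boundary' or 'patch'")
        if self.injected_current_A == 0:
            raise ConfigurationError("injected current must be nonzero")


@dataclass
class FieldSolution:
    """Discrete potential (volts) for a given source on a given grid."""

    grid: ConductivityGrid
    source: SourceSpec
    phi: np.ndarray  # (nx, ny, nz) volts
    relative_residual: float
    iterations: int
    diagnostics: dict = field(default_factory=dict)
    _interp: RegularGridInterpolator | None = field(default=None, repr=False)

    @property
    def phi_unit(self) -> np.ndarray:
        """Potential per injected ampere (V/A)."""
        return self.phi / self.source.injected_current_A

    def to_hdf5(self, path: str) -> None:
        """Persist the potential with its grid metadata (hierarchical binary)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("phi", data=self.phi, compression="gzip")
            f.create_dataset("labels", data=self.grid.labels, compression="gzip")
            f.create_dataset("sigma", data=self.grid.sigma, compression="gzip")
            f.attrs["origin_um"] = self.grid.origin_um
            f.attrs["spacing_um"] = self.grid.spacing_um
            f.attrs["electrode_labels"] = list(self.grid.electrode_labels)
            f.attrs["active_electrode"] = self.source.active_electrode
            f.attrs["injected_current_A"] = self.source.injected_current_A
            f.attrs["relative_residual"] = self.relative_residual
            f.attrs["iterations"] = self.iterations

    @classmethod
    def from_hdf5(cls, path: str) -> "FieldSolution":
        import h5py

        from .conductivity import TissueConductivities

        with h5py.File(path, "r") as f:
            grid = ConductivityGrid(
                origin_um=np.asarray(f.attrs["origin_um"]),
                spacing_um=float(f.attrs["spacing_um"]),
                labels=f["labels"][()],
                sigma=f["sigma"][()],
                electrode_id=np.full(f["labels"].shape, -1, dtype=np.int32),
                electrode_labels=[str(s) for s in f.attrs["electrode_labels"]],
                conductivities=TissueConductivities(),
            )
            return cls(
                grid=grid,
                source=SourceSpec(
                    active_electrode=str(f.attrs["active_electrode"]),
                    injected_current_A=float(f.attrs["injected_current_A"]),
                ),
                phi=f["phi"][()],
                relative_residual=float(f.attrs["relative_residual"]),
                iterations=int(f.attrs["iterations"]),
            )

    def interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            xs, ys, zs = self.grid.cell_centers_1d()
            self._interp = RegularGridInterpolator(
                (xs, ys, zs), self.phi, method="linear", bounds_error=True
            )
        return self._interp


# --------------------------------------------------------------------------
# Discretization
# --------------------------------------------------------------------------


_FACE_NAMES = ("x-", "x+", "y-", "y+", "z-", "z+")


def _face_conductances(grid: ConductivityGrid, src: SourceSpec, boundary=None):
    """Face conductance arrays (S) incl. boundary faces and the RPE membrane.

    ``boundary`` is None (default: grounded far-vitreous ``z-`` face per
    ``src.return_policy``, Neumann elsewhere), a callable ``phi(points_um)``
    imposed as Dirichlet data on all six faces, or a dict mapping face names
    ("x-", "x+", ..., "z+") to "neumann", "ground" or a callable.
    Returns (operator, rhs_bc) where rhs_bc carries inhomogeneous Dirichlet
    contributions.
    """
    h_m = grid.spacing_um * 1e-6
    area = h_m * h_m
    sigma = grid.sigma
    labels = grid.labels
    zc = grid.conductivities.rpe_contact_impedance

    with np.errstate(divide="ignore"):
        inv = np.where(sigma > 0, 1.0 / np.where(sigma > 0, sigma, 1.0), np.inf)

    def interior(axis: int) -> np.ndarray:
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        r = 0.5 * h_m * (inv[tuple(sl_lo)] + inv[tuple(sl_hi)])
        if zc > 0:
            a, b = labels[tuple(sl_lo)], labels[tuple(sl_hi)]
            rpe = ((a == RETINA) & (b == SCLERA)) | ((a == SCLERA) & (b == RETINA))
            r = r + np.where(rpe, zc, 0.0)
        with np.errstate(divide="ignore"):
            g = np.where(np.isfinite(r), area / np.where(r > 0, r, 1.0), 0.0)
        return g

    nx, ny, nz = grid.shape
    Gx = np.zeros((nx + 1, ny, nz))
    Gy = np.zeros((nx, ny + 1, nz))
    Gz = np.zeros((nx, ny, nz + 1))
    Gx[1:-1] = interior(0)
    Gy[:, 1:-1] = interior(1)
    Gz[:, :, 1:-1] = interior(2)

    if boundary is None:
        spec = {name: "neumann" for name in _FACE_NAMES}
        spec["z-"] = "ground"
    elif callable(boundary):
        spec = {name: boundary for name in _FACE_NAMES}
    else:
        spec = {name: "neumann" for name in _FACE_NAMES}
        spec.update(boundary)

    rhs_bc = np.zeros(grid.shape)
    xs, ys, zs = grid.cell_centers_1d()
    h = grid.spacing_um
    faces = {
        "x-": (Gx, (0, Ellipsis), (slice(0, 1), slice(None), slice(None)), 0, -1),
        "x+": (Gx, (nx, Ellipsis), (slice(nx - 1, nx), slice(None), slice(None)), 0, +1),
        "y-": (Gy, (slice(None), 0, slice(None)), (slice(None), slice(0, 1), slice(None)), 1, -1),
        "y+": (Gy, (slice(None), ny, slice(None)), (slice(None), slice(ny - 1, ny), slice(None)), 1, +1),
        "z-": (Gz, (Ellipsis, 0), (slice(None), slice(None), slice(0, 1)), 2, -1),
        "z+": (Gz, (Ellipsis, nz), (slice(None), slice(None), slice(nz - 1, nz)), 2, +1),
    }
    for name, (G, face_idx, cell_sl, axis, sign) in faces.items():
        mode = spec[name]
        if mode == "neumann":
            continue
        inv_face = inv[cell_sl].reshape(G[face_idx].shape)
        open_cells = np.isfinite(inv_face)
        if name == "z-" and mode == "ground" and src.return_policy == "patch":
            cxp, cyp = (np.asarray(src.patch_center_mm) * 1e3)
            hx, hy = (np.asarray(src.patch_half_size_mm) * 1e3)
            in_patch = (np.abs(xs[:, None] - cxp) <= hx) & (np.abs(ys[None, :] - cyp) <= hy)
            open_cells &= in_patch
            if not open_cells.any():
                raise ConfigurationError("ground patch misses the grid's return face")
        g_face = np.where(open_cells, area / (0.5 * h_m * np.where(open_cells, inv_face, 1.0)), 0.0)
        G[face_idx] = g_face
        if callable(mode):
            # ghost value = Dirichlet data at the face centre
            centers = (xs, ys, zs)
            edge = centers[axis][0] - 0.5 * h if sign < 0 else centers[axis][-1] + 0.5 * h
            axes_2d = [a for a in range(3) if a != axis]
            P = np.meshgrid(centers[axes_2d[0]], centers[axes_2d[1]], indexing="ij")
            pts = np.zeros(P[0].shape + (3,))
            pts[..., axes_2d[0]] = P[0]
            pts[..., axes_2d[1]] = P[1]
            pts[..., axis] = edge
            ghost = np.asarray(mode(pts.reshape(-1, 3))).reshape(P[0].shape)
            rhs_bc[cell_sl] += (g_face * ghost).reshape(rhs_bc[cell_sl].shape)
    op = FaceOperator(
        np.ascontiguousarray(Gx), np.ascontiguousarray(Gy), np.ascontiguousarray(Gz)
    )
    return op, rhs_bc


def solve_field(
    grid: ConductivityGrid,
    src: SourceSpec,
    tol: float = 1e-8,
    *,
    maxiter: int = 2000,
    x0: np.ndarray | None = None,
    use_multigrid: bool = True,
    boundary=None,
    operator: tuple | None = None,
) -> FieldSolution:
    """Solve the quasi-static Poisson problem for one active electrode.

    ``tol`` is the relative residual of the linear system.  ``boundary``
    selects the outer boundary treatment (see ``_face_conductances``); pass
    ``operator`` (a previous ``(op, rhs_bc)`` pair) to reuse a
    discretization of the same grid.
    """
    if not 0 < tol < 1:
        raise ConfigurationError("tol must lie in (0, 1)")
    op, rhs_bc = operator if operator is not None else _face_conductances(grid, src, boundary)
    cells = grid.electrode_cells(src.active_electrode)
    if len(cells) == 0:
        raise ConfigurationError(f"electrode {src.active_electrode} has no metal voxels")
    rhs = rhs_bc.copy()
    rhs[cells[:, 0], cells[:, 1], cells[:, 2]] += src.injected_current_A / len(cells)
    n_elec = int(grid.electrode_id.max()) + 1
    deflation = [np.argwhere(grid.electrode_id == e) for e in range(n_elec)]
    deflation = [c for c in deflation if len(c)]
    phi, info = pcg(
        op,
        rhs,
        tol=tol,
        maxiter=maxiter,
        x0=x0,
        use_multigrid=use_multigrid,
        deflation_cells=deflation,
    )

    phi_active = phi[cells[:, 0], cells[:, 1], cells[:, 2]]
    diagnostics = {
        "active_equipotential_spread_V": float(phi_active.max() - phi_active.min()),
        "n_active_cells": int(len(cells)),
    }
    return FieldSolution(
        grid=grid,
        source=src,
        phi=phi,
        relative_residual=info["relative_residual"],
        iterations=info["iterations"],
        diagnostics=diagnostics,
    )


# --------------------------------------------------------------------------
# Sampling, impedance, oracles
# --------------------------------------------------------------------------


def sample_potentials(sol: FieldSolution, points_um: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of phi (V) at scene points (um).

    Exact at cell centres.  Raises :class:`OutOfDomainError` for points
    outside the cell-centre hull.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    try:
        return sol.interpolator()(pts)
    except ValueError as exc:
        raise OutOfDomainError(str(exc)) from exc


def compute_impedance(sol: FieldSolution, current_A: float | None = None) -> float:
    """Impedance (Ohm) = maximum potential divided by the stimulus current."""
    current = sol.source.injected_current_A if current_A is None else current_A
    if current <= 0:
        raise ConfigurationError("current must be positive")
    scale = current / sol.source.injected_current_A
    return float(np.max(sol.phi) * scale / current)


def analytic_disk_resistance(sigma: float, radius_um: float) -> float:
    """Access resistance 1/(4 sigma a) of an equipotential disk on a half-space."""
    if sigma <= 0 or radius_um <= 0:
        raise ConfigurationError("sigma and radius must be positive")
    return 1.0 / (4.0 * sigma * radius_um * 1e-6)


def point_source_potential(
    sigma: float, r_um: np.ndarray, current_A: float = 1.0
) -> np.ndarray:
    """Infinite-medium monopole potential I / (4 pi sigma r), volts."""
    r_m = np.asarray(r_um, dtype=float) * 1e-6
    return current_A / (4.0 * np.pi * sigma * r_m)


def box_net_current(
    sol: FieldSolution, lo: tuple[int, int, int], hi: tuple[int, int, int], boundary=None
) -> float:
    """Net current (A) flowing OUT of the voxel box ``[lo, hi)`` (index space).

    Uses the same face conductances as the solve, so discrete conservation
    holds to the solver residual: the result is ~I for boxes containing the
    active electrode and ~0 otherwise.
    """
    op, _ = _face_conductances(sol.grid, sol.source, boundary)
    phi = sol.phi
    i0, j0, k0 = lo
    i1, j1, k1 = hi
    nx, ny, nz = sol.grid.shape
    if not (0 <= i0 < i1 <= nx and 0 <= j0 < j1 <= ny and 0 <= k0 < k1 <= nz):
        raise ConfigurationError("box indices out of range")
    total = 0.0

    def flux(G, inner, outer):
        return float(np.sum(G * (phi[inner] - phi[outer])))

    if i0 > 0:
        total += flux(op.Gx[i0, j0:j1, k0:k1], (i0, slice(j0, j1), slice(k0, k1)), (i0 - 1, slice(j0, j1), slice(k0, k1)))
    if i1 < nx:
        total += flux(op.Gx[i1, j0:j1, k0:k1], (i1 - 1, slice(j0, j1), slice(k0, k1)), (i1, slice(j0, j1), slice(k0, k1)))
    if j0 > 0:
        total += flux(op.Gy[i0:i1, j0, k0:k1], (slice(i0, i1), j0, slice(k0, k1)), (slice(i0, i1), j0 - 1, slice(k0, k1)))
    if j1 < ny:
        total += flux(op.Gy[i0:i1, j1, k0:k1], (slice(i0, i1), j1 - 1, slice(k0, k1)), (slice(i0, i1), j1, slice(k0, k1)))
    if k0 > 0:
        total += flux(op.Gz[i0:i1, j0:j1, k0], (slice(i0, i1), slice(j0, j1), k0), (slice(i0, i1), slice(j0, j1), k0 - 1))
    if k1 < nz:
        total += flux(op.Gz[i0:i1, j0:j1, k1], (slice(i0, i1), slice(j0, j1), k1 - 1), (slice(i0, i1), slice(j0, j1), k1))
    # boundary faces treat the Dirichlet ghost as 0; use interior boxes when
    # inhomogeneous boundary data is in play
    if i0 == 0:
        total += float(np.sum(op.Gx[0, j0:j1, k0:k1] * phi[0, j0:j1, k0:k1]))
    if i1 == nx:
        total += float(np.sum(op.Gx[nx, j0:j1, k0:k1] * phi[nx - 1, j0:j1, k0:k1]))
    if j0 == 0:
        total += float(np.sum(op.Gy[i0:i1, 0, k0:k1] * phi[i0:i1, 0, k0:k1]))
    if j1 == ny:
        total += float(np.sum(op.Gy[i0:i1, ny, k0:k1] * phi[i0:i1, ny - 1, k0:k1]))
    if k0 == 0:
        total += float(np.sum(op.Gz[i0:i1, j0:j1, 0] * phi[i0:i1, j0:j1, 0]))
    if k1 == nz:
        total += float(np.sum(op.Gz[i0:i1, j0:j1, nz] * phi[i0:i1, j0:j1, nz - 1]))
    return total


# --------------------------------------------------------------------------
# Fibrotic-conductivity calibration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationResult:
    sigma_fibrotic: float
    impedance_ohm: float
    out_of_range: bool
    monotone: bool
    sweep: tuple[tuple[float, float], ...]  # (sigma, Z) pairs


def calibrate_fibrotic_conductivity(
    grid_builder: Callable[[float], ConductivityGrid],
    target_z_ohm: float,
    bounds: tuple[float, float] = (0.15, 0.37),
    electrode: str = "C5",
    *,
    solver_tol: float = 1e-7,
    sigma_tol: float = 1e-4,
    n_sweep: int = 5,
) -> CalibrationResult:
    """Invert the impedance-vs-fibrotic-conductivity relation.

    ``grid_builder(sigma_f)`` must return the conductivity grid with the
    fibrotic domain set to ``sigma_f``.  Searches ``bounds`` for the value
    whose impedance at ``electrode`` matches ``target_z_ohm``; a target
    outside the achievable interval returns the nearer boundary with
    ``out_of_range=True``.  Impedance is expected to decrease with
    ``sigma_f`` (checked on a small sweep; ``monotone=False`` otherwise).
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ConfigurationError("bounds must satisfy 0 < lo < hi")
    if target_z_ohm <= 0:
        raise ConfigurationError("target impedance must be positive")

    def z_of(sig: float) -> float:
        grid = grid_builder(sig)
        sol = solve_field(grid, SourceSpec(active_electrode=electrode), tol=solver_tol)
        return compute_impedance(sol)

    sweep_sigmas = np.linspace(lo, hi, max(2, n_sweep))
    sweep = [(float(s), z_of(float(s))) for s in sweep_sigmas]
    zs = np.array([z for _, z in sweep])
    monotone = bool(np.all(np.diff(zs) < 0))
    z_lo, z_hi = sweep[0][1], sweep[-1][1]

    if target_z_ohm >= z_lo:
        return CalibrationResult(lo, z_lo, True, monotone, tuple(sweep))
    if target_z_ohm <= z_hi:
        return CalibrationResult(hi, z_hi, True, monotone, tuple(sweep))

    # bracket within the sweep to save solves
    k = int(np.searchsorted(-zs, -target_z_ohm)) - 1
    a, b = sweep_sigmas[k], sweep_sigmas[k + 1]
    sig = float(brentq(lambda s: z_of(s) - target_z_ohm, a, b, xtol=sigma_tol))
    return CalibrationResult(sig, z_of(sig), False, monotone, tuple(sweep))


# --------------------------------------------------------------------------
# Grid convergence
# --------------------------------------------------------------------------


def grid_convergence_report(
    geometry,
    spacings_um: Sequence[float],
    conductivities: TissueConductivities | None = None,
    *,
    electrode: str = "C5",
    extent_mm: float | tuple[float, float] = 6.5,
    solver_tol: float = 1e-8,
    profile_depths_um: np.ndarray | None = None,
    threshold_fn: Callable[[FieldSolution], float] | None = None,
    rel_change_flag: float = 0.02,
    **grid_kwargs,
) -> pd.DataFrame:
    """Impedance / field-profile (optionally threshold) vs grid spacing.

    Solves the same scene at each spacing and reports successive relative
    changes; the ``converged`` column flags the coarsest spacing whose
    change relative to the next finer grid is below ``rel_change_flag``.
    """
    from .conductivity import build_conductivity_grid

    spacings = list(spacings_um)
    if len(spacings) < 2:
        raise ConfigurationError("need at least two spacings")
    if profile_depths_um is None:
        profile_depths_um = np.linspace(60.0, 400.0, 18)

    cond = conductivities or TissueConductivities()
    rows = []
    for h in spacings:
        grid = build_conductivity_grid(geometry, h, extent_mm, cond, **grid_kwargs)
        sol = solve_field(grid, SourceSpec(active_electrode=electrode), tol=solver_tol)
        pos = geometry.electrode_positions_um()[electrode]
        n = geometry.array.normal()
        pts = pos[None, :] + profile_depths_um[:, None] * n[None, :]
        profile = sample_potentials(sol, pts)
        row = {
            "spacing_um": float(h),
            "impedance_ohm": compute_impedance(sol),
            "profile_rms_V": float(np.sqrt(np.mean(profile**2))),
        }
        if threshold_fn is not None:
            row["threshold_uA"] = float(threshold_fn(sol))
        rows.append(row)

    df = pd.DataFrame(rows)
    for col in [c for c in ("impedance_ohm", "profile_rms_V", "threshold_uA") if c in df]:
        ref = df[col].shift(-1)  # next (finer) spacing
        df[f"rel_change_{col}"] = np.where(ref != 0, np.abs(df[col] - ref) / np.abs(ref), 0.0)
    change_cols = [c for c in df.columns if c.startswith("rel_change_")]
    ok = (df[change_cols].fillna(0.0) < rel_change_flag).all(axis=1)
    ok.iloc[-1] = False  # finest row has no comparison
    df["converged"] = ok
    return df
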