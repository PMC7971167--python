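"""Numba kernels for the cell-centred finite-volume Poisson solver.

The discrete operator is defined by face conductances (siemens):
``(A phi)_c = sum_faces G_f (phi_c - phi_nbr)`` with Dirichlet ghost values
of zero folded into boundary faces.  Cells whose total face conductance is
zero (insulator interior) are decoupled: they get a unit diagonal and zero
right-hand side, pinning phi = 0 there.

A Galerkin two-to-one coarsening (piecewise-constant prolongation, summed
restriction) turns the face-conductance description into an exact coarse
operator, which makes the V-cycle robust to the strong conductivity
contrasts of metal/tissue/insulator grids.  The V-cycle (symmetric red-black
Gauss-Seidel smoothing) is used as a preconditioner for conjugate gradients.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

__all__ = ["FaceOperator", "pcg", "SolverError"]


class SolverError(RuntimeError):
    pass


@njit(cache=True, fastmath=True)
def _matvec(phi, Gx, Gy, Gz, out):
    nx, ny, nz = phi.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                gxm = Gx[i, j, k]
                gxp = Gx[i + 1, j, k]
                gym = Gy[i, j, k]
                gyp = Gy[i, j + 1, k]
                gzm = Gz[i, j, k]
                gzp = Gz[i, j, k + 1]
                diag = gxm + gxp + gym + gyp + gzm + gzp
                if diag == 0.0:
                    out[i, j, k] = phi[i, j, k]  # decoupled cell
                    continue
                acc = diag * phi[i, j, k]
                if i > 0:
                    acc -= gxm * phi[i - 1, j, k]
                if i < nx - 1:
                    acc -= gxp * phi[i + 1, j, k]
                if j > 0:
                    acc -= gym * phi[i, j - 1, k]
                if j < ny - 1:
                    acc -= gyp * phi[i, j + 1, k]
                if k > 0:
                    acc -= gzm * phi[i, j, k - 1]
                if k < nz - 1:
                    acc -= gzp * phi[i, j, k + 1]
                out[i, j, k] = acc
    return out


@njit(cache=True, fastmath=True)
def _rbgs(phi, rhs, Gx, Gy, Gz, color):
    """One red-black Gauss-Seidel half-sweep over cells with (i+j+k)%2 == color."""
    nx, ny, nz = phi.shape
    for i in range(nx):
        for j in range(ny):
            k0 = (i + j + color) % 2
            for k in range(k0, nz, 2):
                gxm = Gx[i, j, k]
                gxp = Gx[i + 1, j, k]
                gym = Gy[i, j, k]
                gyp = Gy[i, j + 1, k]
                gzm = Gz[i, j, k]
                gzp = Gz[i, j, k + 1]
                diag = gxm + gxp + gym + gyp + gzm + gzp
                if diag == 0.0:
                    phi[i, j, k] = rhs[i, j, k]
                    continue
                acc = rhs[i, j, k]
                if i > 0:
                    acc += gxm * phi[i - 1, j, k]
                if i < nx - 1:
                    acc += gxp * phi[i + 1, j, k]
                if j > 0:
                    acc += gym * phi[i, j - 1, k]
                if j < ny - 1:
                    acc += gyp * phi[i, j + 1, k]
                if k > 0:
                    acc += gzm * phi[i, j, k - 1]
                if k < nz - 1:
                    acc += gzp * phi[i, j, k + 1]
                phi[i, j, k] = acc / diag


@njit(cache=True, fastmath=True)
def _residual(phi, rhs, Gx, Gy, Gz, out):
    _matvec(phi, Gx, Gy, Gz, out)
    nx, ny, nz = phi.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out[i, j, k] = rhs[i, j, k] - out[i, j, k]


@njit(cache=True)
def _restrict(fine, coarse):
    """coarse[ic,jc,kc] = sum of fine cells in the 2x2x2 (or smaller) block."""
    coarse[:, :, :] = 0.0
    nx, ny, nz = fine.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                coarse[i // 2, j // 2, k // 2] += fine[i, j, k]


@njit(cache=True)
def _prolong_add(coarse, fine):
    nx, ny, nz = fine.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                fine[i, j, k] += coarse[i // 2, j // 2, k // 2]


def _coarsen_faces_x(Gx: np.ndarray) -> np.ndarray:
    """Galerkin coarse x-face conductances for piecewise-constant prolongation."""
    nfx, ny, nz = Gx.shape
    nx = nfx - 1
    ncx, ncy, ncz = (nx + 1) // 2, (ny + 1) // 2, (nz + 1) // 2
    out = np.zeros((ncx + 1, ncy, ncz))
    jc = np.arange(ny) // 2
    kc = np.arange(nz) // 2
    for i in range(nx + 1):
        if i == 0:
            ic = 0
        elif i == nx:
            ic = ncx
        elif i % 2 == 0:
            ic = i // 2
        else:
            continue  # interior to a block: cancels in Galerkin product
        # accumulate over (j, k) into coarse (jc, kc)
        tmp = np.zeros((ncy, nz))
        np.add.at(tmp, jc, Gx[i])
        tmp2 = np.zeros((ncy, ncz))
        np.add.at(tmp2.T, kc, tmp.T)
        out[ic] += tmp2
    return out


def _coarsen_faces(Gx, Gy, Gz):
    cx = _coarsen_faces_x(Gx)
    cy = _coarsen_faces_x(Gy.transpose(1, 0, 2)).transpose(1, 0, 2)
    cz = _coarsen_faces_x(Gz.transpose(2, 1, 0)).transpose(2, 1, 0)
    return np.ascontiguousarray(cx), np.ascontiguousarray(cy), np.ascontiguousarray(cz)


class FaceOperator:
    """Variable-coefficient 7-point operator defined by face conductances."""

    def __init__(self, Gx: np.ndarray, Gy: np.ndarray, Gz: np.ndarray):
        self.Gx, self.Gy, self.Gz = Gx, Gy, Gz
        self.shape = (Gx.shape[0] - 1, Gy.shape[1] - 1, Gz.shape[2] - 1)

    def matvec(self, phi: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
        if out is None:
            out = np.empty_like(phi)
        return _matvec(phi, self.Gx, self.Gy, self.Gz, out)

    def coarsen(self) -> "FaceOperator":
        return FaceOperator(*_coarsen_faces(self.Gx, self.Gy, self.Gz))


class _Hierarchy:
    def __init__(self, op: FaceOperator, min_cells: int = 64, max_levels: int = 12):
        self.levels = [op]
        while np.prod(self.levels[-1].shape) > min_cells and len(self.levels) < max_levels:
            nxt = self.levels[-1].coarsen()
            if nxt.shape == self.levels[-1].shape:
                break
            self.levels.append(nxt)
        self._scratch = [
            (np.zeros(lv.shape), np.zeros(lv.shape)) for lv in self.levels
        ]

    def vcycle(self, rhs: np.ndarray, nu: int = 2) -> np.ndarray:
        return self._vcycle(0, rhs, nu)

    def _vcycle(self, lev: int, rhs: np.ndarray, nu: int) -> np.ndarray:
        op = self.levels[lev]
        phi = np.zeros(op.shape)
        if lev == len(self.levels) - 1:
            for _ in range(60):
                _rbgs(phi, rhs, op.Gx, op.Gy, op.Gz, 0)
                _rbgs(phi, rhs, op.Gx, op.Gy, op.Gz, 1)
            return phi
        for _ in range(nu):
            _rbgs(phi, rhs, op.Gx, op.Gy, op.Gz, 0)
            _rbgs(phi, rhs, op.Gx, op.Gy, op.Gz, 1)
        res, _ = self._scratch[lev]
        _residual(phi, rhs, op.Gx, op.Gy, op.Gz, res)
        coarse_rhs = np.zeros(self.levels[lev + 1].shape)
        _restrict(res, coarse_rhs)
        corr = self._vcycle(lev + 1, coarse_rhs, nu)
        _prolong_add(corr, phi)
        for _ in range(nu):  # reversed colors -> symmetric cycle
            _rbgs(phi, rhs, op.Gx, op.Gy, op.Gz, 1)
            _rbgs(phi, rhs, op.Gx, op.Gy, op.Gz, 0)
        return phi


def pcg(
    op: FaceOperator,
    rhs: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 2000,
    x0: np.ndarray | None = None,
    use_multigrid: bool = True,
    deflation_cells: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, dict]:
    """Preconditioned conjugate gradients; relative-residual stopping rule.

    ``deflation_cells`` lists voxel-index arrays (n_i, 3) whose indicator
    vectors are added to the preconditioner as rank-one corrections.  Used
    for high-conductivity (floating-electrode) clusters whose rigid
    potential shifts are the slowest modes of the contrast problem.

    Returns (phi, info) where info has 'iterations', 'relative_residual'.
    Raises :class:`SolverError` on non-convergence.
    """
    rhs = np.ascontiguousarray(rhs, dtype=np.float64)
    bnorm = float(np.linalg.norm(rhs))
    if bnorm == 0.0:
        return np.zeros(op.shape), {"iterations": 0, "relative_residual": 0.0}
    hier = _Hierarchy(op) if use_multigrid else None

    defl: list[tuple[tuple[np.ndarray, ...], float]] = []
    if deflation_cells:
        tmp = np.zeros(op.shape)
        out = np.empty(op.shape)
        for cells in deflation_cells:
            idx = tuple(np.asarray(cells).T)
            tmp[idx] = 1.0
            op.matvec(tmp, out)
            quad = float(out[idx].sum())  # 1^T A 1 = net boundary conductance
            tmp[idx] = 0.0
            if quad > 0:
                defl.append((idx, 1.0 / quad))

    def precond(r: np.ndarray) -> np.ndarray:
        z = hier.vcycle(r) if hier else r.copy()
        for idx, alpha in defl:
            z[idx] += alpha * float(r[idx].sum())
        return z

    x = np.zeros(op.shape) if x0 is None else np.array(x0, dtype=np.float64)
    r = np.empty_like(x)
    _residual(x, rhs, op.Gx, op.Gy, op.Gz, r)
    z = precond(r)
    p = z.copy()
    rz = float(np.vdot(r, z))
    Ap = np.empty_like(x)
    for it in range(1, maxiter + 1):
        op.matvec(p, Ap)
        pAp = float(np.vdot(p, Ap))
        if pAp <= 0:
            raise SolverError(f"operator lost positive-definiteness at iteration {it}")
        alpha = rz / pAp
        x += alpha * p
        r -= alpha * Ap
        rnorm = float(np.linalg.norm(r))
        if rnorm / bnorm < tol:
            return x, {"iterations": it, "relative_residual": rnorm / bnorm}
        z = precond(r)
        rz_new = float(np.vdot(r, z))
        beta = rz_new / rz
        rz = rz_new
        p = z + beta * p
    raise SolverError(
        f"PCG did not converge in {maxiter} iterations "
        f"(relative residual {rnorm / bnorm:.3e})"
    )
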