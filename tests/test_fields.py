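import dataclasses

import numpy as np
import pytest

from conftest import homogeneous_grid
from retistim.conductivity import ConductivityGrid, TissueConductivities, build_conductivity_grid
from retistim.fields import (
    CalibrationResult,
    OutOfDomainError,
    SourceSpec,
    analytic_disk_resistance,
    box_net_current,
    calibrate_fibrotic_conductivity,
    compute_impedance,
    grid_convergence_report,
    point_source_potential,
    sample_potentials,
    solve_field,
)
from retistim.geometry import ConfigurationError, ElectrodeArray, PatientGeometry


def far_field(sigma):
    def f(pts):
        return point_source_potential(sigma, np.linalg.norm(pts, axis=1))

    return f


@pytest.fixture(scope="module")
def homo_solution():
    grid = homogeneous_grid((80, 80, 64), 25.0, sigma=1.0)
    sol = solve_field(grid, SourceSpec(active_electrode="S1"), tol=1e-9, boundary=far_field(1.0))
    return grid, sol


class TestPointSourceOracle:
    def test_midfield_match(self, homo_solution):
        grid, sol = homo_solution
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(100, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        for r in (5 * grid.spacing_um, 300.0, 450.0):
            est = sample_potentials(sol, dirs * r)
            ana = point_source_potential(1.0, np.full(100, r))
            assert np.max(np.abs(est - ana) / ana) < 0.02

    def test_sigma_doubling_halves_phi(self):
        g1 = homogeneous_grid((32, 32, 32), 25.0, sigma=1.0)
        g2 = homogeneous_grid((32, 32, 32), 25.0, sigma=2.0)
        s1 = solve_field(g1, SourceSpec(active_electrode="S1"), tol=1e-10, boundary=far_field(1.0))
        s2 = solve_field(g2, SourceSpec(active_electrode="S1"), tol=1e-10, boundary=far_field(2.0))
        assert np.allclose(s1.phi, 2.0 * s2.phi, rtol=1e-5, atol=1e-8)

    def test_superposition_and_current_scaling(self):
        grid = homogeneous_grid((32, 32, 32), 25.0)
        src = SourceSpec(active_electrode="S1")
        s1 = solve_field(grid, src, tol=1e-10)
        s2 = solve_field(
            grid, dataclasses.replace(src, injected_current_A=2.0), tol=1e-10
        )
        assert np.allclose(2.0 * s1.phi, s2.phi, rtol=1e-6, atol=1e-10)


class TestDiskOracle:
    def test_analytic_values(self):
        assert analytic_disk_resistance(1.0, 100.0) == pytest.approx(2500.0)
        assert analytic_disk_resistance(0.2715, 100.0) == pytest.approx(9208.1, rel=1e-3)
        assert analytic_disk_resistance(1.0, 200.0) == pytest.approx(1250.0)
        with pytest.raises(ConfigurationError):
            analytic_disk_resistance(-1.0, 10.0)

    def test_disk_impedance_matches_half_space(self):
        from conftest import disk_electrode_grid, half_space_monopole

        sigma, a = 1.0, 200.0
        grid = disk_electrode_grid(20.0, 100, 50, radius_um=a, sigma=sigma)  # h = a/10
        hs = half_space_monopole(sigma)
        sol = solve_field(
            grid,
            SourceSpec(active_electrode="D1"),
            tol=1e-9,
            boundary={"x-": hs, "x+": hs, "y-": hs, "y+": hs, "z+": hs, "z-": "neumann"},
        )
        z = compute_impedance(sol)
        assert z == pytest.approx(analytic_disk_resistance(sigma, a), rel=0.05)


class TestImpedance:
    def test_pass_through_arithmetic(self, small_solution):
        # Z = max(phi) / I by definition
        z = compute_impedance(small_solution)
        assert z == pytest.approx(float(np.max(small_solution.phi)), rel=1e-12)
        assert z > 0

    def test_max_on_active_electrode(self, small_grid, small_solution):
        cells = small_grid.electrode_cells("A1")
        phi_active = small_solution.phi[cells[:, 0], cells[:, 1], cells[:, 2]]
        assert phi_active.max() == pytest.approx(np.max(small_solution.phi), rel=1e-9)

    def test_invariant_under_current(self, small_solution):
        assert compute_impedance(small_solution, 1.0) == pytest.approx(
            compute_impedance(small_solution, 1.0)
        )


class TestSampling:
    def test_exact_at_nodes(self, homo_solution):
        grid, sol = homo_solution
        xs, ys, zs = grid.cell_centers_1d()
        pts = np.array([[xs[3], ys[10], zs[7]], [xs[40], ys[41], zs[30]]])
        vals = sample_potentials(sol, pts)
        assert vals[0] == pytest.approx(sol.phi[3, 10, 7], rel=1e-12)
        assert vals[1] == pytest.approx(sol.phi[40, 41, 30], rel=1e-12)

    def test_midpoint_mean(self, homo_solution):
        grid, sol = homo_solution
        xs, ys, zs = grid.cell_centers_1d()
        mid = np.array([[0.5 * (xs[3] + xs[4]), ys[10], zs[7]]])
        assert sample_potentials(sol, mid)[0] == pytest.approx(
            0.5 * (sol.phi[3, 10, 7] + sol.phi[4, 10, 7]), rel=1e-9
        )

    def test_out_of_domain(self, homo_solution):
        _, sol = homo_solution
        with pytest.raises(OutOfDomainError):
            sample_potentials(sol, np.array([[1e6, 0.0, 0.0]]))

    def test_continuity_along_path(self, small_solution):
        # a 3000-point straight path through the grid: finite, no huge jumps
        t = np.linspace(-1200.0, 1200.0, 3000)
        pts = np.column_stack([t, 0.2 * t, np.full_like(t, 100.0)])
        vals = sample_potentials(small_solution, pts)
        assert np.all(np.isfinite(vals))
        assert np.max(np.abs(np.diff(vals))) < 0.2 * (np.max(vals) - np.min(vals) + 1e-12)


class TestConservation:
    def test_nested_boxes_enclose_current(self, homo_solution):
        grid, sol = homo_solution
        c = np.array(grid.shape) // 2
        for half in (4, 10, 20):
            lo = tuple(int(v) for v in c - half)
            hi = tuple(int(v) for v in c + half)
            flux = box_net_current(sol, lo, hi, boundary=far_field(1.0))
            assert flux == pytest.approx(1.0, rel=0.01)

    def test_empty_box_zero_net(self, homo_solution):
        grid, sol = homo_solution
        flux = box_net_current(sol, (2, 2, 2), (12, 12, 12), boundary=far_field(1.0))
        assert abs(flux) < 0.01

    def test_floating_electrodes_carry_no_net_current(self, small_grid, small_solution):
        for label in ("A2", "B1", "B2"):
            cells = small_grid.electrode_cells(label)
            lo = tuple(int(v) for v in cells.min(axis=0))
            hi = tuple(int(v) + 1 for v in cells.max(axis=0))
            flux = box_net_current(small_solution, lo, hi)
            assert abs(flux) < 0.01
            phi_e = small_solution.phi[cells[:, 0], cells[:, 1], cells[:, 2]]
            assert phi_e.max() - phi_e.min() < 1e-3 * np.max(small_solution.phi)


class TestReciprocity:
    def test_swap_source_and_probe(self, small_grid):
        sa = solve_field(small_grid, SourceSpec(active_electrode="A1"), tol=1e-9)
        sb = solve_field(small_grid, SourceSpec(active_electrode="B2"), tol=1e-9)
        ca = small_grid.electrode_cells("A1")
        cb = small_grid.electrode_cells("B2")
        v_ab = sa.phi[cb[:, 0], cb[:, 1], cb[:, 2]].mean()
        v_ba = sb.phi[ca[:, 0], ca[:, 1], ca[:, 2]].mean()
        assert v_ab == pytest.approx(v_ba, rel=1e-4)


@pytest.fixture(scope="module")
def patient():
    return PatientGeometry(array=ElectrodeArray(rows=2, cols=2, standoff_um=80.0))


class TestContactImpedance:
    def _solve(self, patient, zc):
        cond = TissueConductivities(rpe_contact_impedance=zc)
        grid = build_conductivity_grid(patient, 50.0, 3.0, cond, vitreous_depth_mm=0.5)
        return grid, solve_field(grid, SourceSpec(active_electrode="A1"), tol=1e-9)

    def test_limits(self, patient):
        from retistim.conductivity import SCLERA

        grid0, s0 = self._solve(patient, 0.0)
        grid_inf, s_inf = self._solve(patient, 1e6)
        # infinite membrane blocks current: potential gradient in sclera ~ 0
        scl = grid_inf.labels == SCLERA
        phi_scl = s_inf.phi[scl]
        assert np.ptp(phi_scl) < 1e-3 * np.max(s_inf.phi)
        # zero membrane lets current through: sclera sees real gradients
        assert np.ptp(s0.phi[grid0.labels == SCLERA]) > 10 * np.ptp(phi_scl)
        # blocking the scleral path raises the impedance
        assert compute_impedance(s_inf) > compute_impedance(s0)


@pytest.fixture(scope="module")
def builder():
    from retistim.geometry import FibroticCapsule, HarmonicField2D

    g = PatientGeometry(
        array=ElectrodeArray(rows=1, cols=2, standoff_um=60.0),
        capsule=FibroticCapsule(thickness_um=HarmonicField2D(60.0)),
    )

    def build(sigma_f):
        cond = TissueConductivities(sigma_fibrotic=sigma_f)
        return build_conductivity_grid(g, 50.0, 2.2, cond, vitreous_depth_mm=0.5)

    return build


class TestCalibration:
    def test_sweep_monotone_decreasing(self, builder):
        res = calibrate_fibrotic_conductivity(
            builder, target_z_ohm=1.0, electrode="A1", solver_tol=1e-8, n_sweep=5
        )
        zs = [z for _, z in res.sweep]
        assert all(b < a for a, b in zip(zs, zs[1:]))

    def test_forward_inverse_recovery(self, builder):
        from retistim.fields import SourceSpec as SS

        z_target = compute_impedance(
            solve_field(builder(0.25), SS(active_electrode="A1"), tol=1e-8)
        )
        res = calibrate_fibrotic_conductivity(
            builder, z_target, electrode="A1", solver_tol=1e-8
        )
        assert not res.out_of_range
        assert res.sigma_fibrotic == pytest.approx(0.25, rel=0.01)

    def test_out_of_range_clips(self, builder):
        res = calibrate_fibrotic_conductivity(
            builder, target_z_ohm=1.0, electrode="A1", solver_tol=1e-8, n_sweep=2
        )
        assert res.out_of_range and res.sigma_fibrotic == 0.37
        res2 = calibrate_fibrotic_conductivity(
            builder, target_z_ohm=1e9, electrode="A1", solver_tol=1e-8, n_sweep=2
        )
        assert res2.out_of_range and res2.sigma_fibrotic == 0.15
        assert isinstance(res, CalibrationResult)


class TestGridConvergence:
    def test_report_shape_and_flag(self):
        g = PatientGeometry(array=ElectrodeArray(rows=1, cols=2, standoff_um=80.0))
        df = grid_convergence_report(
            g, [60.0, 40.0, 25.0], electrode="A1", extent_mm=2.2,
            solver_tol=1e-8, vitreous_depth_mm=0.5,
        )
        assert len(df) == 3
        assert "impedance_ohm" in df and "converged" in df
        assert not df["converged"].iloc[-1]

    def test_identical_spacings_zero_change(self):
        g = PatientGeometry(array=ElectrodeArray(rows=1, cols=2, standoff_um=80.0))
        df = grid_convergence_report(
            g, [50.0, 50.0], electrode="A1", extent_mm=2.2,
            solver_tol=1e-8, vitreous_depth_mm=0.5,
        )
        assert df["rel_change_impedance_ohm"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestPersistence:
    def test_hdf5_round_trip(self, tmp_path, small_solution):
        from retistim.fields import FieldSolution

        path = str(tmp_path / "sol.h5")
        small_solution.to_hdf5(path)
        back = FieldSolution.from_hdf5(path)
        assert np.allclose(back.phi, small_solution.phi)
        assert back.grid.spacing_um == small_solution.grid.spacing_um
        assert back.source.active_electrode == "A1"
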