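import numpy as np
import pytest
from scipy.spatial import cKDTree

from retistim.geometry import ConfigurationError, HarmonicField2D, RetinalSurface
from retistim.retinotopy import (
    AxonTrajectory,
    JansoniusParams,
    axon_slope_range,
    embed_neuron,
    jansonius_path,
    lloyd_disk_sample,
)

FOVEA = (0.0, 0.0)
DISC_MM = (15.0 * 0.286, 2.0 * 0.286)


def nn_cv(points):
    d, _ = cKDTree(points).query(points, k=2)
    nn = d[:, 1]
    return nn.std() / nn.mean()


class TestLloyd:
    def test_single_point_converges_to_center(self):
        p = lloyd_disk_sample(1, 500.0, seed=0, iterations=60)
        assert np.linalg.norm(p.points_um) < 0.01 * 500.0

    def test_points_inside_radius(self):
        p = lloyd_disk_sample(250, 500.0, seed=1)
        assert np.all(np.linalg.norm(p.points_um, axis=1) <= 500.0 + 1e-6)
        assert len(np.unique(p.points_um, axis=0)) == 250

    def test_cv_decreases(self):
        before = lloyd_disk_sample(250, 500.0, seed=2, iterations=0)
        after = lloyd_disk_sample(250, 500.0, seed=2, iterations=50)
        assert nn_cv(after.points_um) < nn_cv(before.points_um)

    def test_seed_determinism(self):
        a = lloyd_disk_sample(40, 300.0, seed=5)
        b = lloyd_disk_sample(40, 300.0, seed=5)
        assert np.array_equal(a.points_um, b.points_um)
        c = lloyd_disk_sample(40, 300.0, seed=6)
        assert not np.array_equal(a.points_um, c.points_um)

    def test_center_offset(self):
        p = lloyd_disk_sample(10, 100.0, seed=0, center_um=(2000.0, -500.0))
        assert np.all(np.linalg.norm(p.points_um - [2000.0, -500.0], axis=1) <= 100.0 + 1e-6)

    def test_invalid_args(self):
        with pytest.raises(ConfigurationError):
            lloyd_disk_sample(0, 500.0, seed=0)


class TestBundleModel:
    def test_nasal_on_axis_straight(self):
        start = (DISC_MM[0] + 2.0, DISC_MM[1])  # nasal of the disc, on axis
        t = jansonius_path(start, "right", fovea_mm=FOVEA)
        assert t.degenerate
        assert np.all(np.abs(t.slopes) < 1e-9)

    def test_superior_temporal_arcs_to_superior_disc(self):
        t = jansonius_path((-1.0, 1.0), "right", fovea_mm=FOVEA)
        end = t.polyline_mm[-1]
        assert end[1] > DISC_MM[1]  # enters from the superior side
        assert t.polyline_mm[:, 1].min() >= 0.99  # arcs above, never dips

    def test_inferior_mirror_exact(self):
        params = JansoniusParams().mirrored_inferior()
        y_axis = 2 * DISC_MM[1]
        t_sup = jansonius_path((-1.0, 1.0), "right", params, fovea_mm=FOVEA)
        t_inf = jansonius_path((-1.0, y_axis - 1.0), "right", params, fovea_mm=FOVEA)
        mirrored = t_inf.polyline_mm.copy()
        mirrored[:, 1] = y_axis - mirrored[:, 1]
        assert np.allclose(t_sup.polyline_mm, mirrored, atol=1e-12)

    def test_raphe_never_crossed(self):
        # disc on the fovea's horizontal: hemifields separate exactly at y=0
        from dataclasses import replace

        params = replace(JansoniusParams(), disc_center_deg=(15.0, 0.0))
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(1000):
            x = rng.uniform(-3.0, 2.0)
            y = rng.uniform(-2.5, 2.5)
            if np.hypot(x / 0.286 - 15.0, y / 0.286) <= params.r0_deg + 0.3:
                continue
            t = jansonius_path((x, y), "right", params, fovea_mm=FOVEA)
            temporal = t.polyline_mm[:, 0] < 0.0
            ys = t.polyline_mm[temporal, 1]
            if len(ys) == 0:
                continue
            if y > 0:
                assert ys.min() > -1e-9
            elif y < 0:
                assert ys.max() < 1e-9
            checked += 1
        assert checked > 500

    def test_terminates_at_disc(self):
        t = jansonius_path((-1.5, 0.8), "right", fovea_mm=FOVEA)
        end_deg = (t.polyline_mm[-1] - np.array(FOVEA)) / 0.286
        r_end = np.hypot(end_deg[0] - 15.0, end_deg[1] - 2.0)
        assert r_end == pytest.approx(JansoniusParams().r0_deg, abs=1e-6)
        assert np.isfinite(t.arc_length_mm)

    def test_left_eye_flips_slopes(self):
        tr = jansonius_path((-1.0, 1.0), "right", fovea_mm=FOVEA)
        tl = jansonius_path((-1.0, 1.0), "left", fovea_mm=FOVEA)
        assert np.allclose(tr.slopes, -tl.slopes, equal_nan=True)
        assert np.allclose(tr.polyline_mm, tl.polyline_mm)

    def test_start_inside_disc_rejected(self):
        with pytest.raises(ConfigurationError):
            jansonius_path(DISC_MM, "right", fovea_mm=FOVEA)

    def test_raphe_start_flagged_superior(self):
        start = (DISC_MM[0] - 3.0, DISC_MM[1])  # temporal on the model axis
        t = jansonius_path(start, "right", fovea_mm=FOVEA)
        assert t.raphe_flagged
        assert t.phi0_deg >= 0  # superior branch by the declared tie-break


class TestEmbedding:
    def _traj(self, start=(-0.3, 0.6)):
        return jansonius_path(start, "right", fovea_mm=FOVEA)

    def test_flat_surface_constant_axon_depth(self):
        surface = RetinalSurface()
        emb = embed_neuron((-300.0, 600.0), self._traj(), surface)
        path = emb["path_um"]
        # beyond the soma+ascent prefix the z is the axon depth
        assert np.allclose(path[3:, 2], 15.0, atol=1e-9)

    def test_ascent_length_40(self):
        surface = RetinalSurface()
        emb = embed_neuron((-300.0, 600.0), self._traj(), surface)
        path = emb["path_um"]
        iA = 1  # soma centre
        assert path[iA, 2] == pytest.approx(55.0)
        assert path[iA + 1, 2] == pytest.approx(15.0)
        assert np.linalg.norm(path[iA + 1] - path[iA]) == pytest.approx(40.0)

    def test_undulating_surface_tracked(self):
        surface = RetinalSurface(
            surface_height_um=HarmonicField2D(
                0.0, (20.0,), ((2 * np.pi / 3000.0, 0.0),), (0.4,)
            )
        )
        emb = embed_neuron((-300.0, 600.0), self._traj(), surface)
        path = emb["path_um"]
        zs = surface.surface_z(path[3:, 0], path[3:, 1])
        assert np.allclose(path[3:, 2] - zs, 15.0, atol=1e-6)

    def test_arc_length_covers_cable(self):
        surface = RetinalSurface()
        emb = embed_neuron((-300.0, 600.0), self._traj(), surface, total_length_um=3000.0)
        arclen = np.linalg.norm(np.diff(emb["path_um"], axis=0), axis=1).sum()
        assert arclen >= 3000.0

    def test_short_trajectory_extends_flagged(self):
        surface = RetinalSurface()
        start = (DISC_MM[0] - 1.6, DISC_MM[1] + 0.3)  # close to the disc
        traj = jansonius_path(start, "right", fovea_mm=FOVEA)
        emb = embed_neuron(
            (start[0] * 1e3, start[1] * 1e3), traj, surface, total_length_um=3000.0
        )
        assert emb["extended"]
        arclen = np.linalg.norm(np.diff(emb["path_um"], axis=0), axis=1).sum()
        assert arclen >= 3000.0


class TestSlopeRange:
    def _synthetic(self, slope):
        x = np.linspace(-1.0, 1.0, 50)
        poly = np.column_stack([x, slope * x])
        slopes = np.full(len(x) - 1, float(slope))
        return AxonTrajectory(polyline_mm=poly, slopes=slopes, phi0_deg=0.0)

    def test_horizontal_trajectories(self):
        rng = axon_slope_range([self._synthetic(0.0)] * 3, (0.0, 0.0))
        assert rng == (0.0, 0.0)

    def test_45_degree_bundle(self):
        rng = axon_slope_range([self._synthetic(1.0)] * 5, (0.0, 0.0))
        assert rng == pytest.approx((1.0, 1.0))

    def test_empty_footprint(self):
        rng = axon_slope_range([self._synthetic(0.0)], (50.0 * 1e3, 0.0), radius_um=100.0)
        assert rng is None

    def test_slope_varies_with_vertical_offset(self):
        # bundles above the disc axis slope one way, below the other
        ranges = []
        cases = [(-1.0, -1.2), (2.0, DISC_MM[1]), (-1.0, 1.5)]
        for x_mm, y_mm in cases:
            trajs = [
                jansonius_path((x_mm + dx, y_mm), "right", fovea_mm=FOVEA)
                for dx in (-0.1, 0.0, 0.1)
            ]
            ranges.append(axon_slope_range(trajs, (x_mm * 1e3, y_mm * 1e3), radius_um=500.0))
        mids = [0.5 * (lo + hi) for lo, hi in ranges]
        assert mids[0] < -0.05  # inferior-temporal: negative slope
        assert abs(mids[1]) < 0.3  # papillomacular zone: shallow
        assert mids[2] > 0.05  # superior-temporal: positive slope
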