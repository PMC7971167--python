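"""Shared fixtures.

Field solves and cable builds are expensive, so small scenes are solved once
per session and reused read-only by the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from retistim.cable import ChannelParams, Morphometry, StimulusWaveform, build_cable
from retistim.conductivity import ConductivityGrid, TissueConductivities, build_conductivity_grid
from retistim.fields import SourceSpec, solve_field
from retistim.geometry import ElectrodeArray, PatientGeometry


def homogeneous_grid(
    n: tuple[int, int, int],
    spacing_um: float,
    sigma: float = 1.0,
    source_radius_cells: float = 1.5,
) -> ConductivityGrid:
    """All-one-tissue grid with a small spherical current source at the centre
    (labelled as electrode "S1" but with tissue conductivity, so the medium
    stays exactly homogeneous)."""
    labels = np.zeros(n, dtype=np.uint8)
    sig = np.full(n, float(sigma))
    eid = np.full(n, -1, dtype=np.int32)
    c = np.array(n) / 2
    ii, jj, kk = np.meshgrid(*[np.arange(m) for m in n], indexing="ij")
    r2 = (ii + 0.5 - c[0]) ** 2 + (jj + 0.5 - c[1]) ** 2 + (kk + 0.5 - c[2]) ** 2
    eid[r2 <= source_radius_cells**2] = 0
    cond = TissueConductivities(
        sigma_vitreous=sigma,
        sigma_retina=sigma,
        sigma_sclera=sigma,
        sigma_fibrotic=sigma,
        rpe_contact_impedance=0.0,
    )
    return ConductivityGrid(
        origin_um=-np.array(n) * spacing_um / 2,
        spacing_um=spacing_um,
        labels=labels,
        sigma=sig,
        electrode_id=eid,
        electrode_labels=["S1"],
        conductivities=cond,
    )


def disk_electrode_grid(
    spacing_um: float,
    nxy: int,
    nz: int,
    radius_um: float = 200.0,
    sigma: float = 1.0,
) -> ConductivityGrid:
    """Equipotential metal disk on an insulating plane over a half-space.

    Metal cells are inset by one cell (centres within radius - spacing):
    the one-cell-thick pillbox conducts through its side wall, and the inset
    compensates that effective-radius inflation.
    """
    n = (nxy, nxy, nz)
    h = spacing_um
    labels = np.zeros(n, dtype=np.uint8)
    sig = np.full(n, float(sigma))
    eid = np.full(n, -1, dtype=np.int32)
    c = np.array(n[:2]) / 2
    ii, jj = np.meshgrid(np.arange(n[0]), np.arange(n[1]), indexing="ij")
    disk = (ii + 0.5 - c[0]) ** 2 + (jj + 0.5 - c[1]) ** 2 <= ((radius_um - h) / h) ** 2
    eid[:, :, 0][disk] = 0
    sig[:, :, 0][disk] = 1e7
    cond = TissueConductivities(
        sigma_vitreous=sigma,
        sigma_retina=sigma,
        sigma_sclera=sigma,
        sigma_fibrotic=sigma,
        rpe_contact_impedance=0.0,
    )
    return ConductivityGrid(
        origin_um=np.array([-nxy * h / 2, -nxy * h / 2, 0.0]),
        spacing_um=h,
        labels=labels,
        sigma=sig,
        electrode_id=eid,
        electrode_labels=["D1"],
        conductivities=cond,
    )


def half_space_monopole(sigma: float):
    def f(pts):
        r = np.linalg.norm(pts, axis=1)
        return 1.0 / (2.0 * np.pi * sigma * r * 1e-6)

    return f


@pytest.fixture(scope="session")
def small_patient() -> PatientGeometry:
    """2x2 electrode array, flat retina, 80 um standoff — cheap to voxelize."""
    return PatientGeometry(array=ElectrodeArray(rows=2, cols=2, standoff_um=80.0))


@pytest.fixture(scope="session")
def small_grid(small_patient) -> ConductivityGrid:
    return build_conductivity_grid(small_patient, 40.0, 3.5)


@pytest.fixture(scope="session")
def small_solution(small_grid):
    return solve_field(small_grid, SourceSpec(active_electrode="A1"), tol=1e-7)


@pytest.fixture(scope="session")
def straight_chain():
    m = Morphometry()
    n_pts = 3201
    path = np.column_stack(
        [np.linspace(0, 3200, n_pts), np.zeros(n_pts), np.zeros(n_pts)]
    )
    return build_cable(m, path, ChannelParams())


@pytest.fixture(scope="session")
def short_wave_spec() -> StimulusWaveform:
    """Single biphasic pulse in a 25 ms window (20 Hz period)."""
    return StimulusWaveform(train_duration_ms=25.0)
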