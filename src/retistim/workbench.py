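"""Configuration, orchestration, and end-to-end pipeline runs.

``run_pipeline`` chains geometry -> field solve -> population placement ->
axon routing -> cable thresholds for a set of electrodes, writing every
stage artifact (JSON/CSV) plus a checksum manifest into a run directory.
Every stochastic stage draws its seed from the master seed through named
``SeedSequence`` streams, so a rerun of the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cable import ChannelParams, Morphometry, StimulusWaveform, build_cable
from .conductivity import TissueConductivities, build_conductivity_grid
from .fields import SourceSpec, compute_impedance, solve_field
from .geometry import (
    ConfigurationError,
    PatientGeometry,
    SynthRanges,
    electrode_retina_distances,
    generate_synthetic_patient,
)
from .retinotopy import embed_neuron, jansonius_path, lloyd_disk_sample, params_for_geometry
from .thresholds import electrode_threshold, neuron_threshold

__all__ = ["RunConfig", "run_pipeline", "report", "derive_seed"]


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Stable per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    master_seed: int = 0
    geometry: dict | None = None  # serialized PatientGeometry; None -> synthesize
    synth_ranges: SynthRanges = field(default_factory=SynthRanges)
    conductivities: TissueConductivities = field(default_factory=TissueConductivities)
    grid_spacing_um: float = 30.0
    grid_extent_mm: float = 6.5
    solver_tol: float = 1e-7
    waveform: StimulusWaveform = field(default_factory=StimulusWaveform)
    population_n: int = 250
    population_radius_um: float = 500.0
    lloyd_iterations: int = 30
    threshold_tol_uA: float = 0.25
    bracket_hi_uA: float = 1000.0
    sim_dt_ms: float = 0.01
    soma_depth_um: float = 55.0
    axon_depth_um: float = 15.0
    cable_total_um: float = 3000.0

    def resolve_geometry(self) -> PatientGeometry:
        if self.geometry is not None:
            return PatientGeometry.from_dict(self.geometry)
        return generate_synthetic_patient(
            derive_seed(self.master_seed, "geometry"), self.synth_ranges
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["waveform"] = dataclasses.asdict(self.waveform)
        d["conductivities"] = dataclasses.asdict(self.conductivities)
        d["synth_ranges"] = dataclasses.asdict(self.synth_ranges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "waveform" in d:
            d["waveform"] = StimulusWaveform(**d["waveform"])
        if "conductivities" in d:
            d["conductivities"] = TissueConductivities(**d["conductivities"])
        if "synth_ranges" in d:
            sr = {k: tuple(v) for k, v in d["synth_ranges"].items()}
            d["synth_ranges"] = SynthRanges(**sr)
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ve_at_points(sol, points_um: np.ndarray) -> np.ndarray:
    """Unit-current potential at points, 0 outside the solved grid (far field)."""
    interp = sol.interpolator()
    pts = np.atleast_2d(points_um)
    inside = sol.grid.contains_points(pts)
    out = np.zeros(len(pts))
    if inside.any():
        out[inside] = interp(pts[inside])
    return out


def run_pipeline(
    cfg: RunConfig,
    electrodes: list[str],
    out_dir: str | Path,
    *,
    resume: bool = True,
) -> Path:
    """Execute the per-electrode pipeline and write a manifest.

    Electrodes are independent; completed per-electrode outputs are skipped
    on resume.  Returns the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())

    g = cfg.resolve_geometry()
    (out / "geometry.json").write_text(g.to_json())
    distances = electrode_retina_distances(g)

    grid = build_conductivity_grid(g, cfg.grid_spacing_um, cfg.grid_extent_mm, cfg.conductivities)
    jparams = params_for_geometry(g)
    positions = g.electrode_positions_um()

    morph = Morphometry().with_total_length(cfg.cable_total_um)
    chan = ChannelParams()
    wave_spec = cfg.waveform

    impedances = {}
    for ei, elec in enumerate(electrodes):
        if elec not in positions:
            raise ConfigurationError(f"unknown electrode {elec}")
        tpath = out / f"thresholds_{elec}.csv"
        if resume and tpath.exists():
            impedances[elec] = None  # fill from existing impedance file later
            continue
        sol = solve_field(grid, SourceSpec(active_electrode=elec), tol=cfg.solver_tol)
        impedances[elec] = compute_impedance(sol)

        seed = derive_seed(cfg.master_seed, "placement", ei)
        center = positions[elec][:2]
        placement = lloyd_disk_sample(
            cfg.population_n,
            cfg.population_radius_um,
            seed,
            iterations=cfg.lloyd_iterations,
            center_um=tuple(center),
        )
        rows = []
        for ni, soma in enumerate(placement.points_um):
            traj = jansonius_path(
                tuple(soma / 1e3), g.eye.eye_side, jparams, fovea_mm=g.fovea_position_mm
            )
            emb = embed_neuron(
                tuple(soma),
                traj,
                g.surface,
                soma_depth_um=cfg.soma_depth_um,
                axon_depth_um=cfg.axon_depth_um,
                total_length_um=cfg.cable_total_um,
            )
            chain = build_cable(morph, emb["path_um"], chan)
            ve = _ve_at_points(sol, chain.centers_um)
            res = neuron_threshold(
                chain,
                ve,
                wave_spec,
                tol_uA=cfg.threshold_tol_uA,
                bracket_hi_uA=cfg.bracket_hi_uA,
                dt_ms=cfg.sim_dt_ms,
            )
            rows.append(
                {
                    "electrode": elec,
                    "neuron": ni,
                    "soma_x_um": soma[0],
                    "soma_y_um": soma[1],
                    "threshold_uA": res.threshold_uA,
                    "bracket_lo_uA": res.bracket_lo_uA,
                    "bracket_hi_uA": res.bracket_hi_uA,
                    "excitable": res.excitable,
                    "init_region": res.initiation_region,
                    "init_compartment": res.initiation_compartment,
                    "extended_path": emb["extended"],
                }
            )
        pd.DataFrame(rows).to_csv(tpath, index=False)

    imp_rows = [
        {
            "electrode": e,
            "impedance_ohm": z,
            "distance_um": distances[e],
        }
        for e, z in impedances.items()
        if z is not None
    ]
    imp_path = out / "impedance.csv"
    if imp_rows or not imp_path.exists():
        old = pd.read_csv(imp_path) if imp_path.exists() else pd.DataFrame()
        new = pd.concat([old, pd.DataFrame(imp_rows)]).drop_duplicates("electrode", keep="last")
        new.sort_values("electrode").to_csv(imp_path, index=False)

    manifest = {
        "electrodes": electrodes,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def report(run_dir: str | Path) -> dict:
    """Aggregate a completed run from its stored tables (no recomputation).

    Returns summary tables; missing stage outputs are listed under "gaps".
    """
    run = Path(run_dir)
    gaps = []
    out: dict = {"gaps": gaps}

    imp_path = run / "impedance.csv"
    if imp_path.exists():
        out["impedance"] = pd.read_csv(imp_path)
    else:
        gaps.append("impedance.csv")

    tfiles = sorted(run.glob("thresholds_*.csv"))
    if not tfiles:
        gaps.append("thresholds_*.csv")
        out["thresholds"] = pd.DataFrame()
        return out
    thr = pd.concat([pd.read_csv(p) for p in tfiles], ignore_index=True)
    out["thresholds"] = thr

    per_elec = []
    for elec, grp in thr.groupby("electrode"):
        resolved = grp[grp["excitable"] == True]  # noqa: E712
        per_elec.append(
            {
                "electrode": elec,
                "threshold_uA": resolved["threshold_uA"].min() if len(resolved) else np.nan,
                "n_resolved": int(len(resolved)),
            }
        )
    per_elec = pd.DataFrame(per_elec)
    out["electrode_thresholds"] = per_elec
    vals = per_elec["threshold_uA"].dropna()
    out["summary"] = {
        "mean_uA": float(vals.mean()) if len(vals) else np.nan,
        "sd_uA": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        "n_electrodes": int(len(vals)),
    }
    tally = thr[thr["excitable"] == True]["init_region"].value_counts()  # noqa: E712
    out["initiation_tally"] = tally.to_dict()
    if imp_path.exists() and len(per_elec):
        merged = per_elec.merge(out["impedance"], on="electrode", how="left")
        out["distance_vs_threshold"] = merged[["electrode", "distance_um", "threshold_uA"]]
    return out
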