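"""Activation thresholds: per-neuron bisection, per-electrode prediction,
activation maps, and convergence sweeps.

The per-neuron criterion is "at least one action potential attributed to
every stimulus pulse" (attribution window = [pulse onset, next onset));
switch to any-pulse with ``criterion="any_pulse"``.  The search brackets the
criterion between a failing ``lo`` and a succeeding ``hi`` and bisects to a
0.25 uA default tolerance, so monotonicity of the criterion is verified at
the bracket ends by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cable import (
    CompartmentChain,
    StimulusWaveform,
    initiation_site,
    make_waveform,
    simulate,
)
from .geometry import ConfigurationError

__all__ = [
    "NeuronThreshold",
    "ElectrodeThreshold",
    "neuron_threshold",
    "point_source_scenario",
    "electrode_threshold",
    "activation_map",
    "axon_length_convergence",
    "distance_threshold_table",
]


@dataclass(frozen=True)
class NeuronThreshold:
    """Bisection outcome for one neuron."""

    threshold_uA: float | None  # midpoint of the final bracket; None if not excitable
    bracket_lo_uA: float
    bracket_hi_uA: float
    excitable: bool
    initiation_region: str | None
    initiation_compartment: int | None
    n_simulations: int

    @property
    def bracket_width_uA(self) -> float:
        return self.bracket_hi_uA - self.bracket_lo_uA


@dataclass(frozen=True)
class ElectrodeThreshold:
    electrode: str
    threshold_uA: float | None
    argmin_neuron: int | None
    n_resolved: int
    n_not_excitable: int


def neuron_threshold(
    chain: CompartmentChain,
    ve_unit_V_per_A: np.ndarray,
    wave_spec: StimulusWaveform | None = None,
    tol_uA: float = 0.25,
    bracket_hi_uA: float = 1000.0,
    *,
    cap_uA: float = 10_000.0,
    dt_ms: float | None = None,
    criterion: str = "every_pulse",
    spike_threshold_mV: float = 0.0,
) -> NeuronThreshold:
    """Bisection search for the smallest amplitude meeting the spike criterion.

    Starts from [0, ``bracket_hi_uA``], expanding geometrically up to
    ``cap_uA`` if needed; a criterion unmet at the cap yields a
    not-excitable result (not an error).  The returned threshold is the
    midpoint of the final bracket whose width is <= ``tol_uA``.
    """
    if tol_uA <= 0 or bracket_hi_uA <= 0:
        raise ConfigurationError("tolerance and bracket cap must be positive")
    if criterion not in ("every_pulse", "any_pulse"):
        raise ConfigurationError("criterion must be 'every_pulse' or 'any_pulse'")
    wave_spec = wave_spec or StimulusWaveform()

    n_sims = 0
    last_supra = None

    def meets(amp: float):
        nonlocal n_sims, last_supra
        n_sims += 1
        wave = make_waveform(amp, wave_spec)
        sim = simulate(
            chain,
            ve_unit_V_per_A,
            wave,
            dt_ms=dt_ms,
            spike_threshold_mV=spike_threshold_mV,
            abort_on_missed_pulse=(criterion == "every_pulse"),
            record_every=10**9,
        )
        if criterion == "every_pulse":
            ok = not sim.aborted_missed_window and len(sim.event_times_ms) > 0
        else:
            ok = len(sim.event_times_ms) > 0
        if ok:
            last_supra = sim
        return ok

    lo, hi = 0.0, float(bracket_hi_uA)
    while not meets(hi):
        lo = hi
        hi *= 2.0
        if hi > cap_uA:
            return NeuronThreshold(
                threshold_uA=None,
                bracket_lo_uA=lo,
                bracket_hi_uA=hi,
                excitable=False,
                initiation_region=None,
                initiation_compartment=None,
                n_simulations=n_sims,
            )
    while hi - lo > tol_uA:
        mid = 0.5 * (lo + hi)
        if meets(mid):
            hi = mid
        else:
            lo = mid
    init = initiation_site(last_supra) if last_supra is not None else None
    return NeuronThreshold(
        threshold_uA=0.5 * (lo + hi),
        bracket_lo_uA=lo,
        bracket_hi_uA=hi,
        excitable=True,
        initiation_region=init["region"] if init else None,
        initiation_compartment=init["compartment"] if init else None,
        n_simulations=n_sims,
    )


def point_source_scenario(
    distance_um: float,
    *,
    sigma_S_per_m: float = 0.1,
    total_length_um: float = 3000.0,
    morphometry=None,
    channel_params=None,
    over_region: str = "socb",
) -> tuple[CompartmentChain, np.ndarray]:
    """Straight cable in a homogeneous medium with a monopole source placed
    ``distance_um`` above the centre of ``over_region``.

    Returns (chain, ve_unit) ready for :func:`neuron_threshold`.
    """
    from .cable import ChannelParams, Morphometry, build_cable
    from .fields import point_source_potential

    m = (morphometry or Morphometry()).with_total_length(total_length_um)
    params = channel_params or ChannelParams()
    L = m.total_length_um
    n_pts = int(L) + 101
    path = np.column_stack([np.linspace(0, L + 100, n_pts), np.zeros(n_pts), np.zeros(n_pts)])
    chain = build_cable(m, path, params)
    sl = chain.region_slice(over_region)
    mid = (sl.start + sl.stop) // 2
    src = chain.centers_um[mid] + np.array([0.0, 0.0, -float(distance_um)])
    r = np.linalg.norm(chain.centers_um - src[None, :], axis=1)
    ve_unit = point_source_potential(sigma_S_per_m, r)
    return chain, ve_unit


def electrode_threshold(
    results: Sequence[NeuronThreshold], electrode: str = ""
) -> ElectrodeThreshold:
    """Perceptual-threshold proxy: the minimum resolved neuron threshold."""
    resolved = [(i, r) for i, r in enumerate(results) if r.excitable]
    if not resolved:
        return ElectrodeThreshold(
            electrode=electrode,
            threshold_uA=None,
            argmin_neuron=None,
            n_resolved=0,
            n_not_excitable=len(results),
        )
    i_min, r_min = min(resolved, key=lambda t: t[1].threshold_uA)
    return ElectrodeThreshold(
        electrode=electrode,
        threshold_uA=r_min.threshold_uA,
        argmin_neuron=i_min,
        n_resolved=len(resolved),
        n_not_excitable=len(results) - len(resolved),
    )


def activation_map(
    soma_points_um: np.ndarray,
    thresholds_uA: Sequence[float | None],
    amplitude_uA: float,
    *,
    center_um: tuple[float, float] = (0.0, 0.0),
    grid_n: int = 61,
    radius_um: float = 500.0,
) -> dict:
    """Active set, bounding radius, and an interpolated threshold contour.

    active set = somas with resolved threshold <= amplitude; bounding radius
    = greatest active-soma distance from the electrode centre (0 if none).
    The contour grid is presentational (linear interpolation over somas).
    """
    pts = np.asarray(soma_points_um, dtype=float)
    thr = np.array([np.nan if t is None else float(t) for t in thresholds_uA])
    if len(pts) != len(thr):
        raise ConfigurationError("soma points and thresholds must align")
    active = np.isfinite(thr) & (thr <= amplitude_uA)
    center = np.asarray(center_um, dtype=float)
    dist = np.linalg.norm(pts - center[None, :], axis=1)
    bounding = float(dist[active].max()) if active.any() else 0.0

    ax = np.linspace(-radius_um, radius_um, grid_n)
    gx, gy = np.meshgrid(ax + center[0], ax + center[1], indexing="ij")
    contour = np.full(gx.shape, np.nan)
    good = np.isfinite(thr)
    if good.sum() >= 3:
        from scipy.interpolate import griddata

        contour = griddata(pts[good], thr[good], (gx, gy), method="linear")
    return {
        "active": active,
        "bounding_radius_um": bounding,
        "contour_x_um": gx,
        "contour_y_um": gy,
        "contour_threshold_uA": contour,
    }


def axon_length_convergence(
    lengths_um: Sequence[float],
    threshold_at_length: Callable[[float], float | None],
    *,
    rel_tol: float = 0.01,
) -> pd.DataFrame:
    """Threshold vs total cable length, with the convergence length flagged.

    ``threshold_at_length`` evaluates the fixed scenario at one total length
    (duplicate lengths are served from a cache, so they are bitwise equal).
    The convergence length is the shortest length whose threshold is within
    ``rel_tol`` of the longest-length reference.
    """
    lengths = [float(v) for v in lengths_um]
    if sorted(lengths) != lengths:
        raise ConfigurationError("lengths must be non-decreasing")
    cache: dict[float, float | None] = {}
    rows = []
    for L in lengths:
        if L not in cache:
            cache[L] = threshold_at_length(L)
        rows.append({"length_um": L, "threshold_uA": cache[L]})
    df = pd.DataFrame(rows)
    ref = df["threshold_uA"].iloc[-1]
    if ref is None or not np.isfinite(ref):
        df["within_tol"] = False
        df.attrs["convergence_length_um"] = None
        return df
    df["within_tol"] = np.abs(df["threshold_uA"].astype(float) - ref) <= rel_tol * abs(ref)
    conv = df.loc[df["within_tol"], "length_um"]
    df.attrs["convergence_length_um"] = float(conv.min()) if len(conv) else None
    return df


def distance_threshold_table(
    distances_um: Sequence[float],
    threshold_at_distance: Callable[[float], float | None],
) -> pd.DataFrame:
    """Electrode threshold vs electrode-retina distance.

    Thresholds are expected to be monotone non-decreasing in distance;
    violations are flagged, not raised.  Duplicate distances are served from
    a cache (determinism contract).
    """
    cache: dict[float, float | None] = {}
    rows = []
    for d in distances_um:
        d = float(d)
        if d not in cache:
            cache[d] = threshold_at_distance(d)
        rows.append({"distance_um": d, "threshold_uA": cache[d]})
    df = pd.DataFrame(rows)
    thr = df["threshold_uA"].astype(float).to_numpy()
    order = np.argsort(df["distance_um"].to_numpy(), kind="stable")
    monotone = bool(np.all(np.diff(thr[order]) >= -1e-12))
    df.attrs["monotone"] = monotone
    if len(df) >= 3 and np.isfinite(thr).all():
        from scipy.stats import pearsonr

        uniq = df.drop_duplicates("distance_um")
        if uniq["threshold_uA"].nunique() > 1 and len(uniq) >= 3:
            r, p = pearsonr(uniq["distance_um"], uniq["threshold_uA"].astype(float))
            df.attrs["pearson_r"] = float(r)
            df.attrs["pearson_p"] = float(p)
    return df
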