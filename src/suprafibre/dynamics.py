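"""Internal-dynamics analyses of fibre trajectories.

Axial monomer shifting (Δz relative to the fibre core), the
drift-velocity-versus-radius profile showing that surface monomers move
faster than core ones, and hot-spot residence/hopping statistics
extracted from coordination time series with two-threshold hysteresis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure import SwitchingParams
from .surrogate import FibreTrajectory

__all__ = [
    "DisplacementSeries", "DriftProfile", "ResidenceEvents", "HotspotSeries",
    "delta_z", "drift_profile", "hotspot_coordination_series",
    "extract_residence_events",
]


@dataclass
class DisplacementSeries:
    """Per-monomer axial displacement Δz(t) in nm, core-COM-relative."""

    times: np.ndarray
    dz: np.ndarray               # (n_frames, n_monomers), nm
    radial: np.ndarray           # (n_monomers,) time-averaged distance from axis, Å

    def max_shifts(self) -> tuple[float, float]:
        """(most positive, most negative) per-monomer final shift, nm."""
        final = self.dz[-1]
        return float(final.max()), float(final.min())


@dataclass
class DriftProfile:
    """Mean |v̄_z| per radial bin, with s.e.m. over monomers."""

    bin_edges: np.ndarray        # Å
    mean_speed: np.ndarray       # nm per time unit
    sem: np.ndarray
    occupancy: np.ndarray        # monomers per bin


@dataclass
class HotspotSeries:
    """Coordination of a tagged core to the nearest hot-spot core."""

    times: np.ndarray
    coordination: np.ndarray
    nearest_id: np.ndarray       # hot-spot monomer id per frame (−1 if none)


@dataclass
class ResidenceEvents:
    """Hot-spot visits of a tagged monomer.

    ``events`` is a list of (hot-spot id, t_enter, t_exit); the final
    event is flagged censored when the trajectory ends inside a visit.
    Hops are consecutive events on different hot spots.
    """

    events: list[tuple[int, float, float]]
    censored_final: bool
    duration: float

    @property
    def intervals(self) -> np.ndarray:
        """Completed residence intervals (censored final excluded)."""
        ev = self.events[:-1] if self.censored_final else self.events
        return np.array([e[2] - e[1] for e in ev])

    @property
    def hops(self) -> list[tuple[int, int]]:
        out = []
        for (a, *_), (b, *_) in zip(self.events, self.events[1:]):
            if a != b:
                out.append((a, b))
        return out

    @property
    def gap_total(self) -> float:
        occupied = sum(e[2] - e[1] for e in self.events)
        return self.duration - occupied


# ----------------------------------------------------------------------

def _unwrap_z(z: np.ndarray, box_z: float) -> np.ndarray:
    """Remove minimum-image jumps (|Δ| > box_z/2) along the time axis."""
    jumps = np.diff(z, axis=0)
    jumps -= box_z * np.round(jumps / box_z)
    return np.concatenate([z[:1], z[:1] + np.cumsum(jumps, axis=0)], axis=0)


def delta_z(traj: FibreTrajectory, core_fraction: float = 0.5) -> DisplacementSeries:
    """Axial displacement of every monomer relative to the fibre core.

    z is unwrapped per frame (minimum image), then the centre-of-mass z
    of the core region — the central ``core_fraction`` of monomers by
    radial distance from the fibre axis — is subtracted frame by frame.
    Output in nm.
    """
    if traj.box is None or traj.box[2] <= 0:
        raise ValueError("trajectory carries no z-periodic box")
    z = traj.core_positions[..., 2]
    if traj.z_periodic:
        z = _unwrap_z(np.mod(z, traj.box[2]), traj.box[2])
    xy = traj.core_positions[..., :2]
    axis_xy = xy.mean(axis=(0, 1))
    radial = np.linalg.norm(xy - axis_xy, axis=-1).mean(axis=0)
    n_core = max(1, int(round(core_fraction * traj.n_monomers)))
    core_ids = np.argsort(radial)[:n_core]
    com = z[:, core_ids].mean(axis=1)
    dz = (z - z[0]) - (com - com[0])[:, None]
    return DisplacementSeries(times=traj.times, dz=dz / 10.0, radial=radial)


def drift_profile(series: DisplacementSeries, window: float,
                  bins: int | np.ndarray = 5) -> DriftProfile:
    """Mean absolute windowed drift speed |Δz(w)|/w, binned radially.

    The speed of each monomer is the average over non-overlapping
    windows; the profile reports the monomer mean and s.e.m. per radial
    bin (empty bins dropped).  Requires at least 10 windows.
    """
    dt = float(series.times[1] - series.times[0])
    w_frames = max(1, int(round(window / dt)))
    n_win = (len(series.times) - 1) // w_frames
    if n_win < 10:
        raise ValueError("trajectory shorter than 10 drift windows")
    z = series.dz[: n_win * w_frames + 1: w_frames]   # nm at window edges
    speeds = np.abs(np.diff(z, axis=0)).mean(axis=0) / (w_frames * dt)
    edges = (np.asarray(bins, dtype=float) if np.ndim(bins)
             else np.linspace(0.0, series.radial.max() + 1e-9, bins + 1))
    idx = np.clip(np.digitize(series.radial, edges) - 1, 0, len(edges) - 2)
    means, sems, occ, keep = [], [], [], []
    for b in range(len(edges) - 1):
        sel = speeds[idx == b]
        if len(sel) == 0:
            continue
        keep.append(b)
        means.append(sel.mean())
        sems.append(sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else 0.0)
        occ.append(len(sel))
    keep = np.array(keep, dtype=int)
    pair_edges = np.column_stack([edges[keep], edges[keep + 1]])
    return DriftProfile(bin_edges=pair_edges, mean_speed=np.array(means),
                        sem=np.array(sems), occupancy=np.array(occ))


def hotspot_coordination_series(traj: FibreTrajectory, tagged: Optional[int] = None,
                                hot_spots: Optional[Sequence[int]] = None,
                                sw: Optional[SwitchingParams] = None,
                                refresh: bool = False) -> HotspotSeries:
    """Switching-function coordination of the tagged core to the nearest
    hot-spot core, per frame.

    With ``refresh`` the hot-spot set is re-identified each frame as the
    cores with hard-count coordination ≤ 1 (hot spots form and heal
    dynamically); otherwise the fixed reference set is used.
    """
    sw = sw or SwitchingParams()
    tagged = traj.tagged if tagged is None else tagged
    if tagged is None:
        raise ValueError("no tagged monomer given or stored on the trajectory")
    pos = traj.core_positions
    bz = traj.box[2]

    def midist(d):
        if traj.z_periodic:
            d = d.copy()
            d[..., 2] -= bz * np.round(d[..., 2] / bz)
        return np.linalg.norm(d, axis=-1)

    if refresh:
        others = np.arange(traj.n_monomers) != tagged
        coord = np.empty(traj.n_frames)
        nearest = np.empty(traj.n_frames, dtype=int)
        hard = SwitchingParams(mode="hard_cutoff", cutoff=sw.cutoff)
        for f in range(traj.n_frames):
            d = midist(pos[f, :, None, :] - pos[f, None, :, :])
            np.fill_diagonal(d, np.inf)
            # the tagged (visiting) monomer does not heal a hot spot
            counts = (d[:, others] <= hard.cutoff).sum(axis=1)
            hs = np.flatnonzero((counts <= 1) & others)
            if len(hs) == 0:
                coord[f] = 0.0
                nearest[f] = -1
                continue
            dh = d[tagged, hs]
            j = int(np.argmin(dh))
            coord[f] = float(sw.f(dh[j]))
            nearest[f] = int(hs[j])
        return HotspotSeries(times=traj.times, coordination=coord, nearest_id=nearest)

    hs = tuple(hot_spots) if hot_spots is not None else tuple(
        h for h in traj.hot_spots if h != tagged)
    if not hs:
        raise ValueError("empty hot-spot set")
    d = midist(pos[:, list(hs), :] - pos[:, [tagged], :])  # (n_frames, n_hs)
    j = np.argmin(d, axis=1)
    dmin = d[np.arange(len(d)), j]
    return HotspotSeries(times=traj.times, coordination=np.asarray(sw.f(dmin)),
                         nearest_id=np.array([hs[k] for k in j]))


def extract_residence_events(series: HotspotSeries,
                             hysteresis: tuple[float, float] = (0.7, 0.3)
                             ) -> ResidenceEvents:
    """Binarise a coordination series into residence events.

    An event opens on an upward crossing of the ``on`` threshold and
    closes on a downward crossing of ``off`` (two-threshold hysteresis
    suppresses chatter between the thresholds); the final open event is
    flagged censored.
    """
    on, off = hysteresis
    if on <= off:
        raise ValueError("hysteresis requires on > off")
    c = series.coordination
    if len(c) < 2:
        raise ValueError("series too short")
    events: list[tuple[int, float, float]] = []
    open_t = None
    open_id = -1
    for k in range(len(c)):
        if open_t is None:
            if c[k] >= on:
                open_t = float(series.times[k])
                open_id = int(series.nearest_id[k])
        else:
            if c[k] <= off:
                events.append((open_id, open_t, float(series.times[k])))
                open_t = None
    censored = open_t is not None
    if censored:
        events.append((open_id, open_t, float(series.times[-1])))
    return ResidenceEvents(events=events, censored_final=censored,
                           duration=float(series.times[-1] - series.times[0]))
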