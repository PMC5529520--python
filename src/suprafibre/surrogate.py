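"""Surrogate fibre trajectories with designed internal-dynamics kinetics.

Long unbiased simulations of fibre models are out of reach at desk
scale; this module generates trajectories whose statistics are designed:
a tagged monomer performs hot-spot hopping with i.i.d. exponential
residence times (mean t4), and every monomer drifts axially with a mean
speed set by a radial drift profile (surface monomers fast, core static).
These trajectories feed the internal-dynamics analyses and the residence
-time estimators, which must recover the designed parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fibre import FibreConformation
from .structure import SwitchingParams, coordination_number

__all__ = ["SurrogateKineticsSpec", "FibreTrajectory", "simulate_fibre_surrogate"]


@dataclass(frozen=True)
class SurrogateKineticsSpec:
    """Designed kinetics of a surrogate run.

    ``residence_mean`` is the hot-spot residence time t4 (trajectory time
    units); hops target hot spots drawn from ``hop_weights`` (uniform
    when omitted).  ``drift_profile`` maps radial distance from the fibre
    axis (Å) to mean axial speed |v_z| (Å per time unit), given as
    (radius, speed) pairs; monomers whose interpolated speed is 0 stay
    static.  ``designed_max_shifts`` optionally pins given monomers to a
    deterministic linear drift reaching the stated Δz (Å) at the end of
    the run.
    """

    residence_mean: float                       # t4
    hop_weights: Optional[dict[int, float]] = None
    escape_rate_to_water: float = 0.0           # 1/time
    drift_profile: tuple[tuple[float, float], ...] = ()
    seed: int = 0
    travel_time: Optional[float] = None         # gap between residences
    drift_persistence: Optional[float] = None   # direction-flip timescale
    designed_max_shifts: Optional[dict[int, float]] = None
    tagged: Optional[int] = None
    enable_hopping: bool = True

    def __post_init__(self):
        if self.residence_mean <= 0:
            raise ValueError("residence_mean (t4) must be positive")
        if self.escape_rate_to_water < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class FibreTrajectory:
    """Time-resolved core positions of a fibre (unwrapped coordinates)."""

    times: np.ndarray            # (n_frames,)
    core_positions: np.ndarray   # (n_frames, n_monomers, 3), Å, unwrapped
    box: np.ndarray
    z_periodic: bool = True
    dt: float = 1.0
    tagged: Optional[int] = None
    hot_spots: tuple[int, ...] = ()
    residence_truth: tuple[float, ...] = ()  # designed residence draws (diagnostics)

    @property
    def n_frames(self) -> int:
        return self.core_positions.shape[0]

    @property
    def n_monomers(self) -> int:
        return self.core_positions.shape[1]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def wrapped_z(self) -> np.ndarray:
        return np.mod(self.core_positions[..., 2], self.box[2])


def _hot_spot_set(conf: FibreConformation) -> tuple[int, ...]:
    sw = SwitchingParams(mode="hard_cutoff")
    coords = np.array([coordination_number(conf, i, sw)
                       for i in range(conf.n_monomers)])
    return tuple(int(i) for i in np.flatnonzero(coords <= 1))


def simulate_fibre_surrogate(conf: FibreConformation, kin: SurrogateKineticsSpec,
                             duration: float, dt: float) -> FibreTrajectory:
    """Generate a surrogate trajectory from a starting conformation.

    The tagged monomer (default: the least-coordinated one) alternates
    exponential residences stacked on a hot spot with short travel
    excursions; all other monomers follow the radial drift profile with
    direction flips every persistence interval.  Reproducible per seed.
    """
    if dt >= kin.residence_mean:
        raise ValueError("dt must be smaller than the residence mean "
                         "(event aliasing)")
    rng = np.random.default_rng(kin.seed)
    n_frames = int(round(duration / dt)) + 1
    times = np.arange(n_frames) * dt
    n = conf.n_monomers
    cores0 = conf.cores.copy()
    axis_xy = cores0[:, :2].mean(axis=0)
    radial = np.linalg.norm(cores0[:, :2] - axis_xy, axis=1)

    hot_spots = _hot_spot_set(conf)
    tagged = kin.tagged
    if tagged is None:
        sw = SwitchingParams(mode="hard_cutoff")
        coords = [coordination_number(conf, i, sw) for i in range(n)]
        tagged = int(np.argmin(coords))

    pos = np.broadcast_to(cores0, (n_frames, n, 3)).copy()

    # ---- axial drift of untagged monomers -----------------------------
    if kin.drift_profile:
        prof = np.asarray(kin.drift_profile, dtype=float)
        speeds = np.interp(radial, prof[:, 0], prof[:, 1])
    else:
        speeds = np.zeros(n)
    persistence = kin.drift_persistence or duration / 5.0
    pers_frames = max(1, int(round(persistence / dt)))
    n_seg = n_frames // pers_frames + 1
    signs = rng.choice([-1.0, 1.0], size=(n_seg, n))
    sign_t = np.repeat(signs, pers_frames, axis=0)[:n_frames]
    dz = np.cumsum(sign_t * speeds[None, :] * dt, axis=0)
    dz -= dz[0]
    if kin.designed_max_shifts:
        for mono, target in kin.designed_max_shifts.items():
            dz[:, mono] = np.linspace(0.0, target, n_frames)
    pos[..., 2] += dz

    # ---- tagged-monomer hot-spot hopping ------------------------------
    residences: list[float] = []
    if hot_spots and kin.enable_hopping:
        others = [h for h in hot_spots if h != tagged] or list(hot_spots)
        ids = np.array(others)
        if kin.hop_weights:
            w = np.array([kin.hop_weights.get(int(h), 0.0) for h in ids], dtype=float)
            if w.sum() <= 0:
                raise ValueError("hop_weights assign no mass to available hot spots")
            w /= w.sum()
        else:
            w = np.full(len(ids), 1.0 / len(ids))
        travel = kin.travel_time if kin.travel_time is not None \
            else max(2 * dt, 0.02 * kin.residence_mean)
        c = conf.spec.stacking_distance if conf.spec else 3.5
        far = np.array([30.0, 0.0, 0.0])
        frame = 0
        current = int(rng.choice(ids, p=w))
        while frame < n_frames:
            tau = float(rng.exponential(kin.residence_mean))
            residences.append(tau)
            n_res = max(1, int(round(tau / dt)))
            stop = min(n_frames, frame + n_res)
            anchor = pos[frame:stop, current] + np.array([0.0, 0.0, c])
            pos[frame:stop, tagged] = anchor
            frame = stop
            if frame >= n_frames:
                break
            # travel gap (possibly a long water excursion)
            gap = travel
            if kin.escape_rate_to_water > 0 and rng.random() < (
                    1.0 - np.exp(-kin.escape_rate_to_water * kin.residence_mean)):
                gap = travel + float(rng.exponential(5.0 * travel))
            n_gap = max(1, int(round(gap / dt)))
            stop = min(n_frames, frame + n_gap)
            pos[frame:stop, tagged] = pos[frame:stop, current] + far
            frame = stop
            current = int(rng.choice(ids, p=w))

    return FibreTrajectory(times=times, core_positions=pos, box=conf.box.copy(),
                           z_periodic=conf.z_periodic, dt=dt, tagged=tagged,
                           hot_spots=hot_spots,
                           residence_truth=tuple(residences[:-1]))
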