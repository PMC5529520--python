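"""Langevin dynamics, well-tempered metadynamics and FES estimators.

The samplers act on :class:`~suprafibre.landscapes.PotentialField` objects
in collective-variable (CV) space.  Two integrators are provided:
overdamped Euler–Maruyama (the default for CV dynamics, with diffusion
coefficient D = kB·T/friction) and an underdamped BAOAB splitting.
Metadynamics deposits Gaussian hills on the CV; in well-tempered mode the
hill height decays as w0·exp(−V/(kB·ΔT)) with ΔT = (γ−1)·T, so the bias
converges to −(1−1/γ)·F and the free energy is recovered by inversion,
F = −γ/(γ−1)·V.  Three FES estimators are implemented: well-tempered bias
inversion, standard (non-tempered) metadynamics with time-averaged bias,
and Boltzmann inversion of unbiased histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from heapq import heappush, heappop
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import ROOM, SimulationConstants
from .landscapes import PotentialField

__all__ = [
    "LangevinParams", "MetaDParams", "GridSpec", "Hill", "BiasState",
    "CVTrajectory", "MetaDRun", "FESGrid", "CVDefinition",
    "simulate_langevin", "deposit_hill", "run_metad",
    "fes_from_bias", "fes_from_histogram", "barrier_height",
    "mfpt_bruteforce", "mfpt_quadrature",
]

_BLOCK = 8192  # random-number block size for the scalar fast path


class WallEscapeError(RuntimeError):
    """Trajectory left the confined region by more than the tolerance."""


@dataclass(frozen=True)
class LangevinParams:
    dt: float
    friction: float
    temperature: float
    n_steps: int
    seed: int
    init: float | tuple[float, ...]
    mode: str = "overdamped"  # or "baoab"

    def __post_init__(self):
        if self.dt <= 0 or self.friction <= 0:
            raise ValueError("dt and friction must be positive")
        if self.dt * self.friction >= 2:
            raise ValueError("dt*friction must be < 2 for integrator stability")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.mode not in ("overdamped", "baoab"):
            raise ValueError(f"unknown integrator mode {self.mode!r}")

    @property
    def diffusion(self) -> float:
        """Overdamped CV diffusion D = kB·T/friction."""
        from .constants import KB_KCAL_MOL_K
        return KB_KCAL_MOL_K * self.temperature / self.friction


def friction_for(field: PotentialField, const: SimulationConstants = ROOM) -> float:
    """Friction that realises the landscape's designed CV diffusion."""
    return const.kT / field.spec.diffusion


@dataclass(frozen=True)
class GridSpec:
    lo: tuple[float, ...]
    hi: tuple[float, ...]
    spacing: float = 0.05  # CV units

    def __post_init__(self):
        object.__setattr__(self, "lo", tuple(np.atleast_1d(self.lo).astype(float)))
        object.__setattr__(self, "hi", tuple(np.atleast_1d(self.hi).astype(float)))

    def axes(self) -> list[np.ndarray]:
        return [np.linspace(lo, hi, int(round((hi - lo) / self.spacing)) + 1)
                for lo, hi in zip(self.lo, self.hi)]

    @classmethod
    def for_field(cls, field: PotentialField, pad: float = 0.3,
                  spacing: float = 0.05) -> "GridSpec":
        lo = tuple(w[0] - pad for w in field.spec.walls)
        hi = tuple(w[1] + pad for w in field.spec.walls)
        return cls(lo, hi, spacing)


@dataclass(frozen=True)
class MetaDParams:
    w0: float                 # initial hill height, kcal/mol
    sigma: float | tuple      # hill widths, CV units
    pace: int                 # steps between depositions
    gamma: float              # bias factor (>1 for well-tempered)
    grid: GridSpec
    well_tempered: bool = True

    def __post_init__(self):
        object.__setattr__(self, "sigma", tuple(np.atleast_1d(self.sigma).astype(float)))
        if self.well_tempered and self.gamma <= 1:
            raise ValueError("well-tempered metadynamics requires gamma > 1")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma must be positive")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")

    def delta_T(self, temperature: float) -> float:
        return (self.gamma - 1.0) * temperature


@dataclass(frozen=True)
class Hill:
    time: float
    centre: tuple[float, ...]
    sigma: tuple[float, ...]
    height: float


class BiasState:
    """Accumulated metadynamics bias: the hill log plus a cached grid.

    The grid cache is updated incrementally at each deposition and equals
    the direct hill summation at the nodes to machine precision; queries
    between nodes use (bi)linear interpolation.
    """

    def __init__(self, grid: GridSpec, gamma: float = 1.0):
        self.grid_spec = grid
        self.gamma = gamma
        self.hills: list[Hill] = []
        self.axes = grid.axes()
        self.dim = len(self.axes)
        if self.dim == 1:
            self.grid_cache = np.zeros(len(self.axes[0]))
        else:
            self.grid_cache = np.zeros(tuple(len(a) for a in self.axes))
        # scalar-fast-path caches (1-D)
        self._lo = float(self.axes[0][0])
        self._h = float(self.axes[0][1] - self.axes[0][0]) if len(self.axes[0]) > 1 else 1.0
        self._v_list: list[float] = self.grid_cache.tolist() if self.dim == 1 else []
        self._f_list: list[float] = [0.0] * len(self._v_list)

    # -- deposition ----------------------------------------------------
    def add_hill(self, hill: Hill) -> None:
        self.hills.append(hill)
        c = np.asarray(hill.centre)
        s = np.asarray(hill.sigma)
        if self.dim == 1:
            d = (self.axes[0] - c[0]) / s[0]
            self.grid_cache += hill.height * np.exp(-0.5 * d * d)
            self._v_list = self.grid_cache.tolist()
            f = -np.gradient(self.grid_cache, self._h)
            self._f_list = f.tolist()
        else:
            mesh = np.meshgrid(*self.axes, indexing="ij")
            q = sum(((m - ci) / si) ** 2 for m, ci, si in zip(mesh, c, s))
            self.grid_cache += hill.height * np.exp(-0.5 * q)

    # -- queries -------------------------------------------------------
    def bias_direct(self, x) -> float:
        """Bias by direct summation over all hills (exact, slower)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        v = 0.0
        for h in self.hills:
            q = sum(((xi - ci) / si) ** 2
                    for xi, ci, si in zip(x, h.centre, h.sigma))
            v += h.height * math.exp(-0.5 * q)
        return v

    def bias_at(self, x: float) -> float:
        """Interpolated bias from the grid cache (1-D fast path)."""
        if self.dim != 1:
            return self._bias_nd(x)
        t = (float(x) - self._lo) / self._h
        i = int(t)
        if i < 0:
            return self._v_list[0]
        if i >= len(self._v_list) - 1:
            return self._v_list[-1]
        frac = t - i
        v0 = self._v_list[i]
        return v0 + (self._v_list[i + 1] - v0) * frac

    def force_at(self, x: float) -> float:
        """Interpolated bias force −dV/ds (1-D)."""
        t = (float(x) - self._lo) / self._h
        i = int(t)
        if i < 0 or i >= len(self._f_list) - 1:
            return 0.0
        frac = t - i
        f0 = self._f_list[i]
        return f0 + (self._f_list[i + 1] - f0) * frac

    def _bias_nd(self, x) -> float:
        from scipy.interpolate import RegularGridInterpolator
        interp = RegularGridInterpolator(self.axes, self.grid_cache,
                                         bounds_error=False, fill_value=None)
        return float(interp(np.atleast_2d(x))[0])


def deposit_hill(state: BiasState, s, p: MetaDParams, time: float = 0.0,
                 const: SimulationConstants = ROOM) -> BiasState:
    """Deposit one Gaussian hill at CV point ``s`` (in place; returns state).

    Well-tempered height: w0·exp(−V(s,t)/(kB·ΔT)); otherwise w0.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if p.well_tempered:
        v = state.bias_direct(s) if len(state.hills) < 64 else state.bias_at(
            s[0]) if state.dim == 1 else state.bias_direct(s)
        h = p.w0 * math.exp(-v / (const.kB * p.delta_T(const.temperature)))
    else:
        h = p.w0
    state.add_hill(Hill(time=time, centre=tuple(s), sigma=p.sigma, height=h))
    return state


@dataclass
class CVTrajectory:
    times: np.ndarray
    positions: np.ndarray  # (n,) for 1-D, (n, dim) otherwise
    dt: float
    stride: int = 1


@dataclass
class MetaDRun:
    """Result of a (possibly biased) Langevin run with metadynamics."""

    traj: CVTrajectory
    bias: BiasState
    t_metad: float          # biased clock time actually simulated
    t_unbiased: float       # Σ dt·exp(β·V(s_k, t_k))
    bias_series: np.ndarray  # V(s_k, t_k) recorded before any deposition at step k
    committed: Optional[str] = None  # state label reached, if a stop rule was given
    censored: bool = False
    bias_average: Optional[np.ndarray] = None  # time-averaged bias grid

    @property
    def alpha(self) -> float:
        """Acceleration factor ⟨e^{βV}⟩ = t_unbiased / t_metad."""
        return self.t_unbiased / self.t_metad if self.t_metad > 0 else 1.0


# ----------------------------------------------------------------------
# samplers
# ----------------------------------------------------------------------

def simulate_langevin(field: PotentialField, p: LangevinParams,
                      bias: Optional[BiasState] = None,
                      stride: int = 1,
                      escape_tolerance: float = 1.5) -> CVTrajectory:
    """Langevin dynamics on a potential field, optionally under a fixed bias.

    Overdamped mode integrates dx = −βD·∇(U+V_bias)·dt + √(2D·dt)·ξ with
    D = kB·T/friction; BAOAB integrates the underdamped equations with
    unit mass.  Raises :class:`WallEscapeError` if the trajectory leaves
    the wall region by more than ``escape_tolerance`` CV units.
    """
    if field.dim != 1:
        return _simulate_langevin_nd(field, p, bias, stride, escape_tolerance)
    run = _run_1d(field, p, bias=bias, metad=None, const=SimulationConstants(p.temperature),
                  stride=stride, escape_tolerance=escape_tolerance)
    return run.traj


def run_metad(field: PotentialField, metad: MetaDParams, p: LangevinParams,
              const: Optional[SimulationConstants] = None,
              stride: int = 10,
              stop: Optional[Callable[[float, int], Optional[str]]] = None,
              average_from: Optional[float] = None,
              escape_tolerance: float = 1.5) -> MetaDRun:
    """Metadynamics-biased Langevin run on a 1-D field.

    ``stop(x, step)`` may return a state label to terminate the run
    (commitment); ``average_from`` (fraction of depositions) switches on
    accumulation of the time-averaged bias grid used by the
    standard-metadynamics FES estimator.
    """
    if field.dim != 1:
        raise NotImplementedError("metadynamics driver is 1-D")
    if const is None:
        const = SimulationConstants(p.temperature)
    return _run_1d(field, p, bias=BiasState(metad.grid, metad.gamma), metad=metad,
                   const=const, stride=stride, stop=stop, average_from=average_from,
                   escape_tolerance=escape_tolerance)


def _run_1d(field: PotentialField, p: LangevinParams, bias: Optional[BiasState],
            metad: Optional[MetaDParams], const: SimulationConstants,
            stride: int, stop=None, average_from: Optional[float] = None,
            escape_tolerance: float = 1.5) -> MetaDRun:
    rng = np.random.default_rng(p.seed)
    dt = p.dt
    beta = const.beta
    D = const.kT / p.friction
    bD = beta * D
    noise_scale = math.sqrt(2.0 * D * dt)
    x = float(np.atleast_1d(p.init)[0])
    lo = field._lo0 - escape_tolerance
    hi = field._hi0 + escape_tolerance
    grad1 = field.grad1

    n = p.n_steps
    rec_n = n // stride + 1
    xs = np.empty(rec_n)
    xs[0] = x
    rec_i = 1
    v_series = np.zeros(n)
    sum_exp = 0.0
    have_bias = bias is not None
    pace = metad.pace if metad is not None else 0
    avg_grid = None
    avg_count = 0
    avg_start = None
    if metad is not None and average_from is not None:
        est_hills = max(1, n // pace)
        avg_start = int(average_from * est_hills)
        avg_grid = np.zeros_like(bias.grid_cache)

    committed = None
    normals = rng.standard_normal(_BLOCK)
    nb = 0
    # underdamped state
    baoab = p.mode == "baoab"
    if baoab:
        v = math.sqrt(const.kT) * float(rng.standard_normal())
        c1 = math.exp(-p.friction * dt)
        c2 = math.sqrt(const.kT * (1.0 - c1 * c1))

    step = 0
    while step < n:
        if have_bias:
            vb = bias.bias_at(x)
            fb = bias.force_at(x)
        else:
            vb = 0.0
            fb = 0.0
        v_series[step] = vb
        sum_exp += math.exp(beta * vb)
        if metad is not None and (step + 1) % pace == 0:
            deposit_hill(bias, x, metad, time=(step + 1) * dt, const=const)
            if avg_grid is not None and len(bias.hills) > avg_start:
                avg_grid += bias.grid_cache
                avg_count += 1
        if nb >= _BLOCK:
            normals = rng.standard_normal(_BLOCK)
            nb = 0
        g = normals[nb]
        nb += 1
        if baoab:
            f = -grad1(x) + fb
            v += 0.5 * dt * f
            x += 0.5 * dt * v
            v = c1 * v + c2 * g
            x += 0.5 * dt * v
            v += 0.5 * dt * (-grad1(x) + (bias.force_at(x) if have_bias else 0.0))
        else:
            x += -bD * (grad1(x) - fb) * dt + noise_scale * g
        step += 1
        if step % stride == 0 and rec_i < rec_n:
            xs[rec_i] = x
            rec_i += 1
        if x < lo or x > hi:
            raise WallEscapeError(
                f"CV escaped confined region at step {step}: x={x:.3f}")
        if stop is not None:
            label = stop(x, step)
            if label:
                committed = label
                break

    n_done = step
    traj = CVTrajectory(times=np.arange(rec_i) * dt * stride,
                        positions=xs[:rec_i], dt=dt, stride=stride)
    t_metad = n_done * dt
    t_unbiased = sum_exp * dt
    return MetaDRun(
        traj=traj,
        bias=bias if bias is not None else BiasState(GridSpec((0.0,), (1.0,), 1.0)),
        t_metad=t_metad, t_unbiased=t_unbiased,
        bias_series=v_series[:n_done],
        committed=committed,
        censored=(stop is not None and committed is None),
        bias_average=(avg_grid / avg_count) if avg_count else None,
    )


def _simulate_langevin_nd(field, p, bias, stride, escape_tolerance):
    rng = np.random.default_rng(p.seed)
    const = SimulationConstants(p.temperature)
    D = const.kT / p.friction
    dt = p.dt
    x = np.array(np.atleast_1d(p.init), dtype=float)
    lo = field._lo - escape_tolerance
    hi = field._hi + escape_tolerance
    rec = [x.copy()]
    for step in range(p.n_steps):
        f = -field.gradient(x)
        x = x + const.beta * D * f * dt + math.sqrt(2 * D * dt) * rng.standard_normal(field.dim)
        if np.any(x < lo) or np.any(x > hi):
            raise WallEscapeError(f"CV escaped confined region at step {step}")
        if (step + 1) % stride == 0:
            rec.append(x.copy())
    pos = np.array(rec)
    return CVTrajectory(times=np.arange(len(pos)) * dt * stride, positions=pos,
                        dt=dt, stride=stride)


# ----------------------------------------------------------------------
# FES estimators
# ----------------------------------------------------------------------

@dataclass
class FESGrid:
    """Free-energy estimate on a CV grid, min-shifted to zero."""

    grid: np.ndarray            # 1-D nodes or (nx, ny, 2) coordinates
    F: np.ndarray               # kcal/mol; NaN where undefined
    method: str
    sem: Optional[np.ndarray] = None
    states: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        finite = np.isfinite(self.F)
        if finite.any():
            self.F = self.F - np.nanmin(self.F[finite])

    def value_at(self, x: float) -> float:
        return float(np.interp(x, self.grid, self.F))


def fes_from_bias(state: BiasState, method: str = "bias_inversion",
                  states: Optional[dict] = None,
                  bias_average: Optional[np.ndarray] = None) -> FESGrid:
    """FES from the metadynamics bias.

    Well-tempered inversion uses F = −γ/(γ−1)·V(s, t_final); the
    standard-metadynamics estimator uses the time-averaged bias
    F = −⟨V⟩ (pass ``bias_average`` from a non-tempered run).
    """
    grid = state.axes[0] if state.dim == 1 else np.stack(
        np.meshgrid(*state.axes, indexing="ij"), axis=-1)
    if method == "bias_inversion":
        if state.gamma <= 1:
            raise ValueError("bias inversion requires a well-tempered run (gamma > 1)")
        v = bias_average if bias_average is not None else state.grid_cache
        F = -state.gamma / (state.gamma - 1.0) * np.asarray(v, dtype=float)
    elif method == "standard_metad":
        v = bias_average if bias_average is not None else state.grid_cache
        F = -np.asarray(v, dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FESGrid(grid=grid, F=F.copy(), method=method, states=dict(states or {}))


def fes_from_histogram(traj: CVTrajectory | np.ndarray,
                       const: SimulationConstants = ROOM,
                       bins: int | np.ndarray = 80,
                       states: Optional[dict] = None) -> FESGrid:
    """Boltzmann inversion of the sampled CV density: F = −kB·T·ln ρ.

    Empty bins are masked (NaN), never propagated as ±∞.
    """
    x = traj.positions if isinstance(traj, CVTrajectory) else np.asarray(traj)
    if x.ndim != 1:
        raise NotImplementedError("histogram FES is 1-D")
    counts, edges = np.histogram(x, bins=bins)
    if counts.sum() == 0:
        raise ValueError("empty trajectory: all histogram bins are empty")
    centres = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        F = np.where(counts > 0, -const.kT * np.log(np.maximum(counts, 1e-300)), np.nan)
    F[counts == 0] = np.nan
    sem = np.where(counts > 0, const.kT / np.sqrt(np.maximum(counts, 1)), np.nan)
    return FESGrid(grid=centres, F=F, method="histogram", sem=sem,
                   states=dict(states or {}))


def _resolve_state(fes: FESGrid, state) -> tuple[float, float]:
    if isinstance(state, str):
        box = fes.states.get(state)
        if box is None:
            raise KeyError(f"FES carries no state {state!r}")
        return box[0] if np.ndim(box[0]) else tuple(box)  # 1-D interval
    return tuple(state)


def barrier_height(fes: FESGrid, source, target) -> float:
    """Minimax-path barrier between two states on an FES grid (kcal/mol).

    1-D: maximum of F between the two state minima, minus the source
    minimum.  2-D: minimax path over 4-neighbour grid adjacency.  An
    unsampled (NaN) gap between the states raises, naming the gap.
    """
    if fes.F.ndim == 1:
        (slo, shi) = _resolve_state(fes, source)
        (tlo, thi) = _resolve_state(fes, target)
        g = fes.grid
        smask = (g >= slo) & (g <= shi) & np.isfinite(fes.F)
        tmask = (g >= tlo) & (g <= thi) & np.isfinite(fes.F)
        if not smask.any():
            raise ValueError("source state unsampled on this FES")
        if not tmask.any():
            raise ValueError("target state unsampled on this FES")
        i = np.flatnonzero(smask)[np.argmin(fes.F[smask])]
        j = np.flatnonzero(tmask)[np.argmin(fes.F[tmask])]
        a, b = sorted((i, j))
        seg = fes.F[a:b + 1]
        if np.isnan(seg).any():
            k = a + int(np.flatnonzero(np.isnan(seg))[0])
            raise ValueError(
                f"unsampled gap between states near s = {fes.grid[k]:.3f}")
        return float(seg.max() - fes.F[i])
    return _barrier_2d(fes, source, target)


def _barrier_2d(fes: FESGrid, source, target) -> float:
    F = fes.F
    nx, ny = F.shape
    s_box = _resolve_state(fes, source) if isinstance(source, str) else source
    t_box = _resolve_state(fes, target) if isinstance(target, str) else target

    def box_argmin(box):
        (xlo, xhi), (ylo, yhi) = box
        gx = fes.grid[..., 0]
        gy = fes.grid[..., 1]
        m = (gx >= xlo) & (gx <= xhi) & (gy >= ylo) & (gy <= yhi) & np.isfinite(F)
        if not m.any():
            raise ValueError("state unsampled on this FES")
        flat = np.where(m, F, np.inf)
        return np.unravel_index(np.argmin(flat), F.shape)

    si = box_argmin(s_box)
    ti = box_argmin(t_box)
    # Dijkstra on "max along path" objective
    best = np.full(F.shape, np.inf)
    start_val = F[si]
    best[si] = start_val
    heap = [(start_val, si)]
    while heap:
        val, (i, j) = heappop(heap)
        if (i, j) == ti:
            return float(val - F[si])
        if val > best[i, j]:
            continue
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < nx and 0 <= jj < ny and np.isfinite(F[ii, jj]):
                nv = max(val, F[ii, jj])
                if nv < best[ii, jj]:
                    best[ii, jj] = nv
                    heappush(heap, (nv, (ii, jj)))
    raise ValueError("no sampled path between source and target (unsampled gap)")


# ----------------------------------------------------------------------
# mean first-passage time
# ----------------------------------------------------------------------

def mfpt_bruteforce(field: PotentialField, p: LangevinParams,
                    source, absorbing, n_replicas: int = 20,
                    max_steps: Optional[int] = None,
                    n_boot: int = 1000) -> tuple[float, tuple[float, float], np.ndarray]:
    """Replica-mean first-passage time by direct unbiased simulation.

    ``source`` is a CV start point (or state label resolved to its
    minimum); ``absorbing`` an interval (lo, hi) or state label.  Returns
    (mean, bootstrap 95% CI, times).  Raises if fewer than 5 replicas
    reach the absorbing region within the step budget.
    """
    if isinstance(source, str):
        source = float(field.state_minimum(source)[0][0])
    if isinstance(absorbing, str):
        absorbing = field.spec.states[absorbing][0]
    alo, ahi = absorbing
    budget = max_steps or p.n_steps
    times = []
    for rep in range(n_replicas):
        pr = LangevinParams(dt=p.dt, friction=p.friction, temperature=p.temperature,
                            n_steps=budget, seed=p.seed + rep, init=source, mode=p.mode)

        def stop(x, step, alo=alo, ahi=ahi):
            return "hit" if alo <= x <= ahi else None

        run = _run_1d(field, pr, bias=None, metad=None,
                      const=SimulationConstants(p.temperature), stride=max(budget // 100, 1),
                      stop=stop)
        if run.committed:
            times.append(run.t_metad)
    times = np.asarray(times)
    if len(times) < 5:
        raise RuntimeError(
            f"only {len(times)}/{n_replicas} replicas reached the absorbing "
            "state within the step budget; increase n_steps")
    rng = np.random.default_rng(p.seed + 10_000)
    boots = rng.choice(times, size=(n_boot, len(times)), replace=True).mean(axis=1)
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    return float(times.mean()), ci, times


def mfpt_quadrature(field: PotentialField, source, absorbing_edge: float,
                    const: SimulationConstants = ROOM,
                    diffusion: Optional[float] = None, n_grid: int = 4001) -> float:
    """Exact overdamped 1-D MFPT by the double-integral formula.

    τ(x0) = (1/D) ∫_{x0}^{b} dy e^{βU(y)} ∫_{lo}^{y} dz e^{−βU(z)},
    reflecting at the lower wall, absorbing at ``absorbing_edge``.
    """
    if isinstance(source, str):
        source = float(field.state_minimum(source)[0][0])
    D = diffusion if diffusion is not None else field.spec.diffusion
    lo = field._lo0 - 1.0
    ys = np.linspace(lo, absorbing_edge, n_grid)
    U = field.energy(ys)
    U = U - U.min()
    # clip the wall region (outside the masked integration range anyway)
    bu = np.exp(np.minimum(const.beta * U, 700.0))
    bmu = np.exp(-const.beta * U)
    inner = np.concatenate([[0.0], np.cumsum(0.5 * (bmu[1:] + bmu[:-1]) * np.diff(ys))])
    integrand = bu * inner
    mask = ys >= source
    return float(np.trapezoid(integrand[mask], ys[mask]) / D)


# ----------------------------------------------------------------------
# collective variables on fibre conformations
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CVDefinition:
    """A collective variable evaluable on fibre conformations.

    kinds: ``min_core_distance`` (Å to the closest other core),
    ``core_coordination`` (rational switching-function coordination) and
    ``landscape_coordinate`` (identity on model-landscape trajectories).
    """

    kind: str
    monomer_id: int = 0
    params: dict = dc_field(default_factory=dict)

    def evaluate(self, conf) -> float:
        from . import structure
        if self.kind == "min_core_distance":
            return structure.min_core_distance(conf, self.monomer_id)
        if self.kind == "core_coordination":
            sw = self.params.get("switching") or structure.SwitchingParams()
            return structure.coordination_number(conf, self.monomer_id, sw)
        if self.kind == "landscape_coordinate":
            raise TypeError("landscape_coordinate applies to CV trajectories, "
                            "not conformations")
        raise ValueError(f"unknown CV kind {self.kind!r}")
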