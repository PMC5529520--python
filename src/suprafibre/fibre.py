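"""Synthetic coarse-grained fibre conformations.

A fibre is a one-dimensional stack of discotic monomers on the z axis
(the fibre axis), each monomer one core bead plus a radial shell of side
beads (three "amide" beads carrying the ±q point charges that mimic the
threefold inter-monomer H-bonding, plus outer hydrophobic/solubilising
beads).  The box is periodic along z only.  Defects — breaks, folds,
surface-adsorbed and dissolved monomers — are injected on top of the
ideal stack to give the conformations the coordination/SASA/ΔE structure
of defected water-soluble fibres.

The geometry is schematic: side beads exist to give surface-area and
pair-energy structure, not to reproduce any force field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "PairPotentialParams", "DefectSpec", "FibreSpec", "FibreConformation",
    "generate_fibre", "write_xyz", "read_xyz",
    "BEAD_RADII", "default_defects",
]

#: per-bead-type radii (Å) used for SASA
BEAD_RADII = {"C": 2.3, "N": 2.3, "S": 2.6}
# C = aromatic-core bead, N = amide (charged) bead, S = generic side bead


@dataclass(frozen=True)
class PairPotentialParams:
    """12-6 plus screened-charge pair potential between fibre beads.

    ``eps_core`` is the core–core well depth (the reference value is
    0.627 kcal/mol); ``eps_scale`` multiplies it in the ε-scaling toy
    model (0.75 / 1.0 / 1.5 / 3.0).  Switching ``hbond_enabled`` off
    zeroes the ±q amide charges (the noHB variant).
    """

    eps_core: float = 0.627      # kcal/mol
    sigma_core: float = 3.5 / 2 ** (1 / 6)  # Å; 12-6 minimum at the stacking distance
    eps_side: float = 0.30       # kcal/mol
    sigma_side: float = 3.5 / 2 ** (1 / 6)  # Å; side beads also stack at c
    hbond_q: float = 0.30        # e
    hbond_enabled: bool = True
    eps_scale: float = 1.0
    dielectric: float = 15.0     # relative permittivity of the screened Coulomb term
    screening_length: float = 3.5  # Å; Yukawa decay of the charge term
    cutoff: float = 12.0         # Å

    def __post_init__(self):
        if self.eps_scale not in (0.75, 1.0, 1.5, 3.0):
            # other values are allowed but must still give a bound core pair
            if self.eps_core * self.eps_scale <= 0:
                raise ValueError("eps_core*eps_scale must be positive")
        if self.eps_core * self.eps_scale <= 0:
            raise ValueError("eps_core*eps_scale must be positive")

    @property
    def effective_hbond_q(self) -> float:
        return self.hbond_q if self.hbond_enabled else 0.0


@dataclass(frozen=True)
class DefectSpec:
    """A structural defect injected into the ideal stack.

    kinds: ``break`` (axial gap of ``magnitude`` Å opened above the
    monomer), ``fold`` (lateral kink: monomer displaced off-axis by
    ``magnitude`` Å), ``adsorbed`` (monomer moved radially onto the fibre
    surface), ``dissolved`` (monomer removed into solvent by
    ``magnitude`` Å).
    """

    kind: str
    at_monomer: int
    magnitude: float  # Å (gap width or displacement)

    def __post_init__(self):
        if self.kind not in ("break", "fold", "adsorbed", "dissolved"):
            raise ValueError(f"unknown defect kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("defect magnitude must be non-negative")


@dataclass(frozen=True)
class FibreSpec:
    """Geometry of a synthetic stacked fibre (80 monomers by default)."""

    n_monomers: int = 80
    n_side: int = 6              # side beads per monomer (first 3 are amides)
    stacking_distance: float = 3.5  # Å, the core-core stacking spacing c
    amide_radius: float = 2.4    # Å, radial distance of amide beads
    side_radius: float = 5.2     # Å, radial distance of outer side beads
    box_xy: float = 80.0         # Å
    z_periodic: bool = True
    defects: tuple[DefectSpec, ...] = ()
    thermal_noise: float = 0.0   # Å, Gaussian jitter on every bead
    seed: int = 0

    def __post_init__(self):
        if self.n_monomers < 2:
            raise ValueError("a fibre needs at least 2 monomers")
        if self.stacking_distance <= 0:
            raise ValueError("stacking distance must be positive")
        at = [d.at_monomer for d in self.defects]
        if len(set(at)) != len(at):
            raise ValueError("defect monomer indices collide")
        for d in self.defects:
            if not 0 <= d.at_monomer < self.n_monomers:
                raise ValueError(f"defect index {d.at_monomer} out of range")

    @property
    def box(self) -> np.ndarray:
        gaps = sum(d.magnitude for d in self.defects if d.kind == "break")
        return np.array([self.box_xy, self.box_xy,
                         self.n_monomers * self.stacking_distance + gaps])

    @property
    def beads_per_monomer(self) -> int:
        return 1 + self.n_side


@dataclass
class FibreConformation:
    """Bead positions of one fibre snapshot.

    ``positions`` has shape (n_monomers, beads_per_monomer, 3), bead 0 of
    each monomer being the core.  Coordinates are stored unwrapped;
    :meth:`wrapped` applies z-periodic wrapping.
    """

    positions: np.ndarray
    bead_types: tuple[str, ...]   # per bead slot, length beads_per_monomer
    charges: np.ndarray           # (n_monomers, beads_per_monomer)
    box: np.ndarray               # (3,)
    z_periodic: bool = True
    spec: Optional[FibreSpec] = None
    time: float = 0.0

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[0]

    @property
    def cores(self) -> np.ndarray:
        """Core bead positions, (n_monomers, 3)."""
        return self.positions[:, 0, :]

    def wrapped(self) -> "FibreConformation":
        if not self.z_periodic:
            return self
        pos = self.positions.copy()
        pos[..., 2] = np.mod(pos[..., 2], self.box[2])
        return replace_conf(self, positions=pos)

    def translated(self, shift) -> "FibreConformation":
        return replace_conf(self, positions=self.positions + np.asarray(shift))

    def rotated_z(self, angle: float) -> "FibreConformation":
        c, s = math.cos(angle), math.sin(angle)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        centre = self.positions.reshape(-1, 3).mean(axis=0)
        pos = (self.positions - centre) @ R.T + centre
        return replace_conf(self, positions=pos)


def replace_conf(conf: FibreConformation, **kw) -> FibreConformation:
    d = dict(positions=conf.positions, bead_types=conf.bead_types,
             charges=conf.charges, box=conf.box, z_periodic=conf.z_periodic,
             spec=conf.spec, time=conf.time)
    d.update(kw)
    return FibreConformation(**d)


def generate_fibre(spec: FibreSpec,
                   pot: Optional[PairPotentialParams] = None) -> FibreConformation:
    """Build a fibre conformation from its spec (deterministic per seed).

    Cores sit on the z axis at spacing c; three amide beads at 120°
    spacing (charges alternating ±q by monomer parity so stacked
    neighbours attract) and outer side beads further out; defects are
    applied in list order, then seeded thermal jitter.
    """
    pot = pot or PairPotentialParams()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_monomers, spec.beads_per_monomer
    c = spec.stacking_distance
    box = spec.box.copy()
    centre_xy = box[0] / 2.0

    pos = np.zeros((n, m, 3))
    charges = np.zeros((n, m))
    bead_types = ["C"] + ["N"] * min(3, spec.n_side) + ["S"] * max(0, spec.n_side - 3)

    angles_amide = np.deg2rad([0.0, 120.0, 240.0])[: min(3, spec.n_side)]
    n_outer = max(0, spec.n_side - 3)
    angles_outer = np.deg2rad(60.0 + 120.0 * np.arange(n_outer) % 360)

    z = 0.0
    gap_after = {d.at_monomer: d.magnitude for d in spec.defects if d.kind == "break"}
    for i in range(n):
        pos[i, 0] = (centre_xy, centre_xy, z)
        k = 1
        for a in angles_amide:
            pos[i, k] = (centre_xy + spec.amide_radius * math.cos(a),
                         centre_xy + spec.amide_radius * math.sin(a), z)
            charges[i, k] = pot.effective_hbond_q * (1 if i % 2 == 0 else -1)
            k += 1
        for a in angles_outer:
            pos[i, k] = (centre_xy + spec.side_radius * math.cos(a),
                         centre_xy + spec.side_radius * math.sin(a), z)
            k += 1
        z += c
        if i in gap_after:
            z += gap_after[i]

    for d in spec.defects:
        i = d.at_monomer
        if d.kind == "break":
            pass  # gap already opened while stacking
        elif d.kind == "fold":
            pos[i] += (d.magnitude, 0.0, 0.0)
        elif d.kind == "adsorbed":
            pos[i] += (d.magnitude, 0.0, 0.5 * c)
        elif d.kind == "dissolved":
            pos[i] += (d.magnitude, 0.0, 0.0)

    if spec.thermal_noise > 0:
        pos += rng.normal(scale=spec.thermal_noise, size=pos.shape)

    return FibreConformation(positions=pos, bead_types=tuple(bead_types),
                             charges=charges, box=box, z_periodic=spec.z_periodic,
                             spec=spec)


def default_defects() -> tuple[DefectSpec, ...]:
    """The documented defect list of the default defected-fibre ensemble.

    Breaks with gaps wide enough to sever the stacking contact, a
    doubly-broken (isolated-in-place) monomer and one dissolved monomer.
    Each severed contact removes one stacking interaction and exposes one
    monomer face, so the ensemble spans fully incorporated
    (coordination ≈ 2), fragment-end (≈1) and free (≈0) monomers — the
    contact-counting spectrum behind the linear ΔE–SASA trend of
    defected water-soluble fibres.
    """
    return (
        DefectSpec("break", 11, 8.0),
        DefectSpec("break", 31, 10.0),
        DefectSpec("break", 54, 14.0),
        DefectSpec("break", 43, 9.0),
        DefectSpec("break", 44, 9.0),   # gaps both sides: monomer 44 isolated
    )


def default_defected_ensemble(seed: int = 2024, n_frames: int = 8,
                              n_monomers: int = 80,
                              thermal_noise: float = 0.15) -> list[FibreConformation]:
    """Frames of the default defected fibre-1-like ensemble.

    Independent thermal jitter per frame around the same defect scaffold;
    per-monomer metrics are meant to be frame-averaged.
    """
    return [generate_fibre(FibreSpec(n_monomers=n_monomers,
                                     defects=default_defects(),
                                     thermal_noise=thermal_noise,
                                     seed=seed + k))
            for k in range(n_frames)]


# ----------------------------------------------------------------------
# XYZ I/O (element column encodes bead type; comment carries box & time)
# ----------------------------------------------------------------------

def write_xyz(path, conf_or_frames, mode: str = "w") -> None:
    frames = conf_or_frames if isinstance(conf_or_frames, (list, tuple)) \
        else [conf_or_frames]
    with open(path, mode) as fh:
        for conf in frames:
            pos = conf.positions.reshape(-1, 3)
            types = list(conf.bead_types) * conf.n_monomers
            fh.write(f"{len(pos)}\n")
            bx, by, bz = conf.box
            fh.write(f"box {bx:.6f} {by:.6f} {bz:.6f} "
                     f"z_periodic {int(conf.z_periodic)} time {conf.time:.9g}\n")
            for t, (x, y, z) in zip(types, pos):
                fh.write(f"{t} {x:.9f} {y:.9f} {z:.9f}\n")


def read_xyz(path, beads_per_monomer: int) -> list[FibreConformation]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nat = int(lines[i].strip())
        comment = lines[i + 1].split()
        box = np.array([float(comment[1]), float(comment[2]), float(comment[3])])
        zp = bool(int(comment[5])) if "z_periodic" in comment else True
        t = float(comment[7]) if "time" in comment else 0.0
        types, pos = [], []
        for row in lines[i + 2: i + 2 + nat]:
            toks = row.split()
            types.append(toks[0])
            pos.append([float(v) for v in toks[1:4]])
        n_mono = nat // beads_per_monomer
        pos = np.array(pos).reshape(n_mono, beads_per_monomer, 3)
        frames.append(FibreConformation(
            positions=pos, bead_types=tuple(types[:beads_per_monomer]),
            charges=np.zeros((n_mono, beads_per_monomer)), box=box,
            z_periodic=zp, time=t))
        i += 2 + nat
    return frames
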