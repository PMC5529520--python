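"""Langevin sampler, metadynamics engine and FES estimators."""

import itertools
import math

import numpy as np
import pytest

from suprafibre.constants import ROOM, SimulationConstants
from suprafibre.landscapes import LandscapeSpec, Well, build_landscape
from suprafibre.sampling import (BiasState, FESGrid, GridSpec, Hill,
                                 LangevinParams, MetaDParams, WallEscapeError,
                                 barrier_height, deposit_hill, fes_from_bias,
                                 fes_from_histogram, friction_for,
                                 mfpt_bruteforce, mfpt_quadrature, run_metad,
                                 simulate_langevin)


def make_grid():
    return GridSpec((0.0,), (3.5,), 0.05)


# ----------------------------------------------------------------------
# Langevin
# ----------------------------------------------------------------------

class TestLangevin:
    def test_equipartition_in_harmonic_well(self, gaussian_well):
        """Position variance ≈ kB·T/k for curvature k = depth/width²."""
        k = 50.0  # kcal/mol per CV² at the well bottom
        p = LangevinParams(dt=0.002, friction=ROOM.kT / 0.1, temperature=300.0,
                           n_steps=400_000, seed=2, init=0.0)
        traj = simulate_langevin(gaussian_well, p, stride=4)
        burn = traj.positions[100:]
        # Gaussian well softens quartically: allow a few % above kT/k
        assert burn.var() == pytest.approx(ROOM.kT / k, rel=0.06)

    def test_baoab_equipartition(self, gaussian_well):
        p = LangevinParams(dt=0.01, friction=5.0, temperature=300.0,
                           n_steps=300_000, seed=3, init=0.0, mode="baoab")
        traj = simulate_langevin(gaussian_well, p, stride=3)
        assert traj.positions[200:].var() == pytest.approx(ROOM.kT / 50.0, rel=0.08)

    def test_near_zero_temperature_stays_at_minimum(self, gaussian_well):
        p = LangevinParams(dt=0.002, friction=1.0, temperature=1e-6,
                           n_steps=20_000, seed=0, init=0.0)
        traj = simulate_langevin(gaussian_well, p)
        assert np.abs(traj.positions).max() < 1e-3

    def test_double_well_boltzmann_ratio(self, fibre1_field):
        """Occupancy ratio of A vs B matches the Boltzmann weights."""
        f = fibre1_field
        p = LangevinParams(dt=0.01, friction=friction_for(f), temperature=300.0,
                           n_steps=1_500_000, seed=7, init=1.0)
        pos = simulate_langevin(f, p, stride=3).positions
        nA = ((pos > 0.6) & (pos < 1.4)).sum()
        nB = ((pos > 2.1) & (pos < 3.0)).sum()
        # independent oracle: numerical partition integrals per state
        xs = np.linspace(0.4, 3.1, 4001)
        w = np.exp(-ROOM.beta * f.energy(xs))
        zA = np.trapezoid(w[(xs > 0.6) & (xs < 1.4)], dx=xs[1] - xs[0])
        zB = np.trapezoid(w[(xs > 2.1) & (xs < 3.0)], dx=xs[1] - xs[0])
        assert math.log(nA / nB) == pytest.approx(math.log(zA / zB), abs=0.25)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LangevinParams(dt=1.0, friction=3.0, temperature=300.0,
                           n_steps=10, seed=0, init=0.0)
        with pytest.raises(ValueError):
            LangevinParams(dt=0.01, friction=1.0, temperature=300.0,
                           n_steps=0, seed=0, init=0.0)

    def test_wall_escape_aborts_with_diagnostic(self, gaussian_well):
        p = LangevinParams(dt=0.002, friction=ROOM.kT / 0.1, temperature=300.0,
                           n_steps=500_000, seed=5, init=0.0)
        with pytest.raises(WallEscapeError, match="step"):
            simulate_langevin(gaussian_well, p, escape_tolerance=-3.7)


# ----------------------------------------------------------------------
# hill deposition / bias bookkeeping
# ----------------------------------------------------------------------

class TestBias:
    def test_first_hill_height_is_w0(self):
        p = MetaDParams(w0=0.3, sigma=0.1, pace=10, gamma=5.0, grid=make_grid())
        st = BiasState(p.grid, p.gamma)
        deposit_hill(st, 1.0, p)
        assert st.hills[0].height == pytest.approx(0.3)

    def test_second_hill_at_same_point_formula(self):
        """Height decays by exp(−V/(kB·ΔT)) with V = w0 from the first hill."""
        p = MetaDParams(w0=0.3, sigma=0.1, pace=10, gamma=5.0, grid=make_grid())
        st = BiasState(p.grid, p.gamma)
        deposit_hill(st, 1.0, p)
        deposit_hill(st, 1.0, p)
        dT = p.delta_T(300.0)
        expected = 0.3 * math.exp(-0.3 / (ROOM.kB * dT))
        assert st.hills[1].height == pytest.approx(expected, rel=1e-12)

    def test_repeated_deposition_heights_strictly_decrease(self):
        p = MetaDParams(w0=0.4, sigma=0.1, pace=10, gamma=4.0, grid=make_grid())
        st = BiasState(p.grid, p.gamma)
        for _ in range(40):
            deposit_hill(st, 1.2, p)
        h = [hill.height for hill in st.hills]
        assert all(a > b for a, b in zip(h, h[1:]))
        # bias stays bounded: V < kB·ΔT·log-growth envelope, far below n*w0
        assert st.bias_direct([1.2]) < 40 * 0.4 * 0.5

    def test_non_tempered_heights_constant(self):
        p = MetaDParams(w0=0.2, sigma=0.1, pace=10, gamma=2.0,
                        grid=make_grid(), well_tempered=False)
        st = BiasState(p.grid, 1.0)
        for _ in range(5):
            deposit_hill(st, 1.0, p)
        assert all(h.height == 0.2 for h in st.hills)

    def test_grid_cache_matches_direct_summation(self):
        p = MetaDParams(w0=0.3, sigma=0.12, pace=10, gamma=5.0, grid=make_grid())
        st = BiasState(p.grid, p.gamma)
        rng = np.random.default_rng(0)
        for x in rng.uniform(0.5, 3.0, size=30):
            deposit_hill(st, float(x), p)
        nodes = st.axes[0]
        direct = np.array([st.bias_direct([x]) for x in nodes])
        assert np.allclose(st.grid_cache, direct, atol=1e-9)

    def test_gamma_required_for_well_tempered(self):
        with pytest.raises(ValueError, match="gamma"):
            MetaDParams(w0=0.3, sigma=0.1, pace=10, gamma=1.0, grid=make_grid())


# ----------------------------------------------------------------------
# FES estimators
# ----------------------------------------------------------------------

class TestFES:
    def test_empty_hills_flat_fes(self):
        st = BiasState(make_grid(), gamma=5.0)
        fes = fes_from_bias(st)
        assert np.allclose(fes.F, 0.0)

    def test_bias_inversion_rejects_non_tempered(self):
        st = BiasState(make_grid(), gamma=1.0)
        with pytest.raises(ValueError, match="gamma"):
            fes_from_bias(st)

    def test_converged_run_recovers_harmonic_well(self, gaussian_well):
        """Bias-inverted FES matches the analytic potential to 0.2 kcal/mol."""
        mp = MetaDParams(w0=0.15, sigma=0.15, pace=300, gamma=9.0,
                         grid=GridSpec.for_field(gaussian_well, pad=0.0))
        p = LangevinParams(dt=0.002, friction=ROOM.kT / 0.1, temperature=300.0,
                           n_steps=1_500_000, seed=4, init=0.0)
        run = run_metad(gaussian_well, mp, p, average_from=0.5)
        fes = fes_from_bias(run.bias, bias_average=run.bias_average)
        U = gaussian_well.energy(fes.grid)
        U -= U.min()
        sel = U <= 5.0
        rmsd = np.sqrt(((fes.F[sel] - U[sel]) ** 2).mean())
        assert rmsd <= 0.2

    def test_histogram_uniform_samples_flat(self):
        rng = np.random.default_rng(1)
        fes = fes_from_histogram(rng.uniform(0, 1, 200_000), bins=20)
        assert np.nanmax(fes.F) < 0.05

    def test_histogram_gaussian_curvature(self):
        """F is quadratic with curvature kB·T/σ² for Gaussian samples."""
        rng = np.random.default_rng(2)
        sigma = 0.3
        x = rng.normal(0.0, sigma, 400_000)
        fes = fes_from_histogram(x, bins=np.linspace(-0.9, 0.9, 61))
        coeff = np.polyfit(fes.grid, fes.F, 2)
        assert coeff[0] == pytest.approx(0.5 * ROOM.kT / sigma**2, rel=0.05)

    def test_histogram_masks_empty_bins(self):
        fes = fes_from_histogram(np.array([0.05, 0.05, 0.95, 0.95]),
                                 bins=np.linspace(0, 1, 11))
        assert np.isnan(fes.F[5])
        assert np.isfinite(fes.F[0])

    def test_histogram_empty_rejected(self):
        with pytest.raises(ValueError):
            fes_from_histogram(np.empty(0), bins=10)

    def test_estimators_agree_on_low_barrier(self, fibre1_field):
        """Bias inversion, standard MetaD and histogram give nearly
        identical FES on a ≤3 kcal/mol landscape (RMSD ≤ 0.3)."""
        f = fibre1_field
        states = f.spec.states
        grid = GridSpec.for_field(f)
        pm = LangevinParams(dt=0.01, friction=friction_for(f), temperature=300.0,
                            n_steps=1_000_000, seed=3, init=1.0)
        wt = run_metad(f, MetaDParams(w0=0.1, sigma=0.1, pace=300, gamma=7.7,
                                      grid=grid), pm, average_from=0.4)
        fes_wt = fes_from_bias(wt.bias, states=states, bias_average=wt.bias_average)
        std = run_metad(f, MetaDParams(w0=0.12, sigma=0.1, pace=500, gamma=2.0,
                                       grid=grid, well_tempered=False),
                        pm, average_from=0.5)
        fes_std = fes_from_bias(std.bias, method="standard_metad", states=states,
                                bias_average=std.bias_average)
        pu = LangevinParams(dt=0.01, friction=friction_for(f), temperature=300.0,
                            n_steps=1_500_000, seed=5, init=1.0)
        tr = simulate_langevin(f, pu, stride=2)
        fes_h = fes_from_histogram(tr, bins=np.arange(0.3, 3.25, 0.05),
                                   states=states)
        xs = np.arange(0.5, 3.0, 0.05)
        U = f.energy(xs)
        U -= U.min()
        sel = U <= 4.0

        def on(fes):
            m = np.isfinite(fes.F)
            return np.interp(xs, np.ravel(fes.grid)[m], fes.F[m])

        curves = [on(fes_wt), on(fes_std), on(fes_h)]
        for a, b in itertools.combinations(curves, 2):
            assert np.sqrt(((a[sel] - b[sel]) ** 2).mean()) <= 0.3

    def test_biased_density_at_effective_temperature(self, gaussian_well):
        """Long-time WT sampling is Boltzmann at T_eff = γ·T."""
        gamma = 6.0
        mp = MetaDParams(w0=0.25, sigma=0.3, pace=200, gamma=gamma,
                         grid=GridSpec.for_field(gaussian_well, pad=0.0))
        p = LangevinParams(dt=0.002, friction=ROOM.kT / 0.1, temperature=300.0,
                           n_steps=2_000_000, seed=8, init=0.0)
        run = run_metad(gaussian_well, mp, p, stride=4)
        pos = run.traj.positions[len(run.traj.positions) // 2:]
        # oracle: Boltzmann variance at T_eff by numerical quadrature
        xs = np.linspace(-3.0, 3.0, 4001)
        w = np.exp(-ROOM.beta * gaussian_well.energy(xs) / gamma)
        w /= np.trapezoid(w, xs)
        var_exact = np.trapezoid(xs**2 * w, xs) - np.trapezoid(xs * w, xs) ** 2
        assert pos.var() == pytest.approx(var_exact, rel=0.12)


# ----------------------------------------------------------------------
# barrier_height
# ----------------------------------------------------------------------

def minimax_oracle_2d(F, si, ti):
    """Exhaustive minimax: lowest threshold connecting source to target."""
    import scipy.ndimage as ndi
    levels = np.unique(F[np.isfinite(F)])
    for lev in levels:
        mask = F <= lev
        lab, _ = ndi.label(mask)
        if lab[si] and lab[si] == lab[ti]:
            return lev
    raise AssertionError("no path")


class TestBarrierHeight:
    def test_flat_fes_zero(self):
        g = np.linspace(0, 3, 61)
        fes = FESGrid(grid=g, F=np.zeros(61), method="histogram")
        assert barrier_height(fes, (0.0, 0.5), (2.5, 3.0)) == 0.0

    def test_1d_equals_running_max_oracle(self):
        rng = np.random.default_rng(3)
        g = np.linspace(0, 3, 61)
        F = rng.uniform(0, 5, 61)
        F[5], F[55] = 0.0, 0.5
        fes = FESGrid(grid=g, F=F, method="histogram")
        got = barrier_height(fes, (g[4], g[6]), (g[54], g[56]))
        expect = F[5:56].max() - F[5]
        assert got == pytest.approx(expect)

    def test_unsampled_gap_raises_with_location(self):
        g = np.linspace(0, 3, 61)
        F = np.zeros(61)
        F[30] = np.nan
        fes = FESGrid(grid=g, F=F, method="histogram")
        with pytest.raises(ValueError, match="gap"):
            barrier_height(fes, (0.0, 0.5), (2.5, 3.0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_2d_minimax_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.uniform(0, 10, (6, 6))
        F[0, 0] = 0.0
        F[5, 5] = 1.0
        gx, gy = np.meshgrid(np.arange(6.0), np.arange(6.0), indexing="ij")
        grid = np.stack([gx, gy], axis=-1)
        fes = FESGrid(grid=grid, F=F.copy(), method="histogram")
        got = barrier_height(fes, ((-.1, .1), (-.1, .1)),
                             ((4.9, 5.1), (4.9, 5.1)))
        lev = minimax_oracle_2d(fes.F, (0, 0), (5, 5))
        assert got == pytest.approx(lev - fes.F[0, 0])


# ----------------------------------------------------------------------
# MFPT
# ----------------------------------------------------------------------

class TestMFPT:
    def test_free_diffusion_closed_form(self):
        """Reflecting at 0, absorbing at L: MFPT ≈ L²/(2D).

        The wall is a steep quartic rather than a hard reflector, so a
        small penetration-depth excess over the ideal closed form is
        expected; the quadrature oracle (exact for the soft wall) pins
        the simulation, and both sit near L²/(2D).
        """
        spec = LandscapeSpec(name="flat", dim=1, wells=(),
                             walls=((0.0, 10.0),), states={"A": ((0.0, 10.0),)},
                             diffusion=0.1, wall_k=500.0)
        f = build_landscape(spec, calibrate=False)
        L, D = 4.0, 0.1
        exact = mfpt_quadrature(f, 0.0, L, diffusion=D)
        assert exact == pytest.approx(L**2 / (2 * D), rel=0.15)
        p = LangevinParams(dt=0.002, friction=ROOM.kT / D, temperature=300.0,
                           n_steps=600_000, seed=1, init=0.0)
        mean, ci, times = mfpt_bruteforce(f, p, 0.0, (L, 10.0), n_replicas=60)
        assert ci[0] < exact < ci[1]

    def test_bruteforce_matches_quadrature(self, low_barrier_field):
        f = low_barrier_field
        edge = float(f.spec.states["B"][0][0])
        exact = mfpt_quadrature(f, "A", edge)
        p = LangevinParams(dt=0.01, friction=friction_for(f), temperature=300.0,
                           n_steps=400_000, seed=2, init=1.0)
        mean, ci, _ = mfpt_bruteforce(f, p, "A", (edge, 3.0), n_replicas=60)
        assert ci[0] < exact < ci[1]

    def test_kramers_ratio_for_kT_ln10_barrier_increase(self):
        """Raising the barrier by kBT·ln 10 slows escape ~10×."""
        from suprafibre.landscapes import catalogue_field
        f1 = catalogue_field("fibre1_step1")
        f2 = catalogue_field("fibre2_step1")
        edge = float(f1.spec.states["B"][0][0])
        r_exact = mfpt_quadrature(f2, "A", edge) / mfpt_quadrature(f1, "A", edge)
        assert r_exact == pytest.approx(10.0, rel=0.2)
        p = LangevinParams(dt=0.01, friction=friction_for(f1), temperature=300.0,
                           n_steps=1_500_000, seed=3, init=1.0)
        m1, _, _ = mfpt_bruteforce(f1, p, "A", (edge, 3.0), n_replicas=40)
        m2, _, _ = mfpt_bruteforce(f2, p, "A", (edge, 3.0), n_replicas=40)
        assert m2 / m1 == pytest.approx(r_exact, rel=0.5)

    def test_too_few_passages_is_an_error(self, fibre1_field):
        p = LangevinParams(dt=0.01, friction=friction_for(fibre1_field),
                           temperature=300.0, n_steps=50, seed=1, init=1.0)
        with pytest.raises(RuntimeError, match="replicas"):
            mfpt_bruteforce(fibre1_field, p, "A", "B", n_replicas=8)
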