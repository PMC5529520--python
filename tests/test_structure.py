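"""Per-monomer structural metrics: coordination, SASA, ΔE, hot spots."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suprafibre.fibre import (DefectSpec, FibreSpec, PairPotentialParams,
                              default_defected_ensemble, generate_fibre)
from suprafibre.structure import (MonomerMetrics, SwitchingParams,
                                  classify_hot_spots, compute_monomer_metrics,
                                  coordination_number, incorporation_energy,
                                  min_core_distance, regress_dE_sasa, sasa,
                                  sasa_percent_deviation)
from suprafibre.constants import COULOMB_KCAL_A_E2

HARD = SwitchingParams(mode="hard_cutoff")


# ----------------------------------------------------------------------
# coordination
# ----------------------------------------------------------------------

class TestCoordination:
    def test_ideal_interior_about_two(self, ideal_stack):
        assert coordination_number(ideal_stack, 12) == pytest.approx(2.0,
                                                                     abs=0.15)

    def test_isolated_monomer_about_zero(self):
        conf = generate_fibre(FibreSpec(
            n_monomers=24, thermal_noise=0.0, seed=0,
            defects=(DefectSpec("dissolved", 10, 40.0),)))
        assert coordination_number(conf, 10) < 0.05

    def test_fragment_end_hard_mode_exactly_one(self, two_break_fibre):
        assert coordination_number(two_break_fibre, 5, HARD) == 1.0
        assert coordination_number(two_break_fibre, 6, HARD) == 1.0

    def test_switching_function_limit_at_r0(self):
        sw = SwitchingParams()
        assert sw.f(sw.r0) == pytest.approx(sw.n_exp / sw.m_exp, abs=1e-9)

    @given(st.floats(min_value=0.5, max_value=14.9))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_switching_function_continuous_and_decreasing(self, r):
        sw = SwitchingParams()
        eps = 1e-7
        assert abs(sw.f(r + eps) - sw.f(r)) < 1e-4
        assert sw.f(r) >= sw.f(r + 0.5) - 1e-12
        assert 0.0 <= sw.f(r) <= 1.0 + 1e-9

    def test_exponent_validation(self):
        with pytest.raises(ValueError):
            SwitchingParams(n_exp=12, m_exp=6)
        with pytest.raises(ValueError):
            SwitchingParams(n_exp=5, m_exp=12)


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------

def brute_min_distance(conf, i):
    """Oracle: exhaustive pairwise scan with explicit z images."""
    best = np.inf
    bz = conf.box[2]
    for j in range(conf.n_monomers):
        if j == i:
            continue
        for shift in (-bz, 0.0, bz):
            d = conf.cores[j] + np.array([0, 0, shift]) - conf.cores[i]
            best = min(best, float(np.linalg.norm(d)))
    return best


class TestMinCoreDistance:
    def test_ideal_stack_is_stacking_distance(self, ideal_stack):
        assert min_core_distance(ideal_stack, 12) == 3.5

    def test_wraps_across_periodic_boundary(self, ideal_stack):
        assert min_core_distance(ideal_stack, 0) == 3.5
        assert min_core_distance(ideal_stack, 23) == 3.5

    def test_random_instance_matches_brute_force(self):
        conf = generate_fibre(FibreSpec(n_monomers=10, thermal_noise=2.0,
                                        seed=5))
        for i in range(10):
            assert min_core_distance(conf, i) == pytest.approx(
                brute_min_distance(conf, i), abs=1e-9)


# ----------------------------------------------------------------------
# SASA
# ----------------------------------------------------------------------

class TestSASA:
    def test_single_bead_closed_form(self):
        conf = generate_fibre(FibreSpec(n_monomers=2, n_side=0,
                                        stacking_distance=60.0, box_xy=200.0,
                                        z_periodic=False, seed=0))
        a = sasa(conf, probe=1.9, n_sphere_points=960)
        exact = 4 * math.pi * (2.3 + 1.9) ** 2
        assert a[0] == pytest.approx(exact, rel=0.01)

    def test_two_spheres_analytic_cap(self):
        """Accessible area of two equal spheres at distance d: each loses a
        cap of height h = R − d/2 on the inflated sphere of radius R."""
        d = 4.0
        conf = generate_fibre(FibreSpec(n_monomers=2, n_side=0,
                                        stacking_distance=d, box_xy=200.0,
                                        z_periodic=False, seed=0))
        a = sasa(conf, probe=1.9, n_sphere_points=2000)
        R = 2.3 + 1.9
        h = R - d / 2
        exact = 4 * math.pi * R**2 - 2 * math.pi * R * h
        assert a[0] == pytest.approx(exact, rel=0.02)

    def test_point_floor_rejected(self, ideal_stack):
        with pytest.raises(ValueError, match="accuracy"):
            sasa(ideal_stack, n_sphere_points=40)

    def test_fragment_ends_more_exposed(self, two_break_fibre):
        a = sasa(two_break_fibre, n_sphere_points=240)
        assert a[5] > a.mean()
        assert a[8] < a[5]


# ----------------------------------------------------------------------
# incorporation energy
# ----------------------------------------------------------------------

def brute_force_dE(conf, i, pot):
    """Oracle: explicit double loop over beads with explicit z images."""
    from suprafibre.structure import _pair_tables
    eps_b, sig_b = _pair_tables(conf, pot)
    bz = conf.box[2]
    e = 0.0
    n, m, _ = conf.positions.shape
    for bi in range(m):
        for j in range(n):
            if j == i:
                continue
            for bj in range(m):
                best = np.inf
                for shift in (-bz, 0.0, bz):
                    d = (conf.positions[j, bj] + np.array([0, 0, shift])
                         - conf.positions[i, bi])
                    best = min(best, float(np.linalg.norm(d)))
                r = best
                eps = math.sqrt(eps_b[bi] * eps_b[bj])
                sig = 0.5 * (sig_b[bi] + sig_b[bj])
                e += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
                qq = conf.charges[i, bi] * conf.charges[j, bj]
                if pot.hbond_enabled and qq != 0.0:
                    e += (COULOMB_KCAL_A_E2 * qq
                          * math.exp(-r / pot.screening_length)
                          / (pot.dielectric * r))
    return e


class TestIncorporationEnergy:
    def test_isolated_monomer_zero(self):
        conf = generate_fibre(FibreSpec(
            n_monomers=3, thermal_noise=0.0, seed=0,
            defects=(DefectSpec("dissolved", 1, 60.0),), box_xy=200.0))
        assert incorporation_energy(conf, 1) == pytest.approx(0.0, abs=1e-6)

    def test_pair_at_lj_minimum_is_minus_eps(self):
        pot = PairPotentialParams(hbond_enabled=False)
        conf = generate_fibre(FibreSpec(n_monomers=2, n_side=0,
                                        stacking_distance=2 ** (1 / 6)
                                        * pot.sigma_core,
                                        z_periodic=False, seed=0))
        assert incorporation_energy(conf, 0, pot) == pytest.approx(-0.627,
                                                                   abs=1e-9)

    def test_eps_scale_multiplies_core_term(self):
        pot = PairPotentialParams(hbond_enabled=False, eps_scale=3.0)
        conf = generate_fibre(FibreSpec(n_monomers=2, n_side=0,
                                        stacking_distance=2 ** (1 / 6)
                                        * pot.sigma_core,
                                        z_periodic=False, seed=0))
        assert incorporation_energy(conf, 0, pot) == pytest.approx(-3 * 0.627,
                                                                   abs=1e-9)

    def test_five_monomer_toy_matches_brute_force(self):
        pot = PairPotentialParams()
        conf = generate_fibre(FibreSpec(n_monomers=5, thermal_noise=0.05,
                                        seed=3), pot)
        for i in range(5):
            got = incorporation_energy(conf, i, pot, cutoff=1e6)
            assert got == pytest.approx(brute_force_dE(conf, i, pot),
                                        rel=1e-9)

    def test_overlapping_beads_rejected(self):
        conf = generate_fibre(FibreSpec(n_monomers=2, n_side=0,
                                        stacking_distance=0.05,
                                        z_periodic=False, seed=0))
        with pytest.raises(ValueError, match="overlap"):
            incorporation_energy(conf, 0)


# ----------------------------------------------------------------------
# hot spots, regression, percentages
# ----------------------------------------------------------------------

class TestHotSpots:
    def test_ideal_stack_has_none(self, ideal_stack):
        mets = compute_monomer_metrics(ideal_stack, n_sphere_points=240)
        assert classify_hot_spots(mets) == set()

    def test_two_break_fibre_flags_exactly_four_ends(self, two_break_fibre):
        mets = compute_monomer_metrics(two_break_fibre, sw=HARD,
                                       n_sphere_points=240)
        assert classify_hot_spots(mets) == {5, 6, 15, 16}

    def test_identical_monomers_no_hot_spot_by_tie_rule(self):
        mets = [MonomerMetrics(i, coordination=0.5, sasa=100.0,
                               sasa_pct_dev=0.0, dE=-1.0, min_core_dist=3.5)
                for i in range(6)]
        assert classify_hot_spots(mets) == set()

    def test_invariant_under_rigid_motion_and_wrap(self, two_break_fibre):
        base = classify_hot_spots(compute_monomer_metrics(
            two_break_fibre, sw=HARD, n_sphere_points=240))
        moved = two_break_fibre.translated((3.0, -2.0, 11.0)).rotated_z(0.7)
        wrapped = moved.wrapped()
        got = classify_hot_spots(compute_monomer_metrics(
            wrapped, sw=HARD, n_sphere_points=240))
        assert got == base

    def test_healing_break_raises_coordination_lowers_sasa(self):
        broken = generate_fibre(FibreSpec(
            n_monomers=24, thermal_noise=0.0, seed=1,
            defects=(DefectSpec("break", 5, 8.0),)))
        healed = generate_fibre(FibreSpec(n_monomers=24, thermal_noise=0.0,
                                          seed=1))
        for i in (5, 6):
            assert coordination_number(healed, i) > \
                coordination_number(broken, i)
        sb = sasa(broken, n_sphere_points=240)
        sh = sasa(healed, n_sphere_points=240)
        assert sh[5] < sb[5] and sh[6] < sb[6]


class TestRegression:
    def test_collinear_points_r2_one(self):
        mets = [MonomerMetrics(i, 2.0, sasa=200.0 + 10 * i, sasa_pct_dev=0.0,
                               dE=-15.0 + 0.3 * i, min_core_dist=3.5)
                for i in range(6)]
        assert regress_dE_sasa(mets).r_squared == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(200, 400, 30)
        y = -20 + 0.03 * x + rng.normal(0, 0.5, 30)
        mets = [MonomerMetrics(i, 2.0, sasa=xi, sasa_pct_dev=0.0, dE=yi,
                               min_core_dist=3.5)
                for i, (xi, yi) in enumerate(zip(x, y))]
        reg = regress_dE_sasa(mets)
        X = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg.slope == pytest.approx(slope, rel=1e-9)
        assert reg.intercept == pytest.approx(intercept, rel=1e-9)

    def test_zero_variance_rejected(self):
        mets = [MonomerMetrics(i, 2.0, sasa=100.0, sasa_pct_dev=0.0,
                               dE=-1.0 * i, min_core_dist=3.5)
                for i in range(5)]
        with pytest.raises(ValueError, match="variance"):
            regress_dE_sasa(mets)

    def test_default_ensemble_strong_inverse_linearity(self):
        """Frame-averaged ΔE vs SASA on the default defected ensemble is
        nearly perfectly linear, incorporation weakening with exposure."""
        frames = default_defected_ensemble(seed=2024, n_frames=4)
        mets = compute_monomer_metrics(frames, n_sphere_points=480)
        reg = regress_dE_sasa(mets)
        assert reg.r_squared > 0.97
        assert reg.slope > 0  # ΔE less negative (weaker) at higher SASA


class TestSasaPercentDeviation:
    def test_all_equal_zero(self):
        mets = [MonomerMetrics(i, 2.0, sasa=123.0, sasa_pct_dev=0.0, dE=-1.0,
                               min_core_dist=3.5) for i in range(4)]
        assert np.allclose(sasa_percent_deviation(mets), 0.0)

    def test_mean_centering_identity(self):
        sas = [100.0, 150.0, 200.0, 90.0]
        mets = [MonomerMetrics(i, 2.0, sasa=s, sasa_pct_dev=0.0, dE=-1.0,
                               min_core_dist=3.5)
                for i, s in enumerate(sas)]
        dev = sasa_percent_deviation(mets)
        assert dev.sum() == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_values(self):
        sas = [100.0, 300.0]  # mean 200
        mets = [MonomerMetrics(i, 2.0, sasa=s, sasa_pct_dev=0.0, dE=-1.0,
                               min_core_dist=3.5)
                for i, s in enumerate(sas)]
        np.testing.assert_allclose(sasa_percent_deviation(mets),
                                   [-50.0, 50.0])


def test_ensemble_negative_favourability_consistency():
    """Higher SASA implies less favourable ΔE across defected ensembles."""
    for seed in (1, 2):
        frames = default_defected_ensemble(seed=seed, n_frames=2)
        mets = compute_monomer_metrics(frames, n_sphere_points=240)
        sa = np.array([m.sasa for m in mets])
        de = np.array([m.dE for m in mets])
        assert np.corrcoef(sa, de)[0, 1] > 0.9
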