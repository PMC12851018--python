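"""Geometry optimisation, constrained scans, crossing location, RMSD and
benchmark statistics against closed-form oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from nsepot import (
    AtomicSystem,
    BenchmarkRow,
    ReactionProfile,
    benchmark_stats,
    crossing_point,
    optimize_geometry,
    profile_mad,
    reaction_energetics,
    rmsd_aligned,
    scan_1d,
    scan_2d,
)
from nsepot.reactions import ProfilePoint
from nsepot.surrogate import analytic_dimer_energy


def _profile(xs, es, mult=1.0):
    points = [ProfilePoint((float(x),),
                           AtomicSystem([1, 1], [[0, 0, 0], [max(x, 0.1), 0, 0]]),
                           float(e))
              for x, e in zip(xs, es)]
    return ReactionProfile(points, multiplicity=mult)


@pytest.fixture()
def dimer_pot(oracle):
    return oracle.as_potential(1)


class TestOptimizeGeometry:
    def test_already_at_minimum(self, oracle, dimer_pot):
        r_e = oracle.morse_for(1, 1, 1).r_e
        h2 = AtomicSystem([1, 1], [[0, 0, 0], [r_e, 0, 0]])
        opt, info = optimize_geometry(dimer_pot, h2)
        assert info["converged"] and info["steps"] <= 2
        r = np.linalg.norm(opt.coordinates[1] - opt.coordinates[0])
        assert r == pytest.approx(r_e, abs=1e-4)

    def test_converges_to_analytic_minimum(self, oracle, dimer_pot):
        r_e = oracle.morse_for(1, 1, 1).r_e
        start = AtomicSystem([1, 1], [[0, 0, 0], [r_e + 0.3, 0, 0]])
        opt, info = optimize_geometry(dimer_pot, start)
        assert info["converged"]
        r = np.linalg.norm(opt.coordinates[1] - opt.coordinates[0])
        assert r == pytest.approx(r_e, abs=1e-3)

    def test_infinite_tolerance_returns_input(self, dimer_pot, h2):
        opt, info = optimize_geometry(dimer_pot, h2, max_force_tol=np.inf)
        np.testing.assert_array_equal(opt.coordinates, h2.coordinates)
        assert info["steps"] == 0

    def test_energy_monotone_over_steps(self, oracle_coulomb, water):
        pot = oracle_coulomb.as_potential(1)
        e_start, _ = pot.energy_forces(water)
        opt, info = optimize_geometry(pot, water, max_steps=40)
        assert info["energy"] <= e_start + 1e-12


class TestScan1D:
    def test_rigid_scan_matches_analytic_morse(self, oracle, dimer_pot, h2):
        grid = np.linspace(0.6, 4.0, 25)
        profile = scan_1d(dimer_pot, h2, (0, 1), grid, multiplicity=1)
        np.testing.assert_allclose(profile.energies(),
                                   analytic_dimer_energy(oracle, 1, 1, 1, grid),
                                   atol=1e-8)

    def test_reversed_grid_gives_reversed_energies(self, dimer_pot, h2):
        grid = np.linspace(0.6, 3.0, 11)
        fwd = scan_1d(dimer_pot, h2, (0, 1), grid, multiplicity=1, mark=False)
        rev = scan_1d(dimer_pot, h2, (0, 1), grid[::-1], multiplicity=1, mark=False)
        np.testing.assert_allclose(rev.energies(), fwd.energies()[::-1], atol=1e-12)

    def test_relaxed_dimer_equals_rigid(self, dimer_pot, h2):
        grid = np.linspace(0.65, 2.0, 6)
        rigid = scan_1d(dimer_pot, h2, (0, 1), grid, multiplicity=1)
        relaxed = scan_1d(dimer_pot, h2, (0, 1), grid, multiplicity=1, relax=True)
        np.testing.assert_allclose(relaxed.energies(), rigid.energies(), atol=1e-3)

    def test_relaxation_never_raises_energy(self, oracle_coulomb, water):
        pot = oracle_coulomb.as_potential(1)
        grid = np.linspace(0.9, 1.4, 4)
        rigid = scan_1d(pot, water, (0, 1), grid)
        relaxed = scan_1d(pot, water, (0, 1), grid, relax=True)
        assert np.all(relaxed.energies() <= rigid.energies() + 1e-8)
        for point, target in zip(relaxed.points, grid):
            r = np.linalg.norm(point.system.coordinates[0] - point.system.coordinates[1])
            assert abs(r - target) <= 5e-3

    def test_input_validation(self, dimer_pot, h2):
        with pytest.raises(ValueError, match="distinct"):
            scan_1d(dimer_pot, h2, (0, 0), [1.0, 2.0])
        with pytest.raises(ValueError, match="out of range"):
            scan_1d(dimer_pot, h2, (0, 5), [1.0, 2.0])
        with pytest.raises(ValueError, match="monotone"):
            scan_1d(dimer_pot, h2, (0, 1), [1.0, 2.0, 1.5])


class TestScan2D:
    def test_degenerates_to_1d(self, oracle, dimer_pot, h2):
        grid = np.linspace(0.7, 1.5, 5)
        profile = scan_1d(dimer_pot, h2, (0, 1), grid, multiplicity=1)
        # a second constraint on a disjoint far-away pair leaves the dimer term
        system = AtomicSystem([1, 1, 1, 1],
                              [[0, 0, 0], [0.9, 0, 0], [50, 50, 50], [50.9, 50, 50]])
        grid2d = scan_2d(dimer_pot, system, ((0, 1), (2, 3)), grid, [0.9],
                         relax=False)
        offset = analytic_dimer_energy(oracle, 1, 1, 1, 0.9)  # the far pair
        np.testing.assert_allclose(grid2d[:, 0] - offset, profile.energies(),
                                   atol=1e-6)

    def test_symmetric_molecule_symmetric_grid(self, oracle):
        """Linear H-C-H with equivalent arms: E[a,b] = E[b,a]."""
        pot = oracle.as_potential(1)
        system = AtomicSystem([6, 1, 1],
                              [[0, 0, 0], [1.1, 0, 0], [-1.1, 0, 0]])
        grid = np.linspace(1.0, 1.8, 3)
        energies = scan_2d(pot, system, ((0, 1), (0, 2)), grid, grid, relax=False)
        np.testing.assert_allclose(energies, energies.T, atol=1e-6)

    def test_all_finite_on_3x3(self, oracle_coulomb, water):
        pot = oracle_coulomb.as_potential(1)
        grid = np.linspace(0.9, 1.3, 3)
        energies = scan_2d(pot, water, ((0, 1), (0, 2)), grid, grid, relax=False)
        assert energies.shape == (3, 3) and np.all(np.isfinite(energies))

    def test_shared_pair_rejected(self, dimer_pot, h2):
        with pytest.raises(ValueError, match="share both atoms"):
            scan_2d(dimer_pot, h2, ((0, 1), (1, 0)), [1.0], [1.0])


class TestReactionEnergetics:
    def test_hand_example(self):
        assert reaction_energetics(-10.0, -4.0, -12.0) == (-2.0, 6.0)

    def test_thermoneutral_and_barrierless(self):
        assert reaction_energetics(-5.0, 0.0, -5.0)[0] == 0.0
        assert reaction_energetics(-5.0, -5.0, -8.0)[1] == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            reaction_energetics(np.nan, 0.0, 0.0)


class TestCrossingPoint:
    def test_two_parabolas(self):
        xs = np.arange(0.0, 3.1, 0.5)
        pa = _profile(xs, xs**2)
        pb = _profile(xs, (xs - 2.0) ** 2)
        result = crossing_point(pa, pb)
        assert result.crossed
        assert result.coordinate == pytest.approx(1.0, abs=1e-12)
        assert result.energy == pytest.approx(1.0, abs=1e-12)

    def test_identical_profiles_flagged_degenerate(self):
        xs = np.linspace(0, 1, 5)
        pa = _profile(xs, xs + 1)
        pb = _profile(xs, xs + 1)
        result = crossing_point(pa, pb)
        assert not result.crossed and "degenerate" in result.note
        assert result.coordinate == xs[0]

    def test_no_crossing_returns_closest_contact(self):
        xs = np.linspace(0, 1, 5)
        result = crossing_point(_profile(xs, xs), _profile(xs, xs + 2 - xs**2))
        assert not result.crossed and "closest contact" in result.note

    def test_symmetric_in_arguments(self):
        xs = np.arange(0.0, 3.1, 0.5)
        pa = _profile(xs, xs**2)
        pb = _profile(xs, (xs - 2.0) ** 2)
        r1, r2 = crossing_point(pa, pb), crossing_point(pb, pa)
        assert r1.coordinate == r2.coordinate and r1.crossed == r2.crossed

    def test_mismatched_grids_rejected(self):
        pa = _profile([1.0, 2.0], [0.0, 1.0])
        pb = _profile([1.0, 2.5], [0.0, 1.0])
        with pytest.raises(ValueError, match="identical coordinate grid"):
            crossing_point(pa, pb)

    def test_surrogate_dimer_crossing_near_analytic(self, oracle):
        from nsepot import analytic_crossing_distance

        grid = np.linspace(0.75, 4.0, 66)
        prof_s = scan_1d(oracle.as_potential(1),
                         AtomicSystem([1, 1], [[0, 0, 0], [0.75, 0, 0]]),
                         (0, 1), grid, multiplicity=1)
        prof_t = scan_1d(oracle.as_potential(3),
                         AtomicSystem([1, 1], [[0, 0, 0], [0.75, 0, 0]], 0, 3),
                         (0, 1), grid, multiplicity=3, mark=False)
        result = crossing_point(prof_s, prof_t)
        step = grid[1] - grid[0]
        assert abs(result.coordinate - analytic_crossing_distance(oracle)) < step


class TestRmsd:
    def test_identical_structures(self, water):
        assert rmsd_aligned(water, water) < 1e-12

    def test_rotated_translated_copy(self, water, rng):
        rot = Rotation.random(random_state=5).as_matrix()
        moved = water.with_coordinates(water.coordinates @ rot.T + rng.normal(size=3))
        assert rmsd_aligned(water, moved) < 1e-8

    def test_never_exceeds_unaligned(self, rng):
        for _ in range(5):
            a = AtomicSystem([6] * 5, rng.normal(size=(5, 3)))
            b = AtomicSystem([6] * 5, rng.normal(size=(5, 3)))
            pa = a.coordinates - a.coordinates.mean(axis=0)
            pb = b.coordinates - b.coordinates.mean(axis=0)
            unaligned = np.sqrt(((pa - pb) ** 2).sum() / 5)
            assert rmsd_aligned(a, b) <= unaligned + 1e-12

    def test_matches_bruteforce_rotation_search(self, rng):
        a = AtomicSystem([6, 1, 1, 8], rng.normal(size=(4, 3)))
        b = AtomicSystem([6, 1, 1, 8],
                         a.coordinates + rng.normal(0, 0.4, size=(4, 3)))
        target = rmsd_aligned(a, b)
        p = a.coordinates - a.coordinates.mean(axis=0)
        q = b.coordinates - b.coordinates.mean(axis=0)

        def objective(rotvec):
            r_mat = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(((p - q @ r_mat.T) ** 2).sum() / 4)

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000}).fun
            for x0 in (np.zeros(3), np.ones(3), np.array([-1.0, 2.0, 0.5]))
        )
        assert target == pytest.approx(best, abs=1e-6)

    def test_triangle_like_bound(self, rng):
        for _ in range(10):
            base = rng.normal(size=(5, 3))
            a = AtomicSystem([6] * 5, base)
            b = AtomicSystem([6] * 5, base + rng.normal(0, 0.2, size=(5, 3)))
            c = AtomicSystem([6] * 5, base + rng.normal(0, 0.3, size=(5, 3)))
            assert rmsd_aligned(a, c) <= rmsd_aligned(a, b) + rmsd_aligned(b, c) + 1e-6

    def test_mismatches_rejected(self, water, h2):
        with pytest.raises(ValueError, match="atom count"):
            rmsd_aligned(water, h2)
        swapped = AtomicSystem([1, 8, 1], water.coordinates)
        with pytest.raises(ValueError, match="element order"):
            rmsd_aligned(water, swapped)


class TestBenchmarkStats:
    def test_symmetric_deviations(self):
        rows = [BenchmarkRow("a", 10.0, 11.0), BenchmarkRow("b", 10.0, 9.0)]
        stats = benchmark_stats(rows)
        assert stats.md == pytest.approx(0.0)
        assert stats.mad == pytest.approx(1.0)

    def test_perfect_predictions(self):
        rows = [BenchmarkRow(str(i), float(i), float(i)) for i in range(5)]
        stats = benchmark_stats(rows)
        assert (stats.md, stats.mad, stats.r2) == (0.0, 0.0, 1.0)

    def test_two_table_style_entries(self):
        rows = [BenchmarkRow("1", 0.0, -4.07), BenchmarkRow("2", 0.0, -4.09)]
        stats = benchmark_stats(rows)
        assert stats.md == pytest.approx(-4.08)
        assert stats.mad == pytest.approx(4.08)
        assert stats.r2 is None  # zero reference variance

    def test_deviation_sign_convention(self):
        assert BenchmarkRow("x", 2.0, 5.0).deviation == 3.0


class TestProfileMad:
    def test_identical_and_offset_profiles(self):
        xs = np.linspace(0, 1, 4)
        pa = _profile(xs, [0.0, 2.0, 5.0, 1.0])
        assert profile_mad(pa, pa) == 0.0
        pb = _profile(xs, [7.0, 9.0, 12.0, 8.0])  # constant shift
        assert profile_mad(pa, pb) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        xs = np.linspace(0, 1, 3)
        pa = _profile(xs, [0.0, 1.0, 2.0])
        pb = _profile(xs, [0.0, 2.0, 4.0])
        assert profile_mad(pa, pb) == pytest.approx(1.0)

    def test_length_mismatch(self):
        pa = _profile([0.0, 1.0], [0.0, 1.0])
        pb = _profile([0.0, 0.5, 1.0], [0.0, 0.5, 1.0])
        with pytest.raises(ValueError):
            profile_mad(pa, pb)
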