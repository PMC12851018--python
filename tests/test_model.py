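"""The equilibration layers, the potential's structural guarantees, and the
long-range terms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsepot import (
    AtomicSystem,
    EquilibrationWeights,
    ModelConfig,
    NSEPotential,
    coulomb_energy,
    dispersion_energy,
    ensemble_predict,
    load_checkpoint,
    nqe_update,
    nse_update,
    save_checkpoint,
)
from nsepot.model import COULOMB_K
from nsepot.validation import random_valid_system


class TestEquilibrationUpdates:
    def test_hand_example(self):
        """Deficit 0.4 split 1:3 between the two atoms."""
        out = nqe_update([0.2, -0.1], [1.0, 3.0], 0.5)
        np.testing.assert_allclose(out, [0.3, 0.2], atol=1e-15)

    def test_no_correction_when_sum_already_matches(self):
        q = np.array([0.3, -0.1, 0.05])
        out = nqe_update(q, [1.0, 2.0, 3.0], q.sum())
        np.testing.assert_array_equal(out, q)

    def test_single_atom_takes_whole_total(self):
        assert nqe_update([0.7], [2.3], -1.5) == pytest.approx([-1.5])

    def test_weights_must_be_positive(self):
        with pytest.raises(ValueError, match="strictly positive"):
            EquilibrationWeights([1.0, 0.0])

    @given(
        n=st.integers(1, 10),
        total=st.floats(-3, 3),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_conserves_idempotent_and_affine_in_total(self, n, total, seed):
        rng = np.random.default_rng(seed)
        q = rng.normal(size=n)
        f = rng.uniform(0.05, 4.0, size=n)
        out = nqe_update(q, f, total)
        assert out.sum() == pytest.approx(total, abs=1e-10)
        np.testing.assert_allclose(nqe_update(out, f, total), out, atol=1e-12)
        # affine in the target total with slope f/sum(f)
        out2 = nqe_update(q, f, total + 1.0)
        np.testing.assert_allclose(out2 - out, f / f.sum(), atol=1e-10)

    def test_nse_channels_are_independent(self):
        state = nse_update([0.2, -0.1], [0.0, 0.0], [1.0, 3.0], [1.0, 1.0], 0.5, -1.0)
        np.testing.assert_allclose(state.q_alpha, [0.3, 0.2], atol=1e-15)
        np.testing.assert_allclose(state.q_beta, [-0.5, -0.5], atol=1e-15)

    def test_nse_channel_symmetry(self):
        state = nse_update([0.1, 0.2], [0.1, 0.2], [1.0, 2.0], [1.0, 2.0], 0.4, 0.4)
        np.testing.assert_array_equal(state.q_alpha, state.q_beta)


class TestForwardGuarantees:
    def test_conservation_is_architectural(self, tiny_model, rng):
        """Channel sums hit the (Q, S)-derived totals for untrained params."""
        for _ in range(50):
            system = random_valid_system(rng, 2, 8)
            out = tiny_model.forward(system)
            ea, eb = out.spin_charges.conservation_errors()
            assert max(ea, eb) < 1e-8

    def test_energy_bookkeeping_identity(self, tiny_model, water):
        out = tiny_model.forward(water)
        assert out.bookkeeping_residual() < 1e-8

    def test_rigid_motion_invariance(self, tiny_model, methyl_radical, rng):
        e0 = tiny_model.forward(methyl_radical).energy
        q_mat, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q_mat) < 0:
            q_mat[:, 0] *= -1
        moved = methyl_radical.with_coordinates(
            methyl_radical.coordinates @ q_mat.T + [10.0, -3.0, 1.0])
        assert abs(tiny_model.forward(moved).energy - e0) < 1e-8

    def test_permutation_invariance_and_equivariance(self, tiny_model, methyl_radical):
        out0 = tiny_model.forward(methyl_radical)
        perm = np.array([2, 0, 3, 1])
        permuted = AtomicSystem(methyl_radical.atomic_numbers[perm],
                                methyl_radical.coordinates[perm], 0, 2)
        out1 = tiny_model.forward(permuted)
        assert abs(out1.energy - out0.energy) < 1e-8
        np.testing.assert_allclose(out1.spin_charges.q_alpha,
                                   out0.spin_charges.q_alpha[perm], atol=1e-10)

    def test_singlet_channels_may_polarize_but_balance(self, tiny_model, water):
        """Independent channels can spin-polarize a closed-shell molecule
        atom-wise, but the net spin population is exactly zero."""
        out = tiny_model.forward(water)
        assert abs(out.spin_charges.spin_population.sum()) < 1e-8

    def test_smoothness_in_continuous_multiplicity(self, tiny_model, methyl_radical):
        eps = 1e-3
        e0 = tiny_model.forward(methyl_radical).energy
        e_eps = tiny_model.forward(methyl_radical, multiplicity=2 + eps).energy
        e_big = tiny_model.forward(methyl_radical, multiplicity=2.1).energy
        slope = abs(e_big - e0) / 0.1
        assert abs(e_eps - e0) <= 5.0 * max(slope, 1e-6) * eps

    def test_forces_match_finite_differences(self, tiny_model, rng):
        system = random_valid_system(rng, 5, 7)
        out = tiny_model.forward(system, compute_forces=True)
        step = 1e-4
        fd = np.zeros_like(out.forces)
        for i in range(system.n_atoms):
            for k in range(3):
                cp, cm = system.coordinates.copy(), system.coordinates.copy()
                cp[i, k] += step
                cm[i, k] -= step
                fd[i, k] = -(tiny_model.forward(system.with_coordinates(cp)).energy
                             - tiny_model.forward(system.with_coordinates(cm)).energy) / (2 * step)
        rel = np.abs(fd - out.forces).max() / max(np.abs(out.forces).max(), 1e-10)
        assert rel < 1e-4
        assert np.abs(out.forces.sum(axis=0)).max() < 1e-6

    def test_net_torque_vanishes(self, tiny_model, rng):
        """Rotational invariance implies zero net torque about the centroid."""
        system = random_valid_system(rng, 4, 6)
        out = tiny_model.forward(system, compute_forces=True)
        rel = system.coordinates - system.coordinates.mean(axis=0)
        torque = np.cross(rel, out.forces).sum(axis=0)
        assert np.abs(torque).max() < 1e-6

    def test_translated_system_same_forces(self, tiny_model, water):
        f0 = tiny_model.forward(water, compute_forces=True).forces
        moved = water.with_coordinates(water.coordinates + [5.0, 5.0, 5.0])
        f1 = tiny_model.forward(moved, compute_forces=True).forces
        np.testing.assert_allclose(f0, f1, atol=1e-9)

    def test_unsupported_element_raises(self, tiny_model):
        gold = AtomicSystem([79], [[0, 0, 0]], 0, 2)
        with pytest.raises(KeyError, match="unsupported element"):
            tiny_model.forward(gold)

    def test_nqe_mode_ties_channels(self, water):
        cfg = ModelConfig(elements=(1, 8), mode="nqe", n_basis=6,
                          embedding_dim=6, hidden_dim=16, seed=3)
        model = NSEPotential(cfg)
        out = model.forward(water)
        assert abs(out.spin_charges.q_total.sum() - water.charge) < 1e-10
        np.testing.assert_allclose(out.spin_charges.q_alpha,
                                   out.spin_charges.q_beta, atol=1e-12)

    def test_checkpoint_round_trip(self, tiny_model, water, tmp_path):
        path = tmp_path / "model.ckpt"
        save_checkpoint(tiny_model, path)
        back = load_checkpoint(path)
        assert back.forward(water).energy == tiny_model.forward(water).energy


class TestLongRangeTerms:
    def test_coulomb_zero_charges(self, rng):
        coords = rng.normal(size=(4, 3))
        assert coulomb_energy(np.zeros(4), coords) == 0.0

    def test_coulomb_bare_law_at_large_separation(self):
        r = 50.0
        e = coulomb_energy([1.0, 1.0], [[0, 0, 0], [r, 0, 0]])
        assert e == pytest.approx(COULOMB_K / r, rel=1e-3)

    def test_coulomb_swap_symmetry_and_finite_at_contact(self):
        coords = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        e_ab = coulomb_energy([0.3, -0.4], coords)
        e_ba = coulomb_energy([-0.4, 0.3], coords[::-1])
        assert e_ab == pytest.approx(e_ba, abs=1e-12)
        assert np.isfinite(coulomb_energy([1.0, 1.0], np.zeros((2, 3))))

    def test_dispersion_single_atom_and_decay(self):
        assert dispersion_energy([6], [[0, 0, 0]]) == 0.0
        far = dispersion_energy([6, 6], [[0, 0, 0], [100.0, 0, 0]])
        assert -1e-8 < far <= 0.0

    def test_dispersion_matches_pair_formula(self):
        r, c6, d = 2.5, 28.0, 3.0
        e = dispersion_energy([6, 6], [[0, 0, 0], [r, 0, 0]],
                              c6_table={6: c6}, damping_d=d)
        assert e == pytest.approx(-c6 / (r**6 + d**6), abs=1e-12)
        assert np.isfinite(dispersion_energy([6, 6], np.zeros((2, 3))))


class TestEnsemble:
    def test_identical_members_zero_std(self, tiny_model, water):
        mean, std, forces = ensemble_predict([tiny_model, tiny_model], water)
        assert std == 0.0
        assert mean == pytest.approx(tiny_model.forward(water).energy)

    def test_mean_and_population_std(self, water):
        cfg = ModelConfig(elements=(1, 8), n_basis=4, embedding_dim=4,
                          hidden_dim=8, seed=0)
        m1, m2 = NSEPotential(cfg), NSEPotential(ModelConfig(
            elements=(1, 8), n_basis=4, embedding_dim=4, hidden_dim=8, seed=1))
        e1 = m1.forward(water).energy
        e2 = m2.forward(water).energy
        mean, std, forces = ensemble_predict([m1, m2], water)
        assert mean == pytest.approx((e1 + e2) / 2)
        assert std == pytest.approx(abs(e1 - e2) / 2)  # population std, K=2
        f1 = m1.forward(water, compute_forces=True).forces
        f2 = m2.forward(water, compute_forces=True).forces
        np.testing.assert_allclose(forces, (f1 + f2) / 2, atol=1e-12)
        # distinct members genuinely disagree atom-wise
        assert np.abs(f1 - f2).max() > 0

    def test_empty_ensemble_rejected(self, water):
        with pytest.raises(ValueError):
            ensemble_predict([], water)
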