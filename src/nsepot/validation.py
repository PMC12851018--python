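"""Quantitative self-checks of the potential's structural guarantees.

Each routine here measures one property the architecture is supposed to
enforce — spin-charge conservation, equilibration-formula correctness,
force/energy consistency, rigid-motion and permutation invariance,
smoothness in the spin multiplicity, surrogate-PES recovery after training,
QEq correctness and Kabsch-RMSD correctness — and returns the measured
number(s).  They are used by the test suite and by the reproduction script;
nothing here asserts, so callers choose their own tolerances.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import ModelConfig, NSEPotential, nqe_update
from .reactions import crossing_point, rmsd_aligned, scan_1d
from .surrogate import (
    SurrogateOracle,
    analytic_crossing_distance,
    default_oracle,
    dimer_scan_dataset,
    qeq_charges,
)
from .systems import AtomicSystem, spin_channel_totals
from .training import LossConfig, train

__all__ = [
    "random_valid_system",
    "conservation_suite",
    "nse_layer_agreement",
    "force_consistency",
    "symmetry_invariance",
    "spin_smoothness",
    "qeq_agreement",
    "rmsd_checks",
    "train_dimer_model",
    "dimer_recovery",
]

_ELEMENTS = (1, 6, 7, 8)


def random_valid_system(rng: np.random.Generator, n_min: int = 5, n_max: int = 10,
                        elements: Sequence[int] = _ELEMENTS) -> AtomicSystem:
    """A random molecule with parity-consistent (Q, S) drawn from
    Q in {-1, 0, +1} and S in {1, 2, 3}; atoms are jittered grid points so
    no two sit closer than ~0.8 Angstrom."""
    n = int(rng.integers(n_min, n_max + 1))
    z = rng.choice(elements, size=n)
    grid = np.array([[i, j, k] for i in range(3) for j in range(3) for k in range(3)],
                    dtype=np.float64) * 1.6
    sites = rng.permutation(len(grid))[:n]
    coords = grid[sites] + rng.normal(0.0, 0.15, size=(n, 3))
    charge = float(rng.integers(-1, 2))
    n_e = z.sum() - charge
    mult_options = [m for m in (1, 2, 3) if (n_e - (m - 1)) % 2 == 0 and n_e >= m - 1]
    mult = float(rng.choice(mult_options))
    return AtomicSystem(z, coords, charge, mult)


def _random_model(rng: np.random.Generator, mode: str = "nse") -> NSEPotential:
    cfg = ModelConfig(elements=_ELEMENTS, seed=int(rng.integers(0, 2**31)),
                      n_basis=8, embedding_dim=8, hidden_dim=32, mode=mode)
    return NSEPotential(cfg)


def conservation_suite(n_draws: int = 1000, seed: int = 0, n_models: int = 20) -> dict:
    """Max |channel sum - channel total| over random (system, Q, S) draws
    through untrained randomly initialised models."""
    rng = np.random.default_rng(seed)
    models = [_random_model(rng) for _ in range(n_models)]
    worst = 0.0
    for k in range(n_draws):
        system = random_valid_system(rng, 2, 8)
        out = models[k % n_models].forward(system)
        ea, eb = out.spin_charges.conservation_errors()
        worst = max(worst, ea, eb)
    return {"max_conservation_error": worst, "n": n_draws}


def nse_layer_agreement(n_draws: int = 200, seed: int = 0) -> dict:
    """Max |layer output - direct evaluation of the update formula| over
    random inputs, plus the idempotence residual of a second application."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    worst_idem = 0.0
    for _ in range(n_draws):
        n = int(rng.integers(1, 12))
        q = rng.normal(0.0, 1.0, n)
        f = rng.uniform(0.1, 5.0, n)
        total = float(rng.normal(0.0, 2.0))
        out = nqe_update(q, f, total)
        hand = q + f / f.sum() * (total - q.sum())
        worst = max(worst, float(np.abs(out - hand).max()),
                    abs(float(out.sum()) - total))
        again = nqe_update(out, f, total)
        worst_idem = max(worst_idem, float(np.abs(again - out).max()))
    return {"max_update_error": worst, "max_idempotence_error": worst_idem, "n": n_draws}


def force_consistency(n_systems: int = 50, seed: int = 0, step: float = 1e-4) -> dict:
    """Max relative error of analytic forces against central finite
    differences over random 5-10-atom systems and random models."""
    rng = np.random.default_rng(seed)
    worst_rel = 0.0
    worst_net = 0.0
    for _ in range(n_systems):
        model = _random_model(rng)
        system = random_valid_system(rng)
        out = model.forward(system, compute_forces=True)
        fd = np.zeros_like(out.forces)
        for i in range(system.n_atoms):
            for k in range(3):
                cp = system.coordinates.copy()
                cm = system.coordinates.copy()
                cp[i, k] += step
                cm[i, k] -= step
                ep = model.forward(system.with_coordinates(cp)).energy
                em = model.forward(system.with_coordinates(cm)).energy
                fd[i, k] = -(ep - em) / (2 * step)
        scale = max(np.abs(out.forces).max(), 1e-10)
        worst_rel = max(worst_rel, float(np.abs(fd - out.forces).max() / scale))
        worst_net = max(worst_net, float(np.abs(out.forces.sum(axis=0)).max()))
    return {"max_relative_force_error": worst_rel, "max_net_force": worst_net,
            "n": n_systems}


def symmetry_invariance(n_draws: int = 100, seed: int = 0) -> dict:
    """Max |energy change| under random rigid motions and atom permutations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        model = _random_model(rng)
        system = random_valid_system(rng)
        e0 = model.forward(system).energy
        # random proper rotation via QR with determinant fix, plus translation
        q_mat, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q_mat) < 0:
            q_mat[:, 0] *= -1
        moved = system.with_coordinates(system.coordinates @ q_mat.T + rng.normal(size=3) * 5)
        e1 = model.forward(moved).energy
        perm = rng.permutation(system.n_atoms)
        permuted = AtomicSystem(system.atomic_numbers[perm], system.coordinates[perm],
                                system.charge, system.multiplicity)
        e2 = model.forward(permuted).energy
        worst = max(worst, abs(e1 - e0), abs(e2 - e0))
    return {"max_energy_invariance_error": worst, "n": n_draws}


def spin_smoothness(n_draws: int = 20, seed: int = 0, eps: float = 1e-3) -> dict:
    """Continuity of E in continuous S: the small-step difference
    |E(S+eps) - E(S)| is compared with eps times a secant slope estimated at
    step 0.1.  A jump would blow the ratio up; smooth behaviour keeps it
    near 1."""
    rng = np.random.default_rng(seed)
    worst_ratio = 0.0
    for _ in range(n_draws):
        model = _random_model(rng)
        system = random_valid_system(rng)
        s0 = system.multiplicity
        e0 = model.forward(system).energy
        e_eps = model.forward(system, multiplicity=s0 + eps).energy
        e_big = model.forward(system, multiplicity=s0 + 0.1).energy
        slope_big = abs(e_big - e0) / 0.1
        small = abs(e_eps - e0)
        ratio = small / (eps * max(slope_big, 1e-8))
        worst_ratio = max(worst_ratio, ratio)
    return {"max_smoothness_ratio": worst_ratio, "n": n_draws, "eps": eps}


def qeq_agreement(n_instances: int = 100, seed: int = 0,
                  oracle: Optional[SurrogateOracle] = None) -> dict:
    """Max |KKT solution - numeric constrained minimiser| over random
    molecules, plus the closed-form two-atom check."""
    oracle = oracle or default_oracle()
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        system = random_valid_system(rng, 2, 6)
        q_kkt = qeq_charges(oracle, system)
        chi = np.array([oracle.chi[int(z)] for z in system.atomic_numbers])
        eta = np.array([oracle.eta[int(z)] for z in system.atomic_numbers])
        from .surrogate import _coulomb_kernel
        kernel = _coulomb_kernel(oracle, system.coordinates)
        n = system.n_atoms
        # eliminate the sum constraint: q = q0 + B y with columns of B
        # spanning the zero-sum subspace, then minimise unconstrained
        q0 = np.full(n, system.charge / n)
        basis = np.linalg.svd(np.ones((1, n)))[2][1:].T  # (n, n-1)
        a_mat = np.diag(eta) + kernel

        def objective(y):
            q = q0 + basis @ y
            return chi @ q + 0.5 * q @ (a_mat @ q)

        def gradient(y):
            q = q0 + basis @ y
            return basis.T @ (chi + a_mat @ q)

        res = minimize(objective, np.zeros(n - 1), jac=gradient, method="BFGS",
                       options={"gtol": 1e-13, "maxiter": 1000})
        q_num = q0 + basis @ res.x
        worst = max(worst, float(np.abs(q_kkt - q_num).max()))
    return {"max_qeq_disagreement": worst, "n": n_instances}


def rmsd_checks(n_draws: int = 20, seed: int = 0) -> dict:
    """Kabsch RMSD on rotated copies (should be 0) and against brute-force
    minimisation over a rotation-vector parameterisation."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    worst_rot = 0.0
    worst_brute = 0.0
    for _ in range(n_draws):
        a = random_valid_system(rng, 4, 8)
        rot = Rotation.random(random_state=int(rng.integers(0, 2**31))).as_matrix()
        b_rot = a.with_coordinates(a.coordinates @ rot.T + rng.normal(size=3))
        worst_rot = max(worst_rot, rmsd_aligned(a, b_rot))
        b = AtomicSystem(a.atomic_numbers,
                         a.coordinates + rng.normal(0, 0.3, a.coordinates.shape),
                         a.charge, a.multiplicity)
        target = rmsd_aligned(a, b)
        p = a.coordinates - a.coordinates.mean(axis=0)
        q = b.coordinates - b.coordinates.mean(axis=0)

        def objective(rotvec):
            r_mat = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(((p - q @ r_mat.T) ** 2).sum() / a.n_atoms)

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000}).fun
            for x0 in (np.zeros(3), np.array([1.0, 0.5, -0.5]), np.array([-2.0, 1.0, 2.0]))
        )
        worst_brute = max(worst_brute, abs(target - best))
    return {"max_rmsd_rotated_copy": worst_rot,
            "max_rmsd_vs_bruteforce": worst_brute, "n": n_draws}


def train_dimer_model(seed: int = 1, n_frames: int = 3000, max_epochs: int = 80,
                      oracle: Optional[SurrogateOracle] = None,
                      batch_size: int = 256):
    """Fit a fresh potential to the surrogate singlet/triplet H2 dissociation
    curves (40-point grid on [0.6, 4.0] Angstrom).  Returns (model, oracle,
    history)."""
    oracle = oracle or default_oracle(use_coulomb=False)
    frames = dimer_scan_dataset(oracle, n_frames=n_frames, seed=seed)
    n_val = max(len(frames) // 10, 1)
    train_frames, val_frames = frames[:-n_val], frames[-n_val:]
    config = ModelConfig(elements=(1,), seed=seed)
    loss_config = LossConfig(seed=seed, batch_size=batch_size, lr=5e-3,
                             max_epochs=max_epochs, plateau_patience=8, patience=40)
    model = NSEPotential(config)
    fitted, history = train(model, train_frames, val_frames, loss_config)
    return fitted, oracle, history


class _FixedSpinModel:
    """Adapter pinning the spin state for scans over a trained model."""

    def __init__(self, model: NSEPotential, multiplicity: float):
        self.model = model
        self.multiplicity = multiplicity

    def energy_forces(self, system: AtomicSystem):
        out = self.model.forward(
            AtomicSystem(system.atomic_numbers, system.coordinates,
                         system.charge, self.multiplicity),
            compute_forces=True)
        return out.energy, out.forces


def dimer_recovery(seed: int = 1, n_frames: int = 3000, max_epochs: int = 80,
                   n_scan: int = 200) -> dict:
    """Train on the dimer curves and compare the model's singlet/triplet
    crossing distance and well depths with the analytic surrogate."""
    fitted, oracle, history = train_dimer_model(seed, n_frames, max_epochs)
    h2 = AtomicSystem([1, 1], [[0.0, 0.0, 0.0], [0.741, 0.0, 0.0]])
    grid = np.linspace(0.741, 4.0, n_scan)
    prof_s = scan_1d(_FixedSpinModel(fitted, 1.0), h2, (0, 1), grid, multiplicity=1.0)
    prof_t = scan_1d(_FixedSpinModel(fitted, 3.0), h2, (0, 1), grid,
                     multiplicity=3.0, mark=False)
    crossing = crossing_point(prof_s, prof_t)
    analytic = analytic_crossing_distance(oracle)
    e_s, e_t = prof_s.energies(), prof_t.energies()
    depth_s = float(e_s[-1] - e_s.min())
    depth_t = float(e_t[-1] - e_t.min())
    return {
        "crossing_distance": crossing.coordinate,
        "analytic_crossing_distance": analytic,
        "crossing_distance_error": abs(crossing.coordinate - analytic),
        "well_depth_singlet": depth_s,
        "well_depth_triplet": depth_t,
        "depth_ordering_ok": depth_s > depth_t,
        "final_val_loss": history[-1]["val_total"],
        "n": n_frames,
    }
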