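"""Analytic spin-state-dependent reference oracle and dataset generation.

Training a spin-aware potential needs labels — energies, forces and
per-spin-channel atomic charges — that an electronic-structure code would
normally provide.  This module supplies a fully analytic stand-in: pairwise
Morse energetics with separate singlet/triplet parameter sets (doublet =
their mean), classical electronegativity-equalisation (QEq) charges, and a
deterministic spin-splitting rule.  The surrogate is not chemically
realistic; its job is to define smooth spin-resolved potential energy
curves with a known singlet/triplet crossing and labels that satisfy the
same conservation contract the model enforces.

The triplet Morse set carries a lowered dissociation asymptote, so for the
default parameters the singlet and triplet dimer curves cross exactly once
between the singlet minimum and 10 Angstrom — a ground-truth crossing point
for the reaction-analysis machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .model import COULOMB_K
from .systems import AtomicSystem, XYZFrame, spin_channel_totals

__all__ = [
    "MorseParams",
    "SurrogateOracle",
    "LabeledFrame",
    "qeq_charges",
    "split_spin_labels",
    "surrogate_energy_forces",
    "generate_dataset",
    "default_oracle",
    "default_templates",
    "analytic_dimer_energy",
    "analytic_crossing_distance",
]


@dataclass(frozen=True)
class MorseParams:
    """One pair interaction: D_e (kcal/mol), a (1/Angstrom), r_e (Angstrom),
    and the dissociation asymptote (kcal/mol, the r -> inf limit)."""

    d_e: float
    a: float
    r_e: float
    asymptote: float = 0.0

    def __post_init__(self):
        if self.d_e <= 0 or self.a <= 0 or self.r_e <= 0:
            raise ValueError("Morse parameters D_e, a, r_e must be positive")

    def energy(self, r):
        x = 1.0 - np.exp(-self.a * (np.asarray(r, dtype=np.float64) - self.r_e))
        return self.d_e * (x * x - 1.0) + self.asymptote

    def derivative(self, r):
        e = np.exp(-self.a * (np.asarray(r, dtype=np.float64) - self.r_e))
        return 2.0 * self.d_e * self.a * (1.0 - e) * e


def _mean_params(p1: MorseParams, p2: MorseParams) -> MorseParams:
    return MorseParams(
        0.5 * (p1.d_e + p2.d_e), 0.5 * (p1.a + p2.a),
        0.5 * (p1.r_e + p2.r_e), 0.5 * (p1.asymptote + p2.asymptote),
    )


@dataclass
class SurrogateOracle:
    """Analytic labeler: QEq electrostatics + spin-state Morse energetics."""

    chi: Dict[int, float]                     # per-element electronegativity
    eta: Dict[int, float]                     # per-element hardness, > 0
    w_spin: Dict[int, float]                  # spin-affinity weights
    morse_singlet: Dict[Tuple[int, int], MorseParams]
    morse_triplet: Dict[Tuple[int, int], MorseParams]
    use_coulomb: bool = True
    coulomb_damping_w: float = 1.5
    coulomb_k: float = COULOMB_K

    def __post_init__(self):
        if any(v <= 0 for v in self.eta.values()):
            raise ValueError("hardness must be positive for every element")
        if self.use_coulomb:
            # The damped kernel k/sqrt(r^2 + w^2) is a positive-semidefinite
            # function of distance, so the electrostatic functional is
            # strictly convex (unique QEq minimum) whenever every hardness
            # exceeds the kernel's r = 0 value k/w.
            floor = self.coulomb_k / self.coulomb_damping_w
            if any(v <= floor for v in self.eta.values()):
                raise ValueError(
                    f"with Coulomb coupling every hardness must exceed k/w = {floor:.1f} "
                    "kcal/mol/e^2 to keep the QEq functional convex"
                )

    def _pair_key(self, z1: int, z2: int) -> Tuple[int, int]:
        return (min(z1, z2), max(z1, z2))

    def morse_for(self, z1: int, z2: int, multiplicity: int) -> MorseParams:
        key = self._pair_key(z1, z2)
        table_s = self.morse_singlet
        table_t = self.morse_triplet
        ps = table_s.get(key, table_s[(0, 0)])
        pt = table_t.get(key, table_t[(0, 0)])
        if multiplicity == 1:
            return ps
        if multiplicity == 3:
            return pt
        if multiplicity == 2:
            return _mean_params(ps, pt)
        raise ValueError(f"unsupported multiplicity {multiplicity} for surrogate labeling")

    def as_potential(self, multiplicity: Optional[int] = None) -> "_OraclePotential":
        """Adapter with an `energy_forces(system)` method (optionally pinning S)."""
        return _OraclePotential(self, multiplicity)


class _OraclePotential:
    def __init__(self, oracle: SurrogateOracle, multiplicity: Optional[int]):
        self.oracle = oracle
        self.multiplicity = multiplicity

    def energy_forces(self, system: AtomicSystem):
        if self.multiplicity is not None and self.multiplicity != system.multiplicity:
            system = AtomicSystem(system.atomic_numbers, system.coordinates,
                                  system.charge, self.multiplicity, system.frame_id)
        return surrogate_energy_forces(self.oracle, system)


@dataclass
class LabeledFrame:
    """A training sample: geometry plus energy/force/spin-charge labels."""

    system: AtomicSystem
    energy: float
    forces: np.ndarray
    q_alpha: np.ndarray
    q_beta: np.ndarray
    extra: dict = field(default_factory=dict)

    def conservation_errors(self):
        qa, qb = self.system.channel_totals()
        return (abs(float(np.sum(self.q_alpha)) - qa),
                abs(float(np.sum(self.q_beta)) - qb))


# ---------------------------------------------------------------------------
# QEq charges
# ---------------------------------------------------------------------------

def _coulomb_kernel(oracle: SurrogateOracle, coords: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    if not oracle.use_coulomb or n < 2:
        return np.zeros((n, n))
    delta = coords[:, None, :] - coords[None, :, :]
    r2 = (delta**2).sum(axis=-1)
    kernel = oracle.coulomb_k / np.sqrt(r2 + oracle.coulomb_damping_w**2)
    np.fill_diagonal(kernel, 0.0)
    return kernel


def qeq_charges(oracle: SurrogateOracle, system: AtomicSystem) -> np.ndarray:
    """Electronegativity-equalisation charges: the unique minimiser of

        E(q) = sum_i (chi_i q_i + 1/2 eta_i q_i^2) + sum_{i<j} k q_i q_j g(r_ij)

    subject to sum_i q_i = Q, obtained from the exact KKT linear system.
    """
    z = system.atomic_numbers
    n = system.n_atoms
    chi = np.array([oracle.chi[int(zz)] for zz in z])
    eta = np.array([oracle.eta[int(zz)] for zz in z])
    a_mat = np.diag(eta) + _coulomb_kernel(oracle, system.coordinates)
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = a_mat
    kkt[:n, n] = 1.0
    kkt[n, :n] = 1.0
    rhs = np.concatenate([-chi, [system.charge]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:  # cannot occur for eta > 0; guarded anyway
        raise RuntimeError(f"singular QEq system: {exc}") from None
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("non-finite QEq solution")
    return sol[:n]


def electrostatic_energy(oracle: SurrogateOracle, system: AtomicSystem,
                         q: np.ndarray) -> float:
    chi = np.array([oracle.chi[int(zz)] for zz in system.atomic_numbers])
    eta = np.array([oracle.eta[int(zz)] for zz in system.atomic_numbers])
    kernel = _coulomb_kernel(oracle, system.coordinates)
    return float(chi @ q + 0.5 * q @ (eta * q) + 0.5 * q @ kernel @ q)


def split_spin_labels(oracle: SurrogateOracle, q_total: np.ndarray,
                      system: AtomicSystem):
    """Split total charges into (q_alpha, q_beta) channel labels.

    The n_u = S - 1 unpaired electrons are distributed over atoms in
    proportion to the per-element spin-affinity weights; channel sums then
    hit the (Q_alpha, Q_beta) totals exactly by construction.
    """
    q_total = np.asarray(q_total, dtype=np.float64)
    n_u = system.multiplicity - 1.0
    w = np.array([oracle.w_spin[int(zz)] for zz in system.atomic_numbers])
    u = n_u * w / w.sum()
    q_alpha = 0.5 * q_total - 0.5 * u
    q_beta = 0.5 * q_total + 0.5 * u
    return q_alpha, q_beta


def surrogate_energy_forces(oracle: SurrogateOracle, system: AtomicSystem):
    """Analytic energy (kcal/mol) and forces (kcal/mol/Angstrom).

    E = sum_pairs Morse_S(r_ij) + E_es(q*) where q* are the QEq charges.
    Because q* minimises the constrained electrostatic functional, forces
    follow from the envelope theorem: only the explicit r-dependence of the
    Morse terms and of the Coulomb kernel contributes.
    """
    mult = system.multiplicity
    if not float(mult).is_integer() or int(mult) not in (1, 2, 3):
        raise ValueError(f"unsupported multiplicity {mult} for surrogate labeling")
    mult = int(mult)
    coords = system.coordinates
    z = system.atomic_numbers
    n = system.n_atoms
    energy = 0.0
    forces = np.zeros((n, 3))
    if n >= 2:
        ii, jj = np.triu_indices(n, k=1)
        delta = coords[ii] - coords[jj]
        r = np.linalg.norm(delta, axis=1)
        for idx in range(len(ii)):
            p = oracle.morse_for(int(z[ii[idx]]), int(z[jj[idx]]), mult)
            energy += float(p.energy(r[idx]))
            dEdr = float(p.derivative(r[idx]))
            f_pair = -dEdr * delta[idx] / r[idx]
            forces[ii[idx]] += f_pair
            forces[jj[idx]] -= f_pair
    if oracle.use_coulomb:
        q = qeq_charges(oracle, system)
        energy += electrostatic_energy(oracle, system, q)
        if n >= 2:
            w2 = oracle.coulomb_damping_w**2
            delta = coords[ii] - coords[jj]
            r2 = (delta**2).sum(axis=1)
            # d/dr of k/sqrt(r^2+w^2) at fixed charges (envelope theorem)
            pref = -oracle.coulomb_k * q[ii] * q[jj] * (r2 + w2) ** -1.5
            f_pairs = -pref[:, None] * delta
            np.add.at(forces, ii, f_pairs)
            np.add.at(forces, jj, -f_pairs)
    return energy, forces


def label_frame(oracle: SurrogateOracle, system: AtomicSystem,
                extra: Optional[dict] = None) -> LabeledFrame:
    energy, forces = surrogate_energy_forces(oracle, system)
    q = qeq_charges(oracle, system)
    q_alpha, q_beta = split_spin_labels(oracle, q, system)
    return LabeledFrame(system, energy, forces, q_alpha, q_beta, extra or {})


# ---------------------------------------------------------------------------
# default parameters and templates
# ---------------------------------------------------------------------------

def default_oracle(use_coulomb: bool = True) -> SurrogateOracle:
    """Shipped defaults.  The (H, H) singlet set is H2-like (D_e = 109.5
    kcal/mol, r_e = 0.741 A); its triplet companion is shallow with a
    dissociation asymptote lowered by 22 kcal/mol, which puts the
    singlet/triplet curve crossing near 1.7 A.  The (0, 0) key is the
    fallback for any other element pair."""
    # Pauling-pattern electronegativities and hardnesses on a kcal/mol/e
    # scale; hardnesses exceed the Coulomb kernel's contact value k/w so the
    # QEq functional is strictly convex (see SurrogateOracle)
    chi = {1: 51.0, 6: 59.0, 7: 70.0, 8: 79.0}
    eta = {1: 320.0, 6: 250.0, 7: 295.0, 8: 304.0}
    w_spin = {1: 1.0, 6: 1.2, 7: 1.3, 8: 1.5}
    morse_singlet = {
        (1, 1): MorseParams(109.5, 1.94, 0.741, 0.0),
        (1, 6): MorseParams(104.0, 1.80, 1.09, 0.0),
        (6, 6): MorseParams(85.0, 1.90, 1.54, 0.0),
        (0, 0): MorseParams(80.0, 1.80, 1.50, 0.0),
    }
    morse_triplet = {
        (1, 1): MorseParams(9.0, 1.20, 1.35, -22.0),
        (1, 6): MorseParams(12.0, 1.10, 1.60, -20.0),
        (6, 6): MorseParams(14.0, 1.00, 2.00, -18.0),
        (0, 0): MorseParams(12.0, 1.00, 2.00, -18.0),
    }
    return SurrogateOracle(chi=chi, eta=eta, w_spin=w_spin,
                           morse_singlet=morse_singlet,
                           morse_triplet=morse_triplet,
                           use_coulomb=use_coulomb)


def default_templates() -> List[AtomicSystem]:
    """Small template geometries: H2, a CH3-like 4-atom cluster, and a
    6-atom C/H chain.  All neutral singlets."""
    h2 = AtomicSystem([1, 1], [[0.0, 0.0, 0.0], [0.741, 0.0, 0.0]], frame_id="H2")
    ch3 = AtomicSystem(
        [6, 1, 1, 1],
        [[0.0, 0.0, 0.1], [1.07, 0.0, -0.2], [-0.53, 0.93, -0.2], [-0.53, -0.93, -0.2]],
        charge=1.0, multiplicity=1.0, frame_id="CH3+",
    )
    chain = AtomicSystem(
        [6, 6, 6, 1, 1, 1],
        [[0.0, 0.0, 0.0], [1.45, 0.2, 0.0], [2.9, 0.0, 0.1],
         [-0.6, 0.9, 0.0], [1.45, 1.3, 0.0], [3.5, 0.9, 0.1]],
        frame_id="C3H3+", charge=1.0,
    )
    return [h2, ch3, chain]


def analytic_dimer_energy(oracle: SurrogateOracle, z1: int, z2: int,
                          multiplicity: int, r) -> np.ndarray:
    """Closed-form dimer curve (Morse only; QEq adds a constant for a fixed
    homonuclear pair where the charges vanish by symmetry)."""
    return oracle.morse_for(z1, z2, multiplicity).energy(r)


def analytic_crossing_distance(oracle: SurrogateOracle, z1: int = 1, z2: int = 1,
                               r_max: float = 10.0) -> float:
    """The unique distance in (r_e_singlet, r_max) where the singlet and
    triplet dimer curves intersect (root of their difference, by Brent)."""
    ps = oracle.morse_for(z1, z2, 1)

    def gap(r):
        return (analytic_dimer_energy(oracle, z1, z2, 1, r)
                - analytic_dimer_energy(oracle, z1, z2, 3, r))

    lo, hi = ps.r_e, r_max
    grid = np.linspace(lo, hi, 2001)
    vals = gap(grid)
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_changes) != 1:
        raise RuntimeError(f"expected exactly one crossing, found {len(sign_changes)}")
    k = sign_changes[0]
    return float(brentq(gap, grid[k], grid[k + 1], xtol=1e-12))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _charge_spin_edits(template: AtomicSystem) -> List[dict]:
    """The augmentation strategy: electron attachment/removal (doublets),
    electron unpairing (triplet at the template charge), and H removal
    (doublet radical), filtered for parity consistency."""
    edits = []
    for edit in (
        {"dq": 0.0, "mult": template.multiplicity, "remove_h": False},   # as-is
        {"dq": +1.0, "mult": 2.0, "remove_h": False},                    # remove an electron
        {"dq": -1.0, "mult": 2.0, "remove_h": False},                    # add an electron
        {"dq": 0.0, "mult": 3.0, "remove_h": False},                     # unpair electrons
        {"dq": 0.0, "mult": 2.0, "remove_h": True},                      # H abstraction
    ):
        if edit["remove_h"] and not np.any(template.atomic_numbers == 1):
            continue
        z = template.atomic_numbers
        if edit["remove_h"]:
            h_idx = int(np.nonzero(z == 1)[0][-1])
            z = np.delete(z, h_idx)
        n_e = z.sum() - (template.charge + edit["dq"])
        n_u = edit["mult"] - 1.0
        if round(n_e - n_u) % 2 != 0 or n_e < n_u:
            continue
        edits.append(edit)
    if not edits:
        raise ValueError(f"template {template.frame_id}: no valid charge/spin edit")
    return edits


def generate_dataset(oracle: SurrogateOracle, templates: Optional[Sequence[AtomicSystem]] = None,
                     n_frames: int = 100, seed: int = 0,
                     displacement_scale: float = 0.15) -> List[LabeledFrame]:
    """Labeled frames from Gaussian-perturbed templates under cycled
    charge/spin edits.  Fully reproducible for a fixed seed."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if templates is None:
        templates = default_templates()
    rng = np.random.default_rng(seed)
    combos = []
    for template in templates:
        for edit in _charge_spin_edits(template):
            combos.append((template, edit))
    frames = []
    for k in range(n_frames):
        template, edit = combos[k % len(combos)]
        z = template.atomic_numbers.copy()
        coords = template.coordinates.copy()
        if edit["remove_h"]:
            h_idx = int(np.nonzero(z == 1)[0][-1])
            z = np.delete(z, h_idx)
            coords = np.delete(coords, h_idx, axis=0)
        coords = coords + rng.normal(0.0, displacement_scale, size=coords.shape)
        system = AtomicSystem(z, coords, template.charge + edit["dq"], edit["mult"],
                              frame_id=f"{template.frame_id}:{k}")
        frames.append(label_frame(oracle, system))
    return frames


def dimer_scan_dataset(oracle: SurrogateOracle, z1: int = 1, z2: int = 1,
                       r_min: float = 0.6, r_max: float = 4.0, n_points: int = 40,
                       n_frames: int = 3000, seed: int = 0,
                       jitter: float = 0.01) -> List[LabeledFrame]:
    """Labeled dimer frames covering singlet and triplet dissociation curves.

    Frames cycle through an `n_points` grid on [r_min, r_max] alternating the
    spin state between singlet and triplet, with a small Gaussian jitter on
    the distance so repeated grid visits are not duplicates.  This is the
    desk-scale training task for recovering a spin-resolved bond-breaking
    potential energy surface with a known singlet/triplet crossing.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(r_min, r_max, n_points)
    frames = []
    for k in range(n_frames):
        r = float(np.clip(grid[k % n_points] + rng.normal(0.0, jitter), 0.4, None))
        mult = 1.0 if (k // n_points) % 2 == 0 else 3.0
        system = AtomicSystem([z1, z2], [[0.0, 0.0, 0.0], [r, 0.0, 0.0]],
                              0.0, mult, frame_id=f"dimer:{k}")
        frames.append(label_frame(oracle, system))
    return frames


def frames_to_xyz(frames: Sequence[LabeledFrame]) -> List[XYZFrame]:
    return [XYZFrame(f.system, energy=f.energy, forces=f.forces,
                     q_alpha=f.q_alpha, q_beta=f.q_beta) for f in frames]


def xyz_to_frames(xyz_frames: Sequence[XYZFrame]) -> List[LabeledFrame]:
    out = []
    for f in xyz_frames:
        if f.energy is None or f.forces is None or f.q_alpha is None:
            raise ValueError("frame is missing energy/forces/charge labels")
        out.append(LabeledFrame(f.system, f.energy, f.forces, f.q_alpha, f.q_beta))
    return out
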