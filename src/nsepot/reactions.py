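"""Reaction energetics, PES scans, spin-surface crossings and benchmarks.

Everything here is potential-agnostic: any object with an
``energy_forces(system) -> (energy, forces)`` method can drive the
optimiser and the scans — a trained model, an ensemble adapter, or the
analytic surrogate oracle.

Scans are constrained optimisations, not true reaction paths: the scanned
distance(s) are held by a stiff harmonic restraint whose centre is
iteratively corrected until the realised distance matches the target, and
all remaining degrees of freedom are relaxed (or the displacement is rigid
along the bond axis).  Transition-state markers are interior energy maxima
of a scan — an approximation to a true saddle search.  Singlet/triplet
crossing points are located by linear interpolation of the surface gap on a
common grid; when the surfaces never cross, the closest-contact point is
returned and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .systems import AtomicSystem

__all__ = [
    "ReactionProfile",
    "ProfilePoint",
    "BenchmarkRow",
    "BenchmarkStats",
    "CrossingResult",
    "EnsemblePotential",
    "optimize_geometry",
    "scan_1d",
    "scan_2d",
    "reaction_energetics",
    "crossing_point",
    "rmsd_aligned",
    "benchmark_stats",
    "profile_mad",
]


class EnsemblePotential:
    """Adapter: a list of potentials exposed as one, with prediction spread."""

    def __init__(self, members: Sequence):
        if len(members) == 0:
            raise ValueError("empty ensemble")
        self.members = list(members)

    def energy_forces(self, system: AtomicSystem):
        energies, forces = zip(*(m.energy_forces(system) for m in self.members))
        return float(np.mean(energies)), np.mean(forces, axis=0)

    def energy_std(self, system: AtomicSystem) -> float:
        return float(np.std([m.energy_forces(system)[0] for m in self.members], ddof=0))


@dataclass
class ProfilePoint:
    coordinate: Tuple[float, ...]
    system: AtomicSystem
    energy: float
    energy_std: Optional[float] = None


@dataclass
class ReactionProfile:
    """Ordered scan/path points on one spin surface, with R/TS/P markers."""

    points: List[ProfilePoint]
    multiplicity: float
    reactant_index: Optional[int] = None
    ts_index: Optional[int] = None
    product_index: Optional[int] = None

    def __post_init__(self):
        coords = self.coordinates()
        if coords.shape[1] == 1 and len(self.points) > 1:
            d = np.diff(coords[:, 0])
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("1-D scan coordinates must be strictly monotone")
        for name in ("reactant_index", "ts_index", "product_index"):
            idx = getattr(self, name)
            if idx is not None and not (0 <= idx < len(self.points)):
                raise ValueError(f"{name} out of range")
        if self.ts_index is not None:
            e = self.energies()
            if e[self.ts_index] < max(e[0], e[-1]) - 1e-10:
                raise ValueError("TS marker must not lie below both endpoints")

    def coordinates(self) -> np.ndarray:
        return np.array([p.coordinate for p in self.points], dtype=np.float64)

    def energies(self) -> np.ndarray:
        return np.array([p.energy for p in self.points])

    def mark_stationary_points(self) -> "ReactionProfile":
        """Set reactant/product to the endpoints and TS to the interior
        energy maximum (left unset if no interior point tops both ends)."""
        e = self.energies()
        self.reactant_index = 0
        self.product_index = len(self.points) - 1
        if len(self.points) > 2:
            interior = np.argmax(e[1:-1]) + 1
            if e[interior] >= max(e[0], e[-1]):
                self.ts_index = int(interior)
        return self


@dataclass
class BenchmarkRow:
    reaction_id: str
    reference: float
    predicted: float

    @property
    def deviation(self) -> float:
        return self.predicted - self.reference


@dataclass
class BenchmarkStats:
    md: float
    mad: float
    r2: Optional[float]  # None when the reference has zero variance


@dataclass
class CrossingResult:
    coordinate: float
    energy: float
    crossed: bool
    note: str = ""


# ---------------------------------------------------------------------------
# geometry optimisation
# ---------------------------------------------------------------------------

def _max_force(forces: np.ndarray) -> float:
    return float(np.linalg.norm(forces, axis=1).max())


def optimize_geometry(potential, system: AtomicSystem, max_force_tol: float = 1e-3,
                      max_steps: int = 500) -> Tuple[AtomicSystem, dict]:
    """Monotone BFGS descent until the largest per-atom force norm is below
    `max_force_tol` (kcal/mol/Angstrom) or `max_steps` is exhausted.

    Uses Armijo backtracking, so the energy never increases over accepted
    steps; a non-finite energy during the line search aborts with the last
    good geometry.  Returns (optimised system, info dict).
    """
    x = system.coordinates.ravel().copy()
    n = x.size
    energy, forces = potential.energy_forces(system)
    g = -forces.ravel()
    h_inv = np.eye(n)
    info = {"converged": _max_force(forces) <= max_force_tol, "steps": 0,
            "final_max_force": _max_force(forces), "energy": energy}
    if info["converged"]:
        return system.with_coordinates(x.reshape(-1, 3)), info
    for step in range(max_steps):
        p = -h_inv @ g
        if p @ g > 0:  # not a descent direction; reset
            h_inv = np.eye(n)
            p = -g
        alpha, ls_ok = 1.0, False
        for _ in range(40):
            x_new = x + alpha * p
            trial = system.with_coordinates(x_new.reshape(-1, 3))
            e_new, f_new = potential.energy_forces(trial)
            if not np.isfinite(e_new):
                info["note"] = "non-finite energy in line search; returning last good geometry"
                info["steps"] = step
                return system.with_coordinates(x.reshape(-1, 3)), info
            if e_new <= energy + 1e-4 * alpha * (g @ p):
                ls_ok = True
                break
            alpha *= 0.5
        if not ls_ok:
            break
        g_new = -f_new.ravel()
        s, y = x_new - x, g_new - g
        sy = s @ y
        if sy > 1e-12:
            rho = 1.0 / sy
            i_mat = np.eye(n)
            h_inv = (i_mat - rho * np.outer(s, y)) @ h_inv @ (i_mat - rho * np.outer(y, s)) \
                + rho * np.outer(s, s)
        x, energy, g = x_new, e_new, g_new
        info.update(steps=step + 1, energy=energy, final_max_force=_max_force(f_new))
        if info["final_max_force"] <= max_force_tol:
            info["converged"] = True
            break
    return system.with_coordinates(x.reshape(-1, 3)), info


# ---------------------------------------------------------------------------
# constrained scans
# ---------------------------------------------------------------------------

class _RestrainedPotential:
    """Potential + harmonic distance restraints 0.5 k (r_ij - center)^2."""

    def __init__(self, potential, pairs, centers, k_restraint: float):
        self.potential = potential
        self.pairs = pairs
        self.centers = list(centers)
        self.k = k_restraint

    def energy_forces(self, system: AtomicSystem):
        energy, forces = self.potential.energy_forces(system)
        forces = forces.copy()
        for (i, j), center in zip(self.pairs, self.centers):
            delta = system.coordinates[i] - system.coordinates[j]
            r = float(np.linalg.norm(delta))
            energy += 0.5 * self.k * (r - center) ** 2
            f_pair = -self.k * (r - center) * delta / r
            forces[i] += f_pair
            forces[j] -= f_pair
        return energy, forces


def _distance(system: AtomicSystem, i: int, j: int) -> float:
    return float(np.linalg.norm(system.coordinates[i] - system.coordinates[j]))


def _set_distance_rigid(system: AtomicSystem, i: int, j: int, target: float) -> AtomicSystem:
    """Move atom j along the i->j axis so that r_ij = target exactly."""
    coords = system.coordinates.copy()
    axis = coords[j] - coords[i]
    r = np.linalg.norm(axis)
    coords[j] = coords[i] + axis / r * target
    return system.with_coordinates(coords)


def _relax_with_targets(potential, system, pairs, targets, k_restraint,
                        dist_tol, max_outer=30, opt_tol=1e-4):
    """Restrained relaxation with iterative restraint-centre correction.

    A finite-stiffness restraint leaves a residual offset |r - target| of
    order |dE/dr| / k; re-centring the restraint by the observed residual
    and re-relaxing drives the realised distance to the target, keeping the
    scheme potential-agnostic while meeting a tight distance tolerance.
    """
    centers = list(targets)
    current = system
    for _ in range(max_outer):
        restrained = _RestrainedPotential(potential, pairs, centers, k_restraint)
        current, _ = optimize_geometry(restrained, current, max_force_tol=opt_tol,
                                       max_steps=300)
        residuals = [_distance(current, i, j) - t for (i, j), t in zip(pairs, targets)]
        if max(abs(r) for r in residuals) <= dist_tol:
            break
        centers = [c - r for c, r in zip(centers, residuals)]
    return current


def scan_1d(potential, system: AtomicSystem, pair: Tuple[int, int],
            distances: Sequence[float], multiplicity: Optional[float] = None,
            relax: bool = False, k_restraint: float = 1e4,
            dist_tol: float = 1e-6, mark: bool = True) -> ReactionProfile:
    """Bond scan: energy at each target i-j distance on one spin surface.

    relax=False displaces atom j rigidly along the bond axis; relax=True
    relaxes all remaining degrees of freedom under the distance restraint.
    Recorded energies exclude the restraint term.
    """
    i, j = pair
    if i == j:
        raise ValueError("scan pair must be two distinct atoms")
    if not (0 <= i < system.n_atoms and 0 <= j < system.n_atoms):
        raise ValueError("scan pair atom index out of range")
    distances = list(distances)
    diffs = np.diff(distances)
    if len(distances) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("scan distances must be strictly monotone")
    if multiplicity is not None:
        system = AtomicSystem(system.atomic_numbers, system.coordinates,
                              system.charge, multiplicity, system.frame_id)
    points = []
    current = system
    for d in distances:
        geom = _set_distance_rigid(current, i, j, d)
        if relax:
            geom = _relax_with_targets(potential, geom, [(i, j)], [d],
                                       k_restraint, dist_tol)
            realized = _distance(geom, i, j)
            if abs(realized - d) > 5e-3:
                raise RuntimeError(f"relaxed scan missed target: |{realized:.4f} - {d:.4f}|")
            current = geom  # warm-start the next point
        energy, _ = potential.energy_forces(geom)
        std = potential.energy_std(geom) if isinstance(potential, EnsemblePotential) else None
        points.append(ProfilePoint((float(d),), geom, float(energy), std))
    profile = ReactionProfile(points, multiplicity=geom.multiplicity)
    return profile.mark_stationary_points() if mark else profile


def scan_2d(potential, system: AtomicSystem, pairs, grid1: Sequence[float],
            grid2: Sequence[float], multiplicity: Optional[float] = None,
            relax: bool = True, k_restraint: float = 1e4,
            dist_tol: float = 1e-6) -> np.ndarray:
    """Energy grid over the Cartesian product of two distance constraints.

    Returns a (len(grid1), len(grid2)) row-major array; grid1 varies along
    rows (axis 0).
    """
    (i1, j1), (i2, j2) = pairs
    if {i1, j1} == {i2, j2}:
        raise ValueError("constrained pairs must not share both atoms")
    if multiplicity is not None:
        system = AtomicSystem(system.atomic_numbers, system.coordinates,
                              system.charge, multiplicity, system.frame_id)
    energies = np.empty((len(grid1), len(grid2)))
    for a, d1 in enumerate(grid1):
        for b, d2 in enumerate(grid2):
            geom = _set_distance_rigid(system, i1, j1, d1)
            geom = _set_distance_rigid(geom, i2, j2, d2)
            if relax:
                geom = _relax_with_targets(potential, geom, [(i1, j1), (i2, j2)],
                                           [d1, d2], k_restraint, dist_tol)
            energy, _ = potential.energy_forces(geom)
            energies[a, b] = energy
    return energies


# ---------------------------------------------------------------------------
# energetics, crossings, structure, statistics
# ---------------------------------------------------------------------------

def reaction_energetics(e_reactant: float, e_ts: float, e_product: float):
    """(reaction energy, barrier) = (E_p - E_r, E_TS - E_r)."""
    for v in (e_reactant, e_ts, e_product):
        if not np.isfinite(v):
            raise ValueError("energetics inputs must be finite")
    return e_product - e_reactant, e_ts - e_reactant


def crossing_point(profile_a: ReactionProfile, profile_b: ReactionProfile) -> CrossingResult:
    """Locate where two spin-surface profiles on the same grid intersect.

    Linear interpolation inside the first grid interval where the energy gap
    changes sign; with no sign change, the grid point of closest approach is
    returned with ``crossed=False``.
    """
    xa = profile_a.coordinates()
    xb = profile_b.coordinates()
    if xa.shape != xb.shape or not np.allclose(xa, xb, atol=1e-12):
        raise ValueError("profiles must share an identical coordinate grid")
    x = xa[:, 0]
    gap = profile_a.energies() - profile_b.energies()
    if np.allclose(gap, 0.0, atol=1e-12):
        return CrossingResult(float(x[0]), float(profile_a.energies()[0]), False,
                              "degenerate: profiles identical")
    zero_hits = np.nonzero(np.isclose(gap, 0.0, atol=1e-12))[0]
    if len(zero_hits):
        k = int(zero_hits[0])
        return CrossingResult(float(x[k]), float(profile_a.energies()[k]), True,
                              "crossing at grid point")
    signs = np.sign(gap)
    changes = np.nonzero(np.diff(signs) != 0)[0]
    if len(changes) == 0:
        k = int(np.argmin(np.abs(gap)))
        return CrossingResult(float(x[k]), float(profile_a.energies()[k]), False,
                              "closest contact, no crossing")
    k = int(changes[0])
    frac = gap[k] / (gap[k] - gap[k + 1])
    xc = x[k] + frac * (x[k + 1] - x[k])
    ea = profile_a.energies()
    ec = ea[k] + frac * (ea[k + 1] - ea[k])
    return CrossingResult(float(xc), float(ec), True, "linear interpolation")


def rmsd_aligned(structure_a: AtomicSystem, structure_b: AtomicSystem) -> float:
    """Minimum RMSD over proper rotations + translations (Kabsch, with the
    SVD determinant correction excluding reflections)."""
    if structure_a.n_atoms != structure_b.n_atoms:
        raise ValueError("atom count mismatch")
    if not np.array_equal(structure_a.atomic_numbers, structure_b.atomic_numbers):
        raise ValueError("element order mismatch")
    p = structure_a.coordinates - structure_a.coordinates.mean(axis=0)
    q = structure_b.coordinates - structure_b.coordinates.mean(axis=0)
    u, s, vt = np.linalg.svd(p.T @ q)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt  # optimal proper rotation for q
    # evaluating the residual directly avoids the cancellation error of the
    # |P|^2 + |Q|^2 - 2 tr(S) trace formula on near-identical structures
    diff = p - q @ rot.T
    return float(np.sqrt((diff**2).sum() / structure_a.n_atoms))


def benchmark_stats(rows: Sequence[BenchmarkRow]) -> BenchmarkStats:
    """Mean (signed) deviation, mean absolute deviation and R^2 of predicted
    versus reference values."""
    if len(rows) == 0:
        raise ValueError("no benchmark rows")
    dev = np.array([r.deviation for r in rows])
    md = float(dev.mean())
    mad = float(np.abs(dev).mean())
    r2: Optional[float] = None
    if len(rows) >= 2:
        ref = np.array([r.reference for r in rows])
        ss_tot = float(np.sum((ref - ref.mean()) ** 2))
        if ss_tot > 0:
            r2 = 1.0 - float(np.sum(dev**2)) / ss_tot
    return BenchmarkStats(md=md, mad=mad, r2=r2)


def profile_mad(profile_pred: ReactionProfile, profile_ref: ReactionProfile) -> float:
    """Mean |energy difference| over profile points after zeroing both
    profiles at their reactant (first) point, making the statistic invariant
    to the absolute energy offset."""
    e_pred = profile_pred.energies()
    e_ref = profile_ref.energies()
    if e_pred.shape != e_ref.shape:
        raise ValueError("profiles have different numbers of points")
    return float(np.abs((e_pred - e_pred[0]) - (e_ref - e_ref[0])).mean())
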