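"""The spin-charge-equilibrated message-passing potential.

The model predicts molecular energy, forces and per-atom spin-resolved
partial charges for an arbitrary combination of total charge Q and spin
multiplicity S.  Its distinctive ingredient is the neural spin-charge
equilibration (NSE) layer: after every message-passing iteration the network
emits candidate per-atom charges q~ and positive weights f for each spin
channel s in {alpha, beta}, and the layer redistributes the channel residual

    q_i^s = q~_i^s + f_i^s / sum_j f_j^s * (Q^s - sum_j q~_j^s)

so that each channel sums exactly to its prescribed total.  Conservation is
therefore architectural — it holds for untrained random parameters.  The
single-channel variant (NQE) is recovered by tying the two channels.

Energies are kcal/mol, coordinates Angstrom, charges elementary charges.
Long-range physics is explicit: damped Coulomb on the summed (alpha+beta)
charges and a BJ-style damped -C6/r^6 pair dispersion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, concat, gather, grad, segment_sum, tensor
from .descriptors import NeighborList, RadialBasis, build_neighbor_list, featurize
from .systems import AtomicSystem, SpinChargeState, spin_channel_totals

__all__ = [
    "EquilibrationWeights",
    "ModelConfig",
    "NSEPotential",
    "PotentialOutput",
    "nqe_update",
    "nse_update",
    "coulomb_energy",
    "dispersion_energy",
    "compute_forces",
    "ensemble_predict",
    "save_checkpoint",
    "load_checkpoint",
]

COULOMB_K = 332.0637128  # kcal mol^-1 Angstrom e^-2, e^2/(4 pi eps0)

#: fallback C6 (kcal/mol Angstrom^6) for elements missing from the config table
_DEFAULT_C6 = {1: 4.0, 6: 28.0, 7: 21.0, 8: 16.0, 9: 11.0, 14: 90.0, 16: 65.0, 17: 55.0}


@dataclass
class EquilibrationWeights:
    """Strictly positive per-atom redistribution weights (one spin channel)."""

    f: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=np.float64)
        if self.f.ndim != 1 or self.f.size == 0:
            raise ValueError("weights must be a nonempty 1-D vector")
        if np.any(self.f <= 0):
            raise ValueError("equilibration weights must be strictly positive")


def _as_weight_vector(f):
    if isinstance(f, EquilibrationWeights):
        return f.f
    return EquilibrationWeights(np.asarray(f, dtype=np.float64)).f


def nqe_update(q_tilde, f, total_charge: float):
    """Charge-conserving update: q = q~ + f/sum(f) * (Q - sum(q~)).

    Linear in both q~ and Q; idempotent (a second application with the same
    f and Q is the identity).  Works on plain arrays (returns ndarray) and on
    autodiff Tensors (returns Tensor) alike.
    """
    if isinstance(q_tilde, Tensor) or isinstance(f, Tensor):
        q_t = tensor(q_tilde)
        f_t = tensor(f if not isinstance(f, EquilibrationWeights) else f.f)
        return q_t + f_t * ((total_charge - q_t.sum()) / f_t.sum())
    fv = _as_weight_vector(f)
    q = np.asarray(q_tilde, dtype=np.float64)
    if q.shape != fv.shape:
        raise ValueError("charge vector and weight vector length mismatch")
    return q + fv / fv.sum() * (total_charge - q.sum())


def nse_update(q_tilde_alpha, q_tilde_beta, f_alpha, f_beta,
               total_alpha: float, total_beta: float) -> SpinChargeState:
    """Two-channel spin-charge equilibration: the NQE update applied to the
    alpha and beta channels independently, each against its own total."""
    qa = np.asarray(q_tilde_alpha, dtype=np.float64)
    qb = np.asarray(q_tilde_beta, dtype=np.float64)
    if qa.shape != qb.shape:
        raise ValueError("alpha/beta channel length mismatch")
    out_a = nqe_update(qa, f_alpha, total_alpha)
    out_b = nqe_update(qb, f_beta, total_beta)
    return SpinChargeState(out_a, out_b, float(total_alpha), float(total_beta))


def _nqe_update_segmented(q_tilde: Tensor, f: Tensor, totals: np.ndarray,
                          frame_ids: np.ndarray, n_frames: int) -> Tensor:
    """Per-frame NQE update inside a batched computation graph."""
    fsum = gather(segment_sum(f, frame_ids, n_frames), frame_ids)
    qsum = segment_sum(q_tilde, frame_ids, n_frames)
    deficit = gather(tensor(totals) - qsum, frame_ids)
    return q_tilde + f / fsum * deficit


# ---------------------------------------------------------------------------
# long-range terms
# ---------------------------------------------------------------------------

def _pair_distances(coords, pairs_i, pairs_j):
    c = tensor(coords)
    delta = c[pairs_i] - c[pairs_j]
    return ((delta * delta).sum(axis=1) + 1e-300).sqrt()


def _coulomb_pair_energy(q, r, k: float, damping_w: float):
    """k q_i q_j g(r)/r per pair with g(r) = r / sqrt(r^2 + w^2): finite at
    r = 0, saturating to the bare 1/r law beyond a few Angstrom."""
    qi_qj = q
    return qi_qj * (k / ((r * r + damping_w**2) ** 0.5))


def coulomb_energy(q_total, coordinates, k: float = COULOMB_K, damping_w: float = 1.5) -> float:
    """Damped pairwise Coulomb energy (kcal/mol) of per-atom charges."""
    q = np.asarray(q_total, dtype=np.float64)
    coords = np.asarray(coordinates, dtype=np.float64)
    n = q.size
    if n < 2:
        return 0.0
    ii, jj = np.triu_indices(n, k=1)
    r = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    return float(np.sum(k * q[ii] * q[jj] / np.sqrt(r**2 + damping_w**2)))


def dispersion_energy(atomic_numbers, coordinates, c6_table: Optional[dict] = None,
                      damping_d: float = 3.0) -> float:
    """BJ-style damped pair dispersion: -sum_{i<j} C6_ij / (r^6 + d^6).

    C6_ij is the geometric mean of per-element coefficients; finite at r = 0,
    decays as r^-6.  Always <= 0.
    """
    z = np.asarray(atomic_numbers)
    coords = np.asarray(coordinates, dtype=np.float64)
    table = dict(_DEFAULT_C6)
    if c6_table:
        table.update({int(k): float(v) for k, v in c6_table.items()})
    c6 = np.array([table.get(int(zz), 10.0) for zz in z])
    n = z.size
    if n < 2:
        return 0.0
    ii, jj = np.triu_indices(n, k=1)
    r = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    c6_pair = np.sqrt(c6[ii] * c6[jj])
    return float(-np.sum(c6_pair / (r**6 + damping_d**6)))


# ---------------------------------------------------------------------------
# the potential
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    elements: Sequence[int] = (1, 6, 7, 8)
    cutoff: float = 5.0
    n_basis: int = 16
    embedding_dim: int = 16
    hidden_dim: int = 64
    n_passes: int = 3
    mode: str = "nse"          # "nse" (two channels) or "nqe" (tied channels)
    coulomb_damping_w: float = 1.5
    dispersion_damping: float = 3.0
    c6_table: dict = field(default_factory=dict)
    f_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("nse", "nqe"):
            raise ValueError(f"mode must be 'nse' or 'nqe', got {self.mode!r}")
        if self.n_passes < 1:
            raise ValueError("need at least one message-passing iteration")
        self.elements = tuple(sorted(int(z) for z in set(self.elements)))


@dataclass
class PotentialOutput:
    energy: float
    forces: Optional[np.ndarray]
    spin_charges: SpinChargeState
    per_atom_energies: np.ndarray
    coulomb: float
    dispersion: float

    def bookkeeping_residual(self) -> float:
        """|energy - (sum per-atom + Coulomb + dispersion)|, ~1e-12."""
        return abs(self.energy - (float(self.per_atom_energies.sum())
                                  + self.coulomb + self.dispersion))


class _Batch:
    """Concatenated frames for vectorised evaluation/training."""

    __slots__ = ("z", "coords", "frame_ids", "n_frames", "n_atoms_per_frame",
                 "totals_alpha", "totals_beta", "nb_pairs", "lr_i", "lr_j",
                 "pair_frames")

    def __init__(self, systems: Sequence[AtomicSystem], cutoff: float,
                 multiplicities: Optional[Sequence[float]] = None):
        zs, coords, fids = [], [], []
        ta, tb, counts = [], [], []
        nb_i, nb_j, lr_i, lr_j, pf = [], [], [], [], []
        offset = 0
        for k, sys_ in enumerate(systems):
            n = sys_.n_atoms
            mult = sys_.multiplicity if multiplicities is None else multiplicities[k]
            qa, qb = spin_channel_totals(sys_.z_sum, sys_.charge, mult)
            zs.append(sys_.atomic_numbers)
            coords.append(sys_.coordinates)
            fids.append(np.full(n, k, dtype=np.intp))
            ta.append(qa)
            tb.append(qb)
            counts.append(n)
            nl = build_neighbor_list(sys_, cutoff)
            nb_i.append(nl.pairs[:, 0] + offset)
            nb_j.append(nl.pairs[:, 1] + offset)
            if n >= 2:
                ii, jj = np.triu_indices(n, k=1)
                lr_i.append(ii + offset)
                lr_j.append(jj + offset)
                pf.append(np.full(ii.size, k, dtype=np.intp))
            offset += n
        self.z = np.concatenate(zs)
        self.coords = np.concatenate(coords, axis=0)
        self.frame_ids = np.concatenate(fids)
        self.n_frames = len(systems)
        self.n_atoms_per_frame = np.array(counts)
        self.totals_alpha = np.array(ta)
        self.totals_beta = np.array(tb)
        self.nb_pairs = (np.concatenate(nb_i) if nb_i else np.zeros(0, np.intp),
                         np.concatenate(nb_j) if nb_j else np.zeros(0, np.intp))
        self.lr_i = np.concatenate(lr_i) if lr_i else np.zeros(0, np.intp)
        self.lr_j = np.concatenate(lr_j) if lr_j else np.zeros(0, np.intp)
        self.pair_frames = np.concatenate(pf) if pf else np.zeros(0, np.intp)


class NSEPotential:
    """Message-passing potential with iterative (spin-)charge equilibration."""

    FORMAT_VERSION = 1

    def __init__(self, config: ModelConfig, params: Optional[dict] = None,
                 element_shifts: Optional[np.ndarray] = None):
        self.config = config
        self.z_to_idx = {z: i for i, z in enumerate(config.elements)}
        self.basis = RadialBasis(n_basis=config.n_basis, cutoff=config.cutoff)
        # constant per-element energy offsets, fitted by linear regression
        # before network training (they carry the arbitrary energy zero)
        self.element_shifts = (np.zeros(len(config.elements))
                               if element_shifts is None
                               else np.asarray(element_shifts, dtype=np.float64))
        self.params = params if params is not None else self._init_params(config.seed)

    # -- parameters --------------------------------------------------------
    def _init_params(self, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        cfg = self.config
        n_el = len(cfg.elements)
        d_in = cfg.embedding_dim + cfg.n_basis * cfg.embedding_dim + 2
        h = cfg.hidden_dim
        n_head = 4 if cfg.mode == "nse" else 2

        def w(shape, scale):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        params = {"embed": w((n_el, cfg.embedding_dim), 1.0)}
        for t in range(cfg.n_passes):
            params[f"pass{t}/W1"] = w((d_in, h), d_in**-0.5)
            params[f"pass{t}/b1"] = w((h,), 0.0)
            params[f"pass{t}/W2"] = w((h, h), h**-0.5)
            params[f"pass{t}/b2"] = w((h,), 0.0)
            params[f"pass{t}/Wh"] = w((h, n_head), 0.1 * h**-0.5)
            params[f"pass{t}/bh"] = w((n_head,), 0.0)
        params["energy/W1"] = w((d_in, h), d_in**-0.5)
        params["energy/b1"] = w((h,), 0.0)
        params["energy/W2"] = w((h, h), h**-0.5)
        params["energy/b2"] = w((h,), 0.0)
        params["energy/Wo"] = w((h, 1), 0.1 * h**-0.5)
        params["energy/bo"] = w((1,), 0.0)
        return params

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([self.params[k].value.ravel() for k in sorted(self.params)])

    def copy(self) -> "NSEPotential":
        params = {k: Tensor(v.value.copy(), requires_grad=True) for k, v in self.params.items()}
        return NSEPotential(self.config, params, self.element_shifts.copy())

    # -- forward ------------------------------------------------------------
    def _element_indices(self, z: np.ndarray) -> np.ndarray:
        try:
            return np.array([self.z_to_idx[int(zz)] for zz in z], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unsupported element Z={exc.args[0]}") from None

    def _mlp(self, x: Tensor, prefix: str) -> Tensor:
        p = self.params
        h = ((x @ p[f"{prefix}/W1"]) + p[f"{prefix}/b1"]).tanh()
        return ((h @ p[f"{prefix}/W2"]) + p[f"{prefix}/b2"]).tanh()

    def _forward_graph(self, batch: _Batch, coords: Tensor):
        """Energy per frame plus final spin charges, as graph tensors."""
        cfg = self.config
        elem_idx = self._element_indices(batch.z)
        fids, n_frames = batch.frame_ids, batch.n_frames
        emb = self.params["embed"]
        self_emb = gather(emb, elem_idx)

        # geometric environment (fixed across passes)
        pi, pj = batch.nb_pairs
        n_feat = cfg.n_basis * cfg.embedding_dim
        if pi.size:
            r_nb = _pair_distances(coords, pi, pj)
            g = self.basis.evaluate(r_nb)
            neigh = gather(emb, elem_idx[pj])
            outer = g.reshape(-1, cfg.n_basis, 1) * neigh.reshape(-1, 1, cfg.embedding_dim)
            env = segment_sum(outer.reshape(-1, n_feat), pi, len(batch.z))
        else:
            env = Tensor(np.zeros((len(batch.z), n_feat)))

        # uniform initial channel charges consistent with the frame totals
        per_atom_a = batch.totals_alpha / batch.n_atoms_per_frame
        per_atom_b = batch.totals_beta / batch.n_atoms_per_frame
        qa = tensor(per_atom_a[fids])
        qb = tensor(per_atom_b[fids])

        floor = cfg.f_floor
        for t in range(cfg.n_passes):
            x = concat([self_emb, env,
                        (qa + qb).reshape(-1, 1),
                        (qb - qa).reshape(-1, 1)], axis=1)
            h = self._mlp(x, f"pass{t}")
            head = (h @ self.params[f"pass{t}/Wh"]) + self.params[f"pass{t}/bh"]
            if cfg.mode == "nse":
                qta, qtb = head[:, 0], head[:, 1]
                fa = head[:, 2].softplus() + floor
                fb = head[:, 3].softplus() + floor
            else:  # tied channels: one candidate + one weight, split evenly
                qta = qtb = head[:, 0] * 0.5
                fa = fb = head[:, 1].softplus() + floor
            qa = _nqe_update_segmented(qta, fa, batch.totals_alpha, fids, n_frames)
            qb = _nqe_update_segmented(qtb, fb, batch.totals_beta, fids, n_frames)

        x = concat([self_emb, env,
                    (qa + qb).reshape(-1, 1),
                    (qb - qa).reshape(-1, 1)], axis=1)
        h = self._mlp(x, "energy")
        e_atoms = ((h @ self.params["energy/Wo"]) + self.params["energy/bo"]).reshape(-1)
        e_atoms = e_atoms + self.element_shifts[elem_idx]
        e_local = segment_sum(e_atoms, fids, n_frames)

        # explicit long-range terms on summed charges / element identities
        if batch.lr_i.size:
            r_lr = _pair_distances(coords, batch.lr_i, batch.lr_j)
            q_tot = qa + qb
            e_pair_c = _coulomb_pair_energy(q_tot[batch.lr_i] * q_tot[batch.lr_j],
                                            r_lr, COULOMB_K, cfg.coulomb_damping_w)
            table = dict(_DEFAULT_C6)
            table.update({int(k): float(v) for k, v in cfg.c6_table.items()})
            c6 = np.array([table.get(int(zz), 10.0) for zz in batch.z])
            c6_pair = np.sqrt(c6[batch.lr_i] * c6[batch.lr_j])
            e_pair_d = (-1.0 * c6_pair) / (r_lr ** 6.0 + cfg.dispersion_damping**6)
            e_coul = segment_sum(e_pair_c, batch.pair_frames, n_frames)
            e_disp = segment_sum(e_pair_d, batch.pair_frames, n_frames)
        else:
            e_coul = Tensor(np.zeros(n_frames))
            e_disp = Tensor(np.zeros(n_frames))

        energy = e_local + e_coul + e_disp
        return energy, qa, qb, e_atoms, e_coul, e_disp

    def forward(self, system: AtomicSystem, compute_forces: bool = False,
                multiplicity: Optional[float] = None) -> PotentialOutput:
        """Evaluate energy, spin charges and (optionally) forces.

        `multiplicity` overrides the system's S (continuous values allowed,
        interpolating the channel totals linearly in S)."""
        mult = system.multiplicity if multiplicity is None else multiplicity
        batch = _Batch([system], self.config.cutoff, multiplicities=[mult])
        coords = Tensor(batch.coords, requires_grad=compute_forces)
        energy, qa, qb, e_atoms, e_coul, e_disp = self._forward_graph(batch, coords)
        forces = None
        if compute_forces:
            forces = -grad(energy.sum(), coords).value
        state = SpinChargeState(qa.value, qb.value,
                                float(batch.totals_alpha[0]), float(batch.totals_beta[0]))
        return PotentialOutput(
            energy=float(energy.value[0]),
            forces=forces,
            spin_charges=state,
            per_atom_energies=e_atoms.value.copy(),
            coulomb=float(e_coul.value[0]),
            dispersion=float(e_disp.value[0]),
        )

    # convenience adapter used by reaction_analysis
    def energy_forces(self, system: AtomicSystem):
        out = self.forward(system, compute_forces=True)
        return out.energy, out.forces


def compute_forces(model: NSEPotential, system: AtomicSystem) -> np.ndarray:
    """Forces as -dE/dR via reverse-mode automatic differentiation."""
    return model.forward(system, compute_forces=True).forces


def ensemble_predict(models: Sequence[NSEPotential], system: AtomicSystem):
    """(mean energy, population std of energy, mean forces) over members."""
    if len(models) == 0:
        raise ValueError("empty ensemble")
    energies, forces = [], []
    for m in models:
        e, f = m.energy_forces(system)
        energies.append(e)
        forces.append(f)
    energies = np.array(energies)
    return float(energies.mean()), float(energies.std(ddof=0)), np.mean(forces, axis=0)


# ---------------------------------------------------------------------------
# checkpoints (single-file JSON: config + parameter arrays + format version)
# ---------------------------------------------------------------------------

def save_checkpoint(model: NSEPotential, path) -> None:
    payload = {
        "format_version": NSEPotential.FORMAT_VERSION,
        "config": asdict(model.config),
        "element_shifts": model.element_shifts.tolist(),
        "params": {k: {"shape": list(v.value.shape), "data": v.value.ravel().tolist()}
                   for k, v in model.params.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> NSEPotential:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != NSEPotential.FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint version {payload.get('format_version')}")
    cfg_dict = payload["config"]
    cfg_dict["elements"] = tuple(cfg_dict["elements"])
    cfg_dict["c6_table"] = {int(k): v for k, v in cfg_dict.get("c6_table", {}).items()}
    config = ModelConfig(**cfg_dict)
    params = {k: Tensor(np.array(v["data"]).reshape(v["shape"]), requires_grad=True)
              for k, v in payload["params"].items()}
    shifts = np.array(payload["element_shifts"], dtype=np.float64)
    return NSEPotential(config, params, shifts)
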