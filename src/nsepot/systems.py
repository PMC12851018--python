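"""Molecular systems with explicit total charge and spin multiplicity.

The central bookkeeping of the package lives here: an :class:`AtomicSystem`
carries the nuclear identities and coordinates together with the molecular
total charge ``Q`` (elementary charges) and spin multiplicity ``S``; the pair
``(Q, S)`` determines the per-spin-channel charge totals that every
equilibration step must conserve.  File exchange uses a small extended-XYZ
dialect with ``charge=... multiplicity=...`` in the comment line and optional
per-atom force and spin-charge columns.

Sign convention: electrons carry charge -1 and the alpha channel hosts the
``S - 1`` excess unpaired electrons, so ``Q_alpha <= Q_beta``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomicSystem",
    "SpinChargeState",
    "XYZFrame",
    "spin_channel_totals",
    "read_extxyz",
    "write_extxyz",
    "ELEMENT_SYMBOLS",
    "symbol_to_z",
]

# Z -> symbol for the elements this package can ever meet (H..Rn covers the
# 14-element organic/main-group scope with lots of headroom).
ELEMENT_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn",
]
_SYMBOL_TO_Z = {s: z for z, s in enumerate(ELEMENT_SYMBOLS) if z > 0}


def symbol_to_z(symbol: str) -> int:
    try:
        return _SYMBOL_TO_Z[symbol.capitalize()]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


class ParityError(ValueError):
    """Raised when (Q, S) is inconsistent with the electron count."""


def spin_channel_totals(z_sum: float, charge: float, multiplicity: float):
    """Per-spin-channel charge totals (Q_alpha, Q_beta) from Q and S.

    With ``n_u = S - 1`` unpaired electrons assigned to the alpha channel,

        Q_alpha = (Q - n_u) / 2,   Q_beta = (Q + n_u) / 2.

    For integer ``S`` the electron count ``N_e = sum(Z) - Q`` must be able to
    host ``n_u`` unpaired electrons: ``N_e - n_u`` must be even and
    nonnegative.  Non-integer ``S`` (used only to probe smoothness of model
    predictions in S) skips the parity check and interpolates linearly.
    """
    if multiplicity < 1:
        raise ValueError(f"multiplicity must be >= 1, got {multiplicity}")
    n_u = multiplicity - 1.0
    is_integral = float(multiplicity).is_integer()
    if is_integral:
        n_electrons = z_sum - charge
        if (round(n_electrons - n_u)) % 2 != 0 or n_electrons < n_u:
            raise ParityError(
                "inconsistent charge/multiplicity: "
                f"{n_electrons:g} electrons cannot host {n_u:g} unpaired electrons"
            )
    q_alpha = (charge - n_u) / 2.0
    q_beta = (charge + n_u) / 2.0
    return q_alpha, q_beta


@dataclass
class AtomicSystem:
    """A molecule: nuclei, Cartesian coordinates (Angstrom), Q and S."""

    atomic_numbers: np.ndarray
    coordinates: np.ndarray
    charge: float = 0.0
    multiplicity: float = 1.0
    frame_id: Optional[str] = None

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.atomic_numbers.ndim != 1 or self.atomic_numbers.size == 0:
            raise ValueError("need at least one atom")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be >= 1")
        if self.coordinates.shape != (self.atomic_numbers.size, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{self.atomic_numbers.size} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        # validates parity as a side effect (raises ParityError if violated)
        spin_channel_totals(float(self.atomic_numbers.sum()), self.charge, self.multiplicity)

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.size)

    @property
    def z_sum(self) -> float:
        return float(self.atomic_numbers.sum())

    def channel_totals(self):
        return spin_channel_totals(self.z_sum, self.charge, self.multiplicity)

    def with_coordinates(self, coordinates: np.ndarray) -> "AtomicSystem":
        return AtomicSystem(
            self.atomic_numbers.copy(),
            np.asarray(coordinates, dtype=np.float64),
            self.charge,
            self.multiplicity,
            self.frame_id,
        )

    def symbols(self) -> list:
        return [ELEMENT_SYMBOLS[z] for z in self.atomic_numbers]


@dataclass
class SpinChargeState:
    """Per-atom alpha/beta charges and the channel totals they must sum to."""

    q_alpha: np.ndarray
    q_beta: np.ndarray
    total_alpha: float
    total_beta: float

    def __post_init__(self):
        self.q_alpha = np.asarray(self.q_alpha, dtype=np.float64)
        self.q_beta = np.asarray(self.q_beta, dtype=np.float64)
        if self.q_alpha.shape != self.q_beta.shape:
            raise ValueError("alpha/beta channel length mismatch")

    @property
    def q_total(self) -> np.ndarray:
        """Conventional partial charges (sum of channels)."""
        return self.q_alpha + self.q_beta

    @property
    def spin_population(self) -> np.ndarray:
        """Local unpaired-electron population, q_beta - q_alpha."""
        return self.q_beta - self.q_alpha

    def conservation_errors(self):
        return (
            abs(float(self.q_alpha.sum()) - self.total_alpha),
            abs(float(self.q_beta.sum()) - self.total_beta),
        )

    def validate(self, atol: float = 1e-8) -> None:
        ea, eb = self.conservation_errors()
        if ea > atol or eb > atol:
            raise ValueError(f"channel sums off target: alpha {ea:.2e}, beta {eb:.2e}")


@dataclass
class XYZFrame:
    """An AtomicSystem plus whatever labels a file carried for it."""

    system: AtomicSystem
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None
    q_alpha: Optional[np.ndarray] = None
    q_beta: Optional[np.ndarray] = None
    extra: dict = field(default_factory=dict)


def _parse_comment_line(line: str) -> dict:
    out = {}
    for tok in line.split():
        if "=" not in tok:
            continue
        key, _, val = tok.partition("=")
        out[key] = val
    return out


def read_extxyz(path) -> list:
    """Read a (possibly multi-frame) extended-XYZ file into XYZFrames.

    Comment-line keys ``charge`` and ``multiplicity`` default to 0 and 1 with
    a logged warning; per-atom columns beyond x/y/z are interpreted, in
    order, as ``fx fy fz`` (7 columns) and ``q_alpha q_beta`` (6 or 9
    columns).
    """
    frames = []
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise ValueError(
                f"frame {frame_index}: malformed atom count line {lines[pos]!r}"
            ) from None
        if pos + 1 >= len(lines):
            raise ValueError(f"frame {frame_index}: missing comment line")
        header = _parse_comment_line(lines[pos + 1])
        try:
            charge = float(header["charge"]) if "charge" in header else None
            mult = float(header["multiplicity"]) if "multiplicity" in header else None
            energy = float(header["energy"]) if "energy" in header else None
        except ValueError as exc:
            raise ValueError(f"frame {frame_index}: non-numeric header field ({exc})") from None
        if charge is None:
            logger.warning("frame %d: no charge key, defaulting to 0", frame_index)
            charge = 0.0
        if mult is None:
            logger.warning("frame %d: no multiplicity key, defaulting to 1", frame_index)
            mult = 1.0
        zs, coords, extras = [], [], []
        for k in range(n_atoms):
            line_idx = pos + 2 + k
            if line_idx >= len(lines) or not lines[line_idx].strip() or len(lines[line_idx].split()) < 4:
                raise ValueError(
                    f"frame {frame_index}: declared {n_atoms} atoms but atom line {k} is missing/short"
                )
            parts = lines[line_idx].split()
            zs.append(symbol_to_z(parts[0]))
            try:
                nums = [float(x) for x in parts[1:]]
            except ValueError:
                raise ValueError(
                    f"frame {frame_index}: non-numeric field in atom line {k}: {lines[line_idx]!r}"
                ) from None
            coords.append(nums[:3])
            extras.append(nums[3:])
        try:
            system = AtomicSystem(
                np.array(zs), np.array(coords), charge, mult,
                frame_id=header.get("frame_id"),
            )
        except ValueError as exc:
            raise ValueError(f"frame {frame_index}: {exc}") from None
        n_extra = len(extras[0])
        if any(len(e) != n_extra for e in extras):
            raise ValueError(f"frame {frame_index}: ragged per-atom columns")
        forces = q_alpha = q_beta = None
        ex = np.array(extras, dtype=np.float64) if n_extra else np.zeros((n_atoms, 0))
        if n_extra >= 3:
            forces = ex[:, :3]
        if n_extra in (2, 5):
            q_alpha, q_beta = ex[:, -2], ex[:, -1]
        frames.append(XYZFrame(system, energy=energy, forces=forces,
                               q_alpha=q_alpha, q_beta=q_beta, extra=dict(header)))
        pos += 2 + n_atoms
        frame_index += 1
    return frames


def _fmt(x: float) -> str:
    return f"{x:.12f}"


def write_extxyz(path, frames: Sequence, header_extra: Optional[dict] = None) -> None:
    """Write XYZFrame-like records (system + optional labels) to `path`.

    ``header_extra`` key/values are stamped into every comment line (used by
    the CLI for config-hash/seed provenance).  Multiplicity is written as an
    integer; writing a frame with non-integer S is refused.
    """
    with open(path, "w") as fh:
        for frame in frames:
            system = frame.system
            if not float(system.multiplicity).is_integer():
                raise ValueError("file I/O only writes integer multiplicities")
            forces = getattr(frame, "forces", None)
            q_alpha = getattr(frame, "q_alpha", None)
            q_beta = getattr(frame, "q_beta", None)
            energy = getattr(frame, "energy", None)
            for label, width in ((forces, (system.n_atoms, 3)),):
                if label is not None and np.shape(label) != width:
                    raise ValueError(f"forces shape {np.shape(label)} != {width}")
            for label in (q_alpha, q_beta):
                if label is not None and np.shape(label) != (system.n_atoms,):
                    raise ValueError("charge label length does not match system")
            if (q_alpha is None) != (q_beta is None):
                raise ValueError("q_alpha and q_beta must be written together")
            header = [f"charge={system.charge:g}", f"multiplicity={int(system.multiplicity)}"]
            if energy is not None:
                header.append(f"energy={energy:.12f}")
            if system.frame_id is not None:
                header.append(f"frame_id={system.frame_id}")
            for key, val in (header_extra or {}).items():
                header.append(f"{key}={val}")
            fh.write(f"{system.n_atoms}\n")
            fh.write(" ".join(header) + "\n")
            for i, (sym, xyz) in enumerate(zip(system.symbols(), system.coordinates)):
                cols = [sym] + [_fmt(v) for v in xyz]
                if forces is not None:
                    cols += [_fmt(v) for v in np.asarray(forces)[i]]
                if q_alpha is not None:
                    cols += [_fmt(np.asarray(q_alpha)[i]), _fmt(np.asarray(q_beta)[i])]
                fh.write(" ".join(cols) + "\n")
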