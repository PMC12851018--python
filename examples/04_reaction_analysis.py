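"""Reaction-analysis toolbox on the analytic surrogate potential.

Geometry optimisation to a known Morse minimum, a rigid bond scan,
reaction energetics from scan markers, optimal-superposition RMSD, and
benchmark statistics recomputed from the shipped activation-barrier
deviation table.
"""

from importlib import resources

import numpy as np
import pandas as pd

from nsepot import (
    AtomicSystem,
    BenchmarkRow,
    benchmark_stats,
    default_oracle,
    optimize_geometry,
    reaction_energetics,
    rmsd_aligned,
    scan_1d,
)

oracle = default_oracle(use_coulomb=False)
pot = oracle.as_potential(1)

# --- optimisation to the analytic minimum ---------------------------------
start = AtomicSystem([1, 1], [[0, 0, 0], [1.1, 0, 0]])
opt, info = optimize_geometry(pot, start)
r_opt = np.linalg.norm(opt.coordinates[1] - opt.coordinates[0])
print(f"optimised H2 bond: {r_opt:.4f} A (analytic r_e = "
      f"{oracle.morse_for(1, 1, 1).r_e} A, {info['steps']} steps)")

# --- scan + energetics ----------------------------------------------------
profile = scan_1d(pot, opt, (0, 1), np.linspace(0.741, 3.5, 30), multiplicity=1)
energies = profile.energies()
de_rxn, barrier = reaction_energetics(energies[0], energies.max(), energies[-1])
print(f"dissociation scan: reaction energy {de_rxn:.2f} kcal/mol "
      f"(barrier along scan {barrier:.2f})")

# --- structural comparison ------------------------------------------------
jittered = opt.with_coordinates(
    opt.coordinates + np.random.default_rng(3).normal(0, 0.05, (2, 3)))
print(f"RMSD optimised vs jittered copy: {rmsd_aligned(opt, jittered):.4f} A")

# --- benchmark statistics from published deviations -----------------------
with resources.files("nsepot").joinpath("data/baschem19_deviations.csv").open() as fh:
    table = pd.read_csv(fh)
rows = [BenchmarkRow(str(r.reaction), 0.0, float(r.aimnet2_nse))
        for r in table.itertuples()]
stats = benchmark_stats(rows)
print(f"BASChem19 barrier deviations (spin-aware MLIP column, n={len(rows)}): "
      f"MD {stats.md:.2f}, MAD {stats.mad:.2f} kcal/mol")
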