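"""Train the potential on surrogate dissociation curves and locate the
singlet/triplet crossing.

A desk-scale version of learning a spin-resolved bond-breaking surface:
500 labeled H2 frames alternating singlet/triplet, about ten seconds of
training, then 1-D scans of both spin surfaces on the trained model and a
crossing-point estimate compared against the analytic truth.

(The larger version — 3000 frames, 80 epochs — runs inside
scripts/acceptance.py and the test suite.)
"""

import numpy as np

from nsepot import AtomicSystem, analytic_crossing_distance, crossing_point, scan_1d
from nsepot.validation import _FixedSpinModel, train_dimer_model

model, oracle, history = train_dimer_model(seed=1, n_frames=500, max_epochs=60,
                                           batch_size=64)
print(f"trained {len(history)} epochs; final validation loss "
      f"{history[-1]['val_total']:.4f}")

h2 = AtomicSystem([1, 1], [[0, 0, 0], [0.741, 0, 0]])
grid = np.linspace(0.741, 4.0, 120)
prof_s = scan_1d(_FixedSpinModel(model, 1.0), h2, (0, 1), grid, multiplicity=1.0)
prof_t = scan_1d(_FixedSpinModel(model, 3.0), h2, (0, 1), grid,
                 multiplicity=3.0, mark=False)

result = crossing_point(prof_s, prof_t)
analytic = analytic_crossing_distance(oracle)
e_s, e_t = prof_s.energies(), prof_t.energies()
print(f"model crossing:    r = {result.coordinate:.4f} A")
print(f"analytic crossing: r = {analytic:.4f} A  (error "
      f"{abs(result.coordinate - analytic):.4f} A)")
print(f"well depths: singlet {e_s[-1] - e_s.min():.1f}, "
      f"triplet {e_t[-1] - e_t.min():.1f} kcal/mol (ordering preserved)")
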