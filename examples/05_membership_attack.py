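"""Black-box membership inference against a generator's output.

The attacker knows every candidate record and sees only synthetic output;
it claims 'member' for the candidates closest to any synthetic record.
Two extremes bracket a real generator: a memorizer (synthetic = copies of
training records) is caught with accuracy 1, while a generator whose
output is independent of membership pushes the attack to a coin flip.
"""

import numpy as np

import mtsgan as M
from mtsgan.privacy import AttackSetup

cand = M.simulate_batch(M.SimulatorConfig(n_patients=200, seed=0))
mask = np.zeros(200, dtype=bool)
mask[np.random.default_rng(0).choice(200, 100, replace=False)] = True

memorized = cand.subset(np.flatnonzero(mask))
res = M.membership_attack(AttackSetup(candidates=cand, member_mask=mask,
                                      synthetic=memorized))
print(f"memorizing generator:  accuracy={res.accuracy:.3f} "
      f"recall={res.recall:.3f}   (worst case: training data fully exposed)")

independent = M.simulate_batch(M.SimulatorConfig(n_patients=200, seed=99))
res = M.membership_attack(AttackSetup(candidates=cand, member_mask=mask,
                                      synthetic=independent))
print(f"independent generator: accuracy={res.accuracy:.3f} "
      f"recall={res.recall:.3f}   (ideal: 0.5 = random guessing)")
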