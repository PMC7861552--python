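"""The 3-state mPTP chain and its closed-form stationary open probability.

Prints P_open(alpha_mPTP) at a fixed mitochondrial Ca2+ and checks the
closed form against a long stochastic simulation of many independent pores.
"""

import numpy as np

from mitoca import MPTPParams, mptp_steady_state, mptp_transition_step
from mitoca.mitochondria import MitoState, MPTP_O
import dataclasses

ca_m = 0.6  # uM, the paced depolarized operating point
print(f"stationary open probability at [Ca2+]_m = {ca_m} uM:")
for alpha in (0.1, 1.0, 10.0, 30.0, 60.0, 100.0, 1000.0):
    p = mptp_steady_state(MPTPParams(alpha_mptp=alpha), ca_m)
    print(f"  alpha_mPTP = {alpha:7.1f} -> P_open = {p:.4f}")

# Monte-Carlo cross-check at alpha = 60
params = MPTPParams(alpha_mptp=60.0)
state = MitoState.resting(512)
rng = np.random.default_rng(1)
hits = 0
n = 30000
for i in range(2 * n):
    mptp_transition_step(state, params, 5.0, rng, ca_m=ca_m)
    if i >= n:
        hits += int(np.sum(state.mptp_state == MPTP_O))
print(f"\nMonte-Carlo (512 pores, 150 s): {hits / (n * 512):.4f} "
      f"vs closed form {mptp_steady_state(params, ca_m):.4f}")
print("At the paced mitochondrial Ca2+ level, a 60-fold rise of the C1->O "
      "rate takes the pore from near-zero to ~30% open.")
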