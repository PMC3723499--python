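"""Homogeneous palimpsest: strong-but-brief vs weak-but-lasting memories.

Simulates N binary synapses that store one new random memory per time step
with learning rate q, and compares the Monte-Carlo signal of the memory
stored at t=0 with the mean-field exponential N q (1-q)^t. The initial SNR
is sqrt(N) q and the lifetime ln(sqrt(N) q)/q: fast synapses give vivid
memories that are quickly overwritten, slow synapses the reverse.
"""

import numpy as np

from memsim import ModelConfig, simulate_population
from memsim.meanfield import lifetime_homogeneous, mf_homogeneous_discrete

N = 10_000
for q in (0.5, 0.05):
    cfg = ModelConfig.homogeneous(N, q)
    T = int(4 / q)
    trace = simulate_population(cfg, T=T, n_real=200, seed=0)
    t_show = [0, T // 4, T // 2, T]
    print(f"\nq = {q}: initial SNR = {np.sqrt(N) * q:.1f}, "
          f"lifetime = {lifetime_homogeneous(N, q):.1f} memories")
    for t in t_show:
        mc = trace.signal_mean[0, t]
        th = mf_homogeneous_discrete(N, q, t)
        print(f"  t={t:4d}  signal: simulated {mc:9.1f}   mean-field {th:9.1f}")

print("\nLarger q -> stronger initial trace but shorter lifetime: the "
      "plasticity-rigidity dilemma a single synapse population cannot escape.")
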