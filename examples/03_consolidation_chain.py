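"""Memory transfer: stochastic synaptic copying down a chain of stages.

Five stages with geometrically decreasing learning rates. Only stage 1 sees
new memories; each downstream synapse copies its upstream counterpart with
its stage's probability. The tracked memory's trace in stage k >= 2 starts
at zero, rises as the trace is handed down, and decays again — the
non-monotonic signature of systems consolidation. The Monte-Carlo means
are compared with the exact mean-field recursion.
"""

import numpy as np

from memsim import ModelConfig, simulate_transfer_chain
from memsim.meanfield import mf_transfer_discrete

cfg = ModelConfig(N=5 * 10_000, n=5, q1=0.5, qn=0.01)
T = 300
trace = simulate_transfer_chain(cfg, T=T, n_real=200, seed=0)
rec = mf_transfer_discrete(cfg, T)

print("stage   q_k      peak time (sim / mean-field)   peak signal (sim / mf)")
for k in range(cfg.n):
    pk_sim = int(np.argmax(trace.signal_mean[k]))
    pk_mf = int(np.argmax(rec.per_stage_signal[k]))
    print(f"  {k + 1}   {cfg.rates[k]:7.4f}      {pk_sim:5d} / {pk_mf:5d}"
          f"            {trace.signal_mean[k, pk_sim]:8.0f} /"
          f" {rec.per_stage_signal[k, pk_mf]:8.0f}")

print("\nStage 1 peaks at encoding (t=0); each later stage peaks later and "
      "lower — the memory travels as a wave from fast to slow stages.")
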