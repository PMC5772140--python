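"""Per-edge messages are exact on trees.

On a finite tree the message-passing equations solved per directed edge
reproduce the stochastic epidemic exactly (no mean-field approximation is
involved).  Here a 10,000-run Markovian ensemble on a 5-node star is
compared with the per-edge solution node by node.
"""

import numpy as np

from netsir import (DiseaseModel, StaticNetwork, ensemble_average,
                    parse_delay_spec, simulate_rejection, solve_mp_per_edge)

star = StaticNetwork(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
beta, gamma, z = 0.3, 0.5, 0.9
model = DiseaseModel(parse_delay_spec(f"exp:{beta}"), parse_delay_spec(f"exp:{gamma}"))

grid = np.arange(0, 8.0 + 1e-9, 0.5)
runs = 10_000
logs = [simulate_rejection(star, beta, parse_delay_spec(f"exp:{gamma}"),
                           1 - z, seed=[3, i]) for i in range(runs)]
ens = ensemble_average(logs, grid)

res = solve_mp_per_edge(star, model, z, T=8.0, h=0.05)
S_exact = res.node_susceptibility.mean(axis=0)[::10]

print(" t    S(sim)   S(tree-exact)  |diff|/SE")
for j, t in enumerate(grid):
    se = max(ens.S_se[j], 1e-12)
    print(f"{t:4.1f}  {ens.S_mean[j]:.4f}   {S_exact[j]:.4f}        "
          f"{abs(ens.S_mean[j]-S_exact[j])/se:5.2f}")
print(f"(|diff|/SE stays O(1) over {runs} runs: agreement to Monte-Carlo error)")
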