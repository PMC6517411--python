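# ictonet

Does the choice of dynamical model change which brain regions a network
model of epilepsy surgery would recommend removing?  `ictonet` answers this
question in simulation.  It implements three stochastic seizure-transition
models on binary directed networks — a modified Jansen–Rit neural mass
("physiological"), the theta model (SNIC normal form), and a bistable
subcritical-Hopf normal form — and measures, for each network and model:

* **BNI** (brain network ictogenicity): the propensity of the network to be
  in the seizure-like state, mapped over a regular excitability×coupling
  parameter grid.  For the recurrently switching models BNI is the fraction
  of a reference window spent in the ictal state; for the bistable model it
  is `1 − ⟨escape time⟩/T`, the normalised first passage from the
  background fixed point to the oscillatory attractor.
* **NI** (node ictogenicity): the effect of a virtual resection,
  `NI_i = (⟨BNI⟩₀ − ⟨BNI⟩_i)/⟨BNI⟩₀`, where `⟨·⟩` averages over the whole
  parameter map and `i` indexes the removed node.  NI is negative when a
  removal makes the remaining network *more* ictogenic.
* **Cross-model agreement**: the weighted Kendall rank coefficient
  `τ = (P−Q)/(P+Q)` between two models' NI vectors, each node pair
  weighted by `|NI_i^A − NI_j^A|·|NI_i^B − NI_j^B|`, plus ensemble
  analyses relating agreement to NI heterogeneity
  (`ΔNI = max_i NI_i − min_i NI_i`) and to outdegree dispersion
  `σ_out/⟨k_out⟩`.

The network ensembles are generated, not measured: all 13 weakly-connected
nonisomorphic 3-node digraphs, all 199 4-node ones, and stratified random
19-node digraphs with edge counts approximately uniform on [18, 342].

Audience: computational neuroscientists and methodologists studying
virtual-resection / network-perturbation pipelines, and anyone who needs a
reproducible, seedable implementation of these three models with BNI/NI
semantics.

## Worked example

Node ictogenicity of the 4-node network in which node 3 drives two leaves
and exchanges edges with node 2:

```python
import numpy as np
from ictonet import (Network, compute_ni, default_grid, weighted_kendall,
                     preset_sim_config)

adj = np.array([[0, 0, 0, 1],
                [0, 0, 0, 1],
                [1, 1, 0, 1],
                [0, 1, 0, 0]], dtype=np.int8)
net = Network(adj)

ni = {}
for model in ("physiological", "theta", "bistable"):
    dist = compute_ni(net, model,
                      grid=default_grid(model, resolution=24),
                      config=preset_sim_config(model, "desk"),
                      master_seed=7)
    ni[model] = dist
    print(model, np.round(dist.ni, 3), "dNI =", round(dist.delta_ni, 3))

tau = weighted_kendall(ni["physiological"].ni, ni["theta"].ni)
print("tau(phys, theta) =", round(tau.tau, 3))
```

Output (≈25 s on one CPU; identical on reruns with the same seed):

```
physiological [0.047 0.182 0.095 0.298] dNI = 0.251
theta [-0.013  0.305  0.178  0.503] dNI = 0.516
bistable [0.002 0.476 0.009 0.668] dNI = 0.667
tau(phys, theta) = 1.0
```

All three models rank node 3 — the network's highest-degree node — as most
ictogenic, and the peripheral node 0 as nearly irrelevant: removing it
barely changes the remaining network's ictogenicity (under the theta model
its NI is even slightly negative, i.e. removal marginally *increases*
ictogenicity).  The weighted Kendall τ of 1.0 says the physiological and
theta rankings agree on every node pair that carries weight, despite the
models' very different NI scales.

The same analyses run from the shell:

```bash
ictonet enumerate --n 4 --out nets4/
ictonet ni --network nets4/net_4n_100.tsv --model theta --preset desk --seed 7 --out ni_theta
ictonet run --config experiment.yaml --seed 7 --dry-run
```

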