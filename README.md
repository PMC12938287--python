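# inflamnet

Agent-based simulation of inflammation under normal and aging
(*inflammaging*) conditions, with an information-theoretic analysis of how
much the model's macrophages and fibroblasts "talk" to each other through
their migration dynamics.

## The problem

Wound healing depends on communication between pro-inflammatory macrophages
(which secrete TNF) and pro-healing fibroblasts (which secrete TGF). Aging
alters this communication — TNF synthesis is enhanced, tissue regenerates
more slowly, fibrosis persists — and the inflammation course shifts from
full recovery to sustained injury. `inflamnet` is for computational
biologists who want to study that shift *as an information-flow problem*:
rather than reading cytokine levels directly, it infers cell–cell influence
purely from the cells' observable migration paths, the way one would from
imaging-based tracking data.

The package has three layers, usable independently:

1. **Simulator** (`params`, `fields`, `agents`, `engine`) — a lattice model:
   epithelial cells die when local TNF exceeds an apoptosis threshold and
   heal under TGF; motile cells perform collision-avoiding biased random
   walks (chemotaxis via softmax over Moore-neighbourhood concentrations);
   cytokines obey `dφ/dt = D∇²φ − Kφ` (explicit Euler, no-flux boundaries);
   aging presets **N**, **A1**, **A2** set the synthesis gates
   Beta(α₃, β₃)/Beta(α₄, β₄), the apoptosis threshold, mitosis probability,
   healing time and fibrosis duration.
2. **Information flow** (`infoflow`) — turning angles
   θ_t ∈ [0, 2π) between consecutive displacement vectors, discretised into
   20 bins; plug-in Shannon entropy, mutual information
   `I(X;Y) = H(X) + H(Y) − H(X,Y)`, conditional mutual information, and
   transfer entropy `T(M→F) = I(F_t ; M_{t−1} | F_{t−1})` in bits, per
   macrophage–fibroblast pair. Works on simulator output or any tracking
   CSV with columns `t, slot_id, kind, segment, row, col`.
3. **Networks** (`networks`, `pipeline`) — per condition, the pooled TE
   distribution's [Q1, Q3] interval generates edges of an undirected
   bipartite graph; normalised betweenness centrality is summed per part
   and the fibroblast/macrophage ratio **F/M** summarises whether the
   network is fibroblast-centred (F/M > 1) or macrophage-centred (F/M < 1).

## Worked example

```python
import numpy as np
from inflamnet import (SimulationParams, aging_preset, run_replicates,
                       pairwise_te, condition_summary)

params = SimulationParams(grid_rows=60, grid_cols=60, n_iterations=500,
                          stimulus=0.4, aging=aging_preset("N"), seed=7)
results = run_replicates(params, 5, base_seed=7)
print("final inflammation scores:",
      [int(r.inflammation_score[-1]) for r in results])

te_matrices = [pairwise_te(r.tracks) for r in results]
pooled = np.concatenate([m.defined_values() for m in te_matrices])
print(f"defined TE entries: {pooled.size}/2000, mean = {pooled.mean():.3f} bits")

summary = condition_summary(te_matrices)
print(f"edge criterion: [{summary.criterion.lower:.3f}, {summary.criterion.upper:.3f}] bits")
print(f"mean F/M = {summary.mean_fm:.3f} +/- {summary.fm_stderr:.3f}")
```

prints

```
final inflammation scores: [3585, 3598, 3590, 3588, 3595]
defined TE entries: 1537/2000, mean = 1.790 bits
edge criterion: [1.641, 1.944] bits
mean F/M = 1.362 +/- 0.226
```

Reading the output: under moderate stimulus (S = 0.4) the injury is
sustained — nearly all 3600 epithelial sites are dead at iteration 500, as
cytokine accumulation at this grid scale outruns clearance (see
`docs/methods.md` §4 for why, and what that implies for interpreting the
TE values). 1537 of the 2000 macrophage–fibroblast pairs had enough
aligned migration data (≥ 50 triples) for a transfer-entropy estimate; the
quartile criterion brackets the most likely TE values and the resulting
networks put slightly more betweenness on the fibroblast side (F/M > 1).
With `stimulus=0.0` the score is identically zero for every seed — no
stimulus, no activation, no cytokine, no injury.

A full condition grid (stimuli × presets × replicates) with archived
intermediates:

```bash
inflamnet experiment --out archive/ --stimuli 0,0.2,0.4 --presets N,A2 \
    --replicates 5 --grid 60 --iterations 500 --seed 0
inflamnet report archive/
```

Other verbs: `simulate`, `angles`, `te`, `network` (each consumes the
previous stage's CSV output; run `inflamnet --help`).

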