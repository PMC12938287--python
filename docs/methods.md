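# Methods

`inflamnet` couples a grid-based stochastic model of acute inflammation and
inflammaging to an information-theoretic analysis of the migration of the
model's motile cells. This note records the model, its parameters, the
estimators, the numerical conventions, and — importantly — what the
implementation's default operating regime does and does not show.

## 1. The agent-based model

The tissue is a 2-D lattice (default 100×100 sites; all analyses in the test
and acceptance suites use 60×60 with 500 iterations, chosen so a full
replicated condition grid runs in minutes on one CPU). Four agent classes
interact:

* **Epithelial cells** occupy every lattice site, in state alive (1) or dead
  (0). The count of dead sites at an iteration is the *inflammation score*.
* **Motile cells** — 20 macrophages and 20 fibroblasts — perform biased
  random walks (velocity 3 single-site Moore sub-steps per iteration, with
  collision avoidance). Each lives 20 iterations; expired cells are replaced
  with fresh, unactivated cells at random free sites every 5 iterations. A
  population *slot* persists across these lifetimes; its track is segmented
  so that analyses never bridge two different cells.
* **Cytokines** — one pro-inflammatory species (TNF) and one
  anti-inflammatory species (TGF) — live on the same lattice and evolve by
  `dφ/dt = D ∇²φ − K φ` with D_TNF = 0.07, D_TGF = 0.10, K_TNF = 1e−3,
  K_TGF = 1e−5 (lattice units, per iteration).
* **Mechanical stimulus** S ∈ [0, 1] seeds the process: at iteration 0 each
  macrophage activates with probability S.

Per iteration, agents are updated one at a time in a fresh random
permutation (an asynchronous-update convention):

1. An unactivated macrophage activates with probability min(1, local TNF),
   where "local" for activation means the maximum over the 3×3 Moore block —
   activation is biased toward cytokine-rich neighbourhoods. An unactivated
   fibroblast activates the same way. Activation of a fibroblast immobilises
   it (it settles at the injury site) and cuts its remaining lifespan to
   25%; macrophages stay mobile.
2. An activated macrophage deposits +1 TNF at its site iff a draw
   u ~ Beta(α₃, β₃) satisfies u ≥ TGF at its site (TGF inhibits TNF
   synthesis). An activated fibroblast deposits +1 TGF iff
   u ~ Beta(α₄, β₄) ≤ TNF at its site (TNF promotes TGF synthesis). Gate
   comparisons use the cell's own site; only activation and the epithelial
   rules look at the Moore neighbourhood.
3. Mobile cells take 3 Moore sub-steps, sampling the own-site-plus-free-
   neighbours candidate set with probability ∝ exp(concentration/T), T = 1
   (macrophages read the TNF field, fibroblasts the TGF field). On a flat
   field this degenerates exactly to a uniform random walk.

After the agent sweep the epithelium updates (vectorised):
(a) alive sites whose Moore-max TNF exceeds the apoptosis threshold die;
(b) dead sites exposed to TGF accumulate a healing clock; once it reaches
the healing time t_h they regrow with the mitosis probability P_mt per
iteration, seeding one fibrosis site (counter K_c) at a random Moore
neighbour; (c) alive sites die with probability N_c/9, where N_c counts
fibrosis sites in their 3×3 block; fibrosis counters then decrement.
Finally both fields advance one explicit-Euler step and the populations age
and repopulate.

Identical parameters and seed give bit-identical results.

### Aging presets

| parameter | N | A1 | A2 |
|---|---|---|---|
| TNF synthesis gate (α₃, β₃) | (1.0, 3.0) | (1.2, 2.5) | (1.5, 2.0) |
| TGF synthesis gate (α₄, β₄) | (2.0, 1.0) | (2.0, 1.0) | (2.0, 1.0) |
| apoptosis threshold | 0.8 | 0.6 | 0.4 |
| mitosis probability P_mt | 0.20 | 0.16 | 0.10 |
| healing time t_h (iter) | 5 | 6 | 8 |
| fibrosis duration K_c (iter) | 50 | 75 | 100 |

The presets are totally ordered in severity: aging raises the α/β ratio of
the TNF gate (synthesis encouraged), lowers the apoptosis threshold, slows
regrowth and prolongs fibrosis.

### Numerical conventions

* Explicit forward Euler, Δx = Δt = 1, 5-point Laplacian; stability demands
  D ≤ 1/4 and is validated at construction. Boundaries are no-flux
  (edge-replicated ghost cells), so diffusion alone conserves total mass —
  a property the test suite checks. Decay is applied after the diffusion
  half-update; the ordering is a convention with O(D·K) effect.
* Deposits are additive (+1 per synthesis event); concentrations are
  dimensionless model units and unbounded above.
* A fully enclosed motile cell stays put (not an error). Two cells never
  share a site.
* Healing combines t_h (required accumulated TGF exposure) with P_mt
  (per-iteration regrowth probability once the clock has elapsed); "TGF
  present" means Moore-max TGF > 0, with no threshold.
* N_c/9 reads the collagen-damage probability as the fibrosis count in the
  3×3 block over its size, so it is a proper probability.

## 2. Turning angles and information estimators

The observable used for inference is the *turning angle*: for a cell with
per-iteration positions P^t, the signed angle from the displacement ending
at t−1 to the displacement ending at t, mapped to [0, 2π) via the
cross-product sign (arccos alone would fold the domain to [0, π]).
Resting steps (zero displacement) yield undefined angles and are skipped;
angles are never formed across lifetime-segment boundaries. Angles are
discretised into 20 equal bins (width π/10); 15- and 25-bin variants are
exposed for sensitivity analysis.

All estimators are plain plug-in (histogram) quantities in bits, with no
bias correction:

* Shannon entropy of the macrophage configuration: block-occupancy
  fractions over 10×10-site blocks (a coarse spatial-order diagnostic).
* I(X;Y) = H(X) + H(Y) − H(X,Y).
* I(X;Y|Z) = H(X,Z) + H(Y,Z) − H(X,Y,Z) − H(Z).
* Transfer entropy T(Y→X) = I(X_t ; Y_{t−1} | X_{t−1}) over
  (X_t, X_{t−1}, Y_{t−1}) triples.

The pipeline's macrophage→fibroblast quantity uses the macrophage series as
source and the fibroblast series as target: it measures how much a
macrophage's past direction reduces uncertainty about a fibroblast's next
direction beyond the fibroblast's own past. Both directions are computable
by swapping arguments; the direction is always explicit in the API because
the two readings differ and neither is privileged mathematically.

Pairs with fewer than 50 triples (after aligning on common iterations and
respecting segment boundaries) are reported *missing* (NaN), not zero.
Missing entries contribute neither to the edge criterion nor to edges.

## 3. Transfer-entropy networks

Per condition (stimulus × preset), the defined TE entries of all replicates
are pooled and their first and third quartiles (linear-interpolation
convention) form the edge criterion; the histogram mode (tallest of 20 bins)
is reported as a diagnostic. Each replicate then yields an undirected
bipartite graph: an edge (m, f) iff Q1 ≤ T(m→f) ≤ Q3, all 40 slots present
as nodes. Normalised shortest-path betweenness (divisor (n−1)(n−2)/2) is
computed per node and summed per part; the F/M ratio (fibroblast sum over
macrophage sum) summarises which cell type carries the network's shortest
paths. An edgeless network has F/M undefined (NaN). Condition summaries
report the replicate mean F/M and its standard error (sample sd/√n).

## 4. What the simulator emulates — and its operating regime

The generator emulates the *study conditions*: the preset constants above,
S ∈ {0, 0.2, 0.4, 0.8}, three presets, replicated seeds. It does not model
monocyte recruitment, senescent cells/SASP, M1/M2 phenotypes, ECM
mechanics, age-dependent motility, or dose-dependent secretion; populations
are constant by design so that information-exchange effects are not
confounded with abundance effects.

Two regime facts matter for interpreting any downstream statistic, and both
are measurable with the package itself:

* **Cytokine saturation.** With 20 macrophages depositing ~1 unit/iteration
  and K_TNF = 1e−3, total TNF grows far faster than it decays on any grid
  of order 10⁴ sites: by iteration ~300 of a stimulated 60×60 run the mean
  TNF exceeds every apoptosis threshold, the epithelium dies essentially
  grid-wide under all presets, and the field becomes nearly uniform. A
  near-uniform field has no usable gradients, so late-run migration is
  effectively an unbiased random walk and fibroblasts activate (and
  immobilise) almost immediately everywhere. Preset differences therefore
  live mostly in the early transient at this scale; the inflammation-score
  ordering across presets and full recovery under N are not resolved at the
  default run length.
* **Plug-in bias.** A 20-bin angle alphabet puts TE triples in a 20³ = 8000
  cell table, while a stimulated 500-iteration run yields only ~100–500
  triples per pair. In this regime the plug-in TE is dominated by its
  positive small-sample bias, which scales inversely with the triple count;
  pairwise TE values therefore track sample counts (and the target's angle
  entropy) more than genuine coupling, and rank stability across bin counts
  is limited. Consumers who need bias-robust estimates should lengthen runs
  (triples scale linearly with iterations) or reduce the alphabet; both are
  plain function arguments.

Passing tests consequently demonstrate: the causal chain S=0 ⇒ no
activation ⇒ no cytokine ⇒ zero injury for every seed; exact determinism;
exact agreement of all information estimators with brute-force joint-table
summation; exact field-solver closed forms; and exact betweenness against
path enumeration. They do not demonstrate that the desk-scale network
topology separates aging presets — in this regime it measurably does not —
nor anything about real (non-synthetic) cell-tracking data.

## 5. Open design choices

* Chemotactic bias law: softmax over candidate-site concentrations,
  temperature 1 (configurable); degenerates to uniform on flat fields.
* Velocity 3 as three single-site sub-steps (collision-checked), not a
  3-site jump.
* Activation probability min(1, neighbourhood-max concentration).
* Repopulated cells inherit the slot index but start a new track segment;
  TE triples pool across segments without bridging them.
* Logarithm base 2 throughout (bits).
* Quartiles by linear interpolation; undirected edges despite TE's
  directionality, because ordinary betweenness on the bipartite graph is
  the intended summary.

## 6. Sizes used by the shipped analyses

Unit tests use 25×25–40×40 grids and 60–250 iterations; the acceptance
suites use 60×60 grids, 500 iterations and 5 replicates per condition
(~2 minutes per full condition grid on one CPU). These sizes are the
package's declared desk scale; every size is a constructor argument.
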