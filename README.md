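# trophoshift

Inference and description of multivariate diet-niche evolution on
time-calibrated phylogenies.

Comparative datasets on diets (and many other ecological traits) arrive as
*primary natural-history observations*: per-species counts of prey records
over a set of prey categories, with sample sizes that span orders of
magnitude and tables that are strongly zero inflated.  `trophoshift` treats
the diet of every species as a latent multinomial distribution — a point
**x** on the (J−1)-simplex over J prey categories — and models the evolution
of these "niche states" along a phylogeny, so that poorly sampled species
borrow strength from well-sampled relatives and ancestral diets come with
honest uncertainty.  It is aimed at researchers in phylogenetic comparative
methods who want to reconstruct, quantify, and visualize the tempo and mode
of multivariate ecological change.

## The model

* Every node of the tree (tip and ancestor) occupies one of at most *K*
  latent states; each state is a multinomial vector over the J categories.
* States change along branches under a symmetric Markov jump process with a
  tree-wide event rate; each jump draws a new state uniformly among the
  other K−1, so the stay probability over a branch of length *t* is
  `1/K + (1 − 1/K)·exp(−λtK/(K−1))`.  Large K makes every change expensive
  and favors parsimonious histories.
* State vectors carry a symmetric Dirichlet(α) prior and are integrated out:
  tips sharing a state pool their counts through the Dirichlet-multinomial
  marginal.  A collapsed Gibbs sampler (node-wise updates, Metropolis step
  for the rate) returns a posterior over node-state assignments,
  per-state utilization vectors, and the event rate.

Downstream of the fit:

* **Evolutionary flux** — change between an ancestor's and descendant's
  vectors is the optimal transport plan *U* between them (rows sum to the
  ancestral vector, columns to the descendant's) under a 0/1 cost; the
  off-diagonal mass `Σ_jk U_jk (1 − I_jk)` counts the effective number of
  per-category gains and losses.  Plans are weighted by exact branch
  endpoint probabilities `w_qr = P(child = r | parent = q, D) P(parent = q | D)`
  and averaged over the posterior.  Clade rates divide a clade's total flux
  by its total branch length; tip rates are age-weighted path averages
  (weights `age^w`, default w = 1) that regularize toward the tree-wide rate.
* **Ecospace expansion** — among-lineage diet breadth `Σ_j D_j`, where `D_j`
  is the range of utilization of category j across all lineages at least as
  old as a focal node, traced through time and compared against a
  permutation null that relabels state vectors while holding the marginal
  ancestral state probabilities fixed (99 permutations per posterior sample).
* **Diet-through-time profiles**, per-lineage breadth (effective number of
  prey categories), gain/loss matrices, Moran's I phylogenetic clustering,
  additive color mixing for tree painting, and trophic-network export.

A fully seeded synthetic-data generator (`trophoshift.synth`) produces
ultrametric birth-death trees, jump-process state histories, sparse state
vectors, and realistic sample-size laws (lognormal, median ≈ 12 records per
species) together with ground truth for recovery scoring.

## Worked example

```python
import numpy as np
import trophoshift as ts

scenario = ts.SimScenario(n_tips=30, J=5, K_true=3, seed=7,
                          sample_size=("fixed", 200))
truth = ts.simulate(scenario)

config = ts.ModelConfig(K=8, iterations=600, thin=5, burnin=40, seed=8)
chain = ts.gibbs_sample(truth.tree, truth.counts, config)

report = ts.recovery_metrics(truth, chain)
flux, _ = ts.tree_fluxes(truth.tree, chain.posterior)
per_branch = {c: ts.branch_total_flux(U) for c, U in flux.items()}
rates = ts.clade_rates(truth.tree, per_branch)
res = ts.permutation_test(truth.tree, ts.select_top_samples(chain, 50),
                          n_perm=99, seed=9)
```

Output of the accompanying print statements:

```
tree height: 100.0 Myr; total records: 6000
recorded samples: 120 | post-burn-in: 80
modal number of realized diet states: 3
tip-partition ARI: 1.000 | mean L1 on state vectors: 0.037
whole-tree rate of prey switching: 0.0020 flux / Myr
largest gain/loss entry: cat1 -> cat3 (0.56 transitions)
mean P (nodes older than half the root age): 0.914
```

The sampler recovers the three simulated diet states exactly (adjusted Rand
index 1.0) with a mean L1 error of 0.037 on the utilization vectors; the
whole-tree rate says that about 0.2% of the diet turns over per lineage per
Myr; and the permutation P-values near 1 show that, for data simulated under
the homogeneous jump process, observed ecospace expansion is entirely
compatible with the null — as it should be.

The same pipeline is available from the shell:

```sh
trophoshift simulate --tips 200 --j 10 --ktrue 4 --seed 1 --out sim/
trophoshift fit --tree sim/tree.nwk --counts sim/counts.csv \
    --k 50 --iters 30000 --thin 10 --burnin 500 --seed 1 --out fit/
trophoshift flux --fit fit/ --out flux/
trophoshift rates --fit fit/ --flux flux/ --w 1 --out rates/
trophoshift dtt --fit fit/ --out dtt/
trophoshift permtest --fit fit/ --nperm 99 --top 500 --out perm/
```

## Documentation

`docs/methods.md` describes the model, its assumptions, the numerical
choices, what the synthetic generator does and does not emulate, and known
limitations.
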