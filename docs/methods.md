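# Methods

## Model

Let a phylogeny have branch lengths in time units (Myr throughout) and let
each species' diet be summarized by counts over J prey categories.  The
model assumes:

1. Every node *u* (tip or ancestor) carries a latent niche state: a
   multinomial vector x̂(u) on the (J−1)-simplex.  At most K distinct
   vectors exist on the tree; ancestral states must be among the states
   present at the tips (plus, with small prior probability, states realized
   nowhere).
2. States evolve by a symmetric Markov jump process: changes occur along
   branches as a Poisson process with tree-wide rate λ (events per Myr), and
   each event replaces the current state with one of the other K−1 states
   uniformly.  The resulting transition kernel over a branch of length t has
   stay probability `1/K + (1 − 1/K)·exp(−λ t K/(K−1))` and equal
   off-diagonal entries.  The root state is uniform over the K states.
3. Observed per-species counts are multinomial samples from the tip's state.
   State vectors carry a symmetric Dirichlet(α) prior and are integrated
   out, so all tips assigned to one state pool their counts through the
   Dirichlet-multinomial marginal
   `Γ(Jα)/Γ(Jα+N) · Π_j Γ(α+n_j)/Γ(α)`
   (the multinomial coefficient is constant in the assignments and omitted;
   absolute log joints are therefore comparable within, not across,
   datasets).

The role of K deserves emphasis: it is an upper bound, not an estimate.  The
number of realized states is inferred, and a large K strengthens the
penalty per change event (each specific alternative state has prior
transition probability ∝ 1/K), favoring parsimonious histories.

## Inference

A collapsed Gibbs sampler sweeps over nodes in random order.  A tip's full
conditional multiplies the transition probability on its parent branch by
the change in pooled Dirichlet-multinomial marginals from moving its counts
between state pools; an internal node's conditional involves only its
adjacent branches.  Unoccupied states are exchangeable, so their likelihood
term is computed once per update.  The event rate is updated once per sweep
by a Metropolis step with a lognormal random-walk proposal (step 0.6 on the
log scale) under an exponential prior whose mean defaults to one expected
change over the whole tree (rate 1/total branch length); the rate can also
be fixed.  Node-wise blocking was chosen over subtree blocking for
simplicity; correctness is established against brute-force enumeration on
small trees (co-assignment probabilities, since raw labels are exchangeable)
rather than against any external sampler.

Recorded samples store the assignment, a Dirichlet(α + pooled counts) draw
of each realized state's vector, the rate, and the log joint.  Defaults
follow common practice for this model class: α = 1, 30,000 sweeps, every
10th recorded, first 500 recorded samples discarded as burn-in; all
experiments in the test suite use smaller, stated sizes.

### Ancestral marginals and branch endpoint joints

Within one posterior sample, marginal ancestral state probabilities
P(x̂(u) = q | tip states, λ) are computed exactly by the sum-product
(pruning) algorithm.  The K − m states not realized at the tips are lumped
into one aggregate state; the symmetric kernel is exactly lumpable for this
partition, so the computation is exact at any K (including K = 1,000) at
cost O(n·m²).  The same recursion yields the exact per-branch endpoint
joint P(parent = q, child = r | D).  These joints weight the flux matrices
directly — an analytic replacement for estimating endpoint frequencies by
Monte Carlo stochastic mapping, which would add simulation noise at
identical conditioning.  Full stochastic-map realizations (used for
branch-slice diet-through-time profiles) are drawn exactly: the number of
jumps on a branch conditional on its endpoints follows the endpoint-tilted
Poisson law of the uniformized jump chain, whose n-step endpoint
probabilities have a closed form; intermediate states are then sampled
sequentially and jump times are order statistics of uniforms.

## Evolutionary flux and rates

Between two states the transport plan U minimizes Σ C_jk U_jk subject to
row sums x̂(u) and column sums x̂(v).  The cost matrix is 0 on the diagonal
and 1 off it, making the minimum cost equal to the total-variation distance
`1 − Σ_j min(x̂_j(u), x̂_j(v))` and the off-diagonal entries of U
interpretable as fractional per-category gains and losses.  Plans are
computed by log-domain Sinkhorn iteration with the regularization annealed
0.1 → 10⁻³ (warm-started potentials, per-stage marginal tolerance 10⁻⁸,
per-stage cap 12,000 iterations with converged problems dropped from the
batch), then projected onto the exact marginals.  On random simplex pairs
the resulting cost is within 10⁻⁴ of the linear-programming optimum, which
is kept as an exact backend (`method="lp"`) and as the test oracle.  With
0/1 cost and more than one surplus/deficit category the optimal plan is not
unique; the entropic solution is reported, and all headline statistics
(cost, total flux, per-category gains/losses) are plan-independent.

Per branch, `U_w = Σ_qr w_qr U^(q,r) / Σ_qr w_qr` with w the exact endpoint
joints; same-state pairs contribute diagonal plans.  U_w is averaged over
post-burn-in (optionally top-m) samples.  A clade's rate is the summed flux
of the branches descended from its root divided by their summed length.  A
tip's rate is the weighted mean of the clade rates of its ancestors with
weights `(node age)^w`, default w = 1: older clades weigh more, pulling
volatile tip rates toward the tree-wide average.  Age was chosen as the
weight covariate because it is the natural monotone quantity on the
root path; w = 0 recovers the unweighted path mean and larger w strengthens
the regularization (verified as a monotone property in the tests).

## Breadth, diet-through-time, permutation null

Per-lineage breadth defaults to the effective number of categories
exp(Shannon entropy) (1 = pure specialist, J = uniform); inverse Simpson
and a ≥5%-utilization category count are selectable.  Among-lineage breadth
of a node set is `Σ_j (max_j − min_j)` of the nodes' expected utilization
vectors (marginal-probability-weighted mixtures of state vectors).  Breadth
and diet-through-time curves are evaluated at inclusive age thresholds —
each internal node's age, ties grouped — from the root (where the node-mode
profile is a point mass on the root state) to the present.

The permutation null holds every node's marginal state probabilities fixed
and uniformly relabels the model-estimated vectors among the realized
states; 99 permutations per sample, top 500 samples by default.  Per node,
P is the proportion of permutations with breadth at least the observed
(observed not added to the denominator; an (r+1)/(n+1) convention is
available).  P-values are averaged arithmetically across samples and the
per-sample matrix is also returned, so either aggregate-then-threshold or
threshold-then-aggregate summaries can be formed; the envelope pools all
permuted curves.  Because the breadth at a threshold depends on the *set*
of states present, permutations often tie with the observed arrangement and
the test is conservative where all states are already present — calibration
tests therefore check the false-positive rate as an upper bound (≤ 5% plus
three binomial standard errors under the shuffled-vector null) rather than
exact uniformity.

Moran's I uses inverse patristic distance weights, row-normalized with zero
diagonal (the weighting is unspecified in most applications; this choice is
the common default for tree-structured autocorrelation), and requires ≥ 3
tips and non-constant values.

## Synthetic data

The generator emulates the statistical shape of large compiled diet
datasets: ultrametric birth-death trees (dendropy's sampler, run forward to
the next event after the last speciation so no zero-length cherry remains,
then rescaled to a 100-Myr height); jump-process state histories at a rate
defaulting to about six expected events per tree; sparse state vectors
(symmetric Dirichlet, concentration 0.2, drawn subject to a minimum
pairwise total-variation separation of 0.5 so "distinct states" are
meaningfully distinct); and per-species sample sizes from a discretized
lognormal (median ≈ 12, about 1% of species at 500+ records) or a fixed
constant for large-N recovery experiments, where 1,000 records per tip is
used as the informative regime.  Desk-scale defaults are 200 tips, J = 10,
4 true states.

What the generator does **not** emulate: intraspecific (ontogenetic,
sexual, geographic) diet structure, trait-dependent diversification,
correlated prey co-occurrence within diets beyond what sparse Dirichlet
vectors induce, and category-specific detectability of prey records.
Passing recovery tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to these
real-data features.

Recovery is scored by (i) the adjusted Rand index between true and modal
inferred tip partitions, (ii) the mean L1 distance between true state
vectors and matched inferred cluster means under an optimal label pairing
(Hungarian algorithm; cluster means are averaged over tips and samples, so
they are stable under label switching), and (iii) coverage of true vector
entries by central 95% posterior intervals.

## Numerical choices and degenerate inputs

* All likelihood math is in log space; Dirichlet-multinomial terms use
  log-gamma; pruning messages are rescaled per node.
* Ultrametricity: a relative tip-depth spread ≤ 10⁻⁶ of tree height passes
  silently, larger spreads warn, and age-based analyses refuse trees beyond
  10⁻³ (published time trees carry rounding noise; anything larger is a
  data problem).
* Zero-length branches are hard constraints (stay probability 1) and are
  handled explicitly in the Gibbs conditionals.
* Polytomies are accepted and treated as hard.
* Modal-state ties break toward the lowest state index; top-sample ties
  break toward the earlier sample.
* Empty species rows are dropped with a log notice; unmappable prey taxa
  are collected and reported, never silently discarded.
* The permutation test degenerates with fewer than two realized states and
  returns P ≡ 1 with a warning.

## Limitations

* A single tree-wide event rate: rate variation among clades is recovered
  descriptively through clade/tip rates, not modeled generatively.
* The scalar Dirichlet hyperparameter applies one α to all categories.
* Pooled-mode marginals across samples are reported but state labels are
  only identified within samples; cross-sample summaries should use
  label-invariant quantities (as the tests do).
* The entropic transport plan is reported where the optimal plan is
  non-unique; only plan-independent statistics should be interpreted
  per-category.
* Desk-scale problem sizes are used throughout the test suite (stated in
  each test); the paper-scale regime (hundreds of tips, K in the hundreds)
  is supported by the same code paths via the lumped-state pruning and
  pooled-likelihood optimizations.
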