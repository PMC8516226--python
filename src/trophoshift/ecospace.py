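"""Diet-breadth summaries and the tempo of ecospace expansion.

Two breadth notions are used.  Per-lineage breadth is a diversity of one
utilization vector (default: the effective number of prey categories,
exp(Shannon entropy); 1 for a pure specialist, J for a uniform diet).
Among-lineage breadth of a set of lineages is ``sum_j D_j`` where D_j is the
range (max - min) of proportional utilization of category j across the set
-- a measure of occupied dietary ecospace.  Evaluated over the sets of nodes
at least as old as each internal node, it traces ecospace expansion through
time; age thresholds are inclusive, with exactly-tied ages grouped.

The permutation null holds each sample's marginal ancestral state
probabilities fixed but randomly relabels the model-estimated utilization
vectors among the realized states (phylogenetic signal preserved; ecological
opportunity random with respect to time and phylogeny).  Per node, the
P-value is the proportion of permutations whose among-lineage breadth is at
least the observed one (the observed curve is not added to the denominator;
an add-one convention is available).

Moran's I quantifies phylogenetic clustering of a per-tip scalar (e.g., the
proportion of one prey category in the sampled diet) with inverse patristic
distance weights, row-normalized, zero diagonal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dmm import (MarginalStateProbs, PosteriorSample, node_marginals,
                  StochasticMapRealization)
from .treedata import Phylogeny

__all__ = [
    "per_lineage_breadth", "among_lineage_breadth", "BreadthCurve",
    "breadth_curve", "DTTProfile", "dtt_profile", "PermutationResult",
    "permutation_test", "morans_i", "expected_node_vectors",
]


# ---------------------------------------------------------------------------
# Breadth metrics
# ---------------------------------------------------------------------------

def per_lineage_breadth(state, metric: str = "hill-shannon") -> float:
    """Diet breadth of a single utilization vector.

    Metrics: ``hill-shannon`` (exp of Shannon entropy, the default),
    ``inverse-simpson`` (1 / sum p^2), ``count`` (number of categories with
    at least 5% utilization).
    """
    x = np.asarray(state, dtype=float)
    if np.any(x < -1e-12) or abs(x.sum() - 1.0) > 1e-6:
        raise ValueError("state must lie on the simplex")
    x = np.clip(x, 0.0, None)
    if metric == "hill-shannon":
        nz = x[x > 0]
        return float(np.exp(-np.sum(nz * np.log(nz))))
    if metric == "inverse-simpson":
        return float(1.0 / np.sum(x ** 2))
    if metric == "count":
        return float(np.sum(x >= 0.05))
    raise ValueError(f"unknown metric {metric!r}")


def among_lineage_breadth(states: np.ndarray) -> float:
    """Total among-lineage breadth sum_j (max_j - min_j) over a set of vectors."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.size == 0:
        raise ValueError("empty node set")
    return float((states.max(axis=0) - states.min(axis=0)).sum())


def expected_node_vectors(marginals: MarginalStateProbs,
                          vectors: np.ndarray) -> np.ndarray:
    """Marginal-probability-weighted mixture vector for every node.

    ``vectors`` rows follow ``marginals.labels`` (+ the aggregate state last
    when present).
    """
    if vectors.shape[0] != marginals.n_states:
        raise ValueError("vector rows must match marginal states")
    return marginals.probs @ vectors


@dataclass
class BreadthCurve:
    """Among-lineage breadth at inclusive age thresholds (old -> young)."""

    ages: np.ndarray
    breadth: np.ndarray
    mean_per_lineage: np.ndarray | None = None
    min_per_lineage: np.ndarray | None = None
    max_per_lineage: np.ndarray | None = None


def _threshold_grid(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique internal-node ages (desc) and node order old -> young."""
    ages = tree.node_ages()
    internal = np.array([v for v in range(tree.n_nodes) if not tree.is_tip(v)])
    thresholds = np.unique(np.round(ages[internal], 12))[::-1]
    order = np.argsort(-ages)  # all nodes, oldest first
    return thresholds, ages, order


def _breadth_at_thresholds(thresholds: np.ndarray, ages: np.ndarray,
                           order: np.ndarray, vectors: np.ndarray,
                           ) -> np.ndarray:
    """Incremental sum_j (max-min) as the inclusive age threshold decreases."""
    J = vectors.shape[1]
    cur_max = np.full(J, -np.inf)
    cur_min = np.full(J, np.inf)
    out = np.empty(thresholds.size)
    i = 0
    n = order.size
    for k, thr in enumerate(thresholds):
        while i < n and ages[order[i]] >= thr - 1e-12:
            v = vectors[order[i]]
            np.maximum(cur_max, v, out=cur_max)
            np.minimum(cur_min, v, out=cur_min)
            i += 1
        out[k] = (cur_max - cur_min).sum()
    return out


def breadth_curve(tree: Phylogeny, node_vectors: np.ndarray,
                  metric: str = "hill-shannon") -> BreadthCurve:
    """Observed among-lineage breadth curve plus per-lineage summaries.

    ``node_vectors`` is (n_nodes, J): an expected utilization vector per node
    (see :func:`expected_node_vectors`).
    """
    thresholds, ages, order = _threshold_grid(tree)
    breadth = _breadth_at_thresholds(thresholds, ages, order, node_vectors)
    pl = np.array([per_lineage_breadth(v, metric) for v in node_vectors])
    mean_pl = np.empty(thresholds.size)
    min_pl = np.empty(thresholds.size)
    max_pl = np.empty(thresholds.size)
    i = 0
    vals: list[float] = []
    for k, thr in enumerate(thresholds):
        while i < order.size and ages[order[i]] >= thr - 1e-12:
            vals.append(pl[order[i]])
            i += 1
        arr = np.array(vals)
        mean_pl[k], min_pl[k], max_pl[k] = arr.mean(), arr.min(), arr.max()
    return BreadthCurve(ages=thresholds, breadth=breadth,
                        mean_per_lineage=mean_pl, min_per_lineage=min_pl,
                        max_per_lineage=max_pl)


# ---------------------------------------------------------------------------
# Diet-through-time profiles
# ---------------------------------------------------------------------------

@dataclass
class DTTProfile:
    """Proportional representation of diet states at successive time slices."""

    slices: np.ndarray
    labels: list[int]
    proportions: np.ndarray  # (n_slices, n_labels), rows sum to 1


def dtt_profile(tree: Phylogeny, sample: PosteriorSample,
                realization: StochasticMapRealization | None = None,
                slices: np.ndarray | None = None,
                mode: str = "nodes") -> DTTProfile:
    """Diet-through-time profile for one posterior sample.

    ``mode="nodes"``: at each internal-node age threshold, the state
    frequencies among all nodes at least that old (the sample's assignment
    supplies node states).  ``mode="branches"``: at each time slice, the
    states of the lineages crossing that slice under a stochastic-map
    realization (required for this mode).
    """
    z = sample.assignment
    ages = tree.node_ages()
    labels = sorted(int(s) for s in np.unique(z))
    col = {lab: i for i, lab in enumerate(labels)}
    if mode == "nodes":
        thresholds, ages, order = _threshold_grid(tree)
        if slices is not None:
            thresholds = np.asarray(slices, dtype=float)
            if not np.any(ages.max() >= thresholds):
                raise ValueError("no nodes as old as the oldest slice")
        props = np.zeros((thresholds.size, len(labels)))
        for k, thr in enumerate(thresholds):
            sel = ages >= thr - 1e-12
            if not sel.any():
                raise ValueError("no nodes as old as the oldest slice")
            for v in np.flatnonzero(sel):
                props[k, col[int(z[v])]] += 1.0
        props /= props.sum(axis=1, keepdims=True)
        return DTTProfile(slices=thresholds, labels=labels, proportions=props)
    if mode == "branches":
        if realization is None:
            raise ValueError("branch mode needs a stochastic-map realization")
        if slices is None:
            root_age = ages.max()
            slices = np.linspace(root_age, 0.0, 50)
        slices = np.asarray(slices, dtype=float)
        props = np.zeros((slices.size, len(labels)))
        for k, a in enumerate(slices):
            found = False
            for c in range(tree.n_nodes):
                if c == tree.root:
                    continue
                top = ages[tree.parent[c]]
                bot = ages[c]
                # lineage crosses age a if parent is older and child not older
                if not (top > a >= bot or (a == 0 and bot == 0)):
                    continue
                state = int(z[tree.parent[c]])
                for t_off, new_state in realization.events.get(c, []):
                    if top - t_off > a:
                        state = int(new_state)
                    else:
                        break
                props[k, col[state]] += 1.0
                found = True
            if not found and a >= ages.max() - 1e-12:
                props[k, col[int(z[tree.root])]] = 1.0
                found = True
            if not found:
                raise ValueError(f"no lineages cross time slice {a}")
        props /= props.sum(axis=1, keepdims=True)
        return DTTProfile(slices=slices, labels=labels, proportions=props)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Permutation null for ecospace expansion
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Observed breadth curve against the shuffled-vector null.

    ``p`` averages the per-sample P-values arithmetically across samples;
    ``p_per_sample`` keeps them separate (values lie on the lattice
    ``{0, 1/n_perm, ..., 1}``).  The envelope pools all permuted curves.
    """

    ages: np.ndarray
    observed: np.ndarray           # cross-sample mean observed breadth
    null_mean: np.ndarray
    null_min: np.ndarray
    null_max: np.ndarray
    ratio: np.ndarray              # observed / null mean
    p: np.ndarray
    p_per_sample: np.ndarray       # (n_samples, n_thresholds)


def _marginals_and_vectors(tree: Phylogeny, sample: PosteriorSample,
                           marginal_mode: str):
    if marginal_mode == "pruning":
        marg = node_marginals(tree, sample)
        vecs = [sample.state_vectors[lab] for lab in marg.labels]
        if marg.has_other:
            vecs.append(sample.other_vector)
        return marg.probs, np.stack(vecs), len(marg.labels)
    if marginal_mode == "indicator":
        labels = sorted(int(s) for s in np.unique(sample.assignment))
        col = {lab: i for i, lab in enumerate(labels)}
        probs = np.zeros((tree.n_nodes, len(labels)))
        for v in range(tree.n_nodes):
            probs[v, col[int(sample.assignment[v])]] = 1.0
        vecs = np.stack([sample.state_vectors[lab] for lab in labels])
        return probs, vecs, len(labels)
    raise ValueError(f"unknown marginal mode {marginal_mode!r}")


def permutation_test(tree: Phylogeny, samples: list[PosteriorSample],
                     n_perm: int = 99, seed: int = 0,
                     marginal_mode: str = "pruning",
                     p_convention: str = "plain") -> PermutationResult:
    """Ecospace-expansion permutation test over a set of posterior samples.

    For each sample the marginal ancestral state probabilities stay fixed
    while the realized states' utilization vectors are uniformly relabeled
    among themselves (``n_perm`` times, default 99); per age threshold the
    P-value is the proportion of permutations whose among-lineage breadth is
    at least the observed one.  ``p_convention="add-one"`` uses
    (r + 1) / (n_perm + 1) instead.  With fewer than 2 realized states the
    permutation is degenerate and P = 1 is returned with a warning.
    """
    if not samples:
        raise ValueError("no posterior samples")
    rng = np.random.default_rng(seed)
    thresholds, ages, order = _threshold_grid(tree)
    n_thr = thresholds.size
    obs = np.zeros((len(samples), n_thr))
    p_per = np.zeros((len(samples), n_thr))
    null_curves = []
    for i, sample in enumerate(samples):
        probs, vectors, n_real = _marginals_and_vectors(
            tree, sample, marginal_mode)
        node_vecs = probs @ vectors
        obs[i] = _breadth_at_thresholds(thresholds, ages, order, node_vecs)
        if n_real < 2:
            warnings.warn("fewer than 2 realized states: permutation "
                          "degenerate, P = 1", stacklevel=2)
            p_per[i] = 1.0
            null_curves.append(np.tile(obs[i], (n_perm, 1)))
            continue
        exceed = np.zeros(n_thr)
        curves = np.empty((n_perm, n_thr))
        for b in range(n_perm):
            perm = vectors.copy()
            # shuffle vectors among the realized state labels only; the
            # aggregate unrealized state (if present) keeps its vector
            idx = rng.permutation(n_real)
            perm[:n_real] = vectors[idx]
            pv = probs @ perm
            curves[b] = _breadth_at_thresholds(thresholds, ages, order, pv)
            exceed += curves[b] >= obs[i] - 1e-12
        if p_convention == "plain":
            p_per[i] = exceed / n_perm
        elif p_convention == "add-one":
            p_per[i] = (exceed + 1.0) / (n_perm + 1.0)
        else:
            raise ValueError(f"unknown p convention {p_convention!r}")
        null_curves.append(curves)
    null_all = np.concatenate(null_curves, axis=0)
    null_mean = null_all.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(null_mean > 0, obs.mean(axis=0) / null_mean, np.nan)
    return PermutationResult(
        ages=thresholds, observed=obs.mean(axis=0), null_mean=null_mean,
        null_min=null_all.min(axis=0), null_max=null_all.max(axis=0),
        ratio=ratio, p=p_per.mean(axis=0), p_per_sample=p_per)


# ---------------------------------------------------------------------------
# Phylogenetic clustering
# ---------------------------------------------------------------------------

def morans_i(values, tree: Phylogeny | None = None,
             weights: np.ndarray | None = None) -> float:
    """Moran's I of a per-tip scalar with inverse-patristic-distance weights.

    Weights are 1/d(i, j) off the diagonal, row-normalized.  Requires at
    least 3 tips and non-constant values (permutation expectation is
    -1/(n-1)).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 tips")
    if np.allclose(x, x[0]):
        raise ValueError("values have zero variance")
    if weights is None:
        if tree is None:
            raise ValueError("need a tree or a weight matrix")
        D = tree.patristic_matrix()
        with np.errstate(divide="ignore"):
            W = 1.0 / D
        np.fill_diagonal(W, 0.0)
    else:
        W = np.asarray(weights, dtype=float).copy()
        np.fill_diagonal(W, 0.0)
    W = W / W.sum(axis=1, keepdims=True)
    z = x - x.mean()
    s0 = W.sum()
    return float((n / s0) * (z @ W @ z) / (z @ z))
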