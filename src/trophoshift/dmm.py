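"""Dirichlet-multinomial Markov model of latent diet states on a phylogeny.

The model: every node of the tree (tip or ancestor) occupies one of at most K
latent niche states.  A state is a multinomial distribution over the J prey
categories; observed per-species prey counts are samples from the tip's
state.  States change along branches under a symmetric K-state Markov jump
process (jumps at a tree-wide rate; each jump picks a new state uniformly
among the other K-1), so the prior over histories penalizes every state
change -- more strongly for larger K.  Integrating each state's multinomial
vector against a symmetric Dirichlet(alpha) prior leaves a collapsed
Dirichlet-multinomial likelihood in which tips sharing a state pool their
counts.

Inference is a collapsed Gibbs sampler over node-state assignments with a
Metropolis update for the event rate (exponential prior, mean of one expected
change over the whole tree by default).  Per-sample ancestral-state marginals
and branch endpoint joints are computed exactly by the pruning (sum-product)
algorithm on a lumped chain in which the K - m unrealized states collapse to
one aggregate state; the symmetric kernel is exactly lumpable for that
partition.  Full state-change histories along branches are drawn conditional
on branch endpoints by direct sampling of the uniformized jump chain.

All likelihood math is in log space; Dirichlet-multinomial terms use log-gamma.
The multinomial coefficient is omitted throughout (constant in the node
assignments for fixed per-tip counts), so absolute log joint probabilities
are comparable across runs only.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .treedata import Phylogeny, DietCountTable

__all__ = [
    "ModelConfig", "PosteriorSample", "PosteriorChain", "MarginalStateProbs",
    "dm_marginal_loglik", "transition_probability", "joint_logprob",
    "gibbs_sample", "marginal_state_probs", "node_marginals",
    "branch_pair_joints", "select_top_samples", "stochastic_map",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Run configuration for the Gibbs sampler.

    ``iterations`` counts Gibbs sweeps; every ``thin``-th sweep is recorded
    and the first ``burnin`` *recorded* samples are treated as burn-in by
    downstream summaries.  ``rate=None`` samples the event rate (Metropolis
    step each sweep, exponential prior with mean ``rate_prior_mean``,
    defaulting to 1 / total tree length); a float fixes it.
    """

    K: int = 50
    alpha: float = 1.0
    iterations: int = 30000
    thin: int = 10
    burnin: int = 500
    seed: int = 0
    rate: float | None = None
    rate_prior_mean: float | None = None
    mh_step: float = 0.6
    init: str = "single"  # "single" | "random"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (self.iterations >= self.thin >= 1):
            raise ValueError("need iterations >= thin >= 1")
        if self.rate is not None and self.rate < 0:
            raise ValueError("rate must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "K", "alpha", "iterations", "thin", "burnin", "seed",
            "rate", "rate_prior_mean", "mh_step", "init")}


# ---------------------------------------------------------------------------
# Elementary probability pieces
# ---------------------------------------------------------------------------

def dm_marginal_loglik(counts, alpha: float) -> float:
    """Log Dirichlet-multinomial marginal of pooled counts (coefficient omitted).

    With a symmetric Dirichlet(alpha) prior over the J-category multinomial,
    integrating the vector out gives

        log Gamma(J a) - log Gamma(J a + N) + sum_j [log Gamma(a + n_j) - log Gamma(a)]

    An all-zero count vector yields 0 (the empty product).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        return 0.0
    a_tot = c.size * alpha
    return float(gammaln(a_tot) - gammaln(a_tot + total)
                 + np.sum(gammaln(alpha + c)) - c.size * gammaln(alpha))


def _same_diff_probs(rate: float, t, K: int):
    """Stay / per-target-switch probabilities of the symmetric K-state kernel."""
    t = np.asarray(t, dtype=float)
    if K == 1:
        return np.ones_like(t), np.zeros_like(t)
    decay = np.exp(-rate * t * K / (K - 1))
    p_same = 1.0 / K + (1.0 - 1.0 / K) * decay
    p_diff = (1.0 - decay) / K
    return p_same, p_diff


def transition_probability(rate: float, t: float, K: int) -> np.ndarray:
    """K x K transition kernel of the symmetric jump process over time t.

    Stay probability ``1/K + (1 - 1/K) exp(-rate t K/(K-1))``; all
    off-diagonal entries equal.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    p_same, p_diff = _same_diff_probs(rate, t, K)
    P = np.full((K, K), float(p_diff))
    np.fill_diagonal(P, float(p_same))
    return P


def _rate_prior_mean(config: ModelConfig, tree: Phylogeny) -> float:
    if config.rate_prior_mean is not None:
        return config.rate_prior_mean
    return 1.0 / tree.total_length


def _rate_log_prior(rate: float, mean: float) -> float:
    if rate < 0:
        return -np.inf
    return -np.log(mean) - rate / mean


# ---------------------------------------------------------------------------
# Posterior containers
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    """One recorded Gibbs draw.

    ``assignment`` maps every node to a state label in ``0..K-1``;
    ``state_vectors`` holds a posterior Dirichlet draw of the utilization
    vector for every label in use (conditional Dirichlet(alpha + pooled tip
    counts); labels realized only at internal nodes pool nothing and draw
    from the prior).  ``other_vector`` is a prior draw standing for the
    aggregate of unrealized states in marginal computations.
    """

    assignment: np.ndarray
    state_vectors: dict[int, np.ndarray]
    other_vector: np.ndarray
    rate: float
    log_joint: float
    K: int
    n_tips: int | None = None

    @property
    def realized_labels(self) -> list[int]:
        return sorted(self.state_vectors)

    def n_realized(self, tips_only: bool = True) -> int:
        """Distinct states in use; by default among the terminal nodes only."""
        z = self.assignment
        if tips_only and self.n_tips is not None:
            z = z[: self.n_tips]
        return len(np.unique(z))


@dataclass
class PosteriorChain:
    """Ordered recorded samples plus the config echo and likelihood trace."""

    samples: list[PosteriorSample]
    config: ModelConfig
    trace: pd.DataFrame

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def posterior(self) -> list[PosteriorSample]:
        """Post-burn-in samples."""
        return self.samples[self.config.burnin:]

    # -- serialization ------------------------------------------------------
    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)
        with open(os.path.join(outdir, "meta.json"), "w") as fh:
            json.dump({"n_tips": self.samples[0].n_tips}, fh)
        self.trace.to_csv(os.path.join(outdir, "trace.csv"), index=False)
        assign = np.stack([s.assignment for s in self.samples])
        pd.DataFrame(assign).to_csv(
            os.path.join(outdir, "assignments.csv.gz"), index=False)
        rows = []
        for i, s in enumerate(self.samples):
            for lab, vec in s.state_vectors.items():
                rows.append([i, lab, *vec])
            rows.append([i, -1, *s.other_vector])
        J = len(self.samples[0].other_vector)
        pd.DataFrame(rows, columns=["sample", "state", *range(J)]).to_csv(
            os.path.join(outdir, "state_vectors.csv.gz"), index=False)

    @classmethod
    def load(cls, outdir: str) -> "PosteriorChain":
        with open(os.path.join(outdir, "config.json")) as fh:
            config = ModelConfig(**json.load(fh))
        n_tips = None
        meta_path = os.path.join(outdir, "meta.json")
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                n_tips = json.load(fh).get("n_tips")
        trace = pd.read_csv(os.path.join(outdir, "trace.csv"))
        assign = pd.read_csv(
            os.path.join(outdir, "assignments.csv.gz")).to_numpy()
        vec_df = pd.read_csv(os.path.join(outdir, "state_vectors.csv.gz"))
        samples = []
        for i in range(assign.shape[0]):
            sub = vec_df[vec_df["sample"] == i]
            vectors, other = {}, None
            for _, row in sub.iterrows():
                vec = row.iloc[2:].to_numpy(dtype=float)
                if int(row["state"]) == -1:
                    other = vec
                else:
                    vectors[int(row["state"])] = vec
            samples.append(PosteriorSample(
                assignment=assign[i], state_vectors=vectors,
                other_vector=other, rate=float(trace["rate"].iloc[i]),
                log_joint=float(trace["log_joint"].iloc[i]), K=config.K,
                n_tips=n_tips))
        return cls(samples=samples, config=config, trace=trace)


@dataclass
class MarginalStateProbs:
    """Per-node distributions over one sample's realized states.

    ``probs`` has shape (n_nodes, S); column ``s < len(labels)`` is state
    ``labels[s]`` and, if ``has_other``, the final column aggregates all
    unrealized states.
    """

    labels: list[int]
    probs: np.ndarray
    has_other: bool

    @property
    def n_states(self) -> int:
        return self.probs.shape[1]


# ---------------------------------------------------------------------------
# Joint probability
# ---------------------------------------------------------------------------

def _pooled_counts(tree: Phylogeny, counts: np.ndarray, assignment: np.ndarray,
                   K: int) -> np.ndarray:
    pool = np.zeros((K, counts.shape[1]))
    np.add.at(pool, assignment[: tree.n_tips], counts)
    return pool


def joint_logprob(tree: Phylogeny, counts: np.ndarray, sample: PosteriorSample,
                  config: ModelConfig) -> float:
    """Log joint of (assignment, rate, data): CTMC prior x pooled DM terms x rate prior."""
    z = np.asarray(sample.assignment)
    K, alpha = config.K, config.alpha
    p_same, p_diff = _same_diff_probs(sample.rate, tree.blen, K)
    with np.errstate(divide="ignore"):
        log_same, log_diff = np.log(p_same), np.log(p_diff)
    lp = -np.log(K)  # uniform root prior
    nonroot = np.arange(tree.n_nodes) != tree.root
    same = z[nonroot] == z[tree.parent[nonroot]]
    lp += log_same[nonroot][same].sum() + log_diff[nonroot][~same].sum()
    pool = _pooled_counts(tree, counts, z, K)
    for s in np.flatnonzero(pool.sum(axis=1) > 0):
        lp += dm_marginal_loglik(pool[s], alpha)
    lp += _rate_log_prior(sample.rate, _rate_prior_mean(config, tree))
    return float(lp)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _as_count_array(tree: Phylogeny, counts) -> np.ndarray:
    if isinstance(counts, DietCountTable):
        return counts.to_array(tree.tip_labels).astype(float)
    arr = np.asarray(counts, dtype=float)
    if arr.shape[0] != tree.n_tips:
        raise ValueError("count rows must match tree tips")
    return arr


def _categorical(logits: np.ndarray, rng: np.random.Generator) -> int:
    m = logits.max()
    if not np.isfinite(m):
        raise FloatingPointError("non-finite full conditional")
    p = np.exp(logits - m)
    cdf = np.cumsum(p)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))


class _Sampler:
    """Mutable state of one Gibbs run (collapsed, node-wise updates)."""

    def __init__(self, tree: Phylogeny, counts, config: ModelConfig):
        self.tree = tree
        self.config = config
        self.X = _as_count_array(tree, counts)
        if np.any(self.X.sum(axis=1) < 1):
            raise ValueError("every tip needs at least one observation; "
                             "merge_and_prune drops unobserved species")
        self.K = config.K
        self.alpha = config.alpha
        self.J = self.X.shape[1]
        self.rng = np.random.default_rng(config.seed)
        self.prior_mean = _rate_prior_mean(config, tree)
        self.rate = config.rate if config.rate is not None else self.prior_mean
        n = tree.n_nodes
        if config.init == "random":
            self.z = self.rng.integers(0, self.K, size=n)
        else:
            self.z = np.zeros(n, dtype=int)
        self.pool = _pooled_counts(tree, self.X, self.z, self.K)
        self.pool_tot = self.pool.sum(axis=1)
        self.tip_count = np.bincount(self.z[: tree.n_tips], minlength=self.K)
        # adjacency: (branch edge id, neighbor node) per node; edges are keyed
        # by their child node
        self.adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for v in range(n):
            if v != tree.root:
                self.adj[v].append((v, tree.parent[v]))
                self.adj[tree.parent[v]].append((v, v))
        self._nz = [np.flatnonzero(self.X[i]) for i in range(tree.n_tips)]
        self._set_rate(self.rate)

    # -- transition log-probs cached per rate -------------------------------
    def _set_rate(self, rate: float) -> None:
        self.rate = rate
        p_same, p_diff = _same_diff_probs(rate, self.tree.blen, self.K)
        with np.errstate(divide="ignore"):
            self.log_same = np.log(p_same)
            self.log_diff = np.log(p_diff)

    def _prior_logits(self, v: int) -> np.ndarray:
        out = np.zeros(self.K)
        for edge, nb in self.adj[v]:
            ld, ls = self.log_diff[edge], self.log_same[edge]
            if np.isneginf(ld):  # zero-length branch: hard constraint
                mask = np.full(self.K, -np.inf)
                mask[self.z[nb]] = ls
                out += mask
            else:
                out += ld
                out[self.z[nb]] += ls - ld
        return out

    def _lik_deltas(self, tip: int) -> np.ndarray:
        """log DM(pool_s + c_tip) - log DM(pool_s), for every candidate state."""
        nz = self._nz[tip]
        c = self.X[tip, nz]
        n_c = c.sum()
        a_tot = self.J * self.alpha
        occ = np.flatnonzero(self.tip_count > 0)
        d_empty = (gammaln(a_tot) - gammaln(a_tot + n_c)
                   + np.sum(gammaln(self.alpha + c)) - nz.size * gammaln(self.alpha))
        out = np.full(self.K, d_empty)
        if occ.size:
            P = self.pool[np.ix_(occ, nz)]
            S = self.pool_tot[occ]
            out[occ] = (gammaln(a_tot + S) - gammaln(a_tot + S + n_c)
                        + (gammaln(self.alpha + P + c)
                           - gammaln(self.alpha + P)).sum(axis=1))
        return out

    def _detach_tip(self, tip: int) -> None:
        s = self.z[tip]
        self.pool[s] -= self.X[tip]
        self.pool_tot[s] -= self.X[tip].sum()
        self.tip_count[s] -= 1

    def _attach_tip(self, tip: int, s: int) -> None:
        self.pool[s] += self.X[tip]
        self.pool_tot[s] += self.X[tip].sum()
        self.tip_count[s] += 1
        self.z[tip] = s

    def _ctmc_logprior(self, log_same: np.ndarray, log_diff: np.ndarray) -> float:
        tree = self.tree
        nonroot = np.arange(tree.n_nodes) != tree.root
        same = self.z[nonroot] == self.z[tree.parent[nonroot]]
        with np.errstate(invalid="ignore"):
            tot = log_same[nonroot][same].sum() + log_diff[nonroot][~same].sum()
        return float(tot)

    def _update_rate(self) -> None:
        prop = self.rate * np.exp(self.config.mh_step * self.rng.normal())
        p_same, p_diff = _same_diff_probs(prop, self.tree.blen, self.K)
        with np.errstate(divide="ignore"):
            ls, ld = np.log(p_same), np.log(p_diff)
        log_acc = (self._ctmc_logprior(ls, ld)
                   - self._ctmc_logprior(self.log_same, self.log_diff)
                   + _rate_log_prior(prop, self.prior_mean)
                   - _rate_log_prior(self.rate, self.prior_mean)
                   + np.log(prop) - np.log(self.rate))  # lognormal RW Jacobian
        if np.log(self.rng.random()) < log_acc:
            self._set_rate(prop)

    def sweep(self) -> None:
        tree = self.tree
        for v in self.rng.permutation(tree.n_nodes):
            if tree.is_tip(v):
                self._detach_tip(v)
                logits = self._prior_logits(v) + self._lik_deltas(v)
                self._attach_tip(v, _categorical(logits, self.rng))
            else:
                self.z[v] = _categorical(self._prior_logits(v), self.rng)
        if self.config.rate is None:
            self._update_rate()

    # -- recording ----------------------------------------------------------
    def record(self) -> PosteriorSample:
        labels = np.unique(self.z)
        vectors = {
            int(s): self.rng.dirichlet(self.alpha + self.pool[s])
            for s in labels
        }
        other = self.rng.dirichlet(np.full(self.J, self.alpha))
        sample = PosteriorSample(
            assignment=self.z.copy(), state_vectors=vectors,
            other_vector=other, rate=self.rate, log_joint=0.0, K=self.K,
            n_tips=self.tree.n_tips)
        sample.log_joint = joint_logprob(self.tree, self.X, sample, self.config)
        return sample


def gibbs_sample(tree: Phylogeny, counts, config: ModelConfig) -> PosteriorChain:
    """Run the collapsed Gibbs sampler; deterministic given ``config.seed``."""
    sampler = _Sampler(tree, counts, config)
    samples: list[PosteriorSample] = []
    rows = []
    for it in range(1, config.iterations + 1):
        sampler.sweep()
        if it % config.thin == 0:
            s = sampler.record()
            samples.append(s)
            dm = sum(dm_marginal_loglik(sampler.pool[lab], config.alpha)
                     for lab in np.flatnonzero(sampler.tip_count > 0))
            rows.append((it, s.log_joint, dm, s.rate, s.n_realized()))
    trace = pd.DataFrame(
        rows, columns=["iteration", "log_joint", "loglik_dm", "rate",
                       "n_realized"])
    return PosteriorChain(samples=samples, config=config, trace=trace)


def select_top_samples(chain: PosteriorChain, m: int) -> list[PosteriorSample]:
    """The m most probable post-burn-in samples (ties: earlier sample first)."""
    if m <= 0:
        raise ValueError("m must be > 0")
    post = chain.posterior
    if m > len(post):
        raise ValueError("m exceeds post-burn-in chain length")
    order = sorted(range(len(post)), key=lambda i: (-post[i].log_joint, i))
    return [post[i] for i in order[:m]]


# ---------------------------------------------------------------------------
# Exact within-sample marginals via pruning on the lumped chain
# ---------------------------------------------------------------------------

def _lumped_transition(p_same: float, p_diff: float, m: int, m0: int) -> np.ndarray:
    """Transition kernel over (m realized states, optional aggregate of m0)."""
    S = m + (1 if m0 > 0 else 0)
    T = np.full((S, S), p_diff)
    np.fill_diagonal(T, p_same)
    if m0 > 0:
        T[:m, m] = m0 * p_diff
        T[m, m] = p_same + (m0 - 1) * p_diff
    return T


def _pruning(tree: Phylogeny, sample: PosteriorSample):
    """Upward pass; returns (labels, m0, per-branch T, scaled up-messages)."""
    K = sample.K
    tip_states = sample.assignment[: tree.n_tips]
    labels = sorted(int(s) for s in np.unique(tip_states))
    m = len(labels)
    m0 = K - m
    S = m + (1 if m0 > 0 else 0)
    col = {lab: i for i, lab in enumerate(labels)}
    p_same, p_diff = _same_diff_probs(sample.rate, tree.blen, K)
    T = np.empty((tree.n_nodes, S, S))
    for v in range(tree.n_nodes):
        T[v] = _lumped_transition(p_same[v], p_diff[v], m, m0)
    up = np.zeros((tree.n_nodes, S))
    for v in tree.postorder:
        if tree.is_tip(v):
            up[v, col[int(tip_states[v])]] = 1.0
        else:
            msg = np.ones(S)
            for c in tree.children[v]:
                msg *= T[c] @ up[c]
            tot = msg.sum()
            if tot <= 0:
                raise FloatingPointError("zero partial likelihood")
            up[v] = msg / tot  # rescale; marginals are scale-free
    return labels, m0, col, T, up


def node_marginals(tree: Phylogeny, sample: PosteriorSample) -> MarginalStateProbs:
    """Exact marginal state probabilities P(state(u) = q | tip states, rate).

    Conditions on the sample's tip assignments and event rate, integrating
    over internal-node states.  Tips come out as point masses.
    """
    labels, m0, _, T, up = _pruning(tree, sample)
    S = up.shape[1]
    root_prior = np.full(S, 1.0 / sample.K)
    if m0 > 0:
        root_prior[-1] = m0 / sample.K
    probs = np.zeros((tree.n_nodes, S))
    r = root_prior * up[tree.root]
    probs[tree.root] = r / r.sum()
    for v in tree.preorder:
        for c in tree.children[v]:
            lik = T[c] * up[c][None, :]          # q -> r unnormalized
            norm = lik.sum(axis=1, keepdims=True)
            cond = np.divide(lik, norm, out=np.zeros_like(lik), where=norm > 0)
            probs[c] = probs[v] @ cond
    return MarginalStateProbs(labels=labels, probs=probs, has_other=m0 > 0)


def branch_pair_joints(tree: Phylogeny, sample: PosteriorSample,
                       ) -> tuple[MarginalStateProbs, dict[int, np.ndarray]]:
    """Exact per-branch endpoint joints w[q, r] = P(parent=q, child=r | D).

    Returned jointly with the node marginals; ``joints[c]`` refers to the
    branch whose child node is ``c``.  Rows index the parent state, columns
    the child state, in the order of ``marginals.labels`` (+ aggregate).
    """
    labels, m0, _, T, up = _pruning(tree, sample)
    S = up.shape[1]
    root_prior = np.full(S, 1.0 / sample.K)
    if m0 > 0:
        root_prior[-1] = m0 / sample.K
    marg = np.zeros((tree.n_nodes, S))
    r = root_prior * up[tree.root]
    marg[tree.root] = r / r.sum()
    joints: dict[int, np.ndarray] = {}
    for v in tree.preorder:
        for c in tree.children[v]:
            lik = T[c] * up[c][None, :]
            norm = lik.sum(axis=1, keepdims=True)
            cond = np.divide(lik, norm, out=np.zeros_like(lik), where=norm > 0)
            w = marg[v][:, None] * cond
            joints[c] = w
            marg[c] = w.sum(axis=0)
    return MarginalStateProbs(labels=labels, probs=marg, has_other=m0 > 0), joints


def marginal_state_probs(tree: Phylogeny, obj, mode: str = "within"):
    """Marginal state probabilities per node.

    ``mode="within"`` takes one :class:`PosteriorSample` and conditions on its
    realized tip states (exact pruning; used by the flux and permutation
    analyses).  ``mode="pooled"`` takes a chain and returns empirical
    label frequencies across post-burn-in samples (note state labels are only
    identified within, not across, samples).
    """
    if mode == "within":
        if not isinstance(obj, PosteriorSample):
            raise TypeError("within mode expects a PosteriorSample")
        return node_marginals(tree, obj)
    if mode == "pooled":
        samples = obj.posterior if isinstance(obj, PosteriorChain) else list(obj)
        if not samples:
            raise ValueError("empty chain")
        labels = sorted({int(s) for smp in samples
                         for s in np.unique(smp.assignment)})
        col = {lab: i for i, lab in enumerate(labels)}
        probs = np.zeros((tree.n_nodes, len(labels)))
        for smp in samples:
            for v in range(tree.n_nodes):
                probs[v, col[int(smp.assignment[v])]] += 1.0
        probs /= len(samples)
        return MarginalStateProbs(labels=labels, probs=probs, has_other=False)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Stochastic mapping (endpoint-conditioned jump histories)
# ---------------------------------------------------------------------------

def _jump_chain_step_prob(n: int, K: int) -> tuple[float, float]:
    """(P same endpoint, P specific different endpoint) after n jump-chain steps."""
    if K == 1:
        return 1.0, 0.0
    phi = (-1.0 / (K - 1)) ** n
    diag = 1.0 / K + (1.0 - 1.0 / K) * phi
    off = (1.0 - diag) / (K - 1)
    return diag, off


def _sample_n_events(q: int, r: int, x: float, K: int,
                     rng: np.random.Generator, cap: int = 10**6) -> int:
    """Draw the number of jumps on a branch given endpoints; x = rate * t."""
    n_max = int(np.ceil(x + 12.0 * np.sqrt(x + 1.0) + 30.0))
    while n_max <= cap:
        n = np.arange(n_max + 1)
        log_pois = n * np.log(x) - gammaln(n + 1) if x > 0 else \
            np.where(n == 0, 0.0, -np.inf)
        step = np.array([_jump_chain_step_prob(int(k), K)[0 if q == r else 1]
                         for k in n])
        with np.errstate(divide="ignore"):
            logw = log_pois + np.log(np.maximum(step, 0.0))
        w = np.exp(logw - logw.max()) if np.any(np.isfinite(logw)) else None
        if w is None or w.sum() == 0:
            raise RuntimeError(
                f"no jump history consistent with endpoints ({q}->{r}, "
                f"rate*t={x:g}, K={K})")
        if w[-1] / w.sum() > 1e-12:  # tail not negligible; extend
            n_max *= 2
            continue
        cdf = np.cumsum(w)
        return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
    raise RuntimeError("event-count sampler exceeded iteration cap")


def _sample_path(q: int, r: int, n: int, K: int,
                 rng: np.random.Generator) -> list[int]:
    """States after each of n jumps, from q to r, under the uniform jump chain."""
    states = []
    cur = q
    for i in range(1, n):
        remaining = n - i
        diag, off = _jump_chain_step_prob(remaining, K)
        # candidate next states: r (weight diag) and the others != cur, != r
        # (weight off each); cur itself is excluded by the jump chain
        if r != cur:
            w_r, n_other = diag, K - 2
        else:
            w_r, n_other = 0.0, K - 1
        w_other = off * n_other
        tot = w_r + w_other
        if tot <= 0:
            raise RuntimeError("stuck jump-chain path")
        if rng.random() * tot < w_r:
            nxt = r
        else:
            choices = [s for s in range(K) if s != cur and s != r]
            nxt = choices[rng.integers(len(choices))]
        states.append(nxt)
        cur = nxt
    if n >= 1:
        states.append(r)
    return states


@dataclass
class StochasticMapRealization:
    """Event history: per branch (keyed by child node), jump times and states.

    ``events[c]`` is a list of (time offset from the parent end, new state);
    times are strictly increasing within (0, branch length) and the final
    state equals the child's assigned state.
    """

    events: dict[int, list[tuple[float, int]]]


def stochastic_map(tree: Phylogeny, sample: PosteriorSample,
                   rate: float | None = None, n_realizations: int = 1,
                   seed: int = 0) -> list[StochasticMapRealization]:
    """Draw full state-change histories conditional on the sample's assignment.

    Branch endpoints are fixed by ``sample.assignment``; within each branch
    the number of jumps and the intermediate states are drawn exactly from
    the endpoint-conditioned uniformized jump chain, and jump times are order
    statistics of uniforms on the branch.
    """
    rng = np.random.default_rng(seed)
    rate = sample.rate if rate is None else rate
    K = sample.K
    z = sample.assignment
    out = []
    for _ in range(n_realizations):
        events: dict[int, list[tuple[float, int]]] = {}
        for c in range(tree.n_nodes):
            if c == tree.root:
                continue
            q, r = int(z[tree.parent[c]]), int(z[c])
            t = float(tree.blen[c])
            n = _sample_n_events(q, r, rate * t, K, rng)
            if n == 0:
                events[c] = []
                continue
            states = _sample_path(q, r, n, K, rng)
            times = np.sort(rng.random(n)) * t
            events[c] = list(zip(times.tolist(), states))
        out.append(StochasticMapRealization(events=events))
    return out
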