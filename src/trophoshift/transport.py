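"""Optimal-transport evolutionary flux and net rates of prey switching.

Evolutionary change between an ancestor's and a descendant's niche states is
measured as the minimum-cost transport plan U between the two utilization
vectors: U's rows sum to the ancestral vector, its columns to the descendant
vector, and with the default 0/1 cost (0 on the diagonal, 1 off it) the
entries of U count the effective number of per-category gains and losses in
the transition.  Under that cost the optimal cost has the total-variation
closed form ``1 - sum_j min(x_u[j], x_v[j])``; plans are computed by a
log-domain Sinkhorn-Knopp solver with annealed entropic regularization (an
exact LP backend is available and doubles as the test oracle).

Per branch, plans between all weighted pairs of endpoint states are averaged
with the exact endpoint joint probabilities w_qr = P(child=r, parent=q | D)
to give the branch flux matrix U_w; its off-diagonal mass is the branch's
total flux.  A clade's net rate is its total flux divided by its total
branch length; a tip's rate is an age-weighted average of the clade rates on
its path to the root (weights ``age^w``, default w = 1), which regularizes
tip rates toward the tree-wide average.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .dmm import PosteriorSample, branch_pair_joints
from .treedata import Phylogeny

__all__ = [
    "default_cost", "exact_cost", "lp_plan", "sinkhorn_plan", "optimal_plan",
    "TransportPlan", "BranchFlux", "branch_flux", "branch_total_flux",
    "tree_fluxes", "clade_rate", "clade_rates", "tip_rate", "tip_rates",
    "gain_loss_totals", "category_gains_losses",
]

#: annealing schedule for the entropic regularization
EPS_SCHEDULE = (0.1, 0.03, 0.01, 3e-3, 1e-3)
MARGINAL_TOL = 1e-8
#: per-stage iteration cap; only the small tail of hard (degenerate) pairs
#: ever uses the full budget, and the final rounding absorbs what remains
MAX_ITER = 12000
#: pre-rounding violation above which the solve is considered failed
FAIL_TOL = 1e-2


def default_cost(J: int) -> np.ndarray:
    """0/1 cost matrix: free to keep a category, unit cost to exchange it."""
    return 1.0 - np.eye(J)


def exact_cost(x_u, x_v) -> float:
    """Closed-form optimal cost under the 0/1 cost (total-variation identity)."""
    x_u = np.asarray(x_u, float)
    x_v = np.asarray(x_v, float)
    return float(1.0 - np.minimum(x_u, x_v).sum())


@dataclass
class TransportPlan:
    """Optimal plan U with its marginals and total cost d_U."""

    plan: np.ndarray
    source: np.ndarray
    target: np.ndarray
    cost: float

    def marginal_violation(self) -> float:
        return float(max(np.abs(self.plan.sum(axis=1) - self.source).max(),
                         np.abs(self.plan.sum(axis=0) - self.target).max()))


def _check_simplex(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or abs(x.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} must lie on the simplex")
    return np.clip(x, 0.0, None)


def _round_to_marginals(P: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Project an almost-feasible plan onto the exact marginals (Altschuler rounding)."""
    r = P.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(r > 0, np.minimum(1.0, a / r), 1.0)
    P = P * sr[:, None]
    c = P.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sc = np.where(c > 0, np.minimum(1.0, b / c), 1.0)
    P = P * sc[None, :]
    da = a - P.sum(axis=1)
    db = b - P.sum(axis=0)
    s = da.sum()
    if s > 0:
        P = P + np.outer(da, db) / s
    return P


def lp_plan(x_u, x_v, C: np.ndarray | None = None) -> TransportPlan:
    """Exact optimal transport plan via linear programming (HiGHS)."""
    a = _check_simplex(x_u, "x_u")
    b = _check_simplex(x_v, "x_v")
    a = a / a.sum()
    b = b / b.sum()
    J = a.size
    C = default_cost(J) if C is None else np.asarray(C, float)
    # the 2J marginal constraints have rank 2J - 1; drop the redundant last
    # column constraint so rounding noise cannot make the system inconsistent
    A_eq = np.zeros((2 * J - 1, J * J))
    for i in range(J):
        A_eq[i, i * J:(i + 1) * J] = 1.0          # row sums
    for i in range(J - 1):
        A_eq[J + i, i::J] = 1.0                   # column sums
    res = linprog(C.ravel(), A_eq=A_eq,
                  b_eq=np.concatenate([a, b[:-1]]),
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"LP transport failed: {res.message}")
    P = res.x.reshape(J, J)
    P = _round_to_marginals(P, a, b)
    return TransportPlan(plan=P, source=a, target=b,
                         cost=float((P * C).sum()))


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    """log-sum-exp along ``axis``, tolerant of -inf blocks."""
    m = np.max(x, axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(x - m_safe), axis=axis)) + np.squeeze(m_safe, axis)
    return np.where(np.isfinite(np.squeeze(m, axis)), out, -np.inf)


def sinkhorn_plans(A: np.ndarray, B: np.ndarray, C: np.ndarray | None = None,
                   eps_schedule=EPS_SCHEDULE, tol: float = MARGINAL_TOL,
                   max_iter: int = MAX_ITER) -> np.ndarray:
    """Batched log-domain Sinkhorn: one plan per row pair of (A, B).

    Potentials are warm-started across the annealing schedule and the final
    plans are rounded onto the exact marginals.  Zero marginal entries are
    handled through -inf potentials.  Returns plans of shape (n, J, J);
    raises on non-convergence within ``max_iter`` iterations per stage.
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    n, J = A.shape
    C = default_cost(J) if C is None else np.asarray(C, float)
    with np.errstate(divide="ignore"):
        LA, LB = np.log(A), np.log(B)
    f = np.where(A > 0, 0.0, -np.inf)
    g = np.where(B > 0, 0.0, -np.inf)
    for eps in eps_schedule:
        # pairs converge at very different speeds: freeze finished ones and
        # keep iterating only the active remainder of the batch
        active = np.arange(n)
        fa, ga = f, g
        la, lb, aa = LA, LB, A
        for it in range(max_iter):
            fa = eps * la - eps * _lse((ga[:, None, :] - C[None]) / eps, axis=2)
            ga = eps * lb - eps * _lse((fa[:, :, None] - C[None]) / eps, axis=1)
            if it % 10 == 9 or it == max_iter - 1:
                P = np.exp((fa[:, :, None] + ga[:, None, :] - C[None]) / eps)
                viol = np.abs(P.sum(axis=2) - aa).max(axis=1)
                done = viol < tol
                if done.any():
                    f[active[done]] = fa[done]
                    g[active[done]] = ga[done]
                    keep = ~done
                    active = active[keep]
                    fa, ga = fa[keep], ga[keep]
                    la, lb, aa = la[keep], lb[keep], aa[keep]
                if active.size == 0:
                    break
        if active.size:
            f[active] = fa
            g[active] = ga
    eps = eps_schedule[-1]
    P = np.exp((f[:, :, None] + g[:, None, :] - C[None]) / eps)
    worst = np.abs(P.sum(axis=2) - A).max()
    if not np.isfinite(worst) or worst > FAIL_TOL:
        raise RuntimeError(
            f"Sinkhorn failed to converge (violation {worst:.3g} after "
            f"{max_iter} iterations per stage)")
    for i in range(n):
        P[i] = _round_to_marginals(P[i], A[i], B[i])
    return P


def sinkhorn_plan(x_u, x_v, C: np.ndarray | None = None,
                  eps_schedule=EPS_SCHEDULE, tol: float = MARGINAL_TOL,
                  max_iter: int = MAX_ITER) -> TransportPlan:
    """Entropically regularized plan, annealed toward the unregularized optimum."""
    a = _check_simplex(x_u, "x_u")
    b = _check_simplex(x_v, "x_v")
    J = a.size
    C_full = default_cost(J) if C is None else np.asarray(C, float)
    P = sinkhorn_plans(a[None, :], b[None, :], C_full, eps_schedule, tol,
                       max_iter)[0]
    return TransportPlan(plan=P, source=a, target=b,
                         cost=float((P * C_full).sum()))


def optimal_plan(x_u, x_v, C: np.ndarray | None = None,
                 method: str = "sinkhorn", **kwargs) -> TransportPlan:
    """Optimal transport plan between two niche states (``sinkhorn`` or ``lp``)."""
    if method == "sinkhorn":
        return sinkhorn_plan(x_u, x_v, C, **kwargs)
    if method == "lp":
        return lp_plan(x_u, x_v, C)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Branch fluxes
# ---------------------------------------------------------------------------

@dataclass
class BranchFlux:
    """Weighted flux matrix U_w for one branch (keyed by its child node)."""

    branch: int
    U_w: np.ndarray

    @property
    def total(self) -> float:
        return branch_total_flux(self.U_w)


def branch_total_flux(U_w: np.ndarray) -> float:
    """Off-diagonal mass of the flux matrix: sum_jk U_jk (1 - I_jk)."""
    U_w = np.asarray(U_w, float)
    return float(U_w.sum() - np.trace(U_w))


class _PlanCache:
    """Memoizes pairwise plans within one posterior sample."""

    def __init__(self, vectors: np.ndarray, method: str = "sinkhorn"):
        self.vectors = vectors
        self.method = method
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def precompute(self, pairs: set[tuple[int, int]]) -> None:
        """Batch-solve all off-diagonal pairs in one Sinkhorn call."""
        todo = sorted(p for p in pairs if p[0] != p[1] and p not in self._cache)
        if not todo:
            return
        if self.method == "sinkhorn":
            A = np.stack([self.vectors[q] for q, _ in todo])
            B = np.stack([self.vectors[r] for _, r in todo])
            plans = sinkhorn_plans(A, B)
            for key, P in zip(todo, plans):
                self._cache[key] = P
        else:
            for q, r in todo:
                self._cache[(q, r)] = optimal_plan(
                    self.vectors[q], self.vectors[r], method=self.method).plan

    def plan(self, q: int, r: int) -> np.ndarray:
        if q == r:
            return np.diag(self.vectors[q])
        key = (q, r)
        if key not in self._cache:
            self._cache[key] = optimal_plan(
                self.vectors[q], self.vectors[r], method=self.method).plan
        return self._cache[key]


def branch_flux(weights: np.ndarray, vectors: np.ndarray,
                method: str = "sinkhorn", weight_tol: float = 1e-9,
                cache: "_PlanCache | None" = None) -> np.ndarray:
    """Weighted average flux matrix U_w = sum_qr w_qr U^(q,r) / sum_qr w_qr.

    ``weights[q, r]`` is the endpoint joint probability P(parent=q, child=r);
    ``vectors[s]`` the utilization vector of state s.  Same-state pairs
    contribute pure-diagonal plans.  The denominator is analytically 1 but is
    computed for safety.
    """
    weights = np.asarray(weights, float)
    S, J = vectors.shape
    if weights.shape != (S, S):
        raise ValueError("weights must be (S, S) over the state vectors")
    cache = cache or _PlanCache(vectors, method)
    U = np.zeros((J, J))
    total_w = 0.0
    for q in range(S):
        for r in range(S):
            w = weights[q, r]
            if w <= weight_tol:
                total_w += max(w, 0.0)
                continue
            U += w * cache.plan(q, r)
            total_w += w
    if total_w <= 0:
        raise ValueError("endpoint weights sum to zero")
    return U / total_w


def _sample_vector_matrix(sample: PosteriorSample, labels: list[int],
                          has_other: bool) -> np.ndarray:
    rows = [sample.state_vectors[lab] for lab in labels]
    if has_other:
        rows.append(sample.other_vector)
    return np.stack(rows)


def tree_fluxes(tree: Phylogeny, samples: list[PosteriorSample],
                method: str = "sinkhorn", weight_tol: float = 1e-6,
                ) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Posterior-average flux matrix per branch.

    For each sample, the exact endpoint joints on every branch weight the
    pairwise transport plans between that sample's state vectors; the
    resulting U_w matrices are averaged over samples.  Returns
    ``(flux_by_branch, per_sample_totals)`` where ``per_sample_totals`` has
    shape (n_samples, n_nodes) (column = child node id; root column zero),
    so clade-rate posteriors can be formed per sample.
    """
    if not samples:
        raise ValueError("no posterior samples")
    n = tree.n_nodes
    J = len(samples[0].other_vector)
    acc: dict[int, np.ndarray] = {c: np.zeros((J, J)) for c in range(n)
                                  if c != tree.root}
    totals = np.zeros((len(samples), n))
    for i, sample in enumerate(samples):
        marg, joints = branch_pair_joints(tree, sample)
        V = _sample_vector_matrix(sample, marg.labels, marg.has_other)
        cache = _PlanCache(V, method)
        needed = {(q, r)
                  for w in joints.values()
                  for q, r in zip(*np.nonzero(w > weight_tol))}
        cache.precompute({(int(q), int(r)) for q, r in needed})
        for c, w in joints.items():
            U = branch_flux(w, V, method=method, weight_tol=weight_tol,
                            cache=cache)
            acc[c] += U
            totals[i, c] = branch_total_flux(U)
    for c in acc:
        acc[c] /= len(samples)
    return acc, totals


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def clade_rate(tree: Phylogeny, branch_totals: dict[int, float] | np.ndarray,
               clade_root: int) -> float:
    """Total flux over the clade's branches divided by its total branch length."""
    if isinstance(branch_totals, dict):
        bt = np.zeros(tree.n_nodes)
        for c, v in branch_totals.items():
            bt[c] = v
    else:
        bt = np.asarray(branch_totals, float)
    # branches descended from the clade's root; the stem branch is excluded
    nodes = tree.subtree_nodes(clade_root)
    branches = nodes[nodes != clade_root]
    length = tree.blen[branches].sum()
    if length <= 0:
        raise ValueError("clade has zero total branch length")
    return float(bt[branches].sum() / length)


def clade_rates(tree: Phylogeny, branch_totals) -> np.ndarray:
    """Clade rate for every internal node (NaN at tips)."""
    out = np.full(tree.n_nodes, np.nan)
    for v in range(tree.n_tips, tree.n_nodes):
        out[v] = clade_rate(tree, branch_totals, v)
    if tree.root < tree.n_tips:  # degenerate single-tip tree
        out[tree.root] = clade_rate(tree, branch_totals, tree.root)
    return out


def tip_rate(tree: Phylogeny, clade_rate_by_node: np.ndarray, tip: int,
             w: float = 1.0, ages: np.ndarray | None = None) -> float:
    """Age-weighted average of the clade rates on the tip's path to the root.

    Weight of the clade rooted at internal node i is ``age(i)**w``; larger w
    pulls each tip rate toward the whole-tree rate (the root carries the
    largest weight).  ``w=0`` gives the unweighted path mean.
    """
    if w < 0:
        raise ValueError("w must be >= 0")
    if ages is None:
        ages = tree.node_ages()
    path = tree.path_to_root(tip)
    rates = np.array([clade_rate_by_node[v] for v in path])
    weights = np.power(ages[path], w)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    return float(np.sum(weights * rates) / weights.sum())


def tip_rates(tree: Phylogeny, clade_rate_by_node: np.ndarray,
              w: float = 1.0) -> np.ndarray:
    ages = tree.node_ages()
    return np.array([tip_rate(tree, clade_rate_by_node, i, w, ages)
                     for i in range(tree.n_tips)])


# ---------------------------------------------------------------------------
# Gains and losses
# ---------------------------------------------------------------------------

def gain_loss_totals(flux_by_branch: dict[int, np.ndarray]) -> np.ndarray:
    """Tree-wide J x J matrix of average gains/losses.

    Entry (j, k) accumulates, over all branches, the posterior-average flux
    from ancestral category j into derived category k; the diagonal is zero.
    """
    it = iter(flux_by_branch.values())
    first = next(it)
    total = first.copy()
    for U in it:
        total += U
    np.fill_diagonal(total, 0.0)
    return total


def category_gains_losses(x_u, x_v) -> tuple[np.ndarray, np.ndarray]:
    """Plan-independent per-category losses and gains for one transition.

    Under the 0/1 cost every optimal plan keeps ``min(x_u, x_v)`` in place,
    so category j loses ``max(0, x_u[j] - x_v[j])`` and gains
    ``max(0, x_v[j] - x_u[j])`` regardless of how the off-diagonal mass is
    arranged.
    """
    x_u = np.asarray(x_u, float)
    x_v = np.asarray(x_v, float)
    return np.maximum(x_u - x_v, 0.0), np.maximum(x_v - x_u, 0.0)
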