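import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import logsumexp

import trophoshift as ts
from trophoshift.dmm import (PosteriorSample, branch_pair_joints,
                             joint_logprob, node_marginals, stochastic_map)


def enumerate_posterior(tree, counts, config):
    """Brute-force joint over all K^n assignments at a fixed rate."""
    n = tree.n_nodes
    rate = config.rate
    keys, logps = [], []
    for z in itertools.product(range(config.K), repeat=n):
        s = PosteriorSample(np.array(z), {}, np.ones(counts.shape[1]), rate,
                            0.0, config.K)
        keys.append(z)
        logps.append(joint_logprob(tree, counts, s, config))
    w = np.exp(np.array(logps) - logsumexp(logps))
    return keys, w


def coassignment_probs(keys, w, n):
    """P(z_u == z_v) for every node pair — a label-invariant functional."""
    out = np.zeros((n, n))
    for z, wi in zip(keys, w):
        z = np.asarray(z)
        out += wi * (z[:, None] == z[None, :])
    return out


def batch_se(x, n_batches=20):
    x = np.asarray(x, float)
    m = x.size // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestDMMarginal:
    def test_single_draw_is_one_over_J(self):
        c = np.zeros(22)
        c[5] = 1
        assert ts.dm_marginal_loglik(c, 1.0) == pytest.approx(np.log(1 / 22))

    def test_two_zero_case_is_one_third(self):
        assert ts.dm_marginal_loglik([2, 0], 1.0) == pytest.approx(np.log(1 / 3))

    def test_all_zero_counts_give_log_one(self):
        assert ts.dm_marginal_loglik([0, 0, 0], 1.0) == 0.0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            ts.dm_marginal_loglik([1, 0], 0.0)


class TestTransitionProbability:
    def test_zero_time_is_identity(self):
        assert np.allclose(ts.transition_probability(1.0, 0.0, 4), np.eye(4))

    def test_long_time_is_uniform(self):
        P = ts.transition_probability(1.0, 1e6, 4)
        assert np.allclose(P, 0.25)

    def test_matches_matrix_exponential(self):
        # independent oracle: expm of the explicit generator
        for K, rate, t in [(2, 1.0, 1.0), (3, 0.7, 2.5), (5, 0.2, 10.0)]:
            Q = np.full((K, K), rate / (K - 1))
            np.fill_diagonal(Q, -rate)
            assert np.allclose(ts.transition_probability(rate, t, K),
                               expm(Q * t), atol=1e-12)
        stay = ts.transition_probability(1.0, 1.0, 2)[0, 0]
        assert stay == pytest.approx((1 + np.exp(-2)) / 2)

    def test_rows_sum_to_one(self):
        P = ts.transition_probability(0.3, 2.0, 7)
        assert np.allclose(P.sum(axis=1), 1.0)


class TestJointLogprob:
    def test_single_branch_tree(self):
        tree = ts.read_tree("(A:1);")
        counts = np.array([[2.0, 0.0]])
        cfg = ts.ModelConfig(K=3, rate=1.0, rate_prior_mean=1.0)
        s = PosteriorSample(np.array([0, 0]), {}, np.ones(2), 1.0, 0.0, 3)
        stay = ts.transition_probability(1.0, 1.0, 3)[0, 0]
        expect = (-np.log(3)               # uniform root prior
                  + np.log(stay)           # one branch, no change
                  + np.log(1 / 3)          # DM of counts (2, 0) at alpha=1
                  - 1.0)                   # Exp(mean 1) log-density at rate 1
        assert joint_logprob(tree, counts, s, cfg) == pytest.approx(expect)

    def test_unused_label_permutation_invariance(self, three_tip_tree):
        counts = np.array([[3.0, 0], [0, 2], [1, 1]])
        cfg = ts.ModelConfig(K=5, rate=0.4)
        z = np.array([0, 1, 0, 0, 1])
        s = PosteriorSample(z, {}, np.ones(2), 0.4, 0.0, 5)
        base = joint_logprob(three_tip_tree, counts, s, cfg)
        # swap two labels (used<->used and used<->unused): joint unchanged
        for perm in [{0: 1, 1: 0}, {1: 4, 4: 1}]:
            z2 = np.array([perm.get(v, v) for v in z])
            s2 = PosteriorSample(z2, {}, np.ones(2), 0.4, 0.0, 5)
            assert joint_logprob(three_tip_tree, counts, s2, cfg) == \
                pytest.approx(base, abs=1e-12)

    def test_all_same_state_dominates_as_rate_vanishes(self, three_tip_tree):
        counts = np.array([[3.0, 0], [0, 2], [1, 1]])
        cfg = ts.ModelConfig(K=2, rate=1e-9)
        keys, w = enumerate_posterior(three_tip_tree, counts, cfg)
        mass_same = sum(wi for z, wi in zip(keys, w) if len(set(z)) == 1)
        assert mass_same > 0.999


class TestGibbs:
    def test_matches_enumeration_on_two_tip_tree(self):
        tree = ts.read_tree("(A:1,B:1);")
        counts = np.array([[3.0, 0.0], [0.0, 2.0]])
        cfg = ts.ModelConfig(K=2, rate=0.5, iterations=20000, thin=1,
                             burnin=200, seed=5)
        keys, w = enumerate_posterior(tree, counts, cfg)
        target = coassignment_probs(keys, w, tree.n_nodes)
        chain = ts.gibbs_sample(tree, counts, cfg)
        Z = np.stack([s.assignment for s in chain.posterior])
        pairs = [(u, v) for u in range(tree.n_nodes)
                 for v in range(u + 1, tree.n_nodes)]
        for u, v in pairs:
            x = (Z[:, u] == Z[:, v]).astype(float)
            se = max(batch_se(x), 1e-4)
            assert abs(x.mean() - target[u, v]) < 3 * se, (u, v)

    def test_identical_tips_collapse_to_one_state(self):
        # identical, well-sampled diets: the per-change penalty at large K
        # should concentrate the posterior on a single realized state
        tree = ts.read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        counts = np.tile([200.0, 200.0], (4, 1))
        cfg = ts.ModelConfig(K=50, iterations=3000, thin=5, burnin=100, seed=2)
        chain = ts.gibbs_sample(tree, counts, cfg)
        n_real = np.array([s.n_realized() for s in chain.posterior])
        assert (n_real == 1).mean() >= 0.95

    def test_seed_reproducibility(self, three_tip_tree):
        counts = np.array([[3.0, 0], [0, 2], [1, 1]])
        cfg = ts.ModelConfig(K=3, iterations=200, thin=2, burnin=10, seed=42)
        c1 = ts.gibbs_sample(three_tip_tree, counts, cfg)
        c2 = ts.gibbs_sample(three_tip_tree, counts, cfg)
        assert np.array_equal(
            np.stack([s.assignment for s in c1.samples]),
            np.stack([s.assignment for s in c2.samples]))
        assert c1.trace["log_joint"].equals(c2.trace["log_joint"])

    def test_chain_length_contract(self, three_tip_tree):
        counts = np.array([[3.0, 0], [0, 2], [1, 1]])
        cfg = ts.ModelConfig(K=2, iterations=100, thin=10, burnin=2, seed=0)
        chain = ts.gibbs_sample(three_tip_tree, counts, cfg)
        assert len(chain) == 10 and len(chain.posterior) == 8
        assert np.isfinite(chain.trace["log_joint"]).all()

    def test_state_vectors_on_simplex(self, small_truth_and_chain):
        _, chain = small_truth_and_chain
        for s in chain.posterior[:10]:
            for vec in s.state_vectors.values():
                assert vec.min() >= 0
                assert vec.sum() == pytest.approx(1.0, abs=1e-9)


class TestMarginals:
    def test_pruning_matches_enumeration_conditional(self, three_tip_tree):
        tree = three_tip_tree
        counts = np.array([[3.0, 0], [0, 2], [1, 1]])
        cfg = ts.ModelConfig(K=3, rate=0.5)
        ztip = (0, 1, 0)
        # enumerate internal assignments conditional on the tip states
        sub = []
        for zint in itertools.product(range(3), repeat=2):
            z = np.array(ztip + zint)
            s = PosteriorSample(z, {}, np.ones(2), 0.5, 0.0, 3)
            sub.append((z, joint_logprob(tree, counts, s, cfg)))
        lp = np.array([x[1] for x in sub])
        w = np.exp(lp - logsumexp(lp))
        expect = np.zeros((tree.n_nodes, 3))
        for (z, _), wi in zip(sub, w):
            for v in range(tree.n_nodes):
                expect[v, z[v]] += wi
        sample = PosteriorSample(np.array(ztip + (0, 0)),
                                 {0: np.ones(2) / 2, 1: np.ones(2) / 2},
                                 np.ones(2) / 2, 0.5, 0.0, 3)
        marg = node_marginals(tree, sample)
        # columns: realized labels 0, 1 then the aggregate (only label 2)
        assert marg.labels == [0, 1] and marg.has_other
        assert np.allclose(marg.probs[:, :2], expect[:, :2], atol=1e-12)
        assert np.allclose(marg.probs[:, 2], expect[:, 2], atol=1e-12)

    def test_rows_sum_to_one_and_tips_are_point_masses(self,
                                                       small_truth_and_chain):
        truth, chain = small_truth_and_chain
        s = chain.posterior[-1]
        marg = node_marginals(truth.tree, s)
        assert np.allclose(marg.probs.sum(axis=1), 1.0, atol=1e-9)
        tips = marg.probs[: truth.tree.n_tips]
        assert np.allclose(tips.max(axis=1), 1.0)

    def test_pair_joints_consistent_with_marginals(self, small_truth_and_chain):
        truth, chain = small_truth_and_chain
        s = chain.posterior[-1]
        marg, joints = branch_pair_joints(truth.tree, s)
        tree = truth.tree
        for c, w in joints.items():
            assert np.allclose(w.sum(axis=1), marg.probs[tree.parent[c]],
                               atol=1e-9)
            assert np.allclose(w.sum(axis=0), marg.probs[c], atol=1e-9)

    def test_pooled_mode_identical_samples_yield_indicators(self,
                                                            three_tip_tree):
        z = np.array([0, 1, 0, 0, 0])
        s = PosteriorSample(z, {0: np.ones(2) / 2, 1: np.ones(2) / 2},
                            np.ones(2) / 2, 0.1, 0.0, 2)
        marg = ts.marginal_state_probs(three_tip_tree, [s, s, s], mode="pooled")
        assert set(np.unique(marg.probs)) == {0.0, 1.0}

    def test_well_sampled_specialist_tip_pins_its_state(self):
        scenario = ts.SimScenario(n_tips=16, J=4, K_true=2, seed=3,
                                  sample_size=("fixed", 2000),
                                  min_separation=0.8)
        truth = ts.simulate(scenario)
        cfg = ts.ModelConfig(K=6, iterations=800, thin=5, burnin=40, seed=4)
        chain = ts.gibbs_sample(truth.tree, truth.counts, cfg)
        s = chain.posterior[-1]
        marg = node_marginals(truth.tree, s)
        tip_col = marg.probs[0].argmax()
        assert marg.probs[0, tip_col] >= 0.99


class TestMixing:
    def test_seeds_agree_on_realized_state_mode(self, small_truth_and_chain):
        from collections import Counter
        truth, chain = small_truth_and_chain
        cfg2 = ts.ModelConfig(K=8, iterations=600, thin=5, burnin=40, seed=99)
        chain2 = ts.gibbs_sample(truth.tree, truth.counts, cfg2)
        mode1 = Counter(s.n_realized()
                        for s in chain.posterior).most_common(1)[0][0]
        mode2 = Counter(s.n_realized()
                        for s in chain2.posterior).most_common(1)[0][0]
        assert mode1 == mode2

    def test_log_joint_trace_reaches_plateau(self, small_truth_and_chain):
        _, chain = small_truth_and_chain
        lj = chain.trace["log_joint"].to_numpy()
        q = lj.size // 4
        # the chain climbs out of its start and then stays level
        assert lj[-q:].mean() >= lj[:q].mean()
        late_shift = abs(lj[-q:].mean() - lj[-2 * q:-q].mean())
        assert late_shift < 3 * lj[-2 * q:].std() + 1e-9


class TestTopSamples:
    def test_ordering_and_edge_cases(self, small_truth_and_chain):
        _, chain = small_truth_and_chain
        top = ts.select_top_samples(chain, 5)
        lps = [s.log_joint for s in top]
        assert lps == sorted(lps, reverse=True)
        assert top[0].log_joint == max(s.log_joint for s in chain.posterior)
        everything = ts.select_top_samples(chain, len(chain.posterior))
        assert len(everything) == len(chain.posterior)
        with pytest.raises(ValueError):
            ts.select_top_samples(chain, 0)


class TestStochasticMap:
    def _sample(self, tree, z, rate, K):
        return PosteriorSample(np.asarray(z), {}, np.ones(2), rate, 0.0, K)

    def test_equal_endpoints_never_one_event(self, three_tip_tree):
        s = self._sample(three_tip_tree, [0, 0, 0, 0, 0], 1.0, 3)
        reals = stochastic_map(three_tip_tree, s, n_realizations=300, seed=1)
        for r in reals:
            for ev in r.events.values():
                assert len(ev) != 1

    def test_unequal_endpoints_at_least_one_event(self, three_tip_tree):
        s = self._sample(three_tip_tree, [0, 1, 0, 0, 0], 1.0, 3)
        reals = stochastic_map(three_tip_tree, s, n_realizations=200, seed=2)
        for r in reals:
            assert len(r.events[1]) >= 1

    def test_small_rate_limit_no_events(self, three_tip_tree):
        s = self._sample(three_tip_tree, [0, 0, 0, 0, 0], 1e-6, 3)
        reals = stochastic_map(three_tip_tree, s, n_realizations=300, seed=3)
        frac0 = np.mean([all(len(ev) == 0 for ev in r.events.values())
                         for r in reals])
        assert frac0 > 0.99

    def test_endpoint_consistency_and_time_bounds(self, three_tip_tree):
        tree = three_tip_tree
        z = [0, 1, 2, 1, 0]
        s = self._sample(tree, z, 1.5, 3)
        for r in stochastic_map(tree, s, n_realizations=100, seed=4):
            for c, ev in r.events.items():
                times = [t for t, _ in ev]
                assert times == sorted(times)
                assert all(0 < t < tree.blen[c] for t in times)
                state = z[tree.parent[c]]
                for _, new in ev:
                    assert new != state
                    state = new
                assert state == z[c]

    def test_event_count_distribution_matches_kernel(self):
        # P(N=0 | same endpoints) = e^{-rate t} / stay probability
        tree = ts.read_tree("(A:1,B:1);")
        rate, K = 0.8, 4
        s = self._sample(tree, [0, 0, 0], rate, K)
        reals = stochastic_map(tree, s, n_realizations=4000, seed=5)
        frac0 = np.mean([len(r.events[0]) == 0 for r in reals])
        stay = ts.transition_probability(rate, 1.0, K)[0, 0]
        expect = np.exp(-rate) / stay
        assert abs(frac0 - expect) < 3 * np.sqrt(expect * (1 - expect) / 4000)
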