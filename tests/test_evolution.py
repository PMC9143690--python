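"""Birth-death kernel, pruning likelihood, reconstruction, recovery."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from figlipase.evolution import (
    BDModel,
    bd_transition_prob,
    estimate_lambda,
    reconstruct_ancestral,
    simulate_counts,
    transition_matrix,
    tree_loglik,
)
from figlipase.synth import SimConfig, gen_tree


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


THREE_LEAF = "((A:7.0,B:11.0):5.0,C:13.0);"


class TestTransitionKernel:
    def test_zero_branch_is_identity(self):
        model = BDModel(lam=0.01, cap=20)
        for s in range(6):
            for c in range(6):
                expected = 1.0 if c == s else 0.0
                assert bd_transition_prob(s, c, model, 0.0) == expected

    def test_extinction_from_single_copy_is_alpha(self):
        model = BDModel(lam=0.01, cap=20)
        for t in (1.0, 10.0, 100.0):
            assert bd_transition_prob(1, 0, model, t) == pytest.approx(model.alpha(t))

    def test_zero_state_absorbing(self):
        model = BDModel(lam=0.05, cap=20)
        assert bd_transition_prob(0, 0, model, 7.0) == 1.0
        assert bd_transition_prob(0, 3, model, 7.0) == 0.0

    def test_matches_matrix_exponential_oracle(self):
        """The closed-form kernel equals expm of the linear birth-death rate
        matrix (birth and death both at lam per copy), truncated at cap 50."""
        lam, cap = 0.01, 50
        model = BDModel(lam=lam, cap=cap)
        rates = np.zeros((cap + 1, cap + 1))
        for i in range(1, cap + 1):
            rates[i, i - 1] = i * lam
            rates[i, i] = -2 * i * lam
            if i < cap:
                rates[i, i + 1] = i * lam
        for t in (5.0, 20.0, 50.0):
            oracle = expm(rates * t)
            kernel = transition_matrix(model, t)
            # truncation effects stay far from small parent states
            assert np.abs(kernel[:11, :40] - oracle[:11, :40]).max() < 1e-10

    def test_rows_sum_to_one(self):
        model = BDModel(lam=0.025, cap=100)
        kernel = transition_matrix(model, 20.0)  # lam * t = 0.5
        assert np.abs(kernel[:11].sum(axis=1) - 1.0).max() < 1e-8

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            bd_transition_prob(-1, 0, BDModel(lam=0.01), 1.0)


class TestTreeLoglik:
    def test_single_branch_reduces_to_kernel(self):
        """With one leaf below the root, conditioning the enumeration on the
        root state recovers log P(c | s, t) from the kernel."""
        model = BDModel(lam=0.02, cap=15)
        tree = _tree("(A:9.0);")
        # pruning with uniform root prior: L = (1/M) sum_s P(c | s, t)
        c = 4
        got = tree_loglik(tree, {"A": c}, model)
        kernel = transition_matrix(model, 9.0)
        expected = np.log(kernel[1:, c].sum() / model.cap)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_three_leaf_enumeration_oracle(self):
        """Pruning equals brute-force enumeration over all internal states."""
        model = BDModel(lam=0.015, cap=12)
        tree = _tree(THREE_LEAF)
        counts = {"A": 3, "B": 5, "C": 2}
        k_in = transition_matrix(model, 5.0)  # root -> internal
        k_a = transition_matrix(model, 7.0)
        k_b = transition_matrix(model, 11.0)
        k_c = transition_matrix(model, 13.0)
        total = 0.0
        for root in range(1, model.cap + 1):
            for internal in range(model.cap + 1):
                total += (
                    (1.0 / model.cap)
                    * k_in[root, internal]
                    * k_a[internal, counts["A"]]
                    * k_b[internal, counts["B"]]
                    * k_c[root, counts["C"]]
                )
        assert tree_loglik(tree, counts, model) == pytest.approx(np.log(total), rel=1e-10)

    def test_small_lambda_concentrates_on_no_change(self):
        tree = _tree(THREE_LEAF)
        equal = {"A": 4, "B": 4, "C": 4}
        ll_small = tree_loglik(tree, equal, BDModel(lam=1e-7, cap=10))
        # all mass on "root = 4, nothing changed": prior mass 1/cap
        assert ll_small == pytest.approx(np.log(1 / 10), abs=1e-3)

    def test_outlier_leaf_lowers_likelihood(self):
        tree = _tree(THREE_LEAF)
        model = BDModel(lam=0.005, cap=30)
        close = tree_loglik(tree, {"A": 4, "B": 4, "C": 4}, model)
        far = tree_loglik(tree, {"A": 4, "B": 4, "C": 14}, model)
        assert close > far

    def test_missing_leaf_count_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            tree_loglik(_tree(THREE_LEAF), {"A": 1, "B": 2}, BDModel(lam=0.01))

    def test_count_above_cap_rejected(self):
        with pytest.raises(ValueError, match="cap"):
            tree_loglik(_tree(THREE_LEAF), {"A": 1, "B": 2, "C": 99}, BDModel(lam=0.01, cap=10))


class TestEstimateLambda:
    def test_recovers_simulation_rate(self):
        """lambda estimated from 200 simulated families lands within 50%."""
        true_lam = 0.002
        tree = gen_tree(SimConfig(seed=11))
        model = BDModel(lam=true_lam, cap=40)
        families = [
            simulate_counts(tree, 5, model, np.random.default_rng(5000 + i))
            for i in range(200)
        ]
        est = estimate_lambda(tree, families, cap=40, bounds=(1e-5, 0.1))
        assert abs(est - true_lam) / true_lam < 0.5

    def test_degenerate_data_hits_lower_bound(self):
        tree = _tree(THREE_LEAF)
        est = estimate_lambda(
            tree, [{"A": 3, "B": 3, "C": 3}], cap=10, bounds=(1e-4, 0.5)
        )
        assert est == pytest.approx(1e-4, rel=1e-2)

    def test_estimate_is_local_optimum(self):
        tree = gen_tree(SimConfig(seed=13))
        model = BDModel(lam=0.004, cap=40)
        families = [
            simulate_counts(tree, 5, model, np.random.default_rng(7000 + i))
            for i in range(50)
        ]
        est = estimate_lambda(tree, families, cap=40, bounds=(1e-5, 0.1))
        at = sum(tree_loglik(tree, f, BDModel(lam=est, cap=40)) for f in families)
        below = sum(tree_loglik(tree, f, BDModel(lam=est / 2, cap=40)) for f in families)
        above = sum(tree_loglik(tree, f, BDModel(lam=est * 2, cap=40)) for f in families)
        assert at >= below and at >= above


class TestReconstructAncestral:
    def test_equal_leaves_short_branches_reconstruct_root(self):
        tree = _tree("(A:0.5,B:0.5);")
        report = reconstruct_ancestral(tree, {"A": 5, "B": 5}, BDModel(lam=0.01, cap=20))
        root_label = [k for k in report.node_counts if k not in ("A", "B")][0]
        assert report.node_counts[root_label] == 5
        assert all(b.net_change == 0 for b in report.branches)

    def test_three_leaf_joint_maximization_oracle(self):
        model = BDModel(lam=0.03, cap=8)
        tree = _tree(THREE_LEAF)
        counts = {"A": 2, "B": 4, "C": 1}
        k_in = transition_matrix(model, 5.0)
        k_a = transition_matrix(model, 7.0)
        k_b = transition_matrix(model, 11.0)
        k_c = transition_matrix(model, 13.0)
        best, best_states = -np.inf, None
        for root in range(1, model.cap + 1):
            for internal in range(model.cap + 1):
                score = (
                    k_in[root, internal]
                    * k_a[internal, counts["A"]]
                    * k_b[internal, counts["B"]]
                    * k_c[root, counts["C"]]
                )
                if score > best:
                    best, best_states = score, (root, internal)
        report = reconstruct_ancestral(tree, counts, model)
        internal_label = "mrca(A,B)"
        root_label = "mrca(A,B,C)"
        assert report.node_counts[root_label] == best_states[0]
        assert report.node_counts[internal_label] == best_states[1]

    def test_net_changes_telescope_along_paths(self):
        tree = gen_tree(SimConfig(seed=17))
        model = BDModel(lam=0.004, cap=40)
        counts = simulate_counts(tree, 6, model, np.random.default_rng(123))
        report = reconstruct_ancestral(tree, counts, model)
        changes = {(b.parent, b.child): b.net_change for b in report.branches}
        parents = {b.child: b.parent for b in report.branches}
        root = (set(parents.values()) - set(parents.keys())).pop()
        for leaf in counts:
            total, node = 0, leaf
            while node != root:
                total += changes[(parents[node], node)]
                node = parents[node]
            assert total == report.node_counts[leaf] - report.node_counts[root]


class TestSimulateCounts:
    def test_zero_rate_limit_keeps_root_count(self):
        tree = _tree(THREE_LEAF)
        # lam * t << 1 on every branch: change is essentially impossible
        counts = simulate_counts(tree, 7, BDModel(lam=1e-9, cap=20), 1)
        assert set(counts.values()) == {7}

    def test_same_seed_reproduces(self):
        tree = gen_tree(SimConfig(seed=19))
        model = BDModel(lam=0.01, cap=30)
        assert simulate_counts(tree, 5, model, 99) == simulate_counts(tree, 5, model, 99)

    def test_branch_distribution_matches_kernel(self):
        """Empirical child counts over one branch agree with the kernel row
        within 3-sigma multinomial bounds."""
        model = BDModel(lam=0.02, cap=30)
        tree = _tree("(A:10.0,B:0.001);")
        draws = 10_000
        root_count = 4
        observed = np.zeros(model.cap + 1)
        rng = np.random.default_rng(2024)
        for _ in range(draws):
            observed[simulate_counts(tree, root_count, model, rng)["A"]] += 1
        expected = transition_matrix(model, 10.0)[root_count] * draws
        mask = expected > 10
        sigma = np.sqrt(expected[mask] * (1 - expected[mask] / draws))
        assert (np.abs(observed[mask] - expected[mask]) <= 3 * sigma + 1).all()
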