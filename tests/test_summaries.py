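"""Tests for tree and simulation summary statistics."""

import dataclasses
import math

import numpy as np
import pytest
from dendropy.calculate import treemeasure
from scipy import stats

import ephespec as e

from conftest import build_result


def tree_from_newick(s):
    return e.read_newick(s, is_string=True)


class TestLTT:
    def test_single_tip(self):
        curve = e.compute_ltt(tree_from_newick("A:3.0;"))
        assert curve.pairs == [(0.0, 1)]

    def test_three_tip_hand_enumeration(self):
        # splits at depths 1.0 and 2.0, horizon 3.0
        curve = e.compute_ltt(tree_from_newick("((A:1,B:1):1,C:2):1;"))
        assert [(round(t, 9), n) for t, n in curve] == [(0.0, 1), (1.0, 2), (2.0, 3)]

    def test_extinct_tip_decrements(self):
        # splits at 1.0 and 1.5; B dies at depth 2.0; A, C reach 3.0
        curve = e.compute_ltt(tree_from_newick("((A:1.5,B:0.5):0.5,C:2):1;"))
        assert [(round(t, 9), n) for t, n in curve] == [
            (0.0, 1), (1.0, 2), (1.5, 3), (2.0, 2)]

    def test_final_count_equals_tips_for_reconstructed_trees(self):
        params = e.ModelParams(lambda_i=1.0, mu_i=0.5, lambda_f=0.1, t_max=6.0)
        for s in range(20):
            res = e.condition_on_survival(
                dataclasses.replace(params, seed=s * 300), max_tries=100)
            tree = e.collapse_to_species_tree(res, extant_only=True)
            curve = e.compute_ltt(tree, extant_only=True)
            assert curve.pairs[-1][1] == sum(1 for _ in tree.leaf_node_iter())
            assert all(b >= a for (_, a), (_, b) in zip(curve.pairs, curve.pairs[1:]))

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError):
            e.compute_ltt(tree_from_newick("((A:1,B:-1):1,C:2):1;"))

    def test_polytomy_allowed_for_ltt(self):
        curve = e.compute_ltt(tree_from_newick("(A:2,B:2,C:2):1;"))
        assert curve.pairs == [(0.0, 1), (1.0, 3)]


class TestGamma:
    def test_hand_computed_three_tip_value(self):
        # splits at 1.0, 2.0, height 3.0: g2 = g3 = 1, T = 5, T_2 = 2
        # gamma = (2 - 2.5) / (5 * sqrt(1/12)) = -0.34641016...
        tree = tree_from_newick("((A:1,B:1):1,C:2):1;")
        assert e.gamma_statistic(tree) == pytest.approx(-0.34641016151377546)

    def test_matches_independent_implementation_on_simulated_trees(self):
        params = e.ModelParams(lambda_i=1.0, mu_i=0.5, lambda_f=0.1, t_max=8.0)
        checked = 0
        for s in range(12):
            res = e.condition_on_survival(
                dataclasses.replace(params, seed=s * 700), max_tries=100)
            if res.n_species_extant < 3:
                continue
            tree = e.collapse_to_species_tree(res, extant_only=True)
            ours = e.gamma_statistic(tree)
            oracle = treemeasure.pybus_harvey_gamma(tree)
            assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-9)
            checked += 1
        assert checked >= 5

    def test_scale_invariance(self):
        tree = tree_from_newick("(((A:1,B:1):1,C:2):1,D:3):0.5;")
        base = e.gamma_statistic(tree)
        for c in (0.001, 3.7, 1e6):
            scaled = tree_from_newick("(((A:1,B:1):1,C:2):1,D:3):0.5;")
            for nd in scaled.preorder_node_iter():
                if nd.edge.length is not None:
                    nd.edge.length *= c
            assert e.gamma_statistic(scaled) == pytest.approx(base, rel=1e-9)

    def test_requires_three_tips(self):
        with pytest.raises(ValueError):
            e.gamma_statistic(tree_from_newick("(A:1,B:1):1;"))

    def test_requires_ultrametric(self):
        with pytest.raises(ValueError):
            e.gamma_statistic(tree_from_newick("((A:1,B:2):1,C:2):1;"))

    def test_mean_zero_under_fixed_n_pure_birth(self):
        # gamma is centred on 0 for pure-birth trees of fixed tip count:
        # the interval with k lineages is Exp(k * lambda)
        rng = np.random.default_rng(21)
        gammas = []
        for _ in range(500):
            gaps = rng.exponential(1.0 / (np.arange(2, 26)))
            times = np.concatenate([[0.0], np.cumsum(gaps)])
            ages = times[-1] - times[:-1]
            gammas.append(e.gamma_from_branching_ages(ages))
        g = np.array(gammas)
        se = g.std(ddof=1) / math.sqrt(len(g))
        assert abs(g.mean()) < 3 * se

    def test_duration_conditioning_biases_gamma_negative(self):
        # filtering fixed-duration pure-birth trees on a minimum tip
        # count selects clades that grew early, so mean gamma < 0
        params = e.BDParams(lambda_=1.0, mu=0.0, t_max=3.5)
        gammas = []
        s = 0
        while len(gammas) < 300:
            res = e.simulate_bd(dataclasses.replace(params, seed=s))
            s += 1
            if res.event_log.n_alive_final < 20:
                continue
            tree = e.collapse_to_species_tree(res, extant_only=True)
            gammas.append(e.gamma_statistic(tree))
        g = np.array(gammas)
        se = g.std(ddof=1) / math.sqrt(len(g))
        assert g.mean() < -3 * se


def brute_force_colless(tree):
    """Independent Colless computation by explicit tip-set enumeration."""
    leaf_sets = {}
    for nd in tree.postorder_node_iter():
        if not nd.child_nodes():
            leaf_sets[nd] = {nd.taxon.label}
        else:
            kids = nd.child_nodes()
            assert len(kids) == 2
            leaf_sets[nd] = set().union(*(leaf_sets[c] for c in kids))
    return sum(
        abs(len(leaf_sets[nd.child_nodes()[0]]) - len(leaf_sets[nd.child_nodes()[1]]))
        for nd in tree.preorder_internal_node_iter()
    )


def caterpillar(n):
    s = "(A0:1,A1:1)"
    for i in range(2, n):
        s = f"({s}:1,A{i}:{i})"
    return s + ";"


class TestColless:
    def test_balanced_four_tips(self):
        assert e.colless_index(tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")) == 0

    def test_caterpillar_four_tips(self):
        assert e.colless_index(tree_from_newick(caterpillar(4))) == 3

    @pytest.mark.parametrize("n", range(3, 21))
    def test_caterpillar_closed_form(self, n):
        tree = tree_from_newick(caterpillar(n))
        expected = (n - 1) * (n - 2) // 2
        assert e.colless_index(tree) == expected
        assert brute_force_colless(tree) == expected

    def test_polytomy_rejected(self):
        with pytest.raises(ValueError):
            e.colless_index(tree_from_newick("(A:1,B:1,C:1);"))

    def test_matches_brute_force_on_simulated_trees(self):
        params = e.ModelParams(lambda_i=1.0, mu_i=0.5, lambda_f=0.1, t_max=7.0)
        for s in range(10):
            res = e.condition_on_survival(
                dataclasses.replace(params, seed=s * 900), max_tries=100)
            tree = e.collapse_to_species_tree(res, extant_only=True)
            if sum(1 for _ in tree.leaf_node_iter()) < 2:
                continue
            assert e.colless_index(tree) == brute_force_colless(tree)


class TestIncipientDistribution:
    def test_zero_event_replicate(self):
        res = build_result(2.0, [])
        hist = e.incipient_distribution(res, 1.0)
        assert hist.histogram == {1: 1}
        assert hist.skewness is None

    def test_hand_fixture_counts(self):
        # species memberships {1, 1, 1, 5}
        actions = [("branch", 0.1 * i, 0) for i in range(1, 8)]
        actions += [("convert", 1.0, 5), ("convert", 1.1, 6), ("convert", 1.2, 7)]
        res = build_result(2.0, actions)
        hist = e.incipient_distribution(res, 1.5)
        assert hist.histogram == {1: 3, 5: 1}
        assert hist.mean == pytest.approx(2.0)
        assert hist.median == pytest.approx(1.0)
        assert hist.skewness > 0

    def test_no_species_alive_raises(self):
        res = build_result(2.0, [("loss", 0.5, 0)])
        with pytest.raises(ValueError):
            e.incipient_distribution(res, 1.0)

    def test_pooled_distribution_right_skewed(self):
        # a few species hold many incipient forms; most hold few
        params = e.ModelParams(lambda_i=1.0, mu_i=0.5, lambda_f=0.05, t_max=10.0)
        values = []
        n_surv, s = 0, 0
        while n_surv < 120:
            res = e.simulate(dataclasses.replace(params, seed=s))
            s += 1
            if not res.surviving:
                continue
            n_surv += 1
            values.extend(e.species_membership_counts(res, 10.0).values())
        values = np.array(values)
        counts = np.bincount(values)
        assert counts.argmax() == 1  # modal class k = 1
        assert stats.skew(values, bias=False) > 0

    def test_histogram_mass_equals_species_count(self):
        params = e.ModelParams(lambda_i=1.0, mu_i=0.6, lambda_f=0.2, t_max=5.0)
        for s in range(30):
            res = e.simulate(dataclasses.replace(params, seed=s))
            if not res.surviving:
                continue
            hist = e.incipient_distribution(res, 5.0)
            assert hist.n_species == len(e.species_membership_counts(res, 5.0))


class TestEffectiveRates:
    def test_no_conversion_rate_zero(self):
        res = build_result(2.0, [("branch", 0.5, 0)])
        (rates,) = e.effective_rates(res)
        assert rates.speciation_rate == 0.0
        assert rates.n_conversions_from == 0

    def test_hand_exposure_division(self):
        # species 0: 1 lineage on [0, 0.3], 2 on [0.3, 1.1], 1 on [1.1, 1.2]
        # -> exposure 0.3 + 1.6 + 0.1 = 2.0 lineage-Myr, 1 conversion -> 0.5
        res = build_result(1.2, [("branch", 0.3, 0), ("convert", 1.1, 1)])
        rates = {r.species_id: r for r in e.effective_rates(res)}
        assert rates[0].exposure == pytest.approx(2.0)
        assert rates[0].speciation_rate == pytest.approx(0.5)

    def test_extinction_exposure_decreases_with_membership(self):
        actions = [("branch", 0.1 * i, 0) for i in range(1, 5)]
        actions += [("convert", 0.9, 4)]
        res = build_result(2.0, actions)
        rates = {r.species_id: r for r in e.effective_rates(res)}
        # species 0 has 4 members, species 1 has 1: H_4 > H_1
        assert rates[0].extinction_exposure < rates[1].extinction_exposure

    def test_membership_predicts_speciation_rate(self):
        # pooled across replicates: Spearman correlation between final
        # membership and realized conversion rate is positive
        cfg = e.default_config()
        members, rates_ = [], []
        s = 0
        while len(members) < 1000:
            res = e.simulate(dataclasses.replace(cfg.params, seed=s))
            s += 1
            if not res.surviving:
                continue
            for r in e.effective_rates(res):
                members.append(r.n_members_final)
                rates_.append(r.speciation_rate)
        rho = stats.spearmanr(members, rates_)
        assert rho.statistic > 0
        assert rho.pvalue < 0.01
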