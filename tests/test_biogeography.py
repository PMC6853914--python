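"""Dispersal kernel, exact/IS/MC likelihoods, range MCMC, Savage-Dickey,
migration counting, and the Sankoff migration mode."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import cauchy, norm

from oncophylogeo.biogeography import (BiogeographyModel, DispersalModel,
                                       branch_path_log_density,
                                       dispersal_rates, exact_range_likelihood,
                                       is_range_likelihood, _kernel,
                                       naive_likelihood_mc,
                                       sankoff_migration_history,
                                       savage_dickey_bf,
                                       simulate_range_history)
from oncophylogeo.coalescent import sample_coalescent_tree
from oncophylogeo.filtering import SampleGeometry
from oncophylogeo.parsimony import brute_force_min_cost
from oncophylogeo.trees import Tree


class TestDispersalRates:
    def test_distance_independent_when_beta_zero(self, geometry3):
        gain, loss = dispersal_rates([1, 0, 0], geometry3,
                                     DispersalModel(0.7, 0.2, 0.0))
        assert gain[1] == gain[2] == pytest.approx(0.7)

    def test_gain_ratio_follows_power_law(self):
        geo = SampleGeometry(["s", "x", "y"], [[0, 0], [1, 0], [2, 0]],
                             ["r"] * 3)
        for beta in (0.5, 1.7, -1.0):
            gain, _ = dispersal_rates([1, 0, 0], geo,
                                      DispersalModel(1.0, 1.0, beta))
            assert gain[1] / gain[2] == pytest.approx(2.0 ** beta)

    def test_loss_forbidden_for_last_location(self, geometry3):
        _, loss = dispersal_rates([0, 1, 0], geometry3,
                                  DispersalModel(0.5, 0.5, 0.0))
        assert np.all(loss == 0)

    def test_zero_distance_rejected(self):
        geo = SampleGeometry(["a", "b"], [[0, 0], [0, 0]], ["r", "r"])
        with pytest.raises(ValueError, match="jitter"):
            dispersal_rates([1, 0], geo, DispersalModel(1, 1, 1.0))


class TestExactLikelihood:
    def test_single_location(self):
        geo = SampleGeometry(["a"], [[0.0, 0.0]], ["r"])
        tree = Tree([2, 2, -1], [0, 0, 1.0], ["t1", "t2"])
        # with one location the only state is occupancy: likelihood 1
        model = DispersalModel(0.5, 0.5, 0.0)
        ll = exact_range_likelihood(tree, np.array([[1], [1]], bool), geo, model)
        assert ll == pytest.approx(0.0)

    def test_two_locations_hand_built_rate_matrix(self):
        geo = SampleGeometry(["a", "b"], [[0, 0], [1, 0]], ["r", "r"])
        model = DispersalModel(0.4, 0.3, 0.0)
        tree = Tree([2, 2, -1], [0, 0, 1.2], ["t1", "t2"])
        tips = np.array([[1, 0], [0, 1]], bool)
        ll = exact_range_likelihood(tree, tips, geo, model, root_prior="uniform")
        # hand assembly: states {10, 01, 11}; beta=0 so eta=1
        lg, ll_ = 0.4, 0.3
        Q = np.array([
            [-lg, 0.0, lg],          # {a}: gain b
            [0.0, -lg, lg],          # {b}: gain a
            [ll_, ll_, -2 * ll_],    # {a,b}: lose either
        ])
        P = expm(Q * 1.2)
        prior = np.ones(3) / 3
        lik = sum(prior[s] * P[s, 0] * P[s, 1] for s in range(3))
        assert ll == pytest.approx(math.log(lik))

    def test_refuses_large_state_space(self):
        geo = SampleGeometry([f"s{i}" for i in range(5)],
                             np.random.default_rng(0).uniform(size=(5, 2)),
                             ["r"] * 5)
        tree = Tree([2, 2, -1], [0, 0, 1.0], ["t1", "t2"])
        with pytest.raises(ValueError, match="4 locations"):
            exact_range_likelihood(tree, np.ones((2, 5), bool), geo,
                                   DispersalModel(1, 1, 0))


@pytest.fixture(scope="module")
def fixture3():
    geo = SampleGeometry(["a", "b", "c"], [[0, 0], [1, 0], [0, 2]],
                         ["r1", "r1", "r2"])
    tree = Tree([3, 3, 4, 4, -1], [0, 0, 0, 0.8, 1.6],
                ["t1", "t2", "t3"])
    tips = np.array([[1, 0, 0], [0, 1, 0], [0, 1, 1]], bool)
    return geo, tree, tips


class TestSamplerAgainstOracle:

    def test_importance_sampling_matches_exact(self, fixture3):
        geo, tree, tips = fixture3
        for i, model in enumerate([DispersalModel(0.4, 0.3, 1.2),
                                   DispersalModel(0.8, 0.5, -0.8)]):
            exact = exact_range_likelihood(tree, tips, geo, model)
            est, se = is_range_likelihood(tree, tips, geo, model,
                                          n_samples=3000, rng=i)
            assert abs(est - exact) < 4 * se + 0.02

    def test_naive_monte_carlo_matches_exact(self, fixture3):
        geo, tree, tips = fixture3
        model = DispersalModel(0.4, 0.3, 1.2)
        exact = math.exp(exact_range_likelihood(tree, tips, geo, model))
        p, se = naive_likelihood_mc(tree, tips, geo, model, n_sims=40000, rng=5)
        assert abs(p - exact) < 4 * se


class TestRangeMcmc:
    def test_static_tips_pin_root(self, geometry3):
        tree = sample_coalescent_tree(5, n0=100, r=0.0, rng=2,
                                      tip_labels=list("abcde"))
        tips = np.zeros((5, 3), bool)
        tips[:, 0] = True  # everyone only at location 0
        model = BiogeographyModel(tree, tips, geometry3,
                                  prior_mean_gain=0.01, prior_mean_loss=0.01)
        res = model.fit(chain_length=1200, thin=2, burn_in=0.3, seed=0)
        # marginal posterior occupancy of the shared location at the root
        root_occ = np.mean([s[tree.root, 0] for s in res.range_samples])
        assert root_occ > 0.99

    def test_identical_seeds_identical_traces(self, geometry3):
        tree = sample_coalescent_tree(4, n0=50, r=0.0, rng=3,
                                      tip_labels=list("abcd"))
        tips = np.eye(3, dtype=bool)[[0, 1, 2, 0]]
        m1 = BiogeographyModel(tree, tips, geometry3)
        m2 = BiogeographyModel(tree, tips, geometry3)
        r1 = m1.fit(chain_length=600, thin=2, seed=9)
        r2 = m2.fit(chain_length=600, thin=2, seed=9)
        assert np.allclose(r1.trace["beta"], r2.trace["beta"])
        assert np.allclose(r1.trace["log_density"], r2.trace["log_density"])

    def test_history_conservation(self, geometry3):
        # gains and losses along each sampled branch history reconcile the
        # parent and child ranges in every posterior sample
        from oncophylogeo.biogeography import _apply_events

        tree = sample_coalescent_tree(4, n0=50, r=0.0, rng=4,
                                      tip_labels=list("abcd"))
        tips = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]], bool)
        res = BiogeographyModel(tree, tips, geometry3).fit(
            chain_length=800, thin=4, seed=1)
        for ranges, paths in zip(res.range_samples, res.path_samples):
            for node, events in paths.items():
                end = _apply_events(ranges[tree.parent[node]], events)
                assert np.array_equal(end, ranges[node])
            assert np.array_equal(ranges[: 4], tips)


class TestSavageDickey:
    def test_prior_samples_give_unit_bayes_factor(self):
        rng = np.random.default_rng(0)
        x = cauchy.rvs(size=100_000, random_state=rng)
        out = savage_dickey_bf(x, prior_density_at_0=cauchy.pdf(0))
        assert out["bf01"] == pytest.approx(1.0, rel=0.2)

    def test_conjugate_normal_matches_analytic(self):
        # theta ~ N(0, tau2); x_i ~ N(theta, 1): BF01 analytic vs SD estimate
        rng = np.random.default_rng(1)
        tau2, n = 2.0, 20
        x = rng.normal(0.4, 1.0, size=n)
        post_var = 1 / (1 / tau2 + n)
        post_mean = post_var * x.sum()
        samples = rng.normal(post_mean, math.sqrt(post_var), size=50_000)
        out = savage_dickey_bf(samples, prior_density_at_0=norm.pdf(0, 0, math.sqrt(tau2)))
        analytic = norm.pdf(0, post_mean, math.sqrt(post_var)) / \
            norm.pdf(0, 0, math.sqrt(tau2))
        assert out["bf01"] == pytest.approx(analytic, rel=0.1)

    def test_concentrated_posterior_tiny_bf(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(2.0, 0.05, size=20_000)
        out = savage_dickey_bf(samples)
        assert out["bf01"] < 1e-3
        assert out.get("bf01_is_upper_bound", False)

    def test_bandwidth_sensitivity_reported(self):
        rng = np.random.default_rng(3)
        out = savage_dickey_bf(rng.normal(0.3, 0.5, size=20_000))
        assert "bf01_bw_low" in out and "bf01_bw_high" in out


@pytest.fixture(scope="module")
def fitted():
    geo = SampleGeometry(["a", "b", "c"], [[0, 0], [1, 0], [0, 2]],
                         ["r1", "r1", "r2"])
    tree = sample_coalescent_tree(4, n0=50, r=0.0, rng=5,
                                  tip_labels=list("wxyz"))
    tips = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1]], bool)
    res = BiogeographyModel(tree, tips, geo).fit(
        chain_length=1000, thin=2, seed=2)
    return geo, tree, res


class TestAncestralRangesAndMigrations:

    def test_modal_ranges_and_marginals(self, fitted):
        geo, tree, res = fitted
        modal, marginals, labels = res.ancestral_range_map()
        assert modal.shape == (tree.n_nodes, 3)
        assert np.all(marginals.sum(axis=1) >= 1.0 - 1e-9)  # non-empty ranges
        # deterministic at the tips
        assert np.all(marginals[: tree.n_tips][modal[: tree.n_tips]] == 1.0)

    def test_single_region_zero_migrations(self):
        geo = SampleGeometry(["a", "b"], [[0, 0], [1, 0]], ["r1", "r1"])
        tree = sample_coalescent_tree(3, n0=50, r=0.0, rng=6,
                                      tip_labels=list("abc"))
        tips = np.array([[1, 0], [0, 1], [1, 1]], bool)
        res = BiogeographyModel(tree, tips, geo).fit(chain_length=500, thin=2,
                                                     seed=3)
        mean_mig, table = res.count_migrations()
        assert mean_mig == 0.0
        assert len(table) == 0

    def test_migrations_invariant_to_relabeling_within_region(self, fitted):
        geo, tree, res = fitted
        mean1, _ = res.count_migrations()
        # swap the labels of the two locations inside region r1
        relabeled = ["r1", "r1", "r2"]
        mean2, _ = res.count_migrations(regions=relabeled)
        assert mean1 == mean2

    def test_constructed_history_single_migration(self, fitted):
        geo, tree, res = fitted
        from oncophylogeo.biogeography import RangeHistoryResults

        ranges = np.zeros((tree.n_nodes, 3), bool)
        ranges[:, 0] = True
        paths = {n: [] for n in range(tree.n_nodes) if tree.parent[n] >= 0}
        # one gain into region r2 on the branch above tip 0
        paths[0] = [(0.01, 2, +1)]
        ranges[0, 2] = True
        doctored = RangeHistoryResults(res.model, res.trace.iloc[:1],
                                       [ranges], [paths], {}, 0)
        mean_mig, table = doctored.count_migrations()
        assert mean_mig == 1.0
        assert table.iloc[0]["source_region"] == "r1"
        assert table.iloc[0]["target_region"] == "r2"


class TestSankoffMigrations:
    def test_all_primary_zero_migrations(self, tree4):
        out = sankoff_migration_history(tree4, ["colon"] * 4, "colon")
        assert out["min_migrations"] == 0
        assert len(out["labelings"]) == 1

    def test_liver_colon_example(self):
        # ((L1,L2),(C1,C2)) with the root constrained to the colon:
        # exactly one colon->liver migration
        tree = Tree([4, 4, 5, 5, 6, 6, -1], [0, 0, 0, 0, 1.0, 1.0, 2.0],
                    ["L1", "L2", "C1", "C2"])
        out = sankoff_migration_history(
            tree, ["liver", "liver", "colon", "colon"], "colon")
        assert out["min_migrations"] == 1
        assert all(pc == {("colon", "liver"): 1} for pc in out["pair_counts"])

    def test_dp_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        sites = ["colon", "liver", "lymph", "lung"]
        for rep in range(12):
            n = int(rng.integers(3, 7))
            tree = sample_coalescent_tree(n, n0=10, r=0.0, rng=rng)
            labels = [sites[i] for i in rng.integers(0, 4, size=n)]
            out = sankoff_migration_history(tree, labels, "colon",
                                            site_names=sites)
            tips = np.array([sites.index(s) for s in labels])
            brute = brute_force_min_cost(tree, tips, 4, root_state=0)
            assert out["min_migrations"] == brute
            for lab in out["labelings"]:
                changes = sum(lab[tree.parent[x]] != lab[x]
                              for x in range(tree.n_nodes)
                              if tree.parent[x] >= 0)
                assert changes == out["min_migrations"]

    def test_unknown_label_rejected(self, tree4):
        with pytest.raises(ValueError, match="unknown"):
            sankoff_migration_history(tree4, ["colon", "mars", "colon", "colon"],
                                      "colon", site_names=["colon", "liver"])
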