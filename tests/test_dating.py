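"""Divergence-time MCMC, calendar conversion, doubling time, path sampling."""

import math

import numpy as np
import pandas as pd
import pytest

from oncophylogeo.coalescent import sample_coalescent_tree
from oncophylogeo.dating import (CloneDatingModel, calendar_conversion,
                                 doubling_time, path_sampling, run_mcmc)
from oncophylogeo.likelihood import Alignment, ClockModel, simulate_snv_alignment


@pytest.fixture(scope="module")
def small_run():
    rng = np.random.default_rng(10)
    tree = sample_coalescent_tree(8, n0=500, r=0.01, rng=rng)
    aln, n_const = simulate_snv_alignment(tree, 50_000,
                                          clock=ClockModel("strict", 2e-6),
                                          rng=rng)
    model = CloneDatingModel(aln, clock_rate=2e-6,
                             tree_prior="exponential_growth",
                             ascertainment="constant_site_weights",
                             constant_weights=float(n_const),
                             init_tree=tree)
    res = model.fit(chain_length=4000, thin=10, burn_in=0.2, seed=3)
    return tree, aln, n_const, res


def test_identical_seeds_identical_traces(small_run):
    tree, aln, n_const, res = small_run
    model = CloneDatingModel(aln, clock_rate=2e-6,
                             tree_prior="exponential_growth",
                             ascertainment="constant_site_weights",
                             constant_weights=float(n_const), init_tree=tree)
    res2 = model.fit(chain_length=4000, thin=10, burn_in=0.2, seed=3)
    pd.testing.assert_frame_equal(res.trace, res2.trace)


def test_posterior_tracks_truth_roughly(small_run):
    tree, _, _, res = small_run
    med = res.trace["tmrca"].median()
    assert 0.4 * tree.heights.max() < med < 2.5 * tree.heights.max()


def test_mcc_tree_from_results(small_run):
    _, _, _, res = small_run
    summary, support = res.mcc_tree(min_trees=100)
    assert summary.n_tips == 8
    assert all(0 < s <= 1 for s in support.values())


def test_run_mcmc_functional_wrapper():
    rng = np.random.default_rng(1)
    tree = sample_coalescent_tree(5, n0=100, r=0.0, rng=rng)
    aln, n_const = simulate_snv_alignment(
        tree, 5000, clock=ClockModel("strict", 2e-5), rng=rng)
    res = run_mcmc(aln, model_spec={
        "clock_rate": 2e-5, "tree_prior": "constant",
        "ascertainment": "constant_site_weights",
        "constant_weights": float(n_const)},
        chain={"length": 800, "thin": 10, "seed": 5})
    assert len(res.trace) > 50
    assert "tmrca" in res.trace


def test_relaxed_clock_runs_and_mixes():
    rng = np.random.default_rng(2)
    tree = sample_coalescent_tree(5, n0=200, r=0.0, rng=rng)
    aln, n_const = simulate_snv_alignment(
        tree, 10_000, clock=ClockModel("strict", 1e-5), rng=rng)
    model = CloneDatingModel(aln, clock_rate=1e-5,
                             clock_kind="relaxed_exponential",
                             tree_prior="constant",
                             ascertainment="constant_site_weights",
                             constant_weights=float(n_const), init_tree=tree)
    res = model.fit(chain_length=2000, thin=10, burn_in=0.2, seed=1)
    assert np.isfinite(res.trace["posterior"]).all()


# ---------------------------------------------------------------- calendar
def test_calendar_conversion_arithmetic():
    trace = pd.DataFrame({"tmrca": [91.3125]})
    df, summary = calendar_conversion(trace, generation_days=4.0)
    assert df["tmrca_years"].iloc[0] == pytest.approx(1.0)


def test_calendar_hpd_of_constant_trace():
    trace = pd.DataFrame({"tmrca": np.full(50, 200.0)})
    _, summary = calendar_conversion(trace, generation_days=4.0)
    lo, hi = summary["tmrca_years"]["hpd95"]
    assert lo == hi == pytest.approx(200 * 4 / 365.25)


def test_relative_divergence_computed_per_sample():
    # asymmetric joint trace: median of differences != difference of medians
    tmrca = np.array([10.0, 20.0, 30.0])
    mmrca = np.array([8.0, 4.0, 9.0])
    df, summary = calendar_conversion(pd.DataFrame({"tmrca": tmrca, "mmrca": mmrca}))
    diff = df["relative_divergence_years"]
    med_of_diff = np.median(diff)
    diff_of_med = np.median(df["tmrca_years"]) - np.median(df["mmrca_years"])
    assert med_of_diff != pytest.approx(diff_of_med)
    expected = np.median((tmrca - mmrca) * 4 / 365.25)
    assert med_of_diff == pytest.approx(expected)


def test_calendar_conversion_from_substitutions():
    trace = pd.DataFrame({"tmrca": [4.6e-10 * 91.3125]})
    df, _ = calendar_conversion(trace, mu=4.6e-10, heights_in="substitutions")
    assert df["tmrca_years"].iloc[0] == pytest.approx(1.0)


# ---------------------------------------------------------------- doubling
def test_doubling_time_values():
    assert doubling_time(math.log(2), 4.0) == pytest.approx(4.0)
    assert doubling_time(0.013862943611, 4.0) == pytest.approx(200.0, rel=1e-9)


def test_doubling_time_monotone_decreasing():
    r = np.linspace(0.001, 0.1, 50)
    d = doubling_time(r)
    assert np.all(np.diff(d) < 0)


def test_doubling_time_invalid():
    with pytest.raises(ValueError):
        doubling_time(0.0)
    with pytest.raises(ValueError):
        doubling_time(np.array([0.01, -0.02]))


# ---------------------------------------------------------------- path sampling
class NormalToy:
    """Conjugate normal model: theta ~ N(0, tau2), x | theta ~ N(theta, s2)."""

    def __init__(self, x, tau2=4.0, s2=1.0):
        self.x = np.asarray(x, dtype=float)
        self.tau2, self.s2 = tau2, s2

    def log_marginal(self):
        n = len(self.x)
        from scipy.stats import multivariate_normal

        cov = self.s2 * np.eye(n) + self.tau2 * np.ones((n, n))
        return float(multivariate_normal(np.zeros(n), cov).logpdf(self.x))

    # adapter protocol
    def init_state(self, rng):
        return {"theta": rng.normal(0, math.sqrt(self.tau2)), "ll": None}

    def log_lik(self, state):
        th = state["theta"]
        return float(-0.5 * np.sum((self.x - th) ** 2) / self.s2
                     - 0.5 * len(self.x) * math.log(2 * math.pi * self.s2))

    def step(self, state, rng, beta):
        th = state["theta"]
        prop = th + 0.8 * rng.standard_normal()
        def logpost(t):
            lp = -0.5 * t * t / self.tau2
            ll = (-0.5 * np.sum((self.x - t) ** 2) / self.s2
                  - 0.5 * len(self.x) * math.log(2 * math.pi * self.s2))
            return lp + beta * ll
        if math.log(rng.random()) < logpost(prop) - logpost(th):
            state = {"theta": prop}
        return state


def test_path_sampling_matches_conjugate_marginal():
    rng = np.random.default_rng(6)
    toy = NormalToy(rng.normal(1.0, 1.0, size=12))
    est = path_sampling(toy, n_steps=24, chain_len=6000, seed=2)
    assert est == pytest.approx(toy.log_marginal(), abs=0.1)


def test_same_model_bayes_factor_near_zero():
    rng = np.random.default_rng(7)
    toy = NormalToy(rng.normal(0.5, 1.0, size=10))
    a = path_sampling(toy, n_steps=12, chain_len=2500, seed=3)
    b = path_sampling(toy, n_steps=12, chain_len=2500, seed=11)
    assert abs(a - b) < 0.2


def test_path_sampling_requires_enough_rungs():
    toy = NormalToy([0.0])
    with pytest.raises(ValueError):
        path_sampling(toy, n_steps=4)
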