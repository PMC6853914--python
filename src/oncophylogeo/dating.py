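"""Bayesian divergence-time inference on clone sequences.

A :class:`CloneDatingModel` combines the pruning likelihood (optionally
conditioned on variable sites, the SNV ascertainment correction), a strict
or exponential relaxed clock, and a coalescent tree prior (constant size,
exponential growth, or Bayesian skyline) into a Metropolis-Hastings sampler
over node heights, topology, clock and demographic parameters.  ``fit``
returns a :class:`DatingResults` carrying the trace and sampled trees, with
maximum-clade-credibility summarization, calendar conversion (generations
-> years via the generation time), growth-to-doubling-time conversion, and
path-sampling marginal likelihoods for model comparison by Bayes factors.

Chain-length defaults are desk-scale; the study-scale settings (1e8 steps
sampled every 2000) remain reachable through the same arguments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import CoalescentPrior, coalescent_log_density
from .diagnostics import hpd_interval, trace_diagnostics
from .likelihood import Alignment, ClockModel, tree_log_likelihood
from .trees import Tree, mcc_tree

log = logging.getLogger("oncophylogeo.dating")

__all__ = [
    "CloneDatingModel",
    "DatingResults",
    "run_mcmc",
    "path_sampling",
    "path_sampling_marginal",
    "calendar_conversion",
    "doubling_time",
]

DAYS_PER_YEAR = 365.25


# ======================================================================
class _State:
    """Mutable sampler state with cached posterior terms."""

    __slots__ = ("tree", "r", "log_n0", "log_rate", "mult", "ne", "gs",
                 "loglik", "logprior")

    def copy(self):
        s = _State()
        s.tree = self.tree.copy()
        s.r = self.r
        s.log_n0 = self.log_n0
        s.log_rate = self.log_rate
        s.mult = None if self.mult is None else self.mult.copy()
        s.ne = None if self.ne is None else self.ne.copy()
        s.gs = None if self.gs is None else self.gs.copy()
        s.loglik = self.loglik
        s.logprior = self.logprior
        return s


@dataclass
class CloneDatingModel:
    """Divergence-time model for a clone alignment.

    Parameters
    ----------
    alignment : Alignment
        Clone sequences (tips of the genealogy).
    subst : {"JC69", "HKY"}
    clock_kind : {"strict", "relaxed_exponential"}
        Relaxed clocks draw i.i.d. exponential branch-rate multipliers with
        mean 1 around the mean clock rate.
    clock_rate : float
        Mean clock rate in substitutions/site/generation (the prior median
        when the rate is sampled).
    sample_rate : bool
        Sample the mean rate (lognormal prior, sd ``rate_prior_sd`` in log
        space) instead of fixing it.
    tree_prior : {"constant", "exponential_growth", "skyline"}
    r_prior_scale : float
        Scale of the Laplace(0, scale) prior on the growth rate.
    n0_bounds : tuple
        Support of the log-uniform prior on N0 (and on the first skyline Ne).
    n_groups : int
        Skyline group count (tree_prior="skyline").
    ascertainment : {"variable_sites_only", "constant_site_weights", "none"}
    constant_weights : float or array, optional
        Invariant-site weights for ascertainment="constant_site_weights"
        (e.g. target size minus the number of SNVs).
    fixed_topology : bool
        Restrict moves to node heights and parameters.
    """

    alignment: Alignment
    subst: str = "JC69"
    clock_kind: str = "strict"
    clock_rate: float = 4.6e-10
    sample_rate: bool = False
    rate_prior_sd: float = 0.3
    tree_prior: str = "exponential_growth"
    r_prior_scale: float = 0.1
    n0_bounds: tuple = (1.0, 1e12)
    n_groups: int = 5
    ascertainment: str = "variable_sites_only"
    constant_weights: object = None
    fixed_topology: bool = False
    init_tree: Tree | None = None
    likelihood_off: bool = False

    def __post_init__(self):
        if self.tree_prior not in ("constant", "exponential_growth", "skyline"):
            raise ValueError(f"unknown tree prior {self.tree_prior!r}")
        if self.alignment.n_seqs > 64:
            raise ValueError("topology search is limited to <= 64 tips")
        if self.tree_prior == "skyline" and self.n_groups < 2:
            raise ValueError("skyline requires at least 2 groups")
        if self.tree_prior == "skyline" and self.n_groups > self.alignment.n_seqs - 1:
            raise ValueError("n_groups must be <= n_tips - 1")

    # -------------------------------------------------- posterior terms
    def _clock(self, state) -> ClockModel:
        rate = math.exp(state.log_rate)
        if self.clock_kind == "relaxed_exponential":
            return ClockModel("relaxed_exponential", rate,
                              branch_rates=rate * state.mult)
        return ClockModel("strict", rate)

    def _lik_setup(self, tree):
        """Cache patterns, tip partials and the substitution model."""
        from .likelihood import _get_model, tip_partials

        aln = self.alignment.subset(tree.tip_labels)
        patterns, weights = aln.patterns()
        model = _get_model(self.subst)
        if self.ascertainment != "none":
            const = np.tile(np.arange(4, dtype=np.int8)[None, :],
                            (tree.n_tips, 1))
            patterns = np.concatenate([patterns, const], axis=1)
        cw = self.constant_weights
        if self.ascertainment == "constant_site_weights":
            if cw is None:
                raise ValueError("constant_site_weights requires constant_weights")
            cw = np.asarray(cw, dtype=float)
            if cw.ndim == 0:
                cw = float(cw) * model.freqs
        self._cache = {
            "patterns": patterns, "weights": weights, "model": model,
            "tips": tip_partials(patterns), "cw": cw,
        }

    def _log_lik(self, state) -> float:
        if self.likelihood_off:
            return 0.0
        from .likelihood import pattern_log_likelihoods

        if not hasattr(self, "_cache"):
            self._lik_setup(state.tree)
        c = self._cache
        tree = state.tree
        rates = self._clock(state).rates(tree.n_nodes)
        branch_subs = tree.branch_lengths * rates
        logs = pattern_log_likelihoods(tree, branch_subs, c["patterns"],
                                       c["model"], tips=c["tips"])
        if np.any(~np.isfinite(logs)):
            return -np.inf
        n_data = len(c["weights"])
        ll = float(np.dot(c["weights"], logs[:n_data]))
        if self.ascertainment == "variable_sites_only":
            cl = logs[n_data:]
            mx = cl.max()
            logp_const = float(mx + np.log(np.exp(cl - mx).sum()))
            if logp_const >= 0:
                return -np.inf
            ll -= c["weights"].sum() * np.log1p(-np.exp(logp_const))
        elif self.ascertainment == "constant_site_weights":
            ll += float(np.dot(c["cw"], logs[n_data:]))
        return ll

    def _coal_prior(self, state) -> CoalescentPrior:
        if self.tree_prior == "skyline":
            return CoalescentPrior("skyline", n0=1.0, ne_values=state.ne,
                                   group_sizes=state.gs)
        return CoalescentPrior(self.tree_prior, n0=math.exp(state.log_n0),
                               r=state.r if self.tree_prior == "exponential_growth" else 0.0)

    def _log_prior(self, state) -> float:
        lp = coalescent_log_density(state.tree, self._coal_prior(state))
        lo, hi = math.log(self.n0_bounds[0]), math.log(self.n0_bounds[1])
        if self.tree_prior == "skyline":
            # log-uniform on the first Ne, exponential Markov smoothing after
            lne = np.log(state.ne)
            if not (lo <= lne[0] <= hi):
                return -np.inf
            for i in range(1, len(state.ne)):
                lp += -state.ne[i] / state.ne[i - 1] - math.log(state.ne[i - 1])
        else:
            if not (lo <= state.log_n0 <= hi):
                return -np.inf
            if self.tree_prior == "exponential_growth":
                lp += -abs(state.r) / self.r_prior_scale - math.log(2 * self.r_prior_scale)
        if self.sample_rate:
            mu0 = math.log(self.clock_rate)
            lp += -0.5 * ((state.log_rate - mu0) / self.rate_prior_sd) ** 2
        if self.clock_kind == "relaxed_exponential":
            if np.any(state.mult <= 0):
                return -np.inf
            lp += -state.mult.sum()  # i.i.d. Exp(1) multipliers
        return float(lp)

    # -------------------------------------------------- initialization
    def init_state(self, rng) -> _State:
        state = _State()
        if self.init_tree is not None:
            state.tree = self.init_tree.copy()
        else:
            from .coalescent import sample_coalescent_tree

            # quick NJ-free start: random coalescent tree at a rough scale
            p_div = 0.1 + 0.4 * rng.random()
            rough = max(p_div / max(math.exp(math.log(self.clock_rate)), 1e-300), 1.0)
            state.tree = sample_coalescent_tree(
                self.alignment.n_seqs, n0=rough, r=0.0, rng=rng,
                tip_labels=list(self.alignment.names))
        state.r = 0.01 * rng.random() if self.tree_prior == "exponential_growth" else 0.0
        root_h = state.tree.heights.max()
        state.log_n0 = min(max(math.log(max(root_h, 1.0)),
                               math.log(self.n0_bounds[0])),
                           math.log(self.n0_bounds[1]))
        state.log_rate = math.log(self.clock_rate)
        state.mult = (np.ones(state.tree.n_nodes)
                      if self.clock_kind == "relaxed_exponential" else None)
        if self.tree_prior == "skyline":
            n_int = self.alignment.n_seqs - 1
            base = n_int // self.n_groups
            gs = np.full(self.n_groups, base)
            gs[: n_int - base * self.n_groups] += 1
            state.gs = gs
            state.ne = np.full(self.n_groups, max(root_h, 1.0))
        else:
            state.gs = state.ne = None
        state.loglik = self._log_lik(state)
        state.logprior = self._log_prior(state)
        return state

    # -------------------------------------------------- proposal moves
    def _moves(self):
        moves = [("node_height", 3.0), ("root_scale", 2.0), ("tree_scale", 1.0)]
        if self.likelihood_off and self.tree_prior != "skyline":
            # exact Gibbs resample of the genealogy from the coalescent prior
            moves += [("tree_gibbs", 3.0)]
        if not self.fixed_topology:
            moves += [("narrow_exchange", 2.0), ("wide_exchange", 1.0)]
        if self.tree_prior == "exponential_growth":
            moves += [("r_walk", 1.5), ("r_retime", 1.5), ("r_retime_prior", 1.0),
                      ("n0_scale", 0.5), ("n0_retime", 1.5)]
        elif self.tree_prior == "constant":
            moves += [("n0_scale", 1.0)]
        else:
            moves += [("ne_scale", 2.0), ("group_shift", 1.0)]
        if self.sample_rate:
            moves += [("rate_scale", 1.0), ("updown", 1.0)]
        if self.clock_kind == "relaxed_exponential":
            moves += [("mult_scale", 2.0)]
        return moves

    def _propose(self, state, name, rng, steps):
        """Return (new_state, log_hastings) or (None, None) if invalid."""
        new = state.copy()
        tree = new.tree
        n_tips = tree.n_tips
        if name == "tree_gibbs":
            from .coalescent import sample_coalescent_tree

            try:
                t = sample_coalescent_tree(
                    n_tips, n0=math.exp(new.log_n0),
                    r=new.r if self.tree_prior == "exponential_growth" else 0.0,
                    rng=rng, tip_labels=tree.tip_labels)
            except ValueError:
                return None, None
            new.tree = t
            # exact conditional draw: Hastings ratio cancels the prior ratio
            return new, -(self._log_prior(new) - self._log_prior(state))
        if name == "node_height":
            internal = [n for n in range(n_tips, tree.n_nodes) if n != tree.root]
            if not internal:
                name = "root_scale"
            else:
                node = int(rng.choice(internal))
                ch = np.flatnonzero(tree.parent == node)
                lo = tree.heights[ch].max()
                hi = tree.heights[tree.parent[node]]
                if hi <= lo:
                    return None, None
                tree.heights[node] = lo + (hi - lo) * rng.random()
                return new, 0.0
        if name == "root_scale":
            root = tree.root
            f = math.exp(steps["root_scale"] * (rng.random() - 0.5))
            ch = np.flatnonzero(tree.parent == root)
            lo = tree.heights[ch].max()
            h = tree.heights[root] * f
            if h <= lo:
                return None, None
            tree.heights[root] = h
            return new, math.log(f)
        if name == "tree_scale":
            f = math.exp(steps["tree_scale"] * (rng.random() - 0.5))
            tree.heights[n_tips:] *= f
            return new, (tree.n_nodes - n_tips) * math.log(f)
        if name == "narrow_exchange":
            # swap a node with its uncle when heights permit
            cand = [n for n in range(tree.n_nodes)
                    if tree.parent[n] >= 0 and tree.parent[tree.parent[n]] >= 0]
            if not cand:
                return None, None
            x = int(rng.choice(cand))
            p = tree.parent[x]
            g = tree.parent[p]
            uncles = [u for u in np.flatnonzero(tree.parent == g) if u != p]
            u = uncles[0]
            if tree.heights[p] <= tree.heights[u]:
                return None, None
            tree.parent[x], tree.parent[u] = g, p
            return new, 0.0
        if name == "wide_exchange":
            i, j = rng.integers(0, tree.n_nodes, size=2)
            if i == j or tree.parent[i] < 0 or tree.parent[j] < 0:
                return None, None
            pi, pj = tree.parent[i], tree.parent[j]
            if pi == pj:
                return None, None
            # ancestry check
            a = pi
            anc_i = set()
            while a >= 0:
                anc_i.add(a)
                a = tree.parent[a]
            if j in anc_i or i == pj:
                return None, None
            a = pj
            while a >= 0:
                if a == i:
                    return None, None
                a = tree.parent[a]
            if tree.heights[pi] <= tree.heights[j] or tree.heights[pj] <= tree.heights[i]:
                return None, None
            tree.parent[i], tree.parent[j] = pj, pi
            return new, 0.0
        if name == "r_walk":
            new.r = state.r + steps["r_walk"] * rng.standard_normal()
            return new, 0.0
        if name in ("r_retime", "r_retime_prior", "n0_retime"):
            # move (r, N0) while holding the tree's standard-coalescent
            # coordinates tau fixed: heights are remapped deterministically,
            # which removes the (rate, heights) posterior ridge.  The
            # coalescent-density change cancels against the Jacobian, so
            # only hyperpriors (and the likelihood) decide acceptance.
            r_old = state.r
            n0_old = math.exp(state.log_n0)
            h = tree.heights[n_tips:].copy()
            if r_old * h.max() > 700:
                return None, None
            if r_old == 0.0:
                tau = h / n0_old
            else:
                tau = np.expm1(r_old * h) / (r_old * n0_old)
            log_q = 0.0
            r_new, n0_new = r_old, n0_old
            if name == "r_retime":
                r_new = r_old + steps["r_retime"] * rng.standard_normal()
            elif name == "r_retime_prior":
                u = rng.random() - 0.5
                r_new = -self.r_prior_scale * math.copysign(
                    math.log1p(-2 * abs(u)), u)
                log_q = (abs(r_new) - abs(r_old)) / self.r_prior_scale
            else:
                n0_new = n0_old * math.exp(steps["n0_retime"] * (rng.random() - 0.5))
                new.log_n0 = math.log(n0_new)
            arg = r_new * n0_new * tau
            if np.any(arg <= -1.0 + 1e-12):
                return None, None  # non-coalescing under the proposal
            if r_new == 0.0:
                h_new = n0_new * tau
            else:
                h_new = np.log1p(arg) / r_new
            if not np.all(np.isfinite(h_new)):
                return None, None
            tree.heights[n_tips:] = h_new
            new.r = r_new
            log_jac = float(np.sum((r_old * h - math.log(n0_old))
                                   - (r_new * h_new - math.log(n0_new))))
            return new, log_jac + log_q
        if name == "n0_scale":
            new.log_n0 = state.log_n0 + steps["n0_scale"] * (rng.random() - 0.5)
            return new, 0.0  # uniform prior on log n0
        if name == "ne_scale":
            i = int(rng.integers(len(new.ne)))
            f = math.exp(steps["ne_scale"] * (rng.random() - 0.5))
            new.ne[i] *= f
            return new, math.log(f)
        if name == "group_shift":
            i = int(rng.integers(len(new.gs) - 1))
            d = 1 if rng.random() < 0.5 else -1
            new.gs[i] += d
            new.gs[i + 1] -= d
            if new.gs[i] < 1 or new.gs[i + 1] < 1:
                return None, None
            return new, 0.0
        if name == "rate_scale":
            new.log_rate = state.log_rate + steps["rate_scale"] * (rng.random() - 0.5)
            return new, 0.0
        if name == "updown":
            f = math.exp(steps["updown"] * (rng.random() - 0.5))
            tree.heights[n_tips:] *= f
            new.log_rate = state.log_rate - math.log(f)
            return new, (tree.n_nodes - n_tips - 1) * math.log(f)
        if name == "mult_scale":
            b = int(rng.integers(tree.n_nodes))
            f = math.exp(steps["mult_scale"] * (rng.random() - 0.5))
            new.mult[b] *= f
            return new, math.log(f)
        raise AssertionError(name)

    def step(self, state, rng, steps, beta: float = 1.0, moves=None):
        """One Metropolis-Hastings update; returns (state, move, accepted)."""
        moves = moves or self._move_cache
        names, weights = moves
        name = names[rng.choice(len(names), p=weights)]
        new, log_h = self._propose(state, name, rng, steps)
        if new is None:
            return state, name, False
        new.logprior = self._log_prior(new)
        if not np.isfinite(new.logprior):
            return state, name, False
        new.loglik = self._log_lik(new)
        delta = beta * (new.loglik - state.loglik) + new.logprior - state.logprior
        if math.log(rng.random()) < delta + log_h:
            return new, name, True
        return state, name, False

    # -------------------------------------------------- main sampler
    def fit(self, chain_length: int = 20000, thin: int = 20,
            burn_in: float = 0.1, seed: int = 0) -> "DatingResults":
        """Run the MCMC and return a results object (post burn-in samples)."""
        if not 0 <= burn_in < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")
        rng = np.random.default_rng(seed)
        state = self.init_state(rng)
        names = [m[0] for m in self._moves()]
        weights = np.array([m[1] for m in self._moves()])
        self._move_cache = (names, weights / weights.sum())
        steps = {"root_scale": 0.4, "tree_scale": 0.3, "r_walk": 0.05,
                 "r_retime": 0.05, "n0_retime": 2.0,
                 "n0_scale": 2.0, "ne_scale": 2.0, "rate_scale": 0.5,
                 "updown": 0.3, "mult_scale": 0.8}
        acc = {n: 0 for n in names}
        tries = {n: 0 for n in names}
        adapt_until = int(burn_in * chain_length)
        rows = []
        trees = []
        for it in range(chain_length):
            state, name, ok = self.step(state, rng, steps)
            tries[name] += 1
            acc[name] += ok
            if it < adapt_until and name in steps and tries[name] % 25 == 0:
                rate = acc[name] / tries[name]
                steps[name] *= math.exp(0.5 * (rate - 0.3))
            if (it + 1) % thin == 0:
                row = {
                    "sample": it + 1,
                    "posterior": state.loglik + state.logprior,
                    "loglik": state.loglik,
                    "logprior": state.logprior,
                    "tmrca": state.tree.heights[state.tree.root],
                    "tree_length": state.tree.branch_lengths.sum(),
                    "clock_rate": math.exp(state.log_rate),
                }
                if self.tree_prior == "exponential_growth":
                    row["growth_rate"] = state.r
                    row["n0"] = math.exp(state.log_n0)
                elif self.tree_prior == "constant":
                    row["n0"] = math.exp(state.log_n0)
                else:
                    for i, v in enumerate(state.ne):
                        row[f"ne{i}"] = v
                rows.append(row)
                trees.append((state.tree.copy(),
                              None if state.ne is None else state.ne.copy(),
                              None if state.gs is None else state.gs.copy()))
        rates = {n: acc[n] / max(tries[n], 1) for n in names}
        overall = sum(acc.values()) / max(sum(tries.values()), 1)
        if not 0.01 < overall < 0.9:
            log.warning("overall acceptance rate %.3f outside (0.01, 0.9)", overall)
        trace = pd.DataFrame(rows)
        start = int(burn_in * len(trace))
        return DatingResults(
            model=self,
            trace=trace.iloc[start:].reset_index(drop=True),
            trees=[t for t, _, _ in trees[start:]],
            skyline_samples=[(n, g) for _, n, g in trees[start:]]
            if self.tree_prior == "skyline" else None,
            acceptance=rates, seed=seed,
        )

    # -------------------------------------------------- path sampling
    def path_sampling_marginal(self, n_steps: int = 12, chain_len: int = 1500,
                               seed: int = 0) -> float:
        """Log marginal likelihood by path sampling (see :func:`path_sampling`)."""
        names = [m[0] for m in self._moves()]
        weights = np.array([m[1] for m in self._moves()])
        self._move_cache = (names, weights / weights.sum())
        steps = {"root_scale": 0.4, "tree_scale": 0.3, "r_walk": 0.05,
                 "r_retime": 0.05, "n0_retime": 2.0,
                 "n0_scale": 2.0, "ne_scale": 2.0, "rate_scale": 0.5,
                 "updown": 0.3, "mult_scale": 0.8}

        class _Adapter:
            def init_state(adapter, rng):
                return self.init_state(rng)

            def step(adapter, state, rng, beta):
                out, _, _ = self.step(state, rng, steps, beta=beta)
                return out

            def log_lik(adapter, state):
                return state.loglik

        return path_sampling(_Adapter(), n_steps=n_steps, chain_len=chain_len,
                             seed=seed)


# ======================================================================
def path_sampling(adapter, n_steps: int = 12, chain_len: int = 1500,
                  seed: int = 0, beta_shape: float = 0.3,
                  burn_frac: float = 0.3) -> float:
    """Thermodynamic-integration estimate of the log marginal likelihood.

    Runs MCMC chains targeting the power posteriors ``prior * lik^beta_k``
    at inverse temperatures spaced as quantiles of Beta(beta_shape, 1)
    (denser near the prior), warm-starting each rung from the previous one,
    and integrates the mean log-likelihood over beta by the trapezoid rule.

    ``adapter`` must provide ``init_state(rng)``, ``step(state, rng, beta)``
    and ``log_lik(state)``.
    """
    if n_steps < 8:
        raise ValueError("need at least 8 path-sampling steps")
    rng = np.random.default_rng(seed)
    betas = (np.arange(n_steps) / (n_steps - 1)) ** (1.0 / beta_shape)
    state = adapter.init_state(rng)
    means = []
    for beta in betas:
        lls = []
        burn = int(burn_frac * chain_len)
        for it in range(chain_len):
            state = adapter.step(state, rng, beta)
            if it >= burn:
                lls.append(adapter.log_lik(state))
        m = float(np.mean(lls))
        if not np.isfinite(m):
            raise RuntimeError(
                f"non-finite mean log-likelihood at rung beta={beta:.4f}")
        means.append(m)
    return float(np.trapezoid(means, betas))


def path_sampling_marginal(alignment, n_steps: int = 12, chain_len: int = 1500,
                           seed: int = 0, **model_kwargs) -> float:
    """Convenience wrapper: marginal likelihood of a dating model spec."""
    model = CloneDatingModel(alignment, **model_kwargs)
    return model.path_sampling_marginal(n_steps=n_steps, chain_len=chain_len,
                                        seed=seed)


# ======================================================================
@dataclass
class DatingResults:
    """Posterior trace, sampled trees, and summaries of a dating run."""

    model: CloneDatingModel
    trace: pd.DataFrame
    trees: list
    skyline_samples: list | None
    acceptance: dict
    seed: int

    def hpd(self, param: str, mass: float = 0.95):
        return hpd_interval(self.trace[param].to_numpy(), mass)

    def ess(self) -> dict:
        cols = [c for c in self.trace.columns if c != "sample"]
        return trace_diagnostics(self.trace[cols])

    def mcc_tree(self, min_trees: int = 100):
        if len(self.trees) < min_trees:
            raise ValueError(f"need >= {min_trees} post-burn-in trees")
        return mcc_tree(self.trees)

    def clade_mrca_samples(self, tip_labels) -> np.ndarray:
        """Per-sample MRCA height (generations) of the given tips."""
        idx = [self.trees[0].tip_labels.index(t) for t in tip_labels]
        return np.array([t.heights[t.mrca(idx)] for t in self.trees])

    def summary(self, generation_days: float = 4.0) -> pd.DataFrame:
        rows = []
        for col in self.trace.columns:
            if col in ("sample",):
                continue
            x = self.trace[col].to_numpy()
            lo, hi = hpd_interval(x) if len(x) >= 10 else (np.nan, np.nan)
            rows.append({"parameter": col, "median": float(np.median(x)),
                         "mean": float(np.mean(x)),
                         "hpd95_lower": lo, "hpd95_upper": hi})
        tm = self.trace["tmrca"].to_numpy() * generation_days / DAYS_PER_YEAR
        lo, hi = hpd_interval(tm) if len(tm) >= 10 else (np.nan, np.nan)
        rows.append({"parameter": "tmrca_years", "median": float(np.median(tm)),
                     "mean": float(np.mean(tm)), "hpd95_lower": lo,
                     "hpd95_upper": hi})
        return pd.DataFrame(rows).set_index("parameter")


def run_mcmc(alignment, model_spec: dict | None = None, chain: dict | None = None):
    """Functional entry point: build a dating model and run its chain."""
    model = CloneDatingModel(alignment, **(model_spec or {}))
    chain = chain or {}
    return model.fit(
        chain_length=chain.get("length", 20000), thin=chain.get("thin", 20),
        burn_in=chain.get("burn_in", 0.1), seed=chain.get("seed", 0))


# ======================================================================
def calendar_conversion(trace, mu: float = 4.6e-10, generation_days: float = 4.0,
                        heights_in: str = "generations", columns=None):
    """Convert height columns of a trace to years before sampling.

    ``heights_in="substitutions"`` first divides by ``mu``; conversion is
    then ``years = generations * generation_days / 365.25``.  When both
    ``tmrca`` and ``mmrca`` columns are present the derived relative
    divergence ``tmrca - mmrca`` is computed per posterior sample (never as
    a difference of summaries).  Returns ``(converted_trace, summary)``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if generation_days <= 0:
        raise ValueError("generation time must be positive")
    if heights_in not in ("generations", "substitutions"):
        raise ValueError("heights_in must be 'generations' or 'substitutions'")
    df = trace.copy()
    if columns is None:
        columns = [c for c in df.columns
                   if c in ("tmrca", "mmrca") or c.endswith("_height")]
    factor = generation_days / DAYS_PER_YEAR
    for c in columns:
        x = df[c].to_numpy(dtype=float)
        if heights_in == "substitutions":
            x = x / mu
        df[c + "_years"] = x * factor
    if "tmrca_years" in df.columns and "mmrca_years" in df.columns:
        df["relative_divergence_years"] = df["tmrca_years"] - df["mmrca_years"]
    summary = {}
    for c in df.columns:
        if c.endswith("_years"):
            x = df[c].to_numpy()
            lo, hi = hpd_interval(x) if len(x) >= 10 else (float(x.min()), float(x.max()))
            summary[c] = {"median": float(np.median(x)),
                          "hpd95": [lo, hi]}
    return df, summary


def doubling_time(r, generation_days: float = 4.0):
    """Population doubling time in days, ``generation_days * ln 2 / r``.

    Accepts a scalar or an array of posterior draws (per-draw conversion;
    summarize afterwards by the median).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("doubling time is undefined for r <= 0")
    out = generation_days * math.log(2) / r
    return float(out) if out.ndim == 0 else out
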