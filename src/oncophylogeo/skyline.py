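"""Bayesian skyline reconstruction of effective population size.

The skyline tree prior models Ne(t) as piecewise constant over groups of
consecutive coalescent intervals; the MCMC (shared with the dating engine)
jointly samples the genealogy, the group boundaries, and the per-group Ne
values under an exponential Markov smoothing prior.  Summaries evaluate
each posterior sample's Ne step function on a regular time grid (100 bins
by default, youngest tip at time 0) and report binwise medians with 95%
HPD bounds, for the whole tree or restricted to a clade (e.g. the
metastatic clones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import CoalescentPrior, step_function
from .dating import CloneDatingModel, DatingResults
from .diagnostics import hpd_interval

__all__ = ["SkylineModel", "SkylineResults", "SkylineTrajectory",
           "skyline_mcmc", "summarize_trajectory", "clade_skyline"]


@dataclass
class SkylineTrajectory:
    """Binned Ne trajectory with uncertainty."""

    times: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    clade: str = "all"
    skipped_trees: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "ne_median": self.median,
            "ne_hpd95_lower": self.lower, "ne_hpd95_upper": self.upper,
            "clade": self.clade,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _sample_step_functions(results: DatingResults):
    """(coal_times, ne_values, group_sizes) per posterior sample."""
    if results.skyline_samples is None:
        raise ValueError("results were not produced under a skyline prior")
    out = []
    for tree, (ne, gs) in zip(results.trees, results.skyline_samples):
        times = np.sort(tree.heights[tree.n_tips:])
        out.append((times, ne, gs))
    return out


def _eval_step(times, ne, gs, grid):
    breaks, values = step_function(times, None, CoalescentPrior(
        "skyline", ne_values=ne, group_sizes=gs))
    idx = np.clip(np.searchsorted(breaks[1:-1], grid, side="right"), 0, len(values) - 1)
    return values[idx]


def _summarize(step_fns, grid):
    vals = np.array([_eval_step(t, ne, gs, grid) for t, ne, gs in step_fns])
    med = np.median(vals, axis=0)
    if len(step_fns) >= 10:
        bounds = np.array([hpd_interval(vals[:, b]) for b in range(len(grid))])
        lo, hi = bounds[:, 0], bounds[:, 1]
    else:
        lo, hi = vals.min(axis=0), vals.max(axis=0)
    return med, lo, hi


def summarize_trajectory(results: DatingResults, bins: int = 100) -> SkylineTrajectory:
    """Whole-tree skyline trajectory on a regular grid of bin midpoints.

    The grid spans time 0 (youngest tip) to the median posterior root
    height; each sample's step function extends by its last value.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    fns = _sample_step_functions(results)
    root_med = float(np.median([t[-1] for t, _, _ in fns]))
    grid = (np.arange(bins) + 0.5) * root_med / bins
    med, lo, hi = _summarize(fns, grid)
    return SkylineTrajectory(grid, med, lo, hi, clade="all")


def clade_skyline(results: DatingResults, clade_tips, bins: int = 100,
                  clade_label: str = "clade") -> SkylineTrajectory:
    """Skyline restricted to the coalescent intervals of a clade.

    For each posterior sample in which the clade is monophyletic, the
    sampled Ne values are re-timed on the clade subtree's own coalescent
    intervals (group sizes allocated proportionally), so the trajectory
    reflects when demographic transitions occur within that clade.  Samples
    lacking the clade are skipped and counted.
    """
    fns = []
    skipped = 0
    tip_idx = None
    for tree, (ne, gs) in zip(results.trees, results.skyline_samples):
        if tip_idx is None:
            tip_idx = [tree.tip_labels.index(t) for t in clade_tips]
        if len(tip_idx) < len(tree.tip_labels) and not tree.is_monophyletic(tip_idx):
            skipped += 1
            continue
        mrca = tree.mrca(tip_idx)
        masks = tree.clade_masks()
        target = masks[mrca]
        sub_times = np.sort([tree.heights[n] for n in range(tree.n_tips, tree.n_nodes)
                             if masks[n] & target == masks[n]])
        n_int = len(sub_times)
        # proportional re-allocation of group sizes (largest remainder)
        props = np.asarray(gs, dtype=float) / np.sum(gs)
        alloc = np.floor(props * n_int).astype(int)
        rem = n_int - alloc.sum()
        order = np.argsort(-(props * n_int - alloc))
        for i in range(rem):
            alloc[order[i % len(alloc)]] += 1
        keep = alloc > 0
        fns.append((sub_times, np.asarray(ne)[keep], alloc[keep]))
    if not fns:
        raise ValueError("clade is never monophyletic in the posterior sample")
    root_med = float(np.median([t[-1] for t, _, _ in fns]))
    grid = (np.arange(bins) + 0.5) * root_med / bins
    med, lo, hi = _summarize(fns, grid)
    return SkylineTrajectory(grid, med, lo, hi, clade=clade_label,
                             skipped_trees=skipped)


# ======================================================================
class SkylineModel(CloneDatingModel):
    """Skyline-prior specialization of the dating model."""

    def __init__(self, alignment, n_groups: int = 5, **kwargs):
        kwargs.pop("tree_prior", None)
        super().__init__(alignment, tree_prior="skyline", n_groups=n_groups,
                         **kwargs)

    def fit(self, chain_length=20000, thin=20, burn_in=0.1, seed=0):
        res = super().fit(chain_length, thin, burn_in, seed)
        return SkylineResults(**vars(res))


@dataclass
class SkylineResults(DatingResults):
    """Dating results plus trajectory summarization."""

    def trajectory(self, bins: int = 100) -> SkylineTrajectory:
        return summarize_trajectory(self, bins)

    def clade_trajectory(self, clade_tips, bins: int = 100,
                         clade_label: str = "clade") -> SkylineTrajectory:
        return clade_skyline(self, clade_tips, bins, clade_label)


def skyline_mcmc(alignment, n_groups: int = 5, chain: dict | None = None,
                 seed: int = 0, **model_kwargs) -> "SkylineResults":
    """Functional entry point for the skyline analysis."""
    model = SkylineModel(alignment, n_groups=n_groups, **model_kwargs)
    chain = chain or {}
    return model.fit(chain_length=chain.get("length", 20000),
                     thin=chain.get("thin", 20),
                     burn_in=chain.get("burn_in", 0.1), seed=seed)
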