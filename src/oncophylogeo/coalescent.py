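"""Coalescent tree priors: constant size, exponential growth, skyline.

Time runs backwards from the contemporaneous tips (height 0).  Under
exponential growth at rate ``r`` per generation the effective size looking
backwards is ``N(t) = N0 * exp(-r t)``, so coalescence accelerates into the
past for ``r > 0``.  Densities integrate to 1 over the ordered node heights
of a ranked genealogy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import Tree

__all__ = [
    "CoalescentPrior",
    "coalescent_log_density",
    "coalescent_intervals",
    "sample_coalescent_tree",
]


@dataclass
class CoalescentPrior:
    """Tree prior specification.

    kind: ``constant`` | ``exponential_growth`` | ``skyline``.
    For ``skyline``, ``ne_values`` holds one Ne per group and ``group_sizes``
    the number of coalescent intervals per group (youngest first).
    """

    kind: str = "exponential_growth"
    n0: float = 1e5
    r: float = 0.0
    ne_values: np.ndarray | None = None
    group_sizes: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("constant", "exponential_growth", "skyline"):
            raise ValueError(f"unknown coalescent prior {self.kind!r}")
        if self.n0 <= 0:
            raise ValueError("N0 must be positive")


def coalescent_intervals(tree: Tree):
    """Sorted coalescent event heights and lineage counts through time.

    Returns ``(times, k)`` where ``times`` are the n-1 node heights in
    ascending order and ``k[i]`` is the number of lineages present in the
    interval ending at ``times[i]``.
    """
    if not tree.is_ultrametric(tol=1e-6):
        raise ValueError("tree must be ultrametric (contemporaneous tips)")
    ev = np.sort(tree.heights[tree.n_tips:])
    n = tree.n_tips
    k = np.arange(n, 1, -1)
    return ev, k


def _integral_inv_n(a, b, n0, r):
    """integral of 1/N(t) dt over [a, b] with N(t) = n0 exp(-r t)."""
    if r == 0.0:
        return (b - a) / n0
    if r * b > 700:  # coalescent rate astronomically large: density -> 0
        return np.inf
    return (np.exp(r * b) - np.exp(r * a)) / (r * n0)


def coalescent_log_density(tree: Tree, prior: CoalescentPrior) -> float:
    """Log density of the node heights under the coalescent prior."""
    times, ks = coalescent_intervals(tree)
    if prior.kind == "skyline":
        return _skyline_log_density(times, ks, prior)
    r = prior.r if prior.kind == "exponential_growth" else 0.0
    n0 = prior.n0
    logp = 0.0
    prev = 0.0
    for t, k in zip(times, ks):
        pairs = k * (k - 1) / 2.0
        logp -= pairs * _integral_inv_n(prev, t, n0, r)
        logp += np.log(pairs) + (r * t - np.log(n0))  # log(pairs / N(t))
        prev = t
    return float(logp)


def _skyline_log_density(times, ks, prior) -> float:
    ne = np.asarray(prior.ne_values, dtype=float)
    sizes = np.asarray(prior.group_sizes, dtype=int)
    if sizes.sum() != len(times):
        raise ValueError("group sizes must sum to the number of coalescent intervals")
    if np.any(ne <= 0):
        raise ValueError("Ne values must be positive")
    group_of = np.repeat(np.arange(len(sizes)), sizes)
    logp = 0.0
    prev = 0.0
    for i, (t, k) in enumerate(zip(times, ks)):
        pairs = k * (k - 1) / 2.0
        n_e = ne[group_of[i]]
        logp -= pairs * (t - prev) / n_e
        logp += np.log(pairs / n_e)
        prev = t
    return float(logp)


def step_function(times, ks, prior):
    """Ne as a function of time before present implied by a skyline prior.

    Returns ``(breaks, values)``: Ne equals ``values[i]`` on
    ``[breaks[i], breaks[i+1])``; the last value extends to infinity.
    """
    sizes = np.asarray(prior.group_sizes, dtype=int)
    ne = np.asarray(prior.ne_values, dtype=float)
    bounds = np.concatenate([[0.0], np.asarray(times)])
    breaks = [0.0]
    values = []
    pos = 0
    for g, size in enumerate(sizes):
        pos += size
        breaks.append(bounds[pos])
        values.append(ne[g])
    return np.array(breaks), np.array(values)


# ----------------------------------------------------------------------
def _growth_waiting_time(t, k, n0, r, rng):
    pairs = k * (k - 1) / 2.0
    e = rng.exponential()
    if r == 0.0:
        return e * n0 / pairs
    arg = np.exp(r * t) + r * n0 * e / pairs
    if arg <= 0:
        return np.inf  # lineages escape to the past (r < 0)
    return np.log(arg) / r - t


def sample_coalescent_tree(n_tips, n0=1e5, r=0.0, rng=None, tip_labels=None,
                           max_height=None) -> Tree:
    """Simulate a coalescent genealogy under (exponential-growth) size N(t).

    Raises
    ------
    ValueError
        If the configuration does not coalesce (possible for ``r < 0``).
    """
    rng = np.random.default_rng(rng)
    if tip_labels is None:
        tip_labels = [f"clone{i}" for i in range(n_tips)]
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    heights = np.zeros(n_nodes)
    active = list(range(n_tips))
    t = 0.0
    nxt = n_tips
    while len(active) > 1:
        k = len(active)
        w = _growth_waiting_time(t, k, n0, r, rng)
        if not np.isfinite(w):
            raise ValueError(
                "non-coalescing configuration: growth rate r=%g shrinks the "
                "coalescent rate too fast backwards in time" % r
            )
        t += w
        if max_height is not None and t > max_height:
            raise ValueError("coalescence exceeded max_height")
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        heights[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Tree(parent, heights, tip_labels)
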