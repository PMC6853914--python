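"""Small-parsimony machinery shared by mutation mapping and migration history.

Implements the Sankoff dynamic program on a rooted tree with an arbitrary
cost matrix, plus full backtracking of every cost-minimal internal labeling.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["sankoff_costs", "sankoff_min_cost", "enumerate_optimal_labelings"]

INF = np.inf


def sankoff_costs(tree, tip_states, n_states, cost=None):
    """Per-node, per-state minimal subtree costs.

    Parameters
    ----------
    tree : Tree
    tip_states : array of int
        State per tip (index < n_tips); ``-1`` means missing (any state).
    n_states : int
    cost : (n_states, n_states) array, optional
        Transition costs; defaults to unit cost off-diagonal.
    """
    if cost is None:
        cost = 1.0 - np.eye(n_states)
    S = np.full((tree.n_nodes, n_states), INF)
    ch = tree.children()
    for node in tree.postorder():
        if node < tree.n_tips:
            s = tip_states[node]
            if s < 0:
                S[node] = 0.0
            else:
                S[node, s] = 0.0
        else:
            total = np.zeros(n_states)
            for c in ch[node]:
                total += (cost + S[c][None, :]).min(axis=1)
            S[node] = total
    return S, cost


def sankoff_min_cost(tree, tip_states, n_states, cost=None, root_state=None):
    """Minimal total transition cost over internal labelings."""
    S, cost = sankoff_costs(tree, tip_states, n_states, cost)
    root = tree.root
    if root_state is not None:
        return float(S[root, root_state])
    return float(S[root].min())


def enumerate_optimal_labelings(
    tree, tip_states, n_states, cost=None, root_state=None, max_labelings=None
):
    """All internal-node labelings achieving the Sankoff minimum.

    Returns
    -------
    (min_cost, labelings)
        ``labelings`` is a list of int arrays over all nodes (tips keep their
        observed states).  Enumeration is capped at ``max_labelings`` if set.
    """
    S, cost = sankoff_costs(tree, tip_states, n_states, cost)
    root = tree.root
    ch = tree.children()
    if root_state is not None:
        min_cost = S[root, root_state]
        root_choices = [root_state]
    else:
        min_cost = S[root].min()
        root_choices = [s for s in range(n_states) if S[root, s] <= min_cost + 1e-12]
    if not np.isfinite(min_cost):
        raise ValueError("no feasible labeling (conflicting tip states?)")

    # per (node, parent_state) the optimal child states
    def child_options(node, parent_state):
        vals = cost[parent_state] + S[node]
        m = vals.min()
        return [s for s in range(n_states) if vals[s] <= m + 1e-12]

    labelings = []
    order = tree.preorder()

    def backtrack(assign, idx):
        if max_labelings is not None and len(labelings) >= max_labelings:
            return
        if idx == len(order):
            labelings.append(assign.copy())
            return
        node = order[idx]
        if node == root:
            for s in root_choices:
                assign[node] = s
                backtrack(assign, idx + 1)
            return
        if node < tree.n_tips and tip_states[node] >= 0:
            assign[node] = tip_states[node]
            backtrack(assign, idx + 1)
            return
        for s in child_options(node, assign[tree.parent[node]]):
            assign[node] = s
            backtrack(assign, idx + 1)

    assign = np.full(tree.n_nodes, -1, dtype=int)
    backtrack(assign, 0)
    return float(min_cost), labelings


def brute_force_min_cost(tree, tip_states, n_states, cost=None, root_state=None):
    """Exhaustive minimum over all internal labelings (test oracle)."""
    if cost is None:
        cost = 1.0 - np.eye(n_states)
    internal = [n for n in range(tree.n_nodes) if n >= tree.n_tips]
    best = INF
    for combo in itertools.product(range(n_states), repeat=len(internal)):
        assign = np.array(tip_states, dtype=int).tolist() + [0] * (tree.n_nodes - tree.n_tips)
        for node, s in zip(internal, combo):
            assign[node] = s
        if root_state is not None and assign[tree.root] != root_state:
            continue
        total = 0.0
        for node in range(tree.n_nodes):
            p = tree.parent[node]
            if p >= 0:
                total += cost[assign[p], assign[node]]
        best = min(best, total)
    return float(best)
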