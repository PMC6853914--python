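"""Branch-level selection scanning on the clone genealogy.

Maps SNVs onto tree branches by small parsimony (all most-parsimonious
placements enumerated; ties resolved toward the rootmost branch and
flagged) or marginal maximum likelihood, assembles an in-frame codon
alignment from the coding mutations' codon contexts, and estimates
branch-specific dN/dS under a Goldman-Yang-style codon model (kappa,
omega, F1x4 codon frequencies).  Each candidate branch is tested by a
likelihood-ratio test of the one-ratio model M0 against a two-ratio model
granting the branch its own omega (chi-square, 1 df).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .likelihood import NT, NT_INDEX, Alignment
from .parsimony import enumerate_optimal_labelings
from .trees import Tree

log = logging.getLogger("oncophylogeo.selection")

__all__ = [
    "BranchMutationMap",
    "DnDsResult",
    "map_mutations_to_branches",
    "build_coding_sequences",
    "CodonAlignment",
    "CodonModel",
    "BranchDnDsModel",
    "branch_dnds_test",
    "simulate_codon_alignment",
    "counting_dnds",
]


def _standard_code():
    from Bio.Data.CodonTable import standard_dna_table

    code = dict(standard_dna_table.forward_table)
    for c in standard_dna_table.stop_codons:
        code[c] = "*"
    return code


_CODE = _standard_code()
SENSE_CODONS = sorted(c for c, aa in _CODE.items() if aa != "*")
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ======================================================================
@dataclass
class BranchMutationMap:
    """Per-site branch assignments with optional annotation columns."""

    table: pd.DataFrame            # site, branch, ambiguous, n_placements (+meta)
    method: str
    tree: Tree

    def per_branch(self) -> dict:
        return {int(b): g for b, g in self.table.groupby("branch")}

    def counts(self) -> pd.DataFrame:
        out = self.table.groupby("branch").size().rename("n_mutations").to_frame()
        if "effect" in self.table.columns:
            for eff in ("synonymous", "nonsynonymous"):
                out[eff] = (self.table[self.table["effect"] == eff]
                            .groupby("branch").size())
            out = out.fillna(0).astype(int)
        return out


def _node_depths(tree: Tree) -> np.ndarray:
    depth = np.zeros(tree.n_nodes, dtype=int)
    for node in tree.preorder():
        if tree.parent[node] >= 0:
            depth[node] = depth[tree.parent[node]] + 1
    return depth


def _with_outgroup(tree: Tree):
    """Extend the tree with a reference outgroup above the root.

    Changes on the branch leading to the old root ("stem") represent
    truncal mutations; the returned map sends extended node ids back to
    original ones, with the stem branch mapped to the old root id.
    """
    n = tree.n_tips
    ext_parent = np.full(2 * (n + 1) - 1, -1, dtype=np.int64)
    ext_heights = np.zeros(2 * (n + 1) - 1)
    node_map = {}
    for node in range(tree.n_nodes):
        e = node if node < n else node + 1
        node_map[e] = node
        ext_heights[e] = tree.heights[node]
        p = tree.parent[node]
        if p >= 0:
            ext_parent[e] = p + 1
    new_root = 2 * (n + 1) - 2
    old_root_e = tree.root + 1
    ext_parent[old_root_e] = new_root
    ext_parent[n] = new_root  # outgroup tip
    ext_heights[new_root] = tree.heights[tree.root] * 1.5 + 1.0
    labels = tree.tip_labels + ["__outgroup__"]
    return Tree(ext_parent, ext_heights, labels), node_map


def map_mutations_to_branches(
    alignment: Alignment,
    tree: Tree,
    method: str = "parsimony",
    annotations: pd.DataFrame | None = None,
    root_state: str | int = 0,
    max_placements: int = 256,
) -> BranchMutationMap:
    """Assign each variable site's state changes to tree branches.

    Parsimony enumerates every most-parsimonious ancestral reconstruction
    (a reference-state outgroup roots the states, so fully clonal changes
    land on the stem branch above the root); among reconstructions implying
    different change placements the rootmost placement (smallest branch
    depths) is chosen and the site flagged as ambiguous.  ``annotations``
    (one row per alignment site, e.g. effect labels and codon contexts) are
    carried through to the output table.
    """
    if sorted(alignment.names) != sorted(tree.tip_labels):
        raise ValueError("alignment tips must match tree tips")
    if method not in ("parsimony", "ml"):
        raise ValueError(f"unknown mapping method {method!r}")
    aln = alignment.subset(tree.tip_labels)
    root_code = NT_INDEX[root_state] if isinstance(root_state, str) else int(root_state)
    ext, node_map = _with_outgroup(tree)
    depth = _node_depths(ext)
    rows = []
    for site in range(aln.n_sites):
        col_orig = aln.codes[:, site]
        if len(set(int(c) for c in col_orig if c >= 0)) <= 1 and (
                col_orig[col_orig >= 0].size == 0
                or int(col_orig[col_orig >= 0][0]) == root_code):
            continue  # no event implied
        col = np.append(col_orig, root_code)
        if method == "parsimony":
            placements = _parsimony_placements(ext, col, root_code, max_placements)
        else:
            placements = [_ml_placement(ext, col, root_code)]
        # rootmost placement: lexicographically smallest sorted depth profile
        keyed = sorted(
            placements,
            key=lambda pl: sorted(depth[b] for b, _, _ in pl) + [sorted(b for b, _, _ in pl)],
        )
        chosen = keyed[0]
        distinct = {frozenset((b, a, d) for b, a, d in pl) for pl in placements}
        for b, from_s, to_s in chosen:
            if b not in node_map:
                continue  # outgroup stem artifacts (ML mode only)
            rows.append({
                "site": site, "branch": int(node_map[b]),
                "from_state": NT[from_s], "to_state": NT[to_s],
                "ambiguous": len(distinct) > 1,
                "n_placements": len(distinct),
            })
    table = pd.DataFrame(rows, columns=["site", "branch", "from_state",
                                        "to_state", "ambiguous", "n_placements"])
    if annotations is not None:
        table = table.merge(annotations, left_on="site", right_index=True, how="left")
    return BranchMutationMap(table, method, tree)


def _parsimony_placements(tree, col, root_code, max_placements):
    _, labelings = enumerate_optimal_labelings(
        tree, np.asarray(col, dtype=int), 4, root_state=root_code,
        max_labelings=max_placements)
    placements = []
    for assign in labelings:
        changes = []
        for node in range(tree.n_nodes):
            p = tree.parent[node]
            if p >= 0 and assign[p] != assign[node]:
                changes.append((int(node), int(assign[p]), int(assign[node])))
        placements.append(changes)
    return placements


def _ml_placement(tree, col, root_code):
    """Marginal ML ancestral states under JC69; changes at argmax switches."""
    from .likelihood import jc69

    model = jc69()
    bl = tree.branch_lengths
    scale = 0.5 / max(bl.sum(), 1e-12)
    P = model.transition_matrices(bl * scale + 1e-9)
    ch = tree.children()
    up = np.ones((tree.n_nodes, 4))
    for node in tree.postorder():
        if node < tree.n_tips:
            up[node] = 0.0
            if col[node] >= 0:
                up[node, col[node]] = 1.0
            else:
                up[node] = 1.0
        else:
            for c in ch[node]:
                up[node] *= P[c] @ up[c]
    # downward pass for marginals
    down = np.ones((tree.n_nodes, 4))
    assign = np.zeros(tree.n_nodes, dtype=int)
    root_prior = np.zeros(4)
    root_prior[root_code] = 1.0
    for node in tree.preorder():
        if node == tree.root:
            marg = root_prior * up[node]
        else:
            p = tree.parent[node]
            sib = [c for c in ch[p] if c != node]
            msg = down[p].copy()
            for s in sib:
                msg *= P[s] @ up[s]
            down[node] = msg @ P[node]
            marg = down[node] * up[node]
        assign[node] = int(np.argmax(marg))
    changes = []
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p >= 0 and assign[p] != assign[node]:
            changes.append((int(node), int(assign[p]), int(assign[node])))
    return changes


# ======================================================================
class CodonAlignment:
    """In-frame codon alignment stored as sense-codon indices."""

    def __init__(self, names, codon_indices):
        self.names = list(names)
        self.codes = np.asarray(codon_indices, dtype=np.int16)

    @property
    def n_seqs(self):
        return self.codes.shape[0]

    @property
    def n_codons(self):
        return self.codes.shape[1]

    def patterns(self):
        cols = np.ascontiguousarray(self.codes.T)
        uniq, counts = np.unique(cols, axis=0, return_counts=True)
        return uniq.T, counts.astype(float)

    def sequences(self):
        return ["".join(SENSE_CODONS[c] for c in row) for row in self.codes]

    def to_fasta(self, path):
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.sequences()):
                fh.write(f">{name}\n{seq}\n")

    @classmethod
    def from_fasta(cls, path):
        aln = Alignment.from_fasta(path)
        seqs = aln.sequences()
        names = aln.names
        idx = [[CODON_INDEX[s[i:i + 3]] for i in range(0, len(s), 3)] for s in seqs]
        return cls(names, idx)


def build_coding_sequences(branch_map: BranchMutationMap, tree: Tree | None = None
                           ) -> CodonAlignment:
    """Concatenated codon alignment of the clones from coding mutations.

    Each coding mutation contributes one codon column: clones carrying the
    mutation (tips below its branch) show the mutated codon, all others the
    reference codon.  Mutations without codon context are excluded and
    counted; contexts with a stop-codon reference are excluded with a
    warning.
    """
    tree = tree or branch_map.tree
    tab = branch_map.table
    required = {"ref_codon", "codon_pos"}
    if not required <= set(tab.columns):
        raise ValueError("branch map lacks codon-context annotations")
    masks = tree.clade_masks()
    names = list(tree.tip_labels)
    columns = []
    n_noncoding = 0
    n_stop = 0
    for _, row in tab.iterrows():
        codon = row.get("ref_codon", "")
        if not isinstance(codon, str) or len(codon) != 3:
            n_noncoding += 1
            continue
        if _CODE.get(codon, "*") == "*":
            n_stop += 1
            continue
        pos = int(row["codon_pos"])
        alt_nt = row["to_state"]
        mut_codon = codon[:pos] + alt_nt + codon[pos + 1:]
        if mut_codon not in CODON_INDEX:
            # nonsense change: excluded from the codon model's state space
            n_stop += 1
            continue
        carrier_mask = masks[int(row["branch"])]
        col = [CODON_INDEX[mut_codon] if (carrier_mask >> t) & 1 else CODON_INDEX[codon]
               for t in range(tree.n_tips)]
        columns.append(col)
    if n_stop:
        log.warning("excluded %d mutations with stop-codon reference or "
                    "nonsense change", n_stop)
    if n_noncoding:
        log.info("excluded %d non-coding mutations", n_noncoding)
    if not columns:
        return CodonAlignment(names, np.zeros((len(names), 0), dtype=np.int16))
    return CodonAlignment(names, np.array(columns).T)


# ======================================================================
_NEIGHBOR_CACHE = []


def _neighbor_structure():
    """Static single-nucleotide neighbor structure of the sense codons."""
    if not _NEIGHBOR_CACHE:
        I, J, TS, NS = [], [], [], []
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i == j:
                    continue
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    continue
                I.append(i)
                J.append(j)
                TS.append(diffs[0] in _TRANSITIONS)
                NS.append(_CODE[ci] != _CODE[cj])
        _NEIGHBOR_CACHE.extend([np.array(I), np.array(J),
                                np.array(TS), np.array(NS)])
    return _NEIGHBOR_CACHE


class CodonModel:
    """Goldman-Yang-style codon substitution model with F1x4 frequencies."""

    def __init__(self, kappa: float = 2.0, omega: float = 1.0, nt_freqs=None):
        self.kappa = float(kappa)
        self.omega = float(omega)
        pi_nt = np.asarray(nt_freqs if nt_freqs is not None else [0.25] * 4, float)
        pi_nt = pi_nt / pi_nt.sum()
        pi = np.array([np.prod([pi_nt[NT_INDEX[c]] for c in codon])
                       for codon in SENSE_CODONS])
        self.freqs = pi / pi.sum()
        self._build()

    def _build(self):
        n = len(SENSE_CODONS)
        I, J, TS, NS = _neighbor_structure()
        Q = np.zeros((n, n))
        Q[I, J] = (self.freqs[J] * np.where(TS, self.kappa, 1.0)
                   * np.where(NS, self.omega, 1.0))
        np.fill_diagonal(Q, -Q.sum(axis=1))
        self.scale_factor = -np.dot(self.freqs, np.diag(Q))
        Q /= self.scale_factor  # branch lengths in expected subs/codon
        s = np.sqrt(self.freqs)
        B = (Q * s[:, None]) / s[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2)
        self._w, self._V, self._s = w, V, s

    def transition_matrices(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        E = np.exp(self._w[None, :] * t[:, None])
        M = (self._V[None, :, :] * E[:, None, :]) @ self._V.T
        P = (M / self._s[:, None]) * self._s[None, :]
        return np.clip(P, 0.0, None)


def _codon_pruning(tree, branch_subs, patterns, weights, models, branch_model):
    """Pruning over 61 codon states with per-branch model assignment."""
    m = patterns.shape[1]
    n_states = len(SENSE_CODONS)
    Ps = {}
    for k, model in models.items():
        Ps[k] = model.transition_matrices(branch_subs)
    partials = [None] * tree.n_nodes
    scalers = np.zeros(m)
    ch = tree.children()
    for node in tree.postorder():
        if node < tree.n_tips:
            part = np.zeros((m, n_states))
            part[np.arange(m), patterns[node]] = 1.0
            partials[node] = part
        else:
            part = np.ones((m, n_states))
            for c in ch[node]:
                P = Ps[branch_model[c]][c]
                part = part * (partials[c] @ P.T)
            mx = part.max(axis=1)
            mx[mx == 0] = 1.0
            scalers += np.log(mx)
            partials[node] = part / mx[:, None]
    freqs = next(iter(models.values())).freqs
    site = partials[tree.root] @ freqs
    if np.any(site <= 0):
        return -np.inf
    return float(np.dot(weights, np.log(site) + scalers))


@dataclass
class DnDsResult:
    """Per-branch two-ratio test results."""

    table: pd.DataFrame
    m0_omega: float
    m0_kappa: float
    m0_loglik: float

    def significant(self, alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
        t = self.table
        if bh:
            from statsmodels.stats.multitest import multipletests

            rej, qv, _, _ = multipletests(t["p_value"], alpha=alpha, method="fdr_bh")
            t = t.assign(q_value=qv)
            return t[rej]
        return t[t["p_value"] < alpha]


@dataclass
class BranchDnDsModel:
    """M0 vs two-ratio dN/dS tests over candidate branches.

    ``branches=None`` tests every branch carrying at least one
    nonsynonymous mutation when a branch map is supplied, otherwise every
    branch of positive length.
    """

    alignment: CodonAlignment
    tree: Tree
    branch_map: BranchMutationMap | None = None
    branches: list | None = None
    nt_freqs: tuple = (0.25, 0.25, 0.25, 0.25)

    def _candidate_branches(self):
        if self.branches is not None:
            return list(self.branches)
        if self.branch_map is not None and "effect" in self.branch_map.table.columns:
            tab = self.branch_map.table
            cand = sorted(set(tab.loc[tab["effect"] == "nonsynonymous", "branch"]))
            return [int(b) for b in cand]
        bl = self.tree.branch_lengths
        return [n for n in range(self.tree.n_nodes) if bl[n] > 0]

    def _fit_model(self, patterns, weights, proportions, foreground=None, x0=None):
        tree = self.tree
        n_par = 4 if foreground is not None else 3

        def unpack(x):
            kappa = math.exp(x[0])
            scale = math.exp(x[-1])
            if foreground is None:
                omegas = {"bg": math.exp(x[1])}
            else:
                omegas = {"bg": math.exp(x[1]), "fg": math.exp(x[2])}
            return kappa, omegas, scale

        branch_model = ["bg"] * tree.n_nodes
        if foreground is not None:
            branch_model[foreground] = "fg"

        def nll(x):
            if np.any(np.abs(x) > 12):
                return 1e9
            kappa, omegas, scale = unpack(x)
            models = {k: CodonModel(kappa, w, self.nt_freqs)
                      for k, w in omegas.items()}
            ll = _codon_pruning(tree, proportions * scale, patterns, weights,
                                models, branch_model)
            return -ll if np.isfinite(ll) else 1e9

        if x0 is None:
            x0 = np.array([math.log(2.0), math.log(0.5), math.log(0.2)])
            if foreground is not None:
                x0 = np.insert(x0, 2, x0[1])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            raise RuntimeError(f"codon model optimization failed: {res}")
        return res

    def fit(self, branches=None) -> DnDsResult:
        if self.alignment.n_codons == 0:
            raise ValueError("empty codon alignment")
        patterns, weights = self.alignment.patterns()
        # order rows by tree tips
        order = [self.alignment.names.index(t) for t in self.tree.tip_labels]
        patterns = patterns[order]
        bl = self.tree.branch_lengths
        proportions = bl / max(bl.sum(), 1e-300)
        m0 = self._fit_model(patterns, weights, proportions)
        k0, w0, s0 = math.exp(m0.x[0]), math.exp(m0.x[1]), math.exp(m0.x[2])
        lnL0 = -m0.fun
        rows = []
        for b in (branches or self._candidate_branches()):
            x0 = np.array([m0.x[0], m0.x[1], m0.x[1], m0.x[2]])
            alt = self._fit_model(patterns, weights, proportions,
                                  foreground=int(b), x0=x0)
            lnL1 = -alt.fun
            lrt = max(2.0 * (lnL1 - lnL0), 0.0)
            rows.append({
                "branch": int(b),
                "omega_foreground": math.exp(alt.x[2]),
                "omega_background": math.exp(alt.x[1]),
                "lnL0": lnL0, "lnL1": lnL1, "LRT": lrt,
                "p_value": float(chi2.sf(lrt, df=1)),
            })
        return DnDsResult(pd.DataFrame(rows), w0, k0, lnL0)


def branch_dnds_test(codon_alignment, tree, branch, **kwargs) -> dict:
    """Two-ratio test for a single branch (functional wrapper)."""
    model = BranchDnDsModel(codon_alignment, tree, **kwargs)
    res = model.fit(branches=[branch])
    return res.table.iloc[0].to_dict()


# ======================================================================
def simulate_codon_alignment(tree, n_codons, kappa=2.0, omega=1.0,
                             branch_omegas=None, nt_freqs=None, rng=None,
                             tree_scale=None) -> CodonAlignment:
    """Simulate codon sequences down a tree under the GY-style model.

    ``branch_omegas`` maps node -> omega for branch-specific selection;
    ``tree_scale`` rescales total tree length to this many expected
    substitutions/codon (branch proportions preserved).
    """
    rng = np.random.default_rng(rng)
    bl = tree.branch_lengths.astype(float)
    if tree_scale is not None:
        bl = bl / max(bl.sum(), 1e-300) * tree_scale
    omegas = {"bg": omega}
    branch_model = ["bg"] * tree.n_nodes
    if branch_omegas:
        for i, (b, w) in enumerate(sorted(branch_omegas.items())):
            key = f"fg{i}"
            omegas[key] = w
            branch_model[b] = key
    models = {k: CodonModel(kappa, w, nt_freqs) for k, w in omegas.items()}
    Ps = {k: m.transition_matrices(bl) for k, m in models.items()}
    freqs = models["bg"].freqs
    n_states = len(SENSE_CODONS)
    states = np.zeros((tree.n_nodes, n_codons), dtype=np.int16)
    order = tree.preorder()
    states[order[0]] = rng.choice(n_states, size=n_codons, p=freqs)
    for node in order[1:]:
        P = Ps[branch_model[node]][node]
        cum = np.cumsum(P[states[tree.parent[node]]], axis=1)
        u = rng.random(n_codons)[:, None] * cum[:, -1][:, None]
        states[node] = (u > cum).sum(axis=1)
    return CodonAlignment(tree.tip_labels, states[: tree.n_tips])


# ======================================================================
def _codon_site_counts(codon: str):
    """NG86 synonymous/nonsynonymous site counts for one codon."""
    syn = 0.0
    for pos in range(3):
        for alt in NT:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if _CODE.get(mut, "*") == "*":
                continue
            if _CODE[mut] == _CODE[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def counting_dnds(branch_map: BranchMutationMap) -> pd.DataFrame:
    """Counting-based (NG86-style) per-branch dN/dS from mapped mutations.

    Site totals come from the reference codons of all coding mutations;
    observed synonymous/nonsynonymous changes are the branch's mapped
    mutation labels.  Used as a rank-order cross-check of the ML estimates.
    """
    tab = branch_map.table
    coding = tab[tab["ref_codon"].map(
        lambda c: isinstance(c, str) and len(c) == 3)]
    if not len(coding):
        raise ValueError("no coding mutations in the branch map")
    S = N = 0.0
    for codon in coding["ref_codon"]:
        s, n = _codon_site_counts(codon)
        S += s
        N += n
    rows = []
    for b, grp in coding.groupby("branch"):
        sd = int((grp["effect"] == "synonymous").sum())
        nd = int((grp["effect"] == "nonsynonymous").sum())
        pn = nd / N
        ps = sd / S
        rows.append({"branch": int(b), "n_syn": sd, "n_nonsyn": nd,
                     "omega_count": (pn / ps) if ps > 0 else np.inf})
    return pd.DataFrame(rows)
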