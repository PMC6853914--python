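"""Alignments, nucleotide substitution models, and the pruning likelihood.

The clone alignments produced by deconvolution are binary (A = ancestral /
reference, T = derived / alternative) but are treated as ordinary nucleotide
data under JC69 or HKY.  Because only variable positions enter those
alignments, the likelihood can condition on variability (SNV ascertainment
correction): per-site likelihoods are divided by ``1 - sum_c P(all-c site)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}

__all__ = [
    "Alignment",
    "ClockModel",
    "SubstitutionModel",
    "jc69",
    "hky",
    "tree_log_likelihood",
    "pruning_log_likelihood",
    "simulate_alignment",
]


class Alignment:
    """Multiple sequence alignment over ACGT with pattern compression."""

    def __init__(self, names, codes):
        self.names = list(names)
        self.codes = np.asarray(codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (n_seqs x n_sites)")
        if len(self.names) != self.codes.shape[0]:
            raise ValueError("names/codes mismatch")

    @property
    def n_seqs(self):
        return self.codes.shape[0]

    @property
    def n_sites(self):
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, names, seqs) -> "Alignment":
        codes = np.array(
            [[NT_INDEX.get(c.upper(), -1) for c in s] for s in seqs], dtype=np.int8
        )
        return cls(names, codes)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        if not names:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(names, seqs)

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seq_write
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq("".join(NT[c] if c >= 0 else "N" for c in row)), id=name, description="")
            for name, row in zip(self.names, self.codes)
        ]
        seq_write(recs, str(path), "fasta")

    def sequences(self):
        return ["".join(NT[c] if c >= 0 else "N" for c in row) for row in self.codes]

    def patterns(self):
        """Unique site patterns and their weights."""
        cols = np.ascontiguousarray(self.codes.T)
        uniq, counts = np.unique(cols, axis=0, return_counts=True)
        return uniq.T.astype(np.int8), counts.astype(float)

    def variable_sites(self) -> "Alignment":
        var = np.array([len(np.unique(col[col >= 0])) > 1 for col in self.codes.T])
        return Alignment(self.names, self.codes[:, var])

    def subset(self, names) -> "Alignment":
        idx = [self.names.index(n) for n in names]
        return Alignment([self.names[i] for i in idx], self.codes[idx])

    def __repr__(self):
        return f"<Alignment {self.n_seqs} x {self.n_sites}>"


# ----------------------------------------------------------------------
@dataclass
class ClockModel:
    """Molecular clock linking generations to expected substitutions/site.

    kind ``strict`` uses ``mean_rate`` on every branch; ``relaxed_exponential``
    draws i.i.d. per-branch rates from an exponential with mean ``mean_rate``.
    """

    kind: str = "strict"
    mean_rate: float = 4.6e-10
    branch_rates: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("strict", "relaxed_exponential"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.mean_rate <= 0:
            raise ValueError("clock rate must be positive")

    def rates(self, n_nodes: int) -> np.ndarray:
        if self.kind == "strict" or self.branch_rates is None:
            return np.full(n_nodes, self.mean_rate)
        return np.asarray(self.branch_rates, dtype=float)


@dataclass
class SubstitutionModel:
    """Reversible nucleotide model given by exchangeabilities and base freqs."""

    name: str
    freqs: np.ndarray
    rate_matrix: np.ndarray  # scaled so expected rate = 1
    _eig: tuple = field(default=None, repr=False, compare=False)

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths; shape (len(t), 4, 4)."""
        if self._eig is None:
            pi = self.freqs
            s = np.sqrt(pi)
            B = (self.rate_matrix * s[:, None]) / s[None, :]
            w, V = np.linalg.eigh((B + B.T) / 2)
            self._eig = (w, V, s)
        w, V, s = self._eig
        t = np.asarray(t, dtype=float)
        E = np.exp(w[None, :] * t[:, None])  # (m, 4)
        # P = diag(1/s) V E V^T diag(s)
        M = np.einsum("ij,mj,kj->mik", V, E, V)
        P = (M / s[:, None]) * s[None, :]
        return np.clip(P, 0.0, None)


def _scale(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def jc69() -> SubstitutionModel:
    pi = np.full(4, 0.25)
    Q = np.ones((4, 4))
    return SubstitutionModel("JC69", pi, _scale(Q, pi))


def hky(kappa: float = 2.0, freqs=None) -> SubstitutionModel:
    pi = np.asarray(freqs if freqs is not None else [0.25] * 4, dtype=float)
    pi = pi / pi.sum()
    Q = np.tile(pi, (4, 1)).astype(float)
    for i, j in [(0, 2), (2, 0), (1, 3), (3, 1)]:  # A<->G, C<->T transitions
        Q[i, j] *= kappa
    return SubstitutionModel(f"HKY(k={kappa:g})", pi, _scale(Q, pi))


def _get_model(subst) -> SubstitutionModel:
    if isinstance(subst, SubstitutionModel):
        return subst
    if subst == "JC69":
        return jc69()
    if subst == "HKY":
        return hky()
    raise ValueError(f"unknown substitution model {subst!r}")


# ----------------------------------------------------------------------
def tip_partials(patterns) -> list:
    """One-hot tip partial matrices (missing data = all ones)."""
    out = []
    m = patterns.shape[1]
    for codes in patterns:
        part = np.zeros((m, 4))
        known = codes >= 0
        part[known, codes[known]] = 1.0
        part[~known] = 1.0
        out.append(part)
    return out


def pattern_log_likelihoods(tree, branch_subs, patterns, model,
                            tips=None, order=None, children=None) -> np.ndarray:
    """Per-pattern log-likelihoods by Felsenstein pruning with rescaling.

    ``tips`` (precomputed tip partials), ``order`` (postorder) and
    ``children`` may be supplied to avoid recomputation in samplers.
    """
    n_tips = tree.n_tips
    m = patterns.shape[1]
    P = model.transition_matrices(branch_subs)
    partials = [None] * tree.n_nodes
    scalers = np.zeros(m)
    ch = children if children is not None else tree.children()
    for node in (order if order is not None else tree.postorder()):
        if node < n_tips:
            if tips is not None:
                partials[node] = tips[node]
                continue
            part = np.zeros((m, 4))
            codes = patterns[node]
            known = codes >= 0
            part[known, codes[known]] = 1.0
            part[~known] = 1.0
            partials[node] = part
        else:
            part = np.ones((m, 4))
            for c in ch[node]:
                part = part * (partials[c] @ P[c].T)
            mx = part.max(axis=1)
            mx[mx == 0] = 1.0
            scalers += np.log(mx)
            partials[node] = part / mx[:, None]
    site_lik = partials[tree.root] @ model.freqs
    return np.log(np.maximum(site_lik, 1e-300)) + scalers


def pruning_log_likelihood(tree, branch_subs, patterns, weights, model) -> float:
    """Weighted pruning log-likelihood (see :func:`pattern_log_likelihoods`)."""
    logs = pattern_log_likelihoods(tree, branch_subs, patterns, model)
    if np.any(~np.isfinite(logs)):
        return -np.inf
    return float(np.dot(weights, logs))


def _constant_pattern_logprobs(tree, branch_subs, model) -> np.ndarray:
    """Per-state log P(all tips show state c), c in ACGT."""
    const = np.tile(np.arange(4, dtype=np.int8)[None, :], (tree.n_tips, 1))
    n_tips = tree.n_tips
    P = model.transition_matrices(branch_subs)
    partials = [None] * tree.n_nodes
    scalers = np.zeros(4)
    ch = tree.children()
    for node in tree.postorder():
        if node < n_tips:
            part = np.zeros((4, 4))
            part[np.arange(4), const[node]] = 1.0
            partials[node] = part
        else:
            part = np.ones((4, 4))
            for c in ch[node]:
                part = part * (partials[c] @ P[c].T)
            mx = part.max(axis=1)
            mx[mx == 0] = 1.0
            scalers += np.log(mx)
            partials[node] = part / mx[:, None]
    lik = partials[tree.root] @ model.freqs
    return np.log(np.maximum(lik, 1e-300)) + scalers


def tree_log_likelihood(
    alignment,
    tree,
    subst="JC69",
    clock: ClockModel | None = None,
    ascertainment: str = "none",
    constant_weights=None,
) -> float:
    """Log-likelihood of an SNV alignment on a dated tree.

    Ascertainment handling for alignments containing only variable sites:

    * ``"variable_sites_only"`` — condition on variability by dividing each
      site likelihood by ``1 - P(constant site)``; corrects relative branch
      lengths but carries no absolute-scale information.
    * ``"constant_site_weights"`` — add ``constant_weights`` invariant sites
      (scalar total, split by the stationary frequencies, or a length-4
      array of per-state counts) to the likelihood, the mechanism used to
      analyze SNV-only clone alignments against an exome-scale target.
    """
    if alignment.n_sites == 0:
        raise ValueError("zero-length alignment")
    if ascertainment not in ("none", "variable_sites_only", "constant_site_weights"):
        raise ValueError(f"unknown ascertainment mode {ascertainment!r}")
    if sorted(alignment.names) != sorted(tree.tip_labels):
        raise ValueError("alignment tips do not match tree tips")
    aln = alignment.subset(tree.tip_labels)
    model = _get_model(subst)
    clock = clock or ClockModel("strict", 1.0)
    rates = clock.rates(tree.n_nodes)
    branch_subs = tree.branch_lengths * rates
    patterns, weights = aln.patterns()
    if ascertainment == "none":
        return pruning_log_likelihood(tree, branch_subs, patterns, weights, model)
    # append the four constant patterns so one pruning pass serves both the
    # data likelihood and the ascertainment term
    const = np.tile(np.arange(4, dtype=np.int8)[None, :], (tree.n_tips, 1))
    logs = pattern_log_likelihoods(
        tree, branch_subs, np.concatenate([patterns, const], axis=1), model)
    data_logs, const_logs = logs[: patterns.shape[1]], logs[patterns.shape[1]:]
    ll = float(np.dot(weights, data_logs))
    if ascertainment == "variable_sites_only":
        mx = const_logs.max()
        logp_const = float(mx + np.log(np.exp(const_logs - mx).sum()))
        if logp_const >= 0:
            return -np.inf
        ll -= weights.sum() * np.log1p(-np.exp(logp_const))
    else:
        if constant_weights is None:
            raise ValueError("constant_site_weights requires constant_weights")
        w = np.asarray(constant_weights, dtype=float)
        if w.ndim == 0:
            w = float(w) * model.freqs
        ll += float(np.dot(w, const_logs))
    return ll


# ----------------------------------------------------------------------
def simulate_alignment(tree, n_sites, subst="JC69", clock=None, rng=None,
                       variable_only: bool = False) -> Alignment:
    """Simulate sequences down a dated tree.

    With ``variable_only`` sites are simulated until ``n_sites`` variable ones
    are collected (mimicking an SNV-only alignment).
    """
    rng = np.random.default_rng(rng)
    model = _get_model(subst)
    clock = clock or ClockModel("strict", 1.0)
    rates = clock.rates(tree.n_nodes)

    def batch(k):
        P = model.transition_matrices(tree.branch_lengths * rates)
        states = np.zeros((tree.n_nodes, k), dtype=np.int8)
        order = tree.preorder()
        states[order[0]] = rng.choice(4, size=k, p=model.freqs)
        for node in order[1:]:
            par = tree.parent[node]
            probs = P[node][states[par]]
            cum = np.cumsum(probs, axis=1)
            u = rng.random(k)[:, None]
            states[node] = (u > cum).sum(axis=1)
        return states[: tree.n_tips]

    if not variable_only:
        return Alignment(tree.tip_labels, batch(int(n_sites)))
    cols = []
    got = 0
    while got < n_sites:
        tips = batch(int(max(64, n_sites)))
        var = (tips != tips[0]).any(axis=0)
        sel = tips[:, var]
        cols.append(sel)
        got += sel.shape[1]
    codes = np.concatenate(cols, axis=1)[:, : int(n_sites)]
    return Alignment(tree.tip_labels, codes)


def simulate_snv_alignment(tree, genome_sites, subst="JC69", clock=None,
                           rng=None):
    """Simulate the SNV-only view of a ``genome_sites``-long alignment.

    Draws the number of variable sites from Binomial(genome_sites, P(var))
    and their patterns conditionally on variability, avoiding materializing
    the (mostly invariant) full alignment.  Returns ``(alignment,
    n_constant)`` — feed ``n_constant`` to the likelihood as constant-site
    weights.
    """
    rng = np.random.default_rng(rng)
    model = _get_model(subst)
    clock = clock or ClockModel("strict", 1.0)
    branch_subs = tree.branch_lengths * clock.rates(tree.n_nodes)
    logs = _constant_pattern_logprobs(tree, branch_subs, model)
    mx = logs.max()
    p_const = float(np.exp(mx) * np.exp(logs - mx).sum())
    k = int(rng.binomial(int(genome_sites), max(0.0, 1.0 - p_const)))
    if k == 0:
        raise ValueError("no variable sites simulated; increase rate or sites")
    aln = simulate_alignment(tree, k, subst=subst, clock=clock, rng=rng,
                             variable_only=True)
    return aln, int(genome_sites) - k
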