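"""Simplified clonal deconvolution from cross-sample VAF profiles.

Mutations with indistinguishable VAF profiles across bulk samples are the
signature of a shared clone-tree branch.  The pipeline therefore (1) gates
loci on read support, (2) discretizes per-sample VAFs into present / absent
/ uninformative, (3) groups loci with identical presence patterns and merges
groups whose mean VAF profiles are within an L-infinity radius, and (4)
orders the resulting clusters by perfect-phylogeny containment of their
presence patterns to emit clone genotypes, binary (A = reference, T =
alternative) clone sequences, and per-sample clone frequencies by
constrained least squares.  Thresholds default to the printed settings of
the deconvolution tools this stage stands in for (minimum read count 40,
mutant read count 6, clone frequency cutoff 0.075, presence threshold
0.075, absence threshold 0, cluster merge radius 0.1, VAF sanity cap 0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import VariantCallTable
from .likelihood import Alignment

log = logging.getLogger("oncophylogeo.deconvolution")

__all__ = [
    "VAFClusterSet",
    "CloneGenotypeSet",
    "cluster_mutations",
    "build_clone_genotypes",
    "encode_sequences",
]


@dataclass
class VAFClusterSet:
    """Partition of retained loci into VAF-profile clusters."""

    assignments: np.ndarray          # cluster id per retained locus
    centroids: np.ndarray            # (n_clusters, n_tumor_samples) mean VAF
    sizes: np.ndarray
    locus_index: np.ndarray          # indices into the input table
    tumor_samples: list
    min_vaf_present: float
    small_clusters: np.ndarray       # ids below min_cluster_size
    high_vaf_flagged: np.ndarray     # loci indices exceeding the VAF cap
    audit: dict = field(default_factory=dict)
    centroid_se: np.ndarray | None = None  # binomial SE of centroid VAFs

    @property
    def n_clusters(self):
        return len(self.sizes)

    def presence_patterns(self) -> np.ndarray:
        return self.centroids >= self.min_vaf_present

    def to_tsv(self, path, table: VariantCallTable) -> None:
        df = table.loci.iloc[self.locus_index].reset_index(drop=True).copy()
        df["cluster"] = self.assignments
        df.to_csv(path, sep="\t", index=False)


@dataclass
class CloneGenotypeSet:
    """Inferred clones: binary genotypes over loci plus per-sample frequencies."""

    genotypes: np.ndarray            # (n_clones, n_loci) bool
    frequencies: pd.DataFrame        # samples x clones
    clone_labels: list
    locus_index: np.ndarray
    cluster_of_clone: list
    parent: list                     # parent clone index (-1 for founder)

    @property
    def n_clones(self):
        return self.genotypes.shape[0]

    def to_tsv(self, genotype_path, freq_path, table: VariantCallTable | None = None):
        g = pd.DataFrame(self.genotypes.astype(int), index=self.clone_labels)
        g.to_csv(genotype_path, sep="\t")
        self.frequencies.to_csv(freq_path, sep="\t")


# ======================================================================
def _agglomerate(members, alt, dep, v, z_gate, d_gate):
    """Greedy merging of clusters while pooled profiles are compatible.

    Merges the pair with the smallest max-over-samples binomial z first,
    subject to z <= z_gate and centroid L-infinity distance <= d_gate.
    """
    members = [np.asarray(m) for m in members]
    k = len(members)
    if k <= 1:
        return members
    alt_sum = np.array([alt[m].sum(axis=0) for m in members])
    dep_sum = np.array([dep[m].sum(axis=0) for m in members])
    cent = np.array([v[m].mean(axis=0) for m in members])
    alive = np.ones(k, dtype=bool)

    def score(a, b):
        pa, pb = alt_sum[a] / dep_sum[a], alt_sum[b] / dep_sum[b]
        pooled = (alt_sum[a] + alt_sum[b]) / (dep_sum[a] + dep_sum[b])
        se = np.sqrt(np.maximum(pooled * (1 - pooled), 1e-9)
                     * (1 / dep_sum[a] + 1 / dep_sum[b]))
        z = float(np.max(np.abs(pa - pb) / se))
        d = float(np.max(np.abs(cent[a] - cent[b])))
        return z if (z <= z_gate and d <= d_gate) else np.inf

    Z = np.full((k, k), np.inf)
    for a in range(k):
        for b in range(a + 1, k):
            Z[a, b] = score(a, b)
    while True:
        best = np.unravel_index(np.argmin(Z), Z.shape)
        if not np.isfinite(Z[best]):
            break
        a, b = best
        members[a] = np.concatenate([members[a], members[b]])
        alt_sum[a] += alt_sum[b]
        dep_sum[a] += dep_sum[b]
        cent[a] = v[members[a]].mean(axis=0)
        alive[b] = False
        Z[b, :] = np.inf
        Z[:, b] = np.inf
        for c in np.flatnonzero(alive):
            if c == a:
                continue
            lo, hi = min(a, c), max(a, c)
            Z[lo, hi] = score(lo, hi)
    return [members[i] for i in np.flatnonzero(alive)]


def cluster_mutations(
    table: VariantCallTable,
    min_vaf_present: float = 0.075,
    max_vaf_absent: float = 0.0,
    max_cluster_dist: float = 0.1,
    min_cluster_size: int = 2,
    min_read_count: int = 40,
    min_mut_reads: int = 6,
    max_vaf_valid: float = 0.7,
    merge_z: float = 4.5,
) -> VAFClusterSet:
    """Cluster mutations by their cross-sample VAF profiles.

    Loci failing the read-support gates (maximum depth below
    ``min_read_count`` or maximum mutant reads below ``min_mut_reads``) are
    dropped.  Remaining loci are discretized per tumor sample into present
    (VAF >= ``min_vaf_present``), absent (VAF <= ``max_vaf_absent``) or
    uninformative, grouped by identical presence patterns (splitting groups
    whose pooled VAF profiles differ decisively), and groups are
    agglomeratively merged while the pooled binomial max-z stays below
    ``merge_z`` (about the 1e-4 familywise null quantile across samples)
    and the centroid L-infinity distance stays within ``max_cluster_dist``.
    Loci whose VAF exceeds ``max_vaf_valid`` anywhere are flagged as
    putative copy-number artifacts (kept).
    """
    tumor = ~table.is_healthy
    vaf = table.vaf[:, tumor]
    depth = table.depth

    read_ok = depth.max(axis=1) >= min_read_count
    mut_ok = table.alt_count.max(axis=1) >= min_mut_reads
    keep = read_ok & mut_ok
    locus_index = np.flatnonzero(keep)
    if len(locus_index) == 0:
        raise ValueError("no loci pass the read-support gates")
    v = vaf[keep]

    present = v >= min_vaf_present
    absent = v <= max_vaf_absent
    informative = present | absent
    if not informative.any():
        raise ValueError("all loci uninformative at the given thresholds")
    state = np.where(present, 1, np.where(absent, 0, 2)).astype(np.int8)

    # group loci with identical discretized patterns, then agglomeratively
    # merge groups whose pooled VAF profiles are statistically
    # indistinguishable (binomial z on pooled read counts) and whose
    # centroids stay within the L-infinity merge radius; the z-gate keeps
    # deep data from merging genuinely distinct profiles and lets shallow
    # noisy patterns coalesce as clusters grow
    patterns, pattern_of = np.unique(state, axis=0, return_inverse=True)
    alt_t = table.alt_count[keep][:, tumor].astype(float)
    dep_t = np.maximum(depth[keep][:, tumor], 1).astype(float)

    # singleton-up merging inside each pattern group splits branches that
    # share a presence pattern but differ in VAF (detectable at high depth)
    members = []
    for p in range(len(patterns)):
        idx = np.flatnonzero(pattern_of == p)
        members.extend(_agglomerate([np.array([i]) for i in idx],
                                    alt_t, dep_t, v, merge_z, np.inf))
    members = _agglomerate(members, alt_t, dep_t, v, merge_z, max_cluster_dist)
    n_raw = len(patterns)

    final_assign = np.empty(len(v), dtype=int)
    for c, m in enumerate(members):
        final_assign[m] = c
    final_centroids = np.array([v[m].mean(axis=0) for m in members])
    sizes = np.array([len(m) for m in members])
    pooled_p = np.array([alt_t[m].sum(axis=0) / dep_t[m].sum(axis=0)
                         for m in members])
    centroid_se = np.sqrt(np.maximum(pooled_p * (1 - pooled_p), 1e-9)
                          / np.array([dep_t[m].sum(axis=0) for m in members]))
    small = np.flatnonzero(sizes < min_cluster_size)
    high = locus_index[np.flatnonzero((v > max_vaf_valid).any(axis=1))]

    audit = {
        "input_loci": int(table.n_loci),
        "fail_read_count": int((~read_ok).sum()),
        "fail_mut_reads": int((~mut_ok & read_ok).sum()),
        "clustered_loci": int(len(locus_index)),
        "raw_patterns": int(n_raw),
        "clusters": int(len(members)),
        "flagged_high_vaf": int(len(high)),
    }
    log.info("cluster_mutations: %s", audit)
    return VAFClusterSet(
        final_assign, final_centroids, sizes, locus_index,
        [s for s, t in zip(table.samples, tumor) if t],
        min_vaf_present, small, high, audit, centroid_se,
    )


# ======================================================================
def _containment_order(patterns: np.ndarray, centroids: np.ndarray,
                       ccf_tol: float = 0.05, centroid_se=None):
    """Ancestry of clusters by sample-set containment + CCF monotonicity.

    A cluster's parent must be observed in a superset of its samples and
    carry at least its cancer-cell fraction (2 x VAF) in every sample; among
    qualifying ancestors the smallest sample set wins (ties by smaller CCF
    excess, then larger mean VAF).  Clusters without a qualifying ancestor
    attach to the (germline) root.  Violations of the pigeonhole/sum
    condition — overlapping clusters whose joint CCF exceeds the available
    cell fraction with neither containing the other — are returned for
    reporting.
    """
    n = len(patterns)
    mean_vaf = centroids.mean(axis=1)
    ccf = np.clip(2.0 * centroids, 0.0, 1.0)
    se = (np.zeros_like(centroids) if centroid_se is None
          else 2.0 * np.asarray(centroid_se))  # CCF-scale standard errors
    parents = np.full(n, -1, dtype=int)
    sets = [frozenset(np.flatnonzero(p)) for p in patterns]
    capacity = {c: ccf[c].copy() for c in range(n)}
    order = sorted(range(n), key=lambda c: (-mean_vaf[c], c))
    for c in order:
        candidates = []
        for d in range(n):
            if c == d:
                continue
            nested = sets[c] < sets[d] or (
                sets[c] == sets[d] and
                (mean_vaf[d], -d) > (mean_vaf[c], -c))
            tol = ccf_tol + 2.0 * (se[c] + se[d])
            if (nested and np.all(ccf[d] >= ccf[c] - tol)
                    and np.all(capacity[d] >= ccf[c] - tol)):
                # prefer parents that strictly dominate the child's cell
                # fraction everywhere (true ancestors always do; a sibling
                # masquerading as an ancestor usually dips below somewhere)
                viol = float(np.sum(np.maximum(ccf[c] - capacity[d], 0.0)))
                excess = float(np.sum(ccf[d] - ccf[c]))
                candidates.append((round(viol, 6), len(sets[d]), excess,
                                   -mean_vaf[d], d))
        if candidates:
            p = min(candidates)[4]
            parents[c] = p
            capacity[p] = capacity[p] - ccf[c]
    violations = []
    for c in range(n):
        for d in range(c + 1, n):
            if not (sets[c] & sets[d]):
                continue
            if sets[c] <= sets[d] or sets[d] <= sets[c]:
                continue
            tol = ccf_tol + 2.0 * (se[c] + se[d])
            if not np.any(ccf[c] + ccf[d] > 1.0 + tol):
                continue
            # only a true conflict if the pair is also incompatible with
            # nesting either way (otherwise they may be one noisy lineage)
            nest_cd = np.all(ccf[c] <= ccf[d] + tol)
            nest_dc = np.all(ccf[d] <= ccf[c] + tol)
            if not (nest_cd or nest_dc):
                violations.append((c, d))
    return parents, violations


def build_clone_genotypes(
    clusters: VAFClusterSet,
    clone_freq_cutoff: float = 0.075,
    conflict_tolerance: float = 0.0,
) -> CloneGenotypeSet:
    """Order clusters by perfect-phylogeny containment and emit clones.

    Each cluster defines one clone whose genotype carries the cluster's
    mutations plus those of all ancestral clusters.  Per-sample clone
    frequencies solve ``VAF ~ 0.5 * G^T f`` by non-negative least squares
    with the per-sample constraint ``sum(f) <= 1``; clones never reaching
    ``clone_freq_cutoff`` in any sample are dropped.
    """
    if clusters.n_clusters == 0:
        raise ValueError("empty cluster set")
    patterns = clusters.presence_patterns()
    mean_vaf = clusters.centroids.mean(axis=1)
    parents, conflicts = _containment_order(patterns, clusters.centroids,
                                            centroid_se=clusters.centroid_se)
    max_allowed = int(conflict_tolerance * clusters.n_clusters)
    if len(conflicts) > max_allowed:
        raise ValueError(
            "pigeonhole/sum condition violated for cluster pairs "
            f"{conflicts}; increase conflict_tolerance to proceed"
        )
    if conflicts:
        log.warning("pigeonhole/sum violations for cluster pairs %s", conflicts)

    n_loci = len(clusters.assignments)
    n_c = clusters.n_clusters
    genotypes = np.zeros((n_c, n_loci), dtype=bool)
    for c in range(n_c):
        node = c
        while node >= 0:
            genotypes[c, clusters.assignments == node] = True
            node = parents[node]

    # frequencies by constrained least squares per sample
    from scipy.optimize import lsq_linear

    samples = clusters.tumor_samples
    A = np.zeros((n_c, n_c))
    for c in range(n_c):
        node = c
        while node >= 0:
            A[node, c] = 1.0  # clone c carries cluster `node`'s mutations
            node = parents[node]
    freqs = np.zeros((len(samples), n_c))
    for s in range(len(samples)):
        target = 2.0 * clusters.centroids[:, s]  # cell fraction scale
        res = lsq_linear(A, np.clip(target, 0, 1), bounds=(0.0, 1.0))
        f = res.x
        if f.sum() > 1.0:
            # project onto the simplex face sum(f) = 1
            from scipy.optimize import minimize

            cons = [{"type": "ineq", "fun": lambda x: 1.0 - x.sum()}]
            r2 = minimize(lambda x: ((A @ x - np.clip(target, 0, 1)) ** 2).sum(),
                          f / f.sum(), bounds=[(0, 1)] * n_c, constraints=cons,
                          method="SLSQP")
            f = r2.x
        freqs[s] = f
    keep = freqs.max(axis=0) >= clone_freq_cutoff
    if not keep.any():
        keep = np.array([True] * n_c)
        log.warning("all clones below the frequency cutoff; keeping all")
    kept = np.flatnonzero(keep)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d clones below frequency cutoff %.3f", dropped, clone_freq_cutoff)
    # relabel by descending mean VAF for stable output
    kept = sorted(kept, key=lambda c: (-mean_vaf[c], c))
    labels = [chr(ord("A") + i) if len(kept) <= 26 else f"clone{i}"
              for i in range(len(kept))]
    parent_of = []
    for c in kept:
        p = parents[c]
        while p >= 0 and p not in kept:
            p = parents[p]
        parent_of.append(kept.index(p) if p >= 0 else -1)
    return CloneGenotypeSet(
        genotypes[kept],
        pd.DataFrame(freqs[:, kept], index=samples, columns=labels),
        labels,
        clusters.locus_index,
        [int(c) for c in kept],
        parent_of,
    )


# ======================================================================
def encode_sequences(
    genotypes: CloneGenotypeSet,
    table: VariantCallTable | None = None,
    mode: str = "binary",
    include_outgroup: bool = False,
    outgroup_label: str = "healthy",
) -> Alignment:
    """Clone sequences over the retained loci.

    ``binary`` writes A for reference status and T for the alternative
    allele; ``nucleotide`` substitutes each locus's actual ref/alt bases
    (requires ``table``).  Optionally appends an all-reference healthy
    outgroup.
    """
    G = genotypes.genotypes
    uniq = {tuple(row) for row in G}
    if len(uniq) < len(G):
        raise ValueError("clone genotypes are not distinct")
    if mode == "binary":
        ref_chars = np.full(G.shape[1], "A")
        alt_chars = np.full(G.shape[1], "T")
    elif mode == "nucleotide":
        if table is None:
            raise ValueError("nucleotide mode requires the variant table")
        loci = table.loci.iloc[genotypes.locus_index]
        ref_chars = loci["ref"].to_numpy()
        alt_chars = loci["alt"].to_numpy()
    else:
        raise ValueError(f"unknown encoding mode {mode!r}")
    names = list(genotypes.clone_labels)
    seqs = ["".join(np.where(row, alt_chars, ref_chars)) for row in G]
    if include_outgroup:
        names.append(outgroup_label)
        seqs.append("".join(ref_chars))
    return Alignment.from_sequences(names, seqs)
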