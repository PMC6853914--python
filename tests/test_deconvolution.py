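"""VAF clustering, clone genotype construction, and sequence encoding."""

import numpy as np
import pandas as pd
import pytest

from oncophylogeo.deconvolution import (build_clone_genotypes,
                                        cluster_mutations, encode_sequences)
from oncophylogeo.filtering import (VariantCallTable, call_filter,
                                    deconvolution_prefilter)
from oncophylogeo.simulate import (SimulationConfig, render_bulk_samples,
                                   simulate_clone_history)


def table_from_vafs(vafs, depth=200, healthy=0):
    n, s = np.asarray(vafs).shape
    names = [f"T{i}" for i in range(s - healthy)] + [f"N{i}" for i in range(healthy)]
    is_h = np.array([False] * (s - healthy) + [True] * healthy)
    d = np.full((n, s), depth)
    loci = pd.DataFrame({"chrom": "1", "pos": np.arange(n) + 1,
                         "ref": "A", "alt": "T"})
    return VariantCallTable(loci, names, d, np.rint(np.asarray(vafs) * depth).astype(int),
                           np.full((n, s), 60.0), is_h)


def noise_free_scenario(seed, n_clones=6, depth=1000):
    cfg = SimulationConfig(n_clones=n_clones, seed=seed, noise="none",
                           mean_depth=depth, purity=1.0, cn_segment_count=0,
                           cn_fraction=0.0, low_qual_fraction=0.0,
                           min_clone_freq=0.16)
    history = simulate_clone_history(cfg)
    table, cn, truth = render_bulk_samples(history)
    pre = deconvolution_prefilter(call_filter(table, cn), cn)
    return history, pre


def truth_genotypes(history, pre, locus_index):
    M = history.clone_mutation_matrix()
    pos_to_mut = {p: i for i, p in enumerate(history.mutations["pos"])}
    cols = [pos_to_mut[pre.loci["pos"].iloc[li]] for li in locus_index]
    return M[:, cols]


class TestClusterMutations:
    def test_identical_profiles_share_cluster(self):
        v = np.array([[0.3, 0.0, 0.2]] * 2 + [[0.0, 0.4, 0.1]] * 3)
        cl = cluster_mutations(table_from_vafs(v), min_read_count=40)
        a = cl.assignments
        assert a[0] == a[1]
        assert a[2] == a[3] == a[4]
        assert a[0] != a[2]

    def test_read_count_gate_drops_shallow_locus(self):
        v = np.array([[0.3, 0.3, 0.3]] * 3)
        table = table_from_vafs(v, depth=39)
        table.depth[1:] = 60
        table.alt_count[1:] = 18
        cl = cluster_mutations(table)
        assert 0 not in cl.locus_index
        assert cl.audit["fail_read_count"] == 1

    def test_mut_read_gate(self):
        v = np.array([[0.05, 0.0, 0.0]] + [[0.3, 0.3, 0.3]] * 2)
        cl = cluster_mutations(table_from_vafs(v, depth=100))
        assert 0 not in cl.locus_index  # 5 mutant reads < 6

    def test_noise_free_clusters_equal_distinct_branch_sets(self):
        history, pre = noise_free_scenario(2, n_clones=5)
        cl = cluster_mutations(pre)
        pos_to_branch = dict(zip(history.mutations["pos"], history.mutations["branch"]))
        branches = [pos_to_branch[pre.loci["pos"].iloc[li]] for li in cl.locus_index]
        n_distinct = len(set(branches))
        assert cl.n_clusters == n_distinct
        # and the partition matches the branch partition exactly
        df = pd.DataFrame({"cluster": cl.assignments, "branch": branches})
        assert (df.groupby("cluster")["branch"].nunique() == 1).all()

    def test_all_uninformative_raises(self):
        v = np.full((4, 3), 0.05)  # between absent (0) and present (0.075)
        with pytest.raises(ValueError, match="uninformative"):
            cluster_mutations(table_from_vafs(v, depth=200))

    def test_high_vaf_flagged(self):
        v = np.array([[0.8, 0.3, 0.3]] + [[0.3, 0.3, 0.3]] * 2)
        cl = cluster_mutations(table_from_vafs(v, depth=100))
        assert 0 in cl.high_vaf_flagged


class TestBuildCloneGenotypes:
    def test_single_cluster_single_clone(self):
        v = np.array([[0.4, 0.42, 0.41]] * 5)
        genotypes = build_clone_genotypes(cluster_mutations(table_from_vafs(v)))
        assert genotypes.n_clones == 1
        assert genotypes.genotypes.all()

    def test_low_frequency_clone_dropped(self):
        # truncal cluster plus a subclone never above the 0.075 cutoff
        v = np.concatenate([
            np.tile([0.4, 0.4, 0.4], (5, 1)),
            np.tile([0.03, 0.03, 0.03], (5, 1)),
        ])
        cl = cluster_mutations(table_from_vafs(v, depth=400),
                               min_vaf_present=0.02)
        genotypes = build_clone_genotypes(cl)
        freqs = genotypes.frequencies.to_numpy()
        # every retained clone reaches the cutoff somewhere
        assert (freqs.max(axis=0) >= 0.075).all()

    def test_exact_recovery_noise_free(self):
        history, pre = noise_free_scenario(1)
        genotypes = build_clone_genotypes(cluster_mutations(pre))
        truth = truth_genotypes(history, pre, genotypes.locus_index)
        assert {tuple(r) for r in truth} == {tuple(r) for r in genotypes.genotypes}

    def test_recovery_up_to_relabeling_across_seeds(self):
        hits = 0
        for seed in (1, 2, 4, 7):
            history, pre = noise_free_scenario(seed)
            genotypes = build_clone_genotypes(cluster_mutations(pre))
            truth = truth_genotypes(history, pre, genotypes.locus_index)
            hits += {tuple(r) for r in truth} == {tuple(r) for r in genotypes.genotypes}
        assert hits == 4

    def test_frequencies_sum_below_one(self):
        history, pre = noise_free_scenario(2)
        genotypes = build_clone_genotypes(cluster_mutations(pre))
        sums = genotypes.frequencies.to_numpy().sum(axis=1)
        assert np.all(sums <= 1.0 + 1e-6)


class TestEncodeSequences:
    def _genotypes(self):
        history, pre = noise_free_scenario(1)
        return build_clone_genotypes(cluster_mutations(pre)), pre

    def test_binary_alphabet_and_length(self):
        genotypes, pre = self._genotypes()
        aln = encode_sequences(genotypes)
        assert aln.n_sites == len(genotypes.locus_index)
        seqs = aln.sequences()
        assert set("".join(seqs)) <= {"A", "T"}

    def test_outgroup_all_reference(self):
        genotypes, pre = self._genotypes()
        aln = encode_sequences(genotypes, include_outgroup=True)
        assert aln.names[-1] == "healthy"
        assert set(aln.sequences()[-1]) == {"A"}

    def test_encoding_preserves_hamming_distances(self):
        genotypes, pre = self._genotypes()
        b = encode_sequences(genotypes, mode="binary")
        n = encode_sequences(genotypes, table=pre, mode="nucleotide")

        def ham(aln):
            c = aln.codes
            return {(i, j): int((c[i] != c[j]).sum())
                    for i in range(len(c)) for j in range(i)}

        assert ham(b) == ham(n)

    def test_clone_without_mutations_is_all_reference(self):
        # a clone genotype of all-False encodes to all-A
        from oncophylogeo.deconvolution import CloneGenotypeSet

        g = CloneGenotypeSet(
            np.array([[False] * 4, [True, False, True, False]]),
            pd.DataFrame([[0.5, 0.3]], index=["s"], columns=["A", "B"]),
            ["A", "B"], np.arange(4), [0, 1], [-1, 0])
        aln = encode_sequences(g)
        assert aln.sequences()[0] == "AAAA"
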