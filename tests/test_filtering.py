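"""Somatic filtering rules, VAF PCA, Hudson FST, and the Mantel test."""

import numpy as np
import pandas as pd
import pytest

from oncophylogeo.filtering import (CopyNumberSegments, VariantCallTable,
                                    call_filter, deconvolution_prefilter,
                                    hudson_fst_locus, mantel_test,
                                    pairwise_fst, vaf_pca)
from oncophylogeo.simulate import (SimulationConfig, render_bulk_samples,
                                   simulate_clone_history)

from conftest import HEALTHY, SAMPLES


def audit_call_filter(table, cn, min_cov=20, min_vaf=0.05, min_qual=20):
    """Independent plain-loop audit of the somatic call filter rules."""
    keep = []
    diploid, covered = cn.status(table.loci, table.samples)
    for i in range(table.n_loci):
        ok = all(table.depth[i, j] >= min_cov for j in range(len(table.samples)))
        call = False
        for j, h in enumerate(table.is_healthy):
            if h:
                if table.alt_count[i, j] > 0:
                    ok = False
            else:
                vaf = table.alt_count[i, j] / table.depth[i, j]
                if vaf >= min_vaf and table.qual[i, j] >= min_qual:
                    call = True
        vaf_any = any(table.alt_count[i, j] / table.depth[i, j] >= min_vaf
                      for j, h in enumerate(table.is_healthy) if not h)
        ok = ok and call and vaf_any
        for j, h in enumerate(table.is_healthy):
            if not h and covered[i, j] and not diploid[i, j]:
                ok = False
        keep.append(ok)
    return np.array(keep)


class TestCallFilter:
    def test_toy_table_retains_hand_audited_set(self, toy_table):
        table, cn = toy_table
        out = call_filter(table, cn)
        expected = audit_call_filter(table, cn)
        assert out.n_loci == 9
        assert set(out.loci["pos"]) == set(table.loci["pos"][expected])

    def test_low_coverage_in_healthy_sample_removed(self, toy_table):
        table, cn = toy_table
        out = call_filter(table, cn)
        assert 3001 not in set(out.loci["pos"])  # healthy sample at 19x

    def test_germline_evidence_removed(self, toy_table):
        table, cn = toy_table
        out = call_filter(table, cn)
        assert not (set(out.loci["pos"]) & {4000, 4001, 4002})

    def test_empty_table(self):
        loci = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        z = np.zeros((0, 5), dtype=int)
        table = VariantCallTable(loci, SAMPLES, z, z, z.astype(float), HEALTHY)
        out = call_filter(table, CopyNumberSegments.empty())
        assert out.n_loci == 0
        assert out.audit["retained"] == 0

    def test_requires_healthy_sample(self, toy_table):
        table, cn = toy_table
        tumor_only = VariantCallTable(
            table.loci, table.samples[:3], table.depth[:, :3],
            table.alt_count[:, :3], table.qual[:, :3], np.zeros(3, bool))
        with pytest.raises(ValueError, match="healthy"):
            call_filter(tumor_only, cn)

    def test_idempotent(self, toy_table):
        table, cn = toy_table
        once = call_filter(table, cn)
        twice = call_filter(once, cn)
        assert twice.n_loci == once.n_loci
        assert list(twice.loci["pos"]) == list(once.loci["pos"])

    def test_noise_free_simulation_separates_somatic_from_germline(self):
        cfg = SimulationConfig(n_clones=5, seed=3, noise="none", purity=1.0,
                               mean_depth=200, cn_segment_count=0,
                               cn_fraction=0.0, low_qual_fraction=0.0,
                               min_clone_freq=0.12)
        history = simulate_clone_history(cfg)
        table, cn, truth = render_bulk_samples(history)
        out = call_filter(table, cn)
        kept = set(zip(out.loci["chrom"], out.loci["pos"]))
        for _, row in truth.iterrows():
            key = (row["chrom"], row["pos"])
            if row["is_germline"]:
                assert key not in kept
            elif row["expected_vaf_max"] >= 0.05:
                assert key in kept


class TestPrefilter:
    def test_toy_follow_up_counts(self, toy_table):
        table, cn = toy_table
        out = deconvolution_prefilter(call_filter(table, cn), cn)
        # the two VAF-0.08 loci drop below the 0.10 deconvolution floor
        assert out.n_loci == 7
        assert not (set(out.loci["pos"]) & {2000, 2001})

    def test_cn_overlap_removed(self, toy_table):
        table, cn = toy_table
        out = deconvolution_prefilter(table, cn)
        assert not (set(out.loci["pos"]) & {7000, 7001})

    def test_high_vaf_diploid_retained(self, toy_table):
        table, cn = toy_table
        out = deconvolution_prefilter(table, cn)
        assert {1000, 1001} <= set(out.loci["pos"])


class TestVafPca:
    def _table(self, vafs):
        n, s = vafs.shape
        depth = np.full((n, s), 100)
        alt = np.rint(vafs * 100).astype(int)
        loci = pd.DataFrame({"chrom": "1", "pos": np.arange(n) + 1,
                             "ref": "A", "alt": "T"})
        return VariantCallTable(loci, [f"s{i}" for i in range(s)], depth, alt,
                                np.full((n, s), 60.0), np.zeros(s, bool))

    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 0.5, size=(30, 1))
        vafs = np.concatenate([v, v, rng.uniform(0, 0.5, (30, 2))], axis=1)
        coords, _ = vaf_pca(self._table(vafs))
        assert np.allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(1)
        coords, explained = vaf_pca(self._table(rng.uniform(0, 0.5, (40, 6))))
        assert abs(explained.sum() - 1.0) < 1e-9

    def test_degenerate_matrix_raises(self):
        vafs = np.tile(np.linspace(0.1, 0.4, 20)[:, None], (1, 4))
        with pytest.raises(ValueError, match="degenerate"):
            vaf_pca(self._table(vafs))

    def test_two_clade_mixture_separates_on_pc1(self):
        from sklearn.metrics import silhouette_score

        cfg = SimulationConfig(n_clones=8, seed=5, mean_depth=200,
                               cn_segment_count=0, low_qual_fraction=0.0)
        history = simulate_clone_history(cfg)
        table, cn, _ = render_bulk_samples(history)
        filtered = call_filter(table, cn)
        coords, _ = vaf_pca(filtered, tumor_only=True)
        # label samples by whether the left root clade dominates them
        tree = history.tree
        ch = [c for c in range(tree.n_nodes) if tree.parent[c] == tree.root]
        masks = tree.clade_masks()
        left = [t for t in range(tree.n_tips) if masks[ch[0]] >> t & 1]
        mix = history.mixtures.to_numpy()
        labels = (mix[:, left].sum(axis=1) > 0.5).astype(int)
        if len(set(labels)) == 2:
            score = silhouette_score(coords[["PC1"]].to_numpy(), labels)
            assert score > 0


class TestHudsonFst:
    def _pair_table(self, v1, v2, depth=100):
        n = len(v1)
        vafs = np.stack([v1, v2], axis=1)
        loci = pd.DataFrame({"chrom": "1", "pos": np.arange(n) + 1,
                             "ref": "A", "alt": "T"})
        d = np.full((n, 2), depth)
        return VariantCallTable(loci, ["s1", "s2"], d,
                                np.rint(vafs * depth).astype(int),
                                np.full((n, 2), 60.0), np.zeros(2, bool))

    def test_identical_profiles_zero(self):
        v = np.linspace(0.1, 0.4, 20)
        fst = pairwise_fst(self._pair_table(v, v))
        assert fst.iloc[0, 1] == 0.0

    def test_fixed_difference_matches_per_locus_oracle(self):
        v1 = np.zeros(30)
        v2 = np.full(30, 0.5)
        table = self._pair_table(v1, v2)
        fst = pairwise_fst(table)
        num, den = hudson_fst_locus(v1, v2, np.full(30, 100), np.full(30, 100))
        expected = np.clip(num.sum() / den.sum(), 0, 1)
        assert fst.iloc[0, 1] == pytest.approx(expected)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 0.5, size=(25, 3))
        loci = pd.DataFrame({"chrom": "1", "pos": np.arange(25) + 1,
                             "ref": "A", "alt": "T"})
        d = np.full((25, 3), 80)
        table = VariantCallTable(loci, ["a", "b", "c"], d,
                                 np.rint(v * 80).astype(int),
                                 np.full((25, 3), 60.0), np.zeros(3, bool))
        fst = pairwise_fst(table)
        assert np.allclose(fst, fst.T)
        assert np.all(np.diag(fst) == 0)


class TestMantel:
    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(6, 2))
        from scipy.spatial.distance import cdist

        D = cdist(x, x)
        r, p = mantel_test(D, D, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(size=(7, 7))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        B = rng.uniform(size=(7, 7))
        B = (B + B.T) / 2
        np.fill_diagonal(B, 0)
        r1, p1 = mantel_test(A, B, n_perm=499, seed=9)
        perm = rng.permutation(7)
        r2, p2 = mantel_test(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)],
                             n_perm=499, seed=9)
        assert r1 == pytest.approx(r2)
        # p compares the same statistic distribution either way
        assert abs(p1 - p2) < 0.05

    def test_type_one_error_rate(self):
        # independent random matrices: p < 0.05 in about 5% of replicates
        rng = np.random.default_rng(5)
        hits = 0
        reps = 300
        for _ in range(reps):
            A = rng.uniform(size=(10, 10))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            B = rng.uniform(size=(10, 10))
            B = (B + B.T) / 2
            np.fill_diagonal(B, 0)
            _, p = mantel_test(A, B, n_perm=199, seed=int(rng.integers(2**31)))
            hits += p < 0.05
        # binomial 99% band around 0.05 for 300 reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 2.58 * se + 1e-9

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            mantel_test(np.zeros((2, 2)), np.zeros((2, 2)))


def test_mantel_statistic_matches_skbio():
    # independent oracle: skbio computes the same Pearson Mantel r
    skbio = pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

    rng = np.random.default_rng(8)
    x = rng.uniform(size=(8, 2))
    y = rng.uniform(size=(8, 2))
    from scipy.spatial.distance import cdist

    A, B = cdist(x, x), cdist(y, y)
    r_ours, _ = mantel_test(A, B, n_perm=99, seed=0)
    r_sk, _, _ = sk_mantel(DistanceMatrix(A), DistanceMatrix(B),
                           permutations=0)
    assert r_ours == pytest.approx(r_sk, abs=1e-9)
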