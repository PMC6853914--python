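"""Somatic variant filtering and spatial population structure.

Implements the two-stage filtering used for multiregion bulk tumor exomes:

* a high-stringency somatic call filter (coverage >= 20x in every sample,
  VAF >= 0.05 in at least one tumor sample, Phred quality >= 20, no alt
  evidence in any healthy sample, diploid copy number in all tumor samples),
* a pre-deconvolution filter (max tumor VAF >= 0.10, read depth >= 20 in at
  least one sample, no overlap with copy-number events),

plus PCA of VAF profiles, Hudson's pairwise FST between bulk samples, and a
Mantel permutation test of genetic versus anatomical distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

log = logging.getLogger("oncophylogeo.filtering")

__all__ = [
    "VariantCallTable",
    "CopyNumberSegments",
    "SampleGeometry",
    "call_filter",
    "deconvolution_prefilter",
    "vaf_pca",
    "pairwise_fst",
    "mantel_test",
]


@dataclass
class VariantCallTable:
    """Per-locus, per-sample read evidence for candidate SNVs.

    ``loci`` has columns chrom, pos (1-based), ref, alt; the matrices are
    (n_loci, n_samples).
    """

    loci: pd.DataFrame
    samples: list
    depth: np.ndarray
    alt_count: np.ndarray
    qual: np.ndarray
    is_healthy: np.ndarray
    audit: dict = field(default_factory=dict)

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=float)
        self.is_healthy = np.asarray(self.is_healthy, dtype=bool)
        if np.any(self.alt_count > self.depth) or np.any(self.alt_count < 0):
            raise ValueError("alt counts must satisfy 0 <= alt <= depth")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_loci(self):
        return len(self.loci)

    @property
    def vaf(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(self.depth > 0, self.alt_count / np.maximum(self.depth, 1), 0.0)
        return v

    @property
    def tumor_samples(self):
        return [s for s, h in zip(self.samples, self.is_healthy) if not h]

    def subset_loci(self, mask) -> "VariantCallTable":
        mask = np.asarray(mask)
        return VariantCallTable(
            self.loci.loc[mask].reset_index(drop=True),
            self.samples,
            self.depth[mask],
            self.alt_count[mask],
            self.qual[mask],
            self.is_healthy,
            dict(self.audit),
        )

    # -------------------------------------------------- I/O (TSV + VCF)
    def to_tsv(self, path) -> None:
        df = self.loci.copy()
        for j, s in enumerate(self.samples):
            df[f"{s}.depth"] = self.depth[:, j]
            df[f"{s}.alt"] = self.alt_count[:, j]
            df[f"{s}.qual"] = self.qual[:, j]
        with open(path, "w") as fh:
            fh.write("#healthy_samples=" + ",".join(
                s for s, h in zip(self.samples, self.is_healthy) if h) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VariantCallTable":
        with open(path) as fh:
            first = fh.readline().strip()
            healthy = set()
            if first.startswith("#healthy_samples="):
                names = first.split("=", 1)[1]
                healthy = set(n for n in names.split(",") if n)
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        samples = [c[: -len(".depth")] for c in df.columns if c.endswith(".depth")]
        loci = df[["chrom", "pos", "ref", "alt"]].copy()
        depth = np.stack([df[f"{s}.depth"].to_numpy() for s in samples], axis=1)
        alt = np.stack([df[f"{s}.alt"].to_numpy() for s in samples], axis=1)
        qual = np.stack([df[f"{s}.qual"].to_numpy() for s in samples], axis=1)
        is_h = np.array([s in healthy for s in samples])
        return cls(loci, samples, depth, alt, qual, is_h)

    def to_vcf(self, path) -> None:
        """Write as a minimal multi-sample VCF 4.2 with DP/AD/GQ."""
        import pysam

        header = pysam.VariantHeader()
        header.add_line('##source=oncophylogeo')
        header.add_line('##healthy_samples=' + ",".join(
            s for s, h in zip(self.samples, self.is_healthy) if h))
        for chrom in pd.unique(self.loci["chrom"].astype(str)):
            header.contigs.add(chrom, length=2**29)
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("DP", 1, "Integer", "Read depth")
        header.formats.add("AD", "R", "Integer", "Allelic depths (ref,alt)")
        header.formats.add("GQ", 1, "Integer", "Call quality (Phred)")
        for s in self.samples:
            header.add_sample(s)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for i, row in self.loci.iterrows():
                rec = vcf.new_record(
                    contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                    alleles=(str(row["ref"]), str(row["alt"])),
                )
                for j, s in enumerate(self.samples):
                    dp = int(self.depth[i, j])
                    ad = int(self.alt_count[i, j])
                    rec.samples[s]["GT"] = (0, 1) if ad > 0 else (0, 0)
                    rec.samples[s]["DP"] = dp
                    rec.samples[s]["AD"] = (dp - ad, ad)
                    rec.samples[s]["GQ"] = int(round(self.qual[i, j]))
                vcf.write(rec)

    @classmethod
    def from_vcf(cls, path) -> "VariantCallTable":
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            samples = list(vcf.header.samples)
            healthy = set()
            for rec in vcf.header.records:
                line = str(rec)
                if line.startswith("##healthy_samples="):
                    healthy = set(line.strip().split("=", 1)[1].split(","))
            rows, depth, alt, qual = [], [], [], []
            for rec in vcf:
                if len(rec.alts or ()) != 1:
                    continue  # bi-allelic records only
                rows.append((rec.contig, rec.pos, rec.ref, rec.alts[0]))
                depth.append([rec.samples[s].get("DP", 0) or 0 for s in samples])
                ad = [rec.samples[s].get("AD", (0, 0)) for s in samples]
                alt.append([a[1] if a and a[1] is not None else 0 for a in ad])
                qual.append([rec.samples[s].get("GQ", 0) or 0 for s in samples])
        loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        return cls(loci, samples, np.array(depth), np.array(alt),
                   np.array(qual, dtype=float),
                   np.array([s in healthy for s in samples]))


@dataclass
class CopyNumberSegments:
    """Copy-number segments per sample (0-based, half-open intervals).

    ``segments`` columns: sample, chrom, start, end, total_cn, minor_cn.
    """

    segments: pd.DataFrame

    COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]

    def __post_init__(self):
        self.segments = self.segments.reset_index(drop=True)
        for col in self.COLUMNS:
            if col not in self.segments.columns:
                raise ValueError(f"missing column {col!r}")
        for (samp, chrom), grp in self.segments.groupby(["sample", "chrom"]):
            g = grp.sort_values("start")
            if np.any(g["end"].to_numpy()[:-1] > g["start"].to_numpy()[1:]):
                raise ValueError(f"overlapping segments for {samp}/{chrom}")

    @classmethod
    def empty(cls) -> "CopyNumberSegments":
        return cls(pd.DataFrame(columns=cls.COLUMNS))

    @classmethod
    def from_tsv(cls, path) -> "CopyNumberSegments":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.segments.to_csv(path, sep="\t", index=False)

    def status(self, loci: pd.DataFrame, samples) -> tuple:
        """(diploid, covered) boolean arrays of shape (n_loci, n_samples).

        A locus (1-based position) is diploid for a sample when every
        overlapping segment has total_cn == 2 and minor_cn == 1; positions
        with no overlapping segment are flagged uncovered.
        """
        n_loci = len(loci)
        diploid = np.ones((n_loci, len(samples)), dtype=bool)
        covered = np.zeros((n_loci, len(samples)), dtype=bool)
        pos0 = loci["pos"].to_numpy() - 1
        chroms = loci["chrom"].astype(str).to_numpy()
        for j, s in enumerate(samples):
            seg = self.segments[self.segments["sample"] == s]
            for chrom, grp in seg.groupby(seg["chrom"].astype(str)):
                g = grp.sort_values("start")
                starts = g["start"].to_numpy()
                ends = g["end"].to_numpy()
                dip = (g["total_cn"].to_numpy() == 2) & (g["minor_cn"].to_numpy() == 1)
                sel = chroms == chrom
                idx = np.searchsorted(starts, pos0[sel], side="right") - 1
                inside = (idx >= 0) & (pos0[sel] < ends[np.clip(idx, 0, None)])
                rows = np.flatnonzero(sel)
                covered[rows[inside], j] = True
                diploid[rows[inside], j] = dip[idx[inside]]
        return diploid, covered


@dataclass
class SampleGeometry:
    """2-D anatomical coordinates (cm) and region labels per location."""

    names: list
    coords: np.ndarray
    regions: list

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 2):
            raise ValueError("coordinates must be (n_locations, 2)")
        if len(self.regions) != len(self.names):
            raise ValueError("one region label per location required")

    @property
    def n_locations(self):
        return len(self.names)

    @property
    def distance_matrix(self) -> np.ndarray:
        return cdist(self.coords, self.coords)

    @classmethod
    def from_csv(cls, path) -> "SampleGeometry":
        df = pd.read_csv(path)
        return cls(df["location"].tolist(),
                   df[["x", "y"]].to_numpy(), df["region"].tolist())

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "location": self.names,
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
            "region": self.regions,
        }).to_csv(path, index=False)


# ======================================================================
def call_filter(
    table: VariantCallTable,
    cn: CopyNumberSegments | None = None,
    min_cov: int = 20,
    min_vaf: float = 0.05,
    min_qual: float = 20.0,
    uncovered: str = "diploid",
) -> VariantCallTable:
    """High-stringency somatic call filter.

    Retains loci that (1) reach ``min_cov`` coverage in every tumor and
    healthy sample, (2) have VAF >= ``min_vaf`` in at least one tumor sample,
    (3) have call quality >= ``min_qual`` in every sample with alt evidence,
    (4) show zero alt reads in every healthy sample (germline removal), and
    (5) fall in diploid (2 total / 1 minor) segments in all tumor samples.
    Per-rule removal counts are stored in ``result.audit`` and logged.
    """
    if not np.any(table.is_healthy):
        raise ValueError("germline filtering requires at least one healthy sample")
    if uncovered not in ("diploid", "remove"):
        raise ValueError("uncovered must be 'diploid' or 'remove'")
    cn = cn or CopyNumberSegments.empty()
    tumor = ~table.is_healthy
    vaf = table.vaf

    cov_ok = (table.depth >= min_cov).all(axis=1)
    # a somatic call stands where some tumor sample supports it with both
    # sufficient VAF and a confident (Phred) call
    vaf_pass = vaf[:, tumor] >= min_vaf
    vaf_ok = vaf_pass.any(axis=1)
    qual_ok = (vaf_pass & (table.qual[:, tumor] >= min_qual)).any(axis=1) | ~vaf_ok
    germ_ok = (table.alt_count[:, table.is_healthy] == 0).all(axis=1)
    diploid, covered = cn.status(table.loci, table.samples)
    n_uncovered = int((~covered[:, tumor]).any(axis=1).sum())
    if uncovered == "diploid":
        dip_ok = np.where(covered[:, tumor], diploid[:, tumor], True).all(axis=1)
        if n_uncovered and len(cn.segments):
            log.warning("%d loci uncovered by CN segments treated as diploid", n_uncovered)
    else:
        dip_ok = (diploid[:, tumor] & covered[:, tumor]).all(axis=1)

    keep = cov_ok & vaf_ok & qual_ok & germ_ok & dip_ok
    audit = {
        "input_loci": int(table.n_loci),
        "fail_coverage": int((~cov_ok).sum()),
        "fail_vaf": int((~vaf_ok).sum()),
        "fail_quality": int((~qual_ok).sum()),
        "fail_germline": int((~germ_ok).sum()),
        "fail_nondiploid": int((~dip_ok).sum()),
        "uncovered_loci": n_uncovered,
        "retained": int(keep.sum()),
    }
    log.info("call_filter: %s", audit)
    out = table.subset_loci(keep)
    out.audit = audit
    return out


def deconvolution_prefilter(
    table: VariantCallTable, cn: CopyNumberSegments | None = None
) -> VariantCallTable:
    """Filter applied before clonal deconvolution.

    Removes loci whose maximum tumor VAF is below 0.10, loci with read depth
    below 20 in *all* samples, and loci overlapping any copy-number event
    (non-diploid segment) in any sample.
    """
    cn = cn or CopyNumberSegments.empty()
    tumor = ~table.is_healthy
    vaf = table.vaf
    maxvaf_ok = (vaf[:, tumor] >= 0.10).any(axis=1)
    depth_ok = (table.depth >= 20).any(axis=1)
    diploid, covered = cn.status(table.loci, table.samples)
    cn_ok = ~((covered & ~diploid).any(axis=1))
    keep = maxvaf_ok & depth_ok & cn_ok
    audit = {
        "input_loci": int(table.n_loci),
        "fail_max_vaf": int((~maxvaf_ok).sum()),
        "fail_depth_everywhere": int((~depth_ok).sum()),
        "fail_cn_overlap": int((~cn_ok).sum()),
        "retained": int(keep.sum()),
    }
    log.info("deconvolution_prefilter: %s", audit)
    out = table.subset_loci(keep)
    out.audit = audit
    return out


# ======================================================================
def vaf_pca(table: VariantCallTable, tumor_only: bool = False):
    """Centered PCA of the sample x locus VAF matrix.

    Returns ``(coords, explained)``: sample coordinates on the principal
    axes (DataFrame indexed by sample) and explained-variance fractions.
    """
    from sklearn.decomposition import PCA

    vaf = table.vaf
    samples = list(table.samples)
    if tumor_only:
        keep = ~table.is_healthy
        vaf = vaf[:, keep]
        samples = [s for s, k in zip(table.samples, keep) if k]
    X = vaf.T  # samples x loci
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate VAF matrix: all samples identical")
    pca = PCA()
    coords = pca.fit_transform(X)
    cols = [f"PC{i+1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=samples, columns=cols), pca.explained_variance_ratio_


def hudson_fst_locus(p1, p2, n1, n2):
    """Per-locus Hudson FST numerator and denominator (test oracle uses this)."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pairwise_fst(table: VariantCallTable, estimator: str = "hudson") -> pd.DataFrame:
    """Hudson-type pairwise FST between tumor samples.

    VAFs play the role of allele frequencies and read depths the role of
    sample sizes; loci are combined as a ratio of averages and the result is
    clamped to [0, 1].
    """
    if estimator != "hudson":
        raise ValueError("only the Hudson estimator is implemented")
    tumor_idx = np.flatnonzero(~table.is_healthy)
    if len(tumor_idx) < 2:
        raise ValueError("need at least two tumor samples")
    names = [table.samples[i] for i in tumor_idx]
    vaf = table.vaf
    fst = np.zeros((len(tumor_idx), len(tumor_idx)))
    for a in range(len(tumor_idx)):
        for b in range(a + 1, len(tumor_idx)):
            i, j = tumor_idx[a], tumor_idx[b]
            ok = (table.depth[:, i] >= 2) & (table.depth[:, j] >= 2)
            num, den = hudson_fst_locus(
                vaf[ok, i], vaf[ok, j], table.depth[ok, i], table.depth[ok, j]
            )
            informative = den > 0
            if not np.any(informative):
                log.warning("no informative loci for pair (%s, %s)", names[a], names[b])
                val = np.nan
            else:
                val = float(np.clip(num[informative].sum() / den[informative].sum(), 0.0, 1.0))
            fst[a, b] = fst[b, a] = val
    return pd.DataFrame(fst, index=names, columns=names)


def mantel_test(genetic, geographic, n_perm: int = 999, seed: int = 0):
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson correlation of the off-diagonal elements;
    rows and columns of the second matrix are permuted jointly and the
    one-sided p-value is ``(1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    A = np.asarray(genetic, dtype=float)
    B = np.asarray(geographic, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    if not (np.allclose(A, A.T, equal_nan=True) and np.allclose(B, B.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")
    n = A.shape[0]
    if n < 3:
        raise ValueError("Mantel test requires at least 3 samples")
    iu = np.triu_indices(n, k=1)
    valid = np.isfinite(A) & np.isfinite(B)

    def corr(Bp):
        a, b = A[iu], Bp[iu]
        m = np.isfinite(a) & np.isfinite(b)
        a, b = a[m], b[m]
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(B[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p
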