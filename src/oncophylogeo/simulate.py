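"""Forward simulator of an exponentially growing, spatially dispersing
clone population rendered into bulk multiregion sequencing tables.

The generative direction follows the inferential models downstream: the
clone genealogy is drawn backwards from a coalescent with exponentially
growing population size; mutations and geographic ranges then evolve
forwards along its branches.  Defaults emulate the structure of a
metastatic colorectal cancer autopsy series: 16 tumor locations in four
anatomical regions (primary colon tumor, colonic and hepatic lymph nodes,
liver) sampled at ~60x exome coverage, 21 clones, growth rate 0.014 per
generation, one generation every 4 days, and a few hundred diploid somatic
SNVs.  The somatic mutation rate default (1.5e-9 /site/generation) sits in
the upper range reported for metastatic colorectal cancer so that an
exome-scale target carries a realistic number of segregating SNVs; the
experimentally derived 4.6e-10 used as the dating prior remains the clock
default elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biogeography import DispersalModel, simulate_range_history
from .coalescent import sample_coalescent_tree
from .filtering import CopyNumberSegments, SampleGeometry, VariantCallTable
from .trees import Tree

__all__ = ["SimulationConfig", "CloneHistory", "simulate_clone_history",
           "render_bulk_samples", "default_geometry", "write_history"]

_BASES = "ACGT"
_CODON_TABLE = {}


def _genetic_code():
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for c in standard_dna_table.stop_codons:
            _CODON_TABLE[c] = "*"
    return _CODON_TABLE


def default_geometry() -> SampleGeometry:
    """Anatomical layout (cm) emulating a colorectal autopsy series.

    Eight primary-tumor locations (C1-C8), two colonic lymph nodes, two
    hepatic lymph nodes and four liver locations; the liver cluster sits
    ~25 cm from the colon.
    """
    names = ([f"C{i}" for i in range(1, 9)] + ["CL1", "CL2"]
             + ["HL1", "HL2"] + [f"L{i}" for i in range(1, 5)])
    regions = (["primary"] * 8 + ["colonic_lymph_node"] * 2
               + ["hepatic_lymph_node"] * 2 + ["liver"] * 4)
    coords = np.array([
        [0.0, 0.0], [1.5, 0.5], [0.8, 1.6], [-0.9, 1.2],
        [-1.4, -0.6], [0.3, -1.5], [1.9, -0.9], [-0.3, 2.3],   # primary
        [5.5, 2.0], [6.5, -1.0],                                # colonic LN
        [21.0, 9.5], [22.5, 11.0],                              # hepatic LN
        [27.0, 12.0], [28.5, 13.5], [29.5, 11.0], [27.5, 14.5], # liver
    ])
    return SampleGeometry(names, coords, regions)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic tumor (defaults = study-like conditions)."""

    n_clones: int = 21
    n_locations: int = 16
    geometry: SampleGeometry = None
    growth_rate_r: float = 0.014          # per generation
    n0: float = 6e5                       # present-day effective size
    generation_days: float = 4.0
    mutation_rate_mu: float = 1.5e-9        # substitutions/site/generation
    target_sites: int = 30_000_000
    coding_fraction: float = 0.75
    dispersal_beta: float = 1.0
    gain_rate: float = 2.5e-4             # per generation
    loss_rate: float = 1.2e-4
    seed_location: int = 0
    n_samples: int = 16                   # tumor samples
    n_healthy: int = 2
    mean_depth: float = 60.0
    purity: float = 0.9
    noise: str = "binomial"               # or "none"
    n_germline: int = 150
    low_qual_fraction: float = 0.05
    cn_segment_count: int = 3
    cn_fraction: float = 0.04
    min_clone_freq: float = 0.05
    mixture_alpha: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.geometry is None:
            self.geometry = default_geometry()
        if self.geometry.n_locations != self.n_locations:
            raise ValueError("coordinates count must equal n_locations")
        for name in ("growth_rate_r", "mutation_rate_mu", "gain_rate",
                     "loss_rate", "mean_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if not 0 <= self.coding_fraction <= 1:
            raise ValueError("coding_fraction must be in [0, 1]")
        if self.noise not in ("binomial", "none"):
            raise ValueError("noise must be 'binomial' or 'none'")


@dataclass
class CloneHistory:
    """Ground truth of one simulated tumor."""

    tree: Tree
    mutations: pd.DataFrame        # id, branch, coding, effect, codon context
    node_ranges: np.ndarray        # (n_nodes, L) bool
    branch_events: dict
    event_log: list
    mixtures: pd.DataFrame         # tumor samples x clones, rows sum to 1
    sample_locations: list         # location index per tumor sample
    config: SimulationConfig

    def __post_init__(self):
        if len(self.mixtures):
            sums = self.mixtures.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0):
                raise ValueError("mixture proportions must sum to 1 per sample")
        tips = self.node_ranges[: self.tree.n_tips]
        if np.any(~tips.any(axis=1)):
            raise ValueError("tip ranges must be non-empty")

    @property
    def clone_ranges(self) -> np.ndarray:
        return self.node_ranges[: self.tree.n_tips]

    def clone_mutation_matrix(self) -> np.ndarray:
        """(n_clones, n_mutations) presence of each mutation in each clone."""
        masks = self.tree.clade_masks()
        n = self.tree.n_tips
        M = np.zeros((n, len(self.mutations)), dtype=bool)
        for col, branch in enumerate(self.mutations["branch"]):
            m = masks[branch]
            for tip in range(n):
                M[tip, col] = bool(m >> tip & 1)
        return M


def _draw_codon_context(rng):
    """Random codon, position and alternative base; returns effect label."""
    code = _genetic_code()
    sense = [c for c, aa in code.items() if aa != "*"]
    codon = sense[rng.integers(len(sense))]
    pos = int(rng.integers(3))
    ref_nt = codon[pos]
    alt_nt = rng.choice([b for b in _BASES if b != ref_nt])
    alt_codon = codon[:pos] + alt_nt + codon[pos + 1:]
    effect = "synonymous" if code[alt_codon] == code[codon] else "nonsynonymous"
    return codon, pos, ref_nt, alt_nt, effect


def simulate_clone_history(config: SimulationConfig) -> CloneHistory:
    """Draw the clone genealogy, its mutations, and its geographic history."""
    rng = np.random.default_rng(config.seed)
    tree = sample_coalescent_tree(
        config.n_clones, n0=config.n0, r=config.growth_rate_r, rng=rng,
        tip_labels=[chr(ord("A") + i) if config.n_clones <= 26 else f"clone{i}"
                    for i in range(config.n_clones)],
    )
    # mutations: Poisson along each branch, positions unique over the target
    bl = tree.branch_lengths
    per_branch = rng.poisson(config.mutation_rate_mu * config.target_sites * bl)
    per_branch[tree.root] = 0
    n_mut = int(per_branch.sum())
    positions = np.sort(rng.choice(config.target_sites, size=n_mut, replace=False)) + 1
    rows = []
    i = 0
    for node in range(tree.n_nodes):
        for _ in range(int(per_branch[node])):
            coding = bool(rng.random() < config.coding_fraction)
            if coding:
                codon, cpos, ref_nt, alt_nt, effect = _draw_codon_context(rng)
            else:
                codon, cpos, effect = "", -1, "noncoding"
                ref_nt = _BASES[rng.integers(4)]
                alt_nt = rng.choice([b for b in _BASES if b != ref_nt])
            rows.append({
                "id": f"m{i}", "branch": int(node), "coding": coding,
                "effect": effect, "ref_codon": codon, "codon_pos": cpos,
                "chrom": "1", "pos": int(positions[i]),
                "ref": ref_nt, "alt": alt_nt,
            })
            i += 1
    mutations = pd.DataFrame(
        rows, columns=["id", "branch", "coding", "effect", "ref_codon",
                       "codon_pos", "chrom", "pos", "ref", "alt"])

    # geographic ranges
    model = DispersalModel(config.gain_rate, config.loss_rate, config.dispersal_beta)
    root_range = np.zeros(config.n_locations, dtype=bool)
    root_range[config.seed_location] = True
    node_ranges, branch_events, event_log = simulate_range_history(
        tree, config.geometry, model, root_range, rng)

    # bulk sample composition
    sample_locations = [i % config.n_locations for i in range(config.n_samples)]
    tip_ranges = node_ranges[: tree.n_tips]
    D = config.geometry.distance_matrix
    mix_rows = []
    names = []
    for s, loc in enumerate(sample_locations):
        present = np.flatnonzero(tip_ranges[:, loc])
        if len(present) == 0:
            # sample falls where no clone lives: take the nearest occupied site
            occ_loc = np.flatnonzero(tip_ranges.any(axis=0))
            loc = occ_loc[np.argmin(D[loc, occ_loc])]
            present = np.flatnonzero(tip_ranges[:, loc])
        w = rng.dirichlet(np.full(len(present), config.mixture_alpha))
        # detectability floor: drop trace clones, renormalize
        while True:
            low = (w > 0) & (w < config.min_clone_freq) & (w < w.max())
            if not low.any():
                break
            w[low] = 0.0
            w = w / w.sum()
        full = np.zeros(tree.n_tips)
        full[present] = w
        mix_rows.append(full)
        names.append(config.geometry.names[sample_locations[s]])
    seen: dict = {}
    uniq = []
    for n in names:
        seen[n] = seen.get(n, 0) + 1
        uniq.append(n if seen[n] == 1 else f"{n}_{seen[n]}")
    mixtures = pd.DataFrame(np.array(mix_rows), index=uniq, columns=tree.tip_labels)
    return CloneHistory(tree, mutations, node_ranges, branch_events,
                        event_log, mixtures, sample_locations, config)


# ======================================================================
def render_bulk_samples(history: CloneHistory, config: SimulationConfig | None = None):
    """Render a clone history into bulk sequencing evidence.

    Returns ``(table, cn_segments, truth)`` where ``truth`` maps each
    rendered locus to its origin (somatic mutation id or germline).
    Depth is Poisson(mean_depth), alt reads Binomial(depth, expected VAF)
    with expected VAF = purity * 0.5 * (clone-weighted mutation presence);
    germline het sites sit at VAF 0.5 in every sample including healthy.
    """
    config = config or history.config
    if max(history.sample_locations) >= config.n_locations:
        raise ValueError("history references locations absent from config")
    rng = np.random.default_rng(config.seed + 1)
    tree = history.tree
    mix = history.mixtures.to_numpy()                      # samples x clones
    presence = history.clone_mutation_matrix()             # clones x muts
    evaf_somatic = 0.5 * config.purity * (mix @ presence)  # samples x muts

    tumor_names = list(history.mixtures.index)
    healthy_names = [f"N{i+1}" for i in range(config.n_healthy)]
    samples = tumor_names + healthy_names
    n_t, n_h = len(tumor_names), len(healthy_names)

    # germline het loci at distinct positions
    n_som = len(history.mutations)
    used = set(history.mutations["pos"])
    germ_pos = []
    while len(germ_pos) < config.n_germline:
        p = int(rng.integers(1, config.target_sites + 1))
        if p not in used:
            used.add(p)
            germ_pos.append(p)
    loci_rows = []
    evaf = np.zeros((n_som + config.n_germline, n_t + n_h))
    for i, row in history.mutations.iterrows():
        loci_rows.append((row["chrom"], row["pos"], row["ref"], row["alt"]))
        evaf[i, :n_t] = evaf_somatic[:, i]
    for g, p in enumerate(sorted(germ_pos)):
        ref = _BASES[rng.integers(4)]
        alt = rng.choice([b for b in _BASES if b != ref])
        loci_rows.append(("1", p, ref, alt))
        evaf[n_som + g, :] = 0.5
    loci = pd.DataFrame(loci_rows, columns=["chrom", "pos", "ref", "alt"])
    order = np.argsort(loci["pos"].to_numpy(), kind="stable")
    loci = loci.iloc[order].reset_index(drop=True)
    evaf = evaf[order]
    is_germline = np.array([i >= n_som for i in order])
    origin = np.array(
        [history.mutations["id"].iloc[i] if i < n_som else "germline" for i in order])

    n_loci = len(loci)
    n_s = n_t + n_h
    if config.noise == "binomial":
        depth = rng.poisson(config.mean_depth, size=(n_loci, n_s))
        depth = np.maximum(depth, 1)
        alt = rng.binomial(depth, np.clip(evaf, 0, 1))
        qual = rng.uniform(30, 90, size=(n_loci, n_s))
        low = rng.random((n_loci, n_s)) < config.low_qual_fraction
        qual[low] = rng.uniform(5, 19.9, size=int(low.sum()))
    else:
        depth = np.full((n_loci, n_s), int(round(config.mean_depth)))
        alt = np.rint(depth * evaf).astype(np.int64)
        qual = np.full((n_loci, n_s), 60.0)
    table = VariantCallTable(
        loci, samples, depth, alt, qual,
        np.array([False] * n_t + [True] * n_h))

    # copy-number segments shared by all tumor samples
    seg_rows = []
    if config.cn_segment_count > 0 and config.cn_fraction > 0:
        span = int(config.cn_fraction * config.target_sites / config.cn_segment_count)
        starts = rng.choice(config.target_sites - span, size=config.cn_segment_count,
                            replace=False)
        for st in sorted(starts):
            total = int(rng.choice([1, 3, 4]))
            for s in tumor_names:
                seg_rows.append({"sample": s, "chrom": "1", "start": int(st),
                                 "end": int(st + span), "total_cn": total,
                                 "minor_cn": 0 if total == 1 else 1})
    cn = CopyNumberSegments(pd.DataFrame(seg_rows, columns=CopyNumberSegments.COLUMNS))

    truth = pd.DataFrame({
        "chrom": loci["chrom"], "pos": loci["pos"],
        "origin": origin, "is_germline": is_germline,
        "expected_vaf_max": evaf.max(axis=1),
    })
    return table, cn, truth


# ======================================================================
def write_history(history: CloneHistory, outdir) -> None:
    """Write ground truth: newick tree, mutation/range/mixture TSVs, JSON log."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "true_tree.nwk"), "w") as fh:
        fh.write(history.tree.newick() + "\n")
    history.mutations.to_csv(os.path.join(outdir, "mutations.tsv"), sep="\t", index=False)
    ranges = pd.DataFrame(
        history.clone_ranges.astype(int),
        index=history.tree.tip_labels, columns=history.config.geometry.names)
    ranges.to_csv(os.path.join(outdir, "clone_ranges.tsv"), sep="\t")
    history.mixtures.to_csv(os.path.join(outdir, "mixtures.tsv"), sep="\t")
    cfg = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
           for k, v in vars(history.config).items() if k != "geometry"}
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump({"config": cfg, "event_log": history.event_log}, fh, indent=1)
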