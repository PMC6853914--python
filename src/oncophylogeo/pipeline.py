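"""End-to-end pipeline: simulate -> filter -> structure -> deconvolve ->
date -> skyline -> dnds -> biogeography -> sankoff.

Every stage writes machine-readable outputs under the configured output
directory and contributes to a single JSON report; one master seed fans out
to fixed per-stage offsets so stages are independently reproducible and a
rerun with the same configuration is byte-identical (no timestamps in the
report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biogeography as bg
from . import deconvolution as dc
from . import filtering as fl
from . import selection as sel
from .dating import CloneDatingModel, doubling_time
from .diagnostics import hpd_interval, trace_diagnostics
from .simulate import (CloneHistory, SimulationConfig, render_bulk_samples,
                       simulate_clone_history, write_history)
from .skyline import SkylineModel

log = logging.getLogger("oncophylogeo.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "DESK", "PAPER"]

ALL_STAGES = ("simulate", "filter", "structure", "deconvolve", "date",
              "skyline", "dnds", "biogeo", "sankoff")

# chain-length presets
DESK = {
    "date_chain": 14000, "date_thin": 14,
    "skyline_chain": 9000, "skyline_thin": 9,
    "biogeo_chain": 4000, "biogeo_thin": 2,
    "dnds_max_branches": 3,
}
PAPER = {
    "date_chain": 100_000_000, "date_thin": 2000,
    "skyline_chain": 100_000_000, "skyline_thin": 2000,
    "biogeo_chain": 100_000_000, "biogeo_thin": 2000,
    "dnds_max_branches": None,
}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str = "oncophylogeo_run"
    seed: int = 0
    scale: str = "desk"                      # desk | paper
    stages: tuple = ALL_STAGES
    simulation: dict = field(default_factory=dict)
    clone_presence_threshold: float = 0.075  # clone frequency -> range scoring
    generation_days: float = 4.0
    params: dict = field(default_factory=dict)

    def preset(self) -> dict:
        base = dict(DESK if self.scale == "desk" else PAPER)
        base.update(self.params)
        return base

    def stage_seed(self, stage: str) -> int:
        return (self.seed + 1000 * ALL_STAGES.index(stage)) % (2**31 - 1)

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _jsonify(obj):
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(x) for x in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def clone_ranges_from_frequencies(frequencies: pd.DataFrame, sample_locations,
                                  n_locations: int, threshold: float = 0.075):
    """Score clone presence at a location from per-sample clone frequencies.

    A clone occupies a location when its frequency reaches ``threshold`` in
    any sample taken there; clones detected nowhere keep their single best
    location so ranges stay non-empty.
    """
    freqs = frequencies.to_numpy()
    n_clones = freqs.shape[1]
    ranges = np.zeros((n_clones, n_locations), dtype=bool)
    best = np.zeros((n_clones, n_locations))
    for s, loc in enumerate(sample_locations):
        ranges[:, loc] |= freqs[s] >= threshold
        best[:, loc] = np.maximum(best[:, loc], freqs[s])
    for c in range(n_clones):
        if not ranges[c].any():
            ranges[c, int(np.argmax(best[c]))] = True
    return ranges


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages and return (and write) the JSON report."""
    os.makedirs(config.outdir, exist_ok=True)
    preset = config.preset()
    report: dict = {"seed": config.seed, "scale": config.scale,
                    "stages": list(config.stages)}
    ctx: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            log.info("pipeline stage: %s", stage)
            _STAGE_FUNCS[stage](config, preset, ctx, report)
    except Exception as err:  # preserve partial outputs, identify the stage
        _write_report(config, report)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    _write_report(config, report)
    return report


def _write_report(config, report):
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(_jsonify(report), fh, indent=1, sort_keys=True)
    with open(os.path.join(config.outdir, "config.json"), "w") as fh:
        json.dump(_jsonify(config.to_json()), fh, indent=1, sort_keys=True)


# ======================================================================
def _stage_simulate(config, preset, ctx, report):
    sim_cfg = SimulationConfig(seed=config.stage_seed("simulate"),
                               **config.simulation)
    history = simulate_clone_history(sim_cfg)
    table, cn, truth = render_bulk_samples(history)
    outdir = os.path.join(config.outdir, "simulate")
    write_history(history, outdir)
    table.to_tsv(os.path.join(outdir, "variants.tsv"))
    table.to_vcf(os.path.join(outdir, "variants.vcf"))
    cn.to_tsv(os.path.join(outdir, "cn_segments.tsv"))
    truth.to_csv(os.path.join(outdir, "locus_truth.tsv"), sep="\t", index=False)
    ctx.update(history=history, table=table, cn=cn, truth=truth,
               sim_cfg=sim_cfg, geometry=sim_cfg.geometry)
    report["simulate"] = {
        "n_clones": history.tree.n_tips,
        "n_somatic_mutations": int(len(history.mutations)),
        "n_dispersal_events": int(len(history.event_log)),
        "true_tmrca_generations": float(history.tree.heights.max()),
        "true_growth_rate": sim_cfg.growth_rate_r,
    }


def _stage_filter(config, preset, ctx, report):
    table = ctx["table"]
    filtered = fl.call_filter(table, ctx.get("cn"))
    filtered.to_tsv(os.path.join(config.outdir, "filtered_variants.tsv"))
    ctx["filtered"] = filtered
    report["filter"] = {"audit": filtered.audit,
                        "n_somatic_snvs": filtered.n_loci}


def _stage_structure(config, preset, ctx, report):
    filtered = ctx["filtered"]
    coords, explained = fl.vaf_pca(filtered)
    coords.to_csv(os.path.join(config.outdir, "pca_coordinates.tsv"), sep="\t")
    fst = fl.pairwise_fst(filtered)
    fst.to_csv(os.path.join(config.outdir, "fst_matrix.tsv"), sep="\t")
    geometry = ctx["geometry"]
    history = ctx["history"]
    locs = history.sample_locations
    D = geometry.distance_matrix
    geo = D[np.ix_(locs, locs)]
    genetic = fst.to_numpy()
    r, p = fl.mantel_test(genetic, geo, n_perm=999,
                          seed=config.stage_seed("structure"))
    report["structure"] = {
        "pc1_explained": float(explained[0]),
        "pc2_explained": float(explained[1]) if len(explained) > 1 else 0.0,
        "mantel_r": r, "mantel_p": p,
        "mean_fst": float(np.nanmean(genetic[np.triu_indices(len(genetic), 1)])),
    }


def _stage_deconvolve(config, preset, ctx, report):
    pre = fl.deconvolution_prefilter(ctx["filtered"], ctx.get("cn"))
    clusters = dc.cluster_mutations(pre)
    genotypes = dc.build_clone_genotypes(clusters)
    aln = dc.encode_sequences(genotypes, table=pre, mode="binary")
    clusters.to_tsv(os.path.join(config.outdir, "clusters.tsv"), pre)
    genotypes.to_tsv(os.path.join(config.outdir, "clone_genotypes.tsv"),
                     os.path.join(config.outdir, "clone_frequencies.tsv"))
    aln.to_fasta(os.path.join(config.outdir, "clone_alignment.fasta"))
    ctx.update(prefiltered=pre, clusters=clusters, genotypes=genotypes,
               clone_alignment=aln)
    report["deconvolve"] = {
        "prefilter_audit": pre.audit,
        "n_loci_deconvolution": pre.n_loci,
        "n_clusters": clusters.n_clusters,
        "n_clones": genotypes.n_clones,
    }


def _metastatic_clones(ctx, config):
    """Clones whose inferred range touches the liver (hematogenous spread)."""
    genotypes = ctx["genotypes"]
    history = ctx["history"]
    geometry = ctx["geometry"]
    ranges = clone_ranges_from_frequencies(
        genotypes.frequencies, history.sample_locations,
        geometry.n_locations, config.clone_presence_threshold)
    ctx["clone_ranges"] = ranges
    region = np.array(geometry.regions)
    met_regions = {"liver", "hepatic_lymph_node"}
    met = [genotypes.clone_labels[c] for c in range(ranges.shape[0])
           if set(region[ranges[c]]) & met_regions]
    return met


def _stage_date(config, preset, ctx, report):
    aln = ctx["clone_alignment"]
    sim_cfg = ctx["sim_cfg"]
    # SNV-only alignment against an exome-scale target: invariant sites
    # enter as constant-site weights so absolute node ages are identified
    model = CloneDatingModel(
        aln, clock_kind="strict", clock_rate=sim_cfg.mutation_rate_mu,
        tree_prior="exponential_growth",
        ascertainment="constant_site_weights",
        constant_weights=float(sim_cfg.target_sites - aln.n_sites))
    res = model.fit(chain_length=preset["date_chain"], thin=preset["date_thin"],
                    burn_in=0.1, seed=config.stage_seed("date"))
    res.trace.to_csv(os.path.join(config.outdir, "dating_trace.tsv"),
                     sep="\t", index=False)
    summary_tree, support = res.mcc_tree(min_trees=50)
    with open(os.path.join(config.outdir, "mcc_tree.nwk"), "w") as fh:
        fh.write(summary_tree.newick() + "\n")
    ctx.update(dating=res, mcc=summary_tree, mcc_support=support)

    gd = config.generation_days
    tmrca = res.trace["tmrca"].to_numpy()
    r = res.trace["growth_rate"].to_numpy()
    years = tmrca * gd / 365.25
    entry = {
        "tmrca_years_median": float(np.median(years)),
        "tmrca_years_hpd95": list(hpd_interval(years)),
        "growth_rate_median": float(np.median(r)),
        "growth_rate_hpd95": list(hpd_interval(r)),
        "ess": {k: v["ess"] for k, v in
                trace_diagnostics(res.trace[["tmrca", "growth_rate"]]).items()},
    }
    pos = r[r > 0]
    if len(pos) >= 10:
        entry["doubling_time_days_median"] = float(np.median(doubling_time(pos, gd)))
    met = _metastatic_clones(ctx, config)
    ctx["metastatic_clones"] = met
    if len(met) >= 2:
        mm = res.clade_mrca_samples(met) * gd / 365.25
        entry["mmrca_years_median"] = float(np.median(mm))
        entry["mmrca_years_hpd95"] = list(hpd_interval(mm))
        entry["relative_divergence_years_median"] = float(np.median(years - mm))
    report["date"] = entry


def _stage_skyline(config, preset, ctx, report):
    aln = ctx["clone_alignment"]
    sim_cfg = ctx["sim_cfg"]
    model = SkylineModel(aln, n_groups=5, clock_rate=sim_cfg.mutation_rate_mu,
                         ascertainment="constant_site_weights",
                         constant_weights=float(sim_cfg.target_sites - aln.n_sites))
    res = model.fit(chain_length=preset["skyline_chain"],
                    thin=preset["skyline_thin"], burn_in=0.1,
                    seed=config.stage_seed("skyline"))
    traj = res.trajectory(bins=100)
    traj.to_tsv(os.path.join(config.outdir, "skyline.tsv"))
    entry = {"ne_present_median": float(traj.median[0]),
             "ne_root_median": float(traj.median[-1]),
             "ne_fold_change": float(traj.median.max() / max(traj.median.min(), 1e-12))}
    met = ctx.get("metastatic_clones") or []
    if len(met) >= 2:
        try:
            met_traj = res.clade_trajectory(met, bins=100, clade_label="metastatic")
            met_traj.to_tsv(os.path.join(config.outdir, "skyline_metastatic.tsv"))
            entry["metastatic_skipped_trees"] = met_traj.skipped_trees
        except ValueError:
            entry["metastatic_skipped_trees"] = -1  # never monophyletic
    ctx["skyline"] = res
    report["skyline"] = entry


def _locus_annotations(ctx):
    """Codon contexts of retained loci recovered from the simulation truth."""
    genotypes = ctx["genotypes"]
    pre = ctx["prefiltered"]
    truth_mut = ctx["history"].mutations.set_index("id")
    origin = ctx["truth"].set_index(["chrom", "pos"])["origin"]
    rows = []
    for li in genotypes.locus_index:
        locus = pre.loci.iloc[li]
        key = (locus["chrom"], locus["pos"])
        mid = origin.get(key, "unknown")
        if isinstance(mid, str) and mid.startswith("m") and mid in truth_mut.index:
            m = truth_mut.loc[mid]
            rows.append({"effect": m["effect"], "ref_codon": m["ref_codon"],
                         "codon_pos": m["codon_pos"]})
        else:
            rows.append({"effect": "noncoding", "ref_codon": "", "codon_pos": -1})
    return pd.DataFrame(rows)


def _stage_dnds(config, preset, ctx, report):
    aln = ctx["clone_alignment"]
    tree = ctx["mcc"]
    annotations = _locus_annotations(ctx)
    bmap = sel.map_mutations_to_branches(aln, tree, method="parsimony",
                                         annotations=annotations)
    codon_aln = sel.build_coding_sequences(bmap, tree)
    codon_aln.to_fasta(os.path.join(config.outdir, "codon_alignment.fasta"))
    counts = bmap.counts()
    cand = counts[counts.get("nonsynonymous", 0) > 0].copy() if "nonsynonymous" in counts \
        else counts
    cand = cand.sort_values("nonsynonymous", ascending=False) \
        if "nonsynonymous" in cand else cand
    branches = [int(b) for b in cand.index]
    max_b = preset.get("dnds_max_branches")
    if max_b:
        branches = branches[:max_b]
    model = sel.BranchDnDsModel(codon_aln, tree, branch_map=bmap)
    res = model.fit(branches=branches)
    res.table.to_csv(os.path.join(config.outdir, "dnds_results.tsv"),
                     sep="\t", index=False)
    ctx["dnds"] = res
    report["dnds"] = {
        "m0_omega": res.m0_omega,
        "n_branches_tested": len(res.table),
        "n_significant": int((res.table["p_value"] < 0.05).sum()),
        "max_omega_foreground": float(res.table["omega_foreground"].max())
        if len(res.table) else np.nan,
        "n_coding_mutations": codon_aln.n_codons,
    }


def _stage_biogeo(config, preset, ctx, report):
    tree = ctx["mcc"]
    geometry = ctx["geometry"]
    ranges = ctx["clone_ranges"]
    order = [ctx["genotypes"].clone_labels.index(t) for t in tree.tip_labels]
    tip_ranges = ranges[order]
    # rescale heights to years so rates are per year (report notes the unit)
    scaled = tree.copy()
    scaled.heights = scaled.heights * config.generation_days / 365.25
    model = bg.BiogeographyModel(scaled, tip_ranges, geometry,
                                 prior_mean_gain=0.05, prior_mean_loss=0.05)
    res = model.fit(chain_length=preset["biogeo_chain"],
                    thin=preset["biogeo_thin"], burn_in=0.1,
                    seed=config.stage_seed("biogeo"))
    res.trace.to_csv(os.path.join(config.outdir, "biogeo_trace.tsv"),
                     sep="\t", index=False)
    modal, marginals, labels = res.ancestral_range_map()
    pd.DataFrame(marginals, columns=geometry.names).to_csv(
        os.path.join(config.outdir, "node_occupancy.tsv"), sep="\t")
    mean_mig, mig_table = res.count_migrations()
    mig_table.to_csv(os.path.join(config.outdir, "migration_events.tsv"),
                     sep="\t", index=False)
    sd = res.savage_dickey_bf()
    ctx["biogeo"] = res
    root = tree.root
    report["biogeo"] = {
        "beta_median": float(np.median(res.beta_samples)),
        "beta_hpd95": list(hpd_interval(res.beta_samples)),
        "bf01_distance_model": sd["bf01"],
        "mean_migrations": mean_mig,
        "root_modal_range": [geometry.names[i] for i in np.flatnonzero(modal[root])],
    }


def _stage_sankoff(config, preset, ctx, report):
    tree = ctx["mcc"]
    geometry = ctx["geometry"]
    ranges = ctx["clone_ranges"]
    order = [ctx["genotypes"].clone_labels.index(t) for t in tree.tip_labels]
    region = np.array(geometry.regions)
    labels = []
    freqs = ctx["genotypes"].frequencies.to_numpy()
    locs = ctx["history"].sample_locations
    for t, c in enumerate(order):
        occ = np.flatnonzero(ranges[c])
        # label by the region where the clone is most frequent
        best_loc = occ[0]
        best = -1.0
        for s, loc in enumerate(locs):
            if ranges[c, loc] and freqs[s, c] > best:
                best, best_loc = freqs[s, c], loc
        labels.append(region[best_loc])
    result = bg.sankoff_migration_history(tree, labels, primary_site="primary",
                                          site_names=sorted(set(region)),
                                          max_labelings=256)
    with open(os.path.join(config.outdir, "sankoff_histories.json"), "w") as fh:
        json.dump(_jsonify({k: result[k] for k in
                            ("min_migrations", "site_names", "pair_counts")}),
                  fh, indent=1)
    report["sankoff"] = {
        "min_migrations": result["min_migrations"],
        "n_optimal_labelings": len(result["labelings"]),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "structure": _stage_structure,
    "deconvolve": _stage_deconvolve,
    "date": _stage_date,
    "skyline": _stage_skyline,
    "dnds": _stage_dnds,
    "biogeo": _stage_biogeo,
    "sankoff": _stage_sankoff,
}
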