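# Methods

`oncophylogeo` reconstructs the evolutionary and biogeographic history of a
single tumor from multiregion bulk sequencing: somatic SNVs are filtered,
deconvolved into clones, the clone genealogy is dated under a coalescent
model, effective population size and branch-level selection are estimated,
and clone movement between anatomical locations is inferred under a
distance-dependent dispersal–extinction model.  A forward simulator
generates study-like data with full ground truth so every stage can be
validated end to end.

## Synthetic tumor generator

The generative direction mirrors the inferential models: the clone
genealogy is drawn *backwards* from a coalescent with effective size
N(t) = N0·e^(−rt) (t in generations before sampling), then mutations and
geographic ranges evolve *forwards* along its branches.

* Mutations per branch ~ Poisson(μ·L·Δt) over a target of L sites.  Each
  coding mutation (fraction 0.75 of the exome-style target) receives a
  random sense-codon context from the standard genetic code; the
  synonymous/nonsynonymous label follows from the context.  Mapping
  mutations to a real annotated exome is out of scope; contexts are
  packaged with the mutation instead.
* Ranges evolve by the same gain/loss process the biogeography module
  fits (shared kernel, below), from a single seeded location.
* Bulk samples: one per tumor location (16) plus healthy samples (2).
  A sample at location ℓ mixes the clones present at ℓ with
  Dirichlet(α = 2) proportions; proportions under a detectability floor
  (default 0.05) are zeroed and the rest renormalized — bulk sequencing
  cannot evidence arbitrarily rare clones, and carrying undetectable
  mass would make "exact recovery" meaningless.  Read evidence per locus
  and sample: depth ~ Poisson(60), alt reads ~ Binomial(depth,
  purity·0.5·clone-weighted presence); germline heterozygous sites
  (VAF 0.5 everywhere, healthy included) and low-quality calls (5% of
  calls below Phred 20) are injected so each filter rule is exercised;
  a few non-diploid segments are emitted as a copy-number table.

Default parameter choices emulate the structure of a metastatic
colorectal adenocarcinoma autopsy series: 21 clones over 16 locations in
four regions (primary colon, colonic and hepatic lymph nodes, liver, with
the liver cluster ~25 cm from the colon), growth r = 0.014 per
generation, one generation every 4 days, 60× coverage, and a few hundred
diploid somatic SNVs.  Two defaults deserve comment:

* **Mutation rate** 1.5e-9 /site/generation.  The experimentally derived
  colorectal rate of 4.6e-10 (which remains the default *clock prior* in
  the dating module) would leave only ~150 SNVs segregating on a
  ~10,000-generation clone tree; rates up to an order of magnitude higher
  have been reported for metastatic colorectal cancer, and 1.5e-9 places
  ~475 SNVs on the default tree.
* **N0 = 6e5**, giving a tumor age around 650 generations (~7 years at
  4 days/generation), and gain/loss rates 2.5e-4 / 1.2e-4 per generation,
  giving clones that occupy a handful of locations and trees carrying
  tens of dispersal events.

What the generator deliberately does not emulate: sequencing error and
mapping artifacts beyond the quality-score channel, copy-number-driven
VAF distortion (non-diploid loci are flagged, not re-modelled),
within-sample spatial structure, and mutation-rate variation along the
genome.  Passing tests therefore validate the *inference machinery*, not
robustness to artifacts the generator does not produce.

## Filtering

Call filter (high stringency): coverage ≥ 20× in every sample; at least
one tumor sample with VAF ≥ 0.05 *and* call quality ≥ 20 (call-level
reading — demanding quality in every alt-bearing sample would discard a
third of true SNVs at a 5% low-quality call rate); zero alt reads in all
healthy samples; diploid (2 total / 1 minor) copy number in all tumor
samples, positions without a segment treated as diploid with a warning.
Pre-deconvolution filter: maximum tumor VAF ≥ 0.10, depth ≥ 20 somewhere,
no overlap with copy-number events.  Both emit per-rule removal counts.

Population structure: centered PCA of the sample×locus VAF matrix;
Hudson-type FST with VAFs as allele frequencies and read depths as sample
sizes (ratio of averages, clamped to [0,1]); Mantel test with the exact
permutation p-value (1 + #{r_perm ≥ r_obs})/(n_perm + 1).

## Clonal deconvolution

A transparent cluster-then-perfect-phylogeny stand-in for full
deconvolution tools, honoring their printed thresholds (read count ≥ 40,
mutant reads ≥ 6, presence ≥ 0.075, absence = 0, merge radius 0.1, clone
frequency cutoff 0.075, VAF sanity cap 0.7):

1. Loci are discretized per sample to present/absent/uninformative and
   grouped by identical presence patterns; groups are split when their
   pooled VAF profiles differ decisively and merged greedily while the
   pooled binomial max-z across samples stays below 4.5 (≈1e-4 familywise
   null quantile over 16 samples) and centroids stay within L∞ 0.1.  The
   z-gate is what makes one threshold work at both 60× (noisy singletons
   must coalesce) and 1000× (an 0.08-VAF gap must split).
2. Cluster ancestry by sample-set containment with cancer-cell-fraction
   (CCF = 2·VAF) monotonicity and a capacity (pigeonhole) budget,
   processing clusters in descending mean VAF.  Violations of the sum
   condition that are incompatible with nesting either way are reported
   and, beyond a tolerance, fatal.
3. Each cluster defines a clone (its mutations plus its ancestors');
   per-sample clone frequencies solve VAF ≈ 0.5·Gᵀf by bounded least
   squares with Σf ≤ 1; clones never reaching the 0.075 cutoff are
   dropped.  Sequences are encoded A = reference / T = alternative (or
   the actual ref/alt bases).

Identifiability caveat: when one clone's detectable sample set nests
inside a non-ancestor's and its cell fraction never exceeds the other's,
the nested and unnested genotypes are observationally equivalent; exact
recovery is then impossible for any method.  The exact-recovery test
asserts this precondition on its fixture.

## Dating

Likelihood: Felsenstein pruning under JC69 (HKY available) with pattern
compression.  Because the clone alignment contains only variable sites,
two ascertainment modes exist: conditioning on variability (divide each
site by 1 − P(constant)), which corrects relative branch lengths but is
exactly scale-free for two taxa and nearly so in general; and
constant-site weights (add L − S invariant sites to the likelihood),
which also restores the absolute time scale and is the default whenever
the target size is known.  The identifiability argument is why the
calibration experiments use the weighted form.

Tree priors: constant size, exponential growth (N(t) = N0·e^(−rt)), and
Bayesian skyline (piecewise-constant Ne over groups of coalescent
intervals with an exponential Markov smoothing prior).  Hyperpriors:
r ~ Laplace(0, 0.1); log N0 uniform on a wide bracket; clock rate fixed
or lognormal.  For r < 0 the coalescent is defective (lineages may never
coalesce), so the *joint* prior down-weights negative growth; the
prior-sampling validation therefore compares MCMC output against a
rejection-sampling oracle of the same joint prior rather than the raw
Laplace.

Sampler: Metropolis–Hastings over node heights (uniform within bounds),
root and whole-tree scalers, narrow and wide exchange for topology,
random walks and prior-independence draws for parameters, and a
"re-time" move that changes r or N0 while holding the genealogy's
standard-coalescent coordinates fixed (heights remapped through
τ = (e^{rt}−1)/(rN0)); the coalescent-density change cancels the
Jacobian exactly, removing the rate–heights ridge that otherwise stalls
mixing.  Step sizes adapt toward 30% acceptance during burn-in only.
Chain defaults are desk scale (10^4–10^5 steps); study-scale settings
(10^8, thinned 2000, 10% burn-in) are plain arguments.

Summaries: maximum-clade-credibility topology with per-clade median
heights and posterior supports; calendar conversion years =
generations·4/365.25; relative divergence tMRCA − mMRCA computed per
posterior draw (never as a difference of summaries); doubling time
ln 2·generation_days/r per draw, summarized by the median.  Path-sampling
marginal likelihoods use power posteriors at Beta(0.3, 1)-quantile
temperatures and trapezoid integration; model comparison is by the
difference of log marginals.

## Skyline summaries

Trajectories evaluate each posterior sample's Ne step function at 100 bin
midpoints between the present and the median root height.  Clade
restriction re-times the sampled Ne values on the clade subtree's own
coalescent intervals (group sizes allocated proportionally); this shows
*when* demographic transitions happen inside a clade — the primary versus
metastatic comparison of interest — while sharing the Ne scale with the
whole-tree analysis.  Samples in which the clade is not monophyletic are
skipped and counted.

## Selection scan

Mutations are mapped to branches by small parsimony (Sankoff DP with the
reference state held above the root via a virtual outgroup, so truncal
mutations land on the stem); all most-parsimonious placements are
enumerated, the rootmost chosen, ties flagged; a marginal-ML mode exists.
Coding mutations' codon contexts build a concatenated in-frame codon
alignment (stop-codon contexts excluded with a warning).  dN/dS uses a
Goldman–Yang-style codon model (κ, ω, F1×4 frequencies, 61 sense codons)
with branch lengths proportional to the dated tree and a free overall
scale; M0 (one ω) is compared with a two-ratio model per candidate branch
(those carrying ≥ 1 nonsynonymous mutation) by a χ²(1) likelihood-ratio
test, the alternative initialized at the null optimum so the LRT is
non-negative.  Benjamini–Hochberg correction is available but off by
default (per-branch ratios are reported as-is).  An NG86-style counting
estimate cross-checks the ML ranks.

## Biogeography

Ranges are non-empty location sets evolving anagenetically: location j is
gained at λ_gain·η_j with η_j = (1/|R|)Σ_{i∈R}(d_ij/d̄)^(−β) (d̄ = mean
off-diagonal distance, so β = 0 is distance-independent), and lost at
λ_loss unless it is the last location.  Cladogenetic range splitting is
not modelled.  β has a Cauchy(0, 1) prior on the whole real line
(negative values favor long-distance dispersal); the gain/loss rates have
exponential priors.

Inference is data-augmented MCMC: branch histories are proposed from a
reference process of per-location independent two-state chains —
endpoint-conditioned paths by modified rejection sampling, densities and
endpoint probabilities in closed form — and accepted against the exact
path density of the distance-dependent process; node ranges update by
single-bit flips with joint re-proposal of incident branch paths; rates
and β by random walks against the summed path densities.  This works for
any number of locations.  Two independent oracles validate it on small
instances: exact pruning over all 2^L − 1 ranges with matrix exponentials
(L ≤ 4), and an importance-sampling likelihood estimate that draws
complete histories from the reference-process posterior and reweights by
the target density.  Zero-length branches of summary trees are floored at
1e-4 of the root height so state changes remain representable.

Savage–Dickey Bayes factors divide the posterior density of β at 0
(Gaussian KDE; robust Silverman bandwidth using min(sd, IQR/1.34), since
heavy-tailed traces break the variance-based rule) by the prior density
1/π; a ±50% bandwidth sensitivity band accompanies the estimate, and when
no posterior mass lies within five bandwidths of zero only an upper bound
is reported.  BF01 < 1 favors distance-dependent dispersal.

Migrations: in each sampled history, a gain into a region the lineage did
not occupy at that moment counts as one migration (source = region of the
nearest occupied location); counts are summarized as the posterior mean
and per-branch event frequencies.  Clone presence at a location is scored
from inferred clone frequencies at the samples taken there, at the clone
frequency cutoff (0.075).  The parsimony mode assigns one anatomical site
per tip, fixes the primary site at the root, and enumerates every
minimum-migration labeling by Sankoff DP with full backtracking.

## Pipeline and reproducibility

`run-all` chains all stages; one master seed fans out to fixed per-stage
offsets, the resolved configuration is written next to the outputs, and
the JSON report contains no timestamps, so a rerun with the same seed is
byte-identical.  The dating stage feeds the clone alignment with
constant-site weights spanning the rest of the target; ages are therefore
biased downward by SNV detection efficiency (only deconvolution-grade
SNVs enter the alignment) — a property shared by any SNV-only design, and
left visible rather than corrected.

## Validation protocol and problem sizes

The acceptance tests run at desk scale, chosen so the whole suite fits an
ordinary workstation session: dating calibration uses 20 replicates of 20
clones with ~450–500 SNVs on a 10^6-site genome (rate 100× the clock
prior, preserving μ·L), chains of 1.6e4 steps with the true topology
fixed; the skyline check uses 10 replicates at Ne = 1000 with 20 tips;
selection calibration uses 200 four-taxon replicates of 120 codons
(type-I) and 20 six-taxon replicates of 600 codons (power at ω = 5 vs
0.5); biogeography recovery uses 10 replicates of 12 clones over 8
locations under β = 2 and β = 0.  Replicate counts and pass thresholds
are part of the protocol; only per-replicate problem sizes are scaled.

## Known limitations

* Clone count and genotypes degrade gracefully but are not identifiable
  below the frequency cutoff or under sample-set nesting (above).
* The dating and skyline models assume contemporaneous tips and no
  within-host population structure in the coalescent.
* The biogeography sampler mixes slowly when ranges are near-saturated
  (little signal about β in that regime anyway).
* dN/dS branch tests condition on the mapped mutations and the summary
  topology; mapping ambiguity is flagged but not integrated over.
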