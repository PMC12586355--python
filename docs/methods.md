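# Methods

`mycolink` quantifies how soil properties organise a fungal community at
the level of co-occurrence network modules rather than the whole
community.  This note documents the statistical procedures, the synthetic
study generator that makes the chain testable, the numerical conventions,
and the known limitations.

## Analysis chain

### Aggregate stability indices

Wet sieving yields fraction masses `w_i` over seven size classes
(> 2, 2–1, 1–0.5, 0.5–0.25, 0.25–0.106, 0.106–0.053, < 0.053 mm).  With
`x_i` the representative diameter of class *i*:

* `WSA = M_{>0.25} / M_T` — mass fraction of water-stable aggregates
  (> 0.25 mm).  Classes are half-open `[lower, upper)`, so mass retained
  on the 0.25 mm sieve counts as stable.  Reported as a fraction in
  `[0, 1]`, not percent.
* `MWD = Σ x_i w_i / Σ w_i` (mm).
* `GMD = exp(Σ w_i ln x_i / Σ w_i)` (mm), with the `0·ln x = 0`
  convention for empty classes.  `GMD ≤ MWD` by the weighted AM–GM
  inequality.

Representative diameters default to class midpoints.  The two open
classes have no midpoint; the top class uses `(2 + cap)/2` with a
configurable cap (default 5 mm) and the bottom class `0.053/2` mm.  Wet
sieving literature is not uniform here and published index values cannot
adjudicate the convention when raw masses are unpublished, so both are
explicit, overridable parameters.

### Community preprocessing and statistics

Counts are rarefied (exact multivariate-hypergeometric subsampling
without replacement) to a common depth — by default the minimum library
size — then ASVs present in **strictly more than 20 %** of samples are
retained (with 33 samples that means ≥ 7).  Community dissimilarity is
Bray-Curtis on relative abundances.  Group effects are tested with Anosim
(rank-based R with label permutations) and per-variable one-way ANOVA
plus Tukey's HSD with a compact letter display (insert-and-absorb,
groups ordered by ascending mean, so the display is deterministic).

All permutation tests use the add-one estimator
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, so `p ∈ (0, 1]`, and are
seeded; a master seed deterministically derives one child seed per stage
(CRC-32-tagged `SeedSequence` spawning), so re-running a stage in
isolation reproduces the full-run output.

The Mantel test (Pearson correlation of condensed distance vectors,
simultaneous row/column permutations of one matrix, default one-sided
"greater" per ecological convention) and Anosim are implemented as
vectorised permutation engines: one permutation set is evaluated against
many companion matrices at once.  This is what makes module × variable
linkage grids and null-calibration experiments with hundreds of
replicates cheap.  Unit tests cross-check both statistics against
scikit-bio's implementations.

### Co-occurrence network

On the retained, rarefied table (rarefaction makes counts
rank-equivalent to proportions at equal depth), every ASV pair gets a
Spearman correlation with a two-sided p-value from the t approximation;
pairs with a constant series are flagged and never become edges.
p-values are Benjamini–Hochberg adjusted over all pairs.  An edge exists
iff `|ρ| ≥ 0.6` **and** `q < 0.05`; the sign is kept (negative edges are
mutual exclusions) and the Louvain weight is `|ρ|`.  ASVs without any
surviving edge are excluded from the node set — they re-enter nothing
downstream, matching the convention that module statistics cover
connected taxa only.

Modules come from seeded weighted Louvain modularity optimisation at
resolution 1.0 (the algorithm behind desktop modularity tools).  Module
ids are re-indexed by decreasing size so they are stable labels.  Node
roles use the within-module degree z-score `Zi` and participation
coefficient `Pi = 1 − Σ_m (k_im/k_i)²` on **unweighted** degrees (the
original formulation; a weighted variant sits behind a flag), with the
conventional thresholds `Zi = 2.5`, `Pi = 0.62` splitting peripherals,
connectors, module hubs and network hubs.  Modules whose within-degree
standard deviation is zero (e.g. 2-node modules) assign `Zi = 0` rather
than NaN.

### Module–soil linkage and classification

Each module's abundance is the summed percent relative abundance of its
members over all samples, reported as `log10` (a module containing the
whole of a 33-sample table would score `log10(3300)`).  Member
abundances come from the full-table normalisation — not renormalised
within the module — preserving the module's abundance context
(renormalisation is available behind a flag).

For every (module, soil variable) pair a Mantel test compares
Bray-Curtis distances on the module's member sub-table against
`|Δ|` distances on the z-standardised variable (999 permutations,
α = 0.05, one shared permutation set per module).  Zero-variance
variables and constant module distance matrices are flagged as
untested, never dropped silently.  Sample pairs in which no member
occurs get Bray-Curtis distance 0 (identical emptiness).  Tests are
**not** multiplicity-corrected by default — the classification operates
at a plain per-test α, as module-wise linkage screens in this
literature usually do — and a BH-corrected mode is available for
sensitivity analysis.

The significance pattern, split by variable block, labels each module:

| label | chemical link | aggregate link |
|-------|---------------|----------------|
| MUCA  | –             | –              |
| MRC   | ≥ 1           | –              |
| MRCA  | ≥ 1           | ≥ 1            |
| MRA   | –             | ≥ 1            |

MRA (aggregate-only) is kept as an explicit fourth label with a warning
rather than being coerced: the three-type scheme reflects the empirical
observation that aggregate stability does not act on modules alone, and
silently folding MRA into another class would hide exactly the cases
that falsify it.

### Trophic composition

A FUNGuild-style table maps ASVs to trophic-mode strings.  Single modes
carry weight 1; composite strings ("Pathotroph-Saprotroph") split their
weight equally; entries below the confidence threshold (default
"Probable") and unknown tokens become `unassigned` — nothing is
dropped.  Module composition is abundance-weighted by default
(count-weighted behind a flag); module-type composition aggregates
modules weighted by their summed abundance.  Differences between module
types are tested per trophic mode with one-way ANOVA + Tukey letters
using modules as replicates; types with fewer than two modules are
excluded with a warning.  A constant mode (no variance anywhere) yields
F = 0, p = 1 and a single shared letter rather than an error.

## The synthetic study generator

The generator emulates the structure of an 11-species × 3-replicate
grassland revegetation survey (33 samples, 300 ASVs) with planted ground
truth, so every stage of the chain can be scored against a known answer.

Two independent standardised soil axes drive everything: a chemical
(fertility/salinity) axis read out by two collinear chemical variables
(EC- and AP-like, readout noise sd 0.03), and an aggregate-stability
axis that tilts the expected wet-sieve mass distribution toward coarse
classes (logit-linear tilt, β = 0.25, Dirichlet concentration 8000,
total mass 50 g).  WSA/MWD/GMD are then *computed* from the simulated
masses by the aggregate-indices code — the aggregate block is never
synthesised directly, so the end-to-end test exercises that module too.
Both axes carry group-level mean shifts (75 % of variance between
species by default; setting the share to 0 makes per-variable ANOVA a
calibrated 5 % test).  The realised axes are orthogonalised in-sample:
with 11 groups their chance correlation (sd ≈ 0.3) would otherwise blur
the planted distinction between chemistry-only and chemistry+aggregate
linkage — and the motivating field observation is precisely that
aggregate stability and chemistry vary independently.

Six planted modules of 25 ASVs each get one latent factor per sample:

* two `none` modules (planted MUCA): i.i.d. standard normal latents;
* two `chemical` modules (planted MRC): `±0.66 · chem + noise`;
* two `chemical+aggregate` modules (planted MRCA):
  `±0.69 · chem + 0.69 · agg + noise` (latent_effect 0.97, chemical
  share 0.50).

Two deliberate symmetries keep the planted structure clean.  The
chemical sign alternates within each plan class, which (i) makes
same-class latents uncorrelated instead of correlated at `+e²`, and
(ii) cancels the chemical axis' net imprint on total library size, so
compositional closure (the shared `1/total` factor in relative
abundances) does not propagate soil signal to unlinked taxa.  And the
noise components of linked modules are orthogonalised in-sample against
the axes and each other, so realised cross-correlations equal their
design values exactly instead of scattering by ±0.12 at n = 33 — the
scatter's tail otherwise occasionally fuses two planted blocks into one
detected module.  `none` modules keep plain independent noise: their
chance correlations with the axes are genuine null behaviour that the
permutation tests must absorb, and sterilising them would fake the
false-positive regime.

Member counts are negative binomial (size 25 for planted taxa) with
log-mean `baseline + loading × latent` (baseline ~ logN(log 15, 0.3),
loading ~ N(0.75, 0.1) truncated at 0), then each sample is multinomially
resampled to a uniform random depth in [8000, 12000], mimicking amplicon
library-size variation and compositionality.  The 150 background ASVs
split into 28 moderately common taxa (logN(log 100, 0.35), negative
binomial size 3 — abundant generalists are strongly overdispersed in
real amplicon data, and the extra noise keeps them from riding total-
composition fluctuations into the network) and a rare tail
(logN(log 0.04, 0.7)) that the prevalence filter removes, as the rare
biosphere mostly is in real surveys.

Trophic plans make each planted type dominated by one mode
(MUCA: 82 % saprotroph; MRC: 80 % symbiotroph; MRCA: 80 % pathotroph;
background saprotroph-leaning), with an 8 % composite-string rate and a
confidence-rank distribution exercising the parser's gate.  The
contrasts are deliberately strong: with only two modules per type the
Tukey comparison has three error degrees of freedom, and weaker planted
contrasts would make the design's own headline check a coin flip rather
than a test of the machinery.

Default effect sizes were fixed once by a pre-registered simulation
sweep (≥ 20 seeds per candidate) targeting the package's stated
behavioural contract: median within-block |Spearman ρ| ≥ 0.6 on the
network's working table, planted-partition recovery ARI ≥ 0.9, stable
module counts, and high power for the planted linkage channels, while
keeping planted blocks statistically separable.  They are study
conditions, not tuning knobs.

### What the generator does not emulate

No sequence-level reality (reads, chimeras, taxonomy strings), no
phylogenetic correlation among ASVs, no real co-abundance beyond the
single-latent block structure, no spatial autocorrelation between plots,
and soil variables are deliberately low-dimensional (one fertility axis
behind two readouts, one stability axis behind three indices) rather
than the ten-odd partially collinear chemical variables of a real
survey.  Passing the recovery tests therefore shows the pipeline is
correct and well calibrated under its own assumptions — it does not
certify power or error rates on any particular real dataset, where
effect sizes are unknown and soil covariates are messier.

## Evaluation protocol

Recovered modules are matched to planted blocks by majority membership.
Classification accuracy scores the pipeline's MUCA/MRC/MRCA labels
against the plan-derived truth for each planted module.  The trophic
check groups recovered modules by the *planted* type of the block they
match before running the ANOVA/Tukey comparison: it measures composition
recovery and the letter-display machinery without compounding the
classification noise that the label-accuracy check already scores.

A known calibration ceiling is worth stating plainly.  A null module is
tested against two chemical and three aggregate variables at per-test
α = 0.05 with no multiplicity correction (the default, mirroring common
practice).  The chemical readouts are collinear enough to act as one
test (~4.9 % cluster-level false-link rate), but WSA, MWD and GMD
respond to the stability axis with genuinely different curvature, so
their rejections decouple near the threshold and the aggregate cluster
rejects ~6–7 % of null modules.  The union puts the expected fraction of
truly unlinked modules correctly labelled MUCA at ~88–90 %.  Measured
values over 20-seed batches land exactly there (e.g. 105–107/120); a
materially higher specificity is unreachable without changing α,
correcting for multiplicity, or shrinking the variable set.

## Problem sizes

Default experiments use the desk-scale design throughout: 33 samples,
300 ASVs, six planted 25-ASV modules, 999 permutations for analysis
runs, 199 permutations and 500–800 replicates for null-calibration
experiments, and 20 master seeds for recovery studies.  These sizes keep
a full recovery study in the low minutes on a single core while leaving
every statistical check adequately powered.

## Known limitations

* Spearman p-values use the t approximation; with heavy zero-tie
  structure in sparse ASVs the approximation is rough.  The prevalence
  filter removes most such taxa, and the FDR step dominates the edge
  decision for borderline pairs.
* Louvain is a stochastic heuristic; seeds make runs reproducible but
  different seeds can split or merge borderline modules.  Module counts
  on the default design vary by at most one in practice.
* The per-variable, uncorrected linkage screen has the specificity
  ceiling described above; the BH-corrected mode trades sensitivity for
  specificity and changes the MUCA/MRC/MRCA balance accordingly.
* Compact letter displays are not unique in general; the deterministic
  insert-and-absorb construction here is one standard choice.
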