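# Methods

`saltscan` implements a demography-aware genome scan for paired population
comparisons: it asks whether 25 kb windows of elevated FST between an
upland and a saltmarsh population exceed what neutral demography alone can
produce, and whether the survivors carry the footprint of selective
sweeps and recur across independent species pairs.

## Variant filtering

Two filter regimes serve two purposes.  The *scan* set feeds the windowed
statistics: biallelic SNPs with minor allele frequency ≥ 5% (computed over
non-missing genotypes; a site at exactly 5% is kept, since only sites
*below* 5% are removed), mean site depth within [2, 50]X inclusive, and at
most 20% missing genotypes.  The *SFS* set feeds demographic inference and
deliberately keeps rare variants: biallelic SNPs with depth strictly
between 8X and 50X, called in every individual, off the Z chromosome
(which has a smaller effective size than the autosomes), and more than
100 kb from the nearest annotated exon to limit the imprint of direct and
linked selection.  A site exactly 100 kb from an exon is excluded — the
conservative reading of the buffer.  Internal coordinates are 0-based
half-open everywhere; VCF and GFF3 conventions are converted at the
boundary.  Multi-allelic records are kept at load time and removed by the
filters so that removal counts are reportable.

## Windowed statistics

Per-SNP FST is the Weir & Cockerham (1984) two-population
analysis-of-variance estimator; the per-site estimate a/(a+b+c) may be
negative and is left unclamped, matching what VCFtools reports.  Window
mean FST is the arithmetic mean of per-site estimates over the window
(the wording used for the original scans); a ratio-of-sums variant is
available as an option.  Nucleotide diversity per window is
Σ 2p̂(1−p̂)·n/(n−1) over sites divided by the window length; Tajima's D
uses the 1989 normalisation with, under missing data, a single n equal to
the minimum number of called chromosomes across the window's segregating
sites (the constants assume one sample size; taking the minimum is
conservative).  Windows tile each chromosome from coordinate 0 in fixed
25 kb steps; a short terminal window is computed but flagged partial and,
like windows with fewer than `min_snps` (default 5) informative SNPs,
excluded from the genome-wide mean/SD.  Whether sparse windows belong in
the cutoff estimation is genuinely open; the choice is exposed as
configuration.

## Coalescent engine

The null model is a two-deme isolation-with-migration structured
coalescent: piecewise-constant diploid sizes per deme (a post-split
bottleneck in the colonising deme is one extra epoch), a clean merge into
the ancestral population at `T_split`, and continuous bidirectional
migration.  Migration is parameterised forward in time as the proportion
of the receiving deme composed of new immigrants each generation; backward
in time that is exactly the per-lineage rate of tracing into the source
deme, which is how the simulator draws events.  Event times are exact
exponential waiting times with rates refreshed at epoch boundaries (no
discretisation).  Mutation is infinite sites: Poisson counts on total
branch length, branches chosen proportional to length, unique uniform
positions.  Mutation and generation-time defaults are the passerine values
(3.3 × 10⁻⁹ substitutions/site/year, 1-year generations).

Recombination is approximated as free between fixed-length blocks and
absent within blocks.  The default block equals the 25 kb analysis window;
at 0.14 cM/Mb the expected number of breakpoints inside a window is
~0.035 per meiosis, and ignoring them only *widens* the simulated
window-mean FST distribution, making cutoff calibration conservative.
Full ancestral-recombination-graph simulation is out of scope; the engine
is cross-validated against msprime on a shared parameter set in the test
suite.  The Monte-Carlo hot path (branch-length accumulation per joint-SFS
class) has a numba-compiled kernel; a pure-Python engine of the identical
process remains available and the two are compared statistically in tests.

Reproducibility: one master seed; per-block substreams derive from
`(seed, region, block)`, so datasets are bit-reproducible and blocks are
independent.

### Default study conditions

`study_model()` fixes the synthetic study conditions: ancestral size 1e5,
upland deme 1.5e5, saltmarsh deme founded through a 5e3 bottleneck (older
half of the post-split period) recovering to 5e4, split 6e4 generations
ago, symmetric migration 2e-5 per generation.  These orders of magnitude —
splits of 1e4–1e5 years, genome-wide FST of a few percent, saltmarsh π
below upland π — are typical of the upland/saltmarsh passerine pairs this
package targets.  Sample sizes default to 10 diploids per deme.  What the
generator does **not** emulate: real recombination-rate and mutation-rate
heterogeneity, background selection, reference bias, genotyping error and
depth heterogeneity (simulated depths are constant so the scan filters
pass).  Tests passing under these conditions therefore validate the
machinery and its calibration logic, not the biology of any particular
dataset.

## Joint-SFS demographic inference

The observed joint SFS is an (n₁+1)×(n₂+1) count matrix over derived
(outgroup-polarized) or minor (folded) allele classes; the invariant
corners are always masked, and sites whose outgroup allele matches
neither allele are dropped and counted.  Folding assigns tie sites (minor
count exactly half) half to each complementary cell, which makes the fold
exactly allele-flip symmetric.

The expected spectrum under a model is Monte-Carlo: per-genealogy branch
lengths are accumulated per (i, j) class and averaged — a
Rao-Blackwellised version of dropping mutations with far lower variance —
and divided by 4N_ref so the model prediction is θ·expected.  Fitting
maximises a Poisson composite likelihood (sites treated as independent);
θ has its analytic MLE Σobs/Σexp, and the scaled parameters (sizes ν
relative to N_ref, split time T in 2N_ref generations, migration
M = 2N_ref·m) are optimised by Nelder–Mead in log space from several
multiplicatively perturbed starts (default 10).  Three numerical choices
matter:

* **Common random numbers.** The Monte-Carlo seed is fixed within a fit,
  so the objective is a deterministic (if slightly rough) surface.
* **Projection.** `project=(m1, m2)` fits on the hypergeometrically
  down-projected spectrum.  Besides matching sample sizes, projection
  smooths sparse cells — without it the Monte-Carlo surface has
  floored-to-ε cells that wreck optimisation whenever n exceeds ~8
  chromosomes per deme.
* **Centred simplices and restarts.** Each start runs two Nelder–Mead
  rounds with a wide, centred initial simplex (one-sided simplices bias
  truncated runs); an optional polish round re-optimises briefly with a
  much larger genealogy count to damp noise along flat ridges.

Zero expected cells facing observations are floored at 1e-8 of total
expected mass.  Model families cover split-without-migration,
symmetric/asymmetric-migration, and a saltmarsh-bottleneck variant
(bottleneck occupying the older half of the post-split period).

Model ranking uses composite-likelihood AIC, clearly labelled as such in
output: with linked sites AIC can spuriously favour complex models, so
parameter uncertainty comes from a nonparametric chromosome bootstrap
(chromosomes resampled with replacement, spectrum rebuilt, model refit;
95% CI = 2.5/97.5 percentiles).  Bootstrap refits reuse the point fit's
Monte-Carlo stream so replicate-to-replicate spread reflects data
resampling, not simulation jitter.  **Known limitation:** split time and
migration trade off along a flat likelihood ridge in IM models, so T and
M intervals from fast refits under-cover at desk scale; the deme-size
parameters and θ are well identified.  Time conversion assumes T in units
of 2N_ref generations (the convention is configurable and stamped on
output, because the alternative N_ref convention is a classic silent
error); natural units come from θ = 4N_ref·μ·L with L the callable length
behind the SFS.

## Cutoff calibration

The empirical cutoff is mean + 5·SD (sample SD, multiplier configurable)
of eligible window mean FST; windows strictly above it are elevated, and
adjacent elevated windows merge into regions (adjacency only — no gap
tolerance, since window-vs-region terminology is otherwise ambiguous).
`calibrate_null` simulates a whole genome under the fitted neutral model
(default 1072 × 1 Mb to approximate a passerine genome; tests and the
acceptance script use 100 × 100 kb, a documented reduced scale) and
reports mean, SD and 95th/99th percentiles for per-SNP FST, window FST,
and per-deme window π and D, plus verdict flags comparing the empirical
cutoff with the simulated cutoff and percentiles.  `uncertainty_sweep`
redraws model parameters uniformly within per-parameter 95% CIs (invalid
combinations rejected and counted), simulates each draw (default
scaled-down genome of 100 × 100 kb; full scale by flag — 1000 full
genomes is cluster work), and compares the 99th percentile of the
per-draw FST percentiles with the empirical cutoff.

## Sweep co-signals

Elevated windows are compared with an equal number of randomly chosen
neutral windows (all non-elevated eligible windows form the pool) via a
label-permutation test on the one-way ANOVA F statistic, with the
difference in means reported alongside and the add-one p-value rule
(p = (1 + #{null ≥ obs})/(1 + n_perm), never zero).  Identical constant
groups make F undefined and are reported as a no-test with the reason.
Merged regions are flagged *negative-D* when the saltmarsh deme's D
averaged over the region's windows is below zero, and *reduced-π* when
region mean π falls below the genome-wide median window π.  Which deme
defines a "dip" is configurable; the saltmarsh (colonising) deme is the
default because sweeps are hypothesised there.

## Candidate genes and cross-pair classification

Genes whose interval lies within 50 kb of a merged region (gap distance;
0 on overlap; inclusive at exactly 50 kb) are its candidates; regions with
no annotated neighbour are reported separately rather than dropped.
Across pairs, candidates are matched **by gene identity** in one shared
annotation namespace — never by coordinate overlap — a gene found in ≥ 2
pairs is a shared (parallel-selection) candidate, a gene in exactly one
pair is lineage-specific, and exact Venn cell counts are computed for
every pair subset.  Duplicate genes within a pair collapse with a logged
count; a name-normalisation hook absorbs label drift.

## Problem sizes used by tests and the acceptance script

Chosen as the package's own reduced study scale: null-calibration checks
use 20 repetitions of 50-region empirical genomes against 100 × 100 kb
calibration genomes; estimator calibration uses 10⁴ two-lineage blocks,
600 Tajima windows and 2.5 × 10³ equilibrium blocks; SFS recovery uses ten
~20k-SNP datasets (40 × 1 Mb regions, 6 diploids per deme, 50 kb linked
blocks) with 2-start fits of 2000 genealogies per likelihood evaluation;
bootstrap coverage uses 16-replicate chromosome bootstraps on five of
those datasets.  The acceptance script simulates two pairs of 100 × 100 kb
genomes with two divergent regions each (one shared), where a divergent
region — a stand-in for linked selection — is simulated with drastically
reduced local sizes and no gene flow, the same footprint a sweep leaves
in windowed FST.
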