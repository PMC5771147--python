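# Methods

## The score

For a biallelic SNP polarised against an ancestral-allele annotation, the
per-group score is the product `FineMAV_i = DAP × DAF_i × CADD`:

* `DAP = Σ_i f_i^x` with shares `f_i = d_i / Σ_j d_j` computed from
  per-group derived allele counts (count mode), or from per-group derived
  allele frequencies, `f_i = DAF_i / Σ_j DAF_j`, when groups are unequally
  represented (frequency mode).  The two modes coincide for equal sample
  sizes.  DAP lies in (0, 1], equals 1 exactly when one group holds every
  derived copy, and for an allele shared equally by *n* groups equals
  `n^(1−x)`.  If the derived allele is absent from every group DAP is
  undefined; the streaming scorer skips such sites (they are counted in
  the `no_derived` skip counter) and the library signals
  `UndefinedDAPError`.
* `DAF_i` is the continental derived allele frequency: the unweighted mean
  of the subpopulation DAFs within the continent (a sample-size-weighted
  mean is available as an option).  A "global" scoring mode replaces
  `DAF_i` with the mean of the continental DAFs, yielding one score per
  variant that is then assigned to the group maximising ΔDAF.  Continental
  mode is the default and the reported mode.
* `CADD` is consumed, never computed: an allele-specific PHRED-scaled
  score table keyed by (chrom, pos, ref, alt).  Lookups fall back to the
  swapped allele orientation so that sites whose derived allele is the VCF
  REF still join to the score of the same substitution.  Variants with no
  table entry are skipped and counted (`no_cadd`): the scorer only ranks
  annotated SNPs.

ΔDAF, the comparison statistic, is implemented one-vs-rest (target group's
DAF minus the mean of the others); a pairwise-maximum variant is available
behind a flag.  Outlier ranking sorts descending by score with ties broken
by (chromosome, position) so output is deterministic.

## Penalty calibration

The penalty *x* trades population differentiation against functionality.
The calibration procedure scores a window (default: 1000 SNPs, or a
base-pair interval) centred on each gold-standard selected variant, and
for each *x* in a grid (default 1–4 in steps of 0.25) computes the fold
change between the target's score and the best-scoring background SNP in
the expected population.  Because fold-change profiles typically rise and
then flatten, the per-window optimum is plateau-aware: the smallest *x*
within 1% (relative) of the window's maximal fold change.  The consensus
penalty is the median of per-window optima, reported with their spread.
Two diagnostics complement it: the mean rank of the targets in the full
descending score ordering per *x*, and the pairwise overlap of top-k
outlier sets across *x*.

At *x* = 1 the fold change reduces exactly to a DAF × CADD ratio, which is
how the package exposes the undifferentiated regime (nearly fixed,
functional alleles dominating the ranking).

For other group counts the calibrated anchor (n = 3, x = 3.5) is carried
over by `solve_penalty`, which solves `n^(1−x) = 3^(1−3.5)` in closed
form: `x(n) = 1 + 2.5·ln 3 / ln n`.  This keeps the purity of a minimally
differentiated allele — and hence the score scale — invariant to *n*.

A small table of eight experimentally validated selected variants
(gene, rsid, GRCh37 position, derived allele, continental group) ships
with the package as a convenience for building calibration windows from
real data; its coordinates come from dbSNP, and it doubles as a fixture
for the CLI tests.

## Simulation study

The simulator is a diploid, individual-based Wright–Fisher forward model
of one genomic window: `n_snps` loci (default 1000) uniformly spaced over
`window_bp` (default 1 Mb), per-generation recombination between adjacent
loci equal to their physical spacing × 1e-8, non-overlapping generations,
multinomial migration (each offspring picks its parents' population), and
additive viability selection (fitness 1, 1 + s, 1 + 2s) at a single
selected locus in one population.

**Demography.**  Three populations with a two-epoch out-of-Africa
history.  The simulation starts `divergence_gens` (default 3,500)
generations before sampling with an African population (diploid size
14,000) and an OOA bottleneck population (1,860) whose loci share
beta-drawn starting frequencies; at `split_gens` (default 2,000) the OOA
pool founds the European and East Asian populations (5,000 each).
Pairwise migration defaults to 3e-5 (AFR–EUR), 1.9e-5 (AFR–EAS), 9.6e-5
(EUR–EAS) and 1.5e-4 (AFR–OOA).  Sizes and migration follow published
three-population estimates; the divergence and split times follow the
coalescent-calibrated scale in which the Eurasian split precedes selection
onset.  That ordering is structural, not cosmetic: a new advantageous
allele starting at DAF 0.01 establishes with probability roughly
`1 − (1 − 2s)^(2N·0.01)`, so placing onset inside an Ne ≈ 1,900 bottleneck
caps every statistic's power at ~0.5 regardless of *s* and erases the
strong s-dependence that sweep detection is supposed to show.  All values
are plain configuration fields; setting `divergence_gens = 0` collapses
the model to a single epoch for small experiments.

**Scenario protocol.**  Neutral starting frequencies are drawn once per
locus from Beta(0.2, 2.0) (low-frequency-skewed, SFS-like) and shared by
all populations at the start of the history, so neutral differentiation
accrues from the simulated drift itself.  Selection begins
`generations` (default 1,000) generations before sampling: at onset the
selected locus is re-initialised to DAF 0.01 in every population and
selection then acts in the selected population (EUR by default; its OOA
ancestor if onset predates the split).  At the end, 500 individuals per
population are sampled and per-locus derived counts recorded.  Loss of
the selected allele is a valid outcome, not an error.  Scenarios use
s ∈ {0, 0.001, 0.007, 0.01}, 100 replicates by default.

**Rescaling.**  A factor λ divides sizes and all epoch lengths and
multiplies s, migration and recombination, preserving N·s, N·m, N·r and
t/N.  Rescaled runs are approximations (selection coefficients of order
λ·s must stay well below 1); λ = 10 keeps a full scenario grid at a few
minutes per statistic and is what the test suite uses.  Note that
rescaling changes which establishment outcomes a given seed produces —
only distributions, not realisations, are preserved.

**CADD assignment.**  Neutral SNPs draw scores from a surrogate for the
genome-wide CADD distribution of common derived alleles:
Exponential(scale 3.764) truncated at 50, chosen so ~7% of draws exceed
10 (mirroring the PHRED tail law `P(score>c) = 10^(−c/10)` thinned to
common variants) with an upper tail reaching ~40.  The selected SNP draws
from the functional outlier range, uniform on [10.78, 47].  An empirical
mode (`CaddModel.from_scores`) replaces the surrogate with a user-supplied
score pool, which is what reproducing score-dependent results from real
annotation data requires; the surrogate supports qualitative conclusions
(ranking improvements, FDR control) but not score-scale quantities such
as the absolute neutral cutoff.

**Evaluation.**  Top-hit power is the fraction of replicate windows in
which the selected SNP *strictly* attains the window maximum of a
statistic (ΔDAF, DAPxDAF or FineMAV) in the selected population — ties
count as failure, a conservative choice.  The outlier analysis bootstraps
1000 FineMAV values from the neutral (s = 0) windows 100 times and takes
the maximum sampled value as the cutoff; outside-neutral power is the
fraction of selected SNPs above it and FDR the neutral share of all calls
above it (a zero denominator is flagged rather than divided).

## Synthetic data fixtures

`fixtures.make_fixture` writes a VCF (with `INFO/AA` ancestral
annotation), CADD-style table, sample panel and truth table.  Genotypes
are constructed to hit requested per-group DAFs exactly — counts, not
sampling — so each planted variant's DAP and FineMAV are closed-form and
the truth table is exact; infeasible DAF/sample-size combinations raise.
Two archetypes are provided: private-and-fixed with CADD 20 (scores 20 in
its group) and fixed-everywhere with CADD 45 (scores ≈ 2.89 per group at
x = 3.5).  Background sites get random counts and scores.  The generator
emulates file plumbing, not population genetics: passing the round-trip
tests shows the formats and arithmetic are right, while realism (LD,
SFS, drift) lives in the simulator.  Conversely, the simulator emulates a
single sweep window, not whole genomes: no purifying or background
selection, no CADD–fitness correlation for neutral sites, free
recombination beyond the window, and an equilibrium (constant-size)
history within each epoch.  Passing its tests therefore says the method
behaves as designed under the modelled conditions, not that real-data
power will match.

## Numerical and interface choices

* Positions are 1-based in VCF/TSV and 0-based half-open in BED.
* Multi-allelic records and indels are skipped ("SNPs only"), as are
  sites with missing/unusable ancestral annotation; lowercase
  (low-confidence) ancestral calls are accepted by default with a
  `strict_aa` flag to skip them.  Every skip category is counted and the
  counts are printed as a machine-readable summary block.
* Missing genotypes are excluded from frequency denominators; haploid
  calls contribute one chromosome.
* Duplicate CADD keys keep the maximum score (logged).
* Score ties in ranking break by genomic coordinate; score ties across
  groups (global mode) are assigned by ΔDAF.
* Floating comparisons in tests use absolute tolerance 1e-9 for closed
  forms and 0.005 for values printed to 2–3 decimals.
* Every stochastic operation is a pure function of (configuration, seed);
  replicate streams use spawned child seeds, one for the sweep and one
  for score assignment, so adding CADD never perturbs the sweep.

## Test problem sizes

The acceptance-level simulation checks run the default demography at
λ = 10 with 60 replicates per selection coefficient and fixed seeds; the
drift-unbiasedness property uses 500 replicates of a small single-epoch
configuration; the streaming benchmark scores a generated million-site
VCF with six samples.  These sizes were chosen so the whole suite stays
desk-scale while keeping binomial standard errors on power estimates
around 0.06.

## Known limitations

* The two-epoch demography omits post-split growth and admixture; power
  estimates shift by several percentage points across published
  out-of-Africa parameterizations, and the divergence-time scale is the
  dominant lever on neutral ΔDAF backgrounds.
* With the packaged CADD surrogate, quantities tied to the absolute score
  scale (the neutral cutoff's value, score-threshold power) are not
  comparable to analyses using genuine genome-wide CADD tables; use the
  empirical CaddModel for those.
* At x = 1 the score degenerates to DAF × CADD and the top-hit criterion
  effectively requires the sweep to complete within the selection epoch;
  with onset at DAF 0.01 and s ≤ 0.01 the additive logistic fixation time
  exceeds 1,000 generations, so x = 1 power is near zero under this
  protocol.
* The VCF reader trusts `INFO/AA` polarity; mispolarised annotation
  propagates directly into the scores.
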