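# Methods

## The scan criterion

For a partition of the cohort into k phenotype groups, a locus is called
sex-linked when every group has a *dominant* genotype class and the dominant
classes are not all equal. The class alphabet is {HOM, HET, INDEL, ABSENT}:
homozygous and heterozygous SNP calls, any called genotype at an indel site
(indel state is one category), and no call. Four classes give 4^k − 4
possible between-group patterns (12 for two groups); every family reported by
the scan — heterozygous-in-one-group, homozygous-in-the-minority,
presence/absence, and mixed "other" patterns — is an instance of this single
rule, so no family needs its own detector.

Dominance is thresholded at θ (default 0.8, i.e. "at least 80% of the
group"), compared as exact rationals: a group of 6 with 5 concordant calls is
5/6 ≥ 4/5, decided without floating point, so boundary counts never flip with
rounding. θ > 0.5 is enforced, which makes the dominant class unique.

**Denominators.** ABSENT dominance is judged against the whole group: a locus
ungenotyped in ≥ θ of a group is treated as absent there, which is how
sex-limited RAD loci (restriction-site presence/absence polymorphisms)
surface. Dominance of a *called* class is judged among the genotyped samples
of the group, with ABSENT taking precedence when it reaches θ. The
alternative — counting ungenotyped samples against a called class — makes
ordinary RAD missingness veto real markers: at 5% missingness plus 5%
genotyping error, a perfectly sex-linked locus would reach 80% concordance in
a 14-sample group only ~85% of the time, and jointly over two groups ~76%.
Scanning concordance among genotyped calls restores recovery to ~97% while
leaving the presence/absence channel intact. A side effect is that a group
with very few genotyped samples can have a trivially dominant called class;
at the missingness levels the generator emulates this is negligible, but on
sparser data a per-group minimum call count is worth adding before trusting
calls.

Candidates are ordered by (contig, position); group membership is gathered by
sample id, so the verdicts are invariant to sample column order.

## Filters

Site-level hard filters remove loci with QD < 2.0 OR FS > 60.0 OR MQ < 40.0
(strict inequalities, as in standard short-read hard-filtering practice); a
locus missing one of these INFO keys passes that key's test, since synthetic
or third-party VCFs often omit them and absence of evidence is not failure.
The validation-quality coverage filter keeps candidates whose mean depth over
genotyped samples strictly exceeds 15×. The aggregate ("mean over genotyped
samples") is a choice: nothing canonical defines per-locus "coverage" across
a cohort, and the mean over called samples is the least surprising option;
the threshold and the filter are both configurable.

## Validation statistics

Targeted genotypes of a candidate are tabulated against phenotype groups and
tested with Pearson's chi-square, Σ(O−E)²/E, no continuity correction —
the reference contrasts are 3 genotypes × 2 groups (df = 2), and Yates'
correction is a 2×2 device. All-zero rows/columns are dropped before df is
computed. Expected cells below 5 set a flag rather than switching to an exact
test: with ~10 animals per validation group the asymptotic test is what the
field reports, and the flag carries the caveat. Contrasts are MM vs FF,
MM vs pooled others, FF vs pooled others, and the four-group table, flagged
at α = 0.05 per contrast; a Bonferroni-adjusted p across the four contrasts
is emitted alongside for readers who want it, but no multiple-testing
correction is applied to the primary flags.

`null_pass_probability` is the false-positive yardstick: the probability that
a neutral Hardy–Weinberg locus passes the scan. Because θ > 0.5 makes the
dominant class unique, the per-group probability that class c dominates is a
binomial tail (summed over the number of ABSENT samples, whose own dominance
is a separate tail), and groups are independent, so

P(pass) = Π_g P(some class dominates in g) − Σ_c Π_g P(c dominates in g).

This is exact for any group size — no enumeration cap — and a Monte-Carlo
path with the same dominance rule is kept as an independent cross-check (it
reports a standard error). The per-sample class distribution composes the
same noise chain the simulator applies (below), so simulated neutral pass
rates and the analytic null agree to sampling error.

## Simulators

The generator emulates the study design the pipeline is for: a small cohort
sexed in two consecutive seasons and RAD-genotyped. Defaults are the study
conditions — 26 individuals in four phenotype classes (8 MF, 6 FM, 6 MM,
6 FF), thousands of neutral loci, genotyping error ε = 0.05, missingness
μ = 0.05, mean depth 8.39× (negative binomial, dispersion 5 — a standard
overdispersed model for RAD coverage), neutral allele frequencies uniform on
(0.05, 0.95), and 10% of neutral loci indels (matching the roughly 1:9
indel:SNP ratio of shotgun variant calls). Haplotype-level dropout
(restriction-site loss) defaults to 0 so that noise-free runs are exactly
clean; enabling it produces apparent homozygotes (one haplotype silenced)
and ABSENT calls (both silenced, depth 0), the mechanistic source of
presence/absence loci.

Models:

* **XY / ZW** — sex fixed by the genotype at the planted locus
  (heterogametic sex heterozygous); no sex change, so only FF and MM
  phenotype classes are reachable.
* **Two-genotype single locus** — heterozygotes always male; homozygotes
  draw their sex independently each season (default P(female) = 0.5), which
  generates both FM and MF changers among them.
* **Three-genotype single locus** — MM male, FF female, FM protandric: male
  at first maturation, female at the second with probability *f* (the
  model's heterogeneity parameter).
* **Polygenic threshold (PGSD)** — liability = equal additive effects over
  `pgsd_n_loci` loci at frequency 0.5 (scaled so the genetic variance equals
  the heritability h², default 0.5) plus an independent per-season standard
  normal environmental deviate scaled to 1 − h²; female iff liability > 0.
  Sex change happens when the environmental term flips the sign between
  seasons; with ρ = h² between season liabilities the expected change rate is
  arccos(h²)/π ≈ 1/3 at the default, the right order for an
  alternating-sexuality cohort.

When per-class counts are requested, individuals are drawn i.i.d. from the
model and kept while their class has open quota — the same
conditioning-on-phenotype a field study performs — so genotype–phenotype
joint distributions are correct given the class. Unreachable quotas (e.g.
sex changers under XY) are rejected at configuration time.

Noise is applied per cell in a fixed order: dropout, then error, then
missingness. Error moves a called genotype to a uniformly chosen *other
called* refined state (HOM_REF/HET/HOM_ALT at SNPs; a no-op at indel loci,
where INDEL is the only called class); missingness blanks the call but keeps
the drawn depth (a no-call at a covered site), while dropout-absent cells
have depth 0. Keeping error within called states and missingness as the sole
ABSENT source keeps emitted VCFs exactly round-trippable and the null model
closed-form.

What the generator does **not** emulate: linkage disequilibrium between
loci, population structure or relatedness, depth-dependent genotyping error,
batch effects, or environmental covariates beyond the PGSD per-season
deviate. Passing tests therefore show the pipeline's logic is correct under
an idealized HWE cohort, not that real RAD data are this well behaved —
in particular, real missingness is depth- and locus-correlated, which
inflates the presence/absence channel relative to this model.

## Numerical and design choices

* θ, fractions and summary rates use `fractions.Fraction`; percent rendering
  rounds half-up to 2 decimals.
* VCF writing is plain deterministic text (fixed float format, fixed header
  order) so a fixed seed gives byte-identical cohorts; reading uses cyvcf2.
* Chi-square uses `scipy.stats.chi2_contingency(correction=False)` behind
  the module interface; the test suite keeps an explicit expected-matrix
  oracle.
* The refined SNP alphabet (HOM_REF vs HOM_ALT distinguished) is available
  for sensitivity analysis (`alphabet="refined"`); the default collapses
  them, since heterozygosity-vs-homozygosity is the contrast the pattern
  families are defined on.
* Pattern-family labels generalize to any k through the multiset of
  dominant classes: `het-in-1-of-3`, `absent-in-2-of-4`, etc., so per-family
  count tables can be reconstructed for any grouping.
* Simulated contigs hold 1,000 loci at 100-bp spacing with planted loci
  first; coordinates are purely synthetic.

## Problem sizes used in checks

The shipped checks run the scan-vs-oracle comparison on 500 random matrices
(≤ 20 loci × 10 samples), planted-marker recovery on 200 replicate XY
cohorts (12 vs 14), the polygenic negative control on 2,000 liability loci,
and the chi-square oracle on 1,000 random tables; the full suite and the
reproduction script each complete in seconds on one core.

## Known limitations

* The scan is purely criterion-based; it attaches no per-locus significance.
  The neutral null gives the expected false-positive count, not per-locus p.
* Small genotyped denominators can make called-class dominance easy (see
  above); a minimum-call floor is not applied by default.
* The exact null covers SNP loci; indel loci have a single called class and
  only contribute presence/absence-type patterns.
* Validation contrasts on ~10-per-group cohorts routinely trip the
  low-expected-count flag; treat those p-values as indicative.
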