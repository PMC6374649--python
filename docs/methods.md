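# Methods

`nestkin` reconstructs the spatial ecology and mating system of an annual,
facultatively polyandrous haplodiploid social insect (the motivating system
is a suburban bumble bee population) from codominant microsatellite
genotypes of field-sampled workers and dissected queens. This note records
the models, the estimators, the tunable parameters, and the design choices
made where the design was genuinely open.

## Study system and data model

Colonies are headed by a single diploid queen mated to a small number of
haploid males. Workers inherit one maternal allele (one of the queen's two)
and their father's single allele at every locus. Full sisters therefore
share their father's allele and draw their maternal allele from the same
pair; maternal half-sisters (same queen, different father) share only the
queen. Genotypes are unordered diploid allele pairs per locus; a locus call
is missing as a unit. Observed calls carry symmetric allelic mistyping
(allele replaced by a random allele at population frequencies with
probability *e*) and locus-level missingness.

## Locus quality control (`nestkin.qc`)

* **Hardy–Weinberg**: Monte-Carlo exact test. Tables conditional on the
  allele counts are ranked by their conditional probability
  (two-sided probability ordering); the p-value is the fraction of random
  allele pairings producing a table no more probable than the observed one,
  with the +1 correction so p is never zero. Default 10,000 replicates,
  seeded. Tested per sampling year (the population may be structured in
  time shortly after colonization).
* **Multiple testing**: Bonferroni throughout (the corrected threshold is
  alpha divided by the number of tests).
* **Null alleles**: the Chakraborty homozygote-excess summary estimator
  r = (He − Ho)/(He + Ho), with Nei's unbiased expected heterozygosity.
  Negative values (heterozygote excess) are reported, not clamped.
* **Linkage disequilibrium**: permutation test on the chi-square statistic
  of the two-locus single-locus-genotype contingency table, permuting one
  locus across individuals.
* **Selection rules**: a locus is dropped when (a) HWE-significant after
  correction in *every* year, (b) its null-allele estimate exceeds 0.1, or
  (c) it is significantly linked to a locus with higher expected
  heterozygosity (ties broken lexicographically, dropping the larger name).
  Selection is idempotent and input-order independent.

## Queen mating frequency (`nestkin.mating`)

Sperm dissected from a queen's spermatheca is genotyped and compared with
the queen's own (wing-muscle) genotype. Because queen tissue can
contaminate the sperm sample, two seeded Monte-Carlo calibrations frame the
count:

1. **Contamination screen.** For every typed locus the probability that the
   queen's distinct alleles would all appear among the pooled alleles of
   two random mates is computed by inclusion–exclusion over the queen's
   alleles (heterozygote {a,b} with two mates: 2·p_a·p_b; homozygote {a}:
   1 − (1 − p_a)^n). "Match" is read literally as *all* the queen's
   distinct alleles being present; for homozygous queens the single allele
   must appear at least once — one of two defensible readings, chosen
   because it treats the queen's genotype as a set. Bernoulli trials of
   these probabilities (10,000 by default; the analytic binomial mean is
   available and agrees) give each queen an expected match rate; the
   across-queen mean + 2 SD is the critical value (the normal upper tail at
   z = 2 being p = 0.0228). Samples whose observed queen-match rate
   exceeds it are flagged as contaminated. Double mating is assumed in the
   screen because it is the commonest polyandrous class.
2. **Minimum mate count.** Per locus, male-attributable alleles are the
   sperm alleles minus queen alleles — subtracted only when the sample is
   flagged *and* the queen's complete genotype is present at that locus
   (contaminating tissue should amplify both her alleles). The count is the
   largest per-locus value supported at ≥ 2 loci (guarding against
   single-locus artefacts), floored at 1. This is deliberately
   conservative: the count never exceeds the true number of contributing
   males under the error-free counting model.
3. **Miscount calibration.** Pairing each real queen genotype with
   simulated sperm from t = 1..9 random males and re-running the identical
   screen-and-count procedure yields P(observed = k | true = t). The
   maximum likely mating frequency is the largest t whose probability of
   being observed at or below the maximum observed count is ≥ 0.05.

## Sibship reconstruction (`nestkin.sibship`)

Full-pedigree MCMC samplers (COLONY-style) are the field standard for this
step; one is deliberately not reimplemented here. The substitute keeps the
same contracts
(inclusion probability ≥ 0.8, within-year assignment only, polyandrous
female / monandrous male model, colonies rejected above the patriline cap)
with a deterministic two-stage algorithm:

1. **Pairwise full-sib stage.** Per locus, exact likelihood matrices over
   observed genotype pairs are computed for full-sib, maternal half-sib and
   unrelated relationships by marginalizing the queen (Hardy–Weinberg
   prior), the father(s) (population frequencies) and maternal-allele
   picks, with the symmetric mistyping kernel
   E[obs|true] = (1−e)·1[obs=true] + e·p_obs. These matrices are validated
   against exhaustive enumeration. Greedy agglomeration on full-sib
   log-odds recovers full-sib groups, which carry a strong pairwise signal
   (shared paternal allele).
2. **Joint colony stage.** Pairwise half-sib odds are inherently weak, so
   full-sib groups are merged into colonies under a *joint* colony
   likelihood: for a candidate colony, one unknown queen is shared by all
   groups (summed over her genotypes with HW prior) and one unknown father
   is shared within each group. Merging proceeds greedily while the
   likelihood gain plus the prior log-odds of a merge is positive, followed
   by hill-climbing reassignment of whole groups. The relationship priors
   enter as expected sampled sibship sizes: with mating frequency *m* and
   mean sampled patriline size *n*, a random same-year pair is a full sib
   with prior (n−1)/(N−1) and a maternal sib with (mn−1)/(N−1). An
   initial pass with the weakly-informative default (n = 2, m = 1.5)
   provides the partition from which *n* is estimated; the final pass uses
   (m from the mating analysis, estimated n).
3. **Inclusion probabilities** are the softmax posterior of each worker's
   placement (exact own-colony score with the worker detached, versus
   attachment to every other colony or isolation). Workers under the 0.8
   threshold are left as singletons.

Queen genotypes are inferred per colony and locus as the maximum-posterior
genotype given the workers, *with the full-sib grouping supplied*: without
it, a shared father is statistically indistinguishable from the queen and
the posterior splits. Loci are retained only at posterior ≥ 0.8. Patrilines
are labelled by greedy grouping of workers whose candidate paternal alleles
are mutually compatible at every confidently-typed locus (deterministic,
worker-id order); colonies with more than 5 patrilines — the maximum likely
mating frequency — are rejected (counts of exactly 5 are accepted; the
boundary follows the published rejection of counts above five).

Numerical notes: all likelihoods are accumulated in log space;
log-probabilities of impossible configurations are floored at −400 so that
incremental cluster-sum updates stay finite; ties everywhere break on
worker/locus identifiers.

## Nests, foraging distances and density (`nestkin.spatial`)

Nest locations are the coordinate-wise mean centre of each accepted
colony's worker sampling points (no habitat snapping). Colonies qualify
with ≥ 2 workers separated by more than 4 m (GPS precision). The
colony-specific foraging distance is the mean worker-to-centre Euclidean
distance; the population summary is the mean over colonies and the maximum
over workers. Reconstructed full- versus half-sister pairwise sampling
distances are compared with Welch's t-test as an over-assignment check.

Total colony numbers are estimated with the classic abundance-based
coverage estimator over the workers-per-colony vector (singletons drive
F₁): S_ACE = S_abund + S_rare/C_ACE + (F₁/C_ACE)·γ², with
C_ACE = 1 − F₁/N_rare, rare cutoff 10 (the classic default), and γ² the
truncated squared coefficient of variation. When every rare colony is a
singleton, C_ACE = 0 and the estimator is undefined; the code raises an
error directing users to a Chao1-type fallback rather than answering
silently. The standard error is a seeded bootstrap over workers (1,000
replicates by default; the delta-method variance was not reproduced), and
the 95% CI is ± 1.96 SE. Nest density divides the estimate by the core
sampling area plus an outward buffer one mean foraging distance wide
(four edge strips + quarter-circle corners: 4·side·r + π·r²).

Caveat: under grid-capped sampling of a dense population, detection
heterogeneity among colonies is strong and ACE can overshoot the true
colony number; the estimator is reported as specified, and the synthetic
truth makes the behaviour measurable.

## Lineage survival and isolation by distance (`nestkin.lineage`)

Inferred queens of the later year are scored as candidate full/half sisters
of each earlier-year colony's workers with the same kinship engine (sum of
sib log-odds over colony members; softmax over colonies plus a no-match
option; acceptance at ≥ 0.8). Lineage survival is the fraction of
earlier-year colonies with at least one accepted match. Matching is
conservative when later-year colonies are small, because weakly-inferred
queen genotypes carry few confident loci.

Pairwise relatedness between inferred queens uses the Queller–Goodnight
estimator, symmetrized by pooling numerators and denominators over the two
reference directions and over loci. (The estimator is undefined for a
heterozygous reference at a diallelic locus with allele frequencies 0.5 —
the denominator vanishes; such loci simply contribute nothing.) Isolation
by distance is the OLS regression of pairwise relatedness on between-nest
distance in metres (untransformed; a log₁₀ option exists for display
parity), with the F test of the slope at df (1, n_pairs − 2). Pairwise
observations are not independent; the naive F test is reported as the
primary result to match common practice, and a Mantel permutation test is
provided as a clearly-labelled alternative. Under the generator's
no-structure default the naive test's type-I error measures ≈ 5% (checked
over 200 seeded replicates).

## Synthetic populations (`nestkin.simulate`)

The generator emulates the study design so every stage is testable against
known truth. Defaults (one choice each, held fixed):

| parameter | default | rationale |
|---|---|---|
| arena | 2 × 2 km, 500 m grid squares, cap 40 workers/square | the sampling design |
| colonies per year | 1250 / 350 | the scale of the estimated population in the two study years |
| mating-number distribution | {1: 0.34, 2: 0.62, 3: 0.04} | 34% monandry and mean 1.7 mates, range 1–3 |
| loci | 20, 4–10 alleles, Dirichlet(1) spectra | the polymorphic panel |
| mistyping / missingness | 2.26% / 15% per locus | re-genotyping error rate; median typed loci below panel size |
| foraging kernel | half-normal radial, mean 103.6 m | only mean displacement is identified by the data |
| workers available per colony | Poisson(2) | yields ~640 capped workers and a realistic singleton fraction (~85%) |
| queens sampled | 44, sperm dropout 0.1, contamination prob 0.9 | low sperm DNA yields; nearly all real samples screened as contaminated |
| lineage survival | 0.1 per year-1 colony | the order of the published estimate |

Patriline sizes within a colony are equal in expectation (no sperm-use
skew) — an explicit assumption, as no within-colony distribution is
identified. Year-2 immigrant queens are unrelated draws from the same
frequencies: no isolation by distance is built in (matching the null
finding); a spatial-structure switch for power studies is deliberately out
of the default path. Workers displaced outside the arena are not sampled.

What the generator does **not** emulate: temporal colony demography, floral
resource maps, genotyping artefacts beyond symmetric mistyping (no
locus-specific stutter or allele-size-dependent dropout), and non-uniform
nest habitat. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to every field artefact.

## Orchestration and reproducibility

`nestkin.pipeline.run_pipeline` executes QC → mating → sibship → spatial →
density → lineage → IBD from one config; every threshold (inclusion 0.8,
null 0.1, patriline cap 5, queen-locus confidence 0.8, GPS precision 4 m,
rare cutoff 10) lives in the config, and every random stage receives a seed
derived deterministically from the master seed, so identical config + seed
reproduce byte-identical summaries. The `nestkin` CLI exposes the stages as
verbs (`simulate`, `qc`, `mating`, `sibship`, `spatial`, `density`,
`lineage`, `ibd`, `run-all`).

Problem sizes used by the test suite and `scripts/acceptance.py` (our
choices for a single-CPU desk run): partition recovery on 30 colonies × 5
workers at 14 loci; mating recovery on 300 queens; kernel recovery on 50
colonies × 5 workers; IBD calibration over 200 replicates of 30 colonies;
lineage recovery at survival 0.1 over 200 colonies; the end-to-end
acceptance run uses the full default scenario (~1,200 workers over two
years) with Monte-Carlo depths of 1,000–2,000 where the defaults would use
10,000.

## Known limitations

* The two-stage partition is a point estimate with greedy search; it has no
  posterior over partitions, and the inclusion probability is a softmax
  approximation, not an MCMC marginal.
* Mate counts are minima by construction; with sperm dropout the monandry
  fraction is biased upward by a few points, exactly as the miscount
  calibration quantifies.
* Queen-genotype confidence filtering leaves few usable loci for singleton
  and two-worker colonies, making cross-year matching conservative at low
  sampling depth.
* ACE inherits its assumptions: abundance-driven detectability and a
  homogeneous rare class; strong detection heterogeneity inflates it.
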