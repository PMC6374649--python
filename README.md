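# nestkin

Colony kinship, mating-system and nest-density inference for haplodiploid
social insects from codominant microsatellite genotypes.

Molecular mark–recapture of *colonies* is the standard way to study the
cryptic spatial ecology of bumble bees and other eusocial insects: workers
netted while foraging are genotyped, grouped into full/half sibships (one
sibship = one colony), and the reconstructed colonies yield worker foraging
distances, nest densities, between-year lineage survival and fine-scale
genetic structure — none of which can be observed directly. `nestkin`
implements that entire chain for an annual, facultatively polyandrous
species, plus the sperm-genotyping analysis that estimates how many males
each queen mated with, and a spatially explicit synthetic-population
generator so every stage can be validated against known truth.

## The models at the core

* **Haplodiploid kinship likelihoods.** For workers x, y with unordered
  diploid genotypes, per-locus likelihoods of full sibship (shared queen and
  father), maternal half sibship (shared queen) and non-relationship are
  computed by marginalizing the queen genotype q (Hardy–Weinberg prior),
  father alleles f (population frequencies p) and maternal picks, through a
  symmetric mistyping kernel E[o|a] = (1−e)·1[o=a] + e·p_o. Colonies are
  reconstructed by clustering full-sib groups first (strong pairwise
  signal), then merging groups under the joint likelihood
  Σ_q HW(q) Π_groups [Σ_f p_f Π_workers P(o|q,f)], which captures the
  shared-mother constraint pairwise scores cannot.
* **Minimum queen mating frequency.** Sperm dissected from the spermatheca
  is compared with the queen's own genotype; a Monte-Carlo contamination
  screen flags samples matching the queen at more loci than chance
  (critical value = mean + 2 SD of the expected match rate under double
  mating), and the mate count is the largest per-locus number of
  male-attributable alleles supported at ≥ 2 loci. A second simulation
  calibrates P(observed count | true count) and bounds the maximum likely
  mating frequency.
* **Nest density via ACE.** Detected colonies are corrected for unsampled
  ones with the abundance-based coverage estimator
  S_ACE = S_abund + S_rare/C_ACE + (F₁/C_ACE)·γ², C_ACE = 1 − F₁/N_rare,
  over the workers-per-colony abundance vector; density divides the
  estimate by the sampling area plus a buffer one mean foraging distance
  wide (4·side·r + π·r²).
* **Lineage survival and isolation by distance.** Queen genotypes inferred
  from worker sibships (loci kept at posterior ≥ 0.8) are matched across
  years with the same kinship engine, and pairwise Queller–Goodnight
  relatedness is regressed on between-nest distance.

See `docs/methods.md` for assumptions, priors, numerical choices and
limitations.

## Worked example

Simulate one field season, reconstruct colonies, and estimate foraging
distance and nest density:

```python
from nestkin import (
    SimulationConfig, simulate_population, simulate_workers,
    apply_genotyping_error, reconstruct_colonies, SibshipPriors,
    colony_foraging_distances, ace_estimate, buffer_area, nest_density,
)
from nestkin.spatial import foraging_summary

cfg = SimulationConfig(
    n_colonies=(60, 1), n_loci=14, min_alleles=5, max_alleles=10,
    workers_per_colony_mean=4, workers_per_colony_dist="poisson",
    kernel_mean_m=103.6, square_cap=40,
)
pop = simulate_population(cfg, seed=1)
workers = [w for w in simulate_workers(pop, cfg, seed=2) if w.year == 2014]
observed = apply_genotyping_error(
    [w.genotype for w in workers], pop.freqs,
    cfg.mistyping_rate, cfg.missing_rate, seed=3,
)

partition = reconstruct_colonies(
    observed, pop.freqs, priors=SibshipPriors(m=1.7, n=2.0), year=2014
)
locations = {w.worker_id: (w.x, w.y) for w in workers}
members = {c: partition.members(c) for c in partition.accepted_colonies()}
nests, _ = colony_foraging_distances(members, locations)
summary = foraging_summary(nests)

abundances = partition.frame.groupby("colony_id").size().to_numpy()
ace = ace_estimate(abundances, seed=4)
buffer_ha = buffer_area(cfg.arena_side_m, summary["mean_colony_foraging_distance_m"])
dens = nest_density(ace, core_area_ha=400.0, buffer_area_ha=buffer_ha, year=2014)
```

Output:

```
workers sampled:      228
colonies detected:    87
accepted (>=2 workers, <=5 patrilines): 49
mean colony-specific foraging distance: 85.6 m
estimated total colonies: 125.8 (SE 7.2)
nest density: 0.27 colonies/ha over 470.7 ha
sample completeness: 0.69
```

Reading it: 228 capped-grid worker captures resolve into 87 distinct
colonies (singletons included), 49 of which pass the acceptance rules and
contribute nest locations. The mean distance between a worker's capture
point and its colony's mean centre — the colony-specific foraging distance —
is 85.6 m here (the generating kernel mean was 103.6 m; mean-centre
estimates shrink at small per-colony sample sizes). ACE corrects the 87
detected colonies for the undetected remainder via the singleton/doubleton
structure, and the density spreads that estimate over the 400 ha sampling
square plus its 70.7 ha foraging buffer.

The same analysis runs end-to-end from the shell:

```bash
nestkin run-all --seed 1 --out results/demo      # default study conditions
nestkin simulate --config my_scenario.yaml       # just write a dataset
```

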