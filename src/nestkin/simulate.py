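"""Synthetic populations of polyandrous haplodiploid colonies in space.

The generator emulates the sampling design the analysis assumes: colonies
headed by one diploid queen mated to a small number of haploid males, nests
placed uniformly in a square arena, workers displaced from their nest by an
isotropic foraging kernel and captured under a per-grid-square cap, genotypes
observed with allelic mistyping and locus-level missingness, and queen sperm
samples optionally contaminated with the queen's own tissue. True colony and
patriline labels are carried through so every inference stage can be scored.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .genotypes import (
    AlleleFrequencies,
    Locus,
    MultilocusGenotype,
    estimate_allele_frequencies,
)
from .mating import SpermProfile


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic population.

    Defaults follow the system the analysis targets: a 2 x 2 km suburban
    arena split into 500 m sampling squares capped at 40 workers each, 20
    polymorphic microsatellites, queens mating with 1-3 males (mean 1.7, 34%
    monandrous), a half-normal foraging kernel with mean displacement
    103.6 m, 2.26% allelic mistyping, and a between-year lineage survival
    probability of 0.1.
    """

    arena_side_m: float = 2000.0
    grid_square_m: float = 500.0
    square_cap: int = 40
    years: tuple[int, int] = (2014, 2015)
    n_colonies: tuple[int, int] = (1250, 350)
    mating_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.34, 2: 0.62, 3: 0.04}
    )
    kernel: str = "half_normal"  # or "exponential"
    kernel_mean_m: float = 103.6
    n_loci: int = 20
    min_alleles: int = 4
    max_alleles: int = 10
    freq_spectrum: str = "dirichlet"  # or "uniform"
    dirichlet_alpha: float = 1.0
    mistyping_rate: float = 0.0226
    missing_rate: float = 0.15
    contamination_prob: float = 0.9
    sperm_dropout: float = 0.1
    workers_per_colony_mean: float = 2.0
    workers_per_colony_dist: str = "poisson"  # or "constant"
    lineage_survival: float = 0.1
    n_queens_sampled: int = 44

    def __post_init__(self) -> None:
        for name in (
            "mistyping_rate",
            "missing_rate",
            "contamination_prob",
            "sperm_dropout",
            "lineage_survival",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.square_cap < 1:
            raise ValueError("square_cap must be >= 1")
        if self.kernel_mean_m < 0:
            raise ValueError("kernel mean must be >= 0")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        if not self.mating_distribution:
            raise ValueError("empty mating-number distribution")
        total = sum(self.mating_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("mating-number distribution must sum to 1")
        if self.kernel not in ("half_normal", "exponential"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TrueColony:
    colony_id: str
    year: int
    queen: MultilocusGenotype
    fathers: list[MultilocusGenotype]
    nest_x: float
    nest_y: float
    parent_colony: str | None = None  # year-1 colony this queen descends from


@dataclass
class WorkerObservation:
    worker_id: str
    year: int
    genotype: MultilocusGenotype  # as observed (after any genotyping error)
    x: float
    y: float
    true_colony: str
    true_patriline: int


@dataclass
class Population:
    loci: list[Locus]
    freqs: AlleleFrequencies  # the generating (true) allele frequencies
    colonies: dict[int, list[TrueColony]]

    def colonies_flat(self) -> list[TrueColony]:
        return [c for year in sorted(self.colonies) for c in self.colonies[year]]


# ---------------------------------------------------------------------------
# building blocks


def draw_loci(config: SimulationConfig, rng: np.random.Generator) -> tuple[
    list[Locus], AlleleFrequencies
]:
    """Draw the marker panel: allele counts and frequency spectra per locus."""
    loci: list[Locus] = []
    freqs: dict[str, dict[int, float]] = {}
    for i in range(config.n_loci):
        k = int(rng.integers(config.min_alleles, config.max_alleles + 1))
        name = f"L{i + 1:02d}"
        # allele labels mimic fragment sizes: locus-specific offset, 2 bp steps
        labels = tuple(100 + 10 * i + 2 * j for j in range(k))
        if config.freq_spectrum == "dirichlet":
            p = rng.dirichlet(np.full(k, config.dirichlet_alpha))
            p = np.clip(p, 1e-3, None)
            p = p / p.sum()
        elif config.freq_spectrum == "uniform":
            p = np.full(k, 1.0 / k)
        else:
            raise ValueError(f"unknown frequency spectrum {config.freq_spectrum!r}")
        loci.append(Locus(name, labels))
        freqs[name] = {a: float(x) for a, x in zip(labels, p)}
    return loci, AlleleFrequencies(freqs)


def _draw_diploid(
    loci: list[Locus], freqs: AlleleFrequencies, rng: np.random.Generator, id_: str
) -> MultilocusGenotype:
    calls = {}
    for locus in loci:
        p = freqs.vector(locus.name)
        a, b = rng.choice(len(locus.alleles), size=2, p=p)
        calls[locus.name] = (locus.alleles[a], locus.alleles[b])
    return MultilocusGenotype(id_, calls, ploidy="diploid")


def _draw_haploid(
    loci: list[Locus], freqs: AlleleFrequencies, rng: np.random.Generator, id_: str
) -> MultilocusGenotype:
    calls = {}
    for locus in loci:
        p = freqs.vector(locus.name)
        a = rng.choice(len(locus.alleles), p=p)
        calls[locus.name] = (locus.alleles[a],)
    return MultilocusGenotype(id_, calls, ploidy="haploid")


def _daughter_queen(
    colony: TrueColony, loci: list[Locus], rng: np.random.Generator, id_: str
) -> MultilocusGenotype:
    """A diploid daughter of the colony's queen and one of her mates."""
    father = colony.fathers[rng.integers(len(colony.fathers))]
    calls = {}
    for locus in loci:
        q = colony.queen.call(locus.name)
        f = father.call(locus.name)
        maternal = q[rng.integers(2)]
        calls[locus.name] = (maternal, f[0])
    return MultilocusGenotype(id_, calls, ploidy="diploid")


def _kernel_displacement(
    config: SimulationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """n isotropic displacements whose radial distance has the configured mean."""
    mu = config.kernel_mean_m
    if mu == 0:
        return np.zeros((n, 2))
    if config.kernel == "half_normal":
        sigma = mu * math.sqrt(math.pi / 2.0)
        r = np.abs(rng.normal(0.0, sigma, size=n))
    else:  # exponential
        r = rng.exponential(mu, size=n)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


# ---------------------------------------------------------------------------
# population and worker sampling


def simulate_population(config: SimulationConfig, seed: int) -> Population:
    """Simulate colonies for both years.

    Queens are Hardy-Weinberg draws from the configured frequencies; each
    mates with 1-5 haploid males drawn i.i.d. from the same frequencies.
    Nests are uniform in the arena. Each year-1 colony independently leaves a
    surviving daughter colony in year 2 with the configured lineage-survival
    probability; the remaining year-2 colonies are founded by immigrant
    (unrelated) queens.
    """
    rng = np.random.default_rng(seed)
    loci, freqs = draw_loci(config, rng)
    mate_numbers = sorted(config.mating_distribution)
    mate_probs = np.array([config.mating_distribution[k] for k in mate_numbers])

    def new_colony(cid: str, year: int, queen: MultilocusGenotype) -> TrueColony:
        n_mates = int(rng.choice(mate_numbers, p=mate_probs))
        fathers = [
            _draw_haploid(loci, freqs, rng, f"{cid}_m{j + 1}")
            for j in range(n_mates)
        ]
        x, y = rng.uniform(0.0, config.arena_side_m, size=2)
        return TrueColony(cid, year, queen, fathers, float(x), float(y))

    year1, year2 = config.years
    n1, n2 = config.n_colonies
    colonies: dict[int, list[TrueColony]] = {year1: [], year2: []}
    for i in range(n1):
        cid = f"{year1}_C{i + 1:04d}"
        colonies[year1].append(new_colony(cid, year1, _draw_diploid(loci, freqs, rng, cid + "_Q")))

    survivors = rng.random(n1) < config.lineage_survival
    idx2 = 0
    for i, parent in enumerate(colonies[year1]):
        if not survivors[i] or idx2 >= n2:
            continue
        idx2 += 1
        cid = f"{year2}_C{idx2:04d}"
        queen = _daughter_queen(parent, loci, rng, cid + "_Q")
        col = new_colony(cid, year2, queen)
        col.parent_colony = parent.colony_id
        colonies[year2].append(col)
    while idx2 < n2:
        idx2 += 1
        cid = f"{year2}_C{idx2:04d}"
        colonies[year2].append(new_colony(cid, year2, _draw_diploid(loci, freqs, rng, cid + "_Q")))

    return Population(loci, freqs, colonies)


def _worker_genotype(
    colony: TrueColony,
    loci: list[Locus],
    rng: np.random.Generator,
    wid: str,
) -> tuple[MultilocusGenotype, int]:
    patriline = int(rng.integers(len(colony.fathers)))  # equal sperm use
    father = colony.fathers[patriline]
    calls = {}
    for locus in loci:
        q = colony.queen.call(locus.name)
        maternal = q[rng.integers(2)]
        calls[locus.name] = (maternal, father.call(locus.name)[0])
    return MultilocusGenotype(wid, calls, ploidy="diploid"), patriline


def simulate_workers(
    population: Population, config: SimulationConfig, seed: int
) -> list[WorkerObservation]:
    """Sample workers with foraging displacement and the per-square cap.

    Worker counts per colony follow the configured distribution; sampled
    locations are nest + kernel draw. Workers displaced outside the arena are
    not encountered; within each grid square at most ``square_cap`` workers
    are kept (uniform thinning). Genotypes here are error-free; pass them
    through :func:`apply_genotyping_error` to obtain observed calls.
    """
    if not population.colonies_flat():
        return []
    rng = np.random.default_rng(seed)
    loci = population.loci
    out: list[WorkerObservation] = []
    for year in sorted(population.colonies):
        candidates: list[WorkerObservation] = []
        for colony in population.colonies[year]:
            if config.workers_per_colony_dist == "constant":
                n_w = int(round(config.workers_per_colony_mean))
            elif config.workers_per_colony_dist == "poisson":
                n_w = int(rng.poisson(config.workers_per_colony_mean))
            else:
                raise ValueError(
                    f"unknown worker-count distribution {config.workers_per_colony_dist!r}"
                )
            if n_w == 0:
                continue
            disp = _kernel_displacement(config, rng, n_w)
            for j in range(n_w):
                wid = f"{colony.colony_id}_w{j + 1}"
                geno, patriline = _worker_genotype(colony, loci, rng, wid)
                candidates.append(
                    WorkerObservation(
                        wid,
                        year,
                        geno,
                        colony.nest_x + float(disp[j, 0]),
                        colony.nest_y + float(disp[j, 1]),
                        colony.colony_id,
                        patriline,
                    )
                )
        # arena clipping, then the per-square cap
        inside = [
            w
            for w in candidates
            if 0.0 <= w.x <= config.arena_side_m and 0.0 <= w.y <= config.arena_side_m
        ]
        by_square: dict[tuple[int, int], list[WorkerObservation]] = {}
        n_sq = max(int(math.ceil(config.arena_side_m / config.grid_square_m)), 1)
        for w in inside:
            sq = (
                min(int(w.x // config.grid_square_m), n_sq - 1),
                min(int(w.y // config.grid_square_m), n_sq - 1),
            )
            by_square.setdefault(sq, []).append(w)
        kept: list[WorkerObservation] = []
        for sq in sorted(by_square):
            group = by_square[sq]
            if len(group) > config.square_cap:
                idx = rng.choice(len(group), size=config.square_cap, replace=False)
                group = [group[i] for i in sorted(idx)]
            kept.extend(group)
        kept.sort(key=lambda w: w.worker_id)
        out.extend(kept)
    return out


# ---------------------------------------------------------------------------
# observation error


def apply_genotyping_error(
    genotypes: list[MultilocusGenotype],
    freqs: AlleleFrequencies,
    mistyping_rate: float,
    missing_rate: float,
    seed: int,
) -> list[MultilocusGenotype]:
    """Observe genotypes with allelic mistyping and locus-level missingness.

    Each allele is independently replaced by a random allele drawn at the
    locus's frequencies with probability ``mistyping_rate`` (the replacement
    may coincide with the truth); each locus call is set missing as a unit
    with probability ``missing_rate``.
    """
    if not 0.0 <= mistyping_rate <= 1.0 or not 0.0 <= missing_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for g in genotypes:
        calls: dict[str, tuple[int, ...] | None] = {}
        for locus, call in g.calls.items():
            if call is None or rng.random() < missing_rate:
                calls[locus] = None
                continue
            locus_obj = freqs.as_locus(locus)
            p = freqs.vector(locus)
            observed = []
            for a in call:
                if rng.random() < mistyping_rate:
                    a = locus_obj.alleles[rng.choice(len(p), p=p)]
                observed.append(a)
            calls[locus] = tuple(observed)
        out.append(MultilocusGenotype(g.id, calls, ploidy=g.ploidy))
    return out


# ---------------------------------------------------------------------------
# sperm samples


def simulate_sperm_samples(
    colonies: list[TrueColony],
    contamination_prob: float,
    seed: int,
    dropout: float = 0.1,
) -> dict[str, SpermProfile]:
    """Sperm profiles per queen: union of her mates' alleles, with dropout.

    Each male allele amplifies independently with probability 1 - dropout.
    With probability ``contamination_prob`` the sample is contaminated with
    queen tissue, adding BOTH queen alleles at every amplified locus. Loci at
    which nothing amplified carry no alleles and are flagged unamplified.
    """
    rng = np.random.default_rng(seed)
    profiles: dict[str, SpermProfile] = {}
    for colony in colonies:
        contaminated = rng.random() < contamination_prob
        alleles: dict[str, frozenset[int]] = {}
        amplified: dict[str, bool] = {}
        for locus in colony.queen.calls:
            male_alleles = set()
            for father in colony.fathers:
                call = father.call(locus)
                if call is not None and rng.random() >= dropout:
                    male_alleles.add(call[0])
            if contaminated:
                # queen tissue amplifies reliably: both her alleles join the
                # profile wherever she is typed
                q = colony.queen.call(locus)
                if q is not None:
                    male_alleles |= set(q)
            amplified[locus] = bool(male_alleles)
            alleles[locus] = frozenset(male_alleles)
        profiles[colony.colony_id] = SpermProfile(alleles, amplified)
    return profiles


# ---------------------------------------------------------------------------
# convenience: queens for the mating-system analysis


def simulate_queen_sample(
    config: SimulationConfig,
    seed: int,
    loci: list[Locus] | None = None,
    freqs: AlleleFrequencies | None = None,
) -> tuple[list[Locus], AlleleFrequencies, list[TrueColony], dict[str, SpermProfile]]:
    """Queens with sperm samples, as collected for mating-system estimation.

    Returns the marker panel, true frequencies, one TrueColony per sampled
    queen (nest location unused) and her sperm profile. Pass an existing
    panel (``loci``, ``freqs``) to type the queens at the same markers as a
    simulated worker population.
    """
    rng = np.random.default_rng(seed)
    if loci is None or freqs is None:
        loci, freqs = draw_loci(config, rng)
    mate_numbers = sorted(config.mating_distribution)
    mate_probs = np.array([config.mating_distribution[k] for k in mate_numbers])
    queens: list[TrueColony] = []
    for i in range(config.n_queens_sampled):
        qid = f"Q{i + 1:03d}"
        queen = _draw_diploid(loci, freqs, rng, qid)
        n_mates = int(rng.choice(mate_numbers, p=mate_probs))
        fathers = [
            _draw_haploid(loci, freqs, rng, f"{qid}_m{j + 1}") for j in range(n_mates)
        ]
        queens.append(TrueColony(qid, config.years[0], queen, fathers, 0.0, 0.0))
    sperm_seed = int(rng.integers(2**31 - 1))
    profiles = simulate_sperm_samples(
        queens, config.contamination_prob, sperm_seed, dropout=config.sperm_dropout
    )
    return loci, freqs, queens, profiles


def worker_frequencies(workers: list[WorkerObservation]) -> AlleleFrequencies:
    """Population allele frequencies from the sampled workers' genotypes."""
    return estimate_allele_frequencies([w.genotype for w in workers])
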