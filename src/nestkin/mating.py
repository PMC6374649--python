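"""Queen mating-frequency estimation from spermathecal sperm genotypes.

A queen's minimum mate number is the largest per-locus count of
male-attributable alleles in her sperm sample that is supported at two or
more loci. Because sperm dissections can be contaminated with queen tissue,
samples are first screened with a Monte-Carlo calibration: the expected rate
at which a queen's alleles would be matched by chance by the combined
alleles of two random mates is simulated per queen, and samples matching the
queen above the across-queen mean + 2 SD of that rate are flagged as
contaminated. For flagged samples, queen alleles are subtracted at a locus
only when the queen's complete genotype is present there. A second
simulation pairs each queen with synthetic sperm from known numbers of
males to tabulate how often a true mate count is observed as a smaller one,
which bounds the maximum likely mating frequency in the sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genotypes import AlleleFrequencies, MultilocusGenotype


@dataclass
class SpermProfile:
    """Distinct alleles amplified per locus from a queen's stored sperm."""

    alleles: dict[str, frozenset[int]]
    amplified: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.amplified:
            self.amplified = {l: bool(a) for l, a in self.alleles.items()}
        for locus, ok in self.amplified.items():
            if not ok and self.alleles.get(locus):
                raise ValueError(f"unamplified locus {locus} carries alleles")

    def amplified_loci(self) -> list[str]:
        return [l for l, ok in self.amplified.items() if ok]


@dataclass
class QueenRecord:
    id: str
    genotype: MultilocusGenotype
    sperm: SpermProfile
    site: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        extra = set(self.sperm.alleles) - set(self.genotype.calls)
        if extra:
            raise ValueError(f"queen {self.id}: sperm loci {extra} not in genotype")

    def typed_loci(self) -> list[str]:
        return self.genotype.typed_loci()


@dataclass
class MatchSimResult:
    expected_matches: dict[str, float]
    expected_rate: dict[str, float]
    mean_rate: float
    sd_rate: float

    @property
    def critical_value(self) -> float:
        return self.mean_rate + 2.0 * self.sd_rate


@dataclass
class MiscountMatrix:
    """P(observed mate count = k | true count = t), averaged across queens."""

    true_counts: list[int]
    probs: np.ndarray  # shape (len(true_counts), max(true)+1); column k
    replicates: int

    def p_observed_at_most(self, observed: int, true: int) -> float:
        row = self.probs[self.true_counts.index(true)]
        return float(row[: min(observed, row.size - 1) + 1].sum())


# ---------------------------------------------------------------------------
# per-locus match probability


def locus_match_probability(
    queen_alleles: Sequence[int],
    locus_freqs: Mapping[int, float],
    n_males: int = 2,
) -> float:
    """P(all the queen's distinct alleles appear among n i.i.d. male draws).

    By inclusion-exclusion over the queen's distinct alleles. For a
    heterozygote {a, b} with two mates this is 2 p_a p_b; for a homozygote
    {a, a} it is 1 - (1 - p_a)^n.
    """
    if n_males < 1:
        raise ValueError("n_males must be >= 1")
    distinct = sorted(set(queen_alleles))
    for a in distinct:
        if a not in locus_freqs:
            raise KeyError(f"allele {a} absent from frequency table")
    total = 0.0
    for size in range(len(distinct) + 1):
        for subset in combinations(distinct, size):
            miss = sum(locus_freqs[a] for a in subset)
            total += (-1.0) ** size * (1.0 - miss) ** n_males
    return float(min(max(total, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Simulation 1: contamination critical value


def run_simulation_1(
    queens: Iterable[QueenRecord],
    freqs: AlleleFrequencies,
    reps: int = 10000,
    seed: int = 0,
    n_males: int = 2,
    bernoulli: bool = True,
) -> MatchSimResult:
    """Expected chance rate of queen-sperm allele matching, per queen.

    For every typed locus the match probability under ``n_males`` random
    mates is computed; ``reps`` Bernoulli trials per locus are summed within
    queens to give the expected number of matching loci, divided by the
    number of typed loci for the rate. ``bernoulli=False`` uses the analytic
    binomial mean instead of Monte Carlo.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    expected_matches: dict[str, float] = {}
    expected_rate: dict[str, float] = {}
    for queen in queens:
        loci = [l for l in queen.typed_loci() if l in freqs]
        if not loci:
            raise ValueError(f"queen {queen.id}: no typed loci with frequencies")
        probs = np.array(
            [
                locus_match_probability(
                    queen.genotype.call(l), freqs[l], n_males=n_males
                )
                for l in loci
            ]
        )
        if bernoulli:
            draws = rng.random((reps, probs.size)) < probs
            matches = float(draws.sum(axis=1).mean())
        else:
            matches = float(probs.sum())
        expected_matches[queen.id] = matches
        expected_rate[queen.id] = matches / len(loci)
    rates = np.array(list(expected_rate.values()))
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return MatchSimResult(expected_matches, expected_rate, mean, sd)


def observed_match_rate(queen: QueenRecord) -> float:
    """Fraction of typed+amplified loci at which all the queen's distinct
    alleles appear in the sperm profile."""
    loci = [
        l
        for l in queen.typed_loci()
        if queen.sperm.amplified.get(l, False)
    ]
    if not loci:
        raise ValueError(f"queen {queen.id}: no amplified loci to compare")
    matches = sum(
        1
        for l in loci
        if queen.genotype.distinct_alleles(l) <= queen.sperm.alleles[l]
    )
    return matches / len(loci)


def flag_contamination(queen: QueenRecord, critical_value: float) -> bool:
    """Flag a sperm sample whose queen-match rate exceeds the critical value."""
    return observed_match_rate(queen) > critical_value


# ---------------------------------------------------------------------------
# minimum mate count


def _male_allele_count(
    queen_alleles: frozenset[int], sperm_alleles: frozenset[int], contaminated: bool
) -> int:
    """Male-attributable alleles at one locus.

    Queen alleles are subtracted only when the sample is flagged as
    contaminated AND the queen's complete genotype at the locus is present
    in the profile; otherwise every shared allele is treated as a true male
    allele (for an unflagged sample, or when a heterozygous queen's other
    allele is absent).
    """
    if contaminated and queen_alleles <= sperm_alleles:
        return len(sperm_alleles - queen_alleles)
    return len(sperm_alleles)


def count_min_males(queen: QueenRecord, contaminated: bool) -> int:
    """Minimum mate number: the largest per-locus male-allele count supported
    at two or more loci (floor of 1 for any non-empty profile)."""
    loci = [l for l in queen.typed_loci() if queen.sperm.amplified.get(l, False)]
    if not loci:
        raise ValueError(f"queen {queen.id}: empty sperm profile")
    counts = [
        _male_allele_count(
            queen.genotype.distinct_alleles(l), queen.sperm.alleles[l], contaminated
        )
        for l in loci
    ]
    best = 1
    for k in range(2, max(counts, default=1) + 1):
        if sum(1 for c in counts if c >= k) >= 2:
            best = k
    return best


# ---------------------------------------------------------------------------
# Simulation 2: miscount calibration


def _simulate_observed_counts(
    queen: QueenRecord,
    freqs: AlleleFrequencies,
    true_count: int,
    reps: int,
    critical_value: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observed mate counts for ``reps`` synthetic sperm samples from
    ``true_count`` random males, run through the identical screen+count.

    Vectorized across replicates; the counting model is error-free (no
    dropout, no mistyping), so observed <= true in every replicate.
    """
    loci = [l for l in queen.typed_loci() if l in freqs]
    n_loci = len(loci)
    # per-locus allele presence of male draws, and of the queen
    match = np.zeros((reps, n_loci), dtype=bool)
    male_counts = np.zeros((reps, n_loci), dtype=np.int64)
    contaminated_counts = np.zeros((reps, n_loci), dtype=np.int64)
    full_genotype_present = np.zeros((reps, n_loci), dtype=bool)
    for j, locus in enumerate(loci):
        p = freqs.vector(locus)
        k = p.size
        labels = freqs.as_locus(locus).alleles
        draws = rng.choice(k, size=(reps, true_count), p=p)
        presence = np.zeros((reps, k), dtype=bool)
        rows = np.repeat(np.arange(reps), true_count)
        presence[rows, draws.ravel()] = True
        q_idx = [labels.index(a) for a in queen.genotype.distinct_alleles(locus)]
        q_present = presence[:, q_idx].all(axis=1)
        match[:, j] = q_present
        n_distinct = presence.sum(axis=1)
        male_counts[:, j] = n_distinct
        full_genotype_present[:, j] = q_present
        n_queen_in = presence[:, q_idx].sum(axis=1)
        contaminated_counts[:, j] = n_distinct - np.where(q_present, n_queen_in, 0)
    rate = match.mean(axis=1)
    flagged = rate > critical_value
    counts = np.where(flagged[:, None] & full_genotype_present, contaminated_counts, male_counts)
    # largest per-locus count supported at >= 2 loci, floor 1
    observed = np.ones(reps, dtype=np.int64)
    for k in range(2, true_count + 1):
        ok = (counts >= k).sum(axis=1) >= 2
        observed = np.where(ok, k, observed)
    return observed


def run_simulation_2(
    queens: Iterable[QueenRecord],
    freqs: AlleleFrequencies,
    critical_value: float,
    true_range: Sequence[int] = range(1, 10),
    reps: int = 10000,
    seed: int = 0,
) -> MiscountMatrix:
    """Probability of observing k mates given t true mates, averaged over
    queens, under the identical flagging and counting procedure."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    queens = list(queens)
    true_counts = sorted(true_range)
    t_max = max(true_counts)
    probs = np.zeros((len(true_counts), t_max + 1))
    rng = np.random.default_rng(seed)
    for i, t in enumerate(true_counts):
        acc = np.zeros(t_max + 1)
        for queen in queens:
            observed = _simulate_observed_counts(
                queen, freqs, t, reps, critical_value, rng
            )
            acc += np.bincount(observed, minlength=t_max + 1) / reps
        probs[i] = acc / len(queens)
    return MiscountMatrix(true_counts, probs, reps)


def max_likely_frequency(
    matrix: MiscountMatrix, observed_max: int, tail: float = 0.05
) -> int:
    """Largest true mate count t with P(observed <= observed_max | t) >= tail.

    This bounds the mating frequencies compatible with the largest observed
    count at the given tail probability.
    """
    if observed_max < 1 or observed_max > max(matrix.true_counts):
        raise ValueError(f"observed_max {observed_max} outside matrix range")
    best = None
    for t in matrix.true_counts:
        if matrix.p_observed_at_most(observed_max, t) >= tail:
            best = t
    if best is None:
        raise ValueError("no true count places mass at or below observed_max")
    return best


# ---------------------------------------------------------------------------
# per-sample summary


@dataclass
class MatingSummary:
    per_queen: dict[str, dict[str, float | bool | int]]
    mean_min_mating_frequency: float
    percent_monandrous: float
    critical_value: float
    max_observed: int

    @property
    def counts(self) -> list[int]:
        return [int(v["min_males"]) for v in self.per_queen.values()]


def summarize_mating(
    queens: Iterable[QueenRecord], sim1: MatchSimResult
) -> MatingSummary:
    """Screen every queen against the Simulation-1 critical value and count
    her minimum mate number."""
    per_queen: dict[str, dict[str, float | bool | int]] = {}
    counts = []
    for queen in queens:
        rate = observed_match_rate(queen)
        flagged = rate > sim1.critical_value
        n = count_min_males(queen, flagged)
        per_queen[queen.id] = {
            "observed_match_rate": rate,
            "contaminated": flagged,
            "min_males": n,
        }
        counts.append(n)
    counts_arr = np.array(counts)
    return MatingSummary(
        per_queen,
        float(counts_arr.mean()),
        float((counts_arr == 1).mean() * 100.0),
        sim1.critical_value,
        int(counts_arr.max()),
    )
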