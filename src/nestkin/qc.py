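"""Locus quality control for microsatellite panels.

Loci are screened per sampling year for departure from Hardy-Weinberg
equilibrium (Monte-Carlo exact test), for null-allele signal (Chakraborty
homozygote-excess estimator) and, pairwise, for genotypic linkage
disequilibrium (permutation test). A locus is dropped from the kinship panel
if it deviates from HWE in every year after Bonferroni correction, if its
null-allele estimate exceeds a threshold, or if it is significantly linked to
a more informative (higher expected heterozygosity) locus.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import DiploidCall

HWE_BOTH_YEARS = "hwe_both_years"
NULL_EXCESS = "null_gt_0.1"
LINKED = "linked_less_informative"


# ---------------------------------------------------------------------------
# Hardy-Weinberg


@dataclass(frozen=True)
class HweResult:
    p_value: float | None
    testable: bool
    reason: str | None = None


def _table_statistic(het_count: int, genotype_counts: np.ndarray) -> float:
    # log of the permutation-variable part of the conditional table probability
    # P(table | allele counts): h*log 2 - sum log n_ij!
    return het_count * np.log(2.0) - float(np.sum(gammaln(genotype_counts + 1.0)))


def hwe_test(
    counts: Mapping[DiploidCall, int], reps: int = 10000, seed: int = 0
) -> HweResult:
    """Monte-Carlo exact test for Hardy-Weinberg proportions at one locus.

    Tables are ranked by their conditional probability given the allele
    counts (probability ordering, two-sided); the p-value is the fraction of
    resampled pairings whose tables are no more probable than the observed
    one, with the observed table included.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    alleles = sorted({a for pair in counts for a in pair})
    if len(alleles) < 2:
        return HweResult(None, False, "monomorphic")
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    pool: list[int] = []
    obs = np.zeros((k, k))
    het_obs = 0
    for (a, b), n in counts.items():
        if n < 0:
            raise ValueError("negative genotype count")
        i, j = sorted((index[a], index[b]))
        obs[i, j] += n
        if i != j:
            het_obs += n
        pool.extend([i] * n + [j] * n)
    stat_obs = _table_statistic(het_obs, obs[np.triu_indices(k)])

    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool, dtype=np.int64)
    n_ind = pool_arr.size // 2
    hits = 0
    flat = np.zeros(k * k)
    for _ in range(reps):
        rng.shuffle(pool_arr)
        a = pool_arr[:n_ind]
        b = pool_arr[n_ind:]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        codes = lo * k + hi
        flat[:] = 0.0
        np.add.at(flat, codes, 1.0)
        het = int(np.sum((lo != hi) * 1))
        stat = _table_statistic(het, flat[flat > 0])
        if stat <= stat_obs + 1e-9:
            hits += 1
    p = (hits + 1) / (reps + 1)
    return HweResult(min(p, 1.0), True)


# ---------------------------------------------------------------------------
# Multiple-test correction (Bonferroni)


def correct_multiple_tests(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[float, list[bool]]:
    """Bonferroni-corrected threshold and per-test significance flags."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if len(p_values) == 0:
        raise ValueError("no p-values supplied")
    corrected = alpha / len(p_values)
    return corrected, [p < corrected for p in p_values]


# ---------------------------------------------------------------------------
# Null alleles


def null_allele_from_heterozygosity(he: float, ho: float) -> float:
    """Chakraborty summary estimator r = (He - Ho) / (He + Ho).

    Negative values (heterozygote excess) are reported, not clamped.
    """
    if he + ho == 0:
        raise ValueError("He + Ho = 0: estimator undefined")
    return (he - ho) / (he + ho)


def heterozygosities(counts: Mapping[DiploidCall, int]) -> tuple[float, float]:
    """(unbiased expected, observed) heterozygosity from genotype counts."""
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no genotypes")
    allele_counts: dict[int, int] = {}
    hom = 0
    for (a, b), c in counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
        if a == b:
            hom += c
    total = 2 * n
    p = np.array(list(allele_counts.values()), dtype=float) / total
    he = (total / (total - 1)) * (1.0 - float(np.sum(p**2)))
    ho = 1.0 - hom / n
    return he, ho


def estimate_null_allele_frequency(counts: Mapping[DiploidCall, int]) -> float:
    alleles = {a for pair in counts for a in pair}
    if len(alleles) < 2:
        raise ValueError("null-allele estimate requires a polymorphic locus")
    he, ho = heterozygosities(counts)
    return null_allele_from_heterozygosity(he, ho)


# ---------------------------------------------------------------------------
# Linkage disequilibrium


@dataclass(frozen=True)
class LdResult:
    p_value: float | None
    statistic: float | None
    testable: bool
    reason: str | None = None


def _contingency_chi2(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    table = pd.crosstab(codes_a, codes_b).to_numpy(dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(chi.sum())


def ld_test(
    genotypes_a: Sequence[DiploidCall],
    genotypes_b: Sequence[DiploidCall],
    reps: int = 10000,
    seed: int = 0,
) -> LdResult:
    """Permutation test for genotypic association between two loci.

    The chi-square statistic of the single-locus-genotype contingency table
    is compared against its null distribution obtained by permuting one
    locus's genotypes across individuals.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    if len(genotypes_a) != len(genotypes_b):
        raise ValueError("genotype vectors differ in length")
    ga = [tuple(sorted(g)) for g in genotypes_a]
    gb = [tuple(sorted(g)) for g in genotypes_b]
    if len(set(ga)) < 2 or len(set(gb)) < 2:
        return LdResult(None, None, False, "monomorphic")
    codes_a = pd.factorize(pd.Series(ga))[0]
    codes_b = pd.factorize(pd.Series(gb))[0]
    stat_obs = _contingency_chi2(codes_a, codes_b)
    rng = np.random.default_rng(seed)
    perm = codes_b.copy()
    hits = 0
    ka = codes_a.max() + 1
    kb = codes_b.max() + 1
    for _ in range(reps):
        rng.shuffle(perm)
        # direct bincount contingency, faster than crosstab in the loop
        table = np.bincount(codes_a * kb + perm, minlength=ka * kb).reshape(
            ka, kb
        ).astype(float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            chi = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
        if chi.sum() >= stat_obs - 1e-9:
            hits += 1
    p = (hits + 1) / (reps + 1)
    return LdResult(min(p, 1.0), stat_obs, True)


# ---------------------------------------------------------------------------
# Mistyping rate from re-genotyped individuals


def mistyping_rate(
    pairs: Mapping[str, Sequence[tuple[DiploidCall, DiploidCall]]],
) -> tuple[dict[str, float | None], float | None]:
    """Per-locus allelic mismatch rate between original and repeat calls.

    Each comparable pair contributes two allele comparisons (the calls are
    matched as multisets); loci with no comparable pairs yield ``None``.
    Returns (per-locus rates, mean across testable loci).
    """
    rates: dict[str, float | None] = {}
    for locus, locus_pairs in pairs.items():
        mismatched = 0
        compared = 0
        for orig, repeat in locus_pairs:
            if orig is None or repeat is None:
                continue
            a = sorted(orig)
            b = sorted(repeat)
            compared += len(a)
            # multiset overlap
            b_left = list(b)
            shared = 0
            for x in a:
                if x in b_left:
                    b_left.remove(x)
                    shared += 1
            mismatched += len(a) - shared
        rates[locus] = None if compared == 0 else mismatched / compared
    usable = [r for r in rates.values() if r is not None]
    mean = float(np.mean(usable)) if usable else None
    return rates, mean


# ---------------------------------------------------------------------------
# Locus selection


@dataclass
class LocusQCReport:
    """Per-locus QC outcomes feeding the exclusion rules.

    ``hwe_significant``: locus -> {year: bool} after correction;
    ``null_estimates``: locus -> Chakraborty estimate;
    ``informativeness``: locus -> unbiased expected heterozygosity;
    ``ld_significant``: set of unordered locus-name pairs significant after
    correction. ``hwe_p``/``ld_p`` keep raw p-values for reporting.
    """

    loci: list[str]
    hwe_significant: dict[str, dict[str, bool]]
    null_estimates: dict[str, float]
    informativeness: dict[str, float]
    ld_significant: set[frozenset[str]]
    hwe_p: dict[str, dict[str, float | None]] = field(default_factory=dict)
    ld_p: dict[frozenset[str], float | None] = field(default_factory=dict)
    null_threshold: float = 0.1
    exclusions: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        years = sorted({y for d in self.hwe_significant.values() for y in d})
        rows = []
        for locus in self.loci:
            row: dict[str, object] = {"locus": locus}
            for y in years:
                row[f"hwe_p_{y}"] = self.hwe_p.get(locus, {}).get(y)
                row[f"hwe_sig_{y}"] = self.hwe_significant.get(locus, {}).get(y)
            row["null_estimate"] = self.null_estimates.get(locus)
            row["expected_het"] = self.informativeness.get(locus)
            row["excluded"] = locus in self.exclusions
            row["reason"] = self.exclusions.get(locus, "")
            rows.append(row)
        return pd.DataFrame(rows)


def select_loci(qc: LocusQCReport) -> list[str]:
    """Apply the three exclusion rules; returns retained loci in input order.

    Linked pairs drop the less informative member (lower expected
    heterozygosity; lexicographically larger name on ties), considering only
    pairs whose members are still retained, processed in sorted pair order so
    the outcome is independent of input order.
    """
    excluded: dict[str, str] = {}
    for locus in qc.loci:
        years = qc.hwe_significant.get(locus, {})
        if years and all(years.values()):
            excluded[locus] = HWE_BOTH_YEARS
    for locus in qc.loci:
        if locus in excluded:
            continue
        if qc.null_estimates.get(locus, 0.0) > qc.null_threshold:
            excluded[locus] = NULL_EXCESS
    for pair in sorted(qc.ld_significant, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        if a in excluded or b in excluded:
            continue
        ha = qc.informativeness.get(a, 0.0)
        hb = qc.informativeness.get(b, 0.0)
        if ha > hb:
            drop = b
        elif hb > ha:
            drop = a
        else:
            drop = max(a, b)  # deterministic tie-break by name
        excluded[drop] = LINKED
    qc.exclusions = excluded
    return [l for l in qc.loci if l not in excluded]
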