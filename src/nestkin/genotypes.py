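"""Genotype containers for codominant microsatellite data.

Individuals are diploid females (workers, queens) or haploid males. A
locus-level call is either a full unordered allele pair (diploid), a single
allele (haploid), or missing as a unit — partial calls are rejected at parse
time.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

Allele = int
DiploidCall = tuple[Allele, Allele]


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker with its observed allele set.

    Allele labels are integer fragment sizes; they must be unique and
    non-empty.
    """

    name: str
    alleles: tuple[Allele, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) == 0:
            raise ValueError(f"locus {self.name!r} has no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name!r} has duplicate allele labels")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def index_of(self, allele: Allele) -> int:
        return self.alleles.index(allele)


@dataclass
class MultilocusGenotype:
    """Per-locus allele calls for one individual.

    ``calls`` maps locus name to an unordered allele pair (diploid), a
    1-tuple (haploid male) or ``None`` (missing). Diploid pairs are stored
    sorted so that equality is order-free.
    """

    id: str
    calls: dict[str, tuple[Allele, ...] | None] = field(default_factory=dict)
    ploidy: str = "diploid"

    def __post_init__(self) -> None:
        if self.ploidy not in ("diploid", "haploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        want = 2 if self.ploidy == "diploid" else 1
        norm: dict[str, tuple[Allele, ...] | None] = {}
        for locus, call in self.calls.items():
            if call is None:
                norm[locus] = None
                continue
            call = tuple(call)
            if len(call) != want:
                raise ValueError(
                    f"{self.id}: locus {locus} call {call} incompatible with "
                    f"{self.ploidy} ploidy"
                )
            norm[locus] = tuple(sorted(call))
        self.calls = norm

    def call(self, locus: str) -> tuple[Allele, ...] | None:
        return self.calls.get(locus)

    def typed_loci(self) -> list[str]:
        return [l for l, c in self.calls.items() if c is not None]

    def distinct_alleles(self, locus: str) -> frozenset[Allele]:
        call = self.calls.get(locus)
        return frozenset() if call is None else frozenset(call)

    def is_heterozygous(self, locus: str) -> bool | None:
        call = self.calls.get(locus)
        if call is None or len(call) != 2:
            return None
        return call[0] != call[1]


class AlleleFrequencies:
    """Per-locus allele frequency tables.

    Frequencies at each locus are strictly positive and sum to one. Loci with
    zero non-missing calls at estimation time are recorded in ``absent`` and
    are not silently reported as zero-frequency.
    """

    def __init__(
        self,
        freqs: Mapping[str, Mapping[Allele, float]],
        absent: Iterable[str] = (),
    ) -> None:
        self._freqs: dict[str, dict[Allele, float]] = {}
        for locus, table in freqs.items():
            total = float(sum(table.values()))
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"locus {locus}: frequencies sum to {total}")
            if any(f <= 0 for f in table.values()):
                raise ValueError(f"locus {locus}: non-positive frequency")
            self._freqs[locus] = dict(table)
        self.absent = frozenset(absent)

    def loci(self) -> list[str]:
        return list(self._freqs)

    def __contains__(self, locus: str) -> bool:
        return locus in self._freqs

    def __getitem__(self, locus: str) -> dict[Allele, float]:
        return self._freqs[locus]

    def frequency(self, locus: str, allele: Allele) -> float:
        table = self._freqs[locus]
        if allele not in table:
            raise KeyError(f"allele {allele} absent from locus {locus}")
        return table[allele]

    def as_locus(self, locus: str) -> Locus:
        return Locus(locus, tuple(self._freqs[locus]))

    def vector(self, locus: str) -> np.ndarray:
        """Frequencies as an array aligned with ``as_locus(locus).alleles``."""
        return np.array(list(self._freqs[locus].values()), dtype=float)


def estimate_allele_frequencies(
    genotypes: Iterable[MultilocusGenotype],
    loci: Iterable[str] | None = None,
) -> AlleleFrequencies:
    """Estimate population allele frequencies by direct allele counting.

    Missing calls are excluded from the denominators. Haploid individuals
    contribute one allele per locus, diploids two.
    """
    genotypes = list(genotypes)
    if loci is None:
        seen: dict[str, None] = {}
        for g in genotypes:
            for l in g.calls:
                seen.setdefault(l)
        loci = list(seen)
    counts: dict[str, dict[Allele, int]] = {l: {} for l in loci}
    for g in genotypes:
        for locus in loci:
            call = g.calls.get(locus)
            if call is None:
                continue
            table = counts[locus]
            for a in call:
                table[a] = table.get(a, 0) + 1
    freqs: dict[str, dict[Allele, float]] = {}
    absent: list[str] = []
    for locus, table in counts.items():
        total = sum(table.values())
        if total == 0:
            absent.append(locus)
            continue
        freqs[locus] = {a: c / total for a, c in sorted(table.items())}
    return AlleleFrequencies(freqs, absent=absent)


def augment_frequencies(
    freqs: AlleleFrequencies,
    genotypes: Iterable[MultilocusGenotype],
    floor_fraction: float = 0.5,
) -> AlleleFrequencies:
    """Extend frequency tables with alleles carried by ``genotypes`` but
    unseen in the estimation sample.

    Each missing allele enters at ``floor_fraction`` times the smallest
    observed frequency at its locus and the table is renormalized. Used when
    reference individuals (queens) carry rare alleles the worker sample
    missed.
    """
    extra: dict[str, set[Allele]] = {}
    for g in genotypes:
        for locus, call in g.calls.items():
            if call is None or locus not in freqs:
                continue
            for a in call:
                if a not in freqs[locus]:
                    extra.setdefault(locus, set()).add(a)
    if not extra:
        return freqs
    tables = {l: dict(freqs[l]) for l in freqs.loci()}
    for locus, alleles in extra.items():
        floor = floor_fraction * min(tables[locus].values())
        for a in alleles:
            tables[locus][a] = floor
        total = sum(tables[locus].values())
        tables[locus] = {a: v / total for a, v in sorted(tables[locus].items())}
    return AlleleFrequencies(tables, absent=freqs.absent)


def genotype_counts(
    genotypes: Iterable[MultilocusGenotype], locus: str
) -> dict[DiploidCall, int]:
    """Unordered diploid genotype counts at one locus (missing excluded)."""
    out: dict[DiploidCall, int] = {}
    for g in genotypes:
        call = g.calls.get(locus)
        if call is None:
            continue
        if len(call) != 2:
            raise ValueError(f"{g.id}: genotype counts require diploid calls")
        key = (call[0], call[1])
        out[key] = out.get(key, 0) + 1
    return out
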