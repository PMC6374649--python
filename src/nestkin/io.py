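"""CSV dialects for genotypes, coordinates, sperm profiles and outputs.

Genotype tables follow a GenAlEx-like layout: one row per individual with
``id``, ``year``, then two columns per locus (``<locus>.1``, ``<locus>.2``)
holding integer allele sizes, with 0 meaning a missing locus call. A cell
may hold a ``;``-separated allele list (as exported from ambiguous peak
calls); individuals showing more than two distinct alleles at any locus are
rejected and logged, since triploidy and sample contamination cannot be
told apart.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .genotypes import MultilocusGenotype
from .mating import SpermProfile

logger = logging.getLogger("nestkin")

MISSING = 0


def _parse_cell(value) -> list[int]:
    if pd.isna(value):
        return []
    if isinstance(value, str):
        parts = [p for p in value.replace(";", " ").split() if p]
        return [int(float(p)) for p in parts]
    return [int(value)]


def read_genotype_table(
    path: str | Path,
) -> tuple[list[MultilocusGenotype], dict[str, int], list[str]]:
    """Read a genotype CSV.

    Returns (genotypes, id -> year, rejected ids). Records with more than
    two distinct alleles at any locus are rejected and logged.
    """
    df = pd.read_csv(path, dtype={"id": str})
    locus_cols = [c for c in df.columns if c.endswith(".1")]
    loci = [c[:-2] for c in locus_cols]
    genotypes: list[MultilocusGenotype] = []
    years: dict[str, int] = {}
    rejected: list[str] = []
    for _, row in df.iterrows():
        ind = str(row["id"])
        calls: dict[str, tuple[int, ...] | None] = {}
        bad = False
        for locus in loci:
            alleles = _parse_cell(row[f"{locus}.1"]) + _parse_cell(row[f"{locus}.2"])
            alleles = [a for a in alleles if a != MISSING]
            distinct = set(alleles)
            if len(distinct) > 2:
                bad = True
                break
            if not alleles:
                calls[locus] = None
            elif len(alleles) == 1:
                calls[locus] = None  # partial call: missing as a unit
            else:
                calls[locus] = (alleles[0], alleles[1])
        if bad:
            logger.warning("rejected %s: >2 alleles at locus %s", ind, locus)
            rejected.append(ind)
            continue
        genotypes.append(MultilocusGenotype(ind, calls))
        years[ind] = int(row["year"]) if "year" in df.columns else 0
    return genotypes, years, rejected


def write_genotype_table(
    genotypes: list[MultilocusGenotype],
    years: dict[str, int],
    path: str | Path,
    loci: list[str] | None = None,
) -> None:
    if loci is None:
        seen: dict[str, None] = {}
        for g in genotypes:
            for l in g.calls:
                seen.setdefault(l)
        loci = list(seen)
    rows = []
    for g in genotypes:
        row: dict[str, object] = {"id": g.id, "year": years.get(g.id, 0)}
        for locus in loci:
            call = g.call(locus)
            if call is None:
                row[f"{locus}.1"] = MISSING
                row[f"{locus}.2"] = MISSING
            else:
                row[f"{locus}.1"] = call[0]
                row[f"{locus}.2"] = call[-1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_coordinates(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path, dtype={"id": str})
    return {str(r["id"]): (float(r["x_m"]), float(r["y_m"])) for _, r in df.iterrows()}


def write_coordinates(
    coords: dict[str, tuple[float, float]], years: dict[str, int], path: str | Path
) -> None:
    rows = [
        {"id": i, "x_m": x, "y_m": y, "year": years.get(i, 0)}
        for i, (x, y) in coords.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sperm_profiles(path: str | Path) -> dict[str, SpermProfile]:
    """Sperm CSV: one row per queen x locus with a ;-separated allele list."""
    df = pd.read_csv(path, dtype={"queen_id": str, "locus": str})
    out: dict[str, SpermProfile] = {}
    for queen_id, grp in df.groupby("queen_id"):
        alleles: dict[str, frozenset[int]] = {}
        amplified: dict[str, bool] = {}
        for _, row in grp.iterrows():
            locus = row["locus"]
            amp = bool(row["amplified"])
            vals = frozenset(_parse_cell(row["alleles"])) if amp else frozenset()
            alleles[locus] = vals
            amplified[locus] = amp and bool(vals)
        out[str(queen_id)] = SpermProfile(alleles, amplified)
    return out


def write_sperm_profiles(profiles: dict[str, SpermProfile], path: str | Path) -> None:
    rows = []
    for queen_id in sorted(profiles):
        profile = profiles[queen_id]
        for locus in sorted(profile.alleles):
            vals = sorted(profile.alleles[locus])
            rows.append(
                {
                    "queen_id": queen_id,
                    "locus": locus,
                    "alleles": ";".join(str(v) for v in vals),
                    "amplified": profile.amplified.get(locus, bool(vals)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth(workers, path: str | Path) -> None:
    """Truth CSV from simulated worker observations, for scoring."""
    rows = [
        {
            "worker_id": w.worker_id,
            "year": w.year,
            "colony_id": w.true_colony,
            "patriline": w.true_patriline,
            "x_m": w.x,
            "y_m": w.y,
        }
        for w in workers
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
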