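"""Nest locations, worker foraging distances and colony-density estimation.

Nest locations are the mean centres of each accepted colony's worker
sampling points; the colony-specific foraging distance is the mean
worker-to-centre Euclidean distance. Total colony numbers (sampled plus
undetected) are estimated with the classic abundance-based coverage
estimator (ACE) over the workers-per-colony abundance vector, and nest
density divides that estimate by the sampling area plus an outward buffer
one mean foraging distance wide.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NestEstimate:
    colony_id: str
    x: float
    y: float
    worker_distances: list[float]
    foraging_distance: float  # mean of worker distances, m
    n_workers: int


@dataclass
class AceResult:
    s_obs: int
    s_rare: int
    s_abund: int
    rare_cutoff: int
    f_counts: dict[int, int]  # i -> number of colonies with i workers (i <= cutoff)
    n_rare: int
    coverage: float  # C_ACE
    gamma_sq: float
    estimate: float
    se: float | None
    ci95: tuple[float, float] | None

    @property
    def completeness(self) -> float:
        if self.estimate == 0:
            return 1.0  # nothing estimated, nothing observed
        return self.s_obs / self.estimate


@dataclass
class DensityEstimate:
    year: int
    estimate: float
    core_area_ha: float
    buffer_area_ha: float
    density: float  # colonies per hectare
    completeness: float


class AceCoverageError(ValueError):
    """All rare colonies are singletons (C_ACE = 0); ACE is undefined.

    Use a Chao1-type estimator instead; this situation is never answered
    silently.
    """


# ---------------------------------------------------------------------------


def mean_centre(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Coordinate-wise arithmetic mean of sampling locations."""
    if len(points) == 0:
        raise ValueError("mean centre of no points")
    arr = np.asarray(points, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def colony_foraging_distances(
    colony_members: Mapping[str, Sequence[str]],
    locations: Mapping[str, tuple[float, float]],
    gps_precision_m: float = 4.0,
) -> tuple[list[NestEstimate], list[str]]:
    """Nest estimates for colonies passing the location-spread rule.

    A colony needs at least two workers separated by more than the GPS
    precision; excluded colonies are returned for logging.
    """
    nests: list[NestEstimate] = []
    excluded: list[str] = []
    for colony_id in sorted(colony_members):
        ids = list(colony_members[colony_id])
        pts = np.array([locations[w] for w in ids], dtype=float)
        if len(ids) < 2:
            excluded.append(colony_id)
            continue
        d_pair = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        if float(d_pair.max()) <= gps_precision_m:
            excluded.append(colony_id)
            continue
        cx, cy = mean_centre([tuple(p) for p in pts])
        dist = np.sqrt((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2)
        nests.append(
            NestEstimate(
                colony_id,
                cx,
                cy,
                [float(d) for d in dist],
                float(dist.mean()),
                len(ids),
            )
        )
    return nests, excluded


def foraging_summary(nests: Sequence[NestEstimate]) -> dict[str, float]:
    """Population summary: mean colony-specific distance, max worker distance."""
    if not nests:
        raise ValueError("no nest estimates")
    colony_means = [n.foraging_distance for n in nests]
    all_workers = [d for n in nests for d in n.worker_distances]
    return {
        "mean_colony_foraging_distance_m": float(np.mean(colony_means)),
        "max_worker_foraging_distance_m": float(np.max(all_workers)),
        "n_colonies": len(nests),
        "n_workers": len(all_workers),
    }


def compare_sister_distances(
    partition_frame: pd.DataFrame,
    locations: Mapping[str, tuple[float, float]],
) -> dict[str, float]:
    """Welch two-sample t-test of full- vs half-sister pairwise distances.

    Full-sister pairs share colony and patriline; half-sister pairs share
    the colony only. Only accepted colonies contribute.
    """
    full: list[float] = []
    half: list[float] = []
    df = partition_frame[partition_frame["accepted"]]
    for _, grp in df.groupby("colony_id"):
        ids = list(grp["worker_id"])
        pat = dict(zip(grp["worker_id"], grp["patriline"]))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                (x1, y1), (x2, y2) = locations[a], locations[b]
                d = math.hypot(x1 - x2, y1 - y2)
                (full if pat[a] == pat[b] else half).append(d)
    if len(full) < 2 or len(half) < 2:
        raise ValueError("need at least two pairs in each sister class")
    res = stats.ttest_ind(full, half, equal_var=False)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "n_full_pairs": len(full),
        "n_half_pairs": len(half),
        "mean_full_m": float(np.mean(full)),
        "mean_half_m": float(np.mean(half)),
    }


# ---------------------------------------------------------------------------
# buffer geometry


def buffer_area(square_side_m: float, r_m: float) -> float:
    """Outward buffer of a square, in hectares.

    Four edge strips plus four quarter-circle corners:
    4*side*r + pi*r^2 (m^2), converted to ha.
    """
    if square_side_m <= 0:
        raise ValueError("square side must be positive")
    if r_m < 0:
        raise ValueError("negative buffer radius")
    return (4.0 * square_side_m * r_m + math.pi * r_m**2) / 1e4


# ---------------------------------------------------------------------------
# ACE


def _ace_point(abundances: np.ndarray, cutoff: int) -> AceResult:
    counts = abundances[abundances > 0]
    s_obs = counts.size
    rare = counts[counts <= cutoff]
    abund = counts[counts > cutoff]
    s_rare = rare.size
    s_abund = abund.size
    f = {i: int((rare == i).sum()) for i in range(1, cutoff + 1)}
    n_rare = int(rare.sum())
    if s_rare == 0:
        return AceResult(
            s_obs, 0, s_abund, cutoff, f, 0, 1.0, 0.0, float(s_obs), None, None
        )
    f1 = f.get(1, 0)
    if n_rare == 0 or f1 == n_rare:
        raise AceCoverageError(
            "all rare colonies are singletons: sample coverage is zero; "
            "use a Chao1-type estimator"
        )
    coverage = 1.0 - f1 / n_rare
    num = sum(i * (i - 1) * f.get(i, 0) for i in range(1, cutoff + 1))
    gamma_sq = max((s_rare / coverage) * num / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    estimate = s_abund + s_rare / coverage + (f1 / coverage) * gamma_sq
    return AceResult(
        s_obs,
        s_rare,
        s_abund,
        cutoff,
        f,
        n_rare,
        coverage,
        gamma_sq,
        float(estimate),
        None,
        None,
    )


def ace_estimate(
    abundances: Sequence[int],
    rare_cutoff: int = 10,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> AceResult:
    """Classic ACE over a workers-per-colony abundance vector.

    S_ACE = S_abund + S_rare/C_ACE + (F1/C_ACE) * gamma^2 with
    C_ACE = 1 - F1/N_rare. The standard error is a seeded bootstrap over
    workers (resampling individuals, re-deriving the abundance vector);
    the 95% CI is estimate +/- 1.96 SE.
    """
    arr = np.asarray(abundances, dtype=np.int64)
    if arr.size == 0 or arr.sum() == 0:
        raise ValueError("no colonies observed")
    if np.any(arr < 0):
        raise ValueError("negative abundance")
    point = _ace_point(arr, rare_cutoff)
    se = None
    ci = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(arr.size), arr)
        n = labels.size
        boots = []
        for _ in range(bootstrap_reps):
            resampled = rng.choice(labels, size=n, replace=True)
            counts = np.bincount(resampled, minlength=arr.size)
            try:
                boots.append(_ace_point(counts, rare_cutoff).estimate)
            except AceCoverageError:
                continue
        if len(boots) >= 2:
            se = float(np.std(boots, ddof=1))
            ci = (point.estimate - 1.96 * se, point.estimate + 1.96 * se)
    return AceResult(
        point.s_obs,
        point.s_rare,
        point.s_abund,
        rare_cutoff,
        point.f_counts,
        point.n_rare,
        point.coverage,
        point.gamma_sq,
        point.estimate,
        se,
        ci,
    )


def nest_density(
    ace: AceResult, core_area_ha: float, buffer_area_ha: float, year: int = 0
) -> DensityEstimate:
    """Colonies per hectare over core + buffer area, with completeness."""
    if core_area_ha <= 0 or buffer_area_ha < 0:
        raise ValueError("areas must be positive")
    total = core_area_ha + buffer_area_ha
    return DensityEstimate(
        year,
        ace.estimate,
        core_area_ha,
        buffer_area_ha,
        ace.estimate / total,
        ace.completeness,
    )
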