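"""Cross-year lineage survival and isolation by distance.

Inferred queen genotypes of the later year are tested as candidate full or
half sisters of each earlier-year colony's workers using the same pairwise
kinship machinery as the sibship stage; a match at posterior >= 0.8 marks a
lineage surviving across years. Pairwise relatedness between inferred queens
uses the Queller-Goodnight estimator (symmetrized, ratio of sums over loci),
and isolation by distance is the OLS regression of pairwise relatedness on
between-nest distance. The pairwise observations are not independent; the
naive F test is reported as the primary result (matching common practice)
with a Mantel permutation test available as a clearly-labelled extra.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import AlleleFrequencies, MultilocusGenotype
from .sibship import InferredQueenGenotype, PairwiseKin, SibshipPriors


@dataclass
class LineageMatch:
    queen_colony: str  # later-year colony whose inferred queen matched
    matched_colony: str  # earlier-year colony
    probability: float


@dataclass
class RelatednessMatrix:
    ids: list[str]
    r: np.ndarray  # symmetric, nan on diagonal and for non-comparable pairs
    distance_m: np.ndarray

    def pairs_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "queen_i": self.ids[i],
                        "queen_j": self.ids[j],
                        "r": self.r[i, j],
                        "distance_m": self.distance_m[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class IbdRegression:
    slope: float
    intercept: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    r_squared: float
    n_pairs: int


# ---------------------------------------------------------------------------
# cross-year matching


def match_queens_across_years(
    inferred_queens: list[InferredQueenGenotype],
    earlier_partition_frame: pd.DataFrame,
    earlier_workers: dict[str, MultilocusGenotype],
    freqs: AlleleFrequencies,
    priors: SibshipPriors | None = None,
    threshold: float = 0.8,
    error_rate: float = 0.0226,
    loci: list[str] | None = None,
) -> tuple[list[LineageMatch], list[str]]:
    """Assign each inferred queen to at most one earlier-year colony.

    The queen's genotype is scored as a candidate sibling of each colony's
    workers (sum of pairwise sib log-odds); the posterior across colonies
    plus a no-match option is a softmax of those scores. Queens with zero
    confident loci are returned unmatched for logging.
    """
    priors = priors or SibshipPriors()
    kin = PairwiseKin(freqs, loci, error_rate)
    colony_of = dict(
        zip(earlier_partition_frame["worker_id"], earlier_partition_frame["colony_id"])
    )
    worker_ids = sorted(colony_of)
    genos = [earlier_workers[w] for w in worker_ids]
    colonies = sorted(set(colony_of.values()))
    members_of = {
        c: [i for i, wid in enumerate(worker_ids) if colony_of[wid] == c]
        for c in colonies
    }
    matches: list[LineageMatch] = []
    unmatched: list[str] = []
    n_prior = len(worker_ids) + 1
    for queen in inferred_queens:
        if not queen.genotype.typed_loci():
            unmatched.append(queen.colony_id)
            continue
        qw = kin.sib_log_odds_row(queen.genotype, genos, priors, n_for_prior=n_prior)
        arr = np.array([qw[members_of[c]].sum() for c in colonies] + [0.0])
        m = arr.max()
        soft = np.exp(arr - m)
        soft /= soft.sum()
        best = int(np.argmax(soft[:-1]))
        prob = float(soft[best])
        if prob >= threshold:
            matches.append(LineageMatch(queen.colony_id, colonies[best], prob))
        else:
            unmatched.append(queen.colony_id)
    return matches, unmatched


def lineage_survival_rate(matches: list[LineageMatch], n_earlier_colonies: int) -> float:
    """Fraction of earlier-year colonies contributing a surviving lineage."""
    if n_earlier_colonies < 1:
        raise ValueError("need at least one earlier-year colony")
    contributed = {m.matched_colony for m in matches}
    return len(contributed) / n_earlier_colonies


# ---------------------------------------------------------------------------
# Queller-Goodnight relatedness


def _qg_directional(
    gx: tuple[int, int], gy: tuple[int, int], p: dict[int, float]
) -> tuple[float, float]:
    """Single-locus (numerator, denominator) with x as the reference."""
    a, b = gx
    c, d = gy
    i_ac, i_ad = float(a == c), float(a == d)
    i_bc, i_bd = float(b == c), float(b == d)
    i_ab = float(a == b)
    num = 0.5 * (i_ac + i_ad + i_bc + i_bd) - p[a] - p[b]
    den = 1.0 + i_ab - p[a] - p[b]
    return num, den


def queller_goodnight(
    g1: MultilocusGenotype,
    g2: MultilocusGenotype,
    freqs: AlleleFrequencies,
) -> float:
    """Symmetrized multilocus Queller-Goodnight relatedness.

    Ratio of sums over shared typed loci, averaged over the two reference
    directions by pooling numerators and denominators. Returns nan when no
    locus is comparable or the pooled denominator vanishes.
    """
    num = 0.0
    den = 0.0
    shared = 0
    for locus in freqs.loci():
        c1, c2 = g1.call(locus), g2.call(locus)
        if c1 is None or c2 is None:
            continue
        table = freqs[locus]
        if any(a not in table for a in c1 + c2):
            continue
        shared += 1
        n1, d1 = _qg_directional(c1, c2, table)
        n2, d2 = _qg_directional(c2, c1, table)
        num += n1 + n2
        den += d1 + d2
    if shared == 0 or den == 0.0:
        return float("nan")
    return num / den


def pairwise_relatedness(
    queens: list[InferredQueenGenotype],
    freqs: AlleleFrequencies,
    positions: dict[str, tuple[float, float]],
) -> RelatednessMatrix:
    """Relatedness and between-nest distance for every queen pair.

    Pairs sharing no confidently-typed locus get nan and are excluded from
    any downstream regression.
    """
    ids = [q.colony_id for q in queens]
    n = len(ids)
    r = np.full((n, n), np.nan)
    d = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            rij = queller_goodnight(queens[i].genotype, queens[j].genotype, freqs)
            r[i, j] = r[j, i] = rij
            (x1, y1) = positions[ids[i]]
            (x2, y2) = positions[ids[j]]
            dij = float(np.hypot(x1 - x2, y1 - y2))
            d[i, j] = d[j, i] = dij
    return RelatednessMatrix(ids, r, d)


# ---------------------------------------------------------------------------
# isolation by distance


def ibd_regression(matrix: RelatednessMatrix, log10_distance: bool = False) -> IbdRegression:
    """OLS of pairwise relatedness on pairwise nest distance (m).

    The F statistic tests the slope with df (1, n_pairs - 2). Distance is
    untransformed by default; ``log10_distance`` applies a display-style
    log10 transform instead.
    """
    df_pairs = matrix.pairs_frame().dropna(subset=["r", "distance_m"])
    if len(df_pairs) < 3:
        raise ValueError("need at least three comparable pairs")
    x = df_pairs["distance_m"].to_numpy(dtype=float)
    if log10_distance:
        if np.any(x <= 0):
            raise ValueError("non-positive distance under log10 transform")
        x = np.log10(x)
    y = df_pairs["r"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero-variance distances")
    n = x.size
    if np.allclose(y, y[0]):
        # constant relatedness: flat line, no explained variance
        return IbdRegression(0.0, float(y[0]), 0.0, (1, n - 2), 1.0, 0.0, n)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        f = float("inf")
    else:
        f = r2 * (n - 2) / (1.0 - r2)
    return IbdRegression(
        float(res.slope),
        float(res.intercept),
        f,
        (1, n - 2),
        float(res.pvalue),
        r2,
        n,
    )


def mantel_test(
    matrix: RelatednessMatrix, reps: int = 999, seed: int = 0
) -> dict[str, float]:
    """Mantel permutation test (optional extra; permutes queen identities).

    Accounts for the non-independence of pairwise observations that the
    primary F test ignores.
    """
    r = matrix.r
    d = matrix.distance_m
    n = r.shape[0]
    iu = np.triu_indices(n, 1)

    def corr(perm: np.ndarray) -> float:
        rp = r[np.ix_(perm, perm)][iu]
        dd = d[iu]
        m = ~np.isnan(rp) & ~np.isnan(dd)
        return float(np.corrcoef(rp[m], dd[m])[0, 1])

    obs = corr(np.arange(n))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        if abs(corr(perm)) >= abs(obs) - 1e-12:
            hits += 1
    return {"r": obs, "p": (hits + 1) / (reps + 1), "reps": reps}
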