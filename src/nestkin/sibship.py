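"""Sibship reconstruction for haplodiploid workers.

Workers are partitioned into colonies (maternal sibships) using pairwise
likelihoods of three relationships — full sisters (same queen, same haploid
father), maternal half-sisters (same queen, independent fathers) and
unrelated — computed by marginalizing over queen genotypes (Hardy-Weinberg
prior) and father alleles (population frequencies), with a symmetric
per-allele mistyping model. Partitioning runs in two stages: greedy
agglomeration on pairwise full-sib log-odds first recovers patrilines
(full sisters carry a strong pairwise signal), then patrilines are merged
into colonies under a joint likelihood in which one unknown queen is
shared by the whole colony and one unknown father by each patriline —
the shared-mother constraint that weak pairwise half-sib odds cannot
resolve — followed by hill-climbing reassignment. Workers whose colony
membership is not supported at the inclusion threshold are left as
singletons. Colonies are only accepted when the minimum number of fathers
consistent with their workers' paternal alleles does not exceed the
maximum plausible mating frequency.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencies, MultilocusGenotype


@dataclass
class SibshipPriors:
    """Expected sampled sibship sizes used as relationship prior odds.

    ``m`` is the mean queen mating frequency, ``n`` the mean number of
    sampled workers per patriline; a sample then holds ``m*n`` maternal
    sisters for every ``n`` paternal sisters. The defaults (n = 2, m = 1.5)
    are the weakly-informative prior used for the initial, prior-free
    assignment pass from which ``n`` is then re-estimated.
    """

    m: float = 1.5
    n: float = 2.0
    weight: float = 0.25

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be >= 1")

    @property
    def maternal_sibship_size(self) -> float:
        return self.m * self.n

    def prior_odds(self, n_workers: int) -> tuple[float, float, float]:
        """(full-sib, half-sib, unrelated) prior for a random same-year pair."""
        denom = max(n_workers - 1, 1)
        p_fs = max(self.n - 1.0, 0.01) / denom
        p_hs = max(self.m * self.n - self.n, 0.01) / denom
        p_fs = min(p_fs, 0.49)
        p_hs = min(p_hs, 0.49)
        return p_fs, p_hs, 1.0 - p_fs - p_hs


# ---------------------------------------------------------------------------
# single-locus relationship likelihood matrices


class LocusKinModel:
    """Per-locus likelihood matrices over observed unordered genotype pairs.

    With error kernel E[obs, true] = (1-e)*I + e*p_obs, the emission of an
    observed unordered pair o = {x, y} given true (maternal, paternal)
    alleles (m, f) is W[o, m, f]. Maternal alleles of two same-queen workers
    follow M2 = 0.5*diag(p) + 0.5*p p^T (same vs different maternal slot of
    the queen). Then

    full sibs      FS[o1,o2] = sum_{m1 m2 f} W[o1,m1,f] W[o2,m2,f] M2 p_f
    half sibs      HS[o1,o2] = sum          W[o1,m1,f] W[o2,m2,g] M2 p_f p_g
    unrelated      U[o1,o2]  = u u^T with u[o] = sum W[o,m,f] p_m p_f
    """

    def __init__(self, freqs_vector: np.ndarray, error_rate: float) -> None:
        p = np.asarray(freqs_vector, dtype=float)
        k = p.size
        self.k = k
        self.p = p
        E = error_rate * np.tile(p[:, None], (1, k))
        E[np.diag_indices(k)] += 1.0 - error_rate
        pairs = [(i, j) for i in range(k) for j in range(i, k)]
        self.pairs = pairs
        self.pair_index = {pair: g for g, pair in enumerate(pairs)}
        n_pairs = len(pairs)
        W = np.zeros((n_pairs, k, k))
        for g, (x, y) in enumerate(pairs):
            if x == y:
                W[g] = np.outer(E[x], E[x])
            else:
                W[g] = np.outer(E[x], E[y]) + np.outer(E[y], E[x])
        M2 = 0.5 * np.diag(p) + 0.5 * np.outer(p, p)
        self.FS = np.einsum("amf,bnf,mn,f->ab", W, W, M2, p, optimize=True)
        # half sibs: independent fathers f, g
        Wf = np.einsum("amf,f->am", W, p)
        self.HS = np.einsum("am,bn,mn->ab", Wf, Wf, M2, optimize=True)
        u = np.einsum("amf,m,f->a", W, p, p)
        self.U = np.outer(u, u)
        self.W = W

    def genotype_index(self, call: tuple[int, int], locus_alleles: tuple[int, ...]) -> int:
        i = locus_alleles.index(call[0])
        j = locus_alleles.index(call[1])
        return self.pair_index[(min(i, j), max(i, j))]


class PairwiseKin:
    """Multilocus pairwise relationship log-likelihoods for a worker set."""

    def __init__(
        self,
        freqs: AlleleFrequencies,
        loci: list[str] | None = None,
        error_rate: float = 0.0226,
    ) -> None:
        self.freqs = freqs
        self.loci = list(loci) if loci is not None else freqs.loci()
        self.error_rate = error_rate
        self.models = {l: LocusKinModel(freqs.vector(l), error_rate) for l in self.loci}

    def _indices(self, genotypes: list[MultilocusGenotype], locus: str) -> np.ndarray:
        model = self.models[locus]
        alleles = self.freqs.as_locus(locus).alleles
        idx = np.full(len(genotypes), -1, dtype=np.int64)
        for i, g in enumerate(genotypes):
            call = g.call(locus)
            if call is None:
                continue
            if any(a not in alleles for a in call):
                continue  # allele unseen in the frequency table: uninformative
            idx[i] = model.genotype_index(call, alleles)
        return idx

    def log_likelihoods(
        self, genotypes: list[MultilocusGenotype]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(logFS, logHS, logU), each n x n, summed over shared typed loci."""
        n = len(genotypes)
        logFS = np.zeros((n, n))
        logHS = np.zeros((n, n))
        logU = np.zeros((n, n))
        with np.errstate(divide="ignore"):
            for locus in self.loci:
                model = self.models[locus]
                idx = self._indices(genotypes, locus)
                typed = np.where(idx >= 0)[0]
                if typed.size < 2:
                    continue
                sub = idx[typed]
                sel = np.ix_(typed, typed)
                logFS[sel] += np.log(model.FS)[sub[:, None], sub[None, :]]
                logHS[sel] += np.log(model.HS)[sub[:, None], sub[None, :]]
                logU[sel] += np.log(model.U)[sub[:, None], sub[None, :]]
        return logFS, logHS, logU

    def sib_log_odds(
        self,
        genotypes: list[MultilocusGenotype],
        priors: SibshipPriors,
        n_for_prior: int | None = None,
    ) -> np.ndarray:
        """log [pi_FS L_FS + pi_HS L_HS] - log [pi_U L_U] per pair."""
        n = len(genotypes)
        logFS, logHS, logU = self.log_likelihoods(genotypes)
        p_fs, p_hs, p_u = priors.prior_odds(n_for_prior or n)
        sib = np.logaddexp(log(p_fs) + logFS, log(p_hs) + logHS)
        w = sib - (log(p_u) + logU)
        np.fill_diagonal(w, 0.0)
        return w

    def sib_log_odds_row(
        self,
        query: MultilocusGenotype,
        genotypes: list[MultilocusGenotype],
        priors: SibshipPriors,
        n_for_prior: int | None = None,
    ) -> np.ndarray:
        """Sib-vs-unrelated log odds of one query against each genotype."""
        n = len(genotypes)
        logFS = np.zeros(n)
        logHS = np.zeros(n)
        logU = np.zeros(n)
        with np.errstate(divide="ignore"):
            for locus in self.loci:
                model = self.models[locus]
                qi = self._indices([query], locus)[0]
                if qi < 0:
                    continue
                idx = self._indices(genotypes, locus)
                typed = idx >= 0
                logFS[typed] += np.log(model.FS)[qi, idx[typed]]
                logHS[typed] += np.log(model.HS)[qi, idx[typed]]
                logU[typed] += np.log(model.U)[qi, idx[typed]]
        p_fs, p_hs, p_u = priors.prior_odds(n_for_prior or (n + 1))
        sib = np.logaddexp(log(p_fs) + logFS, log(p_hs) + logHS)
        return sib - (log(p_u) + logU)

    def pair_relationship_likelihoods(
        self, g1: MultilocusGenotype, g2: MultilocusGenotype
    ) -> dict[str, float]:
        """Likelihoods (not log) for one pair: full-sib, half-sib, unrelated."""
        shared = [
            l
            for l in self.loci
            if g1.call(l) is not None and g2.call(l) is not None
        ]
        if not shared:
            raise ValueError("pair shares no typed loci")
        logFS, logHS, logU = self.log_likelihoods([g1, g2])
        return {
            "full_sib": float(np.exp(logFS[0, 1])),
            "half_sib": float(np.exp(logHS[0, 1])),
            "unrelated": float(np.exp(logU[0, 1])),
        }


def pairwise_relationship_likelihoods(
    g1: MultilocusGenotype,
    g2: MultilocusGenotype,
    freqs: AlleleFrequencies,
    error_rate: float = 0.0,
) -> dict[str, float]:
    """Convenience wrapper for a single pair of diploid genotypes."""
    loci = [l for l in freqs.loci() if l in g1.calls or l in g2.calls]
    return PairwiseKin(freqs, loci, error_rate).pair_relationship_likelihoods(g1, g2)


# ---------------------------------------------------------------------------
# partitioning


@dataclass
class ColonyPartition:
    """Worker-to-colony assignment with inclusion probabilities."""

    frame: pd.DataFrame  # worker_id, year, colony_id, inclusion, patriline, accepted
    colony_info: pd.DataFrame  # colony_id, year, size, patriline_count, accepted

    def colonies(self, year: int | None = None) -> list[str]:
        df = self.colony_info
        if year is not None:
            df = df[df["year"] == year]
        return list(df["colony_id"])

    def members(self, colony_id: str) -> list[str]:
        df = self.frame
        return list(df.loc[df["colony_id"] == colony_id, "worker_id"])

    def accepted_colonies(self, year: int | None = None) -> list[str]:
        df = self.colony_info
        if year is not None:
            df = df[df["year"] == year]
        return list(df.loc[df["accepted"], "colony_id"])

    def patriline_sizes(self) -> list[int]:
        df = self.frame
        return list(df.groupby(["colony_id", "patriline"]).size())


def _greedy_merge(w: np.ndarray) -> list[int]:
    """Agglomerative clustering maximizing the sum of within-cluster weights."""
    n = w.shape[0]
    S = w.copy()
    np.fill_diagonal(S, -np.inf)
    labels = np.arange(n)
    active = np.ones(n, dtype=bool)
    while active.sum() > 1:
        masked = np.where(active[:, None] & active[None, :], S, -np.inf)
        flat = np.argmax(masked)
        a, b = divmod(flat, n)
        if masked[a, b] <= 0:
            break
        a, b = min(a, b), max(a, b)
        labels[labels == b] = a
        S[a, :] += S[b, :]
        S[:, a] += S[:, b]
        S[a, a] = -np.inf
        active[b] = False
        S[b, :] = -np.inf
        S[:, b] = -np.inf
    return list(labels)


def _lse(v: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(v, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        return np.squeeze(m, axis) + np.log(np.sum(np.exp(v - m), axis=axis))


class PatrilineColonyModel:
    """Joint likelihood of colonies built from full-sib groups (patrilines).

    Per locus, the likelihood of a colony made of patrilines P_1..P_k
    sharing one unknown queen q is

        sum_q HW(q) prod_j [ sum_f p_f prod_{w in P_j} P(o_w | q, f) ]

    with P(o | q, f) = 0.5 (W[o, q1, f] + W[o, q2, f]): each worker picks
    one maternal allele of the queen, workers of a patriline share the
    father f, distinct patrilines have independent fathers. Scores are
    log-ratios against the unrelated baseline prod_w P(o_w), so an empty
    colony and a singleton worker both score exactly zero.
    """

    def __init__(
        self,
        kin: PairwiseKin,
        genotypes: list[MultilocusGenotype],
        patriline_labels: np.ndarray,
    ) -> None:
        self.n = len(genotypes)
        pat_ids = list(np.unique(patriline_labels))
        self.pat_ids = pat_ids
        self.pat_members = [np.where(patriline_labels == c)[0] for c in pat_ids]
        self.pat_of_worker = np.array(
            [pat_ids.index(c) for c in patriline_labels]
        )
        self.n_pat = len(pat_ids)
        self.loghw: list[np.ndarray] = []  # per locus (G,)
        # per locus: logw[(G, K, n)] = log P(o_i | q, f) - log P(o_i)/|...|
        self.logw: list[np.ndarray] = []
        self.logpf: list[np.ndarray] = []  # per locus log p (father prior)
        with np.errstate(divide="ignore"):
            for locus in kin.loci:
                model = kin.models[locus]
                idx = kin._indices(genotypes, locus)
                p = model.p
                k = model.k
                G = len(model.pairs)
                q1 = np.array([a for a, _ in model.pairs])
                q2 = np.array([b for _, b in model.pairs])
                hw = p[q1] * p[q2] * np.where(q1 != q2, 2.0, 1.0)
                self.loghw.append(np.log(hw))
                self.logpf.append(np.log(p))
                # conditional per observed genotype class: (G, K, n_classes)
                cond = 0.5 * (model.W[:, q1, :] + model.W[:, q2, :])  # (O, G, K)
                u = np.einsum("omf,m,f->o", model.W, p, p)
                logw = np.full((G, k, self.n), 0.0)
                typed = idx >= 0
                if typed.any():
                    vals = np.log(cond[idx[typed]]) - np.log(u[idx[typed]])[
                        :, None, None
                    ]  # (nt, G, K)
                    # floor impossible configurations so that incremental
                    # additions/subtractions of cluster sums stay finite
                    vals = np.maximum(vals, -400.0)
                    logw[:, :, typed] = np.moveaxis(vals, 0, 2)
                self.logw.append(logw)

    def patriline_vector(self, locus_i: int, members: np.ndarray) -> np.ndarray:
        """log sum_f p_f prod_{w in members} P(o_w|q,f)/P(o_w)^(1/..), (G,)."""
        s = self.logw[locus_i][:, :, members].sum(axis=2)  # (G, K)
        return _lse(self.logpf[locus_i][None, :] + s)

    def patriline_matrix(self, locus_i: int) -> np.ndarray:
        """(n_pat, G) matrix of patriline vectors at one locus."""
        return np.stack(
            [self.patriline_vector(locus_i, m) for m in self.pat_members]
        )

    def score_from_sums(self, sums: list[np.ndarray]) -> float:
        """Colony log-score from per-locus sums of patriline vectors."""
        return float(sum(_lse(lh + s) for lh, s in zip(self.loghw, sums)))


def _merge_colonies(
    model: PatrilineColonyModel, lam: float
) -> np.ndarray:
    """Agglomerate patrilines into colonies while the joint-likelihood gain
    plus the prior log-odds ``lam`` of a merge stays positive.

    Returns colony label per patriline.
    """
    P = model.n_pat
    mats = [model.patriline_matrix(l) for l in range(len(model.loghw))]
    sums = [[mats[l][j] for l in range(len(mats))] for j in range(P)]
    score = np.array([model.score_from_sums(s) for s in sums])
    joint = np.zeros((P, P))
    for a in range(P):  # row-wise to bound memory
        for l, lh in enumerate(model.loghw):
            joint[a] += _lse(lh[None, :] + mats[l][a][None, :] + mats[l])
    gain = joint - score[:, None] - score[None, :] + lam
    np.fill_diagonal(gain, -np.inf)
    labels = np.arange(P)
    active = np.ones(P, dtype=bool)
    while active.sum() > 1:
        masked = np.where(active[:, None] & active[None, :], gain, -np.inf)
        flat = int(np.argmax(masked))
        a, b = divmod(flat, P)
        if masked[a, b] <= 0:
            break
        a, b = min(a, b), max(a, b)
        labels[labels == b] = a
        sums[a] = [sa + sb for sa, sb in zip(sums[a], sums[b])]
        score[a] = model.score_from_sums(sums[a])
        active[b] = False
        gain[b, :] = -np.inf
        gain[:, b] = -np.inf
        row = np.zeros(P)
        for l, lh in enumerate(model.loghw):
            S = np.stack([s[l] for s in sums])
            row += _lse(lh[None, :] + sums[a][l][None, :] + S)
        new_gain = row - score[a] - score + lam
        new_gain[~active] = -np.inf
        new_gain[a] = -np.inf
        gain[a, :] = new_gain
        gain[:, a] = new_gain
    return labels


def _colony_sums(
    model: PatrilineColonyModel, colony_of_pat: np.ndarray, mats: list[np.ndarray]
) -> tuple[list[int], list[list[np.ndarray]], np.ndarray]:
    """Per-colony per-locus sums of patriline vectors and colony scores."""
    colony_ids = sorted(set(int(c) for c in colony_of_pat))
    sums = []
    for c in colony_ids:
        pats = np.where(colony_of_pat == c)[0]
        sums.append([m[pats].sum(axis=0) for m in mats])
    scores = np.array([model.score_from_sums(s) for s in sums])
    return colony_ids, sums, scores


def _patriline_moves(
    model: PatrilineColonyModel,
    colony_of_pat: np.ndarray,
    lam: float,
    max_sweeps: int = 3,
) -> np.ndarray:
    """Hill-climbing reassignment of whole patrilines between colonies.

    A patriline's placement value is its colony's joint-score gain from
    holding it (plus the attachment prior ``lam``), or its lone-colony
    score when isolated; each sweep moves every patriline to its
    best-value placement. Colony sums are updated incrementally.
    """
    L = len(model.loghw)
    mats = [model.patriline_matrix(l) for l in range(L)]  # per locus (P, G)
    colony_of_pat = colony_of_pat.copy()
    # relabel colonies to dense indices; allow one spare slot per patriline
    uniq = sorted(set(int(c) for c in colony_of_pat))
    remap = {c: k for k, c in enumerate(uniq)}
    col = np.array([remap[int(c)] for c in colony_of_pat])
    n_slots = len(uniq) + model.n_pat
    S = [np.zeros((n_slots, lh.size)) for lh in model.loghw]
    for l in range(L):
        np.add.at(S[l], col, mats[l])
    occupied = np.bincount(col, minlength=n_slots)

    def colony_score(k: int) -> float:
        return float(sum(_lse(lh + S[l][k]) for l, lh in enumerate(model.loghw)))

    scores = np.array([colony_score(k) for k in range(n_slots)])
    next_free = len(uniq)
    alone_values = np.array(
        [
            float(sum(_lse(lh + m[j]) for lh, m in zip(model.loghw, mats)))
            for j in range(model.n_pat)
        ]
    )
    for _ in range(max_sweeps):
        changed = False
        for j in range(model.n_pat):
            k0 = int(col[j])
            Vj = [m[j] for m in mats]
            if occupied[k0] == 1:
                stay = alone_values[j]
                base0 = 0.0
            else:
                base0 = float(
                    sum(
                        _lse(lh + S[l][k0] - Vj[l])
                        for l, lh in enumerate(model.loghw)
                    )
                )
                stay = scores[k0] - base0 + lam
            # join gains against every occupied colony at once
            join = np.full(n_slots, -np.inf)
            active = (occupied > 0) & (np.arange(n_slots) != k0)
            if active.any():
                acc = np.full(int(active.sum()), lam)
                rows = np.where(active)[0]
                for l, lh in enumerate(model.loghw):
                    acc += _lse(lh[None, :] + S[l][rows] + Vj[l][None, :])
                join[rows] = acc - scores[rows]
            best_k = int(np.argmax(join))
            best_gain = join[best_k]
            target = k0
            if best_gain > stay + 1e-9:
                target = best_k
            if (
                occupied[k0] > 1
                and alone_values[j] > max(best_gain, stay) + 1e-9
            ):
                target = next_free
            if target != k0:
                for l in range(L):
                    S[l][k0] -= Vj[l]
                    S[l][target] += Vj[l]
                occupied[k0] -= 1
                occupied[target] += 1
                col[j] = target
                scores[k0] = colony_score(k0) if occupied[k0] else 0.0
                scores[target] = colony_score(target)
                if target == next_free:
                    next_free += 1
                changed = True
        if not changed:
            break
    return col


def _worker_inclusion(
    model: PatrilineColonyModel, colony_of_pat: np.ndarray, lam: float
) -> np.ndarray:
    """Softmax posterior support for each worker's colony membership.

    The own-colony score is exact (worker detached from its patriline);
    alternative colonies are scored with the worker attached as a fresh
    singleton patriline, the dominant attachment route once full-sib groups
    have been resolved. The singleton option always scores zero.
    """
    L = len(model.loghw)
    mats = [model.patriline_matrix(l) for l in range(L)]
    colony_ids, sums, scores = _colony_sums(model, colony_of_pat, mats)
    index_of = {c: k for k, c in enumerate(colony_ids)}
    S = [np.stack([s[l] for s in sums]) for l in range(L)]  # per locus (C, G)
    # per-worker singleton vectors (G, n) per locus
    sv = [
        _lse(lpf[None, :, None] + lw, axis=1)
        for lpf, lw in zip(model.logpf, model.logw)
    ]
    out = np.ones(model.n)
    C = len(colony_ids)
    for i in range(model.n):
        j = model.pat_of_worker[i]
        c0 = int(colony_of_pat[j])
        k0 = index_of[c0]
        # joining each colony as a fresh patriline
        join = np.full(C, lam)
        for l in range(L):
            join += _lse(model.loghw[l][None, :] + S[l] + sv[l][:, i][None, :])
        join -= scores
        # exact own-colony score: detach i from its patriline first
        members = model.pat_members[j]
        others = members[members != i]
        own_alone = others.size == 0 and (colony_of_pat == c0).sum() == 1
        if own_alone:
            own_score = 0.0
        else:
            base = []
            for l in range(L):
                v_old = mats[l][j]
                v_new = (
                    model.patriline_vector(l, others)
                    if others.size
                    else np.zeros_like(v_old)
                )
                base.append(sums[k0][l] - v_old + v_new)
            own_score = scores[k0] - model.score_from_sums(base) + lam
        join[k0] = own_score
        options = np.append(join, 0.0)  # singleton option
        if own_alone:
            # the own-colony entry IS the singleton option: do not count twice
            options = np.delete(options, k0)
            own_idx = len(options) - 1
        else:
            own_idx = k0 if k0 < len(options) - 1 else k0
        m = options.max()
        out[i] = float(np.exp(options[own_idx] - m) / np.exp(options - m).sum())
    return out


def reconstruct_colonies(
    workers: list[MultilocusGenotype],
    freqs: AlleleFrequencies,
    priors: SibshipPriors | None = None,
    min_inclusion: float = 0.8,
    error_rate: float = 0.0226,
    seed: int = 0,
    year: int = 0,
    loci: list[str] | None = None,
    max_patrilines: int = 5,
    queen_confidence: float = 0.8,
) -> ColonyPartition:
    """Partition same-year workers into colonies.

    Two stages: (1) greedy agglomeration on pairwise full-sib log-odds,
    recovering patrilines (full sisters carry a strong pairwise signal);
    (2) agglomeration of those groups under the joint queen-marginal colony
    likelihood, which detects maternal half-sib groups that pairwise scores
    cannot, followed by hill-climbing single-worker reassignment. Workers
    below ``min_inclusion`` posterior support for their colony are demoted
    to singletons. Per colony the queen genotype is inferred, worker
    patrilines are labelled, and the colony is accepted when it has at
    least two workers and at most ``max_patrilines`` patrilines.
    """
    if not workers:
        raise ValueError("no workers to assign")
    priors = priors or SibshipPriors()
    order = np.argsort([g.id for g in workers])
    workers = [workers[i] for i in order]
    kin = PairwiseKin(freqs, loci, error_rate)
    n = len(workers)
    p_fs, p_hs, p_u = priors.prior_odds(n)
    logFS, _, logU = kin.log_likelihoods(workers)
    w_fs = (log(p_fs) + logFS) - (log(p_u) + logU)
    np.fill_diagonal(w_fs, 0.0)
    pat_labels = np.asarray(_greedy_merge(w_fs))
    p_mat = min(p_fs + p_hs, 0.98)
    lam = log(p_mat) - log(1.0 - p_mat)

    model = PatrilineColonyModel(kin, workers, pat_labels)
    colony_of_pat = _merge_colonies(model, lam)
    colony_of_pat = _patriline_moves(model, colony_of_pat, lam)
    labels = colony_of_pat[model.pat_of_worker]
    inclusion = _worker_inclusion(model, colony_of_pat, lam)
    # demote unsupported singleton-patriline workers to their own colony
    # (workers inside multi-member full-sib groups stay with their group)
    demote = (
        (inclusion < min_inclusion)
        & np.array([np.sum(labels == l) > 1 for l in labels])
        & np.array(
            [model.pat_members[model.pat_of_worker[i]].size == 1 for i in range(n)]
        )
    )
    if demote.any():
        colony_of_pat = colony_of_pat.copy()
        max_col = int(colony_of_pat.max()) + 1
        for i in np.where(demote)[0]:
            colony_of_pat[model.pat_of_worker[i]] = max_col
            max_col += 1
        labels = colony_of_pat[model.pat_of_worker]
        inclusion = _worker_inclusion(model, colony_of_pat, lam)

    # name colonies deterministically by their first worker id
    fs_group = {
        workers[i].id: int(model.pat_of_worker[i]) for i in range(n)
    }
    rows = []
    colony_rows = []
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        member_ids = [workers[i].id for i in members]
        colony_id = f"{year}_col_{min(member_ids)}"
        colony_workers = [workers[i] for i in members]
        queen = infer_queen_genotype(
            colony_workers, freqs, error_rate, colony_id=colony_id,
            min_confidence=queen_confidence, kin=kin, patrilines=fs_group,
        )
        patrilines, flagged = assign_patrilines(colony_workers, queen, kin.loci)
        n_pat = len(set(patrilines.values()))
        accepted = len(members) >= 2 and n_pat <= max_patrilines and not flagged
        colony_rows.append(
            {
                "colony_id": colony_id,
                "year": year,
                "size": len(members),
                "patriline_count": n_pat,
                "accepted": accepted,
            }
        )
        for i in members:
            rows.append(
                {
                    "worker_id": workers[i].id,
                    "year": year,
                    "colony_id": colony_id,
                    "inclusion": float(inclusion[i]),
                    "patriline": patrilines[workers[i].id],
                    "accepted": accepted,
                }
            )
    frame = pd.DataFrame(rows).sort_values("worker_id").reset_index(drop=True)
    info = pd.DataFrame(colony_rows).sort_values("colony_id").reset_index(drop=True)
    return ColonyPartition(frame, info)


# ---------------------------------------------------------------------------
# queen genotype inference


@dataclass
class InferredQueenGenotype:
    colony_id: str
    genotype: MultilocusGenotype  # confident loci only; others missing
    confidence: dict[str, float]  # per-locus max posterior (0 when filtered)


def infer_queen_genotype(
    colony_workers: list[MultilocusGenotype],
    freqs: AlleleFrequencies,
    error_rate: float = 0.0226,
    colony_id: str = "",
    min_confidence: float = 0.8,
    loci: list[str] | None = None,
    kin: PairwiseKin | None = None,
    patrilines: Mapping[str, int] | None = None,
) -> InferredQueenGenotype:
    """Posterior over the colony queen's genotype per locus.

    For a candidate queen genotype q, workers within a full-sib group
    (``patrilines``, worker id -> group label) share one father allele
    marginalized at population frequencies; groups are independent given
    q. Without grouping every worker is its own group, which is
    conservative: a shared father is then indistinguishable from the
    queen, leaving the posterior split. The maximum-posterior genotype is
    retained only where its posterior reaches ``min_confidence``.
    """
    if not colony_workers:
        raise ValueError("colony has no workers")
    if kin is None:
        kin = PairwiseKin(freqs, loci, error_rate)
    loci = kin.loci
    if patrilines is None:
        patrilines = {g.id: i for i, g in enumerate(colony_workers)}
    calls: dict[str, tuple[int, ...] | None] = {}
    confidence: dict[str, float] = {}
    for locus in loci:
        model = kin.models[locus]
        alleles = freqs.as_locus(locus).alleles
        p = model.p
        groups: dict[int, list[int]] = {}
        for g in colony_workers:
            call = g.call(locus)
            if call is None or any(a not in alleles for a in call):
                continue
            groups.setdefault(patrilines[g.id], []).append(
                model.genotype_index(call, alleles)
            )
        if not groups:
            calls[locus] = None
            confidence[locus] = 0.0
            continue
        log_post = np.full(len(model.pairs), -np.inf)
        with np.errstate(divide="ignore"):
            for gi, (q1, q2) in enumerate(model.pairs):
                hw = p[q1] * p[q2] * (2.0 if q1 != q2 else 1.0)
                cond = 0.5 * (model.W[:, q1, :] + model.W[:, q2, :])  # (O, K)
                total = np.log(hw)
                for members in groups.values():
                    # shared father within the group, prior p
                    lik = float(np.prod(cond[members, :], axis=0) @ p)
                    if lik <= 0:
                        total = -np.inf
                        break
                    total += np.log(lik)
                log_post[gi] = total
        m = log_post.max()
        if not np.isfinite(m):
            calls[locus] = None
            confidence[locus] = 0.0
            continue
        post = np.exp(log_post - m)
        post /= post.sum()
        best = int(np.argmax(post))
        conf = float(post[best])
        if conf >= min_confidence:
            q1, q2 = model.pairs[best]
            calls[locus] = (alleles[q1], alleles[q2])
            confidence[locus] = conf
        else:
            calls[locus] = None
            confidence[locus] = 0.0
    genotype = MultilocusGenotype(colony_id + "_queen", calls, ploidy="diploid")
    return InferredQueenGenotype(colony_id, genotype, confidence)


# ---------------------------------------------------------------------------
# patrilines


def assign_patrilines(
    colony_workers: list[MultilocusGenotype],
    queen: InferredQueenGenotype,
    loci: list[str],
) -> tuple[dict[str, int], bool]:
    """Greedy grouping of workers by compatible paternal alleles.

    Per worker and locus the candidate paternal alleles are those
    reconcilable with the inferred queen genotype (alleles not carried by
    the queen are paternal; alleles shared with the queen remain ambiguous).
    Workers are processed in id order and joined to the first existing
    patriline whose running per-locus candidate sets all intersect theirs.
    Returns (worker -> patriline label, flagged) where ``flagged`` marks a
    worker irreconcilable with the queen at every confidently-typed locus.
    """
    candidates: dict[str, dict[str, set[int]]] = {}
    flagged = False
    for g in sorted(colony_workers, key=lambda x: x.id):
        per_locus: dict[str, set[int]] = {}
        comparable = 0
        for locus in loci:
            call = g.call(locus)
            q_call = queen.genotype.call(locus)
            if call is None or q_call is None:
                continue
            comparable += 1
            qa = set(q_call)
            a, b = call
            cands: set[int] = set()
            if a in qa:
                cands.add(b)
            if b in qa:
                cands.add(a)
            if not cands:
                continue  # mistyping or queen error at this locus: skip
            per_locus[locus] = cands
        if comparable > 0 and not per_locus:
            flagged = True
        candidates[g.id] = per_locus

    typed_any = any(candidates[w] for w in candidates)
    if not typed_any and len(colony_workers) > 0:
        # no resolvable paternal candidates: one patriline by convention,
        # but keep any irreconcilability flag raised above
        return {g.id: 0 for g in colony_workers}, flagged

    patrilines: list[dict[str, set[int]]] = []
    assignment: dict[str, int] = {}
    for wid in sorted(candidates):
        placed = False
        for label, profile in enumerate(patrilines):
            ok = True
            for locus, cands in candidates[wid].items():
                if locus in profile and not (profile[locus] & cands):
                    ok = False
                    break
            if ok:
                for locus, cands in candidates[wid].items():
                    if locus in profile:
                        profile[locus] &= cands
                    else:
                        profile[locus] = set(cands)
                assignment[wid] = label
                placed = True
                break
        if not placed:
            patrilines.append({l: set(c) for l, c in candidates[wid].items()})
            assignment[wid] = len(patrilines) - 1
    return assignment, flagged


def count_patrilines(
    colony_workers: list[MultilocusGenotype],
    queen: InferredQueenGenotype,
    loci: list[str] | None = None,
) -> int:
    """Minimum number of haploid fathers consistent with the workers."""
    loci = loci or [l for l, c in queen.genotype.calls.items()]
    assignment, flagged = assign_patrilines(colony_workers, queen, loci)
    if flagged:
        raise ValueError("colony has workers irreconcilable with the queen")
    return len(set(assignment.values()))


# ---------------------------------------------------------------------------
# priors from a partition


def estimate_sibship_priors(partition: ColonyPartition, m: float) -> SibshipPriors:
    """n = mean sampled patriline size from a (prior-free) partition."""
    sizes = partition.patriline_sizes()
    if not sizes:
        raise ValueError("empty partition")
    n = float(np.mean(sizes))
    return SibshipPriors(m=m, n=max(n, 1.0))
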