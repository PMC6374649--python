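from itertools import product

import numpy as np
import pandas as pd
import pytest

from nestkin.genotypes import AlleleFrequencies, MultilocusGenotype
from nestkin.sibship import (
    ColonyPartition,
    InferredQueenGenotype,
    SibshipPriors,
    assign_patrilines,
    count_patrilines,
    estimate_sibship_priors,
    infer_queen_genotype,
    pairwise_relationship_likelihoods,
    reconstruct_colonies,
)


def brute_force_likelihoods(call1, call2, freqs_table, error):
    """Exhaustive enumeration over queen genotypes, fathers and maternal
    picks for one locus; symmetric per-allele error kernel."""
    alleles = sorted(freqs_table)
    p = {a: freqs_table[a] for a in alleles}

    def emis(obs, true):
        return (1 - error) * (obs == true) + error * p[obs]

    def obs_pair(obs, m, f):
        x, y = obs
        if x == y:
            return emis(x, m) * emis(x, f)
        return emis(x, m) * emis(y, f) + emis(y, m) * emis(x, f)

    fs = hs = 0.0
    for q1, q2 in product(alleles, repeat=2):
        pq = p[q1] * p[q2]
        for ma, mb in product((q1, q2), repeat=2):
            for f1 in alleles:
                for f2 in alleles:
                    w = pq * 0.25 * p[f1] * p[f2]
                    term = obs_pair(call1, ma, f1) * obs_pair(call2, mb, f2)
                    hs += w * term
                    if f1 == f2:
                        fs += w / p[f2] * term
    u1 = sum(
        p[m] * p[f] * obs_pair(call1, m, f) for m in alleles for f in alleles
    )
    u2 = sum(
        p[m] * p[f] * obs_pair(call2, m, f) for m in alleles for f in alleles
    )
    return {"full_sib": fs, "half_sib": hs, "unrelated": u1 * u2}


class TestPairwiseLikelihoods:
    def test_disjoint_pair_excludes_full_sibship(self):
        # full sisters must share the paternal allele; a fully disjoint pair
        # cannot. A heterozygous queen can still mother both via different
        # maternal alleles, so the half-sib likelihood stays positive.
        freqs = AlleleFrequencies({"L1": {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}})
        g1 = MultilocusGenotype("w1", {"L1": (1, 2)})
        g2 = MultilocusGenotype("w2", {"L1": (3, 4)})
        lik = pairwise_relationship_likelihoods(g1, g2, freqs, error_rate=0.0)
        assert lik["full_sib"] == 0.0
        assert lik["half_sib"] > 0.0
        assert lik["unrelated"] > 0.0

    def test_monomorphic_locus_uninformative(self):
        freqs = AlleleFrequencies({"L1": {1: 1.0}})
        g1 = MultilocusGenotype("w1", {"L1": (1, 1)})
        g2 = MultilocusGenotype("w2", {"L1": (1, 1)})
        lik = pairwise_relationship_likelihoods(g1, g2, freqs, error_rate=0.0)
        assert lik["full_sib"] == pytest.approx(lik["half_sib"])
        assert lik["full_sib"] == pytest.approx(lik["unrelated"])

    @pytest.mark.parametrize("error", [0.0, 0.05])
    @pytest.mark.parametrize(
        "call1,call2",
        [((1, 2), (1, 2)), ((1, 2), (2, 3)), ((1, 1), (1, 2)), ((1, 2), (3, 3))],
    )
    def test_matches_brute_force_enumeration(self, call1, call2, error):
        table = {1: 0.2, 2: 0.3, 3: 0.5}
        freqs = AlleleFrequencies({"L1": table})
        g1 = MultilocusGenotype("w1", {"L1": call1})
        g2 = MultilocusGenotype("w2", {"L1": call2})
        got = pairwise_relationship_likelihoods(g1, g2, freqs, error_rate=error)
        want = brute_force_likelihoods(call1, call2, table, error)
        for key in want:
            assert got[key] == pytest.approx(want[key], rel=1e-9)

    def test_zero_shared_loci_rejected(self):
        freqs = AlleleFrequencies({"L1": {1: 0.5, 2: 0.5}, "L2": {1: 0.5, 2: 0.5}})
        g1 = MultilocusGenotype("w1", {"L1": (1, 2), "L2": None})
        g2 = MultilocusGenotype("w2", {"L1": None, "L2": (1, 2)})
        with pytest.raises(ValueError):
            pairwise_relationship_likelihoods(g1, g2, freqs)


class TestReconstruct:
    def test_single_worker_singleton_with_full_inclusion(self, uniform_freqs):
        worker = MultilocusGenotype("w1", {"L1": (100, 102)})
        part = reconstruct_colonies([worker], uniform_freqs, year=2014)
        assert len(part.colonies()) == 1
        assert part.frame.loc[0, "inclusion"] == pytest.approx(1.0)

    def test_duplicated_genotype_co_assigned(self, uniform_freqs):
        calls = {l: (100, 102) for l in uniform_freqs.loci()}
        twins = [
            MultilocusGenotype("w1", dict(calls)),
            MultilocusGenotype("w2", dict(calls)),
        ]
        part = reconstruct_colonies(twins, uniform_freqs, error_rate=0.0, year=2014)
        assert len(part.colonies()) == 1
        assert (part.frame["inclusion"] >= 0.8).all()

    def test_unrelated_workers_not_co_assigned(self, uniform_freqs):
        rng = np.random.default_rng(10)
        workers = []
        for i in range(8):
            calls = {}
            for l in uniform_freqs.loci():
                alleles = list(uniform_freqs[l])
                calls[l] = tuple(rng.choice(alleles, 2))
            workers.append(MultilocusGenotype(f"w{i}", calls))
        part = reconstruct_colonies(workers, uniform_freqs, year=2014)
        # unrelated random genotypes should mostly stay singletons
        assert len(part.colonies()) >= 6

    def test_recovery_on_small_truth(self, standard_scenario):
        pytest.importorskip("sklearn")
        from sklearn.metrics import adjusted_rand_score

        pop, workers, observed, truth = standard_scenario
        subset_colonies = sorted({w.true_colony for w in workers})[:10]
        keep = [w.worker_id for w in workers if w.true_colony in subset_colonies]
        obs = [g for g in observed if g.id in keep]
        part = reconstruct_colonies(
            obs,
            pop.freqs,
            priors=SibshipPriors(m=1.7, n=2.5),
            error_rate=0.02,
            year=2014,
        )
        pred = dict(zip(part.frame["worker_id"], part.frame["colony_id"]))
        ids = sorted(keep)
        ari = adjusted_rand_score(
            [truth[i] for i in ids], [pred[i] for i in ids]
        )
        assert ari >= 0.8

    def test_empty_input_rejected(self, uniform_freqs):
        with pytest.raises(ValueError):
            reconstruct_colonies([], uniform_freqs)


def _queen(colony_id, calls, conf=1.0):
    genotype = MultilocusGenotype(colony_id + "_q", calls)
    confidence = {l: (conf if c is not None else 0.0) for l, c in calls.items()}
    return InferredQueenGenotype(colony_id, genotype, confidence)


class TestPatrilines:
    def test_single_father_colony(self):
        queen = _queen("c", {"L1": (1, 2), "L2": (3, 4)})
        workers = [
            MultilocusGenotype("w1", {"L1": (1, 9), "L2": (3, 7)}),
            MultilocusGenotype("w2", {"L1": (2, 9), "L2": (4, 7)}),
            MultilocusGenotype("w3", {"L1": (1, 9), "L2": (4, 7)}),
        ]
        assert count_patrilines(workers, queen, ["L1", "L2"]) == 1

    def test_two_fathers_separated_at_two_loci(self):
        queen = _queen("c", {"L1": (1, 2), "L2": (3, 4)})
        workers = [
            MultilocusGenotype("w1", {"L1": (1, 9), "L2": (3, 7)}),
            MultilocusGenotype("w2", {"L1": (2, 8), "L2": (4, 6)}),
        ]
        assert count_patrilines(workers, queen, ["L1", "L2"]) == 2

    def test_six_father_colony_exceeds_acceptance_cap(self):
        queen = _queen("c", {"L1": (1, 2), "L2": (3, 4)})
        workers = [
            MultilocusGenotype(
                f"w{k}", {"L1": (1, 10 + k), "L2": (3, 30 + k)}
            )
            for k in range(6)
        ]
        count = count_patrilines(workers, queen, ["L1", "L2"])
        assert count == 6
        assert count > 5  # rejected by the max-patrilines rule downstream

    def test_irreconcilable_worker_flagged(self):
        queen = _queen("c", {"L1": (1, 2)})
        stranger = MultilocusGenotype("w1", {"L1": (8, 9)})
        with pytest.raises(ValueError):
            count_patrilines([stranger], queen, ["L1"])

    def test_assignment_deterministic_in_id_order(self):
        queen = _queen("c", {"L1": (1, 2)})
        workers = [
            MultilocusGenotype("w2", {"L1": (1, 9)}),
            MultilocusGenotype("w1", {"L1": (2, 9)}),
        ]
        labels, flagged = assign_patrilines(workers, queen, ["L1"])
        labels_rev, _ = assign_patrilines(list(reversed(workers)), queen, ["L1"])
        assert labels == labels_rev
        assert not flagged


class TestPriors:
    def test_maternal_prior_product(self):
        priors = SibshipPriors(m=1.7, n=1.44)
        assert priors.maternal_sibship_size == pytest.approx(2.448)

    def test_all_singletons_give_n_of_one(self):
        frame = pd.DataFrame(
            {
                "worker_id": ["w1", "w2"],
                "year": [2014, 2014],
                "colony_id": ["a", "b"],
                "inclusion": [1.0, 1.0],
                "patriline": [0, 0],
                "accepted": [False, False],
            }
        )
        info = pd.DataFrame(
            {"colony_id": ["a", "b"], "year": [2014] * 2, "size": [1, 1],
             "patriline_count": [1, 1], "accepted": [False, False]}
        )
        priors = estimate_sibship_priors(ColonyPartition(frame, info), m=1.7)
        assert priors.n == 1.0

    def test_mean_patriline_size(self):
        frame = pd.DataFrame(
            {
                "worker_id": ["w1", "w2", "w3"],
                "year": [2014] * 3,
                "colony_id": ["a", "a", "a"],
                "inclusion": [1.0] * 3,
                "patriline": [0, 1, 1],
                "accepted": [True] * 3,
            }
        )
        info = pd.DataFrame(
            {"colony_id": ["a"], "year": [2014], "size": [3],
             "patriline_count": [2], "accepted": [True]}
        )
        priors = estimate_sibship_priors(ColonyPartition(frame, info), m=1.7)
        assert priors.n == pytest.approx(1.5)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            SibshipPriors(m=0.5, n=1.0)


class TestQueenInference:
    def test_forced_maternal_alleles(self):
        freqs = AlleleFrequencies({"L1": {j: 0.2 for j in range(5)}})
        # paternal allele 0 shared; maternal alleles 1 and 2
        workers = [
            MultilocusGenotype("w1", {"L1": (0, 1)}),
            MultilocusGenotype("w2", {"L1": (0, 2)}),
            MultilocusGenotype("w3", {"L1": (0, 1)}),
            MultilocusGenotype("w4", {"L1": (0, 2)}),
        ]
        pat = {w.id: 0 for w in workers}  # one full-sib group
        queen = infer_queen_genotype(
            workers, freqs, error_rate=0.0, colony_id="c", patrilines=pat
        )
        assert queen.genotype.call("L1") == (1, 2)
        assert queen.confidence["L1"] >= 0.8

    def test_single_worker_ambiguous(self):
        freqs = AlleleFrequencies({"L1": {j: 0.2 for j in range(5)}})
        worker = MultilocusGenotype("w1", {"L1": (0, 1)})
        queen = infer_queen_genotype([worker], freqs, 0.0, colony_id="c")
        assert queen.genotype.call("L1") is None
        assert queen.confidence["L1"] == 0.0

    def test_posterior_matches_enumeration(self):
        table = {0: 0.2, 1: 0.3, 2: 0.5}
        freqs = AlleleFrequencies({"L1": table})
        calls = [(0, 1), (0, 1), (1, 2)]
        workers = [
            MultilocusGenotype(f"w{i}", {"L1": c}) for i, c in enumerate(calls)
        ]
        pat = {"w0": 0, "w1": 0, "w2": 1}
        alleles = list(table)

        def worker_lik(call, q, f):
            # error-free: maternal from q, paternal = f, unordered
            total = 0.0
            for m in q:
                pair = tuple(sorted((m, f)))
                total += 0.5 * (pair == tuple(sorted(call)))
            return total

        post = {}
        for qa in alleles:
            for qb in alleles:
                if qa > qb:
                    continue
                hw = table[qa] * table[qb] * (2 if qa != qb else 1)
                lik = 1.0
                for group in ({0, 1}, {2}):
                    s = 0.0
                    for f in alleles:
                        prod = 1.0
                        for i in group:
                            prod *= worker_lik(calls[i], (qa, qb), f)
                        s += table[f] * prod
                    lik *= s
                post[(qa, qb)] = hw * lik
        total = sum(post.values())
        best = max(post, key=post.get)
        want_conf = post[best] / total

        queen = infer_queen_genotype(
            workers, freqs, 0.0, colony_id="c", patrilines=pat, min_confidence=0.0
        )
        assert queen.genotype.call("L1") == best
        assert queen.confidence["L1"] == pytest.approx(want_conf, rel=1e-9)

    def test_confidence_grows_with_colony_size(self):
        # paternal alleles span three values so that no alternative queen
        # genotype can explain the colony
        freqs = AlleleFrequencies({"L1": {j: 0.2 for j in range(5)}})
        pat = {f"w{i}": i for i in range(8)}  # all distinct fathers

        def colony(n):
            out = []
            for i in range(n):
                maternal = (0, 1)[i % 2]
                paternal = 2 + i % 3
                out.append(
                    MultilocusGenotype(f"w{i}", {"L1": (maternal, paternal)})
                )
            return out

        small = infer_queen_genotype(
            colony(2), freqs, 0.0, colony_id="c", patrilines=pat, min_confidence=0.0
        )
        large = infer_queen_genotype(
            colony(8), freqs, 0.0, colony_id="c", patrilines=pat, min_confidence=0.0
        )
        assert large.confidence["L1"] > small.confidence["L1"]
        assert large.confidence["L1"] >= 0.95
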