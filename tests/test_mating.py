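from itertools import product

import numpy as np
import pytest

from nestkin.genotypes import AlleleFrequencies, MultilocusGenotype
from nestkin.mating import (
    MatchSimResult,
    MiscountMatrix,
    QueenRecord,
    SpermProfile,
    count_min_males,
    flag_contamination,
    locus_match_probability,
    max_likely_frequency,
    observed_match_rate,
    run_simulation_1,
    run_simulation_2,
    summarize_mating,
)


def make_queen(qid, queen_calls, sperm_alleles, freq_tables=None):
    genotype = MultilocusGenotype(qid, queen_calls)
    profile = SpermProfile({l: frozenset(a) for l, a in sperm_alleles.items()})
    return QueenRecord(qid, genotype, profile)


class TestLocusMatchProbability:
    def test_heterozygote_two_mates(self):
        assert locus_match_probability((1, 2), {1: 0.5, 2: 0.5}, 2) == pytest.approx(
            0.5
        )

    def test_monomorphic_homozygote(self):
        assert locus_match_probability((1, 1), {1: 1.0}, 2) == pytest.approx(1.0)

    def test_homozygote_general(self):
        p = {1: 0.3, 2: 0.7}
        assert locus_match_probability((1, 1), p, 3) == pytest.approx(
            1 - 0.7**3
        )

    @pytest.mark.parametrize("pa,pb", [(0.2, 0.3), (0.1, 0.6), (0.45, 0.45)])
    def test_matches_enumeration_over_male_pairs(self, pa, pb):
        freqs = {1: pa, 2: pb, 3: 1 - pa - pb}
        want = 0.0
        for m1, m2 in product(freqs, repeat=2):
            if {1, 2} <= {m1, m2}:
                want += freqs[m1] * freqs[m2]
        assert locus_match_probability((1, 2), freqs, 2) == pytest.approx(want)

    def test_unknown_allele_rejected(self):
        with pytest.raises(KeyError):
            locus_match_probability((9, 9), {1: 1.0}, 2)


class TestSimulation1:
    def _ten_locus_queen(self):
        tables = {f"L{i}": {1: 0.5, 2: 0.5} for i in range(10)}
        freqs = AlleleFrequencies(tables)
        queen = MultilocusGenotype("q1", {f"L{i}": (1, 2) for i in range(10)})
        profile = SpermProfile({f"L{i}": frozenset() for i in range(10)},
                               {f"L{i}": False for i in range(10)})
        return QueenRecord("q1", queen, profile), freqs

    def test_binomial_mean_recovered(self):
        queen, freqs = self._ten_locus_queen()
        res = run_simulation_1([queen], freqs, reps=4000, seed=1)
        assert res.expected_matches["q1"] == pytest.approx(5.0, abs=0.15)
        assert res.expected_rate["q1"] == pytest.approx(0.5, abs=0.015)

    def test_analytic_route_agrees(self):
        queen, freqs = self._ten_locus_queen()
        mc = run_simulation_1([queen], freqs, reps=4000, seed=2)
        exact = run_simulation_1([queen], freqs, reps=1, seed=2, bernoulli=False)
        assert exact.expected_matches["q1"] == pytest.approx(5.0)
        assert mc.expected_matches["q1"] == pytest.approx(
            exact.expected_matches["q1"], abs=0.2
        )

    def test_deterministic_given_seed(self):
        queen, freqs = self._ten_locus_queen()
        a = run_simulation_1([queen], freqs, reps=500, seed=3)
        b = run_simulation_1([queen], freqs, reps=500, seed=3)
        assert a.expected_matches == b.expected_matches
        assert a.critical_value == b.critical_value

    def test_critical_value_is_mean_plus_two_sd(self):
        res = MatchSimResult({}, {}, 0.369, 0.075)
        assert res.critical_value == pytest.approx(0.519)


class TestContaminationFlag:
    def test_full_queen_genotype_everywhere_flagged(self):
        q = make_queen(
            "q",
            {"L1": (1, 2), "L2": (3, 3)},
            {"L1": {1, 2, 5}, "L2": {3, 7}},
        )
        assert observed_match_rate(q) == 1.0
        assert flag_contamination(q, 0.52)

    def test_no_shared_alleles_not_flagged(self):
        q = make_queen("q", {"L1": (1, 2)}, {"L1": {5, 6}})
        assert observed_match_rate(q) == 0.0
        assert not flag_contamination(q, 0.52)

    def test_rate_above_critical_is_flagged(self):
        # 11 of 20 loci match: rate 0.55 > 0.520
        calls = {f"L{i}": (1, 2) for i in range(20)}
        sperm = {f"L{i}": {1, 2} for i in range(11)}
        sperm.update({f"L{i}": {5} for i in range(11, 20)})
        q = make_queen("q", calls, sperm)
        assert observed_match_rate(q) == pytest.approx(0.55)
        assert flag_contamination(q, 0.520)

    def test_no_amplified_loci_rejected(self):
        genotype = MultilocusGenotype("q", {"L1": (1, 2)})
        profile = SpermProfile({"L1": frozenset()}, {"L1": False})
        with pytest.raises(ValueError):
            observed_match_rate(QueenRecord("q", genotype, profile))


class TestCountMinMales:
    def test_worked_example_with_contamination(self):
        # queen {a,b},{c,c},{d,e}; sperm {a,f},{c,g},{d,h}; flagged sample:
        # locus1: b absent -> a is a true male allele -> 2
        # locus2: homozygous queen fully present -> c subtracted -> 1
        # locus3: e absent -> d is a true male allele -> 2
        q = make_queen(
            "q",
            {"L1": (1, 2), "L2": (3, 3), "L3": (4, 5)},
            {"L1": {1, 6}, "L2": {3, 7}, "L3": {4, 8}},
        )
        assert count_min_males(q, contaminated=True) == 2

    def test_unshared_single_father(self):
        q = make_queen("q", {"L1": (1, 2), "L2": (3, 4)}, {"L1": {6}, "L2": {7}})
        assert count_min_males(q, contaminated=False) == 1

    def test_two_alleles_at_single_locus_not_enough(self):
        q = make_queen(
            "q",
            {"L1": (1, 2), "L2": (3, 4), "L3": (5, 6)},
            {"L1": {7, 8}, "L2": {9}, "L3": {9}},
        )
        assert count_min_males(q, contaminated=False) == 1

    def test_unflagged_sample_keeps_shared_alleles(self):
        # both queen alleles in sperm at two loci, sample NOT flagged:
        # shared alleles count as male
        q = make_queen(
            "q", {"L1": (1, 2), "L2": (3, 4)}, {"L1": {1, 2}, "L2": {3, 4}}
        )
        assert count_min_males(q, contaminated=False) == 2
        assert count_min_males(q, contaminated=True) == 1

    def test_empty_profile_rejected(self):
        genotype = MultilocusGenotype("q", {"L1": (1, 2)})
        profile = SpermProfile({"L1": frozenset()}, {"L1": False})
        with pytest.raises(ValueError):
            count_min_males(QueenRecord("q", genotype, profile), False)


@pytest.fixture(scope="module")
def informative_panel():
    """20 loci x 10 equifrequent alleles; 4 queens."""
    tables = {f"L{i:02d}": {j: 0.1 for j in range(10)} for i in range(20)}
    freqs = AlleleFrequencies(tables)
    rng = np.random.default_rng(44)
    queens = []
    for k in range(4):
        calls = {l: tuple(sorted(rng.choice(10, 2))) for l in tables}
        genotype = MultilocusGenotype(f"q{k}", calls)
        profile = SpermProfile({l: frozenset({0}) for l in tables})
        queens.append(QueenRecord(f"q{k}", genotype, profile))
    return queens, freqs


class TestSimulation2:
    def test_true_one_always_observed_one(self, informative_panel):
        queens, freqs = informative_panel
        matrix = run_simulation_2(
            queens, freqs, critical_value=0.52, true_range=[1], reps=200, seed=5
        )
        assert matrix.probs[0, 1] == pytest.approx(1.0)

    def test_observed_never_exceeds_true(self, informative_panel):
        queens, freqs = informative_panel
        matrix = run_simulation_2(
            queens, freqs, critical_value=0.52, true_range=[1, 2, 3], reps=300, seed=6
        )
        for i, t in enumerate(matrix.true_counts):
            assert matrix.probs[i, t + 1 :].sum() == 0.0
            assert matrix.probs[i].sum() == pytest.approx(1.0)

    def test_informative_panel_counts_two_reliably(self, informative_panel):
        queens, freqs = informative_panel
        matrix = run_simulation_2(
            queens, freqs, critical_value=0.52, true_range=[2], reps=400, seed=7
        )
        assert matrix.probs[0, 2] >= 0.95

    def test_rows_stochastically_ordered(self, informative_panel):
        # more true mates never shift observed counts downwards
        queens, freqs = informative_panel
        matrix = run_simulation_2(
            queens, freqs, critical_value=0.52, true_range=[1, 2, 3, 4], reps=300, seed=8
        )
        for i in range(len(matrix.true_counts) - 1):
            for k in range(1, 5):
                lo = matrix.probs[i, : k + 1].sum()
                hi = matrix.probs[i + 1, : k + 1].sum()
                assert hi <= lo + 0.05  # MC slack


class TestMaxLikelyFrequency:
    def _matrix(self, rows):
        t = sorted(rows)
        size = max(t) + 1
        probs = np.zeros((len(t), size))
        for i, k in enumerate(t):
            probs[i, : len(rows[k])] = rows[k]
        return MiscountMatrix(t, probs, 1)

    def test_identity_matrix_returns_observed(self):
        rows = {t: [0.0] * t + [1.0] for t in range(1, 6)}
        matrix = self._matrix(rows)
        assert max_likely_frequency(matrix, 3) == 3

    def test_constructed_tail_rule(self):
        # P(observed<=3 | t=5) = 0.06 >= 0.05 but t=6 gives 0.04
        rows = {
            t: [0.0] * t + [1.0] for t in range(1, 5)
        }
        rows[5] = [0.0, 0.0, 0.0, 0.06, 0.0, 0.94]
        rows[6] = [0.0, 0.0, 0.0, 0.04, 0.0, 0.0, 0.96]
        matrix = self._matrix(rows)
        assert max_likely_frequency(matrix, 3, tail=0.05) == 5

    def test_out_of_range_rejected(self):
        rows = {1: [0.0, 1.0]}
        with pytest.raises(ValueError):
            max_likely_frequency(self._matrix(rows), 5)


class TestSummary:
    def test_summary_statistics(self):
        queens = [
            make_queen("q1", {"L1": (1, 2), "L2": (3, 4)}, {"L1": {6}, "L2": {7}}),
            make_queen(
                "q2", {"L1": (1, 2), "L2": (3, 4)}, {"L1": {6, 7}, "L2": {8, 9}}
            ),
        ]
        sim1 = MatchSimResult({}, {}, 0.369, 0.075)
        summary = summarize_mating(queens, sim1)
        assert summary.counts == [1, 2]
        assert summary.mean_min_mating_frequency == pytest.approx(1.5)
        assert summary.percent_monandrous == pytest.approx(50.0)
        assert summary.max_observed == 2
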