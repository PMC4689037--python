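import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iclipkit.motifpairs import (TRIMERS, all_pair_specs, bootstrap_fdr,
                                 fisher_one_sided, find_pairs, has_pair,
                                 mark_positions, mutate_trimers,
                                 pair_presence_matrix, pair_test,
                                 positional_tests, region_sequence,
                                 rank_all_pairs)
from tests.conftest import make_exon, random_seq

dna50 = st.text(alphabet="ACGT", min_size=6, max_size=50)


def brute_force_pairs(seq, k_min=3):
    """Oracle: O(n^2) double loop over all start-position pairs."""
    out = []
    for i in range(len(seq) - 2):
        if seq[i:i + 3] not in TRIMERS:
            continue
        for j in range(i + k_min, len(seq) - 2):
            if seq[j:j + 3] in TRIMERS:
                out.append((i, seq[i:i + 3], j, seq[j:j + 3]))
    return out


def hypergeom_tail_oracle(a, b, c, d):
    """Oracle: exact integer enumeration of P(X >= a) with fixed margins."""
    N, K, n = a + b + c + d, a + b, a + c
    denom = math.comb(N, n)
    total = 0
    for k in range(max(a, 0, n - (N - K)), min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k)
    return total / denom


class TestFindPairs:
    def test_paper_overlap_exclusion_example(self):
        assert find_pairs("AAGA") == []

    def test_aagaaga_three_pairs(self):
        pairs = find_pairs("AAGAAGA")
        assert sorted(pairs) == sorted([(0, "AAG", 3, "AAG"),
                                        (0, "AAG", 4, "AGA"),
                                        (1, "AGA", 4, "AGA")])
        assert sorted(pairs) == sorted(brute_force_pairs("AAGAAGA"))

    def test_no_targets(self):
        assert find_pairs("CCCCCC") == []

    def test_k_min_below_three_rejected(self):
        with pytest.raises(ValueError):
            find_pairs("AAGAAGA", k_min=2)

    def test_max_gap(self):
        pairs = find_pairs("AAG" + "C" * 20 + "AGA", max_gap=10)
        assert pairs == []
        pairs = find_pairs("AAG" + "C" * 20 + "AGA", max_gap=30)
        assert len(pairs) == 1

    @settings(max_examples=200, deadline=None)
    @given(seq=dna50)
    def test_matches_brute_force(self, seq):
        assert sorted(find_pairs(seq)) == sorted(brute_force_pairs(seq))

    def test_thousand_random_sequences_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            seq = random_seq(rng, 50)
            assert sorted(find_pairs(seq)) == sorted(brute_force_pairs(seq))


class TestFisher:
    def test_oracle_small_grid(self):
        for a in range(0, 8):
            for b in range(0, 8):
                for c in range(0, 8):
                    for d in range(0, 8):
                        if a + b == 0 or c + d == 0:
                            continue
                        p = fisher_one_sided(a, b, c, d)
                        oracle = hypergeom_tail_oracle(a, b, c, d)
                        assert p == pytest.approx(oracle, rel=1e-10), \
                            (a, b, c, d)

    def test_spec_table_example(self):
        # (a=5, b=5, c=0, d=10)
        assert fisher_one_sided(5, 5, 0, 10) == pytest.approx(
            hypergeom_tail_oracle(5, 5, 0, 10), rel=1e-12)

    def test_matches_scipy_fisher(self):
        from scipy.stats import fisher_exact
        for table in [(3, 7, 1, 9), (10, 0, 2, 8), (0, 5, 5, 0)]:
            a, b, c, d = table
            assert fisher_one_sided(a, b, c, d) == pytest.approx(
                fisher_exact([[a, b], [c, d]], alternative="greater").pvalue,
                rel=1e-9)


class TestPairTest:
    def _exons(self, seqs, label="x"):
        return [make_exon(f"{label}{i}", s) for i, s in enumerate(seqs)]

    def test_identical_sets_not_significant(self, rng):
        # With identical target and control sets a == c and the one-sided
        # tail from the observed count is never below 0.5 (and exactly 1
        # when the pair is absent from both sets).
        seqs = [random_seq(rng, 120) for _ in range(30)]
        target = self._exons(seqs, "t")
        control = self._exons(seqs, "c")
        for u, d in all_pair_specs():
            r = pair_test(target, control, u, d)
            assert r.a == r.c
            assert r.p_fisher >= 0.5
            assert not r.significant
            if r.a == 0:
                assert r.p_fisher == pytest.approx(1.0)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            pair_test([], [make_exon("c", "A" * 120)], "AGA", "Any")

    def test_any_count_at_least_max_specific(self, rng):
        target = self._exons([random_seq(rng, 150) for _ in range(40)], "t")
        control = self._exons([random_seq(rng, 150) for _ in range(40)], "c")
        results = {(r.up_trimer, r.down_trimer): r
                   for r in rank_all_pairs(target, control)}
        for u in TRIMERS:
            any_a = results[(u, "Any")].a
            for d in TRIMERS:
                assert any_a >= results[(u, d)].a

    def test_counts_match_presence_matrix(self, rng):
        target = self._exons([random_seq(rng, 150) for _ in range(25)], "t")
        control = self._exons([random_seq(rng, 150) for _ in range(25)], "c")
        mat = pair_presence_matrix(target, "exon_last50", 3)
        specs = all_pair_specs()
        for j, (u, d) in enumerate(specs):
            r = pair_test(target, control, u, d)
            assert r.a == mat[:, j].sum()
            assert r.a + r.b == len(target)

    def test_rank_ordering_deterministic(self, rng):
        target = self._exons([random_seq(rng, 150) for _ in range(30)], "t")
        control = self._exons([random_seq(rng, 150) for _ in range(30)], "c")
        results = rank_all_pairs(target, control)
        assert [r.rank for r in results] == list(range(1, 13))
        keys = [(r.p_fisher, -r.a, r.pair_name) for r in results]
        assert keys == sorted(keys)


class TestMarkPositions:
    def test_trailing_aag_marked(self):
        seq = "C" * 97 + "AAG"  # AAG at final start position of last-50
        counts, used = mark_positions([make_exon("e", seq)])
        assert used == 1
        assert counts[-1] == 1 and counts.sum() == 1

    def test_all_c_controls_zero(self):
        counts, _ = mark_positions([make_exon("e", "C" * 120)])
        assert counts.sum() == 0

    def test_against_regex_oracle(self, rng):
        exons = [make_exon(f"e{i}", random_seq(rng, 150)) for i in range(20)]
        counts, used = mark_positions(exons, region="exon_last50")
        assert used == 20
        oracle = np.zeros(48, dtype=int)
        for ex in exons:
            window = ex.sequence[-50:]
            for i in range(48):
                if window[i:i + 3] in TRIMERS:
                    oracle[i] += 1
        assert (counts == oracle).all()

    def test_short_exon_skipped(self):
        counts, used = mark_positions([make_exon("e", "ACG" * 10)])
        assert used == 0

    def test_positional_tests_p_values(self, rng):
        target = [make_exon(f"t{i}", random_seq(rng, 120)) for i in range(15)]
        control = [make_exon(f"c{i}", random_seq(rng, 120)) for i in range(15)]
        pc = positional_tests(target, control)
        assert ((pc.p_values > 0) & (pc.p_values <= 1)).all()
        assert (pc.target_counts <= pc.n_target).all()


class TestRegionSequence:
    def test_variants(self):
        ex = make_exon("e", "A" * 60 + "C" * 60,
                       upstream_intron_seq="G" * 80,
                       downstream_intron_seq="T" * 80)
        assert region_sequence(ex, "exon_first50") == "A" * 50
        assert region_sequence(ex, "exon_last50") == "C" * 50
        assert region_sequence(ex, "upstream_intron_last50") == "G" * 50
        assert region_sequence(ex, "downstream_intron_first50") == "T" * 50
        with pytest.raises(ValueError):
            region_sequence(ex, "exon_middle50")

    def test_too_short_returns_none(self):
        ex = make_exon("e", "A" * 30)
        assert region_sequence(ex, "exon_last50") is None


class TestBootstrapFdr:
    def _sets(self, rng, n_pop=400):
        target = [make_exon(f"t{i}", random_seq(rng, 150))
                  for i in range(30)]
        control = [make_exon(f"c{i}", random_seq(rng, 150))
                   for i in range(30)]
        population = [make_exon(f"p{i}", random_seq(rng, 150))
                      for i in range(n_pop)]
        return target, control, population

    def test_observed_p_one_gives_fdr_one(self, rng):
        target, control, population = self._sets(rng)
        results = rank_all_pairs(target, control)
        for r in results:
            r.p_fisher = 1.0  # every trial ties or beats it
        bootstrap_fdr(results, population, control, n_trials=50,
                      sample_size=30, rng=np.random.default_rng(0))
        for r in results:
            assert r.fdr_bootstrap == pytest.approx(1.0)

    def test_unbeaten_p_reported_as_upper_bound(self, rng):
        target, control, population = self._sets(rng)
        results = rank_all_pairs(target, control)
        results[0].p_fisher = 1e-300  # force unbeatable observed p
        bootstrap_fdr(results, population, control, n_trials=40,
                      sample_size=30, rng=np.random.default_rng(1))
        r = results[0]
        assert r.fdr_upper_bound and r.fdr_bootstrap == pytest.approx(1 / 40)

    def test_monotone_in_observed_p(self, rng):
        target, control, population = self._sets(rng)
        fdrs = []
        for forced_p in (0.9, 0.09):
            results = rank_all_pairs(target, control)
            spec_r = [r for r in results
                      if (r.up_trimer, r.down_trimer) == ("AGA", "Any")][0]
            spec_r.p_fisher = forced_p
            bootstrap_fdr(results, population, control, n_trials=60,
                          sample_size=30, rng=np.random.default_rng(5))
            fdrs.append(spec_r.fdr_bootstrap)
        assert fdrs[1] <= fdrs[0]

    def test_parameter_validation(self, rng):
        target, control, population = self._sets(rng, n_pop=50)
        results = rank_all_pairs(target, control)
        with pytest.raises(ValueError):
            bootstrap_fdr(results, population, control, n_trials=0)
        with pytest.raises(ValueError):
            bootstrap_fdr(results, population, control, n_trials=10,
                          sample_size=109)


class TestMutateTrimers:
    def test_gaaga_example(self):
        mutated, edits = mutate_trimers("GAAGA")
        assert mutated == "CAACA"
        assert {(p, f, t) for p, f, t in edits} == \
               {(0, "G", "C"), (3, "G", "C")}

    def test_no_targets_unchanged(self):
        mutated, edits = mutate_trimers("CCCTTT")
        assert mutated == "CCCTTT" and edits == []

    @settings(max_examples=300, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=0, max_size=80))
    def test_postconditions(self, seq):
        mutated, edits = mutate_trimers(seq)
        # no target trimer remains
        for i in range(len(mutated) - 2):
            assert mutated[i:i + 3] not in TRIMERS
        # only G->C substitutions, length preserved
        assert len(mutated) == len(seq)
        for pos, frm, to in edits:
            assert frm == "G" and to == "C" and seq[pos] == "G"
        diff = [i for i in range(len(seq)) if seq[i] != mutated[i]]
        assert set(diff) == {p for p, _, _ in edits}
        # idempotence
        again, edits2 = mutate_trimers(mutated)
        assert again == mutated and edits2 == []

    def test_every_edit_was_inside_matched_trimer(self):
        seq = "AGAAGAAGGAAGA"
        mutated, edits = mutate_trimers(seq)
        # replay greedily: at each round every edited G must be in a match
        current = list(seq)
        remaining = {p for p, _, _ in edits}
        while remaining:
            s = "".join(current)
            in_match = set()
            for i in range(len(s) - 2):
                if s[i:i + 3] in TRIMERS:
                    in_match.update(range(i, i + 3))
            round_edits = {p for p in remaining
                           if p in in_match and current[p] == "G"}
            assert round_edits, "edit not justified by any current match"
            for p in round_edits:
                current[p] = "C"
            remaining -= round_edits
        assert "".join(current) == mutated


class TestHasPair:
    def test_any_downstream(self):
        assert has_pair("AGACCCGAA", "AGA", "Any")
        assert has_pair("AGACCCGAA", "AGA", None)
        assert not has_pair("AGACCCGAA", "GAA", "Any")
        assert has_pair("AGACCCGAA", "AGA", "GAA")
        assert not has_pair("AGACCCGAA", "AGA", "AAG")
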