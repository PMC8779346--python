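"""Tolerance rule and spacing-constrained pattern search."""

import re

import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_force_matches, n_candidate_tuples, oracle_gap_tolerance
from metscan.constants import AA_ONE_LETTER
from metscan.domain_scan import ProteinRecord
from metscan.mbp_library import MetalBindingPattern, dedupe
from metscan.mbp_matcher import (
    ConsistencyError,
    MatchPolicy,
    filter_candidates,
    gap_tolerance,
    match_mbp,
)


def mbp(ligands, gaps, element="Zn"):
    return MetalBindingPattern(
        mbp_id=f"{element}_{ligands}", element=element, ligands=tuple(ligands), gaps=tuple(gaps)
    )


class TestGapTolerance:
    @pytest.mark.parametrize(
        "gap,expected",
        [(1, 1), (2, 1), (3, 1), (4, 1), (5, 1), (9, 1), (10, 2), (25, 5), (50, 10)],
    )
    def test_default_rule(self, gap, expected):
        assert gap_tolerance(gap) == expected

    def test_rejects_non_positive_gap(self):
        with pytest.raises(ValueError):
            gap_tolerance(0)

    def test_zero_tolerance_policy_gives_zero(self):
        policy = MatchPolicy(relative_tolerance=0.0, short_gap_abs=0)
        assert all(gap_tolerance(g, policy) == 0 for g in (1, 5, 50))

    def test_explicit_short_gap_threshold(self):
        policy = MatchPolicy(short_gap_threshold=10, short_gap_abs=2)
        assert gap_tolerance(3, policy) == 2  # floor(0.6)=0 -> abs rule
        assert gap_tolerance(10, policy) == 2  # floor(2.0)=2, max with abs
        assert gap_tolerance(11, policy) == 2  # above threshold: floor only
        assert gap_tolerance(50, policy) == 10

    @given(st.integers(min_value=1, max_value=500))
    def test_matches_restated_rule(self, gap):
        assert gap_tolerance(gap) == oracle_gap_tolerance(gap)


class TestMatchMBP:
    def test_exact_planted_placement(self):
        seq = "AACAAACAAAAAAAAAAAAAHAAAAH"
        matches = match_mbp(seq, mbp("CCHH", (4, 14, 5)))
        assert [(m.positions, m.deviations) for m in matches] == [
            ((3, 7, 21, 26), (0, 0, 0))
        ]

    def test_within_tolerance_deviation(self):
        seq = "AACAAACAAAAAAAAAAAAAHAAAAH"
        matches = match_mbp(seq, mbp("CCHH", (4, 16, 5)))
        assert [(m.positions, m.deviations) for m in matches] == [
            ((3, 7, 21, 26), (0, -2, 0))
        ]

    def test_mutated_ligand_kills_match(self):
        seq = "AACAAAAAAAAAAAAAAAAAHAAAAH"  # second C mutated to A
        assert match_mbp(seq, mbp("CCHH", (4, 14, 5))) == []

    def test_absence_is_a_value_not_error(self):
        assert match_mbp("AAAA", mbp("CC", (3,))) == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            match_mbp("", mbp("CC", (3,)))

    def test_deterministic_ordering(self):
        seq = "CACACACA"
        matches = match_mbp(seq, mbp("CC", (2,)))
        positions = [m.positions for m in matches]
        assert positions == sorted(positions)

    def test_window_restriction(self):
        seq = "CACAAAAAAACACA"
        pattern = mbp("CC", (2,))
        full = {m.positions for m in match_mbp(seq, pattern)}
        windowed = {m.positions for m in match_mbp(seq, pattern, window=(11, 14))}
        assert windowed == {(11, 13)} and windowed < full

    def test_substitution_groups(self):
        policy = MatchPolicy(substitution_groups=(("D", "E"),))
        seq = "AEAAAD"
        assert match_mbp(seq, mbp("DD", (4,), element="Ca"), policy)
        assert not match_mbp(seq, mbp("DD", (4,), element="Ca"))

    def test_brute_force_equivalence_random(self, rng):
        for _ in range(200):
            n = int(rng.integers(30, 200))
            seq = "".join(rng.choice(list(AA_ONE_LETTER), size=n))
            k = int(rng.integers(2, 5))
            ligands = tuple(rng.choice(list(AA_ONE_LETTER), size=k))
            gaps = tuple(int(g) for g in rng.integers(1, 30, size=k - 1))
            if n_candidate_tuples(seq, ligands) > 10**6:
                continue
            got = {m.positions for m in match_mbp(seq, mbp(ligands, gaps))}
            want = brute_force_matches(seq, ligands, gaps)
            assert got == want

    def test_tolerance_monotonicity(self, rng):
        pattern = mbp("CHC", (6, 12))
        for _ in range(50):
            seq = "".join(rng.choice(list(AA_ONE_LETTER), size=120))
            previous: set = set()
            for t in (0.1, 0.2, 0.3):
                current = {
                    m.positions
                    for m in match_mbp(seq, pattern, MatchPolicy(relative_tolerance=t))
                }
                assert previous <= current
                previous = current

    def test_reversal_symmetry(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list(AA_ONE_LETTER), size=100))
            ligands = tuple(rng.choice(list(AA_ONE_LETTER), size=3))
            gaps = tuple(int(g) for g in rng.integers(1, 20, size=2))
            fwd = {m.positions for m in match_mbp(seq, mbp(ligands, gaps))}
            rev = {
                m.positions
                for m in match_mbp(seq[::-1], mbp(ligands[::-1], gaps[::-1]))
            }
            n = len(seq)
            mirrored = {tuple(n + 1 - p for p in reversed(t)) for t in rev}
            assert fwd == mirrored

    def test_zero_tolerance_equals_regex(self, rng):
        policy = MatchPolicy(relative_tolerance=0.0, short_gap_abs=0)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACDH"), size=80))
            ligands = tuple(rng.choice(list("ACDH"), size=3))
            gaps = tuple(int(g) for g in rng.integers(1, 10, size=2))
            pattern = mbp(ligands, gaps)
            got = {m.positions[0] for m in match_mbp(seq, pattern, policy)}
            regex = (
                re.escape(ligands[0])
                + f".{{{gaps[0] - 1}}}" + re.escape(ligands[1])
                + f".{{{gaps[1] - 1}}}" + re.escape(ligands[2])
            )
            want = {
                m.start() + 1 for m in re.finditer(f"(?={regex})", seq)
            }
            assert got == want

    def test_span_mode_frees_individual_gaps(self):
        # gaps 5+5=10 observed as 4+6: per-gap tolerance ±1 allows it,
        # but 2+8 does not; span mode accepts both (span preserved).
        pattern = mbp("CHC", (5, 5))
        seq_shift = "C" + "A" * 3 + "H" + "A" * 5 + "C"  # gaps 4, 6
        seq_skew = "C" + "A" * 1 + "H" + "A" * 7 + "C"  # gaps 2, 8
        per_gap = MatchPolicy()
        span = MatchPolicy(mode="span")
        assert match_mbp(seq_shift, pattern, per_gap)
        assert not match_mbp(seq_skew, pattern, per_gap)
        assert match_mbp(seq_skew, pattern, span)


class TestFilterCandidates:
    def test_planted_candidate_retained_mutant_rejected(self, zinc_finger_mbp):
        lib = dedupe([zinc_finger_mbp])
        intact = "AAA" + "C" + "A" * 4 + "C" + "A" * 14 + "H" + "A" * 5 + "H" + "AAA"
        mutated = intact.replace("H", "A", 1)
        proteome = [
            ProteinRecord(protein_id="P1", sequence=intact),
            ProteinRecord(protein_id="P2", sequence=mutated),
        ]
        out = filter_candidates({"Zn": {"P1", "P2"}}, proteome, lib)
        assert {pid for pid, _e, _m in out} == {"P1"}

    def test_missing_candidate_raises(self, zinc_finger_mbp):
        lib = dedupe([zinc_finger_mbp])
        proteome = [ProteinRecord(protein_id="P1", sequence="ACDEF")]
        with pytest.raises(ConsistencyError):
            filter_candidates({"Zn": {"P1", "GHOST"}}, proteome, lib)

    def test_ground_truth_recovery(self, planted_bundle, default_policy, small_library):
        gt = planted_bundle.ground_truth
        candidates = {}
        for entry in gt.entries:
            candidates.setdefault(entry.element, set()).add(entry.protein_id)
        out = filter_candidates(candidates, planted_bundle.records, small_library, default_policy)
        got_pairs = {(pid, e) for pid, e, _m in out}
        assert got_pairs == gt.surviving_pairs()
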