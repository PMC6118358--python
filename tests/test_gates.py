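"""Gate-set structure, duplex mapping, and orthogonality screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdstorm import gates
from sdstorm.gates import (
    GateSet,
    InvalidAlphabetError,
    Strand,
    ZeroLengthToeholdError,
    cross_reactivity,
    duplex_map,
    longest_complementary_run,
    parse_gate_file,
    reverse_complement,
    toehold_of,
    verify_gate,
)

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_longest_run(a: str, b: str) -> int:
    """Oracle: longest L such that some length-L substring of ``a`` equals
    the reverse complement of some substring of ``b``."""
    best = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            if j - i <= best:
                continue
            if _rc(a[i:j]) in b:
                best = j - i
    return best


def brute_force_paired_count(a: str, b: str) -> int:
    """Oracle: most Watson-Crick pairs on any antiparallel diagonal."""
    best = 0
    for s in range(len(a) + len(b) - 1):
        count = sum(
            1
            for i in range(len(a))
            if 0 <= s - i < len(b) and a[i] == b[s - i].translate(_COMP)
        )
        best = max(best, count)
    return best


dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestReverseComplement:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", "ACGT"),
        ("AAAA", "TTTT"),
        # Set A protector maps onto the first 30 nt of the Set A template
        ("GCCTGCTTTATCTCTGTTCTACTATTTCCG", "CGGAAATAGTAGAACAGAGATAAAGCAGGC"),
    ])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_invalid_character_names_position(self):
        with pytest.raises(InvalidAlphabetError, match="position 2"):
            reverse_complement("ACUT")

    def test_involution_on_many_random_strands(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            s = "".join(rng.choice(bases, size=rng.integers(1, 60)))
            assert reverse_complement(reverse_complement(s)) == s

    @given(dna)
    @settings(derandomize=True, max_examples=200)
    def test_involution_property(self, s):
        assert reverse_complement(reverse_complement(s)) == s


class TestDuplexMap:
    def test_printed_sets_form_30bp_duplex(self, gate_a, gate_b):
        for gate in (gate_a, gate_b):
            count, pairs = duplex_map(gate.template, gate.protector)
            assert count == 30
            assert len(pairs) == 30
            # all pairs on one antiparallel diagonal
            assert len({i + j for i, j in pairs}) == 1

    def test_strand_vs_own_reverse_complement(self):
        s = "GATTACAGATTACA"
        count, _ = duplex_map(s, _rc(s))
        assert count == len(s)

    @given(dna, dna)
    @settings(derandomize=True, max_examples=150)
    def test_symmetry(self, a, b):
        assert duplex_map(a, b)[0] == duplex_map(b, a)[0]

    @given(dna, dna)
    @settings(derandomize=True, max_examples=100)
    def test_agrees_with_brute_force(self, a, b):
        assert duplex_map(a, b)[0] == brute_force_paired_count(a, b)

    def test_linker_excluded(self, gate_a):
        # the protector's full synthesized form carries a 3' TT linker
        assert gate_a.protector.full_sequence.endswith("TT")
        assert len(gate_a.protector) == 30


class TestToehold:
    def test_set_a_toehold(self, gate_a):
        th = toehold_of(gate_a)
        assert (th.length, th.segment_sequence) == (8, "AAACGAAA")
        assert (th.start, th.end) == (30, 38)

    def test_set_b_toehold(self, gate_b):
        th = toehold_of(gate_b)
        assert (th.length, th.segment_sequence) == (8, "TTGATATT")

    def test_duplex_plus_toehold_spans_template(self, gate_a, gate_b):
        for gate in (gate_a, gate_b):
            assert gate.duplex_length + gate.toehold.length == len(gate.template)

    def test_fully_paired_template_has_no_toehold(self):
        prot = Strand("p", "protector", "GATTACAGATTACAGATTACA")
        templ = Strand("t", "template", _rc(prot.sequence))
        inv = Strand("i", "invader", _rc(templ.sequence))
        with pytest.raises(ZeroLengthToeholdError):
            GateSet(name="x", protector=prot, template=templ, invader=inv)


class TestVerifyGate:
    def test_printed_sets_pass_all_checks(self, gate_a, gate_b):
        for gate in (gate_a, gate_b):
            report = verify_gate(gate)
            assert report.all_passed, [c for c in report if not c.passed]
            by_name = {c.name: c for c in report}
            assert by_name["template_length"].observed == 38
            assert by_name["protector_length"].observed == 30
            assert by_name["duplex_length"].observed == 30
            assert by_name["toehold_nonzero"].observed == 8
            assert by_name["invader_full_complement"].observed == 38

    def test_swapped_invader_fails_complementarity(self, gate_a, gate_b):
        hybrid = GateSet(
            name="A_with_B_invader",
            protector=gate_a.protector,
            template=gate_a.template,
            invader=gate_b.invader,
        )
        report = verify_gate(hybrid)
        by_name = {c.name: c for c in report}
        assert not by_name["invader_full_complement"].passed
        # the oracle: brute-force pairing falls short of the template length
        assert brute_force_paired_count(
            gate_b.invader.sequence, gate_a.template.sequence
        ) < 38


class TestCrossReactivity:
    def test_printed_sets_are_orthogonal(self, gate_a, gate_b):
        report = cross_reactivity(gate_a, gate_b)
        assert len(report.per_pair_scores) == 9
        assert report.orthogonal
        assert not report.same_set_warning
        # exact agreement with the all-substrings oracle, pair by pair
        for score in report.per_pair_scores:
            strands = {s.name: s for s in gate_a.strands + gate_b.strands}
            expected = brute_force_longest_run(
                strands[score.strand_a].sequence, strands[score.strand_b].sequence
            )
            assert score.longest_complementary_run == expected

    def test_self_comparison_warns_and_finds_full_complement(self, gate_a):
        report = cross_reactivity(gate_a, gate_a)
        assert report.same_set_warning
        assert report.max_run == 38  # template vs invader

    def test_homopolymer_sets_score_zero(self):
        def homo(name, base):
            p = Strand(f"{name}_p", "protector", base * 20)
            t = Strand(f"{name}_t", "template", base * 28)
            i = Strand(f"{name}_i", "invader", _rc(base * 28))
            return GateSet(name=name, protector=p, template=t, invader=i)

        report = cross_reactivity(homo("polyA", "A"), homo("polyG", "G"))
        # only pairs not involving the (complementary) invaders can hit zero;
        # the max over A-side non-invader vs G-side non-invader pairs is 0
        scores = {
            (s.strand_a, s.strand_b): s.longest_complementary_run
            for s in report.per_pair_scores
        }
        assert scores[("polyA_t", "polyG_t")] == 0
        assert scores[("polyA_p", "polyG_p")] == 0

    @given(dna, dna)
    @settings(derandomize=True, max_examples=100)
    def test_run_score_matches_brute_force(self, a, b):
        run, _ = longest_complementary_run(a, b)
        assert run == brute_force_longest_run(a, b)


class TestParsing:
    GATE_FILE = [
        ">A_protector",
        "GCCTGCTTTATCTCTGTTCTACTATTTCCGTT/3AzideN/",
        ">A_template",
        "/5Alex647N/CGGAAATAGTAGAACAGAGATAAAGCAGGCAAACGAAA",
        ">A_invader",
        "TTTCGTTTGCCTGCTTTATCTCTGTTCTACTATTTCCG",
    ]

    def test_parse_idt_style_records(self, gate_a):
        sets = parse_gate_file(self.GATE_FILE)
        parsed = sets["A"]
        assert parsed.protector.sequence == gate_a.protector.sequence
        assert parsed.protector.linker == "TT"
        assert parsed.protector.three_prime_mod == "3AzideN"
        assert parsed.template.five_prime_mod == "5Alex647N"
        assert parsed.duplex_length == 30
        assert toehold_of(parsed).segment_sequence == "AAACGAAA"

    def test_lowercase_canonicalized_u_rejected(self):
        assert Strand("s", "invader", "acgt").sequence == "ACGT"
        with pytest.raises(InvalidAlphabetError):
            Strand("s", "invader", "ACGU")

    def test_missing_role_reported(self):
        with pytest.raises(ValueError, match="missing roles"):
            parse_gate_file([">A_protector", "ACGTACGTACGT"])
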