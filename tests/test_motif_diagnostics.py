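import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinscan.errors import ParseError, ValidationError
from kinscan.io_formats import AMINO_ACIDS, Msa, ProteinSequence
from kinscan.motif_diagnostics import (
    ABSENT,
    DiagnosticRule,
    MotifPattern,
    column_stats,
    default_rules,
    diagnose_tk,
    discover_group_specific_motifs,
    match_at,
    parse_pattern,
    read_rules,
    scan_window,
    write_rules,
)
from kinscan.profile_model import SubdomainAnchors

from .oracles import pattern_to_regex

LOG2_20 = math.log2(20)


class TestParsePattern:
    @pytest.mark.parametrize(
        "text,expected_len",
        [
            ("DL(R/A)A(A/R)N", 6),
            ("XP(I/V)(K/R)W(T/M)APE", 9),
            ("GXR(M/L)", 4),
            ("CW(X)6RPXF", 12),
            ("CW(X)_6_RPXF", 12),
        ],
    )
    def test_element_counts(self, text, expected_len):
        assert len(parse_pattern(text)) == expected_len

    def test_catalytic_loop_elements(self):
        p = parse_pattern("DL(R/A)A(A/R)N")
        assert p.elements == (
            frozenset("D"), frozenset("L"), frozenset("RA"),
            frozenset("A"), frozenset("AR"), frozenset("N"),
        )

    def test_repeat_expansion(self):
        p = parse_pattern("CW(X)6RPXF")
        assert p.elements[2:8] == (None,) * 6
        assert p.elements[8] == frozenset("R")

    @pytest.mark.parametrize("bad", ["DL(R/A", "A(B/1)N", "CW(X)0RPXF", "ab", "A-N"])
    def test_malformed_rejected_with_offset(self, bad):
        with pytest.raises(ParseError, match="offset"):
            parse_pattern(bad)

    def test_round_trip_through_text(self):
        for text in ("DL(R/A)A(A/R)N", "GXR(L/M)", "CW(X)6RPXF"):
            p = parse_pattern(text)
            assert parse_pattern(p.to_text()).elements == p.elements


class TestMatchAt:
    def test_catalytic_loop_instances(self):
        p = parse_pattern("DL(R/A)A(A/R)N")
        assert match_at(p, "DLRAAN")
        assert match_at(p, "DLAARN")  # every element within its allowed set
        assert not match_at(p, "DLRPAN")  # fixed position 4 requires A

    def test_gxr_motif_rejects_fslk_proline(self):
        p = parse_pattern("GXR(M/L)")
        assert match_at(p, "GARM")
        assert not match_at(p, "GARP")

    def test_wildcards_accept_everything(self):
        p = MotifPattern("w", (None, None, None))
        assert match_at(p, "XQW")

    def test_x_fails_fixed_and_set_elements(self):
        p = parse_pattern("GXR(M/L)")
        assert not match_at(p, "GAXM")  # X at fixed R
        assert not match_at(p, "GARX")  # X at allowed set

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            match_at(parse_pattern("GXR(M/L)"), "GAR")

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_regex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(2, 12))
        elements = []
        for _ in range(length):
            kind = rng.integers(3)
            if kind == 0:
                elements.append(None)
            else:
                k = 1 if kind == 1 else int(rng.integers(2, 4))
                picks = rng.choice(20, size=k, replace=False)
                elements.append(frozenset(AMINO_ACIDS[int(i)] for i in picks))
        pattern = MotifPattern("rand", tuple(elements))
        window = "".join(
            (AMINO_ACIDS + "X")[int(i)] for i in rng.integers(0, 21, size=length)
        )
        expected = pattern_to_regex(pattern).fullmatch(window) is not None
        assert match_at(pattern, window) is expected


class TestScanWindow:
    def _anchors(self, intervals):
        return SubdomainAnchors("s", dict(intervals))

    def test_motif_inside_window_found_at_position(self):
        seq = ProteinSequence("s", "AAAAAGARMAAAAA")
        anchors = self._anchors({"X": (4, 10)})
        assert scan_window(seq, anchors, parse_pattern("GXR(M/L)", "X")) == 5

    def test_motif_far_outside_window_missed(self):
        seq = ProteinSequence("s", "GARM" + "A" * 30)
        anchors = self._anchors({"X": (24, 30)})
        assert scan_window(seq, anchors, parse_pattern("GXR(M/L)", "X"), slack=5) is None

    def test_absent_subdomain(self):
        seq = ProteinSequence("s", "GARM")
        anchors = self._anchors({"X": None})
        assert scan_window(seq, anchors, parse_pattern("GXR(M/L)", "X")) is ABSENT


class TestDiagnoseTk:
    """Verdict logic on template sequences and all rule-outcome combinations."""

    def _tk_variant(self, templates, states):
        """TK consensus with each rule forced to pass/fail via its key site."""
        tk = templates["TK"]
        seq = list(tk.consensus)
        positions = {sd: start for _, sd, start in tk.planted_motifs}
        # key sites: motif1 element 3 (A->P), motif2 element 1 (P->V),
        # motif3 element 3 (M->P)
        fail_edits = {
            "motif1": (positions["VI"] + 3, "P"),
            "motif2": (positions["VIII"] + 1, "V"),
            "motif3": (next(s for i, sd, s in tk.planted_motifs if i == "GARM") + 3, "P"),
        }
        for rule_name, state in states.items():
            if state == "fail":
                pos, repl = fail_edits[rule_name]
                seq[pos] = repl
        return ProteinSequence("v", "".join(seq))

    def _full_anchors(self, templates, absent=()):
        intervals = {sd: iv for sd, iv in templates["TK"].subdomain_annotation.items()}
        for sd in absent:
            intervals[sd] = None
        return SubdomainAnchors("v", intervals)

    @pytest.mark.parametrize(
        "states",
        list(itertools.product(["pass", "fail", "absent"], repeat=3)),
        ids=lambda s: "-".join(s),
    )
    def test_verdict_is_pure_function_of_rule_outcomes(self, templates, states):
        names = ("motif1", "motif2", "motif3")
        state_map = dict(zip(names, states))
        subdomain_of = {"motif1": "VI", "motif2": "VIII", "motif3": "X"}
        absent = [subdomain_of[n] for n in names if state_map[n] == "absent"]
        seq = self._tk_variant(templates, state_map)
        anchors = self._full_anchors(templates, absent=absent)
        report = diagnose_tk(seq, anchors)
        if absent:
            assert report.verdict == "indeterminate"
        elif all(s == "pass" for s in states):
            assert report.verdict == "TK-like"
        else:
            assert report.verdict == "non-TK"

    def test_unmutated_tk_template_is_tk_like(self, templates):
        tk = templates["TK"]
        report = diagnose_tk(
            ProteinSequence("tk", tk.consensus), self._full_anchors(templates)
        )
        assert report.verdict == "TK-like"
        assert all(o.motif_found for o in report.outcomes)

    def test_fslk_template_fails_motif3_key(self, templates):
        fslk = templates["FslK"]
        anchors = SubdomainAnchors(
            "f", {sd: iv for sd, iv in fslk.subdomain_annotation.items()}
        )
        report = diagnose_tk(ProteinSequence("f", fslk.consensus), anchors)
        assert report.verdict == "non-TK"
        motif3 = next(o for o in report.outcomes if o.rule_name == "motif3")
        assert not motif3.motif_found
        assert ("motif3 fourth residue M/L", "fail") in motif3.key_checks

    def test_truncation_takes_precedence_over_failure(self, templates):
        seq = self._tk_variant(templates, {"motif1": "fail", "motif2": "pass", "motif3": "pass"})
        anchors = self._full_anchors(templates, absent=("X",))
        assert diagnose_tk(seq, anchors).verdict == "indeterminate"


class TestColumnStats:
    def test_conserved_column_full_information(self):
        stats = column_stats(Msa([("a", "D"), ("b", "D"), ("c", "D")]))
        assert stats[0].information_bits == pytest.approx(LOG2_20, abs=1e-9)

    def test_uniform_column_zero_information(self):
        rows = [(f"r{i}", aa) for i, aa in enumerate(AMINO_ACIDS)]
        stats = column_stats(Msa(rows))
        assert stats[0].information_bits == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_mixed_column(self):
        # {D x3, E x1}: H = -(0.75 log2 0.75 + 0.25 log2 0.25) = 0.8113
        rows = [("a", "D"), ("b", "D"), ("c", "D"), ("d", "E")]
        stats = column_stats(Msa(rows))
        assert stats[0].information_bits == pytest.approx(LOG2_20 - 0.8113, abs=1e-4)
        assert stats[0].information_bits == pytest.approx(3.5106, abs=1e-4)

    def test_small_sample_correction_subtracts(self):
        rows = [("a", "D"), ("b", "D"), ("c", "D"), ("d", "E")]
        plain = column_stats(Msa(rows))[0].information_bits
        corrected = column_stats(Msa(rows), small_sample_correction=True)[0].information_bits
        assert corrected == pytest.approx(plain - 19 / (2 * math.log(2) * 4), abs=1e-9)

    def test_all_gap_column_reported_none(self):
        stats = column_stats(Msa([("a", "-D"), ("b", "-D")]))
        assert stats[0] is None and stats[1] is not None

    def test_row_permutation_invariant(self):
        rows = [("a", "DKN"), ("b", "EKN"), ("c", "DRN")]
        forward = column_stats(Msa(rows))
        backward = column_stats(Msa(rows[::-1]))
        for f, b in zip(forward, backward):
            assert f.information_bits == pytest.approx(b.information_bits, abs=1e-12)

    def test_mixing_toward_uniform_never_increases_information(self):
        # progressively replace conserved D's with distinct other residues
        residues = "DDDDDDDDDD"
        others = "ACEFGHIKLM"
        previous = None
        for k in range(10):
            col = others[:k] + residues[k:]
            rows = [(f"r{i}", ch) for i, ch in enumerate(col)]
            ic = column_stats(Msa(rows))[0].information_bits
            if previous is not None:
                assert ic <= previous + 1e-12
            previous = ic


class TestDiscovery:
    def _group_msa(self, core, n_rows, prefix):
        # identical scaffold, differing only at the 4-residue core
        rows = [(f"{prefix}{i}", f"QQQQ{core}NNNN") for i in range(n_rows)]
        return Msa(rows)

    def test_planted_group_specific_motif_recovered(self):
        msa_a = self._group_msa("GARM", 8, "a")
        msa_b = self._group_msa("GSKP", 8, "b")
        hits = discover_group_specific_motifs(msa_a, msa_b, width=4)
        specific = [h for h in hits if h.specific]
        assert specific, "planted motif not recovered"
        best = max(specific, key=lambda h: h.in_group_match_fraction)
        assert best.in_group_match_fraction == 1.0
        assert best.out_group_match_fraction == 0.0

    def test_shared_motif_not_specific(self):
        msa_a = self._group_msa("GARM", 8, "a")
        msa_b = self._group_msa("GARM", 8, "b")
        hits = discover_group_specific_motifs(msa_a, msa_b, width=4)
        assert hits and all(not h.specific for h in hits)
        assert all(h.out_group_match_fraction == 1.0 for h in hits)

    def test_single_row_target_every_window_consensus(self):
        msa_a = Msa([("a", "QQGARMNN")])
        msa_b = self._group_msa("GARM", 4, "b")[0:1] if False else self._group_msa("GSKP", 4, "b")
        msa_b = Msa([(i, r[:8]) for i, r in msa_b.rows])
        hits = discover_group_specific_motifs(msa_a, msa_b, width=4, max_set_size=2)
        assert all(h.in_group_match_fraction == 1.0 for h in hits)

    def test_swapping_groups_flips_shared_motif_fractions(self):
        msa_a = self._group_msa("GARM", 8, "a")
        msa_b = self._group_msa("GARM", 8, "b")
        ab = discover_group_specific_motifs(msa_a, msa_b, width=4)
        ba = discover_group_specific_motifs(msa_b, msa_a, width=4)
        assert [(h.start_column, h.specific) for h in ab] == [
            (h.start_column, h.specific) for h in ba
        ]

    def test_width_larger_than_alignment_rejected(self):
        msa = self._group_msa("GARM", 3, "a")
        with pytest.raises(ValidationError):
            discover_group_specific_motifs(msa, msa, width=msa.ncol + 1)


def test_rules_config_round_trip(tmp_path):
    rules = default_rules()
    path = tmp_path / "rules.txt"
    write_rules(rules, path)
    loaded = read_rules(path)
    assert len(loaded) == len(rules)
    for lr, r in zip(loaded, rules):
        assert lr.motif.elements == r.motif.elements
        assert lr.motif.subdomain == r.motif.subdomain
        assert [(i, a) for i, a, _ in lr.key_positions] == [
            (i, a) for i, a, _ in r.key_positions
        ]
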