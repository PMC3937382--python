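import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinscan.errors import DegenerateAlignmentError, UnanchorableError, ValidationError
from kinscan.io_formats import Msa, ProteinSequence
from kinscan.profile_model import (
    build_profile,
    anchor_subdomains,
    encode,
    read_profile,
    rescaled,
    score_local,
    score_only,
    trim_columns,
    write_profile,
)

from .conftest import random_profile, random_sequence
from .oracles import brute_force_local_score

LOG2_20 = math.log2(20)


class TestTrimColumns:
    def test_gapless_unchanged(self):
        msa = Msa([("a", "DLRAAN"), ("b", "DLKAAN")])
        assert trim_columns(msa, 0.5).rows == msa.rows

    def test_all_gap_column_removed(self):
        msa = Msa([("a", "DL-AAN"), ("b", "DL-AAN")])
        assert trim_columns(msa, 0.99).ncol == 5

    def test_quarter_gap_threshold_boundary(self):
        # one column with gap fraction exactly 0.25 (1 gap in 4 rows)
        msa = Msa([("a", "D-A"), ("b", "DKA"), ("c", "DKA"), ("d", "DKA")])
        assert trim_columns(msa, 0.25).ncol == 3
        assert trim_columns(msa, 0.20).ncol == 2

    def test_all_removed_is_degenerate(self):
        msa = Msa([("a", "--"), ("b", "AA")])
        with pytest.raises(DegenerateAlignmentError):
            trim_columns(msa, 0.4)

    def test_idempotent(self):
        msa = Msa([("a", "D-RA-N"), ("b", "DLRAAN"), ("c", "DLR--N")])
        once = trim_columns(msa, 0.34)
        assert trim_columns(once, 0.34).rows == once.rows

    def test_annotation_remapped(self):
        msa = Msa(
            [("a", "D--RAAN"), ("b", "D--KAAN")],
            subdomain_annotation={"I": (0, 3), "II": (3, 7)},
        )
        trimmed = trim_columns(msa, 0.4)
        assert trimmed.subdomain_annotation == {"I": (0, 1), "II": (1, 5)}


class TestBuildProfile:
    def test_single_seed_alpha_to_zero_scores_log2_20(self):
        profile = build_profile(Msa([("a", "DLRAAN")]), pseudocount_weight=1e-9)
        codes = encode("DLRAAN")
        for c, code in enumerate(codes):
            assert profile.log_odds[c, code] == pytest.approx(LOG2_20, abs=1e-6)

    def test_background_matching_column_scores_zero(self):
        # 20 rows, one of each residue: empirical distribution == background
        rows = [(f"r{i}", aa) for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")]
        profile = build_profile(Msa(rows), pseudocount_weight=3.7)
        assert np.allclose(profile.log_odds[0, :20], 0.0, atol=1e-12)

    def test_two_row_pseudocount_hand_value(self):
        # column {D, D}, alpha=1, uniform background: log2((2.05/3)/0.05)
        profile = build_profile(Msa([("a", "D"), ("b", "D")]), pseudocount_weight=1.0)
        expected = math.log2((2.05 / 3.0) / 0.05)
        assert profile.log_odds[0, encode("D")[0]] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(3.7726, abs=1e-4)

    def test_empty_column_directs_to_trim(self):
        msa = Msa([("a", "D-N"), ("b", "D-N")])
        with pytest.raises(DegenerateAlignmentError, match="trim"):
            build_profile(msa)

    def test_x_scores_zero_everywhere(self):
        profile = build_profile(Msa([("a", "DLRAAN")]))
        assert np.all(profile.log_odds[:, 20] == 0.0)


class TestScoreLocal:
    def test_consensus_of_single_seed_scores_column_sum(self):
        profile = build_profile(Msa([("a", "DLRAAN")]), pseudocount_weight=1e-9)
        result = score_local(profile, ProteinSequence("q", "DLRAAN"))
        assert result.score_bits == pytest.approx(6 * LOG2_20, abs=1e-6)
        assert result.seq_interval == (0, 6)
        assert result.profile_interval == (0, 6)
        assert result.column_map == [(i, i) for i in range(6)]

    def test_empty_profile_or_no_positive_score(self):
        profile = build_profile(Msa([("a", "DLRAAN")]), pseudocount_weight=1e-9)
        result = score_local(profile, ProteinSequence("q", "X"))
        assert result.score_bits == 0.0 and result.column_map == []

    def test_score_recomputes_from_trace(self, template_profiles):
        """The reported score equals matched log-odds minus gap penalties."""
        profile = template_profiles["TK"]
        rng = np.random.default_rng(5)
        from kinscan.synthetic_data import mutate_sequence

        seq = ProteinSequence("m", mutate_sequence(profile.consensus(), 0.2, 0.05, 2.0, rng))
        result = score_local(profile, seq)
        codes = encode(seq.residues)
        total = 0.0
        prev_col, prev_idx = None, None
        for col, idx in result.column_map:
            total += profile.log_odds[col, codes[idx]]
            if prev_col is not None:
                dcol, didx = col - prev_col - 1, idx - prev_idx - 1
                if dcol:
                    total -= profile.gap_open + (dcol - 1) * profile.gap_extend
                if didx:
                    total -= profile.gap_open + (didx - 1) * profile.gap_extend
            prev_col, prev_idx = col, idx
        assert result.score_bits == pytest.approx(total, abs=1e-6)

    def test_column_map_strictly_increasing(self, template_profiles):
        rng = np.random.default_rng(11)
        seq = random_sequence(rng, 120)
        result = score_local(template_profiles["TK"], seq)
        for (c0, i0), (c1, i1) in zip(result.column_map, result.column_map[1:]):
            assert c1 > c0 and i1 > i0

    def test_matches_bruteforce_oracle_small_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            profile = random_profile(rng, int(rng.integers(1, 11)))
            seq = random_sequence(rng, int(rng.integers(0, 13)))
            expected = brute_force_local_score(
                profile.log_odds.tolist(), profile.gap_open, profile.gap_extend,
                encode(seq.residues).tolist(),
            )
            expected = max(expected, 0.0)
            assert score_only(profile, seq) == pytest.approx(expected, abs=1e-9)
            assert score_local(profile, seq).score_bits == pytest.approx(expected, abs=1e-9)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 8.0))
    def test_rescaling_multiplies_scores(self, seed, k):
        """Multiplying scores and penalties by k > 0 scales every optimal score."""
        rng = np.random.default_rng(seed)
        profile = random_profile(rng, int(rng.integers(2, 9)))
        seq = random_sequence(rng, int(rng.integers(1, 12)))
        base = score_only(profile, seq)
        scaled = score_only(rescaled(profile, k), seq)
        assert scaled == pytest.approx(k * base, rel=1e-9, abs=1e-9)

    def test_consensus_optimality_single_seed(self):
        """With a near-zero pseudocount, no sequence outscores the consensus."""
        profile = build_profile(Msa([("a", "DLRAANWTAPE")]), pseudocount_weight=1e-9)
        consensus_score = score_only(profile, "DLRAANWTAPE")
        rng = np.random.default_rng(3)
        for _ in range(50):
            other = random_sequence(rng, int(rng.integers(1, 20)))
            assert score_only(profile, other) <= consensus_score + 1e-9

    def test_seed_rows_score_positive(self):
        rows = [("a", "DLRAANW"), ("b", "DLKAANW"), ("c", "DLRPANW")]
        profile = build_profile(Msa(rows), pseudocount_weight=0.01)
        for _, row in rows:
            assert score_only(profile, row) > 0.0


class TestAnchorSubdomains:
    def test_reference_consensus_maps_identically(self, templates, template_profiles):
        tk = templates["TK"]
        anchors = anchor_subdomains(
            template_profiles["TK"], ProteinSequence("c", tk.consensus)
        )
        assert anchors.intervals == {sd: iv for sd, iv in tk.subdomain_annotation.items()}

    def test_insertion_shifts_downstream_subdomains(self, templates, template_profiles):
        tk = templates["TK"]
        ann = tk.subdomain_annotation
        cut = (ann["II"][1] + ann["III"][0]) // 2  # between subdomains II and III
        seq = ProteinSequence("ins", tk.consensus[:cut] + "WWW" + tk.consensus[cut:])
        anchors = anchor_subdomains(template_profiles["TK"], seq)
        for sd in ("I", "II"):
            assert anchors.intervals[sd] == ann[sd]
        for sd in ("III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI"):
            s, e = ann[sd]
            assert anchors.intervals[sd] == (s + 3, e + 3)

    def test_unrelated_sequence_unanchorable(self, template_profiles):
        with pytest.raises(UnanchorableError):
            anchor_subdomains(template_profiles["TK"], ProteinSequence("a", "A" * 50))

    def test_truncated_sequence_missing_tail_subdomains(self, templates, template_profiles):
        tk = templates["TK"]
        cut = tk.subdomain_annotation["VIII"][0]
        anchors = anchor_subdomains(template_profiles["TK"], ProteinSequence("t", tk.consensus[:cut]))
        assert anchors.intervals["X"] is None and anchors.intervals["XI"] is None
        assert anchors.intervals["VI"] is not None
        assert not anchors.complete()


def test_profile_serialization_round_trip(tmp_path, template_profiles):
    profile = template_profiles["TK"]
    path = tmp_path / "tk.profile"
    write_profile(profile, path)
    loaded = read_profile(path)
    assert loaded.name == profile.name
    assert loaded.subdomains == profile.subdomains
    assert np.allclose(loaded.log_odds, profile.log_odds, atol=1e-9)
    assert (loaded.gap_open, loaded.gap_extend, loaded.cutoff_bits) == (
        profile.gap_open, profile.gap_extend, profile.cutoff_bits,
    )


def test_profile_reader_rejects_unknown_version(tmp_path):
    path = tmp_path / "bad.profile"
    path.write_text("#kinscan-profile v99\nname\tx\n")
    with pytest.raises(ValidationError, match="version"):
        read_profile(path)
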