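"""Motif grammar, forward/reverse scanning, windows, and status calls."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbh3kit.formats import AMINO_ACIDS, Alignment, ProteinSequence
from rbh3kit.motifs import (
    BH3_LIKE_L_PATTERN,
    BH3_PATTERN,
    HYDROPHOBIC,
    MotifGrammarError,
    MotifStatus,
    MotifWindow,
    Orientation,
    assess_rbh3_status,
    clade_motif_summary,
    compile_motif,
    extract_window,
    scan_forward,
    scan_reverse,
    window_annotations,
)

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


def naive_scan(text: str, motif, reverse: bool = False):
    """Position-by-position membership oracle."""
    L = len(motif)
    hits = []
    for i in range(len(text) - L + 1):
        window = text[i:i + L]
        probe = window[::-1] if reverse else window
        if all(probe[k] in tok for k, tok in enumerate(motif.tokens)):
            hits.append((i, i + L))
    return hits


class TestCompile:
    def test_bh3_consensus_expands_to_12_tokens(self):
        motif = compile_motif(BH3_PATTERN)
        assert len(motif) == 12
        assert motif.tokens[4] == frozenset("L")
        assert motif.tokens[8] == frozenset("G")
        assert motif.tokens[9] == frozenset("D")
        assert motif.tokens[0] == HYDROPHOBIC

    def test_bh3_like_expands_to_6_tokens(self):
        assert len(compile_motif(BH3_LIKE_L_PATTERN)) == 6

    def test_bracket_alternatives_and_h_alias(self):
        motif = compile_motif("[DE]-h-X")
        assert motif.tokens[0] == frozenset("DE")
        assert motif.tokens[1] == HYDROPHOBIC

    @pytest.mark.parametrize("bad", ["X(0)", "Z", "Φ(", "[*]-X", ""])
    def test_malformed_tokens_rejected(self, bad):
        with pytest.raises(MotifGrammarError):
            compile_motif(bad)


class TestScan:
    def test_constructed_forward_hit(self):
        seq = ProteinSequence("s", "LAAALAALGDAL")
        hits = scan_forward(seq, compile_motif(BH3_PATTERN, "BH3"))
        assert [(h.start, h.end) for h in hits] == [(0, 12)]
        assert hits[0].orientation is Orientation.FORWARD

    def test_fixed_residue_violation_kills_hit(self):
        seq = ProteinSequence("s", "LAAALAALGEAL")  # D -> E at the fixed D
        assert scan_forward(seq, compile_motif(BH3_PATTERN)) == []

    def test_reverse_hit_of_mirrored_sequence(self):
        seq = ProteinSequence("s", "LADGLAALAAAL")
        hits = scan_reverse(seq, compile_motif(BH3_PATTERN, "BH3"))
        assert [(h.start, h.end) for h in hits] == [(0, 12)]
        assert hits[0].orientation is Orientation.REVERSE

    def test_gaps_stripped_before_scanning(self):
        plain = ProteinSequence("s", "LAAALAALGDAL")
        gapped = ProteinSequence("s", "LA--AALAA-LGDAL")
        motif = compile_motif(BH3_PATTERN)
        assert [(h.start, h.end) for h in scan_forward(gapped, motif)] == [
            (h.start, h.end) for h in scan_forward(plain, motif)
        ]

    def test_composite_sequence_reports_both_orientations(self):
        text = "LAAALAALGDAL" + "KKK" + "LADGLAALAAAL"
        seq = ProteinSequence("s", text)
        motif = compile_motif(BH3_PATTERN)
        fwd = scan_forward(seq, motif)
        rev = scan_reverse(seq, motif)
        assert (0, 12) in [(h.start, h.end) for h in fwd]
        assert (15, 27) in [(h.start, h.end) for h in rev]

    @given(seq_strategy)
    @settings(max_examples=200, deadline=None)
    def test_matches_naive_oracle_both_orientations(self, text):
        seq = ProteinSequence("s", text)
        motif = compile_motif(BH3_LIKE_L_PATTERN)
        assert [(h.start, h.end) for h in scan_forward(seq, motif)] == naive_scan(
            text, motif
        )
        assert [(h.start, h.end) for h in scan_reverse(seq, motif)] == naive_scan(
            text, motif, reverse=True
        )

    @given(seq_strategy)
    @settings(max_examples=100, deadline=None)
    def test_mirror_identity(self, text):
        """reverse-scan(s) == mirror of forward-scan(reversed s)."""
        motif = compile_motif(BH3_LIKE_L_PATTERN)
        seq = ProteinSequence("s", text)
        mirrored = ProteinSequence("s", text[::-1])
        n = len(text)
        expected = sorted(
            (n - h.end, n - h.start) for h in scan_forward(mirrored, motif)
        )
        assert [(h.start, h.end) for h in scan_reverse(seq, motif)] == expected


class TestExtractWindow:
    def _alignment(self, width=30, n=3):
        return Alignment(
            [ProteinSequence(f"s{i}", AMINO_ACIDS[i] * width) for i in range(n)]
        )

    def test_centered_window_columns(self):
        win = extract_window(self._alignment(), 8, "s0")
        assert len(win.residues) == 18
        assert win.residues == "A" * 18  # columns 0..17 of an all-A row

    def test_left_boundary_padded(self):
        win = extract_window(self._alignment(), 2, "s0")
        assert win.residues.startswith("------")
        assert len(win.residues) == 18

    def test_unknown_sequence_rejected(self):
        with pytest.raises(KeyError):
            extract_window(self._alignment(), 8, "ghost")

    @given(st.integers(0, 29))
    @settings(max_examples=30, deadline=None)
    def test_window_length_always_18(self, anchor):
        win = extract_window(self._alignment(), anchor, "s1")
        assert len(win.residues) == 18


def build_window(acid: str, hyd1: str, hyd2: str, filler: str = "SGNTQRH") -> str:
    """18-mer with chosen residues at positions 8, 10, 13 (1-based)."""
    chars = list("SGNTQRHxGxQRxDTSKN")
    chars[7], chars[9], chars[12] = acid, hyd1, hyd2
    return "".join(chars)


class TestStatus:
    def test_intact_canonical_triple(self):
        win = MotifWindow("s", build_window("E", "L", "M"), 8)
        assert assess_rbh3_status(win) is MotifStatus.INTACT

    def test_aspartate_counts_as_intact_with_variant_flag(self):
        win = MotifWindow("s", build_window("D", "L", "V"), 8)
        assert assess_rbh3_status(win) is MotifStatus.INTACT
        assert "E->D" in window_annotations(win)

    def test_shifted_triple_at_minus_one(self):
        chars = list("SGNTQRELGLQMXDTSKN".replace("X", "S"))
        # triple at 7/9/12: E, L, M; position 8 must not be acidic
        chars[6], chars[8], chars[11] = "E", "L", "M"
        chars[7], chars[9], chars[12] = "G", "Q", "S"
        win = MotifWindow("s", "".join(chars), 8)
        assert assess_rbh3_status(win) is MotifStatus.SHIFTED

    def test_alanine_ablation_is_lost(self):
        win = MotifWindow("s", build_window("A", "L", "M"), 8)
        assert assess_rbh3_status(win) is MotifStatus.LOST

    def test_lost_takes_precedence_over_bh3_like(self):
        # A at 8 and a forward BH3-like motif both present -> lost
        residues = "SGLKRIAEGSRTDTSKNG"  # L..I..E forward match at 3..8
        chars = list(residues)
        chars[7] = "A"
        win = MotifWindow("s", "".join(chars), 8)
        assert win.residues[7] == "A"
        assert assess_rbh3_status(win) is MotifStatus.LOST

    def test_forward_bh3_like_when_triple_fails(self):
        win = MotifWindow("s", "SGLKRIDEGSRTDTSKNG", 8)
        assert assess_rbh3_status(win) is MotifStatus.BH3_LIKE

    def test_absent_when_nothing_matches(self):
        win = MotifWindow("s", "SGNTQRHGGSRTSDTSKN", 8)
        assert assess_rbh3_status(win) is MotifStatus.ABSENT

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError, match="18"):
            MotifWindow("s", "SHORT", 8)

    def test_decision_table_enumeration(self):
        """Status precedence over the full {E,D,A,G} x {L,G} x {M,G} grid."""
        for acid, h1, h2 in itertools.product("EDAG", "LG", "MG"):
            win = MotifWindow("s", build_window(acid, h1, h2), 8)
            status = assess_rbh3_status(win)
            if acid in "ED" and h1 == "L" and h2 == "M":
                assert status is MotifStatus.INTACT
            elif acid == "A":
                assert status is MotifStatus.LOST
            else:
                # no shifted triple or forward motif in this scaffold
                assert status in (MotifStatus.ABSENT, MotifStatus.BH3_LIKE)


class TestCladeSummary:
    def test_recovers_synthetic_truth(self, default_family):
        aln, truth = default_family
        table = clade_motif_summary(aln, anchor_column=truth.anchor_column)
        from collections import Counter

        expected = Counter(
            (truth.clade_labels[leaf], status.value)
            for leaf, status in truth.statuses.items()
        )
        for (clade, status), count in expected.items():
            assert table.loc[clade, status] == count
        assert int(table.to_numpy().sum()) == aln.n_rows

    def test_single_clade_all_intact(self):
        rows = [
            ProteinSequence(f"s{i}", build_window("E", "L", "M"))
            for i in range(4)
        ]
        aln = Alignment(rows, {r.id: "Mammalia" for r in rows})
        table = clade_motif_summary(aln, anchor_column=8)
        assert table.loc["Mammalia", "intact"] == 4

    def test_counts_partition_each_clade(self, default_family):
        aln, truth = default_family
        table = clade_motif_summary(aln, anchor_column=truth.anchor_column)
        from collections import Counter

        sizes = Counter(truth.clade_labels.values())
        for clade, size in sizes.items():
            assert int(table.loc[clade].sum()) == size

    def test_unlabeled_rows_rejected(self):
        rows = [ProteinSequence("a", build_window("E", "L", "M"))]
        aln = Alignment(rows)
        with pytest.raises(ValueError, match="a"):
            clade_motif_summary(aln, anchor_column=8)

    def test_empty_clade_reports_zero_row(self):
        rows = [ProteinSequence("a", build_window("E", "L", "M"))]
        aln = Alignment(rows, {"a": "Mammalia"})
        table = clade_motif_summary(aln, anchor_column=8, clades=["Aves"])
        assert int(table.loc["Aves"].sum()) == 0
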