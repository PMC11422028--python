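"""Context extraction, labeling, paralog alignment/imputation, encoding."""

import numpy as np
import pytest

from polyx_ppi.dataset import (
    ContextRow,
    LABEL_INTERACTING,
    LABEL_UNKNOWN,
    PROVENANCE_DIRECT,
    PROVENANCE_PARALOG,
    align_paralogs,
    build_context_rows,
    cc_overlap_flags,
    encode,
    extract_context,
    impute_paralog_positives,
    label_by_overlap,
    position_code,
    raw_variable_count,
    signed_positions,
)
from polyx_ppi.detection import HomorepeatRegion
from polyx_ppi.io_formats import (
    AnnotatedRegion,
    PAD_SYMBOL,
    ParalogPair,
    ProteinRecord,
    RegionKind,
)


def _region(pid, start, end, target="Q"):
    return HomorepeatRegion(pid, target, start, end, end - start + 1, end - start + 1)


class TestExtractContext:
    def test_terminal_repeat_is_all_padding(self):
        rec = ProteinRecord("P1", "QQQQQQ")
        symbols = extract_context(rec, _region("P1", 1, 6), 10, 10)
        assert set(symbols.values()) == {PAD_SYMBOL}
        assert len(symbols) == 20

    def test_direct_indexing(self):
        rec = ProteinRecord("P1", "MKQQQQGPA")
        symbols = extract_context(rec, _region("P1", 3, 6), 2, 2)
        assert symbols == {-2: "M", -1: "K", 1: "G", 2: "P"}

    def test_matches_naive_string_lookup_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(200):
            n = int(rng.integers(20, 60))
            seq = "".join(aa[j] for j in rng.integers(0, 20, size=n))
            start = int(rng.integers(1, n - 3))
            end = min(n, start + int(rng.integers(0, 6)))
            rec = ProteinRecord("P", seq)
            symbols = extract_context(rec, _region("P", start, end), 10, 10)
            for k in range(1, 11):
                want_m = seq[start - k - 1] if start - k >= 1 else PAD_SYMBOL
                want_p = seq[end + k - 1] if end + k <= n else PAD_SYMBOL
                assert symbols[-k] == want_m
                assert symbols[k] == want_p

    def test_nonstandard_letters_map_to_padding(self):
        rec = ProteinRecord("P1", "XUQQQQBZ")
        symbols = extract_context(rec, _region("P1", 3, 6), 2, 2)
        assert symbols == {-2: PAD_SYMBOL, -1: PAD_SYMBOL, 1: PAD_SYMBOL, 2: PAD_SYMBOL}

    def test_out_of_bounds_region_raises(self):
        rec = ProteinRecord("P1", "MKQ")
        with pytest.raises(ValueError, match="out of bounds"):
            extract_context(rec, _region("P1", 2, 9), 2, 2)

    def test_wrong_protein_raises(self):
        rec = ProteinRecord("P1", "MKQQQQ")
        with pytest.raises(ValueError, match="belong"):
            extract_context(rec, _region("P2", 3, 6), 2, 2)


class TestLabelByOverlap:
    def test_one_residue_overlap_is_interacting(self):
        labels = label_by_overlap(
            [_region("P1", 10, 20)],
            [AnnotatedRegion("P1", 20, 30, RegionKind.INTERACTION)],
        )
        assert labels == [LABEL_INTERACTING]

    def test_adjacent_without_overlap_is_unknown(self):
        labels = label_by_overlap(
            [_region("P1", 10, 20)],
            [AnnotatedRegion("P1", 21, 30, RegionKind.INTERACTION)],
        )
        assert labels == [LABEL_UNKNOWN]

    def test_other_protein_does_not_label(self):
        labels = label_by_overlap(
            [_region("P1", 10, 20)],
            [AnnotatedRegion("P2", 10, 20, RegionKind.INTERACTION)],
        )
        assert labels == [LABEL_UNKNOWN]

    def test_labeling_is_monotone_in_interfaces(self):
        regions = [_region("P1", 10, 20), _region("P2", 5, 9)]
        some = [AnnotatedRegion("P1", 15, 40, RegionKind.INTERACTION)]
        more = some + [AnnotatedRegion("P2", 1, 5, RegionKind.INTERACTION)]
        before = label_by_overlap(regions, some)
        after = label_by_overlap(regions, more)
        for b, a in zip(before, after):
            assert not (b == LABEL_INTERACTING and a == LABEL_UNKNOWN)

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            label_by_overlap(
                [_region("P1", 1, 4)],
                [AnnotatedRegion("P1", 1, 4, RegionKind.COILED_COIL)],
            )


class TestCcOverlapFlags:
    def test_no_coiled_coils_all_false(self):
        rec = ProteinRecord("P1", "M" * 30)
        flags = cc_overlap_flags(rec, _region("P1", 11, 16), [], 10, 10)
        assert not any(flags.values())

    def test_cc_spanning_downstream_context(self):
        rec = ProteinRecord("P1", "M" * 40)
        cc = [AnnotatedRegion("P1", 17, 26, RegionKind.COILED_COIL)]
        flags = cc_overlap_flags(rec, _region("P1", 11, 16), cc, 10, 10)
        assert all(flags[k] for k in range(1, 11))
        assert not any(flags[-k] for k in range(1, 11))

    def test_padding_positions_are_false(self):
        rec = ProteinRecord("P1", "M" * 12)
        cc = [AnnotatedRegion("P1", 1, 12, RegionKind.COILED_COIL)]
        flags = cc_overlap_flags(rec, _region("P1", 3, 8), cc, 10, 10)
        assert flags[5] is False  # beyond the C-terminus
        assert flags[4] is True

    def test_matches_membership_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(30, 80))
            rec = ProteinRecord("P", "L" * n)
            start = int(rng.integers(5, n - 10))
            end = start + int(rng.integers(0, 5))
            ccs = [
                AnnotatedRegion(
                    "P", s, min(n, s + int(rng.integers(0, 15))), RegionKind.COILED_COIL
                )
                for s in rng.integers(1, n, size=3).tolist()
            ]
            flags = cc_overlap_flags(rec, _region("P", start, end), ccs, 10, 10)
            for pos in signed_positions(10, 10):
                idx = start + pos if pos < 0 else end + pos
                want = 1 <= idx <= n and any(c.start <= idx <= c.end for c in ccs)
                assert flags[pos] == want


class TestAlignParalogs:
    def test_identical_sequences_identity_map(self):
        a = ProteinRecord("A", "MKQQQQGPAW")
        b = ProteinRecord("B", "MKQQQQGPAW")
        aln = align_paralogs(a, b)
        assert aln.a_to_b == {i: i for i in range(1, 11)}

    def test_insertion_maps_within_block(self):
        # verified against exhaustive DP on these tiny sequences: the four
        # Qs of A align inside B's five-residue Q block
        a = ProteinRecord("A", "WQQQQW")
        b = ProteinRecord("B", "WQQAQQW")
        aln = align_paralogs(a, b)
        mapped = [aln.a_to_b.get(i) for i in range(2, 6)]
        assert all(m is None or 2 <= m <= 6 for m in mapped)
        assert sum(m is not None for m in mapped) == 4

    def test_score_symmetric(self):
        a = ProteinRecord("A", "MKQQLPGA")
        b = ProteinRecord("B", "MKQLPGAW")
        assert align_paralogs(a, b).score == align_paralogs(b, a).score

    def test_map_strictly_increasing(self):
        a = ProteinRecord("A", "MKQQQQGPAWLVST")
        b = ProteinRecord("B", "MKQQGPAWSTLVST")
        aln = align_paralogs(a, b)
        items = sorted(aln.a_to_b.items())
        values = [v for _, v in items]
        assert values == sorted(values)
        assert len(set(values)) == len(values)


def _row(pid, start, end, label=LABEL_UNKNOWN, provenance=None, target="Q"):
    region = _region(pid, start, end, target)
    return ContextRow(
        region=region,
        flank_symbols={-1: "L", 1: "L"},
        repeat_length=region.length,
        label=label,
        provenance=provenance,
    )


class TestImputeParalogPositives:
    def test_identity_paralog_imputes(self):
        seqs = {
            "A": ProteinRecord("A", "LLLLQQQQLLLL"),
            "B": ProteinRecord("B", "LLLLQQQQLLLL"),
        }
        rows = [
            _row("A", 5, 8),
            _row("B", 5, 8, LABEL_INTERACTING, PROVENANCE_DIRECT),
        ]
        n = impute_paralog_positives(rows, [ParalogPair("A", "B")], seqs)
        assert n == 1
        assert rows[0].label == LABEL_INTERACTING
        assert rows[0].provenance == PROVENANCE_PARALOG

    def test_gap_alignment_blocks_imputation(self):
        # B's positive repeat has no counterpart in A: aligned entirely to a gap
        seqs = {
            "A": ProteinRecord("A", "MKWLVSTFEYHRNDCI"),
            "B": ProteinRecord("B", "MKWLVSTQQQQFEYHRNDCI"),
        }
        rows = [
            _row("A", 1, 2),  # unrelated repeat far from the gap
            _row("B", 8, 11, LABEL_INTERACTING, PROVENANCE_DIRECT),
        ]
        n = impute_paralog_positives(rows, [ParalogPair("A", "B")], seqs)
        assert n == 0
        assert rows[0].label == LABEL_UNKNOWN

    def test_target_type_must_match(self):
        seqs = {
            "A": ProteinRecord("A", "LLLLQQQQLLLL"),
            "B": ProteinRecord("B", "LLLLQQQQLLLL"),
        }
        rows = [
            _row("A", 5, 8, target="A"),
            _row("B", 5, 8, LABEL_INTERACTING, PROVENANCE_DIRECT, target="Q"),
        ]
        assert impute_paralog_positives(rows, [ParalogPair("A", "B")], seqs) == 0

    def test_idempotent_and_direct_never_downgraded(self):
        seqs = {
            "A": ProteinRecord("A", "LLLLQQQQLLLL"),
            "B": ProteinRecord("B", "LLLLQQQQLLLL"),
        }
        rows = [
            _row("A", 5, 8),
            _row("B", 5, 8, LABEL_INTERACTING, PROVENANCE_DIRECT),
        ]
        pairs = [ParalogPair("A", "B")]
        assert impute_paralog_positives(rows, pairs, seqs) == 1
        assert impute_paralog_positives(rows, pairs, seqs) == 0
        assert rows[1].provenance == PROVENANCE_DIRECT

    def test_unknown_protein_skipped_with_warning(self, caplog):
        seqs = {"A": ProteinRecord("A", "LLLLQQQQLLLL")}
        rows = [_row("A", 5, 8)]
        with caplog.at_level("WARNING"):
            n = impute_paralog_positives(rows, [ParalogPair("A", "Z")], seqs)
        assert n == 0
        assert "unknown protein" in caplog.text

    def test_fixture_with_known_imputable_set(self, small_fixture):
        from polyx_ppi.detection import DetectorConfig, detect_all

        fx = small_fixture
        regions = detect_all(fx.records, DetectorConfig("Q"))
        rows = build_context_rows(fx.records_by_id, regions, fx.interfaces, 6, 6)
        n = impute_paralog_positives(rows, fx.pairs, fx.records_by_id)
        expected = sum(t.imputable for t in fx.truth)
        assert expected > 0
        assert n == expected
        imputed_ids = {
            r.region.protein_id for r in rows if r.provenance == PROVENANCE_PARALOG
        }
        assert imputed_ids == {t.protein_id for t in fx.truth if t.imputable}

    def test_no_positives_in_proteins_without_paralogs(self, small_fixture):
        from polyx_ppi.detection import DetectorConfig, detect_all

        fx = small_fixture
        regions = detect_all(fx.records, DetectorConfig("Q"))
        rows = build_context_rows(fx.records_by_id, regions, fx.interfaces, 6, 6)
        paired = {p.protein_id_a for p in fx.pairs} | {
            p.protein_id_b for p in fx.pairs
        }
        impute_paralog_positives(rows, fx.pairs, fx.records_by_id)
        for row in rows:
            if row.provenance == PROVENANCE_PARALOG:
                assert row.region.protein_id in paired


class TestEncode:
    def _rows(self, n_ctx, with_cc, n=5):
        rng = np.random.default_rng(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        rows = []
        for i in range(n):
            positions = signed_positions(n_ctx, n_ctx)
            rows.append(
                ContextRow(
                    region=_region(f"P{i}", 20, 25),
                    flank_symbols={p: aa[int(rng.integers(0, 20))] for p in positions},
                    repeat_length=6,
                    cc_flags=(
                        {p: bool(rng.integers(0, 2)) for p in positions}
                        if with_cc
                        else None
                    ),
                    label=LABEL_INTERACTING if i % 2 else LABEL_UNKNOWN,
                )
            )
        return rows

    def test_polyq_final_model_has_25_raw_variables(self):
        assert raw_variable_count(6, 6, with_cc=True) == 25

    def test_polya_final_model_has_41_raw_variables(self):
        assert raw_variable_count(10, 10, with_cc=True) == 41

    def test_context_alphabet_has_21_symbols(self):
        from polyx_ppi.io_formats import CONTEXT_ALPHABET

        assert len(CONTEXT_ALPHABET) == 21
        assert len(set(CONTEXT_ALPHABET)) == 21

    @pytest.mark.parametrize("n_ctx,with_cc", [(6, True), (10, True), (10, False)])
    def test_encoded_column_count(self, n_ctx, with_cc):
        matrix = encode(self._rows(n_ctx, with_cc))
        expected = 2 * n_ctx * 21 + 1 + (2 * n_ctx if with_cc else 0)
        assert matrix.n_features == expected
        assert len(matrix.feature_names) == expected

    def test_indicator_groups_sum_to_one(self):
        matrix = encode(self._rows(6, True))
        for pos_block in range(12):
            block = matrix.X[:, pos_block * 21 : (pos_block + 1) * 21]
            assert np.all(block.sum(axis=1) == 1.0)

    def test_feature_name_convention(self):
        matrix = encode(self._rows(6, True))
        assert "M6C" in matrix.feature_names
        assert "P3P" in matrix.feature_names
        assert "length" in matrix.feature_names
        assert "ccM6" in matrix.feature_names
        assert "ccP6" in matrix.feature_names
        assert position_code(-6) == "M6"
        assert position_code(3) == "P3"

    def test_inconsistent_rows_rejected(self):
        rows = self._rows(6, True) + self._rows(10, True)
        with pytest.raises(ValueError, match="inconsistent"):
            encode(rows)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            encode([])
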