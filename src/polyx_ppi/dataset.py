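"""Build the labeled, encoded feature table from detected homorepeats.

Each homorepeat contributes one row: the amino acids at signed context
positions -N..-1 and +1..+N around the repeat (the repeat itself is never a
feature, since repeats diverge in length), the repeat length, optional
per-position coiled-coil overlap flags, and the interaction label derived
from overlap with annotated interface regions, optionally augmented by
paralogy imputation.

Feature names follow the M/P code used throughout: ``M6C`` means "position
-6 is cysteine", ``P3P`` means "position +3 is proline"; coiled-coil flags
are named ``ccM6`` .. ``ccP10`` and the repeat length is ``length``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .detection import HomorepeatRegion
from .io_formats import (
    AMINO_ACIDS,
    CONTEXT_ALPHABET,
    PAD_SYMBOL,
    AnnotatedRegion,
    ParalogPair,
    ProteinRecord,
    RegionKind,
)

logger = logging.getLogger(__name__)

LABEL_INTERACTING = "interacting"
LABEL_UNKNOWN = "unknown"
PROVENANCE_DIRECT = "direct"
PROVENANCE_PARALOG = "paralog_imputed"

_AA_SET = set(AMINO_ACIDS)


def position_code(pos: int) -> str:
    """M/P code of a signed context position: -6 -> 'M6', +3 -> 'P3'."""
    if pos == 0:
        raise ValueError("position 0 is inside the repeat")
    return ("M" if pos < 0 else "P") + str(abs(pos))


def signed_positions(n_before: int, n_after: int) -> list[int]:
    """Ordered signed positions -n_before..-1, +1..+n_after."""
    return list(range(-n_before, 0)) + list(range(1, n_after + 1))


@dataclass
class ContextRow:
    """Per-repeat feature record prior to numeric encoding."""

    region: HomorepeatRegion
    flank_symbols: dict[int, str]
    repeat_length: int
    cc_flags: dict[int, bool] | None = None
    label: str = LABEL_UNKNOWN
    provenance: str | None = None

    @property
    def is_positive(self) -> bool:
        return self.label == LABEL_INTERACTING


@dataclass
class EncodedDesignMatrix:
    """Indicator-expanded numeric design matrix with aligned labels."""

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    rows: list[ContextRow] = field(repr=False, default_factory=list)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def extract_context(
    record: ProteinRecord,
    region: HomorepeatRegion,
    n_before: int,
    n_after: int,
) -> dict[int, str]:
    """Flanking symbols at signed positions around a repeat.

    Position -k maps to ``sequence[start-k]`` when it exists, else the
    padding symbol; +k maps to ``sequence[end+k]`` likewise. Letters outside
    the 20-letter alphabet are mapped to the padding symbol so the context
    dictionary is always exactly 21 symbols.
    """
    if region.protein_id != record.protein_id:
        raise ValueError(
            f"region {region.protein_id} does not belong to {record.protein_id}"
        )
    n = len(record.sequence)
    if region.start < 1 or region.end > n:
        raise ValueError(
            f"region {region.start}-{region.end} out of bounds for "
            f"{record.protein_id} (length {n})"
        )
    symbols: dict[int, str] = {}
    for k in range(n_before, 0, -1):
        idx = region.start - k  # 1-based
        symbols[-k] = _context_symbol(record.sequence, idx, n)
    for k in range(1, n_after + 1):
        idx = region.end + k
        symbols[k] = _context_symbol(record.sequence, idx, n)
    return symbols


def _context_symbol(seq: str, idx: int, n: int) -> str:
    if idx < 1 or idx > n:
        return PAD_SYMBOL
    aa = seq[idx - 1]
    return aa if aa in _AA_SET else PAD_SYMBOL


def label_by_overlap(
    regions: Sequence[HomorepeatRegion],
    interfaces: Sequence[AnnotatedRegion],
) -> list[str]:
    """Label each repeat interacting iff it shares >= 1 residue with an
    annotated interface region on the same protein."""
    by_protein: dict[str, list[AnnotatedRegion]] = {}
    for iface in interfaces:
        if iface.kind != RegionKind.INTERACTION:
            raise ValueError(f"expected interaction regions, got {iface.kind}")
        by_protein.setdefault(iface.protein_id, []).append(iface)
    labels = []
    for reg in regions:
        hits = by_protein.get(reg.protein_id, ())
        pos = any(i.overlaps(reg.start, reg.end) for i in hits)
        labels.append(LABEL_INTERACTING if pos else LABEL_UNKNOWN)
    return labels


def cc_overlap_flags(
    record: ProteinRecord,
    region: HomorepeatRegion,
    cc_regions: Sequence[AnnotatedRegion],
    n_before: int,
    n_after: int,
) -> dict[int, bool]:
    """Per-position overlap of the context with coiled-coil regions.

    The flag at signed position p is true iff the absolute residue index
    exists and lies inside any coiled-coil span of the same protein;
    padding positions are false.
    """
    n = len(record.sequence)
    mine = [
        cc
        for cc in cc_regions
        if cc.protein_id == record.protein_id and cc.kind == RegionKind.COILED_COIL
    ]
    flags: dict[int, bool] = {}
    for pos in signed_positions(n_before, n_after):
        idx = region.start + pos if pos < 0 else region.end + pos
        if idx < 1 or idx > n:
            flags[pos] = False
        else:
            flags[pos] = any(cc.start <= idx <= cc.end for cc in mine)
    return flags


@dataclass(frozen=True)
class PairwiseAlignment:
    """Global alignment of two proteins as a residue-index map.

    ``a_to_b`` maps each 1-based residue index of A to the aligned 1-based
    index of B; residues of A aligned to a gap are absent from the map.
    The map is strictly increasing over its entries.
    """

    protein_id_a: str
    protein_id_b: str
    a_to_b: dict[int, int]
    score: float

    def invert(self) -> "PairwiseAlignment":
        return PairwiseAlignment(
            self.protein_id_b,
            self.protein_id_a,
            {v: k for k, v in self.a_to_b.items()},
            self.score,
        )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def align_paralogs(a: ProteinRecord, b: ProteinRecord) -> PairwiseAlignment:
    """Global pairwise alignment of two paralogs (BLOSUM62, affine gaps
    open 10 / extend 0.5), returning the residue-coordinate map.

    The first optimal traceback reported by the aligner is used, which is
    deterministic for fixed inputs.
    """
    alignment = _ALIGNER.align(a.sequence, b.sequence)[0]
    a_to_b: dict[int, int] = {}
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            a_to_b[a_start + offset + 1] = b_start + offset + 1
    return PairwiseAlignment(a.protein_id, b.protein_id, a_to_b, alignment.score)


def _mapped_overlap(
    alignment: PairwiseAlignment, span_b: tuple[int, int], span_a: tuple[int, int]
) -> bool:
    """True iff >= 1 residue of A's span aligns into B's span."""
    b_to_a = {v: k for k, v in alignment.a_to_b.items()}
    for b_idx in range(span_b[0], span_b[1] + 1):
        a_idx = b_to_a.get(b_idx)
        if a_idx is not None and span_a[0] <= a_idx <= span_a[1]:
            return True
    return False


def impute_paralog_positives(
    rows: Sequence[ContextRow],
    pairs: Sequence[ParalogPair],
    sequences: Mapping[str, ProteinRecord],
    alignments: dict[tuple[str, str], PairwiseAlignment] | None = None,
) -> int:
    """Impute unknown repeats as interacting from directly-positive paralogs.

    An unknown-labeled repeat R in protein A becomes interacting
    (paralog-imputed) iff some paralog B of A has a directly-positive repeat
    of the same target residue whose span, mapped through the global
    alignment of A and B, overlaps R's span by at least one aligned residue.
    Direct positives are never downgraded. Mutates ``rows`` in place and
    returns the number of newly imputed positives. Idempotent: imputed
    positives never seed further imputation.
    """
    rows_by_protein: dict[str, list[ContextRow]] = {}
    for row in rows:
        rows_by_protein.setdefault(row.region.protein_id, []).append(row)

    direct_by_protein: dict[str, list[ContextRow]] = {
        pid: [r for r in rws if r.is_positive and r.provenance == PROVENANCE_DIRECT]
        for pid, rws in rows_by_protein.items()
    }

    if alignments is None:
        alignments = {}

    n_imputed = 0
    for pair in pairs:
        a, b = pair.protein_id_a, pair.protein_id_b
        if a not in sequences or b not in sequences:
            logger.warning("paralog pair (%s, %s) references unknown protein", a, b)
            continue
        for donor, recipient in ((b, a), (a, b)):
            donors = direct_by_protein.get(donor, [])
            candidates = [
                r for r in rows_by_protein.get(recipient, []) if not r.is_positive
            ]
            if not donors or not candidates:
                continue
            key = (recipient, donor)
            if key not in alignments:
                aln = align_paralogs(sequences[recipient], sequences[donor])
                alignments[key] = aln
                alignments[(donor, recipient)] = aln.invert()
            aln = alignments[key]
            for cand in candidates:
                for pos_row in donors:
                    if pos_row.region.target_aa != cand.region.target_aa:
                        continue
                    if _mapped_overlap(
                        aln,
                        (pos_row.region.start, pos_row.region.end),
                        (cand.region.start, cand.region.end),
                    ):
                        cand.label = LABEL_INTERACTING
                        cand.provenance = PROVENANCE_PARALOG
                        n_imputed += 1
                        break
    return n_imputed


def build_context_rows(
    records: Mapping[str, ProteinRecord],
    regions: Sequence[HomorepeatRegion],
    interfaces: Sequence[AnnotatedRegion],
    n_before: int,
    n_after: int,
    cc_regions: Sequence[AnnotatedRegion] | None = None,
) -> list[ContextRow]:
    """Assemble labeled context rows for a set of detected repeats.

    Repeats on proteins absent from ``records`` are skipped with a counted
    warning (annotation releases drift; fail soft).
    """
    kept = [r for r in regions if r.protein_id in records]
    n_skipped = len(regions) - len(kept)
    if n_skipped:
        logger.warning("skipped %d repeats on proteins missing from FASTA", n_skipped)
    labels = label_by_overlap(kept, interfaces)
    rows = []
    for reg, label in zip(kept, labels):
        rec = records[reg.protein_id]
        flanks = extract_context(rec, reg, n_before, n_after)
        flags = (
            cc_overlap_flags(rec, reg, cc_regions, n_before, n_after)
            if cc_regions is not None
            else None
        )
        rows.append(
            ContextRow(
                region=reg,
                flank_symbols=flanks,
                repeat_length=reg.length,
                cc_flags=flags,
                label=label,
                provenance=PROVENANCE_DIRECT if label == LABEL_INTERACTING else None,
            )
        )
    return rows


def raw_variable_count(n_before: int, n_after: int, with_cc: bool) -> int:
    """Number of raw (pre-expansion) model variables: context positions,
    optional per-position coiled-coil overlaps, and the repeat length."""
    n_ctx = n_before + n_after
    return n_ctx + (n_ctx if with_cc else 0) + 1


def encode(rows: Sequence[ContextRow]) -> EncodedDesignMatrix:
    """Indicator-expand context rows into a numeric design matrix.

    Every context position is expanded to the fixed 21-symbol dictionary
    (20 amino acids + padding), whether or not a symbol is observed, so
    models trained on different datasets share one feature space. The
    integer repeat length and, when present, 0/1 coiled-coil flags are
    appended. Column count is (2N x 21) + 1 (+ 2N with coiled-coil flags).
    """
    if not rows:
        raise ValueError("cannot encode an empty row list")
    positions = sorted(rows[0].flank_symbols)
    has_cc = rows[0].cc_flags is not None
    for row in rows:
        if sorted(row.flank_symbols) != positions:
            raise ValueError("inconsistent context positions across rows")
        if (row.cc_flags is not None) != has_cc:
            raise ValueError("inconsistent coiled-coil flag presence across rows")

    feature_names: list[str] = []
    for pos in positions:
        code = position_code(pos)
        feature_names.extend(f"{code}{sym}" for sym in CONTEXT_ALPHABET)
    feature_names.append("length")
    if has_cc:
        feature_names.extend(f"cc{position_code(pos)}" for pos in positions)

    sym_index = {sym: i for i, sym in enumerate(CONTEXT_ALPHABET)}
    n_sym = len(CONTEXT_ALPHABET)
    X = np.zeros((len(rows), len(feature_names)), dtype=np.float64)
    y = np.zeros(len(rows), dtype=np.int64)
    for i, row in enumerate(rows):
        for j, pos in enumerate(positions):
            X[i, j * n_sym + sym_index[row.flank_symbols[pos]]] = 1.0
        X[i, len(positions) * n_sym] = row.repeat_length
        if has_cc:
            base = len(positions) * n_sym + 1
            for j, pos in enumerate(positions):
                X[i, base + j] = 1.0 if row.cc_flags[pos] else 0.0
        y[i] = 1 if row.is_positive else 0
    return EncodedDesignMatrix(feature_names, X, y, list(rows))


def restrict_window(
    rows: Sequence[ContextRow],
    records: Mapping[str, ProteinRecord],
    n: int,
    cc_regions: Sequence[AnnotatedRegion] | None = None,
) -> list[ContextRow]:
    """Re-derive rows with a symmetric context window of +/- n positions.

    Coiled-coil flags are recomputed from ``cc_regions`` when given,
    otherwise dropped.
    """
    out = []
    for row in rows:
        rec = records[row.region.protein_id]
        flanks = extract_context(rec, row.region, n, n)
        flags = (
            cc_overlap_flags(rec, row.region, cc_regions, n, n)
            if cc_regions is not None
            else None
        )
        out.append(
            ContextRow(
                region=row.region,
                flank_symbols=flanks,
                repeat_length=row.repeat_length,
                cc_flags=flags,
                label=row.label,
                provenance=row.provenance,
            )
        )
    return out
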