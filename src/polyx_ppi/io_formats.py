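"""Readers and writers for the external file formats of the pipeline.

All downstream modules consume only the in-memory types defined here:
:class:`ProteinRecord`, :class:`AnnotatedRegion` and :class:`ParalogPair`.
Coordinates are 1-based inclusive throughout, following the UniProt /
Interactome3D convention.

Sequences may contain non-proteinogenic letters (X, U, B, Z, J, O, ...).
Such records are kept: the offending positions can never be part of a
homorepeat of a standard target residue, and at feature-encoding time any
letter outside the 20-letter alphabet is mapped to the padding symbol ``-``,
so detection and encoding remain total functions.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 proteinogenic amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Padding symbol for positions that fall outside the protein.
PAD_SYMBOL = "-"

#: Full context alphabet: 20 amino acids plus the padding symbol.
CONTEXT_ALPHABET = tuple(AMINO_ACIDS) + (PAD_SYMBOL,)


class RegionKind(str, enum.Enum):
    """Type of an annotated protein region."""

    INTERACTION = "interaction"
    COILED_COIL = "coiled_coil"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier.

    ``protein_id`` is a UniProt-accession-like token; ``sequence`` is the
    uppercase amino-acid string (length >= 1).
    """

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotatedRegion:
    """A 1-based inclusive residue span annotated on a protein."""

    protein_id: str
    start: int
    end: int
    kind: RegionKind

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"{self.protein_id}: invalid span {self.start}-{self.end}"
            )

    def overlaps(self, start: int, end: int) -> bool:
        """True iff the region shares at least one residue with [start, end]."""
        return max(self.start, start) <= min(self.end, end)


@dataclass(frozen=True)
class ParalogPair:
    """An unordered pair of paralogous proteins, canonicalized a < b."""

    protein_id_a: str
    protein_id_b: str

    def __post_init__(self) -> None:
        if self.protein_id_a == self.protein_id_b:
            raise ValueError(f"self-pair: {self.protein_id_a}")
        if self.protein_id_a > self.protein_id_b:
            a, b = self.protein_id_b, self.protein_id_a
            object.__setattr__(self, "protein_id_a", a)
            object.__setattr__(self, "protein_id_b", b)


def _accession_from_header(header_token: str) -> str:
    """Extract the accession from a FASTA id token.

    UniProt-style ``db|ACC|NAME`` headers yield the accession field; any
    other token is returned as-is.
    """
    if "|" in header_token:
        parts = header_token.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return header_token


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from a FASTA file.

    The protein id is the first whitespace-delimited token of the header;
    with UniProt ``db|ACC|NAME`` headers, the accession field. Duplicate
    ids raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = _accession_from_header(entry.id)
        if pid in seen:
            raise ValueError(f"duplicate protein id in FASTA: {pid}")
        seen.add(pid)
        records.append(ProteinRecord(pid, str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as a plain FASTA file (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_regions(path: str | Path, kind: RegionKind | str) -> list[AnnotatedRegion]:
    """Read annotated regions from a TSV with columns protein_id, start, end.

    Duplicate (protein_id, start, end) rows are collapsed to one region,
    matching the "unique protein regions" semantics of positional
    interaction annotations. Inverted or non-integer spans raise.
    """
    kind = RegionKind(kind)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    regions: list[AnnotatedRegion] = []
    seen: set[tuple[str, int, int]] = set()
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: non-integer coordinates for {row.protein_id}: "
                f"{row.start}-{row.end}"
            ) from exc
        key = (str(row.protein_id), start, end)
        if key in seen:
            continue
        seen.add(key)
        regions.append(AnnotatedRegion(str(row.protein_id), start, end, kind))
    return regions


def write_regions(regions: Iterable[AnnotatedRegion], path: str | Path) -> None:
    """Write regions as a TSV (protein_id, start, end), sorted."""
    rows = sorted(
        (r.protein_id, r.start, r.end) for r in regions
    )
    df = pd.DataFrame(rows, columns=["protein_id", "start", "end"])
    df.to_csv(path, sep="\t", index=False)


def read_paralog_pairs(path: str | Path) -> list[ParalogPair]:
    """Read paralog pairs from a TSV with columns protein_id_a, protein_id_b.

    Pairs are canonicalized (unordered) and deduplicated; self-pairs are
    dropped with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id_a", "protein_id_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    pairs: list[ParalogPair] = []
    seen: set[tuple[str, str]] = set()
    n_self = 0
    for row in df.itertuples(index=False):
        a, b = str(row.protein_id_a), str(row.protein_id_b)
        if a == b:
            n_self += 1
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(ParalogPair(*key))
    if n_self:
        logger.warning("dropped %d self-pairs from %s", n_self, path)
    return pairs


def write_paralog_pairs(pairs: Iterable[ParalogPair], path: str | Path) -> None:
    rows = sorted((p.protein_id_a, p.protein_id_b) for p in pairs)
    df = pd.DataFrame(rows, columns=["protein_id_a", "protein_id_b"])
    df.to_csv(path, sep="\t", index=False)


PREDICTION_COLUMNS = [
    "protein_id",
    "repeat_type",
    "start",
    "end",
    "length",
    "label_known",
    "score",
]


def write_predictions(records: Sequence, path: str | Path) -> None:
    """Write prediction records as a TSV with stable (protein_id, start) order.

    ``records`` are :class:`polyx_ppi.scoring.PredictionRecord` objects;
    scores are printed with 6 decimal places so round-trips are exact.
    """
    rows = []
    for rec in records:
        if not 0.0 <= rec.score <= 1.0:
            raise ValueError(f"score out of [0,1]: {rec.score}")
        rows.append(
            (
                rec.region.protein_id,
                rec.region.target_aa,
                rec.region.start,
                rec.region.end,
                rec.region.length,
                rec.label_known,
                f"{rec.score:.6f}",
            )
        )
    rows.sort(key=lambda r: (r[0], int(r[2])))
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a prediction TSV back into a DataFrame (typed columns)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "protein_id": str,
            "repeat_type": str,
            "start": int,
            "end": int,
            "length": int,
            "label_known": str,
            "score": float,
        },
    )
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_feature_table(rows: Sequence, path: str | Path) -> None:
    """Write context rows as a TSV feature table.

    Columns: protein_id, target_aa, start, end (1-based inclusive), length,
    one column per signed context position (M/P-coded), optional ``cc*``
    flag columns, label and provenance. Round-trips through
    :func:`read_feature_table`.
    """
    from .dataset import position_code  # local import: dataset depends on us

    if not rows:
        raise ValueError("cannot write an empty feature table")
    positions = sorted(rows[0].flank_symbols)
    has_cc = rows[0].cc_flags is not None
    header = ["protein_id", "target_aa", "start", "end", "length", "purity"]
    header += [position_code(p) for p in positions]
    if has_cc:
        header += [f"cc{position_code(p)}" for p in positions]
    header += ["label", "provenance"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            reg = row.region
            fields = [
                reg.protein_id,
                reg.target_aa,
                str(reg.start),
                str(reg.end),
                str(row.repeat_length),
                str(reg.purity),
            ]
            fields += [row.flank_symbols[p] for p in positions]
            if has_cc:
                fields += [str(int(row.cc_flags[p])) for p in positions]
            fields += [row.label, row.provenance or "."]
            fh.write("\t".join(fields) + "\n")


def _decode_position(code: str) -> int:
    sign = -1 if code[0] == "M" else 1
    return sign * int(code[1:])


def read_feature_table(path: str | Path) -> list:
    """Read a feature table TSV back into context rows."""
    from .dataset import ContextRow
    from .detection import HomorepeatRegion

    df = pd.read_csv(path, sep="\t", dtype=str)
    pos_cols = [c for c in df.columns if c[0] in "MP" and c[1:].isdigit()]
    cc_cols = [c for c in df.columns if c.startswith("cc")]
    rows = []
    for rec in df.itertuples(index=False):
        rec = rec._asdict()
        start, end = int(rec["start"]), int(rec["end"])
        length = int(rec["length"])
        region = HomorepeatRegion(
            protein_id=rec["protein_id"],
            target_aa=rec["target_aa"],
            start=start,
            end=end,
            length=length,
            purity=int(rec.get("purity", length) or length),
        )
        flanks = {_decode_position(c): rec[c] for c in pos_cols}
        flags = (
            {_decode_position(c[2:]): bool(int(rec[c])) for c in cc_cols}
            if cc_cols
            else None
        )
        provenance = rec["provenance"]
        rows.append(
            ContextRow(
                region=region,
                flank_symbols=flanks,
                repeat_length=length,
                cc_flags=flags,
                label=rec["label"],
                provenance=None if provenance in (".", None) else provenance,
            )
        )
    return rows


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
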