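"""Synthetic proteome fixtures with planted, controllable signal.

The generator emits format-identical inputs (FASTA, interface TSV,
coiled-coil TSV, paralog TSV) in which every homorepeat, its label and its
discriminative signal are known by construction, so the whole pipeline can
be exercised and validated without any database download.

The planted structure mirrors what discriminates interacting homorepeats in
real proteomes: interacting repeats are shorter on average, are enriched
for a specific residue at position +3 (proline after polyQ, glycine after
polyA), and co-locate with coiled-coil regions more often than
non-interacting repeats. Paralog duplicates carry mutated copies of their
source protein with the repeat span preserved, so paralogy-based label
imputation has a known ground-truth imputable set.

Every generated protein is validated against the sliding-window detector:
background segments are resampled until detection recovers exactly the
planted repeat span, which makes the detect-then-label round trip exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .detection import DetectorConfig, HomorepeatRegion, detect_polyx
from .io_formats import (
    AMINO_ACIDS,
    AnnotatedRegion,
    ParalogPair,
    ProteinRecord,
    RegionKind,
    write_fasta,
    write_paralog_pairs,
    write_regions,
)

logger = logging.getLogger(__name__)

#: Signal residue planted at context position +3, per repeat type.
SIGNAL_RESIDUE = {"Q": "P", "A": "G"}


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic proteome.

    Defaults reproduce the study conditions of the real-data analysis: a
    positive (interacting) fraction of 7.53% for polyQ (use 0.1026 for
    polyA), shorter repeats among positives, and a +3 signal residue carried
    by 80% of positives. Background residue usage is uniform over the 20
    amino acids.
    """

    seed: int = 0
    n_proteins: int = 300
    protein_length: tuple[int, int] = (150, 400)
    target_aa: str = "Q"
    positive_fraction: float = 0.0753
    pos_length_range: tuple[int, int] = (4, 8)
    neg_length_range: tuple[int, int] = (4, 15)
    p_signal: float = 0.8
    p_signal_negative: float | None = None  # None: background chance only
    cc_prob_positive: float = 0.6
    cc_prob_negative: float = 0.1
    paralog_fraction: float = 0.0
    paralog_mutation_rate: float = 0.05
    decoy_interface_rate: float = 0.2

    def __post_init__(self) -> None:
        for p in (
            self.positive_fraction,
            self.p_signal,
            self.cc_prob_positive,
            self.cc_prob_negative,
            self.paralog_fraction,
            self.paralog_mutation_rate,
            self.decoy_interface_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0,1)")
        if self.target_aa not in SIGNAL_RESIDUE:
            raise ValueError("target_aa must be Q or A")
        max_repeat = max(self.pos_length_range[1], self.neg_length_range[1])
        if self.protein_length[0] < max_repeat + 9:
            raise ValueError(
                f"proteins of length {self.protein_length[0]} cannot embed "
                f"repeats up to {max_repeat} residues with flanks"
            )


@dataclass
class TruthRow:
    """Ground truth for one planted repeat."""

    protein_id: str
    start: int
    end: int
    length: int
    is_positive: bool
    signal_planted: bool
    cc_planted: bool
    imputable: bool = False
    source_protein: str | None = None


@dataclass
class Fixture:
    """In-memory fixture plus its ground truth."""

    config: FixtureConfig
    records: list[ProteinRecord]
    interfaces: list[AnnotatedRegion]
    cc_regions: list[AnnotatedRegion]
    pairs: list[ParalogPair]
    truth: list[TruthRow] = field(default_factory=list)

    @property
    def records_by_id(self) -> dict[str, ProteinRecord]:
        return {r.protein_id: r for r in self.records}


def _random_background(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, len(AMINO_ACIDS), size=n)


def _build_protein(
    rng: np.random.Generator,
    pid: str,
    length: int,
    repeat_len: int,
    target_aa: str,
    signal: bool,
    detector: DetectorConfig,
    max_tries: int = 200,
) -> tuple[ProteinRecord, int, int]:
    """Assemble one protein with a pure planted run; resample background
    until the detector recovers exactly the planted span."""
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    # keep >= 4 residues clear of each terminus so contexts are non-trivial
    start0 = int(rng.integers(4, length - repeat_len - 4))
    for _ in range(max_tries):
        seq = aa[_random_background(rng, length)].tobytes().decode()
        chars = list(seq)
        chars[start0 : start0 + repeat_len] = target_aa * repeat_len
        sig_idx = start0 + repeat_len + 2  # 0-based position +3
        if signal:
            chars[sig_idx] = SIGNAL_RESIDUE[target_aa]
        record = ProteinRecord(pid, "".join(chars))
        detected = detect_polyx(record, detector)
        if len(detected) == 1 and (
            detected[0].start,
            detected[0].end,
        ) == (start0 + 1, start0 + repeat_len):
            return record, start0 + 1, start0 + repeat_len
    raise RuntimeError(f"could not embed a clean repeat in {pid} after {max_tries} tries")


def generate(config: FixtureConfig, out_dir: str | Path | None = None) -> Fixture:
    """Generate the synthetic proteome, annotations and ground truth.

    When ``out_dir`` is given the fixture is also written as
    ``proteins.fasta``, ``interfaces.tsv``, ``coiled_coils.tsv``,
    ``paralogs.tsv``, ``truth.tsv`` and a copy of the configuration in
    ``fixture.yaml``. Same seed, same files, byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    detector = DetectorConfig(config.target_aa)
    records: list[ProteinRecord] = []
    interfaces: list[AnnotatedRegion] = []
    cc_regions: list[AnnotatedRegion] = []
    truth: list[TruthRow] = []

    n_pos = int(round(config.n_proteins * config.positive_fraction))
    is_positive = np.zeros(config.n_proteins, dtype=bool)
    is_positive[rng.choice(config.n_proteins, size=n_pos, replace=False)] = True

    for i in range(config.n_proteins):
        pid = f"SYN{i:05d}"
        pos = bool(is_positive[i])
        length = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
        lo, hi = config.pos_length_range if pos else config.neg_length_range
        repeat_len = int(rng.integers(lo, hi + 1))
        if pos:
            signal = bool(rng.random() < config.p_signal)
        elif config.p_signal_negative is not None:
            signal = bool(rng.random() < config.p_signal_negative)
        else:
            signal = False  # background may still supply the residue by chance
        record, start, end = _build_protein(
            rng, pid, length, repeat_len, config.target_aa, signal, detector
        )
        records.append(record)

        cc_prob = config.cc_prob_positive if pos else config.cc_prob_negative
        cc_planted = bool(rng.random() < cc_prob)
        if cc_planted:
            # coiled coil overlapping the downstream context of the repeat
            cc_start = end + 1
            cc_end = min(len(record), end + 10)
            cc_regions.append(
                AnnotatedRegion(pid, cc_start, cc_end, RegionKind.COILED_COIL)
            )

        if pos:
            iface_start = max(1, start - 2)
            iface_end = min(len(record), end + 2)
            interfaces.append(
                AnnotatedRegion(pid, iface_start, iface_end, RegionKind.INTERACTION)
            )
        elif rng.random() < config.decoy_interface_rate:
            decoy = _decoy_interface(rng, pid, len(record), start, end)
            if decoy is not None:
                interfaces.append(decoy)

        truth.append(
            TruthRow(pid, start, end, end - start + 1, pos, signal, cc_planted)
        )

    pairs = _add_paralogs(rng, config, detector, records, truth)

    fixture = Fixture(config, records, interfaces, cc_regions, pairs, truth)
    if out_dir is not None:
        _write_fixture(fixture, Path(out_dir))
    return fixture


def _decoy_interface(
    rng: np.random.Generator, pid: str, n: int, repeat_start: int, repeat_end: int
) -> AnnotatedRegion | None:
    """An interface span that does not touch the planted repeat."""
    for _ in range(20):
        width = int(rng.integers(5, 30))
        start = int(rng.integers(1, max(2, n - width)))
        end = min(n, start + width - 1)
        if end < repeat_start or start > repeat_end:
            return AnnotatedRegion(pid, start, end, RegionKind.INTERACTION)
    return None


def _add_paralogs(
    rng: np.random.Generator,
    config: FixtureConfig,
    detector: DetectorConfig,
    records: list[ProteinRecord],
    truth: list[TruthRow],
) -> list[ParalogPair]:
    """Duplicate a fraction of proteins with point mutations, keeping the
    repeat span intact; copies of positives form the imputable set."""
    if config.paralog_fraction == 0:
        return []
    pairs: list[ParalogPair] = []
    n_dup = int(round(len(truth) * config.paralog_fraction))
    chosen = rng.choice(len(truth), size=n_dup, replace=False)
    aa = AMINO_ACIDS
    for i in sorted(chosen):
        src = records[i]
        row = truth[i]
        dup_id = f"{src.protein_id}P"
        span0 = (row.start - 1, row.end - 1)
        for _ in range(200):
            chars = list(src.sequence)
            for j in range(len(chars)):
                if span0[0] <= j <= span0[1]:
                    continue
                if rng.random() < config.paralog_mutation_rate:
                    chars[j] = aa[int(rng.integers(0, 20))]
            dup = ProteinRecord(dup_id, "".join(chars))
            detected = detect_polyx(dup, detector)
            if len(detected) == 1 and (detected[0].start, detected[0].end) == (
                row.start,
                row.end,
            ):
                break
        else:
            logger.warning("skipping paralog of %s: no clean mutant", src.protein_id)
            continue
        records.append(dup)
        truth.append(
            TruthRow(
                dup_id,
                row.start,
                row.end,
                row.length,
                is_positive=False,
                signal_planted=row.signal_planted,
                cc_planted=False,
                imputable=row.is_positive,
                source_protein=src.protein_id,
            )
        )
        pairs.append(ParalogPair(src.protein_id, dup_id))
    return pairs


def _write_fixture(fixture: Fixture, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.records, out_dir / "proteins.fasta")
    write_regions(fixture.interfaces, out_dir / "interfaces.tsv")
    write_regions(fixture.cc_regions, out_dir / "coiled_coils.tsv")
    write_paralog_pairs(fixture.pairs, out_dir / "paralogs.tsv")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write(
            "protein_id\tstart\tend\tlength\tis_positive\tsignal_planted\t"
            "cc_planted\timputable\tsource_protein\n"
        )
        for row in fixture.truth:
            fh.write(
                f"{row.protein_id}\t{row.start}\t{row.end}\t{row.length}\t"
                f"{int(row.is_positive)}\t{int(row.signal_planted)}\t"
                f"{int(row.cc_planted)}\t{int(row.imputable)}\t"
                f"{row.source_protein or '.'}\n"
            )
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(fixture.config).items()
    }
    (out_dir / "fixture.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def make_imbalanced_labeling(
    n_total: int,
    n_pos: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[ProteinRecord], list[HomorepeatRegion], list[AnnotatedRegion]]:
    """A minimal proteome of ``n_total`` single-repeat proteins whose
    interface annotation yields exactly ``n_pos`` positives under
    overlap labeling.

    Each protein is a clean 6-residue pure polyQ run between inert flanks,
    so detection at 4/6 recovers exactly one repeat per protein; interfaces
    overlap the repeats of a seeded random subset of size ``n_pos``.
    """
    if n_pos > n_total:
        raise ValueError("n_pos cannot exceed n_total")
    rng = np.random.default_rng(seed)
    positive_ids = set(rng.choice(n_total, size=n_pos, replace=False).tolist())
    records: list[ProteinRecord] = []
    regions: list[HomorepeatRegion] = []
    interfaces: list[AnnotatedRegion] = []
    for i in range(n_total):
        pid = f"IMB{i:05d}"
        seq = "L" * 10 + "Q" * 6 + "L" * 10
        records.append(ProteinRecord(pid, seq))
        regions.append(HomorepeatRegion(pid, "Q", 11, 16, 6, 6))
        if i in positive_ids:
            interfaces.append(AnnotatedRegion(pid, 14, 20, RegionKind.INTERACTION))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "proteins.fasta")
        write_regions(interfaces, out_dir / "interfaces.tsv")
    return records, regions, interfaces
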