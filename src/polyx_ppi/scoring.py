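"""Proteome-wide scoring of homorepeats with a trained classifier.

The prediction score is the model's probability that a homorepeat is
involved in a protein-protein interaction. High-scoring repeats without
known annotation ("candidates") are the actionable output: regions likely
to interact that structural databases have not yet covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (
    ContextRow,
    EncodedDesignMatrix,
    PROVENANCE_PARALOG,
    encode,
)
from .detection import HomorepeatRegion
from .models import TrainedClassifier

LABEL_KNOWN_DIRECT = "interacting_direct"
LABEL_KNOWN_PARALOG = "interacting_paralog"
LABEL_KNOWN_UNKNOWN = "unknown"


@dataclass(frozen=True)
class PredictionRecord:
    """A scored homorepeat with its known-label provenance."""

    region: HomorepeatRegion
    score: float
    label_known: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score out of [0,1]: {self.score}")


def _label_known(row: ContextRow) -> str:
    if not row.is_positive:
        return LABEL_KNOWN_UNKNOWN
    if row.provenance == PROVENANCE_PARALOG:
        return LABEL_KNOWN_PARALOG
    return LABEL_KNOWN_DIRECT


def predict_all(
    classifier: TrainedClassifier, rows: Sequence[ContextRow]
) -> list[PredictionRecord]:
    """Score every context row with the trained model.

    The rows are encoded into the classifier's exact feature space; any
    mismatch between the encoded feature names and the classifier's raises
    with the differing names listed.
    """
    matrix: EncodedDesignMatrix = encode(list(rows))
    if matrix.feature_names != classifier.feature_names:
        extra = sorted(set(matrix.feature_names) - set(classifier.feature_names))
        missing = sorted(set(classifier.feature_names) - set(matrix.feature_names))
        raise ValueError(
            "feature names do not match the classifier: "
            f"unexpected={extra[:5]}, missing={missing[:5]} "
            f"(showing up to 5 of each)"
        )
    scores = classifier.predict_scores(matrix.X)
    return [
        PredictionRecord(row.region, float(score), _label_known(row))
        for row, score in zip(rows, scores)
    ]


@dataclass
class ScoreReport:
    """Summary of a prediction run at a score threshold."""

    threshold: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    counts_above_threshold: dict[str, int]
    candidates: list[PredictionRecord] = field(default_factory=list)
    score_vs_length: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_records(self) -> int:
        return int(self.bin_counts.sum())


def score_report(
    records: Sequence[PredictionRecord], threshold: float = 0.7
) -> ScoreReport:
    """Histogram, above-threshold counts by label, and a score-vs-length table.

    The histogram uses 20 equal right-closed bins on [0, 1] (scores of
    exactly 0 fall in the first bin). Unknown-labeled records above the
    threshold are flagged as candidates.
    """
    scores = np.array([r.score for r in records], dtype=float)
    edges = np.linspace(0.0, 1.0, 21)
    if len(scores):
        # right-closed bins: (a, b]; np.digitize(right=True) maps 0 to bin 0
        idx = np.clip(np.digitize(scores, edges[1:], right=True), 0, 19)
        counts = np.bincount(idx, minlength=20)
    else:
        counts = np.zeros(20, dtype=int)

    above: dict[str, int] = {
        LABEL_KNOWN_DIRECT: 0,
        LABEL_KNOWN_PARALOG: 0,
        LABEL_KNOWN_UNKNOWN: 0,
    }
    candidates = []
    for rec in records:
        if rec.score > threshold:
            above[rec.label_known] += 1
            if rec.label_known == LABEL_KNOWN_UNKNOWN:
                candidates.append(rec)

    table = pd.DataFrame(
        {
            "protein_id": [r.region.protein_id for r in records],
            "length": [r.region.length for r in records],
            "label_known": [r.label_known for r in records],
            "score": scores,
        }
    )
    return ScoreReport(
        threshold=threshold,
        bin_edges=edges,
        bin_counts=counts,
        counts_above_threshold=above,
        candidates=sorted(candidates, key=lambda r: -r.score),
        score_vs_length=table,
    )


def write_report(report: ScoreReport, path) -> None:
    """Write the report as a TSV: histogram block, then threshold counts."""
    with open(path, "w") as fh:
        fh.write("# score histogram (20 right-closed bins on [0,1])\n")
        fh.write("bin_low\tbin_high\tcount\n")
        for lo, hi, c in zip(
            report.bin_edges[:-1], report.bin_edges[1:], report.bin_counts
        ):
            fh.write(f"{lo:.2f}\t{hi:.2f}\t{int(c)}\n")
        fh.write(f"# counts with score > {report.threshold}\n")
        fh.write("label_known\tcount\n")
        for label, count in sorted(report.counts_above_threshold.items()):
            fh.write(f"{label}\t{count}\n")
        fh.write("# candidates (unknown label above threshold)\n")
        fh.write("protein_id\tstart\tend\tscore\n")
        for rec in report.candidates:
            fh.write(
                f"{rec.region.protein_id}\t{rec.region.start}\t"
                f"{rec.region.end}\t{rec.score:.6f}\n"
            )
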