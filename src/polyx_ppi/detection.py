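"""Sliding-window detection of homorepeats (polyQ, polyA, any polyX).

A residue window of size ``window`` qualifies when it contains at least
``min_count`` copies of the target residue (default 4-of-6). The union of
all qualifying windows forms candidate spans, which are then trimmed so the
first and last residue of every reported region is the target residue.
Two qualifying spans separated by at least one uncovered residue are
reported as separate regions.

Proteins shorter than the window are evaluated as a single whole-sequence
window with the same ``min_count``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import ProteinRecord


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the sliding-window homorepeat rule."""

    target_aa: str
    min_count: int = 4
    window: int = 6

    def __post_init__(self) -> None:
        if len(self.target_aa) != 1 or not self.target_aa.isalpha():
            raise ValueError(f"target_aa must be one letter, got {self.target_aa!r}")
        object.__setattr__(self, "target_aa", self.target_aa.upper())
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not 1 <= self.min_count <= self.window:
            raise ValueError("min_count must satisfy 1 <= min_count <= window")


@dataclass(frozen=True)
class HomorepeatRegion:
    """A detected homorepeat span (1-based inclusive, trimmed to targets).

    ``length`` is ``end - start + 1``; ``purity`` counts the target residues
    inside the span (a 4/6 region of length 6 has purity 4).
    """

    protein_id: str
    target_aa: str
    start: int
    end: int
    length: int
    purity: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid span {self.start}-{self.end}")
        if self.length != self.end - self.start + 1:
            raise ValueError("length must equal end - start + 1")


def count_in_window(window_seq: str, target_aa: str) -> int:
    """Count exact occurrences of the target letter in a window sequence."""
    return window_seq.count(target_aa)


def detect_polyx(record: ProteinRecord, config: DetectorConfig) -> list[HomorepeatRegion]:
    """Detect all homorepeat regions of ``config.target_aa`` in a protein.

    Returns regions sorted by start, non-overlapping, each beginning and
    ending with the target residue. Returns an empty list when no window
    qualifies.
    """
    seq = record.sequence
    n = len(seq)
    w = min(config.window, n)
    target = config.target_aa

    # Mark residues covered by qualifying windows.
    covered = bytearray(n)
    count = count_in_window(seq[:w], target)
    if count >= config.min_count:
        covered[0:w] = b"\x01" * w
    for i in range(1, n - w + 1):
        count += (seq[i + w - 1] == target) - (seq[i - 1] == target)
        if count >= config.min_count:
            covered[i : i + w] = b"\x01" * w

    regions: list[HomorepeatRegion] = []
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j < n and covered[j]:
            j += 1
        region = _trim_span(seq, i, j - 1, target)
        if region is not None:
            start0, end0 = region
            purity = seq[start0 : end0 + 1].count(target)
            regions.append(
                HomorepeatRegion(
                    protein_id=record.protein_id,
                    target_aa=target,
                    start=start0 + 1,
                    end=end0 + 1,
                    length=end0 - start0 + 1,
                    purity=purity,
                )
            )
        i = j
    return regions


def _trim_span(seq: str, start0: int, end0: int, target: str) -> tuple[int, int] | None:
    """Trim a 0-based candidate span to its outermost target residues."""
    while start0 <= end0 and seq[start0] != target:
        start0 += 1
    while end0 >= start0 and seq[end0] != target:
        end0 -= 1
    if start0 > end0:
        return None
    return start0, end0


def detect_all(
    records: Iterable[ProteinRecord], config: DetectorConfig
) -> list[HomorepeatRegion]:
    """Detect homorepeats across a collection of proteins."""
    out: list[HomorepeatRegion] = []
    for rec in records:
        out.extend(detect_polyx(rec, config))
    return out
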