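"""Core domain containers shared across the pipeline.

Coordinates are 0-based throughout; event sample intervals are half-open
``[start, start + length)`` over the parent raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: model-1 label alphabet: true base, Insertion (spurious read base), Deletion
#: (a reference base missing from the read, attached to the preceding event).
LABELS1 = "ACGTID"
#: model-2 label alphabet: the true base under the event.
LABELS2 = "ACGT"

METHYL_TYPES = ("m6A", "m4C", "modified")
METHYL_NONE = "none"


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class RawSignal:
    """Per-read raw current trace (pA or normalized units)."""

    read_id: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("raw signal must be one-dimensional")

    @property
    def sample_count(self) -> int:
        return int(self.samples.size)


@dataclass
class Event:
    """One basecaller event: a contiguous stretch of samples attributed to a
    single pore state."""

    start: int
    length: int
    mean: float
    stdv: float
    model_state: str
    move: int
    weight: float
    p_model_state: float
    base: str

    def validate(self, sample_count: int | None = None) -> None:
        if self.length <= 0:
            raise ValueError(f"event length must be positive, got {self.length}")
        if self.move not in (0, 1, 2):
            raise ValueError(f"move must be 0, 1 or 2, got {self.move}")
        if self.base not in BASES:
            raise ValueError(f"called base must be one of {BASES}, got {self.base!r}")
        if not 0.0 <= self.p_model_state <= 1.0:
            raise ValueError("p_model_state must lie in [0, 1]")
        if sample_count is not None and self.start + self.length > sample_count:
            raise ValueError(
                f"event [{self.start}, {self.start + self.length}) exceeds "
                f"signal of {sample_count} samples"
            )

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class EventTable:
    """Ordered per-read event stream plus the basecalled sequence."""

    read_id: str
    events: list[Event]
    sequence: str

    def validate(self, raw: RawSignal | None = None) -> None:
        n = raw.sample_count if raw is not None else None
        prev_end = -1
        for ev in self.events:
            ev.validate(n)
            if ev.start < prev_end:
                raise ValueError("events overlap or are out of order")
            prev_end = ev.start
        total_move = sum(ev.move for ev in self.events)
        if total_move != len(self.sequence):
            raise ValueError(
                f"sum of moves ({total_move}) != sequence length "
                f"({len(self.sequence)})"
            )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)


@dataclass
class AlignmentRecord:
    """A primary read-to-reference alignment in SAM semantics.

    ``query`` and ``cigar`` are in SAM (reference) orientation; for a
    reverse-strand read the stored query is the reverse complement of the
    basecalled read.
    """

    read_id: str
    ref_name: str
    ref_start: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    query: str
    aligned_ref_segment: str

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "=XIMS")

    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "=XMD")


@dataclass
class LabeledEvent:
    """Base-level event with its two training labels and methylation flag."""

    event: Event
    label1: str  # in LABELS1
    label2: str  # in LABELS2
    methyl: str = METHYL_NONE
    ref_pos: int | None = None  # reference coordinate, None for clips/inserts
    soft_clipped: bool = False

    def __post_init__(self) -> None:
        if self.label1 not in LABELS1:
            raise ValueError(f"label1 must be in {LABELS1}, got {self.label1!r}")
        if self.label2 not in LABELS2:
            raise ValueError(f"label2 must be in {LABELS2}, got {self.label2!r}")
        if self.label1 in LABELS2 and self.label1 != self.label2:
            raise ValueError("base labels must agree between the two models")
        if self.label1 == "I" and self.label2 != self.event.base:
            raise ValueError("an inserted event's label2 must be its called base")


@dataclass
class MethylAnnotation:
    """Reference methylation intervals, BED-style half-open coordinates."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, mtype in self.intervals:
            if mtype not in METHYL_TYPES:
                raise ValueError(f"unknown methylation type {mtype!r}")
            if end <= start:
                raise ValueError("methylation interval must be non-empty")

    def chroms(self) -> set[str]:
        return {iv[0] for iv in self.intervals}

    def for_chrom(self, chrom: str) -> list[tuple[int, int, str]]:
        return sorted(
            (s, e, t) for c, s, e, t in self.intervals if c == chrom
        )


@dataclass
class AlignmentStats:
    """CIGAR-derived error counts; the operands of the rate formulas."""

    read_length: int = 0
    deletion_length: int = 0
    insertion_length: int = 0
    mismatch_length: int = 0
    # per-methylation-type counters: bases covered, deletions, insertions,
    # mismatches at annotated reference positions
    methyl: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def __add__(self, other: "AlignmentStats") -> "AlignmentStats":
        merged: dict[str, tuple[int, int, int, int]] = {}
        for key in set(self.methyl) | set(other.methyl):
            a = self.methyl.get(key, (0, 0, 0, 0))
            b = other.methyl.get(key, (0, 0, 0, 0))
            merged[key] = tuple(x + y for x, y in zip(a, b))  # type: ignore[assignment]
        return AlignmentStats(
            read_length=self.read_length + other.read_length,
            deletion_length=self.deletion_length + other.deletion_length,
            insertion_length=self.insertion_length + other.insertion_length,
            mismatch_length=self.mismatch_length + other.mismatch_length,
            methyl=merged,
        )


def aggregate_stats(stats: Sequence[AlignmentStats]) -> AlignmentStats:
    """Pool counts over a read set (micro-average: sum lengths, then rate)."""
    total = AlignmentStats()
    for s in stats:
        total = total + s
    return total
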