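"""Alignment-based evaluation rates.

All rates share the alignment-length denominator

    Alignlength = readlength + deletionlength

so that deletion, insertion and mismatch rates and their sum (the error
rate) are directly comparable. Rates over annotated methylated areas use
the annotated base count of each type as denominator; the pooled
methylated-area rate is the literal sum of the per-type rates (a
base-weighted pooling is available behind a flag).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .types import (AlignmentRecord, AlignmentStats, MethylAnnotation,
                    METHYL_TYPES, aggregate_stats)

logger = logging.getLogger(__name__)

_METHYL_PRIORITY = ("m6A", "m4C", "modified")


def stats_from_alignment(aln: AlignmentRecord,
                         annotation: MethylAnnotation | None = None
                         ) -> AlignmentStats:
    """Count deletion/insertion/mismatch lengths over the CIGAR, optionally
    restricted per methylation type at annotated reference positions.

    Insertions (which consume no reference base) are attributed to the
    annotation status of the preceding reference position.
    """
    if any(op == "M" for op, _ in aln.cigar):
        raise ValueError(
            f"{aln.read_id}: ambiguous 'M' CIGAR runs; resolve against a "
            "reference before computing stats")
    stats = AlignmentStats()
    stats.read_length = sum(n for op, n in aln.cigar if op in "=XIS")

    intervals: list[tuple[int, int, str]] = []
    if annotation is not None and aln.ref_name in annotation.chroms():
        intervals = annotation.for_chrom(aln.ref_name)

    def methyl_type(ref_pos: int) -> str | None:
        hits = [t for s, e, t in intervals if s <= ref_pos < e]
        return min(hits, key=_METHYL_PRIORITY.index) if hits else None

    counters = {t: [0, 0, 0, 0] for t in METHYL_TYPES}  # bases, del, ins, mm
    ri = aln.ref_start
    for op, n in aln.cigar:
        if op in "SH":
            continue
        if op == "=":
            for p in range(ri, ri + n):
                t = methyl_type(p)
                if t:
                    counters[t][0] += 1
            ri += n
        elif op == "X":
            stats.mismatch_length += n
            for p in range(ri, ri + n):
                t = methyl_type(p)
                if t:
                    counters[t][0] += 1
                    counters[t][3] += 1
            ri += n
        elif op == "D":
            stats.deletion_length += n
            for p in range(ri, ri + n):
                t = methyl_type(p)
                if t:
                    counters[t][0] += 1
                    counters[t][1] += 1
            ri += n
        elif op == "I":
            stats.insertion_length += n
            t = methyl_type(ri - 1) if ri > aln.ref_start else None
            if t:
                counters[t][2] += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")

    stats.methyl = {t: tuple(v) for t, v in counters.items() if v[0] > 0}
    return stats


@dataclass
class RateReport:
    """Deletion/insertion/mismatch/error rates as percentages."""

    deletion_rate: float
    insertion_rate: float
    mismatch_rate: float
    error_rate: float
    align_length: int
    read_length: int
    methylated: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "deletion_rate": self.deletion_rate,
            "insertion_rate": self.insertion_rate,
            "mismatch_rate": self.mismatch_rate,
            "error_rate": self.error_rate,
            "align_length": self.align_length,
            "read_length": self.read_length,
        }
        if self.methylated:
            out["methylated"] = self.methylated
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        for k, v in self.to_dict().items():
            if k == "methylated":
                for typ, rates in v.items():
                    for rk, rv in rates.items():
                        lines.append(f"methylated.{typ}.{rk}\t{rv}")
            else:
                lines.append(f"{k}\t{v}")
        return "\n".join(lines) + "\n"


def compute_rates(stats: AlignmentStats,
                  annotation_rates: bool = True,
                  base_weighted_pool: bool = False) -> RateReport:
    """Turn pooled counts into the percentage rate report."""
    if stats.read_length <= 0:
        raise ValueError("read_length must be positive")
    align_length = stats.read_length + stats.deletion_length
    if align_length == 0:
        raise ValueError("zero alignment length")
    d = 100.0 * stats.deletion_length / align_length
    i = 100.0 * stats.insertion_length / align_length
    x = 100.0 * stats.mismatch_length / align_length
    report = RateReport(
        deletion_rate=d, insertion_rate=i, mismatch_rate=x,
        error_rate=d + i + x, align_length=align_length,
        read_length=stats.read_length)
    if annotation_rates and stats.methyl:
        report.methylated = methylated_rates(
            stats, base_weighted_pool=base_weighted_pool)
    return report


def methylated_rates(stats: AlignmentStats,
                     base_weighted_pool: bool = False) -> dict:
    """Per-type and pooled rates over annotated methylated areas.

    Per type k: ``XRate_k = Xbases_k / methylated_bases_k`` and
    ``ErrorRate_k`` is their sum. The pooled rates sum the per-type rates;
    with ``base_weighted_pool`` they instead divide pooled counts by pooled
    bases.
    """
    out: dict = {}
    pooled_counts = [0, 0, 0, 0]
    pooled_rates = [0.0, 0.0, 0.0]
    for typ in METHYL_TYPES:
        if typ not in stats.methyl:
            continue
        bases, dels, ins, mms = stats.methyl[typ]
        if bases == 0:
            logger.info("methylation type %s has no covered bases; omitted",
                        typ)
            continue
        d = 100.0 * dels / bases
        i = 100.0 * ins / bases
        x = 100.0 * mms / bases
        out[typ] = {"bases": bases, "deletion_rate": d, "insertion_rate": i,
                    "mismatch_rate": x, "error_rate": d + i + x}
        for idx, v in enumerate((bases, dels, ins, mms)):
            pooled_counts[idx] += v
        pooled_rates[0] += d
        pooled_rates[1] += i
        pooled_rates[2] += x
    if not out:
        return out
    if base_weighted_pool:
        bases = pooled_counts[0]
        d = 100.0 * pooled_counts[1] / bases
        i = 100.0 * pooled_counts[2] / bases
        x = 100.0 * pooled_counts[3] / bases
    else:
        d, i, x = pooled_rates
        bases = pooled_counts[0]
    out["pooled"] = {"bases": bases, "deletion_rate": d, "insertion_rate": i,
                     "mismatch_rate": x, "error_rate": d + i + x}
    return out


def rates_for_read_set(alignments: list[AlignmentRecord],
                       annotation: MethylAnnotation | None = None,
                       base_weighted_pool: bool = False) -> RateReport:
    """Micro-averaged rates over a read set: pool the lengths, then divide."""
    stats = aggregate_stats(
        [stats_from_alignment(a, annotation) for a in alignments])
    return compute_rates(stats, base_weighted_pool=base_weighted_pool)
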