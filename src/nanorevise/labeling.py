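"""Training labels from reference alignments.

Each base-level event receives two labels derived from the read's primary
alignment: the error-type label (model 1) over ``{A, C, G, T, I, D}`` and
the true-base label (model 2) over ``{A, C, G, T}``:

* match: both labels are the called base;
* mismatch: both labels are the reference base (reverse-complemented into
  read orientation for minus-strand reads);
* inserted read base: label1 = ``I``, label2 = the called base (so the
  revision rule "model 1 says insertion and model 2 agrees with the read
  base -> delete" is self-consistent);
* reference deletion: the event immediately preceding the deletion carries
  label1 = ``D`` and label2 = the first deleted reference base. Only the
  first base of a multi-base deletion is recoverable in one pass, matching
  the one-label-per-event output space.

Soft-clipped events keep their called base as labels but are flagged and
excluded from training windows. Events stay in read (basecall) orientation
throughout; for minus-strand alignments the reference segment and CIGAR are
reverse-complemented before the walk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from .types import (LABELS1, LABELS2, AlignmentRecord, EventTable,
                    LabeledEvent, MethylAnnotation, RawSignal, revcomp)
from .windows import WindowSet, windows_from_events

logger = logging.getLogger(__name__)

_CIGAR_OPS = "MIDNSHP=X"
_METHYL_PRIORITY = ("m6A", "m4C", "modified")


class LabelingError(ValueError):
    pass


@dataclass
class ParseReport:
    parsed: int = 0
    excluded_unmapped: int = 0
    excluded_secondary: int = 0
    excluded_missing: int = 0


def _resolve_matches(cigar: list[tuple[str, int]], query: str, ref: str
                     ) -> list[tuple[str, int]]:
    """Rewrite ``M`` runs as explicit ``=``/``X`` using the aligned
    sequences."""
    if not any(op == "M" for op, _ in cigar):
        return cigar
    out: list[tuple[str, int]] = []
    qi = ri = 0
    for op, n in cigar:
        if op == "M":
            for j in range(n):
                o = "=" if query[qi + j] == ref[ri + j] else "X"
                if out and out[-1][0] == o:
                    out[-1] = (o, out[-1][1] + 1)
                else:
                    out.append((o, 1))
            qi += n
            ri += n
        else:
            out.append((op, n))
            if op in "=XIS":
                qi += n
            if op in "DN":
                ri += n
    return out


def parse_alignment(sam_path: str, read_ids: set[str] | None = None,
                    reference=None) -> tuple[dict[str, AlignmentRecord],
                                             ParseReport]:
    """Load primary alignments from a SAM/BAM file.

    ``reference`` maps chromosome name to sequence (dict or pyfaidx.Fasta);
    when absent, the MD tag must allow reference reconstruction. Unmapped,
    secondary and supplementary records are skipped and counted.
    """
    report = ParseReport()
    records: dict[str, AlignmentRecord] = {}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam:
            if read_ids is not None and rec.query_name not in read_ids:
                continue
            if rec.is_unmapped:
                report.excluded_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                report.excluded_secondary += 1
                continue
            cigar = [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples]
            ref_span = sum(n for op, n in cigar if op in "=XMD")
            if reference is not None:
                ref_seq = str(reference[rec.reference_name]
                              [rec.reference_start:
                               rec.reference_start + ref_span]).upper()
            else:
                try:
                    ref_seq = rec.get_reference_sequence().upper()
                except ValueError as exc:
                    raise LabelingError(
                        f"{rec.query_name}: cannot resolve 'M' CIGAR runs; "
                        "provide a reference FASTA or MD tags") from exc
            query = rec.query_sequence
            cigar = _resolve_matches(cigar, query, ref_seq)
            records[rec.query_name] = AlignmentRecord(
                read_id=rec.query_name, ref_name=rec.reference_name,
                ref_start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=cigar, query=query, aligned_ref_segment=ref_seq)
            report.parsed += 1
    if read_ids is not None:
        report.excluded_missing = len(read_ids) - len(
            read_ids & set(records))
        if report.excluded_missing:
            logger.info("%d requested reads absent from %s",
                        report.excluded_missing, sam_path)
    return records, report


def label_events(table: EventTable, aln: AlignmentRecord
                 ) -> list[LabeledEvent]:
    """One LabeledEvent per base-level event, in read orientation."""
    read = table.sequence
    n_query = sum(n for op, n in aln.cigar if op in "=XIMS")
    if len(table.events) != len(read) or n_query != len(read):
        raise LabelingError(
            f"{table.read_id}: {len(table.events)} events vs CIGAR query "
            f"length {n_query} vs read length {len(read)}")
    if any(op == "M" for op, _ in aln.cigar):
        raise LabelingError(
            f"{table.read_id}: unresolved 'M' runs; parse with a reference")
    if any(op == "H" for op, _ in aln.cigar):
        raise LabelingError(f"{table.read_id}: hard clips are unsupported")

    ref_span = sum(n for op, n in aln.cigar if op in "=XD")
    if aln.strand == "+":
        cigar = aln.cigar
        ref = aln.aligned_ref_segment
    else:  # canonicalize into read orientation
        cigar = list(reversed(aln.cigar))
        ref = revcomp(aln.aligned_ref_segment)

    labels1: list[str] = [""] * len(read)
    labels2: list[str] = [""] * len(read)
    ref_pos: list[int | None] = [None] * len(read)
    clipped = [False] * len(read)

    qi = ri = 0
    pending_deletion: str | None = None  # leading deletion, attach forward
    for op, n in cigar:
        if op == "S":
            for j in range(qi, qi + n):
                labels1[j] = labels2[j] = read[j]
                clipped[j] = True
            qi += n
        elif op in "=X":
            for j in range(n):
                true = read[qi] if op == "=" else ref[ri]
                labels1[qi] = labels2[qi] = true
                ref_pos[qi] = (aln.ref_start + ri if aln.strand == "+"
                               else aln.ref_start + (ref_span - 1 - ri))
                if pending_deletion is not None:
                    labels1[qi] = "D"
                    labels2[qi] = pending_deletion
                    pending_deletion = None
                qi += 1
                ri += 1
        elif op == "I":
            for j in range(qi, qi + n):
                labels1[j] = "I"
                labels2[j] = read[j]
            qi += n
        elif op == "D":
            first_deleted = ref[ri]
            prev = qi - 1
            if prev >= 0 and not clipped[prev]:
                labels1[prev] = "D"
                labels2[prev] = first_deleted
            else:
                pending_deletion = first_deleted
            ri += n
        else:
            raise LabelingError(f"unsupported CIGAR op {op!r}")

    return [
        LabeledEvent(event=ev, label1=labels1[i], label2=labels2[i],
                     ref_pos=ref_pos[i], soft_clipped=clipped[i])
        for i, ev in enumerate(table.events)
    ]


def annotate_methylation(labeled: list[LabeledEvent], aln: AlignmentRecord,
                         annotation: MethylAnnotation) -> list[LabeledEvent]:
    """Set each event's methylation flag from annotated reference intervals.

    When an event's reference position falls inside intervals of several
    types, priority is m6A > m4C > modified.
    """
    if aln.ref_name not in annotation.chroms():
        if annotation.intervals:
            logger.warning("chromosome %s absent from methylation annotation",
                           aln.ref_name)
        for ev in labeled:
            ev.methyl = "none"
        return labeled
    intervals = annotation.for_chrom(aln.ref_name)
    for ev in labeled:
        ev.methyl = "none"
        if ev.ref_pos is None:
            continue
        hits = [t for s, e, t in intervals if s <= ev.ref_pos < e]
        if hits:
            ev.methyl = min(hits, key=_METHYL_PRIORITY.index)
    return labeled


def make_windows(labeled: list[LabeledEvent], raw_norm: RawSignal,
                 window: int = 13, with_methyl: bool = False,
                 sig_cap: int = 40, read_id: str = "") -> WindowSet:
    """Cut a labeled read into centred windows with per-event labels.

    Soft-clipped centres are kept (one window per event) but flagged
    non-trainable.
    """
    events = [lv.event for lv in labeled]
    methyl = [lv.methyl for lv in labeled] if with_methyl else None
    ws = windows_from_events(events, raw_norm, window=window,
                             sig_cap=sig_cap, methyl=methyl, read_id=read_id)
    ws.labels1 = np.array([LABELS1.index(lv.label1) for lv in labeled],
                          dtype=np.int64)
    ws.labels2 = np.array([LABELS2.index(lv.label2) for lv in labeled],
                          dtype=np.int64)
    ws.trainable = np.array([not lv.soft_clipped for lv in labeled],
                            dtype=bool)
    return ws


def apply_labels(labeled: list[LabeledEvent]) -> str:
    """Apply the labels as edits to the read, reconstructing the reference
    segment the read aligns to (soft-clipped events are skipped).

    Used as the round-trip check of the labeling rules: on a correct
    labeling the result equals the aligned reference segment exactly,
    provided deletions are single-base and do not abut other errors.
    """
    out: list[str] = []
    for lv in labeled:
        if lv.soft_clipped:
            continue
        if lv.label1 == "I":
            continue
        if lv.label1 == "D":
            out.append(lv.event.base)
            out.append(lv.label2)
        else:
            out.append(lv.label1)
    return "".join(out)
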