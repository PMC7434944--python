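"""Merge the two models' per-event predictions into a revised sequence.

The decision rules, applied in order to (original base, model-1 argmax,
model-2 argmax):

1. if model 1 predicts a base (not I/D) and either model agrees with the
   original base, the original base is preserved;
2. if both models predict the same base, different from the original, the
   base is substituted;
3. if model 1 calls the base an insertion and model 2 agrees with the
   original base, the base is deleted;
4. if model 1 calls a deletion, the original base is kept and the base
   inferred by model 2 is inserted after it (a D prediction concerns a
   missing neighbour, not the event's own base, so it takes precedence over
   preservation);
5. in every other case the original base is preserved, to avoid introducing
   new errors.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import BASES, LABELS1, LABELS2

logger = logging.getLogger(__name__)

KEEP = "KEEP"
SUBSTITUTE = "SUBSTITUTE"
DELETE = "DELETE"
KEEP_THEN_INSERT = "KEEP_THEN_INSERT"


@dataclass(frozen=True)
class Action:
    kind: str
    base: str | None = None


def decide(original: str, pred1: str, pred2: str) -> Action:
    """Revision action for one event. Total on the 4 x 6 x 4 input grid."""
    if original not in BASES:
        raise ValueError(f"original base must be in {BASES}, got {original!r}")
    if pred1 not in LABELS1:
        raise ValueError(f"model-1 class must be in {LABELS1}, got {pred1!r}")
    if pred2 not in LABELS2:
        raise ValueError(f"model-2 class must be in {LABELS2}, got {pred2!r}")
    if pred1 not in "ID" and (pred1 == original or pred2 == original):
        return Action(KEEP)
    if pred1 == pred2 and pred1 != original:
        return Action(SUBSTITUTE, pred1)
    if pred1 == "I" and pred2 == original:
        return Action(DELETE)
    if pred1 == "D":
        return Action(KEEP_THEN_INSERT, pred2)
    return Action(KEEP)


def revise_read(sequence: str, decisions: list[Action]) -> str:
    """Apply per-event actions left to right."""
    if len(decisions) != len(sequence):
        raise ValueError(
            f"{len(decisions)} decisions for a read of {len(sequence)} bases")
    out: list[str] = []
    for base, action in zip(sequence, decisions):
        if action.kind == KEEP:
            out.append(base)
        elif action.kind == SUBSTITUTE:
            out.append(action.base)
        elif action.kind == DELETE:
            pass
        elif action.kind == KEEP_THEN_INSERT:
            out.append(base)
            out.append(action.base)
        else:
            raise ValueError(f"unknown action kind {action.kind!r}")
    return "".join(out)


def revise_quality(quality: list[int], decisions: list[Action],
                   inserted_qual: int = 15) -> list[int]:
    """Quality string transform matching ``revise_read``."""
    out: list[int] = []
    for q, action in zip(quality, decisions):
        if action.kind == KEEP:
            out.append(q)
        elif action.kind == SUBSTITUTE:
            out.append(q)
        elif action.kind == DELETE:
            pass
        elif action.kind == KEEP_THEN_INSERT:
            out.append(q)
            out.append(inserted_qual)
    return out


def revise_file(input_path: str | os.PathLike, output_path: str | os.PathLike,
                decisions: dict[str, list[Action]],
                inserted_qual: int = 15) -> int:
    """Revise a FASTA/FASTQ file record by record.

    Reads without predictions pass through unchanged (counted and logged).
    Returns the number of records written.
    """
    fmt_in = _guess_format(input_path)
    fmt_out = _guess_format(output_path)
    passthrough = 0
    written = 0
    records_out = []
    for rec in SeqIO.parse(os.fspath(input_path), fmt_in):
        acts = decisions.get(rec.id)
        if acts is None:
            passthrough += 1
            new = rec
        else:
            seq = revise_read(str(rec.seq), acts)
            new = SeqRecord(Seq(seq), id=rec.id, description=rec.description)
            if fmt_out == "fastq":
                quals = rec.letter_annotations.get(
                    "phred_quality", [inserted_qual] * len(rec.seq))
                new.letter_annotations["phred_quality"] = revise_quality(
                    list(quals), acts, inserted_qual)
        if fmt_out == "fastq" and "phred_quality" not in new.letter_annotations:
            new = SeqRecord(Seq(str(new.seq)), id=new.id,
                            description=new.description)
            new.letter_annotations["phred_quality"] = \
                [inserted_qual] * len(new.seq)
        records_out.append(new)
        written += 1
    SeqIO.write(records_out, os.fspath(output_path), fmt_out)
    if passthrough:
        logger.info("%d reads lacked predictions and passed through",
                    passthrough)
    return written


def _guess_format(path: str | os.PathLike) -> str:
    name = os.fspath(path).lower()
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"
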