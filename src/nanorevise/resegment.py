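"""Re-segment basecaller events into exactly one event per called base.

The basecaller's ``move`` field says how many bases the DNA advanced between
consecutive events (0 = the strand stayed, 1 = one base, 2 = two bases).
Re-segmentation regroups the sample intervals accordingly:

* a move-0 event's samples are merged into the preceding base-level event
  (the pore state had not advanced past the previous base);
* a move-2 event covers two bases and its interval is split at the midpoint
  (``ceil(length / 2)`` samples to the first base);
* a leading move-0 event, which has no predecessor, merges forward into the
  first moving event.

Each output event covers one called base, carries ``move == 1``, a centred
k-mer ``model_state`` and mean/stdv recomputed from the covered raw samples.
The union of sample intervals is conserved and the operation is idempotent.
"""

from __future__ import annotations

import numpy as np

from .types import Event, EventTable, RawSignal


def interval_stats(raw: RawSignal, start: int, length: int
                   ) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation of
    ``raw.samples[start:start+length]``."""
    if length <= 0:
        raise ValueError("interval length must be positive")
    if start < 0 or start + length > raw.sample_count:
        raise ValueError(
            f"interval [{start}, {start + length}) outside signal of "
            f"{raw.sample_count} samples")
    window = raw.samples[start : start + length]
    return float(np.mean(window)), float(np.std(window))


def _kmer_at(sequence: str, i: int, k: int) -> str:
    """Centred k-mer around position ``i``, clamped at the read ends by
    repeating the terminal base."""
    half = k // 2
    chars = []
    for j in range(i - half, i - half + k):
        chars.append(sequence[min(max(j, 0), len(sequence) - 1)])
    return "".join(chars)


def resegment_events(table: EventTable, raw: RawSignal) -> EventTable:
    """Convert a basecaller event stream into base-level events.

    Returns a table with exactly ``sum(move)`` events, one per called base in
    read order. ``weight``/``p_model_state`` of merged intervals carry the
    longest constituent's values (passthrough metadata).
    """
    total_move = sum(ev.move for ev in table.events)
    if total_move == 0:
        raise ValueError(f"read {table.read_id}: sum(move) == 0, unalignable")
    if total_move != len(table.sequence):
        raise ValueError(
            f"read {table.read_id}: sum(move) ({total_move}) != sequence "
            f"length ({len(table.sequence)})")
    for ev in table.events:
        if ev.start + ev.length > raw.sample_count:
            raise ValueError(
                f"read {table.read_id}: event at {ev.start} references "
                f"samples beyond the raw signal")

    # Per base: list of (start, length) pieces plus metadata donor pieces.
    pieces: list[list[tuple[int, int, Event]]] = []
    pending: list[tuple[int, int, Event]] = []  # leading move-0 intervals
    for ev in table.events:
        if ev.move == 0:
            target = pieces[-1] if pieces else pending
            target.append((ev.start, ev.length, ev))
        elif ev.move == 1:
            pieces.append(pending + [(ev.start, ev.length, ev)])
            pending = []
        else:  # move == 2: midpoint split, first base gets ceil(length/2)
            first_len = (ev.length + 1) // 2
            second_len = ev.length - first_len
            pieces.append(pending + [(ev.start, first_len, ev)])
            pending = []
            if second_len > 0:
                pieces.append([(ev.start + first_len, second_len, ev)])
            else:  # single-sample move-2 event: second base gets no samples;
                # borrow a zero-length marker resolved below
                pieces.append([(ev.start + ev.length, 0, ev)])

    if pending:  # trailing stays with no base emitted afterwards
        pieces[-1].extend(pending)

    events: list[Event] = []
    k = len(table.events[0].model_state) if table.events else 5
    for i, plist in enumerate(pieces):
        start = min(p[0] for p in plist)
        end = max(p[0] + p[1] for p in plist)
        if end <= start:
            # degenerate zero-length split: cover one sample shared with the
            # neighbour so stats stay defined
            start = max(start - 1, 0)
            end = start + 1
        length = end - start
        mean, stdv = interval_stats(raw, start, length)
        donor = max(plist, key=lambda p: p[1])[2]
        events.append(
            Event(
                start=start, length=length, mean=mean, stdv=stdv,
                model_state=_kmer_at(table.sequence, i, k), move=1,
                weight=donor.weight, p_model_state=donor.p_model_state,
                base=table.sequence[i],
            )
        )

    out = EventTable(read_id=table.read_id, events=events,
                     sequence=table.sequence)
    return out
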