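"""Read and write raw signals and basecaller event tables.

Two on-disk representations are supported:

* an HDF5 container in the single-read fast5 layout (raw signal under
  ``Raw/Reads/<read>/Signal``, events under
  ``Analyses/Basecall_1D_000/BaseCalled_template/Events``), and
* a plain tab-separated dialect defined by this package so that fixtures and
  pipelines never require HDF5 tooling.

The TSV dialect: ``#``-prefixed header lines carry ``read_id``, ``sequence``
and the raw signal (``#signal=`` comma-separated values, or ``#signal_file=``
pointing at a one-value-per-line sidecar); the column header line is
``#start	length	mean	stdv	model_state	move	weight	p_model_state	base``
followed by one tab-separated row per event.

``model_state`` uses the centred convention: the k-mer surrounding the
event's called base, with the called base at index ``k // 2``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import h5py
import numpy as np

from .types import Event, EventTable, RawSignal

logger = logging.getLogger(__name__)

TSV_COLUMNS = (
    "start", "length", "mean", "stdv", "model_state", "move",
    "weight", "p_model_state", "base",
)


class MalformedContainerError(ValueError):
    """An input container lacks a required dataset or holds invalid data."""


@dataclass
class Fast5Layout:
    """Configurable HDF5 group paths."""

    raw_group: str = "Raw/Reads"
    signal_name: str = "Signal"
    events_path: str = "Analyses/Basecall_1D_000/BaseCalled_template/Events"
    fastq_path: str = "Analyses/Basecall_1D_000/BaseCalled_template/Fastq"


_EVENT_DTYPE = np.dtype(
    [
        ("start", "<i8"),
        ("length", "<i8"),
        ("mean", "<f8"),
        ("stdv", "<f8"),
        ("model_state", "S16"),
        ("move", "<i8"),
        ("weight", "<f8"),
        ("p_model_state", "<f8"),
        ("base", "S1"),
    ]
)


def _sequence_from_events(events: list[Event]) -> str:
    # Fallback when no fastq dataset is present: under the centred
    # model_state convention an event with move m contributes the m k-mer
    # characters ending at the centre position.
    parts = []
    for ev in events:
        if ev.move == 0:
            continue
        c = len(ev.model_state) // 2
        parts.append(ev.model_state[c - ev.move + 1 : c + 1])
    return "".join(parts)


def read_fast5(path: str | os.PathLike, layout: Fast5Layout | None = None
               ) -> tuple[RawSignal, EventTable]:
    """Load one read's raw signal and event table from an HDF5 container."""
    layout = layout or Fast5Layout()
    with h5py.File(path, "r") as f:
        if layout.raw_group not in f:
            raise MalformedContainerError(
                f"{path}: missing raw signal group {layout.raw_group!r}")
        reads = list(f[layout.raw_group])
        if not reads:
            raise MalformedContainerError(f"{path}: no reads under raw group")
        read_group = f[layout.raw_group][reads[0]]
        if layout.signal_name not in read_group:
            raise MalformedContainerError(
                f"{path}: missing dataset "
                f"{layout.raw_group}/{reads[0]}/{layout.signal_name}")
        samples = np.asarray(read_group[layout.signal_name], dtype=np.float64)
        if samples.size == 0:
            raise MalformedContainerError(f"{path}: empty raw signal")
        read_id = read_group.attrs.get("read_id", reads[0])
        if isinstance(read_id, bytes):
            read_id = read_id.decode()

        if layout.events_path not in f:
            raise MalformedContainerError(
                f"{path}: missing event dataset {layout.events_path!r}")
        rows = f[layout.events_path][()]
        events = [
            Event(
                start=int(r["start"]), length=int(r["length"]),
                mean=float(r["mean"]), stdv=float(r["stdv"]),
                model_state=r["model_state"].decode(), move=int(r["move"]),
                weight=float(r["weight"]),
                p_model_state=float(r["p_model_state"]),
                base=r["base"].decode(),
            )
            for r in rows
        ]
        if layout.fastq_path in f:
            fastq = f[layout.fastq_path][()]
            if isinstance(fastq, bytes):
                fastq = fastq.decode()
            sequence = fastq.splitlines()[1]
        else:
            sequence = _sequence_from_events(events)

    raw = RawSignal(read_id=str(read_id), samples=samples)
    table = EventTable(read_id=str(read_id), events=events, sequence=sequence)
    table.validate(raw)
    return raw, table


def write_fast5(path: str | os.PathLike, raw: RawSignal, table: EventTable,
                layout: Fast5Layout | None = None) -> None:
    layout = layout or Fast5Layout()
    with h5py.File(path, "w") as f:
        grp = f.create_group(f"{layout.raw_group}/Read_{raw.read_id}")
        grp.attrs["read_id"] = raw.read_id
        grp.create_dataset(layout.signal_name, data=raw.samples)
        rows = np.zeros(len(table.events), dtype=_EVENT_DTYPE)
        for i, ev in enumerate(table.events):
            rows[i] = (ev.start, ev.length, ev.mean, ev.stdv,
                       ev.model_state.encode(), ev.move, ev.weight,
                       ev.p_model_state, ev.base.encode())
        f.create_dataset(layout.events_path, data=rows)
        qual = "!" * len(table.sequence)
        f.create_dataset(
            layout.fastq_path,
            data=f"@{table.read_id}\n{table.sequence}\n+\n{qual}\n")


def write_event_tsv(path: str | os.PathLike, raw: RawSignal,
                    table: EventTable, signal_file: str | None = None) -> None:
    """Write the TSV dialect; signal is inlined unless ``signal_file`` names
    a sidecar (written next to ``path``)."""
    with open(path, "w") as out:
        out.write(f"#read_id={table.read_id}\n")
        out.write(f"#sequence={table.sequence}\n")
        if signal_file is None:
            sig = ",".join(format(x, ".6g") for x in raw.samples)
            out.write(f"#signal={sig}\n")
        else:
            out.write(f"#signal_file={signal_file}\n")
            sidecar = os.path.join(os.path.dirname(os.fspath(path)), signal_file)
            np.savetxt(sidecar, raw.samples, fmt="%.6g")
        out.write("#" + "\t".join(TSV_COLUMNS) + "\n")
        for ev in table.events:
            out.write(
                f"{ev.start}\t{ev.length}\t{ev.mean:.6g}\t{ev.stdv:.6g}\t"
                f"{ev.model_state}\t{ev.move}\t{ev.weight:.6g}\t"
                f"{ev.p_model_state:.6g}\t{ev.base}\n")


def read_event_tsv(path: str | os.PathLike) -> tuple[RawSignal, EventTable]:
    read_id = ""
    sequence = ""
    samples: np.ndarray | None = None
    events: list[Event] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:]
                if body.startswith("read_id="):
                    read_id = body[len("read_id="):]
                elif body.startswith("sequence="):
                    sequence = body[len("sequence="):]
                elif body.startswith("signal="):
                    payload = body[len("signal="):]
                    samples = np.array(
                        [float(t) for t in payload.split(",") if t],
                        dtype=np.float64)
                elif body.startswith("signal_file="):
                    sidecar = os.path.join(
                        os.path.dirname(os.fspath(path)),
                        body[len("signal_file="):])
                    samples = np.loadtxt(sidecar, ndmin=1)
                continue
            fields = line.split("\t")
            if len(fields) != len(TSV_COLUMNS):
                raise MalformedContainerError(
                    f"{path}:{lineno}: expected {len(TSV_COLUMNS)} columns, "
                    f"got {len(fields)}")
            try:
                ev = Event(
                    start=int(fields[0]), length=int(fields[1]),
                    mean=float(fields[2]), stdv=float(fields[3]),
                    model_state=fields[4], move=int(fields[5]),
                    weight=float(fields[6]), p_model_state=float(fields[7]),
                    base=fields[8],
                )
                ev.validate()
            except ValueError as exc:
                raise MalformedContainerError(
                    f"{path}:{lineno}: {exc}") from exc
            events.append(ev)
    if samples is None:
        raise MalformedContainerError(f"{path}: no signal header found")
    if not events:
        logger.warning("%s: header-only event table (no events)", path)
    raw = RawSignal(read_id=read_id, samples=samples)
    table = EventTable(read_id=read_id, events=events, sequence=sequence)
    if events:
        table.validate(raw)
    return raw, table


def normalize_signal(raw: RawSignal) -> RawSignal:
    """Median/MAD-scale a raw signal: ``(x - median) / (1.4826 * MAD)``.

    Robust to current spikes. Falls back to the standard deviation when the
    MAD is zero, and to an all-zero output when the spread is zero entirely.
    Idempotent (a normalized signal passes through unchanged) whenever the
    MAD is positive.
    """
    x = raw.samples
    if x.size == 0:
        raise ValueError("cannot normalize an empty signal")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0.0:
        scale = float(np.std(x))
    if scale == 0.0:
        return RawSignal(read_id=raw.read_id, samples=np.zeros_like(x))
    return RawSignal(read_id=raw.read_id, samples=(x - med) / scale)
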