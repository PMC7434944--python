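"""The three user-facing commands: train, revise, eval.

Each command is a plain function over paths; the click CLI in
:mod:`nanorevise.cli` is a thin wrapper. Inputs are event TSVs (or fast5
containers), a SAM/BAM alignment, a reference FASTA and optionally a
methylation BED; all randomness flows from a single seed.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass

from pyfaidx import Fasta

from .event_io import normalize_signal, read_event_tsv, read_fast5
from .labeling import (annotate_methylation, label_events, make_windows,
                       parse_alignment)
from .metrics import RateReport, rates_for_read_set
from .model import (ModelConfig, build_main_model, load_checkpoint,
                    predict_events, save_checkpoint, train_model)
from .resegment import resegment_events
from .revision import decide, revise_read
from .synthetic import read_methylation_bed
from .types import LABELS1, LABELS2
from .windows import concat_window_sets, windows_from_events

logger = logging.getLogger(__name__)


def _load_reads(input_path: str):
    """Yield (raw, table) from a directory of TSVs, a glob, or single
    TSV/fast5 files."""
    if os.path.isdir(input_path):
        paths = sorted(glob.glob(os.path.join(input_path, "*.tsv")))
        paths += sorted(glob.glob(os.path.join(input_path, "*.fast5")))
    else:
        paths = sorted(glob.glob(input_path)) or [input_path]
    for p in paths:
        if p.endswith(".fast5"):
            yield read_fast5(p)
        else:
            yield read_event_tsv(p)


def _load_reference(path: str) -> dict[str, str]:
    fa = Fasta(path)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


@dataclass
class TrainPaths:
    events: str
    sam: str
    reference: str
    out_dir: str
    methyl_bed: str | None = None


def cmd_train(paths: TrainPaths, config: ModelConfig | None = None,
              with_methyl: bool = False) -> dict:
    """Preprocess, label, window and train both models; writes
    ``model1.npz``, ``model2.npz`` and ``loss_log.tsv`` to ``out_dir``."""
    base_cfg = config or ModelConfig()
    reference = _load_reference(paths.reference)
    annotation = (read_methylation_bed(paths.methyl_bed)
                  if paths.methyl_bed else None)
    alignments, report = parse_alignment(paths.sam, reference=reference)
    logger.info("parsed %d alignments (%d unmapped, %d secondary skipped)",
                report.parsed, report.excluded_unmapped,
                report.excluded_secondary)

    sets = []
    skipped = 0
    for raw, table in _load_reads(paths.events):
        aln = alignments.get(table.read_id)
        if aln is None:
            skipped += 1
            continue
        norm = normalize_signal(raw)
        base = resegment_events(table, norm)
        labeled = label_events(base, aln)
        if with_methyl and annotation is not None:
            labeled = annotate_methylation(labeled, aln, annotation)
        sets.append(make_windows(labeled, norm, window=base_cfg.window,
                                 with_methyl=with_methyl,
                                 sig_cap=base_cfg.sig_cap,
                                 read_id=table.read_id))
    if not sets:
        raise RuntimeError(
            f"no mappable reads ({skipped} reads lacked alignments)")
    windows = concat_window_sets(sets)

    os.makedirs(paths.out_dir, exist_ok=True)
    log_path = os.path.join(paths.out_dir, "loss_log.tsv")
    traces = {}
    with open(log_path, "w") as log:
        log.write("model\tepoch\ttotal\tls\tlc\n")
        for name, ncls, key in (("model1", 6, "labels1"),
                                ("model2", 4, "labels2")):
            cfg = ModelConfig(**{**base_cfg.__dict__,
                                 "num_classes": ncls,
                                 "feature_dim": windows.feature_dim})
            model = build_main_model(cfg)
            trace = train_model(model, windows, label_key=key)
            for row in trace:
                log.write(f"{name}\t{row['epoch']}\t{row['total']:.6f}\t"
                          f"{row['ls']:.6f}\t{row['lc']:.6f}\n")
            save_checkpoint(model, os.path.join(paths.out_dir, f"{name}.npz"))
            traces[name] = trace
    return traces


@dataclass
class RevisePaths:
    events: str
    model1: str
    model2: str
    output: str
    sam: str | None = None
    reference: str | None = None
    methyl_bed: str | None = None


def cmd_revise(paths: RevisePaths) -> int:
    """Revise every input read with the two checkpoints; returns the number
    of records written."""
    model1 = load_checkpoint(paths.model1)
    model2 = load_checkpoint(paths.model2)
    if model1.config.window != model2.config.window or \
            model1.config.sig_cap != model2.config.sig_cap or \
            model1.config.feature_dim != model2.config.feature_dim:
        raise ValueError("model1/model2 checkpoints have incompatible "
                         "window or feature configurations")
    cfg = model1.config
    with_methyl = cfg.feature_dim == 10
    annotation = alignments = None
    if with_methyl:
        if not (paths.methyl_bed and paths.sam):
            raise ValueError("methylation-aware checkpoints need --sam and "
                             "--methylation inputs")
        annotation = read_methylation_bed(paths.methyl_bed)
        reference = (_load_reference(paths.reference)
                     if paths.reference else None)
        alignments, _ = parse_alignment(paths.sam, reference=reference)

    n = 0
    with open(paths.output, "w") as out:
        for raw, table in _load_reads(paths.events):
            norm = normalize_signal(raw)
            base = resegment_events(table, norm)
            methyl = None
            if with_methyl and alignments and table.read_id in alignments:
                labeled = label_events(base, alignments[table.read_id])
                labeled = annotate_methylation(
                    labeled, alignments[table.read_id], annotation)
                methyl = [lv.methyl for lv in labeled]
            ws = windows_from_events(base.events, norm, window=cfg.window,
                                     sig_cap=cfg.sig_cap, methyl=methyl,
                                     read_id=table.read_id)
            p1 = predict_events(model1, ws).argmax(axis=1)
            p2 = predict_events(model2, ws).argmax(axis=1)
            decisions = [decide(ev.base, LABELS1[p1[i]], LABELS2[p2[i]])
                         for i, ev in enumerate(base.events)]
            revised = revise_read(base.sequence, decisions)
            out.write(f">{table.read_id}\n{revised}\n")
            n += 1
    return n


def cmd_eval(sam_path: str, reference_path: str,
             methyl_bed: str | None = None,
             out_prefix: str | None = None) -> tuple[RateReport, int]:
    """Alignment-based rate report for a SAM; returns (report, n_reads)."""
    reference = _load_reference(reference_path)
    annotation = read_methylation_bed(methyl_bed) if methyl_bed else None
    alignments, report = parse_alignment(sam_path, reference=reference)
    if not alignments:
        # still leave a report behind so downstream tooling sees the count
        if out_prefix:
            with open(out_prefix + ".json", "w") as fh:
                fh.write('{"reads": 0}\n')
            with open(out_prefix + ".tsv", "w") as fh:
                fh.write("metric\tvalue\nreads\t0\n")
        raise RuntimeError("no primary alignments in input SAM")
    rates = rates_for_read_set(list(alignments.values()), annotation)
    if out_prefix:
        with open(out_prefix + ".json", "w") as fh:
            fh.write(rates.to_json())
        with open(out_prefix + ".tsv", "w") as fh:
            fh.write(rates.to_tsv())
    return rates, len(alignments)
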