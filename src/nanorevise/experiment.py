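"""End-to-end error-reduction experiment on synthetic reads.

Simulates a read set with injected errors, trains the twin models on a
training split, revises a held-out test split, and measures alignment-based
error rates before and after revision with the same aligner (edlib,
infix mode) for both arms. This is the desk-scale analogue of training on
real runs: the quantity of interest is the error-rate drop, not its
absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .event_io import normalize_signal
from .labeling import annotate_methylation, label_events, make_windows
from .metrics import rates_for_read_set
from .model import MainModel, ModelConfig, build_main_model, predict_events, train_model
from .resegment import resegment_events
from .revision import decide, revise_read
from .synthetic import Dataset, ErrorProfile, PoreModel, SimulatedRead, generate_dataset
from .types import LABELS1, LABELS2, AlignmentRecord, MethylAnnotation, revcomp
from .windows import WindowSet, concat_window_sets

logger = logging.getLogger(__name__)


def align_to_reference(read_id: str, sequence: str, reference: str,
                       ref_name: str, strand: str) -> AlignmentRecord:
    """Infix-align a read against the reference with edlib and return an
    alignment record in SAM orientation."""
    query = sequence if strand == "+" else revcomp(sequence)
    res = edlib.align(query, reference, mode="HW", task="path")
    start, end = res["locations"][0]
    cigar: list[tuple[str, int]] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            cigar.append((ch, int(num)))
            num = ""
    return AlignmentRecord(
        read_id=read_id, ref_name=ref_name, ref_start=start, strand=strand,
        cigar=cigar, query=query,
        aligned_ref_segment=reference[start : end + 1])


def prepare_training_windows(reads: list[SimulatedRead],
                             annotation: MethylAnnotation | None,
                             window: int, sig_cap: int,
                             with_methyl: bool) -> WindowSet:
    sets = []
    for sr in reads:
        norm = normalize_signal(sr.raw)
        base = resegment_events(sr.table, norm)
        labeled = label_events(base, sr.aln)
        if with_methyl and annotation is not None:
            labeled = annotate_methylation(labeled, sr.aln, annotation)
        sets.append(make_windows(labeled, norm, window=window,
                                 with_methyl=with_methyl, sig_cap=sig_cap,
                                 read_id=sr.table.read_id))
    return concat_window_sets(sets)


def revise_simulated_read(sr: SimulatedRead, model1: MainModel,
                          model2: MainModel,
                          annotation: MethylAnnotation | None,
                          with_methyl: bool) -> str:
    norm = normalize_signal(sr.raw)
    base = resegment_events(sr.table, norm)
    labeled = label_events(base, sr.aln)
    if with_methyl and annotation is not None:
        labeled = annotate_methylation(labeled, sr.aln, annotation)
    cfg = model1.config
    ws = make_windows(labeled, norm, window=cfg.window,
                      with_methyl=with_methyl, sig_cap=cfg.sig_cap,
                      read_id=sr.table.read_id)
    p1 = predict_events(model1, ws)
    p2 = predict_events(model2, ws)
    a1 = p1.argmax(axis=1)
    a2 = p2.argmax(axis=1)
    decisions = [decide(ev.base, LABELS1[a1[i]], LABELS2[a2[i]])
                 for i, ev in enumerate(base.events)]
    return revise_read(base.sequence, decisions)


@dataclass
class ExperimentResult:
    per_seed: dict = field(default_factory=dict)

    def all_improved(self) -> bool:
        return all(v["revised"]["error_rate"] < v["unrevised"]["error_rate"]
                   for v in self.per_seed.values())


def train_models(windows: WindowSet, seed: int, window: int, sig_cap: int,
                 feature_dim: int, epochs: int = 10
                 ) -> tuple[MainModel, MainModel, list[dict], list[dict]]:
    cfg1 = ModelConfig.reduced(num_classes=6, seed=seed, window=window,
                               sig_cap=sig_cap, feature_dim=feature_dim,
                               epochs=epochs)
    cfg2 = ModelConfig.reduced(num_classes=4, seed=seed, window=window,
                               sig_cap=sig_cap, feature_dim=feature_dim,
                               epochs=epochs)
    model1 = build_main_model(cfg1)
    model2 = build_main_model(cfg2)
    trace1 = train_model(model1, windows, label_key="labels1")
    trace2 = train_model(model2, windows, label_key="labels2")
    return model1, model2, trace1, trace2


def run_error_reduction_experiment(
        seeds: tuple[int, ...] = (1, 2, 3),
        n_train: int = 200, n_test: int = 50, span: int = 500,
        base_seed: int = 0,
        pore: PoreModel | None = None,
        errors: ErrorProfile | None = None,
        methyl_density: float = 0.0,
        with_methyl: bool = False,
        ref_length: int | None = None,
        window: int = 13, sig_cap: int = 16, epochs: int = 10,
        dataset: Dataset | None = None) -> ExperimentResult:
    """Train on ``n_train`` reads, revise ``n_test`` held-out reads, and
    report pooled error rates before and after revision for each seed.

    ``base_seed`` drives the data simulation; each entry of ``seeds`` drives
    one independent model initialization/shuffling run on the same data.
    """
    if dataset is None:
        dataset = generate_dataset(
            n_train + n_test, span, pore=pore, errors=errors, seed=base_seed,
            ref_length=ref_length, methyl_density=methyl_density)
    train_reads = dataset.reads[:n_train]
    test_reads = dataset.reads[n_train : n_train + n_test]
    annotation = dataset.annotation if dataset.annotation.intervals else None

    windows = prepare_training_windows(
        train_reads, annotation, window, sig_cap, with_methyl)
    feature_dim = windows.feature_dim

    unrevised_alns = [
        align_to_reference(sr.table.read_id, sr.table.sequence,
                           dataset.reference, dataset.ref_name, sr.strand)
        for sr in test_reads]
    unrevised = rates_for_read_set(unrevised_alns, annotation,
                                   base_weighted_pool=True)

    result = ExperimentResult()
    for seed in seeds:
        model1, model2, trace1, trace2 = train_models(
            windows, seed, window, sig_cap, feature_dim, epochs)
        revised_alns = []
        for sr in test_reads:
            revised_seq = revise_simulated_read(
                sr, model1, model2, annotation, with_methyl)
            revised_alns.append(align_to_reference(
                sr.table.read_id, revised_seq, dataset.reference,
                dataset.ref_name, sr.strand))
        revised = rates_for_read_set(revised_alns, annotation,
                                     base_weighted_pool=True)
        result.per_seed[seed] = {
            "unrevised": unrevised.to_dict(),
            "revised": revised.to_dict(),
            "final_loss_model1": trace1[-1]["total"],
            "final_loss_model2": trace2[-1]["total"],
        }
        logger.info("seed %d: error %.2f%% -> %.2f%%", seed,
                    unrevised.error_rate, revised.error_rate)
    return result


#: Desk-scale study conditions for the end-to-end experiment: the nominal
#: run (200 training + 50 test reads of 500 bp over a 2 kb reference,
#: ~50x training coverage) shrunk to fit a single-CPU NumPy training loop
#: while preserving that coverage. All model and error settings are the
#: nominal ones: 15% error split del:ins:mm = 6:5:8, window 13, reduced
#: network (8 filters, LSTM states 16/32, batch 64), 10 epochs.
DESK_SCALE = dict(n_train=75, n_test=20, span=150, ref_length=180,
                  sig_cap=8, epochs=10, window=13)


def run_desk_scale_experiment(base_seed: int = 0,
                              seeds: tuple[int, ...] = (1, 2, 3),
                              methyl_shift: float = 15.0,
                              methyl_density: float = 0.05) -> dict:
    """The shared end-to-end run: one methylated synthetic read set (well
    separated methylation currents), trained and revised per seed twice —
    without and with the methylation feature channel.

    Returns ``{"plain": ExperimentResult, "methyl": ExperimentResult}``.
    """
    pore = PoreModel(methyl_shift=methyl_shift)
    ds = generate_dataset(
        DESK_SCALE["n_train"] + DESK_SCALE["n_test"], DESK_SCALE["span"],
        pore=pore, seed=base_seed, ref_length=DESK_SCALE["ref_length"],
        methyl_density=methyl_density)
    kwargs = dict(seeds=seeds, n_train=DESK_SCALE["n_train"],
                  n_test=DESK_SCALE["n_test"], span=DESK_SCALE["span"],
                  window=DESK_SCALE["window"], sig_cap=DESK_SCALE["sig_cap"],
                  epochs=DESK_SCALE["epochs"], dataset=ds)
    plain = run_error_reduction_experiment(with_methyl=False, **kwargs)
    methyl = run_error_reduction_experiment(with_methyl=True, **kwargs)
    return {"plain": plain, "methyl": methyl}
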