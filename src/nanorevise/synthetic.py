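"""Fully synthetic reads with known ground truth.

The generative model is the minimal one consistent with event semantics:
each base dwells in the pore for a geometric number of samples and emits
Gaussian current around a per-k-mer level (centred k-mer context, optional
additive shift at annotated methylated positions). Basecalling errors are
injected against a reference window:

* mismatch — the called base differs, the signal reflects the true k-mer;
* insertion — a spurious extra called base whose samples duplicate the
  preceding pore level (a split event miscalled as a base);
* deletion — a true base missing from the read; its samples are absorbed
  into the preceding called base's event (an anomalously long, mixed event).

Errors are injected by a first-order process that forbids errors at
adjacent template positions (so each truth alignment is unambiguous and
every deletion is single-base) while preserving the configured marginal
rates, and keeps a 3-base error-free margin at the read ends. The event
stream then receives stay events (``move == 0``, a random split of one
base's samples) and fusions (``move == 2``, two bases sharing one event).
Truth alignments are written directly from the injection log — never
re-aligned — so labeling tests are alignment-tool independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (AlignmentRecord, BASES, Event, EventTable,
                    MethylAnnotation, RawSignal, revcomp)

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_EDGE_MARGIN = 3


@dataclass
class PoreModel:
    """Per-k-mer Gaussian current model with geometric dwell times."""

    k: int = 5
    level_mean: float = 100.0    # pA, grand mean over k-mers
    level_spread: float = 12.0   # pA, between-k-mer spread
    noise_sd: float = 1.5        # pA, within-event noise
    dwell: float = 9.0           # mean samples per base (>= 1)
    methyl_shift: float = 5.0    # pA, added at annotated positions
    stay_prob: float = 0.15      # P(a base's event is split by a stay)
    fuse_prob: float = 0.05      # P(two neighbouring bases share an event)
    table_seed: int = 2024

    def __post_init__(self) -> None:
        if self.dwell < 1:
            raise ValueError("mean dwell must be >= 1 sample per base")
        if self.noise_sd <= 0 or self.level_spread <= 0:
            raise ValueError("spreads must be positive")
        rng = np.random.default_rng(self.table_seed)
        n = 4 ** self.k
        self._means = self.level_mean + self.level_spread * rng.standard_normal(n)
        self._sds = self.noise_sd * rng.uniform(0.75, 1.25, size=n)

    def kmer_index(self, kmer: str) -> int:
        idx = 0
        for ch in kmer:
            idx = idx * 4 + _BASE_IDX[ch]
        return idx

    def level(self, kmer: str) -> tuple[float, float]:
        i = self.kmer_index(kmer)
        return float(self._means[i]), float(self._sds[i])


@dataclass
class ErrorProfile:
    """Per-base injection probabilities; defaults follow the del:ins:mm =
    6:5:8 split of a 15% total error rate."""

    mismatch: float = 0.15 * 8 / 19
    insertion: float = 0.15 * 5 / 19
    deletion: float = 0.15 * 6 / 19
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = (self.mismatch, self.insertion, self.deletion)
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) >= 1:
            raise ValueError("error probabilities must lie in [0,1] and "
                             "sum to less than 1")

    @property
    def total(self) -> float:
        return self.mismatch + self.insertion + self.deletion

    @classmethod
    def error_free(cls) -> "ErrorProfile":
        return cls(mismatch=0.0, insertion=0.0, deletion=0.0)


@dataclass
class SimulatedRead:
    raw: RawSignal
    table: EventTable
    aln: AlignmentRecord        # truth alignment, SAM orientation
    strand: str
    ref_start: int
    ref_span: int
    expected_intervals: list[tuple[int, int]]  # per base, post-resegmentation
    error_counts: dict = field(default_factory=dict)


@dataclass
class Dataset:
    reference: str
    ref_name: str
    annotation: MethylAnnotation
    reads: list[SimulatedRead]


def simulate_reference(length: int, seed: int, k: int = 5,
                       methyl_density: float = 0.0, name: str = "ref"
                       ) -> tuple[str, MethylAnnotation]:
    """Uniform random reference plus single-base methylation intervals
    (m6A on A, m4C on C, 'modified' elsewhere) at the stated density."""
    if length < k:
        raise ValueError(f"reference length {length} shorter than k-mer {k}")
    rng = np.random.default_rng(seed)
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    intervals: list[tuple[str, int, int, str]] = []
    if methyl_density > 0:
        hits = np.flatnonzero(rng.random(length) < methyl_density)
        for p in hits:
            base = seq[p]
            mtype = {"A": "m6A", "C": "m4C"}.get(base, "modified")
            intervals.append((name, int(p), int(p) + 1, mtype))
    return seq, MethylAnnotation(intervals=intervals)


def _kmer_at(seq: str, i: int, k: int) -> str:
    half = k // 2
    return "".join(seq[min(max(j, 0), len(seq) - 1)]
                   for j in range(i - half, i - half + k))


def simulate_read(reference: str, ref_start: int, span: int, pore: PoreModel,
                  errors: ErrorProfile, seed: int, strand: str = "+",
                  annotation: MethylAnnotation | None = None,
                  ref_name: str = "ref", read_id: str = "read"
                  ) -> SimulatedRead:
    """Simulate one read over ``reference[ref_start:ref_start+span]``."""
    if ref_start < 0 or ref_start + span > len(reference):
        raise ValueError("read window outside the reference")
    if span < 2 * _EDGE_MARGIN + pore.k:
        raise ValueError("read span too short for the error-free margins")
    rng = np.random.default_rng(seed)
    window = reference[ref_start : ref_start + span]
    template = window if strand == "+" else revcomp(window)

    methyl_pos: set[int] = set()
    if annotation is not None:
        for chrom, s, e, _t in annotation.intervals:
            if chrom == ref_name:
                methyl_pos.update(range(s, e))

    def genomic(i: int) -> int:
        return ref_start + i if strand == "+" else ref_start + span - 1 - i

    # --- error injection over template positions --------------------------
    # Adjusted probabilities preserve the marginal rates despite the
    # forced error-free position after each error.
    denom = 1.0 - errors.total
    q_mm = errors.mismatch / denom if denom > 0 else 0.0
    q_ins = errors.insertion / denom if denom > 0 else 0.0
    q_del = errors.deletion / denom if denom > 0 else 0.0

    read_chars: list[str] = []
    origin: list[tuple[str, int]] = []  # per read base: (kind, template idx)
    cigar_ops: list[str] = []           # template-orientation ops, one char each
    absorb: dict[int, int] = {}         # read base j -> deleted template idx
    counts = {"mismatch": 0, "insertion": 0, "deletion": 0}
    cooldown = False
    for i in range(span):
        kind = "match"
        if _EDGE_MARGIN <= i < span - _EDGE_MARGIN and not cooldown:
            u = rng.random()
            if u < q_mm:
                kind = "mismatch"
            elif u < q_mm + q_del:
                kind = "deletion"
            elif u < q_mm + q_del + q_ins:
                kind = "insertion"
        cooldown = kind != "match"
        if kind == "deletion":
            counts["deletion"] += 1
            absorb[len(read_chars) - 1] = i
            cigar_ops.append("D")
            continue
        if kind == "mismatch":
            counts["mismatch"] += 1
            true = template[i]
            alt = BASES[(rng.integers(1, 4) + _BASE_IDX[true]) % 4]
            read_chars.append(alt)
            origin.append(("mismatch", i))
            cigar_ops.append("X")
            continue
        read_chars.append(template[i])
        origin.append(("match", i))
        cigar_ops.append("=")
        if kind == "insertion":
            counts["insertion"] += 1
            read_chars.append(BASES[rng.integers(0, 4)])
            origin.append(("insert", i))
            cigar_ops.append("I")
    read = "".join(read_chars)

    # --- signal generation -------------------------------------------------
    per_base_samples: list[np.ndarray] = []
    for j, (kind, i) in enumerate(origin):
        kmer = _kmer_at(template, i, pore.k)
        mean, sd = pore.level(kmer)
        if kind != "insert" and genomic(i) in methyl_pos:
            mean += pore.methyl_shift
        dwell = int(rng.geometric(1.0 / pore.dwell))
        per_base_samples.append(rng.normal(mean, sd, size=dwell))
    for j, i_del in absorb.items():
        kmer = _kmer_at(template, i_del, pore.k)
        mean, sd = pore.level(kmer)
        if genomic(i_del) in methyl_pos:
            mean += pore.methyl_shift
        dwell = int(rng.geometric(1.0 / pore.dwell))
        per_base_samples[j] = np.concatenate(
            [per_base_samples[j], rng.normal(mean, sd, size=dwell)])

    samples = np.concatenate(per_base_samples)
    starts = np.concatenate([[0], np.cumsum([s.size for s in per_base_samples])])
    base_intervals = [(int(starts[j]), int(starts[j + 1] - starts[j]))
                      for j in range(len(read))]

    # --- basecaller event stream: fusions then stays -----------------------
    def make_event(start: int, length: int, move: int, j: int) -> Event:
        seg = samples[start : start + length]
        return Event(start=start, length=length, mean=float(seg.mean()),
                     stdv=float(seg.std()),
                     model_state=_kmer_at(read, j, pore.k), move=move,
                     weight=1.0, p_model_state=float(rng.uniform(0.2, 1.0)),
                     base=read[j])

    expected = list(base_intervals)
    events: list[Event] = []
    j = 0
    while j < len(read):
        s, L = base_intervals[j]
        if (j + 1 < len(read) and rng.random() < pore.fuse_prob
                and base_intervals[j][1] + base_intervals[j + 1][1] >= 2):
            s2, L2 = base_intervals[j + 1]
            total = L + L2
            events.append(make_event(s, total, 2, j + 1))
            first_len = (total + 1) // 2
            expected[j] = (s, first_len)
            expected[j + 1] = (s + first_len, total - first_len)
            j += 2
            continue
        if L >= 2 and rng.random() < pore.stay_prob:
            cut = int(rng.integers(1, L))
            events.append(make_event(s, cut, 1, j))
            events.append(make_event(s + cut, L - cut, 0, j))
        else:
            events.append(make_event(s, L, 1, j))
        j += 1

    raw = RawSignal(read_id=read_id, samples=samples)
    table = EventTable(read_id=read_id, events=events, sequence=read)

    # --- truth alignment (SAM orientation) ---------------------------------
    ops = cigar_ops if strand == "+" else list(reversed(cigar_ops))
    runs: list[tuple[str, int]] = []
    for op in ops:
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    aln = AlignmentRecord(
        read_id=read_id, ref_name=ref_name, ref_start=ref_start,
        strand=strand, cigar=runs,
        query=read if strand == "+" else revcomp(read),
        aligned_ref_segment=window)

    return SimulatedRead(raw=raw, table=table, aln=aln, strand=strand,
                         ref_start=ref_start, ref_span=span,
                         expected_intervals=expected, error_counts=counts)


def generate_dataset(n_reads: int, span: int,
                     pore: PoreModel | None = None,
                     errors: ErrorProfile | None = None,
                     seed: int = 0, ref_length: int | None = None,
                     methyl_density: float = 0.0,
                     reverse_fraction: float = 0.5,
                     ref_name: str = "ref") -> Dataset:
    """Simulate a self-consistent read set over one random reference."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    pore = pore or PoreModel()
    errors = errors or ErrorProfile()
    ref_length = ref_length or max(2 * span, 2000)
    rng = np.random.default_rng(seed)
    ref_seed = int(rng.integers(2 ** 31))
    reference, annotation = simulate_reference(
        ref_length, ref_seed, k=pore.k, methyl_density=methyl_density,
        name=ref_name)
    reads = []
    for r in range(n_reads):
        start = int(rng.integers(0, ref_length - span + 1))
        strand = "-" if rng.random() < reverse_fraction else "+"
        child = int(rng.integers(2 ** 31))
        reads.append(simulate_read(
            reference, start, span, pore, errors, seed=child, strand=strand,
            annotation=annotation, ref_name=ref_name, read_id=f"read{r:05d}"))
    return Dataset(reference=reference, ref_name=ref_name,
                   annotation=annotation, reads=reads)


def write_dataset(dataset: Dataset, out_dir: str) -> None:
    """Write the on-disk fixture set: per-read event TSVs, reference FASTA,
    truth SAM (written from the injection log, never re-aligned), called
    reads FASTA and methylation BED."""
    import os
    import pysam
    from .event_io import write_event_tsv

    os.makedirs(os.path.join(out_dir, "events"), exist_ok=True)
    with open(os.path.join(out_dir, "ref.fa"), "w") as fa:
        fa.write(f">{dataset.ref_name}\n")
        for i in range(0, len(dataset.reference), 70):
            fa.write(dataset.reference[i : i + 70] + "\n")
    with open(os.path.join(out_dir, "reads.fasta"), "w") as fa:
        for sr in dataset.reads:
            fa.write(f">{sr.table.read_id}\n{sr.table.sequence}\n")
    with open(os.path.join(out_dir, "methyl.bed"), "w") as bed:
        for chrom, s, e, t in dataset.annotation.intervals:
            bed.write(f"{chrom}\t{s}\t{e}\t{t}\n")
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": dataset.ref_name, "LN": len(dataset.reference)}]}
    with pysam.AlignmentFile(os.path.join(out_dir, "truth.sam"), "w",
                             header=header) as sam:
        for sr in dataset.reads:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = sr.table.read_id
            a.query_sequence = sr.aln.query
            a.flag = 16 if sr.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = sr.ref_start
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{n}{op}" for op, n in sr.aln.cigar)
            sam.write(a)
    for sr in dataset.reads:
        write_event_tsv(
            os.path.join(out_dir, "events", f"{sr.table.read_id}.tsv"),
            sr.raw, sr.table)


def read_methylation_bed(path: str) -> MethylAnnotation:
    """BED3+1 (4th column = m6A / m4C / modified)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, t = line.split("\t")[:4]
            intervals.append((chrom, int(s), int(e), t))
    return MethylAnnotation(intervals=intervals)
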