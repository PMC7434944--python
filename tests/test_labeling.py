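"""Alignment-derived training labels, methylation flags and windowing."""

import numpy as np
import pytest

from nanorevise.event_io import normalize_signal
from nanorevise.labeling import (LabelingError, annotate_methylation,
                                 apply_labels, label_events, make_windows,
                                 parse_alignment)
from nanorevise.resegment import resegment_events
from nanorevise.types import (AlignmentRecord, Event, EventTable,
                              MethylAnnotation, RawSignal, revcomp)


def _table_for(read, seed=0):
    rng = np.random.default_rng(seed)
    events = []
    start = 0
    for i, b in enumerate(read):
        ln = int(rng.integers(3, 9))
        events.append(Event(start=start, length=ln, mean=0.0, stdv=1.0,
                            model_state="AAAAA", move=1, weight=1.0,
                            p_model_state=0.9, base=b))
        start += ln
    raw = RawSignal("r", rng.normal(0, 1, size=start))
    return raw, EventTable("r", events, read)


def _aln(read, ref, cigar, strand="+", ref_start=0):
    return AlignmentRecord(read_id="r", ref_name="ref", ref_start=ref_start,
                           strand=strand, cigar=cigar,
                           query=read if strand == "+" else revcomp(read),
                           aligned_ref_segment=ref)


class TestLabelEvents:
    def test_insertion_labels(self):
        # read ACGT vs ref ACT: G is an inserted base
        _, table = _table_for("ACGT")
        aln = _aln("ACGT", "ACT", [("=", 2), ("I", 1), ("=", 1)])
        lab = label_events(table, aln)
        assert [lv.label1 for lv in lab] == ["A", "C", "I", "T"]
        assert [lv.label2 for lv in lab] == ["A", "C", "G", "T"]

    def test_deletion_attaches_to_preceding_event(self):
        # read ACT vs ref ACGT: G deleted; event 'C' carries the deletion
        _, table = _table_for("ACT")
        aln = _aln("ACT", "ACGT", [("=", 2), ("D", 1), ("=", 1)])
        lab = label_events(table, aln)
        assert [lv.label1 for lv in lab] == ["A", "D", "T"]
        assert lab[1].label2 == "G"

    def test_perfect_match_labels_called_bases(self):
        _, table = _table_for("ACGT")
        aln = _aln("ACGT", "ACGT", [("=", 4)])
        lab = label_events(table, aln)
        for lv, b in zip(lab, "ACGT"):
            assert lv.label1 == lv.label2 == b == lv.event.base

    def test_mismatch_takes_reference_base(self):
        _, table = _table_for("AAGT")
        aln = _aln("AAGT", "ACGT", [("=", 1), ("X", 1), ("=", 2)])
        lab = label_events(table, aln)
        assert lab[1].label1 == lab[1].label2 == "C"

    def test_reverse_strand_labels_in_read_orientation(self):
        # ref segment ACGT, read is its reverse complement with a mismatch:
        # read orientation truth is revcomp(ACGT) = ACGT
        ref = "AACGTT"
        read_true = revcomp(ref)
        read = read_true[:2] + ("G" if read_true[2] != "G" else "T") + read_true[3:]
        _, table = _table_for(read)
        # SAM stores query in reference orientation with the X at the
        # mirrored position
        qpos = 2
        sam_pos = len(read) - 1 - qpos
        cigar = []
        if sam_pos > 0:
            cigar.append(("=", sam_pos))
        cigar.append(("X", 1))
        if sam_pos < len(read) - 1:
            cigar.append(("=", len(read) - 1 - sam_pos))
        aln = _aln(read, ref, cigar, strand="-")
        lab = label_events(table, aln)
        assert [lv.label1 for lv in lab] == list(read_true)

    def test_count_mismatch_raises_with_lengths(self):
        _, table = _table_for("ACGT")
        aln = _aln("ACG", "ACG", [("=", 3)])
        with pytest.raises(LabelingError, match="4"):
            label_events(table, aln)

    def test_soft_clips_flagged(self):
        _, table = _table_for("AACGTT")
        aln = _aln("AACGTT", "ACGT",
                   [("S", 1), ("=", 4), ("S", 1)])
        lab = label_events(table, aln)
        assert [lv.soft_clipped for lv in lab] == \
               [True, False, False, False, False, True]

    def test_roundtrip_on_synthetic_truth(self, small_dataset):
        ds = small_dataset
        for sr in ds.reads:
            norm = normalize_signal(sr.raw)
            base = resegment_events(sr.table, norm)
            lab = label_events(base, sr.aln)
            window = ds.reference[sr.ref_start:sr.ref_start + sr.ref_span]
            tpl = window if sr.strand == "+" else revcomp(window)
            assert apply_labels(lab) == tpl

    def test_roundtrip_realignment_has_no_mismatches(self, small_dataset):
        import edlib
        ds = small_dataset
        for sr in ds.reads[:10]:
            norm = normalize_signal(sr.raw)
            base = resegment_events(sr.table, norm)
            lab = label_events(base, sr.aln)
            # rebuilt sequence is in read orientation: align to the matching
            # reference strand
            rebuilt = apply_labels(lab)
            target = (ds.reference if sr.strand == "+"
                      else revcomp(ds.reference))
            res = edlib.align(rebuilt, target, mode="HW", task="path")
            assert res["editDistance"] == 0

    def test_error_free_reads_have_base_labels_only(self, clean_dataset):
        for sr in clean_dataset.reads:
            norm = normalize_signal(sr.raw)
            base = resegment_events(sr.table, norm)
            lab = label_events(base, sr.aln)
            assert all(lv.label1 in "ACGT" and lv.label1 == lv.label2
                       for lv in lab)


class TestParseAlignment:
    def test_parse_and_exclusions(self, tmp_path, small_dataset):
        from nanorevise.synthetic import write_dataset
        out = tmp_path / "ds"
        write_dataset(small_dataset, str(out))
        ref = {small_dataset.ref_name: small_dataset.reference}
        records, report = parse_alignment(str(out / "truth.sam"),
                                          reference=ref)
        assert report.parsed == len(small_dataset.reads)
        assert set(records) == {sr.table.read_id
                                for sr in small_dataset.reads}
        for sr in small_dataset.reads:
            rec = records[sr.table.read_id]
            assert rec.cigar == sr.aln.cigar
            assert rec.strand == sr.strand
            assert rec.ref_start == sr.ref_start

    def test_unmapped_and_m_resolution(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:ref\tLN:8\n"
            "mapped\t0\tref\t1\t60\t2=1X1=\t*\t0\t0\tACTT\t*\n"
            "withM\t0\tref\t1\t60\t4M\t*\t0\t0\tACTT\t*\n"
            "lost\t4\t*\t0\t0\t*\t*\t0\t0\tAC\t*\n")
        ref = {"ref": "ACGTACGT"}
        records, report = parse_alignment(str(sam), reference=ref)
        assert report.excluded_unmapped == 1
        assert records["mapped"].cigar == [("=", 2), ("X", 1), ("=", 1)]
        # 'M' run resolved into =/X against the reference
        assert records["withM"].cigar == [("=", 2), ("X", 1), ("=", 1)]


class TestAnnotateMethylation:
    def _labeled(self, ref_positions):
        out = []
        for p in ref_positions:
            ev = Event(start=0, length=1, mean=0, stdv=0, model_state="AAAAA",
                       move=1, weight=1, p_model_state=0.9, base="A")
            from nanorevise.types import LabeledEvent
            out.append(LabeledEvent(event=ev, label1="A", label2="A",
                                    ref_pos=p))
        return out

    def _aln(self):
        return AlignmentRecord("r", "ref", 0, "+", [("=", 20)], "A" * 20,
                               "A" * 20)

    def test_containment(self):
        ann = MethylAnnotation([("ref", 5, 15, "m6A")])
        lab = annotate_methylation(self._labeled([10]), self._aln(), ann)
        assert lab[0].methyl == "m6A"

    def test_empty_annotation_gives_none(self):
        lab = annotate_methylation(self._labeled([3]), self._aln(),
                                   MethylAnnotation([]))
        assert lab[0].methyl == "none"

    def test_absent_chromosome_warns_and_flags_none(self, caplog):
        ann = MethylAnnotation([("chr9", 0, 5, "m6A")])
        with caplog.at_level("WARNING"):
            lab = annotate_methylation(self._labeled([3]), self._aln(), ann)
        assert lab[0].methyl == "none"

    def test_priority_exhaustive_over_type_pairs(self):
        # any overlap combination resolves by m6A > m4C > modified
        types = ["m6A", "m4C", "modified"]
        order = {t: i for i, t in enumerate(types)}
        for a in types:
            for b in types:
                for c in types:
                    ann = MethylAnnotation([("ref", 0, 20, a),
                                            ("ref", 5, 15, b),
                                            ("ref", 9, 11, c)])
                    lab = annotate_methylation(self._labeled([10]),
                                               self._aln(), ann)
                    expected = min((a, b, c), key=order.get)
                    assert lab[0].methyl == expected


class TestMakeWindows:
    def _labeled_read(self, n=20, seed=1):
        rng = np.random.default_rng(seed)
        from nanorevise.types import LabeledEvent
        events, labs = [], []
        start = 0
        for i in range(n):
            ln = int(rng.integers(3, 9))
            b = "ACGT"[int(rng.integers(0, 4))]
            ev = Event(start=start, length=ln, mean=0.1, stdv=1.0,
                       model_state="AAAAA", move=1, weight=1.0,
                       p_model_state=0.9, base=b)
            labs.append(LabeledEvent(event=ev, label1=b, label2=b))
            events.append(ev)
            start += ln
        raw = RawSignal("r", rng.normal(0, 1, size=start))
        return labs, raw

    def test_one_window_per_event(self):
        labs, raw = self._labeled_read(20)
        ws = make_windows(labs, raw, window=13)
        assert len(ws) == 20

    def test_first_window_has_left_pads(self):
        labs, raw = self._labeled_read(20)
        ws = make_windows(labs, raw, window=13)
        np.testing.assert_array_equal(ws.features[0, :6, :], 0.0)
        assert np.any(ws.features[0, 6, :] != 0)

    def test_feature_dimensions(self):
        labs, raw = self._labeled_read(20)
        assert make_windows(labs, raw).feature_dim == 7
        for lv in labs:
            lv.methyl = "m6A"
        ws = make_windows(labs, raw, with_methyl=True)
        assert ws.feature_dim == 10
        assert np.all(ws.features[5, 6, 7] == 1.0)

    def test_window_too_large_rejected(self):
        labs, raw = self._labeled_read(4)
        with pytest.raises(ValueError, match="too large"):
            make_windows(labs, raw, window=11)

    def test_signal_blocks_are_capped_and_padded(self):
        labs, raw = self._labeled_read(15)
        cap = 5
        ws = make_windows(labs, raw, window=13, sig_cap=cap)
        assert ws.signal.shape == (15, 13 * cap)
        # centre block of window i equals the first <=cap samples of event i
        i = 7
        ev = labs[i].event
        block = ws.signal[i, 6 * cap : 7 * cap]
        seg = raw.samples[ev.start : ev.start + min(ev.length, cap)]
        np.testing.assert_allclose(block[: seg.size], seg, rtol=1e-6)
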