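"""Footprint counting, offset inference, periodicity scoring, subcodon profiles."""

import numpy as np
import pysam
import pytest

from riboscope import profiles
from riboscope.profiles import (
    OffsetTable,
    ProfileError,
    RawProfile,
    build_subcodon_profile,
    infer_offsets,
    load_alignments,
    metagene,
    readlength_distribution,
    score_periodicity,
)
from riboscope.transcriptome import TranscriptomeSet

from conftest import make_record


def _toy_tset(length=120, cds_start=31, cds_stop=90):
    rec = make_record("A" * length, cds_start=cds_start, cds_stop=cds_stop, transcript_id="t")
    return TranscriptomeSet([rec])


def _write_sam(path, reads, refs={"t": 120}):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": n, "LN": l} for n, l in refs.items()]}
    names = list(refs)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, (ref, pos0, rl, flag) in enumerate(reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"r{i}"
            a.reference_id = names.index(ref)
            a.reference_start = pos0
            a.flag = flag
            a.mapping_quality = 255
            a.cigartuples = [(0, rl)]
            a.query_sequence = "A" * rl
            fh.write(a)


class TestLoadAlignments:
    def test_forward_reverse_and_duplicates(self, tmp_path):
        sam = tmp_path / "a.sam"
        _write_sam(
            sam,
            [
                ("t", 9, 28, 0),    # forward, 5' end at position 10
                ("t", 9, 28, 0),    # identical -> counted twice
                ("t", 20, 28, 16),  # reverse strand -> skipped
                ("t", 30, 28, 256),  # secondary -> skipped
            ],
        )
        raw = load_alignments(sam, _toy_tset(), 25, 35)
        assert raw.counts[("t", 28)][10] == 2
        assert raw.total() == 2

    def test_unknown_reference_counted_and_skipped(self, tmp_path):
        sam = tmp_path / "b.sam"
        _write_sam(sam, [("t", 9, 28, 0), ("x", 5, 28, 0)], refs={"t": 120, "x": 80})
        raw = load_alignments(sam, _toy_tset(), 25, 35)
        assert raw.skipped_references["x"] == 1
        assert raw.total() == 1

    def test_zero_usable_alignments_is_error(self, tmp_path):
        sam = tmp_path / "c.sam"
        _write_sam(sam, [("t", 9, 28, 16)])
        with pytest.raises(ProfileError):
            load_alignments(sam, _toy_tset(), 25, 35)

    def test_length_window_filter(self, tmp_path):
        sam = tmp_path / "d.sam"
        _write_sam(sam, [("t", 9, 28, 0), ("t", 9, 40, 0)])
        raw = load_alignments(sam, _toy_tset(), 25, 35)
        assert raw.read_lengths() == [28]


class TestInferOffsets:
    def test_metagene_argmax(self):
        tset = _toy_tset()
        raw = RawProfile()
        # two-peak metagene with maximum at -13
        raw.add("t", 29, 31 - 13, 5)
        raw.add("t", 29, 31 - 10, 3)
        assert infer_offsets(raw, tset)[29] == 13

    def test_fallback_when_no_reads_near_start(self):
        tset = _toy_tset()
        raw = RawProfile()
        raw.add("t", 30, 100, 4)  # far from cds_start
        assert infer_offsets(raw, tset)[30] == 12

    def test_tie_resolved_toward_smaller_offset(self):
        tset = _toy_tset()
        raw = RawProfile()
        raw.add("t", 28, 31 - 12, 2)
        raw.add("t", 28, 31 - 9, 2)
        assert infer_offsets(raw, tset)[28] == 9

    def test_recovers_simulated_offset_exactly(self, sim_loaded):
        offsets = sim_loaded["offsets"]
        for rl in sim_loaded["raw"].read_lengths():
            assert offsets[rl] == sim_loaded["cfg"].offset_true


class TestScorePeriodicity:
    def test_frame_count_arithmetic(self):
        tset = _toy_tset()
        offsets = OffsetTable({28: 0})
        raw = RawProfile()
        # A-sites inside CDS interior (34..87), frames rel. to cds_start=31
        raw.add("t", 28, 34, 90)  # frame 0
        raw.add("t", 28, 35, 5)
        raw.add("t", 28, 36, 5)
        table = score_periodicity(raw, offsets, tset)
        assert table.frame_counts(28) == (90, 5, 5)
        assert table.score(28) == pytest.approx(0.9)

    def test_uniform_gives_one_third(self):
        tset = _toy_tset()
        raw = RawProfile()
        for pos in (37, 38, 39):
            raw.add("t", 28, pos, 10)
        table = score_periodicity(raw, OffsetTable({28: 0}), tset)
        assert table.score(28) == pytest.approx(1 / 3)

    def test_no_in_cds_asites_gives_absent_score(self):
        tset = _toy_tset()
        raw = RawProfile()
        raw.add("t", 28, 5, 3)  # leader only
        table = score_periodicity(raw, OffsetTable({28: 0}), tset)
        assert table.score(28) is None

    def test_first_and_last_codons_excluded(self):
        tset = _toy_tset()
        raw = RawProfile()
        raw.add("t", 28, 31, 100)  # initiation peak, first codon
        raw.add("t", 28, 88, 100)  # stop codon
        raw.add("t", 28, 40, 1)
        table = score_periodicity(raw, OffsetTable({28: 0}), tset)
        assert table.frame_counts(28) == (1, 0, 0)

    def test_score_converges_to_simulated_p(self, sim_p08):
        tset, raw, cfg = sim_p08["tset"], sim_p08["raw"], sim_p08["cfg"]
        offsets = infer_offsets(raw, tset)
        table = score_periodicity(raw, offsets, tset)
        total_in_cds = sum(sum(c) for c, s in table.table.values())
        assert total_in_cds >= 5000
        for rl in raw.read_lengths():
            assert table.score(rl) == pytest.approx(0.8, abs=0.03)


class TestSubcodonProfile:
    def test_threshold_filters_weak_lengths(self):
        tset = _toy_tset()
        raw = RawProfile()
        raw.add("t", 28, 34, 8)   # strongly periodic
        raw.add("t", 28, 35, 1)
        raw.add("t", 28, 36, 1)
        raw.add("t", 30, 34, 4)   # weak: uniform
        raw.add("t", 30, 35, 4)
        raw.add("t", 30, 36, 4)
        offsets = OffsetTable({28: 0, 30: 0})
        per = score_periodicity(raw, offsets, tset)
        prof = build_subcodon_profile(raw, offsets, per, tset, min_score=0.5)
        assert prof.total() == 10  # only length 28 survives
        prof_all = build_subcodon_profile(raw, offsets, per, tset, min_score=1 / 3)
        assert prof_all.total() == 22  # identity threshold keeps everything

    def test_all_lengths_filtered_is_error(self):
        tset = _toy_tset()
        raw = RawProfile()
        for pos in (34, 35, 36):
            raw.add("t", 28, pos, 5)
        offsets = OffsetTable({28: 0})
        per = score_periodicity(raw, offsets, tset)
        with pytest.raises(ProfileError, match="periodicity"):
            build_subcodon_profile(raw, offsets, per, tset, min_score=0.9)

    def test_frame_vector_assignment_and_conservation(self):
        tset = _toy_tset()
        raw = RawProfile()
        raw.add("t", 28, 7, 3)  # offset 0 -> A-site 7, frame (7-1)%3 = 0
        raw.add("t", 28, 40, 2)
        offsets = OffsetTable({28: 0})
        per = profiles.PeriodicityTable({28: ((1, 0, 0), 1.0)})
        prof = build_subcodon_profile(raw, offsets, per, tset, min_score=1 / 3)
        f0, f1, f2 = prof.frame_vectors("t")
        assert f0[6] == 3 and f1[6] == 0 and f2[6] == 0
        assert prof.total() == raw.total()
        np.testing.assert_array_equal(f0 + f1 + f2, prof.counts("t"))

    def test_conservation_on_simulation(self, sim_loaded):
        raw, offsets, per, tset = (
            sim_loaded["raw"], sim_loaded["offsets"], sim_loaded["periodicity"], sim_loaded["tset"],
        )
        prof = build_subcodon_profile(raw, offsets, per, tset, min_score=1 / 3)
        surviving = {rl for rl in raw.read_lengths() if per.score(rl) is not None}
        expected = sum(
            sum(c.values()) for (tid, rl), c in raw.items() if rl in surviving
        )
        # A-sites shifted past transcript ends are dropped; none should be here
        assert prof.total() == expected


class TestMetagene:
    def test_single_read_at_start(self):
        tset = _toy_tset()
        raw = RawProfile()
        raw.add("t", 28, 31, 1)
        vec = metagene(raw, OffsetTable({28: 0}), tset, anchor="cds_start", span=5)
        expected = np.zeros(11, dtype=int)
        expected[5] = 1
        np.testing.assert_array_equal(vec, expected)

    def test_additivity_and_stop_anchor(self):
        rec1 = make_record("A" * 120, cds_start=31, cds_stop=90, transcript_id="a")
        rec2 = make_record("A" * 120, cds_start=31, cds_stop=90, transcript_id="b", gene_id="g2")
        tset = TranscriptomeSet([rec1, rec2])
        raw = RawProfile()
        raw.add("a", 28, 93, 1)  # +3 from cds_stop
        raw.add("b", 28, 93, 1)
        vec = metagene(raw, OffsetTable({28: 0}), tset, anchor="cds_stop", span=5)
        assert vec[5 + 3] == 2


def test_readlength_distribution_conservation(sim_loaded):
    raw = sim_loaded["raw"]
    dist = readlength_distribution(raw)
    assert sum(dist.values()) == raw.total()
    assert readlength_distribution(RawProfile()) == {}
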