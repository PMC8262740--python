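"""ORF enumeration, classification, feature extraction and rank aggregation."""

import numpy as np
import pandas as pd
import pytest

from riboscope import orfdetect
from riboscope.orfdetect import (
    OrfDetectError,
    OrfRecord,
    classify_orf,
    detect,
    enumerate_orfs,
    extract_features,
    rank_orfs,
)
from riboscope.profiles import SubcodonProfile

from conftest import make_record


class TestEnumerateOrfs:
    def test_direct_scan(self):
        rec = make_record("ATGAAATAA")
        (orf,) = enumerate_orfs(rec, min_codons=1)
        assert (orf.start, orf.stop, orf.length_codons) == (1, 9, 2)

    def test_five_prime_most_start_kept(self):
        rec = make_record("ATGATGAAATAA")
        (orf,) = enumerate_orfs(rec, min_codons=1)
        assert orf.start == 1
        both = enumerate_orfs(rec, min_codons=1, all_starts=True)
        assert [o.start for o in both] == [1, 4]

    def test_near_cognate_start(self):
        rec = make_record("CTGAAATAG")
        (orf,) = enumerate_orfs(rec, start_codons={"CTG"}, min_codons=1)
        assert orf.start == 1 and orf.start_codon == "CTG"

    def test_min_codons_and_no_stop(self):
        assert enumerate_orfs(make_record("ATGAAATAA"), min_codons=3) == []
        assert enumerate_orfs(make_record("ATGAAAAAA"), min_codons=1) == []  # no stop

    def test_n_codons_never_match(self):
        rec = make_record("ATGNAATAA")
        orfs = enumerate_orfs(rec, min_codons=1)
        assert [o.start for o in orfs] == [1]  # ATN/NAA ignored as start/stop

    def test_no_internal_inframe_stop_invariant(self, sim_loaded):
        rec = next(iter(sim_loaded["tset"]))
        for orf in enumerate_orfs(rec):
            inner = rec.sequence[orf.start - 1 : orf.stop - 3]
            codons = [inner[i : i + 3] for i in range(0, len(inner), 3)]
            assert not any(c in {"TAA", "TAG", "TGA"} for c in codons[1:])
            assert rec.sequence[orf.stop - 3 : orf.stop] in {"TAA", "TAG", "TGA"}


class TestClassifyOrf:
    # CDS at 31..90, frame (31-1)%3 = 0
    rec = make_record("A" * 120, cds_start=31, cds_stop=90)

    def _orf(self, start, stop):
        return OrfRecord("tx1", start, stop, "ATG")

    @pytest.mark.parametrize(
        "start,stop,expected",
        [
            (4, 15, "uORF"),          # entirely 5' of the CDS
            (5, 46, "ouORF"),         # starts in leader, ends in CDS, frame 1
            (13, 90, "extension"),    # in-frame upstream start sharing the stop
            (37, 60, "nested"),       # inside CDS, frame 0? -> see below
            (94, 105, "dORF"),        # entirely 3' of the CDS
            (59, 100, "odORF"),       # starts in CDS, ends in trailer, frame 1
        ],
    )
    def test_categories(self, start, stop, expected):
        if expected == "nested":
            start, stop = 38, 61  # frame 1, inside CDS
        assert classify_orf(self._orf(start, stop), self.rec) == expected

    def test_cds_itself_excluded(self):
        assert classify_orf(self._orf(31, 90), self.rec) is None

    def test_noncoding_record(self):
        nc = make_record("A" * 60)
        assert classify_orf(self._orf(10, 30), nc) == "ncRNA_ORF"


def _profile_with(tid, length, counts):
    prof = SubcodonProfile()
    vec = prof.ensure(tid, length)
    for pos, n in counts.items():
        vec[pos - 1] = n
    return prof


class TestExtractFeatures:
    def test_stated_arithmetic(self):
        # 3-codon uORF region at 10..21 (stop 19..21), in-frame counts 5 each
        rec = make_record("A" * 60, cds_start=31, cds_stop=57)
        orf = OrfRecord("tx1", 10, 21, "ATG", category="uORF")
        prof = _profile_with("tx1", 60, {10: 5, 13: 5, 16: 5})
        f = extract_features(orf, rec, prof)
        assert f.start_rise == pytest.approx(16.0)   # (15+1)/(0+1)
        assert f.stop_drop == pytest.approx(16.0)
        assert f.inframe_excess == pytest.approx(15 / 16)
        assert f.dominant_codons == 3

    def test_all_zero_counts_neutral(self):
        rec = make_record("A" * 60, cds_start=31, cds_stop=57)
        orf = OrfRecord("tx1", 10, 21, "ATG", category="uORF")
        f = extract_features(orf, rec, SubcodonProfile())
        assert (f.start_rise, f.stop_drop, f.inframe_excess, f.dominant_codons) == (1, 1, 0, 0)

    def test_extension_has_no_stop_drop(self):
        rec = make_record("A" * 90, cds_start=31, cds_stop=90)
        orf = OrfRecord("tx1", 13, 90, "ATG", category="extension")
        f = extract_features(orf, rec, SubcodonProfile())
        assert f.stop_drop is None

    def test_overlap_categories_use_non_cds_region_only(self):
        # ouORF 20..46 (frame 1) vs CDS 31..90: region = codons fully before 31
        rec = make_record("A" * 120, cds_start=31, cds_stop=90)
        orf = OrfRecord("tx1", 20, 46, "ATG", category="ouORF")
        region = orfdetect.region_codon_starts(orf, rec)
        assert region == [20, 23, 26]  # codon 29..31 overlaps the CDS, excluded

    def test_sub_codon_region_dropped(self):
        rec = make_record("A" * 120, cds_start=31, cds_stop=90)
        orf = OrfRecord("tx1", 29, 46, "ATG", category="ouORF")  # only codon overlaps CDS
        assert extract_features(orf, rec, SubcodonProfile()) is None


def brute_force_rank(df: pd.DataFrame) -> pd.DataFrame:
    """Independent oracle: per-feature competition ranks by explicit counting."""
    out = df.copy()
    for col in ("start_rise", "stop_drop", "inframe_excess", "dominant_codons"):
        ranks = []
        vals = out[col].tolist()
        for v in vals:
            if pd.isna(v):
                ranks.append(np.nan)
            else:
                ranks.append(1 + sum(1 for w in vals if not pd.isna(w) and w > v))
        out[f"rank_{col}"] = pd.Series(ranks, index=out.index, dtype=float)
    rank_cols = [f"rank_{c}" for c in ("start_rise", "stop_drop", "inframe_excess", "dominant_codons")]
    out["global_rank"] = out[rank_cols].mean(axis=1, skipna=True)
    out = out.sort_values(
        ["global_rank", "inframe_excess", "transcript_id", "start"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def _random_feature_table(rng, n):
    return pd.DataFrame(
        {
            "transcript_id": [f"t{rng.integers(0, 5)}" for _ in range(n)],
            "start": rng.integers(1, 500, size=n),
            "start_rise": rng.choice([0.5, 1.0, 2.0, 4.0, 8.0], size=n),
            "stop_drop": np.where(
                rng.random(n) < 0.2, np.nan, rng.choice([0.5, 1.0, 2.0, 4.0], size=n)
            ),
            "inframe_excess": np.round(rng.uniform(-1, 1, size=n), 2),
            "dominant_codons": rng.integers(0, 10, size=n),
        }
    )


class TestRankOrfs:
    def test_dominance(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["a", "b"],
                "start": [1, 1],
                "start_rise": [4.0, 2.0],
                "stop_drop": [4.0, 2.0],
                "inframe_excess": [0.9, 0.1],
                "dominant_codons": [5, 1],
            }
        )
        ranked = rank_orfs(df)
        assert ranked["global_rank"].tolist() == [1.0, 2.0]
        assert ranked["transcript_id"].tolist() == ["a", "b"]

    def test_all_tied(self):
        df = pd.DataFrame(
            {
                "transcript_id": ["b", "a"],
                "start": [1, 1],
                "start_rise": [1.0, 1.0],
                "stop_drop": [1.0, 1.0],
                "inframe_excess": [0.0, 0.0],
                "dominant_codons": [0, 0],
            }
        )
        ranked = rank_orfs(df)
        assert ranked["global_rank"].tolist() == [1.0, 1.0]
        assert ranked["transcript_id"].tolist() == ["a", "b"]  # lexicographic tie-break

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            df = _random_feature_table(rng, int(rng.integers(2, 50)))
            got = rank_orfs(df, top_n=None)
            want = brute_force_rank(df)
            pd.testing.assert_frame_equal(
                got.reset_index(drop=True), want, check_like=True
            )

    def test_empty_is_error(self):
        with pytest.raises(OrfDetectError):
            rank_orfs(pd.DataFrame())


class TestDetect:
    def test_truth_uorfs_recovered(self, sim_loaded):
        table = detect(
            sim_loaded["tset"],
            sim_loaded["raw"],
            sim_loaded["offsets"],
            sim_loaded["periodicity"],
            categories={"uORF"},
        )
        truth = sim_loaded["truth"]
        truth_keys = set(zip(truth.transcript_id, truth.stop))
        found = set(zip(table.transcript_id, table.stop)) & truth_keys
        assert len(found) == len(truth_keys)  # all 20 planted uORFs present
        assert (table.category == "uORF").all()

    def test_category_filter(self, sim_loaded):
        table = detect(
            sim_loaded["tset"],
            sim_loaded["raw"],
            sim_loaded["offsets"],
            sim_loaded["periodicity"],
            categories={"dORF"},
        )
        assert (table.category == "dORF").all()

    def test_no_binary_call_emitted(self, sim_loaded):
        table = detect(
            sim_loaded["tset"],
            sim_loaded["raw"],
            sim_loaded["offsets"],
            sim_loaded["periodicity"],
            categories={"uORF"},
        )
        assert not any("translated" in c for c in table.columns)

    def test_monotonicity_more_inframe_reads_never_worse(self):
        # two identical uORF candidates on separate transcripts; boost one
        recs = {}
        for tid in ("a", "b"):
            recs[tid] = make_record(
                "A" * 9 + "ATGAAAAAAAAAAAATAA" + "A" * 3 + "ATG" + "A" * 57 + "TAA" + "A" * 10,
                cds_start=31,
                cds_stop=93,
                transcript_id=tid,
                gene_id=tid,
            )
        prof = SubcodonProfile()
        for tid in ("a", "b"):
            vec = prof.ensure(tid, recs[tid].length)
            vec[9:24] = 2  # flat counts over the uORF
        base = []
        for tid in ("a", "b"):
            orf = OrfRecord(tid, 10, 27, "ATG", category="uORF")
            base.append(extract_features(orf, recs[tid], prof))
        # boost in-frame counts of 'a'
        prof.counts("a")[9:24:3] += 10
        boosted = extract_features(OrfRecord("a", 10, 27, "ATG", category="uORF"), recs["a"], prof)
        assert boosted.start_rise >= base[0].start_rise
        assert boosted.inframe_excess >= base[0].inframe_excess
        assert boosted.dominant_codons >= base[0].dominant_codons
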