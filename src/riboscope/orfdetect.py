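"""Rank-based detection of non-canonically translated ORFs.

Candidate ORFs outside annotated CDS regions are enumerated and classified by
their position relative to the annotated CDS (uORF, overlapping uORF, nested,
dORF, overlapping dORF, N-terminal extension, or ORFs on non-coding RNAs).
For each candidate three to four translational-signal features are extracted
from the periodicity-filtered A-site profile:

* ``start_rise``   — footprint density step up across the start codon,
* ``stop_drop``    — density step down across the stop codon (absent for
  N-terminal extensions, whose stop is the annotated stop),
* ``inframe_excess`` — normalised excess of in-frame over out-of-frame
  A-sites in the region of interest,
* ``dominant_codons`` — number of codons whose in-frame count strictly beats
  both out-of-frame counts.

Each feature is ranked from strongest signal to weakest (competition ranking,
ties share the minimum rank) and the per-feature ranks are averaged into a
global rank. The output is an ordered table, not a translated/untranslated
call: the method surfaces candidates for manual inspection and makes no
binary claim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    DEFAULT_MIN_PERIODICITY,
    OffsetTable,
    PeriodicityTable,
    RawProfile,
    SubcodonProfile,
    build_subcodon_profile,
)
from .transcriptome import (
    NEAR_COGNATE_STARTS,
    START_CODONS_DEFAULT,
    STOP_CODONS,
    TranscriptRecord,
    TranscriptomeSet,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("uORF", "ouORF", "nested", "dORF", "odORF", "extension", "ncRNA_ORF")

FEATURE_COLUMNS = ("start_rise", "stop_drop", "inframe_excess", "dominant_codons")


class OrfDetectError(ValueError):
    pass


@dataclass
class OrfRecord:
    """A candidate ORF in transcript coordinates (stop codon included)."""

    transcript_id: str
    start: int  # 1-based first nt of start codon
    stop: int  # 1-based last nt of stop codon
    start_codon: str
    category: Optional[str] = None

    @property
    def frame(self) -> int:
        return (self.start - 1) % 3

    @property
    def length_codons(self) -> int:
        # excluding the stop codon
        return (self.stop - self.start + 1) // 3 - 1


def enumerate_orfs(
    record: TranscriptRecord,
    start_codons: Iterable[str] = START_CODONS_DEFAULT,
    stop_codons: Iterable[str] = STOP_CODONS,
    min_codons: int = 5,
    all_starts: bool = False,
) -> list[OrfRecord]:
    """All ORFs on a transcript: a start codon extended in-frame to the first stop.

    Only ORFs that terminate on-transcript and encode at least ``min_codons``
    codons (stop excluded) are returned. Within one (stop, frame) pair only
    the 5'-most start is kept — the longest-isoform rule — unless
    ``all_starts`` is set. Codons containing N never match either codon set.
    """
    starts = {c.upper().replace("U", "T") for c in start_codons}
    stops = {c.upper().replace("U", "T") for c in stop_codons}
    if starts & stops:
        raise OrfDetectError("start and stop codon sets overlap")
    if min_codons < 1:
        raise OrfDetectError("min_codons must be >= 1")
    seq = record.sequence
    n = len(seq)
    # first in-frame stop at-or-after each position, per frame
    next_stop: dict[int, dict[int, int]] = {0: {}, 1: {}, 2: {}}
    for f in range(3):
        upcoming = None
        for p in range(n - 3 - (n - f) % 3, f - 1, -3):
            codon = seq[p : p + 3]
            if codon in stops:
                upcoming = p
            if upcoming is not None:
                next_stop[f][p] = upcoming

    orfs: list[OrfRecord] = []
    seen_stop_frame: set[tuple[int, int]] = set()
    for p in range(n - 2):
        codon = seq[p : p + 3]
        if codon not in starts:
            continue
        f = p % 3
        stop0 = next_stop[f].get(p)
        if stop0 is None or stop0 == p:
            continue
        key = (stop0, f)
        if not all_starts and key in seen_stop_frame:
            continue
        length_codons = (stop0 - p) // 3
        if length_codons < min_codons:
            # a longer ORF with the same stop cannot exist 3' of here, but a
            # shorter one cannot pass either; still mark the stop as taken
            # only when a qualifying ORF was emitted, so do not mark here
            continue
        seen_stop_frame.add(key)
        orfs.append(
            OrfRecord(
                transcript_id=record.transcript_id,
                start=p + 1,
                stop=stop0 + 3,
                start_codon=codon,
            )
        )
    return orfs


def classify_orf(orf: OrfRecord, record: TranscriptRecord) -> Optional[str]:
    """Category of an ORF relative to the annotated CDS.

    Returns ``None`` for ORFs identical to the annotated CDS (excluded from
    output) and for in-frame configurations that fit no category (e.g. an
    in-frame ORF sharing neither bound with the CDS).
    """
    if not record.coding:
        return "ncRNA_ORF"
    cs, ce = record.cds_start, record.cds_stop
    cds_frame = (cs - 1) % 3
    if orf.start == cs and orf.stop == ce:
        return None
    if orf.stop < cs:
        return "uORF"
    if orf.start > ce:
        return "dORF"
    if orf.start < cs <= orf.stop:
        if orf.frame == cds_frame:
            return "extension" if orf.stop == ce else None
        return "ouORF"
    if cs <= orf.start and orf.stop <= ce:
        return "nested" if orf.frame != cds_frame else None
    if orf.start <= ce < orf.stop:
        return "odORF" if orf.frame != cds_frame else None
    return None


# ---------------------------------------------------------------------------
# features


@dataclass
class OrfFeatures:
    start_rise: float
    stop_drop: Optional[float]  # absent for extensions
    inframe_excess: float
    dominant_codons: int


def _window_sum(vec: np.ndarray, lo: int, hi: int) -> float:
    """Sum of counts over 1-based positions lo..hi, truncated at bounds."""
    lo = max(lo, 1)
    hi = min(hi, len(vec))
    if lo > hi:
        return 0.0
    return float(vec[lo - 1 : hi].sum())


def region_codon_starts(orf: OrfRecord, record: TranscriptRecord) -> list[int]:
    """Codon start positions of the ORF's region of interest.

    The region is the ORF's translated codons (stop codon excluded); for
    categories that overlap the annotated CDS in a different frame
    (ouORF, odORF) or in the same frame (extension), codons overlapping the
    CDS are removed — inside the annotated CDS the annotated frame dominates
    and would mask the candidate's own signal.
    """
    starts = list(range(orf.start, orf.stop - 1, 3))[:-1]  # drop stop codon
    if orf.category in ("ouORF", "extension", "odORF") and record.coding:
        cs, ce = record.cds_start, record.cds_stop
        starts = [p for p in starts if p + 2 < cs or p > ce]
    return starts


def extract_features(
    orf: OrfRecord,
    record: TranscriptRecord,
    profile: SubcodonProfile,
    window_codons: int = 5,
    pseudocount: float = 1.0,
) -> Optional[OrfFeatures]:
    """The 3-4 translational-signal features of one candidate ORF.

    Returns ``None`` (and logs why) when the region of interest is shorter
    than one codon. Flanking windows are truncated at transcript bounds; the
    pseudocount keeps ratios finite and neutral (value 1) on empty profiles.
    """
    vec = profile.counts(orf.transcript_id)
    if len(vec) == 0:
        vec = np.zeros(record.length, dtype=np.int64)
    region = region_codon_starts(orf, record)
    if not region:
        logger.info(
            "%s ORF %d-%d dropped: region of interest shorter than one codon",
            orf.transcript_id,
            orf.start,
            orf.stop,
        )
        return None
    w = window_codons
    first = region[: w]
    last = region[-w:]

    region_first_nt = region[0]
    first_counts = sum(_window_sum(vec, p, p + 2) for p in first)
    flank5 = _window_sum(vec, region_first_nt - 3 * w, region_first_nt - 1)
    start_rise = (first_counts + pseudocount) / (flank5 + pseudocount)

    if orf.category == "extension":
        stop_drop = None
    else:
        last_counts = sum(_window_sum(vec, p, p + 2) for p in last)
        flank3 = _window_sum(vec, orf.stop + 1, orf.stop + 3 * w)
        stop_drop = (last_counts + pseudocount) / (flank3 + pseudocount)

    inframe = 0.0
    out1 = 0.0
    out2 = 0.0
    dominant = 0
    for p in region:
        a = _window_sum(vec, p, p)
        b = _window_sum(vec, p + 1, p + 1)
        c = _window_sum(vec, p + 2, p + 2)
        inframe += a
        out1 += b
        out2 += c
        if a > b and a > c:
            dominant += 1
    total = inframe + out1 + out2
    inframe_excess = (inframe - max(out1, out2)) / (total + pseudocount)

    return OrfFeatures(
        start_rise=start_rise,
        stop_drop=stop_drop,
        inframe_excess=inframe_excess,
        dominant_codons=dominant,
    )


# ---------------------------------------------------------------------------
# ranking


def rank_orfs(features: pd.DataFrame, top_n: Optional[int] = 1000) -> pd.DataFrame:
    """Rank a feature table from strongest translational signal to weakest.

    Expects columns ``start_rise``, ``stop_drop`` (may be NaN),
    ``inframe_excess``, ``dominant_codons`` plus identifying columns
    (``transcript_id``, ``start``). Each feature is ranked descending with
    competition ranking (ties share the minimum rank); ``stop_drop`` is
    ranked over the rows where it is present. The global rank is the mean of
    the available per-feature ranks (3 or 4). Output is sorted by global rank
    ascending, ties broken by ``inframe_excess`` descending then
    (transcript_id, start); ``top_n=None`` returns the full table.
    """
    if features.empty:
        raise OrfDetectError("rank_orfs: empty feature table")
    df = features.copy()
    rank_cols = []
    for col in FEATURE_COLUMNS:
        rcol = f"rank_{col}"
        rank_cols.append(rcol)
        df[rcol] = df[col].rank(method="min", ascending=False)
    df["global_rank"] = df[rank_cols].mean(axis=1, skipna=True)
    df = df.sort_values(
        ["global_rank", "inframe_excess", "transcript_id", "start"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top_n is not None:
        df = df.head(top_n)
    return df


def detect(
    tset: TranscriptomeSet,
    raw: RawProfile,
    offsets: OffsetTable,
    periodicity: PeriodicityTable,
    min_score: float = DEFAULT_MIN_PERIODICITY,
    categories: Optional[Iterable[str]] = None,
    start_codons: Iterable[str] = START_CODONS_DEFAULT,
    min_codons: int = 5,
    top_n: Optional[int] = 1000,
    all_starts: bool = False,
    joint: bool = False,
    window_codons: int = 5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """End-to-end detection of non-canonical translated ORF candidates.

    Builds the periodicity-filtered subcodon profile, enumerates and
    classifies candidate ORFs on principal isoforms, extracts features and
    ranks. By default each category is ranked separately (features are not
    comparable between 3- and 4-feature categories); ``joint=True`` ranks
    everything in one pool. Returns the ranked table truncated to ``top_n``
    rows per ranking pool.
    """
    wanted = set(categories) if categories is not None else set(CATEGORIES)
    unknown = wanted - set(CATEGORIES)
    if unknown:
        raise OrfDetectError(f"unknown categories: {sorted(unknown)}")
    profile = build_subcodon_profile(raw, offsets, periodicity, tset, min_score)

    rows = []
    for rec in sorted(tset.principal_records(), key=lambda r: r.transcript_id):
        for orf in enumerate_orfs(
            rec, start_codons=start_codons, min_codons=min_codons, all_starts=all_starts
        ):
            cat = classify_orf(orf, rec)
            if cat is None or cat not in wanted:
                continue
            orf.category = cat
            feats = extract_features(
                orf, rec, profile, window_codons=window_codons, pseudocount=pseudocount
            )
            if feats is None:
                continue
            rows.append(
                {
                    "transcript_id": orf.transcript_id,
                    "gene_id": rec.gene_id,
                    "category": cat,
                    "start": orf.start,
                    "stop": orf.stop,
                    "frame": orf.frame,
                    "start_codon": orf.start_codon,
                    "length_codons": orf.length_codons,
                    "start_rise": feats.start_rise,
                    "stop_drop": feats.stop_drop if feats.stop_drop is not None else np.nan,
                    "inframe_excess": feats.inframe_excess,
                    "dominant_codons": feats.dominant_codons,
                }
            )
    if not rows:
        raise OrfDetectError("no candidate ORFs with a usable region of interest")
    table = pd.DataFrame(rows)
    if joint:
        return rank_orfs(table, top_n=top_n)
    ranked = [
        rank_orfs(sub, top_n=top_n) for _, sub in table.groupby("category", sort=True)
    ]
    return pd.concat(ranked, ignore_index=True)


def write_orf_tsv(table: pd.DataFrame, out_path, header: str = "") -> None:
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_orf_bed(table: pd.DataFrame, out_path, header: str = "") -> None:
    """Candidate ORFs as BED (0-based half-open) in transcript coordinates."""
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        for _, row in table.iterrows():
            name = f"{row['category']}|rank={row['global_rank']:g}"
            fh.write(
                f"{row['transcript_id']}\t{row['start'] - 1}\t{row['stop']}\t{name}\t0\t+\n"
            )
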