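"""Footprint profiles in transcript space.

Ribosome-protected fragments aligned against the transcriptome are reduced to
per-(transcript, read length) counts of 5' end positions (:class:`RawProfile`).
From these we infer read-length-specific A-site offsets from the metagene
around annotated start codons, score triplet periodicity per read length,
filter weakly periodic lengths, and accumulate frame-resolved (subcodon)
A-site profiles — the substrate for ORF detection and for the usual
quality-control summaries (read-length distribution, metagene profiles).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pysam

from .transcriptome import TranscriptomeSet

logger = logging.getLogger(__name__)

FALLBACK_OFFSET = 12  # canonical 5'-end -> A-site distance for ~28-31 nt RPFs
DEFAULT_MIN_PERIODICITY = 0.55


class ProfileError(ValueError):
    pass


@dataclass
class RawProfile:
    """5'-end counts keyed by (transcript_id, read_length) -> {position: n}.

    Positions are 1-based transcript coordinates of the leftmost (5') aligned
    base.
    """

    counts: dict[tuple[str, int], Counter] = field(default_factory=dict)
    skipped_references: Counter = field(default_factory=Counter)

    def add(self, transcript_id: str, read_length: int, position: int, n: int = 1) -> None:
        self.counts.setdefault((transcript_id, read_length), Counter())[position] += n

    def read_lengths(self) -> list[int]:
        return sorted({rl for (_, rl) in self.counts})

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def items(self):
        return self.counts.items()


@dataclass
class OffsetTable:
    """Per-read-length offset such that A-site = 5' end + offset."""

    offsets: dict[int, int] = field(default_factory=dict)

    def __getitem__(self, read_length: int) -> int:
        return self.offsets.get(read_length, FALLBACK_OFFSET)

    def __contains__(self, read_length: int) -> bool:
        return read_length in self.offsets

    def items(self):
        return sorted(self.offsets.items())


@dataclass
class PeriodicityTable:
    """Per-read-length frame counts and majority-frame score.

    ``frame_counts`` are tallied relative to the annotated CDS frame (index 0
    = in the annotated frame); ``score = max(frame_counts)/sum`` lies in
    [1/3, 1] and is ``None`` for read lengths without in-CDS A-sites.
    """

    table: dict[int, tuple[tuple[int, int, int], Optional[float]]] = field(default_factory=dict)

    def score(self, read_length: int) -> Optional[float]:
        entry = self.table.get(read_length)
        return entry[1] if entry else None

    def frame_counts(self, read_length: int) -> Optional[tuple[int, int, int]]:
        entry = self.table.get(read_length)
        return entry[0] if entry else None

    def items(self):
        return sorted(self.table.items())


class SubcodonProfile:
    """Per-transcript A-site counts split by transcript-anchored frame.

    Internally one dense count vector per transcript (index = position - 1);
    the three frame vectors are the position vector masked by
    ``(position - 1) % 3`` and therefore have disjoint support, so the
    per-position totals trivially equal the sum of the frame vectors.
    """

    def __init__(self) -> None:
        self._counts: dict[str, np.ndarray] = {}

    def ensure(self, transcript_id: str, length: int) -> np.ndarray:
        if transcript_id not in self._counts:
            self._counts[transcript_id] = np.zeros(length, dtype=np.int64)
        return self._counts[transcript_id]

    def counts(self, transcript_id: str) -> np.ndarray:
        return self._counts.get(transcript_id, np.zeros(0, dtype=np.int64))

    def transcripts(self) -> list[str]:
        return sorted(self._counts)

    def frame_vectors(self, transcript_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        vec = self.counts(transcript_id)
        out = []
        for f in range(3):
            fv = np.zeros_like(vec)
            fv[f::3] = vec[f::3]
            out.append(fv)
        return tuple(out)

    def total(self) -> int:
        return int(sum(v.sum() for v in self._counts.values()))


# ---------------------------------------------------------------------------
# operations


def load_alignments(
    bam_path: str | Path,
    tset: TranscriptomeSet,
    min_len: int = 25,
    max_len: int = 35,
) -> RawProfile:
    """Count 5' ends of transcriptome alignments per read length.

    Keeps primary, forward-strand alignments whose read length lies in
    ``[min_len, max_len]`` (footprints map to the mRNA sense strand);
    secondary, supplementary and reverse-strand alignments are skipped.
    Alignments to references absent from the transcriptome set are tallied in
    ``skipped_references`` and dropped.
    """
    if min_len > max_len:
        raise ProfileError(f"min_len {min_len} > max_len {max_len}")
    raw = RawProfile()
    usable = 0
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_reverse:
                continue
            rl = aln.query_length or aln.infer_read_length()
            if rl is None or not min_len <= rl <= max_len:
                continue
            tid = aln.reference_name
            if tid not in tset:
                raw.skipped_references[tid] += 1
                continue
            raw.add(tid, rl, aln.reference_start + 1)
            usable += 1
    if raw.skipped_references:
        logger.warning(
            "skipped %d alignments to %d unknown references",
            sum(raw.skipped_references.values()),
            len(raw.skipped_references),
        )
    if usable == 0:
        raise ProfileError(f"no usable alignments in {bam_path}")
    return raw


def infer_offsets(raw: RawProfile, tset: TranscriptomeSet, search_window: int = 24) -> OffsetTable:
    """Infer the 5'-end -> A-site offset per read length.

    For each read length a metagene of 5'-end counts relative to annotated
    start codons (over all coding transcripts) is built; the offset is the
    distance of the metagene maximum in ``-search_window..0``. Ties are
    resolved toward the smaller offset; read lengths with an empty metagene
    fall back to the canonical 12 nt.
    """
    table: dict[int, int] = {}
    metagenes: dict[int, np.ndarray] = {}
    for (tid, rl), positions in raw.items():
        rec = tset[tid] if tid in tset else None
        if rec is None or not rec.coding:
            continue
        meta = metagenes.setdefault(rl, np.zeros(search_window + 1, dtype=np.int64))
        for pos, n in positions.items():
            rel = pos - rec.cds_start
            if -search_window <= rel <= 0:
                meta[rel + search_window] += n
    for rl in raw.read_lengths():
        meta = metagenes.get(rl)
        if meta is None or meta.sum() == 0:
            table[rl] = FALLBACK_OFFSET
            continue
        # index i corresponds to rel = i - search_window; prefer the largest
        # index (smallest |offset|) among tied maxima
        best_idx = len(meta) - 1 - int(np.argmax(meta[::-1]))
        offset = search_window - best_idx
        table[rl] = min(offset, rl - 1)
    return OffsetTable(table)


def score_periodicity(
    raw: RawProfile, offsets: OffsetTable, tset: TranscriptomeSet
) -> PeriodicityTable:
    """Majority-frame fraction of CDS-interior A-sites, per read length.

    5' ends are shifted by the inferred offset; A-sites strictly inside the
    annotated CDS (first and last codon excluded, to keep initiation and
    termination peaks out of the tally) are binned by frame relative to the
    annotated start codon. The score is the maximum frame fraction: 1/3 for
    frame-blind data, 1.0 for perfectly periodic data.
    """
    frames: dict[int, np.ndarray] = {}
    for (tid, rl), positions in raw.items():
        if tid not in tset:
            continue
        rec = tset[tid]
        if not rec.coding:
            continue
        off = offsets[rl]
        tally = frames.setdefault(rl, np.zeros(3, dtype=np.int64))
        lo, hi = rec.cds_start + 3, rec.cds_stop - 3
        for pos, n in positions.items():
            a = pos + off
            if lo <= a <= hi:
                tally[(a - rec.cds_start) % 3] += n
    table: dict[int, tuple[tuple[int, int, int], Optional[float]]] = {}
    for rl in raw.read_lengths():
        tally = frames.get(rl, np.zeros(3, dtype=np.int64))
        total = int(tally.sum())
        if total == 0:
            table[rl] = ((0, 0, 0), None)
        else:
            table[rl] = (tuple(int(x) for x in tally), float(tally.max()) / total)
    return PeriodicityTable(table)


def build_subcodon_profile(
    raw: RawProfile,
    offsets: OffsetTable,
    periodicity: PeriodicityTable,
    tset: TranscriptomeSet,
    min_score: float = DEFAULT_MIN_PERIODICITY,
) -> SubcodonProfile:
    """Accumulate A-site counts from read lengths passing the periodicity filter.

    Read lengths whose score is below ``min_score`` (or absent) are dropped;
    surviving 5' ends are shifted by their offset and added to the
    transcript's position vector. A-sites shifted past the transcript end are
    discarded.
    """
    if not 1 / 3 <= min_score <= 1:
        raise ProfileError(f"min_score {min_score} outside [1/3, 1]")
    surviving = [
        rl for rl in raw.read_lengths()
        if periodicity.score(rl) is not None and periodicity.score(rl) >= min_score
    ]
    if not surviving:
        raise ProfileError(
            f"all read lengths fall below periodicity {min_score}; lower --min-periodicity"
        )
    keep = set(surviving)
    profile = SubcodonProfile()
    for (tid, rl), positions in raw.items():
        if rl not in keep or tid not in tset:
            continue
        rec = tset[tid]
        vec = profile.ensure(tid, rec.length)
        off = offsets[rl]
        for pos, n in positions.items():
            a = pos + off
            if 1 <= a <= rec.length:
                vec[a - 1] += n
    return profile


def metagene(
    raw: RawProfile,
    offsets: OffsetTable,
    tset: TranscriptomeSet,
    anchor: str = "cds_start",
    span: int = 60,
) -> np.ndarray:
    """Aggregate A-site counts around CDS starts or stops.

    Returns a vector indexed ``-span..+span`` (length ``2*span + 1``).
    Transcripts contribute at a relative position only where that position
    exists on the transcript.
    """
    if anchor not in ("cds_start", "cds_stop"):
        raise ProfileError(f"anchor must be cds_start or cds_stop, got {anchor!r}")
    if span < 1:
        raise ProfileError("span must be >= 1")
    vec = np.zeros(2 * span + 1, dtype=np.int64)
    for (tid, rl), positions in raw.items():
        if tid not in tset:
            continue
        rec = tset[tid]
        if not rec.coding:
            continue
        a0 = rec.cds_start if anchor == "cds_start" else rec.cds_stop
        off = offsets[rl]
        for pos, n in positions.items():
            a = pos + off
            rel = a - a0
            if -span <= rel <= span and 1 <= a <= rec.length:
                vec[rel + span] += n
    return vec


def readlength_distribution(raw: RawProfile) -> dict[int, int]:
    """Total usable alignments per read length."""
    dist: Counter = Counter()
    for (_, rl), positions in raw.items():
        dist[rl] += sum(positions.values())
    return dict(sorted(dist.items()))


# ---------------------------------------------------------------------------
# TSV export


def write_subcodon_tsv(profile: SubcodonProfile, out_path: str | Path, header: str = "") -> None:
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("transcript_id\tposition\tframe0\tframe1\tframe2\n")
        for tid in profile.transcripts():
            f0, f1, f2 = profile.frame_vectors(tid)
            total = profile.counts(tid)
            for idx in np.nonzero(total)[0]:
                fh.write(f"{tid}\t{idx + 1}\t{f0[idx]}\t{f1[idx]}\t{f2[idx]}\n")


def write_periodicity_tsv(
    periodicity: PeriodicityTable, offsets: OffsetTable, out_path: str | Path, header: str = ""
) -> None:
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("read_length\toffset\tframe0\tframe1\tframe2\tscore\n")
        for rl, (counts, score) in periodicity.items():
            score_s = f"{score:.6g}" if score is not None else "NA"
            fh.write(f"{rl}\t{offsets[rl]}\t{counts[0]}\t{counts[1]}\t{counts[2]}\t{score_s}\n")
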