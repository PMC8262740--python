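"""Transcript-coordinate view of a transcriptome.

Everything downstream of alignment works in *transcript space*: position 1 is
the 5' end of the mature transcript, and the CDS is a single contiguous
interval ``[cds_start, cds_stop]`` (1-based, inclusive, stop codon included).
This module loads a transcript FASTA plus a GTF annotation into
:class:`TranscriptRecord` objects, projects genomic CDS coordinates through
the exon map, selects principal isoforms, and provides region extraction,
merged-CDS unions and motif annotation.

Coordinate conventions
----------------------
All public fields and arguments are 1-based inclusive (the GTF convention).
The frame of a transcript position ``p`` is ``(p - 1) % 3``, anchored to the
transcript, not to the CDS, so that a reading-frame colour is well defined
outside annotated coding regions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_NT = set("ACGTN")

START_CODONS_DEFAULT = frozenset({"ATG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NEAR_COGNATE_STARTS = frozenset(
    {"CTG", "GTG", "TTG", "ACG", "ATT", "ATC", "ATA", "AGG", "AAG"}
)


class TranscriptomeError(ValueError):
    """Raised for inconsistent annotation / sequence input."""


@dataclass
class Exon:
    chrom: str
    start: int  # genomic, 1-based inclusive
    end: int
    strand: str  # '+' or '-'

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptRecord:
    """One transcript in transcript coordinates.

    ``exons`` are ordered 5'->3' in transcript orientation (descending genomic
    coordinates on the minus strand). ``cds_start``/``cds_stop`` are 1-based
    transcript positions of the first nucleotide of the start codon and the
    last nucleotide of the stop codon; both are ``None`` for non-coding
    transcripts.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: Optional[int] = None
    cds_stop: Optional[int] = None
    exons: list[Exon] = field(default_factory=list)
    principal: bool = False
    cds_genomic: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = set(self.sequence) - _VALID_NT
        if bad:
            raise TranscriptomeError(
                f"{self.transcript_id}: invalid characters in sequence: {sorted(bad)}"
            )
        if self.exons and sum(len(e) for e in self.exons) != len(self.sequence):
            raise TranscriptomeError(
                f"{self.transcript_id}: exon lengths sum to "
                f"{sum(len(e) for e in self.exons)} but sequence is {len(self.sequence)} nt"
            )

    @property
    def coding(self) -> bool:
        return self.cds_start is not None and self.cds_stop is not None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return (self.cds_stop - self.cds_start + 1) if self.coding else 0

    @property
    def strand(self) -> Optional[str]:
        return self.exons[0].strand if self.exons else None

    @property
    def chrom(self) -> Optional[str]:
        return self.exons[0].chrom if self.exons else None

    # -- coordinate projection ------------------------------------------------

    def genome_to_transcript(self, gpos: int) -> Optional[int]:
        """Project a genomic position onto this transcript (1-based).

        Returns ``None`` when the position falls outside every exon.
        """
        offset = 0
        for exon in self.exons:
            if exon.start <= gpos <= exon.end:
                if exon.strand == "+":
                    return offset + (gpos - exon.start + 1)
                return offset + (exon.end - gpos + 1)
            offset += len(exon)
        return None

    def transcript_to_genome(self, tpos: int) -> int:
        if not 1 <= tpos <= self.length:
            raise TranscriptomeError(
                f"{self.transcript_id}: transcript position {tpos} out of range 1..{self.length}"
            )
        offset = 0
        for exon in self.exons:
            if tpos <= offset + len(exon):
                within = tpos - offset
                if exon.strand == "+":
                    return exon.start + within - 1
                return exon.end - within + 1
            offset += len(exon)
        raise AssertionError("unreachable")

    def transcript_interval_to_genomic(
        self, t_start: int, t_stop: int
    ) -> list[tuple[str, int, int, str]]:
        """Map a transcript interval back to (possibly several) genomic intervals."""
        if t_start > t_stop:
            raise TranscriptomeError("t_start must be <= t_stop")
        out: list[tuple[str, int, int, str]] = []
        offset = 0
        for exon in self.exons:
            lo = max(t_start, offset + 1)
            hi = min(t_stop, offset + len(exon))
            if lo <= hi:
                if exon.strand == "+":
                    g_lo = exon.start + (lo - offset) - 1
                    g_hi = exon.start + (hi - offset) - 1
                else:
                    g_hi = exon.end - (lo - offset) + 1
                    g_lo = exon.end - (hi - offset) + 1
                out.append((exon.chrom, g_lo, g_hi, exon.strand))
            offset += len(exon)
        return out


@dataclass
class IntervalList:
    """Sorted, non-overlapping 1-based inclusive transcript intervals."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_unsorted(cls, raw: Iterable[tuple[int, int]]) -> "IntervalList":
        merged: list[tuple[int, int]] = []
        for start, stop in sorted(raw):
            if start > stop:
                raise TranscriptomeError(f"invalid interval ({start}, {stop})")
            if merged and start <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
            else:
                merged.append((start, stop))
        return cls(merged)

    def contains_interval(self, start: int, stop: int) -> bool:
        return any(s <= start and stop <= e for s, e in self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


class TranscriptomeSet:
    """Collection of :class:`TranscriptRecord` with a gene index."""

    def __init__(self, records: Iterable[TranscriptRecord]):
        self.records: dict[str, TranscriptRecord] = {}
        self.gene_index: dict[str, list[str]] = {}
        for rec in records:
            if rec.transcript_id in self.records:
                raise TranscriptomeError(f"duplicate transcript_id {rec.transcript_id}")
            self.records[rec.transcript_id] = rec
            self.gene_index.setdefault(rec.gene_id, []).append(rec.transcript_id)
        # every gene gets a principal isoform; keep caller-provided flags
        for tids in self.gene_index.values():
            recs = [self.records[t] for t in tids]
            if not any(r.principal for r in recs):
                best = min(recs, key=lambda r: _principal_key(r, False))
                best.principal = True

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.records

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        try:
            return self.records[transcript_id]
        except KeyError:
            raise TranscriptomeError(f"unknown transcript_id {transcript_id!r}") from None

    def __iter__(self):
        return iter(self.records.values())

    def principal_records(self) -> list[TranscriptRecord]:
        return [r for r in self.records.values() if r.principal]

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptRecord]:
        return [self.records[t] for t in self.gene_index.get(gene_id, [])]


# ---------------------------------------------------------------------------
# loading


def _principal_key(rec: TranscriptRecord, appris: bool) -> tuple:
    # sort descending on (appris tag, CDS length, transcript length),
    # ascending on ID -- first element wins
    return (not appris, -rec.cds_length, -rec.length, rec.transcript_id)


def load_transcriptome(
    fasta_path: str | Path,
    gtf_path: str | Path,
    principal_only: bool = False,
) -> TranscriptomeSet:
    """Load transcript sequences (FASTA) and annotation (GTF) into a set.

    FASTA identifiers must match GTF ``transcript_id`` attributes. CDS bounds
    are projected from genomic to transcript coordinates; when a
    ``stop_codon`` feature is present the CDS is extended 3 nt to include it
    (Ensembl/GENCODE dialect). A transcript whose projected CDS length is not
    a multiple of 3 is demoted to non-coding with a warning.

    With ``principal_only`` one transcript per gene is flagged principal,
    preferring an APPRIS principal tag, then longest CDS, longest transcript,
    smallest ID; other isoforms are still loaded (merged-CDS needs them) but
    carry ``principal=False``. Without the flag every transcript of its gene
    is ranked the same way and the winner flagged, so `principal` is always
    defined.
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list[Exon]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    has_stop_feature: set[str] = set()
    gene_of: dict[str, str] = {}
    appris_tag: set[str] = set()

    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS", "stop_codon"}:
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            continue
        tid = tids[0]
        gene_of.setdefault(tid, feat.attributes.get("gene_id", [tid])[0])
        tags = feat.attributes.get("tag", [])
        if any("appris_principal" in t for t in tags):
            appris_tag.add(tid)
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(Exon(feat.seqid, feat.start, feat.end, feat.strand))
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append((feat.start, feat.end))
        else:
            has_stop_feature.add(tid)

    records: list[TranscriptRecord] = []
    for tid, exon_list in exons.items():
        if tid not in sequences:
            raise TranscriptomeError(f"no FASTA sequence for annotated transcript {tid!r}")
        strand = exon_list[0].strand
        exon_list.sort(key=lambda e: e.start, reverse=(strand == "-"))
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_id=gene_of[tid],
            sequence=sequences[tid],
            exons=exon_list,
        )
        if tid in cds:
            _assign_cds(rec, cds[tid], stop_excluded=tid in has_stop_feature)
        records.append(rec)

    tset = TranscriptomeSet(records)
    _flag_principals(tset, appris_tag)
    if principal_only:
        survivors = []
        for gene_id, tids in tset.gene_index.items():
            recs = [tset.records[t] for t in tids]
            survivors.extend(r for r in recs if r.principal)
        tset = TranscriptomeSet(survivors)
    return tset


def _assign_cds(rec: TranscriptRecord, genomic_cds: list[tuple[int, int]], stop_excluded: bool) -> None:
    tpos: list[int] = []
    for g_start, g_end in genomic_cds:
        for g in (g_start, g_end):
            t = rec.genome_to_transcript(g)
            if t is None:
                raise TranscriptomeError(
                    f"{rec.transcript_id}: CDS position {g} falls outside annotated exons"
                )
            tpos.append(t)
    cds_start, cds_stop = min(tpos), max(tpos)
    if stop_excluded:
        cds_stop += 3
    if cds_stop > rec.length:
        logger.warning(
            "%s: CDS (with stop codon) extends past the transcript end; marking non-coding",
            rec.transcript_id,
        )
        return
    if (cds_stop - cds_start + 1) % 3 != 0:
        logger.warning(
            "%s: CDS length %d not divisible by 3; marking non-coding",
            rec.transcript_id,
            cds_stop - cds_start + 1,
        )
        return
    rec.cds_start, rec.cds_stop = cds_start, cds_stop
    rec.cds_genomic = rec.transcript_interval_to_genomic(cds_start, cds_stop)


def _flag_principals(tset: TranscriptomeSet, appris_tag: set[str]) -> None:
    for gene_id, tids in tset.gene_index.items():
        recs = [tset.records[t] for t in tids]
        best = min(recs, key=lambda r: _principal_key(r, r.transcript_id in appris_tag))
        for r in recs:
            r.principal = r is best


# ---------------------------------------------------------------------------
# operations

REGIONS = ("leader", "cds", "trailer", "full")


def extract_region(record: TranscriptRecord, region: str) -> str:
    """Return the leader / CDS / trailer / full sequence of a transcript.

    The leader is everything 5' of the start codon, the trailer everything 3'
    of the stop codon; either may be empty. Leader/CDS/trailer require a
    coding record.
    """
    if region not in REGIONS:
        raise TranscriptomeError(f"unknown region {region!r}; expected one of {REGIONS}")
    if region == "full":
        return record.sequence
    if not record.coding:
        raise TranscriptomeError(
            f"{record.transcript_id} is non-coding; region {region!r} undefined"
        )
    if region == "leader":
        return record.sequence[: record.cds_start - 1]
    if region == "cds":
        return record.sequence[record.cds_start - 1 : record.cds_stop]
    return record.sequence[record.cds_stop :]


def merged_cds(tset: TranscriptomeSet, transcript_id: str) -> IntervalList:
    """Union of all same-strand annotated CDS regions at the locus, projected
    onto one transcript.

    Every CDS interval (stop codon included) of every transcript in the set
    that lies on the same chromosome and strand is projected through the query
    transcript's exon map; positions the query does not cover are dropped.
    Opposite-strand CDSs are excluded: they cannot explain footprints on this
    transcript's sense strand.
    """
    query = tset[transcript_id]
    raw: list[tuple[int, int]] = []
    for rec in tset:
        for chrom, g_lo, g_hi, strand in rec.cds_genomic:
            if chrom != query.chrom or strand != query.strand:
                continue
            run_start: Optional[int] = None
            prev: Optional[int] = None
            # walk genomic positions in query-transcript orientation
            g_range = range(g_lo, g_hi + 1)
            for g in g_range:
                t = query.genome_to_transcript(g)
                if t is None:
                    continue
                if run_start is None:
                    run_start = prev = t
                elif abs(t - prev) == 1:
                    prev = t
                else:
                    raw.append((min(run_start, prev), max(run_start, prev)))
                    run_start = prev = t
            if run_start is not None:
                raw.append((min(run_start, prev), max(run_start, prev)))
    return IntervalList.from_unsorted(raw)


def find_motif(record: TranscriptRecord, pattern: str) -> list[tuple[int, int]]:
    """All (possibly overlapping) exact matches of a nucleotide motif.

    Returns 1-based start positions with the transcript-anchored frame
    ``(position - 1) % 3``. RNA input (U) is accepted.
    """
    pattern = pattern.upper().replace("U", "T")
    if not pattern:
        raise TranscriptomeError("empty motif pattern")
    bad = set(pattern) - set("ACGT")
    if bad:
        raise TranscriptomeError(f"motif contains invalid characters: {sorted(bad)}")
    hits = []
    for m in re.finditer(f"(?=({re.escape(pattern)}))", record.sequence):
        pos = m.start() + 1
        hits.append((pos, (pos - 1) % 3))
    return hits


def write_region_fasta(
    tset: TranscriptomeSet, region: str, out_path: str | Path, subset: Optional[Iterable[str]] = None
) -> int:
    """Export a region of every (or a subset of) transcript(s) as FASTA."""
    tids = list(subset) if subset is not None else sorted(tset.records)
    n = 0
    with open(out_path, "w") as fh:
        for tid in tids:
            rec = tset[tid]
            if region != "full" and not rec.coding:
                continue
            seq = extract_region(rec, region)
            if not seq:
                continue
            fh.write(f">{tid}|{region}\n{seq}\n")
            n += 1
    return n


def write_merged_cds_bed(tset: TranscriptomeSet, transcript_id: str, out_path: str | Path) -> None:
    """Merged-CDS intervals as BED (0-based half-open) in transcript coordinates."""
    union = merged_cds(tset, transcript_id)
    with open(out_path, "w") as fh:
        for start, stop in union:
            fh.write(f"{transcript_id}\t{start - 1}\t{stop}\tmerged_CDS\n")
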