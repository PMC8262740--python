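"""Three-frame proteogenomic peptide mapping.

Peptide identifications from an upstream database search (e.g. MSFragger
scored and FDR-filtered with Philosopher) are located on transcripts by exact
string matching against the translation of *all three* reading frames of each
(principal) transcript — not just the annotated CDS — so that peptides
supporting uORFs, extensions or ORFs on non-coding RNAs are found and can be
frame-coloured like footprint data.

Only the peptide/FDR table is consumed here; spectral search and FDR
estimation belong to the upstream tools. I and L are kept distinct: mapping
is exact-sequence, collapsing isobaric residues is a search-engine concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

from .transcriptome import TranscriptomeSet, TranscriptRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class PeptideError(ValueError):
    pass


@dataclass
class PeptideHit:
    """One exact peptide occurrence on a transcript frame translation.

    ``aa_start`` is the 1-based residue index in the frame translation;
    ``nt_start``/``nt_stop`` are 1-based transcript coordinates and satisfy
    ``nt_stop - nt_start + 1 == 3 * len(peptide)`` and
    ``frame == (nt_start - 1) % 3``.
    """

    peptide: str
    transcript_id: str
    frame: int
    aa_start: int
    nt_start: int
    nt_stop: int
    fdr: float = float("nan")


def translate_three_frames(record: TranscriptRecord) -> tuple[str, str, str]:
    """Standard-code translation of the three transcript frames.

    Stops are rendered as ``*``, codons containing N as ``X``; a trailing
    partial codon is dropped.
    """
    seq = record.sequence
    if len(seq) < 3:
        raise PeptideError(f"{record.transcript_id}: sequence shorter than one codon")
    out = []
    for f in range(3):
        sub = seq[f : f + 3 * ((len(seq) - f) // 3)]
        out.append(str(Seq(sub).translate(table=1)) if sub else "")
    return tuple(out)


def filter_fdr(hits: pd.DataFrame, max_fdr: float = 0.01) -> pd.DataFrame:
    """Drop peptide rows with FDR above the threshold (boundary kept).

    Mirrors the usual proteogenomics convention of *removing* peptides with
    FDR > 1%, so a row at exactly the threshold survives.
    """
    if "fdr" not in hits.columns:
        raise PeptideError("peptide table lacks an 'fdr' column")
    return hits[hits["fdr"] <= max_fdr].reset_index(drop=True)


def map_peptides(
    peptides: Iterable[str],
    tset: TranscriptomeSet,
    principal_only: bool = True,
    fdrs: Iterable[float] | None = None,
) -> list[PeptideHit]:
    """Every exact occurrence of each peptide in each frame of each transcript.

    Returns hits with transcript-space nucleotide coordinates
    ``nt_start = 3*(aa_start - 1) + frame + 1``. Overlapping and multiple
    occurrences are all reported; an absent peptide simply yields no hits.
    """
    peptides = list(peptides)
    fdr_list = list(fdrs) if fdrs is not None else [float("nan")] * len(peptides)
    if len(fdr_list) != len(peptides):
        raise PeptideError("fdrs must match peptides in length")
    for pep in peptides:
        if not pep:
            raise PeptideError("empty peptide")
        bad = set(pep.upper()) - AA_ALPHABET
        if bad:
            raise PeptideError(f"peptide {pep!r} contains invalid residues {sorted(bad)}")

    records = tset.principal_records() if principal_only else list(tset)
    records.sort(key=lambda r: r.transcript_id)
    hits: list[PeptideHit] = []
    for rec in records:
        if rec.length < 3:
            continue
        translations = translate_three_frames(rec)
        for frame, protein in enumerate(translations):
            for pep, fdr in zip(peptides, fdr_list):
                p = pep.upper()
                idx = protein.find(p)
                while idx != -1:
                    aa_start = idx + 1
                    nt_start = 3 * (aa_start - 1) + frame + 1
                    hits.append(
                        PeptideHit(
                            peptide=p,
                            transcript_id=rec.transcript_id,
                            frame=frame,
                            aa_start=aa_start,
                            nt_start=nt_start,
                            nt_stop=nt_start + 3 * len(p) - 1,
                            fdr=fdr,
                        )
                    )
                    idx = protein.find(p, idx + 1)
    return hits


def map_peptide_table(
    table: pd.DataFrame,
    tset: TranscriptomeSet,
    max_fdr: float = 0.01,
    principal_only: bool = True,
) -> pd.DataFrame:
    """FDR-filter a (peptide, fdr) table and map the survivors.

    Extra columns are carried through onto every hit row.
    """
    if "peptide" not in table.columns:
        raise PeptideError("peptide table lacks a 'peptide' column")
    kept = filter_fdr(table, max_fdr=max_fdr)
    rows = []
    for _, row in kept.iterrows():
        for hit in map_peptides([row["peptide"]], tset, principal_only=principal_only):
            out = dict(row)
            out.update(
                transcript_id=hit.transcript_id,
                frame=hit.frame,
                aa_start=hit.aa_start,
                nt_start=hit.nt_start,
                nt_stop=hit.nt_stop,
            )
            rows.append(out)
    columns = list(table.columns) + ["transcript_id", "frame", "aa_start", "nt_start", "nt_stop"]
    return pd.DataFrame(rows, columns=columns)


def write_hits_tsv(hits: pd.DataFrame, out_path: str | Path, header: str = "") -> None:
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        hits.to_csv(fh, sep="\t", index=False)


def write_hits_bed(hits: pd.DataFrame, out_path: str | Path, header: str = "") -> None:
    """Peptide hits as BED in transcript coordinates, one colour-frame per name."""
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        for _, row in hits.iterrows():
            fh.write(
                f"{row['transcript_id']}\t{row['nt_start'] - 1}\t{row['nt_stop']}\t"
                f"{row['peptide']}|frame{row['frame']}\t0\t+\n"
            )
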