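"""Transcriptome metainformation: descriptive statistics over an annotation.

Answers the simple questions about a transcriptome that do not involve any
sequencing data: how many genes/transcripts are annotated and how many are
coding, codon usage within principal CDSs, leader/trailer lengths and GC
content (optionally compared between gene groups, e.g. up- vs down-regulated
genes), and sliding-window nucleotide composition along one transcript.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptome import TranscriptomeSet, TranscriptRecord, extract_region

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


class MetainfoError(ValueError):
    pass


def summary_counts(tset: TranscriptomeSet) -> dict[str, int]:
    """Gene / transcript / coding / non-coding tallies."""
    coding = sum(1 for r in tset if r.coding)
    return {
        "genes": len(tset.gene_index),
        "transcripts": len(tset),
        "coding": coding,
        "noncoding": len(tset) - coding,
    }


def codon_usage(
    tset: TranscriptomeSet,
    subset: Optional[Iterable[str]] = None,
    include_stop: bool = True,
) -> pd.DataFrame:
    """In-frame codon counts over principal CDSs.

    Returns a 64-row DataFrame indexed by codon with ``count`` and
    ``frequency`` columns (frequencies sum to 1). The stop codon is part of
    the CDS under this package's conventions and is counted by default;
    ``include_stop=False`` excludes the final codon of each CDS. Codons
    containing N are not counted.
    """
    genes = set(subset) if subset is not None else None
    counts = dict.fromkeys(ALL_CODONS, 0)
    total = 0
    seen_coding = False
    for rec in tset.principal_records():
        if genes is not None and rec.gene_id not in genes:
            continue
        if not rec.coding:
            continue
        seen_coding = True
        cds = extract_region(rec, "cds")
        if not include_stop:
            cds = cds[:-3]
        for i in range(0, len(cds) - 2, 3):
            codon = cds[i : i + 3]
            if codon in counts:
                counts[codon] += 1
                total += 1
    if not seen_coding:
        raise MetainfoError("no coding transcripts in the requested subset")
    df = pd.DataFrame({"count": pd.Series(counts)})
    df.index.name = "codon"
    df["frequency"] = df["count"] / total if total else 0.0
    return df


def _gc_fraction(seq: str) -> float:
    """GC fraction with N excluded; NaN (absent) for empty/all-N sequences."""
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def region_stats(
    tset: TranscriptomeSet, subset: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Per-transcript region lengths and GC fractions (principal, coding).

    Zero-length regions get GC ``NaN`` (absent), never 0.
    """
    genes = set(subset) if subset is not None else None
    rows = []
    for rec in tset.principal_records():
        if genes is not None and rec.gene_id not in genes:
            continue
        if not rec.coding:
            continue
        leader = extract_region(rec, "leader")
        cds = extract_region(rec, "cds")
        trailer = extract_region(rec, "trailer")
        rows.append(
            {
                "transcript_id": rec.transcript_id,
                "gene_id": rec.gene_id,
                "leader_length": len(leader),
                "cds_length": len(cds),
                "trailer_length": len(trailer),
                "leader_gc": _gc_fraction(leader),
                "cds_gc": _gc_fraction(cds),
                "trailer_gc": _gc_fraction(trailer),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_id",
            "leader_length",
            "cds_length",
            "trailer_length",
            "leader_gc",
            "cds_gc",
            "trailer_gc",
        ],
    )


def compare_groups(
    tset: TranscriptomeSet, group_a: Iterable[str], group_b: Iterable[str]
) -> pd.DataFrame:
    """Median comparison of region metrics between two disjoint gene groups.

    Reports per-metric group medians plus a descriptive Mann-Whitney U rank
    statistic and its p-value (no multiple-testing machinery — this mirrors a
    boxplot-style comparison, not a formal test battery).
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise MetainfoError("gene groups must be disjoint")
    stats_a = region_stats(tset, subset=group_a)
    stats_b = region_stats(tset, subset=group_b)
    rows = []
    for metric in ("leader_length", "cds_length", "trailer_length", "leader_gc", "cds_gc", "trailer_gc"):
        va = stats_a[metric].dropna()
        vb = stats_b[metric].dropna()
        if len(va) and len(vb):
            u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        else:
            u, p = np.nan, np.nan
        rows.append(
            {
                "metric": metric,
                "median_a": va.median() if len(va) else np.nan,
                "median_b": vb.median() if len(vb) else np.nan,
                "mannwhitney_u": u,
                "p_value": p,
                "n_a": len(va),
                "n_b": len(vb),
            }
        )
    return pd.DataFrame(rows)


def sliding_composition(
    record: TranscriptRecord, window: int = 60, step: int = 1, metric: str = "gc"
) -> pd.DataFrame:
    """Windowed base composition along a transcript.

    ``metric`` is ``gc`` or a single base ``a|c|g|t``. Returns window centre
    positions (1-based transcript coordinates, the midpoint of each window)
    and the fraction of the metric base(s) within the window, N bases
    excluded from both numerator and denominator.

    The same windowing is the natural place to hang an RNA secondary-structure
    minimum-free-energy track computed externally (e.g. with RNAfold); that
    computation is not performed here.
    """
    metric = metric.lower()
    if metric not in ("gc", "a", "c", "g", "t"):
        raise MetainfoError(f"metric must be gc|a|c|g|t, got {metric!r}")
    if step < 1:
        raise MetainfoError("step must be >= 1")
    if window > record.length:
        raise MetainfoError(
            f"window {window} exceeds transcript length {record.length}"
        )
    targets = ("G", "C") if metric == "gc" else (metric.upper(),)
    seq = record.sequence
    rows = []
    for lo in range(0, record.length - window + 1, step):
        win = seq[lo : lo + window]
        denom = sum(win.count(b) for b in BASES)
        frac = sum(win.count(b) for b in targets) / denom if denom else np.nan
        rows.append({"center": lo + (window + 1) / 2.0, "fraction": frac})
    return pd.DataFrame(rows, columns=["center", "fraction"])


def write_table_tsv(df: pd.DataFrame, out_path: str | Path, header: str = "", index: bool = False) -> None:
    with open(out_path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=index)
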