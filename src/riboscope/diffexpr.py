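"""Differential expression / translation via the z-score transformation.

The z-score route needs no replicates: per gene the log2 fold change between
two conditions is standardised against genes of similar expression, on the
assumption that fold-change variance depends on expression level. Genes are
ordered by mean expression and each gene's fold change is standardised
against a robust location/scale (median, normal-consistent MAD) of the fold
changes in a sliding window of neighbours in that ordering.

Genes are then classified by comparing footprint (Ribo-Seq) and mRNA
(RNA-Seq) z-scores: a footprint change without an mRNA change is a
translational change; any mRNA change is classified at the mRNA level.

More powerful replicate-aware methods (DESeq2, anota2seq) are deliberately
not re-implemented; :func:`export_deseq2_counts` / :func:`export_anota2seq_counts`
write the count matrices those packages consume, after validating their
replicate minima (two and three per condition respectively).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .profiles import OffsetTable, RawProfile
from .transcriptome import TranscriptomeSet

CLASSES = ("unchanged", "translation_up", "translation_down", "mrna_up", "mrna_down")


class DiffExprError(ValueError):
    pass


def aggregate_counts(
    raw: RawProfile,
    tset: TranscriptomeSet,
    assay: str,
    offsets: Optional[OffsetTable] = None,
    region: Optional[str] = None,
) -> pd.Series:
    """Gene-level counts from a raw profile, on principal isoforms.

    For ``assay='ribo'`` A-sites (5' end + offset) falling in the region are
    counted (default region ``cds``); for ``assay='rna'`` raw 5' ends are
    counted (default region ``full``). Genes whose principal transcript is
    non-coding are excluded when the region requires CDS bounds.
    """
    if assay not in ("ribo", "rna"):
        raise DiffExprError(f"assay must be 'ribo' or 'rna', got {assay!r}")
    if region is None:
        region = "cds" if assay == "ribo" else "full"
    if region not in ("cds", "full"):
        raise DiffExprError(f"region must be 'cds' or 'full', got {region!r}")
    if assay == "ribo" and offsets is None:
        offsets = OffsetTable()

    principal = {r.transcript_id: r for r in tset.principal_records()}
    out = {r.gene_id: 0 for r in principal.values() if region == "full" or r.coding}
    for (tid, rl), positions in raw.items():
        rec = principal.get(tid)
        if rec is None:
            continue
        if region == "cds" and not rec.coding:
            continue
        shift = offsets[rl] if assay == "ribo" else 0
        lo, hi = (rec.cds_start, rec.cds_stop) if region == "cds" else (1, rec.length)
        for pos, n in positions.items():
            p = pos + shift
            if lo <= p <= hi:
                out[rec.gene_id] += n
    return pd.Series(out, name=assay).sort_index()


def _sum_replicates(
    counts: pd.DataFrame, samples: pd.DataFrame, assay: str
) -> tuple[pd.Series, pd.Series, tuple[str, str]]:
    sub = samples[samples["assay"] == assay]
    conditions = sorted(sub["condition"].unique())
    if len(conditions) != 2:
        raise DiffExprError(
            f"need exactly two conditions for assay {assay!r}, found {conditions}"
        )
    cond_a, cond_b = conditions
    col_a = sub.loc[sub["condition"] == cond_a, "sample"].tolist()
    col_b = sub.loc[sub["condition"] == cond_b, "sample"].tolist()
    return counts[col_a].sum(axis=1), counts[col_b].sum(axis=1), (cond_a, cond_b)


def zscore_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    assay: str,
    window: int = 300,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Expression-ordered sliding-window z-scores of log2 fold changes.

    ``counts`` is genes x samples; ``samples`` holds columns (sample, assay,
    condition, replicate). Replicates are summed within condition. With
    condition sums ``A_g``, ``B_g``:

    * ``log2fc_g = log2((B_g + pc) / (A_g + pc))``
    * genes are ordered by mean expression ``m_g = (A_g + B_g)/2``
    * ``z_g = (log2fc_g - mu_g) / sigma_g`` with ``mu_g`` the median and
      ``sigma_g`` the normal-consistent MAD (``1.4826 * MAD``) of ``log2fc``
      over the ``window`` genes centred on ``g`` in that ordering (the window
      shrinks at the extremes; ``sigma_g == 0`` yields ``z_g = 0``).

    Robust location/scale rather than mean/s.d.: genuinely regulated genes
    sit in their own windows (and, by shifting in the expression ordering,
    cluster in their neighbours'), and would otherwise inflate the scale
    estimate and mask themselves. Under a pure null the two standardisations
    agree (MAD is consistent for the s.d.).

    Returns a DataFrame indexed by gene with columns ``mean_expr``,
    ``log2fc``, ``z``.
    """
    if window < 3:
        raise DiffExprError("window must be >= 3")
    if len(counts) < 3:
        raise DiffExprError("need at least 3 genes")
    if (counts.values < 0).any():
        raise DiffExprError("negative counts")
    a, b, _ = _sum_replicates(counts, samples, assay)
    fc = np.log2((b + pseudocount) / (a + pseudocount))
    mean_expr = (a + b) / 2.0

    order = mean_expr.sort_values(kind="mergesort").index
    fc_sorted = fc.loc[order].to_numpy(dtype=float)
    n = len(fc_sorted)
    half = window // 2
    z_sorted = np.zeros(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        win = fc_sorted[lo:hi]
        mu = np.median(win)
        sd = 1.4826 * np.median(np.abs(win - mu))
        z_sorted[i] = (fc_sorted[i] - mu) / sd if sd > 0 else 0.0
    z = pd.Series(z_sorted, index=order).reindex(counts.index)
    return pd.DataFrame(
        {"mean_expr": mean_expr, "log2fc": fc, "z": z}, index=counts.index
    )


def classify_de(z_ribo: pd.Series, z_rna: pd.Series, z_threshold: float = 2.0) -> pd.Series:
    """Gene classes from footprint and mRNA z-scores.

    An mRNA-level change (|z_rna| >= t) wins regardless of the footprint
    z-score; a footprint change without an mRNA change is translational;
    everything else is unchanged.
    """
    if not z_ribo.index.equals(z_rna.index):
        z_rna = z_rna.reindex(z_ribo.index)
        if z_rna.isna().any():
            raise DiffExprError("ribo and rna gene universes differ")
    t = z_threshold
    cls = pd.Series("unchanged", index=z_ribo.index, name="class")
    trans = (z_ribo.abs() >= t) & (z_rna.abs() < t)
    cls[trans & (z_ribo > 0)] = "translation_up"
    cls[trans & (z_ribo < 0)] = "translation_down"
    mrna = z_rna.abs() >= t
    cls[mrna & (z_rna > 0)] = "mrna_up"
    cls[mrna & (z_rna < 0)] = "mrna_down"
    return cls


def de_table(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    window: int = 300,
    pseudocount: float = 1.0,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Full per-gene table: fold changes, z-scores and class for both assays."""
    ribo = zscore_de(counts, samples, "ribo", window=window, pseudocount=pseudocount)
    rna = zscore_de(counts, samples, "rna", window=window, pseudocount=pseudocount)
    cls = classify_de(ribo["z"], rna["z"], z_threshold=z_threshold)
    return pd.DataFrame(
        {
            "mean_expr": (ribo["mean_expr"] + rna["mean_expr"]) / 2.0,
            "log2fc_ribo": ribo["log2fc"],
            "log2fc_rna": rna["log2fc"],
            "z_ribo": ribo["z"],
            "z_rna": rna["z"],
            "class": cls,
        },
        index=counts.index,
    )


def _validate_replicates(samples: pd.DataFrame, minimum: int, method: str) -> None:
    for (assay, condition), grp in samples.groupby(["assay", "condition"]):
        if len(grp) < minimum:
            raise DiffExprError(
                f"{method} requires >= {minimum} replicates per condition; "
                f"assay {assay!r} condition {condition!r} has {len(grp)}"
            )


def export_deseq2_counts(
    counts: pd.DataFrame, samples: pd.DataFrame, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write count matrix + coldata TSVs in the layout DESeq2 expects.

    Requires at least two replicates per (assay, condition).
    """
    _validate_replicates(samples, 2, "DESeq2")
    out_prefix = Path(out_prefix)
    counts_path = out_prefix.with_suffix(".counts.tsv")
    coldata_path = out_prefix.with_suffix(".coldata.tsv")
    counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    samples.set_index("sample").to_csv(coldata_path, sep="\t")
    return counts_path, coldata_path


def export_anota2seq_counts(
    counts: pd.DataFrame, samples: pd.DataFrame, out_prefix: str | Path
) -> tuple[Path, Path]:
    """As :func:`export_deseq2_counts`, with anota2seq's three-replicate minimum."""
    _validate_replicates(samples, 3, "anota2seq")
    out_prefix = Path(out_prefix)
    ribo_cols = samples.loc[samples["assay"] == "ribo", "sample"].tolist()
    rna_cols = samples.loc[samples["assay"] == "rna", "sample"].tolist()
    ribo_path = out_prefix.with_suffix(".ribo.tsv")
    rna_path = out_prefix.with_suffix(".rna.tsv")
    counts[ribo_cols].to_csv(ribo_path, sep="\t", index_label="gene_id")
    counts[rna_cols].to_csv(rna_path, sep="\t", index_label="gene_id")
    return ribo_path, rna_path


def read_counts_tsv(counts_path: str | Path, samples_path: str | Path):
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    samples = pd.read_csv(samples_path, sep="\t", comment="#")
    required = {"sample", "assay", "condition"}
    missing = required - set(samples.columns)
    if missing:
        raise DiffExprError(f"sample sheet lacks columns: {sorted(missing)}")
    unknown = set(samples["sample"]) - set(counts.columns)
    if unknown:
        raise DiffExprError(f"sample sheet names absent from count matrix: {sorted(unknown)}")
    return counts, samples
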