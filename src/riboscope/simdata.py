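"""Synthetic transcriptomes, footprint alignments, count matrices and peptides.

Every analysis module in this package can be exercised end-to-end without
external downloads: this module generates

* a transcriptome of 5'leader-CDS-3'trailer transcripts (FASTA + GTF, one
  single-exon gene per transcript on a synthetic chromosome), with a truth
  set of planted non-canonical ORFs (uORFs in leaders, dORFs in trailers,
  off-frame nested ORFs inside CDSs, N-terminal extensions sharing the
  annotated stop, ORFs on non-coding RNAs);
* ribosome-footprint alignments (SAM) with per-codon Poisson coverage,
  tunable in-frame probability ``periodicity_p``, a fixed 5'-end -> A-site
  offset ``offset_true``, and uniform background noise in untranslated
  regions;
* gene x sample count matrices with negative-binomial noise and optional
  spiked differential-translation genes;
* peptide/FDR tables derived from truth-ORF translations plus decoys.

All randomness flows from a single integer seed through one generator stream
in a fixed iteration order, so outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .transcriptome import STOP_CODONS

BASES = np.array(list("ACGT"))
_STOPS = sorted(STOP_CODONS)
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Lengths are nucleotides; ``coverage_mean`` is the expected number of
    A-sites per codon in translated regions, ``background_rate`` the expected
    A-sites per nucleotide in untranslated regions. ``truth_orfs`` lists
    (category, count, coverage multiplier) of planted translated ORFs.
    """

    seed: int = 0
    n_genes: int = 100
    n_noncoding: int = 0
    leader_range: tuple[int, int] = (60, 120)
    cds_range: tuple[int, int] = (300, 600)
    trailer_range: tuple[int, int] = (60, 120)
    read_length_weights: dict[int, float] = field(
        default_factory=lambda: {27: 0.10, 28: 0.35, 29: 0.25, 30: 0.20, 31: 0.10}
    )
    offset_true: int = 12
    periodicity_p: float = 0.85
    coverage_mean: float = 2.0
    initiation_boost: float = 5.0  # extra A-site density on each start codon
    background_rate: float = 0.05
    truth_orfs: tuple[tuple[str, int, float], ...] = (("uORF", 20, 1.0),)
    orf_codons_range: tuple[int, int] = (8, 14)
    de_spike: tuple[float, float, str] = (0.05, 2.0, "ribo")
    de_mean_log: float = 5.0  # natural-log scale of the lognormal gene means
    de_dispersion: float = 0.02  # technical-scale NB overdispersion: all samples
    # share identical per-gene means, i.e. library-vs-library comparison
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not 1 / 3 < self.periodicity_p <= 1:
            raise SimulationError("periodicity_p must lie in (1/3, 1]")
        for lo, hi in (self.leader_range, self.cds_range, self.trailer_range):
            if lo > hi or lo < 1:
                raise SimulationError("invalid length range")
        if self.offset_true < 0:
            raise SimulationError("offset_true must be non-negative")
        w = sum(self.read_length_weights.values())
        if w <= 0:
            raise SimulationError("read_length_weights must have positive mass")


@dataclass
class SimulatedTranscriptome:
    fasta_path: Path
    gtf_path: Path
    truth: pd.DataFrame  # transcript_id, start, stop, category, translated, multiplier
    sequences: dict[str, str]
    cds_bounds: dict[str, tuple[int, int]]  # transcript coords, stop included


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(BASES[rng.integers(0, 4, size=n)])


def _random_nonstop_codons(rng: np.random.Generator, k: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=k)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _scrub_upstream_inframe_starts(seq: list[str], start: int) -> None:
    """Mutate in-frame ATGs 5' of ``start`` (1-based) up to the first in-frame
    stop, so the planted start codon stays the 5'-most of its (stop, frame).

    ATG -> ATC (G -> C at the wobble position) can create neither a stop nor
    a new ATG in any frame.
    """
    q = start - 3
    while q >= 1:
        codon = "".join(seq[q - 1 : q + 2])
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            seq[q + 1] = "C"
        q -= 3


def _plant_orf_seq(rng: np.random.Generator, codons: int) -> str:
    """An ORF of ``codons`` translated codons (start included) plus its stop:
    ATG + (codons - 1) non-stop codons + a stop codon, 3*(codons+1) nt."""
    if codons < 1:
        raise SimulationError("planted ORF needs at least one codon")
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + _random_nonstop_codons(rng, codons - 1) + stop


def simulate_transcriptome(cfg: SimConfig, out_dir: str | Path) -> SimulatedTranscriptome:
    """Generate FASTA + GTF + truth table under ``out_dir``.

    Transcripts are named ``T0000..``, genes ``G0000..``; each transcript is
    a single-exon plus-strand gene on chromosome ``simchr``. The GTF uses the
    Ensembl dialect (CDS excludes the stop codon; a ``stop_codon`` feature is
    written). Deterministic given ``cfg.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    n_total = cfg.n_genes + cfg.n_noncoding
    seqs: dict[str, list[str]] = {}
    cds_bounds: dict[str, tuple[int, int]] = {}
    for i in range(n_total):
        tid = f"T{i:04d}"
        coding = i < cfg.n_genes
        leader_len = int(rng.integers(cfg.leader_range[0], cfg.leader_range[1] + 1))
        trailer_len = int(rng.integers(cfg.trailer_range[0], cfg.trailer_range[1] + 1))
        if coding:
            lo, hi = (cfg.cds_range[0] // 3), (cfg.cds_range[1] // 3)
            cds_nt = 3 * int(rng.integers(lo, hi + 1))
            cds_seq = "ATG" + _random_nonstop_codons(rng, cds_nt // 3 - 2) + _STOPS[
                rng.integers(0, len(_STOPS))
            ]
            seq = _random_seq(rng, leader_len) + list(cds_seq) + _random_seq(rng, trailer_len)
            cds_bounds[tid] = (leader_len + 1, leader_len + cds_nt)
        else:
            seq = _random_seq(rng, leader_len + cfg.cds_range[0] + trailer_len)
        seqs[tid] = seq

    truth_rows = _plant_truth_orfs(cfg, rng, seqs, cds_bounds)
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "start", "stop", "category", "translated", "multiplier"],
    )

    fasta_path = out_dir / "transcriptome.fa"
    gtf_path = out_dir / "annotation.gtf"
    _write_fasta(fasta_path, seqs)
    _write_gtf(gtf_path, seqs, cds_bounds)
    return SimulatedTranscriptome(
        fasta_path=fasta_path,
        gtf_path=gtf_path,
        truth=truth,
        sequences={t: "".join(s) for t, s in seqs.items()},
        cds_bounds=cds_bounds,
    )


def _plant_truth_orfs(
    cfg: SimConfig,
    rng: np.random.Generator,
    seqs: dict[str, list[str]],
    cds_bounds: dict[str, tuple[int, int]],
) -> list[dict]:
    coding_tids = sorted(cds_bounds)
    noncoding_tids = sorted(set(seqs) - set(cds_bounds))
    rows: list[dict] = []
    used: set[str] = set()
    min_start = cfg.offset_true + 2  # keep 5' ends of start-codon reads on-transcript
    for category, count, multiplier in cfg.truth_orfs:
        if category == "ncRNA_ORF":
            pool = [t for t in noncoding_tids if t not in used]
        else:
            pool = [t for t in coding_tids if t not in used]
        if count > len(pool):
            raise SimulationError(
                f"cannot plant {count} {category} ORFs: only {len(pool)} unused transcripts"
            )
        chosen = [pool[j] for j in rng.choice(len(pool), size=count, replace=False)]
        for tid in sorted(chosen):
            used.add(tid)
            start, stop = _plant_one(cfg, rng, category, seqs[tid], cds_bounds.get(tid), min_start)
            rows.append(
                {
                    "transcript_id": tid,
                    "start": start,
                    "stop": stop,
                    "category": category,
                    "translated": True,
                    "multiplier": multiplier,
                }
            )
    rows.sort(key=lambda r: (r["transcript_id"], r["start"]))
    return rows


def _plant_one(
    cfg: SimConfig,
    rng: np.random.Generator,
    category: str,
    seq: list[str],
    cds: Optional[tuple[int, int]],
    min_start: int,
) -> tuple[int, int]:
    k_lo, k_hi = cfg.orf_codons_range
    if category == "uORF":
        leader_len = cds[0] - 1
        k_max = (leader_len - min_start + 1) // 3 - 1
        if k_max < k_lo:
            raise SimulationError(
                f"leader of {leader_len} nt too short to plant a uORF of >= {k_lo} codons "
                f"starting at or after position {min_start}"
            )
        k = int(rng.integers(k_lo, min(k_hi, k_max) + 1))
        s = int(rng.integers(min_start, leader_len - 3 * (k + 1) + 2))
        seq[s - 1 : s - 1 + 3 * (k + 1)] = list(_plant_orf_seq(rng, k))
        _scrub_upstream_inframe_starts(seq, s)
        return s, s + 3 * (k + 1) - 1
    if category == "dORF":
        ce = cds[1]
        trailer_len = len(seq) - ce
        k_max = (trailer_len - 1) // 3 - 1
        if k_max < k_lo:
            raise SimulationError(f"trailer of {trailer_len} nt too short to plant a dORF")
        k = int(rng.integers(k_lo, min(k_hi, k_max) + 1))
        s = ce + 1 + int(rng.integers(0, trailer_len - 3 * (k + 1) + 1))
        seq[s - 1 : s - 1 + 3 * (k + 1)] = list(_plant_orf_seq(rng, k))
        _scrub_upstream_inframe_starts(seq, s)
        return s, s + 3 * (k + 1) - 1
    if category == "extension":
        cs, ce = cds
        leader_len = cs - 1
        k_max = (leader_len - min_start + 1) // 3
        if k_max < 1:
            raise SimulationError("leader too short to plant an N-terminal extension")
        k = int(rng.integers(1, min(k_hi, k_max) + 1))
        s = cs - 3 * k
        seq[s - 1 : cs - 1] = list("ATG" + _random_nonstop_codons(rng, k - 1))
        _scrub_upstream_inframe_starts(seq, s)
        return s, ce
    if category == "nested":
        cs, ce = cds
        frame_shift = int(rng.integers(1, 3))
        k = int(rng.integers(k_lo, k_hi + 1))
        span = 3 * (k + 1)
        j_max = (ce - 3 - span - (cs + frame_shift)) // 3
        if j_max < 0:
            raise SimulationError("CDS too short to plant a nested ORF")
        for _ in range(500):
            j = int(rng.integers(0, j_max + 1))
            s = cs + frame_shift + 3 * j
            candidate = list(_plant_orf_seq(rng, k))
            backup = seq[s - 1 : s - 1 + span]
            seq[s - 1 : s - 1 + span] = candidate
            if _cds_frame_clean(seq, cs, ce, s - 3, s + span + 2):
                _scrub_upstream_inframe_starts(seq, s)
                return s, s + span - 1
            seq[s - 1 : s - 1 + span] = backup
        raise SimulationError("failed to plant a nested ORF without breaking the CDS frame")
    if category == "ncRNA_ORF":
        k = int(rng.integers(k_lo, k_hi + 1))
        span = 3 * (k + 1)
        if len(seq) < min_start + span:
            raise SimulationError("non-coding transcript too short to plant an ORF")
        s = int(rng.integers(min_start, len(seq) - span + 2))
        seq[s - 1 : s - 1 + span] = list(_plant_orf_seq(rng, k))
        _scrub_upstream_inframe_starts(seq, s)
        return s, s + span - 1
    raise SimulationError(f"unknown truth ORF category {category!r}")


def _cds_frame_clean(seq: list[str], cs: int, ce: int, lo: int, hi: int) -> bool:
    """No premature stop codon in the annotated frame within [lo, hi]."""
    for p in range(cs, ce - 3, 3):
        if p + 2 < lo or p > hi:
            continue
        if "".join(seq[p - 1 : p + 2]) in STOP_CODONS:
            return False
    return True


def _write_fasta(path: Path, seqs: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for tid in sorted(seqs):
            fh.write(f">{tid}\n")
            s = "".join(seqs[tid])
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")


def _write_gtf(path: Path, seqs: dict[str, list[str]], cds_bounds: dict[str, tuple[int, int]]) -> None:
    gap = 100
    gpos = 1
    with open(path, "w") as fh:
        for tid in sorted(seqs):
            gid = "G" + tid[1:]
            length = len(seqs[tid])
            g_start, g_end = gpos, gpos + length - 1
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            biotype = "protein_coding" if tid in cds_bounds else "lncRNA"
            fh.write(
                f'simchr\tsim\tgene\t{g_start}\t{g_end}\t.\t+\t.\tgene_id "{gid}"; gene_biotype "{biotype}";\n'
            )
            fh.write(f"simchr\tsim\ttranscript\t{g_start}\t{g_end}\t.\t+\t.\t{attrs}\n")
            fh.write(f"simchr\tsim\texon\t{g_start}\t{g_end}\t.\t+\t.\t{attrs} exon_number \"1\";\n")
            if tid in cds_bounds:
                cs, ce = cds_bounds[tid]
                # Ensembl dialect: CDS excludes the stop codon
                fh.write(
                    f"simchr\tsim\tCDS\t{g_start + cs - 1}\t{g_start + ce - 4}\t.\t+\t0\t{attrs}\n"
                )
                fh.write(
                    f"simchr\tsim\tstop_codon\t{g_start + ce - 3}\t{g_start + ce - 1}\t.\t+\t0\t{attrs}\n"
                )
            gpos = g_end + gap + 1


# ---------------------------------------------------------------------------
# footprints


def simulate_riboseq(
    sim: SimulatedTranscriptome,
    cfg: SimConfig,
    out_path: str | Path,
) -> Path:
    """Write synthetic ribosome-footprint alignments as SAM.

    For every translated region (annotated CDS with multiplier 1, plus each
    truth ORF with its own multiplier) per-codon A-site counts are drawn
    Poisson(coverage_mean x multiplier), the first codon boosted by
    ``initiation_boost`` to emulate the start-codon peak of real libraries;
    each A-site lands on the codon's
    first nucleotide with probability ``periodicity_p`` and otherwise
    uniformly on one of the other two. The read 5' end is the A-site minus
    ``offset_true``; read lengths are sampled from ``read_length_weights``.
    Untranslated positions receive uniform background A-sites at
    ``background_rate`` per nucleotide. Reads that would run off either
    transcript end are discarded. Deterministic given ``cfg.seed``.
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(cfg.seed + 1)
    lengths = sorted(cfg.read_length_weights)
    weights = np.array([cfg.read_length_weights[l] for l in lengths], dtype=float)
    weights = weights / weights.sum()

    truth_by_tid: dict[str, list[tuple[int, int, float]]] = {}
    for row in sim.truth.itertuples():
        truth_by_tid.setdefault(row.transcript_id, []).append(
            (row.start, row.stop, row.multiplier)
        )

    reads: list[tuple[str, int, int]] = []  # (tid, five_prime_1based, read_length)
    for tid in sorted(sim.sequences):
        seq = sim.sequences[tid]
        length = len(seq)
        regions: list[tuple[int, int, float]] = []
        if tid in sim.cds_bounds:
            cs, ce = sim.cds_bounds[tid]
            regions.append((cs, ce, 1.0))
        regions.extend(truth_by_tid.get(tid, []))

        translated = np.zeros(length + 1, dtype=bool)  # 1-based mask
        for start, stop, mult in regions:
            translated[start : stop + 1] = True
            for p in range(start, stop - 2, 3):  # stop codon itself not occupied
                boost = cfg.initiation_boost if p == start else 1.0
                n = rng.poisson(cfg.coverage_mean * mult * boost)
                for _ in range(n):
                    if rng.random() < cfg.periodicity_p:
                        a = p
                    else:
                        a = p + int(rng.integers(1, 3))
                    _emit_read(reads, rng, tid, a, length, cfg.offset_true, lengths, weights)

        if cfg.background_rate > 0:
            untranslated = np.flatnonzero(~translated[1:]) + 1
            if len(untranslated):
                n_bg = rng.poisson(cfg.background_rate * len(untranslated))
                for idx in rng.integers(0, len(untranslated), size=n_bg):
                    _emit_read(
                        reads, rng, tid, int(untranslated[idx]), length,
                        cfg.offset_true, lengths, weights,
                    )

    _write_sam(out_path, sim.sequences, reads)
    return out_path


def _emit_read(
    reads: list,
    rng: np.random.Generator,
    tid: str,
    a_site: int,
    length: int,
    offset: int,
    lengths: list[int],
    weights: np.ndarray,
) -> None:
    five = a_site - offset
    rl = lengths[int(rng.choice(len(lengths), p=weights))]
    if five >= 1 and five + rl - 1 <= length:
        reads.append((tid, five, rl))


def _write_sam(out_path: Path, sequences: dict[str, str], reads: list[tuple[str, int, int]]) -> None:
    tids = sorted(sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": t, "LN": len(sequences[t])} for t in tids],
    }
    ref_id = {t: i for i, t in enumerate(tids)}
    reads = sorted(reads)
    with pysam.AlignmentFile(str(out_path), "wh", header=header) as fh:
        for i, (tid, five, rl) in enumerate(reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"read{i:07d}"
            a.reference_id = ref_id[tid]
            a.reference_start = five - 1
            a.mapping_quality = 255
            a.cigartuples = [(0, rl)]
            a.query_sequence = sequences[tid][five - 1 : five - 1 + rl]
            a.query_qualities = pysam.qualitystring_to_array("I" * rl)
            a.flag = 0
            fh.write(a)
    return None


# ---------------------------------------------------------------------------
# count matrices


def simulate_counts(
    cfg: SimConfig, gene_ids: Optional[list[str]] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene x sample count matrices for the differential-translation path.

    Counts are negative-binomial around lognormal per-gene means shared by
    every sample; for spiked genes the mean of condition B in the spiked
    assay is multiplied by ``2**log2fc``. Returns (counts, sample sheet,
    spike table). Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    genes = gene_ids if gene_ids is not None else [f"G{i:04d}" for i in range(cfg.n_genes)]
    n = len(genes)
    frac, log2fc, spike_assay = cfg.de_spike
    means = rng.lognormal(mean=cfg.de_mean_log, sigma=1.0, size=n)
    n_spike = int(round(frac * n))
    spike_idx = np.sort(rng.choice(n, size=n_spike, replace=False)) if n_spike else np.array([], dtype=int)

    samples = []
    for assay in ("ribo", "rna"):
        for condition in ("A", "B"):
            for rep in range(1, cfg.n_replicates + 1):
                samples.append(
                    {
                        "sample": f"{assay}_{condition}_{rep}",
                        "assay": assay,
                        "condition": condition,
                        "replicate": rep,
                    }
                )
    sample_sheet = pd.DataFrame(samples)

    r = 1.0 / cfg.de_dispersion
    data = {}
    for row in samples:
        m = means.copy()
        if row["assay"] == spike_assay and row["condition"] == "B" and len(spike_idx):
            m[spike_idx] = m[spike_idx] * (2.0 ** log2fc)
        p = r / (r + m)
        data[row["sample"]] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    spikes = pd.DataFrame(
        {
            "gene_id": [genes[i] for i in spike_idx],
            "log2fc": log2fc,
            "assay": spike_assay,
        },
        columns=["gene_id", "log2fc", "assay"],
    )
    return counts, sample_sheet, spikes


# ---------------------------------------------------------------------------
# peptides


def simulate_peptides(
    sim: SimulatedTranscriptome,
    cfg: SimConfig,
    n_decoys: int = 50,
    peptide_length_range: tuple[int, int] = (8, 12),
) -> pd.DataFrame:
    """Peptide/FDR table: tilings of truth-ORF translations plus random decoys.

    True peptides carry FDR in [0, 0.01]; decoys carry FDR in (0.01, 0.3] so
    the standard 1% filter removes them.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    lo, hi = peptide_length_range
    rows = []
    for row in sim.truth.itertuples():
        seq = sim.sequences[row.transcript_id][row.start - 1 : row.stop - 3]
        protein = str(Seq(seq).translate(table=1))
        i = 0
        while i + lo <= len(protein):
            plen = int(rng.integers(lo, hi + 1))
            pep = protein[i : i + plen]
            if len(pep) >= lo and "*" not in pep:
                rows.append(
                    {
                        "peptide": pep,
                        "fdr": float(rng.uniform(0, 0.01)),
                        "source": f"{row.transcript_id}:{row.start}-{row.stop}",
                    }
                )
            i += plen
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(n_decoys):
        plen = int(rng.integers(lo, hi + 1))
        pep = "".join(aa[rng.integers(0, len(aa), size=plen)])
        rows.append({"peptide": pep, "fdr": float(rng.uniform(0.011, 0.3)), "source": "decoy"})
    return pd.DataFrame(rows, columns=["peptide", "fdr", "source"])


# ---------------------------------------------------------------------------
# one-call convenience


def simulate_all(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full fixture set (FASTA, GTF, SAM, truth, counts, peptides)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_transcriptome(cfg, out_dir)
    sam_path = simulate_riboseq(sim, cfg, out_dir / "riboseq.sam")
    counts, samples, spikes = simulate_counts(cfg)
    peptides = simulate_peptides(sim, cfg)
    paths = {
        "fasta": sim.fasta_path,
        "gtf": sim.gtf_path,
        "sam": sam_path,
        "truth": out_dir / "truth_orfs.tsv",
        "counts": out_dir / "counts.tsv",
        "samples": out_dir / "samples.tsv",
        "spikes": out_dir / "de_spikes.tsv",
        "peptides": out_dir / "peptides.tsv",
    }
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    counts.to_csv(paths["counts"], sep="\t")
    samples.to_csv(paths["samples"], sep="\t", index=False)
    spikes.to_csv(paths["spikes"], sep="\t", index=False)
    peptides.to_csv(paths["peptides"], sep="\t", index=False)
    return paths


__all__ = [
    "SimConfig",
    "SimulatedTranscriptome",
    "SimulationError",
    "simulate_transcriptome",
    "simulate_riboseq",
    "simulate_counts",
    "simulate_peptides",
    "simulate_all",
    "replace",
]
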