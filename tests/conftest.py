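"""Shared fixtures: hand-built toy annotations and one seeded simulation.

Everything is generated at test time; nothing is read from checked-in data.
"""

from __future__ import annotations

import textwrap
from dataclasses import replace

import pandas as pd
import pytest

from riboscope import profiles, simdata
from riboscope.transcriptome import TranscriptRecord, TranscriptomeSet, load_transcriptome

SIM_SEED = 42


def write_fasta(path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)) + "\n")


def write_gtf(path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def gtf_line(chrom, feature, start, end, strand, gene_id, transcript_id, extra=""):
    attrs = f'gene_id "{gene_id}"; transcript_id "{transcript_id}";{extra}'
    return f"{chrom}\tt\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"


def make_record(sequence, cds_start=None, cds_stop=None, transcript_id="tx1", gene_id="g1"):
    """Toy transcript without an exon map (transcript-space-only tests)."""
    return TranscriptRecord(
        transcript_id=transcript_id,
        gene_id=gene_id,
        sequence=sequence,
        cds_start=cds_start,
        cds_stop=cds_stop,
    )


@pytest.fixture(scope="session")
def sim_default(tmp_path_factory):
    """Default study conditions: 100 genes, 20 planted translated uORFs,
    in-frame probability 0.85, 2 A-sites/codon, 5'-end offset 12."""
    out = tmp_path_factory.mktemp("sim_default")
    cfg = simdata.SimConfig(seed=SIM_SEED)
    paths = simdata.simulate_all(cfg, out)
    return cfg, paths


@pytest.fixture(scope="session")
def sim_loaded(sim_default):
    cfg, paths = sim_default
    tset = load_transcriptome(paths["fasta"], paths["gtf"])
    raw = profiles.load_alignments(paths["sam"], tset)
    offsets = profiles.infer_offsets(raw, tset)
    periodicity = profiles.score_periodicity(raw, offsets, tset)
    truth = pd.read_csv(paths["truth"], sep="\t")
    return dict(
        cfg=cfg, paths=paths, tset=tset, raw=raw, offsets=offsets,
        periodicity=periodicity, truth=truth,
    )


@pytest.fixture(scope="session")
def sim_perfect(tmp_path_factory):
    """Noise-free conditions: p=1, no background — periodicity is exactly 1."""
    out = tmp_path_factory.mktemp("sim_perfect")
    cfg = simdata.SimConfig(
        seed=SIM_SEED, n_genes=40, periodicity_p=1.0, background_rate=0.0
    )
    sim = simdata.simulate_transcriptome(cfg, out)
    sam = simdata.simulate_riboseq(sim, cfg, out / "riboseq.sam")
    tset = load_transcriptome(sim.fasta_path, sim.gtf_path)
    raw = profiles.load_alignments(sam, tset)
    return dict(cfg=cfg, sim=sim, tset=tset, raw=raw)


@pytest.fixture(scope="session")
def sim_p08(tmp_path_factory):
    """p=0.8 conditions for score-convergence checks (>= 5000 in-CDS reads)."""
    out = tmp_path_factory.mktemp("sim_p08")
    cfg = simdata.SimConfig(
        seed=SIM_SEED, n_genes=40, periodicity_p=0.8, background_rate=0.0
    )
    sim = simdata.simulate_transcriptome(cfg, out)
    sam = simdata.simulate_riboseq(sim, cfg, out / "riboseq.sam")
    tset = load_transcriptome(sim.fasta_path, sim.gtf_path)
    raw = profiles.load_alignments(sam, tset)
    return dict(cfg=cfg, sim=sim, tset=tset, raw=raw)
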