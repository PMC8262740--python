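# riboscope

Offline, transcript-space analysis of ribosome profiling (Ribo-Seq) and
RNA-Seq data: frame-resolved footprint profiles, rank-based detection of
non-canonically translated ORFs, three-frame proteogenomic peptide mapping,
z-score differential expression/translation, and transcriptome descriptive
statistics — with a synthetic-data generator so the entire stack is testable
without downloading anything.

It is aimed at people who want the computational core of an interactive
Ribo-Seq browser as a scriptable library and CLI: every analysis consumes
plain FASTA/GTF/SAM/TSV and emits TSV/BED/FASTA tables.

## The methods in brief

**Subcodon profiles.** Ribosome-protected fragments aligned to the
transcriptome are reduced to per-read-length counts of 5′-end positions. For
each read length an offset Δ(ℓ) to the ribosomal A-site is inferred as the
argmax of the 5′-end metagene in the window [−24, 0] nt around annotated
start codons (fallback 12 nt). Triplet periodicity per read length is scored
as the majority-frame fraction

  score(ℓ) = max(n₀, n₁, n₂) / (n₀ + n₁ + n₂) ∈ [⅓, 1],

over A-sites strictly inside annotated CDSs (first/last codon excluded,
frames relative to the annotated start). Read lengths below a score
threshold (default 0.55) are discarded; surviving A-sites build
frame-coloured profiles with frame (p − 1) mod 3 anchored to the transcript.

**Translated-ORF detection.** Candidate ORFs (AUG or near-cognate starts,
first in-frame stop, ≥ 5 codons, 5′-most start per stop/frame) are
classified relative to the annotated CDS — uORF, overlapping uORF, nested,
dORF, overlapping dORF, N-terminal extension, or ncRNA ORF — and scored by
three to four features over the region of interest (the ORF minus any part
overlapping the annotated CDS): the density rise across the start codon,
the drop across the stop codon (absent for extensions), the normalised
in-frame excess, and the number of in-frame-dominant codons. Each feature
is ranked 1 = strongest (competition ranking), and the global rank is the
mean of the per-feature ranks. The output is a ranked table — deliberately
no translated/untranslated call.

**Proteogenomics.** Peptide identifications (a `peptide, fdr` TSV from an
upstream search pipeline) are filtered at FDR ≤ 1% and located by exact
match in the translations of *all three* reading frames of each principal
transcript, yielding frame-coded coordinates compatible with the footprint
profiles.

**Differential expression/translation.** For two conditions without
replicates, per-gene log₂ fold changes are standardised against genes of
similar expression: genes are ordered by mean expression and each fold
change is converted to a z-score using the median and normal-consistent MAD
of the fold changes in a 300-gene sliding window. Genes with |z_ribo| ≥ 2
but |z_rna| < 2 are translationally regulated; |z_rna| ≥ 2 is an mRNA-level
change. Count matrices for DESeq2/anota2seq (which need ≥ 2 / ≥ 3
replicates) can be exported.

## Worked example

Generate a synthetic study — 100 transcripts, 20 planted translated uORFs,
in-frame probability 0.85, 2 A-sites/codon, 5′-end→A-site offset 12 nt —
then rank uORF candidates:

```
$ riboscope simulate --seed 7 --out-dir demo
$ riboscope orfdetect --bam demo/riboseq.sam --fasta demo/transcriptome.fa \
      --gtf demo/annotation.gtf --categories uORF --out demo/orfs.tsv
wrote 53 ranked ORFs to demo/orfs.tsv
$ head -3 demo/orfs.tsv
# riboscope v0.1.0 | orfdetect | ... min_codons=5 min_periodicity=0.55 ...
transcript_id  gene_id  category  start  stop  frame  start_codon  length_codons  start_rise  stop_drop  inframe_excess  dominant_codons  ...
T0028          G0028    uORF      40     81    0      ATG          13             12          4.33333    0.85            11               ...
```

53 candidate uORFs were enumerated from the leaders; the top-ranked one
(T0028, 40–81, global rank 3.75) is a planted truth ORF
(`demo/truth_orfs.tsv` lists `T0028  40  81  uORF  True`). `start_rise = 12`
means the first five codons carry 12× the footprint density of the window
just upstream; `inframe_excess = 0.85` means 85% more in-frame than
out-of-frame A-site signal after normalisation; 11 of 13 codons are
in-frame-dominant. Every output file starts with a `# riboscope …` header
recording the full parameter set that produced it.

The other subcommands follow the same pattern: `riboscope profile`
(offset/periodicity/metagene/subcodon tables), `riboscope pepmap`,
`riboscope diffexpr`, `riboscope metainfo summary|codon-usage|regions|windows|sequences|merged-cds`,
and `riboscope validate`.

## Scope notes

Upstream read processing (trimming, rRNA removal, alignment) and the
spectral search that produces peptide/FDR tables are out of scope, as are
replicate-aware DE statistics (use the exported DESeq2/anota2seq inputs)
and RNA secondary-structure tracks (`sliding_composition` documents where
an external RNAfold track would attach). See `docs/methods.md` for model
assumptions, parameter defaults and known limitations.
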