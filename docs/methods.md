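# Methods

This note documents the models and procedures implemented in `riboscope`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Coordinates, frames and the CDS convention

All public coordinates are 1-based inclusive transcript coordinates (the
GTF convention); BAM/SAM 0-based positions are converted at the boundary.
The CDS interval **includes the stop codon**: when the annotation follows
the Ensembl/GENCODE dialect (CDS lines exclude the stop, a `stop_codon`
feature exists) the CDS is extended by 3 nt on loading. A CDS whose length
is not a multiple of 3 after this is demoted to non-coding with a warning
rather than propagating frame errors downstream.

The *frame* of a transcript position p is (p − 1) mod 3, anchored to the
transcript, not to the CDS. This makes frame colours well defined in
leaders, trailers and non-coding RNAs, where there is no CDS to anchor to.
The one place where frames are instead taken relative to the annotated
start codon is the periodicity score (below), which by construction asks
"what fraction of A-sites support the annotated frame" and must therefore
be comparable across transcripts with different leader lengths.

Principal isoforms are chosen per gene by: APPRIS principal tag → longest
CDS → longest transcript → lexicographically smallest ID. The fallback
chain is deterministic and needs no external databases. Sets constructed
programmatically without tags use the same chain, so a principal isoform
always exists.

## A-site offsets

For each read length ℓ, the 5′-end metagene around annotated start codons
is computed over all coding transcripts and the offset is

  Δ(ℓ) = −argmax over lag ∈ [−24, 0] of metagene(lag),

ties resolved toward the smaller |Δ|, with a fallback of 12 nt for read
lengths with an empty metagene. The procedure relies on initiation sites
being locally enriched (the familiar start-codon peak of Ribo-Seq
libraries); on data with perfectly flat coverage the argmax is a tie among
all in-frame lags and the fallback/tie-break takes over. 12 nt is the
canonical 5′-end→P/A-site distance for 28–31-nt footprints.

## Periodicity score and filtering

Per read length, A-sites (5′ end + Δ(ℓ)) strictly inside annotated CDSs —
excluding the first and last codon, so initiation/termination peaks cannot
dominate the tally — are binned by frame relative to the annotated start.
The score is the majority-frame fraction, bounded in [⅓, 1], monotone in
signal, and equal to the simulated in-frame probability in expectation.
Read lengths scoring below `min_score` (default 0.55, i.e. clearly above
the frame-blind ⅓ but permissive enough for moderately periodic libraries)
are removed before any profile is built; a read length with no in-CDS
A-sites has no score and is treated as weak. Filtering is applied per read
length over the whole input.

## ORF candidate features and ranking

Candidates are enumerated per transcript (default starts {ATG}; a
near-cognate set {CTG, GTG, TTG, ACG, ATT, ATC, ATA, AGG, AAG} is available
by flag), extended to the first in-frame stop, with a minimum of 5 codons
and the 5′-most start kept per (stop, frame) — the longest-isoform rule —
unless `all_starts` is set. Codons containing N match neither start nor
stop sets. ORFs identical to the annotated CDS are dropped.

The *region of interest* is the ORF's translated codons; for categories
overlapping the annotated CDS (ouORF, odORF, extension) codons overlapping
the CDS are removed, because inside the CDS the annotated frame dominates
and would mask the candidate's own signal. Features, with A-site count
vectors and pseudocount 1, windows of 5 codons truncated at transcript
bounds:

* `start_rise` = (counts in first 5 region codons + 1) / (counts in the
  5 codons immediately 5′ + 1)
* `stop_drop` = (counts in last 5 region codons + 1) / (counts in the
  5 codons immediately 3′ of the stop + 1); *absent for extensions*, whose
  stop is the annotated stop and is flanked by CDS signal on both sides
* `inframe_excess` = (in-frame − max of the two out-of-frame totals) /
  (region total + 1) ∈ [−1, 1]
* `dominant_codons` = number of region codons whose in-frame count strictly
  exceeds both out-of-frame counts

Ratio/difference forms with a unit pseudocount are scale-robust and return
neutral values (1, 1, 0, 0) on empty profiles. Each feature is ranked
descending (1 = strongest) with competition ranking (ties share the
minimum rank); `stop_drop` is ranked over the rows where it exists. The
global rank is the arithmetic mean of the 3–4 available ranks; output is
sorted by global rank, ties broken by `inframe_excess` descending, then
(transcript, start). Categories are ranked separately by default — mean
ranks over 3 features are not comparable with means over 4 — with a
`joint` option. The method deliberately emits a ranking for manual
inspection, never a translated/untranslated classification, and no
p-values: there is no null model, only relative signal strength.

## Peptide mapping

Peptides are located by exact string matching in the standard-code
translations of all three frames of each principal transcript (stops as
`*`, N-codons as `X`, trailing partial codons dropped). nt coordinates
follow from the residue index: nt_start = 3(aa_start − 1) + frame + 1.
I and L are not collapsed — mapping is exact-sequence; isobaric handling is
a search-engine concern. The FDR filter removes rows with fdr > 1%
(boundary kept). Peptides containing `*` are rejected as input errors.

## Z-score differential expression/translation

Replicates are summed within condition (the z-score path exists precisely
for unreplicated designs); with condition sums A, B per gene:
log₂fc = log₂((B + 1)/(A + 1)). Genes are ordered by mean expression
(A + B)/2 and each fold change is standardised against the `window` = 300
genes centred on it in that ordering (windows shrink at the extremes;
scale 0 ⇒ z = 0). Location and scale are the **median and 1.4826 × MAD**
rather than mean and s.d.: genuinely regulated genes sit in their own
windows and — by moving up the expression ordering — cluster in their
neighbours' windows, where they would inflate a non-robust scale estimate
and mask themselves. Under a pure null the two choices agree (the scaled
MAD is consistent for the s.d.; measured null z s.d. ≈ 0.99–1.07).

Classification at threshold t (default 2): |z_rna| ≥ t ⇒ mRNA-level change
(up/down by sign); else |z_ribo| ≥ t ⇒ translational change; else
unchanged. An mRNA-level change takes precedence because a footprint change
accompanied by an mRNA change is explained at the mRNA level.

DESeq2 and anota2seq are not re-implemented; exporters write their input
count matrices after validating the 2-/3-replicate minima they require.

## Transcriptome metainformation

Codon usage counts in-frame codons of principal CDSs, stop codon included
(it is part of the CDS under the conventions above; `include_stop=False`
excludes it). GC fractions exclude N from numerator and denominator and
are *absent* (NaN), not 0, for empty regions. Group comparisons report
per-metric medians plus a descriptive Mann–Whitney U and p-value — a
boxplot-style comparison, not a corrected test battery. Sliding-window
composition reports window-centre positions and base fractions; the same
windowing is where an externally computed RNA minimum-free-energy track
(e.g. RNAfold) would attach — structure prediction itself is out of scope.

## Synthetic data: what it emulates, and what it does not

The generator produces single-exon, plus-strand 5′leader–CDS–3′trailer
transcripts (leaders/trailers 60–120 nt, CDSs 300–600 nt by default, i.i.d.
uniform base composition) with planted truth ORFs: uORFs in leaders, dORFs
in trailers, off-frame nested ORFs inside CDSs (re-sampled until the
annotated frame stays stop-free), N-terminal extensions sharing the
annotated stop, and ORFs on optional non-coding transcripts. In-frame ATGs
upstream of a planted start (up to the first in-frame stop) are mutated
ATG→ATC so the planted start remains the 5′-most of its (stop, frame);
that mutation can create neither a stop nor a new start in any frame.

Footprints: per-codon A-site counts are Poisson with mean
`coverage_mean` (default 2/codon) times the region multiplier, the first
codon of each translated region boosted ×5 (`initiation_boost`) to emulate
the start-codon peak of real libraries — which is also what makes
metagene-argmax offset inference well-posed; each A-site is in-frame with
probability `periodicity_p` (default 0.85), otherwise uniform over the two
other frames; the 5′ end is A-site − 12 (`offset_true`); read lengths are
drawn from {27..31} with fixed weights; untranslated positions receive
uniform background at 0.05 A-sites/nt — low enough for recovery, non-zero
so ranking has something to rank. Reads that would overhang a transcript
end are dropped.

Count matrices: per-gene lognormal means (ln-mean 5, σ 1; mean counts
≈ 250) with negative-binomial noise at dispersion 0.02 — the *technical*
scale, consistent with the generator's design in which every sample shares
identical per-gene means (a library-vs-library comparison, the z-score
method's use case). At biological-replicate dispersions (≥ 0.1) the
z-score method's recovery of +2 log₂fc spikes at t = 2 drops to ~50–60%;
this is a real limitation of the method, not of the implementation.
Spiked genes multiply the condition-B mean of one assay by 2^log2fc.

Peptide tables tile the translations of planted ORFs into 8–12-mers with
FDR ∈ [0, 0.01] plus random decoys with FDR ∈ (0.01, 0.3].

Not emulated: multi-exon gene structures (projection code is exercised by
hand-built multi-exon fixtures instead), realistic base composition and
codon bias, sequencing errors, multimapping, UMI duplicates, positional
coverage autocorrelation (ramps, pauses) beyond the initiation peak.
Passing recovery tests on these data therefore demonstrates correctness of
the machinery and statistical behaviour under the stated noise model — not
performance on real libraries, where offsets vary with digestion and
periodicity varies along transcripts.

## Problem sizes and determinism

Recovery checks run at 100 transcripts / 20 planted uORFs (ORF detection),
40 transcripts (periodicity/offset; ≳ 10⁴ in-CDS A-sites), 2000 genes
(differential translation). Null z calibration is assessed over all genes
rather than within single 300-gene windows: one window's moment estimates
carry Monte-Carlo error (s.e. ≈ 0.06 on the mean) larger than the
tolerance being checked. All randomness flows from one integer seed
through one generator stream in fixed iteration order; seeded outputs are
byte-reproducible, and every CLI output file carries a header with the
tool version and full parameter set needed to regenerate it.

## Known limitations

* Offset inference assumes a single dominant offset per read length and an
  initiation peak; it does not model per-transcript offset heterogeneity.
* The periodicity filter is global per read length, not per study/sample.
* Feature ranks are relative to the candidate pool: adding or removing
  candidates changes global ranks (competition ranking), so cross-dataset
  rank comparisons are not meaningful.
* `merged_cds` projects genomic CDS intervals position-by-position through
  the query's exon map — exact, but O(locus length); fine for loci, not
  for chromosome-scale unions.
* The z-score classifier inherits the usual caveat of unreplicated
  designs: it measures discordance against expression-matched genes, not
  biological variability.
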