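# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `riboqc`.

## The digestion-completeness model

Ribosome footprinting with an RNase A + T1 cocktail (cuts after C/U and G
respectively, never after A) trims polysome-bound mRNA to the ~28 nt
ribosome-protected core.  When the enzyme concentration in the digestion
reaction is too low — the typical situation when RNase is dosed per unit
RNA in low-input samples — digestion is incomplete, and the recovered
footprints differ in four coupled ways: they are longer, GC-richer,
contaminated by UTR-derived fragments, and less triplet-periodic.  The
simulator makes this explicit with a single sample-level parameter,
`completeness` c ∈ (0, 1], interpreted as the degree to which digestion
has reached the protected core.  It drives:

| phenomenon | model | defaults |
|---|---|---|
| footprint length | unimodal, binomial-shaped pmf (Binomial(10, 0.4) shifted to [mode−4, mode+6]) with mode `length_peak_complete + round(length_shift_max·(1−c))`, truncated to the gel size-selection window and renormalized | peak 28 nt, shift ≤ 5 nt, window 26–34 nt |
| GC selection | candidate fragments accepted with weight `exp(β·(1−c)·(GC−0.5))`, an exponential tilt on fragment GC that vanishes at complete digestion | β = 6 |
| frame fidelity | P-site placed on a codon start with probability `floor + (complete − floor)·c`, otherwise shifted ±1 nt (uniform) | complete = 0.9, floor = ⅓ |
| UTR contamination | a fraction `utr_contamination_max·(1−c)` of molecules drawn from UTRs (5′ vs 3′ proportional to length) | max = 0.3 |
| end chemistry | per-end base weights on the terminal nucleotides; 3′ A strongly disfavoured (no cut after A), 5′ A enriched | 5′ A = 2.0, 3′ A = 0.05 |
| PCR duplication | copy count per unique molecule ~ Geometric(1 − p), so the expected duplicate fraction among emitted reads equals p; each molecule carries a random 8 nt UMI | p = 0 |

The GC tilt is an *acceptance-weight* mechanism: the observed phenomenon
(GC-rich footprints under incomplete digestion) is reproduced without
committing to a molecular mechanism, which is not established.  The
accept/reject loop is stratified by source region so that the tilt
reshapes fragments *within* each region without perturbing the UTR
fraction, which the model pins exactly at `utr_contamination_max·(1−c)`.
Likewise the mechanistic origin of the 5′-A enrichment seen in A+T1
digests is not settled, so it is exposed as a free weight rather than
derived.

The P-site offset for in-frame reads is fixed at 12 nt from the 5′ end
(the common convention for ~28 nt footprints), configurable per length.
Randomness is split into independent streams per purpose (placement,
acceptance, UMIs, duplication, contaminant labels) derived from one seed,
so toggling one bias does not perturb the draws of the others, and
identical parameters yield byte-identical FASTQ and truth outputs.

If two independent molecules collide on the deduplication key
(transcript, start, length, UMI), the truth table marks the later one as
a duplicate of the first: ground truth agrees by construction with what
any UMI-based deduplicator can in principle recover.

### Synthetic transcriptomes

Transcripts are laid out 5′UTR / CDS / 3′UTR with the UTRs at ~12% and
~22% of transcript length (minimums 20 and 30 nt), lengths uniform in
(400, 1500) nt by default, CDS starting with ATG and ending with a stop
codon.  Bases are i.i.d. with P(G) = P(C) = gc/2 per region; defaults are
0.60 for CDS (mammalian coding sequence is GC-rich) and 0.45 for UTRs.
Per-transcript GC targets may be supplied to create the GC heterogeneity
that digestion-driven batch effects act on.  The generator does **not**
model codon usage, ORF integrity (internal stops may occur), splice
isoforms, or abundance-correlated sequence features.

## What passing tests do and do not show

The simulator realizes the digestion-completeness model exactly, so tests
demonstrate that the metrics *recover the model's parameters* — e.g. that
windowed GC and peak length fall monotonically with completeness
(Pearson r ≤ −0.9 against the log-scale concentration axis), or that the
estimated P-site offset matches the generative one.  They do not show
that real digests obey the model quantitatively; in real data the same
metrics are diagnostic signatures, not parameter estimates.  Notably, in
real libraries fully digested footprints can sit near 50% GC even though
coding sequence averages ~60% — a discrepancy with no established
mechanism.  The simulator is neutral at complete digestion (footprint GC
equals source GC), so the canonical "50% GC at 28 nt" endpoint appears
when the source CDS GC is set to 0.50, and the complete-digestion check
is phrased as "no GC shift relative to neutral sampling of the source".

## Metric definitions and numerical choices

- **Composition matrix**: position p (1-based from the 5′ end) uses only
  reads of length ≥ p in its denominator; N bases are excluded and
  counted separately.
- **Windowed GC**: mean of (G+C) fractions per position over a 1-based
  inclusive window, ×100.  Defaults: positions 10–20 for footprints,
  10–65 for mRNA-length reads.  This averages *per-position* fractions
  (matching composition-plot annotation); with equal-length reads
  spanning the window it equals per-read GC averaging exactly, which a
  test asserts.
- **Length peak**: histogram argmax; ties resolve to the smallest length.
- **Region assignment**: by the region containing the P-site (each read
  counted once); a bedtools-style any-overlap mode is available behind a
  flag for comparability with interval-intersection pipelines.
- **P-site offsets** (per read length L): 5′-end density is aggregated
  at positions upstream of annotated start codons; reads with P-sites on
  CDS codons form a period-3 comb whose most upstream occupied tooth
  lies exactly one offset before the start codon.  Candidates span
  [L/4, L/2] (avoiding degenerate maxima).  The estimator picks the
  dominant comb phase (mod 3) by total density, subtracts a smooth
  background estimated from same-phase slots upstream of the window
  (UTR reads have no comb structure), and returns the most upstream
  tooth rising at least halfway from background to the comb peak.  A
  plain argmax is not identifiable under uniform elongation — teeth at
  o and o−3 tie in expectation — whereas the upstream edge is, and the
  two coincide when an initiation peak dominates.  Confidence =
  window peak/mean; lengths below 2 are flagged, and lengths with fewer
  than `min_reads` (default 200) reads inherit the modal offset of the
  passing lengths.  Under heavy UTR contamination with low frame
  fidelity, per-length estimates can still wander by ±3 nt (one codon);
  the confidence flag marks these.
- **Frame preference**: frame = (P-site − CDS start) mod 3, over reads
  with CDS P-sites; reported per length, with the "best" length
  maximizing the frame-0 fraction (ties to the shortest, selection among
  lengths with ≥ `min_reads` reads).  Because the best length is a
  maximum over noisy classes, its frame-0 fraction sits slightly above
  the generative fidelity.
- **Metagene profiles**: per-nucleotide P-site counts → normalization
  (`library_size`: divide by total reads; `cds_mean_density`: divide by
  mean CDS coverage) → mean over replicates → centered moving average.
  An even smoothing window is widened by 1 (default 30 → 31); at the
  edges the window truncates and renormalizes, so totals are conserved
  up to edge effects.
- **Adapter trimming**: 3′-anchored prefix matching, mismatches only (no
  indels), minimum overlap 5, error rate ≤ 0.1; score = matches −
  mismatches, ties to the earliest start (the longest trim — conservative
  against adapter read-through).
- **Demultiplexing**: unique whitelist barcode within Hamming distance
  `max_mismatch` (default 1); the whitelist must have pairwise distance
  > 2·max_mismatch, checked up front.
- **Deduplication**: key = (reference, start, strand, length, UMI) —
  footprints differing at the 3′ end are distinct molecules, the
  conservative reading of UMI-based duplicate marking.  Exact UMI match
  only; no error-tolerant UMI clustering.
- **Trimmed-CDS counting**: unique footprints whose P-site lies in
  [CDS start + trim, CDS end − trim), default trim 30 nt, excluding the
  initiation and termination peaks; one representative transcript per
  gene.
- **Normalization**: median-of-ratios size factors (geometric-mean
  reference over genes nonzero in all samples; total-count fallback with
  a warning), then log2(count/sf + 1).  This is a deliberate, documented
  stand-in for a regularized log transform: absolute values differ, but
  the correlation/PCA structure used for QC is preserved.
- **PCA**: genes centered, not scaled (the R `prcomp` default; scaling
  available behind a flag), samples as observations, top-variance gene
  selection before decomposition; variance fractions are reported against
  the total variance of the selected matrix.
- **Hypergeometric overlap**: upper tail P(X ≥ k) accumulated in log
  space (log-sum-exp over the log pmf), with the universe an explicit
  argument — no default universe is assumed.  `log_p_value` stays finite
  when the p-value underflows.

## Batch × genotype expression designs

`simulate_expression_design` builds a 2-batch × 2-genotype, 2-replicate
experiment (8 samples × 30,000 reads over 300 genes by default) in which
batch enters *only* through digestion completeness and genotype through
fold changes on a random gene subset.  Gene-level GC targets are spread
uniformly over [0.45, 0.70] so the GC tilt has per-gene leverage.  The
default batch-dominant condition uses completeness (1.0, 0.5) with a
1.3-fold genotype effect on 10% of genes; the genotype-dominant reverse
uses completeness (1.0, 0.95) with a 2.5-fold effect on 30% of genes.
These magnitudes were chosen as realistic strengths of the two effects;
the qualitative claim under test is that PC1 membership flips as the
simulated batch effect crosses the genotype effect, measured by PC1
silhouette scores.

## Problem sizes

Simulation-backed checks use 20,000 reads per sample for the
completeness grid and frame/P-site recovery, 10,000 for duplicate
accounting, 1,000 for the library round trip, and the 8 × 30,000-read
design above for expression QC — sizes at which the stochastic metrics
are stable to well within the asserted margins while the whole suite
stays fast.

## Scope and limitations

- Transcript-coordinate simulation only: no introns/junctions, no
  genome-space alignment, no spliced-read resolution.
- No sequencing-error model (constant Q37 qualities by default); adapter
  trimming is indel-free; no paired-end support.
- rRNA/tRNA contaminants are consumed as pre-assigned labels (or a flat
  labeled fraction in the simulator); the toolkit does not realign.
- Monosome disassembly at high RNase concentrations is an
  operator-supplied flag per titration step — it is judged from sucrose
  gradient profiles, and no sequence-based proxy is defined.
- No differential-expression inference, batch *correction*, GO
  enrichment, or footprint-classification scores: this toolkit diagnoses
  technical quality upstream of those analyses.
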