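# riboqc

Quality control for ribosome profiling (ribo-seq) libraries, focused on a
failure mode that standard pipelines miss: **incomplete RNase digestion**.

In ribosome profiling, RNase trims mRNA down to the ~28 nt fragment
protected by the 80S ribosome (the ribosome-protected footprint, RPF).
When the enzyme-to-RNA ratio is too low — typically in low-input samples
where RNase is dosed per unit of RNA — digestion stalls before reaching the
protected core.  The resulting footprints are systematically **longer**,
**GC-richer**, more **UTR-contaminated** and less **triplet-periodic** than
properly digested ones, and because the severity varies between processing
batches, incomplete digestion masquerades as a batch effect that can
dominate the biological signal in downstream expression analysis.

`riboqc` provides:

- **footprint QC metrics** — per-position nucleotide composition, mean GC
  over a positional window (default positions 10–20), footprint length
  distribution and peak, 5′UTR/CDS/3′UTR assignment, P-site offset
  estimation, reading-frame preference, and smoothed metagene coverage;
- **read preparation** — demultiplexing by 5 nt sample barcode, 3′-anchored
  adapter trimming, 8 nt UMI extraction;
- **alignment accounting** — UMI-based PCR-duplicate marking and
  unique/multimapped/unmapped/duplicate/contaminant category summaries;
- **titration analysis** — geometric RNase escalation plans, Pearson
  correlation of GC and peak length against the log-scale concentration
  axis, and an optimal-condition recommendation;
- **expression QC** — trimmed-CDS counting, low-count filtering,
  median-of-ratios normalization with a log2 transform, pairwise sample
  correlation, PCA on the most variable genes, and a log-space
  hypergeometric gene-set overlap test;
- **a ground-truth simulator** — synthetic transcriptomes and footprints
  generated under an explicit digestion-completeness model, so every metric
  is testable without external data.

## The digestion-completeness model

The simulator couples all observable symptoms to one scalar,
`completeness` c ∈ (0, 1]:

- modal footprint length: `28 + round(5·(1−c))` nt, binomial-shaped
  distribution truncated to the 26–34 nt gel window;
- GC selection: candidate fragments accepted with weight
  `exp(β·(1−c)·(GC−0.5))` (default β = 6);
- in-frame P-site probability: `⅓ + (0.9 − ⅓)·c`, P-site 12 nt from the
  5′ end, out-of-frame reads shifted ±1 nt;
- UTR read fraction: `0.3·(1−c)`;
- end chemistry of an RNase A+T1 digest: the 3′-terminal base avoids A
  (the cocktail cuts after C/U and G, never after A) and the 5′ end is
  A-enriched;
- PCR duplication with geometric copy counts over random 8 nt UMIs.

## Worked example

`examples/01_titration_planning.py` plans the default 5-fold RNase A+T1
escalation, simulates a footprint sample per step (mapping step k to
completeness 0.2·k over a ~50%-GC coding transcriptome), and picks the
optimal condition:

```
 step  rnaseA_ng_per_ug  rnaseT1_U_per_ug  rnaseA_ng_total  rnaseT1_U_total
    1               4.8               0.6              9.6              1.2
    2              24.0               3.0             48.0              6.0
    3             120.0              15.0            240.0             30.0
    4             600.0              75.0           1200.0            150.0
    5            3000.0             375.0           6000.0            750.0
step 1: GC 53.9%  peak 32 nt
step 2: GC 53.0%  peak 31 nt
step 3: GC 52.1%  peak 30 nt
step 4: GC 51.0%  peak 29 nt
step 5: GC 49.9%  peak 28 nt

Pearson r vs log5(concentration): GC -0.999, length -1.000
recommended: step 4: GC 51.0% within +/-2.0 of 50.0%, peak length 29 nt in [28, 29], monosomes intact
```

Both QC metrics fall strictly with enzyme concentration (r ≈ −1): the
milder steps are under-digested.  Step 5 reaches the canonical 28 nt/50%
endpoint but its monosomes were flagged as disassembled, so the mildest
fully qualifying condition, step 4, is recommended.

The other examples cover single-sample QC (`02`), the FASTQ round trip
through barcode/UMI/adapter handling (`03`), and digestion-driven batch
effects in expression PCA (`04`).  Each prints a short, explained summary.

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
riboqc simulate --config sim.yaml --out-dir sim/ --seed 1
riboqc prep     --fastq sim/AATCG.fastq --barcodes AATCG,GGCTA --out-dir prep/
riboqc dedup    --in aligned.tsv --out dedup.tsv
riboqc qc       --footprints sim/AATCG.truth.tsv --format truth --fasta sim/transcriptome.fa
riboqc titrate  --design design.yaml
riboqc expr     --counts counts.tsv --top 1000
```

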