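"""Emit a simulated library FASTQ and recover inserts through read prep.

Each library read is [5 nt barcode][8 nt UMI][insert][3' adapter]; the
prep pipeline demultiplexes, trims the adapter and moves the UMI into
read metadata, recovering the exact footprint inserts.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from riboqc import (
    DigestionParams,
    emit_fastq,
    generate_transcriptome,
    prep_pipeline,
    simulate_footprints,
)
from riboqc.read_prep import read_fastq

transcripts = generate_transcriptome(50, seed=3)
params = DigestionParams(completeness=0.7, seed=7)
reads, truth = simulate_footprints(transcripts, params, 1_000, barcode="AATCG")

with TemporaryDirectory() as tmp:
    fq = Path(tmp) / "library.fastq"
    emit_fastq(reads, fq, umis=[t.umi for t in truth], barcode="AATCG")
    per_sample, stats = prep_pipeline(list(read_fastq(fq)), ["AATCG", "GGCTA"])

print("prep stats:", stats)
recovered = {r.id: r for r in per_sample["AATCG"]}
exact = sum(
    (recovered[r.id].umi, recovered[r.id].sequence) == (t.umi, r.sequence)
    for r, t in zip(reads, truth)
)
print(f"inserts + UMIs recovered exactly: {exact}/{len(reads)}")
# 100% recovery on error-free reads: demultiplexing, adapter trimming
# and UMI extraction are exact inverses of the library layout.
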