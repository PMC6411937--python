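"""Ground-truth ribosome footprint simulator.

The simulator embodies an explicit model of RNase digestion
completeness, the variable this toolkit's QC metrics are designed to
diagnose.  A single scalar ``completeness`` in (0, 1] drives four
coupled phenomena observed when footprinting is incomplete:

* **longer footprints** — the modal length rises from the canonical
  ~28 nt by up to ``length_shift_max`` nt as completeness falls;
* **GC-rich footprints** — candidate fragments are accepted with weight
  ``exp(gc_bias_strength * (1 - completeness) * (GC - 0.5))``, an
  exponential tilt that vanishes at complete digestion;
* **degraded reading-frame periodicity** — the P-site is placed in
  frame with probability interpolating between ``frame_fidelity_floor``
  and ``frame_fidelity_complete``;
* **UTR contamination** — a fraction ``utr_contamination_max *
  (1 - completeness)`` of footprints is drawn from UTRs instead of the
  CDS.

End chemistry of an RNase A + T1 digest is modelled as base weights on
the terminal nucleotides: the cocktail cuts after C/U (RNase A) and G
(RNase T1) but never after A, so the 3' terminal base avoids A, while
the 5' end is empirically A-enriched (exposed as a free weight).

Each unique footprint molecule receives a random 8 nt UMI and is then
PCR-amplified with a geometric copy count, producing the duplicate
structure that UMI deduplication must undo.  Ground truth for every
emitted read is returned alongside the reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .read_prep import DEFAULT_ADAPTER, RawRead, ReadLayout, default_layout
from .transcripts import TranscriptModel, generate_transcriptome

__all__ = [
    "DigestionParams",
    "SimTruth",
    "TRUTH_COLUMNS",
    "simulate_footprints",
    "emit_fastq",
    "truth_to_frame",
    "write_truth",
    "read_truth",
    "simulate_expression_design",
    "ExpressionDesign",
]

#: columns of the truth table TSV emitted next to simulated FASTQ
TRUTH_COLUMNS = (
    "read_id",
    "barcode",
    "transcript",
    "start",
    "length",
    "psite",
    "frame",
    "region",
    "umi",
    "duplicate_of",
    "category",
)


@dataclass(frozen=True)
class DigestionParams:
    """Parameters of the digestion-completeness model for one sample.

    completeness : (0, 1], 1 = complete digestion.
    length_peak_complete : modal footprint length at complete digestion (nt).
    length_shift_max : maximal modal-length shift at completeness -> 0 (nt).
    gc_bias_strength : exponent of the GC acceptance tilt (0 disables).
    frame_fidelity_complete / frame_fidelity_floor : probability that the
        P-site lands in frame at completeness 1 / in the completeness -> 0
        limit (floor <= complete).
    utr_contamination_max : UTR read fraction in the completeness -> 0 limit.
    end_bias : per-end base weights, ``{"five_prime": {...}, "three_prime":
        {...}}``; unlisted bases weigh 1.  The default encodes an A+T1
        digest: 3' terminal A strongly disfavoured, 5' A enriched.
    pcr_dup_rate : geometric PCR duplication rate in [0, 1); the expected
        duplicate fraction among emitted reads equals this rate.
    length_window : inclusive gel size-selection window (nt).
    psite_offset : distance from the footprint 5' end to the P-site for
        in-frame reads — an int for all lengths or a length -> offset map.
    """

    completeness: float = 1.0
    length_peak_complete: int = 28
    length_shift_max: int = 5
    gc_bias_strength: float = 6.0
    frame_fidelity_complete: float = 0.9
    frame_fidelity_floor: float = 1.0 / 3.0
    utr_contamination_max: float = 0.3
    end_bias: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"five_prime": {"A": 2.0}, "three_prime": {"A": 0.05}}
    )
    pcr_dup_rate: float = 0.0
    length_window: tuple[int, int] = (26, 34)
    psite_offset: int | Mapping[int, int] = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must be in (0, 1]")
        if self.gc_bias_strength < 0:
            raise ValueError("gc_bias_strength must be >= 0")
        for name in ("frame_fidelity_complete", "frame_fidelity_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frame_fidelity_floor > self.frame_fidelity_complete:
            raise ValueError("frame_fidelity_floor must be <= frame_fidelity_complete")
        if not 0.0 <= self.utr_contamination_max < 1.0:
            raise ValueError("utr_contamination_max must be in [0, 1)")
        if not 0.0 <= self.pcr_dup_rate < 1.0:
            raise ValueError("pcr_dup_rate must be in [0, 1)")
        if self.length_shift_max < 0 or self.length_peak_complete <= 0:
            raise ValueError("length parameters must be positive")

    def offset_for(self, length: int) -> int:
        if isinstance(self.psite_offset, Mapping):
            return int(self.psite_offset.get(length, 12))
        return int(self.psite_offset)

    @property
    def modal_length(self) -> int:
        return self.length_peak_complete + round(self.length_shift_max * (1 - self.completeness))

    @property
    def frame_fidelity(self) -> float:
        return self.frame_fidelity_floor + (
            self.frame_fidelity_complete - self.frame_fidelity_floor
        ) * self.completeness

    @property
    def utr_fraction(self) -> float:
        return self.utr_contamination_max * (1 - self.completeness)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one emitted read."""

    read_id: str
    barcode: str
    transcript: str
    start: int
    length: int
    psite: int
    frame: int
    region: str
    umi: str
    duplicate_of: str | None
    category: str = "unique"


def _length_pmf(params: DigestionParams) -> tuple[np.ndarray, np.ndarray]:
    """Binomial-shaped unimodal pmf over [mode-4, mode+6], truncated to the
    gel size-selection window and renormalized."""
    mode = params.modal_length
    support = np.arange(mode - 4, mode + 7)
    pmf = stats.binom.pmf(support - (mode - 4), 10, 0.4)  # Binomial(10, 0.4) has mode 4
    lo, hi = params.length_window
    keep = (support >= lo) & (support <= hi)
    support, pmf = support[keep], pmf[keep]
    if support.size == 0 or pmf.sum() <= 0:
        raise ValueError(
            f"modal length {mode} is incompatible with size-selection window {params.length_window}"
        )
    return support, pmf / pmf.sum()


class _TranscriptomeIndex:
    """Concatenated numeric view of a transcriptome for vectorized sampling."""

    _CODE = {b: i for i, b in enumerate("ACGT")}

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        if not transcripts:
            raise ValueError("transcript list is empty")
        self.transcripts = list(transcripts)
        self.ids = [t.id for t in transcripts]
        self.length = np.array([t.length for t in transcripts])
        self.utr5_end = np.array([t.utr5_end for t in transcripts])
        self.cds_end = np.array([t.cds_end for t in transcripts])
        self.offset = np.concatenate([[0], np.cumsum(self.length)[:-1]])
        codes = np.frombuffer(
            "".join(t.sequence for t in transcripts).encode(), dtype=np.uint8
        )
        lut = np.zeros(256, dtype=np.int8)
        for b, i in self._CODE.items():
            lut[ord(b)] = i
        self.codes = lut[codes]
        self.cum_gc = np.concatenate([[0], np.cumsum((self.codes == 1) | (self.codes == 2))])

    def gc(self, tx_idx: np.ndarray, start: np.ndarray, length: np.ndarray) -> np.ndarray:
        g0 = self.offset[tx_idx] + start
        return (self.cum_gc[g0 + length] - self.cum_gc[g0]) / length

    def base(self, tx_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        return self.codes[self.offset[tx_idx] + pos]

    def slice(self, tx_idx: int, start: int, length: int) -> str:
        return self.transcripts[tx_idx].sequence[start : start + length]


def _base_weights(bias: Mapping[str, float] | None) -> np.ndarray:
    w = np.ones(4)
    for b, v in (bias or {}).items():
        w["ACGT".index(b)] = float(v)
    return w


def _propose(
    idx: _TranscriptomeIndex,
    params: DigestionParams,
    n: int,
    tx_p: np.ndarray,
    from_utr: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, ...]:
    """Propose n candidate footprints of one stratum (CDS or UTR):
    (transcript, start, length, psite).  Invalid placements are dropped."""
    support, pmf = _length_pmf(params)
    tx = rng.choice(len(idx.ids), size=n, p=tx_p)
    length = support[rng.choice(support.size, size=n, p=pmf)]
    offset = np.array([params.offset_for(L) for L in length])
    utr5, cds_end, tlen = idx.utr5_end[tx], idx.cds_end[tx], idx.length[tx]

    if from_utr:
        # uniform over UTR positions keeping the footprint inside the transcript;
        # 5' vs 3' UTR chosen proportionally to their lengths
        pick5 = rng.random(n) * (utr5 + (tlen - cds_end)) < utr5
        lo = np.where(pick5, offset, cds_end)
        hi = np.where(pick5, utr5 - 1, np.minimum(tlen - 1, tlen - length + offset))
        valid = hi >= lo
        psite = lo + (rng.random(n) * np.maximum(hi - lo + 1, 1)).astype(np.int64)
    else:
        # P-site on a codon start p = utr5 + 3k; out-of-frame reads shift +-1
        in_frame = rng.random(n) < params.frame_fidelity
        k_lo = np.ceil(np.maximum(offset - utr5, 0) / 3).astype(np.int64)
        k_hi = np.minimum((cds_end - 3 - utr5) // 3, (tlen - length + offset - utr5) // 3)
        valid = k_hi >= k_lo
        k = k_lo + (rng.random(n) * np.maximum(k_hi - k_lo + 1, 1)).astype(np.int64)
        psite = utr5 + 3 * k
        shift = np.where(rng.random(n) < 0.5, -1, 1)
        psite = np.where(in_frame, psite, psite + shift)

    start = psite - offset
    valid &= (start >= 0) & (start + length <= tlen)
    return tx[valid], start[valid], length[valid], psite[valid]


def simulate_footprints(
    transcripts: Sequence[TranscriptModel],
    params: DigestionParams,
    n_reads: int,
    abundance_model: Sequence[float] | None = None,
    barcode: str = "AATCG",
    contaminant_fractions: Mapping[str, float] | None = None,
) -> tuple[list[RawRead], list[SimTruth]]:
    """Simulate ``n_reads`` unique footprint molecules plus PCR duplicates.

    Returns ``(reads, truth)``: raw reads carrying only the insert
    sequence (assemble the full library read with :func:`emit_fastq`),
    and one :class:`SimTruth` per emitted read.  ``abundance_model``
    gives unnormalized per-transcript sampling weights (uniform when
    omitted).  ``contaminant_fractions`` relabels a flat fraction of
    molecules, e.g. ``{"contaminant_rRNA": 0.05}``, to exercise
    mapping-category accounting.

    Randomness derives from ``params.seed`` through independent streams
    per purpose (placement, acceptance, UMIs, duplication), so toggling
    one bias does not perturb the others.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    idx = _TranscriptomeIndex(transcripts)
    if abundance_model is None:
        tx_p = np.full(len(idx.ids), 1.0 / len(idx.ids))
    else:
        tx_p = np.asarray(abundance_model, dtype=float)
        if tx_p.size != len(idx.ids) or (tx_p < 0).any() or tx_p.sum() <= 0:
            raise ValueError("abundance_model must be non-negative weights, one per transcript")
        tx_p = tx_p / tx_p.sum()

    ss = np.random.SeedSequence(params.seed)
    rng_place, rng_accept, rng_umi, rng_dup, rng_contam = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    tilt = params.gc_bias_strength * (1 - params.completeness)
    w5 = _base_weights(params.end_bias.get("five_prime"))
    w3 = _base_weights(params.end_bias.get("three_prime"))
    w_max = float(np.exp(tilt * 0.5) * w5.max() * w3.max())

    # Stratify the accept/reject loop by source region so the GC tilt
    # reshapes footprints *within* each region without perturbing the
    # UTR read fraction, which the model pins at utr_fraction exactly.
    n_utr = int(rng_place.binomial(n_reads, params.utr_fraction))
    parts: dict[bool, dict[str, np.ndarray]] = {}
    for from_utr, target in ((False, n_reads - n_utr), (True, n_utr)):
        cols: dict[str, list[np.ndarray]] = {k: [] for k in ("tx", "start", "length", "psite")}
        accepted = 0
        while accepted < target:
            m = max(4 * (target - accepted), 1000)
            tx, start, length, psite = _propose(idx, params, m, tx_p, from_utr, rng_place)
            if tx.size == 0:
                continue
            w = np.exp(tilt * (idx.gc(tx, start, length) - 0.5))
            w = w * w5[idx.base(tx, start)] * w3[idx.base(tx, start + length - 1)]
            keep = rng_accept.random(tx.size) * w_max < w
            for name, arr in zip(cols, (tx, start, length, psite)):
                cols[name].append(arr[keep])
            accepted += int(keep.sum())
        parts[from_utr] = {
            k: np.concatenate(v)[:target] if target else np.empty(0, dtype=np.int64)
            for k, v in cols.items()
        }

    tx = np.concatenate([parts[False]["tx"], parts[True]["tx"]])
    start = np.concatenate([parts[False]["start"], parts[True]["start"]])
    length = np.concatenate([parts[False]["length"], parts[True]["length"]])
    psite = np.concatenate([parts[False]["psite"], parts[True]["psite"]])
    # interleave strata deterministically so read order is not region-blocked
    order = rng_place.permutation(n_reads)
    tx, start, length, psite = tx[order], start[order], length[order], psite[order]
    region_code = np.where(psite < idx.utr5_end[tx], 1, np.where(psite < idx.cds_end[tx], 0, 2))

    umis = np.array(list("ACGT"))[rng_umi.integers(0, 4, size=(n_reads, 8))]
    copies = (
        rng_dup.geometric(1 - params.pcr_dup_rate, size=n_reads)
        if params.pcr_dup_rate > 0
        else np.ones(n_reads, dtype=np.int64)
    )
    category = np.full(n_reads, "unique", dtype=object)
    if contaminant_fractions:
        u = rng_contam.random(n_reads)
        edge = 0.0
        for label, frac in contaminant_fractions.items():
            category[(u >= edge) & (u < edge + frac)] = label
            edge += frac
        if edge >= 1:
            raise ValueError("contaminant fractions must sum to < 1")

    region_label = np.array(["cds", "utr5", "utr3"])
    reads: list[RawRead] = []
    truth: list[SimTruth] = []
    first_seen: dict[tuple, str] = {}
    emitted = 0
    for i in range(n_reads):
        umi = "".join(umis[i])
        insert = idx.slice(int(tx[i]), int(start[i]), int(length[i]))
        key = (idx.ids[tx[i]], int(start[i]), int(length[i]), umi)
        for _ in range(int(copies[i])):
            rid = f"{barcode}_r{emitted:07d}"
            emitted += 1
            dup_of = first_seen.get(key)
            if dup_of is None:
                first_seen[key] = rid
            reads.append(RawRead(id=rid, sequence=insert, qualities="F" * len(insert)))
            truth.append(
                SimTruth(
                    read_id=rid,
                    barcode=barcode,
                    transcript=idx.ids[tx[i]],
                    start=int(start[i]),
                    length=int(length[i]),
                    psite=int(psite[i]),
                    frame=int((psite[i] - idx.utr5_end[tx[i]]) % 3),
                    region=str(region_label[region_code[i]]),
                    umi=umi,
                    duplicate_of=dup_of,
                    category=str(category[i]),
                )
            )
    return reads, truth


def emit_fastq(
    reads: Sequence[RawRead],
    path: str | Path,
    layout: ReadLayout | None = None,
    adapter: str = DEFAULT_ADAPTER,
    barcode: str = "AATCG",
    umis: Sequence[str] | None = None,
    read_length: int | None = None,
    quality_char: str = "F",
    seed: int = 0,
) -> None:
    """Assemble library-layout reads and write a 4-line Phred+33 FASTQ.

    Each record is the layout-order concatenation of barcode, UMI,
    insert and adapter.  UMIs default to fresh random 8-mers unless
    provided (pass the truth UMIs for a consistent simulated library).
    With a ``read_length`` budget the adapter — never the insert — is
    truncated to fit.  Qualities are constant (Q37 by default).
    """
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    umi_w = layout.width("umi")
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            if umis is not None:
                umi = umis[i]
            elif read.umi is not None:
                umi = read.umi
            else:
                umi = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=umi_w)])
            if len(umi) != umi_w:
                raise ValueError(f"{read.id}: UMI {umi!r} does not match layout width {umi_w}")
            parts = []
            for name, _ in layout.segments:
                if name == "barcode":
                    parts.append(barcode)
                elif name == "umi":
                    parts.append(umi)
                elif name == "insert":
                    parts.append(read.sequence)
                elif name == "adapter":
                    parts.append(adapter)
            seq = "".join(parts)
            if read_length is not None:
                fixed = sum(len(p) for p in parts[:-1])  # everything but the adapter
                if fixed > read_length:
                    raise ValueError(
                        f"{read.id}: fixed segments ({fixed} nt) exceed read length {read_length}"
                    )
                seq = seq[:read_length]
            fh.write(f"@{read.id}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ---------------------------------------------------------------------------
# Truth table I/O

def truth_to_frame(truth: Sequence[SimTruth]) -> pd.DataFrame:
    df = pd.DataFrame([t.__dict__ for t in truth], columns=list(TRUTH_COLUMNS))
    df["duplicate_of"] = df["duplicate_of"].fillna("")
    return df


def write_truth(truth: Sequence[SimTruth], path: str | Path) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[SimTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"duplicate_of": str})
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns {sorted(missing)}")
    return [
        SimTruth(
            read_id=str(r.read_id),
            barcode=str(r.barcode),
            transcript=str(r.transcript),
            start=int(r.start),
            length=int(r.length),
            psite=int(r.psite),
            frame=int(r.frame),
            region=str(r.region),
            umi=str(r.umi),
            duplicate_of=str(r.duplicate_of) or None,
            category=str(r.category),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Multi-sample expression designs (batch x genotype)

@dataclass
class ExpressionDesign:
    """A simulated multi-sample footprint experiment.

    counts : genes x samples CDS count matrix (representative transcript
        per gene, P-site counting on deduplicated unique reads).
    metadata : per-sample batch and genotype labels.
    de_genes : transcript ids carrying a genotype effect.
    transcripts : the underlying transcriptome.
    truth : per-sample ground-truth read records.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    de_genes: list[str]
    transcripts: list[TranscriptModel]
    truth: dict[str, list[SimTruth]]


def simulate_expression_design(
    n_genes: int = 300,
    n_reads: int = 30_000,
    reps: int = 2,
    batch_completeness: tuple[float, float] = (1.0, 0.5),
    genotype_fold: float = 1.3,
    frac_de: float = 0.1,
    cds_trim: int = 30,
    seed: int = 0,
) -> ExpressionDesign:
    """Simulate a 2-batch x 2-genotype footprint experiment.

    Batch effects enter through digestion completeness (per-batch values
    in ``batch_completeness``): incomplete digestion tilts footprint
    recovery toward GC-rich transcripts, which perturbs the whole count
    profile.  Genotype (WT vs KO) enters as a ``genotype_fold`` change
    on a random ``frac_de`` of genes (alternating up/down in KO).
    Transcript GC targets are spread uniformly over [0.45, 0.70] so the
    GC tilt has per-gene leverage, emulating natural GC heterogeneity.

    Counting uses each gene's single transcript with the first and last
    ``cds_trim`` nt of the CDS excluded.
    """
    from .expression import count_cds  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    gc = rng.uniform(0.45, 0.70, size=n_genes)
    transcripts = generate_transcriptome(
        n_genes, cds_gc_target=gc, length_range=(500, 1500), seed=int(rng.integers(2**31))
    )
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    n_de = max(1, round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    ko = base.copy()
    ko[de_idx[::2]] *= genotype_fold
    ko[de_idx[1::2]] /= genotype_fold

    samples: dict[str, list] = {}
    truth: dict[str, list[SimTruth]] = {}
    meta = []
    for b, completeness in enumerate(batch_completeness, start=1):
        for genotype, abund in (("WT", base), ("KO", ko)):
            for r in range(1, reps + 1):
                name = f"b{b}_{genotype}{r}"
                params = DigestionParams(
                    completeness=completeness, seed=int(rng.integers(2**31))
                )
                _, t = simulate_footprints(
                    transcripts, params, n_reads, abundance_model=abund, barcode="AAAAA"
                )
                truth[name] = t
                meta.append({"sample": name, "batch": f"batch{b}", "genotype": genotype})

    from .align import footprints_from_truth, mark_duplicates

    per_sample = {
        name: [f for f in mark_duplicates(footprints_from_truth(t)) if f.category == "unique"]
        for name, t in truth.items()
    }
    counts = count_cds(per_sample, transcripts, trim=cds_trim)
    return ExpressionDesign(
        counts=counts,
        metadata=pd.DataFrame(meta).set_index("sample"),
        de_genes=[transcripts[i].id for i in sorted(de_idx)],
        transcripts=transcripts,
        truth=truth,
    )
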