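"""Digestion-diagnostic QC metrics for ribosome footprints.

The metrics here are the readouts that distinguish complete from
incomplete RNase digestion without any wet-lab information:

* per-position nucleotide composition of footprints (5'-anchored);
* mean GC content within a positional window (default positions 10-20
  for footprints, 10-65 for mRNA-length reads) — incomplete digestion
  leaves GC-rich footprints;
* the footprint length distribution and its peak — complete digestion
  trims to ~28 nt;
* 5'UTR / CDS / 3'UTR assignment fractions — incomplete digestion
  leaks footprints into UTRs;
* P-site offsets per read length and reading-frame preference —
  genuine elongating footprints are triplet-periodic;
* normalized, smoothed metagene coverage along a transcript.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import Footprint
from .transcripts import TranscriptModel

__all__ = [
    "CompositionMatrix",
    "QCReport",
    "nucleotide_composition",
    "windowed_gc",
    "length_histogram",
    "length_peak",
    "assign_regions",
    "estimate_psite_offsets",
    "frame_preference",
    "FrameResult",
    "metagene_profile",
    "smooth_profile",
    "compute_qc_report",
    "psite_of",
]

_BASES = "ACGT"


def psite_of(footprint: Footprint, offsets: int | Mapping[int, int] = 12) -> int:
    """P-site transcript position of a footprint: 5' end + per-length offset."""
    if isinstance(offsets, Mapping):
        off = offsets.get(footprint.length, 12)
    else:
        off = offsets
    return footprint.start + int(off)


@dataclass(frozen=True)
class CompositionMatrix:
    """Per-position base fractions among reads covering each position.

    ``fractions`` is positions (1-based from the 5' end) x {A, C, G, T};
    position p is computed over reads of length >= p.  N bases are
    excluded from denominators and tracked in ``n_count``.
    """

    fractions: pd.DataFrame
    coverage: pd.Series  # reads with length >= position (non-N)
    n_count: int

    @property
    def max_position(self) -> int:
        return int(self.fractions.index.max())


def nucleotide_composition(
    footprints: Iterable[Footprint], max_position: int | None = None
) -> CompositionMatrix:
    """Base composition at each 5'-anchored position of the footprints."""
    seqs = []
    for f in footprints:
        if f.sequence is None:
            raise ValueError(f"{f.read_id}: footprint has no sequence")
        seqs.append(f.sequence.upper())
    if not seqs:
        raise ValueError("no footprints given")
    longest = max(len(s) for s in seqs)
    P = min(longest, max_position) if max_position else longest
    counts = np.zeros((P, 4), dtype=np.int64)
    n_count = 0
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    for s in seqs:
        codes = lut[np.frombuffer(s[:P].encode(), dtype=np.uint8)]
        valid = codes >= 0
        n_count += int((~valid).sum())
        pos = np.nonzero(valid)[0]
        np.add.at(counts, (pos, codes[pos]), 1)
    coverage = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / coverage[:, None]
    index = pd.RangeIndex(1, P + 1, name="position")
    return CompositionMatrix(
        fractions=pd.DataFrame(frac, index=index, columns=list(_BASES)),
        coverage=pd.Series(coverage, index=index, name="coverage"),
        n_count=n_count,
    )


def windowed_gc(composition: CompositionMatrix, window: tuple[int, int] = (10, 20)) -> float:
    """Mean GC percentage over a 1-based inclusive positional window.

    Averages (G fraction + C fraction) per position across the window,
    matching composition-plot annotation; x100 to a percentage.
    """
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError("window must be (lo, hi) with 1 <= lo <= hi")
    if hi > composition.max_position:
        raise ValueError(
            f"window {window} exceeds composition positions (max {composition.max_position})"
        )
    sub = composition.fractions.loc[lo:hi]
    if sub[list(_BASES)].isna().any().any():
        raise ValueError("window includes positions with no covering reads")
    return float((sub["G"] + sub["C"]).mean() * 100.0)


def length_histogram(footprints: Iterable[Footprint]) -> dict[int, int]:
    return dict(sorted(Counter(f.length for f in footprints).items()))


def length_peak(histogram: Mapping[int, int]) -> int:
    """Modal footprint length; ties resolve to the smallest length."""
    if not histogram:
        raise ValueError("empty length histogram")
    best = max(histogram.values())
    return min(L for L, c in histogram.items() if c == best)


def assign_regions(
    footprints: Iterable[Footprint],
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    offsets: int | Mapping[int, int] = 12,
    mode: str = "psite",
) -> dict[str, float]:
    """5'UTR / CDS / 3'UTR assignment fractions.

    ``mode='psite'`` (default) assigns each footprint to the region
    containing its P-site, so every assignable read counts exactly once.
    ``mode='overlap'`` counts a read toward every region it overlaps
    (bedtools-intersect-style), with fractions over total assignments.
    """
    tx = transcripts if isinstance(transcripts, Mapping) else {t.id: t for t in transcripts}
    counts = {"utr5": 0, "cds": 0, "utr3": 0}
    for f in footprints:
        if f.reference not in tx:
            raise ValueError(f"{f.read_id}: unknown transcript {f.reference}")
        t = tx[f.reference]
        if mode == "psite":
            p = psite_of(f, offsets)
            if 0 <= p < t.length:
                counts[t.region_of(p)] += 1
        elif mode == "overlap":
            if f.start < t.utr5_end:
                counts["utr5"] += 1
            if f.start < t.cds_end and f.end > t.utr5_end:
                counts["cds"] += 1
            if f.end > t.cds_end:
                counts["utr3"] += 1
        else:
            raise ValueError("mode must be 'psite' or 'overlap'")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no assignable footprints")
    return {k: v / total for k, v in counts.items()}


def estimate_psite_offsets(
    footprints: Iterable[Footprint],
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    min_reads: int = 200,
    confidence_threshold: float = 2.0,
) -> tuple[dict[int, int], dict[int, float], set[int]]:
    """Estimate the P-site offset per read length from start-codon geometry.

    For each read length L, the 5'-end density at positions upstream of
    annotated start codons is aggregated over transcripts; a footprint
    whose P-site sits on codon k of the CDS has its 5' end at
    (start codon - offset + 3k), so the density forms a period-3 comb
    whose most upstream occupied tooth sits exactly one offset before
    the start codon.  Candidate offsets span [L/4, L/2].  The estimator
    (1) picks the dominant comb phase (mod 3) by total candidate
    density — triplet-periodic reads outvote the +-1-shifted,
    frame-degraded ones; (2) within that phase, subtracts a smooth
    background estimated from same-phase slots upstream of the window
    (UTR-contamination reads have no comb structure) and returns the
    most upstream tooth rising at least halfway from background to the
    comb peak.  That edge coincides with the classical density
    argmax when an initiation peak exists and stays identifiable under
    uniform elongation, where teeth at o and o-3 tie in expectation.

    Lengths with fewer than ``min_reads`` reads inherit the modal offset
    of the passing lengths.  Returns (offsets, confidence ratios
    (candidate-window peak / mean), low-confidence lengths).
    """
    tx = transcripts if isinstance(transcripts, Mapping) else {t.id: t for t in transcripts}
    by_length: dict[int, Counter] = {}
    n_by_length: Counter = Counter()
    for f in footprints:
        t = tx[f.reference]
        rel = f.start - t.utr5_end  # 5' end relative to the start codon
        by_length.setdefault(f.length, Counter())[rel] += 1
        n_by_length[f.length] += 1

    offsets: dict[int, int] = {}
    confidence: dict[int, float] = {}
    low_conf: set[int] = set()
    for L in sorted(by_length):
        if n_by_length[L] < min_reads:
            continue
        dens = by_length[L]
        cand = list(range(int(np.ceil(L / 4)), int(L // 2) + 1))
        d = np.array([dens.get(-o, 0) for o in cand], dtype=float)
        if d.max() == 0:
            low_conf.add(L)
            offsets[L] = 12
            confidence[L] = 0.0
            continue
        phase_totals = {
            phi: sum(v for o, v in zip(cand, d) if (-o) % 3 == phi) for phi in range(3)
        }
        phase = max(phase_totals, key=lambda phi: (phase_totals[phi], -phi))
        comb = [(o, v) for o, v in zip(cand, d) if (-o) % 3 == phase]
        # smooth background (e.g. 5'UTR contamination) estimated from
        # same-phase slots strictly upstream of the candidate window
        bg_slots = [max(o for o, _ in comb) + 3 * j for j in (1, 2, 3)]
        background = float(np.mean([dens.get(-o, 0) for o in bg_slots]))
        peak = max(v for _, v in comb)
        floor_level = background + 0.5 * max(peak - background, 1.0)
        occupied = [o for o, v in comb if v >= floor_level]
        offsets[L] = max(occupied) if occupied else max(comb, key=lambda t: t[1])[0]
        ratio = float(d.max() / d.mean()) if d.mean() > 0 else float("inf")
        confidence[L] = ratio
        if ratio < confidence_threshold:
            low_conf.add(L)
    if not offsets:
        raise ValueError(
            f"no read length reaches min_reads={min_reads}; supply more reads or lower the threshold"
        )
    modal = Counter(offsets.values()).most_common()
    best_count = modal[0][1]
    global_offset = min(o for o, c in modal if c == best_count)
    for L in sorted(n_by_length):
        if L not in offsets:
            offsets[L] = global_offset
    return offsets, confidence, low_conf


@dataclass(frozen=True)
class FrameResult:
    """Reading-frame preference per read length."""

    per_length: pd.DataFrame  # index length, columns f0/f1/f2/n_reads
    best_length: int

    @property
    def best_fractions(self) -> dict[str, float]:
        row = self.per_length.loc[self.best_length]
        return {k: float(row[k]) for k in ("f0", "f1", "f2")}

    @property
    def overall(self) -> dict[str, float]:
        w = self.per_length["n_reads"]
        return {
            k: float((self.per_length[k] * w).sum() / w.sum()) for k in ("f0", "f1", "f2")
        }


def frame_preference(
    footprints: Iterable[Footprint],
    transcripts: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    psite_offsets: int | Mapping[int, int] = 12,
    min_reads: int = 200,
) -> FrameResult:
    """P-site reading-frame fractions per read length, for CDS P-sites.

    Frame = (P-site - CDS start) mod 3.  The best length maximizes the
    frame-0 fraction among lengths with >= ``min_reads`` CDS reads (all
    lengths if none qualifies); ties resolve to the shortest length.
    """
    tx = transcripts if isinstance(transcripts, Mapping) else {t.id: t for t in transcripts}
    frames: dict[int, np.ndarray] = {}
    for f in footprints:
        t = tx[f.reference]
        p = psite_of(f, psite_offsets)
        if not t.utr5_end <= p < t.cds_end:
            continue
        frames.setdefault(f.length, np.zeros(3, dtype=np.int64))[(p - t.utr5_end) % 3] += 1
    if not frames:
        raise ValueError("no footprints with a CDS P-site")
    rows = {
        L: {"f0": c[0] / c.sum(), "f1": c[1] / c.sum(), "f2": c[2] / c.sum(), "n_reads": c.sum()}
        for L, c in frames.items()
    }
    per_length = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    per_length.index.name = "length"
    eligible = per_length[per_length["n_reads"] >= min_reads]
    if eligible.empty:
        eligible = per_length
    best_f0 = eligible["f0"].max()
    best_length = int(eligible.index[eligible["f0"] == best_f0].min())
    return FrameResult(per_length=per_length, best_length=best_length)


def smooth_profile(profile: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; an even window is widened by 1; at the
    edges the window is truncated to the available positions."""
    if window <= 1:
        return np.asarray(profile, dtype=float)
    if window % 2 == 0:
        window += 1
    x = np.asarray(profile, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def metagene_profile(
    samples: Sequence[Iterable[Footprint]],
    transcript: TranscriptModel,
    normalization: str = "library_size",
    smooth_window: int = 30,
    psite_offsets: int | Mapping[int, int] = 12,
    library_sizes: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-nucleotide P-site density along one transcript.

    Per replicate: P-site counts at each position -> normalization
    (``library_size``: divide by total reads in the replicate;
    ``cds_mean_density``: divide by mean count over CDS positions) ->
    mean across replicates -> centered moving average of width
    ``smooth_window`` (default 30, widened to 31; 0/1 disables).
    """
    profiles = []
    for r, footprints in enumerate(samples):
        footprints = list(footprints)
        counts = np.zeros(transcript.length, dtype=float)
        for f in footprints:
            if f.reference != transcript.id:
                continue
            p = psite_of(f, psite_offsets)
            if 0 <= p < transcript.length:
                counts[p] += 1
        if normalization == "library_size":
            total = library_sizes[r] if library_sizes is not None else len(footprints)
            if total <= 0:
                raise ValueError("library size must be positive")
            counts = counts / total
        elif normalization == "cds_mean_density":
            mean_cds = counts[transcript.utr5_end : transcript.cds_end].mean()
            if mean_cds == 0:
                warnings.warn(f"{transcript.id}: no CDS coverage in replicate {r}; left unscaled")
            else:
                counts = counts / mean_cds
        elif normalization != "none":
            raise ValueError("normalization must be library_size, cds_mean_density or none")
        profiles.append(counts)
    if not profiles:
        raise ValueError("no replicate samples given")
    mean_profile = np.mean(profiles, axis=0)
    return smooth_profile(mean_profile, smooth_window)


@dataclass
class QCReport:
    """Per-sample bundle of digestion-diagnostic metrics."""

    sample_id: str
    n_reads: int
    gc_window_mean: float
    length_histogram: dict[int, int]
    length_peak: int
    region_fractions: dict[str, float]
    frame_fractions: dict[str, float]
    best_frame_length: int
    psite_offsets: dict[int, int]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "sample_id": self.sample_id,
                "n_reads": self.n_reads,
                "gc_window_mean": self.gc_window_mean,
                "length_histogram": {str(k): v for k, v in self.length_histogram.items()},
                "length_peak": self.length_peak,
                "region_fractions": self.region_fractions,
                "frame_fractions": self.frame_fractions,
                "best_frame_length": self.best_frame_length,
                "psite_offsets": {str(k): v for k, v in self.psite_offsets.items()},
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_reads", self.n_reads),
            ("gc_window_mean", self.gc_window_mean),
            ("length_peak", self.length_peak),
            ("best_frame_length", self.best_frame_length),
            *[(f"region_{k}", v) for k, v in self.region_fractions.items()],
            *[(f"frame_{k}", v) for k, v in self.frame_fractions.items()],
        ]
        return pd.DataFrame(rows, columns=["metric", "value"]).assign(sample=self.sample_id)


def compute_qc_report(
    footprints: Iterable[Footprint],
    transcripts: Sequence[TranscriptModel],
    sample_id: str = "sample",
    gc_window: tuple[int, int] = (10, 20),
    psite_offsets: int | Mapping[int, int] | str = "estimate",
    min_reads: int = 200,
) -> QCReport:
    """Assemble the per-sample QC report from unique footprints.

    Composition/GC metrics follow convention and are computed on reads
    whose P-site falls in the CDS.  ``psite_offsets='estimate'`` runs
    :func:`estimate_psite_offsets`, falling back to the canonical 12 nt
    when no length class has enough reads.
    """
    footprints = [f for f in footprints if f.category == "unique"]
    if not footprints:
        raise ValueError("no unique footprints")
    tx = {t.id: t for t in transcripts}

    if psite_offsets == "estimate":
        try:
            offsets, _, _ = estimate_psite_offsets(footprints, tx, min_reads=min_reads)
        except ValueError:
            offsets = 12
    else:
        offsets = psite_offsets  # type: ignore[assignment]

    cds_reads = [
        f
        for f in footprints
        if tx[f.reference].utr5_end <= psite_of(f, offsets) < tx[f.reference].cds_end
    ]
    comp_source = cds_reads if cds_reads else footprints
    composition = nucleotide_composition(comp_source)
    hist = length_histogram(cds_reads if cds_reads else footprints)
    frame = frame_preference(footprints, tx, offsets, min_reads=min_reads)
    offsets_map = (
        offsets
        if isinstance(offsets, Mapping)
        else {L: int(offsets) for L in hist}
    )
    return QCReport(
        sample_id=sample_id,
        n_reads=len(footprints),
        gc_window_mean=windowed_gc(composition, gc_window),
        length_histogram=hist,
        length_peak=length_peak(hist),
        region_fractions=assign_regions(footprints, tx, offsets),
        frame_fractions=frame.best_fractions,
        best_frame_length=frame.best_length,
        psite_offsets=dict(offsets_map),
    )
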