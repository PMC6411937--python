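"""Aligned-footprint accounting: loading, UMI deduplication, category summaries.

This toolkit does not align reads; it consumes alignments produced
upstream (or simulator ground truth) and handles the bookkeeping that
follows: normalizing coordinates, marking UMI-based PCR duplicates, and
summarizing the mapping categories (unique / multimapped / unmapped /
duplicate / rRNA / tRNA contaminants) that a library QC report tabulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .simulate import SimTruth
from .transcripts import TranscriptModel

CATEGORIES = (
    "unique",
    "duplicate",
    "multimapped",
    "unmapped",
    "contaminant_rRNA",
    "contaminant_tRNA",
)

#: documented 8-column SAM-like TSV dialect (0-based half-open coordinates)
TSV8_COLUMNS = ("read_id", "reference", "start", "end", "strand", "umi", "sequence", "category")

__all__ = [
    "CATEGORIES",
    "TSV8_COLUMNS",
    "Footprint",
    "MappingSummary",
    "load_alignments",
    "footprints_from_truth",
    "mark_duplicates",
    "summarize_mapping",
    "write_footprints",
]


@dataclass
class Footprint:
    """One aligned ribosome-protected fragment."""

    read_id: str
    reference: str
    start: int  # 0-based leftmost
    length: int
    strand: str = "+"
    sequence: str | None = None
    umi: str | None = None
    category: str = "unique"

    def __post_init__(self) -> None:
        if self.start < 0 or self.length <= 0:
            raise ValueError(f"{self.read_id}: start must be >= 0 and length > 0")
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: strand must be + or -")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.read_id}: unknown category {self.category!r}")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class MappingSummary:
    """Per-sample mapping-category accounting (counts and fractions)."""

    counts: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.total for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": list(self.fractions.values()),
            }
        )


def footprints_from_truth(
    truth: Sequence[SimTruth], transcripts: Sequence[TranscriptModel] | None = None
) -> list[Footprint]:
    """Convert simulator ground truth into footprints (category as labeled;
    sequences attached when transcripts are provided)."""
    seqs = {t.id: t.sequence for t in transcripts} if transcripts else {}
    out = []
    for t in truth:
        seq = None
        if t.transcript in seqs:
            seq = seqs[t.transcript][t.start : t.start + t.length]
        out.append(
            Footprint(
                read_id=t.read_id,
                reference=t.transcript,
                start=t.start,
                length=t.length,
                sequence=seq,
                umi=t.umi,
                category=t.category,
            )
        )
    return out


def _parse_tsv8(path: Path) -> list[Footprint]:
    out: list[Footprint] = []
    by_read: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "read_id":  # optional header
                continue
            if len(fields) != len(TSV8_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(TSV8_COLUMNS)} columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[2]), int(fields[3])
                fp = Footprint(
                    read_id=fields[0],
                    reference=fields[1],
                    start=start,
                    length=end - start,
                    strand=fields[4],
                    umi=fields[5] or None,
                    sequence=fields[6] or None,
                    category=fields[7] or "unique",
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            by_read.setdefault(fp.read_id, []).append(len(out))
            out.append(fp)
    # reads with >1 alignment record are multimapped and excluded downstream
    for read_id, rows in by_read.items():
        if len(rows) > 1:
            for r in rows:
                out[r] = replace(out[r], category="multimapped")
    return out


def _parse_bed(path: Path) -> list[Footprint]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED needs >= 6 columns")
            try:
                chrom, start, end, name, _, strand = fields[:6]
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record: {exc}") from exc
            umi = name.rsplit("_", 1)[1] if "_" in name else None
            out.append(
                Footprint(
                    read_id=name,
                    reference=chrom,
                    start=start,
                    length=end - start,
                    strand=strand,
                    umi=umi,
                )
            )
    return out


def load_alignments(
    path: str | Path,
    format: str = "tsv8",
    transcripts: Sequence[TranscriptModel] | None = None,
) -> list[Footprint]:
    """Load footprints from ``tsv8`` (8-column SAM-like TSV), ``bed``
    (BED6/12, UMI parsed from the name after the last '_'), or ``truth``
    (simulator truth TSV).

    Coordinates are normalized to 0-based half-open.  When transcripts
    are given, references are validated against them and sequences
    attached where absent.
    """
    path = Path(path)
    if format == "tsv8":
        fps = _parse_tsv8(path)
    elif format == "bed":
        fps = _parse_bed(path)
    elif format == "truth":
        from .simulate import read_truth

        fps = footprints_from_truth(read_truth(path), transcripts)
    else:
        raise ValueError(f"unknown format {format!r}; use tsv8, bed or truth")

    if transcripts is not None:
        known = {t.id: t for t in transcripts}
        offenders = sorted({f.reference for f in fps} - set(known))
        if offenders:
            raise ValueError(f"unknown reference ids: {', '.join(offenders)}")
        for i, f in enumerate(fps):
            if f.sequence is None:
                fps[i] = replace(
                    f, sequence=known[f.reference].sequence[f.start : f.start + f.length]
                )
    return fps


def mark_duplicates(footprints: Iterable[Footprint]) -> list[Footprint]:
    """Mark UMI-based PCR duplicates among unique-category footprints.

    Within each key (reference, start, strand, length, UMI) the
    first-encountered footprint stays ``unique`` and the rest become
    ``duplicate``.  Footprints differing in length (3' end) are distinct
    molecules.  Non-unique categories pass through untouched.
    """
    seen: set[tuple] = set()
    out = []
    for f in footprints:
        if f.category != "unique":
            out.append(f)
            continue
        if f.umi is None:
            raise ValueError(f"{f.read_id}: unique footprint lacks a UMI")
        key = (f.reference, f.start, f.strand, f.length, f.umi)
        if key in seen:
            out.append(replace(f, category="duplicate"))
        else:
            seen.add(key)
            out.append(f)
    return out


def summarize_mapping(footprints: Iterable[Footprint]) -> MappingSummary:
    """Count footprints per mapping category (all categories reported,
    including zero counts); fractions sum to 1 over a non-empty input."""
    counts = {c: 0 for c in CATEGORIES}
    total = 0
    for f in footprints:
        counts[f.category] += 1
        total += 1
    return MappingSummary(counts=counts, total=total)


def write_footprints(footprints: Iterable[Footprint], path: str | Path) -> None:
    """Write footprints in the 8-column TSV dialect (with header)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV8_COLUMNS) + "\n")
        for f in footprints:
            fh.write(
                "\t".join(
                    [
                        f.read_id,
                        f.reference,
                        str(f.start),
                        str(f.end),
                        f.strand,
                        f.umi or "",
                        f.sequence or "",
                        f.category,
                    ]
                )
                + "\n"
            )
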