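"""Pre-mapping read processing: demultiplexing, adapter trimming, UMIs.

The library layout mirrors a small-RNA-style ribosome profiling library:
each sequenced read is [5 nt sample barcode][8 nt UMI][footprint insert]
[3' adapter].  Segment order and widths are configurable through
:class:`ReadLayout`; the operations below consume the layout rather than
hard-coding offsets.  Adapter matching is 3'-anchored prefix matching
with mismatches only (no indels), the standard model for ligated small
RNA adapters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

#: 3' adapter ligated to footprints in the library protocol this toolkit targets.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAGATCGGAAGAGCGGTTCAGCAGGAATGCCGAGACCG"

__all__ = [
    "DEFAULT_ADAPTER",
    "RawRead",
    "ReadLayout",
    "default_layout",
    "hamming",
    "demultiplex",
    "trim_adapter",
    "extract_umi",
    "prep_pipeline",
    "read_fastq",
    "write_fastq",
]


@dataclass
class RawRead:
    """A sequencing read, with barcode/UMI populated as they are stripped."""

    id: str
    sequence: str
    qualities: str
    barcode: str | None = None
    umi: str | None = None
    adapter_trimmed: bool | None = None  # None = trimming not attempted yet

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.id}: qualities length != sequence length")


@dataclass(frozen=True)
class ReadLayout:
    """Ordered read segments; exactly one variable-width 'insert'.

    ``segments`` is a tuple of (name, width) with width ``None`` for the
    insert.  The adapter, if present, must immediately follow the insert
    (it is removed by alignment, not by width).
    """

    segments: tuple[tuple[str, int | None], ...] = (
        ("barcode", 5),
        ("umi", 8),
        ("insert", None),
        ("adapter", None),
    )

    def __post_init__(self) -> None:
        names = [n for n, _ in self.segments]
        if names.count("insert") != 1:
            raise ValueError("layout needs exactly one insert segment")
        for n, w in self.segments:
            if n != "insert" and n != "adapter" and (w is None or w < 0):
                raise ValueError(f"segment {n} needs a non-negative fixed width")
        if "adapter" in names and names.index("adapter") != names.index("insert") + 1:
            raise ValueError("adapter segment must immediately follow the insert")

    def width(self, name: str) -> int:
        for n, w in self.segments:
            if n == name:
                return 0 if w is None else w
        raise KeyError(name)

    def prefix_names(self) -> list[str]:
        """Fixed-width segments 5' of the insert, in order."""
        out = []
        for n, _ in self.segments:
            if n == "insert":
                break
            out.append(n)
        return out

    def offset_of(self, name: str, stripped: set[str]) -> int:
        """5' offset of a fixed segment given which segments are already gone."""
        off = 0
        for n in self.prefix_names():
            if n == name:
                return off
            if n not in stripped:
                off += self.width(n)
        raise KeyError(f"{name} is not a fixed prefix segment of this layout")


def default_layout() -> ReadLayout:
    return ReadLayout()


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def _stripped_segments(read: RawRead) -> set[str]:
    s = set()
    if read.barcode is not None:
        s.add("barcode")
    if read.umi is not None:
        s.add("umi")
    return s


def demultiplex(
    reads: Iterable[RawRead],
    barcode_whitelist: Sequence[str],
    max_mismatch: int = 1,
    layout: ReadLayout | None = None,
) -> tuple[dict[str, list[RawRead]], list[RawRead]]:
    """Split reads by sample barcode; strip the barcode segment.

    Each read is assigned to the unique whitelist barcode within
    ``max_mismatch`` Hamming distance of its barcode segment, otherwise
    routed to the unassigned stream.  The whitelist must have pairwise
    Hamming distance > 2*max_mismatch so assignment is unambiguous.

    Returns (barcode -> reads, unassigned reads).
    """
    layout = layout or default_layout()
    width = layout.width("barcode")
    whitelist = list(barcode_whitelist)
    for bc in whitelist:
        if len(bc) != width:
            raise ValueError(f"barcode {bc!r} does not match layout width {width}")
    for i, a in enumerate(whitelist):
        for b in whitelist[i + 1 :]:
            if hamming(a, b) <= 2 * max_mismatch:
                raise ValueError(
                    f"ambiguous whitelist: {a} and {b} are within Hamming distance "
                    f"{2 * max_mismatch} at max_mismatch={max_mismatch}"
                )

    assigned: dict[str, list[RawRead]] = {bc: [] for bc in whitelist}
    unassigned: list[RawRead] = []
    for read in reads:
        off = layout.offset_of("barcode", _stripped_segments(read))
        observed = read.sequence[off : off + width]
        hit = None
        if len(observed) == width:
            for bc in whitelist:
                if hamming(observed, bc) <= max_mismatch:
                    hit = bc
                    break
        if hit is None:
            unassigned.append(read)
            continue
        assigned[hit].append(
            replace(
                read,
                sequence=read.sequence[:off] + read.sequence[off + width :],
                qualities=read.qualities[:off] + read.qualities[off + width :],
                barcode=hit,
            )
        )
    return assigned, unassigned


def trim_adapter(
    read: RawRead,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
) -> RawRead:
    """Remove a 3'-anchored adapter-prefix match from the read end.

    Scans every suffix start; a suffix of the read matching the adapter
    prefix of the same length (>= ``min_overlap``), with mismatches at
    rate <= ``max_error_rate``, is a candidate.  The best-scoring
    candidate (matches - mismatches, ties to the earliest start, i.e.
    the longest trim) wins.  Reads without a candidate are returned
    unchanged and flagged ``adapter_trimmed=False``.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    if not 0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    seq = read.sequence
    best_score, best_start = None, None
    for start in range(0, len(seq) - min_overlap + 1):
        overlap = min(len(seq) - start, len(adapter))
        if overlap < min_overlap:
            break
        mism = hamming(seq[start : start + overlap], adapter[:overlap])
        if mism > max_error_rate * overlap:
            continue
        score = overlap - 2 * mism
        if best_score is None or score > best_score:
            best_score, best_start = score, start
    if best_start is None:
        return replace(read, adapter_trimmed=False)
    return replace(
        read,
        sequence=seq[:best_start],
        qualities=read.qualities[:best_start],
        adapter_trimmed=True,
    )


def extract_umi(read: RawRead, layout: ReadLayout | None = None) -> RawRead | None:
    """Move the UMI segment out of the sequence into read metadata.

    Returns ``None`` for reads whose insert would be empty (too short to
    carry a footprint); callers count these as dropped.  A zero-width
    UMI segment yields ``umi=""`` with the sequence unchanged.
    """
    layout = layout or default_layout()
    width = layout.width("umi")
    off = layout.offset_of("umi", _stripped_segments(read))
    if width == 0:
        return replace(read, umi="")
    if len(read.sequence) < off + width:
        return None
    umi = read.sequence[off : off + width]
    new = replace(
        read,
        sequence=read.sequence[:off] + read.sequence[off + width :],
        qualities=read.qualities[:off] + read.qualities[off + width :],
        umi=umi,
    )
    if len(new.sequence) == 0:  # barcode+UMI only: no insert
        return None
    return new


def prep_pipeline(
    reads: Iterable[RawRead],
    barcode_whitelist: Sequence[str],
    adapter: str = DEFAULT_ADAPTER,
    layout: ReadLayout | None = None,
    max_mismatch: int = 1,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
) -> tuple[dict[str, list[RawRead]], dict[str, int]]:
    """Demultiplex, trim the adapter and extract UMIs in layout order.

    Returns (barcode -> processed reads, stats).  Stats partition the
    input: assigned + unassigned + dropped = total.
    """
    layout = layout or default_layout()
    reads = list(reads)
    assigned, unassigned = demultiplex(reads, barcode_whitelist, max_mismatch, layout)
    out: dict[str, list[RawRead]] = {bc: [] for bc in assigned}
    dropped = 0
    for bc, group in assigned.items():
        for read in group:
            read = trim_adapter(read, adapter, min_overlap, max_error_rate)
            read = extract_umi(read, layout)
            if read is None:
                dropped += 1
            else:
                out[bc].append(read)
    stats = {
        "total": len(reads),
        "assigned": sum(len(v) for v in out.values()),
        "unassigned": len(unassigned),
        "dropped": dropped,
    }
    return out, stats


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line, Phred+33)

def read_fastq(path: str | Path) -> Iterator[RawRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield RawRead(id=rec.id, sequence=str(rec.seq).upper(), qualities=quals)


def write_fastq(reads: Iterable[RawRead], path: str | Path, umi_delimiter: str = "_") -> None:
    """Write reads; an extracted UMI is carried in the read id after the delimiter."""
    with open(path, "w") as fh:
        for r in reads:
            name = r.id if r.umi in (None, "") else f"{r.id}{umi_delimiter}{r.umi}"
            fh.write(f"@{name}\n{r.sequence}\n+\n{r.qualities}\n")
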