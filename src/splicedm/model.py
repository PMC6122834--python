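"""Core domain types for splicing-event analysis.

Coordinates are 0-based half-open throughout; GTF input (1-based inclusive)
is converted on read.  A *gene cluster* is the unit of analysis: all
transcripts whose exonic spans overlap on one strand.  Within a cluster the
exon boundaries of every transcript partition the exonic union into numbered
*exonic parts*; a splicing event is a pair of alternative paths through
those parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

EVENT_TYPES = ("ES", "A5SS", "A3SS", "ME", "IR", "AFE", "ALE")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One annotated transcript: ordered, non-overlapping exons on one strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple chrom/strand"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end


@dataclass(frozen=True)
class ExonicPart:
    """Maximal sub-exonic interval between consecutive exon boundaries.

    ``index`` is the 1-based ordinal of the part within its cluster, in
    genomic order; paths of splicing events are lists of these indices.
    """

    index: int
    interval: GenomicInterval


@dataclass(frozen=True, order=True)
class Junction:
    """An annotated exon-exon junction (splice gap between two parts)."""

    chrom: str
    donor_end: int       # 0-based exclusive end of the upstream part
    acceptor_start: int  # 0-based start of the downstream part
    strand: str

    def __post_init__(self) -> None:
        if not self.donor_end < self.acceptor_start:
            raise ValueError(
                f"junction requires donor_end < acceptor_start, got "
                f"{self.donor_end} >= {self.acceptor_start}"
            )


@dataclass
class GeneCluster:
    cluster_id: str
    transcripts: list[TranscriptModel]
    exonic_parts: list[ExonicPart] = field(default_factory=list)
    junctions: set[Junction] = field(default_factory=set)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def gene_ids(self) -> list[str]:
        return sorted({t.gene_id for t in self.transcripts})

    def part(self, index: int) -> ExonicPart:
        return self.exonic_parts[index - 1]


@dataclass
class SplicingEvent:
    """A two-path alternative-splicing event.

    ``path1``/``path2`` are ordered exonic-part indices including the shared
    flanking constitutive parts; ``numerator_path`` names the path whose
    usage defines PSI (longer isoform for ES/A5SS/A3SS/ME/IR, proximal
    isoform for AFE/ALE).  ``anchor`` spans the variable region: the union
    of parts present in exactly one path.
    """

    event_type: str
    path1: tuple[int, ...]
    path2: tuple[int, ...]
    numerator_path: int
    gene_id: str
    cluster_id: str
    anchor: GenomicInterval
    chrom: str
    strand: str
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if tuple(self.path1) == tuple(self.path2):
            raise ValueError("path1 and path2 must differ")
        if self.numerator_path not in (1, 2):
            raise ValueError("numerator_path must be 1 or 2")

    @property
    def numerator(self) -> tuple[int, ...]:
        return self.path1 if self.numerator_path == 1 else self.path2


@dataclass
class AlignedRead:
    """A uniquely-or-multiply mapped read as ordered match blocks.

    Gaps between consecutive blocks are splice gaps (CIGAR ``N``); small
    deletions are merged into blocks on read.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: list[GenomicInterval]
    n_hits: Optional[int] = 1
    mapq: int = 255

    def __post_init__(self) -> None:
        if self.n_hits is not None and self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.end > b.start:
                raise ValueError(f"read {self.read_id}: overlapping blocks")

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """(donor_end, acceptor_start) pairs between consecutive blocks."""
        return [
            (a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:])
        ]
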