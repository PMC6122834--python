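"""Read counting: unique-read filtering, exonic-part and junction counts,
and per-event path-support assignment.

A read supports an event path through the features exclusive to that path:
exonic parts present in exactly one path and splice junctions implied by
exactly one path.  Features shared by both paths are uninformative and
contribute to neither count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import pandas as pd
from intervaltree import IntervalTree

from .annotation import path_junctions
from .model import AlignedRead, GeneCluster, GenomicInterval, Junction, SplicingEvent

logger = logging.getLogger(__name__)

UNKNOWN_JUNCTION = "__unknown__"

ALIGNMENT_TSV_COLUMNS = ("read_id", "chrom", "strand", "blocks", "n_hits", "mapq")


@dataclass
class UniquePolicy:
    """Fallback rule when the aligner's hit-multiplicity tag is absent."""

    min_mapq: int = 255


@dataclass
class PartCounts:
    sample_id: str
    counts: dict[tuple[str, int], int] = field(default_factory=dict)

    def get(self, cluster_id: str, part_index: int) -> int:
        return self.counts.get((cluster_id, part_index), 0)


@dataclass
class JunctionCounts:
    sample_id: str
    counts: dict[Junction, int] = field(default_factory=dict)
    unknown: int = 0

    def get(self, junction: Junction) -> int:
        return self.counts.get(junction, 0)


class AlignmentParseError(ValueError):
    pass


def _blocks_from_cigar(cigartuples, pos: int, chrom: str, strand: str) -> list[GenomicInterval]:
    """Reference blocks from CIGAR: M/=/X/D extend the block, N splits it."""
    blocks: list[tuple[int, int]] = []
    cur_start, cur = pos, pos
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference within a block
            cur += length
        elif op == 3:  # N: splice gap
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur_start = cur = cur + length
        elif op in (1, 4, 5, 6):  # I, S, H, P: no reference consumed
            continue
        else:
            raise AlignmentParseError(f"unsupported CIGAR op {op}")
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return [GenomicInterval(chrom, s, e, strand) for s, e in blocks]


def _read_sam(path: Union[str, Path]) -> list[AlignedRead]:
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.cigartuples is None:
                raise AlignmentParseError(
                    f"read {rec.query_name}: mapped record without CIGAR"
                )
            strand = "-" if rec.is_reverse else "+"
            blocks = _blocks_from_cigar(
                rec.cigartuples, rec.reference_start, rec.reference_name, strand
            )
            n_hits = rec.get_tag("NH") if rec.has_tag("NH") else None
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    strand=strand,
                    blocks=blocks,
                    n_hits=n_hits,
                    mapq=rec.mapping_quality,
                )
            )
    return reads


def _parse_tsv_line(line: str, lineno: int) -> AlignedRead:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 6:
        raise AlignmentParseError(
            f"line {lineno}: expected 6 fields {ALIGNMENT_TSV_COLUMNS}, got {len(fields)}"
        )
    read_id, chrom, strand, blocks_s, n_hits_s, mapq_s = fields
    try:
        blocks = []
        for span in blocks_s.split(","):
            s, e = span.split("-")
            blocks.append(GenomicInterval(chrom, int(s), int(e), strand))
        n_hits = None if n_hits_s in (".", "") else int(n_hits_s)
        mapq = int(mapq_s)
    except ValueError as exc:
        raise AlignmentParseError(f"line {lineno}: read {read_id}: {exc}") from exc
    return AlignedRead(read_id, chrom, strand, blocks, n_hits, mapq)


def read_alignments(
    source: Union[str, Path, IO[str], Iterable[str]],
    dialect: str = "tsv",
) -> list[AlignedRead]:
    """Load alignments from SAM/BAM (``dialect='sam'``) or the simplified
    block-interval TSV dialect (``dialect='tsv'``).

    TSV columns: ``read_id chrom strand blocks n_hits mapq`` with blocks as
    comma-separated 0-based half-open ``start-end`` spans.
    """
    if dialect == "sam":
        return _read_sam(source)  # type: ignore[arg-type]
    if dialect != "tsv":
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    reads = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        reads.append(_parse_tsv_line(line, lineno))
    return reads


def filter_unique(
    reads: Iterable[AlignedRead], policy: Optional[UniquePolicy] = None
) -> list[AlignedRead]:
    """Keep uniquely mapped reads: n_hits == 1 when multiplicity is
    reported, else mapq >= policy.min_mapq."""
    policy = policy or UniquePolicy()
    out = []
    for r in reads:
        if r.n_hits is not None:
            if r.n_hits == 1:
                out.append(r)
        elif r.mapq >= policy.min_mapq:
            out.append(r)
    return out


def _part_tree(clusters: list[GeneCluster]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for c in clusters:
        tree = trees.setdefault(c.chrom, IntervalTree())
        for p in c.exonic_parts:
            tree.addi(p.interval.start, p.interval.end, (c.cluster_id, p.index))
    return trees


def _read_part_hits(
    read: AlignedRead, trees: dict[str, IntervalTree], min_overlap: int
) -> set[tuple[str, int]]:
    hits: set[tuple[str, int]] = set()
    tree = trees.get(read.chrom)
    if tree is None:
        return hits
    for block in read.blocks:
        for iv in tree.overlap(block.start, block.end):
            if min(block.end, iv.end) - max(block.start, iv.begin) >= min_overlap:
                hits.add(iv.data)
    return hits


def count_exonic_parts(
    reads: Iterable[AlignedRead],
    clusters: list[GeneCluster],
    sample_id: str = "sample",
    min_overlap: int = 1,
) -> PartCounts:
    """Count reads per exonic part.

    A read increments every part any of its blocks overlaps by at least
    ``min_overlap`` bases; reads touching parts of more than one gene
    cluster are discarded as ambiguous.
    """
    trees = _part_tree(clusters)
    pc = PartCounts(sample_id=sample_id)
    for read in reads:
        hits = _read_part_hits(read, trees, min_overlap)
        if len({cid for cid, _ in hits}) != 1:
            continue  # no hit, or ambiguous between clusters
        for key in hits:
            pc.counts[key] = pc.counts.get(key, 0) + 1
    return pc


def count_junctions(
    reads: Iterable[AlignedRead],
    clusters: list[GeneCluster],
    sample_id: str = "sample",
) -> JunctionCounts:
    """Count gapped reads per annotated junction (exact coordinate match).

    Gaps that match no annotated junction accumulate in the ``unknown``
    sink, which is reported but never used for event counts.
    """
    annotated: dict[tuple[str, int, int], Junction] = {}
    for c in clusters:
        for j in c.junctions:
            annotated[(j.chrom, j.donor_end, j.acceptor_start)] = j
    jc = JunctionCounts(sample_id=sample_id)
    for read in reads:
        for donor_end, acceptor_start in read.gaps:
            j = annotated.get((read.chrom, donor_end, acceptor_start))
            if j is None:
                jc.unknown += 1
            else:
                jc.counts[j] = jc.counts.get(j, 0) + 1
    return jc


def event_exclusive_features(
    event: SplicingEvent, cluster: GeneCluster
) -> tuple[tuple[set[int], set[Junction]], tuple[set[int], set[Junction]]]:
    """Parts and junctions exclusive to path1 and path2 respectively."""
    n_parts = len(cluster.exonic_parts)
    for idx in (*event.path1, *event.path2):
        if not 1 <= idx <= n_parts:
            raise ValueError(
                f"event {event.event_id}: path references unknown part {idx} "
                f"of cluster {cluster.cluster_id}"
            )
    p1, p2 = set(event.path1), set(event.path2)
    j1 = path_junctions(cluster, event.path1)
    j2 = path_junctions(cluster, event.path2)
    return (p1 - p2, j1 - j2), (p2 - p1, j2 - j1)


def assign_event_path_counts(
    event: SplicingEvent,
    cluster: GeneCluster,
    part_counts: PartCounts,
    junction_counts: JunctionCounts,
) -> tuple[int, int]:
    """Per-sample read support (x1, x2) for the two paths of an event."""
    (parts1, juncs1), (parts2, juncs2) = event_exclusive_features(event, cluster)
    x1 = sum(part_counts.get(cluster.cluster_id, i) for i in parts1) + sum(
        junction_counts.get(j) for j in juncs1
    )
    x2 = sum(part_counts.get(cluster.cluster_id, i) for i in parts2) + sum(
        junction_counts.get(j) for j in juncs2
    )
    return x1, x2


def build_event_counts(
    events: list[SplicingEvent],
    clusters: list[GeneCluster],
    sample_reads: dict[str, list[AlignedRead]],
    condition_map: dict[str, str],
    policy: Optional[UniquePolicy] = None,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Full counting pass: unique-filter reads per sample, count parts and
    junctions, and assign path support for every event.

    Returns the event-counts table with columns
    ``event_id sample_id condition x1 x2``.
    """
    by_cluster = {c.cluster_id: c for c in clusters}
    rows = []
    for sample_id in sorted(sample_reads):
        reads = filter_unique(sample_reads[sample_id], policy)
        pc = count_exonic_parts(reads, clusters, sample_id, min_overlap)
        jc = count_junctions(reads, clusters, sample_id)
        for ev in events:
            x1, x2 = assign_event_path_counts(ev, by_cluster[ev.cluster_id], pc, jc)
            rows.append(
                {
                    "event_id": ev.event_id,
                    "sample_id": sample_id,
                    "condition": condition_map[sample_id],
                    "x1": x1,
                    "x2": x2,
                }
            )
    return pd.DataFrame(rows, columns=["event_id", "sample_id", "condition", "x1", "x2"])


def write_event_counts(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_event_counts(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"x1": int, "x2": int})
    required = {"event_id", "sample_id", "condition", "x1", "x2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event-counts table missing columns: {sorted(missing)}")
    if (df[["x1", "x2"]] < 0).any().any():
        raise ValueError("negative counts in event-counts table")
    return df
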