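"""Annotation parsing, gene clustering and splicing-event enumeration.

The event model follows the flattened-exonic-part convention: within each
gene cluster, the exon boundaries of all transcripts partition the exonic
union into numbered parts, and every transcript corresponds to an ordered
path of part indices.  Pairs of transcript paths are diffed; each minimal
contiguous region of difference is classified into one of the seven event
types (ES, A5SS, A3SS, ME, IR, AFE, ALE).
"""

from __future__ import annotations

import logging
import re
from typing import IO, Iterable, Optional

from .model import (
    ExonicPart,
    GeneCluster,
    GenomicInterval,
    Junction,
    SplicingEvent,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    pass


def parse_gtf(stream: IO[str] | Iterable[str]) -> list[TranscriptModel]:
    """Parse exon features from a GTF stream into transcript models.

    GTF coordinates (1-based, inclusive) are converted to 0-based half-open.
    Non-exon features are ignored.  Raises :class:`GtfParseError` naming the
    offending line number on malformed input.
    """
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
        if end1 < start1:
            raise GtfParseError(
                f"line {lineno}: rejected record with end < start ({end1} < {start1})"
            )
        if strand not in ("+", "-"):
            raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
        attr_map = dict(_ATTR_RE.findall(attrs))
        try:
            gene_id = attr_map["gene_id"]
            transcript_id = attr_map["transcript_id"]
        except KeyError as exc:
            raise GtfParseError(
                f"line {lineno}: exon feature missing {exc.args[0]} attribute"
            ) from exc
        key = (gene_id, transcript_id)
        if key not in exons:
            exons[key] = []
            order.append(key)
        exons[key].append(GenomicInterval(chrom, start1 - 1, end1, strand))
    return [
        TranscriptModel(transcript_id=tid, gene_id=gid, exons=exs)
        for (gid, tid), exs in ((k, exons[k]) for k in order)
    ]


def build_gene_clusters(transcripts: list[TranscriptModel]) -> list[GeneCluster]:
    """Merge transcripts with overlapping exonic spans on one strand.

    Clustering is strand-specific: antisense overlaps never merge.  The
    cluster_id is the lexicographically smallest gene_id of its members.
    """
    by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_key.setdefault((t.chrom, t.strand), []).append(t)
    clusters: list[GeneCluster] = []
    for key in sorted(by_key):
        ts = sorted(by_key[key], key=lambda t: t.span)
        group: list[TranscriptModel] = []
        group_end = -1
        for t in ts:
            s, e = t.span
            if group and s >= group_end:
                clusters.append(_finish_cluster(group))
                group = []
                group_end = -1
            group.append(t)
            group_end = max(group_end, e)
        if group:
            clusters.append(_finish_cluster(group))
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.transcripts[0].span[0]))
    return [flatten_exonic_parts(c) for c in clusters]


def _finish_cluster(group: list[TranscriptModel]) -> GeneCluster:
    cid = min(t.gene_id for t in group)
    return GeneCluster(cluster_id=cid, transcripts=list(group))


def flatten_exonic_parts(cluster: GeneCluster) -> GeneCluster:
    """Populate exonic parts (boundary-split exon union) and junctions."""
    boundaries: set[int] = set()
    for t in cluster.transcripts:
        for e in t.exons:
            boundaries.add(e.start)
            boundaries.add(e.end)
    cuts = sorted(boundaries)
    chrom, strand = cluster.chrom, cluster.strand
    exon_list = [e for t in cluster.transcripts for e in t.exons]
    parts: list[ExonicPart] = []
    for lo, hi in zip(cuts, cuts[1:]):
        if any(e.start <= lo and hi <= e.end for e in exon_list):
            parts.append(
                ExonicPart(
                    index=len(parts) + 1,
                    interval=GenomicInterval(chrom, lo, hi, strand),
                )
            )
    cluster.exonic_parts = parts
    cluster.junctions = {
        Junction(chrom, a.end, b.start, strand)
        for t in cluster.transcripts
        for a, b in zip(t.exons, t.exons[1:])
        if a.end < b.start
    }
    return cluster


def transcript_part_path(cluster: GeneCluster, transcript: TranscriptModel) -> tuple[int, ...]:
    """Ordered exonic-part indices covered by the transcript's exons."""
    out = []
    for p in cluster.exonic_parts:
        iv = p.interval
        if any(e.start <= iv.start and iv.end <= e.end for e in transcript.exons):
            out.append(p.index)
    return tuple(out)


def path_junctions(cluster: GeneCluster, path: tuple[int, ...]) -> set[Junction]:
    """Splice junctions implied by a part path (gaps between consecutive parts)."""
    out = set()
    for i, j in zip(path, path[1:]):
        a, b = cluster.part(i).interval, cluster.part(j).interval
        if a.end < b.start:
            out.add(Junction(cluster.chrom, a.end, b.start, cluster.strand))
    return out


class _DiffRegion:
    __slots__ = ("a_parts", "b_parts", "left", "right")

    def __init__(self, a_parts, b_parts, left, right):
        self.a_parts = a_parts  # part indices only in path A, sorted
        self.b_parts = b_parts  # part indices only in path B, sorted
        self.left = left        # nearest shared part index upstream (genomic), or None
        self.right = right      # nearest shared part index downstream, or None


def _diff_regions(path_a: tuple[int, ...], path_b: tuple[int, ...]) -> list[_DiffRegion]:
    set_a, set_b = set(path_a), set(path_b)
    common = set_a & set_b
    if not common:
        return []
    union = sorted(set_a | set_b)
    regions: list[_DiffRegion] = []
    run: list[int] = []
    prev_common: Optional[int] = None
    for idx in union:
        if idx in common:
            if run:
                regions.append(
                    _DiffRegion(
                        [i for i in run if i in set_a],
                        [i for i in run if i in set_b],
                        prev_common,
                        idx,
                    )
                )
                run = []
            prev_common = idx
        else:
            run.append(idx)
    if run:
        regions.append(
            _DiffRegion(
                [i for i in run if i in set_a],
                [i for i in run if i in set_b],
                prev_common,
                None,
            )
        )
    return regions


def _contiguous(cluster: GeneCluster, i: int, j: int) -> bool:
    """True when parts i < j are genomically abutting (no splice gap)."""
    return cluster.part(i).interval.end == cluster.part(j).interval.start


def _is_contig_run(cluster: GeneCluster, parts: list[int]) -> bool:
    return all(
        b == a + 1 and _contiguous(cluster, a, b) for a, b in zip(parts, parts[1:])
    )


def _classify_region(cluster: GeneCluster, region: _DiffRegion) -> Optional[str]:
    a, b = region.a_parts, region.b_parts
    left, right = region.left, region.right
    strand = cluster.strand
    if left is not None and right is not None:
        if a and b:
            # candidate mutually exclusive exons: one spliced variable block
            # per path, non-interleaved
            if not (_is_contig_run(cluster, a) and _is_contig_run(cluster, b)):
                return None
            if not (max(a) < min(b) or max(b) < min(a)):
                return None
            return "ME"
        parts = a or b
        left_contig = parts[0] == left + 1 and _contiguous(cluster, left, parts[0])
        right_contig = parts[-1] == right - 1 and _contiguous(cluster, parts[-1], right)
        if left_contig and right_contig:
            if _is_contig_run(cluster, parts):
                return "IR"
            return None
        if left_contig and not right_contig:
            if not _is_contig_run(cluster, parts):
                return None
            return "A5SS" if strand == "+" else "A3SS"
        if right_contig and not left_contig:
            if not _is_contig_run(cluster, parts):
                return None
            return "A3SS" if strand == "+" else "A5SS"
        return "ES"
    # terminal region: require distinct terminal exons on both paths, each
    # spliced to the shared flank; a one-sided terminal extension is not one
    # of the seven types
    if not (a and b):
        return None
    if left is None and right is not None:
        if _contiguous(cluster, max(a), right) or _contiguous(cluster, max(b), right):
            return None
        return "AFE" if strand == "+" else "ALE"
    if right is None and left is not None:
        if _contiguous(cluster, left, min(a)) or _contiguous(cluster, left, min(b)):
            return None
        return "ALE" if strand == "+" else "AFE"
    return None


def _path_length(cluster: GeneCluster, path: tuple[int, ...]) -> int:
    return sum(len(cluster.part(i).interval) for i in path)


def _terminal_distance(cluster: GeneCluster, var_parts: list[int], left, right) -> int:
    """Splice-site distance from a variable terminal exon to the shared exon."""
    if left is None:
        return cluster.part(right).interval.start - cluster.part(max(var_parts)).interval.end
    return cluster.part(min(var_parts)).interval.start - cluster.part(left).interval.end


def _assign_numerator(
    cluster: GeneCluster,
    event_type: str,
    path1: tuple[int, ...],
    path2: tuple[int, ...],
    region: _DiffRegion,
    var1: list[int],
    var2: list[int],
) -> int:
    if event_type in ("AFE", "ALE"):
        d1 = _terminal_distance(cluster, var1, region.left, region.right)
        d2 = _terminal_distance(cluster, var2, region.left, region.right)
        if d1 == d2:
            logger.debug("proximal tie for %s event; defaulting to path1", event_type)
            return 1
        return 1 if d1 < d2 else 2
    l1, l2 = _path_length(cluster, path1), _path_length(cluster, path2)
    if l1 == l2:
        logger.debug("length tie for %s event; defaulting to path1", event_type)
        return 1
    return 1 if l1 > l2 else 2


def enumerate_events(cluster: GeneCluster) -> list[SplicingEvent]:
    """Enumerate two-path splicing events from all transcript pairs.

    Events are deduplicated by (type, path1, path2); path1 is the
    lexicographically smaller part-index tuple.  Unclassifiable difference
    regions are skipped with a warning.
    """
    if not cluster.exonic_parts:
        flatten_exonic_parts(cluster)
    paths = {
        t.transcript_id: transcript_part_path(cluster, t)
        for t in cluster.transcripts
    }
    genes = {t.transcript_id: t.gene_id for t in cluster.transcripts}
    tids = sorted(paths)
    seen: dict[tuple, SplicingEvent] = {}
    for i in range(len(tids)):
        for j in range(i + 1, len(tids)):
            pa, pb = paths[tids[i]], paths[tids[j]]
            if pa == pb:
                continue
            gene_id = min(genes[tids[i]], genes[tids[j]])
            for region in _diff_regions(pa, pb):
                etype = _classify_region(cluster, region)
                if etype is None:
                    logger.warning(
                        "cluster %s: unclassifiable difference region between "
                        "%s and %s (parts %s vs %s); skipped",
                        cluster.cluster_id, tids[i], tids[j],
                        region.a_parts, region.b_parts,
                    )
                    continue
                flanks = [f for f in (region.left, region.right) if f is not None]
                ra = tuple(sorted(region.a_parts + flanks))
                rb = tuple(sorted(region.b_parts + flanks))
                if ra <= rb:
                    path1, path2 = ra, rb
                    var1, var2 = region.a_parts, region.b_parts
                else:
                    path1, path2 = rb, ra
                    var1, var2 = region.b_parts, region.a_parts
                key = (etype, path1, path2)
                if key in seen:
                    continue
                var_all = region.a_parts + region.b_parts
                anchor = GenomicInterval(
                    cluster.chrom,
                    min(cluster.part(k).interval.start for k in var_all),
                    max(cluster.part(k).interval.end for k in var_all),
                    cluster.strand,
                )
                num = _assign_numerator(
                    cluster, etype, path1, path2, region, var1, var2
                )
                ev = SplicingEvent(
                    event_type=etype,
                    path1=path1,
                    path2=path2,
                    numerator_path=num,
                    gene_id=gene_id,
                    cluster_id=cluster.cluster_id,
                    anchor=anchor,
                    chrom=cluster.chrom,
                    strand=cluster.strand,
                )
                ev.event_id = format_event_id(ev)
                seen[key] = ev
    return sorted(seen.values(), key=lambda e: e.event_id)


def format_event_id(event: SplicingEvent) -> str:
    """Serialize an event to its canonical id string.

    Grammar: ``<cluster>|<chrom>|<strand>|<start>-<end>|<gene>|<type>|<p1~p2>``
    with paths dash-joined.
    """
    p1 = "-".join(str(i) for i in event.path1)
    p2 = "-".join(str(i) for i in event.path2)
    return (
        f"{event.cluster_id}|{event.chrom}|{event.strand}|"
        f"{event.anchor.start}-{event.anchor.end}|{event.gene_id}|"
        f"{event.event_type}|{p1}~{p2}"
    )


def parse_event_id(event_id: str) -> dict:
    """Parse a formatted event id back into its components."""
    cluster_id, chrom, strand, pos, gene_id, etype, pp = event_id.split("|")
    start, end = (int(x) for x in pos.split("-"))
    p1s, p2s = pp.split("~")
    return {
        "cluster_id": cluster_id,
        "chrom": chrom,
        "strand": strand,
        "anchor": (start, end),
        "gene_id": gene_id,
        "event_type": etype,
        "path1": tuple(int(x) for x in p1s.split("-")),
        "path2": tuple(int(x) for x in p2s.split("-")),
    }


def enumerate_all_events(clusters: Iterable[GeneCluster]) -> list[SplicingEvent]:
    return [e for c in clusters for e in enumerate_events(c)]
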