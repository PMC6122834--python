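"""Annotation parsing, exonic-part flattening and event enumeration."""

import numpy as np
import pytest

import splicedm as sp
from splicedm.annotation import GtfParseError, transcript_part_path
from splicedm.model import GenomicInterval, TranscriptModel


def _gtf_line(chrom, start1, end1, strand, gene, tx, feature="exon"):
    return (
        f"{chrom}\tsrc\t{feature}\t{start1}\t{end1}\t.\t{strand}\t.\t"
        f'gene_id "{gene}"; transcript_id "{tx}";'
    )


class TestParseGtf:
    def test_coordinate_conversion_to_half_open(self):
        ts = sp.parse_gtf([_gtf_line("chr1", 1, 100, "+", "g", "t")])
        (t,) = ts
        assert (t.exons[0].start, t.exons[0].end) == (0, 100)
        assert len(t.exons[0]) == 100

    def test_exons_grouped_per_transcript(self):
        ts = sp.parse_gtf(
            [
                _gtf_line("chr1", 1, 100, "+", "g", "t"),
                _gtf_line("chr1", 201, 300, "+", "g", "t"),
            ]
        )
        assert len(ts) == 1 and len(ts[0].exons) == 2

    def test_non_exon_features_ignored(self):
        ts = sp.parse_gtf([_gtf_line("chr1", 1, 100, "+", "g", "t", feature="CDS")])
        assert ts == []

    def test_malformed_line_names_line_number(self):
        with pytest.raises(GtfParseError, match="line 2"):
            sp.parse_gtf([_gtf_line("chr1", 1, 100, "+", "g", "t"), "garbage"])

    def test_end_before_start_rejected(self):
        with pytest.raises(GtfParseError, match="end < start"):
            sp.parse_gtf([_gtf_line("chr1", 100, 1, "+", "g", "t")])


class TestClustering:
    def test_disjoint_genes_separate_clusters(self):
        ts = sp.parse_gtf(
            [
                _gtf_line("chr1", 1, 100, "+", "gA", "tA"),
                _gtf_line("chr1", 1001, 1100, "+", "gB", "tB"),
            ]
        )
        assert len(sp.build_gene_clusters(ts)) == 2

    def test_two_transcripts_one_gene_merge(self):
        ts = sp.parse_gtf(
            [
                _gtf_line("chr1", 1, 100, "+", "gA", "t1"),
                _gtf_line("chr1", 51, 200, "+", "gA", "t2"),
            ]
        )
        clusters = sp.build_gene_clusters(ts)
        assert len(clusters) == 1
        assert clusters[0].cluster_id == "gA"

    def test_antisense_overlap_never_merges(self):
        ts = sp.parse_gtf(
            [
                _gtf_line("chr1", 1, 100, "+", "gA", "tA"),
                _gtf_line("chr1", 51, 200, "-", "gB", "tB"),
            ]
        )
        assert len(sp.build_gene_clusters(ts)) == 2


class TestExonicParts:
    def test_single_transcript_parts_equal_exons(self):
        t = TranscriptModel("t", "g", [
            GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300),
        ])
        cluster = sp.build_gene_clusters([t])[0]
        ivs = [(p.interval.start, p.interval.end) for p in cluster.exonic_parts]
        assert ivs == [(0, 100), (200, 300)]
        assert [p.index for p in cluster.exonic_parts] == [1, 2]

    def test_shared_boundary_forces_split(self):
        t1 = TranscriptModel("t1", "g", [GenomicInterval("c", 0, 100)])
        t2 = TranscriptModel("t2", "g", [GenomicInterval("c", 0, 150)])
        cluster = sp.build_gene_clusters([t1, t2])[0]
        ivs = [(p.interval.start, p.interval.end) for p in cluster.exonic_parts]
        assert ivs == [(0, 100), (100, 150)]

    def test_partition_matches_per_base_oracle(self):
        # random toy clusters; parts must be disjoint, sorted, and cover
        # exactly the per-base union of all exons
        rng = np.random.default_rng(42)
        for _ in range(25):
            transcripts = []
            for ti in range(rng.integers(1, 4)):
                cuts = np.sort(rng.choice(np.arange(1, 500), size=6, replace=False))
                exons = [
                    GenomicInterval("c", int(cuts[i]), int(cuts[i + 1]))
                    for i in range(0, 6, 2)
                ]
                transcripts.append(TranscriptModel(f"t{ti}", "g", exons))
            covered = np.zeros(500, dtype=bool)
            for t in transcripts:
                for e in t.exons:
                    covered[e.start:e.end] = True
            cluster = sp.flatten_exonic_parts(
                sp.GeneCluster("g", transcripts)
            )
            part_cover = np.zeros(500, dtype=bool)
            prev_end = -1
            for p in cluster.exonic_parts:
                assert p.interval.start >= prev_end  # disjoint & sorted
                assert not part_cover[p.interval.start:p.interval.end].any()
                part_cover[p.interval.start:p.interval.end] = True
                prev_end = p.interval.end
            assert (part_cover == covered).all()


EXPECTED_TOY_EVENTS = {
    "ES": ((1, 2, 3), (1, 3), 1),
    "A5SS": ((1, 2, 3), (1, 3), 1),
    "A3SS": ((1, 2, 3), (1, 3), 1),
    "ME": ((1, 2, 4), (1, 3, 4), 1),
    "IR": ((1, 2, 3), (1, 3), 1),
    "AFE": ((1, 3), (2, 3), 2),   # proximal first exon is path2
    "ALE": ((1, 2), (1, 3), 1),   # proximal last exon is path1
}


class TestEnumerateEvents:
    def test_toy_cluster_yields_one_event_per_type(self, toy_events):
        assert len(toy_events) == 7
        by_type = {e.event_type: e for e in toy_events}
        assert set(by_type) == set(sp.EVENT_TYPES)
        for etype, (p1, p2, num) in EXPECTED_TOY_EVENTS.items():
            ev = by_type[etype]
            assert (ev.path1, ev.path2, ev.numerator_path) == (p1, p2, num), etype

    def test_identical_transcripts_no_events(self):
        exons = [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300)]
        t1 = TranscriptModel("t1", "g", list(exons))
        t2 = TranscriptModel("t2", "g", list(exons))
        cluster = sp.build_gene_clusters([t1, t2])[0]
        assert sp.enumerate_events(cluster) == []

    def test_paths_realizable_by_some_transcript(self, toy_clusters, toy_events):
        by_cluster = {c.cluster_id: c for c in toy_clusters}
        for ev in toy_events:
            c = by_cluster[ev.cluster_id]
            tx_paths = {transcript_part_path(c, t) for t in c.transcripts}
            for path in (ev.path1, ev.path2):
                assert any(set(path) <= set(tp) for tp in tx_paths)

    def test_invariant_to_transcript_order(self, toy_clusters):
        for c in toy_clusters:
            rev = sp.GeneCluster(c.cluster_id, list(reversed(c.transcripts)))
            sp.flatten_exonic_parts(rev)
            a = [(e.event_type, e.path1, e.path2) for e in sp.enumerate_events(c)]
            b = [(e.event_type, e.path1, e.path2) for e in sp.enumerate_events(rev)]
            assert a == b

    def test_strand_mirror_preserves_event_types(self, toy_clusters):
        # reflect coordinates and flip strand: the classifier must see the
        # same event in transcription-direction terms
        for c in toy_clusters:
            span_hi = max(t.span[1] for t in c.transcripts) + 10
            flip = "-" if c.strand == "+" else "+"
            mirrored = [
                TranscriptModel(
                    t.transcript_id,
                    t.gene_id,
                    [
                        GenomicInterval(e.chrom, span_hi - e.end, span_hi - e.start, flip)
                        for e in t.exons
                    ],
                )
                for t in c.transcripts
            ]
            mc = sp.build_gene_clusters(mirrored)[0]
            orig = sorted(e.event_type for e in sp.enumerate_events(c))
            mirr = sorted(e.event_type for e in sp.enumerate_events(mc))
            assert orig == mirr


class TestEventId:
    def test_round_trip(self, toy_events):
        for ev in toy_events:
            parsed = sp.parse_event_id(sp.format_event_id(ev))
            assert parsed["event_type"] == ev.event_type
            assert parsed["path1"] == ev.path1
            assert parsed["path2"] == ev.path2
            assert parsed["gene_id"] == ev.gene_id
            assert parsed["anchor"] == (ev.anchor.start, ev.anchor.end)

    def test_ids_distinct_and_stable(self, toy_gtf, toy_events):
        ids = [e.event_id for e in toy_events]
        assert len(set(ids)) == len(ids)
        again = sp.enumerate_all_events(
            sp.build_gene_clusters(sp.parse_gtf(toy_gtf.splitlines()))
        )
        assert [e.event_id for e in again] == ids
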