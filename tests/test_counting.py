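"""Alignment parsing, unique filtering, part/junction counting and
event path-support assignment."""

import math

import pytest

import splicedm as sp
from splicedm.counting import (
    AlignmentParseError,
    JunctionCounts,
    PartCounts,
    UniquePolicy,
    count_exonic_parts,
    count_junctions,
)
from splicedm.model import AlignedRead, GenomicInterval, Junction


def _read(blocks, chrom="chrS", n_hits=1, mapq=255, rid="r"):
    return AlignedRead(
        rid, chrom, "+", [GenomicInterval(chrom, s, e) for s, e in blocks], n_hits, mapq
    )


SAM_TEXT = """\
@HD\tVN:1.6\tSO:unordered
@SQ\tSN:chr1\tLN:100000
plain\t0\tchr1\t101\t255\t50M\t*\t0\t0\t*\t*\tNH:i:1
gapped\t0\tchr1\t101\t255\t20M100N30M\t*\t0\t0\t*\t*\tNH:i:1
deletion\t0\tchr1\t101\t255\t10M5D10M\t*\t0\t0\t*\t*\tNH:i:1
multi\t0\tchr1\t101\t255\t50M\t*\t0\t0\t*\t*\tNH:i:2
unmapped\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*
"""


class TestReadAlignments:
    def test_sam_match_block_convention(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_TEXT)
        reads = {r.read_id: r for r in sp.read_alignments(sam, dialect="sam")}
        assert "unmapped" not in reads
        b = reads["plain"].blocks
        assert [(x.start, x.end) for x in b] == [(100, 150)]

    def test_sam_n_gap_splits_blocks_deletion_merges(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_TEXT)
        reads = {r.read_id: r for r in sp.read_alignments(sam, dialect="sam")}
        gapped = reads["gapped"].blocks
        assert [(x.start, x.end) for x in gapped] == [(100, 120), (220, 250)]
        deletion = reads["deletion"].blocks
        assert [(x.start, x.end) for x in deletion] == [(100, 125)]

    def test_tsv_dialect_round_trip(self):
        reads = [_read([(10, 40), (100, 120)], rid="x")]
        text = sp.to_alignment_tsv(reads)
        back = sp.read_alignments(text.splitlines())
        assert [(b.start, b.end) for b in back[0].blocks] == [(10, 40), (100, 120)]
        assert back[0].n_hits == 1 and back[0].mapq == 255

    def test_tsv_malformed_line_errors(self):
        with pytest.raises(AlignmentParseError, match="line 1"):
            sp.read_alignments(["only\tthree\tfields"])


class TestFilterUnique:
    def test_multiplicity_rules(self):
        reads = [
            _read([(0, 50)], n_hits=1, rid="keep"),
            _read([(0, 50)], n_hits=2, rid="drop"),
        ]
        kept = sp.filter_unique(reads)
        assert [r.read_id for r in kept] == ["keep"]

    def test_mapq_fallback_when_multiplicity_missing(self):
        reads = [
            _read([(0, 50)], n_hits=None, mapq=255, rid="hi"),
            _read([(0, 50)], n_hits=None, mapq=10, rid="lo"),
        ]
        kept = sp.filter_unique(reads, UniquePolicy(min_mapq=255))
        assert [r.read_id for r in kept] == ["hi"]


class TestPartAndJunctionCounts:
    def test_block_in_part_and_straddling_blocks(self, toy_clusters):
        es = next(c for c in toy_clusters if c.cluster_id == "GES0000")
        # ES gene occupies [0,100),[200,300),[400,500) on chrS
        inside = _read([(210, 260)])
        straddle = _read([(90, 100), (200, 210)])  # gapped read touching parts 1 and 2
        pc = count_exonic_parts([inside, straddle], [es])
        assert pc.get("GES0000", 2) == 2
        assert pc.get("GES0000", 1) == 1

    def test_read_touching_two_clusters_discarded(self, toy_clusters):
        es = next(c for c in toy_clusters if c.cluster_id == "GES0000")
        a5 = next(c for c in toy_clusters if c.cluster_id == "GA5SS0000")
        bridging = _read([(0, 50), (a5.exonic_parts[0].interval.start, a5.exonic_parts[0].interval.start + 30)])
        pc = count_exonic_parts([bridging], [es, a5])
        assert pc.counts == {}

    def test_junction_exact_match_and_unknown_sink(self, toy_clusters):
        es = next(c for c in toy_clusters if c.cluster_id == "GES0000")
        exact = _read([(80, 100), (200, 220)])      # junction 100->200
        off_by_one = _read([(80, 99), (200, 220)])  # gap 99->200: unannotated
        ungapped = _read([(10, 60)])
        jc = count_junctions([exact, off_by_one, ungapped], [es])
        assert jc.get(Junction("chrS", 100, 200, "+")) == 1
        assert jc.unknown == 1
        assert sum(jc.counts.values()) == 1


class TestAssignEventPathCounts:
    def test_es_exclusive_feature_sum(self, toy_clusters, toy_events):
        # hand-enumerated: inclusion junctions 5+5, skipped part 6 -> x1=16;
        # skip junction 4 -> x2=4
        es_ev = next(e for e in toy_events if e.event_type == "ES")
        cluster = next(c for c in toy_clusters if c.cluster_id == es_ev.cluster_id)
        pc = PartCounts("s", {("GES0000", 2): 6})
        jc = JunctionCounts(
            "s",
            {
                Junction("chrS", 100, 200, "+"): 5,
                Junction("chrS", 300, 400, "+"): 5,
                Junction("chrS", 100, 400, "+"): 4,
            },
        )
        assert sp.assign_event_path_counts(es_ev, cluster, pc, jc) == (16, 4)

    def test_no_reads_zero_counts(self, toy_clusters, toy_events):
        es_ev = next(e for e in toy_events if e.event_type == "ES")
        cluster = next(c for c in toy_clusters if c.cluster_id == es_ev.cluster_id)
        pc, jc = PartCounts("s"), JunctionCounts("s")
        assert sp.assign_event_path_counts(es_ev, cluster, pc, jc) == (0, 0)

    def test_unknown_part_reference_errors(self, toy_clusters, toy_events):
        es_ev = next(e for e in toy_events if e.event_type == "ES")
        cluster = next(c for c in toy_clusters if c.cluster_id == es_ev.cluster_id)
        bad = sp.SplicingEvent(
            event_type="ES", path1=(1, 99), path2=(1, 3), numerator_path=1,
            gene_id="g", cluster_id=cluster.cluster_id,
            anchor=GenomicInterval("chrS", 0, 1), chrom="chrS", strand="+",
        )
        with pytest.raises(ValueError, match="unknown part"):
            sp.assign_event_path_counts(bad, cluster, PartCounts("s"), JunctionCounts("s"))


class TestEndToEndCounting:
    def test_skip_only_mixture_gives_zero_inclusion(self, toy_clusters, toy_transcripts, toy_events):
        reads = sp.simulate_reads(
            toy_transcripts, {"GES0000": {"GES0000.T2": 1.0}}, depth=300, seed=2
        )
        counts = sp.build_event_counts(
            toy_events, toy_clusters, {"s1": reads}, {"s1": "mutant"}
        )
        es = counts[counts.event_id.str.contains("|ES|", regex=False)].iloc[0]
        assert es.x1 == 0 and es.x2 > 0

    def test_multimapped_reads_contribute_zero(self, toy_clusters, toy_events):
        multi = _read([(210, 260)], n_hits=2)
        counts = sp.build_event_counts(
            toy_events, toy_clusters, {"s1": [multi]}, {"s1": "mutant"}
        )
        assert (counts[["x1", "x2"]] == 0).all().all()

    def test_mixture_proportions_converge(self, toy_clusters, toy_transcripts, toy_events):
        # 50/50 ES mixture at depth 10,000; expected exclusive-feature counts
        # from uniform read placement:
        #   T1 (len 300, reads 50): part2 hit 149/251, junction 1-2 and 2-3
        #     each 49/251 -> E[x1 per T1 read] = 247/251
        #   T2 (len 200): skip junction 49/151 -> E[x2 per T2 read] = 49/151
        depth = 10_000
        reads = sp.simulate_reads(
            toy_transcripts,
            {"GES0000": {"GES0000.T1": 0.5, "GES0000.T2": 0.5}},
            depth=depth, read_len=50, seed=7,
        )
        counts = sp.build_event_counts(
            toy_events, toy_clusters, {"s1": reads}, {"s1": "mutant"}
        )
        es = counts[counts.event_id.str.contains("|ES|", regex=False)].iloc[0]
        e_x1 = 0.5 * depth * (247 / 251)
        e_x2 = 0.5 * depth * (49 / 151)
        # a read can hit up to two inclusion features; 3 SE with a
        # conservative per-read variance bound of 2*mean
        assert abs(es.x1 - e_x1) < 3 * math.sqrt(2 * e_x1)
        assert abs(es.x2 - e_x2) < 3 * math.sqrt(e_x2)

    def test_counting_independent_of_read_order(self, toy_clusters, toy_transcripts, toy_events):
        reads = sp.simulate_reads(
            toy_transcripts,
            {"GES0000": {"GES0000.T1": 0.5, "GES0000.T2": 0.5}},
            depth=500, seed=3,
        )
        fwd = sp.build_event_counts(toy_events, toy_clusters, {"s": reads}, {"s": "m"})
        rev = sp.build_event_counts(
            toy_events, toy_clusters, {"s": list(reversed(reads))}, {"s": "m"}
        )
        assert fwd.equals(rev)
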