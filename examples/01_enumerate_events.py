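"""Enumerate the seven alternative-splicing event types from an annotation.

Builds a small two-transcript-per-gene annotation, flattens each gene
cluster into numbered exonic parts, and prints every event with its two
paths.  Path 1 / path 2 are exonic-part index lists; the numerator path is
the one whose usage defines PSI (longer isoform, or proximal terminal exon
for AFE/ALE).
"""

import splicedm as sp

gtf = sp.make_toy_annotation(n_events_per_type=1, seed=0)
clusters = sp.build_gene_clusters(sp.parse_gtf(gtf.splitlines()))
events = sp.enumerate_all_events(clusters)

print(f"{'type':<6}{'path1':<10}{'path2':<10}{'PSI path':<10}event_id")
for ev in events:
    p1 = "-".join(map(str, ev.path1))
    p2 = "-".join(map(str, ev.path2))
    print(f"{ev.event_type:<6}{p1:<10}{p2:<10}{ev.numerator_path:<10}{ev.event_id}")
print(f"\n{len(events)} events from {len(clusters)} gene clusters.")
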