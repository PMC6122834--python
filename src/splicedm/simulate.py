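"""Synthetic data emulating the study design: two conditions with two
biological replicates each, per-event two-path counts drawn from the
Dirichlet-multinomial generative model, plus toy annotations and gapped
synthetic reads so the whole pipeline is testable end to end.

The count generator IS the fitted model: per sample the event depth is
Poisson, the replicate-level path-1 proportion is Beta(s*pi, s*(1-pi)),
and the path-1 count is binomial given both — exactly the two-category
Dirichlet-multinomial.  What it does not emulate: sequence content,
alignment error, positional coverage bias, and shared reads between
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import EVENT_TYPES, AlignedRead, TranscriptModel

# fixed offsets carving independent substreams out of one master seed
_SEED_MOD = 2**31
SUBSTREAM_ANNOTATION = 1
SUBSTREAM_COUNTS = 2
SUBSTREAM_READS = 3


def substream_seed(seed: int, offset: int) -> int:
    return (int(seed) + offset) % _SEED_MOD


@dataclass
class SimConfig:
    """Study-design parameters for count simulation.

    Defaults mirror the emulated experiment: two replicates per condition,
    moderate depth, and a base inclusion level of one half.
    """

    n_events_per_type: int = 1
    depth_mean: float = 100.0
    s_true: float = 20.0
    delta_psi_true: Union[float, Sequence[float]] = 0.0
    pi_base: Union[float, Sequence[float]] = 0.5
    n_replicates: int = 2
    seed: int = 0
    mutant: str = "mutant"
    control: str = "control"

    def __post_init__(self) -> None:
        if self.n_events_per_type < 0:
            raise ValueError("n_events_per_type must be >= 0")
        if self.depth_mean <= 0 or self.s_true <= 0 or self.n_replicates < 1:
            raise ValueError("depth_mean, s_true and n_replicates must be positive")


# Per-type exon templates (relative 0-based half-open coordinates) for two
# transcripts that differ by exactly one event of the named type.
_TEMPLATES: dict[str, tuple[list, list]] = {
    "ES":   ([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]),
    "A5SS": ([(0, 150), (400, 500)],             [(0, 100), (400, 500)]),
    "A3SS": ([(0, 100), (350, 500)],             [(0, 100), (400, 500)]),
    "ME":   ([(0, 100), (200, 320), (600, 700)], [(0, 100), (400, 500), (600, 700)]),
    "IR":   ([(0, 500)],                          [(0, 100), (400, 500)]),
    "AFE":  ([(0, 100), (600, 700)],             [(300, 400), (600, 700)]),
    "ALE":  ([(0, 100), (200, 300)],             [(0, 100), (500, 600)]),
}
_TEMPLATE_SPAN = 1000
_CONST_TEMPLATE = [(0, 100), (300, 400)]


def make_toy_annotation(
    n_events_per_type: int = 1, seed: int = 0, chrom: str = "chrS"
) -> str:
    """GTF text with ``n_events_per_type`` genes per event type, each a
    two-transcript gene realizing exactly one event, plus one
    constitutive-only gene.  Byte-identical for identical arguments."""
    rng = np.random.default_rng(substream_seed(seed, SUBSTREAM_ANNOTATION))
    lines: list[str] = []
    offset = 0

    def emit(gene_id: str, transcript_id: str, exons, off: int) -> None:
        for s, e in exons:
            attrs = f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'
            lines.append(
                f"{chrom}\tsplicedm_sim\texon\t{off + s + 1}\t{off + e}\t.\t+\t.\t{attrs}"
            )

    for k in range(n_events_per_type):
        for etype in EVENT_TYPES:
            gid = f"G{etype}{k:04d}"
            t1, t2 = _TEMPLATES[etype]
            emit(gid, f"{gid}.T1", t1, offset)
            emit(gid, f"{gid}.T2", t2, offset)
            offset += _TEMPLATE_SPAN + int(rng.integers(500, 1500))
    gid = "GCONST0000"
    emit(gid, f"{gid}.T1", _CONST_TEMPLATE, offset)
    return "\n".join(lines) + "\n"


@dataclass
class SimTruth:
    """Ground truth of one simulated count table."""

    table: pd.DataFrame  # event_id, event_type, pi_mut, pi_ctrl, s, depth_<sample>
    config: SimConfig = field(repr=False, default=None)


def simulate_event_counts(
    config: SimConfig, event_ids: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw per-event, per-sample two-path counts from the generative model.

    Per sample: n ~ Poisson(depth_mean); p ~ Beta(s*pi_c, s*(1-pi_c));
    x1 ~ Binomial(n, p).  pi_mut = pi_base + delta_psi_true (per-event or
    global).  Returns the event-counts table and the ground truth.
    """
    if event_ids is None:
        n_events = config.n_events_per_type * len(EVENT_TYPES)
        event_ids = [
            f"SIM:{EVENT_TYPES[i % len(EVENT_TYPES)]}:{i:05d}" for i in range(n_events)
        ]
        etypes = [EVENT_TYPES[i % len(EVENT_TYPES)] for i in range(n_events)]
    else:
        event_ids = list(event_ids)
        n_events = len(event_ids)
        etypes = ["NA"] * n_events
    pi_ctrl = np.broadcast_to(
        np.asarray(config.pi_base, dtype=float), (n_events,)
    ).copy()
    delta = np.broadcast_to(
        np.asarray(config.delta_psi_true, dtype=float), (n_events,)
    ).copy()
    pi_mut = pi_ctrl + delta
    if np.any((pi_mut <= 0) | (pi_mut >= 1) | (pi_ctrl <= 0) | (pi_ctrl >= 1)):
        raise ValueError("pi_base and pi_base + delta_psi_true must lie in (0,1)")
    rng = np.random.default_rng(substream_seed(config.seed, SUBSTREAM_COUNTS))
    samples = [
        (f"{config.mutant}_{r + 1}", config.mutant) for r in range(config.n_replicates)
    ] + [
        (f"{config.control}_{r + 1}", config.control) for r in range(config.n_replicates)
    ]
    rows = []
    depth_cols: dict[str, list[int]] = {s: [] for s, _ in samples}
    for i, eid in enumerate(event_ids):
        for sample_id, cond in samples:
            pi = pi_mut[i] if cond == config.mutant else pi_ctrl[i]
            n = int(rng.poisson(config.depth_mean))
            if n == 0:
                x1 = 0
            else:
                p = rng.beta(config.s_true * pi, config.s_true * (1.0 - pi))
                x1 = int(rng.binomial(n, p))
            rows.append(
                {
                    "event_id": eid,
                    "sample_id": sample_id,
                    "condition": cond,
                    "x1": x1,
                    "x2": n - x1,
                }
            )
            depth_cols[sample_id].append(n)
    counts = pd.DataFrame(rows, columns=["event_id", "sample_id", "condition", "x1", "x2"])
    truth_df = pd.DataFrame(
        {
            "event_id": event_ids,
            "event_type": etypes,
            "pi_mut": pi_mut,
            "pi_ctrl": pi_ctrl,
            "s": config.s_true,
        }
    )
    for sample_id, _ in samples:
        truth_df[f"depth_{sample_id}"] = depth_cols[sample_id]
    return counts, SimTruth(table=truth_df, config=config)


def simulate_reads(
    transcripts: Sequence[TranscriptModel],
    isoform_mixture: dict[str, dict[str, float]],
    depth: int,
    read_len: int = 50,
    seed: int = 0,
) -> list[AlignedRead]:
    """Uniform single-end reads from a per-gene isoform mixture.

    ``isoform_mixture`` maps gene_id -> {transcript_id: proportion}; the
    proportions must sum to 1 per gene.  ``depth`` reads are drawn per gene
    with uniform start positions along the chosen transcript; reads
    crossing exon boundaries become gapped multi-block alignments.  All
    reads are emitted uniquely mapped (n_hits=1, mapq=255).
    """
    by_tid = {t.transcript_id: t for t in transcripts}
    for gene_id, mix in isoform_mixture.items():
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"mixture for gene {gene_id} sums to {total}, not 1")
        for tid in mix:
            if tid not in by_tid:
                raise ValueError(f"unknown transcript {tid} in mixture")
    rng = np.random.default_rng(substream_seed(seed, SUBSTREAM_READS))
    reads: list[AlignedRead] = []
    for gene_id in sorted(isoform_mixture):
        mix = isoform_mixture[gene_id]
        tids = sorted(mix)
        probs = np.array([mix[t] for t in tids])
        choices = rng.choice(len(tids), size=depth, p=probs)
        for i, ci in enumerate(choices):
            t = by_tid[tids[ci]]
            tlen = sum(len(e) for e in t.exons)
            rl = min(read_len, tlen)
            start = int(rng.integers(0, tlen - rl + 1))
            blocks = _transcript_to_genome_blocks(t, start, start + rl)
            reads.append(
                AlignedRead(
                    read_id=f"{gene_id}_r{i:06d}",
                    chrom=t.chrom,
                    strand=t.strand,
                    blocks=blocks,
                    n_hits=1,
                    mapq=255,
                )
            )
    return reads


def _transcript_to_genome_blocks(t: TranscriptModel, tstart: int, tend: int):
    """Map a transcript-coordinate interval to genomic match blocks."""
    from .model import GenomicInterval

    blocks = []
    pos = 0
    for e in t.exons:
        elen = len(e)
        lo = max(tstart, pos)
        hi = min(tend, pos + elen)
        if lo < hi:
            blocks.append(
                GenomicInterval(t.chrom, e.start + (lo - pos), e.start + (hi - pos), t.strand)
            )
        pos += elen
        if pos >= tend:
            break
    return blocks


def to_alignment_tsv(reads: Sequence[AlignedRead]) -> str:
    """Serialize reads in the simplified alignment TSV dialect."""
    lines = []
    for r in reads:
        blocks = ",".join(f"{b.start}-{b.end}" for b in r.blocks)
        n_hits = "." if r.n_hits is None else str(r.n_hits)
        lines.append(
            f"{r.read_id}\t{r.chrom}\t{r.strand}\t{blocks}\t{n_hits}\t{r.mapq}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
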