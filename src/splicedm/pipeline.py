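"""Run orchestration: config, the events→counts→test→report chain, and
run manifests that make every run reproducible bit for bit."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotation as anno
from . import counting, das, expression
from .model import GeneCluster

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    annotation: Optional[str] = None
    counts: Optional[str] = None              # precomputed event-counts TSV
    alignments: dict[str, str] = field(default_factory=dict)  # sample -> path
    alignment_dialect: str = "tsv"
    gene_counts: Optional[str] = None         # gene_id, length, <samples...>
    output_dir: str = "splicedm_out"
    conditions: dict[str, str] = field(default_factory=dict)  # sample -> label
    mutant: str = "mutant"
    control: str = "control"
    dpsi_thresh: float = das.DPSI_THRESHOLD
    q_thresh: float = das.Q_THRESHOLD
    fold_thresh: float = expression.FOLD_THRESHOLD
    min_count: int = das.MIN_COUNT
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for t, name in (
            (self.dpsi_thresh, "dpsi_thresh"),
            (self.q_thresh, "q_thresh"),
            (self.fold_thresh, "fold_thresh"),
        ):
            if t <= 0:
                raise ConfigError(f"{name} must be positive, got {t}")
        labels = set(self.conditions.values())
        if self.conditions and labels != {self.mutant, self.control}:
            raise ConfigError(
                f"condition map must use exactly the two labels "
                f"{{{self.mutant!r}, {self.control!r}}}, got {sorted(labels)}"
            )
        for p in filter(None, [self.annotation, self.counts, self.gene_counts]):
            if not Path(p).exists():
                raise ConfigError(f"input file does not exist: {p}")
        for sample, p in self.alignments.items():
            if not Path(p).exists():
                raise ConfigError(f"alignment file for {sample} does not exist: {p}")
            if sample not in self.conditions:
                raise ConfigError(f"sample {sample} missing from condition map")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_annotation(path: str | Path) -> list[GeneCluster]:
    with open(path) as fh:
        transcripts = anno.parse_gtf(fh)
    return anno.build_gene_clusters(transcripts)


def _event_counts(config: RunConfig, clusters, events) -> pd.DataFrame:
    if config.counts:
        return counting.read_event_counts(config.counts)
    if not config.alignments:
        raise ConfigError("need either a counts table or per-sample alignments")
    sample_reads = {
        sample: counting.read_alignments(path, config.alignment_dialect)
        for sample, path in config.alignments.items()
    }
    return counting.build_event_counts(
        events, clusters, sample_reads, config.conditions
    )


def run_das(config: RunConfig) -> pd.DataFrame:
    """Full differential-splicing run; writes results.tsv and manifest.json.

    Pipeline order: enumerate events from the annotation, obtain per-sample
    path counts (from alignments or a precomputed table), test each event
    with the Dirichlet-multinomial LRT, BH-adjust pooled p-values, compute
    PSI/delta-PSI, and apply the significance rule.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_by_id = None
    clusters: list[GeneCluster] = []
    annotation_hash = None
    if config.annotation:
        clusters = load_annotation(config.annotation)
        events = anno.enumerate_all_events(clusters)
        events_by_id = {e.event_id: e for e in events}
        annotation_hash = file_sha256(config.annotation)
    elif not config.counts:
        raise ConfigError("need an annotation unless a counts table is supplied")
    counts = _event_counts(
        config, clusters, list(events_by_id.values()) if events_by_id else []
    )
    results = das.test_events(
        counts,
        events=events_by_id,
        mutant=config.mutant,
        control=config.control,
        min_count=config.min_count,
        dpsi_thresh=config.dpsi_thresh,
        q_thresh=config.q_thresh,
    )
    if len(results) == 0:
        logger.warning("zero testable events; writing empty result table")
    das.write_results(results, outdir / "results.tsv")
    manifest = {
        "stage": "das",
        "inputs": {
            "annotation": config.annotation,
            "counts": config.counts,
            "alignments": config.alignments,
        },
        "annotation_sha256": annotation_hash,
        "thresholds": {
            "dpsi": config.dpsi_thresh,
            "q": config.q_thresh,
            "min_count": config.min_count,
        },
        "conditions": config.conditions,
        "mutant": config.mutant,
        "control": config.control,
        "seed": config.seed,
        "n_tested": int(len(results)),
        "n_significant": int(results["significant"].sum()) if len(results) else 0,
        "untestable_events": results.attrs.get("untestable", []),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results.attrs["annotation_sha256"] = annotation_hash
    return results


def run_expression(config: RunConfig) -> pd.DataFrame:
    """RPKM + 2-fold calling; writes expression.tsv and a manifest."""
    config.validate()
    if not config.gene_counts:
        raise ConfigError("expression stage needs a gene_counts table")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(config.gene_counts, sep="\t")
    if "gene_id" not in table.columns:
        raise ConfigError("gene_counts table must have a gene_id column")
    if "length" in table.columns:
        lengths = table.set_index("gene_id")["length"]
        count_cols = [c for c in table.columns if c not in ("gene_id", "length")]
    elif config.annotation:
        clusters = load_annotation(config.annotation)
        lengths = pd.Series(expression.gene_lengths(clusters))
        count_cols = [c for c in table.columns if c != "gene_id"]
    else:
        raise ConfigError("need a length column or an annotation for gene lengths")
    missing = set(count_cols) - set(config.conditions)
    if missing:
        raise ConfigError(f"samples missing from condition map: {sorted(missing)}")
    counts = table.set_index("gene_id")[count_cols]
    result = expression.expression_table(
        counts,
        lengths,
        config.conditions,
        mutant=config.mutant,
        control=config.control,
        fold_threshold=config.fold_thresh,
    )
    result.to_csv(outdir / "expression.tsv", sep="\t", index=False, float_format="%.6g")
    manifest = {
        "stage": "expression",
        "inputs": {"gene_counts": config.gene_counts, "annotation": config.annotation},
        "thresholds": {"fold": config.fold_thresh},
        "conditions": config.conditions,
        "n_genes": int(len(result)),
        "n_up": int((result["regulation"] == "up").sum()),
        "n_down": int((result["regulation"] == "down").sum()),
    }
    with open(outdir / "expression_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


def report_overlap(
    results_a: pd.DataFrame | str | Path,
    results_b: pd.DataFrame | str | Path,
    hash_a: Optional[str] = None,
    hash_b: Optional[str] = None,
) -> das.OverlapSummary:
    """Overlap of significant events between two runs (e.g. two mutants)."""
    if not isinstance(results_a, pd.DataFrame):
        results_a = pd.read_csv(results_a, sep="\t")
    if not isinstance(results_b, pd.DataFrame):
        results_b = pd.read_csv(results_b, sep="\t")
    return das.compare_mutant_results(results_a, results_b, hash_a, hash_b)
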