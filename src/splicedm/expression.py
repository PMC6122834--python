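"""RPKM normalization and two-fold expression-change calling.

RPKM = count / ((gene length in kb) * (library total in millions)); genes
are called up- or down-regulated when the mutant/control ratio of mean
replicate RPKM reaches 2-fold (inclusive boundaries), with a small floor on
the means to keep ratios finite at very low expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FOLD_THRESHOLD = 2.0
RPKM_FLOOR = 0.1


def compute_rpkm(count, length_bp, library_total):
    """Reads per kilobase of gene per million mapped reads (vectorized)."""
    length_bp = np.asarray(length_bp, dtype=float)
    library_total = np.asarray(library_total, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("gene length must be positive")
    if np.any(library_total <= 0):
        raise ValueError("library total must be positive")
    out = np.asarray(count, dtype=float) / ((length_bp / 1e3) * (library_total / 1e6))
    return out if out.ndim else float(out)


def fold_change_call(
    mean_rpkm_mut: float,
    mean_rpkm_ctrl: float,
    fold_threshold: float = FOLD_THRESHOLD,
    floor: float = RPKM_FLOOR,
) -> tuple[float, str]:
    """Floored mutant/control fold change and its regulation call.

    ``up`` when fold >= threshold, ``down`` when fold <= 1/threshold,
    else ``none``.
    """
    if mean_rpkm_mut < 0 or mean_rpkm_ctrl < 0:
        raise ValueError("mean RPKM must be non-negative")
    fold = max(mean_rpkm_mut, floor) / max(mean_rpkm_ctrl, floor)
    if fold >= fold_threshold:
        regulation = "up"
    elif fold <= 1.0 / fold_threshold:
        regulation = "down"
    else:
        regulation = "none"
    return fold, regulation


def expression_table(
    counts: pd.DataFrame,
    lengths: dict[str, int] | pd.Series,
    condition_map: dict[str, str],
    mutant: str = "mutant",
    control: str = "control",
    library_totals: dict[str, int] | None = None,
    fold_threshold: float = FOLD_THRESHOLD,
    floor: float = RPKM_FLOOR,
) -> pd.DataFrame:
    """Per-gene RPKM, condition means, fold change and regulation call.

    ``counts`` is a genes x samples table of raw unique-read counts
    (gene_id index, sample columns).  ``library_totals`` defaults to the
    per-sample column sums.  Condition means are arithmetic means of
    per-sample RPKM.
    """
    lengths = pd.Series(lengths)
    missing = set(counts.index) - set(lengths.index)
    if missing:
        raise ValueError(f"genes without length: {sorted(missing)[:5]}...")
    samples = list(counts.columns)
    unknown = set(samples) - set(condition_map)
    if unknown:
        raise ValueError(f"samples without condition label: {sorted(unknown)}")
    if counts.empty:
        cols = ["gene_id"] + [f"rpkm_{s}" for s in samples] + [
            "mean_mut", "mean_ctrl", "fold_change", "regulation",
        ]
        return pd.DataFrame(columns=cols)
    if library_totals is None:
        library_totals = counts.sum(axis=0).to_dict()
    rpkm = pd.DataFrame(index=counts.index)
    for s in samples:
        rpkm[f"rpkm_{s}"] = compute_rpkm(
            counts[s].to_numpy(), lengths.loc[counts.index].to_numpy(),
            library_totals[s],
        )
    mut_cols = [f"rpkm_{s}" for s in samples if condition_map[s] == mutant]
    ctrl_cols = [f"rpkm_{s}" for s in samples if condition_map[s] == control]
    if not mut_cols or not ctrl_cols:
        raise ValueError("need at least one sample per condition")
    rpkm["mean_mut"] = rpkm[mut_cols].mean(axis=1)
    rpkm["mean_ctrl"] = rpkm[ctrl_cols].mean(axis=1)
    folds, regs = [], []
    for m, c in zip(rpkm["mean_mut"], rpkm["mean_ctrl"]):
        f, r = fold_change_call(m, c, fold_threshold, floor)
        folds.append(f)
        regs.append(r)
    rpkm["fold_change"] = folds
    rpkm["regulation"] = regs
    rpkm.insert(0, "gene_id", rpkm.index)
    return rpkm.reset_index(drop=True)


def gene_lengths(clusters) -> dict[str, int]:
    """Exonic-union length per gene (union over all of its transcripts)."""
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        for t in c.transcripts:
            by_gene.setdefault(t.gene_id, []).extend(
                (e.start, e.end) for e in t.exons
            )
    out = {}
    for gid, ivs in by_gene.items():
        ivs.sort()
        total, cur_s, cur_e = 0, *ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        out[gid] = total
    return out
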