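"""Differential alternative-splicing analysis over an event-counts table.

Each event carries replicate path counts for two conditions (mutant vs
control).  Per event the Dirichlet-multinomial likelihood-ratio test yields
a p-value; Benjamini-Hochberg adjustment across all tested events yields
q-values; PSI per condition comes from the alternative-model MLE mapped to
the event's numerator path; an event is called significant when
|delta PSI| > 0.03 and q < 0.25 (both strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import parse_event_id
from .dm import PI_EPS, estimate_dispersion_mom, likelihood_ratio_test
from .model import EVENT_TYPES, SplicingEvent

logger = logging.getLogger(__name__)

DPSI_THRESHOLD = 0.03
Q_THRESHOLD = 0.25
MIN_COUNT = 10

RESULT_COLUMNS = [
    "event_id", "event_type", "path1", "path2",
    "logodds_mut", "logodds_ctrl", "logoddsratio",
    "pval", "qval", "psi_mut", "psi_ctrl", "delta_psi",
    "significant", "favored_path",
]

# column aliases matching the published supplementary-table schema
S4_COLUMN_ALIASES = {
    "event_id": "Event_id", "event_type": "Event_type",
    "path1": "Path1", "path2": "Path2",
    "logodds_mut": "logoddsB", "logodds_ctrl": "logoddsW",
    "logoddsratio": "logoddratio", "pval": "pval", "qval": "qval",
    "psi_mut": "PSI_B", "psi_ctrl": "PSI_W", "delta_psi": "Delta_PSI",
}


class IntegrityError(RuntimeError):
    pass


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending sort order,
    mapped back to the input order and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def logit(p: float) -> float:
    p = min(max(p, PI_EPS), 1.0 - PI_EPS)
    return float(np.log(p) - np.log1p(-p))


def compute_psi(pi_path1: float, numerator_path: int) -> float:
    """Map the fitted path-1 proportion to PSI of the numerator path."""
    return pi_path1 if numerator_path == 1 else 1.0 - pi_path1


def compute_log_odds(psi_mut: float, psi_ctrl: float) -> tuple[float, float, float]:
    """Natural-log odds per condition and their difference (mutant - control)."""
    lo_m = logit(psi_mut)
    lo_c = logit(psi_ctrl)
    return lo_m, lo_c, lo_m - lo_c


def call_significant(
    delta_psi: float,
    qval: float,
    numerator_path: int,
    dpsi_thresh: float = DPSI_THRESHOLD,
    q_thresh: float = Q_THRESHOLD,
) -> tuple[bool, int]:
    """Apply the strict |dPSI| > threshold AND q < threshold rule.

    Returns (significant, favored_path) where favored_path is the path
    gaining usage in the mutant (the numerator path when delta_psi > 0).
    """
    significant = abs(delta_psi) > dpsi_thresh and qval < q_thresh
    other = 2 if numerator_path == 1 else 1
    favored = numerator_path if delta_psi >= 0 else other
    return significant, favored


def _event_meta(event_id: str, events: dict[str, SplicingEvent] | None):
    if events is not None and event_id in events:
        ev = events[event_id]
        return ev.event_type, ev.path1, ev.path2, ev.numerator_path
    try:
        info = parse_event_id(event_id)
        # numerator orientation is not recoverable from the id alone;
        # default to path1 (PSI then refers to path1 usage)
        return info["event_type"], info["path1"], info["path2"], 1
    except Exception:
        pass
    fields = event_id.split(":")
    if len(fields) == 3 and fields[0] == "SIM" and fields[1] in EVENT_TYPES:
        return fields[1], (), (), 1
    return "NA", (), (), 1


def test_events(
    counts: pd.DataFrame,
    events: dict[str, SplicingEvent] | None = None,
    mutant: str = "mutant",
    control: str = "control",
    min_count: int = MIN_COUNT,
    dpsi_thresh: float = DPSI_THRESHOLD,
    q_thresh: float = Q_THRESHOLD,
    dispersion: str = "pooled",
) -> pd.DataFrame:
    """Run the full per-event analysis over an event-counts table.

    ``counts`` columns: event_id, sample_id, condition, x1, x2 (x1 supports
    path1).  An event is testable only when each condition has at least one
    sample and replicate-summed depth x1 + x2 >= ``min_count``.  With
    ``dispersion='pooled'`` (default) one precision is estimated across all
    events from within-condition replicate scatter and held fixed per
    event, which keeps the chi-square reference calibrated at two
    replicates; ``'per-event'`` re-estimates it per event instead.  BH is
    applied once, pooled across all event types.  Untestable event ids are
    recorded in ``result.attrs['untestable']``; the shared precision in
    ``result.attrs['dispersion_s']``.
    """
    if dispersion not in ("pooled", "per-event"):
        raise ValueError(f"dispersion must be 'pooled' or 'per-event', got {dispersion!r}")
    labels = set(counts["condition"].unique())
    if not {mutant, control} <= labels:
        missing = {mutant, control} - labels
        raise ValueError(f"conditions missing from counts table: {sorted(missing)}")
    testable = []
    untestable: list[str] = []
    for event_id, grp in counts.groupby("event_id", sort=True):
        g_mut = grp[grp["condition"] == mutant]
        g_ctrl = grp[grp["condition"] == control]
        n_mut = int(g_mut["x1"].sum() + g_mut["x2"].sum())
        n_ctrl = int(g_ctrl["x1"].sum() + g_ctrl["x2"].sum())
        if len(g_mut) == 0 or len(g_ctrl) == 0 or n_mut < min_count or n_ctrl < min_count:
            untestable.append(event_id)
            continue
        # per-sample zero-depth replicates carry no information; drop them
        x1m = g_mut["x1"].to_numpy()
        x2m = g_mut["x2"].to_numpy()
        keep_m = (x1m + x2m) > 0
        x1c = g_ctrl["x1"].to_numpy()
        x2c = g_ctrl["x2"].to_numpy()
        keep_c = (x1c + x2c) > 0
        testable.append(
            (event_id, x1m[keep_m], x2m[keep_m], x1c[keep_c], x2c[keep_c])
        )
    s_fixed = None
    if dispersion == "pooled" and testable:
        units = [(x1m, x2m) for _, x1m, x2m, _, _ in testable]
        units += [(x1c, x2c) for _, _, _, x1c, x2c in testable]
        s_fixed = estimate_dispersion_mom(units)
        logger.info("pooled precision estimate s = %.4g", s_fixed)
    rows = []
    for event_id, x1m, x2m, x1c, x2c in testable:
        lrt, _null, alt = likelihood_ratio_test(x1m, x2m, x1c, x2c, s_fixed=s_fixed)
        etype, path1, path2, num_path = _event_meta(event_id, events)
        psi_mut = compute_psi(alt.fit_mut.pi, num_path)
        psi_ctrl = compute_psi(alt.fit_ctrl.pi, num_path)
        lo_m, lo_c, lor = compute_log_odds(psi_mut, psi_ctrl)
        rows.append(
            {
                "event_id": event_id,
                "event_type": etype,
                "path1": "-".join(map(str, path1)),
                "path2": "-".join(map(str, path2)),
                "logodds_mut": lo_m,
                "logodds_ctrl": lo_c,
                "logoddsratio": lor,
                "pval": lrt.pval,
                "psi_mut": psi_mut,
                "psi_ctrl": psi_ctrl,
                "delta_psi": psi_mut - psi_ctrl,
                "_numerator_path": num_path,
            }
        )
    if untestable:
        logger.info("%d events untestable under min_count=%d", len(untestable), min_count)
    if not rows:
        result = pd.DataFrame(columns=RESULT_COLUMNS)
        result.attrs["untestable"] = untestable
        result.attrs["dispersion_s"] = s_fixed
        return result
    result = pd.DataFrame(rows)
    result["qval"] = bh_adjust(result["pval"].to_numpy())
    sig, fav = [], []
    for _, r in result.iterrows():
        s, f = call_significant(
            r["delta_psi"], r["qval"], int(r["_numerator_path"]),
            dpsi_thresh, q_thresh,
        )
        sig.append(s)
        fav.append(f)
    result["significant"] = sig
    result["favored_path"] = fav
    result = result[RESULT_COLUMNS]
    result.attrs["untestable"] = untestable
    result.attrs["dispersion_s"] = s_fixed
    return result


@dataclass
class OverlapSummary:
    only_a: set[str]
    common: set[str]
    only_b: set[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.only_a), len(self.common), len(self.only_b)


def compare_mutant_results(
    results_a: pd.DataFrame | set,
    results_b: pd.DataFrame | set,
    annotation_hash_a: str | None = None,
    annotation_hash_b: str | None = None,
) -> OverlapSummary:
    """Overlap of significant event ids between two mutant-vs-control runs.

    Both runs must come from the same annotation (same event-id space);
    mismatched annotation hashes raise :class:`IntegrityError`.
    """
    if (
        annotation_hash_a is not None
        and annotation_hash_b is not None
        and annotation_hash_a != annotation_hash_b
    ):
        raise IntegrityError(
            "result sets come from different annotations; overlap undefined"
        )
    set_a = _significant_ids(results_a)
    set_b = _significant_ids(results_b)
    return OverlapSummary(
        only_a=set_a - set_b, common=set_a & set_b, only_b=set_b - set_a
    )


def _significant_ids(results) -> set[str]:
    if isinstance(results, pd.DataFrame):
        return set(results.loc[results["significant"], "event_id"])
    return set(results)


def write_results(
    results: pd.DataFrame, path, s4_style: bool = False
) -> None:
    """Write the result TSV; ``s4_style`` renames columns to the published
    supplementary-table schema."""
    df = results
    if s4_style:
        df = results.rename(columns=S4_COLUMN_ALIASES)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
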