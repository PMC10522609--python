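"""qPCR relative expression (2^-ΔCT) and predicted-vs-observed concordance.

Relative expression per sample is 2^-(Ct_target - Ct_housekeeping); values
are then normalized to the reference-group mean per gene.  Group comparison
uses the normality-driven test selection, and a prediction is validated when
the observed change is significant and in the predicted direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import compare_two

logger = logging.getLogger(__name__)

__all__ = [
    "delta_ct",
    "relative_expression",
    "normalize_to_group",
    "compare_expression",
    "concordance",
]

DEFAULT_ALPHA = 0.05

QPCR_COLUMNS = ["sample_id", "group", "gene_id", "ct_target", "ct_housekeeping"]


def delta_ct(ct_target: float, ct_housekeeping: float) -> float:
    """Relative expression 2^-(Ct_target - Ct_housekeeping)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_housekeeping)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_housekeeping)


def relative_expression(qpcr: pd.DataFrame,
                        blacklist: set[str] | None = None) -> pd.DataFrame:
    """Add ``rel_expr`` to a long Ct table; drop blacklisted samples.

    Required columns: ``sample_id, group, gene_id, ct_target,
    ct_housekeeping``.  The blacklist models explicit technical exclusions.
    """
    missing = [c for c in QPCR_COLUMNS if c not in qpcr.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    out = qpcr.copy()
    if blacklist:
        n_before = out.sample_id.nunique()
        out = out[~out.sample_id.isin(blacklist)]
        logger.info("excluded %d blacklisted samples", n_before - out.sample_id.nunique())
    out["rel_expr"] = [
        delta_ct(r.ct_target, r.ct_housekeeping) for r in out.itertuples()
    ]
    return out


def normalize_to_group(rel: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Divide each gene's ``rel_expr`` by its reference-group mean.

    Adds ``rel_to_reference``; the reference-group mean becomes exactly 1.
    """
    if reference_group not in set(rel.group):
        raise ValueError(f"reference group {reference_group!r} absent")
    ref_means = (rel[rel.group == reference_group]
                 .groupby("gene_id").rel_expr.mean())
    out = rel.copy()
    out["rel_to_reference"] = out.rel_expr / out.gene_id.map(ref_means)
    return out


def compare_expression(rel: pd.DataFrame, reference_group: str, test_group: str,
                       alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-gene two-group comparison of relative expression.

    Returns one row per gene: test used, p-value, observed direction of the
    test group versus the reference ("up"/"down" when p < alpha, else
    "none"), and the test-group mean ratio.  Genes lacking data in either
    group are marked untestable.
    """
    rel = normalize_to_group(rel, reference_group)
    rows = []
    for gene, sub in rel.groupby("gene_id", sort=True):
        a = sub.loc[sub.group == reference_group, "rel_to_reference"].to_numpy()
        b = sub.loc[sub.group == test_group, "rel_to_reference"].to_numpy()
        if a.size < 2 or b.size < 2:
            rows.append({"gene_id": gene, "test": None, "p_value": np.nan,
                         "mean_ratio": np.nan, "observed_direction": "untestable"})
            continue
        res = compare_two(a, b, method="auto", alpha=alpha)
        ratio = float(b.mean())  # reference mean is 1 by construction
        if res.p_value < alpha:
            observed = "up" if ratio > 1.0 else "down"
        else:
            observed = "none"
        rows.append({"gene_id": gene, "test": res.descriptor.name,
                     "p_value": res.p_value, "mean_ratio": ratio,
                     "observed_direction": observed})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConcordanceSummary:
    n_tested: int
    n_validated: int
    n_trend_only: int
    n_unchanged: int
    n_untestable: int


def concordance(strengths: pd.DataFrame, comparisons: pd.DataFrame,
                alpha: float = DEFAULT_ALPHA) -> tuple[pd.DataFrame, ConcordanceSummary]:
    """Score predicted against observed regulation per gene.

    ``strengths`` rows supply ``predicted_direction`` (positive strength
    predicts downregulation); ``comparisons`` comes from
    :func:`compare_expression`.  A gene is validated when its observed
    change is significant and matches the prediction; trend-only when the
    mean ratio moves the predicted way without significance.
    """
    pred = strengths.set_index("gene_id").predicted_direction
    shared = [g for g in comparisons.gene_id if g in pred.index]
    if not shared:
        raise ValueError("no overlap between predicted and measured genes")
    comp = comparisons.set_index("gene_id").loc[shared]

    rows = []
    counts = {"validated": 0, "trend_only": 0, "unchanged": 0, "untestable": 0}
    for gene, row in comp.iterrows():
        predicted = pred[gene]
        observed = row.observed_direction
        if observed == "untestable":
            status = "untestable"
            validated = False
        elif observed == predicted:
            status = "validated"
            validated = True
        elif observed == "none" and predicted in ("up", "down") and (
            (predicted == "down" and row.mean_ratio < 1.0)
            or (predicted == "up" and row.mean_ratio > 1.0)
        ):
            status = "trend_only"
            validated = False
        else:
            status = "unchanged"
            validated = False
        counts[status] += 1
        rows.append({"gene_id": gene, "predicted_direction": predicted,
                     "observed_direction": observed, "p_value": row.p_value,
                     "mean_ratio": row.mean_ratio, "status": status,
                     "validated": validated})
    report = pd.DataFrame(rows)
    summary = ConcordanceSummary(
        n_tested=len(shared) - counts["untestable"],
        n_validated=counts["validated"],
        n_trend_only=counts["trend_only"],
        n_unchanged=counts["unchanged"],
        n_untestable=counts["untestable"],
    )
    return report, summary
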