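"""Immune-checkpoint status of normal lung tissue.

Expression of checkpoint genes (CTLA-4, PD-L1, ICOS) in the *normal*
tissue is clustered per gene into high/low by exact 1-D k-means (k = 2)
on the log2 scale, and the three calls combine into a per-patient label:
tolerant (all three high — checkpoint co-overexpression presumed to damp
the response to residual tumor cells), competent (CTLA-4 low with PD-L1
and ICOS high — the favorable profile), or other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ddpp_core import kmeans2_1d

logger = logging.getLogger(__name__)

CHECKPOINT_GENES = ("CTLA4", "PDL1", "ICOS")

#: high/low pattern (CTLA4, PDL1, ICOS) defining the immune-competent label
COMPETENT_RULE = ("low", "high", "high")


@dataclass
class ImmuneGeneCall:
    """High/low call of one checkpoint gene across patients."""

    gene_id: str
    calls: pd.Series  # "high" / "low" per patient
    cluster_means: tuple[float, float]  # (low, high) on log2 scale
    t_stat: float
    p_value: float


def cluster_separation_test(values, labels) -> tuple[float, float]:
    """Student's (pooled-variance) two-sample t-test between high and low calls."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    high = values[labels == "high"]
    low = values[labels == "low"]
    if high.size < 2 or low.size < 2:
        raise ValueError("both clusters need >= 2 members for a t-test")
    t, p = stats.ttest_ind(high, low, equal_var=True)
    return float(t), float(p)


def call_gene_high_low(normal_expr: pd.Series, gene_id: str) -> ImmuneGeneCall:
    """Cluster one gene's log2 normal-tissue expression into high/low."""
    values = np.log2(normal_expr.to_numpy(dtype=float))
    labels, centers, _ = kmeans2_1d(values)
    calls = pd.Series(np.where(labels == 1, "high", "low"), index=normal_expr.index)
    try:
        t, p = cluster_separation_test(values, calls.to_numpy())
    except ValueError:
        t, p = float("nan"), float("nan")
    return ImmuneGeneCall(gene_id=gene_id, calls=calls, cluster_means=centers,
                          t_stat=t, p_value=p)


def rank_checkpoint_genes(expr, candidate_genes) -> list[ImmuneGeneCall]:
    """Call each candidate in normal tissue; rank by separation p (ties by id)."""
    calls = []
    for gene in candidate_genes:
        if gene not in expr.tumor.index:
            logger.warning("candidate gene %s absent from expression matrix; skipped", gene)
            continue
        calls.append(call_gene_high_low(expr.normal.loc[gene], gene))
    return sorted(
        calls,
        key=lambda c: (np.isnan(c.p_value), c.p_value, c.gene_id),
    )


def assign_combined_status(
    calls: dict[str, ImmuneGeneCall],
    genes: tuple[str, str, str] = CHECKPOINT_GENES,
    competent_rule: tuple[str, str, str] = COMPETENT_RULE,
) -> pd.DataFrame:
    """Combine the three checkpoint calls into tolerant/competent/other.

    Returns a DataFrame indexed by patient with one column per gene plus
    ``combined``.  Patients lacking any of the three calls are excluded
    (listed in ``attrs['excluded']`` with a reason).
    """
    missing = [g for g in genes if g not in calls]
    if missing:
        raise KeyError(f"missing checkpoint calls for {missing}")
    table = pd.DataFrame({g: calls[g].calls for g in genes})
    complete = table.dropna()
    excluded = [
        {"patient_id": p, "reason": "missing immune checkpoint call"}
        for p in table.index.difference(complete.index)
    ]
    pattern = list(zip(*(complete[g] for g in genes)))
    combined = []
    for row in pattern:
        if all(c == "high" for c in row):
            combined.append("tolerant")
        elif tuple(row) == tuple(competent_rule):
            combined.append("competent")
        else:
            combined.append("other")
    complete = complete.copy()
    complete["combined"] = combined
    complete.attrs["excluded"] = excluded
    return complete
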