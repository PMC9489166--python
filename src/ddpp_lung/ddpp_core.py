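"""DDPP scoring: gene weights, DFS screening, per-group correlators, risk classes.

The Digital Display Precision Predictor (DDPP) relates differential
expression between a patient's tumor and matched normal tissue to
disease-free survival (DFS).  The per-gene, per-patient weight is

    w[g, p] = log2(T[g, p] / N[g, p]) * log_1.1(I[g, p])

where T and N are linear-scale tumor and normal intensities and I is the
intensity in a designated source tissue (tumor or normal).  Within each
histology-by-treatment group, gene weights are screened by Pearson
correlation against DFS with Benjamini-Hochberg control at FDR < 0.05; an
aggregate (median, mean or sum) of the most significant genes is regressed
on DFS, and the fitted line predicts DFS in months for every patient.  A
one-dimensional k-means (k = 2) over the pooled predicted values splits the
cohort into DDPP-high (longer predicted DFS) and DDPP-low classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # two-sided p-values are floored here to keep log-scale reports finite

AGGREGATION_MODES = ("median", "mean", "sum")
INTENSITY_SOURCES = ("tumor", "normal")

_LOG2_OF_1P1 = np.log2(1.1)


class NoSignificantGenesError(RuntimeError):
    """Raised when no gene passes the FDR gate for a group."""


def gene_weight(t: float, n: float, i: float) -> float:
    """Weight of one gene in one patient: log2(t/n) * log base-1.1 of i."""
    if t <= 0 or n <= 0 or i <= 0:
        raise ValueError("intensities must be strictly positive")
    return float(np.log2(t / n) * (np.log2(i) / _LOG2_OF_1P1))


def weight_matrix(expr, intensity_source: str = "tumor") -> pd.DataFrame:
    """Genes x patients weight matrix for one intensity source."""
    if intensity_source not in INTENSITY_SOURCES:
        raise ValueError(f"intensity_source must be one of {INTENSITY_SOURCES}")
    intensity = expr.tumor if intensity_source == "tumor" else expr.normal
    fold = np.log2(expr.tumor.to_numpy() / expr.normal.to_numpy())
    w = fold * (np.log2(intensity.to_numpy()) / _LOG2_OF_1P1)
    return pd.DataFrame(w, index=expr.tumor.index, columns=expr.tumor.columns)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Pearson correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(max(p, P_FLOOR))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_genes(weights: pd.DataFrame, dfs: pd.Series, patients: list[str]) -> pd.DataFrame:
    """Per-gene Pearson screen of weights against DFS within one group.

    Returns a DataFrame indexed by gene with columns r, p, q, rank (1 =
    smallest p).  Genes with constant weight across the group are excluded
    (column ``constant`` on the returned attrs lists them).
    """
    if len(patients) < 4:
        raise ValueError(f"group has {len(patients)} patients; need >= 4 to screen")
    X = weights[patients].to_numpy()
    y = dfs.loc[patients].to_numpy(dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("DFS constant within group; screen undefined")

    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    x_ss = np.einsum("ij,ij->i", xc, xc)
    keep = x_ss > 0
    dropped = weights.index[~keep].tolist()
    if dropped:
        logger.warning("excluding %d constant-weight genes from screen", len(dropped))

    r = np.full(X.shape[0], np.nan)
    denom = np.sqrt(x_ss[keep] * (yc @ yc))
    r[keep] = np.clip((xc[keep] @ yc) / denom, -1.0, 1.0)

    rk = r[keep]
    with np.errstate(divide="ignore"):
        t = rk * np.sqrt((n - 2) / np.maximum(1.0 - rk * rk, 0.0))
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df=n - 2), P_FLOOR)

    result = pd.DataFrame(index=weights.index[keep])
    result["r"] = rk
    result["p"] = p
    result["q"] = bh_fdr(p)
    # stable rank: ascending p, gene id breaking ties, so selection is deterministic
    order = np.lexsort((result.index.to_numpy(), result["p"].to_numpy()))
    ranks = np.empty(len(result), dtype=int)
    ranks[order] = np.arange(1, len(result) + 1)
    result["rank"] = ranks
    result.attrs["constant_genes"] = dropped
    return result


def aggregate(weights: pd.DataFrame, gene_set, mode: str) -> pd.Series:
    """Per-patient aggregate (median/mean/sum) of a gene set's weights."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"mode must be one of {AGGREGATION_MODES}")
    missing = [g for g in gene_set if g not in weights.index]
    if missing:
        raise KeyError(f"genes not in weight matrix: {missing[:5]}")
    sub = weights.loc[gene_set]
    return getattr(sub, mode)(axis=0)


def fit_correlator(agg, dfs) -> tuple[float, float, float, float]:
    """OLS of DFS (months) on the aggregate: (slope, intercept, fit_r, fit_p)."""
    agg = np.asarray(agg, dtype=float)
    dfs = np.asarray(dfs, dtype=float)
    if agg.size != dfs.size or agg.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    if np.ptp(agg) == 0:
        raise ValueError("constant aggregate: correlator undefined")
    fit = stats.linregress(agg, dfs)
    p = fit.pvalue if agg.size == 2 else max(fit.pvalue, P_FLOOR)
    return float(fit.slope), float(fit.intercept), float(np.clip(fit.rvalue, -1, 1)), float(p)


@dataclass(frozen=True)
class SelectionConfig:
    """Search space for the per-group predictor selection.

    ``modes`` doubles as the tie-preference order.  The mean comes first:
    a perfect-fit tie can only be resolved toward the informative gene
    set by an aggregate that every member gene influences — the median is
    robust to an admixed irrelevant gene and so cannot disambiguate.
    """

    k_min: int = 3
    k_max: int = 20
    fdr: float = 0.05
    modes: tuple[str, ...] = ("mean", "median", "sum")
    sources: tuple[str, ...] = INTENSITY_SOURCES


@dataclass(frozen=True)
class Correlator:
    """A fitted per-group linear predictor of DFS."""

    group: str
    gene_ids: tuple[str, ...]
    aggregation: str
    intensity_source: str
    slope: float
    intercept: float
    fit_r: float
    fit_p: float
    n_patients: int

    def predict(self, weights: pd.DataFrame, patients: list[str]) -> pd.Series:
        agg = aggregate(weights[patients], self.gene_ids, self.aggregation)
        return self.intercept + self.slope * agg

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "gene_ids": list(self.gene_ids),
            "aggregation": self.aggregation,
            "intensity_source": self.intensity_source,
            "slope": self.slope,
            "intercept": self.intercept,
            "fit_r": self.fit_r,
            "fit_p": self.fit_p,
            "n_patients": self.n_patients,
        }


def select_predictor(
    weights_by_source: dict[str, pd.DataFrame],
    dfs: pd.Series,
    patients: list[str],
    group: str,
    cfg: SelectionConfig = SelectionConfig(),
) -> Correlator:
    """Search source x aggregation x top-k gene sets for the best correlator.

    Genes passing the FDR gate are taken in ascending-p order; for each
    k in [k_min, k_max] (capped at the number of significant genes) and
    each aggregation mode, DFS is regressed on the aggregate and the
    candidate maximizing |fit_r| wins.  |fit_r| values are compared after
    rounding to 9 decimals; exact ties resolve by mode preference
    (``cfg.modes`` order, mean first), then to the larger gene set, then
    tumor before normal, so a noiseless planted signature is recovered in
    full rather than an arbitrary perfectly-correlated subset.
    """
    y = dfs.loc[patients]
    best: tuple | None = None
    best_corr: Correlator | None = None
    for src_idx, source in enumerate(cfg.sources):
        screen = screen_genes(weights_by_source[source], dfs, patients)
        sig = screen[screen["q"] < cfg.fdr].sort_values("rank")
        if len(sig) < cfg.k_min:
            continue
        ranked_genes = list(sig.index)
        w = weights_by_source[source]
        for k in range(cfg.k_min, min(cfg.k_max, len(ranked_genes)) + 1):
            genes = tuple(ranked_genes[:k])
            for mode_idx, mode in enumerate(cfg.modes):
                agg = aggregate(w[patients], genes, mode)
                if np.ptp(agg.to_numpy()) == 0:
                    continue
                slope, intercept, r, p = fit_correlator(agg, y)
                key = (round(abs(r), 9), -mode_idx, k, -src_idx)
                if best is None or key > best:
                    best = key
                    best_corr = Correlator(
                        group=group, gene_ids=genes, aggregation=mode,
                        intensity_source=source, slope=slope, intercept=intercept,
                        fit_r=r, fit_p=p, n_patients=len(patients),
                    )
    if best_corr is None:
        raise NoSignificantGenesError(f"no significant correlator for group {group}")
    return best_corr


def score_patients(
    correlators: dict[tuple[str, bool], Correlator],
    weights_by_source: dict[str, pd.DataFrame],
    clinical: pd.DataFrame,
    groups: dict[tuple[str, bool], list[str]],
) -> tuple[pd.DataFrame, list[dict]]:
    """Predicted DFS (months) per patient from their group's correlator.

    Returns (scores, excluded): scores has columns group, score; excluded
    lists patients whose group lacks a correlator, with a reason.
    """
    from .data_model_io import group_label

    rows = []
    excluded = []
    for key, patients in groups.items():
        if not patients:
            continue
        corr = correlators.get(key)
        if corr is None:
            excluded.extend(
                {"patient_id": p, "reason": f"no correlator for group {group_label(key)}"}
                for p in patients
            )
            continue
        preds = corr.predict(weights_by_source[corr.intensity_source], patients)
        rows.extend(
            {"patient_id": p, "group": group_label(key), "score": float(preds[p])}
            for p in patients
        )
    grouped = clinical.dropna(subset=["histology", "chemo"]).index
    excluded.extend(
        {"patient_id": p, "reason": "missing histology or treatment arm"}
        for p in clinical.index.difference(grouped)
    )
    scores = pd.DataFrame(rows).set_index("patient_id") if rows else pd.DataFrame(
        columns=["group", "score"]
    )
    return scores, excluded


def kmeans2_1d(values) -> tuple[np.ndarray, tuple[float, float], float]:
    """Exact optimal two-cluster split of a 1-D sample.

    Enumerates the contiguous splits of the sorted values and minimizes
    within-cluster sum of squares (the 1-D k=2 problem has a contiguous
    optimum).  Returns (labels, (low_center, high_center), threshold) with
    label 1 for the high-center side; threshold is the midpoint of the two
    boundary values, strictly between the centers.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D sample of at least two values")
    s = np.sort(v)
    if s[0] == s[-1]:
        raise ValueError("all values identical: no two-cluster split exists")

    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    n = s.size
    idx = np.arange(1, n)  # split after position i-1 -> left size i
    left_n = idx.astype(float)
    right_n = n - left_n
    left_sum = csum[idx - 1]
    right_sum = csum[-1] - left_sum
    wss = (csq[idx - 1] - left_sum**2 / left_n) + (csq[-1] - csq[idx - 1] - right_sum**2 / right_n)
    valid = s[idx] > s[idx - 1]  # split only between distinct values
    wss[~valid] = np.inf
    i = int(idx[np.argmin(wss)])

    threshold = float((s[i - 1] + s[i]) / 2.0)
    centers = (float(s[:i].mean()), float(s[i:].mean()))
    labels = (v > threshold).astype(int)
    return labels, centers, threshold


@dataclass
class DDPPResult:
    """DDPP high/low stratification of pooled predicted-DFS scores."""

    scores: pd.Series
    classes: pd.Series  # "high" / "low"
    threshold: float
    cluster_centers: tuple[float, float]

    def counts(self) -> dict[str, int]:
        return self.classes.value_counts().to_dict()


def classify_ddpp(scores: pd.Series) -> DDPPResult:
    """k-means (k=2) over pooled scores; the higher-center cluster is DDPP high."""
    labels, centers, threshold = kmeans2_1d(scores.to_numpy())
    classes = pd.Series(np.where(labels == 1, "high", "low"), index=scores.index)
    return DDPPResult(scores=scores, classes=classes, threshold=threshold,
                      cluster_centers=centers)


def brute_force_two_partition(values) -> float:
    """Minimum WSS over *all* 2-partitions (reference oracle, n <= 20)."""
    v = np.asarray(values, dtype=float)
    best = np.inf
    index = range(v.size)
    for size in range(1, v.size):
        for subset in combinations(index, size):
            mask = np.zeros(v.size, dtype=bool)
            mask[list(subset)] = True
            a, b = v[mask], v[~mask]
            wss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            best = min(best, wss)
    return float(best)
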