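"""Analytical validation: random-gene-set specificity and bootstrap stability.

Two designs probe the per-group correlators.  Specificity draws many
random gene sets of the signature's size, fits each as a correlator
(mean aggregation, tumor intensities) and asks how many reach
significance after Benjamini-Hochberg correction across draws — on data
without planted structure the answer should be none.  Stability
repeatedly refits the full selection procedure on random training
subsets of a group, predicts the held-out patients, and reports how
often the selected gene set matches the full-group correlator along
with the pooled predicted-versus-observed correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ddpp_core import (
    NoSignificantGenesError,
    SelectionConfig,
    bh_fdr,
    pearson_with_p,
    select_predictor,
)

logger = logging.getLogger(__name__)


@dataclass
class SpecificityResult:
    n_iterations: int
    set_size: int
    fit_p: np.ndarray  # per-iteration correlator p-value
    n_significant: int  # after BH across iterations at 0.05
    seed: int


@dataclass
class StabilityResult:
    n_iterations: int
    train_size: int
    selected_sets: list  # frozenset per iteration (empty if selection failed)
    identical_fraction: float  # fraction matching the full-group gene set
    n_failed: int  # iterations whose training set yielded no correlator
    pooled_predicted: np.ndarray
    pooled_observed: np.ndarray
    pooled_r: float
    pooled_p: float
    seed: int


def random_set_specificity(
    weights: pd.DataFrame,
    dfs: pd.Series,
    patients: list[str],
    set_size: int = 10,
    n_iter: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SpecificityResult:
    """Correlator p-values of random gene sets, BH-corrected across draws.

    Each draw takes ``set_size`` genes uniformly without replacement,
    aggregates their tumor-source weights by the mean, and regresses the
    group's DFS on the aggregate.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n_genes = weights.shape[0]
    if set_size > n_genes:
        raise ValueError(f"set_size {set_size} exceeds gene universe {n_genes}")
    rng = np.random.default_rng(seed)
    W = weights[patients].to_numpy()
    y = dfs.loc[patients].to_numpy(dtype=float)
    n = y.size

    agg = np.empty((n_iter, n))
    for i in range(n_iter):
        idx = rng.choice(n_genes, size=set_size, replace=False)
        agg[i] = W[idx].mean(axis=0)

    ac = agg - agg.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt(np.einsum("ij,ij->i", ac, ac) * (yc @ yc))
    r = np.clip((ac @ yc) / denom, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df=n - 2), 1e-300)
    n_sig = int((bh_fdr(p) < alpha).sum())
    return SpecificityResult(n_iterations=n_iter, set_size=set_size, fit_p=p,
                             n_significant=n_sig, seed=seed)


def bootstrap_stability(
    weights_by_source: dict[str, pd.DataFrame],
    dfs: pd.Series,
    patients: list[str],
    group: str,
    train_size: int = 18,
    n_iter: int = 200,
    seed: int = 0,
    selection: SelectionConfig = SelectionConfig(),
) -> StabilityResult:
    """Training/held-out resampling of the full selection procedure.

    Per iteration the group splits uniformly at random into ``train_size``
    training patients and the rest held out; the predictor is re-selected
    on the training set and used to predict held-out DFS.  An iteration
    whose training set yields no significant correlator is recorded as
    unstable (empty selected set), never dropped silently.
    """
    if train_size >= len(patients):
        raise ValueError("train_size must be smaller than the group")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    full = select_predictor(weights_by_source, dfs, patients, group, selection)
    full_set = frozenset(full.gene_ids)

    rng = np.random.default_rng(seed)
    selected_sets: list[frozenset] = []
    predicted: list[np.ndarray] = []
    observed: list[np.ndarray] = []
    n_failed = 0
    for _ in range(n_iter):
        perm = rng.permutation(len(patients))
        train = [patients[i] for i in perm[:train_size]]
        held = [patients[i] for i in perm[train_size:]]
        try:
            corr = select_predictor(weights_by_source, dfs, train, group, selection)
        except NoSignificantGenesError:
            n_failed += 1
            selected_sets.append(frozenset())
            continue
        selected_sets.append(frozenset(corr.gene_ids))
        w = weights_by_source[corr.intensity_source]
        predicted.append(corr.predict(w, held).to_numpy())
        observed.append(dfs.loc[held].to_numpy(dtype=float))

    identical = float(np.mean([s == full_set for s in selected_sets]))
    if predicted:
        pred = np.concatenate(predicted)
        obs = np.concatenate(observed)
        pooled_r, pooled_p = pearson_with_p(pred, obs)
    else:
        pred = obs = np.empty(0)
        pooled_r = pooled_p = float("nan")
    if n_failed:
        logger.warning("%d/%d bootstrap iterations yielded no correlator", n_failed, n_iter)
    return StabilityResult(
        n_iterations=n_iter, train_size=train_size, selected_sets=selected_sets,
        identical_fraction=identical, n_failed=n_failed,
        pooled_predicted=pred, pooled_observed=obs,
        pooled_r=pooled_r, pooled_p=pooled_p, seed=seed,
    )
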