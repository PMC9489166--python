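"""Kaplan-Meier curves, log-rank tests and Cox proportional-hazards fits.

Kaplan-Meier estimation and Cox fitting (Efron tie handling, Wald CIs)
delegate to lifelines; the log-rank statistic is computed directly from
the observed-minus-expected event counts with the hypergeometric variance
at each distinct event time, so per-group observed/expected tallies are
available in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray  # distinct observed times, ascending
    at_risk: np.ndarray
    survival: np.ndarray  # S(t) at each time
    median_months: float  # nan if S never reaches 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "at_risk": self.at_risk, "survival": self.survival}
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate; median is the smallest t with S(t) <= 0.5."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival sample")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table[kmf.event_table.index > 0]
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
    median = kmf.median_survival_time_
    return KMCurve(
        times=table.index.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=int),
        survival=surv,
        median_months=float(median) if np.isfinite(median) else float("nan"),
    )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray  # per-group observed events
    expected: np.ndarray


def logrank_test(groups) -> LogRankResult:
    """k-sample log-rank test.

    ``groups`` is a sequence of (times, events) pairs.  At each distinct
    event time the expected events per group are d * n_g / n, with the
    multivariate hypergeometric covariance; the chi-square statistic uses
    the first k-1 groups against the pooled pseudo-inverse covariance.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    parsed = []
    for times, events in groups:
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=bool)
        if t.size == 0:
            raise ValueError("empty group in log-rank test")
        parsed.append((t, e))
    k = len(parsed)
    all_event_times = np.unique(np.concatenate([t[e] for t, e in parsed]))
    if all_event_times.size == 0:
        raise ValueError("no events in any group")

    observed = np.zeros(k)
    expected = np.zeros(k)
    u = np.zeros(k - 1)
    cov = np.zeros((k - 1, k - 1))
    for et in all_event_times:
        n_g = np.array([(t >= et).sum() for t, _ in parsed], dtype=float)
        d_g = np.array([((t == et) & e).sum() for t, e in parsed], dtype=float)
        n = n_g.sum()
        d = d_g.sum()
        e_g = d * n_g / n
        observed += d_g
        expected += e_g
        u += (d_g - e_g)[: k - 1]
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1)
            cov += v * (np.diag(frac[: k - 1]) - np.outer(frac[: k - 1], frac[: k - 1]))
    chi2 = float(u @ np.linalg.pinv(cov) @ u)
    df = k - 1
    return LogRankResult(
        statistic=max(chi2, 0.0),
        df=df,
        p_value=float(stats.chi2.sf(max(chi2, 0.0), df)),
        observed=observed,
        expected=expected,
    )


@dataclass
class CoxModelFit:
    """Cox proportional-hazards fit summary."""

    summary: pd.DataFrame  # covariate, hr, ci_low, ci_high, p
    log_likelihood: float
    aic: float
    converged: bool
    reference_levels: dict


def _expand_covariates(table: pd.DataFrame, reference: dict | None):
    """Dummy-code categorical columns against a stated reference level."""
    reference = dict(reference or {})
    out = {}
    refs = {}
    for col in table.columns:
        series = table[col]
        if series.dtype == bool:
            out[col] = series.astype(float)
        elif pd.api.types.is_numeric_dtype(series):
            out[col] = series.astype(float)
        else:
            levels = sorted(series.astype(str).unique())
            ref = str(reference.get(col, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from column {col!r}")
            refs[col] = ref
            for level in levels:
                if level != ref:
                    out[f"{col}[{level}]"] = (series.astype(str) == level).astype(float)
    return pd.DataFrame(out, index=table.index), refs


def cox_fit(covariate_table: pd.DataFrame, times, events,
            reference: dict | None = None) -> CoxModelFit:
    """Maximum partial-likelihood Cox fit (Efron ties) via lifelines.

    Categorical covariates are expanded against a reference level
    (alphabetically first unless given).  Non-convergence is flagged, not
    silently returned.
    """
    if covariate_table.shape[1] < 1:
        raise ValueError("need at least one covariate")
    design, refs = _expand_covariates(covariate_table, reference)
    for col in design.columns:
        if design[col].nunique() <= 1:
            raise ValueError(f"constant covariate {col!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < design.shape[1]:
        raise ValueError("fewer events than covariates; fit unreliable")

    df = design.copy()
    df["_T"] = times
    df["_E"] = events.astype(int)
    cph = CoxPHFitter()
    converged = True
    try:
        cph.fit(df, duration_col="_T", event_col="_E")
    except ConvergenceError:
        return CoxModelFit(summary=pd.DataFrame(), log_likelihood=float("nan"),
                           aic=float("nan"), converged=False, reference_levels=refs)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "covariate": s.index,
            "hr": s["exp(coef)"].to_numpy(),
            "ci_low": s["exp(coef) lower 95%"].to_numpy(),
            "ci_high": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    loglik = float(cph.log_likelihood_)
    return CoxModelFit(
        summary=summary,
        log_likelihood=loglik,
        aic=float(2 * design.shape[1] - 2 * loglik),
        converged=converged,
        reference_levels=refs,
    )


def cox_partial_loglik(beta, x, times, events) -> float:
    """Breslow partial log-likelihood of a single covariate (no ties assumed).

    Reference implementation used for likelihood-improvement checks; exact
    when event times are distinct.
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    ll = 0.0
    for t in times[events]:
        at_risk = times >= t
        i = np.flatnonzero((times == t) & events)[0]
        ll += beta * x[i] - np.log(np.exp(beta * x[at_risk]).sum())
    return float(ll)


def _significance_marker(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def build_forest_table(fits: dict[str, CoxModelFit]) -> pd.DataFrame:
    """Tidy forest-plot table over one or more converged fits.

    One row per coefficient plus a HR = 1 reference row for each expanded
    categorical covariate.
    """
    rows = []
    for model, fit in fits.items():
        if not fit.converged:
            continue
        for col, ref in fit.reference_levels.items():
            rows.append({"model": model, "covariate": f"{col}[{ref}]", "hr": 1.0,
                         "ci_low": 1.0, "ci_high": 1.0, "p": float("nan"),
                         "marker": "reference"})
        for _, row in fit.summary.iterrows():
            rows.append({"model": model, "covariate": row["covariate"], "hr": row["hr"],
                         "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                         "p": row["p"], "marker": _significance_marker(row["p"])})
    if not rows:
        raise ValueError("no converged fits to tabulate")
    return pd.DataFrame(rows)
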