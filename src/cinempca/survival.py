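"""Survival evaluation of prognostic models.

Covariate standardization (training statistics frozen for validation), Cox
proportional-hazards regression (Efron ties), Harrell's concordance index,
AIC, likelihood-ratio tests between nested models, Kaplan-Meier curves with
median-threshold risk grouping and the log-rank test, 1-year ROC/AUC, and a
scaled-Schoenfeld-residual check of the proportional-hazards assumption.

Cox, Kaplan-Meier and log-rank fits are delegated to lifelines; the c-index
is implemented here as a direct pairwise statistic (ties in risk count 1/2)
so it can be checked against exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score

ONE_YEAR = 365.25 / 365.25  # years; times in this package are in years


@dataclass
class CoxResult:
    covariates: list
    coefficients: np.ndarray  # log-hazard per (standardized) unit
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_params: int
    c_index: float
    aic: float
    n: int
    n_events: int
    converged: bool = True
    warnings: list = field(default_factory=list)
    fitter: object = None

    def summary_row(self, name):
        i = self.covariates.index(name)
        return {
            "HR": self.hazard_ratios[i],
            "CI": (self.ci_lower[i], self.ci_upper[i]),
            "p": self.p_values[i],
        }


def _records_frame(records) -> pd.DataFrame:
    """Accept a DataFrame with time/event columns or a list of mappings."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            row = {"subject_id": r.get("subject_id"), "time": r["time"], "event": r["event"]}
            row.update(r.get("covariates", {}))
            rows.append(row)
        df = pd.DataFrame(rows)
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_covariates(table: pd.DataFrame, columns=None, reference_stats=None):
    """Z-score covariate columns; training defines the statistics.

    Returns ``(standardized table, stats)`` where ``stats`` maps column ->
    (mean, sd).  Pass ``reference_stats`` to standardize a validation table
    with frozen training statistics.  Zero-SD columns are dropped with a
    warning attribute rather than producing NaNs.
    """
    df = table.copy()
    if columns is None:
        columns = [c for c in df.columns
                   if c not in ("subject_id", "time", "event")
                   and np.issubdtype(df[c].dtype, np.number)]
    if reference_stats is None:
        reference_stats = {}
        for c in columns:
            sd = float(df[c].std(ddof=0))
            if sd == 0:
                df = df.drop(columns=[c])
                continue
            reference_stats[c] = (float(df[c].mean()), sd)
    for c, (m, s) in reference_stats.items():
        if c in df.columns:
            df[c] = (df[c] - m) / s
    return df, reference_stats


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def cox_fit(records, covariate_names, alpha: float = 0.05) -> CoxResult:
    """Maximize the Cox partial likelihood (Efron tie handling) and report
    coefficients, Wald CIs/p-values, Harrell c-index and AIC."""
    df = _records_frame(records)
    missing = [c for c in covariate_names if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")
    for c in covariate_names:
        if df[c].nunique() <= 1:
            raise ValueError(f"constant covariate: {c}")
    sub = df[["time", "event", *covariate_names]].astype(float)
    cph = CoxPHFitter(alpha=alpha)
    warnings_list = []
    try:
        cph.fit(sub, duration_col="time", event_col="event")
    except Exception as exc:  # monotone likelihood / separation
        raise RuntimeError(f"Cox fit failed (possible separation): {exc}") from exc
    coefs = cph.params_.loc[list(covariate_names)].to_numpy()
    se = cph.standard_errors_.loc[list(covariate_names)].to_numpy()
    if np.any(se > 100):
        warnings_list.append("very large standard errors: possible monotone likelihood")
    z = stats.norm.ppf(1 - alpha / 2)
    ll = float(cph.log_likelihood_)
    k = len(covariate_names)
    risk = sub[list(covariate_names)].to_numpy() @ coefs
    c = concordance_index(risk, sub["time"].to_numpy(), sub["event"].to_numpy().astype(bool))
    return CoxResult(
        covariates=list(covariate_names),
        coefficients=coefs,
        hazard_ratios=np.exp(coefs),
        ci_lower=np.exp(coefs - z * se),
        ci_upper=np.exp(coefs + z * se),
        p_values=cph.summary["p"].loc[list(covariate_names)].to_numpy(),
        log_likelihood=ll,
        n_params=k,
        c_index=c,
        aic=2 * k - 2 * ll,
        n=len(sub),
        n_events=int(sub["event"].sum()),
        converged=True,
        warnings=warnings_list,
        fitter=cph,
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(risk_scores, times, events) -> float:
    """Harrell's c over comparable pairs.

    A pair is comparable when the earlier time is an event and the other
    subject's time is strictly later (event or censored).  Concordant when
    the earlier-event subject has the higher risk; risk ties count 1/2.
    """
    risk = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = len(t)
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if not e[i]:
            continue
        later = t > t[i]
        comparable += int(later.sum())
        concordant += (risk[later] < risk[i]).sum() + 0.5 * (risk[later] == risk[i]).sum()
    if comparable == 0:
        return float("nan")
    return float(concordant / comparable)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def likelihood_ratio_test(nested: CoxResult, full: CoxResult) -> float:
    """LRT p-value: 2*(LL_full - LL_nested) ~ chi2(df = k_full - k_nested)."""
    if not set(nested.covariates) <= set(full.covariates):
        raise ValueError("models are not nested")
    if nested.n != full.n or nested.n_events != full.n_events:
        raise ValueError("models were fit on different records")
    df = full.n_params - nested.n_params
    if df == 0:
        return 1.0
    statistic = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    return float(stats.chi2.sf(statistic, df))


def model_comparison_table(
    models: dict, records, baseline: str, n_bootstrap: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per-model c-index with bootstrap percentile 95% CI, AIC, and LRT p
    versus the declared baseline model — the nested-model comparison table."""
    df = _records_frame(records)
    rng = np.random.default_rng(seed)
    n = len(df)
    rows = []
    boot_idx = [rng.integers(0, n, size=n) for _ in range(n_bootstrap)]
    for name, res in models.items():
        if res.n != n:
            raise ValueError(f"model {name} was fit on a different record set")
        risk = df[res.covariates].to_numpy(dtype=float) @ res.coefficients
        t, e = df["time"].to_numpy(), df["event"].to_numpy().astype(bool)
        cs = []
        for idx in boot_idx:
            cb = concordance_index(risk[idx], t[idx], e[idx])
            if np.isfinite(cb):
                cs.append(cb)
        lo, hi = np.percentile(cs, [2.5, 97.5])
        base = models[baseline]
        if name == baseline:
            p = np.nan
        elif set(base.covariates) <= set(res.covariates):
            p = likelihood_ratio_test(base, res)
        elif set(res.covariates) <= set(base.covariates):
            p = likelihood_ratio_test(res, base)
        else:
            p = np.nan  # not nested with the baseline: LRT undefined
        rows.append({
            "model": name, "c_index": res.c_index, "c_index_lo": lo, "c_index_hi": hi,
            "aic": res.aic, "lrt_p_vs_baseline": p,
        })
    return pd.DataFrame(rows).set_index("model")


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / grouping
# ---------------------------------------------------------------------------

def km_logrank(records, group_labels):
    """Product-limit survival per group plus the two-sided log-rank p.

    Returns ``(curves, p)`` where curves maps group -> fitted
    KaplanMeierFitter.
    """
    df = _records_frame(records)
    groups = np.asarray(group_labels)
    if len(groups) != len(df):
        raise ValueError("one group label per record required")
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    curves = {}
    for g in uniq:
        m = groups == g
        if m.sum() == 0:
            raise ValueError(f"empty group {g}")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(df["time"][m], event_observed=df["event"][m])
        curves[g] = kmf
    if len(uniq) != 2:
        raise ValueError("log-rank comparison implemented for 2 groups")
    a, b = uniq
    res = logrank_test(
        df["time"][groups == a], df["time"][groups == b],
        event_observed_A=df["event"][groups == a],
        event_observed_B=df["event"][groups == b],
    )
    return curves, float(res.p_value)


def median_risk_grouping(probabilities, reference_probabilities):
    """High/low risk split at the median of the reference (training) scores."""
    ref = np.asarray(reference_probabilities, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference")
    p = np.asarray(probabilities, dtype=float)
    if np.allclose(p, p[0]):
        raise ValueError("degenerate split: all probabilities identical")
    thr = float(np.median(ref))
    return np.where(p >= thr, "high", "low")


# ---------------------------------------------------------------------------
# 1-year ROC
# ---------------------------------------------------------------------------

def one_year_labels(times, events, horizon: float = ONE_YEAR):
    """1-year mortality labels: event within the horizon is positive, event-
    free follow-up past it negative; early censored cases are excluded."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    positive = e & (t <= horizon)
    negative = t > horizon
    include = positive | negative
    return positive[include], include


def roc_auc_1yr(probabilities, times, events, horizon: float = ONE_YEAR):
    """AUC for 1-year mortality (trapezoidal = normalized Mann-Whitney U).

    Returns ``(auc, n_used)``; NaN if only one class is represented.
    """
    p = np.asarray(probabilities, dtype=float)
    labels, include = one_year_labels(times, events, horizon)
    p = p[include]
    if labels.all() or not labels.any():
        return float("nan"), int(include.sum())
    return float(roc_auc_score(labels, p)), int(include.sum())


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic
# ---------------------------------------------------------------------------

def schoenfeld_ph_check(cox: CoxResult, records) -> dict:
    """Correlation test of scaled Schoenfeld residuals against event-time
    rank; one p-value per covariate.  Small p flags non-proportionality."""
    df = _records_frame(records)
    if df["event"].sum() < 3:
        raise ValueError("need at least 3 events for the Schoenfeld check")
    sub = df[["time", "event", *cox.covariates]].astype(float)
    resid = cox.fitter.compute_residuals(sub, kind="scaled_schoenfeld")
    ranks = stats.rankdata(sub.loc[resid.index, "time"].to_numpy())
    out = {}
    for c in cox.covariates:
        r, p = stats.pearsonr(ranks, resid[c].to_numpy())
        out[c] = float(p)
    return out
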