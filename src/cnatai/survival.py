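"""Survival analysis: Kaplan-Meier, log-rank, and Cox models with TAI per SD.

Thin, typed surface over lifelines.  Cox models use Efron tie handling
(survival times at month resolution tie heavily) and report Wald confidence
intervals and p-values; the TAI covariate always enters on the per-SD
(z-score) scale so hazard ratios read "per 1 SD increase of TAI".
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank
from lifelines.utils import median_survival_times


@dataclass
class KMCurve:
    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    median_ci: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.timeline, "survival": self.survival, "at_risk": self.at_risk}
        )


def kaplan_meier(times, events) -> KMCurve:
    """Product-limit estimate with log-log median CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    return KMCurve(
        timeline=timeline,
        survival=kmf.survival_function_["KM_estimate"].to_numpy(),
        at_risk=at_risk,
        median=float(kmf.median_survival_time_),
        median_ci=(lo, hi),
    )


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-covariate estimates from a proportional-hazards fit."""

    covariates: list[str]
    beta: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    hr: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    n: int = 0
    n_events: int = 0


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Newton-Raphson).

    Raises ValueError on too few events, constant covariates, or
    non-convergence (e.g. monotone likelihood from separation — collapse
    groups or drop the covariate).
    """
    df = data[[duration_col, event_col, *covariates]].dropna()
    if int(df[event_col].sum()) < 2:
        raise ValueError("Cox fit needs at least 2 events")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as e:
        raise ValueError(f"Cox fit did not converge: {e}") from e
    s = cph.summary
    return CoxResult(
        covariates=covariates,
        beta={c: float(s.loc[c, "coef"]) for c in covariates},
        se={c: float(s.loc[c, "se(coef)"]) for c in covariates},
        hr={c: float(s.loc[c, "exp(coef)"]) for c in covariates},
        ci_low={c: float(s.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_high={c: float(s.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        p={c: float(s.loc[c, "p"]) for c in covariates},
        n=len(df),
        n_events=int(df[event_col].sum()),
    )


def build_table2(clinical: pd.DataFrame, tai: pd.DataFrame) -> dict:
    """Survival summary: per endpoint, log-rank across the TAI median split,
    univariate Cox on TAI per SD, and multivariate Cox (z + age + stage +
    grade as numeric ordinals).

    Returns nested dict ``{endpoint: {"logrank": (chi2, p), "cox_uni":
    CoxResult, "cox_multi": CoxResult | None}}`` plus "n"; the multivariate
    fit is None when a covariate is degenerate in the joined data.
    """
    df = clinical.merge(tai[["sample_id", "group", "z"]], on="sample_id", how="inner")
    if df.empty:
        raise ValueError("no overlapping samples between clinical and TAI tables")
    out: dict = {"n": len(df)}
    for endpoint, tcol, ecol in (
        ("pfs", "pfs_months", "pfs_event"),
        ("os", "os_months", "os_event"),
    ):
        low = df[df["group"] == "low"]
        high = df[df["group"] == "high"]
        chi2, p = logrank(low[tcol], low[ecol], high[tcol], high[ecol])
        uni = cox_fit(df, tcol, ecol, ["z"])
        try:
            multi = cox_fit(df, tcol, ecol, ["z", "age", "stage", "grade"])
        except ValueError:
            multi = None
        out[endpoint] = {"logrank": (chi2, p), "cox_uni": uni, "cox_multi": multi}
    return out


def table2_frame(table2: dict) -> pd.DataFrame:
    """Flatten a build_table2 result for TSV output."""
    rows = []
    for endpoint in ("pfs", "os"):
        blk = table2[endpoint]
        chi2, p = blk["logrank"]
        rows.append({"endpoint": endpoint, "analysis": "logrank", "term": "group",
                     "estimate": chi2, "ci_low": np.nan, "ci_high": np.nan, "p": p})
        for kind in ("cox_uni", "cox_multi"):
            res = blk[kind]
            if res is None:
                continue
            for c in res.covariates:
                rows.append({"endpoint": endpoint, "analysis": kind, "term": c,
                             "estimate": res.hr[c], "ci_low": res.ci_low[c],
                             "ci_high": res.ci_high[c], "p": res.p[c]})
    return pd.DataFrame(rows)
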