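"""Survival estimation and the anchor-stratified synthetic-lethal screen.

The screen formalizes the tumor-transcriptome synthetic-lethality idea:
split patients into anchor-high and anchor-low groups at the median anchor
expression (low GSG2 standing in for pharmacological HASPIN inhibition),
then ask, candidate by candidate, whether low candidate expression carries
excess hazard specifically in the anchor-low group.  A candidate is called
an SL partner when the low-vs-high hazard ratio is significantly above 1 in
the anchor-low stratum (95% CI lower bound > 1) but not in the anchor-high
stratum.

Estimation is standard and delegated to lifelines: Kaplan-Meier
product-limit curves, the two-group log-rank test, and univariate Cox
proportional-hazards fits with Efron tie handling and Wald intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .synthetic import ExpressionCohort

__all__ = [
    "KMEstimate",
    "CoxResult",
    "SLScreenResult",
    "km_estimate",
    "logrank",
    "cox_hr",
    "stratified_sl_screen",
]


@dataclass
class KMEstimate:
    """A Kaplan-Meier curve as a right-continuous step function.

    ``times`` are the distinct event times; ``survival`` the product-limit
    estimate just after each.  ``__call__`` evaluates S(t); S(t) = 1 before
    the first event.
    """

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_time_event(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if len(time) == 0:
        raise ValueError("no survival records")
    if (time <= 0).any():
        raise ValueError("survival times must be strictly positive")
    return time, event


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Product-limit survival estimate from (time, event) records."""
    time, event = _as_time_event(records)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0  # drop the t=0 anchor row; S(t<first change)=1 by construction
    return KMEstimate(times=t[keep], survival=s[keep])


def logrank(records_a: pd.DataFrame, records_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta, ea = _as_time_event(records_a)
    tb, eb = _as_time_event(records_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined with zero events")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    """Univariate proportional-hazards estimate with Wald CI and p-value."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    indeterminate: bool = False
    reason: str = ""

    @property
    def significantly_above_one(self) -> bool:
        return (not self.indeterminate) and self.ci_low > 1.0


def cox_hr(
    covariate: Sequence[float] | np.ndarray | pd.Series,
    records: pd.DataFrame,
    alpha: float = 0.05,
) -> CoxResult:
    """Univariate Cox HR = exp(beta) for one covariate.

    Non-convergence or monotone likelihood (complete separation of events)
    yields an indeterminate result rather than an exception.  Efron tie
    handling (the lifelines default) is used.
    """
    time, event = _as_time_event(records)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(time):
        raise ValueError("covariate length does not match records")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    if event.sum() == 0:
        raise ValueError("no events; hazard ratio undefined")
    df = pd.DataFrame({"time": time, "event": event, "x": x})
    cph = CoxPHFitter(alpha=alpha)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("ignore", category=FutureWarning)
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, RuntimeWarning, ValueError) as exc:
        return CoxResult(np.nan, np.nan, np.nan, np.nan, True, f"{type(exc).__name__}: {exc}")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 50 or abs(beta) > 20:
        return CoxResult(np.nan, np.nan, np.nan, np.nan, True, "monotone likelihood")
    ci = cph.confidence_intervals_
    lo = float(np.exp(ci.iloc[0, 0]))
    hi = float(np.exp(ci.iloc[0, 1]))
    p = float(cph.summary["p"].iloc[0])
    return CoxResult(hr=float(np.exp(beta)), ci_low=lo, ci_high=hi, p=p)


@dataclass
class SLScreenResult:
    """Per-candidate stratified hazard ratios and SL classifications.

    ``table`` is indexed by candidate gene with columns hr_low, ci_low_lo,
    ci_low_hi, p_low, hr_high, ci_high_lo, ci_high_hi, p_high and
    classification in {SL-partner, not-partner, indeterminate}.  Hazard
    ratios compare LOW vs HIGH candidate expression within each anchor
    stratum (HR > 1: low expression is deleterious).
    """

    table: pd.DataFrame
    anchor: str
    split: str = "median"
    skipped: dict[str, str] = field(default_factory=dict)

    def partners(self) -> list[str]:
        t = self.table
        return sorted(t.index[t["classification"] == "SL-partner"])


_SPLIT_QUANTILE = {"median": 0.5, "tertile": 1 / 3, "quartile": 0.25}


def _low_mask(x: np.ndarray, split: str) -> np.ndarray:
    """Low-expression mask; ties at the cut point go to 'low'."""
    q = _SPLIT_QUANTILE[split]
    return x <= np.quantile(x, q)


def stratified_sl_screen(
    cohort: ExpressionCohort,
    anchor: str,
    candidates: Iterable[str],
    split: str = "median",
    covariate: str = "dichotomized",
    alpha: float = 0.05,
) -> SLScreenResult:
    """Screen candidates for synthetic lethality with the anchor.

    Patients are split at the ``split`` quantile of tumor anchor expression
    (ties to low).  Per candidate and per stratum, the candidate's tumor
    expression is either dichotomized at the within-stratum median (low = 1,
    the default) or used continuously, and a univariate Cox HR is estimated.
    Classification: SL-partner iff HR is significantly > 1 in the anchor-low
    stratum (CI lower bound > 1) and not significantly > 1 in the
    anchor-high stratum.  A candidate whose fit is indeterminate in either
    stratum is classified indeterminate; candidates skipped outright (e.g. a
    stratum without events for them) are recorded with a reason.
    """
    if split not in _SPLIT_QUANTILE:
        raise ValueError(f"split must be one of {sorted(_SPLIT_QUANTILE)}")
    if covariate not in ("dichotomized", "continuous"):
        raise ValueError("covariate must be 'dichotomized' or 'continuous'")
    tumor = cohort.tumor_matrix()
    if anchor not in tumor.index:
        raise ValueError(f"anchor gene {anchor!r} not in cohort")
    candidates = sorted(set(candidates))
    missing = [g for g in candidates if g not in tumor.index]
    if missing:
        raise ValueError(f"candidate genes not in cohort: {missing[:5]}")
    anchor_x = tumor.loc[anchor].to_numpy()
    if np.all(anchor_x == anchor_x[0]):
        raise ValueError("anchor expression is constant; cannot stratify")
    low_stratum = _low_mask(anchor_x, split)
    patients = list(tumor.columns)
    surv = cohort.survival.loc[patients]
    strata = {
        "low": surv[low_stratum],
        "high": surv[~low_stratum],
    }
    for name, rec in strata.items():
        if rec["event"].sum() == 0:
            raise ValueError(f"anchor-{name} stratum contains no events")

    rows = {}
    skipped: dict[str, str] = {}
    for gene in candidates:
        expr = tumor.loc[gene].to_numpy()
        res = {}
        for name, mask in (("low", low_stratum), ("high", ~low_stratum)):
            x = expr[mask]
            if covariate == "dichotomized":
                cov = _low_mask(x, "median").astype(float)
            else:
                cov = -x  # continuous: sign chosen so HR>1 means low is deleterious
            try:
                res[name] = cox_hr(cov, surv[mask], alpha=alpha)
            except ValueError as exc:
                res[name] = CoxResult(np.nan, np.nan, np.nan, np.nan, True, str(exc))
        low, high = res["low"], res["high"]
        if low.indeterminate or high.indeterminate:
            cls = "indeterminate"
        elif low.significantly_above_one and not high.significantly_above_one:
            cls = "SL-partner"
        else:
            cls = "not-partner"
        rows[gene] = {
            "hr_low": low.hr, "ci_low_lo": low.ci_low, "ci_low_hi": low.ci_high,
            "p_low": low.p,
            "hr_high": high.hr, "ci_high_lo": high.ci_low,
            "ci_high_hi": high.ci_high, "p_high": high.p,
            "classification": cls,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return SLScreenResult(table=table, anchor=anchor, split=split, skipped=skipped)
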