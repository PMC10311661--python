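"""Chou-Talalay median-effect modeling and combination-index analysis.

The median-effect equation relates dose D to fraction affected fa:

    fa / (1 - fa) = (D / Dm)^m

with Dm the dose producing 50% effect and m the sigmoidicity of the
dose-effect curve.  Taking log10 of both sides linearizes it, so (m, Dm)
come from an ordinary least-squares line of logit10(fa) on log10(D).

For a combination delivering doses (d1, d2) that produces fraction affected
fa, the combination index under the mutually exclusive (Loewe-type) form is

    CI = d1 / Dx1(fa) + d2 / Dx2(fa),

where Dxk(fa) = Dm_k * (fa/(1-fa))^(1/m_k) is the dose of drug k alone that
would produce fa.  CI < 1 indicates synergy, CI = 1 additivity and CI > 1
antagonism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseResponse",
    "MedianEffectFit",
    "FaCiTable",
    "median_effect_fit",
    "dx",
    "combination_index",
    "fa_ci_table",
]

#: fa values outside this window are excluded from fits and flagged in
#: Fa-CI tables: the logit10 transform blows up near 0 and 1.
DEFAULT_FA_WINDOW = (0.01, 0.99)


@dataclass
class DoseResponse:
    """Dose / fraction-affected measurements for one drug or one drug pair.

    ``data`` has columns ``dose1``, ``dose2`` (NaN for single agents),
    ``fa`` and ``flag`` (empty string for clean rows, otherwise the reason
    the row is unusable, e.g. a failed root solve in the generator).
    """

    drugs: tuple[str, ...]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"dose1", "dose2", "fa", "flag"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DoseResponse data missing columns {sorted(missing)}")
        if (self.data["dose1"] <= 0).any():
            raise ValueError("doses must be positive")
        d2 = self.data["dose2"]
        if (d2.dropna() <= 0).any():
            raise ValueError("doses must be positive")

    @property
    def is_single(self) -> bool:
        return len(self.drugs) == 1

    def clean(self) -> pd.DataFrame:
        """Rows without a flag."""
        return self.data[self.data["flag"] == ""]


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters (m, Dm) for a single agent."""

    drug: str
    m: float
    dm: float
    r_squared: float
    n_points: int
    flagged: bool = False
    reason: str = ""


@dataclass
class FaCiTable:
    """Fa-CI table for one fixed pair of single-agent fits."""

    table: pd.DataFrame
    fit1: MedianEffectFit
    fit2: MedianEffectFit
    exclusivity: str = "mutually_exclusive"


def _logit10(fa: np.ndarray) -> np.ndarray:
    return np.log10(fa / (1.0 - fa))


def median_effect_fit(
    dr: DoseResponse,
    fa_window: tuple[float, float] = DEFAULT_FA_WINDOW,
) -> MedianEffectFit:
    """Fit the median-effect line logit10(fa) ~ log10(D) for a single agent.

    Rows whose fa falls outside ``fa_window`` and flagged rows are excluded.
    A nonpositive slope (dose-effect not increasing) yields a flagged fit
    rather than an exception; fewer than two distinct usable doses is an
    error.
    """
    if not dr.is_single:
        raise ValueError("median_effect_fit expects a single-agent DoseResponse")
    rows = dr.clean()
    lo, hi = fa_window
    rows = rows[(rows["fa"] > lo) & (rows["fa"] < hi)]
    doses = rows["dose1"].to_numpy(dtype=float)
    fa = rows["fa"].to_numpy(dtype=float)
    if len(np.unique(doses)) < 2:
        raise ValueError(
            f"drug {dr.drugs[0]!r}: need >=2 distinct doses with usable fa, "
            f"got {len(np.unique(doses))}"
        )
    res = stats.linregress(np.log10(doses), _logit10(fa))
    m = float(res.slope)
    r2 = float(res.rvalue**2)
    if m <= 0:
        return MedianEffectFit(
            drug=dr.drugs[0], m=m, dm=math.nan, r_squared=r2, n_points=len(fa),
            flagged=True, reason="nonpositive median-effect slope",
        )
    dm = 10.0 ** (-float(res.intercept) / m)
    return MedianEffectFit(
        drug=dr.drugs[0], m=m, dm=dm, r_squared=r2, n_points=len(fa)
    )


def dx(fa: float, fit: MedianEffectFit) -> float:
    """Dose of the fitted drug alone producing fraction affected ``fa``.

    Dx = Dm * (fa/(1-fa))^(1/m); strictly increasing in fa, Dx(0.5) = Dm.
    """
    if not 0.0 < fa < 1.0:
        raise ValueError(f"fa must be in (0, 1), got {fa}")
    if fit.flagged or not (fit.m > 0 and fit.dm > 0):
        raise ValueError(f"invalid median-effect fit for drug {fit.drug!r}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    d1: float,
    d2: float,
    fa: float,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
) -> float:
    """Mutually exclusive combination index at one measured (d1, d2, fa).

    CI = d1/Dx1(fa) + d2/Dx2(fa).  Either dose may be zero (single agent as
    a degenerate combination); both negative doses are rejected.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be nonnegative")
    ci = 0.0
    if d1 > 0:
        ci += d1 / dx(fa, fit1)
    if d2 > 0:
        ci += d2 / dx(fa, fit2)
    return ci


def fa_ci_table(
    single1: DoseResponse,
    single2: DoseResponse,
    combo: DoseResponse,
    fa_window: tuple[float, float] = DEFAULT_FA_WINDOW,
) -> FaCiTable:
    """Fa-CI table for a combination, one row per combination measurement.

    Single-agent curves are refit here; the fa entering each CI is the
    measured combination value, never a model prediction.  Rows whose fa
    falls outside ``fa_window`` (or that arrived flagged) are kept in the
    table with CI = NaN and a reason in the flag column.  The table is
    sorted by fa.
    """
    fit1 = median_effect_fit(single1, fa_window)
    fit2 = median_effect_fit(single2, fa_window)
    for fit in (fit1, fit2):
        if fit.flagged:
            raise ValueError(
                f"invalid single-agent fit for drug {fit.drug!r}: {fit.reason}"
            )
    lo, hi = fa_window
    rows = []
    for r in combo.data.itertuples(index=False):
        flag = r.flag
        ci = math.nan
        fa = float(r.fa)
        d2 = 0.0 if pd.isna(r.dose2) else float(r.dose2)
        if flag == "" and not (lo < fa < hi):
            flag = f"fa outside window ({lo}, {hi})"
        if flag == "":
            ci = combination_index(float(r.dose1), d2, fa, fit1, fit2)
        rows.append((float(r.dose1), d2, fa, ci, flag))
    table = pd.DataFrame(rows, columns=["d1", "d2", "fa", "ci", "flag"])
    table = table.sort_values("fa", kind="stable").reset_index(drop=True)
    return FaCiTable(table=table, fit1=fit1, fit2=fit2)
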