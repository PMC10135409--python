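"""Rank-trajectory components and bivariate validation regressions.

A male's lifetime rank curve is summarised by six components, each with
its own eligibility rule (sample restrictions that keep the component
well defined):

1. *entry cardinal* — cardinal score on the hierarchy-entry date;
   requires entry at age 12 (entry age in [12, 13)).
2. *rise slope* — cardinal change per year from entry to the first day
   at the male's best (lowest) ordinal rank; same eligibility as entry.
   Inapplicable for a male who never rose above his entry rank.
3. *peak cardinal* — maximum cardinal achieved; requires rank data to at
   least age 26.
4. *best ordinal* — minimum ordinal achieved (1 = alpha); same
   eligibility as the peak.
5. *top tenure* — days between the first and last day at the best
   ordinal; requires best ordinal <= 3, entry before age 16, and rank
   data to at least age 26.
6. *decline slope* — cardinal change per year over the two years after
   the last day at the best ordinal; requires at least two years of
   data past that day.

Validation regresses each component on a z-scored personality trait by
ordinary least squares, reporting the slope with its normal-theory 95%
confidence interval, optionally after sensitivity exclusions.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import DAYS_PER_YEAR, age_on

__all__ = [
    "TrajectoryComponents",
    "RegressionResult",
    "extract_components",
    "z_transform",
    "validate_component",
]

COMPONENTS = ["entry_cardinal", "rise_slope", "peak_cardinal",
              "best_ordinal", "top_tenure_days", "decline_slope"]

#: trailing window (days) over which the post-peak decline is measured
DECLINE_WINDOW_DAYS = round(2 * DAYS_PER_YEAR)


@dataclasses.dataclass
class TrajectoryComponents:
    male_id: str
    entry_cardinal: float
    rise_slope: float
    peak_cardinal: float
    best_ordinal: float
    top_tenure_days: float
    decline_slope: float
    eligibility: dict[str, tuple[bool, str]]


@dataclasses.dataclass
class RegressionResult:
    """OLS slope of a trajectory component on a z-scored trait."""
    beta: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float
    excluded_ids: tuple[str, ...] = ()


def _components_one(series: pd.DataFrame, birth_date) -> dict:
    """Components for one male's daily series (sorted by date)."""
    s = series.dropna(subset=["cardinal", "ordinal"])
    out = {c: np.nan for c in COMPONENTS}
    elig: dict[str, tuple[bool, str]] = {}
    if s.empty:
        for c in COMPONENTS:
            elig[c] = (False, "no rank days with >=2 males present")
        out["eligibility"] = elig
        return out

    entry_date = s["date"].iloc[0]
    last_date = s["date"].iloc[-1]
    entry_age = age_on(birth_date, entry_date)
    last_age = age_on(birth_date, last_date)

    out["entry_cardinal"] = float(s["cardinal"].iloc[0])
    best = float(s["ordinal"].min())
    out["best_ordinal"] = best
    out["peak_cardinal"] = float(s["cardinal"].max())

    at_best = s[s["ordinal"] == best]
    first_best, last_best = at_best["date"].iloc[0], at_best["date"].iloc[-1]
    out["top_tenure_days"] = float((last_best - first_best).days)

    rise_days = (first_best - entry_date).days
    if rise_days > 0:
        rise = float(at_best["cardinal"].iloc[0]) - out["entry_cardinal"]
        out["rise_slope"] = rise / (rise_days / DAYS_PER_YEAR)

    window_end = last_best + pd.Timedelta(days=DECLINE_WINDOW_DAYS)
    post = s[(s["date"] > last_best) & (s["date"] <= window_end)]
    if not post.empty:
        dt_years = (post["date"].iloc[-1] - last_best).days / DAYS_PER_YEAR
        start_card = float(s.loc[s["date"] == last_best, "cardinal"].iloc[0])
        out["decline_slope"] = (float(post["cardinal"].iloc[-1])
                                - start_card) / dt_years

    entered_at_12 = 12.0 <= entry_age < 13.0
    to_26 = last_age >= 26.0
    elig["entry_cardinal"] = (entered_at_12,
                              "" if entered_at_12 else
                              f"entered at age {entry_age:.1f}, not in [12,13)")
    never_rose = rise_days <= 0
    elig["rise_slope"] = (entered_at_12 and not never_rose,
                          "never rose above entry rank" if never_rose
                          else elig["entry_cardinal"][1])
    elig["peak_cardinal"] = (to_26, "" if to_26 else
                             f"rank data end at age {last_age:.1f} < 26")
    elig["best_ordinal"] = elig["peak_cardinal"]
    tenure_ok = best <= 3 and entry_age < 16.0 and to_26
    elig["top_tenure_days"] = (
        tenure_ok, "" if tenure_ok else
        f"best ordinal {best:.0f}, entry age {entry_age:.1f}, "
        f"data to age {last_age:.1f}")
    decline_ok = (last_date - last_best).days >= DECLINE_WINDOW_DAYS
    elig["decline_slope"] = (
        decline_ok, "" if decline_ok else
        "fewer than 2 years of data past last day at best ordinal")
    out["eligibility"] = elig
    return out


def extract_components(daily: pd.DataFrame,
                       roster: pd.DataFrame) -> pd.DataFrame:
    """Six trajectory components plus eligibility flags, one row per male.

    ``daily`` must carry ``male_id, date, cardinal, ordinal`` (singleton
    days already missing).  Ineligible components are still computed when
    defined; the ``<name>_eligible`` columns carry the restriction, and
    ``<name>_reason`` the explanation when ineligible.
    """
    births = roster.set_index("male_id")["birth_date"]
    rows = []
    for male, grp in daily.groupby("male_id", sort=False):
        if male not in births.index:
            continue
        res = _components_one(grp.sort_values("date"), births[male])
        row = {"male_id": male}
        row.update({c: res[c] for c in COMPONENTS})
        for c in COMPONENTS:
            ok, why = res["eligibility"][c]
            row[f"{c}_eligible"] = ok
            row[f"{c}_reason"] = why
        rows.append(row)
    return pd.DataFrame(rows)


def z_transform(values) -> pd.Series:
    """Standardise to mean 0, SD 1 (denominator n-1); NaNs propagate."""
    values = pd.Series(values, dtype=float)
    sd = values.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("z_transform requires >= 2 distinct non-missing values")
    return (values - values.mean()) / sd


def validate_component(component: pd.Series, trait: pd.Series,
                       exclude: Iterable[str] = (),
                       z_sample: pd.Series | None = None) -> RegressionResult:
    """Bivariate OLS of a component on a z-scored trait.

    ``component`` and ``trait`` are indexed by male id.  The trait is
    z-scored over ``z_sample`` if given (e.g. the full rated sample),
    otherwise over the trait series itself; the regression then uses the
    paired complete observations minus ``exclude``.
    """
    exclude = tuple(exclude)
    z_basis = trait if z_sample is None else z_sample
    trait_z = (trait - z_basis.mean()) / z_basis.std(ddof=1)
    df = pd.concat({"y": component, "x": trait_z}, axis=1).dropna()
    df = df[~df.index.isin(exclude)]
    if len(df) < 3:
        raise ValueError(f"insufficient data for regression (n={len(df)})")
    fit = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
    lo, hi = fit.conf_int().loc["x"]
    return RegressionResult(beta=float(fit.params["x"]), ci_low=float(lo),
                            ci_high=float(hi), n=len(df),
                            p_value=float(fit.pvalues["x"]),
                            excluded_ids=exclude)
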