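"""Questionnaire trait scoring and interrater reliability.

Observers rate each chimpanzee on a 24-item adjective questionnaire
(1 = negligible amounts of the trait, 7 = extremely large amounts).
Nineteen items with adequate interrater reliability are aggregated into
six trait scores — Dominance, Extraversion, Conscientiousness,
Agreeableness, Neuroticism, Openness — by unit-weighted averaging:
negatively keyed items are reversed (x -> 8 - x), each rater's trait
score is the mean of the keyed items, and the male's trait score is the
mean over his raters.

Reliability of the mean rating is quantified with the two-way
consistency intraclass correlation for the average of k raters,
ICC(3,k) = (BMS - EMS) / BMS from the targets x raters ANOVA; for
unbalanced designs k is summarised by the harmonic mean of raters per
target.

The item -> trait key is a configuration input.  The default key shipped
here is a synthetic unit-weighted key assembled from the adjectives that
define each trait; analyses of deposited ratings should load the
instrument's own key from YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from statsmodels.formula.api import ols

__all__ = [
    "TRAITS",
    "DEFAULT_KEY",
    "ReliabilityResult",
    "load_scoring_key",
    "validate_key",
    "rater_trait_scores",
    "score_traits",
    "icc_mean_raters",
    "trait_reliabilities",
]

TRAITS = ["dominance", "extraversion", "conscientiousness",
          "agreeableness", "neuroticism", "openness"]

#: Synthetic default scoring key: 19 reliable items, unit weights,
#: '-' items reversed.  The five remaining questionnaire items
#: (intelligent, persistent, bullying, stingy, manipulative) are left
#: unkeyed, mirroring an instrument where low-reliability items are
#: dropped before scoring.
DEFAULT_KEY: dict[str, list[tuple[str, str]]] = {
    "dominance": [("dominant", "+"), ("decisive", "+"), ("dependent", "-"),
                  ("fearful", "-"), ("timid", "-")],
    "extraversion": [("sociable", "+"), ("active", "+"), ("solitary", "-"),
                     ("individualistic", "-")],
    "conscientiousness": [("predictable", "+"), ("impulsive", "-"),
                          ("reckless", "-")],
    "agreeableness": [("sympathetic", "+"), ("helpful", "+"),
                      ("sensitive", "+")],
    "neuroticism": [("excitable", "+"), ("stable", "-")],
    "openness": [("inventive", "+"), ("inquisitive", "+")],
}


@dataclasses.dataclass
class ReliabilityResult:
    name: str
    icc_mean_raters: float
    icc_single_rater: float
    k_effective: float
    n_targets: int


def load_scoring_key(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read a trait scoring key from YAML: ``trait: {item: '+'|'-'}``."""
    raw = yaml.safe_load(Path(path).read_text())
    key = {trait: [(item, str(sign)) for item, sign in items.items()]
           for trait, items in raw.items()}
    return validate_key(key)


def validate_key(key: dict[str, list[tuple[str, str]]]) -> dict:
    for trait, items in key.items():
        names = [i for i, _ in items]
        if len(set(names)) != len(names):
            raise ValueError(f"{trait}: item keyed twice")
        for item, sign in items:
            if sign not in {"+", "-"}:
                raise ValueError(f"{trait}.{item}: sign must be '+' or '-'")
    return key


def rater_trait_scores(ratings: pd.DataFrame,
                       key: dict | None = None) -> pd.DataFrame:
    """Per-rater trait scores: mean of keyed items after reversal.

    ``ratings`` is long format (``rater_id, male_id, item, score``).
    Missing items are excluded pairwise.  Returns one row per
    rater x male with one column per trait.
    """
    key = validate_key(key or DEFAULT_KEY)
    wide = ratings.pivot_table(index=["male_id", "rater_id"], columns="item",
                               values="score", aggfunc="first")
    out = {}
    for trait, items in key.items():
        cols = []
        for item, sign in items:
            if item not in wide.columns:
                continue
            col = wide[item].astype(float)
            cols.append(8.0 - col if sign == "-" else col)
        if not cols:
            raise KeyError(f"no keyed items present for trait '{trait}'")
        out[trait] = pd.concat(cols, axis=1).mean(axis=1)
    return pd.DataFrame(out).reset_index()


def score_traits(ratings: pd.DataFrame, key: dict | None = None,
                 min_raters: int = 1) -> pd.DataFrame:
    """Trait scores per male: mean over raters of per-rater trait scores.

    Males with fewer than ``min_raters`` raters are omitted.  Returns a
    frame indexed by ``male_id`` with the six trait columns (1-7 scale)
    plus ``n_raters``.
    """
    per_rater = rater_trait_scores(ratings, key)
    grouped = per_rater.groupby("male_id")
    scores = grouped[list((key or DEFAULT_KEY))].mean()
    scores["n_raters"] = grouped["rater_id"].nunique()
    return scores[scores["n_raters"] >= min_raters]


def icc_mean_raters(matrix: pd.DataFrame, name: str = "") -> ReliabilityResult:
    """ICC(3,k): consistency of the mean of k raters' ratings.

    ``matrix`` is targets x raters, NaN for missing cells (unbalanced
    designs permitted).  From the two-way targets x raters ANOVA,
    ``ICC(3,k) = (BMS - EMS) / BMS`` and
    ``ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS)`` with k the harmonic
    mean of raters per target.
    """
    long = (matrix.rename_axis(index="target", columns="rater")
            .stack().rename("score").reset_index())
    n_targets = long["target"].nunique()
    if n_targets < 2:
        raise ValueError("ICC requires at least 2 targets")
    if long["rater"].nunique() < 2:
        raise ValueError("ICC requires at least 2 raters")
    long["score"] = long["score"].astype(float)
    fit = ols("score ~ C(rater) + C(target)", data=long).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    bms = anova.loc["C(target)", "sum_sq"] / anova.loc["C(target)", "df"]
    dfe = anova.loc["Residual", "df"]
    ems = (anova.loc["Residual", "sum_sq"] / dfe) if dfe > 0 else 0.0
    raters_per_target = long.groupby("target")["rater"].nunique()
    k = len(raters_per_target) / (1.0 / raters_per_target).sum()
    if bms <= 0:
        icc_k = icc_1 = float("nan")
    else:
        icc_k = (bms - ems) / bms
        icc_1 = (bms - ems) / (bms + (k - 1) * ems)
    return ReliabilityResult(name=name, icc_mean_raters=float(icc_k),
                             icc_single_rater=float(icc_1),
                             k_effective=float(k), n_targets=int(n_targets))


def trait_reliabilities(ratings: pd.DataFrame,
                        key: dict | None = None) -> pd.DataFrame:
    """ICC(3,k) of each trait score across raters, one row per trait."""
    per_rater = rater_trait_scores(ratings, key)
    rows = []
    for trait in (key or DEFAULT_KEY):
        mat = per_rater.pivot(index="male_id", columns="rater_id",
                              values=trait)
        rows.append(dataclasses.asdict(icc_mean_raters(mat, name=trait)))
    return pd.DataFrame(rows).set_index("name")
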