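"""Siring-success risk sets, binomial GLMM, and AICc model comparison.

Each genetically confirmed offspring defines one *siring event*.  The
estimated siring date is the offspring's birth date minus the
population-specific mean gestation length for singleton births (228
days).  The event's *risk set* contains every male at least 11 years old
on that date with rank (cardinal Elo), trait and relatedness data;
exactly one row per event is the true sire.

Siring success is modelled as a binomial GLMM with a logit link: fixed
effects drawn from age, cardinal Elo, mother-male relatedness, trait
scores, their squares, and trait x age / trait x Elo products, plus a
random intercept per male.  The random intercept is integrated out of
the likelihood by Gauss-Hermite quadrature (the adaptive-Laplace family
of approximations used by standard mixed-model software).  Candidate
models are ranked by the small-sample corrected Akaike criterion,

    AICc = -2 l + 2 p + 2 p (p + 1) / (n - p - 1),

with ``n`` the number of candidate rows (Bernoulli observations), and
summarised with Akaike weights ``w_i = exp(-delta_i / 2) / sum_j
exp(-delta_j / 2)``.  ``delta_i = AICc_i - AICc_best >= 0`` throughout.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .data_model import age_on

__all__ = [
    "GESTATION_DAYS",
    "MIN_CANDIDATE_AGE",
    "GlmmFit",
    "assemble_risk_sets",
    "build_design",
    "fit_siring_glmm",
    "aicc",
    "aicc_compare",
    "default_model_family",
]

#: mean gestation length for singleton births, days
GESTATION_DAYS = 228
#: minimum candidate-sire age (years) on the estimated siring date
MIN_CANDIDATE_AGE = 11.0

TRAITS = ["dominance", "extraversion", "conscientiousness",
          "agreeableness", "neuroticism", "openness"]

BASE_TERMS = ("age_z", "elo_z", "relatedness")


class RiskSetIntegrityError(ValueError):
    """The true sire of an event fails the candidate filters."""


def assemble_risk_sets(paternity: pd.DataFrame, roster: pd.DataFrame,
                       daily: pd.DataFrame, relatedness: pd.DataFrame,
                       traits: pd.DataFrame,
                       min_age: float = MIN_CANDIDATE_AGE,
                       gestation_days: int = GESTATION_DAYS) -> pd.DataFrame:
    """One row per candidate sire x siring event.

    Candidates are males at least ``min_age`` years old on the estimated
    siring date (birth minus gestation) with a cardinal Elo score that
    day and trait scores; dyads with missing mother-male relatedness are
    excluded.  Age and Elo are z-scored across the retained rows, trait
    scores across the candidate male sample.  An event whose true sire
    fails the filters raises :class:`RiskSetIntegrityError`.
    """
    births = roster.set_index("male_id")["birth_date"]
    elo_lookup = daily.set_index(["male_id", "date"])["cardinal"]
    rel_lookup = relatedness.set_index(["mother_id", "male_id"])["r_value"]
    rows = []
    for ev in paternity.itertuples(index=False):
        siring_date = ev.birth_date - pd.Timedelta(days=gestation_days)
        for male in roster["male_id"]:
            if births[male] > siring_date:
                continue
            age = age_on(births[male], siring_date)
            if age < min_age or male not in traits.index:
                continue
            elo = elo_lookup.get((male, siring_date), np.nan)
            if pd.isna(elo):
                continue
            r = rel_lookup.get((ev.mother_id, male), np.nan)
            rows.append({"event_id": ev.offspring_id, "male_id": male,
                         "sired": int(male == ev.sire_id), "age": age,
                         "cardinal": float(elo), "relatedness": r})
        ev_rows = [r for r in rows if r["event_id"] == ev.offspring_id]
        if not any(r["sired"] for r in ev_rows):
            raise RiskSetIntegrityError(
                f"true sire {ev.sire_id} of {ev.offspring_id} fails the "
                "candidate filters")
    df = pd.DataFrame(rows)
    n_missing = int(df["relatedness"].isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} candidate rows dropped for missing "
                      "relatedness")
    df = df.dropna(subset=["relatedness"]).reset_index(drop=True)
    lost = df.groupby("event_id")["sired"].sum()
    bad = lost[lost != 1].index.tolist()
    if bad:
        raise RiskSetIntegrityError(
            f"events losing their sire to relatedness exclusion: {bad}")
    df["age_z"] = (df["age"] - df["age"].mean()) / df["age"].std(ddof=1)
    df["elo_z"] = (df["cardinal"] - df["cardinal"].mean()) \
        / df["cardinal"].std(ddof=1)
    males = sorted(set(df["male_id"]))
    sample = traits.loc[males]
    for trait in TRAITS:
        if trait not in sample.columns:
            continue
        z = (sample[trait] - sample[trait].mean()) / sample[trait].std(ddof=1)
        df[f"{trait}_z"] = df["male_id"].map(z)
    return df


def build_design(rows: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Design matrix from term strings: ``x``, ``x^2`` or ``x:y``."""
    def factor(name: str) -> np.ndarray:
        if name.endswith("^2"):
            return rows[name[:-2]].to_numpy(float) ** 2
        return rows[name].to_numpy(float)

    cols = [np.ones(len(rows))]
    for term in terms:
        parts = [factor(p) for p in term.split(":")]
        cols.append(np.prod(parts, axis=0))
    return np.column_stack(cols)


@dataclasses.dataclass
class GlmmFit:
    terms: tuple[str, ...]
    coefficients: pd.Series
    se: pd.Series
    odds_ratios: pd.DataFrame  # OR, ci_low, ci_high, p
    sigma: float
    loglik: float
    n_params: int
    n_rows: int
    n_events: int
    converged: bool


def _glmm_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
              group_slices: list[np.ndarray], nodes: np.ndarray,
              logw: np.ndarray, sigma_fixed: float | None) -> float:
    if sigma_fixed is None:
        beta, sigma = theta[:-1], math.exp(theta[-1])
    else:
        beta, sigma = theta, sigma_fixed
    eta = X @ beta
    total = 0.0
    if sigma == 0.0:
        z = np.where(y == 1, eta, -eta)
        return float(np.sum(np.logaddexp(0.0, -z)))
    offs = math.sqrt(2.0) * sigma * nodes  # quadrature offsets
    for idx in group_slices:
        e = eta[idx][:, None] + offs[None, :]
        z = np.where(y[idx][:, None] == 1, e, -e)
        log_lik_q = -np.logaddexp(0.0, -z).sum(axis=0)
        total += logsumexp(logw + log_lik_q)
    return float(-total)


def fit_siring_glmm(rows: pd.DataFrame, terms: tuple[str, ...],
                    sigma_fixed: float | None = None,
                    n_quad: int = 25, outcome: str = "sired",
                    group: str = "male_id") -> GlmmFit:
    """ML fit of the logit GLMM with a per-male random intercept.

    The marginal likelihood integrates the random intercept out with
    ``n_quad``-node Gauss-Hermite quadrature; ``sigma_fixed=0`` reduces
    the model to plain logistic regression.  Odds ratios are exponentiated
    coefficients with Wald 95% intervals from the numerical Hessian at
    the optimum.  Separation or non-convergence is flagged, not raised.
    """
    terms = tuple(terms)
    X = build_design(rows, terms)
    y = rows[outcome].to_numpy(int)
    groups = [np.where((rows[group] == g).to_numpy())[0]
              for g in rows[group].unique()]
    t_nodes, t_w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(t_w) - 0.5 * math.log(math.pi)
    p_fixed = X.shape[1]

    def nll(theta):
        return _glmm_nll(theta, X, y, groups, t_nodes, logw, sigma_fixed)

    theta0 = np.zeros(p_fixed + (0 if sigma_fixed is not None else 1))
    if sigma_fixed is None:
        theta0[-1] = math.log(0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                                bounds=[(None, None)] * p_fixed
                                + ([(-8.0, 4.0)]
                                   if sigma_fixed is None else []),
                                options={"maxiter": 2000, "maxfun": 10 ** 5})
    theta = res.x
    beta = theta[:p_fixed]
    sigma = sigma_fixed if sigma_fixed is not None else math.exp(theta[-1])
    hess = _numerical_hessian(nll, theta)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_all = np.full(len(theta), np.nan)
    se = se_all[:p_fixed]
    names = ["intercept"] + list(terms)
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    or_table = pd.DataFrame({
        "OR": np.exp(beta),
        "ci_low": np.exp(beta - 1.959963984540054 * se),
        "ci_high": np.exp(beta + 1.959963984540054 * se),
        "p": pvals,
    }, index=names)
    n_params = p_fixed + (1 if sigma_fixed is None else 0)
    return GlmmFit(terms=terms,
                   coefficients=pd.Series(beta, index=names),
                   se=pd.Series(se, index=names), odds_ratios=or_table,
                   sigma=float(sigma), loglik=float(-res.fun),
                   n_params=n_params, n_rows=len(rows),
                   n_events=int(rows["event_id"].nunique()
                                if "event_id" in rows else y.sum()),
                   converged=bool(res.success))


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i, j in itertools.product(range(n), range(n)):
        if j < i:
            H[i, j] = H[j, i]
            continue
        ei = np.zeros(n)
        ej = np.zeros(n)
        ei[i] = h
        ej[j] = h
        if i == j:
            H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h ** 2
        else:
            H[i, j] = (f(x + ei + ej) - f(x + ei - ej)
                       - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h ** 2)
    return H


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n_obs - n_params - 1 <= 0:
        return np.inf
    return (-2.0 * loglik + 2.0 * n_params
            + 2.0 * n_params * (n_params + 1) / (n_obs - n_params - 1))


def default_model_family() -> dict[str, tuple[str, ...]]:
    """The 14 candidate models: the base terms (age, Elo, relatedness)
    plus linear, quadratic and interaction terms in Dominance and
    Conscientiousness, and one model with all six traits."""
    b = BASE_TERMS
    d, c = "dominance_z", "conscientiousness_z"
    return {
        "base": b,
        "base + dominance": b + (d,),
        "base + dominance + dominance^2": b + (d, f"{d}^2"),
        "base + dominance x age": b + (d, f"{d}:age_z"),
        "base + dominance x age + dominance^2": b + (d, f"{d}:age_z",
                                                     f"{d}^2"),
        "base + dominance x age + dominance^2 x age":
            b + (d, f"{d}:age_z", f"{d}^2", f"{d}^2:age_z"),
        "base + dominance x elo": b + (d, f"{d}:elo_z"),
        "base + conscientiousness": b + (c,),
        "base + conscientiousness + conscientiousness^2": b + (c, f"{c}^2"),
        "base + conscientiousness x age": b + (c, f"{c}:age_z"),
        "base + conscientiousness x age + conscientiousness^2":
            b + (c, f"{c}:age_z", f"{c}^2"),
        "base + conscientiousness x elo": b + (c, f"{c}:elo_z"),
        "base + dominance + conscientiousness": b + (d, c),
        "base + all six traits": b + tuple(f"{t}_z" for t in TRAITS),
    }


def aicc_compare(rows: pd.DataFrame,
                 family: dict[str, tuple[str, ...]] | None = None,
                 **fit_kwargs) -> tuple[pd.DataFrame, dict[str, GlmmFit]]:
    """Fit every model of the family on identical rows and rank by AICc.

    Returns the comparison table (df, AICc, delta, weight; sorted by
    AICc ascending) and the fitted models.
    """
    family = family or default_model_family()
    fits = {name: fit_siring_glmm(rows, terms, **fit_kwargs)
            for name, terms in family.items()}
    tab = pd.DataFrame({
        "df": {n: f.n_params for n, f in fits.items()},
        "AICc": {n: aicc(f.loglik, f.n_params, f.n_rows)
                 for n, f in fits.items()},
    })
    tab = tab.sort_values("AICc")
    tab["delta"] = tab["AICc"] - tab["AICc"].iloc[0]
    rel = np.exp(-0.5 * tab["delta"])
    tab["weight"] = rel / rel.sum()
    return tab, fits
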