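"""Maximum-likelihood Elo rating of a dominance hierarchy.

The classical Elo system updates competitive-ability scores after each
contest: the winner gains, and the loser loses, ``k * (1 - p_win)``
points, where ``p_win`` is the probability the winner was expected to
win given the pre-contest score difference.  Here, instead of fixing the
update constant ``k`` and every individual's starting score by
convention, both are free parameters estimated by maximising the
likelihood of the observed win/loss sequence: each male receives his own
score at hierarchy entry, and ``k`` is shared.  Because the likelihood
depends only on score *differences*, entry scores are identified only up
to translation; the mean entry score is anchored at a fixed constant.

From the fitted parameters the engine expands a per-male-day score
series, with two derived daily measures:

* the *cardinal* score — the mean probability of beating each other male
  present in the hierarchy that day, bounded in [0, 1];
* the *ordinal* rank — the integer position from sorting the day's raw
  scores, 1 = alpha.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize
from scipy.special import expit

from .data_model import hierarchy_entry_dates

__all__ = [
    "EloParams",
    "EloFitReport",
    "expected_win_prob",
    "sequence_nll",
    "fit_ml_elo",
    "daily_elo",
    "cardinal_scores",
    "ordinal_ranks",
    "daily_scores",
]

#: logistic scale of the win-probability curve, in rating points
#: (classical Elo convention: a 'scale' point advantage gives odds 10:1).
DEFAULT_SCALE = 400.0
#: translation anchor for the mean entry score.
DEFAULT_ANCHOR = 1000.0


@dataclasses.dataclass
class EloParams:
    """Update constant plus per-male entry scores."""

    k: float
    entry_scores: dict[str, float]
    scale: float = DEFAULT_SCALE
    anchor: float = DEFAULT_ANCHOR

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclasses.dataclass
class EloFitReport:
    params: EloParams
    nll: float
    converged: bool
    n_interactions: int
    n_evaluations: int
    message: str


def expected_win_prob(score_i, score_j, scale: float = DEFAULT_SCALE):
    """P(i beats j) = 1 / (1 + 10^((score_j - score_i)/scale)).

    Satisfies ``p(i, j) + p(j, i) == 1``; accepts scalars or arrays.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    diff = np.asarray(score_i, dtype=float) - np.asarray(score_j, dtype=float)
    out = expit(math.log(10.0) / scale * diff)
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _seq_nll_core(winner: np.ndarray, loser: np.ndarray, entry: np.ndarray,
                  k: float, scale: float) -> float:
    scores = entry.copy()
    c = math.log(10.0) / scale
    nll = 0.0
    for t in range(winner.size):
        x = c * (scores[winner[t]] - scores[loser[t]])
        # stable -log(sigmoid(x)) and sigmoid(x)
        if x >= 0.0:
            e = math.exp(-x)
            p = 1.0 / (1.0 + e)
            nll += math.log1p(e)
        else:
            e = math.exp(x)
            p = e / (1.0 + e)
            nll += math.log1p(e) - x
        upd = k * (1.0 - p)
        scores[winner[t]] += upd
        scores[loser[t]] -= upd
    return nll


def _encode(interactions: pd.DataFrame,
            male_index: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Winner/loser integer codes in input order (receiver wins)."""
    win = interactions["receiver_id"].map(male_index)
    lose = interactions["giver_id"].map(male_index)
    if win.isna().any() or lose.isna().any():
        missing = sorted(
            set(interactions.loc[win.isna(), "receiver_id"])
            | set(interactions.loc[lose.isna(), "giver_id"]))
        raise KeyError(f"participant(s) without entry score: {missing}")
    return win.to_numpy(np.int64), lose.to_numpy(np.int64)


def sequence_nll(interactions: pd.DataFrame, params: EloParams) -> float:
    """Negative log-likelihood (nats) of the ordered win/loss sequence.

    Scores start at the entry values; after each interaction the winner
    (pant-grunt receiver) gains and the loser gives up ``k * (1 - p_win)``
    points.  Interactions must be sorted by date with a stable within-day
    order (input order is part of the data contract).
    """
    males = list(params.entry_scores)
    idx = {m: i for i, m in enumerate(males)}
    win, lose = _encode(interactions, idx)
    entry = np.array([params.entry_scores[m] for m in males], dtype=float)
    return float(_seq_nll_core(win, lose, entry, params.k, params.scale))


def fit_ml_elo(interactions: pd.DataFrame,
               roster: pd.DataFrame | None = None,
               scale: float = DEFAULT_SCALE,
               anchor: float = DEFAULT_ANCHOR,
               k_start: float = 16.0,
               gtol: float = 1e-8,
               maxiter: int = 2000,
               fix_entries: Mapping[str, float] | None = None) -> EloFitReport:
    """Estimate ``k`` and per-male entry scores by maximum likelihood.

    ``k`` is optimised on the log scale (positivity); entry scores are
    parameterised as anchor-centred deviations, so the flat translation
    direction of the likelihood is projected out.  Deterministic given
    the fixed documented start (``k = k_start``, all entries at the
    anchor).  ``fix_entries`` holds the entry scores at given values and
    optimises ``k`` alone.  Non-convergence is reported in the returned
    :class:`EloFitReport`, not raised.
    """
    interactions = interactions.sort_values("date", kind="stable")
    males = sorted(set(interactions["giver_id"]) | set(interactions["receiver_id"]))
    if len(males) < 2 or len(interactions) < 1:
        raise ValueError("need at least 2 males and 1 interaction")
    idx = {m: i for i, m in enumerate(males)}
    win, lose = _encode(interactions, idx)
    n = len(males)

    fixed_vec = None
    if fix_entries is not None:
        fixed_vec = np.array([fix_entries[m] for m in males], dtype=float)

    def unpack(theta: np.ndarray) -> tuple[float, np.ndarray]:
        k = math.exp(theta[0])
        if fixed_vec is not None:
            return k, fixed_vec
        v = theta[1:]
        entry = anchor + v - v.mean()
        return k, entry

    def objective(theta: np.ndarray) -> float:
        k, entry = unpack(theta)
        return _seq_nll_core(win, lose, entry, k, scale)

    theta0 = np.zeros(1 if fixed_vec is not None else n + 1)
    theta0[0] = math.log(k_start)
    res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                            options={"gtol": gtol, "maxiter": maxiter,
                                     "maxfun": 10 ** 6})
    k_hat, entry_hat = unpack(res.x)
    params = EloParams(k=k_hat,
                       entry_scores={m: float(entry_hat[idx[m]]) for m in males},
                       scale=scale, anchor=anchor)
    if roster is not None:
        for m in roster["male_id"]:
            params.entry_scores.setdefault(m, anchor)
    return EloFitReport(params=params, nll=float(res.fun),
                        converged=bool(res.success),
                        n_interactions=len(interactions),
                        n_evaluations=int(res.nfev), message=str(res.message))


def _replay_scores(interactions: pd.DataFrame,
                   params: EloParams) -> pd.DataFrame:
    """End-of-day raw score for each (male, interaction day) he took part in."""
    males = list(params.entry_scores)
    idx = {m: i for i, m in enumerate(males)}
    win, lose = _encode(interactions, idx)
    entry = np.array([params.entry_scores[m] for m in males], dtype=float)
    scores = entry.copy()
    c = math.log(10.0) / params.scale
    rows: dict[tuple[int, pd.Timestamp], float] = {}
    dates = interactions["date"].to_numpy()
    for t in range(len(win)):
        p = 1.0 / (1.0 + math.exp(-c * (scores[win[t]] - scores[lose[t]])))
        upd = params.k * (1.0 - p)
        scores[win[t]] += upd
        scores[lose[t]] -= upd
        d = dates[t]
        rows[(win[t], d)] = scores[win[t]]
        rows[(lose[t], d)] = scores[lose[t]]
    # overwrite within-day so each key keeps the day's final value
    out = pd.DataFrame(
        [(males[i], pd.Timestamp(d), s) for (i, d), s in rows.items()],
        columns=["male_id", "date", "raw_elo"])
    return out.sort_values(["male_id", "date"], kind="stable")


def daily_elo(params: EloParams, interactions: pd.DataFrame,
              roster: pd.DataFrame, end_date=None) -> pd.DataFrame:
    """Expand fitted parameters to one raw-Elo record per male per day.

    Each male's series runs from his hierarchy-entry date (the later of
    his age-12 date and his first filtered interaction) to his last day
    in the study (death or last observation, capped at ``end_date``).
    The raw score is constant between interaction days and steps on an
    interaction day after that day's updates.
    """
    interactions = interactions.sort_values("date", kind="stable")
    entry = hierarchy_entry_dates(roster, interactions)
    stepped = _replay_scores(interactions, params)
    info = roster.set_index("male_id")
    frames = []
    for male in roster["male_id"]:
        if male not in entry.index or male not in params.entry_scores:
            continue
        start = entry.loc[male]
        stop = info.loc[male, "last_observed"]
        death = info.loc[male, "death_date"]
        if pd.notna(death) and death < stop:
            stop = death
        if end_date is not None:
            stop = min(stop, pd.Timestamp(end_date))
        if pd.isna(start) or stop < start:
            continue
        days = pd.date_range(start, stop, freq="D")
        series = pd.Series(np.nan, index=days)
        series.iloc[0] = params.entry_scores[male]
        steps = stepped[stepped.male_id == male]
        steps = steps[(steps.date >= start) & (steps.date <= stop)]
        series.loc[steps["date"].to_numpy()] = steps["raw_elo"].to_numpy()
        series = series.ffill()
        frames.append(pd.DataFrame({"male_id": male, "date": days,
                                    "raw_elo": series.to_numpy()}))
    return pd.concat(frames, ignore_index=True)


def cardinal_scores(daily: pd.DataFrame,
                    scale: float = DEFAULT_SCALE) -> pd.DataFrame:
    """Attach the cardinal score: mean win probability against the day's field.

    ``cardinal_i = (1/(n-1)) * sum_{j != i} P(i beats j)`` over the ``n``
    males present that day.  Values lie in [0, 1], preserve the within-day
    ordering of raw scores, and sum to ``n/2`` per day.  Days with a
    single male present yield a missing cardinal.
    """
    daily = daily.reset_index(drop=True)
    cardinal = np.full(len(daily), np.nan)
    n_present = np.zeros(len(daily), dtype=int)
    c = math.log(10.0) / scale
    for _, grp in daily.groupby("date", sort=False):
        s = grp["raw_elo"].to_numpy()
        n = len(s)
        n_present[grp.index] = n
        if n < 2:
            continue
        p = expit(c * (s[:, None] - s[None, :]))
        np.fill_diagonal(p, 0.0)
        cardinal[grp.index] = p.sum(axis=1) / (n - 1)
    daily["cardinal"] = cardinal
    daily["n_present"] = n_present
    return daily


def ordinal_ranks(daily: pd.DataFrame) -> pd.DataFrame:
    """Attach the ordinal rank: 1 = highest raw score; ties share the
    smallest applicable rank.  Singleton days yield a missing rank."""
    daily = daily.copy()
    rank = daily.groupby("date")["raw_elo"].rank(method="min",
                                                 ascending=False)
    n = daily.groupby("date")["raw_elo"].transform("size")
    daily["ordinal"] = rank.where(n >= 2)
    return daily


def daily_scores(params: EloParams, interactions: pd.DataFrame,
                 roster: pd.DataFrame, end_date=None) -> pd.DataFrame:
    """Full per-male-day series: raw, cardinal and ordinal scores."""
    daily = daily_elo(params, interactions, roster, end_date=end_date)
    daily = cardinal_scores(daily, scale=params.scale)
    return ordinal_ranks(daily)
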