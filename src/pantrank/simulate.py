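"""Synthetic study communities with known ground truth.

The generator emulates the statistical structure every pipeline stage
assumes, so that estimators can be scored against truth:

* a roster of males with staggered hierarchy entries and deaths over a
  multi-decade study window;
* a single latent *quality* scalar per male that loads on his true entry
  score, his true personality traits (with a configurable
  Dominance-Conscientiousness correlation near -0.6), and his siring
  odds — so every cross-stage association can be switched on or off;
* a pant-grunt interaction stream generated sequentially from a true
  Elo process (winner drawn from the expected win probability at the
  current true scores, scores updated with the true ``k``);
* questionnaire ratings = true trait + rater noise, discretised to the
  1-7 item scale, with noise calibrated so interrater reliabilities of
  mean ratings land in the 0.35-0.55 band typical of such instruments;
* siring events whose sire is drawn by a multinomial logit over the
  candidate males, with configurable coefficients on rank, age,
  relatedness, Dominance and Dominance squared;
* mother-male relatedness from a mixture (most dyads near 0, a minority
  at 0.25/0.5), with some dyads missing to exercise the exclusion path.

All randomness flows from one seed through named sub-streams (roster,
interactions, ratings, relatedness, siring), so stages can be
re-randomised independently.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DAYS_PER_YEAR, StudyBundle, validate_bundle
from .personality import DEFAULT_KEY, TRAITS

__all__ = ["SimConfig", "SyntheticTruth", "simulate_study",
           "recovery_report"]

#: questionnaire items that carry no trait signal (the 'unreliable' five)
FILLER_ITEMS = ["intelligent", "persistent", "bullying", "stingy",
                "manipulative"]


@dataclasses.dataclass
class SimConfig:
    """Generator settings; defaults mirror the study conditions."""

    n_males: int = 30
    study_start: str = "1978-01-01"
    study_years: float = 37.0
    #: age-12 dates spread from this many years before study start ...
    entry_lead_years: float = 10.0
    #: ... to this many years before study end
    entry_tail_years: float = 4.0
    #: mean adult lifespan beyond age 12 (exponential), years
    mean_adult_years: float = 14.0
    min_adult_years: float = 1.5
    #: true Elo process
    true_k: float = 20.0
    #: SD of true entry scores (rating points).  On the 400-point logistic
    #: scale this spreads entry win probabilities over roughly the
    #: 0.1-0.5 cardinal range seen in a real mid-sized hierarchy.
    entry_score_sd: float = 300.0
    entry_quality_loading: float = 0.6
    scale: float = 400.0
    anchor: float = 1000.0
    interactions_per_male_year: float = 16.0
    #: latent quality -> trait loadings (z-scale); the Dominance and
    #: Conscientiousness values give a trait correlation near -0.6
    trait_loadings: dict = dataclasses.field(default_factory=lambda: {
        "dominance": 0.775, "extraversion": 0.30,
        "conscientiousness": -0.775, "agreeableness": -0.20,
        "neuroticism": -0.30, "openness": 0.20})
    n_raters_choices: tuple[int, ...] = (3, 3, 3, 4, 5)
    #: rater noise has two parts, both in z-trait units: an error in the
    #: rater's perception of the male's latent quality, which propagates
    #: through the same trait loadings (halo: the same misjudgement
    #: pushes Dominance up and Conscientiousness down together), and an
    #: independent per-trait residual.  The split keeps interrater
    #: reliabilities of mean scores near 0.35-0.55 while the observed
    #: Dominance-Conscientiousness correlation stays near the configured
    #: trait-level value instead of attenuating toward zero.
    rater_quality_noise_sd: float = 2.0
    #: per-trait independent rater residual SD; the competitive-prowess
    #: traits carry less (their items are behaviorally salient and raters
    #: agree more), so their reliability stays at the top of the band
    rater_trait_noise_sd: dict = dataclasses.field(default_factory=lambda: {
        "dominance": 0.7, "conscientiousness": 0.7, "extraversion": 1.8,
        "agreeableness": 1.8, "neuroticism": 1.8, "openness": 1.4})
    item_noise_sd: float = 0.8
    item_signal_scale: float = 0.8
    #: siring process
    n_events: int = 55
    n_mothers: int = 24
    gestation_days: int = 228
    siring_coefs: dict = dataclasses.field(default_factory=lambda: {
        "elo_z": 0.6, "age_z": -0.2, "relatedness": -2.0,
        "dominance": 0.6, "dominance2": -0.2})
    relatedness_missing_rate: float = 0.10
    seed: int = 0

    @classmethod
    def recovery_benchmark(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Small, dense community for parameter-recovery studies: 10 males
        over 18 years at an interaction density that accumulates a few
        thousand dyadic events."""
        base = dict(n_males=10, study_years=18.0,
                    interactions_per_male_year=40.0, n_events=20, seed=seed)
        base.update(overrides)
        return cls(**base)


@dataclasses.dataclass
class SyntheticTruth:
    k: float
    entry_scores: pd.Series
    quality: pd.Series
    traits: pd.DataFrame  # z-scale true trait values
    siring_coefs: dict
    sire_by_event: pd.Series
    config: SimConfig


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["roster", "interactions", "ratings", "relatedness", "siring"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _make_roster(cfg: SimConfig, rng: np.random.Generator,
                 start: pd.Timestamp, end: pd.Timestamp) -> pd.DataFrame:
    ids = [f"M{i:02d}" for i in range(cfg.n_males)]
    lead = cfg.entry_lead_years
    span = cfg.study_years - cfg.entry_tail_years + lead
    rows = []
    for m in ids:
        while True:
            mature_offset = rng.uniform(-lead, span - lead)  # years from start
            mature = start + pd.Timedelta(
                days=round(mature_offset * DAYS_PER_YEAR))
            adult_years = max(cfg.min_adult_years,
                              rng.exponential(cfg.mean_adult_years))
            death = mature + pd.Timedelta(
                days=round(adult_years * DAYS_PER_YEAR))
            if death >= start + pd.Timedelta(days=90):
                break  # redraw males dead before the window opens
        birth = mature - pd.Timedelta(days=round(12.0 * DAYS_PER_YEAR))
        first = max(birth, start)
        last = min(death, end)
        rows.append({"male_id": m, "birth_date": birth, "first_observed": first,
                     "last_observed": last,
                     "death_date": death if death <= end else pd.NaT,
                     "excluded": False})
    return pd.DataFrame(rows)


def _true_cardinal(scores: np.ndarray, scale: float) -> np.ndarray:
    c = math.log(10.0) / scale
    p = 1.0 / (1.0 + np.exp(-c * (scores[:, None] - scores[None, :])))
    np.fill_diagonal(p, 0.0)
    return p.sum(axis=1) / max(len(scores) - 1, 1)


def _simulate_interactions(cfg: SimConfig, rng, roster, entry_scores,
                           start, end):
    """Sequential true-Elo process; returns the event table and a helper
    giving each male's true score on any day."""
    ids = list(roster["male_id"])
    idx = {m: i for i, m in enumerate(ids)}
    mature = roster["birth_date"] + pd.Timedelta(days=round(12 * DAYS_PER_YEAR))
    enter_day = np.maximum((mature - start).dt.days.to_numpy(), 0)
    last_day = (roster["last_observed"] - start).dt.days.to_numpy()
    n_days = (end - start).days + 1
    scores = entry_scores.to_numpy().copy()
    c = math.log(10.0) / cfg.scale
    daily_rate = cfg.interactions_per_male_year / DAYS_PER_YEAR
    first_int_day = np.full(len(ids), -1)
    events = []
    score_history: list[tuple[int, np.ndarray]] = [(0, scores.copy())]
    for day in range(n_days):
        present = np.where((enter_day <= day) & (day <= last_day))[0]
        if len(present) < 2:
            continue
        n_ev = rng.poisson(daily_rate * len(present))
        changed = False
        for _ in range(n_ev):
            i, j = rng.choice(present, size=2, replace=False)
            p_i = 1.0 / (1.0 + math.exp(-c * (scores[i] - scores[j])))
            if rng.random() < p_i:
                w, l = i, j
                p_w = p_i
            else:
                w, l = j, i
                p_w = 1.0 - p_i
            upd = cfg.true_k * (1.0 - p_w)
            scores[w] += upd
            scores[l] -= upd
            date = start + pd.Timedelta(days=day)
            events.append({"date": date, "giver_id": ids[l],
                           "receiver_id": ids[w]})
            for part in (w, l):
                if first_int_day[part] < 0:
                    first_int_day[part] = day
            changed = True
        if changed:
            score_history.append((day, scores.copy()))
    inter = pd.DataFrame(events)
    hist_days = np.array([d for d, _ in score_history])
    hist_scores = np.vstack([s for _, s in score_history])

    def score_on(day: int) -> np.ndarray:
        pos = np.searchsorted(hist_days, day, side="right") - 1
        return hist_scores[max(pos, 0)]

    present_mask = (enter_day, last_day, first_int_day)
    return inter, score_on, present_mask


def _simulate_ratings(cfg: SimConfig, rng, roster,
                      traits_z: pd.DataFrame) -> pd.DataFrame:
    items_by_trait = {t: DEFAULT_KEY[t] for t in TRAITS}
    rater_pool = [f"R{i:02d}" for i in range(12)]
    rows = []
    for male in roster["male_id"]:
        k = int(rng.choice(cfg.n_raters_choices))
        raters = rng.choice(rater_pool, size=k, replace=False)
        for rater in raters:
            u = rng.normal(0.0, cfg.rater_quality_noise_sd)  # halo error
            for trait, items in items_by_trait.items():
                load = cfg.trait_loadings.get(trait, 0.0)
                res_sd = cfg.rater_trait_noise_sd.get(trait, 1.8)
                delta = load * u + rng.normal(0.0, res_sd)
                for item, sign in items:
                    signal = traits_z.loc[male, trait] + delta
                    val = 4.0 + cfg.item_signal_scale * signal \
                        * (1 if sign == "+" else -1) \
                        + rng.normal(0.0, cfg.item_noise_sd)
                    rows.append({"rater_id": rater, "male_id": male,
                                 "item": item,
                                 "score": int(np.clip(round(val), 1, 7))})
            for item in FILLER_ITEMS:
                val = 4.0 + rng.normal(0.0, 1.5)
                rows.append({"rater_id": rater, "male_id": male, "item": item,
                             "score": int(np.clip(round(val), 1, 7))})
    return pd.DataFrame(rows)


def _simulate_relatedness(cfg: SimConfig, rng, mothers,
                          roster) -> pd.DataFrame:
    rows = []
    for mother in mothers:
        for male in roster["male_id"]:
            if rng.random() < cfg.relatedness_missing_rate:
                continue  # un-genotyped dyad
            u = rng.random()
            if u < 0.70:
                r = rng.uniform(-0.05, 0.05)
            elif u < 0.85:
                r = 0.125
            elif u < 0.95:
                r = 0.25
            else:
                r = 0.5
            rows.append({"mother_id": mother, "male_id": male,
                         "r_value": round(float(r), 4)})
    return pd.DataFrame(rows)


def _simulate_siring(cfg: SimConfig, rng, roster, relatedness, traits_z,
                     score_on, present_mask, start, end):
    enter_day, last_day, first_int_day = present_mask
    ids = list(roster["male_id"])
    births = roster.set_index("male_id")["birth_date"]
    mothers = sorted(set(relatedness["mother_id"]))
    rel = relatedness.set_index(["mother_id", "male_id"])["r_value"]
    coefs = cfg.siring_coefs
    latest_birth_day = (end - start).days
    earliest = cfg.gestation_days

    # pass 1: place events and collect candidate covariates
    drafts = []
    attempts = 0
    while len(drafts) < cfg.n_events and attempts < cfg.n_events * 200:
        attempts += 1
        birth_day = int(rng.integers(earliest + 1, latest_birth_day + 1))
        siring_day = birth_day - cfg.gestation_days
        mother = mothers[rng.integers(len(mothers))]
        scores = score_on(siring_day)
        cand = [i for i, m in enumerate(ids)
                if enter_day[i] <= siring_day <= last_day[i]
                and 0 <= first_int_day[i] <= siring_day  # in observed hierarchy
                and (mother, m) in rel.index]
        if len(cand) < 2:
            continue
        cand = np.array(cand)
        card = _true_cardinal(scores[cand], cfg.scale)
        ages = np.array([
            (siring_day - (births[ids[i]] - start).days) / DAYS_PER_YEAR
            for i in cand])
        rvals = np.array([rel[(mother, ids[i])] for i in cand])
        drafts.append({"birth_day": birth_day, "mother": mother,
                       "cand": cand, "card": card, "ages": ages,
                       "rvals": rvals})
    if len(drafts) < cfg.n_events:
        raise RuntimeError("could not place the requested siring events; "
                           "fewer than 2 co-present candidates too often")

    # pass 2: z-scale age and cardinal over all candidate rows (the scale
    # the risk-set assembly uses), then draw sires by multinomial logit
    all_card = np.concatenate([d["card"] for d in drafts])
    all_ages = np.concatenate([d["ages"] for d in drafts])
    mu_c, sd_c = all_card.mean(), all_card.std(ddof=1)
    mu_a, sd_a = all_ages.mean(), all_ages.std(ddof=1)
    dom_all = traits_z["dominance"].to_numpy()
    events, truth_sires = [], {}
    for n_done, d in enumerate(drafts, start=1):
        dom = dom_all[d["cand"]]
        logits = (coefs["elo_z"] * (d["card"] - mu_c) / sd_c
                  + coefs["age_z"] * (d["ages"] - mu_a) / sd_a
                  + coefs["relatedness"] * d["rvals"]
                  + coefs["dominance"] * dom
                  + coefs["dominance2"] * dom ** 2)
        pr = np.exp(logits - logits.max())
        pr /= pr.sum()
        sire_i = int(rng.choice(d["cand"], p=pr))
        off = f"O{n_done:03d}"
        events.append({"offspring_id": off,
                       "birth_date": start + pd.Timedelta(days=d["birth_day"]),
                       "mother_id": d["mother"], "sire_id": ids[sire_i]})
        truth_sires[off] = ids[sire_i]
    pat = pd.DataFrame(events).sort_values("birth_date").reset_index(drop=True)
    return pat, pd.Series(truth_sires, name="sire_id")


def simulate_study(config: SimConfig | None = None
                   ) -> tuple[StudyBundle, SyntheticTruth]:
    """Generate a full synthetic study bundle plus its ground truth.

    Byte-identical output for identical configs (single seed, named
    sub-streams).  Raises if the configuration cannot co-locate at least
    two males often enough to place interactions and siring events.
    """
    cfg = config or SimConfig()
    rngs = _streams(cfg.seed)
    start = pd.Timestamp(cfg.study_start)
    end = start + pd.Timedelta(days=round(cfg.study_years * DAYS_PER_YEAR))
    roster = _make_roster(cfg, rngs["roster"], start, end)
    ids = list(roster["male_id"])

    r = rngs["roster"]
    quality = pd.Series(r.normal(size=cfg.n_males), index=ids, name="quality")
    lam = cfg.entry_quality_loading
    entry = cfg.anchor + cfg.entry_score_sd * (
        lam * quality + math.sqrt(max(1 - lam ** 2, 0.0))
        * r.normal(size=cfg.n_males))
    entry -= entry.mean() - cfg.anchor
    entry_scores = pd.Series(entry.to_numpy(), index=ids, name="entry_score")

    traits_z = pd.DataFrame(index=ids, columns=TRAITS, dtype=float)
    tr = rngs["ratings"]
    for trait, load in cfg.trait_loadings.items():
        noise = tr.normal(size=cfg.n_males)
        traits_z[trait] = load * quality.to_numpy() \
            + math.sqrt(max(1 - load ** 2, 0.0)) * noise

    inter, score_on, present_mask = _simulate_interactions(
        cfg, rngs["interactions"], roster, entry_scores, start, end)
    if inter.empty:
        raise RuntimeError("no interactions generated; fewer than 2 males "
                           "ever co-present under this configuration")
    ratings = _simulate_ratings(cfg, rngs["ratings"], roster, traits_z)
    mothers = [f"F{i:02d}" for i in range(cfg.n_mothers)]
    relatedness = _simulate_relatedness(cfg, rngs["relatedness"], mothers,
                                        roster)
    paternity, sire_by_event = _simulate_siring(
        cfg, rngs["siring"], roster, relatedness, traits_z, score_on,
        present_mask, start, end)

    bundle = validate_bundle(StudyBundle(
        roster=roster, interactions=inter, ratings=ratings,
        paternity=paternity, relatedness=relatedness))
    truth = SyntheticTruth(k=cfg.true_k, entry_scores=entry_scores,
                           quality=quality, traits=traits_z,
                           siring_coefs=dict(cfg.siring_coefs),
                           sire_by_event=sire_by_event, config=cfg)
    return bundle, truth


def simulate_risk_rows(n_events: int = 55, candidates_per_event: int = 11,
                       n_males: int = 22,
                       coefs: dict | None = None,
                       sigma: float = 0.3,
                       seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Risk-set rows drawn directly from the binomial GLMM.

    Unlike the community simulator (which assigns exactly one sire per
    event by a multinomial logit), this draws each row's outcome as an
    independent Bernoulli with a per-male random intercept — the exact
    data-generating process the GLMM assumes — so it is the right bench
    for coefficient recovery and CI-coverage properties.  Returns the
    rows and the true coefficient dict (including ``intercept`` and
    ``sigma``).
    """
    rng = np.random.default_rng(seed)
    coefs = dict(coefs or {"intercept": -2.2, "age_z": -0.2, "elo_z": 0.4,
                           "relatedness": -2.0, "dominance_z": 0.5,
                           "dominance_z^2": -0.2})
    intercept = coefs.pop("intercept", -2.2)
    males = [f"M{i:02d}" for i in range(n_males)]
    b_male = rng.normal(0.0, sigma, size=n_males)
    dom = rng.normal(size=n_males)
    rows = []
    for ev in range(n_events):
        cand = rng.choice(n_males, size=min(candidates_per_event, n_males),
                          replace=False)
        for i in cand:
            x = {"age_z": rng.normal(), "elo_z": rng.normal(),
                 "relatedness": max(rng.normal(0.05, 0.12), -0.1),
                 "dominance_z": dom[i]}
            eta = intercept + b_male[i]
            for term, beta in coefs.items():
                if term.endswith("^2"):
                    eta += beta * x[term[:-2]] ** 2
                else:
                    eta += beta * x[term]
            y = int(rng.random() < 1.0 / (1.0 + math.exp(-eta)))
            rows.append({"event_id": f"E{ev:03d}", "male_id": males[i],
                         "sired": y, **x})
    truth = dict(coefs)
    truth["intercept"] = intercept
    truth["sigma"] = sigma
    return pd.DataFrame(rows), truth


def recovery_report(truth: SyntheticTruth,
                    k_hat: float | None = None,
                    entry_hat: pd.Series | None = None,
                    traits_hat: pd.DataFrame | None = None,
                    siring_fit=None) -> pd.DataFrame:
    """Score pipeline estimates against the generator's ground truth.

    Returns a metric table with one row per comparison: relative error
    of ``k``, Spearman correlation of entry scores, per-trait RMSE after
    z-scoring, and bias plus Wald-CI coverage for each siring
    coefficient present in both the truth and the fit.
    """
    rows = []
    if k_hat is not None:
        rows.append({"metric": "k_relative_error",
                     "value": abs(k_hat - truth.k) / truth.k})
    if entry_hat is not None:
        common = truth.entry_scores.index.intersection(entry_hat.index)
        rho = stats.spearmanr(truth.entry_scores[common],
                              entry_hat[common]).statistic
        rows.append({"metric": "entry_score_spearman", "value": float(rho)})
    if traits_hat is not None:
        for trait in TRAITS:
            if trait not in traits_hat.columns:
                continue
            est = traits_hat[trait].dropna()
            common = truth.traits.index.intersection(est.index)
            est_z = (est[common] - est[common].mean()) / est[common].std(ddof=1)
            tr_z = truth.traits.loc[common, trait]
            tr_z = (tr_z - tr_z.mean()) / tr_z.std(ddof=1)
            rmse = float(np.sqrt(np.mean((est_z - tr_z) ** 2)))
            rows.append({"metric": f"trait_rmse_z[{trait}]", "value": rmse})
    if siring_fit is not None:
        name_map = {"elo_z": "elo_z", "age_z": "age_z",
                    "relatedness": "relatedness",
                    "dominance": "dominance_z",
                    "dominance2": "dominance_z^2"}
        for tkey, term in name_map.items():
            if term not in siring_fit.coefficients.index:
                continue
            b = siring_fit.coefficients[term]
            se = siring_fit.se[term]
            true_b = truth.siring_coefs[tkey]
            rows.append({"metric": f"siring_bias[{term}]",
                         "value": float(b - true_b)})
            covered = (b - 1.96 * se) <= true_b <= (b + 1.96 * se)
            rows.append({"metric": f"siring_ci_covers[{term}]",
                         "value": float(covered)})
    return pd.DataFrame(rows).set_index("metric")
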