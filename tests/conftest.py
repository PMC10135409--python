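import warnings

import pandas as pd
import pytest

from pantrank.data_model import StudyBundle, validate_bundle
from pantrank.simulate import SimConfig, simulate_study


def _d(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture(scope="session")
def toy_bundle() -> StudyBundle:
    """Three males, five interactions, minimal satellite tables."""
    roster = pd.DataFrame({
        "male_id": ["A", "B", "C"],
        "birth_date": [_d("1980-01-01"), _d("1978-06-01"), _d("1981-03-15")],
        "first_observed": [_d("1990-01-01")] * 3,
        "last_observed": [_d("2000-12-31")] * 3,
        "death_date": [pd.NaT, pd.NaT, pd.NaT],
        "excluded": [False, False, False],
    })
    interactions = pd.DataFrame({
        "date": [_d("1995-01-10"), _d("1995-02-20"), _d("1995-03-05"),
                 _d("1995-06-01"), _d("1995-09-15")],
        "giver_id": ["A", "C", "C", "B", "B"],
        "receiver_id": ["B", "A", "B", "A", "C"],
    })
    ratings = pd.DataFrame({
        "rater_id": ["R1"] * 3 + ["R2"] * 3,
        "male_id": ["A", "B", "C"] * 2,
        "item": ["dominant"] * 6,
        "score": [5, 6, 3, 4, 6, 2],
    })
    paternity = pd.DataFrame({
        "offspring_id": ["O1"],
        "birth_date": [_d("1996-01-01")],
        "mother_id": ["F1"],
        "sire_id": ["B"],
    })
    relatedness = pd.DataFrame({
        "mother_id": ["F1"] * 3,
        "male_id": ["A", "B", "C"],
        "r_value": [0.0, 0.125, 0.0],
    })
    return validate_bundle(StudyBundle(roster=roster, interactions=interactions,
                                       ratings=ratings, paternity=paternity,
                                       relatedness=relatedness))


@pytest.fixture(scope="session")
def small_community():
    """A compact simulated community shared across pipeline tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, truth = simulate_study(
            SimConfig(seed=7, n_males=12, study_years=16, n_events=15))
    return bundle, truth


@pytest.fixture(scope="session")
def small_pipeline(small_community):
    """Elo fit, daily scores and trait scores on the small community."""
    from pantrank.data_model import filter_adult_interactions
    from pantrank.elo import daily_scores, fit_ml_elo
    from pantrank.personality import score_traits

    bundle, truth = small_community
    adult = filter_adult_interactions(bundle.interactions, bundle.roster)
    report = fit_ml_elo(adult, bundle.roster)
    daily = daily_scores(report.params, adult, bundle.roster)
    traits = score_traits(bundle.ratings)
    return {"bundle": bundle, "truth": truth, "adult": adult,
            "report": report, "daily": daily, "traits": traits}
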