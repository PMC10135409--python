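"""Study tables, validation, and date/age arithmetic.

The study revolves around five delimited-text tables:

``roster``
    One row per male: ``male_id, birth_date, first_observed, last_observed,
    death_date, excluded``.  ``excluded`` flags sensitivity exclusions
    (e.g. a male whose atypical trajectory is removed in robustness
    re-runs); downstream stages consume the flag, rows are never dropped
    silently.
``interactions``
    Dated pant-grunt events, ``date, giver_id, receiver_id``.  The giver
    (pant-grunter) is the subordinate; the receiver is treated as the
    winner of the dyadic contest by the Elo engine.
``ratings``
    Long-format questionnaire ratings, ``rater_id, male_id, item, score``
    with integer scores on a 1-7 scale.
``paternity``
    ``offspring_id, birth_date, mother_id, sire_id`` with genetically
    confirmed sires.
``relatedness``
    Pairwise mother x candidate-male genetic relatedness,
    ``mother_id, male_id, r_value``.

All dates are ISO-8601 calendar dates, day arithmetic is in whole days,
and ages are decimal years with 1 year = 365.25 days.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "SchemaError",
    "IntegrityError",
    "StudyBundle",
    "load_study_tables",
    "save_study_tables",
    "age_on",
    "filter_adult_interactions",
    "hierarchy_entry_dates",
]

DAYS_PER_YEAR = 365.25
#: minimum age (years) for a pant-grunt participant to enter the rank record
ADULT_AGE = 12.0

_SCHEMAS: dict[str, list[str]] = {
    "roster": ["male_id", "birth_date", "first_observed", "last_observed"],
    "interactions": ["date", "giver_id", "receiver_id"],
    "ratings": ["rater_id", "male_id", "item", "score"],
    "paternity": ["offspring_id", "birth_date", "mother_id", "sire_id"],
    "relatedness": ["mother_id", "male_id", "r_value"],
}

_DATE_COLS: dict[str, list[str]] = {
    "roster": ["birth_date", "first_observed", "last_observed", "death_date"],
    "interactions": ["date"],
    "paternity": ["birth_date"],
}


class SchemaError(ValueError):
    """A table is missing required columns or has unparseable values."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


@dataclasses.dataclass
class StudyBundle:
    """Validated study tables ready for the analysis stages."""

    roster: pd.DataFrame
    interactions: pd.DataFrame
    ratings: pd.DataFrame
    paternity: pd.DataFrame
    relatedness: pd.DataFrame

    def male_ids(self) -> list[str]:
        return list(self.roster["male_id"])

    def copy(self) -> "StudyBundle":
        return StudyBundle(**{
            f.name: getattr(self, f.name).copy()
            for f in dataclasses.fields(self)
        })


def _parse_dates(df: pd.DataFrame, table: str) -> pd.DataFrame:
    for col in _DATE_COLS.get(table, []):
        if col not in df.columns:
            continue
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError):
            parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
            bad = df.index[parsed.isna() & df[col].notna()]
            raise SchemaError(
                f"{table}.{col}: unparseable date at row(s) {list(bad[:5])}"
            ) from None
    return df


def _check_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _read_table(path: Path, table: str,
                column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    sep = "\t" if Path(path).suffix in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    _check_columns(df, table)
    return df


def validate_bundle(bundle: StudyBundle) -> StudyBundle:
    """Run schema, invariant and referential-integrity checks in place."""
    roster = bundle.roster
    _check_columns(roster, "roster")
    if "death_date" not in roster.columns:
        roster["death_date"] = pd.NaT
    if "excluded" not in roster.columns:
        roster["excluded"] = False
    roster["excluded"] = roster["excluded"].astype(str).str.lower().isin(
        {"true", "1", "yes"}) if roster["excluded"].dtype == object \
        else roster["excluded"].astype(bool)
    if roster["male_id"].duplicated().any():
        dup = roster.loc[roster["male_id"].duplicated(), "male_id"].tolist()
        raise IntegrityError(f"roster: duplicate male_id(s) {dup}")

    bad = roster[(roster.birth_date > roster.first_observed)
                 | (roster.first_observed > roster.last_observed)]
    if len(bad):
        raise IntegrityError(
            "roster: birth_date <= first_observed <= last_observed violated "
            f"for {bad.male_id.tolist()}")
    has_death = roster.death_date.notna()
    bad = roster[has_death & (roster.death_date
                              < roster.last_observed - pd.Timedelta(days=1))]
    if len(bad):
        raise IntegrityError(
            f"roster: death_date precedes last_observed for {bad.male_id.tolist()}")

    males = set(roster.male_id)
    inter = bundle.interactions
    if (inter.giver_id == inter.receiver_id).any():
        raise IntegrityError("interactions: self-directed pant-grunt records")
    for table, cols in [("interactions", ["giver_id", "receiver_id"]),
                        ("ratings", ["male_id"]),
                        ("relatedness", ["male_id"])]:
        df = getattr(bundle, table)
        for col in cols:
            unknown = sorted(set(df[col]) - males)
            if unknown:
                raise IntegrityError(
                    f"{table}.{col}: unknown male id(s) {unknown}")
    unknown = sorted(set(bundle.paternity.sire_id) - males)
    if unknown:
        raise IntegrityError(f"paternity.sire_id: unknown male id(s) {unknown}")

    scores = pd.to_numeric(bundle.ratings["score"], errors="coerce")
    if scores.isna().any() or not scores.isin(range(1, 8)).all():
        raise SchemaError("ratings.score: values must be integers in 1..7")
    bundle.ratings["score"] = scores.astype(int)
    if bundle.ratings.duplicated(["rater_id", "male_id", "item"]).any():
        raise IntegrityError("ratings: duplicate rater x male x item rows")

    rel = bundle.relatedness
    rel["r_value"] = pd.to_numeric(rel["r_value"])
    if rel.duplicated(["mother_id", "male_id"]).any():
        raise IntegrityError("relatedness: duplicate mother x male dyads")
    return bundle


def load_study_tables(paths: Mapping[str, str | Path],
                      column_maps: Mapping[str, Mapping[str, str]] | None = None,
                      ) -> StudyBundle:
    """Read, validate and bundle the five study tables.

    Parameters
    ----------
    paths
        Mapping from table name (``roster``, ``interactions``, ``ratings``,
        ``paternity``, ``relatedness``) to a CSV/TSV path.
    column_maps
        Optional per-table mapping from file column names to the canonical
        names, for data deposited under different headers.
    """
    missing = sorted(set(_SCHEMAS) - set(paths))
    if missing:
        raise SchemaError(f"missing table path(s): {missing}")
    tables = {}
    for name in _SCHEMAS:
        cmap = (column_maps or {}).get(name)
        tables[name] = _parse_dates(_read_table(Path(paths[name]), name, cmap),
                                    name)
    return validate_bundle(StudyBundle(**tables))


def save_study_tables(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical normalized tables as comma-delimited text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in _SCHEMAS:
        df = getattr(bundle, name).copy()
        for col in _DATE_COLS.get(name, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    return written


def age_on(birth_date, date) -> float:
    """Age in decimal years on ``date`` for an animal born ``birth_date``.

    Whole-day difference divided by 365.25.  Raises ``ValueError`` for
    dates before birth.
    """
    birth_date = pd.Timestamp(birth_date)
    date = pd.Timestamp(date)
    if date < birth_date:
        raise ValueError(f"date {date.date()} precedes birth {birth_date.date()}")
    return (date - birth_date).days / DAYS_PER_YEAR


def _ages_vector(dates: pd.Series, births: pd.Series) -> np.ndarray:
    return (dates.to_numpy() - births.to_numpy()) / np.timedelta64(1, "D") \
        / DAYS_PER_YEAR


def filter_adult_interactions(interactions: pd.DataFrame,
                              roster: pd.DataFrame,
                              min_age: float = ADULT_AGE) -> pd.DataFrame:
    """Retain pant-grunt records where both participants are adults.

    Both the giver and the receiver must be at least ``min_age`` decimal
    years old on the interaction date (inclusive boundary).  Row order is
    preserved; the filter is idempotent.
    """
    births = roster.set_index("male_id")["birth_date"]
    g_age = _ages_vector(interactions["date"],
                         interactions["giver_id"].map(births))
    r_age = _ages_vector(interactions["date"],
                         interactions["receiver_id"].map(births))
    keep = (g_age >= min_age) & (r_age >= min_age)
    return interactions.loc[keep].reset_index(drop=True)


def hierarchy_entry_dates(roster: pd.DataFrame,
                          interactions: pd.DataFrame,
                          min_age: float = ADULT_AGE) -> pd.Series:
    """Operational hierarchy-entry date per male.

    Entry = the later of the male's age-``min_age`` date and his first
    appearance in the (already adult-filtered) interaction record.  Males
    absent from the interaction record enter at the age threshold.
    """
    entry_offset = pd.Timedelta(days=round(min_age * DAYS_PER_YEAR))
    age_date = roster.set_index("male_id")["birth_date"] + entry_offset
    first_seen = pd.concat([
        interactions.groupby("giver_id")["date"].min(),
        interactions.groupby("receiver_id")["date"].min(),
    ], axis=1).min(axis=1)
    entry = age_date.to_frame("age_date").join(first_seen.rename("first_int"))
    out = entry[["age_date", "first_int"]].max(axis=1)
    out.name = "entry_date"
    out.index.name = "male_id"
    return out
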