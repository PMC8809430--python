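"""Reading, validating and collapsing raw survey tables; report-table output.

Raw surveys arrive as one row per site x station x date x 30-minute interval x
species.  The analysis-ready object is a site x month x species count array
with an aligned effort (survey duration) covariate.  The collapse follows the
field protocol: within a station-survey the count is the maximum over 30-min
intervals; stations combine into a site value by a configurable rule (max by
default, to stay conservative against double counting); repeat surveys of a
site within one calendar month collapse again by maximum; effort is the total
duration, in hours, of that site's survey sessions in the month.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateCovariateError, ValidationError

SURVEY_COLUMNS = (
    "site_id",
    "station_id",
    "survey_date",
    "interval_index",
    "species",
    "count",
    "effort_minutes",
)

RESPONDENT_BASE_COLUMNS = ("respondent_id", "age", "gender", "education")

GENDER_LEVELS = ("male", "female")
EDUCATION_LEVELS = ("formal", "nonformal")


@dataclasses.dataclass(frozen=True)
class RawSurveyRecord:
    """One 30-minute interval count of one species at one station."""

    site_id: str
    station_id: str
    survey_date: _dt.date
    interval_index: int
    species: str
    count: int
    effort_minutes: float

    def __post_init__(self) -> None:
        if self.interval_index < 1:
            raise ValidationError(f"interval_index must be >= 1, got {self.interval_index}")
        if self.count < 0:
            raise ValidationError(f"count must be non-negative, got {self.count}")
        if not float(self.effort_minutes) > 0:
            raise ValidationError(f"effort_minutes must be positive, got {self.effort_minutes}")


@dataclasses.dataclass
class SurveyDataset:
    """Collapsed site x month x species counts with aligned effort covariate.

    ``counts`` has shape (S, T, K) and ``effort_raw``/``effort_std`` shape
    (S, T).  Missing site-months are NaN in both counts and effort; a zero
    count is an observation, the absence of a survey is not.  ``effort_std``
    is the scaled-and-centered effort covariate (mean 0, sample SD 1 over
    non-missing cells), except when every recorded effort is equal, in which
    case it is all zero and ``effort_degenerate`` is set.
    """

    sites: list[str]
    months: list[int]
    species: list[str]
    counts: np.ndarray
    effort_raw: np.ndarray
    effort_std: np.ndarray
    month_labels: list[str] | None = None
    effort_degenerate: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.effort_raw = np.asarray(self.effort_raw, dtype=float)
        self.effort_std = np.asarray(self.effort_std, dtype=float)
        S, T, K = len(self.sites), len(self.months), len(self.species)
        if self.counts.shape != (S, T, K):
            raise ValidationError(
                f"counts shape {self.counts.shape} != (n_sites, n_months, n_species) {(S, T, K)}"
            )
        if self.effort_raw.shape != (S, T) or self.effort_std.shape != (S, T):
            raise ValidationError("effort arrays must have shape (n_sites, n_months)")
        if list(self.months) != list(range(self.months[0], self.months[0] + T)):
            raise ValidationError("months must be consecutive integers")
        obs = ~np.isnan(self.counts)
        eff_obs = ~np.isnan(self.effort_raw)
        if not np.array_equal(obs.any(axis=2), eff_obs) or not np.array_equal(
            obs.all(axis=2), eff_obs
        ):
            raise ValidationError("counts must be missing exactly where effort is missing")
        vals = self.counts[obs]
        if vals.size and (np.any(vals < 0) or np.any(vals != np.round(vals))):
            raise ValidationError("counts must be non-negative integers")
        if np.any(self.effort_raw[eff_obs] <= 0):
            raise ValidationError("effort must be positive where present")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_months(self) -> int:
        return len(self.months)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, species: str | int | None = None) -> int:
        if species is None:
            if self.n_species != 1:
                raise ValidationError(
                    "dataset holds multiple species; one must be named explicitly"
                )
            return 0
        if isinstance(species, (int, np.integer)):
            return int(species)
        try:
            return self.species.index(species)
        except ValueError:
            raise ValidationError(f"unknown species label {species!r}") from None

    def species_counts(self, species: str | int | None = None) -> np.ndarray:
        """(S, T) count slice for one species."""
        return self.counts[:, :, self.species_index(species)]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, site in enumerate(self.sites):
            for j, month in enumerate(self.months):
                if np.isnan(self.effort_raw[i, j]):
                    continue
                for k, sp in enumerate(self.species):
                    rows.append(
                        {
                            "site": site,
                            "month": month,
                            "species": sp,
                            "count": int(self.counts[i, j, k]),
                            "effort_hours": self.effort_raw[i, j],
                        }
                    )
        return pd.DataFrame(rows, columns=["site", "month", "species", "count", "effort_hours"])

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "SurveyDataset":
        required = {"site", "month", "species", "count", "effort_hours"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"missing columns: {sorted(missing)}")
        sites = sorted(frame["site"].astype(str).unique())
        months = list(range(int(frame["month"].min()), int(frame["month"].max()) + 1))
        species = sorted(frame["species"].astype(str).unique())
        S, T, K = len(sites), len(months), len(species)
        counts = np.full((S, T, K), np.nan)
        effort = np.full((S, T), np.nan)
        si = {s: i for i, s in enumerate(sites)}
        mi = {m: j for j, m in enumerate(months)}
        ki = {k: i for i, k in enumerate(species)}
        for _, row in frame.iterrows():
            i, j, k = si[str(row["site"])], mi[int(row["month"])], ki[str(row["species"])]
            counts[i, j, k] = row["count"]
            e = float(row["effort_hours"])
            if not np.isnan(effort[i, j]) and abs(effort[i, j] - e) > 1e-9:
                raise ValidationError(
                    f"conflicting effort for site {row['site']} month {row['month']}"
                )
            effort[i, j] = e
        # a surveyed site-month with a species absent from the file is a zero count
        surveyed = ~np.isnan(effort)
        for k in range(K):
            sl = counts[:, :, k]
            sl[surveyed & np.isnan(sl)] = 0.0
        effort_std, degenerate = _effort_std_or_zero(effort)
        return cls(sites, months, species, counts, effort, effort_std,
                   effort_degenerate=degenerate)


@dataclasses.dataclass
class RespondentTable:
    """Questionnaire records: one adult respondent per row.

    ``frame`` carries respondent_id, age, gender, education plus one column
    per question.  Ages must exceed 16 (adults only); gender and education
    come from their closed category sets.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(RESPONDENT_BASE_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"respondent table missing columns: {sorted(missing)}")
        ages = self.frame["age"]
        if not (ages > 16).all():
            raise ValidationError("all respondents must be adults (age > 16)")
        bad_gender = set(self.frame["gender"].dropna()) - set(GENDER_LEVELS)
        if bad_gender:
            raise ValidationError(f"unknown gender levels: {sorted(bad_gender)}")
        bad_edu = set(self.frame["education"].dropna()) - set(EDUCATION_LEVELS)
        if bad_edu:
            raise ValidationError(f"unknown education levels: {sorted(bad_edu)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def questions(self) -> list[str]:
        return [c for c in self.frame.columns if c not in RESPONDENT_BASE_COLUMNS]


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return pd.Timestamp(value).date()


def read_survey_csv(
    path, columns: Mapping[str, str] | None = None
) -> list[RawSurveyRecord]:
    """Read raw interval-count records from a CSV file.

    ``columns`` maps canonical field names (``site_id`` ... ``effort_minutes``)
    to the column names actually present in the file.  Validation errors cite
    the physical file line (header = line 1).
    """
    frame = pd.read_csv(path)
    rename = {}
    colmap = dict(columns or {})
    for canonical in SURVEY_COLUMNS:
        actual = colmap.get(canonical, canonical)
        if actual not in frame.columns:
            raise ConfigurationError(f"missing required column {actual!r} (for {canonical})")
        rename[actual] = canonical
    frame = frame.rename(columns=rename)

    records: list[RawSurveyRecord] = []
    for pos, row in enumerate(frame.to_dict("records")):
        line = pos + 2
        count = row["count"]
        if pd.isna(count) or float(count) != int(count) or int(count) < 0:
            raise ValidationError(f"row {line}: count must be a non-negative integer, got {count}")
        try:
            rec = RawSurveyRecord(
                site_id=str(row["site_id"]),
                station_id=str(row["station_id"]),
                survey_date=_parse_date(row["survey_date"]),
                interval_index=int(row["interval_index"]),
                species=str(row["species"]),
                count=int(count),
                effort_minutes=float(row["effort_minutes"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {line}: {exc}") from None
        records.append(rec)

    keys = [(r.site_id, r.station_id, r.survey_date, r.interval_index, r.species)
            for r in records]
    if len(set(keys)) != len(keys):
        seen: set = set()
        for pos, key in enumerate(keys):
            if key in seen:
                raise ValidationError(f"row {pos + 2}: duplicate record key {key}")
            seen.add(key)
    return records


def _month_index(date: _dt.date) -> int:
    return date.year * 12 + (date.month - 1)


def collapse_station_counts(
    records: Sequence[RawSurveyRecord], aggregation: str = "max"
) -> SurveyDataset:
    """Collapse raw interval records into the analysis-ready dataset.

    Within a station-survey the count is the interval maximum; stations
    combine into a site value by ``aggregation`` ("max" or "sum"); repeat
    surveys of a site in one calendar month collapse by maximum.  Effort per
    site-month is the total duration in hours of that site's survey sessions
    (a session's duration being the longest station effort on that date).
    """
    if not records:
        raise ValidationError("no survey records to collapse")
    if aggregation not in ("max", "sum"):
        raise ConfigurationError(f"aggregation must be 'max' or 'sum', got {aggregation!r}")

    df = pd.DataFrame(
        {
            "site": [r.site_id for r in records],
            "station": [r.station_id for r in records],
            "date": [r.survey_date for r in records],
            "species": [r.species for r in records],
            "count": [r.count for r in records],
            "effort": [r.effort_minutes for r in records],
        }
    )
    effort_check = df.groupby(["site", "station", "date"])["effort"].nunique()
    if (effort_check > 1).any():
        bad = effort_check[effort_check > 1].index[0]
        raise ValidationError(f"conflicting effort values for station-survey {bad}")

    # interval max per station-survey-species
    station = (
        df.groupby(["site", "station", "date", "species"], as_index=False)
        .agg(count=("count", "max"), effort=("effort", "first"))
    )
    # across-station aggregation per site-survey-species
    site_survey = (
        station.groupby(["site", "date", "species"], as_index=False)
        .agg(count=("count", aggregation))
    )
    # session duration: longest station effort that date (observers are simultaneous)
    session_effort = (
        station.groupby(["site", "date"], as_index=False).agg(effort=("effort", "max"))
    )

    site_survey["month"] = site_survey["date"].map(_month_index)
    session_effort["month"] = session_effort["date"].map(_month_index)

    sites = sorted(df["site"].unique())
    species = sorted(df["species"].unique())
    m0 = int(site_survey["month"].min())
    m1 = int(site_survey["month"].max())
    T = m1 - m0 + 1
    S, K = len(sites), len(species)
    months = list(range(1, T + 1))
    month_labels = [
        f"{(m0 + t) // 12:04d}-{(m0 + t) % 12 + 1:02d}" for t in range(T)
    ]

    counts = np.full((S, T, K), np.nan)
    effort = np.full((S, T), np.nan)
    si = {s: i for i, s in enumerate(sites)}
    ki = {k: i for i, k in enumerate(species)}

    eff_month = session_effort.groupby(["site", "month"])["effort"].sum()
    for (site, month), minutes in eff_month.items():
        effort[si[site], month - m0] = minutes / 60.0

    # repeat surveys within a month collapse by maximum
    cnt_month = site_survey.groupby(["site", "month", "species"])["count"].max()
    for (site, month, sp), c in cnt_month.items():
        counts[si[site], month - m0, ki[sp]] = c

    surveyed = ~np.isnan(effort)
    for k in range(K):
        sl = counts[:, :, k]
        sl[surveyed & np.isnan(sl)] = 0.0

    effort_std, degenerate = _effort_std_or_zero(effort)

    return SurveyDataset(
        sites, months, species, counts, effort, effort_std,
        month_labels=month_labels, effort_degenerate=degenerate,
    )


def _effort_std_or_zero(effort: np.ndarray) -> tuple[np.ndarray, bool]:
    """Standardized effort, or an all-zero covariate (flagged) when the
    recorded efforts carry no contrast (all equal, or a single survey)."""
    surveyed = ~np.isnan(effort)
    if surveyed.sum() < 2:
        return np.where(surveyed, 0.0, np.nan), True
    try:
        return standardize_effort(effort), False
    except DegenerateCovariateError:
        return np.where(surveyed, 0.0, np.nan), True


def standardize_effort(effort_raw: np.ndarray) -> np.ndarray:
    """Scale and center effort to mean 0 and sample SD 1 over non-missing cells.

    Missing (NaN) positions stay missing.  Raises DegenerateCovariateError
    when all non-missing values are equal (the caller may then drop the
    effort term).
    """
    arr = np.asarray(effort_raw, dtype=float)
    obs = ~np.isnan(arr)
    vals = arr[obs]
    if vals.size < 2:
        raise ValidationError("need at least two non-missing effort values")
    sd = np.std(vals, ddof=1)
    if sd == 0 or np.allclose(vals, vals[0], rtol=0, atol=1e-12 * max(1.0, abs(vals[0]))):
        raise DegenerateCovariateError("all effort values equal; cannot scale to unit SD")
    out = np.full_like(arr, np.nan)
    out[obs] = (vals - vals.mean()) / sd
    return out


def write_summary_csv(summary, path) -> None:
    """Write an AbundanceSummary as a report CSV (Table-1 shape).

    Columns: species, site, n_observations, pct_2_5, median, pct_97_5.
    Values round-trip losslessly at 6 significant digits.
    """
    frame = summary.to_frame()
    frame.to_csv(path, index=False, float_format="%.6g")


def read_summary_csv(path):
    from .summaries import AbundanceSummary

    return AbundanceSummary.from_frame(pd.read_csv(path))


def read_respondents_csv(path) -> RespondentTable:
    return RespondentTable(pd.read_csv(path))


def write_respondents_csv(table: RespondentTable, path) -> None:
    table.frame.to_csv(path, index=False)
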