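"""Coding, imputation, weighting and exclusion rules for raw panel records.

Turns raw survey answers (activity-limitation items, the current-employment
item, arthritis ever-diagnosis, self-reported height/weight, fixed
demographics and per-wave cross-sectional weights) into an analysis-ready
coded panel: one row per person-wave with a state code, time-varying
arthritis/obesity, a single longitudinal weight per person, and exact
fractional ages.

Coding conventions
------------------
* "Healthy" means no reported limitation on any of three activity-limitation
  items; any "yes" codes unhealthy.  A record with no item answered is
  missing; a partially answered record with no "yes" cannot be confirmed
  healthy and is also treated as missing.
* "Working" means the current-employment item is "working now"; any other
  stated answer (laid off, unemployed, disabled, retired, homemaker, other)
  codes not working.
* Arthritis is irreversible: once reported it is carried forward, and it is
  taken as absent at and before an explicit negative response.
* Obesity is BMI >= 30 (inclusive), from baseline height and per-wave
  weight; per-wave self-reported heights are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import DEAD, UNKNOWN_STATE, UNKNOWN_VITAL
from .timeutil import age_at, month_index, month_str

YES = "yes"
NO = "no"

WORKING_NOW = "working now"
NOT_WORKING_ANSWERS = frozenset({
    "temporarily laid off",
    "unemployed and looking for work",
    "disabled and unable to work",
    "retired",
    "homemaker",
    "other",
})

HIGH_SCHOOL_OR_ABOVE = frozenset({
    "high school diploma", "ged", "some college", "college and above",
    "high school", "college",
})
LESS_THAN_HIGH_SCHOOL = frozenset({"less than high school", "none"})

# US Census Bureau four-region grouping (50 states + DC)
REGIONS = {
    "Midwest": [
        "Illinois", "Indiana", "Iowa", "Kansas", "Michigan", "Minnesota",
        "Missouri", "Nebraska", "North Dakota", "Ohio", "South Dakota",
        "Wisconsin",
    ],
    "Northeast": [
        "Connecticut", "Maine", "Massachusetts", "New Hampshire", "New Jersey",
        "New York", "Pennsylvania", "Rhode Island", "Vermont",
    ],
    "South": [
        "Alabama", "Arkansas", "Delaware", "District of Columbia", "Florida",
        "Georgia", "Kentucky", "Louisiana", "Maryland", "Mississippi",
        "North Carolina", "Oklahoma", "South Carolina", "Tennessee", "Texas",
        "Virginia", "West Virginia",
    ],
    "West": [
        "Alaska", "Arizona", "California", "Colorado", "Hawaii", "Idaho",
        "Montana", "Nevada", "New Mexico", "Oregon", "Utah", "Washington",
        "Wyoming",
    ],
}
_STATE_TO_REGION = {s: r for r, states in REGIONS.items() for s in states}


class CodingError(ValueError):
    """An answer outside the documented answer set."""


class AllMissing(ValueError):
    """A per-wave series with no observed value; the person must be excluded
    upstream rather than imputed."""


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v == ""


def classify_health(answers) -> str:
    """Code the three activity-limitation answers.

    Returns ``"healthy"`` (all three answered "no"), ``"not_healthy"``
    (any "yes"), or ``"missing"`` otherwise.
    """
    if len(answers) != 3:
        raise ValueError("expected exactly three limitation answers")
    coded = []
    for a in answers:
        if _is_missing(a):
            coded.append(None)
        elif str(a).strip().lower() in (YES, NO):
            coded.append(str(a).strip().lower())
        else:
            raise CodingError(f"limitation answer must be yes/no/missing, got {a!r}")
    if any(a == YES for a in coded):
        return "not_healthy"
    if all(a == NO for a in coded):
        return "healthy"
    return "missing"


def classify_work(answer) -> str:
    """Code the current-employment item: ``"working"`` iff "working now";
    any other stated answer is ``"not_working"``; otherwise ``"missing"``."""
    if _is_missing(answer):
        return "missing"
    a = str(answer).strip().lower()
    if a == WORKING_NOW:
        return "working"
    if a in NOT_WORKING_ANSWERS:
        return "not_working"
    raise CodingError(
        f"unrecognized employment answer {answer!r}; allowed: "
        f"{[WORKING_NOW] + sorted(NOT_WORKING_ANSWERS)}"
    )


def encode_state(health: str, work: str, vital_status: str = "alive") -> int:
    """Combine health/work classifications and vital status into a state code.

    dead -> DEAD; alive with both classifications known -> 1..4; alive with
    either missing -> -1; unknown vital status -> -2.
    """
    if vital_status == "dead":
        return DEAD
    if vital_status == "unknown":
        return UNKNOWN_VITAL
    if vital_status != "alive":
        raise CodingError(f"vital status must be alive/dead/unknown, got {vital_status!r}")
    if health == "missing" or work == "missing":
        return UNKNOWN_STATE
    table = {("healthy", "working"): 1, ("healthy", "not_working"): 2,
             ("not_healthy", "working"): 3, ("not_healthy", "not_working"): 4}
    try:
        return table[(health, work)]
    except KeyError:
        raise CodingError(f"invalid classification pair ({health!r}, {work!r})") from None


def impute_time_varying_nearest(values: list) -> list:
    """Fill missing per-wave values from the nearest observed wave.

    Nearest is by wave distance; on a tie the earlier wave wins (no future
    information).  Raises :class:`AllMissing` when nothing is observed.
    """
    observed = [i for i, v in enumerate(values) if not _is_missing(v)]
    if not observed:
        raise AllMissing("no observed value at any wave")
    out = list(values)
    for i in range(len(values)):
        if _is_missing(values[i]):
            donor = min(observed, key=lambda j: (abs(j - i), j))
            out[i] = values[donor]
    return out


def enforce_arthritis_irreversibility(answers: list) -> list[int]:
    """Per-wave arthritis indicators from yes/no/missing answers.

    Missing answers are first filled from the nearest wave (earlier wave on
    ties), then irreversibility is enforced: once "yes", all later waves are
    1, overriding any later "no"; absent an earlier "yes", waves at and
    before an explicit "no" are 0.
    """
    coded = []
    for a in answers:
        if _is_missing(a):
            coded.append(None)
        else:
            s = str(a).strip().lower()
            if s in (YES, "1", "1.0", "true"):
                coded.append(1)
            elif s in (NO, "0", "0.0", "false"):
                coded.append(0)
            else:
                raise CodingError(f"arthritis answer must be yes/no/missing, got {a!r}")
    filled = impute_time_varying_nearest(coded)
    out = []
    ever = 0
    for v in filled:
        ever = max(ever, int(v))
        out.append(ever)
    return out


def compute_bmi_obesity(height, weight, unit_system: str = "metric"):
    """Obesity flag from self-reported height and weight: BMI >= 30.

    Metric: kg / m**2.  US units: 703 * lb / in**2.  Non-positive or
    implausible values (height outside the 1.2-2.3 m equivalent) raise a
    validation warning and yield a missing value (None).
    """
    if _is_missing(height) or _is_missing(weight):
        return None
    height, weight = float(height), float(weight)
    if unit_system == "metric":
        height_m = height
        bmi = weight / height**2 if height > 0 else np.inf
    elif unit_system == "us":
        height_m = height * 0.0254
        bmi = 703.0 * weight / height**2 if height > 0 else np.inf
    else:
        raise ValueError("unit_system must be 'metric' or 'us'")
    if height <= 0 or weight <= 0 or not 1.2 <= height_m <= 2.3:
        warnings.warn(
            f"implausible height/weight ({height}, {weight}) [{unit_system}]; "
            "treated as missing",
            stacklevel=2,
        )
        return None
    return int(bmi >= 30.0)


def map_state_to_region(us_state_name: str) -> str:
    """US Census region (Midwest/Northeast/South/West) of a state or DC."""
    try:
        return _STATE_TO_REGION[str(us_state_name).strip()]
    except KeyError:
        raise CodingError(f"unknown US state {us_state_name!r}") from None


def impute_dates(birth, death, interview_months: list[int]):
    """Complete month-resolution birth and death dates.

    ``birth``/``death`` are (year, month-or-None); ``death`` may be None.
    Missing birth month becomes June.  Missing death month becomes June
    unless June precedes a participation date, then December; a recorded
    death month is moved to December when an interview later in the same
    year contradicts it.  A death record without a year is ignored.
    Returns (birth_month_index, death_month_index_or_None).
    """
    by, bm = birth
    if by is None:
        raise ValueError("birth year is required")
    b_idx = month_index((int(by), int(bm) if not _is_missing(bm) else 6))
    if death is None:
        return b_idx, None
    dy, dm = death
    if _is_missing(dy):
        return b_idx, None  # death record without a date is ignored
    dy = int(dy)
    if dy < by:
        raise ValueError(f"death year {dy} precedes birth year {by}")
    if _is_missing(dm):
        d_idx = month_index((dy, 6))
        if any(m > d_idx for m in interview_months):
            d_idx = month_index((dy, 12))
    else:
        d_idx = month_index((dy, int(dm)))
        same_year_conflict = any(
            m > d_idx and m // 12 == dy for m in interview_months
        )
        if same_year_conflict:
            d_idx = month_index((dy, 12))
    return b_idx, d_idx


def assign_longitudinal_weight(weights: list, ages: list):
    """First non-zero cross-sectional weight from a wave taken at age >= 50;
    None when no wave qualifies (the person is ineligible)."""
    for w, a in zip(weights, ages, strict=True):
        if _is_missing(w):
            continue
        if w < 0:
            raise ValueError(f"negative survey weight {w}")
        if a >= 50 and w > 0:
            return float(w)
    return None


def _classify_education(value) -> int | None:
    if _is_missing(value):
        return None
    v = str(value).strip().lower()
    if v in ("0", "1"):
        return int(v)
    if v in HIGH_SCHOOL_OR_ABOVE:
        return 1
    if v in LESS_THAN_HIGH_SCHOOL:
        return 0
    raise CodingError(f"unknown education level {value!r}")


def _classify_sex(value) -> int | None:
    if _is_missing(value):
        return None
    v = str(value).strip().lower()
    if v in ("female", "f", "1", "1.0"):
        return 1
    if v in ("male", "m", "0", "0.0"):
        return 0
    raise CodingError(f"unknown sex {value!r}")


RAW_COLUMNS = [
    "id", "interview_date", "birth_year", "birth_month", "death_year",
    "death_month", "sex", "education", "ethnicity", "us_state", "xs_weight",
    "limit_paid_work", "limit_housework", "limit_activities", "employment",
    "arthritis", "height", "weight_body",
]


@dataclass
class ExclusionLog:
    """Per-person exclusion reasons and summary counts."""

    entries: pd.DataFrame  # columns: id, reason

    def counts(self) -> pd.Series:
        if self.entries.empty:
            return pd.Series(dtype=int)
        return self.entries["reason"].value_counts()


def prepare_panel(raw: pd.DataFrame, unit_system: str = "metric"):
    """Raw answer records -> coded analysis panel + exclusion log.

    Applies, in order: date completion, state coding, arthritis
    irreversibility (nearest-wave imputation then monotone enforcement),
    baseline-height BMI/obesity with nearest-wave imputation, longitudinal
    weight assignment, and the exclusion rules (missing fixed covariate;
    time-varying covariate missing at every wave; no qualifying weight).
    Observations before age 50 are dropped from the retained panel.
    """
    missing_cols = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"raw panel lacks columns {missing_cols}")
    rows = []
    excluded = []
    for pid, g in raw.groupby("id", sort=True):
        g = g.copy()
        if g["interview_date"].isna().any() or (g["interview_date"] == "").any():
            raise ValueError(f"person {pid}: wave with missing interview date")
        g["month_idx"] = g["interview_date"].map(month_index)
        if g["month_idx"].duplicated().any():
            raise ValueError(f"person {pid}: duplicate interview dates")
        g = g.sort_values("month_idx")
        first = g.iloc[0]

        death = None
        if not _is_missing(first["death_year"]):
            death = (first["death_year"], first["death_month"])
        b_idx, d_idx = impute_dates(
            (first["birth_year"], first["birth_month"]), death,
            g["month_idx"].tolist(),
        )

        sex = _classify_sex(first["sex"])
        education = _classify_education(first["education"])
        ethnicity = None if _is_missing(first["ethnicity"]) else str(first["ethnicity"]).strip().lower()
        try:
            region = None if _is_missing(first["us_state"]) else map_state_to_region(first["us_state"])
        except CodingError:
            region = None
        fixed = {"sex": sex, "education": education, "ethnicity": ethnicity, "region": region}
        missing_fixed = [k for k, v in fixed.items() if v is None]
        if missing_fixed:
            excluded += [(pid, f"fixed_covariate:{k}") for k in missing_fixed]
            continue

        try:
            arthritis = enforce_arthritis_irreversibility(g["arthritis"].tolist())
        except AllMissing:
            excluded.append((pid, "time_varying_all_missing:arthritis"))
            continue

        baseline_height = next(
            (h for h in g["height"] if not _is_missing(h)), None
        )
        obese_raw = [
            compute_bmi_obesity(baseline_height, w, unit_system)
            for w in g["weight_body"]
        ]
        try:
            obese = impute_time_varying_nearest(obese_raw)
        except AllMissing:
            excluded.append((pid, "time_varying_all_missing:obesity"))
            continue

        ages = [age_at(b_idx, m) for m in g["month_idx"]]
        weight = assign_longitudinal_weight(g["xs_weight"].tolist(), ages)
        if weight is None:
            excluded.append((pid, "no_qualifying_weight"))
            continue

        states = [
            encode_state(
                classify_health([r.limit_paid_work, r.limit_housework, r.limit_activities]),
                classify_work(r.employment),
                "alive",
            )
            for r in g.itertuples(index=False)
        ]
        for i, (_, r) in enumerate(g.iterrows()):
            if ages[i] < 50:
                continue
            rows.append({
                "id": pid,
                "date": month_str(r["month_idx"]),
                "age": ages[i],
                "state": states[i],
                "arthritis": arthritis[i],
                "obese": obese[i],
                "sex": sex,
                "education": education,
                "ethnicity": ethnicity,
                "region": region,
                "weight": weight,
                "birth_date": month_str(b_idx),
                "death_date": month_str(d_idx) if d_idx is not None else "",
            })
    panel = pd.DataFrame(rows, columns=[
        "id", "date", "age", "state", "arthritis", "obese", "sex", "education",
        "ethnicity", "region", "weight", "birth_date", "death_date",
    ])
    log = ExclusionLog(pd.DataFrame(excluded, columns=["id", "reason"]))
    return panel, log


def _nearest_wave_fill(values: pd.Series, ids: pd.Series) -> pd.Series:
    """Vectorized nearest-wave imputation within person (rows pre-sorted by
    person and time; earlier wave wins ties).  Persons with nothing observed
    keep NaN."""
    df = pd.DataFrame({"id": ids.to_numpy(), "v": pd.to_numeric(values, errors="coerce").to_numpy()})
    pos = df.groupby("id").cumcount()
    df["pi"] = pos.where(df["v"].notna())
    g = df.groupby("id")
    prev_pos, next_pos = g["pi"].ffill(), g["pi"].bfill()
    prev_val, next_val = g["v"].ffill(), g["v"].bfill()
    d_prev = (pos - prev_pos).fillna(np.inf)
    d_next = (next_pos - pos).fillna(np.inf)
    out = np.where(d_prev <= d_next, prev_val, next_val)
    return pd.Series(out, index=values.index)


def prepare_coded_panel(panel: pd.DataFrame):
    """Prep a panel whose states are already coded (e.g. generator output).

    Computes exact fractional ages, imputes the time-varying covariates
    across participated waves (nearest wave, earlier on ties) and enforces
    arthritis irreversibility, drops observations before age 50, applies the
    exclusion rules, and passes the per-person longitudinal weight through.
    Idempotent: prepping a prepped panel is a no-op.
    """
    df = panel.copy()
    df["month_idx"] = df["date"].map(month_index)
    df = df.sort_values(["id", "month_idx"], kind="mergesort").reset_index(drop=True)
    birth = pd.to_datetime(df["birth_date"], format="%Y-%m") + pd.Timedelta(days=14)
    obs = pd.to_datetime(df["date"], format="%Y-%m") + pd.Timedelta(days=14)
    df["age"] = (obs - birth).dt.days / 365.25

    excluded = []
    first = df.groupby("id", sort=True).first()
    for k in ("sex", "education", "ethnicity", "region"):
        bad = first.index[first[k].isna() | (first[k] == "")]
        excluded += [(pid, f"fixed_covariate:{k}") for pid in bad]
    fixed_bad = {pid for pid, _ in excluded}

    participated = df["state"] != UNKNOWN_VITAL
    art = _nearest_wave_fill(df["arthritis"].where(participated), df["id"])
    ob = _nearest_wave_fill(df["obese"].where(participated), df["id"])
    art_missing = set(df.loc[art.isna(), "id"]) - fixed_bad
    ob_missing = set(df.loc[ob.isna(), "id"]) - fixed_bad - art_missing
    excluded += [(pid, "time_varying_all_missing:arthritis") for pid in sorted(art_missing)]
    excluded += [(pid, "time_varying_all_missing:obesity") for pid in sorted(ob_missing)]
    # irreversibility: once reported, carried forward
    df["arthritis"] = art.groupby(df["id"]).cummax()
    df["obese"] = ob

    good_weight = df.groupby("id")["weight"].first() > 0
    bad_w = set(good_weight.index[~good_weight]) - fixed_bad - art_missing - ob_missing
    excluded += [(pid, "no_qualifying_weight") for pid in sorted(bad_w)]

    drop_ids = fixed_bad | art_missing | ob_missing | bad_w
    out = df[~df["id"].isin(drop_ids) & (df["age"] >= 50)].drop(columns=["month_idx"])
    out = out.astype({"arthritis": int, "obese": int}).reset_index(drop=True)
    log = ExclusionLog(pd.DataFrame(sorted(excluded), columns=["id", "reason"]))
    return out, log
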