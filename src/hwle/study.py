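"""Desk-scale study orchestration: stratified estimates and sensitivity.

Reproduces the shape of the published analysis on any prepped panel:
descriptive weighted/unweighted counts, healthy-working and life
expectancies overall and per stratum (arthritis crossed with sex,
education, region, ethnicity and obesity), and the calendar-period
sensitivity check on state prevalences at fixed ages.

Two covariate strategies are supported.  ``stratified`` (default) refits
the transition model inside each stratum, mirroring a table whose rows are
separate populations.  ``pooled`` fits one model with binary covariates on
every logit and evaluates the expectancies at each covariate profile,
holding the remaining covariates at their weighted sample means.  Fixed
covariates stratify at the person level; the time-varying ones (arthritis,
obesity) assign each transition interval by its value at the interval's
origin wave and each prevalence observation by its value at that wave.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expectancy import (
    ExpectancyTable,
    confidence_intervals,
    initial_prevalence,
    percent_of_le,
)
from .model import IntervalSet, _IntervalGroup, build_intervals, fit_mle
from .states import LIVING_STATES, TransitionStructure

logger = logging.getLogger("hwle")

DEFAULT_STRATA = ["overall", "arthritis", "sex", "education", "region", "ethnicity", "obese"]
TIME_VARYING = ("arthritis", "obese")
MIN_INTERVALS = 50  # below this a stratum is skipped as unidentifiable


def descriptive_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Observed and weighted person counts and percentages per variable.

    One row per variable level; time-varying variables are summarized as
    "ever" (reported at any wave).
    """
    person = panel.groupby("id").agg(
        sex=("sex", "first"), education=("education", "first"),
        region=("region", "first"), ethnicity=("ethnicity", "first"),
        arthritis=("arthritis", "max"), obese=("obese", "max"),
        weight=("weight", "first"),
    )
    rows = []
    total_w = person["weight"].sum()
    rows.append(("total", "", len(person), 100.0, total_w, 100.0))
    for var in ("sex", "education", "region", "ethnicity", "arthritis", "obese"):
        for level, g in person.groupby(var, sort=True):
            rows.append((
                var, str(level), len(g), 100.0 * len(g) / len(person),
                g["weight"].sum(), 100.0 * g["weight"].sum() / total_w,
            ))
    return pd.DataFrame(
        rows,
        columns=["variable", "level", "n", "pct", "weighted_n", "weighted_pct"],
    )


def _filter_tv_intervals(intervals: IntervalSet, tv: dict[str, int]) -> IntervalSet:
    """Keep intervals whose origin-wave time-varying values match ``tv``,
    then drop the covariate columns (the stratum model has none)."""
    names = intervals.covariate_names
    groups = []
    n_kept = 0
    for g in intervals.groups:
        m = np.ones(g.weights.size, dtype=bool)
        for k, v in tv.items():
            m &= g.X[:, names.index(k)] == v
        if m.any():
            groups.append(_IntervalGroup(
                g.kind, g.origin[m], None if g.dest is None else g.dest[m],
                g.ages[m], g.offsets[m], g.weights[m], None,
            ))
            n_kept += int(m.sum())
    return IntervalSet(groups, intervals.n_individuals, n_kept, [])


def _prevalence_with_widening(sub: pd.DataFrame, age_anchor, window, structure):
    try:
        return initial_prevalence(sub, age_anchor, window, structure)
    except ValueError:
        wider = max(window, 5.0)
        logger.warning(
            "empty prevalence window [%s, %s); widening to [%s, %s)",
            age_anchor, age_anchor + window, age_anchor, age_anchor + wider,
        )
        return initial_prevalence(sub, age_anchor, wider, structure)


def estimate_stratum(
    panel: pd.DataFrame,
    fixed: dict | None = None,
    tv: dict | None = None,
    structure: TransitionStructure | None = None,
    step_months: int = 12,
    age_anchor: float = 50.0,
    horizon: float = 60.0,
    prevalence_window: float = 1.0,
    n_draws: int = 1000,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> ExpectancyTable | None:
    """Fit the transition model in one stratum and return its expectancies.

    ``fixed`` filters persons on time-invariant columns; ``tv`` assigns
    transition intervals (by origin wave) and prevalence observations on the
    time-varying columns.  Returns None when the stratum holds too few
    transitions to identify the model.
    """
    structure = structure or TransitionStructure()
    sub = panel
    for k, v in (fixed or {}).items():
        sub = sub[sub[k] == v]
    if sub.empty:
        logger.warning("stratum %s/%s is empty; skipped", fixed, tv)
        return None
    tv = tv or {}
    intervals = build_intervals(sub, structure, step_months, list(tv) or None)
    if tv:
        intervals = _filter_tv_intervals(intervals, tv)
    if intervals.n_intervals < MIN_INTERVALS:
        logger.warning(
            "stratum %s/%s has %d intervals (< %d); skipped",
            fixed, tv, intervals.n_intervals, MIN_INTERVALS,
        )
        return None
    fitted = fit_mle(intervals, structure, step_months=step_months,
                     **(fit_kwargs or {}))
    if not fitted.converged:
        logger.warning("stratum %s/%s: optimizer reports %s", fixed, tv, fitted.message)
    prev_sub = sub
    for k, v in tv.items():
        prev_sub = prev_sub[prev_sub[k] == v]
    prevalence = _prevalence_with_widening(prev_sub, age_anchor, prevalence_window, structure)
    table = confidence_intervals(
        fitted, prevalence, age_anchor, horizon, n_draws=n_draws, seed=seed,
    )
    table.n_individuals = sub["id"].nunique()
    table.n_intervals = intervals.n_intervals
    table.converged = fitted.converged
    return table


def _strata_rows(panel: pd.DataFrame, strata):
    """Yield (variable, level, arthritis_level, fixed, tv) per report row."""
    for var in strata:
        if var == "overall":
            yield ("overall", "", None, {}, {})
        elif var == "arthritis":
            for a in (0, 1):
                yield ("arthritis", "", a, {}, {"arthritis": a})
        else:
            if var == "ethnicity":
                levels = [lv for lv in ("black", "white") if lv in set(panel[var])]
            else:
                levels = sorted(panel[var].dropna().unique())
            for level in levels:
                for a in (0, 1):
                    if var in TIME_VARYING:
                        yield (var, str(level), a, {}, {var: level, "arthritis": a})
                    else:
                        yield (var, str(level), a, {var: level}, {"arthritis": a})


def _result_row(meta, table: ExpectancyTable | None):
    var, level, arth = meta
    row = {"stratum": var, "level": level, "arthritis": arth,
           "converged": None, "n_individuals": None, "n_intervals": None}
    labels = ["hwle", "e_healthy_not_working", "e_not_healthy_working",
              "e_not_healthy_not_working"]
    for name in labels + ["le", "hwle_lo", "hwle_hi", "le_lo", "le_hi",
                          "pct_hwle_of_le"]:
        row[name] = np.nan
    if table is None:
        return row
    for j, name in enumerate(labels):
        row[name] = round(float(table.expectancies[j]), 2)
    row["le"] = round(table.le, 2)
    if table.ci is not None:
        row["hwle_lo"], row["hwle_hi"] = (round(float(v), 2) for v in table.ci["hwle"])
        row["le_lo"], row["le_hi"] = (round(float(v), 2) for v in table.ci["le"])
    row["pct_hwle_of_le"] = percent_of_le(table.hwle, table.le)
    row["converged"] = table.converged
    row["n_individuals"] = table.n_individuals
    row["n_intervals"] = table.n_intervals
    return row


def run_stratified_analysis(
    panel: pd.DataFrame,
    strata: list[str] | None = None,
    mode: str = "stratified",
    structure: TransitionStructure | None = None,
    step_months: int = 12,
    age_anchor: float = 50.0,
    horizon: float = 60.0,
    prevalence_window: float = 1.0,
    n_draws: int = 1000,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Expectancy estimates per stratum (rounded for reporting: years to two
    decimals, percentages to integers).

    ``mode="stratified"`` refits per stratum; ``mode="pooled"`` fits one
    model with binary covariates and evaluates per profile.  Every emitted
    row satisfies the sum identity: the four expectancy columns add up to
    the life-expectancy column (within the printed rounding).
    """
    strata = strata or DEFAULT_STRATA
    if mode not in ("stratified", "pooled"):
        raise ValueError("mode must be 'stratified' or 'pooled'")
    rows = []
    if mode == "stratified":
        for var, level, arth, fixed, tv in _strata_rows(panel, strata):
            logger.info("stratum %s=%s arthritis=%s", var, level, arth)
            table = estimate_stratum(
                panel, fixed, tv, structure, step_months, age_anchor, horizon,
                prevalence_window, n_draws, seed, fit_kwargs,
            )
            rows.append(_result_row((var, level, arth), table))
        return pd.DataFrame(rows)
    return _run_pooled(panel, strata, structure, step_months, age_anchor,
                       horizon, prevalence_window, n_draws, seed, fit_kwargs)


def _run_pooled(panel, strata, structure, step_months, age_anchor, horizon,
                prevalence_window, n_draws, seed, fit_kwargs):
    """One pooled fit with binary covariates on every logit; expectancies per
    covariate profile with the remaining covariates at weighted means."""
    structure = structure or TransitionStructure()
    df = panel.copy()
    dummies = {"sex": "sex", "education": "education",
               "arthritis": "arthritis", "obese": "obese"}
    cov_names = [dummies[v] for v in strata if v in dummies and v != "overall"]
    if "arthritis" not in cov_names:
        cov_names = ["arthritis"] + cov_names
    for var in ("region", "ethnicity"):
        if var in strata:
            levels = sorted(df[var].dropna().unique())
            for lv in levels[1:]:
                name = f"{var}_{lv}"
                df[name] = (df[var] == lv).astype(int)
                cov_names.append(name)
    fitted = fit_mle(df, structure, covariate_names=cov_names,
                     step_months=step_months, **(fit_kwargs or {}))
    means = {c: float(np.average(df[c], weights=df["weight"])) for c in cov_names}

    rows = []
    for var, level, arth, fixed, tv in _strata_rows(df, strata):
        values = dict(means)
        values["arthritis"] = 0.0 if arth is None else float(arth)
        sub = df
        for k, v in {**fixed, **tv}.items():
            sub = sub[sub[k] == v]
            if k in ("region", "ethnicity"):
                for c in cov_names:
                    if c.startswith(f"{k}_"):
                        values[c] = 1.0 if c == f"{k}_{v}" else 0.0
            elif k in values:
                values[k] = float(v)
        if sub.empty:
            rows.append(_result_row((var, level, arth), None))
            continue
        prevalence = _prevalence_with_widening(sub, age_anchor, prevalence_window, structure)
        table = confidence_intervals(
            fitted, prevalence, age_anchor, horizon, n_draws=n_draws, seed=seed,
            covariate_values=values,
        )
        table.n_individuals = sub["id"].nunique()
        table.n_intervals = fitted.n_intervals
        table.converged = fitted.converged
        rows.append(_result_row((var, level, arth), table))
    return pd.DataFrame(rows)


def sensitivity_prevalence_by_wave(
    panel: pd.DataFrame,
    ages: tuple[float, ...] = (55.0, 60.0, 65.0),
    age_window: float = 1.0,
    tolerance_band: float = 10.0,
    min_count: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """State prevalence by survey year at fixed target ages.

    For each survey calendar year and target age, the survey-weighted
    prevalence (percent) of each living state among respondents within
    +/- ``age_window`` years of the target.  The flags table reports, per
    (age, state), the range across years and ``"trend"`` when it exceeds
    ``tolerance_band`` percentage points, else ``"stable"`` — an automated
    stand-in for a visual trend check.  Cells with no respondents (or fewer
    than ``min_count``, which would make the range pure noise) are reported
    missing.  With a single survey year no flags are produced.
    """
    df = panel[panel["state"].isin(LIVING_STATES)].copy()
    df["survey_year"] = df["date"].str.slice(0, 4).astype(int)
    rows = []
    for year in sorted(df["survey_year"].unique()):
        for age in ages:
            sub = df[(df["survey_year"] == year) & (abs(df["age"] - age) <= age_window)]
            for state in LIVING_STATES:
                if len(sub) <= max(min_count - 1, 0):
                    rows.append((year, age, state, np.nan))
                else:
                    w = sub.loc[sub["state"] == state, "weight"].sum()
                    rows.append((year, age, state, 100.0 * w / sub["weight"].sum()))
    prev = pd.DataFrame(rows, columns=["survey_year", "target_age", "state", "prevalence_pct"])

    flags = []
    for (age, state), g in prev.dropna().groupby(["target_age", "state"]):
        if g["survey_year"].nunique() < 2:
            continue
        rng = g["prevalence_pct"].max() - g["prevalence_pct"].min()
        flags.append((age, state, rng, "trend" if rng > tolerance_band else "stable"))
    flags = pd.DataFrame(flags, columns=["target_age", "state", "range_pct", "flag"])
    return prev, flags
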