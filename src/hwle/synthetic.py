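"""Synthetic biennial panel cohorts from a known five-state monthly process.

The generator emulates the design of a large biennial ageing survey: adults
enter at ages 50-60, are interviewed every two years for up to 14 waves,
report a coded health/work state (or fail to: codes -1 and -2), acquire an
irreversible arthritis diagnosis and a time-varying obesity flag, die with a
month-resolution death date, and carry a positive longitudinal survey
weight.  Because the generating step-transition parameters are known, every
downstream stage (coding, likelihood, fitting, expectancies) can be tested
by parameter and expectancy recovery.

The simulation grid equals the estimator's interpolation step (12 months by
default) so that estimator error can be isolated from generator error; a
finer grid can be configured to probe discretization bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import step_matrices
from .states import DEAD, UNKNOWN_STATE, UNKNOWN_VITAL, ParameterVector, TransitionStructure
from .timeutil import month_str


def default_true_params(structure: TransitionStructure | None = None) -> ParameterVector:
    """Plausible ground-truth step-transition parameters for a US cohort at 50+.

    Log-odds are per 12-month step at the reference age of 50.  Orders of
    magnitude: ~5%/year exit from work while healthy, ~10%/year return to
    work at 50 declining with age, mortality near 0.3-1%/year at 50 with a
    Gompertz-like doubling time of about 8 years (slope ~0.09/year).
    """
    structure = structure or TransitionStructure()
    table = {
        (1, 2): (-3.0, 0.07),
        (1, 3): (-3.2, 0.04),
        (1, 4): (-4.5, 0.06),
        (1, DEAD): (-6.2, 0.09),
        (2, 1): (-2.2, -0.10),
        (2, 3): (-4.5, 0.02),
        (2, 4): (-3.0, 0.05),
        (2, DEAD): (-6.0, 0.09),
        (3, 1): (-2.5, -0.04),
        (3, 2): (-4.0, 0.00),
        (3, 4): (-2.2, 0.07),
        (3, DEAD): (-5.6, 0.09),
        (4, 1): (-3.5, -0.06),
        (4, 2): (-2.8, -0.02),
        (4, 3): (-3.8, -0.05),
        (4, DEAD): (-5.0, 0.095),
    }
    a = np.array([table[p][0] for p in structure.permitted])
    b = np.array([table[p][1] for p in structure.permitted])
    return ParameterVector(structure, a, b, reference_age=50.0)


def params_with_arthritis_effect(
    base: ParameterVector | None = None,
    exit_effect: float = 0.5,
    death_effect: float = 0.3,
) -> ParameterVector:
    """Ground truth in which arthritis raises the hazards out of the
    healthy-and-working state (log-odds shifts on the state-1 exit logits)."""
    p = base or default_true_params()
    struct = p.structure
    eff = np.zeros(struct.n_transitions)
    for t, (i, j) in enumerate(struct.permitted):
        if i == 1:
            eff[t] = death_effect if j == DEAD else exit_effect
    cov = dict(p.covariate_effects)
    cov["arthritis"] = eff
    return ParameterVector(struct, p.intercept.copy(), p.age_slope.copy(), cov,
                           p.reference_age)


DEFAULT_COVARIATE_PREVALENCES = {
    "female": 0.53,
    "highschool": 0.765,
    "ethnicity": {"black": 0.19, "white": 0.73, "other": 0.08},
    "region": {"Northeast": 0.175, "Midwest": 0.225, "South": 0.44, "West": 0.16},
    "obese": 0.30,
    "arthritis": 0.35,
}


@dataclass
class TrueModelConfig:
    """Generative ground truth for a synthetic cohort.

    ``arthritis_onset`` is (logit at age 50, slope per year) of the per-step
    onset probability among those without a diagnosis; onset is irreversible.
    Obesity switches on/off with small per-step rates around a baseline
    prevalence.  ``weight_distribution`` is ("constant", v),
    ("uniform", lo, hi) or ("lognormal", mu, sigma); weights are i.i.d. and
    positive.  Missingness rates are arbitrary, configurable defaults (the
    source survey's participation pattern is not public knowledge).
    """

    n_individuals: int = 1000
    seed: int = 0
    entry_age_range: tuple[float, float] = (50.0, 60.0)
    n_waves: int = 14
    wave_spacing: int = 24      # months between interviews
    step_length: int = 12       # months per simulation / interpolation step
    transition_params: ParameterVector | None = None
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    initial_state_probs: tuple[float, ...] = (0.55, 0.15, 0.12, 0.18)
    arthritis_onset: tuple[float, float] = (-3.4, 0.03)
    obesity_onset_rate: float = 0.02
    obesity_remission_rate: float = 0.01
    missing_state_rate: float = 0.05
    skipped_wave_rate: float = 0.05
    weight_distribution: tuple = ("constant", 1.0)
    first_wave_year: int = 1994

    def __post_init__(self):
        if self.transition_params is None:
            self.transition_params = default_true_params()
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        if self.wave_spacing <= 0 or self.step_length <= 0:
            raise ValueError("wave_spacing and step_length must be positive")
        if (self.wave_spacing % self.step_length) and (self.step_length % self.wave_spacing):
            raise ValueError("wave_spacing must be a multiple of step_length or vice versa")
        for r in (self.missing_state_rate, self.skipped_wave_rate):
            if not 0 <= r <= 1:
                raise ValueError("missingness rates must be in [0, 1]")
        p = np.asarray(self.initial_state_probs, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1) > 1e-9:
            raise ValueError("initial_state_probs must be a probability vector")
        if len(p) != self.transition_params.structure.n_living:
            raise ValueError("initial_state_probs length must match the living states")
        if self.entry_age_range[0] > self.entry_age_range[1] or self.entry_age_range[0] < 0:
            raise ValueError("invalid entry_age_range")


class Observation(NamedTuple):
    """One interview: date, coded state, and time-varying covariate answers.

    ``state`` uses the panel codes (1-4, -1 unknown state, -2 not
    participated); arthritis/obese are None at -2 waves (not collected).
    """

    date: str
    state: int
    arthritis: int | None
    obese: int | None


@dataclass
class SimulatedIndividual:
    id: int
    birth_date: str
    sex: int                    # 1 = female
    education: int              # 1 = high-school education or above
    ethnicity: str
    region: str
    weight: float
    death_date: str | None
    observations: list[Observation]
    true_path: list[int] = field(default_factory=list, compare=False, repr=False)
    arthritis_path: list[int] = field(default_factory=list, compare=False, repr=False)
    obese_path: list[int] = field(default_factory=list, compare=False, repr=False)


def _draw_weights(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    kind = spec[0]
    if kind == "constant":
        w = np.full(n, float(spec[1]))
    elif kind == "uniform":
        w = rng.uniform(spec[1], spec[2], n)
    elif kind == "lognormal":
        w = rng.lognormal(spec[1], spec[2], n)
    else:
        raise ValueError(f"unknown weight distribution {kind!r}")
    if np.any(w <= 0):
        raise ValueError("survey weights must be positive")
    return w


def _categorical(rng, probs: dict[str, float], n: int) -> np.ndarray:
    labels = list(probs)
    p = np.array([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return np.array(labels)[rng.choice(len(labels), size=n, p=p)]


def generate_cohort(config: TrueModelConfig) -> list[SimulatedIndividual]:
    """Simulate a cohort from the ground-truth process; deterministic per seed.

    States evolve step-by-step on the simulation grid from the ground-truth
    step matrices evaluated at each individual's current age and covariates;
    observed states are the true states at interview dates, with missingness
    injected afterwards at the configured rates.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    params = config.transition_params
    struct = params.structure
    L = struct.n_living
    prev = config.covariate_prevalences

    female = (rng.random(n) < prev.get("female", 0.5)).astype(int)
    highschool = (rng.random(n) < prev.get("highschool", 0.75)).astype(int)
    ethnicity = _categorical(rng, prev.get("ethnicity", {"white": 1.0}), n)
    region = _categorical(rng, prev.get("region", {"South": 1.0}), n)
    obese = (rng.random(n) < prev.get("obese", 0.3)).astype(int)
    arthritis = (rng.random(n) < prev.get("arthritis", 0.35)).astype(int)
    weights = _draw_weights(rng, config.weight_distribution, n)

    lo, hi = config.entry_age_range
    entry_age_months = rng.integers(round(lo * 12), round(hi * 12) + 1, size=n)
    entry_month = config.first_wave_year * 12 + rng.integers(0, 12, size=n)
    birth_month = entry_month - entry_age_months

    horizon_months = (config.n_waves - 1) * config.wave_spacing
    h = config.step_length
    n_steps = int(np.ceil(horizon_months / h)) if horizon_months else 0

    # ``initial_state_probs`` is the state distribution at age 50; entrants
    # older than 50 draw from that distribution evolved (conditional on
    # being alive, at population-average covariates) to their entry age, so
    # that the cohort is age-consistent and state prevalence at a given age
    # carries no calendar trend.
    base_age_months = 600  # 50 years
    grid = np.arange(base_age_months, int(entry_age_months.max()) + h, h)
    X_mean = None
    if params.covariate_names:
        mean_of = {"arthritis": arthritis.mean(), "obese": obese.mean(),
                   "female": female.mean(), "highschool": highschool.mean()}
        X_mean = np.array([[mean_of.get(c, 0.0) for c in params.covariate_names]])
    occ_table = np.empty((len(grid), L))
    occ = np.asarray(config.initial_state_probs, dtype=float)
    for gi, am in enumerate(grid):
        occ_table[gi] = occ
        Mg = step_matrices(np.array([am / 12.0]), params, X_mean)[0]
        nxt = occ @ Mg[:L, :L]
        occ = nxt / nxt.sum()
    gi = np.clip(np.round((entry_age_months - base_age_months) / h).astype(int),
                 0, len(grid) - 1)
    probs0 = occ_table[gi]
    state = (probs0.cumsum(axis=1) < rng.random(n)[:, None]).sum(axis=1)
    state = np.minimum(state, L - 1)
    dead_idx = L
    paths = np.empty((n, n_steps + 1), dtype=int)
    art_paths = np.empty((n, n_steps + 1), dtype=int)
    ob_paths = np.empty((n, n_steps + 1), dtype=int)
    paths[:, 0] = state
    art_paths[:, 0] = arthritis
    ob_paths[:, 0] = obese
    death_step = np.full(n, -1)

    cov_values = {
        "arthritis": lambda art, ob: art,
        "obese": lambda art, ob: ob,
        "female": lambda art, ob: female,
        "highschool": lambda art, ob: highschool,
    }
    a_art, b_art = config.arthritis_onset

    art = arthritis.astype(float)
    ob = obese.astype(float)
    for s in range(n_steps):
        ages = (entry_age_months + s * h) / 12.0
        alive = paths[:, s] < dead_idx
        # irreversible arthritis onset, then obesity switching, then the move
        onset_p = 1.0 / (1.0 + np.exp(-(a_art + b_art * (ages - 50.0))))
        art = np.where((art == 0) & (rng.random(n) < onset_p), 1.0, art)
        flip_on = rng.random(n) < config.obesity_onset_rate
        flip_off = rng.random(n) < config.obesity_remission_rate
        ob = np.where(ob == 0, np.where(flip_on, 1.0, 0.0), np.where(flip_off, 0.0, 1.0))
        X = None
        if params.covariate_names:
            try:
                X = np.column_stack(
                    [np.asarray(cov_values[c](art, ob), dtype=float)
                     for c in params.covariate_names]
                )
            except KeyError as e:
                raise ValueError(f"unsupported generator covariate {e.args[0]!r}") from None
        M = step_matrices(ages, params, X)  # (n, S, S)
        probs = M[np.arange(n), paths[:, s]]
        nxt = (probs.cumsum(axis=1) < rng.random(n)[:, None]).sum(axis=1)
        nxt = np.where(alive, nxt, dead_idx)
        newly_dead = alive & (nxt == dead_idx) & (paths[:, s] != dead_idx)
        death_step[newly_dead & (death_step < 0)] = s
        paths[:, s + 1] = nxt
        art_paths[:, s + 1] = art
        ob_paths[:, s + 1] = ob

    death_month = np.where(death_step >= 0, entry_month + (death_step + 1) * h, -1)

    cohort: list[SimulatedIndividual] = []
    living_codes = list(struct.living_states)
    for i in range(n):
        obs: list[Observation] = []
        for w in range(config.n_waves):
            m = int(entry_month[i] + w * config.wave_spacing)
            if death_month[i] >= 0 and m >= death_month[i]:
                break
            sidx = (w * config.wave_spacing) // h
            code = living_codes[paths[i, sidx]] if paths[i, sidx] < dead_idx else DEAD
            obs.append(Observation(month_str(m), code, int(art_paths[i, sidx]),
                                   int(ob_paths[i, sidx])))
        cohort.append(
            SimulatedIndividual(
                id=i,
                birth_date=month_str(int(birth_month[i])),
                sex=int(female[i]),
                education=int(highschool[i]),
                ethnicity=str(ethnicity[i]),
                region=str(region[i]),
                weight=float(weights[i]),
                death_date=month_str(int(death_month[i])) if death_month[i] >= 0 else None,
                observations=obs,
                true_path=[living_codes[p] if p < dead_idx else DEAD for p in paths[i]],
                arthritis_path=art_paths[i].tolist(),
                obese_path=ob_paths[i].tolist(),
            )
        )
    miss_seed = int(rng.integers(0, 2**31 - 1))
    return inject_missingness(cohort, config.missing_state_rate,
                              config.skipped_wave_rate, miss_seed)


def inject_missingness(
    cohort: list[SimulatedIndividual],
    missing_state_rate: float,
    skipped_wave_rate: float,
    seed: int,
) -> list[SimulatedIndividual]:
    """Convert participated waves to unknown-state (-1) or skipped (-2).

    A wave is skipped (-2, covariates not collected) with probability
    ``skipped_wave_rate``; a participated wave has its state blanked to -1
    with probability ``missing_state_rate``.  Death dates are untouched, and
    the last wave of an individual whose death date is retained is never
    converted to -2.
    """
    for r in (missing_state_rate, skipped_wave_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for ind in cohort:
        obs = []
        for j, o in enumerate(ind.observations):
            last_before_death = ind.death_date is not None and j == len(ind.observations) - 1
            if rng.random() < skipped_wave_rate and not last_before_death:
                obs.append(Observation(o.date, UNKNOWN_VITAL, None, None))
            elif rng.random() < missing_state_rate:
                obs.append(Observation(o.date, UNKNOWN_STATE, o.arthritis, o.obese))
            else:
                obs.append(o)
        out.append(
            SimulatedIndividual(
                ind.id, ind.birth_date, ind.sex, ind.education, ind.ethnicity,
                ind.region, ind.weight, ind.death_date, obs,
                ind.true_path, ind.arthritis_path, ind.obese_path,
            )
        )
    return out


# ---------------------------------------------------------------------------
# panel CSV round trip
# ---------------------------------------------------------------------------

PANEL_COLUMNS = [
    "id", "date", "state", "arthritis", "obese", "birth_date", "death_date",
    "sex", "education", "ethnicity", "region", "weight",
]


def cohort_to_panel(cohort: list[SimulatedIndividual]) -> pd.DataFrame:
    """Long-format panel, one row per person-wave (including -1/-2 waves)."""
    rows = []
    for ind in cohort:
        for o in ind.observations:
            rows.append(
                (ind.id, o.date, o.state, o.arthritis, o.obese, ind.birth_date,
                 ind.death_date or "", ind.sex, ind.education, ind.ethnicity,
                 ind.region, ind.weight)
            )
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def write_panel(cohort: list[SimulatedIndividual] | pd.DataFrame, path) -> None:
    """Write the documented panel CSV dialect (dates as YYYY-MM; state codes
    1-4, -1, -2; empty death_date when alive at last contact)."""
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_panel(cohort)
    df.to_csv(path, index=False)


def read_panel(path) -> list[SimulatedIndividual]:
    """Read a panel CSV back into individuals (inverse of :func:`write_panel`
    on all persisted fields; simulation-only true paths are not persisted)."""
    df = pd.read_csv(path, dtype={"date": str, "birth_date": str, "death_date": str},
                     keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file lacks columns {missing}")
    cohort = []
    for pid, g in df.groupby("id", sort=True):
        obs = []
        for r, row in enumerate(g.itertuples(index=False)):
            try:
                state = int(row.state)
                art = None if row.arthritis == "" else int(float(row.arthritis))
                ob = None if row.obese == "" else int(float(row.obese))
                obs.append(Observation(row.date, state, art, ob))
            except (TypeError, ValueError) as e:
                raise ValueError(
                    f"malformed value in row {r} of person {pid} "
                    f"(columns state/arthritis/obese): {e}"
                ) from None
        first = g.iloc[0]
        cohort.append(
            SimulatedIndividual(
                id=int(pid), birth_date=first["birth_date"], sex=int(first["sex"]),
                education=int(first["education"]), ethnicity=first["ethnicity"],
                region=first["region"], weight=float(first["weight"]),
                death_date=first["death_date"] or None, observations=obs,
            )
        )
    return cohort


def write_imach(cohort: list[SimulatedIndividual], path) -> None:
    """Export in the reference interpolated-Markov-chain program's input
    dialect: one line per person with fixed-order fields

        id weight <sex> <education> birth(mm/yyyy) death(mm/yyyy) then one
        (interview mm/yyyy, state) pair per wave,

    with 99/9999 for an absent death date and state -2 for skipped waves.
    """
    def mmyyyy(date: str | None) -> str:
        if not date:
            return "99/9999"
        y, m = date.split("-")
        return f"{m}/{y}"

    with open(path, "w") as fh:
        for ind in cohort:
            parts = [str(ind.id), f"{ind.weight:g}", str(ind.sex), str(ind.education),
                     mmyyyy(ind.birth_date), mmyyyy(ind.death_date)]
            for o in ind.observations:
                parts += [mmyyyy(o.date), str(o.state)]
            fh.write(" ".join(parts) + "\n")


_REGION_EXEMPLAR_STATE = {"Midwest": "Ohio", "Northeast": "New York",
                          "South": "Texas", "West": "California"}


def emit_raw_answers(cohort: list[SimulatedIndividual], seed: int = 0) -> pd.DataFrame:
    """Answer-level fixture mode: raw survey answers consistent with the
    coded states, to exercise the panel-coding rules end to end.

    Healthy states answer "no" to all three limitation items; unhealthy
    states answer "yes" to a random non-empty subset.  Working states answer
    "working now"; non-working states draw another employment category.
    Unknown-state (-1) waves leave the limitation and employment items
    blank; skipped (-2) waves emit no row.  Heights/weights are chosen so
    the BMI threshold reproduces the obesity flag.
    """
    rng = np.random.default_rng(seed)
    not_working = sorted(["retired", "homemaker", "temporarily laid off",
                          "unemployed and looking for work",
                          "disabled and unable to work", "other"])
    rows = []
    for ind in cohort:
        by, bm = (int(p) for p in ind.birth_date.split("-"))
        dy = dm = None
        if ind.death_date:
            dy, dm = (int(p) for p in ind.death_date.split("-"))
        for o in ind.observations:
            if o.state == UNKNOWN_VITAL:
                continue
            limits = [None, None, None]
            employment = None
            if o.state != UNKNOWN_STATE:
                healthy = o.state in (1, 2)
                working = o.state in (1, 3)
                if healthy:
                    limits = ["no", "no", "no"]
                else:
                    limits = ["no", "no", "no"]
                    for j in np.flatnonzero(rng.random(3) < 0.5):
                        limits[j] = "yes"
                    if "yes" not in limits:
                        limits[int(rng.integers(3))] = "yes"
                employment = "working now" if working else not_working[
                    int(rng.integers(len(not_working)))]
            rows.append({
                "id": ind.id, "interview_date": o.date,
                "birth_year": by, "birth_month": bm,
                "death_year": dy, "death_month": dm,
                "sex": "female" if ind.sex else "male",
                "education": "high school diploma" if ind.education
                             else "less than high school",
                "ethnicity": ind.ethnicity,
                "us_state": _REGION_EXEMPLAR_STATE[ind.region],
                "xs_weight": ind.weight,
                "limit_paid_work": limits[0], "limit_housework": limits[1],
                "limit_activities": limits[2], "employment": employment,
                "arthritis": None if o.arthritis is None
                             else ("yes" if o.arthritis else "no"),
                "height": 1.70,
                "weight_body": 95.0 if o.obese else 70.0,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectory-simulation expectancy oracle
# ---------------------------------------------------------------------------

def simulate_expectancies(
    params: ParameterVector,
    initial_state_probs,
    n_trajectories: int,
    seed: int,
    age_anchor: float = 50.0,
    horizon: float = 60.0,
    step_months: int = 12,
    covariates: dict[str, float] | None = None,
):
    """Monte-Carlo state expectancies from full simulated trajectories.

    Starts ``n_trajectories`` walkers at ``age_anchor`` with states drawn
    from ``initial_state_probs`` and scores occupancy with the trapezoid
    convention (a transition within a step credits half a step to each
    endpoint state), matching the analytic expectancy integration.  Returns
    (mean years per living state, standard errors).
    """
    rng = np.random.default_rng(seed)
    struct = params.structure
    L = struct.n_living
    n_steps = int(np.ceil(horizon * 12 / step_months))
    h = step_months / 12.0
    X = None
    if params.covariate_names:
        covariates = covariates or {}
        X = np.tile([[covariates.get(k, 0.0) for k in params.covariate_names]],
                    (n_trajectories, 1))
    state = rng.choice(L, size=n_trajectories, p=np.asarray(initial_state_probs))
    years = np.zeros((n_trajectories, L))
    for s in range(n_steps):
        ages = np.full(n_trajectories, age_anchor + s * h)
        M = step_matrices(ages, params, X)
        probs = M[np.arange(n_trajectories), state]
        nxt = (probs.cumsum(axis=1) < rng.random(n_trajectories)[:, None]).sum(axis=1)
        nxt = np.where(state < L, nxt, L)
        for j in range(L):
            years[:, j] += (h / 2) * ((state == j).astype(float) + (nxt == j))
        state = nxt
    return years.mean(axis=0), years.std(axis=0, ddof=1) / np.sqrt(n_trajectories)
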