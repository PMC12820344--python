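"""Health expectancies from a fitted step-transition model.

Starting from each living state at an anchor age (50 by default), occupancy
vectors are propagated by repeated step-matrix multiplication with age
advancing; expected years in each state are the trapezoidal integral of
occupancy over the horizon.  Population expectancies average the
conditional rows with the survey-weighted prevalence of the states at the
anchor age; the healthy-working expectancy is the population expectancy of
state 1, and life expectancy is by definition the sum of the four state
expectancies.

Uncertainty is by parametric simulation: parameter vectors are drawn from
the multivariate normal of the fit, the prevalence weights are redrawn
around their observed values at the window's effective sample size, and the
whole expectancy pipeline is recomputed per draw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .model import FittedModel, step_matrices
from .states import ParameterVector, TransitionStructure

STATE_EXPECTANCY_LABELS = [
    "healthy_working", "healthy_not_working",
    "not_healthy_working", "not_healthy_not_working",
]


@dataclass
class PrevalenceWeights:
    """Survey-weighted distribution over living states in an age window."""

    weights: np.ndarray
    age_anchor: float
    window: float
    n_obs: int
    effective_n: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.min() < -1e-12 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("prevalence weights must be a probability vector")
        self.weights = np.clip(w, 0.0, None)


def initial_prevalence(
    panel: pd.DataFrame,
    age_anchor: float = 50.0,
    window: float = 1.0,
    structure: TransitionStructure | None = None,
) -> PrevalenceWeights:
    """Observed prevalence of each living state in [anchor, anchor + window).

    Weighted by the longitudinal survey weights; waves with unknown state or
    vital status are excluded from numerator and denominator.  The effective
    sample size is the Kish approximation (sum w)^2 / sum w^2, used later to
    propagate prevalence sampling noise into the confidence intervals.
    """
    structure = structure or TransitionStructure()
    living = list(structure.living_states)
    sel = (
        panel["state"].isin(living)
        & (panel["age"] >= age_anchor)
        & (panel["age"] < age_anchor + window)
    )
    sub = panel.loc[sel]
    if sub.empty:
        raise ValueError(
            f"no known-state observations with age in [{age_anchor}, "
            f"{age_anchor + window}); widen the window (refreshment samples "
            "may not include the exact anchor age)"
        )
    totals = sub.groupby("state")["weight"].sum().reindex(living).fillna(0.0)
    w = totals.to_numpy() / totals.sum()
    eff = float(sub["weight"].sum() ** 2 / (sub["weight"] ** 2).sum())
    return PrevalenceWeights(w, age_anchor, window, int(len(sub)), eff)


def _substep_matrix(M: np.ndarray, m: int) -> np.ndarray:
    """Principal m-th root of a step matrix, projected back to stochastic.

    Sub-steps refine the occupancy integration within one model step without
    changing the step transition law (the product of the m sub-step matrices
    reproduces M up to the projection)."""
    if m == 1:
        return M
    R = scipy.linalg.fractional_matrix_power(M, 1.0 / m)
    R = np.real(R)
    R = np.clip(R, 0.0, None)
    R /= R.sum(axis=1, keepdims=True)
    return R


def conditional_state_expectancies(
    fitted: FittedModel | ParameterVector,
    age_anchor: float = 50.0,
    horizon: float = 60.0,
    step_months: int | None = None,
    substeps: int = 1,
    covariates: dict[str, float] | None = None,
) -> np.ndarray:
    """Expected years in each living state by starting state at the anchor age.

    Returns e[i, j] = years in state j for a person in state i at
    ``age_anchor``, integrated (trapezoid) to ``age_anchor + horizon``.
    Warns if living occupancy at the horizon exceeds 1e-4 (horizon too
    short for the fitted mortality).
    """
    if isinstance(fitted, FittedModel):
        params = fitted.params
        step_months = step_months or fitted.step_months
    else:
        params = fitted
        step_months = step_months or 12
    struct = params.structure
    L = struct.n_living
    h = step_months / 12.0
    n_steps = int(math.ceil(horizon / h))
    X = None
    if params.covariate_names:
        covariates = covariates or {}
        X = np.array([[float(covariates.get(k, 0.0)) for k in params.covariate_names]])

    occ = np.zeros((L, L + 1))
    occ[:, :L] = np.eye(L)
    e = np.zeros((L, L))
    remaining = horizon
    for s in range(n_steps):
        age = age_anchor + s * h
        M = step_matrices(np.array([age]), params, X)[0]
        frac = min(remaining, h) / h
        if frac < 1.0:
            # partial final step: scale the exit odds by the elapsed fraction
            M = step_matrices(np.array([age]), params, X,
                              np.array([np.log(frac)]))[0]
        sub = _substep_matrix(M, substeps)
        h_sub = h * frac / substeps
        for _ in range(substeps):
            nxt = occ @ sub
            e += (h_sub / 2.0) * (occ[:, :L] + nxt[:, :L])
            occ = nxt
        remaining -= h * frac
    living_left = occ[:, :L].sum(axis=1).max()
    if living_left > 1e-4:
        warnings.warn(
            f"living occupancy {living_left:.2e} remains at the horizon; "
            "expectancies are truncated — consider a longer horizon",
            stacklevel=2,
        )
    return e


@dataclass
class ExpectancyTable:
    """Population expectancies: E_j = sum_i w_i e_ij over starting states i.

    ``hwle`` is the expectancy of the healthy-and-working state; ``le`` is
    the sum of the four state expectancies (the definition of life
    expectancy in this framework, so the identity is exact by construction).
    """

    conditional: np.ndarray          # e_ij, years
    weights: np.ndarray              # prevalence weights over starting states
    expectancies: np.ndarray         # E_j, years
    hwle: float
    le: float
    age_anchor: float
    horizon: float
    se: dict | None = None
    ci: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = {label: [self.expectancies[j]] for j, label in
                enumerate(STATE_EXPECTANCY_LABELS)}
        rows["le"] = [self.le]
        df = pd.DataFrame(rows)
        if self.ci is not None:
            for key in ("hwle", "le"):
                df[f"{key}_lo"], df[f"{key}_hi"] = self.ci[key]
        return df


def population_expectancies(
    conditional: np.ndarray,
    weights: PrevalenceWeights | np.ndarray,
    age_anchor: float = 50.0,
    horizon: float = 60.0,
) -> ExpectancyTable:
    """Prevalence-weighted population expectancies from the conditional rows."""
    w = weights.weights if isinstance(weights, PrevalenceWeights) else np.asarray(weights, float)
    e = np.asarray(conditional, dtype=float)
    if e.shape[0] != w.shape[0]:
        raise ValueError("weights and conditional expectancies are not conformable")
    E = w @ e
    return ExpectancyTable(
        conditional=e, weights=w, expectancies=E,
        hwle=float(E[0]), le=float(E.sum()),
        age_anchor=age_anchor, horizon=horizon,
    )


# ---------------------------------------------------------------------------
# parametric-simulation uncertainty
# ---------------------------------------------------------------------------

def _batch_expectancies(
    thetas: np.ndarray,
    structure: TransitionStructure,
    covariate_names: list[str],
    covariate_values: dict[str, float] | None,
    reference_age: float,
    age_anchor: float,
    horizon: float,
    step_months: int,
) -> np.ndarray:
    """Conditional expectancies e_ij for a batch of flat parameter vectors.

    Returns shape (n_draws, L, L).  Same propagation as
    :func:`conditional_state_expectancies` with substeps=1, vectorized over
    draws."""
    D = thetas.shape[0]
    L = structure.n_living
    S = structure.n_states
    nT = structure.n_transitions
    rows, cols = structure.transition_indices()
    mask = rows[None, :] == np.arange(L)[:, None]
    A = thetas[:, :nT]
    B = thetas[:, nT: 2 * nT]
    off = np.zeros((D, nT))
    for c, name in enumerate(covariate_names):
        x = float((covariate_values or {}).get(name, 0.0))
        off = off + x * thetas[:, (2 + c) * nT: (3 + c) * nT]
    h = step_months / 12.0
    n_steps = int(math.ceil(horizon / h))
    occ = np.zeros((D, L, S))
    occ[:, :, :L] = np.eye(L)
    e = np.zeros((D, L, L))
    for s in range(n_steps):
        age = age_anchor + s * h
        eta = A + B * (age - reference_age) + off
        E = np.exp(np.minimum(eta, 500.0))
        denom = 1.0 + E @ mask.T
        p = E / denom[:, rows]
        M = np.zeros((D, S, S))
        M[:, rows, cols] = p
        for r in range(L):
            M[:, r, r] = 1.0 - M[:, r].sum(axis=1)
        M[:, S - 1, S - 1] = 1.0
        nxt = np.einsum("dls,dst->dlt", occ, M)
        e += (h / 2.0) * (occ[:, :, :L] + nxt[:, :, :L])
        occ = nxt
    return e


def confidence_intervals(
    fitted: FittedModel,
    prevalence: PrevalenceWeights,
    age_anchor: float = 50.0,
    horizon: float = 60.0,
    n_draws: int = 1000,
    seed: int = 0,
    covariate_values: dict[str, float] | None = None,
    include_prevalence_uncertainty: bool = True,
    level: float = 0.95,
):
    """Simulation SEs and CIs for the population expectancies.

    Draws parameter vectors from N(estimate, covariance), redraws the
    prevalence weights from a Dirichlet at the window's effective sample
    size (unless disabled), recomputes the expectancies per draw, and
    summarizes.  Deterministic given the seed.  If the fitted covariance is
    unavailable the point estimates are returned with ``se``/``ci`` None.
    """
    e_hat = _batch_expectancies(
        fitted.params.to_array()[None, :], fitted.params.structure,
        fitted.params.covariate_names, covariate_values,
        fitted.params.reference_age, age_anchor, horizon, fitted.step_months,
    )[0]
    table = population_expectancies(e_hat, prevalence, age_anchor, horizon)
    if fitted.covariance is None:
        return table
    rng = np.random.default_rng(seed)
    thetas = rng.multivariate_normal(
        fitted.params.to_array(), fitted.covariance, size=n_draws,
        method="eigh",
    )
    e_draws = _batch_expectancies(
        thetas, fitted.params.structure, fitted.params.covariate_names,
        covariate_values, fitted.params.reference_age, age_anchor, horizon,
        fitted.step_months,
    )
    if include_prevalence_uncertainty and np.isfinite(prevalence.effective_n):
        alpha = np.maximum(prevalence.weights * prevalence.effective_n, 1e-9)
        w_draws = rng.dirichlet(alpha, size=n_draws)
    else:
        w_draws = np.tile(prevalence.weights, (n_draws, 1))
    E_draws = np.einsum("di,dij->dj", w_draws, e_draws)
    draws = {
        "expectancies": E_draws,
        "hwle": E_draws[:, 0],
        "le": E_draws.sum(axis=1),
    }
    lo_q, hi_q = 100 * (0.5 - level / 2), 100 * (0.5 + level / 2)
    table.se = {k: np.std(v, axis=0, ddof=1) for k, v in draws.items()}
    table.ci = {
        k: (np.percentile(v, lo_q, axis=0), np.percentile(v, hi_q, axis=0))
        for k, v in draws.items()
    }
    return table


def percent_of_le(hwle: float, le: float) -> int:
    """Healthy-working share of life expectancy as an integer percent
    (round half away from zero, the convention of published HWLE tables)."""
    if le <= 0:
        raise ValueError("life expectancy must be positive")
    x = 100.0 * hwle / le
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def working_days_lost(
    hwle_ref: float, hwle_cmp: float, working_days_per_year: float = 260.0
) -> float:
    """Working days separating two healthy-working expectancies, assuming a
    fixed count of working days per year."""
    if working_days_per_year <= 0:
        raise ValueError("working_days_per_year must be positive")
    return (hwle_ref - hwle_cmp) * working_days_per_year


def round_to_hundred(days: float) -> int:
    """Reporting helper: nearest hundred days."""
    return int(round(days / 100.0)) * 100
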