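"""Shared fixtures: tiny hand-built panels and the replicate simulation study.

The replicate study (100 independent cohorts of 2,000 individuals, 14
biennial waves, fitted and summarized) backs the parameter-recovery and
interval-coverage checks; it is session-scoped because several tests read
different summaries of the same replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hwle
from hwle.expectancy import conditional_state_expectancies, population_expectancies
from hwle.model import build_intervals, fit_mle


def make_panel(rows, **person_fields):
    """Panel DataFrame from (id, date, age, state) tuples plus defaults."""
    defaults = dict(weight=1.0, arthritis=0, obese=0, sex=0, education=1,
                    ethnicity="white", region="South", death_date="")
    defaults.update(person_fields)
    df = pd.DataFrame(rows, columns=["id", "date", "age", "state"])
    for k, v in defaults.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def truth():
    return hwle.default_true_params()


@pytest.fixture(scope="session")
def true_initial_probs():
    return np.array(hwle.TrueModelConfig().initial_state_probs)


@pytest.fixture(scope="session")
def true_expectancies(truth, true_initial_probs):
    """Ground-truth population expectancies implied by the generator."""
    e = conditional_state_expectancies(truth, 50.0, 60.0)
    return population_expectancies(e, true_initial_probs)


def run_replicate(seed: int, n: int = 2000, n_waves: int = 14,
                  compute_covariance: bool = True):
    """One full generate -> prep -> fit -> expectancy replicate."""
    cfg = hwle.TrueModelConfig(n_individuals=n, seed=seed, n_waves=n_waves)
    panel = hwle.cohort_to_panel(hwle.generate_cohort(cfg))
    prepped, _ = hwle.prepare_coded_panel(panel)
    intervals = build_intervals(prepped, cfg.transition_params.structure)
    fitted = fit_mle(intervals, cfg.transition_params.structure,
                     init=cfg.transition_params,
                     compute_covariance=compute_covariance)
    return cfg, prepped, fitted


@pytest.fixture(scope="session")
def replicate_study(truth, true_expectancies):
    """100 replicate fits at n=2,000, 14 biennial waves, under the default
    generating conditions; summaries for recovery and coverage checks."""
    from hwle.expectancy import confidence_intervals, initial_prevalence

    n_rep = 100
    theta_true = truth.to_array()
    estimates, ses, hwles, hwle_ses, hwle_cis, converged = [], [], [], [], [], []
    for r in range(n_rep):
        cfg, prepped, fitted = run_replicate(seed=1000 + r)
        est = fitted.params.to_array()
        se = fitted.standard_errors()
        if se is None:
            se = np.full_like(est, np.nan)
        prevalence = initial_prevalence(prepped, 50.0, 1.0)
        table = confidence_intervals(fitted, prevalence, n_draws=1000, seed=r)
        estimates.append(est)
        ses.append(se)
        hwles.append(table.hwle)
        if table.se is None:
            hwle_ses.append(np.nan)
            hwle_cis.append((np.nan, np.nan))
        else:
            hwle_ses.append(float(table.se["hwle"]))
            hwle_cis.append(tuple(float(v) for v in table.ci["hwle"]))
        converged.append(fitted.converged)
    return {
        "theta_true": theta_true,
        "estimates": np.array(estimates),
        "ses": np.array(ses),
        "hwle_true": true_expectancies.hwle,
        "hwles": np.array(hwles),
        "hwle_ses": np.array(hwle_ses),
        "hwle_cis": np.array(hwle_cis),
        "converged": np.array(converged),
    }
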