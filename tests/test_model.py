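"""Estimator core: step matrices, interval probabilities, likelihood, MLE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hwle
from hwle.model import (
    brute_force_interval_probability,
    build_intervals,
    fit_mle,
    individual_log_likelihood,
    interval_transition_probability,
    loglik_and_grad,
    step_matrices,
    step_transition_matrix,
    total_log_likelihood,
)
from hwle.states import DEAD, ParameterVector, TransitionStructure

from conftest import make_panel


def random_params(seed, structure=None, scale=1.0):
    structure = structure or TransitionStructure()
    rng = np.random.default_rng(seed)
    return ParameterVector(
        structure,
        rng.normal(-2.0, scale, structure.n_transitions),
        rng.normal(0.0, 0.05, structure.n_transitions),
    )


class TestStepMatrix:
    def test_single_exit_logit_zero_gives_half(self):
        s = TransitionStructure(living_states=(1, 2), permitted=((1, 2),))
        p = ParameterVector(s, np.zeros(1), np.zeros(1))
        M = step_transition_matrix(50.0, p)
        assert M[0, 1] == pytest.approx(0.5)
        assert M[0, 0] == pytest.approx(0.5)
        assert M[1, 1] == 1.0  # no modelled exit: reference category only

    def test_structural_zeros_give_identity_on_living(self):
        s = TransitionStructure(permitted=())
        p = ParameterVector(s, np.zeros(0), np.zeros(0))
        M = step_transition_matrix(63.2, p)
        assert np.array_equal(M, np.eye(5))

    def test_very_negative_logits_approach_identity(self):
        p = random_params(0)
        p.intercept[:] = -60.0
        p.age_slope[:] = 0.0
        M = step_transition_matrix(70.0, p)
        assert np.allclose(M, np.eye(5), atol=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_stochastic_and_match_direct_softmax(self, seed):
        """Row sums are 1 to 1e-12 and entries match an independently coded
        per-row softmax."""
        p = random_params(seed, scale=2.0)
        age = 55.0 + 3 * seed
        M = step_transition_matrix(age, p)
        assert np.all(M >= 0) and np.all(M <= 1)
        assert np.abs(M.sum(axis=1) - 1).max() < 1e-12
        # independent oracle: build each row's softmax directly
        expected = np.eye(5)
        for i, state in enumerate((1, 2, 3, 4)):
            etas = {}
            for t, (a, b) in enumerate(p.structure.permitted):
                if a == state:
                    etas[b] = p.intercept[t] + p.age_slope[t] * (age - p.reference_age)
            denom = 1.0 + sum(np.exp(v) for v in etas.values())
            row = np.zeros(5)
            row[i] = 1.0 / denom
            for dest, v in etas.items():
                row[p.structure.state_index(dest)] = np.exp(v) / denom
            expected[i] = row
        assert np.allclose(M, expected, atol=1e-14)

    def test_age_slope_moves_probability(self):
        p = random_params(1)
        M50 = step_transition_matrix(50.0, p)
        M80 = step_transition_matrix(80.0, p)
        assert not np.allclose(M50, M80)

    def test_nan_parameter_rejected(self):
        s = TransitionStructure()
        with pytest.raises(ValueError):
            ParameterVector(s, np.full(16, np.nan), np.zeros(16))


class TestIntervalProbability:
    def test_zero_length_interval_is_indicator(self):
        p = random_params(2)
        assert interval_transition_probability(1, 50.0, 1, 50.0, p) == 1.0
        assert interval_transition_probability(1, 50.0, 3, 50.0, p) == 0.0

    def test_two_state_toy_survival(self):
        """Constant per-step death probability 0.1: alive->alive over two
        steps is 0.9**2."""
        s = TransitionStructure(living_states=(1,), permitted=((1, DEAD),))
        p = ParameterVector(s, np.array([np.log(1 / 9)]), np.zeros(1))
        prob = interval_transition_probability(1, 50.0, 1, 52.0, p)
        assert prob == pytest.approx(0.81, abs=1e-12)

    def test_chapman_kolmogorov_two_steps_by_hand(self):
        s = TransitionStructure(living_states=(1, 2), permitted=((1, 2), (2, 1), (1, DEAD), (2, DEAD)))
        p = ParameterVector(s, np.array([-1.0, -0.5, -2.0, -1.5]),
                            np.array([0.02, -0.01, 0.05, 0.04]))
        M1 = step_transition_matrix(60.0, p)
        M2 = step_transition_matrix(61.0, p)
        hand = sum(M1[0, k] * M2[k, 1] for k in range(3))
        assert brute_force_interval_probability(1, 60.0, 2, 62.0, p) == pytest.approx(hand, abs=1e-15)
        assert interval_transition_probability(1, 60.0, 2, 62.0, p) == pytest.approx(hand, abs=1e-15)

    def test_one_step_brute_force_equals_matrix_entry(self):
        p = random_params(3)
        M = step_transition_matrix(57.0, p)
        assert brute_force_interval_probability(2, 57.0, 4, 58.0, p) == pytest.approx(
            M[1, 3], abs=1e-15
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matrix_product_agrees_with_path_enumeration(self, seed):
        """Matrix-product and exhaustive path-sum interval probabilities agree
        to 1e-12 for up to 6 steps, including partial trailing steps."""
        rng = np.random.default_rng(seed)
        p = random_params(seed + 100, scale=1.5)
        steps = rng.integers(1, 7)
        months = int(steps) * 12 - rng.integers(0, 2) * 5  # sometimes fractional
        age_a = float(rng.uniform(50, 80))
        age_b = age_a + months / 12.0
        s_a = int(rng.integers(1, 5))
        s_b = int(rng.choice([1, 2, 3, 4, DEAD, -1]))
        got = interval_transition_probability(s_a, age_a, s_b, age_b, p)
        want = brute_force_interval_probability(s_a, age_a, s_b, age_b, p)
        assert got == pytest.approx(want, abs=1e-12)

    def test_enumeration_refuses_excess_steps(self):
        p = random_params(4)
        with pytest.raises(ValueError, match="enumeration"):
            brute_force_interval_probability(1, 50.0, 2, 60.0, p)

    def test_raising_death_intercept_lowers_survival(self):
        """Increasing any living->dead intercept strictly decreases P(alive)
        over a fixed interval."""
        p = random_params(5)
        base = interval_transition_probability(1, 55.0, -1, 59.0, p)
        for t, (i, j) in enumerate(p.structure.permitted):
            if j == DEAD:
                q = p.copy()
                q.intercept[t] += 0.5
                assert interval_transition_probability(1, 55.0, -1, 59.0, q) < base


class TestLikelihood:
    def test_single_observation_contributes_zero(self):
        p = random_params(6)
        panel = make_panel([(1, "2000-06", 55.0, 1)])
        assert individual_log_likelihood(panel, p) == 0.0

    def test_single_step_pair_reduces_to_log_entry(self):
        p = random_params(7)
        w = 2.5
        panel = make_panel([(1, "2000-06", 55.0, 1), (1, "2001-06", 56.0, 2)], weight=w)
        M = step_transition_matrix(55.0, p)
        assert individual_log_likelihood(panel, p) == pytest.approx(w * np.log(M[0, 1]))

    def test_chains_across_unknown_vital_status(self):
        """A -2 wave contributes nothing; the interval spans it as a product
        of four annual steps."""
        p = random_params(8)
        panel = make_panel([
            (1, "2000-06", 55.0, 1),
            (1, "2002-06", 57.0, -2),
            (1, "2004-06", 59.0, 4),
        ])
        want = np.log(brute_force_interval_probability(1, 55.0, 4, 59.0, p))
        assert individual_log_likelihood(panel, p) == pytest.approx(want, abs=1e-12)

    def test_intermediate_unknown_state_is_implied(self):
        """A -1 wave between two known states adds no information beyond the
        product over the full interval."""
        p = random_params(9)
        with_unknown = make_panel([
            (1, "2000-06", 55.0, 2),
            (1, "2002-06", 57.0, -1),
            (1, "2004-06", 59.0, 1),
        ])
        without = make_panel([
            (1, "2000-06", 55.0, 2),
            (1, "2004-06", 59.0, 1),
        ])
        assert individual_log_likelihood(with_unknown, p) == pytest.approx(
            individual_log_likelihood(without, p)
        )

    def test_trailing_unknown_state_contributes_survival(self):
        p = random_params(10)
        panel = make_panel([(1, "2000-06", 55.0, 3), (1, "2002-06", 57.0, -1)])
        want = np.log(interval_transition_probability(3, 55.0, -1, 57.0, p))
        assert individual_log_likelihood(panel, p) == pytest.approx(want, abs=1e-12)

    def test_death_localized_to_final_step(self):
        """Death with a known month: survive among the living to the start of
        the final step, then move to dead within it."""
        p = random_params(11)
        panel = make_panel(
            [(1, "2000-06", 55.0, 2)], death_date="2003-06",
        )
        M1 = step_transition_matrix(55.0, p)
        M2 = step_transition_matrix(56.0, p)
        M3 = step_transition_matrix(57.0, p)
        surv = (M1 @ M2)[1, :4]  # alive states after two steps
        want = np.log(surv @ M3[:4, 4])
        assert individual_log_likelihood(panel, p) == pytest.approx(want, abs=1e-12)

    def test_likelihood_additive_and_order_invariant(self):
        p = random_params(12)
        cfg = hwle.TrueModelConfig(n_individuals=120, seed=2, n_waves=6)
        panel, _ = hwle.prepare_coded_panel(hwle.cohort_to_panel(hwle.generate_cohort(cfg)))
        total = total_log_likelihood(panel, p)
        per_person = sum(
            individual_log_likelihood(g, p) for _, g in panel.groupby("id")
        )
        assert total == pytest.approx(per_person, rel=1e-12)
        shuffled = panel.sample(frac=1.0, random_state=0)
        assert total_log_likelihood(shuffled, p) == pytest.approx(total, rel=1e-12)

    def test_weights_scale_likelihood_and_gradient_linearly(self):
        """Doubling every weight doubles the log-likelihood and its gradient,
        hence leaves the argmax unchanged."""
        p = random_params(13)
        cfg = hwle.TrueModelConfig(n_individuals=100, seed=4, n_waves=5)
        panel, _ = hwle.prepare_coded_panel(hwle.cohort_to_panel(hwle.generate_cohort(cfg)))
        iv1 = build_intervals(panel, p.structure)
        doubled = panel.assign(weight=panel["weight"] * 2)
        iv2 = build_intervals(doubled, p.structure)
        ll1, g1 = loglik_and_grad(iv1, p)
        ll2, g2 = loglik_and_grad(iv2, p)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)
        assert np.allclose(g2, 2 * g1, rtol=1e-10)

    def test_analytic_gradient_matches_finite_differences(self):
        cfg = hwle.TrueModelConfig(n_individuals=80, seed=6, n_waves=6)
        panel, _ = hwle.prepare_coded_panel(hwle.cohort_to_panel(hwle.generate_cohort(cfg)))
        p = hwle.default_true_params()
        iv = build_intervals(panel, p.structure)
        _, grad = loglik_and_grad(iv, p)
        theta = p.to_array()
        h = 1e-6
        for j in range(0, theta.size, 5):
            num = 0.0
            for sign in (1, -1):
                t2 = theta.copy()
                t2[j] += sign * h
                num += sign * total_log_likelihood(
                    iv, ParameterVector.from_array(t2, p.structure)
                ) / (2 * h)
            assert grad[j] == pytest.approx(num, rel=1e-4, abs=1e-5)


class TestFit:
    def test_binomial_death_mle_closed_form(self):
        """Two-state chain observed over single steps: the fitted death
        probability equals the closed-form binomial MLE k/n."""
        s = TransitionStructure(living_states=(1,), permitted=((1, DEAD),))
        k, n = 13, 80
        rows = []
        for i in range(n - k):
            rows += [(i, "2000-06", 60.0, 1), (i, "2001-06", 61.0, 1)]
        panel = make_panel(rows)
        dead_rows = make_panel([(1000 + i, "2000-06", 60.0, 1) for i in range(k)],
                               death_date="2001-06")
        panel = pd.concat([panel, dead_rows], ignore_index=True)
        fitted = fit_mle(panel, s, init=ParameterVector(s, np.array([-2.0]), np.zeros(1),
                                                        reference_age=60.0),
                         fit_age_slopes=False, reference_age=60.0)
        p_hat = 1 / (1 + np.exp(-fitted.params.intercept[0]))
        assert p_hat == pytest.approx(k / n, abs=1e-6)

    def test_default_init_reaches_same_optimum_as_truth_init(self):
        cfg = hwle.TrueModelConfig(n_individuals=400, seed=8, n_waves=8)
        panel, _ = hwle.prepare_coded_panel(hwle.cohort_to_panel(hwle.generate_cohort(cfg)))
        iv = build_intervals(panel, cfg.transition_params.structure)
        f1 = fit_mle(iv, init=cfg.transition_params, compute_covariance=False)
        f2 = fit_mle(iv, compute_covariance=False)
        assert f1.converged and f2.converged
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-3)
        assert np.allclose(f1.params.to_array(), f2.params.to_array(), atol=5e-3)

    def test_fitted_model_round_trips_through_json(self, tmp_path):
        cfg = hwle.TrueModelConfig(n_individuals=150, seed=9, n_waves=5)
        panel, _ = hwle.prepare_coded_panel(hwle.cohort_to_panel(hwle.generate_cohort(cfg)))
        fitted = fit_mle(panel, init=cfg.transition_params, maxiter=30,
                         compute_covariance=False)
        path = tmp_path / "model.json"
        fitted.save(path)
        loaded = hwle.FittedModel.load(path)
        assert np.allclose(loaded.params.to_array(), fitted.params.to_array())
        assert loaded.step_months == fitted.step_months
        assert loaded.params.structure.permitted == fitted.params.structure.permitted


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 10**6))
def test_parameter_vector_round_trips_flat_layout(seed):
    p = random_params(seed)
    q = ParameterVector.from_array(p.to_array(), p.structure)
    assert np.array_equal(q.intercept, p.intercept)
    assert np.array_equal(q.age_slope, p.age_slope)


def test_recovered_parameters_nearly_unbiased(truth):
    """Mean estimation error across replicates at n=5,000 stays under half a
    replicate SD for every parameter, up to the Monte-Carlo noise of
    estimating the bias itself with R replicates (a 2 sd/sqrt(R) allowance)."""
    ests = []
    from conftest import run_replicate

    n_rep = 20
    for r in range(n_rep):
        _, _, fitted = run_replicate(seed=5000 + r, n=5000,
                                     compute_covariance=False)
        assert fitted.converged
        ests.append(fitted.params.to_array())
    ests = np.array(ests)
    bias = ests.mean(axis=0) - truth.to_array()
    sd = ests.std(axis=0, ddof=1)
    assert np.all(np.abs(bias) < (0.5 + 2 / np.sqrt(n_rep)) * sd)
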