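"""Rounding, trial simulation, MLE fitting and operating characteristics."""

import numpy as np
import pytest
from scipy.optimize import minimize as sp_minimize
from scipy.special import expit

from crdesign import (
    ContinuousDesign,
    CRParams,
    DoseInterval,
    FitResult,
    TrialData,
    UndeterminedEstimateError,
    estimate_targets,
    fit_cr_mle,
    mtd,
    obd,
    operating_characteristics,
    outcome_probabilities,
    round_design,
    simulate_trial,
)

from conftest import table1_design


class TestRoundDesign:
    @pytest.mark.parametrize(
        "label, counts",
        [
            ("I", [12, 18, 10]),
            ("II", [16, 8, 16]),
            ("III", [25, 15]),
            ("IV", [15, 25]),
        ],
    )
    def test_reproduces_reference_allocations(self, label, counts):
        exact = round_design(table1_design(label), 40)
        assert exact.counts.tolist() == counts
        assert exact.counts.sum() == 40

    def test_exact_fractions_round_exactly(self):
        design = ContinuousDesign([1.0, 2.0, 3.0], [0.25, 0.25, 0.5])
        exact = round_design(design, 40)
        assert exact.counts.tolist() == [10, 10, 20]

    def test_requires_enough_patients(self):
        design = ContinuousDesign([1.0, 2.0, 3.0], [0.3, 0.3, 0.4])
        with pytest.raises(ValueError):
            round_design(design, 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_within_one_patient_of_ideal(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 6)
        w = rng.dirichlet(np.ones(k) * 2)
        while w.min() < 0.02:
            w = rng.dirichlet(np.ones(k) * 2)
        design = ContinuousDesign(np.sort(rng.uniform(0, 10, k)), w)
        n = int(rng.integers(k, 200))
        exact = round_design(design, n)
        assert exact.counts.sum() == n
        assert np.all(exact.counts >= 0)
        # divisor-type apportionment bound; tightens to <1 patient unless a
        # single weight dominates a small sample
        dev = np.abs(exact.counts - n * design.weights)
        assert np.all(dev <= k / 2 * design.weights + 1.0)
        if k / 2 * design.weights.max() <= 1.0:
            assert np.all(dev < 1.0)


class TestSimulateTrial:
    def test_outcome_frequencies_match_model(self, worked_params):
        design = ContinuousDesign([3.0, 7.0], [0.5, 0.5])
        exact = round_design(design, 100_000)
        data = simulate_trial(exact, worked_params, 2024)
        for d in exact.doses:
            probs = outcome_probabilities(d, worked_params)
            sel = data.doses == d
            n_d = sel.sum()
            for code, p in enumerate(probs):
                freq = np.mean(data.outcomes[sel] == code)
                se = np.sqrt(p * (1 - p) / n_d)
                assert abs(freq - p) <= 3 * se + 1e-9

    def test_negligible_toxicity_produces_no_toxic_outcomes(self):
        params = CRParams(-50.0, 0.01, -1.0, 1.0)
        exact = round_design(ContinuousDesign([2.0, 8.0], [0.5, 0.5]), 1000)
        data = simulate_trial(exact, params, 7)
        assert np.all(data.outcomes != 2)

    def test_deterministic_given_seed(self, worked_params):
        exact = round_design(table1_design("I"), 40)
        a = simulate_trial(exact, worked_params, 55)
        b = simulate_trial(exact, worked_params, 55)
        assert np.array_equal(a.doses, b.doses)
        assert np.array_equal(a.outcomes, b.outcomes)


def _trinomial_negll(theta, doses, outcomes):
    a1, b1, a2, b2 = theta
    pt = expit(a1 + b1 * doses)
    pe = expit(a2 + b2 * doses)
    ll = np.where(
        outcomes == 2,
        np.log(pt),
        np.log1p(-pt)
        + np.where(outcomes == 1, np.log(pe), np.log1p(-pe)),
    )
    return -ll.sum()


class TestFitCRMLE:
    def test_all_toxic_is_undetermined(self):
        data = TrialData(np.repeat([2.0, 6.0], 5), np.full(10, 2))
        fit = fit_cr_mle(data)
        assert not fit.determined

    def test_regular_mle_satisfies_score_equations(self):
        doses = np.repeat([2.0, 6.0], 10)
        outcomes = np.array([0] * 7 + [1, 1, 2] + [0, 0] + [1] * 4 + [2] * 4)
        fit = fit_cr_mle(TrialData(doses, outcomes))
        assert fit.determined
        a1, b1, a2, b2 = fit.params_hat
        pt = expit(a1 + b1 * doses)
        tox = (outcomes == 2).astype(float)
        assert abs(np.sum(tox - pt)) < 1e-6
        assert abs(np.sum((tox - pt) * doses)) < 1e-6
        safe = outcomes != 2
        pe = expit(a2 + b2 * doses[safe])
        eff = (outcomes[safe] == 1).astype(float)
        assert abs(np.sum(eff - pe)) < 1e-6
        assert abs(np.sum((eff - pe) * doses[safe])) < 1e-6

    def test_factorized_fit_maximizes_full_trinomial_likelihood(self):
        """The two logistic fits jointly solve the trinomial ML problem."""
        doses = np.repeat([2.0, 6.0], 6)
        outcomes = np.array([0, 0, 0, 1, 1, 2, 0, 1, 1, 2, 2, 2])
        fit = fit_cr_mle(TrialData(doses, outcomes))
        assert fit.determined
        res = sp_minimize(
            _trinomial_negll,
            x0=np.array([0.0, 0.5, 0.0, 0.5]),
            args=(doses, outcomes),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20000},
        )
        assert np.allclose(fit.params_hat, res.x, atol=1e-5)


class TestEstimateTargets:
    def test_truth_plugin_recovers_model_quantities(
        self, worked_params, study_interval, gamma
    ):
        fit = FitResult(params_hat=worked_params.to_array(), determined=True)
        mtd_hat, obd_hat = estimate_targets(fit, gamma, study_interval)
        assert mtd_hat == pytest.approx(mtd(worked_params, gamma), abs=1e-9)
        assert obd_hat == pytest.approx(obd(worked_params, study_interval), abs=1e-5)

    def test_nonpositive_toxicity_slope_reclassified(self, study_interval):
        fit = FitResult(params_hat=np.array([-2.0, -0.5, -3.0, 1.0]), determined=True)
        with pytest.raises(UndeterminedEstimateError):
            estimate_targets(fit, 0.2, study_interval)

    def test_undetermined_fit_is_contract_violation(self, study_interval):
        fit = FitResult(params_hat=np.full(4, np.nan), determined=False)
        with pytest.raises(ValueError):
            estimate_targets(fit, 0.2, study_interval)

    @pytest.mark.parametrize("seed", range(5))
    def test_obd_estimate_always_inside_interval(self, seed, study_interval):
        rng = np.random.default_rng(seed)
        theta = np.array(
            [rng.uniform(-8, 2), rng.uniform(0.05, 2), rng.uniform(-8, 2), rng.uniform(0.05, 2)]
        )
        fit = FitResult(params_hat=theta, determined=True)
        _, obd_hat = estimate_targets(fit, 0.2, study_interval)
        assert 0.0 <= obd_hat <= 10.0


class TestOperatingCharacteristics:
    def test_rmse_identity_and_determinism(self, worked_params, study_interval, gamma):
        design = table1_design("IV")
        oc1 = operating_characteristics(
            design, worked_params, gamma, study_interval, n=40, n_reps=50, seed=5
        )
        oc2 = operating_characteristics(
            design, worked_params, gamma, study_interval, n=40, n_reps=50, seed=5
        )
        assert oc1 == oc2
        assert oc1.mtd_rmse**2 == pytest.approx(
            oc1.mtd_bias**2 + oc1.mtd_sd**2, abs=1e-9
        )
        assert oc1.obd_rmse**2 == pytest.approx(
            oc1.obd_bias**2 + oc1.obd_sd**2, abs=1e-9
        )
        assert oc1.n_determined + round(oc1.pr_no_mle * oc1.n_reps) == oc1.n_reps

    def test_mle_consistency_shrinks_bias_with_sample_size(
        self, worked_params, study_interval, gamma
    ):
        design = table1_design("IV")
        small = operating_characteristics(
            design, worked_params, gamma, study_interval, n=40, n_reps=400, seed=9
        )
        large = operating_characteristics(
            design, worked_params, gamma, study_interval, n=4000, n_reps=400, seed=9
        )
        assert abs(large.mtd_bias) < abs(small.mtd_bias)
        assert large.mtd_rmse < small.mtd_rmse

    def test_undetermined_rate_decreases_with_sample_size(
        self, worked_params, study_interval, gamma
    ):
        design = table1_design("II")
        small = operating_characteristics(
            design, worked_params, gamma, study_interval, n=40, n_reps=300, seed=3
        )
        large = operating_characteristics(
            design, worked_params, gamma, study_interval, n=400, n_reps=300, seed=3
        )
        assert large.pr_no_mle < small.pr_no_mle

    def test_parameter_recovery_at_large_n(self, worked_params):
        """Fitted parameters are unbiased at n=4000 under the D-optimal design."""
        exact = round_design(table1_design("I"), 4000)
        estimates = []
        for r in range(500):
            data = simulate_trial(
                exact, worked_params, np.random.SeedSequence([77, r])
            )
            fit = fit_cr_mle(data)
            if fit.determined:
                estimates.append(fit.params_hat)
        est = np.array(estimates)
        assert est.shape[0] > 450
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / np.sqrt(est.shape[0])
        truth = worked_params.to_array()
        # 3 MC standard errors plus an O(1/n) allowance for the second-order
        # (Cox-Snell) bias of the logistic MLE, which does not average away
        assert np.all(np.abs(mean - truth) <= 3 * se + 50.0 / 4000)
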