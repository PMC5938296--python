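"""Fixed-effects cumulative-logit fitting: oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import logistic

from vgrlab import (
    ConvergenceError,
    CumulativeLogitVGR,
    ModelSpec,
    SimulationConfig,
    fit_fixed,
    prepare_covariates,
    simulate_study,
    tube_load_effect_by_algorithm,
)

LN_98_42 = np.log(98.0 / 42.0)


def make_records(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "observer_id", "criterion", "left_mAs",
                 "left_algo", "right_mAs", "right_algo", "score",
                 "replicate_index"],
    )


def one_covariate_fixture():
    """30 deterministic records over two FBP dose pairs, scores in -1..1."""
    scores_a = [1, 0, 1, 1, -1, 0, 1, 1, 0, 1, -1, 1, 0, 1, 1]   # 42 vs 98
    scores_b = [1, 1, 1, 0, 1, 1, -1, 1, 1, 1, 0, 1, 1, 1, 0]    # 42 vs 140
    rows = []
    for i, s in enumerate(scores_a):
        if i % 4 == 0:  # mirrored presentation
            rows.append([f"P{i}", "O1", 1, 98.0, "FBP", 42.0, "FBP", -s, 0])
        else:
            rows.append([f"P{i}", "O1", 1, 42.0, "FBP", 98.0, "FBP", s, 0])
    for i, s in enumerate(scores_b):
        rows.append([f"Q{i}", "O1", 1, 42.0, "FBP", 140.0, "FBP", s, 0])
    return make_records(rows)


def brute_force_loglik(dlog, y_cat, n_cats=3, rounds=14, width=8.0):
    """Iterated grid refinement over (a, theta_1, theta_2).

    Independent of the fitting code: plain logistic-CDF differences on a
    shrinking 3-D grid.
    """
    assert n_cats == 3
    center = np.array([0.0, -1.0, 1.0])
    widths = np.array([width, width, width])
    grid_n = 13
    best_val, best = -np.inf, center
    for _ in range(rounds):
        axes = [np.linspace(c - w, c + w, grid_n) for c, w in zip(center, widths)]
        A, T1, T2 = np.meshgrid(*axes, indexing="ij")
        valid = T2 > T1
        eta = np.einsum("i,jkl->ijkl", dlog, A)
        cdf1 = logistic.cdf(T1[None] - eta)
        cdf2 = logistic.cdf(T2[None] - eta)
        p = np.stack([cdf1, cdf2 - cdf1, 1.0 - cdf2])  # (3, n, grid^3)
        probs = p[y_cat, np.arange(len(y_cat))]
        ll = np.where(valid[None], np.log(np.clip(probs, 1e-300, None)), -np.inf).sum(axis=0)
        ll[~valid] = -np.inf
        idx = np.unravel_index(np.argmax(ll), ll.shape)
        if ll[idx] > best_val:
            best_val = float(ll[idx])
            best = np.array([axes[d][idx[d]] for d in range(3)])
        center = best
        widths = widths * (2.0 / (grid_n - 1)) * 1.5  # keep neighbours in range
    return best_val, best


class TestPrepareCovariates:
    def test_dose_difference_on_log_scale(self, default_design):
        df = make_records([["P1", "O1", 1, 42.0, "FBP", 98.0, "FBP", 1, 0]])
        data = prepare_covariates(df, ModelSpec())
        assert data.columns[0] == "log_tube_load"
        assert data.X[0, 0] == pytest.approx(LN_98_42, abs=1e-12)
        assert np.all(data.X[0, 1:] == 0)

    def test_signed_algorithm_indicator(self):
        df = make_records([
            ["P1", "O1", 1, 98.0, "FBP", 98.0, "IR3", 1, 0],
            ["P1", "O1", 1, 98.0, "IR3", 98.0, "FBP", -1, 0],
        ])
        data = prepare_covariates(df, ModelSpec())
        j = data.columns.index("algo:IR3")
        assert data.X[0, 0] == 0.0
        assert data.X[0, j] == 1.0 and data.X[1, j] == -1.0

    def test_dose_interval_filter_matches_hand_count(self):
        rows = []
        for i in range(8):
            rows.append([f"P{i}", "O1", 1, 42.0, "FBP", 98.0, "FBP", 0, 0])
        for i in range(7):
            rows.append([f"P{i}", "O1", 1, 98.0, "IR3", 140.0, "IR3", 1, 0])
        for i in range(5):
            rows.append([f"P{i}", "O1", 1, 42.0, "FBP", 42.0, "IR5", -1, 0])
        df = make_records(rows)
        data = prepare_covariates(df, ModelSpec(dose_interval=(42.0, 98.0)))
        assert len(data.y) == 13  # the seven 140-mAs rows are excluded

    def test_response_on_observed_categories(self):
        df = one_covariate_fixture()
        data = prepare_covariates(df, ModelSpec(covariates=("log_tube_load",)))
        assert list(data.categories) == [-1, 0, 1]
        assert data.K == 3


class TestFitFixed:
    def test_loglik_matches_brute_force_grid(self):
        df = one_covariate_fixture()
        fit = fit_fixed(df, ModelSpec(covariates=("log_tube_load",), random_effects=()))
        data = prepare_covariates(df, ModelSpec(covariates=("log_tube_load",)))
        ll_grid, params = brute_force_loglik(data.X[:, 0], data.y)
        assert fit.loglik == pytest.approx(ll_grid, abs=1e-4)
        assert fit.loglik >= ll_grid - 1e-4

    def test_agrees_with_statsmodels_ordered_model(self, small_study):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        spec = ModelSpec(random_effects=())
        fit = fit_fixed(small_study, spec, criterion=1)
        data = prepare_covariates(small_study, spec)
        y = pd.Series(pd.Categorical(data.y, ordered=True))
        sm_fit = OrderedModel(y, data.X, distr="logit").fit(
            method="bfgs", disp=0, gtol=1e-8
        )
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        for j, name in enumerate(data.columns):
            assert fit.coef[name] == pytest.approx(
                sm_fit.params.iloc[j], abs=1e-3
            )

    def test_null_data_recovers_null(self):
        cfg = SimulationConfig(
            n_patients=40, true_a=0.0, true_b={"IR3": 0.0, "IR5": 0.0},
            sigma_patient=0.0, sigma_observer=0.0, n_replicates=0, seed=21,
            criteria=(1,),
        )
        fit = fit_fixed(simulate_study(cfg), ModelSpec(random_effects=()))
        for name in fit.fixed_names:
            assert abs(fit.coef[name]) < 3 * fit.se[name]

    def test_degenerate_response_rejected(self):
        df = make_records(
            [[f"P{i}", "O1", 1, 42.0, "FBP", 98.0, "FBP", 1, 0] for i in range(10)]
        )
        with pytest.raises(ConvergenceError, match="degenerate"):
            fit_fixed(df, ModelSpec(covariates=("log_tube_load",)))

    def test_rank_deficiency_names_covariate(self):
        # equal-dose pairs only: the log-tube-load column is identically zero
        df = make_records(
            [[f"P{i}", "O1", 1, 98.0, "FBP", 98.0, "IR3", (i % 3) - 1, 0]
             for i in range(12)]
        )
        with pytest.raises(ConvergenceError, match="log_tube_load"):
            fit_fixed(df, ModelSpec())

    def test_orientation_invariance(self, small_study):
        """Mirroring every pair and negating scores leaves coefficients

        unchanged and reverses the thresholds' signs."""
        spec = ModelSpec(random_effects=())
        fit = fit_fixed(small_study, spec, criterion=1)
        flipped = small_study.rename(
            columns={"left_mAs": "right_mAs", "right_mAs": "left_mAs",
                     "left_algo": "right_algo", "right_algo": "left_algo"}
        )
        flipped["score"] = -flipped["score"]
        fit2 = fit_fixed(flipped, spec, criterion=1)
        for name in fit.fixed_names:
            assert fit2.coef[name] == pytest.approx(fit.coef[name], abs=5e-6)
        assert fit2.thresholds == pytest.approx(
            -fit.thresholds[::-1], abs=5e-6
        )

    def test_predicted_probabilities_are_proper(self, small_study):
        est = CumulativeLogitVGR(random_effects=()).fit(
            small_study[small_study["criterion"] == 1]
        )
        proba = est.predict_proba(small_study[small_study["criterion"] == 1])
        assert np.all(proba >= 0)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        cum = np.cumsum(proba, axis=1)
        assert np.all(np.diff(cum, axis=1) >= -1e-12)

    def test_multi_criteria_table_requires_selection(self, default_study):
        with pytest.raises(ValueError, match="criterion"):
            fit_fixed(default_study, ModelSpec(random_effects=()))


class TestTubeLoadEffectByAlgorithm:
    def test_positive_dose_effect_detected(self, default_study):
        fit = tube_load_effect_by_algorithm(
            default_study, "FBP", (42.0, 98.0), criterion=1
        )
        assert fit.a > 0
        assert fit.p_values["log_tube_load"] < 0.05

    def test_null_dose_effect_within_noise(self):
        cfg = SimulationConfig(
            n_patients=40, true_a=0.0, true_b={"IR3": 0.0, "IR5": 0.0},
            sigma_patient=0.0, sigma_observer=0.0, n_replicates=0, seed=33,
            criteria=(1,),
        )
        fit = tube_load_effect_by_algorithm(
            simulate_study(cfg), "IR3", (42.0, 98.0)
        )
        assert abs(fit.a) < 3 * fit.se["log_tube_load"]

    def test_absent_subset_rejected(self, default_study):
        with pytest.raises(ValueError, match="no records"):
            tube_load_effect_by_algorithm(
                default_study, "XX", (42.0, 98.0), criterion=1
            )
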