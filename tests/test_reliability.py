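"""Weighted kappa, observer-reliability summaries and score distributions."""

import numpy as np
import pandas as pd
import pytest

from vgrlab import (
    ImageCondition,
    SimulationConfig,
    interobserver_summary,
    intraobserver_summary,
    score_distribution,
    score_distribution_table,
    simulate_study,
    weighted_kappa,
)


def brute_force_weighted_kappa(x, y, categories, weights):
    """Independent double-loop evaluation of the weighted-kappa formula."""
    n = len(x)
    K = len(categories)
    idx = {c: i for i, c in enumerate(categories)}
    obs = [[0.0] * K for _ in range(K)]
    for a, b in zip(x, y):
        obs[idx[a]][idx[b]] += 1.0 / n
    row = [sum(obs[i]) for i in range(K)]
    col = [sum(obs[i][j] for i in range(K)) for j in range(K)]
    num = den = 0.0
    for i in range(K):
        for j in range(K):
            if weights == "linear":
                w = abs(i - j) / (K - 1)
            else:
                w = ((i - j) / (K - 1)) ** 2
            num += w * obs[i][j]
            den += w * row[i] * col[j]
    return 1.0 - num / den


class TestWeightedKappa:
    def test_perfect_agreement(self):
        x = [-2, -1, 0, 1, 2, 0, 1, -1]
        res = weighted_kappa(x, x)
        assert res.kappa_w == pytest.approx(1.0, abs=1e-12)
        assert res.percent_agreement == 100.0

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_matches_brute_force_on_small_table(self, weights):
        # a deliberately unbalanced 3-category fixture
        x = [0, 0, 1, 1, 1, 2, 2, 0, 1, 2, 2, 2, 0, 1, 1, 2, 0, 0, 2, 1]
        y = [0, 1, 1, 0, 1, 2, 1, 0, 2, 2, 2, 1, 0, 1, 0, 2, 1, 0, 2, 2]
        res = weighted_kappa(x, y, weights=weights, categories=(0, 1, 2))
        oracle = brute_force_weighted_kappa(x, y, (0, 1, 2), weights)
        assert res.kappa_w == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_matches_sklearn_cohen_kappa(self, weights):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        x = rng.integers(-2, 3, size=300)
        y = np.clip(x + rng.integers(-1, 2, size=300), -2, 2)
        res = weighted_kappa(x, y, weights=weights)
        ref = cohen_kappa_score(
            x, y, labels=[-2, -1, 0, 1, 2], weights=weights
        )
        assert res.kappa_w == pytest.approx(ref, abs=1e-12)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(12)
        x = rng.integers(-2, 3, size=4000)
        y = rng.integers(-2, 3, size=4000)
        res = weighted_kappa(x, y)
        assert abs(res.kappa_w) < 3 * res.se

    def test_both_weightings_agree_in_sign(self):
        rng = np.random.default_rng(4)
        x = rng.integers(-2, 3, size=500)
        y = np.clip(x + rng.integers(-1, 2, size=500), -2, 2)
        lin = weighted_kappa(x, y, weights="linear")
        quad = weighted_kappa(x, y, weights="quadratic")
        assert np.sign(lin.kappa_w) == np.sign(quad.kappa_w)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            weighted_kappa([0, 1], [0, 1, 2])

    def test_single_category_undefined(self):
        res = weighted_kappa([0] * 10, [0] * 10)
        assert not res.defined
        assert "undefined" in res.note
        assert res.percent_agreement == 100.0

    def test_agreement_invariant_under_joint_relabelling(self):
        rng = np.random.default_rng(8)
        x = rng.integers(-2, 3, size=200)
        y = rng.integers(-2, 3, size=200)
        base = weighted_kappa(x, y)
        # order-preserving relabelling -2..2 -> 1..5
        shifted = weighted_kappa(x + 3, y + 3, categories=(1, 2, 3, 4, 5))
        assert shifted.percent_agreement == base.percent_agreement
        assert shifted.kappa_w == pytest.approx(base.kappa_w, abs=1e-12)


class TestInterObserver:
    def test_ten_pairs_for_five_observers(self, default_study):
        summary = interobserver_summary(default_study)
        assert len(summary.results) == 10
        assert not summary.skipped
        klo, khi = summary.kappa_range
        assert -1 <= klo <= khi <= 1

    def test_uses_originals_only(self, default_study):
        originals = default_study[default_study["replicate_index"] == 0]
        s_all = interobserver_summary(default_study)
        s_orig = interobserver_summary(originals)
        for a, b in zip(s_all.results, s_orig.results):
            assert a.kappa_w == pytest.approx(b.kappa_w, abs=1e-12)
            assert a.n == b.n

    def test_shared_signal_drives_agreement(self):
        """Observers agree beyond chance only through components they share:

        strong fixed effects raise the mean inter-observer kappa relative to
        a null simulation, and shared patient heterogeneity raises it
        further."""
        def mean_kappa(true_a, true_b, sigma_patient):
            cfg = SimulationConfig(
                n_patients=30, criteria=(1,), true_a=true_a, true_b=true_b,
                sigma_patient=sigma_patient, sigma_observer=0.5,
                n_replicates=0, seed=19,
            )
            s = interobserver_summary(simulate_study(cfg))
            return float(np.mean([r.kappa_w for r in s.results]))

        null_b = {"IR3": 0.0, "IR5": 0.0}
        strong_b = {"IR3": 1.0, "IR5": 1.7}
        k_null = mean_kappa(0.0, null_b, 0.0)
        k_signal = mean_kappa(2.3, strong_b, 0.0)
        k_shared = mean_kappa(2.3, strong_b, 1.5)
        assert k_signal > k_null
        assert k_shared > k_signal

    def test_disjoint_observers_skipped(self):
        cfg = SimulationConfig(
            n_patients=8, observer_ids=("A", "B"), criteria=(1,),
            n_replicates=0, seed=5,
        )
        df = simulate_study(cfg)
        half = df["patient_id"] <= "P004"
        disjoint = pd.concat([
            df[(df["observer_id"] == "A") & half],
            df[(df["observer_id"] == "B") & ~half],
        ])
        summary = interobserver_summary(disjoint)
        assert not summary.results
        assert any("no shared" in s for s in summary.skipped)


class TestIntraObserver:
    def test_copied_replicates_give_kappa_one(self, small_study):
        df = small_study[small_study["replicate_index"] == 0]
        reps = df.groupby("observer_id", group_keys=False).head(30).copy()
        reps["replicate_index"] = 1
        summary = intraobserver_summary(pd.concat([df, reps]))
        assert summary.results
        for r in summary.results:
            assert r.kappa_w == pytest.approx(1.0, abs=1e-12)
            assert r.percent_agreement == 100.0

    def test_default_replication_count(self, default_study):
        summary = intraobserver_summary(default_study)
        assert len(summary.results) == 5  # one per observer
        # 5 replicated hangings x 6 criteria paired ratings per observer
        assert all(r.n == 30 for r in summary.results)

    def test_no_replicates_notice(self, default_study):
        originals = default_study[default_study["replicate_index"] == 0]
        summary = intraobserver_summary(originals)
        assert not summary.results
        assert any("no replicated" in s for s in summary.skipped)


class TestScoreDistribution:
    def test_sign_flip_definition(self):
        cond = ImageCondition(98.0, "IR3")
        df = pd.DataFrame({
            "patient_id": ["P1", "P2"],
            "observer_id": ["O1", "O1"],
            "criterion": [1, 1],
            "left_mAs": [98.0, 98.0],
            "left_algo": ["FBP", "IR3"],
            "right_mAs": [98.0, 98.0],
            "right_algo": ["IR3", "FBP"],
            "score": [2, -2],  # IR3 wins on both presentations
            "replicate_index": [0, 0],
        })
        dist = score_distribution(df, cond)
        assert dist.percentages[2] == 100.0
        assert dist.n == 2

    def test_percentages_sum_to_100(self, default_study):
        dist = score_distribution(default_study, ImageCondition(42.0, "FBP"))
        assert sum(dist.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_absent_condition_rejected(self, default_study):
        with pytest.raises(ValueError, match="absent"):
            score_distribution(default_study, ImageCondition(70.0, "FBP"))

    def test_null_simulation_symmetric(self):
        cfg = SimulationConfig(
            n_patients=60, true_a=0.0, true_b={"IR3": 0.0, "IR5": 0.0},
            sigma_patient=0.0, sigma_observer=0.0, n_replicates=0, seed=23,
        )
        dist = score_distribution(simulate_study(cfg), ImageCondition(98.0, "FBP"))
        for s in (1, 2):
            diff = abs(dist.percentages[s] - dist.percentages[-s])
            mc_sd = 100.0 * np.sqrt(2 * 0.25 / dist.n)
            assert diff < 3 * mc_sd

    def test_every_record_counted_twice_overall(self, default_design, default_study):
        table = score_distribution_table(default_study, default_design.conditions)
        assert table["n"].sum() == 2 * len(default_study)
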