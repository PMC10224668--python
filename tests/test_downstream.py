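"""Outcome labeling, scenario construction, and the utility suite."""

import numpy as np
import pytest

import mtsgan as M
from mtsgan.data import SplitPlan
from mtsgan.downstream import (OUTCOME_CLASSES, classify_windows,
                               predict_proba, run_utility_suite)

from conftest import rand_batch


@pytest.fixture
def rng():
    return np.random.default_rng(51)


def _batch_with_channel(channel: np.ndarray, rng) -> M.MixedSeriesBatch:
    """24-step batch whose single intervention channel is given (N x 24)."""
    n = channel.shape[0]
    return M.MixedSeriesBatch(
        x_cont=rng.normal(size=(n, 24, 2)), x_disc=channel[:, :, None],
        feature_names_cont=["v0", "v1"], feature_names_disc=["d:vent"])


class TestLabelOutcomes:
    def test_always_on_and_always_off(self, rng):
        chan = np.vstack([np.ones((3, 24)), np.zeros((3, 24))])
        batch = _batch_with_channel(chan, rng)
        lab = M.label_outcomes(batch, "d:vent")
        assert [OUTCOME_CLASSES[i] for i in lab[:3]] == ["Stay on"] * 3
        assert [OUTCOME_CLASSES[i] for i in lab[3:]] == ["Stay off"] * 3

    def test_exhaustive_partition_of_all_prediction_windows(self):
        """Every binary window of length 12 lands in exactly one class."""
        W = 12
        patterns = ((np.arange(2 ** W)[:, None] >> np.arange(W)) & 1).astype(float)
        lab = classify_windows(patterns)
        assert set(np.unique(lab)) <= {0, 1, 2, 3}
        # each pattern got exactly one class (classify is total): recompute
        # membership by definition and compare
        begins_on = patterns[:, 0] == 1
        all_on = patterns.min(axis=1) == 1
        all_off = patterns.max(axis=1) == 0
        expect = np.where(begins_on & all_on, 0,
                          np.where(begins_on, 2, np.where(all_off, 3, 1)))
        np.testing.assert_array_equal(lab, expect)
        counts = np.bincount(lab, minlength=4)
        assert counts.sum() == 2 ** W
        # begins-on patterns split into Stay on / Switch off
        assert counts[0] + counts[2] == 2 ** (W - 1)

    def test_unknown_channel_rejected(self, rng):
        batch = _batch_with_channel(np.zeros((2, 24)), rng)
        with pytest.raises(ValueError, match="unknown"):
            M.label_outcomes(batch, "d:nope")


def _plan(n=40, n_b=6, rng=None, T=24):
    rng = rng or np.random.default_rng(0)
    idx = np.arange(n)
    synth = rand_batch(rng, n=n_b, T=T)
    return SplitPlan(train=idx[: int(0.7 * n)],
                     subtrain=idx[int(0.7 * n): int(0.85 * n)],
                     subtest=idx[int(0.85 * n):], synthetic=synth)


class TestBuildScenario:
    def test_tsrtr_alpha_train_size(self, rng):
        plan = _plan(rng=rng, n_b=100)
        sc = M.AugmentationScenario("TSRTR_alpha", 0.5)
        train, test = M.build_scenario(plan, sc, seed=1)
        assert len(train) == len(plan.subtrain) + 50

    def test_tstr_contains_no_real_records(self, rng):
        plan = _plan(rng=rng)
        train, _ = M.build_scenario(plan, M.AugmentationScenario("TSTR"), seed=1)
        assert all(kind == "synth" for kind, _ in train)

    def test_seeded_subsample_reproducible(self, rng):
        plan = _plan(rng=rng, n_b=20)
        sc = M.AugmentationScenario("TSRTR_beta", 0.5)
        t1, _ = M.build_scenario(plan, sc, seed=9)
        t2, _ = M.build_scenario(plan, sc, seed=9)
        assert t1 == t2

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            M.AugmentationScenario("TSRTR_alpha", 1.5)
        with pytest.raises(ValueError, match="ratio"):
            M.AugmentationScenario("TRTR", 0.5)


class TestPredictor:
    def test_separable_windows_reach_high_accuracy(self, rng):
        n = 40
        y = rng.integers(0, 2, size=n) * 3     # classes 0 and 3
        x = np.zeros((n, 12, 2))
        x[y == 0] += 2.0
        x[y == 3] -= 2.0
        x += rng.normal(scale=0.1, size=x.shape)
        clf = M.train_predictor(x, y, hidden=8, epochs=30, seed=0)
        pred = predict_proba(clf, x).argmax(axis=1)
        assert (pred == y).mean() == 1.0

    def test_probabilities_sum_to_one_and_deterministic(self, rng):
        y = np.array([0, 1, 2, 3] * 5)
        x = rng.normal(size=(20, 12, 2))
        c1 = M.train_predictor(x, y, hidden=8, epochs=2, seed=3)
        c2 = M.train_predictor(x, y, hidden=8, epochs=2, seed=3)
        p1, p2 = predict_proba(c1, x), predict_proba(c2, x)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single-class"):
            M.train_predictor(rng.normal(size=(8, 12, 2)), np.zeros(8, int))


class TestMacroAUROC:
    def test_uninformative_scores_give_half(self):
        scores = np.full((10, 4), 0.25)
        labels = np.array([0, 1] * 5)
        assert M.macro_auroc(scores, labels) == pytest.approx(0.5)

    def test_perfect_ranking_gives_one(self):
        scores = np.zeros((4, 4))
        scores[:2, 0] = 1.0
        scores[2:, 1] = 1.0
        labels = np.array([0, 0, 1, 1])
        assert M.macro_auroc(scores, labels) == 1.0

    def test_matches_bruteforce_pairwise_statistic(self, rng):
        n = 20
        labels = rng.integers(0, 2, size=n)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, size=n)
        scores = rng.uniform(size=(n, 4))

        def auc_one_vs_rest(c):
            pos = scores[labels == c, c]
            neg = scores[labels != c, c]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            return wins / (len(pos) * len(neg))

        expect = np.mean([auc_one_vs_rest(c) for c in np.unique(labels)])
        assert M.macro_auroc(scores, labels) == pytest.approx(expect, abs=1e-12)

    def test_single_class_test_labels_rejected(self):
        with pytest.raises(ValueError):
            M.macro_auroc(np.zeros((4, 4)), np.zeros(4, int))


class TestUtilitySuite:
    @pytest.fixture(scope="class")
    def coupled_real(self):
        """Cohort where vitals genuinely predict the intervention course."""
        return M.simulate_batch(M.SimulatorConfig(n_patients=160, seed=12))

    def test_cheat_generator_matches_trtr_and_noise_degrades(self, coupled_real):
        real = coupled_real
        plan = M.split_dataset(real, seed=0)
        kw = {"epochs": 25, "hidden": 16}
        # cheat generator: B is an exact copy of A'_Tr
        plan.synthetic = real.subset(plan.subtrain)
        rows = run_utility_suite(
            real, plan, "d:intervention_0",
            [M.AugmentationScenario("TRTR"), M.AugmentationScenario("TSTR")],
            repeats=3, seed=0, predictor_kwargs=kw)
        by = {r["scenario"]: r for r in rows}
        assert abs(by["TSTR"]["auroc_mean"] - by["TRTR"]["auroc_mean"]) < 0.1
        # label-destroying generator: independent noise B
        rng = np.random.default_rng(1)
        noise_b = M.MixedSeriesBatch(
            x_cont=rng.normal(size=(len(plan.subtrain), 24, 5)),
            x_disc=(rng.uniform(size=(len(plan.subtrain), 24, 2)) < 0.5
                    ).astype(float),
            feature_names_cont=real.feature_names_cont,
            feature_names_disc=real.feature_names_disc)
        plan_noise = M.SplitPlan(train=plan.train, subtrain=plan.subtrain,
                                 subtest=plan.subtest, synthetic=noise_b)
        rows_n = run_utility_suite(
            real, plan_noise, "d:intervention_0",
            [M.AugmentationScenario("TRTR"), M.AugmentationScenario("TSTR")],
            repeats=3, seed=0, predictor_kwargs=kw)
        by_n = {r["scenario"]: r for r in rows_n}
        assert by_n["TSTR"]["auroc_mean"] < by_n["TRTR"]["auroc_mean"]

    def test_report_schema_and_test_set_isolation(self, coupled_real):
        real = coupled_real
        plan = M.split_dataset(real, seed=3)
        plan.synthetic = real.subset(plan.subtrain)
        scenarios = [M.AugmentationScenario("TRTR"),
                     M.AugmentationScenario("TSRTR_alpha", 0.25)]
        rows = run_utility_suite(real, plan, "d:intervention_0", scenarios,
                                 repeats=2, seed=1,
                                 predictor_kwargs={"epochs": 3, "hidden": 8})
        assert len(rows) == 2
        for r in rows:
            assert {"scenario", "ratio", "channel", "auroc_mean",
                    "auroc_sd", "n_repeats"} <= set(r)
            assert 0.0 <= r["auroc_mean"] <= 1.0
        assert rows[1]["p_vs_trtr"] is not None
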