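"""Oracles for the fidelity/correlation battery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import mtsgan as M
from mtsgan.evaluation import (KernelConfig, _sample_acf, coracc_mu_abs,
                               dimension_wise_probability, ppc_heatmap,
                               trajectory_summary)

from conftest import rand_batch


@pytest.fixture
def rng():
    return np.random.default_rng(31)


def _mmd_bruteforce(x, y, sigmas):
    """Naive triple-loop unbiased MMD^2 (independent oracle)."""
    def k(a, b):
        return sum(np.exp(-np.linalg.norm(a - b, "fro") ** 2 / s ** 2)
                   for s in sigmas)
    n, m = len(x), len(y)
    t1 = sum(k(x[i], x[j]) for i in range(n) for j in range(n) if i != j)
    t2 = sum(k(x[i], y[j]) for i in range(n) for j in range(m))
    t3 = sum(k(y[i], y[j]) for i in range(m) for j in range(m) if i != j)
    return t1 / (n * (n - 1)) - 2 * t2 / (n * m) + t3 / (m * (m - 1))


class TestMMD:
    def test_matches_bruteforce_triple_loop(self, rng):
        x = rng.normal(size=(5, 4, 3))
        y = rng.normal(size=(5, 4, 3)) + 0.3
        sigmas = [0.5, 1.0, 2.0]
        got = M.mmd(x, y, KernelConfig(bandwidths=sigmas))
        assert got == pytest.approx(_mmd_bruteforce(x, y, sigmas), abs=1e-10)

    def test_symmetry(self, rng):
        x = rng.normal(size=(6, 4, 2))
        y = rng.normal(size=(7, 4, 2))
        assert M.mmd(x, y) == pytest.approx(M.mmd(y, x), abs=1e-12)

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            M.mmd(rng.normal(size=(1, 4, 2)), rng.normal(size=(5, 4, 2)))

    def test_null_mean_near_zero(self):
        """Same-distribution draws: the unbiased estimator averages to ~0."""
        vals = []
        for rep in range(20):
            cfg_a = M.SimulatorConfig(n_patients=200, seed=1000 + 2 * rep)
            cfg_b = M.SimulatorConfig(n_patients=200, seed=1001 + 2 * rep)
            vals.append(M.mmd(M.simulate_batch(cfg_a).x_cont,
                              M.simulate_batch(cfg_b).x_cont))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-4

    def test_shifted_distribution_detected(self, rng):
        x = rng.normal(size=(100, 6, 2))
        x2 = rng.normal(size=(100, 6, 2))
        y = rng.normal(size=(100, 6, 2)) + 1.0
        assert M.mmd(x, y) > 0.3
        assert abs(M.mmd(x, x2)) < 0.05


class TestDimensionWiseProbability:
    def test_identity(self, rng):
        d = (rng.uniform(size=(50, 6, 3)) < 0.4).astype(float)
        res = dimension_wise_probability(d, d)
        assert res.rmse == 0.0
        assert res.cc == pytest.approx(1.0)

    def test_complement_anticorrelated(self, rng):
        d = (rng.uniform(size=(200, 6, 3)) < rng.uniform(0.2, 0.8, size=(1, 6, 3))
             ).astype(float)
        res = dimension_wise_probability(d, 1.0 - d)
        assert res.cc == pytest.approx(-1.0)

    def test_hand_rmse(self):
        # rates 0.2/0.8 vs 0.3/0.7 on every (k,t) cell -> RMSE = 0.1
        real = np.zeros((10, 2, 2))
        synth = np.zeros((10, 2, 2))
        real[:2, :, 0] = 1     # rate 0.2
        real[:8, :, 1] = 1     # rate 0.8
        synth[:3, :, 0] = 1    # rate 0.3
        synth[:7, :, 1] = 1    # rate 0.7
        res = dimension_wise_probability(real, synth)
        assert res.rmse == pytest.approx(0.1, abs=1e-12)

    def test_constant_probability_flags_cc(self):
        real = np.zeros((10, 3, 2))
        with pytest.warns(UserWarning, match="constant"):
            res = dimension_wise_probability(real, real)
        assert res.cc is None
        assert res.rmse == 0.0


class TestDiscriminativeScore:
    def test_separable_case_near_one(self, rng):
        batch = M.simulate_batch(M.SimulatorConfig(n_patients=100, seed=3))
        noise = M.MixedSeriesBatch(
            x_cont=rng.uniform(size=(100, 24, 5)) * 20 - 10,
            x_disc=(rng.uniform(size=(100, 24, 2)) < 0.5).astype(float),
            feature_names_cont=batch.feature_names_cont,
            feature_names_disc=batch.feature_names_disc)
        acc, _ = M.discriminative_score(batch, noise, epochs=30, seed=0)
        assert acc > 0.9

    def test_deterministic_given_seed(self, rng):
        a = rand_batch(rng, n=24, T=6)
        b = rand_batch(rng, n=24, T=6)
        s1 = M.discriminative_score(a, b, epochs=2, seed=4)
        s2 = M.discriminative_score(a, b, epochs=2, seed=4)
        assert s1 == s2

    def test_unequal_sizes_rejected(self, rng):
        a, b = rand_batch(rng, n=24), rand_batch(rng, n=23)
        with pytest.raises(ValueError, match="equal size"):
            M.discriminative_score(a, b)


class TestTrajectorySummary:
    def test_constant_feature_zero_sd(self):
        batch = M.MixedSeriesBatch(
            x_cont=np.full((5, 4, 1), 3.0), x_disc=np.zeros((5, 4, 1)),
            feature_names_cont=["a"], feature_names_disc=["d:b"])
        s = trajectory_summary(batch)
        np.testing.assert_array_equal(s["cont_sd"], 0.0)

    def test_single_record_sd_flagged(self, rng):
        batch = rand_batch(rng, n=1)
        s = trajectory_summary(batch)
        assert not s["sd_defined"]
        assert np.isnan(s["cont_sd"]).all()

    def test_mean_curve_matches_simulator_moments(self):
        cfg = M.SimulatorConfig(n_patients=3000, seed=8)
        batch = M.simulate_batch(cfg)
        s = trajectory_summary(batch)
        mom = M.theoretical_moments(cfg)
        se = np.sqrt(mom.var_cont) / np.sqrt(cfg.n_patients)
        assert np.all(np.abs(s["cont_mean"] - mom.mean_cont) < 4 * se)


class TestPPCHeatmap:
    def test_diagonal_and_symmetry(self, rng):
        batch = rand_batch(rng, n=40)
        corr, names = ppc_heatmap(batch, stride_hours=2)
        np.testing.assert_array_equal(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        assert len(names) == corr.shape[0]

    def test_cross_type_sign_matches_loading_product(self):
        """vital_0 and intervention_0 load positively on the same latent dim
        -> their same-time correlation is positive."""
        batch = M.simulate_batch(M.SimulatorConfig(n_patients=2000, seed=9))
        corr, names = ppc_heatmap(batch, stride_hours=3)
        i = names.index("vital_0@12h")
        j = names.index("d:intervention_0@12h")
        assert corr[i, j] > 0.05

    def test_zero_variance_column_flagged(self):
        batch = M.MixedSeriesBatch(
            x_cont=np.random.default_rng(0).normal(size=(20, 4, 1)),
            x_disc=np.zeros((20, 4, 1)),
            feature_names_cont=["a"], feature_names_disc=["d:b"])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, _ = ppc_heatmap(batch, stride_hours=2)
        assert np.all(corr[-1, :-1] == 0)


class TestCorAccMuAbs:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.float64, (6, 6), elements=st.floats(-1, 1)))
    def test_identity_for_any_heatmap(self, a):
        np.fill_diagonal(a, 1.0)
        coracc, mu = coracc_mu_abs(a, a.copy())
        assert coracc == 1.0
        assert mu == 0.0

    def test_opposite_extreme_bins_score_zero(self):
        a = np.full((4, 4), 0.7)
        np.fill_diagonal(a, 1.0)
        b = -a
        np.fill_diagonal(b, 1.0)
        coracc, _ = coracc_mu_abs(a, b)
        assert coracc == 0.0

    def test_hand_bin_assignment(self):
        a = np.array([[1.0, 0.2], [0.4, 1.0]])
        b = np.array([[1.0, 0.25], [0.55, 1.0]])
        coracc, mu = coracc_mu_abs(a, b)
        assert coracc == 0.5            # 0.2/0.25 same bin; 0.4/0.55 differ
        assert mu == pytest.approx((0.05 + 0.15) / 2)


class TestACF:
    def test_lag0_is_one_and_self_rmse_zero(self, rng):
        batch = rand_batch(rng, n=20, T=10)
        res = M.acf_compare(batch, batch, max_lag=5)
        np.testing.assert_allclose(res.acf_real[:, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(res.rmse, 0.0, atol=1e-15)

    def test_constant_series_excluded_with_count(self, rng):
        x = rng.normal(size=(10, 8, 1))
        x[3] = 5.0                       # one constant patient series
        batch = M.MixedSeriesBatch(
            x_cont=x, x_disc=(rng.uniform(size=(10, 8, 1)) < 0.5).astype(float),
            feature_names_cont=["a"], feature_names_disc=["d:b"])
        res = M.acf_compare(batch, batch, max_lag=3)
        assert res.n_excluded_real >= 1

    def test_ar1_signal_decay_ordering(self):
        """Persistent simulated vitals decay slower than white noise."""
        strong = M.simulate_batch(M.SimulatorConfig(
            n_patients=500, seed=10, noise_sd_cont=1e-3))
        white = M.simulate_batch(M.SimulatorConfig(
            n_patients=500, seed=11, ar_coef=0.0, noise_sd_cont=1e-3))
        rs = M.acf_compare(strong, strong, max_lag=1)
        rw = M.acf_compare(white, white, max_lag=1)
        assert np.all(rs.acf_real[:5, 1] > rw.acf_real[:5, 1] + 0.3)

    def test_max_lag_bound(self, rng):
        batch = rand_batch(rng, T=6)
        with pytest.raises(ValueError):
            M.acf_compare(batch, batch, max_lag=6)
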