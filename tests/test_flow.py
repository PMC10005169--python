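"""Coupling flow: likelihoods, gradients, training, WAIC, AU-ROC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msimon.flow import (
    CouplingFlow,
    FlowEnsemble,
    FlowTrainingError,
    TrainConfig,
    evaluate_auroc,
    ischemia_index,
    log_likelihood,
    minmax_normalize,
    roi_waic,
    train_flow,
    waic,
)

N16_LOGP0 = -8 * np.log(2 * np.pi)  # identity flow at the origin, dim 16


class _ScalingFlow:
    """Minimal 1-D flow z = x / 2 used as an analytic reference."""

    def forward(self, x):
        x = np.atleast_2d(x)
        return x / 2.0, np.full(x.shape[0], -np.log(2.0))


class TestLogLikelihood:
    def test_identity_flow_at_origin(self):
        flow = CouplingFlow(dim=16, n_blocks=8, hidden=64, seed=0)
        assert log_likelihood(flow, np.zeros(16))[0] == pytest.approx(
            N16_LOGP0, abs=1e-6
        )

    def test_identity_flow_general_point(self, rng):
        flow = CouplingFlow(dim=16, seed=1)
        x = rng.normal(0, 1, (20, 16))
        expected = -0.5 * (x**2).sum(axis=1) + N16_LOGP0
        assert np.allclose(log_likelihood(flow, x), expected, atol=1e-9)

    def test_scaling_flow_matches_change_of_variables(self):
        lp = log_likelihood(_ScalingFlow(), np.zeros((1, 1)))[0]
        assert lp == pytest.approx(-0.5 * np.log(2 * np.pi) - np.log(2.0), abs=1e-5)
        assert lp == pytest.approx(-1.61209, abs=1e-5)

    def test_non_finite_input_rejected(self):
        flow = CouplingFlow(dim=16, seed=0)
        with pytest.raises(ValueError):
            log_likelihood(flow, np.full(16, np.nan))


class TestFlowMechanics:
    def test_invertibility_on_random_batches(self, rng):
        flow = CouplingFlow(dim=16, n_blocks=8, hidden=64, seed=2)
        X = rng.normal(0, 2, (1000, 16))
        flow2, _ = train_flow(
            flow, X, TrainConfig(epochs=5, batch_size=256, seed=2)
        )
        z, _ = flow2.forward(X)
        assert np.abs(flow2.inverse(z) - X).max() < 1e-5

    def test_gradients_match_finite_differences(self, rng):
        flow = CouplingFlow(dim=6, n_blocks=3, hidden=8, seed=3)
        for p in flow.params:  # randomise the zero-initialised heads
            p["W3"] = rng.normal(0, 0.1, p["W3"].shape)
            p["b3"] = rng.normal(0, 0.1, p["b3"].shape)
        U = rng.normal(0, 1, (7, 6))
        _, grads = flow.nll_and_grads(U)
        eps = 1e-6
        r = np.random.default_rng(0)
        for blk in range(flow.n_blocks):
            for key, g in grads[blk].items():
                flat = flow.params[blk][key].ravel()
                for idx in r.choice(flat.size, size=min(3, flat.size), replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up, _ = flow.nll_and_grads(U)
                    flat[idx] = orig - eps
                    down, _ = flow.nll_and_grads(U)
                    flat[idx] = orig
                    assert g.ravel()[idx] == pytest.approx(
                        (up - down) / (2 * eps), abs=1e-6, rel=1e-4
                    )

    def test_logdet_matches_numerical_jacobian(self, rng):
        flow = CouplingFlow(dim=4, n_blocks=3, hidden=8, seed=4)
        X = rng.normal(0, 1, (200, 4))
        flow, _ = train_flow(flow, X, TrainConfig(epochs=10, batch_size=64, seed=4))
        eps = 1e-6
        for x in rng.normal(0, 1, (10, 4)):
            _, logdet = flow.forward(x)
            J = np.empty((4, 4))
            for j in range(4):
                xp, xm = x.copy(), x.copy()
                xp[j] += eps
                xm[j] -= eps
                zp, _ = flow.forward(xp)
                zm, _ = flow.forward(xm)
                J[:, j] = (zp[0] - zm[0]) / (2 * eps)
            assert logdet[0] == pytest.approx(
                np.log(abs(np.linalg.det(J))), abs=1e-3
            )


@pytest.fixture(scope="module")
def gaussian_flow():
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (20_000, 16))
    flow, trace = train_flow(
        CouplingFlow(dim=16, n_blocks=8, hidden=64, seed=5),
        X,
        TrainConfig(epochs=10, batch_size=512, seed=5),
    )
    return flow, trace


@pytest.fixture(scope="module")
def trained_ensemble():
    rng = np.random.default_rng(10)
    X = rng.normal(0, 1, (4000, 16))
    ens = FlowEnsemble.initialize(dim=16, n_members=3, base_seed=10)
    ens.train(X, TrainConfig(epochs=8, batch_size=512, seed=10))
    return ens


class TestTraining:

    def test_heldout_likelihood_near_gaussian_entropy(self, gaussian_flow):
        flow, _ = gaussian_flow
        X = np.random.default_rng(123).normal(0, 1, (5000, 16))
        mean_lp = log_likelihood(flow, X).mean()
        assert mean_lp == pytest.approx(-8 * (1 + np.log(2 * np.pi)), abs=0.5)

    def test_loss_decreases(self, gaussian_flow):
        _, trace = gaussian_flow
        assert trace[-1] < trace[0]

    def test_same_seed_reproduces_final_loss(self, rng):
        X = rng.uniform(0, 1, (500, 16))
        cfg = TrainConfig(epochs=3, batch_size=128, seed=9)
        _, t1 = train_flow(CouplingFlow(16, 4, 32, seed=9), X, cfg)
        _, t2 = train_flow(CouplingFlow(16, 4, 32, seed=9), X, cfg)
        assert np.array_equal(t1, t2)

    def test_diverged_loss_raises_with_advice(self, rng):
        X = rng.normal(0, 1, (300, 16))
        flow = CouplingFlow(16, 4, 16, seed=1)
        flow.params[0]["W1"][0, 0] = np.nan  # simulate a diverged update
        with pytest.raises(FlowTrainingError, match="learning rate"):
            train_flow(flow, X, TrainConfig(epochs=1, seed=1))

    def test_too_few_spectra_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            train_flow(CouplingFlow(16), rng.normal(size=(50, 16)), TrainConfig())


class TestWaic:
    def test_degenerate_ensemble_gives_negative_logp(self):
        assert waic(np.array([-5.0, -5.0, -5.0])) == pytest.approx(5.0)

    def test_two_member_population_variance_example(self):
        # members (-1, -3): Var = 1, mean = -2, WAIC = 1 - (-2) = 3
        assert waic(np.array([-1.0, -3.0])) == pytest.approx(3.0)

    @settings(max_examples=30, deadline=None)
    @given(c=st.floats(-50, 50), seed=st.integers(0, 100))
    def test_constant_shift_property(self, c, seed):
        lp = np.random.default_rng(seed).normal(-10, 2, (5, 7))
        assert np.allclose(waic(lp + c), waic(lp) - c, atol=1e-9)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError, match="2 ensemble members"):
            waic(np.array([[-1.0, -2.0]]))

    def test_roi_aggregation_is_median(self):
        assert roi_waic(np.full((5, 5), 3.3)) == pytest.approx(3.3)
        assert roi_waic(np.array([1.0, 2.0, 100.0])) == pytest.approx(2.0)
        rng = np.random.default_rng(2)
        m = rng.normal(0, 1, (5, 5))
        assert roi_waic(m) == np.median(np.sort(m.ravel()))

    def test_frame_index_is_roi_mean_with_fallback(self):
        assert ischemia_index(1.0, 3.0) == pytest.approx(2.0)
        assert ischemia_index(2.5, 2.5) == pytest.approx(2.5)
        assert ischemia_index(4.2) == pytest.approx(4.2)  # single-ROI fallback


class TestMinMax:
    def test_example_and_order_preservation(self):
        out = minmax_normalize(np.array([2.0, 4.0, 6.0]))
        assert np.allclose(out, [0.0, 0.5, 1.0])
        rng = np.random.default_rng(1)
        v = rng.normal(0, 3, 50)
        out = minmax_normalize(v)
        assert np.array_equal(np.argsort(out), np.argsort(v))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_auroc_invariant_under_minmax(self, rng):
        neg = rng.normal(0, 1, 30)
        pos = rng.normal(1, 1, 30)
        pooled = np.concatenate([neg, pos])
        normed = minmax_normalize(pooled)
        assert evaluate_auroc(neg, pos) == pytest.approx(
            evaluate_auroc(normed[:30], normed[30:])
        )

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize(np.ones(5))


class TestAuroc:
    def test_perfect_separation(self):
        assert evaluate_auroc([0.1, 0.2], [0.3, 0.4]) == 1.0

    def test_identical_groups(self):
        assert evaluate_auroc([0.5, 0.7], [0.5, 0.7]) == 0.5

    def test_tie_counting_example(self):
        # pairs: (.1,.3)+, (.1,.5)+, (.3,.3) tie, (.3,.5)+ -> 3.5/4
        assert evaluate_auroc([0.1, 0.3], [0.3, 0.5]) == pytest.approx(0.875)

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n_neg=st.integers(1, 40),
        n_pos=st.integers(1, 40),
    )
    def test_matches_exhaustive_pair_counting(self, seed, n_neg, n_pos):
        r = np.random.default_rng(seed)
        # coarse grid to provoke ties
        neg = r.integers(0, 8, n_neg) / 4.0
        pos = r.integers(0, 8, n_pos) / 4.0
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert evaluate_auroc(neg, pos) == pytest.approx(wins / (n_neg * n_pos))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_auroc([], [0.1])


class TestEnsembleOod:
    def test_members_share_znorm(self, trained_ensemble):
        m0 = trained_ensemble.members[0]
        for m in trained_ensemble.members[1:]:
            assert np.array_equal(m.znorm_mean, m0.znorm_mean)
            assert np.array_equal(m.znorm_std, m0.znorm_std)

    def test_displaced_spectra_score_higher_waic(self, trained_ensemble):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(11)
        inlier = rng.normal(0, 1, (200, 16))
        shift = np.full(16, 5.0 / np.sqrt(16))  # 5 whitened units
        outlier = rng.normal(0, 1, (200, 16)) + shift
        w_in = trained_ensemble.waic(inlier)
        w_out = trained_ensemble.waic(outlier)
        stat, p = mannwhitneyu(w_out, w_in, alternative="greater")
        assert p < 0.01

    def test_save_load_round_trip(self, trained_ensemble, tmp_path):
        trained_ensemble.save(tmp_path / "ens")
        loaded = FlowEnsemble.load(tmp_path / "ens")
        x = np.random.default_rng(3).normal(0, 1, (10, 16))
        assert np.allclose(
            loaded.log_likelihoods(x), trained_ensemble.log_likelihoods(x), atol=1e-12
        )
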