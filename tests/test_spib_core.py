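"""SPIB: loss, gradients, label refinement, training behavior, RC export."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp

from resikit import spib_core as sc
from resikit.featurize import FeatureTrajectory


def two_state_trajectory(seed=0, n=4000, dwell=40, sep=4.0, noise=0.5):
    """Markov jump process between two well-separated 2-D clouds."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [sep, sep]])
    state, states = 0, []
    for _ in range(n):
        if rng.random() < 1.0 / dwell:
            state = 1 - state
        states.append(state)
    states = np.array(states)
    values = centers[states] + noise * rng.standard_normal((n, 2))
    return FeatureTrajectory(times=np.arange(n, dtype=float), values=values,
                             labels=("x", "y")), states


def tiny_params(rng, D=3, L=2, H=5, K0=4, P=4):
    return {
        "W": 0.3 * rng.standard_normal((L, D)),
        "b": 0.1 * rng.standard_normal(L),
        "logvar": 0.3 * rng.standard_normal(L) - 1.5,
        "U": rng.standard_normal((P, D)),
        "omega": 0.2 * rng.standard_normal(P),
        "W1": rng.standard_normal((H, L)) / math.sqrt(L),
        "b1": 0.1 * rng.standard_normal(H),
        "W2": rng.standard_normal((K0, H)) / math.sqrt(H),
        "b2": 0.1 * rng.standard_normal(K0),
    }


class TestInitLabels:
    def test_separable_clouds_recovered_exactly(self):
        traj, states = two_state_trajectory(seed=1, noise=0.3)
        labels = sc.init_labels([traj], K0=2, seed=0)
        got = labels.labels[0]
        agreement = max(np.mean(got == states), np.mean(got == 1 - states))
        assert agreement == 1.0

    def test_single_state_trivial(self):
        traj, _ = two_state_trajectory(seed=2, n=100)
        labels = sc.init_labels([traj], K0=1, seed=0)
        assert labels.K == 1 and np.all(labels.labels[0] == 0)

    def test_deterministic_for_fixed_seed(self):
        traj, _ = two_state_trajectory(seed=3, n=500)
        a = sc.init_labels([traj], K0=3, seed=7)
        b = sc.init_labels([traj], K0=3, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a.labels, b.labels))

    def test_more_clusters_than_frames_rejected(self):
        traj, _ = two_state_trajectory(seed=4, n=10)
        with pytest.raises(ValueError, match="K0"):
            sc.init_labels([traj], K0=50, seed=0)


class TestMakePairs:
    def test_pair_count_is_length_minus_lag(self):
        traj, _ = two_state_trajectory(seed=0, n=100)
        X, y = sc.make_pairs([traj], [np.zeros(100, int)], lag=10)
        assert X.shape[0] == 90 and y.shape[0] == 90

    def test_maximum_lag_leaves_one_pair(self):
        traj, _ = two_state_trajectory(seed=0, n=100)
        X, y = sc.make_pairs([traj], [np.zeros(100, int)], lag=99)
        assert X.shape[0] == 1

    def test_pairs_never_cross_trajectory_boundaries(self):
        t1, _ = two_state_trajectory(seed=1, n=50)
        t2, _ = two_state_trajectory(seed=2, n=60)
        X, y = sc.make_pairs([t1, t2], [np.zeros(50, int), np.ones(60, int)], lag=10)
        assert X.shape[0] == (50 - 10) + (60 - 10)
        # targets from the first trajectory are all 0, from the second all 1
        assert np.all(y[:40] == 0) and np.all(y[40:] == 1)

    def test_short_trajectory_skipped_with_warning(self):
        t1, _ = two_state_trajectory(seed=1, n=5)
        t2, _ = two_state_trajectory(seed=2, n=60)
        with pytest.warns(UserWarning, match="skipped"):
            X, _ = sc.make_pairs([t1, t2], [np.zeros(5, int), np.zeros(60, int)], lag=10)
        assert X.shape[0] == 50

    def test_all_trajectories_too_short_raises(self):
        t1, _ = two_state_trajectory(seed=1, n=5)
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="pairs"):
            sc.make_pairs([t1], [np.zeros(5, int)], lag=10)


class TestLoss:
    def test_beta_zero_reduces_to_cross_entropy(self, rng):
        params = tiny_params(rng)
        X = rng.standard_normal((8, 3))
        y = rng.integers(0, 4, 8)
        eps = rng.standard_normal((8, 2))
        loss = sc.spib_loss(params, X, y, eps, beta_ib=0.0)
        # independent cross-entropy computation
        z = X @ params["W"].T + params["b"] + np.exp(0.5 * params["logvar"]) * eps
        h = np.tanh(z @ params["W1"].T + params["b1"])
        logits = h @ params["W2"].T + params["b2"]
        ce = logsumexp(logits, axis=1) - logits[np.arange(8), y]
        assert loss == pytest.approx(float(ce.mean()), rel=1e-12)

    def test_confident_correct_decoder_has_zero_prediction_loss(self, rng):
        params = tiny_params(rng)
        params["W2"] = np.zeros_like(params["W2"])
        params["b2"] = np.array([200.0, 0.0, 0.0, 0.0])  # certainty on state 0
        X = rng.standard_normal((6, 3))
        y = np.zeros(6, dtype=int)
        eps = rng.standard_normal((6, 2))
        assert sc.spib_loss(params, X, y, eps, beta_ib=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_small_variance_loss_matches_independent_evaluation(self, rng):
        # eps = 0 pins z at the posterior mean; evaluate every term longhand
        params = tiny_params(rng)
        params["logvar"][:] = math.log(1e-4)
        X = rng.standard_normal((5, 3))
        y = rng.integers(0, 4, 5)
        eps = np.zeros((5, 2))
        beta = 0.7
        z = X @ params["W"].T + params["b"]
        h = np.tanh(z @ params["W1"].T + params["b1"])
        logits = h @ params["W2"].T + params["b2"]
        ce = logsumexp(logits, axis=1) - logits[np.arange(5), y]
        lv = params["logvar"]
        log_q = -0.5 * np.sum(np.log(2 * np.pi) + lv)
        mu_k = params["U"] @ params["W"].T + params["b"]
        log_w = params["omega"] - logsumexp(params["omega"])
        var = np.exp(lv)
        log_nk = -0.5 * np.sum(
            np.log(2 * np.pi) + lv + (z[:, None, :] - mu_k[None]) ** 2 / var, axis=2
        )
        log_r = logsumexp(log_w[None, :] + log_nk, axis=1)
        expected = float(np.mean(ce + beta * (log_q - log_r)))
        assert sc.spib_loss(params, X, y, eps, beta) == pytest.approx(expected, rel=1e-12)

    def test_analytic_gradients_match_finite_differences(self, rng):
        params = tiny_params(rng, D=2, L=2, H=4, K0=3, P=3)
        X = rng.standard_normal((6, 2))
        y = rng.integers(0, 3, 6)
        eps = rng.standard_normal((6, 2))
        beta = 0.4
        _, grads = sc.spib_loss_grads(params, X, y, eps, beta)
        h = 1e-6
        for key, v in params.items():
            it = np.nditer(v, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = v[i]
                v[i] = orig + h
                lp = sc.spib_loss(params, X, y, eps, beta)
                v[i] = orig - h
                lm = sc.spib_loss(params, X, y, eps, beta)
                v[i] = orig
                num = (lp - lm) / (2 * h)
                assert grads[key][i] == pytest.approx(num, rel=5e-4, abs=1e-7), key

    def test_empty_batch_rejected(self, rng):
        params = tiny_params(rng)
        with pytest.raises(ValueError, match="empty"):
            sc.spib_loss(params, np.empty((0, 3)), np.empty(0, int),
                         np.empty((0, 2)), 0.1)


class TestRefinement:
    def test_refined_labels_match_independent_argmax_loop(self, rng):
        traj, _ = two_state_trajectory(seed=5, n=200)
        params = tiny_params(rng, D=2)
        model = sc.TrainedSPIB(
            params=params,
            mean=traj.values.mean(0), scale=traj.values.std(0),
            op_labels=("x", "y"),
            config=sc.SPIBConfig(lag=1, K0=4),
            active_states=np.arange(4),
            labels=sc.StateLabels(labels=[np.zeros(200, int)], K=1),
            raw_labels=[np.zeros(200, int)],
            history={},
        )
        refined = sc.refine_labels(model, [traj])
        # brute force, one frame at a time
        raw = []
        for row in traj.values:
            xn = (row - model.mean) / model.scale
            mu = params["W"] @ xn + params["b"]
            hh = np.tanh(params["W1"] @ mu + params["b1"])
            logits = params["W2"] @ hh + params["b2"]
            raw.append(int(np.argmax(logits)))
        kept = sorted(set(raw))
        expected = [kept.index(r) for r in raw]
        assert refined.labels[0].tolist() == expected
        assert refined.K == len(kept)


@pytest.fixture(scope="module")
def trained():
    traj, _ = two_state_trajectory(seed=6, n=4000)
    cfg = sc.SPIBConfig(lag=5, K0=4, seed=0, epochs_per_refinement=4,
                        max_refinements=8, batch_size=256)
    return traj, sc.train_spib([traj], cfg)


class TestTraining:

    def test_two_state_system_converges_to_two_states(self, trained):
        _, model = trained
        assert model.K == 2

    def test_state_count_never_increases_across_refinements(self, trained):
        _, model = trained
        ks = model.history["states_per_refinement"]
        assert all(b <= a for a, b in zip(ks, ks[1:]))

    def test_converged_labels_are_a_fixed_point(self, trained):
        traj, model = trained
        again = sc.refine_labels(model, [traj])
        frac = np.mean(again.labels[0] != model.labels.labels[0])
        assert frac < model.config.refinement_tolerance

    def test_encoder_posterior_mean_is_affine(self, trained, rng):
        _, model = trained
        x1 = rng.standard_normal((1, 2)) * 3
        x2 = rng.standard_normal((1, 2)) * 3
        for alpha in (0.0, 0.3, 0.8, 1.0):
            combo = sc.project(model, alpha * x1 + (1 - alpha) * x2)
            parts = alpha * sc.project(model, x1) + (1 - alpha) * sc.project(model, x2)
            assert np.allclose(combo, parts, atol=1e-10)

    def test_seeded_training_reproducible(self):
        traj, _ = two_state_trajectory(seed=8, n=2000)
        cfg = sc.SPIBConfig(lag=5, K0=3, seed=11, epochs_per_refinement=3,
                            max_refinements=5, batch_size=256)
        m1 = sc.train_spib([traj], cfg)
        m2 = sc.train_spib([traj], cfg)
        assert m1.K == m2.K
        agree = np.mean(m1.labels.labels[0] == m2.labels.labels[0])
        assert agree > 0.99

    def test_checkpoint_round_trip(self, trained, tmp_path):
        traj, model = trained
        path = tmp_path / "spib.json"
        model.save(path)
        loaded = sc.TrainedSPIB.load(path)
        assert loaded.K == model.K
        assert np.allclose(loaded.params["W"], model.params["W"])
        assert np.allclose(sc.project(loaded, traj.values[:10]),
                           sc.project(model, traj.values[:10]))


class TestRCSpec:
    def test_identity_model_rc_returns_first_ops(self):
        rc = sc.RCSpec(
            labels=("a", "b", "c"),
            mean=np.zeros(3), scale=np.ones(3),
            coefficients=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
            offsets=np.zeros(2),
        )
        X = np.arange(12.0).reshape(4, 3)
        assert np.allclose(rc.apply(X), X[:, :2])

    def test_exported_rc_reproduces_encoder_means(self):
        traj, _ = two_state_trajectory(seed=9, n=1500)
        cfg = sc.SPIBConfig(lag=3, K0=3, seed=2, epochs_per_refinement=2,
                            max_refinements=3, batch_size=256)
        model = sc.train_spib([traj], cfg)
        rc = sc.export_rc(model)
        assert np.allclose(rc.apply(traj.values), sc.project(model, traj.values),
                           atol=1e-10)

    def test_json_round_trip_identical(self):
        rc = sc.RCSpec(
            labels=("p", "q"),
            mean=np.array([0.5, -0.25]), scale=np.array([2.0, 0.5]),
            coefficients=np.array([[0.1, -0.7], [1.3, 0.02]]),
            offsets=np.array([0.9, -1.1]),
        )
        rc2 = sc.RCSpec.from_json(rc.to_json())
        assert rc2.labels == rc.labels
        for f in ("mean", "scale", "coefficients", "offsets"):
            assert np.array_equal(getattr(rc, f), getattr(rc2, f))
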