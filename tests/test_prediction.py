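import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegrecon import (EpochSet, PenaltySpec, SynthConfig, build_delay_design,
                      fit_elastic_net, fit_predictor, fit_ridge, generate,
                      implied_channel_map, predict_channels, score_r2,
                      select_channels)
from eegrecon.prediction import ChannelPredictor
from _oracles import (enet_objective, line_search_1d, prox_gradient_enet,
                      soft_threshold)


def _epoch_pair(n=2, u=2, v=3, m=50, seed=0):
    rng = np.random.default_rng(seed)
    eu = EpochSet(rng.standard_normal((n, u, m)), 250.0,
                  tuple(f"u{i}" for i in range(u)),
                  np.ones(n, int), {1: "left"})
    ev = EpochSet(rng.standard_normal((n, v, m)), 250.0,
                  tuple(f"v{i}" for i in range(v)),
                  np.ones(n, int), {1: "left"})
    return eu, ev


class TestDelayDesign:
    def test_hand_transcribed_minimal_case(self):
        # one trial, one channel, samples [x1, x2, x3], delay 1
        eu = EpochSet(np.array([[[1.0, 2.0, 3.0]]]), 250.0, ("a",),
                      np.array([1]), {1: "left"})
        d = build_delay_design(eu, eu, tau=1)
        assert d.X.shape == (2, 2)
        assert np.array_equal(d.X, [[1, 2], [2, 3]])
        assert np.array_equal(d.Y, [[1, 2]])

    def test_study_scale_dimensions(self):
        eu, ev = _epoch_pair(n=2, u=8, v=22, m=1700)
        d = build_delay_design(eu, ev, tau=1)
        assert d.X.shape == (16, 2 * 1699)
        assert d.Y.shape == (22, 2 * 1699)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(n=st.integers(1, 4), u=st.integers(1, 5), v=st.integers(1, 5),
           m=st.integers(3, 30), tau=st.integers(1, 2))
    def test_dimension_formula_on_random_shapes(self, n, u, v, m, tau):
        if tau >= m:
            return
        eu, ev = _epoch_pair(n=n, u=u, v=v, m=m)
        d = build_delay_design(eu, ev, tau=tau)
        assert d.X.shape == (2 * u, n * (m - tau))
        assert d.Y.shape == (v, n * (m - tau))
        assert (d.column_trial == np.repeat(np.arange(n), m - tau)).all()

    def test_delay_block_structure(self, rng):
        """Rows u..2u-1 of the design hold the same trial shifted by tau:
        shifting all trials by one sample moves the delayed block onto
        the old undelayed block."""
        eu, _ = _epoch_pair(n=3, u=2, m=20, seed=4)
        d = build_delay_design(eu, eu, tau=1)
        shifted = EpochSet(eu.data[:, :, 1:], eu.fs, eu.labels, eu.classes,
                           eu.class_names)
        d2 = build_delay_design(shifted, shifted, tau=1)
        # undelayed rows of the shifted design == delayed rows of the
        # original, dropping each trial's last column
        keep = np.ones(d.X.shape[1], bool)
        for t in range(3):
            keep[np.flatnonzero(d.column_trial == t)[-1]] = False
        assert np.allclose(d2.X[:2], d.X[2:][:, keep])

    def test_tau_equal_to_m_rejected(self):
        eu, ev = _epoch_pair(m=5)
        with pytest.raises(ValueError, match="tau"):
            build_delay_design(eu, ev, tau=5)

    def test_trial_count_mismatch_rejected(self):
        eu, _ = _epoch_pair(n=2)
        ev, _ = _epoch_pair(n=3)
        with pytest.raises(ValueError, match="trial count"):
            build_delay_design(eu, ev, tau=1)


def _standardized(p, N, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((p, N))
    X -= X.mean(axis=1, keepdims=True)
    X /= X.std(axis=1, keepdims=True)  # ||x_j||^2 = N
    y = rng.standard_normal(N)
    y -= y.mean()
    return X, y


class TestElasticNet:
    def test_zero_response_gives_null_solution(self):
        X, _ = _standardized(4, 30, 0)
        fit = fit_elastic_net(X, np.zeros(30), PenaltySpec(alpha=0.5))
        assert np.allclose(fit.coef, 0.0)
        assert fit.intercept == 0.0

    def test_single_predictor_closed_form_and_line_search(self):
        X, y = _standardized(1, 40, 1)
        alpha, rho = 0.3, 0.6
        fit = fit_elastic_net(X, y, PenaltySpec(alpha=alpha, l1_ratio=rho,
                                                tol=1e-12))
        closed = soft_threshold(X[0] @ y / 40, alpha * rho) \
            / (1 + alpha * (1 - rho))
        assert fit.coef[0] == pytest.approx(closed, abs=1e-10)
        grid = line_search_1d(X[0], y, alpha, rho, lo=-3, hi=3)
        assert fit.coef[0] == pytest.approx(grid, abs=1e-5)

    @pytest.mark.parametrize("alpha,rho", [(0.1, 0.5), (1.0, 0.9),
                                           (0.01, 0.0)])
    def test_objective_matches_proximal_gradient_oracle(self, alpha, rho):
        X, y = _standardized(10, 20, 2)
        fit = fit_elastic_net(X, y, PenaltySpec(alpha=alpha, l1_ratio=rho,
                                                tol=1e-12, max_iter=20000))
        oracle = prox_gradient_enet(X, y, alpha, rho)
        assert enet_objective(X, y, fit.coef, alpha, rho) \
            <= enet_objective(X, y, oracle, alpha, rho) + 1e-6

    def test_objective_non_increasing_over_sweeps(self):
        X, y = _standardized(8, 25, 3)
        fit = fit_elastic_net(X, y, PenaltySpec(alpha=0.2, l1_ratio=0.5,
                                                tol=1e-14, max_iter=500))
        h = np.array(fit.objective_history)
        assert (np.diff(h) <= 1e-12).all()

    def test_ridge_limit_matches_closed_form(self):
        X, y = _standardized(6, 30, 4)
        alpha = 0.7
        fit = fit_elastic_net(X, y, PenaltySpec(alpha=alpha, l1_ratio=0.0,
                                                tol=1e-13, max_iter=50000))
        beta_ridge = fit_ridge(X, y, lambda2=30 * alpha)
        assert np.abs(fit.coef - beta_ridge).max() < 1e-6

    def test_lasso_limit_matches_proximal_oracle(self):
        X, y = _standardized(6, 30, 5)
        fit = fit_elastic_net(X, y, PenaltySpec(alpha=0.3, l1_ratio=1.0,
                                                tol=1e-13, max_iter=50000))
        oracle = prox_gradient_enet(X, y, 0.3, 1.0)
        assert np.abs(fit.coef - oracle).max() < 1e-6

    def test_zero_penalty_matches_ols(self):
        X, y = _standardized(5, 40, 6)
        fit = fit_elastic_net(X, y, PenaltySpec(alpha=0.0, tol=1e-13,
                                                max_iter=50000))
        ols = np.linalg.lstsq(X.T, y, rcond=None)[0]
        assert np.abs(fit.coef - ols).max() < 1e-6

    def test_agrees_with_sklearn(self):
        """Independent cross-check against an established solver."""
        from sklearn.linear_model import ElasticNet

        X, y = _standardized(7, 60, 7)
        fit = fit_elastic_net(X, y, PenaltySpec(alpha=0.2, l1_ratio=0.5,
                                                tol=1e-12, max_iter=20000))
        sk = ElasticNet(alpha=0.2, l1_ratio=0.5, fit_intercept=True,
                        tol=1e-12, max_iter=100000).fit(X.T, y)
        assert np.abs(fit.coef - sk.coef_).max() < 1e-6

    def test_solution_independent_of_initialization(self):
        """Coordinate descent reaches the same objective from a cold
        start, a random start, and the ridge warm start."""
        from eegrecon.prediction import _cd_elastic_net

        X, y = _standardized(8, 40, 9)
        spec = PenaltySpec(alpha=0.3, l1_ratio=0.5, tol=1e-13,
                           max_iter=50000)
        G, c = X @ X.T, X @ y
        objs = []
        rng = np.random.default_rng(spec.seed)
        for beta0 in (None, rng.standard_normal(8) * 3):
            beta, _, conv, hist = _cd_elastic_net(G, c, float(y @ y), 40,
                                                  spec, beta0=beta0)
            assert conv
            objs.append(hist[-1])
        assert abs(objs[0] - objs[1]) < 1e-10

    def test_non_finite_input_rejected(self):
        X, y = _standardized(3, 10, 8)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_elastic_net(X, y)


class TestRidge:
    def test_matches_direct_solve(self, rng):
        X = rng.standard_normal((3, 10))
        y = rng.standard_normal(10)
        beta = fit_ridge(X, y, 1.0)
        expected = np.linalg.solve(X @ X.T + np.eye(3), X @ y)
        assert np.abs(beta - expected).max() < 1e-10

    def test_zero_penalty_full_rank_is_ols(self, rng):
        X = rng.standard_normal((3, 50))
        y = rng.standard_normal(50)
        beta = fit_ridge(X, y, 0.0)
        ols = np.linalg.lstsq(X.T, y, rcond=None)[0]
        assert np.abs(beta - ols).max() < 1e-8

    def test_norm_shrinks_monotonically(self, rng):
        X = rng.standard_normal((4, 30))
        y = rng.standard_normal(30)
        norms = [np.linalg.norm(fit_ridge(X, y, lam))
                 for lam in (0.0, 1.0, 10.0, 100.0, 1e4)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]

    def test_singular_zero_penalty_falls_back_to_pinv(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0]])  # rank 1
        with pytest.warns(RuntimeWarning, match="singular"):
            beta = fit_ridge(X, np.array([1.0, 2.0]), 0.0)
        assert np.isfinite(beta).all()


class TestPredictor:
    def test_coefficient_shape_22x16(self, det_map_epochs, montage):
        pred = fit_predictor(det_map_epochs, montage, tau=1,
                             spec=PenaltySpec(alpha=1e-6))
        assert pred.coef.shape == (22, 16)
        assert pred.output_labels == montage.labels
        assert pred.input_labels == montage.input_subset

    def test_deterministic_refit_is_bit_identical(self, montage):
        e = generate(SynthConfig(n_trials_per_class=4, seed=9))
        p1 = fit_predictor(e, montage)
        p2 = fit_predictor(e, montage)
        assert np.array_equal(p1.coef, p2.coef)
        assert np.array_equal(p1.intercepts, p2.intercepts)

    def test_noiseless_recovery(self, det_map_epochs, montage):
        """Channels that are exact linear functions of the inputs are
        recovered essentially perfectly at vanishing penalty."""
        pred = fit_predictor(det_map_epochs, montage, tau=1,
                             spec=PenaltySpec(alpha=1e-6, tol=1e-10))
        reduced = select_channels(det_map_epochs, montage.input_subset)
        recon = predict_channels(pred, reduced)
        assert score_r2(det_map_epochs, recon).mean >= 0.999

    def test_implied_linear_map_recovered(self, det_map_epochs, montage):
        cfg = SynthConfig(n_trials_per_class=6, deterministic_map=True,
                          snr_db=None, seed=7)
        pred = fit_predictor(det_map_epochs, montage, tau=1,
                             spec=PenaltySpec(alpha=1e-6, tol=1e-10))
        L = implied_channel_map(cfg)
        err = np.linalg.norm(pred.coef[:, :8] - L) / np.linalg.norm(L)
        assert err < 1e-2

    def test_self_prediction_of_input_channel(self, det_map_epochs, montage):
        pred = fit_predictor(det_map_epochs, montage, tau=1,
                             spec=PenaltySpec(alpha=1e-6, tol=1e-10))
        reduced = select_channels(det_map_epochs, montage.input_subset)
        recon = predict_channels(pred, reduced)
        r2 = score_r2(det_map_epochs, recon)
        j = recon.labels.index("C3")  # C3 is both input and output
        assert r2.per_channel[j] > 0.999999

    def test_prediction_metadata_and_delay_trimming(self, det_map_epochs,
                                                    montage):
        pred = fit_predictor(det_map_epochs, montage, tau=1,
                             spec=PenaltySpec(alpha=1e-6, tol=1e-10))
        reduced = select_channels(det_map_epochs, montage.input_subset)
        recon = predict_channels(pred, reduced)
        assert recon.n_samples == det_map_epochs.n_samples - 1
        assert (recon.classes == det_map_epochs.classes).all()

    def test_boundary_single_sample_epochs(self, montage):
        e = generate(SynthConfig(n_trials_per_class=3, seed=2))
        pred = fit_predictor(e, montage, tau=1,
                             spec=PenaltySpec(max_iter=5))
        reduced = select_channels(e, montage.input_subset)
        tiny = EpochSet(reduced.data[:, :, :2], e.fs, reduced.labels,
                        e.classes, e.class_names)
        recon = predict_channels(pred, tiny)
        assert recon.n_samples == 1

    def test_missing_input_channel_named(self, montage, small_synthetic):
        pred = fit_predictor(small_synthetic, montage, tau=1,
                             spec=PenaltySpec(max_iter=5))
        bad = select_channels(small_synthetic, ("C3", "C1"))
        with pytest.raises(KeyError, match="Cz"):
            predict_channels(pred, bad)

    def test_csv_round_trip(self, tmp_path, montage, det_map_epochs):
        pred = fit_predictor(det_map_epochs, montage, tau=1,
                             spec=PenaltySpec(alpha=1e-6, max_iter=50))
        p2 = ChannelPredictor.from_csv(pred.to_csv(tmp_path / "pred.csv"))
        assert np.array_equal(p2.coef, pred.coef)
        assert np.array_equal(p2.x_center, pred.x_center)
        assert p2.input_labels == pred.input_labels
        assert p2.output_labels == pred.output_labels
        assert p2.tau == pred.tau


class TestScoreR2:
    def _sets(self, actual, predicted):
        a = EpochSet(np.asarray(actual, float)[None, None, :], 250.0,
                     ("a",), np.array([1]), {1: "left"})
        p = EpochSet(np.asarray(predicted, float)[None, None, :], 250.0,
                     ("a",), np.array([1]), {1: "left"})
        return a, p

    def test_identity_gives_one(self):
        a, p = self._sets([1, 2, 3, 4], [1, 2, 3, 4])
        assert score_r2(a, p).per_channel[0] == 1.0

    def test_mean_predictor_gives_zero(self):
        a, p = self._sets([1, 2, 3, 4], [2.5] * 4)
        assert score_r2(a, p).per_channel[0] == pytest.approx(0.0)

    def test_hand_example(self):
        a, p = self._sets([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8])
        r2 = score_r2(a, p)
        assert r2.per_channel[0] == pytest.approx(0.98)

    def test_zero_variance_channel_reported_missing(self):
        a, p = self._sets([5, 5, 5, 5], [5, 5, 5, 5])
        assert np.isnan(score_r2(a, p).per_channel[0])
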