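"""Constrained Gaussian-HMM estimation and decoding."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gazephase.exceptions import DataError, NumericalError
from gazephase.hmm import (ConstrainedGaussianHMM, ConstraintConfig,
                           GazeStateModel, fit_emhmm, forward_backward,
                           project_constraints, roi_area, viterbi)

from conftest import enumerate_paths_log, random_hmm_model


def single_state_model(mean=(0.5, 0.5), var=0.01):
    return GazeStateModel(
        means=np.array([mean]), covariances=np.array([np.eye(2) * var]),
        transition=np.array([[1.0]]), initial=np.array([1.0]),
    )


class TestForwardBackward:
    def test_single_state_closed_form(self):
        """K=1: posteriors are 1 and the log-likelihood is the sum of
        Gaussian log-densities."""
        rng = np.random.default_rng(0)
        model = single_state_model()
        obs = rng.normal(0.5, 0.1, size=(20, 2))
        seq = forward_backward(model, obs)
        assert np.allclose(seq.posteriors, 1.0)
        expected = multivariate_normal.logpdf(
            obs, mean=model.means[0], cov=model.covariances[0]).sum()
        assert seq.log_likelihood == pytest.approx(expected, abs=1e-8)
        assert np.all(seq.viterbi_path == 0)

    def test_toy_instance_matches_path_enumeration(self):
        """T=6, K=3: likelihood equals the brute-force sum over all 3^6
        paths and the Viterbi path attains the enumerated maximum."""
        rng = np.random.default_rng(42)
        model = random_hmm_model(rng, 3)
        obs = rng.uniform(0.2, 0.8, size=(6, 2))
        total, best, argbest = enumerate_paths_log(model, obs)
        seq = forward_backward(model, obs)
        assert seq.log_likelihood == pytest.approx(total, abs=1e-8)
        assert tuple(seq.viterbi_path) in argbest

    @pytest.mark.parametrize("seed", range(25))
    def test_random_instances_match_enumeration(self, seed):
        """Forward likelihood and Viterbi probability agree with full
        path enumeration on random instances with T<=8, K<=3."""
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 4))
        T = int(rng.integers(2, 9))
        model = random_hmm_model(rng, K)
        obs = rng.uniform(0.0, 1.0, size=(T, 2))
        total, best, argbest = enumerate_paths_log(model, obs)
        seq = forward_backward(model, obs)
        assert seq.log_likelihood == pytest.approx(total, abs=1e-8)
        assert tuple(seq.viterbi_path) in argbest
        assert np.allclose(seq.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_identical_obs_symmetric_chain_posteriors_stationary(self):
        """A symmetric 2-state chain with identical emissions leaves the
        posterior at the stationary mixture weights at every t."""
        var = 0.01
        model = GazeStateModel(
            means=np.array([[0.5, 0.5], [0.5, 0.5]]),
            covariances=np.array([np.eye(2) * var, np.eye(2) * var]),
            transition=np.array([[0.7, 0.3], [0.3, 0.7]]),
            initial=np.array([0.5, 0.5]),
        )
        obs = np.tile([0.4, 0.6], (10, 1))
        seq = forward_backward(model, obs)
        assert np.allclose(seq.posteriors, 0.5, atol=1e-12)

    def test_underflow_raises(self):
        """Zero total emission likelihood must raise, not renormalise."""
        model = single_state_model(var=1e-12)
        obs = np.array([[0.5, 0.5], [1e200, 1e200]])
        with pytest.raises(NumericalError):
            forward_backward(model, obs)
        with pytest.raises(NumericalError):
            viterbi(model, obs)


class TestViterbi:
    def test_tie_break_toward_lower_index(self):
        """Fully symmetric model: every path ties, so the contract picks
        the constant path in state 0."""
        var = 0.01
        model = GazeStateModel(
            means=np.array([[0.5, 0.5], [0.5, 0.5]]),
            covariances=np.array([np.eye(2) * var, np.eye(2) * var]),
            transition=np.array([[0.5, 0.5], [0.5, 0.5]]),
            initial=np.array([0.5, 0.5]),
        )
        obs = np.tile([0.5, 0.5], (5, 1))
        path = viterbi(model, obs)
        assert np.all(path == 0)


class TestConstraints:
    def test_projection_enforces_area_band(self):
        cfg = ConstraintConfig()
        rng = np.random.default_rng(3)
        means = rng.uniform(0, 1, size=(6, 2))
        covs = np.array([np.eye(2) * v for v in
                         [1e-9, 1e-5, 1e-3, 0.01, 0.1, 1.0]])
        projected, events = project_constraints(means, covs, cfg)
        areas = np.array([roi_area(c, cfg) for c in projected])
        assert np.all(areas >= cfg.area_min_frac - 1e-12)
        assert np.all(areas <= cfg.area_max_frac + 1e-12)
        assert events  # out-of-band inputs must be reported

    def test_projection_idempotent_on_feasible_model(self):
        """A model satisfying both the area band and the axis clamp is
        returned unchanged, and re-projection is a no-op."""
        cfg = ConstraintConfig()
        rng = np.random.default_rng(4)
        means = rng.uniform(0.2, 0.8, size=(6, 2))
        base = np.array([[2.0e-3, 3.0e-4], [3.0e-4, 2.5e-3]])
        covs = np.array([base * s for s in
                         np.linspace(0.9, 1.1, 6)])  # homogeneous axes
        areas = np.array([roi_area(c, cfg) for c in covs])
        assert np.all((areas > cfg.area_min_frac)
                      & (areas < cfg.area_max_frac))
        projected, events = project_constraints(means, covs, cfg)
        assert np.allclose(projected, covs, atol=1e-12)
        assert not events
        proj2, _ = project_constraints(means, projected, cfg)
        assert np.allclose(proj2, projected, atol=1e-12)

    def test_infeasible_band_rejected(self):
        with pytest.raises(Exception):
            ConstraintConfig(area_min_frac=0.5, area_max_frac=0.1)


class TestFit:
    def test_single_cluster_k1(self):
        """One tight cluster, K=1: mean at the centroid, transition [[1]]."""
        rng = np.random.default_rng(5)
        obs = [rng.normal([0.3, 0.7], 0.01, size=(50, 2)) for _ in range(4)]
        model = fit_emhmm(obs, K=1, n_restarts=2, seed=0)
        centroid = np.concatenate(obs).mean(axis=0)
        assert np.allclose(model.means[0], centroid, atol=0.01)
        assert np.allclose(model.transition, [[1.0]])

    def test_em_loglik_monotone_up_to_projection(self):
        """Per-restart log-likelihood never decreases beyond projection
        tolerance, and decreases are surfaced in the event log."""
        rng = np.random.default_rng(6)
        obs = [rng.uniform(0, 1, size=(40, 2)) for _ in range(5)]
        est = ConstrainedGaussianHMM(obs, n_states=3)
        res = est.fit(n_restarts=1, seed=1, max_iter=50)
        trace = np.array(res.loglik_trace)
        drops = np.diff(trace) < -1e-8
        projection_drops = [e for e in res.projection_events
                            if "decreased" in e]
        assert drops.sum() <= len(projection_drops)

    def test_three_state_recovery(self):
        """Means of a well-separated 3-state model are recovered within
        0.05 after Hungarian matching."""
        from scipy.optimize import linear_sum_assignment

        from gazephase.simulate import GenerativeConfig, simulate_episode

        true = GazeStateModel(
            means=np.array([[0.2, 0.2], [0.8, 0.3], [0.5, 0.8]]),
            covariances=np.array([np.eye(2) * 4e-4] * 3),
            transition=np.full((3, 3), 1 / 3),
            initial=np.full(3, 1 / 3),
        )
        cfg = GenerativeConfig(sampling_rate_hz=120.0, K_true=3,
                               stickiness_explore=0.3)
        rng = np.random.default_rng(7)
        obs = []
        for _ in range(30):
            ep, truth = simulate_episode(true, tau_s=np.inf, duration_s=8.0,
                                         config=cfg, seed=rng)
            centres = []
            for onset, st in zip(truth.event_onsets, truth.event_states):
                sel = (ep.t >= onset) & (ep.t < onset + 0.2)
                if sel.any():
                    centres.append([ep.x[sel].mean(), ep.y[sel].mean()])
            obs.append(np.array(centres))
        model = fit_emhmm(obs, K=3, n_restarts=4, seed=2)
        d = np.linalg.norm(
            model.means[:, None, :] - true.means[None, :, :], axis=2)
        r, c = linear_sum_assignment(d)
        assert d[r, c].mean() < 0.05

    def test_degenerate_k_exceeds_distinct_locations(self):
        obs = [np.array([[0.5, 0.5]] * 10)]
        with pytest.raises(DataError, match="degenerate"):
            ConstrainedGaussianHMM(obs, n_states=3)

    def test_states_ordered_by_occupancy(self, small_study):
        data, gt = small_study
        eps = [e for e in data.episodes
               if e.artwork_id == "art00"][:4]
        from gazephase.io import detect_fixations

        for e in eps:
            e.fixations = detect_fixations(e)
        est = ConstrainedGaussianHMM.from_episodes(eps, n_states=3)
        res = est.fit(n_restarts=2, seed=3)
        occ = res.model.stationary_distribution()
        assert np.all(np.diff(occ) <= 1e-9)

    def test_cross_check_against_reference_hmm_library(self):
        """Unconstrained decoding agrees with hmmlearn on the same
        parameters (independent implementation cross-check)."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(8)
        model = random_hmm_model(rng, 3)
        obs = rng.uniform(0, 1, size=(50, 2))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                   init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.means_ = model.means
        ref.covars_ = model.covariances
        ref_ll = ref.score(obs)
        seq = forward_backward(model, obs)
        assert seq.log_likelihood == pytest.approx(ref_ll, abs=1e-8)
        assert np.array_equal(seq.viterbi_path, ref.predict(obs))


class TestSerialisation:
    def test_round_trip_bit_stable(self, tmp_path):
        rng = np.random.default_rng(9)
        model = random_hmm_model(rng, 4)
        for ext in ("json", "yaml"):
            path = tmp_path / f"m.{ext}"
            model.save(path)
            back = GazeStateModel.load(path)
            assert np.array_equal(back.means, model.means)
            assert np.array_equal(back.covariances, model.covariances)
            assert np.array_equal(back.transition, model.transition)
            assert np.array_equal(back.initial, model.initial)
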