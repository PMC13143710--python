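import numpy as np
import pytest

from gazephase.simulate import GenerativeConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact effect-present study shared by read-only tests."""
    cfg = GenerativeConfig(
        n_participants=6, n_artworks=4, n_high=2,
        sampling_rate_hz=60.0, K_true=5, seed=11,
    )
    return simulate_study(cfg)


def random_hmm_model(rng: np.random.Generator, K: int, separation: float = 0.0):
    """A random (unconstrained-ish) gaze-state model for oracle tests."""
    from gazephase.hmm import ConstraintConfig, GazeStateModel

    means = rng.uniform(0.1, 0.9, size=(K, 2))
    if separation:
        means = np.linspace(0.15, 0.85, K)[:, None] * np.ones((1, 2))
        means += rng.normal(0, 0.02, size=(K, 2))
    covs = np.empty((K, 2, 2))
    for k in range(K):
        a = rng.uniform(0.01, 0.05)
        b = rng.uniform(0.01, 0.05)
        rho = rng.uniform(-0.5, 0.5)
        covs[k] = np.array([[a * a, rho * a * b], [rho * a * b, b * b]])
    A = rng.uniform(0.2, 1.0, size=(K, K))
    A /= A.sum(axis=1, keepdims=True)
    init = rng.uniform(0.2, 1.0, size=K)
    init /= init.sum()
    return GazeStateModel(means=means, covariances=covs, transition=A,
                          initial=init, constraints=ConstraintConfig())


def enumerate_paths_log(model, obs):
    """Brute-force path enumeration oracle (independent of the package).

    Returns (total log-likelihood via log-sum-exp over all K^T paths,
    max path log-probability, the set of maximising paths).
    """
    from itertools import product

    from scipy.special import logsumexp
    from scipy.stats import multivariate_normal

    K = model.n_states
    T = len(obs)
    logB = np.column_stack([
        multivariate_normal.logpdf(obs, mean=model.means[k],
                                   cov=model.covariances[k])
        for k in range(K)
    ]).reshape(T, K)
    logA = np.log(model.transition)
    log_init = np.log(model.initial)
    paths = np.array(list(product(range(K), repeat=T)))
    lp = log_init[paths[:, 0]] + logB[0, paths[:, 0]]
    for t in range(1, T):
        lp = lp + logA[paths[:, t - 1], paths[:, t]] + logB[t, paths[:, t]]
    best = lp.max()
    argbest = {tuple(p) for p in paths[np.isclose(lp, best, atol=1e-9)]}
    return float(logsumexp(lp)), float(best), argbest
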