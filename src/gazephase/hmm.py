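"""Constrained Gaussian hidden-Markov gaze-state estimation.

Scanpaths are modelled with a per-stimulus hidden Markov model whose
hidden states are spatial regions of interest (ROIs): each state emits
2-D gaze positions from a Gaussian with its own mean and covariance, and
the transition matrix captures how gaze moves between regions.  Fitting
is maximum-likelihood Baum-Welch EM over all observers' sequences for
one stimulus, with two empirical constraints projected into the
parameters after every M-step so the estimated regions stay
interpretable:

* the ROI ellipse area (at a configurable probability mass, default the
  68% ellipse) must lie within a band of the total image area
  (default 0.1%-5%), and
* ROI axis lengths are clamped to mean +/- N sigma of the axis lengths
  across all ROIs (default N=2), preventing single outlier regions.

Multiple seeded restarts are run and the restart with the best
log-likelihood kept; states are re-indexed by descending stationary
occupancy so fits are reproducible and comparable.

The estimator follows the statsmodels convention: build a
:class:`ConstrainedGaussianHMM` from observation sequences, call
:meth:`~ConstrainedGaussianHMM.fit`, and work with the returned
:class:`GazeStateResults` (parameters, diagnostics, ``summary()``,
``decode()``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats
from sklearn.cluster import kmeans_plusplus

from .exceptions import ConfigurationError, DataError, NumericalError

logger = logging.getLogger(__name__)

__all__ = [
    "ConstraintConfig",
    "GazeStateModel",
    "StateSequence",
    "ConstrainedGaussianHMM",
    "GazeStateResults",
    "fit_emhmm",
    "forward_backward",
    "viterbi",
    "project_constraints",
    "roi_area",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ConstraintConfig:
    """Empirical constraints on the fitted ROIs.

    ``area_definition`` is the probability mass whose covering ellipse
    defines the ROI "area"; 0.68 gives the conventional 1-sigma-
    equivalent ellipse.  ``axis_clamp_n`` is the N in the mean +/- N
    sigma clamp on axis lengths across ROIs.
    """

    area_min_frac: float = 0.001
    area_max_frac: float = 0.05
    axis_clamp_n: float = 2.0
    area_definition: float = 0.68
    cov_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.area_min_frac < self.area_max_frac < 1.0):
            raise ConfigurationError(
                "area band must satisfy 0 < min < max < 1, got "
                f"[{self.area_min_frac}, {self.area_max_frac}]"
            )

    @property
    def chi2_scale(self) -> float:
        """Squared Mahalanobis radius of the mass-defining ellipse."""
        return float(stats.chi2.ppf(self.area_definition, df=2))


def roi_area(cov: np.ndarray, constraints: ConstraintConfig) -> float:
    """Area of one ROI's mass-defining ellipse (image area = 1)."""
    det = float(np.linalg.det(cov))
    return float(np.pi * constraints.chi2_scale * np.sqrt(max(det, 0.0)))


@dataclass
class GazeStateModel:
    """Parameters of a fitted (or ground-truth) gaze-state HMM.

    Coordinates are normalised, so the image area is 1 and ROI areas are
    directly fractions of image area.
    """

    means: np.ndarray            # (K, 2)
    covariances: np.ndarray      # (K, 2, 2)
    transition: np.ndarray       # (K, K) row-stochastic
    initial: np.ndarray          # (K,)
    constraints: ConstraintConfig = field(default_factory=ConstraintConfig)
    fit_log_likelihood: float | None = None
    n_restarts_used: int | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K = self.n_states
        if self.means.shape != (K, 2) or self.covariances.shape != (K, 2, 2):
            raise ConfigurationError("inconsistent parameter shapes")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ConfigurationError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-8):
            raise ConfigurationError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.initial)

    def roi_areas(self) -> np.ndarray:
        """Per-state ellipse areas as fractions of image area."""
        return np.array(
            [roi_area(c, self.constraints) for c in self.covariances]
        )

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        vals, vecs = np.linalg.eig(self.transition.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        total = pi.sum()
        if total <= 0 or not np.isfinite(total):  # reducible corner case
            pi = np.ones(self.n_states)
            total = float(self.n_states)
        return pi / total

    # -- serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "n_states": self.n_states,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "constraints": {
                "area_min_frac": self.constraints.area_min_frac,
                "area_max_frac": self.constraints.area_max_frac,
                "axis_clamp_n": self.constraints.axis_clamp_n,
                "area_definition": self.constraints.area_definition,
                "cov_floor": self.constraints.cov_floor,
            },
            "fit_log_likelihood": self.fit_log_likelihood,
            "n_restarts_used": self.n_restarts_used,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GazeStateModel":
        return cls(
            means=np.array(d["means"], dtype=float),
            covariances=np.array(d["covariances"], dtype=float),
            transition=np.array(d["transition"], dtype=float),
            initial=np.array(d["initial"], dtype=float),
            constraints=ConstraintConfig(**d.get("constraints", {})),
            fit_log_likelihood=d.get("fit_log_likelihood"),
            n_restarts_used=d.get("n_restarts_used"),
        )

    def save(self, path) -> None:
        path = str(path)
        payload = self.to_dict()
        if path.endswith((".yaml", ".yml")):
            with open(path, "w") as fh:
                yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            with open(path, "w") as fh:
                json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GazeStateModel":
        path = str(path)
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                payload = yaml.safe_load(fh)
            else:
                payload = json.load(fh)
        return cls.from_dict(payload)


@dataclass
class StateSequence:
    """Decoded state representation of one observation sequence."""

    posteriors: np.ndarray   # (T, K), rows on the simplex
    viterbi_path: np.ndarray  # (T,) int state indices, 0-based
    log_likelihood: float

    @property
    def T(self) -> int:
        return len(self.viterbi_path)

    @property
    def n_states(self) -> int:
        return self.posteriors.shape[1]


# ---------------------------------------------------------------------------
# emission densities


def _emission_logprobs(model_means, model_covs, obs: np.ndarray) -> np.ndarray:
    """(T, K) log N(obs_t | mu_k, Sigma_k) for 2-D Gaussians."""
    K = len(model_means)
    T = len(obs)
    out = np.empty((T, K))
    for k in range(K):
        cov = model_covs[k]
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
        if det <= 0 or not np.isfinite(det):
            raise NumericalError(f"non-SPD covariance in state {k}")
        inv = np.array([[cov[1, 1], -cov[0, 1]],
                        [-cov[1, 0], cov[0, 0]]]) / det
        d = obs - model_means[k]
        with np.errstate(over="ignore", invalid="ignore"):
            quad = (d @ inv * d).sum(axis=1)
            out[:, k] = -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad
        out[np.isnan(out[:, k]), k] = -np.inf  # inf - inf from overflow
    return out


def forward_backward(model: GazeStateModel, observations: np.ndarray,
                     logB: np.ndarray | None = None) -> StateSequence:
    """Scaled forward-backward smoothing for one sequence.

    Returns posteriors, the Viterbi path and the exact data
    log-likelihood under the model.  Raises :class:`NumericalError` if
    the total emission likelihood underflows at any timepoint (instead
    of silently renormalising garbage).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise DataError("observations must be a (T, 2) array")
    if not np.all(np.isfinite(obs)):
        raise DataError("observations must be finite")
    if logB is None:
        logB = _emission_logprobs(model.means, model.covariances, obs)
    T, K = logB.shape
    shift = logB.max(axis=1)
    if not np.all(np.isfinite(shift)):
        t_bad = int(np.nonzero(~np.isfinite(shift))[0][0])
        raise NumericalError(f"emission likelihood underflow at t={t_bad}")
    B = np.exp(logB - shift[:, None])

    A = model.transition
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = model.initial * B[0]
    c[0] = a.sum()
    if c[0] <= 0 or not np.isfinite(c[0]):
        raise NumericalError("emission likelihood underflow at t=0")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] <= 0 or not np.isfinite(c[t]):
            raise NumericalError(f"emission likelihood underflow at t={t}")
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    path = viterbi(model, obs, logB=logB)
    return StateSequence(posteriors=post, viterbi_path=path,
                         log_likelihood=loglik)


def viterbi(model: GazeStateModel, observations: np.ndarray,
            logB: np.ndarray | None = None) -> np.ndarray:
    """Most probable state path; ties broken toward the lower index."""
    obs = np.asarray(observations, dtype=float)
    if logB is None:
        logB = _emission_logprobs(model.means, model.covariances, obs)
    T, K = logB.shape
    if not np.all(np.isfinite(logB.max(axis=1))):
        t_bad = int(np.nonzero(~np.isfinite(logB.max(axis=1)))[0][0])
        raise NumericalError(f"emission likelihood underflow at t={t_bad}")
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition)
        log_init = np.log(model.initial)
    delta = log_init + logB[0]
    back = np.empty((T, K), dtype=np.intp)
    for t in range(1, T):
        trans = delta[:, None] + logA
        # argmax returns the first (lowest-index) maximiser: tie-break rule
        back[t] = np.argmax(trans, axis=0)
        delta = trans[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# constraint projection


def project_constraints(means: np.ndarray, covs: np.ndarray,
                        constraints: ConstraintConfig):
    """Project covariances onto the feasible set; idempotent.

    Order of operations: eigenvalue floor, axis-length clamp (mean +/- N
    sigma across all ROI axis lengths), then the area band, enforced
    last so every returned ROI area is guaranteed inside the band.  Area
    rescaling is isotropic (both eigenvalues scaled equally), preserving
    orientation and aspect ratio.

    Returns ``(covs, events)`` where ``events`` lists which ROIs were
    adjusted and why.
    """
    K = len(covs)
    s = constraints.chi2_scale
    events: list[str] = []
    eigvals = np.empty((K, 2))
    eigvecs = np.empty((K, 2, 2))
    for k in range(K):
        w, v = np.linalg.eigh(0.5 * (covs[k] + covs[k].T))
        eigvals[k] = np.maximum(w, constraints.cov_floor)
        eigvecs[k] = v

    # axis clamp: semi-axis lengths of the mass-defining ellipse
    axes = np.sqrt(s * eigvals)           # (K, 2)
    mean_ax = axes.mean()
    sd_ax = axes.std()
    lo = max(mean_ax - constraints.axis_clamp_n * sd_ax,
             np.sqrt(s * constraints.cov_floor))
    hi = mean_ax + constraints.axis_clamp_n * sd_ax
    clamped = np.clip(axes, lo, hi)
    changed = ~np.isclose(clamped, axes)
    if changed.any():
        for k in np.nonzero(changed.any(axis=1))[0]:
            events.append(f"state {k}: axis length clamped")
        eigvals = clamped ** 2 / s

    # area band, enforced last
    amin, amax = constraints.area_min_frac, constraints.area_max_frac
    out = np.empty_like(covs)
    for k in range(K):
        area = np.pi * s * np.sqrt(eigvals[k, 0] * eigvals[k, 1])
        target = None
        if area < amin:
            target = amin
        elif area > amax:
            target = amax
        if target is not None:
            eigvals[k] *= target / area
            events.append(
                f"state {k}: area {area:.3g} rescaled to {target:.3g}"
            )
        out[k] = eigvecs[k] @ np.diag(eigvals[k]) @ eigvecs[k].T
        out[k] = 0.5 * (out[k] + out[k].T)
    return out, events


# ---------------------------------------------------------------------------
# estimator


class ConstrainedGaussianHMM:
    """Gaussian-emission HMM estimator with ROI constraints.

    Parameters
    ----------
    observations : sequence of (T_i, 2) arrays
        One observation sequence per viewing episode, in normalised
        coordinates.  By convention these are fixation centroids (the
        usual observation unit for scanpath HMMs), but raw or
        downsampled gaze samples work identically.
    n_states : int
        Number of ROIs (K).  The pipeline default is 14.
    constraints : ConstraintConfig
    """

    def __init__(self, observations, n_states: int = 14,
                 constraints: ConstraintConfig | None = None):
        self.observations = [np.asarray(o, dtype=float) for o in observations
                             if len(o) > 0]
        if not self.observations:
            raise DataError("need at least one non-empty observation sequence")
        for o in self.observations:
            if o.ndim != 2 or o.shape[1] != 2:
                raise DataError("each observation sequence must be (T, 2)")
        self.n_states = int(n_states)
        self.constraints = constraints or ConstraintConfig()
        self._pooled = np.concatenate(self.observations, axis=0)
        n_distinct = len(np.unique(self._pooled, axis=0))
        if self.n_states > n_distinct:
            raise DataError(
                f"degenerate fit: K={self.n_states} exceeds the "
                f"{n_distinct} distinct observation locations"
            )

    @classmethod
    def from_episodes(cls, episodes, n_states: int = 14,
                      constraints: ConstraintConfig | None = None,
                      observation_unit: str = "fixations",
                      fixation_config=None,
                      downsample_hz: float = 10.0):
        """Build the estimator from viewing episodes.

        ``observation_unit`` is ``"fixations"`` (I-DT centroids, the
        default and the conventional choice) or ``"samples"``
        (gaze samples downsampled to ``downsample_hz``).
        """
        from .io import detect_fixations

        seqs = []
        for ep in episodes:
            if getattr(ep, "rejected", False):
                continue
            if observation_unit == "fixations":
                fx = ep.fixations
                if fx is None:
                    fx = detect_fixations(ep, fixation_config)
                seqs.append(np.array([[f.x, f.y] for f in fx]))
            elif observation_unit == "samples":
                step = max(1, int(round(
                    1.0 / (downsample_hz * np.median(np.diff(ep.t)))
                ))) if ep.n_samples > 1 else 1
                m = ep.valid[::step]
                seqs.append(np.column_stack([ep.x[::step][m], ep.y[::step][m]]))
            else:
                raise ConfigurationError(
                    f"unknown observation unit {observation_unit!r}"
                )
        return cls([s for s in seqs if len(s)], n_states=n_states,
                   constraints=constraints)

    # -- fitting ------------------------------------------------------

    def fit(self, n_restarts: int = 20, seed: int | None = None,
            tol: float = 1e-6, max_iter: int = 200) -> "GazeStateResults":
        """Run Baum-Welch from ``n_restarts`` seeded k-means++ starts."""
        rng = np.random.default_rng(seed)
        best = None
        for r in range(n_restarts):
            try:
                fitted = self._fit_once(rng, tol, max_iter)
            except NumericalError as err:
                logger.warning("restart %d failed: %s", r, err)
                continue
            if best is None or fitted["log_likelihood"] > best["log_likelihood"]:
                best = fitted
                best["restart"] = r
        if best is None:
            raise NumericalError(
                f"all {n_restarts} restarts failed numerically"
            )
        model = GazeStateModel(
            means=best["means"], covariances=best["covs"],
            transition=best["transition"], initial=best["initial"],
            constraints=self.constraints,
            fit_log_likelihood=best["log_likelihood"],
            n_restarts_used=n_restarts,
        )
        model = _reindex_by_occupancy(model)
        return GazeStateResults(
            model=model, estimator=self,
            log_likelihood=best["log_likelihood"],
            n_iter=best["n_iter"], converged=best["converged"],
            projection_events=best["projection_events"],
            loglik_trace=best["trace"], best_restart=best["restart"],
        )

    def _init_params(self, rng: np.random.Generator):
        K = self.n_states
        centers, _ = kmeans_plusplus(
            self._pooled, n_clusters=K,
            random_state=int(rng.integers(2**31 - 1)),
        )
        pooled_var = self._pooled.var(axis=0).mean()
        base_var = max(pooled_var / max(K, 1), 10 * self.constraints.cov_floor)
        covs = np.tile(np.eye(2) * base_var, (K, 1, 1))
        covs, _ = project_constraints(centers, covs, self.constraints)
        transition = np.full((K, K), 0.2 / max(K - 1, 1))
        np.fill_diagonal(transition, 0.8 if K > 1 else 1.0)
        initial = np.full(K, 1.0 / K)
        return centers.astype(float), covs, transition, initial

    def _fit_once(self, rng: np.random.Generator, tol: float, max_iter: int):
        K = self.n_states
        means, covs, A, init = self._init_params(rng)
        prev_ll = -np.inf
        trace: list[float] = []
        projection_events: list[str] = []
        converged = False
        n_iter = 0
        for it in range(max_iter):
            # E-step
            ll = 0.0
            g_sum = np.zeros(K)                 # sum of posteriors
            g_obs = np.zeros((K, 2))            # posterior-weighted obs
            g_outer = np.zeros((K, 2, 2))
            xi_sum = np.zeros((K, K))
            init_sum = np.zeros(K)
            for obs in self.observations:
                logB = _emission_logprobs(means, covs, obs)
                seq_ll, gamma, xi = _e_step(A, init, logB)
                ll += seq_ll
                init_sum += gamma[0]
                g_sum += gamma.sum(axis=0)
                g_obs += gamma.T @ obs
                for k in range(K):
                    d = obs - means[k]
                    g_outer[k] += (gamma[:, k, None] * d).T @ d
                xi_sum += xi
            trace.append(ll)
            if ll + tol < prev_ll:
                projection_events.append(
                    f"iter {it}: log-likelihood decreased by "
                    f"{prev_ll - ll:.3g} after constraint projection"
                )
            if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
                converged = True
                n_iter = it + 1
                break
            prev_ll = ll
            n_iter = it + 1

            # M-step
            init = init_sum / init_sum.sum()
            row = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(row > 0, xi_sum / np.where(row > 0, row, 1.0),
                         1.0 / K)
            A /= A.sum(axis=1, keepdims=True)
            occ = np.maximum(g_sum, 1e-12)
            new_means = g_obs / occ[:, None]
            new_covs = np.empty_like(covs)
            for k in range(K):
                # recentre the scatter on the updated mean
                dm = new_means[k] - means[k]
                new_covs[k] = (g_outer[k] / occ[k]
                               - np.outer(dm, dm))
                new_covs[k] = 0.5 * (new_covs[k] + new_covs[k].T)
            means = new_means
            covs, events = project_constraints(means, new_covs,
                                               self.constraints)
            projection_events.extend(f"iter {it}: {e}" for e in events)
        return {
            "means": means, "covs": covs, "transition": A, "initial": init,
            "log_likelihood": trace[-1], "n_iter": n_iter,
            "converged": converged, "trace": trace,
            "projection_events": projection_events,
        }


def _e_step(A, init, logB):
    """Scaled forward-backward returning (loglik, gamma, xi_sum)."""
    T, K = logB.shape
    shift = logB.max(axis=1)
    if not np.all(np.isfinite(shift)):
        t_bad = int(np.nonzero(~np.isfinite(shift))[0][0])
        raise NumericalError(f"emission likelihood underflow at t={t_bad}")
    B = np.exp(logB - shift[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = init * B[0]
    c[0] = a.sum()
    if c[0] <= 0 or not np.isfinite(c[0]):
        raise NumericalError("emission likelihood underflow at t=0")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] <= 0 or not np.isfinite(c[t]):
            raise NumericalError(f"emission likelihood underflow at t={t}")
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / c[t + 1]
        xi += np.outer(alpha[t], bb) * A / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return loglik, gamma, xi


def _reindex_by_occupancy(model: GazeStateModel) -> GazeStateModel:
    order = np.argsort(-model.stationary_distribution(), kind="stable")
    return GazeStateModel(
        means=model.means[order],
        covariances=model.covariances[order],
        transition=model.transition[np.ix_(order, order)],
        initial=model.initial[order],
        constraints=model.constraints,
        fit_log_likelihood=model.fit_log_likelihood,
        n_restarts_used=model.n_restarts_used,
    )


class GazeStateResults:
    """Fit results: parameters, diagnostics and decoding."""

    def __init__(self, model: GazeStateModel, estimator, log_likelihood: float,
                 n_iter: int, converged: bool, projection_events: list[str],
                 loglik_trace: list[float], best_restart: int):
        self.model = model
        self.estimator = estimator
        self.log_likelihood = log_likelihood
        self.n_iter = n_iter
        self.converged = converged
        self.projection_events = projection_events
        self.loglik_trace = loglik_trace
        self.best_restart = best_restart

    def decode(self, observations: np.ndarray) -> StateSequence:
        """Posterior smoothing + Viterbi path for one sequence."""
        return forward_backward(self.model, observations)

    def save(self, path) -> None:
        self.model.save(path)

    def summary(self) -> str:
        m = self.model
        areas = m.roi_areas() * 100
        occ = m.stationary_distribution()
        lines = [
            "Constrained Gaussian HMM gaze-state fit",
            "=" * 55,
            f"states (K):          {m.n_states}",
            f"sequences:           {len(self.estimator.observations)}",
            f"observations:        {sum(len(o) for o in self.estimator.observations)}",
            f"log-likelihood:      {self.log_likelihood:.3f}",
            f"best restart:        {self.best_restart} "
            f"(of {m.n_restarts_used})",
            f"EM iterations:       {self.n_iter} "
            f"({'converged' if self.converged else 'max_iter reached'})",
            f"constraint events:   {len(self.projection_events)}",
            "",
            f"{'state':>5} {'mean_x':>8} {'mean_y':>8} "
            f"{'area_%':>8} {'occupancy':>10}",
        ]
        for k in range(m.n_states):
            lines.append(
                f"{k:>5} {m.means[k, 0]:>8.3f} {m.means[k, 1]:>8.3f} "
                f"{areas[k]:>8.3f} {occ[k]:>10.3f}"
            )
        return "\n".join(lines)


def fit_emhmm(observations, K: int = 14,
              constraint_config: ConstraintConfig | None = None,
              n_restarts: int = 20, seed: int | None = None,
              tol: float = 1e-6, max_iter: int = 200) -> GazeStateModel:
    """Functional wrapper: fit and return the best model."""
    est = ConstrainedGaussianHMM(observations, n_states=K,
                                 constraints=constraint_config)
    return est.fit(n_restarts=n_restarts, seed=seed, tol=tol,
                   max_iter=max_iter).model
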