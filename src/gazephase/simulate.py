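"""Seeded synthetic gaze studies with the structure the analysis assumes.

The generator emulates a self-paced aesthetic-judgment experiment:
35 participants view 12 artworks (6 destined for high ratings, 6 for
low) and click when their judgment is established, with gaze sampled at
300 Hz.  The mechanism producing the group contrast is a
time-inhomogeneous hidden Markov chain over ground-truth ROIs operating
at fixation-event granularity:

* before a per-artwork convergence onset tau the chain is in an
  *exploration* regime (low self-transition, uniform off-diagonal),
* from tau onward it is in a *convergence* regime in which every row
  concentrates on a per-episode focus state (high self-transition at
  the focus, fast attraction toward it).

High-rated artworks get an earlier tau than low-rated ones, realising
the earlier exploration-to-convergence transition whose downstream
signatures (lower Hnorm/TV in the middle bins) the analysis is built to
detect.  Each fixation event draws its centre from the occupied ROI's
Gaussian; gaze samples are the centre plus small tracker-like jitter,
so I-DT detection and sample-level decoding both see realistic input.

Every draw flows from one seed; the same config + seed reproduce a
study exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .datatypes import StimulusInfo, ViewingEpisode
from .exceptions import ConfigurationError
from .hmm import ConstraintConfig, GazeStateModel, roi_area

__all__ = [
    "GenerativeConfig",
    "EpisodeTruth",
    "GroundTruth",
    "StudyData",
    "make_ground_truth_model",
    "simulate_episode",
    "simulate_study",
    "BiasConfig",
    "simulate_preference_trial",
    "expected_choice_curve",
]


@dataclass
class GenerativeConfig:
    """All generator knobs in one (YAML-serialisable) place.

    Defaults mirror the study design the pipeline targets: 35
    participants x 12 artworks (6 per evaluation group), 300 Hz
    sampling, self-paced judgment times with mean 13.1 s (SD 1.21)
    truncated to [3, 30] s, convergence onsets of 6 s (high group) and
    12 s (low group), and group rating levels 0.668 / 0.357 on the
    normalised scale.
    """

    n_participants: int = 35
    n_artworks: int = 12
    n_high: int = 6
    sampling_rate_hz: float = 300.0
    K_true: int = 14
    tau_high_s: float = 6.0
    tau_low_s: float = 12.0
    stickiness_explore: float = 0.15
    stickiness_converge: float = 0.92
    n_focus_candidates: int = 3
    dwell_mean_s: float = 0.30
    dwell_sd_s: float = 0.12
    dwell_min_s: float = 0.06
    judgment_time_mean_s: float = 13.1
    judgment_time_sd_s: float = 1.21
    judgment_time_range_s: tuple[float, float] = (3.0, 30.0)
    rating_mean_high: float = 0.668
    rating_mean_low: float = 0.357
    rating_noise_sd: float = 0.12
    jitter_sd: float = 0.0015
    image_width_px: float = 1920.0
    image_height_px: float = 1080.0
    constraints: ConstraintConfig = field(default_factory=ConstraintConfig)
    depth_points: str = "focus"     # "focus" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stickiness_explore", "stickiness_converge"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_high > self.n_artworks:
            raise ConfigurationError("n_high cannot exceed n_artworks")
        if self.K_true < 1:
            raise ConfigurationError("K_true must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["judgment_time_range_s"] = list(self.judgment_time_range_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeConfig":
        d = dict(d)
        if "constraints" in d and isinstance(d["constraints"], dict):
            d["constraints"] = ConstraintConfig(**d["constraints"])
        if "judgment_time_range_s" in d:
            d["judgment_time_range_s"] = tuple(d["judgment_time_range_s"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GenerativeConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class EpisodeTruth:
    """Ground-truth state path of one simulated episode."""

    event_states: np.ndarray    # (E,) state per fixation event
    event_onsets: np.ndarray    # (E,) event start times, seconds
    sample_states: np.ndarray   # (T,) state per gaze sample
    focus_state: int
    tau_s: float


@dataclass
class GroundTruth:
    """Everything needed for recovery tests on a generated study."""

    models: dict[str, GazeStateModel]       # artwork -> generating model
    group: dict[str, str]                    # artwork -> "high" | "low"
    tau: dict[str, float]                    # artwork -> convergence onset
    episodes: dict[tuple[str, str], EpisodeTruth]
    focus_candidates: dict[str, np.ndarray]  # artwork -> candidate states


@dataclass
class StudyData:
    """A generated dataset in the same shape real data take."""

    episodes: list[ViewingEpisode]
    ratings: pd.DataFrame
    stimuli: list[StimulusInfo]
    config: GenerativeConfig


def make_ground_truth_model(K_true: int, constraint_config: ConstraintConfig
                            | None = None,
                            seed: int | np.random.Generator = 0,
                            stickiness: float = 0.15) -> GazeStateModel:
    """Draw a ground-truth gaze-state model with feasible ROIs.

    Means are placed in the interior of the unit square; each
    covariance is a randomly oriented ellipse whose area (under the
    constraint config's mass convention) is drawn log-uniformly inside
    the constraint band, so generated models are feasible by
    construction.  The stored transition matrix is the exploration-
    regime matrix (self-transition ``stickiness``, uniform elsewhere).
    """
    constraints = constraint_config or ConstraintConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if K_true < 1:
        raise ConfigurationError("K_true must be >= 1")
    s = constraints.chi2_scale
    means = rng.uniform(0.12, 0.88, size=(K_true, 2))
    covs = np.empty((K_true, 2, 2))
    log_amin = np.log(constraints.area_min_frac)
    log_amax = np.log(constraints.area_max_frac)
    for k in range(K_true):
        # keep clear of the band edges so emission noise cannot leak out
        area = np.exp(rng.uniform(log_amin + 0.3, log_amax - 0.3))
        det = (area / (np.pi * s)) ** 2          # = l1 * l2
        aspect = rng.uniform(1.0, 2.5)
        l1 = np.sqrt(det * aspect)
        l2 = np.sqrt(det / aspect)
        theta = rng.uniform(0, np.pi)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        covs[k] = R @ np.diag([l1, l2]) @ R.T
    transition = _explore_matrix(K_true, stickiness)
    initial = np.full(K_true, 1.0 / K_true)
    model = GazeStateModel(means=means, covariances=covs,
                           transition=transition, initial=initial,
                           constraints=constraints)
    areas = model.roi_areas()
    if np.any(areas < constraints.area_min_frac - 1e-12) or \
            np.any(areas > constraints.area_max_frac + 1e-12):
        raise ConfigurationError("constraint band infeasible for K_true")
    return model


def _explore_matrix(K: int, stickiness: float) -> np.ndarray:
    if K == 1:
        return np.ones((1, 1))
    A = np.full((K, K), (1.0 - stickiness) / (K - 1))
    np.fill_diagonal(A, stickiness)
    return A


def _converge_row_sampler(K: int, focus: int, stickiness: float,
                          rng: np.random.Generator):
    """Next-state draw in the convergence regime.

    From any state the chain moves to (or stays at) the focus state
    with probability ``stickiness``; the remainder spreads uniformly
    over the other states.  With stickiness 1 the path is constant
    from the first post-onset transition.
    """
    others = np.delete(np.arange(K), focus)

    def step(_current: int) -> int:
        if rng.random() < stickiness or K == 1:
            return focus
        return int(rng.choice(others))

    return step


def simulate_episode(model: GazeStateModel, tau_s: float, duration_s: float,
                     config: GenerativeConfig,
                     seed: int | np.random.Generator = 0,
                     focus_state: int | None = None
                     ) -> tuple[ViewingEpisode, EpisodeTruth]:
    """Simulate one viewing episode from a ground-truth model.

    The hidden path runs at fixation-event granularity: each event
    dwells for a Gamma-distributed duration, then transitions under the
    exploration regime before ``tau_s`` and the convergence regime
    after.  Every event's fixation centre is drawn from the occupied
    ROI's Gaussian; samples add isotropic jitter around the centre.

    Returns the episode (normalised coordinates, all samples valid) and
    its ground truth.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    K = model.n_states
    if focus_state is None:
        focus_state = int(rng.integers(K))
    converge_step = _converge_row_sampler(
        K, focus_state, config.stickiness_converge, rng)
    se = config.stickiness_explore

    # dwell-duration Gamma parameters from mean/sd
    mean_d = config.dwell_mean_s
    var_d = config.dwell_sd_s ** 2
    shape = mean_d ** 2 / var_d
    scale = var_d / mean_d

    states: list[int] = []
    onsets: list[float] = []
    t = 0.0
    state = int(rng.choice(K, p=model.initial))
    while t < duration_s:
        states.append(state)
        onsets.append(t)
        t += max(config.dwell_min_s, rng.gamma(shape, scale))
        if t >= duration_s:
            break
        # regime chosen by the start time of the *next* event
        if t < tau_s:
            if rng.random() >= se and K > 1:
                state = int(rng.choice(np.delete(np.arange(K), state)))
        else:
            state = converge_step(state)
    event_states = np.array(states, dtype=int)
    event_onsets = np.array(onsets, dtype=float)

    dt = 1.0 / config.sampling_rate_hz
    times = np.arange(0.0, duration_s, dt)
    ev_idx = np.searchsorted(event_onsets, times, side="right") - 1
    sample_states = event_states[ev_idx]

    # per-event fixation centre from the ROI Gaussian
    centres = np.empty((len(event_states), 2))
    for i, st in enumerate(event_states):
        centres[i] = rng.multivariate_normal(
            model.means[st], model.covariances[st])
    pos = centres[ev_idx] + rng.normal(0.0, config.jitter_sd,
                                       size=(len(times), 2))
    pos = np.clip(pos, 0.0, 1.0 - 1e-9)

    episode = ViewingEpisode(
        participant_id="sim", artwork_id="sim",
        t=times, x=pos[:, 0], y=pos[:, 1],
        valid=np.ones(len(times), dtype=bool),
        judgment_time=float(duration_s),
        normalized=True,
    )
    truth = EpisodeTruth(
        event_states=event_states, event_onsets=event_onsets,
        sample_states=sample_states, focus_state=focus_state, tau_s=tau_s,
    )
    return episode, truth


def _draw_judgment_time(config: GenerativeConfig, tau_s: float,
                        rng: np.random.Generator) -> float:
    lo, hi = config.judgment_time_range_s
    lo = max(lo, tau_s)
    for _ in range(1000):
        jt = rng.normal(config.judgment_time_mean_s,
                        config.judgment_time_sd_s)
        if lo <= jt <= hi:
            return float(jt)
    return float(np.clip(config.judgment_time_mean_s, lo, hi))


def simulate_study(config: GenerativeConfig | None = None
                   ) -> tuple[StudyData, GroundTruth]:
    """Generate a full crossed participants x artworks study.

    High-group artworks receive ``tau_high_s`` and the high rating
    level; low-group artworks ``tau_low_s`` and the low level.  Ratings
    are generated on the normalised scale and inverse-mapped to 1-10
    integers through a per-participant affine response scale, so the
    rating-normalisation stage is exercised end to end.  Deterministic
    under ``config.seed``.
    """
    config = config or GenerativeConfig()
    rng = np.random.default_rng(config.seed)
    artwork_ids = [f"art{i:02d}" for i in range(config.n_artworks)]
    participant_ids = [f"p{i:02d}" for i in range(config.n_participants)]
    group = {a: ("high" if i < config.n_high else "low")
             for i, a in enumerate(artwork_ids)}
    tau = {a: (config.tau_high_s if group[a] == "high" else config.tau_low_s)
           for a in artwork_ids}

    models: dict[str, GazeStateModel] = {}
    focus_candidates: dict[str, np.ndarray] = {}
    stimuli: list[StimulusInfo] = []
    for a in artwork_ids:
        m = make_ground_truth_model(
            config.K_true, config.constraints, seed=rng,
            stickiness=config.stickiness_explore,
        )
        models[a] = m
        cand = np.arange(min(config.n_focus_candidates, config.K_true))
        focus_candidates[a] = cand
        depth = ([tuple(m.means[c]) for c in cand]
                 if config.depth_points == "focus" else [])
        stimuli.append(StimulusInfo(
            artwork_id=a, width_px=config.image_width_px,
            height_px=config.image_height_px,
            depth_points=depth,
        ))

    # per-participant affine rating scales
    scale_lo = rng.integers(1, 4, size=config.n_participants)
    scale_hi = rng.integers(8, 11, size=config.n_participants)

    episodes: list[ViewingEpisode] = []
    truths: dict[tuple[str, str], EpisodeTruth] = {}
    rating_rows = []
    for pi, pid in enumerate(participant_ids):
        for a in artwork_ids:
            jt = _draw_judgment_time(config, tau[a], rng)
            focus = int(rng.choice(focus_candidates[a]))
            ep, truth = simulate_episode(
                models[a], tau[a], jt, config, seed=rng, focus_state=focus,
            )
            ep.participant_id = pid
            ep.artwork_id = a
            level = (config.rating_mean_high if group[a] == "high"
                     else config.rating_mean_low)
            v = float(np.clip(level + rng.normal(0, config.rating_noise_sd),
                              0.0, 1.0))
            rating = int(np.clip(
                round(scale_lo[pi] + v * (scale_hi[pi] - scale_lo[pi])),
                1, 10))
            ep.rating = rating
            episodes.append(ep)
            truths[(pid, a)] = truth
            rating_rows.append({
                "participant_id": pid, "artwork_id": a,
                "rating": rating, "latent_value": v,
            })

    ratings = pd.DataFrame(rating_rows)
    data = StudyData(episodes=episodes, ratings=ratings, stimuli=stimuli,
                     config=config)
    gt = GroundTruth(models=models, group=group, tau=tau, episodes=truths,
                     focus_candidates=focus_candidates)
    return data, gt


# ---------------------------------------------------------------------------
# 2AFC preference trials (gaze-cascade generator)


@dataclass
class BiasConfig:
    """Ramped gaze bias toward the to-be-chosen option.

    P(sample on chosen option) rises linearly from ``baseline`` at
    stimulus onset to ``final_prob`` at decision time.
    """

    baseline: float = 0.5
    final_prob: float = 0.9
    presentation_constraint_s: float | None = None  # 0.3, 0.9 or None
    decision_time_mean_s: float = 1.5
    sampling_rate_hz: float = 300.0
    left_box: tuple[float, float, float, float] = (0.05, 0.30, 0.45, 0.70)
    right_box: tuple[float, float, float, float] = (0.55, 0.30, 0.95, 0.70)


def simulate_preference_trial(bias_config: BiasConfig | None = None,
                              seed: int | np.random.Generator = 0):
    """Simulate one 2AFC preference trial with a pre-decision gaze bias."""
    from .supplementary import PreferenceTrial

    cfg = bias_config or BiasConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if cfg.presentation_constraint_s is not None:
        decision_time = float(cfg.presentation_constraint_s)
    else:
        decision_time = float(max(0.3, rng.normal(
            cfg.decision_time_mean_s, 0.3 * cfg.decision_time_mean_s)))
    chosen = "left" if rng.random() < 0.5 else "right"
    dt = 1.0 / cfg.sampling_rate_hz
    t = np.arange(dt, decision_time + dt / 2, dt)
    frac = t / decision_time
    p_chosen = cfg.baseline + (cfg.final_prob - cfg.baseline) * frac
    on_chosen = rng.random(len(t)) < p_chosen
    boxes = {"left": cfg.left_box, "right": cfg.right_box}
    other = "right" if chosen == "left" else "left"
    x = np.empty(len(t))
    y = np.empty(len(t))
    for mask, box_name in ((on_chosen, chosen), (~on_chosen, other)):
        x0, y0, x1, y1 = boxes[box_name]
        n = int(mask.sum())
        x[mask] = rng.uniform(x0, x1, size=n)
        y[mask] = rng.uniform(y0, y1, size=n)
    return PreferenceTrial(
        t=t, x=x, y=y, valid=np.ones(len(t), dtype=bool),
        decision_time=decision_time, chosen=chosen,
        left_box=cfg.left_box, right_box=cfg.right_box,
        presentation_constraint_s=cfg.presentation_constraint_s,
    )


def expected_choice_curve(bias_config: BiasConfig, n_time_bins: int = 10
                          ) -> np.ndarray:
    """Generator-implied P(gaze on chosen) per normalised-time bin."""
    edges = np.linspace(0.0, 1.0, n_time_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return (bias_config.baseline
            + (bias_config.final_prob - bias_config.baseline) * mid)
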