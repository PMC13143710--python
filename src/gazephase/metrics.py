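"""Time-binned gaze-state distributions and the five phase indices.

Decoded episodes are aggregated over the first 30 s of viewing in 3-s
bins.  Each populated bin is summarised by its mean posterior state
distribution p (the dwell-probability profile), Viterbi visit counts and
dwell times, and then scored with five indices:

Hnorm
    Shannon entropy of p divided by log K (natural log).  1 = gaze
    spread evenly over all states (exploratory), 0 = fully converged.
MaxP
    max_i p_i, the dominance of the strongest gaze state.
NeffNorm
    exp(H)/K, the effective number of substantively used states as a
    fraction of K.
TV
    half the L1 distance between the state distributions of consecutive
    populated bins; attributed to the earlier bin of the pair.
Switch
    fraction of adjacent Viterbi timepoints whose states differ within
    the bin; undefined (NaN) for bins with fewer than 2 timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .hmm import StateSequence

logger = logging.getLogger(__name__)

__all__ = [
    "BinDistribution",
    "bin_sequence",
    "hnorm",
    "maxp",
    "neffnorm",
    "total_variation",
    "switch_rate",
    "episode_metrics",
    "metrics_table",
    "METRIC_NAMES",
]

METRIC_NAMES = ("Hnorm", "MaxP", "NeffNorm", "TV", "Switch")


@dataclass
class BinDistribution:
    """Gaze-state summary of one half-open time bin [t_start, t_end)."""

    bin_index: int
    t_start: float
    t_end: float
    p: np.ndarray            # (K,) mean posterior distribution
    hit_count: np.ndarray    # (K,) Viterbi entries into each state
    dwell_time: np.ndarray   # (K,) seconds on the Viterbi path
    n_timepoints: int
    populated: bool
    sample_slice: slice      # indices into the episode's time axis

    @property
    def window_label(self) -> str:
        return f"{self.t_start:g}-{self.t_end:g} s"


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DataError("probabilities must be non-negative")
    return p


def hnorm(p, K: int | None = None) -> float:
    """Normalised Shannon entropy of a state distribution, in [0, 1]."""
    p = _check_simplex(p)
    K = K if K is not None else len(p)
    if K <= 1:
        return 0.0
    pos = p[p > 0]
    H = float(-(pos * np.log(pos)).sum())
    return H / np.log(K)


def maxp(p) -> float:
    """Maximum state probability; dominance of the strongest state."""
    p = _check_simplex(p)
    return float(p.max())


def neffnorm(p, K: int | None = None) -> float:
    """Effective number of states exp(H) as a fraction of K."""
    p = _check_simplex(p)
    K = K if K is not None else len(p)
    pos = p[p > 0]
    H = float(-(pos * np.log(pos)).sum())
    return float(np.exp(H)) / K


def total_variation(p, q) -> float:
    """Total-variation distance between two state distributions."""
    p = _check_simplex(p)
    q = _check_simplex(q)
    if len(p) != len(q):
        raise DataError(
            f"distributions must share a state space, got {len(p)} vs {len(q)}"
        )
    return float(0.5 * np.abs(np.asarray(q) - np.asarray(p)).sum())


def switch_rate(path_segment) -> float:
    """Fraction of adjacent state pairs that differ; NaN when undefined."""
    path = np.asarray(path_segment)
    if len(path) < 2:
        if len(path) == 0:
            logger.debug("switch_rate on empty segment -> missing")
        return float("nan")
    return float((path[1:] != path[:-1]).mean())


def bin_sequence(seq: StateSequence, times: np.ndarray,
                 bin_width_s: float = 3.0, horizon_s: float = 30.0,
                 min_points_fraction: float = 0.1) -> list[BinDistribution]:
    """Aggregate a decoded sequence into fixed-width time bins.

    All bins covering [0, horizon) are returned; bins whose timepoint
    count falls below ``min_points_fraction`` of the expected count for
    a full bin are flagged unpopulated (and excluded by downstream
    statistics).  Hit counts are *entries*: a state scores one hit when
    the Viterbi path enters it, plus one for the state occupied at the
    start of the bin.
    """
    times = np.asarray(times, dtype=float)
    if len(times) != seq.T:
        raise DataError("times and decoded sequence lengths differ")
    K = seq.n_states
    n_bins = int(np.ceil(horizon_s / bin_width_s))
    dt = float(np.median(np.diff(times))) if len(times) > 1 else bin_width_s
    expected = bin_width_s / dt if dt > 0 else 1
    min_points = max(1, int(np.ceil(min_points_fraction * expected)))

    edges = np.arange(n_bins + 1) * bin_width_s
    idx = np.searchsorted(times, edges, side="left")
    bins: list[BinDistribution] = []
    for b in range(n_bins):
        lo, hi = idx[b], idx[b + 1]
        n = hi - lo
        sl = slice(lo, hi)
        if n == 0:
            bins.append(BinDistribution(
                b, edges[b], edges[b + 1], np.full(K, np.nan),
                np.zeros(K, dtype=int), np.zeros(K), 0, False, sl))
            continue
        p = seq.posteriors[sl].mean(axis=0)
        path = seq.viterbi_path[sl]
        hits = np.zeros(K, dtype=int)
        hits[path[0]] += 1
        if n > 1:
            entries = path[1:][path[1:] != path[:-1]]
            np.add.at(hits, entries, 1)
        dwell = np.bincount(path, minlength=K).astype(float) * dt
        bins.append(BinDistribution(
            b, edges[b], edges[b + 1], p, hits, dwell, int(n),
            n >= min_points, sl))
    return bins


def episode_metrics(bins: list[BinDistribution],
                    viterbi_path: np.ndarray) -> pd.DataFrame:
    """All five indices per populated bin of one episode.

    TV is computed between consecutive *populated* bins and attributed
    to the earlier bin, so an episode with B populated bins yields
    exactly B-1 TV values.
    """
    path = np.asarray(viterbi_path)
    populated = [b for b in bins if b.populated]
    tv_by_bin: dict[int, float] = {}
    for earlier, later in zip(populated[:-1], populated[1:]):
        tv_by_bin[earlier.bin_index] = total_variation(earlier.p, later.p)
    rows = []
    for b in populated:
        K = len(b.p)
        rows.append({
            "bin": b.bin_index,
            "t_start": b.t_start,
            "t_end": b.t_end,
            "n_timepoints": b.n_timepoints,
            "Hnorm": hnorm(b.p, K),
            "MaxP": maxp(b.p),
            "NeffNorm": neffnorm(b.p, K),
            "TV": tv_by_bin.get(b.bin_index, np.nan),
            "Switch": switch_rate(path[b.sample_slice]),
        })
    return pd.DataFrame(
        rows, columns=["bin", "t_start", "t_end", "n_timepoints",
                       *METRIC_NAMES])


def metrics_table(decoded: dict, times: dict,
                  bin_width_s: float = 3.0, horizon_s: float = 30.0,
                  min_points_fraction: float = 0.1) -> pd.DataFrame:
    """Tidy long-format table of indices for a whole study.

    Parameters
    ----------
    decoded : dict mapping (participant_id, artwork_id) -> StateSequence
    times : dict mapping the same keys -> sample time arrays

    Returns
    -------
    DataFrame with columns participant, artwork, bin, t_start, t_end,
    metric, value — the pipeline's central tabular artefact.
    """
    frames = []
    for key, seq in decoded.items():
        pid, aid = key
        bins = bin_sequence(seq, times[key], bin_width_s=bin_width_s,
                            horizon_s=horizon_s,
                            min_points_fraction=min_points_fraction)
        em = episode_metrics(bins, seq.viterbi_path)
        if em.empty:
            continue
        long = em.melt(
            id_vars=["bin", "t_start", "t_end"],
            value_vars=list(METRIC_NAMES),
            var_name="metric", value_name="value",
        )
        long.insert(0, "participant", pid)
        long.insert(1, "artwork", aid)
        frames.append(long)
    if not frames:
        return pd.DataFrame(columns=["participant", "artwork", "bin",
                                     "t_start", "t_end", "metric", "value"])
    return pd.concat(frames, ignore_index=True)
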