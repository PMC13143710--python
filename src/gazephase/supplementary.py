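"""Supplementary analyses: depth-point fixations and pre-decision gaze bias.

Depth-related points are annotated image locations carrying pictorial
depth cues.  A fixation *hits* a depth point when its centroid lies
within a radius (normalised units) of any annotated point; per 3-s bin
we count hits, the first hit time and the mean dwell of hitting
fixations, plus a running cumulative hit count, which is where group
differences tend to accumulate even when single bins show none.

The 2AFC analysis computes the gaze-cascade curve: the probability of
gaze resting on the ultimately chosen option as a function of time
normalised to the decision (1 = decision moment), with the final bin
reported separately as the decision-proximal estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import (GroupAssignment, bh_fdr, rank_biserial,
                      wilcoxon_rank_sum)
from .datatypes import Fixation
from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "depth_hits",
    "cumulative_comparison",
    "PreferenceTrial",
    "choice_gaze_probability",
]


def depth_hits(fixations: list[Fixation], depth_points,
               radius: float = 0.05, bin_width_s: float = 3.0,
               horizon_s: float = 30.0) -> pd.DataFrame:
    """Per-bin depth-fixation indices for one episode.

    Returns a DataFrame with one row per bin: ``hit_count``,
    ``first_hit_time`` (first hitting fixation onset inside the bin,
    NaN if none), ``mean_dwell`` (mean duration of hitting fixations,
    NaN if none) and ``cumulative_hit_count``.  A fixation belongs to
    the bin containing its onset.
    """
    pts = np.asarray(depth_points, dtype=float).reshape(-1, 2)
    n_bins = int(np.ceil(horizon_s / bin_width_s))
    hit_count = np.zeros(n_bins, dtype=int)
    first_hit = np.full(n_bins, np.nan)
    dwell_sum = np.zeros(n_bins)
    if len(pts) == 0:
        logger.info("no depth annotation: depth analysis yields empty counts")
    else:
        for fx in fixations:
            if fx.onset >= horizon_s:
                continue
            d = np.hypot(pts[:, 0] - fx.x, pts[:, 1] - fx.y)
            if d.min() <= radius:
                b = int(fx.onset // bin_width_s)
                hit_count[b] += 1
                dwell_sum[b] += fx.duration
                if np.isnan(first_hit[b]) or fx.onset < first_hit[b]:
                    first_hit[b] = fx.onset
    with np.errstate(invalid="ignore"):
        mean_dwell = np.where(hit_count > 0, dwell_sum / np.maximum(hit_count, 1),
                              np.nan)
    return pd.DataFrame({
        "bin": np.arange(n_bins),
        "t_start": np.arange(n_bins) * bin_width_s,
        "t_end": (np.arange(n_bins) + 1) * bin_width_s,
        "hit_count": hit_count,
        "first_hit_time": first_hit,
        "mean_dwell": mean_dwell,
        "cumulative_hit_count": np.cumsum(hit_count),
    })


def cumulative_comparison(summaries: dict, groups: GroupAssignment,
                          unit: str = "episode") -> pd.DataFrame:
    """Group comparison of cumulative depth hit counts per window.

    ``summaries`` maps (participant_id, artwork_id) to the DataFrame
    from :func:`depth_hits`.  For each cumulative window [0, t_end) a
    Wilcoxon rank-sum test compares the cumulative hit counts between
    high and low artwork groups; its own BH-FDR family.  Effect sign:
    positive = high group more hits.
    """
    rows = []
    for (pid, aid), df in summaries.items():
        g = groups.group.get(aid)
        if g is None:
            raise DataError(f"artwork {aid!r} has no group assignment")
        for r in df.itertuples(index=False):
            rows.append({
                "participant": pid, "artwork": aid, "group": g,
                "bin": r.bin, "t_end": r.t_end,
                "value": r.cumulative_hit_count,
            })
    tidy = pd.DataFrame(rows)
    out_rows = []
    for b, sub in tidy.groupby("bin"):
        t_end = float(sub["t_end"].iloc[0])
        if unit == "artwork":
            sub = sub.groupby(["group", "artwork"], as_index=False)["value"].mean()
        elif unit == "participant":
            sub = sub.groupby(["group", "participant"], as_index=False)["value"].mean()
        high = sub.loc[sub["group"] == "high", "value"].to_numpy()
        low = sub.loc[sub["group"] == "low", "value"].to_numpy()
        row = {"bin": int(b), "window": f"0-{t_end:g} s",
               "n_high": len(high), "n_low": len(low)}
        if len(high) < 2 or len(low) < 2:
            row.update(z=np.nan, p=np.nan, r=np.nan, testable=False)
        else:
            wr = wilcoxon_rank_sum(high, low)
            row.update(z=wr.z, p=wr.p,
                       r=rank_biserial(wr.z, wr.n_a + wr.n_b),
                       testable=True)
        out_rows.append(row)
    out = pd.DataFrame(out_rows).sort_values("bin").reset_index(drop=True)
    out["q"] = np.nan
    mask = out["testable"].fillna(False).astype(bool)
    if mask.any():
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out


@dataclass
class PreferenceTrial:
    """One 2AFC preference trial: gaze stream, options and decision."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    decision_time: float
    chosen: str                               # "left" | "right"
    left_box: tuple[float, float, float, float]
    right_box: tuple[float, float, float, float]
    presentation_constraint_s: float | None = None

    def __post_init__(self) -> None:
        if self.decision_time <= 0:
            raise DataError("decision_time must be positive")
        if self.chosen not in ("left", "right"):
            raise DataError(f"chosen must be left/right, got {self.chosen!r}")


def _in_box(x, y, box) -> np.ndarray:
    x0, y0, x1, y1 = box
    return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)


def choice_gaze_probability(trials: list[PreferenceTrial],
                            n_time_bins: int = 10) -> pd.DataFrame:
    """Gaze-cascade curve: P(gaze on chosen) vs normalised time.

    Each trial's timeline is rescaled to [0, 1] with 1 = decision; per
    bin the fraction of valid in-region samples on the chosen option is
    computed and averaged across trials.  Samples outside both option
    regions are excluded from the denominator (their fraction is
    reported).  The last bin is the decision-proximal estimate.
    """
    if not trials:
        raise DataError("need at least one trial")
    edges = np.linspace(0.0, 1.0, n_time_bins + 1)
    per_trial = np.full((len(trials), n_time_bins), np.nan)
    excluded = 0
    total = 0
    for i, tr in enumerate(trials):
        frac_t = np.asarray(tr.t) / tr.decision_time
        chosen_box = tr.left_box if tr.chosen == "left" else tr.right_box
        other_box = tr.right_box if tr.chosen == "left" else tr.left_box
        on_chosen = _in_box(tr.x, tr.y, chosen_box)
        on_other = _in_box(tr.x, tr.y, other_box)
        usable = tr.valid & (on_chosen | on_other)
        excluded += int((tr.valid & ~usable).sum())
        total += int(tr.valid.sum())
        which = np.clip(np.searchsorted(edges, frac_t, side="right") - 1,
                        0, n_time_bins - 1)
        for b in range(n_time_bins):
            m = usable & (which == b)
            if m.any():
                per_trial[i, b] = on_chosen[m].mean()
    if total:
        logger.info("choice curve: %.2f%% of valid samples outside both "
                    "option regions", 100.0 * excluded / total)
    have = ~np.isnan(per_trial)
    n_trials = have.sum(axis=0)
    sums = np.where(have, per_trial, 0.0).sum(axis=0)
    curve = np.where(n_trials > 0, sums / np.maximum(n_trials, 1), np.nan)
    sem = np.full(n_time_bins, np.nan)
    for b in range(n_time_bins):
        vals = per_trial[~np.isnan(per_trial[:, b]), b]
        if len(vals) > 1:
            sem[b] = vals.std(ddof=1) / np.sqrt(len(vals))
    return pd.DataFrame({
        "bin": np.arange(n_time_bins),
        "time_lo": edges[:-1],
        "time_hi": edges[1:],
        "p_gaze_chosen": curve,
        "sem": sem,
        "n_trials": n_trials,
        "final_bin": np.arange(n_time_bins) == n_time_bins - 1,
    })
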