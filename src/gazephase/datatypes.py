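"""Core data model for self-paced art-viewing gaze studies.

A study is a set of *viewing episodes*: one participant looking at one
artwork until they click to report an aesthetic rating (1-10).  Episodes
carry the raw gaze stream as flat numpy arrays (time, x, y, validity)
rather than per-sample objects, because a single episode at 300 Hz holds
thousands of samples and every downstream stage is vectorised.

Coordinate convention: origin top-left, y increases downward, positions
normalised to the half-open unit square [0, 1) x [0, 1); time in seconds
with 0 = stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GazeSample",
    "Fixation",
    "ViewingEpisode",
    "StimulusInfo",
]


@dataclass(frozen=True)
class GazeSample:
    """A single gaze sample (convenience view; episodes store arrays)."""

    t: float
    x: float
    y: float
    valid: bool = True


@dataclass(frozen=True)
class Fixation:
    """A dispersion-defined fixation with its centroid in normalised units."""

    onset: float
    duration: float
    x: float
    y: float

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class ViewingEpisode:
    """One participant x artwork self-paced viewing episode.

    Parameters
    ----------
    t, x, y : ndarray
        Sample times (seconds from stimulus onset, strictly increasing)
        and gaze positions.  Positions are in pixels until
        :func:`gazephase.io.normalize_coordinates` is applied.
    valid : ndarray of bool
        Per-sample validity (tracker loss, out-of-bounds, blinks).
    judgment_time : float or None
        Time of the mouse click establishing the judgment; None for
        fixed-duration conditions.
    rating : int or None
        Aesthetic rating on the 1-10 scale.
    """

    participant_id: str
    artwork_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    judgment_time: float | None = None
    rating: int | None = None
    fixations: list[Fixation] | None = None
    rejected: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if self.rating is not None and not (1 <= int(self.rating) <= 10):
            raise ValueError(f"rating must be in 1..10, got {self.rating}")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Episode duration: last sample time plus one nominal interval."""
        if len(self.t) == 0:
            return 0.0
        if len(self.t) == 1:
            return float(self.t[0])
        dt = float(np.median(np.diff(self.t)))
        return float(self.t[-1]) + dt

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if len(self.valid) else 0.0

    def samples(self):
        """Iterate samples as :class:`GazeSample` records."""
        for ti, xi, yi, vi in zip(self.t, self.x, self.y, self.valid):
            yield GazeSample(float(ti), float(xi), float(yi), bool(vi))

    def copy(self, **changes) -> "ViewingEpisode":
        out = replace(self, **changes)
        # replace() shares arrays; copy any not explicitly overridden
        for name in ("t", "x", "y", "valid"):
            if name not in changes:
                setattr(out, name, getattr(self, name).copy())
        return out


@dataclass
class StimulusInfo:
    """Stimulus metadata: pixel dimensions and optional depth-cue points.

    Depth points are annotated locations carrying pictorial depth cues,
    given in normalised coordinates; they drive the supplementary
    depth-fixation analysis.
    """

    artwork_id: str
    width_px: float
    height_px: float
    depth_points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            from .exceptions import ConfigurationError

            raise ConfigurationError(
                f"stimulus {self.artwork_id!r}: dimensions must be positive, "
                f"got {self.width_px} x {self.height_px}"
            )
        for p in self.depth_points:
            if not (0 <= p[0] <= 1 and 0 <= p[1] <= 1):
                from .exceptions import ConfigurationError

                raise ConfigurationError(
                    f"depth point {p} outside the unit square"
                )
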