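"""Frame-by-frame RULA scoring of joint-angle time series.

An inertial motion-capture take is represented as an :class:`AngleStream`:
an ordered sequence of complete posture descriptions sampled at a fixed
rate over a capture window (typically 30 s of static seated work).  Every
frame is scored independently through the RULA chain, and the take is
summarised by the relative time spent in each grand-score level 1-7.  The
time-weighted mean over levels (which equals the arithmetic mean of the
per-frame grand scores) gives a continuous overall score, and per-region
sub-scores are averaged the same way — which is why aggregated RULA values
are generally non-integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import ANGLE_FIELDS, FLAG_FIELDS, MODIFIER_FIELDS, RulaInputs, RulaResult, score_posture_arrays
from .errors import InputError

__all__ = [
    "AngleStream",
    "ScoreDistribution",
    "REGIONS",
    "score_stream",
    "time_distribution",
    "aggregate_rula",
    "summarize_stream",
]

#: Body regions reported alongside the overall score.
REGIONS = ("upper_arm", "lower_arm", "wrist", "neck", "trunk")

STREAM_FIELDS = ANGLE_FIELDS + FLAG_FIELDS + MODIFIER_FIELDS


@dataclass
class AngleStream:
    """A fixed-rate sequence of postures from one capture."""

    rate: float
    frames: list[RulaInputs]

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise InputError(f"sampling rate must be positive, got {self.rate}")
        if len(self.frames) == 0:
            raise InputError("angle stream must contain at least one frame")

    @property
    def duration(self) -> float:
        """Capture length in seconds."""
        return len(self.frames) / self.rate

    def to_arrays(self) -> dict[str, np.ndarray]:
        """Column arrays (one per posture field) for vectorised scoring."""
        cols: dict[str, np.ndarray] = {}
        for name in ANGLE_FIELDS:
            cols[name] = np.array([getattr(fr, name) for fr in self.frames], dtype=float)
        for name in FLAG_FIELDS:
            cols[name] = np.array([getattr(fr, name) for fr in self.frames], dtype=bool)
        for name in MODIFIER_FIELDS:
            cols[name] = np.array([getattr(fr, name) for fr in self.frames], dtype=int)
        return cols


@dataclass
class ScoreDistribution:
    """Relative time spent in each grand-score level plus region means."""

    level_fraction: dict[int, float]
    per_region_mean: dict[str, float]
    n_frames: int

    def __post_init__(self) -> None:
        total = sum(self.level_fraction.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"level fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.level_fraction.values()):
            raise InputError("level fractions must be non-negative")


def _scored_columns(stream: AngleStream) -> dict[str, np.ndarray]:
    cols = stream.to_arrays()
    for name in ANGLE_FIELDS:
        bad = ~np.isfinite(cols[name])
        if bad.any():
            idx = int(np.argmax(bad))
            raise InputError(f"frame {idx}: non-finite {name}")
    return score_posture_arrays(**{name: cols[name] for name in STREAM_FIELDS})


def score_stream(stream: AngleStream) -> list[RulaResult]:
    """Score every frame, preserving order; errors name the offending frame."""
    scored = _scored_columns(stream)
    fields = RulaResult._fields
    return [RulaResult(*row) for row in zip(*(scored[f].tolist() for f in fields))]


def time_distribution(scores: Sequence[RulaResult]) -> ScoreDistribution:
    """Fraction of frames at each grand level 1-7 and mean region sub-scores."""
    if len(scores) == 0:
        raise InputError("cannot summarise an empty score sequence")
    n = len(scores)
    grands = np.array([s.grand for s in scores])
    level_fraction = {k: float(np.count_nonzero(grands == k)) / n for k in range(1, 8)}
    per_region_mean = {
        region: float(np.mean([getattr(s, region) for s in scores])) for region in REGIONS
    }
    return ScoreDistribution(level_fraction, per_region_mean, n)


def aggregate_rula(dist: ScoreDistribution) -> dict[str, float]:
    """Continuous scores: overall = sum(level * fraction) plus region means.

    The overall value is algebraically identical to the arithmetic mean of
    the per-frame grand scores and always lies in [1, 7].
    """
    overall = float(sum(k * f for k, f in dist.level_fraction.items()))
    out = {"overall": overall}
    out.update(dist.per_region_mean)
    return out


def summarize_stream(stream: AngleStream) -> tuple[ScoreDistribution, dict[str, float]]:
    """Distribution and aggregates in one pass without materialising results."""
    scored = _scored_columns(stream)
    n = scored["grand"].size
    level_fraction = {
        k: float(np.count_nonzero(scored["grand"] == k)) / n for k in range(1, 8)
    }
    per_region_mean = {region: float(scored[region].mean()) for region in REGIONS}
    dist = ScoreDistribution(level_fraction, per_region_mean, n)
    return dist, aggregate_rula(dist)
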