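"""Social-preference assay analysis.

The test area of the rectangular chamber is split at its midline into two
equal halves: the half adjacent to the occupied stimulus area is the
*social* region of interest (ROI), the other half the *antisocial* ROI.
The outcome measure is the percentage of tracked time the fish spends in
the social ROI over the analysis window (the last 10 min of the 12 min
test phase, since stimulus fish need up to 2 min to settle).

Fish with reduced motion (freezing) are excluded: per age group, the mean
swim speed of each genotype group is computed and 0.6 times the smallest
group mean is the exclusion threshold; fish at or above the threshold are
included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, UndefinedStatisticError
from .geometry import Rect, RectangularChamber
from .trajectory import TrajectorySet, Window, mean_swim_speed


@dataclass(frozen=True)
class RegionOfInterest:
    """One half of the test area, in chamber coordinates (mm).

    Boundary tie rule (deterministic, measure-zero on continuous data):
    points exactly on the midline belong to the *social* ROI, so
    ``include_max_x`` / ``include_min_x`` flags mark which vertical edges
    are closed; horizontal (y) edges are always closed.
    """

    label: str  # "social" | "antisocial"
    rect: Rect
    include_min_x: bool = True
    include_max_x: bool = True

    def contains(self, x, y):
        x = np.asarray(x)
        y = np.asarray(y)
        in_x_lo = x >= self.rect.x0 if self.include_min_x else x > self.rect.x0
        in_x_hi = x <= self.rect.x1 if self.include_max_x else x < self.rect.x1
        return in_x_lo & in_x_hi & (y >= self.rect.y0) & (y <= self.rect.y1)


@dataclass(frozen=True)
class AssayProtocol:
    """Phase structure of the preference assay (seconds).

    Default: 10 min habituation, 12 min test, scored over the last 10 min
    of test.
    """

    habituation_s: float = 600.0
    test_s: float = 720.0
    analysis_last_s: float = 600.0

    def __post_init__(self) -> None:
        if min(self.habituation_s, self.test_s, self.analysis_last_s) < 0:
            raise ConfigurationError("protocol durations must be >= 0")
        if self.analysis_last_s > self.test_s:
            raise ConfigurationError("analysis window must lie within the test phase")

    @property
    def total_s(self) -> float:
        return self.habituation_s + self.test_s

    def habituation_window(self, frame_rate_hz: float) -> Window:
        return (0, int(round(self.habituation_s * frame_rate_hz)))

    def test_window(self, frame_rate_hz: float) -> Window:
        return (
            int(round(self.habituation_s * frame_rate_hz)),
            int(round(self.total_s * frame_rate_hz)),
        )

    def analysis_window(self, frame_rate_hz: float) -> Window:
        end = int(round(self.total_s * frame_rate_hz))
        return (end - int(round(self.analysis_last_s * frame_rate_hz)), end)


@dataclass(frozen=True)
class PreferenceResult:
    """Scored assay for one test fish."""

    percent_time_social: float
    mean_speed_test: float
    mean_speed_habituation: float
    included: bool
    threshold_applied: float
    window: Window


def build_rois(geometry: RectangularChamber) -> tuple[RegionOfInterest, RegionOfInterest]:
    """Split the test area at its midline into (social, antisocial) ROIs.

    The half adjacent to the occupied stimulus area is social. The two
    ROIs partition the test area: the midline itself counts as social.
    """
    if geometry.stimulus_side is None:
        raise ConfigurationError("geometry has no stimulus_side; cannot assign ROIs")
    test = geometry.test_area
    mid = geometry.midline_x
    left = Rect(test.x0, test.y0, mid, test.y1)
    right = Rect(mid, test.y0, test.x1, test.y1)
    if geometry.stimulus_side == "left":
        social = RegionOfInterest("social", left, include_min_x=True, include_max_x=True)
        antisocial = RegionOfInterest("antisocial", right, include_min_x=False, include_max_x=True)
    else:
        social = RegionOfInterest("social", right, include_min_x=True, include_max_x=True)
        antisocial = RegionOfInterest("antisocial", left, include_min_x=True, include_max_x=False)
    return social, antisocial


def fraction_time_in_roi(ts: TrajectorySet, roi: RegionOfInterest,
                         window: Window | None = None) -> float:
    """Percent of tracked frames in ``window`` the (single) fish spends in
    the ROI: 100 x (non-missing frames inside) / (non-missing frames)."""
    if ts.n_fish != 1:
        raise ConfigurationError("fraction_time_in_roi expects a single-fish TrajectorySet")
    start, end = ts.check_window(window if window is not None else (0, ts.n_frames))
    pos = ts.positions[0, start:end]
    ok = ~np.isnan(pos[:, 0])
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise UndefinedStatisticError("all frames in window missing; occupancy undefined")
    inside = roi.contains(pos[ok, 0], pos[ok, 1])
    return 100.0 * float(inside.sum()) / n_ok


def exclusion_threshold(group_mean_speeds: Sequence[float] | Iterable[float]) -> float:
    """Speed threshold for excluding freezing fish: 0.6 x the smallest
    genotype-group mean speed (computed per age group)."""
    speeds = list(group_mean_speeds)
    if not speeds:
        raise ConfigurationError("need at least one group mean speed")
    if any(s < 0 for s in speeds):
        raise ConfigurationError("group mean speeds must be >= 0")
    return 0.6 * min(speeds)


def score_assay(ts: TrajectorySet, protocol: AssayProtocol,
                geometry: RectangularChamber | None = None,
                threshold: float = 0.0,
                exclusion_basis: str = "test") -> PreferenceResult:
    """Score one assay recording.

    Computes the percent time in the social ROI over the analysis window,
    the mean swim speeds of both phases, and the inclusion flag
    ``speed >= threshold`` (a fish exactly at the threshold is included).
    A fish that never moved (speed 0) is always excluded as frozen, even
    when the cohort-derived threshold is 0. ``exclusion_basis`` selects
    which speed gates exclusion: ``"test"`` (default), ``"habituation"``
    or ``"min"`` of both.
    """
    if geometry is None:
        if not isinstance(ts.arena, RectangularChamber):
            raise ConfigurationError("trajectory arena is not a rectangular chamber")
        geometry = ts.arena
    needed = int(round(protocol.total_s * ts.frame_rate_hz))
    if ts.n_frames < needed:
        raise ConfigurationError(
            f"trajectory has {ts.n_frames} frames, protocol needs {needed}"
        )
    social, _ = build_rois(geometry)
    window = protocol.analysis_window(ts.frame_rate_hz)
    percent = fraction_time_in_roi(ts, social, window)
    fish = ts.fish_ids[0]
    speed_hab = mean_swim_speed(ts, fish, protocol.habituation_window(ts.frame_rate_hz))
    speed_test = mean_swim_speed(ts, fish, protocol.test_window(ts.frame_rate_hz))
    basis = {"test": speed_test, "habituation": speed_hab,
             "min": min(speed_test, speed_hab)}
    if exclusion_basis not in basis:
        raise ConfigurationError(f"unknown exclusion_basis {exclusion_basis!r}")
    return PreferenceResult(
        percent_time_social=percent,
        mean_speed_test=speed_test,
        mean_speed_habituation=speed_hab,
        included=bool(basis[exclusion_basis] >= threshold and basis[exclusion_basis] > 0),
        threshold_applied=float(threshold),
        window=window,
    )
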