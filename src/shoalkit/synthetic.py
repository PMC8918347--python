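"""Synthetic trajectory generators with known ground truth.

Three generators cover the needs of the two assays:

* :func:`simulate_shared_motion_shoal` — each fish's position is the sum of
  a shared centroid process and an independent per-fish process, both
  stationary mean-reverting (AR(1)/discretized Ornstein-Uhlenbeck) walks.
  The coordination level ``rho = sigma_shared^2 / (sigma_shared^2 +
  sigma_idio^2)`` fixes the population variance explained by the first two
  principal components of the trajectory matrix in closed form
  (:func:`expected_variance_explained`), giving an exact analytic target
  for the polarization statistic.
* :func:`simulate_zonal_shoal` — a standard repulsion/alignment/attraction
  agent model for qualitatively realistic shoals (no analytic target).
* :func:`simulate_preference_fish` — a single fish performing a biased
  random walk in the preference-chamber test area, with drift ``beta``
  (mm/s) toward the stimulus wall; ``beta = 0`` gives 50% expected
  occupancy of the social half by symmetry.

All generators are deterministic for a fixed seed; a single integer seed is
expanded into independent per-fish substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigurationError
from .geometry import ArenaGeometry, CircularArena, RectangularChamber, Rect
from .trajectory import TrajectorySet


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SharedMotionParams:
    """Shared + idiosyncratic stationary-motion shoal model.

    ``sigma_shared`` and ``sigma_idio`` are the per-coordinate stationary
    standard deviations (mm) of the shared centroid process and of each
    fish's own process. ``relaxation_time_s`` is the mean-reversion time
    constant of both processes; it controls the frame-to-frame
    autocorrelation but not the stationary covariance, so the closed-form
    variance explained depends only on rho and the shoal size.
    """

    n_fish: int = 20
    duration_s: float = 1800.0
    frame_rate_hz: float = 30.0
    sigma_shared: float = 35.0
    sigma_idio: float = 35.0
    relaxation_time_s: float = 0.25
    arena: ArenaGeometry = field(default_factory=CircularArena)
    reflect: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 2:
            raise ConfigurationError("n_fish must be >= 2")
        if self.sigma_shared < 0 or self.sigma_idio < 0:
            raise ConfigurationError("sigmas must be >= 0")
        if self.sigma_shared == 0 and self.sigma_idio == 0:
            raise ConfigurationError("at least one sigma must be > 0")
        if self.duration_s * self.frame_rate_hz < 2:
            raise ConfigurationError("need at least 2 frames")
        if self.relaxation_time_s <= 0:
            raise ConfigurationError("relaxation_time_s must be > 0")

    @property
    def rho(self) -> float:
        """Coordination level in [0, 1]."""
        tot = self.sigma_shared**2 + self.sigma_idio**2
        return self.sigma_shared**2 / tot

    @classmethod
    def from_rho(cls, rho: float, sigma_total: float = 50.0, **kwargs) -> "SharedMotionParams":
        """Build params with a given coordination level and total
        per-coordinate SD ``sigma_total = sqrt(sigma_shared^2 + sigma_idio^2)``."""
        if not 0.0 <= rho <= 1.0:
            raise ConfigurationError("rho must lie in [0, 1]")
        return cls(
            sigma_shared=sigma_total * float(np.sqrt(rho)),
            sigma_idio=sigma_total * float(np.sqrt(1.0 - rho)),
            **kwargs,
        )


@dataclass(frozen=True)
class ZonalParams:
    """Repulsion/alignment/attraction agent model parameters."""

    n_fish: int = 20
    duration_s: float = 60.0
    frame_rate_hz: float = 30.0
    r_repulsion: float = 15.0
    r_alignment: float = 60.0
    r_attraction: float = 250.0
    speed_mm_s: float = 40.0
    turning_noise_sd: float = 0.25  # rad per frame
    arena: CircularArena = field(default_factory=CircularArena)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 2:
            raise ConfigurationError("n_fish must be >= 2")
        if not (0 < self.r_repulsion < self.r_alignment < self.r_attraction):
            raise ConfigurationError("zone radii must satisfy 0 < r_rep < r_align < r_attr")
        if self.speed_mm_s <= 0 or self.turning_noise_sd < 0:
            raise ConfigurationError("speed must be > 0 and noise >= 0")


@dataclass(frozen=True)
class PreferenceSimParams:
    """Single-fish biased random walk in the preference chamber test area."""

    geometry: RectangularChamber = field(
        default_factory=lambda: RectangularChamber(stimulus_side="left")
    )
    beta: float = 0.0  # drift toward the stimulus wall, mm/s
    step_sd_mm: float = 0.5  # per-coordinate Gaussian step SD per frame
    frame_rate_hz: float = 20.0
    duration_s: float = 1320.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry.stimulus_side is None:
            raise ConfigurationError("geometry needs stimulus_side for a preference run")
        if self.beta < 0:
            raise ConfigurationError("beta must be >= 0")
        if self.step_sd_mm <= 0:
            raise ConfigurationError("step_sd_mm must be > 0")
        if self.duration_s * self.frame_rate_hz < 2:
            raise ConfigurationError("need at least 2 frames")


# ---------------------------------------------------------------------------
# generators


def _n_frames(duration_s: float, frame_rate_hz: float) -> int:
    return max(2, int(round(duration_s * frame_rate_hz)))


def _ou_series(t: int, n_series: int, sigma: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series, shape (t, n_series), stationary SD sigma."""
    if sigma == 0.0:
        return np.zeros((t, n_series))
    w = rng.standard_normal((t, n_series)) * (sigma * np.sqrt(1.0 - phi**2))
    w[0] = rng.standard_normal(n_series) * sigma  # start in the stationary law
    return lfilter([1.0], [1.0, -phi], w, axis=0)


def _fold(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map unconstrained coordinates into [lo, hi] by mirror reflection."""
    period = 2.0 * (hi - lo)
    y = np.mod(values - lo, period)
    return lo + np.minimum(y, period - y)


def simulate_shared_motion_shoal(p: SharedMotionParams) -> TrajectorySet:
    """Simulate a shoal under the shared-motion model.

    Fish i at frame t sits at ``center + c(t) + e_i(t)`` with c and the e_i
    independent stationary mean-reverting walks. With ``reflect=False``
    (default) the stationary covariance per axis is exactly
    ``sigma_shared^2 J + sigma_idio^2 I`` and the closed form of
    :func:`expected_variance_explained` holds; with reflection the walk is
    folded into the arena bounding box and the closed form is only
    approximate.
    """
    t = _n_frames(p.duration_s, p.frame_rate_hz)
    phi = float(np.exp(-1.0 / (p.frame_rate_hz * p.relaxation_time_s)))
    streams = np.random.SeedSequence(p.seed).spawn(p.n_fish + 1)
    shared_rng = np.random.default_rng(streams[0])
    c = _ou_series(t, 2, p.sigma_shared, phi, shared_rng)  # (T, 2)
    positions = np.empty((p.n_fish, t, 2))
    for i in range(p.n_fish):
        rng = np.random.default_rng(streams[i + 1])
        e = _ou_series(t, 2, p.sigma_idio, phi, rng)
        positions[i] = c + e
    bounds = p.arena.bounds
    cx, cy = bounds.center
    positions[..., 0] += cx
    positions[..., 1] += cy
    if p.reflect:
        positions[..., 0] = _fold(positions[..., 0], bounds.x0, bounds.x1)
        positions[..., 1] = _fold(positions[..., 1], bounds.y0, bounds.y1)
    return TrajectorySet(
        fish_ids=[f"fish{i:02d}" for i in range(p.n_fish)],
        positions=positions,
        frame_rate_hz=p.frame_rate_hz,
        arena=p.arena,
        source_id=f"shared-motion-seed{p.seed}",
        extra_metadata={"model": "shared_motion", "rho": p.rho,
                        "sigma_shared": p.sigma_shared, "sigma_idio": p.sigma_idio,
                        "seed": p.seed},
    )


def expected_variance_explained(p: SharedMotionParams) -> float:
    """Population variance explained by the top two PCs under the
    shared-motion model: ``rho + (1 - rho) / n_fish``.

    Per axis the N x N stationary covariance is ``sigma_shared^2 J +
    sigma_idio^2 I`` with top eigenvalue ``N sigma_shared^2 + sigma_idio^2``
    and the remaining N-1 eigenvalues ``sigma_idio^2``; the x and y blocks
    are independent, so the top two of the 2N eigenvalues (one per axis)
    capture the stated fraction of the total variance.
    """
    return p.rho + (1.0 - p.rho) / p.n_fish


def simulate_zonal_shoal(p: ZonalParams) -> TrajectorySet:
    """Simulate a shoal with the classic three-zone interaction rules.

    Per frame each fish turns directly away from neighbors inside the
    repulsion zone; otherwise it averages the headings of neighbors in the
    alignment zone and steers toward neighbors in the attraction zone.
    Angular noise is added every frame; speed is constant; the circular
    wall reflects.
    """
    t = _n_frames(p.duration_s, p.frame_rate_hz)
    n = p.n_fish
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    radius = p.arena.radius_mm
    cx, cy = p.arena.center
    # dispersed start: uniform in the disc of 0.9 R
    r0 = 0.9 * radius * np.sqrt(rng.random(n))
    a0 = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([cx + r0 * np.cos(a0), cy + r0 * np.sin(a0)])
    heading = rng.uniform(0, 2 * np.pi, n)
    step = p.speed_mm_s / p.frame_rate_hz
    noise = rng.normal(0.0, p.turning_noise_sd, size=(t, n))

    out = np.empty((n, t, 2))
    out[:, 0] = pos
    for k in range(1, t):
        diff = pos[None, :, :] - pos[:, None, :]  # toward neighbor j from i
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        desired = np.empty(n)
        for i in range(n):
            rep = dist[i] < p.r_repulsion
            if rep.any():
                v = -diff[i, rep] / dist[i, rep, None]
                d = v.sum(axis=0)
            else:
                d = np.zeros(2)
                ali = dist[i] < p.r_alignment
                if ali.any():
                    d += np.array([np.cos(heading[ali]).sum(), np.sin(heading[ali]).sum()])
                att = (dist[i] >= p.r_alignment) & (dist[i] < p.r_attraction)
                if att.any():
                    v = diff[i, att] / dist[i, att, None]
                    d += v.sum(axis=0)
            desired[i] = heading[i] if not d.any() else np.arctan2(d[1], d[0])
        heading = desired + noise[k]
        pos = pos + step * np.column_stack([np.cos(heading), np.sin(heading)])
        # reflect off the circular wall radially and head back inside
        dx, dy = pos[:, 0] - cx, pos[:, 1] - cy
        r = np.hypot(dx, dy)
        outside = r > radius
        if outside.any():
            scale = (2 * radius - r[outside]) / r[outside]
            pos[outside, 0] = cx + dx[outside] * scale
            pos[outside, 1] = cy + dy[outside] * scale
            heading[outside] = np.arctan2(cy - pos[outside, 1], cx - pos[outside, 0])
        out[:, k] = pos
    return TrajectorySet(
        fish_ids=[f"fish{i:02d}" for i in range(n)],
        positions=out,
        frame_rate_hz=p.frame_rate_hz,
        arena=p.arena,
        source_id=f"zonal-seed{p.seed}",
        extra_metadata={"model": "zonal", "seed": p.seed},
    )


def _biased_walk(rect: Rect, drift: tuple[float, float], step_sd: float,
                 t: int, rng: np.random.Generator, start: tuple[float, float]) -> np.ndarray:
    """Reflected biased random walk inside a rectangle; (t, 2) array."""
    steps = rng.normal(0.0, step_sd, size=(t - 1, 2))
    steps[:, 0] += drift[0]
    steps[:, 1] += drift[1]
    pos = np.empty((t, 2))
    pos[0] = start
    x, y = start
    for k in range(1, t):
        x = x + steps[k - 1, 0]
        y = y + steps[k - 1, 1]
        if not rect.x0 <= x <= rect.x1:
            x = float(_fold(np.array(x), rect.x0, rect.x1))
        if not rect.y0 <= y <= rect.y1:
            y = float(_fold(np.array(y), rect.y0, rect.y1))
        pos[k, 0] = x
        pos[k, 1] = y
    return pos


def simulate_preference_fish(p: PreferenceSimParams) -> TrajectorySet:
    """Simulate a single test fish in the chamber's test area.

    Per frame the displacement is an isotropic Gaussian step plus
    ``beta / frame_rate_hz`` of drift toward the occupied stimulus wall;
    walls of the test area reflect. The fish starts at the test-area
    center, where a real test fish is released.
    """
    t = _n_frames(p.duration_s, p.frame_rate_hz)
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    rect = p.geometry.test_area
    sign = -1.0 if p.geometry.stimulus_side == "left" else 1.0
    drift = (sign * p.beta / p.frame_rate_hz, 0.0)
    pos = _biased_walk(rect, drift, p.step_sd_mm, t, rng, rect.center)
    return TrajectorySet(
        fish_ids=["fish00"],
        positions=pos[None, :, :],
        frame_rate_hz=p.frame_rate_hz,
        arena=p.geometry,
        source_id=f"preference-seed{p.seed}",
        extra_metadata={"model": "preference", "beta": p.beta, "seed": p.seed},
    )


def simulate_preference_assay(p: PreferenceSimParams, habituation_s: float = 600.0,
                              test_s: float = 720.0) -> TrajectorySet:
    """Simulate a full assay: unbiased walk during habituation (no stimulus
    fish present), then the biased walk of ``p`` during the test phase,
    continuous in position."""
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    rect = p.geometry.test_area
    t_hab = int(round(habituation_s * p.frame_rate_hz))
    t_test = int(round(test_s * p.frame_rate_hz))
    hab = _biased_walk(rect, (0.0, 0.0), p.step_sd_mm, max(t_hab, 1), rng, rect.center)
    sign = -1.0 if p.geometry.stimulus_side == "left" else 1.0
    drift = (sign * p.beta / p.frame_rate_hz, 0.0)
    test = _biased_walk(rect, drift, p.step_sd_mm, t_test + 1, rng, tuple(hab[-1]))
    pos = np.vstack([hab, test[1:]])
    return TrajectorySet(
        fish_ids=["fish00"],
        positions=pos[None, :, :],
        frame_rate_hz=p.frame_rate_hz,
        arena=p.geometry,
        source_id=f"preference-assay-seed{p.seed}",
        extra_metadata={"model": "preference_assay", "beta": p.beta, "seed": p.seed,
                        "habituation_s": habituation_s, "test_s": test_s},
    )
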