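import numpy as np
import pytest

from shoalkit import (
    CircularArena,
    RectangularChamber,
    SharedMotionParams,
    TrajectorySet,
    simulate_shared_motion_shoal,
)


@pytest.fixture
def chamber_left() -> RectangularChamber:
    """Standard 2-4 wpf preference chamber, stimulus fish on the left."""
    return RectangularChamber(stimulus_side="left")


@pytest.fixture
def arena() -> CircularArena:
    return CircularArena()


@pytest.fixture
def small_shoal() -> TrajectorySet:
    """Deterministic 5-fish, 20 s shared-motion shoal."""
    return simulate_shared_motion_shoal(
        SharedMotionParams.from_rho(0.5, n_fish=5, duration_s=20, seed=42)
    )


@pytest.fixture
def gappy_shoal(small_shoal) -> TrajectorySet:
    """Same shoal with a few tracking dropouts punched in."""
    ts = small_shoal.copy()
    ts.positions[0, 5:8] = np.nan   # interior gap, length 3
    ts.positions[1, 0:2] = np.nan   # leading gap
    ts.positions[2, -1] = np.nan    # trailing gap
    return ts


@pytest.fixture
def triangle_shoal(arena) -> TrajectorySet:
    """Three fish frozen at (0,0), (3,4), (6,8): the 3-4-5 worked example."""
    pts = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]])
    positions = np.repeat(pts[:, None, :], 10, axis=1)
    return TrajectorySet(
        fish_ids=["a", "b", "c"],
        positions=positions,
        frame_rate_hz=30.0,
        arena=arena,
        source_id="triangle",
    )
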