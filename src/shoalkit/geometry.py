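"""Arena geometries for the two behavioral setups.

Coordinates are millimetres with the origin at the lower-left corner of the
arena's bounding rectangle (for the circular arena: its bounding square),
x increasing rightward and y upward.

The rectangular preference chamber is laid out left-to-right as
``stimulus | test | stimulus``: both stimulus areas share the full chamber
length, so a chamber with a 25 x 75 mm test area and 8 x 75 mm stimulus
areas spans 41 x 75 mm in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [x0, x1] x [y0, y1] in mm."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ConfigurationError(f"degenerate rectangle {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x, y, *, tol: float = 0.0):
        """Closed-rectangle membership, vectorized over x/y."""
        return (
            (np.asarray(x) >= self.x0 - tol)
            & (np.asarray(x) <= self.x1 + tol)
            & (np.asarray(y) >= self.y0 - tol)
            & (np.asarray(y) <= self.y1 + tol)
        )


@dataclass(frozen=True)
class RectangularChamber:
    """Social-preference chamber: one test area flanked by two stimulus areas.

    The standard chambers are 25 x 75 mm test / 8 x 75 mm stimulus areas for
    2-4 week-old fish and 50 x 75 mm / 16 x 75 mm for 8 week-old fish.
    ``stimulus_side`` marks which stimulus area holds the conspecifics.
    """

    test_width_mm: float = 25.0
    test_length_mm: float = 75.0
    stimulus_width_mm: float = 8.0
    stimulus_length_mm: float = 75.0
    stimulus_side: str | None = None  # "left" | "right" | None (empty chamber)

    def __post_init__(self) -> None:
        for name in ("test_width_mm", "test_length_mm", "stimulus_width_mm", "stimulus_length_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.stimulus_side not in (None, "left", "right"):
            raise ConfigurationError(f"invalid stimulus_side {self.stimulus_side!r}")

    @property
    def test_area(self) -> Rect:
        w = self.stimulus_width_mm
        return Rect(w, 0.0, w + self.test_width_mm, self.test_length_mm)

    @property
    def stimulus_left(self) -> Rect:
        return Rect(0.0, 0.0, self.stimulus_width_mm, self.stimulus_length_mm)

    @property
    def stimulus_right(self) -> Rect:
        w = self.stimulus_width_mm
        x0 = w + self.test_width_mm
        return Rect(x0, 0.0, x0 + w, self.stimulus_length_mm)

    @property
    def midline_x(self) -> float:
        """x of the line splitting the test area into the two ROI halves."""
        return self.stimulus_width_mm + 0.5 * self.test_width_mm

    @property
    def bounds(self) -> Rect:
        return Rect(
            0.0,
            0.0,
            2 * self.stimulus_width_mm + self.test_width_mm,
            max(self.test_length_mm, self.stimulus_length_mm),
        )

    def contains(self, x, y, *, tol: float = 1e-6):
        return self.bounds.contains(x, y, tol=tol)

    def mirrored(self) -> "RectangularChamber":
        """Same chamber with the occupied stimulus area on the other side."""
        if self.stimulus_side is None:
            return self
        other = "right" if self.stimulus_side == "left" else "left"
        return RectangularChamber(
            self.test_width_mm,
            self.test_length_mm,
            self.stimulus_width_mm,
            self.stimulus_length_mm,
            other,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "variant": "rectangular-chamber",
            "test_width_mm": self.test_width_mm,
            "test_length_mm": self.test_length_mm,
            "stimulus_width_mm": self.stimulus_width_mm,
            "stimulus_length_mm": self.stimulus_length_mm,
            "stimulus_side": self.stimulus_side,
        }


@dataclass(frozen=True)
class CircularArena:
    """Round shoaling arena; default diameter 700 mm."""

    diameter_mm: float = 700.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ConfigurationError("diameter_mm must be > 0")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    @property
    def center(self) -> tuple[float, float]:
        return (self.radius_mm, self.radius_mm)

    @property
    def bounds(self) -> Rect:
        d = self.diameter_mm
        return Rect(0.0, 0.0, d, d)

    def contains(self, x, y, *, tol: float = 1e-6):
        # bounding-square membership; the disc itself is only enforced by
        # generators with reflection enabled
        return self.bounds.contains(x, y, tol=tol)

    def to_dict(self) -> dict[str, Any]:
        return {"variant": "circular-arena", "diameter_mm": self.diameter_mm}


ArenaGeometry = RectangularChamber | CircularArena


def arena_from_dict(d: dict[str, Any]) -> ArenaGeometry:
    """Inverse of ``to_dict`` for both arena variants."""
    try:
        variant = d["variant"]
    except (KeyError, TypeError):
        raise ConfigurationError("arena metadata missing 'variant'")
    if variant == "rectangular-chamber":
        return RectangularChamber(
            test_width_mm=float(d["test_width_mm"]),
            test_length_mm=float(d["test_length_mm"]),
            stimulus_width_mm=float(d["stimulus_width_mm"]),
            stimulus_length_mm=float(d["stimulus_length_mm"]),
            stimulus_side=d.get("stimulus_side"),
        )
    if variant == "circular-arena":
        return CircularArena(diameter_mm=float(d["diameter_mm"]))
    raise ConfigurationError(f"unknown arena variant {variant!r}")
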