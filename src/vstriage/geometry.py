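"""Axis-aligned grid-box geometry shared by receptor prep, site clustering and engine configs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

Vec3 = Tuple[float, float, float]


@dataclass(frozen=True)
class Box:
    """An axis-aligned docking grid box.

    Attributes
    ----------
    centre : (x, y, z) in Å.
    edges : edge lengths (Å) along x, y, z.
    spacing : grid-point spacing in Å (AutoDock convention); ``None`` when
        the box is purely geometric (e.g. receptor bounds).
    """

    centre: Vec3
    edges: Vec3
    spacing: float | None = None

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.edges):
            raise ValueError(f"box edges must be non-negative, got {self.edges}")
        if self.spacing is not None and self.spacing <= 0:
            raise ValueError(f"grid spacing must be > 0, got {self.spacing}")

    @property
    def lo(self) -> Vec3:
        return tuple(c - e / 2.0 for c, e in zip(self.centre, self.edges))  # type: ignore[return-value]

    @property
    def hi(self) -> Vec3:
        return tuple(c + e / 2.0 for c, e in zip(self.centre, self.edges))  # type: ignore[return-value]

    @property
    def volume(self) -> float:
        ex, ey, ez = self.edges
        return ex * ey * ez

    def contains(self, point) -> bool:
        return all(l <= p <= h for l, p, h in zip(self.lo, point, self.hi))
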