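"""Two-dimensional cell geometry for simulated bacteria.

The cell body is modelled as the 2D projection of a spherocylinder: a
rectangle of length ``length - width`` capped by two semicircles of radius
``width / 2``, centred at the origin with the long axis along x.  All
coordinates are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylindrical cell outline plus the nucleoid/membrane partition.

    Parameters
    ----------
    length : float
        Pole-to-pole cell length (µm).
    width : float
        Cell width, i.e. diameter of the caps (µm).
    membrane_band : float
        Width of the boundary annulus counted as "membrane" (µm).
    nucleoid_axes : tuple of float
        Semi-axes (a, b) of the centred nucleoid ellipse (µm).  ``(0, 0)``
        means no nucleoid.
    """

    length: float = 3.0
    width: float = 1.0
    membrane_band: float = 0.173
    nucleoid_axes: tuple[float, float] = (1.0, 0.3)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.width > self.length:
            raise ValueError("width must not exceed length")
        if not self.membrane_band < self.width / 2:
            raise ValueError("membrane_band must be less than width/2")
        a, b = self.nucleoid_axes
        if a < 0 or b < 0:
            raise ValueError("nucleoid axes must be non-negative")
        # ellipse must fit strictly inside the cell interior
        if a >= self.length / 2 or b >= self.width / 2:
            raise ValueError("nucleoid ellipse must be contained in the cell")

    @property
    def radius(self) -> float:
        return self.width / 2

    @property
    def half_axis(self) -> float:
        """Half-length of the straight (cylindrical) part of the midline."""
        return max(self.length / 2 - self.radius, 0.0)

    def _axis_point(self, xy: np.ndarray) -> np.ndarray:
        """Closest point on the midline segment for each point (N, 2)."""
        ax = np.clip(xy[..., 0], -self.half_axis, self.half_axis)
        out = np.zeros_like(xy)
        out[..., 0] = ax
        return out

    def distance_from_midline(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return np.linalg.norm(xy - self._axis_point(xy), axis=-1)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the cell outline."""
        return self.distance_from_midline(xy) <= self.radius

    def in_nucleoid(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        a, b = self.nucleoid_axes
        if a == 0 or b == 0:
            return np.zeros(xy.shape[:-1], dtype=bool)
        return (xy[..., 0] / a) ** 2 + (xy[..., 1] / b) ** 2 <= 1.0

    def reflect(self, xy: np.ndarray) -> np.ndarray:
        """Specularly reflect points that left the cell back inside.

        Points are mirrored across the closest boundary point; the operation
        is iterated because a large excursion can bounce past the far wall.
        """
        xy = np.array(xy, dtype=float)
        for _ in range(32):
            d = self.distance_from_midline(xy)
            outside = d > self.radius
            if not np.any(outside):
                break
            c = self._axis_point(xy[outside])
            v = xy[outside] - c
            norm = np.linalg.norm(v, axis=-1, keepdims=True)
            # mirror across the boundary circle of radius r around c
            xy[outside] = c + v * (2 * self.radius / norm - 1.0)
        else:  # pragma: no cover - pathological step sizes are refused upstream
            d = self.distance_from_midline(xy)
            bad = d > self.radius
            c = self._axis_point(xy[bad])
            v = xy[bad] - c
            xy[bad] = c + v * (self.radius / np.linalg.norm(v, axis=-1, keepdims=True))
        return xy

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Rejection-sample n points uniformly over the cell area."""
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 16)
            cand = rng.uniform(
                [-self.length / 2, -self.width / 2],
                [self.length / 2, self.width / 2],
                size=(m, 2),
            )
            cand = cand[self.contains(cand)]
            take = min(len(cand), n - filled)
            out[filled : filled + take] = cand[:take]
            filled += take
        return out

    @property
    def area(self) -> float:
        r = self.radius
        return 2 * self.half_axis * self.width + np.pi * r**2
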