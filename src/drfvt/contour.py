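"""Closed-outline extraction from binary silhouettes.

The outer boundary of the first (raster-order) foreground component is
followed with an eight-direction adaptive tracking walk: from the current
boundary pixel the eight neighbours are probed in a fixed cyclic direction
order, starting from a search direction carried over from the previous
step, so the walk hugs the outside of the region until it returns to its
starting pixel.  The traced boundary is then parameterized as a complex
periodic signal ``z_l = x_l + i*y_l`` by uniform arc-length resampling, the
form consumed by the Fourier-descriptor stage.

Coordinate convention: ``x`` is the column index, ``y`` the row index,
origin at the top-left, 0-based.  Direction code 0 points east and codes
increase counterclockwise in 45-degree steps with "up" meaning a
*decreasing* row index (1 = northeast, 2 = north, ..., 7 = southeast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Contour",
    "TracingError",
    "NoForegroundError",
    "NonClosedBoundaryError",
    "trace_outline",
    "contour_to_signal",
]


class TracingError(ValueError):
    """Base class for outline-tracing failures."""


class NoForegroundError(TracingError):
    """The image contains no foreground pixel."""


class NonClosedBoundaryError(TracingError):
    """The boundary walk exceeded its step budget without returning home."""


# Neighbour offsets per direction code (0 = east, counterclockwise).
_DX = (1, 1, 0, -1, -1, -1, 0, 1)
_DY = (0, -1, -1, -1, 0, 1, 1, 1)

#: Initial search direction: probe "up" first from the raster-first pixel.
_INITIAL_DIRECTION = 2


@dataclass
class Contour:
    """Ordered outer boundary of a silhouette.

    ``points`` is an ``(n, 2)`` integer array of ``(x, y)`` pairs in
    traversal order; the closing point is implicit (stored once).
    Consecutive points are 8-neighbours.
    """

    points: np.ndarray
    closed: bool

    def __len__(self) -> int:
        return len(self.points)

    def as_complex(self) -> np.ndarray:
        """Boundary points as ``x + i*y``."""
        pts = np.asarray(self.points, dtype=float)
        return pts[:, 0] + 1j * pts[:, 1]

    def perimeter(self) -> float:
        """Polygonal length of the closed boundary."""
        pts = np.asarray(self.points, dtype=float)
        if len(pts) < 2:
            return 0.0
        closed = np.vstack([pts, pts[:1]])
        return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))

    def to_csv(self, path) -> None:
        """Write the boundary as a two-column ``x,y`` CSV."""
        np.savetxt(path, self.points, fmt="%d", delimiter=",",
                   header="x,y", comments="")


def trace_outline(image: np.ndarray, max_steps: int | None = None) -> Contour:
    """Trace the closed outer outline of a binary silhouette.

    Parameters
    ----------
    image
        2-D array; nonzero entries are foreground.  Only the component
        reached first in raster order (top-to-bottom, left-to-right) is
        traced; holes and further components are ignored.
    max_steps
        Safety budget for the boundary walk; defaults to ``4 * width *
        height``.  Exceeding it raises :class:`NonClosedBoundaryError`.

    Returns
    -------
    Contour
        Boundary points in traversal order, starting at the raster-first
        foreground pixel.  An isolated pixel yields a length-1 contour
        flagged not closed.
    """
    fg = np.asarray(image).astype(bool)
    if fg.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not fg.any():
        raise NoForegroundError("image has no foreground pixel")
    h, w = fg.shape
    limit = 4 * w * h if max_steps is None else max_steps

    # np.argwhere returns (row, col) in raster order.
    y0, x0 = (int(v) for v in np.argwhere(fg)[0])
    start = (x0, y0)
    points = [start]
    now = start
    d = _INITIAL_DIRECTION
    steps = 0
    while True:
        found = None
        for j in range(8):
            di = (d + j) % 8
            nx, ny = now[0] + _DX[di], now[1] + _DY[di]
            if 0 <= nx < w and 0 <= ny < h and fg[ny, nx]:
                found = di
                break
        if found is None:
            # No neighbour at all: isolated single pixel.
            return Contour(np.array(points, dtype=int), closed=False)
        # Resume the next search just past the direction we came from.
        d = (found + 4 + 1) % 8
        now = (nx, ny)
        if now == start:
            return Contour(np.array(points, dtype=int), closed=True)
        points.append(now)
        steps += 1
        if steps > limit:
            raise NonClosedBoundaryError(
                f"boundary walk did not close within {limit} steps")


def contour_to_signal(contour: Contour, n_points: int = 256) -> np.ndarray:
    """Resample a closed contour to ``n_points`` uniform arc-length samples.

    The contour is treated as a closed polygon; samples are placed at equal
    cumulative arc-length intervals starting at the contour's first point.
    Returns the complex outline signal ``z_l = x_l + i*y_l`` of even
    period ``n_points``.

    The descriptor stage assumes the standard counterclockwise
    parameterization of the (x, y) plane, under which the fundamental
    coefficient ``Z_1`` dominates and serves as the scale reference.
    Because image rows grow downward, a traced boundary arrives clockwise
    in plane coordinates; the traversal is therefore reversed (keeping
    the starting point) whenever the polygon's shoelace signed area is
    negative, so every signal leaves here counterclockwise.
    """
    if not contour.closed:
        raise ValueError("contour must be closed for resampling")
    if len(contour) < 3:
        raise ValueError("need at least 3 contour points")
    if n_points % 2 != 0:
        raise ValueError("n_points must be even")
    if n_points < 8:
        raise ValueError("n_points must be >= 8")

    pts = np.asarray(contour.points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    signed_area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed_area < 0.0:
        pts = np.vstack([pts[:1], pts[:0:-1]])  # reverse, keep start point
    poly = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(poly, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total == 0.0:
        raise ValueError("degenerate contour with zero perimeter")
    t = np.arange(n_points) * (total / n_points)
    x = np.interp(t, arclen, poly[:, 0])
    y = np.interp(t, arclen, poly[:, 1])
    return x + 1j * y
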