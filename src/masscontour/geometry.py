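"""Closed mass contours and their 1D signatures.

A mass boundary is an ordered, closed, anticlockwise sequence of pixel
vertices ``C = {p_i = (x_i, y_i)}``.  Two 1D signatures are derived from it:

* the *radial* signature ``h_p(i)``: Euclidean distance from each vertex to
  the vertex centroid (the traditional radial-distance descriptor), and
* the *ellipse-residual* signature ``h(i)``: distance from each vertex to the
  point ``q_i`` where the ray centroid->vertex crosses a centroid-anchored
  reference ellipse whose diameters are the contour's x- and y-coordinate
  ranges.

A regular (near-elliptical) boundary hugs its reference ellipse, so its
ellipse-residual signature is small and flat; a spiculated or microlobulated
boundary produces a large, rough residual.  This makes the residual signature
sensitive to both irregularity and departure from circular/oval shape.

Coordinate convention: overlay rows/columns map to ``(x=column, y=row)``, and
"anticlockwise" means positive shoelace signed area in that frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    ChainCodeError,
    DegenerateContourError,
    OpenPathError,
)

__all__ = [
    "Contour",
    "ReferenceEllipse",
    "Signature",
    "DEFAULT_DIRECTION_MAP",
    "parse_chain_code",
    "encode_chain_code",
    "signed_area",
    "centroid",
    "bounding_diameters",
    "reference_ellipse",
    "align_start",
    "radial_signature",
    "ellipse_signature",
]

#: Freeman 8-direction map: code 0 steps +x, successive codes advance
#: anticlockwise by 45 degrees.  Overlay dialects differ, so parsers accept
#: an alternative map.
DEFAULT_DIRECTION_MAP: Mapping[int, tuple[int, int]] = {
    0: (1, 0),
    1: (1, 1),
    2: (0, 1),
    3: (-1, 1),
    4: (-1, 0),
    5: (-1, -1),
    6: (0, -1),
    7: (1, -1),
}


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive = anticlockwise)."""
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Closed anticlockwise vertex sequence in pixel coordinates.

    Invariants (enforced at construction): at least 3 vertices, no two
    consecutive vertices identical (the successor of the last vertex is the
    first), positive signed area.  Index arithmetic is modulo ``N``.
    """

    points: np.ndarray
    contour_id: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(pts) < 3:
            raise ValueError("a contour needs at least 3 vertices")
        nxt = np.roll(pts, -1, axis=0)
        if np.any(np.all(pts == nxt, axis=1)):
            raise ValueError("consecutive duplicate vertices are not allowed")
        if signed_area(pts) <= 0:
            raise ValueError(
                "contour orientation must be anticlockwise "
                "(positive signed area); use Contour.from_points to auto-fix"
            )
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_points(
        cls,
        points: Sequence[Sequence[float]] | np.ndarray,
        contour_id: str | None = None,
    ) -> "Contour":
        """Build a contour, reversing vertex order if it traces clockwise.

        The first vertex is kept first, so a reversed contour still starts at
        the same boundary point.
        """
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("points must be an (N>=3, 2) array")
        # drop consecutive duplicates (digitization artifact), incl. wrap
        keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
        pts = pts[keep]
        if len(pts) < 3:
            raise DegenerateContourError("contour collapses after dedup")
        if signed_area(pts) < 0:
            pts = pts[np.r_[0, np.arange(len(pts) - 1, 0, -1)]]
        return cls(pts, contour_id=contour_id)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class ReferenceEllipse:
    """Centroid-anchored axis-aligned ellipse, the 'standard' regular shape.

    Semi-axes are half the contour's coordinate ranges (``D_x/2``, ``D_y/2``);
    when ``D_x = D_y`` the ellipse degenerates to a circle.
    """

    center: tuple[float, float]
    semi_axis_x: float
    semi_axis_y: float

    def __post_init__(self) -> None:
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise DegenerateContourError("semi-axes must be strictly positive")

    def radius_at(self, theta: np.ndarray | float) -> np.ndarray | float:
        """Polar radius of the ellipse boundary at angle ``theta`` from center.

        ``r_e(theta) = a b / sqrt((b cos theta)^2 + (a sin theta)^2)``.
        """
        a, b = self.semi_axis_x, self.semi_axis_y
        return a * b / np.hypot(b * np.cos(theta), a * np.sin(theta))


@dataclass(frozen=True)
class Signature:
    """1D signature h(i): one sample per contour vertex, unit spacing.

    ``kind`` is ``"radial"`` (h_p) or ``"ellipse_residual"`` (h); synthetic
    profile generators may use other kind labels.  For ellipse-residual
    signatures the companion arrays ``radial`` (h_p), ``ellipse_radius``
    (h_q) and ``theta`` are carried along for export and diagnostics.
    """

    values: np.ndarray
    kind: str
    source_contour_id: str | None = None
    theta: np.ndarray | None = field(default=None, repr=False)
    radial: np.ndarray | None = field(default=None, repr=False)
    ellipse_radius: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


def parse_chain_code(
    start: tuple[int, int],
    codes: Sequence[int],
    direction_map: Mapping[int, tuple[int, int]] | None = None,
    on_open: str = "error",
) -> Contour:
    """Trace a Freeman chain code into a closed contour.

    Parameters
    ----------
    start
        Start pixel ``(x, y)``.
    codes
        Direction codes, each in ``[0, 7]``.  The final step must return to
        ``start``; the start vertex is not duplicated at the end.
    direction_map
        Code -> unit-step mapping; defaults to 0=+x advancing anticlockwise
        by 45 degrees per code.
    on_open
        ``"error"`` (default) raises :class:`OpenPathError` when the path
        does not close; ``"close"`` appends greedy 8-connected closing steps
        and warns.

    Returns
    -------
    Contour
        Anticlockwise; if the traced loop is clockwise the vertex order is
        reversed (start vertex kept first).
    """
    dmap = dict(DEFAULT_DIRECTION_MAP if direction_map is None else direction_map)
    codes = list(codes)
    if not codes:
        raise ChainCodeError("empty chain code")
    bad = [c for c in codes if c not in dmap]
    if bad:
        raise ChainCodeError(f"unknown chain code(s): {sorted(set(bad))}")

    x, y = int(start[0]), int(start[1])
    verts = [(x, y)]
    for c in codes:
        dx, dy = dmap[c]
        x, y = x + dx, y + dy
        verts.append((x, y))

    if verts[-1] != verts[0]:
        if on_open == "close":
            warnings.warn(
                f"chain code does not close (gap {verts[-1]} -> {verts[0]}); "
                "appending closing steps",
                stacklevel=2,
            )
            tx, ty = verts[0]
            while (x, y) != (tx, ty):
                x += int(np.sign(tx - x))
                y += int(np.sign(ty - y))
                verts.append((x, y))
        else:
            raise OpenPathError(verts[-1], verts[0])
    verts = verts[:-1]  # closure is implicit
    return Contour.from_points(np.asarray(verts, dtype=float))


def encode_chain_code(
    contour: Contour,
    direction_map: Mapping[int, tuple[int, int]] | None = None,
) -> tuple[tuple[int, int], list[int]]:
    """Re-encode an 8-connected contour as (start pixel, chain codes).

    Inverse of :func:`parse_chain_code` for anticlockwise 8-connected input.
    Raises :class:`ChainCodeError` if a vertex-to-vertex step is not a unit
    8-neighborhood move.
    """
    dmap = dict(DEFAULT_DIRECTION_MAP if direction_map is None else direction_map)
    inv = {tuple(v): k for k, v in dmap.items()}
    pts = np.rint(contour.points).astype(int)
    steps = np.roll(pts, -1, axis=0) - pts
    codes = []
    for dx, dy in steps:
        key = (int(dx), int(dy))
        if key not in inv:
            raise ChainCodeError(f"step {key} is not a unit 8-connected move")
        codes.append(inv[key])
    return (int(pts[0, 0]), int(pts[0, 1])), codes


def contour_to_chain(
    contour: Contour,
    direction_map: Mapping[int, tuple[int, int]] | None = None,
) -> tuple[tuple[int, int], list[int]]:
    """Chain-code approximation of an arbitrary contour.

    Vertices are rounded to the pixel grid and joined by greedy 8-connected
    walks, so contours whose vertices are farther than one pixel apart (e.g.
    synthetic polar samples) still export as a valid closed chain.  For an
    already 8-connected contour this reduces to :func:`encode_chain_code`.
    """
    dmap = dict(DEFAULT_DIRECTION_MAP if direction_map is None else direction_map)
    inv = {tuple(v): k for k, v in dmap.items()}
    pts = np.rint(contour.points).astype(int)
    codes: list[int] = []
    n = len(pts)
    for i in range(n):
        x, y = pts[i]
        tx, ty = pts[(i + 1) % n]
        while (x, y) != (tx, ty):
            dx, dy = int(np.sign(tx - x)), int(np.sign(ty - y))
            codes.append(inv[(dx, dy)])
            x, y = x + dx, y + dy
    return (int(pts[0, 0]), int(pts[0, 1])), codes


def centroid(contour: Contour) -> tuple[float, float]:
    """Vertex centroid (arithmetic mean of the vertices, not the area centroid)."""
    m = contour.points.mean(axis=0)
    return float(m[0]), float(m[1])


def bounding_diameters(contour: Contour) -> tuple[float, float]:
    """Coordinate ranges ``D_x = max x - min x`` and ``D_y`` likewise."""
    dx = float(np.ptp(contour.x))
    dy = float(np.ptp(contour.y))
    if dx == 0 or dy == 0:
        raise DegenerateContourError(
            f"contour is degenerate: D_x={dx}, D_y={dy}"
        )
    return dx, dy


def reference_ellipse(contour: Contour) -> ReferenceEllipse:
    """Reference ellipse: centered at the centroid, semi-axes D_x/2, D_y/2."""
    dx, dy = bounding_diameters(contour)
    return ReferenceEllipse(centroid(contour), dx / 2.0, dy / 2.0)


def align_start(contour: Contour) -> Contour:
    """Cyclically re-index so the first vertex is the right-hand crossover.

    The start vertex is where the horizontal line through the centroid meets
    the contour on the side ``x > x_0``: among vertices with ``x_i > x_0``,
    the one minimizing ``|y_i - y_0|``, ties broken by larger ``x_i`` then
    smaller original index.  Idempotent; the vertex multiset is unchanged.
    """
    x0, y0 = centroid(contour)
    pts = contour.points
    mask = pts[:, 0] > x0
    # a closed contour contains its x-maximum vertex, which satisfies x > x0
    assert mask.any(), "no vertex right of the centroid"
    idx = np.flatnonzero(mask)
    dy = np.abs(pts[idx, 1] - y0)
    # lexsort: last key is primary
    order = np.lexsort((idx, -pts[idx, 0], dy))
    start = idx[order[0]]
    return Contour(np.roll(pts, -start, axis=0), contour_id=contour.contour_id)


def _polar(contour: Contour) -> tuple[np.ndarray, np.ndarray]:
    x0, y0 = centroid(contour)
    dx = contour.x - x0
    dy = contour.y - y0
    return np.hypot(dx, dy), np.arctan2(dy, dx)


def radial_signature(contour: Contour) -> Signature:
    """Traditional radial signature h_p(i): vertex-to-centroid distance."""
    r, theta = _polar(contour)
    return Signature(
        values=r,
        kind="radial",
        source_contour_id=contour.contour_id,
        theta=theta,
        radial=r,
    )


def ellipse_signature(contour: Contour, signed: bool = False) -> Signature:
    """Ellipse-residual signature h(i) = |h_p(i) - h_q(i)|.

    For each vertex ``p_i`` at polar angle ``theta_i`` about the centroid,
    ``q_i`` is the intersection of the ray centroid->p_i with the reference
    ellipse, at radius ``h_q(i) = r_e(theta_i)``.  With ``signed=True`` the
    residual keeps its sign (positive outside the ellipse).
    """
    ell = reference_ellipse(contour)
    r, theta = _polar(contour)
    rq = np.asarray(ell.radius_at(theta), dtype=float)
    h = r - rq if signed else np.abs(r - rq)
    return Signature(
        values=h,
        kind="ellipse_residual",
        source_contour_id=contour.contour_id,
        theta=theta,
        radial=r,
        ellipse_radius=rq,
    )
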