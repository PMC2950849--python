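"""Spatial sampling design for use-availability foraging studies.

This module implements the geometric half of the study design: minimum
convex polygon (MCP) home ranges, random availability points with an
exclusion buffer around observed foraging locations, patch-scale covariate
extraction on a raster landscape, and temporal thinning of telemetry
tracks.

Coordinates are planar metres throughout (a projected CRS is assumed);
geographic coordinates are rejected, never converted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import (
    DegenerateGeometryError,
    InfeasibleDesignError,
    OutOfBoundsError,
    TrackOrderError,
)

__all__ = [
    "Point",
    "Activity",
    "TimedFix",
    "Polygon",
    "PatchCovariates",
    "minimum_convex_polygon",
    "sample_availability",
    "sample_patch",
    "sample_patches",
    "thin_track",
]


@dataclass(frozen=True)
class Point:
    """A planar location in metres (easting, northing)."""

    x: float
    y: float

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def distance(self, other: "Point") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))


class Activity(str, Enum):
    FORAGING = "foraging"
    OTHER = "other"


@dataclass(frozen=True)
class TimedFix:
    """A telemetry fix: location, seconds since track start, activity."""

    point: Point
    t: float
    activity: Activity = Activity.FORAGING

    def __post_init__(self):
        if self.t < 0:
            raise ValueError(f"negative fix time {self.t}")


@dataclass(frozen=True)
class PatchCovariates:
    """Ground-vegetation structure of one sampling circle.

    ``bare`` is the proportion of the circle with no vegetation cover seen
    vertically from above; ``height`` is the mean vegetation height (cm)
    over the vegetated part of the circle, defined as 0 when the circle is
    entirely bare so the covariate exists everywhere.
    """

    bare: float
    height: float

    def __post_init__(self):
        if not 0.0 <= self.bare <= 1.0:
            raise ValueError(f"bare proportion {self.bare} outside [0, 1]")
        if self.height < 0:
            raise ValueError(f"negative vegetation height {self.height}")


class Polygon:
    """A simple convex polygon given by its CCW vertex ring.

    Thin wrapper around a :mod:`shapely` polygon; vertices are exposed as an
    ``(n, 2)`` array with the closing vertex implied.
    """

    def __init__(self, vertices: np.ndarray | Sequence[Point]):
        verts = np.asarray(
            [[p.x, p.y] for p in vertices]
            if len(vertices) and isinstance(vertices[0], Point)
            else vertices,
            dtype=float,
        )
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
            raise DegenerateGeometryError(
                f"polygon needs >= 3 vertices, got shape {verts.shape}"
            )
        geom = ShapelyPolygon(verts)
        if not geom.is_valid or geom.area <= 0:
            raise DegenerateGeometryError("polygon is self-intersecting or has zero area")
        # normalise to CCW orientation
        if not geom.exterior.is_ccw:
            verts = verts[::-1]
            geom = ShapelyPolygon(verts)
        self.vertices = verts
        self._geom = geom

    @property
    def area(self) -> float:
        return float(self._geom.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self._geom.bounds

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        """Boundary-inclusive containment test for an (n, 2) array."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return shapely.intersects_xy(self._geom, xy[:, 0], xy[:, 1])

    def contains(self, p: Point) -> bool:
        return bool(self.contains_points(np.array([[p.x, p.y]]))[0])

    def to_shapely(self) -> ShapelyPolygon:
        return self._geom

    def __geo_interface__(self):  # pragma: no cover - convenience
        return self._geom.__geo_interface__


def minimum_convex_polygon(points: Iterable[Point], label: str | None = None) -> Polygon:
    """Minimum convex polygon (100% MCP) home range of a point set.

    Parameters
    ----------
    points
        Foraging locations of one individual; at least three, not all
        collinear.
    label
        Optional individual id used in error messages.

    Returns
    -------
    Polygon
        Convex, containing every input point, with vertices a subset of the
        input points in counter-clockwise order.
    """
    pts = list(points)
    who = f" (individual {label})" if label else ""
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 points for a home range, got {len(pts)}{who}"
        )
    xy = np.array([[p.x, p.y] for p in pts], dtype=float)
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"points are collinear or otherwise degenerate{who}"
        ) from exc
    # qhull returns hull vertex indices in CCW order for 2-D input
    return Polygon(xy[hull.vertices])


def sample_availability(
    home_range: Polygon,
    used: Sequence[Point],
    n: int,
    exclusion_radius: float = 10.0,
    rng_seed: int | np.random.Generator = 0,
    *,
    attempt_factor: int = 1000,
    feasible_floor: float = 0.005,
) -> list[Point]:
    """Random availability points inside a home range, away from used points.

    Rejection sampling from the polygon's bounding box: a candidate is kept
    when it lies inside the polygon (boundary inclusive) and strictly more
    than ``exclusion_radius`` from every used location. Deterministic for a
    given seed.

    Raises
    ------
    InfeasibleDesignError
        If the attempt budget (``attempt_factor * n``) is exhausted and the
        estimated feasible fraction of the bounding box is below
        ``feasible_floor``.
    """
    if exclusion_radius <= 0:
        raise ValueError("exclusion_radius must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    minx, miny, maxx, maxy = home_range.bounds
    tree = cKDTree(np.array([[p.x, p.y] for p in used])) if len(used) else None

    budget = attempt_factor * n
    attempted = 0
    accepted: list[np.ndarray] = []
    n_accepted = 0
    batch = max(4 * n, 64)
    while n_accepted < n and attempted < budget:
        m = min(batch, budget - attempted)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        attempted += m
        ok = home_range.contains_points(cand)
        if tree is not None and ok.any():
            d, _ = tree.query(cand[ok], k=1)
            sub = np.flatnonzero(ok)
            ok[sub] = d > exclusion_radius
        kept = cand[ok]
        if len(kept):
            accepted.append(kept)
            n_accepted += len(kept)
    if n_accepted < n:
        frac = n_accepted / attempted if attempted else 0.0
        raise InfeasibleDesignError(
            f"availability sampling exhausted {attempted} attempts with only "
            f"{n_accepted}/{n} accepted; estimated feasible fraction of the "
            f"bounding box is {frac:.4f} (floor {feasible_floor})",
            feasible_fraction=frac,
        )
    out = np.concatenate(accepted)[:n]
    return [Point(float(x), float(y)) for x, y in out]


def _disk_lattice(radius: float, step: float) -> np.ndarray:
    """Midpoint lattice of offsets covering a disk of given radius."""
    k = int(np.ceil(radius / step))
    ax = (np.arange(-k, k + 1) + 0.0) * step
    ox, oy = np.meshgrid(ax, ax)
    inside = ox**2 + oy**2 <= radius**2
    return np.column_stack([ox[inside], oy[inside]])


def sample_patches(landscape, centers: np.ndarray, radius: float) -> np.ndarray:
    """Patch covariates for many circles at once.

    Integrates the landscape raster over each circle on a deterministic
    midpoint lattice (step ``radius / 24``). Returns an ``(n, 2)`` array of
    ``(bare, height)``; height is the mean over the vegetated part of the
    circle, 0 when the circle is entirely bare.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    ex, ey = landscape.extent
    lo = centers - radius
    hi = centers + radius
    if (lo < 0).any() or (hi[:, 0] > ex).any() or (hi[:, 1] > ey).any():
        bad = np.flatnonzero(
            (lo < 0).any(axis=1) | (hi[:, 0] > ex) | (hi[:, 1] > ey)
        )[0]
        raise OutOfBoundsError(
            f"sampling circle at ({centers[bad, 0]:.1f}, {centers[bad, 1]:.1f}) "
            f"with radius {radius} exits the landscape extent {ex}x{ey} m"
        )
    offsets = _disk_lattice(radius, radius / 24.0)
    g = landscape.grain
    nx = landscape.bare_mask.shape[1]
    ny = landscape.bare_mask.shape[0]
    pts = centers[:, None, :] + offsets[None, :, :]  # (n, m, 2)
    ix = np.clip((pts[..., 0] // g).astype(np.intp), 0, nx - 1)
    iy = np.clip((pts[..., 1] // g).astype(np.intp), 0, ny - 1)
    bare_cells = landscape.bare_mask[iy, ix]
    bare = bare_cells.mean(axis=1)
    veg = ~bare_cells
    hsum = np.where(veg, landscape.height[iy, ix], 0.0).sum(axis=1)
    nveg = veg.sum(axis=1)
    height = np.where(nveg > 0, hsum / np.maximum(nveg, 1), 0.0)
    return np.column_stack([bare, height])


def sample_patch(landscape, center: Point, radius: float) -> PatchCovariates:
    """Ground-vegetation covariates of one sampling circle.

    The circle must lie entirely inside the landscape extent. ``radius`` is
    1 m for most species presets and 5 m for woodlarks, but any positive
    value is accepted.
    """
    bare, height = sample_patches(landscape, np.array([[center.x, center.y]]), radius)[0]
    return PatchCovariates(bare=float(bare), height=float(height))


def thin_track(
    track: Sequence[TimedFix],
    min_interval: float = 300.0,
    site_radius: float = 10.0,
) -> list[TimedFix]:
    """Temporal thinning of a foraging track.

    Greedy forward pass: a foraging fix is kept iff at least
    ``min_interval`` seconds have elapsed since the last kept fix, or the
    bird has moved more than ``site_radius`` metres from it (a different
    foraging site). Non-foraging fixes are never kept. Idempotent.
    """
    ts = [f.t for f in track]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise TrackOrderError("track fixes are not sorted by time")
    kept: list[TimedFix] = []
    for fix in track:
        if fix.activity is not Activity.FORAGING:
            continue
        if not kept:
            kept.append(fix)
            continue
        last = kept[-1]
        if fix.t - last.t >= min_interval or fix.point.distance(last.point) > site_radius:
            kept.append(fix)
    return kept
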