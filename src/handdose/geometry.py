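"""Constructive-solid scene geometry with ray tracing.

The scene is an ordered list of :class:`Region` objects (world first),
each an axis-aligned primitive — box, finite (optionally hollow)
circular cylinder, or elliptical tube — filled with a material.
Containment ties are broken by declaration order: regions declared
later are "deeper" and win, so a syringe interior declared after the
shield shadows it wherever they touch.

Two query families are provided: the scalar contracts
:func:`locate` / :func:`distance_to_boundary` / :func:`region_mass`,
and vectorized batch kernels (``SceneGeometry.locate_many``,
``SceneGeometry.first_crossing``) used by the transport engine.

Coordinates are continuous centimetres in a right-handed frame; the
default scene orients the syringe axis along +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .materials import Material

__all__ = [
    "Shape",
    "Box",
    "Cylinder",
    "EllipticalTube",
    "Region",
    "SceneGeometry",
    "BoundaryCrossing",
    "OutsideWorldError",
    "locate",
    "distance_to_boundary",
    "region_mass",
    "vec3",
]

_EPS_T = 1e-9  # minimum accepted crossing parameter, cm
PUSH = 1e-6  # post-crossing nudge used by callers, cm


class OutsideWorldError(ValueError):
    """A query point lies outside the world volume."""


def vec3(x: float, y: float, z: float) -> np.ndarray:
    """Build a 3-vector (cm), validating finiteness."""
    v = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("vector components must be finite")
    return v


def _as_points(points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must have shape (N, 3)")
    return pts


class Shape:
    """Base class for axis-aligned primitives."""

    def contains_many(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def hits_many(self, points: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Candidate ray-surface crossing parameters, shape (N, k).

        Invalid candidates are ``+inf``. Only crossings with
        ``t > _EPS_T`` are reported.
        """
        raise NotImplementedError

    def volume(self) -> float:
        raise NotImplementedError

    def contains(self, point) -> bool:
        return bool(self.contains_many(_as_points(point))[0])


@dataclass(frozen=True)
class Box(Shape):
    """Axis-aligned box given by center and full side lengths (cm)."""

    center: np.ndarray
    sides: np.ndarray  # (a, b, c) full extents

    def __post_init__(self):
        object.__setattr__(self, "center", vec3(*np.asarray(self.center)))
        object.__setattr__(
            self, "sides", np.asarray(self.sides, dtype=float)
        )
        if not np.all(self.sides > 0):
            raise ValueError("box extents must be positive")

    @property
    def half(self) -> np.ndarray:
        return self.sides / 2.0

    def contains_many(self, points):
        d = np.abs(points - self.center)
        return np.all(d <= self.half, axis=1)

    def hits_many(self, points, dirs):
        # slab method; entry and exit are the two surface crossings
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / dirs
            t1 = (self.center - self.half - points) * inv
            t2 = (self.center + self.half - points) * inv
        lo = np.where(np.isnan(t1), -np.inf, np.minimum(t1, t2))
        hi = np.where(np.isnan(t2), np.inf, np.maximum(t1, t2))
        # rays parallel to a slab: inside -> (-inf, inf), outside -> miss
        par = dirs == 0.0
        out = np.abs(points - self.center) > self.half
        miss_par = np.any(par & out, axis=1)
        tmin = np.max(np.where(par, -np.inf, lo), axis=1)
        tmax = np.min(np.where(par, np.inf, hi), axis=1)
        valid = (tmax > tmin) & ~miss_par
        tmin = np.where(valid & (tmin > _EPS_T), tmin, np.inf)
        tmax = np.where(valid & (tmax > _EPS_T), tmax, np.inf)
        return np.stack([tmin, tmax], axis=1)

    def volume(self):
        return float(np.prod(self.sides))


@dataclass(frozen=True)
class EllipticalTube(Shape):
    """Finite elliptical tube along a coordinate axis.

    ``semi`` are the two transverse semi-axes in ascending-dimension
    order (e.g. axis=1 -> semi = (semi_x, semi_z)).
    """

    center: np.ndarray
    axis: int  # 0=x, 1=y, 2=z
    semi: tuple  # transverse semi-axes, cm
    length: float  # full axial extent, cm

    def __post_init__(self):
        object.__setattr__(self, "center", vec3(*np.asarray(self.center)))
        s = tuple(float(v) for v in self.semi)
        object.__setattr__(self, "semi", s)
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")
        if not (s[0] > 0 and s[1] > 0 and self.length > 0):
            raise ValueError("tube extents must be positive")

    @property
    def _tdims(self):
        return tuple(d for d in range(3) if d != self.axis)

    def _ellipse_val(self, points):
        i, j = self._tdims
        si, sj = self.semi
        u = (points[:, i] - self.center[i]) / si
        v = (points[:, j] - self.center[j]) / sj
        return u * u + v * v

    def contains_many(self, points):
        k = self.axis
        ax = np.abs(points[:, k] - self.center[k]) <= self.length / 2.0
        return ax & (self._ellipse_val(points) <= 1.0)

    def _lateral_roots(self, points, dirs, scale=1.0):
        """Roots of the (scaled) lateral quadratic, (N, 2), inf invalid."""
        i, j = self._tdims
        si, sj = self.semi[0] * scale, self.semi[1] * scale
        ui = (points[:, i] - self.center[i]) / si
        uj = (points[:, j] - self.center[j]) / sj
        di = dirs[:, i] / si
        dj = dirs[:, j] / sj
        a = di * di + dj * dj
        b = 2.0 * (ui * di + uj * dj)
        c = ui * ui + uj * uj - 1.0
        disc = b * b - 4.0 * a * c
        with np.errstate(divide="ignore", invalid="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            r1 = (-b - sq) / (2.0 * a)
            r2 = (-b + sq) / (2.0 * a)
        bad = (disc <= 0.0) | (a == 0.0)
        r1 = np.where(bad, np.inf, r1)
        r2 = np.where(bad, np.inf, r2)
        k = self.axis
        zs = points[:, k] - self.center[k]
        dz = dirs[:, k]
        half = self.length / 2.0
        z1 = zs + np.where(np.isfinite(r1), r1, 0.0) * dz
        z2 = zs + np.where(np.isfinite(r2), r2, 0.0) * dz
        r1 = np.where((np.abs(z1) <= half) & (r1 > _EPS_T), r1, np.inf)
        r2 = np.where((np.abs(z2) <= half) & (r2 > _EPS_T), r2, np.inf)
        return np.stack([r1, r2], axis=1)

    def _cap_hits(self, points, dirs, inner_scale=None):
        k = self.axis
        half = self.length / 2.0
        zs = points[:, k] - self.center[k]
        dz = dirs[:, k]
        with np.errstate(divide="ignore", invalid="ignore"):
            tlo = (-half - zs) / dz
            thi = (half - zs) / dz
        cols = []
        for t in (tlo, thi):
            t = np.where(np.isfinite(t) & (t > _EPS_T), t, np.inf)
            hit = points + np.where(np.isfinite(t), t, 0.0)[:, None] * dirs
            val = self._ellipse_val(hit)
            ok = val <= 1.0
            if inner_scale is not None:
                ok &= val >= inner_scale**2
            cols.append(np.where(ok, t, np.inf))
        return np.stack(cols, axis=1)

    def hits_many(self, points, dirs):
        return np.concatenate(
            [self._lateral_roots(points, dirs), self._cap_hits(points, dirs)],
            axis=1,
        )

    def volume(self):
        return float(np.pi * self.semi[0] * self.semi[1] * self.length)


@dataclass(frozen=True)
class Cylinder(EllipticalTube):
    """Finite circular cylinder, optionally hollow (tube of material)."""

    r_inner: float = 0.0

    def __init__(self, center, axis, r_outer, length, r_inner=0.0):
        super().__init__(
            center=center, axis=axis, semi=(r_outer, r_outer), length=length
        )
        object.__setattr__(self, "r_inner", float(r_inner))
        if self.r_inner < 0:
            raise ValueError("inner radius must be >= 0")
        if self.r_inner >= self.r_outer:
            if self.r_inner != 0.0:
                raise ValueError("inner radius must be < outer radius")

    @property
    def r_outer(self) -> float:
        return self.semi[0]

    def contains_many(self, points):
        inside = super().contains_many(points)
        if self.r_inner > 0:
            scale = self.r_inner / self.r_outer
            inside &= self._ellipse_val(points) >= scale * scale
        return inside

    def hits_many(self, points, dirs):
        if self.r_inner <= 0:
            return super().hits_many(points, dirs)
        scale = self.r_inner / self.r_outer
        return np.concatenate(
            [
                self._lateral_roots(points, dirs),
                self._lateral_roots(points, dirs, scale=scale),
                self._cap_hits(points, dirs, inner_scale=scale),
            ],
            axis=1,
        )

    def volume(self):
        return float(
            np.pi * (self.r_outer**2 - self.r_inner**2) * self.length
        )


@dataclass(frozen=True)
class Region:
    """A named, material-filled shape; ``scoring`` marks dose regions."""

    name: str
    shape: Shape
    material: Material
    scoring: bool = False


class BoundaryCrossing(NamedTuple):
    distance: float  # cm to the nearest surface along the ray
    next_region: Optional[Region]  # region entered past the crossing
    exits_world: bool


@dataclass
class SceneGeometry:
    """Ordered region list; later declarations take containment priority."""

    regions: Sequence[Region]
    _shapes: list = field(init=False, repr=False)

    def __post_init__(self):
        if not self.regions:
            raise ValueError("scene needs at least a world region")
        self.regions = list(self.regions)
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        self._shapes = [r.shape for r in self.regions]

    @property
    def world(self) -> Region:
        return self.regions[0]

    def region_index(self, name: str) -> int:
        for i, r in enumerate(self.regions):
            if r.name == name:
                return i
        raise KeyError(f"no region named {name!r}")

    def region(self, name: str) -> Region:
        return self.regions[self.region_index(name)]

    @property
    def scoring_regions(self) -> list[Region]:
        return [r for r in self.regions if r.scoring]

    def locate_many(self, points) -> np.ndarray:
        """Region index per point; -1 where outside the world."""
        pts = _as_points(points)
        idx = np.full(len(pts), -1, dtype=np.int64)
        for i, shape in enumerate(self._shapes):
            inside = shape.contains_many(pts)
            idx = np.where(inside, i, idx)
        return idx

    def first_crossing(self, points, dirs) -> np.ndarray:
        """Distance (cm) to the nearest surface of any region, per ray."""
        pts = _as_points(points)
        drs = _as_points(dirs)
        best = np.full(len(pts), np.inf)
        for shape in self._shapes:
            hits = shape.hits_many(pts, drs)
            best = np.minimum(best, hits.min(axis=1))
        return best

    def translated(self, offset) -> "SceneGeometry":
        """Scene with every region rigidly shifted by ``offset`` (cm)."""
        off = np.asarray(offset, dtype=float)
        moved = []
        for r in self.regions:
            s = r.shape
            if isinstance(s, Cylinder):
                ns = Cylinder(
                    s.center + off, s.axis, s.r_outer, s.length, s.r_inner
                )
            elif isinstance(s, EllipticalTube):
                ns = EllipticalTube(s.center + off, s.axis, s.semi, s.length)
            elif isinstance(s, Box):
                ns = Box(s.center + off, s.sides)
            else:  # pragma: no cover - no other primitives exist
                raise TypeError(type(s))
            moved.append(Region(r.name, ns, r.material, r.scoring))
        return SceneGeometry(moved)


def locate(point, scene: SceneGeometry) -> Region:
    """Highest-priority region containing ``point``.

    Raises :class:`OutsideWorldError` if the point is outside the world.
    """
    idx = int(scene.locate_many(point)[0])
    if idx < 0:
        raise OutsideWorldError(f"point {np.asarray(point)!r} outside world")
    return scene.regions[idx]


def distance_to_boundary(point, direction, scene) -> BoundaryCrossing:
    """Nearest ray-surface crossing from ``point`` along ``direction``.

    ``direction`` must be unit length. Returns the crossing distance, the
    region entered just past it (None when the ray leaves the world), and
    an exit flag.
    """
    p = vec3(*np.asarray(point, dtype=float))
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    locate(p, scene)  # contract: start inside world
    t = float(scene.first_crossing(p, d)[0])
    if not np.isfinite(t):  # pragma: no cover - closed world guards this
        return BoundaryCrossing(np.inf, None, True)
    probe = p + (t + PUSH) * d
    idx = int(scene.locate_many(probe)[0])
    if idx < 0:
        return BoundaryCrossing(t, None, True)
    return BoundaryCrossing(t, scene.regions[idx], False)


def region_mass(region: Region) -> float:
    """Mass of a scoring region in kg (analytic volume x density).

    Raises ``ValueError`` for non-scoring regions — dose is only defined
    for declared scoring volumes.
    """
    if not region.scoring:
        raise ValueError(f"region {region.name!r} is not a scoring region")
    grams = region.shape.volume() * region.material.density
    if grams <= 0:  # pragma: no cover - shape invariants forbid this
        raise ValueError("non-positive region mass")
    return grams / 1000.0
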