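"""Cones of Sight and the distance primitives behind conification.

A Cone of Sight (CoS) is the solid cone with vertex at the origin whose
boundary surface is tangent to a *generating sphere* ``S((a, b, c), R)``.
Every line through the origin tangent to the sphere lies on that surface,
so the cone is circular with

* axis        ``(a, b, c) / ||(a, b, c)||``
* half-angle  ``arcsin(R / ||(a, b, c)||)``.

The same surface is the zero set of the quadratic

    (-2ax - 2by - 2cz)^2 - 4 (x^2 + y^2 + z^2) (a^2 + b^2 + c^2 - R^2) = 0

and replacing ``=`` by ``>=`` selects the points on or inside the (double)
cone.  The quadratic form is sign-symmetric, so it also admits the nappe
opposite the generating sphere; membership therefore additionally requires
``ax + by + cz >= 0``, keeping only the nappe that actually contains the
sphere.  Both forms are implemented; the angular one is the work-horse, the
algebraic one is kept as a verified-equivalent predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ConeOfSight",
    "derive_cone",
    "cone_contains",
    "cone_contains_algebraic",
    "point_to_cone_distance",
    "point_to_set_distance",
    "hausdorff_distance",
]


def _as_point(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("point coordinates must be finite")
    return p


@dataclass(frozen=True)
class ConeOfSight:
    """A solid circular cone with vertex at the origin.

    Parameters
    ----------
    label : str
        Direction name (e.g. ``"TF"`` for top-front).
    center : ndarray, shape (3,)
        Center of the generating sphere.
    radius : float
        Radius of the generating sphere; must satisfy ``||center|| > radius``.
    axis : ndarray, shape (3,)
        Unit vector along the cone axis (``center`` normalised).
    half_angle : float
        Half-opening angle in radians, ``arcsin(radius / ||center||)``.
    """

    label: str
    center: np.ndarray
    radius: float
    axis: np.ndarray = field(repr=False)
    half_angle: float

    def __post_init__(self):
        if not 0.0 < self.half_angle < np.pi / 2:
            raise ValueError("half_angle must lie in (0, pi/2)")

    def contains(self, p) -> bool:
        return cone_contains(self, p)

    def distance(self, p) -> float:
        return point_to_cone_distance(p, self)


def derive_cone(label: str, center, radius: float) -> ConeOfSight:
    """Derive the tangent Cone of Sight from a generating sphere.

    Raises
    ------
    ValueError
        If the vertex (origin) lies inside or on the sphere — no tangent
        cone exists then.
    """
    center = _as_point(center)
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    d = float(np.linalg.norm(center))
    if d <= radius:
        raise ValueError(
            f"cone {label!r}: vertex inside or on sphere "
            f"(||center|| = {d:.6g} <= radius = {radius:.6g})"
        )
    return ConeOfSight(
        label=label,
        center=center,
        radius=float(radius),
        axis=center / d,
        half_angle=float(np.arcsin(radius / d)),
    )


def cone_contains(cone: ConeOfSight, p) -> bool:
    """True iff ``p`` lies on or inside the solid cone (angular test).

    Membership means ``angle(p, axis) <= half_angle``.  The vertex (origin)
    is on the boundary of every cone and counts as inside.
    """
    p = _as_point(p)
    # dot >= ||p|| cos(theta); exact for p = 0 (0 >= 0).
    return bool(float(p @ cone.axis) >= np.linalg.norm(p) * np.cos(cone.half_angle))


def cone_contains_algebraic(cone: ConeOfSight, p) -> bool:
    """Quadratic-surface membership test with the nappe restriction.

    Evaluates ``(-2ax-2by-2cz)^2 - 4(x^2+y^2+z^2)(a^2+b^2+c^2-R^2) >= 0``
    together with ``ax+by+cz >= 0``.  Equivalent to :func:`cone_contains`;
    the equivalence is exercised by the test suite on random points.
    """
    p = _as_point(p)
    a, b, c = cone.center
    x, y, z = p
    dot = a * x + b * y + c * z
    q = (-2.0 * dot) ** 2 - 4.0 * (x * x + y * y + z * z) * (
        a * a + b * b + c * c - cone.radius**2
    )
    return bool(q >= 0.0 and dot >= 0.0)


def cone_contains_many(cone: ConeOfSight, points: np.ndarray) -> np.ndarray:
    """Vectorised angular membership for an (n, 3) array of points."""
    points = np.asarray(points, dtype=float)
    return points @ cone.axis >= np.linalg.norm(points, axis=1) * np.cos(
        cone.half_angle
    )


def point_to_cone_distance(p, cone: ConeOfSight) -> float:
    """Euclidean distance from ``p`` to the closed solid cone.

    Closed form by the angle ``alpha`` between ``p`` and the axis:

    * ``alpha <= theta``            → 0 (inside)
    * ``theta < alpha <= theta + pi/2`` → ``||p|| sin(alpha - theta)``
      (foot of the perpendicular onto the boundary ray)
    * otherwise                     → ``||p||`` (the apex is nearest)
    """
    p = _as_point(p)
    return float(point_to_cone_distance_many(p[None, :], cone)[0])


def point_to_cone_distance_many(points: np.ndarray, cone: ConeOfSight) -> np.ndarray:
    """Vectorised :func:`point_to_cone_distance` for an (n, 3) array."""
    points = np.asarray(points, dtype=float)
    norms = np.linalg.norm(points, axis=1)
    with np.errstate(invalid="ignore"):
        cosa = np.where(norms > 0, points @ cone.axis / np.where(norms > 0, norms, 1.0), 1.0)
    alpha = np.arccos(np.clip(cosa, -1.0, 1.0))
    theta = cone.half_angle
    out = np.where(
        alpha <= theta,
        0.0,
        np.where(alpha <= theta + np.pi / 2, norms * np.sin(alpha - theta), norms),
    )
    return out


def point_to_set_distance(x, points) -> float:
    """Minimum Euclidean distance from point ``x`` to a finite point set."""
    x = _as_point(x)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("point set must be nonempty")
    return float(np.min(np.linalg.norm(points - x, axis=1)))


def hausdorff_distance(A, B) -> float:
    """Hausdorff distance between two finite point sets.

    ``max( sup_{x in A} dist(x, B), sup_{y in B} dist(y, A) )`` with
    ``dist`` the point-to-set Euclidean distance.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("Hausdorff distance requires two nonempty sets")
    d_ab = cKDTree(B).query(A, k=1)[0].max()
    d_ba = cKDTree(A).query(B, k=1)[0].max()
    return float(max(d_ab, d_ba))
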