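"""Spherical triangles and the geodesic parametrization of their boundary.

A spherical triangle is a region of a sphere bounded by three great-circle
arcs.  Placing one vertex at the north pole of the sphere, the two sides
meeting at the pole become longitude lines and the opposite side follows the
geodesic equation

    cot(theta) = a * cos(phi - phi0),

so the whole patch is described by the azimuthal opening ``alpha`` of the two
longitude sides, the two polar side arcs ``beta2``/``beta3``, and the geodesic
parameters ``(a, phi0)`` of the opposite side.  Everything downstream (density
interpolation, field series, moments) works in this canonical frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphericalTriangle",
    "CanonicalFrame",
    "GeodesicParams",
    "DegenerateTriangleError",
    "canonicalize",
    "geodesic_params",
    "beta_of_phi",
    "arc_length_opposite",
]

#: absolute tolerance for angle comparisons (radians)
ANGLE_TOL = 1e-12
#: looser tolerance for identities that involve cancellation
IDENTITY_TOL = 1e-10


class DegenerateTriangleError(ValueError):
    """Raised when three vertex directions do not span a proper triangle."""


@dataclass(frozen=True)
class SphericalTriangle:
    """A great-arc-bounded triangular patch on a sphere.

    Parameters
    ----------
    v1, v2, v3 : (3,) array_like
        Unit vectors from the sphere center to the three vertices.
    center : (3,) array_like, optional
        Sphere center (defaults to the origin).
    radius : float, optional
        Sphere radius (defaults to 1).  All angular quantities are
        independent of the radius; it only enters dimensional scaling of
        potentials and charges.
    """

    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 1.0

    def __post_init__(self):
        for name in ("v1", "v2", "v3", "center"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        for name in ("v1", "v2", "v3"):
            v = getattr(self, name)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError(
                    f"vertex direction {name} must be a unit vector "
                    f"(|{name}| = {np.linalg.norm(v):.16g})"
                )
        dots = (
            float(self.v1 @ self.v2),
            float(self.v2 @ self.v3),
            float(self.v1 @ self.v3),
        )
        for d in dots:
            if not (-1.0 < d < 1.0):
                raise DegenerateTriangleError(
                    "coincident or antipodal vertices (pairwise dot out of (-1, 1))"
                )
        if abs(self.triple_product()) < 1e-14:
            raise DegenerateTriangleError(
                "vertices lie on one great circle (triple product ~ 0)"
            )

    def triple_product(self) -> float:
        return float(self.v1 @ np.cross(self.v2, self.v3))

    @property
    def vertices(self) -> np.ndarray:
        return np.stack([self.v1, self.v2, self.v3])

    def max_side_arc(self) -> float:
        """Largest of the three side arc lengths (radians)."""
        v = self.vertices
        return max(
            _arc(v[0], v[1]), _arc(v[1], v[2]), _arc(v[0], v[2])
        )


def _arc(u: np.ndarray, v: np.ndarray) -> float:
    """Great-arc angle between two unit vectors, accurate near 0."""
    return float(2.0 * math.asin(min(1.0, np.linalg.norm(u - v) / 2.0)))


@dataclass(frozen=True)
class CanonicalFrame:
    """Rotation placing one vertex at the pole, plus the canonical angles.

    ``rotation`` maps world coordinates to the canonical frame: the pole
    vertex goes to (0, 0, 1), the second vertex to azimuth 0 at polar angle
    ``beta3``, the third vertex to azimuth ``alpha`` at polar angle
    ``beta2``.  ``vertex_order`` records which of the original vertex
    indices (0-based) became (pole, second, third); a winding relabel swaps
    the last two so that ``0 < alpha < pi``.
    """

    rotation: np.ndarray
    pole_index: int
    beta2: float
    beta3: float
    alpha: float
    zeta23: float
    vertex_order: tuple[int, int, int]
    relabeled: bool

    @property
    def r2hat_dot_r3hat(self) -> float:
        return 1.0 - self.zeta23

    def to_canonical(self, points: np.ndarray) -> np.ndarray:
        """Rotate world-frame unit vectors into the canonical frame."""
        return np.asarray(points) @ self.rotation.T

    def from_canonical(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation

    def vertex_canonical(self, which: int) -> np.ndarray:
        """Canonical coordinates of vertex 1, 2 or 3 (1 = pole)."""
        if which == 1:
            return np.array([0.0, 0.0, 1.0])
        if which == 2:
            return np.array(
                [math.sin(self.beta3), 0.0, math.cos(self.beta3)]
            )
        if which == 3:
            return np.array(
                [
                    math.sin(self.beta2) * math.cos(self.alpha),
                    math.sin(self.beta2) * math.sin(self.alpha),
                    math.cos(self.beta2),
                ]
            )
        raise ValueError("vertex index must be 1, 2 or 3")


@dataclass(frozen=True)
class GeodesicParams:
    """Parameters (a, phi0) of cot(theta) = a cos(phi - phi0), plus the
    arc length ``beta1`` of the side opposite the pole."""

    a: float
    phi0: float
    beta1: float


def canonicalize(tri: SphericalTriangle, pole_index: int = 1) -> CanonicalFrame:
    """Rotate a spherical triangle so the chosen vertex sits at the pole.

    The remaining two vertices are placed at azimuth 0 and azimuth
    ``alpha``; if the raw winding would give ``alpha`` in (pi, 2 pi) the two
    non-pole vertices are relabeled so that ``0 < alpha < pi`` (reported via
    ``CanonicalFrame.relabeled``; vertex densities must be permuted with
    ``CanonicalFrame.vertex_order``).

    Parameters
    ----------
    tri : SphericalTriangle
    pole_index : int
        1-based index of the vertex to put at the pole.
    """
    if pole_index not in (1, 2, 3):
        raise ValueError("pole_index must be 1, 2 or 3")
    verts = tri.vertices
    p = pole_index - 1
    order = [p, (p + 1) % 3, (p + 2) % 3]

    def build(second: int, third: int):
        zhat = verts[p]
        w2 = verts[second]
        w3 = verts[third]
        x = w2 - (w2 @ zhat) * zhat
        nx = np.linalg.norm(x)
        if nx < 1e-14:
            raise DegenerateTriangleError("pole and second vertex coincide")
        xhat = x / nx
        yhat = np.cross(zhat, xhat)
        rot = np.stack([xhat, yhat, zhat])
        c3 = rot @ w3
        alpha = math.atan2(c3[1], c3[0])
        return rot, alpha

    rot, alpha = build(order[1], order[2])
    relabeled = False
    if alpha < 0.0:  # raw winding gives alpha in (pi, 2*pi): swap
        order[1], order[2] = order[2], order[1]
        rot, alpha = build(order[1], order[2])
        relabeled = True
    if not (0.0 < alpha < math.pi):
        raise DegenerateTriangleError(
            f"canonical opening alpha = {alpha:.6g} outside (0, pi)"
        )
    second, third = verts[order[1]], verts[order[2]]
    beta3 = _arc(verts[p], second)  # arc pole -> second vertex
    beta2 = _arc(verts[p], third)   # arc pole -> third vertex
    zeta23 = 1.0 - float(second @ third)
    return CanonicalFrame(
        rotation=rot,
        pole_index=pole_index,
        beta2=beta2,
        beta3=beta3,
        alpha=alpha,
        zeta23=zeta23,
        vertex_order=tuple(order),
        relabeled=relabeled,
    )


def geodesic_params(frame: CanonicalFrame) -> GeodesicParams:
    """Geodesic parameters of the side opposite the pole.

    Solves cot(beta3) = a cos(phi0) and cot(beta2) = a cos(alpha - phi0)
    for (a, phi0).  When both cotangents vanish (the opposite side lies on
    the equator) ``a = 0`` and ``phi0`` is unidentifiable; the convention
    ``phi0 = 0`` is used.
    """
    b2, b3, al = frame.beta2, frame.beta3, frame.alpha
    cot2 = math.cos(b2) / math.sin(b2)
    cot3 = math.cos(b3) / math.sin(b3)
    # a cos(phi0) = cot(beta3);  a sin(phi0) = (cot(beta2) - cos(alpha) cot(beta3)) / sin(alpha)
    ac = cot3
    as_ = (cot2 - math.cos(al) * cot3) / math.sin(al)
    a = math.hypot(ac, as_)
    if a < 1e-14:
        return GeodesicParams(a=0.0, phi0=0.0, beta1=arc_length_opposite_raw(0.0, 0.0, al))
    phi0 = math.atan2(as_, ac)
    if math.cos(phi0) <= 0.0 or math.cos(al - phi0) <= 0.0:
        # Cannot happen for a valid spherical triangle with 0 < alpha < pi;
        # guards against corrupt frames.
        raise ValueError("geodesic parameters violate cos(phi0) > 0 bounds")
    beta1 = arc_length_opposite_raw(a, phi0, al)
    return GeodesicParams(a=a, phi0=phi0, beta1=beta1)


def arc_length_opposite_raw(a: float, phi0: float, alpha: float) -> float:
    """Closed form of the arc length of the geodesic side on [0, alpha]:

        beta1 = atan(tan(alpha - phi0)/sqrt(1+a^2)) + atan(tan(phi0)/sqrt(1+a^2))

    written with atan2 so the octant limit (beta = pi/2 sides) is exact.
    """
    s = math.sqrt(1.0 + a * a)
    t1 = math.atan2(math.sin(alpha - phi0), math.cos(alpha - phi0) * s)
    t2 = math.atan2(math.sin(phi0), math.cos(phi0) * s)
    return t1 + t2


def arc_length_opposite(g: GeodesicParams, alpha: float) -> float:
    """Arc length ``beta1`` of the side opposite the pole."""
    return arc_length_opposite_raw(g.a, g.phi0, alpha)


def beta_of_phi(phi, g: GeodesicParams, alpha: float | None = None):
    """Polar angle of the geodesic side at azimuth ``phi``:
    beta(phi) = arccot(a cos(phi - phi0)), in (0, pi/2] for a >= 0.

    ``phi`` may be a scalar or array; values must lie in [0, alpha] when
    ``alpha`` is given.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if alpha is not None:
        if np.any(phi_arr < -ANGLE_TOL) or np.any(phi_arr > alpha + ANGLE_TOL):
            raise ValueError("phi outside [0, alpha]")
    val = np.arctan2(1.0, g.a * np.cos(phi_arr - g.phi0))
    if np.ndim(phi) == 0:
        return float(val)
    return val
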