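"""Brute-force adaptive quadrature for patch potentials, fields and moments.

Every closed form and every series in this package is validated against the
integrals evaluated here.  The rule is iterated (outer phi, inner theta)
adaptive Gauss-Kronrod quadrature with the inner tolerance 10x tighter than
the outer; integrands are smooth except for the integrable on-sphere kernel,
which is handled with the exact regularization
sin(theta)/sqrt(1 - cos(theta)) = sqrt(2) cos(theta/2) where applicable.

All lengths are in units of the sphere radius (R = 1); potentials scale as
sigma * R and fields as sigma under restoration of units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, quad_vec

from .density import VertexDensities, interpolation_coefficients, sigma_grid, t_of_theta
from .geometry import CanonicalFrame, GeodesicParams, beta_of_phi

__all__ = [
    "QuadratureSpec",
    "QuadratureWarning",
    "potential_quadrature",
    "field_quadrature",
    "radial_field_quadrature",
    "vertex_ez_quadrature",
    "moments_quadrature",
]


class QuadratureWarning(UserWarning):
    """Emitted when a requested quadrature tolerance was not certified."""


@dataclass(frozen=True)
class QuadratureSpec:
    rel_tol: float = 1e-10
    abs_tol: float = 1e-13
    max_subdivisions: int = 200
    regularization: bool = True

    def __post_init__(self):
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")


DEFAULT_SPEC = QuadratureSpec()


def _check(err: float, val: float, spec: QuadratureSpec, what: str) -> None:
    if err > spec.abs_tol + spec.rel_tol * abs(val) + 1e-14:
        warnings.warn(
            f"{what}: estimated quadrature error {err:.2e} exceeds tolerance",
            QuadratureWarning,
            stacklevel=3,
        )


def _point_on_open_patch(point, frame, g, tol=1e-12) -> bool:
    p = np.asarray(point, dtype=float)
    r = np.linalg.norm(p)
    if abs(r - 1.0) > 1e-9:
        return False
    c = frame.to_canonical(p / r)
    phi = math.atan2(c[1], c[0])
    theta = math.acos(min(1.0, max(-1.0, c[2])))
    if not (tol < phi < frame.alpha - tol):
        return theta < tol  # the pole itself
    return theta < beta_of_phi(phi, g) - tol


def potential_quadrature(
    point,
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    spec: QuadratureSpec = DEFAULT_SPEC,
) -> float:
    """Coulomb potential of the patch at ``point`` (world frame, units of R).

    int_0^alpha dphi int_0^beta(phi) sin(theta) dtheta
        sigma(theta, phi) / |r~ - r|.
    """
    if _point_on_open_patch(point, frame, g):
        raise ValueError("point lies on the open patch surface")
    pt = frame.to_canonical(np.asarray(point, dtype=float))
    inner_opts = dict(epsabs=spec.abs_tol / 10, epsrel=spec.rel_tol / 10,
                      limit=spec.max_subdivisions)

    def outer(phi):
        beta = beta_of_phi(phi, g)

        def inner(theta):
            s, c = math.sin(theta), math.cos(theta)
            r = np.array([s * math.cos(phi), s * math.sin(phi), c])
            d = pt - r
            return float(
                sigma_grid(np.array(theta), phi, frame, g, dens)
            ) * s / math.sqrt(d @ d)

        val, _ = quad(inner, 0.0, beta, **inner_opts)
        return val

    val, err = quad(outer, 0.0, frame.alpha, epsabs=spec.abs_tol,
                    epsrel=spec.rel_tol, limit=spec.max_subdivisions)
    _check(err, val, spec, "potential_quadrature")
    return val


def field_quadrature(
    point,
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    spec: QuadratureSpec = DEFAULT_SPEC,
) -> np.ndarray:
    """Electric field 3-vector (world frame) at an off-surface point."""
    if _point_on_open_patch(point, frame, g):
        raise ValueError("point lies on the open patch surface")
    pt = frame.to_canonical(np.asarray(point, dtype=float))
    inner_opts = dict(epsabs=spec.abs_tol / 10, epsrel=spec.rel_tol / 10,
                      limit=spec.max_subdivisions)

    def outer(phi):
        beta = beta_of_phi(phi, g)

        def inner(theta):
            s, c = math.sin(theta), math.cos(theta)
            r = np.array([s * math.cos(phi), s * math.sin(phi), c])
            d = pt - r
            dist = math.sqrt(d @ d)
            sig = float(sigma_grid(np.array(theta), phi, frame, g, dens))
            return sig * s * d / dist**3

        val, _ = quad_vec(inner, 0.0, beta, **inner_opts)
        return val

    val, err = quad_vec(outer, 0.0, frame.alpha, epsabs=spec.abs_tol,
                        epsrel=spec.rel_tol)
    _check(err, float(np.linalg.norm(val)), spec, "field_quadrature")
    return frame.from_canonical(val)


def radial_field_quadrature(
    direction,
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    spec: QuadratureSpec = DEFAULT_SPEC,
) -> float:
    """Radial field on the sphere surface at a direction outside the patch:

        E_r = (1/2) int dphi int sin(theta) dtheta
              sigma(theta, phi) / sqrt(2 - 2 rhat~ . rhat).
    """
    dhat = np.asarray(direction, dtype=float)
    dhat = dhat / np.linalg.norm(dhat)
    if _point_on_open_patch(dhat, frame, g):
        raise ValueError("direction lies inside the open patch")
    dc = frame.to_canonical(dhat)
    inner_opts = dict(epsabs=spec.abs_tol / 10, epsrel=spec.rel_tol / 10,
                      limit=spec.max_subdivisions)

    def outer(phi):
        beta = beta_of_phi(phi, g)
        cp, sp = math.cos(phi), math.sin(phi)

        def inner(theta):
            s, c = math.sin(theta), math.cos(theta)
            cosang = dc[0] * s * cp + dc[1] * s * sp + dc[2] * c
            sig = float(sigma_grid(np.array(theta), phi, frame, g, dens))
            return sig * s / math.sqrt(max(2.0 - 2.0 * cosang, 1e-300))

        val, _ = quad(inner, 0.0, beta, **inner_opts)
        return val

    val, err = quad(outer, 0.0, frame.alpha, epsabs=spec.abs_tol,
                    epsrel=spec.rel_tol, limit=spec.max_subdivisions)
    _check(err, val, spec, "radial_field_quadrature")
    return 0.5 * val


def vertex_ez_quadrature(
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    spec: QuadratureSpec = DEFAULT_SPEC,
) -> float:
    """Continuous part of the normal field at the pole vertex, using the
    exact regularization sin(theta)/sqrt(2 - 2 cos(theta)) = cos(theta/2):

        E_z = int dphi int dtheta  sigma(theta, phi) cos(theta/2) / 2.
    """
    inner_opts = dict(epsabs=spec.abs_tol / 10, epsrel=spec.rel_tol / 10,
                      limit=spec.max_subdivisions)

    def outer(phi):
        beta = beta_of_phi(phi, g)

        def inner(theta):
            sig = float(sigma_grid(np.array(theta), phi, frame, g, dens))
            return sig * math.cos(theta / 2.0) / 2.0

        val, _ = quad(inner, 0.0, beta, **inner_opts)
        return val

    val, err = quad(outer, 0.0, frame.alpha, epsabs=spec.abs_tol,
                    epsrel=spec.rel_tol, limit=spec.max_subdivisions)
    _check(err, val, spec, "vertex_ez_quadrature")
    return val


def moments_quadrature(
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    spec: QuadratureSpec = DEFAULT_SPEC,
) -> dict:
    """All geometric and charge moments of the patch in one adaptive pass.

    Returns a dict with area ``A``, the area-weighted direction integrals
    ``tA`` (3,), total charge ``q0``, first moments ``m1`` (3,), and the
    symmetric second-moment matrix ``m2`` (3, 3), all in canonical-frame
    components on the unit sphere.
    """
    def outer(phi):
        beta = beta_of_phi(phi, g)
        coeffs = interpolation_coefficients(phi, frame, g)
        edge = (1.0 - coeffs.lam) * dens.sigma2 + coeffs.lam * dens.sigma3
        cp, sp = math.cos(phi), math.sin(phi)

        def inner(theta):
            s, c = np.sin(theta), np.cos(theta)
            sig = dens.sigma1 + t_of_theta(theta, coeffs.C, coeffs.D) * (
                edge - dens.sigma1
            )
            rx, ry, rz = s * cp, s * sp, c
            return s * np.array([
                1.0,
                rx, ry, rz,
                sig,
                sig * rx, sig * ry, sig * rz,
                sig * rx * rx, sig * rx * ry, sig * rx * rz,
                sig * ry * ry, sig * ry * rz, sig * rz * rz,
            ])

        val, _ = quad_vec(inner, 0.0, beta, epsabs=spec.abs_tol / 10,
                          epsrel=spec.rel_tol / 10)
        return val

    vec, err = quad_vec(outer, 0.0, frame.alpha, epsabs=spec.abs_tol,
                        epsrel=spec.rel_tol)
    _check(err, float(np.max(np.abs(vec))), spec, "moments_quadrature")
    m2 = np.array([
        [vec[8], vec[9], vec[10]],
        [vec[9], vec[11], vec[12]],
        [vec[10], vec[12], vec[13]],
    ])
    return {
        "A": vec[0],
        "tA": vec[1:4].copy(),
        "q0": vec[4],
        "m1": vec[5:8].copy(),
        "m2": m2,
    }
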