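"""Coordinate-free interpolation of vertex charge densities over a patch.

Densities are prescribed at the three vertices.  A linear interpolant is
built on the flat triangle through the vertices and carried onto the
spherical triangle by central projection from the sphere center, giving

    sigma(theta, phi) = sigma1 + t(theta) * [(1 - lambda) sigma2
                                             + lambda sigma3 - sigma1]

in the canonical frame, where lambda(phi) is the chord fraction along the
flat edge v2 -> v3 hit by the azimuthal plane and t(theta) is the radial
projection fraction along the slice chord.  The scheme is intrinsic to each
great-arc edge (only the two edge densities enter there), so neighboring
patches interpolate identically along a shared edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import ANGLE_TOL, CanonicalFrame, GeodesicParams, beta_of_phi

__all__ = [
    "VertexDensities",
    "InterpolationCoefficients",
    "lambda_of_phi",
    "delta_of_phi",
    "interpolation_coefficients",
    "t_of_theta",
    "sigma_at",
    "sigma_at_point",
]


@dataclass(frozen=True)
class VertexDensities:
    """Charge densities at the three vertices, pole vertex first."""

    sigma1: float
    sigma2: float
    sigma3: float

    @classmethod
    def from_frame(cls, sigmas, frame: CanonicalFrame) -> "VertexDensities":
        """Permute raw per-vertex densities into the canonical order of a
        frame (consistent with any winding relabel)."""
        s = np.asarray(sigmas, dtype=float)
        i, j, k = frame.vertex_order
        return cls(float(s[i]), float(s[j]), float(s[k]))

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma1, self.sigma2, self.sigma3])


@dataclass(frozen=True)
class InterpolationCoefficients:
    """Interpolation geometry at a fixed azimuth phi.

    ``lam`` is the chord fraction, ``delta_over_R`` the chord depth below
    the sphere, ``C``/``D`` the coefficients of t(theta) =
    sin(theta) / (C sin(theta) + D cos(theta)), ``h_tilde`` the order-1
    combination zeta23 * lam * (1-lam) * a^2 cos^2(phi - phi0) and
    ``eta_sq`` = (C^2 + D^2)/C^2.  ``lam_prod_zeta`` stores
    zeta23 * lam * (1-lam) itself, which stays well defined when a = 0.
    """

    phi: float
    beta: float
    lam: float
    delta_over_R: float
    C: float
    D: float
    lam_prod_zeta: float
    h_tilde: float
    eta_sq: float


def lambda_of_phi(phi, frame: CanonicalFrame):
    """Chord fraction lambda(phi) along the flat edge v2 -> v3.

    Evaluated in the sin form
    lambda = sin(beta3) sin(phi) / [sin(beta2) sin(alpha - phi)
                                    + sin(beta3) sin(phi)],
    which is regular at phi = pi/2 (the tan form is not).
    """
    phi_arr = np.asarray(phi, dtype=float)
    al = frame.alpha
    if np.any(phi_arr < -ANGLE_TOL) or np.any(phi_arr > al + ANGLE_TOL):
        raise ValueError("phi outside [0, alpha]")
    num = math.sin(frame.beta3) * np.sin(phi_arr)
    den = math.sin(frame.beta2) * np.sin(al - phi_arr) + num
    lam = num / den
    if np.ndim(phi) == 0:
        return float(lam)
    return lam


def delta_of_phi(phi, frame: CanonicalFrame, lam=None):
    """Chord depth delta/R = 1 - sqrt(1 - 2 lam (1-lam) zeta23)."""
    if lam is None:
        lam = lambda_of_phi(phi, frame)
    lam = np.asarray(lam, dtype=float)
    val = 1.0 - np.sqrt(1.0 - 2.0 * lam * (1.0 - lam) * frame.zeta23)
    if np.ndim(phi) == 0:
        return float(val)
    return val


def interpolation_coefficients(
    phi: float, frame: CanonicalFrame, g: GeodesicParams
) -> InterpolationCoefficients:
    """All interpolation quantities at azimuth ``phi``."""
    lam = lambda_of_phi(phi, frame)
    dor = 1.0 - math.sqrt(1.0 - 2.0 * lam * (1.0 - lam) * frame.zeta23)
    beta = beta_of_phi(phi, g, frame.alpha)
    cb, sb = math.cos(beta), math.sin(beta)
    C = (1.0 - cb) + dor * cb
    D = (1.0 - dor) * sb
    lpz = frame.zeta23 * lam * (1.0 - lam)
    ac = g.a * math.cos(phi - g.phi0)
    h_tilde = lpz * ac * ac
    eta_sq = 1.0 + (D / C) ** 2 if C != 0.0 else math.inf
    return InterpolationCoefficients(
        phi=phi,
        beta=beta,
        lam=lam,
        delta_over_R=dor,
        C=C,
        D=D,
        lam_prod_zeta=lpz,
        h_tilde=h_tilde,
        eta_sq=eta_sq,
    )


def t_of_theta(theta, C: float, D: float):
    """Radial projection fraction t(theta) = sin / (C sin + D cos)."""
    theta = np.asarray(theta, dtype=float)
    s, c = np.sin(theta), np.cos(theta)
    out = np.where(theta == 0.0, 0.0, s / (C * s + D * c))
    if out.ndim == 0:
        return float(out)
    return out


def sigma_at(
    theta: float,
    phi: float,
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    tol: float = 1e-9,
) -> float:
    """Interpolated charge density at canonical coordinates (theta, phi).

    Raises for points outside the closed patch (within ``tol`` radians).
    """
    if not (-tol <= phi <= frame.alpha + tol):
        raise ValueError(f"phi = {phi} outside patch azimuth range")
    beta = beta_of_phi(min(max(phi, 0.0), frame.alpha), g)
    if not (-tol <= theta <= beta + tol):
        raise ValueError(f"theta = {theta} outside patch at this azimuth")
    if theta <= 0.0:
        return dens.sigma1
    coeffs = interpolation_coefficients(min(max(phi, 0.0), frame.alpha), frame, g)
    t = t_of_theta(min(theta, beta), coeffs.C, coeffs.D)
    edge = (1.0 - coeffs.lam) * dens.sigma2 + coeffs.lam * dens.sigma3
    return dens.sigma1 + t * (edge - dens.sigma1)


def sigma_grid(
    theta: np.ndarray,
    phi: float,
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
) -> np.ndarray:
    """Vectorized sigma over an array of theta at fixed phi (no bounds
    checks beyond the patch definition; used by the quadrature oracle)."""
    coeffs = interpolation_coefficients(phi, frame, g)
    t = t_of_theta(theta, coeffs.C, coeffs.D)
    edge = (1.0 - coeffs.lam) * dens.sigma2 + coeffs.lam * dens.sigma3
    return dens.sigma1 + t * (edge - dens.sigma1)


def sigma_at_point(
    point: np.ndarray,
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    tol: float = 1e-9,
) -> float:
    """Interpolated density at a world-frame unit vector on the patch."""
    c = frame.to_canonical(np.asarray(point, dtype=float))
    theta = math.acos(min(1.0, max(-1.0, c[2])))
    phi = math.atan2(c[1], c[0])
    if phi < 0 and phi > -tol:
        phi = 0.0
    if theta < tol:
        return dens.sigma1
    return sigma_at(theta, phi, frame, g, dens, tol=tol)
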