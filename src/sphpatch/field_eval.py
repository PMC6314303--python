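"""Potential and field of a charged patch away from the patch itself.

Two regimes:

* on the same sphere, outside the patch: the radial field is exactly half
  the potential kernel,

      E_r = (1/2) int dphi int sin(theta) dtheta
            sigma(theta, phi) / sqrt(2 - 2 rhat~ . rhat),

  (an average of the interior and exterior radial derivatives of the
  spherical-harmonic expansion), expanded about the patch's average
  direction with the charge moments as coefficients;

* outside the sphere: the Coulomb kernel expanded about the average patch
  position r_ave = R * t, the standard shifted multipole expansion through
  second moments.

Both expansions are gated by a convergence criterion comparing the distance
of the evaluation direction to the patch against the patch diameter, with
adaptive quadrature as the fallback (and the reference).  Units: R = 1;
potentials scale as sigma R, fields as sigma.
"""

from __future__ import annotations

import math

import numpy as np

from .density import VertexDensities
from .geometry import CanonicalFrame, GeodesicParams, SphericalTriangle, beta_of_phi
from .patch_moments import PatchMoments, charge_moments
from .vertex_field import FieldEvaluation
from . import oracle as _oracle

__all__ = [
    "expansion_converges",
    "radial_field_on_sphere",
    "exterior_potential",
    "exterior_field",
    "point_in_patch",
]

#: evaluation directions closer than this arc to the patch boundary are
#: refused for on-sphere quadrature (documented contract)
BOUNDARY_EXCLUSION_ARC = 1e-3
#: series/expansion validity limit on patch arcs for method="auto"
AUTO_BETA_MAX = 0.35


def point_in_patch(
    direction, frame: CanonicalFrame, g: GeodesicParams, margin: float = 0.0
) -> bool:
    """Whether a unit direction lies inside the (closed) spherical triangle,
    optionally grown by ``margin`` radians in the polar coordinate."""
    c = frame.to_canonical(np.asarray(direction, dtype=float))
    phi = math.atan2(c[1], c[0])
    theta = math.acos(min(1.0, max(-1.0, c[2])))
    if theta <= margin:
        return True
    if not (-margin <= phi <= frame.alpha + margin):
        return False
    phi_c = min(max(phi, 0.0), frame.alpha)
    return theta <= beta_of_phi(phi_c, g) + margin


def expansion_converges(
    direction, tri: SphericalTriangle
) -> tuple[bool, float]:
    """Convergence gate for the on-sphere moment expansion:

        1 - (1/3) rhat~ . (r1 + r2 + r3)  >  2 [1 - min pairwise ri . rj]

    Returns (converges, margin = LHS - RHS)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    v = tri.vertices
    lhs = 1.0 - d @ (v[0] + v[1] + v[2]) / 3.0
    mindot = min(float(v[0] @ v[1]), float(v[1] @ v[2]), float(v[0] @ v[2]))
    rhs = 2.0 * (1.0 - mindot)
    margin = lhs - rhs
    return margin > 0.0, margin


def _onsphere_kernel_expansion(dc: np.ndarray, mom: PatchMoments) -> float:
    """Second-order expansion of (1/2) <1/sqrt(2-2 c)> over the charge
    distribution, about the average direction t (canonical frame)."""
    t = mom.t
    c0 = float(dc @ t)
    one_m = 1.0 - c0
    # x = d.(rhat - t) / (1 - d.t); need <x> and <x^2> over sigma dA
    dm1 = float(dc @ mom.m1)
    dm2 = float(dc @ mom.m2 @ dc)
    x1 = (dm1 - c0 * mom.q0) / one_m
    x2 = (dm2 - 2.0 * c0 * dm1 + c0 * c0 * mom.q0) / one_m**2
    series = mom.q0 + 0.5 * x1 + 0.375 * x2
    return series / (2.0 * math.sqrt(2.0 * one_m))


def radial_field_on_sphere(
    direction,
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    tri: SphericalTriangle | None = None,
    method: str = "auto",
    moments: PatchMoments | None = None,
) -> FieldEvaluation:
    """Radial electric field at a unit direction on the sphere, outside the
    patch (units of sigma; multiply by 1 for fields, by R for potential via
    the identity potential = 2 R E_r).

    ``method``: "expansion" forces the second-order moment expansion
    (errors if the convergence gate fails), "quadrature" forces the oracle,
    "auto" selects the expansion iff the gate passes and the patch is in
    the small-arc regime.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if point_in_patch(d, frame, g, margin=BOUNDARY_EXCLUSION_ARC):
        raise ValueError(
            "evaluation direction inside or within the boundary exclusion "
            "zone of the patch; use the vertex-field machinery instead"
        )
    if tri is None:
        verts = [frame.vertex_canonical(i) for i in (1, 2, 3)]
        tri = SphericalTriangle(*[frame.from_canonical(v) for v in verts])
    ok, margin = expansion_converges(d, tri)
    use_exp = {
        "auto": ok and tri.max_side_arc() <= AUTO_BETA_MAX,
        "expansion": True,
        "quadrature": False,
    }[method]
    if method == "expansion" and not ok:
        raise ValueError(
            f"moment expansion does not converge here (margin {margin:.3g})"
        )
    if use_exp:
        if moments is None:
            moments = charge_moments(frame, g, dens, method="exact")
        dc = frame.to_canonical(d)
        val = _onsphere_kernel_expansion(dc, moments)
        # third-order term scale as truncation estimate
        one_m = 1.0 - float(dc @ moments.t)
        diam = tri.max_side_arc()
        err = abs(moments.q0) * (diam**2 / (2.0 * one_m)) ** 1.5 / (
            2.0 * math.sqrt(2.0 * one_m)
        )
        return FieldEvaluation(value=val, method="moment_expansion", err_est=err)
    val = _oracle.radial_field_quadrature(d, frame, g, dens)
    return FieldEvaluation(value=val, method="quadrature", err_est=1e-10)


def _exterior_expansion_terms(pt: np.ndarray, mom: PatchMoments):
    """Potential (and its gradient) of the shifted second-order expansion
    about r_ave, at exterior point ``pt`` (canonical frame)."""
    t = mom.t
    dvec = pt - t
    dsq = float(dvec @ dvec)
    dlen = math.sqrt(dsq)
    t2 = float(t @ t)
    # w = (2 pt.(r - t) + t^2 - 1) / d^2 for unit-sphere source points r
    wc = (t2 - 1.0 - 2.0 * float(pt @ t)) / dsq
    ptm1 = float(pt @ mom.m1)
    ptm2 = float(pt @ mom.m2 @ pt)
    # <(1 - w)^(-1/2)> ~ <1 + w/2 + 3 w^2/8>
    val = (
        mom.q0 * (1.0 + 0.5 * wc + 0.375 * wc * wc)
        + ptm1 * (1.0 + 1.5 * wc) / dsq
        + 1.5 * ptm2 / dsq**2
    ) / dlen
    # gradient w.r.t. pt
    grad_wc = (-2.0 * t - 2.0 * wc * dvec) / dsq
    grad_val = (
        mom.q0 * (0.5 + 0.75 * wc) * grad_wc
        + (mom.m1 * (1.0 + 1.5 * wc) + ptm1 * 1.5 * grad_wc) / dsq
        - ptm1 * (1.0 + 1.5 * wc) * 2.0 * dvec / dsq**2
        + 3.0 * (mom.m2 @ pt) / dsq**2
        - 6.0 * ptm2 * dvec / dsq**3
    ) / dlen
    grad_val += val * (-dvec / dsq)
    return val, grad_val


def _exterior_eval(
    point, frame, g, dens, method, moments, want_field
) -> FieldEvaluation:
    pt = np.asarray(point, dtype=float)
    r = np.linalg.norm(pt)
    if r <= 1.0:
        raise ValueError("exterior evaluation requires |r| > R")
    if moments is None:
        moments = charge_moments(frame, g, dens, method="exact")
    ptc = frame.to_canonical(pt)
    verts = [frame.vertex_canonical(i) for i in (1, 2, 3)]
    tri = SphericalTriangle(*[frame.from_canonical(v) for v in verts])
    diam = tri.max_side_arc()
    dist_to_ave = np.linalg.norm(ptc - moments.t)
    use_exp = {
        "auto": dist_to_ave >= 2.0 * diam,
        "expansion": True,
        "quadrature": False,
    }[method]
    if use_exp:
        val, grad = _exterior_expansion_terms(ptc, moments)
        err = abs(moments.q0) * (diam / dist_to_ave) ** 3 / dist_to_ave
        if want_field:
            return FieldEvaluation(
                value=frame.from_canonical(-grad),
                method="moment_expansion",
                err_est=err,
            )
        return FieldEvaluation(value=val, method="moment_expansion", err_est=err)
    if want_field:
        val = _oracle.field_quadrature(pt, frame, g, dens)
    else:
        val = _oracle.potential_quadrature(pt, frame, g, dens)
    return FieldEvaluation(value=val, method="quadrature", err_est=1e-10)


def exterior_potential(
    point,
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    method: str = "auto",
    moments: PatchMoments | None = None,
) -> FieldEvaluation:
    """Potential at a point outside the sphere (world frame, units
    sigma * R); far limit q0 R^2 / |r|."""
    return _exterior_eval(point, frame, g, dens, method, moments, False)


def exterior_field(
    point,
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    method: str = "auto",
    moments: PatchMoments | None = None,
) -> FieldEvaluation:
    """Electric field 3-vector at a point outside the sphere (world
    frame); the expansion route differentiates the shifted expansion term
    by term."""
    return _exterior_eval(point, frame, g, dens, method, moments, True)
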