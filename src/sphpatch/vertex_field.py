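"""Electric field just above/below a vertex of a charged patch.

The field at a charged surface splits into a continuous (principal-value)
part plus a jump of +/- 2 pi sigma (Gaussian units) on the two sides.  For a
point at a vertex of the canonical patch the continuous normal component is

    E_z = int_0^alpha dphi int_0^beta(phi) sigma(theta, phi)
          sin(theta) dtheta / (2 sqrt(2) sqrt(1 - cos(theta)))

which is regular (sin(theta)/sqrt(2-2cos theta) = cos(theta/2)).  The theta
integral has an exact closed form; expanding it in the arc-length parameter
1/(a cos(phi - phi0)) = O(beta) gives the series evaluated through the F/G
integral family with a strict beta-order truncation.

Fields are reported in units of the vertex charge density scale (Gaussian
units, R = 1 internally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .density import (
    VertexDensities,
    interpolation_coefficients,
)
from .geometry import (
    CanonicalFrame,
    GeodesicParams,
    SphericalTriangle,
    beta_of_phi,
    canonicalize,
    geodesic_params,
)
from .series_integrals import F_series, G_term, substitution_params
from . import oracle as _oracle

__all__ = [
    "FieldEvaluation",
    "PatchTooLargeError",
    "cap_axial_field",
    "ez_theta_integral_exact",
    "ez_continuous",
    "ez_at_vertex",
    "DEFAULT_BETA_MAX",
]

#: default validity limit (radians) for series mode on any side arc
DEFAULT_BETA_MAX = 0.35

_SQRT2 = math.sqrt(2.0)


class PatchTooLargeError(ValueError):
    """Raised when a patch exceeds the series validity range; callers
    should fall back to the quadrature oracle."""


@dataclass(frozen=True)
class FieldEvaluation:
    """Field (or potential) evaluation result with provenance."""

    value: float | np.ndarray
    method: str            # "series" | "moment_expansion" | "quadrature"
    err_est: float = 0.0
    order: int | None = None
    side: str = "none"     # "above" | "below" | "none"

    def __post_init__(self):
        if self.err_est < 0:
            raise ValueError("err_est must be nonnegative")
        if self.method not in ("series", "moment_expansion", "quadrature"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.side not in ("above", "below", "none"):
            raise ValueError(f"unknown side {self.side!r}")


def cap_axial_field(beta: float, side: str, sigma: float) -> float:
    """Axial field of a uniformly charged spherical cap 0 <= theta <= beta
    at a point immediately above/below the pole:

        E_z = 2 pi sigma [ sin(beta/2) + sgn ],  sgn = +1 above, -1 below.

    ``side="none"`` returns the continuous part only.  Gauss-law limits:
    beta = pi gives 4 pi sigma above and 0 below.
    """
    if not (0.0 < beta <= math.pi):
        raise ValueError("beta must be in (0, pi]")
    jump = {"above": 1.0, "below": -1.0, "none": 0.0}[side]
    return 2.0 * math.pi * sigma * (math.sin(beta / 2.0) + jump)


def ez_theta_integral_exact(phi, coeffs, beta_phi: float | None = None) -> float:
    """Exact theta integral of the t-weighted vertex kernel at azimuth phi:

        I = int_0^beta(phi)  t(theta) cos(theta/2) / 2  dtheta ,
        t(theta) = sin(theta) / (C sin(theta) + D cos(theta)).

    Closed form obtained by rationalizing the denominator
    (C sin + D cos -> C^2 (1 - eta^2 cos^2 theta)) and partial fractions in
    u = sqrt(2) sin(theta/2) and v = sqrt(2) cos(theta/2).  Requires the
    positivity condition eta cos(beta) > 1 (equivalently
    (1 - delta/R) cos beta > 1/2); otherwise falls back to quadrature.
    """
    C, D = coeffs.C, coeffs.D
    beta = coeffs.beta if beta_phi is None else beta_phi
    eta = math.sqrt(coeffs.eta_sq)
    if eta * eta * math.cos(beta) ** 2 <= 1.0 + 1e-12:
        import warnings

        warnings.warn(
            "eta*cos(beta) <= 1: closed form invalid, using quadrature",
            stacklevel=2,
        )
        val, _ = quad(
            lambda th: math.sin(th)
            / (C * math.sin(th) + D * math.cos(th))
            * math.cos(th / 2.0)
            / 2.0,
            0.0,
            beta,
            epsabs=1e-15,
            epsrel=1e-12,
        )
        return val
    cm, cp = 1.0 - 1.0 / eta, 1.0 + 1.0 / eta
    u0 = _SQRT2 * math.sin(beta / 2.0)
    v0 = _SQRT2 * math.cos(beta / 2.0)
    amp = (eta * eta - 1.0) / (2.0 * eta)
    jm = -math.atanh(u0 / math.sqrt(cm)) / math.sqrt(cm)
    jp = -math.atanh(u0 / math.sqrt(cp)) / math.sqrt(cp)
    part1 = (u0 + amp * (jm - jp)) / (_SQRT2 * C * eta * eta)

    def bigk(c: float) -> float:
        sc = math.sqrt(c)
        return math.log(
            (_SQRT2 - sc) * (v0 + sc) / ((_SQRT2 + sc) * (v0 - sc))
        ) / (2.0 * sc)

    part2 = (
        D
        / (_SQRT2 * C * C * eta * eta)
        * ((_SQRT2 - v0) + 0.5 * cp * bigk(cp) + 0.5 * cm * bigk(cm))
    )
    return part1 + part2


# Series coefficients of the vertex field.
#
# sigma1 part: the theta integral is sin(beta(phi)/2) whose expansion in
# eps = 1/(a cos(phi-phi0)) is (eps/2)(1 - 3/8 eps^2 + 31/128 eps^4
# - 187/1024 eps^6 + ...), giving F(0,0,p) weights below.
_SIGMA1_COEF = {1: 0.5, 3: -3.0 / 16.0, 5: 31.0 / 256.0, 7: -187.0 / 2048.0}
# B(phi) part: t-kernel expansion
#   (1/(a cos)) [1/4 + (16 h - 19)/(192 a^2 cos^2)
#                + (640 h^2 - 216 h + 507)/(7680 a^4 cos^4) + ...]
# expressed as weights of F(l, d, p) with d = 0 (sigma2-sigma1 slot) or
# d = 1 (sigma3-sigma2 slot); entries are (coef, l, p).
_BPART_COEF = {
    1: [(0.25, 0, 1)],
    3: [(-19.0 / 192.0, 0, 3), (1.0 / 12.0, 1, 3)],
    5: [
        (507.0 / 7680.0, 0, 5),
        (-216.0 / 7680.0, 1, 5),
        (640.0 / 7680.0, 2, 5),
    ],
}


def _series_validity(frame: CanonicalFrame, g: GeodesicParams, beta_max: float):
    arcs = (frame.beta2, frame.beta3, g.beta1)
    if max(arcs) > beta_max:
        raise PatchTooLargeError(
            f"max side arc {max(arcs):.3f} exceeds series limit {beta_max}; "
            "use the quadrature oracle"
        )
    if g.a < 1.0:
        raise PatchTooLargeError("geodesic parameter a < 1: series invalid")


def ez_continuous(
    frame: CanonicalFrame,
    g: GeodesicParams,
    dens: VertexDensities,
    order: int = 3,
    beta_max: float = DEFAULT_BETA_MAX,
) -> FieldEvaluation:
    """Continuous part of the normal field at the pole vertex, summed to
    the requested beta order (1, 3, 5 via the G-integral combinations;
    7 routes the azimuthal integral numerically over the series kernel).

    The sigma-difference terms carry one extra beta order (neighboring
    vertex densities of a smooth distribution differ at O(beta)), so they
    are truncated one order lower (see the methods note).
    """
    if order not in (1, 3, 5, 7):
        raise ValueError("order must be 1, 3, 5 or 7")
    _series_validity(frame, g, beta_max)
    s1 = dens.sigma1
    d2 = dens.sigma2 - dens.sigma1
    d3 = dens.sigma3 - dens.sigma2
    sub = substitution_params(frame, g)
    if order == 7:
        value = _ez_series_order7(frame, g, dens)
    else:
        total = 0.0
        for p, coef in _SIGMA1_COEF.items():
            if p <= order:
                total += s1 * coef * F_series(0, 0, 0, 0, p, order, frame, g, sub=sub)
        for p, terms in _BPART_COEF.items():
            if p <= order - 1 or (order == 1 and p == 1):
                # at order 1 nothing from B survives (B itself is O(beta))
                if order == 1:
                    continue
                for coef, l, pp in terms:
                    total += d2 * coef * F_series(
                        0, 0, l, 0, pp, order - 1, frame, g, sub=sub
                    )
                    total += d3 * coef * F_series(
                        0, 0, l, 1, pp, order - 1, frame, g, sub=sub
                    )
        value = total
    # truncation estimate: magnitude of the first dropped sigma1/B terms
    nxt = abs(G_term(0, 0, 0, 0, 0, min(order + 2, 7), frame, g, sub=sub))
    err = abs(s1) * nxt + (abs(d2) + abs(d3)) * nxt
    return FieldEvaluation(value=value, method="series", err_est=err, order=order)


def _ez_series_order7(frame, g, dens) -> float:
    """O(beta^7) field: numeric phi integration of the series theta-kernel
    (all four retained kernel terms), plus the exact sigma1 theta integral
    sin(beta/2) integrated numerically."""
    s1 = dens.sigma1
    d2 = dens.sigma2 - dens.sigma1
    d3 = dens.sigma3 - dens.sigma2

    def integrand(phi):
        co = interpolation_coefficients(phi, frame, g)
        ac = g.a * math.cos(phi - g.phi0)
        h = co.h_tilde
        kern = (
            0.25
            + (16.0 * h - 19.0) / 192.0 / ac**2
            + (640.0 * h * h - 216.0 * h + 507.0) / 7680.0 / ac**4
            + (186368.0 * h**3 - 47488.0 * h * h + 29280.0 * h - 87637.0)
            / 1720320.0
            / ac**6
        ) / ac
        b = d2 + co.lam * d3
        return s1 * math.sin(co.beta / 2.0) + b * kern

    val, _ = quad(integrand, 0.0, frame.alpha, epsabs=1e-15, epsrel=1e-12, limit=200)
    return val


def ez_at_vertex(
    patches: list[SphericalTriangle],
    sigmas: list,
    vertex_ids: list[int],
    side: str = "above",
    order: int = 3,
    beta_max: float = DEFAULT_BETA_MAX,
    allow_quadrature: bool = True,
) -> FieldEvaluation:
    """Normal field immediately above/below a vertex shared by ``patches``.

    Parameters
    ----------
    patches : list of SphericalTriangle sharing the vertex.
    sigmas : per-patch (sigma1, sigma2, sigma3) in each patch's own vertex
        order; the densities assigned to the shared vertex must agree.
    vertex_ids : 1-based index of the shared vertex within each patch.
    side : "above" adds +2 pi sigma_vertex, "below" adds -2 pi sigma_vertex,
        "none" returns the continuous sum only.

    The continuous parts use the series when each patch fits the series
    regime, otherwise (if ``allow_quadrature``) the regularized quadrature
    oracle.
    """
    if len(patches) != len(sigmas) or len(patches) != len(vertex_ids):
        raise ValueError("patches, sigmas, vertex_ids must have equal length")
    sigma_vertex = None
    total = 0.0
    err = 0.0
    used_quadrature = False
    for tri, sig, vid in zip(patches, sigmas, vertex_ids):
        sig = np.asarray(sig, dtype=float)
        sv = float(sig[vid - 1])
        if sigma_vertex is None:
            sigma_vertex = sv
        elif abs(sv - sigma_vertex) > 1e-12 * max(1.0, abs(sigma_vertex)):
            raise ValueError(
                "inconsistent densities at the shared vertex "
                f"({sv} vs {sigma_vertex})"
            )
        frame = canonicalize(tri, pole_index=vid)
        g = geodesic_params(frame)
        dens = VertexDensities.from_frame(sig, frame)
        try:
            ev = ez_continuous(frame, g, dens, order=order, beta_max=beta_max)
            total += ev.value
            err += ev.err_est
        except PatchTooLargeError:
            if not allow_quadrature:
                raise
            total += _oracle.vertex_ez_quadrature(frame, g, dens)
            used_quadrature = True
    jump = {"above": 1.0, "below": -1.0, "none": 0.0}[side]
    total += 2.0 * math.pi * sigma_vertex * jump
    return FieldEvaluation(
        value=total,
        method="quadrature" if used_quadrature else "series",
        err_est=err,
        order=None if used_quadrature else order,
        side=side,
    )
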