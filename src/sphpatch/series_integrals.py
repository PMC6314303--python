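"""The F/G family of azimuthal integrals behind every series result.

All series expansions of patch fields and moments reduce to integrals

    F_{nc,ns}(l, d, p) = int_0^alpha  h~^l lam^d cos^nc(phi) sin^ns(phi)
                         / (a^p cos^p(phi - phi0))  dphi

with h~ = zeta23 lam (1-lam) a^2 cos^2(phi-phi0) an order-1 quantity.  With
x = tan(phi/2) each F becomes a rational integral; expanding the near-equal
denominators tan(phi0) vs (sin b3/sin b2 - cos a)/sin a (they differ at
O(beta^2)) yields terms G(l, d, k, p) of order beta^(p+2k), so truncating
the k-sum at floor((order - p)/2) retains a prescribed beta order.

The defining integrals are evaluated by adaptive Gauss-Kronrod quadrature
(rel tol 1e-12); the integrands are smooth on the closed interval, so this
is exact to working precision while keeping the closed-form bookkeeping of
the series in the truncation rule rather than in large antiderivative
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .density import lambda_of_phi
from .geometry import CanonicalFrame, GeodesicParams

__all__ = [
    "SubstitutionParams",
    "substitution_params",
    "sec_odd_integral",
    "F_direct",
    "G_term",
    "F_series",
    "k_max_for_order",
]

_QUAD_OPTS = dict(epsabs=1e-15, epsrel=1e-12, limit=200)


@dataclass(frozen=True)
class SubstitutionParams:
    """Shorthand quantities of the x = tan(phi/2) substitution."""

    A: float        # sin(beta3)
    B1: float       # sin(beta2) sin(alpha)
    B2: float       # -sin(beta2) cos(alpha)
    mu: float       # B2/B1 = -cot(alpha)
    tau: float      # tan(phi0)
    tau_prime: float  # (A + B2)/B1
    x_max: float    # tan(alpha/2)
    zeta23: float
    kappa: float    # 1 - cos(beta2)/cos(beta3); (tau' - tau) = (A/B1) * kappa

    def f(self, x):
        """f(x) = 1 - x^2 + 2 tau x; positive on [0, x_max]."""
        return 1.0 - x * x + 2.0 * self.tau * x


def substitution_params(frame: CanonicalFrame, g: GeodesicParams) -> SubstitutionParams:
    b2, b3, al = frame.beta2, frame.beta3, frame.alpha
    A = math.sin(b3)
    B1 = math.sin(b2) * math.sin(al)
    B2 = -math.sin(b2) * math.cos(al)
    return SubstitutionParams(
        A=A,
        B1=B1,
        B2=B2,
        mu=B2 / B1,
        tau=math.tan(g.phi0),
        tau_prime=(A + B2) / B1,
        x_max=math.tan(al / 2.0),
        zeta23=frame.zeta23,
        kappa=1.0 - math.cos(b2) / math.cos(b3),
    )


def sec_odd_integral(l: int, phi0: float, alpha: float) -> float:
    """Closed form of  int_0^alpha sec^(2l+1)(phi - phi0) dphi.

    With y = sin(phi - phi0) this is int dy / (1-y^2)^(l+1) between
    -sin(phi0) and sin(alpha - phi0):

        (2l-1)!!/(2^(l+1) l!) * ln((1+y)/(1-y))
        + sum_{p=0}^{l-1} (2l-1)!! (l-p-1)! / (2^(p+1) l! (2l-1-2p)!!)
                          * y / (1-y^2)^(l-p)

    valid while cos(phi - phi0) > 0 on the whole range.
    """
    if l < 0:
        raise ValueError("l must be nonnegative")
    if math.cos(-phi0) <= 0 or math.cos(alpha - phi0) <= 0:
        raise ValueError("integrand pole inside [0, alpha]")
    # cos(phi-phi0) has a single max at phi = phi0; checking endpoints suffices.
    dfact = lambda n: 1.0 if n <= 0 else math.prod(range(n, 0, -2))

    def antideriv(y: float) -> float:
        out = dfact(2 * l - 1) / (2.0 ** (l + 1) * math.factorial(l)) * math.log(
            (1.0 + y) / (1.0 - y)
        )
        for p in range(l):
            coef = (
                dfact(2 * l - 1)
                * math.factorial(l - p - 1)
                / (2.0 ** (p + 1) * math.factorial(l) * dfact(2 * l - 1 - 2 * p))
            )
            out += coef * y / (1.0 - y * y) ** (l - p)
        return out

    return antideriv(math.sin(alpha - phi0)) - antideriv(-math.sin(phi0))


def _f_integrand(frame: CanonicalFrame, g: GeodesicParams, nc, ns, l, d, p):
    zeta = frame.zeta23
    a, phi0 = g.a, g.phi0

    def integrand(phi):
        lam = lambda_of_phi(phi, frame)
        ac = a * math.cos(phi - phi0)
        h = zeta * lam * (1.0 - lam) * ac * ac
        val = h**l * lam**d
        if nc:
            val *= math.cos(phi) ** nc
        if ns:
            val *= math.sin(phi) ** ns
        return val / ac**p

    return integrand


def F_direct(
    nc: int, ns: int, l: int, d: int, p: int,
    frame: CanonicalFrame, g: GeodesicParams,
) -> float:
    """F_{nc,ns}(l, d, p) by adaptive quadrature of the defining integral."""
    if g.a <= 0:
        raise ValueError("F integrals require a > 0 (series regime)")
    val, _ = quad(_f_integrand(frame, g, nc, ns, l, d, p), 0.0, frame.alpha, **_QUAD_OPTS)
    return val


def G_term(
    nc: int, ns: int, l: int, d: int, k: int, p: int,
    frame: CanonicalFrame, g: GeodesicParams,
    sub: SubstitutionParams | None = None,
) -> float:
    """Single term G_{nc,ns}(l, d, k, p) of the expansion of F, of order
    beta^(p+2k).  For l = d = 0 only k = 0 is nonzero and equals F exactly.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    if sub is None:
        sub = substitution_params(frame, g)
    # C(2l+d+k-1, k); equals 1 at k = 0 (including the l = d = 0 case where
    # the top index is -1) and 0 whenever k exceeds the expansion order.
    binom = 1 if k == 0 else (
        math.comb(2 * l + d + k - 1, k) if 2 * l + d + k - 1 >= k else 0
    )
    if binom == 0:
        return 0.0
    a, phi0 = g.a, g.phi0
    pref = (
        2.0
        * sub.zeta23**l
        * (2.0 * sub.A / sub.B1) ** (l + d + k)
        * (a * math.cos(phi0)) ** (2 * l - p)
        * (-1.0) ** k
        * binom
        * sub.kappa**k
    )
    mu, tau = sub.mu, sub.tau
    nden = p + d + k
    npow = 2 * l - p + 1 + nc + ns

    def integrand(x):
        x2 = x * x
        qmu = 1.0 - x2 + 2.0 * mu * x
        qtau = 1.0 - x2 + 2.0 * tau * x
        val = x ** (l + d + k + ns) * (1.0 - x2) ** nc
        if l:
            val *= qmu**l
        if ns:
            val *= 2.0**ns
        return val / (qtau**nden * (1.0 + x2) ** npow)

    val, _ = quad(integrand, 0.0, sub.x_max, **_QUAD_OPTS)
    return pref * val


def k_max_for_order(p: int, target_order: int) -> int:
    """Number of retained correction terms: k <= floor((order - p)/2).

    Matches the stated truncation cases (p=5 -> k=0, p=3 -> k<=1,
    p=1 -> k<=2 for an O(beta^5) result)."""
    if target_order < p:
        raise ValueError("target_order must be >= p")
    return (target_order - p) // 2


def F_series(
    nc: int, ns: int, l: int, d: int, p: int,
    target_order: int,
    frame: CanonicalFrame, g: GeodesicParams,
    sub: SubstitutionParams | None = None,
    return_terms: bool = False,
):
    """Partial sum of G terms approximating F to O(beta^target_order).

    Returns the value, or ``(value, terms)`` with the individual G terms
    when ``return_terms`` is true.  For l = d = 0 the single k = 0 term is
    exact regardless of the requested order.
    """
    if sub is None:
        sub = substitution_params(frame, g)
    kmax = 0 if (l == 0 and d == 0) else k_max_for_order(p, target_order)
    terms = [
        G_term(nc, ns, l, d, k, p, frame, g, sub=sub) for k in range(kmax + 1)
    ]
    total = math.fsum(terms)
    if return_terms:
        return total, terms
    return total
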