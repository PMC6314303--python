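"""Field just above/below a patch vertex: cap limits, exact theta
integral, series vs quadrature, and the 4 pi sigma jump."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from sphpatch.density import VertexDensities, interpolation_coefficients
from sphpatch.geometry import SphericalTriangle, canonicalize, geodesic_params
from sphpatch.io import FixtureSpec, generate_fixtures
from sphpatch.oracle import vertex_ez_quadrature
from sphpatch.vertex_field import (
    PatchTooLargeError,
    cap_axial_field,
    ez_at_vertex,
    ez_continuous,
    ez_theta_integral_exact,
)

from conftest import canonical_frame


def cap_field_1d(beta: float, s: float) -> float:
    """1-D quadrature of the cap field at s = R/(R + eps); extra break
    points resolve the boundary layer of width ~ sqrt(eps) near theta = 0."""
    def integrand(theta):
        c = math.cos(theta)
        return (
            2.0 * math.pi * s * s * math.sin(theta) * (1.0 - s * c)
            / (1.0 + s * s - 2.0 * s * c) ** 1.5
        )

    val, _ = quad(integrand, 0.0, beta, epsabs=1e-13, epsrel=1e-11,
                  points=[1e-4, 1e-3, 1e-2, 0.1], limit=800)
    return val


class TestCapField:
    def test_gauss_law_limits(self):
        assert cap_axial_field(math.pi, "above", 1.0) == pytest.approx(
            4.0 * math.pi, abs=1e-14
        )
        assert cap_axial_field(math.pi, "below", 1.0) == 0.0

    def test_against_boundary_layer_quadrature(self):
        """The defining integral evaluated at eps/R = +/- 1e-6 approaches
        the surface limits (residual is O(sqrt(eps)))."""
        beta, sigma = math.pi / 3, 1.0
        for side, sign in (("above", 1.0), ("below", -1.0)):
            val = cap_field_1d(beta, 1.0 / (1.0 + 1e-6 * sign))
            assert cap_axial_field(beta, side, sigma) == pytest.approx(
                val, abs=2e-3
            )

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            cap_axial_field(0.0, "above", 1.0)


class TestThetaIntegralExact:
    def test_against_quadrature_random_fixtures(self):
        fixtures = generate_fixtures(FixtureSpec(seed=3, n=10, arc_range=(0.05, 0.3)))
        checked = 0
        for patch in fixtures:
            frame = canonicalize(patch.tri, 1)
            g = geodesic_params(frame)
            for phi in np.linspace(0.02, frame.alpha - 0.02, 5):
                co = interpolation_coefficients(phi, frame, g)
                closed = ez_theta_integral_exact(phi, co)
                ref, _ = quad(
                    lambda th: math.sin(th)
                    / (co.C * math.sin(th) + co.D * math.cos(th))
                    * math.cos(th / 2.0) / 2.0,
                    0.0,
                    co.beta,
                    epsabs=1e-16,
                    epsrel=1e-13,
                )
                assert closed == pytest.approx(ref, rel=1e-10)
                checked += 1
        assert checked == 50

    def test_leading_order_head(self):
        """At tiny beta the integral approaches 1/(4 a cos(phi - phi0))."""
        frame, g = canonical_frame(0.01, 0.01, math.pi / 3)
        phi = frame.alpha / 2
        co = interpolation_coefficients(phi, frame, g)
        head = 1.0 / (4.0 * g.a * math.cos(phi - g.phi0))
        assert ez_theta_integral_exact(phi, co) == pytest.approx(head, rel=1e-4)

    def test_invalid_regime_falls_back_with_warning(self):
        class FakeCoeffs:
            C = 0.8
            D = 0.3
            beta = 1.4
            eta_sq = 1.0 + (0.3 / 0.8) ** 2

        with pytest.warns(UserWarning, match="quadrature"):
            val = ez_theta_integral_exact(0.1, FakeCoeffs())
        ref, _ = quad(
            lambda th: math.sin(th)
            / (0.8 * math.sin(th) + 0.3 * math.cos(th))
            * math.cos(th / 2.0) / 2.0,
            0.0,
            1.4,
        )
        assert val == pytest.approx(ref, rel=1e-9)

    def test_regularization_identity(self):
        thetas = np.linspace(0.01, math.pi - 0.01, 1000)
        lhs = np.sin(thetas) / np.sqrt(1.0 - np.cos(thetas))
        rhs = math.sqrt(2.0) * np.cos(thetas / 2.0)
        assert np.max(np.abs(lhs - rhs)) < 1e-12


class TestEzContinuous:
    def test_zero_density(self):
        frame, g = canonical_frame(0.1, 0.1, math.pi / 3)
        ev = ez_continuous(frame, g, VertexDensities(0.0, 0.0, 0.0), order=3)
        assert ev.value == 0.0
        assert ev.method == "series"

    def test_uniform_patch_vs_oracle(self):
        frame, g = canonical_frame(0.1, 0.1, math.pi / 3)
        dens = VertexDensities(1.0, 1.0, 1.0)
        ref = vertex_ez_quadrature(frame, g, dens)
        ev = ez_continuous(frame, g, dens, order=3)
        assert abs(ev.value - ref) <= abs(ref) * 0.1**2  # O(beta^3)/O(beta)
        assert ev.order == 3

    @pytest.mark.parametrize("order,tol", [(1, 3e-3), (3, 3e-6), (5, 5e-8), (7, 1e-11)])
    def test_order_hierarchy(self, order, tol):
        frame, g = canonical_frame(0.1, 0.08, 1.0)
        dens = VertexDensities(1.0, 0.9, 1.1)
        ref = vertex_ez_quadrature(frame, g, dens)
        ev = ez_continuous(frame, g, dens, order=order)
        assert abs(ev.value - ref) < tol

    def test_series_accuracy_small_arcs(self):
        """Order 3 within 1% relative at arcs <= 0.15; within 0.1% at
        arcs <= 0.05."""
        for arcs, tol in (((0.03, 0.15), 1e-2), ((0.02, 0.05), 1e-3)):
            spec = FixtureSpec(seed=21, n=10, arc_range=arcs, sigma_range=(0.5, 1.5))
            for patch in generate_fixtures(spec):
                frame = canonicalize(patch.tri, 1)
                g = geodesic_params(frame)
                dens = VertexDensities.from_frame(patch.sigma, frame)
                ref = vertex_ez_quadrature(frame, g, dens)
                ev = ez_continuous(frame, g, dens, order=3)
                assert abs(ev.value - ref) <= tol * max(abs(ref), 1e-3)

    def test_refuses_large_patch(self):
        frame, g = canonical_frame(0.6, 0.6, 1.0)
        with pytest.raises(PatchTooLargeError):
            ez_continuous(frame, g, VertexDensities(1.0, 1.0, 1.0))


def pole_cap_tiling(n: int, beta: float):
    ring = [
        (
            math.sin(beta) * math.cos(2 * math.pi * i / n),
            math.sin(beta) * math.sin(2 * math.pi * i / n),
            math.cos(beta),
        )
        for i in range(n)
    ]
    tris = [
        SphericalTriangle((0, 0, 1), ring[i], ring[(i + 1) % n]) for i in range(n)
    ]
    return tris


class TestEzAtVertex:
    def test_cap_tiling_matches_cap_closed_form(self):
        """A polar cap tiled by 12 congruent triangles reproduces the cap
        field within the series truncation error."""
        beta = 0.25
        tris = pole_cap_tiling(12, beta)
        sigmas = [(1.0, 1.0, 1.0)] * 12
        vids = [1] * 12
        ev = ez_at_vertex(tris, sigmas, vids, side="none", order=5)
        ref = cap_axial_field(beta, "none", 1.0)
        # the tiling is not the cap: the 12 geodesic outer edges cut
        # slightly inside the circle theta = beta
        cap_area = 2.0 * math.pi * (1.0 - math.cos(beta))
        from sphpatch.patch_moments import area as patch_area

        tiled_area = sum(
            patch_area(canonicalize(t, 1), geodesic_params(canonicalize(t, 1)))
            for t in tris
        )
        # leading field ~ area/(2 pi) * d(field)/d(area); compare at
        # matching solid angle instead of raw beta
        beta_eff = math.acos(1.0 - tiled_area / (2.0 * math.pi))
        ref_eff = cap_axial_field(beta_eff, "none", 1.0)
        assert ev.value == pytest.approx(ref_eff, rel=5e-3)
        assert ev.value < ref  # strictly smaller than the full cap

    def test_jump_is_4pi_sigma(self):
        tris = pole_cap_tiling(6, 0.2)
        sig = 0.37
        sigmas = [(sig, 0.5, 0.1)] * 6
        vids = [1] * 6
        above = ez_at_vertex(tris, sigmas, vids, side="above", order=3).value
        below = ez_at_vertex(tris, sigmas, vids, side="below", order=3).value
        assert above - below == pytest.approx(4.0 * math.pi * sig, abs=1e-12)

    def test_zero_vertex_density_no_jump(self):
        tris = pole_cap_tiling(6, 0.2)
        sigmas = [(0.0, 0.5, 0.1)] * 6
        vids = [1] * 6
        above = ez_at_vertex(tris, sigmas, vids, side="above", order=3).value
        below = ez_at_vertex(tris, sigmas, vids, side="below", order=3).value
        assert above == pytest.approx(below, abs=1e-14)

    def test_inconsistent_shared_density_rejected(self):
        tris = pole_cap_tiling(6, 0.2)[:2]
        sigmas = [(1.0, 0.5, 0.1), (0.9, 0.5, 0.1)]
        with pytest.raises(ValueError, match="inconsistent"):
            ez_at_vertex(tris, sigmas, [1, 1], side="above")

    def test_large_patch_falls_back_to_quadrature(self):
        tris = pole_cap_tiling(4, 0.8)
        sigmas = [(1.0, 1.0, 1.0)] * 4
        ev = ez_at_vertex(tris, sigmas, [1] * 4, side="none", order=3)
        assert ev.method == "quadrature"
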