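"""Central-projection density interpolation over the spherical triangle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sphpatch.density import (
    VertexDensities,
    delta_of_phi,
    interpolation_coefficients,
    lambda_of_phi,
    sigma_at,
    sigma_at_point,
    t_of_theta,
)
from sphpatch.geometry import (
    SphericalTriangle,
    beta_of_phi,
    canonicalize,
    geodesic_params,
)

from conftest import canonical_frame, canonical_triangle


def lambda_3d_oracle(phi, frame):
    """Chord fraction by direct intersection of the azimuthal half-plane
    with the flat chord v2 -> v3 in Cartesian coordinates."""
    r2 = frame.vertex_canonical(2)
    r3 = frame.vertex_canonical(3)
    c, s = math.cos(phi), math.sin(phi)
    # P(lam) = r2 + lam (r3 - r2) with  Py cos(phi) - Px sin(phi) = 0
    num = r2[1] * c - r2[0] * s
    den = (r3[1] - r2[1]) * c - (r3[0] - r2[0]) * s
    return -num / den


class TestLambda:
    def test_endpoints(self):
        frame, _ = canonical_frame(0.2, 0.1, 1.0)
        assert lambda_of_phi(0.0, frame) == 0.0
        assert lambda_of_phi(frame.alpha, frame) == pytest.approx(1.0, abs=1e-15)

    def test_symmetric_midpoint(self):
        frame, _ = canonical_frame(0.15, 0.15, math.pi / 3)
        assert lambda_of_phi(frame.alpha / 2, frame) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("phi", [0.1, 0.4, 0.7, 0.95])
    def test_against_3d_intersection(self, phi):
        frame, _ = canonical_frame(0.2, 0.1, 1.0)
        assert lambda_of_phi(phi, frame) == pytest.approx(
            lambda_3d_oracle(phi, frame), abs=1e-14
        )

    def test_regular_at_phi_equal_half_pi(self):
        """The sin form works where tan(phi) diverges."""
        frame, _ = canonical_frame(0.3, 0.3, 2.5)
        val = lambda_of_phi(math.pi / 2, frame)
        assert 0.0 < val < 1.0
        assert val == pytest.approx(lambda_3d_oracle(math.pi / 2, frame), abs=1e-14)

    def test_monotone(self):
        frame, _ = canonical_frame(0.25, 0.1, 1.3)
        phis = np.linspace(0.0, frame.alpha, 300)
        lams = lambda_of_phi(phis, frame)
        assert np.all(np.diff(lams) >= 0.0)


class TestDelta:
    def test_endpoints_zero(self):
        frame, _ = canonical_frame(0.2, 0.1, 1.0)
        assert delta_of_phi(0.0, frame) == pytest.approx(0.0, abs=1e-15)
        assert delta_of_phi(frame.alpha, frame) == pytest.approx(0.0, abs=1e-15)

    def test_midpoint_closed_form(self):
        frame, _ = canonical_frame(0.2, 0.2, 1.0)
        lam = 0.5
        expect = 1.0 - math.sqrt(1.0 - frame.zeta23 / 2.0)
        assert delta_of_phi(frame.alpha / 2, frame, lam) == pytest.approx(
            expect, abs=1e-15
        )

    @pytest.mark.parametrize("phi", [0.05, 0.3, 0.8])
    def test_against_vector_norm(self, phi):
        frame, _ = canonical_frame(0.22, 0.13, 0.9)
        lam = lambda_of_phi(phi, frame)
        p = frame.vertex_canonical(2) + lam * (
            frame.vertex_canonical(3) - frame.vertex_canonical(2)
        )
        assert delta_of_phi(phi, frame) == pytest.approx(
            1.0 - np.linalg.norm(p), abs=1e-14
        )


class TestSigma:
    def test_constant_density(self):
        frame, g = canonical_frame(0.2, 0.1, 1.0)
        dens = VertexDensities(0.7, 0.7, 0.7)
        rng = np.random.default_rng(1)
        for _ in range(30):
            phi = rng.uniform(0.0, frame.alpha)
            theta = rng.uniform(0.0, beta_of_phi(phi, g))
            assert sigma_at(theta, phi, frame, g, dens) == pytest.approx(
                0.7, abs=1e-13
            )

    def test_vertices_and_pole(self):
        frame, g = canonical_frame(0.2, 0.1, 1.0)
        dens = VertexDensities(1.0, 2.0, 3.0)
        assert sigma_at(0.0, 0.3, frame, g, dens) == 1.0
        assert sigma_at(frame.beta3, 0.0, frame, g, dens) == pytest.approx(
            2.0, abs=1e-12
        )
        assert sigma_at(frame.beta2, frame.alpha, frame, g, dens) == pytest.approx(
            3.0, abs=1e-12
        )

    def test_flat_centroid_value(self):
        """The point projecting to the flat-triangle centroid (lambda = 1/2,
        t = 2/3) interpolates to the mean of the vertex densities."""
        frame, g = canonical_frame(0.2, 0.2, 0.8)
        dens = VertexDensities(1.0, 2.0, 3.0)
        phi = frame.alpha / 2  # lambda = 1/2 by symmetry
        co = interpolation_coefficients(phi, frame, g)
        # solve t(theta) = 2/3 for theta
        thetas = np.linspace(0.0, co.beta, 200001)
        tv = t_of_theta(thetas, co.C, co.D)
        theta = float(np.interp(2.0 / 3.0, tv, thetas))
        assert sigma_at(theta, phi, frame, g, dens) == pytest.approx(
            2.0, abs=1e-8
        )

    def test_outside_patch_rejected(self):
        frame, g = canonical_frame(0.2, 0.1, 1.0)
        dens = VertexDensities(1.0, 2.0, 3.0)
        with pytest.raises(ValueError):
            sigma_at(0.05, frame.alpha + 0.2, frame, g, dens)
        with pytest.raises(ValueError):
            sigma_at(beta_of_phi(0.3, g) + 0.05, 0.3, frame, g, dens)

    def test_range_bounded_by_vertex_values(self):
        frame, g = canonical_frame(0.3, 0.2, 1.1)
        dens = VertexDensities(-0.5, 1.0, 0.3)
        lo, hi = -0.5, 1.0
        for phi in np.linspace(0.0, frame.alpha, 100):
            beta = beta_of_phi(phi, g)
            for theta in np.linspace(0.0, beta, 100):
                v = sigma_at(theta, phi, frame, g, dens)
                assert lo - 1e-12 <= v <= hi + 1e-12

    def test_edge_consistency_between_patches(self):
        """Two patches sharing a great-arc edge interpolate identically on
        it: the chord fraction is intrinsic to the chord."""
        a = np.array([0.0, 0.0, 1.0])
        b = np.array([math.sin(0.25), 0.0, math.cos(0.25)])
        cdir = np.array(
            [math.sin(0.2) * math.cos(1.0), math.sin(0.2) * math.sin(1.0), math.cos(0.2)]
        )
        ddir = np.array(
            [math.sin(0.22) * math.cos(-0.9), math.sin(0.22) * math.sin(-0.9), math.cos(0.22)]
        )
        sig_a, sig_b = 1.3, -0.4
        tri1 = SphericalTriangle(a, b, cdir)
        tri2 = SphericalTriangle(a, b, ddir)
        fr1 = canonicalize(tri1, 1)
        g1 = geodesic_params(fr1)
        d1 = VertexDensities.from_frame([sig_a, sig_b, 0.8], fr1)
        fr2 = canonicalize(tri2, 1)
        g2 = geodesic_params(fr2)
        d2 = VertexDensities.from_frame([sig_a, sig_b, -2.0], fr2)
        for t in np.linspace(0.001, 0.999, 50):
            p = a + t * (b - a)
            p = p / np.linalg.norm(p)
            s1 = sigma_at_point(p, fr1, g1, d1)
            s2 = sigma_at_point(p, fr2, g2, d2)
            assert s1 == pytest.approx(s2, abs=1e-12)

    def test_relabel_permutes_densities(self):
        tri = canonical_triangle(0.21, 0.12, 1.1)
        swapped = SphericalTriangle(tri.v1, tri.v3, tri.v2)
        fr = canonicalize(swapped, 1)
        dens = VertexDensities.from_frame([1.0, 2.0, 3.0], fr)
        # original v2 (here index 2 after swap) carries density 3.0 and is
        # mapped back to canonical slot 2
        assert (dens.sigma1, dens.sigma2, dens.sigma3) == (1.0, 3.0, 2.0)


class TestScalingOrders:
    def test_C_and_D_scaling(self):
        """Under uniform scaling of the side arcs, max|C| ~ s^2, max|D| ~ s."""
        scales = [0.2, 0.1, 0.05]
        maxC, maxD = [], []
        for s in scales:
            frame, g = canonical_frame(0.9 * s, 0.7 * s, 1.1)
            phis = np.linspace(1e-3, frame.alpha - 1e-3, 50)
            cs = [interpolation_coefficients(p, frame, g) for p in phis]
            maxC.append(max(abs(c.C) for c in cs))
            maxD.append(max(abs(c.D) for c in cs))
        slopeC = np.polyfit(np.log(scales), np.log(maxC), 1)[0]
        slopeD = np.polyfit(np.log(scales), np.log(maxD), 1)[0]
        assert abs(slopeC - 2.0) < 0.1
        assert abs(slopeD - 1.0) < 0.1

    def test_positivity_condition(self):
        """eta^2 cos^2 beta > 1 whenever (1 - delta/R) cos(beta) > 1/2."""
        frame, g = canonical_frame(0.3, 0.25, 1.3)
        for phi in np.linspace(1e-4, frame.alpha - 1e-4, 60):
            co = interpolation_coefficients(phi, frame, g)
            if (1.0 - co.delta_over_R) * math.cos(co.beta) > 0.5:
                assert co.eta_sq * math.cos(co.beta) ** 2 > 1.0


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    phi_frac=st.floats(0.0, 1.0),
    theta_frac=st.floats(0.0, 1.0),
    b2=st.floats(0.05, 0.45),
    b3=st.floats(0.05, 0.45),
    alpha=st.floats(0.3, 2.8),
)
def test_t_parameter_bounds(phi_frac, theta_frac, b2, b3, alpha):
    """t(0) = 0 and t(beta(phi)) = 1: the projection fraction spans [0, 1]
    along every radial slice of the patch."""
    frame, g = canonical_frame(b2, b3, alpha)
    phi = phi_frac * frame.alpha
    co = interpolation_coefficients(phi, frame, g)
    assert t_of_theta(0.0, co.C, co.D) == 0.0
    assert t_of_theta(co.beta, co.C, co.D) == pytest.approx(1.0, abs=1e-12)
    t = t_of_theta(theta_frac * co.beta, co.C, co.D)
    assert -1e-12 <= t <= 1.0 + 1e-12
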