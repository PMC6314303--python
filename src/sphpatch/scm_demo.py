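"""Demonstration boundary solve: induced charge on a dielectric sphere.

A point charge q sits inside (or outside) a sphere of radius R = 1 with
permittivity ``eps_in`` inside and ``eps_out`` outside.  In the surface
charge method the polarization is represented by an induced surface density
sigma on the interface; potentials and fields are vacuum Coulomb sums over
the source charge and sigma.  The interface condition
eps_in E_n(R-) = eps_out E_n(R+), with E_n(R+/-) = E_n^PV +/- 2 pi sigma,
gives the linear equation

    sigma = f * (E_n^source + E_n^PV[sigma]),
    f = (eps_in - eps_out) / (2 pi (eps_in + eps_out)),

solved here for vertex densities on an icosphere mesh whose faces are the
curved spherical-triangle patches of this package: self/neighbor patch
contributions use the vertex field series (or the regularized quadrature
oracle when a face is too large), distant patches the moment expansion
gated by the convergence criterion, near-but-not-incident patches a fixed
high-order product Gauss rule.

The analytic reference is the classical Legendre-series solution; for a
charge at distance b < R from the center,

    sigma_l = f q (l+1) b^l / (1 - 2 pi f / (2l+1)),
    sigma(gamma) = sum_l sigma_l P_l(cos gamma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

from .density import VertexDensities
from .geometry import SphericalTriangle, canonicalize, geodesic_params
from .patch_moments import area, charge_moments
from .vertex_field import PatchTooLargeError, ez_continuous, DEFAULT_BETA_MAX
from . import oracle as _oracle

__all__ = [
    "DielectricScene",
    "SCMResult",
    "build_icosphere",
    "assemble_and_solve",
    "legendre_surface_charge",
    "total_induced_charge",
]


@dataclass
class DielectricScene:
    """One dielectric sphere (R = 1, centered at origin) with point
    charges off the surface."""

    eps_in: float
    eps_out: float
    charges: list  # list of (position (3,), q)
    level: int = 2

    def __post_init__(self):
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValueError("permittivities must be positive")
        for pos, _q in self.charges:
            r = np.linalg.norm(np.asarray(pos, dtype=float))
            if abs(r - 1.0) < 1e-9:
                raise ValueError("point charge on the sphere surface")


@dataclass
class SCMResult:
    vertices: np.ndarray     # (N, 3) unit vectors
    faces: np.ndarray        # (M, 3) vertex indices
    sigma: np.ndarray        # (N,) vertex densities
    residual: float          # max |boundary-condition residual|
    total_charge: float      # sum of patch charges from the solution
    vertex_weights: np.ndarray = field(default=None)  # area weights (N,)


# ---------------------------------------------------------------------------
# icosphere
# ---------------------------------------------------------------------------

def build_icosphere(level: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Subdivided icosahedron on the unit sphere: 20 * 4^level faces, all
    edges great arcs (any two surface points are joined by one).  Returns
    (vertices, faces)."""
    if level < 0:
        raise ValueError("level must be >= 0")
    t = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=int)
    for _ in range(level):
        verts_list = [v for v in verts]
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts_list[i] + verts_list[j]
                m /= np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=int)
    return verts, faces


# ---------------------------------------------------------------------------
# analytic reference
# ---------------------------------------------------------------------------

def legendre_surface_charge(
    gamma, q: float, b: float, eps_in: float, eps_out: float, n_terms: int = 50
):
    """Analytic induced surface density at polar angle(s) ``gamma`` from the
    source direction, for a charge q at radius b < 1 inside the sphere."""
    f = (eps_in - eps_out) / (2.0 * math.pi * (eps_in + eps_out))
    ls = np.arange(n_terms + 1)
    coef = f * q * (ls + 1.0) * b**ls / (1.0 - 2.0 * math.pi * f / (2.0 * ls + 1.0))
    return npleg.legval(np.cos(np.asarray(gamma, dtype=float)), coef)


def total_induced_charge(q: float, eps_in: float, eps_out: float) -> float:
    """Sum rule for the total induced surface charge seen from outside."""
    return q * (1.0 / eps_out - 1.0)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _face_basis_ez_coeffs(tri, vid, beta_max):
    """Coefficients (c_a, c_b, c_c) of the continuous vertex field at the
    face vertex ``vid`` (1-based) as a linear function of the densities at
    the face's own vertices."""
    frame = canonicalize(tri, pole_index=vid)
    g = geodesic_params(frame)
    coeffs = np.zeros(3)
    for k in range(3):
        basis = np.zeros(3)
        basis[k] = 1.0
        dens = VertexDensities.from_frame(basis, frame)
        try:
            coeffs[k] = ez_continuous(frame, g, dens, order=3, beta_max=beta_max).value
        except PatchTooLargeError:
            coeffs[k] = _oracle.vertex_ez_quadrature(frame, g, dens)
    return coeffs


def _gauss_nodes(frame, g, n_phi=16, n_theta=12):
    """Fixed product Gauss rule over the patch, with per-node positions,
    weights and the three basis density values."""
    from numpy.polynomial.legendre import leggauss
    from .density import interpolation_coefficients, t_of_theta

    xp, wp = leggauss(n_phi)
    xt, wt = leggauss(n_theta)
    phis = 0.5 * frame.alpha * (xp + 1.0)
    wphis = 0.5 * frame.alpha * wp
    pos, wgt, bas = [], [], []
    from .geometry import beta_of_phi
    for phi, wphi in zip(phis, wphis):
        beta = beta_of_phi(phi, g)
        co = interpolation_coefficients(phi, frame, g)
        thetas = 0.5 * beta * (xt + 1.0)
        wthetas = 0.5 * beta * wt * np.sin(thetas)
        tvals = t_of_theta(thetas, co.C, co.D)
        s, c = np.sin(thetas), np.cos(thetas)
        pts = np.stack(
            [s * math.cos(phi), s * math.sin(phi), c], axis=1
        )
        pos.append(pts)
        wgt.append(wphi * wthetas)
        # basis densities at nodes in canonical order (1, 2, 3)
        b1 = 1.0 - tvals
        b2 = tvals * (1.0 - co.lam)
        b3 = tvals * co.lam
        bas.append(np.stack([b1, b2, b3], axis=1))
    return (
        np.concatenate(pos),
        np.concatenate(wgt),
        np.concatenate(bas),
    )


def assemble_and_solve(
    scene: DielectricScene,
    beta_max: float = DEFAULT_BETA_MAX,
    near_margin: float = 0.0,
) -> SCMResult:
    """Solve the discrete boundary condition for the vertex densities.

    Builds the dense influence matrix M with M[i, j] the principal-value
    normal field at vertex i per unit density at vertex j, then solves
    (I - f M) sigma = f E_n^source.
    """
    verts, faces = build_icosphere(scene.level)
    nv = len(verts)
    f = (scene.eps_in - scene.eps_out) / (
        2.0 * math.pi * (scene.eps_in + scene.eps_out)
    )

    # source normal field (vacuum Coulomb)
    e_src = np.zeros(nv)
    for pos, q in scene.charges:
        pos = np.asarray(pos, dtype=float)
        d = verts - pos
        dist = np.linalg.norm(d, axis=1)
        e_src += q * np.einsum("ij,ij->i", d, verts) / dist**3

    M = np.zeros((nv, nv))
    face_area = np.zeros(len(faces))
    face_q0_basis = np.zeros((len(faces), 3))

    for fi, (a, b, c) in enumerate(faces):
        tri = SphericalTriangle(verts[a], verts[b], verts[c])
        idx = np.array([a, b, c])
        frame = canonicalize(tri, pole_index=1)
        g = geodesic_params(frame)
        face_area[fi] = area(frame, g)

        # basis moments in the face frame (canonical order -> face order)
        basis_moms = []
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            basis_moms.append(
                charge_moments(frame, g, VertexDensities.from_frame(e, frame))
            )
        face_q0_basis[fi] = [m.q0 for m in basis_moms]

        # incident vertices: continuous vertex-field series
        for local, vid in enumerate(idx):
            coeffs = _face_basis_ez_coeffs(tri, local + 1, beta_max)
            M[vid, idx] += coeffs

        # all other vertices: expansion where the gate passes, fixed
        # quadrature otherwise
        others = np.ones(nv, dtype=bool)
        others[idx] = False
        oidx = np.nonzero(others)[0]
        dirs = verts[oidx]
        lhs = 1.0 - dirs @ (verts[a] + verts[b] + verts[c]) / 3.0
        mindot = min(
            verts[a] @ verts[b], verts[b] @ verts[c], verts[a] @ verts[c]
        )
        margin = lhs - 2.0 * (1.0 - mindot)
        far = margin > near_margin

        dc = frame.to_canonical(dirs[far])  # (nf, 3)
        for k, mom in enumerate(basis_moms):
            c0 = dc @ mom.t
            one_m = 1.0 - c0
            dm1 = dc @ mom.m1
            dm2 = np.einsum("ij,jk,ik->i", dc, mom.m2, dc)
            x1 = (dm1 - c0 * mom.q0) / one_m
            x2 = (dm2 - 2.0 * c0 * dm1 + c0 * c0 * mom.q0) / one_m**2
            vals = (mom.q0 + 0.5 * x1 + 0.375 * x2) / (
                2.0 * np.sqrt(2.0 * one_m)
            )
            M[oidx[far], idx[k]] += vals

        near_idx = oidx[~far]
        if len(near_idx):
            pos, wgt, bas = _gauss_nodes(frame, g)
            dcn = frame.to_canonical(verts[near_idx])  # (nn, 3)
            cosang = dcn @ pos.T                        # (nn, nq)
            kern = wgt / (2.0 * np.sqrt(2.0 - 2.0 * cosang))
            contrib = kern @ bas                        # (nn, 3) canonical
            M[near_idx[:, None], idx[None, :]] += contrib

    rhs = f * e_src
    sigma = np.linalg.solve(np.eye(nv) - f * M, rhs)
    residual = float(np.max(np.abs((np.eye(nv) - f * M) @ sigma - rhs)))

    total = float(face_q0_basis.ravel() @ sigma[faces].ravel())
    # vertex area weights: 1/3 of incident face areas
    weights = np.zeros(nv)
    np.add.at(weights, faces.ravel(), np.repeat(face_area / 3.0, 3))
    return SCMResult(
        vertices=verts,
        faces=faces,
        sigma=sigma,
        residual=residual,
        total_charge=total,
        vertex_weights=weights,
    )
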